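"""Rule-based predictor of DNA damage response outcomes as a function of
laser dose band and pharmacological treatment.

The underlying biology, condensed into deterministic rules: low input-power
microirradiation produces relatively simple strand breaks at low density —
53BP1 is recruited robustly and persistently, PARP activation is weak and
TRF2 stays away.  High input power produces dense strand breaks plus
complex damage (UV-type crosslinks, oxidative base damage) — PARP signaling
is robust, TRF2 is recruited within a minute and leaves by ~5 min, while
53BP1 clustering is suppressed both by PAR itself and by ATM/DNA-PK-driven
pan-nuclear gamma-H2AX that disperses MDC1.  Inhibiting PARP (Pi) removes
PAR and TRF2 recruitment and de-represses 53BP1; inhibiting ATM+DNA-PK
(Ai+Di) re-localizes gamma-H2AX and MDC1 and partially restores 53BP1;
all three together restore 53BP1 fully; stabilizing PAR with a PARG
inhibitor suppresses 53BP1 even at low dose.  A high-dose site also
suppresses 53BP1 at a co-irradiated low-dose site in the same nucleus
(trans-inhibition), unless the responsible signaling is inhibited.

Recruitment-type markers live on a 4-point ordinal scale
``none < weak < robust < enhanced``; spatial-pattern markers
(gamma-H2AX, MDC1, pChk1/2) use categorical pattern values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .dosimetry import LaserSystemSpec
from .errors import InvalidArgumentError, OutOfRangeError

__all__ = [
    "ORDINAL_LEVELS",
    "MARKERS",
    "RecruitmentThresholds",
    "TreatmentCondition",
    "DDRPrediction",
    "dose_band",
    "predict",
    "trans_inhibition",
]

#: 4-point ordinal intensity scale for recruitment/level markers.
ORDINAL_LEVELS = ("none", "weak", "robust", "enhanced")

_PATTERN_LEVELS = {
    "gammaH2AX_pattern": ("none", "local", "pan_nuclear"),
    "MDC1_at_site": ("at_site", "dispersed"),
    "pChk1_pattern": ("none", "at_site", "pan_nuclear", "suppressed"),
    "pChk2_pattern": ("none", "at_site", "pan_nuclear", "suppressed"),
}

_ORDINAL_MARKERS = (
    "53BP1_early",
    "53BP1_late",
    "TRF2",
    "PAR",
    "Ub",
    "CPD",
    "base_damage_NTH1",
    "XPA",
)

#: Every marker the predictor reports, with its allowed level set.
MARKERS: Mapping[str, tuple[str, ...]] = {
    **{m: ORDINAL_LEVELS + (("occasional",) if m == "XPA" else ()) for m in _ORDINAL_MARKERS},
    **_PATTERN_LEVELS,
}

_VALID_INHIBITORS = frozenset({"Pi", "Ai", "Di", "PARGi"})
_VALID_KNOCKDOWNS = frozenset({"PARP1_siRNA", "TRF2_siRNA"})

BANDS = ("sub_threshold", "low", "high")


@dataclass(frozen=True)
class RecruitmentThresholds:
    """Operational recruitment thresholds, expressed in instrument power
    settings per system (the dose bands are system-relative; cross-system
    comparison goes through the dosimetry module's irradiances).

    ``per_system`` maps a system name to (low, high): below ``low`` neither
    reporter is recruited in a majority of cells; from ``low`` 53BP1
    responds; from ``high`` 53BP1 early recruitment is lost and TRF2
    responds.  Detection windows are the monitoring periods used to score a
    cell as recruited; the majority rule is a strict > fraction.
    """

    per_system: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"Mira-900": (25.0, 85.0), "Meta": (15.0, 25.0)}
    )
    detection_window_min: Mapping[str, float] = field(
        default_factory=lambda: {"53BP1": 15.0, "TRF2": 6.0}
    )
    majority_rule: float = 0.5

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.per_system.items():
            if not lo < hi:
                raise InvalidArgumentError(
                    f"{name}: low threshold must be < high threshold"
                )
        if not (0 < self.majority_rule < 1):
            raise InvalidArgumentError("majority_rule must be in (0, 1)")

    def bands_for(self, system_name: str) -> tuple[float, float]:
        try:
            return self.per_system[system_name]
        except KeyError:
            raise InvalidArgumentError(
                f"no recruitment thresholds configured for system {system_name!r}"
            ) from None


@dataclass(frozen=True)
class TreatmentCondition:
    """Pharmacological / genetic state of the irradiated cell."""

    inhibitors: frozenset[str] = frozenset()
    knockdowns: frozenset[str] = frozenset()
    hoechst: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "inhibitors", frozenset(self.inhibitors))
        object.__setattr__(self, "knockdowns", frozenset(self.knockdowns))
        bad = self.inhibitors - _VALID_INHIBITORS
        if bad:
            raise InvalidArgumentError(f"unknown inhibitor token(s): {sorted(bad)}")
        bad = self.knockdowns - _VALID_KNOCKDOWNS
        if bad:
            raise InvalidArgumentError(f"unknown knockdown token(s): {sorted(bad)}")

    @classmethod
    def from_tokens(cls, tokens: Iterable[str]) -> "TreatmentCondition":
        """Build a condition from flat CLI-style tokens
        ({Pi, Ai, Di, PARGi, PARP1_siRNA, TRF2_siRNA, hoechst})."""
        inhibitors, knockdowns, hoechst = set(), set(), False
        for t in tokens:
            if t in _VALID_INHIBITORS:
                inhibitors.add(t)
            elif t in _VALID_KNOCKDOWNS:
                knockdowns.add(t)
            elif t == "hoechst":
                hoechst = True
            else:
                raise InvalidArgumentError(f"unknown condition token {t!r}")
        return cls(frozenset(inhibitors), frozenset(knockdowns), hoechst)


@dataclass(frozen=True)
class DDRPrediction:
    """Qualitative per-marker outcome for one irradiated site."""

    system: str
    power_setting: float
    band: str
    condition: TreatmentCondition
    marker_levels: Mapping[str, str]
    timing_notes: Mapping[str, str]
    endogenous_trf2_detectable: bool = False

    def __post_init__(self) -> None:
        for marker, level in self.marker_levels.items():
            if marker not in MARKERS:
                raise InvalidArgumentError(f"unknown marker {marker!r}")
            if level not in MARKERS[marker]:
                raise InvalidArgumentError(
                    f"level {level!r} not allowed for marker {marker}"
                )


_BASELINES: dict[str, dict[str, str]] = {
    # Below the 53BP1 detection threshold: strand breaks are induced and
    # marked locally, but no reporter is recruited in a majority of cells.
    "sub_threshold": {
        "53BP1_early": "none",
        "53BP1_late": "none",
        "TRF2": "none",
        "PAR": "none",
        "Ub": "weak",
        "CPD": "none",
        "base_damage_NTH1": "none",
        "XPA": "none",
        "gammaH2AX_pattern": "local",
        "MDC1_at_site": "at_site",
        "pChk1_pattern": "none",
        "pChk2_pattern": "none",
    },
    "low": {
        "53BP1_early": "robust",
        "53BP1_late": "robust",
        "TRF2": "none",
        "PAR": "weak",
        "Ub": "robust",
        "CPD": "none",
        "base_damage_NTH1": "none",
        "XPA": "none",
        "gammaH2AX_pattern": "local",
        "MDC1_at_site": "at_site",
        "pChk1_pattern": "none",
        "pChk2_pattern": "none",
    },
    "high": {
        "53BP1_early": "none",
        "53BP1_late": "weak",
        "TRF2": "robust",
        "PAR": "robust",
        "Ub": "weak",
        "CPD": "robust",
        "base_damage_NTH1": "robust",
        "XPA": "occasional",
        "gammaH2AX_pattern": "pan_nuclear",
        "MDC1_at_site": "dispersed",
        "pChk1_pattern": "at_site",
        "pChk2_pattern": "pan_nuclear",
    },
}

_TIMING_NOTES: dict[str, dict[str, str]] = {
    "low": {
        "53BP1_early": "detectable 5-7 min p.i., increasing through first 30 min",
        "53BP1_late": "peaks ~3-4 h p.i., largely retained past 24 h",
    },
    "high": {
        "53BP1_late": "weak delayed clustering from ~4 h p.i.",
        "TRF2": "within 1 min p.i., transient, mostly limited to first 5 min",
        "PAR": "rapid and transient",
    },
    "sub_threshold": {},
}


def _upgrade(level: str) -> str:
    i = ORDINAL_LEVELS.index(level)
    return ORDINAL_LEVELS[min(i + 1, len(ORDINAL_LEVELS) - 1)]


def _upgrade_pattern(level: str) -> str:
    scale = ("none", "local", "pan_nuclear")
    i = scale.index(level)
    return scale[min(i + 1, len(scale) - 1)]


def dose_band(
    system: LaserSystemSpec,
    power_setting: float,
    thresholds: RecruitmentThresholds | None = None,
) -> str:
    """Assign a power setting to the sub-threshold / low / high dose band.

    Band edges are inclusive on the upper side: the low band starts at the
    53BP1 detection threshold and the high band at the 53BP1-loss / TRF2
    threshold.
    """
    thresholds = thresholds or RecruitmentThresholds()
    lo, hi = system.calibration.domain
    if not (lo <= power_setting <= hi):
        raise OutOfRangeError(
            f"setting {power_setting} outside calibration domain of {system.name}"
        )
    low, high = thresholds.bands_for(system.name)
    if power_setting < low:
        return "sub_threshold"
    if power_setting < high:
        return "low"
    return "high"


def predict(
    system: LaserSystemSpec,
    power_setting: float,
    condition: TreatmentCondition | None = None,
    thresholds: RecruitmentThresholds | None = None,
) -> DDRPrediction:
    """Predict per-marker outcomes for one irradiated site.

    The prediction is a pure function of (band, condition): the band
    selects a baseline marker table and the condition applies a fixed set
    of modifier rules, evaluated as predicates on the whole condition set,
    so commuting modifiers are order-independent by construction.
    """
    condition = condition or TreatmentCondition()
    band = dose_band(system, power_setting, thresholds)
    levels = dict(_BASELINES[band])
    notes = dict(_TIMING_NOTES[band])
    endogenous_trf2 = False

    pi = "Pi" in condition.inhibitors
    ai = "Ai" in condition.inhibitors
    di = "Di" in condition.inhibitors
    pargi = "PARGi" in condition.inhibitors
    parp1_kd = "PARP1_siRNA" in condition.knockdowns
    # TRF2_siRNA intentionally has no effect on any predicted marker
    # (PARP1 localization is TRF2-independent).

    if pi or parp1_kd:
        # PAR-dependent TRF2 targeting is lost whenever PAR synthesis is.
        levels["TRF2"] = "none"
        notes.pop("TRF2", None)
    if pi:
        levels["PAR"] = "none"
        # De-repression of 53BP1: enhanced at low dose, partial restore at
        # high dose.
        levels["53BP1_early"] = _upgrade(levels["53BP1_early"])
    if ai and di:
        # DDR-kinase inhibition reverses gamma-H2AX spreading and MDC1
        # dispersion, and silences checkpoint-kinase phosphorylation.
        levels["gammaH2AX_pattern"] = "local"
        levels["MDC1_at_site"] = "at_site"
        if levels["pChk2_pattern"] != "none":
            levels["pChk2_pattern"] = "suppressed"
        if band == "high":
            levels["53BP1_early"] = _upgrade(levels["53BP1_early"])
    elif ai or di:
        # Only the combination was characterized; a single kinase inhibitor
        # is modeled as a partial 53BP1 restore at high dose with no
        # pattern changes (documented extrapolation).
        if band == "high":
            levels["53BP1_early"] = _upgrade(levels["53BP1_early"])
    if pi and ai and di:
        # Joint release of both inhibitory arms: full 53BP1 restoration.
        levels["53BP1_early"] = "robust"
    if pargi:
        # PARG inhibition stabilizes PAR chains, amplifying the PAR signal
        # and suppressing 53BP1 at doses where it would otherwise respond.
        levels["PAR"] = _upgrade(levels["PAR"])
        if band == "low":
            levels["53BP1_early"] = "weak"
            notes["53BP1_early"] = "discernible in a minority of cells, weaker signal"
    if condition.hoechst:
        # Photosensitization increases strand breaks (gamma-H2AX up) and is
        # required to visualize the endogenous TRF2 at all.
        levels["gammaH2AX_pattern"] = _upgrade_pattern(levels["gammaH2AX_pattern"])
        endogenous_trf2 = True

    return DDRPrediction(
        system=system.name,
        power_setting=float(power_setting),
        band=band,
        condition=condition,
        marker_levels=levels,
        timing_notes=notes,
        endogenous_trf2_detectable=endogenous_trf2,
    )


def trans_inhibition(predictions: Sequence[DDRPrediction]) -> list[DDRPrediction]:
    """Adjust co-irradiated sites within one nucleus for trans-acting
    suppression of 53BP1.

    A high-band site floods the shared nucleus with inhibitory signaling
    (PAR plus pan-nuclear gamma-H2AX), so early 53BP1 recruitment at any
    low-band site in the same nucleus is lost — unless PARP or ATM+DNA-PK
    signaling is pharmacologically silenced, in which case the per-site
    modifier rules already encode the restoration.  No marker other than
    53BP1_early is ever touched.
    """
    if not predictions:
        raise InvalidArgumentError("need at least one site prediction")
    condition = predictions[0].condition
    if any(p.condition != condition for p in predictions):
        raise InvalidArgumentError("all sites must share one treatment condition")
    any_high = any(p.band == "high" for p in predictions)
    pi = "Pi" in condition.inhibitors
    aidi = {"Ai", "Di"} <= condition.inhibitors
    if not any_high or pi or aidi:
        return list(predictions)
    adjusted = []
    for p in predictions:
        if p.band == "low":
            levels = dict(p.marker_levels)
            levels["53BP1_early"] = "none"
            notes = dict(p.timing_notes)
            notes["53BP1_early"] = "suppressed in trans by co-irradiated high-dose site"
            p = replace(p, marker_levels=levels, timing_notes=notes)
        adjusted.append(p)
    return adjusted
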