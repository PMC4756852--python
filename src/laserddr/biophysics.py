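"""Closed-form biophysics of femtosecond NIR microirradiation: photothermal
confinement, inter-macropulse cooling, thermoelastic stress confinement and
damage-mechanism threshold classification.

The calculus is deliberately simple — every quantity is an algebraic
function of laser and medium constants:

* thermal diffusion time        T_d   = 0.124 lambda^2 / (k NA^2)
* heat retained after a delay   dT(t)/dT(0) = 1 - exp(-d^2 / (4 k t))
* stress relaxation factor      tau_m = t_p c_s / d

Peak irradiances are compared against literature thresholds for
photochemical damage (0.26e12 W/cm^2), thermoelastic stress confinement
damage (5e12) and optical breakdown / plasma formation (6e12); low-density
plasma effects are flagged from 5% of the plasma-formation threshold.
Thresholds are compared, never derived.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .dosimetry import DoseRow, LaserSystemSpec
from .errors import InvalidArgumentError

__all__ = [
    "MediumConstants",
    "DamageThresholds",
    "RegimeFlags",
    "BiophysicsReport",
    "thermal_diffusion_time",
    "is_thermally_confined",
    "heat_retained_fraction",
    "stress_relaxation_factor",
    "classify_regime",
    "biophysics_report",
]

_NM = 1e-9
_FS = 1e-15
_UM = 1e-6
_MS = 1e-3
_NS = 1e-9


@dataclass(frozen=True)
class MediumConstants:
    """Thermo-mechanical constants of the irradiated medium.

    Defaults treat the surroundings as water (thermal diffusivity
    1.4e-7 m^2/s, speed of sound 2600 m/s) and the interphase chromatin
    target as a uniformly heated 1 um slab.
    """

    thermal_diffusivity_m2_s: float = 1.4e-7
    speed_of_sound_m_s: float = 2600.0
    slab_thickness_um: float = 1.0

    def __post_init__(self) -> None:
        if (
            self.thermal_diffusivity_m2_s <= 0
            or self.speed_of_sound_m_s <= 0
            or self.slab_thickness_um <= 0
        ):
            raise InvalidArgumentError("medium constants must all be > 0")


@dataclass(frozen=True)
class DamageThresholds:
    """Literature peak-irradiance thresholds for fs NIR damage mechanisms,
    in W/cm^2, plus the energy fraction at which low-density plasma effects
    become plausible."""

    photochemical_w_cm2: float = 0.26e12
    thermoelastic_confinement_w_cm2: float = 5e12
    plasma_formation_w_cm2: float = 6e12
    low_density_plasma_energy_fraction: float = 0.05

    def __post_init__(self) -> None:
        if min(
            self.photochemical_w_cm2,
            self.thermoelastic_confinement_w_cm2,
            self.plasma_formation_w_cm2,
        ) <= 0:
            raise InvalidArgumentError("thresholds must be > 0")
        if not (0 < self.low_density_plasma_energy_fraction < 1):
            raise InvalidArgumentError(
                "low_density_plasma_energy_fraction must be in (0, 1)"
            )


@dataclass(frozen=True)
class RegimeFlags:
    above_photochemical: bool
    above_stress_threshold: bool
    above_plasma: bool
    low_density_plasma_possible: bool


@dataclass(frozen=True)
class BiophysicsReport:
    """All confinement quantities and threshold flags for one dose.

    ``heat_retained_fraction`` is populated only for gated (macropulsed)
    delivery, where an inter-macropulse cooling gap exists; continuously
    scanning systems have no such gap and the field is None.
    """

    system: str
    power_setting: float
    peak_irradiance_w_cm2: float
    thermal_diffusion_time_ns: float
    thermally_confined: bool
    heat_retained_fraction: float | None
    stress_relaxation_factor: float
    stress_confined: bool
    above_photochemical: bool
    above_stress_threshold: bool
    above_plasma: bool
    low_density_plasma_possible: bool


def thermal_diffusion_time(
    wavelength_nm: float, objective_na: float, thermal_diffusivity_m2_s: float
) -> float:
    """Thermal diffusion time constant T_d = 0.124 lambda^2 / (k NA^2), ns.

    ~289 ns for 800 nm / 1.4 NA and ~319 ns for 780 nm / 1.3 NA in water.
    """
    if wavelength_nm <= 0 or objective_na <= 0 or thermal_diffusivity_m2_s <= 0:
        raise InvalidArgumentError("all inputs must be > 0")
    lam = wavelength_nm * _NM
    t_d_s = 0.124 * lam**2 / (thermal_diffusivity_m2_s * objective_na**2)
    return t_d_s / _NS


def is_thermally_confined(thermal_diffusion_time_ns: float, pulse_width_fs: float) -> bool:
    """Photothermal confinement holds when heat cannot leave the focal
    volume within one pulse: T_d > t_p."""
    if thermal_diffusion_time_ns <= 0 or pulse_width_fs <= 0:
        raise InvalidArgumentError("times must be > 0")
    return thermal_diffusion_time_ns * _NS > pulse_width_fs * _FS


def heat_retained_fraction(
    slab_thickness_um: float,
    thermal_diffusivity_m2_s: float,
    delay_ms: float,
    warnings: list[str] | None = None,
) -> float:
    """Fraction of the temperature rise retained at the slab centre after a
    cooling delay: 1 - exp(-d^2 / (4 k t)).

    For a 1 um slab in water after the 100 ms gap between gated macropulses
    this is ~1.78e-5, i.e. essentially complete cooling.  ``delay_ms = 0``
    returns the limit value 1 and appends a note to ``warnings`` if given.
    """
    if slab_thickness_um <= 0 or thermal_diffusivity_m2_s <= 0 or delay_ms < 0:
        raise InvalidArgumentError("thickness and diffusivity must be > 0, delay >= 0")
    if delay_ms == 0:
        if warnings is not None:
            warnings.append("delay = 0: returning the no-cooling limit 1")
        return 1.0
    d = slab_thickness_um * _UM
    t = delay_ms * _MS
    return 1.0 - math.exp(-(d**2) / (4.0 * thermal_diffusivity_m2_s * t))


def stress_relaxation_factor(
    pulse_width_fs: float, speed_of_sound_m_s: float, slab_thickness_um: float
) -> float:
    """Stress relaxation factor tau_m = t_p c_s / d (dimensionless).

    Values << 1 mean the pulse ends long before stress waves can traverse
    the heated structure, so thermoelastic stress is confined.
    """
    if pulse_width_fs <= 0 or speed_of_sound_m_s <= 0 or slab_thickness_um <= 0:
        raise InvalidArgumentError("all inputs must be > 0")
    return pulse_width_fs * _FS * speed_of_sound_m_s / (slab_thickness_um * _UM)


def classify_regime(peak_irradiance_w_cm2: float, thresholds: DamageThresholds) -> RegimeFlags:
    """Compare a peak irradiance against the damage-mechanism thresholds.

    Comparisons are inclusive (>=); raising the irradiance never clears a
    flag.  Low-density plasma is flagged from the configured fraction of
    the plasma-formation threshold onward.
    """
    if peak_irradiance_w_cm2 <= 0:
        raise InvalidArgumentError("peak irradiance must be > 0")
    i = peak_irradiance_w_cm2
    return RegimeFlags(
        above_photochemical=i >= thresholds.photochemical_w_cm2,
        above_stress_threshold=i >= thresholds.thermoelastic_confinement_w_cm2,
        above_plasma=i >= thresholds.plasma_formation_w_cm2,
        low_density_plasma_possible=i
        >= thresholds.low_density_plasma_energy_fraction * thresholds.plasma_formation_w_cm2,
    )


def biophysics_report(
    system: LaserSystemSpec,
    dose: DoseRow,
    medium: MediumConstants | None = None,
    thresholds: DamageThresholds | None = None,
) -> BiophysicsReport:
    """Full confinement/threshold report for one system at one dose."""
    medium = medium or MediumConstants()
    thresholds = thresholds or DamageThresholds()
    t_d_ns = thermal_diffusion_time(
        system.wavelength_nm, system.objective_na, medium.thermal_diffusivity_m2_s
    )
    confined = is_thermally_confined(t_d_ns, system.pulse_width_fs)
    retained: float | None = None
    if system.macropulse is not None and system.macropulse.mode == "gated":
        retained = heat_retained_fraction(
            medium.slab_thickness_um,
            medium.thermal_diffusivity_m2_s,
            system.macropulse.gap_ms,
        )
    tau_m = stress_relaxation_factor(
        system.pulse_width_fs, medium.speed_of_sound_m_s, medium.slab_thickness_um
    )
    flags = classify_regime(dose.peak_irradiance_w_cm2, thresholds)
    return BiophysicsReport(
        system=system.name,
        power_setting=dose.power_setting,
        peak_irradiance_w_cm2=dose.peak_irradiance_w_cm2,
        thermal_diffusion_time_ns=t_d_ns,
        thermally_confined=confined,
        heat_retained_fraction=retained,
        stress_relaxation_factor=tau_m,
        stress_confined=tau_m < 1.0,
        above_photochemical=flags.above_photochemical,
        above_stress_threshold=flags.above_stress_threshold,
        above_plasma=flags.above_plasma,
        low_density_plasma_possible=flags.low_density_plasma_possible,
    )
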