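"""Laser dosimetry: from instrument power settings to in-situ pulse energy
and focal-spot peak irradiance.

Two femtosecond Ti:Sapphire NIR platforms are bundled as presets:

* ``Mira-900`` — 800 nm, 200 fs, 76 MHz, 63x/1.4 NA objective.  The power
  setting is the input power at the microscope side port in mW; the in-situ
  energy per pulse is linear in that setting (throughput coefficient fitted
  from the calibration table).
* ``Meta`` — 780 nm, 140 fs, 80 MHz, 100x/1.3 NA objective on a laser
  scanning microscope.  The power setting is the software transmission
  parameter in percent, which is *not* linear in delivered energy, so the
  calibration is a lookup table with linear interpolation between measured
  rows and no extrapolation.

All internal computation is in SI units; nJ, fs, nm, mW and W/cm^2 appear
only at the interface boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, OutOfRangeError

__all__ = [
    "PowerCalibration",
    "MacropulseStructure",
    "LaserSystemSpec",
    "DoseRow",
    "DoseTable",
    "focal_spot_diameter",
    "energy_per_pulse",
    "peak_irradiance",
    "dose_table",
    "MIRA_900",
    "META",
    "BUILTIN_SYSTEMS",
]

_NJ = 1e-9  # J per nJ
_FS = 1e-15  # s per fs
_NM = 1e-9  # m per nm
_CM2_PER_M2 = 1e4  # W/m^2 -> W/cm^2 divisor


@dataclass(frozen=True)
class PowerCalibration:
    """Measured relation between the instrument power setting and the
    in-situ energy per pulse.

    ``linear_throughput`` mode stores a single nJ-per-setting-unit
    coefficient.  ``lookup`` mode stores measured (setting, energy_nJ) rows,
    interpolated linearly in energy; settings outside the tabulated range
    raise :class:`OutOfRangeError` rather than extrapolate.
    """

    mode: str
    setting_unit: str = "mW"
    throughput_nj_per_unit: float | None = None
    rows: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("linear_throughput", "lookup"):
            raise InvalidArgumentError(f"unknown calibration mode {self.mode!r}")
        if self.setting_unit not in ("mW", "percent"):
            raise InvalidArgumentError(f"unknown setting unit {self.setting_unit!r}")
        if self.mode == "linear_throughput":
            if self.throughput_nj_per_unit is None or self.throughput_nj_per_unit <= 0:
                raise InvalidArgumentError("throughput_nj_per_unit must be > 0")
        else:
            if not self.rows or len(self.rows) < 2:
                raise InvalidArgumentError("lookup calibration needs >= 2 rows")
            settings = [r[0] for r in self.rows]
            energies = [r[1] for r in self.rows]
            if any(b <= a for a, b in zip(settings, settings[1:])):
                raise InvalidArgumentError("lookup settings must be strictly increasing")
            if any(b <= a for a, b in zip(energies, energies[1:])):
                raise InvalidArgumentError("lookup energies must be strictly increasing")
            if energies[0] <= 0:
                raise InvalidArgumentError("lookup energies must be positive")

    @property
    def domain(self) -> tuple[float, float]:
        """Closed [min, max] range of admissible power settings."""
        if self.mode == "lookup":
            return (self.rows[0][0], self.rows[-1][0])
        return (0.0, math.inf)


@dataclass(frozen=True)
class MacropulseStructure:
    """How micropulse trains are delivered: gated ms exposures with cooling
    gaps (point-and-shoot systems) or continuous raster scanning."""

    mode: str  # "gated" | "continuous"
    exposure_ms: float | None = None
    gap_ms: float | None = None
    pixel_dwell_us: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("gated", "continuous"):
            raise InvalidArgumentError(f"unknown macropulse mode {self.mode!r}")
        if self.mode == "gated" and (
            self.exposure_ms is None or self.gap_ms is None
            or self.exposure_ms <= 0 or self.gap_ms <= 0
        ):
            raise InvalidArgumentError("gated mode requires exposure_ms > 0 and gap_ms > 0")


@dataclass(frozen=True)
class LaserSystemSpec:
    """Immutable description of one microirradiation platform."""

    name: str
    wavelength_nm: float
    pulse_width_fs: float
    repetition_rate_mhz: float
    objective_na: float
    objective_transmission: float
    calibration: PowerCalibration
    macropulse: MacropulseStructure | None = None

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise InvalidArgumentError("wavelength_nm must be > 0")
        if self.pulse_width_fs <= 0:
            raise InvalidArgumentError("pulse_width_fs must be > 0")
        if self.repetition_rate_mhz <= 0:
            raise InvalidArgumentError("repetition_rate_mhz must be > 0")
        if not (0 < self.objective_na <= 1.7):
            raise InvalidArgumentError("objective_na must be in (0, 1.7]")
        if not (0 < self.objective_transmission <= 1):
            raise InvalidArgumentError("objective_transmission must be in (0, 1]")

    @property
    def spot_diameter_nm(self) -> float:
        return focal_spot_diameter(self.wavelength_nm, self.objective_na)


@dataclass(frozen=True)
class DoseRow:
    """One power setting fully resolved to physical dose quantities."""

    power_setting: float
    setting_unit: str
    spot_diameter_nm: float
    energy_per_pulse_nj: float
    peak_irradiance_w_cm2: float


@dataclass(frozen=True)
class DoseTable:
    system: str
    rows: tuple[DoseRow, ...] = field(default_factory=tuple)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "system": self.system,
                "setting": [r.power_setting for r in self.rows],
                "setting_unit": [r.setting_unit for r in self.rows],
                "spot_diameter_nm": [r.spot_diameter_nm for r in self.rows],
                "energy_nJ": [r.energy_per_pulse_nj for r in self.rows],
                "peak_irradiance_W_cm2": [r.peak_irradiance_w_cm2 for r in self.rows],
            }
        )


def focal_spot_diameter(wavelength_nm: float, objective_na: float) -> float:
    """Diffraction-limited (Airy) focal spot diameter, d = 1.22 lambda / NA.

    Returns nanometres.  For the bundled systems this gives ~697 nm
    (800 nm / 1.4 NA) and ~732 nm (780 nm / 1.3 NA).
    """
    if wavelength_nm <= 0 or objective_na <= 0:
        raise InvalidArgumentError("wavelength and NA must be > 0")
    return 1.22 * wavelength_nm / objective_na


def energy_per_pulse(system: LaserSystemSpec, power_setting: float) -> float:
    """In-situ energy per pulse (nJ) at the given instrument power setting.

    Linear-throughput systems scale the setting by the fitted coefficient;
    lookup systems return the tabulated or linearly interpolated energy.
    Settings outside the calibration domain raise :class:`OutOfRangeError`.
    """
    cal = system.calibration
    lo, hi = cal.domain
    if not math.isfinite(power_setting) or not (lo <= power_setting <= hi):
        raise OutOfRangeError(
            f"power setting {power_setting} {cal.setting_unit} outside "
            f"calibration domain [{lo}, {hi}] for {system.name}"
        )
    if cal.mode == "linear_throughput":
        return cal.throughput_nj_per_unit * power_setting
    settings = np.array([r[0] for r in cal.rows], dtype=float)
    energies = np.array([r[1] for r in cal.rows], dtype=float)
    return float(np.interp(power_setting, settings, energies))


def peak_irradiance(
    energy_per_pulse_nj: float, pulse_width_fs: float, spot_diameter_nm: float
) -> float:
    """Peak irradiance I = (E / t_p) / (pi (d/2)^2) in W/cm^2.

    The pulse is treated as a top-hat in time over the pulse width and a
    uniform disc over the Airy diameter.
    """
    if energy_per_pulse_nj <= 0 or pulse_width_fs <= 0 or spot_diameter_nm <= 0:
        raise InvalidArgumentError("energy, pulse width and spot diameter must be > 0")
    power_w = (energy_per_pulse_nj * _NJ) / (pulse_width_fs * _FS)
    radius_m = spot_diameter_nm * _NM / 2.0
    area_m2 = math.pi * radius_m**2
    return power_w / area_m2 / _CM2_PER_M2


def dose_table(system: LaserSystemSpec, settings: Sequence[float]) -> DoseTable:
    """Resolve a list of power settings into a full dose table.

    Rows are kept in the given order; each composes the Airy spot diameter,
    the calibrated pulse energy and the peak irradiance.
    """
    d_nm = system.spot_diameter_nm
    rows = []
    for s in settings:
        e_nj = energy_per_pulse(system, s)
        rows.append(
            DoseRow(
                power_setting=float(s),
                setting_unit=system.calibration.setting_unit,
                spot_diameter_nm=d_nm,
                energy_per_pulse_nj=e_nj,
                peak_irradiance_w_cm2=peak_irradiance(
                    e_nj, system.pulse_width_fs, d_nm
                ),
            )
        )
    return DoseTable(system=system.name, rows=tuple(rows))


# Throughput coefficient fitted from the 20 mW calibration row
# (5.33e-2 nJ / 20 mW); all other measured rows agree within rounding.
MIRA_900 = LaserSystemSpec(
    name="Mira-900",
    wavelength_nm=800.0,
    pulse_width_fs=200.0,
    repetition_rate_mhz=76.0,
    objective_na=1.4,
    objective_transmission=0.47,
    calibration=PowerCalibration(
        mode="linear_throughput",
        setting_unit="mW",
        throughput_nj_per_unit=5.33e-2 / 20.0,
    ),
    macropulse=MacropulseStructure(mode="gated", exposure_ms=10.0, gap_ms=100.0),
)

# The percent transmission parameter is demonstrably non-linear in delivered
# energy, hence a lookup calibration over the measured rows.
META = LaserSystemSpec(
    name="Meta",
    wavelength_nm=780.0,
    pulse_width_fs=140.0,
    repetition_rate_mhz=80.0,
    objective_na=1.3,
    objective_transmission=0.47,
    calibration=PowerCalibration(
        mode="lookup",
        setting_unit="percent",
        rows=((15.0, 1.91e-2), (20.0, 2.49e-2), (25.0, 3.10e-2)),
    ),
    macropulse=MacropulseStructure(mode="continuous", pixel_dwell_us=12.8),
)

BUILTIN_SYSTEMS: dict[str, LaserSystemSpec] = {
    MIRA_900.name: MIRA_900,
    META.name: META,
}
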