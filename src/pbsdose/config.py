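"""Beamline configuration: every fitted constant and tolerance in one validated tree.

The defaults are the published characterisation of the Manchester research
beamline (power-law spot sizes, scanning calibration, dose-per-MU parameters,
range–energy fit, electrometer timing). A YAML file can override any subset;
unknown keys are rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

__all__ = ["BeamlineConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised when a configuration file fails schema validation."""


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class PowerLaw(_Model):
    """y = coeff * E**exp with E in MeV."""

    coeff: float = Field(gt=0)
    exp: float


class ScanAxisConfig(_Model):
    coeff: float = Field(gt=0, description="a in mm/A = a*E^b")
    exp: float = Field(lt=0, description="b in mm/A = a*E^b")
    slew_A_per_10us: float = Field(gt=0)
    ref_speed_mps: float = Field(gt=0, description="measured scan speed at 245 MeV")


class SpotPowerLawConfig(_Model):
    h: PowerLaw = PowerLaw(coeff=239.494, exp=-0.723)
    v: PowerLaw = PowerLaw(coeff=188.177, exp=-0.631)


class ScanConfig(_Model):
    h: ScanAxisConfig = ScanAxisConfig(
        coeff=10.944, exp=-0.553, slew_A_per_10us=0.45, ref_speed_mps=10.64
    )
    v: ScanAxisConfig = ScanAxisConfig(
        coeff=7.853, exp=-0.542, slew_A_per_10us=0.17, ref_speed_mps=2.75
    )


class OpticsConfig(_Model):
    spot_power_law: SpotPowerLawConfig = SpotPowerLawConfig()
    scan: ScanConfig = ScanConfig()
    ref_energy_MeV: float = 245.0
    # rho=0 / 5%-growth-over-200mm divergence placeholders: the per-energy
    # Courant-Snyder table was not published, so defaults are synthetic.
    cs_default_rho: float = 0.0
    cs_growth_fraction_200mm: float = 0.05


class SurfaceCoeffs(_Model):
    """Coefficients of the two-factor rational 20 mm WET -> surface dose ratio."""

    a: float = 2.429e-02
    b: float = -6.587e-04
    c: float = 9.689e-07
    d: float = -2.426e-02
    e: float = 8.322e-07
    f: float = -3.347e-05
    g: float = 5.5290e-07
    h: float = -2.255e-04
    i: float = 1.023


class CalibrationConfig(_Model):
    x1: float = 4.615e-02
    x2: float = 6.913
    x3: float = 2.056e02
    d1: float = -3.699e-02
    d2: float = 5.213
    d3: float = -5.389
    t1: float = 3.613e-12
    t2: float = 4.086
    t3: float = 1.235e-13
    t4: float = 1.094e-01
    surface: SurfaceCoeffs = SurfaceCoeffs()
    # "adopted": negate x1 so chi rises to its plateau; "printed": use x1 as-is.
    chi_sign_convention: Literal["adopted", "printed"] = "adopted"
    tp_correction_factor: float = Field(default=1.0, gt=0)


class RangeConfig(_Model):
    coeff: float = Field(default=1.690e-02, gt=0)
    exponent: float = Field(default=1.809, gt=1.5, lt=2.1)


class WetConfig(_Model):
    chamber_window_mm: float = 2.029
    tank_window_mm: float = 5.952


class DepthDoseConfig(_Model):
    range: RangeConfig = RangeConfig()
    wet: WetConfig = WetConfig()


class DeliveryConfig(_Model):
    ref_energy_MeV: float = 245.0
    ref_current_nA: float = 800.0
    ref_peak_rate_Gy_per_s: float = 171.93
    detector_active_area_mm2: float = 3.8
    ref_spot_spacing_mm: float = 2.5
    pixel_pitch_mm: float = Field(default=0.5, gt=0)
    max_field_mm: tuple[float, float] = (400.0, 300.0)
    # MU counting rate per nA of nozzle current; not published, cancels in ratios.
    mu_rate_per_nozzle_nA: float = Field(default=100.0, gt=0)


class ElectrometerConfigModel(_Model):
    capacitance_pF: float = Field(default=100.0, gt=0)
    integration_time_us: float = Field(default=111.0, gt=0)
    reset_time_us: float = Field(default=49.0, gt=0)
    gain: float = Field(default=5.0, gt=0)
    fpga_sampling_kHz: float = Field(default=25.0, gt=0)
    max_current_uA: float = Field(default=5.6, gt=0)
    monitor_range_V: float = Field(default=10.0, gt=0)
    # counts per volt-second of integrated monitor signal; arbitrary, cancels in ratios
    mu_per_volt_second: float = Field(default=1000.0, gt=0)


class SimulateConfig(_Model):
    electrometer: ElectrometerConfigModel = ElectrometerConfigModel()
    dose_noise_rel: float = Field(default=0.01, ge=0)
    image_noise_rel: float = Field(default=0.01, ge=0)
    jitter_mm: float = Field(default=0.03, ge=0)
    seed: int = 12345


class QAConfig(_Model):
    hi_percent: float = 3.0
    dose_percent: float = 2.0
    repeatability_mm: float = 0.1
    sigma_percent: float = 10.0


class PhysicsConfig(_Model):
    proton_mass_MeV: float = 938.272


class BeamlineConfig(_Model):
    physics: PhysicsConfig = PhysicsConfig()
    optics: OpticsConfig = OpticsConfig()
    calibration: CalibrationConfig = CalibrationConfig()
    depthdose: DepthDoseConfig = DepthDoseConfig()
    delivery: DeliveryConfig = DeliveryConfig()
    simulate: SimulateConfig = SimulateConfig()
    qa: QAConfig = QAConfig()
    energy_min_MeV: float = 70.0
    energy_max_MeV: float = 245.0
    energy_extrapolation_max_MeV: float = 250.0
    energy_grid_step_MeV: float = 10.0
    energy_policy: Literal["warn", "strict"] = "warn"

    def energy_grid(self) -> list[float]:
        """Commissioned energy grid (10 MeV steps from 70, plus the 245 endpoint)."""
        grid: list[float] = []
        e = self.energy_min_MeV
        while e < self.energy_max_MeV - 1e-9:
            grid.append(e)
            e += self.energy_grid_step_MeV
        grid.append(self.energy_max_MeV)
        return grid

    def digest(self) -> str:
        """Stable short hash of the full constant set, stamped into reports."""
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | Path | None = None) -> BeamlineConfig:
    """Load a YAML config, applying defaults for any key not present.

    An empty (or absent) file yields the full default configuration. Unknown
    keys and malformed values raise :class:`ConfigError` naming the offender.
    """
    if path is None:
        return BeamlineConfig()
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:  # pragma: no cover - yaml error text varies
        raise ConfigError(f"could not parse config {path}: {exc}") from exc
    if data is None:
        return BeamlineConfig()
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    try:
        return BeamlineConfig.model_validate(data)
    except ValidationError as exc:
        keys = ", ".join(".".join(str(p) for p in err["loc"]) for err in exc.errors())
        raise ConfigError(f"invalid config keys: {keys}\n{exc}") from exc
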