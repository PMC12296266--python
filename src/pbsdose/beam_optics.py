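"""Beam optics between nozzle and focal plane.

Models the three fitted descriptions of the scanned pencil beam:

* energy-dependent power laws for the Gaussian spot sigma at the focal plane,
* the Courant-Snyder quadratic envelope sigma(z) around the focal plane,
* the scanning-magnet calibration (mm per ampere, again a power law in energy)
  and scan speed, which scales with relativistic momentum from its measured
  245 MeV reference values.

Depth z is measured in mm from the focal plane, negative toward the nozzle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._validation import check_energy, normalize_axis
from .config import BeamlineConfig

__all__ = [
    "SpotShapeModel",
    "CourantSnyderParams",
    "ScanCalibration",
    "relativistic_momentum",
    "sigma_at_depth",
    "fit_courant_snyder",
    "default_courant_snyder",
]

PROTON_MASS_MEV = 938.272


def relativistic_momentum(kinetic_energy, mass_MeV: float = PROTON_MASS_MEV):
    """Proton momentum in MeV/c from kinetic energy in MeV: sqrt(T(T+2m))."""
    t = np.asarray(kinetic_energy, dtype=float)
    if np.any(t < 0):
        raise ValueError(f"kinetic energy must be >= 0, got {kinetic_energy}")
    p = np.sqrt(t * (t + 2.0 * mass_MeV))
    return p if p.ndim else float(p)


@dataclass(frozen=True)
class SpotShapeModel:
    """Focal-plane spot sigma vs energy: sigma = coeff * E**exp per axis.

    An optional per-axis measured table ``{axis: (energies_MeV, sigmas_mm)}``
    overrides the power law with linear interpolation between its knots.
    """

    coeff_h: float = 239.494
    exp_h: float = -0.723
    coeff_v: float = 188.177
    exp_v: float = -0.631
    measured_table: dict | None = None
    energy_policy: str = "warn"

    def __post_init__(self):
        if self.coeff_h <= 0 or self.coeff_v <= 0:
            raise ValueError("spot power-law coefficients must be positive")
        if self.exp_h >= 0 or self.exp_v >= 0:
            raise ValueError("spot power-law exponents must be negative")

    @classmethod
    def from_config(cls, config: BeamlineConfig | None = None) -> "SpotShapeModel":
        cfg = config or BeamlineConfig()
        pl = cfg.optics.spot_power_law
        return cls(
            coeff_h=pl.h.coeff,
            exp_h=pl.h.exp,
            coeff_v=pl.v.coeff,
            exp_v=pl.v.exp,
            energy_policy=cfg.energy_policy,
        )

    def sigma(self, energy, axis):
        """Spot sigma in mm at the focal plane for the requested axis."""
        ax = normalize_axis(axis)
        e = check_energy(energy, policy=self.energy_policy)
        if self.measured_table and ax in self.measured_table:
            knots_e, knots_s = map(np.asarray, self.measured_table[ax])
            out = np.interp(e, knots_e, knots_s)
        elif ax == "h":
            out = self.coeff_h * np.asarray(e) ** self.exp_h
        else:
            out = self.coeff_v * np.asarray(e) ** self.exp_v
        out = np.asarray(out)
        return out if out.ndim else float(out)


def spot_sigma_focal(energy, axis, model: SpotShapeModel | None = None):
    """Focal-plane sigma (mm) from the default fitted power laws."""
    return (model or SpotShapeModel()).sigma(energy, axis)


@dataclass(frozen=True)
class CourantSnyderParams:
    """Envelope parameters at the focal plane for one transverse axis.

    sigma0 in mm, rho0 the dimensionless correlation (clipped to |rho| <= 0.99,
    matching the restriction used when fitting), phi0 the divergence in rad.
    """

    sigma0: float
    rho0: float
    phi0: float
    axis: str = "h"

    def __post_init__(self):
        if self.sigma0 <= 0:
            raise ValueError(f"sigma0 must be > 0, got {self.sigma0}")
        if abs(self.rho0) > 0.99 + 1e-12:
            raise ValueError(f"|rho0| must be <= 0.99, got {self.rho0}")
        if self.phi0 < 0:
            raise ValueError(f"phi0 must be >= 0, got {self.phi0}")
        object.__setattr__(self, "axis", normalize_axis(self.axis))

    @property
    def phi0_mrad(self) -> float:
        return self.phi0 * 1e3


def sigma_at_depth(z, params: CourantSnyderParams):
    """Envelope sigma (mm) at depth z (mm; negative toward the nozzle).

    sigma^2(z) = sigma0^2 - 2 rho0 sigma0 phi0 z + phi0^2 z^2.
    """
    z = np.asarray(z, dtype=float)
    s2 = (
        params.sigma0**2
        - 2.0 * params.rho0 * params.sigma0 * params.phi0 * z
        + params.phi0**2 * z**2
    )
    if np.any(s2 < 0):
        bad = np.asarray(z)[np.asarray(s2) < 0]
        raise ValueError(f"envelope sigma^2 negative at z = {bad} mm")
    s = np.sqrt(s2)
    return s if s.ndim else float(s)


def fit_courant_snyder(
    samples: Sequence[tuple[float, float]], axis: str = "h"
) -> CourantSnyderParams:
    """Least-squares fit of the envelope model to (z mm, sigma mm) samples.

    The model is an exact quadratic in sigma^2, so the fit is a linear
    least-squares problem: sigma^2 = A + B z + C z^2 with A = sigma0^2,
    B = -2 rho sigma0 phi, C = phi^2. rho is clipped to [-0.99, 0.99].
    """
    pts = np.asarray(list(samples), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (z, sigma) samples")
    z, sig = pts[:, 0], pts[:, 1]
    if np.unique(z).size < 3:
        raise ValueError("need at least 3 distinct depths to fit the envelope")
    if np.any(sig <= 0):
        raise ValueError("sigma samples must be positive")
    c2, c1, c0 = np.polyfit(z, sig**2, 2)
    if c0 <= 0:
        raise ValueError("fit produced non-positive sigma^2 at the focal plane")
    sigma0 = math.sqrt(c0)
    phi0 = math.sqrt(max(c2, 0.0))
    if phi0 == 0.0:
        rho0 = 0.0
    else:
        rho0 = float(np.clip(-c1 / (2.0 * sigma0 * phi0), -0.99, 0.99))
    return CourantSnyderParams(sigma0=sigma0, rho0=rho0, phi0=phi0, axis=axis)


def default_courant_snyder(
    energy: float, axis: str, config: BeamlineConfig | None = None
) -> CourantSnyderParams:
    """Synthetic placeholder envelope parameters (the per-energy table is unpublished).

    Uses the power-law focal sigma, rho = 0, and a divergence chosen so sigma
    grows by the configured fraction (default 5%) over 200 mm.
    """
    cfg = config or BeamlineConfig()
    sigma0 = SpotShapeModel.from_config(cfg).sigma(energy, axis)
    growth = 1.0 + cfg.optics.cs_growth_fraction_200mm
    phi0 = sigma0 * math.sqrt(growth**2 - 1.0) / 200.0
    return CourantSnyderParams(
        sigma0=sigma0, rho0=cfg.optics.cs_default_rho, phi0=phi0, axis=axis
    )


@dataclass(frozen=True)
class ScanCalibration:
    """Scanning-magnet position calibration and scan-speed model for one axis.

    mm/A follows coeff * E**exp; scan speed scales the measured reference speed
    at ``ref_energy`` by the inverse ratio of relativistic momentum.
    """

    coeff: float
    exp: float
    slew_A_per_10us: float
    ref_speed_mps: float
    axis: str = "h"
    ref_energy: float = 245.0
    proton_mass_MeV: float = PROTON_MASS_MEV
    energy_policy: str = "warn"

    def __post_init__(self):
        if self.coeff <= 0 or self.exp >= 0 or self.ref_speed_mps <= 0:
            raise ValueError("require coeff > 0, exp < 0, ref_speed > 0")
        object.__setattr__(self, "axis", normalize_axis(self.axis))

    @classmethod
    def from_config(
        cls, axis: str, config: BeamlineConfig | None = None
    ) -> "ScanCalibration":
        cfg = config or BeamlineConfig()
        ax = normalize_axis(axis)
        sc = cfg.optics.scan.h if ax == "h" else cfg.optics.scan.v
        return cls(
            coeff=sc.coeff,
            exp=sc.exp,
            slew_A_per_10us=sc.slew_A_per_10us,
            ref_speed_mps=sc.ref_speed_mps,
            axis=ax,
            ref_energy=cfg.optics.ref_energy_MeV,
            proton_mass_MeV=cfg.physics.proton_mass_MeV,
            energy_policy=cfg.energy_policy,
        )

    def mm_per_amp(self, energy):
        """Beam displacement per ampere of scanning-magnet current (mm/A)."""
        e = check_energy(energy, policy=self.energy_policy)
        out = self.coeff * np.asarray(e) ** self.exp
        return out if out.ndim else float(out)

    def speed(self, energy):
        """Scan speed in m/s: ref_speed * p(ref_energy) / p(E)."""
        e = check_energy(energy, policy=self.energy_policy)
        p_ref = relativistic_momentum(self.ref_energy, self.proton_mass_MeV)
        out = self.ref_speed_mps * p_ref / relativistic_momentum(e, self.proton_mass_MeV)
        out = np.asarray(out)
        return out if out.ndim else float(out)

    def current_for_position(self, offset_mm, energy):
        """Inverse calibration: magnet current (A) producing a given offset (mm)."""
        off = np.asarray(offset_mm, dtype=float)
        if np.any(~np.isfinite(off)):
            raise ValueError("offset must be finite")
        out = off / self.mm_per_amp(energy)
        return out if out.ndim else float(out)


def scan_mm_per_amp(energy, axis, config: BeamlineConfig | None = None):
    return ScanCalibration.from_config(axis, config).mm_per_amp(energy)


def scan_speed(energy, axis, config: BeamlineConfig | None = None):
    return ScanCalibration.from_config(axis, config).speed(energy)


def current_for_position(offset_mm, energy, axis, config: BeamlineConfig | None = None):
    return ScanCalibration.from_config(axis, config).current_for_position(
        offset_mm, energy
    )
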