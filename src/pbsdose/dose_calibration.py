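"""Dose-per-MU calibration of the scanned proton beam.

The monitor-unit calibration has the rational form

    D/MU = D / (chi(E) * D + Delta(I_c, E))

with a dose-dependent component chi(E) = x3 - exp(x1*E + x2) (MU/Gy, rising
to a plateau of ~205 MU/Gy at high energy) and a dose-independent component
Delta(I_c, E) = (-exp(d1*E + d2) + d3) * I_c * T(E) (MU), where
T(E) = t1*E^t2 + t3*exp(t4*E) is the cyclotron-to-nozzle transmission
fraction and I_c the cyclotron current in nA. Delta is negative for the
fitted beamline constants: the monitor chain undercounts at low dose / high
instantaneous current because of electrometer dead time, which inflates the
measured Gy/MU in the low-dose region.

Fitting mirrors the commissioning workflow: a first pass with chi and Delta
free per (energy, current) stratum, a fit of chi(E), a re-fit of Delta with
chi frozen, and finally the Delta(I_c, E) surface.

A note on the sign of x1: the published table lists x1 positive, which would
make chi decrease without bound, contradicting its described (and physically
sensible) rise to a plateau. The default "adopted" convention therefore uses
-|x1|; the raw "printed" convention is selectable for auditing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from ._validation import check_energy
from .config import BeamlineConfig

__all__ = [
    "CalibrationParams",
    "DeliveryRequest",
    "CalibrationFit",
    "fit_calibration",
    "degrader_dose_scaling",
]


class CalibrationDomainError(ValueError):
    """Requested dose/MU combination outside the model's validity domain."""


@dataclass(frozen=True)
class CalibrationParams:
    """Fitted constants of the dose-per-MU calibration surface.

    x1..x3 parametrise chi(E) in MU/Gy; d1..d3 the energy coefficient of
    Delta; t1..t4 the transmission fraction; surface the nine coefficients
    (a..i) of the 20 mm WET -> surface dose ratio. tp_correction is the
    multiplicative temperature/pressure MU adjustment (1 = reference
    conditions; a factor of 1 leaves every output bit-identical).
    """

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
    surface: tuple = (
        2.429e-02,
        -6.587e-04,
        9.689e-07,
        -2.426e-02,
        8.322e-07,
        -3.347e-05,
        5.5290e-07,
        -2.255e-04,
        1.023,
    )
    chi_sign_convention: str = "adopted"
    tp_correction: float = 1.0
    energy_policy: str = "warn"
    surface_ratio_table: tuple | None = None  # optional measured (E, ratio) override

    def __post_init__(self):
        if self.chi_sign_convention not in ("adopted", "printed"):
            raise ValueError(
                f"chi_sign_convention must be 'adopted' or 'printed', "
                f"got {self.chi_sign_convention!r}"
            )
        if len(self.surface) != 9:
            raise ValueError("surface requires the nine coefficients a..i")

    @classmethod
    def from_config(cls, config: BeamlineConfig | None = None) -> "CalibrationParams":
        cfg = config or BeamlineConfig()
        c = cfg.calibration
        s = c.surface
        return cls(
            x1=c.x1,
            x2=c.x2,
            x3=c.x3,
            d1=c.d1,
            d2=c.d2,
            d3=c.d3,
            t1=c.t1,
            t2=c.t2,
            t3=c.t3,
            t4=c.t4,
            surface=(s.a, s.b, s.c, s.d, s.e, s.f, s.g, s.h, s.i),
            chi_sign_convention=c.chi_sign_convention,
            tp_correction=c.tp_correction_factor,
            energy_policy=cfg.energy_policy,
        )

    # -- component models ---------------------------------------------------

    def _x1_effective(self) -> float:
        return -abs(self.x1) if self.chi_sign_convention == "adopted" else self.x1

    def chi(self, energy):
        """Dose-dependent calibration component chi(E) in MU/Gy."""
        e = check_energy(energy, policy=self.energy_policy)
        out = self.x3 - np.exp(self._x1_effective() * np.asarray(e) + self.x2)
        if np.any(np.asarray(out) <= 0):
            raise CalibrationDomainError(
                f"chi(E) <= 0 at E={energy} MeV with x1={self.x1}, x2={self.x2}, "
                f"x3={self.x3} (convention {self.chi_sign_convention!r})"
            )
        return out if np.ndim(out) else float(out)

    def transmission_fraction(self, energy):
        """Cyclotron-to-nozzle transmission T(E) = t1*E^t2 + t3*exp(t4*E)."""
        e = check_energy(energy, policy=self.energy_policy)
        e = np.asarray(e, dtype=float)
        out = self.t1 * e**self.t2 + self.t3 * np.exp(self.t4 * e)
        return out if out.ndim else float(out)

    def nozzle_current(self, cyclotron_current_nA, energy):
        """Nozzle current in nA: cyclotron current times transmission."""
        i = np.asarray(cyclotron_current_nA, dtype=float)
        if np.any(i < 0):
            raise ValueError("cyclotron current must be >= 0")
        out = i * self.transmission_fraction(energy)
        return out if out.ndim else float(out)

    def delta_energy_coefficient(self, energy):
        """The -exp(d1*E + d2) + d3 factor of Delta (MU per nA of nozzle current)."""
        e = np.asarray(check_energy(energy, policy=self.energy_policy), dtype=float)
        out = -np.exp(self.d1 * e + self.d2) + self.d3
        return out if out.ndim else float(out)

    def delta(self, cyclotron_current_nA, energy):
        """Dose-independent calibration component Delta(I_c, E) in MU."""
        i = np.asarray(cyclotron_current_nA, dtype=float)
        if np.any(i < 0):
            raise ValueError("cyclotron current must be >= 0")
        out = (
            self.delta_energy_coefficient(energy)
            * i
            * self.transmission_fraction(energy)
        )
        return out if out.ndim else float(out)

    # -- the calibration surface ---------------------------------------------

    def min_valid_dose(self, energy, cyclotron_current_nA):
        """Smallest dose with positive denominator: max(0, -Delta/chi) in Gy."""
        d = self.delta(cyclotron_current_nA, energy)
        out = np.maximum(0.0, -np.asarray(d) / np.asarray(self.chi(energy)))
        return out if out.ndim else float(out)

    def mu_for_dose(self, dose_Gy, energy, cyclotron_current_nA, *, margin=0.01):
        """MU required for a field dose: MU = (chi*D + Delta) * tp_correction.

        Doses within ``margin`` of the validity boundary -Delta/chi are
        refused rather than mapped to non-physical MU.
        """
        d = np.asarray(dose_Gy, dtype=float)
        if np.any(d <= 0):
            raise CalibrationDomainError(f"dose must be > 0, got {dose_Gy}")
        min_dose = np.asarray(self.min_valid_dose(energy, cyclotron_current_nA))
        if np.any(d < min_dose * (1.0 + margin)):
            raise CalibrationDomainError(
                f"dose {dose_Gy} Gy below model validity; minimum valid dose is "
                f"{float(np.max(min_dose)):.4g} Gy (+{margin:.0%} margin) at "
                f"E={energy} MeV, I_c={cyclotron_current_nA} nA"
            )
        mu = (
            np.asarray(self.chi(energy)) * d
            + np.asarray(self.delta(cyclotron_current_nA, energy))
        ) * self.tp_correction
        return mu if mu.ndim else float(mu)

    def dose_per_mu(self, dose_Gy, energy, cyclotron_current_nA):
        """Calibration factor D/MU in Gy/MU; decreasing in D, asymptote 1/chi."""
        d = np.asarray(dose_Gy, dtype=float)
        if np.any(d <= 0):
            raise CalibrationDomainError(f"dose must be > 0, got {dose_Gy}")
        denom = (
            np.asarray(self.chi(energy)) * d
            + np.asarray(self.delta(cyclotron_current_nA, energy))
        ) * self.tp_correction
        if np.any(denom <= 0):
            min_dose = self.min_valid_dose(energy, cyclotron_current_nA)
            raise CalibrationDomainError(
                f"chi*D + Delta <= 0: dose {dose_Gy} Gy below the minimum valid "
                f"dose {min_dose} Gy at E={energy} MeV, I_c={cyclotron_current_nA} nA"
            )
        out = d / denom
        return out if out.ndim else float(out)

    def surface_scaling(self, energy):
        """Ratio D_20mm / D_surface from the two-factor rational fit.

        The first factor is a small difference of ~0.024-magnitude terms and is
        ill-conditioned with 4-significant-figure coefficients: it evaluates to
        ~1.20 at 70 MeV and ~1.05 at 245 MeV, not the independently quoted
        measured factors (1.32 / 1.07). A measured-ratio table, if supplied,
        overrides the analytic form via linear interpolation.
        """
        e = np.asarray(
            check_energy(energy, policy=self.energy_policy), dtype=float
        )
        if self.surface_ratio_table is not None:
            knots_e, knots_r = map(np.asarray, self.surface_ratio_table)
            out = np.interp(e, knots_e, knots_r)
            return out if out.ndim else float(out)
        a, b, c, d, ee, f, g, h, i = self.surface
        num = a * e**b + c * e + d
        den1 = ee * e + f
        den2 = g * e**2 + h * e + i
        if np.any(np.abs(den1) < 1e-12) or np.any(np.abs(den2) < 1e-12):
            raise CalibrationDomainError(
                f"surface-scaling denominator vanishes near E={energy} MeV"
            )
        out = num / den1 / den2
        return out if out.ndim else float(out)

    def validate(self, lo: float = 70.0, hi: float = 250.0) -> None:
        """Check the structural invariants over the commissioned range."""
        grid = np.linspace(lo, hi, 181)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t = np.asarray(self.transmission_fraction(grid))
            if np.any(t <= 0) or np.any(np.diff(t) <= 0):
                raise ValueError(
                    "transmission must be positive and strictly increasing over "
                    f"[{lo}, {hi}] MeV"
                )
            chi = np.asarray(self.chi(grid))
        if np.any(chi <= 0) or np.any(chi > self.x3):
            raise ValueError(f"chi must lie in (0, x3] over [{lo}, {hi}] MeV")


@dataclass(frozen=True)
class DeliveryRequest:
    """A requested delivery: field dose (Gy), energy (MeV), cyclotron current (nA)."""

    dose_Gy: float
    energy_MeV: float
    cyclotron_current_nA: float

    def __post_init__(self):
        if self.dose_Gy <= 0:
            raise ValueError(f"dose must be > 0, got {self.dose_Gy}")
        check_energy(self.energy_MeV)
        if not 10.0 <= self.cyclotron_current_nA <= 800.0:
            warnings.warn(
                f"cyclotron current {self.cyclotron_current_nA} nA outside the "
                "exercised 10-800 nA range",
                UserWarning,
                stacklevel=2,
            )


# -- module-level conveniences ------------------------------------------------


def chi(energy, params: CalibrationParams | None = None):
    return (params or CalibrationParams()).chi(energy)


def transmission_fraction(energy, params: CalibrationParams | None = None):
    return (params or CalibrationParams()).transmission_fraction(energy)


def nozzle_current(cyclotron_current_nA, energy, params: CalibrationParams | None = None):
    return (params or CalibrationParams()).nozzle_current(cyclotron_current_nA, energy)


def delta(cyclotron_current_nA, energy, params: CalibrationParams | None = None):
    return (params or CalibrationParams()).delta(cyclotron_current_nA, energy)


def dose_per_mu(
    dose_Gy, energy, cyclotron_current_nA, params: CalibrationParams | None = None
):
    return (params or CalibrationParams()).dose_per_mu(
        dose_Gy, energy, cyclotron_current_nA
    )


def mu_for_dose(
    dose_Gy, energy, cyclotron_current_nA, params: CalibrationParams | None = None
):
    return (params or CalibrationParams()).mu_for_dose(
        dose_Gy, energy, cyclotron_current_nA
    )


def surface_scaling(energy, params: CalibrationParams | None = None):
    return (params or CalibrationParams()).surface_scaling(energy)


def cyclotron_current_for_nozzle(
    nozzle_nA: float = 2.0,
    energy=245.0,
    params: CalibrationParams | None = None,
    max_cyclotron_nA: float = 800.0,
):
    """Cyclotron current (nA) giving the requested nozzle current.

    Deliveries nominally target a 2 nA nozzle current; below ~150 MeV the
    transmission makes that unreachable and the cyclotron current saturates at
    its maximum, so the result is capped at ``max_cyclotron_nA``.
    """
    cal = params or CalibrationParams()
    t = np.asarray(cal.transmission_fraction(energy))
    out = np.minimum(nozzle_nA / t, max_cyclotron_nA)
    return out if out.ndim else float(out)


def degrader_dose_scaling(energy, table):
    """Cell-dose / detector-dose ratio from a user-supplied lookup table.

    The table is Monte Carlo-derived (this package does not compute it) and is
    interpolated linearly; the ratio settles to ~1 above ~76 MeV. Energies
    outside the table's knots raise rather than extrapolate.
    """
    knots_e = np.asarray(table[0] if isinstance(table, (tuple, list)) else table.index)
    knots_r = np.asarray(table[1] if isinstance(table, (tuple, list)) else table.values)
    if knots_e.size < 2 or np.any(np.diff(knots_e) <= 0):
        raise ValueError("degrader table needs >= 2 strictly increasing energies")
    e = np.asarray(energy, dtype=float)
    if np.any(e < knots_e[0]) or np.any(e > knots_e[-1]):
        raise ValueError(
            f"energy {energy} outside degrader table range "
            f"[{knots_e[0]:g}, {knots_e[-1]:g}] MeV"
        )
    out = np.interp(e, knots_e, knots_r)
    return out if out.ndim else float(out)


# -- the staged fitting workflow ----------------------------------------------

REQUIRED_COLUMNS = ("energy_MeV", "cyclotron_current_nA", "dose_Gy", "mu")


@dataclass
class CalibrationFit:
    """Result of the staged calibration fit."""

    params: CalibrationParams
    stage1: pd.DataFrame = field(repr=False)  # per-(E, I_c) free chi/Delta fits
    stage3: pd.DataFrame = field(repr=False)  # per-(E, I_c) Delta with chi frozen
    stage2_r2: float = float("nan")
    stage4_r2: float = float("nan")
    overall_r2: float = float("nan")

    def summary(self) -> dict:
        p = self.params
        return {
            "x1": p.x1,
            "x2": p.x2,
            "x3": p.x3,
            "d1": p.d1,
            "d2": p.d2,
            "d3": p.d3,
            "stage2_r2": self.stage2_r2,
            "stage4_r2": self.stage4_r2,
            "overall_r2": self.overall_r2,
            "n_strata": int(len(self.stage1)),
        }


def _pooling_sigma(se: np.ndarray) -> np.ndarray | None:
    """Relative weights for pooling stratum estimates: their standard errors.

    Noiseless data yields (near-)zero standard errors; in that case the fit is
    already exact and unweighted pooling is used instead of dividing by zero.
    """
    if np.all(se > 0) and np.isfinite(se).all() and se.max() / se.min() < 1e6:
        return se
    return None


def _r_squared(observed, predicted) -> float:
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    ss_res = float(np.sum((observed - predicted) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0


def _dpm_sigma(d, y):
    """Propagated residual scale of D/MU under multiplicative dose noise.

    With recorded dose D(1+eps) and exact MU, the D/MU residual at the truth
    is ~ chi * D^2 * eps / MU^2, so sigma ~ (D/MU)^2 up to constants that
    cancel in the weighting.
    """
    return np.maximum(y**2, 1e-300)


def _fit_stratum_free(d, y):
    """Stage 1: fit D/MU = D/(chi*D + delta) with chi, delta free."""

    def model(dose, chi_, delta_):
        return dose / (chi_ * dose + delta_)

    # linear MU = chi*D + delta gives an excellent starting point
    chi0, delta0 = np.polyfit(d, d / y, 1)
    popt, pcov = curve_fit(
        model, d, y, p0=[chi0, delta0], sigma=_dpm_sigma(d, y), maxfev=20000
    )
    se = np.sqrt(np.abs(np.diag(pcov)))
    return (
        float(popt[0]),
        float(popt[1]),
        _r_squared(y, model(d, *popt)),
        float(se[0]),
        float(se[1]),
    )


def _fit_stratum_delta(d, y, chi_fixed):
    """Stage 3: refit delta only, chi frozen to the chi(E) fit."""

    def model(dose, delta_):
        return dose / (chi_fixed * dose + delta_)

    delta0 = float(np.mean(d / y - chi_fixed * d))
    popt, pcov = curve_fit(
        model, d, y, p0=[delta0], sigma=_dpm_sigma(d, y), maxfev=20000
    )
    return (
        float(popt[0]),
        _r_squared(y, model(d, *popt)),
        float(np.sqrt(abs(pcov[0, 0]))),
    )


def fit_calibration(
    measurements: pd.DataFrame,
    *,
    transmission_params: tuple[float, float, float, float] | None = None,
    fit_transmission: bool = False,
    min_energies: int = 4,
    min_currents: int = 2,
    min_doses: int = 4,
) -> CalibrationFit:
    """Fit the calibration surface to (energy, current, dose, MU) measurements.

    Stages: (1) per-(E, I_c) nonlinear least squares on the D/MU residuals
    with chi and Delta free; (2) fit chi(E) = x3 - exp(x1*E + x2) to the
    stage-1 chi values; (3) refit each stratum with chi frozen, Delta free;
    (4) fit the Delta(I_c, E) surface to the stage-3 values.

    Transmission is measured independently of the dose calibration (Faraday
    cup vs machine logs), so by default t1..t4 are taken as given
    (``transmission_params``, defaulting to the published constants) and
    stage 4 estimates only d1..d3; pass ``fit_transmission=True`` to free all
    seven surface parameters.
    """
    df = measurements.copy()
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurements missing columns: {missing}")
    bad = (df["mu"] <= 0) | (df["dose_Gy"] <= 0)
    if bad.any():
        warnings.warn(
            f"dropping {int(bad.sum())} rows with non-positive MU or dose",
            UserWarning,
            stacklevel=2,
        )
        df = df[~bad]

    n_e = df["energy_MeV"].nunique()
    n_i = df["cyclotron_current_nA"].nunique()
    n_d = df["dose_Gy"].nunique()
    lacking = []
    if n_e < min_energies:
        lacking.append(f"energies ({n_e} < {min_energies})")
    if n_i < min_currents:
        lacking.append(f"currents ({n_i} < {min_currents})")
    if n_d < min_doses:
        lacking.append(f"doses ({n_d} < {min_doses})")
    if lacking:
        raise ValueError("insufficient design coverage: " + ", ".join(lacking))

    df = df.assign(dpm=df["dose_Gy"] / df["mu"])

    # -- stage 1: free chi/Delta per stratum
    rows = []
    for (e, ic), grp in df.groupby(["energy_MeV", "cyclotron_current_nA"]):
        if grp["dose_Gy"].nunique() < 2:
            continue
        try:
            chi_, delta_, r2, chi_se, delta_se = _fit_stratum_free(
                grp["dose_Gy"].to_numpy(), grp["dpm"].to_numpy()
            )
        except RuntimeError as exc:
            raise RuntimeError(
                f"stage 1 fit failed for E={e} MeV, I_c={ic} nA: {exc}"
            ) from exc
        rows.append({"energy_MeV": e, "cyclotron_current_nA": ic,
                     "chi": chi_, "delta": delta_, "r2": r2,
                     "chi_se": chi_se, "delta_se": delta_se})
    stage1 = pd.DataFrame(rows)
    if stage1.empty:
        raise ValueError("no stratum had >= 2 distinct doses; cannot fit")

    # -- stage 2: chi(E) = x3 - exp(x1*E + x2)
    e_arr = stage1["energy_MeV"].to_numpy(dtype=float)
    chi_arr = stage1["chi"].to_numpy(dtype=float)

    def chi_model(e, x1, x2, x3):
        return x3 - np.exp(x1 * e + x2)

    x3_0 = float(chi_arr.max()) + 0.5
    gap = np.maximum(x3_0 - chi_arr, 1e-9)
    x1_0, x2_0 = np.polyfit(e_arr, np.log(gap), 1)
    chi_sigma = _pooling_sigma(stage1["chi_se"].to_numpy(dtype=float))
    try:
        (x1_f, x2_f, x3_f), _ = curve_fit(
            chi_model, e_arr, chi_arr, p0=[x1_0, x2_0, x3_0],
            sigma=chi_sigma, maxfev=40000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"stage 2 (chi vs energy) fit failed: {exc}") from exc
    stage2_r2 = _r_squared(chi_arr, chi_model(e_arr, x1_f, x2_f, x3_f))

    # -- stage 3: refit Delta with chi frozen
    rows = []
    for (e, ic), grp in df.groupby(["energy_MeV", "cyclotron_current_nA"]):
        if grp["dose_Gy"].nunique() < 2:
            continue
        chi_fixed = float(chi_model(e, x1_f, x2_f, x3_f))
        try:
            delta_, r2, delta_se = _fit_stratum_delta(
                grp["dose_Gy"].to_numpy(), grp["dpm"].to_numpy(), chi_fixed
            )
        except RuntimeError as exc:
            raise RuntimeError(
                f"stage 3 fit failed for E={e} MeV, I_c={ic} nA: {exc}"
            ) from exc
        rows.append({"energy_MeV": e, "cyclotron_current_nA": ic,
                     "delta": delta_, "r2": r2, "delta_se": delta_se})
    stage3 = pd.DataFrame(rows)

    # -- stage 4: Delta(I_c, E) surface
    tp = transmission_params or (3.613e-12, 4.086, 1.235e-13, 1.094e-01)
    e3 = stage3["energy_MeV"].to_numpy(dtype=float)
    i3 = stage3["cyclotron_current_nA"].to_numpy(dtype=float)
    delta3 = stage3["delta"].to_numpy(dtype=float)

    def transmission(e, t1, t2, t3, t4):
        return t1 * e**t2 + t3 * np.exp(t4 * e)

    # initial d-guesses from the reduced variable w = Delta / (I_c * T(E))
    w = delta3 / (i3 * transmission(e3, *tp))
    d3_0 = float(w.max()) + 0.5
    gap = np.maximum(d3_0 - w, 1e-9)
    d1_0, d2_0 = np.polyfit(e3, np.log(gap), 1)

    if fit_transmission:

        def delta_model(x, d1, d2, d3, t1, t2, t3, t4):
            e, ic = x
            return (-np.exp(d1 * e + d2) + d3) * ic * transmission(e, t1, t2, t3, t4)

        p0 = [d1_0, d2_0, d3_0, *tp]
    else:

        def delta_model(x, d1, d2, d3):
            e, ic = x
            return (-np.exp(d1 * e + d2) + d3) * ic * transmission(e, *tp)

        p0 = [d1_0, d2_0, d3_0]

    delta_sigma = _pooling_sigma(stage3["delta_se"].to_numpy(dtype=float))
    try:
        popt, _ = curve_fit(
            delta_model, (e3, i3), delta3, p0=p0, sigma=delta_sigma, maxfev=60000
        )
    except RuntimeError as exc:
        raise RuntimeError(f"stage 4 (Delta surface) fit failed: {exc}") from exc
    stage4_r2 = _r_squared(delta3, delta_model((e3, i3), *popt))
    d1_f, d2_f, d3_f = (float(v) for v in popt[:3])
    t_fit = tuple(float(v) for v in popt[3:]) if fit_transmission else tp

    params = CalibrationParams(
        x1=float(x1_f),
        x2=float(x2_f),
        x3=float(x3_f),
        d1=d1_f,
        d2=d2_f,
        d3=d3_f,
        t1=t_fit[0],
        t2=t_fit[1],
        t3=t_fit[2],
        t4=t_fit[3],
        chi_sign_convention="printed",  # x1 carries its fitted (negative) sign
    )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        predicted = params.dose_per_mu(
            df["dose_Gy"].to_numpy(),
            df["energy_MeV"].to_numpy(),
            df["cyclotron_current_nA"].to_numpy(),
        )
    overall_r2 = _r_squared(df["dpm"].to_numpy(), predicted)

    return CalibrationFit(
        params=params,
        stage1=stage1,
        stage3=stage3,
        stage2_r2=stage2_r2,
        stage4_r2=stage4_r2,
        overall_r2=overall_r2,
    )
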