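"""Shared input checks (energy-range policy, axis normalisation)."""

from __future__ import annotations

import warnings

import numpy as np

COMMISSIONED_MIN_MEV = 70.0
COMMISSIONED_MAX_MEV = 245.0
EXTRAPOLATION_MAX_MEV = 250.0


class EnergyRangeError(ValueError):
    """Energy outside the range the models can be extrapolated to."""


class EnergyRangeWarning(UserWarning):
    """Energy outside the commissioned range but within extrapolation limits."""


def check_energy(
    energy,
    *,
    policy: str = "warn",
    lo: float = COMMISSIONED_MIN_MEV,
    hi: float = COMMISSIONED_MAX_MEV,
    hard_max: float = EXTRAPOLATION_MAX_MEV,
):
    """Validate energies against the commissioned range.

    Inside [lo, hi]: pass. Between hi and hard_max (or below lo but positive):
    warn and extrapolate under the default policy, error under "strict".
    Beyond hard_max or non-positive: always an error.
    """
    e = np.asarray(energy, dtype=float)
    if np.any(~np.isfinite(e)) or np.any(e <= 0):
        raise EnergyRangeError(f"energy must be positive and finite, got {energy}")
    if np.any(e > hard_max):
        raise EnergyRangeError(
            f"energy {np.max(e):g} MeV beyond extrapolation limit {hard_max:g} MeV"
        )
    outside = np.any(e < lo) or np.any(e > hi)
    if outside:
        if policy == "strict":
            raise EnergyRangeError(
                f"energy {energy} outside commissioned range [{lo:g}, {hi:g}] MeV"
            )
        warnings.warn(
            f"energy {energy} outside commissioned range [{lo:g}, {hi:g}] MeV; "
            "extrapolating fitted models",
            EnergyRangeWarning,
            stacklevel=3,
        )
    return e if e.ndim else float(e)


def normalize_axis(axis: str) -> str:
    """Map axis spellings ('h', 'H', 'horizontal', ...) onto 'h' / 'v'."""
    a = str(axis).strip().lower()
    if a in ("h", "horizontal", "x"):
        return "h"
    if a in ("v", "vertical", "y"):
        return "v"
    raise ValueError(f"axis must be horizontal or vertical, got {axis!r}")
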