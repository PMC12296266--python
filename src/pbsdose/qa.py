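"""Quality-assurance checks mirroring the beamline's routine dosimetry QA.

Checks: field homogeneity (HI <= 3%), dose accuracy against the calibration
prediction (within +/-2%), spot sigma against the fitted power law, and spot
positional repeatability (< 0.1 mm). Any check whose inputs are missing is
reported as skipped — never silently passed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from .beam_optics import SpotShapeModel
from .config import BeamlineConfig
from .dose_calibration import CalibrationParams
from .field_delivery import DoseMap, fit_spot_centroid, homogeneity_index

__all__ = ["QACheck", "QAReport", "run_qa"]


@dataclass(frozen=True)
class QACheck:
    name: str
    status: str  # "pass" | "fail" | "skipped"
    measured: float | None = None
    tolerance: float | None = None
    detail: str = ""


@dataclass(frozen=True)
class QAReport:
    checks: tuple
    config_digest: str
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    @property
    def overall_pass(self) -> bool:
        """AND over evaluated checks; a report with no evaluated check fails."""
        evaluated = [c for c in self.checks if c.status != "skipped"]
        return bool(evaluated) and all(c.status == "pass" for c in evaluated)

    @property
    def n_skipped(self) -> int:
        return sum(c.status == "skipped" for c in self.checks)

    def to_json(self) -> str:
        return json.dumps(
            {
                "timestamp": self.timestamp,
                "config_digest": self.config_digest,
                "overall_pass": self.overall_pass,
                "checks": [asdict(c) for c in self.checks],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "QAReport":
        data = json.loads(text)
        return cls(
            checks=tuple(QACheck(**c) for c in data["checks"]),
            config_digest=data["config_digest"],
            timestamp=data["timestamp"],
        )


def _check_homogeneity(dose_map: DoseMap, cfg: BeamlineConfig) -> QACheck:
    hi = homogeneity_index(dose_map)
    tol = cfg.qa.hi_percent
    return QACheck(
        name="homogeneity_index",
        status="pass" if hi <= tol else "fail",
        measured=hi,
        tolerance=tol,
        detail=f"HI over central 50% of field = {hi:.3f}% (tolerance {tol:g}%)",
    )


def _check_dose_accuracy(
    measurements: pd.DataFrame, cal: CalibrationParams, cfg: BeamlineConfig
) -> QACheck:
    mu = measurements["mu"].to_numpy(dtype=float)
    dose = measurements["dose_Gy"].to_numpy(dtype=float)
    e = measurements["energy_MeV"].to_numpy(dtype=float)
    ic = measurements["cyclotron_current_nA"].to_numpy(dtype=float)
    predicted = (mu / cal.tp_correction - np.asarray(cal.delta(ic, e))) / np.asarray(
        cal.chi(e)
    )
    rel = np.abs(predicted - dose) / dose * 100.0
    worst = float(rel.max())
    tol = cfg.qa.dose_percent
    return QACheck(
        name="dose_accuracy",
        status="pass" if worst <= tol else "fail",
        measured=worst,
        tolerance=tol,
        detail=f"worst |predicted-measured| dose deviation {worst:.2f}% over "
        f"{len(measurements)} deliveries (tolerance {tol:g}%)",
    )


def _check_spot_sigma(
    image: DoseMap, energy_MeV: float, model: SpotShapeModel, cfg: BeamlineConfig
) -> QACheck:
    fit = fit_spot_centroid(image)
    dev_h = abs(fit.sigma_h_mm / model.sigma(energy_MeV, "h") - 1.0) * 100.0
    dev_v = abs(fit.sigma_v_mm / model.sigma(energy_MeV, "v") - 1.0) * 100.0
    worst = max(dev_h, dev_v)
    tol = cfg.qa.sigma_percent
    return QACheck(
        name="spot_sigma",
        status="pass" if worst <= tol else "fail",
        measured=worst,
        tolerance=tol,
        detail=f"spot sigma deviates {worst:.2f}% from the power law at "
        f"{energy_MeV:g} MeV (tolerance {tol:g}%)",
    )


def _check_repeatability(images: list, cfg: BeamlineConfig) -> QACheck:
    if len(images) < 2:
        return QACheck(
            name="repeatability",
            status="skipped",
            detail="need >= 2 repeat spot images",
        )
    centroids = np.array(
        [(f.x_mm, f.y_mm) for f in (fit_spot_centroid(img) for img in images)]
    )
    stat = float(np.mean(centroids.std(axis=0, ddof=1)))
    tol = cfg.qa.repeatability_mm
    return QACheck(
        name="repeatability",
        status="pass" if stat < tol else "fail",
        measured=stat,
        tolerance=tol,
        detail=f"mean per-axis centroid std over {len(images)} repeats = "
        f"{stat:.4f} mm (tolerance {tol:g} mm)",
    )


def run_qa(
    *,
    dose_map: DoseMap | None = None,
    measurements: pd.DataFrame | None = None,
    spot_image: DoseMap | None = None,
    spot_energy_MeV: float | None = None,
    repeat_spot_images: list | None = None,
    config: BeamlineConfig | None = None,
    calibration: CalibrationParams | None = None,
) -> QAReport:
    """Evaluate all QA checks for which inputs were supplied."""
    cfg = config or BeamlineConfig()
    cal = calibration or CalibrationParams.from_config(cfg)
    model = SpotShapeModel.from_config(cfg)
    checks = []

    if dose_map is not None:
        checks.append(_check_homogeneity(dose_map, cfg))
    else:
        checks.append(
            QACheck(name="homogeneity_index", status="skipped", detail="no dose map")
        )

    if measurements is not None and len(measurements):
        checks.append(_check_dose_accuracy(measurements, cal, cfg))
    else:
        checks.append(
            QACheck(name="dose_accuracy", status="skipped", detail="no measurements")
        )

    if spot_image is not None and spot_energy_MeV is not None:
        checks.append(_check_spot_sigma(spot_image, spot_energy_MeV, model, cfg))
    else:
        checks.append(
            QACheck(
                name="spot_sigma",
                status="skipped",
                detail="no spot image / energy",
            )
        )

    checks.append(_check_repeatability(repeat_spot_images or [], cfg))
    return QAReport(checks=tuple(checks), config_digest=cfg.digest())
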