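"""Delimited-text readers and writers for the toolkit's tabular formats.

All formats are plain comma-separated text with a header row; metadata travels
in '#key: value' comment lines. Dose maps round-trip bit-exactly (values are
written with full repr precision).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .depth_dose import DepthDoseCurve
from .field_delivery import DoseMap, SpotMap

__all__ = [
    "read_measurements",
    "write_measurements",
    "read_depth_sigma",
    "write_depth_sigma",
    "read_idd",
    "write_idd",
    "read_spot_map",
    "write_spot_map",
    "read_dose_map",
    "write_dose_map",
]

MEASUREMENT_COLUMNS = ["energy_MeV", "cyclotron_current_nA", "dose_Gy", "mu"]
DEPTH_SIGMA_COLUMNS = ["z_mm", "sigma_mm", "axis", "energy_MeV"]


def _read_metadata(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
    return meta


def read_measurements(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement file {path} missing columns: {missing}")
    return df


def write_measurements(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=MEASUREMENT_COLUMNS)


def read_depth_sigma(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in DEPTH_SIGMA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"depth-sigma file {path} missing columns: {missing}")
    return df


def write_depth_sigma(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=DEPTH_SIGMA_COLUMNS)


def read_idd(path) -> DepthDoseCurve:
    """Read depth_mm, relative_dose columns; '#' lines may carry energy/WET."""
    path = Path(path)
    meta = _read_metadata(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    for col in ("depth_mm", "relative_dose"):
        if col not in df.columns:
            raise ValueError(f"IDD file {path} missing column {col!r}")
    energy = float(meta["energy_MeV"]) if "energy_MeV" in meta else None
    wet = float(meta.get("wet_offset_mm", 0.0))
    return DepthDoseCurve(
        depths_mm=df["depth_mm"].to_numpy(),
        doses=df["relative_dose"].to_numpy(),
        energy_MeV=energy,
        wet_offset_mm=wet,
    )


def write_idd(curve: DepthDoseCurve, path) -> None:
    with open(path, "w") as fh:
        if curve.energy_MeV is not None:
            fh.write(f"#energy_MeV: {float(curve.energy_MeV)!r}\n")
        fh.write(f"#wet_offset_mm: {float(curve.wet_offset_mm)!r}\n")
        fh.write("depth_mm,relative_dose\n")
        for d, y in zip(curve.depths_mm, curve.doses):
            fh.write(f"{float(d)!r},{float(y)!r}\n")


def read_spot_map(path) -> SpotMap:
    path = Path(path)
    meta = _read_metadata(path)
    if "energy_MeV" not in meta:
        raise ValueError(f"spot map {path} missing '#energy_MeV' metadata")
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    for col in ("x_mm", "y_mm", "mu"):
        if col not in df.columns:
            raise ValueError(f"spot map {path} missing column {col!r}")

    def opt(key, cast):
        return cast(meta[key]) if key in meta else None

    fs = None
    if "field_size_mm" in meta:
        w, h = meta["field_size_mm"].split("x")
        fs = (float(w), float(h))
    return SpotMap(
        x_mm=df["x_mm"].to_numpy(),
        y_mm=df["y_mm"].to_numpy(),
        mu=df["mu"].to_numpy(),
        energy_MeV=float(meta["energy_MeV"]),
        cyclotron_current_nA=opt("cyclotron_current_nA", float),
        spacing_mm=opt("spacing_mm", float),
        field_size_mm=fs,
    )


def write_spot_map(spot_map: SpotMap, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#energy_MeV: {spot_map.energy_MeV!r}\n")
        if spot_map.cyclotron_current_nA is not None:
            fh.write(f"#cyclotron_current_nA: {spot_map.cyclotron_current_nA!r}\n")
        if spot_map.spacing_mm is not None:
            fh.write(f"#spacing_mm: {spot_map.spacing_mm!r}\n")
        if spot_map.field_size_mm is not None:
            fh.write(
                f"#field_size_mm: {float(spot_map.field_size_mm[0])!r} x "
                f"{float(spot_map.field_size_mm[1])!r}\n"
            )
        fh.write("x_mm,y_mm,mu\n")
        for x, y, m in zip(spot_map.x_mm, spot_map.y_mm, spot_map.mu):
            fh.write(f"{float(x)!r},{float(y)!r},{float(m)!r}\n")


def read_dose_map(path) -> DoseMap:
    path = Path(path)
    meta = _read_metadata(path)
    if "pitch_mm" not in meta:
        raise ValueError(f"dose map {path} missing '#pitch_mm' metadata")
    grid = np.loadtxt(path, comments="#")
    fs = None
    if "field_size_mm" in meta:
        w, h = meta["field_size_mm"].split("x")
        fs = (float(w), float(h))
    return DoseMap(
        grid=np.atleast_2d(grid),
        pixel_pitch_mm=float(meta["pitch_mm"]),
        field_size_mm=fs,
    )


def write_dose_map(dose_map: DoseMap, path) -> None:
    header = [f"pitch_mm: {dose_map.pixel_pitch_mm!r}"]
    if dose_map.field_size_mm is not None:
        header.append(
            f"field_size_mm: {float(dose_map.field_size_mm[0])!r} x "
            f"{float(dose_map.field_size_mm[1])!r}"
        )
    np.savetxt(
        path,
        dose_map.grid,
        fmt="%.17g",
        header="\n".join(header),
        comments="#",
    )
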