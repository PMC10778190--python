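"""Readers and writers for the on-disk formats.

Movies and maps travel as TIFF with a JSON sidecar carrying the physical
metadata (pixel size, frame interval, origin); point tables travel as CSV
with unit-bearing column names that are validated on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .alignment import AlignmentTransform
from .rendering import RenderedMap, quantize_16bit

LOC_REQUIRED = ["x_nm", "y_nm"]
SPARK_REQUIRED = ["x_um", "y_um", "t_frame", "fwhm_um", "amplitude", "r2", "mass"]
PUNCTA_REQUIRED = ["x_nm", "y_nm", "area_nm2"]

DEFAULT_PRECISION_NM = 10.0


class SchemaError(ValueError):
    """A table is missing a required column."""


def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{what} table is missing required column '{col}'")


def write_movie(path: str | Path, movie: np.ndarray, pixel_size_um: float, frame_interval_ms: float) -> None:
    path = Path(path)
    arr = np.clip(np.asarray(movie), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, arr)
    sidecar = {"pixel_size_um": pixel_size_um, "frame_interval_ms": frame_interval_ms, "n_frames": int(arr.shape[0])}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_movie(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    movie = tifffile.imread(path).astype(np.float64)
    meta_path = path.with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return movie, meta


def write_map(path: str | Path, rmap: RenderedMap, clip_percentile: float = 99.9) -> None:
    """Export a rendered map as 16-bit TIFF + georeferencing sidecar."""
    path = Path(path)
    tifffile.imwrite(path, quantize_16bit(rmap, clip_percentile))
    sidecar = {
        "pixel_size_nm": rmap.pixel_size_nm,
        "origin_x_nm": rmap.origin_nm[0],
        "origin_y_nm": rmap.origin_nm[1],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_localizations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, LOC_REQUIRED, "localization")
    if "precision_nm" not in df.columns:
        df = df.copy()
        df["precision_nm"] = DEFAULT_PRECISION_NM
    return df


def write_localizations(path: str | Path, locs: pd.DataFrame) -> None:
    _check_columns(locs, LOC_REQUIRED, "localization")
    locs.to_csv(path, index=False)


def read_sparks(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, SPARK_REQUIRED, "spark")
    return df


def write_sparks(path: str | Path, sparks: pd.DataFrame) -> None:
    _check_columns(sparks, SPARK_REQUIRED, "spark")
    sparks.to_csv(path, index=False)


def read_puncta(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, PUNCTA_REQUIRED, "puncta")
    return df


def write_puncta(path: str | Path, puncta: pd.DataFrame) -> None:
    _check_columns(puncta, PUNCTA_REQUIRED, "puncta")
    puncta.to_csv(path, index=False)


def write_transform(path: str | Path, transform: AlignmentTransform) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "dx_nm": transform.dx_nm,
                "dy_nm": transform.dy_nm,
                "peak_correlation": transform.peak_correlation,
                "method": transform.method,
                "search_radius_nm": transform.search_radius_nm,
                "flags": list(transform.flags),
            },
            indent=2,
        )
    )


def read_transform(path: str | Path) -> AlignmentTransform:
    d = json.loads(Path(path).read_text())
    return AlignmentTransform(
        dx_nm=d["dx_nm"],
        dy_nm=d["dy_nm"],
        peak_correlation=d.get("peak_correlation", float("nan")),
        method=d.get("method", "fine"),
        search_radius_nm=d.get("search_radius_nm", float("nan")),
        flags=list(d.get("flags", [])),
    )


def write_mask(path: str | Path, mask: np.ndarray, pixel_size_um: float) -> None:
    path = Path(path)
    tifffile.imwrite(path, mask.astype(np.uint8))
    path.with_suffix(".json").write_text(json.dumps({"pixel_size_um": pixel_size_um}, indent=2))


def read_mask(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    mask = tifffile.imread(path) > 0
    meta_path = path.with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return mask, meta
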