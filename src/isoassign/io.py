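"""Reading and writing the pipeline's tabular and spatial formats.

Tabular data are CSV; rasters are ESRI ASCII grids (see
:mod:`isoassign.grids`); the study-area polygon is GeoJSON with
coordinates already in the projected km frame; configuration is YAML.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml
from shapely.geometry import shape
from shapely.geometry.base import BaseGeometry

from .variogram import VariogramModel

__all__ = [
    "read_records",
    "read_polygon",
    "write_polygon",
    "write_variogram_sidecar",
    "read_variogram_sidecar",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("id", "loc_id", "x_km", "y_km", "year", "age", "d2H")
VALID_AGES = ("SY", "ASY")


def read_records(path: str | Path) -> pd.DataFrame:
    """Read and validate an individual-records CSV.

    Required columns: id, loc_id, x_km, y_km, year, age, d2H; d34S is
    optional (the study measured sulfur for subsets only) and blank
    values are kept as missing. Rows with a non-numeric isotope value
    are rejected with a logged line number; an invalid age class is an
    error.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"records file {path} missing required column(s): {missing}")
    if "d34S" not in df.columns:
        df["d34S"] = float("nan")
    bad_age = ~df["age"].isin(VALID_AGES)
    if bad_age.any():
        raise ValueError(
            f"invalid age class(es) {sorted(df.loc[bad_age, 'age'].unique())}; "
            f"expected one of {VALID_AGES}"
        )
    for col in ("d2H", "d34S", "x_km", "y_km"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            for idx in df.index[bad]:
                logger.warning(
                    "%s: rejecting row %d (line %d): non-numeric %s=%r",
                    path.name, idx, idx + 2, col, df.loc[idx, col],
                )
            df = df[~bad]
            coerced = coerced[~bad]
        df = df.assign(**{col: coerced.astype(float)})
    df["year"] = df["year"].astype(int)
    n_missing_s = int(df["d34S"].isna().sum())
    if n_missing_s:
        logger.info("%s: %d record(s) without δ34S", path.name, n_missing_s)
    return df.reset_index(drop=True)


def read_polygon(path: str | Path) -> BaseGeometry:
    """Study-area polygon from GeoJSON (planar km coordinates)."""
    with Path(path).open() as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        gj = gj["features"][0]["geometry"]
    elif gj.get("type") == "Feature":
        gj = gj["geometry"]
    return shape(gj)


def write_polygon(geom: BaseGeometry, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        json.dump(geom.__geo_interface__, fh)


def write_variogram_sidecar(
    model: VariogramModel, path: str | Path, rmse: float | None = None
) -> None:
    """Small key/value text sidecar describing a fitted variogram."""
    data = model.to_dict()
    if rmse is not None:
        data["loocv_rmse"] = rmse
    with Path(path).open("w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def read_variogram_sidecar(path: str | Path) -> VariogramModel:
    with Path(path).open() as fh:
        data = yaml.safe_load(fh)
    return VariogramModel(
        family=data["family"],
        nugget=data["nugget"],
        partial_sill=data["partial_sill"],
        range_=data["range_km"],
    )
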