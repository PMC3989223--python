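"""Feather isoscapes: location summaries, model selection, ordinary kriging.

An isoscape is a raster of expected feather isotope values interpolated
from per-location means of after-second-year (ASY) males, which are taken
to carry the local isotopic signal because experienced breeders moult near
their previous breeding territory. Spatial structure is modelled with a
semivariogram fitted to the location means; the family is chosen by
leave-one-out cross-validated RMSE and the winning model drives ordinary
kriging (weights constrained to sum to 1) on a cell-centre grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import lu_factor, lu_solve

from .grids import Grid, Raster
from .variogram import (
    FAMILIES,
    EmpiricalVariogram,
    VariogramFitError,
    VariogramModel,
    empirical_semivariogram,
    fit_variogram,
)

__all__ = [
    "Isoscape",
    "KrigingError",
    "summarize_locations",
    "location_variogram",
    "loocv_rmse",
    "select_model",
    "krige",
]

logger = logging.getLogger(__name__)

ISOTOPES = ("d2H", "d34S")


class KrigingError(RuntimeError):
    pass


@dataclass
class Isoscape:
    """Kriged mean surface plus kriging variance for one isotope."""

    isotope: str
    mean: Raster
    variance: Raster
    model: VariogramModel
    rmse: float | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def grid(self) -> Grid:
        return self.mean.grid


def summarize_locations(
    records: pd.DataFrame,
    pooling: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-location isotope summaries (mean, SD, n) and centroids.

    ``pooling`` maps a site id to a pooled location id (identity if None);
    the paper's study district pools 12 sites into 4 locations so that
    each of the 26 locations contributes a similar number of ASY males.
    Centroids are the mean coordinates of member sites; means are
    arithmetic means of individual values. Locations left empty after
    dropping missing values are dropped with a warning.
    """
    df = records.copy()
    if pooling is not None:
        unknown = set(df["loc_id"].astype(str)) - set(pooling)
        if unknown:
            raise ValueError(f"sites missing from pooling map: {sorted(unknown)}")
        df["loc_id"] = df["loc_id"].astype(str).map(pooling)

    rows = []
    for loc_id, grp in df.groupby("loc_id", sort=True):
        # centroid = mean of member-site coordinates (one entry per site)
        sites = grp.drop_duplicates(subset=["x_km", "y_km"])[["x_km", "y_km"]]
        row: dict = {
            "loc_id": loc_id,
            "x_km": float(sites["x_km"].mean()),
            "y_km": float(sites["y_km"].mean()),
        }
        any_iso = False
        for iso in ISOTOPES:
            vals = grp[iso].dropna() if iso in grp else pd.Series(dtype=float)
            row[f"n_{iso}"] = int(len(vals))
            row[f"mean_{iso}"] = float(vals.mean()) if len(vals) else np.nan
            row[f"sd_{iso}"] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
            any_iso = any_iso or len(vals) > 0
        if not any_iso:
            logger.warning("location %s has no isotope values; dropped", loc_id)
            continue
        rows.append(row)
    return pd.DataFrame(rows).reset_index(drop=True)


def location_variogram(
    summaries: pd.DataFrame,
    isotope: str,
    n_bins: int = 12,
    max_lag: float | None = None,
) -> EmpiricalVariogram:
    """Empirical semivariogram of the per-location means for one isotope."""
    sub = summaries.dropna(subset=[f"mean_{isotope}"])
    coords = sub[["x_km", "y_km"]].to_numpy()
    values = sub[f"mean_{isotope}"].to_numpy()
    return empirical_semivariogram(coords, values, n_bins=n_bins, max_lag=max_lag)


def _check_coords(coords: np.ndarray) -> None:
    d = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((d**2).sum(-1))
    iu = np.triu_indices(len(coords), k=1)
    dup = np.argwhere(dist[iu] == 0.0)
    if len(dup):
        i, j = iu[0][dup[0][0]], iu[1][dup[0][0]]
        raise KrigingError(
            f"duplicate coordinates make the kriging system singular "
            f"(observations {i} and {j})"
        )


def _ok_weights(
    coords: np.ndarray, model: VariogramModel, targets: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the ordinary-kriging system for each target point.

    Returns (weights ``(n_obs, n_targets)``, Lagrange multipliers
    ``(n_targets,)``). The system matrix uses γ on off-diagonal pairs and
    0 on the diagonal (self-pairs carry no nugget), bordered with the
    unit-sum constraint.
    """
    n = len(coords)
    _check_coords(coords)
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = model.gamma(d)
    np.fill_diagonal(A[:n, :n], 0.0)
    A[n, :n] = 1.0
    A[:n, n] = 1.0
    A[n, n] = 0.0
    try:
        lu = lu_factor(A)
    except Exception as exc:
        raise KrigingError(f"singular kriging system: {exc}") from exc
    dt = np.sqrt(((coords[:, None, :] - targets[None, :, :]) ** 2).sum(-1))
    B = np.empty((n + 1, dt.shape[1]))
    B[:n] = model.gamma(dt)
    B[n] = 1.0
    sol = lu_solve(lu, B)
    if not np.all(np.isfinite(sol)):
        raise KrigingError("singular kriging system (non-finite weights)")
    return sol[:n], sol[n]


def ordinary_krige_points(
    coords: np.ndarray,
    values: np.ndarray,
    model: VariogramModel,
    targets: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ordinary-kriging predictions and variances at arbitrary points.

    Returns (predictions, kriging variances, weights ``(n_obs, n_targets)``).
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    targets = np.asarray(targets, dtype=float)
    lam, mu = _ok_weights(coords, model, targets)
    pred = lam.T @ values
    dt = np.sqrt(((coords[:, None, :] - targets[None, :, :]) ** 2).sum(-1))
    var = np.einsum("it,it->t", lam, model.gamma(dt)) + mu
    return pred, np.maximum(var, 0.0), lam


def loocv_rmse(summaries: pd.DataFrame, isotope: str, model: VariogramModel) -> float:
    """Leave-one-out cross-validated RMSE of location means under a model.

    Each location is predicted by ordinary kriging from all other
    locations; the RMSE of (predicted − observed) means is the model
    selection criterion.
    """
    sub = summaries.dropna(subset=[f"mean_{isotope}"])
    coords = sub[["x_km", "y_km"]].to_numpy()
    values = sub[f"mean_{isotope}"].to_numpy()
    n = len(values)
    if n < 4:
        raise ValueError("LOOCV needs at least 4 locations")
    errs = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        pred, _, _ = ordinary_krige_points(
            coords[mask], values[mask], model, coords[i : i + 1]
        )
        errs[i] = pred[0] - values[i]
    return float(np.sqrt(np.mean(errs**2)))


def select_model(
    summaries: pd.DataFrame,
    isotope: str,
    families: tuple[str, ...] = FAMILIES,
    n_bins: int = 12,
    max_lag: float | None = None,
) -> tuple[VariogramModel, float]:
    """Fit every family and return the one minimizing LOOCV RMSE.

    Ties are broken by the canonical family order. Raises an error
    aggregating per-family failures if nothing fits.
    """
    ev = location_variogram(summaries, isotope, n_bins=n_bins, max_lag=max_lag)
    fits: list[tuple[float, int, VariogramModel]] = []
    failures: list[str] = []
    for k, fam in enumerate(families):
        try:
            model = fit_variogram(ev, fam)
            rmse = loocv_rmse(summaries, isotope, model)
        except (VariogramFitError, KrigingError, ValueError) as exc:
            failures.append(f"{fam}: {exc}")
            continue
        fits.append((rmse, k, model))
        logger.info("%s variogram %s: LOOCV RMSE %.4g", isotope, fam, rmse)
    if not fits:
        raise VariogramFitError(
            "no variogram family could be fitted: " + "; ".join(failures)
        )
    fits.sort(key=lambda t: (t[0], t[1]))
    rmse, _, model = fits[0]
    return model, rmse


def krige(
    summaries: pd.DataFrame,
    isotope: str,
    model: VariogramModel,
    grid: Grid,
    rmse: float | None = None,
) -> Isoscape:
    """Ordinary kriging of location means onto a grid.

    With a zero nugget the surface interpolates the observations exactly
    at their centroids; kriging weights sum to 1 at every cell.
    """
    sub = summaries.dropna(subset=[f"mean_{isotope}"])
    coords = sub[["x_km", "y_km"]].to_numpy()
    values = sub[f"mean_{isotope}"].to_numpy()
    X, Y = grid.cell_centers()
    targets = np.column_stack([X.ravel(), Y.ravel()])
    pred, var, _ = ordinary_krige_points(coords, values, model, targets)
    return Isoscape(
        isotope=isotope,
        mean=Raster(grid, pred.reshape(grid.ny, grid.nx)),
        variance=Raster(grid, var.reshape(grid.ny, grid.nx)),
        model=model,
        rmse=rmse,
        provenance={"model": model.to_dict(), "loocv_rmse": rmse, "n_locations": len(values)},
    )
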