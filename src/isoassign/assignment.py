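"""Bivariate-normal likelihood assignment of individuals to origin cells.

For an individual with calibrated feather values (x, y) = (δ²H, δ³⁴S),
every raster cell j of the dual isoscape proposes a mean vector
μ_j = (μ_H(j), μ_S(j)). The likelihood that the individual grew its
feathers in cell j is the bivariate normal density

    f(x, y | μ_j, Σ) = (2π σ_H σ_S √(1−ω²))⁻¹ ·
        exp(−[z_H² − 2ω z_H z_S + z_S²] / (2(1−ω²))),  z = (value − μ)/σ

with a single variance–covariance structure Σ (within-location SDs σ_H,
σ_S and correlation ω) assumed stationary across the study area. The
densities are normalized to cell masses summing to 1, and a 2:1 (or 4:1)
odds ratio converts the surface to a binary likely/unlikely origin mask:
the highest-mass cells are included until their cumulative mass reaches
odds/(odds+1) — 2/3 for 2:1, the "upper 67%" of cumulative probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import Grid, Raster
from .isoscape import Isoscape

__all__ = [
    "CovStructure",
    "LikelihoodSurface",
    "BinarySurface",
    "estimate_cov_structure",
    "bnpdf",
    "likelihood_surface",
    "odds_binarize",
    "sum_binary_surfaces",
    "odds_threshold",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CovStructure:
    """Within-location dispersion of (δ²H, δ³⁴S): SDs and correlation."""

    sigma_H: float
    sigma_S: float
    omega: float

    def __post_init__(self) -> None:
        if self.sigma_H <= 0 or self.sigma_S <= 0:
            raise ValueError("standard deviations must be positive")
        if not -1.0 < self.omega < 1.0:
            raise ValueError(f"correlation must lie in (-1, 1), got {self.omega}")

    @property
    def covariance(self) -> float:
        return self.sigma_H * self.sigma_S * self.omega

    @property
    def matrix(self) -> np.ndarray:
        """2×2 variance–covariance matrix (positive-definite by construction)."""
        c = self.covariance
        return np.array([[self.sigma_H**2, c], [c, self.sigma_S**2]])


def estimate_cov_structure(validation_records: pd.DataFrame) -> CovStructure:
    """Pooled within-location covariance structure from a validation cohort.

    Residuals are individual values minus their location mean, pooled
    across locations; locations contributing fewer than two birds with
    both isotopes carry no information and are dropped. The pooled SDs
    use ``N − L`` degrees of freedom (L locations each absorb one mean).
    """
    df = validation_records.dropna(subset=["d2H", "d34S"])
    counts = df.groupby("loc_id").size()
    keep = counts[counts >= 2].index
    df = df[df["loc_id"].isin(keep)]
    if df.empty:
        raise ValueError("no location has >= 2 birds with both isotopes")
    n_loc = df["loc_id"].nunique()
    if n_loc < 2:
        raise ValueError("need residuals from at least 2 locations")
    res_h = df["d2H"] - df.groupby("loc_id")["d2H"].transform("mean")
    res_s = df["d34S"] - df.groupby("loc_id")["d34S"].transform("mean")
    dof = len(df) - n_loc
    ss_h = float((res_h**2).sum())
    ss_s = float((res_s**2).sum())
    if ss_h == 0.0 or ss_s == 0.0:
        raise ValueError("degenerate validation cohort: zero within-location variance")
    sigma_h = np.sqrt(ss_h / dof)
    sigma_s = np.sqrt(ss_s / dof)
    omega = float((res_h * res_s).sum() / dof / (sigma_h * sigma_s))
    if abs(omega) >= 1.0 - 1e-9:
        raise ValueError(f"residual correlation {omega} on the boundary; invalid")
    return CovStructure(sigma_H=float(sigma_h), sigma_S=float(sigma_s), omega=omega)


def bnpdf(x, y, mu_H, mu_S, cov: CovStructure) -> np.ndarray:
    """Bivariate normal density of (x, y) around (μ_H, μ_S) under ``cov``.

    Vectorized over the μ arguments (one per raster cell).
    """
    zh = (np.asarray(x, dtype=float) - np.asarray(mu_H, dtype=float)) / cov.sigma_H
    zs = (np.asarray(y, dtype=float) - np.asarray(mu_S, dtype=float)) / cov.sigma_S
    om2 = 1.0 - cov.omega**2
    norm = 1.0 / (2.0 * np.pi * cov.sigma_H * cov.sigma_S * np.sqrt(om2))
    q = (zh**2 - 2.0 * cov.omega * zh * zs + zs**2) / (2.0 * om2)
    return norm * np.exp(-q)


def _log_bnpdf(x, y, mu_H, mu_S, cov: CovStructure) -> np.ndarray:
    zh = (x - np.asarray(mu_H, dtype=float)) / cov.sigma_H
    zs = (y - np.asarray(mu_S, dtype=float)) / cov.sigma_S
    om2 = 1.0 - cov.omega**2
    return (
        -np.log(2.0 * np.pi * cov.sigma_H * cov.sigma_S * np.sqrt(om2))
        - (zh**2 - 2.0 * cov.omega * zh * zs + zs**2) / (2.0 * om2)
    )


@dataclass
class LikelihoodSurface:
    """Per-cell origin likelihood and normalized probability mass."""

    individual_id: str
    likelihood: Raster = field(repr=False)
    mass: Raster = field(repr=False)

    @property
    def grid(self) -> Grid:
        return self.likelihood.grid


@dataclass
class BinarySurface:
    """Likely (1) / unlikely (0) origin mask at a given odds ratio."""

    individual_id: str
    odds: float
    mask: Raster = field(repr=False)
    included_mass: float = np.nan

    @property
    def grid(self) -> Grid:
        return self.mask.grid

    @property
    def n_included(self) -> int:
        return int(self.mask.values.sum())


def likelihood_surface(
    individual: pd.Series | dict,
    iso_H: Isoscape,
    iso_S: Isoscape,
    cov: CovStructure,
) -> LikelihoodSurface:
    """Normalized bivariate likelihood surface for one individual.

    The density is evaluated per cell at that cell's (μ_H, μ_S) and
    normalized to a discrete probability mass over cells (sum 1). The
    normalization is done in log space so individuals far off the
    isoscape scale do not underflow to an all-zero surface.
    """
    if iso_H.grid != iso_S.grid:
        raise ValueError("isoscapes do not share grid registration")
    x = individual["d2H"]
    y = individual["d34S"]
    if pd.isna(x) or pd.isna(y):
        raise ValueError(
            f"individual {individual.get('id', '?')} missing an isotope value"
        )
    logf = _log_bnpdf(float(x), float(y), iso_H.mean.values, iso_S.mean.values, cov)
    dens = np.exp(logf)
    shifted = np.exp(logf - logf.max())
    mass = shifted / shifted.sum()
    return LikelihoodSurface(
        individual_id=str(individual.get("id", "")),
        likelihood=Raster(iso_H.grid, dens),
        mass=Raster(iso_H.grid, mass),
    )


def odds_threshold(odds: float) -> float:
    """Cumulative-mass threshold odds/(odds+1); 2:1 → 2/3 (the '67%')."""
    if odds <= 0:
        raise ValueError("odds ratio must be positive")
    return odds / (odds + 1.0)


def odds_binarize(ls: LikelihoodSurface, odds: float) -> BinarySurface:
    """Highest-density origin region at the given odds ratio.

    Cells are sorted by mass (descending, stable in cell index) and
    included until the cumulative mass reaches odds/(odds+1), boundary
    inclusive. The result is minimal: dropping its lowest-mass cell
    would fall below the threshold.
    """
    thr = odds_threshold(odds)
    m = ls.mass.values.ravel()
    order = np.argsort(-m, kind="stable")
    csum = np.cumsum(m[order])
    k = int(np.searchsorted(csum, thr - 1e-12)) + 1
    k = min(k, len(m))
    mask = np.zeros(m.shape, dtype=float)
    mask[order[:k]] = 1.0
    return BinarySurface(
        individual_id=ls.individual_id,
        odds=odds,
        mask=Raster(ls.grid, mask.reshape(ls.mass.values.shape)),
        included_mass=float(csum[k - 1]),
    )


def sum_binary_surfaces(surfaces: list[BinarySurface]) -> Raster:
    """Per-cell count of individuals whose likely-origin mask covers it."""
    if not surfaces:
        raise ValueError("no surfaces to sum")
    grid = surfaces[0].grid
    total = np.zeros((grid.ny, grid.nx))
    for s in surfaces:
        if s.grid != grid:
            raise ValueError("binary surfaces on mismatched grids")
        total += s.mask.values
    return Raster(grid, total)
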