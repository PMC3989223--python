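"""Bivariate likelihood surfaces, odds-ratio regions, and covariance recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from isoassign.assignment import (
    CovStructure,
    LikelihoodSurface,
    bnpdf,
    estimate_cov_structure,
    likelihood_surface,
    odds_binarize,
    odds_threshold,
    sum_binary_surfaces,
)
from isoassign.grids import Grid, Raster

from conftest import make_isoscape

DEFAULT_COV = CovStructure(sigma_H=10.5, sigma_S=3.8, omega=0.29)


class TestCovStructure:
    def test_matrix_is_positive_definite(self):
        m = DEFAULT_COV.matrix
        assert np.allclose(m, m.T)
        assert np.all(np.linalg.eigvalsh(m) > 0)
        assert m[0, 1] == pytest.approx(10.5 * 3.8 * 0.29)

    @pytest.mark.parametrize("kw", [dict(sigma_H=0.0), dict(omega=1.0),
                                    dict(omega=-1.2)])
    def test_invalid_rejected(self, kw):
        base = dict(sigma_H=10.5, sigma_S=3.8, omega=0.29)
        base.update(kw)
        with pytest.raises(ValueError):
            CovStructure(**base)


def _validation_cohort(rng, n_loc=22, per_loc=3,
                       sigma=(10.5, 3.8), omega=0.29):
    cov = np.array(
        [[sigma[0] ** 2, sigma[0] * sigma[1] * omega],
         [sigma[0] * sigma[1] * omega, sigma[1] ** 2]]
    )
    L = np.linalg.cholesky(cov)
    rows = []
    for j in range(n_loc):
        mu = rng.uniform([-100, 4], [-50, 15])
        eps = rng.standard_normal((per_loc, 2)) @ L.T
        for k in range(per_loc):
            rows.append(
                {"id": f"b{j}_{k}", "loc_id": f"L{j}",
                 "d2H": mu[0] + eps[k, 0], "d34S": mu[1] + eps[k, 1]}
            )
    return pd.DataFrame(rows)


class TestEstimateCov:
    def test_recovery_at_validation_sample_size(self):
        """66 birds over 22 locations (the validation design) recover the
        generating dispersion; single cohorts scatter (SE of ω is ~0.15
        at n=66), so the estimator is checked on the mean of 10 cohorts."""
        rng = np.random.default_rng(42)
        ests = [estimate_cov_structure(_validation_cohort(rng)) for _ in range(10)]
        assert np.mean([e.sigma_H for e in ests]) == pytest.approx(10.5, rel=0.10)
        assert np.mean([e.sigma_S for e in ests]) == pytest.approx(3.8, rel=0.10)
        assert np.mean([e.omega for e in ests]) == pytest.approx(0.29, abs=0.10)

    def test_singleton_locations_carry_no_information(self):
        df = _validation_cohort(np.random.default_rng(1), n_loc=5, per_loc=1)
        with pytest.raises(ValueError):
            estimate_cov_structure(df)

    def test_zero_residuals_degenerate(self):
        df = pd.DataFrame(
            {"id": list("abcd"), "loc_id": ["L1", "L1", "L2", "L2"],
             "d2H": [-70.0, -70.0, -80.0, -80.0], "d34S": [6.0, 6.0, 7.0, 7.0]}
        )
        with pytest.raises(ValueError):
            estimate_cov_structure(df)

    def test_perfect_correlation_boundary_rejected(self):
        df = pd.DataFrame(
            {"id": list("abcd"), "loc_id": ["L1", "L1", "L2", "L2"],
             "d2H": [-1.0, 1.0, -1.0, 1.0], "d34S": [-1.0, 1.0, -1.0, 1.0]}
        )
        with pytest.raises(ValueError, match="boundary|correlation"):
            estimate_cov_structure(df)


class TestBnpdf:
    def test_standard_normal_mode(self):
        cov = CovStructure(1.0, 1.0, 1e-12)
        assert bnpdf(0.0, 0.0, 0.0, 0.0, cov) == pytest.approx(
            1.0 / (2 * np.pi), rel=1e-9
        )

    def test_matches_scipy_multivariate_normal(self):
        rng = np.random.default_rng(0)
        mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=DEFAULT_COV.matrix)
        assert bnpdf(0.0, 0.0, 0.0, 0.0, DEFAULT_COV) == pytest.approx(
            mvn.pdf([0.0, 0.0]), abs=1e-12
        )
        for _ in range(20):
            x, y = rng.normal(0, 15, 2)
            assert bnpdf(x, y, 0.0, 0.0, DEFAULT_COV) == pytest.approx(
                mvn.pdf([x, y]), rel=1e-12
            )

    def test_factorizes_when_uncorrelated(self):
        cov = CovStructure(10.5, 3.8, 0.0)
        x, y = -63.2, 7.7
        expected = stats.norm.pdf(x, -70.0, 10.5) * stats.norm.pdf(y, 6.5, 3.8)
        assert bnpdf(x, y, -70.0, 6.5, cov) == pytest.approx(expected, rel=1e-12)


class TestLikelihoodSurface:
    def test_flat_isoscapes_give_uniform_mass(self, toy_grid):
        iso_h = make_isoscape(toy_grid, -70.0, "d2H")
        iso_s = make_isoscape(toy_grid, 6.5, "d34S")
        ls = likelihood_surface(
            {"id": "b1", "d2H": -64.0, "d34S": 7.0}, iso_h, iso_s, DEFAULT_COV
        )
        n = toy_grid.n_cells
        assert np.allclose(ls.mass.values, 1.0 / n, atol=1e-12)
        assert ls.mass.values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_mode_at_matching_cell(self, toy_grid):
        X, Y = toy_grid.cell_centers()
        iso_h = make_isoscape(toy_grid, -90.0 + 2.0 * X, "d2H")
        iso_s = make_isoscape(toy_grid, 4.0 + 0.8 * Y, "d34S")
        r, c = 4, 5
        ind = {"id": "b1", "d2H": iso_h.mean.values[r, c],
               "d34S": iso_s.mean.values[r, c]}
        ls = likelihood_surface(ind, iso_h, iso_s, DEFAULT_COV)
        assert np.unravel_index(np.argmax(ls.mass.values),
                                ls.mass.values.shape) == (r, c)

    def test_three_cell_hand_computation(self):
        grid = Grid(xmin=0.0, ymin=0.0, cell=1.0, nx=3, ny=1)
        mu_h = np.array([[-80.0, -70.0, -60.0]])
        mu_s = np.array([[5.0, 7.0, 9.0]])
        iso_h = make_isoscape(grid, mu_h, "d2H")
        iso_s = make_isoscape(grid, mu_s, "d34S")
        cov = CovStructure(10.0, 4.0, 0.25)
        x, y = -72.0, 6.0
        ls = likelihood_surface({"id": "b", "d2H": x, "d34S": y}, iso_h, iso_s, cov)
        om2 = 1 - 0.25**2
        dens = []
        for mh, ms in zip(mu_h[0], mu_s[0]):
            zh, zs = (x - mh) / 10.0, (y - ms) / 4.0
            q = (zh**2 - 2 * 0.25 * zh * zs + zs**2) / (2 * om2)
            dens.append(np.exp(-q) / (2 * np.pi * 10.0 * 4.0 * np.sqrt(om2)))
        dens = np.array(dens)
        assert np.allclose(ls.mass.values[0], dens / dens.sum(), atol=1e-12)
        assert np.allclose(ls.likelihood.values[0], dens, atol=1e-15)

    def test_grid_mismatch_errors(self, toy_grid):
        other = Grid(xmin=0.0, ymin=0.0, cell=3.0, nx=8, ny=6)
        with pytest.raises(ValueError, match="grid"):
            likelihood_surface(
                {"id": "b", "d2H": -70.0, "d34S": 6.0},
                make_isoscape(toy_grid, -70.0), make_isoscape(other, 6.0, "d34S"),
                DEFAULT_COV,
            )

    def test_missing_isotope_errors(self, toy_grid):
        with pytest.raises(ValueError, match="missing"):
            likelihood_surface(
                {"id": "b", "d2H": -70.0, "d34S": np.nan},
                make_isoscape(toy_grid, -70.0),
                make_isoscape(toy_grid, 6.0, "d34S"), DEFAULT_COV,
            )

    def test_far_off_scale_individual_still_normalizes(self, toy_grid):
        """Values hundreds of ‰ off the isoscape must not underflow to an
        all-zero surface (log-space normalization)."""
        iso_h = make_isoscape(toy_grid, -70.0, "d2H")
        iso_s = make_isoscape(toy_grid, 6.5, "d34S")
        ls = likelihood_surface(
            {"id": "b", "d2H": 500.0, "d34S": -200.0}, iso_h, iso_s, DEFAULT_COV
        )
        assert ls.mass.values.sum() == pytest.approx(1.0, abs=1e-9)


def _surface_from_masses(masses) -> LikelihoodSurface:
    masses = np.atleast_2d(np.asarray(masses, dtype=float))
    grid = Grid(xmin=0.0, ymin=0.0, cell=1.0, nx=masses.shape[1],
                ny=masses.shape[0])
    return LikelihoodSurface("b", Raster(grid, masses), Raster(grid, masses))


class TestOddsBinarize:
    def test_threshold_values(self):
        assert odds_threshold(2.0) == pytest.approx(2.0 / 3.0)
        assert odds_threshold(4.0) == pytest.approx(0.8)
        with pytest.raises(ValueError):
            odds_threshold(0.0)

    def test_uniform_three_cells_two_included(self):
        bs = odds_binarize(_surface_from_masses([1 / 3, 1 / 3, 1 / 3]), 2.0)
        assert bs.n_included == 2
        assert bs.included_mass == pytest.approx(2 / 3)

    def test_cumulative_hand_example_2to1(self):
        bs = odds_binarize(_surface_from_masses([0.5, 0.3, 0.15, 0.05]), 2.0)
        assert bs.mask.values.ravel().tolist() == [1.0, 1.0, 0.0, 0.0]
        assert bs.included_mass == pytest.approx(0.8)

    def test_cumulative_hand_example_4to1_boundary_inclusive(self):
        bs = odds_binarize(_surface_from_masses([0.5, 0.3, 0.15, 0.05]), 4.0)
        assert bs.mask.values.ravel().tolist() == [1.0, 1.0, 0.0, 0.0]

    @given(st.lists(st.floats(0.001, 1.0), min_size=3, max_size=40),
           st.sampled_from([2.0, 4.0]))
    def test_minimality_and_mass_bounds(self, raw, odds):
        masses = np.array(raw) / np.sum(raw)
        bs = odds_binarize(_surface_from_masses(masses), odds)
        thr = odds_threshold(odds)
        assert thr - 1e-9 <= bs.included_mass <= 1.0 + 1e-9
        inc = masses[bs.mask.values.ravel() > 0]
        if len(inc) > 1:  # dropping the smallest included cell breaks it
            assert bs.included_mass - inc.min() < thr

    @given(st.lists(st.floats(0.001, 1.0), min_size=3, max_size=40))
    def test_nesting_two_to_one_inside_four_to_one(self, raw):
        masses = np.array(raw) / np.sum(raw)
        ls = _surface_from_masses(masses)
        m2 = odds_binarize(ls, 2.0).mask.values
        m4 = odds_binarize(ls, 4.0).mask.values
        assert np.all(m4 >= m2)


class TestSumSurfaces:
    def test_identity_and_disjoint(self):
        a = odds_binarize(_surface_from_masses([0.6, 0.3, 0.06, 0.04]), 2.0)
        total = sum_binary_surfaces([a])
        assert np.array_equal(total.values, a.mask.values)
        b = odds_binarize(_surface_from_masses([0.04, 0.06, 0.3, 0.6]), 2.0)
        both = sum_binary_surfaces([a, b])
        assert both.values.max() <= 1.0  # disjoint regions never stack
        assert both.values.sum() == a.mask.values.sum() + b.mask.values.sum()

    def test_recount_oracle(self):
        rng = np.random.default_rng(5)
        surfaces = []
        for _ in range(35):
            raw = rng.uniform(0.01, 1.0, size=(4, 6))
            surfaces.append(odds_binarize(_surface_from_masses(raw / raw.sum()), 2.0))
        total = sum_binary_surfaces(surfaces)
        stack = np.stack([s.mask.values for s in surfaces])
        assert np.array_equal(total.values, stack.sum(axis=0))
        assert total.values.max() <= 35


class TestCoverage:
    def test_true_origin_covered_by_two_to_one_region(self):
        """On birds generated under the assignment model the 2:1 region
        contains the true origin in at least 60% of 200 cases (the
        region is a ~2/3 highest-density region)."""
        rng = np.random.default_rng(0)
        grid = Grid(xmin=0.0, ymin=0.0, cell=10.0, nx=40, ny=40)
        X, Y = grid.cell_centers()
        mu_h = -95.0 + 0.08 * X + 0.03 * Y
        mu_s = 4.0 + 0.02 * X
        iso_h = make_isoscape(grid, mu_h, "d2H")
        iso_s = make_isoscape(grid, mu_s, "d34S")
        L = np.linalg.cholesky(DEFAULT_COV.matrix)
        hits = 0
        n = 200
        for i in range(n):
            r = rng.integers(0, grid.ny)
            c = rng.integers(0, grid.nx)
            eps = L @ rng.standard_normal(2)
            ind = {"id": f"b{i}", "d2H": mu_h[r, c] + eps[0],
                   "d34S": mu_s[r, c] + eps[1]}
            ls = likelihood_surface(ind, iso_h, iso_s, DEFAULT_COV)
            bs = odds_binarize(ls, 2.0)
            hits += bs.mask.values[r, c] > 0
        assert hits / n >= 0.60

    def test_age_shift_moves_mode_along_gradient(self):
        """Shifting δ2H moves each modal origin cell monotonically along
        the δ2H gradient direction (here: east)."""
        grid = Grid(xmin=0.0, ymin=0.0, cell=10.0, nx=30, ny=10)
        X, _ = grid.cell_centers()
        iso_h = make_isoscape(grid, -90.0 + 0.1 * X, "d2H")
        iso_s = make_isoscape(grid, 6.5, "d34S")
        mode_x = []
        for shift in (-6.0, -3.0, 0.0, 3.0, 6.0):
            ls = likelihood_surface(
                {"id": "b", "d2H": -75.0 + shift, "d34S": 6.5},
                iso_h, iso_s, DEFAULT_COV,
            )
            idx = np.unravel_index(np.argmax(ls.mass.values), ls.mass.values.shape)
            mode_x.append(X[idx])
        assert all(b >= a for a, b in zip(mode_x, mode_x[1:]))
        assert mode_x[-1] > mode_x[0]
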