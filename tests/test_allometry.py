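"""PGLS allometric correction and the running variance profile."""

import numpy as np
import pandas as pd
import pytest

import wingmod as wm
from wingmod.allometry import (
    CANONICAL_ELEMENTS,
    MODULE_MAP,
    fit_pgls_allometry,
    mass_sorted_species,
    residual_matrix,
    running_iqr,
)
from wingmod.phylo import inv_matrix, pagel_transform, simulate_bm
from wingmod.synthetic import SyntheticConfig, simulate_mass, simulate_tree

from conftest import star_newick


def make_table(tree, log_mass, sizes):
    """Trait table with every element column equal to `sizes` plus offsets."""
    df = pd.DataFrame(
        {el: sizes + 0.01 * i for i, el in enumerate(CANONICAL_ELEMENTS)},
        index=tree.tips,
    )
    df.insert(0, "log_mass", log_mass)
    return df


@pytest.fixture(scope="module")
def setup32():
    cfg = SyntheticConfig(n_species=32, seed=5)
    tree = simulate_tree(cfg)
    cov = wm.vcv_matrix(tree)
    log_mass = simulate_mass(tree, cfg, cov=cov)
    return tree, cov, log_mass


def test_module_map_is_the_canonical_partition():
    assert len(CANONICAL_ELEMENTS) == 13
    counts = pd.Series(MODULE_MAP).value_counts()
    assert counts.to_dict() == {"trunk": 4, "wing": 4, "leg": 3, "head": 2}


class TestPglsAllometry:
    def test_exact_allometry_gives_zero_residuals(self, setup32):
        tree, cov, log_mass = setup32
        sizes = 0.33 * log_mass.to_numpy() + 1.0
        table = make_table(tree, log_mass, sizes)
        fit = fit_pgls_allometry(table, "humerus", tree, cov=cov)
        assert fit.slope == pytest.approx(0.33, abs=1e-8)
        assert np.allclose(fit.residuals, 0.0, atol=1e-8)

    def test_lambda_zero_equals_ols_normal_equations(self, setup32, rng):
        tree, cov, log_mass = setup32
        sizes = 0.33 * log_mass.to_numpy() + rng.normal(0, 0.05, cov.n)
        table = make_table(tree, log_mass, sizes)
        fit = fit_pgls_allometry(table, "femur", tree, cov=cov, lam=0.0)
        x = log_mass.loc[cov.tip_order].to_numpy()
        y = table.loc[cov.tip_order, "femur"].to_numpy()
        # OLS via explicit normal equations; lambda=0 leaves only the
        # (equal, ultrametric) diagonal so GLS collapses to OLS
        X = np.column_stack([np.ones(cov.n), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-8)
        assert fit.slope == pytest.approx(beta[1], abs=1e-8)

    def test_residuals_gls_orthogonal_to_mass(self, setup32, rng):
        tree, cov, log_mass = setup32
        sizes = (
            0.33 * log_mass.to_numpy()
            + simulate_bm(cov, rng, sigma2=0.01)[0]
        )
        table = make_table(tree, log_mass, sizes)
        fit = fit_pgls_allometry(table, "ulna", tree, cov=cov)
        Vinv = inv_matrix(pagel_transform(cov, fit.lambda_hat).C)
        e = fit.residuals.to_numpy()
        x = log_mass.loc[cov.tip_order].to_numpy()
        assert abs(np.ones(cov.n) @ Vinv @ e) < 1e-8  # zero GLS mean
        xc = x - np.mean(x)
        corr = (e @ Vinv @ xc) / np.sqrt((e @ Vinv @ e) * (xc @ Vinv @ xc))
        assert abs(corr) < 1e-6

    def test_star_tree_pgls_collapses_to_ols(self, rng):
        tree = wm.read_newick(star_newick(16))
        cov = wm.vcv_matrix(tree)
        log_mass = pd.Series(rng.uniform(1, 3, 16), index=tree.tips)
        sizes = 0.3 * log_mass.to_numpy() + rng.normal(0, 0.1, 16)
        table = make_table(tree, log_mass, sizes)
        free = fit_pgls_allometry(table, "cranium", tree, cov=cov)
        ols = fit_pgls_allometry(table, "cranium", tree, cov=cov, lam=0.0)
        assert free.slope == pytest.approx(ols.slope, abs=1e-8)
        assert free.intercept == pytest.approx(ols.intercept, abs=1e-8)

    def test_constant_mass_is_singular(self, setup32):
        tree, cov, log_mass = setup32
        table = make_table(tree, pd.Series(2.0, index=tree.tips), np.ones(cov.n))
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            fit_pgls_allometry(table, "humerus", tree, cov=cov)

    def test_slope_recovery_on_synthetic_data(self):
        slopes = []
        for seed in range(10):
            cfg = SyntheticConfig(n_species=128, seed=seed)
            tree = simulate_tree(cfg)
            cov = wm.vcv_matrix(tree)
            log_mass = simulate_mass(tree, cfg, cov=cov)
            rng = np.random.default_rng(seed + 1000)
            sizes = 0.33 * log_mass.to_numpy() + rng.normal(0, 0.05, cov.n)
            table = make_table(tree, log_mass, sizes)
            slopes.append(fit_pgls_allometry(table, "radius", tree, cov=cov).slope)
        assert abs(np.mean(slopes) - 0.33) < 0.03


class TestResidualMatrix:
    def test_shape_and_perfect_allometry(self, setup32):
        tree, cov, log_mass = setup32
        table = make_table(tree, log_mass, 0.33 * log_mass.to_numpy())
        R = residual_matrix(table, tree, cov=cov)
        assert R.shape == (32, 13)
        assert np.allclose(R.to_numpy(), 0.0, atol=1e-8)

    def test_columns_match_individual_fits(self, setup32, rng):
        tree, cov, log_mass = setup32
        sizes = 0.33 * log_mass.to_numpy() + rng.normal(0, 0.05, cov.n)
        table = make_table(tree, log_mass, sizes)
        R = residual_matrix(table, tree, cov=cov)
        for el in ("cranium", "sternum", "tarsometatarsus"):
            fit = fit_pgls_allometry(table, el, tree, cov=cov)
            assert np.array_equal(R[el].to_numpy(), fit.residuals.to_numpy())


class TestRunningIqr:
    def test_constant_values_flat_zero(self, setup32):
        tree, _, log_mass = setup32
        v = pd.Series(1.0, index=tree.tips, name="humerus")
        prof = running_iqr(v, log_mass, window=30)
        assert np.allclose(prof.iqr, 0.0)
        assert len(prof.iqr) == 32

    def test_rank_values_interior_iqr(self):
        n = 60
        idx = [f"s{i:02d}" for i in range(n)]
        log_mass = pd.Series(np.linspace(1, 3, n), index=idx)
        v = pd.Series(np.arange(1.0, n + 1), index=idx, name="x")
        prof = running_iqr(v, log_mass, window=30)
        # interior window is 30 consecutive ranks: IQR of 1..30 with
        # linear-interpolation quantiles is 22.25 - 8.75 = 14.5
        assert prof.iqr[30] == pytest.approx(14.5)

    def test_row_order_invariance(self, setup32, rng):
        tree, _, log_mass = setup32
        v = pd.Series(rng.standard_normal(32), index=tree.tips, name="x")
        shuffled = v.sample(frac=1, random_state=1)
        p1 = running_iqr(v, log_mass, window=30)
        p2 = running_iqr(shuffled, log_mass, window=30)
        assert p1.species == p2.species
        assert np.allclose(p1.iqr, p2.iqr)

    def test_window_larger_than_n_errors(self, setup32):
        tree, _, log_mass = setup32
        v = pd.Series(1.0, index=tree.tips, name="x")
        with pytest.raises(ValueError):
            running_iqr(v, log_mass, window=64)

    def test_mass_proportional_scatter_gives_rising_profile(self):
        from scipy.stats import spearmanr

        rhos = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 100
            idx = [f"s{i:03d}" for i in range(n)]
            m = pd.Series(np.linspace(1, 3, n), index=idx)
            v = pd.Series(rng.normal(0, m.to_numpy()), index=idx, name="x")
            prof = running_iqr(v, m, window=30)
            rhos.append(spearmanr(np.arange(n), prof.iqr).statistic)
        assert np.mean(rhos) > 0


def test_mass_sort_breaks_ties_by_name():
    idx = ["b", "a", "c"]
    t = pd.DataFrame({"log_mass": [2.0, 2.0, 1.0]}, index=idx)
    assert mass_sorted_species(t) == ["c", "a", "b"]
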