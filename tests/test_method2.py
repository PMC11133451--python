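"""Major-axis dispersion, running ribbons, resampling and heteroskedasticity."""

import numpy as np
import pandas as pd
import pytest

from wingmod.method2 import (
    Method2Config,
    bp_test_one_tailed,
    dispersion_record,
    flame_analysis,
    gaussian_mass_resample,
    major_axis_distance,
    run_method2,
    running_ribbon,
)
from wingmod.synthetic import generate_scenario


class TestMajorAxisDistance:
    def test_collinear_points_have_zero_distance(self):
        m, d = major_axis_distance([0.0, 1.0, 2.0], [0.0, 1.0, 2.0])
        assert np.allclose(d, 0.0, atol=1e-12)
        assert np.allclose(m, [1, 1] / np.sqrt(2))

    def test_geometric_oracle(self):
        x = np.array([0.0, 2.0, 1.0])
        y = np.array([0.0, 0.0, 1.0])
        m, d = major_axis_distance(x, y)
        # oracle: perpendicular distance of each centred point from the
        # leading eigenvector line through the centroid
        P = np.column_stack([x - x.mean(), y - y.mean()])
        S = np.cov(P.T)
        w, U = np.linalg.eigh(S)
        v = U[:, np.argmax(w)]
        perp = P - np.outer(P @ v, v)
        assert np.allclose(np.abs(d), np.linalg.norm(perp, axis=1), atol=1e-12)

    def test_swap_symmetry_up_to_sign(self, rng):
        x = rng.standard_normal(40)
        y = 0.8 * x + 0.3 * rng.standard_normal(40)
        _, d1 = major_axis_distance(x, y)
        _, d2 = major_axis_distance(y, x)
        assert np.allclose(np.abs(d1), np.abs(d2), atol=1e-10)

    def test_isotropic_cloud_is_ambiguous(self):
        x = np.array([1.0, -1.0, 0.0, 0.0])
        y = np.array([0.0, 0.0, 1.0, -1.0])
        with pytest.raises(ValueError, match="ambiguous"):
            major_axis_distance(x, y)

    def test_centred_and_variance_partition(self, rng):
        """D_m sums to ~0 and its energy is the non-major-axis variance."""
        x = rng.standard_normal(60)
        y = 0.6 * x + 0.5 * rng.standard_normal(60)
        _, d = major_axis_distance(x, y)
        assert abs(d.mean()) < 1e-10
        P = np.column_stack([x - x.mean(), y - y.mean()])
        S = P.T @ P / 59
        w = np.linalg.eigvalsh(S)
        assert d @ d == pytest.approx(59 * (np.trace(S) - w[-1]), abs=1e-10)


class TestRunningRibbon:
    def _series(self, values, masses):
        idx = [f"s{i:03d}" for i in range(len(values))]
        return (
            pd.Series(values, index=idx, name="D_m"),
            pd.Series(masses, index=idx, name="log_mass"),
        )

    def test_symmetric_signs_give_symmetric_bands(self):
        d, m = self._series(
            [1.0 if i % 2 else -1.0 for i in range(40)], np.linspace(1, 3, 40)
        )
        rib = running_ribbon(d, m, window=30)
        interior = rib.iloc[15:-15]
        assert np.allclose(interior["lo1"], -interior["hi1"], atol=1e-12)

    def test_bands_nested(self, rng):
        d, m = self._series(rng.standard_normal(50), np.linspace(1, 3, 50))
        rib = running_ribbon(d, m, window=30)
        assert (rib["lo2"] <= rib["lo1"]).all()
        assert (rib["hi1"] <= rib["hi2"]).all()

    def test_band_width_tracks_mass_dependent_scatter(self):
        ratios = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 200
            mass = np.linspace(1, 3, n)
            sd = 1.0 + (mass - 1) / 2  # doubles across the range
            d, m = self._series(rng.normal(0, sd), mass)
            rib = running_ribbon(d, m, window=30)
            first = rib.iloc[20]
            last = rib.iloc[-20]
            ratios.append(
                (last["hi1"] - last["lo1"]) / (first["hi1"] - first["lo1"])
            )
        assert 1.5 <= np.mean(ratios) <= 2.5


class TestGaussianMassResample:
    def _mass(self, values):
        return pd.Series(values, index=[f"s{i:03d}" for i in range(len(values))])

    def test_single_interval_cap(self):
        m = self._mass(np.r_[np.zeros(30), 10.0])  # 30 species share a bin
        sub = gaussian_mass_resample(list(m.index), m, seed=0)
        from collections import Counter

        bins = Counter(0 if m[s] < 5 else 1 for s in sub)
        assert bins[0] <= 10

    def test_deterministic_under_seed(self):
        m = self._mass(np.linspace(1, 3, 80))
        a = gaussian_mass_resample(list(m.index), m, seed=5)
        b = gaussian_mass_resample(list(m.index), m, seed=5)
        assert a == b

    def test_reduces_right_skew(self):
        from scipy.stats import skew

        rng = np.random.default_rng(0)
        m = self._mass(np.sort(rng.exponential(0.4, 200) + 1))
        full_skew = abs(skew(m))
        hits = 0
        for it in range(100):
            sub = gaussian_mass_resample(list(m.index), m, seed=it)
            hits += abs(skew(m.loc[sub])) < full_skew
        assert hits >= 80


class TestBreuschPagan:
    def test_matches_nr2_auxiliary_oracle(self):
        d = np.array([0.1, -0.4, 0.2, 0.5, -0.3, -0.1, 0.25, -0.15, 0.05, 0.33])
        m = np.array([1.0, 1.2, 1.5, 1.9, 2.1, 2.4, 2.5, 2.8, 3.0, 3.3])
        # oracle: OLS residuals, then n * R^2 of e^2 on mass, chi2 1 df
        from scipy.stats import chi2

        X = np.column_stack([np.ones(10), m])
        e = d - X @ np.linalg.lstsq(X, d, rcond=None)[0]
        u = e**2
        uhat = X @ np.linalg.lstsq(X, u, rcond=None)[0]
        r2 = 1 - ((u - uhat) ** 2).sum() / ((u - u.mean()) ** 2).sum()
        p_two = chi2.sf(10 * r2, 1)
        slope = np.polyfit(m, u, 1)[0]
        direction = "increasing" if slope > 0 else "decreasing"
        p_one = bp_test_one_tailed(d, m, direction=direction)
        assert p_one == pytest.approx(p_two / 2, abs=1e-10)
        other = "decreasing" if direction == "increasing" else "increasing"
        assert bp_test_one_tailed(d, m, other) == pytest.approx(1 - p_two / 2, abs=1e-10)

    def test_power_against_mass_proportional_scatter(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            m = np.linspace(1, 3, 150)
            d = rng.normal(0, m)
            hits += bp_test_one_tailed(d, m, "increasing") < 0.05
        assert hits >= 80

    def test_constant_mass_errors(self):
        with pytest.raises(ValueError):
            bp_test_one_tailed(np.arange(10.0), np.ones(10), "increasing")


@pytest.fixture(scope="module")
def md59():
    return generate_scenario("mass_dependent", seed=6, n_species=59)


class TestFlameAndRunMethod2:
    def test_flame_deterministic_and_valid_p(self, md59):
        from wingmod.allometry import residual_matrix

        tree, table, _ = md59
        R = residual_matrix(table, tree, elements=("humerus", "carpometacarpus"))
        kw = dict(pair=("humerus", "carpometacarpus"), direction="decreasing",
                  n_iter=10, master_seed=3)
        f1 = flame_analysis(R, table["log_mass"], **kw)
        f2 = flame_analysis(R, table["log_mass"], **kw)
        assert np.array_equal(f1.real_p, f2.real_p)
        assert np.array_equal(f1.null_p, f2.null_p)
        for p in (f1.real_p, f1.null_p):
            assert ((p > 0) & (p <= 1)).all()

    def test_run_method2_outliers_match_definition(self, md59):
        tree, table, _ = md59
        cfg = Method2Config(n_iter=5, master_seed=2)
        res = run_method2(table, tree, cfg)
        for pair, rec in res.records.items():
            rib = res.ribbons[pair]
            d = rec.D_m.loc[rib.index]
            outside = set(rib.index[(d < rib["lo2"]) | (d > rib["hi2"])])
            tag = f"{pair[0]}|{pair[1]}"
            listed = set(res.outliers.query("pair == @tag")["species"])
            assert listed == outside

    def test_run_method2_deterministic(self, md59):
        tree, table, _ = md59
        cfg = Method2Config(n_iter=5, master_seed=8)
        r1 = run_method2(table, tree, cfg)
        r2 = run_method2(table, tree, cfg)
        for f1, f2 in zip(r1.flames, r2.flames):
            assert np.array_equal(f1.real_p, f2.real_p)
        pd.testing.assert_frame_equal(r1.outliers, r2.outliers)
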