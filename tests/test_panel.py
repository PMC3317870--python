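"""Panel validation, transforms, pooled and fixed-effects OLS."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spanel import (
    add_spatial_lags,
    fe_ols,
    log_outcome,
    pooled_ols,
    validate_panel,
    within_transform,
)
from spanel.synthetic import SyntheticConfig, lattice_for, simulate_panel

from conftest import make_panel


def long_records(n=2, t=2, shuffle_seed=None):
    rows = []
    for s in range(t):
        for i in range(n):
            rows.append(
                {
                    "region_id": f"r{i}",
                    "period": f"p{s}",
                    "outcome": 10.0 * s + i + 1,
                    "x0": float(i - s),
                }
            )
    if shuffle_seed is not None:
        rng = np.random.default_rng(shuffle_seed)
        rows = [rows[j] for j in rng.permutation(len(rows))]
    return rows


class TestValidate:
    def test_period_major_ordering(self):
        p = validate_panel(long_records())
        assert p.region_ids == ["r0", "r1"]
        assert p.period_labels == ["p0", "p1"]
        assert np.allclose(p.y, [1, 2, 11, 12])

    def test_shuffle_invariance(self):
        a = validate_panel(long_records(3, 3))
        b = validate_panel(long_records(3, 3, shuffle_seed=5))
        assert np.array_equal(a.y, b.y) and np.array_equal(a.X, b.X)

    def test_missing_pair_named(self):
        rows = long_records()[:-1]
        with pytest.raises(ValueError, match=r"\('r1', 'p1'\)"):
            validate_panel(rows)

    def test_duplicate_pair_rejected(self):
        rows = long_records() + [long_records()[0]]
        with pytest.raises(ValueError, match="duplicated"):
            validate_panel(rows)

    def test_non_numeric_covariate(self):
        rows = long_records()
        rows[0]["x0"] = "abc"
        with pytest.raises(ValueError, match="x0"):
            validate_panel(rows)


class TestLogOutcome:
    def test_unit_maps_to_zero_and_inverse(self):
        p = validate_panel(long_records())
        p1 = log_outcome(p)
        assert np.allclose(np.exp(p1.y), p.y)
        p.y[:] = 1.0
        assert np.allclose(log_outcome(p).y, 0.0)

    def test_base10_magnitude(self):
        p = validate_panel(long_records())
        p.y[:] = 86.77
        assert log_outcome(p, base=10).y[0] == pytest.approx(1.938, abs=5e-4)

    def test_nonpositive_rejected(self):
        p = validate_panel(long_records())
        p.y[2] = -1.0
        with pytest.raises(ValueError, match="nonpositive"):
            log_outcome(p)


class TestSpatialLagColumns:
    def test_constant_and_shape(self, rook3_std, rng):
        p = make_panel(rng, 9, 3, 2)
        p.region_ids = list(rook3_std.ids)
        p.X[:, 0] = 4.2
        out = add_spatial_lags(p, rook3_std, ["x0", "x1"])
        assert out.X.shape[1] == 4
        assert out.covariate_names[-2:] == ["W*x0", "W*x1"]
        assert np.allclose(out.X[:, 2], 4.2)

    def test_matches_per_period_neighbour_loop(self, rook3_std, rng):
        p = make_panel(rng, 9, 3, 1)
        p.region_ids = list(rook3_std.ids)
        out = add_spatial_lags(p, rook3_std, ["x0"])
        xb = p.x_blocks()
        for s in range(3):
            want = np.array([xb[s, nb, 0].mean() for nb in rook3_std.neighbors])
            got = out.x_blocks()[s, :, 1]
            assert np.allclose(got, want, atol=1e-12)

    def test_unknown_name(self, rook3_std, rng):
        p = make_panel(rng, 9, 2, 1)
        p.region_ids = list(rook3_std.ids)
        with pytest.raises(ValueError, match="unknown"):
            add_spatial_lags(p, rook3_std, ["nope"])


class TestWithin:
    def test_constant_region_maps_to_zero(self, rng):
        p = make_panel(rng, 4, 3, 2)
        yb = p.y_blocks()
        yb[:] = yb[0]
        p.y = yb.ravel()
        d = within_transform(p).panel
        assert np.allclose(d.y, 0.0)

    def test_region_time_means_vanish(self, rng):
        p = make_panel(rng, 7, 4, 3)
        d = within_transform(p).panel
        assert np.abs(d.y_blocks().mean(axis=0)).max() < 1e-12
        assert np.abs(d.x_blocks().mean(axis=0)).max() < 1e-12

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(2, 9), st.integers(2, 5), st.integers(0, 2**31 - 1))
    def test_idempotent(self, n, t, seed):
        p = make_panel(np.random.default_rng(seed), n, t, 2)
        once = within_transform(p).panel
        twice = within_transform(once).panel
        assert np.allclose(once.y, twice.y, atol=1e-12)
        assert np.allclose(once.X, twice.X, atol=1e-12)


def lsdv_fit(p):
    """Dummy-variable oracle: OLS of y on [X, region dummies]."""
    n, t = p.n_regions, p.n_periods
    D = np.tile(np.eye(n), (t, 1))
    Z = np.column_stack([p.X, D])
    coef, *_ = np.linalg.lstsq(Z, p.y, rcond=None)
    k = p.X.shape[1]
    return coef[:k], coef[k:]


class TestPooled:
    def test_exact_linear_fit(self, rng):
        p = make_panel(rng, 10, 2, 2)
        p.y = 1.5 + p.X @ np.array([2.0, -1.0])
        fr = pooled_ols(p)
        assert fr.r2 == pytest.approx(1.0)
        assert np.abs(fr.residuals).max() < 1e-10

    def test_matches_normal_equations(self, rng):
        p = make_panel(rng, 50, 1, 3)
        fr = pooled_ols(p)
        Xc = np.column_stack([np.ones(50), p.X])
        want = np.linalg.solve(Xc.T @ Xc, Xc.T @ p.y)
        assert np.allclose(np.concatenate([[fr.alpha], fr.beta]), want, atol=1e-10)

    def test_row_permutation_invariance(self, rng):
        p = make_panel(rng, 12, 1, 2)
        fr = pooled_ols(p)
        perm = rng.permutation(12)
        p2 = make_panel(rng, 12, 1, 2)
        p2.y, p2.X = p.y[perm], p.X[perm]
        fr2 = pooled_ols(p2)
        assert np.allclose(fr.beta, fr2.beta, atol=1e-12)

    def test_rank_deficiency_names_column(self, rng):
        p = make_panel(rng, 20, 1, 3)
        p.X[:, 2] = 2 * p.X[:, 0]
        with pytest.raises(ValueError, match="x2"):
            pooled_ols(p)

    def test_adding_covariate_never_lowers_r2(self, rng):
        p = make_panel(rng, 30, 2, 3)
        small = make_panel(rng, 30, 2, 3)
        small.y, small.X = p.y, p.X[:, :2]
        small.covariate_names = p.covariate_names[:2]
        assert pooled_ols(p).r2 >= pooled_ols(small).r2 - 1e-12
        assert 0.0 <= pooled_ols(p).r2 <= 1.0


class TestFixedEffects:
    def test_equals_lsdv(self, rng):
        p = make_panel(rng, 8, 3, 2)
        fr = fe_ols(p)
        beta, effects = lsdv_fit(p)
        assert np.allclose(fr.beta, beta, atol=1e-10)
        assert np.allclose(fr.mu, effects - effects.mean(), atol=1e-8)

    def test_mu_sums_to_zero_and_reconstruction(self, rng):
        p = make_panel(rng, 10, 3, 2)
        fr = fe_ols(p)
        assert fr.mu.sum() == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(fr.fitted + fr.residuals, p.y, atol=1e-10)

    def test_time_invariant_covariate_named(self, rng):
        p = make_panel(rng, 6, 3, 2)
        xb = p.x_blocks()
        xb[:, :, 1] = xb[0, :, 1]
        p.X = xb.reshape(p.n_obs, -1)
        with pytest.raises(ValueError, match="x1"):
            fe_ols(p)

    def test_recovers_slopes_under_strong_heterogeneity(self, lattice20_std):
        """Monte-Carlo: beta=(true vector) recovered within 3 MC SEs despite
        region effects an order of magnitude larger than the noise."""
        reps = 200
        w = lattice20_std
        est = []
        for s in range(reps):
            cfg = SyntheticConfig(process="none", sigma_mu=1.5, seed=20_000 + s)
            p, truth = simulate_panel(cfg, w)
            est.append(fe_ols(p).beta)
        est = np.array(est)
        mcse = est.std(axis=0, ddof=1) / np.sqrt(reps)
        assert np.all(np.abs(est.mean(axis=0) - truth.beta) < 3 * mcse)

    def test_pooled_and_fe_agree_without_heterogeneity(self, lattice20_std):
        cfg = SyntheticConfig(process="none", sigma_mu=1e-12, seed=5)
        p, _ = simulate_panel(cfg, lattice20_std)
        diff = np.abs(pooled_ols(p).beta - fe_ols(p).beta)
        se = pooled_ols(p).std_errors
        assert np.all(diff < 4 * se)
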