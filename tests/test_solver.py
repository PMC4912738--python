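import numpy as np
import pytest
import scipy.stats

from exprecover import (
    MatrixCompletion,
    ObservationMask,
    SVTParams,
    SyntheticSpec,
    complete,
    default_delta,
    default_tau,
    frobenius_relative_error,
    generate_low_rank,
    nuclear_norm,
    sample_mask,
    shrink,
)


class TestShrink:
    def test_tau_zero_is_identity(self, rng):
        x = rng.normal(size=(12, 8))
        np.testing.assert_allclose(shrink(x, 0.0), x, atol=1e-12)

    def test_diagonal_closed_form(self):
        # SVD of diag(5,3,1) is itself; soft threshold by 2 -> diag(3,1,0)
        x = np.diag([5.0, 3.0, 1.0])
        np.testing.assert_allclose(shrink(x, 2.0), np.diag([3.0, 1.0, 0.0]), atol=1e-12)

    def test_singular_values_match_full_svd_oracle(self, rng):
        for _ in range(10):
            x = rng.normal(size=(20, 20))
            s = np.linalg.svd(x, compute_uv=False)
            for tau in (0.0, 0.5 * s[0], s[0]):
                got = np.linalg.svd(shrink(x, tau), compute_uv=False)
                np.testing.assert_allclose(got, np.maximum(s - tau, 0.0), atol=1e-9)

    def test_never_increases_singular_values_and_rank_decreasing_in_tau(self, rng):
        x = rng.normal(size=(15, 10))
        s0 = np.linalg.svd(x, compute_uv=False)
        prev_rank = np.inf
        for tau in (0.0, 1.0, 3.0, 10.0):
            s = np.linalg.svd(shrink(x, tau), compute_uv=False)
            assert np.all(s <= s0 + 1e-10)
            rank = int((s > 1e-10).sum())
            assert rank <= prev_rank
            prev_rank = rank

    def test_nonfinite_input_fails(self):
        with pytest.raises(ValueError):
            shrink(np.array([[np.nan, 1.0]]), 1.0)


class TestNuclearNorm:
    def test_zero_and_diagonal(self):
        assert nuclear_norm(np.zeros((3, 4))) == 0.0
        assert nuclear_norm(np.diag([5.0, 3.0, 1.0])) == pytest.approx(9.0)

    def test_orthogonal_invariance(self, rng):
        x = rng.normal(size=(10, 10))
        q = scipy.stats.ortho_group.rvs(10, random_state=rng)
        r = scipy.stats.ortho_group.rvs(10, random_state=rng)
        assert nuclear_norm(q @ x @ r) == pytest.approx(nuclear_norm(x), rel=1e-10)

    def test_matches_svd_oracle(self, rng):
        x = rng.normal(size=(9, 14))
        assert nuclear_norm(x) == pytest.approx(
            np.linalg.svd(x, compute_uv=False).sum(), rel=1e-12)


class TestDefaults:
    @pytest.mark.parametrize("m,n,expected", [(150, 150, 750.0), (2000, 2000, 10000.0), (1, 1, 5.0)])
    def test_default_tau(self, m, n, expected):
        assert default_tau(m, n) == pytest.approx(expected)

    @pytest.mark.parametrize("m,n,k,expected", [(10, 10, 100, 1.2), (10, 10, 50, 2.4), (100, 10, 100, 12.0)])
    def test_default_delta(self, m, n, k, expected):
        assert default_delta(m, n, k) == pytest.approx(expected)

    def test_default_delta_rejects_zero_observed(self):
        with pytest.raises(ValueError):
            default_delta(10, 10, 0)


class TestSVTParams:
    @pytest.mark.parametrize("kw", [dict(tau=-1, delta=1), dict(tau=1, delta=0),
                                    dict(tau=1, delta=1, tolerance=0),
                                    dict(tau=1, delta=1, max_iterations=0),
                                    dict(tau=1, delta=1, divergence_factor=1.0)])
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            SVTParams(**kw)


class TestComplete:
    def test_exact_recovery_noiseless(self, lowrank_80x60):
        x, mask = lowrank_80x60
        res = complete(x, mask)
        assert res.converged
        assert res.effective_rank == 2
        assert frobenius_relative_error(x.values, res.recovered.values) <= 1e-3

    def test_fully_observed_converges_and_matches_on_omega(self, rng):
        x = rng.normal(size=(20, 15))
        mask = ObservationMask.full(20, 15)
        res = complete(x, mask)
        assert res.converged
        assert res.omega_error <= 1e-8
        np.testing.assert_array_equal(mask.values_at(res.recovered.values),
                                      mask.values_at(x))

    def test_restore_observed_flag(self, lowrank_80x60):
        x, mask = lowrank_80x60
        kept = complete(x, mask, restore_observed=True)
        raw = complete(x, mask, restore_observed=False)
        np.testing.assert_array_equal(mask.values_at(kept.recovered.values),
                                      mask.values_at(x.values))
        # the raw iterate is close on Omega but not bitwise equal
        assert not np.array_equal(mask.values_at(raw.recovered.values),
                                  mask.values_at(x.values))

    def test_trace_invariants(self, lowrank_80x60):
        x, mask = lowrank_80x60
        res = complete(x, mask)
        assert len(res.omega_error_trace) == res.iterations_run
        assert res.converged == (res.omega_error_trace[-1] <= res.params.tolerance)
        assert res.effective_rank <= min(x.shape)

    def test_empty_mask_fails(self, rng):
        x = rng.normal(size=(5, 5))
        with pytest.raises(ValueError, match="empty mask"):
            MatrixCompletion(x, ObservationMask((5, 5), [], []))

    def test_zero_observed_norm_fails(self):
        x = np.zeros((4, 4))
        with pytest.raises(ValueError, match="omega error is undefined"):
            MatrixCompletion(x, ObservationMask.full(4, 4))

    def test_divergence_flagged(self, lowrank_80x60):
        x, mask = lowrank_80x60
        # a grossly oversized step makes the omega error blow up
        params = SVTParams(tau=default_tau(80, 60), delta=500.0,
                           max_iterations=200, divergence_factor=100.0)
        res = complete(x, mask, params=params)
        assert res.diverged and not res.converged
        assert res.iterations_run < 200  # stopped early, not at the cap

    def test_deterministic_traces(self, lowrank_80x60):
        x, mask = lowrank_80x60
        t1 = complete(x, mask).omega_error_trace
        t2 = complete(x, mask).omega_error_trace
        np.testing.assert_array_equal(t1, t2)

    def test_truncated_backend_matches_full_svd_reference(self):
        x = generate_low_rank(SyntheticSpec(40, 30, 3, seed=3))
        mask = sample_mask(40, 30, 0.7, seed=4)
        params = SVTParams.defaults_for(40, 30, len(mask), max_iterations=150)
        full = complete(x, mask, params=params, svd_backend="full")
        trunc = complete(x, mask, params=params, svd_backend="truncated")
        n = min(len(full.omega_error_trace), len(trunc.omega_error_trace))
        np.testing.assert_allclose(full.omega_error_trace[:n],
                                   trunc.omega_error_trace[:n], atol=1e-8)
        np.testing.assert_allclose(full.recovered.values, trunc.recovered.values,
                                   atol=1e-8)

    def test_summary_mentions_key_quantities(self, lowrank_80x60):
        x, mask = lowrank_80x60
        s = complete(x, mask).summary()
        assert "omega error" in s and "effective rank" in s and "converged" in s

    def test_evaluate_returns_error_report(self, lowrank_80x60):
        x, mask = lowrank_80x60
        rep = complete(x, mask).evaluate(x)
        assert rep.frobenius_relative <= 1e-3
        assert rep.observability == pytest.approx(0.6)
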