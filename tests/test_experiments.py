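import numpy as np
import pandas as pd
import pytest
import scipy.stats

from exprecover import SyntheticSpec, generate_low_rank, generate_two_class, sample_mask
from exprecover.experiments import (
    bh_adjust,
    checkpoint_only_matrix,
    de_concordance,
    de_test,
    noise_benchmark,
    observability_sweep,
    parameter_sweep,
    top_genes,
)
from exprecover.io import ExpressionMatrix


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        # step-up on (0.01, 0.02, 0.03, 0.04): p_(i) * 4/i, cummin from the top
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_monotone_and_bounded(self, rng):
        p = rng.uniform(size=50)
        q = bh_adjust(p)
        assert np.all(q <= 1.0) and np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestDeTest:
    def test_identical_classes_zero_logfc(self, rng):
        half = rng.normal(size=(30, 4))
        x = ExpressionMatrix(np.hstack([half, half]), scale="log")
        labels = [0] * 4 + [1] * 4
        de = de_test(x, labels)
        np.testing.assert_allclose(de["logfc"], 0.0, atol=1e-12)

    def test_planted_genes_occupy_top_ranks(self):
        x, labels, planted = generate_two_class(300, 40, 15, effect_size=5.0,
                                                noise_sd=1.0, seed=1)
        de = de_test(x, labels)
        top = set(top_genes(de, 15))
        assert top == {x.gene_ids[g] for g in planted}

    def test_small_class_rejected(self, rng):
        x = ExpressionMatrix(rng.normal(size=(10, 3)), scale="log")
        with pytest.raises(ValueError, match="at least 2 samples"):
            de_test(x, [0, 1, 1])

    def test_moderated_variance_shrinks_toward_prior(self):
        # genes with extreme sample variances get pulled toward the pool
        x, labels, _ = generate_two_class(400, 4, 0, seed=2)
        de = de_test(x, labels)
        t_mod = de["t"].to_numpy()
        v = x.values
        g0, g1 = np.array(labels) == 0, np.array(labels) == 1
        t_ord = scipy.stats.ttest_ind(v[:, g1], v[:, g0], axis=1).statistic
        # moderation compresses the spread of t at tiny sample size
        assert np.std(t_mod) < np.std(t_ord)


class TestCheckpointOnly:
    def test_observed_cells_kept_and_missing_imputed_with_gene_mean(self):
        vals = np.array([[1.0, 3.0, 5.0, 7.0], [2.0, 2.0, 2.0, 10.0]])
        x = ExpressionMatrix(vals, scale="log")
        mask = sample_mask(2, 4, 0.5, seed=3)
        cpo = checkpoint_only_matrix(x, mask)
        np.testing.assert_array_equal(mask.values_at(cpo.values), mask.values_at(vals))
        comp = mask.complement()
        obs_bool = mask.to_bool()
        for i, j in zip(comp.rows, comp.cols):
            assert cpo.values[i, j] == pytest.approx(vals[i, obs_bool[i]].mean())


class TestDeConcordance:
    def test_identical_recovery_gives_full_overlap(self):
        x, labels, _ = generate_two_class(100, 10, 10, seed=4)
        out = de_concordance(x, x, x, labels, top_k=10)
        assert out["recovered"] == 1.0 and out["checkpoint_only"] == 1.0

    def test_random_rankings_overlap_near_k_over_m(self, rng):
        # independent noise-only matrices: expected top-k overlap is k/m
        m, k, reps = 400, 40, 20
        overlaps = []
        for rep in range(reps):
            a, labels, _ = generate_two_class(m, 10, 0, seed=rep * 2)
            b, _, _ = generate_two_class(m, 10, 0, seed=rep * 2 + 1)
            ta = set(top_genes(de_test(a, labels), k))
            tb = set(top_genes(de_test(b, labels), k))
            overlaps.append(len(ta & tb) / k)
        expected = k / m
        se = np.sqrt(expected * (1 - expected) / (k * reps))
        assert abs(np.mean(overlaps) - expected) < 5 * se

    def test_top_k_exceeding_genes_rejected(self):
        x, labels, _ = generate_two_class(20, 5, 2, seed=5)
        with pytest.raises(ValueError):
            de_concordance(x, x, x, labels, top_k=21)


class TestNoiseBenchmark:
    def test_reproducible_and_ordered_in_ratio(self):
        rows = noise_benchmark(60, 60, 3, ratios=[0.0, 0.3],
                               observabilities=[0.6], iterations=150,
                               replicates=2, seed=9)
        again = noise_benchmark(60, 60, 3, ratios=[0.0, 0.3],
                                observabilities=[0.6], iterations=150,
                                replicates=2, seed=9)
        assert [r.relative_error_mean for r in rows] == \
               [r.relative_error_mean for r in again]
        err = {r.ratio: r.relative_error_mean for r in rows}
        assert err[0.0] < err[0.3]
        assert all(r.n_failed == 0 for r in rows)

    def test_noiseless_generous_iterations_recovers(self):
        rows = noise_benchmark(60, 60, 3, ratios=[0.0], observabilities=[0.6],
                               iterations=400, replicates=2, seed=10)
        assert rows[0].relative_error_mean <= 1e-3


class TestParameterSweep:
    def test_default_cell_competitive_and_huge_tau_worse(self):
        # a noise floor keeps well-tuned cells at a comparable error level
        grid = parameter_sweep(60, 60, 3, observability=0.5,
                               tau_grid=None, delta_grid=None,
                               iterations=150, seed=11, noise_ratio=0.05)
        from exprecover import default_tau
        tau0 = default_tau(60, 60)
        default_cell = grid.loc[tau0].iloc[2]  # delta factor 1.0
        assert default_cell <= 10 * np.nanmin(grid.to_numpy())
        # overshrinking: tau >= 10x default degrades the error
        assert grid.loc[tau0 * 10].iloc[2] > default_cell

    def test_duplicate_grid_points_identical(self):
        grid = parameter_sweep(40, 40, 2, tau_grid=[200.0, 200.0],
                               delta_grid=[2.0], iterations=80, seed=12)
        assert grid.iloc[0, 0] == grid.iloc[1, 0]


class TestObservabilitySweep:
    def test_error_decreases_with_observability_and_high_O_recovers(self):
        x = generate_low_rank(SyntheticSpec(100, 60, 3, seed=13))
        summary, runs = observability_sweep(
            x, [0.3, 0.9], runs_per_point=3, seed=14, iterations=400)
        e = summary.set_index("observability")["frobenius"]
        assert e[0.9] <= e[0.3]
        assert e[0.9] <= 1e-3
        assert len(runs) == 6
        assert set(runs.columns) >= {"observability", "frobenius", "spectral",
                                     "omega", "converged", "diverged"}

    def test_invalid_observability_rejected(self):
        x = generate_low_rank(SyntheticSpec(20, 20, 2, seed=15))
        with pytest.raises(ValueError):
            observability_sweep(x, [1.0], runs_per_point=1, seed=0)
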