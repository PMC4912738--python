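"""End-to-end simulation studies.

Four designs, mirroring the package's validation strategy:

* :func:`noise_benchmark` — recovery error of rank-r Gaussian-factor
  matrices across a grid of noise deviation ratios and observabilities,
  with the solver capped at a fixed iteration count.
* :func:`parameter_sweep` — recovery error over a (tau, delta) grid on one
  fixed matrix/mask realisation, to sanity-check the default heuristics.
* :func:`observability_sweep` — Frobenius/spectral/omega error averaged
  over repeated random maskings at each observability; the per-run records
  allow checking that the omega error (computable without ground truth)
  tracks the full-matrix error.
* :func:`de_test` / :func:`de_concordance` — moderated-t differential
  expression on two-class data, and the overlap of top-ranked gene lists
  between the original matrix, its low-rank recovery, and a naive
  checkpoint-only comparator.  This asks whether a recovered matrix can
  stand in for the original in downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix
from .masking import ObservationMask, sample_mask
from .metrics import error_report, frobenius_relative_error
from .solver import SVTParams, complete
from .synthetic import NoiseSpec, SyntheticSpec, add_noise, generate_low_rank


# ---------------------------------------------------------------------------
# noise benchmark


@dataclass(frozen=True)
class BenchmarkRow:
    """One (noise ratio, observability) cell of the noise benchmark."""

    ratio: float
    observability: float
    iterations: int
    relative_error_mean: float
    relative_error_sd: float
    replicates: int
    seeds: tuple[int, ...]
    n_failed: int = 0


def _spawn_seeds(seed: int, k: int) -> list[int]:
    """k reproducible child seeds below 2**31 derived from one parent."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(k)]


def noise_benchmark(
    m: int,
    n: int,
    rank: int,
    ratios: list[float],
    observabilities: list[float],
    iterations: int = 100,
    replicates: int = 5,
    seed: int = 0,
    restore_observed: bool = False,
) -> list[BenchmarkRow]:
    """Recovery error vs clean truth over a (ratio, observability) grid.

    Per replicate: generate a rank-``rank`` Gaussian-factor truth, sample a
    mask, add checkpoint noise at the given ratio, run SVT capped at
    ``iterations``, and record the Frobenius relative error against the
    clean matrix.  Solver failures are recorded per cell, not fatal.

    The error is measured on the solver's raw low-rank iterate by default:
    with noisy checkpoints the restored measured values would re-inject
    their own noise (a sqrt(O)*ratio floor) and mask the estimator's
    accuracy.  Pass ``restore_observed=True`` to measure the restored
    matrix instead.
    """
    rows: list[BenchmarkRow] = []
    cell_seeds = _spawn_seeds(seed, len(ratios) * len(observabilities))
    idx = 0
    for obs in observabilities:
        for ratio in ratios:
            rep_seeds = _spawn_seeds(cell_seeds[idx], replicates)
            idx += 1
            errs = []
            n_failed = 0
            for rs in rep_seeds:
                s_truth, s_mask, s_noise = _spawn_seeds(rs, 3)
                truth = generate_low_rank(SyntheticSpec(m, n, rank, seed=s_truth))
                mask = sample_mask(m, n, obs, seed=s_mask)
                noisy = add_noise(truth, mask, NoiseSpec(ratio=ratio, seed=s_noise))
                try:
                    params = SVTParams.defaults_for(
                        m, n, len(mask), max_iterations=iterations)
                    res = complete(noisy, mask, params=params,
                                   restore_observed=restore_observed)
                    errs.append(frobenius_relative_error(
                        truth.values, res.recovered.values))
                except (ValueError, FloatingPointError):
                    n_failed += 1
            errs = np.asarray(errs)
            rows.append(BenchmarkRow(
                ratio=ratio,
                observability=obs,
                iterations=iterations,
                relative_error_mean=float(errs.mean()) if errs.size else float("nan"),
                relative_error_sd=float(errs.std(ddof=1)) if errs.size > 1 else 0.0,
                replicates=len(errs),
                seeds=tuple(rep_seeds),
                n_failed=n_failed,
            ))
    return rows


def benchmark_frame(rows: list[BenchmarkRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])


# ---------------------------------------------------------------------------
# tau/delta sweep


def parameter_sweep(
    m: int,
    n: int,
    rank: int,
    observability: float = 0.5,
    tau_grid: list[float] | None = None,
    delta_grid: list[float] | None = None,
    iterations: int = 100,
    seed: int = 0,
    noise_ratio: float = 0.0,
) -> pd.DataFrame:
    """Frobenius relative error over a (tau, delta) grid.

    One fixed matrix/mask/noise realisation; grid defaults bracket the
    5*sqrt(mn) and 1.2*mn/|Omega| heuristics by factors of 10 either way.
    Failed cells are NaN.
    """
    from .solver import default_delta, default_tau

    s_truth, s_mask, s_noise = _spawn_seeds(seed, 3)
    truth = generate_low_rank(SyntheticSpec(m, n, rank, seed=s_truth))
    mask = sample_mask(m, n, observability, seed=s_mask)
    observed = add_noise(truth, mask, NoiseSpec(ratio=noise_ratio, seed=s_noise))
    tau0 = default_tau(m, n)
    delta0 = default_delta(m, n, len(mask))
    if tau_grid is None:
        tau_grid = [tau0 * f for f in (0.1, 0.5, 1.0, 5.0, 10.0)]
    if delta_grid is None:
        delta_grid = [delta0 * f for f in (0.1, 0.5, 1.0, 2.0)]
    grid = pd.DataFrame(index=pd.Index(tau_grid, name="tau"),
                        columns=pd.Index(delta_grid, name="delta"), dtype=float)
    for tau in tau_grid:
        for delta in delta_grid:
            try:
                params = SVTParams(tau=tau, delta=delta,
                                   max_iterations=iterations)
                res = complete(observed, mask, params=params,
                               restore_observed=False)
                grid.loc[tau, delta] = frobenius_relative_error(
                    truth.values, res.recovered.values)
            except (ValueError, FloatingPointError):
                grid.loc[tau, delta] = np.nan
    return grid


# ---------------------------------------------------------------------------
# observability sweep


def observability_sweep(
    x: ExpressionMatrix,
    observabilities: list[float] | None = None,
    runs_per_point: int = 10,
    seed: int = 0,
    iterations: int = 750,
    noise_ratio: float = 0.0,
    restore_observed: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Recovery errors of ``x`` under repeated random masking.

    For each observability, ``runs_per_point`` independent maskings are
    completed and evaluated against ``x``; mask locations differ between
    runs.  Divergent runs are excluded from the means and counted.

    Returns
    -------
    (summary, runs)
        ``summary`` has one row per observability with mean errors and the
        divergent-run count; ``runs`` has one row per individual run
        (columns observability, run, frobenius, spectral, omega, converged,
        diverged), for e.g. omega-vs-Frobenius correlation analyses.
    """
    if observabilities is None:
        observabilities = [round(0.1 * k, 1) for k in range(1, 10)]
    if any(not (0.0 < o < 1.0) for o in observabilities):
        raise ValueError("observabilities must lie in (0, 1)")
    m, n = x.shape
    point_seeds = _spawn_seeds(seed, len(observabilities))
    run_rows = []
    for obs, ps in zip(observabilities, point_seeds):
        for run, rs in enumerate(_spawn_seeds(ps, runs_per_point)):
            s_mask, s_noise = _spawn_seeds(rs, 2)
            mask = sample_mask(m, n, obs, seed=s_mask)
            observed = add_noise(x, mask, NoiseSpec(ratio=noise_ratio, seed=s_noise))
            params = SVTParams.defaults_for(m, n, len(mask),
                                            max_iterations=iterations)
            res = complete(observed, mask, params=params,
                           restore_observed=restore_observed)
            rep = error_report(x.values, res.recovered.values, mask)
            run_rows.append(dict(
                observability=obs, run=run,
                frobenius=rep.frobenius_relative,
                spectral=rep.spectral_relative,
                omega=res.omega_error,
                converged=res.converged, diverged=res.diverged,
            ))
    runs = pd.DataFrame(run_rows)
    ok = runs[~runs["diverged"]]
    summary = (
        ok.groupby("observability")[["frobenius", "spectral", "omega"]]
        .mean()
        .reset_index()
    )
    summary["runs"] = ok.groupby("observability").size().values
    summary["diverged"] = (
        runs.groupby("observability")["diverged"].sum().reindex(
            summary["observability"]).values
    )
    return summary, runs


# ---------------------------------------------------------------------------
# differential expression


def _squeeze_var(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of per-gene variances (Smyth 2004).

    Fits a scaled inverse-chi-square prior (s0^2, d0) to the observed
    sample variances by moment matching on log s^2, then returns the
    posterior variances (d0*s0^2 + df*s^2) / (d0 + df) together with
    (d0, s0^2).  d0 = inf means complete shrinkage to the prior.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2 > 0
    if not np.any(pos):
        return np.full_like(s2, 1.0), np.inf, 1.0
    z = np.log(s2[pos])
    e = z - scipy.special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) if e.size > 1 else 0.0
    evar_resid = evar - scipy.special.polygamma(1, df / 2.0)
    if evar_resid > 0:
        d0 = 2.0 * _trigamma_inverse(evar_resid)
        s02 = float(np.exp(
            emean + scipy.special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # no excess dispersion beyond chi-square sampling noise: variances
        # are exchangeable and the prior collapses to their plain mean
        d0 = np.inf
        s02 = float(s2[pos].mean())
    if np.isinf(d0):
        post = np.full_like(s2, s02)
    else:
        post = (d0 * s02 + df * s2) / (d0 + df)
    return post, d0, s02


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = scipy.special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / scipy.special.polygamma(2, x)
        x = x + dif
        if -dif / x < 1e-8:
            break
    return float(x)


def de_test(x: ExpressionMatrix, labels) -> pd.DataFrame:
    """Per-gene moderated two-sample t-test with BH correction.

    Ordinary pooled-variance t-statistics are unstable with few samples;
    the moderated t shrinks each gene's variance toward a common prior
    fitted across all genes (empirical Bayes), gaining d0 prior degrees of
    freedom.  Input must be log-scale; logFC is the difference of class
    means (class 1 minus class 0), i.e. the log2-fold-change when the data
    is log2.

    Returns
    -------
    DataFrame indexed by gene id with columns
    ``logfc, ave_expr, t, pvalue, qvalue`` (qvalue = BH-adjusted p).
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.size}")
    g0 = labels == classes[0]
    g1 = labels == classes[1]
    n0, n1 = int(g0.sum()), int(g1.sum())
    if n0 < 2 or n1 < 2:
        raise ValueError("each class needs at least 2 samples")
    if x.scale != "log":
        raise ValueError("de_test expects log-scale values")
    v = x.values
    if np.isnan(v).any():
        raise ValueError("de_test requires a complete matrix (no NaN)")
    mean0 = v[:, g0].mean(axis=1)
    mean1 = v[:, g1].mean(axis=1)
    logfc = mean1 - mean0
    df = n0 + n1 - 2
    s2 = (v[:, g0].var(axis=1, ddof=1) * (n0 - 1)
          + v[:, g1].var(axis=1, ddof=1) * (n1 - 1)) / df
    s2_post, d0, _ = _squeeze_var(s2, df)
    se = np.sqrt(s2_post * (1.0 / n0 + 1.0 / n1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, 0.0)
    # total df capped at the pooled residual df across all genes
    df_total = min(df + d0, s2.size * df)
    pvalue = 2.0 * scipy.stats.t.sf(np.abs(t), df_total)
    qvalue = multipletests(pvalue, method="fdr_bh")[1]
    return pd.DataFrame(
        dict(logfc=logfc, ave_expr=v.mean(axis=1), t=t,
             pvalue=pvalue, qvalue=qvalue),
        index=pd.Index(x.gene_ids, name="gene_id"),
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def checkpoint_only_matrix(observed: ExpressionMatrix, mask: ObservationMask) -> ExpressionMatrix:
    """Naive comparator: unobserved cells imputed by the gene's observed mean.

    Genes with no observed cell fall back to the grand observed mean, so
    the DE machinery can run on a complete matrix.
    """
    v = observed.values.copy()
    obs = mask.to_bool()
    obs_vals = mask.values_at(observed.values)
    grand = float(np.mean(obs_vals))
    for i in range(v.shape[0]):
        row_obs = obs[i]
        fill = v[i, row_obs].mean() if row_obs.any() else grand
        v[i, ~row_obs] = fill
    out = ExpressionMatrix(v, observed.gene_ids, observed.sample_ids,
                           scale=observed.scale)
    return out


def top_genes(de: pd.DataFrame, k: int) -> list[str]:
    """Top-k gene ids ranked by |logFC| (ties broken by p-value)."""
    ranked = de.assign(abs_logfc=de["logfc"].abs()).sort_values(
        ["abs_logfc", "pvalue"], ascending=[False, True])
    return list(ranked.index[:k])


def de_concordance(
    original: ExpressionMatrix,
    recovered: ExpressionMatrix,
    checkpoint_only: ExpressionMatrix,
    labels,
    top_k: int,
) -> dict[str, float]:
    """Top-k gene-list overlap of recovered/checkpoint-only vs original.

    Runs the identical moderated-t pipeline on all three matrices and
    returns |top_k(original) & top_k(other)| / top_k for each comparator.
    A useful recovery should preserve the original ranking far better than
    the checkpoint-only matrix does.
    """
    m = original.shape[0]
    if top_k > m:
        raise ValueError(f"top_k={top_k} exceeds number of genes {m}")
    ref = set(top_genes(de_test(original, labels), top_k))
    out = {}
    for name, mat in (("recovered", recovered), ("checkpoint_only", checkpoint_only)):
        hits = ref & set(top_genes(de_test(mat, labels), top_k))
        out[name] = len(hits) / top_k
    return out
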