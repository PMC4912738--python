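"""Synthetic data generators for the simulation studies.

Three generators:

* :func:`generate_low_rank` — exact rank-r Gaussian-factor matrices, the
  test bed for the parameter sweeps and the noise-robustness grid.
* :func:`add_noise` — additive white Gaussian measurement noise on the
  observed checkpoints, parameterised by the noise deviation ratio
  sigma_eps / sigma_x.
* :func:`generate_two_class` — two-condition log-expression data with a
  planted set of differentially expressed genes, a stand-in for a
  case/control profiling experiment used by the DE-concordance study.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import ExpressionMatrix
from .masking import ObservationMask


@dataclass(frozen=True)
class NoiseSpec:
    """Additive white Gaussian noise on the checkpoints.

    ``ratio`` is the noise deviation ratio sigma_eps / sigma_x: the noise
    standard deviation relative to that of the signal.  sigma_x is by
    default estimated over the observed cells (the quantity available in
    practice); ``sigma_over_full`` switches to the full-matrix estimate.
    """

    ratio: float
    seed: int = 0
    sigma_over_full: bool = False

    def __post_init__(self):
        if not np.isfinite(self.ratio) or self.ratio < 0:
            raise ValueError(f"noise ratio must be finite and >= 0, got {self.ratio}")


@dataclass(frozen=True)
class SyntheticSpec:
    """Rank-r Gaussian-factor matrix description: A (m x r) @ B^T (r x n)."""

    m: int
    n: int
    rank: int
    factor_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not (1 <= self.rank <= min(self.m, self.n)):
            raise ValueError(
                f"rank must be in [1, min(m, n)] = [1, {min(self.m, self.n)}], "
                f"got {self.rank}")
        if self.factor_scale <= 0:
            raise ValueError("factor_scale must be positive")


def generate_low_rank(spec: SyntheticSpec) -> ExpressionMatrix:
    """A @ B^T with independent N(0, factor_scale^2) factor entries.

    The product has numerical rank exactly ``spec.rank`` (almost surely),
    emulating the idealised low-rank structure of a correlated expression
    matrix.  Values are synthetic log-scale expression.
    """
    rng = np.random.default_rng(spec.seed)
    a = rng.standard_normal((spec.m, spec.rank)) * spec.factor_scale
    b = rng.standard_normal((spec.n, spec.rank)) * spec.factor_scale
    return ExpressionMatrix(a @ b.T, scale="log")


def add_noise(x: ExpressionMatrix, mask: ObservationMask, spec: NoiseSpec) -> ExpressionMatrix:
    """Add N(0, (ratio * sigma_x)^2) noise to the cells in Omega only.

    Cells outside Omega are returned bitwise unchanged; recovery error is
    then measured against the clean matrix.
    """
    if mask.shape != x.shape:
        raise ValueError(f"mask shape {mask.shape} != matrix shape {x.shape}")
    if spec.ratio == 0.0:
        return x
    obs_vals = mask.values_at(x.values)
    sigma_x = float(np.std(x.values if spec.sigma_over_full else obs_vals, ddof=1))
    rng = np.random.default_rng(spec.seed)
    noisy = x.values.copy()
    noisy[mask.rows, mask.cols] = obs_vals + rng.standard_normal(len(mask)) * (
        spec.ratio * sigma_x)
    return replace(x, values=noisy)


def generate_two_class(
    m: int,
    n_per_class: int,
    n_de: int,
    effect_size: float = 2.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    baseline_mean: float = 7.0,
    baseline_sd: float = 2.0,
):
    """Two-condition log-expression data with planted DE genes.

    Per-gene baseline log2-expression is drawn from
    N(baseline_mean, baseline_sd^2) — centred on typical log2 microarray
    intensities.  The first ``n_de`` genes (after a seeded shuffle) receive
    a mean shift of ``effect_size`` log2 units in class 2; i.i.d.
    N(0, noise_sd^2) noise is added everywhere.

    Returns
    -------
    (ExpressionMatrix, ndarray of int labels (0/1), ndarray of planted gene row indices)
    """
    if n_de > m:
        raise ValueError(f"n_de={n_de} exceeds number of genes m={m}")
    if n_per_class < 2:
        raise ValueError("need at least 2 samples per class")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    baseline = rng.normal(baseline_mean, baseline_sd, size=m)
    values = baseline[:, None] + rng.standard_normal((m, n)) * noise_sd
    de_genes = rng.permutation(m)[:n_de]
    labels = np.repeat([0, 1], n_per_class)
    if n_de:
        values[np.ix_(de_genes, np.nonzero(labels == 1)[0])] += effect_size
    sample_ids = [f"c{lab}_s{j}" for j, lab in enumerate(labels)]
    x = ExpressionMatrix(values, sample_ids=sample_ids, scale="log")
    return x, labels, np.sort(de_genes)
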