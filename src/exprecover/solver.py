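"""Singular-value-thresholding (SVT) solver for low-rank matrix completion.

The expression matrix M (genes x samples) is assumed to lie close to a
low-dimensional linear subspace: genes act in concert, so their expression
profiles are strongly correlated and the data matrix is approximately low
rank.  Recovery from the observed subset Omega is posed as nuclear-norm
minimisation,

    minimise ||X||_*   subject to  X_ij = M_ij  for (i, j) in Omega,

the tightest convex relaxation of rank minimisation.  SVT solves it by
iterating, from Y^0 = 0,

    X^k = shrink(Y^{k-1}, tau)
    Y^k = Y^{k-1} + delta * P_Omega(M - X^k)

where shrink soft-thresholds the singular values: sigma -> max(sigma - tau, 0).
The iteration stops when the omega error
||P_Omega(X - M)||_F / ||P_Omega(M)||_F drops below a tolerance, when the
iteration cap is hit, or when the omega error blows up (divergence).

The solver is exposed statsmodels-style: build a :class:`MatrixCompletion`
model from the observed data and call :meth:`~MatrixCompletion.fit` to get a
:class:`CompletionResults` carrying the recovered matrix, the omega-error
trace and diagnostics.  :func:`complete` is a one-call convenience wrapper.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse
import scipy.sparse.linalg

from .io import ExpressionMatrix
from .masking import ObservationMask, observability

__all__ = [
    "SVTParams",
    "MatrixCompletion",
    "CompletionResults",
    "complete",
    "shrink",
    "nuclear_norm",
    "default_tau",
    "default_delta",
]

# below this min(m, n) a full dense SVD is cheaper than iterative methods
FULL_SVD_THRESHOLD = 300
# extra singular triplets requested per probe when the truncated backend
# searches for the first singular value at or below tau
_PROBE_STEP = 5


def default_tau(m: int, n: int) -> float:
    """Default singular-value threshold, 5 * sqrt(m * n).

    Large enough that the Frobenius term in the regularised objective is
    negligible and the iteration effectively minimises the nuclear norm.
    """
    if m < 1 or n < 1:
        raise ValueError("m and n must be >= 1")
    return 5.0 * np.sqrt(m * n)


def default_delta(m: int, n: int, observed_count: int) -> float:
    """Default step size, 1.2 * m * n / |Omega| (larger when data is sparser)."""
    if observed_count < 1:
        raise ValueError("observed_count must be >= 1")
    if observed_count > m * n:
        raise ValueError("observed_count exceeds m*n")
    return 1.2 * m * n / observed_count


def nuclear_norm(x: np.ndarray) -> float:
    """Sum of singular values (Schatten 1-norm / trace norm)."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("nuclear_norm: input contains non-finite entries")
    return float(np.linalg.svd(x, compute_uv=False).sum())


def shrink(x: np.ndarray, tau: float) -> np.ndarray:
    """Soft-threshold the singular values of ``x`` by ``tau``.

    Returns sum_i max(sigma_i - tau, 0) u_i v_i^T where x = U diag(sigma) V^T.
    tau = 0 reproduces ``x`` up to SVD round-off.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("shrink: input contains non-finite entries")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    s = np.maximum(s - tau, 0.0)
    return (u * s) @ vt


@dataclass
class SVTParams:
    """SVT solver configuration.

    Attributes
    ----------
    tau : float
        Singular-value threshold; default 5*sqrt(m*n) via :func:`default_tau`.
    delta : float
        Constant step size; default 1.2*m*n/|Omega| via :func:`default_delta`.
    tolerance : float
        Omega-error stopping threshold (default 1e-8).
    max_iterations : int
        Iteration cap (default 750).
    divergence_factor : float
        Declare divergence when the omega error exceeds this multiple of its
        first-iteration value (default 100).
    """

    tau: float
    delta: float
    tolerance: float = 1e-8
    max_iterations: int = 750
    divergence_factor: float = 100.0

    def __post_init__(self):
        for name in ("tau", "delta", "tolerance"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive, got {v}")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.divergence_factor <= 1:
            raise ValueError("divergence_factor must be > 1")

    @classmethod
    def defaults_for(cls, m: int, n: int, observed_count: int, **overrides) -> "SVTParams":
        kw = dict(tau=default_tau(m, n), delta=default_delta(m, n, observed_count))
        kw.update(overrides)
        return cls(**kw)


class _ShrinkBackend:
    """Soft-thresholding of a sparse iterate, full or truncated SVD.

    The SVT iterate Y lives on Omega only (Y^0 = 0 and updates touch Omega),
    so for large problems the truncated backend runs ARPACK ``svds`` on the
    sparse Y, probing for the number of singular values above tau: request
    s = r_prev + 1 triplets, and grow s until the smallest computed singular
    value is <= tau (the standard incremental scheme for SVT solvers).
    """

    def __init__(self, shape: tuple[int, int], mode: str = "auto"):
        if mode not in ("auto", "full", "truncated"):
            raise ValueError(f"unknown SVD backend mode {mode!r}")
        m, n = shape
        self.shape = shape
        if mode == "auto":
            mode = "full" if min(m, n) <= FULL_SVD_THRESHOLD else "truncated"
        self.mode = mode
        self._prev_rank = 0

    def shrink_sparse(self, y: scipy.sparse.spmatrix, tau: float):
        """Return (u, s_shrunk, vt, effective_rank) of shrink(Y, tau)."""
        m, n = self.shape
        minmn = min(m, n)
        if scipy.sparse.linalg.norm(y) == 0.0:
            # early iterations: Y has not yet grown past the threshold
            self._prev_rank = 0
            return np.zeros((m, 0)), np.zeros(0), np.zeros((0, n)), 0
        if self.mode == "full":
            u, s, vt = np.linalg.svd(y.toarray(), full_matrices=False)
        else:
            # deterministic ARPACK start so identical inputs give identical traces
            v0 = np.random.default_rng(0).standard_normal(minmn)
            k = min(max(self._prev_rank + 1, 1), minmn - 1)
            while True:
                u, s, vt = scipy.sparse.linalg.svds(y, k=k, v0=v0)
                order = np.argsort(s)[::-1]
                u, s, vt = u[:, order], s[order], vt[order]
                if s[-1] <= tau or k >= minmn - 1:
                    break
                k = min(k + _PROBE_STEP, minmn - 1)
            if s[-1] > tau and k >= minmn - 1:
                # rank saturates the truncated solver; fall back to dense
                u, s, vt = np.linalg.svd(y.toarray(), full_matrices=False)
        keep = s > tau
        r = int(keep.sum())
        self._prev_rank = r
        return u[:, keep], s[keep] - tau, vt[keep], r


class MatrixCompletion:
    """Low-rank completion model for a partially observed expression matrix.

    Parameters
    ----------
    observed : ExpressionMatrix or ndarray
        The data matrix; only cells in ``mask`` are read.  The pipeline
        normally log-transforms first (see :func:`exprecover.io.log_transform`).
    mask : ObservationMask
        The checkpoint set Omega.
    tau, delta : float, optional
        Solver parameters; defaults follow the 5*sqrt(mn) and
        1.2*mn/|Omega| heuristics.
    svd_backend : {"auto", "full", "truncated"}
        "auto" uses a dense SVD when min(m, n) <= 300 and a truncated
        sparse SVD otherwise.

    Examples
    --------
    >>> model = MatrixCompletion(observed, mask)
    >>> res = model.fit()
    >>> res.converged, res.effective_rank
    (True, 2)
    >>> X = res.recovered.values
    """

    def __init__(self, observed, mask: ObservationMask, tau: float | None = None,
                 delta: float | None = None, svd_backend: str = "auto"):
        if isinstance(observed, ExpressionMatrix):
            self.data = observed
        else:
            self.data = ExpressionMatrix(np.asarray(observed, dtype=float))
        if mask.shape != self.data.shape:
            raise ValueError(
                f"mask shape {mask.shape} != matrix shape {self.data.shape}")
        if len(mask) == 0:
            raise ValueError("empty mask: nothing is observed")
        self.mask = mask
        obs_vals = mask.values_at(self.data.values)
        if not np.all(np.isfinite(obs_vals)):
            raise ValueError("observed entries contain non-finite values")
        self._obs_vals = obs_vals
        self._obs_norm = float(np.linalg.norm(obs_vals))
        if self._obs_norm == 0.0:
            raise ValueError(
                "||P_Omega(M)||_F is zero: omega error is undefined")
        m, n = self.data.shape
        self.tau = default_tau(m, n) if tau is None else float(tau)
        self.delta = default_delta(m, n, len(mask)) if delta is None else float(delta)
        self.svd_backend = svd_backend

    def fit(self, tolerance: float = 1e-8, max_iterations: int = 750,
            divergence_factor: float = 100.0, restore_observed: bool = True,
            params: SVTParams | None = None) -> "CompletionResults":
        """Run the SVT iteration.

        Parameters
        ----------
        restore_observed : bool
            If True (default) the recovered matrix has its Omega cells
            overwritten with the measured values: the constraint is equality
            on Omega and downstream analyses treat checkpoints as exact.
            Set False to return the raw final iterate.
        params : SVTParams, optional
            Overrides tolerance/max_iterations/divergence_factor/tau/delta
            in one object.
        """
        if params is not None:
            tau, delta = params.tau, params.delta
            tolerance = params.tolerance
            max_iterations = params.max_iterations
            divergence_factor = params.divergence_factor
        else:
            tau, delta = self.tau, self.delta
            params = SVTParams(tau=tau, delta=delta, tolerance=tolerance,
                               max_iterations=max_iterations,
                               divergence_factor=divergence_factor)

        m, n = self.data.shape
        rows, cols = self.mask.rows, self.mask.cols
        obs = self._obs_vals
        backend = _ShrinkBackend((m, n), self.svd_backend)

        y_vals = np.zeros(len(obs))  # Y^k restricted to Omega (Y^0 = 0)
        trace: list[float] = []
        converged = False
        diverged = False
        u = np.zeros((m, 0))
        s = np.zeros(0)
        vt = np.zeros((0, n))
        rank = 0

        for _ in range(max_iterations):
            y = scipy.sparse.csr_matrix((y_vals, (rows, cols)), shape=(m, n))
            u, s, vt, rank = backend.shrink_sparse(y, tau)
            x_omega = _eval_on_omega(u, s, vt, rows, cols)
            residual = obs - x_omega
            err = float(np.linalg.norm(residual)) / self._obs_norm
            if not np.isfinite(err):
                raise FloatingPointError(
                    f"SVT diverged: non-finite omega error at iteration {len(trace) + 1}")
            trace.append(err)
            if err <= tolerance:
                converged = True
                break
            if err > divergence_factor * trace[0]:
                diverged = True
                break
            y_vals += delta * residual

        recovered_values = (u * s) @ vt
        if restore_observed:
            recovered_values[rows, cols] = obs
        recovered = ExpressionMatrix(recovered_values, self.data.gene_ids,
                                     self.data.sample_ids, scale=self.data.scale)
        return CompletionResults(
            model=self,
            params=params,
            recovered=recovered,
            omega_error_trace=np.asarray(trace),
            iterations_run=len(trace),
            converged=converged,
            diverged=diverged,
            effective_rank=rank,
            observed_restored=restore_observed,
        )


def _eval_on_omega(u, s, vt, rows, cols, block: int = 500_000) -> np.ndarray:
    """Entries of (u * s) @ vt at the (rows, cols) index pairs, blockwise."""
    out = np.empty(rows.size)
    us = u * s
    for start in range(0, rows.size, block):
        sl = slice(start, min(start + block, rows.size))
        out[sl] = np.einsum("ij,ji->i", us[rows[sl]], vt[:, cols[sl]])
    return out


@dataclass
class CompletionResults:
    """Fit results of :class:`MatrixCompletion`.

    Attributes
    ----------
    recovered : ExpressionMatrix
        The completed matrix X (Omega cells restored to measured values
        unless the fit was called with ``restore_observed=False``).
    omega_error_trace : ndarray
        Omega error ||P_Omega(X^k - M)||_F / ||P_Omega(M)||_F per iteration.
    converged : bool
        True when the final omega error reached the tolerance.
    diverged : bool
        True when the omega error exceeded divergence_factor times its
        first-iteration value.
    effective_rank : int
        Number of singular values retained at the final shrink.
    """

    model: MatrixCompletion
    params: SVTParams
    recovered: ExpressionMatrix
    omega_error_trace: np.ndarray
    iterations_run: int
    converged: bool
    diverged: bool
    effective_rank: int
    observed_restored: bool = True

    @property
    def omega_error(self) -> float:
        """Final omega error (doubles as the convergence criterion)."""
        return float(self.omega_error_trace[-1])

    def evaluate(self, truth) -> "ErrorReport":
        """Error report of the recovery against a fully known matrix."""
        from .metrics import error_report
        values = truth.values if isinstance(truth, ExpressionMatrix) else np.asarray(truth)
        return error_report(values, self.recovered.values, self.model.mask)

    def summary(self) -> str:
        m, n = self.model.data.shape
        status = "converged" if self.converged else ("diverged" if self.diverged else "iteration cap reached")
        lines = [
            "Low-rank matrix completion (SVT)",
            "=" * 48,
            f"matrix size            {m} x {n}",
            f"observed entries       {len(self.model.mask)}"
            f"  (observability {observability(self.model.mask):.3f})",
            f"tau                    {self.params.tau:.6g}",
            f"delta                  {self.params.delta:.6g}",
            f"tolerance              {self.params.tolerance:.3g}",
            f"iterations run         {self.iterations_run}"
            f" / {self.params.max_iterations}",
            f"status                 {status}",
            f"final omega error      {self.omega_error:.6g}",
            f"effective rank         {self.effective_rank}",
            f"observed restored      {self.observed_restored}",
        ]
        return "\n".join(lines)


def complete(observed, mask: ObservationMask, params: SVTParams | None = None,
             restore_observed: bool = True, svd_backend: str = "auto") -> CompletionResults:
    """One-call SVT completion: build the model and fit it.

    Uses the default tau/delta heuristics, tolerance 1e-8 and a cap of 750
    iterations unless ``params`` overrides them.
    """
    model = MatrixCompletion(observed, mask, svd_backend=svd_backend)
    return model.fit(params=params, restore_observed=restore_observed)
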