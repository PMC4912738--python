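"""Recovery-error metrics: Frobenius, spectral, and omega relative error.

All three compare a recovered matrix X against the original M:

* Frobenius relative error   ||M - X||_F / ||M||_F   — overall mismatch.
* Spectral relative error    ||M - X||_2 / ||M||_2   — mismatch in the
  dominant direction (operator 2-norm = largest singular value).
* Omega error                ||P_Omega(X - M)||_F / ||P_Omega(M)||_F —
  mismatch on the observed cells only; available without ground truth, it
  doubles as the solver's convergence criterion and is a practical
  indicator of full-matrix recovery quality.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import scipy.sparse.linalg

from .masking import ObservationMask, observability

_SPECTRAL_DENSE_LIMIT = 500  # use full SVD when min(m, n) is at most this


@dataclass(frozen=True)
class ErrorReport:
    """The three recovery errors plus the observability they were measured at."""

    frobenius_relative: float
    spectral_relative: float
    omega_relative: float
    observability: float

    def to_dict(self) -> dict[str, float]:
        return asdict(self)


def _as_pair(original, recovered):
    a = np.asarray(original, dtype=float)
    b = np.asarray(recovered, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def frobenius_relative_error(original, recovered) -> float:
    """||M - X||_F / ||M||_F."""
    m, x = _as_pair(original, recovered)
    denom = np.linalg.norm(m)
    if denom == 0.0:
        raise ValueError("original matrix has zero Frobenius norm")
    return float(np.linalg.norm(m - x) / denom)


def _spectral_norm(a: np.ndarray) -> float:
    if min(a.shape) <= _SPECTRAL_DENSE_LIMIT:
        return float(np.linalg.norm(a, 2))
    try:
        s = scipy.sparse.linalg.svds(a, k=1, return_singular_vectors=False,
                                     tol=1e-10)
        return float(s[0])
    except Exception:
        # power iteration fallback for ARPACK breakdowns
        rng = np.random.default_rng(0)
        v = rng.standard_normal(a.shape[1])
        v /= np.linalg.norm(v)
        sigma = 0.0
        for _ in range(200):
            w = a.T @ (a @ v)
            nw = np.linalg.norm(w)
            if nw == 0.0:
                return 0.0
            v_new = w / nw
            sigma_new = np.sqrt(nw)
            if abs(sigma_new - sigma) <= 1e-10 * max(sigma_new, 1.0):
                return float(sigma_new)
            v, sigma = v_new, sigma_new
        return float(sigma)


def spectral_relative_error(original, recovered) -> float:
    """||M - X||_2 / ||M||_2 (operator 2-norm)."""
    m, x = _as_pair(original, recovered)
    denom = _spectral_norm(m)
    if denom == 0.0:
        raise ValueError("original matrix has zero spectral norm")
    return float(_spectral_norm(m - x) / denom)


def omega_error(original, recovered, mask: ObservationMask) -> float:
    """||P_Omega(X - M)||_F / ||P_Omega(M)||_F."""
    m, x = _as_pair(original, recovered)
    if mask.shape != m.shape:
        raise ValueError(f"mask shape {mask.shape} != matrix shape {m.shape}")
    if len(mask) == 0:
        raise ValueError("empty mask: omega error undefined")
    m_omega = mask.values_at(m)
    denom = np.linalg.norm(m_omega)
    if denom == 0.0:
        raise ValueError("||P_Omega(M)||_F is zero: omega error undefined")
    return float(np.linalg.norm(mask.values_at(x) - m_omega) / denom)


def error_report(original, recovered, mask: ObservationMask) -> ErrorReport:
    """All three metrics in one object."""
    return ErrorReport(
        frobenius_relative=frobenius_relative_error(original, recovered),
        spectral_relative=spectral_relative_error(original, recovered),
        omega_relative=omega_error(original, recovered, mask),
        observability=observability(mask),
    )
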