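"""Hybrid sparsity penalties and their iteratively-reweighted surrogates.

The genetic weight matrix U (p SNPs x F views) carries three structured
penalties:

* fused-group norm  sum_{i<p} sqrt(||u_i||^2 + ||u_{i+1}||^2)  — adjacent SNPs
  tend to act together (LD), so neighbouring rows are encouraged to vanish or
  survive jointly;
* l2,1 norm  sum_i ||u_i||  — selects SNPs consistently across views;
* l1,1 norm  sum_{i,f} |u_{i,f}|  — view-specific elementwise sparsity.

Each non-smooth norm is handled in the blockwise closed-form solve through a
half-quadratic (IRLS) diagonal surrogate: for s = ||.||^2 the concavity of
sqrt(s + eps) gives sqrt(s' + eps) <= sqrt(s + eps) + (s' - s) / (2 sqrt(s +
eps)), a quadratic majorizer whose curvature is the diagonal weight stored
here.  eps > 0 keeps the weights finite at exact zeros.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "PenaltyWeights",
    "SmoothedPenaltyState",
    "fgl21_norm",
    "l21_norm",
    "l11_norm",
    "update_smoothed_weights",
    "soft_threshold",
]

DEFAULT_EPSILON = 1e-8


@dataclass
class PenaltyWeights:
    """Nonnegative penalty coefficients and the IRLS smoothing constant."""

    lambda_u1: float = 0.01   # fused-group norm on U
    lambda_u2: float = 0.01   # l2,1 norm on U
    lambda_u3: float = 0.01   # l1,1 norm on U
    lambda_v: float = 0.01    # l1 norm on each v_f
    lambda_Q: float = 0.01    # l2 ridge on the sample weights
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        for name in ("lambda_u1", "lambda_u2", "lambda_u3", "lambda_v", "lambda_Q"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class SmoothedPenaltyState:
    """Diagonal IRLS weights for the three U penalties at the current iterate."""

    D1: np.ndarray       # p entries, fused-group norm
    D2: np.ndarray       # p entries, l2,1 norm
    D3: np.ndarray       # p x F entries, l1,1 norm

    def __post_init__(self) -> None:
        for D in (self.D1, self.D2, self.D3):
            if not (np.all(np.isfinite(D)) and np.all(D > 0)):
                raise ValueError("smoothed penalty weights must be positive finite")


def _as_2d(U: np.ndarray) -> np.ndarray:
    U = np.asarray(U, dtype=float)
    return U[:, None] if U.ndim == 1 else U


def fgl21_norm(U: np.ndarray, breaks: np.ndarray | None = None) -> float:
    """Fused-group norm over adjacent SNP rows.

    ``breaks`` optionally lists indices i at which the chain i-1 -> i is cut
    (e.g. LD block starts), so no fusion happens across those boundaries.
    For p = 1 the row norm itself is returned by convention.
    """
    U = _as_2d(U)
    p = U.shape[0]
    sq = np.einsum("ij,ij->i", U, U)
    if p == 1:
        log.debug("fused-group norm on a single row: returning its l2 norm")
        return float(np.sqrt(sq[0]))
    pair = sq[:-1] + sq[1:]
    if breaks is not None:
        keep = np.ones(p - 1, dtype=bool)
        for b in np.asarray(breaks, dtype=int):
            if 1 <= b <= p - 1:
                keep[b - 1] = False
        pair = pair[keep]
    return float(np.sum(np.sqrt(pair)))


def l21_norm(U: np.ndarray) -> float:
    """Sum of row-wise Euclidean norms."""
    U = _as_2d(U)
    return float(np.sum(np.sqrt(np.einsum("ij,ij->i", U, U))))


def l11_norm(U: np.ndarray) -> float:
    """Elementwise absolute sum."""
    return float(np.sum(np.abs(U)))


def update_smoothed_weights(U: np.ndarray, epsilon: float = DEFAULT_EPSILON,
                            breaks: np.ndarray | None = None) -> SmoothedPenaltyState:
    """IRLS diagonal weights at the current U for all three penalties.

    D2_i = 1/(2 sqrt(||u_i||^2 + eps));  D3_{i,f} = 1/(2 sqrt(u_{i,f}^2 + eps));
    D1_i sums the curvatures of the (at most two) adjacent-pair terms row i
    participates in, boundary terms dropped.
    """
    U = _as_2d(U)
    if not np.all(np.isfinite(U)):
        raise ValueError("U must be finite")
    p = U.shape[0]
    sq = np.einsum("ij,ij->i", U, U)

    D2 = 1.0 / (2.0 * np.sqrt(sq + epsilon))
    D3 = 1.0 / (2.0 * np.sqrt(U ** 2 + epsilon))

    D1 = np.zeros(p)
    if p == 1:
        D1 = D2.copy()      # single-row convention: fused norm degenerates to l2,1
    else:
        keep = np.ones(p - 1, dtype=bool)
        if breaks is not None:
            for b in np.asarray(breaks, dtype=int):
                if 1 <= b <= p - 1:
                    keep[b - 1] = False
        w = np.where(keep, 1.0 / (2.0 * np.sqrt(sq[:-1] + sq[1:] + epsilon)), 0.0)
        D1[:-1] += w
        D1[1:] += w
        # rows outside every kept pair would get zero curvature; floor keeps
        # the system matrix positive definite
        D1 = np.maximum(D1, 1.0 / (2.0 * np.sqrt(1.0 / epsilon)))
    return SmoothedPenaltyState(D1=D1, D2=D2, D3=D3)


def soft_threshold(w: np.ndarray, t: float) -> np.ndarray:
    """Elementwise sign(w) * max(|w| - t, 0); the proximal map of t*||.||_1."""
    if t < 0:
        raise ValueError("threshold must be nonnegative")
    w = np.asarray(w, dtype=float)
    return np.sign(w) * np.maximum(np.abs(w) - t, 0.0)
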