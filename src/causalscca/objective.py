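"""Objective terms of the causality-aware multi-view sparse CCA model.

The model couples three ingredients over F phenotype views:

* a sample-weighted bidirectional association term  -u_f' X' diag(Q) Y_f v_f
  per view, under the scale constraints ||X u_f|| = ||Y_f v_f|| = 1;
* a diagnosis loss psi(v_f; Y_f, z) tying each phenotype projection to the
  disease label with equal weight to the association term;
* a decorrelation loss on the sample weights Q: within every LD block, the
  Q-weighted covariance between each SNP pair should vanish, emulating a
  reweighted population in which LD-driven indirect associations disappear.

Empirical expectations in the decorrelation loss use (1/n)*sum so the
trade-off eta is comparable across sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ld import LDBlockPartition
from .penalties import PenaltyWeights, fgl21_norm, l11_norm, l21_norm

__all__ = [
    "HyperParams",
    "association_term",
    "causal_loss",
    "causal_loss_grad_Q",
    "psi_loss",
    "psi_grad",
    "full_objective",
]


@dataclass
class HyperParams:
    """Model hyperparameters.

    eta weighs the decorrelation loss; gamma_ridge multiplies the weighted
    Gram term in the closed-form U solve (realizing the scale constraint as a
    ridge); psi_kind selects the diagnosis loss ('linear', 'logistic', or
    'off'); learning_rate is the initial step for the backtracking gradient
    updates of Q and V.
    """

    eta: float = 0.1
    gamma_ridge: float = 1.0
    penalty: PenaltyWeights = field(default_factory=PenaltyWeights)
    psi_kind: str = "linear"
    learning_rate: float = 1.0
    max_iter: int = 100
    tol: float = 1e-5
    allow_negative_q: bool = False
    fgl_respect_blocks: bool = False
    init: str = "svd"
    fix_q: bool = False     # hold Q at its initialization (reweighting off)

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ValueError("eta must be nonnegative")
        if self.gamma_ridge <= 0:
            raise ValueError("gamma_ridge must be positive")
        if self.learning_rate <= 0 or self.tol <= 0:
            raise ValueError("learning_rate and tol must be positive")
        if self.psi_kind not in ("linear", "logistic", "off"):
            raise ValueError(f"unknown psi_kind {self.psi_kind!r}")
        if self.init not in ("svd", "constant", "random"):
            raise ValueError(f"unknown init mode {self.init!r}")


def association_term(X: np.ndarray, Y_f: np.ndarray, u_f: np.ndarray,
                     v_f: np.ndarray, Q: np.ndarray) -> float:
    """Negative Q-weighted cross-covariance  -u' X' diag(Q) Y v  of one view."""
    xu = X @ u_f
    yv = Y_f @ v_f
    if xu.shape != yv.shape or xu.shape[0] != np.asarray(Q).ravel().shape[0]:
        raise ValueError("dimension mismatch in association term")
    return float(-(xu * np.asarray(Q).ravel()) @ yv)


def _weighted_cov_stacks(X: np.ndarray, Q: np.ndarray,
                         partition: LDBlockPartition):
    """Batched Q-weighted within-block covariances, E(.) = (1/n)*sum.

    Yields ``(Xb, C)`` per block-size group: Xb is (n, m, s) block columns and
    C the (m, s, s) weighted covariance stack.  Singleton blocks are skipped
    (no pairs).
    """
    n = X.shape[0]
    w = Q / n
    wX = w[:, None] * X
    for s, idx, _ in partition.grouped():
        if s < 2:
            continue
        Xb = X[:, idx]                                   # n x m x s
        Xm = np.ascontiguousarray(Xb.transpose(1, 2, 0))  # m x s x n
        second = Xm @ wX[:, idx].transpose(1, 0, 2)       # m x s x s
        first = w @ Xb.reshape(n, -1)
        first = first.reshape(idx.shape)                  # m x s
        C = second - first[:, :, None] * first[:, None, :]
        yield Xb, first, C


def causal_loss(X: np.ndarray, Q: np.ndarray,
                partition: LDBlockPartition) -> float:
    """Sum of squared Q-weighted covariances over unordered SNP pairs within
    each LD block.  Zero iff the reweighted SNPs are pairwise uncorrelated
    (in the weighted-covariance sense) inside every block."""
    X = np.asarray(X, float)
    Q = np.asarray(Q, float).ravel()
    total = 0.0
    for _, _, C in _weighted_cov_stacks(X, Q, partition):
        s = C.shape[1]
        iu = np.triu_indices(s, k=1)
        off = C[:, iu[0], iu[1]]
        total += float(np.sum(off * off))
    return total


def causal_loss_grad_Q(X: np.ndarray, Q: np.ndarray,
                       partition: LDBlockPartition) -> np.ndarray:
    """Analytic gradient of :func:`causal_loss` in Q.

    With C_ij the weighted covariance and m = X' Q / n, sample l contributes
    (1/n)[x_l' C~ x_l - 2 x_l' C~ m] per block, where C~ is C with the
    diagonal zeroed (unordered pairs counted via the 1/2 symmetric form).
    """
    X = np.asarray(X, float)
    Q = np.asarray(Q, float).ravel()
    n = X.shape[0]
    grad = np.zeros(n)
    for Xb, first, C in _weighted_cov_stacks(X, Q, partition):
        Ct = C.copy()
        s = Ct.shape[1]
        Ct[:, np.arange(s), np.arange(s)] = 0.0
        XC = (Xb.transpose(1, 0, 2) @ Ct).transpose(1, 0, 2)   # n x m x s
        grad += ((XC * Xb).sum(axis=(1, 2))
                 - 2.0 * (XC * first[None, :, :]).sum(axis=(1, 2))) / n
    return grad


def psi_loss(v_f: np.ndarray, Y_f: np.ndarray, z: np.ndarray, kind: str) -> float:
    """Diagnosis loss tying the phenotype projection to the disease label.

    linear:    (1/2) sum_i (z_i - <Y_i, v>)^2
    logistic:  (1/2) sum_i (log(1 + exp<Y_i, v>) - z_i <Y_i, v>),  z in {0,1}
    """
    s = np.asarray(Y_f, float) @ np.asarray(v_f, float)
    z = np.asarray(z, float).ravel()
    if kind == "off":
        return 0.0
    if kind == "linear":
        r = z - s
        return 0.5 * float(r @ r)
    if kind == "logistic":
        if not np.all(np.isin(z, (0.0, 1.0))):
            raise ValueError("logistic diagnosis loss requires labels in {0,1}")
        return 0.5 * float(np.sum(np.logaddexp(0.0, s) - z * s))
    raise ValueError(f"unknown psi kind {kind!r}")


def psi_grad(v_f: np.ndarray, Y_f: np.ndarray, z: np.ndarray, kind: str) -> np.ndarray:
    """Gradient of :func:`psi_loss` with respect to v_f."""
    Y_f = np.asarray(Y_f, float)
    s = Y_f @ np.asarray(v_f, float)
    z = np.asarray(z, float).ravel()
    if kind == "off":
        return np.zeros(Y_f.shape[1])
    if kind == "linear":
        return Y_f.T @ (s - z)
    if kind == "logistic":
        if not np.all(np.isin(z, (0.0, 1.0))):
            raise ValueError("logistic diagnosis loss requires labels in {0,1}")
        sig = 1.0 / (1.0 + np.exp(-s))
        return 0.5 * (Y_f.T @ (sig - z))
    raise ValueError(f"unknown psi kind {kind!r}")


def full_objective(U: np.ndarray, V: list[np.ndarray], Q: np.ndarray,
                   X: np.ndarray, Ys: list[np.ndarray], z: np.ndarray,
                   partition: LDBlockPartition, hp: HyperParams) -> tuple[float, dict]:
    """Total objective and a per-term breakdown (exact, non-smoothed penalties).

    The breakdown's values carry their trade-off coefficients, so they sum to
    the returned total.
    """
    pen = hp.penalty
    Q = np.asarray(Q, float).ravel()
    assoc = 0.0
    psi = 0.0
    lv = 0.0
    for f, (Y_f, v_f) in enumerate(zip(Ys, V)):
        assoc += association_term(X, Y_f, U[:, f], v_f, Q)
        psi += psi_loss(v_f, Y_f, z, hp.psi_kind)
        lv += float(np.sum(np.abs(v_f)))
    breaks = None
    if hp.fgl_respect_blocks:
        breaks = np.array([b[0] for b in partition.blocks[1:]], dtype=int)
    breakdown = {
        "association": assoc,
        "psi": psi,
        "causal": hp.eta * causal_loss(X, Q, partition) if hp.eta > 0 else 0.0,
        "penalty_u_fgl21": pen.lambda_u1 * fgl21_norm(U, breaks=breaks),
        "penalty_u_l21": pen.lambda_u2 * l21_norm(U),
        "penalty_u_l11": pen.lambda_u3 * l11_norm(U),
        "penalty_v_l1": pen.lambda_v * lv,
        "penalty_q_l2": pen.lambda_Q * float(Q @ Q),
    }
    return float(sum(breakdown.values())), breakdown
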