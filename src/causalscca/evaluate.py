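"""Scoring and model selection: held-out canonical correlations, nested CV
over the power-of-ten grid, marker ranking, support recovery, and a
top-feature classification check.

Model selection follows the standard protocol for sparse CCA: hyperparameters
are drawn from 10^i (i = -4..4), the three U penalty coefficients are tied to
a single lambda_u, eta is fixed at 0.1 and lambda_Q at 1, and the (lambda_u,
lambda_v) pair is chosen by inner cross-validated mean test CCC — by default
with a coordinate sweep (lambda_u first, then lambda_v), the full grid being
available for small problems.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from .io import DiagnosisLabels, GenotypeMatrix, PhenotypeViews, standardize_columns
from .ld import pairwise_corr, partition_ld_blocks
from .objective import HyperParams
from .penalties import PenaltyWeights
from .simulate import SimulationTruth
from .solver import fit

log = logging.getLogger(__name__)

__all__ = ["CVReport", "ccc", "nested_cv", "rank_top_markers",
           "support_recovery", "classify_top_features", "benchmark_preset"]


@dataclass
class CVReport:
    """Outer-fold test CCCs with the selected hyperparameters."""

    grid: list[tuple[float, float]]
    fold_cccs: np.ndarray                 # outer_folds x F
    best_points: list[tuple[float, float]]
    seeds: int
    mean_test_ccc: np.ndarray = field(default=None)   # per view, mean over folds
    mean_over_views_then_folds: float = 0.0
    mean_over_folds_then_views: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_test_ccc is None:
            self.mean_test_ccc = self.fold_cccs.mean(axis=0)
        self.mean_over_views_then_folds = float(self.fold_cccs.mean(axis=1).mean())
        self.mean_over_folds_then_views = float(self.fold_cccs.mean(axis=0).mean())


def ccc(X_test: np.ndarray, u: np.ndarray, Y_test: np.ndarray,
        v: np.ndarray) -> float:
    """Canonical correlation coefficient: Pearson correlation of the held-out
    projections X u and Y v.  Zero-variance projections score 0."""
    a = np.asarray(X_test, float) @ u
    b = np.asarray(Y_test, float) @ v
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        warnings.warn("zero-variance projection in CCC; returning 0")
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _unpack(data):
    X, Ys, z = data
    if isinstance(X, GenotypeMatrix):
        X = X.values
    if isinstance(Ys, PhenotypeViews):
        Ys = Ys.views
    if isinstance(z, DiagnosisLabels):
        z = z.z
    return np.asarray(X, float), [np.asarray(Y, float) for Y in Ys], np.asarray(z, float).ravel()


def _standardize_split(X, Ys, z, train, test):
    Xtr, mx, sx = standardize_columns(X[train])
    Xte, _, _ = standardize_columns(X[test], mx, sx)
    Ytr, Yte = [], []
    for Y in Ys:
        t, my, sy = standardize_columns(Y[train])
        Ytr.append(t)
        Yte.append(standardize_columns(Y[test], my, sy)[0])
    return (Xtr, Ytr, z[train]), (Xte, Yte, z[test])


def _fit_and_score(train, test, lam_u, lam_v, hp_base, ld_threshold, seed,
                   partition=None):
    Xtr, Ytr, ztr = train
    Xte, Yte, _ = test
    pen = replace(hp_base.penalty, lambda_u1=lam_u, lambda_u2=lam_u,
                  lambda_u3=lam_u, lambda_v=lam_v)
    hp = replace(hp_base, penalty=pen)
    if partition is None:
        partition = partition_ld_blocks(pairwise_corr(Xtr), threshold=ld_threshold)
    res = fit((Xtr, Ytr, ztr), partition, hp, seed=seed)
    return np.array([ccc(Xte, res.U[:, f], Yte[f], res.V[f])
                     for f in range(len(Ytr))]), res


def nested_cv(data, grid_exponents=range(-4, 5), outer_folds: int = 5,
              inner_folds: int = 5, seed: int = 0, search: str = "coordinate",
              hp_base: HyperParams | None = None,
              ld_threshold: float = 0.2, inner_max_iter: int = 30) -> CVReport:
    """Nested cross-validation over the 10^i hyperparameter grid.

    The inner loop selects (lambda_u, lambda_v) by the highest mean inner-test
    CCC averaged over views and folds; the winner is refit on the outer
    training set and scored on the outer test fold.  Standardization always
    uses training-fold statistics, and the LD partition is re-estimated from
    each training set.
    """
    X, Ys, z = _unpack(data)
    n = X.shape[0]
    if n < outer_folds:
        raise ValueError("need at least one subject per outer fold")
    lams = [10.0 ** i for i in grid_exponents]
    if not lams:
        raise ValueError("empty hyperparameter grid")
    hp_base = hp_base or HyperParams(
        eta=0.1, penalty=PenaltyWeights(lambda_Q=1.0))

    def inner_cache(train, fold_seed):
        """Pre-standardized inner splits with their training-set partitions,
        shared across every grid candidate."""
        inner = KFold(inner_folds, shuffle=True, random_state=fold_seed)
        cache = []
        idx = np.arange(train[0].shape[0])
        for itr, ite in inner.split(idx):
            tr, te = _standardize_split(train[0], train[1], train[2], itr, ite)
            part = partition_ld_blocks(pairwise_corr(tr[0]), threshold=ld_threshold)
            cache.append((tr, te, part))
        return cache

    # candidate scoring runs the same fit under a reduced iteration budget;
    # the winning point is refit at the full budget
    hp_inner = replace(hp_base, max_iter=min(inner_max_iter, hp_base.max_iter))

    def inner_score(cache, lam_u, lam_v, fold_seed):
        scores = [
            _fit_and_score(tr, te, lam_u, lam_v, hp_inner, ld_threshold,
                           fold_seed, partition=part)[0].mean()
            for tr, te, part in cache
        ]
        return float(np.mean(scores))

    outer = KFold(outer_folds, shuffle=True, random_state=seed)
    fold_cccs, best_points, grid_seen = [], [], []
    for ofold, (otr, ote) in enumerate(outer.split(np.arange(n))):
        train, test = _standardize_split(X, Ys, z, otr, ote)
        fold_seed = seed * 1000 + ofold
        cache = inner_cache(train, fold_seed)
        if search == "grid":
            candidates = [(lu, lv) for lu in lams for lv in lams]
            scores = {c: inner_score(cache, *c, fold_seed) for c in candidates}
            best = max(candidates, key=lambda c: scores[c])
        elif search == "coordinate":
            lv0 = hp_base.penalty.lambda_v
            scores = {(lu, lv0): inner_score(cache, lu, lv0, fold_seed)
                      for lu in lams}
            best_lu = max(lams, key=lambda lu: scores[(lu, lv0)])
            for lv in lams:
                if (best_lu, lv) not in scores:
                    scores[(best_lu, lv)] = inner_score(cache, best_lu, lv, fold_seed)
            best_lv = max(lams, key=lambda lv: scores[(best_lu, lv)])
            best = (best_lu, best_lv)
            candidates = list(scores)
        else:
            raise ValueError(f"unknown search mode {search!r}")
        part = partition_ld_blocks(pairwise_corr(train[0]), threshold=ld_threshold)
        cccs, _ = _fit_and_score(train, test, *best, hp_base, ld_threshold,
                                 fold_seed, partition=part)
        fold_cccs.append(cccs)
        best_points.append(best)
        grid_seen = candidates
        log.info("outer fold %d: best (lambda_u, lambda_v) = %s, test CCCs %s",
                 ofold, best, np.round(cccs, 3))
    return CVReport(grid=grid_seen, fold_cccs=np.asarray(fold_cccs),
                    best_points=best_points, seeds=seed)


def rank_top_markers(W: np.ndarray, M: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-M markers by |mean weight across columns|, descending, stable ties.

    Returns ``(indices, signed_mean_weights)``; signs are preserved so effect
    directions survive into reports.
    """
    W = np.asarray(W, float)
    mean_w = W if W.ndim == 1 else W.mean(axis=1)
    if M > mean_w.shape[0]:
        raise ValueError("M exceeds the number of markers")
    order = np.argsort(-np.abs(mean_w), kind="stable")[:M]
    return order, mean_w[order]


def support_recovery(U_hat: np.ndarray, truth: SimulationTruth) -> dict:
    """Precision/recall/F1 of the top-|support| ranked SNPs against the
    planted support."""
    true_set = set(truth.u_support.tolist())
    k = len(true_set)
    idx, _ = rank_top_markers(U_hat, k)
    hit = len(set(idx.tolist()) & true_set)
    precision = hit / k if k else 0.0
    recall = hit / k if k else 0.0
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return {"precision": precision, "recall": recall, "f1": f1, "k": k}


def classify_top_features(data, fit_result, top_m: int = 10, folds: int = 5,
                          seed: int = 0) -> dict:
    """Cross-validated soft-margin SVM accuracy using the top-m ranked SNPs
    plus the top-m phenotype features of every view as the feature table."""
    X, Ys, z = _unpack(data)
    if len(np.unique(z)) < 2:
        raise ValueError("need at least two diagnostic classes")
    snp_idx, _ = rank_top_markers(fit_result.U, min(top_m, X.shape[1]))
    cols = [X[:, snp_idx]]
    for f, Y in enumerate(Ys):
        fi, _ = rank_top_markers(fit_result.V[f], min(top_m, Y.shape[1]))
        cols.append(Y[:, fi])
    table = np.hstack(cols)
    cv = StratifiedKFold(folds, shuffle=True, random_state=seed)
    scores = cross_val_score(SVC(kernel="linear"), table, z, cv=cv)
    return {"accuracy_mean": float(scores.mean()), "accuracy_sd": float(scores.std()),
            "fold_scores": scores}


def benchmark_preset(name: str, seeds, outer_folds: int = 5, inner_folds: int = 5,
                     search: str = "coordinate", grid_exponents=range(-4, 5),
                     hp_base: HyperParams | None = None) -> dict:
    """Run the synthetic benchmark protocol: generate a preset for each seed,
    run nested CV, and average the outer-test CCCs per view across seeds."""
    from .simulate import make_dataset, make_truth, preset as make_preset

    per_seed = []
    for s in seeds:
        cfg = make_preset(name, seed=int(s))
        truth = make_truth(cfg)
        geno, pheno, labels = make_dataset(truth, cfg)
        rep = nested_cv((geno, pheno, labels), grid_exponents=grid_exponents,
                        outer_folds=outer_folds, inner_folds=inner_folds,
                        seed=int(s), search=search, hp_base=hp_base)
        per_seed.append(rep.mean_test_ccc)
    arr = np.asarray(per_seed)
    return {"per_seed_ccc": arr, "mean_ccc_per_view": arr.mean(axis=0),
            "sd_ccc_per_view": arr.std(axis=0), "n_seeds": len(per_seed)}
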