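"""Synthetic genotype-phenotype benchmarks with planted sparse signals.

A latent per-subject score mu drives both sides: genotype column i is drawn
around mu * u_i with LD-like grouped correlation, phenotype column k of view
f around mu * v_{f,k} with independent noise, and the diagnosis label is a
threshold of mu.  Ground truth (u, the v_f, mu, supports) is returned so
support recovery can be scored exactly.

Four presets span three noise levels at n >> p and one large-p-small-n
regime; the first three share one seed-fixed truth and differ only in noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import DiagnosisLabels, GenotypeMatrix, PhenotypeViews, standardize_columns

__all__ = ["SimulationConfig", "SimulationTruth", "make_truth", "make_dataset",
           "preset", "make_spurious_pair_dataset"]


@dataclass
class SimulationConfig:
    """Generator settings.

    ``sparsity`` is the nonzero fraction of the genetic signal u (rounded to
    whole LD groups); ``sparsity_v`` that of each phenotype signal v_f
    (defaults to ``sparsity``).  ``sigma_x``/``sigma_y`` scale the noise
    *covariance* around the rank-one signal (x_i ~ N(mu u_i, sigma_x Sigma_x),
    so the noise standard deviation is sqrt(sigma)); ``within_block_corr`` is
    the equicorrelation of the genotype noise inside each LD group of size
    ``block_size``.
    """

    n: int = 500
    p: int = 100
    q: tuple[int, ...] = (120, 100, 80)
    sparsity: float = 0.2
    sparsity_v: float | tuple[float, ...] | None = None
    sigma_x: float = 0.1
    sigma_y: float = 0.1
    block_size: int = 10
    within_block_corr: float = 0.7
    seed: int = 0
    n_classes: int = 2
    discretize: bool = False

    def __post_init__(self) -> None:
        if min(self.n, self.p, min(self.q)) <= 0:
            raise ValueError("n, p and every q_f must be positive")
        if not (0 < self.sparsity < 1):
            raise ValueError("sparsity must lie in (0, 1)")
        if self.sigma_x < 0 or self.sigma_y < 0:
            raise ValueError("noise scales must be nonnegative")
        if not (0 <= self.within_block_corr < 1):
            raise ValueError("within_block_corr must lie in [0, 1)")

    def sv(self, f: int) -> float:
        """Nonzero fraction of view f's signal (scalar or per-view)."""
        if self.sparsity_v is None:
            return self.sparsity
        if np.isscalar(self.sparsity_v):
            return float(self.sparsity_v)
        return float(self.sparsity_v[f])


@dataclass
class SimulationTruth:
    """Planted signals: u (p), v_f per view, latent mu (n), and supports."""

    u_true: np.ndarray
    v_true: list[np.ndarray]
    mu: np.ndarray
    u_support: np.ndarray = field(default=None)
    v_support: list[np.ndarray] = field(default=None)

    def __post_init__(self) -> None:
        if self.u_support is None:
            self.u_support = np.flatnonzero(self.u_true)
        if self.v_support is None:
            self.v_support = [np.flatnonzero(v) for v in self.v_true]


def _signed_run(rng: np.random.Generator, length: int) -> np.ndarray:
    """Contiguous signal run with both signs: first half +, second half -."""
    mags = rng.uniform(0.8, 1.2, size=length)
    half = max(1, length // 2)
    signs = np.ones(length)
    signs[half:] = -1.0
    return mags * signs


def make_truth(config: SimulationConfig) -> SimulationTruth:
    """Draw the latent scores and plant group-aligned signed sparse signals."""
    if config.sparsity * config.p < 1:
        raise ValueError("sparsity * p must be at least 1")
    rng = np.random.default_rng([config.seed, 0])
    mu = rng.standard_normal(config.n)

    n_groups = max(1, config.p // config.block_size)
    starts = np.arange(n_groups) * config.block_size
    n_sig_groups = max(1, round(config.sparsity * config.p / config.block_size))
    n_sig_groups = min(n_sig_groups, n_groups)
    chosen = np.sort(rng.choice(n_groups, size=n_sig_groups, replace=False))

    u = np.zeros(config.p)
    if n_sig_groups == 1:
        g = chosen[0]
        size = min(config.block_size, config.p - starts[g])
        u[starts[g]:starts[g] + size] = _signed_run(rng, size)
    else:
        for j, g in enumerate(chosen):
            size = min(config.block_size, config.p - starts[g])
            sign = 1.0 if j % 2 == 0 else -1.0
            u[starts[g]:starts[g] + size] = sign * rng.uniform(0.8, 1.2, size=size)

    v_true = []
    for f, qf in enumerate(config.q):
        k = max(2, round(config.sv(f) * qf))
        start = int(rng.integers(0, qf - k + 1))
        v = np.zeros(qf)
        v[start:start + k] = _signed_run(rng, k)
        v_true.append(v)
    return SimulationTruth(u_true=u, v_true=v_true, mu=mu)


def make_dataset(truth: SimulationTruth, config: SimulationConfig):
    """Generate (GenotypeMatrix, PhenotypeViews, DiagnosisLabels).

    Genotype noise is equicorrelated within each LD group (shared-factor
    construction) and independent across groups; phenotype noise is white.
    Columns are z-scored after generation.  ``discretize`` optionally maps the
    continuous dosages to {0,1,2} by per-column quantiles.
    """
    rng = np.random.default_rng([config.seed, 1])
    n, p = config.n, config.p
    rho = config.within_block_corr

    E = rng.standard_normal((n, p))
    if rho > 0:
        for start in range(0, p, config.block_size):
            stop = min(start + config.block_size, p)
            shared = rng.standard_normal(n)
            E[:, start:stop] = (np.sqrt(rho) * shared[:, None]
                                + np.sqrt(1 - rho) * E[:, start:stop])
    X = truth.mu[:, None] * truth.u_true[None, :] + np.sqrt(config.sigma_x) * E

    if config.discretize:
        Xd = np.empty_like(X)
        for j in range(p):
            qs = np.quantile(X[:, j], [1 / 3, 2 / 3])
            Xd[:, j] = np.digitize(X[:, j], qs)
        X = Xd
    X, _, _ = standardize_columns(X)

    views = []
    for f, qf in enumerate(config.q):
        Y = (truth.mu[:, None] * truth.v_true[f][None, :]
             + np.sqrt(config.sigma_y) * rng.standard_normal((n, qf)))
        Y, _, _ = standardize_columns(Y)
        views.append(Y)

    if config.n_classes == 2:
        z = (truth.mu > np.median(truth.mu)).astype(float)
    else:
        qs = np.quantile(truth.mu, np.arange(1, config.n_classes) / config.n_classes)
        z = np.digitize(truth.mu, qs).astype(float)

    geno = GenotypeMatrix(X, [f"s{i + 1}" for i in range(n)],
                          [f"snp{j + 1}" for j in range(p)])
    pheno = PhenotypeViews(
        views=views,
        feature_ids=[[f"v{f + 1}_feat{k + 1}" for k in range(qf)]
                     for f, qf in enumerate(config.q)],
        view_names=[f"view{f + 1}" for f in range(len(config.q))],
    )
    return geno, pheno, DiagnosisLabels(z)


_PRESETS = {
    "data1": dict(n=500, p=100, q=(120, 100, 80), sparsity=0.2, sigma_x=0.1, sigma_y=0.1),
    "data2": dict(n=500, p=100, q=(120, 100, 80), sparsity=0.2, sigma_x=0.6, sigma_y=0.6),
    "data3": dict(n=500, p=100, q=(120, 100, 80), sparsity=0.2, sigma_x=1.2, sigma_y=1.2),
    # data4's per-view signal densities encode modality heterogeneity: an
    # imaging-like wide view with very few affected features, a proteomic-like
    # middle view, and a cognitive-like narrow view whose items are mostly
    # informative -- so held-out CCC degrades from view 3 to view 1.
    "data4": dict(n=80, p=1000, q=(120, 100, 80), sparsity=0.02,
                  sparsity_v=(2 / 120, 6 / 100, 24 / 80),
                  sigma_x=0.3, sigma_y=0.3),
}


def preset(name: str, seed: int = 0, **overrides) -> SimulationConfig:
    """Named benchmark regimes.

    data1/2/3 share the seed-fixed truth (same n, p, q, sparsity, seed) and
    differ only in noise scale (0.1 / 0.6 / 1.2, decreasing SNR); data4 is the
    large-p-small-n regime (n=80, p=1000, sigma=0.3).
    """
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    kw = dict(within_block_corr=0.7, block_size=10, **_PRESETS[name])
    kw.update(overrides)
    return SimulationConfig(seed=seed, **kw)


def make_spurious_pair_dataset(seed: int, n: int = 30, p: int = 12, q: int = 20,
                               sigma: float = 2.5, r: float = 0.9):
    """One phenotype-driving SNP with a non-causal LD proxy correlated r to it.

    The causal SNP drives the phenotype columns directly; the proxy's only
    path to the phenotype runs through its LD with the causal SNP, so in a
    reweighted sample where the pair's weighted covariance vanishes the proxy
    carries no signal.  An association-only model sees the proxy's marginal
    correlation (r times the causal one) and, with the fused/group penalties
    smoothing the pair and ``sigma``-scale sampling noise, can rank the proxy
    above the causal SNP.  Returns
    ``(geno, pheno, labels, causal_idx, spurious_idx)``; the causal/proxy pair
    occupies columns 0 and 1 (one LD block under the default threshold).
    """
    rng = np.random.default_rng([seed, 2])
    causal, spur = 0, 1
    X = rng.standard_normal((n, p))
    X[:, spur] = r * X[:, causal] + np.sqrt(1 - r ** 2) * rng.standard_normal(n)
    X, _, _ = standardize_columns(X)

    k = max(2, q // 5)
    v = np.zeros(q)
    v[:k] = _signed_run(rng, k)
    Y = X[:, causal][:, None] * v[None, :] + sigma * rng.standard_normal((n, q))
    Y, _, _ = standardize_columns(Y)
    z = (X[:, causal] > np.median(X[:, causal])).astype(float)

    geno = GenotypeMatrix(X, [f"s{i + 1}" for i in range(n)],
                          [f"snp{j + 1}" for j in range(p)])
    pheno = PhenotypeViews([Y], [[f"feat{j + 1}" for j in range(q)]], ["view1"])
    return geno, pheno, DiagnosisLabels(z), causal, spur
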