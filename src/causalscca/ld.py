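"""Linkage-disequilibrium block partitioning.

SNPs are split into disjoint blocks from the empirical genotype correlation
matrix.  Correlation is sign-agnostic (|r|), since flipping the allele coding
of a SNP negates its correlations without changing the LD structure.  Two
grouping rules are provided:

* ``contiguous`` (default) — scan adjacent SNPs in genomic order and start a
  new block whenever the adjacent |r| drops to the threshold or below.  LD is
  local along the genome, so blocks are index intervals.
* ``components`` — connected components of the graph with edges |r| above the
  threshold, for inputs without a meaningful ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .io import GenotypeMatrix

log = logging.getLogger(__name__)

__all__ = ["LDBlockPartition", "pairwise_corr", "partition_ld_blocks", "block_gram"]

DEFAULT_LD_THRESHOLD = 0.2


@dataclass
class LDBlockPartition:
    """Disjoint cover of SNP indices by LD blocks, ordered by first index."""

    blocks: list[np.ndarray]
    threshold: float

    def __post_init__(self) -> None:
        self.blocks = [np.asarray(b, dtype=int) for b in self.blocks]
        all_idx = np.concatenate(self.blocks) if self.blocks else np.empty(0, int)
        p = all_idx.size
        if p == 0 or not np.array_equal(np.sort(all_idx), np.arange(p)):
            raise ValueError("blocks must disjointly cover indices 0..p-1")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def sizes(self) -> list[int]:
        return [b.size for b in self.blocks]

    @property
    def p(self) -> int:
        return sum(self.sizes)

    def grouped(self) -> list[tuple[int, np.ndarray, np.ndarray]]:
        """Blocks grouped by size for batched linear algebra.

        Returns ``[(s, idx, pos)]`` tuples where ``idx`` is an (m, s) integer
        array holding the column indices of the m blocks of size s and ``pos``
        their positions in ``self.blocks``.  Cached.
        """
        cache = getattr(self, "_grouped", None)
        if cache is None:
            by_size: dict[int, tuple[list[np.ndarray], list[int]]] = {}
            for k, b in enumerate(self.blocks):
                by_size.setdefault(b.size, ([], []))[0].append(b)
                by_size[b.size][1].append(k)
            cache = [(s, np.vstack(bs), np.asarray(ks))
                     for s, (bs, ks) in sorted(by_size.items())]
            object.__setattr__(self, "_grouped", cache)
        return cache

    def block_ids(self) -> np.ndarray:
        """Per-SNP block label, for serialization as snp_id -> block_id."""
        out = np.empty(self.p, dtype=int)
        for k, b in enumerate(self.blocks):
            out[b] = k
        return out


def pairwise_corr(X: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Pearson correlation between SNP columns; constant columns get r = 0."""
    values = X.values if isinstance(X, GenotypeMatrix) else np.asarray(X, float)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 subjects to estimate correlations")
    std = values.std(axis=0)
    const = std == 0
    if const.any():
        log.warning("%d constant SNP column(s); correlations set to 0", const.sum())
    centred = values - values.mean(axis=0)
    denom = np.where(const, 1.0, std) * np.sqrt(values.shape[0])
    Z = centred / denom
    R = Z.T @ Z
    R[const, :] = 0.0
    R[:, const] = 0.0
    np.fill_diagonal(R, 1.0)
    return np.clip(R, -1.0, 1.0)


def partition_ld_blocks(R: np.ndarray, threshold: float = DEFAULT_LD_THRESHOLD,
                        mode: str = "contiguous",
                        max_block_size: int = 500) -> LDBlockPartition:
    """Group SNPs whose correlation magnitude exceeds ``threshold``.

    Oversized blocks are split at their weakest adjacent link so the blockwise
    solver's cubic per-block cost stays bounded.
    """
    R = np.asarray(R, dtype=float)
    if not (0 <= threshold < 1):
        raise ValueError(f"threshold must lie in [0, 1), got {threshold}")
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("correlation matrix must be square")
    p = R.shape[0]
    A = np.abs(R)

    if mode == "contiguous":
        adj = np.diagonal(A, offset=1)
        cuts = np.flatnonzero(adj <= threshold) + 1       # block start indices
        bounds = np.concatenate(([0], cuts, [p]))
        blocks = [np.arange(a, b) for a, b in zip(bounds[:-1], bounds[1:])]
    elif mode == "components":
        mask = np.triu(A > threshold, k=1)
        graph = csr_matrix(mask)
        _, labels = connected_components(graph, directed=False)
        order = np.argsort(labels, kind="stable")
        blocks = []
        for lab in np.unique(labels):
            blocks.append(np.flatnonzero(labels == lab))
        blocks.sort(key=lambda b: b[0])
    else:
        raise ValueError(f"unknown partition mode {mode!r}")

    blocks = _cap_block_sizes(blocks, A, max_block_size)
    return LDBlockPartition(blocks=blocks, threshold=threshold)


def _cap_block_sizes(blocks: list[np.ndarray], A: np.ndarray,
                     max_block_size: int) -> list[np.ndarray]:
    """Split blocks above the size cap at their weakest adjacent |r| link."""
    out: list[np.ndarray] = []
    stack = list(blocks)[::-1]
    while stack:
        b = stack.pop()
        if b.size <= max_block_size:
            out.append(b)
            continue
        links = A[b[:-1], b[1:]]
        cut = int(np.argmin(links)) + 1
        stack.append(b[cut:])
        stack.append(b[:cut])
    out.sort(key=lambda b: b[0])
    return out


def block_gram(X: GenotypeMatrix | np.ndarray, Q: np.ndarray,
               partition: LDBlockPartition) -> list[np.ndarray]:
    """Weighted within-block Gram matrices X_k^T diag(Q) X_k, one per block."""
    values = X.values if isinstance(X, GenotypeMatrix) else np.asarray(X, float)
    Q = np.asarray(Q, dtype=float).ravel()
    if values.shape[0] != Q.shape[0]:
        raise ValueError("Q length must match number of subjects")
    if partition.p != values.shape[1]:
        raise ValueError("partition does not cover the SNP axis")
    WX = Q[:, None] * values
    grams: list[np.ndarray | None] = [None] * partition.n_blocks
    for s, idx, pos in partition.grouped():
        stack = np.einsum("nms,nmt->mst", values[:, idx], WX[:, idx],
                          optimize=True)
        for row, k in zip(stack, pos):
            grams[k] = row
    return grams
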