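"""Data containers and file I/O.

All matrices travel as labelled TSV (tab-separated, one header row, first
column holds row identifiers).  Genotypes may alternatively arrive as PLINK
``.raw`` allele-count exports.  Phenotype views are plain numeric tables with
subjects in rows.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "GenotypeMatrix",
    "PhenotypeViews",
    "DiagnosisLabels",
    "FitResult",
    "read_genotypes",
    "read_matrix",
    "write_matrix",
    "write_fit_result",
    "standardize_columns",
]


class FormatError(ValueError):
    """Raised when a file does not parse under the expected dialect."""


@dataclass
class GenotypeMatrix:
    """Additive-coded genotype matrix: subjects x SNPs, minor-allele counts.

    ``values`` holds counts in [0, 2] after imputation (continuous dosages are
    accepted when the matrix comes from simulation or imputation software).
    """

    values: np.ndarray
    subject_ids: list[str]
    snp_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, p = self.values.shape
        if n < 2 or p < 1:
            raise ValueError(f"need n >= 2 subjects and p >= 1 SNPs, got {n}x{p}")
        if len(self.subject_ids) != n or len(self.snp_ids) != p:
            raise ValueError("identifier lists do not match matrix dimensions")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("genotype matrix contains non-finite entries")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass
class PhenotypeViews:
    """Ordered collection of phenotype views sharing the subject axis."""

    views: list[np.ndarray]
    feature_ids: list[list[str]]
    view_names: list[str]

    def __post_init__(self) -> None:
        if len(self.views) < 1:
            raise ValueError("need at least one phenotype view")
        self.views = [np.asarray(v, dtype=float) for v in self.views]
        n = self.views[0].shape[0]
        for k, v in enumerate(self.views):
            if v.ndim != 2 or v.shape[0] != n or v.shape[1] < 1:
                raise ValueError(f"view {k} has invalid shape {v.shape}")
            if len(self.feature_ids[k]) != v.shape[1]:
                raise ValueError(f"view {k} feature ids do not match shape")
        if len(self.view_names) != len(self.views):
            raise ValueError("view_names length mismatch")

    @property
    def n(self) -> int:
        return self.views[0].shape[0]

    @property
    def n_views(self) -> int:
        return len(self.views)


@dataclass
class DiagnosisLabels:
    """Per-subject diagnostic status (0/1 for logistic loss; any real coding
    such as ordinal 0/1/2 for the linear loss)."""

    z: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float).ravel()

    @property
    def n(self) -> int:
        return self.z.shape[0]

    def require_binary(self) -> None:
        if not np.all(np.isin(self.z, (0.0, 1.0))):
            raise ValueError("logistic diagnosis loss requires labels in {0,1}")


@dataclass
class FitResult:
    """Fitted canonical weights and sample weights with convergence metadata."""

    U: np.ndarray                      # p x F genetic weights
    V: list[np.ndarray]                # per-view q_f weights
    Q: np.ndarray                      # n sample weights, >= 0, sum n
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = False
    n_iter: int = 0
    snp_ids: list[str] | None = None
    feature_ids: list[list[str]] | None = None
    view_names: list[str] | None = None
    pruned_views: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# readers


def read_matrix(path: str | Path, orientation: str = "subjects_rows") -> pd.DataFrame:
    """Read a labelled numeric TSV (header row + id column) as a DataFrame.

    ``orientation='subjects_cols'`` transposes so subjects end up in rows.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged or malformed TSV: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no data columns")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise ValueError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
        df[col] = coerced
    if orientation == "subjects_cols":
        df = df.T
    elif orientation != "subjects_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    return df


def _impute_counts(values: np.ndarray, snp_ids: Sequence[str]) -> np.ndarray:
    """Impute missing allele counts to the per-SNP rounded mean (stays in 0..2)."""
    out = values.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        miss = np.isnan(col)
        if miss.all():
            out[miss, j] = 0.0
            log.warning("SNP %s entirely missing; imputed to 0", snp_ids[j])
        elif miss.any():
            fill = float(np.clip(np.rint(np.nanmean(col)), 0, 2))
            out[miss, j] = fill
        if np.all(out[:, j] == 0):
            log.warning("SNP %s is constant zero", snp_ids[j])
    return out


def read_genotypes(path: str | Path, format: str = "tsv") -> GenotypeMatrix:
    """Read an additive-coded genotype matrix.

    ``format='tsv'`` expects strict allele counts in {0,1,2,NA}; ``'plink_raw'``
    reads a PLINK ``.raw`` export (space-separated, six leading pedigree
    columns, NA for missing).  Missing entries are imputed to the per-SNP
    rounded mean.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"],
                         float_precision="round_trip")
        if df.shape[1] == 0:
            raise FormatError(f"{path}: no SNP columns")
        values = df.to_numpy(dtype=float)
        obs = values[~np.isnan(values)]
        if not np.all(np.isin(obs, (0.0, 1.0, 2.0))):
            i, j = np.argwhere(~(np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0))))[0]
            raise ValueError(
                f"{path}: entry {values[i, j]!r} at row {df.index[i]!r}, "
                f"column {df.columns[j]!r} is outside {{0,1,2,NA}}"
            )
        subject_ids = [str(s) for s in df.index]
        snp_ids = [str(s) for s in df.columns]
    elif format == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
        lead = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        if list(df.columns[:6]) != lead:
            raise FormatError(f"{path}: not a PLINK .raw header (expected {lead})")
        snp_ids = [str(c) for c in df.columns[6:]]
        if not snp_ids:
            raise FormatError(f"{path}: no SNP columns after pedigree fields")
        values = df[snp_ids].to_numpy(dtype=float)
        obs = values[~np.isnan(values)]
        if not np.all(np.isin(obs, (0.0, 1.0, 2.0))):
            raise ValueError(f"{path}: allele counts outside {{0,1,2,NA}}")
        subject_ids = [str(s) for s in df["IID"]]
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    values = _impute_counts(values, snp_ids)
    return GenotypeMatrix(values, subject_ids, snp_ids)


# ---------------------------------------------------------------------------
# writers


def write_matrix(df_or_values, path: str | Path, index_ids=None, columns=None) -> None:
    """Write a labelled matrix as TSV (header row + id column)."""
    if isinstance(df_or_values, pd.DataFrame):
        df = df_or_values
    else:
        df = pd.DataFrame(np.asarray(df_or_values), index=index_ids, columns=columns)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format="%.17g")


def write_fit_result(result: FitResult, out_dir: str | Path, extra: dict | None = None) -> list[Path]:
    """Write U, each V_f, Q, the objective trace, and a run summary to TSV/JSON."""
    out_dir = Path(out_dir)
    if not out_dir.exists():
        out_dir.mkdir(parents=True)
        log.info("created output directory %s", out_dir)
    if not np.all(np.isfinite(result.U)):
        raise ValueError("fit result contains non-finite U")
    F = result.U.shape[1]
    names = result.view_names or [f"view{f + 1}" for f in range(F)]
    snps = result.snp_ids or [f"snp{i + 1}" for i in range(result.U.shape[0])]
    written: list[Path] = []

    p = out_dir / "U.tsv"
    write_matrix(result.U, p, index_ids=snps, columns=names)
    written.append(p)
    for f, v in enumerate(result.V):
        fids = (result.feature_ids[f] if result.feature_ids
                else [f"feat{i + 1}" for i in range(v.shape[0])])
        p = out_dir / f"V_{names[f]}.tsv"
        write_matrix(v[:, None], p, index_ids=fids, columns=["weight"])
        written.append(p)
    p = out_dir / "Q.tsv"
    write_matrix(result.Q[:, None], p,
                 index_ids=[f"s{i + 1}" for i in range(result.Q.shape[0])],
                 columns=["weight"])
    written.append(p)
    p = out_dir / "objective_trace.tsv"
    write_matrix(result.objective_trace[:, None], p,
                 index_ids=[str(i) for i in range(result.objective_trace.shape[0])],
                 columns=["objective"])
    written.append(p)
    summary = {
        "converged": bool(result.converged),
        "n_iter": int(result.n_iter),
        "pruned_views": list(result.pruned_views),
    }
    if extra:
        summary.update(extra)
    p = out_dir / "run_summary.json"
    p.write_text(json.dumps(summary, indent=2, sort_keys=True, default=str))
    written.append(p)
    return written


# ---------------------------------------------------------------------------
# preprocessing


def standardize_columns(values: np.ndarray, mean: np.ndarray | None = None,
                        std: np.ndarray | None = None):
    """z-score columns; zero-variance columns are left centred (std treated as 1).

    Returns ``(standardized, mean, std)`` so test folds can reuse training
    statistics.
    """
    values = np.asarray(values, dtype=float)
    if mean is None:
        mean = values.mean(axis=0)
    if std is None:
        std = values.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    return (values - mean) / std, mean, std
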