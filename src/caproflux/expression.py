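"""Transcriptome summary statistics on gene-level expression tables.

The pipeline consumes precomputed differential results (log2 fold change
and BH-adjusted p-values, lactate vs glucose) and implements the downstream
procedures: TPM normalization, differential-gene thresholding with strict
inequalities (|log2FC| > 1 and padj < 0.05), transcript-fraction summaries,
upper-tail hypergeometric COG enrichment (no multiple-testing correction by
default), the 2^-ddCT relative-expression transform, and RNA-seq/qPCR
fold-change concordance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DegSets",
    "EnrichmentResult",
    "tpm_from_counts",
    "deg_filter",
    "cog_enrichment",
    "transcript_fraction",
    "ddct_relative_expression",
    "fold_change_concordance",
]


def tpm_from_counts(counts, lengths) -> np.ndarray:
    """Transcripts per million: rate = count/length, scaled to sum to 1e6."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if counts.shape != lengths.shape:
        raise ValueError("counts and lengths have different shapes")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    rates = counts / lengths
    total = rates.sum()
    if total == 0:
        warnings.warn("all counts are zero; TPM vector is all-zero", stacklevel=2)
        return np.zeros_like(rates)
    return rates / total * 1e6


@dataclass(frozen=True)
class DegSets:
    up: Set[str]
    down: Set[str]

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


def deg_filter(
    table: pd.DataFrame,
    lfc_threshold: float = 1.0,
    padj_threshold: float = 0.05,
    gene_col: str = "gene_id",
    lfc_col: str = "log2fc",
    padj_col: str = "padj",
) -> DegSets:
    """Differential genes at |log2FC| > lfc_threshold and padj < padj_threshold.

    Both inequalities are strict, so boundary genes (log2FC exactly 1, padj
    exactly 0.05) are excluded.  Up = higher under the numerator condition
    (lactate, as supplied).
    """
    for col in (gene_col, lfc_col, padj_col):
        if col not in table.columns:
            raise KeyError(f"missing required column {col!r}")
    ok = table[padj_col].notna() & (table[padj_col] < padj_threshold)
    up = set(table.loc[ok & (table[lfc_col] > lfc_threshold), gene_col])
    down = set(table.loc[ok & (table[lfc_col] < -lfc_threshold), gene_col])
    return DegSets(up=up, down=down)


@dataclass(frozen=True)
class EnrichmentResult:
    cog: str
    genome_size: int  # N: tested gene universe
    category_size: int  # K: universe genes in this COG
    deg_size: int  # n: differential genes drawn
    deg_in_category: int  # k
    pvalue: float
    flag: str  # "" / "*" (p<0.05) / "**" (p<0.01)


def cog_enrichment(
    deg_set: Iterable[str],
    genome_table: pd.DataFrame,
    min_genes: int = 5,
    gene_col: str = "gene_id",
    cog_col: str = "cog",
) -> List[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment P(X >= k) per COG category.

    The universe N is every gene in ``genome_table``; only categories with
    more than ``min_genes`` members in that universe are reported.  No
    multiple-testing correction is applied; results carry significance
    flags at the 0.05 (*) and 0.01 (**) levels.
    """
    if genome_table.empty:
        raise ValueError("empty genome table")
    genes = genome_table[gene_col]
    deg_set = set(deg_set)
    unknown = deg_set - set(genes)
    if unknown:
        raise ValueError(f"differential genes not in genome table: {sorted(unknown)[:5]}")
    n_universe = len(genes)
    n_deg = len(deg_set)
    cogs = genome_table[cog_col].fillna("")
    results: List[EnrichmentResult] = []
    for cat in sorted(c for c in cogs.unique() if c):
        members = set(genes[cogs == cat])
        big_k = len(members)
        if big_k <= min_genes:
            continue
        k = len(deg_set & members)
        p = float(stats.hypergeom.sf(k - 1, n_universe, big_k, n_deg))
        flag = "**" if p < 0.01 else "*" if p < 0.05 else ""
        results.append(EnrichmentResult(cat, n_universe, big_k, n_deg, k, p, flag))
    return results


def transcript_fraction(
    table: pd.DataFrame,
    gene_ids: Sequence[str],
    condition: str,
    gene_col: str = "gene_id",
) -> float:
    """Percent of total transcripts contributed by the selected genes.

    ``condition`` names a TPM column (e.g. ``tpm_lactate``).  Because TPM
    sums to 1e6 within a sample, the fraction is sum(TPM)/1e6 * 100.
    """
    col = condition if condition in table.columns else f"tpm_{condition}"
    if col not in table.columns:
        raise KeyError(f"no TPM column for condition {condition!r}")
    idx = table.set_index(gene_col)[col]
    missing = [g for g in gene_ids if g not in idx.index]
    if missing:
        raise KeyError(f"unknown gene id(s): {missing}")
    return float(idx.loc[list(gene_ids)].sum()) / 1e6 * 100.0


def ddct_relative_expression(
    ct_target: float,
    ct_reference: float,
    ct_target_control: float,
    ct_reference_control: float,
) -> float:
    """Relative expression by the 2^-ddCT method.

    dCT = CT(target) - CT(reference gene); ddCT subtracts the control
    sample's dCT, so the control evaluates to exactly 1.0.
    """
    for v in (ct_target, ct_reference, ct_target_control, ct_reference_control):
        if not np.isfinite(v):
            raise ValueError("CT values must be finite")
    ddct = (ct_target - ct_reference) - (ct_target_control - ct_reference_control)
    return float(2.0 ** (-ddct))


def fold_change_concordance(
    log2fc_rnaseq: Sequence[float], log2fc_qpcr: Sequence[float]
) -> Tuple[float, int]:
    """Pearson correlation of RNA-seq vs qPCR log2 fold changes; returns (r, n)."""
    x = np.asarray(log2fc_rnaseq, dtype=float)
    y = np.asarray(log2fc_qpcr, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors differ in length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("undefined correlation: zero variance in one vector")
    r = float(stats.pearsonr(x, y).statistic)
    return r, int(x.size)
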