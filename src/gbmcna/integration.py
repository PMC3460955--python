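"""Gene-level CN summarisation and CN-expression dosage screening.

A gene is "dosage sensitive" when its mRNA level tracks its DNA copy
number across paired tumor samples. The screen computes, per gene, the
Pearson correlation r between gene-level CN and RMA-scale expression over
the shared samples, with the two-sided p-value from the t transform
t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 degrees of freedom, and applies a dual
strict filter: R^2 > ``r2_min`` and p < ``p_max``.

At the reference sample size n = 23 the two default conditions nearly
coincide: the p implied by R^2 = 0.70 is ~6.5e-7, within a factor of two
of the 5e-7 cutoff, so the dual filter behaves as a single R^2 cutoff.
No multiple-testing correction is applied, deliberately: the screen uses
one fixed p cutoff across all genes (documented in the report header).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import CnProfile, GeneModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    """Dual strict dosage filter: R^2 > r2_min and p < p_max."""

    r2_min: float = 0.70
    p_max: float = 5e-7

    def __post_init__(self) -> None:
        if not 0 <= self.r2_min <= 1:
            raise ValueError("r2_min must be in [0, 1]")
        if not 0 < self.p_max < 1:
            raise ValueError("p_max must be in (0, 1)")


DEFAULT_FILTER = FilterConfig()


@dataclass(frozen=True)
class DosageResult:
    """Per-gene CN-expression correlation statistics."""

    gene: str
    n: int
    r: float
    r_squared: float
    p_value: float
    passes_filter: bool
    cytoband: str | None = None
    cn_from_nearest: bool = False


class GeneCn(NamedTuple):
    """Gene-level CN summary; ``from_nearest`` flags the no-overlap fallback."""

    value: float
    from_nearest: bool


def summarize_gene_cn(
    profile: CnProfile,
    gene: GeneModel,
    flank: int = 10_000,
    stat: str = "mean",
) -> GeneCn:
    """Summarise probe CN over [start - flank, end + flank] of a gene.

    Mean (default) or median of the overlapping probes; when no probe
    overlaps, the nearest probe's value is used and flagged.
    """
    sub = profile.probes[profile.probes["chrom"] == gene.chrom]
    if sub.empty:
        raise ValueError(
            f"chromosome {gene.chrom} absent from profile {profile.sample_id}"
        )
    pos = sub["pos"].to_numpy()
    cn = sub["cn"].to_numpy(dtype=float)
    lo, hi = gene.start - flank, gene.end + flank
    mask = (pos >= lo) & (pos <= hi)
    if mask.any():
        values = cn[mask]
        value = float(np.median(values)) if stat == "median" else float(values.mean())
        return GeneCn(value, False)
    dist = np.where(pos < gene.start, gene.start - pos, pos - gene.end)
    return GeneCn(float(cn[int(np.argmin(dist))]), True)


def gene_cn_matrix(
    profiles: Sequence[CnProfile],
    genes: Sequence[GeneModel],
    flank: int = 10_000,
    stat: str = "mean",
) -> pd.DataFrame:
    """Genes x samples matrix of gene-level CN summaries."""
    data = {
        p.sample_id: [summarize_gene_cn(p, g, flank, stat).value for g in genes]
        for p in profiles
    }
    return pd.DataFrame(data, index=pd.Index([g.symbol for g in genes], name="gene"))


def dosage_p_value(r_squared: float, n: int) -> float:
    """Two-sided p for a Pearson R^2 at sample size n, via the t transform."""
    if not 0 <= r_squared <= 1:
        raise ValueError("r_squared must be in [0, 1]")
    if n < 3:
        raise ValueError("n must be >= 3")
    if r_squared >= 1.0:
        return 0.0
    t = math.sqrt(r_squared * (n - 2) / (1.0 - r_squared))
    return 2.0 * float(stats.t.sf(t, n - 2))


def passes_dosage_filter(
    r_squared: float, n: int, config: FilterConfig = DEFAULT_FILTER
) -> bool:
    """Apply the dual strict filter to an R^2 value at sample size n."""
    return r_squared > config.r2_min and dosage_p_value(r_squared, n) < config.p_max


def pearson_dosage(
    cn_vector: Sequence[float],
    expr_vector: Sequence[float],
    gene: str = "gene",
    config: FilterConfig = DEFAULT_FILTER,
    cytoband: str | None = None,
    cn_from_nearest: bool = False,
) -> DosageResult:
    """Pearson CN-expression correlation for one gene."""
    x = np.asarray(cn_vector, dtype=float)
    y = np.asarray(expr_vector, dtype=float)
    if x.shape != y.shape:
        raise ValueError("CN and expression vectors differ in length")
    n = len(x)
    if n < 3:
        raise ValueError("need >= 3 paired samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError(f"{gene}: zero variance, correlation undefined")
    r, p = stats.pearsonr(x, y)
    r = float(r)
    r2 = r * r
    return DosageResult(
        gene=gene,
        n=n,
        r=r,
        r_squared=r2,
        p_value=float(p),
        passes_filter=(r2 > config.r2_min and p < config.p_max),
        cytoband=cytoband,
        cn_from_nearest=cn_from_nearest,
    )


def dosage_screen(
    cn_matrix: pd.DataFrame,
    expr_matrix: pd.DataFrame,
    config: FilterConfig = DEFAULT_FILTER,
    cytobands: dict[str, str] | None = None,
) -> list[DosageResult]:
    """Screen every shared gene for CN-expression dosage correlation.

    Both inputs are genes x samples. The screen runs over ALL genes shared
    between the two matrices, not only genes inside called events. Genes
    with zero variance in either vector are skipped with a log entry.
    Results are sorted by R^2 descending (gene symbol as tie-break).
    """
    shared_samples = [s for s in cn_matrix.columns if s in set(expr_matrix.columns)]
    if len(shared_samples) < 3:
        raise ValueError(
            f"only {len(shared_samples)} shared samples; need >= 3 for the screen"
        )
    shared_genes = [g for g in cn_matrix.index if g in set(expr_matrix.index)]
    results: list[DosageResult] = []
    for gene in shared_genes:
        try:
            results.append(
                pearson_dosage(
                    cn_matrix.loc[gene, shared_samples].to_numpy(dtype=float),
                    expr_matrix.loc[gene, shared_samples].to_numpy(dtype=float),
                    gene=gene,
                    config=config,
                    cytoband=(cytobands or {}).get(gene),
                )
            )
        except ValueError as exc:
            logger.warning("dosage screen: skipping %s (%s)", gene, exc)
    results.sort(key=lambda d: (-d.r_squared, d.gene))
    return results


def spearman_validation(
    values_a: Sequence[float], values_b: Sequence[float]
) -> float:
    """Spearman rank correlation (average ranks for ties).

    Used to validate array-based mRNA levels against an orthogonal assay
    (e.g. quantitative RT-PCR).
    """
    x = np.asarray(values_a, dtype=float)
    y = np.asarray(values_b, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors differ in length")
    if len(x) < 3:
        raise ValueError("need >= 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input, rank correlation undefined")
    return float(stats.spearmanr(x, y).statistic)
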