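"""Enrichment testing: is the candidate list better than random genes?

Calling a gene "significant" (it contains at least one SNP below a fixed
threshold) is a Bernoulli trial, so the number of significant genes among
an n-gene list follows, to good approximation, Binomial(n, p) with p the
store-wide background rate — the proportion of all genes in the gene
database that contain a sub-threshold SNP. The enrichment p-value is the
complementary cumulative binomial probability

    P(X >= x) = 1 - sum_{k=0}^{x-1} C(n, k) p^k (1-p)^(n-k),

evaluated through the survival function to avoid the catastrophic
cancellation a literal 1-minus-CDF would suffer for very small tails.

Two null distributions back this approximation up: the resampling null
(random gene lists of the same size, optionally recomputing the list-wise
Bonferroni threshold per draw, then counting significant genes) and the
direct binomial simulation. Their agreement is assessed by pairing their
order statistics (a QQ plot) and reporting the Spearman rank correlation
of the paired quantiles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .gene_db import GeneModel, GeneStore, is_gonosomal
from .gwas_io import GwasIndex, GwasRecord, GwasTable
from .ld_reference import PrunedSnpStore
from .prioritize import (
    DEFAULT_ALPHA,
    DEFAULT_FLANK_BP,
    SignificanceThreshold,
    ThresholdMethod,
    flank_gene,
)

logger = logging.getLogger(__name__)


def _as_index(summary: GwasIndex | GwasTable | Iterable[GwasRecord]) -> GwasIndex:
    if isinstance(summary, GwasIndex):
        return summary
    if isinstance(summary, GwasTable):
        return summary.index()
    return GwasIndex.from_records(summary)


def _store_genes(store: GeneStore | Sequence[GeneModel], exclude_gonosomes: bool) -> list[GeneModel]:
    genes = list(store)
    if exclude_gonosomes:
        genes = [g for g in genes if not is_gonosomal(g.chromosome)]
    return genes


def gene_min_pvalues(
    genes: Sequence[GeneModel],
    summary: GwasIndex | GwasTable | Iterable[GwasRecord],
    flank_bp: int = DEFAULT_FLANK_BP,
) -> np.ndarray:
    """Smallest summary p-value inside each gene's flanked region.

    ``inf`` marks genes whose region contains no SNP; a gene is significant
    at threshold t iff its entry is strictly below t.
    """
    index = _as_index(summary)
    out = np.empty(len(genes))
    for i, gene in enumerate(genes):
        region = flank_gene(gene, flank_bp)
        out[i] = index.min_p(gene.chromosome, region.region_start, region.region_end)
    return out


@dataclass(frozen=True)
class BackgroundRate:
    """Store-wide per-gene significance rate at a fixed threshold."""

    p: float
    n_significant: int
    total_genes: int


def background_rate(
    store: GeneStore | Sequence[GeneModel],
    summary: GwasIndex | GwasTable | Iterable[GwasRecord],
    threshold_value: float,
    flank_bp: int = DEFAULT_FLANK_BP,
    exclude_gonosomes: bool = True,
) -> BackgroundRate:
    """Scan every stored gene at one fixed threshold.

    p = (genes with a sub-threshold SNP in their flanked region) / total.
    Requires a single fixed threshold (list-wise Bonferroni, FDR or fixed
    mode); the binomial model has no meaning under per-gene thresholds.
    When gonosomal genes are excluded from candidate lists they are also
    excluded from this universe, keeping numerator and denominator
    consistent.
    """
    if not (0.0 < threshold_value <= 1.0):
        raise ValueError("threshold_value must lie in (0, 1]")
    genes = _store_genes(store, exclude_gonosomes)
    if not genes:
        raise ValueError("gene store is empty")
    min_p = gene_min_pvalues(genes, summary, flank_bp)
    n_significant = int((min_p < threshold_value).sum())
    return BackgroundRate(
        p=n_significant / len(genes), n_significant=n_significant, total_genes=len(genes)
    )


def enrichment_pvalue(n: int, p: float, x: int) -> float:
    """P(X >= x) under Binomial(n, p), the complementary cumulative tail.

    Evaluated via the survival function; P(X >= 0) is exactly 1.
    """
    if not (0 <= x <= n):
        raise ValueError(f"require 0 <= x <= n, got x={x}, n={n}")
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"background rate p must lie in [0, 1], got {p}")
    return float(stats.binom.sf(x - 1, n, p))


def resampling_null(
    store: GeneStore | Sequence[GeneModel],
    summary: GwasIndex | GwasTable | Iterable[GwasRecord],
    list_size: int,
    iterations: int = 2000,
    flank_bp: int = DEFAULT_FLANK_BP,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    snp_store: PrunedSnpStore | None = None,
    ancestry: str | None = None,
    fixed_threshold: float | None = None,
    exclude_gonosomes: bool = True,
) -> np.ndarray:
    """Significant-gene counts over random gene lists drawn from the store.

    Each iteration draws ``list_size`` genes uniformly without replacement.
    With ``fixed_threshold`` set, every draw is scored against that single
    threshold (the regime used to check the binomial approximation).
    Otherwise the list-wise Bonferroni threshold alpha / sum(m_g) is
    recomputed for each draw from the pruned-SNP store, which accounts for
    the differing size and LD structure of the drawn genes.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    genes = _store_genes(store, exclude_gonosomes)
    if list_size > len(genes):
        raise ValueError(f"list_size {list_size} exceeds store size {len(genes)}")
    min_p = gene_min_pvalues(genes, summary, flank_bp)

    m_g: np.ndarray | None = None
    if fixed_threshold is None:
        if snp_store is None or ancestry is None:
            raise ValueError(
                "per-draw threshold recomputation needs snp_store and ancestry; "
                "or pass fixed_threshold"
            )
        m_g = np.empty(len(genes), dtype=np.int64)
        for i, gene in enumerate(genes):
            region = flank_gene(gene, flank_bp)
            m_g[i] = snp_store.count_independent(
                ancestry, gene.chromosome, region.region_start + 1, region.region_end + 1
            )

    rng = np.random.default_rng(seed)
    counts = np.empty(iterations, dtype=np.int64)
    for it in range(iterations):
        draw = rng.choice(len(genes), size=list_size, replace=False)
        if fixed_threshold is not None:
            threshold = fixed_threshold
        else:
            M = int(m_g[draw].sum())  # type: ignore[index]
            threshold = alpha / M if M > 0 else float(np.nextafter(0.0, 1.0))
        counts[it] = int((min_p[draw] < threshold).sum())
    return counts


def binomial_null_sim(
    n: int, p: float, iterations: int = 2000, seed: int = 0
) -> np.ndarray:
    """``iterations`` independent Binomial(n, p) draws (the simulated null)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    if n < 0 or iterations < 1:
        raise ValueError("need n >= 0 and iterations >= 1")
    rng = np.random.default_rng(seed)
    return rng.binomial(n, p, size=iterations).astype(np.int64)


@dataclass(frozen=True)
class NullComparison:
    """QQ-paired order statistics of two null-count samples."""

    quantiles_a: np.ndarray
    quantiles_b: np.ndarray
    spearman: float


def compare_nulls(
    counts_a: Sequence[int] | np.ndarray, counts_b: Sequence[int] | np.ndarray
) -> NullComparison:
    """Pair the sorted counts quantile-wise and rank-correlate them.

    Spearman uses average ranks for ties; if either sample is constant the
    coefficient is undefined and reported as NaN with a warning.
    """
    a = np.sort(np.asarray(counts_a))
    b = np.sort(np.asarray(counts_b))
    if a.size != b.size:
        raise ValueError(f"sample sizes differ: {a.size} vs {b.size}")
    if a.size == 0:
        raise ValueError("empty samples")
    if np.all(a == a[0]) or np.all(b == b[0]):
        logger.warning("constant null sample: Spearman coefficient undefined (NaN)")
        rho = float("nan")
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho = float(stats.spearmanr(a, b).statistic)
    return NullComparison(quantiles_a=a, quantiles_b=b, spearman=rho)


@dataclass
class EnrichmentResult:
    """Everything the enrichment report needs, including the null samples."""

    n: int
    x: int
    p: float
    p_enrichment: float
    threshold_used: SignificanceThreshold
    iterations: int = 2000
    seed: int = 0
    null_counts_resampling: np.ndarray | None = None
    null_counts_binomial: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "x": self.x,
            "background_rate": self.p,
            "p_enrichment": self.p_enrichment,
            "threshold_method": self.threshold_used.method.value,
            "threshold_value": self.threshold_used.value,
            "M": self.threshold_used.M,
            "iterations": self.iterations,
            "seed": self.seed,
        }


def evaluate_enrichment(
    store: GeneStore | Sequence[GeneModel],
    summary: GwasIndex | GwasTable | Iterable[GwasRecord],
    threshold: SignificanceThreshold,
    n: int,
    x: int,
    flank_bp: int = DEFAULT_FLANK_BP,
    iterations: int = 2000,
    seed: int = 0,
    null_mode: str = "binomial",
    snp_store: PrunedSnpStore | None = None,
    ancestry: str | None = None,
    alpha: float = DEFAULT_ALPHA,
    exclude_gonosomes: bool = True,
) -> EnrichmentResult:
    """Full enrichment evaluation for an observed candidate-list outcome.

    ``threshold`` must carry a single fixed value (list-wise, FDR or fixed
    mode); per-gene mode is rejected because the binomial background rate
    presumes one threshold applied uniformly to every gene.
    """
    if threshold.method is ThresholdMethod.BONFERRONI_PER_GENE or threshold.value is None:
        raise ValueError(
            "enrichment requires a single fixed threshold: use the list-wise "
            "Bonferroni option (or a fixed/FDR threshold), not per-gene mode"
        )
    if null_mode not in {"binomial", "resampling", "both", "none"}:
        raise ValueError("null_mode must be binomial|resampling|both|none")
    index = _as_index(summary)
    background = background_rate(
        store, index, threshold.value, flank_bp, exclude_gonosomes
    )
    result = EnrichmentResult(
        n=n,
        x=x,
        p=background.p,
        p_enrichment=enrichment_pvalue(n, background.p, x),
        threshold_used=threshold,
        iterations=iterations,
        seed=seed,
    )
    if null_mode in {"binomial", "both"}:
        result.null_counts_binomial = binomial_null_sim(n, background.p, iterations, seed)
    if null_mode in {"resampling", "both"}:
        result.null_counts_resampling = resampling_null(
            store,
            index,
            list_size=n,
            iterations=iterations,
            flank_bp=flank_bp,
            alpha=alpha,
            seed=seed,
            snp_store=snp_store,
            ancestry=ancestry,
            fixed_threshold=None if snp_store is not None else threshold.value,
            exclude_gonosomes=exclude_gonosomes,
        )
    return result


def plot_null_distribution(
    counts: np.ndarray,
    n: int,
    p: float,
    observed_x: int,
    path,
    title: str | None = None,
) -> None:
    """Histogram of null counts, binomial density overlay, observed-x line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    counts = np.asarray(counts)
    fig, ax = plt.subplots(figsize=(6, 4))
    hi = int(max(counts.max(initial=0), observed_x)) + 2
    bins = np.arange(-0.5, hi + 0.5)
    ax.hist(counts, bins=bins, density=True, color="lightsteelblue", edgecolor="white",
            label="null counts")
    k = np.arange(0, hi + 1)
    ax.plot(k, stats.binom.pmf(k, n, p), "o-", color="firebrick", markersize=3,
            label=f"Binomial(n={n}, p={p:.3g})")
    ax.axvline(observed_x, color="black", linewidth=1.5, label=f"observed x = {observed_x}")
    ax.set_xlabel("significant genes per list")
    ax.set_ylabel("density")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
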