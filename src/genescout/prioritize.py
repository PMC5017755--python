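"""The three-step candidate-gene prioritization core.

Step 1 resolves a list of human gene symbols against the gene store and
flanks each span (10 kb up- and downstream by default), so the tested
region covers exons, introns and proximal regulatory sequence. Step 2
derives a significance threshold from the number of independent SNPs in
those regions — per-gene Bonferroni (alpha / m_g) by default, list-wise
Bonferroni (alpha / sum of m_g), Benjamini-Hochberg FDR, or a fixed
user-supplied value. Step 3 streams the GWAS summary file and extracts
every SNP that falls inside a region with p strictly below the applied
threshold, annotated to its gene; a SNP inside k overlapping regions is
emitted once per gene.

The list-wise sum deliberately does not deduplicate independent SNPs
shared by overlapping flanked regions: the resulting larger denominator
gives a stricter (conservative) threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .gene_db import GeneModel, GeneStore, is_gonosomal, normalize_chromosome
from .gwas_io import MIN_PVALUE, GwasIndex, GwasRecord, GwasTable
from .ld_reference import PrunedSnpStore

logger = logging.getLogger(__name__)

DEFAULT_FLANK_BP = 10_000
DEFAULT_ALPHA = 0.05


@dataclass
class CandidateList:
    """A resolved candidate gene list with its filtering audit trail."""

    name: str
    requested_symbols: list[str]
    resolved: list[GeneModel]
    filtered: dict[str, str] = field(default_factory=dict)
    duplicates: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.resolved)


def resolve_candidates(
    symbols: Sequence[str],
    store: GeneStore,
    exclude_gonosomes: bool = True,
    name: str = "candidates",
) -> CandidateList:
    """Map requested symbols to stored gene models, filtering as we go.

    Duplicates collapse to their first occurrence (warned); symbols absent
    from the store are filtered as ``unmapped``; X/Y genes are filtered as
    ``gonosomal`` when ``exclude_gonosomes`` is set (autosomal GWAS files
    carry no sex-chromosome statistics). Raises if nothing resolves.
    """
    if not symbols:
        raise ValueError("candidate symbol list is empty")
    resolved: list[GeneModel] = []
    filtered: dict[str, str] = {}
    duplicates: list[str] = []
    seen: set[str] = set()
    for symbol in symbols:
        symbol = symbol.strip()
        if not symbol:
            continue
        if symbol in seen:
            duplicates.append(symbol)
            continue
        seen.add(symbol)
        model = store.lookup(symbol)
        if model is None:
            filtered[symbol] = "unmapped"
            continue
        if exclude_gonosomes and is_gonosomal(model.chromosome):
            filtered[symbol] = "gonosomal"
            continue
        resolved.append(model)
    if duplicates:
        logger.warning("collapsed %d duplicate symbol(s): %s", len(duplicates), duplicates)
    if filtered:
        logger.info("filtered %d symbol(s): %s", len(filtered), filtered)
    if not resolved:
        raise ValueError("no candidate genes resolved: nothing to analyze")
    return CandidateList(
        name=name,
        requested_symbols=[s for s in symbols if s.strip()],
        resolved=resolved,
        filtered=filtered,
        duplicates=duplicates,
    )


@dataclass
class GeneRegion:
    """A gene span plus flank; carries its independent-SNP count ``m_g``."""

    gene_symbol: str
    chromosome: str
    region_start: int  # 0-based
    region_end: int  # half-open
    flank_bp: int = DEFAULT_FLANK_BP
    m_g: int | None = None

    def __post_init__(self) -> None:
        if self.region_start < 0 or self.region_start >= self.region_end:
            raise ValueError(f"invalid region for {self.gene_symbol}")


def flank_gene(gene: GeneModel, flank_bp: int = DEFAULT_FLANK_BP) -> GeneRegion:
    """Flanked region of a single gene, clipped at the chromosome start."""
    return GeneRegion(
        gene_symbol=gene.gene_symbol,
        chromosome=gene.chromosome,
        region_start=max(0, gene.start - flank_bp),
        region_end=gene.end + flank_bp,
        flank_bp=flank_bp,
    )


def define_regions(
    candidates: CandidateList | Sequence[GeneModel], flank_bp: int = DEFAULT_FLANK_BP
) -> list[GeneRegion]:
    """One flanked region per resolved gene; overlaps are not merged."""
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    genes = candidates.resolved if isinstance(candidates, CandidateList) else list(candidates)
    return [flank_gene(gene, flank_bp) for gene in genes]


class ThresholdMethod(str, Enum):
    BONFERRONI_PER_GENE = "bonferroni_per_gene"
    BONFERRONI_LISTWISE = "bonferroni_listwise"
    FDR = "fdr"
    FIXED = "fixed"


@dataclass
class SignificanceThreshold:
    """The derived significance threshold and how it was obtained.

    List-wise/FDR/fixed modes carry a single ``value``; per-gene mode
    carries a ``per_gene`` mapping (genes with m_g = 0 are absent and are
    excluded from scanning). ``M`` is the list-wise independent-SNP total.
    """

    method: ThresholdMethod
    alpha: float = DEFAULT_ALPHA
    M: int | None = None
    value: float | None = None
    per_gene: dict[str, float] | None = None

    def threshold_for(self, gene_symbol: str) -> float | None:
        if self.method is ThresholdMethod.BONFERRONI_PER_GENE:
            assert self.per_gene is not None
            return self.per_gene.get(gene_symbol)
        return self.value


def fill_independent_counts(
    regions: Sequence[GeneRegion], snp_store: PrunedSnpStore, ancestry: str
) -> None:
    """Populate each region's ``m_g`` from the pruned-SNP store.

    The region's 0-based half-open span converts to 1-based positions by
    adding 1 to the start; the store query is then [start+1, end+1) on
    1-based coordinates, i.e. exactly the positions the scanner covers.
    """
    for region in regions:
        region.m_g = snp_store.count_independent(
            ancestry, region.chromosome, region.region_start + 1, region.region_end + 1
        )


def _bh_threshold(pvalues: np.ndarray, q: float) -> float:
    """Benjamini-Hochberg cut: strict-inequality threshold just above the
    largest p with p_(k) <= q*k/m, or just above 0 when nothing passes."""
    if pvalues.size == 0:
        return float(np.nextafter(0.0, 1.0))
    p_sorted = np.sort(pvalues)
    m = p_sorted.size
    ranks = np.arange(1, m + 1)
    passing = p_sorted <= q * ranks / m
    if not passing.any():
        return float(np.nextafter(0.0, 1.0))
    largest = p_sorted[np.flatnonzero(passing)[-1]]
    return float(np.nextafter(largest, 1.0))


def compute_threshold(
    regions: Sequence[GeneRegion],
    snp_store: PrunedSnpStore | None = None,
    ancestry: str | None = None,
    method: ThresholdMethod | str = ThresholdMethod.BONFERRONI_PER_GENE,
    alpha: float = DEFAULT_ALPHA,
    fixed_value: float | None = None,
    fdr_q: float | None = None,
    summary: GwasIndex | GwasTable | None = None,
) -> SignificanceThreshold:
    """Derive the significance threshold for a set of candidate regions.

    Bonferroni modes need independent-SNP counts: ``m_g`` is filled from
    ``snp_store``/``ancestry`` unless every region already carries one
    (precomputed counts are accepted so thresholds can be derived without
    a store at hand). The FDR mode needs the ``summary`` to collect the
    candidate-region p-values it ranks; the fixed mode just echoes
    ``fixed_value``.
    """
    if not regions:
        raise ValueError("no regions: cannot compute a threshold")
    method = ThresholdMethod(method)

    if method in (ThresholdMethod.BONFERRONI_PER_GENE, ThresholdMethod.BONFERRONI_LISTWISE):
        if any(region.m_g is None for region in regions):
            if snp_store is None or ancestry is None:
                raise ValueError("Bonferroni modes need snp_store and ancestry (or preset m_g)")
            fill_independent_counts(regions, snp_store, ancestry)
        if method is ThresholdMethod.BONFERRONI_LISTWISE:
            M = int(sum(region.m_g for region in regions))  # type: ignore[misc]
            if M == 0:
                raise ValueError("list-wise Bonferroni: zero independent SNPs across regions")
            return SignificanceThreshold(
                method=method, alpha=alpha, M=M, value=alpha / M
            )
        per_gene: dict[str, float] = {}
        for region in regions:
            if region.m_g == 0:
                logger.warning(
                    "gene %s has 0 independent SNPs; excluded from scanning", region.gene_symbol
                )
                continue
            per_gene[region.gene_symbol] = alpha / region.m_g  # type: ignore[operator]
        M = int(sum(region.m_g for region in regions))  # type: ignore[misc]
        return SignificanceThreshold(method=method, alpha=alpha, M=M, per_gene=per_gene)

    if method is ThresholdMethod.FIXED:
        if fixed_value is None or not (0.0 < fixed_value <= 1.0):
            raise ValueError("fixed method requires fixed_value in (0, 1]")
        return SignificanceThreshold(method=method, alpha=alpha, value=float(fixed_value))

    # FDR: Benjamini-Hochberg over the candidate-region SNP p-values.
    if fdr_q is None or not (0.0 < fdr_q < 1.0):
        raise ValueError("fdr method requires fdr_q in (0, 1)")
    if summary is None:
        raise ValueError("fdr method requires the GWAS summary to rank p-values")
    index = summary.index() if isinstance(summary, GwasTable) else summary
    chunks = [
        index.pvalues_in(region.chromosome, region.region_start, region.region_end)
        for region in regions
    ]
    pvalues = np.concatenate(chunks) if chunks else np.empty(0)
    return SignificanceThreshold(
        method=method, alpha=alpha, value=_bh_threshold(pvalues, fdr_q)
    )


@dataclass
class HitTable:
    """Sub-threshold SNPs annotated to their genes, plus the gene tally.

    ``frame`` columns: the summary file's standardized and pass-through
    columns followed by gene_symbol, region_start, region_end and the
    applied threshold; sorted by (chromosome, position, gene).
    ``x`` = number of distinct genes with at least one hit.
    """

    frame: pd.DataFrame
    significant_genes: set[str]
    n_skipped: int = 0

    @property
    def x(self) -> int:
        return len(self.significant_genes)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def scan_gwas(
    summary: GwasTable | Iterable[GwasRecord],
    regions: Sequence[GeneRegion],
    threshold: SignificanceThreshold,
    passthrough_names: Sequence[str] | None = None,
) -> HitTable:
    """Extract sub-threshold SNPs inside the candidate regions.

    Strict inequality: a SNP with p exactly equal to the applied threshold
    is not a hit. A SNP inside k overlapping regions yields k rows. Rows
    are sorted by (chromosome, position, gene_symbol), so the result does
    not depend on the input row order.
    """
    if not regions:
        raise ValueError("no regions: nothing to scan")
    if isinstance(summary, GwasTable):
        passthrough_names = summary.passthrough_names
        records: Iterable[GwasRecord] = summary.records()
    else:
        records = summary
    passthrough_names = list(passthrough_names or [])

    trees: dict[str, IntervalTree] = {}
    for idx, region in enumerate(regions):
        if threshold.threshold_for(region.gene_symbol) is None:
            continue  # per-gene mode with m_g = 0: excluded
        key = normalize_chromosome(region.chromosome)
        # 1-based position q is inside [start, end) 0-based iff start < q <= end
        trees.setdefault(key, IntervalTree()).addi(
            region.region_start + 1, region.region_end + 1, idx
        )

    rows: list[dict] = []
    n_skipped = 0
    for record in records:
        if not np.isfinite(record.p_value) or not (0.0 < record.p_value <= 1.0):
            n_skipped += 1
            continue
        tree = trees.get(normalize_chromosome(record.chromosome))
        if tree is None:
            continue
        for interval in tree[record.position]:
            region = regions[interval.data]
            applied = threshold.threshold_for(region.gene_symbol)
            if record.p_value < applied:
                row = {
                    "snp_id": record.snp_id,
                    "chromosome": record.chromosome,
                    "position": record.position,
                    "p_value": record.p_value,
                }
                row.update(dict(zip(passthrough_names, record.passthrough)))
                row.update(
                    {
                        "gene_symbol": region.gene_symbol,
                        "region_start": region.region_start,
                        "region_end": region.region_end,
                        "applied_threshold": applied,
                    }
                )
                rows.append(row)
    if n_skipped:
        logger.warning("scan skipped %d record(s) with invalid p-values", n_skipped)

    columns = (
        ["snp_id", "chromosome", "position", "p_value"]
        + passthrough_names
        + ["gene_symbol", "region_start", "region_end", "applied_threshold"]
    )
    frame = pd.DataFrame(rows, columns=columns)
    if not frame.empty:
        frame = frame.assign(_chrom=frame["chromosome"].map(normalize_chromosome))
        frame = (
            frame.sort_values(["_chrom", "position", "gene_symbol"], kind="mergesort")
            .drop(columns="_chrom")
            .reset_index(drop=True)
        )
    return HitTable(
        frame=frame,
        significant_genes=set(frame["gene_symbol"]) if not frame.empty else set(),
        n_skipped=n_skipped,
    )


def run_summary(
    candidates: CandidateList,
    regions: Sequence[GeneRegion],
    threshold: SignificanceThreshold,
    hits: HitTable,
) -> dict:
    """JSON-serializable run summary (n, M, threshold, x, filtering)."""
    return {
        "candidate_list": candidates.name,
        "n_requested": len(candidates.requested_symbols),
        "n_resolved": candidates.n,
        "filtered": candidates.filtered,
        "duplicates": candidates.duplicates,
        "threshold_method": threshold.method.value,
        "alpha": threshold.alpha,
        "M": threshold.M,
        "threshold_value": threshold.value,
        "x_significant_genes": hits.x,
        "significant_genes": sorted(hits.significant_genes),
        "n_hit_rows": int(len(hits.frame)),
        "n_skipped_rows": hits.n_skipped,
    }
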