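"""Synthetic fixtures: gene catalogs, LD-structured panels, GWAS summaries.

Everything the pipeline consumes can be generated here at desk scale with
no download: a refFlat-format gene catalog over toy chromosomes (with a
truth table of the expected canonical span per gene), reference genotype
panels with block-exchangeable LD, and GWAS summary files whose p-values
are i.i.d. Uniform(0, 1) under the null with optional planted low-p
signals inside chosen genes.

The LD model is deliberately simple: SNPs in a block share a latent
haplotype and differ from it by independent flips calibrated so the
haplotype correlation between block-mates is approximately
``within_block_r``; cross-block correlation is ~0. That is enough to
exercise MAF filtering and windowed r² pruning and is analytically
transparent — it makes no claim to a realistic allele-frequency spectrum
or recombination map.

All generators are pure functions of their configuration: the same seed
yields byte-identical output files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ld_reference import GenotypePanel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PlantedSignal:
    """A gene to receive ``n_signals`` SNPs at p = ``p_value`` in its flanked span."""

    gene_symbol: str
    n_signals: int = 2
    p_value: float = 1e-15


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults give a small two-chromosome world (200 genes, ~50k SNPs per
    chromosome) suitable for unit tests; :func:`null_study_config` and
    :func:`planted_study_config` return the larger fixed conditions used
    for the null-calibration and signal-recovery studies.

    ``intergenic_gap_range`` defaults to more than twice the default 10 kb
    flank so flanked regions of neighboring genes do not overlap and
    gene-level significance events are independent under the null.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length_bp: int = 3_500_000
    n_genes: int = 200
    gene_length_range: tuple[int, int] = (2_000, 5_000)
    intergenic_gap_range: tuple[int, int] = (21_000, 25_000)
    n_snps_per_chrom: int = 50_000
    n_samples: int = 100
    ld_block_size: int = 5
    within_block_r: float = 0.0
    maf_range: tuple[float, float] = (0.1, 0.5)
    flank_bp: int = 10_000
    gwas_keep_every: int = 1
    planted_genes: tuple[PlantedSignal, ...] = ()
    ancestry_label: str = "EUR"

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "chrom_length_bp", "n_genes", "n_snps_per_chrom",
                     "n_samples", "ld_block_size", "gwas_keep_every"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.within_block_r <= 1.0):
            raise ValueError("within_block_r must lie in [0, 1]")


def null_study_config(seed: int = 0) -> SyntheticConfig:
    """Conditions of the null-calibration study (binomial vs resampling).

    ~2,000 genes over four chromosomes, 10 kb flanks, ~48 bp mean SNP
    spacing so a flanked region holds roughly 500 summary SNPs. That count
    keeps every threshold in the evaluated 1e-2 .. 1e-5 range informative:
    the per-gene hit rate stays clearly below 1 at the loose end while the
    expected per-draw count stays above ~1 at the tight end, so neither
    null count distribution collapses to a constant.
    """
    return SyntheticConfig(
        seed=seed,
        n_chromosomes=4,
        chrom_length_bp=16_000_000,
        n_genes=2_000,
        n_snps_per_chrom=333_000,
    )


def planted_study_config(seed: int = 0) -> SyntheticConfig:
    """Conditions of the planted-signal recovery study.

    One 16 Mb chromosome with 500 genes; the reference panel averages one
    SNP per 400 bp while the GWAS summary file keeps every fourth panel
    site, emulating an array-based GWAS typed at a subset of the
    reference-panel variants.
    """
    return SyntheticConfig(
        seed=seed,
        n_chromosomes=1,
        chrom_length_bp=16_000_000,
        n_genes=500,
        intergenic_gap_range=(24_000, 28_000),
        n_snps_per_chrom=40_000,
        gwas_keep_every=4,
    )


@dataclass
class GeneCatalog:
    """refFlat lines plus the truth table of expected canonical spans."""

    refflat_lines: list[str]
    truth: pd.DataFrame  # gene_symbol, chromosome, strand, start, end, transcript_id

    def write_refflat(self, path: str | Path) -> None:
        Path(path).write_text("".join(self.refflat_lines))


def generate_gene_catalog(config: SyntheticConfig) -> GeneCatalog:
    """Pack non-overlapping genes onto toy chromosomes, 1-3 transcripts each.

    The first transcript of every gene spans the full gene and is strictly
    the longest, so the truth table is the exact expected output of
    canonical-transcript selection. Raises if the genes do not fit on the
    configured chromosomes.
    """
    rng = np.random.default_rng(config.seed)
    lines: list[str] = []
    truth_rows: list[dict] = []
    per_chrom = -(-config.n_genes // config.n_chromosomes)  # ceil
    gene_no = 0
    transcript_no = 0
    lo_len, hi_len = config.gene_length_range
    lo_gap, hi_gap = config.intergenic_gap_range
    for chrom_index in range(config.n_chromosomes):
        chrom = str(chrom_index + 1)
        cursor = config.flank_bp  # leave room so flanked regions stay on-chromosome
        for _ in range(per_chrom):
            if gene_no >= config.n_genes:
                break
            gap = int(rng.integers(lo_gap, hi_gap + 1))
            length = int(rng.integers(lo_len, hi_len + 1))
            start = cursor + gap
            end = start + length
            if end + config.flank_bp > config.chrom_length_bp:
                raise ValueError(
                    f"infeasible packing: gene {gene_no + 1} of {config.n_genes} exceeds "
                    f"chromosome length {config.chrom_length_bp}"
                )
            cursor = end
            gene_no += 1
            symbol = f"GENE{gene_no:05d}"
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            transcript_no += 1
            canonical_id = f"NM_{transcript_no:06d}"
            transcripts = [(canonical_id, start, end)]
            for _extra in range(int(rng.integers(0, 3))):
                transcript_no += 1
                # strictly shorter sub-span of the canonical transcript
                shrink = int(rng.integers(1, max(2, length // 3)))
                transcripts.append((f"NM_{transcript_no:06d}", start + shrink, end))
            for tid, ts, te in transcripts:
                lines.append(
                    f"{symbol}\t{tid}\tchr{chrom}\t{strand}\t{ts}\t{te}"
                    f"\t{ts}\t{te}\t1\t{ts},\t{te},\n"
                )
            truth_rows.append(
                {
                    "gene_symbol": symbol,
                    "chromosome": f"chr{chrom}",
                    "strand": strand,
                    "start": start,
                    "end": end,
                    "transcript_id": canonical_id,
                }
            )
    if gene_no < config.n_genes:
        raise ValueError("infeasible packing: not all genes placed")
    return GeneCatalog(refflat_lines=lines, truth=pd.DataFrame(truth_rows))


def _snp_positions(rng: np.random.Generator, n: int, chrom_length: int) -> np.ndarray:
    """n distinct uniform-random positions in [1, chrom_length], increasing."""
    if n > chrom_length:
        raise ValueError("more SNPs requested than available positions")
    oversample = min(chrom_length, int(n * 1.2) + 16)
    candidates = np.unique(rng.integers(1, chrom_length + 1, size=oversample))
    while candidates.size < n:
        extra = rng.integers(1, chrom_length + 1, size=oversample)
        candidates = np.unique(np.concatenate([candidates, extra]))
    chosen = rng.choice(candidates, size=n, replace=False)
    return np.sort(chosen)


def generate_ld_panel(config: SyntheticConfig, chromosome: str | int) -> GenotypePanel:
    """Reference genotypes with block-exchangeable LD for one chromosome.

    Each block of ``ld_block_size`` consecutive SNPs shares a latent
    haplotype of frequency drawn from ``maf_range``; individual SNPs flip
    away from it with probability (1 - sqrt(r))/2 so block-mates correlate
    at ~``within_block_r`` (exactly duplicated columns at r = 1). At r = 0
    SNPs are independent draws with their own frequency. Dosage = sum of
    two independent haplotypes per sample.
    """
    if config.n_samples < 2:
        raise ValueError("need at least 2 samples for a genotype panel")
    chrom = str(chromosome)
    seed_offset = int(chrom) if chrom.isdigit() else abs(hash(chrom)) % 1000
    rng = np.random.default_rng((config.seed, 1, seed_offset))
    n = config.n_snps_per_chrom
    positions = _snp_positions(rng, n, config.chrom_length_bp)
    snp_ids = [f"rs{chrom}_{i + 1}" for i in range(n)]

    n_blocks = -(-n // config.ld_block_size)
    lo_f, hi_f = config.maf_range
    dosage = np.empty((config.n_samples, n), dtype=np.float64)
    r = config.within_block_r
    flip = (1.0 - np.sqrt(r)) / 2.0 if r > 0 else None
    for b in range(n_blocks):
        s = b * config.ld_block_size
        e = min(s + config.ld_block_size, n)
        width = e - s
        if r > 0:
            f = rng.uniform(lo_f, hi_f)
            hap = rng.random((config.n_samples, 2)) < f  # two latent haplotypes
            alleles = np.empty((config.n_samples, 2, width))
            for h in range(2):
                flips = rng.random((config.n_samples, width)) < flip
                alleles[:, h, :] = hap[:, h][:, None] ^ flips
            dosage[:, s:e] = alleles.sum(axis=1)
        else:
            f = rng.uniform(lo_f, hi_f, size=width)
            dosage[:, s:e] = rng.binomial(2, f, size=(config.n_samples, width))
    return GenotypePanel(
        ancestry_label=config.ancestry_label,
        chromosome=chrom,
        positions=positions,
        snp_ids=snp_ids,
        dosages=dosage,
    )


def generate_ld_panels(config: SyntheticConfig) -> list[GenotypePanel]:
    return [generate_ld_panel(config, c + 1) for c in range(config.n_chromosomes)]


def generate_snp_positions(config: SyntheticConfig) -> dict[str, np.ndarray]:
    """SNP positions per chromosome, identical to the panel's, without
    materializing genotypes (used when only a summary file is needed)."""
    out: dict[str, np.ndarray] = {}
    for c in range(config.n_chromosomes):
        chrom = str(c + 1)
        rng = np.random.default_rng((config.seed, 1, c + 1))
        out[chrom] = _snp_positions(rng, config.n_snps_per_chrom, config.chrom_length_bp)
    return out


@dataclass
class GwasSummary:
    """A synthetic summary-statistics table plus its planted-signal truth."""

    frame: pd.DataFrame  # SNP, CHR, POS, P, BETA
    truth: pd.DataFrame  # gene_symbol, snp_id, chromosome, position, p_value

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            handle.write("SNP\tCHR\tPOS\tP\tBETA\n")
            for snp, chrom, pos, p, beta in self.frame.itertuples(index=False, name=None):
                handle.write(f"{snp}\t{chrom}\t{pos}\t{p:.17g}\t{beta:.6g}\n")


def generate_gwas_summary(
    catalog: GeneCatalog,
    positions_by_chrom: dict[str, np.ndarray],
    config: SyntheticConfig,
    snp_ids_by_chrom: dict[str, Sequence[str]] | None = None,
) -> GwasSummary:
    """Uniform-null GWAS summary rows with optional planted signals.

    One row per summary SNP (every ``gwas_keep_every``-th panel site) with
    p ~ Uniform(0, 1); for each planted gene, ``n_signals`` SNPs inside
    its flanked span are reassigned the planted p-value. A BETA column of
    small Gaussian effects is included as a pass-through payload. Raises
    if a planted gene has too few summary SNPs in its span.
    """
    rng = np.random.default_rng((config.seed, 2))
    truth = catalog.truth.set_index("gene_symbol")
    frames: list[pd.DataFrame] = []
    planted_rows: list[dict] = []
    planted_by_chrom: dict[str, list[PlantedSignal]] = {}
    for signal in config.planted_genes:
        if signal.gene_symbol not in truth.index:
            raise ValueError(f"planted gene {signal.gene_symbol} not in the catalog")
        chrom_key = str(truth.loc[signal.gene_symbol, "chromosome"])
        key = chrom_key[3:] if chrom_key.startswith("chr") else chrom_key
        planted_by_chrom.setdefault(key, []).append(signal)

    for chrom in sorted(positions_by_chrom, key=lambda c: (len(c), c)):
        panel_pos = np.asarray(positions_by_chrom[chrom])
        keep = np.arange(0, panel_pos.size, config.gwas_keep_every)
        pos = panel_pos[keep]
        if snp_ids_by_chrom is not None:
            ids = [snp_ids_by_chrom[chrom][i] for i in keep]
        else:
            ids = [f"rs{chrom}_{i + 1}" for i in keep]
        pvals = rng.uniform(0.0, 1.0, size=pos.size)
        betas = rng.normal(0.0, 0.05, size=pos.size)
        for signal in planted_by_chrom.get(chrom, []):
            gene = truth.loc[signal.gene_symbol]
            lo = max(0, int(gene["start"]) - config.flank_bp)
            hi = int(gene["end"]) + config.flank_bp
            inside = np.flatnonzero((pos > lo) & (pos <= hi))
            if inside.size < signal.n_signals:
                raise ValueError(
                    f"planted gene {signal.gene_symbol} has only {inside.size} summary "
                    f"SNP(s) in its flanked span; need {signal.n_signals} — use a larger "
                    "flank or denser SNPs"
                )
            chosen = rng.choice(inside, size=signal.n_signals, replace=False)
            pvals[chosen] = signal.p_value
            for c in sorted(chosen):
                planted_rows.append(
                    {
                        "gene_symbol": signal.gene_symbol,
                        "snp_id": ids[c],
                        "chromosome": chrom,
                        "position": int(pos[c]),
                        "p_value": signal.p_value,
                    }
                )
        frames.append(
            pd.DataFrame(
                {"SNP": ids, "CHR": chrom, "POS": pos, "P": pvals, "BETA": betas}
            )
        )
    frame = pd.concat(frames, ignore_index=True)
    truth_frame = pd.DataFrame(
        planted_rows, columns=["gene_symbol", "snp_id", "chromosome", "position", "p_value"]
    )
    return GwasSummary(frame=frame, truth=truth_frame)


def write_vcf(panels: Sequence[GenotypePanel], path: str | Path) -> None:
    """Write panels as one minimal VCF 4.2 file with unphased GT calls."""
    panels = list(panels)
    if not panels:
        raise ValueError("no panels to write")
    n_samples = panels[0].n_samples
    sample_names = [f"S{i + 1:04d}" for i in range(n_samples)]
    gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as handle:
        handle.write("##fileformat=VCFv4.2\n")
        handle.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for panel in panels:
            handle.write(f"##contig=<ID={panel.chromosome}>\n")
        handle.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names)
            + "\n"
        )
        for panel in panels:
            for j in range(panel.n_snps):
                calls = []
                for dose in panel.dosages[:, j]:
                    calls.append("./." if np.isnan(dose) else gt_code[float(dose)])
                handle.write(
                    f"{panel.chromosome}\t{panel.positions[j]}\t{panel.snp_ids[j]}"
                    f"\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
                )


@dataclass
class FixtureSet:
    """Paths of a written fixture directory."""

    refflat: Path
    vcf: Path
    gwas: Path
    gene_truth: Path
    planted_truth: Path
    candidate_list: Path | None = None


def generate_fixture_set(config: SyntheticConfig, out_dir: str | Path) -> FixtureSet:
    """Generate and write a complete self-contained fixture directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    catalog = generate_gene_catalog(config)
    panels = generate_ld_panels(config)
    summary = generate_gwas_summary(
        catalog,
        {p.chromosome: p.positions for p in panels},
        config,
        {p.chromosome: p.snp_ids for p in panels},
    )
    paths = FixtureSet(
        refflat=out_dir / "genes.refflat",
        vcf=out_dir / "panel.vcf",
        gwas=out_dir / "gwas.tsv",
        gene_truth=out_dir / "gene_truth.tsv",
        planted_truth=out_dir / "planted_truth.tsv",
    )
    catalog.write_refflat(paths.refflat)
    write_vcf(panels, paths.vcf)
    summary.write_tsv(paths.gwas)
    catalog.truth.to_csv(paths.gene_truth, sep="\t", index=False)
    summary.truth.to_csv(paths.planted_truth, sep="\t", index=False)
    if config.planted_genes:
        candidates = out_dir / "candidates.txt"
        candidates.write_text(
            "".join(f"{s.gene_symbol}\n" for s in config.planted_genes)
        )
        paths.candidate_list = candidates
    logger.info("fixture set written to %s", out_dir)
    return paths


def config_from_json(path: str | Path) -> SyntheticConfig:
    """Load a SyntheticConfig from a flat JSON file (CLI ``simulate``)."""
    data = json.loads(Path(path).read_text())
    if "planted_genes" in data:
        data["planted_genes"] = tuple(
            PlantedSignal(**entry) for entry in data["planted_genes"]
        )
    for key in ("gene_length_range", "intergenic_gap_range", "maf_range"):
        if key in data:
            data[key] = tuple(data[key])
    return SyntheticConfig(**data)
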