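"""Independent-SNP store: MAF filtering, windowed r² pruning, region counts.

The multiple-testing correction in this package divides the type-I error by
the number of *independent* common SNPs in the tested regions rather than
the raw SNP count. Independence is operationalized the way plink's
``--indep-pairwise 50 5 0.2 --maf 0.01`` does it: SNPs below a minor-allele
frequency floor are dropped, then a window of 50 SNPs slides in steps of 5
and, within each window, one member of every retained pair with squared
dosage correlation above 0.2 is greedily removed. The retained positions
are persisted chromosome-wise per ancestry panel and counted inside
arbitrary genomic regions.

The pruning here is a reimplementation, not a byte-for-byte plink clone:
plink's internal tie-handling is not published, so the removal rule is
fixed deterministically (drop the lower-MAF member of the currently worst
pair; on an MAF tie drop the position-later member). The guarantee that
matters downstream — no retained pair that ever shared a window exceeds
the r² threshold — holds by construction.
"""

from __future__ import annotations

import logging
import re
import sqlite3
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .gene_db import normalize_chromosome

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PruningConfig:
    """Window/step/r²/MAF settings of the pruning pass (plink-style units).

    ``window_size`` and ``step`` are SNP counts, not base pairs.
    """

    window_size: int = 50
    step: int = 5
    r2_threshold: float = 0.2
    maf_min: float = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.step <= self.window_size):
            raise ValueError("require 0 < step <= window_size")
        if not (0.0 <= self.r2_threshold <= 1.0):
            raise ValueError("r2_threshold must lie in [0, 1]")
        if not (0.0 <= self.maf_min <= 0.5):
            raise ValueError("maf_min must lie in [0, 0.5]")


@dataclass
class GenotypePanel:
    """Reference genotypes for one chromosome of one ancestry panel.

    ``dosages`` holds ALT-allele counts as floats with NaN for missing
    genotypes; rows are samples, columns are SNPs aligned with
    ``positions`` (1-based, strictly increasing) and ``snp_ids``.
    """

    ancestry_label: str
    chromosome: str
    positions: np.ndarray
    snp_ids: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples x SNPs matrix")
        n_snps = self.positions.shape[0]
        if self.dosages.shape[1] != n_snps or len(self.snp_ids) != n_snps:
            raise ValueError("positions, snp_ids and dosage columns must align")
        if n_snps > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("panel positions must be strictly increasing")

    @property
    def n_snps(self) -> int:
        return int(self.positions.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.dosages.shape[0])


def allele_frequency(dosage_column: Sequence[float] | np.ndarray) -> float:
    """Minor-allele frequency of one dosage column, ignoring missing entries.

    MAF = min(f, 1-f) with f = sum(dosages) / (2 * non-missing count).
    """
    column = np.asarray(dosage_column, dtype=np.float64)
    observed = ~np.isnan(column)
    n = int(observed.sum())
    if n == 0:
        raise ValueError("allele frequency undefined: all genotypes missing")
    f = float(column[observed].sum()) / (2.0 * n)
    return min(f, 1.0 - f)


def r2(col_a: Sequence[float] | np.ndarray, col_b: Sequence[float] | np.ndarray) -> float:
    """Squared Pearson correlation of two dosage columns.

    Computed over the pairwise-complete subset; returns 0.0 when either
    column is constant on that subset (no linkage information).
    """
    a = np.asarray(col_a, dtype=np.float64)
    b = np.asarray(col_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"dosage vectors differ in length: {a.shape} vs {b.shape}")
    observed = ~(np.isnan(a) | np.isnan(b))
    if int(observed.sum()) < 2:
        raise ValueError("need at least 2 pairwise-complete samples for r2")
    x = a[observed]
    y = b[observed]
    x = x - x.mean()
    y = y - y.mean()
    denom = float(np.sqrt((x * x).sum() * (y * y).sum()))
    if denom == 0.0:
        return 0.0
    r = float((x * y).sum()) / denom
    return min(r * r, 1.0)


def _maf_vector(dosages: np.ndarray) -> np.ndarray:
    """Per-column MAF; NaN for all-missing columns."""
    observed = ~np.isnan(dosages)
    counts = observed.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.nansum(dosages, axis=0) / (2.0 * counts)
    maf = np.minimum(f, 1.0 - f)
    maf[counts == 0] = np.nan
    return maf


def _pairwise_r2(columns: np.ndarray) -> np.ndarray:
    """Pairwise r² matrix of dosage columns (samples x k), diagonal zeroed."""
    if np.isnan(columns).any():
        k = columns.shape[1]
        matrix = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                matrix[i, j] = matrix[j, i] = r2(columns[:, i], columns[:, j])
        return matrix
    with np.errstate(invalid="ignore", divide="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            corr = np.corrcoef(columns, rowvar=False)
    corr = np.nan_to_num(np.atleast_2d(corr), nan=0.0)
    matrix = np.minimum(corr * corr, 1.0)
    np.fill_diagonal(matrix, 0.0)
    return matrix


def prune_chromosome(panel: GenotypePanel, config: PruningConfig | None = None) -> np.ndarray:
    """Greedy windowed LD pruning; returns retained SNP indices (increasing).

    Procedure: (1) drop SNPs with MAF below ``maf_min``; (2) slide a window
    of ``window_size`` surviving SNPs forward by ``step`` SNPs; within each
    window, while any retained pair has r² above ``r2_threshold``, remove
    one member of the currently worst (highest-r²) pair — the one with the
    lower MAF, or the position-later one on an MAF tie. A SNP removed in
    any window stays removed. In the final set no pair that ever shared a
    window exceeds the threshold.
    """
    config = config or PruningConfig()
    mafs = _maf_vector(panel.dosages)
    with np.errstate(invalid="ignore"):
        keep_mask = mafs >= config.maf_min
    if np.isnan(mafs).any():
        logger.warning("%d all-missing SNP column(s) dropped", int(np.isnan(mafs).sum()))
    kept = np.flatnonzero(keep_mask)
    if kept.size == 0:
        logger.warning(
            "no SNPs left after MAF >= %g filter on chromosome %s",
            config.maf_min,
            panel.chromosome,
        )
        return kept
    removed = np.zeros(kept.size, dtype=bool)

    n = kept.size
    for window_start in range(0, n, config.step):
        window = [
            j for j in range(window_start, min(window_start + config.window_size, n))
            if not removed[j]
        ]
        if len(window) >= 2:
            columns = panel.dosages[:, kept[window]]
            matrix = _pairwise_r2(columns)
            while True:
                flat = int(np.argmax(matrix))
                i, j = divmod(flat, matrix.shape[1])
                if matrix[i, j] <= config.r2_threshold:
                    break
                maf_i = mafs[kept[window[i]]]
                maf_j = mafs[kept[window[j]]]
                if maf_i < maf_j:
                    drop = i
                elif maf_j < maf_i:
                    drop = j
                else:
                    drop = max(i, j)  # MAF tie: drop the position-later member
                removed[window[drop]] = True
                matrix[drop, :] = 0.0
                matrix[:, drop] = 0.0
        if window_start + config.window_size >= n:
            break
    return kept[~removed]


_NAME_RE = re.compile(r"[^A-Za-z0-9]")


def _table_name(ancestry: str, chromosome: str) -> str:
    ancestry = _NAME_RE.sub("_", ancestry)
    chromosome = _NAME_RE.sub("_", normalize_chromosome(chromosome))
    return f"independent_{ancestry}_{chromosome}"


class PrunedSnpStore:
    """Per-(ancestry, chromosome) tables of retained independent SNPs.

    Stored in the same single-file SQLite dialect as the gene store, one
    table per chromosome (``independent_<ancestry>_<chrom>``) plus a
    ``panels`` header table recording counts and the pruning settings.
    Region queries are half-open on 1-based positions: start inclusive,
    end exclusive.
    """

    def __init__(self, path: str | Path, create: bool = False):
        self.path = Path(path)
        if not create and not self.path.exists():
            raise FileNotFoundError(f"independent-SNP store not found: {self.path}")
        self._conn = sqlite3.connect(str(self.path))
        if create:
            self._conn.execute(
                "CREATE TABLE IF NOT EXISTS panels ("
                " ancestry TEXT NOT NULL, chromosome TEXT NOT NULL,"
                " table_name TEXT NOT NULL, n_snps INTEGER NOT NULL,"
                " window_size INTEGER, step INTEGER, r2_threshold REAL, maf_min REAL,"
                " PRIMARY KEY (ancestry, chromosome))"
            )
            self._conn.commit()

    @classmethod
    def create(cls, path: str | Path) -> "PrunedSnpStore":
        return cls(path, create=True)

    def add_panel(
        self,
        ancestry: str,
        chromosome: str,
        positions: np.ndarray,
        snp_ids: Sequence[str],
        config: PruningConfig | None = None,
    ) -> None:
        """Insert (or replace) the retained SNPs of one chromosome."""
        positions = np.asarray(positions, dtype=np.int64)
        if positions.size > 1 and not np.all(np.diff(positions) > 0):
            raise ValueError("retained positions must be strictly increasing")
        chromosome = normalize_chromosome(chromosome)
        table = _table_name(ancestry, chromosome)
        self._conn.execute(f'DROP TABLE IF EXISTS "{table}"')
        self._conn.execute(
            f'CREATE TABLE "{table}" (position INTEGER PRIMARY KEY, snp_id TEXT NOT NULL)'
        )
        self._conn.executemany(
            f'INSERT INTO "{table}" VALUES (?, ?)',
            [(int(p), str(s)) for p, s in zip(positions, snp_ids)],
        )
        config = config or PruningConfig()
        self._conn.execute(
            "INSERT OR REPLACE INTO panels VALUES (?, ?, ?, ?, ?, ?, ?, ?)",
            (
                ancestry,
                chromosome,
                table,
                int(positions.size),
                config.window_size,
                config.step,
                config.r2_threshold,
                config.maf_min,
            ),
        )
        self._conn.commit()

    def ancestries(self) -> list[str]:
        rows = self._conn.execute("SELECT DISTINCT ancestry FROM panels ORDER BY ancestry")
        return [row[0] for row in rows]

    def chromosomes(self, ancestry: str) -> list[str]:
        rows = self._conn.execute(
            "SELECT chromosome FROM panels WHERE ancestry = ? ORDER BY chromosome", (ancestry,)
        )
        return [row[0] for row in rows]

    def _require_ancestry(self, ancestry: str) -> None:
        available = self.ancestries()
        if ancestry not in available:
            raise ValueError(
                f"unknown ancestry label {ancestry!r}; available: {', '.join(available) or 'none'}"
            )

    def count_independent(
        self, ancestry: str, chromosome: str, start_bp: int, end_bp: int
    ) -> int:
        """Number of retained positions q with start_bp <= q < end_bp."""
        if start_bp > end_bp:
            raise ValueError("start_bp must be <= end_bp")
        self._require_ancestry(ancestry)
        chromosome = normalize_chromosome(chromosome)
        table = _table_name(ancestry, chromosome)
        row = self._conn.execute(
            "SELECT table_name FROM panels WHERE ancestry = ? AND chromosome = ?",
            (ancestry, chromosome),
        ).fetchone()
        if row is None:
            return 0
        (count,) = self._conn.execute(
            f'SELECT COUNT(*) FROM "{table}" WHERE position >= ? AND position < ?',
            (int(start_bp), int(end_bp)),
        ).fetchone()
        return int(count)

    def chromosome_total(self, ancestry: str, chromosome: str) -> int:
        self._require_ancestry(ancestry)
        row = self._conn.execute(
            "SELECT n_snps FROM panels WHERE ancestry = ? AND chromosome = ?",
            (ancestry, normalize_chromosome(chromosome)),
        ).fetchone()
        return int(row[0]) if row else 0

    def positions(self, ancestry: str, chromosome: str) -> np.ndarray:
        self._require_ancestry(ancestry)
        table = _table_name(ancestry, chromosome)
        rows = self._conn.execute(f'SELECT position FROM "{table}" ORDER BY position')
        return np.asarray([row[0] for row in rows], dtype=np.int64)

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "PrunedSnpStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def count_independent(
    store: PrunedSnpStore, ancestry: str, chromosome: str, start_bp: int, end_bp: int
) -> int:
    """Module-level alias for :meth:`PrunedSnpStore.count_independent`."""
    return store.count_independent(ancestry, chromosome, start_bp, end_bp)


def build_snp_store(
    panels: Sequence[GenotypePanel],
    destination: str | Path,
    config: PruningConfig | None = None,
    append: bool = False,
) -> PrunedSnpStore:
    """Prune each panel chromosome-wise and persist the survivors."""
    config = config or PruningConfig()
    destination = Path(destination)
    if destination.exists() and not append:
        destination.unlink()
    store = PrunedSnpStore.create(destination)
    for panel in panels:
        retained = prune_chromosome(panel, config)
        store.add_panel(
            panel.ancestry_label,
            panel.chromosome,
            panel.positions[retained],
            [panel.snp_ids[i] for i in retained],
            config,
        )
        logger.info(
            "pruned %s chr%s: %d of %d SNPs retained",
            panel.ancestry_label,
            normalize_chromosome(panel.chromosome),
            retained.size,
            panel.n_snps,
        )
    return store


def read_vcf_panel(path: str | Path, ancestry_label: str) -> list[GenotypePanel]:
    """Load biallelic SNPs from a VCF into per-chromosome genotype panels.

    Uses the GT field; each genotype contributes its ALT-allele count
    (missing alleles give a missing dosage). Multiallelic records and
    duplicate positions are skipped with a warning.
    """
    import pysam

    data: dict[str, dict[str, list]] = {}
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for record in vcf:
            if record.alts is None or len(record.alts) != 1:
                n_skipped += 1
                continue
            chrom = record.chrom
            slot = data.setdefault(chrom, {"pos": [], "ids": [], "dos": []})
            if slot["pos"] and record.pos <= slot["pos"][-1]:
                logger.warning(
                    "VCF %s: non-increasing position %s:%d skipped", path, chrom, record.pos
                )
                n_skipped += 1
                continue
            dosages = []
            for sample in samples:
                alleles = record.samples[sample].get("GT")
                if alleles is None or any(a is None for a in alleles):
                    dosages.append(np.nan)
                else:
                    dosages.append(float(sum(1 for a in alleles if a != 0)))
            slot["pos"].append(record.pos)
            slot["ids"].append(record.id or f"{chrom}:{record.pos}")
            slot["dos"].append(dosages)
    if n_skipped:
        logger.warning("VCF %s: skipped %d record(s)", path, n_skipped)
    panels = []
    for chrom, slot in data.items():
        panels.append(
            GenotypePanel(
                ancestry_label=ancestry_label,
                chromosome=chrom,
                positions=np.asarray(slot["pos"], dtype=np.int64),
                snp_ids=list(slot["ids"]),
                dosages=np.asarray(slot["dos"], dtype=np.float64).T,
            )
        )
    return panels


def read_dosage_tsv(path: str | Path, ancestry_label: str, chromosome: str) -> GenotypePanel:
    """Load a plain dosage matrix (rows samples, columns ``id:pos`` headers)."""
    import pandas as pd

    frame = pd.read_csv(path, sep="\t")
    ids: list[str] = []
    positions: list[int] = []
    for column in frame.columns:
        snp_id, _, pos = str(column).rpartition(":")
        if not snp_id:
            raise ValueError(f"dosage header {column!r} is not of the form id:pos")
        ids.append(snp_id)
        positions.append(int(pos))
    dosages = frame.to_numpy(dtype=np.float64)
    return GenotypePanel(
        ancestry_label=ancestry_label,
        chromosome=chromosome,
        positions=np.asarray(positions, dtype=np.int64),
        snp_ids=ids,
        dosages=dosages,
    )
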