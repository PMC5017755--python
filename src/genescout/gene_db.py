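"""Gene-coordinate store built from refFlat annotation.

A refFlat dump (UCSC table format) lists one transcript per line. For
region-based GWAS mining we need exactly one genomic span per gene symbol,
so this module keeps the longest transcript of each gene, drops genes whose
transcripts map to more than one chromosome (ambiguous placement), and
persists the result in a single-file SQLite store. The store's size
(``total_genes``) later serves as the denominator of the enrichment
background rate.

Coordinates are kept in refFlat's native convention: 0-based start,
half-open end. Conversion to the 1-based positions used by GWAS summary
files happens at query time, never in the store.
"""

from __future__ import annotations

import gzip
import logging
import sqlite3
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

VALID_STRANDS = ("+", "-")


def normalize_chromosome(name: str) -> str:
    """Strip an optional ``chr`` prefix so ``chr7`` and ``7`` compare equal."""
    name = name.strip()
    if name.lower().startswith("chr"):
        return name[3:]
    return name


def is_gonosomal(chromosome: str) -> bool:
    """True for sex chromosomes (X/Y), which typical autosomal GWAS files omit."""
    return normalize_chromosome(chromosome).upper() in {"X", "Y"}


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript line of a refFlat file (0-based half-open span)."""

    gene_symbol: str
    transcript_id: str
    chromosome: str
    strand: str
    tx_start: int
    tx_end: int

    @property
    def span(self) -> int:
        return self.tx_end - self.tx_start


@dataclass(frozen=True)
class GeneModel:
    """The canonical (longest-transcript) genomic span of one gene."""

    gene_symbol: str
    chromosome: str
    strand: str
    start: int
    end: int
    transcript_id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_symbol}: start {self.start} must be < end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def parse_refflat(lines: Iterable[str]) -> list[TranscriptRecord]:
    """Parse refFlat-format lines into transcript records.

    Expects at least the first six tab-separated refFlat columns
    (geneName, name, chrom, strand, txStart, txEnd). Malformed lines —
    too few fields, non-integer coordinates, an invalid strand, or a
    non-positive span — are skipped with a logged warning rather than
    aborting the whole load.

    Raises
    ------
    ValueError
        If the input contains no lines at all (empty annotation source).
    """
    records: list[TranscriptRecord] = []
    saw_input = False
    n_skipped = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        saw_input = True
        fields = line.split("\t")
        if len(fields) < 6:
            logger.warning("refFlat line %d: fewer than 6 fields, skipped", lineno)
            n_skipped += 1
            continue
        gene_symbol, transcript_id, chromosome, strand = (f.strip() for f in fields[:4])
        try:
            tx_start = int(fields[4])
            tx_end = int(fields[5])
        except ValueError:
            logger.warning("refFlat line %d: non-integer coordinates, skipped", lineno)
            n_skipped += 1
            continue
        if strand not in VALID_STRANDS:
            logger.warning("refFlat line %d: invalid strand %r, skipped", lineno, strand)
            n_skipped += 1
            continue
        if not gene_symbol or not chromosome:
            logger.warning("refFlat line %d: empty gene symbol or chromosome, skipped", lineno)
            n_skipped += 1
            continue
        if tx_start >= tx_end:
            logger.warning(
                "refFlat line %d: txStart %d >= txEnd %d, skipped", lineno, tx_start, tx_end
            )
            n_skipped += 1
            continue
        records.append(
            TranscriptRecord(gene_symbol, transcript_id, chromosome, strand, tx_start, tx_end)
        )
    if not saw_input:
        raise ValueError("empty refFlat input: no lines to parse")
    if n_skipped:
        logger.warning("refFlat parsing skipped %d malformed line(s)", n_skipped)
    return records


def read_refflat(path: str | Path) -> list[TranscriptRecord]:
    """Read a refFlat file (plain text or gzip) into transcript records."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:  # type: ignore[operator]
        return parse_refflat(handle)


def select_canonical(
    transcripts: Sequence[TranscriptRecord],
) -> tuple[list[GeneModel], dict[str, str]]:
    """Collapse transcripts to one canonical span per gene symbol.

    Per symbol, the transcript with the largest span wins; span ties break
    on the lexicographically smallest transcript id so the store is
    reproducible. Genes whose transcripts fall on more than one chromosome
    are excluded entirely and listed in the returned exclusion report
    (symbol -> reason). Output order is first-occurrence order of symbols.
    """
    by_symbol: dict[str, list[TranscriptRecord]] = {}
    for record in transcripts:
        by_symbol.setdefault(record.gene_symbol, []).append(record)

    models: list[GeneModel] = []
    excluded: dict[str, str] = {}
    for symbol, group in by_symbol.items():
        chromosomes = {normalize_chromosome(t.chromosome) for t in group}
        if len(chromosomes) > 1:
            excluded[symbol] = "ambiguous: transcripts on chromosomes " + ",".join(
                sorted(chromosomes)
            )
            continue
        best = min(group, key=lambda t: (-t.span, t.transcript_id))
        models.append(
            GeneModel(
                gene_symbol=symbol,
                chromosome=best.chromosome,
                strand=best.strand,
                start=best.tx_start,
                end=best.tx_end,
                transcript_id=best.transcript_id,
            )
        )
    if excluded:
        logger.info("excluded %d gene(s) with ambiguous chromosome mapping", len(excluded))
    return models, excluded


_SCHEMA = """
CREATE TABLE genes (
    gene_symbol   TEXT PRIMARY KEY,
    chromosome    TEXT NOT NULL,
    strand        TEXT NOT NULL,
    start         INTEGER NOT NULL,
    end           INTEGER NOT NULL,
    transcript_id TEXT NOT NULL,
    length        INTEGER NOT NULL
);
"""


class GeneStore:
    """Persisted, symbol-indexed table of canonical gene spans.

    ``total_genes`` is the database size used as the denominator when
    estimating the background rate of significant genes.
    """

    def __init__(self, path: str | Path):
        self.path = Path(path)
        if not self.path.exists():
            raise FileNotFoundError(f"gene store not found: {self.path}")
        self._conn = sqlite3.connect(str(self.path))

    @property
    def total_genes(self) -> int:
        (count,) = self._conn.execute("SELECT COUNT(*) FROM genes").fetchone()
        return int(count)

    def lookup(self, symbol: str) -> GeneModel | None:
        row = self._conn.execute(
            "SELECT gene_symbol, chromosome, strand, start, end, transcript_id "
            "FROM genes WHERE gene_symbol = ?",
            (symbol,),
        ).fetchone()
        if row is None:
            return None
        return GeneModel(*row)

    def __contains__(self, symbol: str) -> bool:
        return self.lookup(symbol) is not None

    def __iter__(self) -> Iterator[GeneModel]:
        cursor = self._conn.execute(
            "SELECT gene_symbol, chromosome, strand, start, end, transcript_id "
            "FROM genes ORDER BY rowid"
        )
        for row in cursor:
            yield GeneModel(*row)

    def symbols(self) -> list[str]:
        return [row[0] for row in self._conn.execute("SELECT gene_symbol FROM genes ORDER BY rowid")]

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "GeneStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def build_gene_store(models: Sequence[GeneModel], destination: str | Path) -> GeneStore:
    """Persist gene models to ``destination``, replacing any existing store.

    Raises
    ------
    ValueError
        On an empty model list or a duplicated gene symbol (the offending
        symbol is named).
    """
    if not models:
        raise ValueError("cannot build a gene store from zero gene models")
    seen: set[str] = set()
    for model in models:
        if model.gene_symbol in seen:
            raise ValueError(f"duplicate gene symbol in input: {model.gene_symbol}")
        seen.add(model.gene_symbol)

    destination = Path(destination)
    conn = sqlite3.connect(str(destination))
    try:
        conn.execute("DROP TABLE IF EXISTS genes")
        conn.execute(_SCHEMA)
        conn.executemany(
            "INSERT INTO genes VALUES (?, ?, ?, ?, ?, ?, ?)",
            [
                (m.gene_symbol, m.chromosome, m.strand, m.start, m.end, m.transcript_id, m.length)
                for m in models
            ],
        )
        conn.commit()
    finally:
        conn.close()
    logger.info("gene store written to %s (%d genes)", destination, len(models))
    return GeneStore(destination)


def write_exclusion_report(excluded: dict[str, str], path: str | Path) -> None:
    """Write the plain-text exclusion report (symbol<TAB>reason per line)."""
    with open(path, "w") as handle:
        for symbol in sorted(excluded):
            handle.write(f"{symbol}\t{excluded[symbol]}\n")
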