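"""Reading and indexing GWAS summary-statistics files.

Summary files are delimited text (tab by default, gzip transparently
handled) with at least a SNP identifier, chromosome, 1-based position and
association p-value; every other column is carried through to the output
verbatim. Column locations are configured by name or 1-based index so
files from different consortia can be consumed without reformatting.

Two in-memory views are provided: a validated :class:`GwasTable` (pandas
frame plus skip/clamp bookkeeping) whose :meth:`~GwasTable.records` stream
feeds the region scanner, and a compact :class:`GwasIndex` (per-chromosome
sorted position/p-value arrays) used for the repeated region-minimum
queries of background-rate estimation and the resampling null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .gene_db import normalize_chromosome

logger = logging.getLogger(__name__)

MIN_PVALUE = float(np.nextafter(0.0, 1.0))


@dataclass(frozen=True)
class ColumnMap:
    """Where to find the four required columns (names or 1-based indices)."""

    snp_id: str | int = "SNP"
    chromosome: str | int = "CHR"
    position: str | int = "POS"
    p_value: str | int = "P"

    def resolve(self, columns: Sequence) -> dict[str, str]:
        resolved = {}
        for role in ("snp_id", "chromosome", "position", "p_value"):
            spec = getattr(self, role)
            if isinstance(spec, int):
                if not (1 <= spec <= len(columns)):
                    raise ValueError(f"column index {spec} for {role} out of range")
                resolved[role] = columns[spec - 1]
            else:
                if spec not in columns:
                    raise ValueError(
                        f"column {spec!r} for {role} not found; file has: {list(columns)}"
                    )
                resolved[role] = spec
        return resolved


@dataclass(frozen=True)
class GwasRecord:
    """One SNP row of a summary file (validated p in (0, 1])."""

    snp_id: str
    chromosome: str
    position: int
    p_value: float
    passthrough: tuple = ()


@dataclass
class GwasTable:
    """Validated summary rows plus parse bookkeeping.

    ``frame`` holds the standardized columns ``snp_id``, ``chromosome``,
    ``position``, ``p_value`` followed by the original pass-through
    columns; ``n_skipped`` counts rows dropped for unparseable position or
    p-value, ``n_clamped`` rows whose p of exactly 0 was clamped to the
    smallest positive float.
    """

    frame: pd.DataFrame
    passthrough_names: list[str] = field(default_factory=list)
    n_skipped: int = 0
    n_clamped: int = 0

    def __len__(self) -> int:
        return len(self.frame)

    def records(self) -> Iterator[GwasRecord]:
        if self.passthrough_names:
            passthrough = list(
                self.frame[self.passthrough_names].itertuples(index=False, name=None)
            )
        else:
            passthrough = [()] * len(self.frame)
        core = zip(
            self.frame["snp_id"].to_numpy(),
            self.frame["chromosome"].to_numpy(),
            self.frame["position"].to_numpy(),
            self.frame["p_value"].to_numpy(),
        )
        for (snp, chrom, pos, p), extra in zip(core, passthrough):
            yield GwasRecord(str(snp), str(chrom), int(pos), float(p), tuple(extra))

    def index(self) -> "GwasIndex":
        return GwasIndex.from_table(self)


def load_gwas(
    source: str | Path | pd.DataFrame,
    colmap: ColumnMap | None = None,
    sep: str | None = "\t",
) -> GwasTable:
    """Load and validate a GWAS summary file (or prebuilt DataFrame).

    Rows with unparseable position or p-value, p outside (0, 1], or
    position < 1 are skipped and counted; p-values of exactly 0 are clamped
    to the smallest positive float with a warning (they would otherwise be
    unreachable under any strict threshold).
    """
    colmap = colmap or ColumnMap()
    if isinstance(source, pd.DataFrame):
        raw = source.copy()
    else:
        raw = pd.read_csv(
            source,
            sep=sep,
            engine="python" if sep is None else "c",
            dtype=str,
        )
    if raw.empty and raw.columns.empty:
        raise ValueError("GWAS summary input is empty")
    resolved = colmap.resolve(list(raw.columns))
    passthrough_names = [c for c in raw.columns if c not in set(resolved.values())]

    frame = pd.DataFrame(
        {
            "snp_id": raw[resolved["snp_id"]].astype(str),
            "chromosome": raw[resolved["chromosome"]].astype(str),
            "position": pd.to_numeric(raw[resolved["position"]], errors="coerce"),
            "p_value": pd.to_numeric(raw[resolved["p_value"]], errors="coerce"),
        }
    )
    for name in passthrough_names:
        frame[name] = raw[name]

    valid = (
        frame["position"].notna()
        & frame["p_value"].notna()
        & (frame["position"] >= 1)
        & (frame["p_value"] >= 0)
        & (frame["p_value"] <= 1)
    )
    n_skipped = int((~valid).sum())
    if n_skipped:
        logger.warning("GWAS summary: skipped %d unparseable/invalid row(s)", n_skipped)
    frame = frame.loc[valid].copy()
    frame["position"] = frame["position"].astype(np.int64)

    zero = frame["p_value"] == 0.0
    n_clamped = int(zero.sum())
    if n_clamped:
        logger.warning(
            "GWAS summary: %d p-value(s) of exactly 0 clamped to %g", n_clamped, MIN_PVALUE
        )
        frame.loc[zero, "p_value"] = MIN_PVALUE
    frame = frame.reset_index(drop=True)
    return GwasTable(
        frame=frame,
        passthrough_names=passthrough_names,
        n_skipped=n_skipped,
        n_clamped=n_clamped,
    )


class GwasIndex:
    """Per-chromosome sorted (position, p-value) arrays for fast region queries.

    Chromosome keys are normalized (``chr`` prefix stripped). Region
    arguments use the gene store's 0-based half-open convention; a 1-based
    SNP position q falls in region [start, end) iff start < q <= end.
    """

    def __init__(self, arrays: Mapping[str, tuple[np.ndarray, np.ndarray]]):
        self._arrays: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (positions, pvalues) in arrays.items():
            positions = np.asarray(positions, dtype=np.int64)
            pvalues = np.asarray(pvalues, dtype=np.float64)
            order = np.argsort(positions, kind="stable")
            self._arrays[normalize_chromosome(chrom)] = (positions[order], pvalues[order])

    @classmethod
    def from_table(cls, table: GwasTable) -> "GwasIndex":
        arrays = {}
        for chrom, group in table.frame.groupby("chromosome", sort=False):
            key = normalize_chromosome(str(chrom))
            positions = group["position"].to_numpy(np.int64)
            pvalues = group["p_value"].to_numpy(np.float64)
            if key in arrays:
                positions = np.concatenate([arrays[key][0], positions])
                pvalues = np.concatenate([arrays[key][1], pvalues])
            arrays[key] = (positions, pvalues)
        return cls(arrays)

    @classmethod
    def from_records(cls, records: Iterable[GwasRecord]) -> "GwasIndex":
        buckets: dict[str, tuple[list, list]] = {}
        for record in records:
            pos, pv = buckets.setdefault(normalize_chromosome(record.chromosome), ([], []))
            pos.append(record.position)
            pv.append(record.p_value)
        return cls({c: (np.asarray(p), np.asarray(v)) for c, (p, v) in buckets.items()})

    def chromosomes(self) -> list[str]:
        return list(self._arrays)

    def _slice(self, chromosome: str, start: int, end: int) -> tuple[np.ndarray, np.ndarray]:
        key = normalize_chromosome(chromosome)
        if key not in self._arrays:
            empty = np.empty(0)
            return empty.astype(np.int64), empty
        positions, pvalues = self._arrays[key]
        lo = int(np.searchsorted(positions, start + 1, side="left"))
        hi = int(np.searchsorted(positions, end, side="right"))
        return positions[lo:hi], pvalues[lo:hi]

    def min_p(self, chromosome: str, start: int, end: int) -> float:
        """Smallest p-value at positions inside 0-based half-open [start, end).

        Returns ``inf`` when the region contains no SNPs.
        """
        _, pvalues = self._slice(chromosome, start, end)
        if pvalues.size == 0:
            return float("inf")
        return float(pvalues.min())

    def n_in(self, chromosome: str, start: int, end: int) -> int:
        positions, _ = self._slice(chromosome, start, end)
        return int(positions.size)

    def pvalues_in(self, chromosome: str, start: int, end: int) -> np.ndarray:
        _, pvalues = self._slice(chromosome, start, end)
        return pvalues
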