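"""Readers and writers for pool-seq count tables and study metadata.

The central exchange format is the popoolation-style *sync* table: one
TAB-separated line per genomic site with a ``A:T:C:G:N:del`` count column
per pool.  Pools are described by a sample sheet (TSV) mapping each pool to
an experimental treatment (``E`` = elevated polyandry, ``M`` = enforced
monogamy) and a replicate line.  Gene annotations travel as a BED-like TSV
with optional differential-expression flags and sex-bias fold changes.

Coordinates are 1-based inclusive throughout, matching the sync convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

NUCLEOTIDES = "ATCG"
#: order of the six count fields in a sync column
COUNT_ORDER = "ATCGN*"
MISSING = "."


class SchemaError(ValueError):
    """Input file does not match the expected schema."""


class ParseError(ValueError):
    """A field could not be parsed; the message names the offending line."""


@dataclass(frozen=True)
class PoolInfo:
    pool_id: str
    treatment: str  # "E" or "M"
    replicate: int
    pool_size: int  # diploid individuals in the pool


@dataclass
class SampleSheet:
    """Ordered collection of sequenced pools.

    Pool order here defines the column order of every sync table and count
    matrix downstream.
    """

    pools: list[PoolInfo]

    def __post_init__(self) -> None:
        ids = [p.pool_id for p in self.pools]
        if len(set(ids)) != len(ids):
            raise SchemaError("duplicate pool_id in sample sheet")
        for p in self.pools:
            if p.treatment not in ("E", "M"):
                raise SchemaError(f"unknown treatment code {p.treatment!r}")
            if p.replicate < 1:
                raise SchemaError(f"replicate must be >= 1, got {p.replicate}")
            if p.pool_size < 1:
                raise SchemaError(f"pool_size must be >= 1, got {p.pool_size}")

    @property
    def n_pools(self) -> int:
        return len(self.pools)

    @property
    def pool_ids(self) -> list[str]:
        return [p.pool_id for p in self.pools]

    @property
    def treatments(self) -> np.ndarray:
        return np.array([p.treatment for p in self.pools])

    @property
    def e_mask(self) -> np.ndarray:
        return self.treatments == "E"

    @property
    def m_mask(self) -> np.ndarray:
        return self.treatments == "M"

    @property
    def pool_sizes(self) -> np.ndarray:
        return np.array([p.pool_size for p in self.pools])

    def replicate_pairs(self) -> list[tuple[int, int]]:
        """(E index, M index) per replicate; raises unless fully paired."""
        self.validate_paired()
        pairs = {}
        for i, p in enumerate(self.pools):
            pairs.setdefault(p.replicate, {})[p.treatment] = i
        return [(d["E"], d["M"]) for r, d in sorted(pairs.items())]

    def validate_paired(self) -> None:
        seen: dict[int, list[str]] = {}
        for p in self.pools:
            seen.setdefault(p.replicate, []).append(p.treatment)
        for rep, treats in seen.items():
            if sorted(treats) != ["E", "M"]:
                raise SchemaError(
                    f"replicate {rep} is not an E/M pair (treatments {treats}); "
                    "paired analysis requires exactly one E and one M pool per replicate"
                )


@dataclass
class SyncSite:
    """Per-site nucleotide counts, one (A,T,C,G,N,del) sextet per pool."""

    chrom: str
    pos: int
    ref: str
    counts: np.ndarray  # shape (n_pools, 6), int

    def total_coverage(self) -> np.ndarray:
        """Per-pool A/T/C/G coverage (N and deletions excluded)."""
        return self.counts[:, :4].sum(axis=1)


@dataclass
class GeneInterval:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    is_de: bool = False
    log2fc_e: float | None = None
    log2fc_m: float | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise SchemaError(f"gene {self.gene_id}: start > end")


# ---------------------------------------------------------------------------
# sample sheet


def read_sample_sheet(path: str | Path, paired: bool = False) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype={"pool_id": str})
    required = {"pool_id", "treatment", "replicate", "pool_size"}
    if not required.issubset(df.columns):
        raise SchemaError(f"sample sheet missing columns {sorted(required - set(df.columns))}")
    pools = [
        PoolInfo(str(r.pool_id), str(r.treatment), int(r.replicate), int(r.pool_size))
        for r in df.itertuples()
    ]
    sheet = SampleSheet(pools)
    if paired:
        sheet.validate_paired()
    return sheet


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "pool_id": [p.pool_id for p in sheet.pools],
            "treatment": [p.treatment for p in sheet.pools],
            "replicate": [p.replicate for p in sheet.pools],
            "pool_size": [p.pool_size for p in sheet.pools],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sync


def _parse_count_field(field_: str, lineno: int) -> list[int]:
    parts = field_.split(":")
    if len(parts) != 6:
        raise ParseError(f"line {lineno}: count field {field_!r} does not have 6 values")
    try:
        vals = [int(x) for x in parts]
    except ValueError as exc:
        raise ParseError(f"line {lineno}: malformed count field {field_!r}") from exc
    if any(v < 0 for v in vals):
        raise ParseError(f"line {lineno}: negative count in {field_!r}")
    return vals


def read_sync(path: str | Path, sheet: SampleSheet) -> list[SyncSite]:
    """Parse a sync file; column order must match the sample sheet order."""
    n_pools = sheet.n_pools
    sites: list[SyncSite] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3 + n_pools:
                raise SchemaError(
                    f"line {lineno}: expected {3 + n_pools} columns "
                    f"({n_pools} pools), found {len(fields)}"
                )
            chrom, pos_s, ref = fields[:3]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: bad position {pos_s!r}") from exc
            counts = np.array(
                [_parse_count_field(f, lineno) for f in fields[3:]], dtype=np.int64
            )
            sites.append(SyncSite(chrom, pos, ref, counts))
    return sites


def write_sync(sites: Iterable[SyncSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            cols = [":".join(str(int(v)) for v in row) for row in s.counts]
            fh.write(f"{s.chrom}\t{s.pos}\t{s.ref}\t" + "\t".join(cols) + "\n")


def sync_to_arrays(sites: Sequence[SyncSite]) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stack sites into (chroms, positions, refs, counts[n_sites, n_pools, 6])."""
    chroms = np.array([s.chrom for s in sites], dtype=object)
    pos = np.array([s.pos for s in sites], dtype=np.int64)
    refs = np.array([s.ref for s in sites], dtype=object)
    if sites:
        counts = np.stack([s.counts for s in sites])
    else:
        counts = np.zeros((0, 0, 6), dtype=np.int64)
    return chroms, pos, refs, counts


# ---------------------------------------------------------------------------
# gene annotation


def read_gene_table(path: str | Path) -> list[GeneInterval]:
    df = pd.read_csv(path, sep="\t", na_values=[MISSING], dtype={"chrom": str})
    required = {"chrom", "start", "end", "gene_id"}
    if not required.issubset(df.columns):
        raise SchemaError(f"gene table missing columns {sorted(required - set(df.columns))}")
    genes = []
    ids = set()
    for r in df.itertuples():
        if r.gene_id in ids:
            raise SchemaError(f"duplicate gene_id {r.gene_id}")
        ids.add(r.gene_id)
        genes.append(
            GeneInterval(
                gene_id=str(r.gene_id),
                chrom=str(r.chrom),
                start=int(r.start),
                end=int(r.end),
                is_de=bool(getattr(r, "is_de", False)),
                log2fc_e=None if pd.isna(getattr(r, "log2fc_e", np.nan)) else float(r.log2fc_e),
                log2fc_m=None if pd.isna(getattr(r, "log2fc_m", np.nan)) else float(r.log2fc_m),
            )
        )
    return genes


def write_gene_table(genes: Sequence[GeneInterval], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "gene_id": [g.gene_id for g in genes],
            "is_de": [int(g.is_de) for g in genes],
            "log2fc_e": [g.log2fc_e for g in genes],
            "log2fc_m": [g.log2fc_m for g in genes],
        }
    )
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table: TSV, header, UTF-8, '.' for missing."""
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[MISSING])
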