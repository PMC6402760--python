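"""Reading, validating and writing UTR/CDS sequence catalogs.

A catalog is a set of sequence variants keyed by ``(gene, variant, species,
region)``.  FASTA headers follow the ``gene|variant|species`` convention (the
delimiter is configurable); the region (5' UTR, 3' UTR or CDS) is supplied by
the caller because catalogs are usually kept in region-specific files.
Sequences are stored as uppercase DNA; ``U`` is mapped to ``T`` on input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

__all__ = [
    "Region",
    "UtrRecord",
    "GeneCatalog",
    "CatalogError",
    "read_catalog_fasta",
    "write_catalog_fasta",
    "write_feature_table",
]

_VALID_BASES = frozenset("ACGTN")


class CatalogError(ValueError):
    """Raised for malformed catalogs: bad headers, duplicates, bad alphabets."""


class Region(str, Enum):
    """Which part of the transcript a record represents."""

    FIVE_PRIME = "five_prime"
    THREE_PRIME = "three_prime"
    CDS = "cds"

    @classmethod
    def parse(cls, value: "Region | str") -> "Region":
        if isinstance(value, Region):
            return value
        aliases = {
            "5utr": cls.FIVE_PRIME,
            "5'utr": cls.FIVE_PRIME,
            "five_prime": cls.FIVE_PRIME,
            "3utr": cls.THREE_PRIME,
            "3'utr": cls.THREE_PRIME,
            "three_prime": cls.THREE_PRIME,
            "cds": cls.CDS,
        }
        try:
            return aliases[str(value).lower()]
        except KeyError:
            raise CatalogError(f"unknown region {value!r}") from None


@dataclass(frozen=True)
class UtrRecord:
    """One UTR (or CDS) variant sequence.

    ``variant`` is the opaque letter suffix that distinguishes alternative
    forms of the same gene (e.g. ``"a"``, ``"b(2)"``); its internal structure
    is not interpreted.
    """

    gene: str
    variant: str
    species: str
    region: Region
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise CatalogError(
                f"empty sequence for {self.gene}|{self.variant}|{self.species}"
            )
        bad = [
            (i + 1, c) for i, c in enumerate(self.sequence) if c not in _VALID_BASES
        ]
        if bad:
            positions = ", ".join(f"{c!r}@{i}" for i, c in bad[:10])
            raise CatalogError(
                f"non-IUPAC characters in {self.key}: {positions}"
                + (" ..." if len(bad) > 10 else "")
            )
        if self.region is Region.CDS and len(self.sequence) % 3 != 0:
            warnings.warn(
                f"CDS {self.key} length {len(self.sequence)} not divisible by 3",
                stacklevel=2,
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def key(self) -> tuple[str, str, str, Region]:
        return (self.gene, self.variant, self.species, self.region)

    @property
    def label(self) -> str:
        return f"{self.gene}|{self.variant}|{self.species}"


def _clean_sequence(raw: str) -> str:
    return str(raw).upper().replace("U", "T")


def make_record(
    header: str, sequence: str, region: Region | str, delimiter: str = "|"
) -> UtrRecord:
    """Build a :class:`UtrRecord` from a FASTA header and raw sequence."""
    parts = header.strip().split(delimiter)
    if len(parts) != 3 or not all(parts):
        raise CatalogError(
            f"malformed header {header!r}: expected "
            f"'gene{delimiter}variant{delimiter}species'"
        )
    gene, variant, species = (p.strip() for p in parts)
    return UtrRecord(gene, variant, species, Region.parse(region), _clean_sequence(sequence))


@dataclass
class GeneCatalog:
    """A collection of :class:`UtrRecord` with unique keys.

    ``background`` optionally holds a comparison set (e.g. a random UTR sample
    drawn from a general UTR database) used for composition baselines.
    """

    records: list[UtrRecord] = field(default_factory=list)
    background: list[UtrRecord] | None = None
    _index: dict[tuple, UtrRecord] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.key in self._index:
                raise CatalogError(f"duplicate record key {rec.label} ({rec.region.value})")
            self._index[rec.key] = rec

    def add(self, record: UtrRecord) -> None:
        if record.key in self._index:
            raise CatalogError(f"duplicate record key {record.label} ({record.region.value})")
        self.records.append(record)
        self._index[record.key] = record

    def lookup(
        self, gene: str, variant: str, species: str, region: Region | str
    ) -> UtrRecord | None:
        return self._index.get((gene, variant, species, Region.parse(region)))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def read_catalog_fasta(
    path: str | Path, region: Region | str, delimiter: str = "|"
) -> GeneCatalog:
    """Read a region-specific FASTA file into a :class:`GeneCatalog`.

    Headers must be ``gene|variant|species``.  Sequences are uppercased and
    ``U`` is mapped to ``T``.  Duplicate keys, malformed headers, non-IUPAC
    characters and empty files are all rejected.
    """
    path = Path(path)
    if not path.exists():
        raise CatalogError(f"no such file: {path}")
    region = Region.parse(region)
    catalog = GeneCatalog()
    n = 0
    for seq_record in SeqIO.parse(str(path), "fasta"):
        n += 1
        catalog.add(make_record(seq_record.description, str(seq_record.seq), region, delimiter))
    if n == 0:
        raise CatalogError(f"no FASTA records in {path}")
    return catalog


def write_catalog_fasta(
    catalog: GeneCatalog, path: str | Path, delimiter: str = "|", width: int = 60
) -> None:
    """Write a catalog back to FASTA with ``gene|variant|species`` headers."""
    with open(path, "w") as handle:
        for rec in catalog:
            handle.write(f">{delimiter.join((rec.gene, rec.variant, rec.species))}\n")
            for i in range(0, rec.length, width):
                handle.write(rec.sequence[i : i + width] + "\n")


_SORT_KEYS = ("gene", "variant", "species")


def write_feature_table(
    rows: Iterable[Mapping], path: str | Path, float_decimals: int = 2
) -> pd.DataFrame:
    """Write per-record feature rows as a deterministic TSV.

    All rows must share one column schema.  Floats are printed with
    ``float_decimals`` decimals; rows are ordered by (gene, variant, species)
    when those columns exist, so output bytes do not depend on input order.
    Returns the (sorted) DataFrame for convenience.
    """
    rows = list(rows)
    if rows:
        schema = list(rows[0].keys())
        for i, row in enumerate(rows):
            if list(row.keys()) != schema:
                raise CatalogError(
                    f"row {i} columns {list(row.keys())} differ from schema {schema}"
                )
        frame = pd.DataFrame(rows, columns=schema)
    else:
        frame = pd.DataFrame()
    sort_cols = [c for c in _SORT_KEYS if c in frame.columns]
    if sort_cols:
        frame = frame.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    frame.to_csv(path, sep="\t", index=False, float_format=f"%.{float_decimals}f")
    return frame
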