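"""Polyadenylation-signal (PAS) detection, typing and efficiency classes.

The canonical PAS hexamer is AAUAAA ("C"); AUUAAA is the common non-canonical
signal ("NC"); rarer single-base variants of AAUAAA form the "NC*" class
(default set below, configurable).  Cleavage efficiency is predicted from the
distance between the hexamer start and the annotated 3' end: signals whose
hexamer begins 10-45 nt upstream of the end are productively positioned —
canonical ones are called very efficient (VE), others efficient (E) — while
signals outside that window are low-efficiency (LE).  Non-LE signals also
nominate alternative cleavage positions ~20 nt downstream of the hexamer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Sequence

__all__ = [
    "PasType",
    "PasEfficiency",
    "PasSite",
    "DEFAULT_VARIANT_HEXAMERS",
    "scan_pas",
    "classify_pas_efficiency",
    "annotate_pas",
    "infer_alternative_ends",
]

CANONICAL = "AATAAA"
NON_CANONICAL = "ATTAAA"

# Rare single-base AAUAAA variants (Beaudoing-style catalog), DNA alphabet.
DEFAULT_VARIANT_HEXAMERS: tuple[str, ...] = (
    "TATAAA",
    "AGTAAA",
    "AAGAAA",
    "AATATA",
    "AATACA",
    "CATAAA",
    "GATAAA",
    "AATGAA",
    "TTTAAA",
    "ACTAAA",
    "AATAGA",
)

DEFAULT_WINDOW = (10, 45)  # nt from hexamer start to 3' end, inclusive


class PasType(str, Enum):
    C = "C"  # canonical AAUAAA
    NC = "NC"  # non-canonical AUUAAA
    NC_STAR = "NC*"  # rarer variants


class PasEfficiency(str, Enum):
    VE = "VE"
    E = "E"
    LE = "LE"


@dataclass(frozen=True)
class PasSite:
    """A PAS hexamer occurrence; ``position`` is the 1-based hexamer start."""

    position: int
    hexamer: str
    pas_type: PasType
    distance_to_end: int | None = None
    efficiency: PasEfficiency | None = None


def scan_pas(
    utr3: str, variant_set: Sequence[str] = DEFAULT_VARIANT_HEXAMERS
) -> list[PasSite]:
    """All sense-strand PAS hexamer occurrences in ascending position order.

    Overlapping occurrences are all reported.  Canonical and non-canonical
    hexamers are always searched; ``variant_set`` configures the NC* class.
    """
    seq = utr3.upper()
    if len(seq) < 6:
        raise ValueError("3' UTR shorter than a hexamer")
    types = {CANONICAL: PasType.C, NON_CANONICAL: PasType.NC}
    for hexamer in variant_set:
        types.setdefault(hexamer.upper().replace("U", "T"), PasType.NC_STAR)
    sites = []
    for i in range(len(seq) - 5):
        word = seq[i : i + 6]
        if word in types:
            sites.append(PasSite(position=i + 1, hexamer=word, pas_type=types[word]))
    return sites


def classify_pas_efficiency(
    site: PasSite,
    utr_length: int,
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> PasEfficiency:
    """VE/E/LE from the hexamer-start-to-3'-end distance.

    Within ``window`` (inclusive): canonical -> VE, any other type -> E;
    outside: LE.
    """
    lo, hi = window
    if not lo < hi:
        raise ValueError("window must satisfy min < max")
    distance = utr_length - site.position
    if lo <= distance <= hi:
        return PasEfficiency.VE if site.pas_type is PasType.C else PasEfficiency.E
    return PasEfficiency.LE


def annotate_pas(
    utr3: str,
    variant_set: Sequence[str] = DEFAULT_VARIANT_HEXAMERS,
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> list[PasSite]:
    """Scan a 3' UTR and fill in distance and efficiency for every site."""
    length = len(utr3)
    return [
        replace(
            s,
            distance_to_end=length - s.position,
            efficiency=classify_pas_efficiency(s, length, window),
        )
        for s in scan_pas(utr3, variant_set)
    ]


def infer_alternative_ends(
    sites: Iterable[PasSite], utr_length: int, offset: int = 20
) -> list[int]:
    """Candidate alternative 3'-end coordinates implied by non-LE signals.

    Each usable (VE or E) signal nominates a cleavage position ``offset`` nt
    after the hexamer end, capped at the UTR end; duplicates are collapsed.
    """
    ends = {
        min(s.position + 5 + offset, utr_length)
        for s in sites
        if s.efficiency in (PasEfficiency.VE, PasEfficiency.E)
    }
    return sorted(ends)
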