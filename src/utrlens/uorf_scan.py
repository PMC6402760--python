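"""Upstream AUG / upstream ORF detection and translation-efficiency classes.

A uAUG is any ATG in the 5' UTR; a uORF is a uAUG followed in frame by a stop
codon within the UTR (optionally, ORFs running into the CDS can be kept and
flagged).  Two per-uORF annotations drive the repressiveness prediction:

* initiation context — the bases at −3 (purine favoured) and +4 (G favoured)
  around the AUG, the two most informative Kozak positions;
* cap distance — uORFs starting > 19 nt from the 5' cap are efficiently
  recognised by the scanning ribosome ("optimal"), < 12 nt poorly ("weak"),
  with 12–19 nt an intermediate band.

A simple surrogate decision rule maps a whole-UTR profile to translation
class I (low translation) or III (efficient translation).  The rule is a
deterministic, documented stand-in for the published regression-tree
classifier, whose internal splits were never published: a 5' UTR is class III
iff it has no uORF, is at most ``max_len`` nt long and is not strongly
structured (MFE per nt above a threshold, when structure data is supplied).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ContextClass",
    "DistanceClass",
    "UpstreamOrf",
    "TranslationProfile",
    "TranslationThresholds",
    "find_uaugs",
    "extract_uorfs",
    "classify_uorf",
    "build_profile",
    "assign_translation_class",
    "efficiency_string",
    "context_string",
    "cap_distance_histogram",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class ContextClass(str, Enum):
    OPTIMAL = "optimal"  # -3 in {A,G} and +4 == G
    ADEQUATE = "adequate"  # exactly one of the two holds
    WEAK = "weak"


class DistanceClass(str, Enum):
    OPTIMAL = "optimal"  # cap distance > 19 nt
    INTERMEDIATE = "intermediate"  # 12-19 nt
    WEAK = "weak"  # < 12 nt


@dataclass(frozen=True)
class UpstreamOrf:
    """One upstream ORF.  Coordinates are 1-based inclusive within the UTR."""

    start: int  # position of the A of ATG
    stop_end: int | None  # last base of the stop codon; None if ORF overlaps CDS
    peptide_length: int  # codons excluding the stop (incl. the AUG codon)
    context_minus3: str | None = None
    context_plus4: str | None = None
    context_class: ContextClass | None = None
    distance_class: DistanceClass | None = None
    overlaps_cds: bool = False

    @property
    def cap_distance(self) -> int:
        """Nucleotides between the 5' cap and the A of the AUG."""
        return self.start - 1

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError("uORF start must be >= 1")
        if self.stop_end is not None and (self.stop_end - self.start + 1) % 3 != 0:
            raise ValueError("uORF span not a whole number of codons")


def find_uaugs(utr5: str) -> list[int]:
    """All 1-based positions of ATG in ``utr5``, any frame, overlaps allowed."""
    seq = utr5.upper()
    return [i + 1 for i in range(len(seq) - 2) if seq[i : i + 3] == "ATG"]


def extract_uorfs(
    utr5: str, min_codons: int = 1, require_stop_in_utr: bool = True
) -> list[UpstreamOrf]:
    """Walk each uAUG's frame to its first in-frame stop within the UTR.

    Emits a uORF per uAUG whose stop lies inside the UTR; with
    ``require_stop_in_utr`` off, ORFs that run into the CDS are also emitted
    with ``overlaps_cds=True`` (their peptide length counts the complete
    codons that fit in the UTR).  ``min_codons`` filters on peptide length
    (codons excluding the stop; 1 = AUG immediately followed by a stop).
    """
    if min_codons < 1:
        raise ValueError("min_codons must be >= 1")
    seq = utr5.upper()
    out: list[UpstreamOrf] = []
    for start in find_uaugs(seq):
        stop_end = None
        i = start - 1 + 3
        while i + 3 <= len(seq):
            if seq[i : i + 3] in STOP_CODONS:
                stop_end = i + 3  # 1-based end of stop codon
                break
            i += 3
        if stop_end is not None:
            peptide = (stop_end - (start - 1) - 3) // 3
            if peptide >= min_codons:
                out.append(UpstreamOrf(start, stop_end, peptide))
        elif not require_stop_in_utr:
            peptide = (len(seq) - (start - 1)) // 3
            if peptide >= min_codons:
                out.append(UpstreamOrf(start, None, peptide, overlaps_cds=True))
    return out


def classify_uorf(uorf: UpstreamOrf, utr5: str) -> UpstreamOrf:
    """Annotate a uORF with its initiation-context and cap-distance classes.

    Context: optimal when the −3 base is a purine AND the +4 base is G;
    adequate when exactly one holds; weak otherwise.  A −3 or +4 position that
    falls outside the UTR counts as not satisfying its condition.
    """
    seq = utr5.upper()
    if not 1 <= uorf.start <= len(seq) - 2:
        raise ValueError(f"uORF start {uorf.start} outside UTR of length {len(seq)}")
    minus3 = seq[uorf.start - 4] if uorf.start >= 4 else None
    plus4 = seq[uorf.start + 2] if uorf.start + 2 < len(seq) else None
    good_minus3 = minus3 in ("A", "G")
    good_plus4 = plus4 == "G"
    if good_minus3 and good_plus4:
        context = ContextClass.OPTIMAL
    elif good_minus3 or good_plus4:
        context = ContextClass.ADEQUATE
    else:
        context = ContextClass.WEAK
    d = uorf.cap_distance
    if d > 19:
        distance = DistanceClass.OPTIMAL
    elif d < 12:
        distance = DistanceClass.WEAK
    else:
        distance = DistanceClass.INTERMEDIATE
    return replace(
        uorf,
        context_minus3=minus3,
        context_plus4=plus4,
        context_class=context,
        distance_class=distance,
    )


@dataclass
class TranslationProfile:
    """Whole-5'-UTR uORF profile plus optional structure information."""

    n_uaug: int
    n_uorf: int
    uorfs: list[UpstreamOrf] = field(default_factory=list)
    cart_class: str | None = None  # "I" or "III"
    mfe_per_nt: float | None = None  # kcal/mol/nt, from structure_shapes

    def __post_init__(self) -> None:
        if self.n_uorf > self.n_uaug:
            raise ValueError("n_uorf cannot exceed n_uaug")


def build_profile(
    utr5: str,
    min_codons: int = 1,
    require_stop_in_utr: bool = True,
    mfe_per_nt: float | None = None,
) -> TranslationProfile:
    """Scan a 5' UTR and return its classified uORF profile."""
    uorfs = [
        classify_uorf(u, utr5)
        for u in extract_uorfs(utr5, min_codons, require_stop_in_utr)
    ]
    return TranslationProfile(
        n_uaug=len(find_uaugs(utr5)),
        n_uorf=len(uorfs),
        uorfs=uorfs,
        mfe_per_nt=mfe_per_nt,
    )


@dataclass(frozen=True)
class TranslationThresholds:
    """Tunable thresholds of the surrogate translation-class rule."""

    max_len: int = 100  # nt; longer leaders score as low-translation
    min_mfe_per_nt: float = -0.45  # kcal/mol/nt; more negative = structured


def assign_translation_class(
    profile: TranslationProfile,
    length: int,
    gc_percent: float | None = None,
    thresholds: TranslationThresholds = TranslationThresholds(),
) -> str:
    """Class III (efficient) iff uORF-free, short and not strongly structured.

    ``gc_percent`` is accepted for interface symmetry but the default rule
    does not split on it.  Returns "I" or "III".
    """
    efficient = (
        profile.n_uorf == 0
        and length <= thresholds.max_len
        and (profile.mfe_per_nt is None or profile.mfe_per_nt >= thresholds.min_mfe_per_nt)
    )
    return "III" if efficient else "I"


def _two_letter(cls: ContextClass | DistanceClass | None) -> str:
    # intermediate distance / adequate context collapse to "O" in the
    # two-letter reporting scheme; only outright weak prints as "W"
    return "W" if cls in (ContextClass.WEAK, DistanceClass.WEAK) else "O"


def _counted_string(letters: Iterable[str]) -> str:
    letters = list(letters)
    parts = []
    for letter in ("O", "W"):
        k = letters.count(letter)
        if k:
            parts.append(f"{letter}{k}")
    return "/".join(parts)


def efficiency_string(uorfs: Sequence[UpstreamOrf]) -> str:
    """Cap-distance summary like ``"O2/W1"`` over a UTR's classified uORFs."""
    return _counted_string(_two_letter(u.distance_class) for u in uorfs)


def context_string(uorfs: Sequence[UpstreamOrf]) -> str:
    """Initiation-context summary like ``"O1/W2"``."""
    return _counted_string(_two_letter(u.context_class) for u in uorfs)


def cap_distance_histogram(
    profiles: Iterable[TranslationProfile], bin_width: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of uORF cap distances pooled over profiles.

    Returns ``(counts, bin_edges)`` with bins ``[0, w), [w, 2w), ...`` covering
    every observed distance; total count equals the total number of uORFs.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    distances = [u.cap_distance for p in profiles for u in p.uorfs]
    top = max(distances, default=0) // bin_width + 1
    edges = np.arange(0, (top + 1) * bin_width, bin_width)
    counts, _ = np.histogram(distances, bins=edges)
    return counts, edges
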