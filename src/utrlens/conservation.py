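"""Conservation statistics: pairwise identity, codon-partitioned identity,
identity matrices, homology calls and Nei-Gojobori (1986) Ka/Ks.

Percent identity comes from global (Needleman-Wunsch) alignment with free end
gaps (match +1, mismatch -1, gap open -10, gap extend -0.5 by default) and is
computed over alignment columns excluding terminal-gap overhangs, since UTR
variants frequently differ at their ends.  A pair is called homologous when
identity meets a threshold (default 60%, inclusive) — the conventional cutoff
for human/mouse orthologous non-coding sequence, comparable to third-codon-
position conservation of orthologous CDSs.

Ka/Ks follows the unweighted-pathway method of Nei & Gojobori: each codon
contributes synonymous/nonsynonymous *site* counts (the per-position fraction
of one-step mutations that are synonymous, averaged over the two sequences),
codon pairs differing at several positions average their substitution counts
over all shortest mutational pathways (pathways through stop codons are
excluded), and the Jukes-Cantor correction d = -3/4 ln(1 - 4p/3) maps
proportions to distances.  Ka/Ks > 1 indicates positive selection on the
encoded peptide; the ratio is flagged undefined when Ks is 0 or a proportion
saturates (p >= 3/4).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "AlignmentScoring",
    "IdentityMatrix",
    "KaKsResult",
    "pairwise_identity",
    "aligned_identity",
    "codon_partition_identity",
    "distance_matrix",
    "homology_call",
    "kaks_ng86",
    "jukes_cantor",
]

_CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TO_AA[_stop] = "*"
_BASES = "ACGT"


@dataclass(frozen=True)
class AlignmentScoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -10.0
    gap_extend: float = -0.5

    def build_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = self.match
        aligner.mismatch_score = self.mismatch
        aligner.open_gap_score = self.gap_open
        aligner.extend_gap_score = self.gap_extend
        # free end gaps: UTR variants differ in length at their termini
        try:
            aligner.end_insertion_score = 0.0
            aligner.end_deletion_score = 0.0
        except AttributeError:  # older Biopython spelling
            aligner.target_end_gap_score = 0.0
            aligner.query_end_gap_score = 0.0
        return aligner


def _terminal_mask(row: str) -> np.ndarray:
    """Boolean mask of columns inside the leading/trailing gap run of a row."""
    arr = np.frombuffer(row.encode(), dtype="S1")
    non_gap = np.flatnonzero(arr != b"-")
    mask = np.ones(len(row), dtype=bool)
    if non_gap.size:
        mask[non_gap[0] : non_gap[-1] + 1] = False
    return mask


def aligned_identity(row_a: str, row_b: str) -> float:
    """Percent identity of two already-aligned rows.

    Columns lying in a terminal-gap overhang of either row are excluded from
    the denominator; internal gaps count as differences.
    """
    if len(row_a) != len(row_b):
        raise ValueError("aligned rows differ in length")
    keep = ~(_terminal_mask(row_a) | _terminal_mask(row_b))
    a = np.frombuffer(row_a.upper().encode(), dtype="S1")[keep]
    b = np.frombuffer(row_b.upper().encode(), dtype="S1")[keep]
    if a.size == 0:
        # fully staggered alignment: no alignable region at all
        return 0.0
    matches = int(np.sum((a == b) & (a != b"-")))
    return 100.0 * matches / a.size


def pairwise_identity(
    a: str, b: str, scoring: AlignmentScoring = AlignmentScoring()
) -> float:
    """Percent identity from a global pairwise alignment of two sequences."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = scoring.build_aligner()
    alignment = aligner.align(a.upper(), b.upper())[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    return aligned_identity(row_a, row_b)


def codon_partition_identity(cds_a: str, cds_b: str) -> tuple[float, float]:
    """(identity over codon positions 1+2, identity over position 3), percent.

    Expects two equal-length, in-frame aligned coding sequences; codon columns
    containing a gap or N in either sequence are excluded pairwise.
    """
    a, b = cds_a.upper(), cds_b.upper()
    if len(a) != len(b):
        raise ValueError("aligned CDSs differ in length")
    if len(a) % 3 != 0:
        raise ValueError(f"aligned length {len(a)} not divisible by 3 (frame mismatch)")
    m12 = n12 = m3 = n3 = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if any(c not in _BASES for c in ca + cb):
            continue
        for k in range(2):
            n12 += 1
            m12 += ca[k] == cb[k]
        n3 += 1
        m3 += ca[2] == cb[2]
    if n12 == 0:
        raise ValueError("no comparable codons")
    return 100.0 * m12 / n12, 100.0 * m3 / n3


@dataclass(frozen=True)
class IdentityMatrix:
    labels: tuple[str, ...]
    values: np.ndarray  # percent identity, symmetric, diagonal 100
    method: str  # "pairwise_global" | "msa_columns"

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])


def distance_matrix(
    sequences: Mapping[str, str] | Sequence[tuple[str, str]],
    mode: str = "pairwise_global",
    scoring: AlignmentScoring = AlignmentScoring(),
) -> IdentityMatrix:
    """All pairwise percent identities over a labeled sequence set.

    ``mode="pairwise_global"`` aligns each pair; ``mode="msa_columns"``
    expects pre-aligned rows of equal length and compares columns directly.
    Label order is preserved from the input.
    """
    items = list(sequences.items()) if isinstance(sequences, Mapping) else list(sequences)
    if len(items) < 2:
        raise ValueError("need at least 2 sequences")
    labels = tuple(k for k, _ in items)
    seqs = [v for _, v in items]
    if mode not in ("pairwise_global", "msa_columns"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "msa_columns" and len({len(s) for s in seqs}) != 1:
        raise ValueError("msa_columns mode requires equal-length aligned rows")
    n = len(seqs)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            if mode == "msa_columns":
                ident = aligned_identity(seqs[i], seqs[j])
            else:
                ident = pairwise_identity(seqs[i], seqs[j], scoring)
            values[i, j] = values[j, i] = ident
    return IdentityMatrix(labels=labels, values=values, method=mode)


def homology_call(identity: float, threshold: float = 60.0) -> bool:
    """True when identity meets the threshold (inclusive)."""
    if not 0 <= identity <= 100:
        raise ValueError("identity must be a percent in [0, 100]")
    return identity >= threshold


def jukes_cantor(p: float) -> float:
    """JC69 distance for a proportion of observed differences; NaN at p >= 3/4."""
    if p < 0:
        raise ValueError("proportion cannot be negative")
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def _syn_fraction(codon: str, position: int) -> float:
    """Fraction of the 3 one-step changes at ``position`` that are synonymous.

    Changes creating a stop codon are excluded from the denominator (and a
    stop-free denominator of zero contributes zero synonymous sites, i.e. the
    position counts as fully nonsynonymous), following the SNAP convention.
    """
    aa = _CODON_TO_AA[codon]
    syn = total = 0
    for base in _BASES:
        if base == codon[position]:
            continue
        alt = codon[:position] + base + codon[position + 1 :]
        if _CODON_TO_AA[alt] == "*":
            continue
        total += 1
        syn += _CODON_TO_AA[alt] == aa
    return syn / total if total else 0.0


def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon; they sum to 3."""
    s = sum(_syn_fraction(codon, k) for k in range(3))
    return s, 3.0 - s


def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(syn, nonsyn) substitution counts averaged over shortest pathways.

    Pathways passing through a stop codon are discarded; if every pathway is
    blocked, all pathways are used (degenerate but defined).
    """
    diff = [k for k in range(3) if codon_a[k] != codon_b[k]]
    if not diff:
        return 0.0, 0.0
    pathway_scores = []
    blocked_scores = []
    for order in itertools.permutations(diff):
        current = codon_a
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if _CODON_TO_AA[nxt] == "*":
                blocked = True
            if _CODON_TO_AA[nxt] == _CODON_TO_AA[current]:
                sd += 1
            else:
                nd += 1
            current = nxt
        (blocked_scores if blocked else pathway_scores).append((sd, nd))
    usable = pathway_scores or blocked_scores
    sd = sum(s for s, _ in usable) / len(usable)
    nd = sum(n for _, n in usable) / len(usable)
    return sd, nd


@dataclass(frozen=True)
class KaKsResult:
    ka: float
    ks: float
    n_sites: float
    s_sites: float
    nd: float
    sd: float
    n_codons: int

    @property
    def ratio(self) -> float:
        """Ka/Ks; NaN when undefined (Ks == 0 or saturated distances)."""
        if math.isnan(self.ka) or math.isnan(self.ks) or self.ks == 0.0:
            return float("nan")
        return self.ka / self.ks

    @property
    def ratio_defined(self) -> bool:
        return not math.isnan(self.ratio)


def kaks_ng86(cds_a: str, cds_b: str) -> KaKsResult:
    """Nei-Gojobori (1986) Ka and Ks for two aligned, in-frame CDSs.

    Codons containing gaps, Ns or stop codons (in either sequence) are
    excluded pairwise.  Site counts are averaged over the two sequences;
    substitution counts average over all shortest mutational pathways.
    """
    a, b = cds_a.upper().replace("U", "T"), cds_b.upper().replace("U", "T")
    if len(a) != len(b):
        raise ValueError("aligned CDSs differ in length")
    if len(a) % 3 != 0:
        raise ValueError("aligned length not divisible by 3")
    s_sites = n_sites = sd = nd = 0.0
    n_codons = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if any(c not in _BASES for c in ca + cb):
            continue
        if _CODON_TO_AA[ca] == "*" or _CODON_TO_AA[cb] == "*":
            continue
        n_codons += 1
        sa, na = _codon_sites(ca)
        sb, nb = _codon_sites(cb)
        s_sites += (sa + sb) / 2.0
        n_sites += (na + nb) / 2.0
        ds, dn = _pathway_counts(ca, cb)
        sd += ds
        nd += dn
    if n_codons == 0:
        raise ValueError("no comparable codons")
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    return KaKsResult(
        ka=jukes_cantor(pn),
        ks=jukes_cantor(ps),
        n_sites=n_sites,
        s_sites=s_sites,
        nd=nd,
        sd=sd,
        n_codons=n_codons,
    )
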