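"""Over-represented oligonucleotide (k-mer) detection over a Markov background.

Word occurrences are counted with overlaps across a sequence set, expected
counts come from a Markov background model (default: order 2, estimated from
the input set itself with a small pseudo-count), and significance is an
upper-tail binomial test corrected over the number of words tested.  The
reported ``sig_index`` is -log10 of the Bonferroni-corrected expectation
(E-value): positive values mean fewer than one false positive is expected at
that p-value over the whole word family.

In two-strand mode a word and its reverse complement are pooled (counts added,
expected probabilities summed) and keyed by the lexicographically smaller of
the pair, so e.g. CTGGCA/TGCCAG report a single merged record.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KmerEnrichmentResult",
    "MarkovBackground",
    "reverse_complement",
    "canonical_kmer",
    "count_kmers",
    "expected_count",
    "enrichment_significance",
    "find_enriched_kmers",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASES = "ACGT"


def reverse_complement(kmer: str) -> str:
    return kmer.translate(_COMPLEMENT)[::-1]


def canonical_kmer(kmer: str) -> str:
    """Lexicographically smaller of a word and its reverse complement."""
    rc = reverse_complement(kmer)
    return min(kmer, rc)


def _windows(sequences: Iterable[str], k: int):
    for seq in sequences:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            word = seq[i : i + k]
            if all(c in _BASES for c in word):
                yield word


def count_kmers(
    sequences: Iterable[str], k: int, two_strand: bool = False
) -> dict[str, int]:
    """Overlapping k-mer occurrence counts pooled over ``sequences``.

    With ``two_strand`` the returned mapping is keyed by canonical words and a
    word's count includes its reverse complement's occurrences.  Windows
    containing ambiguous bases are skipped.
    """
    if not 4 <= k <= 10:
        raise ValueError("k must be between 4 and 10")
    sequences = list(sequences)
    if all(len(s) < k for s in sequences):
        raise ValueError(f"no sequence is at least {k} nt long")
    counts = Counter(_windows(sequences, k))
    if not two_strand:
        return dict(counts)
    merged: Counter[str] = Counter()
    for word, n in counts.items():
        merged[canonical_kmer(word)] += n
    return dict(merged)


def total_positions(sequences: Iterable[str], k: int) -> int:
    """Number of sliding windows of width k over the set."""
    return sum(max(len(s) - k + 1, 0) for s in sequences)


class MarkovBackground:
    """Markov chain of order m over {A,C,G,T} with pseudo-count smoothing.

    P(word) = P(prefix of length m) * prod_i P(word[i] | preceding m bases).
    Order 0 reduces to independent base frequencies.
    """

    def __init__(self, order: int, pseudocount: float = 0.01):
        if order not in (0, 1, 2):
            raise ValueError("Markov order must be 0, 1 or 2")
        self.order = order
        self.pseudocount = pseudocount
        self._context: Counter[str] = Counter()
        self._transition: Counter[str] = Counter()
        self._initial: Counter[str] = Counter()
        self._n_initial = 0

    @classmethod
    def train(
        cls, sequences: Iterable[str], order: int = 2, pseudocount: float = 0.01
    ) -> "MarkovBackground":
        model = cls(order, pseudocount)
        for seq in sequences:
            seq = "".join(c for c in seq.upper() if c in _BASES)
            if len(seq) <= order:
                continue
            model._initial[seq[: order]] += 1
            model._n_initial += 1
            for i in range(order, len(seq)):
                model._context[seq[i - order : i]] += 1
                model._transition[seq[i - order : i + 1]] += 1
        if not model._transition:
            raise ValueError("not enough sequence to train the background")
        return model

    @classmethod
    def from_base_frequencies(cls, freqs: Mapping[str, float]) -> "MarkovBackground":
        """Order-0 background from an explicit base-frequency table."""
        model = cls(order=0, pseudocount=0.0)
        scale = 10**9
        for base in _BASES:
            model._transition[base] = int(freqs.get(base, 0.0) * scale)
        model._context[""] = sum(model._transition.values())
        model._initial[""] = 1
        model._n_initial = 1
        return model

    def _p_transition(self, context: str, base: str) -> float:
        num = self._transition[context + base] + self.pseudocount
        den = self._context[context] + 4 * self.pseudocount
        if den == 0:
            raise ValueError(
                f"background has no mass for context {context!r}; "
                "increase the pseudo-count or lower the order"
            )
        return num / den

    def _p_prefix(self, prefix: str) -> float:
        if self.order == 0:
            return 1.0
        # stationary-ish estimate: frequency of the m-mer among all contexts
        num = self._context[prefix] + self._initial[prefix] + self.pseudocount
        den = (
            sum(self._context.values())
            + self._n_initial
            + (4**self.order) * self.pseudocount
        )
        return num / den

    def probability(self, word: str) -> float:
        """P(word) at a single position under the chain."""
        word = word.upper()
        if len(word) <= self.order:
            raise ValueError("word shorter than the Markov order")
        p = self._p_prefix(word[: self.order])
        for i in range(self.order, len(word)):
            p *= self._p_transition(word[i - self.order : i], word[i])
        return p


def expected_count(
    kmer: str,
    background: MarkovBackground,
    total_positions: int,
    two_strand: bool = False,
) -> float:
    """Expected occurrence count of ``kmer`` over ``total_positions`` windows.

    In two-strand mode the probabilities of the word and its reverse
    complement are summed (a palindromic word is not double-counted).
    """
    p = background.probability(kmer)
    if two_strand:
        rc = reverse_complement(kmer)
        if rc != kmer:
            p += background.probability(rc)
    return total_positions * p


@dataclass(frozen=True)
class KmerEnrichmentResult:
    kmer: str
    observed: int
    expected: float
    p_value: float
    sig_index: float


def enrichment_significance(
    observed: int,
    expected: float,
    n_tests: int,
    n_positions: int | None = None,
) -> KmerEnrichmentResult:
    """Upper-tail binomial significance of an observed word count.

    ``p_value = P(X >= observed)`` for X ~ Binomial(n_positions, expected /
    n_positions); when ``n_positions`` is not given (or exceeds 10^4) the
    Poisson approximation with mean ``expected`` is used.  ``sig_index`` is
    -log10(n_tests * p_value), computed in log space so extreme enrichments
    do not underflow to infinity.
    """
    if observed < 0:
        raise ValueError("observed count cannot be negative")
    if expected <= 0:
        raise ValueError("expected count must be positive")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if observed == 0:
        log_p = 0.0  # P(X >= 0) == 1
    elif n_positions is not None and n_positions <= 10_000:
        log_p = float(stats.binom.logsf(observed - 1, n_positions, expected / n_positions))
    else:
        log_p = float(stats.poisson.logsf(observed - 1, expected))
    p = math.exp(log_p)
    sig_index = -(math.log10(n_tests) + log_p / math.log(10))
    return KmerEnrichmentResult(
        kmer="", observed=observed, expected=expected, p_value=p, sig_index=sig_index
    )


def find_enriched_kmers(
    sequences: Sequence[str],
    k: int,
    background: MarkovBackground | None = None,
    markov_order: int = 2,
    two_strand: bool = True,
    n_tests: int | None = None,
) -> pd.DataFrame:
    """Rank all observed k-mers by enrichment over the background.

    The background defaults to a Markov chain of ``markov_order`` trained on
    the input set itself.  ``n_tests`` defaults to the number of distinct
    words actually observed (after strand collapsing); pass ``4**k`` for the
    all-words convention.  Returns a DataFrame sorted by decreasing
    ``sig_index`` with columns kmer/observed/expected/p_value/sig_index.
    """
    sequences = list(sequences)
    counts = count_kmers(sequences, k, two_strand=two_strand)
    if background is None:
        background = MarkovBackground.train(sequences, order=markov_order)
    n_pos = total_positions(sequences, k)
    if n_tests is None:
        n_tests = len(counts)
    rows = []
    for word, observed in counts.items():
        exp = expected_count(word, background, n_pos, two_strand=two_strand)
        res = enrichment_significance(observed, exp, n_tests, n_positions=n_pos)
        rows.append(
            {
                "kmer": word,
                "observed": observed,
                "expected": exp,
                "p_value": res.p_value,
                "sig_index": res.sig_index,
            }
        )
    frame = pd.DataFrame(
        rows, columns=["kmer", "observed", "expected", "p_value", "sig_index"]
    )
    return frame.sort_values(
        ["sig_index", "kmer"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def all_kmers(k: int) -> list[str]:
    """All 4^k words of length k (testing convenience)."""
    return ["".join(t) for t in itertools.product(_BASES, repeat=k)]
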