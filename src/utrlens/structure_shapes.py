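"""Secondary-structure ensembles, abstract-shape censuses, conserved helices.

The census logic asks how many *genuinely different* folds a UTR can adopt
within a fixed energy band above the minimum free energy (default +5
kcal/mol), where "different" is judged at the abstract-shape level: unpaired
stretches are dropped, each maximal helix collapses to one bracket pair, and
helices separated only by internal loops/bulges merge, so loop sizes and
helix lengths do not distinguish structures but branching does.

Two folding engines satisfy the same contract:

* ``ToyEngine`` — base-pair maximization with energy −1 kcal/mol per pair
  (Watson-Crick and G:U), minimum hairpin loop of 3 nt, and *complete*
  enumeration of suboptimal structures within the energy window.  It is exact
  and deterministic, which makes every census property checkable against a
  brute-force oracle.
* ``ViennaREngine`` — nearest-neighbor thermodynamics via the ViennaRNA
  bindings (MFE + ``subopt``), for realistic energies.

A helix of the MFE structure is "conserved" when its exact base-pair set
appears in at least a given fraction (default 60%) of the suboptimal
structures.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Protocol

__all__ = [
    "MIN_LOOP",
    "StructureEnsemble",
    "ShapeCensus",
    "FoldingEngine",
    "ToyEngine",
    "ViennaREngine",
    "fold",
    "pair_table",
    "abstract_shape",
    "shape_census",
    "helices",
    "conserved_elements",
]

MIN_LOOP = 3  # minimum unpaired nucleotides enclosed by a hairpin

_PAIRABLE = {
    ("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G"),
    ("A", "U"), ("U", "A"), ("G", "U"), ("U", "G"),
}


def _can_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRABLE


@dataclass(frozen=True)
class StructureEnsemble:
    sequence: str
    mfe_structure: str
    mfe: float
    suboptimal: tuple[tuple[str, float], ...]  # (dot-bracket, energy), sorted
    energy_window: float

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for db, e in ((self.mfe_structure, self.mfe), *self.suboptimal):
            if len(db) != n:
                raise ValueError("structure length differs from sequence length")


class FoldingEngine(Protocol):
    def fold(
        self, sequence: str, energy_window: float
    ) -> tuple[str, float, list[tuple[str, float]]]:
        """Return (mfe_structure, mfe, suboptimal list incl. the MFE)."""


def pair_table(dot_bracket: str) -> dict[int, int]:
    """Map each paired 0-based position to its partner; errors if unbalanced."""
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for i, c in enumerate(dot_bracket):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced structure at position {i + 1}")
            j = stack.pop()
            pairs[j] = i
            pairs[i] = j
        elif c != ".":
            raise ValueError(f"invalid character {c!r} in dot-bracket string")
    if stack:
        raise ValueError("unbalanced structure: unclosed '('")
    return pairs


def _pairs_to_db(pairs: Iterable[tuple[int, int]], n: int) -> str:
    out = ["."] * n
    for i, j in pairs:
        out[i], out[j] = "(", ")"
    return "".join(out)


class ToyEngine:
    """Exhaustive base-pair-maximization engine (−1 kcal/mol per pair).

    ``max_len`` bounds the sequence length because enumeration is
    exponential; the default comfortably covers oracle-verified sizes.
    """

    def __init__(self, max_len: int = 40):
        self.max_len = max_len

    def fold(
        self, sequence: str, energy_window: float
    ) -> tuple[str, float, list[tuple[str, float]]]:
        seq = sequence.upper()
        n = len(seq)
        if n == 0:
            raise ValueError("empty sequence")
        if n > self.max_len:
            raise ValueError(
                f"ToyEngine enumerates exhaustively; sequence of {n} nt exceeds "
                f"max_len={self.max_len}"
            )
        best = self._max_pairs_table(seq)
        max_pairs = best[0][n - 1] if n > 1 else 0
        min_pairs = max(max_pairs - int(energy_window), 0)

        def bound(i: int, j: int) -> int:
            return best[i][j] if i < j else 0

        kept: list[tuple[str, float]] = []

        def enum(regions: tuple[tuple[int, int], ...], acc: list[tuple[int, int]]):
            # branch-and-bound: prune when even pairing optimally in every
            # remaining region cannot reach min_pairs
            if len(acc) + sum(bound(i, j) for i, j in regions) < min_pairs:
                return
            if not regions:
                kept.append((_pairs_to_db(acc, n), -float(len(acc))))
                return
            (i, j), rest = regions[0], regions[1:]
            if i > j:
                enum(rest, acc)
                return
            # i unpaired
            enum(((i + 1, j),) + rest, acc)
            # i paired with k
            for k in range(i + MIN_LOOP + 1, j + 1):
                if _can_pair(seq[i], seq[k]):
                    acc.append((i, k))
                    enum(((i + 1, k - 1), (k + 1, j)) + rest, acc)
                    acc.pop()

        enum(((0, n - 1),), [])
        kept.sort(key=lambda t: (t[1], t[0]))
        return kept[0][0], -float(max_pairs), kept

    @staticmethod
    def _max_pairs_table(seq: str) -> list[list[int]]:
        """Nussinov-style DP: best[i][j] = max pairs in seq[i..j]."""
        n = len(seq)
        best = [[0] * n for _ in range(n)]
        for span in range(MIN_LOOP + 1, n):
            for i in range(n - span):
                j = i + span
                b = best[i + 1][j]
                for k in range(i + MIN_LOOP + 1, j + 1):
                    if _can_pair(seq[i], seq[k]):
                        inner = best[i + 1][k - 1] if k - i > 1 else 0
                        rest = best[k + 1][j] if k + 1 <= j else 0
                        b = max(b, 1 + inner + rest)
                best[i][j] = b
        return best


class ViennaREngine:
    """Thermodynamic engine backed by the ViennaRNA python bindings."""

    def __init__(self) -> None:
        try:
            import RNA  # noqa: F401
        except ImportError as exc:  # pragma: no cover - environment dependent
            raise ImportError(
                "ViennaRNA python bindings are required for ViennaREngine"
            ) from exc
        self._rna = RNA

    def fold(
        self, sequence: str, energy_window: float
    ) -> tuple[str, float, list[tuple[str, float]]]:
        RNA = self._rna
        seq = sequence.upper().replace("T", "U")
        fc = RNA.fold_compound(seq)
        mfe_db, mfe = fc.mfe()
        subs = []
        for sol in fc.subopt(int(round(energy_window * 100))):
            if sol.structure is not None:
                subs.append((sol.structure, float(sol.energy)))
        subs.sort(key=lambda t: (t[1], t[0]))
        return mfe_db, float(mfe), subs


def fold(
    sequence: str,
    engine: FoldingEngine,
    energy_window: float = 5.0,
) -> StructureEnsemble:
    """Fold a sequence and collect its suboptimal ensemble.

    Structures are ordered by (energy, dot-bracket) so the result is
    deterministic for a given engine.  The MFE structure is always a member
    of the suboptimal set.
    """
    seq = sequence.upper()
    if len(seq) < 5:
        raise ValueError("sequence shorter than 5 nt cannot fold")
    if any(c not in "ACGTU" for c in seq):
        raise ValueError("sequence contains non-ACGU(T) characters")
    mfe_db, mfe, subs = engine.fold(seq, energy_window)
    subs = [(db, e) for db, e in subs if e <= mfe + energy_window + 1e-9]
    subs.sort(key=lambda t: (t[1], t[0]))
    return StructureEnsemble(
        sequence=seq,
        mfe_structure=mfe_db,
        mfe=mfe,
        suboptimal=tuple(subs),
        energy_window=energy_window,
    )


def abstract_shape(dot_bracket: str) -> str:
    """Coarse shape of a structure: helices as ``[]``, open chain as ``_``.

    Unpaired positions are dropped; a maximal helix becomes one bracket pair;
    helices separated only by unpaired bases (stacks, bulges, internal loops)
    merge into a single pair, while multiloop branching is preserved.
    """
    pairs = pair_table(dot_bracket)
    if not pairs:
        return "_"

    def children(i: int, j: int) -> list[tuple[int, int]]:
        """Outermost pairs strictly inside (i, j)."""
        out = []
        k = i
        while k <= j:
            if k in pairs and pairs[k] > k:
                out.append((k, pairs[k]))
                k = pairs[k] + 1
            else:
                k += 1
        return out

    def shape_of_branch(i: int, j: int) -> str:
        # descend through single-child (merged) helices
        while True:
            kids = children(i + 1, j - 1)
            if len(kids) == 1:
                i, j = kids[0]
            else:
                break
        if not kids:
            return "[]"
        return "[" + "".join(shape_of_branch(a, b) for a, b in kids) + "]"

    top = children(0, len(dot_bracket) - 1)
    return "".join(shape_of_branch(a, b) for a, b in top)


@dataclass(frozen=True)
class ShapeCensus:
    shapes: dict[str, int] = field(default_factory=dict)

    @property
    def n_shapes(self) -> int:
        return len(self.shapes)

    @property
    def n_structures(self) -> int:
        return sum(self.shapes.values())


def shape_census(ensemble: StructureEnsemble) -> ShapeCensus:
    """Count distinct abstract shapes over the suboptimal ensemble."""
    if not ensemble.suboptimal:
        raise ValueError("empty ensemble")
    counts = Counter(abstract_shape(db) for db, _ in ensemble.suboptimal)
    return ShapeCensus(shapes=dict(counts))


def helices(dot_bracket: str) -> list[frozenset[tuple[int, int]]]:
    """Maximal stacks of a structure as sets of 0-based pairs.

    A stack extends while consecutive pairs are directly nested,
    (i, j) followed by (i+1, j-1).
    """
    pairs = sorted(
        (i, j) for i, j in pair_table(dot_bracket).items() if i < j
    )
    pair_set = set(pairs)
    out = []
    seen: set[tuple[int, int]] = set()
    for i, j in pairs:
        if (i, j) in seen:
            continue
        stack = [(i, j)]
        a, b = i, j
        while (a + 1, b - 1) in pair_set:
            a, b = a + 1, b - 1
            stack.append((a, b))
        seen.update(stack)
        out.append(frozenset(stack))
    return out


def conserved_elements(
    ensemble: StructureEnsemble, fraction: float = 0.6
) -> list[frozenset[tuple[int, int]]]:
    """MFE helices whose exact pair set recurs in >= ``fraction`` of the
    suboptimal structures (the MFE structure itself included in the census)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    n = len(ensemble.suboptimal)
    if n == 0:
        return []
    sub_pair_sets = [
        set(p for p in pair_table(db).items() if p[0] < p[1])
        for db, _ in ensemble.suboptimal
    ]
    out = []
    for helix in helices(ensemble.mfe_structure):
        support = sum(1 for ps in sub_pair_sets if helix <= ps)
        if support / n >= fraction:
            out.append(helix)
    return out
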