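"""miRNA seed matching and thermodynamic site-accessibility scoring.

A candidate site is a stretch of the 3' UTR whose antiparallel pairing with
the miRNA seed (positions 1..min_seed from the miRNA 5' end) satisfies the
allowed numbers of G:U wobbles and mismatches (position 1 must pair
Watson-Crick).  Each site is then scored with two free energies:

* ``dg_duplex`` — hybridization energy of the miRNA with the site;
* ``dg_open``  — cost of locally unfolding the mRNA around the site, computed
  as (unconstrained ensemble energy) − (ensemble energy with the site forced
  single-stranded) over a window flanking the site; this difference is <= 0.

The interaction score is ``ddg = dg_duplex − dg_open`` (both terms in
kcal/mol).  Sites with ddg < −10 are called accessible; those that in
addition have dg_open > −10 (little structure to melt) are very accessible.

The thermodynamic engine is a pluggable contract: a deterministic stub backs
the test suite and a nearest-neighbor engine (ViennaRNA) can be selected at
runtime when its bindings are importable.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Protocol

__all__ = [
    "AccessClass",
    "SeedMatch",
    "MirnaSite",
    "ThermodynamicEngine",
    "StubEngine",
    "ViennaEngine",
    "find_seed_matches",
    "score_site",
    "classify_targets",
    "DDG_THRESHOLD",
    "DG_OPEN_THRESHOLD",
]

DDG_THRESHOLD = -10.0  # kcal/mol; below => accessible
DG_OPEN_THRESHOLD = -10.0  # kcal/mol; above (less costly) => very accessible

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}  # DNA alphabet: U stored as T


class AccessClass(str, Enum):
    INACCESSIBLE = "inaccessible"
    ACCESSIBLE = "accessible"
    VERY_ACCESSIBLE = "very_accessible"


@dataclass(frozen=True)
class SeedMatch:
    """A seed-complementary UTR stretch; coordinates 1-based inclusive."""

    site_start: int
    site_end: int
    seed_len: int
    n_gu: int
    n_mismatch: int


@dataclass(frozen=True)
class MirnaSite:
    mirna_id: str
    site_start: int
    site_end: int
    seed_len: int
    n_gu: int
    n_mismatch: int
    dg_duplex: float
    dg_open: float

    @property
    def ddg(self) -> float:
        return self.dg_duplex - self.dg_open

    @property
    def access_class(self) -> AccessClass:
        if self.ddg < DDG_THRESHOLD:
            if self.dg_open > DG_OPEN_THRESHOLD:
                return AccessClass.VERY_ACCESSIBLE
            return AccessClass.ACCESSIBLE
        return AccessClass.INACCESSIBLE


def find_seed_matches(
    mirna: str,
    utr3: str,
    min_seed: int = 8,
    max_gu: int = 1,
    max_mismatch: int = 1,
) -> list[SeedMatch]:
    """Seed-complementary sites of ``mirna`` in ``utr3``.

    The seed is miRNA positions 1..min_seed (5'->3'); a UTR window matches
    when, read antiparallel, every seed position pairs Watson-Crick, G:U or
    mismatches within the allowed budgets.  Seed position 1 must pair
    Watson-Crick (neither wobble nor mismatch is tolerated there).
    """
    if min_seed < 6:
        raise ValueError("min_seed must be >= 6")
    mirna = mirna.upper().replace("U", "T")
    utr = utr3.upper().replace("U", "T")
    if len(mirna) < min_seed:
        raise ValueError("miRNA shorter than the seed")
    seed = mirna[:min_seed]
    out = []
    for i in range(len(utr) - min_seed + 1):
        window = utr[i : i + min_seed]
        n_gu = n_mm = 0
        ok = True
        for j in range(min_seed):
            pair = (seed[j], window[min_seed - 1 - j])  # antiparallel
            if pair in _WC:
                continue
            if j == 0:
                ok = False  # position 1 must pair strictly
                break
            if pair in _GU:
                n_gu += 1
            else:
                n_mm += 1
            if n_gu > max_gu or n_mm > max_mismatch:
                ok = False
                break
        if ok:
            out.append(
                SeedMatch(
                    site_start=i + 1,
                    site_end=i + min_seed,
                    seed_len=min_seed,
                    n_gu=n_gu,
                    n_mismatch=n_mm,
                )
            )
    return out


class ThermodynamicEngine(Protocol):
    """Contract the scoring needs from a thermodynamics backend."""

    def duplex_energy(self, mirna: str, target: str) -> float:
        """Hybridization energy (kcal/mol) of two strands."""

    def opening_energy(self, window: str, site_start: int, site_end: int) -> float:
        """Unconstrained minus site-unpaired-constrained ensemble energy of
        ``window`` (kcal/mol, <= 0); site coordinates are 1-based within the
        window."""


@dataclass
class StubEngine:
    """Deterministic lookup engine for tests and dry runs.

    ``duplex``/``opening`` may be constants or ``{key: value}`` mappings keyed
    by the target-site sequence.
    """

    duplex: float | dict[str, float] = -15.0
    opening: float | dict[str, float] = -5.0

    def _get(self, table, key):
        if isinstance(table, dict):
            return table[key]
        return float(table)

    def duplex_energy(self, mirna: str, target: str) -> float:
        return self._get(self.duplex, target)

    def opening_energy(self, window: str, site_start: int, site_end: int) -> float:
        return self._get(self.opening, window[site_start - 1 : site_end])


class ViennaEngine:
    """Nearest-neighbor engine backed by the ViennaRNA bindings (optional)."""

    def __init__(self) -> None:
        try:
            import RNA  # noqa: F401
        except ImportError as exc:  # pragma: no cover - environment dependent
            raise ImportError(
                "ViennaRNA python bindings are required for ViennaEngine"
            ) from exc
        self._rna = RNA

    @staticmethod
    def _to_rna(seq: str) -> str:
        return seq.upper().replace("T", "U")

    def duplex_energy(self, mirna: str, target: str) -> float:
        duplex = self._rna.duplexfold(self._to_rna(mirna), self._to_rna(target))
        return float(duplex.energy)

    def opening_energy(self, window: str, site_start: int, site_end: int) -> float:
        RNA = self._rna
        seq = self._to_rna(window)
        fc = RNA.fold_compound(seq)
        _, g_free = fc.pf()
        fc_con = RNA.fold_compound(seq)
        for pos in range(site_start, site_end + 1):
            fc_con.hc_add_up(pos)
        _, g_con = fc_con.pf()
        return float(g_free - g_con)


def score_site(
    site: SeedMatch,
    utr3: str,
    mirna: str,
    engine: ThermodynamicEngine,
    mirna_id: str = "",
    flank: int = 70,
) -> MirnaSite:
    """Score one seed match: duplex energy, opening energy, ddG and class.

    The opening energy is evaluated on a window extending ``flank`` nt on each
    side of the site, truncated at the UTR ends.
    """
    utr = utr3.upper().replace("U", "T")
    if not 1 <= site.site_start <= site.site_end <= len(utr):
        raise ValueError("site coordinates outside the UTR")
    w_start = max(site.site_start - flank, 1)
    w_end = min(site.site_end + flank, len(utr))
    window = utr[w_start - 1 : w_end]
    target = utr[site.site_start - 1 : site.site_end]
    try:
        dg_duplex = engine.duplex_energy(mirna, target)
        dg_open = engine.opening_energy(
            window, site.site_start - w_start + 1, site.site_end - w_start + 1
        )
    except Exception as exc:
        raise RuntimeError(
            f"thermodynamic engine failed on site {site.site_start}-{site.site_end}"
        ) from exc
    return MirnaSite(
        mirna_id=mirna_id,
        site_start=site.site_start,
        site_end=site.site_end,
        seed_len=site.seed_len,
        n_gu=site.n_gu,
        n_mismatch=site.n_mismatch,
        dg_duplex=dg_duplex,
        dg_open=dg_open,
    )


def classify_targets(sites: Iterable[MirnaSite]) -> tuple[int, int]:
    """(n_accessible, n_very_accessible); very accessible sites count in both."""
    n_acc = n_very = 0
    for s in sites:
        cls = s.access_class
        if cls is AccessClass.VERY_ACCESSIBLE:
            n_acc += 1
            n_very += 1
        elif cls is AccessClass.ACCESSIBLE:
            n_acc += 1
    return n_acc, n_very
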