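"""Synthetic UTR/CDS/ortholog generator with planted, recorded features.

Every analysis stage in this package is a scanner or estimator; this module
manufactures inputs whose ground truth is known exactly, so each stage can be
tested for exact recovery without downloading anything.  A
:class:`SimulationPlan` fixes the study conditions: gene/variant counts, UTR
length distributions, a G+C target for the background, the features to plant
(uORFs with chosen initiation contexts and cap distances, PAS hexamers at
chosen distances from the 3' end, enriched k-mers, miRNA seed sites) and a
divergence specification for ortholog families (per-codon-position and UTR
substitution rates — third positions fastest, as in real coding sequence).

Background sequence is i.i.d. with the requested G+C; after planting, the
generator *scrubs* spurious feature instances (stray ATGs in 5' UTRs, stray
PAS hexamers in 3' UTRs) outside the protected planted intervals, so the
truth tables list every feature instance the scanners should find.  A fixed
seed yields byte-identical output; per-gene substreams make generation order
irrelevant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .catalog_io import GeneCatalog, Region, UtrRecord, write_catalog_fasta
from .kmer_enrichment import reverse_complement
from .pas_scan import CANONICAL, DEFAULT_VARIANT_HEXAMERS, NON_CANONICAL

__all__ = [
    "SimulationPlan",
    "DivergenceSpec",
    "PlanError",
    "simulate_gene",
    "simulate_catalog",
    "diverge_family",
    "expected_pairwise_identity",
    "ed_preset",
    "ld_preset",
    "write_outputs",
]

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
_ALL_PAS = (CANONICAL, NON_CANONICAL) + tuple(DEFAULT_VARIANT_HEXAMERS)


class PlanError(ValueError):
    """Raised when a simulation plan is internally inconsistent."""


@dataclass(frozen=True)
class DivergenceSpec:
    """Per-site substitution rates and the species to derive from the root."""

    pos1: float = 0.05
    pos2: float = 0.05
    pos3: float = 0.15
    utr: float = 0.10
    species: tuple[str, ...] = ("SpA", "SpB")

    def __post_init__(self) -> None:
        for name in ("pos1", "pos2", "pos3", "utr"):
            rate = getattr(self, name)
            if not 0 <= rate <= 0.75:
                raise PlanError(
                    f"{name} rate {rate} outside [0, 0.75] (identity saturates)"
                )


@dataclass
class SimulationPlan:
    """Declarative description of one synthetic catalog.

    Length fields accept either an int (constant) or an inclusive
    ``(lo, hi)`` range sampled uniformly per gene.  ``planted_uorfs`` holds
    ``(cap_distance, context_class, peptide_length)`` triples with
    context_class in {"optimal", "adequate", "weak"}; ``planted_pas`` holds
    ``(hexamer, distance_to_end)``; ``planted_kmers`` holds ``(kmer,
    copies)`` planted in the 5' UTR; ``planted_mirna_sites`` holds
    ``(mirna_id, mirna_sequence, site_start)`` with a perfect seed complement
    written into the 3' UTR at ``site_start`` (1-based).
    """

    seed: int = 0
    n_genes: int = 5
    variants_per_gene: int | tuple[int, int] = 1
    utr5_length: int | tuple[int, int] = 200
    utr3_length: int | tuple[int, int] = 200
    cds_length: int | tuple[int, int] = 300
    gc_target: float = 0.5
    planted_uorfs: list[tuple[int, str, int]] = field(default_factory=list)
    planted_pas: list[tuple[str, int]] = field(default_factory=list)
    planted_kmers: list[tuple[str, int]] = field(default_factory=list)
    planted_mirna_sites: list[tuple[str, str, int]] = field(default_factory=list)
    divergence: DivergenceSpec = field(default_factory=DivergenceSpec)
    species: str = "Syn"
    seed_len: int = 8  # seed length used when planting miRNA sites

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationPlan":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        if "divergence" in data and isinstance(data["divergence"], dict):
            div = dict(data["divergence"])
            if "species" in div:
                div["species"] = tuple(div["species"])
            data["divergence"] = DivergenceSpec(**div)
        for key in ("planted_uorfs", "planted_pas", "planted_kmers", "planted_mirna_sites"):
            if key in data:
                data[key] = [tuple(item) for item in data[key]]
        for key in ("variants_per_gene", "utr5_length", "utr3_length", "cds_length"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj

        with open(path, "w") as handle:
            yaml.safe_dump(plain(asdict(self)), handle, sort_keys=False)


def _draw(spec: int | tuple[int, int], rng: np.random.Generator) -> int:
    if isinstance(spec, (tuple, list)):
        lo, hi = spec
        return int(rng.integers(lo, hi + 1))
    return int(spec)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    return rng.choice(_BASES, size=length, p=p)


def _gene_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _scrub(
    seq: np.ndarray,
    protected: np.ndarray,
    find_bad: "callable",
    rng: np.random.Generator,
    max_iter: int = 10_000,
) -> None:
    """Mutate unprotected positions until ``find_bad`` reports no intervals.

    ``find_bad`` maps the current sequence string to 0-based [start, end)
    intervals of unwanted feature instances.
    """
    for _ in range(max_iter):
        bad = [
            (s, e)
            for s, e in find_bad("".join(seq))
            if not protected[s:e].all()
        ]
        if not bad:
            return
        s, e = bad[0]
        editable = [i for i in range(s, e) if not protected[i]]
        if not editable:
            raise PlanError(
                "a planted feature itself contains a spurious feature instance; "
                "choose non-conflicting planted sequences"
            )
        pos = int(rng.choice(editable))
        current = seq[pos]
        seq[pos] = rng.choice([b for b in "ACGT" if b != current])
    raise PlanError("could not scrub spurious features; plan too dense")


def _find_atg(seq: str) -> list[tuple[int, int]]:
    return [(i, i + 3) for i in range(len(seq) - 2) if seq[i : i + 3] == "ATG"]


def _find_pas(seq: str) -> list[tuple[int, int]]:
    return [
        (i, i + 6) for i in range(len(seq) - 5) if seq[i : i + 6] in _ALL_PAS
    ]


_SAFE_CODONS = ("GCC", "CTC", "TCC", "AGC", "CCT", "GGT")  # no ATG/stop, junction-safe


def _build_uorf(
    cap_distance: int, context: str, peptide_length: int, rng: np.random.Generator
) -> tuple[str, str]:
    """Return (orf_sequence_incl_stop, minus3_base) for a planted uORF.

    The +4 base is the first base after the AUG codon and is therefore part
    of the returned ORF.  Infeasible combinations are rejected: an optimal
    context needs a −3 base (cap distance >= 3) *and* +4 == G, but a
    one-codon ORF's +4 is the first base of its stop codon and no stop codon
    begins with G.
    """
    if context not in ("optimal", "adequate", "weak"):
        raise PlanError(f"unknown context class {context!r}")
    if peptide_length < 1:
        raise PlanError("peptide_length must be >= 1")
    has_minus3 = cap_distance >= 3
    if context == "optimal":
        if not has_minus3:
            raise PlanError("optimal context needs a −3 base (cap distance >= 3)")
        minus3, plus4_g = "A", True
    elif context == "adequate":
        # exactly one of (−3 purine, +4 G); without a −3 base the +4 must hold
        minus3, plus4_g = ("A", False) if has_minus3 else ("", True)
    else:  # weak: neither condition holds (a missing −3 already fails it)
        minus3, plus4_g = ("C" if has_minus3 else ""), False
    if peptide_length == 1:
        if plus4_g:
            raise PlanError(
                "a 1-codon uORF starts its stop codon at +4; no stop codon "
                "begins with G, so a +4 == G context is infeasible"
            )
        body = ""
        stop = "TAA"  # +4 is then T
    else:
        first = "GGT" if plus4_g else "CCT"
        rest = [str(rng.choice(_SAFE_CODONS)) for _ in range(peptide_length - 2)]
        body = first + "".join(rest)
        stop = str(rng.choice(_STOPS))
    return "ATG" + body + stop, minus3


def simulate_gene(
    plan: SimulationPlan, gene_index: int, variant: str = "a"
) -> tuple[UtrRecord, UtrRecord, UtrRecord, dict]:
    """Generate one gene's 5' UTR, 3' UTR and CDS plus its truth record.

    The truth mapping records every planted feature with the coordinates and
    class labels its scanner is expected to recover.
    """
    rng = _gene_rng(plan.seed, gene_index, ord(variant[0]))
    gene = f"G{gene_index:03d}"
    truth: dict = {"gene": gene, "variant": variant}

    # --- 5' UTR: background, then planted uORFs, then ATG scrub -----------
    len5 = _draw(plan.utr5_length, rng)
    utr5 = _random_seq(rng, len5, plan.gc_target)
    protected5 = np.zeros(len5, dtype=bool)
    uorf_truth = []
    uorf_starts = []
    last_end = -1
    for cap_distance, context, peptide_length in sorted(plan.planted_uorfs):
        orf, minus3 = _build_uorf(cap_distance, context, peptide_length, rng)
        start0 = cap_distance  # 0-based index of the A of ATG
        if max(start0 - 3, 0) <= last_end:
            raise PlanError("planted uORFs overlap")
        end0 = start0 + len(orf)  # includes the stop codon
        if end0 > len5:
            raise PlanError(
                f"uORF at cap distance {cap_distance} exceeds the 5' UTR length {len5}"
            )
        utr5[start0:end0] = list(orf)
        if minus3:
            utr5[start0 - 3] = minus3
            protected5[start0 - 3] = True
        # +4 base is orf[3] (or the stop's first base), already in place
        protected5[start0:end0] = True
        last_end = end0
        uorf_starts.append(start0)
        uorf_truth.append(
            {
                "start": start0 + 1,
                "stop_end": end0,
                "cap_distance": cap_distance,
                "peptide_length": peptide_length,
                "context_class": context,
                "distance_class": (
                    "optimal"
                    if cap_distance > 19
                    else "weak" if cap_distance < 12 else "intermediate"
                ),
            }
        )
    kmer_truth = []
    for kmer, copies in plan.planted_kmers:
        kmer = kmer.upper()
        for _ in range(copies):
            placed = False
            for _attempt in range(200):
                pos = int(rng.integers(0, len5 - len(kmer) + 1))
                if not protected5[pos : pos + len(kmer)].any():
                    utr5[pos : pos + len(kmer)] = list(kmer)
                    protected5[pos : pos + len(kmer)] = True
                    kmer_truth.append({"kmer": kmer, "position": pos + 1})
                    placed = True
                    break
            if not placed:
                raise PlanError(f"could not place k-mer {kmer}: 5' UTR too dense")
    # the planted k-mers themselves must not introduce spurious uAUGs
    def bad_atg(seq: str) -> list[tuple[int, int]]:
        return [iv for iv in _find_atg(seq) if iv[0] not in uorf_starts]

    _scrub(utr5, protected5, bad_atg, rng)
    truth["uorfs"] = uorf_truth
    truth["kmers"] = kmer_truth

    # --- 3' UTR: background, planted PAS + miRNA sites, PAS scrub ---------
    len3 = _draw(plan.utr3_length, rng)
    utr3 = _random_seq(rng, len3, plan.gc_target)
    protected3 = np.zeros(len3, dtype=bool)
    pas_truth = []
    pas_starts = []
    for hexamer, distance in plan.planted_pas:
        hexamer = hexamer.upper().replace("U", "T")
        start0 = len3 - distance - 1  # 1-based position = length - distance
        if start0 < 0 or start0 + 6 > len3:
            raise PlanError(
                f"PAS at distance {distance} does not fit in a {len3}-nt 3' UTR"
            )
        if protected3[start0 : start0 + 6].any():
            raise PlanError("planted PAS hexamers overlap")
        utr3[start0 : start0 + 6] = list(hexamer)
        protected3[start0 : start0 + 6] = True
        pas_starts.append(start0)
        pas_truth.append(
            {"hexamer": hexamer, "position": start0 + 1, "distance_to_end": distance}
        )
    site_truth = []
    for mirna_id, mirna_seq, site_start in plan.planted_mirna_sites:
        seed = mirna_seq.upper().replace("U", "T")[: plan.seed_len]
        site = reverse_complement(seed)
        start0 = site_start - 1
        if start0 < 0 or start0 + len(site) > len3:
            raise PlanError(f"miRNA site at {site_start} does not fit the 3' UTR")
        if protected3[start0 : start0 + len(site)].any():
            raise PlanError("planted miRNA site overlaps another feature")
        utr3[start0 : start0 + len(site)] = list(site)
        protected3[start0 : start0 + len(site)] = True
        site_truth.append(
            {
                "mirna_id": mirna_id,
                "mirna": mirna_seq.upper().replace("U", "T"),
                "site_start": site_start,
                "site_end": site_start + len(site) - 1,
            }
        )

    def bad_pas(seq: str) -> list[tuple[int, int]]:
        return [iv for iv in _find_pas(seq) if iv[0] not in pas_starts]

    _scrub(utr3, protected3, bad_pas, rng)
    truth["pas"] = pas_truth
    truth["mirna_sites"] = site_truth

    # --- CDS: ATG + non-stop codons + stop --------------------------------
    n_codons = max(_draw(plan.cds_length, rng) // 3, 3)
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        codon = "".join(rng.choice(_BASES, size=3, p=[(1 - plan.gc_target) / 2,
                                                      plan.gc_target / 2,
                                                      plan.gc_target / 2,
                                                      (1 - plan.gc_target) / 2]))
        if codon not in _STOPS:
            codons.append(codon)
    codons.append("TAA")
    cds_seq = "".join(codons)

    make = lambda region, seq: UtrRecord(gene, variant, plan.species, region, seq)
    return (
        make(Region.FIVE_PRIME, "".join(utr5)),
        make(Region.THREE_PRIME, "".join(utr3)),
        make(Region.CDS, cds_seq),
        truth,
    )


def simulate_catalog(
    plan: SimulationPlan,
) -> tuple[GeneCatalog, GeneCatalog, GeneCatalog, list[dict]]:
    """Generate the full catalog triple (5' UTRs, 3' UTRs, CDSs) plus truths."""
    utr5s, utr3s, cdss = GeneCatalog(), GeneCatalog(), GeneCatalog()
    truths = []
    for g in range(plan.n_genes):
        rng = _gene_rng(plan.seed, g)
        n_var = _draw(plan.variants_per_gene, rng)
        for v in range(n_var):
            variant = chr(ord("a") + v)
            u5, u3, cds, truth = simulate_gene(plan, g, variant)
            utr5s.add(u5)
            utr3s.add(u3)
            cdss.add(cds)
            truths.append(truth)
    return utr5s, utr3s, cdss, truths


# --------------------------------------------------------------------------
# Ortholog families


def diverge_family(
    records: Sequence[UtrRecord],
    spec: DivergenceSpec,
    seed: int,
) -> tuple[dict[str, list[UtrRecord]], pd.DataFrame]:
    """Derive one diverged copy of each record per species, from a shared root.

    Substitutions are Jukes-Cantor-like: each site mutates with its
    position-class rate (codon positions 1/2/3 for CDS records, the flat UTR
    rate otherwise) to a uniformly chosen different base.  CDS mutations are
    re-drawn (or abandoned) when they would create an internal stop codon, so
    every diverged CDS stays open.  Returns the per-species records plus a
    table of realized substitution counts.
    """
    rng_root = np.random.default_rng(np.random.SeedSequence(seed))
    out: dict[str, list[UtrRecord]] = {sp: [] for sp in spec.species}
    rows = []
    for r_idx, record in enumerate(records):
        for s_idx, species in enumerate(spec.species):
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(r_idx, s_idx))
            )
            seq = np.array(list(record.sequence))
            if record.region is Region.CDS:
                rates = np.empty(len(seq))
                rates[0::3], rates[1::3], rates[2::3] = spec.pos1, spec.pos2, spec.pos3
            else:
                rates = np.full(len(seq), spec.utr)
            hits = np.flatnonzero(rng.random(len(seq)) < rates)
            n_sub = 0
            for pos in hits:
                old = seq[pos]
                choices = [b for b in "ACGT" if b != old]
                rng.shuffle(choices)
                for new in choices:
                    seq[pos] = new
                    if record.region is Region.CDS and _creates_internal_stop(seq, pos):
                        seq[pos] = old
                        continue
                    n_sub += 1
                    break
            diverged = UtrRecord(
                record.gene, record.variant, species, record.region, "".join(seq)
            )
            out[species].append(diverged)
            rows.append(
                {
                    "gene": record.gene,
                    "variant": record.variant,
                    "region": record.region.value,
                    "species": species,
                    "n_substitutions": n_sub,
                    "length": record.length,
                }
            )
    del rng_root
    return out, pd.DataFrame(rows)


def _creates_internal_stop(seq: np.ndarray, pos: int) -> bool:
    codon_start = (pos // 3) * 3
    if codon_start + 3 > len(seq) or codon_start == len(seq) - 3:
        return False  # terminal stop codon is allowed
    return "".join(seq[codon_start : codon_start + 3]) in _STOPS


def expected_pairwise_identity(rate: float) -> float:
    """Expected % identity between two branches diverged at ``rate`` each.

    Both copies keep a site with probability (1-rate); two mutated copies
    coincide with probability 1/3.
    """
    p_same = (1 - rate) ** 2 + rate**2 / 3.0
    return 100.0 * p_same


# --------------------------------------------------------------------------
# Presets mirroring the headline early- vs late-diverging contrast


def ed_preset(seed: int = 0) -> SimulationPlan:
    """Early-diverging-like genes: long, uORF-laden 5' UTRs, multiple PAS,
    slow UTR divergence."""
    return SimulationPlan(
        seed=seed,
        n_genes=4,
        variants_per_gene=2,
        utr5_length=(250, 400),
        utr3_length=(200, 400),
        gc_target=0.55,
        planted_uorfs=[(25, "optimal", 4), (80, "weak", 3)],
        planted_pas=[("AATAAA", 23), ("ATTAAA", 120)],
        divergence=DivergenceSpec(pos1=0.05, pos2=0.05, pos3=0.20, utr=0.08,
                                  species=("SpA", "SpB", "SpC")),
    )


def ld_preset(seed: int = 0) -> SimulationPlan:
    """Late-diverging-like genes: short uORF-free 5' UTRs, one proximal PAS,
    fast UTR divergence."""
    return SimulationPlan(
        seed=seed,
        n_genes=4,
        variants_per_gene=1,
        utr5_length=(40, 80),
        utr3_length=(100, 160),
        gc_target=0.55,
        planted_uorfs=[],
        planted_pas=[("AATAAA", 23)],
        divergence=DivergenceSpec(pos1=0.05, pos2=0.05, pos3=0.20, utr=0.35,
                                  species=("SpA", "SpB", "SpC")),
    )


def write_outputs(plan: SimulationPlan, outdir: str | Path) -> dict[str, Path]:
    """Generate a catalog and write FASTA files plus a truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    utr5s, utr3s, cdss, truths = simulate_catalog(plan)
    paths = {
        "utr5": outdir / "utr5.fasta",
        "utr3": outdir / "utr3.fasta",
        "cds": outdir / "cds.fasta",
        "truth": outdir / "truth.tsv",
    }
    write_catalog_fasta(utr5s, paths["utr5"])
    write_catalog_fasta(utr3s, paths["utr3"])
    write_catalog_fasta(cdss, paths["cds"])
    rows = []
    for truth in truths:
        for kind in ("uorfs", "pas", "kmers", "mirna_sites"):
            for item in truth[kind]:
                row = {"gene": truth["gene"], "variant": truth["variant"], "feature": kind}
                row.update({k: str(v) for k, v in item.items()})
                rows.append(row)
    pd.DataFrame(rows).to_csv(paths["truth"], sep="\t", index=False)
    return paths
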