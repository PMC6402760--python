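"""End-to-end characterization pipeline: catalogs in, feature tables out.

`run_characterization` reads the configured FASTA catalogs, runs the enabled
stages and writes deterministic TSV reports:

* ``table1_like.tsv`` — per 5' UTR variant: length, %G+C, MFE (when a folding
  engine is enabled), uAUG/uORF counts, the O/W cap-distance and context
  summary strings and the surrogate translation class (I/III);
* ``table4_like.tsv`` — per 3' UTR variant: length and one row per PAS site
  (position, hexamer, type, efficiency), plus accessible / very-accessible
  miRNA target counts when a miRNA catalog is supplied;
* ``enrichment.tsv`` — over-represented k-mers of the 5' UTR set;
* ``conservation.tsv`` — pairwise identity of ortholog sets, when provided;
* ``run_log.txt`` — config, package version, seed and engine choices.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .catalog_io import GeneCatalog, Region, read_catalog_fasta, write_feature_table
from .composition import gc_content
from .conservation import distance_matrix
from .kmer_enrichment import find_enriched_kmers
from .mirna_accessibility import (
    StubEngine,
    ViennaEngine,
    classify_targets,
    find_seed_matches,
    score_site,
)
from .pas_scan import DEFAULT_VARIANT_HEXAMERS, DEFAULT_WINDOW, annotate_pas
from .structure_shapes import ToyEngine, ViennaREngine, fold
from .uorf_scan import (
    TranslationThresholds,
    assign_translation_class,
    build_profile,
    context_string,
    efficiency_string,
)

__all__ = ["RunConfig", "PipelineError", "run_characterization"]


class PipelineError(RuntimeError):
    """Configuration or input error detected before/ during a run."""


@dataclass
class RunConfig:
    """Inputs, stage toggles and thresholds for one pipeline run.

    Threshold defaults equal the documented defaults of the individual
    modules; the config only gathers them in one place.
    """

    utr5_fasta: str | None = None
    utr3_fasta: str | None = None
    cds_fasta: str | None = None
    mirna_fasta: str | None = None
    ortholog_fastas: list[str] = field(default_factory=list)
    outdir: str = "utrlens_out"
    seed: int = 0

    # stage toggles
    run_uorf: bool = True
    run_pas: bool = True
    run_kmers: bool = True
    run_mirna: bool = False
    run_structure: bool = False
    run_conservation: bool = False

    # thresholds (module defaults)
    min_codons: int = 1
    require_stop_in_utr: bool = True
    cart_max_len: int = 100
    cart_min_mfe_per_nt: float = -0.45
    pas_window: tuple[int, int] = DEFAULT_WINDOW
    pas_variants: tuple[str, ...] = DEFAULT_VARIANT_HEXAMERS
    kmer_k: int = 6
    kmer_markov_order: int = 2
    kmer_two_strand: bool = True
    mirna_min_seed: int = 8
    mirna_max_gu: int = 1
    mirna_max_mismatch: int = 1
    mirna_flank: int = 70
    structure_energy_window: float = 5.0
    structure_engine: str = "toy"  # "toy" | "vienna"
    mirna_engine: str = "stub"  # "stub" | "vienna"
    identity_threshold: float = 60.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        if "pas_window" in data:
            data["pas_window"] = tuple(data["pas_window"])
        if "pas_variants" in data:
            data["pas_variants"] = tuple(data["pas_variants"])
        return cls(**data)


def _structure_engine(config: RunConfig):
    if config.structure_engine == "vienna":
        return ViennaREngine()
    return ToyEngine(max_len=60)


def _mirna_engine(config: RunConfig):
    if config.mirna_engine == "vienna":
        return ViennaEngine()
    return StubEngine()


def _validate(config: RunConfig) -> None:
    needed = []
    if config.run_uorf or config.run_kmers or config.run_structure:
        needed.append(("utr5_fasta", config.utr5_fasta))
    if config.run_pas:
        needed.append(("utr3_fasta", config.utr3_fasta))
    if config.run_mirna:
        needed.append(("utr3_fasta", config.utr3_fasta))
        needed.append(("mirna_fasta", config.mirna_fasta))
    if config.run_conservation and not config.ortholog_fastas:
        raise PipelineError("conservation stage enabled but no ortholog FASTAs given")
    missing = [name for name, path in needed if not path]
    if missing:
        raise PipelineError(f"enabled stages need inputs: {sorted(set(missing))}")
    if not any([config.utr5_fasta, config.utr3_fasta, config.cds_fasta]):
        raise PipelineError("at least one input FASTA is required")
    for name, path in needed:
        if path and not Path(path).exists():
            raise PipelineError(f"{name} does not exist: {path}")


def _read_mirnas(path: str) -> dict[str, str]:
    from Bio import SeqIO

    out = {}
    for rec in SeqIO.parse(path, "fasta"):
        out[rec.id] = str(rec.seq).upper().replace("U", "T")
    if not out:
        raise PipelineError(f"no miRNA records in {path}")
    return out


def _table1(config: RunConfig, utr5s: GeneCatalog, engine) -> list[dict]:
    thresholds = TranslationThresholds(
        max_len=config.cart_max_len, min_mfe_per_nt=config.cart_min_mfe_per_nt
    )
    rows = []
    for rec in utr5s:
        mfe = None
        if config.run_structure:
            try:
                mfe = fold(rec.sequence, engine, config.structure_energy_window).mfe
            except ValueError:
                mfe = None  # e.g. toy engine length cap
        profile = build_profile(
            rec.sequence,
            min_codons=config.min_codons,
            require_stop_in_utr=config.require_stop_in_utr,
            mfe_per_nt=(mfe / rec.length if mfe is not None else None),
        )
        cart = assign_translation_class(
            profile, rec.length, gc_content(rec.sequence).gc_percent, thresholds
        )
        rows.append(
            {
                "gene": rec.gene,
                "variant": rec.variant,
                "species": rec.species,
                "length": rec.length,
                "gc_percent": gc_content(rec.sequence).gc_percent,
                "mfe": mfe if mfe is not None else "",
                "n_uaug": profile.n_uaug,
                "n_uorf": profile.n_uorf,
                "uorf_efficiency": efficiency_string(profile.uorfs),
                "uorf_context": context_string(profile.uorfs),
                "cart_class": cart,
            }
        )
    return rows


def _table4(config: RunConfig, utr3s: GeneCatalog, mirnas: dict[str, str] | None,
            engine) -> list[dict]:
    rows = []
    for rec in utr3s:
        sites = annotate_pas(rec.sequence, config.pas_variants, config.pas_window)
        n_acc = n_very = ""
        if mirnas is not None:
            scored = []
            for mirna_id, mirna_seq in mirnas.items():
                for match in find_seed_matches(
                    mirna_seq,
                    rec.sequence,
                    min_seed=config.mirna_min_seed,
                    max_gu=config.mirna_max_gu,
                    max_mismatch=config.mirna_max_mismatch,
                ):
                    scored.append(
                        score_site(
                            match, rec.sequence, mirna_seq, engine,
                            mirna_id=mirna_id, flank=config.mirna_flank,
                        )
                    )
            n_acc, n_very = classify_targets(scored)
        base = {
            "gene": rec.gene,
            "variant": rec.variant,
            "species": rec.species,
            "length": rec.length,
            "accessible_targets": n_acc,
            "very_accessible_targets": n_very,
        }
        if not sites:
            rows.append({**base, "pas_position": "", "pas_hexamer": "",
                         "pas_type": "", "pas_efficiency": ""})
        for site in sites:
            rows.append(
                {
                    **base,
                    "pas_position": site.position,
                    "pas_hexamer": site.hexamer,
                    "pas_type": site.pas_type.value,
                    "pas_efficiency": site.efficiency.value,
                }
            )
    return rows


def run_characterization(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run all enabled stages; returns the report tables and writes TSVs."""
    _validate(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reports: dict[str, pd.DataFrame] = {}

    s_engine = _structure_engine(config) if config.run_structure else None
    m_engine = _mirna_engine(config) if config.run_mirna else None

    utr5s = (
        read_catalog_fasta(config.utr5_fasta, Region.FIVE_PRIME)
        if config.utr5_fasta
        else None
    )
    utr3s = (
        read_catalog_fasta(config.utr3_fasta, Region.THREE_PRIME)
        if config.utr3_fasta
        else None
    )

    if utr5s is not None and (config.run_uorf or config.run_structure):
        rows = _table1(config, utr5s, s_engine)
        reports["table1_like"] = write_feature_table(rows, outdir / "table1_like.tsv")

    if utr3s is not None and (config.run_pas or config.run_mirna):
        mirnas = _read_mirnas(config.mirna_fasta) if config.run_mirna else None
        rows = _table4(config, utr3s, mirnas, m_engine)
        reports["table4_like"] = write_feature_table(rows, outdir / "table4_like.tsv")

    if utr5s is not None and config.run_kmers:
        frame = find_enriched_kmers(
            [r.sequence for r in utr5s],
            k=config.kmer_k,
            markov_order=config.kmer_markov_order,
            two_strand=config.kmer_two_strand,
        )
        frame.to_csv(outdir / "enrichment.tsv", sep="\t", index=False,
                     float_format="%.4g")
        reports["enrichment"] = frame

    if config.run_conservation:
        blocks = []
        for fasta in config.ortholog_fastas:
            catalog = read_catalog_fasta(fasta, Region.FIVE_PRIME)
            labeled = {f"{r.species}:{r.gene}|{r.variant}": r.sequence for r in catalog}
            matrix = distance_matrix(labeled)
            frame = matrix.to_dataframe().reset_index(names="sequence")
            frame.insert(0, "family", Path(fasta).stem)
            blocks.append(frame)
        frame = pd.concat(blocks, ignore_index=True)
        frame.to_csv(outdir / "conservation.tsv", sep="\t", index=False,
                     float_format="%.2f")
        reports["conservation"] = frame

    log = {
        "utrlens_version": __version__,
        "seed": config.seed,
        "structure_engine": config.structure_engine if config.run_structure else None,
        "mirna_engine": config.mirna_engine if config.run_mirna else None,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
    }
    (outdir / "run_log.txt").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return reports
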