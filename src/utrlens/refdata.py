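"""Curated published feature annotations for the mammalian Lipocalin UTR set.

``LIPOCALIN_PAS_ROWS`` lists the published polyadenylation-signal annotation
of human (Hs) and mouse (Mm) Lipocalin 3' UTR variants: UTR length, 1-based
hexamer start position, signal type (C = canonical AAUAAA, NC = AUUAAA,
NC* = rarer variant) and the published efficiency label (VE/E/LE).  A few
mouse labels were published in parentheses; those calls contradict any
distance-based rule (they sit inside the efficient window yet are labelled
LE) and are flagged with ``parenthesized=True`` so benchmarks can report
them as known exceptions rather than silently fitting them.

The table is used to benchmark the default distance-window efficiency rule
(`pas_scan.classify_pas_efficiency`) against independent published calls,
and to parameterize synthetic catalogs with realistic lengths and positions.
"""

from __future__ import annotations

from dataclasses import dataclass

from .pas_scan import PasEfficiency, PasSite, PasType, classify_pas_efficiency

__all__ = ["PasAnnotation", "LIPOCALIN_PAS_ROWS", "pas_rule_agreement"]


@dataclass(frozen=True)
class PasAnnotation:
    species: str  # "Hs" | "Mm"
    label: str  # gene + variant suffix group as published
    utr_length: int
    pas_position: int  # 1-based hexamer start
    pas_type: PasType
    efficiency: PasEfficiency  # published call
    parenthesized: bool = False

    @property
    def distance_to_end(self) -> int:
        return self.utr_length - self.pas_position


def _row(sp, label, length, pos, ptype, eff, paren=False):
    return PasAnnotation(
        sp, label, length, pos, PasType(ptype), PasEfficiency(eff), paren
    )


LIPOCALIN_PAS_ROWS: tuple[PasAnnotation, ...] = (
    # human
    _row("Hs", "APOD_a,b,c", 198, 153, "C", "VE"),
    _row("Hs", "APOD_a,b,c", 198, 68, "NC*", "LE"),
    _row("Hs", "RBP4_b", 388, 211, "NC", "LE"),
    _row("Hs", "RBP4_b", 388, 360, "NC", "E"),
    _row("Hs", "RBP4_b", 388, 112, "NC*", "LE"),
    _row("Hs", "RBP4_b", 388, 130, "NC*", "LE"),
    _row("Hs", "RBP4_c", 186, 112, "NC*", "LE"),
    _row("Hs", "RBP4_c", 186, 130, "NC*", "LE", paren=True),
    _row("Hs", "PTGDS_c", 214, 191, "C", "VE"),
    _row("Hs", "PTGDS_g", 178, 159, "C", "VE"),
    _row("Hs", "PTGDS_j", 639, 142, "C", "LE"),
    _row("Hs", "PTGDS_j", 639, 510, "NC*", "LE"),
    _row("Hs", "PTGDS_j", 639, 621, "NC*", "E"),
    _row("Hs", "APOM_d,e", 121, 97, "C", "VE"),
    _row("Hs", "C8G_a", 193, 175, "NC", "E"),
    _row("Hs", "OBP2A_b", 133, 114, "C", "VE"),
    _row("Hs", "ORM2_b", 122, 94, "C", "VE"),
    _row("Hs", "LCN1_b,h", 185, 166, "NC*", "E"),
    _row("Hs", "LCN2_b", 153, 130, "C", "VE"),
    _row("Hs", "LCN2_b(2)", 334, 315, "C", "VE"),
    _row("Hs", "LCN8_e", 112, 95, "C", "VE"),
    _row("Hs", "LCN12_c,c(2)", 103, 78, "C", "VE"),
    # mouse
    _row("Mm", "Apod_a,b,d", 223, 203, "C", "LE", paren=True),
    _row("Mm", "Apod_c", 1149, 203, "C", "LE"),
    _row("Mm", "Apod_c", 1149, 672, "NC", "LE"),
    _row("Mm", "Apod_c", 1149, 1128, "NC", "E"),
    _row("Mm", "Rbp4_a,d", 252, 114, "NC", "LE"),
    _row("Mm", "Rbp4_a,d", 252, 225, "NC", "E"),
    _row("Mm", "Rbp4_c", 128, 114, "NC", "LE", paren=True),
    _row("Mm", "Ptgds_d", 159, 139, "C", "VE"),
    _row("Mm", "Ptgds_d", 159, 135, "NC*", "E"),
    _row("Mm", "Ptgds_e", 614, 594, "C", "VE"),
    _row("Mm", "Ptgds_e", 614, 590, "NC*", "E"),
    _row("Mm", "Apom_a", 117, 89, "C", "VE"),
    _row("Mm", "C8g_b,c,d", 154, 136, "NC", "E"),
    _row("Mm", "Obp2A_a", 164, 145, "C", "VE"),
    _row("Mm", "Orm2_a", 113, 84, "C", "VE"),
    _row("Mm", "Lcn1_a", 164, 146, "NC*", "E"),
    _row("Mm", "Lcn2_b", 237, 212, "C", "VE"),
    _row("Mm", "Lcn2_b", 237, 216, "NC*", "E"),
    _row("Mm", "Lcn8_a", 107, 85, "C", "VE"),
    _row("Mm", "Lcn12_a", 78, 55, "C", "VE"),
)


def pas_rule_agreement(
    rows: tuple[PasAnnotation, ...] = LIPOCALIN_PAS_ROWS,
    window: tuple[int, int] = (10, 45),
) -> dict:
    """Score the distance-window efficiency rule against the published calls.

    Returns a dict with the number of rows, matches, the agreement fraction
    and the labels of mismatching rows (expected to be the parenthesized
    exceptions under the default window).
    """
    n = len(rows)
    mismatches = []
    for row in rows:
        site = PasSite(position=row.pas_position, hexamer="", pas_type=row.pas_type)
        predicted = classify_pas_efficiency(site, row.utr_length, window)
        if predicted is not row.efficiency:
            mismatches.append(f"{row.species}:{row.label}@{row.pas_position}")
    return {
        "n_rows": n,
        "n_match": n - len(mismatches),
        "agreement": (n - len(mismatches)) / n,
        "mismatches": mismatches,
    }
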