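"""Length / base-composition summaries and the UTR-CDS G+C correlation.

G+C content of 5' UTRs tracks the G+C of the third codon position of the
downstream CDS (both reflect the isochore context of the locus), so the
module provides codon-position-partitioned G+C and an OLS/Pearson analysis of
UTR vs CDS G+C pairs with a 95% confidence band for the regression line.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CompositionSummary",
    "GcCorrelation",
    "gc_content",
    "codon_position_gc",
    "utr_cds_gc_correlation",
]


@dataclass(frozen=True)
class CompositionSummary:
    length: int
    gc_fraction: float

    @property
    def gc_percent(self) -> float:
        return 100.0 * self.gc_fraction


def gc_content(sequence: str) -> CompositionSummary:
    """G+C fraction of a sequence; ``N`` bases are excluded from the denominator.

    Raises ``ValueError`` for an empty sequence or one consisting only of Ns
    (G+C undefined).
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    denom = gc + seq.count("A") + seq.count("T")
    if denom == 0:
        raise ValueError("G+C undefined: sequence contains no unambiguous bases")
    return CompositionSummary(length=len(seq), gc_fraction=gc / denom)


def codon_position_gc(cds: str, position: int | str) -> float:
    """G+C fraction at the requested codon position(s) of an in-frame CDS.

    ``position`` is 1, 2, 3 or 12 (positions 1 and 2 pooled).  The reading
    frame starts at the first base; a trailing partial codon is ignored with a
    warning.
    """
    if len(cds) < 3:
        raise ValueError(f"CDS shorter than one codon ({len(cds)} nt)")
    if len(cds) % 3 != 0:
        warnings.warn(
            f"CDS length {len(cds)} not divisible by 3; trailing partial codon ignored",
            stacklevel=2,
        )
    in_frame = cds.upper()[: 3 * (len(cds) // 3)]
    offsets = {"1": (0,), "2": (1,), "3": (2,), "12": (0, 1)}[str(position)]
    bases = "".join(in_frame[o::3] for o in offsets)
    return gc_content(bases).gc_fraction


@dataclass(frozen=True)
class GcCorrelation:
    """Pearson correlation plus OLS line for (x, y) = (CDS, UTR) G+C pairs.

    ``confidence_band(x)`` gives the half-width of the 95% confidence band of
    the fitted mean at ``x``; ``ci_low``/``ci_high`` evaluate the band bounds.
    """

    r: float
    p_value: float
    slope: float
    intercept: float
    n: int
    mean_x: float
    sxx: float
    residual_se: float

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def confidence_band(self, x, level: float = 0.95):
        x = np.asarray(x, dtype=float)
        t = stats.t.ppf(0.5 + level / 2.0, self.n - 2)
        return t * self.residual_se * np.sqrt(1.0 / self.n + (x - self.mean_x) ** 2 / self.sxx)

    def ci_low(self, x, level: float = 0.95):
        return self.predict(x) - self.confidence_band(x, level)

    def ci_high(self, x, level: float = 0.95):
        return self.predict(x) + self.confidence_band(x, level)


def utr_cds_gc_correlation(
    pairs: Iterable[Sequence[float]],
) -> GcCorrelation:
    """Pearson r (two-sided p) and OLS regression for UTR vs CDS G+C pairs.

    ``pairs`` holds (x, y) tuples, conventionally (CDS third-position G+C,
    UTR G+C) as fractions or percents.  Requires n >= 3 and non-degenerate
    variance on both axes.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (x, y) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance on one axis")
    n = len(x)
    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    # residual SE with n-2 dof; sxx for the confidence band of the mean line
    sxx = float(np.sum((x - x.mean()) ** 2))
    dof = n - 2
    residual_se = math.sqrt(float(np.sum(resid**2)) / dof) if dof > 0 else float("nan")
    return GcCorrelation(
        r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=n,
        mean_x=float(x.mean()),
        sxx=sxx,
        residual_se=residual_se,
    )
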