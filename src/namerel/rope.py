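"""Graded interpretation of reliability correlations via labelled ROPE bands.

Rather than a single reliable/unreliable cutoff, a reliability correlation is
graded against ordered bands (poor / moderate / good / excellent). The
decision rule is region-of-practical-equivalence style: if the 95% credible
interval falls entirely inside one band, that label is accepted outright; if
it spans several bands, the measure is granted *at least* the reliability of
the lowest band the interval touches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = ["RopeBands", "band_of", "classify_reliability"]

#: conventional band lower edges on the printed two-decimal scale
DEFAULT_EDGES = (0.41, 0.61, 0.81)
DEFAULT_LABELS = ("poor", "moderate", "good", "excellent")


@dataclass(frozen=True)
class RopeBands:
    """Contiguous, ordered correlation bands covering (-1, 1].

    ``edges`` are the lower bounds of the 2nd..k-th bands; band i covers
    [edges[i-1], edges[i]) except the first band, which extends down to -1,
    and the last, which is closed at 1. The printed convention labels bands
    as .41–.6, .61–.8, .81–1 with values below .41 "poor"; intervals are
    closed on the left at the printed lower edge.
    """

    edges: Sequence[float] = DEFAULT_EDGES
    labels: Sequence[str] = DEFAULT_LABELS

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.edges) + 1:
            raise ValueError("need exactly one more label than edge")
        if list(self.edges) != sorted(self.edges):
            raise ValueError("edges must be strictly increasing")
        if len(set(self.edges)) != len(self.edges):
            raise ValueError("edges must be strictly increasing")
        if self.edges and not (-1.0 < self.edges[0] and self.edges[-1] <= 1.0):
            raise ValueError("edges must lie in (-1, 1]")

    def band_index(self, value: float) -> int:
        if not -1.0 <= value <= 1.0:
            raise ValueError(f"correlation {value} outside [-1, 1]")
        idx = 0
        for i, edge in enumerate(self.edges):
            if value >= edge:
                idx = i + 1
        return idx

    def band_of(self, value: float) -> str:
        """Label of the band containing ``value``."""
        return self.labels[self.band_index(value)]


def band_of(value: float, bands: RopeBands | None = None) -> str:
    """Label of the band containing a correlation value under default bands."""
    return (bands or RopeBands()).band_of(value)


def classify_reliability(summary, bands: RopeBands | None = None) -> dict:
    """Grade a reliability correlation by where its credible interval falls.

    Parameters
    ----------
    summary : object with ``ci_low`` and ``ci_high`` attributes
        Posterior summary of the correlation (95% equal-tailed interval).
    bands : RopeBands, optional
        Band definitions; defaults to the poor/moderate/good/excellent table.

    Returns
    -------
    dict with keys ``label``, ``qualifier`` ("exactly" if the interval lies
    inside a single band, else "at_least"), and ``bands_used``.
    """
    bands = bands or RopeBands()
    lo, hi = float(summary.ci_low), float(summary.ci_high)
    if lo > hi:
        raise ValueError(f"degenerate interval [{lo}, {hi}]")
    i_lo, i_hi = bands.band_index(lo), bands.band_index(hi)
    qualifier = "exactly" if i_lo == i_hi else "at_least"
    return {
        "label": bands.labels[i_lo],
        "qualifier": qualifier,
        "bands_used": {
            "labels": list(bands.labels),
            "edges": list(bands.edges),
        },
    }
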