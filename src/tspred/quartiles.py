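"""Quartile-to-percentile comparison of ensemble score distributions.

The core statistic of the pipeline.  For each score term, the first three
quartiles of the mutant ensemble's values are located within the wild-type
ensemble's empirical distribution of the same term and expressed as
percentile fractions in [0, 1].  This normalizes away protein-to-protein
differences in absolute energies: a mutant indistinguishable from wild type
maps to ≈ (0.25, 0.50, 0.75), a strongly destabilized one saturates at
(1, 1, 1).

Conventions (the method is distribution-free, so only the empirical
conventions matter):

* quartiles are nearest-rank order statistics — the element at 1-based index
  ceil(p·n) of the ascending sort, p ∈ {0.25, 0.5, 0.75};
* percentiles use the piecewise-linear inverse of the empirical CDF built on
  plotting positions (i − 0.5)/n, linearly extrapolated beyond the extremes
  and then clamped to [0, 1].  Clamping is what lets a far-shifted mutant
  register as exactly 0 or 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, IntegrityError
from .scorefile import ScoreTable

MIN_ENSEMBLE = 4


@dataclass(frozen=True)
class QuartileTriple:
    q1: float
    q2: float
    q3: float

    def __iter__(self):
        return iter((self.q1, self.q2, self.q3))


def quartiles(values) -> QuartileTriple:
    """Nearest-rank quartiles of `values` (needs ≥ 4 values)."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n < MIN_ENSEMBLE:
        raise InsufficientDataError(f"need ≥ {MIN_ENSEMBLE} values, got {n}")
    idx = [math.ceil(p * n) - 1 for p in (0.25, 0.50, 0.75)]
    return QuartileTriple(*(float(v[i]) for i in idx))


def ecdf_percentile(reference, x: float) -> float:
    """Percentile fraction of `x` within the empirical distribution of
    `reference`, clamped to [0, 1].

    Built on the sorted reference with plotting positions (i − 0.5)/n and
    linear interpolation; beyond the observed extremes the first/last
    distinct segment is extended linearly before clamping.  Ties in the
    reference are handled by the interpolation over the sorted positions.
    """
    ref = np.sort(np.asarray(reference, dtype=float))
    n = ref.size
    if n < MIN_ENSEMBLE:
        raise InsufficientDataError(f"need ≥ {MIN_ENSEMBLE} reference values, got {n}")
    pp = (np.arange(1, n + 1) - 0.5) / n
    if ref[0] == ref[-1]:  # degenerate constant reference
        return 0.5 if x == ref[0] else (0.0 if x < ref[0] else 1.0)
    if x < ref[0]:
        j = int(np.argmax(ref > ref[0]))
        slope = (pp[j] - pp[0]) / (ref[j] - ref[0])
        val = pp[0] + slope * (x - ref[0])
    elif x > ref[-1]:
        j = n - 1 - int(np.argmax(ref[::-1] < ref[-1]))
        slope = (pp[-1] - pp[j]) / (ref[-1] - ref[j])
        val = pp[-1] + slope * (x - ref[-1])
    else:
        val = float(np.interp(x, ref, pp))
    return float(min(1.0, max(0.0, val)))


def quartile_feature_names(terms: list[str]) -> list[str]:
    return [f"{t}Q{k}" for t in terms for k in (1, 2, 3)]


def quartile_feature_vector(
    mutant: ScoreTable, wt: ScoreTable, terms: list[str] | None = None
) -> dict[str, float]:
    """Three features per term: "{term}Q1..Q3" = percentile of each mutant
    quartile within the wild-type values of the same term.

    With the full 31-term score table this yields 93 features."""
    if terms is None:
        terms = mutant.term_names
    features: dict[str, float] = {}
    for term in terms:
        if term not in mutant.data.columns:
            raise IntegrityError(f"term {term!r} missing from mutant ensemble")
        if term not in wt.data.columns:
            raise IntegrityError(f"term {term!r} missing from wild-type ensemble")
        ref = wt.term_values(term)
        for k, q in zip((1, 2, 3), quartiles(mutant.term_values(term))):
            features[f"{term}Q{k}"] = ecdf_percentile(ref, q)
    return features
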