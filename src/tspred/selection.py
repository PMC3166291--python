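"""Correlation-based redundancy detection and the shipped pruning plan.

Features derived from one Rosetta score term (its Q1/Q2/Q3 trio) are always
kept or removed together; individual non-Rosetta features are pruned by
name.  The default plan encodes the removal lists established for the
original training set: redundant Rosetta-term groups (keeping the first term
of each group), the identically-zero irms trio, the secondary-structure
indicators (which degraded performance), the frequency features (redundant
with their PSSM log-odds counterparts), and one of the two category-change
codings.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .scorefile import FeatureMatrix

_QUARTILE_RE = re.compile(r"^(?P<term>.+)Q[123]$")


@dataclass
class PruningPlan:
    """removed_terms drop a whole {term}Q1..Q3 trio each; removed_features
    drop individual non-Rosetta features."""

    removed_terms: list[str] = field(default_factory=list)
    removed_features: list[str] = field(default_factory=list)
    threshold: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise InputError(f"threshold {self.threshold} outside [0, 1]")

    def removed_names(self, feature_names: list[str]) -> set[str]:
        removed = set()
        for name in feature_names:
            m = _QUARTILE_RE.match(name)
            if m and m.group("term") in self.removed_terms:
                removed.add(name)
            elif name in self.removed_features:
                removed.add(name)
        return removed


@dataclass
class CorrelationReport:
    pairs: list[tuple[str, str, float]]  # sorted by descending |r|
    degenerate: list[str]                # zero-variance features (unpaired)


def correlated_pairs(m: FeatureMatrix, threshold: float = 0.9) -> CorrelationReport:
    """All unordered feature pairs with |Pearson r| ≥ threshold.

    Zero-variance features cannot carry a correlation; they are reported in
    the degenerate side channel instead of being paired."""
    if m.shape[0] < 3:
        raise InputError("need ≥ 3 samples to estimate correlations")
    values = m.data.to_numpy(dtype=float)
    names = m.feature_names
    sd = values.std(axis=0)
    live = sd > 0
    degenerate = [n for n, ok in zip(names, live) if not ok]
    live_idx = np.flatnonzero(live)
    pairs: list[tuple[str, str, float]] = []
    if live_idx.size >= 2:
        corr = np.corrcoef(values[:, live_idx], rowvar=False)
        for a in range(live_idx.size):
            for b in range(a + 1, live_idx.size):
                r = float(corr[a, b])
                if abs(r) >= threshold:
                    pairs.append((names[live_idx[a]], names[live_idx[b]], r))
    pairs.sort(key=lambda p: (-abs(p[2]), p[0], p[1]))
    return CorrelationReport(pairs, degenerate)


def default_pruning_plan() -> PruningPlan:
    """The shipped removal lists.

    Rosetta-term trios: fa_atr, fa_sol, fa_intra_rep (redundant with the kept
    fa_dun), maxsub (redundant with gdtmm7_4), rms (redundant with gdtmm2_2),
    and irms (identically zero).  Individual features: the ss indicators,
    the freq_* features (redundant with pssm_*), and aminochange (the
    four-category coding; the seven-category aminochange2 is kept).
    """
    return PruningPlan(
        removed_terms=["fa_atr", "fa_sol", "fa_intra_rep", "maxsub", "rms", "irms"],
        removed_features=[
            "ss_H", "ss_S", "ss_L",
            "freq_mut", "freq_nat", "freq_diff",
            "aminochange",
        ],
    )


def apply_pruning(m: FeatureMatrix, plan: PruningPlan) -> FeatureMatrix:
    """Drop the plan's features from the matrix; sample order unchanged.
    Plan names absent from the matrix warn rather than fail, so one plan can
    serve matrices built with feature subsets."""
    removed = plan.removed_names(m.feature_names)
    missing_trios = [t for t in plan.removed_terms
                     if not any(_QUARTILE_RE.match(n) and n[: -2] == t
                                for n in m.feature_names)]
    missing = [f for f in plan.removed_features if f not in m.feature_names]
    if missing_trios or missing:
        warnings.warn(
            f"pruning plan names absent from matrix: terms={missing_trios} "
            f"features={missing}", stacklevel=2,
        )
    kept = [n for n in m.feature_names if n not in removed]
    if not kept:
        raise InputError("pruning would remove every feature")
    return m.select(kept)
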