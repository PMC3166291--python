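# Methods

This note records the statistical conventions, default parameters, and open
design choices behind `tspred`, in the spirit of a model-description page:
what is computed, under which assumptions, and what the synthetic tests do
and do not demonstrate.

## The quartile-percentile statistic

For one score term with mutant-ensemble values S and wild-type values S′:

* **Quartiles** are nearest-rank order statistics: the element at 1-based
  index ⌈p·|S|⌉ of the ascending sort, p ∈ {0.25, 0.5, 0.75}.  For |S| = 50
  the fractional positions (12.5, 25, 37.5) are not integral, and
  nearest-rank is the simplest convention consistent with "the value at
  position p·|S|"; it is exact for the constant-ensemble and small-n cases
  and keeps Q1 ≤ Q2 ≤ Q3 by construction.
* **Percentiles** use the piecewise-linear inverse of the empirical CDF on
  plotting positions (i − 0.5)/n over the sorted reference, with linear
  extrapolation beyond the extremes followed by clamping to [0, 1].  The
  clamping step is essential to the design: a mutant ensemble shifted far
  outside the wild-type range must register as exactly 0 or 1, which a pure
  "fraction ≤ x" estimator can never produce below 0 or above 1.
  Consequences: a self-comparison maps each quartile to within 1/(2n) of
  (0.25, 0.5, 0.75); the statistic is invariant under strictly increasing
  transforms of a term up to interpolation error ≤ 1/n; ties in the
  reference are handled implicitly by interpolation across the tied
  plotting positions (mid-range behaviour).
* A constant reference (zero spread, e.g. an identically-zero term) is
  degenerate; the percentile is defined as 0/0.5/1 for values
  below/at/above it.

Ensembles need at least 4 values; fewer raise an insufficient-data error.

## Features and pruning

Three families: 93 quartile features (31 score terms × Q1–Q3); structure
features ACCP (percent side-chain accessibility, 0–100) and one-hot ss_H /
ss_S / ss_L; sequence features aminochange (4-class partition), aminochange2
(7-class), pssm_nat/mut/diff (half-bit integer log-odds), freq_nat/mut/diff
(observed percentages) and info_cont (bits).  The category partitions are
configuration data, not code:

* 4-class: nonpolar {A V L I M F W Y}, polar {S T N Q C H},
  charged {D E K R}, special {G P};
* 7-class: small nonpolar {A V}, large hydrophobic {L I M F W Y},
  polar {S T N Q C}, positive {K R H}, negative {D E}, {G}, {P}.

The shipped pruning plan removes, always as whole Q1–Q3 trios per score
term: fa_atr, fa_sol, fa_intra_rep (redundant with the kept fa_dun), maxsub
(with gdtmm7_4), rms (with gdtmm2_2), and irms (identically zero), plus the
individual features ss_H/ss_S/ss_L (degrade performance), freq_* (redundant
with pssm_*), and aminochange (the 7-class aminochange2 is kept; which of
the pair survives is configurable).  Correlation screening uses Pearson r
with default threshold 0.9; rank correlation was considered and rejected
because the quartile features are already rank-based.  Burial uses an
inclusive cutoff (≤ 10 % accessible), exposed as a flag.

## Classifiers

Features are min-max scaled to [0, 1] on training data only (the quartile
features already live there; PSSM and ACCP features do not).  The
quadratic-programming fit is delegated to scikit-learn's SVC; the trained
model stores support vectors, dual coefficients αᵢyᵢ, bias, scaling, and
calibration, and all downstream scoring recomputes the kernel expansion from
those fields, so persistence (JSON) reproduces decision values exactly.

Confidence calibration is a slope-only Platt sigmoid p = σ(a·f(x)), a > 0,
fitted by maximum likelihood on out-of-fold margins from a 3-fold stratified
internal split.  The intercept is deliberately omitted so that p > 0.5 holds
exactly when the decision function is positive — the ranked output and the
label assignment can never disagree.  The cost is a small loss of
calibration flexibility on imbalanced sets; ranking (the primary output) is
unaffected, being invariant under any strictly monotone recalibration.
No class weighting is applied by default for the 75/130 imbalance.

Ties in ranked output break by mutation id, ascending, for determinism.
Output format: header `rank conf id`, confidence to 3 decimals, id
`{protein}-{native}{position}_{MUT3}_{species}`.

## Cross-validation and metrics

Folds are stratified by class (unstratified folds on a 75/130 set can leave
a fold without ts samples, making ts precision undefined) and deterministic
from a single seed; repeated CV reseeds each repetition as seed + r.
The nested 5× leave-out scheme makes five disjoint stratified 80/20 splits;
each 80 % hosts a (C, γ) grid search scored by ts-class precision of
repeated inner CV (AUROC available as an alternative objective), the winner
is retrained on the full 80 % and scored once on the 20 %.  Reported
hyperparameters are component-wise medians of the five winners in log₂
space.  The default lattice is C ∈ 2⁻⁵…2¹⁵, γ ∈ 2⁻¹⁵…2³ at steps of 2² in
the exponent; the test suite and acceptance script use a reduced 5×5 lattice
(C ∈ 2⁻¹…2⁷, γ ∈ 2⁻⁹…2⁻¹) to keep a full nested run under a minute on one
CPU — the problem sizes used there (205 samples, 50-decoy ensembles) are the
package's chosen study scale.  A grid point whose inner CV predicts no ts at
all scores precision 0, so the degenerate always-negative classifier is
never selected.

Metrics are implemented directly and cross-checked against independent
references in the tests: AUROC as the tie-aware average-rank statistic
(≡ Mann–Whitney U / n₁n₀, the probability that a random ts sample outranks
a random non-ts sample); AUPR as the step-sum average precision;
point-biserial correlation as (M₁ − M₀)/sₙ · √(pq) with the population
standard deviation, identical to Pearson correlation with 0/1 coding.
Single-class truth vectors raise an undefined-metric error rather than
returning a default.

## The synthetic study

The generator emulates the upstream inputs at the study's shape: 75 ts /
130 non-ts mutations, 50 decoys per ensemble, 31 score terms with
term-specific locations and spreads of plausible magnitude (the statistic is
location/scale-free, so the magnitudes are cosmetic).

The planted rule operationalizes the intermediate-destabilization premise:
each mutation carries a displacement δ in wild-type-spread units; it is ts
iff δ ∈ [1.5, 4] (the ts band).  Non-ts mutations are 70 % tolerated
(δ below the band) and 30 % loss-of-function (δ above), reflecting that
curated non-ts sets skew toward tolerated substitutions; the asymmetry also
gives a linear classifier a recoverable signed signal.  Spread inflation
grows with destabilization, κ = 1 + 0.25·δ.  Five designated sensitive
terms (score, Repack_stdev_score, p_aa_pp, gdtmm4_3, gdtmm7_4) receive the
full displacement; irms, ref and the disulfide terms receive none (they are
flat or composition-only in real output); all remaining terms co-move at an
attenuated ρ·δ with ρ = 0.3.  The co-movement tier is a deliberate realism
choice: the overall score is a weighted sum of its component terms, so
component terms cannot be independent of the destabilization that moves the
total.  It also matters statistically — with fully independent secondary
terms, the RBF kernel distance is dominated by 66 noise features and
held-out recovery saturates near AUROC 0.8, whereas the co-moving generator
supports ≈ 0.99, insensitive to ρ across [0.2, 0.4].

Sequence and structure features are generated per-sample (random 20-residue
proteins, conservation U(0.2, 0.9), burial U(0, 10 %)) and carry **no**
planted signal; the sequence-only SVM-seq variant therefore scores at
chance on synthetic data, which mirrors — but deliberately exaggerates —
its weakness on real data.

What passing synthetic tests show: the feature extraction, pruning,
training, calibration, nested validation and ranking machinery recover a
planted intermediate-band signal end-to-end, deterministically from one
seed.  What they do not show: performance on real mutations.  Real score
terms are correlated in ways the independent-Gaussian generator ignores,
real ts behaviour has causes other than stability loss, and real sequence
conservation is informative; published-scale precision/AUROC values require
the curated multi-species training set plus full structure-relax ensembles
and are out of scope here.

## Known limitations

* The score-file reader handles the plain-text `SCORE:` dialect only — no
  silent files, compressed files, or PDB payloads.
* PSSMs are parsed from the ASCII PSI-BLAST layout; running BLAST/PSI-BLAST
  is out of scope.
* Accessibility is consumed from a table (position, aa, fraction, ss);
  computing SASA from coordinates is delegated to external tools.
* The relax/rescore stage is external by design: `generate` writes command
  manifests, never executes them.
* Whether the merged "score" column should come from the relax or the
  rescore run is ambiguous in Rosetta's own outputs; the merge rule lets
  the rescore value win on any term-name collision, documented here and in
  the reader's docstring.
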