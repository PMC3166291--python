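"""Synthetic stand-ins for every upstream input of the pipeline.

Real inputs come from Rosetta relax/score runs, Probe accessibility, and
PSI-BLAST — none of which are needed to exercise the statistics.  The
generators here emulate their outputs:

* per-term wild-type score distributions (independent Gaussians with
  term-specific location and spread, 50 decoys by default);
* mutant ensembles whose destabilization-sensitive terms are displaced by
  δ wild-type spreads and inflated by a factor κ ≥ 1;
* a planted labelling rule operationalizing the premise that ts mutations
  sit in an intermediate destabilization window: a mutation is ts iff its
  δ falls inside the ts band (default [1.5, 4] wt-spread units), with
  tolerated (δ below) and loss-of-function (δ above) mutations labelled
  non-ts;
* synthetic PSSMs with controllable per-position conservation, serialized
  in the same ASCII dialect the parser reads.

The training-set generator runs the real feature pipeline (quartile
mapping + sequence/structure features) on these ensembles, so everything
downstream of Rosetta is tested end-to-end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .quartiles import quartile_feature_vector
from .scorefile import FeatureMatrix, ScoreTable, write_scorefile
from .seqfeat import (FOUR_CATEGORY, SEVEN_CATEGORY, PSSM, aminochange,
                      sequence_features, structure_features, write_pssm)
from .sites import AMINO_ACIDS, SS_CODES, MutationSpec, ResidueAccessibility

# The 31 score terms of a merged relax+rescore table: energy terms from the
# relax run, Repack_* summaries, and structural-comparison terms from the
# rescore run.
SCORE_TERMS = (
    "score", "fa_atr", "fa_rep", "fa_sol", "fa_intra_rep", "pro_close",
    "fa_pair", "hbond_sr_bb", "hbond_lr_bb", "hbond_bb_sc", "hbond_sc",
    "dslf_ss_dst", "dslf_cs_ang", "dslf_ss_dih", "dslf_ca_dih", "rama",
    "omega", "fa_dun", "p_aa_pp", "ref", "Repack_average_score",
    "Repack_stdev_score", "gdtmm1_1", "gdtmm2_2", "gdtmm3_3", "gdtmm4_3",
    "gdtmm7_4", "irms", "maxsub", "maxsub2.0", "rms",
)

# Terms displaced by destabilization in the mutant generator; echoes the
# terms that carry the classification signal on real data.
DEFAULT_SENSITIVE_TERMS = (
    "score", "Repack_stdev_score", "p_aa_pp", "gdtmm4_3", "gdtmm7_4",
)

# Terms with no destabilization response at all: irms is identically (near)
# zero, ref depends only on composition, and the disulfide terms are zero
# for proteins without disulfides.  Every other term co-moves weakly with
# destabilization — the overall score is a weighted sum of its components,
# so fully independent component terms would be physically inconsistent.
UNRESPONSIVE_TERMS = (
    "irms", "ref", "dslf_ss_dst", "dslf_cs_ang", "dslf_ss_dih", "dslf_ca_dih",
)

# (location, spread) per term, roughly in the range the relax protocol
# prints for a mid-size domain; magnitudes are plausible but arbitrary —
# the quartile mapping is location/scale-free by construction.
_DEFAULT_TERM_PARAMS: dict[str, tuple[float, float]] = {
    "score": (-250.0, 8.0), "fa_atr": (-480.0, 6.0), "fa_rep": (60.0, 4.0),
    "fa_sol": (270.0, 5.0), "fa_intra_rep": (1.5, 0.15),
    "pro_close": (2.0, 0.5), "fa_pair": (-8.0, 1.0),
    "hbond_sr_bb": (-25.0, 2.0), "hbond_lr_bb": (-18.0, 2.0),
    "hbond_bb_sc": (-12.0, 1.5), "hbond_sc": (-9.0, 1.5),
    "dslf_ss_dst": (0.0, 0.05), "dslf_cs_ang": (0.0, 0.05),
    "dslf_ss_dih": (0.0, 0.05), "dslf_ca_dih": (0.0, 0.05),
    "rama": (-15.0, 2.0), "omega": (35.0, 3.0), "fa_dun": (180.0, 5.0),
    "p_aa_pp": (-20.0, 2.0), "ref": (25.0, 0.5),
    "Repack_average_score": (-248.0, 8.0), "Repack_stdev_score": (3.0, 0.8),
    "gdtmm1_1": (0.55, 0.04), "gdtmm2_2": (0.75, 0.04),
    "gdtmm3_3": (0.85, 0.03), "gdtmm4_3": (0.88, 0.03),
    "gdtmm7_4": (0.95, 0.02), "irms": (0.0, 1e-6),
    "maxsub": (120.0, 5.0), "maxsub2.0": (95.0, 5.0), "rms": (1.2, 0.3),
}


@dataclass
class EnsembleModel:
    """Wild-type score-distribution model: per-term (μ_t, σ_t), ensemble
    size, and noise family."""

    term_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_TERM_PARAMS))
    ensemble_size: int = 50
    noise: str = "normal"

    def __post_init__(self) -> None:
        if self.ensemble_size < 4:
            raise InputError("ensemble_size must be ≥ 4")
        if self.noise not in ("normal", "lognormal"):
            raise InputError(f"unknown noise family {self.noise!r}")
        for term, (_, sigma) in self.term_params.items():
            if sigma <= 0:
                raise InputError(f"σ must be > 0 (term {term})")

    @property
    def terms(self) -> list[str]:
        return list(self.term_params)


@dataclass
class MutationEffect:
    """Displacement δ (in wt-spread units) and spread inflation κ applied to
    the sensitive terms; the planted label is ts iff δ lies in ts_band.

    Non-sensitive, non-unresponsive terms receive the attenuated shift
    ρ·δ·σ (ρ = secondary_response) without inflation, mirroring the weak
    co-movement of component terms with overall destabilization."""

    delta: float
    kappa: float = 1.0
    ts_band: tuple[float, float] = (1.5, 4.0)
    sensitive_terms: tuple[str, ...] = DEFAULT_SENSITIVE_TERMS
    secondary_response: float = 0.3
    unresponsive_terms: tuple[str, ...] = UNRESPONSIVE_TERMS

    def __post_init__(self) -> None:
        if self.kappa < 1.0:
            raise InputError("κ must be ≥ 1")
        if not 0.0 <= self.secondary_response <= 1.0:
            raise InputError("secondary_response must be in [0, 1]")
        lo, hi = self.ts_band
        if not lo < hi:
            raise InputError("ts_band must satisfy δ_lo < δ_hi")

    @property
    def is_ts(self) -> bool:
        lo, hi = self.ts_band
        return lo <= self.delta <= hi


def _draw(rng: np.random.Generator, mu: float, sigma: float, n: int,
          noise: str) -> np.ndarray:
    if noise == "normal":
        return rng.normal(mu, sigma, size=n)
    return mu + sigma * (rng.lognormal(0.0, 0.5, size=n) - np.exp(0.125))


def generate_wt_ensemble(
    model: EnsembleModel, seed: int, ensemble_id: str = "WT"
) -> ScoreTable:
    """ensemble_size decoys with independent per-term draws."""
    rng = np.random.default_rng(seed)
    n = model.ensemble_size
    data = {t: _draw(rng, mu, sigma, n, model.noise)
            for t, (mu, sigma) in model.term_params.items()}
    tags = [f"{ensemble_id}_{i + 1:04d}" for i in range(n)]
    return ScoreTable(ensemble_id, pd.DataFrame(data, index=tags))


def generate_mutant_ensemble(
    model: EnsembleModel, effect: MutationEffect, seed: int,
    ensemble_id: str = "MUT",
) -> ScoreTable:
    """Like the wild type, but sensitive terms are drawn at μ + δσ with
    spread κσ, secondary terms at μ + ρδσ with spread σ, and unresponsive
    terms share the wild-type model."""
    rng = np.random.default_rng(seed)
    n = model.ensemble_size
    data = {}
    for t, (mu, sigma) in model.term_params.items():
        if t in effect.sensitive_terms:
            data[t] = _draw(rng, mu + effect.delta * sigma,
                            effect.kappa * sigma, n, model.noise)
        elif t in effect.unresponsive_terms:
            data[t] = _draw(rng, mu, sigma, n, model.noise)
        else:
            data[t] = _draw(rng, mu + effect.secondary_response * effect.delta * sigma,
                            sigma, n, model.noise)
    tags = [f"{ensemble_id}_{i + 1:04d}" for i in range(n)]
    return ScoreTable(ensemble_id, pd.DataFrame(data, index=tags))


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def generate_pssm(sequence: str, conservation_profile, seed: int) -> PSSM:
    """A PSSM whose per-position observed percentages concentrate on the
    native residue according to the conservation profile (scalar or
    per-position array of fractions).  Log-odds are half-bit integers
    consistent with the frequencies against a uniform 5% background;
    information content is the KL divergence from that background (bits).
    All values are quantized exactly as the ASCII serialization prints them,
    so serialize → parse is the identity.
    """
    for aa in sequence:
        if aa not in AMINO_ACIDS:
            raise InputError(f"non-canonical residue {aa!r} in sequence")
    rng = np.random.default_rng(seed)
    L = len(sequence)
    cons = np.broadcast_to(np.asarray(conservation_profile, dtype=float), (L,))
    if ((cons < 0) | (cons > 1)).any():
        raise InputError("conservation must be in [0, 1]")
    aas = list(AMINO_ACIDS)
    positions = list(range(1, L + 1))
    freq_rows, lo_rows, info = [], [], []
    for i, pos in enumerate(positions):
        native = sequence[i]
        nat_pct = int(round(cons[i] * 100))
        rest = 100 - nat_pct
        others = [a for a in aas if a != native]
        weights = rng.dirichlet(np.ones(len(others)))
        alloc = rng.multinomial(rest, weights)
        freq = {a: int(n) for a, n in zip(others, alloc)}
        freq[native] = nat_pct
        f = np.array([freq[a] for a in aas], dtype=float) / 100.0
        # half-bit log-odds with a +1/+20 pseudocount to keep them finite
        p = (np.array([freq[a] for a in aas], dtype=float) + 1.0) / 120.0
        lo = np.round(2.0 * np.log2(p / 0.05)).astype(int)
        ic = float(np.round(np.sum(f[f > 0] * np.log2(f[f > 0] / 0.05)), 2))
        freq_rows.append([freq[a] for a in aas])
        lo_rows.append(lo.tolist())
        info.append(max(ic, 0.0))
    return PSSM(
        native_aa=pd.Series(list(sequence), index=positions),
        log_odds=pd.DataFrame(lo_rows, index=positions, columns=aas),
        frequencies=pd.DataFrame(freq_rows, index=positions, columns=aas),
        info_content=pd.Series(info, index=positions, dtype=float),
    )


def _sample_delta(rng: np.random.Generator, ts: bool,
                  ts_band: tuple[float, float],
                  tolerated_fraction: float,
                  lethal_extent: float) -> float:
    lo, hi = ts_band
    if ts:
        return float(rng.uniform(lo, hi))
    if rng.uniform() < tolerated_fraction:
        return float(rng.uniform(0.0, lo * 0.95))
    return float(rng.uniform(hi * 1.05, hi + lethal_extent))


def generate_training_set(
    n_ts: int = 75,
    n_nonts: int = 130,
    ts_band: tuple[float, float] = (1.5, 4.0),
    tolerated_fraction: float = 0.7,
    lethal_extent: float = 4.0,
    sensitive_terms: tuple[str, ...] = DEFAULT_SENSITIVE_TERMS,
    kappa_per_delta: float = 0.25,
    ensemble_size: int = 50,
    wt_model: EnsembleModel | None = None,
    seed: int = 0,
    species: str = "Synt",
) -> FeatureMatrix:
    """A labelled feature matrix built by the real feature pipeline on
    synthetic ensembles and PSSMs.

    ts samples draw δ uniformly inside the ts band; non-ts samples draw
    below it (tolerated, fraction `tolerated_fraction`) or above it
    (loss-of-function).  Spread inflation grows with destabilization:
    κ = 1 + kappa_per_delta·δ.  Sequence and structure features come from
    per-sample synthetic proteins and carry no planted label signal.
    """
    if n_ts < 1 or n_nonts < 1:
        raise InputError("need at least one sample per class")
    if wt_model is None:
        wt_model = EnsembleModel(ensemble_size=ensemble_size)
    master = np.random.default_rng(seed)
    rows: list[dict[str, float]] = []
    ids: list[str] = []
    labels: list[str] = []
    flags = [True] * n_ts + [False] * n_nonts
    for i, is_ts in enumerate(flags):
        rng = np.random.default_rng(master.integers(2**31))
        delta = _sample_delta(rng, is_ts, ts_band, tolerated_fraction,
                              lethal_extent)
        effect = MutationEffect(delta, 1.0 + kappa_per_delta * delta,
                                ts_band, sensitive_terms)
        s_wt, s_mut, s_pssm = (int(rng.integers(2**31)) for _ in range(3))
        wt = generate_wt_ensemble(wt_model, s_wt)
        mut = generate_mutant_ensemble(wt_model, effect, s_mut)
        feats = quartile_feature_vector(mut, wt, list(SCORE_TERMS))

        # per-sample synthetic protein context (no planted label signal)
        length = 20
        seq = random_sequence(rng, length)
        pos = int(rng.integers(1, length + 1))
        native = seq[pos - 1]
        mutant = rng.choice([a for a in AMINO_ACIDS if a != native])
        spec = MutationSpec(f"SYN{i:04d}", species, pos, native, str(mutant))
        pssm = generate_pssm(seq, rng.uniform(0.2, 0.9, size=length), s_pssm)
        feats["aminochange"] = aminochange(native, mutant, FOUR_CATEGORY)
        feats["aminochange2"] = aminochange(native, mutant, SEVEN_CATEGORY)
        feats.update(sequence_features(pssm, spec))
        residue = ResidueAccessibility(pos, native,
                                       float(rng.uniform(0.0, 0.10)),
                                       str(rng.choice(SS_CODES)))
        feats.update(structure_features([residue], spec))

        rows.append(feats)
        ids.append(spec.prediction_id)
        labels.append("ts" if effect.is_ts else "non-ts")
    data = pd.DataFrame(rows, index=ids)
    return FeatureMatrix(data, pd.Series(labels, index=ids))


def materialize_workspace(
    directory: str | Path,
    protein: str = "TOY1",
    species: str = "Synt",
    n_residues: int = 8,
    n_buried: int = 2,
    ensemble_size: int = 50,
    seed: int = 0,
) -> dict[str, Path]:
    """Write a complete offline toy workspace: accessibility table, PSSM,
    wild-type and per-mutation score files.  Returns the paths written."""
    from .sites import enumerate_mutations, select_buried_sites

    directory = Path(directory)
    scores = directory / "scores"
    scores.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    seq = random_sequence(rng, n_residues)
    acc = rng.uniform(0.15, 0.8, size=n_residues)
    buried_idx = rng.choice(n_residues, size=n_buried, replace=False)
    acc[buried_idx] = rng.uniform(0.0, 0.08, size=n_buried)
    residues = [
        ResidueAccessibility(i + 1, seq[i], float(acc[i]), str(rng.choice(SS_CODES)))
        for i in range(n_residues)
    ]
    acc_path = directory / f"{protein}.acc.tsv"
    acc_path.write_text(
        "# position aa acc_fraction ss\n"
        + "\n".join(f"{r.position}\t{r.native_aa}\t{r.acc_fraction:.4f}\t{r.ss}"
                    for r in residues) + "\n"
    )

    pssm = generate_pssm(seq, rng.uniform(0.3, 0.9, size=n_residues),
                         int(rng.integers(2**31)))
    pssm_path = directory / f"{protein}.pssm"
    write_pssm(pssm, pssm_path, query_id=protein)

    model = EnsembleModel(ensemble_size=ensemble_size)
    wt = generate_wt_ensemble(model, int(rng.integers(2**31)),
                              ensemble_id=f"{protein}-WT")
    wt_path = scores / f"{protein}-WT.sc"
    write_scorefile(wt, wt_path)

    buried = select_buried_sites(residues, 0.10)
    specs = enumerate_mutations(protein, species, buried, residues)
    for spec in specs:
        delta = float(rng.uniform(0.0, 6.0))
        effect = MutationEffect(delta, 1.0 + 0.25 * delta)
        mut = generate_mutant_ensemble(model, effect, int(rng.integers(2**31)),
                                       ensemble_id=spec.job_name)
        write_scorefile(mut, scores / f"{spec.job_name}.sc")

    return {"accessibility": acc_path, "pssm": pssm_path, "wt_scores": wt_path,
            "scores_dir": scores}
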