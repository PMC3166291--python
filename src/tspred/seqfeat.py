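"""Sequence- and structure-based features outside the Rosetta score terms.

Covers the amino-acid category-change codes (two partitions of the 20
residues into physicochemical classes), the PSI-BLAST PSSM-derived features
(log-odds, observed frequencies, information content), and the two
non-Rosetta structure features (percent accessibility, secondary-structure
indicators).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, InputError, IntegrityError
from .sites import AMINO_ACIDS, SS_CODES, MutationSpec, ResidueAccessibility


@dataclass(frozen=True)
class CategoryScheme:
    """A named partition of the 20 canonical amino acids into disjoint
    classes; used to code how drastic a substitution is."""

    name: str
    groups: dict[str, str]  # group name -> string of member residues

    def __post_init__(self) -> None:
        members = "".join(self.groups.values())
        if sorted(members) != sorted(AMINO_ACIDS):
            raise InputError(
                f"scheme {self.name!r} must partition the 20 amino acids"
            )

    def category_of(self, aa: str) -> str:
        for name, members in self.groups.items():
            if aa in members:
                return name
        raise InputError(f"non-canonical amino acid {aa!r}")


# Default partitions.  Four-class: broad nonpolar / polar / charged plus the
# conformationally special Gly and Pro.  Seven-class: splits size within the
# nonpolar set and sign within the charged set, and isolates Gly and Pro.
FOUR_CATEGORY = CategoryScheme(
    "aminochange",
    {
        "nonpolar": "AVLIMFWY",
        "polar": "STNQCH",
        "charged": "DEKR",
        "special": "GP",
    },
)
SEVEN_CATEGORY = CategoryScheme(
    "aminochange2",
    {
        "small_nonpolar": "AV",
        "large_hydrophobic": "LIMFWY",
        "polar": "STNQC",
        "positive": "KRH",
        "negative": "DE",
        "glycine": "G",
        "proline": "P",
    },
)


def aminochange(native_aa: str, mutant_aa: str, scheme: CategoryScheme) -> int:
    """0 = same residue, 1 = different residue in the same class,
    2 = class change."""
    for aa in (native_aa, mutant_aa):
        if aa not in AMINO_ACIDS:
            raise InputError(f"non-canonical amino acid {aa!r}")
    if native_aa == mutant_aa:
        return 0
    if scheme.category_of(native_aa) == scheme.category_of(mutant_aa):
        return 1
    return 2


@dataclass
class PSSM:
    """A PSI-BLAST position-specific scoring matrix.

    log_odds holds the half-bit integer log-likelihood scores, frequencies
    the observed percentages (0–100), info_content the per-position
    information in bits.  Both frames are indexed by 1-based position with
    one column per amino acid.
    """

    native_aa: pd.Series       # position -> one-letter code
    log_odds: pd.DataFrame     # positions × 20
    frequencies: pd.DataFrame  # positions × 20
    info_content: pd.Series    # position -> bits

    def __post_init__(self) -> None:
        for frame, what in ((self.log_odds, "log_odds"), (self.frequencies, "frequencies")):
            if sorted(frame.columns) != sorted(AMINO_ACIDS):
                raise IntegrityError(f"{what} must have exactly the 20 amino-acid columns")
        if (self.info_content < 0).any():
            raise IntegrityError("information content must be ≥ 0")

    @property
    def positions(self) -> list[int]:
        return list(self.log_odds.index)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PSSM):
            return NotImplemented
        cols = sorted(AMINO_ACIDS)
        return (
            self.native_aa.equals(other.native_aa)
            and self.log_odds[cols].equals(other.log_odds[cols])
            and self.frequencies[cols].equals(other.frequencies[cols])
            and self.info_content.equals(other.info_content)
        )


def parse_pssm(path: str | Path) -> PSSM:
    """Parse an NCBI PSI-BLAST ASCII PSSM.

    The amino-acid column order is taken from the file's own header line
    (first 20 letters for log-odds, second 20 for observed percentages),
    never assumed.  Each data row must carry position, residue, 40 integers
    and the information-content column (a trailing relative-weight column is
    tolerated).
    """
    path = Path(path)
    lo_order: list[str] | None = None
    fr_order: list[str] | None = None
    natives: dict[int, str] = {}
    lo_rows: dict[int, list[int]] = {}
    fr_rows: dict[int, list[int]] = {}
    info: dict[int, float] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        tokens = raw.split()
        if lo_order is None:
            if len(tokens) == 40 and all(t in AMINO_ACIDS for t in tokens):
                lo_order, fr_order = tokens[:20], tokens[20:]
            continue
        if not tokens or not tokens[0].isdigit():
            continue  # footer statistics (K, Lambda, ...) or blank
        pos = int(tokens[0])
        if len(tokens) < 43:
            raise FormatError(
                f"{path}:{lineno}: truncated row at position {pos} "
                f"({len(tokens)} fields, need ≥ 43)"
            )
        aa = tokens[1]
        try:
            lo_rows[pos] = [int(t) for t in tokens[2:22]]
            fr_rows[pos] = [int(t) for t in tokens[22:42]]
            info[pos] = float(tokens[42])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: bad numeric field ({exc})") from exc
        natives[pos] = aa
    if lo_order is None:
        raise FormatError(f"{path}: no 40-column amino-acid header line found")
    if not lo_rows:
        raise FormatError(f"{path}: no PSSM rows found")
    positions = sorted(lo_rows)
    return PSSM(
        native_aa=pd.Series({p: natives[p] for p in positions}),
        log_odds=pd.DataFrame([lo_rows[p] for p in positions], index=positions,
                              columns=lo_order),
        frequencies=pd.DataFrame([fr_rows[p] for p in positions], index=positions,
                                 columns=fr_order),
        info_content=pd.Series({p: info[p] for p in positions}, dtype=float),
    )


def write_pssm(pssm: PSSM, path: str | Path, query_id: str = "query") -> None:
    """Serialize in the ASCII dialect parse_pssm reads."""
    order = list(AMINO_ACIDS)
    header = (
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts"
    )
    lines = [f"PSSM for {query_id}", header, "",
             "    " + "  ".join(order) + "  " + "  ".join(order)]
    for pos in pssm.positions:
        lo = " ".join(f"{int(pssm.log_odds.loc[pos, a]):3d}" for a in order)
        fr = " ".join(f"{int(pssm.frequencies.loc[pos, a]):3d}" for a in order)
        lines.append(
            f"{pos:5d} {pssm.native_aa.loc[pos]}  {lo}  {fr}  "
            f"{pssm.info_content.loc[pos]:.2f}  0.00"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def sequence_features(pssm: PSSM, spec: MutationSpec) -> dict[str, float]:
    """PSSM-derived features for one substitution: native/mutant log-odds
    and observed frequencies, their differences, and the position's
    information content."""
    if spec.position not in pssm.log_odds.index:
        raise InputError(f"position {spec.position} not in PSSM")
    if pssm.native_aa.loc[spec.position] != spec.native_aa:
        raise IntegrityError(
            f"native residue mismatch at position {spec.position}: "
            f"PSSM has {pssm.native_aa.loc[spec.position]!r}, "
            f"spec has {spec.native_aa!r}"
        )
    pos = spec.position
    pssm_nat = float(pssm.log_odds.loc[pos, spec.native_aa])
    pssm_mut = float(pssm.log_odds.loc[pos, spec.mutant_aa])
    freq_nat = float(pssm.frequencies.loc[pos, spec.native_aa])
    freq_mut = float(pssm.frequencies.loc[pos, spec.mutant_aa])
    return {
        "pssm_mut": pssm_mut,
        "pssm_nat": pssm_nat,
        "pssm_diff": pssm_mut - pssm_nat,
        "freq_mut": freq_mut,
        "freq_nat": freq_nat,
        "freq_diff": freq_mut - freq_nat,
        "info_cont": float(pssm.info_content.loc[pos]),
    }


def structure_features(
    residues: list[ResidueAccessibility], spec: MutationSpec
) -> dict[str, float]:
    """Percent accessibility (ACCP, 0–100) and one-hot secondary-structure
    indicators ss_H / ss_S / ss_L for the mutated position."""
    by_pos = {r.position: r for r in residues}
    if spec.position not in by_pos:
        raise InputError(f"position {spec.position} not in residue table")
    res = by_pos[spec.position]
    if res.ss not in SS_CODES:
        raise InputError(f"unknown secondary-structure code {res.ss!r}")
    feats = {"ACCP": res.acc_fraction * 100.0}
    for code in SS_CODES:
        feats[f"ss_{code}"] = 1.0 if res.ss == code else 0.0
    return feats
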