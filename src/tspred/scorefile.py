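"""Tabular I/O: Rosetta-style score files and labelled feature matrices.

A score file is the plain-text ``SCORE:`` table that the Rosetta relax and
score protocols write: a header line naming the score-term columns, then one
line per decoy, every line prefixed by the literal token ``SCORE:``.  The
trailing ``description`` column carries the decoy tag.  Energy terms are in
Rosetta energy units; gdtmm/maxsub-fraction terms are dimensionless
fractions; rms-type terms are in Å.

The feature matrix is a tab-delimited table with one header row; an optional
label column named ``class`` holds ``ts`` / ``non-ts``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError, InputError

_DESCRIPTION = "description"
_LABEL_COLUMN = "class"
LABELS = ("ts", "non-ts")


@dataclass
class ScoreTable:
    """Per-decoy score terms for one ensemble (wild type or one mutation).

    ``data`` is indexed by decoy tag with one column per score term.
    """

    ensemble_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.shape[0] < 1:
            raise IntegrityError(f"{self.ensemble_id}: ensemble has no decoys")
        if self.data.index.has_duplicates:
            dups = sorted(self.data.index[self.data.index.duplicated()])
            raise IntegrityError(f"{self.ensemble_id}: duplicate decoy tags {dups}")
        if any(not tag for tag in self.data.index):
            raise IntegrityError(f"{self.ensemble_id}: empty decoy tag")

    @property
    def term_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def decoy_tags(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return self.data.shape[0]

    def term_values(self, term: str) -> np.ndarray:
        if term not in self.data.columns:
            raise IntegrityError(f"{self.ensemble_id}: missing score term {term!r}")
        return self.data[term].to_numpy(dtype=float)


@dataclass
class FeatureMatrix:
    """Samples × named numeric features, optionally labelled ts / non-ts."""

    data: pd.DataFrame
    labels: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise IntegrityError("duplicate sample ids")
        if self.data.columns.has_duplicates:
            raise IntegrityError("duplicate feature names")
        if self.data.isna().to_numpy().any():
            raise IntegrityError("feature matrix has missing cells")
        if self.labels is not None:
            self.labels = self.labels.reindex(self.data.index)
            bad = set(self.labels.unique()) - set(LABELS)
            if self.labels.isna().any() or bad:
                raise IntegrityError(f"labels must be in {LABELS}, got {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def label_array(self) -> np.ndarray:
        """Labels as +1 (ts) / −1 (non-ts)."""
        if self.labels is None:
            raise InputError("feature matrix is unlabelled")
        return np.where(self.labels.to_numpy() == "ts", 1, -1)

    def select(self, feature_names: list[str]) -> "FeatureMatrix":
        missing = [f for f in feature_names if f not in self.data.columns]
        if missing:
            raise IntegrityError(f"features not in matrix: {missing}")
        return FeatureMatrix(self.data[feature_names].copy(), self.labels)

    def equals(self, other: "FeatureMatrix") -> bool:
        if not self.data.equals(other.data):
            return False
        if (self.labels is None) != (other.labels is None):
            return False
        return self.labels is None or self.labels.equals(other.labels)


def _fmt(x: float) -> str:
    # ≥12 significant digits so ensembles survive a write/read cycle
    return format(float(x), ".12g")


def read_scorefile(path: str | Path) -> ScoreTable:
    """Parse a Rosetta-style ``SCORE:`` table.

    The first ``SCORE:`` line is the header; its columns minus the trailing
    ``description`` column become the score-term names, and ``description``
    populates the decoy tags.  Blank and non-``SCORE:`` lines are ignored.
    """
    path = Path(path)
    header: list[str] | None = None
    tags: list[str] = []
    rows: list[list[float]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or not line.startswith("SCORE:"):
            continue
        tokens = line.split()[1:]
        if header is None:
            if len(tokens) < 2:
                raise FormatError(f"{path}:{lineno}: header needs at least one term column")
            header = tokens
            continue
        if len(tokens) != len(header):
            raise FormatError(
                f"{path}:{lineno}: expected {len(header)} columns, found {len(tokens)}"
            )
        try:
            rows.append([float(t) for t in tokens[:-1]])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric score cell ({exc})") from exc
        tags.append(tokens[-1])
    if header is None:
        raise FormatError(f"{path}: no SCORE: header line found")
    if not rows:
        raise FormatError(f"{path}: header but no data lines")
    terms = header[:-1]  # trailing column is the decoy description
    if len(set(tags)) != len(tags):
        dups = sorted({t for t in tags if tags.count(t) > 1})
        raise IntegrityError(f"{path}: duplicate decoy tags {dups}")
    data = pd.DataFrame(rows, index=tags, columns=terms)
    return ScoreTable(ensemble_id=path.stem.removesuffix(".sc"), data=data)


def write_scorefile(table: ScoreTable, path: str | Path) -> None:
    """Serialize a ScoreTable in the ``SCORE:`` dialect read_scorefile reads."""
    path = Path(path)
    cols = table.term_names + [_DESCRIPTION]
    lines = ["SCORE: " + " ".join(cols)]
    for tag, row in table.data.iterrows():
        lines.append("SCORE: " + " ".join(_fmt(v) for v in row) + f" {tag}")
    path.write_text("\n".join(lines) + "\n")


def _normalize_tag(tag: str) -> str:
    """Decoy-tag normalization across relax/rescore naming: lowercase, then
    strip trailing .gz and .pdb suffixes (the two Rosetta invocations name
    the same decoy differently)."""
    tag = tag.lower()
    for suffix in (".gz", ".pdb"):
        tag = tag.removesuffix(suffix)
    return tag


def merge_relax_rescore(relax: ScoreTable, rescore: ScoreTable) -> ScoreTable:
    """Merge the relax-run and rescore-run tables for one ensemble.

    Relax supplies the energy and Repack_* terms; the rescore run supplies
    structural-comparison terms (gdtmm*, maxsub*, rms, irms).  On a
    term-name collision the rescore value wins.
    """
    left = relax.data.copy()
    right = rescore.data.copy()
    left.index = [_normalize_tag(t) for t in left.index]
    right.index = [_normalize_tag(t) for t in right.index]
    orphans = sorted(set(left.index) ^ set(right.index))
    if orphans:
        raise IntegrityError(
            f"decoys present in only one of relax/rescore: {orphans}"
        )
    right = right.reindex(left.index)
    keep = [c for c in left.columns if c not in right.columns]
    merged = pd.concat([left[keep], right], axis=1)
    return ScoreTable(ensemble_id=relax.ensemble_id, data=merged)


def write_feature_matrix(m: FeatureMatrix, path: str | Path) -> None:
    path = Path(path)
    header = ["sample"] + m.feature_names
    if m.labels is not None:
        header.append(_LABEL_COLUMN)
    lines = ["\t".join(header)]
    for i, sid in enumerate(m.sample_ids):
        cells = [sid] + [format(v, ".17g") for v in m.data.iloc[i]]
        if m.labels is not None:
            cells.append(str(m.labels.iloc[i]))
        lines.append("\t".join(cells))
    path.write_text("\n".join(lines) + "\n")


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(set(header)) != len(header):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise FormatError(f"{path}: duplicate header names {dups}")
    has_labels = header[-1] == _LABEL_COLUMN
    feature_names = header[1 : -1 if has_labels else None]
    ids, rows, labels = [], [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(header):
            raise FormatError(
                f"{path}:{lineno}: expected {len(header)} cells, found {len(cells)}"
            )
        ids.append(cells[0])
        if has_labels:
            labels.append(cells[-1])
            cells = cells[:-1]
        try:
            rows.append([float(c) for c in cells[1:]])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric cell ({exc})") from exc
    data = pd.DataFrame(rows, index=ids, columns=feature_names)
    lab = pd.Series(labels, index=ids) if has_labels else None
    return FeatureMatrix(data, lab)
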