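"""Candidate-site selection and mutation enumeration.

Mutations to buried residues are the ones most likely to destabilize a
protein globally (rather than perturbing a single interface), so candidate
positions are those whose relative side-chain solvent accessibility is at or
below a cutoff (default 10%).  At every selected position all 19
substitutions are enumerated, and a run manifest is emitted with one relax
job for the native structure plus one per mutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .errors import FormatError, InputError, IntegrityError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"  # canonical one-letter codes, sorted

THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

SS_CODES = ("H", "S", "L")  # helix, sheet, loop


@dataclass(frozen=True)
class ResidueAccessibility:
    """One residue of the input model: 1-based position, native amino acid,
    relative side-chain solvent accessibility as a fraction in [0, 1], and a
    three-state secondary-structure code."""

    position: int
    native_aa: str
    acc_fraction: float
    ss: str

    def __post_init__(self) -> None:
        if self.native_aa not in AMINO_ACIDS:
            raise InputError(f"non-canonical amino acid {self.native_aa!r}")
        if not 0.0 <= self.acc_fraction <= 1.0:
            raise InputError(f"acc_fraction {self.acc_fraction} outside [0, 1]")
        if self.ss not in SS_CODES:
            raise InputError(f"unknown secondary-structure code {self.ss!r}")


@dataclass(frozen=True)
class MutationSpec:
    """One candidate substitution: native residue `a` at `position` mutated
    to `mutant_aa` in `protein` of `species` (e.g. Scer)."""

    protein: str
    species: str
    position: int
    native_aa: str
    mutant_aa: str

    def __post_init__(self) -> None:
        if self.native_aa == self.mutant_aa:
            raise InputError("native and mutant residues are identical")
        for aa in (self.native_aa, self.mutant_aa):
            if aa not in AMINO_ACIDS:
                raise InputError(f"non-canonical amino acid {aa!r}")

    @property
    def job_name(self) -> str:
        """Run-script naming: {protein}-{a}{NNN}{b}, position unpadded."""
        return f"{self.protein}-{self.native_aa}{self.position}{self.mutant_aa}"

    @property
    def prediction_id(self) -> str:
        """Ranked-output naming: {protein}-{a}{NNN}_{MUT3}_{species}."""
        return (
            f"{self.protein}-{self.native_aa}{self.position}"
            f"_{THREE_LETTER[self.mutant_aa]}_{self.species}"
        )


def read_accessibility_table(path: str | Path) -> list[ResidueAccessibility]:
    """Read the tab-delimited (position, aa, acc_fraction, ss) table."""
    residues = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cells = line.split()
        if len(cells) != 4:
            raise FormatError(f"{path}:{lineno}: expected 4 columns, found {len(cells)}")
        try:
            residues.append(
                ResidueAccessibility(int(cells[0]), cells[1], float(cells[2]), cells[3])
            )
        except (ValueError, InputError) as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return residues


def select_buried_sites(
    residues: list[ResidueAccessibility],
    cutoff: float = 0.10,
    inclusive: bool = True,
) -> list[int]:
    """Positions whose relative accessibility is ≤ cutoff (or < with
    inclusive=False), ascending.  Default cutoff 0.10 = 10% accessible."""
    if not 0.0 <= cutoff <= 1.0:
        raise InputError(f"cutoff {cutoff} outside [0, 1]")
    if inclusive:
        picked = [r.position for r in residues if r.acc_fraction <= cutoff]
    else:
        picked = [r.position for r in residues if r.acc_fraction < cutoff]
    return sorted(picked)


def enumerate_mutations(
    protein: str,
    species: str,
    buried: list[int],
    residues: list[ResidueAccessibility],
) -> list[MutationSpec]:
    """All 19 non-native substitutions at every buried position, ordered by
    position then mutant residue alphabetically."""
    by_pos = {r.position: r for r in residues}
    specs = []
    for pos in sorted(buried):
        if pos not in by_pos:
            raise InputError(f"position {pos} not in residue table")
        native = by_pos[pos].native_aa
        for aa in AMINO_ACIDS:
            if aa != native:
                specs.append(MutationSpec(protein, species, pos, native, aa))
    return specs


@dataclass(frozen=True)
class JobEntry:
    name: str
    relax_command: str
    rescore_command: str


@dataclass
class RunManifest:
    protein: str
    species: str
    jobs: list[JobEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.jobs)

    def job_names(self) -> list[str]:
        return [j.name for j in self.jobs]


_RELAX_TEMPLATE = (
    "{mini_bin}/relax.linuxgccrelease -database {mini_db} "
    "-s {job}.pdb -native {protein}.pdb -nstruct {nstruct} -relax:fast "
    "-out:file:scorefile {job}.sc -out:pdb_gz"
)
_RESCORE_TEMPLATE = (
    "{mini_bin}/score.linuxgccrelease -database {mini_db} "
    "-s {job}_????.pdb.gz -in:file:native {protein}.pdb -in:file:fullatom "
    "-out:file:scorefile {job}rescore.sc"
)


def build_run_manifest(
    protein: str,
    species: str,
    specs: list[MutationSpec],
    ensemble_size: int = 50,
    mini_bin: str = "$ROSETTA_BIN",
    mini_db: str = "$ROSETTA_DB",
) -> RunManifest:
    """One wild-type job plus one job per substitution: |specs| + 1 entries.

    Each entry records the relax command (ensemble of `ensemble_size` decoys)
    and the rescore command that adds the structural-comparison terms."""

    def entry(job: str) -> JobEntry:
        fmt = dict(mini_bin=mini_bin, mini_db=mini_db, job=job,
                   protein=protein, nstruct=ensemble_size)
        return JobEntry(job, _RELAX_TEMPLATE.format(**fmt),
                        _RESCORE_TEMPLATE.format(**fmt))

    jobs = [entry(f"{protein}-WT")] + [entry(s.job_name) for s in specs]
    names = [j.name for j in jobs]
    if len(set(names)) != len(names):
        dups = sorted({n for n in names if names.count(n) > 1})
        raise IntegrityError(f"duplicate job names {dups}")
    return RunManifest(protein, species, jobs)


def write_manifest(manifest: RunManifest, path: str | Path) -> None:
    """One text record per job: name, relax command, rescore command."""
    lines = [f"# manifest for {manifest.protein} ({manifest.species}): "
             f"{len(manifest)} jobs"]
    for job in manifest.jobs:
        lines += [f"job {job.name}", f"  relax   {job.relax_command}",
                  f"  rescore {job.rescore_command}"]
    Path(path).write_text("\n".join(lines) + "\n")


def write_job_stubs(manifest: RunManifest, directory: str | Path) -> list[Path]:
    """Executable shell stubs, one per job ({name}.sh)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for job in manifest.jobs:
        p = directory / f"{job.name}.sh"
        p.write_text(
            "#!/bin/sh\n" + job.relax_command + "\n" + job.rescore_command + "\n"
        )
        p.chmod(0o755)
        paths.append(p)
    return paths
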