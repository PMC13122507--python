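"""Input/output: protein FASTA, the PSM-table TSV dialect, and result tables.

The PSM dialect is a minimal, search-engine-agnostic export: one row per
peptide-spectrum match with the peptide sequence, its experimental
condition and replicate, and variable modifications carrying residue-level
localization probabilities on a 0-100 percent scale. Columns::

    spectrum_id  condition  replicate  protein_accession  peptide  modifications

where ``modifications`` is empty or semicolon-separated tokens
``<offset><residue>:<ModName>:<prob>`` (offset 1-based within the
peptide), e.g. ``"3S:Phospho:98.2; 1M:Oxidation:100"``.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
PHOSPHO_ACCEPTORS = frozenset("STY")

#: modification name -> residues it may occur on
ALLOWED_MOD_RESIDUES = {
    "Phospho": PHOSPHO_ACCEPTORS,
    "Oxidation": frozenset("M"),
}


class ParseError(ValueError):
    """Malformed input file; message carries the file position."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence; the 1-based coordinate frame for all site calls."""

    accession: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"{self.accession}: illegal residue(s) {sorted(bad)!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue letter at a 1-based position."""
        if not 1 <= position <= self.length:
            raise IndexError(
                f"position {position} outside [1, {self.length}] for {self.accession}"
            )
        return self.sequence[position - 1]


@dataclass(frozen=True)
class Modification:
    """One variable modification on a peptide, with localization confidence."""

    peptide_offset: int  # 1-based within the peptide
    residue: str
    mod_name: str
    localization_probability: float  # percent, 0-100


@dataclass(frozen=True)
class PsmRecord:
    """One peptide-spectrum match; the counting unit of spectral counting."""

    spectrum_id: str
    condition: str
    replicate: int
    protein_accession: str
    peptide: str
    modifications: tuple[Modification, ...] = ()

    def __post_init__(self) -> None:
        for mod in self.modifications:
            if not 1 <= mod.peptide_offset <= len(self.peptide):
                raise ValueError(
                    f"{self.spectrum_id}: modification offset {mod.peptide_offset} "
                    f"outside peptide of length {len(self.peptide)}"
                )
            actual = self.peptide[mod.peptide_offset - 1]
            if actual != mod.residue:
                raise ValueError(
                    f"{self.spectrum_id}: token says {mod.residue} at offset "
                    f"{mod.peptide_offset}, peptide has {actual}"
                )
            allowed = ALLOWED_MOD_RESIDUES.get(mod.mod_name)
            if allowed is None:
                raise ValueError(f"{self.spectrum_id}: unknown modification {mod.mod_name!r}")
            if mod.residue not in allowed:
                raise ValueError(
                    f"{self.spectrum_id}: {mod.mod_name} not allowed on {mod.residue}"
                )
            if not 0.0 <= mod.localization_probability <= 100.0:
                raise ValueError(
                    f"{self.spectrum_id}: localization probability "
                    f"{mod.localization_probability} outside [0, 100]"
                )

    @property
    def phospho_mods(self) -> tuple[Modification, ...]:
        return tuple(m for m in self.modifications if m.mod_name == "Phospho")


@dataclass(frozen=True)
class ExperimentDesign:
    """Conditions, the reference condition, and the replicate count.

    ``mitotic_conditions`` names the perturbed (arrested) conditions used
    for the shared-in-mitosis classification; by default every
    non-reference condition.
    """

    conditions: tuple[str, ...]
    reference: str
    replicates_per_condition: int = 3
    mitotic_conditions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.reference not in self.conditions:
            raise ValueError(f"reference {self.reference!r} not among conditions")
        if self.replicates_per_condition < 1:
            raise ValueError("replicates_per_condition must be >= 1")
        if not self.mitotic_conditions:
            object.__setattr__(
                self,
                "mitotic_conditions",
                tuple(c for c in self.conditions if c != self.reference),
            )
        if self.reference in self.mitotic_conditions:
            raise ValueError("mitotic_conditions must exclude the reference")
        unknown = set(self.mitotic_conditions) - set(self.conditions)
        if unknown:
            raise ValueError(f"unknown mitotic condition(s) {sorted(unknown)}")

    @property
    def replicates(self) -> tuple[int, ...]:
        return tuple(range(1, self.replicates_per_condition + 1))


def default_design() -> ExperimentDesign:
    """The four-compound, three-replicate attachment-state design."""
    return ExperimentDesign(
        conditions=("DMSO", "nocodazole", "paclitaxel", "STLC"),
        reference="DMSO",
        replicates_per_condition=3,
    )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from a (possibly line-wrapped) FASTA file.

    Sequences are uppercased and validated against the 20 standard
    amino-acid letters; errors name the offending line.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    parsed = list(SeqIO.parse(str(path), "fasta"))
    if not parsed:
        raise ParseError(f"{path}: no FASTA records found")
    for rec in parsed:
        accession = rec.id
        sequence = str(rec.seq).upper()
        if accession in seen:
            raise ParseError(
                f"{path}:{_line_of_header(path, accession)}: duplicate accession {accession!r}"
            )
        seen.add(accession)
        bad = set(sequence) - AMINO_ACIDS
        if bad or not sequence:
            line = _line_of_bad_sequence(path, accession, bad)
            what = f"illegal residue(s) {sorted(bad)!r}" if bad else "empty sequence"
            raise ParseError(f"{path}:{line}: {what} in record {accession!r}")
        records.append(ProteinRecord(accession=accession, sequence=sequence))
    return records


def _line_of_header(path: Path, accession: str) -> int:
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if line.startswith(">") and line[1:].split()[:1] == [accession]:
                return i
    return 0


def _line_of_bad_sequence(path: Path, accession: str, bad: set[str]) -> int:
    """Line number of the first sequence line of *accession* containing a bad char."""
    with open(path) as fh:
        in_record = False
        header_line = 0
        for i, line in enumerate(fh, 1):
            if line.startswith(">"):
                in_record = line[1:].split()[:1] == [accession]
                if in_record:
                    header_line = i
                continue
            if in_record and (set(line.strip().upper()) & bad):
                return i
    return header_line


def write_fasta(records: Sequence[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA (round-trips through :func:`read_fasta`)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.accession}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# PSM table

PSM_COLUMNS = (
    "spectrum_id",
    "condition",
    "replicate",
    "protein_accession",
    "peptide",
    "modifications",
)

_MOD_TOKEN = re.compile(
    r"^(?P<offset>\d+)(?P<residue>[A-Z]):(?P<name>\w+):(?P<prob>\d+(?:\.\d+)?)$"
)


def _parse_mod_cell(cell: str, row_no: int) -> tuple[Modification, ...]:
    cell = cell.strip()
    if not cell:
        return ()
    mods = []
    for token in cell.split(";"):
        token = token.strip()
        if not token:
            continue
        m = _MOD_TOKEN.match(token)
        if m is None:
            raise ParseError(f"row {row_no}: malformed modification token {token!r}")
        mods.append(
            Modification(
                peptide_offset=int(m["offset"]),
                residue=m["residue"],
                mod_name=m["name"],
                localization_probability=float(m["prob"]),
            )
        )
    return tuple(mods)


def format_modifications(mods: Iterable[Modification]) -> str:
    return "; ".join(
        f"{m.peptide_offset}{m.residue}:{m.mod_name}:{m.localization_probability:g}"
        for m in mods
    )


def read_psm_table(path: str | Path, design: ExperimentDesign) -> list[PsmRecord]:
    """Read and validate a PSM TSV against the experimental design.

    Every row becomes exactly one :class:`PsmRecord`; any malformed row
    raises :class:`ParseError` with its row number (header = row 1), so no
    row is ever silently dropped.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    records: list[PsmRecord] = []
    seen_ids: set[str] = set()
    for idx, row in enumerate(df.itertuples(index=False), 2):  # header is row 1
        if row.condition not in design.conditions:
            raise ParseError(
                f"{path}: row {idx}: unknown condition {row.condition!r} "
                f"(design has {list(design.conditions)})"
            )
        try:
            replicate = int(row.replicate)
        except ValueError:
            raise ParseError(f"{path}: row {idx}: replicate {row.replicate!r} not an integer")
        if replicate < 1:
            raise ParseError(f"{path}: row {idx}: replicate must be >= 1")
        if row.spectrum_id in seen_ids:
            raise ParseError(f"{path}: row {idx}: duplicate spectrum_id {row.spectrum_id!r}")
        seen_ids.add(row.spectrum_id)
        try:
            rec = PsmRecord(
                spectrum_id=row.spectrum_id,
                condition=row.condition,
                replicate=replicate,
                protein_accession=row.protein_accession,
                peptide=row.peptide,
                modifications=_parse_mod_cell(row.modifications, idx),
            )
        except ValueError as exc:
            raise ParseError(f"{path}: row {idx}: {exc}") from exc
        records.append(rec)
    return records


def write_psm_table(records: Sequence[PsmRecord], path: str | Path) -> None:
    """Write PSMs in the TSV dialect (round-trips through :func:`read_psm_table`)."""
    rows = [
        {
            "spectrum_id": r.spectrum_id,
            "condition": r.condition,
            "replicate": r.replicate,
            "protein_accession": r.protein_accession,
            "peptide": r.peptide,
            "modifications": format_modifications(r.modifications),
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=list(PSM_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# generic result tables


def write_table(records, path: str | Path, float_format: str = "%.2f") -> None:
    """Write tabular results as TSV with a stable column order.

    Accepts a DataFrame, a list of dataclasses, or a list of dicts. Floats
    are rendered at two decimals, matching conventional spectral-count
    reporting (e.g. a mean of 2/3 prints as 0.67). An empty list with no
    inferable columns writes a header-only (empty) file.
    """
    if records is None:
        raise ValueError("records must not be None")
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        if records and dataclasses.is_dataclass(records[0]):
            df = pd.DataFrame([dataclasses.asdict(r) for r in records])
        else:
            df = pd.DataFrame(records)
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
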