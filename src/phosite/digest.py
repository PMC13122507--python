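"""In-silico tryptic digestion, peptide localization, and coverage profiling.

Trypsin cleaves C-terminal to lysine (K) or arginine (R) except when the
next residue is proline (P). Peptide-level modification offsets are
projected onto 1-based protein residue coordinates via the peptide's
unique location in the protein; multi-mapping peptides are excluded from
site calls and coverage and reported as ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from pyteomics import parser as pyt_parser

from phosite.io import ProteinRecord, PsmRecord

#: cleave after K/R unless followed by P
TRYPSIN_RULE = r"[KR](?!P)"


@dataclass(frozen=True)
class PeptideSpan:
    """A digest peptide located on the protein, 1-based inclusive coordinates."""

    start: int
    end: int
    missed_cleavages: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def covers(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class SiteCall:
    """One modification projected into protein coordinates."""

    protein_position: int
    residue: str
    mod_name: str
    localization_probability: float


@dataclass(frozen=True)
class MappedPsm:
    """A PSM uniquely located on its protein, with site calls in protein frame."""

    psm: PsmRecord
    span: PeptideSpan
    site_calls: tuple[SiteCall, ...]


@dataclass(frozen=True)
class MappingReport:
    """Outcome for a PSM that could not be uniquely placed (data, not failure)."""

    psm: PsmRecord
    status: Literal["absent", "ambiguous"]
    locations: tuple[int, ...] = ()


@dataclass
class CoverageProfile:
    """Per-residue PSM depth with percent-coverage and mean-depth summaries.

    ``depth[i]`` (0-based array over 1-based residues i+1) counts every
    uniquely mapped PSM whose span contains the residue, phosphorylated
    or not.
    """

    depth: np.ndarray
    protein_length: int

    @property
    def percent_coverage(self) -> float:
        return 100.0 * int((self.depth >= 1).sum()) / self.protein_length

    @property
    def mean_depth_covered(self) -> float:
        """Mean depth over covered residues only; 0.0 if nothing is covered."""
        covered = self.depth[self.depth >= 1]
        return float(covered.mean()) if covered.size else 0.0

    @property
    def mean_depth_all(self) -> float:
        """Mean depth over all residues (alternative depth convention)."""
        return float(self.depth.mean())


def count_internal_cleavage_sites(peptide: str) -> int:
    """Number of missed tryptic cleavage sites internal to *peptide*.

    A K/R at the final position is the peptide's own C-terminal cleavage
    (or the protein terminus), never a missed one.
    """
    return sum(
        1
        for i in range(len(peptide) - 1)
        if peptide[i] in "KR" and peptide[i + 1] != "P"
    )


def tryptic_digest(protein: ProteinRecord, max_missed: int = 2) -> list[PeptideSpan]:
    """All tryptic peptides of *protein* with 0..max_missed missed cleavages.

    Returns spans sorted by start position then end position.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    # a set: icleave re-yields the terminal peptide when the protein ends
    # in K/R (protein end and terminal cleavage are distinct boundaries)
    spans = {
        PeptideSpan(
            start=start0 + 1,
            end=start0 + len(pep),
            missed_cleavages=count_internal_cleavage_sites(pep),
        )
        for start0, pep in pyt_parser.icleave(
            protein.sequence, TRYPSIN_RULE, missed_cleavages=max_missed, min_length=1
        )
    }
    return sorted(spans, key=lambda s: (s.start, s.end))


def locate_peptide(peptide: str, protein: ProteinRecord) -> list[int]:
    """All 1-based exact-substring start positions of *peptide*, ascending.

    Overlapping occurrences are all reported; I and L are distinct.
    """
    if not peptide:
        raise ValueError("peptide must be non-empty")
    positions = []
    start = protein.sequence.find(peptide)
    while start != -1:
        positions.append(start + 1)
        start = protein.sequence.find(peptide, start + 1)
    return positions


def map_psm(psm: PsmRecord, protein: ProteinRecord) -> MappedPsm | MappingReport:
    """Place a PSM's peptide on the protein and project its modifications.

    A peptide found at exactly one location yields a :class:`MappedPsm`
    with ``protein_position = start + peptide_offset - 1`` for each
    modification; zero or multiple locations yield a
    :class:`MappingReport` (``absent`` / ``ambiguous``).
    """
    if psm.protein_accession != protein.accession:
        raise ValueError(
            f"PSM {psm.spectrum_id} names {psm.protein_accession!r}, "
            f"protein is {protein.accession!r}"
        )
    locations = locate_peptide(psm.peptide, protein)
    if not locations:
        return MappingReport(psm=psm, status="absent")
    if len(locations) > 1:
        return MappingReport(psm=psm, status="ambiguous", locations=tuple(locations))
    start = locations[0]
    span = PeptideSpan(
        start=start,
        end=start + len(psm.peptide) - 1,
        missed_cleavages=count_internal_cleavage_sites(psm.peptide),
    )
    calls = tuple(
        SiteCall(
            protein_position=start + m.peptide_offset - 1,
            residue=m.residue,
            mod_name=m.mod_name,
            localization_probability=m.localization_probability,
        )
        for m in psm.modifications
    )
    return MappedPsm(psm=psm, span=span, site_calls=calls)


def coverage_profile(mapped: Sequence[MappedPsm], protein: ProteinRecord) -> CoverageProfile:
    """Per-residue depth: the number of mapped PSMs overlapping each position."""
    depth = np.zeros(protein.length, dtype=np.int64)
    for m in mapped:
        depth[m.span.start - 1 : m.span.end] += 1
    return CoverageProfile(depth=depth, protein_length=protein.length)


def average_coverage(
    profiles: Sequence[CoverageProfile], covered_only: bool = True
) -> tuple[float, float]:
    """Replicate-averaged (percent_coverage, mean_depth).

    Depth is averaged over covered residues by default; ``covered_only=False``
    averages over all residues instead.
    """
    if not profiles:
        raise ValueError("need at least one coverage profile")
    percents = [p.percent_coverage for p in profiles]
    depths = [
        p.mean_depth_covered if covered_only else p.mean_depth_all for p in profiles
    ]
    return float(np.mean(percents)), float(np.mean(depths))
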