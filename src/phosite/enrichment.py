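"""Spectral-count enrichment of co-purifying proteins.

Protein abundance in an affinity purification is proxied by its PSM count.
For each protein, per-condition counts are averaged across replicates
(zeros included) and compared with the reference condition through a
pseudocount ratio::

    fold_change = (mean_treatment + 1) / (mean_reference + 1)

The +1 pseudocount keeps the ratio finite for proteins absent from the
reference purification. The reference column of the resulting matrix is
identically 1.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from phosite.io import ExperimentDesign, PsmRecord


@dataclass
class ProteinPsmCounts:
    """PSM tallies for one protein across (condition, replicate) cells."""

    protein_accession: str
    counts: dict[tuple[str, int], int]  # (condition, replicate) -> PSM count
    design: ExperimentDesign

    def count(self, condition: str, replicate: int) -> int:
        return self.counts.get((condition, replicate), 0)

    def mean_psms(self, condition: str) -> float:
        """Replicate-averaged PSM count; missing replicates count as zero."""
        total = sum(
            self.count(condition, r) for r in self.design.replicates
        )
        return total / self.design.replicates_per_condition


@dataclass
class FoldChangeMatrix:
    """Protein x condition pseudocount enrichment relative to the reference."""

    values: pd.DataFrame  # index: accession, columns: conditions in design order
    reference: str

    def to_frame(self) -> pd.DataFrame:
        out = self.values.reset_index()
        out.columns = ["protein_accession"] + list(self.values.columns)
        return out


def count_psms_per_protein(
    psms: Sequence[PsmRecord],
    design: ExperimentDesign,
    proteins: Sequence[str] | None = None,
) -> list[ProteinPsmCounts]:
    """Tally PSM rows per protein and (condition, replicate).

    ``proteins`` optionally restricts and orders the output (accessions
    with no PSMs get all-zero rows); otherwise all observed accessions are
    reported in first-seen order.
    """
    tallies: Counter[tuple[str, str, int]] = Counter()
    observed: list[str] = []
    seen: set[str] = set()
    for p in psms:
        tallies[(p.protein_accession, p.condition, p.replicate)] += 1
        if p.protein_accession not in seen:
            seen.add(p.protein_accession)
            observed.append(p.protein_accession)
    accessions = list(proteins) if proteins is not None else observed
    out = []
    for acc in accessions:
        counts = {
            (cond, rep): tallies[(acc, cond, rep)]
            for cond in design.conditions
            for rep in design.replicates
            if tallies[(acc, cond, rep)]
        }
        out.append(ProteinPsmCounts(protein_accession=acc, counts=counts, design=design))
    return out


def fold_change(avg_treatment: float, avg_reference: float) -> float:
    """Pseudocount spectral-count ratio (avg_treatment + 1)/(avg_reference + 1)."""
    if avg_treatment < 0 or avg_reference < 0:
        raise ValueError("PSM averages cannot be negative")
    return (avg_treatment + 1.0) / (avg_reference + 1.0)


def build_matrix(
    counts: Sequence[ProteinPsmCounts], design: ExperimentDesign
) -> FoldChangeMatrix:
    """Fold-change matrix over all proteins and conditions, rows in input order."""
    data = {
        cond: [
            fold_change(c.mean_psms(cond), c.mean_psms(design.reference))
            for c in counts
        ]
        for cond in design.conditions
    }
    values = pd.DataFrame(
        data,
        index=pd.Index([c.protein_accession for c in counts], name="protein_accession"),
        columns=list(design.conditions),
    )
    return FoldChangeMatrix(values=values, reference=design.reference)
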