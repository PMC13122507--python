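"""Phospho-site aggregation, filtering, replicate averaging, classification.

A site is one (protein, residue position). Per (condition, replicate) its
evidence is the number of distinct phospho-PSMs placing a phosphorylation
there and the best (maximum) localization probability among them. A
replicate "passes" when best probability strictly exceeds the confidence
threshold (default 75%) and the phospho-PSM count is at least the minimum
(default 2). A site is "detected" in a condition when at least one of its
replicates passes.

Condition-sharing categories (precedence high to low):

* ``shared_all`` — detected in every condition;
* ``mitotic_shared`` — detected in all mitotic (perturbed) conditions and
  not in the reference;
* ``unique_starred`` — detected in exactly one condition, passing in at
  least 2 replicates there (the "star" of condition-unique sites);
* ``other`` — any remaining detected site.

Mean phospho-PSM counts per condition divide by the design's replicate
number, counting missing replicates as zero, and are independent of the
pass/fail filter.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from phosite.digest import MappedPsm
from phosite.io import ExperimentDesign

CATEGORIES = ("shared_all", "mitotic_shared", "unique_starred", "other")


@dataclass(frozen=True)
class FilterConfig:
    """Detection thresholds for a single replicate's site evidence."""

    confidence_threshold: float = 75.0  # percent; strict >
    min_phospho_psms: int = 2
    min_replicates_for_star: int = 2

    def __post_init__(self) -> None:
        if self.confidence_threshold <= 0 or self.min_phospho_psms <= 0:
            raise ValueError("thresholds must be strictly positive")
        if self.min_replicates_for_star < 1:
            raise ValueError("min_replicates_for_star must be >= 1")


@dataclass(frozen=True)
class SiteEvidence:
    """Phospho-PSM evidence for one (site, condition, replicate)."""

    protein_accession: str
    position: int
    residue: str
    condition: str
    replicate: int
    phospho_psm_count: int
    best_localization_probability: float


@dataclass
class ConditionSummary:
    """Per-condition aggregate for one site."""

    mean_phospho_psms: float
    n_passing_replicates: int

    @property
    def detected(self) -> bool:
        return self.n_passing_replicates >= 1


@dataclass
class SiteSummary:
    """One phospho-site across all conditions, classified."""

    protein_accession: str
    position: int
    residue: str
    per_condition: dict[str, ConditionSummary]
    category: str
    motifs: tuple[str, ...] = ()

    def detected_in(self, condition: str) -> bool:
        return self.per_condition[condition].detected

    def color_bin_for(self, condition: str) -> str:
        cs = self.per_condition[condition]
        return color_bin(cs.mean_phospho_psms) if cs.detected else "absent"


def replicate_passes(evidence: SiteEvidence, cfg: FilterConfig) -> bool:
    """Confidence/count filter for one replicate's evidence.

    Confidence is strict (75.0 exactly fails a 75% threshold).
    """
    return (
        evidence.best_localization_probability > cfg.confidence_threshold
        and evidence.phospho_psm_count >= cfg.min_phospho_psms
    )


def mean_phospho_psms(counts: Iterable[int], n_replicates: int) -> float:
    """Mean phospho-PSM count over the design's replicates, zeros included.

    ``counts`` holds the nonzero observations; replicates without evidence
    contribute zero, so (2,) over 3 replicates averages to 2/3.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    return sum(counts) / n_replicates


def color_bin(mean: float) -> str:
    """Abundance bin for a condition-mean phospho-PSM count.

    gray below 5, blue on [5, 10] (bounds inclusive), coral above 10.
    """
    if mean < 0:
        raise ValueError("mean phospho-PSM count cannot be negative")
    if mean < 5:
        return "gray"
    if mean <= 10:
        return "blue"
    return "coral"


def collect_site_evidence(
    mapped: Sequence[MappedPsm], design: ExperimentDesign
) -> list[SiteEvidence]:
    """Tally phospho-PSMs per (position, condition, replicate).

    Each PSM contributes exactly one count to every phospho-site it
    carries (a doubly phosphorylated peptide counts once at each
    position); the best localization probability per cell is the maximum
    over contributing PSMs. Only cells with at least one phospho-PSM are
    returned, ordered by (position, condition order, replicate).
    """
    counts: dict[tuple[str, int, str, str, int], list[float]] = defaultdict(list)
    for m in mapped:
        phospho_positions = {}
        for call in m.site_calls:
            if call.mod_name != "Phospho":
                continue
            # one PSM counts once per position even if listed twice
            prev = phospho_positions.get(call.protein_position)
            if prev is None or call.localization_probability > prev[1]:
                phospho_positions[call.protein_position] = (
                    call.residue,
                    call.localization_probability,
                )
        for pos, (residue, prob) in phospho_positions.items():
            key = (m.psm.protein_accession, pos, residue, m.psm.condition, m.psm.replicate)
            counts[key].append(prob)
    cond_order = {c: i for i, c in enumerate(design.conditions)}
    evidence = [
        SiteEvidence(
            protein_accession=acc,
            position=pos,
            residue=residue,
            condition=cond,
            replicate=rep,
            phospho_psm_count=len(probs),
            best_localization_probability=max(probs),
        )
        for (acc, pos, residue, cond, rep), probs in counts.items()
    ]
    evidence.sort(key=lambda e: (e.position, cond_order[e.condition], e.replicate))
    return evidence


def _classify(
    detected: Mapping[str, bool],
    passing: Mapping[str, int],
    design: ExperimentDesign,
    cfg: FilterConfig,
) -> str:
    det_conditions = [c for c in design.conditions if detected[c]]
    if not det_conditions:
        return "other"
    if all(detected[c] for c in design.conditions):
        return "shared_all"
    if all(detected[c] for c in design.mitotic_conditions) and not detected[design.reference]:
        return "mitotic_shared"
    if len(det_conditions) == 1 and passing[det_conditions[0]] >= cfg.min_replicates_for_star:
        return "unique_starred"
    return "other"


def detect_and_classify(
    evidence: Sequence[SiteEvidence],
    design: ExperimentDesign,
    cfg: FilterConfig | None = None,
) -> list[SiteSummary]:
    """Aggregate evidence into detected, classified site summaries.

    Sites with no passing replicate in any condition are dropped (never
    detected). Output is ordered by (accession, position).
    """
    cfg = cfg or FilterConfig()
    by_site: dict[tuple[str, int, str], list[SiteEvidence]] = defaultdict(list)
    for ev in evidence:
        by_site[(ev.protein_accession, ev.position, ev.residue)].append(ev)

    summaries = []
    for (acc, pos, residue), evs in sorted(by_site.items()):
        per_condition: dict[str, ConditionSummary] = {}
        for cond in design.conditions:
            cond_evs = [e for e in evs if e.condition == cond]
            per_condition[cond] = ConditionSummary(
                mean_phospho_psms=mean_phospho_psms(
                    (e.phospho_psm_count for e in cond_evs),
                    design.replicates_per_condition,
                ),
                n_passing_replicates=sum(replicate_passes(e, cfg) for e in cond_evs),
            )
        detected = {c: per_condition[c].detected for c in design.conditions}
        if not any(detected.values()):
            continue
        passing = {c: per_condition[c].n_passing_replicates for c in design.conditions}
        summaries.append(
            SiteSummary(
                protein_accession=acc,
                position=pos,
                residue=residue,
                per_condition=per_condition,
                category=_classify(detected, passing, design, cfg),
            )
        )
    return summaries


def site_count_report(
    summaries: Sequence[SiteSummary], design: ExperimentDesign
) -> dict:
    """Per-condition detected-site counts plus union and shared-set counts."""
    per_condition = {
        c: sum(s.detected_in(c) for s in summaries) for c in design.conditions
    }
    by_category = {cat: sum(s.category == cat for s in summaries) for cat in CATEGORIES}
    return {
        "per_condition": per_condition,
        "union": len(summaries),
        "shared_all": by_category["shared_all"],
        "mitotic_shared": by_category["mitotic_shared"],
        "unique_starred": by_category["unique_starred"],
        "other": by_category["other"],
    }


def summaries_to_frame(
    summaries: Sequence[SiteSummary], design: ExperimentDesign
) -> pd.DataFrame:
    """Tabular site summary: one row per site, per-condition column blocks."""
    rows = []
    for s in summaries:
        row: dict = {"position": s.position, "residue": s.residue}
        for cond in design.conditions:
            cs = s.per_condition[cond]
            row[f"{cond}_mean_phospho_psms"] = cs.mean_phospho_psms
            row[f"{cond}_n_passing_replicates"] = cs.n_passing_replicates
            row[f"{cond}_detected"] = cs.detected
            row[f"{cond}_color_bin"] = s.color_bin_for(cond)
        row["category"] = s.category
        row["motifs"] = ",".join(s.motifs)
        rows.append(row)
    columns = ["position", "residue"]
    for cond in design.conditions:
        columns += [
            f"{cond}_mean_phospho_psms",
            f"{cond}_n_passing_replicates",
            f"{cond}_detected",
            f"{cond}_color_bin",
        ]
    columns += ["category", "motifs"]
    return pd.DataFrame(rows, columns=columns)
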