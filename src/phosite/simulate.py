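"""Ground-truthed synthetic PSM tables for end-to-end pipeline testing.

The generator emulates the statistical structure of a deep IP-MS
phosphoproteomics experiment on one bait protein: a multi-condition,
multi-replicate design; tryptic peptides with occasional retained missed
cleavages; per-peptide PSM counts drawn from a Poisson law deep enough to
give tens of PSMs per residue; planted phospho-sites whose occupancy
(probability that a covering PSM is phosphorylated) differs by condition;
well-localized true calls and low-confidence decoy mislocalizations so
the confidence filter is actually exercised. Partial sequence coverage is
produced the way real coverage maps show it: a configurable fraction of
the protein lies in contiguous unobservable regions (peptides that never
ionize or are too short to detect) that stay at zero depth, while the
observable remainder sits at uniform Poisson depth.

Everything is deterministic under the config seed, and the realized
per-site phospho-PSM counts are returned as a ground truth so detection
and classification can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from phosite.digest import PeptideSpan, tryptic_digest
from phosite.io import (
    ExperimentDesign,
    Modification,
    ProteinRecord,
    PsmRecord,
    default_design,
)
from phosite.sites import SiteSummary, _classify, FilterConfig

_NON_KR = "ACDEFGHILMNPQSTVWY"  # 18 letters; K/R placed by kr_frequency


@dataclass(frozen=True)
class PlantedSite:
    """A true phospho-site with per-condition occupancy.

    ``position`` may be None in a config, in which case an S/T/Y residue
    is chosen automatically during generation.
    """

    occupancy: dict[str, float]
    position: int | None = None

    def __post_init__(self) -> None:
        for cond, occ in self.occupancy.items():
            if not 0.0 <= occ <= 1.0:
                raise ValueError(f"occupancy {occ} for {cond!r} outside [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and noise parameters for one synthetic experiment.

    Defaults emulate a four-condition (reference + three mitotic arrests),
    three-replicate spectral-counting experiment with per-residue depth in
    the 20-35 PSM regime.
    """

    seed: int = 0
    protein_length: int = 600
    kr_frequency: float = 0.06
    design: ExperimentDesign = field(default_factory=default_design)
    planted_sites: tuple[PlantedSite, ...] | None = None
    background_depth_mean: float = 27.0
    missed_cleavage_rate: float = 0.1
    decoy_rate: float = 0.02
    oxidation_rate: float = 0.05
    true_prob_range: tuple[float, float] = (90.0, 100.0)
    decoy_prob_range: tuple[float, float] = (30.0, 70.0)
    min_peptide_length: int = 7
    max_peptide_length: int = 40
    masked_fraction: float = 0.25
    n_masked_blocks: int = 4
    accession: str = "SYNPROT1"

    def __post_init__(self) -> None:
        for lo, hi in (self.true_prob_range, self.decoy_prob_range):
            if not 0.0 <= lo <= hi <= 100.0:
                raise ValueError("probability ranges must lie within [0, 100]")
        for rate in (self.kr_frequency, self.missed_cleavage_rate, self.decoy_rate,
                     self.oxidation_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie within [0, 1]")
        if not 0.0 <= self.masked_fraction < 1.0:
            raise ValueError("masked_fraction must lie within [0, 1)")
        if self.protein_length < 20:
            raise ValueError("protein_length must be >= 20")


def default_planted_panel(design: ExperimentDesign) -> tuple[PlantedSite, ...]:
    """The default planted-site panel: the occupancy structure of a bait
    protein whose phosphorylation responds to mitotic arrest.

    One constitutive high-occupancy site present in every condition, one
    low constitutive site, three sites shared by the mitotic conditions
    only, and one site unique to each mitotic condition.
    """
    mitotic = design.mitotic_conditions
    all_conditions = design.conditions
    panel = [
        PlantedSite(occupancy={c: 0.5 for c in all_conditions}),
        PlantedSite(occupancy={c: 0.15 for c in all_conditions}),
    ]
    panel += [PlantedSite(occupancy={c: 0.25 for c in mitotic}) for _ in range(3)]
    panel += [PlantedSite(occupancy={c: 0.25}) for c in mitotic]
    return tuple(panel)


@dataclass
class GroundTruth:
    """What was planted and what was realized, for exact scoring."""

    protein: ProteinRecord
    planted: tuple[PlantedSite, ...]  # positions resolved
    design: ExperimentDesign
    # (position, condition, replicate) -> realized phospho-PSM count
    realized_counts: dict[tuple[int, str, int], int]

    @property
    def planted_positions(self) -> set[int]:
        return {s.position for s in self.planted}

    def expected_category(self, site: PlantedSite) -> str:
        """Sharing category implied by the site's occupancy design."""
        detected = {c: site.occupancy.get(c, 0.0) > 0 for c in self.design.conditions}
        passing = {
            c: self.design.replicates_per_condition if detected[c] else 0
            for c in self.design.conditions
        }
        return _classify(detected, passing, self.design, FilterConfig())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for site in self.planted:
            for cond in self.design.conditions:
                row = {
                    "position": site.position,
                    "residue": self.protein.residue(site.position),
                    "condition": cond,
                    "occupancy": site.occupancy.get(cond, 0.0),
                }
                for rep in self.design.replicates:
                    row[f"rep{rep}_phospho_psms"] = self.realized_counts.get(
                        (site.position, cond, rep), 0
                    )
                rows.append(row)
        return pd.DataFrame(rows)


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)


def generate_protein(cfg: SimulationConfig) -> ProteinRecord:
    """Random protein sequence honoring the config's digest constraints.

    K/R are placed at ``kr_frequency``; afterwards cleavage sites are
    inserted wherever a fully cleaved tryptic peptide would exceed
    ``max_peptide_length``. Deterministic under the config seed.
    """
    if cfg.kr_frequency == 0.0 and cfg.protein_length > cfg.max_peptide_length:
        raise ValueError(
            "kr_frequency 0 cannot satisfy the maximum tryptic peptide length"
        )
    rng = np.random.default_rng([cfg.seed, 0])
    n = cfg.protein_length
    seq = [
        ("K" if rng.random() < 0.5 else "R")
        if rng.random() < cfg.kr_frequency
        else _NON_KR[rng.integers(len(_NON_KR))]
        for _ in range(n)
    ]
    # break any over-long fully-cleaved peptide; a K is a cleavage site
    # only if not followed by P, so the follower is forced non-P
    while True:
        protein = ProteinRecord(cfg.accession, "".join(seq))
        too_long = [
            s for s in tryptic_digest(protein, 0) if s.length > cfg.max_peptide_length
        ]
        if not too_long:
            return protein
        span = too_long[0]
        mid = (span.start + span.end) // 2  # 1-based
        seq[mid - 1] = "K" if rng.random() < 0.5 else "R"
        if mid < n and seq[mid] == "P":
            seq[mid] = _NON_KR[rng.integers(len(_NON_KR))]


def _resolve_planted(
    planted: Sequence[PlantedSite],
    protein: ProteinRecord,
    observable: Sequence[PeptideSpan],
    rng: np.random.Generator,
) -> tuple[PlantedSite, ...]:
    """Assign auto positions to S/T/Y residues inside observable peptides."""
    taken = {s.position for s in planted if s.position is not None}
    candidates = sorted(
        {
            pos
            for span in observable
            for pos in range(span.start, span.end + 1)
            if protein.residue(pos) in "STY" and pos not in taken
        }
    )
    resolved = []
    for site in planted:
        if site.position is not None:
            if protein.residue(site.position) not in "STY":
                raise ValueError(
                    f"planted position {site.position} is "
                    f"{protein.residue(site.position)}, not S/T/Y"
                )
            resolved.append(site)
            continue
        if not candidates:
            raise ValueError("not enough S/T/Y residues in observable peptides")
        pick = int(rng.integers(len(candidates)))
        resolved.append(replace(site, position=candidates.pop(pick)))
    return tuple(resolved)



def _draw_masked_peptides(
    base: Sequence[PeptideSpan], cfg: SimulationConfig, rng: np.random.Generator
) -> set[int]:
    """Choose contiguous runs of digest peptides to be unobservable.

    Runs are sized so the masked residues total about
    ``masked_fraction`` of the protein, split across
    ``n_masked_blocks`` blocks.
    """
    target = round(cfg.masked_fraction * sum(s.length for s in base))
    if target == 0:
        return set()
    masked: set[int] = set()
    masked_residues = 0
    share = max(1, target // max(1, cfg.n_masked_blocks))
    attempts = 0
    while masked_residues < target and attempts < 10 * cfg.n_masked_blocks:
        attempts += 1
        start = int(rng.integers(len(base)))
        if start in masked:
            continue
        block = 0
        j = start
        while j < len(base) and j not in masked and block < share:
            if masked_residues + base[j].length > target + base[j].length // 2:
                break
            masked.add(j)
            block += base[j].length
            masked_residues += base[j].length
            j += 1
    return masked


def simulate_psm_table(
    cfg: SimulationConfig,
) -> tuple[list[PsmRecord], GroundTruth]:
    """Draw a full synthetic PSM table plus its ground truth.

    For every (condition, replicate) and every observable fully cleaved
    peptide, the PSM count is Poisson(``background_depth_mean``). Each PSM
    independently retains a missed cleavage (extending into an adjacent
    peptide) with ``missed_cleavage_rate``, phosphorylates each planted
    site it covers with that site's condition occupancy (localization
    probability uniform in ``true_prob_range``), and with ``decoy_rate``
    carries one decoy phospho call on a non-planted S/T/Y (probability
    uniform in ``decoy_prob_range``). Methionines oxidize at
    ``oxidation_rate`` per PSM.
    """
    protein = generate_protein(cfg)
    rng = np.random.default_rng([cfg.seed, 1])
    base = tryptic_digest(protein, 0)
    masked = _draw_masked_peptides(base, cfg, rng)
    observable = [
        i
        for i, s in enumerate(base)
        if i not in masked and s.length >= cfg.min_peptide_length
    ]
    planted_cfg = (
        cfg.planted_sites
        if cfg.planted_sites is not None
        else default_planted_panel(cfg.design)
    )
    planted = _resolve_planted(
        planted_cfg, protein, [base[i] for i in observable], rng
    )
    site_by_pos = {s.position: s for s in planted}

    psms: list[PsmRecord] = []
    realized: dict[tuple[int, str, int], int] = {}
    counter = 0
    for cond in cfg.design.conditions:
        for rep in cfg.design.replicates:
            for i in observable:
                n_psms = rng.poisson(cfg.background_depth_mean)
                for _ in range(n_psms):
                    lo, hi = i, i
                    if rng.random() < cfg.missed_cleavage_rate:
                        if lo == 0:
                            hi += 1
                        elif hi == len(base) - 1:
                            lo -= 1
                        elif rng.random() < 0.5:
                            lo -= 1
                        else:
                            hi += 1
                        if lo in masked or hi in masked:
                            lo = hi = i  # unobservable neighbor: stay unextended
                    start, end = base[lo].start, base[hi].end
                    peptide = protein.sequence[start - 1 : end]
                    mods: list[Modification] = []
                    phospho_offsets: set[int] = set()
                    for pos in range(start, end + 1):
                        site = site_by_pos.get(pos)
                        if site is None:
                            continue
                        occ = site.occupancy.get(cond, 0.0)
                        if occ > 0 and rng.random() < occ:
                            offset = pos - start + 1
                            prob = rng.uniform(*cfg.true_prob_range)
                            mods.append(
                                Modification(
                                    peptide_offset=offset,
                                    residue=peptide[offset - 1],
                                    mod_name="Phospho",
                                    localization_probability=round(prob, 1),
                                )
                            )
                            phospho_offsets.add(offset)
                            key = (pos, cond, rep)
                            realized[key] = realized.get(key, 0) + 1
                    if rng.random() < cfg.decoy_rate:
                        decoy_offsets = [
                            j + 1
                            for j, aa in enumerate(peptide)
                            if aa in "STY"
                            and (start + j) not in site_by_pos
                            and (j + 1) not in phospho_offsets
                        ]
                        if decoy_offsets:
                            offset = decoy_offsets[int(rng.integers(len(decoy_offsets)))]
                            prob = rng.uniform(*cfg.decoy_prob_range)
                            mods.append(
                                Modification(
                                    peptide_offset=offset,
                                    residue=peptide[offset - 1],
                                    mod_name="Phospho",
                                    localization_probability=round(prob, 1),
                                )
                            )
                    if rng.random() < cfg.oxidation_rate:
                        met_offsets = [j + 1 for j, aa in enumerate(peptide) if aa == "M"]
                        if met_offsets:
                            offset = met_offsets[int(rng.integers(len(met_offsets)))]
                            mods.append(
                                Modification(
                                    peptide_offset=offset,
                                    residue="M",
                                    mod_name="Oxidation",
                                    localization_probability=100.0,
                                )
                            )
                    counter += 1
                    mods.sort(key=lambda m: m.peptide_offset)
                    psms.append(
                        PsmRecord(
                            spectrum_id=f"{cond}_r{rep}_{counter:06d}",
                            condition=cond,
                            replicate=rep,
                            protein_accession=cfg.accession,
                            peptide=peptide,
                            modifications=tuple(mods),
                        )
                    )
    truth = GroundTruth(
        protein=protein,
        planted=planted,
        design=cfg.design,
        realized_counts=realized,
    )
    return psms, truth


@dataclass
class RecoveryReport:
    """How well the analysis recovered the generator's planted truth."""

    sensitivity: float | None  # None when nothing was planted
    false_discoveries: int
    classification_accuracy: float | None
    n_planted: int
    n_detected: int


def evaluate_recovery(
    truth: GroundTruth, summaries: Sequence[SiteSummary]
) -> RecoveryReport:
    """Score detected/classified sites against the planted ground truth.

    Sensitivity is the fraction of planted sites detected in at least one
    condition; false discoveries are detected sites never planted;
    classification accuracy is the fraction of planted sites whose
    assigned category equals the category implied by their occupancy
    design (an undetected planted site counts as a miss).
    """
    detected = {s.position: s for s in summaries}
    planted_pos = truth.planted_positions
    n_planted = len(planted_pos)
    hits = sum(1 for p in planted_pos if p in detected)
    false_discoveries = sum(1 for p in detected if p not in planted_pos)
    if n_planted:
        correct = sum(
            1
            for site in truth.planted
            if site.position in detected
            and detected[site.position].category == truth.expected_category(site)
        )
        sensitivity = hits / n_planted
        accuracy = correct / n_planted
    else:
        sensitivity = None
        accuracy = None
    return RecoveryReport(
        sensitivity=sensitivity,
        false_discoveries=false_discoveries,
        classification_accuracy=accuracy,
        n_planted=n_planted,
        n_detected=len(detected),
    )
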