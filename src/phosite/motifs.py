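"""Sequence-motif scanning and phospho-site motif annotation.

Patterns are position-restricted amino-acid class strings in bracket
notation, e.g. ``[MILV][ED][LIVM]T`` — each position either a literal
letter, ``x``/``.`` for any residue, or a bracketed set of allowed
letters. One position in each pattern is the phospho-acceptor
(``acceptor_offset``, 1-based within the match) and must be restricted to
S/T/Y.

The shipped defaults cover the checkpoint-signaling motifs of the outer
kinetochore: degenerate and strict MELT repeats (MPS1/TTK substrates),
the SHT motif, proline-directed [ST]P (CDK-family consensus), and the
basic [RK]-x-[ST] Aurora B consensus. They are conventions, deliberately
user-overridable through a YAML config; an explicit list of known
acceptor positions can replace scanning when a curated motif inventory
exists.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Sequence

import yaml

from phosite.io import PHOSPHO_ACCEPTORS, AMINO_ACIDS, ProteinRecord
from phosite.sites import SiteSummary

_BRACKET = re.compile(r"\[([A-Z]+)\]|([A-Zx.])")


def parse_pattern(pattern: str) -> tuple[frozenset[str], ...]:
    """Bracket notation -> tuple of allowed-letter sets, one per position."""
    classes = []
    pos = 0
    for m in _BRACKET.finditer(pattern):
        if m.start() != pos:
            raise ValueError(f"malformed pattern {pattern!r} near offset {pos}")
        pos = m.end()
        if m.group(1):
            classes.append(frozenset(m.group(1)))
        elif m.group(2) in ("x", "."):
            classes.append(frozenset(AMINO_ACIDS))
        else:
            classes.append(frozenset(m.group(2)))
    if pos != len(pattern) or not classes:
        raise ValueError(f"malformed pattern {pattern!r}")
    return tuple(classes)


@dataclass(frozen=True)
class MotifPattern:
    """A named motif with a designated phospho-acceptor position."""

    name: str
    pattern: str
    acceptor_offset: int  # 1-based within the match

    def __post_init__(self) -> None:
        classes = parse_pattern(self.pattern)
        if not 1 <= self.acceptor_offset <= len(classes):
            raise ValueError(
                f"{self.name}: acceptor_offset {self.acceptor_offset} outside pattern"
            )
        acceptor_class = classes[self.acceptor_offset - 1]
        if not acceptor_class <= PHOSPHO_ACCEPTORS:
            raise ValueError(
                f"{self.name}: acceptor class {sorted(acceptor_class)} not within S/T/Y"
            )

    @property
    def classes(self) -> tuple[frozenset[str], ...]:
        return parse_pattern(self.pattern)


@dataclass(frozen=True)
class MotifAnnotation:
    """One motif occurrence on a protein, 1-based inclusive coordinates."""

    motif_name: str
    match_start: int
    match_end: int
    acceptor_position: int


def default_patterns() -> list[MotifPattern]:
    """The motif set shipped with the package (see module docstring)."""
    with resources.files("phosite.data").joinpath("motifs.yaml").open() as fh:
        return _patterns_from_yaml(fh)


def load_motif_config(path: str | Path) -> list[MotifPattern]:
    """Load motif patterns from a YAML file (list of name/pattern/acceptor_offset)."""
    with open(path) as fh:
        return _patterns_from_yaml(fh)


def _patterns_from_yaml(fh) -> list[MotifPattern]:
    entries = yaml.safe_load(fh)
    if not isinstance(entries, list):
        raise ValueError("motif config must be a list of pattern entries")
    return [
        MotifPattern(
            name=e["name"],
            pattern=e["pattern"],
            acceptor_offset=int(e["acceptor_offset"]),
        )
        for e in entries
    ]


def scan_motifs(
    protein: ProteinRecord, patterns: Sequence[MotifPattern]
) -> list[MotifAnnotation]:
    """All motif occurrences in the protein, overlaps included.

    Results are sorted by match_start, then pattern order.
    """
    annotations = []
    seq = protein.sequence
    for pat in patterns:
        classes = pat.classes
        k = len(classes)
        for start0 in range(protein.length - k + 1):
            if all(seq[start0 + j] in classes[j] for j in range(k)):
                annotations.append(
                    MotifAnnotation(
                        motif_name=pat.name,
                        match_start=start0 + 1,
                        match_end=start0 + k,
                        acceptor_position=start0 + pat.acceptor_offset,
                    )
                )
    order = {p.name: i for i, p in enumerate(patterns)}
    annotations.sort(key=lambda a: (a.match_start, order[a.motif_name]))
    return annotations


def annotations_from_positions(
    motif_name: str, positions: Sequence[int], protein: ProteinRecord
) -> list[MotifAnnotation]:
    """Wrap a curated list of acceptor positions as single-residue annotations.

    Use when an established motif inventory (literature positions) should
    override pattern scanning; every position must hold an S/T/Y.
    """
    out = []
    for pos in positions:
        residue = protein.residue(pos)
        if residue not in PHOSPHO_ACCEPTORS:
            raise ValueError(f"{motif_name}: position {pos} is {residue}, not S/T/Y")
        out.append(
            MotifAnnotation(
                motif_name=motif_name, match_start=pos, match_end=pos, acceptor_position=pos
            )
        )
    return out


def annotate_sites(
    summaries: Sequence[SiteSummary], annotations: Sequence[MotifAnnotation]
) -> list[SiteSummary]:
    """Attach motif names to sites whose position is a motif acceptor.

    Returns new summaries (input unchanged); detection and classification
    fields are untouched, so annotation is idempotent.
    """
    by_position: dict[int, set[str]] = {}
    for ann in annotations:
        by_position.setdefault(ann.acceptor_position, set()).add(ann.motif_name)
    return [
        replace(s, motifs=tuple(sorted(by_position.get(s.position, ()))))
        for s in summaries
    ]


def motif_condition_tally(
    summaries: Sequence[SiteSummary],
    annotations: Sequence[MotifAnnotation],
    conditions: Sequence[str],
) -> dict[str, dict[str, int]]:
    """Per-motif, per-condition count of distinct acceptors with a detected site."""
    annotated = annotate_sites(summaries, annotations)
    tally: dict[str, dict[str, int]] = {}
    motif_names = sorted({a.motif_name for a in annotations})
    for name in motif_names:
        tally[name] = {
            cond: len(
                {s.position for s in annotated if name in s.motifs and s.detected_in(cond)}
            )
            for cond in conditions
        }
    return tally
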