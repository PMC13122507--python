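"""Scan a protein for checkpoint-signaling motifs and annotate phospho-sites.

Uses the shipped motif config (degenerate MELT, SHT, proline-directed
[S/T]P, and the Aurora B basic consensus) on a toy sequence, then attaches
motif names to a detected site.
"""

from phosite import (
    ProteinRecord,
    default_patterns,
    scan_motifs,
    annotate_sites,
    detect_and_classify,
)
from phosite.io import default_design
from phosite.sites import SiteEvidence

protein = ProteinRecord("DEMO", "AAMELTGGSPKARKSTASHTA")
patterns = default_patterns()
annotations = scan_motifs(protein, patterns)

print(f"{len(annotations)} motif occurrences in {protein.accession}:")
for a in annotations:
    print(f"  {a.motif_name:16s} match {a.match_start}-{a.match_end}, "
          f"phospho-acceptor at residue {a.acceptor_position} "
          f"({protein.residue(a.acceptor_position)})")

design = default_design()
evidence = [
    SiteEvidence("DEMO", 6, "T", cond, rep, 4, 97.0)
    for cond in design.conditions for rep in (1, 2)
]
(summary,) = annotate_sites(detect_and_classify(evidence, design), annotations)
print(f"\ndetected site T{summary.position} ({summary.category}) lies in: "
      f"{', '.join(summary.motifs)}")
print("a site whose acceptor coincides with a MELT threonine is a candidate "
      "MPS1/TTK substrate relevant to spindle-assembly-checkpoint signaling")
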