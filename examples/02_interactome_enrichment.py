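"""Pseudocount spectral-count enrichment of co-purifying proteins.

Builds a tiny PSM table for two proteins and computes the fold-change
matrix (mean PSMs + 1) / (mean reference PSMs + 1), the semi-quantitative
heat-map statistic of IP-MS interactomics.
"""

from phosite import PsmRecord, build_matrix, count_psms_per_protein
from phosite.io import default_design

design = default_design()

# BAIT is equally abundant everywhere; PARTNER is enriched on mitotic arrest
psms = []
sid = 0
for cond, n_bait, n_partner in [
    ("DMSO", 30, 12), ("nocodazole", 30, 27), ("paclitaxel", 31, 26), ("STLC", 29, 42),
]:
    for rep in (1, 2, 3):
        for acc, n in (("BAIT", n_bait), ("PARTNER", n_partner)):
            for _ in range(n):
                sid += 1
                psms.append(PsmRecord(f"s{sid}", cond, rep, acc, "GSAMPLEK", ()))

counts = count_psms_per_protein(psms, design)
matrix = build_matrix(counts, design)
print("fold change relative to DMSO (reference column is exactly 1):\n")
print(matrix.values.round(2).to_string())
print("\nPARTNER rises ~2-3x under every microtubule perturbation while the "
      "bait stays flat - the signature of an attachment-state-responsive "
      "interaction.")
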