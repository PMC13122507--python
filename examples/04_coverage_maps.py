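"""Per-residue coverage and depth profiling of a simulated purification.

Maps every PSM onto the protein, builds per-replicate depth vectors, and
prints the per-condition average coverage and depth-of-coverage summary.
"""

from phosite import (
    MappedPsm,
    SimulationConfig,
    average_coverage,
    coverage_profile,
    map_psm,
    simulate_psm_table,
)

cfg = SimulationConfig(seed=7, protein_length=2000)
psms, truth = simulate_psm_table(cfg)
design = cfg.design
mapped = [m for m in (map_psm(p, truth.protein) for p in psms)
          if isinstance(m, MappedPsm)]

print(f"{len(mapped)} PSMs mapped onto a {truth.protein.length}-residue protein\n")
print(f"{'condition':12s} {'coverage':>9s} {'mean depth':>11s}")
for cond in design.conditions:
    profiles = [
        coverage_profile(
            [m for m in mapped if m.psm.condition == cond and m.psm.replicate == rep],
            truth.protein,
        )
        for rep in design.replicates
    ]
    percent, depth = average_coverage(profiles)
    print(f"{cond:12s} {percent:8.2f}% {depth:11.1f}")
print("\ncoverage is the percent of residues seen by at least one PSM in a "
      "replicate, averaged over replicates; depth is the mean PSM count over "
      "covered residues. Deep spectral counting sits in the 20-35x regime.")
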