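# Methods

## Problem setting

An affinity-purified bait protein is analyzed by LC-MS/MS under several
experimental conditions (one designated the reference) with a fixed
number of replicates per condition. The search engine's output is
reduced to a PSM table: one row per peptide-spectrum match, carrying the
peptide sequence, condition, replicate, and variable modifications with
residue-level localization probabilities on a 0–100 percent scale.
`phosite` is deliberately search-engine-agnostic: rather than parsing a
specific vendor export, it defines a minimal explicit TSV dialect
(`spectrum_id`, `condition`, `replicate`, `protein_accession`,
`peptide`, `modifications`) that any export can be munged into. One row
is one counted PSM; the package never collapses or splits rows.

## Mapping model

Peptides are located in the bait sequence by exact substring match (I/L
distinct, since search engines report a concrete sequence). A peptide
found at exactly one position projects each modification to
`protein_position = start + peptide_offset − 1`. Multi-mapping peptides
are *excluded* from site calls and coverage and tallied as ambiguous:
no splitting rule is defensible without intensity information, and
exclusion is conservative and auditable in the run report. Unmatched
peptides are likewise tallied, never dropped silently.

In-silico digestion follows the classical tryptic rule — cleave
C-terminal to K/R except before P — implemented over
`pyteomics.parser.icleave` with the regex `[KR](?!P)`. The fuller
Keil-style exceptions (WKP, MRP) are intentionally not used; the simple
rule is the one the digest emulates and the one the brute-force test
oracle enumerates. Missed cleavages of a located peptide are counted as
internal K/R-not-before-P positions; a terminal K/R is the peptide's own
cleavage, not a missed one. N- and C-terminal peptides are ordinary
digest products; semi-tryptic peptides are out of scope.

## Coverage

`depth[i]` counts every uniquely mapped PSM overlapping residue *i*,
phosphorylated or not. Percent coverage is the fraction of residues with
depth ≥ 1. "Depth of coverage" is, by default, the mean depth over
*covered* residues (configurable to all residues via
`average_coverage(..., covered_only=False)`); both summaries are
averaged arithmetically across replicates. The identity
`Σ depth = Σ span lengths` holds exactly and is asserted in tests.

## Site detection and classification

Evidence is aggregated per (site, condition, replicate): the phospho-PSM
count (each PSM contributes one count to every distinct phospho-position
it carries — a doubly phosphorylated peptide counts once at each site)
and the best localization probability, taken as the **maximum** over
supporting PSMs. Probabilities are never multiplied or averaged: the
filter asks whether at least one spectrum localizes the site well.

A replicate passes when best probability **strictly** exceeds the
confidence threshold (default 75%) and the count meets the minimum
(default 2). Detection in a condition requires one passing replicate
(union semantics); the "star" for condition-unique sites requires two.
Condition means divide by the design's replicate number with zeros for
missing replicates, and use raw counts unaffected by the pass/fail
filter — so a site observed with 2 phospho-PSMs in one of three
replicates averages 0.67. Abundance bins are gray < 5, blue 5–10
(inclusive on both bounds), coral > 10.

Categories are assigned with precedence
`shared_all > mitotic_shared > unique_starred > other`; the precedence
is defensive — under these definitions the categories cannot actually
overlap — and makes the classification total. The four categories
partition the detected-site union, which the count report asserts.

## Interactome enrichment

Per-protein spectral counts are averaged over replicates (zeros
included) and compared with the reference through
`(mean + 1)/(mean_ref + 1)`. The pseudocount is applied to the
replicate-averaged values, exactly as the ratio is written, keeping the
statistic finite for proteins absent from the reference and making the
reference column identically 1. Each PSM row is attributed to exactly
one accession; protein inference and razor-peptide logic are out of
scope, as are SAINT/CompPASS-style significance scores — the matrix is a
semi-quantitative display statistic, not a test.

## Motif annotation

Motif patterns are position-restricted amino-acid classes in bracket
notation with a designated phospho-acceptor offset. The shipped defaults
(`src/phosite/data/motifs.yaml`) — degenerate MELT `[MILV][ED][LIVM]T`
and strict `MELT` (acceptor T), `SHT` (acceptor T), proline-directed
`[ST]P` (acceptor S/T), Aurora B `[RK]x[ST]` (acceptor S/T) — are
conventional consensus definitions, not ground truth; they are shipped
as config precisely so users can override them, and a curated list of
acceptor positions (`annotations_from_positions`) can replace scanning
entirely when a literature motif inventory exists for the bait. Scanning
reports all matches including overlaps; annotation attaches motif names
to sites whose position equals a motif acceptor and never alters
detection or classification fields.

## Synthetic data generator

The generator produces the complete experiment the analysis assumes,
with a ground truth for exact scoring. Its defaults describe a deep
four-condition (reference + three mitotic arrests), three-replicate
spectral-counting experiment:

| parameter | default | meaning |
|---|---|---|
| `protein_length` | 2000 aa in the acceptance run, smaller in unit tests | bait size |
| `kr_frequency` | 0.06 | per-residue K/R probability (mean tryptic peptide ≈ 17 aa; peptides > 40 aa are broken up) |
| `background_depth_mean` | 27 | Poisson mean PSMs per observable peptide per replicate → per-residue depth in the 20–35× regime |
| `masked_fraction`, `n_masked_blocks` | 0.25, 4 | contiguous unobservable regions → ~72–75% sequence coverage |
| `min_peptide_length` | 7 | shorter fully cleaved peptides never seed PSMs (reachable only via missed-cleavage extensions) |
| `missed_cleavage_rate` | 0.1 | probability a PSM retains one missed cleavage, extending into an adjacent peptide |
| `true_prob_range` | 90–100% | localization of genuine phospho-calls |
| `decoy_prob_range`, `decoy_rate` | 30–70%, 0.02 | low-confidence mislocalizations that exercise the >75% filter |
| `oxidation_rate` | 0.05 | methionine oxidation, as a non-phospho variable modification |

Partial coverage is modeled the way real coverage maps look: a few
contiguous blocks of the sequence (peptides that never ionize) stay at
zero depth, while the observable remainder sits at uniform Poisson
depth. An earlier design that made *short peptides* the only source of
coverage loss was rejected because missed-cleavage extensions re-cover
short peptides at depth ~1–3, producing an unrealistic long low-depth
tail; with masked blocks, ≥90% of covered residues fall inside the
20–35× band at the default depth, which the tests assert.

The default planted panel mirrors the occupancy structure of a
mitotically regulated bait: one constitutive high-occupancy site (0.5
everywhere), one constitutive low site (0.15), three sites at 0.25 in
the mitotic conditions only, and one site at 0.25 unique to each mitotic
condition. Occupancy is the probability that a covering PSM is
phosphorylated at the site, so expected phospho-PSMs per replicate =
occupancy × depth. Poisson sampling (not negative binomial) is the
default noise model; no dispersion information is available to fit, and
over-dispersion can be layered on by the caller by mixing seeds.

Everything derives from `numpy.random.default_rng([seed, k])` streams,
so identical configs give byte-identical PSM and truth tables.

### What the generator does and does not emulate

It reproduces the counting structure the analysis depends on —
replicated Poisson depth, occupancy differences, localization noise,
missed cleavages, partial coverage, multiply phosphorylated peptides. It
does **not** model spectra, retention time, charge states, intensity,
peptide-specific ionization efficiency, correlated replicate effects, or
search-engine score distributions. Passing tests therefore demonstrate
that the aggregation, filtering, classification and enrichment logic is
correct and well-calibrated under the assumed counting model — not that
the filter thresholds are optimal for any particular instrument or
search engine.

## Recovery scoring

`evaluate_recovery` reports sensitivity (planted sites detected /
planted), false discoveries (detected, never planted), and
classification accuracy: the fraction of planted sites whose assigned
category equals the category implied by their occupancy design (a
planted site that goes undetected counts as a misclassification; with no
planted sites, sensitivity and accuracy are reported as NA).

## Numerical and formatting choices

Output floats are rendered at two decimals (`0.67`, `18.33`-style);
internal computation is double precision throughout. Ties: color-bin
bounds 5 and 10 are inclusive to the middle bin; the confidence filter
is strictly greater-than. Degenerate inputs are well-defined: an empty
PSM table yields header-only outputs and a success exit with a warning;
a protein with no covered residues reports 0% coverage and depth 0; an
all-zero protein row in the enrichment matrix is a row of ones.

## Problem sizes

Unit and property tests run on proteins of 120–600 residues with depth
5–10 (hundreds to a few thousand PSMs), sized for exhaustive oracle
comparison; the acceptance run uses the full default regime (2000
residues, depth 27, ~22k PSMs). These sizes were chosen so the oracle
recomputations stay exact and fast while the acceptance run exercises
the generator at its documented defaults.

## Known limitations

- No protein inference: a PSM's accession assignment is trusted.
- No stoichiometry/occupancy estimation from data — spectral counting
  is semi-quantitative by construction, and no differential test is
  attached to the fold-change matrix.
- Localization probabilities are consumed as given; the package neither
  recomputes nor recalibrates them.
- Multi-protein site analysis runs one bait at a time; interactome
  counting is table-wide.
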