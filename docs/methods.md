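# Methods

## Scope and design

`maitcr` analyzes single-cell immune-profiling data of MAIT cells:
gene-expression counts, antibody-derived-tag (ADT) counts, and VDJ contig
annotations for the same barcodes. The package deliberately avoids
clustering, embedding, and dataset integration: subset assignment is a
per-cell rule (clusters in the original workflows are only a vehicle for
the same transcript+antibody evidence), which keeps every downstream
fraction auditable as a ratio of two counts.

## Synthetic-data generator

The generator emulates the statistical structure of sorted blood
MR1-5-OP-RU-tetramer⁺ MAIT cells so that every pipeline stage can be
tested against known ground truth. Its preset defaults are the study
conditions, not tuning knobs:

| parameter | default | meaning |
|---|---|---|
| `subset_probs` | DN 0.50 / CD8 0.35 / CD4 0.15 | subset composition |
| `canonical_alpha_prob_by_subset` | DN 0.65 / CD8 0.85 / CD4 0.10 | P(α = TRAV1-2) per subset |
| `canonical_traj_prob_given_trav12` | 0.90 | P(TRAJ33/20/12 join) for TRAV1-2⁺ chains |
| `canonical_traj_prob_given_noncanonical` | 0.08 | same for TRAV1-2⁻ chains |
| `canonical_trbv_prob_given_trav12` | 0.90 | P(TRBV6-1/6-4/20-1 pairing) |
| `dual_alpha_prob` | 0.09 | P(two productive α chains) |
| `dual_alpha_category_probs` | both 0.35 / one 0.40 / neither 0.25 | TRAV1-2 content of dual-α cells |
| `gly_motif_prob` | 0.25 | P(central GGG/GGGG run) in noncanonical CDR3α |
| `v_at_pos3_prob` | 0.65 | P(valine at CDR3α position 3), mid-range of 60–70% |
| `canonical_len_range` | 12–14 | canonical CDR3α lengths |
| `noncanonical_len_range` | 7–23 | noncanonical CDR3α lengths |
| `contaminant_fraction` | 0.05 | NK/γδ-like cells in the sort |
| `qc_outlier_fraction` | 0.02 | cells planted above QC ceilings |
| `nb_dispersion` | 2.0 | negative-binomial size for gene counts |

Counts are negative binomial over a compact ~40-gene panel (MAIT identity
markers, CD3 complex, coreceptors, effector and costimulatory programs,
housekeeping); ADTs are rounded log-normals (σ = 0.4 on the log scale);
marker means were chosen once to give the clear bimodal separation seen
in sorted CITE-Seq data (identity markers at 8–18 mean counts in MAIT
cells versus ≤2 in contaminants, CD8B/CD4 transcript means of 15 in their
subsets so detection dropout stays below ~1.5%). CD8A is drawn as
1 + NB(μ−1) in MAIT cells, encoding the observation that essentially all
MAIT cells have detectable CD8A transcript regardless of surface
phenotype — which is exactly why the subset rule uses CD8B.

Per-cell QC metrics are planted directly: mitochondrial fraction from
Beta(4, 156) (mean 2.5%), realized through five mitochondrial genes whose
counts reproduce the drawn fraction; detected-gene counts from a clipped
normal (2,500 ± 500). QC violators (2%) are drawn above the ceilings.
The detected-gene metric is carried in a per-cell QC table rather than
derived from the compact panel, whose size is far below transcriptome
scale; annotation consumes the table when present and can recompute both
metrics from a full matrix otherwise.

CDR3α grammar. All strings start with the conserved C/A anchor pair.
Canonical chains (TRAV1-2 with a canonical join) end in the 7-residue
germline tail of their joining segment (TRAJ33 `SNYQLIW`, TRAJ20
`NDYKLSF`, TRAJ12 `SSYKLIF`), each of which places the conserved tyrosine
(Y95α) 5 positions from the C-terminus. Noncanonical chains draw a length
in 7–23, set position 3 to valine with probability 0.65, plant a central
GGG/GGGG run (CD4 cells favor GGGG and may instead carry NNNN, at
probability 0.10) intersecting positions 6–9, and end in J-like residues
from {L, I, T, F, W}. Unplanted glycine runs of length ≥ 3 are scrubbed
so the planted motif rate is identifiable by string inspection; a
TRAV1-2⁺ chain with a noncanonical join draws its length outside 12–14 so
that the 12–14 band's prevalence among TRAV1-2⁺ cells equals the planted
canonical-join rate. Conditions (ex vivo / IL-2 / IL-2+Mtb) are assigned
uniformly with a zero canonical-probability shift by default, because the
encoded proportions are pooled over conditions; the shift is exposed for
experiments.

What the generator does **not** emulate: transcriptome-wide expression,
read-level errors, doublets/hashtag collisions, clonal expansion (each
cell's CDR3 is drawn independently, so clonotype-frequency structure is
absent), germline nucleotide-level recombination, and batch effects.
Passing recovery tests therefore demonstrates that the pipeline's rules
are implemented correctly and are unbiased under realistic noise — not
that the annotation would reach the same accuracy on arbitrary real data.

## QC and annotation

Two shipped QC presets: `kaur` (remove cells with more than 6,000
detected genes or more than 5% mitochondrial content) and `garner`
(3,000 / 8%), both strict inequalities, so boundary cells are kept.
"Gene counts" is read as detected genes per cell (nFeature semantics).

Lineage gating scores each cell as the mean CP10K/log1p expression of
KLRB1, ZBTB16, IL18R1, and SLC4A10 and calls MAIT above an Otsu split of
the bimodal score (a fixed threshold can be supplied), additionally
requiring at least one raw CD3E count. On preset data this yields ≥ 0.95
recall with ≤ 0.05 contaminant leak-through.

Subset assignment is per-cell and dual-modality: CD8⁺ requires CD8B
transcript ≥ 1 (detection) **and** a positive anti-CD8 tag; CD4⁺
symmetrically; both → DP, neither → DN. ADT positivity defaults to a
2-component Gaussian mixture on the tag's CLR values thresholded at the
midpoint of the component means (`random_state=0`, deterministic); a
quantile threshold is available as fallback. CLR is computed per cell
across tags with a +1 pseudocount, so its scaling invariance is exact up
to that pseudocount. Per-cell ADT gating is an approximation of
cluster-level gating; with well-separated tags it agrees with ground
truth at ≥ 0.95 on preset data.

Differential expression between cell groups uses the unpaired Wilcoxon
rank-sum (Mann–Whitney U) test with midrank ties and asymptotic two-sided
p-values, Benjamini–Hochberg adjustment, and log2 fold changes of group
means on the normalized scale with a 0.1 pseudocount.

## Repertoire rules

Only productive, high-confidence contigs enter pairing; redundant
identical contigs (same V/J/CDR3) collapse to the highest-UMI copy.
1 TRA + 1 TRB → single pair; 2 TRA + 1 TRB → dual-α, categorized by the
number of TRAV1-2 α chains; > 2 TRA or > 1 TRB → multiplet, excluded from
all repertoire statistics. Dual-α cells are excluded from single-pair
denominators (the repertoire fractions condition on "cells with a single
paired αβ TCR") and contribute their TRAV1-2 chain, once per cell, to
TRAV1-2-stratified statistics. Gene symbols are normalized at read time:
allele suffixes stripped, `TRAJ-33`-style spellings collapsed, `/DV` dual
names preserved.

Diversity uses natural-log Shannon entropy, reported alongside Simpson,
richness, and Pielou evenness, because published per-subset diversity
axes are rarely labeled with the index used; conclusions in this package
never depend on which of the four is chosen.

## CDR3 conventions

Positions are 1-based in every report. The "conserved tyrosine at
position 95" is operationalized as the 5th residue from the CDR3α
C-terminus: IMGT unique numbering cannot be recovered from a bare CDR3
string, while the J-anchored offset is exact for the germline tails of
all three canonical joining segments across lengths 12–14. The
conserved-terminal summary reports last-k (default 3) residue composition
over {L, I, T, F, W} — these residues are J-segment-encoded C-terminal
ends, although they are sometimes described as "N-terminal" in the
literature; this package uses the C-terminal reading. Motif detection
enumerates overlapping occurrences (a GGGG run contains two GGG hits) and
can optionally require the hit span to intersect the central window
(positions 6–9).

## Epitope matching

Percent similarity is 100 × (matched positions in an optimal global
alignment with match 1, mismatch 0, gap 0) / max(length); with these
scores the optimum equals the longest common subsequence, and the measure
reduces to percent identity for equal lengths. This definition was chosen
because published similarity percentages from web tools come without a
stated formula; it is symmetric, bounded, reproducible, and 100 iff the
strings are identical. Perturbed matching enumerates all variants of the
query with up to two deletions or up to two insertions (any of the 20
residues, internal positions only, preserving the C anchor and terminal
residue; insertions and deletions never mixed in one variant, and the
reference is never edited). Ties break toward smaller budget, then
lexicographic epitope, then reference CDR3. A 12-row synthetic reference
table (canonical MAIT-like plus viral/celiac/cancer-like entries) ships
for tests and demos; real analyses should point `read_reference` at a
downloaded McPAS-style CSV. The similarity percentages produced here are
not expected to reproduce numbers from external web services.

## Numerical and degenerate-input choices

- Empty groups yield count 0 with NaN proportions, flagged rather than
  dropped; all-zero diversity input raises.
- `tyr95_test` on sequences shorter than 6 returns False with a warning.
- Pairing tie-breaks (UMIs descending, then lexicographic CDR3) make all
  calls invariant to contig input order; stable sorts throughout.
- The Gaussian-mixture ADT threshold uses a fixed random state; Otsu is
  deterministic given the data.
- All randomness flows from one `numpy.random.Generator` seeded by the
  config, making generated bundles byte-identical across runs.

## Problem sizes

Recovery checks run at 10,000 simulated cells (seed 42), where binomial
sampling error on the recovered percentages is roughly 0.5–1.5 points for
the subgroup sizes involved; property suites use small crafted fixtures
and 1,000-case randomized oracles. The acceptance script runs the same
10,000-cell pipeline end to end.

## Known limitations

- Per-cell ADT gating approximates cluster-level gating; tags with poor
  separation will degrade subset accuracy before anything else fails.
- The generator's independence assumptions (no clonal structure, no
  condition effects by default) make diversity values on synthetic data
  higher than clonally expanded real repertoires.
- Epitope similarity is sequence-only; it carries no information about
  MHC restriction or binding geometry.
- The compact gene panel supports the pipeline's logic, not
  transcriptome-scale method development.
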