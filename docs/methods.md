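# Methods

## The two-allele demethylation model

A near-diploid cell carries two methylated epialleles at each silenced
promoter CGI. Under drug exposure each allele demethylates independently
with probability `p_demeth`, so the per-cell demethylated-allele fraction at
a locus is k/2 with k ~ Binomial(2, p): exactly 0, ½ or 1, never anything in
between. Demethylation events are independent across alleles, loci and
cells, and clonal expansion is epigenetically faithful — a clone's β profile
is exactly 1 − its founder's allele fraction. There is no re-methylation or
further demethylation during expansion; this is the simplest model
consistent with clones retaining complete demethylation weeks after
treatment. Ploidy is fixed at 2 and not parameterized.

Consequences used throughout:

- bulk β of a silenced locus → 1 − p (partial demethylation only; the
  probability that a 1000-cell bulk average drops below the 0.2 complete-
  demethylation cutoff at p ≤ 0.3 is astronomically small),
- a clone is completely demethylated at a locus with probability p², half
  with 2p(1−p),
- the union over k clones covers 1 − (1−p²)ᵏ of the candidate loci in
  expectation.

## Default study conditions

The simulator's defaults define the synthetic study and are fixed:

| parameter | default | meaning |
|---|---|---|
| `n_loci` | 1040 | silenced promoters: 1039 TSS200-CGI blocks + 1 CGI-less (CDKN2A-like) promoter |
| `n_background_loci` | 960 | baseline-unmethylated open-sea loci (β ≈ 0 everywhere) |
| `n_cells` | 1751 | treated-population size (matches the treated single-cell count analysed) |
| `n_clones` | 9 | single-cell clones sampled without replacement |
| `p_demeth` | 0.3 | per-allele demethylation probability (reference setting for all stated laws) |
| `probes_per_block` | 3 | array probes emitted per locus |
| `beta_noise_concentration` | 100 | Beta-noise concentration κ around the noise-free β |
| `expr_mean` | 5 | mean UMI count of a fully demethylated gene |
| `expr_dispersion` | 1 | negative-binomial size r |
| `isg_coupling` | 1 | γ: ISG mean × (1 + γ · # active ERV loci in the cell) |
| `dead_multiplier` | 1.5 | p multiplier for the dead-cell pool (capped at 1) |

The first silenced loci carry the symbols of genes known to be
methylation-silenced in the modelled colorectal line (the four pathway sets,
FBLN2, ICAM4, and the ERVs ERVMER61-1/ERVW-1) so the pathway and scRNA
stages run with realistic identifiers; the rest are generic. Observed
per-clone complete-demethylation rates of 12–28% in cloned cells would
correspond to p ≈ 0.35–0.53 under this model; 0.3 is kept as the single
reference setting at which all quantitative laws are stated.

`dead_multiplier = 1.5` is a calibration, not a mechanism: whether surviving
clones' lower demethylation reflects selection or chance is unresolved, so
the dead pool simply draws with p × 1.5. With the default locus mix this
puts the dead-minus-surviving mean-Δβ contrast at
(0.45 − 0.30) × (1040/2000) × 100 ≈ 7.8 percentage points.

## Noise and count layers

**Probe noise.** A probe's observed β is Beta(mκ, (1−m)κ) with m the
noise-free block β and κ = `beta_noise_concentration`; boundary truths are
floored into [10⁻³, 1−10⁻³] so the distribution is proper on proportions.
At κ = 100 the probe SD at m = 0.5 is ≈ 0.05; the 3-probe block mean at
baseline β ≈ 1 essentially never crosses the 0.8 threshold, so the baseline
universe at default settings is the full 1039 island blocks.

**UMI counts.** Counts are negative binomial with size r =
`expr_dispersion` and per-cell mean `expr_mean` × allele fraction (TSG/ERV
genes), `expr_mean` (background/housekeeping genes), or
`expr_mean` × (1 + γ · # ERV loci with fraction ≥ ½ in the cell) for
interferon-stimulated genes, which have no methylation entry of their own.
Zero mean yields exactly zero counts. Counts are raw: no library-size
normalisation, log transform or scaling anywhere — inducibility (max mock
count ≤ 2), ranking (mean treated count) and upregulation (count ≥ 3)
operate on deduplicated counts directly, and so do the clustering and
embedding distances.

## Block assembly and classification

Probes group into blocks by (gene, TSS-region class, CGI class); intergenic
probes group by (chromosome, CGI class) split at gaps > 1 kb. Block ids are
deterministic from the grouping key, every probe lands in exactly one block,
and a precomputed block file can override the built-in rules (membership is
recovered from the manifest), since genome-wide block counts are manifest-
and rule-dependent. The manifest schema carries no per-TSS coordinate, so a
gene contributes one block per (region, CGI) combination rather than one
per annotated TSS. Block β is the arithmetic mean of non-missing member
probes; a block is missing only when all members are. Classification is the
half-open partition unmethylated [0, 0.2) / partially methylated [0.2, 0.8)
/ fully methylated [0.8, 1]; NaN maps to an explicit missing sentinel
excluded from downstream counts. Both block-universe totals (all blocks;
blocks non-missing in every sample) are reported, as genome-wide analyses
quote either.

## Clone statistics

Complete demethylation: block β < 0.2 in a clone, restricted to blocks
fully methylated (β ≥ 0.8) in the mock bulk. Percentages are rounded half-up
to one decimal to match hand-reported values. The overlap between two
clones' demethylated sets is reported directionally —
entry(A,B) = 100·|A∩B|/|A| — because published clone-by-clone grids are
asymmetric; a symmetric Jaccard variant (100·|A∩B|/|A∪B|) is computed
alongside, and neither is asserted to be the published convention. A clone
with zero calls has an undefined (missing) overlap row and triggers a
warning. `mean_delta_beta` is the mean of (β_reference − β_sample) over
shared non-missing blocks, in percentage points; the difference of two
samples' values gives contrasts such as dead-pool minus surviving.

Hierarchical clustering (clones and cells) is agglomerative with Euclidean
distance and complete linkage; observations are sorted lexicographically by
label before linkage so ties break deterministically and results are
invariant to input order. Constant profiles yield a degenerate all-zero-
height dendrogram, not an error. Newick export computes branch lengths as
merge-height differences, iteratively (cell-level trees exceed the default
recursion limit).

## Pathway calls

A pathway is "normalized" in a clone iff at least one member gene's
designated block has β < 0.2 there — the operationalisation of single-gene
re-activation driving pathway-level change; functional (phenotypic)
validation is out of scope. Gene sets default to cell-cycle {CDKN2A, CHFR},
WNT {DKK3, SFRP1, SFRP2, SFRP5, SOX17, WIF1}, p53 {IGFBP7, MIR34B}, TGF-β
{BMP2, BMP3, BMP6, BMPR1B} and are overridable via a two-column TSV
(MIR34B is keyed by its own symbol; annotations that house its CGI under a
host gene can override). Gene→block resolution prefers the gene's
TSS200-island block; a gene without one falls back to the candidate block
most 5′ of exon 1, strand-aware (lowest start on +, highest end on −),
given exon-1 coordinates. Every true call records its supporting
(gene, block, β) evidence.

## Embedding

The 2-D embedding is UMAP with a fixed `random_state` (single-threaded for
determinism); its only contract is seed-reproducibility and preservation of
the mock/treated separation, scored as k-means(2) cluster purity of the
condition labels on the embedding. Neighbour count is min(15, n−1) and
min_dist 0.1 by default; these are config keys, not asserted against any
reference layout. Constant matrices embed degenerately with a logged
warning.

## Seeding and reproducibility

One global seed drives named `SeedSequence` substreams (population, mock,
dead pool, founder sampling, probe noise, UMI per condition), so changing
one stage's draws never shifts another's, and identical seed + parameters
give bit-identical outputs — the pipeline's rerun is byte-identical
including the embedding. The pipeline writes a manifest (inputs, outputs,
config hash, seed) and every output file is declared in it.

## What the synthetic data does and does not show

The generator reproduces the mechanistic skeleton: two-allele stochastic
demethylation, faithful clonal inheritance, bulk averaging, bounded probe
noise, and methylation-coupled overdispersed counts with dropout (NB zeros).
It does not model cell-death kinetics or dose–response, re-methylation,
copy-number variation, probe-specific biases, batch effects, doublets or
ambient RNA, and clone founders are drawn uniformly (no fitness selection).
Passing tests therefore demonstrate correctness of the analysis operations
and internal consistency of the model — not that real arrays or real scRNA
libraries satisfy the model's independence assumptions.

## Problem sizes

Tests and the acceptance script run at the default study scale (2000 loci ×
1751 cells, 9 clones) for the pipeline checks, 10,000 cells for the
two-allele law, 50 seeded replicates at 1000 cells for the bulk-versus-
clone contrast, and 20 seeded replicates for the p̂ = √(call fraction)
recovery; hand-built fixtures of ≤ 60 probes back the exact oracles.
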