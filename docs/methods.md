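# Methods

## The model

A matched knockdown design observes an epigenomic factor twice: as ChIP
peak sets in control and knockdown conditions, and as replicate expression
matrices in both conditions. The factor's *epigenomic target genes* are
genes whose promoters carry a peak present in control but lost after
knockdown (binding is defined by presence/absence of signal, not
magnitude; two peaks are "the same" when their overlap covers at least
half of the shorter interval, boundary inclusive). Promoters are the 1 kb
window immediately upstream of the TSS, strand-adjusted
(`[TSS − 1000, TSS)` for `+` genes, `[end, end + 1000)` for `−` genes);
a peak straddling the TSS is classified promoter, not gene body, since the
promoter class is the one the analysis consumes. Multi-gene conflicts
resolve by nearest TSS, then lexicographic symbol.

Cooperation evidence comes from four branches:

* **AME (ChIP)** — for each motif, a promoter is a *hit* when its best
  window's exact score p-value is ≤ 1e-4 (the conventional scanning
  threshold; configurable). Hits in target vs non-target promoters form a
  2×2 table tested with the one-sided Fisher exact (hypergeometric upper
  tail). Window scores are log2 odds against the background composition;
  their null distribution is computed exactly by dynamic programming on an
  integer lattice at 1000 units per bit, with per-cell scores floored onto
  the lattice so reported p-values are conservative. Windows containing N
  are skipped, both strands are scanned, and ties in significance break to
  the smaller offset, then the `+` strand.
* **TFT (ChIP / transcriptomics)** — hypergeometric upper-tail enrichment
  of a TF's regulon in the target-gene set (universe: all modeled
  promoters) or in the DE set (universe: all measured genes). Each
  platform's universe is its own detectable space.
* **URA (transcriptomics)** — the regulon/DE overlap p-value as above plus
  an activation score `z = Σ_t c_t / √N` over the `N ≥ 4` overlapping DE
  targets, where `c_t = −direction_t · sign_t` (edge sign `+1` activating,
  `−1` repressing). The minus sign inverts knockdown-measured directions
  so `z > 0` always means "the regulator is active when the epigenomic
  factor is present". Flipping every DE direction negates `z` exactly.

Differential expression uses a per-gene Welch t-test on log-scale
replicate intensities with Benjamini–Hochberg adjustment (`adj p < 0.05`).
Genes with zero pooled variance get p = 0 when means differ and p = 1
otherwise, so the noise-free fixture is handled exactly. DE genes with
negative log fold change under knockdown are *positively regulated* by
the factor; the regulation split is reported as one-decimal percentages.

## Harmonization and intersection

Sequence-level evidence cannot separate homologous family members, so AME
and ChIP-TFT results are aggregated to TF families (dotted
`superclass.class.family` barcodes, each TF in exactly one family). The
family statistic is the minimum member BH-adjusted p — any member's logo
detects the family — with no extra family-level correction, because member
p-values are already adjusted genome-wide within their branch. Families
significant in all four branches are intersected; individual TFs are then
kept when their family survived *and* both transcriptomic branches call
them at α = 0.05 *and* (by default) `z ≥ 2`, the conventional directional
cut. Both the direction gate and the threshold are configurable, since a
p-only refinement is equally defensible; the default is the stricter,
directional mode. The final network restricts each kept TF's regulon to
targets that are simultaneously DE and epigenomic targets; edges carry
motif/peak/DE evidence flags, per-target TF-degree defines hyperconnected
targets (degree ≥ 3), and specificity is summarised as the percentage of
all classified TFs entering the network.

## The synthetic study

`generate_study(SimConfig(...))` builds a fully deterministic toy study on
one chromosome: `n_genes = 600` genes of 2 kb spaced 3 kb apart with random
strands, i.i.d. promoter sequence at configurable GC (default uniform),
and 10 TFs — 3 cooperating, 3 decoys, 1 family sibling, 3 nulls. Each TF
gets a random signed regulon (60 targets, 65% activating) and a motif: a
10-mer PSSM putting 0.9 on a random consensus base per column. Planted
instances are sampled column-wise from the matrix (not the consensus), so
scanning statistics stay honest; with a zero-entropy matrix this reduces
to the literal consensus. Cooperating TFs receive:

* planted motif instances in their target promoters with probability
  `fg_occupancy = 0.8` (elsewhere `bg_occupancy = 0.05`), at uniform
  random offset and strand — later plants may overwrite overlapping
  earlier ones on shared targets;
* control-only promoter peaks on targets at `peak_rate_target = 0.8`
  (background genes at 0.05), plus shared non-differential gene-body
  peaks (15%) and knockdown-only noise peaks (3%);
* expression shifts of `∓lfc_effect = 2` log2 units (sign = regulon edge
  sign × direction of factor loss: activating targets drop under
  knockdown), with replicate noise scaled so null log fold changes have
  SD `lfc_noise_sd = 0.25` across `n_replicates = 3` per condition.
  Targets shared between regulators take the first regulator's shift.

These defaults describe a compact microarray-scale experiment with strong
but imperfect per-branch signal: each branch's per-TF detection is high
yet below 1, so the four-way intersection — not any single branch — is
what makes recovery reliable.

Decoys violate exactly one branch, and the violation is *structural*, not
chance-level: a merely unsupported branch would still clear α in ~5% of
studies and decoys would leak into the network over repeated runs.
Concretely, the motif-violating decoy's motif is planted only outside the
epigenomic target promoters (depleted, enrichment p ≈ 1); the
peak-violating decoy draws its regulon from peak-free genes (overlap far
below expectation); the direction-violating decoy shifts its targets with
signs chosen to keep the running edge/response consistency balanced, so
`z ≈ 0` even after collisions with other regulons. The sibling shares the
first cooperating TF's motif and family barcode but has no functional
support, exercising the family-versus-gene resolution: its family is
called through the shared logo, the TF itself never survives gene-level
filters.

What the generator does **not** emulate: read-level ChIP signal (peaks are
intervals, not coverage), sequencing error, correlated replicate noise,
isoform structure, higher-order sequence composition, and TF-TF
cooperativity at the sequence level. Passing tests therefore demonstrate
the statistical machinery and its integration, not robustness to real
ChIP artefacts or expression batch effects.

## Numerical choices

* Coordinates are 0-based half-open throughout (BED convention).
* PSSM pseudocount 0.01 per cell (`p' = (p + c)/(1 + 4c)`) keeps log-odds
  finite; consensus strings (IUPAC allowed) import as near-degenerate
  matrices.
* The score-distribution DP carries exact probability mass (checked to
  1e-6); p-values are clipped to `(0, 1]`.
* Fisher/hypergeometric tails come from `scipy.stats.hypergeom`, BH from
  `statsmodels`; both are verified against integer-arithmetic enumeration
  in the test suite. BH is not idempotent in general; its fixed points
  (constant vectors) are tested instead.
* Degenerate inputs: all-zero 2×2 tables give p = 1; an empty DE set
  flags the regulation split as undefined; TFs without surviving edges
  stay in the network as isolated nodes with a warning; peaks on unknown
  chromosomes are classified intergenic with a logged note.
* Null calibration of motif enrichment is run at hit threshold 1e-3 with
  500 sequences per class: at 1e-4 hits are so rare that the exact test's
  discreteness, not any implementation property, dominates the comparison
  with the uniform distribution.

## Problem sizes

The planted-recovery study uses 50 independent studies at the default
conditions (mean Jaccard against ground truth ≥ 0.9, zero decoy or sibling
recoveries); motif-branch power uses 50 studies of 200 + 200 promoters at
occupancy 0.8 vs 0.05; null calibration uses 200 studies; DE calibration
20 studies. Oracle equivalence is exhaustive: every 2×2 table with total
≤ 30 and every background word for motif widths ≤ 6.

## Limitations

* The upstream-regulator score is the published overlap-plus-`z` formula;
  commercial causal-network implementations add curated edge weights and
  mechanistic depth that are out of scope here.
* The AME branch uses one test (Fisher exact on best-hit thresholding);
  rank-based variants are not implemented.
* Family aggregation by minimum member p is deliberately permissive;
  with very unequal family sizes it favours large families, which is
  exactly why the gene-level refinement follows it.
* Meta-gene flanks (3 kb, 100 bp bins, 40 body bins) are a reporting
  convention; only the 1 kb promoter definition feeds the statistics.
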