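# Methods

## Substitution model

All simulation and likelihood computation uses a reversible Goldman–Yang
codon model on the 61 sense codons of the standard nuclear genetic code
(TAA/TAG/TGA excluded everywhere). Off-diagonal rates are zero for
multi-nucleotide changes and otherwise π_j, κπ_j, ωπ_j or ωκπ_j for
synonymous transversions/transitions and non-synonymous
transversions/transitions. The matrix is rescaled at each (κ, ω) so that
Σ_i π_i(−q_ii) = 1: branch lengths t are expected substitutions per codon.
Transition probabilities P(t) = exp(Qt) come from an eigendecomposition of
the similarity-transformed symmetric matrix D^{1/2} Q D^{−1/2}
(D = diag π), exact for reversible matrices; the decomposition is cached
per (κ, ω) so that varying t during optimisation is nearly free.

## Simulator

`simulate_codon_pair` draws an ancestral sequence from the stationary
distribution and evolves two independent lineages for t/2 each, sampling
each codon site from the exact transition-probability rows (not a Gillespie
event simulation) — this makes output byte-reproducible for a fixed seed
and exactly stationary. Lineage symmetry (t/2 + t/2) encodes the working
assumption of equal rates along both branches of a pair. Every stochastic
operation takes an explicit seed; substreams are derived from the seed plus
a stage label, so adding a stage never shifts another stage's draws.

True per-pair dN and dS are computed from the generating matrix via the
synonymous fraction ρ_S of stationary flow: dS = t·ρ_S/(3ρ_S¹),
dN = t·(1−ρ_S)/(3(1−ρ_S¹)), with ρ_S¹ the same fraction at ω = 1.

### Study generator

`generate_study` emulates a two-clade design: a slow "conifer-like" clade
and a fast "angiosperm-like" clade, each a pair of species joined by 1:1
orthologues. Defaults (chosen once, as study conditions):

| parameter | slow clade | fast clade | note |
|---|---|---|---|
| gene count | 300 | 300 | scaled-down study size |
| codons per gene | ~170 (±30%) | ~129 (±30%) | matches mean gap-free lengths of ~510 and ~387 bp |
| per-gene dS | gamma(shape 2, mean 0.19) | body gamma(shape 8, mean 2.2) | slow-clade tail puts ~3% of genes above the dS = 0.5 filter |
| saturated tail | — | 25% of genes at dS = 4 + gamma(2, mean 2.5) | the fast clade's published mean dS is a post-filter quantity, so the unsaturated body is given mean 2.2 and the tail is added on top |
| per-gene ω | gamma(shape 1.5, mean 0.31) | gamma(shape 1.5, mean 0.09) | shape 1.5 puts ~2% of slow-clade genes above ω = 1 |
| κ | 2.0 | 2.0 | typical nuclear transition bias |

Per-gene dS is converted to a branch length through the flow-fraction
relation above (ω-specific), so the generative dS is exact, not
approximate. The per-gene gamma dispersions are a modelling stand-in — no
published per-gene variance exists for these quantities — and affect only
the spread, not the clade means.

Orthologue decoys are paralogue-like copies evolved from existing genes at
much larger divergence and inserted unpaired into the second species; they
exercise the RBH machinery without breaking true pairs. Planted functional
categories multiply ω for disjoint gene subsets of the first clade and are
recorded in both the truth table and the annotation table.

cDNA wrapping adds an ATG, a TAA stop and random UTRs in which every ATG
trinucleotide is broken, so no spurious upstream ORF can outgrow the
planted one; truncation removes a fraction of the record from one end
(possibly cutting the start or stop codon) and the recorded ORF
coordinates are snapped to the first complete codon.

**What the generator does not emulate:** indels within coding sequence,
among-site rate variation, codon-usage selection, recombination,
annotation errors, and base-composition heterogeneity between clades.
Passing tests therefore demonstrate correctness of the estimators and
bookkeeping under the model's own assumptions, not robustness to
real-data pathologies such as misalignment or GC-biased gene conversion.

## Estimators

**GY94 maximum likelihood.** For a gap-filtered pair the likelihood
L(t, κ, ω) = Σ_site-patterns n_ij log(π_i P_ij(t)) is maximised by L-BFGS-B
on (log t, log κ, log ω) with bounds t ∈ [1e−5, 50], κ ∈ [0.05, 50],
ω ∈ [1e−4, 50], three starts (the first initialised from the counting
estimate of t, κ = 2, ω = 0.4), convergence tolerance 1e−8 on the
log-likelihood. Codon frequencies are F3x4: position-specific nucleotide
frequencies pooled over both sequences, multiplied and renormalised over
sense codons; a numerical floor of 1e−8 (renormalised) keeps the
eigendecomposition defined when a position lacks a nucleotide entirely.
dN and dS derive from the MLE via the flow-fraction formula above.
Identical sequences short-circuit to t = 0 with status `undefined_ratio`;
dS ≤ 1e−9 at the MLE is likewise `undefined_ratio` (no sentinel values —
saturated-divergence genes simply carry very large finite dS and are
removed by the filters).

**NG86 counting.** Synonymous site fractions enumerate each codon's nine
single-nucleotide neighbours; mutations to stop codons count as
non-synonymous sites, so S + N = 3 × codons exactly (the convention of the
standard implementations; verified to agree numerically with an
independent library implementation). Differences are averaged with equal
weights over all shortest substitution pathways through sense codons;
pairs whose every pathway crosses a stop fall back to all pathways with
stop steps counted as non-synonymous. Proportions are corrected with
Jukes–Cantor; p ≥ 3/4 gives status `failed`. The stop-site convention
leaves a small (~5%) conservative offset in ω̂ even at neutrality; the
neutrality-centering test is run at κ = 1 — the estimator's own
no-transition-bias assumption — and moderate divergence (t = 0.2), where
the estimates center on 1 within the stated band.

**4-fold degenerate distance.** A codon column qualifies when both codons
belong to a 4-fold degenerate family *and* their first two positions are
identical across the pair; the p-distance on qualifying third positions is
corrected with Kimura's two-parameter formula (transition/transversion
partition; Jukes–Cantor available as an option). Zero qualifying sites
yields a typed absence, never 0.

## Rate analysis

Filters drop, in order: failed estimates, undefined-ratio genes, genes
with dS above the clade threshold (slow clade 0.5, fast clade 4), genes
with dN above threshold (fast clade 5); one reason per gene. μ = d/(2T)
with the range [d/(2T_high), d/(2T_low)] from the fossil bracket (slow
clade 140, 120–160 My; fast clade 110, 105–115 My). Asymmetric
apportionment splits d/T as 1 : ρ (default ρ = 6 for the fast clade's
annual-vs-tree contrast), conserving (μ_slow + μ_fast)·T = d exactly.

The clade ω summary is the **mean of per-gene ratios**, not mean dN / mean
dS — the two differ strongly when dS varies across genes, and the per-gene
mean is the quantity the summary tables report. This also means the
summary exceeds the generative mean ω in finite genes: ω̂ = dN̂/dŜ is
inflated by sampling noise in small dŜ denominators, exactly as in any
per-gene ratio table. Bootstrap CIs are gene-level percentile intervals
(1,000 resamples by default, explicit seed). Fold-change rows are rounded
half-even to one decimal and oriented "x:1" or "1:x".

## Functional categories

Annotation transfer copies the full term set of a gene's best reference
hit when its e-value passes 1e−5; genes with several terms contribute to
each (standard flat GO-slim practice; no ontology propagation). The
Mann–Whitney clade comparison uses the exact null for groups of ≤ 20 and
the tie-corrected normal approximation otherwise. Kruskal–Wallis across
categories uses the chi-squared approximation with k−1 df; an all-constant
input returns H = 0 rather than an error.

The ranked segmentation test performs a two-sided Fisher exact test at 30
(by default) equally spaced rank-quantile thresholds of the ω-ranked gene
list, per category. Multiplicity is handled by Benjamini–Hochberg FDR
applied **jointly over all (category × partition) tests**, with each
category reporting its best partition and the adjusted p: taking the
per-category minimum raw p without accounting for the 30 dependent
partition tests is measurably anti-conservative (≈29% of fully null
replicates produced a spurious q < 0.05; the joint adjustment brings that
to ≈1%, within the ≤ 5% a calibrated procedure allows). The logistic
trend test models membership probability as a logistic function of rank
percentile with a Wald test on the slope; complete separation falls back
to a lightly penalised fit (four half-weight pseudo-observations at the
percentile extremes), flagged in the result. Genes with zero
non-synonymous substitutions are removed from the ranking before either
test, as ranking them by ω is meaningless.

## Numerical and design notes

- Coordinates are 0-based half-open internally and 1-based inclusive in
  written reports.
- ORF search is forward-strand by default (inputs are oriented cDNA);
  reverse frames behind a flag. Open-ended ORFs are enumerated only for
  the fragment (reference-frame) strategy.
- Alignment scoring: BLOSUM62, gap open 11, extend 1, free end gaps (so a
  truncated fragment pays nothing for hanging ends). Of co-optimal
  alignments the aligner's first deterministic traceback is used.
- The column filter recomputes its mask from the aligned strings on every
  call, so it is idempotent by construction; "short run" means a gap-free
  island of ≤ 3 codon columns (configurable), the reading adopted for the
  ~7 bp unreliable-fragment rule.
- Built-in search e-values use ungapped BLOSUM62 Karlin–Altschul constants
  (λ = 0.318, K = 0.134) and are approximate; ingested BLAST tabular files
  are authoritative when provided. RBH ties (equal e-value and bitscore)
  disqualify the gene — conservative strict 1:1.
- Problem sizes in the shipped checks: 200 pairs × 500 codons for
  parameter recovery; 300 + 300 genes for the scaled-down two-clade study;
  500 replicates each for bootstrap-coverage and enrichment-calibration
  simulations.

## Known limitations

- The ML optimiser profiles a 3-parameter surface per gene; for saturated
  pairs (dS ≳ 4) t̂ can run to its bound and dS is then only a "very
  large" indicator — exactly the regime the saturation filters remove.
- NG86's stop-site convention biases ω̂ down by a few percent (see above).
- Karlin–Altschul e-values for the built-in gapped search use ungapped
  constants, so they are conservative rankings rather than calibrated
  significance statements.
- The logistic fallback p under separation is approximate and marked as
  such in the output.
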