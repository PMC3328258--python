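# codonrates

Pairwise codon-model molecular evolution for two-clade comparative studies
of protein-coding genes — built for the kind of question a conifer
genomicist asks: *how much slower do spruce–pine orthologues evolve than
Arabidopsis–poplar orthologues, and is the difference uniform across
functional categories?*

The package covers the full path from raw cDNA-like sequences to absolute
substitution rates:

1. **ORF discovery** — enumerate start-to-stop ORFs; select per transcript
   either by homology rank (full-length cDNA strategy, longest-ORF
   fallback) or by reading-frame agreement with a reference hit
   (EST-fragment strategy, open-ended ORFs allowed).
2. **Orthology** — 1:1 pairs by reciprocal best hit (RBH), from ingested
   BLAST tabular files or the built-in exact Smith–Waterman search
   (BLOSUM62, Karlin–Altschul e-values, default threshold e ≤ 10⁻²⁰).
3. **Codon alignment** — protein-guided global alignment back-mapped to
   codons; gap columns and short unreliable gap-free islands removed;
   alignments under 30 codons discarded.
4. **Distances** — for each pair, dN, dS and ω = dN/dS under the
   Goldman–Yang codon model by maximum likelihood (F3x4 codon frequencies,
   κ estimated from the data), an independent Nei–Gojobori counting
   estimate, and the distance d4 restricted to 4-fold degenerate third
   positions (Kimura two-parameter correction).
5. **Rates** — saturation filters, absolute rates **μ = d / 2T** from
   fossil divergence times (with time ranges and gene-level percentile
   bootstrap CIs), optional asymmetric apportionment between lineages
   (ratio ρ, e.g. a slow tree lineage at one sixth of a fast annual), clade
   summaries and fold-change tables.
6. **Functional categories** — best-hit GO-slim transfer, per-category
   Mann–Whitney clade comparison, Kruskal–Wallis heterogeneity, and
   threshold-free ranked gene-set tests (Fisher-exact segmentation over
   partitions of the ω-ranked list, plus a logistic trend test) with
   Benjamini–Hochberg FDR control.

A synthetic-data generator (`codonrates.simulate`) produces every input
the pipeline consumes — codon pairs evolved under the model with known
(t, κ, ω), cDNA wrappers with UTRs and truncation, decoy paralogues,
planted functional categories — so the whole pipeline is testable with no
downloads.

## Model

Sequences evolve on a reversible 61-state codon rate matrix
(standard nuclear code, stop codons excluded): for codons *i → j* differing
at one nucleotide,

    q_ij = pi_j · kappa^[transition] · omega^[non-synonymous]

scaled so one unit of branch length t is one expected substitution per
codon. For a pair, the likelihood L(t, κ, ω) = Σ_sites log(π_i P_ij(t)) is
maximised (L-BFGS-B on log parameters, three starts, eigendecomposition of
the symmetrised matrix cached per (κ, ω)); dS and dN follow from the
synonymous fraction of the stationary substitution flow at the MLE,
normalised by the same fraction at ω = 1 (the mutational-opportunity site
definition). Absolute rates use μ = d / 2T for a fossil-calibrated
divergence time T; an asymmetric split apportions d/T as 1 : ρ between the
two lineages.

## Worked example

```python
from codonrates import simulate, alignment, distances, rates

# an orthologous pair with known truth: 500 codons, t=0.5, kappa=2, omega=0.3
a, b, truth = simulate.simulate_codon_pair(
    simulate.SimRegime(n_codons=500, t_codon=0.5, kappa=2.0, omega=0.3, seed=1))

aln = alignment.filter_columns(alignment.align_codons(a, b, "demo"))
est = distances.gy94_ml_estimate(aln)
print(f"t={est.t:.3f} kappa={est.kappa:.2f} omega={est.omega:.3f} "
      f"dN={est.dN:.4f} dS={est.dS:.4f}")
# t=0.488 kappa=1.75 omega=0.343 dN=0.1066 dS=0.3107

mu = rates.substitution_rate(0.1908, rates.CONIFER_SCENARIO)
print(f"mu_S = {mu.mu * 1e9:.2f}e-9 per site per year "
      f"(range {mu.mu_low * 1e9:.2f}-{mu.mu_high * 1e9:.2f})")
# mu_S = 0.68e-9 per site per year (range 0.60-0.79)
```

The first block simulates a pair under the codon model and re-estimates the
generating parameters by maximum likelihood (the estimates scatter around
the truth; averaged over 200 replicate pairs the mean ω̂ is within 0.01 of
0.3). The second applies the rate formula to a slow clade with mean
dS = 0.1908 and a 140 (120–160) million-year divergence: 0.68 × 10⁻⁹
synonymous substitutions per site per year, with the divergence-time range
bracketing the rate between 0.60 and ~0.80 × 10⁻⁹.

An end-to-end run on a synthetic two-clade study:

```
codonrates run-all --outdir out/ --seed 1
```

writes per-gene estimate tables, discard ledgers, a rate table with
bootstrap CIs, a fold-change table and a run manifest under `out/`.

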