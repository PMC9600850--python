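# Methods

This note documents the statistical machinery, the synthetic-data generator,
and the numerical and design choices behind `cubgrowth`.

## Codon usage statistics

**Genetic code.** All family bookkeeping uses NCBI translation table 11 (the
bacterial/archaeal code), selectable by table number. Stop codons are never
counted into families; Met and Trp (degeneracy 1) carry no synonymous-choice
information and are excluded from MILC sums. Codons containing non-ACGT
symbols are skipped and counted; a gene whose skipped fraction exceeds 10%
is dropped with a warning, so degraded assemblies cannot silently bias the
community statistics.

**Trimming policy.** Metagenomic gene calls are often partial, so sequences
whose length is not a multiple of three lose their trailing bases (with a
warning), and a terminal stop codon, when present, is removed.

**MILC.** For a gene with observed family counts o_{a,c}, within-gene
frequencies f and background expectation g,

    M_a = 2 Σ_c o_{a,c} ln(f_{a,c}/g_{a,c}),
    MILC = (Σ_a M_a)/L − C,  C = (Σ_a (r_a − 1))/L − 1/2,

with sums over families represented in the gene and L the codons counted in
those families. Terms with o_{a,c} = 0 contribute zero. A gene containing
only single-codon families has no informative codons and raises an error.
When a background frequency is zero at a codon the gene uses (possible for
small backgrounds), one pseudocount is added to every codon of that family
in the background counts before renormalizing, with a warning; this keeps
MILC finite without perturbing well-covered families. The production code
path is vectorized; a family-by-family fallback handles the pseudocount
case, and the test suite requires agreement with an independently written
brute-force implementation to 1e−9 on random inputs.

**Per-gene null backgrounds (iCUB).** The null for a gene is built by
pooling codon counts over 100 (configurable) uniform permutations of the
gene's own nucleotide sequence. Whole-sequence permutation controls for
global nucleotide composition; it deliberately does not preserve per-position
(e.g. GC3) composition, which is the minimal reading of a
composition-controlled null. At many shuffles the pooled frequencies
converge to the analytic i.i.d. composition distribution over in-frame
triplets, which the tests verify. All shuffling is driven by a seeded
generator; identical seeds give bitwise-identical results.

**Ψ (consistency).** Mean MILC of the HE genes against the pooled HE-gene
background. Identical HE genes give Ψ = −C (about 0.3–0.5 for realistic
lengths); fully disjoint codon choices in a two-codon family approach
2 ln 2 + 1/2 ≈ 1.886. Larger Ψ means more dissimilar ribosomal-protein codon
usage, i.e. a mixture of organisms with different preferences.

**Aggregation conventions.** CUB̄_HE is a weighted median (smallest value
whose cumulative normalized weight reaches 1/2; a value landing exactly on
1/2 averages the straddling pair, so equal weights reduce to the plain
median). iCUB̄ quantities are (weighted) arithmetic means; "average CUB" is
read as the mean. The iCUB̄_All background genes are sampled uniformly
without replacement from the non-HE genes (all genes if fewer than 100);
abundance weights enter through the weighted median/means and the weighted
GC, not through the sample itself. The sample-wide MILC background pools
unweighted codon counts of all retained genes.

## Growth models

Doubling times are modeled on the Box-Cox scale. λ is chosen by profile
likelihood on a grid from −2 to 2 in steps of 0.01; the profile is that of
the linear model (response transformed, predictors fixed), matching standard
Box-Cox regression practice — an intercept-only profile cannot recover λ
when the predictors explain most of the response variance. The transformed
response is then fitted by ordinary least squares on the mode's predictors:

- mmv1: `cub_he` (+ `ogt`),
- mmbc: `normalized_cub` = (iCUB̄_All − iCUB̄_HE)/iCUB̄_All and
  `gc_deviation` = |0.5 − GC| (+ `ogt`), entered as two separate regression
  terms with their own coefficients.

The mmv2 predictor dispatches exactly one branch on Ψ (< 0.6 → mmv1,
otherwise mmbc) and never blends. Predictions whose linear predictor leaves
the inverse-transform domain are clamped — to 100 h where the violated side
corresponds to a diverging doubling time, to 1e−3 h where it corresponds to
zero — and carry an explicit warning; these occur only under extreme
extrapolation.

Cross-validation supports seeded random k-fold (k = 10 by default) and
phylum-blocked folds (one fold per phylum label), reporting per-fold MSE on
the Box-Cox fitting scale (hours optionally). Test folds with fewer than two
points are skipped with a warning.

**Shipped coefficients.** The package data contains model sets fitted on the
synthetic generator below (300 genomes, 6 preference clusters, GC uniform on
0.30–0.70, lognormal doubling times with meanlog ln 3 and sdlog 1, clipped
to 0.25–45 h; a variant with planted optimal growth temperatures backs the
temperature models). They are labeled SYNTHETIC in their metadata and exist
to demonstrate and test the machinery; they carry no information about real
organisms and should be replaced by models trained on a measured trait
compilation for any scientific application.

## The synthetic-data generator

The generator emulates the ingredients that community-level codon-usage
predictors are sensitive to; it does not attempt sequence realism beyond
them.

- **Genomes** are sets of coding sequences (default 80 genes of 300 codons,
  ATG-initiated) drawn codon-by-codon: family ~ degeneracy-proportional
  probabilities, codon within family ~ a preference vector.
- **Preferences** have a geometric rank profile (decay 0.25: the preferred
  codon takes ~75% of a four-fold family). Rankings are drawn per "phylum"
  cluster; genomes jitter them mildly (log-normal, sd 0.1). Cluster rankings
  can be blended toward a shared consensus (`cluster_divergence`), which sets
  the Ψ of cross-cluster mixtures: fully independent rankings give Ψ ≈ 2,
  while divergence 0.4 gives Ψ ≈ 0.9–1.3, the range seen in real metagenome
  panels; single-cluster pools with similar GC give Ψ ≈ 0.5.
- **GC content** is controlled by a genome-wide exponential tilt
  exp(β·GC(codon)) solved by bisection so the expected GC hits the target
  (infeasible targets raise an error; realized GC lands within ±0.05).
  Because the tilt acts on synonymous choice, skewed-GC genomes have
  composition-constrained codon usage — reproducing both the Ψ–GC coupling
  (skewed mixtures look codon-consistent) and the GC bias of whole-sample
  background estimators.
- **HE genes** (12.5% of genes, flagged, "ribosomal protein" headers) draw
  from the genome's *realized* codon distribution sharpened by an exponent
  1 + s: translationally optimal codons are the codons the genome itself
  prefers, composition effects included. s = 0 makes HE genes statistically
  identical to the background (verified by a null test); s is planted as
  3/√d, so fast growers get strongly optimized ribosomal proteins.
- **Mixtures** concatenate the genes of 10 distinct genomes (provenance
  retained); relative abundances are lognormal (meanlog 0, sdlog 1)
  normalized to sum to one and assigned to every gene of a genome.
  Temperatures, when simulated, take a sample temperature ~ U(0, 60) °C and
  per-genome optima offset by N(0, 10).
- **Subsampling** draws genes without replacement with inclusion probability
  proportional to abundance weight, reporting the number of unique HE genes
  retained.

**What the generator does not emulate** — sequencing error, assembly
artifacts, gene-calling errors, amino-acid composition differences between
proteins, operon structure, strain-level variation, and real phylogenetic
covariance between traits and codon usage. Passing benchmarks on these
synthetic communities therefore demonstrates the estimator's internal
consistency and bias corrections under controlled violations of its
assumptions, not field performance on real metagenomes.

## Benchmarks

The convergence benchmark asks how well a predictor "converges to itself":
for each mixture, the community prediction is compared with the
abundance-weighted aggregate of per-genome predictions under the same model,
by default the weighted mean on the log10-hours scale (weighted median
available), and errors are squared on that scale. Summaries stratify MSE by
the Ψ switch threshold and by pooled-GC bins. Mixtures that fail prediction
are excluded with a warning and counted. Fixed seeds reproduce results
exactly; per-genome features are computed once and reusable across model
modes.

On these benchmarks, the whole-sample-background model underestimates
community doubling times on preference-divergent mixtures (the pooled
background dilutes every genome's preferences, inflating the apparent HE
bias), the bias-corrected model removes the GC dependence, and the switching
predictor matches the better branch on both sides of Ψ = 0.6. Abundance
weighting reliably improves predictions when abundances are strongly skewed;
at moderate abundance skew its per-mixture benefit is small relative to the
structural error of the community-level median statistic, and on 200-mixture
panels it is not consistently resolvable — the weighting machinery itself is
validated directly by its dominance-limit behavior and by the exact
equal-weights invariance.

## Numerical details and limitations

- All randomness flows through `numpy.random.Generator`; every public
  operation takes a seed or generator, and identical inputs with identical
  seeds give bitwise-identical outputs.
- Benchmark problem sizes in the test suite (30-genome pools, 100–200
  mixtures, 10-genome mixtures, 100 shuffles, 100 background genes) are the
  package's chosen study conditions for desk-scale validation; the
  statistical comparisons are paired nonparametric tests at these sizes.
- Fewer than 10 designated ribosomal proteins triggers a warning (the
  estimate rests on an unstable median); zero is an error.
- The λ grid bounds (−2, 2) cover all observed fits with margin; a fit at a
  grid boundary would indicate a degenerate response.
- Doubling-time clamps (1e−3, 100 h) mark out-of-domain extrapolation; both
  bounds are configurable constants and clamped predictions always carry a
  warning.
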