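# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the limitations of `digitexpr`.

## Normalization

Counts are converted to transcripts per million with per-gene median
transcript lengths: TPM_g = 10⁶·(c_g/L_g)/Σ_j(c_j/L_j). The denominator runs
over a configurable gene universe — the full matrix by default, a gene-list
subset when explicitly requested — and the choice is recorded in the
`ExpressionMatrix.universe` field, because analyses restricted to a gene
list can legitimately be normalized either way and the two are not
interchangeable. A sample with zero total counts yields all-zero TPM with a
warning rather than an error.

For clustering and PCA, TPM is square-root transformed (variance
stabilization for roughly Poisson-scaled abundances) and, when samples from
several stages or limbs enter one analysis, mean-centered per gene within
declared *bulks* (all samples of one stage, or of one limb). Centering makes
within-bulk per-gene means exactly zero, so sample–sample Pearson
correlations range over [−1, 1]; it is idempotent, and a singleton bulk
centers to zeros (logged). Transform states advance monotonically
(`tpm → sqrt_tpm → centered_sqrt_tpm`) and every consumer checks the state
of its input.

## Differential expression

The per-gene model is a negative-binomial GLM with log link:
y_gs ~ NB(μ_gs, φ_g), Var = μ + φμ², log μ_gs = x_sᵀβ_g + o_s. Offsets o_s
are log effective library sizes: total counts by default, or total counts
times a trimmed-mean-of-log-ratios factor (30% trim per tail against the
median-library sample, factors normalized to geometric mean 1). The
trimmed-mean option matters when differential signal is concentrated in one
group — a planted one-digit module shifts that digit's library composition,
and plain total-count offsets leak that shift into every null gene (visible
as inflated single-species false discoveries in `examples/02`; the
cross-species intersection is robust to it either way).

Fitting is Fisher-scoring IRLS run *batched* across genes (one shared
design matrix, per-gene weights, stacked p×p solves), with step halving
whenever a step would decrease the likelihood, convergence at score
sup-norm < 10⁻⁸ or 100 iterations, and linear predictors clipped to ±30 for
overflow safety. Genes whose fits do not converge are reported with p = 1
and flagged; genes with all-zero counts in the tested samples are reported
with p = NA and excluded from the number of tests in FDR control.

Dispersions come from the Cox–Reid adjusted profile likelihood
APL_g(φ) = ℓ_g(β̂(φ); φ) − ½ log det(XᵀWX), evaluated on a 21-point log-φ
grid spanning [10⁻⁶, 5]. The common dispersion maximizes Σ_g APL_g; the
tagwise φ_g maximizes APL_g + (w/df_resid)·APL̄, where APL̄ is the per-gene
average curve and w = 10 "equivalent observations" — a deliberately simple
fixed-prior-weight shrinkage (not the original empirical-Bayes machinery of
count-model packages), whose pull toward the common value strengthens as a
gene's residual degrees of freedom shrink. Grid argmaxes are refined by a
parabolic step in log φ; a gene with identical counts in every sample lands
on the 10⁻⁶ floor. Calibration is validated by simulation (null type-I rate
and p-value uniformity), not by numeric equality with any existing package.

Contrasts are likelihood-ratio tests against χ²: a digit pair (1 df, fitted
on the two digits' samples) or the whole digit factor (#digits − 1 df). An
additive stage factor enters both full and reduced models when a limb was
sampled at two stages, as does any continuous covariate — in particular the
first principal component of the full-matrix sqrt-TPM (gene-centered,
unscaled, standardized before entering the design), used to absorb a
non-biological sample split. Reported log2 fold changes are the digit
coefficient divided by ln 2, oriented second-digit-over-first.

Multiple testing: Benjamini–Hochberg step-up (own implementation,
oracle-checked), and Storey q-values q_g = π̂₀·BH_g with π̂₀ from the λ-grid
(0.05…0.95) smoother — here a cubic polynomial fit of π₀(λ) evaluated at
the largest λ, clipped to (0, 1]. With fewer than 100 p-values π₀ falls
back to 1 with a warning. Since q = π₀·BH with π₀ ≤ 1, Storey never calls
fewer genes than BH at the same threshold.

## Clustering and PCA

The sample dissimilarity is 1 − Pearson r between expression profiles over
the chosen gene universe. Agglomeration is average linkage (UPGMA,
size-weighted Lance–Williams update), hand-implemented so that exact ties
break deterministically on the lexicographically smallest member sets;
heights are non-decreasing to the root and permutation-invariant (checked
against scipy's average linkage on tie-free instances). Node support is the
bootstrap proportion BP: genes resampled with replacement `n_boot` times
(default 1000), trees rebuilt, and BP(node) = % of replicates containing
the node's exact leaf set. A multiscale approximately-unbiased (AU) value
is available as an option: bootstrap at ten resample scales in [0.5, 1.4],
fit z(r) = v√r + c/√r to the probit-transformed proportions, AU =
1 − Φ(v − c).

PCA is gene-centered and unscaled (scaling is an off-by-default option),
computed by SVD, with component signs fixed by making each loading vector's
largest-magnitude entry positive so bootstrap alignment and fixtures are
stable. Held-out samples are projected as supplementary observations,
score = (x − gene means)·loadings, after being bulk-centered *with their
own bulk's means* — the same rule as the training data. Digit
correspondence is a deterministic surrogate for reading regions off a PCA
plot: per-digit centroids of the training scores in the leading plane
(first two components by default; configurable), nearest-centroid
assignment by Euclidean distance, margin to the runner-up reported, exact
ties to the lower digit number.

A caveat the projection workflow makes explicit: when species have
different digit complements (4 vs 5 digits), per-species bulk centering
subtracts different per-gene means, so any expression program that is
monotone along the digit series acquires a systematic offset in the
projected species. The synthetic gradient module is therefore centered and
mixed-direction (below), and real cross-species projections should be read
with this artifact in mind.

## Conservation statistics

Per-species DE sets at a boundary are restricted to the one-to-one ortholog
universe (N groups); the conserved set is their intersection, with a
direction-consistent subset reported when fold-change signs are available.
The chance model is the one a binomial test assumes: each of the N groups
lies in set i independently with probability kᵢ/N, so a fixed gene survives
all intersections with p = Π kᵢ/N, the expected overlap is N·p, and the
overlap tail is the exact sum P(Bin(N, p) ≥ X). A vectorized Monte-Carlo
null with independent memberships cross-checks the exact summation; a
second Monte-Carlo mode draws fixed-size sets instead, under which
memberships are negatively correlated and the binomial tail is
conservative — noticeably so at small N. Both modes are exposed; the
binomial summation is the reported statistic.

Fold changes are log2((TPM_posterior + ε)/(TPM_anterior + ε)) with ε = 1
(configurable): antisymmetric under digit swap and bounded at zero
expression. The matched-random-gene procedure follows the origin species'
DE genes into each other species twice — once through their orthologs, once
through random genes matched on anterior-digit TPM (own ortholog excluded;
ties to the lexicographically smallest ID; matching independent per gene,
so repeats are allowed) — and compares the two collections of Pearson
correlations with a Welch t-test and a Mann–Whitney U test. Degenerate
fold-change vectors (zero variance, or fewer than 3 genes) yield NA for
that comparison.

## The synthetic-data generator

The generator emulates the sampling design of a multi-species digit study:
per species, 4–5 digits × 2–4 replicates (optionally two stages), NB counts
via a gamma-Poisson mixture with mean μ_gs = library_size_s ×
relative_expression and Var = μ + φμ² (φ ≤ 10⁻¹² falls back to Poisson,
recovering the Poisson limit exactly).

Default study conditions, chosen once as a realistic desk-scale analogue:

| quantity | default | rationale |
|---|---|---|
| genes per species | 1250–2000 | enough for stable FDR/π₀ estimation |
| one-to-one ortholog fraction | 0.8 | TF-centred universes are mostly 1:1 |
| baseline relative expression | log-normal, sdlog 1.2 | wide dynamic range without an extreme zero-heavy tail |
| library size | log-normal, mean 10⁶, CV 0.2 | desk-scale stand-in for deep bulk libraries |
| dispersion regimes | φ log-normal around 0.02 ("sibling") / 0.15 ("population"), sdlog 0.5 | inbred-litter vs wild-caught replicate variability |
| cross-species baseline noise | log-normal, sd 0.25 | ortholog matching informative but imperfect |
| transcript lengths | log-uniform 500–5000 bp | nuisance for TPM only |
| conserved D1 module | 30 genes, log2 effect 2 | a strong digit-identity program |
| stage wobble | log-normal, sd 0.15 per gene-stage | makes bulk centering non-trivial |

Digit-identity structure is planted as modules attached to *identities*,
and each species maps digit positions to identities (default: identity =
position). The frame-shift species is a 4-digit limb mapping position 2 to
identity 1 (positions 3, 4 to their own identities; position 1 to none) —
the recoverable analogue of a wing whose anterior digit runs the D1
program. The frame-shift scenario adds an anteroposterior gradient module
(60 genes, max |log2 effect| 2.5, levels centered on the middle digit,
half the genes increasing posteriorly and half anteriorly) plus smaller
D3/D4 modules (12 genes at 1.0). The gradient is centered and
mixed-direction deliberately: a one-directional gradient is confounded,
under per-species bulk centering, with the digit-composition difference
between a 4- and a 5-digit species (the artifact described above), which
would misplace projected digits for reasons unrelated to their identity.

A homogeneous-species flag silences all planted effects (the null for DE
calibration and clustering support). The generator returns per-species
count matrices (species have distinct gene universes), a combined
transcript-length table, the ortholog map, planted gene lists, and a
ground-truth object (module membership, per-digit true means, true φ,
library sizes) from which recovery is scored as sensitivity and false
discovery proportion. Identical seeds reproduce every output exactly.

What the generator does *not* emulate: read-level noise and mapping
artifacts, genuinely correlated gene modules beyond the planted ones,
phylogenetic covariance of expression evolution, annotation errors in the
ortholog map, and batch structure richer than the single PC1-style split.
Passing tests therefore demonstrate that the pipeline's statistics are
calibrated and its recovery logic correct under the stated model — not that
any particular biological dataset satisfies that model.

## Problem sizes and determinism

The test-suite and acceptance scenarios use 300–2000 genes, 2–5 digits × 3
replicates, 2–3 species, 1000 bootstrap replicates, 10⁵ Monte-Carlo draws,
and 3–100 simulation seeds per check — sizes chosen so a full run completes
in minutes on one CPU while keeping Monte-Carlo error well inside the
asserted margins. All randomness flows through `numpy.random.default_rng`
seeds recorded in configs and derived deterministically in scripts; reruns
with the same seed are bit-identical.

## Known limitations

- The tagwise dispersion shrinkage uses a fixed prior weight, not estimated
  prior degrees of freedom; very heterogeneous dispersion landscapes will
  be over- or under-shrunk relative to an adaptive scheme.
- χ² reference distributions for the LRT are asymptotic; at 3 + 3
  replicates the null is close to nominal (validated by simulation) but not
  exact.
- The binomial overlap model ignores the negative correlation induced by
  fixed DE-set sizes and any correlation between species' DE calls; its
  tail is a chance benchmark, not a calibrated p-value under all designs.
- Correspondence calls use the leading plane only; identity axes falling
  outside the first two components are invisible to the call (the plane
  dimensionality is configurable).
- TPM's compositional nature means strong asymmetric signal biases
  total-count offsets; the trimmed-mean option mitigates but does not
  remove this.
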