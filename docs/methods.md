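# Methods

## Latent representation

Each circuitry side is condensed into 18 named coordinates in a fixed,
serialized order: correlation (ρ and transformed adjusted P),
tumor-vs-normal (signed direction, −log10 Wilcoxon P), four survival
endpoints × (signed Cox direction, transformed P, raw log-rank χ²),
microenvironment score, immune polarity code. Design choices:

- **P-value transform.** The Wilcoxon axis is −log10 by definition of
  the representation; we apply −log10 uniformly to the adjusted
  correlation P and the survival P values as well (config
  `pvalue_transform`), capped at 300 to keep underflowing P values
  finite. Uniformity gives every "strength" axis the same semantics and
  bounded range; the raw-probability alternative is one config switch.
- **Immune 4→3 mapping.** Four classes must land on {−1, 0, +1}. Hot
  and cold are the polar states, so hot = +1, cold = −1, and both
  excluded and intermediate map to 0. The map is a config field
  (`immune_code_map`) because the neutral assignment of "excluded" is a
  genuine judgement call.
- **Survival zeroing.** A non-significant endpoint contributes exactly
  (0, 0, 0): direction, strength and χ² are all suppressed so
  non-informative axes cannot deform the geometry. Significance is an
  explicit boolean in the schema; absent cells are an error, never an
  implicit zero.
- χ² enters untransformed (it is already a nonnegative test statistic).

## Embedding

The pooled 2N×18 tensor is globally centered and scaled column-wise.
The SD uses the sample convention (ddof = 1, configurable); zero
variance is detected by exact range (all entries identical) because
floating-point summation leaves ~1e−15 SD noise on constant columns,
and such columns are kept at scale 1 and forced to exact zeros —
retained but contributing nothing. PCA is a full-matrices SVD of the
standardized tensor, so all 18 principal axes exist even for tiny
tables (2N < 18) and full-dimensional scores are an exact isometry of
the standardized space. Signs are pinned by making each loading
column's largest-magnitude entry positive; distances are unaffected,
but barycenter coordinates become bit-reproducible. PC1–PC3 is the
shared coordinate system for distances and visualization; a
centering-only variant (`scale=False`) supports the no-scaling
robustness check.

## Polytopes and descriptors

A latent vector x expands into 36 vertices x ± δ_i·e_i with
δ_i = max(α|x_i|, ε). α rescales volumes monotonically and cancels out
of barycenter distances, so its value does not reorder regimes; default
α = 1. ε > 0 guarantees a full-dimensional polytope even at x = 0;
default 0.05, small against the unit-variance latent scale. The vertex
mean equals x by symmetry, and because projection is affine the
projected barycenter equals the projected latent point — the
permutation and ablation paths exploit this to skip hull construction.

Hull volumes are computed by default on the 36 projected points in 3-D
(Qhull). An alternative mode (`volume_space="latent18"`) uses the exact
closed form for the axis-aligned cross-polytope, 2^d/d!·∏δ_i, in the
full 18-dimensional latent space; both are exposed because the two
spaces answer slightly different questions (projected visible geometry
vs intrinsic latent breadth) and the published operating point is
ambiguous between them. Degenerate hulls (projected rank < 3, e.g. an
all-neutral side) record volume 0 with a flag and are excluded from
quantile fitting rather than failing the run.

Anisotropy is the square root of the extreme-eigenvalue ratio of the
vertex-cloud covariance (1 = isotropic). The asymmetry ratio is
vol_sig/vol_int with the symmetrized form max(r, 1/r) used for
classification.

## Classification

Distance regimes use fixed thresholds 0.5 / 1.5 / 2.5 with half-open
bins (boundary values go up). Volume tiers use type-7 (linear
interpolation) empirical quantiles at probabilities 1/3 and 2/3 over
the pooled finite positive volumes of both sides; the tier scalar is
the geometric mean of the two side volumes (symmetric and
scale-covariant; max and mean are config options). Symmetry bands
default to s1 = 1.5, s2 = 3.0 on the symmetrized ratio — these are not
published constants, so they are config fields echoed into the output
metadata. The four joint phenotypes collapse regime × tier: concordant
iff high-concordance regime; High → high-dimensional, Low →
low-dimensional, Intermediate → high-dimensional only when asymmetric.
The concordance summary compares signs on comparable axes (ρ sign,
tumor-normal, endpoints significant on both sides, microenvironment
sign, immune polarity), excluding axes neutral on either side; all
agree → Only Convergent, all disagree → Only Divergent, otherwise
Mixed, and no comparable axis at all → Indeterminate.

## Statistics

Shannon entropy uses the natural log by default (the magnitudes
reported for four-class mixes, ≈1.0–1.3, sit naturally below
ln 4 ≈ 1.386); base-2 is a config option. Entropy orderings break ties
lexicographically.

Baseline benchmarks are computed on the standardized latent vectors so
the Euclidean baseline is comparable to full-PC-space distances.
Cosine distance with a zero vector is defined as 1 and flagged.
Survival mismatches count only endpoints with significant directions
on both sides. The Spearman matrix uses average ranks; constant
columns yield NaN entries, never silent zeros.

The permutation null reshuffles int-side latent vectors within
cancer-type strata (singleton strata stay fixed) and recomputes the
entire standardize + PCA + project + dbary + regime pipeline per
replicate. Three global statistics are tracked (mean dbary, extreme
proportion, high-concordance proportion), all upper-tailed, with the
bias-corrected estimator p = (k+1)/(B+1), so p is never 0 and its
minimum is 1/(B+1). Each replicate's RNG substream is derived from the
seed by counter, so increasing B extends rather than reshuffles the
null sample. Axis ablation removes a coordinate group (survival's 12
axes, or the immune axis), refits the embedding, and reports the rank
correlation of dbary against the reference plus the fraction of stable
regime labels.

## Synthetic atlas generator

The generator emulates the structure of a per-circuitry annotation
table, not any particular dataset's empirical distributions. Each side
draws three latent factors: a phenotypic orientation r = ±1 (shared
tendency of survival directions, tumor-normal direction,
microenvironment sign, and immune polarity — risky sides skew
up-regulated, pro-tumoral, cold), a significance potency (lognormal,
scales all strengths and χ²), and a survival-significance propensity
(Beta with mean `survival_significance_rate` = 0.5). These correlated
blocks give the pooled atlas dominant principal axes, which real
annotation atlases have and which an independent-coordinate simulation
lacks; without them the PC1–PC3 subspace is nearly degenerate and
distances in it are unstable.

The int side re-realizes the sig side per mixture component:
concordant pairs copy it with small jitter; discordant pairs flip a
component-specific number of polar axes (moderate 1, strong 2, extreme
all available) and diverge in magnitude. Because regime thresholds are
absolute in the embedded space, each discordant circuitry receives a
target separation drawn inside its component's band (moderate
0.75–1.30, strong 1.80–2.25, extreme 2.95–5.5), and a per-circuitry
scale factor on the continuous-axis displacement is solved by bisection
against the atlas's own embedding, respecting coordinate domains
(strengths ≥ 0, |ρ| ≤ 1); the embed-then-solve step iterates five times
because rescaling feeds back into column scales and principal axes.
Direction flips are discrete and unscalable, so flips whose fixed
displacement alone overshoots the target are pruned greedily (keeping
at least one). The default mixture (5.6 / 21.6 / 20.9 / 51.9%) matches
the published prevalence of the four regimes.

What the generator does not emulate: real atlases' pathway/superfamily
composition, inter-circuitry correlation (shared molecules across
circuitries), empirical marginal distributions of any specific dataset,
and the empirical property that observed pairings are *more* discordant
than stratified random re-pairings — in the synthetic atlas random
re-pairing of factor-structured sides is itself highly discordant, so
permutation enrichment runs in the opposite direction. Passing tests
therefore demonstrate correctness of the machinery and recoverability
of planted structure, not distributional fidelity to any real cohort.

## Numerical choices and degenerate inputs

- Vertex means equal the latent vector to machine precision (exact per
  coordinate pair, float rounding only from the mean reduction).
- Hull degeneracy is detected by matrix rank (tol 1e−10) before Qhull.
- The closed-form cross-polytope volume is computed in log space
  (lgamma) to stay finite at d = 18.
- Geometry tables serialize floats via `repr` for bit-exact
  write → read round trips.
- Boundary values of every classifier go to the upper bin, verbatim
  from the regime definitions.

## Problem sizes

The test suite and acceptance script use synthetic atlases of 40–2,000
circuitries, B = 99–200 permutation replicates, and 200 calibration
repeats; these sizes give stable estimates (binomial 99% bands for the
calibration check, ±5 pp for mixture recovery at n = 2,000) while
keeping a full run in minutes on one CPU.

## Known limitations

- The 3-D hull volume depends on the fitted embedding, so volume
  classes are atlas-relative (as are the data-driven tiers).
- α and ε are conventions, not estimates; only volume magnitudes (not
  regime order) depend on them.
- The concordance summary treats all comparable axes equally; no
  weighting by effect size.
- The generator's calibration targets separations in the final
  embedding only approximately (residual spread ~0.2–0.3), which is
  why component bands keep a margin inside their regime bins.
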