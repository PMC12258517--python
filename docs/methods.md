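# Methods

## Setting

Two perturbations of one regulatory cascade are profiled by RNA-seq and
summarized as DE tables: per gene, a log₂ fold change oriented wild-type
over knockout (positive ⇒ the factor upregulates the gene) and a
BH-adjusted *P*. The package's statistics all operate at this summary
level; read processing and DE model fitting are upstream concerns, consumed
as tables.

## Percentile-rank phase enrichment

Ranks use the Hazen definition rᵢ = (rankᵢ − ½)/N with average ranks for
ties, computed over **all** genes in the table with a finite log₂FC. Hazen
was chosen because the full-set median is then exactly 0.5 for distinct
values — the anchor the test compares against; the percent-rank variant
(rank − 1)/(N − 1) is available behind the `method` switch for parity with
codebases that use it, and shifts each rank by at most ½N⁻¹.

Each phase set's ranks are tested against 0.5 with a two-sided one-sample
Wilcoxon signed-rank test. Zero differences (rank exactly 0.5) are dropped,
the classical convention. The exact distribution is used for ≤ 25 nonzero
differences without tied magnitudes; otherwise the normal approximation
with tie-variance and continuity correction. The two agree within 0.01
for set sizes ≥ ~18; below that the approximation can deviate by up to
~0.017 near p ≈ 0.5, which is why the exact path covers small sets. The BH
family is the phases tested in one call (one panel/dataset); cross-dataset
pooling is deliberately not performed. Genes appearing in several phase
sets are tested in each independently. A phase with < 2 usable members is
reported with missing p rather than silently dropped.

## Regulated sets and overlap

Up-regulated: log₂FC > τ and *P*adj < α; down-regulated: log₂FC < −τ and
*P*adj < α, strict inequalities throughout (boundary values excluded);
defaults α = 0.05, τ = 0, with τ = 0.1 as the convention used for GO-input
style gene lists. Genes with missing *P*adj are never significant but stay
in rank statistics while their log₂FC exists.

Overlap significance is the upper-tail hypergeometric probability,
computed as `sf(k − 1)` of the scipy distribution — algebraically the
"P(X ≥ k)" formulation without its off-by-one trap. The universe is the
merged (inner-join) expressed set of the two datasets being compared; a
union universe would count genes that could never appear in both regulated
sets and so inflate enrichment. The universe policy is configurable. BH is
applied per analysis batch (the tests of one figure-panel-sized
comparison).

Gene-id matching is exact and case-sensitive everywhere: these analyses
merge symbol tables from a single annotation, and case-folding two species'
symbol conventions silently would create false joins. An explicit
normalization hook exists, off by default.

## Concordance and attenuation

For a dependent gene set S (default: *P*adj < α in the predictor dataset,
regardless of direction), Spearman ρ is computed over S and referenced
against an empirical null: N draws (default 100,000) of |S| genes sampled
without replacement within a draw — a gene set cannot contain a duplicate —
and with replacement across draws, from all merged genes (S is not
excluded from the pool). Z = (ρ − μ_null)/σ_null, and the one-sided
upper-tail normal probability is computed and reported on the natural-log
scale, never exponentiated, so |Z| > 8 does not underflow. If S equals the
universe every draw reproduces ρ and the null degenerates; this is raised
as an error rather than returning Z = ∞.

The attenuation slope is plain OLS of response log₂FC on predictor log₂FC
over S, CI from the t distribution with n − 2 df (at n in the thousands
this matches the normal CI; at the small n of synthetic checks the exact
form matters). OLS is the estimand on purpose: with noise in the predictor
the coefficient is the structural slope times the predictor's reliability
ratio, and an errors-in-variables correction would change the quantity
being reported, so none is offered.

Group-level "are these fold changes similar" comparisons use a two-sided
paired Wilcoxon signed-rank on the per-gene differences (the small-sample
exact path as above), with a paired t-test behind a switch. All-zero
differences return p = 1 with a flag.

Plot clipping of extreme points (displayed at 0.1 outside an axis limit)
is a display convention only and never touches statistics.

## Proliferation counts

Genotype × {EdU⁺, EdU⁻} tables get the Pearson chi-squared test of
homogeneity; Yates continuity correction for 2×2 tables only, matching the
R default so p-values line up with pipelines built on `chisq.test`.
Post-hoc: all unordered genotype pairs as 2×2 tests, BH across the pairs of
one table; a degenerate pair (zero margin) is flagged and excluded from the
family. Per-group proportion CIs use the Wilson score interval — finite
and inside [0, 1] even at observed 0% or 100%, where the Wald interval
collapses; Wald is available behind the `method` switch. The interval
method for the original error bars is not documented anywhere we could
follow, so Wilson is this package's documented choice.

## Synthetic-data generator

The generator emulates the DE-table summary level, not counts: no library
sizes, dispersion estimation or replicate structure. Defaults are the
study-like conditions used throughout the tests: n_genes 2000,
regulon_fraction 0.25, attenuation f 0.43, effect SD 1.0 (the empirical
effect-size spread of a real regulon is not known; 1.0 on the log₂ scale —
regulon genes typically change 2-fold — is the documented free choice),
noise SD 0.2, n_reps_per_group 1.

Structure: regulon genes carry effects β_g ~ N(0, effect_sd²); the
downstream table's log₂FC is β_g (+ noise), the upstream table's is
f·β_g + noise, non-regulon genes are noise in both. Adjusted *P* comes from
z = log₂FC/(noise_sd/√n_reps) through two-sided normal tails and the same
BH routine the analysis path uses (single source of truth). With the
default n_reps = 1 the null z is exactly standard normal given the table's
own noise; n_reps > 1 emulates replicate averaging upstream of the summary
and sharpens significance relative to the table's noise.

Noise placement: in the default `response_only` mode the regulon's
predictor (downstream) values carry no measurement noise — noise goes on
the upstream response everywhere and on downstream non-regulon genes (so
the table still looks like a DE table). OLS of upstream on downstream over
the regulon is then unbiased for f, which is what CI-coverage recovery
tests require. `both` mode adds noise everywhere and is the realistic
setting for null-calibration and power studies; there OLS estimates
f·reliability, attenuated below f, by design of OLS (see above).

Seeding: one integer seed fans out through
`numpy.random.SeedSequence(seed, spawn_key=(k,))` with fixed stream indices
(0 regulon/effects, 1 downstream noise, 2 upstream noise, 3 base-mean,
4 phase sets, 5 EdU counts). Adding a new stream takes the next index and
cannot perturb existing draws; identical parameters give byte-identical
tables.

What passing synthetic tests do **not** show about real data: real DE
tables have correlated effects within pathways, mean-dependent dispersion,
shared samples between contrasts, and annotation noise in gene symbols —
none of which the generator produces. Recovery results certify the
statistical machinery, not robustness to those features.

## Numerical and design notes

- BH is implemented once (vectorized step-up with NaN passthrough; missing
  entries do not count toward m) and shared by every caller.
- Exact signed-rank p-values cap at 1 after doubling; symmetric-rank inputs
  (a phase set equal to the universe) give p = 1 exactly.
- The bootstrap null is vectorized: per chunk of draws, a uniform matrix is
  argpartitioned to get each draw's k indices without replacement, subsets
  are average-ranked row-wise and correlated by the Pearson formula;
  chunking (10,000 draws) bounds memory at ~n_genes × chunk doubles.
- End-to-end reports serialize with sorted keys so identical config + seed
  ⇒ byte-identical JSON; the provenance block (config hash, seed, version,
  stage counts) suffices to re-run the analysis.
- Problem sizes in the shipped simulation suites (e.g. 200 reps per planted
  f, 2000-draw nulls inside the recovery loop, 10,000-draw nulls for Z
  calibration) are the package's chosen defaults balancing Monte-Carlo
  error against convenience; all are parameters, not constants.

## Known limitations

- No ortholog mapping: gene sets must already be in the DE tables' symbol
  space.
- The hypergeometric universe for published analyses of this kind is often
  unstated; results can move materially between merged-expressed and
  single-dataset universes. The merged choice is the default and the knob
  is exposed.
- The attenuation slope inherits every caveat of OLS on noisy predictors;
  comparisons of slopes between dataset pairs are only meaningful at
  comparable predictor noise.
- Single-cell phase assignment, GO enrichment computation and image
  quantification are out of scope; their outputs are consumed as gene sets
  or count tables.
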