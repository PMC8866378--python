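# Methods

This note documents the statistical models implemented in `qgpanel`, the
choices made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and the numerical details a
maintainer would need.

## Stage 1: genotype means from field records

Trait records from a multi-environment trial with unequal subsampling
follow

    Y_ijl = mu + G_i + E_j + GE_ij + eps_ijl,
    GE_ij ~ N(0, sigma2_ge),   eps_ijl ~ N(0, sigma2_eps),

with genotype `G_i` and environment `E_j` (each environment a location ×
replicate combination) fixed, and the genotype × environment interaction
random — the classical randomized-complete-block-with-subsampling model.
Because the covariance of the records is compound-symmetric within each
genotype × environment cell, the restricted likelihood collapses exactly
to (i) a pooled within-cell sum of squares carrying only `sigma2_eps` and
(ii) a weighted regression over cell means with weights
`n_c/(1 + n_c·lambda)`, `lambda = sigma2_ge/sigma2_eps`. Only `lambda`
is optimised numerically (bounded 1-D search on the log scale over
[−18, 12]); `sigma2_eps` is profiled in closed form. A `lambda` at the
lower bound is reported as `sigma2_ge = 0`.

Genotype means are estimated marginal means with environments weighted
equally (not by replication): sum-to-zero environment contrasts make the
genotype coefficient itself the mean on the response scale. Equal
weighting is an assumption — the alternative (weighting by replication)
collapses to the same answer only for balanced data. Traits are fit
independently. With a single environment `sigma2_ge` is not estimable
and the fit falls back to raw genotype means with a warning.

## Kinship

The prediction matrix is the VanRaden construction
`A = ZZ'/Σ 2 p_k q_k`, centring each marker by twice its *observed*
panel frequency; the denominator makes the mean diagonal `1 + f` with
`f` the within-individual gametic correlation. The association-scan
variant `K = ZZ'/m` omits the `2pq` scaling; any positive scalar on K is
absorbed by the variance components, which the tests verify by refitting
under `2K`.

The shrinkage flavour damps the sampling noise of A when markers are
few: off-diagonal entries are multiplied by `1 − lambda` (the diagonal
is untouched) with

    lambda = (estimated marker-sampling variance of the off-diagonals)
             / (their total squared magnitude),

clipped to [0, 1]. The sampling variance is estimated by recomputing A
on 10 round-robin marker subsets and taking the variance of the mean.
This is a Ledoit–Wolf-style plug-in; `lambda` decays roughly as 1/m, so
shrinkage vanishes as A stabilises. Shrinkage is used by default for
prediction only, never for the association scan.

## Association scan (Q+K, P3D)

The scan model is `y = Xb + s·tau + u + e` with `u ~ N(0, s2G·K)`, X an
intercept plus the first marker-PC score (one PC suffices for a panel
whose first component carries ~10% of marker variance and the rest ~1%;
the count is configurable), and `s` the marker coding — additive
(dosage) or dominance (heterozygosity indicator). Variance components
are estimated once by REML under the no-marker null using a single
eigendecomposition of K (the "population parameters previously
determined" shortcut), and the variance *ratio* `delta = s2e/s2G` is
then fixed for every marker test.

The per-marker test deliberately re-estimates the residual *scale* from
the marker-included generalized-least-squares fit: with weights
`1/(d_i + delta)` in the rotated basis, the statistic is an exact
t-test with `n − p − 1` degrees of freedom. Two consequences: (i) when
K = I the scan reduces *exactly* to the ordinary OLS t-test, giving a
sharp external oracle; (ii) the test does not understate uncertainty for
strong markers the way a fully fixed-variance Wald test would.
Constant markers receive LOD 0 and a flag rather than an error.

**Permutation thresholds.** The phenotype vector and its covariate rows
are permuted jointly against (G, K), breaking the phenotype–kinship
link; `delta` is re-estimated per permutation (cheap under the fixed
eigendecomposition — whether to re-estimate is an open choice, and
re-estimating is the conservative reading). The genome-wide maximum LOD
is recorded per permutation and the threshold is the empirical
`1 − alpha` quantile (defaults: 1000 permutations, alpha = 0.05,
controlling the family-wise error rate).

**Peaks and effect sizes.** Significant markers are grouped per
chromosome with a gap rule: two markers join one peak iff they are
within `merge_window_bp` (default 1 Mb — "peak" needs an explicit
definition for the chi-square degrees of freedom below to be
computable; the window is configurable). The representative is the
highest-LOD member. Backward elimination then fits the ML mixed model
with all representatives as fixed effects and iteratively removes the
peak whose deviance `d = 2(LL_f − LL_r)` is least defensible, judged by
the upper tail of chi-square with df = the peak's member count, until
all surviving peaks have p < 0.05. ML (not REML) likelihoods are used
because REML likelihoods are not comparable across different fixed
effects. Each surviving peak is annotated with
`partial R² = 1 − exp(−d/n)`. Reading the chi-square rule as an
upper-tail probability (rather than literally "the d-th quantile") is a
documented interpretation, not a claim about intent; df for a
single-member peak is 1.

## GBLUP, PEV and reliability

`y = 1·mu + g + e`, `g ~ N(0, s2g·A)` over all accessions, REML on the
phenotyped subset via the same spectral machinery. Breeding values for
all accessions (including unphenotyped ones) come from the conditional
multivariate normal `ĝ = s2g·A[:, obs]·P·y`, where
`P = V⁻¹ − V⁻¹1(1'V⁻¹1)⁻¹1'V⁻¹` absorbs the estimated mean. The
prediction-error variance

    PEV_i = s2g·A_ii − s2g²·aᵢ' P aᵢ

is algebraically the g-block diagonal of the inverse mixed-model-
equation coefficient matrix times `s2e`; the P-form avoids inverting A
(which may be numerically singular when markers are few). Reliability
is `1 − PEV_i/(s2g·A_ii)`, reported alongside raw PEV because the
higher-is-better quantity that tracks heritability across traits is the
reliability, not PEV itself. Degenerate input (all phenotypes equal)
returns zero GEBV deviations and zero reliability rather than failing.

Predictive ability is the Pearson correlation between masked
accessions' GEBVs and their held-out stage-1 genotype means (genotype
means, not raw plot records, are taken as the best available proxy for
"true" phenotypic value), averaged over replicates — defaults mask 10%
of the panel, 100 times.

## Design experiments

* **Marker density:** thin to each window of the default grid
  (0.1 kb, 1, 2, 5, 10, 100, 250, 500, 750 kb, 1–5 Mb), rebuild the
  kinship, re-run cross-validation. The same CV masks (same seed) are
  used at every density so comparisons are paired; ability is fit
  against *realized* marker counts, which is how the curve is
  interpreted. Windows leaving < 10 markers are skipped with a warning.
* **Relatedness:** k-means (k = 8, fixed seed) on the marker-PC scores;
  the cluster farthest from the grand centroid, trimmed or padded by
  distance rank to exactly the VP size (default 60), is the least-
  related VP. It is then diluted by replacing 1, 3, 5, 7, 10, 13, 15,
  17, 24, 27, 31, 35, 45 or 50 members with random accessions (50
  replicates per level by default). Relatedness is measured by a
  PC-space similarity index: for each VP member, the mean of
  `1/(d + epsilon)` over its `n_similar` (default 40) smallest
  Euclidean distances to TP members in the first 100 PCs, averaged over
  the VP; `epsilon = 1e-6` guards duplicated accessions. Averaging over
  VP members (each contributing one mean inverse distance) is the
  coherent reading of the procedure. Two prerequisites matter and are
  easy to violate: the panel must actually be structured (with weak
  structure the "most distant" VP is not meaningfully distant and the
  ability gradient is noise), and the diverged sub-population must not
  be larger than the VP — otherwise the undiluted VP leaves its own
  close relatives in the TP, inverting both the similarity baseline and
  the gradient.
* **Population size:** three modes — subsample the whole panel with a
  10% VP (`absolute`), hold the VP at 60 and vary the total
  (`fixed_vp`), or hold the total fixed and vary the VP size
  (`fixed_total`) — each grid point replicated (default 50 times), and
  ability fit against realized TP size.

All three are summarised by the asymptotic-exponential curve
`y = yf + (y0 − yf)·exp(−exp(log_alpha)·x)` — the same functional form,
rising or falling, used for LD decay. Starting values are self-derived
(asymptote from the far quartile of x, `y0` from the nearest point, rate
from a log-linearised fit), then refined by Levenberg–Marquardt; a
constant response short-circuits to `y0 = yf = mean` since the rate is
then unidentifiable. `distance_at_r2` inverts the fitted curve in
closed form and refuses levels outside `(yf, y0]`.

## Synthetic panels

`simulate_genotypes` uses a founder-mosaic model: each gamete copies
segments of a small founder-haplotype pool, switching to a random
founder between adjacent markers with probability
`1 − exp(−recomb_rate·gap)`. Only the r²-versus-distance shape matters
downstream, and the mosaic controls it directly (a coalescent simulator
would add realism the analyses never see). The finite founder pool sets
the near-pair r² level; the recombination rate sets the decay length.
Defaults (662 accessions, 9 chromosomes × 600 markers over 2 Mb, 4
founder haplotypes per pool, `recomb_rate = 1e-5`/bp) were calibrated
once against the intended panel structure: near-pair r² ≈ 0.13, r²
falling to 0.1 at ~20–25 kb, and — with 10% of accessions drawn from a
frequency-diverged (Balding–Nichols, F = 0.1) founder pool — a first
marker PC carrying ~11% of variance against ~0.5–1% for later PCs.
Markers violating the MAF floor after generation have their founder
alleles redrawn (the mosaic is kept) until the floor holds.

`simulate_phenotypes` builds the breeding value as planted QTL effects
(drawn `N(0, qtl_effect_sd²)` at random markers) plus a polygenic term:
small effects on a random 20% of the remaining markers, rescaled so the
polygenic variance equals `h²/(1 − h²)·(gxe_var + resid_var)` — i.e.
`polygenic_h2` is the heritability the background alone would produce
against the plot-level noise. This makes the GBLUP infinitesimal
assumption approximately true by construction. `h² = 1` requires zero
noise and uses unit variance. Records add a fixed environment effect
(drawn once from N(0, 1) and centred — environments are nuisance, and
centring makes the single-environment limit exactly noiseless), a per-
cell G×E draw, and residual subsample noise, with 1–15 subsamples per
cell across 4 environments by default. The trait defaults are set for
testability; no claim is made that they mimic a specific real trait.

What the generator does **not** emulate: missing or fractional
genotypes (the input contract is an imputed VCF; fractional dosages are
accepted on input but not generated), genotyping error, linked selection
or realistic site-frequency spectra, spatial field trends, and
environment-specific genetic correlations beyond a single iid G×E term.
Passing tests therefore demonstrate internal statistical correctness
and calibration under a clean generative model, not robustness to every
artefact of real field data.

## Numerical choices and edge cases

* One eigendecomposition of K per model; variance-ratio optimisation on
  a 40-point log grid over [−12, 12] followed by bounded Brent
  refinement. Zero-variance phenotypes are rejected explicitly.
* Kinship matrices are validated symmetric and PSD; eigenvalues below
  `−1e-8·λ_max` raise, tinier negatives are clipped to zero with a log
  note.
* Thinning windows are half-open, anchored at coordinate 0, positions
  1-based as in VCF; within a window the highest-MAF marker wins, ties
  to the smaller position. MAF exactly at the filter threshold is kept
  ("less than" is removed). If the VCF carries no depth, depth filters
  are skipped with a warning rather than failing.
* LD binning: 100-bp bins to 10 kb, then log-spaced bins to the
  neighbour horizon (bin widths are a free choice; these keep the
  short-range curve well resolved where it bends).
* Collinear peak representatives are dropped (later peak loses) with a
  warning; deviances are clipped at 0 against optimizer noise.
* Problem sizes in the test-suite and acceptance script (panels of
  100–662 accessions, 500–5400 markers, 200–1000 permutations, 10–100
  CV replicates) are the package's chosen desk-scale study conditions;
  the experiment schedules themselves (thinning grid, dilution levels,
  VP size 60, size ranges) follow the documented defaults.

## Known limitations

Single-trait models only; no dominance/epistatic kinship; no multi-
locus scan; the dominance option is an alternate marker coding of the
same scan engine, not a separate genetic model. The permutation
threshold assumes exchangeability of genotype-mean vectors under the
null, which weak residual structure can violate. The founder-mosaic
simulator cannot produce arbitrarily high near-pair r² without
collapsing founder diversity (near-pair r² ≈ 1/(K − 1) for K founder
haplotypes), so very strong short-range LD regimes are outside its
reach.
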