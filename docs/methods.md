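# Methods

This note documents the models, estimators, and design choices behind
`chassiskit`, in the spirit of a statistical methods appendix: what each stage
assumes, which knobs matter, and what the synthetic-data tests do and do not
demonstrate about real data.

## Study design being modeled

Six bacterial hosts carry an identical genetic inverter: arabinose (Ara, mM)
drives one state (sfGFP), anhydrotetracycline (aTc, nM) the other (mKate).
Per host the data are (i) induction assays — OD-normalized fluorescence vs
inducer concentration, 8 replicate wells; (ii) toggle and growth assays —
OD600 and fluorescence time courses under no induction (NI), Ara, and aTc;
(iii) RNA-seq in biological triplicates under Ara and aTc; and (iv) a
pangenome of orthologous gene clusters with COG annotations. Orthology
inference, read mapping, and annotation are upstream of this package; their
outputs (cluster matrix, count tables, annotation maps) are its inputs.

## Pangenome partitioning and enrichment

A cluster is *present* in a genome when it has ≥1 gene call there; paralog
multiplicity affects gene-call tallies but never binning. Core ⇔ present in
all genomes; unique ⇔ present in exactly one (a subset of accessory).
Percentages are reported to one decimal against the total cluster count.

COG enrichment tests one genome × frequency group × category at a time on a
2×2 table of gene calls (in-group vs rest × in-category vs rest), one-sided in
both directions via Fisher's exact test. The unit of analysis is the gene
call by default — each genome's annotation inventory — with a cluster-level
option (`unit="cluster"`), since published figures of this kind are readable
either way. Bonferroni correction is applied across the categories tested
within one genome × group family (the correction family the category tests
form); a category is "consistently" enriched when significant in ≥3 of 6
genomes. Hierarchical clustering of genomes (presence/absence) and hosts
(log2FC profiles) uses complete linkage on Euclidean distances via SciPy;
SciPy's deterministic merge ordering provides reproducible dendrograms.

## Kinetics

**Fss.** Steady-state fluorescence is the arithmetic mean over the 6–12 h
window (configurable); the same window is used for toggle steady states
unless overridden.

**Hill fits.** C is *fixed* to the mean Fss of zero-inducer wells, never
fitted — an empirical baseline. (β, K, n) minimize squared residuals of
replicate-mean Fss with bounded least squares (β ≥ 0, K > 0, 0.001 ≤ n ≤ 50),
multi-starting the Hill coefficient at {0.5, 1, 2, 4} with K initialized at
the geometric median concentration. Non-convergence is flagged, not raised.
DR = β/C follows the ratio definition; note the saturating output of the
model is β + C, so DR is the *above-baseline* output relative to baseline.
K and n are invariant to fluorescence unit rescaling; β and C scale linearly.

**Rolling maximum specific rate.** OLS of ln(value) vs time in every window
of h = 5 consecutive points; the maximum slope among windows with R² ≥ 0.95
is µ (1/h). Windows containing non-positive values are skipped; numerically
perfect (zero-variance) fits count as R² = 1 so a flat curve returns slope 0.

**Gompertz with lag.** The Zwietering form
y(t) = y0 + A·exp(−exp((µe/A)(λ−t)+1)) has maximum slope exactly µ at its
inflection. Because the rolling estimator differentiates *log* abundance, the
Gompertz model is fit on the same scale (`log_input=True` for OD curves):
y = ln(OD), A = ln(OD_max/OD_0) (the log-scale span, in e-folds), µ the
maximum specific growth rate (1/h), λ the lag (h). Fitting the additive form
to raw OD instead makes the maximum log-slope ≈4µ for realistic inocula
(verified numerically), which would break the internal consistency between
the two µ estimators; the log-scale choice keeps them within 5% on
model-generated data. Multi-start initialization uses the rolling slope and
the data extremes; λ is bounded to [0, t_max].

**Δµ.** Defined as the relative percentage change ((µ₁−µ₂)/µ₁)·100, the
stated meaning of the growth-difference metric; positive = growth burden.

**DR_S.** Induced-state Fss divided by the same host × channel NI-state Fss;
values < 1 mean induction drove output below baseline. A non-positive
baseline yields NaN with a warning rather than an exception.

## Differential expression

The DE stage is intentionally simple and fully documented rather than a
re-implementation of any published engine; its statistical adequacy is
demonstrated by simulation (type-I error and power tests), not by numerical
equivalence claims.

1. *Pooling first.* Gene-call counts are summed within clusters per sample
   before testing, so results are reported per cluster — the cross-species
   unit — and pooling conserves totals exactly by construction.
2. *Size factors.* Median-of-ratios over clusters nonzero in every sample,
   normalized to geometric mean 1; library-size fallback (with warning) when
   no such cluster exists.
3. *Dispersion.* Per-cluster method-of-moments α̂ = (s² − µ̂)/µ̂² (pooled
   within-condition variance, clipped to [1e-8, 10]), a least-squares trend
   α(µ) = a0 + a1/µ, and log-space shrinkage
   log α = (1−w)·log α̂ + w·log α_trend. With 3 replicates per condition the
   moment estimate has ~4 df and is extremely noisy, so a heavy default
   w = 0.9 is used; this weight was chosen so the stage's raw p-values are
   calibrated (fraction < 0.05 within [0.03, 0.07]) in the null simulation
   the test suite runs at the study's design size. Lower w re-weights toward
   per-cluster estimates for data with genuinely heterogeneous dispersions.
4. *Wald test.* log2FC = log2((µ̂_A + 0.5)/(µ̂_B + 0.5)) with a 0.5
   pseudo-mean so clusters expressed in one condition only stay finite;
   SE by the delta method under NB sampling; two-sided normal p; BH across
   all tested clusters of one host (all-zero clusters are excluded from the
   family). Significance: adjusted p < 0.05.

The log2FC matrix sets non-significant and absent cells to exactly 0. The
accessory scope excludes unique clusters, which are nonzero in at most one
host and would artificially inflate between-host distances. DEG
frequency-group enrichment uses the host's expressed (tested) clusters as
background by default (`universe="genome"` for the genome-wide alternative);
the expressed background asks whether DEGs are enriched relative to what the
host can express, which is the sharper question.

## Concordance

PCA is by SVD of the column-centered matrix; features are *not*
variance-scaled by default (the covariance geometry is the signal when all
features share units, as log2FCs do), with `scale=True` for correlation-mode
PCA. The pipeline projects the performance matrix in correlation mode because
its metrics mix RFU, mM, nM, hours, and dimensionless folds, and covariance
PCA would be dominated by the largest-unit metric. Component signs follow a
largest-loading-positive convention; rank-deficient inputs get zero trailing
components with a warning.

Symmetric Procrustes: center both configurations, scale each to unit sum of
squares, rotate (reflections allowed — otherwise the statistic would depend
on arbitrary PCA sign conventions) and uniformly scale one onto the other.
m² = 1 − (Σσ_i)² with σ_i the singular values of X'Y; 0 ≤ m² ≤ 1.

PROTEST permutes the rows of the expression-derived configuration (which
matrix is permuted does not affect exchangeability under the null), computes
t = √(1−m²), and reports the add-one p-value
(1 + #{t_perm ≥ t_obs})/(n_perm + 1). With ≤7 items all n!−1 non-identity
permutations are enumerated — for 6 hosts, 719, making the default n_perm=719
an exact test with minimum attainable p = 1/720 ≈ 0.0014; larger
configurations fall back to uniform sampling. The implementation was
cross-checked against an independent brute-force minimization over rotation
angle, reflection, and scale (acceptance suite) and agrees to machine
precision; per-category analysis reports raw p-values at α = 0.05 without
multiplicity correction by default (the per-category pass is exploratory
localization, not confirmatory testing; a correction can be applied
downstream).

## Differentiation ranking

The three components (n_sig, Σ|log2FC|, pairwise Σ|Δlog2FC|) are each ranked
descending with average ranks for ties; the default combiner is the rank of
the *sum of component ranks* — a scale-free aggregation across components
with incomparable units — with final ties broken by Σ|log2FC| then cluster
id, so combined ranks are unique. This combiner is an explicit interpretation
(the components are standard, their combination is not canonical); a
weighted-sum alternative over the raw components is exposed. Pairs involving
a non-significant host contribute that host as 0 by default, consistent with
the masked matrix; `pairs_require_both_significant` restricts to
doubly-significant pairs.

## Synthetic data generator

Defaults emulate the target study design: 6 genomes, 6,469 clusters, 42.5%
core / 31.1% unique, triplicate RNA-seq per condition, 5% multiplicative
plate-reader noise, NB dispersion 0.1.

* *Pangenome.* Group sizes are exact after rounding the requested fractions.
  Accessory (non-unique) occupancy size is uniform over {2..5} with uniform
  genome subsets — the simplest occupancy model consistent with aggregate
  bin counts. Gene calls per occupied genome are 1 + Poisson(m−1) with
  m = 1.05, matching a pangenome of mostly single-copy orthologs. COG labels
  (23 categories + NA, with NA weight 0.23) are skewed by a factor of 3
  toward housekeeping categories (J K L C E F G H I) in the core and toward
  NA in unique clusters, giving enrichment tests a recoverable planted
  signal.
* *Counts.* Cluster baseline means are log10-uniform on [1, 3] — expressed
  bacterial genes in a ~10 M-read library rarely sit below ~10 counts.
  Planted fold-changes split ±lfc/2 between conditions; cluster totals are
  NB(µ, α) and split multinomially across the cluster's gene calls, so
  pooling reproduces totals exactly (an integer-equality invariant).
* *Latent coupling.* Each host has a latent L_h ∈ R². With strength c, the
  performance block uses Z_perf = √c·L + √(1−c)·E_perf and the core-DE
  log2FC block Z_expr = √c·L + √(1−c)·E_expr (independent E), so c is the
  shared-variance fraction and corr(Z_perf, Z_expr) = c. Both blocks map
  latents through matrices with *orthonormal rows* — similarity transforms —
  so at c=1 with no measurement noise the two configurations are exactly
  congruent (m² = 0), and at c=0 exactly independent. Performance metrics are
  base values (β≈3000 RFU, K_Ara≈0.2 mM, K_aTc≈10 nM, µ≈0.6 h⁻¹, …) times
  exp(0.25·z), i.e. ~25% geometric CV across hosts. Accessory planted
  fold-changes are independent ±magnitude per host — deliberately
  concordance-free, so the accessory scope acts as a negative control.
* *Curves.* OD600 = OD₀·exp(Gompertz) (so the rolling log-slope equals µ);
  fluorescence approaches its steady state with a 1 h rise constant; all
  observations carry lognormal noise with the configured CV (mean-1
  parameterization). Induced states apply a small host-specific growth
  burden so Δµ is informative. Toggle OFF-states leak at 70% of baseline.
* *Seeding.* One master seed feeds named substreams (pangenome, counts,
  curves, coupling) via hashed SeedSequence keys, so stages are
  independently reproducible and call order does not matter.

**What the synthetic tests do not show.** The generator has no read-level
effects (mapping ambiguity, rRNA carry-over, GC bias), no batch structure, no
outlier samples, no dispersion–mean relationships beyond the single α, no
plate spatial effects or spectral cross-talk, and its curve noise is
uncorrelated across time points. Passing the planted-truth tests shows the
estimators are correct and calibrated under the stated model, not that real
data satisfy that model.

## Problem sizes and numerical choices

Stochastic guarantees are checked at these sizes: DE calibration on 2,000
clusters (3 vs 3, mean 100, dispersion 0.1); kinetics recovery over 100
seeded fits at 5% (Hill) and 2% (Gompertz) noise CV; PROTEST null calibration
over 500 six-host pairs; end-to-end concordance recovery over 100 simulated
studies of 1,500 clusters at strength 0.9 — a size chosen to keep 100 full
repetitions cheap while leaving ~100 planted core clusters per study, ample
for a stable two-component projection. Curve fits use bounded
trust-region least squares with tight tolerances (xtol = ftol = 1e-14) and
multi-start; ties in dendrograms and ranks resolve deterministically; the
PROTEST tie rule counts permutations within 1e-12 of the observed statistic
as ≥.

## Known limitations

* The Wald stage's normal reference with 3 replicates leans on the heavy
  dispersion shrinkage; with many replicates a lighter w is preferable.
* Procrustes on two principal components discards higher-order structure;
  the number of components is configurable but 2 is the supported design.
* `per_category_concordance` with 6 hosts has limited power for categories
  with few informative clusters; untestable categories are flagged, not
  dropped silently.
* Plot generation is not included; all outputs are tabular (TSV/JSON) and
  ordination coordinates are exported for external plotting.
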