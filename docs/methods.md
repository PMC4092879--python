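# Methods

## Generative model

Counts follow the NB2 negative binomial: a gene with mean μ and dispersion
φ has Var(Y) = μ + φμ², with φ → 0 recovering the Poisson.  An experiment
compares two groups of `n_per_group` libraries over `n_genes` genes.  A
fraction `prop_de` of genes (positions uniformly random, redrawn for every
replicate dataset) receives a direction indicator d ∈ {+1, −1} split
`up_down_ratio` up:down (up-count = round of the up share, down-count the
remainder — exact for the shipped 1:1 and 3:1 designs).  The fold change is

    FC = (ρ + ρ*)^d,    ρ ~ Gamma(shape = 0.87, rate = 1.36),

read with d as an exponent: d = 0 gives FC = 1 for non-DE genes, and the
fold-change lower bound ρ* is a true bound (FC ≥ ρ* up, FC ≤ 1/ρ* down).
Group-1 counts are NB(μ, φ) and group-2 counts NB(μ·FC, φ): the fold
change acts multiplicatively on the group-2 mean and the dispersion is
shared between groups.  Simulated libraries have equal expected size — the
generative model contains no library-size factor, no batch or gene-length
effects, and no within-pair correlation.

The "lower bound of depth" scenario parameter is interpreted as a lower
bound on the per-gene baseline mean μ, enforced by resampling
below-bound genes (panel size preserved; idempotent).  The alternative
reading — read-depth filtering of simulated counts — would change little
at the shipped bounds (5 and 1); the chosen reading is documented, not
asserted as uniquely correct.

All randomness flows from one master seed through `numpy` seed sequences:
the panel is generated once per scenario (it plays the role of parameters
estimated once from real data) and each replicate dataset gets an
independent child stream for DE assignment, fold changes and counts.

## The stand-in parameter panel

Real per-gene (μ, φ) panels are estimated from a count matrix by the
method of moments within the reference group after total-count
normalization (μ̂ = sample mean; φ̂ = max(0, (s² − μ̂)/μ̂²)).  When no real
data is supplied, a synthetic stand-in panel emulates deep bulk RNA-seq
over a genome-wide gene set:

* μ ~ LogNormal(meanlog = log 300, sdlog = 1.5) — median 300 counts per
  library, spanning ~1 to ~10⁵, the shape of gene-level counts in deep
  (50–100M read) bulk libraries;
* φ ~ Gamma(shape = 2, scale = 0.2) — median ≈ 0.33, i.e. a biological
  coefficient of variation around 0.55, typical of heterogeneous human
  tissue cohorts (tumour/normal), with a realistic spread 0.05–1.5.

The stand-in panel deliberately omits features of real data: no
mean–dispersion trend (φ is drawn independently of μ), no correlation
between genes, no outlier samples, no library-size variation.  Results on
it show how the methods behave under a clean NB world with heterogeneous
dispersions; they do not certify behaviour under the artefacts of real
data.

## Method implementations

All methods share total-count normalization (factor = sample total /
geometric mean of totals) and one fold-change estimator (normalized
group-2 mean + 0.5) / (normalized group-1 mean + 0.5), so cross-method
fold-change concordance reflects normalization only.  Genes with all-zero
counts get p = 1 and FC = 1 by policy so multiplicity adjustment never
sees missing values.

**Poisson pooled test** (`poisson_ma`).  Under a per-gene Poisson model
the group-1 pooled count given the gene's total is binomial with success
probability N₁/(N₁+N₂) (library-size shares); the two-sided p-value uses
the normal approximation.  The conditional-binomial form is used rather
than an MA-plot normal-theory variant because it is exactly specified and
shares the Poisson null.

**Exact conditional NB core** (shared by `nb_exact`, `nb_pooled`, `nbp`).
Under the null the per-group sums of library-size-equalized counts are NB
with sizes n₁/φ and n₂/φ and a common success probability, so conditioning
on the total s gives a negative-hypergeometric law
P(k|s) ∝ C(k+n₁/φ−1, k)·C(s−k+n₂/φ−1, s−k).  The two-sided p-value sums
the probabilities of all splits no more likely than the observed one
(inclusion tolerance 10⁻⁹ relative on the log-pmf, so analytically tied
mirror splits are always included).  The full support is enumerated for
small totals; for large totals the support is sampled on a uniform stride
of at most 1/128 of the conditional standard deviation — a midpoint-rule
quadrature whose stride cancels in the normalized ratio and whose
relative error (~0.3%) is far below the scale at which p-values are used.
Tests verify exact agreement (<10⁻⁸) with brute-force enumeration at all
totals ≤ 30.

**Dispersion estimation.**  All dispersion estimators maximize the
Cox–Reid adjusted profile likelihood (group means profiled at their
fixed-φ MLEs, plus −½ log of the profiled-mean information per group) on
a 64-point log-spaced grid from 10⁻⁴ to 20, with quadratic interpolation
of the argmax in log φ.  The adjustment matters: plain profile ML is
biased low by ~30% at 18 residual df.  `nb_exact` shrinks per-gene
dispersions toward the common value by weighted likelihood with a default
prior weight of 20 df-equivalents; `nb_pooled` fits the parametric trend
φ(μ) = a₁ + a₀/μ by a gamma-family IRLS regression (weights 1/fitted²,
identity link — ordinary least squares is badly attenuated by the
heteroscedastic noise of per-gene estimates) and uses the conservative
max(gene-wise, trend) working value, falling back to the common
dispersion if the regression degenerates; `nbp` fits the global power
model φ(μ) = φ₀·μ^(α−2) by Nelder–Mead ML (α = 2 is constant dispersion,
and the implementation then reproduces the fixed-dispersion exact test to
<10⁻⁶).

**Two-stage Poisson** (`tspm`).  Stage 1 flags overdispersed genes with
the leverage-adjusted score statistic Σ[(y−μ̂)² − y + hμ̂] / √(2Σμ̂²)
against N(0, 1) at level 0.05 (empirical size 0.03–0.07 on Poisson data).
Stage 2 tests the group effect with a Poisson likelihood-ratio test
(χ²₁) for unflagged genes and a quasi-likelihood F-test (Pearson-scale
dispersion, F(1, N−2)) for flagged ones; the two p-value families are
BH-adjusted separately and merged, with the flag recorded per gene.

**Empirical-Bayes posterior** (`eb_nb`).  Counts are modelled as Poisson
with independent gamma rates per sample (marginally NB).  Hyperparameter
pairs (μ, φ) are sampled from moment estimates of a random gene subset —
pooled or per-group statistics with equal probability, so group-level
expression states appear in the empirical prior.  Marginal likelihoods
under "equivalent expression" (one pair for all samples) and "different
expression" (independent pairs per group) are averaged over the sampled
hypers; the prior DE proportion is estimated by EM.  The sampling step is
intentionally randomized: unseeded runs differ slightly run to run, and a
fixed seed makes them bit-reproducible.  The p slot carries 1 − posterior;
significance thresholds use the Bayesian FDR (cumulative mean of
1 − posterior in posterior order), the canonical cutoff rule for
posterior probabilities — applying BH on top of a posterior would correct
twice.  This method reports no direction.

## Evaluation

A gene is called significant when its adjusted p ≤ cutoff (defaults 0.1,
0.05, 0.01).  Ns/FP/TP and the rates FPR = FP/#non-DE, TPR = TP/#DE are
computed per dataset and averaged arithmetically across replicates
(per-dataset values are retained so pooled conventions can be recomputed).
ROC AUC uses the rank-sum identity with midranks, ranking genes by 1 − p
(the posterior for `eb_nb`).  Concordance: pairwise Spearman with
midranks; ICC(2,1) (two-way random effects, absolute agreement, single
measure — methods act as interchangeable raters and absolute values, not
just ranks, are compared) on log fold changes by default; per-direction
Venn cells over all method subsets (directionless methods excluded from
directional cells, still counted in identification frequency);
singleton = a gene called by exactly one method.

## Problem sizes and numerical choices in the shipped tests

The test suite exercises full-size simulation only where it is cheap
(scenario I with the Poisson test, 10 replicates of 10,000 genes); the
multi-method comparisons run at 2,000–3,000 genes and 3 replicates, and
dispersion-recovery checks at 5,000 genes, sizes at which every assertion
is stable across seeds.  Monte-Carlo tolerances are stated per test and
derive from the sampling variance of the quantity asserted.

## Known limitations

* The reference implementations are principle-level: absolute power is
  lower than the tuned R packages (e.g. the exact NB tests reach TPR
  ≈ 0.3–0.45 at BH 0.1 under scenario-I-like settings with the stand-in
  panel, where heavily optimized implementations on a real-data panel
  report ≈ 0.7), and the empirical-Bayes posterior method is markedly
  conservative.  Orderings and qualitative contrasts between families are
  preserved and are what the toolkit asserts.
* Plug-in dispersion estimation inflates the far tail of null p-values
  when true dispersions are strongly heterogeneous (the stand-in panel's
  gamma law): with oracle dispersions the exact test is exactly
  calibrated, but with shrunken estimates the null P(p ≤ 10⁻⁴) is a few
  times 10⁻⁴, so BH false-discovery control on null-only data is not
  achieved at the nominal level.  This is a property of the method family
  (shared with its namesakes), not of the test statistic.
* The simulator omits library-size variation, mean–dispersion trends,
  gene–gene correlation and paired-sample structure; conclusions about
  real-data artefacts are out of scope.
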