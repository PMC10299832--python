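# Methods

## Model

The package models expected neutral heterozygosity (the probability that
two randomly sampled chromosomes differ at a site) at autosomal position
x as

    pi(x) = 2 u(x) / ( 2 u(x) + 1/(2 Ne B(x)) + S(x) ),      u(x) = u0 m(x)

Backward in time, a pair of lineages at x either mutates apart (rate
2u(x)) or coalesces, through drift at rate 1/(2 Ne B(x)) — where B(x) is
the multiplicative reduction in effective population size caused by
background selection — or through a selective sweep at rate S(x).
pi0(x) denotes the same quantity with B = 1 and S = 0.

**Background selection.** Following the classical
Hudson–Kaplan/Nordborg theory, a selected site i with heterozygous
selection coefficient t and deleterious rate U reduces pairwise
coalescence time at a linked neutral site by a factor
`exp(-U t / (t + r(1-t))^2)`, with r the recombination fraction between
the sites.  Effects multiply across selected sites, so

    B(x) = exp( - sum_{a,g} U[a,g] * E[x,a,g] ),
    E[x,a,g] = sum_{i in class a} t_g / (t_g + r(x,i)(1 - t_g))^2 .

The DFE of each annotation class a is a set of point masses on a shared
log-spaced grid of coefficients t_g (default 10^-4.5 … 10^-2, six
points); the products U[a,g] (rate × mass) are the free parameters.
Continuous DFE families are deliberately out of scope: point masses keep
the exponent linear in the parameters, and a one-class BGS model then has
exactly 7 free parameters (6 weights + Ne).

**Sweeps.** Under the star-like approximation, a substitution that swept
with coefficient s forces a pair at recombination fraction r to coalesce
with probability q^2, q = exp(-r tau), tau = (2/s) ln(4 Ne s).  With
alpha[c,g] the fraction of class-c substitutions sweeping at s_g, over a
lineage span of T generations,

    S(x) = sum_{c,g} (alpha[c,g] / T) * G[x,c,g],
    G[x,c,g] = sum_{j in c} q(r(x,j), s_g)^2 .

tau is evaluated at a fixed reference Ne (config `ne_ref`, default 2e4)
rather than the fitted Ne so that the kernels G stay
parameter-independent; the dependence is only logarithmic.  Whether the
pair-coalescence probability should be q^2 with 4 Ne s or a refined
expression inside the logarithm is a modelling choice; the classical
forms above are used throughout and recorded in the kernel-cache
headers.

**Genetic distances.** Map positions are linearly interpolated in cM
from the genetic map; map distance d is converted to recombination
fraction with Haldane's function r = (1 - exp(-2d/100))/2, which is
linear (r = d/100) at the short distances that dominate both kernels.
Positions outside the mapped range are a hard error unless clamping is
requested.

## Kernel precomputation

E and G depend only on site geometry and the grid, never on the free
parameters, so they are computed once per genome; evaluating a candidate
(Ne, U, alpha) is then a matrix product and an exponential.

Two code paths compute E:

* **exact** — the pair sum over every selected site, used for toy-scale
  problems, all oracle tests, and brute-force tripwires;
* **tiered** — exact summation within `near_cm` (default 0.03 cM) of the
  focal site, then histogram aggregation of selected sites on a fine
  (0.001 cM, out to 1.6 cM) and a coarse (0.02 cM) absolute cM grid,
  each occupied bin contributing its site count at its mean map
  position.  Zone boundaries are aligned to bin edges, so the three
  zones partition the selected sites exactly.  Because the kernel decays
  like t/r^2 and is smooth beyond `near_cm`, the midpoint error is
  second order; agreement with the exact path is ~1e-6 relative on
  realistic geometries and is asserted to < 0.1% in the tests.

The tiered path makes 50 Mb genomes (≈3M selected × ≈46k neutral sites)
computable in seconds where the exact path would need hours.  Kernels
beyond `d_max` (default 100 cM) are truncated; the far field of strongly
selected sites is nearly flat in space, so truncation acts as a constant
rescaling absorbed by Ne — and because the synthetic truth is generated
with the same `d_max`, recovery experiments are internally consistent.
An optional exponent cap `e_cap` (disabled by default; a value like 4.0
floors B at exp(-4)) mimics low-B regularisation; when enabled it is
recorded in logs and flattens the lowest calibration bins.

Each truth bundle cross-checks the composed B against a direct
double-loop sum on a subsample of sites (default 1000; 200 at 50 Mb
scale), with tolerance 1e-8 when the kernels are exact and 2e-3 when
tiered; disagreement raises immediately.

## Composite likelihood

Per neutral site the data reduce to C = n(n-1)/2 chromosome pairs and
h = k(n-k) heterozygous pairs; pairs are treated as exchangeable
Bernoulli(pi(x)) draws and sites as independent:

    ll(theta) = sum_x h ln pi(x) + (C - h) ln(1 - pi(x)).

Linked sites are not independent in real data, so this is a composite
likelihood: maximised for point estimation, never differentiated for
standard errors.  pi is clamped to [1e-12, 1-1e-12] before logs.

Optimisation uses L-BFGS-B with an analytic gradient over log Ne,
box-bounded U (each grid weight in [0, 4e-8] per site per generation, in
units of 1e-8) and box-bounded alpha in [0, 1] with a smooth quadratic
penalty holding per-class sums below 1 (never active in practice: fitted
sums are orders of magnitude smaller).  u0 is fixed (default 1.4e-8,
inside the current estimates of the total per-site mutation rate)
because only the product Ne·u0 is identified when 4 Ne u << 1.  Fits run
from 10 seeded starts by default: one deterministic start with Ne
matched to the mean heterozygosity and near-zero selection, the rest
drawn randomly; all starts are recorded in the FitResult.

Out-of-sample maps come from k-fold cross-fitting (default k = 10) over
contiguous 2 Mb windows assigned round-robin to folds; each fold's sites
are predicted from a fit that excluded them, and the union covers every
site exactly once.  A 1-based site at position p belongs to window
floor(p / window) of its chromosome.

## Evaluation statistics

* **Windowed diversity** — per window, observed diversity is pooled
  (sum h / sum C) and divided by the window-mean relative mutation rate;
  predictions analogously; both are normalised by their autosome-wide
  counterparts.  Only full windows are kept (a 3 Mb chromosome gives 5
  windows of 1 Mb at 0.5 Mb overlap).
* **Variance explained** — R^2 = 1 - SSE/SST of the model's own
  predictions in non-overlapping windows (no refit); the squared Pearson
  correlation is reported alongside.
* **Collated profiles** — sites are binned by genetic distance to the
  NEAREST feature (default 160 bins × 0.005 cM); per bin, observed
  diversity is pooled then mutation-rate corrected, and both observed and
  predicted are plotted relative to the autosomal mean.
* **Calibration** — sites are split into 100 equal-count bins of
  predicted B; y is the bin's pooled observed diversity divided by its
  mean m and by the fitted autosomal-average pi0.  The lowest five bins
  are additionally pooled into one point (they share a fate when the
  exponent cap is enabled), and a LOESS curve (span 0.1 over a 2000-bin
  version) is attached for display only — it feeds no statistic.
* **B-reduction summary** — mean and per-decile 1 - B after excluding
  the top 2% of predicted-B percentile bins (outlier guard).
* **Deleterious-rate accounting** — fitted per-class rates are compared
  against the 1.29e-8–1.51e-8 per-site-per-generation bounds on the
  total mutation rate; exceeding the upper bound is flagged, and each
  class's share of total deleterious input is rate × class size.

## Synthetic genomes

The generator produces data from the model's own mean structure plus
sampling noise — it emulates the statistical structure of the real
inputs, not the population dynamics:

* piecewise-constant recombination rates, lognormal (sigma_log 0.6, mean
  1.2 cM/Mb) across 500 kb segments;
* constrained blocks with lognormal lengths (median 400 bp) and
  lognormal gaps (clustered spacing), covering ~6% of sites, each block
  labelled exonic with probability 0.17;
* substitutions at 12/Mb, 70% placed inside constrained blocks and the
  rest uniformly;
* neutral sites on a fixed grid (default every 1000 bp) restricted to
  the complement of the buffered blocks — a desk-scale downsampling of
  the "all neutral sites" design;
* relative mutation rates per block of 6000 consecutive neutral sites,
  gamma-distributed with ~10% spread and renormalised to site-weighted
  mean 1;
* truth parameters: Ne = 2e4, u0 = 1.4e-8 (baseline diversity
  ~1.1e-3), non-exonic deleterious mass 1.0e-8 biased to weak selection
  and exonic mass 4e-9 biased to strong, alpha = 0 — total deleterious
  rate per selected site below the total-rate bound, giving a mean B
  reduction of roughly 10% at 50 Mb;
* polymorphism: per site h ~ Binomial(C, pi) at n = 216 chromosomes,
  sites independent given pi.  The written table carries a cosmetic
  allele count k (the admissible count nearest the drawn h) alongside
  the exact h: at human-scale diversity the k(n-k) grid is ~40× coarser
  than the sampling noise, so consuming the rounded k would erase the
  signal; the likelihood consumes h.

Because sites are independent given pi(x) and the mean structure is the
model itself, recovery tests are exact-model tests: they validate the
estimator and its implementation, and are optimistic about real data,
where linkage correlates sites, annotations are imperfect and the mean
structure is misspecified.  An off-by-default flag adds
introgression-like outliers (20% elevated diversity at the highest-B
sites) for calibration-robustness experiments.

## Problem sizes and numerical choices

Recovery experiments run at L = 50 Mb with ~46k neutral sites, where the
summed deleterious rate is recovered within a few percent and fits take
seconds; the test suite uses 5 seeds and requires a majority to meet the
20% (rate) and 5% (pi0) tolerances.  Cross-fitting for calibration uses
4 optimiser starts per fold (the surface is well-behaved; the full
10-start budget changes nothing but runtime).  Ties in equal-count
binning are broken by stable sort order, so constant tracks put exactly
1/10 of sites in each decile.  Degenerate inputs fail loudly: empty
annotation classes yield zero kernels with a warning, monomorphic-only
data drive Ne to its lower bound, and out-of-map positions raise unless
clamped.

One caveat discovered in testing: when data are simulated without sweeps
and the sweep fractions are freed, their maximum-likelihood estimates sit
at ~1e-3 (effectively zero), but the composite log-likelihood still
improves by a few tenths of a nat — the expected boundary effect of
freeing several non-negative parameters whose truth is 0, of order
sum E[max(0,Z)^2]/2 nats independent of the number of sites.  Judging
"sweeps do not improve the fit" by a per-site log-likelihood threshold
therefore only works when the site count is large enough to swamp this
O(1) term, as in the real-data setting; at 50 Mb it is not.

## Limitations

No Hill–Robertson interference between selected sites; a single
heterozygous coefficient per grid point (no dominance dimension); no
explicit soft/partial sweep dynamics (substitution-anchored S captures
sweeps that fixed); no uncertainty quantification (composite-likelihood
curvature is not a covariance); no VCF/BAM handling — inputs are the
package's TSV/BED dialects.
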