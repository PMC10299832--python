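# linkedsel

Joint inference of **background selection** and **selective sweeps** from
neutral genetic diversity along a genome.

Purifying selection on constrained regions removes linked neutral
variation (background selection), and beneficial substitutions drag
linked variation to fixation (sweeps); both depress diversity near their
targets in proportion to genetic distance.  Given a genetic map,
annotations of putatively selected regions, putatively beneficial
substitutions, a relative mutation-rate covariate and per-site
polymorphism counts, this package fits the joint model and produces
genome-wide maps of the predicted effects — the workflow used to ask
whether background selection or sweeps dominate linked selection in a
species.  It is aimed at population geneticists working with
diversity-map inference, and ships a synthetic-genome generator so every
stage is testable without external data.

## Model

Expected neutral heterozygosity at position x:

    pi(x) = 2u(x) / ( 2u(x) + 1/(2 Ne B(x)) + S(x) ),        u(x) = u0 m(x)

* `B(x) = exp(-Σ_{a,g} U[a,g] E[x,a,g])` — background selection from
  annotation classes a with DFE weights `U[a,g]` on a grid of selection
  coefficients t_g, with unit-rate exponents
  `E[x,a,g] = Σ_{i∈a} t_g / (t_g + r(x,i)(1-t_g))²`
  (Hudson–Kaplan/Nordborg);
* `S(x) = Σ_{c,g} (alpha[c,g]/T) G[x,c,g]` — sweep-induced pair
  coalescence around substitutions, with
  `G[x,c,g] = Σ_{j∈c} exp(-2 r(x,j) · (2/s_g) ln(4 Ne s_g))`
  (star-like hitchhiking approximation).

Free parameters (Ne, U, alpha) are estimated by maximising the per-site
pair-binomial composite likelihood
`Σ_x h ln pi + (C−h) ln(1−pi)`, where `C = n(n−1)/2` and `h = k(n−k)`
are the total and mismatching chromosome pairs at each site.  Kernels E
and G are precomputed once per genome, so likelihood evaluation is a
linear compose plus an exponential.  See `docs/methods.md` for the full
account.

## Worked example

Simulate a 10 Mb genome (6% constrained sites, 216 sampled chromosomes),
fit the 7-parameter BGS model and summarise the map:

```python
from linkedsel import FitConfig, fit, predict_from_theta, b_reduction_summary
from linkedsel.synthetic import (recovery_config, simulate_genome,
                                 make_truth_bundle, simulate_polymorphism)

cfg = recovery_config(seed=1, L=10_000_000)
genome = simulate_genome(cfg)
bundle, kernels, _ = make_truth_bundle(genome, n_check=100, return_kernels=True)
table = simulate_polymorphism(genome.neutral_chrom, genome.neutral_pos,
                              bundle.pi, cfg.n_chrom_samples, seed=42)
result = fit(kernels, table, genome.m, config=FitConfig(n_starts=10, seed=0))
track = predict_from_theta(result.theta_hat, kernels, genome.m)
print(f"Ne_hat = {result.theta_hat.ne:.0f}  (true 20000)")
print(f"sum U_hat = {result.theta_hat.total_udel():.3e}  (true 1.0e-08)")
print(f"mean pi0_hat = {track.pi0.mean():.4e}  (true {bundle.pi0.mean():.4e})")
print(f"mean B reduction = {b_reduction_summary(track)['mean_reduction']:.1%}")
```

Output:

```
Ne_hat = 20081  (true 20000)
sum U_hat = 1.061e-08  (true 1.0e-08)
mean pi0_hat = 1.1233e-03  (true 1.1187e-03)
mean B reduction = 13.9%
```

The fit recovers the effective population size within 0.5%, the summed
deleterious mutation rate per constrained site within ~6%, and the
baseline diversity within 0.5%; on this genome background selection
removes ~14% of neutral diversity on average.

## Command-line pipeline

The same workflow runs from a YAML config:

```bash
linkedsel --config run.yaml run            # all stages
linkedsel --config run.yaml simulate       # or stage by stage
linkedsel --config run.yaml fit crossfit evaluate report
```

Stages (`simulate`, `precompute-bgs`, `precompute-sweeps`, `fit`,
`compute-bmap`, `crossfit`, `evaluate`, `report`) are idempotent: each
artifact carries a provenance stamp (config hash, seed, version) and is
skipped when current (`--force` recomputes).  `evaluate` writes window
series, collated diversity profiles around substitutions, calibration
curves and a JSON summary; `compute-bmap` writes the fitted B map as a
BED-like track.

## Layout

```
src/linkedsel/
  genome_io.py    file formats, genetic-map interpolation, Haldane mapping
  bgs.py          background-selection kernels and B composition
  sweeps.py       sweep coalescence kernels and S composition
  likelihood.py   composite likelihood, fitting, cross-fitting
  evaluation.py   windows, variance explained, collation, calibration
  synthetic.py    synthetic-genome generator and truth bundles
  cli.py          YAML-configured pipeline
```
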