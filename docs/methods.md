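# Methods

## Data model

All analyses operate on a tidy per-cell table with columns `expression`
(total STAT3 fluorescence, a.u., > 0), `response` (STAT3 pY705
fluorescence, a.u., ≥ 0), `dose` (ng/ml, 0 = unstimulated), `time`
(minutes), `replicate` and `line`. FCS 3.0/3.1 list-mode files are read
directly (float or integer data, either byte order); condition metadata,
which FCS does not standardise for this use, travels in a JSON sidecar
(`<file>.fcs.json`) written next to each acquisition — one acquisition
holds one condition. Events with non-finite values in a mapped channel
are dropped and counted. Compensation keywords are ignored: the
two-channel panel this package targets is acquired uncompensated.

## Preprocessing

**Normalisation.** Within one experiment (a replicate at one time point
for one cell line), the mean response is computed per dose and all
response values are rescaled by `100 / max-over-doses(mean response)`;
expression is rescaled the same way, independently. Raw values are kept
in `*_raw` columns; the operation is idempotent. Time points are
normalised separately because each time series is acquired as its own
experiment.

**Tail gating.** `gate_extreme_expressers` selects the fraction `f` of
cells with the lowest and highest expression (default 10 %), by stable
sort so ties keep input order. The low/high response distributions and
their overlap coefficient (∫ min(f,g), shared equal-width histogram)
quantify how strongly the response depends on expression at each dose.

**Heterogeneity truncation.** `truncate_heterogeneity(residual)` keeps
the central `residual` fraction of cells by expression rank — symmetric
quantile trimming, e.g. residual 0.90 removes the 5 % tails. The
alternative reading of small residuals as a window of mean ± residual/2
is implemented as `method="mean_window"` for sensitivity analysis; the
two differ for skewed distributions, and neither is treated as canonical.
Quantile trimming is the default because it is the operational
description and yields predictable counts.

## Mutual information

The MI integrand `p(S,R)·log₂[p(S,R)/(p(S)p(R))]` is integrated over a
rectangle covering the data plus a three-bandwidth margin.

* **Density.** Gaussian kernels with covariance `n^(-1/3) · Cov(data)`
  (Scott's two-dimensional factor on the sample covariance, the same
  choice as scipy's `gaussian_kde`). Orienting the kernel along the data
  correlation keeps the smoothed density's correlation equal to the
  sample's, which is what makes the plug-in MI nearly unbiased on
  Gaussian data — a diagonal product kernel shrinks MI by ~0.25 bits at
  ρ = 0.9, n = 5,000. Reported per-coordinate bandwidths are
  `σ_j · n^(-1/6)`. Marginals are the analytic marginals of the joint
  mixture (1-D mixtures with the same per-coordinate bandwidth), not
  independently refit — this keeps the estimate self-consistent.
* **Integration.** Default is a midpoint rule on a 256×256 grid; the
  joint is evaluated by binning the data onto the grid and
  FFT-convolving with the kernel (binned KDE), so one estimate costs
  well under a second at n = 5,000. The quoted integration error is the
  difference against a half-resolution grid. An adaptive-quadrature
  integrator (scipy QUADPACK `dblquad`, exact mixture evaluation, no
  binning) is available and agrees with the grid to < 0.01 bits on
  Gaussian data, but costs minutes per estimate at realistic n, so the
  grid is the default. Joint-density values below 1e-12 contribute zero
  to the integrand (log-of-zero guard).
* **Transform.** Flow fluorescence is approximately lognormal, so the
  fluorescence-facing wrappers transform both margins with log10(1 + x)
  by default before density estimation (the +1 shift keeps the exact
  zeros produced by an additive noise floor finite; it is negligible for
  typical values of order 100). `arcsinh(x/5)` and raw are available.
  MI is invariant under monotone margin transforms exactly for the
  equal-frequency plug-in estimator and approximately for the KDE.
* **Validation.** Two independent references: the bivariate-Gaussian
  closed form `−½·log₂(1−ρ²)` and an equal-frequency histogram plug-in
  estimator (no bias correction by default; Miller–Madow optional).
* **Negative estimates.** Density and quadrature error can push weakly
  dependent estimates below zero, which is impossible for true MI. Such
  estimates are flagged `valid=False`, excluded from aggregate
  summaries, and reported unchanged — never clamped.
* **Sweep conventions.** `mi_dose_sweep` computes MI per (replicate,
  dose) stratum; strata under 100 cells are skipped with a warning.
  Dose 0 is excluded by default (a baseline, not part of the
  dose-response question). Replicates are summarised by median and
  quartiles per dose, matching the assay's box-plot convention; pooling
  replicates before estimation is available only as a diagnostic.

## Channel capacity

The input alphabet is the finite set of applied doses (dose 0 included
by default — the unstimulated condition is one of the channel's states).

* **Discretised path (oracle and default 1-D route).** Responses are
  binned by pooled quantiles (20 equal-frequency bins in 1-D; a
  per-feature product quantile grid, ~12×12, in 2-D), smoothed with an
  additive pseudocount of 0.5 per bin, row-normalised, and solved
  exactly by Blahut–Arimoto (uniform start; stop when the upper/lower
  capacity bound gap < 1e-8 bits or after 10,000 iterations). Starting
  from uniform also resolves degenerate optima toward the max-entropy
  member.
* **Classifier path.** A ridge-regularised multinomial logistic
  regression on basis-expanded (default quadratic), standardised,
  log10-transformed features predicts the dose from the response under
  the empirical per-dose frequencies; ridge strength is picked from the
  grid {0.1, 1, 10} by held-out log-loss on a stratified 25 % split
  (selection subsampled to ≤ 8,000 cells — it only has to rank three
  candidates). The fitted per-cell posteriors define a Monte-Carlo
  channel: for a candidate input distribution the per-dose divergence is
  the mean log₂ ratio of the reweighted posterior to the prior, and the
  same Blahut–Arimoto fixed point maximises over the simplex (gap
  tolerance 1e-6 bits). Per-cell bootstrap resampling gives an optional
  capacity spread. A level whose posterior mass is ~zero everywhere
  marks the fit degenerate (`converged=False`). The estimator trains on
  empirical frequencies and optimises over the full simplex; whether
  the original analysis used uniform or empirical training priors is
  not stated, and at these sample sizes the difference is within
  estimator noise.
* **basic vs var.** `capacity_basic` decodes from the response alone;
  `capacity_var` from (response, expression). Since expression is
  stimulus-independent, the covariate can only sharpen the decoder:
  `capacity_var ≥ capacity_basic` up to estimator noise, and its
  stability across heterogeneity truncation is the package's readout
  that expression variability — not intrinsic response noise — limits
  the basic capacity.
* **Aggregation.** Capacity is computed per replicate and summarised as
  mean ± sd across replicates; pooled-replicate capacity is a
  diagnostic.

The two paths agree within ~0.01 bits on well-sampled 1-D channels; the
tests assert agreement within 0.1 bits at 10,000 cells per level.

## Synthetic data generator

Per cell at dose `d` (defaults in parentheses):

```
E   ~ LogNormal(mu=ln 100, sigma=0.5)          latent STAT3 expression (a.u.)
h(d) = d^n / (d^n + K^n)                       Hill activation (K=10 ng/ml, n=1.5)
kappa = 1/(1 + phi·h(d)) at t=90 only          SOCS3 feedback (phi=2)
E_eff = E / (1 + (E/e_sat)^m)^(1/m)            capacity-limited expression
                                               (e_sat=300 a.u., m=3)
P   = beta · E_eff · h(d) · kappa              noiseless response (beta=1)
R   = (P + eps_b) · 10^eps_m                   observed response
E_obs = E · 10^eps'_m                          observed expression
```

with `eps_b ~ N(0, 20)` truncated at −P (truncation, not rejection, for
determinism) and `eps_m, eps'_m ~ N(0, 0.05)` in log10 units. Doses
default to 12 levels {0, 0.5, 1, 2.5, 5, 10, 15, 25, 50, 75, 100, 200}
ng/ml (the exact experimental grid is not published; this one spans the
range with saturation near 25 ng/ml), 3 replicates, 10,000 cells per
condition.

The additive floor plus multiplicative expression coupling is the
minimal structure producing dose-dependent MI: at low dose the floor
dominates and the response is expression-independent; at saturating dose
the response tracks the cell's own STAT3. The soft ceiling `e_sat`
models upstream receptor/kinase capacity: cells at normal expression are
STAT3-limited (response ≈ proportional to E), while overexpressing cells
exceed the phosphorylation capacity and decouple from expression. This
term is required for the overexpression scenario to *lower* MI — with
pure proportional coupling, tripling expression raises the signal above
the noise floor and raises MI instead, contradicting the measured
behaviour this generator emulates. `e_sat` must sit between ~1× and ~3×
the normal median for that contrast to exist; 300 a.u. (3× the MEF
median) with sharpness 3 was fixed once from that consideration and not
revisited.

Scenarios are pure parameter transforms, never branches in the sampler:
`STAT3high` shifts `mu` by ln 3 (3-fold overexpression), `SOCS3ko` sets
`phi = 0`, `S727Ahigh` combines the overexpression shift with
`beta × 1.8` (relief of serine-phosphorylation-mediated damping).
Random streams are split per (replicate, dose, time) with the scenario
deliberately excluded from the key, so scenarios share latent draws at a
matched seed and contrasts are paired.

What the generator does **not** emulate: cell-cycle structure in
expression, instrument saturation/clipping, debris and doublets
(fixtures are pre-gated by construction), day effects between
replicates, and any mechanistic JAK/STAT kinetics. A green structural
test therefore establishes that the estimators recover the information
structure of this stated world, not that the biological values are
reproduced; the published capacities can only be checked against the
deposited experimental data via `reproduce_paper`, which is opt-in and
file-path based (no download is attempted).

## Numerical and degenerate-input conventions

* Quantiles use linear interpolation between order statistics; ties are
  kept on the inclusive side via stable sorting.
* Truncation counts are `N − 2·round(N·(1−residual)/2)`, exact and
  predictable.
* KDE requires ≥ 20 paired observations and non-zero variance in both
  margins (`DegenerateDataError` otherwise); capacity requires ≥ 2 input
  levels; tail gating requires ≥ 10 cells and `0 < fraction ≤ 0.5`.
* All-zero responses in a normalisation group raise an error rather than
  produce infinities.
* Every randomised component takes an explicit seed; analyses re-run
  with the same config and seed produce byte-identical CSV outputs.

## Scaled-down test sizes

The test suite and acceptance script run the structural checks at 2,000
cells per condition (1–3 replicates) instead of the generator's 10,000
default, keeping the whole suite within a single-CPU budget of a few
minutes. The asserted properties (dose-dependent MI rise, capacity
ordering across scenarios and truncation levels, cross-estimator
agreement) are scale-stable well below these sizes.

## Known limitations

* The KDE MI estimator inherits smoothing bias for strongly non-Gaussian
  joints; the plug-in estimator bounds the error in tests but no
  k-nearest-neighbour estimator is provided.
* The classifier capacity estimator evaluates posteriors on the training
  sample; at a few hundred cells per level this is mildly optimistic.
  Bootstrap spreads quantify sampling noise, not this bias.
* The FCS reader supports single-data-segment list-mode files with
  uniform 16/32-bit integer or float data — the files this assay
  produces — not the full breadth of the standard.
* No spectral compensation, doublet discrimination, or automated debris
  gating: tables are assumed pre-gated.
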