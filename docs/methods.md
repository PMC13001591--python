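# Statistical methods

This note documents, in the package's own terms, every statistical choice a
user of the results needs to know: the models, their parameters and
defaults, the numerical implementation, what the synthetic generator does
and does not emulate, and known limitations.

## 1. Data model and culling

The atomic record is one trap observation: `(year, day, treatment,
replicate, trap_id, species, adults)`. Culling keeps records with
`year >= 1993` and `day <= 222` (day of year), the window over which the
survey design is assumed consistent; culling is idempotent and
order-preserving.

Aggregation produces one **analysis unit** per `(treatment, replicate,
year)`: the per-species capture sum, group sums for `native` / `exotic` /
`all`, and **effort** = the number of distinct trap-weeks (a trap-week is
one `(trap_id, day)` pair with at least one record, including explicit
zero-count records). Effort therefore reflects traps actually deployed;
missing trap-weeks reduce the offset instead of being imputed.

## 2. Community metrics

For a group `g` the unit response is the summed captures of its member
species. **Predation potential** is the consumption-weighted sum

    P = sum_s captures_s * w_s,     w_s = consumption_rate_s / 100,

where `consumption_rate_s` is the species' per-capita aphid consumption
(aphids/day); the division by 100 makes a rate of 100 aphids/day the unit
weight. `P` is nonnegative and linear in captures, so it enters the same
quasi-likelihood machinery as a count (quasi-Poisson needs only the
mean-variance relationship, not integer support). Predation units use the
whole-community effort.

The bundled consumption rates are order-of-magnitude stand-ins encoding the
relative ranking of the species (large *Coccinella* and *Harmonia* near 1,
small *Brachiacantha* near 0.2); for substantive real-data use, supply
measured rates via the species YAML config.

## 3. Linear trends over dynamical phases

For each metric, captures per trap `y_i = response_i / effort_i` is
regressed on year by ordinary least squares over the whole series and over
four fixed phases:

| phase | years | rationale |
|---|---|---|
| I | 1993–2000 | pre-establishment / early exotic arrivals |
| II | 2001–2005 | post-arrival reshuffling |
| III | 2006–2015 | second exotic wave and decline onset |
| IV | 2016–2023 | recent period |

Reported quantities come from the fitted line: with fitted values `ŷ(a)`
and `ŷ(b)` at the window ends,

    pct_change_total   = 100 * (ŷ(b) − ŷ(a)) / ŷ(a)
    pct_change_per_year = pct_change_total / (b − a + 1)

The per-year figure divides by the **inclusive year count** of the window
(31 for 1993–2023, 8 for 2016–2023), a plain-arithmetic convention rather
than a compounded rate. If `ŷ(a) <= 0` the percentage is undefined and
flagged (`pct_defined = False`) instead of reported. Phases with fewer than
three yearly values are skipped with a warning. Significance is the
two-sided t test of the slope at `alpha` (default 0.05).

## 4. Penalized-spline quasi-Poisson GAM

### Model

For unit `i` with response `y_i`, effort `E_i > 0`, and year `t_i`:

    E[y_i] = mu_i,   Var[y_i] = phi * mu_i        (quasi-Poisson)
    log mu_i = beta_0 + f(t_i) + log E_i          (pooled model)
    log mu_i = beta_{h(i)} + f_{h(i)}(t_i) + log E_i   (by-habitat model)

`f` is a natural cubic regression spline; `log E_i` is a fixed offset, so
fitted means are rates per trap-week scaled to any chosen effort.
Zero-effort units are dropped before fitting and the count of exclusions is
recorded on the fit object.

### Basis and penalty

The spline uses the cardinal natural-cubic-spline parameterization:
coefficients are the function's values at `k` knots placed at the empirical
quantiles of the distinct observed years (first and last years are always
knots). `k = min(5, floor(n_years / 6))` — at most one knot per six years,
capped at five — and at least 3 knots are required; shorter series raise an
error rather than fit an unstable smooth.

The curvature penalty is exact: writing second derivatives at the knots as
`D beta` solved through the banded system `B delta = D beta`, the penalty
matrix is `S = D' B^{-1} D`, which satisfies `beta' S beta =
∫ f''(t)^2 dt` identically (verified in the tests against numerical
quadrature). Straight lines are unpenalized (`S`'s null space).

Each smooth is centered (sum-to-zero over the observed design) by
reparameterizing through the null space of its column-sum constraint, with
an explicit intercept (and habitat one-hot intercepts in the by-habitat
model). Each habitat level needs at least 10 units.

### Fitting

Penalized iteratively reweighted least squares on the working normal
equations `(X'WX + sp * S) beta = X'Wz`, with step-halving whenever a step
would increase the penalized quasi-deviance. Convergence requires the
penalized deviance change to fall below `1e-8 * (|D| + 0.1)` within 200
iterations; non-convergence raises an error carrying the deviance trace.

**Smoothing parameter**: `sp` (default 0.5) multiplies the raw curvature
penalty matrix directly. Because the penalty is in the data's year units
and unscaled, `sp` here is faithful in role but **not numerically
comparable** to the smoothing parameters of other GAM software, which
typically rescale the penalty internally. With only five knots the fit is
insensitive to moderate changes in `sp`; the tests verify the limiting
behavior at both extremes (unpenalized interpolating tendency as `sp → 0`,
exact GLM-with-linear-year as `sp → ∞`).

### Effective degrees of freedom, dispersion, GCV

With `H = (X'WX + sp*S)^{-1}` at convergence and `A = X'WX`:

    edf_j      = [H A]_jj  (summed per term; total_edf = trace)
    phi_hat    = Pearson chi^2 / (n − total_edf)
    GCV        = n * D / (n − total_edf)^2        (D = quasi-deviance)
    V_beta     = phi_hat * H                      (Bayesian covariance)

GCV uses the quasi-deviance, not Pearson chi-square; lower is better. Model
comparison (`compare_gcv`) requires strict inequality to declare a winner
and reports ties as ties.

### Smooth significance

The Wald-type statistic for a smooth with coefficient block `b` and
covariance block `V` is

    F = b' V^+ b / edf_s   referenced to   F(edf_s, n − total_edf),

with `V^+` the pseudo-inverse. The reported **reference df** is the rank of
the smooth's coefficient block (the centered basis dimension); this is this
package's own definition — other software reports differently defined
reference df, so values are not comparable across implementations. The test
is a pragmatic approximation: penalization shrinks `b`, making the test
conservative near the null (type-I error is verified ≤ nominal by
simulation, not claimed exact).

### Standardized prediction

Predictions are `exp(link + log E*)` at a standard effort `E*` (default 50
traps), with the delta-method link-scale standard error from `V_beta`; the
reported ribbon is `exp(link ± 1 SE)` (so a 95% interval uses 1.96 SE on
the link scale). Prediction outside the fitted year range raises — no
extrapolation.

## 5. Synthetic survey generator

The generator emulates the study design, not any particular realized
dataset:

- 14 species (10 native, 4 exotic) with stand-in consumption rates; exotic
  arrival years (1994, 1999, 2007 for the three later arrivals) zero out a
  species before establishment.
- 10 treatments in three habitat classes (4 annual crop, 3 perennial crop,
  3 forest), 6 replicate blocks, 5 traps per plot, 13 weekly samples per
  season ending on day 222, years 1993–2023.
- Each species' expected per-trap-week count follows a log-scale natural
  cubic spline through five control years (the quantile grid of the design:
  1993, 2000.5, 2008, 2015.5, 2023), shared within origin-by-habitat groups
  so that group-level curves have a known closed form
  (`group_rate_curve`). The default shapes encode the qualitative story:
  native increase then sustained decline with a recent trough, exotic rise
  to a mid-2000s peak with partial recent recovery, and strong
  habitat contrasts (annual > perennial > forest baseline).
- Counts are negative-binomial with exactly the quasi-Poisson
  mean-variance relation `Var = phi * mu` (`phi` default 3; `phi = 1`
  gives Poisson). Whole trap-weeks go missing independently with
  probability 0.1.
- Generation is vectorized and deterministic: one RNG stream, a canonical
  cell order, and missingness drawn before counts, so a seed fixes the
  dataset exactly regardless of chunking.

Not emulated: within-season phenology (all weeks of a season share the
year's rate), spatial correlation between plots or traps, observation error
in species identification, and year-to-year autocorrelation beyond the
smooth trajectory.

Rare-native baselines are set low enough that several native species have
zero-capture years late in the series, which is what the detection-limit
summary (`detection_summary`) is designed to surface; it reports, per
species, the window years with zero total captures, plus both readings of
"not detected on an annual basis": the count of native species with ≥ 1
undetected year and with all window years undetected.

## 6. Numerical choices and problem sizes

- The banded spline systems are solved with `scipy.linalg.solve_banded`;
  IRLS solves dense symmetric systems (≤ ~16 parameters), so no sparse
  machinery is needed.
- The default scenario produces ~1.4M records; generation + aggregation
  takes ~1.5 s, a full pipeline run ~6 s, and the replication-based parts
  of the test suite (hundreds of seeded refits) ~5 minutes on one CPU.
- All tabular outputs are CSV with fixed column order and rounding applied
  only at the reporting layer; the pipeline's manifest stores SHA-256
  hashes of every output plus the config hash, and identical config + seed
  reproduce every file byte for byte.

## 7. Limitations

- `sp` is fixed, not estimated; there is no automatic smoothing-parameter
  selection (REML/GCV optimization) and no tensor-product or multivariate
  smooths.
- The smooth F test's null distribution is approximate (see §4); treat
  p-values near the threshold with caution.
- Quasi-likelihood provides no true likelihood, so no AIC; model choice is
  by GCV only.
- Percent changes from SLR on captures per trap can be undefined or
  unstable when the fitted start-of-window value is near zero; the code
  flags rather than extrapolates.
- The bundled consumption rates and the generator's trajectory shapes are
  plausibility stand-ins, adequate for validating estimator behavior, not
  substantive ecological claims.
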