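# Methods

This note documents the models the package implements, the conventions and
defaults it commits to where the literature leaves a choice open, and what
the synthetic-data validation does and does not demonstrate.

## Growth

**Length–weight.** `W = a L^b` is fitted by ordinary least squares of
log10(W) on log10(L), the standard choice in this literature (it matches the
way `b`, its standard error and the significance test against `b = 3` are
conventionally reported, and it is the maximum-likelihood fit under
multiplicative lognormal error, which is how weight scatter behaves). `a` is
back-transformed to the linear scale without a bias correction, matching
common reporting practice. A direct nonlinear fit on the raw scale is
available (`method="nls"`) for sensitivity checks. Isometry is flagged when
`|b − 3| ≤ 0.08` by default; the `b_t_statistic` property supports a formal
t test instead.

**Von Bertalanffy.** `L_t = L∞(1 − e^{−k(t−t₀)})` is fitted to individual
length-at-age records (ages are integer annulus counts; no fractional-year
correction is applied) by Levenberg–Marquardt least squares. Because the
likelihood surface has the well-known `L∞`–`k` ridge, five starts are used:
`L∞ = 1.05 ×` max observed length, `t₀ = −0.5`, and `k ∈ {0.05, 0.1, 0.2,
0.4, 0.8}`; the lowest residual sum of squares wins, with ties broken by the
smallest `|t₀|`. `t₀` is freely estimated. An age-class-means option exists
but individuals are the default (they use all data and match reported sample
sizes). Sexes are pooled within a group.

**Derived quantities.** The weight curve is composed, never refit:
`W∞ = a L∞^b` exactly. The inflection-point age `t_i = ln(b)/k + t₀` is
where the weight growth rate `dW/dt = b W∞ k e^{−kτ}(1 − e^{−kτ})^{b−1}`
peaks; the critical age `t_c = [k t₀ − ln M + ln(bk + M)]/k` is where an
unfished cohort's biomass `N(t) W(t)` peaks under natural mortality `M`.
The growth performance index `φ = log₁₀ k + 2 log₁₀ L∞` is computed with
`L∞` in **mm** throughout; the cm convention would shift every value by
exactly −2, so the unit must travel with the number.

**Display rounding.** Machine outputs carry full precision; human-readable
report output rounds ages and φ to 2 decimals and lengths to 1 mm / whole
mm, the conventional reporting precision for these quantities.

## Mortality

Total mortality uses the Beverton–Holt mean-length estimator
`Z = k(L∞ − L̄)/(L̄ − L_c)`. Its derivation assumes knife-edge selection at
`L_c`, equilibrium recruitment and growth along the mean VBGF curve, so
`L̄` is computed **only over fish with `L ≥ L_c`**. When `L_c` is not
supplied it defaults to the 5th percentile of the retained lengths — a
transparent, configurable rule; a logistic 50%-retention estimator fitted to
the ascending limb of the length-frequency histogram is available as an
alternative (`estimate_lc(..., method="logistic")`).

Natural mortality comes from Pauly's empirical regression. The default
variant is the standard published form — base-10 logarithms with `L∞` in
cm: `log₁₀M = −0.0066 − 0.279 log₁₀L∞ + 0.6543 log₁₀k + 0.4634 log₁₀T`,
`T` the mean annual water temperature in °C. A natural-log variant with
`L∞` in mm (a form that circulates in secondary sources) is provided behind
an explicit flag because the two differ by roughly a factor of two at
plateau-river temperatures; the variant used is always recorded in output.
For the bundled four-tributary parameter sets, the base-10/cm form is the
one consistent with the reported `M` values (inverting it for `T` yields
≈ 11–13.5 °C, plausible for these rivers and ordered by elevation; the
natural-log/mm reading would require implausibly warm water).

`F = Z − M` and `E = F/Z`. A negative `F` is returned with a warning rather
than clamped — it signals inconsistent inputs and should be seen.
Diagnostics report `e^{−k}`, `M/K` and `Z/K` with the conventional
interpretation bands (`e^{−k} < 1` growth-equation reliability; `M/K` within
[1, 2.5] for a trustworthy `M`; `Z/K` above/below 3 separating
fishing-dominated from natural-dominated regimes).

## Per-recruit analysis

The Beverton–Holt relative yield per recruit, for knife-edge selection at
`L_c`, isometric weight (`b = 3` in the cubic expansion) and `U = 1 −
L_c/L∞`:

    Y′/R = E · U^{M/k} · [1 − 3U/(1+m) + 3U²/(1+2m) − U³/(1+3m)],
    m = k/Z = (1 − E)/(M/k).

Sweeping `E` at fixed `M` implies `Z = M/(1 − E)`; this substitution is what
makes `Y′/R` a function of `E` alone. `B′/R = (Y′/R)/F` is evaluated in the
algebraically equivalent form `U^{M/k} · bracket · (1 − E)/M`, which is
finite at `E = 0` (the virgin level used to define `E₀.₅`) and avoids the
0/0 at the origin. The test suite verifies both functions against an
independent numerical integration of the underlying age-structured yield
(recruitment at `t₀`, mortality `M` below the age at `L_c` and `Z` above,
weight ∝ length³) to well under 0.1%.

Reference points: `E_max` by a grid scan (default step 0.001 on [0, 0.999])
followed by bounded scalar refinement to 1e-5 (a non-unimodal grid profile
warns and refines the global argmax); `E₀.₁` as the root of
`dY′/dE − 0.1 · dY′/dE|₀` with central differences at step 1e-5 (the
analytic curve extends smoothly through `E = 0`, so the centred stencil is
valid there); `E₀.₅` as the root of `B′/R(E) − ½B′/R(0)` to 1e-6. All three
are grid-resolution-independent below step 0.005.

**Isopleth shape.** Over the default bounded `L_c/L∞ ∈ [0.1, 0.6]` axis,
each fixed-`E` row of the yield isopleth is unimodal in `L_c` with its ridge
moving to larger `L_c` as `E` grows; for `M/k ≈ 2`–2.2 the ridge sits at
ratios ≈ 0.35–0.55, *inside* the 0.6 bound. Statements that yield increases
with `L_c` all the way to `L_c/L∞ = 0.6` hold only on the lower part of the
axis; the property tests assert the unimodal-ridge behaviour, which is what
the model actually satisfies. The yield-maximising `L_c` reported at a fixed
ratio (`optimal_lc_at_ratio`, default 0.6) is plain `ratio × L∞` arithmetic,
rounded to whole mm.

**Harvest advice.** The recommended minimum catchable length is the mean of
three indices — `L_c` at the fixed ratio, length at `t_i`, length at `t_c`
— rounded to whole mm. For the bundled parameter sets this reproduces the
Duoxiong Zangbo value (257 mm) exactly; the other three recompute 1–3 mm
away from their reported values (248 vs 249, 240 vs 237, 244 vs 242),
consistent with unrecoverable intermediate rounding in the source rather
than a model difference.

## Group comparison

"ANCOVA" is realised as the nested-model F test: full model with per-group
intercepts and slopes versus reduced model with a common slope,
`F = [(RSS_r − RSS_f)/(g−1)] / [RSS_f/(n−2g)]`. Length–weight comparisons
run on the log10–log10 scale; length–age and weight–age comparisons run on
raw scales (the simplest defensible reading when no transform is stated).
The implementation assembles the design matrices explicitly and fits with
statsmodels OLS; tests verify it against a longhand least-squares RSS
computation to 1e-10 and check its type-I error (0.05 ± 0.02 over 1000 null
replicates) and power (b = 2.9 vs 3.1 at n = 500 rejects > 90%).

## Synthetic populations

The generator draws exactly the structure the estimators assume: equilibrium
(constant-recruitment) ages from a truncated exponential at rate `Z` on
[recruitment age, max age]; continuous ages are floored to integer annulus
counts for the `age` column while the fractional age is retained
(`age_true`) for oracle computations; lengths are the VBGF mean at the true
age times `(1 + CV·z)` with `z` standard normal truncated at ±3 (CV < 1/3
keeps lengths positive); weights are `aL^b` times mean-one lognormal noise;
sex is Bernoulli. One `numpy` generator stream seeded from the config drives
all draws, so identical config + seed reproduces records exactly.

Defaults describe a moderately exploited schizothoracine-like population:
`L∞ = 400 mm`, `k = 0.16/yr`, `t₀ = −0.5 yr`, `a = 2×10⁻⁵`, `b = 3`,
`M = 0.33/yr`, `F = 0.30/yr`, ages 0–14, length CV 8%, weight CV 10%,
female fraction 0.55 (the pooled sex ratio of the four field samples),
knife-edge `L_c = 150 mm`.

**What the validation shows.** On these populations the mean-length `Z`
estimator is unbiased to < 2% (n = 10⁶, 20 replicates, noise-free lengths —
its exact generating model) and to ~5% with 8% length noise; VBGF fits
recover truth exactly on noiseless data and `L∞` within 3% / `k` within 10%
at n = 3000 with noise; the full chain (fit growth on the survey sample,
estimate `Z` from the knife-edge catch, `E = (Z−M)/Z` with `M` supplied as
an external input, as it is in practice) recovers `E = 0.476` within 0.05.

**What it does not show.** Real data violate the generator in known ways it
deliberately omits: seasonal growth oscillation, density dependence,
recruitment variability, ageing error, and size-selective survey gear. The
last one matters most: fitting the VBGF to a catch truncated at `L_c =
0.375 L∞` inflates `L∞` by ~27% and halves `k` in our experiments, so
growth must be fitted to an (approximately) unselective sample — as the
multi-mesh survey design of the motivating study intends — and only the
mean-length estimator fed the gear-truncated catch. Passing tests therefore
certify the estimators under their own assumptions, not robustness to these
violations.

## Problem sizes and determinism

Statistical tests use fixed seeds throughout; Monte-Carlo sizes (10⁶ × 20
replicates for the Z-estimator bias, 1000 replicates for the ANCOVA error
rate, 5×5×5 oracle grids) were chosen so the binomial/Monte-Carlo error is
several times smaller than the tolerance being asserted. The report bundle
is byte-deterministic for a given config + seed, and the manifest records
package versions, the seed and a SHA-256 hash of the full configuration.
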