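# lenassess

Length-based stock assessment for data-limited fisheries, built around the
assessment of *Schizopygopsis younghusbandi* (a slow-growing schizothoracine
fish) in four tributaries of the Yarlung Zangbo River. The package chains the
classic desk-study toolkit — growth modelling, mean-length mortality,
Beverton–Holt per-recruit analysis — into one reproducible pipeline, and
ships an individual-based population simulator so every stage can be
validated end-to-end against known truth.

## What it computes

For each population ("group"), from one-fish-per-row records
(`group_id, sex, age, length_mm, weight_g`):

1. **Length–weight allometry** `W = a L^b` by OLS on the log10–log10 scale
   (`b ≈ 3` means isometric growth), with an ANCOVA-style nested-model
   F test for slope homogeneity across groups.
2. **Von Bertalanffy growth** `L_t = L∞(1 − e^{−k(t−t₀)})` by multi-start
   Levenberg–Marquardt, the derived weight curve
   `W_t = W∞(1 − e^{−k(t−t₀)})^b` with `W∞ = a L∞^b`, the four rate and
   acceleration curves, and the derived life-history quantities
   - inflection-point age `t_i = ln(b)/k + t₀` (peak weight growth rate),
   - critical age `t_c = [k t₀ − ln M + ln(bk + M)]/k` (peak cohort biomass),
   - growth performance index `φ = log₁₀k + 2 log₁₀L∞` (L∞ in mm).
3. **Mortality and exploitation**: total mortality from the Beverton–Holt
   mean-length estimator `Z = k(L∞ − L̄)/(L̄ − L_c)`, natural mortality from
   Pauly's empirical formula (base-10 form with L∞ in cm by default), then
   `F = Z − M`, `E = F/Z`, with the standard reliability diagnostics
   (`e^{−k} < 1`, `M/K ∈ [1, 2.5]`, `Z/K` vs 3).
4. **Per-recruit analysis**: relative yield `Y′/R` and biomass `B′/R` as
   functions of `E` (knife-edge selection at `L_c`), the reference points
   `E_max`, `E₀.₁`, `E₀.₅`, the `(E, L_c)` yield isopleth, and a
   three-index minimum-catchable-length recommendation (mean of the
   yield-maximising `L_c` at `L_c/L∞ = 0.6`, the length at `t_i`, and the
   length at `t_c`).

The `lenassess.simulate` module draws equilibrium exploited populations
(exponential ages at rate `Z`, VBGF lengths with multiplicative noise,
allometric weights, knife-edge or logistic gear selectivity) that satisfy the
estimators' assumptions exactly, which is how the test suite demonstrates
parameter recovery.

## Worked example

The published four-tributary parameter sets are bundled
(`lenassess.yarlung_tributaries()`), so the headline advice can be recomputed
in a few lines:

```python
import lenassess as la

for river, p in la.yarlung_tributaries().iterrows():
    vb = la.tributary_vbgf(river)
    s = la.growth_summary(vb, p["b"], p["M"])
    rec = la.recommend_min_catch_length(vb, s, la.optimal_lc_at_ratio(vb.L_inf))
    E = la.exploitation_rate(la.fishing_mortality(p["Z"], p["M"]), p["Z"])
    print(f"{river:16s} t_i={s.t_i:.2f} t_c={s.t_c:.2f} phi={s.phi:.2f} "
          f"E={E:.3f} advice={rec:.0f} mm")
```

```
Duoxiong Zangbo  t_i=6.51 t_c=5.32 phi=4.42 E=0.313 advice=257 mm
Nianchu River    t_i=6.31 t_c=5.13 phi=4.41 E=0.522 advice=248 mm
Lhasa River      t_i=5.60 t_c=4.40 phi=4.42 E=0.659 advice=240 mm
Niyang River     t_i=5.85 t_c=4.46 phi=4.43 E=0.777 advice=244 mm
```

`t_i` and `t_c` are ages in years, `φ` is the dimensionless growth
performance index, and `E` is the exploitation rate — values above 0.5 flag
overexploitation (three of the four tributaries here). The advice column is
the three-index minimum catchable length. The same numbers come from the
CLI:

```sh
$ lenassess advise --linf 414.532 --k 0.154 --t0 -0.556 --b 2.9689 --m 0.311
t_i = 6.51 yr (length 274.9 mm)
t_c = 5.32 yr (length 246.7 mm)
phi = 4.42; L_c* = 249 mm
recommended minimum catchable length: 257 mm
```

A full run on record-level data is driven by a YAML config
(`lenassess run-all --config run.yaml`); see `lenassess --help` for the
`simulate`, `fit-growth`, `mortality`, `ypr`, `isopleth` and `report`
subcommands. `docs/methods.md` documents the models, conventions and
numerical choices.

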