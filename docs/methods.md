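# Methods notes

This note documents the models and conventions implemented in `regcap`,
the choices made where the methodology was genuinely open, and what the
synthetic-data tests do and do not demonstrate.

## Evaluation model

The analysis evaluates n objects (region-years) on m indicators grouped
into capacity dimensions. All indicator processing happens on the
normalized scale `y ∈ [0, 1]`; the raw scale enters only through the
min–max bounds.

**Normalization scope.** Min–max bounds are computed per indicator over
the *pooled* panel (all regions and years) by default, selectable
per-year. Pooling is the default because trend analysis compares scores
across years, which requires a common scale; per-year bounds make each
year's scores span [0, 1] but destroy cross-year comparability.
Frozen bounds from a reference period can be applied to new data, in
which case out-of-sample values are clipped to [0, 1] with a warning.

**Degenerate columns.** An indicator constant over its normalization
group has no min–max image; it is assigned y = 0.5 everywhere with a
warning. This keeps the pipeline total while being self-correcting: a
constant column has entropy 1, hence entropy weight 0, hence combined
weight 0, so the arbitrary 0.5 never influences scores. `0·ln 0 := 0`
in the entropy sum (the standard limit); an ε-shifted variant
(`P + 1e-12`) is available behind a flag for cross-checking only.

**Expert aggregation.** With several experts, the subjective weight is
the mean of per-expert proportion vectors, not the proportion of summed
scores. The two differ when experts use the scale differently (a
"generous" expert's total is larger); per-expert proportions give every
expert equal influence.

**Single weight system.** Entropy weights are computed once on the
pooled normalized panel and the combined weight system is held fixed
across years. Per-year reweighting would confound score trends with
weight drift.

**Frozen published weights.** The bundled schema carries the published
two-level weight system (dimension weights 0.153/0.218/0.289/0.210/
0.130 and within-dimension weights). Printed at three decimals, its
within-dimension vectors sum to 1 only within 2e-3; validation of
frozen weight sets therefore uses a loosened tolerance (5e-3), while
freshly computed weight sets must satisfy 1e-9.

**Printed-precision comparisons.** Published score tables print three
decimals with half-up rounding. Every comparison against printed values
(rank ties, the above-average count) is made after half-up rounding at
3 decimals; full-precision values are carried alongside. Notably, the
count of provinces above the national average is 13 at printed
precision but 14 in full precision (one province's composite equals the
rounded mean exactly); the package exposes both via the `decimals`
argument of `count_above_mean`.

**Ranking.** Descending competition ranking on the 3-decimal composite:
tied values share a rank and the following ranks are skipped, matching
the published "1, 2, 2, 4" pattern.

**ANOVA.** Plain one-way fixed-effects decomposition (F = MSB/MSW,
upper-tail F(k−1, N−k) p-value), no Welch correction and no post-hoc
tests, since the analysis reports a single F and p per score column.
Group SDs use the n−1 denominator. Reconstructing the published F
statistics exactly from the printed 3-decimal scores is not possible
(they were computed on pre-rounding data); recomputation from printed
values yields nearby F values with the same significance pattern, and
that pattern is what the tests assert.

**Obstacle degrees.** Eq-style shortfall shares use the *global*
combined weights W_j (dimension × within-dimension), so degrees are
comparable across dimensions. Regional summaries average member
objects' degree vectors and renormalize to 100% (`mean_of_members`);
computing degrees of the category's mean normalized profile
(`mean_profile`) is implemented behind a flag — both are defensible
aggregations and the package defaults to the simpler one, which is also
flagged in the outputs it writes.

**Vigilance descriptives.** Pass rates and serious-report shares are
plain ratios ×100, rounded half-up at two decimals to match how such
rates are printed; no signal-detection statistics are computed.

## Synthetic data generator

The generator emulates the structure of the study data: 31 provincial
regions in a 12/9/10 eastern/central/western split, 14 indicators with
the bundled schema's units, years 2018–2022, 7 experts on a 1–5 scale.
Its latent model is

    z[r, t, j] = latent(belt) + u_r + trend·(t − t₀) + ε_{r,t,j}

with region effect `u_r ~ N(0, noise_sd²)` and observation noise
`ε ~ N(0, noise_sd²)`. Belt latents default to (0.65, 0.55, 0.45),
i.e. an eastern–western gap of `category_gap = 0.2` with the central
belt midway, twice the default `noise_sd = 0.1` — a clear but not
overwhelming separation consistent with the observed regional
disparities. The default trend of 0.02/year produces the gently rising
series the study period showed; `missing_rate = 0.02` injects sparse
gaps for the interpolation stage (never an entire series).

Each indicator maps z through a monotone unit-appropriate link:
qualified-rate percentages into [85, 100] (realistic sampling pass
rates), other percentages into [0, 100], counts as nonnegative integers
on an exponential scale, monetary amounts positive. Monotone links mean
the latent ordering is preserved in expectation, which is what the
recovery tests measure.

What the generator does **not** emulate: cross-indicator correlation
beyond the shared latent, heavy-tailed or heteroskedastic noise,
reporting artifacts, or real provincial magnitudes beyond plausible
ranges. Passing recovery tests therefore show the pipeline is correct
and well calibrated under its own assumptions — not that real
provincial data meet those assumptions.

Calibration checks run the full pipeline (simulate → normalize →
weight → score → ANOVA on the final year's composite) over 200 seeds:
with a belt gap of twice the noise SD the composite ANOVA rejects at
α = 0.05 in ≥ 90% of runs; with zero gap the rejection rate stays near
the nominal 5% (accepted band 2–9%). Rank recovery uses a 100-seed
median Spearman correlation between latent capacity and composite
(> 0.8 at noise one-tenth of the latent spread). These replicate counts
keep the suite fast while leaving the binomial noise of the estimated
rates well inside the asserted bands.

## Numerical conventions

- Half-up decimal rounding (`_util.round_half_up`) for every
  printed-precision comparison; IEEE half-even everywhere else.
- Weight-sum invariants asserted at 1e-9; oracle equivalence of
  entropy, ANOVA and obstacle computations at 1e-10–1e-12.
- Linear interpolation is performed against the year value, so uneven
  year spacing interpolates correctly; boundary gaps take the nearest
  observed value.
- All simulation randomness flows from one `numpy.random.Generator`
  seeded from the single `seed` field; derived streams (expert scores,
  vigilance) use `SeedSequence` spawns of the same seed.

## Known limitations

- The published weight system cannot be re-derived because the
  underlying expert scores and raw panels are unpublished; it is
  consumed as a frozen fixture, and composite reconstruction is only
  checkable at the printed 3-decimal precision.
- Published regional obstacle-degree tables likewise depend on the
  unpublished raw panels; the obstacle module is validated against
  algebraic oracles and invariants instead.
- The interpolation policy (linear interior, nearest boundary) is a
  reasonable default for short annual series, not a statistical missing
  -data model; heavily missing panels deserve explicit imputation.
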