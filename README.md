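# regcap

Quantitative evaluation of provincial drug-regulatory capacity in China —
a reusable pipeline for composite-indicator analysis with combined
subjective–objective weighting, regional significance testing, and
obstacle-factor diagnosis.

Drug regulation in China is carried out by 31 provincial-level
authorities whose resources, workloads and results differ widely across
the eastern, central and western economic belts. `regcap` turns a raw
panel (region × year × indicator) into a hierarchical capacity index and
the diagnostics policy analysts need: which regions lead, whether belt
differences are statistically significant, and which indicators most
restrict each region's improvement. It is aimed at regulatory-science
and health-policy researchers who work with panel indicator data.

## The methods

Indicators are organized in a two-level system: m indicators grouped
into capacity dimensions (resource acquisition, functional performance,
performance level, learning and development, Internet application).
The pipeline is:

1. **Normalization** (min–max, direction-aware):
   positive indicators `y = (x − x_min)/(x_max − x_min)`, negative
   indicators `y = (x_max − x)/(x_max − x_min)`, so `y ∈ [0, 1]` and 1
   always means better. Missing cells are first filled by linear
   interpolation in the year (nearest value at series boundaries).
2. **Subjective weights** (importance-score AHP): each expert scores
   every indicator 1–5; an expert's weight vector is
   `w_j = d_j / Σ_j d_j` and `B_j` is the mean over experts.
3. **Entropy weights**: with shares `P_ij = y_ij / Σ_i y_ij` and
   entropy `E_j = −(1/ln n) Σ_i P_ij ln P_ij`, the objective weight is
   `A_j = (1 − E_j)/(m − Σ_j E_j)` — dispersed indicators carry more
   information and more weight.
4. **Combined weights**: `W_j = A_j B_j / Σ_j A_j B_j`, decomposed into
   dimension weights `W_d = Σ_{j∈d} W_j` and within-dimension weights
   `W_j / W_d`.
5. **Scoring**: dimension score `s_d = Σ_{j∈d} (W_j/W_d) y_j`,
   composite `C = Σ_d W_d s_d`, with descending competition ranking
   ("1, 2, 2, 4") at 3-decimal precision.
6. **Regional inference**: one-way fixed-effects ANOVA of each score
   column across the three belts (`*` p < 0.05, `**` p < 0.01).
7. **Obstacle diagnosis**: the shortfall share
   `P_ij = (1 − y_ij) W_j / Σ_k (1 − y_ik) W_k × 100%` identifies the
   indicators that most restrict each region; degrees sum to 100% per
   region-year.
8. **Pharmacovigilance descriptives**: national ADR-report trends,
   serious-report shares and clinical-trial approval pass rates.

A synthetic-data module generates study-shaped panels (31 regions in a
12/9/10 belt split, 14 indicators, 2018–2022, 7 experts) from a latent
capacity model with a controllable belt gap, so the whole pipeline is
testable end to end, including power and type-I calibration of the
regional ANOVA.

## Worked example

The package bundles the published 2022 reference table of provincial
dimension scores together with the frozen two-level weight system
(dimension weights 0.153, 0.218, 0.289, 0.210, 0.130):

```python
import regcap as rc
from regcap.datasets import load_indicator_schema, load_provincial_scores_2022
from regcap._util import round_half_up

schema = load_indicator_schema()
weights = rc.WeightSet.from_schema(schema)
ref = load_provincial_scores_2022()

dims = ref.set_index("region")[schema.dimension_ids].astype(float)
composite = rc.composite_scores(dims, weights)
ranks = rc.rank_regions(composite)
for region in ("Jiangsu", "Beijing", "Zhejiang", "Shanghai", "Xinjiang"):
    print(f"{region:10s} composite={round_half_up(composite[region], 3):.3f} "
          f"rank={ranks[region]}")

print("national mean:", round_half_up(float(ref["composite"].mean()), 3))
print("above average:", rc.count_above_mean(ref["composite"], decimals=3))

frame = ref.assign(category=ref["category"].map(lambda c: c.value))
print(rc.anova_table(frame, ["composite", "resource_acquisition"])
      [["column", "F", "p", "stars"]].to_string(index=False))
```

prints

```
Jiangsu    composite=0.204 rank=1
Beijing    composite=0.172 rank=2
Zhejiang   composite=0.172 rank=2
Shanghai   composite=0.162 rank=4
Xinjiang   composite=0.038 rank=31
national mean: 0.113
above average: 13
              column        F        p stars
           composite 3.632093 0.039586     *
resource_acquisition 7.896933 0.001907    **
```

Jiangsu leads the 2022 composite; Beijing and Zhejiang tie at rank 2
(competition ranking skips to 4). Thirteen provinces sit above the
national average of 0.113 when compared at the table's 3-decimal
precision. The belts differ significantly in the composite (p < 0.05)
and strongly in resource acquisition (p < 0.01).

The same classes drive full raw-panel runs — see `regcap run --config
run.yaml`, or the stagewise subcommands `simulate / normalize / weights
/ score / anova / obstacles / vigilance` (`regcap --help`).

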