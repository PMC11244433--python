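# traitpart

Partition plant functional-trait variation into its intraspecific and
interspecific components, within and among communities, and decompose
treatment-induced trait variability into interspecific, intraspecific and
covariation effects.

`traitpart` is aimed at community ecologists running manipulative field
experiments (nutrient addition, warming, grazing) who measure individual-level
traits — e.g. plant height H (cm), leaf area LA (cm²), leaf dry matter content
LDMC (g g⁻¹), specific leaf area SLA (m² kg⁻¹) — across a treatment gradient
and want to know *how much of the community response comes from species
turnover versus within-species trait shifts*.

## The indices

Within a community (plot) with S measured species, relative biomasses `a_i`,
individuals `x_ji` and local species means `x̄_i`:

```
wITV_intra = Σ_i a_i · (1/N_i) Σ_j (x_ji − x̄_i)²        weighted mean within-species variance
wITV_inter = Σ_i a_i · (x̄_i − CWM)²,   CWM = Σ_i a_i x̄_i  weighted variance of species means
```

Their sum is the abundance-weighted total variance of individuals around the
CWM (law of total variance), which the test suite asserts.

Among communities, each plot's trait mean is split into components, under both
biomass weighting (CWM) and equal species weights (CM):

```
CWM_specific = Σ_i a_i x̄_i          local species means (full signal)
CWM_fixed    = Σ_i a_i x̄avg_i       grand species means (composition signal only)
CWM_intra    = CWM_specific − CWM_fixed   within-species shifts
CM_*         = the same with a_i = 1/S
```

where `x̄avg_i` pools all measured individuals of species i across all plots.
Running a one-way ANOVA of each component series against the treatment factor
and subtracting sums of squares gives the decomposition

```
SS_specific = SS_fixed + SS_intra + SS_cov
```

per stratum (between-treatment, within-treatment, total). The covariation term
is positive when species turnover and within-species shifts push community
traits the same way, negative when they oppose. Treatment effects on every
index are tested with one-way ANOVA plus Tukey–Kramer HSD and summarised as
compact letter displays.

A bundled synthetic-community generator emulates a nitrogen-addition design
(5 levels CK, N2.5, N5, N10, N20 × 4 replicate plots, 6 species, ~8
individuals per species per plot, optional species loss at high N, ANPP linear
in the true community trait means) with known ground truth, so the whole
pipeline can be validated by parameter recovery.

## Worked example

```
$ traitpart run --preset paper-like --seed 1 --out out/
```

or, step by step, the scripts under `analysis/` (each writes its tables under
`results/`):

```
$ python analysis/01_simulate_communities.py 1
simulated 20 plots, 928 individuals (seed 1)
species richness per plot: min 5 (high-N loss), max 6

$ python analysis/02_within_community_indices.py
treatment effect on within-community indices (ANOVA):
  witv_inter  H     F= 53.25  p=0.0000 *
  witv_inter  LA    F= 20.41  p=0.0000 *
  witv_intra  H     F=  1.41  p=0.2785 -
  witv_intra  SLA   F=  2.09  p=0.1334 -
  ...
```

In this simulated gradient, N addition reshapes the *interspecific* spread of
trait values inside plots (taller grasses take over, so the weighted variance
of species means in H rises strongly: F = 53.25) but leaves the *intraspecific*
within-plot variance untouched (all p > 0.13) — individual noise does not
respond to treatment in the generator, and the test correctly says so.

```
$ python analysis/04_variance_decomposition.py
percent of total specific SS explained by N addition:
trait scheme  percent_fixed  percent_intra  percent_cov
    H    CWM          52.83           7.37        39.24
    H     CM          13.58          45.20        35.22
 LDMC    CWM           9.49          93.84       -37.41
  ...
ANPP ~ N level: F = 0.57, p = 0.6913
```

Read: for height under biomass weighting, 52.8 % of the total variability of
the specific community mean is treatment-driven species turnover, 7.4 % is
within-species height shifts, and a positive covariation of 39.2 % means both
channels pushed community height the same way. Percentages can exceed 100 or be
negative because the covariation term is a signed cross-product. The
`decomposition_{cwm,cm}.png` figures show the same numbers as stacked bars with
the total drawn as a marker, the gap being the covariation.

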