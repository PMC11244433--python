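# Methods

## Scope and data model

`traitpart` analyses individual-level functional-trait measurements from
replicated community plots arranged along a categorical treatment gradient.
Three tidy CSV tables are the only inputs: individual trait measurements
(plot, treatment, species, individual, one numeric column per trait),
community composition (plot, species, relative biomass) and plot metadata
(plot, treatment, optional ANPP in g m⁻²). Trait values must be finite and
strictly positive; abundances are always re-normalised to unit sum per plot,
so raw biomass may be supplied.

Species present in a plot's composition but never measured there are excluded
from that plot's indices and the remaining abundances re-normalised (field
protocols typically measure the species covering >90 % cumulative abundance,
so indices describe the measured subset). A flag (`renormalize_unmeasured`)
disables the renormalisation for sensitivity checks. All such findings are
routed into a validation report; cross-table reference failures abort the
pipeline, warnings never do.

## Within-community indices

For each plot and trait the package computes the abundance-weighted mean
within-species variance (wITV_intra) and the abundance-weighted variance of
species means around the community weighted mean (wITV_inter). The
within-species variance uses the population divisor N_i rather than N_i − 1:
the index is a plug-in, descriptive decomposition of the realised community
variance, and with the population divisor the two indices sum exactly to the
weighted total variance of individuals around the CWM. A `ddof=1` switch
exists for users who prefer unbiased per-species variances, at the cost of
that exact additivity. Species with one measured individual contribute zero to
wITV_intra rather than being dropped — the index is well defined at N_i = 1
and dropping them would silently re-weight the community.

Both indices are invariant to species relabelling and individual order,
unchanged by adding a constant to all measurements, and scale as c² when
measurements are scaled by c; these properties are asserted by the test suite.

## Among-community components

Each plot's community mean is decomposed under two weighting schemes. The
*specific* mean uses plot-local species means; the *fixed* mean replaces them
with grand species means pooled over **all measured individuals in all
plots** (not a mean of plot means — with unbalanced sampling the two differ,
and pooling is the declared definition); *intra* is their difference. CWM
weights species by relative biomass; CM gives every species present equal
weight 1/S, so it responds to presence/absence only.

The equal-weight fixed component divides by the number of species S, making it
the unweighted mean over the species present and keeping CM_intra a difference
of means on trait scale. Without the divisor CM_intra would absorb a spurious
species-richness term whenever S varies between plots (as it does under
species loss); the divisor-free literal sum remains available behind
`cm_fixed_divisor=False` for exact-replication attempts against legacy
analyses.

## Treatment tests and SS decomposition

One-way fixed-effects ANOVA is computed from textbook sums of squares with
p-values from the F distribution; Tukey–Kramer HSD uses the studentized-range
distribution with pooled within-group variance and the Kramer correction
`se = sqrt((MSW/2)(1/n_a + 1/n_b))` for unbalanced groups. Both are authored
in-package and cross-checked in the test suite against scipy's independent
implementations on hundreds of random layouts (F and p to 1e-8 relative,
Tukey p to 1e-6; for two groups the Tukey p equals the ANOVA p analytically).
Degenerate inputs are flagged, not fatal: zero residual variance with a real
group difference reports F = ∞, p = 0; fully constant data reports F = 0,
p = 1. Letter groups use the insert-and-absorb algorithm ordered by descending
group means; the sharing-iff-nonsignificant property is re-verified before the
display is returned, so an inconsistent display cannot escape. α defaults to
0.05, and no multiple-testing correction is applied across traits or index
families — each (index, trait) test is reported marginally, as is standard for
this kind of trait screen.

The decomposition runs the treatment ANOVA separately on the per-plot
specific, fixed and intra series and closes the identity
SS_cov = SS_specific − SS_fixed − SS_intra in each stratum; by construction
the identity is exact to machine precision for arbitrary inputs. Contribution
percentages put the between-treatment SS of each component over a denominator
that defaults to the **total** SS of the specific series — so the three
percentages sum to the treatment-explained share of total variability, and
can individually exceed 100 % or go negative because the covariation is a
signed cross-product. The alternative `denominator="explained"` (between-
treatment specific SS) makes them sum to exactly 100 and is what the
parameter-recovery tests use when they ask "which channel carries the
explained signal". No significance test is attached to the covariation term;
stars belong to the three component ANOVAs only.

## Synthetic communities

The generator targets the statistical structure of a nitrogen-addition
grassland experiment, not plant physiology. Defaults mirror the emulated
design: 5 treatments (CK, N2.5, N5, N10, N20) × 4 replicate plots, 6 species,
8 individuals per species per plot (≈ 900 individuals), four traits on field
measurement scales. Two response channels are configured independently per
species and treatment: multiplicative abundance responses (composition
turnover — the interspecific channel) and additive trait-mean shifts
(plasticity — the intraspecific channel). Individual measurements add
Gaussian noise (SDs roughly 5–12 % of base means in the presets, a typical
within-population coefficient of variation for these traits) and are clipped
from below at 1 % of the species base mean to keep traits positive; clips are
counted in the ground truth. Gaussianity is a modelling choice — the noise
distribution is not otherwise constrained — and is exposed in the config.

Species loss is modelled as omission from both composition and trait tables
when a species' relative abundance falls below a threshold (0.02 in the
paper-like preset), so realised richness S varies across the gradient.
ANPP is a linear function of the plot's *true* (noise-free) biomass-weighted
trait means plus Gaussian noise, floored at zero; with zero noise the
configured coefficients are recoverable by least squares to 1e-8, which the
tests verify.

Randomness is hierarchical: every (plot, species) pair draws from a stream
seeded by `(global seed, plot index, crc32(species name))`, so adding or
removing a species never perturbs another species' draws, and the whole
dataset is bit-reproducible from the seed. Abundances are deterministic given
the config; an optional Dirichlet concentration adds replicate-level
composition jitter.

Presets: `composition-only` (turnover, no shifts), `plasticity-only` (shifts,
no turnover), `mixed-positive-cov` / `mixed-negative-cov` (turnover toward
high-trait species combined with upward / downward shifts; species base means
are co-monotone across traits so the designed covariation sign is unambiguous
for every trait), and `paper-like` (the realistic six-species design above).
In the pure scenarios with vanishing noise the pipeline attributes >99 % of
the explained CWM variation to the designed channel; the mixed presets
recover the designed covariation sign in ≥95 of 100 seeds at default noise.
These recovery checks are what passing tests certify — they certify the
*pipeline arithmetic*, not that real field data meet the generator's
assumptions (independent Gaussian individuals, additive shifts, deterministic
composition), which real communities generally will not.

## Problem sizes and numerics

The test suite validates the index formulas against naive double-loop oracles
on 500 random small communities (≤5 species, ≤6 individuals) at 1e-10,
decomposition identities on 200 random datasets at 1e-12, and the ANOVA/Tukey
machinery on 200 random layouts against scipy. The end-to-end determinism
check and the acceptance script use the 20-plot paper-like design; a full
pipeline run takes a few seconds on one core. Ties, empty groups and
single-treatment inputs raise explicit errors; all error paths are exercised
by tests.

## Known limitations

- Only one treatment factor (one-way layouts); no blocking, repeated measures
  or mixed models.
- The decomposition assigns no uncertainty to SS_cov and no test is attached
  to it.
- wITV values are analysed untransformed by default (variances are often
  right-skewed); `log_transform_witv` applies log1p before the ANOVAs.
- The generator does not simulate mechanistic growth or N cycling, and its
  ANPP model is intentionally a plain linear map from true community means.
- Random-forest style variable-importance screening of ANPP drivers is out of
  scope; the per-plot index tables written by the pipeline are the natural
  input if users want to run one themselves.
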