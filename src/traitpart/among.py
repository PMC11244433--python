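"""Community trait means and their specific / fixed / intraspecific parts.

Two weighting schemes per plot and trait:

* **CWM** (community weighted mean) — species weighted by relative
  biomass ``a_i``:

  - specific: ``sum_i a_i * xbar_i`` with ``xbar_i`` the plot-local
    species mean,
  - fixed: ``sum_i a_i * xavg_i`` with ``xavg_i`` the species grand mean
    pooled over all measured individuals in all plots,
  - intra: ``specific - fixed``.

* **CM** (non-weighted mean) — every species present counts equally:
  ``specific = mean_i xbar_i``, ``fixed = mean_i xavg_i``,
  ``intra = specific - fixed``.

The fixed component tracks species-composition change only (each
species carries one global trait value); the intra component is the
abundance-weighted average departure of local species means from their
grand means, i.e. within-species trait shifts among communities.
``cm_fixed_divisor=False`` gives the plain sum over species for the CM
fixed component instead of the mean (an exact-replication switch; it
adds a species-richness term to CM_intra and is not the default).
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .datamodel import BIOMASS, PLOT, SPECIES, normalize_abundances
from .within import melt_traits, species_plot_stats

__all__ = ["grand_species_means", "community_trait_means",
           "cwm_components", "cm_components"]

SCHEMES = ("CWM", "CM")


def grand_species_means(traits: pd.DataFrame,
                        traits_list: Sequence[str] | None = None) -> pd.DataFrame:
    """Pooled grand mean per (species, trait) over all measured individuals.

    This is the mean over individuals pooled across every plot and
    treatment — not a mean of per-plot means, so plots with more
    individuals weigh more when sampling is unbalanced.
    """
    long = melt_traits(traits, traits_list)
    out = (long.groupby([SPECIES, "trait"], sort=True)["value"]
           .mean().rename("grand_mean").reset_index())
    return out


def _components_frame(stats: pd.DataFrame, comp: pd.DataFrame | None,
                      grand: pd.DataFrame,
                      cm_fixed_divisor: bool = True) -> pd.DataFrame:
    merged = stats.merge(grand, on=[SPECIES, "trait"], how="left")
    if merged["grand_mean"].isna().any():
        bad = merged.loc[merged["grand_mean"].isna(), SPECIES].unique().tolist()
        raise KeyError(f"species missing from grand means: {bad}")

    frames = []
    if comp is not None:
        w = merged.merge(comp[[PLOT, SPECIES, BIOMASS]],
                         on=[PLOT, SPECIES], how="left")
        if w[BIOMASS].isna().any():
            bad = w.loc[w[BIOMASS].isna(), [PLOT, SPECIES]].drop_duplicates()
            raise KeyError("species without composition row: "
                           f"{bad.to_records(index=False).tolist()}")
        totals = w.groupby([PLOT, "trait"])[BIOMASS].transform("sum")
        w["a"] = w[BIOMASS] / totals
        g = w.groupby([PLOT, "trait"], sort=True)
        cwm = pd.DataFrame({
            "specific": g.apply(lambda d: (d["a"] * d["mean"]).sum(),
                                include_groups=False),
            "fixed": g.apply(lambda d: (d["a"] * d["grand_mean"]).sum(),
                             include_groups=False),
        }).reset_index()
        cwm["scheme"] = "CWM"
        frames.append(cwm)

    g = merged.groupby([PLOT, "trait"], sort=True)
    cm = pd.DataFrame({
        "specific": g["mean"].mean(),
        "fixed": g["grand_mean"].mean() if cm_fixed_divisor
        else g["grand_mean"].sum(),
    }).reset_index()
    cm["scheme"] = "CM"
    frames.append(cm)

    out = pd.concat(frames, ignore_index=True)
    out["intra"] = out["specific"] - out["fixed"]
    return out[[PLOT, "trait", "scheme", "specific", "fixed", "intra"]]


def community_trait_means(traits: pd.DataFrame, comp: pd.DataFrame,
                          traits_list: Sequence[str] | None = None,
                          cm_fixed_divisor: bool = True) -> pd.DataFrame:
    """Specific, fixed and intra components per plot, trait and scheme.

    Returns a tidy frame with columns ``plot_id``, ``trait``, ``scheme``
    (CWM or CM), ``specific``, ``fixed``, ``intra``; the identity
    ``intra == specific - fixed`` holds to machine precision.
    """
    stats = species_plot_stats(traits, traits_list)
    grand = grand_species_means(traits, traits_list)
    comp = normalize_abundances(comp)
    return _components_frame(stats, comp, grand, cm_fixed_divisor)


def cwm_components(stats: pd.DataFrame, comp: pd.DataFrame,
                   grand: pd.DataFrame, plot, trait) -> tuple[float, float, float]:
    """(specific, fixed, intra) under biomass weighting for one plot/trait."""
    frame = _components_frame(stats[stats["trait"] == trait],
                              normalize_abundances(comp), grand)
    sel = frame[(frame[PLOT] == plot) & (frame["scheme"] == "CWM")]
    if sel.empty:
        raise KeyError(f"no data for plot {plot!r}, trait {trait!r}")
    row = sel.iloc[0]
    return float(row["specific"]), float(row["fixed"]), float(row["intra"])


def cm_components(stats: pd.DataFrame, grand: pd.DataFrame, plot, trait,
                  cm_fixed_divisor: bool = True) -> tuple[float, float, float]:
    """(specific, fixed, intra) with equal species weights for one plot/trait."""
    sub = stats[(stats["trait"] == trait) & (stats[PLOT] == plot)]
    if sub.empty:
        raise KeyError(f"no data for plot {plot!r}, trait {trait!r}")
    frame = _components_frame(sub, None, grand, cm_fixed_divisor)
    row = frame.iloc[0]
    return float(row["specific"]), float(row["fixed"]), float(row["intra"])
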