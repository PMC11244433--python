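"""Abundance-weighted trait-variation indices within a community.

For a plot with S measured species, relative biomasses ``a_i`` and trait
values ``x_ji`` (individual j of species i, species mean ``xbar_i``):

.. math::

    wITV_{intra} = \\sum_i a_i \\cdot \\frac{1}{N_i} \\sum_j (x_{ji} - \\bar x_i)^2

    wITV_{inter} = \\sum_i a_i (\\bar x_i - CWM)^2,
    \\qquad CWM = \\sum_i a_i \\bar x_i

i.e. the abundance-weighted mean within-species variance and the
abundance-weighted variance of species means around the community
weighted mean.  Both are in squared trait units; smaller values mean
stronger convergence.  Their sum equals the abundance-weighted total
variance of individuals around the CWM (law of total variance under
these weights), which the test-suite asserts.

The within-species variance uses the population divisor ``N_i`` (not
``N_i - 1``); ``ddof=1`` is available but non-default.  Species with a
single individual contribute 0 to ``wITV_intra``.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .datamodel import (BIOMASS, PLOT, SPECIES, TREATMENT,
                        normalize_abundances, trait_columns)

__all__ = ["species_plot_stats", "within_community_indices",
           "witv_intra", "witv_inter"]


def melt_traits(traits: pd.DataFrame,
                traits_list: Sequence[str] | None = None) -> pd.DataFrame:
    """Long form of a trait table: one row per (individual, trait)."""
    cols = list(traits_list) if traits_list is not None else trait_columns(traits)
    id_cols = [c for c in (PLOT, TREATMENT, SPECIES) if c in traits.columns]
    return traits.melt(id_vars=id_cols, value_vars=cols,
                       var_name="trait", value_name="value")


def species_plot_stats(traits: pd.DataFrame,
                       traits_list: Sequence[str] | None = None,
                       ddof: int = 0) -> pd.DataFrame:
    """Per (plot, species, trait): individual count, mean and variance.

    ``ddof=0`` gives the population variance (divisor N_i); with
    ``ddof=1`` single-individual species get variance 0 by convention.
    """
    long = melt_traits(traits, traits_list)
    grouped = long.groupby([PLOT, SPECIES, "trait"], sort=True)["value"]
    stats = grouped.agg(n_individuals="count", mean="mean",
                        variance=lambda v: v.var(ddof=ddof)).reset_index()
    stats["variance"] = stats["variance"].fillna(0.0)
    return stats


def _weighted(stats: pd.DataFrame, comp: pd.DataFrame) -> pd.DataFrame:
    """Attach abundances to stats, renormalised per plot over the species
    actually present in ``stats`` (defensive: a no-op for already matching,
    unit-sum compositions)."""
    merged = stats.merge(comp[[PLOT, SPECIES, BIOMASS]],
                         on=[PLOT, SPECIES], how="left")
    if merged[BIOMASS].isna().any():
        missing = merged.loc[merged[BIOMASS].isna(), [PLOT, SPECIES]]
        raise KeyError("species without composition row: "
                       f"{missing.drop_duplicates().to_records(index=False).tolist()}")
    merged = merged.rename(columns={BIOMASS: "a"})
    totals = merged.groupby([PLOT, "trait"])["a"].transform("sum")
    merged["a"] = merged["a"] / totals
    return merged


def within_community_indices(traits: pd.DataFrame, comp: pd.DataFrame,
                             traits_list: Sequence[str] | None = None,
                             ddof: int = 0) -> pd.DataFrame:
    """wITV_intra and wITV_inter for every plot and trait.

    Returns a tidy frame with columns ``plot_id``, ``trait``,
    ``witv_intra``, ``witv_inter``.
    """
    stats = species_plot_stats(traits, traits_list, ddof=ddof)
    w = _weighted(stats, normalize_abundances(comp))
    w["aw_var"] = w["a"] * w["variance"]
    w["aw_mean"] = w["a"] * w["mean"]
    per_plot = w.groupby([PLOT, "trait"], sort=True)
    cwm = per_plot["aw_mean"].sum().rename("cwm")
    intra = per_plot["aw_var"].sum().rename("witv_intra")
    w = w.merge(cwm, on=[PLOT, "trait"])
    w["aw_dev2"] = w["a"] * (w["mean"] - w["cwm"]) ** 2
    inter = w.groupby([PLOT, "trait"], sort=True)["aw_dev2"].sum().rename("witv_inter")
    out = pd.concat([intra, inter], axis=1).reset_index()
    return out


def _plot_value(indices: pd.DataFrame, plot, trait, column: str) -> float:
    sel = indices[(indices[PLOT] == plot) & (indices["trait"] == trait)]
    if sel.empty:
        raise KeyError(f"no data for plot {plot!r}, trait {trait!r}")
    return float(sel[column].iloc[0])


def witv_intra(stats: pd.DataFrame, comp: pd.DataFrame, plot, trait) -> float:
    """Abundance-weighted mean within-species variance for one plot/trait."""
    w = _weighted(stats[stats["trait"] == trait], normalize_abundances(comp))
    w = w[w[PLOT] == plot]
    if w.empty:
        raise KeyError(f"no data for plot {plot!r}, trait {trait!r}")
    return float((w["a"] * w["variance"]).sum())


def witv_inter(stats: pd.DataFrame, comp: pd.DataFrame, plot, trait) -> float:
    """Abundance-weighted variance of species means around the CWM."""
    w = _weighted(stats[stats["trait"] == trait], normalize_abundances(comp))
    w = w[w[PLOT] == plot]
    if w.empty:
        raise KeyError(f"no data for plot {plot!r}, trait {trait!r}")
    cwm = float((w["a"] * w["mean"]).sum())
    return float((w["a"] * (w["mean"] - cwm) ** 2).sum())
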