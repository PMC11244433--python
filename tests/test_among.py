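import numpy as np
import pandas as pd
import pytest

from traitpart import (cm_components, community_trait_means, cwm_components,
                       grand_species_means, species_plot_stats)
from tests.conftest import make_tables


def dataset(plot_values, abundances):
    """plot_values: {plot: {species: [values]}}; abundances: {plot: {sp: a}}."""
    rows, comp_rows = [], []
    for plot, by_sp in plot_values.items():
        for s, vals in by_sp.items():
            for j, v in enumerate(vals):
                rows.append({"plot_id": plot, "treatment": "T1",
                             "species_id": s, "individual_id": f"{s}-{j}",
                             "H": float(v)})
    for plot, by_sp in abundances.items():
        for s, a in by_sp.items():
            comp_rows.append({"plot_id": plot, "species_id": s,
                              "relative_biomass": a})
    return pd.DataFrame(rows), pd.DataFrame(comp_rows)


class TestGrandSpeciesMeans:
    def test_pooled_over_individuals(self):
        traits, _ = dataset({"P1": {"A": [2]}, "P2": {"A": [4]}},
                            {"P1": {"A": 1.0}, "P2": {"A": 1.0}})
        grand = grand_species_means(traits)
        assert grand["grand_mean"].iloc[0] == 3.0

    def test_unbalanced_pooling_is_not_mean_of_means(self):
        traits, _ = dataset({"P1": {"A": [2, 2]}, "P2": {"A": [5]}},
                            {"P1": {"A": 1.0}, "P2": {"A": 1.0}})
        grand = grand_species_means(traits)
        assert grand["grand_mean"].iloc[0] == pytest.approx(3.0)  # not 3.25

    def test_single_plot_species(self):
        traits, _ = dataset({"P1": {"A": [1, 5]}}, {"P1": {"A": 1.0}})
        assert grand_species_means(traits)["grand_mean"].iloc[0] == 3.0


class TestComponents:
    def test_cwm_hand_example(self):
        # a=(0.25,0.75), plot means (2,4), grand means (3,3)
        traits, comp = dataset(
            {"P1": {"A": [2], "B": [4]}, "P2": {"A": [4], "B": [2]}},
            {"P1": {"A": 0.25, "B": 0.75}, "P2": {"A": 0.5, "B": 0.5}})
        stats = species_plot_stats(traits)
        grand = grand_species_means(traits)
        specific, fixed, intra = cwm_components(stats, comp, grand, "P1", "H")
        assert specific == pytest.approx(3.5)
        assert fixed == pytest.approx(3.0)
        assert intra == pytest.approx(0.5)

    def test_cm_hand_example(self):
        # plot means (2,4), grand means (3,5) -> specific 3, fixed 4, intra -1
        traits, comp = dataset(
            {"P1": {"A": [2], "B": [4]}, "P2": {"A": [4], "B": [6]}},
            {"P1": {"A": 0.5, "B": 0.5}, "P2": {"A": 0.5, "B": 0.5}})
        stats = species_plot_stats(traits)
        grand = grand_species_means(traits)
        specific, fixed, intra = cm_components(stats, grand, "P1", "H")
        assert (specific, fixed, intra) == pytest.approx((3.0, 4.0, -1.0))

    def test_single_species_plot(self):
        traits, comp = dataset({"P1": {"A": [2]}, "P2": {"A": [6]}},
                               {"P1": {"A": 1.0}, "P2": {"A": 1.0}})
        stats = species_plot_stats(traits)
        grand = grand_species_means(traits)
        cwm = cwm_components(stats, comp, grand, "P1", "H")
        cm = cm_components(stats, grand, "P1", "H")
        assert cwm == pytest.approx((2.0, 4.0, -2.0))
        assert cm == pytest.approx(cwm)

    def test_equal_abundances_collapse_cm_to_cwm(self):
        traits, comp = dataset(
            {"P1": {"A": [1, 3], "B": [4, 8]}},
            {"P1": {"A": 0.5, "B": 0.5}})
        means = community_trait_means(traits, comp)
        piv = means.set_index("scheme")
        assert piv.loc["CM", "specific"] == pytest.approx(
            piv.loc["CWM", "specific"], abs=1e-12)

    def test_literal_cm_fixed_form(self):
        """The divisor-free variant returns the plain sum over species."""
        traits, comp = dataset(
            {"P1": {"A": [2], "B": [4]}}, {"P1": {"A": 0.5, "B": 0.5}})
        means = community_trait_means(traits, comp, cm_fixed_divisor=False)
        cm = means[means["scheme"] == "CM"].iloc[0]
        assert cm["fixed"] == pytest.approx(6.0)  # 2 + 4, no 1/S

    def test_unknown_species_in_grand_means_raises(self):
        traits, comp = dataset({"P1": {"A": [2]}}, {"P1": {"A": 1.0}})
        stats = species_plot_stats(traits)
        grand = grand_species_means(traits)
        grand = grand[grand["species_id"] != "A"]
        with pytest.raises(KeyError):
            cwm_components(stats, comp, grand, "P1", "H")


def test_intra_is_specific_minus_fixed_exactly():
    rng = np.random.default_rng(42)
    for _ in range(20):
        traits, comp, _ = make_tables(rng, n_plots=3)
        means = community_trait_means(traits, comp)
        np.testing.assert_allclose(
            means["intra"], means["specific"] - means["fixed"], atol=1e-12)


def test_cm_depends_only_on_species_presence():
    """Permuting a plot's abundances changes CWM but never CM."""
    traits, comp = dataset(
        {"P1": {"A": [1, 2], "B": [5, 7], "C": [9, 11]},
         "P2": {"A": [2, 3], "B": [6, 6], "C": [8, 12]}},
        {"P1": {"A": 0.6, "B": 0.3, "C": 0.1},
         "P2": {"A": 0.2, "B": 0.5, "C": 0.3}})
    base = community_trait_means(traits, comp)
    permuted = comp.copy()
    mask = permuted["plot_id"] == "P1"
    permuted.loc[mask, "relative_biomass"] = [0.1, 0.6, 0.3]
    out = community_trait_means(traits, permuted)
    cm_cols = ["specific", "fixed", "intra"]
    np.testing.assert_allclose(
        out[out["scheme"] == "CM"][cm_cols],
        base[base["scheme"] == "CM"][cm_cols], atol=1e-12)
    assert not np.allclose(
        out[(out["scheme"] == "CWM") & (out["plot_id"] == "P1")][cm_cols],
        base[(base["scheme"] == "CWM") & (base["plot_id"] == "P1")][cm_cols])


def test_identical_composition_gives_constant_fixed_components():
    """Same species sets and abundances everywhere -> fixed is flat."""
    traits, comp = dataset(
        {"P1": {"A": [1, 3], "B": [6, 8]}, "P2": {"A": [4, 4], "B": [5, 9]}},
        {"P1": {"A": 0.3, "B": 0.7}, "P2": {"A": 0.3, "B": 0.7}})
    means = community_trait_means(traits, comp)
    for scheme in ("CWM", "CM"):
        fixed = means[means["scheme"] == scheme]["fixed"]
        assert fixed.nunique() == 1 or np.ptp(fixed.to_numpy()) < 1e-12


def test_oracle_equivalence_naive_loops():
    """Vectorised components match a per-species summation loop."""
    rng = np.random.default_rng(7)
    for _ in range(30):
        traits, comp, _ = make_tables(rng, n_plots=3)
        means = community_trait_means(traits, comp)
        # naive recomputation
        grand = {}
        for (s, t), d in traits.melt(
                id_vars=["plot_id", "treatment", "species_id", "individual_id"],
                var_name="trait").groupby(["species_id", "trait"]):
            grand[(s, t)] = d["value"].mean()
        for _, row in means.iterrows():
            plot, trait, scheme = row["plot_id"], row["trait"], row["scheme"]
            sub = traits[traits["plot_id"] == plot]
            species = sorted(sub["species_id"].unique())
            local = {s: sub.loc[sub["species_id"] == s, trait].mean()
                     for s in species}
            if scheme == "CWM":
                w = comp[comp["plot_id"] == plot].set_index("species_id")
                w = w.loc[species, "relative_biomass"]
                w = w / w.sum()
                spec = sum(w[s] * local[s] for s in species)
                fix = sum(w[s] * grand[(s, trait)] for s in species)
            else:
                spec = np.mean([local[s] for s in species])
                fix = np.mean([grand[(s, trait)] for s in species])
            assert row["specific"] == pytest.approx(spec, abs=1e-10)
            assert row["fixed"] == pytest.approx(fix, abs=1e-10)
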