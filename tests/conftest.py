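import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")


def make_tables(rng: np.random.Generator, n_plots=2, max_species=5,
                max_individuals=6, traits=("H", "LA")):
    """Small random trait/composition/plot tables for oracle checks."""
    trait_rows, comp_rows, plot_rows = [], [], []
    species_pool = [f"sp{i}" for i in range(1, max_species + 1)]
    for p in range(n_plots):
        plot = f"P{p + 1}"
        treatment = f"T{p % 2 + 1}"
        plot_rows.append({"plot_id": plot, "treatment": treatment})
        n_sp = int(rng.integers(1, max_species + 1))
        chosen = rng.choice(species_pool, size=n_sp, replace=False)
        weights = rng.uniform(0.2, 2.0, n_sp)
        for s, w in zip(chosen, weights):
            comp_rows.append({"plot_id": plot, "species_id": s,
                              "relative_biomass": float(w)})
            n_ind = int(rng.integers(1, max_individuals + 1))
            for j in range(n_ind):
                row = {"plot_id": plot, "treatment": treatment,
                       "species_id": s, "individual_id": f"{s}-{j}"}
                for t in traits:
                    row[t] = float(rng.uniform(0.5, 10.0))
                trait_rows.append(row)
    return (pd.DataFrame(trait_rows), pd.DataFrame(comp_rows),
            pd.DataFrame(plot_rows))


@pytest.fixture
def tiny_tables():
    """Two plots, two species, hand-enterable values."""
    traits = pd.DataFrame({
        "plot_id": ["P1"] * 4 + ["P2"] * 4,
        "treatment": ["T1"] * 4 + ["T2"] * 4,
        "species_id": ["A", "A", "B", "B"] * 2,
        "individual_id": ["a1", "a2", "b1", "b2"] * 2,
        "H": [1.0, 3.0, 2.0, 4.0, 2.0, 2.0, 5.0, 5.0],
    })
    comp = pd.DataFrame({
        "plot_id": ["P1", "P1", "P2", "P2"],
        "species_id": ["A", "B", "A", "B"],
        "relative_biomass": [0.5, 0.5, 0.25, 0.75],
    })
    plots = pd.DataFrame({"plot_id": ["P1", "P2"],
                          "treatment": ["T1", "T2"]})
    return traits, comp, plots
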