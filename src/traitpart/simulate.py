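"""Synthetic alpine-meadow communities with known variance structure.

The generator emulates a nitrogen-addition field design: ``n_treatments``
levels (default CK, N2.5, N5, N10, N20 — 0 to 20 g N m^-2 yr^-1) with
``n_replicates`` plots each, a fixed species pool with per-trait base
means and base abundances, and two treatment-response channels:

* **composition turnover** — per-species abundance multipliers per
  treatment (interspecific channel; drives the fixed component),
* **trait plasticity** — per-species additive trait shifts per treatment
  (intraspecific channel; drives the intra component),

plus Gaussian individual noise, optional species loss below a relative-
abundance threshold, optional Dirichlet replicate jitter, and an ANPP
that is linear in the plot's true (noise-free) biomass-weighted trait
means.  The ground truth returned alongside the tables holds the
realised abundances, the true species means and the implied true
community-mean components, so recovery tests know the right answer.

Randomness is hierarchical: each (plot, species) pair owns a stream
keyed by the global seed, the plot index and a stable hash of the
species name, so adding or removing a species never perturbs the draws
of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .datamodel import ANPP, BIOMASS, INDIVIDUAL, PLOT, SPECIES, TREATMENT

__all__ = ["AnppModel", "SpeciesProfile", "SyntheticConfig", "GroundTruth",
           "generate_dataset", "scenario_presets", "PRESETS"]

DEFAULT_TREATMENTS = ("CK", "N2.5", "N5", "N10", "N20")

#: clip individual draws at this fraction of the species base mean so
#: traits stay strictly positive
POSITIVITY_FLOOR = 0.01


@dataclass(frozen=True)
class AnppModel:
    """ANPP = intercept + sum_t coefficient_t * true CWM_specific_t + noise."""
    intercept: float
    coefficients: Mapping[str, float]
    noise_sd: float = 0.0


@dataclass(frozen=True)
class SpeciesProfile:
    """One species' base state and treatment responses.

    ``abundance_multipliers`` and ``trait_shifts`` are keyed by
    treatment label; missing treatments default to multiplier 1 and
    shift 0 (no response).
    """
    base_means: Mapping[str, float]
    base_abundance: float
    abundance_multipliers: Mapping[str, float] = field(default_factory=dict)
    trait_shifts: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def multiplier(self, treatment: str) -> float:
        return float(self.abundance_multipliers.get(treatment, 1.0))

    def shift(self, treatment: str, trait: str) -> float:
        return float(self.trait_shifts.get(treatment, {}).get(trait, 0.0))


@dataclass(frozen=True)
class SyntheticConfig:
    species: Mapping[str, SpeciesProfile]
    noise_sd: Mapping[str, float]
    treatments: tuple[str, ...] = DEFAULT_TREATMENTS
    n_replicates: int = 4
    n_individuals: int = 8
    loss_threshold: float | None = None
    anpp: AnppModel | None = None
    dirichlet_concentration: float | None = None
    seed: int = 0
    scenario: str = "custom"

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("species pool is empty")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ValueError("noise SDs must be >= 0")
        for name, sp in self.species.items():
            if sp.base_abundance <= 0:
                raise ValueError(f"{name}: base abundance must be > 0")
            if any(m <= 0 for m in sp.abundance_multipliers.values()):
                raise ValueError(f"{name}: abundance multipliers must be > 0")
            if any(v <= 0 for v in sp.base_means.values()):
                raise ValueError(f"{name}: base trait means must be > 0")

    @property
    def traits(self) -> tuple[str, ...]:
        first = next(iter(self.species.values()))
        return tuple(first.base_means)


@dataclass
class GroundTruth:
    """Realised structure behind a generated dataset (pre-noise)."""
    scenario: str
    seed: int
    abundances: pd.DataFrame          # plot_id, species_id, relative_biomass
    true_species_means: pd.DataFrame  # plot_id, species_id, trait, true_mean
    true_community_means: pd.DataFrame  # plot_id, trait, scheme, specific, fixed, intra
    n_clipped: int = 0


def _species_key(name: str) -> int:
    return zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *key]))


def _plot_abundances(cfg: SyntheticConfig, treatment: str, plot_idx: int,
                     seed: int) -> dict[str, float]:
    raw = {name: sp.base_abundance * sp.multiplier(treatment)
           for name, sp in cfg.species.items()}
    total = sum(raw.values())
    rel = {k: v / total for k, v in raw.items()}
    if cfg.loss_threshold is not None:
        rel = {k: v for k, v in rel.items() if v >= cfg.loss_threshold}
        if not rel:
            raise ValueError(
                f"loss threshold leaves no species in treatment {treatment!r}")
        total = sum(rel.values())
        rel = {k: v / total for k, v in rel.items()}
    if cfg.dirichlet_concentration is not None:
        rng = _rng(seed, plot_idx, 0xD1C)
        draws = rng.dirichlet(
            [cfg.dirichlet_concentration * v for v in rel.values()])
        rel = dict(zip(rel.keys(), draws.tolist()))
    return rel


def _true_community_means(abund: pd.DataFrame, true_means: pd.DataFrame
                          ) -> pd.DataFrame:
    """Implied specific/fixed/intra components of the noise-free world.

    The grand mean per species pools its true means over the plots where
    it occurs (individuals per species per plot are constant, so the
    pooled mean over individuals equals the mean over occupied plots).
    """
    grand = (true_means.groupby([SPECIES, "trait"])["true_mean"]
             .mean().rename("grand_mean").reset_index())
    m = true_means.merge(grand, on=[SPECIES, "trait"])
    m = m.merge(abund, on=[PLOT, SPECIES])
    rows = []
    for (plot, trait), d in m.groupby([PLOT, "trait"], sort=True):
        a = d[BIOMASS].to_numpy()
        a = a / a.sum()
        mu = d["true_mean"].to_numpy()
        g = d["grand_mean"].to_numpy()
        for scheme, spec, fix in (
                ("CWM", float(a @ mu), float(a @ g)),
                ("CM", float(mu.mean()), float(g.mean()))):
            rows.append({PLOT: plot, "trait": trait, "scheme": scheme,
                         "specific": spec, "fixed": fix,
                         "intra": spec - fix})
    return pd.DataFrame(rows)


def generate_dataset(cfg: SyntheticConfig, seed: int | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw one dataset: (TraitTable, CompositionTable, PlotTable, GroundTruth).

    Fully deterministic given the config and seed (``seed`` overrides
    ``cfg.seed`` when given).  Individual values are species true mean
    plus Gaussian noise, clipped from below at 1 % of the species base
    mean to keep traits strictly positive; clips are counted in the
    ground truth.
    """
    seed = cfg.seed if seed is None else int(seed)
    traits = cfg.traits
    trait_rows, comp_rows, plot_rows = [], [], []
    true_mean_rows = []
    n_clipped = 0

    plot_idx = 0
    for treatment in cfg.treatments:
        for rep in range(1, cfg.n_replicates + 1):
            plot = f"{treatment}-r{rep}"
            rel = _plot_abundances(cfg, treatment, plot_idx, seed)
            plot_rows.append({PLOT: plot, TREATMENT: treatment})
            for name, a in rel.items():
                sp = cfg.species[name]
                comp_rows.append({PLOT: plot, SPECIES: name, BIOMASS: a})
                rng = _rng(seed, plot_idx, _species_key(name))
                true_means = {t: sp.base_means[t] + sp.shift(treatment, t)
                              for t in traits}
                for t in traits:
                    true_mean_rows.append(
                        {PLOT: plot, SPECIES: name, "trait": t,
                         "true_mean": true_means[t]})
                noise = {t: rng.normal(0.0, cfg.noise_sd.get(t, 0.0),
                                       cfg.n_individuals)
                         for t in traits}
                for j in range(cfg.n_individuals):
                    row = {PLOT: plot, TREATMENT: treatment, SPECIES: name,
                           INDIVIDUAL: f"{name}-{j + 1}"}
                    for t in traits:
                        floor = POSITIVITY_FLOOR * sp.base_means[t]
                        value = true_means[t] + noise[t][j]
                        if value < floor:
                            value = floor
                            n_clipped += 1
                        row[t] = value
                    trait_rows.append(row)
            plot_idx += 1

    trait_df = pd.DataFrame(trait_rows)
    comp_df = pd.DataFrame(comp_rows)
    plot_df = pd.DataFrame(plot_rows)
    abund = comp_df.copy()
    true_means_df = pd.DataFrame(true_mean_rows)
    true_cm = _true_community_means(abund, true_means_df)

    if cfg.anpp is not None:
        rng = _rng(seed, 0x5EED)
        cwm = true_cm[(true_cm["scheme"] == "CWM")]
        anpp_values = []
        for plot in plot_df[PLOT]:
            sel = cwm[cwm[PLOT] == plot].set_index("trait")["specific"]
            value = cfg.anpp.intercept + sum(
                coef * sel[t] for t, coef in cfg.anpp.coefficients.items())
            value += rng.normal(0.0, cfg.anpp.noise_sd) if cfg.anpp.noise_sd else 0.0
            anpp_values.append(max(value, 0.0))
        plot_df[ANPP] = anpp_values

    truth = GroundTruth(scenario=cfg.scenario, seed=seed, abundances=abund,
                        true_species_means=true_means_df,
                        true_community_means=true_cm, n_clipped=n_clipped)
    return trait_df, comp_df, plot_df, truth


# ---------------------------------------------------------------------------
# presets


def _linear_shifts(treatments, trait_means, scale_per_level):
    """Additive shifts growing linearly along the treatment gradient."""
    return {trt: {t: scale_per_level * i * m for t, m in trait_means.items()}
            for i, trt in enumerate(treatments)}


def _paper_like(seed: int) -> SyntheticConfig:
    trts = DEFAULT_TREATMENTS
    # six species typical of a Tibetan alpine meadow: two dominant
    # graminoid groups, a sedge, and three subordinate forbs/legumes
    # H in cm, LA in cm^2, LDMC in g/g, SLA in m^2/kg
    def profile(base, abund, mult, h_shift, sla_shift):
        shifts = {trt: {"H": h_shift * i,
                        "LA": -0.02 * i * base["LA"],
                        "LDMC": -0.008 * i * base["LDMC"],
                        "SLA": sla_shift * i}
                  for i, trt in enumerate(trts)}
        return SpeciesProfile(base_means=base, base_abundance=abund,
                              abundance_multipliers=dict(zip(trts, mult)),
                              trait_shifts=shifts)

    species = {
        "Kobresia pygmaea": profile(
            {"H": 4.0, "LA": 0.4, "LDMC": 0.42, "SLA": 9.0},
            0.34, (1.0, 0.95, 0.85, 0.70, 0.55), 0.15, 0.25),
        "Stipa purpurea": profile(
            {"H": 28.0, "LA": 1.8, "LDMC": 0.38, "SLA": 11.0},
            0.26, (1.0, 1.15, 1.40, 1.80, 2.30), 1.40, 0.30),
        "Carex moorcroftii": profile(
            {"H": 13.0, "LA": 1.1, "LDMC": 0.40, "SLA": 10.0},
            0.18, (1.0, 1.00, 1.00, 0.95, 0.90), 0.60, 0.20),
        "Stracheya tibetica": profile(
            {"H": 5.0, "LA": 0.9, "LDMC": 0.30, "SLA": 16.0},
            0.09, (1.0, 0.95, 0.85, 0.65, 0.45), 0.20, 0.40),
        "Potentilla bifurca": profile(
            {"H": 8.0, "LA": 1.3, "LDMC": 0.33, "SLA": 14.0},
            0.07, (1.0, 0.90, 0.75, 0.55, 0.35), 0.25, 0.35),
        "Potentilla nivea": profile(
            {"H": 7.0, "LA": 2.2, "LDMC": 0.28, "SLA": 18.0},
            0.06, (1.0, 0.85, 0.65, 0.40, 0.25), 0.25, 0.35),
    }
    return SyntheticConfig(
        species=species,
        noise_sd={"H": 1.5, "LA": 0.15, "LDMC": 0.03, "SLA": 1.2},
        loss_threshold=0.02,
        anpp=AnppModel(intercept=80.0,
                       coefficients={"H": -1.2, "LDMC": 200.0, "SLA": -1.0},
                       noise_sd=8.0),
        seed=seed, scenario="paper-like")


def _generic_species(shift_sign: float, turnover: bool):
    """Four species whose base means are co-monotone across all traits,
    so composition and plasticity channels have a well-defined joint
    direction per trait."""
    trts = DEFAULT_TREATMENTS
    scales = {"H": 1.0, "LA": 0.08, "LDMC": 0.012, "SLA": 0.5}
    ranks = {"sp1": 10.0, "sp2": 16.0, "sp3": 24.0, "sp4": 34.0}
    mult = {
        "sp1": (1.0, 0.80, 0.60, 0.45, 0.30),
        "sp2": (1.0, 0.90, 0.80, 0.70, 0.60),
        "sp3": (1.0, 1.10, 1.20, 1.35, 1.50),
        "sp4": (1.0, 1.25, 1.60, 2.00, 2.50),
    }
    species = {}
    for name, r in ranks.items():
        base = {t: r * s for t, s in scales.items()}
        multipliers = dict(zip(trts, mult[name])) if turnover else {}
        shifts = _linear_shifts(trts, base, shift_sign * 0.03)
        species[name] = SpeciesProfile(
            base_means=base, base_abundance=0.25,
            abundance_multipliers=multipliers, trait_shifts=shifts)
    noise = {t: 0.05 * 20.0 * s for t, s in scales.items()}
    return species, noise


def scenario_presets(name: str, seed: int = 0) -> SyntheticConfig:
    """Named configurations with known dominant variance components.

    * ``composition-only`` — abundance turnover, zero trait shifts: the
      fixed component carries all treatment signal.
    * ``plasticity-only`` — constant composition, nonzero trait shifts:
      the intra component carries all treatment signal.
    * ``mixed-positive-cov`` / ``mixed-negative-cov`` — turnover toward
      high-trait species combined with upward / downward trait shifts,
      fixing the sign of the between-treatment covariation term.
    * ``paper-like`` — 5 treatments x 4 replicates, 6 species, 4 traits
      on field measurement scales, species loss at high N, and a
      trait-linked ANPP.
    """
    if name == "paper-like":
        return _paper_like(seed)
    if name == "composition-only":
        species, noise = _generic_species(shift_sign=0.0, turnover=True)
        return SyntheticConfig(species=species, noise_sd=noise, seed=seed,
                               scenario=name)
    if name == "plasticity-only":
        species, noise = _generic_species(shift_sign=1.0, turnover=False)
        return SyntheticConfig(species=species, noise_sd=noise, seed=seed,
                               scenario=name)
    if name == "mixed-positive-cov":
        species, noise = _generic_species(shift_sign=1.0, turnover=True)
        return SyntheticConfig(species=species, noise_sd=noise, seed=seed,
                               scenario=name)
    if name == "mixed-negative-cov":
        species, noise = _generic_species(shift_sign=-1.0, turnover=True)
        return SyntheticConfig(species=species, noise_sd=noise, seed=seed,
                               scenario=name)
    raise ValueError(f"unknown preset {name!r}; known: {sorted(PRESETS)}")


PRESETS = ("composition-only", "plasticity-only", "mixed-positive-cov",
           "mixed-negative-cov", "paper-like")


def with_noise(cfg: SyntheticConfig, sd: float | Mapping[str, float]
               ) -> SyntheticConfig:
    """Copy of ``cfg`` with individual noise replaced (scalar = all traits)."""
    if isinstance(sd, (int, float)):
        sd = {t: float(sd) for t in cfg.traits}
    return replace(cfg, noise_sd=dict(sd))
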