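"""End-to-end orchestration: load/simulate -> validate -> indices ->
community means -> ANOVA/Tukey/letters -> SS decomposition -> report.

The pipeline is a pure function of its :class:`RunConfig`: identical
configs (including seed) reproduce every output CSV byte for byte.
Input files are never mutated; everything is written under the
configured output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .among import community_trait_means
from .datamodel import (ANPP, PLOT, TREATMENT, load_tables,
                        normalize_abundances, restrict_to_measured,
                        trait_columns, validate_dataset, write_tables)
from .simulate import generate_dataset, scenario_presets
from .stats import (compact_letter_display, contribution_percentages,
                    one_way_anova, ss_decompose, tukey_hsd)
from .within import within_community_indices

log = logging.getLogger("traitpart")

INDEX_FAMILIES = ("witv_intra", "witv_inter",
                  "cwm_specific", "cwm_fixed", "cwm_intra",
                  "cm_specific", "cm_fixed", "cm_intra")


@dataclass
class RunConfig:
    """Everything a run needs; loadable from YAML via :meth:`from_yaml`."""
    out_dir: str | Path = "traitpart-out"
    trait_csv: str | None = None
    composition_csv: str | None = None
    plot_csv: str | None = None
    preset: str | None = None
    traits: list[str] | None = None
    treatment_order: list[str] | None = None
    alpha: float = 0.05
    variance_ddof: int = 0
    cm_fixed_divisor: bool = True
    percent_denominator: str = "total"
    renormalize_unmeasured: bool = True
    log_transform_witv: bool = False
    make_figures: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        has_files = all(p is not None for p in
                        (self.trait_csv, self.composition_csv, self.plot_csv))
        if not has_files and self.preset is None:
            raise ValueError("provide the three input CSVs or a preset")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class ResultBundle:
    config: RunConfig
    within_indices: pd.DataFrame
    community_means: pd.DataFrame
    anova_results: pd.DataFrame
    tukey_results: pd.DataFrame
    letters: pd.DataFrame
    decomposition: pd.DataFrame
    validation_summary: str
    manifest: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _treatment_levels(plots: pd.DataFrame, order: list[str] | None) -> list[str]:
    seen = list(dict.fromkeys(plots[TREATMENT]))
    if order is None:
        return seen
    unknown = set(seen) - set(order)
    if unknown:
        raise ValueError(f"treatment_order omits level(s): {sorted(unknown)}")
    return [lv for lv in order if lv in seen]


def _index_table(within: pd.DataFrame, means: pd.DataFrame) -> pd.DataFrame:
    """One tidy table of every per-plot index family: plot, trait,
    family, value."""
    rows = [within.melt(id_vars=[PLOT, "trait"],
                        value_vars=["witv_intra", "witv_inter"],
                        var_name="family", value_name="value")]
    for scheme in ("CWM", "CM"):
        sub = means[means["scheme"] == scheme]
        melted = sub.melt(id_vars=[PLOT, "trait"],
                          value_vars=["specific", "fixed", "intra"],
                          var_name="component", value_name="value")
        melted["family"] = scheme.lower() + "_" + melted["component"]
        rows.append(melted[[PLOT, "trait", "family", "value"]])
    return pd.concat(rows, ignore_index=True)


def _treatment_tests(indexed: pd.DataFrame, plots: pd.DataFrame,
                     levels: list[str], alpha: float):
    """ANOVA + Tukey + letters for every (family, trait) series."""
    anova_rows, tukey_rows, letter_rows = [], [], []
    merged = indexed.merge(plots[[PLOT, TREATMENT]], on=PLOT)
    for (family, trait), d in merged.groupby(["family", "trait"], sort=True):
        by_level = {lv: d.loc[d[TREATMENT] == lv, "value"].to_numpy()
                    for lv in levels if (d[TREATMENT] == lv).any()}
        if len(by_level) < 2:
            continue
        a = one_way_anova(by_level)
        anova_rows.append({"family": family, "trait": trait,
                           "ss_between": a.ss_between, "ss_within": a.ss_within,
                           "df_between": a.df_between, "df_within": a.df_within,
                           "f_stat": a.f_stat, "p_value": a.p_value,
                           "degenerate": a.degenerate})
        pw = tukey_hsd(by_level, alpha=alpha)
        pw.insert(0, "trait", trait)
        pw.insert(0, "family", family)
        tukey_rows.append(pw)
        means = {lv: float(v.mean()) for lv, v in by_level.items()}
        letters = compact_letter_display(pw, alpha=alpha, means=means)
        for lv in levels:
            if lv in letters:
                letter_rows.append({"family": family, "trait": trait,
                                    TREATMENT: lv, "mean": means[lv],
                                    "letters": letters[lv]})
    return (pd.DataFrame(anova_rows),
            pd.concat(tukey_rows, ignore_index=True) if tukey_rows
            else pd.DataFrame(),
            pd.DataFrame(letter_rows))


def _decomposition_table(means: pd.DataFrame, plots: pd.DataFrame,
                         traits: list[str], denominator: str) -> pd.DataFrame:
    rows = []
    for trait in traits:
        for scheme in ("CWM", "CM"):
            d = contribution_percentages(
                ss_decompose(means, plots, trait, scheme), denominator)
            for stratum in ("between", "within", "total"):
                row = {"trait": trait, "scheme": scheme, "stratum": stratum}
                for comp in ("specific", "fixed", "intra", "cov"):
                    row[f"ss_{comp}"] = d.ss[stratum][comp]
                if stratum == "between":
                    row.update(percent_fixed=d.percent_fixed,
                               percent_intra=d.percent_intra,
                               percent_cov=d.percent_cov,
                               p_specific=d.anova["specific"].p_value,
                               p_fixed=d.anova["fixed"].p_value,
                               p_intra=d.anova["intra"].p_value)
                rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> ResultBundle:
    """Execute every stage and write all outputs under ``cfg.out_dir``."""
    t0 = time.perf_counter()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": cfg.seed,
                      "config": {k: (str(v) if isinstance(v, Path) else v)
                                 for k, v in asdict(cfg).items()}}

    if cfg.preset is not None:
        sim = scenario_presets(cfg.preset, seed=cfg.seed)
        traits_df, comp_df, plots_df, truth = generate_dataset(sim)
        data_dir = out / "data"
        paths = write_tables(traits_df, comp_df, plots_df, data_dir)
        manifest["inputs"] = {k: _sha256(p) for k, p in paths.items()}
        manifest["scenario"] = truth.scenario
        log.info("simulate: preset=%s plots=%d individuals=%d",
                 cfg.preset, len(plots_df), len(traits_df))
    else:
        traits_df, comp_df, plots_df = load_tables(
            cfg.trait_csv, cfg.composition_csv, cfg.plot_csv, cfg.traits)
        manifest["inputs"] = {name: _sha256(Path(p)) for name, p in
                              (("traits", cfg.trait_csv),
                               ("composition", cfg.composition_csv),
                               ("plots", cfg.plot_csv))}
        log.info("load: plots=%d individuals=%d", len(plots_df), len(traits_df))

    report = validate_dataset(traits_df, comp_df, plots_df)
    if not report.is_valid:
        raise ValueError("validation failed:\n" + report.summary())
    for w in report.warnings:
        log.warning("%s: %s", w.code, w.message)

    if cfg.renormalize_unmeasured:
        comp_df, dropped = restrict_to_measured(comp_df, traits_df)
        if len(dropped):
            log.warning("dropped %d unmeasured composition row(s)", len(dropped))
    else:
        comp_df = normalize_abundances(comp_df)

    traits_list = cfg.traits or trait_columns(traits_df)
    levels = _treatment_levels(plots_df, cfg.treatment_order)

    within = within_community_indices(traits_df, comp_df, traits_list,
                                      ddof=cfg.variance_ddof)
    log.info("within-community indices: %d rows", len(within))
    means = community_trait_means(traits_df, comp_df, traits_list,
                                  cm_fixed_divisor=cfg.cm_fixed_divisor)
    log.info("community means: %d rows", len(means))

    indexed = _index_table(within, means)
    if cfg.log_transform_witv:
        import numpy as np
        mask = indexed["family"].str.startswith("witv")
        indexed.loc[mask, "value"] = np.log1p(indexed.loc[mask, "value"])
    anova_df, tukey_df, letters_df = _treatment_tests(
        indexed, plots_df, levels, cfg.alpha)
    log.info("treatment tests: %d ANOVA rows", len(anova_df))

    if ANPP in plots_df.columns:
        by_level = {lv: plots_df.loc[plots_df[TREATMENT] == lv, ANPP].to_numpy()
                    for lv in levels}
        a = one_way_anova(by_level)
        anova_df = pd.concat([anova_df, pd.DataFrame([{
            "family": "anpp", "trait": "ANPP",
            "ss_between": a.ss_between, "ss_within": a.ss_within,
            "df_between": a.df_between, "df_within": a.df_within,
            "f_stat": a.f_stat, "p_value": a.p_value,
            "degenerate": a.degenerate}])], ignore_index=True)
        pw = tukey_hsd(by_level, alpha=cfg.alpha)
        pw.insert(0, "trait", "ANPP")
        pw.insert(0, "family", "anpp")
        tukey_df = pd.concat([tukey_df, pw], ignore_index=True)

    decomposition = _decomposition_table(means, plots_df, list(traits_list),
                                         cfg.percent_denominator)

    # attach treatment labels to per-plot outputs
    within = within.merge(plots_df[[PLOT, TREATMENT]], on=PLOT)
    within = within[[PLOT, TREATMENT, "trait", "witv_intra", "witv_inter"]]
    means = means.merge(plots_df[[PLOT, TREATMENT]], on=PLOT)
    means = means[[PLOT, TREATMENT, "trait", "scheme",
                   "specific", "fixed", "intra"]]

    outputs = {
        "within_indices.csv": within,
        "community_means.csv": means,
        "anova_results.csv": anova_df,
        "tukey_results.csv": tukey_df,
        "letters.csv": letters_df,
        "decomposition.csv": decomposition,
    }
    for name, df in outputs.items():
        df.to_csv(out / name, index=False)

    if cfg.make_figures:
        from .plotting import decomposition_barplot
        for scheme in ("CWM", "CM"):
            decomposition_barplot(decomposition, scheme,
                                  out / f"decomposition_{scheme.lower()}.png")

    summary = _summary_markdown(cfg, plots_df, anova_df, decomposition,
                                report.summary())
    (out / "summary.md").write_text(summary, encoding="utf-8")
    manifest["outputs"] = {name: _sha256(out / name) for name in outputs}
    manifest["runtime_stages"] = "see log"
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
    log.info("pipeline done in %.2f s", time.perf_counter() - t0)

    return ResultBundle(config=cfg, within_indices=within,
                        community_means=means, anova_results=anova_df,
                        tukey_results=tukey_df, letters=letters_df,
                        decomposition=decomposition,
                        validation_summary=report.summary(),
                        manifest=manifest)


def _summary_markdown(cfg, plots_df, anova_df, decomposition, validation):
    lines = ["# traitpart run summary", "",
             f"- plots: {len(plots_df)}",
             f"- treatments: {plots_df[TREATMENT].nunique()}",
             f"- alpha: {cfg.alpha}",
             f"- percentage denominator: {cfg.percent_denominator}",
             "", "## Validation", "```", validation, "```", "",
             "## Treatment effects (ANOVA p-values)", ""]
    if len(anova_df):
        piv = anova_df.pivot_table(index="family", columns="trait",
                                   values="p_value")
        lines += ["```", piv.round(4).to_string(), "```", ""]
    lines += ["## Decomposition (between-treatment, % of specific SS)", ""]
    between = decomposition[decomposition["stratum"] == "between"]
    cols = ["trait", "scheme", "percent_fixed", "percent_intra", "percent_cov",
            "p_specific", "p_fixed", "p_intra"]
    lines += ["```", between[cols].round(3).to_string(index=False), "```", ""]
    return "\n".join(lines)
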