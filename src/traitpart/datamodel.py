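"""Tidy-table data model, validation and CSV I/O.

Three comma-delimited, UTF-8 tables drive every analysis:

``TraitTable``
    One row per measured individual: ``plot_id``, ``treatment``,
    ``species_id``, ``individual_id`` and one numeric column per trait
    (by convention ``H`` in cm, ``LA`` in cm^2, ``LDMC`` in g g^-1,
    ``SLA`` in m^2 kg^-1, but any positive trait works).

``CompositionTable``
    One row per (plot, species): ``plot_id``, ``species_id``,
    ``relative_biomass``.  Abundances are re-normalised to sum to one
    per plot before use, so inputs may be raw biomass.

``PlotTable``
    One row per plot: ``plot_id``, ``treatment`` and optionally
    ``anpp`` (above-ground net primary productivity, g m^-2).

Tables are plain :class:`pandas.DataFrame` objects with the column
contracts above; the functions here load, check and write them.
Unknown extra columns are preserved on load but ignored by analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PLOT = "plot_id"
TREATMENT = "treatment"
SPECIES = "species_id"
INDIVIDUAL = "individual_id"
BIOMASS = "relative_biomass"
ANPP = "anpp"

#: columns of the trait table that are identifiers, not measurements
TRAIT_ID_COLUMNS = (PLOT, TREATMENT, SPECIES, INDIVIDUAL)

DEFAULT_TRAITS = ("H", "LA", "LDMC", "SLA")


class SchemaError(ValueError):
    """An input table violates its declared column contract."""


class DegeneratePlotError(ValueError):
    """A plot has no usable species or zero total biomass."""


class ConsistencyError(ValueError):
    """Cross-table references do not resolve (e.g. unknown species)."""


# ---------------------------------------------------------------------------
# loading


def _read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _coerce_numeric(df: pd.DataFrame, col: str, path) -> None:
    raw = df[col].astype(str).str.strip()
    values = pd.to_numeric(raw, errors="coerce")
    bad = values.isna()
    if bad.any():
        rows = df.index[bad].tolist()[:10]
        kind = "empty" if (raw[bad] == "").all() else "unparsable"
        raise SchemaError(
            f"{path}: column {col!r} has {kind} numeric cell(s) at row(s) {rows}"
        )
    df[col] = values.astype(float)


def trait_columns(traits: pd.DataFrame) -> list[str]:
    """Names of the measurement columns of a trait table."""
    return [c for c in traits.columns if c not in TRAIT_ID_COLUMNS
            and pd.api.types.is_numeric_dtype(traits[c])]


def load_trait_table(path: str | Path,
                     traits: Sequence[str] | None = None) -> pd.DataFrame:
    """Load and type-check an individual-level trait table.

    ``traits`` names the measurement columns; by default every
    non-identifier column is treated as a trait and must be numeric.
    """
    df = _read_csv(path)
    _require_columns(df, TRAIT_ID_COLUMNS, path)
    if traits is None:
        # every fully-numeric non-identifier column is a trait; columns that
        # parse nowhere are preserved as opaque extras, a partially numeric
        # column is a data error
        traits = []
        for col in df.columns:
            if col in TRAIT_ID_COLUMNS:
                continue
            parsed = pd.to_numeric(df[col].astype(str).str.strip(),
                                   errors="coerce")
            if parsed.notna().all():
                traits.append(col)
            elif parsed.notna().any():
                _coerce_numeric(df, col, path)  # raises with row indices
    else:
        _require_columns(df, traits, path)
    for col in traits:
        _coerce_numeric(df, col, path)
    check_trait_table(df, traits)
    return df


def load_composition_table(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path)
    _require_columns(df, (PLOT, SPECIES, BIOMASS), path)
    _coerce_numeric(df, BIOMASS, path)
    check_composition_table(df)
    return df


def load_plot_table(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path)
    _require_columns(df, (PLOT, TREATMENT), path)
    if ANPP in df.columns:
        _coerce_numeric(df, ANPP, path)
    check_plot_table(df)
    return df


def load_tables(trait_path, composition_path, plot_path,
                traits: Sequence[str] | None = None):
    """Load the three pipeline inputs; see module docstring for schemas."""
    return (load_trait_table(trait_path, traits),
            load_composition_table(composition_path),
            load_plot_table(plot_path))


# ---------------------------------------------------------------------------
# per-table invariants


def check_trait_table(df: pd.DataFrame,
                      traits: Sequence[str] | None = None) -> None:
    traits = list(traits) if traits is not None else trait_columns(df)
    if not traits:
        raise SchemaError("trait table has no trait columns")
    dup = df.duplicated([PLOT, SPECIES, INDIVIDUAL])
    if dup.any():
        keys = df.loc[dup, [PLOT, SPECIES, INDIVIDUAL]].iloc[0].tolist()
        raise SchemaError(f"duplicate (plot, species, individual) key {keys}")
    values = df[traits].to_numpy(dtype=float)
    if not np.isfinite(values).all() or (values <= 0).any():
        raise SchemaError("trait values must be finite and strictly positive")
    multi = df.groupby(PLOT)[TREATMENT].nunique()
    if (multi > 1).any():
        raise SchemaError(
            f"plot(s) mapped to several treatments: {multi[multi > 1].index.tolist()}")


def check_composition_table(df: pd.DataFrame) -> None:
    if df.duplicated([PLOT, SPECIES]).any():
        raise SchemaError("duplicate (plot, species) row in composition table")
    if (df[BIOMASS].to_numpy() <= 0).any() or not np.isfinite(df[BIOMASS]).all():
        raise SchemaError("relative_biomass must be finite and > 0")


def check_plot_table(df: pd.DataFrame) -> None:
    if df[PLOT].duplicated().any():
        raise SchemaError("duplicate plot_id in plot table")
    if ANPP in df.columns and (df[ANPP].to_numpy() < 0).any():
        raise SchemaError("anpp must be >= 0")


# ---------------------------------------------------------------------------
# abundance handling


def normalize_abundances(comp: pd.DataFrame) -> pd.DataFrame:
    """Rescale relative biomass to sum to exactly one within each plot.

    Idempotent and scale-invariant: multiplying one plot's biomasses by
    any positive constant leaves the output unchanged.
    """
    out = comp.copy()
    totals = out.groupby(PLOT)[BIOMASS].transform("sum")
    if (totals <= 0).any():
        bad = out.loc[totals <= 0, PLOT].unique().tolist()
        raise DegeneratePlotError(f"plot(s) with zero total biomass: {bad}")
    out[BIOMASS] = out[BIOMASS] / totals
    return out


def restrict_to_measured(comp: pd.DataFrame, traits: pd.DataFrame,
                         renormalize: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop composition rows for species without trait data in that plot.

    Indices are computed over the measured species subset (field studies
    typically measure species covering >90 % cumulative abundance), so
    abundances are re-normalised over that subset by default.  Returns
    ``(composition, dropped_rows)``.
    """
    measured = traits[[PLOT, SPECIES]].drop_duplicates()
    merged = comp.merge(measured.assign(_m=1), on=[PLOT, SPECIES], how="left")
    keep = merged["_m"].notna()
    dropped = comp.loc[~keep.to_numpy()].copy()
    kept = comp.loc[keep.to_numpy()].copy()
    if kept.empty:
        raise DegeneratePlotError("no measured species remain in any plot")
    if renormalize:
        kept = normalize_abundances(kept)
    return kept, dropped


# ---------------------------------------------------------------------------
# cross-table validation


@dataclass(frozen=True)
class Finding:
    code: str
    message: str
    keys: tuple = ()


@dataclass
class ValidationReport:
    errors: list[Finding] = field(default_factory=list)
    warnings: list[Finding] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not self.errors

    def summary(self) -> str:
        lines = [f"valid: {self.is_valid} "
                 f"({len(self.errors)} errors, {len(self.warnings)} warnings)"]
        for f in self.errors:
            lines.append(f"ERROR   {f.code}: {f.message}")
        for f in self.warnings:
            lines.append(f"WARNING {f.code}: {f.message}")
        return "\n".join(lines)


def validate_dataset(traits: pd.DataFrame, comp: pd.DataFrame,
                     plots: pd.DataFrame) -> ValidationReport:
    """Cross-check the three tables; all findings go into the report.

    Errors: trait or composition rows referencing plots absent from the
    plot table, and trait rows for (plot, species) pairs absent from the
    composition.  Warnings: species present in the composition but never
    measured (they are excluded and weights renormalised downstream) and
    species with a single measured individual in a plot (within-species
    variance defined but weak).
    """
    report = ValidationReport()
    known_plots = set(plots[PLOT])

    for name, df in (("traits", traits), ("composition", comp)):
        orphan = sorted(set(df[PLOT]) - known_plots)
        if orphan:
            report.errors.append(Finding(
                "unknown-plot",
                f"{name} table references plot(s) missing from plot table: {orphan}",
                tuple(orphan)))

    comp_keys = set(map(tuple, comp[[PLOT, SPECIES]].itertuples(index=False)))
    trait_keys = set(map(tuple, traits[[PLOT, SPECIES]].drop_duplicates()
                         .itertuples(index=False)))
    for key in sorted(trait_keys - comp_keys):
        report.errors.append(Finding(
            "missing-composition",
            f"species {key[1]!r} measured in plot {key[0]!r} has no "
            f"composition row", key))
    for key in sorted(comp_keys - trait_keys):
        report.warnings.append(Finding(
            "unmeasured-species",
            f"species {key[1]!r} in plot {key[0]!r} has no trait "
            f"measurements; it will be excluded and weights renormalised", key))

    n_ind = traits.groupby([PLOT, SPECIES]).size()
    for key, n in n_ind[n_ind < 2].items():
        report.warnings.append(Finding(
            "single-individual",
            f"species {key[1]!r} in plot {key[0]!r} has {n} measured "
            f"individual; its within-species variance is 0", tuple(key)))
    return report


# ---------------------------------------------------------------------------
# writing


def write_tables(traits: pd.DataFrame, comp: pd.DataFrame, plots: pd.DataFrame,
                 directory: str | Path) -> dict[str, Path]:
    """Write the three tables as ``traits.csv``, ``composition.csv``,
    ``plots.csv`` under ``directory``; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "traits": directory / "traits.csv",
        "composition": directory / "composition.csv",
        "plots": directory / "plots.csv",
    }
    traits.to_csv(paths["traits"], index=False)
    comp.to_csv(paths["composition"], index=False)
    plots.to_csv(paths["plots"], index=False)
    return paths
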