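"""Treatment-effect statistics and the sum-of-squares decomposition.

One-way fixed-effects ANOVA, Tukey–Kramer HSD with studentized-range
p-values, a compact letter display, and the decomposition of the
community-mean series into interspecific (fixed), intraspecific (intra)
and covariation components:

    SS_specific = SS_fixed + SS_intra + SS_cov

evaluated separately in the between-treatment, within-treatment and
total strata.  Because ``intra = specific - fixed`` per plot, the
covariation term is exactly twice the corresponding cross sum of
products: it is positive when composition change and within-species
shifts push community traits the same way, negative when they oppose.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import PLOT, TREATMENT

__all__ = ["AnovaResult", "one_way_anova", "tukey_hsd",
           "compact_letter_display", "DecompositionResult",
           "ss_decompose", "contribution_percentages"]

STRATA = ("between", "within", "total")
COMPONENTS = ("specific", "fixed", "intra")


@dataclass(frozen=True)
class AnovaResult:
    ss_between: float
    ss_within: float
    df_between: int
    df_within: int
    f_stat: float
    p_value: float
    degenerate: bool = False

    @property
    def ss_total(self) -> float:
        return self.ss_between + self.ss_within


def _as_groups(values_by_level: Mapping[str, Sequence[float]]
               ) -> list[tuple[str, np.ndarray]]:
    groups = [(str(k), np.asarray(v, dtype=float))
              for k, v in values_by_level.items()]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two levels")
    if any(g.size < 1 for _, g in groups):
        raise ValueError("every level needs at least one value")
    if sum(g.size for _, g in groups) - len(groups) < 1:
        raise ValueError("at least one level needs two or more values")
    return groups


def one_way_anova(values_by_level: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Textbook fixed-effects one-way ANOVA.

    Degenerate inputs are flagged rather than erroring: zero
    within-group variance with a real between-group difference reports
    an infinite F and p = 0; completely constant data reports F = 0,
    p = 1.
    """
    groups = _as_groups(values_by_level)
    all_values = np.concatenate([g for _, g in groups])
    grand = all_values.mean()
    ss_between = float(sum(g.size * (g.mean() - grand) ** 2 for _, g in groups))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for _, g in groups))
    df_between = len(groups) - 1
    df_within = all_values.size - len(groups)

    if ss_within <= 0.0:
        if ss_between > 0.0:
            return AnovaResult(ss_between, 0.0, df_between, df_within,
                               np.inf, 0.0, degenerate=True)
        return AnovaResult(0.0, 0.0, df_between, df_within,
                           0.0, 1.0, degenerate=True)
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(sps.f.sf(f, df_between, df_within))
    return AnovaResult(ss_between, ss_within, df_between, df_within, f, p)


def tukey_hsd(values_by_level: Mapping[str, Sequence[float]],
              alpha: float = 0.05) -> pd.DataFrame:
    """All-pairs Tukey–Kramer HSD after a one-way layout.

    Uses the pooled within-group variance and the studentized-range
    distribution; unequal group sizes get the Kramer correction
    ``se = sqrt((MSW/2) * (1/n_a + 1/n_b))``.  Returns one row per
    unordered level pair with ``mean_diff`` (b minus a), ``q_stat``,
    ``p_adj`` and a boolean ``significant`` at ``alpha``.
    """
    groups = _as_groups(values_by_level)
    anova = one_way_anova(values_by_level)
    df_within = anova.df_within
    msw = anova.ss_within / df_within if df_within > 0 else 0.0

    rows = []
    for (name_a, a), (name_b, b) in itertools.combinations(groups, 2):
        diff = float(b.mean() - a.mean())
        if msw > 0:
            se = np.sqrt(msw / 2.0 * (1.0 / a.size + 1.0 / b.size))
            q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, len(groups), df_within))
        else:
            # no residual variance: any real difference is unambiguous
            q = np.inf if diff != 0 else 0.0
            p = 0.0 if diff != 0 else 1.0
        rows.append({"level_a": name_a, "level_b": name_b,
                     "mean_diff": diff, "q_stat": q,
                     "p_adj": min(max(p, 0.0), 1.0)})
    out = pd.DataFrame(rows)
    out["significant"] = out["p_adj"] < alpha
    return out


_LETTERS = "abcdefghijklmnopqrstuvwxyz"


def compact_letter_display(pairwise: pd.DataFrame, alpha: float = 0.05,
                           means: Mapping[str, float] | None = None
                           ) -> dict[str, str]:
    """Letter groups from a pairwise table (insert-and-absorb).

    Two levels share a letter iff their adjusted p-value is >= alpha;
    this sharing-iff-nonsignificant property is re-checked before
    returning.  Levels are ordered by descending group mean (when
    ``means`` is given) and letters assigned alphabetically down that
    order, matching the convention of treatment-effect figures.
    """
    levels = sorted(set(pairwise["level_a"]) | set(pairwise["level_b"]))
    if means is not None:
        levels.sort(key=lambda lv: -means[lv])
    sig_pairs = [
        (r["level_a"], r["level_b"])
        for _, r in pairwise.iterrows() if r["p_adj"] < alpha
    ]

    columns: list[set[str]] = [set(levels)]
    for a, b in sig_pairs:
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            columns.append(col - {a})
            columns.append(col - {b})
        # absorb columns that became subsets of another
        columns = [c for c in columns
                   if c and not any(c < d for d in columns)]
        # drop duplicates while keeping order
        seen: list[set[str]] = []
        for c in columns:
            if c not in seen:
                seen.append(c)
        columns = seen

    rank = {lv: i for i, lv in enumerate(levels)}
    columns.sort(key=lambda c: min(rank[lv] for lv in c))
    letter_of = {}
    for i, col in enumerate(columns):
        letter = _LETTERS[i % 26] * (i // 26 + 1)
        for lv in col:
            letter_of.setdefault(lv, []).append(letter)
    display = {lv: "".join(sorted(letter_of.get(lv, []))) for lv in levels}

    # post-hoc consistency: shared letter <=> not significant
    sig_set = {frozenset(p) for p in sig_pairs}
    for a, b in itertools.combinations(levels, 2):
        shared = set(display[a]) & set(display[b])
        if bool(shared) == (frozenset((a, b)) in sig_set):
            raise RuntimeError(
                f"letter display inconsistent for pair ({a}, {b})")
    return display


# ---------------------------------------------------------------------------
# SS decomposition


@dataclass
class DecompositionResult:
    """SS decomposition of one trait under one weighting scheme.

    ``ss[stratum][component]`` holds the sums of squares for stratum in
    {between, within, total} and component in {specific, fixed, intra,
    cov}; ``anova`` maps the three component series to their treatment
    ANOVAs.  Percentages are filled by :func:`contribution_percentages`.
    """
    trait: str
    scheme: str
    anova: dict[str, AnovaResult]
    ss: dict[str, dict[str, float]]
    percent_fixed: float | None = None
    percent_intra: float | None = None
    percent_cov: float | None = None
    percent_denominator: str | None = None
    percent_degenerate: bool = False
    extras: dict = field(default_factory=dict)

    @property
    def p_values(self) -> dict[str, float]:
        return {k: v.p_value for k, v in self.anova.items()}


def ss_decompose(means: pd.DataFrame, plots: pd.DataFrame,
                 trait: str, scheme: str) -> DecompositionResult:
    """Decompose treatment-induced variation in community means.

    ``means`` is the tidy specific/fixed/intra table from
    :func:`traitpart.among.community_trait_means`; ``plots`` supplies
    the treatment factor.  Each component series gets its own one-way
    ANOVA, and per stratum the covariation term closes the identity
    ``ss_specific = ss_fixed + ss_intra + ss_cov``.
    """
    sub = means[(means["trait"] == trait) & (means["scheme"] == scheme)]
    if sub.empty:
        raise KeyError(f"no community means for trait {trait!r}, "
                       f"scheme {scheme!r}")
    sub = sub.merge(plots[[PLOT, TREATMENT]], on=PLOT, how="left")
    if sub[TREATMENT].isna().any():
        bad = sub.loc[sub[TREATMENT].isna(), PLOT].tolist()
        raise KeyError(f"plot(s) missing from plot table: {bad}")
    if sub[TREATMENT].nunique() < 2:
        raise ValueError("decomposition needs at least two treatments")

    anovas: dict[str, AnovaResult] = {}
    for component in COMPONENTS:
        by_level = {t: g[component].to_numpy()
                    for t, g in sub.groupby(TREATMENT, sort=False)}
        anovas[component] = one_way_anova(by_level)

    ss: dict[str, dict[str, float]] = {}
    for stratum in STRATA:
        row = {}
        for component in COMPONENTS:
            a = anovas[component]
            row[component] = {"between": a.ss_between, "within": a.ss_within,
                              "total": a.ss_total}[stratum]
        row["cov"] = row["specific"] - row["fixed"] - row["intra"]
        ss[stratum] = row
    return DecompositionResult(trait=trait, scheme=scheme,
                               anova=anovas, ss=ss)


def contribution_percentages(d: DecompositionResult,
                             denominator: str = "total") -> DecompositionResult:
    """Express treatment-explained components as percentages.

    Numerators are the between-treatment SS of the fixed, intra and
    covariation components.  ``denominator="total"`` (default) divides
    by the total SS of the specific series, so the three percentages sum
    to the share of total variability explained by the treatment;
    ``denominator="explained"`` divides by the between-treatment
    specific SS so they sum to 100.  The covariation percentage may be
    negative.  A zero denominator is flagged and yields NaNs.
    """
    if denominator == "total":
        denom = d.ss["total"]["specific"]
    elif denominator == "explained":
        denom = d.ss["between"]["specific"]
    else:
        raise ValueError("denominator must be 'total' or 'explained'")
    if denom <= 0.0:
        return replace(d, percent_fixed=float("nan"),
                       percent_intra=float("nan"), percent_cov=float("nan"),
                       percent_denominator=denominator, percent_degenerate=True)
    between = d.ss["between"]
    return replace(
        d,
        percent_fixed=100.0 * between["fixed"] / denom,
        percent_intra=100.0 * between["intra"] / denom,
        percent_cov=100.0 * between["cov"] / denom,
        percent_denominator=denominator,
        percent_degenerate=False,
    )
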