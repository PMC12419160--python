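"""Replicate-aware statistics for hierarchical imaging data.

Cells imaged within one experimental replicate (one transfection, one dish,
one day) are not independent, so inference treats the replicate mean — not
the cell — as the unit of analysis, in the style of SuperPlots: per-group
grand means are means of replicate means, error bars are the SEM across
replicates, and t tests / ANOVA run on the replicate means.  Per-cell
values remain available for display.

Provided tests: one-sample and two-sample t, one-way fixed-effects ANOVA
with R², Šídák multiple-comparison adjustment, many-to-one comparisons
against a reference group using the ANOVA's pooled within-group variance,
balanced two-way ANOVA with interaction, and the Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "HierarchicalSample",
    "replicate_means",
    "grand_mean_sem",
    "one_sample_t",
    "two_sample_t",
    "one_way_anova",
    "sidak_adjust",
    "many_to_one_comparisons",
    "two_way_anova_balanced",
    "wilcoxon_signed_rank",
    "anova_null_rejection_rate",
]


@dataclass(frozen=True)
class HierarchicalSample:
    """Tidy (group, replicate, cell, value) table with basic validation."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"group", "replicate", "value"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"table is missing columns {sorted(missing)}")
        if self.table.empty:
            raise ValueError("table is empty")

    def require_replicates(self, k: int = 2) -> None:
        counts = self.table.groupby("group", sort=False)["replicate"].nunique()
        if (counts < k).any():
            bad = counts[counts < k].index.tolist()
            raise ValueError(f"groups {bad} have fewer than {k} replicates")


def replicate_means(h: HierarchicalSample) -> pd.DataFrame:
    """Mean value per (group, replicate) — the unit of inference."""
    out = (
        h.table.groupby(["group", "replicate"], sort=False)["value"]
        .mean()
        .reset_index()
        .rename(columns={"value": "mean"})
    )
    return out


def grand_mean_sem(h: HierarchicalSample) -> pd.DataFrame:
    """Grand mean ± SEM of the replicate means, per group.

    SEM = sd(replicate means, ddof=1) / sqrt(n_reps); a group with a single
    replicate has no SEM and raises.
    """
    reps = replicate_means(h)
    rows = []
    for group, sub in reps.groupby("group", sort=False):
        n = len(sub)
        if n < 2:
            raise ValueError(f"group {group!r} has {n} replicate; SEM is undefined")
        m = sub["mean"].to_numpy()
        rows.append((group, m.mean(), m.std(ddof=1) / np.sqrt(n), n))
    return pd.DataFrame(rows, columns=["group", "grand_mean", "sem", "n_reps"])


def one_sample_t(values: Sequence[float], mu0: float = 0.0) -> tuple[float, int, float]:
    """One-sample t test of mean == mu0; returns (t, df, two-sided p)."""
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 2:
        raise ValueError("need at least two observations")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance; t statistic is undefined")
    t = (v.mean() - mu0) / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), df, float(p)


def two_sample_t(
    a: Sequence[float], b: Sequence[float], welch: bool = False
) -> tuple[float, float, float]:
    """Two-sample t test; pooled-variance Student's t by default.

    Returns (t, df, two-sided p).  ``welch=True`` drops the equal-variance
    assumption (Welch-Satterthwaite df).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    if welch:
        t, p = sps.ttest_ind(a, b, equal_var=False)
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        return float(t), float(df), float(p)
    na, nb = a.size, b.size
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def one_way_anova(
    groups: Sequence[Sequence[float]],
) -> tuple[float, int, int, float, float]:
    """Fixed-effects one-way ANOVA.

    Returns (F, df_between, df_within, p, R²) where R² = SS_between /
    SS_total, the fraction of variance explained by group membership.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    if any(a.size == 0 for a in arrs):
        raise ValueError("empty group")
    all_vals = np.concatenate(arrs)
    grand = all_vals.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    ss_total = ((all_vals - grand) ** 2).sum()
    df_b = len(arrs) - 1
    df_w = all_vals.size - len(arrs)
    if df_w < 1:
        raise ValueError("no within-group degrees of freedom")
    if ss_within == 0:
        f = float("inf") if ss_between > 0 else 0.0
        p = 0.0 if ss_between > 0 else 1.0
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
        p = float(sps.f.sf(f, df_b, df_w))
    r2 = float(ss_between / ss_total) if ss_total > 0 else float("nan")
    return float(f), df_b, df_w, p, r2


def sidak_adjust(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Šídák multiple-comparison adjustment: p_adj = 1 - (1 - p)^m.

    ``m`` defaults to the number of p-values supplied.  Monotone in p and
    never larger than the Bonferroni bound m·p.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size if m is None else m
    return np.clip(1.0 - (1.0 - p) ** m, 0.0, 1.0)


def many_to_one_comparisons(
    groups: Sequence[Sequence[float]],
    reference_index: int = 0,
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Each group versus a reference, with Šídák-adjusted pooled-variance t.

    The pooled within-group variance and degrees of freedom come from the
    one-way ANOVA across all groups (not just each pair), as post hoc
    comparisons conventionally do; the Šídák correction runs over the
    ``n_groups - 1`` comparisons.  Raw p-values are reported alongside the
    adjusted ones.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if not 0 <= reference_index < len(arrs):
        raise ValueError("reference_index out of range")
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrs))]
    _, _, df_w, _, _ = one_way_anova(arrs)
    msw = sum(((a - a.mean()) ** 2).sum() for a in arrs) / df_w
    ref = arrs[reference_index]
    m = len(arrs) - 1
    rows = []
    for i, a in enumerate(arrs):
        if i == reference_index:
            continue
        se = np.sqrt(msw * (1.0 / a.size + 1.0 / ref.size))
        t = (a.mean() - ref.mean()) / se if se > 0 else 0.0
        p = 2.0 * sps.t.sf(abs(t), df_w)
        rows.append((labels[i], float(t), float(p)))
    out = pd.DataFrame(rows, columns=["group", "t", "p_raw"])
    out["p_adj"] = sidak_adjust(out["p_raw"].to_numpy(), m=m)
    return out


def two_way_anova_balanced(table: pd.DataFrame) -> pd.DataFrame:
    """Balanced two-factor fixed-effects ANOVA with interaction.

    ``table`` needs columns ``factor_a``, ``factor_b``, ``value`` with every
    (a, b) cell holding the same number of observations (>= 2 for an error
    term).  Returns one row per effect (A, B, AxB) with SS, df, MS, F, p.
    An unbalanced design raises — the simple sums-of-squares decomposition
    is only orthogonal for balanced data.
    """
    required = {"factor_a", "factor_b", "value"}
    if not required <= set(table.columns):
        raise ValueError(f"table needs columns {sorted(required)}")
    counts = table.groupby(["factor_a", "factor_b"], sort=False)["value"].count()
    a_levels = table["factor_a"].unique()
    b_levels = table["factor_b"].unique()
    if len(counts) != len(a_levels) * len(b_levels) or counts.nunique() != 1:
        raise ValueError("design must be fully crossed and balanced")
    n_cell = int(counts.iloc[0])
    if n_cell < 2:
        raise ValueError("need >= 2 observations per cell for an error term")

    grand = table["value"].mean()
    a_means = table.groupby("factor_a", sort=False)["value"].mean()
    b_means = table.groupby("factor_b", sort=False)["value"].mean()
    cell_means = table.groupby(["factor_a", "factor_b"], sort=False)["value"].mean()

    n_a, n_b = len(a_levels), len(b_levels)
    ss_a = n_cell * n_b * ((a_means - grand) ** 2).sum()
    ss_b = n_cell * n_a * ((b_means - grand) ** 2).sum()
    ss_cells = n_cell * ((cell_means - grand) ** 2).sum()
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = sum(
        ((sub["value"] - cell_means[key]) ** 2).sum()
        for key, sub in table.groupby(["factor_a", "factor_b"], sort=False)
    )
    df_a, df_b = n_a - 1, n_b - 1
    df_ab = df_a * df_b
    df_err = n_a * n_b * (n_cell - 1)
    ms_err = ss_err / df_err

    rows = []
    for name, ss, df in (("A", ss_a, df_a), ("B", ss_b, df_b), ("AxB", ss_ab, df_ab)):
        ms = ss / df if df > 0 else float("nan")
        if ms_err == 0:
            f = float("inf") if ss > 1e-12 else 0.0
            p = 0.0 if ss > 1e-12 else 1.0
        else:
            f = ms / ms_err
            p = float(sps.f.sf(f, df, df_err))
        rows.append((name, float(ss), df, float(ms), float(f), p))
    rows.append(("error", float(ss_err), df_err, float(ms_err), np.nan, np.nan))
    return pd.DataFrame(rows, columns=["effect", "ss", "df", "ms", "F", "p"])


def wilcoxon_signed_rank(values: Sequence[float], mu0: float = 0.0) -> tuple[float, float]:
    """Wilcoxon signed-rank test against a hypothetical value.

    Exact null distribution for n <= 25 without ties, normal approximation
    otherwise.  Returns (W, two-sided p).
    """
    v = np.asarray(values, dtype=float) - mu0
    v = v[v != 0]
    if v.size < 1:
        raise ValueError("all values equal mu0")
    mode = "exact" if (v.size <= 25 and np.unique(np.abs(v)).size == v.size) else "approx"
    w, p = sps.wilcoxon(v, alternative="two-sided", mode=mode)
    return float(w), float(p)


def anova_null_rejection_rate(
    n_groups: int,
    n_reps: int,
    cells_per_rep: int,
    rep_sd: float,
    cell_sd: float,
    n_sims: int,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Monte-Carlo type-I error of the replicate-mean one-way ANOVA.

    Simulates ``n_sims`` null datasets (all group means equal) with the
    two-level replicate/cell noise structure, averages cells to replicate
    means, and returns the fraction of simulations where the one-way ANOVA
    on replicate means rejects at level alpha.  Vectorized across
    simulations so large sweeps stay fast.
    """
    rng = np.random.default_rng(seed)
    reps = rng.normal(0.0, rep_sd, size=(n_sims, n_groups, n_reps))
    cells = rng.normal(0.0, cell_sd, size=(n_sims, n_groups, n_reps, cells_per_rep))
    rep_means = reps + cells.mean(axis=3)  # (sims, groups, reps)

    grand = rep_means.mean(axis=(1, 2), keepdims=True)
    group_means = rep_means.mean(axis=2, keepdims=True)
    ss_between = n_reps * ((group_means - grand) ** 2).sum(axis=(1, 2))
    ss_within = ((rep_means - group_means) ** 2).sum(axis=(1, 2))
    df_b = n_groups - 1
    df_w = n_groups * (n_reps - 1)
    f = (ss_between / df_b) / (ss_within / df_w)
    crit = sps.f.isf(alpha, df_b, df_w)
    return float(np.mean(f > crit))
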