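"""Diet-group comparisons per glycan and per derived trait.

The headline test is the classical unpaired (equal-variance) Student's
t-test, reported per time point and pooled over all time points, with the
conventional star coding of raw two-sided p-values.  Benjamini-Hochberg
adjusted p-values are always emitted as an auxiliary column since many
units are tested per stratum, but significance calls mirror the raw
p-values.
"""
from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def ttest_unpaired(
    x: Sequence[float], y: Sequence[float], equal_var: bool = True
) -> tuple[float, float]:
    """Two-sample t-test, two-sided, equal-variance by default.

    Missing values are dropped; fewer than two values in either group
    raises ``ValueError`` (callers report the reason instead of a number).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError(
            f"need >= 2 values per group, got {len(x)} and {len(y)}"
        )
    t, p = sps.ttest_ind(x, y, equal_var=equal_var)
    return float(t), float(p)


def stars(p: float) -> str:
    """Map a p-value to the conventional significance stars.

    ``p < 0.05 -> '*'``, ``< 0.01 -> '**'``, ``< 0.001 -> '***'``,
    ``< 0.0001 -> '****'``; otherwise ``'ns'``.  NaN maps to ``''``.
    """
    if not np.isfinite(p):
        return ""
    for threshold, label in STAR_THRESHOLDS:
        if p < threshold:
            return label
    return "ns"


def _compare_stratum(
    values: pd.DataFrame,
    meta: pd.DataFrame,
    idx: pd.Index,
    groups: tuple[str, str],
    week_label,
    sex_label: str,
    equal_var: bool,
) -> list[dict]:
    ref, alt = groups  # e.g. AL (reference), CR
    sub = values.loc[idx]
    g = meta.loc[idx, "group"]
    rows = []
    for unit in values.columns:
        a = sub.loc[g == ref, unit].dropna()
        b = sub.loc[g == alt, unit].dropna()
        row = {
            "unit": unit,
            "week": week_label,
            "sex": sex_label,
            f"n_{ref}": len(a),
            f"n_{alt}": len(b),
            f"mean_{ref}": a.mean() if len(a) else np.nan,
            f"sd_{ref}": a.std(ddof=1) if len(a) > 1 else np.nan,
            f"mean_{alt}": b.mean() if len(b) else np.nan,
            f"sd_{alt}": b.std(ddof=1) if len(b) > 1 else np.nan,
        }
        try:
            t, p = ttest_unpaired(a, b, equal_var=equal_var)
            row.update(t=t, p=p, reason="")
        except ValueError as exc:
            row.update(t=np.nan, p=np.nan, reason=str(exc))
        row["stars"] = stars(row["p"])
        diff = row[f"mean_{alt}"] - row[f"mean_{ref}"]
        row["direction"] = int(np.sign(diff)) if np.isfinite(diff) else 0
        rows.append(row)
    return rows


def compare_all(
    values: pd.DataFrame,
    meta: pd.DataFrame,
    groups: tuple[str, str] = ("AL", "CR"),
    per_week: bool = True,
    pooled: bool = True,
    by_sex: bool = False,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Group comparison of every unit (glycan or trait), per stratum.

    ``values`` is samples x units; ``meta`` shares the index and carries
    ``group``, ``sex`` and ``week``.  Strata are the individual weeks
    (``per_week``) and/or all weeks pooled (``pooled``, repeated measures
    of one mouse treated as independent samples); ``by_sex`` additionally
    splits every stratum by sex.  Empty strata are skipped with a log
    entry.  BH-adjusted p-values (``p_bh``) are computed across units
    within each stratum.
    """
    week_labels: list = []
    if per_week:
        week_labels += sorted(meta["week"].unique())
    if pooled:
        week_labels.append("pooled")
    sex_labels = ["pooled"] if not by_sex else sorted(meta["sex"].unique())

    rows: list[dict] = []
    for week in week_labels:
        for sex in sex_labels:
            sel = pd.Series(True, index=meta.index)
            if week != "pooled":
                sel &= meta["week"] == week
            if sex != "pooled":
                sel &= meta["sex"] == sex
            idx = meta.index[sel]
            if not len(idx):
                logger.info("empty stratum week=%s sex=%s skipped", week, sex)
                continue
            rows.extend(
                _compare_stratum(values, meta, idx, groups, week, sex, equal_var)
            )
    out = pd.DataFrame(rows)

    out["p_bh"] = np.nan
    for (week, sex), grp in out.groupby(["week", "sex"]):
        valid = grp["p"].notna()
        if valid.any():
            out.loc[grp.index[valid], "p_bh"] = multipletests(
                grp.loc[valid, "p"], method="fdr_bh"
            )[1]
    return out


def compare_sexes(
    values: pd.DataFrame,
    meta: pd.DataFrame,
    units: Sequence[str] | None = None,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Female-vs-male comparison of selected units within each diet group.

    Used for the sex-dependence of fucosylation traits.  Direction is
    ``sign(mean_F - mean_M)``.
    """
    units = list(units) if units is not None else list(values.columns)
    rows = []
    for group in sorted(meta["group"].unique()):
        idx = meta.index[meta["group"] == group]
        sub = values.loc[idx, units]
        sex = meta.loc[idx, "sex"]
        for unit in units:
            m = sub.loc[sex == "M", unit].dropna()
            f = sub.loc[sex == "F", unit].dropna()
            try:
                t, p = ttest_unpaired(m, f, equal_var=equal_var)
                reason = ""
            except ValueError as exc:
                t, p, reason = np.nan, np.nan, str(exc)
            diff = (f.mean() if len(f) else np.nan) - (
                m.mean() if len(m) else np.nan
            )
            rows.append(
                {
                    "unit": unit,
                    "group": group,
                    "n_M": len(m),
                    "n_F": len(f),
                    "mean_M": m.mean() if len(m) else np.nan,
                    "mean_F": f.mean() if len(f) else np.nan,
                    "t": t,
                    "p": p,
                    "stars": stars(p),
                    "direction": int(np.sign(diff)) if np.isfinite(diff) else 0,
                    "reason": reason,
                }
            )
    return pd.DataFrame(rows)


def heatmap_matrix(
    values: pd.DataFrame,
    meta: pd.DataFrame,
    transform=np.log10,
) -> tuple[pd.DataFrame, int]:
    """log10-transformed samples x glycans matrix in deterministic order.

    Rows are ordered by (group, sex, week, mouse); columns keep the panel
    order.  Nonpositive or missing ratios are masked (NaN) and counted.
    Returns ``(matrix, number of masked nonpositive cells)``.
    """
    order = meta.sort_values(["group", "sex", "week", "mouse_id"]).index
    vals = values.loc[order]
    nonpos = (vals <= 0).to_numpy().sum()
    masked = vals.where(vals > 0)
    return transform(masked), int(nonpos)


def plot_heatmap(matrix: pd.DataFrame, meta: pd.DataFrame, path) -> None:
    """Write the group/week-annotated glycan heatmap."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    fig, ax = plt.subplots(
        figsize=(max(6, 0.22 * matrix.shape[1]), max(4, 0.04 * matrix.shape[0]))
    )
    sns.heatmap(matrix, ax=ax, cmap="vlag", center=0,
                cbar_kws={"label": "log10 light/heavy ratio"})
    ax.set_yticks([])
    ax.set_xlabel("glycan")
    ax.set_ylabel("samples (group / sex / week)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_traits(
    traits: pd.DataFrame, meta: pd.DataFrame, path,
    groups: tuple[str, str] = ("AL", "CR"),
) -> None:
    """Write per-trait group box plots (all time points pooled)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    long = traits.join(meta["group"]).melt(
        id_vars="group", var_name="trait", value_name="value"
    )
    n = traits.shape[1]
    ncols = 6
    nrows = -(-n // ncols)
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(3 * ncols, 2.6 * nrows), squeeze=False
    )
    for ax, trait in zip(axes.ravel(), traits.columns):
        sns.boxplot(
            data=long[long["trait"] == trait], x="group", y="value",
            order=list(groups), ax=ax,
        )
        ax.set_title(trait, fontsize=9)
        ax.set_xlabel("")
        ax.set_ylabel("")
    for ax in axes.ravel()[n:]:
        ax.set_visible(False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
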