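"""Correlation of genetic distance with hybrid performance and heterosis.

All correlations are Pearson's r on pairwise-complete observations, tested
two-sided via the t transform ``t = r * sqrt((n-2) / (1-r^2))`` with ``n-2``
degrees of freedom, and stratified by male-parent population (the male is a
design factor in an NC II factorial, so pooling across males would conflate
male effects with the GD gradient).  Significance marks follow the
conventional footnote rule: ``*`` for p < 0.05, ``**`` for p < 0.01.

Group contrasts between hybrid sets (e.g. Elite x Elite vs Historic x Elite)
use pairwise Welch t-tests with Holm adjustment within each trait.
"""

from __future__ import annotations

from itertools import combinations
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PearsonResult",
    "pearson",
    "significance_mark",
    "correlate_gd_with",
    "correlate_parent_with_f1",
    "compare_groups",
]


class PearsonResult(NamedTuple):
    r: float
    p: float
    n: int
    defined: bool


def pearson(x, y) -> PearsonResult:
    """Pearson correlation on pairwise-complete pairs with a two-sided p.

    Undefined (fewer than 3 complete pairs, or zero variance in either
    series) is returned as a flagged result, never silently as NaN noise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must be paired")
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < 3:
        return PearsonResult(np.nan, np.nan, n, False)
    xs, ys = x[mask], y[mask]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return PearsonResult(np.nan, np.nan, n, False)
    r, p = scipy.stats.pearsonr(xs, ys)
    return PearsonResult(float(r), float(p), n, True)


def significance_mark(p: float) -> str:
    """``"**"`` for p < 0.01, ``"*"`` for p < 0.05, else empty."""
    if not np.isfinite(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


_METRIC_COLUMNS = {"F1": "f1", "MPH": "mph", "BPH": "bph"}


def correlate_gd_with(
    metric: str,
    cross_gd: pd.DataFrame,
    heterosis: pd.DataFrame,
    design: pd.DataFrame,
) -> pd.DataFrame:
    """Correlate GD (both marker systems) with an F1 metric per male x trait.

    ``metric`` is one of ``"F1"``, ``"MPH"``, ``"BPH"``; one output row per
    (male population, trait, marker system), with n, r, p and the
    significance mark.  Strata with fewer than 3 complete crosses are
    reported undefined.
    """
    if metric not in _METRIC_COLUMNS:
        raise ValueError(f"metric must be one of {sorted(_METRIC_COLUMNS)}")
    ycol = _METRIC_COLUMNS[metric]
    merged = heterosis.merge(
        cross_gd[["cross", "gd_ssr", "gd_snp"]], on="cross", how="left"
    )
    males = list(pd.unique(design["male"]))
    rows = []
    for male in males:
        sub = merged[merged["male"] == male]
        for trait, tgrp in sub.groupby("trait", sort=True):
            for system in ("gd_ssr", "gd_snp"):
                res = pearson(tgrp[system].to_numpy(), tgrp[ycol].to_numpy())
                rows.append(
                    {
                        "stratum": male,
                        "trait": trait,
                        "x": system,
                        "y": metric,
                        "n": res.n,
                        "r": res.r,
                        "p": res.p,
                        "sig": significance_mark(res.p) if res.defined else "",
                        "defined": res.defined,
                    }
                )
    return pd.DataFrame(rows)


def correlate_parent_with_f1(
    means: pd.DataFrame,
    heterosis: pd.DataFrame,
    design: pd.DataFrame,
) -> pd.DataFrame:
    """Correlate the mid-parent value with F1 performance, MPH and BPH.

    The parent statistic is the mid-parent mean (reported in the ``x``
    column as ``mid_parent``); one row per (male population, trait, target).
    """
    males = list(pd.unique(design["male"]))
    rows = []
    for male in males:
        sub = heterosis[heterosis["male"] == male]
        for trait, tgrp in sub.groupby("trait", sort=True):
            for target in ("F1", "MPH", "BPH"):
                ycol = _METRIC_COLUMNS[target]
                res = pearson(tgrp["mp"].to_numpy(), tgrp[ycol].to_numpy())
                rows.append(
                    {
                        "stratum": male,
                        "trait": trait,
                        "x": "mid_parent",
                        "y": target,
                        "n": res.n,
                        "r": res.r,
                        "p": res.p,
                        "sig": significance_mark(res.p) if res.defined else "",
                        "defined": res.defined,
                    }
                )
    return pd.DataFrame(rows)


def compare_groups(
    values: pd.DataFrame,
    value_col: str = "value",
    group_col: str = "group",
    trait_col: str | None = "trait",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All pairwise Welch t-tests between groups, Holm-adjusted within trait.

    Each symmetric pair is reported once (group_a < group_b by sort order).
    Degenerate pairs (a group with fewer than 2 observations or both groups
    with zero variance) are flagged untestable and excluded from the Holm
    family.
    """
    df = values.copy()
    if trait_col is None:
        trait_col = "_trait"
        df[trait_col] = "all"
    rows = []
    for trait, tgrp in df.groupby(trait_col, sort=True):
        groups = sorted(tgrp[group_col].unique(), key=str)
        if len(groups) < 2:
            raise ValueError(f"need >= 2 groups for trait {trait!r}")
        samples = {
            g: tgrp.loc[tgrp[group_col] == g, value_col].dropna().to_numpy()
            for g in groups
        }
        trows = []
        for ga, gb in combinations(groups, 2):
            a, b = samples[ga], samples[gb]
            untestable = (
                len(a) < 2
                or len(b) < 2
                or (np.ptp(a) == 0 and np.ptp(b) == 0)
            )
            if untestable:
                t_stat, p_raw = np.nan, np.nan
            else:
                t_stat, p_raw = scipy.stats.ttest_ind(a, b, equal_var=False)
            trows.append(
                {
                    "trait": trait,
                    "group_a": ga,
                    "group_b": gb,
                    "n_a": len(a),
                    "n_b": len(b),
                    "mean_a": a.mean() if len(a) else np.nan,
                    "mean_b": b.mean() if len(b) else np.nan,
                    "t": t_stat,
                    "p_raw": p_raw,
                    "untestable": untestable,
                }
            )
        testable = [r for r in trows if not r["untestable"]]
        if testable:
            _rej, p_adj, _a, _b = multipletests(
                [r["p_raw"] for r in testable], alpha=alpha, method="holm"
            )
            for r, pa in zip(testable, p_adj):
                r["p_adj"] = float(pa)
        for r in trows:
            r.setdefault("p_adj", np.nan)
            r["significant"] = bool(np.isfinite(r["p_adj"]) and r["p_adj"] < alpha)
        rows.extend(trows)
    return pd.DataFrame(rows)
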