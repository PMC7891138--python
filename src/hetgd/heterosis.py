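"""Mid-parent and best-parent heterosis from multi-environment phenotypes.

Phenotype records (entity x trait x year x site) are first averaged over
environments, then each cross x trait gets

    MPH = [F1 - (P1 + P2)/2] / [(P1 + P2)/2] * 100%
    BPH = (F1 - HP) / HP * 100%,        HP = max(P1, P2)

For strictly positive parental values MPH >= BPH always (HP >= MP implies
F1/HP <= F1/MP).  Ratio heterosis is ill-behaved around non-positive
denominators: rows with MP = 0 or HP = 0 are flagged undefined, rows with a
negative MP or HP are computed as printed but flagged ``sign_caution``.
Percentages are carried at full precision; rounding happens only at report
time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import TRAITS

__all__ = [
    "TRAITS",
    "validate_phenotypes",
    "aggregate_environments",
    "compute_heterosis",
    "heterosis_summary",
]

_PHENO_COLUMNS = ("entity", "trait", "year", "site", "value")


def validate_phenotypes(
    phenotypes: pd.DataFrame, allowed_traits: tuple[str, ...] | None = TRAITS
) -> pd.DataFrame:
    """Check the phenotype-record layout and (optionally) the trait vocabulary."""
    missing = [c for c in _PHENO_COLUMNS if c not in phenotypes.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns: {missing}")
    if allowed_traits is not None:
        bad = set(phenotypes["trait"]) - set(allowed_traits)
        if bad:
            raise ValueError(f"unknown trait codes: {sorted(bad)}")
    if np.isinf(phenotypes["value"].to_numpy(dtype=float)).any():
        raise ValueError("phenotype values must be finite or NaN")
    return phenotypes


def aggregate_environments(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean over year x site records per entity x trait.

    Returns columns ``entity, trait, value, n_env`` where ``n_env`` counts
    the contributing (non-missing) records; entity x trait cells with no
    non-missing record carry NaN.
    """
    validate_phenotypes(phenotypes, allowed_traits=None)
    grp = phenotypes.groupby(["entity", "trait"], sort=False)["value"]
    out = grp.agg(value="mean", n_env="count").reset_index()
    return out


def _mean_lookup(means: pd.DataFrame) -> pd.Series:
    dup = means.duplicated(["entity", "trait"])
    if dup.any():
        raise ValueError("duplicate entity x trait rows in aggregated means")
    return means.set_index(["entity", "trait"])["value"]


def compute_heterosis(design: pd.DataFrame, means: pd.DataFrame) -> pd.DataFrame:
    """Per-cross, per-trait F1/MP/HP values and MPH/BPH percentages.

    ``means`` is the output of :func:`aggregate_environments` covering the F1
    entities (named by cross id) and both parents.  A cross x trait with any
    of the three means missing is flagged ``missing`` (kept as a row, values
    NaN), never dropped silently.
    """
    lookup = _mean_lookup(means)
    traits = list(pd.unique(means["trait"]))
    design = design.reset_index(drop=True)
    grid = design.loc[design.index.repeat(len(traits))].reset_index(drop=True)
    grid["trait"] = traits * len(design)

    def get(entities: pd.Series) -> np.ndarray:
        idx = pd.MultiIndex.from_arrays([entities, grid["trait"]])
        return lookup.reindex(idx).to_numpy(dtype=float)

    f1 = get(grid["cross"])
    p1 = get(grid["male"])
    p2 = get(grid["female"])
    mp = (p1 + p2) / 2.0
    hp = np.maximum(p1, p2)
    missing = np.isnan(f1) | np.isnan(p1) | np.isnan(p2)
    undefined = (~missing) & ((mp == 0) | (hp == 0))
    ok = ~(missing | undefined)
    mph = np.full(len(grid), np.nan)
    bph = np.full(len(grid), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        mph[ok] = (f1[ok] - mp[ok]) / mp[ok] * 100.0
        bph[ok] = (f1[ok] - hp[ok]) / hp[ok] * 100.0
    flag = np.where(
        missing, "missing",
        np.where(undefined, "undefined",
                 np.where((mp < 0) | (hp < 0), "sign_caution", "")),
    )
    out = grid[["cross", "male", "female", "trait"]].copy()
    out["f1"] = f1
    out["mp"] = np.where(missing, np.nan, mp)
    out["hp"] = np.where(missing, np.nan, hp)
    out["mph"] = mph
    out["bph"] = bph
    out["flag"] = flag
    return out


def heterosis_summary(
    table: pd.DataFrame, by: str | pd.Series | None = None
) -> pd.DataFrame:
    """Per-trait MPH/BPH summaries over the defined rows.

    Reports mean/min/max of MPH and BPH plus the percentage of crosses with
    positive MPH and positive BPH (one decimal).  ``by`` optionally adds a
    stratification column: either a column name of ``table`` (e.g.
    ``"male"``) or a Series mapping cross id to a group.
    """
    defined = table[table["flag"].isin(("", "sign_caution"))].copy()
    if defined.empty:
        raise ValueError("no defined heterosis rows to summarize")
    keys = ["trait"]
    if by is not None:
        if isinstance(by, str):
            defined["stratum"] = defined[by]
        else:
            defined["stratum"] = defined["cross"].map(by)
        keys = ["stratum", "trait"]
    rows = []
    for key, grp in defined.groupby(keys, sort=True):
        row = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        row["n"] = len(grp)
        for col in ("mph", "bph"):
            row[f"{col}_mean"] = grp[col].mean()
            row[f"{col}_min"] = grp[col].min()
            row[f"{col}_max"] = grp[col].max()
            row[f"pct_positive_{col}"] = round(100.0 * (grp[col] > 0).mean(), 1)
        rows.append(row)
    return pd.DataFrame(rows)
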