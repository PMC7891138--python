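"""Parental genetic distance from SSR band sharing and SNP identity-by-state.

Two classical measures:

* ``GD_SSR = 1 - 2*N_ab / (N_a + N_b)`` (Nei-Li band sharing): over the
  markers scored in both accessions, each distinct allele is a band; ``N_a``
  and ``N_b`` are band counts in the two accessions and ``N_ab`` the bands
  shared, counted per marker and summed panel-wide before the formula is
  applied.
* ``GD_SNP = 1 - IBS``: per-site similarity is the number of shared allele
  copies between two diploid genotypes divided by two (0, 0.5 or 1), averaged
  over pairwise-complete sites.

Missing data is handled by pairwise-complete deletion; the number of
markers/sites actually used is recorded per pair as ``support``, and a pair
with no shared data is undefined (NaN), never 0.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genotypes import MISSING, SNPGenotypes, SSRGenotypes

__all__ = [
    "DistanceMatrix",
    "gd_ssr_matrix",
    "gd_snp_matrix",
    "cross_gd",
    "gd_population_summary",
]


@dataclasses.dataclass
class DistanceMatrix:
    """Symmetric pairwise genetic distances in [0, 1] with per-pair support.

    ``values[i, j]`` is NaN where the pair is undefined (no shared data);
    ``support[i, j]`` counts the markers/sites used for the pair.
    """

    labels: list[str]
    values: np.ndarray
    support: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.values.shape != (n, n) or self.support.shape != (n, n):
            raise ValueError("matrix shapes must match label count")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        finite = np.isfinite(self.values)
        if np.any((self.values[finite] < -1e-9) | (self.values[finite] > 1 + 1e-9)):
            raise ValueError("distances must lie in [0, 1]")

    def lookup(self, a: str, b: str) -> float:
        try:
            i = self.labels.index(a)
            j = self.labels.index(b)
        except ValueError as e:
            raise KeyError(f"accession missing from distance matrix: {e}") from None
        return float(self.values[i, j])

    def subset(self, ids: Sequence[str]) -> "DistanceMatrix":
        index = {s: i for i, s in enumerate(self.labels)}
        try:
            rows = [index[s] for s in ids]
        except KeyError as e:
            raise KeyError(f"accession {e.args[0]!r} missing from matrix") from None
        ix = np.ix_(rows, rows)
        return DistanceMatrix(list(ids), self.values[ix], self.support[ix])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_phylip(self) -> str:
        """Square PHYLIP distance-format rendering (full precision)."""
        lines = [f"    {len(self.labels)}"]
        for lab, row in zip(self.labels, self.values):
            lines.append(lab + "  " + "  ".join(repr(float(v)) for v in row))
        return "\n".join(lines) + "\n"


def _finalize(labels, numer, denom, support, what: str) -> DistanceMatrix:
    undefined = support == 0
    if undefined.any():
        n_pairs = int(np.triu(undefined, 1).sum())
        if n_pairs:
            warnings.warn(
                f"{n_pairs} accession pair(s) share no {what}; "
                "their distances are undefined",
                stacklevel=3,
            )
    with np.errstate(invalid="ignore", divide="ignore"):
        gd = np.where(undefined, np.nan, numer / np.where(denom == 0, 1, denom))
    np.fill_diagonal(gd, np.where(np.diag(support) > 0, 0.0, np.nan))
    return DistanceMatrix(labels=list(labels), values=gd, support=support)


def gd_ssr_matrix(
    genotypes: SSRGenotypes, pairs: Iterable[tuple[str, str]] | None = None
) -> DistanceMatrix:
    """Nei-Li band-sharing distance between all accession pairs.

    Heterozygotes contribute two bands, homozygotes one; only markers scored
    in both members of a pair enter its band counts.  ``pairs`` optionally
    restricts the computation to the accessions involved in the listed pairs.
    """
    if genotypes.n_markers == 0:
        raise ValueError("at least one SSR marker required")
    if pairs is not None:
        involved = sorted({a for p in pairs for a in p})
        genotypes = _subset_ssr(genotypes, involved)
    # Band-presence matrix: rows accessions, columns (marker, allele) bands.
    band_index: dict[tuple[int, int], int] = {}
    for m, alleles in enumerate(genotypes.observed_alleles()):
        for a in sorted(alleles):
            band_index[(m, a)] = len(band_index)
    n, nb, nm = genotypes.n_samples, len(band_index), genotypes.n_markers
    bands = np.zeros((n, nb), dtype=np.int64)
    sizes = np.zeros((n, nm), dtype=np.int64)  # bands per marker; 0 if missing
    for m in range(nm):
        for i, prof in enumerate(genotypes.calls[m, :]):
            if prof is None:
                continue
            sizes[i, m] = len(prof)
            for a in prof:
                bands[i, band_index[(m, a)]] = 1
    present = (sizes > 0).astype(np.int64)
    n_ab = bands @ bands.T
    # Band counts restricted to markers present in BOTH members of the pair.
    n_a = sizes @ present.T
    support = present @ present.T
    denom = n_a + n_a.T
    return _finalize(
        genotypes.samples, denom - 2 * n_ab, denom, support, "scored SSR markers"
    )


def _subset_ssr(genotypes: SSRGenotypes, ids: Sequence[str]) -> SSRGenotypes:
    index = {s: i for i, s in enumerate(genotypes.samples)}
    try:
        cols = [index[s] for s in ids]
    except KeyError as e:
        raise KeyError(f"accession {e.args[0]!r} not genotyped") from None
    return SSRGenotypes(
        samples=list(ids),
        markers=genotypes.markers.copy(),
        calls=genotypes.calls[:, cols],
    )


def gd_snp_matrix(
    genotypes: SNPGenotypes, pairs: Iterable[tuple[str, str]] | None = None
) -> DistanceMatrix:
    """Identity-by-state distance ``1 - IBS`` between all accession pairs.

    Per-site allele sharing between dosages ``d1, d2`` is ``1 - |d1 - d2|/2``
    (the size of the unordered allele-multiset intersection over two), so the
    summed dissimilarity over pairwise-complete sites is ``sum |d1 - d2| / 2``.
    """
    if genotypes.n_sites == 0:
        raise ValueError("at least one SNP site required")
    if pairs is not None:
        involved = sorted({a for p in pairs for a in p})
        genotypes = genotypes.take_samples(involved)
    d = genotypes.dosage
    valid = (d != MISSING).astype(np.int64)
    a0 = ((d == 0) & (d != MISSING)).astype(np.int64)
    a1 = (d == 1).astype(np.int64)
    a2 = (d == 2).astype(np.int64)
    # sum over shared sites of |d_i - d_j|:
    diff = (
        a0 @ a1.T + a1 @ a0.T + a1 @ a2.T + a2 @ a1.T + 2 * (a0 @ a2.T + a2 @ a0.T)
    )
    support = valid @ valid.T
    return _finalize(
        genotypes.samples,
        diff.astype(float),
        (2 * support).astype(float),
        support,
        "called SNP sites",
    )


def cross_gd(
    design: pd.DataFrame,
    ssr_dm: DistanceMatrix | None = None,
    snp_dm: DistanceMatrix | None = None,
) -> pd.DataFrame:
    """Per-cross male-female genetic distance under each marker system.

    Returns one row per design cross with columns ``cross, male, female,
    gd_ssr, gd_snp`` (NaN where a system was not supplied or the pair is
    undefined).  A design parent absent from a supplied matrix raises a
    ``KeyError`` naming the parent.
    """
    if ssr_dm is None and snp_dm is None:
        raise ValueError("at least one distance matrix required")
    out = design[["cross", "male", "female"]].copy()
    for name, dm in (("gd_ssr", ssr_dm), ("gd_snp", snp_dm)):
        if dm is None:
            out[name] = np.nan
            continue
        index = {s: i for i, s in enumerate(dm.labels)}
        for parent in pd.unique(pd.concat([design["male"], design["female"]])):
            if parent not in index:
                raise KeyError(f"design parent {parent!r} missing from {name} matrix")
        mi = out["male"].map(index).to_numpy()
        fi = out["female"].map(index).to_numpy()
        out[name] = dm.values[mi, fi]
    return out


def gd_population_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-male-population GD summary: min/max/mean per marker system plus the
    Pearson correlation between SSR- and SNP-based GD within the male's
    crosses.

    Summaries use defined values only; the correlation is undefined (NaN)
    with fewer than 3 complete pairs or zero variance.
    """
    from .association import pearson

    rows = []
    for male, grp in table.groupby("male", sort=True):
        row: dict[str, object] = {"male": male, "n_crosses": len(grp)}
        for sys in ("gd_ssr", "gd_snp"):
            vals = grp[sys].dropna()
            row[f"{sys}_min"] = vals.min() if len(vals) else np.nan
            row[f"{sys}_max"] = vals.max() if len(vals) else np.nan
            row[f"{sys}_mean"] = vals.mean() if len(vals) else np.nan
        res = pearson(grp["gd_ssr"].to_numpy(), grp["gd_snp"].to_numpy())
        row["r"] = res.r
        row["p"] = res.p
        row["n_pairs"] = res.n
        rows.append(row)
    return pd.DataFrame(rows)
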