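"""Band-sharing and IBS distance: hand examples, oracle equivalence, invariants."""

import numpy as np
import pandas as pd
import pytest

from hetgd import (
    cross_gd,
    derive_f1_genotypes,
    gd_population_summary,
    gd_snp_matrix,
    gd_ssr_matrix,
    make_ncii_design,
)
from hetgd.genotypes import MISSING, SNPGenotypes, SSRGenotypes

from conftest import random_snp_panel, random_ssr_panel


# ---------------------------------------------------------------------------
# Independent brute-force oracles (naive double loops over markers/sites)
# ---------------------------------------------------------------------------


def brute_gd_ssr(geno: SSRGenotypes, i: int, j: int):
    n_a = n_b = n_ab = used = 0
    for m in range(geno.n_markers):
        a, b = geno.calls[m, i], geno.calls[m, j]
        if a is None or b is None:
            continue
        used += 1
        n_a += len(a)
        n_b += len(b)
        n_ab += len(set(a) & set(b))
    if used == 0:
        return np.nan, 0
    return 1.0 - 2.0 * n_ab / (n_a + n_b), used


def brute_gd_snp(geno: SNPGenotypes, i: int, j: int):
    total = used = 0
    for s in range(geno.n_sites):
        d1, d2 = int(geno.dosage[i, s]), int(geno.dosage[j, s])
        if d1 == MISSING or d2 == MISSING:
            continue
        used += 1
        a1 = ["r", "a"][d1 // 2] * 2 if d1 != 1 else "ra"
        a2 = ["r", "a"][d2 // 2] * 2 if d2 != 1 else "ra"
        # unordered allele multiset intersection size
        shared = 0
        pool = list(a2)
        for al in a1:
            if al in pool:
                pool.remove(al)
                shared += 1
        total += shared / 2.0
    if used == 0:
        return np.nan, 0
    return 1.0 - total / used, used


def _ssr_from_profiles(profiles):
    """profiles: dict accession -> list of per-marker frozensets/None."""
    samples = list(profiles)
    nm = len(next(iter(profiles.values())))
    calls = np.empty((nm, len(samples)), dtype=object)
    for c, s in enumerate(samples):
        for m in range(nm):
            calls[m, c] = profiles[s][m]
    markers = pd.DataFrame(
        {"marker": [f"m{m}" for m in range(nm)], "chrom": ["c"] * nm}
    )
    return SSRGenotypes(samples, markers, calls)


# ---------------------------------------------------------------------------
# Hand-evaluated examples
# ---------------------------------------------------------------------------


def test_ssr_identical_profiles_distance_zero():
    g = _ssr_from_profiles(
        {"a": [frozenset({1}), frozenset({2, 3})],
         "b": [frozenset({1}), frozenset({2, 3})]}
    )
    assert gd_ssr_matrix(g).lookup("a", "b") == pytest.approx(0.0)


def test_ssr_disjoint_bands_distance_one():
    g = _ssr_from_profiles(
        {"a": [frozenset({1}), frozenset({2})],
         "b": [frozenset({3}), frozenset({4})]}
    )
    assert gd_ssr_matrix(g).lookup("a", "b") == pytest.approx(1.0)


def test_ssr_partial_sharing_formula():
    # panel-wide bands a={1,2 | 3}, b={2 | 3,4} (bands are marker-scoped):
    # N_a=3, N_b=3, N_ab=2 -> GD = 1 - 2*2/(3+3) = 1/3
    g = _ssr_from_profiles(
        {"a": [frozenset({1, 2}), frozenset({3})],
         "b": [frozenset({2}), frozenset({3, 4})]}
    )
    assert gd_ssr_matrix(g).lookup("a", "b") == pytest.approx(1 / 3)


def _snp_from_dosages(dosages):
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    sites = pd.DataFrame(
        {"chrom": ["Chr01"] * m, "pos": np.arange(1, m + 1), "ref": ["A"] * m,
         "alt": ["G"] * m}
    )
    return SNPGenotypes([f"S{i}" for i in range(n)], sites, dosages)


def test_snp_identical_and_opposite_homozygotes():
    g = _snp_from_dosages([[0, 2, 0], [0, 2, 0], [2, 0, 2]])
    dm = gd_snp_matrix(g)
    assert dm.lookup("S0", "S1") == pytest.approx(0.0)
    assert dm.lookup("S0", "S2") == pytest.approx(1.0)


def test_snp_half_sharing_site():
    # sites: (ref/ref vs ref/ref)=1.0 and (ref/ref vs ref/alt)=0.5
    g = _snp_from_dosages([[0, 0], [0, 1]])
    assert gd_snp_matrix(g).lookup("S0", "S1") == pytest.approx(0.25)


# ---------------------------------------------------------------------------
# Oracle equivalence and invariants
# ---------------------------------------------------------------------------


def test_matrices_match_bruteforce_on_random_instances():
    rng = np.random.default_rng(2024)
    for _ in range(10):
        ssr = random_ssr_panel(rng)
        snp = random_snp_panel(rng)
        sdm, ndm = gd_ssr_matrix(ssr), gd_snp_matrix(snp)
        for i in range(6):
            for j in range(6):
                es, sup_s = brute_gd_ssr(ssr, i, j)
                en, sup_n = brute_gd_snp(snp, i, j)
                np.testing.assert_allclose(sdm.values[i, j], es, atol=1e-12)
                np.testing.assert_allclose(ndm.values[i, j], en, atol=1e-12)
                assert sdm.support[i, j] == sup_s
                assert ndm.support[i, j] == sup_n


def test_symmetry_bounds_and_zero_diagonal(small_study):
    for dm in (gd_ssr_matrix(small_study["ssr"]), gd_snp_matrix(small_study["snp"])):
        np.testing.assert_allclose(dm.values, dm.values.T, equal_nan=True)
        finite = dm.values[np.isfinite(dm.values)]
        assert finite.min() >= 0 and finite.max() <= 1
        assert np.allclose(np.diag(dm.values), 0)


def test_pairwise_complete_deletion_ignores_half_missing_marker():
    base = {"a": [frozenset({1}), frozenset({2})],
            "b": [frozenset({1}), frozenset({3})],
            "c": [frozenset({9}), frozenset({9})]}
    g1 = _ssr_from_profiles(base)
    withhole = {k: list(v) for k, v in base.items()}
    withhole["c"][0] = None  # marker missing only in a non-member of the pair
    g2 = _ssr_from_profiles(withhole)
    assert gd_ssr_matrix(g1).lookup("a", "b") == gd_ssr_matrix(g2).lookup("a", "b")
    # and a marker missing in one member of the pair never changes its GD
    drop = {k: list(v) for k, v in base.items()}
    drop["a"][1] = None
    only_first = {k: [v[0]] for k, v in base.items()}
    assert gd_ssr_matrix(_ssr_from_profiles(drop)).lookup("a", "b") == pytest.approx(
        gd_ssr_matrix(_ssr_from_profiles(only_first)).lookup("a", "b")
    )


def test_zero_shared_markers_undefined_with_warning():
    g = _ssr_from_profiles({"a": [frozenset({1}), None],
                            "b": [None, frozenset({2})]})
    with pytest.warns(UserWarning, match="undefined"):
        dm = gd_ssr_matrix(g)
    assert np.isnan(dm.lookup("a", "b"))
    assert dm.support[0, 1] == 0


def test_parental_gd_equals_f1_heterozygosity(small_study):
    snp, design = small_study["snp"], small_study["design"]
    f1 = small_study["f1"]
    dm = gd_snp_matrix(snp)
    for row in design.iloc[:10].itertuples():
        i = f1.samples.index(row.cross)
        called = f1.dosage[i] != MISSING
        het = (f1.dosage[i][called] == 1).mean()
        assert dm.lookup(row.male, row.female) == pytest.approx(het, abs=1e-12)


# ---------------------------------------------------------------------------
# Cross tables and population summaries
# ---------------------------------------------------------------------------


def test_cross_gd_matches_matrix_lookups(small_study):
    ssr_dm = gd_ssr_matrix(small_study["ssr"])
    snp_dm = gd_snp_matrix(small_study["snp"])
    table = cross_gd(small_study["design"], ssr_dm, snp_dm)
    assert len(table) == len(small_study["design"])
    rng = np.random.default_rng(1)
    for k in rng.choice(len(table), size=20):
        row = table.iloc[int(k)]
        assert row["gd_ssr"] == pytest.approx(ssr_dm.lookup(row["male"], row["female"]), nan_ok=True)
        assert row["gd_snp"] == pytest.approx(snp_dm.lookup(row["male"], row["female"]), nan_ok=True)


def test_cross_gd_missing_parent_named():
    design = make_ncii_design(["M1"], ["F1"])
    g = _snp_from_dosages([[0], [2]])
    dm = gd_snp_matrix(g)
    with pytest.raises(KeyError, match="M1"):
        cross_gd(design, None, dm)


def test_population_summary_against_bruteforce(small_study):
    table = cross_gd(
        small_study["design"],
        gd_ssr_matrix(small_study["ssr"]),
        gd_snp_matrix(small_study["snp"]),
    )
    summary = gd_population_summary(table).set_index("male")
    for male, grp in table.groupby("male"):
        vals = grp["gd_snp"].dropna()
        assert summary.loc[male, "gd_snp_mean"] == pytest.approx(vals.mean())
        assert summary.loc[male, "gd_snp_min"] == pytest.approx(vals.min())
        assert summary.loc[male, "gd_snp_max"] == pytest.approx(vals.max())
        both = grp[["gd_ssr", "gd_snp"]].dropna()
        r = np.corrcoef(both["gd_ssr"], both["gd_snp"])[0, 1]
        assert summary.loc[male, "r"] == pytest.approx(r, abs=1e-12)


def test_population_summary_zero_variance_undefined():
    table = pd.DataFrame(
        {"cross": ["c1", "c2", "c3"], "male": ["M"] * 3,
         "female": ["a", "b", "c"], "gd_ssr": [0.2, 0.2, 0.2],
         "gd_snp": [0.1, 0.3, 0.5]}
    )
    s = gd_population_summary(table)
    assert s.loc[0, "gd_ssr_min"] == s.loc[0, "gd_ssr_max"]
    assert s.loc[0, "gd_ssr_mean"] == pytest.approx(s.loc[0, "gd_ssr_min"])
    assert np.isnan(s.loc[0, "r"])
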