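"""SSR/SNP container, I/O and filtering behavior."""

import numpy as np
import pandas as pd
import pytest

from hetgd.genotypes import (
    MISSING,
    GenotypeFormatError,
    GenotypeParseError,
    SNPGenotypes,
    filter_polymorphic_ssr,
    filter_snps,
    marker_summary,
    read_ssr_table,
    read_vcf,
    write_ssr_table,
    write_vcf,
)

from conftest import random_snp_panel, random_ssr_panel


# ---------------------------------------------------------------------------
# SSR dialect
# ---------------------------------------------------------------------------


SSR_TOY = (
    "marker\tchrom\tAcc1\tAcc2\tAcc3\n"
    "SSR1\tChr01\t120/124\t120\t.\n"
    "SSR2\tChr02\t98\t98/102\t102\n"
)


def test_ssr_toy_parse_and_cells(tmp_path):
    path = tmp_path / "ssr.tsv"
    path.write_text(SSR_TOY)
    g = read_ssr_table(path)
    assert g.samples == ["Acc1", "Acc2", "Acc3"]
    assert g.n_markers == 2
    assert g.calls[0, 0] == frozenset({120, 124})  # "120/124" -> 2 bands
    assert g.calls[0, 1] == frozenset({120})
    assert g.calls[0, 2] is None  # "." is missing
    assert g.calls[1, 2] == frozenset({102})


def test_ssr_round_trip_byte_identical(tmp_path):
    p1 = tmp_path / "a.tsv"
    p1.write_text(SSR_TOY)
    g = read_ssr_table(p1)
    p2 = tmp_path / "b.tsv"
    write_ssr_table(g, p2)
    assert p2.read_text() == SSR_TOY


def test_ssr_round_trip_simulated(tmp_path, small_study):
    g = small_study["ssr"]
    path = tmp_path / "sim.tsv"
    write_ssr_table(g, path)
    back = read_ssr_table(path)
    assert back.samples == g.samples
    assert (back.markers["marker"] == g.markers["marker"]).all()
    assert all(
        back.calls[m, i] == g.calls[m, i]
        for m in range(g.n_markers)
        for i in range(g.n_samples)
    )


@pytest.mark.parametrize(
    "text,match",
    [
        ("marker\tchrom\tA\tA\nSSR1\tChr01\t1\t2\n", "duplicate"),
        ("marker\tchrom\tA\tB\nSSR1\tChr01\tx\t2\n", "malformed"),
        ("marker\tchrom\tA\nSSR1\tChr01\t1/2/3\n", "1 or 2"),
        ("badheader\tchrom\tA\nSSR1\tChr01\t1\n", "header"),
    ],
)
def test_ssr_parse_errors(tmp_path, text, match):
    path = tmp_path / "bad.tsv"
    path.write_text(text)
    with pytest.raises(GenotypeParseError, match=match):
        read_ssr_table(path)


def test_ssr_empty_marker_list_header_only(tmp_path):
    g = read_ssr_table_from(tmp_path, "marker\tchrom\tA\tB\n")
    path = tmp_path / "empty_out.tsv"
    write_ssr_table(g, path)
    assert path.read_text() == "marker\tchrom\tA\tB\n"


def read_ssr_table_from(tmp_path, text):
    p = tmp_path / "in.tsv"
    p.write_text(text)
    return read_ssr_table(p)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


VCF_TOY = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=Chr01>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
Chr01\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t1|1\t./.
Chr01\t200\t.\tC\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
"""


def test_vcf_parse_het_phased_missing(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(VCF_TOY)
    g = read_vcf(path)
    assert g.samples == ["S1", "S2", "S3"]
    # "0/1" het, "1|1" hom alt (phasing discarded), "./." missing
    assert g.dosage[:, 0].tolist() == [1, 2, MISSING]
    assert g.dosage[:, 1].tolist() == [0, 1, 2]


def test_vcf_round_trip_on_calls(tmp_path, small_study):
    g = small_study["snp"]
    path = tmp_path / "sim.vcf"
    write_vcf(g, path)
    back = read_vcf(path)
    assert back.samples == g.samples
    np.testing.assert_array_equal(back.dosage, g.dosage)
    pd.testing.assert_frame_equal(back.sites, g.sites)


def test_vcf_multiallelic_rejected(tmp_path):
    bad = VCF_TOY.replace("A\tG", "A\tG,T", 1)
    path = tmp_path / "multi.vcf"
    path.write_text(bad)
    with pytest.raises(GenotypeFormatError, match="multi-allelic"):
        read_vcf(path)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def _panel_with(dosage):
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    sites = pd.DataFrame(
        {
            "chrom": ["Chr01"] * m,
            "pos": np.arange(1, m + 1) * 10,
            "ref": ["A"] * m,
            "alt": ["G"] * m,
        }
    )
    return SNPGenotypes([f"S{i}" for i in range(n)], sites, dosage)


def test_filter_removes_high_missing_site():
    # 10 accessions, 4 missing calls -> missing rate 0.4 > 0.3
    col = [0, 2, 0, 2, 0, 2, MISSING, MISSING, MISSING, MISSING]
    keep_col = [0, 2] * 5
    g = _panel_with(np.column_stack([col, keep_col]))
    kept = filter_snps(g)
    assert kept.n_sites == 1
    assert kept.sites.iloc[0]["pos"] == 20


def test_filter_maf_boundary_retained():
    # alt count 1 of 20 alleles: MAF exactly 0.05 -> retained (inclusive)
    col = [1] + [0] * 9
    g = _panel_with(np.array(col).reshape(-1, 1))
    assert filter_snps(g, min_maf=0.05).n_sites == 1
    assert filter_snps(g, min_maf=0.050001).n_sites == 0


def test_filter_identity():
    rng = np.random.default_rng(3)
    g = random_snp_panel(rng, n_samples=8, n_sites=30)
    kept = filter_snps(g, max_missing=1.0, min_maf=0.0)
    np.testing.assert_array_equal(kept.dosage, g.dosage)


def test_filter_monotone_nesting():
    rng = np.random.default_rng(4)
    g = random_snp_panel(rng, n_samples=12, n_sites=60, missing=0.3)
    prev = None
    for max_missing, min_maf in [(0.5, 0.0), (0.3, 0.05), (0.2, 0.10), (0.1, 0.2)]:
        kept = set(
            map(tuple, filter_snps(g, max_missing, min_maf).sites[["chrom", "pos"]].to_numpy())
        )
        if prev is not None:
            assert kept <= prev
        prev = kept


def test_filter_polymorphic_matches_bruteforce():
    rng = np.random.default_rng(5)
    g = random_ssr_panel(rng, n_samples=8, n_markers=25, missing=0.4)
    kept = filter_polymorphic_ssr(g)
    expected = []
    for m in range(g.n_markers):
        alleles = set()
        for prof in g.calls[m, :]:
            if prof is not None:
                alleles |= set(prof)
        if len(alleles) >= 2:
            expected.append(g.markers.iloc[m]["marker"])
    assert kept.markers["marker"].tolist() == expected


def test_monomorphic_marker_removed_polymorphic_kept():
    calls = np.empty((2, 3), dtype=object)
    calls[0, :] = [frozenset({100})] * 3  # monomorphic
    calls[1, :] = [frozenset({100}), frozenset({102}), frozenset({100, 102})]
    from hetgd.genotypes import SSRGenotypes

    g = SSRGenotypes(
        ["A", "B", "C"],
        pd.DataFrame({"marker": ["m1", "m2"], "chrom": ["Chr01", "Chr01"]}),
        calls,
    )
    assert filter_polymorphic_ssr(g).markers["marker"].tolist() == ["m2"]


# ---------------------------------------------------------------------------
# Marker summary
# ---------------------------------------------------------------------------


def test_marker_summary_arithmetic(small_study):
    from hetgd.genotypes import SSRGenotypes

    # markers with {2, 3, 5} distinct observed alleles -> total 10, mean 3.33
    calls = np.empty((3, 3), dtype=object)
    calls[0, :] = [frozenset({1, 2}), frozenset({1}), frozenset({2})]
    calls[1, :] = [frozenset({1}), frozenset({3}), frozenset({5})]
    calls[2, :] = [frozenset({1, 2}), frozenset({3, 4}), frozenset({5})]
    ssr = SSRGenotypes(
        ["A", "B", "C"],
        pd.DataFrame({"marker": ["m1", "m2", "m3"], "chrom": ["c"] * 3}),
        calls,
    )
    s = marker_summary(ssr, small_study["snp"])
    assert s.n_polymorphic_alleles == 10
    assert round(s.mean_alleles_per_marker, 2) == 3.33


def test_marker_summary_single_allele():
    calls = np.empty((1, 1), dtype=object)
    calls[0, 0] = frozenset({7})
    from hetgd.genotypes import SSRGenotypes

    ssr = SSRGenotypes(
        ["A"], pd.DataFrame({"marker": ["m"], "chrom": ["c"]}), calls
    )
    snp = _panel_with(np.array([[0]]))
    s = marker_summary(ssr, snp)
    assert s.mean_alleles_per_marker == 1.0


def test_snp_density_half_open_windows():
    g = _panel_with(np.zeros((2, 4)))
    g.sites["pos"] = [1, 500_000, 500_001, 1_000_000]
    calls = np.empty((1, 2), dtype=object)
    calls[0, :] = [frozenset({1}), frozenset({2})]
    from hetgd.genotypes import SSRGenotypes

    ssr = SSRGenotypes(
        ["S0", "S1"], pd.DataFrame({"marker": ["m"], "chrom": ["c"]}), calls
    )
    s = marker_summary(ssr, g, window_bp=500_000)
    # 1-based pos 1..500000 -> window 0; 500001..1000000 -> window 500000
    counts = dict(zip(s.snp_density["window_start"], s.snp_density["n_snps"]))
    assert counts == {0: 2, 500_000: 2}
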