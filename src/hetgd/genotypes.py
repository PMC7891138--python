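"""Genotype containers and I/O for multi-allelic SSR markers and biallelic SNPs.

Two marker systems are carried side by side, mirroring how diversity panels in
cotton (and most inbred crops) are genotyped:

* **SSR** microsatellites: each accession shows one or two fragment-length
  "bands" per marker (one for a homozygote, two for a heterozygote).  Profiles
  are stored as frozensets of integer allele codes; ``None`` is a failed
  amplification.
* **SNP**: biallelic sites stored as alternate-allele dosage (0, 1, 2) with
  ``-1`` for a missing call.  Inbred lines carry only dosages 0 and 2.

The quality filters used throughout are the conventional panel filters: drop
SNP sites with a missing-call rate above 30% or a minor allele frequency below
5% (boundary values are retained), and drop SSR markers that are monomorphic
in the panel.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1  # SNP dosage code for a missing diploid call

__all__ = [
    "MISSING",
    "SNPGenotypes",
    "SSRGenotypes",
    "ParentMeta",
    "MarkerSummary",
    "GenotypeFormatError",
    "GenotypeParseError",
    "read_ssr_table",
    "write_ssr_table",
    "read_vcf",
    "write_vcf",
    "filter_snps",
    "filter_polymorphic_ssr",
    "marker_summary",
]


class GenotypeFormatError(ValueError):
    """A genotype file violates the expected format (VCF dialect, ploidy...)."""


class GenotypeParseError(ValueError):
    """A genotype table cell or header could not be parsed."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise GenotypeParseError(f"duplicate {what} id: {i!r}")
        seen.add(i)


# ---------------------------------------------------------------------------
# SNP container
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SNPGenotypes:
    """Biallelic diploid SNP calls for a set of accessions.

    Parameters
    ----------
    samples
        Ordered accession ids (unique).
    sites
        DataFrame with columns ``chrom``, ``pos`` (1-based), ``ref``, ``alt``;
        positions strictly increasing within each chromosome.
    dosage
        ``(n_samples, n_sites)`` int8 array of alternate-allele dosage
        (0, 1 or 2); ``MISSING`` (-1) marks a missing call.
    """

    samples: list[str]
    sites: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        _check_unique(self.samples, "accession")
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        bad = ~np.isin(self.dosage, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("dosage values must be in {-1, 0, 1, 2}")
        pos = self.sites["pos"].to_numpy()
        for chrom, idx in self.sites.groupby("chrom", sort=False).indices.items():
            p = pos[idx]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def missing_rate(self) -> np.ndarray:
        """Per-site fraction of missing calls."""
        return (self.dosage == MISSING).mean(axis=0)

    def maf(self) -> np.ndarray:
        """Per-site minor allele frequency over non-missing allele counts.

        Sites with no called accession get MAF 0 (they carry no allele-count
        information and are treated as monomorphic).
        """
        called = self.dosage != MISSING
        alt = np.where(called, self.dosage, 0).sum(axis=0)
        total = 2 * called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            af = np.where(total > 0, alt / np.maximum(total, 1), 0.0)
        return np.minimum(af, 1.0 - af)

    def take_sites(self, index: np.ndarray) -> "SNPGenotypes":
        """Subset to the sites selected by ``index`` (order preserved)."""
        return SNPGenotypes(
            samples=list(self.samples),
            sites=self.sites.iloc[index].reset_index(drop=True),
            dosage=self.dosage[:, index],
        )

    def take_samples(self, ids: Sequence[str]) -> "SNPGenotypes":
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            rows = [lookup[s] for s in ids]
        except KeyError as e:
            raise KeyError(f"accession {e.args[0]!r} not genotyped") from None
        return SNPGenotypes(
            samples=list(ids),
            sites=self.sites.copy(),
            dosage=self.dosage[rows, :],
        )


# ---------------------------------------------------------------------------
# SSR container
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SSRGenotypes:
    """Multi-allelic SSR band profiles for a set of accessions.

    ``calls`` is an ``(n_markers, n_samples)`` object array whose entries are
    frozensets of integer allele codes (size 1 or 2) or ``None`` for missing.
    Allele codes are marker-scoped (typically fragment lengths).
    """

    samples: list[str]
    markers: pd.DataFrame  # columns: marker, chrom
    calls: np.ndarray

    def __post_init__(self) -> None:
        _check_unique(self.samples, "accession")
        _check_unique(self.markers["marker"].tolist(), "marker")
        self.calls = np.asarray(self.calls, dtype=object)
        if self.calls.shape != (len(self.markers), len(self.samples)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.markers)} markers x {len(self.samples)} samples"
            )
        for prof in self.calls.flat:
            if prof is not None and len(prof) == 0:
                raise ValueError("band profiles must be non-empty when present")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def observed_alleles(self) -> list[frozenset]:
        """Distinct alleles observed per marker (union over non-missing calls)."""
        out = []
        for row in self.calls:
            alleles: set[int] = set()
            for prof in row:
                if prof is not None:
                    alleles.update(prof)
            out.append(frozenset(alleles))
        return out

    def take_markers(self, index: np.ndarray) -> "SSRGenotypes":
        return SSRGenotypes(
            samples=list(self.samples),
            markers=self.markers.iloc[index].reset_index(drop=True),
            calls=self.calls[index, :],
        )


@dataclasses.dataclass
class ParentMeta:
    """Per-accession metadata: origin class, crossing role, subpopulation.

    ``table`` is indexed by accession id with columns ``origin`` (one of
    ``elite``/``historic``/``exotic``), ``role`` (``male``/``female``) and
    optional ``subpop`` labels.
    """

    table: pd.DataFrame

    ORIGINS = ("elite", "historic", "exotic")
    ROLES = ("male", "female")

    def __post_init__(self) -> None:
        bad = set(self.table["origin"]) - set(self.ORIGINS)
        if bad:
            raise ValueError(f"unknown origin classes: {sorted(bad)}")
        bad = set(self.table["role"]) - set(self.ROLES)
        if bad:
            raise ValueError(f"unknown roles: {sorted(bad)}")
        if not self.table.index.is_unique:
            raise ValueError("duplicate accession ids in metadata")

    def origin_of(self, accession: str) -> str:
        return str(self.table.loc[accession, "origin"])


# ---------------------------------------------------------------------------
# SSR TSV dialect
# ---------------------------------------------------------------------------
#
# Rows are markers, columns accessions.  First two columns: marker id and
# chromosome; header row carries accession ids.  Cells: "a" (homozygote),
# "a/b" (heterozygote, written low/high), "." missing.  Allele codes are
# integers (fragment lengths).


def _parse_ssr_cell(cell: str, line_no: int):
    cell = cell.strip()
    if cell == ".":
        return None
    try:
        alleles = frozenset(int(a) for a in cell.split("/"))
    except ValueError:
        raise GenotypeParseError(
            f"line {line_no}: malformed SSR cell {cell!r}"
        ) from None
    if not 1 <= len(alleles) <= 2:
        raise GenotypeParseError(
            f"line {line_no}: band profile {cell!r} must have 1 or 2 alleles"
        )
    return alleles


def read_ssr_table(path) -> SSRGenotypes:
    """Read an SSR genotype table (markers x accessions TSV dialect)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenotypeParseError("empty SSR table")
    header = lines[0].rstrip("\n").split("\t")
    if len(header) < 2 or header[0] != "marker" or header[1] != "chrom":
        raise GenotypeParseError(
            "SSR table header must start with 'marker\\tchrom'"
        )
    samples = header[2:]
    _check_unique(samples, "accession")
    marker_ids, chroms, rows = [], [], []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            raise GenotypeParseError(
                f"line {ln}: expected {len(header)} fields, got {len(fields)}"
            )
        marker_ids.append(fields[0])
        chroms.append(fields[1])
        rows.append([_parse_ssr_cell(c, ln) for c in fields[2:]])
    calls = np.empty((len(marker_ids), len(samples)), dtype=object)
    for i, row in enumerate(rows):
        calls[i, :] = row
    return SSRGenotypes(
        samples=samples,
        markers=pd.DataFrame({"marker": marker_ids, "chrom": chroms}),
        calls=calls,
    )


def write_ssr_table(genotypes: SSRGenotypes, path) -> None:
    """Write an SSR genotype table; inverse of :func:`read_ssr_table`."""
    out = ["\t".join(["marker", "chrom"] + list(genotypes.samples))]
    for i in range(genotypes.n_markers):
        cells = []
        for prof in genotypes.calls[i, :]:
            if prof is None:
                cells.append(".")
            else:
                cells.append("/".join(str(a) for a in sorted(prof)))
        out.append(
            "\t".join(
                [
                    str(genotypes.markers.iloc[i]["marker"]),
                    str(genotypes.markers.iloc[i]["chrom"]),
                ]
                + cells
            )
        )
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------


def read_vcf(path) -> SNPGenotypes:
    """Read biallelic diploid SNP genotypes (GT field) from a VCF v4.2 file.

    Multi-allelic records and non-diploid GT entries are rejected; phased
    separators are accepted and stored unphased.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chroms, poss, refs, alts = [], [], [], []
    columns = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise GenotypeFormatError(
                f"multi-allelic record at {var.CHROM}:{var.POS} not supported"
            )
        if "GT" not in (var.FORMAT or []):
            raise GenotypeFormatError(
                f"record at {var.CHROM}:{var.POS} lacks a GT field"
            )
        for g in var.genotypes:
            # cyvcf2 genotype entries are [allele..., phased]; diploid => len 3
            if len(g) != 3:
                raise GenotypeFormatError(
                    f"non-diploid GT at {var.CHROM}:{var.POS}"
                )
        gt = var.gt_types.astype(np.int8)  # gts012: 0,1,2 dosage; 3 unknown
        gt[gt == 3] = MISSING
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        columns.append(gt)
    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    if columns:
        dosage = np.stack(columns, axis=1)
    else:
        dosage = np.zeros((len(samples), 0), dtype=np.int8)
    return SNPGenotypes(samples=samples, sites=sites, dosage=dosage)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(genotypes: SNPGenotypes, path) -> None:
    """Write genotypes as a minimal VCF v4.2 file (GT-only)."""
    lines = [
        "##fileformat=VCFv4.2",
        "##source=hetgd",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for chrom in pd.unique(genotypes.sites["chrom"]):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(genotypes.samples)
    )
    for j, site in enumerate(genotypes.sites.itertuples(index=False)):
        gts = "\t".join(_GT_STRINGS[int(d)] for d in genotypes.dosage[:, j])
        lines.append(
            f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t.\tPASS\t.\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Filters and summaries
# ---------------------------------------------------------------------------


def filter_snps(
    genotypes: SNPGenotypes,
    max_missing: float = 0.30,
    min_maf: float = 0.05,
) -> SNPGenotypes:
    """Retain sites with missing rate <= ``max_missing`` and MAF >= ``min_maf``.

    Boundary values survive (a site at exactly 5% MAF or 30% missingness is
    kept).  MAF is computed on non-missing allele counts (two per called
    accession).  The accession set and site order are unchanged.
    """
    if not (0 <= max_missing <= 1 and 0 <= min_maf <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    keep = (genotypes.missing_rate() <= max_missing) & (genotypes.maf() >= min_maf)
    if not keep.any():
        warnings.warn("all SNP sites removed by filtering", stacklevel=2)
    return genotypes.take_sites(np.flatnonzero(keep))


def filter_polymorphic_ssr(genotypes: SSRGenotypes) -> SSRGenotypes:
    """Retain markers with >= 2 distinct observed alleles among non-missing calls."""
    keep = np.array(
        [len(a) >= 2 for a in genotypes.observed_alleles()], dtype=bool
    )
    return genotypes.take_markers(np.flatnonzero(keep))


@dataclasses.dataclass
class MarkerSummary:
    """Panel-level marker statistics for reporting.

    ``mean_alleles_per_marker`` is kept at full precision; ``round(x, 2)`` is
    applied at report time.
    """

    n_markers: int
    n_polymorphic_alleles: int
    mean_alleles_per_marker: float
    ssr_per_chromosome: pd.Series
    snp_density: pd.DataFrame  # chrom, window_start (0-based), n_snps
    window_bp: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "statistic": [
                    "n_ssr_markers",
                    "n_polymorphic_alleles",
                    "mean_alleles_per_marker",
                ],
                "value": [
                    self.n_markers,
                    self.n_polymorphic_alleles,
                    round(self.mean_alleles_per_marker, 2),
                ],
            }
        )


def marker_summary(
    ssr: SSRGenotypes, snp: SNPGenotypes, window_bp: int = 500_000
) -> MarkerSummary:
    """Summarize SSR allele richness and SNP density.

    Allele totals sum the distinct non-missing alleles per marker; SNP density
    counts sites per half-open window ``[k*w, (k+1)*w)`` of 1-based positions
    mapped to 0-based starts.
    """
    if ssr.n_markers == 0:
        raise ValueError("empty SSR marker set")
    alleles = ssr.observed_alleles()
    total = int(sum(len(a) for a in alleles))
    per_chrom = ssr.markers.groupby("chrom", sort=True).size()
    window = ((snp.sites["pos"] - 1) // window_bp) * window_bp
    density = (
        snp.sites.assign(window_start=window)
        .groupby(["chrom", "window_start"], sort=True)
        .size()
        .rename("n_snps")
        .reset_index()
    )
    return MarkerSummary(
        n_markers=ssr.n_markers,
        n_polymorphic_alleles=total,
        mean_alleles_per_marker=total / ssr.n_markers,
        ssr_per_chromosome=per_chrom,
        snp_density=density,
        window_bp=window_bp,
    )
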