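"""End-to-end orchestration: filters -> GD -> grouping -> heterosis -> correlations.

``run_pipeline`` executes the full analysis on supplied input files or on a
freshly simulated panel, writing every intermediate table as TSV plus a JSON
manifest (package version, parameters, input checksums) that suffices to
reproduce the bundle exactly.  ``demo`` runs the pipeline on a synthetic
panel at the reference design shape (4 males x 282 females) with desk-scale
marker counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .association import (
    compare_groups,
    correlate_gd_with,
    correlate_parent_with_f1,
)
from .cluster import assign_f1_groups, cut_groups, group_gd_summary, upgma_cluster
from .distance import cross_gd, gd_population_summary, gd_snp_matrix, gd_ssr_matrix
from .genotypes import (
    filter_polymorphic_ssr,
    filter_snps,
    marker_summary,
    read_ssr_table,
    read_vcf,
    write_ssr_table,
    write_vcf,
)
from .heterosis import aggregate_environments, compute_heterosis, heterosis_summary
from .simulate import SimConfig, simulate_study

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "demo"]

log = logging.getLogger("hetgd")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclasses.dataclass
class PipelineConfig:
    """Configuration for a full pipeline run.

    Either all four input paths are given (analysis of existing files) or
    ``sim`` is given (simulate-then-analyze).  Thresholds follow the
    conventional panel filters; ``k_snp``/``k_ssr`` are the group counts cut
    from the SNP- and SSR-based trees.
    """

    out_dir: str
    ssr_path: str | None = None
    vcf_path: str | None = None
    pheno_path: str | None = None
    design_path: str | None = None
    meta_path: str | None = None
    sim: SimConfig | None = None
    max_missing: float = 0.30
    min_maf: float = 0.05
    k_snp: int = 5
    k_ssr: int = 3
    rounding: int = 2

    def __post_init__(self) -> None:
        file_mode = all(
            p is not None
            for p in (self.ssr_path, self.vcf_path, self.pheno_path, self.design_path)
        )
        if not file_mode and self.sim is None:
            raise PipelineError(
                "config: provide either all input paths or a simulation config"
            )
        if not 0 <= self.max_missing <= 1 or not 0 <= self.min_maf <= 1:
            raise PipelineError("config: thresholds must lie in [0, 1]")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, provenance: dict) -> None:
    header = "".join(f"# {k}={v}\n" for k, v in sorted(provenance.items()))
    path.write_text(header + df.to_csv(sep="\t", index=False))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle under ``config.out_dir``.

    Returns a dict of the in-memory results keyed by stage name.  Any stage
    failure raises :class:`PipelineError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = {
        "hetgd_version": __version__,
        "max_missing": config.max_missing,
        "min_maf": config.min_maf,
        "k_snp": config.k_snp,
        "k_ssr": config.k_ssr,
    }
    inputs: dict[str, str] = {}

    # --- stage: load or simulate ---
    try:
        if config.sim is not None:
            log.info("simulating panel (seed=%d)", config.sim.seed)
            ssr, snp, _f1, design, pheno, meta, _truth = simulate_study(config.sim)
            write_ssr_table(ssr, out / "input_ssr.tsv")
            write_vcf(snp, out / "input_snp.vcf")
            pheno.to_csv(out / "input_phenotypes.tsv", sep="\t", index=False)
            design.to_csv(out / "input_design.tsv", sep="\t", index=False)
            meta.table.to_csv(out / "input_parents.tsv", sep="\t")
            for f in ("input_ssr.tsv", "input_snp.vcf", "input_phenotypes.tsv",
                      "input_design.tsv", "input_parents.tsv"):
                inputs[f] = _sha256(out / f)
            prov["seed"] = config.sim.seed
            meta_table = meta.table
        else:
            for p in (config.ssr_path, config.vcf_path, config.pheno_path,
                      config.design_path):
                if not Path(p).exists():
                    raise PipelineError(f"load: input path not found: {p}")
            log.info("reading inputs")
            ssr = read_ssr_table(config.ssr_path)
            snp = read_vcf(config.vcf_path)
            pheno = pd.read_csv(config.pheno_path, sep="\t")
            design = pd.read_csv(config.design_path, sep="\t")
            meta_table = (
                pd.read_csv(config.meta_path, sep="\t", index_col=0)
                if config.meta_path
                else None
            )
            for p in (config.ssr_path, config.vcf_path, config.pheno_path,
                      config.design_path):
                inputs[Path(p).name] = _sha256(Path(p))
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(f"load: {e}") from e

    results: dict = {"design": design}
    try:
        log.info("filtering markers (missing<=%.2f, MAF>=%.2f)",
                 config.max_missing, config.min_maf)
        snp_f = filter_snps(snp, config.max_missing, config.min_maf)
        ssr_f = filter_polymorphic_ssr(ssr)
        summary = marker_summary(ssr_f, snp_f)
        _write_tsv(summary.to_frame(), out / "marker_summary.tsv", prov)
        _write_tsv(summary.snp_density, out / "snp_density.tsv", prov)
        results["marker_summary"] = summary
    except Exception as e:
        raise PipelineError(f"filter: {e}") from e

    try:
        log.info("computing genetic distances")
        ssr_dm = gd_ssr_matrix(ssr_f)
        snp_dm = gd_snp_matrix(snp_f)
        ssr_dm.to_frame().to_csv(out / "gd_ssr.tsv", sep="\t")
        snp_dm.to_frame().to_csv(out / "gd_snp.tsv", sep="\t")
        table = cross_gd(design, ssr_dm, snp_dm)
        _write_tsv(table, out / "cross_gd.tsv", prov)
        pop = gd_population_summary(table)
        _write_tsv(pop.round(4), out / "gd_population_summary.tsv", prov)
        results.update(cross_gd=table, gd_population_summary=pop,
                       ssr_dm=ssr_dm, snp_dm=snp_dm)
    except Exception as e:
        raise PipelineError(f"gd: {e}") from e

    try:
        log.info("clustering female parents (k_snp=%d, k_ssr=%d)",
                 config.k_snp, config.k_ssr)
        females = list(pd.unique(design["female"]))
        groups = {}
        for name, dm, k in (("snp", snp_dm, config.k_snp),
                            ("ssr", ssr_dm, config.k_ssr)):
            tree = upgma_cluster(dm.subset(females))
            (out / f"dendrogram_{name}.nwk").write_text(tree.to_newick() + "\n")
            female_groups = cut_groups(tree, k)
            f1_groups = assign_f1_groups(female_groups, design)
            _write_tsv(
                female_groups.groups.rename_axis("female").reset_index(),
                out / f"groups_{name}_females.tsv", prov,
            )
            _write_tsv(
                f1_groups.groups.rename_axis("cross").reset_index(),
                out / f"groups_{name}_f1.tsv", prov,
            )
            _write_tsv(group_gd_summary(f1_groups, table).round(4),
                       out / f"group_gd_{name}.tsv", prov)
            groups[name] = (tree, female_groups, f1_groups)
        results["groups"] = groups
    except Exception as e:
        raise PipelineError(f"cluster: {e}") from e

    try:
        log.info("computing heterosis")
        means = aggregate_environments(pheno)
        het = compute_heterosis(design, means)
        _write_tsv(het.round({"f1": 4, "mp": 4, "hp": 4, "mph": 4, "bph": 4}),
                   out / "heterosis.tsv", prov)
        het_sum = heterosis_summary(het)
        _write_tsv(het_sum.round(config.rounding), out / "heterosis_summary.tsv", prov)
        _write_tsv(heterosis_summary(het, by="male").round(config.rounding),
                   out / "heterosis_summary_by_male.tsv", prov)
        results.update(means=means, heterosis=het, heterosis_summary=het_sum)
    except Exception as e:
        raise PipelineError(f"heterosis: {e}") from e

    try:
        log.info("correlating GD with performance and heterosis")
        for metric in ("F1", "MPH", "BPH"):
            tab = correlate_gd_with(metric, table, het, design)
            _write_tsv(tab.round({"r": 4, "p": 6}),
                       out / f"corr_gd_{metric.lower()}.tsv", prov)
            results[f"corr_gd_{metric.lower()}"] = tab
        parent_tab = correlate_parent_with_f1(means, het, design)
        _write_tsv(parent_tab.round({"r": 4, "p": 6}),
                   out / "corr_parent_f1.tsv", prov)
        results["corr_parent_f1"] = parent_tab
    except Exception as e:
        raise PipelineError(f"correlate: {e}") from e

    try:
        log.info("comparing trait distributions between groups")
        _f1_tree, _fg, f1_groups = groups["snp"]
        f1_values = het[het["flag"] == ""][["cross", "trait", "f1"]].copy()
        f1_values["group"] = f1_values["cross"].map(f1_groups.groups)
        if f1_values["group"].nunique() >= 2:
            comp = compare_groups(f1_values, value_col="f1")
            _write_tsv(comp.round({"mean_a": 4, "mean_b": 4, "t": 4,
                                   "p_raw": 6, "p_adj": 6}),
                       out / "group_comparison_snp.tsv", prov)
            results["group_comparison_snp"] = comp
        if meta_table is not None:
            origin = meta_table["origin"]
            sets = het[het["flag"] == ""][["cross", "female", "trait", "f1"]].copy()
            sets["group"] = sets["female"].map(origin).map(
                {"elite": "ElitexElite", "historic": "HistoricxElite",
                 "exotic": "ExoticxElite"}
            )
            comp = compare_groups(sets.dropna(subset=["group"]), value_col="f1")
            _write_tsv(comp.round({"mean_a": 4, "mean_b": 4, "t": 4,
                                   "p_raw": 6, "p_adj": 6}),
                       out / "group_comparison_hybrid_sets.tsv", prov)
            results["group_comparison_hybrid_sets"] = comp
    except Exception as e:
        raise PipelineError(f"compare: {e}") from e

    manifest = {
        "hetgd_version": __version__,
        "parameters": {
            "max_missing": config.max_missing,
            "min_maf": config.min_maf,
            "k_snp": config.k_snp,
            "k_ssr": config.k_ssr,
            "sim": dataclasses.asdict(config.sim) if config.sim else None,
        },
        "inputs": inputs,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )
    log.info("report bundle written to %s", out)
    return results


def demo(seed: int, out_dir: str, n_snps: int = 800, n_ssr: int = 60) -> dict:
    """Simulate a panel at the reference design shape and run the pipeline."""
    sim = SimConfig(seed=seed, n_snps=n_snps, n_ssr=n_ssr)
    return run_pipeline(PipelineConfig(out_dir=out_dir, sim=sim))
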