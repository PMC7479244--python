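"""End-to-end orchestration: simulate -> QC -> cluster -> differential ->
annotate -> validate, with a machine-readable run manifest.

Every stage logs one structured line with input/output record counts; the
manifest echoes every threshold (no silent defaults) and the per-stage counts
(CpGs read -> CpGs10 -> tested -> DMCs -> DMRs per comparison).  A stage
failure aborts the run with the stage name and writes ``error.json``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .annotation import GenomeAnnotation, enrichment_vs_background, background_gene_list
from .cluster import completeness_filter, correlation_distance_matrix, hierarchical_cluster
from .core import CountMatrix, ksample_permutation_test, qc_summary
from .differential import ComparisonSpec, DifferentialMethylation, compare_dmc_sets
from .simulate import SimulationConfig, SimulatedCohort, simulate_cohort, simulate_pyro, write_simulation
from .validation import consolidate_replicates, per_cpg_group_tests, spearman_concordance

logger = logging.getLogger("rrbsdiff.pipeline")

DEFAULT_COMPARISONS = [
    {"group1": "HM15", "group2": "MM15", "paired": False},
    {"group1": "HM15", "group2": "MM16", "paired": False},
    {"group1": "MM15", "group2": "MM16", "paired": True},
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    outdir: str = "rrbsdiff_run"
    seed: int = 0
    # either a simulation config ...
    simulation: SimulationConfig | None = field(default_factory=SimulationConfig)
    # ... or input paths for existing data
    coverage_dir: str | None = None
    sample_sheet: str | None = None
    gtf: str | None = None
    cgi_bed: str | None = None
    repeat_bed: str | None = None
    spikein_csv: str | None = None
    pyro_csv: str | None = None
    # thresholds
    min_reads: int = 10
    min_samples_per_group: int = 4
    alpha_adj: float = 0.1
    min_diff: float = 10.0
    dmr_min_dmcs: int = 3
    dmr_max_gap: int = 100
    ihw_alpha: float = 0.05
    ihw_bins: int = 10
    n_perm: int = 100_000
    cluster_min_per_group: int = 4
    cluster_min_shared_sites: int = 100
    comparisons: list = field(default_factory=lambda: [dict(c) for c in DEFAULT_COMPARISONS])
    max_validation_regions: int = 4

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "simulation" in d and d["simulation"] is not None:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        return cls(**d)

    def thresholds(self) -> dict:
        return {
            "min_reads": self.min_reads,
            "min_samples_per_group": self.min_samples_per_group,
            "alpha_adj": self.alpha_adj,
            "min_diff": self.min_diff,
            "dmr_min_dmcs": self.dmr_min_dmcs,
            "dmr_max_gap": self.dmr_max_gap,
            "ihw_alpha": self.ihw_alpha,
            "ihw_bins": self.ihw_bins,
            "n_perm": self.n_perm,
            "cluster_min_per_group": self.cluster_min_per_group,
        }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order and return the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from . import __version__

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": config.thresholds(),
        "stages": {},
        "comparisons": {},
    }
    stage = "setup"
    cohort: SimulatedCohort | None = None
    try:
        # ------------------------------------------------------------ simulate
        if config.simulation is not None:
            stage = "simulate"
            sim = config.simulation
            sim.seed = config.seed if config.seed is not None else sim.seed
            bundle, fragments, cohort = simulate_cohort(sim)
            paths = write_simulation(bundle, cohort, outdir / "sim")
            config.coverage_dir = paths["coverage_dir"]
            config.sample_sheet = paths["sample_sheet"]
            config.gtf = paths["gtf"]
            config.cgi_bed = paths["cgi_bed"]
            config.repeat_bed = paths["repeat_bed"]
            config.spikein_csv = paths["spikeins"]
            manifest["stages"]["simulate"] = {
                "n_fragments": int(sum(len(v) for v in fragments.values())),
                "n_cpgs_truth": int(len(cohort.truth)),
                "n_planted_dmcs": int(cohort.truth["planted_dmc"].sum()),
                "n_samples": int(len(cohort.sheet)),
            }
            _log(manifest, "simulate")

        # ---------------------------------------------------------------- load
        stage = "load"
        sheet = _io.read_sample_sheet(config.sample_sheet)
        matrix = CountMatrix.from_coverage_dir(config.coverage_dir, sheet, merge_strands=True)
        spikeins = _io.read_spikein_csv(config.spikein_csv) if config.spikein_csv else None
        cpgs_read = matrix.n_sites
        matrix10 = matrix.filter_cpg10(config.min_reads)
        manifest["stages"]["load"] = {
            "n_samples": matrix.n_samples,
            "cpgs_read": int(cpgs_read),
            "cpgs10": int(matrix10.n_sites),
        }
        _log(manifest, "load")

        # ------------------------------------------------------------------ qc
        stage = "qc"
        qc = qc_summary(matrix, spikeins, min_reads=config.min_reads)
        qc.to_csv(outdir / "qc_summary.csv", index=False)
        qc_tests = {}
        labels = sorted(qc["group_label"].unique())
        for metric in ("mean_coverage", "mean_methylation_cpg10_pct", "pct_cpg10"):
            groups = [qc.loc[qc["group_label"] == g, metric].dropna().to_numpy() for g in labels]
            if any(len(g) < 2 for g in groups):
                continue
            res = ksample_permutation_test(
                groups, n_perm=config.n_perm, seed=config.seed + 11
            )
            qc_tests[metric] = {
                "statistic": res.statistic,
                "p": res.p_value,
                "n_perm": res.n_perm,
                "statistic_kind": "between-group variance of group means",
            }
        with open(outdir / "qc_group_tests.json", "w") as fh:
            json.dump(qc_tests, fh, indent=2)
        manifest["stages"]["qc"] = {"n_samples": int(len(qc)), "group_tests": qc_tests}
        _log(manifest, "qc")

        # ------------------------------------------------------------- cluster
        stage = "cluster"
        pct = matrix10.methylation_percent()
        group_of = {s.sample_id: s.group_label for s in matrix10.samples}
        pct_complete = completeness_filter(pct, group_of, config.cluster_min_per_group)
        dist = correlation_distance_matrix(
            pct_complete, min_shared_sites=config.cluster_min_shared_sites
        )
        dend = hierarchical_cluster(dist)
        dist.to_csv(outdir / "sample_distances.csv")
        (outdir / "clustering.nwk").write_text(dend.newick() + "\n")
        dend.cut(2).to_csv(outdir / "cluster_assignments.csv")
        manifest["stages"]["cluster"] = {
            "sites_complete": int(len(pct_complete)),
            "linkage": dend.method,
            "correlation": "pearson",
        }
        _log(manifest, "cluster")

        # -------------------------------------------------------- differential
        stage = "differential"
        results = {}
        for comp in config.comparisons:
            spec = ComparisonSpec(
                group1=comp["group1"],
                group2=comp["group2"],
                min_samples_per_group=config.min_samples_per_group,
                alpha_adj=config.alpha_adj,
                min_diff=config.min_diff,
                ihw_alpha=config.ihw_alpha,
                ihw_bins=config.ihw_bins,
                paired=bool(comp.get("paired", False)),
            )
            cmp_matrix = matrix10
            if spec.paired:
                # restrict to bulls present in both groups of the comparison
                in1 = {s.bull_id for s in matrix10.samples if s.group_label == spec.group1}
                in2 = {s.bull_id for s in matrix10.samples if s.group_label == spec.group2}
                shared = in1 & in2
                keep = [
                    s.sample_id
                    for s in matrix10.samples
                    if s.bull_id in shared and s.group_label in (spec.group1, spec.group2)
                ]
                cmp_matrix = matrix10.subset_samples(keep)
            name = f"{spec.group1}_vs_{spec.group2}"
            res = DifferentialMethylation(cmp_matrix, spec).fit()
            results[name] = res
            res.to_csv(
                dmc_path=outdir / f"dmc_{name}.csv",
                dmr_bed_path=outdir / f"dmr_{name}.bed",
                dmr_csv_path=outdir / f"dmr_{name}.csv",
            )
            res.volcano_table().to_csv(outdir / f"volcano_{name}.csv", index=False)
            dmrs = res.dmrs(config.dmr_min_dmcs, config.dmr_max_gap)
            manifest["comparisons"][name] = {
                "tested": int(res.n_eligible),
                "dmcs": int(len(res.dmcs)),
                "dmrs": int(len(dmrs)),
                "pct_hyper_group1": (
                    float(100.0 * (res.dmcs["direction"] == "hyper_in_group1").mean())
                    if len(res.dmcs)
                    else None
                ),
            }
        if len(results) >= 2:
            names = list(results)
            summary = compare_dmc_sets(results[names[0]].dmcs, results[names[1]].dmcs)
            summary["set_a"], summary["set_b"] = names[0], names[1]
            with open(outdir / "dmc_set_comparison.json", "w") as fh:
                json.dump(summary, fh, indent=2)
            manifest["stages"]["set_comparison"] = summary
        _log(manifest, "differential")

        # ---------------------------------------------------------- annotation
        stage = "annotation"
        chrom_lengths = None
        if config.simulation is not None:
            chrom_lengths = {c: len(s) for c, s in bundle.sequences.items()}
        ann = GenomeAnnotation.from_files(
            config.gtf, config.cgi_bed, config.repeat_bed, chrom_lengths
        )
        first = results[list(results)[0]]
        background_sites = first.tests[["chrom", "pos"]].copy()
        background_sites["start"] = background_sites.pop("pos")
        background_sites["end"] = background_sites["start"] + 1
        bg_ann = ann.annotate(background_sites)
        bg_ann.to_csv(outdir / "background_annotation.csv", index=False)
        for name, res in results.items():
            if res.dmcs.empty:
                continue
            q = pd.DataFrame(
                {
                    "chrom": res.dmcs["chrom"],
                    "start": res.dmcs["pos"],
                    "end": res.dmcs["pos"] + 1,
                }
            )
            q_ann = ann.annotate(q)
            q_ann = pd.concat(
                [q_ann.reset_index(drop=True), res.dmcs[["diff", "p_adj", "direction"]].reset_index(drop=True)],
                axis=1,
            )
            q_ann.to_csv(outdir / f"dmc_annotation_{name}.csv", index=False)
            enr = enrichment_vs_background(q_ann, bg_ann)
            enr.to_csv(outdir / f"enrichment_{name}.csv", index=False)
            genes = sorted(
                {g for gs in q_ann["genes_within_10kb"] if gs for g in gs.split(";")}
            )
            (outdir / f"genes_{name}.txt").write_text("\n".join(genes) + "\n")
            manifest["comparisons"][name]["genes_within_10kb"] = len(genes)
        bg_genes = background_gene_list(background_sites, ann.genes)
        (outdir / "genes_background.txt").write_text("\n".join(bg_genes) + "\n")
        manifest["stages"]["annotation"] = {
            "background_sites": int(len(bg_ann)),
            "background_genes": len(bg_genes),
        }
        _log(manifest, "annotation")

        # ---------------------------------------------------------- validation
        stage = "validation"
        val_info = {"regions": 0}
        first_name = list(results)[0]
        dmrs = results[first_name].dmrs(config.dmr_min_dmcs, config.dmr_max_gap)
        pyro = None
        if config.pyro_csv:
            pyro = _io.read_pyro_csv(config.pyro_csv)
        elif cohort is not None and len(dmrs):
            top = dmrs.sort_values("n_dmcs", ascending=False).head(config.max_validation_regions)
            site_key = {
                (c, p): i
                for i, (c, p) in enumerate(zip(cohort.truth["chrom"], cohort.truth["pos"]))
            }
            regions = {}
            for _, r in top.iterrows():
                idx = [site_key[(r["chrom"], p)] for p in r["member_pos"] if (r["chrom"], p) in site_key]
                if idx:
                    regions[f"{r['chrom']}:{r['start'] + 1}-{r['end'] + 1}"] = idx
            if regions:
                pyro = simulate_pyro(
                    cohort, regions, rng=np.random.default_rng(config.seed + 23)
                )
                pyro.to_csv(outdir / "pyro_replicates.csv", index=False)
        if pyro is not None and len(pyro):
            consolidated = consolidate_replicates(pyro)
            consolidated.to_csv(outdir / "pyro_consolidated.csv", index=False)
            pct10 = matrix10.methylation_percent()
            rrbs_rows = []
            for region in consolidated["region"].unique():
                chrom, span = region.split(":")
                start, end = (int(x) for x in span.split("-"))
                sel = pct10.loc[
                    (pct10.index.get_level_values("chrom") == chrom)
                    & (pct10.index.get_level_values("pos") >= start - 1)
                    & (pct10.index.get_level_values("pos") <= end - 1)
                ]
                for sid in sel.columns:
                    rrbs_rows.append(
                        {"region": region, "sample_id": sid, "percentage": sel[sid].mean()}
                    )
            rrbs_means = pd.DataFrame(rrbs_rows)
            pyro_means = (
                consolidated.dropna(subset=["percentage"])
                .groupby(["region", "sample_id"], as_index=False)["percentage"]
                .mean()
            )
            concordance = spearman_concordance(rrbs_means, pyro_means)
            concordance.to_csv(outdir / "pyro_concordance.csv", index=False)
            cpg_tests = per_cpg_group_tests(
                consolidated, sheet, n_perm=config.n_perm, seed=config.seed + 31
            )
            cpg_tests.to_csv(outdir / "pyro_cpg_tests.csv", index=False)
            val_info = {
                "regions": int(consolidated["region"].nunique()),
                "median_rho": float(concordance["rho"].median())
                if concordance["rho"].notna().any()
                else None,
                "cpgs_tested": int(len(cpg_tests)),
            }
        manifest["stages"]["validation"] = val_info
        _log(manifest, "validation")

        # ------------------------------------------------------------ manifest
        stage = "manifest"
        _check_monotonicity(manifest)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=_json_default)
        return manifest
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        err = {"stage": stage, "error": str(exc), "type": type(exc).__name__}
        try:
            with open(outdir / "error.json", "w") as fh:
                json.dump(err, fh, indent=2)
        except OSError:
            pass
        logger.error("stage %s failed: %s", stage, exc)
        raise PipelineError(stage, exc) from exc


def _check_monotonicity(manifest: dict) -> None:
    load = manifest["stages"].get("load", {})
    if load:
        assert load["cpgs10"] <= load["cpgs_read"], "CpGs10 exceeds CpGs read"
        for name, c in manifest["comparisons"].items():
            assert c["dmcs"] <= c["tested"], f"{name}: DMCs exceed tested sites"


def _log(manifest: dict, stage: str) -> None:
    info = manifest["stages"].get(stage) or manifest.get("comparisons")
    logger.info("stage=%s %s", stage, json.dumps(info, default=_json_default)[:400])


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def small_simulation_config(seed: int = 0) -> SimulationConfig:
    """A reduced-scale configuration for smoke tests and examples: same
    distributional structure, ~40x smaller genome."""
    return SimulationConfig(
        seed=seed,
        n_chroms=2,
        chrom_length=120_000,
        n_genes=10,
        n_cgis=14,
        spikein_cytosines=5_000,
    )
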