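"""End-to-end run orchestration: simulate/load -> connect -> cluster ->
filter -> metrics -> stats, with all interface files written to one output
directory and a manifest for reproducibility.

Stage order follows the analysis design: per-subject absolute-Pearson
matrices, group means, hierarchical network partitions (matched to the
reference labeling), BCa reliability filtering with Fisher z transform,
degree centrality and network mean FC, then the statistical battery.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import (
    NetworkPartition,
    hierarchical_partition,
    match_to_reference,
    partition_shift,
    reference_partition,
)
from .connectivity import group_mean_matrix, pearson_abs_matrix
from .metrics import degree_table, network_fc_table
from .regions import REGION_NAMES
from .reliability import (
    compute_edge_intervals,
    filter_cohort,
    filter_groups_matched,
    fisher_z_connectome,
)
from .stats import (
    GroupStatsReport,
    demographics_table,
    edgewise_compare,
    network_level_compare,
    nodewise_compare,
    score_correlation,
)
from .synth import (
    CONTROL_GROUP,
    PATIENT_GROUP,
    CohortConfig,
    SubjectRecord,
    generate_cohort,
    read_cohort,
    write_cohort,
)

__all__ = ["RunConfig", "run", "load_timeseries", "PipelineError"]


class PipelineError(RuntimeError):
    """Stage failure; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    mode: str = "simulate"  # or "load"
    input_dir: str | None = None  # load mode: cohort directory
    cohort: CohortConfig = field(default_factory=CohortConfig)
    B: int = 10000
    alpha: float = 0.05
    k: int = 3
    linkage: str = "average"
    t_variant: str = "student"
    partition_mode: str = "nc"  # {nc, amci, reference, pooled}
    ci_mode: str = "matched_width"  # {matched_width, pooled, per_group}
    include_zeros: bool = True
    q: float = 0.05
    seed: int = 0
    outdir: str = "reliafc_run"
    write_cohort_files: bool = False
    plots: bool = False

    def validate(self) -> None:
        if self.mode not in ("simulate", "load"):
            raise ValueError("mode must be 'simulate' or 'load'")
        if self.mode == "load":
            if self.input_dir is None or not Path(self.input_dir).exists():
                raise ValueError(f"input directory not found: {self.input_dir!r}")
        if self.partition_mode not in ("nc", "amci", "reference", "pooled"):
            raise ValueError("partition_mode must be nc/amci/reference/pooled")
        if self.ci_mode not in ("matched_width", "pooled", "per_group"):
            raise ValueError("ci_mode must be matched_width/pooled/per_group")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort_raw = raw.pop("cohort", {})
        config = cls(**raw)
        if cohort_raw:
            base = config.cohort.to_dict()
            base.update(cohort_raw)
            # partition keys load as plain dicts already
            config.cohort = CohortConfig(**base)
        return config

    def to_dict(self) -> dict:
        out = {
            k: v
            for k, v in self.__dict__.items()
            if k != "cohort"
        }
        out["cohort"] = self.cohort.to_dict()
        return out


def load_timeseries(path: str | Path) -> list[SubjectRecord]:
    """Load validated subject records from a cohort directory.

    Expects one TSV per subject (43 named region columns) and a
    ``covariates.csv``; columns are harmonized to the canonical region
    order by name.
    """
    return read_cohort(path)


def _covariate_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "group": r.group,
                "age": r.covariates["age"],
                "gender": r.covariates["gender"],
                "education": r.covariates["education"],
                "mean_fd": r.covariates["mean_fd"],
                "mmse": r.covariates["mmse"],
            }
            for r in records
        ]
    )


def _derived_seed(seed: int, salt: int) -> int:
    return int(np.random.SeedSequence([seed, salt]).generate_state(1)[0] % (2**31))


def run(config: RunConfig) -> dict:
    """Execute all stages; returns the in-memory results dictionary.

    Writes group mean matrices, partitions (CSV) and linkage trees (JSON),
    edge interval tables, filtered connectomes, Dc and network-FC tables,
    the five statistics tables, ``report.json`` and ``manifest.json`` to
    ``config.outdir``.  Reruns with the same config reproduce the data
    outputs bit-for-bit (manifest timings excepted).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    marker = outdir / "INCOMPLETE"
    marker.write_text("run in progress\n")

    def _stage(name):
        timings[name] = time.perf_counter()
        return name

    try:
        # ---- input -------------------------------------------------------
        stage = _stage("input")
        if config.mode == "simulate":
            cohort = generate_cohort(config.cohort)
            records = cohort.records
            pd_repairs = cohort.manifest["pd_repairs"]
            if config.write_cohort_files:
                write_cohort(cohort, outdir / "cohort")
        else:
            records = load_timeseries(config.input_dir)
            pd_repairs = []
        by_group = {
            PATIENT_GROUP: [r for r in records if r.group == PATIENT_GROUP],
            CONTROL_GROUP: [r for r in records if r.group == CONTROL_GROUP],
        }
        for group, recs in by_group.items():
            if len(recs) < 2:
                raise PipelineError(stage, f"group {group} has fewer than 2 subjects")
        covariates = _covariate_frame(records)
        timings[stage] = time.perf_counter() - timings[stage]

        # ---- connectivity ------------------------------------------------
        stage = _stage("connectivity")
        matrices = {
            group: [
                pearson_abs_matrix(r.timeseries, subject_id=r.subject_id)
                for r in recs
            ]
            for group, recs in by_group.items()
        }
        means = {
            group: group_mean_matrix(mats, group=group)
            for group, mats in matrices.items()
        }
        for group, mean in means.items():
            mean.to_csv(outdir / f"mean_fc_{group}.csv")
        timings[stage] = time.perf_counter() - timings[stage]

        # ---- clustering --------------------------------------------------
        stage = _stage("clustering")
        reference = reference_partition()
        partitions: dict[str, NetworkPartition] = {}
        for group, mean in means.items():
            raw = hierarchical_partition(mean, k=config.k, method=config.linkage)
            partitions[group] = match_to_reference(raw, reference)
            partitions[group].to_csv(outdir / f"partition_{group}.csv")
            partitions[group].tree_to_json(outdir / f"linkage_{group}.json")
        shifts = partition_shift(partitions[CONTROL_GROUP], partitions[PATIENT_GROUP])
        if config.partition_mode == "reference":
            analysis_partition = reference
        elif config.partition_mode == "pooled":
            pooled_mean = group_mean_matrix(
                matrices[PATIENT_GROUP] + matrices[CONTROL_GROUP], group="pooled"
            )
            analysis_partition = match_to_reference(
                hierarchical_partition(pooled_mean, k=config.k, method=config.linkage),
                reference,
            )
        else:
            key = CONTROL_GROUP if config.partition_mode == "nc" else PATIENT_GROUP
            analysis_partition = partitions[key]
        timings[stage] = time.perf_counter() - timings[stage]

        # ---- reliability filtering --------------------------------------
        stage = _stage("reliability")
        filtered = {}
        intervals = {}
        exclusions = {}
        preset: dict[str, "object"] = {}
        if config.ci_mode == "matched_width":
            filtered, intervals, exclusions = filter_groups_matched(
                matrices, B=config.B, alpha=config.alpha,
                seed=_derived_seed(config.seed, 0),
            )
        elif config.ci_mode == "pooled":
            pooled_intervals = compute_edge_intervals(
                matrices[PATIENT_GROUP] + matrices[CONTROL_GROUP],
                B=config.B,
                alpha=config.alpha,
                seed=_derived_seed(config.seed, 0),
                group="pooled",
            )
            preset = {g: pooled_intervals for g in matrices}
        if config.ci_mode != "matched_width":
            for idx, group in enumerate((PATIENT_GROUP, CONTROL_GROUP)):
                filtered[group], intervals[group], exclusions[group] = filter_cohort(
                    matrices[group],
                    B=config.B,
                    alpha=config.alpha,
                    seed=_derived_seed(config.seed, idx + 1),
                    group=group,
                    intervals=preset.get(group),
                )
        for group in (PATIENT_GROUP, CONTROL_GROUP):
            intervals[group].to_csv(outdir / f"edge_cis_{group}.csv")
            subdir = outdir / f"filtered_{group}"
            subdir.mkdir(exist_ok=True)
            for conn in filtered[group]:
                conn.to_csv(subdir / f"{conn.subject_id}.csv")
        with open(outdir / "exclusions.json", "w") as fh:
            json.dump(exclusions, fh, indent=2, sort_keys=True)
            fh.write("\n")
        included_ids = {
            group: [c.subject_id for c in filtered[group]] for group in filtered
        }
        cov_by_group = {
            group: covariates.set_index("subject_id")
            .loc[included_ids[group]]
            .reset_index()
            for group in filtered
        }
        timings[stage] = time.perf_counter() - timings[stage]

        # ---- metrics -----------------------------------------------------
        stage = _stage("metrics")
        dc = {group: degree_table(filtered[group]) for group in filtered}
        net_fc = {
            group: network_fc_table(
                filtered[group], analysis_partition, include_zeros=config.include_zeros
            )
            for group in filtered
        }
        for group in filtered:
            dc[group].to_csv(outdir / f"dc_{group}.csv", float_format="%.17g")
            net_fc[group].to_csv(
                outdir / f"network_fc_{group}.csv", float_format="%.17g"
            )
        timings[stage] = time.perf_counter() - timings[stage]

        # ---- statistics --------------------------------------------------
        stage = _stage("stats")
        cov_a = cov_by_group[PATIENT_GROUP]
        cov_b = cov_by_group[CONTROL_GROUP]
        network_level = network_level_compare(
            filtered[PATIENT_GROUP],
            filtered[CONTROL_GROUP],
            analysis_partition,
            cov_a,
            cov_b,
            variant=config.t_variant,
            include_zeros=config.include_zeros,
        )
        edge_level = edgewise_compare(
            filtered[PATIENT_GROUP], filtered[CONTROL_GROUP], cov_a, cov_b,
            q=config.q, variant=config.t_variant,
        )
        node_level = nodewise_compare(
            filtered[PATIENT_GROUP], filtered[CONTROL_GROUP], cov_a, cov_b,
            variant=config.t_variant,
        )
        demographics = demographics_table(covariates, variant=config.t_variant)
        mmse = np.concatenate(
            [cov_a["mmse"].to_numpy(float), cov_b["mmse"].to_numpy(float)]
        )
        # Score correlations run on the unfiltered Fisher-z matrices
        # (basis "unfiltered"): the retention band removes between-subject
        # variance by construction, so clipped values cannot carry
        # individual-differences signal.  The filtered basis is reported
        # alongside for comparison.
        raw_z = {
            group: [
                fisher_z_connectome(m, group=group)
                for m in matrices[group]
                if m.tag in included_ids[group]
            ]
            for group in matrices
        }
        raw_dc = {group: degree_table(raw_z[group]) for group in raw_z}
        raw_fc = {
            group: network_fc_table(raw_z[group], analysis_partition)
            for group in raw_z
        }
        corr_rows = []
        for basis, fc_tabs, dc_tabs in (
            ("unfiltered", raw_fc, raw_dc),
            ("filtered", net_fc, dc),
        ):
            for key in fc_tabs[PATIENT_GROUP].columns:
                pooled_vals = np.concatenate(
                    [fc_tabs[PATIENT_GROUP][key].to_numpy(),
                     fc_tabs[CONTROL_GROUP][key].to_numpy()]
                )
                if pooled_vals.std() == 0.0:
                    continue
                r, p = score_correlation(pooled_vals, mmse)
                corr_rows.append({"measure": f"FC:{key}", "basis": basis, "R": r, "p": p})
            for region in REGION_NAMES:
                pooled_vals = np.concatenate(
                    [dc_tabs[PATIENT_GROUP][region].to_numpy(),
                     dc_tabs[CONTROL_GROUP][region].to_numpy()]
                )
                if pooled_vals.std() == 0.0:
                    continue
                r, p = score_correlation(pooled_vals, mmse)
                corr_rows.append({"measure": f"Dc:{region}", "basis": basis, "R": r, "p": p})
        score_correlations = pd.DataFrame(corr_rows)
        report = GroupStatsReport(
            network_level=network_level,
            edge_level=edge_level,
            node_level=node_level,
            demographics=demographics,
            score_correlations=score_correlations,
            meta={
                "seed": config.seed,
                "B": config.B,
                "alpha": config.alpha,
                "q": config.q,
                "ci_mode": config.ci_mode,
                "partition_mode": config.partition_mode,
                "t_variant": config.t_variant,
                "include_zeros": config.include_zeros,
                "exclusions": exclusions,
                "partition_shifts": [list(s) for s in shifts],
                "overlap": {g: partitions[g].overlap for g in partitions},
                "bh_threshold": edge_level.attrs["bh_threshold"],
                "fdr_family_size": edge_level.attrs["family_size"],
                "untestable_edges": edge_level.attrs["untestable_edges"],
            },
        )
        network_level.to_csv(outdir / "network_level.csv", index=False,
                             float_format="%.17g")
        edge_level.to_csv(outdir / "edge_level.csv", index=False, float_format="%.17g")
        node_level.to_csv(outdir / "node_level.csv", index=False, float_format="%.17g")
        demographics.to_csv(outdir / "demographics.csv", index=False,
                            float_format="%.17g")
        score_correlations.to_csv(outdir / "correlations.csv", index=False,
                                  float_format="%.17g")
        with open(outdir / "report.json", "w") as fh:
            json.dump(report.to_json_dict(), fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        timings[stage] = time.perf_counter() - timings[stage]

        if config.plots:
            stage = _stage("plots")
            _write_plots(means, partitions, outdir)
            timings[stage] = time.perf_counter() - timings[stage]

        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "pd_repairs": pd_repairs,
            "exclusions": exclusions,
            "stage_timings_s": {k: round(v, 4) for k, v in timings.items()},
            "outputs": sorted(
                str(p.relative_to(outdir)) for p in outdir.rglob("*") if p.is_file()
            ),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        marker.unlink()
    except PipelineError:
        raise
    except Exception as exc:  # annotate the failing stage
        raise PipelineError(stage, str(exc)) from exc

    return {
        "records": records,
        "matrices": matrices,
        "means": means,
        "partitions": partitions,
        "analysis_partition": analysis_partition,
        "shifts": shifts,
        "filtered": filtered,
        "intervals": intervals,
        "exclusions": exclusions,
        "dc": dc,
        "network_fc": net_fc,
        "report": report,
        "manifest": manifest,
    }


def _write_plots(means, partitions, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import dendrogram

    for group, mean in means.items():
        fig, axes = plt.subplots(1, 2, figsize=(13, 5))
        im = axes[0].imshow(mean.values, vmin=0, vmax=1, cmap="viridis")
        axes[0].set_title(f"mean |r| ({group})")
        fig.colorbar(im, ax=axes[0])
        dendrogram(
            partitions[group].linkage_tree,
            labels=list(mean.region_names),
            ax=axes[1],
            leaf_font_size=5,
        )
        axes[1].set_title(f"average-linkage tree ({group})")
        fig.tight_layout()
        fig.savefig(outdir / f"overview_{group}.png", dpi=120)
        plt.close(fig)
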