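"""Repeated-cohort simulation studies of the pipeline's operating
characteristics: null calibration of the group tests, power to recover the
planted coupling increases and the planted centrality/cognition
correlation, hierarchical-clustering recovery of the planted blocks, and
frequentist coverage of the BCa interval.

These are the computations behind the package's validation numbers; they
run the same library code paths as :func:`reliafc.pipeline.run`, minus the
file I/O, so many cohorts fit in a test budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clustering import hierarchical_partition, match_to_reference, partition_shift, reference_partition
from .connectivity import group_mean_matrix, pearson_abs_matrix
from .metrics import degree_table
from .regions import NETWORK_PAIRS, NETWORKS
from .reliability import (
    bca_interval,
    bootstrap_means,
    compute_edge_intervals,
    filter_cohort,
    filter_groups_matched,
    fisher_z_connectome,
)
from .stats import edgewise_compare, network_level_compare, score_correlation
from .synth import CONTROL_GROUP, PATIENT_GROUP, CohortConfig, generate_cohort
from .pipeline import _covariate_frame

__all__ = [
    "null_cohort_config",
    "analyze_cohort",
    "null_calibration",
    "effect_recovery",
    "clustering_recovery",
    "shift_recovery",
    "bca_coverage",
]

NETWORK_KEYS = [f"{n}-{n}" for n in NETWORKS] + [f"{a}-{b}" for a, b in NETWORK_PAIRS]


def _cohort_seeds(master_seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(master_seed).generate_state(n) % (2**31)


def null_cohort_config(seed: int = 0, **overrides) -> CohortConfig:
    """Default cohort with no group effect and no planted score coupling."""
    fields = CohortConfig(seed=seed).to_dict()
    fields["group_effect"] = {}
    fields["dc_score_rho"] = 0.0
    fields.update(overrides)
    return CohortConfig(**fields)


@dataclass
class CohortAnalysis:
    """Light-weight per-cohort result set used by the repeated studies."""

    network_level: dict
    n_fdr_edges: int
    dc_mmse_r: float
    dc_mmse_p: float
    exclusions: dict
    shifts: list = field(default_factory=list)
    overlap: dict = field(default_factory=dict)


def analyze_cohort(
    config: CohortConfig,
    B: int = 2000,
    ci_mode: str = "matched_width",
    partition_mode: str = "nc",
    with_edgewise: bool = True,
    with_clustering: bool = False,
) -> CohortAnalysis:
    """Generate one cohort and run the in-memory analysis chain."""
    cohort = generate_cohort(config)
    by_group = {
        g: [r for r in cohort.records if r.group == g]
        for g in (PATIENT_GROUP, CONTROL_GROUP)
    }
    matrices = {
        g: [pearson_abs_matrix(r.timeseries, subject_id=r.subject_id) for r in recs]
        for g, recs in by_group.items()
    }
    covariates = _covariate_frame(cohort.records)

    reference = reference_partition()
    shifts: list = []
    overlap: dict = {}
    if with_clustering or partition_mode in ("nc", "amci", "pooled"):
        means = {g: group_mean_matrix(m, group=g) for g, m in matrices.items()}
        parts = {
            g: match_to_reference(hierarchical_partition(means[g]), reference)
            for g in means
        }
        overlap = {g: parts[g].overlap for g in parts}
        shifts = partition_shift(parts[CONTROL_GROUP], parts[PATIENT_GROUP])
    if partition_mode == "reference":
        partition = reference
    elif partition_mode == "amci":
        partition = parts[PATIENT_GROUP]
    else:
        partition = parts[CONTROL_GROUP]

    if ci_mode == "matched_width":
        filtered, _, exclusions = filter_groups_matched(
            matrices, B=B, seed=int(config.seed)
        )
    else:
        preset: dict = {}
        if ci_mode == "pooled":
            pooled_iv = compute_edge_intervals(
                matrices[PATIENT_GROUP] + matrices[CONTROL_GROUP],
                B=B, seed=int(config.seed), group="pooled",
            )
            preset = {g: pooled_iv for g in matrices}
        filtered = {}
        exclusions = {}
        for idx, g in enumerate((PATIENT_GROUP, CONTROL_GROUP)):
            filtered[g], _, exclusions[g] = filter_cohort(
                matrices[g], B=B, seed=int(config.seed) + idx + 1, group=g,
                intervals=preset.get(g),
            )
    included = {g: [c.subject_id for c in filtered[g]] for g in filtered}
    cov = {
        g: covariates.set_index("subject_id").loc[included[g]].reset_index()
        for g in filtered
    }

    network_level = network_level_compare(
        filtered[PATIENT_GROUP], filtered[CONTROL_GROUP], partition,
        cov[PATIENT_GROUP], cov[CONTROL_GROUP],
    )
    net_rows = {
        row["comparison"]: {"t": row["t"], "p": row["p"]}
        for row in network_level.to_dict(orient="records")
    }

    n_fdr = 0
    if with_edgewise:
        edge_level = edgewise_compare(
            filtered[PATIENT_GROUP], filtered[CONTROL_GROUP],
            cov[PATIENT_GROUP], cov[CONTROL_GROUP],
        )
        n_fdr = int(edge_level["fdr_significant"].sum())

    # score correlation on the unfiltered Fisher-z basis (see pipeline)
    raw_dc = {
        g: degree_table(
            [fisher_z_connectome(m, group=g) for m in matrices[g]
             if m.tag in included[g]]
        )
        for g in matrices
    }
    node = config.dc_score_node
    pooled_dc = np.concatenate(
        [raw_dc[PATIENT_GROUP][node].to_numpy(), raw_dc[CONTROL_GROUP][node].to_numpy()]
    )
    pooled_mmse = np.concatenate(
        [cov[PATIENT_GROUP]["mmse"].to_numpy(float), cov[CONTROL_GROUP]["mmse"].to_numpy(float)]
    )
    if pooled_dc.std() == 0.0 or pooled_mmse.std() == 0.0:
        dc_r, dc_p = 0.0, 1.0
    else:
        dc_r, dc_p = score_correlation(pooled_dc, pooled_mmse)

    return CohortAnalysis(
        network_level=net_rows,
        n_fdr_edges=n_fdr,
        dc_mmse_r=dc_r,
        dc_mmse_p=dc_p,
        exclusions=exclusions,
        shifts=shifts,
        overlap=overlap,
    )


def null_calibration(
    n_cohorts: int = 1000, B: int = 100, seed: int = 0, ci_mode: str = "matched_width"
) -> dict:
    """Type-I behaviour under the exchangeable-groups null generator.

    Returns per-comparison rejection rates of the six network-level tests
    at P < 0.05 and the fraction of cohorts with at least one
    FDR-significant edge.
    """
    seeds = _cohort_seeds(seed, n_cohorts)
    rejections = {key: 0 for key in NETWORK_KEYS}
    any_fdr = 0
    for s in seeds:
        config = null_cohort_config(seed=int(s))
        result = analyze_cohort(config, B=B, ci_mode=ci_mode, partition_mode="reference")
        for key in NETWORK_KEYS:
            if result.network_level[key]["p"] < 0.05:
                rejections[key] += 1
        if result.n_fdr_edges > 0:
            any_fdr += 1
    return {
        "n_cohorts": n_cohorts,
        "rejection_rate": {k: v / n_cohorts for k, v in rejections.items()},
        "mean_rejection_rate": float(np.mean(list(rejections.values())) / n_cohorts),
        "fdr_any_edge_rate": any_fdr / n_cohorts,
    }


def effect_recovery(
    n_seeds_fc: int = 20,
    n_seeds_rho: int = 50,
    B: int = 2000,
    seed: int = 0,
    ci_mode: str = "matched_width",
) -> dict:
    """Power to see the planted patient coupling increases and the planted
    negative degree-centrality/MMSE correlation through the full chain."""
    n = max(n_seeds_fc, n_seeds_rho)
    seeds = _cohort_seeds(seed, n)
    dn_detected = 0
    dn_stats = []
    rho_recovered = 0
    rho_values = []
    for k, s in enumerate(seeds):
        config = CohortConfig(seed=int(s))
        result = analyze_cohort(config, B=B, ci_mode=ci_mode, partition_mode="reference",
                                with_edgewise=False)
        row = result.network_level["DN-DN"]
        if k < n_seeds_fc:
            dn_stats.append((row["t"], row["p"]))
            if row["p"] < 0.05 and row["t"] > 0:  # patients listed first
                dn_detected += 1
        if k < n_seeds_rho:
            rho_values.append(result.dc_mmse_r)
            if result.dc_mmse_r < 0 and result.dc_mmse_p < 0.05:
                rho_recovered += 1
    return {
        "dn_detection_rate": dn_detected / n_seeds_fc,
        "n_seeds_fc": n_seeds_fc,
        "dn_t_mean": float(np.mean([t for t, _ in dn_stats])),
        "dc_mmse_recovery_rate": rho_recovered / n_seeds_rho,
        "n_seeds_rho": n_seeds_rho,
        "dc_mmse_r_mean": float(np.mean(rho_values)),
    }


def clustering_recovery(n_seeds: int = 20, seed: int = 0) -> dict:
    """How often hierarchical clustering recovers the planted 16/14/13 blocks.

    Per cohort, both group-mean matrices are clustered and matched; the
    score is the total overlap with the planted labels (out of 43).
    """
    seeds = _cohort_seeds(seed, n_seeds)
    reference = reference_partition()
    totals = []
    ok = 0
    for s in seeds:
        config = CohortConfig(seed=int(s))
        cohort = generate_cohort(config)
        cohort_ok = True
        for g in (PATIENT_GROUP, CONTROL_GROUP):
            mats = [
                pearson_abs_matrix(r.timeseries) for r in cohort.records if r.group == g
            ]
            mean = group_mean_matrix(mats, group=g)
            part = match_to_reference(hierarchical_partition(mean), reference)
            total = sum(part.overlap.values())
            totals.append(total)
            if total < 41:
                cohort_ok = False
        if cohort_ok:
            ok += 1
    return {
        "n_seeds": n_seeds,
        "recovery_rate": ok / n_seeds,
        "min_overlap": int(min(totals)),
        "mean_overlap": float(np.mean(totals)),
    }


def shift_recovery(
    n_seeds: int = 20, shifted: dict[str, str] | None = None, seed: int = 0
) -> dict:
    """Recovery of planted patient-group membership shifts in the
    clustered-partition comparison."""
    if shifted is None:
        shifted = {"L.aINS": "DN", "R.aINS": "DN"}  # move two CN regions into DN
    seeds = _cohort_seeds(seed, n_seeds)
    hits = 0
    for s in seeds:
        config = CohortConfig(seed=int(s), shifted_regions=dict(shifted))
        cohort = generate_cohort(config)
        parts = {}
        reference = reference_partition()
        for g in (PATIENT_GROUP, CONTROL_GROUP):
            mats = [
                pearson_abs_matrix(r.timeseries) for r in cohort.records if r.group == g
            ]
            parts[g] = match_to_reference(
                hierarchical_partition(group_mean_matrix(mats, group=g)), reference
            )
        moved = {region for region, _, _ in
                 partition_shift(parts[CONTROL_GROUP], parts[PATIENT_GROUP])}
        if set(shifted) <= moved:
            hits += 1
    return {"n_seeds": n_seeds, "recovery_rate": hits / n_seeds, "planted": shifted}


def bca_coverage(
    n_reps: int = 1000,
    n: int = 50,
    B: int = 2000,
    mu: float = 0.3,
    sigma: float = 0.1,
    seed: int = 0,
) -> dict:
    """Empirical coverage of the 95% BCa interval for a Normal mean."""
    rng = np.random.default_rng(seed)
    covered = 0
    degenerate = 0
    for _ in range(n_reps):
        sample = rng.normal(mu, sigma, size=n)
        boot = bootstrap_means(sample, B, rng)
        lower, upper, degen = bca_interval(sample, boot)
        degenerate += int(degen)
        if lower <= mu <= upper:
            covered += 1
    return {
        "n_reps": n_reps,
        "coverage": covered / n_reps,
        "degenerate": degenerate,
    }
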