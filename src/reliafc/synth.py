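"""Synthetic two-group resting-state cohort generator.

Emulates the statistical structure the downstream analysis assumes: two
cohorts (amnestic-MCI patients and normal controls) of temporally
autocorrelated 43-region BOLD-like time series whose cross-sectional
covariance has a three-block network structure (16 DN / 14 CN / 13 AN),
patient-specific coupling increases on configurable network blocks,
demographic covariates drawn from published group moments, and an MMSE
score correlated with one node's coupling strength (so a planted
degree-centrality/cognition association exists to recover).

The signal model is an AR(1) Gaussian process with a static cross-sectional
correlation target: ``x_t = phi * x_{t-1} + e_t`` with ``e_t ~ N(0,
(1-phi^2) * Sigma)``, whose stationary covariance is exactly ``Sigma``.
Only second-order structure matters to a Pearson-correlation analysis, so
no hemodynamic convolution is modeled.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .regions import N_REGIONS, NETWORKS, REFERENCE_LABELS, REGION_NAMES, region_index

__all__ = [
    "CohortConfig",
    "SubjectRecord",
    "Cohort",
    "build_group_covariance",
    "generate_subject",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

PATIENT_GROUP = "aMCI"
CONTROL_GROUP = "NC"
GROUPS = (PATIENT_GROUP, CONTROL_GROUP)

#: Eigenvalue floor used when coupling increments push a target matrix off
#: positive definiteness; repairs are recorded in the cohort manifest.
PD_FLOOR = 1e-6


class UnstableCorrelationWarning(UserWarning):
    """Raised when runs are short enough to make subject correlations noisy."""


def _default_covariate_params() -> dict:
    # Group means/SDs for age (years), education (years), MMSE (0-30 score)
    # and mean framewise displacement (mm), plus male counts, as published
    # for the 25-patient / 51-control cohort.
    return {
        PATIENT_GROUP: {
            "age": (73.60, 7.26),
            "education": (12.28, 3.12),
            "mmse": (27.52, 1.44),
            "mean_fd": (0.12, 0.07),
            "male_fraction": 17 / 25,
        },
        CONTROL_GROUP: {
            "age": (70.67, 7.00),
            "education": (12.57, 3.08),
            "mmse": (28.33, 1.34),
            "mean_fd": (0.11, 0.07),
            "male_fraction": 26 / 51,
        },
    }


def _pair_key(a: str, b: str) -> str:
    """Canonical unordered key 'DN-CN' for a network pair (or 'DN-DN')."""
    order = {name: k for k, name in enumerate(NETWORKS)}
    x, y = sorted((a, b), key=order.__getitem__)
    return f"{x}-{y}"


@dataclass
class CohortConfig:
    """Generative description of one two-group cohort.

    Coupling values are on the correlation scale.  ``group_effect`` holds
    additive increments applied to the patient group's coupling on the
    named network blocks (within-network keys like ``"DN-DN"``, between
    like ``"DN-CN"``); entries absent from the dict are 0.
    """

    n_patients: int = 25
    n_controls: int = 51
    n_regions: int = N_REGIONS  # fixed at 43
    n_timepoints: int = 235  # typical run at TR = 2 s after discarding 5 volumes
    ar_coefficient: float = 0.4
    reference_partition: dict[str, str] = field(
        default_factory=lambda: dict(REFERENCE_LABELS)
    )
    base_within_coupling: dict[str, float] = field(
        default_factory=lambda: {"DN": 0.45, "CN": 0.45, "AN": 0.45}
    )
    base_between_coupling: dict[str, float] = field(
        default_factory=lambda: {"DN-CN": 0.12, "DN-AN": 0.12, "CN-AN": 0.12}
    )
    group_effect: dict[str, float] = field(
        default_factory=lambda: {"DN-DN": 0.10, "CN-CN": 0.10, "DN-CN": 0.10, "DN-AN": 0.10}
    )
    shifted_regions: dict[str, str] = field(default_factory=dict)
    dc_score_node: str = "L.STS"
    dc_score_rho: float = -0.4
    dc_score_scale_sd: float = 0.08
    #: SD of a per-subject global coupling offset (applied to every region
    #: pair).  Models stable individual differences in overall coupling and
    #: is what makes whole-subject exclusion by the reliability filter
    #: possible at all (a subject needs a globally shifted profile for every
    #: edge to leave the group band).
    subject_coupling_sd: float = 0.0
    covariate_params: dict = field(default_factory=_default_covariate_params)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_regions != N_REGIONS:
            raise ValueError(f"n_regions is fixed at {N_REGIONS}")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must lie in [0, 1)")
        if self.n_patients < 0 or self.n_controls < 0:
            raise ValueError("group sizes must be nonnegative")
        if self.n_timepoints < 3:
            raise ValueError("need at least 3 time points")
        sizes: dict[str, int] = {}
        for name in REGION_NAMES:
            if name not in self.reference_partition:
                raise ValueError(f"reference partition misses region {name!r}")
            sizes[self.reference_partition[name]] = (
                sizes.get(self.reference_partition[name], 0) + 1
            )
        if sum(sizes.values()) != self.n_regions:
            raise ValueError("partition block sizes must sum to n_regions")
        for net in NETWORKS:
            if net not in self.base_within_coupling:
                raise ValueError(f"missing within-network coupling for {net}")
        for target in self.shifted_regions.values():
            if target not in NETWORKS:
                raise ValueError(f"shift target must be one of {NETWORKS}, got {target!r}")
        if not -1.0 < self.dc_score_rho < 1.0:
            raise ValueError("dc_score_rho must lie in (-1, 1)")
        if self.dc_score_node not in REGION_NAMES:
            raise ValueError(f"unknown dc_score_node: {self.dc_score_node!r}")

    # -- serialization helpers -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "n_controls": self.n_controls,
            "n_regions": self.n_regions,
            "n_timepoints": self.n_timepoints,
            "ar_coefficient": self.ar_coefficient,
            "reference_partition": dict(self.reference_partition),
            "base_within_coupling": dict(self.base_within_coupling),
            "base_between_coupling": dict(self.base_between_coupling),
            "group_effect": dict(self.group_effect),
            "shifted_regions": dict(self.shifted_regions),
            "dc_score_node": self.dc_score_node,
            "dc_score_rho": self.dc_score_rho,
            "dc_score_scale_sd": self.dc_score_scale_sd,
            "subject_coupling_sd": self.subject_coupling_sd,
            "covariate_params": self.covariate_params,
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class SubjectRecord:
    """One subject: [T x 43] time-series matrix plus covariates."""

    subject_id: str
    group: str
    timeseries: np.ndarray
    covariates: dict

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        # C-contiguous layout so summation order (and hence last-ulp
        # results) never depends on whether data came from disk or memory
        self.timeseries = np.ascontiguousarray(self.timeseries, dtype=float)
        if np.isnan(self.timeseries).any():
            raise ValueError("time series contains missing values")
        if np.any(self.timeseries.std(axis=0) == 0.0):
            raise ValueError("every time-series column must have nonzero variance")


@dataclass
class Cohort:
    records: list[SubjectRecord]
    manifest: dict
    config: CohortConfig


def _effective_network(config: CohortConfig, region: str, group: str) -> str:
    if group == PATIENT_GROUP and region in config.shifted_regions:
        return config.shifted_regions[region]
    return config.reference_partition[region]


def build_group_covariance(
    config: CohortConfig,
    group: str,
    subject_scale: float = 0.0,
    subject_offset: float = 0.0,
    return_repair: bool = False,
):
    """Target correlation matrix (43 x 43, unit diagonal, PD) for one group.

    ``subject_scale`` is an additive per-subject perturbation of the
    ``dc_score_node``'s couplings; it is the latent through which degree
    centrality and MMSE are tied together.  ``subject_offset`` shifts every
    coupling of one subject globally (stable individual differences in
    overall connectivity).

    If coupling increments break positive definiteness the matrix is
    repaired by flooring eigenvalues at ``PD_FLOOR`` and renormalizing the
    diagonal to 1; with ``return_repair=True`` the repair flag is returned
    alongside the matrix.
    """
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}, got {group!r}")
    nets = np.array([_effective_network(config, r, group) for r in REGION_NAMES])
    coupling = {}
    for a in NETWORKS:
        for b in NETWORKS:
            key = _pair_key(a, b)
            base = (
                config.base_within_coupling[a]
                if a == b
                else config.base_between_coupling.get(key, 0.0)
            )
            if group == PATIENT_GROUP:
                base += config.group_effect.get(key, 0.0)
            coupling[(a, b)] = base
    cov = np.empty((config.n_regions, config.n_regions))
    for a in NETWORKS:
        ia = nets == a
        for b in NETWORKS:
            ib = nets == b
            cov[np.ix_(ia, ib)] = coupling[(a, b)]
    if subject_offset != 0.0:
        cov += subject_offset
    if subject_scale != 0.0:
        node = region_index(config.dc_score_node)
        cov[node, :] += subject_scale
        cov[:, node] += subject_scale
    if subject_scale != 0.0 or subject_offset != 0.0:
        np.clip(cov, 0.0, 0.95, out=cov)
    np.fill_diagonal(cov, 1.0)
    repaired = False
    eigmin = np.linalg.eigvalsh(cov)[0]
    if eigmin <= PD_FLOOR:
        w, v = np.linalg.eigh(cov)
        w = np.maximum(w, PD_FLOOR)
        cov = (v * w) @ v.T
        d = np.sqrt(np.diag(cov))
        cov = cov / np.outer(d, d)
        np.fill_diagonal(cov, 1.0)
        repaired = True
        if np.linalg.eigvalsh(cov)[0] <= 0.0:
            offending = _pair_key(nets[0], nets[0])
            raise ValueError(
                f"covariance for group {group} not positive definite even after "
                f"eigenvalue flooring (check coupling block {offending})"
            )
    if return_repair:
        return cov, repaired
    return cov


def _simulate_timeseries(
    cov: np.ndarray, n_timepoints: int, phi: float, rng: np.random.Generator
) -> np.ndarray:
    """AR(1)-filtered Gaussian series with stationary covariance ``cov``."""
    chol = np.linalg.cholesky(cov)
    innovations = rng.standard_normal((n_timepoints, cov.shape[0])) @ chol.T
    if phi == 0.0:
        return innovations
    x0 = rng.standard_normal(cov.shape[0]) @ chol.T
    scaled = innovations * np.sqrt(1.0 - phi * phi)
    series = lfilter([1.0], [1.0, -phi], scaled, axis=0)
    decay = phi ** np.arange(1, n_timepoints + 1)
    return series + decay[:, None] * x0


def _ceiling_adjusted_mean(mu: float, sd: float, ceiling: float = 30.0) -> float:
    """Latent Gaussian mean whose ceiling-clipped expectation equals ``mu``.

    MMSE has a hard ceiling at 30, and published group means sit close to
    it; drawing N(mu, sd) and clipping would bias the observed mean low, so
    the latent mean is raised to compensate (fixed-point on
    E[min(X, c)] = m - sd * (phi(a) - a * (1 - Phi(a))), a = (c - m)/sd).
    """
    from scipy.special import ndtr

    m = mu
    for _ in range(20):
        a = (ceiling - m) / sd
        phi = np.exp(-0.5 * a * a) / np.sqrt(2.0 * np.pi)
        bias = sd * (phi - a * (1.0 - ndtr(a)))
        m_new = mu + bias
        if abs(m_new - m) < 1e-12:
            break
        m = m_new
    return float(m)


def _draw_covariates(
    config: CohortConfig, group: str, u: float, rng: np.random.Generator
) -> dict:
    params = config.covariate_params[group]
    rho = config.dc_score_rho
    age = rng.normal(*params["age"])
    education = max(0.0, rng.normal(*params["education"]))
    gender = "M" if rng.random() < params["male_fraction"] else "F"
    mean_fd = max(0.005, rng.normal(*params["mean_fd"]))
    mu, sd = params["mmse"]
    mmse_z = rho * u + np.sqrt(1.0 - rho * rho) * rng.standard_normal()
    mmse = float(np.clip(_ceiling_adjusted_mean(mu, sd) + sd * mmse_z, 0.0, 30.0))
    return {
        "age": float(age),
        "gender": gender,
        "education": float(education),
        "mean_fd": float(mean_fd),
        "mmse": mmse,
    }


def generate_subject(
    config: CohortConfig,
    group: str,
    rng: np.random.Generator,
    subject_id: str = "S0",
) -> SubjectRecord:
    """Draw one subject (time series + covariates) from the group model.

    The subject-level latent ``u ~ N(0, 1)`` scales the score node's
    coupling (``subject_scale = dc_score_scale_sd * u``) and enters MMSE
    with loading ``dc_score_rho``, so the node-strength/MMSE correlation is
    ``dc_score_rho`` in expectation.
    """
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}, got {group!r}")
    if config.n_timepoints < 4 * config.n_regions:
        warnings.warn(
            f"n_timepoints={config.n_timepoints} is short for {config.n_regions} "
            "regions; subject correlation estimates will be unstable",
            UnstableCorrelationWarning,
            stacklevel=2,
        )
    u = float(rng.standard_normal())
    scale = config.dc_score_scale_sd * u
    offset = float(rng.normal(0.0, config.subject_coupling_sd)) if config.subject_coupling_sd else 0.0
    cov = build_group_covariance(config, group, subject_scale=scale, subject_offset=offset)
    series = _simulate_timeseries(cov, config.n_timepoints, config.ar_coefficient, rng)
    covariates = _draw_covariates(config, group, u, rng)
    covariates["dc_score_scale"] = scale  # latent, kept for diagnostics
    covariates["coupling_offset"] = offset
    return SubjectRecord(
        subject_id=subject_id, group=group, timeseries=series, covariates=covariates
    )


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full two-group cohort with a reproducibility manifest."""
    seq = np.random.SeedSequence(config.seed)
    children = seq.spawn(config.n_patients + config.n_controls)
    records: list[SubjectRecord] = []
    labels = [(PATIENT_GROUP, k + 1) for k in range(config.n_patients)] + [
        (CONTROL_GROUP, k + 1) for k in range(config.n_controls)
    ]
    pd_repairs: list[str] = []
    for (group, num), child in zip(labels, children):
        subject_id = f"{group}-{num:02d}"
        rng = np.random.default_rng(child)
        record = generate_subject(config, group, rng, subject_id=subject_id)
        _, repaired = build_group_covariance(
            config,
            group,
            subject_scale=record.covariates["dc_score_scale"],
            subject_offset=record.covariates["coupling_offset"],
            return_repair=True,
        )
        if repaired:
            pd_repairs.append(subject_id)
        records.append(record)
    ids = [r.subject_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject_id in cohort")
    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_patients": config.n_patients,
        "n_controls": config.n_controls,
        "pd_repairs": pd_repairs,
    }
    return Cohort(records=records, manifest=manifest, config=config)


# ---------------------------------------------------------------------------
# File interchange: one TSV per subject + covariates.csv + manifest.json
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for record in cohort.records:
        frame = pd.DataFrame(record.timeseries, columns=list(REGION_NAMES))
        frame.to_csv(outdir / f"{record.subject_id}.tsv", sep="\t", index=False,
                     float_format="%.17g")
        rows.append(
            {
                "subject_id": record.subject_id,
                "group": record.group,
                "age": record.covariates["age"],
                "gender": record.covariates["gender"],
                "education": record.covariates["education"],
                "mean_fd": record.covariates["mean_fd"],
                "mmse": record.covariates["mmse"],
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "covariates.csv", index=False, float_format="%.17g")
    manifest = dict(cohort.manifest)
    manifest["config"] = cohort.config.to_dict()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir


def read_cohort(indir: str | Path) -> list[SubjectRecord]:
    """Load subject records written by :func:`write_cohort`."""
    indir = Path(indir)
    covariates = pd.read_csv(indir / "covariates.csv", float_precision="round_trip")
    if covariates["subject_id"].duplicated().any():
        dupes = covariates.loc[covariates["subject_id"].duplicated(), "subject_id"]
        raise ValueError(f"duplicated subject ids: {sorted(set(dupes))}")
    records = []
    for row in covariates.itertuples(index=False):
        path = indir / f"{row.subject_id}.tsv"
        frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
        missing = [name for name in REGION_NAMES if name not in frame.columns]
        if missing:
            raise ValueError(f"{path.name}: missing region column(s) {missing}")
        frame = frame[list(REGION_NAMES)]  # harmonize column order by name
        if frame.isna().any().any():
            raise ValueError(f"{path.name}: NaN cells in time series")
        records.append(
            SubjectRecord(
                subject_id=row.subject_id,
                group=row.group,
                timeseries=frame.to_numpy(dtype=float),
                covariates={
                    "age": float(row.age),
                    "gender": str(row.gender),
                    "education": float(row.education),
                    "mean_fd": float(row.mean_fd),
                    "mmse": float(row.mmse),
                },
            )
        )
    return records
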