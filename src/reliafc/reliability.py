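"""Bootstrap edge-reliability filtering of subject connectivity matrices.

For every one of the 903 region pairs, the across-subject mean of the
absolute correlation is given a 95% bias-corrected and accelerated (BCa)
bootstrap confidence interval.  A subject's edge value is preserved iff it
lies inside that interval and set to zero otherwise; subjects whose entire
filtered matrix is zero are excluded (the published analysis discarded
five such subjects).  Retained values are then Fisher z-transformed
(``atanh``), which maps 0 to 0, so zeros pass through unchanged.

BCa details
-----------
With sample mean ``theta_hat``, bootstrap means ``theta*_b`` (b = 1..B) and
jackknife leave-one-out means ``theta_(i)``:

* bias term ``z0 = Phi^-1(#{theta*_b < theta_hat} / B)`` with the
  proportion clamped to ``[1/(2B), 1 - 1/(2B)]``;
* acceleration ``a = sum(d_i^3) / (6 * (sum(d_i^2))^{3/2})`` where
  ``d_i = mean(theta_(.)) - theta_(i)``;
* adjusted levels ``alpha_j = Phi(z0 + (z0 + z_q)/(1 - a (z0 + z_q)))``
  for ``z_q = Phi^-1(alpha/2)`` and ``Phi^-1(1 - alpha/2)``;
* bounds are the corresponding empirical quantiles of the bootstrap means
  using the linear-interpolation quantile definition.

Each edge's resampling stream is seeded from ``(master_seed, edge_index)``
and the subject values are sorted before resampling, so retention depends
only on the multiset of values, never on subject order.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .connectivity import ConnectivityMatrix, edge_index_pairs
from .regions import REGION_NAMES

__all__ = [
    "EdgeIntervalSet",
    "FilteredConnectome",
    "bootstrap_means",
    "bca_interval",
    "compute_edge_intervals",
    "matched_width_intervals",
    "filter_cohort",
    "fisher_z_connectome",
]

#: |r| is clamped below 1 by this margin before atanh so z stays finite.
FISHER_CLAMP = 1e-7

#: Guard against the BCa level transform blowing up for extreme acceleration.
_MIN_DENOM = 0.1


@dataclass
class EdgeIntervalSet:
    """Per-edge BCa bounds for the across-subject mean |r| of one group."""

    group: str
    lower: np.ndarray  # 903 lower bounds (correlation units)
    upper: np.ndarray
    mean: np.ndarray  # point estimates (sample means)
    degenerate: np.ndarray  # bool, zero-spread edges
    n_subjects: int
    n_resamples: int
    alpha: float
    region_names: tuple[str, ...] = REGION_NAMES

    def to_frame(self) -> pd.DataFrame:
        iu, ju = edge_index_pairs(len(self.region_names))
        return pd.DataFrame(
            {
                "i": iu,
                "j": ju,
                "region_i": [self.region_names[k] for k in iu],
                "region_j": [self.region_names[k] for k in ju],
                "mean": self.mean,
                "lower": self.lower,
                "upper": self.upper,
                "degenerate": self.degenerate,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


@dataclass
class FilteredConnectome:
    """Fisher-z connectivity matrix with unreliable edges zeroed."""

    values: np.ndarray  # 43 x 43, atanh units, symmetric, zero diagonal
    subject_id: str
    group: str
    retained_edge_count: int
    region_names: tuple[str, ...] = REGION_NAMES

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.region_names,
                     columns=self.region_names).to_csv(path, float_format="%.17g")


def bootstrap_means(
    values: np.ndarray, B: int, rng: np.random.Generator
) -> np.ndarray:
    """B bootstrap means: each the average of n draws with replacement."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least 2 values to bootstrap a mean")
    if B < 1:
        raise ValueError("B must be positive")
    idx = rng.integers(0, n, size=(B, n))
    return values[idx].mean(axis=1)


def bca_interval(
    values: np.ndarray, boot_means: np.ndarray, alpha: float = 0.05
) -> tuple[float, float, bool]:
    """BCa interval for the mean from precomputed bootstrap means.

    Returns ``(lower, upper, degenerate)``; a zero-variance jackknife makes
    the interval degenerate at the sample mean.
    """
    values = np.asarray(values, dtype=float)
    boot = np.asarray(boot_means, dtype=float)
    n, B = values.shape[0], boot.shape[0]
    if n < 2:
        raise ValueError("need at least 2 values for a confidence interval")
    if B < 100:
        warnings.warn(
            f"B={B} bootstrap resamples give unstable interval tails",
            stacklevel=2,
        )
    theta_hat = values.mean()
    # jackknife leave-one-out means and acceleration
    loo = (theta_hat * n - values) / (n - 1)
    d = loo.mean() - loo
    ss = float(np.sum(d * d))
    # zero jackknife spread (up to summation round-off) means all values
    # coincide: the interval degenerates at the shared value, which is
    # returned exactly so that value always lies inside its own interval
    if np.sqrt(ss / n) <= 1e-12 * max(1.0, abs(theta_hat)):
        return float(values.min()), float(values.max()), True
    accel = float(np.sum(d**3) / (6.0 * ss**1.5))
    # mid-rank tie convention: ties between bootstrap means and the point
    # estimate count half, so a symmetric tied distribution gives z0 = 0
    prop = np.mean(boot < theta_hat) + 0.5 * np.mean(boot == theta_hat)
    prop = min(max(prop, 1.0 / (2 * B)), 1.0 - 1.0 / (2 * B))
    z0 = ndtri(prop)
    zq = ndtri([alpha / 2.0, 1.0 - alpha / 2.0])
    denom = np.maximum(1.0 - accel * (z0 + zq), _MIN_DENOM)
    levels = ndtr(z0 + (z0 + zq) / denom)
    lower, upper = np.quantile(boot, levels, method="linear")
    return float(lower), float(upper), False


def compute_edge_intervals(
    matrices: list[ConnectivityMatrix],
    B: int = 10000,
    alpha: float = 0.05,
    seed: int = 0,
    group: str = "pooled",
) -> EdgeIntervalSet:
    """BCa intervals for every edge's across-subject mean |r|.

    ``seed`` is the master seed; edge e resamples with the stream
    ``default_rng([seed, e])`` on the sorted subject values, making the
    intervals invariant to subject ordering.
    """
    if len(matrices) < 2:
        raise ValueError("need at least 2 subjects to compute edge intervals")
    names = matrices[0].region_names
    p = len(names)
    iu, ju = edge_index_pairs(p)
    values = np.stack([m.values[iu, ju] for m in matrices])  # n x 903
    svals = np.sort(values, axis=0)
    n_edges = svals.shape[1]
    lower = np.empty(n_edges)
    upper = np.empty(n_edges)
    degenerate = np.zeros(n_edges, dtype=bool)
    for e in range(n_edges):
        rng = np.random.default_rng([seed, e])
        boot = bootstrap_means(svals[:, e], B, rng)
        lower[e], upper[e], degenerate[e] = bca_interval(svals[:, e], boot, alpha)
    return EdgeIntervalSet(
        group=group,
        lower=lower,
        upper=upper,
        mean=values.mean(axis=0),
        degenerate=degenerate,
        n_subjects=len(matrices),
        n_resamples=B,
        alpha=alpha,
        region_names=names,
    )


def matched_width_intervals(
    groups: dict[str, list[ConnectivityMatrix]],
    B: int = 10000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, EdgeIntervalSet]:
    """Group-centered retention bands with a common pooled-shape width.

    A CI of the mean has halfwidth ~ 1.96 sigma / sqrt(n_g), so per-group
    bands retain systematically more values in the smaller group — a pure
    sample-size artifact that masquerades as a group difference.  A single
    pooled band avoids that but cancels genuine group mean differences to
    first order.  This variant takes the BCa interval of the pooled sample
    (one width, one asymmetry, shared by construction) and recenters it on
    each group's own per-edge mean, so retained values track the group mean
    while the retention fraction is size-independent.
    """
    all_matrices = [m for mats in groups.values() for m in mats]
    pooled = compute_edge_intervals(all_matrices, B=B, alpha=alpha, seed=seed,
                                    group="pooled")
    iu, ju = edge_index_pairs(len(pooled.region_names))
    out = {}
    for group, mats in groups.items():
        if len(mats) < 2:
            raise ValueError(f"group {group!r} has fewer than 2 subjects")
        values = np.stack([m.values[iu, ju] for m in mats])
        mean_g = values.mean(axis=0)
        out[group] = EdgeIntervalSet(
            group=group,
            lower=mean_g + (pooled.lower - pooled.mean),
            upper=mean_g + (pooled.upper - pooled.mean),
            mean=mean_g,
            degenerate=pooled.degenerate.copy(),
            n_subjects=len(mats),
            n_resamples=B,
            alpha=alpha,
            region_names=pooled.region_names,
        )
    return out


def filter_groups_matched(
    groups: dict[str, list[ConnectivityMatrix]],
    B: int = 10000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[dict[str, list[FilteredConnectome]], dict[str, EdgeIntervalSet], dict[str, list[str]]]:
    """Matched-width retention with leave-one-out band centers.

    Retention for subject i in group g tests the subject's edge value
    against a band whose shape is the pooled BCa interval (offsets relative
    to the pooled mean, identical for both groups) recentered on the
    group's leave-one-out mean ``(n * mean_g - x_i) / (n - 1)``.  The
    leave-one-out center removes the subject's own leverage on the band,
    which otherwise widens effective bands by ``1/(1 - 1/n_g)`` and so,
    like per-group widths, turns group size into a spurious retention
    difference.  The returned :class:`EdgeIntervalSet` per group is the
    band at the full group mean (the group-level summary).
    """
    intervals = matched_width_intervals(groups, B=B, alpha=alpha, seed=seed)
    names = next(iter(groups.values()))[0].region_names
    p = len(names)
    iu, ju = edge_index_pairs(p)
    pooled_keys = list(groups)
    # pooled offsets are identical in every returned interval set
    ref = intervals[pooled_keys[0]]
    lo_off = ref.lower - ref.mean
    hi_off = ref.upper - ref.mean
    filtered: dict[str, list[FilteredConnectome]] = {}
    excluded: dict[str, list[str]] = {}
    for group, mats in groups.items():
        values = np.stack([m.values[iu, ju] for m in mats])  # n x E
        n = values.shape[0]
        mean_g = values.mean(axis=0)
        loo = (n * mean_g - values) / (n - 1)  # per-subject band centers
        keep = (values >= loo + lo_off) & (values <= loo + hi_off)
        filtered[group] = []
        excluded[group] = []
        for row, m in enumerate(mats):
            if not keep[row].any():
                excluded[group].append(m.tag or "<unnamed>")
                continue
            retained = np.where(keep[row], values[row], 0.0)
            z = np.arctanh(np.minimum(retained, 1.0 - FISHER_CLAMP))
            mat = np.zeros((p, p))
            mat[iu, ju] = z
            mat = mat + mat.T
            filtered[group].append(
                FilteredConnectome(
                    values=mat,
                    subject_id=m.tag or "<unnamed>",
                    group=group,
                    retained_edge_count=int(keep[row].sum()),
                    region_names=names,
                )
            )
        if not filtered[group]:
            raise ValueError(
                f"all {n} subjects in group {group!r} were excluded: every edge "
                "value fell outside its reliability band"
            )
    return filtered, intervals, excluded


def fisher_z_connectome(matrix: ConnectivityMatrix, group: str = "") -> FilteredConnectome:
    """Fisher z transform of a full |r| matrix with no reliability mask.

    Used for individual-differences (score correlation) analyses, where
    clipping subject values to a group band would remove exactly the
    between-subject variance of interest.
    """
    values = np.arctanh(np.minimum(matrix.values, 1.0 - FISHER_CLAMP))
    np.fill_diagonal(values, 0.0)
    p = values.shape[0]
    return FilteredConnectome(
        values=values,
        subject_id=matrix.tag or "<unnamed>",
        group=group,
        retained_edge_count=p * (p - 1) // 2,
        region_names=matrix.region_names,
    )


def filter_cohort(
    matrices: list[ConnectivityMatrix],
    B: int = 10000,
    alpha: float = 0.05,
    seed: int = 0,
    group: str = "group",
    intervals: EdgeIntervalSet | None = None,
) -> tuple[list[FilteredConnectome], EdgeIntervalSet, list[str]]:
    """Retain-or-zero filtering of one group's subject matrices.

    Each subject's edge value is kept iff ``lower <= value <= upper`` for
    that edge's interval, zeroed otherwise, then Fisher z-transformed.
    Subjects with an all-zero filtered matrix are dropped and their ids
    returned.  Pass precomputed ``intervals`` (e.g. from the pooled sample
    of both groups) to decouple the reliability reference from the group
    being filtered.
    """
    if len(matrices) < 2:
        raise ValueError("need at least 2 subjects per group")
    if intervals is None:
        intervals = compute_edge_intervals(matrices, B=B, alpha=alpha, seed=seed, group=group)
    names = matrices[0].region_names
    p = len(names)
    iu, ju = edge_index_pairs(p)
    filtered: list[FilteredConnectome] = []
    excluded: list[str] = []
    for m in matrices:
        edge_vals = m.values[iu, ju]
        keep = (edge_vals >= intervals.lower) & (edge_vals <= intervals.upper)
        retained = np.where(keep, edge_vals, 0.0)
        z = np.arctanh(np.minimum(retained, 1.0 - FISHER_CLAMP))
        if not np.any(keep):
            excluded.append(m.tag or "<unnamed>")
            continue
        mat = np.zeros((p, p))
        mat[iu, ju] = z
        mat = mat + mat.T
        filtered.append(
            FilteredConnectome(
                values=mat,
                subject_id=m.tag or "<unnamed>",
                group=group,
                retained_edge_count=int(keep.sum()),
                region_names=names,
            )
        )
    if not filtered:
        raise ValueError(
            f"all {len(matrices)} subjects in group {group!r} were excluded: "
            "every edge value fell outside its reliability interval"
        )
    return filtered, intervals, excluded
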