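"""Group-comparison statistics for the filtered connectivity measures.

The battery mirrors the study design: nuisance covariates (age, gender,
education, mean framewise displacement) are regressed out of each measure
over the pooled sample, residuals are compared between groups with a
two-sample two-tailed t test (Student pooled-variance by default, Welch by
flag), edge-level families are corrected with Benjamini-Hochberg FDR at
q = 0.05 and node-level (degree centrality) families with Bonferroni at
0.05/43, demographics get t / chi-square tests, and cognition (MMSE)
relationships are plain Pearson correlations on the pooled sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .connectivity import edge_index_pairs
from .metrics import degree_table, network_fc_table
from .regions import NETWORK_PAIRS, NETWORKS

__all__ = [
    "GroupStatsReport",
    "residualize",
    "two_sample_t",
    "network_level_compare",
    "edgewise_compare",
    "nodewise_compare",
    "score_correlation",
    "demographics_table",
]

COVARIATE_COLUMNS = ("age", "gender", "education", "mean_fd")


@dataclass
class GroupStatsReport:
    """Bundle of the five result tables produced by one pipeline run."""

    network_level: pd.DataFrame
    edge_level: pd.DataFrame
    node_level: pd.DataFrame
    demographics: pd.DataFrame
    score_correlations: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "meta": self.meta,
            "network_level": self.network_level.to_dict(orient="records"),
            "edge_level_significant": self.edge_level[
                self.edge_level["fdr_significant"]
            ].to_dict(orient="records"),
            "node_level": self.node_level.to_dict(orient="records"),
            "demographics": self.demographics.to_dict(orient="records"),
            "score_correlations_significant": self.score_correlations[
                self.score_correlations["p"] < 0.05
            ].to_dict(orient="records"),
        }


def _design_matrix(covariates: pd.DataFrame) -> np.ndarray:
    missing = [c for c in COVARIATE_COLUMNS if c not in covariates.columns]
    if missing:
        raise ValueError(f"covariate table misses column(s): {missing}")
    if covariates[list(COVARIATE_COLUMNS)].isna().any().any():
        raise ValueError("covariate table contains missing values")
    gender = covariates["gender"]
    if gender.dtype == object:
        gender = gender.map({"M": 1.0, "F": 0.0})
        if gender.isna().any():
            raise ValueError("gender column must contain only 'M'/'F' (or 0/1)")
    X = np.column_stack(
        [
            np.ones(len(covariates)),
            covariates["age"].to_numpy(dtype=float),
            gender.to_numpy(dtype=float),
            covariates["education"].to_numpy(dtype=float),
            covariates["mean_fd"].to_numpy(dtype=float),
        ]
    )
    return X


def _check_rank(X: np.ndarray) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        names = ("intercept",) + COVARIATE_COLUMNS
        # name the columns whose removal restores full rank
        culprits = []
        for k in range(X.shape[1]):
            reduced = np.delete(X, k, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                culprits.append(names[k])
        raise ValueError(f"singular covariate design; collinear column(s): {culprits}")


def residual_projector(covariates: pd.DataFrame) -> np.ndarray:
    """The annihilator matrix M = I - X (X'X)^-1 X' for the nuisance design."""
    X = _design_matrix(covariates)
    if len(covariates) <= X.shape[1] + 1:
        raise ValueError("need more subjects than regressors + 1")
    _check_rank(X)
    return np.eye(X.shape[0]) - X @ np.linalg.pinv(X)


def residualize(values: np.ndarray, covariates: pd.DataFrame) -> np.ndarray:
    """OLS residuals of ``values`` on intercept + the four nuisance covariates.

    Fitted over the pooled sample with no group indicator (including group
    would absorb the effect under test).  Residuals have mean zero.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] != len(covariates):
        raise ValueError("values and covariates must have the same length")
    return residual_projector(covariates) @ values


def two_sample_t(
    a: np.ndarray, b: np.ndarray, variant: str = "student"
) -> tuple[float, float]:
    """Two-sample two-tailed t test; Student pooled-variance by default."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 observations")
    if variant not in ("student", "welch"):
        raise ValueError("variant must be 'student' or 'welch'")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero variance in both groups with unequal means")
    t, p = sps.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(t), float(p)


def network_level_compare(
    connectomes_a,
    connectomes_b,
    partition,
    covariates_a: pd.DataFrame,
    covariates_b: pd.DataFrame,
    variant: str = "student",
    include_zeros: bool = True,
    label_a: str = "aMCI",
    label_b: str = "NC",
) -> pd.DataFrame:
    """Six within/between network mean-FC comparisons, P < 0.05 uncorrected."""
    fc_a = network_fc_table(connectomes_a, partition, include_zeros=include_zeros)
    fc_b = network_fc_table(connectomes_b, partition, include_zeros=include_zeros)
    pooled_cov = pd.concat([covariates_a, covariates_b], ignore_index=True)
    n_a = len(fc_a)
    rows = []
    for key in [f"{n}-{n}" for n in NETWORKS] + [f"{a}-{b}" for a, b in NETWORK_PAIRS]:
        pooled = np.concatenate([fc_a[key].to_numpy(), fc_b[key].to_numpy()])
        resid = residualize(pooled, pooled_cov)
        t, p = two_sample_t(resid[:n_a], resid[n_a:], variant=variant)
        rows.append(
            {
                "comparison": key,
                f"mean_{label_a}": float(fc_a[key].mean()),
                f"mean_{label_b}": float(fc_b[key].mean()),
                "t": t,
                "p": p,
                "significant": bool(p < 0.05),
            }
        )
    return pd.DataFrame(rows)


def _stacked_edges(connectomes) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    p = len(connectomes[0].region_names)
    iu, ju = edge_index_pairs(p)
    values = np.stack([c.values[iu, ju] for c in connectomes])
    return values, iu, ju


def _mass_t(
    resid: np.ndarray, n_a: int, variant: str
) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise two-sample t on residual matrices (subjects x features)."""
    a, b = resid[:n_a], resid[n_a:]
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    diff = a.mean(axis=0) - b.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        if variant == "student":
            sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
            se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
            df = np.full(va.shape, na + nb - 2, dtype=float)
        else:
            se = np.sqrt(va / na + vb / nb)
            df = (va / na + vb / nb) ** 2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
        t = diff / se
    p = 2.0 * sps.t.sf(np.abs(t), df)
    return t, p


def edgewise_compare(
    z_a,
    z_b,
    covariates_a: pd.DataFrame,
    covariates_b: pd.DataFrame,
    q: float = 0.05,
    variant: str = "student",
) -> pd.DataFrame:
    """Per-edge residualized t tests with Benjamini-Hochberg FDR at level q.

    Edges that are zero for every subject in both groups are untestable;
    they are flagged and removed from the BH family (the family size and
    BH threshold end up in the table attributes).
    """
    if len(z_a) < 2 or len(z_b) < 2:
        raise ValueError("need at least 2 subjects per group after exclusions")
    vals_a, iu, ju = _stacked_edges(z_a)
    vals_b, _, _ = _stacked_edges(z_b)
    names = z_a[0].region_names
    pooled = np.vstack([vals_a, vals_b])
    pooled_cov = pd.concat([covariates_a, covariates_b], ignore_index=True)
    resid = residual_projector(pooled_cov) @ pooled
    testable = ~np.all(pooled == 0.0, axis=0)
    t, p = _mass_t(resid, len(z_a), variant)
    table = pd.DataFrame(
        {
            "i": iu,
            "j": ju,
            "region_i": [names[k] for k in iu],
            "region_j": [names[k] for k in ju],
            "t": np.where(testable, t, np.nan),
            "p": np.where(testable, p, np.nan),
            "testable": testable,
            "fdr_significant": False,
        }
    )
    if testable.any():
        reject, _, _, _ = multipletests(p[testable], alpha=q, method="fdr_bh")
        table.loc[testable, "fdr_significant"] = reject
        family_p = np.sort(p[testable])
        m = family_p.size
        passing = family_p[family_p <= (np.arange(1, m + 1) / m) * q]
        bh_threshold = float(passing[-1]) if passing.size else 0.0
    else:
        bh_threshold = 0.0
    table.attrs["bh_threshold"] = bh_threshold
    table.attrs["family_size"] = int(testable.sum())
    table.attrs["untestable_edges"] = int((~testable).sum())
    table.attrs["q"] = q
    return table


def nodewise_compare(
    z_a,
    z_b,
    covariates_a: pd.DataFrame,
    covariates_b: pd.DataFrame,
    alpha: float = 0.05,
    variant: str = "student",
) -> pd.DataFrame:
    """Per-region Dc comparisons, Bonferroni-corrected at alpha / 43."""
    if len(z_a) < 2 or len(z_b) < 2:
        raise ValueError("need at least 2 subjects per group after exclusions")
    dc_a = degree_table(z_a)
    dc_b = degree_table(z_b)
    names = list(dc_a.columns)
    pooled = np.vstack([dc_a.to_numpy(), dc_b.to_numpy()])
    pooled_cov = pd.concat([covariates_a, covariates_b], ignore_index=True)
    resid = residual_projector(pooled_cov) @ pooled
    testable = ~np.all(pooled == 0.0, axis=0)
    t, p = _mass_t(resid, len(z_a), variant)
    threshold = alpha / len(names)
    table = pd.DataFrame(
        {
            "region": names,
            "t": np.where(testable, t, np.nan),
            "p": np.where(testable, p, np.nan),
            "testable": testable,
            "bonferroni_significant": np.where(testable, p < threshold, False),
        }
    )
    table.attrs["bonferroni_threshold"] = threshold
    return table


def score_correlation(values: np.ndarray, scores: np.ndarray) -> tuple[float, float]:
    """Pearson R between a per-subject measure and MMSE, two-tailed p.

    p comes from the exact t transform ``t = R sqrt((n-2)/(1-R^2))`` with
    n - 2 degrees of freedom.
    """
    values = np.asarray(values, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if values.shape[0] != scores.shape[0]:
        raise ValueError("values and scores must have the same length")
    n = values.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects for a correlation")
    if values.std() == 0.0 or scores.std() == 0.0:
        raise ValueError("correlation undefined for constant input")
    r, p = sps.pearsonr(values, scores)
    return float(r), float(p)


def demographics_table(covariates: pd.DataFrame, variant: str = "student") -> pd.DataFrame:
    """Group tests for age/education/MMSE/mean FD (t) and gender (chi-square).

    The gender test is the Pearson chi-square on the 2 x 2 group-by-sex
    count table without continuity correction.
    """
    groups = sorted(covariates["group"].unique())
    if len(groups) != 2:
        raise ValueError("need exactly 2 nonempty groups")
    g_a = covariates[covariates["group"] == groups[0]]
    g_b = covariates[covariates["group"] == groups[1]]
    rows = []
    for col in ("age", "education", "mmse", "mean_fd"):
        if col not in covariates.columns:
            continue
        t, p = two_sample_t(g_a[col].to_numpy(), g_b[col].to_numpy(), variant=variant)
        rows.append(
            {
                "covariate": col,
                "test": "t",
                f"mean_{groups[0]}": float(g_a[col].mean()),
                f"mean_{groups[1]}": float(g_b[col].mean()),
                "statistic": t,
                "p": p,
            }
        )
    counts = np.array(
        [
            [(g["gender"] == "M").sum(), (g["gender"] == "F").sum()]
            for g in (g_a, g_b)
        ],
        dtype=float,
    )
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("a gender cell has expected count 0")
    chi2, p, _, _ = sps.chi2_contingency(counts, correction=False)
    rows.append(
        {
            "covariate": "gender",
            "test": "chi2",
            f"mean_{groups[0]}": float(counts[0, 0]),  # male counts
            f"mean_{groups[1]}": float(counts[1, 0]),
            "statistic": float(chi2),
            "p": float(p),
        }
    )
    return pd.DataFrame(rows)
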