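"""Generator tests: covariance construction, signal law, determinism,
covariate calibration, and file round-trips."""

import numpy as np
import pandas as pd
import pytest

from reliafc.connectivity import pearson_abs_matrix
from reliafc.regions import REFERENCE_LABELS, REGION_NAMES
from reliafc.synth import (
    CohortConfig,
    SubjectRecord,
    UnstableCorrelationWarning,
    _draw_covariates,
    build_group_covariance,
    generate_cohort,
    generate_subject,
    read_cohort,
    write_cohort,
)

from conftest import small_config


def null_config(**overrides):
    fields = CohortConfig().to_dict()
    fields["group_effect"] = {}
    fields["dc_score_rho"] = 0.0
    fields.update(overrides)
    return CohortConfig(**fields)


def block_mask(net_a, net_b):
    la = np.array([REFERENCE_LABELS[r] == net_a for r in REGION_NAMES])
    lb = np.array([REFERENCE_LABELS[r] == net_b for r in REGION_NAMES])
    mask = np.outer(la, lb) | np.outer(lb, la)
    np.fill_diagonal(mask, False)
    return mask


class TestGroupCovariance:
    def test_zero_effect_groups_identical(self):
        cfg = null_config()
        a = build_group_covariance(cfg, "aMCI")
        b = build_group_covariance(cfg, "NC")
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize(
        "pair, expected",
        [(("DN", "DN"), 0.10), (("CN", "CN"), 0.10), (("DN", "CN"), 0.10),
         (("DN", "AN"), 0.10), (("AN", "AN"), 0.0), (("CN", "AN"), 0.0)],
    )
    def test_planted_increment_exact(self, pair, expected):
        cfg = CohortConfig()
        diff = build_group_covariance(cfg, "aMCI") - build_group_covariance(cfg, "NC")
        mask = block_mask(*pair)
        assert abs(diff[mask].mean() - expected) < 1e-12
        assert abs(diff[mask]).max() - expected < 1e-12

    @pytest.mark.parametrize("group", ["aMCI", "NC"])
    @pytest.mark.parametrize("scale", [-0.3, 0.0, 0.4])
    @pytest.mark.parametrize("offset", [-0.1, 0.0, 0.1])
    def test_positive_definite_eigen_oracle(self, group, scale, offset):
        cov = build_group_covariance(
            CohortConfig(), group, subject_scale=scale, subject_offset=offset
        )
        assert np.linalg.eigvalsh(cov)[0] > 0.0
        np.testing.assert_array_equal(np.diag(cov), np.ones(43))
        np.testing.assert_allclose(cov, cov.T, atol=0)

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="group"):
            build_group_covariance(CohortConfig(), "patients")


class TestSubjectGeneration:
    def test_lln_correlation_matches_target(self):
        # white noise (no AR), very long series: empirical correlations
        # converge on the generating matrix
        cfg = null_config(
            n_timepoints=100_000, ar_coefficient=0.0,
            dc_score_scale_sd=0.0, subject_coupling_sd=0.0,
        )
        record = generate_subject(cfg, "NC", np.random.default_rng(0))
        target = np.abs(build_group_covariance(cfg, "NC"))
        np.fill_diagonal(target, 0.0)
        observed = pearson_abs_matrix(record.timeseries).values
        assert np.abs(observed - target).max() < 0.03

    def test_same_seed_identical_records(self):
        cfg = small_config()
        r1 = generate_subject(cfg, "aMCI", np.random.default_rng(5))
        r2 = generate_subject(cfg, "aMCI", np.random.default_rng(5))
        np.testing.assert_array_equal(r1.timeseries, r2.timeseries)
        assert r1.covariates == r2.covariates

    def test_invalid_group_label(self):
        with pytest.raises(ValueError, match="group"):
            generate_subject(small_config(), "MCI", np.random.default_rng(0))

    def test_short_run_warns(self):
        cfg = small_config(n_timepoints=100)
        with pytest.warns(UnstableCorrelationWarning):
            generate_subject(cfg, "NC", np.random.default_rng(0))

    def test_null_rho_uncorrelated_with_mmse(self):
        # planted rho = 0: sample correlation within the n = 76 null band
        cfg = null_config()
        cohort = generate_cohort(cfg)
        scale = np.array([r.covariates["dc_score_scale"] for r in cohort.records])
        mmse = np.array([r.covariates["mmse"] for r in cohort.records])
        groups = np.array([r.group for r in cohort.records])
        # within one group (no group-mean confound), n = 51
        sel = groups == "NC"
        r = np.corrcoef(scale[sel], mmse[sel])[0, 1]
        assert abs(r) < 0.28  # 95% Fisher-z band at n = 51 is ~0.275


class TestCohort:
    def test_default_counts(self):
        cohort = generate_cohort(CohortConfig(n_timepoints=80, seed=1))
        groups = [r.group for r in cohort.records]
        assert groups.count("aMCI") == 25
        assert groups.count("NC") == 51

    def test_control_only_cohort(self):
        cohort = generate_cohort(small_config(n_patients=0))
        assert all(r.group == "NC" for r in cohort.records)

    def test_effect_planting_across_seeds(self):
        # within-DN |r| higher in patients in nearly every seeded cohort
        dn = block_mask("DN", "DN")
        wins = 0
        for seed in range(20):
            cohort = generate_cohort(small_config(seed=seed, n_patients=8, n_controls=8))
            means = {}
            for g in ("aMCI", "NC"):
                mats = [
                    pearson_abs_matrix(r.timeseries).values
                    for r in cohort.records if r.group == g
                ]
                means[g] = np.mean([m[dn].mean() for m in mats])
            wins += means["aMCI"] > means["NC"]
        assert wins >= 19

    def test_write_read_roundtrip(self, small_cohort, tmp_path):
        write_cohort(small_cohort, tmp_path / "cohort")
        records = read_cohort(tmp_path / "cohort")
        assert len(records) == len(small_cohort.records)
        for orig, loaded in zip(small_cohort.records, records):
            assert loaded.subject_id == orig.subject_id
            assert loaded.group == orig.group
            np.testing.assert_array_equal(loaded.timeseries, orig.timeseries)
            for key in ("age", "gender", "education", "mean_fd", "mmse"):
                assert loaded.covariates[key] == orig.covariates[key]

    def test_cohort_files_byte_identical(self, tmp_path):
        cfg = small_config(n_patients=2, n_controls=3)
        for d in ("a", "b"):
            write_cohort(generate_cohort(cfg), tmp_path / d)
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_duplicate_subject_id_rejected(self, tmp_path):
        cov = pd.DataFrame(
            {"subject_id": ["S1", "S1"], "group": ["NC", "NC"],
             "age": [70, 71], "gender": ["M", "F"], "education": [12, 12],
             "mean_fd": [0.1, 0.1], "mmse": [29, 28]}
        )
        cov.to_csv(tmp_path / "covariates.csv", index=False)
        with pytest.raises(ValueError, match="duplicated subject ids"):
            read_cohort(tmp_path)

    def test_manifest_records_seed_and_hash(self, small_cohort):
        assert small_cohort.manifest["seed"] == 42
        assert small_cohort.manifest["config_hash"] == small_cohort.config.config_hash()


class TestCovariateCalibration:
    def test_pooled_means_match_published_moments(self):
        # 50 cohorts of covariate draws; pooled means within 2 SE
        rng = np.random.default_rng(7)
        cfg = CohortConfig()
        targets = {
            "aMCI": {"age": (73.60, 7.26), "education": (12.28, 3.12),
                     "mmse": (27.52, 1.44)},
            "NC": {"age": (70.67, 7.00), "education": (12.57, 3.08),
                   "mmse": (28.33, 1.34)},
        }
        sizes = {"aMCI": 25, "NC": 51}
        for group, cols in targets.items():
            draws = [
                _draw_covariates(cfg, group, rng.standard_normal(), rng)
                for _ in range(50 * sizes[group])
            ]
            frame = pd.DataFrame(draws)
            for col, (mean, sd) in cols.items():
                se = sd / np.sqrt(len(frame))
                assert abs(frame[col].mean() - mean) < 2 * se, (group, col)

    def test_mmse_respects_ceiling(self):
        rng = np.random.default_rng(0)
        cfg = CohortConfig()
        vals = [_draw_covariates(cfg, "NC", rng.standard_normal(), rng)["mmse"]
                for _ in range(500)]
        assert max(vals) <= 30.0


class TestValidation:
    def test_invariants_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(ar_coefficient=1.0)
        with pytest.raises(ValueError):
            CohortConfig(n_regions=42)
        with pytest.raises(ValueError):
            CohortConfig(dc_score_node="L.NOPE")
        with pytest.raises(ValueError):
            CohortConfig(shifted_regions={"L.STS": "XX"})

    def test_subject_record_rejects_nan_and_flat(self):
        ts = np.random.default_rng(0).standard_normal((10, 43))
        bad = ts.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            SubjectRecord("s", "NC", bad, {})
        flat = ts.copy()
        flat[:, 2] = 1.0
        with pytest.raises(ValueError, match="variance"):
            SubjectRecord("s", "NC", flat, {})
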