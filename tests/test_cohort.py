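import numpy as np
import pytest
from scipy.stats import spearmanr

import femrisk as fr


class TestGeneration:
    def test_rank_correlations_near_targets(self, cohort):
        subjects, surfaces, _ = cohort
        m = np.array([s.m for s in subjects])
        H = np.array([s.H for s in subjects])
        S = np.array([surfaces[s.subject_id].values.mean() for s in subjects])
        assert spearmanr(m, H).statistic == pytest.approx(0.429, abs=0.1)
        assert spearmanr(m, S).statistic == pytest.approx(0.264, abs=0.1)
        assert spearmanr(H, S).statistic == pytest.approx(0.294, abs=0.1)

    def test_labels_balanced_half_cases(self, cohort):
        subjects, _, labels = cohort
        assert labels.sum() == len(subjects) // 2
        assert all((s.fracture_label == 1) == (s.group == "fracture") for s in subjects)

    def test_anthropometrics_within_truncation(self, cohort):
        # union of the two groups' +/-3 SD windows (labels are reassigned
        # after drawing, so a subject's group need not match its draw group)
        subjects, _, _ = cohort
        for s in subjects:
            assert 62.6 - 3 * 14.3 - 1e-9 <= s.m <= 62.6 + 3 * 14.3 + 1e-9
            assert 1.58 - 3 * 0.0653 - 1e-9 <= s.H <= 1.58 + 3 * 0.0653 + 1e-9

    def test_odd_cohort_size_rejected(self):
        with pytest.raises(ValueError):
            fr.generate_cohort(fr.CohortGeneratorConfig(n_subjects=7), seed=1)

    def test_reproducible(self):
        cfg = fr.CohortGeneratorConfig(n_subjects=10, label_N=200)
        a = fr.generate_cohort(cfg, seed=3)
        b = fr.generate_cohort(cfg, seed=3)
        assert [s.m for s in a[0]] == [s.m for s in b[0]]
        np.testing.assert_array_equal(a[2], b[2])

    def test_no_signal_limit_auc_near_half(self):
        # shrink all variation: identical subjects, labels are pure noise
        cfg = fr.CohortGeneratorConfig(
            n_subjects=60,
            m_stats={"fracture": fr.GroupStats(63.75, 1e-6), "non-fracture": fr.GroupStats(63.75, 1e-6)},
            H_stats={"fracture": fr.GroupStats(1.58, 1e-8), "non-fracture": fr.GroupStats(1.58, 1e-8)},
            strength_params=fr.SurfaceGenParams(
                mean_strength_spec=fr.GeneralTruncNormSpec(2800.0, 1.0, 2795.0, 2805.0), coeff_sd=0.0
            ),
            label_N=500,
        )
        aucs = []
        for seed in (61, 62, 63):
            subjects, surfaces, labels = fr.generate_cohort(cfg, seed=seed)
            results = fr.run_cohort(subjects, surfaces, fr.FallStochasticModel(), N=500, seed=seed + 100)
            arf = np.array([r.ARF0 for r in results])
            arf = arf + np.random.default_rng(seed).normal(0, 1e-9, len(arf))  # break exact ties
            from sklearn.metrics import roc_auc_score

            aucs.append(roc_auc_score(labels, arf))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.15)

    def test_stronger_strength_signal_raises_auc(self, cohort_arf0, cohort):
        # inflating between-subject strength variance sharpens classification
        from sklearn.metrics import roc_auc_score

        _, _, labels = cohort
        auc_default = roc_auc_score(labels, cohort_arf0)
        cfg_wide = fr.CohortGeneratorConfig(
            strength_params=fr.SurfaceGenParams(
                mean_strength_spec=fr.GeneralTruncNormSpec(2800.0, 2000.0, 390.0, 6330.0)
            ),
            label_N=2000,
        )
        subjects, surfaces, labels_w = fr.generate_cohort(cfg_wide, seed=11)
        results = fr.run_cohort(subjects, surfaces, fr.FallStochasticModel(), N=4000, seed=12)
        auc_wide = roc_auc_score(labels_w, [r.ARF0 for r in results])
        assert auc_wide > auc_default


class TestCalibrationBands:
    def test_arf0_distribution_bands(self, cohort_arf0):
        # engineered calibration: min in [0,10]%, median in [25,45]%, max in [70,95]%
        assert 0.0 <= cohort_arf0.min() <= 10.0
        assert 25.0 <= np.median(cohort_arf0) <= 45.0
        assert 70.0 <= cohort_arf0.max() <= 95.0


class TestIO:
    def test_round_trip_byte_identical(self, cohort, tmp_path):
        subjects, surfaces, _ = cohort
        c1, s1 = tmp_path / "c1.csv", tmp_path / "s1.csv"
        fr.write_cohort(subjects, surfaces, c1, s1)
        subjects2 = fr.read_cohort(c1)
        surfaces2 = fr.read_strengths(s1)
        c2, s2 = tmp_path / "c2.csv", tmp_path / "s2.csv"
        fr.write_cohort(subjects2, surfaces2, c2, s2)
        assert c1.read_bytes() == c2.read_bytes()
        assert s1.read_bytes() == s2.read_bytes()

    def test_missing_orientation_named_in_error(self, cohort, tmp_path):
        import pandas as pd

        subjects, surfaces, _ = cohort
        c, s = tmp_path / "c.csv", tmp_path / "s.csv"
        fr.write_cohort(subjects[:2], surfaces, c, s)
        df = pd.read_csv(s)
        df = df.drop(df.index[5])  # remove one orientation row of subject S001
        df.to_csv(s, index=False)
        with pytest.raises(ValueError, match="S001"):
            fr.read_strengths(s)

    def test_empty_cohort_header_only(self, tmp_path):
        c, s = tmp_path / "c.csv", tmp_path / "s.csv"
        fr.write_cohort([], {}, c, s)
        assert c.read_text().splitlines() == ["subject_id,group,fracture_label,mass_kg,height_m,age_yr"]
        assert s.read_text().splitlines() == ["subject_id,alpha_deg,beta_deg,strength_N"]
        assert fr.read_cohort(c) == [] and fr.read_strengths(s) == {}
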