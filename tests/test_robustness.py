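"""ICC(3,1), robustness classes, morphology, bin selection, PCA importance."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from lesionsr.phantom import CohortSpec, PhantomSpec, make_cohort
from lesionsr.radiomics.table import FeatureTable
from lesionsr.robustness import (
    classify_robustness,
    icc31,
    icc_table,
    load_reference_icc,
    pca_importance,
    perturb_roi,
    relative_difference,
    robustness_report,
    select_optimal_bins,
)


def icc31_oracle(x):
    """Independent full ANOVA decomposition (explicit loops)."""
    n, k = x.shape
    grand = x.mean()
    ss_rows = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = ((x - grand) ** 2).sum()
    ms_r = ss_rows / (n - 1)
    ms_e = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)


class TestICC31:
    def test_4x3_matrix_matches_anova_oracle(self):
        x = np.array([[1, 2, 3], [2, 3, 5], [5, 6, 7], [9, 9, 10]], float)
        res = icc31(x)
        assert res.icc == pytest.approx(icc31_oracle(x), abs=1e-12)

    def test_100_random_tables_match_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(3, 12))
            k = int(rng.integers(2, 7))
            x = rng.normal(size=(n, k)) + rng.normal(size=(n, 1)) * rng.random()
            assert icc31(x).icc == pytest.approx(icc31_oracle(x), abs=1e-12)

    def test_matches_pingouin_reference(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        x = rng.normal(size=(8, 4)) + 2.0 * rng.normal(size=(8, 1))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(8), 4),
                "rater": np.tile(np.arange(4), 8),
                "score": x.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(long, targets="subject", raters="rater",
                                       ratings="score")
        # ICC(C,1): two-way, consistency, single measurement == ICC(3,1)
        icc3 = float(ref.loc[ref["Type"] == "ICC(C,1)", "ICC"].iloc[0])
        assert icc31(x).icc == pytest.approx(icc3, abs=1e-10)

    def test_additive_column_shifts_give_one(self):
        a = np.array([1.0, 4.0, 2.5, 7.0])[:, None]
        b = np.array([0.0, 10.0, -3.0])[None, :]
        res = icc31(a + b)
        assert res.icc == pytest.approx(1.0)
        assert res.ms_e == pytest.approx(0.0, abs=1e-12)

    def test_equal_row_means_k2_give_minus_one(self):
        x = np.array([[1.0, -1.0], [-2.0, 2.0], [0.5, -0.5]])
        assert icc31(x).icc == pytest.approx(-1.0)

    def test_all_constant_table_reported_na(self):
        res = icc31(np.full((4, 3), 2.0))
        assert np.isnan(res.icc)
        assert res.robustness is None
        assert "constant" in res.na_reason

    def test_invariant_to_column_offsets(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(10, 5)) + rng.normal(size=(10, 1))
        shifted = x + rng.normal(size=(1, 5)) * 10
        assert icc31(shifted).icc == pytest.approx(icc31(x).icc, abs=1e-10)

    def test_invariant_to_common_affine_rescaling(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(9, 4)) + rng.normal(size=(9, 1))
        assert icc31(3.7 * x - 11.0).icc == pytest.approx(icc31(x).icc, abs=1e-10)

    def test_cohort_parameter_recovery_closed_form(self):
        """Variance ratio 3:1 between:within -> consistency ICC 0.75 +- 0.03
        at n=500 subjects, k=6 repeated measurements."""
        sigma_b = 30.0
        sigma_w = sigma_b / np.sqrt(3.0)
        # flat lesions: the subject and replicate offsets are then the only
        # variance sources, so the closed form applies exactly
        template = PhantomSpec(shape=(6, 10, 10), lesion_center=(3, 5, 5),
                               lesion_radius_vox=2.0, noise_hu=0.0,
                               texture_amplitude_hu=0.0)
        spec = CohortSpec(n_subjects=500, between_subject_sd=sigma_b,
                          within_noise_sd=sigma_w, template=template, seed=13)
        subjects, _ = make_cohort(spec, n_repeats=6)
        stat = np.array(
            [[vol[mask].mean() for vol, mask in reps] for reps in subjects]
        )
        assert icc31(stat).icc == pytest.approx(0.75, abs=0.03)


class TestClassifyRobustness:
    @pytest.mark.parametrize(
        "icc,expected",
        [(0.5, "Poor"), (0.50001, "Moderate"), (0.75, "Moderate"),
         (0.76, "Good"), (0.9, "Good"), (0.90001, "Excellent"),
         (0.95, "Excellent"), (-0.4, "Poor"), (1.0, "Excellent")],
    )
    def test_band_boundaries(self, icc, expected):
        assert classify_robustness(icc) == expected

    def test_total_monotone_step_function(self):
        order = ["Poor", "Moderate", "Good", "Excellent"]
        grid = np.linspace(-1, 1, 401)
        classes = [order.index(classify_robustness(v)) for v in grid]
        assert np.all(np.diff(classes) >= 0)


class TestPerturbROI:
    def test_nesting_on_100_random_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            mask = ndimage.binary_dilation(
                rng.random((8, 8, 8)) > 0.9, iterations=int(rng.integers(1, 3))
            )
            if not mask.any():
                mask[4, 4, 4] = True
            versions = perturb_roi(mask)
            assert np.all(versions["opened"] <= versions["original"])
            assert np.all(versions["original"] <= versions["closed"])

    def test_single_voxel_opening_empty(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        versions = perturb_roi(mask)
        assert not versions["opened"].any()
        assert versions["closed"].sum() >= 1

    def test_spur_removed_by_opening(self):
        """A 1-voxel spur on a solid blob disappears under opening; the blob
        body survives."""
        mask = np.zeros((10, 10, 10), bool)
        mask[3:7, 3:7, 3:7] = True
        mask[5, 5, 7] = True  # spur, length 2
        mask[5, 5, 8] = True
        versions = perturb_roi(mask)
        assert not versions["opened"][5, 5, 8]  # tip gone
        assert versions["opened"][4:6, 4:6, 4:6].all()
        # closing the opened mask can re-add the removed tip's neighbourhood
        assert versions["closed"][5, 5, 8]

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            perturb_roi(np.zeros((4, 4, 4), bool))


def _table_from_matrix(per_bin_matrices, feature="F0", versions=("original", "opened", "closed")):
    """Build a FeatureTable where pivot(feature, roi_version | n_bins) yields
    the given subjects x versions matrix for each bin setting."""
    rows = []
    for nb, mat in per_bin_matrices.items():
        for sid in range(mat.shape[0]):
            for vi, version in enumerate(versions):
                rows.append((sid, version, nb, feature, mat[sid, vi], ""))
    return FeatureTable(pd.DataFrame(
        rows, columns=["subject", "roi_version", "n_bins", "feature", "value", "na_reason"]
    ))


class TestSelectOptimalBins:
    def _matrix(self, icc_high, rng, n=12):
        """Subjects x 3 matrix with high (additive) or low (noisy) agreement."""
        subj = rng.normal(size=(n, 1)) * 5
        if icc_high:
            return subj + rng.normal(size=(1, 3))
        return subj + rng.normal(size=(n, 3)) * 10

    def test_setting_with_most_excellent_features_wins(self):
        rng = np.random.default_rng(0)
        table = _table_from_matrix({
            8: self._matrix(False, rng),
            64: self._matrix(True, rng),
            128: self._matrix(False, rng),
        })
        best, summary = select_optimal_bins(table)
        assert best == 64
        assert summary.loc[summary["n_bins"] == 64, "n_excellent"].item() == 1

    def test_tie_broken_toward_smallest_bin_count(self):
        rng = np.random.default_rng(1)
        table = _table_from_matrix({
            8: self._matrix(True, rng),
            64: self._matrix(True, rng),
        })
        best, _ = select_optimal_bins(table)
        assert best == 8

    def test_high_bin_noise_pushes_selection_low(self):
        """Replicate-level noise injected only at high bin settings makes a
        lower bin count optimal."""
        rng = np.random.default_rng(2)
        mats = {}
        for nb in (8, 16, 32, 64, 128, 256):
            noisy = nb >= 64
            mats[nb] = self._matrix(not noisy, rng)
        best, _ = select_optimal_bins(_table_from_matrix(mats))
        assert best in (8, 16, 32)


class TestPCAImportance:
    def test_independent_equal_variance_features_equal_importance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(4000, 2))
        ranking = pca_importance(x, feature_names=["a", "b"])
        np.testing.assert_allclose(ranking.eigenvalues, [1.0, 1.0], atol=0.1)
        assert ranking.importance[0] == pytest.approx(ranking.importance[1], rel=0.05)

    def test_duplicated_feature_shares_importance_exactly(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(50, 3))
        x = np.column_stack([base, base[:, 0]])  # feature 3 duplicates feature 0
        ranking = pca_importance(x)
        i0 = ranking.features.index("f0")
        i3 = ranking.features.index("f3")
        assert ranking.importance[i0] == pytest.approx(ranking.importance[i3], abs=1e-9)

    def test_factor_loaded_features_outrank_noise_and_match_oracle(self):
        """Three common factors fill the top-3 PCs; a pure-noise feature
        loads outside them and must rank last."""
        rng = np.random.default_rng(2)
        n = 400
        factors = rng.normal(size=(n, 3))
        x = np.column_stack(
            [factors[:, j] + 0.1 * rng.normal(size=n) for j in range(3) for _ in range(3)]
            + [rng.normal(size=n)]
        )
        ranking = pca_importance(x)
        noise_rank = ranking.rank[9]
        assert noise_rank == 10  # least important

        # brute-force oracle: recompute the correlation eigensystem directly
        z = (x - x.mean(0)) / x.std(0, ddof=1)
        corr = z.T @ z / (n - 1)
        evals, evecs = np.linalg.eigh(corr)
        order = np.argsort(evals)[::-1]
        lam, v = evals[order][:3], evecs[:, order][:, :3]
        expected = np.sqrt((lam[None, :] * v**2).sum(axis=1))
        np.testing.assert_allclose(ranking.importance, expected, atol=1e-10)

    def test_affine_feature_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(60, 5)) + rng.normal(size=(60, 1))
        scaled = x * np.array([1.0, 10.0, 0.1, 5.0, 2.0]) + np.arange(5)
        r1 = pca_importance(x)
        r2 = pca_importance(scaled)
        np.testing.assert_allclose(r1.importance, r2.importance, atol=1e-8)

    def test_zero_variance_feature_dropped_with_log(self):
        rng = np.random.default_rng(4)
        x = np.column_stack([rng.normal(size=30), np.full(30, 2.0)])
        ranking = pca_importance(x, feature_names=["ok", "flat"])
        assert ranking.dropped == ["flat"]
        assert ranking.features == ["ok"]

    def test_variance_fraction_of_top3_reported(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(100, 6))
        ranking = pca_importance(x)
        assert 0.0 < ranking.top3_variance_fraction <= 1.0


class TestRelativeDifference:
    @pytest.mark.parametrize(
        "test,ref,expected",
        [(0.984, 0.980, 0.41), (0.905, 0.822, 10.1), (0.5, 0.5, 0.0)],
    )
    def test_printed_precision_examples(self, test, ref, expected):
        assert relative_difference(test, ref) == pytest.approx(expected, abs=0.005)


class TestRobustnessReport:
    def test_reference_fixture_counts(self):
        ref = load_reference_icc().drop(columns=["feature_id"])
        report = robustness_report(ref)
        assert report["excellent_counts"] == {
            "Original": 10, "Bicubic": 10, "GAN-SR": 10
        }
        assert report["strict_wins"]["GAN-SR"] == 4

    def test_empty_feature_subset_gives_empty_table(self):
        ref = load_reference_icc().drop(columns=["feature_id"])
        report = robustness_report(ref, diff_features=[])
        assert len(report["relative_differences"]) == 0


def test_icc_table_modes(small_phantom):
    """icc_table pivots a FeatureTable correctly in bins and perturb modes."""
    rng = np.random.default_rng(0)
    table = _table_from_matrix({8: rng.normal(size=(5, 3)), 16: rng.normal(size=(5, 3))})
    by_bins = icc_table(table, mode="bins")
    assert set(by_bins.columns) >= {"feature", "icc", "robustness"}
    by_perturb = icc_table(table, mode="perturb", n_bins=8)
    assert len(by_perturb) == 1
    with pytest.raises(ValueError, match="n_bins"):
        icc_table(table, mode="perturb")
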