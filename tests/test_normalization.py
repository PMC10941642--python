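import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metaeval.evaluation import _drop_is
from metaeval.normalization import (
    _design_matrix,
    normalize_ccmn,
    normalize_is_ratio,
    normalize_nomis,
)
from metaeval.properties import property_profile
from metaeval.synthetic import SimDesign, simulate_pair

from conftest import make_dataset


def _with_is(vals, groups, n_is=1):
    p = np.asarray(vals).shape[1]
    return make_dataset(vals, groups, is_flags=[False] * (p - n_is) + [True] * n_is)


def _mean_group_f(ds):
    """Mean one-way ANOVA F over log analytes, biological samples only."""
    mask = ~ds.is_qc()
    X = np.log(ds.matrix[mask])
    gr = ds.effective_group()[mask]
    levels = gr.unique()
    fs = [
        stats.f_oneway(*[X[(gr == lv).to_numpy(), j] for lv in levels]).statistic
        for j in range(X.shape[1])
    ]
    return float(np.nanmean(fs))


class TestCcmn:
    def test_scores_orthogonal_to_design(self):
        d = SimDesign(group_sizes=(8, 8, 8), n_features=6, n_is=2, sigma_e=0.4, seed=0)
        _, area, _ = simulate_pair(d)
        _, model = normalize_ccmn(area)
        Z, _ = _design_matrix(area)
        assert np.abs(Z.T @ model.scores).max() < 1e-8

    def test_constant_is_no_correction(self):
        rng = np.random.default_rng(1)
        vals = np.exp(rng.normal(2, 0.5, size=(6, 4)))
        vals[:, 3] = 7.0  # constant IS: zero-variance residual, zero correction
        d = _with_is(vals, ["a"] * 3 + ["b"] * 3)
        out, _ = normalize_ccmn(d)
        np.testing.assert_allclose(out.matrix, vals[:, :3], rtol=1e-10)

    def test_np_exceeding_is_count_errors(self):
        d = SimDesign(group_sizes=(4, 4), n_features=4, n_is=1, seed=0)
        _, area, _ = simulate_pair(d)
        with pytest.raises(ValueError, match="internal standards"):
            normalize_ccmn(area, n_components=2)

    def test_nonpositive_value_named(self):
        vals = np.ones((4, 3))
        vals[1, 0] = -2.0
        d = _with_is(vals, ["a", "a", "b", "b"])
        with pytest.raises(ValueError, match="s2"):
            normalize_ccmn(d)

    def test_is_columns_dropped(self):
        d = SimDesign(group_sizes=(5, 5), n_features=5, n_is=2, seed=1)
        _, area, _ = simulate_pair(d)
        out, model = normalize_ccmn(area)
        assert out.n_features == 5
        assert model.is_feature_ids == ["IS1", "IS2"]

    def test_reduces_group_cvs_on_shared_error(self):
        wins = 0
        for seed in range(50):
            d = SimDesign(
                group_sizes=(10, 10),
                n_features=8,
                n_dominant=0,
                n_is=2,
                sigma_e=0.3,
                sigma_analyte=0.05,
                sigma_sample=0.1,
                seed=seed,
            )
            _, area, _ = simulate_pair(d)
            cc, _ = normalize_ccmn(area)
            raw_mcv = property_profile(_drop_is(area)).mcv.mean()
            cc_mcv = property_profile(cc).mcv.mean()
            wins += cc_mcv < raw_mcv
        assert wins >= 48  # >= 95% of 50 seeded replicates

    def test_error_score_recovery(self):
        """np=1 score correlates with true log e_i at |r| > 0.9 (n=30, sigma_e=0.3)."""
        ok = 0
        for seed in range(50):
            d = SimDesign(
                group_sizes=(15, 15),
                n_features=10,
                n_dominant=2,
                n_is=2,
                sigma_e=0.3,
                sigma_analyte=0.1,
                sigma_sample=0.2,
                seed=seed,
            )
            _, area, truth = simulate_pair(d)
            _, model = normalize_ccmn(area, n_components=1)
            r = np.corrcoef(model.scores[:, 0], truth["log_e"].to_numpy())[0, 1]
            ok += abs(r) > 0.9
        assert ok >= 45  # >= 90% of 50 replicates

    def test_group_means_unchanged_without_shared_error(self):
        d = SimDesign(group_sizes=(20, 20), n_features=6, n_dominant=0, n_is=2,
                      sigma_e=0.0, sigma_is=0.1, sigma_analyte=0.1, seed=3)
        _, area, _ = simulate_pair(d)
        cc, _ = normalize_ccmn(area)
        raw = _drop_is(area)
        g = area.group
        for lv in g.unique():
            m_raw = np.log(raw.matrix[(g == lv).to_numpy()]).mean(axis=0)
            m_cc = np.log(cc.matrix[(g == lv).to_numpy()]).mean(axis=0)
            np.testing.assert_allclose(m_cc, m_raw, atol=0.05)


class TestNomis:
    def test_independent_is_zero_correction(self):
        # centered log analytes exactly orthogonal to the centered log IS
        logx = np.array([[1.0, 1.0], [1.0, -1.0], [-1.0, 1.0], [-1.0, -1.0]])
        logs = np.array([1.0, -1.0, -1.0, 1.0])
        vals = np.exp(np.column_stack([logx, logs]))
        d = _with_is(vals, ["a", "a", "b", "b"])
        out, _ = normalize_nomis(d)
        np.testing.assert_allclose(out.matrix, vals[:, :2], rtol=1e-10)

    def test_analyte_equal_to_is_perfect_fit(self):
        rng = np.random.default_rng(4)
        s = np.exp(rng.normal(0, 1, size=8))
        vals = np.column_stack([s, s])
        d = _with_is(vals, ["a"] * 4 + ["b"] * 4)
        out, _ = normalize_nomis(d)
        assert np.log(out.matrix[:, 0]).std() < 1e-10

    def test_group_means_unchanged_without_shared_error(self):
        d = SimDesign(group_sizes=(20, 20), n_features=6, n_dominant=0, n_is=2,
                      sigma_e=0.0, sigma_is=0.1, sigma_analyte=0.1, seed=9)
        _, area, _ = simulate_pair(d)
        nm, _ = normalize_nomis(area)
        raw = _drop_is(area)
        g = area.group
        for lv in g.unique():
            m_raw = np.log(raw.matrix[(g == lv).to_numpy()]).mean(axis=0)
            m_nm = np.log(nm.matrix[(g == lv).to_numpy()]).mean(axis=0)
            np.testing.assert_allclose(m_nm, m_raw, atol=0.05)

    def test_ccmn_retains_group_separation_better_with_leak(self):
        wins = 0
        for seed in range(25):
            d = SimDesign(
                group_sizes=(10, 10, 10),
                n_features=10,
                n_dominant=2,
                n_is=1,
                sigma_e=0.3,
                sigma_analyte=0.1,
                is_group_leak=0.5,
                seed=seed,
            )
            _, area, _ = simulate_pair(d)
            cc, _ = normalize_ccmn(area)
            nm, _ = normalize_nomis(area)
            wins += _mean_group_f(cc) >= _mean_group_f(nm)
        assert wins >= 20  # >= 80% of 25 seeds


class TestIsRatio:
    def test_unit_is_identity(self):
        vals = np.array([[2.0, 3.0, 1.0], [4.0, 5.0, 1.0]])
        d = _with_is(vals, ["a", "b"])
        out = normalize_is_ratio(d, "f3")
        np.testing.assert_array_equal(out.matrix, vals[:, :2])

    def test_arithmetic(self):
        vals = np.array([[10.0, 2.0]])
        d = _with_is(vals, ["a"])
        out = normalize_is_ratio(d, "f2")
        assert out.matrix[0, 0] == 5.0

    def test_scale_invariance(self):
        vals = np.array([[10.0, 6.0, 2.0], [3.0, 9.0, 1.5]])
        d = _with_is(vals, ["a", "b"])
        doubled = _with_is(vals * np.array([[2.0], [1.0]]), ["a", "b"])
        np.testing.assert_allclose(
            normalize_is_ratio(d, "f3").matrix,
            normalize_is_ratio(doubled, "f3").matrix,
        )

    def test_nonpositive_is_errors(self):
        vals = np.array([[1.0, 0.0]])
        d = _with_is(vals, ["a"])
        with pytest.raises(ValueError, match="non-positive"):
            normalize_is_ratio(d, "f2")

    def test_unflagged_feature_rejected(self):
        vals = np.array([[1.0, 2.0]])
        d = _with_is(vals, ["a"])
        with pytest.raises(ValueError, match="not flagged"):
            normalize_is_ratio(d, "f1")
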