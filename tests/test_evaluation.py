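import numpy as np
import pandas as pd
import pytest
from itertools import combinations

from metaeval.evaluation import (
    EvaluationConfig,
    cluster_vips,
    enumerate_schemes,
    run_benchmark,
    vip_similarity,
)
from metaeval.synthetic import SimDesign, simulate_pair

from conftest import make_dataset


class TestEnumerateSchemes:
    def test_exactly_97(self):
        assert len(enumerate_schemes()) == 97

    def test_raw_prepended(self):
        schemes = enumerate_schemes(include_raw=True)
        assert len(schemes) == 98
        assert schemes[0].canonical() == "raw"

    def test_no_duplicates(self):
        names = [s.canonical() for s in enumerate_schemes()]
        assert len(set(names)) == len(names)

    def test_block_structure(self):
        schemes = enumerate_schemes()
        by_kind = {
            "transform_only": 0,
            "scale_only": 0,
            "transform_scale": 0,
            "ccmn_only": 0,
            "ccmn_transform": 0,
            "ccmn_scale": 0,
            "ccmn_transform_scale": 0,
        }
        for s in schemes:
            t, sc, nm = s.transformation != "none", s.scaling != "none", s.normalization == "ccmn"
            key = (
                ("ccmn_" if nm else "")
                + ("transform_scale" if t and sc else "transform" if t else "scale" if sc else "only")
            )
            key = {"transform": "transform_only", "scale": "scale_only",
                   "transform_scale": "transform_scale"}.get(key, key)
            by_kind[key] += 1
        assert by_kind == {
            "transform_only": 6,
            "scale_only": 6,
            "transform_scale": 36,
            "ccmn_only": 1,
            "ccmn_transform": 6,
            "ccmn_scale": 6,
            "ccmn_transform_scale": 36,
        }

    def test_deterministic_order(self):
        a = [s.canonical() for s in enumerate_schemes(include_raw=True)]
        b = [s.canonical() for s in enumerate_schemes(include_raw=True)]
        assert a == b


class TestVipSimilarity:
    def test_identical_vectors(self):
        x = np.array([1.2, 0.3, 2.0])
        assert vip_similarity(x, x) == 1.0

    def test_unit_distance(self):
        assert vip_similarity(np.array([1.0, 0.0]), np.array([0.0, 0.0])) == pytest.approx(0.0, abs=1e-12)

    def test_normalized_worked_example(self):
        x = np.array([0.6, 0.8])
        y = np.array([0.0, 0.0])
        assert vip_similarity(x, y, normalize=True) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=5), rng.normal(size=5)
        assert vip_similarity(x, y) == vip_similarity(y, x)

    def test_can_be_negative(self):
        assert vip_similarity(np.array([3.0]), np.array([0.0])) == pytest.approx(-2.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            vip_similarity(np.ones(3), np.ones(4))


class TestClusterVips:
    def test_identical_rows_merge_first_at_zero(self):
        m = pd.DataFrame(
            [[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]], index=["a", "b", "c"]
        )
        tree = cluster_vips(m)
        Z = np.asarray(tree["linkage"])
        assert sorted(Z[0, :2]) == [0, 1]
        assert Z[0, 2] == 0.0

    def test_close_pair_merges_first(self):
        m = pd.DataFrame([[0.0], [1.0], [10.0]], index=["a", "b", "c"])
        tree = cluster_vips(m)
        Z = np.asarray(tree["linkage"])
        assert sorted(Z[0, :2]) == [0, 1]

    def test_complete_linkage_vs_naive_oracle(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(rng.normal(size=(6, 4)))
        Z = np.asarray(cluster_vips(m, method="complete")["linkage"])

        # O(n^3) naive complete-linkage agglomeration
        clusters = {i: [i] for i in range(6)}
        points = m.to_numpy()
        heights = []
        while len(clusters) > 1:
            best = None
            for a, b in combinations(sorted(clusters), 2):
                dmax = max(
                    np.linalg.norm(points[i] - points[j])
                    for i in clusters[a]
                    for j in clusters[b]
                )
                if best is None or dmax < best[0]:
                    best = (dmax, a, b)
            dmax, a, b = best
            heights.append(dmax)
            new_id = max(clusters) + 1
            clusters[new_id] = clusters.pop(a) + clusters.pop(b)
        np.testing.assert_allclose(np.sort(Z[:, 2]), np.sort(heights), atol=1e-8)

    def test_missing_values_rejected(self):
        m = pd.DataFrame([[1.0], [np.nan]])
        with pytest.raises(ValueError, match="missing"):
            cluster_vips(m)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError, match="2 rows"):
            cluster_vips(pd.DataFrame([[1.0]]))


@pytest.fixture(scope="module")
def small_pair():
    d = SimDesign(
        group_sizes=(8, 8, 8),
        n_features=8,
        n_dominant=2,
        n_is=1,
        sigma_e=0.3,
        sigma_analyte=0.1,
        seed=17,
    )
    conc, area, _ = simulate_pair(d)
    return conc, area


class TestRunBenchmark:
    def test_self_reference_raw_is_100(self, small_pair):
        conc, _ = small_pair
        report = run_benchmark(conc, conc, EvaluationConfig(profile=False))
        assert report.similarity.loc["raw", "similarity_pct"] == pytest.approx(100.0)

    def test_row_counts(self, small_pair):
        conc, area = small_pair
        report = run_benchmark(area, conc, EvaluationConfig(profile=False))
        n_rows = len(report.similarity) + len(
            {k for k in report.skipped if not k.endswith(":profile")}
        )
        assert n_rows == 98  # 97 grid schemes + raw
        assert report.vips.shape[0] == len(report.similarity) + 1  # + conc row

    def test_deterministic(self, small_pair):
        conc, area = small_pair
        r1 = run_benchmark(area, conc, EvaluationConfig(profile=False))
        r2 = run_benchmark(area, conc, EvaluationConfig(profile=False))
        pd.testing.assert_frame_equal(r1.similarity, r2.similarity)
        pd.testing.assert_frame_equal(r1.vips, r2.vips)

    def test_schemes_with_zeros_recorded_as_skipped(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(1, 10, size=(9, 4))
        vals[0, 0] = 0.0  # kills log2/log10
        is_col = np.exp(rng.normal(0, 0.1, size=(9, 1)))
        area = make_dataset(
            np.hstack([vals, is_col]),
            ["a"] * 3 + ["b"] * 3 + ["c"] * 3,
            is_flags=[False] * 4 + [True],
        )
        conc = make_dataset(vals, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        report = run_benchmark(area, conc, EvaluationConfig(profile=False))
        assert "none+log2+none" in report.skipped
        assert "log2" in report.skipped["none+log2+none"]
        assert "none+log2+none" not in report.similarity.index

    def test_key_mismatch_errors(self, small_pair):
        conc, area = small_pair
        bad = make_dataset(
            conc.matrix,
            list(conc.group),
            sample_types=list(conc.sample_type),
            feature_ids=["other"] + list(conc.feature_ids[1:]),
        )
        bad.values.index = conc.sample_ids
        with pytest.raises(ValueError, match="met01|other"):
            run_benchmark(area, bad)

    def test_noise_free_raw_is_argmax(self):
        d = SimDesign(
            group_sizes=(6, 6), n_features=6, n_dominant=1, n_is=1,
            sigma_e=0.0, sigma_analyte=0.0, seed=5,
        )
        conc, area, _ = simulate_pair(d)
        report = run_benchmark(area, conc, EvaluationConfig(profile=False))
        sim = report.similarity["similarity"]
        assert sim["raw"] == pytest.approx(1.0, abs=1e-12)
        assert sim.idxmax() == "raw"

    def test_report_written_to_directory(self, small_pair, tmp_path):
        conc, area = small_pair
        report = run_benchmark(area, conc, EvaluationConfig(profile=False))
        out = report.write(tmp_path / "rep")
        for name in ("similarity.csv", "vips.csv", "clustering.json", "config.json"):
            assert (out / name).exists()
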