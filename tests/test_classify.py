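"""Per-path means, average-based thresholds, and quadrant assignment."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from aoiscan import (
    Quadrant,
    classify,
    compute_thresholds,
    per_path_means,
)
from aoiscan.similarity import SimilarityMatrix

from .conftest import sp


def matrix_from_pairs(ids, pairs, metric="jaccard"):
    n = len(ids)
    v = np.ones((n, n))
    for (i, j), val in pairs.items():
        v[i, j] = v[j, i] = val
    return SimilarityMatrix(ids=tuple(ids), values=v, metric=metric)


class TestPerPathMeans:
    def test_two_paths_single_counterpart(self):
        m = matrix_from_pairs(["a", "b"], {(0, 1): 0.6})
        assert per_path_means(m) == pytest.approx({"a": 0.6, "b": 0.6}, abs=1e-12)

    def test_identical_paths_mean_one(self):
        m = matrix_from_pairs(["a", "b", "c"], {(0, 1): 1, (0, 2): 1, (1, 2): 1})
        assert all(v == 1.0 for v in per_path_means(m).values())

    def test_three_path_hand_computed(self):
        # pairwise {ab:0.2, ac:0.4, bc:0.6} -> means a:(.2+.4)/2, b:(.2+.6)/2, c:(.4+.6)/2
        m = matrix_from_pairs(["a", "b", "c"], {(0, 1): 0.2, (0, 2): 0.4, (1, 2): 0.6})
        means = per_path_means(m)
        assert means == pytest.approx({"a": 0.3, "b": 0.4, "c": 0.5}, abs=1e-12)

    def test_single_path_rejected(self):
        with pytest.raises(ValueError):
            per_path_means(SimilarityMatrix(("a",), np.ones((1, 1)), "jaccard"))


class TestThresholds:
    def test_single_pair(self):
        se = matrix_from_pairs(["a", "b"], {(0, 1): 0.143}, "string_edit")
        j = matrix_from_pairs(["a", "b"], {(0, 1): 1.0}, "jaccard")
        t = compute_thresholds(se, j)
        assert (t.string_edit_mean, t.jaccard_mean) == (0.143, 1.0)

    def test_mean_of_enumerated_pairs(self):
        se = matrix_from_pairs(
            ["a", "b", "c"], {(0, 1): 0.2, (0, 2): 0.4, (1, 2): 0.6}, "string_edit"
        )
        j = matrix_from_pairs(["a", "b", "c"], {(0, 1): 0.5, (0, 2): 0.5, (1, 2): 0.5})
        t = compute_thresholds(se, j)
        assert t.string_edit_mean == pytest.approx(0.4, abs=1e-12)
        assert t.jaccard_mean == pytest.approx(0.5, abs=1e-12)

    def test_id_mismatch_rejected(self):
        se = matrix_from_pairs(["a", "b"], {(0, 1): 0.2}, "string_edit")
        j = matrix_from_pairs(["b", "a"], {(0, 1): 0.2})
        with pytest.raises(ValueError, match="mismatch"):
            compute_thresholds(se, j)


sets_st = st.lists(
    st.text(alphabet="ABCDEFGH", min_size=1, max_size=10),
    min_size=3,
    max_size=8,
)


class TestClassify:
    def test_identical_paths_all_high_high(self):
        report = classify([sp("ABCD", f"p{i}") for i in range(4)])
        assert all(p.quadrant is Quadrant.HIGH_SE_HIGH_J for p in report.paths)
        assert report.thresholds.jaccard_mean == 1.0

    def test_two_identical_one_outlier(self):
        report = classify([sp("ABCD", "p1"), sp("ABCD", "p2"), sp("WXYZ", "p3")])
        assert report.quadrant_of("p1") is Quadrant.HIGH_SE_HIGH_J
        assert report.quadrant_of("p2") is Quadrant.HIGH_SE_HIGH_J
        assert report.quadrant_of("p3") is Quadrant.LOW_SE_LOW_J

    def test_two_paths_warns_and_is_high_high(self):
        with pytest.warns(UserWarning, match="uninformative"):
            report = classify([sp("ABC", "a"), sp("DEF", "b")])
        assert all(p.quadrant is Quadrant.HIGH_SE_HIGH_J for p in report.paths)

    def test_single_path_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            classify([sp("ABC")])

    @given(sets_st)
    def test_counts_sum_and_threshold_identity(self, seqs):
        paths = [sp(s, f"p{i}") for i, s in enumerate(seqs)]
        report = classify(paths)
        assert sum(report.quadrant_counts.values()) == report.n_paths == len(paths)
        # mean of per-path means equals the pair-average threshold, per metric
        se_means = [p.string_edit_mean for p in report.paths]
        j_means = [p.jaccard_mean for p in report.paths]
        assert np.mean(se_means) == pytest.approx(
            report.thresholds.string_edit_mean, abs=1e-9
        )
        assert np.mean(j_means) == pytest.approx(
            report.thresholds.jaccard_mean, abs=1e-9
        )

    @given(sets_st, st.randoms(use_true_random=False))
    def test_order_invariance(self, seqs, rnd):
        paths = [sp(s, f"p{i}") for i, s in enumerate(seqs)]
        shuffled = paths.copy()
        rnd.shuffle(shuffled)
        by_id = {p.id: p.quadrant for p in classify(paths).paths}
        by_id_shuffled = {p.id: p.quadrant for p in classify(shuffled).paths}
        assert by_id == by_id_shuffled

    def test_monotonicity_in_similarity(self):
        # raising every pairwise similarity of one path (thresholds fixed)
        # never flips it HIGH -> LOW on that metric
        ids = ["a", "b", "c", "d"]
        base = matrix_from_pairs(
            ids,
            {(0, 1): 0.2, (0, 2): 0.3, (0, 3): 0.1, (1, 2): 0.8, (1, 3): 0.7, (2, 3): 0.9},
        )
        thr = 0.5
        mean_a = per_path_means(base)["a"]
        bumped = matrix_from_pairs(
            ids,
            {(0, 1): 0.6, (0, 2): 0.7, (0, 3): 0.5, (1, 2): 0.8, (1, 3): 0.7, (2, 3): 0.9},
        )
        assert per_path_means(bumped)["a"] >= mean_a
        if mean_a >= thr:
            assert per_path_means(bumped)["a"] >= thr

    def test_report_serialization_round_trip(self, tmp_path):
        report = classify([sp("ABCD", "p1"), sp("ABCE", "p2"), sp("WXYZ", "p3")])
        out = tmp_path / "report.json"
        report.to_json(out)
        import json

        data = json.loads(out.read_text())
        assert data["n_paths"] == 3
        assert sum(data["quadrant_counts"].values()) == 3
        assert {p["id"] for p in data["paths"]} == {"p1", "p2", "p3"}
        frame = report.to_dataframe()
        assert list(frame.columns) == [
            "id",
            "string_edit_mean",
            "jaccard_mean",
            "quadrant",
            "quadrant_description",
        ]

    def test_quadrant_descriptions(self):
        assert Quadrant.HIGH_SE_HIGH_J.value == (
            "Observed similar information using similar patterns"
        )
        assert Quadrant.LOW_SE_LOW_J.value == (
            "Observed different information using different patterns"
        )
        assert Quadrant.from_flags(True, False) is Quadrant.HIGH_SE_LOW_J
        assert Quadrant.from_flags(False, True) is Quadrant.LOW_SE_HIGH_J
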