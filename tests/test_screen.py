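from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mirmarker import (
    PathwayAnnotation,
    RegNetwork,
    auc,
    auc_rank,
    auc_trapezoid,
    call_biomarkers,
    evaluate_markers,
    paired_t,
    pearson,
    screen_candidates,
)
from mirmarker.screen import DOWN_IN_TUMOR, UP_IN_TUMOR, calls_to_frame
from tests.conftest import make_study


def labels(n_pos: int, n_neg: int) -> np.ndarray:
    return np.array(["tumor"] * n_pos + ["normal"] * n_neg)


class TestAUC:
    def test_exhaustive_pair_count_example(self):
        # tumor {3, 1}, normal {2, 0}: wins 3 of 4 pairs, no ties
        value, _ = auc([3, 1, 2, 0], labels(2, 2), fold=False)
        assert value == pytest.approx(0.75)

    def test_perfect_separation(self):
        value, direction = auc([5, 6, 1, 2], labels(2, 2))
        assert value == 1.0 and direction == UP_IN_TUMOR

    def test_ties_count_half(self):
        value, _ = auc([1, 1], labels(1, 1), fold=False)
        assert value == pytest.approx(0.5)

    def test_constant_scores_warn(self):
        with pytest.warns(UserWarning, match="constant"):
            value, _ = auc([2, 2, 2, 2], labels(2, 2))
        assert value == pytest.approx(0.5)

    def test_sign_flip_complements_raw_auc(self, rng):
        scores = rng.normal(size=30)
        labs = labels(14, 16)
        a = auc_rank(scores, labs)
        b = auc_rank(-scores, labs)
        assert a + b == pytest.approx(1.0)

    def test_folding_invariant_to_sign_flip(self, rng):
        scores = rng.normal(size=30)
        labs = labels(14, 16)
        assert auc(scores, labs)[0] == pytest.approx(auc(-scores, labs)[0])

    def test_down_regulated_marker_direction(self):
        value, direction = auc([1, 2, 8, 9], labels(2, 2))
        assert value == 1.0 and direction == DOWN_IN_TUMOR

    @given(st.integers(0, 2**31 - 1))
    def test_rank_statistic_equals_trapezoid_area(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = int(rng.integers(2, 15)), int(rng.integers(2, 15))
        scores = np.round(rng.normal(size=n1 + n2), 1)  # rounding forces ties
        labs = labels(n1, n2)
        assert abs(auc_rank(scores, labs) - auc_trapezoid(scores, labs)) < 1e-12

    def test_matches_sklearn_reference(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(20):
            scores = np.round(rng.normal(size=25), 1)
            labs = labels(12, 13)
            assert auc_rank(scores, labs) == pytest.approx(
                roc_auc_score((labs == "tumor").astype(int), scores), abs=1e-12
            )


class TestEvaluateMarkers:
    def test_strong_markers_score_high_both_directions(self, rng):
        up = (2.0 ** (9 + rng.normal(0, 0.3, 10))).tolist() + (2.0 ** (5 + rng.normal(0, 0.3, 10))).tolist()
        study = make_study(
            tumor={"up_m": up[:10], "down_m": up[10:]},
            normal={"up_m": up[10:], "down_m": up[:10]},
        )
        table = evaluate_markers(study)
        assert table.loc["up_m", "auc"] > 0.95
        assert table.loc["down_m", "auc"] > 0.95
        assert table.loc["up_m", "direction"] == UP_IN_TUMOR
        assert table.loc["down_m", "direction"] == DOWN_IN_TUMOR


class TestScreenCandidates:
    def eval_table(self, aucs: dict[str, float]) -> pd.DataFrame:
        return pd.DataFrame({"auc": pd.Series(aucs), "direction": UP_IN_TUMOR}).rename_axis("mirna")

    def nog_table(self, nogs: dict[str, int]) -> pd.DataFrame:
        return pd.DataFrame({"nog": pd.Series(nogs), "out_degree": 10}).rename_axis("mirna")

    def test_seven_passing_truncated_to_top_five(self):
        aucs = {f"m{i}": 0.99 - 0.01 * i for i in range(7)}
        nogs = {f"m{i}": 5 for i in range(7)}
        out = screen_candidates(self.eval_table(aucs), self.nog_table(nogs))
        assert out == [f"m{i}" for i in range(5)]

    def test_nog_filter_excludes_high_auc_mirna(self):
        aucs = {"strong_auc": 0.99, "both": 0.95}
        nogs = {"strong_auc": 0, "both": 3}
        out = screen_candidates(self.eval_table(aucs), self.nog_table(nogs))
        assert out == ["both"]

    def test_all_nog_zero_empty_with_warning(self):
        aucs = {"a": 0.99, "b": 0.95}
        nogs = {"a": 0, "b": 0}
        with pytest.warns(UserWarning, match="no miRNA"):
            out = screen_candidates(self.eval_table(aucs), self.nog_table(nogs))
        assert out == []

    def test_tie_break_higher_nog_then_lexicographic(self):
        aucs = {"b": 0.95, "a": 0.95, "c": 0.95}
        nogs = {"b": 4, "a": 4, "c": 9}
        out = screen_candidates(self.eval_table(aucs), self.nog_table(nogs), top_k=2)
        assert out == ["c", "a"]

    def test_monotone_in_top_k(self):
        aucs = {f"m{i}": 0.9 + 0.001 * i for i in range(8)}
        nogs = {f"m{i}": 3 for i in range(8)}
        prev: list[str] = []
        for k in range(0, 9):
            with pytest.warns(UserWarning) if k == 0 else _nullcontext():
                out = screen_candidates(self.eval_table(aucs), self.nog_table(nogs), top_k=k)
            assert out[: len(prev)] == prev
            prev = out


class _nullcontext:
    def __enter__(self):
        return self

    def __exit__(self, *a):
        return False


class TestCallBiomarkers:
    def setup_method(self):
        self.net = RegNetwork(
            edges={
                ("m1", "HUB1"): frozenset({"db"}),   # in-degree 1: independent
                ("m1", "G1"): frozenset({"db"}),
                ("m2", "G1"): frozenset({"db"}),     # G1 co-regulated
                ("m2", "HUB2"): frozenset({"db"}),   # independent but irrelevant pathway
            }
        )
        self.ann = PathwayAnnotation(
            assignments={"HUB1": {"hsa03022"}, "HUB2": {"hsa00010"}, "G1": {"hsa03022"}},
            relevant={"hsa03022"},
        )

    def test_single_relevant_independent_hub_called(self):
        calls = call_biomarkers(["m1", "m2"], {"HUB1", "HUB2"}, self.net, self.ann)
        assert [(c.mirna, c.hub_gene) for c in calls] == [("m1", "HUB1")]
        assert calls[0].pathways == frozenset({"hsa03022"})

    def test_coregulated_hub_never_called(self):
        calls = call_biomarkers(["m1", "m2"], {"G1", "HUB2"}, self.net, self.ann)
        assert calls == []

    def test_frame_round_trip_columns(self):
        calls = call_biomarkers(["m1"], {"HUB1"}, self.net, self.ann)
        frame = calls_to_frame(calls)
        assert list(frame.columns) == ["mirna", "hub_gene", "pathways", "auc", "nog", "hub_degree"]
        assert frame.loc[0, "pathways"] == "hsa03022"


class TestValidationStats:
    def test_paired_t_hand_value(self):
        t, p = paired_t([3, 5, 7], [1, 2, 3])
        assert t == pytest.approx(3 * np.sqrt(3), abs=1e-9)
        assert 0 < p < 1

    def test_paired_t_degenerate_flagged(self):
        with pytest.warns(UserWarning, match="zero variance"):
            t, p = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert np.isnan(t) and np.isnan(p)

    def test_pearson_hand_value(self):
        r, p = pearson([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8)

    def test_pearson_perfect_line(self):
        r, _ = pearson([0.0, 1.0, 2.0], [1.0, 3.0, 5.0])
        assert r == pytest.approx(1.0)

    def test_pearson_symmetric_and_affine_invariant(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        assert pearson(x, y)[0] == pytest.approx(pearson(y, x)[0])
        assert pearson(2.5 * x + 3, y)[0] == pytest.approx(pearson(x, y)[0])

    def test_pearson_constant_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            r, p = pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(r)
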