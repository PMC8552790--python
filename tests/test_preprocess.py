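from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mirmarker import (
    ExpressionStudy,
    PreprocessConfig,
    ValidationError,
    filter_missing,
    impute,
    minmax_normalize,
    run_preprocess,
    smote_balance,
)
from tests.conftest import make_study


def study_from_matrix(rows: dict[str, list[float]], labels: list[str]) -> ExpressionStudy:
    cols = [f"s{i+1}" for i in range(len(next(iter(rows.values()))))]
    return ExpressionStudy(
        values=pd.DataFrame(rows, index=cols).T,
        labels=pd.Series(dict(zip(cols, labels))),
    )


LBL5 = ["tumor", "tumor", "tumor", "normal", "normal"]


class TestFilterMissing:
    def test_strict_inequality_at_threshold(self):
        study = study_from_matrix(
            {
                "full": [1, 2, 3, 4, 5],
                "two_of_five": [1, np.nan, 3, np.nan, 5],   # 40% missing -> dropped
                "one_of_five": [1, np.nan, 3, 4, 5],        # exactly 20% -> kept
            },
            LBL5,
        )
        out = filter_missing(study, 0.2)
        assert list(out.values.index) == ["full", "one_of_five"]

    def test_all_dropped_hard_error(self):
        study = study_from_matrix({"r": [np.nan, np.nan, 1.0, np.nan, np.nan]}, LBL5)
        with pytest.raises(ValidationError):
            filter_missing(study, 0.1)


class TestImpute:
    def test_moderate_outlier_survives_z3_but_not_z1_4(self):
        study = study_from_matrix({"r": [1.0, 1.0, 1.0, 100.0, 1.0]}, LBL5)
        # drop the padding 5th sample: use 4 samples as in the hand computation
        study = study.subset_samples(["s1", "s2", "s3", "s4"])
        kept = impute(study, z_thresh=3.0)
        assert kept.values.loc["r"].tolist() == [1.0, 1.0, 1.0, 100.0]
        replaced = impute(study, z_thresh=1.4)
        assert replaced.values.loc["r"].tolist() == [1.0, 1.0, 1.0, 1.0]

    def test_missing_replaced_by_row_median(self):
        study = study_from_matrix({"r": [2.0, np.nan, 4.0, 2.0, 4.0]}, LBL5)
        out = impute(study, z_thresh=10.0)
        assert out.values.loc["r", "s2"] == 3.0

    def test_clean_row_unchanged(self):
        study = study_from_matrix({"r": [1.0, 2.0, 3.0, 4.0, 5.0]}, LBL5)
        out = impute(study, 3.0)
        assert out.values.equals(study.values)
        assert not out.values.isna().any().any()


class TestSmote:
    def imbalanced(self, n_tumor=6, n_normal=2, seed=5):
        rng = np.random.default_rng(seed)
        return make_study(
            tumor={m: rng.uniform(1, 10, n_tumor).tolist() for m in ["a", "b", "c"]},
            normal={m: rng.uniform(1, 10, n_normal).tolist() for m in ["a", "b", "c"]},
        )

    def test_balanced_input_unchanged(self, toy_study):
        out = smote_balance(toy_study, k=1, seed=0)
        assert out.values.equals(toy_study.values)

    def test_counts_equal_and_originals_untouched(self):
        study = self.imbalanced()
        with pytest.warns(UserWarning, match="clamping"):
            out = smote_balance(study, k=5, seed=1)
        assert len(out.tumor_samples) == len(out.normal_samples) == 6
        orig = [s for s in study.samples]
        assert out.values.loc[:, orig].equals(study.values)
        assert len(out.synthetic_samples) == 4

    def test_synthetic_points_on_segment_between_two_minority_points(self):
        """With a minority of two points and k=1 every synthetic sample is a
        convex combination of them."""
        study = self.imbalanced(n_tumor=8, n_normal=2)
        out = smote_balance(study, k=1, seed=3)
        X = study.values.loc[:, study.normal_samples].to_numpy()
        lo, hi = X.min(axis=1), X.max(axis=1)
        for s in out.synthetic_samples:
            v = out.values[s].to_numpy()
            assert np.all(v >= lo - 1e-12) and np.all(v <= hi + 1e-12)

    def test_seed_determinism(self):
        study = self.imbalanced()
        a = smote_balance(study, k=1, seed=9)
        b = smote_balance(study, k=1, seed=9)
        assert a.values.equals(b.values)
        c = smote_balance(study, k=1, seed=10)
        assert not a.values.equals(c.values)

    def test_minority_of_one_hard_error(self):
        study = self.imbalanced(n_tumor=4, n_normal=1)
        with pytest.raises(ValidationError, match="size 1"):
            smote_balance(study, k=1, seed=0)


class TestMinmax:
    def test_hand_example(self):
        study = study_from_matrix({"r": [1.0, 3.0, 5.0, 1.0, 5.0]}, LBL5)
        out = minmax_normalize(study)
        assert out.values.loc["r"].tolist() == [0.0, 0.5, 1.0, 0.0, 1.0]

    def test_already_spanning(self):
        study = study_from_matrix({"r": [0.0, 1.0, 0.0, 1.0, 0.0]}, LBL5)
        assert minmax_normalize(study).values.loc["r"].tolist() == study.values.loc["r"].tolist()

    def test_constant_row_zeros_with_warning(self):
        study = study_from_matrix({"r": [7.0] * 5}, LBL5)
        with pytest.warns(UserWarning, match="constant"):
            out = minmax_normalize(study)
        assert (out.values.loc["r"] == 0).all()

    def test_rows_span_unit_interval(self, rng):
        study = study_from_matrix(
            {f"r{i}": rng.uniform(0, 50, 5).tolist() for i in range(10)}, LBL5
        )
        out = minmax_normalize(study)
        assert np.allclose(out.values.min(axis=1), 0.0)
        assert np.allclose(out.values.max(axis=1), 1.0)


class TestChain:
    def test_full_chain_output_clean_and_balanced(self):
        rng = np.random.default_rng(11)
        study = make_study(
            tumor={m: rng.uniform(1, 10, 7).tolist() for m in ["a", "b", "c", "d"]},
            normal={m: rng.uniform(1, 10, 3).tolist() for m in ["a", "b", "c", "d"]},
        )
        study.values.iloc[0, 0] = np.nan
        cfg = PreprocessConfig(smote_k=2, seed=4)
        out = run_preprocess(study, cfg)
        assert not out.values.isna().any().any()
        assert len(out.tumor_samples) == len(out.normal_samples)
        assert float(out.values.min().min()) >= 0.0 and float(out.values.max().max()) <= 1.0

    def test_each_step_idempotent_on_own_output(self):
        rng = np.random.default_rng(12)
        study = make_study(
            tumor={m: rng.uniform(1, 10, 6).tolist() for m in ["a", "b", "c"]},
            normal={m: rng.uniform(1, 10, 2).tolist() for m in ["a", "b", "c"]},
        )
        filtered = filter_missing(study, 0.2)
        assert filter_missing(filtered, 0.2).values.equals(filtered.values)
        imputed = impute(filtered, 3.0)
        assert impute(imputed, 3.0).values.equals(imputed.values)
        balanced = smote_balance(imputed, k=1, seed=0)
        assert smote_balance(balanced, k=1, seed=0).values.equals(balanced.values)
        normed = minmax_normalize(balanced)
        renormed = minmax_normalize(normed)
        assert np.allclose(normed.values.to_numpy(), renormed.values.to_numpy())

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            PreprocessConfig(max_missing_frac=1.5)
        with pytest.raises(ValueError):
            PreprocessConfig(z_thresh=0)
        with pytest.raises(ValueError):
            PreprocessConfig(smote_k=0)
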