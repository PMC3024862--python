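import math

import numpy as np
import pandas as pd
import pytest

from regmine import bayes
from regmine.bayes import (
    BayesModel,
    LRTable,
    TrainConfig,
    fit_lr_table_1d,
    fit_lr_table_2d,
    lookup_lr,
    train_model,
)
from regmine.features import FeatureVector


def _fv(**kw):
    base = dict(
        pcc=0.5, pcc_defined=True, eld=1.0, dmean=0.2, dsd=0.1,
        modulus=2.0, angle=30.0, vector_defined=True,
        go_score=3.0, go_available=True,
    )
    base.update(kw)
    return FeatureVector(**base)


def _flat_table(name, lr_value, n_bins=4):
    edges = np.linspace(-400, 400, n_bins + 1)
    ones = np.ones(n_bins, dtype=int)
    return LRTable(name, edges, ones, ones, np.full(n_bins, lr_value), 1.0)


def _flat_joint(names, lr_value, n_bins=4):
    edges = np.linspace(-400, 400, n_bins + 1)
    ones = np.ones((n_bins, n_bins), dtype=int)
    return bayes.JointLRTable(
        tuple(names), edges, edges, ones, ones,
        np.full((n_bins, n_bins), lr_value), 1.0,
    )


def _random_features(rng, n, label):
    return pd.DataFrame(
        {
            "tf": [f"a{i}" for i in range(n)],
            "tg": [f"b{i}" for i in range(n)],
            "pcc": rng.uniform(-1, 1, n),
            "pcc_defined": True,
            "eld": rng.uniform(0, 5, n),
            "dmean": rng.uniform(0, 2, n),
            "dsd": rng.uniform(0, 2, n),
            "modulus": rng.uniform(0, 10, n),
            "angle": rng.uniform(0, 360, n),
            "vector_defined": True,
            "go_score": rng.integers(0, 10, n).astype(float),
            "go_available": True,
            "label": float(label),
        }
    )


class TestFitLrTable1d:
    def test_identical_distributions_give_near_unit_ratios(self):
        rng = np.random.default_rng(0)
        table = fit_lr_table_1d(rng.normal(size=5000), rng.normal(size=5000))
        assert np.all(table.lr > 0.8) and np.all(table.lr < 1.25)

    def test_fully_separated_classes_match_hand_computed_smoothing(self):
        table = fit_lr_table_1d(
            [10.0] * 10, [0.0] * 10, n_bins=2, pseudocount=1.0
        )
        # ((0+1)/12)/((10+1)/12) and ((10+1)/12)/((0+1)/12)
        assert table.lr == pytest.approx([1 / 11, 11.0])

    def test_empty_class_is_error(self):
        with pytest.raises(ValueError):
            fit_lr_table_1d([1.0, 2.0], [])

    def test_few_distinct_values_reduce_bins_with_warning(self):
        with pytest.warns(UserWarning, match="distinct"):
            table = fit_lr_table_1d(
                [0.0, 0.0, 1.0, 1.0] * 5, [0.0, 1.0] * 10, n_bins=10
            )
        assert table.n_bins < 10

    def test_counts_conserve_training_sizes(self):
        rng = np.random.default_rng(1)
        pos, neg = rng.normal(size=137), rng.normal(size=89)
        table = fit_lr_table_1d(pos, neg)
        assert table.pos_counts.sum() == 137
        assert table.neg_counts.sum() == 89

    def test_invariant_to_joint_monotone_transform(self):
        rng = np.random.default_rng(2)
        pos, neg = rng.normal(size=300), rng.normal(0.5, 1.2, size=300)
        t1 = fit_lr_table_1d(pos, neg)
        t2 = fit_lr_table_1d(np.exp(pos), np.exp(neg))
        assert np.array_equal(t1.pos_counts, t2.pos_counts)
        assert np.array_equal(t1.neg_counts, t2.neg_counts)


class TestFitLrTable2d:
    def test_identical_clouds_give_near_unit_ratios(self):
        rng = np.random.default_rng(3)
        table = fit_lr_table_2d(
            rng.normal(size=(10000, 2)), rng.normal(size=(10000, 2)), 4, 4
        )
        assert np.all(np.abs(table.lr - 1.0) < 0.3)

    def test_positives_confined_to_one_cell_maximize_it(self):
        rng = np.random.default_rng(4)
        neg = rng.uniform(0, 1, size=(400, 2))
        pos = rng.uniform(0.9, 1.0, size=(400, 2))
        table = fit_lr_table_2d(pos, neg, 3, 3)
        assert table.lr[-1, -1] == table.lr.max()

    def test_2x2_fixture_matches_enumerated_counts(self):
        # pooled marginal medians split at 0; counts enumerated by hand
        pos = [(-1, -1), (-1, -1), (1, 1), (2, 2)]
        neg = [(1, -2), (1, -2), (-2, 1), (2, 2)]
        table = fit_lr_table_2d(pos, neg, 2, 2, pseudocount=1.0)
        assert table.pos_counts.tolist() == [[2, 0], [0, 2]]
        assert table.neg_counts.tolist() == [[0, 1], [2, 1]]
        expect = ((np.array([[2, 0], [0, 2]]) + 1) / 8.0) / (
            (np.array([[0, 1], [2, 1]]) + 1) / 8.0
        )
        assert table.lr == pytest.approx(expect)

    def test_counts_conserved(self):
        rng = np.random.default_rng(5)
        table = fit_lr_table_2d(
            rng.normal(size=(77, 2)), rng.normal(size=(55, 2))
        )
        assert table.pos_counts.sum() == 77
        assert table.neg_counts.sum() == 55


class TestLookupLr:
    def test_below_first_edge_clamps_to_bin_zero(self):
        table = fit_lr_table_1d([0, 1, 2, 3.0], [2, 3, 4, 5.0], n_bins=2)
        assert lookup_lr(table, -100.0) == table.lr[0]
        assert lookup_lr(table, 100.0) == table.lr[-1]

    def test_interior_edge_belongs_to_right_bin(self):
        table = fit_lr_table_1d(
            [0.0, 1.0, 2.0, 3.0], [1.0, 2.0, 3.0, 4.0], n_bins=2
        )
        mid = table.bin_edges[1]
        idx = bayes._bin_index(table.bin_edges, np.array([mid]))[0]
        assert idx == 1

    def test_undefined_value_is_non_informative(self):
        table = _flat_table("pcc", 7.0)
        assert lookup_lr(table, None) == 1.0
        assert lookup_lr(table, math.nan) == 1.0


class TestTrainModel:
    def _frame(self, n=50, seed=0):
        rng = np.random.default_rng(seed)
        pos = _random_features(rng, n, 1)
        pos["pcc"] += 0.3  # mild signal
        neg = _random_features(rng, n, 0)
        return pd.concat([pos, neg], ignore_index=True)

    def test_four_tables_with_go(self):
        model = train_model(self._frame())
        assert set(model.tables) == {"pcc_eld", "dmean_dsd", "modulus_angle", "go"}

    def test_go_absent_gives_three_tables(self):
        model = train_model(self._frame(), go_present=False)
        assert set(model.tables) == {"pcc_eld", "dmean_dsd", "modulus_angle"}

    def test_prior_default_and_override(self):
        frame = self._frame()
        assert train_model(frame).prior_odds == pytest.approx(1.0)
        model = train_model(frame, TrainConfig(prior_odds=0.01))
        assert model.prior_odds == 0.01

    def test_too_few_training_pairs_is_error(self):
        with pytest.raises(ValueError, match=">= 10"):
            train_model(self._frame(n=5))

    def test_constant_feature_group_skipped_with_warning(self):
        frame = self._frame()
        frame["go_score"] = 1.0
        with pytest.warns(UserWarning, match="go"):
            model = train_model(frame)
        assert "go" not in model.tables


class TestIntegration:
    def test_posterior_equals_prior_when_all_lookups_unit(self):
        model = BayesModel(
            prior_odds=0.37,
            tables={
                "pcc_eld": bayes.fit_lr_table_2d(
                    [(0, 0)] * 20, [(0.5, 0.5)] * 20, 2, 2
                ),
            },
        )
        fv = _fv(pcc_defined=False)  # group undefined -> LR 1
        assert bayes.posterior_odds(model, fv) == pytest.approx(0.37)

    def test_prior_times_group_ratios(self):
        model = BayesModel(
            prior_odds=0.1,
            tables={
                "pcc_eld": _flat_joint(("pcc", "eld"), 5.0),
                "dmean_dsd": _flat_joint(("dmean", "dsd"), 2.0),
                "modulus_angle": _flat_joint(("modulus", "angle"), 1.0),
                "go": _flat_table("go", 1.0),
            },
        )
        assert bayes.posterior_odds(model, _fv()) == pytest.approx(1.0)

    def test_log_total_lr_is_additive_over_groups(self, benchmark_frame):
        model = train_model(benchmark_frame)
        rng = np.random.default_rng(7)
        rows = benchmark_frame.iloc[rng.choice(len(benchmark_frame), 100)]
        from regmine.features import frame_row_to_vector

        for _, row in rows.iterrows():
            fv = frame_row_to_vector(row)
            total = bayes.total_lr(model, fv)
            log_sum = sum(
                math.log(v) for v in bayes.group_lrs(model, fv).values()
            )
            assert math.log(total) == pytest.approx(log_sum, abs=1e-9)

    def test_classification_cutoff_conventions(self):
        model = BayesModel(
            prior_odds=1.0, tables={"go": _flat_table("go", 2.0)}, lr_cutoff=2.0
        )
        score, call = bayes.classify(model, _fv())
        assert score == pytest.approx(2.0) and call  # >= cutoff is positive
        model.lr_cutoff = math.inf
        assert not bayes.classify(model, _fv())[1]
        model.lr_cutoff = 1e-300
        assert bayes.classify(model, _fv())[1]

    def test_pcc_only_signal_preserves_pcc_ranking(self):
        rng = np.random.default_rng(11)
        n = 1000
        pos = _random_features(rng, n, 1)
        neg = _random_features(rng, n, 0)
        pos["pcc"] = np.clip(rng.normal(0.6, 0.15, n), -1, 1)
        neg["pcc"] = np.clip(rng.normal(0.0, 0.3, n), -1, 1)
        frame = pd.concat([pos, neg], ignore_index=True)
        model = train_model(frame)
        integrated = bayes.score_frame(model, frame)
        pcc_only = bayes.score_frame(model, frame, groups=["pcc_eld"])
        from scipy.stats import spearmanr

        rho = spearmanr(integrated, pcc_only).statistic
        assert rho >= 0.95


class TestSerialization:
    def test_round_trip_preserves_scores(self, tmp_path, benchmark_frame):
        model = train_model(benchmark_frame)
        path = tmp_path / "model.json"
        bayes.save_model(model, path)
        loaded = bayes.load_model(path)
        s1 = bayes.score_frame(model, benchmark_frame)
        s2 = bayes.score_frame(loaded, benchmark_frame)
        assert np.allclose(s1, s2)
        assert loaded.prior_odds == model.prior_odds

    def test_wrong_format_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"format": "other"}')
        with pytest.raises(ValueError, match="model file"):
            bayes.load_model(path)
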