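import itertools

import numpy as np
import pandas as pd
import pytest

from entropy2d import (
    SweepConfig,
    SweepResult,
    average_accuracy,
    average_max_accuracy,
    best_scale_table,
    evaluate_classifiers,
    pairwise_texture_matrix,
    parameter_optimality_map,
    run_sweep,
    split_dataset,
)
from entropy2d.classify import accuracy_band


class TestSplitDataset:
    def test_histology_sized_split_counts(self):
        """825 + 551 rows at 75/25 → exactly 1032 train and 344 test."""
        y = np.array(["epithelium"] * 825 + ["stroma"] * 551)
        X = np.arange(len(y), dtype=float)[:, None]
        X_tr, X_te, y_tr, y_te = split_dataset(X, y, 0.75, seed=0)
        assert (len(y_tr), len(y_te)) == (1032, 344)

    def test_texture_pair_sized_split_counts(self):
        """41 + 41 rows at 75/25 → exactly 61 train and 21 test."""
        y = np.array([0] * 41 + [1] * 41)
        X = np.arange(82, dtype=float)[:, None]
        _, _, y_tr, y_te = split_dataset(X, y, 0.75, seed=0)
        assert (len(y_tr), len(y_te)) == (61, 21)

    def test_deterministic_and_stratified(self, rng):
        X = rng.normal(size=(40, 3))
        y = np.repeat([0, 1], 20)
        a = split_dataset(X, y, 0.75, seed=3)
        b = split_dataset(X, y, 0.75, seed=3)
        for u, v in zip(a, b):
            assert np.array_equal(u, v)
        assert np.bincount(a[2]).tolist() == [15, 15]

    def test_disjoint_and_exhaustive(self, rng):
        X = rng.normal(size=(20, 2))
        y = np.repeat([0, 1], 10)
        X_tr, X_te, _, _ = split_dataset(X, y, 0.75, seed=1)
        combined = np.vstack([X_tr, X_te])
        assert combined.shape == X.shape
        assert {tuple(r) for r in combined} == {tuple(r) for r in X}

    def test_row_order_invariance(self, rng):
        X = rng.normal(size=(24, 2))
        y = np.repeat([0, 1], 12)
        perm = rng.permutation(24)
        a = split_dataset(X, y, 0.75, seed=5)
        b = split_dataset(X[perm], y[perm], 0.75, seed=5)
        assert {tuple(r) for r in a[0]} == {tuple(r) for r in b[0]}

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(np.zeros((3, 1)), np.array([0, 0, 1]), 0.75, 0)


class TestEvaluateClassifiers:
    def test_perfectly_separable_features(self):
        X_tr = np.array([[0.0]] * 10 + [[1.0]] * 10)
        y_tr = np.repeat([0, 1], 10)
        X_te = np.array([[0.0]] * 4 + [[1.0]] * 4)
        y_te = np.repeat([0, 1], 4)
        scores = evaluate_classifiers(X_tr, y_tr, X_te, y_te)
        for fam in ("naive_bayes", "decision_tree", "svm", "mlp"):
            assert scores[fam] == 1.0
        assert scores["knn"]["max"] == 1.0 and scores["knn"]["mean"] == 1.0

    def test_identical_features_yield_majority_share(self):
        X_tr = np.zeros((30, 1))
        y_tr = np.array([0] * 20 + [1] * 10)
        X_te = np.zeros((9, 1))
        y_te = np.array([0] * 6 + [1] * 3)
        scores = evaluate_classifiers(X_tr, y_tr, X_te, y_te)
        for fam in ("naive_bayes", "decision_tree", "svm", "mlp"):
            assert scores[fam] == pytest.approx(6 / 9)

    def test_permuted_labels_near_chance(self, rng):
        """With labels shuffled, no family should beat chance by more than
        three binomial standard deviations of the test size."""
        X = np.vstack([rng.normal(0, 1, (60, 3)), rng.normal(2, 1, (60, 3))])
        y = rng.permutation(np.repeat([0, 1], 60))
        X_tr, X_te, y_tr, y_te = split_dataset(X, y, 0.75, seed=0)
        scores = evaluate_classifiers(X_tr, y_tr, X_te, y_te)
        bound = 0.5 + 3 * np.sqrt(0.25 / len(y_te))
        for fam in ("naive_bayes", "decision_tree", "svm", "mlp"):
            assert scores[fam] <= bound
        assert scores["knn"]["max"] <= bound

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError):
            evaluate_classifiers(np.zeros((5, 1)), np.zeros(5), np.zeros((2, 1)), np.zeros(2))

    def test_dimensionality_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate_classifiers(
                np.zeros((6, 2)), np.repeat([0, 1], 3), np.zeros((2, 3)), np.array([0, 1])
            )


def _mock_records() -> pd.DataFrame:
    """Fixed sweep table with hand-computable summaries.

    Fuzzy grid m=1, n=2, r ∈ {0.12, 0.48}, τ ∈ {1, 2}; KNN appears with
    two k variants whose mean is the family cell accuracy.
    """
    cells = {
        (0.12, 1): {"naive_bayes": 0.8, "decision_tree": 0.6, "svm": 0.7, "mlp": 0.9, "k=1": 0.6, "k=3": 0.8},
        (0.12, 2): {"naive_bayes": 0.9, "decision_tree": 0.7, "svm": 0.8, "mlp": 1.0, "k=1": 0.8, "k=3": 0.9},
        (0.48, 1): {"naive_bayes": 0.7, "decision_tree": 0.5, "svm": 0.6, "mlp": 0.8, "k=1": 0.5, "k=3": 0.7},
        (0.48, 2): {"naive_bayes": 0.6, "decision_tree": 0.8, "svm": 0.9, "mlp": 0.7, "k=1": 0.9, "k=3": 1.0},
    }
    rows = []
    for (r, tau), accs in cells.items():
        for key, acc in accs.items():
            family = "knn" if key.startswith("k=") else key
            rows.append(
                {
                    "algorithm": "fuzzy", "m": 1, "n": 2, "r": r, "c": np.nan,
                    "tau": tau, "class_a": None, "class_b": None,
                    "family": family, "variant": key if family == "knn" else "",
                    "accuracy": acc,
                }
            )
    return pd.DataFrame(rows)


class TestSummaryMetrics:
    def test_average_accuracy_hand_computed(self):
        assert average_accuracy(_mock_records()) == pytest.approx(75.5)

    def test_average_max_accuracy_hand_computed(self):
        # family maxima: nb 0.9, dt 0.8, svm 0.9, mlp 1.0, knn 1.0
        assert average_max_accuracy(_mock_records()) == pytest.approx(92.0)

    def test_average_max_at_least_average(self, rng):
        records = _mock_records()
        for _ in range(10):
            records["accuracy"] = rng.uniform(0, 1, len(records))
            assert average_max_accuracy(records) >= average_accuracy(records)

    def test_missing_family_rejected(self):
        records = _mock_records()
        assert pytest.raises(
            ValueError, average_max_accuracy, records[records["family"] != "svm"]
        )

    def test_empty_result_rejected(self):
        with pytest.raises(ValueError):
            average_accuracy(pd.DataFrame())

    def test_optimality_map_hand_counted(self):
        omap = parameter_optimality_map(_mock_records(), "fuzzy")
        # single-valued parameters collect all five votes
        assert omap["m"] == {1: 5} and omap["n"] == {2: 5}
        # every family's marginal over r peaks (or ties) at 0.12
        assert omap["r"] == {0.12: 5, 0.48: 0}
        for tally in omap.values():
            assert sum(tally.values()) == 5

    def test_optimality_map_incomplete_grid_rejected(self):
        records = _mock_records()
        broken = records[~((records["r"] == 0.48) & (records["tau"] == 2))]
        with pytest.raises(ValueError):
            parameter_optimality_map(broken, "fuzzy")

    def test_best_scale_hand_computed_with_tie_rule(self):
        table = best_scale_table(_mock_records())
        # naive Bayes and MLP tie across τ and fall back to the smaller τ
        assert table == {
            "naive_bayes": 1, "decision_tree": 2, "svm": 2, "mlp": 1, "knn": 2,
        }


class TestPairwiseMatrix:
    @staticmethod
    def _pairwise_records():
        rows = []
        data = {
            ("A", "B"): {"fuzzy": [0.9, 0.9], "dispersion": [0.8]},
            ("A", "C"): {"fuzzy": [0.6], "dispersion": [0.69]},
            ("B", "C"): {"fuzzy": [0.85], "dispersion": [0.7]},
        }
        for (a, b), by_alg in data.items():
            for alg, accs in by_alg.items():
                for i, acc in enumerate(accs):
                    rows.append(
                        {
                            "algorithm": alg, "m": 2, "n": np.nan, "r": np.nan, "c": 3,
                            "tau": i + 1, "class_a": a, "class_b": b,
                            "family": "svm", "variant": "", "accuracy": acc,
                        }
                    )
        return pd.DataFrame(rows)

    def test_winner_accuracy_and_bands(self):
        mat = pairwise_texture_matrix(self._pairwise_records()).set_index(["class_a", "class_b"])
        assert mat.loc[("A", "B")].tolist() == ["fuzzy", 90.0, "high"]
        assert mat.loc[("A", "C")].tolist() == ["dispersion", 69.0, "low"]
        # exactly 85% sits in the closed mid band
        assert mat.loc[("B", "C")].tolist() == ["fuzzy", 85.0, "mid"]

    def test_band_boundaries(self):
        assert accuracy_band(85.0) == "mid"
        assert accuracy_band(85.0001) == "high"
        assert accuracy_band(70.0) == "mid"
        assert accuracy_band(69.9999) == "low"

    def test_non_pairwise_records_rejected(self):
        with pytest.raises(ValueError):
            pairwise_texture_matrix(_mock_records())


@pytest.fixture(scope="module")
def tiny_sweep():
    from entropy2d import TextureSpec, make_two_class_dataset

    images, labels = make_two_class_dataset(
        8,
        TextureSpec("grating", 32, 4, 20.0),
        TextureSpec("white_noise", 32),
        seed=2,
    )
    cfg = SweepConfig(
        fuzzy_ms=(1,), fuzzy_ns=(2,), fuzzy_rs=(0.36,),
        disp_ms=(2,), disp_cs=(3,), taus=(1, 2),
    )
    return run_sweep(images, labels, cfg), cfg


class TestRunSweep:
    def test_record_coverage(self, tiny_sweep):
        res, cfg = tiny_sweep
        # 2 algorithm cells × 2 τ × (4 families + 9 knn variants)
        assert len(res.records) == 2 * 2 * 13
        assert not res.failures
        assert res.records["accuracy"].between(0, 1).all()

    def test_all_families_present(self, tiny_sweep):
        res, _ = tiny_sweep
        assert set(res.records["family"]) == {
            "naive_bayes", "decision_tree", "svm", "mlp", "knn",
        }

    def test_csv_roundtrip(self, tiny_sweep, tmp_path):
        res, _ = tiny_sweep
        p = tmp_path / "sweep.csv"
        res.to_csv(p)
        back = SweepResult.from_csv(p)
        assert np.allclose(back.records["accuracy"], res.records["accuracy"])

    def test_pairwise_mode_covers_all_pairs(self):
        from entropy2d import TextureSpec, make_texture

        rng = np.random.default_rng(0)
        images, labels = [], []
        for ci, period in enumerate((4, 8, 16)):
            for i in range(6):
                images.append(
                    make_texture(TextureSpec("grating", 32, period, 20.0, seed=int(rng.integers(2**31))))
                )
                labels.append(f"p{period}")
        cfg = SweepConfig(
            fuzzy_ms=(1,), fuzzy_ns=(2,), fuzzy_rs=(0.36,),
            taus=(1,), algorithms=("fuzzy",),
        )
        res = run_sweep(images, labels, cfg)
        pairs = set(map(tuple, res.records[["class_a", "class_b"]].drop_duplicates().values))
        assert pairs == {("p16", "p4"), ("p16", "p8"), ("p4", "p8")}
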