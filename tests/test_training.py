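"""Loss function, LR schedule, splitting protocol and the training loop."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flairvol.architecture import build_3d_cnn
from flairvol.training import (
    TrainingConfig,
    cross_entropy,
    kfold,
    lr_at,
    split_train_test,
    train,
    volumes_to_slice_dataset,
)


class TestCrossEntropy:
    def test_perfect_prediction_limit(self):
        eps = 1e-7
        y = np.array([1.0, 0, 0, 0])
        y_hat = np.array([1 - eps, eps / 3, eps / 3, eps / 3])
        assert cross_entropy(y, y_hat) == pytest.approx(0.0, abs=1e-5)

    def test_uniform_binary_closed_form(self):
        """y=(1,0), p=(0.5,0.5): both output terms contribute ln 2."""
        val = cross_entropy(np.array([1.0, 0.0]), np.array([0.5, 0.5]))
        assert val == pytest.approx(2 * np.log(2), rel=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy(np.array([1.0, 0.0]), np.array([0.3, 0.3, 0.4]))

    @given(st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_matches_term_by_term_oracle(self, seed):
        """Summed-BCE equals an independent per-term python summation."""
        r = np.random.default_rng(seed)
        n = int(r.integers(2, 8))
        y = np.zeros(n)
        y[r.integers(n)] = 1.0
        p = r.dirichlet(np.ones(n))
        expected = 0.0
        for i in range(n):
            pc = min(max(p[i], 1e-7), 1 - 1e-7)
            expected += -(y[i] * np.log(pc) + (1 - y[i]) * np.log(1 - pc))
        assert cross_entropy(y, p) == pytest.approx(expected, abs=1e-12)

    def test_nonnegative_and_permutation_invariant(self, rng):
        y = np.eye(4)[rng.integers(0, 4, size=6)]
        p = rng.dirichlet(np.ones(4), size=6)
        val = cross_entropy(y, p)
        assert val >= 0
        perm = rng.permutation(4)
        assert cross_entropy(y[:, perm], p[:, perm]) == pytest.approx(val, rel=1e-12)

    def test_categorical_variant(self):
        y = np.array([0.0, 1.0, 0.0, 0.0])
        p = np.array([0.1, 0.6, 0.2, 0.1])
        assert cross_entropy(y, p, kind="categorical") == pytest.approx(-np.log(0.6), rel=1e-9)


class TestLrSchedule:
    def test_initial_value_exact(self):
        assert lr_at(0, TrainingConfig()) == 0.01

    @pytest.mark.parametrize("decay", [0.9, 0.5, 0.99])
    def test_closed_form_at_multiples_of_decay_step(self, decay):
        cfg = TrainingConfig(lr_decay=decay)
        assert lr_at(300, cfg) == pytest.approx(0.01 * decay, rel=1e-12)
        assert lr_at(600, cfg) == pytest.approx(0.01 * decay**2, rel=1e-12)

    def test_continuous_exponent(self):
        cfg = TrainingConfig(lr_decay=0.9)
        assert lr_at(150, cfg) == pytest.approx(0.01 * 0.9**0.5, rel=1e-12)

    def test_monotone_nonincreasing(self):
        cfg = TrainingConfig(lr_decay=0.95)
        vals = [lr_at(s, cfg) for s in range(0, 2000, 37)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize(
        "kwargs", [{"lr_init": 0}, {"lr_decay": 1.0}, {"lr_decay": 0.0}, {"decay_step": 0}]
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TrainingConfig(**kwargs)


def _manifest(per_class):
    rows = []
    for label, n in per_class.items():
        for i in range(n):
            rows.append({"subject_id": f"{label}{i:03d}", "label": label})
    return pd.DataFrame(rows)


class TestSplitTrainTest:
    def test_75_25_arithmetic(self):
        m = _manifest({"HC": 25, "NCI": 25, "VaMCI": 25, "VaD": 25})
        plan = split_train_test(m, seed=0)
        assert len(plan.train_ids) == 75 and len(plan.test_ids) == 25
        for label in ("HC", "NCI", "VaMCI", "VaD"):
            n_tr = sum(s.startswith(label) for s in plan.train_ids)
            assert n_tr in (18, 19)  # within one subject of 0.75 * 25

    def test_deterministic_given_seed(self):
        m = _manifest({"HC": 10, "NCI": 12, "VaMCI": 9, "VaD": 8})
        assert split_train_test(m, seed=5) == split_train_test(m, seed=5)
        assert split_train_test(m, seed=5) != split_train_test(m, seed=6)

    def test_disjoint_and_exhaustive(self):
        m = _manifest({"HC": 11, "NCI": 7, "VaMCI": 13, "VaD": 6})
        plan = split_train_test(m, seed=2)
        ids = set(m["subject_id"])
        assert set(plan.train_ids) | set(plan.test_ids) == ids
        assert not set(plan.train_ids) & set(plan.test_ids)

    def test_stratification_bound(self):
        """Per-class train share stays within one subject of the target."""
        m = _manifest({"HC": 46, "NCI": 83, "VaMCI": 82, "VaD": 52})
        plan = split_train_test(m, seed=3)
        for label, n in {"HC": 46, "NCI": 83, "VaMCI": 82, "VaD": 52}.items():
            n_tr = sum(s.startswith(label) for s in plan.train_ids)
            assert abs(n_tr - 0.75 * n) <= 1

    def test_tiny_class_rejected(self):
        m = _manifest({"HC": 1, "NCI": 5, "VaMCI": 5, "VaD": 5})
        with pytest.raises(ValueError, match="fewer than 2"):
            split_train_test(m)


class TestKfold:
    def test_ten_folds_of_ten(self):
        ids = [f"s{i}" for i in range(100)]
        labels = ["A", "B", "C", "D"] * 25
        assign = kfold(ids, labels, k=10, seed=0)
        sizes = np.bincount(list(assign.values()))
        assert (sizes == 10).all()

    def test_fold_sizes_differ_by_at_most_one(self):
        ids = [f"s{i}" for i in range(103)]
        labels = (["A"] * 30 + ["B"] * 30 + ["C"] * 25 + ["D"] * 18)
        sizes = np.bincount(list(kfold(ids, labels, k=10, seed=1).values()))
        assert sizes.max() - sizes.min() <= 1

    def test_folds_partition_ids(self):
        ids = [f"s{i}" for i in range(40)]
        labels = ["A", "B"] * 20
        assign = kfold(ids, labels, k=5, seed=2)
        assert set(assign) == set(ids)
        assert set(assign.values()) == set(range(5))

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            kfold(["a", "b"], ["A", "B"], k=3)


class TestTrainLoop:
    GRID = (16, 16, 16)

    def _xy(self, tiny):
        x, y = tiny
        # crop to a pool-compatible grid and add the channel axis
        return x[:, None, : self.GRID[0], : self.GRID[1], : self.GRID[2]], y

    def test_one_epoch_smoke(self, tiny_cohort_arrays):
        x, y = self._xy(tiny_cohort_arrays)
        spec = build_3d_cnn(self.GRID, base_channels=2, fc_units=(8, 8))
        hist, net = train(spec, x, y, None, None, TrainingConfig(epochs=1, batch_size=4, seed=0))
        assert len(hist.epochs) == 1
        rec = hist.epochs[0]
        assert np.isfinite(rec["train_loss"]) and 0 <= rec["train_acc"] <= 1

    def test_training_deterministic(self, tiny_cohort_arrays):
        x, y = self._xy(tiny_cohort_arrays)
        spec = build_3d_cnn(self.GRID, base_channels=2, fc_units=(8, 8))
        cfg = TrainingConfig(epochs=2, batch_size=4, seed=7)
        h1, _ = train(spec, x, y, x, y, cfg)
        h2, _ = train(spec, x, y, x, y, cfg)
        assert h1.epochs[-1]["train_loss"] == h2.epochs[-1]["train_loss"]
        assert h1.epochs[-1]["test_loss"] == h2.epochs[-1]["test_loss"]

    def test_lr_trace_follows_schedule(self, tiny_cohort_arrays):
        x, y = self._xy(tiny_cohort_arrays)
        spec = build_3d_cnn(self.GRID, base_channels=2, fc_units=(8, 8))
        cfg = TrainingConfig(epochs=2, batch_size=4, seed=0, decay_step=3, lr_decay=0.5)
        hist, _ = train(spec, x, y, None, None, cfg)
        expected = [lr_at(s, cfg) for s in range(len(hist.lr_per_step))]
        assert hist.lr_per_step == expected

    def test_inconsistent_extents_rejected(self, tiny_cohort_arrays):
        x, y = self._xy(tiny_cohort_arrays)
        spec = build_3d_cnn((16, 16, 16), base_channels=2, fc_units=(8, 8))
        with pytest.raises(ValueError, match="extents"):
            train(spec, x[:, :, :12], y, None, None, TrainingConfig(epochs=1))


class TestCrossValidate:
    def test_session_rotation_and_mean(self, tiny_cohort_arrays):
        """k sessions each hold one fold out; reported mean matches them."""
        from flairvol.training import cross_validate

        x, y = tiny_cohort_arrays
        x = x[:, None, :16, :16, :16]
        spec = build_3d_cnn((16, 16, 16), base_channels=2, fc_units=(8, 8))
        cfg = TrainingConfig(epochs=1, batch_size=4, seed=0)
        sids = [f"s{i}" for i in range(len(y))]
        out = cross_validate(spec, x, y, sids, cfg, k=2)
        assert len(out["fold_accuracies"]) == 2
        assert out["mean_accuracy"] == pytest.approx(np.mean(out["fold_accuracies"]))
        assert all(0 <= a <= 1 for a in out["fold_accuracies"])


class TestSliceDataset:
    def test_groups_map_back_to_subjects(self, tiny_cohort_arrays):
        x, y = tiny_cohort_arrays
        xs, ys, groups = volumes_to_slice_dataset(x[:, None], y, step=2)
        assert xs.shape[1:3] == x.shape[1:3][:2] or xs.ndim == 4
        assert len(xs) == len(ys) == len(groups)
        for g in np.unique(groups):
            assert len(set(ys[groups == g])) == 1  # all slices inherit the label
            assert ys[groups == g][0] == y[g]

    def test_empty_filter_rejected(self):
        x = np.zeros((2, 1, 8, 8, 4))
        with pytest.raises(ValueError):
            volumes_to_slice_dataset(x, np.array([0, 1]))
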