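"""Grouping, balanced oversampling, losses, and the training loop."""

import numpy as np
import pandas as pd
import pytest

from videobp.bpe_net import GroupScheme, ModelConfig
from videobp.exceptions import ConfigurationError
from videobp.synthetic_data import SynthConfig, generate_dataset, make_records
from videobp.training import (
    BPRecord,
    TrainConfig,
    assign_group,
    assign_groups,
    classification_loss,
    make_balanced_batches,
    predict,
    regression_loss,
    subject_split,
    total_loss,
    train,
)

SBP = GroupScheme.default_sbp()


def _records(group_sizes, rng=None):
    """Synthetic label-only records with prescribed group occupancy."""
    mids = [100.0, 115.0, 125.0, 145.0]
    recs = []
    k = 0
    for g, size in enumerate(group_sizes):
        for _ in range(size):
            recs.append(BPRecord(subject_id=f"s{k:03d}", sbp=mids[g], dbp=70.0))
            k += 1
    return assign_groups(recs, SBP)


class TestAssignGroup:
    def test_interval_membership(self):
        assert assign_group(115.0, SBP) == 1

    def test_half_open_boundary(self):
        assert assign_group(110.0, SBP) == 1
        assert assign_group(109.999, SBP) == 0

    def test_clamping_with_warnings(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert assign_group(165.0, SBP) == 3
        with pytest.warns(UserWarning, match="clamped"):
            assert assign_group(85.0, SBP) == 0


class TestBalancedBatches:
    def test_exact_1111_ratio_and_distinct_subjects(self):
        recs = _records([40, 5, 3, 2])
        for batch in make_balanced_batches(recs, 8, seed=0, n_batches=1000):
            counts = np.bincount([r.group_index for r in batch], minlength=4)
            np.testing.assert_array_equal(counts, [2, 2, 2, 2])
            ids = [r.subject_id for r in batch]
            assert len(set(ids)) == len(ids)

    def test_minority_subjects_recur_across_batches(self):
        recs = _records([10, 2, 2, 2])
        seen = []
        for batch in make_balanced_batches(recs, 8, seed=1, n_batches=50):
            seen.extend(r.subject_id for r in batch if r.group_index == 3)
        # both group-3 subjects appear every batch: 100 draws from 2 subjects
        assert len(seen) == 100
        assert len(set(seen)) == 2

    def test_single_subject_group_never_repeats_within_batch(self):
        recs = _records([6, 2, 2, 1])
        with pytest.warns(UserWarning, match="fewer distinct subjects"):
            batches = list(make_balanced_batches(recs, 8, seed=0, n_batches=30))
        lone = recs[-1].subject_id
        appearances = 0
        for batch in batches:
            ids = [r.subject_id for r in batch]
            assert ids.count(lone) <= 1
            appearances += ids.count(lone)
        assert appearances == 30  # recurs across batches

    def test_empty_group_is_configuration_error(self):
        recs = _records([4, 4, 4, 0])
        # only 3 groups present -> batch size 8 not divisible by 3
        with pytest.raises(ConfigurationError):
            list(make_balanced_batches(recs, 8, seed=0, n_batches=1))

    def test_seeded_reproducibility(self):
        recs = _records([8, 4, 3, 2])
        a = [[r.subject_id for r in b] for b in make_balanced_batches(recs, 8, 42, 20)]
        b = [[r.subject_id for r in b] for b in make_balanced_batches(recs, 8, 42, 20)]
        assert a == b


class TestLosses:
    def test_perfect_one_hot_prediction_is_zero(self):
        p = np.array([[0.0, 1.0, 0.0, 0.0]])
        assert classification_loss(p, np.array([1])) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_is_ln4(self):
        p = np.full((3, 4), 0.25)
        assert classification_loss(p, np.array([0, 2, 3])) == pytest.approx(np.log(4.0), abs=1e-9)

    def test_cross_entropy_matches_neglog_oracle(self, rng):
        p = rng.dirichlet(np.ones(4), size=16)
        q = rng.integers(0, 4, size=16)
        want = float(np.mean([-np.log(p[i, q[i]]) for i in range(16)]))
        assert classification_loss(p, q) == pytest.approx(want, abs=1e-9)

    def test_zero_probability_clamped(self):
        p = np.array([[1.0, 0.0, 0.0, 0.0]])
        assert np.isfinite(classification_loss(p, np.array([2])))

    def test_l1_printed_example(self):
        assert regression_loss(np.array([120.0, 130.0]), np.array([118.0, 135.0]), "L1") == pytest.approx(3.5)

    def test_identical_vectors_give_zero_for_both_kinds(self, rng):
        v = rng.uniform(90, 160, size=10)
        assert regression_loss(v, v, "L1") == 0.0
        assert regression_loss(v, v, "L2") == 0.0

    def test_regression_losses_match_brute_force(self, rng):
        a = rng.uniform(90, 160, size=25)
        b = rng.uniform(90, 160, size=25)
        assert regression_loss(a, b, "L1") == pytest.approx(np.mean([abs(x - y) for x, y in zip(a, b)]), abs=1e-9)
        assert regression_loss(a, b, "L2") == pytest.approx(np.mean([(x - y) ** 2 for x, y in zip(a, b)]), abs=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            regression_loss(np.zeros(3), np.zeros(4))

    def test_total_loss_is_the_sum(self):
        assert total_loss(1.0, 3.5) == 4.5
        assert total_loss(0.0, 0.0) == 0.0

    def test_total_loss_rejects_non_finite(self):
        with pytest.raises(FloatingPointError):
            total_loss(np.nan, 1.0)
        with pytest.raises(FloatingPointError):
            total_loss(1.0, np.inf)


class TestSubjectSplit:
    def test_no_identity_leakage_and_coverage(self):
        recs = _records([20, 10, 8, 6])
        train_r, val_r = subject_split(recs, 0.2, seed=0)
        assert set(r.subject_id for r in train_r).isdisjoint(r.subject_id for r in val_r)
        assert len(train_r) + len(val_r) == len(recs)
        assert len(val_r) == pytest.approx(0.2 * len(recs), abs=2)

    def test_single_subject_group_stays_in_training(self):
        recs = _records([8, 8, 8, 1])
        train_r, val_r = subject_split(recs, 0.2, seed=0)
        assert any(r.group_index == 3 for r in train_r)
        assert not any(r.group_index == 3 for r in val_r)


def _training_records(n=16, seed=1):
    cfg = SynthConfig(n_subjects=n, seed=seed, duration_s=10.0)
    return make_records(generate_dataset(cfg))


def _fast_cfg(**kw):
    defaults = dict(max_epochs=2, cl=75, seed=0)
    defaults.update(kw)
    return TrainConfig(**defaults)


class TestTrainLoop:
    def test_smoke_run_completes_with_finite_loss(self):
        snap, hist = train(_training_records(16), ModelConfig(width=4, seed=0), _fast_cfg())
        assert len(hist) == 2
        assert np.isfinite(hist["train_loss"]).all()
        assert np.isfinite(snap["val_mae"])
        assert snap["best_epoch"] in (1, 2)

    def test_same_seed_reproduces_history(self):
        recs = _training_records(16)
        _, h1 = train(recs, ModelConfig(width=4, seed=0), _fast_cfg())
        _, h2 = train(recs, ModelConfig(width=4, seed=0), _fast_cfg())
        pd.testing.assert_frame_equal(h1, h2)

    def test_group_coverage_failure_raises(self):
        recs = assign_groups(_training_records(16), SBP)
        recs = [r for r in recs if r.group_index != 3]
        with pytest.raises(ConfigurationError, match="group"):
            train(recs, ModelConfig(width=4, seed=0), _fast_cfg())

    def test_reg_loss_switch_keeps_first_classification_loss(self):
        recs = _training_records(16)
        _, h1 = train(recs, ModelConfig(width=4, seed=0), _fast_cfg(reg_loss="L1", max_epochs=1))
        _, h2 = train(recs, ModelConfig(width=4, seed=0), _fast_cfg(reg_loss="L2", max_epochs=1))
        # identical seeds: the classification term of the very first epoch is
        # computed on identical batches and identical initial weights
        assert h1["train_cla_loss"].iloc[0] == pytest.approx(h2["train_cla_loss"].iloc[0], rel=0.2)

    def test_predict_returns_one_row_per_subject(self):
        recs = _training_records(16)
        snap, _ = train(recs, ModelConfig(width=4, seed=0), _fast_cfg())
        df = predict(recs, snap)
        assert len(df) == 16
        assert set(df.columns) >= {"subject_id", "target", "truth", "r_cla_argmax", "r_reg", "r_final"}
        assert df["r_cla_argmax"].between(0, 3).all()

    def test_alpha_zero_prediction_equals_calculator(self):
        recs = _training_records(16)
        snap, _ = train(recs, ModelConfig(width=4, alpha=0.0, beta=1.0, seed=0), _fast_cfg())
        df = predict(recs, snap)
        np.testing.assert_allclose(df["r_final"], df["r_reg"], atol=1e-9)
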