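"""Pseudo-labeling, threshold dynamics, joint objective, training loops."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wfvit.autodiff import AdamW
from wfvit.data import DataError
from wfvit.model import ModelConfig, WaveletFusionViT
from wfvit.semisup import (
    LabeledSet,
    LossReport,
    ThresholdState,
    UnlabeledSet,
    predict_dataset,
    pseudo_label,
    select_labeled_subset,
    supervised_loss,
    train_ssl,
    train_step,
    train_supervised,
    unsupervised_loss,
    update_thresholds,
)

LN4 = np.log(4.0)


# ---------------------------------------------------------------------------
# labeled subset selection


def test_select_25_per_class_gives_100(small_dataset):
    # 10/class available here, so use a generated 30/class set
    from wfvit.synthetic import SyntheticSpec, generate_dataset

    ds = generate_dataset(30, SyntheticSpec(image_size=32), seed=5)
    labeled, unlabeled = select_labeled_subset(ds, 25, seed=0)
    assert len(labeled) == 100
    assert len(unlabeled) == len(ds) - 100
    counts = np.bincount(labeled.labels(), minlength=4)
    assert (counts == 25).all()


def test_select_zero_per_class(small_dataset):
    labeled, unlabeled = select_labeled_subset(small_dataset, 0, seed=0)
    assert len(labeled) == 0
    assert len(unlabeled) == len(small_dataset)


def test_select_deterministic(small_dataset):
    a, _ = select_labeled_subset(small_dataset, 5, seed=3)
    b, _ = select_labeled_subset(small_dataset, 5, seed=3)
    np.testing.assert_array_equal(a.labels(), b.labels())
    for (ia, _), (ib, _) in zip(a.items, b.items):
        np.testing.assert_array_equal(ia, ib)


def test_select_insufficient_class_names_offender(small_dataset):
    with pytest.raises(DataError, match="healthy|am|pc|cso"):
        select_labeled_subset(small_dataset, 11, seed=0)


# ---------------------------------------------------------------------------
# losses


def test_supervised_loss_confident_correct():
    p = np.array([[0.999999, 1e-6 / 3, 1e-6 / 3, 1e-6 / 3]])
    assert supervised_loss(p, [0]) == pytest.approx(0.0, abs=1e-5)


def test_supervised_loss_uniform_is_ln4():
    p = np.full((3, 4), 0.25)
    assert supervised_loss(p, [0, 1, 2]) == pytest.approx(LN4, abs=1e-12)


def test_supervised_loss_hand_example():
    p = np.array([[0.5, 0.3, 0.1, 0.1], [0.5, 0.25, 0.15, 0.1]])
    # true classes hold probs 0.5 and 0.25 -> mean(-ln .5, -ln .25) = 1.0397
    assert supervised_loss(p, [0, 1]) == pytest.approx(1.0397207708, abs=1e-9)


def test_supervised_loss_label_out_of_range():
    with pytest.raises(ValueError):
        supervised_loss(np.full((1, 4), 0.25), [4])


def test_unsupervised_loss_empty_mask_is_zero():
    p = np.full((3, 4), 0.25)
    assert unsupervised_loss(p, [0, 1, 2], [False, False, False]) == 0.0


def test_unsupervised_loss_all_passing_equals_plain_ce():
    p = np.array([[0.7, 0.1, 0.1, 0.1], [0.2, 0.6, 0.1, 0.1]])
    labels = [0, 1]
    assert unsupervised_loss(p, labels, [True, True]) == pytest.approx(
        supervised_loss(p, labels)
    )


def test_unsupervised_loss_hand_example():
    p = np.array([[0.5, 0.3, 0.1, 0.1], [0.1, 0.1, 0.7, 0.1]])
    # only first sample passes, prob 0.5 on its pseudo-label -> -ln 0.5
    assert unsupervised_loss(p, [0, 2], [True, False]) == pytest.approx(
        0.6931471805599453, abs=1e-9
    )


# ---------------------------------------------------------------------------
# thresholds


def test_threshold_initialization_quarter():
    state = ThresholdState.initial(4)
    assert state.global_tau == pytest.approx(0.25, abs=1e-12)
    np.testing.assert_allclose(state.class_probs, 0.25)
    np.testing.assert_allclose(state.per_class_thresholds(), 0.25)


def test_ema_decay_one_freezes_state(rng):
    state = ThresholdState.initial(4, ema_decay=1.0)
    preds = rng.dirichlet(np.ones(4), size=16)
    new = update_thresholds(state, preds)
    assert new.global_tau == state.global_tau
    np.testing.assert_array_equal(new.class_probs, state.class_probs)


def test_ema_single_batch_hand_oracle(rng):
    lam = 0.9
    preds = rng.dirichlet(np.ones(4), size=8)
    state = update_thresholds(ThresholdState.initial(4, ema_decay=lam), preds)
    m = preds.max(axis=1).mean()
    assert state.global_tau == pytest.approx(lam * 0.25 + (1 - lam) * m, abs=1e-9)
    np.testing.assert_allclose(
        state.class_probs, lam * 0.25 + (1 - lam) * preds.mean(axis=0), atol=1e-9
    )


@settings(max_examples=50, deadline=None)
@given(seed=st.integers(0, 2 ** 16), lam=st.floats(0.5, 0.999), steps=st.integers(1, 30))
def test_global_tau_stays_in_bounds(seed, lam, steps):
    g = np.random.default_rng(seed)
    state = ThresholdState.initial(4, ema_decay=lam)
    for _ in range(steps):
        preds = g.dirichlet(g.uniform(0.2, 5.0, size=4), size=int(g.integers(1, 12)))
        state = update_thresholds(state, preds)
        assert 0.25 - 1e-12 <= state.global_tau <= 1.0 + 1e-12
        assert (state.class_probs >= 0).all() and (state.class_probs <= 1).all()


# ---------------------------------------------------------------------------
# pseudo-labels


def test_pseudo_label_confident_sample():
    state = ThresholdState(global_tau=0.5, class_probs=np.full(4, 0.25))
    labels, mask = pseudo_label(np.array([[0.9, 0.05, 0.03, 0.02]]), state)
    assert labels[0] == 0 and mask[0]


def test_pseudo_label_all_below_threshold():
    state = ThresholdState(global_tau=0.99, class_probs=np.full(4, 0.25))
    _, mask = pseudo_label(np.full((3, 4), 0.25), state)
    assert not mask.any()


def test_pseudo_label_tie_breaks_to_lowest_index():
    state = ThresholdState.initial(4)
    labels, _ = pseudo_label(np.array([[0.4, 0.4, 0.1, 0.1]]), state)
    assert labels[0] == 0


def test_pseudo_label_empty_batch():
    labels, mask = pseudo_label(np.zeros((0, 4)), ThresholdState.initial(4))
    assert labels.size == 0 and mask.size == 0


def test_raising_thresholds_never_admits_more_samples(rng):
    preds = rng.dirichlet(np.ones(4), size=64)
    lo = ThresholdState(global_tau=0.3, class_probs=np.full(4, 0.25))
    hi = ThresholdState(global_tau=0.6, class_probs=np.full(4, 0.25))
    _, mask_lo = pseudo_label(preds, lo)
    _, mask_hi = pseudo_label(preds, hi)
    assert mask_hi.sum() <= mask_lo.sum()
    assert not (mask_hi & ~mask_lo).any()


# ---------------------------------------------------------------------------
# training steps and loops


def test_loss_report_identity_enforced():
    with pytest.raises(AssertionError):
        LossReport(ls=1.0, lu=2.0, total=4.0, utilization=0.0)


@pytest.fixture
def toy_setup(small_dataset):
    cfg = ModelConfig.tiny()
    model = WaveletFusionViT(cfg, seed=0)
    opt = AdamW(model.flat_params(), lr=1e-3)
    labeled, unlabeled = select_labeled_subset(small_dataset, 4, seed=0)
    return model, opt, labeled, unlabeled


def test_train_step_empty_unlabeled_total_is_ls(toy_setup):
    model, opt, labeled, _ = toy_setup
    rng = np.random.default_rng(0)
    state = ThresholdState.initial(4)
    imgs = labeled.images()[:4][:, None]
    state, report = train_step(model, opt, imgs, labeled.labels()[:4], [], state, rng)
    assert report.lu == 0.0
    assert report.total == report.ls


def test_train_step_report_identity(toy_setup):
    model, opt, labeled, unlabeled = toy_setup
    rng = np.random.default_rng(0)
    state = ThresholdState.initial(4)
    imgs = labeled.images()[:4][:, None]
    for _ in range(3):
        state, report = train_step(
            model, opt, imgs, labeled.labels()[:4], unlabeled.items[:8], state, rng
        )
        assert report.total == report.ls + report.lu
        assert 0.0 <= report.utilization <= 1.0


def test_train_supervised_zero_epochs_unchanged(toy_setup):
    model, _, labeled, _ = toy_setup
    before = {k: v.data.copy() for k, v in model.flat_params().items()}
    model, losses = train_supervised(model, labeled, epochs=0, seed=0)
    assert losses == []
    for k, v in model.flat_params().items():
        np.testing.assert_array_equal(v.data, before[k])


def test_train_supervised_smoke_one_epoch(toy_setup):
    model, _, labeled, _ = toy_setup
    subset = LabeledSet(labeled.items[:8])
    model, losses = train_supervised(model, subset, epochs=1, seed=0)
    assert len(losses) == 1 and np.isfinite(losses[0])


def test_train_supervised_empty_rejected(toy_setup):
    model = toy_setup[0]
    with pytest.raises(DataError):
        train_supervised(model, LabeledSet([]), epochs=1)


def test_supervised_converges_on_separable_toy():
    """Quadrant-brightness classes: training accuracy reaches 100%."""
    cfg = ModelConfig.tiny()
    model = WaveletFusionViT(cfg, seed=0)
    rng = np.random.default_rng(0)
    items = []
    for i in range(24):
        cls = i % 4
        img = rng.uniform(0.0, 0.2, size=(32, 32))
        ys, xs = [(0, 0), (0, 16), (16, 0), (16, 16)][cls]
        img[ys : ys + 16, xs : xs + 16] += 0.7
        items.append((img, cls))
    labeled = LabeledSet(items)
    model, _ = train_supervised(model, labeled, epochs=25, seed=0, augment_prob=0.0,
                                lr=2e-3)
    scores = predict_dataset(model, [im for im, _ in items])
    acc = (scores.argmax(1) == labeled.labels()).mean()
    assert acc == 1.0


def test_ssl_ls_decreases_over_steps(small_dataset):
    model = WaveletFusionViT(ModelConfig.tiny(), seed=0)
    labeled, unlabeled = select_labeled_subset(small_dataset, 8, seed=0)
    model, state, history = train_ssl(
        model, labeled, UnlabeledSet(unlabeled.items[:8]), epochs=8, seed=0,
        labeled_batch=8, unlabeled_ratio=1,
    )
    first = np.mean([h.ls for h in history[:4]])
    last = np.mean([h.ls for h in history[-4:]])
    assert last < first
    assert 0.25 <= state.global_tau <= 1.0


def test_ssl_writes_csv_log(small_dataset, tmp_path):
    model = WaveletFusionViT(ModelConfig.tiny(), seed=0)
    labeled, unlabeled = select_labeled_subset(small_dataset, 2, seed=0)
    log = tmp_path / "ssl.csv"
    train_ssl(model, labeled, UnlabeledSet(unlabeled.items[:4]), epochs=1, seed=0,
              log_path=log)
    header = log.read_text().splitlines()[0]
    assert header == "step,ls,lu,total,utilization,global_tau"
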