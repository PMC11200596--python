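"""Metrics against hand arithmetic and brute-force oracles; Grad-CAM."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wfvit.evaluation import (
    ClassMetrics,
    ConfusionMatrix,
    FoldMetrics,
    UndefinedMetricError,
    confusion_matrix,
    crossval_report,
    evaluate_fold,
    gradcam,
    macro_mean,
    one_vs_rest_metrics,
    overlay_heatmap,
    roc_auc,
)
from wfvit.model import ModelConfig, WaveletFusionViT


# ---------------------------------------------------------------------------
# confusion matrix


def test_perfect_predictions_diagonal():
    cm = confusion_matrix([0, 1, 2, 3], [0, 1, 2, 3], 4)
    np.testing.assert_array_equal(cm.counts, np.eye(4, dtype=int))


def test_counting_example():
    cm = confusion_matrix([0, 0, 1], [0, 1, 1], 2)
    assert cm.counts[0, 0] == 1
    assert cm.counts[0, 1] == 1
    assert cm.counts[1, 1] == 1


def test_empty_input_zero_matrix():
    cm = confusion_matrix([], [], 3)
    np.testing.assert_array_equal(cm.counts, 0)


def test_label_out_of_range_rejected():
    with pytest.raises(ValueError):
        confusion_matrix([0, 5], [0, 1], 4)


def test_marginals_conserve_counts(rng):
    t = rng.integers(0, 4, size=200)
    p = rng.integers(0, 4, size=200)
    cm = confusion_matrix(t, p, 4)
    np.testing.assert_array_equal(cm.counts.sum(axis=1), np.bincount(t, minlength=4))
    np.testing.assert_array_equal(cm.counts.sum(axis=0), np.bincount(p, minlength=4))
    assert cm.total == 200


def test_permutation_invariance(rng):
    t = rng.integers(0, 3, size=50)
    p = rng.integers(0, 3, size=50)
    perm = rng.permutation(50)
    np.testing.assert_array_equal(
        confusion_matrix(t, p, 3).counts, confusion_matrix(t[perm], p[perm], 3).counts
    )


# ---------------------------------------------------------------------------
# one-vs-rest metrics


def test_hand_binarized_example():
    # TP=8 FN=2 TN=9 FP=1 -> SN 80, SP 90, ACC 85
    cm = ConfusionMatrix(np.array([[8, 2], [1, 9]]))
    m = one_vs_rest_metrics(cm, 0)
    assert m.sensitivity == pytest.approx(80.0)
    assert m.specificity == pytest.approx(90.0)
    assert m.accuracy == pytest.approx(85.0)


def test_perfect_matrix_all_hundred():
    cm = ConfusionMatrix(np.diag([5, 5, 5, 5]))
    for cls in range(4):
        m = one_vs_rest_metrics(cm, cls)
        assert (m.sensitivity, m.specificity, m.accuracy) == (100.0, 100.0, 100.0)


def test_empty_class_support_flagged():
    cm = ConfusionMatrix(np.array([[3, 0], [0, 0]]))
    with pytest.raises(UndefinedMetricError):
        one_vs_rest_metrics(cm, 1)


def test_published_per_class_accuracy_macro_mean():
    # printed per-class accuracies of the proposed method -> printed mean
    from wfvit.evaluation import round_half_up

    assert round_half_up(macro_mean([98.70, 93.32, 87.39, 86.46]), 2) == 91.47


def test_published_per_class_sensitivity_macro_mean():
    from wfvit.evaluation import round_half_up

    assert round_half_up(macro_mean([98.04, 90.06, 78.33, 51.95]), 2) == 79.60


# ---------------------------------------------------------------------------
# AUC


def _auc_oracle(scores, labels):
    """Brute-force pairwise rank probability with half-credit ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


def test_perfectly_separated_scores():
    assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0


def test_inverted_labels_zero():
    assert roc_auc([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0]) == 0.0


def test_hand_example_075():
    assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)


def test_single_class_undefined():
    with pytest.raises(UndefinedMetricError):
        roc_auc([0.5, 0.6], [1, 1])


@settings(max_examples=100, deadline=None)
@given(seed=st.integers(0, 2 ** 16), n=st.integers(2, 20))
def test_auc_equals_brute_force_oracle(seed, n):
    g = np.random.default_rng(seed)
    labels = g.integers(0, 2, size=n)
    if labels.sum() in (0, n):
        labels[0] = 1 - labels[0]
    scores = np.round(g.uniform(size=n), 1)  # coarse grid to exercise ties
    assert roc_auc(scores, labels) == pytest.approx(_auc_oracle(scores, labels), abs=1e-12)


# ---------------------------------------------------------------------------
# cross-validated aggregation


def _fold(acc):
    return FoldMetrics(per_class=[ClassMetrics(90.0, 95.0, acc, 0.9)] * 4)


def test_identical_folds_zero_std():
    report = crossval_report([_fold(85.0)] * 5)
    mean, std = report.mean_std("accuracy", 0)
    assert (mean, std) == (85.0, 0.0)


def test_two_folds_sample_std():
    report = crossval_report([_fold(80.0), _fold(90.0)])
    mean, std = report.mean_std("accuracy", 0)
    assert mean == pytest.approx(85.0)
    assert std == pytest.approx(7.0710678, abs=1e-6)


def test_macro_mean_identity_per_fold(rng):
    per_class = [ClassMetrics(*rng.uniform(50, 100, size=3), auc=0.9) for _ in range(4)]
    fold = FoldMetrics(per_class=per_class)
    assert fold.macro("accuracy") == pytest.approx(
        np.mean([m.accuracy for m in per_class]), abs=1e-9
    )


def test_crossval_requires_folds():
    with pytest.raises(ValueError):
        crossval_report([])


def test_evaluate_fold_structure(rng):
    scores = rng.dirichlet(np.ones(4), size=60)
    labels = rng.integers(0, 4, size=60)
    fm = evaluate_fold(labels, scores, 4)
    assert len(fm.per_class) == 4
    assert fm.cm.total == 60
    report = crossval_report([fm])
    summary = report.summary()
    assert set(summary) == {"per_class", "macro"}


def test_report_csv_export(rng, tmp_path):
    scores = rng.dirichlet(np.ones(4), size=60)
    labels = rng.integers(0, 4, size=60)
    report = crossval_report([evaluate_fold(labels, scores, 4)])
    path = tmp_path / "metrics.csv"
    report.to_csv(path)
    lines = path.read_text().strip().splitlines()
    assert lines[0] == "class,metric,mean,std"
    assert any(line.startswith("macro,accuracy,") for line in lines)


# ---------------------------------------------------------------------------
# Grad-CAM


def test_gradcam_shape_and_range(tiny_cfg, rng):
    m = WaveletFusionViT(tiny_cfg, seed=0)
    cam = gradcam(m, rng.uniform(size=(32, 32)), target_class=2)
    assert cam.shape == (32, 32)
    assert cam.min() >= 0.0 and cam.max() <= 1.0


def test_gradcam_invalid_class(tiny_cfg, rng):
    m = WaveletFusionViT(tiny_cfg, seed=0)
    with pytest.raises(ValueError):
        gradcam(m, rng.uniform(size=(32, 32)), target_class=7)


def test_gradcam_degenerate_returns_zeros(tiny_cfg, rng):
    m = WaveletFusionViT(tiny_cfg, seed=0)
    # kill the head weights: zero gradient everywhere -> degenerate map
    m.head.w.data[:] = 0.0
    m.head.b.data[:] = 0.0
    cam = gradcam(m, rng.uniform(size=(32, 32)), target_class=0)
    np.testing.assert_array_equal(cam, 0.0)


def test_gradcam_localizes_bright_patch():
    """A model trained to detect one bright patch should attend to it."""
    from wfvit.autodiff import AdamW
    from wfvit.semisup import _ce_loss_t

    cfg = ModelConfig(image_size=16, patch_size=8, embed_dim=16, depth=1, heads=2,
                      n_classes=2, wefm_mode="off")
    m = WaveletFusionViT(cfg, seed=0)
    rng = np.random.default_rng(0)
    # class 1 iff the top-left patch is bright
    imgs, labels = [], []
    for i in range(16):
        img = rng.uniform(0.0, 0.1, size=(16, 16))
        if i % 2:
            img[:8, :8] += 0.9
        imgs.append(img)
        labels.append(i % 2)
    x = np.stack(imgs)[:, None]
    y = np.array(labels)
    opt = AdamW(m.flat_params(), lr=3e-3)
    for _ in range(150):
        loss = _ce_loss_t(m.forward(x), y)
        opt.zero_grad()
        loss.backward()
        opt.step()
    assert (m.forward(x).data.argmax(1) == y).all()
    probe = rng.uniform(0.0, 0.1, size=(16, 16))
    probe[:8, :8] += 0.9
    cam = gradcam(m, probe, target_class=1)
    # the heat maximum falls in the bright top-left patch cell
    iy, ix = np.unravel_index(cam.argmax(), cam.shape)
    assert iy < 8 and ix < 8


def test_overlay_heatmap_rgb(rng):
    img = rng.uniform(size=(16, 16))
    cam = rng.uniform(size=(16, 16))
    out = overlay_heatmap(img, cam)
    assert out.shape == (16, 16, 3)
    assert out.dtype == np.uint8
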