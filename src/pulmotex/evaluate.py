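"""Confusion-matrix metrics, ROC curves and end-to-end pipeline runs.

Metrics follow the standard confusion-count definitions (TP, TN, FP, FN):
accuracy, precision, F1, sensitivity (recall, TP/(TP+FN)) and specificity
(TN/(TN+FP)). Multiclass evaluation is one-vs-rest per class plus a macro
average; the malignant class is the headline positive class.

:func:`run_pipeline` wires the whole method together on phantom data:
Butterworth smoothing, optional sparse-coding enhancement, GLCM texture
extraction, concatenation with the six semantic nodule attributes,
CCSA-RF feature selection on the training split and PNN classification
of the test split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from pulmotex import crowsearch, pnn, preprocess, texture
from pulmotex.synthetic import generate_phantom_dataset
from pulmotex.types import FeatureTable, GrayImage, LABELS, PhantomAnnotation

__all__ = [
    "ConfusionCounts",
    "classification_metrics",
    "multiclass_metrics",
    "roc_points",
    "PipelineConfig",
    "build_feature_table",
    "run_pipeline",
]


@dataclass
class ConfusionCounts:
    """Binary confusion counts for one positive class."""

    tp: int
    tn: int
    fp: int
    fn: int
    positive_label: int | str | None = None

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")
        if self.total == 0:
            raise ValueError("at least one sample is required")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _ratio(num: int, den: int) -> float:
    """NaN (flagged undefined) when the denominator is zero."""
    return num / den if den > 0 else float("nan")


def classification_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, sensitivity, specificity and F1.

    Zero-denominator ratios come back as NaN with the ``undefined`` entry
    naming them; F1 is 0 by convention when precision + recall is 0.
    """
    precision = _ratio(counts.tp, counts.tp + counts.fp)
    sensitivity = _ratio(counts.tp, counts.tp + counts.fn)
    specificity = _ratio(counts.tn, counts.tn + counts.fp)
    accuracy = (counts.tp + counts.tn) / counts.total
    if np.isnan(precision) or np.isnan(sensitivity):
        f1 = float("nan")
    elif precision + sensitivity == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    out = {
        "accuracy": accuracy,
        "precision": precision,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "f1": f1,
    }
    out["undefined"] = tuple(k for k, v in out.items() if isinstance(v, float) and np.isnan(v))
    return out


def confusion_matrix(
    y_true: np.ndarray, y_pred: np.ndarray, labels: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(matrix, label order); rows = true class, columns = predicted."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if labels is None:
        labels = np.unique(np.concatenate([y_true, y_pred]))
    mat = np.zeros((labels.size, labels.size), dtype=int)
    index = {l: i for i, l in enumerate(labels)}
    for t, p in zip(y_true, y_pred):
        mat[index[t], index[p]] += 1
    return mat, labels


def one_vs_rest_counts(
    y_true: np.ndarray, y_pred: np.ndarray, positive
) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(np.sum((y_true == positive) & (y_pred == positive)))
    tn = int(np.sum((y_true != positive) & (y_pred != positive)))
    fp = int(np.sum((y_true != positive) & (y_pred == positive)))
    fn = int(np.sum((y_true == positive) & (y_pred != positive)))
    return ConfusionCounts(tp, tn, fp, fn, positive)


def multiclass_metrics(
    y_true: np.ndarray, y_pred: np.ndarray
) -> dict[str, dict[str, float]]:
    """One-vs-rest metric bundle per class plus the macro average."""
    labels = np.unique(np.asarray(y_true))
    per_class = {
        str(label): classification_metrics(one_vs_rest_counts(y_true, y_pred, label))
        for label in labels
    }
    keys = ("accuracy", "precision", "sensitivity", "specificity", "f1")
    macro = {
        k: float(np.nanmean([per_class[str(l)][k] for l in labels])) for k in keys
    }
    per_class["macro"] = macro
    return per_class


def roc_points(
    scores: np.ndarray,
    labels: np.ndarray,
    n_thresholds: int = 101,
) -> tuple[list[tuple[float, float]], float]:
    """(specificity, sensitivity) pairs over a threshold sweep + area.

    ``labels`` are binary (positive = 1/True). Thresholds sweep the score
    range; the (sens 0) and (sens 1) endpoints are always included. Area
    is the trapezoid integral of sensitivity over the false-positive rate.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    lo, hi = scores.min(), scores.max()
    # a uniform sweep plus every observed score, so the curve is exact
    thresholds = np.concatenate(
        [[-np.inf], np.linspace(lo, hi, n_thresholds), np.unique(scores), [np.inf]]
    )
    pts = []
    n_pos = labels.sum()
    n_neg = labels.size - n_pos
    for t in thresholds:
        pred = scores >= t
        sens = np.sum(pred & labels) / n_pos
        spec = np.sum(~pred & ~labels) / n_neg
        pts.append((float(spec), float(sens)))
    pts = sorted(set(pts), key=lambda p: (1 - p[0], p[1]))
    fpr = np.array([1 - s for s, _ in pts])
    tpr = np.array([t for _, t in pts])
    area = float(np.trapezoid(tpr, fpr))
    return pts, area


@dataclass
class PipelineConfig:
    """End-to-end phantom pipeline settings.

    Filtering always runs; sparse-coding enhancement is opt-in (the
    phantoms are generated at full resolution, so there is nothing to
    upscale unless ``enhance_factor`` is set, in which case each slice is
    degraded and re-enhanced before feature extraction). Selection and
    classification settings mirror the module defaults; the CCSA budget
    here is deliberately smaller than the selection module's default —
    the 22-feature pipeline pool needs fewer iterations than a blind
    search.
    """

    n_train_per_class: int = 67
    n_test_per_class: int = 33
    image_size: int = 128
    filter_order: int = 2
    filter_cutoff: float | None = None
    filter_mode: str = "lowpass"
    enhance_factor: int | None = None
    glcm_levels: int = 8
    glcm_distance: int = 1
    use_semantic: bool = True
    ccsa_crows: int = 15
    ccsa_iters: int = 15
    ccsa_lambda: float = 0.01
    pnn_sigma: float = 0.3


def build_feature_table(
    images: list[GrayImage],
    annotations: list[PhantomAnnotation],
    config: PipelineConfig,
    scnn_params=None,
) -> FeatureTable:
    """Filter each slice, optionally enhance, then extract the 16 GLCM
    features and append the six semantic attributes."""
    from pulmotex import scnn as scnn_mod
    from pulmotex.synthetic import degrade_pair

    fcfg = preprocess.FilterConfig(
        order_n=config.filter_order,
        cutoff_di=config.filter_cutoff,
        mode=config.filter_mode,
    )
    rows = []
    for img, ann in zip(images, annotations):
        work = preprocess.smooth_image(img, fcfg)
        if config.enhance_factor and scnn_params is not None:
            low, _ = degrade_pair(work, config.enhance_factor, seed=ann.seed)
            work = scnn_mod.enhance_image(low, scnn_params)
        feats = texture.extract_texture_vector(
            work, distance=config.glcm_distance, levels_L=config.glcm_levels
        )
        if config.use_semantic:
            feats = np.concatenate([feats, ann.semantic_features()])
        rows.append(feats)
    names = texture.texture_feature_names()
    if config.use_semantic:
        names = names + [
            "diameter_mm", "margin", "spiculation", "lobulation", "subtlety", "malignancy",
        ]
    labels = np.array([ann.class_code for ann in annotations])
    return FeatureTable(np.array(rows), labels, names)


def run_pipeline(config: PipelineConfig | None = None, seed: int = 0) -> dict:
    """Full phantom study: generate, filter, extract, select, classify.

    Returns a report with the selected features, the 3x3 confusion
    matrix, per-class and macro metrics, and the malignant-vs-rest ROC.
    Deterministic for a fixed (config, seed).
    """
    config = config or PipelineConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x717E]))

    train_imgs, train_anns = generate_phantom_dataset(
        config.n_train_per_class, config.image_size, seed=seed * 2 + 1
    )
    test_imgs, test_anns = generate_phantom_dataset(
        config.n_test_per_class, config.image_size, seed=seed * 2 + 2
    )

    train_table = build_feature_table(train_imgs, train_anns, config)
    test_table = build_feature_table(test_imgs, test_anns, config)

    ccsa_cfg = crowsearch.CCSAConfig(
        n_crows=config.ccsa_crows,
        max_iter=config.ccsa_iters,
        lambda_f=config.ccsa_lambda,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    selection = crowsearch.ccsa_select(train_table, ccsa_cfg)
    mask = selection.best_mask.astype(bool)

    model = pnn.fit_pnn(train_table.restrict(mask), sigma=config.pnn_sigma)
    pred, scores = pnn.pnn_classify(model, test_table.features[:, mask])

    y_true = test_table.labels
    mat, labels = confusion_matrix(y_true, pred, np.array([1, 2, 3]))
    metrics = multiclass_metrics(y_true, pred)

    malignant_col = model.classes.index(3)
    roc, auc = roc_points(scores[:, malignant_col], y_true == 3)

    return {
        "selected_features": [
            n for n, keep in zip(train_table.feature_names, mask) if keep
        ],
        "selection_fitness": selection.best_fitness,
        "selection_history": selection.history.tolist(),
        "confusion_matrix": mat.tolist(),
        "class_order": [int(l) for l in labels],
        "label_names": list(LABELS),
        "metrics": metrics,
        "accuracy": float(np.mean(pred == y_true)),
        "roc_malignant": roc,
        "auc_malignant": auc,
        "n_train": train_table.n_samples,
        "n_test": test_table.n_samples,
        "seed": seed,
    }
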