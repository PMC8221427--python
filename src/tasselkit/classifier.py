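"""Binary tassel / no-tassel patch classifier.

The detection framework only requires *some* model that maps a 128x128 RGB
patch to a tassel probability; the network used in production (a
transfer-learned deep CNN) is deliberately behind a small contract so that
any implementation can be swapped in.  The reference implementation here is
a fixed-feature linear model: hand-crafted features that respond to the
visual signature of a tassel -- a thin, locally bright, elongated structure
over textured canopy -- followed by a logistic-regression decision layer.
Only the decision layer is fit, mirroring the "retrain the last layer only"
transfer-learning recipe, and everything is deterministic given the seed.

Features per patch (fixed length 10):

* mean and standard deviation of each RGB channel (6 values);
* fraction of pixels whose luminance exceeds a local-smoothing residual
  threshold -- thin bright structures survive subtraction of a blurred
  copy of the image while smooth canopy does not; components smaller than
  a few pixels are removed first, since sensor speckle would otherwise
  dominate every structural statistic;
* number of connected components of that denoised mask (log1p-scaled);
* mean eccentricity of those components (elongated structures score near
  1, compact blobs near 0);
* maximum per-component red-chromaticity excess over the patch background.
  Tassels are yellow-green rather than green, so their pixels carry more
  red per unit brightness than canopy or leaf veins; taking the maximum
  over components keeps a single small tassel visible among many veins,
  and the chromaticity ratio is insensitive to illumination.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy import ndimage
from sklearn.linear_model import LogisticRegression

from .geometry import MetricsReport, f1

__all__ = [
    "PatchDataset",
    "ClassifierModel",
    "featurize",
    "train",
    "predict_scores",
    "predict_labels",
    "evaluate",
    "save_model",
    "load_model",
    "split_train_test",
]

POSITIVE = "tassel"
NEGATIVE = "no_tassel"
N_FEATURES = 10
MODEL_FORMAT = "tasselkit-linear-model/1"

# Residual threshold in 8-bit luminance units: a pixel is "locally bright"
# when it exceeds its 9x9 neighbourhood mean by more than this.
RESIDUAL_THRESHOLD = 8.0
SMOOTHING_SIZE = 9
# residual-mask components below this pixel count are treated as speckle
MIN_COMPONENT_SIZE = 5

_CONN8 = np.ones((3, 3), dtype=bool)


@dataclass
class PatchDataset:
    """Labelled patches plus a train/test split assignment."""

    patches: list[np.ndarray]
    labels: list[str]
    split: list[str]  # "train" / "test", aligned with patches

    def __post_init__(self) -> None:
        if not len(self.patches) == len(self.labels) == len(self.split):
            raise ValueError("patches, labels and split must be aligned")

    def subset(self, which: str) -> tuple[list[np.ndarray], list[str]]:
        idx = [i for i, s in enumerate(self.split) if s == which]
        return [self.patches[i] for i in idx], [self.labels[i] for i in idx]


@dataclass
class ClassifierModel:
    """Fixed-feature linear patch classifier with a score threshold."""

    coef: np.ndarray
    intercept: float
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    threshold: float = 0.5
    seed: Optional[int] = None


def _luminance(patch: np.ndarray) -> np.ndarray:
    p = patch.astype(np.float64)
    return 0.299 * p[..., 0] + 0.587 * p[..., 1] + 0.114 * p[..., 2]


def _component_stats(mask: np.ndarray) -> tuple[int, float]:
    """Connected-component count and mean eccentricity of a boolean mask.

    Eccentricity is that of the ellipse with the same second central
    moments as the component (1 for a line, 0 for a rotationally symmetric
    blob), computed vectorized over all components at once.
    """
    labelled, n_comp = ndimage.label(mask, structure=_CONN8)
    if n_comp == 0:
        return 0, 0.0
    ys, xs = np.nonzero(labelled)
    ids = labelled[ys, xs]
    n = np.bincount(ids)[1:].astype(np.float64)
    sy = np.bincount(ids, weights=ys)[1:]
    sx = np.bincount(ids, weights=xs)[1:]
    syy = np.bincount(ids, weights=ys * ys)[1:]
    sxx = np.bincount(ids, weights=xs * xs)[1:]
    sxy = np.bincount(ids, weights=xs * ys)[1:]
    # central second moments per component
    myy = syy / n - (sy / n) ** 2
    mxx = sxx / n - (sx / n) ** 2
    mxy = sxy / n - (sx / n) * (sy / n)
    # eigenvalues of the 2x2 covariance
    tr = mxx + myy
    det = mxx * myy - mxy**2
    disc = np.sqrt(np.maximum(tr**2 / 4 - det, 0.0))
    l1 = tr / 2 + disc
    l2 = tr / 2 - disc
    with np.errstate(divide="ignore", invalid="ignore"):
        ecc = np.sqrt(1.0 - np.clip(l2 / np.where(l1 > 0, l1, 1.0), 0.0, 1.0))
    ecc[l1 <= 0] = 0.0  # single pixels / degenerate components
    return int(n_comp), float(ecc.mean())


def _denoise_mask(mask: np.ndarray, min_size: int = MIN_COMPONENT_SIZE) -> np.ndarray:
    """Drop connected components smaller than ``min_size`` pixels."""
    labelled, n_comp = ndimage.label(mask, structure=_CONN8)
    if n_comp == 0:
        return mask
    sizes = np.bincount(labelled.ravel())[1:]
    keep = np.flatnonzero(sizes >= min_size) + 1
    return np.isin(labelled, keep)


def _max_chromaticity_excess(patch: np.ndarray, mask: np.ndarray) -> float:
    """Largest per-component excess of red chromaticity over the background.

    Chromaticity here is R / (R + G + B); the excess of a component is its
    mean chromaticity minus the whole-patch mean.  0 when the mask is empty.
    """
    labelled, n_comp = ndimage.label(mask, structure=_CONN8)
    if n_comp == 0:
        return 0.0
    p = patch.astype(np.float64)
    red_chr = p[..., 0] / (p.sum(axis=-1) + 1e-9)
    base = float(red_chr.mean())
    ids = labelled[mask]
    sums = np.bincount(ids, weights=red_chr[mask], minlength=n_comp + 1)[1:]
    counts = np.bincount(ids, minlength=n_comp + 1)[1:]
    return float(np.max(sums / counts - base))


def featurize(patch: np.ndarray) -> np.ndarray:
    """Map one (S, S, 3) uint8 RGB patch to the fixed 10-vector above."""
    patch = np.asarray(patch)
    if patch.ndim != 3 or patch.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB patch, got shape {patch.shape}")
    p = patch.astype(np.float64)
    means = p.mean(axis=(0, 1))
    stds = p.std(axis=(0, 1))

    lum = _luminance(patch)
    smoothed = ndimage.uniform_filter(lum, size=SMOOTHING_SIZE, mode="reflect")
    mask = _denoise_mask((lum - smoothed) > RESIDUAL_THRESHOLD)
    bright_frac = float(mask.mean())

    n_comp, mean_ecc = _component_stats(mask)
    chroma = _max_chromaticity_excess(patch, mask)

    return np.array(
        [*means, *stds, bright_frac, np.log1p(n_comp), mean_ecc, chroma],
        dtype=np.float64,
    )


def _feature_matrix(patches: Sequence[np.ndarray]) -> np.ndarray:
    return np.stack([featurize(p) for p in patches])


def split_train_test(
    labels: Sequence[str], seed: int, train_frac: float = 0.8
) -> list[str]:
    """Seeded stratified 80/20 assignment, per-class counts within +-1."""
    split = ["test"] * len(labels)
    rng = np.random.default_rng(seed)
    for cls in sorted(set(labels)):
        idx = np.array([i for i, l in enumerate(labels) if l == cls])
        rng.shuffle(idx)
        n_train = int(round(train_frac * len(idx)))
        for i in idx[:n_train]:
            split[int(i)] = "train"
    return split


def train(dataset: PatchDataset, seed: int = 0) -> ClassifierModel:
    """Fit the logistic decision layer on the train split.

    Raises if the train split contains only one class -- a model fitted on
    a single class cannot produce a calibrated tassel score.
    """
    patches, labels = dataset.subset("train")
    classes = set(labels)
    if len(classes) < 2:
        raise ValueError(f"training split contains a single class: {classes}")
    X = _feature_matrix(patches)
    y = np.array([1 if l == POSITIVE else 0 for l in labels])

    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X - mean) / scale

    clf = LogisticRegression(max_iter=2000, random_state=seed)
    clf.fit(Xs, y)
    return ClassifierModel(
        coef=clf.coef_[0].copy(),
        intercept=float(clf.intercept_[0]),
        feature_mean=mean,
        feature_scale=scale,
        threshold=0.5,
        seed=seed,
    )


def predict_scores(model: ClassifierModel, patches: Sequence[np.ndarray]) -> np.ndarray:
    """Tassel probability in [0, 1] for each patch."""
    if len(patches) == 0:
        return np.zeros(0)
    X = (_feature_matrix(patches) - model.feature_mean) / model.feature_scale
    z = X @ model.coef + model.intercept
    return 1.0 / (1.0 + np.exp(-z))


def predict_labels(model: ClassifierModel, patches: Sequence[np.ndarray]) -> list[str]:
    scores = predict_scores(model, patches)
    return [POSITIVE if s >= model.threshold else NEGATIVE for s in scores]


def evaluate(
    model: ClassifierModel, dataset: PatchDataset, which: str = "test"
) -> dict:
    """Confusion counts and accuracy/precision/recall/F1 on one split.

    The positive class is ``tassel``.  Undefined ratios (empty denominator)
    surface as ``None``.
    """
    patches, labels = dataset.subset(which)
    if not patches:
        raise ValueError(f"empty {which!r} split")
    pred = predict_labels(model, patches)
    tp = sum(p == POSITIVE and t == POSITIVE for p, t in zip(pred, labels))
    fp = sum(p == POSITIVE and t != POSITIVE for p, t in zip(pred, labels))
    fn = sum(p != POSITIVE and t == POSITIVE for p, t in zip(pred, labels))
    tn = len(labels) - tp - fp - fn
    report = MetricsReport.from_counts(tp, fp, fn)
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
        "accuracy": (tp + tn) / len(labels),
        "precision": report.precision,
        "recall": report.recall,
        "f1": report.f1,
    }


def save_model(model: ClassifierModel, path: Union[str, Path]) -> None:
    """Serialize to a single portable JSON file with a format header."""
    payload = {
        "format": MODEL_FORMAT,
        "coef": model.coef.tolist(),
        "intercept": model.intercept,
        "feature_mean": model.feature_mean.tolist(),
        "feature_scale": model.feature_scale.tolist(),
        "threshold": model.threshold,
        "seed": model.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def load_model(path: Union[str, Path]) -> ClassifierModel:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if payload.get("format") != MODEL_FORMAT:
        raise ValueError(f"unrecognized model format: {payload.get('format')!r}")
    return ClassifierModel(
        coef=np.array(payload["coef"], dtype=np.float64),
        intercept=float(payload["intercept"]),
        feature_mean=np.array(payload["feature_mean"], dtype=np.float64),
        feature_scale=np.array(payload["feature_scale"], dtype=np.float64),
        threshold=float(payload["threshold"]),
        seed=payload.get("seed"),
    )
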