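"""Box geometry, IoU, detection matching and precision/recall/F1.

Coordinates follow the image convention used throughout :mod:`tasselkit`:
0-based, half-open pixel rectangles ``[xmin, xmax) x [ymin, ymax)`` with the
origin at the top-left corner and *y* increasing downward.  A box therefore
covers exactly ``(xmax - xmin) * (ymax - ymin)`` pixels when its coordinates
are integral.

Two evaluation protocols are provided as :class:`EvalConfig` presets:

``EvalConfig.default_protocol()``
    The stock PASCAL VOC rule set: a detection claims a ground-truth box at
    IoU >= 0.5, every detection enters the counts, and duplicate detections
    of an already-matched ground truth count as false positives.

``EvalConfig.customized_protocol()``
    The agricultural variant: tassels are thin and often annotated as loose
    groups, so partial overlap is informative.  The IoU threshold drops to
    0.3, detections scoring below 0.1 are discarded, and duplicate
    detections of the same ground truth are *dropped* -- excluded from both
    the true-positive and false-positive counts rather than penalized.

Metrics with an empty denominator (e.g. precision with no retained
detections) are reported as ``None`` ("not defined"), never silently 0.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "Box",
    "Detection",
    "DuplicatePolicy",
    "EvalConfig",
    "Verdict",
    "MatchResult",
    "MetricsReport",
    "iou",
    "match_detections",
    "precision_recall",
    "f1",
    "average_precision",
]


@dataclass(frozen=True, order=True)
class Box:
    """Axis-aligned pixel rectangle, 0-based half-open."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise ValueError(
                f"degenerate box (needs xmin<xmax and ymin<ymax): "
                f"({self.xmin}, {self.ymin}, {self.xmax}, {self.ymax})"
            )

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        return self.width * self.height

    def translate(self, dx: float, dy: float) -> "Box":
        return Box(self.xmin + dx, self.ymin + dy, self.xmax + dx, self.ymax + dy)

    def intersection_area(self, other: "Box") -> float:
        w = min(self.xmax, other.xmax) - max(self.xmin, other.xmin)
        h = min(self.ymax, other.ymax) - max(self.ymin, other.ymin)
        if w <= 0 or h <= 0:
            return 0.0
        return w * h


@dataclass(frozen=True)
class Detection:
    """A candidate box plus the detector's confidence score in [0, 1]."""

    box: Box
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must lie in [0, 1], got {self.score}")


class DuplicatePolicy(enum.Enum):
    """What to do with a 2nd+ detection of an already-matched ground truth."""

    COUNT_AS_FP = "count_as_fp"
    DROP = "drop"


class Verdict(enum.Enum):
    TP = "TP"
    FP = "FP"
    DUP_DROPPED = "DUP_DROPPED"
    BELOW_SCORE = "BELOW_SCORE"


@dataclass(frozen=True)
class EvalConfig:
    """Thresholds and duplicate handling for detection evaluation."""

    matching_iou_threshold: float = 0.5
    min_score: float = 0.0
    duplicate_policy: DuplicatePolicy = DuplicatePolicy.COUNT_AS_FP

    def __post_init__(self) -> None:
        if not 0.0 < self.matching_iou_threshold <= 1.0:
            raise ValueError("matching_iou_threshold must lie in (0, 1]")
        if not 0.0 <= self.min_score <= 1.0:
            raise ValueError("min_score must lie in [0, 1]")

    @classmethod
    def default_protocol(cls) -> "EvalConfig":
        """Stock PASCAL VOC: IoU 0.5, all scores, duplicates are FP."""
        return cls(0.5, 0.0, DuplicatePolicy.COUNT_AS_FP)

    @classmethod
    def customized_protocol(cls) -> "EvalConfig":
        """Tassel-detection variant: IoU 0.3, min score 0.1, duplicates dropped."""
        return cls(0.3, 0.1, DuplicatePolicy.DROP)


@dataclass
class MatchResult:
    """Outcome of matching one image's detections against its ground truth.

    ``verdicts`` is aligned with the *input order* of the detections;
    ``gt_matched`` with the input order of the ground-truth boxes.
    """

    verdicts: list[Verdict]
    gt_matched: list[bool]

    @property
    def tp(self) -> int:
        return sum(v is Verdict.TP for v in self.verdicts)

    @property
    def fp(self) -> int:
        return sum(v is Verdict.FP for v in self.verdicts)

    @property
    def fn(self) -> int:
        return sum(not m for m in self.gt_matched)

    @property
    def n_dropped(self) -> int:
        return sum(v is Verdict.DUP_DROPPED for v in self.verdicts)

    @property
    def n_below_score(self) -> int:
        return sum(v is Verdict.BELOW_SCORE for v in self.verdicts)


@dataclass(frozen=True)
class MetricsReport:
    """Precision/recall/F1 with ``None`` marking an undefined ratio."""

    precision: Optional[float]
    recall: Optional[float]
    f1: Optional[float]

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int) -> "MetricsReport":
        p = tp / (tp + fp) if tp + fp > 0 else None
        r = tp / (tp + fn) if tp + fn > 0 else None
        return cls(p, r, f1(p, r))


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two boxes; 0 when disjoint, 1 iff equal."""
    inter = a.intersection_area(b)
    union = a.area + b.area - inter
    return inter / union


def _greedy_order(dets: Sequence[Detection]) -> list[int]:
    # descending score; stable, so ties keep input order
    return sorted(range(len(dets)), key=lambda i: -dets[i].score)


def match_detections(
    dets: Sequence[Detection],
    gts: Sequence[Box],
    cfg: EvalConfig,
) -> MatchResult:
    """Greedy score-ordered matching of detections to ground-truth boxes.

    Detections below ``cfg.min_score`` are tagged BELOW_SCORE and excluded
    from every count.  The remaining detections are visited in descending
    score order (ties broken by input order).  Each is assigned to the
    ground truth of maximal IoU (ties broken by lowest ground-truth index):

    * IoU >= threshold and the ground truth unmatched -> TP;
    * IoU >= threshold but already matched -> duplicate: FP under
      ``COUNT_AS_FP``, DUP_DROPPED under ``DROP``;
    * IoU below threshold (or no ground truth at all) -> FP.

    A ground truth never matched contributes one false negative.
    """
    verdicts: list[Optional[Verdict]] = [None] * len(dets)
    matched = [False] * len(gts)

    for i in _greedy_order(dets):
        det = dets[i]
        if det.score < cfg.min_score:
            verdicts[i] = Verdict.BELOW_SCORE
            continue
        best_j = -1
        best_iou = 0.0
        for j, gt in enumerate(gts):
            v = iou(det.box, gt)
            if v > best_iou:  # strict: ties keep the lowest index
                best_iou = v
                best_j = j
        if best_j >= 0 and best_iou >= cfg.matching_iou_threshold:
            if not matched[best_j]:
                matched[best_j] = True
                verdicts[i] = Verdict.TP
            elif cfg.duplicate_policy is DuplicatePolicy.DROP:
                verdicts[i] = Verdict.DUP_DROPPED
            else:
                verdicts[i] = Verdict.FP
        else:
            verdicts[i] = Verdict.FP

    assert all(v is not None for v in verdicts)
    return MatchResult(verdicts=list(verdicts), gt_matched=matched)  # type: ignore[arg-type]


def precision_recall(m: MatchResult) -> tuple[Optional[float], Optional[float]]:
    """precision = tp/(tp+fp), recall = tp/(tp+fn); ``None`` when undefined.

    Dropped duplicates and below-score detections enter neither ratio.
    """
    tp, fp, fn = m.tp, m.fp, m.fn
    p = tp / (tp + fp) if tp + fp > 0 else None
    r = tp / (tp + fn) if tp + fn > 0 else None
    return p, r


def f1(precision: Optional[float], recall: Optional[float]) -> Optional[float]:
    """Harmonic mean of precision and recall; ``None`` when undefined."""
    if precision is None or recall is None:
        return None
    if precision == 0.0 and recall == 0.0:
        return None
    return 2.0 * precision * recall / (precision + recall)


def average_precision(
    images: Sequence[tuple[Sequence[Detection], Sequence[Box]]],
    cfg: EvalConfig,
) -> Optional[float]:
    """All-points interpolated average precision over a score sweep.

    ``images`` pairs each image's detections with its ground-truth boxes.
    Verdicts come from per-image greedy matching under ``cfg``; the
    precision-recall curve is then swept over all detections pooled across
    images in descending score order, skipping dropped duplicates and
    below-score detections.  Precision is interpolated to its running
    maximum from the right (the "all points" PASCAL variant).

    Returns ``None`` when there is no ground truth at all.
    """
    n_gt = sum(len(gts) for _, gts in images)
    if n_gt == 0:
        return None

    scored: list[tuple[float, Verdict]] = []
    for dets, gts in images:
        res = match_detections(dets, gts, cfg)
        for det, v in zip(dets, res.verdicts):
            scored.append((det.score, v))
    scored.sort(key=lambda t: -t[0])

    precisions: list[float] = []
    recalls: list[float] = []
    tp = fp = 0
    for _, v in scored:
        if v is Verdict.TP:
            tp += 1
        elif v is Verdict.FP:
            fp += 1
        else:
            continue  # DUP_DROPPED / BELOW_SCORE: invisible to the curve
        precisions.append(tp / (tp + fp))
        recalls.append(tp / n_gt)

    if not precisions:
        return 0.0

    # monotone precision envelope, then area under the step curve
    ap = 0.0
    prev_recall = 0.0
    for k in range(len(precisions)):
        precisions[k] = max(precisions[k:])
    for p, r in zip(precisions, recalls):
        ap += p * (r - prev_recall)
        prev_recall = r
    return ap
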