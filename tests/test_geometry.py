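"""Box geometry, IoU, greedy matching and the detection metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tasselkit.geometry import (
    Box,
    Detection,
    DuplicatePolicy,
    EvalConfig,
    MetricsReport,
    Verdict,
    average_precision,
    f1,
    iou,
    match_detections,
    precision_recall,
)

# ---------------------------------------------------------------------------
# IoU
# ---------------------------------------------------------------------------


def pixel_count_iou(a: Box, b: Box) -> float:
    """Oracle: count lattice pixels inside each half-open box directly."""
    pa = {
        (x, y)
        for x in range(int(a.xmin), int(a.xmax))
        for y in range(int(a.ymin), int(a.ymax))
    }
    pb = {
        (x, y)
        for x in range(int(b.xmin), int(b.xmax))
        for y in range(int(b.ymin), int(b.ymax))
    }
    return len(pa & pb) / len(pa | pb)


@pytest.mark.parametrize(
    "a, b, expected",
    [
        (Box(3, 4, 10, 12), Box(3, 4, 10, 12), 1.0),  # identity
        (Box(0, 0, 10, 10), Box(20, 20, 30, 30), 0.0),  # disjoint
        (Box(0, 0, 2, 2), Box(1, 1, 3, 3), 1 / 7),  # 1-pixel overlap
    ],
)
def test_iou_examples(a, b, expected):
    assert iou(a, b) == pytest.approx(expected, abs=1e-12)


def test_degenerate_box_rejected():
    with pytest.raises(ValueError):
        Box(5, 0, 5, 10)
    with pytest.raises(ValueError):
        Box(0, 10, 10, 10)


def test_iou_matches_pixel_counting_oracle(rng):
    """On 1000 random integer box pairs, IoU equals exhaustive pixel counting."""
    for _ in range(1000):
        x0, y0, x1, y1 = rng.integers(0, 30, 4)
        a = Box(min(x0, x1), min(y0, y1), max(x0, x1) + 1, max(y0, y1) + 1)
        x0, y0, x1, y1 = rng.integers(0, 30, 4)
        b = Box(min(x0, x1), min(y0, y1), max(x0, x1) + 1, max(y0, y1) + 1)
        v = iou(a, b)
        assert v == pytest.approx(pixel_count_iou(a, b), abs=1e-12)
        assert v == iou(b, a)  # symmetry
        assert 0.0 <= v <= 1.0


# ---------------------------------------------------------------------------
# Greedy matching
# ---------------------------------------------------------------------------


def greedy_match_oracle(dets, gts, cfg):
    """Independent re-statement of the greedy rule: returns (tp, fp, fn).

    Written without reusing any package internals: per ground truth it is
    enough to know which retained detections name it as their best overlap
    and whether the best of those clears the threshold.
    """
    retained = [(i, d) for i, d in enumerate(dets) if d.score >= cfg.min_score]
    # best gt per retained detection
    assignment = {}
    for i, d in retained:
        ious = [iou(d.box, g) for g in gts]
        if ious:
            j = int(np.argmax(ious))  # argmax takes the lowest index on ties
            assignment[i] = (j, ious[j])
    tp = 0
    fp = 0
    matched = set()
    order = sorted(retained, key=lambda t: (-t[1].score, t[0]))
    for i, d in order:
        j, v = assignment.get(i, (None, 0.0))
        if j is not None and v >= cfg.matching_iou_threshold:
            if j not in matched:
                matched.add(j)
                tp += 1
            elif cfg.duplicate_policy is DuplicatePolicy.COUNT_AS_FP:
                fp += 1
        else:
            fp += 1
    return tp, fp, len(gts) - len(matched)


def random_scene(rng, n_dets, n_gts):
    def rbox():
        x0, y0 = rng.integers(0, 20, 2)
        w, h = rng.integers(1, 12, 2)
        return Box(int(x0), int(y0), int(x0 + w), int(y0 + h))

    gts = [rbox() for _ in range(n_gts)]
    dets = [Detection(rbox(), float(rng.uniform())) for _ in range(n_dets)]
    return dets, gts


def test_exact_single_match():
    gt = Box(10, 10, 50, 50)
    res = match_detections(
        [Detection(gt, 0.9)], [gt], EvalConfig.default_protocol()
    )
    assert (res.tp, res.fp, res.fn) == (1, 0, 0)
    assert res.verdicts == [Verdict.TP]


def test_below_score_detections_excluded():
    gt = Box(0, 0, 10, 10)
    dets = [Detection(gt, 0.05), Detection(gt, 0.9)]
    res = match_detections(dets, [gt], EvalConfig.customized_protocol())
    assert res.verdicts == [Verdict.BELOW_SCORE, Verdict.TP]
    assert (res.tp, res.fp, res.fn) == (1, 0, 0)
    # verdict partition always accounts for every detection
    assert res.tp + res.fp + res.n_dropped + res.n_below_score == len(dets)


def test_empty_inputs_are_legal():
    cfg = EvalConfig.default_protocol()
    res = match_detections([], [Box(0, 0, 5, 5)], cfg)
    assert (res.tp, res.fp, res.fn) == (0, 0, 1)
    res = match_detections([Detection(Box(0, 0, 5, 5), 0.5)], [], cfg)
    assert (res.tp, res.fp, res.fn) == (0, 1, 0)


def test_matching_agrees_with_independent_oracle(rng):
    """Greedy counts match a brute-force restatement on small random scenes."""
    for _ in range(300):
        dets, gts = random_scene(rng, int(rng.integers(0, 6)), int(rng.integers(0, 5)))
        cfg = EvalConfig(
            matching_iou_threshold=float(rng.choice([0.1, 0.3, 0.5])),
            min_score=float(rng.choice([0.0, 0.2])),
            duplicate_policy=rng.choice(list(DuplicatePolicy)),
        )
        res = match_detections(dets, gts, cfg)
        assert (res.tp, res.fp, res.fn) == greedy_match_oracle(dets, gts, cfg)


def test_permutation_invariance_with_distinct_scores(rng):
    for _ in range(50):
        dets, gts = random_scene(rng, 6, 4)
        # force distinct scores
        scores = rng.permutation(np.linspace(0.1, 0.9, len(dets)))
        dets = [Detection(d.box, float(s)) for d, s in zip(dets, scores)]
        cfg = EvalConfig.customized_protocol()
        base = match_detections(dets, gts, cfg)
        perm = rng.permutation(len(dets))
        shuffled = [dets[i] for i in perm]
        res = match_detections(shuffled, gts, cfg)
        assert (res.tp, res.fp, res.fn) == (base.tp, base.fp, base.fn)
        # per-detection verdicts follow the detections through the permutation
        assert [res.verdicts[k] for k in np.argsort(perm)] == base.verdicts


def test_lower_iou_threshold_never_decreases_tp(rng):
    for _ in range(50):
        dets, gts = random_scene(rng, 6, 4)
        tps = []
        for thr in (0.7, 0.5, 0.3, 0.1):
            cfg = EvalConfig(thr, 0.0, DuplicatePolicy.COUNT_AS_FP)
            tps.append(match_detections(dets, gts, cfg).tp)
        assert tps == sorted(tps)


def test_drop_policy_precision_monotone_recall_fixed(rng):
    for _ in range(100):
        dets, gts = random_scene(rng, 7, 4)
        as_fp = match_detections(dets, gts, EvalConfig(0.3, 0.0, DuplicatePolicy.COUNT_AS_FP))
        dropped = match_detections(dets, gts, EvalConfig(0.3, 0.0, DuplicatePolicy.DROP))
        p0, r0 = precision_recall(as_fp)
        p1, r1 = precision_recall(dropped)
        assert r0 == r1
        if p0 is not None and p1 is not None:
            assert p1 >= p0


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def test_precision_recall_examples():
    m = match_detections([], [], EvalConfig.default_protocol())
    assert precision_recall(m) == (None, None)  # tp=fp=fn=0

    rep = MetricsReport.from_counts(1, 7, 4)
    assert rep.precision == pytest.approx(0.125)
    assert rep.recall == pytest.approx(0.2)

    rep = MetricsReport.from_counts(4, 1, 1)
    assert rep.precision == pytest.approx(0.8)
    assert rep.recall == pytest.approx(0.8)


@pytest.mark.parametrize(
    "p, r, expected, decimals",
    [
        (0.972, 0.946, 0.959, 3),
        (1.0, 1.0, 1.0, 12),
        (0.9764, 0.9832, 0.9798, 4),
    ],
)
def test_f1_examples(p, r, expected, decimals):
    assert round(f1(p, r), decimals) == expected


def test_f1_not_defined():
    assert f1(0.0, 0.0) is None
    assert f1(None, 0.5) is None


@settings(derandomize=True, max_examples=200)
@given(
    p=st.floats(0.0, 1.0, allow_nan=False),
    r=st.floats(0.0, 1.0, allow_nan=False),
)
def test_f1_between_min_and_max(p, r):
    v = f1(p, r)
    if v is not None:
        assert min(p, r) - 1e-12 <= v <= max(p, r) + 1e-12


# ---------------------------------------------------------------------------
# Average precision
# ---------------------------------------------------------------------------


def test_ap_perfect_single_detection():
    gt = Box(0, 0, 10, 10)
    images = [([Detection(gt, 0.9)], [gt])]
    assert average_precision(images, EvalConfig.default_protocol()) == pytest.approx(1.0)


def test_ap_nothing_above_min_score():
    gt = Box(0, 0, 10, 10)
    images = [([Detection(gt, 0.05)], [gt])]
    assert average_precision(images, EvalConfig.customized_protocol()) == 0.0


def test_ap_two_point_curve():
    # hand-enumerated: TP at score 0.9 reaches recall 1 at precision 1;
    # the later FP cannot lower the area of the all-points curve
    gt = Box(0, 0, 10, 10)
    dets = [Detection(gt, 0.9), Detection(Box(50, 50, 60, 60), 0.8)]
    assert average_precision([(dets, [gt])], EvalConfig.default_protocol()) == pytest.approx(1.0)


def test_ap_no_ground_truth_not_defined():
    dets = [Detection(Box(0, 0, 10, 10), 0.9)]
    assert average_precision([(dets, [])], EvalConfig.default_protocol()) is None
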