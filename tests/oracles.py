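"""Independent brute-force reimplementations of the evaluation metrics.

Everything here is deliberately naive — pixel-coordinate sets, explicit
loops, threshold enumeration — and shares no code with the package's
evaluation module beyond the documented conventions (greedy
score-descending matching; 0/0 precision and recall map to 1; an image
with no labels and no predictions scores AP 1, an image with no true
positive at any threshold scores 0).
"""

import numpy as np

from phasetime import InstanceMaskSet


def oracle_pair_iou(a, b):
    sa = {(r, c) for r, c in zip(*np.nonzero(a))}
    sb = {(r, c) for r, c in zip(*np.nonzero(b))}
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)


def oracle_match(s_l, s_p, t_iou):
    order = sorted(range(len(s_p)),
                   key=lambda j: -(s_p.scores[j] if s_p.scores else 0))
    taken = [False] * len(s_l)
    pairs = []
    for j in order:
        best, best_iou = -1, t_iou
        for i in range(len(s_l)):
            if taken[i]:
                continue
            iou = oracle_pair_iou(s_l.masks[i], s_p.masks[j])
            if iou > best_iou:
                best, best_iou = i, iou
        if best >= 0:
            taken[best] = True
            pairs.append((best, j, best_iou))
    return pairs


def oracle_pr_points(s_l, s_p, t_iou):
    points = []
    for t_s in sorted(set(s_p.scores)):
        keep = [j for j, s in enumerate(s_p.scores) if s >= t_s]
        sub = InstanceMaskSet(s_p.shape, [s_p.masks[j] for j in keep],
                              [s_p.scores[j] for j in keep])
        tp = len(oracle_match(s_l, sub, t_iou))
        fp = len(sub) - tp
        fn = len(s_l) - tp
        p = 1.0 if tp + fp == 0 else tp / (tp + fp)
        r = 1.0 if tp + fn == 0 else tp / (tp + fn)
        points.append((t_s, p, r))
    return points


def oracle_ap(s_l, s_p, t_iou, m=100):
    if len(s_l) == 0 and len(s_p) == 0:
        return 1.0
    if len(s_p) == 0 or len(s_l) == 0:
        return 0.0
    pts = oracle_pr_points(s_l, s_p, t_iou)
    if all(r == 0 for _, _, r in pts):
        return 0.0
    total = 0.0
    for j in range(1, m + 1):
        level = j / m
        best = 0.0
        for _, p, r in pts:
            if r >= level - 1e-12 and p > best:
                best = p
        total += best
    return total / m
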