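"""Compact anchor-based detect-and-segment network.

The architecture follows the two-stage detect-then-segment design used for
nuclei in phase-contrast patches:

* a small residual backbone (trained from random initialisation) feeds a
  feature pyramid with top-down aggregation and lateral skips, one level
  per anchor scale;
* a region-proposal head scans every pyramid cell with anchors of three
  aspect ratios {1:2, 1:1, 2:1}, scoring objectness and regressing box
  adjustments; overlapping proposals are pruned with non-max suppression;
* proposals are pooled with a 7x7 alignment layer into a classification +
  box-refinement head, and positives are pooled at 14x14 into a small
  fully-convolutional mask head emitting a 28x28 float mask per instance.

Each anchor scale ``s`` is served by the pyramid level whose stride is
``s / 2``, so scanning positions are spaced at half the anchor side even
for the densest per-cell placement.  Training optimises the sum of proposal
objectness (binary cross-entropy) + proposal box (smooth L1) + head
classification (cross-entropy) + head box (smooth L1) + mask
(binary cross-entropy, positives only) losses with Adam; every source of
randomness flows from ``TrainConfig.seed``.

The default head widths are deliberately narrow so that training a useful
model on a single CPU takes minutes; the wide configuration (256-channel
mask head, deeper backbone) is available through :class:`TrainConfig`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from skimage.transform import resize

from . import _autograd as ag
from ._autograd import Tensor
from .instances import Detection, InstanceMaskSet, pairwise_box_iou

__all__ = ["AnchorConfig", "TrainConfig", "generate_anchors", "nms",
           "NucleiDetector", "train", "predict"]


@dataclass
class AnchorConfig:
    """Anchor geometry: square side lengths and aspect ratios.

    The default five scales cover objects up to 128 px and beyond (the 2:1
    anchors at scale 128 are ~181 px long), enough for the largest nucleus
    (~120 px after 2x upsampling at full scale).  ``ratio`` r gives an
    anchor of height ``s*sqrt(r)`` and width ``s/sqrt(r)`` (area ~ s^2).
    """

    scales: tuple[int, ...] = (8, 16, 32, 64, 128)
    aspect_ratios: tuple[float, ...] = (0.5, 1.0, 2.0)

    def __post_init__(self):
        if any(s <= 0 for s in self.scales):
            raise ValueError("anchor scales must be positive")
        if any(r <= 0 for r in self.aspect_ratios):
            raise ValueError("aspect ratios must be positive")

    @property
    def max_side(self) -> float:
        return max(self.scales) * np.sqrt(max(max(self.aspect_ratios),
                                              1 / min(self.aspect_ratios)))


def _ratio_boxes(center_r, center_c, scale, ratios):
    """Anchor boxes of one scale and several ratios around one centre."""
    out = []
    for r in ratios:
        h = scale * np.sqrt(r)
        w = scale / np.sqrt(r)
        out.append((center_r - h / 2, center_c - w / 2,
                    center_r + h / 2, center_c + w / 2))
    return out


def generate_anchors(cfg: AnchorConfig, image_size: tuple[int, int]):
    """Anchors on the half-anchor-side scanning grid, clipped to the image.

    For each scale ``s`` the 1:1 anchor's top-left corner visits
    ``0, s/2, 2*(s/2), ...`` as long as the box fits inside the frame
    (``floor((L - s) / (s/2)) + 1`` placements per axis); each position
    contributes one anchor per aspect ratio.  Returns ``(boxes, levels)``
    where ``levels[i]`` is the index of the scale that produced box ``i``.
    """
    H, W = image_size
    boxes, levels = [], []
    for li, s in enumerate(cfg.scales):
        if s > H or s > W:
            continue
        step = max(s // 2, 1)
        for r0 in range(0, H - s + 1, step):
            for c0 in range(0, W - s + 1, step):
                cr, cc = r0 + s / 2, c0 + s / 2
                for b in _ratio_boxes(cr, cc, s, cfg.aspect_ratios):
                    boxes.append((max(b[0], 0), max(b[1], 0),
                                  min(b[2], H), min(b[3], W)))
                    levels.append(li)
    return np.array(boxes, dtype=float).reshape(-1, 4), np.array(levels, dtype=int)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float) -> list[int]:
    """Greedy descending-score non-max suppression.

    A box is discarded iff its IoU with an already-kept box exceeds
    ``iou_threshold``.  Returns kept indices in descending-score order.
    """
    boxes = np.asarray(boxes, dtype=float).reshape(-1, 4)
    scores = np.asarray(scores, dtype=float)
    if len(boxes) != len(scores):
        raise ValueError("boxes and scores must have equal length")
    order = np.argsort(-scores, kind="stable")
    keep: list[int] = []
    kept_boxes: list[np.ndarray] = []
    for idx in order:
        if kept_boxes:
            ious = pairwise_box_iou(boxes[idx][None], np.array(kept_boxes))[0]
            if (ious > iou_threshold).any():
                continue
        keep.append(int(idx))
        kept_boxes.append(boxes[idx])
    return keep


@dataclass
class TrainConfig:
    """Training and architecture configuration.

    Defaults are the compact, CPU-trainable configuration; ``wide=True``
    switches to the full-width heads (256-channel mask head, wider FPN).
    """

    anchor: AnchorConfig = field(default_factory=lambda: AnchorConfig(scales=(8, 16, 32)))
    fpn_channels: int = 32
    mask_head_channels: int = 32
    head_fc: int = 128
    roi_align_detect: int = 7
    roi_align_mask: int = 14
    mask_out: int = 28
    wide: bool = False
    epochs: int = 10
    learning_rate: float = 2e-3
    batch_size: int = 1
    score_threshold: float = 0.9
    nms_iou: float = 0.3
    rpn_nms_iou: float = 0.7
    pre_nms_top_n: int = 256
    post_nms_top_n: int = 200
    rpn_pos_iou: float = 0.7
    rpn_neg_iou: float = 0.3
    rpn_batch: int = 256  # sampled anchors per image, 1:1 pos:neg capped
    roi_batch: int = 64  # sampled proposals per image
    gt_jitter: int = 4  # jittered copies of each truth box added to proposals
    roi_pos_iou: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.wide:
            self.fpn_channels = max(self.fpn_channels, 64)
            self.mask_head_channels = max(self.mask_head_channels, 256)
            self.head_fc = max(self.head_fc, 512)


# ------------------------------------------------------------------ model

_BACKBONE_CH = (16, 24, 32, 48, 64, 64, 64)  # stem + one entry per stride-2 stage


class _Net:
    """Parameter container + forward passes for the compact network."""

    def __init__(self, cfg: TrainConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.n_levels = len(cfg.anchor.scales)
        # pyramid strides: level i serves scale s_i at stride s_i / 2
        self.strides = [max(s // 2, 1) for s in cfg.anchor.scales]
        if sorted(self.strides) != list(self.strides):
            raise ValueError("anchor scales must be increasing")
        self.params: dict[str, Tensor] = {}
        self._rng = rng
        self._build()

    # -- parameter helpers -------------------------------------------------
    def _conv_p(self, name, cin, cout, k):
        fan_in = cin * k * k
        w = self._rng.normal(0, np.sqrt(2.0 / fan_in), size=(cout, cin, k, k))
        self.params[name + ".w"] = Tensor(w.astype(np.float32), requires_grad=True)
        self.params[name + ".b"] = Tensor(np.zeros(cout, np.float32), requires_grad=True)

    def _fc_p(self, name, din, dout, gain=2.0):
        w = self._rng.normal(0, np.sqrt(gain / din), size=(din, dout))
        self.params[name + ".w"] = Tensor(w.astype(np.float32), requires_grad=True)
        self.params[name + ".b"] = Tensor(np.zeros(dout, np.float32), requires_grad=True)

    def _conv(self, name, x, stride=1, pad=1):
        return ag.conv2d(x, self.params[name + ".w"], self.params[name + ".b"],
                         stride=stride, pad=pad)

    def _fc(self, name, x):
        return ag.add(ag.matmul(x, self.params[name + ".w"]),
                      self.params[name + ".b"])

    def _build(self):
        cfg = self.cfg
        F = cfg.fpn_channels
        ch = _BACKBONE_CH
        self._conv_p("stem", 1, ch[0], 3)
        n_stages = int(np.log2(self.strides[-1]))  # deepest backbone stride
        self.n_stages = n_stages
        for i in range(n_stages):
            cin = ch[i]
            cout = ch[i + 1]
            self._conv_p(f"down{i}", cin, cout, 3)
            self._conv_p(f"res{i}a", cout, cout, 3)
            self._conv_p(f"res{i}b", cout, cout, 3)
        # FPN laterals + smoothing for every level actually used
        self.level_stages = [int(np.log2(s)) for s in self.strides]
        for li, st in enumerate(self.level_stages):
            self._conv_p(f"lat{li}", ch[st], F, 1)
            self._conv_p(f"smooth{li}", F, F, 3)
        A = len(cfg.anchor.aspect_ratios)
        self._conv_p("rpn_shared", F, F, 3)
        self._conv_p("rpn_cls", F, A, 1)
        self._conv_p("rpn_box", F, 4 * A, 1)
        d = F * cfg.roi_align_detect**2
        self._fc_p("head_fc1", d, cfg.head_fc)
        self._fc_p("head_fc2", cfg.head_fc, cfg.head_fc)
        self._fc_p("head_cls", cfg.head_fc, 1, gain=1.0)
        self._fc_p("head_box", cfg.head_fc, 4, gain=1.0)
        M = cfg.mask_head_channels
        self._conv_p("mask0", F, M, 3)
        for i in range(1, 4):
            self._conv_p(f"mask{i}", M, M, 3)
        self._conv_p("mask_up", M, M, 3)
        self._conv_p("mask_out", M, 1, 1)

    def parameters(self) -> list[Tensor]:
        return [self.params[k] for k in sorted(self.params)]

    # -- forward passes ----------------------------------------------------
    def pyramid(self, img: np.ndarray) -> list[Tensor]:
        """Feature maps, one per anchor scale (finest first)."""
        x = Tensor(img[None, None].astype(np.float32))
        x = ag.relu(self._conv("stem", x))
        stage_feats = {0: x}
        for i in range(self.n_stages):
            x = ag.relu(self._conv(f"down{i}", x, stride=2))
            r = ag.relu(self._conv(f"res{i}a", x))
            r = self._conv(f"res{i}b", r)
            x = ag.relu(ag.add(x, r))
            stage_feats[i + 1] = x
        # top-down pathway with lateral skips
        feats: list[Tensor | None] = [None] * self.n_levels
        top = None
        for li in reversed(range(self.n_levels)):
            lat = self._conv(f"lat{li}", stage_feats[self.level_stages[li]], pad=0)
            if top is not None:
                hops = self.level_stages[li + 1] - self.level_stages[li]
                up = top
                for _ in range(hops):
                    up = ag.upsample_nearest2x(up)
                lat = ag.add(lat, up)
            top = lat
            feats[li] = ag.relu(self._conv(f"smooth{li}", lat))
        return feats  # finest (stride s0/2) first

    def rpn(self, feats: list[Tensor]):
        """Per-level objectness logits and box deltas, flattened per anchor.

        Anchor order within a level is row-major over cells, ratios fastest —
        matching :meth:`level_anchor_boxes`.
        """
        logits, deltas = [], []
        A = len(self.cfg.anchor.aspect_ratios)
        for f in feats:
            h = ag.relu(self._conv("rpn_shared", f))
            cls = self._conv("rpn_cls", h, pad=0)  # (1, A, H, W)
            box = self._conv("rpn_box", h, pad=0)  # (1, 4A, H, W)
            _, _, H, W = cls.shape
            cls = ag.reshape(ag.transpose(cls, (0, 2, 3, 1)), (H * W * A,))
            box = ag.reshape(
                ag.transpose(ag.reshape(box, (1, A, 4, H, W)), (0, 3, 4, 1, 2)),
                (H * W * A, 4),
            )
            logits.append(cls)
            deltas.append(box)
        return logits, deltas

    def level_anchor_boxes(self, feats: list[Tensor]) -> list[np.ndarray]:
        """Anchors for each pyramid level, per-cell, ratios fastest."""
        out = []
        for li, f in enumerate(feats):
            _, _, H, W = f.shape
            st = self.strides[li]
            s = self.cfg.anchor.scales[li]
            cy = (np.arange(H) + 0.5) * st
            cx = (np.arange(W) + 0.5) * st
            boxes = []
            for r in self.cfg.anchor.aspect_ratios:
                h = s * np.sqrt(r)
                w = s / np.sqrt(r)
                b = np.zeros((H, W, 4))
                b[..., 0] = cy[:, None] - h / 2
                b[..., 1] = cx[None, :] - w / 2
                b[..., 2] = cy[:, None] + h / 2
                b[..., 3] = cx[None, :] + w / 2
                boxes.append(b)
            arr = np.stack(boxes, axis=2).reshape(-1, 4)  # ratios fastest
            out.append(arr)
        return out

    def roi_level(self, boxes: np.ndarray) -> np.ndarray:
        """Assign each roi to the pyramid level with the closest anchor scale."""
        side = np.maximum(boxes[:, 2] - boxes[:, 0], boxes[:, 3] - boxes[:, 1])
        scales = np.array(self.cfg.anchor.scales, dtype=float)
        return np.argmin(np.abs(np.log2(side[:, None] / scales[None, :])), axis=1)

    def _roi_features(self, feats, boxes, out_size):
        """RoIAlign each box on its assigned level; preserves box order."""
        levels = self.roi_level(boxes)
        pieces, order = [], []
        for li in range(self.n_levels):
            idx = np.flatnonzero(levels == li)
            if idx.size == 0:
                continue
            al = ag.roi_align(feats[li], boxes[idx], out_size,
                              spatial_scale=1.0 / self.strides[li])
            pieces.append(al)
            order.append(idx)
        if not pieces:
            return None, None
        cat_order = np.concatenate(order)
        # concatenate along roi axis via gather on a stacked tensor
        if len(pieces) == 1:
            stacked = pieces[0]
        else:
            stacked = _concat_rois(pieces)
        inv = np.argsort(cat_order)
        return _gather_rois(stacked, inv), cat_order

    def head(self, feats, boxes):
        """Classification logit and box deltas for each roi box."""
        pooled, _ = self._roi_features(feats, boxes, self.cfg.roi_align_detect)
        R = boxes.shape[0]
        flat = ag.reshape(pooled, (R, -1))
        h = ag.relu(self._fc("head_fc1", flat))
        h = ag.relu(self._fc("head_fc2", h))
        cls = ag.reshape(self._fc("head_cls", h), (R,))
        box = self._fc("head_box", h)
        return cls, box

    def mask_head(self, feats, boxes):
        """(R, mask_out, mask_out) mask logits for each roi box."""
        pooled, _ = self._roi_features(feats, boxes, self.cfg.roi_align_mask)
        x = pooled
        for i in range(4):
            x = ag.relu(self._conv(f"mask{i}", x))
        x = ag.upsample_nearest2x(x)
        x = ag.relu(self._conv("mask_up", x))
        x = self._conv("mask_out", x, pad=0)
        R = boxes.shape[0]
        return ag.reshape(x, (R, self.cfg.mask_out, self.cfg.mask_out))


def _concat_rois(pieces: list[Tensor]) -> Tensor:
    """Concatenate RoIAlign outputs along the roi axis (autograd-aware)."""
    datas = [p.data for p in pieces]
    out_data = np.concatenate(datas, axis=0)
    sizes = [d.shape[0] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for p, o0, o1 in zip(pieces, offsets[:-1], offsets[1:]):
            p._accumulate(g[o0:o1])

    return ag._node(out_data, tuple(pieces), backward)


def _gather_rois(t: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx, dtype=np.intp)

    def backward(g):
        dt = np.zeros_like(t.data)
        np.add.at(dt, idx, g)
        t._accumulate(dt)

    return ag._node(t.data[idx], (t,), backward)


# --------------------------------------------------------- box arithmetic

def _box_to_deltas(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    sh = np.maximum(src[:, 2] - src[:, 0], 1e-3)
    sw = np.maximum(src[:, 3] - src[:, 1], 1e-3)
    sy = (src[:, 0] + src[:, 2]) / 2
    sx = (src[:, 1] + src[:, 3]) / 2
    dh = np.maximum(dst[:, 2] - dst[:, 0], 1e-3)
    dw = np.maximum(dst[:, 3] - dst[:, 1], 1e-3)
    dy = (dst[:, 0] + dst[:, 2]) / 2
    dx = (dst[:, 1] + dst[:, 3]) / 2
    return np.stack([(dy - sy) / sh, (dx - sx) / sw,
                     np.log(dh / sh), np.log(dw / sw)], axis=1)


def _deltas_to_box(src: np.ndarray, deltas: np.ndarray) -> np.ndarray:
    sh = np.maximum(src[:, 2] - src[:, 0], 1e-3)
    sw = np.maximum(src[:, 3] - src[:, 1], 1e-3)
    sy = (src[:, 0] + src[:, 2]) / 2
    sx = (src[:, 1] + src[:, 3]) / 2
    dy = sy + deltas[:, 0] * sh
    dx = sx + deltas[:, 1] * sw
    dh = sh * np.exp(np.clip(deltas[:, 2], -2, 2))
    dw = sw * np.exp(np.clip(deltas[:, 3], -2, 2))
    return np.stack([dy - dh / 2, dx - dw / 2, dy + dh / 2, dx + dw / 2], axis=1)


def _clip_boxes(boxes: np.ndarray, shape) -> np.ndarray:
    out = boxes.copy()
    out[:, 0] = np.clip(out[:, 0], 0, shape[0] - 1)
    out[:, 1] = np.clip(out[:, 1], 0, shape[1] - 1)
    out[:, 2] = np.clip(out[:, 2], out[:, 0] + 1, shape[0])
    out[:, 3] = np.clip(out[:, 3], out[:, 1] + 1, shape[1])
    return out


def _mask_target(mask: np.ndarray, box: np.ndarray, out: int) -> np.ndarray:
    r0, c0, r1, c1 = box
    r0i, c0i = int(np.floor(r0)), int(np.floor(c0))
    r1i, c1i = int(np.ceil(r1)), int(np.ceil(c1))
    r0i, c0i = max(r0i, 0), max(c0i, 0)
    crop = mask[r0i:max(r1i, r0i + 1), c0i:max(c1i, c0i + 1)].astype(float)
    t = resize(crop, (out, out), order=1, mode="edge",
               anti_aliasing=False, preserve_range=True)
    return (t >= 0.5).astype(np.float32)


# ------------------------------------------------------------- the model

class NucleiDetector:
    """Trainable detect-and-segment model over phase-contrast patches."""

    def __init__(self, cfg: TrainConfig | None = None):
        self.cfg = cfg or TrainConfig()
        self._rng = np.random.default_rng(self.cfg.seed)
        self.net = _Net(self.cfg, self._rng)
        self.loss_trace: list[dict] = []

    # -------------------------------------------------------------- train
    def _proposals(self, feats, logits, deltas, anchors_per_level,
                   image_shape, top_n):
        scores, boxes = [], []
        for li in range(len(feats)):
            s = ag._sigmoid_np(logits[li].data)
            b = _deltas_to_box(anchors_per_level[li], deltas[li].data)
            scores.append(s)
            boxes.append(b)
        scores = np.concatenate(scores)
        boxes = _clip_boxes(np.concatenate(boxes), image_shape)
        order = np.argsort(-scores, kind="stable")[: self.cfg.pre_nms_top_n]
        keep = nms(boxes[order], scores[order], self.cfg.rpn_nms_iou)[:top_n]
        sel = order[np.array(keep, dtype=int)]
        return boxes[sel], scores[sel]

    def _train_step(self, img: np.ndarray, labels: InstanceMaskSet, opt: ag.Adam):
        cfg = self.cfg
        net = self.net
        feats = net.pyramid(img)
        logits, deltas = net.rpn(feats)
        anchors_pl = net.level_anchor_boxes(feats)
        anchors = np.concatenate(anchors_pl)
        flat_logits = _concat_vec(logits)
        flat_deltas = _concat_rois(deltas)

        gt = labels.boxes
        losses = {}
        rng = self._rng

        # ---- RPN targets
        if len(gt):
            iou = pairwise_box_iou(anchors, gt)
            best_gt = iou.argmax(axis=1)
            best_iou = iou.max(axis=1)
            pos = best_iou >= cfg.rpn_pos_iou
            pos[iou.argmax(axis=0)] = True  # best anchor per truth box
            neg = (best_iou < cfg.rpn_neg_iou) & ~pos
        else:
            pos = np.zeros(len(anchors), dtype=bool)
            neg = np.ones(len(anchors), dtype=bool)
            best_gt = np.zeros(len(anchors), dtype=int)
        pos_idx = np.flatnonzero(pos)
        neg_idx = np.flatnonzero(neg)
        n_pos = min(len(pos_idx), cfg.rpn_batch // 2)
        if len(pos_idx) > n_pos:
            pos_idx = rng.choice(pos_idx, n_pos, replace=False)
        n_neg = min(len(neg_idx), cfg.rpn_batch - n_pos)
        if len(neg_idx) > n_neg:
            neg_idx = rng.choice(neg_idx, n_neg, replace=False)
        samp = np.concatenate([pos_idx, neg_idx]).astype(np.intp)
        targets = np.zeros(len(samp), dtype=np.float32)
        targets[: len(pos_idx)] = 1.0
        losses["rpn_cls"] = ag.bce_with_logits(
            ag.gather_rows(flat_logits, samp), targets)
        if len(pos_idx):
            dts = _box_to_deltas(anchors[pos_idx], gt[best_gt[pos_idx]])
            losses["rpn_box"] = ag.smooth_l1_loss(
                ag.gather_rows(flat_deltas, pos_idx.astype(np.intp)), dts,
                beta=1.0 / 9.0)

        # ---- proposals (+ truth boxes and jittered copies so the head sees
        # positives at slightly wrong alignments, as it will at test time)
        prop, _ = self._proposals(feats, logits, deltas, anchors_pl,
                                  img.shape, top_n=cfg.post_nms_top_n)
        if len(gt):
            jit = []
            for _ in range(cfg.gt_jitter):
                h = (gt[:, 2] - gt[:, 0])[:, None]
                w = (gt[:, 3] - gt[:, 1])[:, None]
                noise = rng.normal(0, 0.08, size=(len(gt), 4))
                jit.append(gt + noise * np.concatenate([h, w, h, w], axis=1))
            prop = np.concatenate([prop, gt] + jit, axis=0)
            prop = _clip_boxes(prop, img.shape)

        if len(gt):
            iou = pairwise_box_iou(prop, gt)
            best_gt_p = iou.argmax(axis=1)
            best_iou_p = iou.max(axis=1)
            posr = np.flatnonzero(best_iou_p >= cfg.roi_pos_iou)
            negr = np.flatnonzero(best_iou_p < cfg.roi_pos_iou)
            n_pos = min(len(posr), cfg.roi_batch // 2)
            if len(posr) > n_pos:
                posr = rng.choice(posr, n_pos, replace=False)
            n_neg = min(len(negr), cfg.roi_batch - n_pos)
            if len(negr) > n_neg:
                negr = rng.choice(negr, n_neg, replace=False)
            rois = np.concatenate([prop[posr], prop[negr]], axis=0)
            roi_t = np.zeros(len(rois), dtype=np.float32)
            roi_t[: len(posr)] = 1.0
            if len(rois):
                cls, box = net.head(feats, rois)
                losses["head_cls"] = ag.bce_with_logits(cls, roi_t)
                if len(posr):
                    dts = _box_to_deltas(prop[posr], gt[best_gt_p[posr]])
                    losses["head_box"] = ag.smooth_l1_loss(
                        _gather_rois(box, np.arange(len(posr), dtype=np.intp)),
                        dts)
                    # ---- mask loss on positive rois only
                    mlogits = net.mask_head(feats, prop[posr])
                    mt = np.stack([
                        _mask_target(labels.masks[best_gt_p[j]], prop[j],
                                     cfg.mask_out)
                        for j in posr
                    ])
                    losses["mask"] = ag.bce_with_logits(mlogits, mt)

        total = None
        for v in losses.values():
            total = v if total is None else ag.add(total, v)
        if total is None:
            return {}
        opt.zero_grad()
        total.backward()
        opt.step()
        out = {k: float(v.data) for k, v in losses.items()}
        out["total"] = float(total.data)
        return out

    def train(self, patches: list[tuple[np.ndarray, InstanceMaskSet]],
              epochs: int | None = None) -> list[dict]:
        """Optimise on (phase patch, instance labels) pairs.

        Returns the per-epoch loss trace (mean of each loss term).  Raises
        if every label set is empty — there is nothing to learn from pure
        background.
        """
        if not patches:
            raise ValueError("no training patches")
        for img, labels in patches:
            if img.shape != labels.shape:
                raise ValueError(
                    f"patch shape {img.shape} != label grid {labels.shape}")
        if all(len(labels) == 0 for _, labels in patches):
            raise ValueError("all label sets are empty; nothing to learn")
        epochs = self.cfg.epochs if epochs is None else epochs
        opt = ag.Adam(self.net.parameters(), lr=self.cfg.learning_rate)
        n = len(patches)
        for ep in range(epochs):
            order = self._rng.permutation(n)
            sums: dict[str, float] = {}
            counts: dict[str, int] = {}
            for i in order:
                img, labels = patches[i]
                step = self._train_step(_normalize(img), labels, opt)
                for k, v in step.items():
                    sums[k] = sums.get(k, 0.0) + v
                    counts[k] = counts.get(k, 0) + 1
            trace = {k: sums[k] / counts[k] for k in sums}
            trace["epoch"] = ep
            self.loss_trace.append(trace)
        return self.loss_trace

    # ------------------------------------------------------------ predict
    def predict(self, img: np.ndarray, score_threshold: float | None = None
                ) -> list[Detection]:
        """Detections above ``score_threshold`` (default from the config)."""
        cfg = self.cfg
        thr = cfg.score_threshold if score_threshold is None else score_threshold
        orig_shape = img.shape
        img = _normalize(img)
        stride = self.net.strides[-1]
        H = int(np.ceil(img.shape[0] / stride)) * stride
        W = int(np.ceil(img.shape[1] / stride)) * stride
        if (H, W) != img.shape:
            pad = np.zeros((H, W), dtype=img.dtype)
            pad[: img.shape[0], : img.shape[1]] = img
            img = pad
        feats = self.net.pyramid(img)
        logits, deltas = self.net.rpn(feats)
        anchors_pl = self.net.level_anchor_boxes(feats)
        prop, _ = self._proposals(feats, logits, deltas, anchors_pl,
                                  img.shape, top_n=cfg.post_nms_top_n)
        if len(prop) == 0:
            return []
        cls, box = self.net.head(feats, prop)
        scores = ag._sigmoid_np(cls.data)
        keep = np.flatnonzero(scores >= thr)
        if keep.size == 0:
            return []
        refined = _clip_boxes(_deltas_to_box(prop[keep], box.data[keep]),
                              orig_shape)
        scores = scores[keep]
        kept = nms(refined, scores, cfg.nms_iou)
        refined, scores = refined[kept], scores[kept]
        mlogits = self.net.mask_head(feats, refined)
        soft = ag._sigmoid_np(mlogits.data)
        return [Detection(b, float(s), m)
                for b, s, m in zip(refined, scores, soft)]

    # ------------------------------------------------------- persistence
    def save(self, path) -> None:
        path = Path(path).with_suffix(".npz")
        arrays = {k: t.data for k, t in self.net.params.items()}
        np.savez_compressed(path, **arrays)
        cfg = asdict(self.cfg)
        cfg["anchor"] = asdict(self.cfg.anchor)
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(cfg, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path) -> "NucleiDetector":
        path = Path(path)
        if not path.suffix:
            path = path.with_suffix(".npz")
        with open(path.with_suffix(".json")) as fh:
            cfg_d = json.load(fh)
        anchor = AnchorConfig(
            scales=tuple(cfg_d["anchor"]["scales"]),
            aspect_ratios=tuple(cfg_d["anchor"]["aspect_ratios"]),
        )
        cfg_d = {k: v for k, v in cfg_d.items() if k != "anchor"}
        cfg = TrainConfig(anchor=anchor, **cfg_d)
        model = cls(cfg)
        data = np.load(path)
        for k in model.net.params:
            model.net.params[k].data = data[k].astype(np.float32)
        return model


def _normalize(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float32)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def _concat_vec(pieces: list[Tensor]) -> Tensor:
    datas = [p.data for p in pieces]
    out_data = np.concatenate(datas)
    sizes = [d.shape[0] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for p, o0, o1 in zip(pieces, offsets[:-1], offsets[1:]):
            p._accumulate(g[o0:o1])

    return ag._node(out_data, tuple(pieces), backward)


# ------------------------------------------------------- module functions

def train(patches, cfg: TrainConfig | None = None) -> NucleiDetector:
    """Train a fresh :class:`NucleiDetector` on (patch, labels) pairs."""
    model = NucleiDetector(cfg)
    model.train(patches)
    return model


def predict(model: NucleiDetector, img: np.ndarray,
            score_threshold: float | None = None) -> list[Detection]:
    return model.predict(img, score_threshold)
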