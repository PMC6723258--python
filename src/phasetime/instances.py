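"""Instance containers shared across the pipeline.

Conventions used everywhere in this package:

* images are 2-D ``numpy`` arrays indexed ``[row, col]``, 0-based;
* bounding boxes are half-open pixel boxes ``(r0, c0, r1, c1)`` so that
  ``area = (r1 - r0) * (c1 - c0)`` and a 1-px object has a 1x1 box;
* an :class:`InstanceMaskSet` holds one binary mask per instance on a common
  grid, with tight boxes derived from the masks and optional per-instance
  confidence scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from skimage.transform import resize


def box_area(box: np.ndarray) -> float:
    r0, c0, r1, c1 = box
    return max(0.0, float(r1) - float(r0)) * max(0.0, float(c1) - float(c0))


def box_iou(a, b) -> float:
    """Intersection-over-union of two half-open boxes ``(r0, c0, r1, c1)``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if box_area(a) <= 0 or box_area(b) <= 0:
        raise ValueError("box_iou requires boxes with positive area")
    r0 = max(a[0], b[0])
    c0 = max(a[1], b[1])
    r1 = min(a[2], b[2])
    c1 = min(a[3], b[3])
    inter = max(0.0, r1 - r0) * max(0.0, c1 - c0)
    union = box_area(a) + box_area(b) - inter
    return inter / union if union > 0 else 0.0


def pairwise_box_iou(boxes_a: np.ndarray, boxes_b: np.ndarray) -> np.ndarray:
    """Vectorised IoU matrix between two ``(N, 4)`` / ``(M, 4)`` box arrays."""
    a = np.asarray(boxes_a, dtype=float).reshape(-1, 4)
    b = np.asarray(boxes_b, dtype=float).reshape(-1, 4)
    r0 = np.maximum(a[:, None, 0], b[None, :, 0])
    c0 = np.maximum(a[:, None, 1], b[None, :, 1])
    r1 = np.minimum(a[:, None, 2], b[None, :, 2])
    c1 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(r1 - r0, 0, None) * np.clip(c1 - c0, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return iou


def mask_bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    """Tight half-open bounding box of a non-empty binary mask."""
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise ValueError("mask is empty")
    return int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1


class InstanceMaskSet:
    """A set of per-instance binary masks over one ``(H, W)`` grid.

    Masks produced by the label generator are pairwise disjoint; predicted
    sets may carry a confidence ``score`` per instance.
    """

    def __init__(
        self,
        shape: tuple[int, int],
        masks: Sequence[np.ndarray] = (),
        scores: Sequence[float] | None = None,
    ):
        self.shape = (int(shape[0]), int(shape[1]))
        self.masks: list[np.ndarray] = []
        for m in masks:
            m = np.asarray(m, dtype=bool)
            if m.shape != self.shape:
                raise ValueError(
                    f"mask shape {m.shape} != grid shape {self.shape}"
                )
            if not m.any():
                raise ValueError("instance masks must be non-empty")
            self.masks.append(m)
        if scores is not None and len(scores) != len(self.masks):
            raise ValueError("scores length must match number of masks")
        self.scores = None if scores is None else [float(s) for s in scores]

    def __len__(self) -> int:
        return len(self.masks)

    @property
    def boxes(self) -> np.ndarray:
        """Tight half-open boxes, shape ``(N, 4)``."""
        if not self.masks:
            return np.zeros((0, 4), dtype=float)
        return np.array([mask_bbox(m) for m in self.masks], dtype=float)

    @property
    def areas(self) -> np.ndarray:
        return np.array([int(m.sum()) for m in self.masks], dtype=int)

    def to_label_map(self) -> np.ndarray:
        """Integer label image: 0 = background, k = instance k (1-based).

        Later instances overwrite earlier ones on (unexpected) overlaps; label
        maps round-trip losslessly only for disjoint sets.
        """
        out = np.zeros(self.shape, dtype=np.uint16)
        for k, m in enumerate(self.masks, start=1):
            out[m] = k
        return out

    @classmethod
    def from_label_map(cls, labels: np.ndarray) -> "InstanceMaskSet":
        labels = np.asarray(labels)
        ids = np.unique(labels)
        ids = ids[ids > 0]
        return cls(labels.shape, [labels == k for k in ids])

    @classmethod
    def empty(cls, shape: tuple[int, int]) -> "InstanceMaskSet":
        return cls(shape, [])

    def filtered_by_score(self, threshold: float) -> "InstanceMaskSet":
        if self.scores is None:
            raise ValueError("instance set carries no scores")
        keep = [i for i, s in enumerate(self.scores) if s >= threshold]
        return InstanceMaskSet(
            self.shape,
            [self.masks[i] for i in keep],
            [self.scores[i] for i in keep],
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, InstanceMaskSet):
            return NotImplemented
        if self.shape != other.shape or len(self) != len(other):
            return False
        return all(np.array_equal(a, b) for a, b in zip(self.masks, other.masks))


@dataclass
class Detection:
    """One predicted instance: a box, a confidence score and a soft mask.

    ``soft_mask`` is a small float grid in [0, 1] (28x28 by default); the
    pixel-level binary mask is materialised by resizing it to the box and
    thresholding at ``threshold``.
    """

    box: np.ndarray  # (r0, c0, r1, c1), half-open, frame coordinates
    score: float
    soft_mask: np.ndarray = field(default_factory=lambda: np.ones((28, 28)))

    def __post_init__(self):
        self.box = np.asarray(self.box, dtype=float)
        self.soft_mask = np.asarray(self.soft_mask, dtype=float)
        if box_area(self.box) <= 0:
            raise ValueError("Detection box must have positive area")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError("Detection score must lie in [0, 1]")

    def binary_mask(self, shape: tuple[int, int], threshold: float = 0.5) -> np.ndarray:
        """Paste the soft mask into a full-frame boolean mask."""
        out = np.zeros(shape, dtype=bool)
        r0 = int(np.floor(max(self.box[0], 0)))
        c0 = int(np.floor(max(self.box[1], 0)))
        r1 = int(np.ceil(min(self.box[2], shape[0])))
        c1 = int(np.ceil(min(self.box[3], shape[1])))
        if r1 <= r0 or c1 <= c0:
            return out
        soft = resize(
            self.soft_mask, (r1 - r0, c1 - c0), order=1, mode="edge",
            anti_aliasing=False, preserve_range=True,
        )
        out[r0:r1, c0:c1] = soft >= threshold
        return out

    def translated(self, dr: float, dc: float) -> "Detection":
        return Detection(
            self.box + np.array([dr, dc, dr, dc], dtype=float),
            self.score,
            self.soft_mask,
        )


def detections_to_maskset(
    detections: Iterable[Detection],
    shape: tuple[int, int],
    mask_threshold: float = 0.5,
) -> InstanceMaskSet:
    """Materialise detections as a scored :class:`InstanceMaskSet`.

    Detections whose binarised mask is empty inside the frame are dropped.
    """
    masks, scores = [], []
    for det in detections:
        m = det.binary_mask(shape, threshold=mask_threshold)
        if m.any():
            masks.append(m)
            scores.append(det.score)
    return InstanceMaskSet(shape, masks, scores)
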