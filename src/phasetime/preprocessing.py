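"""Geometry between raw frames and the detector.

Raw frames are min-max normalised, upsampled by 2 (bilinear for images,
nearest-neighbour for label maps so instance identities survive), and cut
into fixed-size patches on a row-major grid.  After inference the per-patch
detections are translated back to frame coordinates and de-duplicated with
non-max suppression.

Coordinate conventions: row-major 0-based pixels, half-open boxes.  The
bilinear upsampling aligns corners (output corner samples equal input corner
samples), so affine intensity ramps are reproduced exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .instances import Detection, InstanceMaskSet, pairwise_box_iou

__all__ = ["PatchGrid", "upsample2x", "tile_patches", "extract_patches",
           "crop_labels", "stitch_detections"]


def upsample2x(img: np.ndarray, order: int = 1) -> np.ndarray:
    """Upsample a 2-D array to double size.

    ``order=1`` (default) is corner-aligned bilinear for intensity images;
    ``order=0`` is nearest-neighbour for integer label maps.
    """
    img = np.asarray(img)
    H, W = img.shape
    out_shape = (2 * H, 2 * W)
    if H == 1 and W == 1:
        return np.full(out_shape, img[0, 0], dtype=img.dtype)
    rr = np.linspace(0, H - 1, out_shape[0])
    cc = np.linspace(0, W - 1, out_shape[1])
    grid = np.meshgrid(rr, cc, indexing="ij")
    coords = np.stack([g.ravel() for g in grid])
    out = ndi.map_coordinates(
        img.astype(np.float64 if order else img.dtype),
        coords, order=order, mode="nearest",
    ).reshape(out_shape)
    if order == 0:
        return out.astype(img.dtype)
    return out


def upsample_maskset(labels: InstanceMaskSet) -> InstanceMaskSet:
    lm = labels.to_label_map()
    return InstanceMaskSet.from_label_map(upsample2x(lm, order=0))


@dataclass
class PatchGrid:
    """Row-major grid of fixed-size patch origins covering a frame."""

    frame_shape: tuple[int, int]
    patch_size: int
    stride: int
    origins: list[tuple[int, int]]

    def __len__(self) -> int:
        return len(self.origins)


def _axis_starts(length: int, patch: int, stride: int) -> list[int]:
    starts = list(range(0, length - patch + 1, stride))
    if not starts:
        starts = [0]
    if starts[-1] + patch < length:
        starts.append(length - patch)  # shift last patch to end at the edge
    return starts


def tile_patches(img_shape: tuple[int, int], patch_size: int, stride: int) -> PatchGrid:
    """Patch origins covering the frame; the last row/column is shifted so
    its patch ends exactly at the frame edge."""
    H, W = img_shape
    if stride <= 0:
        raise ValueError(f"stride must be positive, got {stride}")
    if stride > patch_size:
        raise ValueError(
            f"stride {stride} > patch_size {patch_size} would leave "
            "uncovered gaps")
    if patch_size > H or patch_size > W:
        raise ValueError(
            f"patch_size {patch_size} exceeds frame shape {img_shape}; pad first"
        )
    rows = _axis_starts(H, patch_size, stride)
    cols = _axis_starts(W, patch_size, stride)
    origins = [(r, c) for r in rows for c in cols]
    return PatchGrid(frame_shape=(H, W), patch_size=patch_size, stride=stride,
                     origins=origins)


def extract_patches(img: np.ndarray, grid: PatchGrid) -> list[np.ndarray]:
    p = grid.patch_size
    return [img[r : r + p, c : c + p] for (r, c) in grid.origins]


def crop_labels(
    labels: InstanceMaskSet, origin: tuple[int, int], patch_size: int,
    min_inside_fraction: float = 0.5,
) -> InstanceMaskSet:
    """Instance set restricted to one patch.

    Instances clipped by the patch border are kept only if at least
    ``min_inside_fraction`` of their area falls inside the patch.
    """
    r0, c0 = origin
    masks = []
    for m in labels.masks:
        crop = m[r0 : r0 + patch_size, c0 : c0 + patch_size]
        inside = crop.sum()
        if inside == 0:
            continue
        if inside / m.sum() >= min_inside_fraction:
            masks.append(crop)
    return InstanceMaskSet((patch_size, patch_size), masks)


def stitch_detections(
    grid: PatchGrid,
    per_patch: list[list[Detection]],
    nms_iou: float = 0.5,
    downscale2x: bool = False,
) -> list[Detection]:
    """Merge per-patch detections into frame coordinates.

    Boxes are translated by their patch origin; duplicates found in
    overlapping patches are removed by score-ranked NMS at ``nms_iou``.
    With ``downscale2x`` the stitched boxes are halved, mapping back to the
    pre-upsampling raw frame.  Output is sorted by descending score.
    """
    if len(per_patch) != len(grid.origins):
        raise ValueError(
            f"{len(per_patch)} detection lists for {len(grid.origins)} patches"
        )
    p = grid.patch_size
    pool: list[Detection] = []
    for (r0, c0), dets in zip(grid.origins, per_patch):
        for det in dets:
            b = det.box
            if b[0] < -1e-6 or b[1] < -1e-6 or b[2] > p + 1e-6 or b[3] > p + 1e-6:
                raise ValueError(
                    f"detection box {b.tolist()} lies outside its {p}x{p} patch"
                )
            pool.append(det.translated(r0, c0))
    if not pool:
        return []
    order = sorted(range(len(pool)), key=lambda i: -pool[i].score)
    boxes = np.array([pool[i].box for i in order])
    keep: list[int] = []
    for idx in range(len(order)):
        if keep:
            ious = pairwise_box_iou(boxes[idx : idx + 1], boxes[keep])[0]
            if (ious > nms_iou).any():
                continue
        keep.append(idx)
    out = [pool[order[i]] for i in keep]
    if downscale2x:
        out = [Detection(d.box / 2.0, d.score, d.soft_mask) for d in out]
    return out
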