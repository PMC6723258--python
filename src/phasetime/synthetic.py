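"""Seeded synthetic paired fluorescence / phase-contrast scenes.

The generator emulates nanowell time-lapse microscopy frames at desk scale:
a grid of square wells (full-scale wells are ~250 px), each holding a few
ellipsoidal nuclei with full diameters in a configured range (20-60 px at
full scale).  Two registered channels are rendered per scene:

* **fluorescence** — bright, blurred nucleus footprints on a dark
  background.  Each footprint is rendered with a *halo*: the super-threshold
  region systematically extends ``fluor_halo`` pixels beyond the true
  nucleus boundary, which is what makes an interior erosion degree optimal
  when labels are generated from this channel;
* **phase contrast** — low-contrast textured nuclei with faint edges inside
  a darker cell-body outline, plus per-image multiplicative illumination
  gain and Gaussian sensor noise.

Two failure motifs seen in real data can be injected: *touching* nucleus
pairs (one foreground component containing two nuclei) and *cell-body
extensions* (a low-intensity lobe protruding from the cell in the phase
channel only).

Ground truth is exact: per-nucleus ellipse masks with no halo, disjoint by
construction (pixels contested by a touching pair go to the nucleus whose
normalised ellipse distance is smaller).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage as ndi

from .instances import InstanceMaskSet


@dataclass
class NucleusSpec:
    """Parameters of one rendered nucleus."""

    center: tuple[float, float]  # (row, col), px
    axes: tuple[float, float]  # (semi-major, semi-minor), px
    orientation: float  # radians
    fluor_halo: float = 4.0  # extra apparent radius in the fluorescence channel, px
    texture_seed: int = 0
    extension: bool = False  # protruding low-intensity body lobe (phase only)

    def __post_init__(self):
        if self.fluor_halo < 0:
            raise ValueError("fluor_halo must be non-negative")
        if self.axes[0] < self.axes[1]:
            raise ValueError("axes must be (semi-major, semi-minor)")


@dataclass
class SceneConfig:
    """Scene geometry, population and noise model.

    Defaults describe the full-scale imaging conditions: ~250 px nanowells
    and nucleus diameters of 20-60 px.  Desk-scale tests shrink
    ``image_size`` / ``nanowell_size`` / ``diameter_range`` together (see
    :func:`patch_scale_config`).
    """

    image_size: tuple[int, int] = (512, 512)
    nanowell_size: int = 250
    n_nuclei: tuple[int, int] = (1, 3)  # inclusive range per well
    diameter_range: tuple[float, float] = (20.0, 60.0)  # full diameter, px
    fluor_halo: float = 4.0
    fluor_contrast: float = 0.6  # foreground-background intensity gap, [0,1] scale
    fluor_background: float = 0.08
    phase_texture_amp: float = 0.13
    noise_sd: float = 0.02
    illumination_gain: tuple[float, float] = (0.9, 1.1)
    touching_fraction: float = 0.0  # fraction of wells holding a touching pair
    extension_fraction: float = 0.0  # fraction of nuclei with a body lobe
    well_margin: int = 4  # keep-out border inside each well, px
    seed: int = 0

    def __post_init__(self):
        for name in ("touching_fraction", "extension_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.diameter_range[0] > self.diameter_range[1]:
            raise ValueError("diameter_range must be (min, max)")
        if self.n_nuclei[0] > self.n_nuclei[1] or self.n_nuclei[0] < 0:
            raise ValueError("n_nuclei must be a non-negative (lo, hi) range")

    def wells(self) -> list[tuple[int, int, int, int]]:
        """Half-open well boxes tiling the image."""
        H, W = self.image_size
        s = min(self.nanowell_size, H, W)
        out = []
        for r0 in range(0, H - s + 1, s):
            for c0 in range(0, W - s + 1, s):
                out.append((r0, c0, r0 + s, c0 + s))
        return out


def patch_scale_config(seed: int = 0, **overrides) -> SceneConfig:
    """Desk-scale configuration: one 128x128 well, nuclei 12-26 px across.

    Geometry is the full-scale model shrunk ~2x so that whole scenes are
    already detector-patch sized; used throughout the test suite.
    """
    kwargs = dict(
        image_size=(128, 128),
        nanowell_size=128,
        n_nuclei=(1, 3),
        diameter_range=(12.0, 26.0),
        fluor_halo=3.0,
        well_margin=6,
        seed=seed,
    )
    kwargs.update(overrides)
    return SceneConfig(**kwargs)


@dataclass
class SyntheticScene:
    config: SceneConfig
    nuclei: list[NucleusSpec]
    fluor: np.ndarray
    phase: np.ndarray
    truth: InstanceMaskSet


def _ellipse_distance(shape, center, axes, orientation) -> np.ndarray:
    """Normalised ellipse distance: <= 1 inside the nucleus."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    ca, sa = np.cos(orientation), np.sin(orientation)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    a, b = max(axes[0], 1e-6), max(axes[1], 1e-6)
    return np.sqrt((u / a) ** 2 + (v / b) ** 2)


def _sample_nucleus(rng, cfg: SceneConfig, well, extension: bool) -> NucleusSpec:
    r0, c0, r1, c1 = well
    d = rng.uniform(*cfg.diameter_range)
    a = d / 2.0
    b = a * rng.uniform(0.65, 1.0)
    margin = a + cfg.fluor_halo + cfg.well_margin
    if r1 - r0 <= 2 * margin or c1 - c0 <= 2 * margin:
        raise ValueError(
            "nanowell too small for requested diameter_range/fluor_halo: "
            f"well size {r1 - r0}, required margin {margin:.1f} px per side"
        )
    center = (
        rng.uniform(r0 + margin, r1 - margin),
        rng.uniform(c0 + margin, c1 - margin),
    )
    return NucleusSpec(
        center=center,
        axes=(a, b),
        orientation=rng.uniform(0, np.pi),
        fluor_halo=cfg.fluor_halo,
        texture_seed=int(rng.integers(0, 2**31 - 1)),
        extension=extension,
    )


def _place_nuclei(rng, cfg: SceneConfig) -> list[NucleusSpec]:
    nuclei: list[NucleusSpec] = []
    for well in cfg.wells():
        n = int(rng.integers(cfg.n_nuclei[0], cfg.n_nuclei[1] + 1))
        if n == 0:
            continue
        touching = n >= 2 and rng.random() < cfg.touching_fraction
        placed: list[NucleusSpec] = []
        for k in range(n):
            ext = rng.random() < cfg.extension_fraction
            for attempt in range(200):
                cand = _sample_nucleus(rng, cfg, well, ext)
                if touching and k == 1 and placed:
                    # snap the second nucleus against the first: centre
                    # distance just under the sum of mean radii
                    ref = placed[0]
                    ang = rng.uniform(0, 2 * np.pi)
                    gap = 0.95 * (np.mean(ref.axes) + np.mean(cand.axes))
                    center = (
                        ref.center[0] + gap * np.cos(ang),
                        ref.center[1] + gap * np.sin(ang),
                    )
                    r0, c0, r1, c1 = well
                    m = cand.axes[0] + cfg.fluor_halo + cfg.well_margin
                    if not (r0 + m < center[0] < r1 - m and c0 + m < center[1] < c1 - m):
                        continue
                    cand = NucleusSpec(
                        center, cand.axes, cand.orientation,
                        cand.fluor_halo, cand.texture_seed, cand.extension,
                    )
                    placed.append(cand)
                    break
                min_sep = 1.0 if (touching and k == 1) else 1.35
                ok = all(
                    np.hypot(
                        cand.center[0] - o.center[0], cand.center[1] - o.center[1]
                    )
                    > min_sep * (cand.axes[0] + o.axes[0])
                    for o in placed
                )
                if ok:
                    placed.append(cand)
                    break
            else:
                raise ValueError(
                    f"could not place nucleus {k + 1}/{n} in well {well}: "
                    "reduce n_nuclei or diameter_range"
                )
        nuclei.extend(placed)
    return nuclei


def _truth_masks(shape, nuclei: list[NucleusSpec]) -> InstanceMaskSet:
    """Exact ellipse masks, disjoint: contested pixels go to the nearest
    nucleus in normalised ellipse distance."""
    if not nuclei:
        return InstanceMaskSet.empty(shape)
    dist = np.stack(
        [_ellipse_distance(shape, n.center, n.axes, n.orientation) for n in nuclei]
    )
    owner = np.argmin(dist, axis=0)
    inside = dist.min(axis=0) <= 1.0
    masks = []
    for k in range(len(nuclei)):
        m = inside & (owner == k)
        if not m.any():
            raise ValueError(f"nucleus {k} rendered an empty truth mask")
        masks.append(m)
    return InstanceMaskSet(shape, masks)


def _render_fluor(rng, cfg: SceneConfig, nuclei) -> np.ndarray:
    H, W = cfg.image_size
    img = np.full((H, W), cfg.fluor_background, dtype=np.float64)
    for n in nuclei:
        # footprint rendered with the halo-enlarged ellipse, then blurred:
        # the super-threshold region strictly contains the true nucleus
        d = _ellipse_distance(
            (H, W), n.center, (n.axes[0] + n.fluor_halo, n.axes[1] + n.fluor_halo),
            n.orientation,
        )
        # flat plateau with a steep rim: the mid-intensity contour (what Otsu
        # recovers) sits close to the halo-enlarged ellipse boundary
        bump = np.clip((1.0 - d) / 0.12, 0.0, 1.0)
        img += cfg.fluor_contrast * np.clip(bump, 0, 1)
    img = ndi.gaussian_filter(img, 0.8)
    gain = rng.uniform(*cfg.illumination_gain)
    img = gain * img + rng.normal(0.0, cfg.noise_sd, size=(H, W))
    return np.clip(img, 0.0, 1.2)


def _render_phase(rng, cfg: SceneConfig, nuclei) -> np.ndarray:
    H, W = cfg.image_size
    img = np.full((H, W), 0.5, dtype=np.float64)
    for n in nuclei:
        tex_rng = np.random.default_rng(n.texture_seed)
        d_nuc = _ellipse_distance((H, W), n.center, n.axes, n.orientation)
        inside = d_nuc <= 1.0
        # darker cell body slightly larger than the nucleus
        body_axes = (n.axes[0] * 1.45 + 2, n.axes[1] * 1.45 + 2)
        d_body = _ellipse_distance((H, W), n.center, body_axes, n.orientation)
        body = d_body <= 1.0
        img[body] -= 0.06
        if n.extension:
            # low-intensity lobe protruding from the body, not in the truth
            ang = tex_rng.uniform(0, 2 * np.pi)
            off = (
                n.center[0] + 1.2 * body_axes[0] * np.cos(ang),
                n.center[1] + 1.2 * body_axes[1] * np.sin(ang),
            )
            d_lobe = _ellipse_distance(
                (H, W), off, (0.7 * n.axes[0], 0.7 * n.axes[1]), ang
            )
            img[d_lobe <= 1.0] -= 0.05
        # band-passed noise texture inside the nucleus ("dirty" appearance)
        noise = tex_rng.normal(0, 1, size=(H, W))
        band = ndi.gaussian_filter(noise, 1.0) - ndi.gaussian_filter(noise, 3.0)
        band /= max(band.std(), 1e-9)
        img[inside] += cfg.phase_texture_amp * band[inside] + 0.05
        # faint edge ring at the nucleus boundary
        ring = np.abs(d_nuc - 1.0) < 0.12
        img[ring] -= 0.08
    gain = rng.uniform(*cfg.illumination_gain)
    img = gain * img + rng.normal(0.0, cfg.noise_sd, size=(H, W))
    return np.clip(img, 0.0, 1.5)


def simulate_scene(config: SceneConfig) -> SyntheticScene:
    """Render one paired fluorescence/phase scene, deterministic in the seed."""
    rng = np.random.default_rng(config.seed)
    nuclei = _place_nuclei(rng, config)
    truth = _truth_masks(config.image_size, nuclei)
    fluor = _render_fluor(rng, config, nuclei)
    phase = _render_phase(rng, config, nuclei)
    return SyntheticScene(config=config, nuclei=nuclei, fluor=fluor, phase=phase, truth=truth)


def simulate_scenes(config: SceneConfig, n_scenes: int) -> list[SyntheticScene]:
    """Render ``n_scenes`` scenes; scene ``i`` uses a counter-derived seed so
    the whole batch is a deterministic function of ``config.seed``."""
    out = []
    for i in range(n_scenes):
        cfg_i = SceneConfig(**{**asdict(config), "seed": (config.seed + 1) * 100003 + i})
        out.append(simulate_scene(cfg_i))
    return out


def _to_uint16(img: np.ndarray) -> np.ndarray:
    return np.clip(img * 65535.0 / 1.5, 0, 65535).astype(np.uint16)


def write_dataset(
    scenes: list[SyntheticScene], directory, overwrite: bool = False
) -> dict:
    """Write scenes as 16-bit TIFFs plus a JSON manifest.

    Per scene: ``scene_<i>_fluor.tif``, ``scene_<i>_phase.tif`` and an
    integer label-map ``scene_<i>_truth.tif`` (0 = background, k = instance
    k).  Refuses to write into a non-empty directory unless ``overwrite``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if any(directory.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{directory} is not empty; pass overwrite=True to replace it"
        )
    manifest = {"scenes": []}
    for i, scene in enumerate(scenes):
        names = {
            "fluor": f"scene_{i:04d}_fluor.tif",
            "phase": f"scene_{i:04d}_phase.tif",
            "truth": f"scene_{i:04d}_truth.tif",
        }
        tifffile.imwrite(directory / names["fluor"], _to_uint16(scene.fluor))
        tifffile.imwrite(directory / names["phase"], _to_uint16(scene.phase))
        tifffile.imwrite(directory / names["truth"], scene.truth.to_label_map())
        cfg = asdict(scene.config)
        manifest["scenes"].append(
            {"index": i, "files": names, "seed": scene.config.seed,
             "n_nuclei": len(scene.nuclei), "config": cfg}
        )
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def read_truth(directory) -> list[InstanceMaskSet]:
    """Load truth label maps listed in a dataset manifest, in scene order."""
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    out = []
    for entry in manifest["scenes"]:
        labels = tifffile.imread(directory / entry["files"]["truth"])
        out.append(InstanceMaskSet.from_label_map(labels))
    return out
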