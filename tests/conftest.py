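import numpy as np
import pytest

from phasetime import InstanceMaskSet, patch_scale_config, simulate_scene


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic 128x128 scene with three nuclei."""
    return simulate_scene(patch_scale_config(seed=3))


@pytest.fixture(scope="session")
def blank_scene():
    """Background-only scene (no nuclei)."""
    return simulate_scene(patch_scale_config(seed=3, n_nuclei=(0, 0)))


def random_maskset(rng, shape=(32, 32), n_max=6, scored=False) -> InstanceMaskSet:
    """Random disjoint rectangular instances for metric tests."""
    n = int(rng.integers(0, n_max + 1))
    occupied = np.zeros(shape, dtype=bool)
    masks = []
    for _ in range(n):
        for _attempt in range(20):
            h = int(rng.integers(3, 9))
            w = int(rng.integers(3, 9))
            r0 = int(rng.integers(0, shape[0] - h))
            c0 = int(rng.integers(0, shape[1] - w))
            m = np.zeros(shape, dtype=bool)
            m[r0 : r0 + h, c0 : c0 + w] = True
            if not (m & occupied).any():
                occupied |= m
                masks.append(m)
                break
    scores = rng.uniform(0.05, 1.0, size=len(masks)).round(3) if scored else None
    return InstanceMaskSet(shape, masks, scores if scored else None)


def perturbed_predictions(rng, labels: InstanceMaskSet, jitter=2, extra_fp=1):
    """Scored predictions derived from labels by shifting, plus spurious FPs."""
    shape = labels.shape
    masks, scores = [], []
    for m in labels.masks:
        dr = int(rng.integers(-jitter, jitter + 1))
        dc = int(rng.integers(-jitter, jitter + 1))
        shifted = np.roll(np.roll(m, dr, axis=0), dc, axis=1)
        if shifted.any():
            masks.append(shifted)
            scores.append(float(rng.uniform(0.5, 1.0)))
    for _ in range(int(rng.integers(0, extra_fp + 1))):
        m = np.zeros(shape, dtype=bool)
        r0 = int(rng.integers(0, shape[0] - 4))
        c0 = int(rng.integers(0, shape[1] - 4))
        m[r0 : r0 + 4, c0 : c0 + 4] = True
        masks.append(m)
        scores.append(float(rng.uniform(0.05, 0.5)))
    return InstanceMaskSet(shape, masks, scores)
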