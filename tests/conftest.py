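import numpy as np
import pytest

from suaseg import (
    ProbabilityMap,
    SceneSpec,
    ThresholdConfig,
    UncertaintyMap,
    generate_scene,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tcfg():
    return ThresholdConfig()


@pytest.fixture
def small_scene():
    return generate_scene(SceneSpec(seed=11))


def make_pmap(values, slide_id="s"):
    return ProbabilityMap(values=np.asarray(values, dtype=float), slide_id=slide_id)


def make_umap(values, slide_id="s"):
    return UncertaintyMap(values=np.asarray(values, dtype=float), slide_id=slide_id)


def flood_fill_label(mask, connectivity=8):
    """Independent BFS flood-fill labeling oracle (raster-order ids)."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=int)
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    next_id = 0
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and labels[r0, c0] == 0:
                next_id += 1
                queue = [(r0, c0)]
                labels[r0, c0] = next_id
                while queue:
                    r, c = queue.pop()
                    for dr, dc in nbrs:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and labels[rr, cc] == 0:
                            labels[rr, cc] = next_id
                            queue.append((rr, cc))
    return labels
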