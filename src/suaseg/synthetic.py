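"""Synthetic slide bundles with planted false-negative structure.

A scene is a small canvas carrying elliptical "tumor" blobs and background.
Blobs come in three roles:

* ``detected_tumor`` — tumor in the ground truth, fused softmax above the
  positive threshold (the model found it);
* ``fn_candidate`` — tumor in the ground truth (100% of pixels), fused
  softmax strictly inside the NPR band ``(t1, t2)`` with a planted mean
  entropy of roughly ``base_entropy + delta * shift``;
* ``tn_distractor`` — zero tumor pixels, fused softmax inside the same band
  with mean entropy around ``base_entropy``.

The entropy separation ``delta`` (scaled down by the domain-shift knob
``shift``) is what makes FN regions detectable; ``delta = 0`` yields
statistically indistinguishable FN/TN regions. Ensemble disagreement is
simulated by per-member offsets that are exactly mean-centered, so the
fused map equals the designed target and all planted guarantees hold by
construction. All randomness flows through one generator seeded from the
spec; no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation
from scipy.optimize import brentq
from skimage import draw

from .errors import CapacityError, InvalidConfigError
from .heatmap import EnsembleStack, write_slide_bundle

__all__ = [
    "SceneSpec",
    "PlantedRegion",
    "SyntheticScene",
    "generate_scene",
    "scene_to_fixture",
    "ROLE_DETECTED",
    "ROLE_FN",
    "ROLE_TN",
]

ROLE_DETECTED = "detected_tumor"
ROLE_FN = "fn_candidate"
ROLE_TN = "tn_distractor"

_EDGE_MARGIN = 0.01  # keep fused targets this far inside (t1, t2)


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic slide."""

    height: int = 96
    width: int = 96
    n_tumor_blobs: int = 6
    fn_blob_fraction: float = 0.5
    k_members: int = 5
    delta: float = 0.3
    shift: float = 1.0
    background_npr_rate: float = 4.0
    noise_sd: float = 0.05
    blob_entropy_sd: float = 0.03
    base_entropy: float = 0.33
    t1: float = 0.55
    t2: float = 0.95
    seed: int = 0
    slide_id: str = "slide_0000"

    def __post_init__(self):
        if self.height < 16 or self.width < 16:
            raise InvalidConfigError("canvas must be at least 16x16")
        if self.n_tumor_blobs < 0 or self.background_npr_rate < 0:
            raise InvalidConfigError("blob counts must be non-negative")
        if not (0.0 <= self.fn_blob_fraction <= 1.0):
            raise InvalidConfigError("fn_blob_fraction must lie in [0, 1]")
        if self.k_members < 1:
            raise InvalidConfigError("k_members must be >= 1")
        if self.delta < 0 or not (0.0 <= self.shift <= 1.0):
            raise InvalidConfigError("delta must be >= 0 and shift in [0, 1]")
        if not (0.0 <= self.t1 < self.t2 <= 1.0):
            raise InvalidConfigError("need 0 <= t1 < t2 <= 1")


@dataclass(frozen=True)
class PlantedRegion:
    blob_id: int
    role: str
    pixels: np.ndarray  # (n, 2) row/col
    target_entropy: float
    fused_target: float

    @property
    def n_pixels(self) -> int:
        return int(self.pixels.shape[0])


@dataclass(frozen=True)
class SyntheticScene:
    stack: EnsembleStack
    gt_mask: np.ndarray
    planted_regions: List[PlantedRegion]
    spec: SceneSpec


def _binary_entropy(p: float) -> float:
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return -(p * np.log(p) + (1.0 - p) * np.log(1.0 - p))


def _prob_for_entropy(e: float) -> float:
    """Probability p > 0.5 with binary entropy e (decreasing branch)."""
    if e >= np.log(2.0):
        return 0.5
    if e <= 0.0:
        return 1.0
    return float(brentq(lambda p: _binary_entropy(p) - e, 0.5, 1.0 - 1e-12))


def _place_blobs(
    rng: np.random.Generator, n: int, height: int, width: int
) -> List[np.ndarray]:
    """Place n non-overlapping ellipses; 2-pixel Chebyshev gap so blobs can
    never merge under 8-connectivity."""
    occupancy = np.zeros((height, width), dtype=bool)
    struct = np.ones((3, 3), dtype=bool)
    blobs = []
    max_tries = 400
    for _ in range(n):
        for attempt in range(max_tries):
            a = rng.uniform(2.5, 6.5)
            b = rng.uniform(2.5, 6.5)
            theta = rng.uniform(0.0, np.pi)
            pad = a + b + 2
            if height - pad <= pad or width - pad <= pad:
                continue  # blob too large for this canvas; counts as a failed try
            r0 = rng.uniform(pad, height - pad)
            c0 = rng.uniform(pad, width - pad)
            rows, cols = draw.ellipse(r0, c0, a, b, shape=(height, width), rotation=theta)
            if rows.size < 4:
                continue
            footprint = np.zeros((height, width), dtype=bool)
            footprint[rows, cols] = True
            grown = binary_dilation(footprint, structure=struct, iterations=2)
            if np.any(grown & occupancy):
                continue
            occupancy |= grown
            blobs.append(np.stack([rows, cols], axis=1))
            break
        else:
            raise CapacityError(
                f"could not place blob {len(blobs) + 1} of {n} on a "
                f"{height}x{width} canvas after {max_tries} attempts"
            )
    return blobs


def generate_scene(spec: SceneSpec) -> SyntheticScene:
    """Render one deterministic synthetic scene from its spec."""
    rng = np.random.default_rng(spec.seed)
    n_fn = int(round(spec.fn_blob_fraction * spec.n_tumor_blobs))
    n_det = spec.n_tumor_blobs - n_fn
    n_tn = int(round(spec.background_npr_rate))
    blobs = _place_blobs(rng, n_fn + n_det + n_tn, spec.height, spec.width)
    roles = [ROLE_FN] * n_fn + [ROLE_DETECTED] * n_det + [ROLE_TN] * n_tn

    # fused-target band for NPR blobs, kept strictly inside (t1, t2) and on
    # the decreasing branch of the entropy curve
    p_lo = max(spec.t1 + _EDGE_MARGIN, 0.505)
    p_hi = spec.t2 - _EDGE_MARGIN
    if p_lo >= p_hi:
        raise InvalidConfigError("(t1, t2) band too narrow for scene generation")
    e_lo = _binary_entropy(p_hi) + 1e-4
    e_hi = _binary_entropy(p_lo) - 1e-4

    # background stays well below t1
    bg_hi = max(spec.t1 - 0.15, 0.5 * spec.t1)
    fused = np.clip(rng.normal(0.08, 0.03, size=(spec.height, spec.width)), 0.0, bg_hi)

    gt_mask = np.zeros((spec.height, spec.width), dtype=np.uint8)
    planted: List[PlantedRegion] = []
    for blob_id, (coords, role) in enumerate(zip(blobs, roles), start=1):
        rows, cols = coords[:, 0], coords[:, 1]
        if role == ROLE_DETECTED:
            target_e = 0.0
            target_p = float(rng.uniform(spec.t2 + 0.005, min(1.0, spec.t2 + 0.04)))
            fused[rows, cols] = np.clip(
                target_p + rng.normal(0.0, spec.noise_sd / 2, size=rows.size),
                spec.t2 + 0.003,
                1.0,
            )
            gt_mask[rows, cols] = 1
        else:
            e_mean = spec.base_entropy
            if role == ROLE_FN:
                e_mean = e_mean + spec.delta * spec.shift
                gt_mask[rows, cols] = 1
            target_e = float(np.clip(rng.normal(e_mean, spec.blob_entropy_sd), e_lo, e_hi))
            target_p = _prob_for_entropy(target_e)
            fused[rows, cols] = np.clip(
                target_p + rng.normal(0.0, spec.noise_sd, size=rows.size), p_lo, p_hi
            )
        planted.append(
            PlantedRegion(
                blob_id=blob_id,
                role=role,
                pixels=coords,
                target_entropy=target_e,
                fused_target=target_p,
            )
        )

    members = _split_into_members(rng, fused, spec)
    stack = EnsembleStack(members=members, slide_id=spec.slide_id)
    return SyntheticScene(stack=stack, gt_mask=gt_mask, planted_regions=planted, spec=spec)


def _split_into_members(
    rng: np.random.Generator, fused: np.ndarray, spec: SceneSpec
) -> np.ndarray:
    """Per-member maps whose exact mean is the fused target.

    Member deviations (a global per-member offset plus per-pixel noise) are
    mean-centered across members, then scaled down wherever they would leave
    [0, 1], which preserves the zero mean.
    """
    k = spec.k_members
    if k == 1:
        return fused[None, ...].astype(np.float32).astype(np.float64)
    dev = rng.normal(0.0, spec.noise_sd, size=(k,) + fused.shape)
    dev += rng.normal(0.0, 0.04, size=(k, 1, 1))  # member-wide bias
    dev -= dev.mean(axis=0, keepdims=True)
    limit = np.minimum(fused, 1.0 - fused)
    peak = np.abs(dev).max(axis=0)
    scale = np.where(peak > limit, limit / np.maximum(peak, 1e-12), 1.0)
    members = fused[None, ...] + dev * scale[None, ...]
    # round to float32 so on-disk fixtures round-trip bit-exactly
    return np.clip(members, 0.0, 1.0).astype(np.float32).astype(np.float64)


def scene_to_fixture(scene: SyntheticScene, out_dir) -> Path:
    """Write the scene as a slide bundle plus a truth CSV of planted regions.

    Layout: ``<out_dir>/<slide_id>/{stack.tif, gt.png, layout.json,
    truth_regions.csv}``. Returns the slide directory.
    """
    out_dir = Path(out_dir)
    slide_dir = out_dir / scene.spec.slide_id
    write_slide_bundle(slide_dir, scene.stack, mask=scene.gt_mask)
    truth_frame(scene).to_csv(slide_dir / "truth_regions.csv", index=False)
    return slide_dir


def truth_frame(scene: SyntheticScene) -> pd.DataFrame:
    """Planted-region truth table, one row per blob."""
    rows = []
    for reg in scene.planted_regions:
        rows.append(
            {
                "slide_id": scene.spec.slide_id,
                "blob_id": reg.blob_id,
                "role": reg.role,
                "n_pixels": reg.n_pixels,
                "center_row": float(reg.pixels[:, 0].mean()),
                "center_col": float(reg.pixels[:, 1].mean()),
                "target_entropy": reg.target_entropy,
                "fused_target": reg.fused_target,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "slide_id",
            "blob_id",
            "role",
            "n_pixels",
            "center_row",
            "center_col",
            "target_entropy",
            "fused_target",
        ],
    )
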