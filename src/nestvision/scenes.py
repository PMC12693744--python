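"""Seeded synthetic cage scenes and inspection cycles with ground truth.

The generator emulates the statistical structure the inspection system
assumes, not farm photorealism: a flat nest background crossed by a dark
wire grid, 0-6 light egg ellipses with mild shading, a rendered EAN-13 cage
label at roughly 2:1 backing aspect, optional salt-and-pepper noise, and
3-frame cycles in which the whole nest is transiently occluded per frame
with probability ``p_occlude`` (a pigeon body covering the eggs) while egg
centers drift by a few pixels between frames.

Default frame size is 1920x1080; :meth:`SceneSpec.scaled` shrinks every
geometric quantity proportionally for fast desk-scale tests.  A single seed
drives layout, noise and occlusion through independent sub-streams, so the
layout is comparable across occlusion settings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
import numpy as np

from .barcode import render_ean13
from .codes import DEFAULT_PREFIX, PositionCode, embed_in_ean13
from .detector import DetectorConfig
from .geometry import Box

__all__ = [
    "SceneSpec",
    "SceneTruth",
    "CycleSpec",
    "PlacementError",
    "render_scene",
    "render_cycle",
    "sample_occlusion_flags",
    "detector_config_for",
]


class PlacementError(RuntimeError):
    """Egg placement infeasible within the retry budget."""


@dataclass(frozen=True)
class SceneSpec:
    width: int = 1920
    height: int = 1080
    n_eggs: int = 2
    egg_long_px: tuple[float, float] = (26.0, 40.0)  # long half-axis range
    egg_ratio: tuple[float, float] = (1.1, 1.6)  # long/short axis ratio range
    egg_albedo: tuple[int, int] = (205, 235)
    background_gray: int = 90
    wire_pitch: int = 120
    wire_thickness: int = 3
    wire_gray: int = 40
    position: PositionCode = field(default_factory=lambda: PositionCode(1, 1, 21, 4))
    prefix: str = DEFAULT_PREFIX
    module_px: int = 4
    quiet_modules: int = 11
    noise_density: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_eggs <= 6:
            raise ValueError("n_eggs must lie in [0, 6]")
        if not 0.0 <= self.noise_density <= 1.0:
            raise ValueError("noise_density must lie in [0, 1]")

    def scaled(self, s: float) -> "SceneSpec":
        """Proportionally smaller (or larger) scene for fast tests."""
        return replace(
            self,
            width=int(round(self.width * s)),
            height=int(round(self.height * s)),
            egg_long_px=(self.egg_long_px[0] * s, self.egg_long_px[1] * s),
            wire_pitch=max(int(round(self.wire_pitch * s)), 8),
            wire_thickness=max(int(round(self.wire_thickness * s)), 1),
            module_px=max(int(round(self.module_px * s)), 2),
        )


@dataclass
class SceneTruth:
    egg_boxes: list[Box]
    uid: str
    label_box: Box
    occluded: list[bool] = field(default_factory=list)


@dataclass(frozen=True)
class CycleSpec:
    scene: SceneSpec = field(default_factory=SceneSpec)
    n_frames: int = 3
    interval: float = 10.0
    p_occlude: float = 0.0
    egg_jitter: float = 8.0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not 0.0 <= self.p_occlude <= 1.0:
            raise ValueError("p_occlude must lie in [0, 1]")


def detector_config_for(spec: SceneSpec) -> DetectorConfig:
    """Reference-detector thresholds matched to the spec's egg geometry."""
    a_min, a_max = spec.egg_long_px
    r_min, r_max = spec.egg_ratio
    area_min = math.pi * a_min * (a_min / r_max)
    area_max = math.pi * a_max * (a_max / r_min)
    return DetectorConfig(
        min_area=0.5 * area_min,
        max_area=2.0 * area_max,
        axis_ratio_max=r_max + 0.3,
    )


# --------------------------------------------------------------------------
# layout and rasterisation


def _label_geometry(spec: SceneSpec) -> tuple[int, int, np.ndarray]:
    """(x0, y0, label raster) of the cage label, placed top-right."""
    code = embed_in_ean13(spec.position, spec.prefix)
    label = render_ean13(code, spec.module_px, quiet_modules=spec.quiet_modules)
    lh, lw = label.shape
    if lw + 40 > spec.width or lh + 32 > spec.height:
        raise PlacementError("scene too small for the cage label")
    return spec.width - lw - 40, 16, label


def _sample_eggs(spec: SceneSpec, rng: np.random.Generator, y_top: int) -> list[dict]:
    """Rejection-sample non-overlapping egg ellipses below the label band."""
    eggs: list[dict] = []
    margin = 10
    for _ in range(spec.n_eggs):
        for attempt in range(300):
            a = rng.uniform(*spec.egg_long_px)
            ratio = rng.uniform(*spec.egg_ratio)
            b = a / ratio
            theta = rng.uniform(0.0, math.pi)
            cx = rng.uniform(a + margin, spec.width - a - margin)
            cy = rng.uniform(y_top + a + margin, spec.height - a - margin)
            albedo = rng.uniform(*spec.egg_albedo)
            # Chebyshev separation keeps the axis-aligned truth boxes disjoint
            if all(
                max(abs(cx - e["cx"]), abs(cy - e["cy"])) > a + e["a"] + 6
                for e in eggs
            ):
                eggs.append(dict(cx=cx, cy=cy, a=a, b=b, theta=theta, albedo=albedo))
                break
        else:
            raise PlacementError("could not place all eggs without overlap")
    return eggs


def _egg_box(e: dict) -> Box:
    ex = math.sqrt(e["a"] ** 2 * math.cos(e["theta"]) ** 2 + e["b"] ** 2 * math.sin(e["theta"]) ** 2)
    ey = math.sqrt(e["a"] ** 2 * math.sin(e["theta"]) ** 2 + e["b"] ** 2 * math.cos(e["theta"]) ** 2)
    return Box(e["cx"] - ex, e["cy"] - ey, e["cx"] + ex, e["cy"] + ey)


def _draw_ellipse(gray: np.ndarray, e: dict, albedo: float | None = None, shade: float = 20.0) -> None:
    h, w = gray.shape
    a, b, theta = e["a"], e["b"], e["theta"]
    val = e["albedo"] if albedo is None else albedo
    r = int(math.ceil(max(a, b))) + 1
    cx, cy = e["cx"], e["cy"]
    x0, x1 = max(int(cx) - r, 0), min(int(cx) + r + 1, w)
    y0, y1 = max(int(cy) - r, 0), min(int(cy) + r + 1, h)
    ys, xs = np.mgrid[y0:y1, x0:x1]
    dx, dy = xs - cx, ys - cy
    u = (dx * math.cos(theta) + dy * math.sin(theta)) / a
    v = (-dx * math.sin(theta) + dy * math.cos(theta)) / b
    q = u * u + v * v
    mask = q <= 1.0
    gray[y0:y1, x0:x1][mask] = np.clip(val - shade * q[mask], 0, 255)


def _render_frame(
    spec: SceneSpec,
    eggs: list[dict],
    occluded: bool,
    noise_rng: np.random.Generator,
) -> np.ndarray:
    gray = np.full((spec.height, spec.width), spec.background_gray, dtype=float)
    # wire grid behind the eggs
    for x in range(0, spec.width, spec.wire_pitch):
        gray[:, x : x + spec.wire_thickness] = spec.wire_gray
    for y in range(0, spec.height, spec.wire_pitch):
        gray[y : y + spec.wire_thickness, :] = spec.wire_gray

    egg_mask = np.zeros_like(gray, dtype=bool)
    for e in eggs:
        before = gray.copy()
        _draw_ellipse(gray, e)
        egg_mask |= gray != before

    lx, ly, label = _label_geometry(spec)
    gray[ly : ly + label.shape[0], lx : lx + label.shape[1]] = label

    if occluded and eggs:
        xs = [e["cx"] for e in eggs]
        ys = [e["cy"] for e in eggs]
        pad = max(e["a"] for e in eggs) + 30.0
        blob = dict(
            cx=float(np.mean(xs)),
            cy=float(np.mean(ys)),
            a=(max(xs) - min(xs)) / 2 + pad,
            b=(max(ys) - min(ys)) / 2 + pad,
            theta=0.0,
            albedo=160.0,
        )
        _draw_ellipse(gray, blob, shade=10.0)

    rgb = np.repeat(gray[:, :, None], 3, axis=2)
    # eggs carry a slight warm tint; luminance is preserved to ~1 gray level
    rgb[..., 0][egg_mask] = np.clip(rgb[..., 0][egg_mask] + 6, 0, 255)
    rgb[..., 2][egg_mask] = np.clip(rgb[..., 2][egg_mask] - 14, 0, 255)

    if spec.noise_density > 0:
        n = int(round(spec.noise_density * spec.width * spec.height))
        if n > 0:
            flat = noise_rng.choice(spec.width * spec.height, size=n, replace=False)
            rr, cc = np.unravel_index(flat, (spec.height, spec.width))
            salt = noise_rng.random(n) < 0.5
            rgb[rr[salt], cc[salt], :] = 255
            rgb[rr[~salt], cc[~salt], :] = 0
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


# --------------------------------------------------------------------------
# public operations


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, SceneTruth]:
    """One frame plus ground truth; bit-identical for identical specs."""
    ss = np.random.SeedSequence(spec.seed)
    layout_seed, noise_seed = ss.spawn(2)
    lx, ly, label = _label_geometry(spec)
    eggs = _sample_eggs(spec, np.random.default_rng(layout_seed), ly + label.shape[0])
    img = _render_frame(spec, eggs, occluded=False, noise_rng=np.random.default_rng(noise_seed))
    truth = SceneTruth(
        egg_boxes=[_egg_box(e) for e in eggs],
        uid=spec.position.uid,
        label_box=Box(lx, ly, lx + label.shape[1], ly + label.shape[0]),
        occluded=[False],
    )
    return img, truth


def sample_occlusion_flags(
    p_occlude: float, n_frames: int, n_cycles: int, seed: int
) -> np.ndarray:
    """(n_cycles, n_frames) Bernoulli occlusion draws — the same per-frame
    interference model render_cycle applies to images."""
    rng = np.random.default_rng(seed)
    return rng.random((n_cycles, n_frames)) < p_occlude


def render_cycle(cyc: CycleSpec) -> tuple[list[np.ndarray], SceneTruth, list[bool]]:
    """N frames of one nest: shared layout, per-frame jitter and occlusion."""
    spec = cyc.scene
    ss = np.random.SeedSequence(spec.seed)
    layout_seed, occl_seed, frame_seed = ss.spawn(3)
    lx, ly, label = _label_geometry(spec)
    eggs = _sample_eggs(spec, np.random.default_rng(layout_seed), ly + label.shape[0])
    occl_rng = np.random.default_rng(occl_seed)
    occluded = (occl_rng.random(cyc.n_frames) < cyc.p_occlude).tolist()
    frame_rngs = [np.random.default_rng(s) for s in frame_seed.spawn(cyc.n_frames)]

    frames = []
    for i in range(cyc.n_frames):
        rng = frame_rngs[i]
        jittered = []
        for e in eggs:
            je = dict(e)
            je["cx"] = float(np.clip(e["cx"] + rng.uniform(-cyc.egg_jitter, cyc.egg_jitter), e["a"], spec.width - e["a"]))
            je["cy"] = float(np.clip(e["cy"] + rng.uniform(-cyc.egg_jitter, cyc.egg_jitter), ly + label.shape[0] + e["a"], spec.height - e["a"]))
            jittered.append(je)
        frames.append(_render_frame(spec, jittered, occluded[i], rng))

    truth = SceneTruth(
        egg_boxes=[_egg_box(e) for e in eggs],
        uid=spec.position.uid,
        label_box=Box(lx, ly, lx + label.shape[1], ly + label.shape[0]),
        occluded=occluded,
    )
    return frames, truth, occluded
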