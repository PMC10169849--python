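"""Synthetic endoscopy-like phantoms with known ground truth.

Each phantom frame carries an elliptical "lesion" whose texture has a
class-distinct dominant spatial frequency and base chroma, over a fifth
background texture, loosely mimicking how NBI surface and vessel pattern
granularity changes across histologic grades. A smooth low-frequency
illumination component underlies every texture so that defocus (Gaussian
blur of a designated region) measurably shifts spectral energy below the
high-pass cutoff. Blackout and halation blobs are rendered at
threshold-violating constant values (red 20, green 255) so the quality
module recovers them pixel-exactly; all other pixels are clipped to
[55, 245] and can never trip either threshold.

The phantoms are deliberately strongly separable so that small CPU-scale
classifiers succeed; photorealism is a non-goal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .types import AnnotatedImage, QualityMasks

FRAME_SIZE = (384, 384)  # 9 x 9 patch grid at 128/32

#: (dominant texture period px, base RGB) per class 0 (background) .. 4 (SMd).
CLASS_TEXTURES = {
    0: (24.0, (150, 110, 90)),
    1: (16.0, (110, 150, 100)),
    2: (10.0, (150, 140, 80)),
    3: (6.0, (140, 100, 150)),
    4: (4.0, (110, 120, 160)),
}

PIXEL_LOW, PIXEL_HIGH = 55, 245  # non-artifact pixel range
BLACKOUT_VALUE = (20, 20, 20)  # red 20 < 50
HALATION_VALUE = (255, 255, 255)  # green 255 > 250


@dataclass(frozen=True)
class Ellipse:
    center: tuple[float, float]  # (row, col)
    axes: tuple[float, float]  # semi-axes (row, col) before rotation
    angle: float = 0.0  # radians

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        dr = rr - self.center[0]
        dc = cc - self.center[1]
        cos, sin = np.cos(self.angle), np.sin(self.angle)
        u = dr * cos + dc * sin
        v = -dr * sin + dc * cos
        return (u / self.axes[0]) ** 2 + (v / self.axes[1]) ** 2 <= 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to render one phantom frame deterministically."""

    image_size: tuple[int, int] = FRAME_SIZE
    lesion: Ellipse = Ellipse(center=(192.0, 192.0), axes=(90.0, 100.0))
    lesion_label: int = 1
    texture_amplitude: float = 25.0
    illumination_amplitude: float = 25.0
    illumination_period: float = 128.0
    noise_sigma: float = 2.0
    n_blackout: int = 2
    blackout_radius: tuple[float, float] = (16.0, 40.0)
    n_halation: int = 1
    halation_radius: tuple[float, float] = (10.0, 24.0)
    blur_sigma: float = 12.0
    blur_region: Optional[tuple[int, int, int, int]] = None  # (r0, c0, r1, c1)
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h <= 0 or w <= 0:
            raise ValueError("frame dimensions must be positive")
        if self.lesion_label not in (1, 2, 3, 4):
            raise ValueError(f"lesion label {self.lesion_label} not in 1-4")
        cr, cc = self.lesion.center
        ar, ac = self.lesion.axes
        reach = max(ar, ac)
        if min(ar, ac) <= 0:
            raise ValueError("lesion axes must be positive")
        if cr - reach < 0 or cc - reach < 0 or cr + reach >= h or cc + reach >= w:
            raise ValueError("lesion must lie strictly inside the frame")


def _texture(
    shape: tuple[int, int], period: float, amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Sum of two randomly oriented sinusoids at the class period."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
    out = np.zeros(shape, dtype=np.float64)
    for _ in range(2):
        theta = rng.uniform(0.0, 2 * np.pi)
        phase = rng.uniform(0.0, 2 * np.pi)
        out += np.sin(
            2 * np.pi / period * (cc * np.cos(theta) + rr * np.sin(theta)) + phase
        )
    return out * (amplitude / 2.0)


def _disk(shape, center, radius) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def generate_image(
    spec: PhantomSpec, image_id: str = "phantom", lesion_id: Optional[str] = None
) -> tuple[AnnotatedImage, QualityMasks]:
    """Render one phantom plus the ground-truth artifact masks."""
    h, w = spec.image_size
    rng = np.random.default_rng(spec.seed)
    lesion_mask = spec.lesion.mask((h, w))

    frame = np.empty((h, w, 3), dtype=np.float64)
    illum = _texture((h, w), spec.illumination_period, spec.illumination_amplitude, rng)
    bg_period, bg_rgb = CLASS_TEXTURES[0]
    le_period, le_rgb = CLASS_TEXTURES[spec.lesion_label]
    bg_tex = _texture((h, w), bg_period, spec.texture_amplitude, rng)
    le_tex = _texture((h, w), le_period, spec.texture_amplitude, rng)
    for ch in range(3):
        frame[..., ch] = np.where(
            lesion_mask, le_rgb[ch] + le_tex, bg_rgb[ch] + bg_tex
        ) + illum
    frame += rng.normal(0.0, spec.noise_sigma, size=(h, w, 3))
    frame = np.clip(frame, PIXEL_LOW, PIXEL_HIGH)

    if spec.blur_region is not None and spec.blur_sigma > 0:
        r0, c0, r1, c1 = spec.blur_region
        blurred = gaussian_filter(frame, sigma=(spec.blur_sigma, spec.blur_sigma, 0))
        region = np.zeros((h, w), dtype=bool)
        region[max(r0, 0) : min(r1, h), max(c0, 0) : min(c1, w)] = True
        frame[region] = blurred[region]

    blackout = np.zeros((h, w), dtype=bool)
    for _ in range(spec.n_blackout):
        center = (rng.uniform(0, h), rng.uniform(0, w))
        radius = rng.uniform(*spec.blackout_radius)
        blackout |= _disk((h, w), center, radius)
    halation = np.zeros((h, w), dtype=bool)
    for _ in range(spec.n_halation):
        center = (rng.uniform(0, h), rng.uniform(0, w))
        radius = rng.uniform(*spec.halation_radius)
        halation |= _disk((h, w), center, radius)
    halation &= ~blackout  # blackout stamped last wins overlaps
    pixels = frame.round().astype(np.uint8)
    pixels[blackout] = BLACKOUT_VALUE
    pixels[halation] = HALATION_VALUE

    image = AnnotatedImage(
        image_id=image_id,
        pixels=pixels,
        lesion_mask=lesion_mask,
        label=spec.lesion_label,
        lesion_id=lesion_id or image_id,
    )
    truth = QualityMasks(
        blackout=blackout, halation=halation, effective=~blackout & ~halation
    )
    return image, truth


@dataclass
class PhantomSet:
    """A generated cohort: images, their labels, and the spec they came from."""

    images: list[AnnotatedImage]
    truth: dict[str, int]
    base_spec: PhantomSpec
    seed: int

    def __len__(self) -> int:
        return len(self.images)


def _random_lesion(rng: np.random.Generator, frame: tuple[int, int]) -> Ellipse:
    h, w = frame
    axes = (rng.uniform(60.0, 105.0), rng.uniform(60.0, 105.0))
    reach = max(axes) + 2.0
    center = (rng.uniform(reach, h - reach - 1), rng.uniform(reach, w - reach - 1))
    return Ellipse(center=center, axes=axes, angle=rng.uniform(0.0, np.pi))


def _random_blur_region(
    rng: np.random.Generator, frame: tuple[int, int]
) -> tuple[int, int, int, int]:
    h, w = frame
    rh = int(rng.uniform(128, 224))
    rw = int(rng.uniform(128, 224))
    r0 = int(rng.uniform(0, h - rh))
    c0 = int(rng.uniform(0, w - rw))
    return (r0, c0, r0 + rh, c0 + rw)


def generate_set(
    n_per_class: Sequence[int],
    base_spec: PhantomSpec = PhantomSpec(),
    seed: int = 0,
    blur: bool = True,
) -> PhantomSet:
    """``n_per_class[i]`` phantoms of label i+1 with randomized lesion
    geometry and artifact placement; reproducible per seed."""
    if len(n_per_class) != 4:
        raise ValueError("n_per_class must give counts for labels 1-4")
    root = np.random.SeedSequence(seed)
    images: list[AnnotatedImage] = []
    truth: dict[str, int] = {}
    for label, count in zip((1, 2, 3, 4), n_per_class):
        if count < 0:
            raise ValueError("phantom counts must be nonnegative")
        for idx in range(count):
            child = root.spawn(1)[0]
            rng = np.random.default_rng(child)
            image_seed = int(rng.integers(0, 2**31 - 1))
            spec = replace(
                base_spec,
                lesion=_random_lesion(rng, base_spec.image_size),
                lesion_label=label,
                blur_region=(
                    _random_blur_region(rng, base_spec.image_size) if blur else None
                ),
                seed=image_seed,
            )
            image_id = f"ph{label}_{idx:03d}"
            image, _ = generate_image(spec, image_id=image_id)
            images.append(image)
            truth[image_id] = label
    return PhantomSet(images=images, truth=truth, base_spec=base_spec, seed=seed)


def artifact_free(base_spec: PhantomSpec = PhantomSpec()) -> PhantomSpec:
    """A spec variant with no blackout, halation or defocus injection."""
    return replace(base_spec, n_blackout=0, n_halation=0, blur_region=None)
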