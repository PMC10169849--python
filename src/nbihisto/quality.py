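"""Pictorial quality control: blackout, halation, effective region, focus.

NBI stills routinely contain unusable regions — near-black sensor shadow or
frame border ("blackout") and specular saturation ("halation") — plus
out-of-focus areas. Blackout and halation are detected by fixed per-pixel
intensity thresholds (red < 50, green > 250 on 8-bit channels); focus is
scored as the fraction of a patch's non-DC spectral energy above a radial
high-pass cutoff expressed as a fraction of the Nyquist frequency.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .types import (
    ChannelError,
    ConfigurationError,
    FocusScore,
    QualityMasks,
    ShapeError,
    ensure_rgb,
)

BLACKOUT_RED_BELOW = 50
HALATION_GREEN_ABOVE = 250
DEFAULT_CUTOFF = 0.0625  # fraction of Nyquist
DEFAULT_FOCUS_THRESHOLD = 0.02
DEFAULT_FOCUS_CHANNEL = 1  # green carries the dominant NBI signal


def blackout_mask(image: np.ndarray, red_below: int = BLACKOUT_RED_BELOW) -> np.ndarray:
    """Pixels whose red component is strictly below ``red_below``."""
    arr = ensure_rgb(image)
    return arr[..., 0] < red_below


def halation_mask(
    image: np.ndarray, green_above: int = HALATION_GREEN_ABOVE
) -> np.ndarray:
    """Pixels whose green component is strictly above ``green_above``."""
    arr = ensure_rgb(image)
    return arr[..., 1] > green_above


def effective_mask(
    image: np.ndarray,
    roi: Optional[np.ndarray] = None,
    red_below: int = BLACKOUT_RED_BELOW,
    green_above: int = HALATION_GREEN_ABOVE,
) -> QualityMasks:
    """Usable area: the ROI (full frame when absent) minus blackout and halation."""
    arr = ensure_rgb(image)
    black = blackout_mask(arr, red_below)
    hal = halation_mask(arr, green_above)
    if roi is None:
        base = np.ones(arr.shape[:2], dtype=bool)
    else:
        base = np.asarray(roi, dtype=bool)
        if base.shape != arr.shape[:2]:
            raise ShapeError(
                f"ROI shape {base.shape} does not match image {arr.shape[:2]}"
            )
    return QualityMasks(
        blackout=black, halation=hal, effective=base & ~black & ~hal
    )


def _radial_frequency(shape: tuple[int, int]) -> np.ndarray:
    """Radial frequency of each 2-D DFT bin in cycles/sample (Nyquist = 0.5)."""
    fy = np.fft.fftfreq(shape[0])
    fx = np.fft.fftfreq(shape[1])
    return np.hypot(fy[:, None], fx[None, :])


def spectral_energy_split(
    patch: np.ndarray, cutoff: float = DEFAULT_CUTOFF
) -> tuple[float, float]:
    """(low-pass, high-pass) non-DC spectral energy of a single-channel patch.

    The split is an ideal radial mask in the 2-D DFT domain at radius
    ``cutoff`` x Nyquist; the two parts sum exactly to the total non-DC
    energy, which makes the split directly testable. The patch is
    mean-subtracted and Hann-windowed first so that spectral leakage from
    strong non-periodic low-frequency content (illumination gradients) does
    not masquerade as high-frequency energy.
    """
    arr = np.asarray(patch, dtype=np.float64)
    if arr.ndim != 2:
        raise ShapeError(f"expected a single-channel 2-D patch, got shape {arr.shape}")
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ShapeError(f"patch {arr.shape} too small for spectral analysis")
    if not 0.0 < cutoff < 1.0:
        raise ValueError(f"cutoff {cutoff} outside (0, 1)")
    arr = arr - arr.mean()
    arr *= np.hanning(arr.shape[0])[:, None] * np.hanning(arr.shape[1])[None, :]
    spectrum = np.abs(np.fft.fft2(arr)) ** 2
    radius = _radial_frequency(arr.shape)
    nondc = np.ones_like(spectrum, dtype=bool)
    nondc[0, 0] = False
    high = radius > cutoff * 0.5
    return (
        float(spectrum[nondc & ~high].sum()),
        float(spectrum[nondc & high].sum()),
    )


def focus_score(
    patch: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
    threshold: Optional[float] = None,
) -> FocusScore:
    """High-frequency energy fraction of a grayscale patch.

    Returns 0 for constant patches (no non-DC energy). The score is
    scale-invariant: multiplying the patch by a constant leaves it unchanged.
    """
    low, high = spectral_energy_split(patch, cutoff)
    total = low + high
    value = 0.0 if total == 0.0 else high / total
    return FocusScore(value=min(value, 1.0), cutoff=cutoff, threshold=threshold)


def focus_channel(image_window: np.ndarray, channel: int = DEFAULT_FOCUS_CHANNEL) -> np.ndarray:
    """Extract the single channel focus is scored on (green by default)."""
    if image_window.ndim == 2:
        return image_window
    if image_window.ndim == 3 and image_window.shape[2] >= channel + 1:
        return image_window[..., channel]
    raise ChannelError(f"cannot take channel {channel} of shape {image_window.shape}")


def is_in_focus(score: FocusScore, threshold: Optional[float] = None) -> bool:
    """In-focus decision: ``value >= threshold`` (the bound itself passes)."""
    bound = threshold if threshold is not None else score.threshold
    if bound is None:
        raise ConfigurationError("no in-focus threshold configured")
    return score.value >= bound
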