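"""Multi-scale wavelet-product membrane masks from a marker channel.

The segmentation follows the à-trous idea used by organelle-masking macros:
blur the marker image with Gaussians at several multiples of the Airy disk
radius, difference adjacent scales to isolate structure at each band
("wavelets"), multiply the bands so that only features present across all
of them survive, and threshold the product at a multiple of the original
image's standard deviation.  A short binary dilation then pads the mask so
the full membrane thickness is captured.

Scale presets per organelle reflect structure size: plasma membrane,
mitochondria and Golgi use scales 1-4x the Airy radius, the ER (fine
tubules) 1-2x, and Rab5 endosomes (small puncta) 1-3x.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .optics import OpticalConfig, airy_radius_px
from .stack import ImageStack

__all__ = [
    "MaskRecipe",
    "PRESETS",
    "gaussian_scale_stack",
    "wavelet_product_mask",
    "per_frame_masks",
]

#: Per-organelle scale multipliers (units of the Airy disk radius).
PRESETS: dict[str, tuple[float, ...]] = {
    "pm": (1, 2, 3, 4),
    "mito": (1, 2, 3, 4),
    "golgi": (1, 2, 3, 4),
    "er": (1, 2),
    "rab5": (1, 2, 3),
}

_STRUCT_8 = np.ones((3, 3), dtype=bool)  # 8-connected dilation element


@dataclass(frozen=True)
class MaskRecipe:
    """Parameters of the wavelet-product mask.

    ``scale_multipliers`` are the Gaussian sigmas in Airy-radius units
    (ascending; at least two are needed to form one wavelet).
    ``threshold_factor`` scales the standard deviation of the original
    image to set the product threshold.  ``dilation_cycles`` rounds of
    1-pixel 8-connected dilation pad the mask.  ``clip_negative_wavelets``
    zeroes negative band values before multiplication, preventing pairs of
    negative bands from multiplying into spurious positives.
    """

    scale_multipliers: tuple[float, ...] = PRESETS["pm"]
    threshold_factor: float = 0.5
    dilation_cycles: int = 1
    clip_negative_wavelets: bool = True
    sd_within_roi: bool = False  # compute the threshold SD inside a ROI if given

    def __post_init__(self) -> None:
        m = tuple(self.scale_multipliers)
        object.__setattr__(self, "scale_multipliers", m)
        if len(m) < 2:
            raise ValueError("need at least two scale multipliers to form a wavelet")
        if any(a <= 0 for a in m) or list(m) != sorted(m):
            raise ValueError("scale multipliers must be positive and ascending")
        if self.threshold_factor <= 0:
            raise ValueError("threshold_factor must be positive")
        if self.dilation_cycles < 0:
            raise ValueError("dilation_cycles must be >= 0")

    @classmethod
    def for_preset(cls, organelle: str, **kwargs) -> "MaskRecipe":
        if organelle not in PRESETS:
            raise KeyError(f"unknown preset {organelle!r}; known: {sorted(PRESETS)}")
        return cls(scale_multipliers=PRESETS[organelle], **kwargs)


def gaussian_scale_stack(
    image: np.ndarray, optics: OpticalConfig, recipe: MaskRecipe
) -> list[np.ndarray]:
    """Blur the image at each scale: Gaussian sigma = multiplier x Airy radius.

    Reflective boundaries; outputs ordered by ascending scale.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or min(image.shape) < 8:
        raise ValueError("image must be 2-D and at least 8 x 8")
    r = airy_radius_px(optics)
    largest_sigma = recipe.scale_multipliers[-1] * r
    if 4 * largest_sigma > min(image.shape):
        raise ValueError(
            f"largest kernel (sigma {largest_sigma:.1f} px) exceeds image support"
        )
    return [
        ndimage.gaussian_filter(image, m * r, mode="reflect")
        for m in recipe.scale_multipliers
    ]


def wavelet_product_mask(
    image: np.ndarray,
    optics: OpticalConfig,
    recipe: MaskRecipe,
    roi: np.ndarray | None = None,
    return_product: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Binary organelle mask from the thresholded product of wavelet bands.

    With blurred copies ``G_1..G_n`` at ascending scales, the bands are
    ``W_i = G_i - G_{i+1}`` (optionally clipped at zero); their product is
    compared against ``threshold_factor * SD(image)``, where the SD is that
    of the original unfiltered image (over the full frame, or within
    ``roi`` when the recipe asks for it); finally the mask is dilated.

    A perfectly flat image has SD 0 and zero bands, so the threshold
    degenerates to 0 and the mask is empty rather than an error.
    """
    image = np.asarray(image, dtype=np.float64)
    blurred = gaussian_scale_stack(image, optics, recipe)
    product = np.ones_like(image)
    for g_small, g_large in zip(blurred[:-1], blurred[1:]):
        w = g_small - g_large
        if recipe.clip_negative_wavelets:
            w = np.maximum(w, 0.0)
        product *= w
    sd_region = image[roi] if (recipe.sd_within_roi and roi is not None) else image
    threshold = recipe.threshold_factor * float(np.std(sd_region))
    mask = product > threshold
    if recipe.dilation_cycles > 0:
        mask = ndimage.binary_dilation(mask, _STRUCT_8, iterations=recipe.dilation_cycles)
    if return_product:
        return mask, product
    return mask


def per_frame_masks(
    stack: ImageStack,
    optics: OpticalConfig,
    recipe: MaskRecipe,
    marker_role: str = "marker",
    mode: str = "per-frame",
) -> tuple[np.ndarray, list[int]]:
    """Masks for every frame of the marker channel.

    ``mode="per-frame"`` re-segments each frame (tracks slow drift);
    ``mode="fixed"`` reuses the frame-0 mask throughout (robust when the
    marker bleaches).  Returns a (T, Y, X) boolean array plus the indices of
    frames whose mask came out empty — recorded, not fatal, so the
    quantifier can decide how to treat them.
    """
    if mode not in ("per-frame", "fixed"):
        raise ValueError("mode must be 'per-frame' or 'fixed'")
    marker = stack.channel(marker_role)
    if mode == "fixed":
        m0 = wavelet_product_mask(marker[0], optics, recipe)
        masks = np.broadcast_to(m0, marker.shape).copy()
        empty = [i for i in range(stack.n_frames)] if not m0.any() else []
        return masks, empty
    masks = np.empty(marker.shape, dtype=bool)
    empty: list[int] = []
    for i in range(stack.n_frames):
        masks[i] = wavelet_product_mask(marker[i], optics, recipe)
        if not masks[i].any():
            empty.append(i)
    return masks, empty
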