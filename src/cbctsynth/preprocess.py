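"""Image preparation: body masking, foreign-pixel replacement, geometric
harmonisation, HU clipping, and the multi-resolution pyramid.

The chain mirrors standard CBCT/CT pre-processing for supervised synthesis:
a body mask removes the couch and other non-anatomy, high-HU foreign
objects present only in the planning CT (contrast swabs, intra-uterine
devices) are replaced by the co-located CBCT value, geometry is harmonised
by nearest-neighbour resizing and center cropping, and intensities are
clipped to [-1000, 1500] HU before conversion to attenuation space.

The resolution pyramid drives hierarchical coarse-to-fine training: level
``L`` of an ``n``-level pyramid is the dataset pushed through ``n - L``
cycles of (2x2-average down-sampling, bilinear up-sampling back to native
size), so every level keeps the native pixel grid while progressively
shedding high-frequency content.  The native level is bit-identical to the
source.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk
from skimage.transform import resize as _sk_resize

from .dataset import PairedDataset, PairedSample
from .image import BinaryMask, ConversionConfig, HUImage, clip_hu, hu_to_mu, mu_to_hu

__all__ = [
    "compute_body_mask",
    "apply_mask",
    "replace_foreign_pixels",
    "clip_hu",
    "hu_to_mu",
    "mu_to_hu",
    "resize",
    "center_crop",
    "downsample2",
    "upsample2",
    "smooth_cycle",
    "ResolutionPyramid",
    "build_resolution_pyramid",
    "preprocess_pair",
]


def compute_body_mask(
    img: HUImage, threshold: float = -300.0, morph_radius: int = 2
) -> BinaryMask:
    """Threshold + largest-connected-component body mask.

    Pixels above ``threshold`` HU are foreground; only the largest connected
    component is kept, interior holes are filled, and a morphological
    closing with a disk of ``morph_radius`` smooths the contour.
    """
    fg = img.pixels > threshold
    if not fg.any():
        raise ValueError(
            f"empty foreground: no pixel above threshold {threshold} HU"
        )
    labels, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    fg = ndimage.binary_fill_holes(fg)
    if morph_radius > 0:
        fg = ndimage.binary_closing(fg, structure=disk(morph_radius))
        fg = ndimage.binary_fill_holes(fg)
    return BinaryMask(pixels=fg)


def apply_mask(img: HUImage, mask: BinaryMask, fill: float = -1000.0) -> HUImage:
    """Set pixels outside the mask to ``fill``; inside unchanged."""
    if mask.shape != img.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {img.shape}")
    return img.with_pixels(np.where(mask.pixels, img.pixels, fill))


def replace_foreign_pixels(
    pct: HUImage,
    cbct: HUImage,
    threshold: float = 1400.0,
    body_mask: BinaryMask | None = None,
) -> HUImage:
    """Replace suspect high-HU planning-CT pixels with co-located CBCT values.

    Foreign objects (contrast swabs, intra-uterine devices) appear in the
    planning CT but not in the CBCT; pixels with ``pct > threshold`` (inside
    the body mask, when given) take the CBCT value at the same position.
    """
    if pct.shape != cbct.shape:
        raise ValueError(f"shape mismatch: pct {pct.shape} vs cbct {cbct.shape}")
    suspect = pct.pixels > threshold
    if body_mask is not None:
        if body_mask.shape != pct.shape:
            raise ValueError("body mask shape does not match images")
        suspect &= body_mask.pixels
    return pct.with_pixels(np.where(suspect, cbct.pixels, pct.pixels))


def resize(img: HUImage, target_size: int) -> HUImage:
    """Nearest-neighbour resampling to ``target_size`` per side.

    Source index for output index ``i`` is ``floor(i * src / dst)``; pixel
    spacing is rescaled to preserve physical extent.
    """
    h, w = img.shape
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    if (h, w) == (target_size, target_size):
        return img
    rows = (np.arange(target_size) * (h / target_size)).astype(int)
    cols = (np.arange(target_size) * (w / target_size)).astype(int)
    out = img.pixels[np.ix_(rows, cols)]
    new_spacing = img.spacing * h / target_size
    return HUImage(out, spacing=new_spacing, modality=img.modality)


def center_crop(img: HUImage, size: int) -> HUImage:
    """Central ``size`` x ``size`` window; for odd remainders the extra
    row/column is dropped from the bottom/right."""
    h, w = img.shape
    if size > h or size > w:
        raise ValueError(f"crop size {size} exceeds image size {h}x{w}")
    top = (h - size) // 2
    left = (w - size) // 2
    return img.with_pixels(img.pixels[top : top + size, left : left + size])


# ---------------------------------------------------------------------------
# Resolution pyramid
# ---------------------------------------------------------------------------

def downsample2(pixels: np.ndarray) -> np.ndarray:
    """Dyadic down-sampling by 2x2 local averaging (sides must be even)."""
    h, w = pixels.shape
    if h % 2 or w % 2:
        raise ValueError(f"down-sampling needs even sides, got {h}x{w}")
    return pixels.reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3))


def upsample2(pixels: np.ndarray) -> np.ndarray:
    """Bilinear up-sampling by a factor of two (constant-preserving)."""
    h, w = pixels.shape
    return _sk_resize(
        pixels, (2 * h, 2 * w), order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )


def smooth_cycle(pixels: np.ndarray, cycles: int) -> np.ndarray:
    """Apply ``cycles`` rounds of (down x2, up x2 back to native size)."""
    out = pixels
    for _ in range(cycles):
        out = upsample2(downsample2(out))
    return out


@dataclass(frozen=True)
class ResolutionPyramid:
    """Coarse-to-fine dataset views; ``levels[0]`` is the coarsest and the
    last level is bit-identical to the source dataset.  All levels keep the
    native pixel dimensions."""

    levels: tuple[PairedDataset, ...]

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def __getitem__(self, i: int) -> PairedDataset:
        return self.levels[i]


def build_resolution_pyramid(ds: PairedDataset, n_levels: int = 3) -> ResolutionPyramid:
    """Build the multi-resolution dataset for hierarchical training."""
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    if len(ds) == 0:
        raise ValueError("cannot build a pyramid from an empty dataset")
    h, w = ds[0].pct.shape
    div = 2 ** (n_levels - 1)
    if h % div or w % div:
        raise ValueError(
            f"image sides {h}x{w} must be divisible by 2**(n_levels-1) = {div}"
        )
    levels = []
    for level in range(1, n_levels + 1):
        cycles = n_levels - level
        if cycles == 0:
            levels.append(ds)
            continue
        samples = []
        for s in ds:
            samples.append(
                PairedSample(
                    patient_id=s.patient_id,
                    slice_index=s.slice_index,
                    cbct=s.cbct.with_pixels(smooth_cycle(s.cbct.pixels, cycles)),
                    pct=s.pct.with_pixels(smooth_cycle(s.pct.pixels, cycles)),
                )
            )
        levels.append(
            PairedDataset(samples=samples, pixel_spacing=ds.pixel_spacing,
                          meta={**ds.meta, "pyramid_level": level})
        )
    return ResolutionPyramid(levels=tuple(levels))


def preprocess_pair(
    cbct: HUImage,
    pct: HUImage,
    conv: ConversionConfig | None = None,
    mask_threshold: float = -300.0,
    morph_radius: int = 2,
    foreign_threshold: float = 1400.0,
) -> tuple[HUImage, HUImage]:
    """Full preparation chain for one aligned pair.

    Body mask from the planning CT, mask both images, replace foreign
    planning-CT pixels from the CBCT, clip to the HU window.
    """
    conv = conv or ConversionConfig()
    mask = compute_body_mask(pct, threshold=mask_threshold, morph_radius=morph_radius)
    cbct_m = apply_mask(cbct, mask, fill=conv.hu_lo)
    pct_m = apply_mask(pct, mask, fill=conv.hu_lo)
    pct_m = replace_foreign_pixels(pct_m, cbct_m, threshold=foreign_threshold,
                                   body_mask=mask)
    return clip_hu(cbct_m, conv), clip_hu(pct_m, conv)
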