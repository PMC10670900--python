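"""Core image containers and the HU <-> linear-attenuation conversion.

The pipeline's universal currency is a 2D axial slice of Hounsfield Units
(HU): water at 0, air at -1000.  The network itself operates on the linear
attenuation coefficient

    mu_i = HU_i * mu_water / 1000 + mu_water,

an affine rescaling that maps air (-1000 HU) to exactly 0 and water (0 HU)
to ``mu_water``.  Both representations carry their pixel spacing so metrics
and reports can be expressed in physical units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "HUImage",
    "MuImage",
    "BinaryMask",
    "ConversionConfig",
    "clip_hu",
    "hu_to_mu",
    "mu_to_hu",
]

#: Default clip window in HU.  Everything outside is clamped before the
#: attenuation transform so that mu >= 0 always holds.
HU_LO = -1000.0
HU_HI = 1500.0


@dataclass(frozen=True)
class ConversionConfig:
    """Parameters of the HU -> attenuation transform and the clip window.

    ``mu_water`` is the linear attenuation coefficient of water in 1/mm;
    0.0192 corresponds to a ~120 kV beam.  Because every HU-space metric is
    computed after converting predictions back through the same config, the
    particular value cancels in reported HU numbers.
    """

    mu_water: float = 0.0192
    hu_lo: float = HU_LO
    hu_hi: float = HU_HI

    def __post_init__(self) -> None:
        if self.mu_water <= 0:
            raise ValueError(f"mu_water must be positive, got {self.mu_water}")
        if self.hu_lo >= self.hu_hi:
            raise ValueError("hu_lo must be below hu_hi")

    @property
    def mu_hi(self) -> float:
        """Attenuation value of the clip ceiling (upper end of mu range)."""
        return (self.hu_hi / 1000.0 + 1.0) * self.mu_water


def _as_float_2d(pixels: np.ndarray) -> np.ndarray:
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D slice, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class HUImage:
    """A 2D slice of Hounsfield Unit values with isotropic pixel spacing."""

    pixels: np.ndarray
    spacing: float = 1.0  # mm per pixel
    modality: str = "pCT"  # one of pCT / CBCT / sCT

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", _as_float_2d(self.pixels))
        if not np.isfinite(self.pixels).all():
            raise ValueError("HUImage requires finite pixel values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray, **kw) -> "HUImage":
        return replace(self, pixels=pixels, **kw)


@dataclass(frozen=True)
class MuImage:
    """The same grid expressed as linear attenuation coefficients (1/mm)."""

    pixels: np.ndarray
    spacing: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", _as_float_2d(self.pixels))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class BinaryMask:
    """Boolean foreground mask with the same shape as its source image."""

    pixels: np.ndarray = field()

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels).astype(bool)
        object.__setattr__(self, "pixels", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def count(self) -> int:
        return int(self.pixels.sum())


def clip_hu(img: HUImage, cfg: ConversionConfig | None = None) -> HUImage:
    """Clamp HU values to the configured window (default [-1000, 1500])."""
    cfg = cfg or ConversionConfig()
    return img.with_pixels(np.clip(img.pixels, cfg.hu_lo, cfg.hu_hi))


def hu_to_mu(img: HUImage, cfg: ConversionConfig | None = None) -> MuImage:
    """Convert HU to linear attenuation: mu = HU*mu_water/1000 + mu_water."""
    cfg = cfg or ConversionConfig()
    # Evaluated as (HU/1000 + 1)*mu_water so that -1000 HU -> exactly 0
    # and 0 HU -> exactly mu_water in floating point.
    mu = (img.pixels / 1000.0 + 1.0) * cfg.mu_water
    return MuImage(pixels=mu, spacing=img.spacing)


def mu_to_hu(
    img: MuImage, cfg: ConversionConfig | None = None, modality: str = "sCT"
) -> HUImage:
    """Exact algebraic inverse of :func:`hu_to_mu`."""
    cfg = cfg or ConversionConfig()
    hu = (img.pixels / cfg.mu_water - 1.0) * 1000.0
    return HUImage(pixels=hu, spacing=img.spacing, modality=modality)
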