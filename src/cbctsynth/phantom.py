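"""Pelvic phantom simulator: paired clean-CT / degraded-CBCT slices.

Stands in for a clinical cohort of paired planning-CT and cone-beam-CT
axial slices.  Each synthetic "patient" is an elliptical soft-tissue body
containing a subcutaneous fat ring, a bladder-like low-HU organ, and bony
structures (cortical rim around marrow) so that both sides of the 500 HU
bone/soft-tissue threshold are populated.  The CBCT of each pair is the
same anatomy pushed through a degradation operator emulating the classic
cone-beam failure modes: reduced soft-tissue contrast, low-frequency
cupping bias, streak lines, blur, noise and a global HU shift.  The pair is
pixel-aligned by construction, so supervised training needs no
registration step.

Severity defaults of :meth:`ArtifactSpec.clinical` are calibrated so the
uncorrected CBCT-vs-CT gap lands in the tens-of-HU range typical of
clinical cone-beam imaging (MAE roughly 40-120 HU, SSIM well below 0.95).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .dataset import PairedDataset, PairedSample
from .image import BinaryMask, HUImage

__all__ = [
    "PhantomSpec",
    "ArtifactSpec",
    "generate_phantom_ct",
    "degrade_to_cbct",
    "generate_dataset",
]

#: Mean and standard deviation (between patients) of tissue HU values.
DEFAULT_TISSUE_HU: dict[str, tuple[float, float]] = {
    "air": (-1000.0, 0.0),
    "fat": (-90.0, 10.0),
    "muscle": (40.0, 10.0),
    "bladder": (8.0, 6.0),
    "bone_cortex": (900.0, 120.0),
    "bone_marrow": (250.0, 50.0),
    "metal": (2800.0, 200.0),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and tissue statistics of the synthetic pelvis."""

    image_size: int = 400
    pixel_spacing: float = 1.0
    body_axes_range: tuple[float, float] = (0.36, 0.46)  # fraction of size
    tissue_hu: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_HU)
    )
    bone_count_range: tuple[int, int] = (2, 4)
    organ_count_range: tuple[int, int] = (1, 2)
    texture_sigma: float = 12.0  # HU, within-tissue smooth variation
    metal_insert: bool = False

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ValueError(
                "image_size must be >= 32 (four dyadic down-samplings)"
            )
        for name, (mean, _sd) in self.tissue_hu.items():
            if name != "metal" and not (-1000.0 <= mean <= 1500.0):
                raise ValueError(f"tissue {name!r} mean {mean} outside [-1000, 1500]")
        lo, hi = self.body_axes_range
        if not (0.0 < lo <= hi < 0.5):
            raise ValueError("body_axes_range must lie within (0, 0.5)")


@dataclass(frozen=True)
class ArtifactSpec:
    """Severity knobs of the CBCT degradation operator (all additive
    amplitudes in HU; the zero/identity spec leaves the image untouched)."""

    cupping_amplitude: float = 0.0
    bias_smoothness: float = 4.0  # px
    streak_count: int = 0
    streak_amplitude: float = 0.0
    global_shift: float = 0.0
    contrast_factor: float = 1.0
    noise_sigma: float = 0.0
    blur_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cupping_amplitude", "streak_amplitude", "noise_sigma",
                     "blur_sigma", "bias_smoothness"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 < self.contrast_factor <= 2.0):
            raise ValueError("contrast_factor must be in (0, 2]")
        if self.streak_count < 0:
            raise ValueError("streak_count must be >= 0")

    @property
    def is_identity(self) -> bool:
        return (
            self.cupping_amplitude == 0
            and self.streak_count == 0
            and self.global_shift == 0
            and self.contrast_factor == 1.0
            and self.noise_sigma == 0
            and self.blur_sigma == 0
        )

    @classmethod
    def clinical(cls, seed: int = 0) -> "ArtifactSpec":
        """Default clinical-like severity (calibrated CBCT-vs-CT gap)."""
        return cls(
            cupping_amplitude=90.0,
            bias_smoothness=4.0,
            streak_count=18,
            streak_amplitude=70.0,
            global_shift=30.0,
            contrast_factor=0.88,
            noise_sigma=70.0,
            blur_sigma=0.7,
            seed=seed,
        )


# ---------------------------------------------------------------------------
# Anatomy sampling and rendering
# ---------------------------------------------------------------------------

def _ellipse_mask(size: int, cy: float, cx: float, ay: float, ax: float,
                  angle: float = 0.0) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    yr = yy - cy
    xr = xx - cx
    if angle:
        c, s = np.cos(angle), np.sin(angle)
        yr, xr = c * yr - s * xr, s * yr + c * xr
    return (yr / ay) ** 2 + (xr / ax) ** 2 <= 1.0


def _sample_anatomy(spec: PhantomSpec, rng: np.random.Generator) -> dict:
    """Draw one patient's anatomy parameters (shared across slices)."""
    n = spec.image_size
    lo, hi = spec.body_axes_range
    ax = rng.uniform(lo, hi) * n
    ay = ax * rng.uniform(0.72, 0.85)  # pelvis wider than tall
    cy = n / 2 + rng.uniform(-0.01, 0.01) * n
    cx = n / 2 + rng.uniform(-0.01, 0.01) * n
    # per-patient tissue means
    tissues = {
        name: rng.normal(mean, sd) if sd > 0 else mean
        for name, (mean, sd) in spec.tissue_hu.items()
    }
    tissues["air"] = -1000.0

    bones = []
    n_bones = int(rng.integers(spec.bone_count_range[0], spec.bone_count_range[1] + 1))
    # two femoral-head analogues first, then midline sacrum-like ellipses
    for k in range(n_bones):
        if k < 2:
            side = -1.0 if k == 0 else 1.0
            bcx = cx + side * ax * rng.uniform(0.55, 0.7)
            bcy = cy + ay * rng.uniform(-0.1, 0.15)
            r = rng.uniform(0.14, 0.2) * min(ax, ay)
            bones.append((bcy, bcx, r, r * rng.uniform(0.9, 1.1), rng.uniform(0, np.pi)))
        else:
            bcx = cx + ax * rng.uniform(-0.15, 0.15)
            bcy = cy + ay * rng.uniform(0.45, 0.65)
            bones.append(
                (bcy, bcx, rng.uniform(0.12, 0.18) * ay,
                 rng.uniform(0.25, 0.4) * ax, rng.uniform(-0.2, 0.2))
            )

    organs = []
    n_org = int(rng.integers(spec.organ_count_range[0], spec.organ_count_range[1] + 1))
    for _ in range(n_org):
        ocx = cx + ax * rng.uniform(-0.2, 0.2)
        ocy = cy - ay * rng.uniform(0.15, 0.4)  # anterior bladder
        organs.append(
            (ocy, ocx, rng.uniform(0.15, 0.28) * ay,
             rng.uniform(0.18, 0.3) * ax, rng.uniform(-0.3, 0.3))
        )
    return {
        "body": (cy, cx, ay, ax),
        "tissues": tissues,
        "bones": bones,
        "organs": organs,
    }


def _jitter_anatomy(anatomy: dict, rng: np.random.Generator, scale: float = 0.03) -> dict:
    """Small per-slice variation of the shared patient anatomy."""
    cy, cx, ay, ax = anatomy["body"]
    f = 1.0 + rng.uniform(-scale, scale)
    out = dict(anatomy)
    out["body"] = (cy, cx, ay * f, ax * f)
    out["bones"] = [
        (by + rng.uniform(-1, 1), bx + rng.uniform(-1, 1), bay * f, bax * f, ang)
        for (by, bx, bay, bax, ang) in anatomy["bones"]
    ]
    out["organs"] = [
        (oy + rng.uniform(-1, 1), ox + rng.uniform(-1, 1),
         oay * (1.0 + rng.uniform(-2 * scale, 2 * scale)), oax, ang)
        for (oy, ox, oay, oax, ang) in anatomy["organs"]
    ]
    return out


def _render(anatomy: dict, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.image_size
    t = anatomy["tissues"]
    cy, cx, ay, ax = anatomy["body"]
    body = _ellipse_mask(n, cy, cx, ay, ax)
    inner = _ellipse_mask(n, cy, cx, 0.85 * ay, 0.85 * ax)

    img = np.full((n, n), -1000.0)
    img[body] = t["fat"]  # subcutaneous ring
    img[inner] = t["muscle"]

    for (oy, ox, oay, oax, ang) in anatomy["organs"]:
        m = _ellipse_mask(n, oy, ox, oay, oax, ang) & inner
        img[m] = t["bladder"]

    erode_iters = max(1, n // 120)
    for (by, bx, bay, bax, ang) in anatomy["bones"]:
        m = _ellipse_mask(n, by, bx, bay, bax, ang) & inner
        marrow = ndimage.binary_erosion(m, iterations=erode_iters)
        img[m] = t["bone_cortex"]
        img[marrow] = t["bone_marrow"]

    if spec.texture_sigma > 0:
        noise = rng.standard_normal((n, n))
        smooth = ndimage.gaussian_filter(noise, sigma=max(1.0, n / 40.0))
        sd = smooth.std()
        if sd > 0:
            img[body] += (smooth * (spec.texture_sigma / sd))[body]
    img[~body] = -1000.0
    return img


def generate_phantom_ct(spec: PhantomSpec, seed: int) -> HUImage:
    """Render one clean planning-CT slice; deterministic in (spec, seed)."""
    rng = np.random.default_rng(seed)
    anatomy = _sample_anatomy(spec, rng)
    pixels = _render(anatomy, spec, rng)
    return HUImage(pixels=pixels, spacing=spec.pixel_spacing, modality="pCT")


def _add_metal(img: np.ndarray, anatomy: dict, spec: PhantomSpec,
               rng: np.random.Generator) -> np.ndarray:
    """Small high-HU insert (intra-uterine-device analogue), pCT only."""
    n = spec.image_size
    cy, cx, ay, ax = anatomy["body"]
    my = cy - 0.2 * ay + rng.uniform(-2, 2)
    mx = cx + rng.uniform(-2, 2)
    r = max(1.5, n / 80.0)
    m = _ellipse_mask(n, my, mx, r, r)
    out = img.copy()
    out[m] = rng.normal(*spec.tissue_hu["metal"])
    return out


# ---------------------------------------------------------------------------
# Degradation operator
# ---------------------------------------------------------------------------

def degrade_to_cbct(
    ct: HUImage,
    artifact: ArtifactSpec,
    body_mask: BinaryMask | None = None,
) -> HUImage:
    """Apply the CBCT degradation chain to a clean CT slice.

    Order: soft-tissue contrast rescale (about a 0 HU pivot), additive
    radial cupping bias, additive streak lines, Gaussian blur, additive
    Gaussian noise, global HU shift; the background outside the body is
    restored to -1000 afterwards.  Deterministic in ``artifact.seed``.
    """
    pixels = ct.pixels.astype(np.float64).copy()
    if not np.isfinite(pixels).all():
        raise ValueError("input CT must be finite")
    if body_mask is not None and body_mask.shape != pixels.shape:
        raise ValueError(
            f"body mask shape {body_mask.shape} does not match image {pixels.shape}"
        )
    if artifact.is_identity:
        return ct.with_pixels(pixels, modality="CBCT")

    body = body_mask.pixels if body_mask is not None else pixels > -500.0
    rng = np.random.default_rng(artifact.seed)
    n = pixels.shape[0]

    if artifact.contrast_factor != 1.0:
        pixels[body] = artifact.contrast_factor * pixels[body]

    if artifact.cupping_amplitude > 0 and body.any():
        dist = ndimage.distance_transform_edt(body)
        dmax = dist.max()
        if dmax > 0:
            bias = -artifact.cupping_amplitude * (dist / dmax)
            if artifact.bias_smoothness > 0:
                bias = ndimage.gaussian_filter(bias, artifact.bias_smoothness)
            pixels += bias

    if artifact.streak_count > 0 and artifact.streak_amplitude > 0:
        yy, xx = np.mgrid[0:pixels.shape[0], 0:pixels.shape[1]].astype(np.float64)
        for _ in range(artifact.streak_count):
            theta = rng.uniform(0, np.pi)
            y0 = rng.uniform(0.25, 0.75) * pixels.shape[0]
            x0 = rng.uniform(0.25, 0.75) * pixels.shape[1]
            amp = rng.uniform(-1.0, 1.0) * artifact.streak_amplitude
            width = rng.uniform(0.8, 2.0)
            d = (xx - x0) * np.sin(theta) - (yy - y0) * np.cos(theta)
            pixels += amp * np.exp(-(d**2) / (2.0 * width**2))

    if artifact.blur_sigma > 0:
        pixels = ndimage.gaussian_filter(pixels, artifact.blur_sigma)

    if artifact.noise_sigma > 0:
        pixels += rng.normal(0.0, artifact.noise_sigma, size=pixels.shape)

    if artifact.global_shift:
        pixels[body] += artifact.global_shift

    pixels[~body] = -1000.0
    return ct.with_pixels(pixels, modality="CBCT")


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def generate_dataset(
    n_patients: int,
    slices_per_patient: int,
    spec: PhantomSpec | None = None,
    artifact: ArtifactSpec | None = None,
    seed: int = 0,
) -> PairedDataset:
    """Simulate a paired cohort: per patient one anatomy with per-slice
    jitter, each slice degraded independently.  Deterministic in ``seed``."""
    if n_patients < 3:
        raise ValueError("need >= 3 patients for a train/val/test split")
    spec = spec or PhantomSpec()
    artifact = artifact if artifact is not None else ArtifactSpec.clinical()
    master = np.random.default_rng(seed)
    samples = []
    for p in range(n_patients):
        pid = f"P{p + 1:03d}"
        patient_rng = np.random.default_rng(master.integers(2**31))
        anatomy = _sample_anatomy(spec, patient_rng)
        for s in range(slices_per_patient):
            sl = _jitter_anatomy(anatomy, patient_rng) if s else anatomy
            base = _render(sl, spec, patient_rng)
            slice_artifact = replace(
                artifact, seed=int(patient_rng.integers(2**31))
            )
            pct_pixels = base
            if spec.metal_insert:
                pct_pixels = _add_metal(base, sl, spec, patient_rng)
            pct = HUImage(pct_pixels, spacing=spec.pixel_spacing, modality="pCT")
            cbct = degrade_to_cbct(
                HUImage(base, spacing=spec.pixel_spacing), slice_artifact
            )
            samples.append(
                PairedSample(patient_id=pid, slice_index=s, cbct=cbct, pct=pct)
            )
    return PairedDataset(
        samples=samples,
        pixel_spacing=spec.pixel_spacing,
        meta={"seed": seed, "n_patients": n_patients,
              "slices_per_patient": slices_per_patient},
    )
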