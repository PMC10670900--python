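"""Paired (CBCT, planning-CT) slice collections with on-disk manifests.

A dataset is a flat list of aligned slice pairs grouped by patient id.  On
disk, each slice is a 16-bit TIFF storing ``round(HU) + 1000`` as unsigned
integers (so the full [-1000, 1500] window plus headroom fits), and a
``manifest.json`` records the schema version, pixel spacing, the HU offset
and the per-sample file paths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .image import HUImage

__all__ = ["PairedSample", "PairedDataset", "MANIFEST_VERSION"]

MANIFEST_VERSION = 1
HU_OFFSET = 1000  # stored value = HU + offset


@dataclass(frozen=True)
class PairedSample:
    """One aligned (CBCT, pCT) slice pair of one patient."""

    patient_id: str
    slice_index: int
    cbct: HUImage
    pct: HUImage

    def __post_init__(self) -> None:
        if self.cbct.shape != self.pct.shape:
            raise ValueError(
                f"sample {self.patient_id}/{self.slice_index}: "
                f"cbct {self.cbct.shape} vs pct {self.pct.shape}"
            )
        if self.cbct.spacing != self.pct.spacing:
            raise ValueError("cbct and pct pixel spacing differ within a sample")

    @property
    def key(self) -> tuple[str, int]:
        return (self.patient_id, self.slice_index)


@dataclass
class PairedDataset:
    """A sequence of paired samples plus manifest metadata."""

    samples: list[PairedSample]
    pixel_spacing: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [s.key for s in self.samples]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (patient_id, slice_index) in dataset")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def __getitem__(self, i: int) -> PairedSample:
        return self.samples[i]

    def patient_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.patient_id, None)
        return list(seen)

    def subset(self, patient_ids) -> "PairedDataset":
        wanted = set(patient_ids)
        return PairedDataset(
            samples=[s for s in self.samples if s.patient_id in wanted],
            pixel_spacing=self.pixel_spacing,
            meta=dict(self.meta),
        )

    def content_hash(self) -> str:
        """SHA-256 over sample keys and pixel data, for determinism checks."""
        import hashlib

        h = hashlib.sha256()
        for s in self.samples:
            h.update(f"{s.patient_id}/{s.slice_index}".encode())
            h.update(np.ascontiguousarray(s.cbct.pixels).tobytes())
            h.update(np.ascontiguousarray(s.pct.pixels).tobytes())
        return h.hexdigest()

    # -- persistence -------------------------------------------------------

    def save(self, out_dir, fmt: str = "tiff") -> Path:
        """Write per-slice images plus ``manifest.json``; returns the
        manifest path.

        ``fmt="tiff"`` stores ``round(HU) + 1000`` as unsigned 16-bit;
        ``fmt="nifti"`` stores float32 HU directly with the pixel spacing
        in the affine.
        """
        if fmt not in ("tiff", "nifti"):
            raise ValueError(f"unknown format {fmt!r}")
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        entries = []
        for s in self.samples:
            stem = f"{s.patient_id}_s{s.slice_index:03d}"
            paths = {}
            for tag, img in (("cbct", s.cbct), ("pct", s.pct)):
                if fmt == "tiff":
                    rel = f"{stem}_{tag}.tif"
                    stored = np.round(img.pixels).astype(np.int64) + HU_OFFSET
                    # unclipped degradations may overshoot the window slightly
                    stored = np.clip(stored, 0, np.iinfo(np.uint16).max)
                    tifffile.imwrite(out / rel, stored.astype(np.uint16))
                else:
                    import nibabel as nib

                    rel = f"{stem}_{tag}.nii"
                    affine = np.diag([self.pixel_spacing, self.pixel_spacing, 1.0, 1.0])
                    nib.save(
                        nib.Nifti1Image(
                            img.pixels.astype(np.float32)[:, :, None], affine
                        ),
                        out / rel,
                    )
                paths[f"{tag}_path"] = rel
            entries.append(
                {"patient_id": s.patient_id, "slice": s.slice_index, **paths}
            )
        manifest = {
            "version": MANIFEST_VERSION,
            "pixel_spacing": self.pixel_spacing,
            "hu_offset": HU_OFFSET,
            "meta": self.meta,
            "samples": entries,
        }
        path = out / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return path

    @classmethod
    def load(cls, manifest_path) -> "PairedDataset":
        manifest_path = Path(manifest_path)
        if manifest_path.is_dir():
            manifest_path = manifest_path / "manifest.json"
        manifest = json.loads(manifest_path.read_text())
        if manifest.get("version") != MANIFEST_VERSION:
            raise ValueError(f"unsupported manifest version: {manifest.get('version')}")
        root = manifest_path.parent
        spacing = float(manifest["pixel_spacing"])
        offset = float(manifest.get("hu_offset", HU_OFFSET))
        samples = []
        for e in manifest["samples"]:
            imgs = {}
            for tag, modality in (("cbct", "CBCT"), ("pct", "pCT")):
                path = root / e[f"{tag}_path"]
                if path.suffix in (".nii", ".gz"):
                    import nibabel as nib

                    hu = np.asanyarray(nib.load(path).dataobj)[:, :, 0]
                    hu = hu.astype(np.float64)
                else:
                    hu = tifffile.imread(path).astype(np.float64) - offset
                imgs[tag] = HUImage(hu, spacing=spacing, modality=modality)
            samples.append(
                PairedSample(
                    patient_id=e["patient_id"],
                    slice_index=int(e["slice"]),
                    cbct=imgs["cbct"],
                    pct=imgs["pct"],
                )
            )
        return cls(samples=samples, pixel_spacing=spacing, meta=manifest.get("meta", {}))
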