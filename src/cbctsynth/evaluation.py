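"""Image-quality metrics, paired method comparison, report surfaces, and
the ablation experiment driver.

Metrics follow the synthesis-evaluation conventions of this task:

* **MAE** — mean absolute HU difference, optionally restricted to a mask;
* **SSIM** — structural similarity with an 11-px Gaussian window over a
  fixed 2500 HU data range (the clipped intensity span);
* **PSNR** — ``20 log10(MAX_I / sqrt(MSE))`` where ``MAX_I`` is by default
  the maximum gray value over *both* images (content-dependent); a
  conventional fixed-range variant is available via ``max_intensity``.

``compare_methods`` reports per-metric mean +/- sd, the mean per-image
relative improvement over the CBCT baseline (sign-flipped for SSIM/PSNR so
that improvement is positive when the metric rises), and a paired
two-sided Wilcoxon signed-rank p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .image import BinaryMask, ConversionConfig, HUImage
from .losses import LossConfig, ssim as _ssim_core
from .nn import NetworkConfig
from .phantom import ArtifactSpec, PhantomSpec, generate_dataset
from .preprocess import build_resolution_pyramid
from .training import (
    StageSchedule,
    predict,
    split_by_patient,
    train_hierarchical,
)

__all__ = [
    "mae_metric",
    "psnr_metric",
    "ssim_metric",
    "MetricsRecord",
    "evaluate_dataset",
    "compare_methods",
    "difference_map",
    "line_profile",
    "hu_histogram",
    "render_report",
    "AblationConfig",
    "run_ablation",
]

#: HU span of the clipped window, used as the SSIM metric data range.
METRIC_DATA_RANGE = 2500.0


def _pixels(img) -> np.ndarray:
    return img.pixels if isinstance(img, HUImage) else np.asarray(img, dtype=np.float64)


def mae_metric(gt, pred, mask: BinaryMask | None = None) -> float:
    """Mean absolute difference in HU (whole image, or within a mask)."""
    g, p = _pixels(gt), _pixels(pred)
    if g.shape != p.shape:
        raise ValueError(f"shape mismatch: {g.shape} vs {p.shape}")
    diff = np.abs(g - p)
    if mask is not None:
        if mask.shape != g.shape:
            raise ValueError("mask shape mismatch")
        if not mask.pixels.any():
            raise ValueError("empty evaluation mask")
        return float(diff[mask.pixels].mean())
    return float(diff.mean())


def psnr_metric(gt, pred, max_intensity: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB.

    By default the peak is the maximum gray value over both images; pass
    ``max_intensity`` (e.g. 2500) for the conventional fixed-range form.
    Identical images return ``inf``.
    """
    g, p = _pixels(gt), _pixels(pred)
    if g.shape != p.shape:
        raise ValueError(f"shape mismatch: {g.shape} vs {p.shape}")
    mse = float(((g - p) ** 2).mean())
    if mse == 0.0:
        return float("inf")
    peak = float(max(g.max(), p.max())) if max_intensity is None else float(max_intensity)
    if peak <= 0:
        raise ValueError("non-positive peak intensity")
    return float(20.0 * np.log10(peak / np.sqrt(mse)))


def ssim_metric(gt, pred, data_range: float = METRIC_DATA_RANGE) -> float:
    """Structural similarity in metric mode (fixed HU data range)."""
    cfg = LossConfig(data_range=data_range)
    return _ssim_core(_pixels(gt), _pixels(pred), cfg)


@dataclass(frozen=True)
class MetricsRecord:
    patient_id: str
    slice_index: int
    method: str
    mae: float
    ssim: float
    psnr: float


def evaluate_dataset(pairs, method: str = "sCT") -> pd.DataFrame:
    """Per-image metrics for (ground truth, candidate, patient_id, slice)
    tuples; returns one row per image."""
    rows = []
    for gt, cand, pid, sl in pairs:
        rows.append(
            MetricsRecord(
                patient_id=pid,
                slice_index=sl,
                method=method,
                mae=mae_metric(gt, cand),
                ssim=ssim_metric(gt, cand),
                psnr=psnr_metric(gt, cand),
            )
        )
    if not rows:
        raise ValueError("no image pairs to evaluate")
    return pd.DataFrame([r.__dict__ for r in rows])


_HIGHER_BETTER = {"mae": False, "ssim": True, "psnr": True}


def compare_methods(baseline: pd.DataFrame, *methods: pd.DataFrame) -> pd.DataFrame:
    """Aggregate metric table with improvement vs the baseline.

    Improvement per image is ``(baseline - method)/baseline`` for MAE and
    ``(method - baseline)/baseline`` for SSIM/PSNR; the table reports the
    mean of these per-image relative improvements, plus paired two-sided
    Wilcoxon signed-rank p-values.  All frames must cover the identical
    (patient, slice) sample set.
    """
    key = ["patient_id", "slice_index"]
    base = baseline.sort_values(key).reset_index(drop=True)
    rows = []
    for frame in (baseline, *methods):
        cur = frame.sort_values(key).reset_index(drop=True)
        if not (cur[key].values == base[key].values).all():
            raise ValueError("method evaluated on a different sample set")
        row = {"method": cur["method"].iloc[0]}
        for metric in ("mae", "ssim", "psnr"):
            b = base[metric].to_numpy(dtype=float)
            m = cur[metric].to_numpy(dtype=float)
            finite = np.isfinite(b) & np.isfinite(m)
            bf, mf = b[finite], m[finite]
            row[f"{metric}_mean"] = float(np.mean(mf))
            row[f"{metric}_sd"] = float(np.std(mf, ddof=1)) if len(mf) > 1 else 0.0
            sign = 1.0 if _HIGHER_BETTER[metric] else -1.0
            improvement = sign * (mf - bf) / np.abs(bf)
            row[f"{metric}_improvement"] = float(np.mean(improvement))
            if np.allclose(mf, bf):
                row[f"{metric}_p"] = 1.0
            else:
                row[f"{metric}_p"] = float(
                    stats.wilcoxon(mf, bf, alternative="two-sided").pvalue
                )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Report surfaces
# ---------------------------------------------------------------------------

def difference_map(gt, pred) -> np.ndarray:
    """Ground truth minus candidate (planning CT minus synthetic/CBCT)."""
    g, p = _pixels(gt), _pixels(pred)
    if g.shape != p.shape:
        raise ValueError("shape mismatch")
    return g - p


def line_profile(img, axis: int, index: int) -> np.ndarray:
    """Extract one row (axis=0) or column (axis=1) of HU values."""
    p = _pixels(img)
    if axis == 0:
        return p[index, :].copy()
    if axis == 1:
        return p[:, index].copy()
    raise ValueError("axis must be 0 (row) or 1 (column)")


def hu_histogram(img, bins: int = 100,
                 hu_range: tuple[float, float] = (-1000.0, 1500.0)):
    """Histogram of HU values over the clip window; returns (counts, edges)."""
    counts, edges = np.histogram(_pixels(img), bins=bins, range=hu_range)
    return counts, edges


def render_report(gt, cbct, sct, out_dir, profile_index: int | None = None) -> list:
    """Write the qualitative report panels as PNG/CSV artifacts.

    Panels: the three images, difference maps (pCT minus candidate) on a
    symmetric colour scale, an HU line profile through ``profile_index``
    (default: centre row), and HU histograms.  Returns the written paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    g, c, s = _pixels(gt), _pixels(cbct), _pixels(sct)
    row = g.shape[0] // 2 if profile_index is None else profile_index
    written = []

    fig, axes = plt.subplots(2, 3, figsize=(12, 7))
    for ax, (img, title) in zip(
        axes[0], [(g, "pCT"), (c, "CBCT"), (s, "sCT")]
    ):
        ax.imshow(img, cmap="gray", vmin=-1000, vmax=1500)
        ax.set_title(title)
        ax.axis("off")
    lim = max(np.abs(difference_map(g, c)).max(), 1.0)
    for ax, (cand, title) in zip(
        axes[1][1:], [(c, "pCT - CBCT"), (s, "pCT - sCT")]
    ):
        im = ax.imshow(difference_map(g, cand), cmap="RdBu_r", vmin=-lim, vmax=lim)
        ax.set_title(title)
        ax.axis("off")
    axes[1][0].axis("off")
    fig.colorbar(im, ax=axes[1][2], shrink=0.8)
    panel = out / "panels.png"
    fig.savefig(panel, dpi=110)
    plt.close(fig)
    written.append(panel)

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(11, 4))
    for img, label in ((g, "pCT"), (c, "CBCT"), (s, "sCT")):
        ax1.plot(line_profile(img, 0, row), label=label)
        counts, edges = hu_histogram(img, bins=80)
        ax2.step(edges[:-1], counts, where="post", label=label)
    ax1.set_title(f"HU line profile (row {row})")
    ax1.set_xlabel("column")
    ax1.set_ylabel("HU")
    ax1.legend()
    ax2.set_title("HU histogram")
    ax2.set_xlabel("HU")
    ax2.set_ylabel("count")
    ax2.legend()
    profiles = out / "profile_histogram.png"
    fig.savefig(profiles, dpi=110)
    plt.close(fig)
    written.append(profiles)

    prof = pd.DataFrame(
        {
            "column": np.arange(g.shape[1]),
            "pct": line_profile(g, 0, row),
            "cbct": line_profile(c, 0, row),
            "sct": line_profile(s, 0, row),
        }
    )
    csv = out / "line_profile.csv"
    prof.to_csv(csv, index=False)
    written.append(csv)
    return written


# ---------------------------------------------------------------------------
# Ablation driver
# ---------------------------------------------------------------------------

#: Loss-function ablation variants, expressed purely via lambda settings.
LOSS_VARIANTS: dict[str, tuple[float, float, float]] = {
    "weighted_mae_only": (1.0, 0.0, 0.0),
    "weighted_mae_with_gdl": (1.0, 0.0, 2.0),
    "weighted_mae_with_ms_ssim": (1.0, 3.0, 0.0),
    "full_loss": (1.0, 3.0, 2.0),
}


@dataclass(frozen=True)
class AblationConfig:
    """Seeded phantom benchmark for the loss and strategy ablations.

    Defaults are desk-scale: a small cohort at 32 px with a short schedule,
    enough to exercise every variant end-to-end and rank them against the
    uncorrected CBCT baseline.
    """

    n_patients: int = 24
    slices_per_patient: int = 4
    image_size: int = 32
    base_filters: int = 8
    epochs_per_stage: tuple[int, ...] = (20, 12, 10)
    seed: int = 0

    def phantom_spec(self) -> PhantomSpec:
        return PhantomSpec(image_size=self.image_size)

    def schedule(self) -> StageSchedule:
        return StageSchedule(epochs_per_stage=self.epochs_per_stage, seed=self.seed)


def _test_pairs(model, test_ds, conv):
    return [
        (
            s.pct,
            # preprocessed CBCT background is exactly air, so the body mask
            # is recovered without re-segmentation
            predict(model, s.cbct, conv,
                    body_mask=BinaryMask(s.cbct.pixels > conv.hu_lo)),
            s.patient_id,
            s.slice_index,
        )
        for s in test_ds
    ]


def run_ablation(cfg: AblationConfig | None = None) -> pd.DataFrame:
    """Train the four loss variants plus a single-stage baseline on one
    seeded phantom benchmark and emit the comparison table.

    Rows: the CBCT baseline, the four loss-lambda configurations (trained
    hierarchically), and the full loss trained single-stage — the last two
    rows of the table mirror the strategy comparison.  BLAS threading is
    pinned to one thread so results do not depend on the host's core count.
    """
    from threadpoolctl import threadpool_limits

    with threadpool_limits(limits=1):
        return _run_ablation(cfg)


def _run_ablation(cfg: AblationConfig | None = None) -> pd.DataFrame:
    cfg = cfg or AblationConfig()
    conv = ConversionConfig()
    ds = generate_dataset(
        cfg.n_patients,
        cfg.slices_per_patient,
        spec=cfg.phantom_spec(),
        artifact=ArtifactSpec.clinical(),
        seed=cfg.seed,
    )
    train, val, test = split_by_patient(ds, seed=cfg.seed)
    net_cfg = NetworkConfig(depth=4, base_filters=cfg.base_filters)
    schedule = cfg.schedule()
    pyramid = build_resolution_pyramid(train, n_levels=schedule.n_stages)
    val_pyramid = build_resolution_pyramid(val, n_levels=schedule.n_stages)

    baseline_pairs = [
        (s.pct, s.cbct, s.patient_id, s.slice_index) for s in test
    ]
    frames = {"cbct_baseline": evaluate_dataset(baseline_pairs, method="cbct_baseline")}

    for name, lambdas in LOSS_VARIANTS.items():
        loss_cfg = LossConfig(lambdas=lambdas)
        model, _ = train_hierarchical(
            net_cfg, pyramid, schedule, loss_cfg, val_pyramid=val_pyramid, conv=conv
        )
        frames[name] = evaluate_dataset(_test_pairs(model, test, conv), method=name)

    # single-stage baseline: same total machinery on the native level only
    single = StageSchedule(
        epochs_per_stage=(sum(cfg.epochs_per_stage),),
        learning_rate=schedule.learning_rate,
        batch_size=schedule.batch_size,
        seed=cfg.seed,
    )
    pyramid1 = build_resolution_pyramid(train, n_levels=1)
    val_pyramid1 = build_resolution_pyramid(val, n_levels=1)
    model, _ = train_hierarchical(
        net_cfg, pyramid1, single, LossConfig(), val_pyramid=val_pyramid1, conv=conv
    )
    frames["full_loss_single_stage"] = evaluate_dataset(
        _test_pairs(model, test, conv), method="full_loss_single_stage"
    )

    order = [
        "weighted_mae_only",
        "weighted_mae_with_gdl",
        "weighted_mae_with_ms_ssim",
        "full_loss",
        "full_loss_single_stage",
    ]
    return compare_methods(frames["cbct_baseline"], *[frames[k] for k in order])
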