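"""Patient-level splitting, staged optimisation, and inference.

Training follows the hierarchical coarse-to-fine recipe: a three-level
resolution pyramid of the training set is consumed coarsest level first,
with each stage warm-starting from the previous stage's weights (50/30/20
epochs by default, Adam at a constant learning rate of 0.001, batch size
8).  Validation during each stage uses the same resolution level as that
stage's training data; the returned model is the best-validation
checkpoint within the final (native-resolution) stage.

The network operates on a normalised attenuation scale: HU are clipped to
[-1000, 1500], converted to linear attenuation via the water coefficient,
and divided by the attenuation of the clip ceiling, giving inputs in
[0, 1].  Because the whole map is affine, loss thresholds and data ranges
are carried through it exactly and predictions are mapped back to HU
losslessly before metrics are computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dataset import PairedDataset
from .image import ConversionConfig, HUImage, clip_hu, hu_to_mu, mu_to_hu, MuImage
from .losses import LossConfig, combined_loss, combined_loss_grad
from .nn import Adam, NetworkConfig, ResidualUNet, build_model, parameter_checksum
from .preprocess import ResolutionPyramid

__all__ = [
    "StageSchedule",
    "TrainHistory",
    "split_by_patient",
    "to_network_space",
    "from_network_space",
    "dataset_to_arrays",
    "train_stage",
    "train_hierarchical",
    "predict",
]


@dataclass(frozen=True)
class StageSchedule:
    """Per-stage epoch counts and shared optimiser settings."""

    epochs_per_stage: tuple[int, ...] = (50, 30, 20)
    learning_rate: float = 0.001
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.epochs_per_stage or any(e < 1 for e in self.epochs_per_stage):
            raise ValueError("every stage needs >= 1 epoch")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    @property
    def n_stages(self) -> int:
        return len(self.epochs_per_stage)

    @property
    def total_epochs(self) -> int:
        return sum(self.epochs_per_stage)

    @classmethod
    def smoke(cls, seed: int = 0) -> "StageSchedule":
        """Short three-stage preset for tests and desk-scale benchmarks."""
        return cls(epochs_per_stage=(10, 6, 4), seed=seed)


@dataclass
class TrainHistory:
    """Per-epoch loss records plus stage hand-off checksums."""

    records: list[dict] = field(default_factory=list)
    stage_init_checksums: list[str] = field(default_factory=list)
    stage_final_checksums: list[str] = field(default_factory=list)

    def append(self, **kw) -> None:
        self.records.append(dict(kw))

    def stage_records(self, stage: int) -> list[dict]:
        return [r for r in self.records if r["stage"] == stage]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.records)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_by_patient(
    ds: PairedDataset,
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> tuple[PairedDataset, PairedDataset, PairedDataset]:
    """Random patient-granularity split (no patient in two subsets).

    Validation and test sizes are the rounded-half-up ratio shares; the
    training set takes the remainder (228 patients at 6:2:2 gives
    136/46/46).
    """
    pids = ds.patient_ids()
    n = len(pids)
    if n < 3:
        raise ValueError("need at least 3 patients to split")
    if not np.isclose(sum(ratios), 1.0):
        raise ValueError("split ratios must sum to 1")
    rng = np.random.default_rng(seed)
    order = [pids[i] for i in rng.permutation(n)]
    n_val = max(1, _round_half_up(ratios[1] * n))
    n_test = max(1, _round_half_up(ratios[2] * n))
    if n_val + n_test >= n:
        raise ValueError("split leaves no training patients")
    train_ids = order[: n - n_val - n_test]
    val_ids = order[n - n_val - n_test : n - n_test]
    test_ids = order[n - n_test :]
    assert not (set(train_ids) & set(val_ids)) and not (set(val_ids) & set(test_ids))
    return ds.subset(train_ids), ds.subset(val_ids), ds.subset(test_ids)


# ---------------------------------------------------------------------------
# Network-space conversion
# ---------------------------------------------------------------------------

def to_network_space(hu: np.ndarray, conv: ConversionConfig) -> np.ndarray:
    """Clipped HU -> attenuation normalised by the clip-ceiling attenuation,
    i.e. values in [0, 1]."""
    img = clip_hu(HUImage(hu), conv)
    mu = hu_to_mu(img, conv)
    return (mu.pixels / conv.mu_hi).astype(np.float32)


def from_network_space(net: np.ndarray, conv: ConversionConfig) -> np.ndarray:
    """Inverse of :func:`to_network_space`, with a final HU clip."""
    mu = MuImage(np.asarray(net, dtype=np.float64) * conv.mu_hi)
    hu = mu_to_hu(mu, conv)
    return np.clip(hu.pixels, conv.hu_lo, conv.hu_hi)


def network_loss_config(loss_cfg: LossConfig, conv: ConversionConfig) -> LossConfig:
    """Map an HU-domain loss configuration into network space."""
    return loss_cfg.in_network_space(hu_lo=conv.hu_lo, hu_hi=conv.hu_hi)


def dataset_to_arrays(
    ds: PairedDataset, conv: ConversionConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Stack a paired dataset into network-space (n, 1, H, W) batches."""
    conv = conv or ConversionConfig()
    cbct = np.stack([to_network_space(s.cbct.pixels, conv) for s in ds])
    pct = np.stack([to_network_space(s.pct.pixels, conv) for s in ds])
    return cbct[:, None, :, :], pct[:, None, :, :]


# ---------------------------------------------------------------------------
# Optimisation
# ---------------------------------------------------------------------------

def _epoch_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def _validation_loss(model, x, y, loss_cfg_net, batch_size):
    total, n = 0.0, 0
    for start in range(0, x.shape[0], batch_size):
        xb = x[start : start + batch_size]
        yb = y[start : start + batch_size]
        pred = model.forward(xb, training=False)
        v, _ = combined_loss(pred[:, 0], yb[:, 0], loss_cfg_net)
        total += v * xb.shape[0]
        n += xb.shape[0]
    return total / max(n, 1)


def train_stage(
    model: ResidualUNet,
    train_data: PairedDataset,
    epochs: int,
    loss_cfg: LossConfig,
    val_data: PairedDataset | None = None,
    schedule: StageSchedule | None = None,
    conv: ConversionConfig | None = None,
    stage: int = 1,
    history: TrainHistory | None = None,
    track_best: bool = False,
    optimizer: Adam | None = None,
) -> tuple[ResidualUNet, TrainHistory]:
    """Run one stage of mini-batch Adam on the combined loss.

    ``loss_cfg`` is given in HU units and mapped into network space here.
    Data order and all randomness derive from ``schedule.seed`` and the
    stage index, so repeated runs are bit-reproducible.  With ``track_best``
    the best-validation parameters are recorded in
    ``history`` (key ``best_state``).
    """
    if len(train_data) == 0:
        raise ValueError("cannot train on an empty dataset")
    schedule = schedule or StageSchedule()
    conv = conv or ConversionConfig()
    history = history or TrainHistory()
    loss_net = network_loss_config(loss_cfg, conv)
    x, y = dataset_to_arrays(train_data, conv)
    if val_data is not None and len(val_data) > 0:
        xv, yv = dataset_to_arrays(val_data, conv)
    else:
        xv = yv = None

    opt = optimizer or Adam(model.named_params(), lr=schedule.learning_rate)
    rng = np.random.default_rng([schedule.seed, stage])
    for epoch in range(1, epochs + 1):
        train_loss, seen = 0.0, 0
        term_sums = {"weighted_mae": 0.0, "ms_ssim_loss": 0.0,
                     "gradient_difference_loss": 0.0}
        for idx in _epoch_batches(x.shape[0], schedule.batch_size, rng):
            xb, yb = x[idx], y[idx]
            pred = model.forward(xb, training=True)
            value, terms, grad = combined_loss_grad(pred[:, 0], yb[:, 0], loss_net)
            if not np.isfinite(value):
                bad = {k: v for k, v in terms.items() if not np.isfinite(v)}
                raise FloatingPointError(
                    f"non-finite training loss at stage {stage} epoch {epoch}; "
                    f"offending terms: {bad or terms}"
                )
            opt.zero_grad()
            model.backward(grad[:, None, :, :].astype(np.float32))
            opt.step()
            train_loss += value * xb.shape[0]
            for k in term_sums:
                term_sums[k] += terms[k] * xb.shape[0]
            seen += xb.shape[0]
        record = {
            "stage": stage,
            "epoch": epoch,
            "train_loss": train_loss / seen,
            **{f"train_{k}": v / seen for k, v in term_sums.items()},
        }
        if xv is not None:
            record["val_loss"] = _validation_loss(
                model, xv, yv, loss_net, schedule.batch_size
            )
            if track_best:
                best = [r.get("val_loss", np.inf) for r in history.stage_records(stage)]
                if record["val_loss"] < min(best, default=np.inf):
                    setattr(history, "best_state", model.state_dict())
                    setattr(history, "best_record", dict(record))
        history.append(**record)
    return model, history


def train_hierarchical(
    cfg: NetworkConfig,
    pyramid: ResolutionPyramid,
    schedule: StageSchedule,
    loss_cfg: LossConfig,
    val_pyramid: ResolutionPyramid | None = None,
    conv: ConversionConfig | None = None,
    select_best_validation: bool = True,
) -> tuple[ResidualUNet, TrainHistory]:
    """Coarse-to-fine training across the pyramid levels.

    Stage ``k`` consumes pyramid level ``k`` (coarsest first) and starts
    from stage ``k-1``'s final weights without re-initialisation.  When a
    validation pyramid is supplied and ``select_best_validation`` is set,
    the returned model carries the best-validation parameters of the final
    stage; the stage hand-off itself always uses stage-final weights.
    """
    if pyramid.n_levels != schedule.n_stages:
        raise ValueError(
            f"pyramid has {pyramid.n_levels} levels but the schedule has "
            f"{schedule.n_stages} stages"
        )
    if val_pyramid is not None and val_pyramid.n_levels != pyramid.n_levels:
        raise ValueError("validation pyramid level count mismatch")
    conv = conv or ConversionConfig()
    model = build_model(cfg, seed=schedule.seed)
    history = TrainHistory()
    # one optimiser across all stages: re-zeroing Adam's moment estimates at
    # a stage boundary would take maximally large first steps and wreck the
    # warm-started weights
    optimizer = Adam(model.named_params(), lr=schedule.learning_rate)
    for stage_idx in range(schedule.n_stages):
        history.stage_init_checksums.append(parameter_checksum(model))
        val_ds = val_pyramid[stage_idx] if val_pyramid is not None else None
        final_stage = stage_idx == schedule.n_stages - 1
        model, history = train_stage(
            model,
            pyramid[stage_idx],
            epochs=schedule.epochs_per_stage[stage_idx],
            loss_cfg=loss_cfg,
            val_data=val_ds,
            schedule=schedule,
            conv=conv,
            stage=stage_idx + 1,
            history=history,
            track_best=final_stage and select_best_validation,
            optimizer=optimizer,
        )
        history.stage_final_checksums.append(parameter_checksum(model))
    best_state = getattr(history, "best_state", None)
    if select_best_validation and best_state is not None:
        model.load_state_dict(best_state)
    return model, history


def predict(
    model: ResidualUNet,
    cbct: HUImage,
    conv: ConversionConfig | None = None,
    body_mask=None,
) -> HUImage:
    """Synthesize a CT slice from one (masked, clipped) CBCT slice.

    HU -> normalised attenuation -> network (evaluation mode) -> HU, with a
    final clip to the HU window.  When ``body_mask`` is given the output
    background is restored to the air value, mirroring the body masking
    applied to every other image in the pipeline.  Deterministic.
    """
    conv = conv or ConversionConfig()
    h, w = cbct.shape
    d = model.cfg.divisor
    if h % d or w % d:
        raise ValueError(
            f"slice sides {h}x{w} not divisible by 2**depth = {d}; "
            "pad or crop the input first"
        )
    x = to_network_space(cbct.pixels, conv)[None, None]
    out = model.forward(x, training=False)[0, 0]
    hu = from_network_space(out, conv)
    if body_mask is not None:
        if body_mask.shape != hu.shape:
            raise ValueError("body mask shape does not match the slice")
        hu = np.where(body_mask.pixels, hu, conv.hu_lo)
    return HUImage(hu, spacing=cbct.spacing, modality="sCT")
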