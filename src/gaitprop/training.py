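"""Dataset splits, optimization, and transfer learning.

Splits are by walking bout (the bouts nearest the comfortable walking speed
become validation and test) or by within-bout ratio (first or last fraction
of each bout trains, the adjacent 10 % validates, the rest tests).
Optimization is Adam (lr 5e-4, weight decay 1e-5) on the mean-squared error
of the %BW estimate, 500 epochs for individual models with best-validation
weight selection; pre-training pools all healthy training frames for 1000
epochs and keeps the last weights, and fine-tuning re-trains from those
weights on a clinical leg's data (all, or the last half, of train+val).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _nn
from .models import GRFEstimator, ModelSpec, build_model, select_channels
from .preprocess import (AlignedDataset, NormConstants, SequenceSet, apply_minmax,
                         fit_minmax, make_sequences)

RATIO_FRACTIONS = (0.15, 0.30, 0.45, 0.60)


@dataclass(frozen=True)
class SplitSpec:
    strategy: str = "by_bout"          # by_bout | ratio_forward | ratio_reverse
    train_fraction: float = 0.15       # ratio strategies only
    val_fraction: float = 0.10

    def __post_init__(self):
        if self.strategy not in ("by_bout", "ratio_forward", "ratio_reverse"):
            raise ValueError(f"unknown split strategy {self.strategy!r}")
        if self.strategy != "by_bout" and not any(
                abs(self.train_fraction - f) < 1e-9 for f in RATIO_FRACTIONS):
            raise ValueError(f"train_fraction must be one of {RATIO_FRACTIONS}")
        if self.train_fraction + self.val_fraction > 1.0 + 1e-9:
            raise ValueError("fractions sum above 1")


@dataclass
class Split:
    """Disjoint frame-index sets partitioning an AlignedDataset."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray

    def check_partition(self, n_frames: int) -> bool:
        joined = np.concatenate([self.train, self.val, self.test])
        return (len(joined) == n_frames
                and np.array_equal(np.sort(joined), np.arange(n_frames)))


def split_by_bout(dataset: AlignedDataset, cws: float | None = None) -> Split:
    """Bouts nearest the CWS become validation (nearer) and test.

    Ties in distance are broken by assigning the earlier bout to validation.
    Requires at least three bouts so at least one remains for training.
    """
    cws = dataset.cws if cws is None else cws
    centers = dataset.bout_centers
    if len(centers) < 3:
        raise ValueError(f"need >= 3 bouts for a by-bout split, got {len(centers)}")
    dist = np.abs(centers - cws)
    order = np.lexsort((np.arange(len(centers)), dist))  # distance, then index
    val_b, test_b = int(order[0]), int(order[1])
    train_idx = np.flatnonzero(~np.isin(dataset.bout_id, [val_b, test_b]))
    return Split(train=train_idx,
                 val=dataset.frames_of_bout(val_b),
                 test=dataset.frames_of_bout(test_b))


def split_by_ratio(dataset: AlignedDataset, spec: SplitSpec) -> Split:
    """Per-bout contiguous split at the configured fractions.

    forward: the first f*N frames of each bout train, the next 0.10*N
    validate, the remainder tests; reverse: the last f*N train, the 0.10*N
    before them validate, the leading remainder tests.
    """
    f, fv = spec.train_fraction, spec.val_fraction
    train, val, test = [], [], []
    for b in range(len(dataset.bout_centers)):
        frames = dataset.frames_of_bout(b)
        n = len(frames)
        n_tr, n_val = int(round(f * n)), int(round(fv * n))
        if n_tr + n_val >= n:
            raise ValueError(f"bout {b} too short for fractions {f}+{fv}")
        if spec.strategy == "ratio_forward":
            train.append(frames[:n_tr])
            val.append(frames[n_tr:n_tr + n_val])
            test.append(frames[n_tr + n_val:])
        else:
            train.append(frames[n - n_tr:])
            val.append(frames[n - n_tr - n_val:n - n_tr])
            test.append(frames[:n - n_tr - n_val])
    return Split(train=np.concatenate(train), val=np.concatenate(val),
                 test=np.concatenate(test))


def make_split(dataset: AlignedDataset, spec: SplitSpec) -> Split:
    if spec.strategy == "by_bout":
        return split_by_bout(dataset)
    return split_by_ratio(dataset, spec)


# ---------------------------------------------------------------------------
# training

@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 500
    lr: float = 5e-4
    weight_decay: float = 1e-5
    batch_size: int = 256
    seed: int = 0
    selection: str = "best_val"      # best_val | last
    subsample: int = 1               # keep every n-th training sample
    val_subsample: int = 1           # keep every n-th validation sample

    def __post_init__(self):
        if self.epochs <= 0 or self.lr <= 0:
            raise ValueError("epochs and lr must be positive")

    @classmethod
    def reduced(cls, seed: int = 0, **kw) -> "TrainConfig":
        """Desk-scale preset: frame subsampling, fewer epochs."""
        defaults = dict(epochs=20, subsample=6, val_subsample=8,
                        batch_size=128, seed=seed)
        defaults.update(kw)
        return cls(**defaults)

    @classmethod
    def pretrain(cls, seed: int = 0, **kw) -> "TrainConfig":
        defaults = dict(epochs=1000, selection="last", seed=seed)
        defaults.update(kw)
        return cls(**defaults)


@dataclass
class TrainedModel:
    model: GRFEstimator
    history: pd.DataFrame
    best_epoch: int
    norm: NormConstants | None = None


def _loss_on(model: GRFEstimator, maps, seqs, y, batch_size: int) -> float:
    if len(y) == 0:
        return float("nan")
    pred = model.predict(maps, seqs, batch_size)
    return float(np.mean((pred - y) ** 2))


def train(model: GRFEstimator, data: dict, config: TrainConfig) -> TrainedModel:
    """Optimize ``model`` on ``data`` = {"train": SequenceSet, "val": SequenceSet}.

    Sequence sets carry the full 23-channel block; the channels the model's
    mode consumes are selected here.  Deterministic given config.seed.
    """
    spec = model.spec
    tr, va = data["train"], data["val"]
    idx = np.arange(0, len(tr), max(config.subsample, 1))
    maps_tr = tr.maps[idx] if spec.has_cnn else None
    seqs_tr = np.ascontiguousarray(select_channels(tr.seqs[idx], spec.mode))
    y_tr = tr.y[idx].astype(_nn.F32)
    vidx = np.arange(0, len(va), max(config.val_subsample, 1))
    maps_va = va.maps[vidx] if spec.has_cnn else None
    seqs_va = np.ascontiguousarray(select_channels(va.seqs[vidx], spec.mode))
    y_va = va.y[vidx].astype(_nn.F32)

    opt = _nn.Adam(model.parameters(), lr=config.lr, weight_decay=config.weight_decay)
    rng = np.random.default_rng(np.random.SeedSequence((int(config.seed), 777)))
    n = len(y_tr)
    best_val, best_state, best_epoch = np.inf, None, -1
    rows = []
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        running, nb = 0.0, 0
        for lo in range(0, n, config.batch_size):
            sel = perm[lo:lo + config.batch_size]
            pred = model.forward(None if maps_tr is None else maps_tr[sel],
                                 seqs_tr[sel])
            loss, grad = _nn.mse_loss(pred, y_tr[sel])
            if not np.isfinite(loss):
                raise RuntimeError(f"NaN/inf loss at epoch {epoch}, batch {lo // config.batch_size}"
                                   f" (lr={config.lr}, n={n})")
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            running += loss
            nb += 1
        val_loss = _loss_on(model, maps_va, seqs_va, y_va, 512)
        rows.append((epoch, running / max(nb, 1), val_loss))
        if config.selection == "best_val" and val_loss < best_val:
            best_val, best_state, best_epoch = val_loss, model.state_dict(), epoch
    if config.selection == "best_val" and best_state is not None:
        model.load_state_dict(best_state)
    else:
        best_epoch = config.epochs - 1
    history = pd.DataFrame(rows, columns=["epoch", "train_loss", "val_loss"])
    return TrainedModel(model=model, history=history, best_epoch=best_epoch)


# ---------------------------------------------------------------------------
# end-to-end helpers

@dataclass
class FitResult:
    trained: TrainedModel
    norm: NormConstants
    sets: dict            # "train"/"val"/"test" -> SequenceSet (23 channels)
    split: Split
    mode: str


def prepare_sets(dataset: AlignedDataset, split: Split,
                 sequence_len: int = 5) -> tuple[NormConstants, dict]:
    """Fit normalization on training frames; build per-subset sequence sets."""
    norm = fit_minmax(dataset, split.train)
    normed = apply_minmax(dataset, norm)
    sets = {name: make_sequences(normed, sequence_len, frames=getattr(split, name))
            for name in ("train", "val", "test")}
    return norm, sets


def fit_mode(dataset: AlignedDataset, split: Split, mode: str,
             config: TrainConfig, spec: ModelSpec | None = None) -> FitResult:
    """Normalize, build and train one input-configuration model on a split."""
    spec = spec or ModelSpec(mode=mode)
    if spec.mode != mode:
        spec = replace(spec, mode=mode)
    norm, sets = prepare_sets(dataset, split, spec.sequence_len)
    model = build_model(spec, seed=config.seed)
    trained = train(model, sets, config)
    trained.norm = norm
    return FitResult(trained=trained, norm=norm, sets=sets, split=split, mode=mode)


# ---------------------------------------------------------------------------
# transfer learning

def pretrain_pooled(healthy_sets: list, config: TrainConfig,
                    spec: ModelSpec | None = None) -> GRFEstimator:
    """Pre-train one model on the pooled training frames of >= 2 healthy legs.

    ``healthy_sets`` is a list of {"train": SequenceSet, "val": SequenceSet}
    (one per healthy session/leg, already normalized).  Last-epoch weights
    are returned, as used to initialize the individualized models.
    """
    if len(healthy_sets) < 2:
        raise ValueError("pooled pre-training needs at least two healthy sessions")
    widths = {s["train"].seqs.shape[2] for s in healthy_sets}
    if len(widths) != 1:
        raise ValueError(f"incompatible channel inventories across sessions: {widths}")
    pooled_train = _concat_sets([s["train"] for s in healthy_sets])
    pooled_val = _concat_sets([s["val"] for s in healthy_sets])
    spec = spec or ModelSpec(mode="fusion")
    model = build_model(spec, seed=config.seed)
    cfg = replace(config, selection="last")
    train(model, {"train": pooled_train, "val": pooled_val}, cfg)
    return model


def _concat_sets(sets: list) -> SequenceSet:
    return SequenceSet(
        maps=np.concatenate([s.maps for s in sets]),
        seqs=np.concatenate([s.seqs for s in sets]),
        y=np.concatenate([s.y for s in sets]),
        stride_id=np.concatenate([s.stride_id for s in sets]),
        bout_id=np.concatenate([s.bout_id for s in sets]),
        frame_idx=np.concatenate([s.frame_idx for s in sets]))


def restrict_split_fraction(dataset: AlignedDataset, split: Split,
                            fraction: float) -> Split:
    """Keep the last ``fraction`` of train+val frames per bout (test unchanged)."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return split
    train_mask = np.zeros(dataset.n_frames, dtype=bool)
    val_mask = np.zeros(dataset.n_frames, dtype=bool)
    train_mask[split.train] = True
    val_mask[split.val] = True
    new_train, new_val = [], []
    for b in range(len(dataset.bout_centers)):
        frames = dataset.frames_of_bout(b)
        tv = frames[train_mask[frames] | val_mask[frames]]
        keep = tv[int(round((1.0 - fraction) * len(tv))):]
        new_train.append(keep[train_mask[keep]])
        new_val.append(keep[val_mask[keep]])
    return Split(train=np.concatenate(new_train), val=np.concatenate(new_val),
                 test=split.test.copy())


def finetune(pretrained: GRFEstimator, dataset: AlignedDataset, split: Split,
             config: TrainConfig, fraction: float = 1.0) -> FitResult:
    """Fine-tune pre-trained weights on one clinical leg.

    ``fraction`` in {0.5, 1.0} keeps the last half or all of the train+val
    frames of each bout; the test set is unchanged.  Initialization comes
    from ``pretrained``; selection follows ``config`` (best-validation by
    default).
    """
    sub = restrict_split_fraction(dataset, split, fraction)
    norm, sets = prepare_sets(dataset, sub, pretrained.spec.sequence_len)
    model = build_model(pretrained.spec, seed=config.seed)
    model.load_state_dict(pretrained.state_dict())
    trained = train(model, sets, config)
    trained.norm = norm
    return FitResult(trained=trained, norm=norm, sets=sets, split=sub,
                     mode=pretrained.spec.mode)
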