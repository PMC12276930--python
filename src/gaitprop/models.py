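"""Estimator architectures: Insole only, IMU only, and IMU + Insole fusion.

All three map the aligned inputs of one frame to the AP GRF (%BW) at that
frame.  The insole branch is a small LeNet-style CNN over the 28 x 28
pressure map (kernels 5 and 3, 2 x 2 average pooling after each convolution,
then a dense layer of 84 units).  The time-series branch is a stack of three
bidirectional LSTM layers (128 hidden units each) over 5-step sequences of
the IMU and/or CoP channels, followed by dense layers of 256, 256 and 84
units.  Branch outputs are concatenated and merged by a dense layer (168
units in fusion mode, 84 in the single-input modes), then a 10-unit layer,
and finally a linear unit producing the signed %BW estimate.  ReLU follows
every layer except that final linear output.

The networks are built on the in-package numpy engine (`gaitprop._nn`);
initialization is fan-in uniform from a fixed seed, so two builds from the
same spec and seed have identical weights.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import _nn
from ._nn import (AvgPool2, BiLSTM, Conv2d, Flatten, Linear, Param, ReLU,
                  Sequential, TakeEnds)

MODES = ("insole_only", "imu_only", "fusion")

N_IMU_CHANNELS = 21
N_COP_CHANNELS = 2
MAP_SIZE = 28


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters of one input configuration."""

    mode: str = "fusion"
    conv_channels: tuple = (6, 16)
    conv_kernels: tuple = (5, 3)
    cnn_fc: int = 84
    lstm_layers: int = 3
    lstm_hidden: int = 128
    lstm_fc: tuple = (256, 256, 84)
    merge_fc_fusion: int = 168
    merge_fc_single: int = 84
    penultimate_fc: int = 10
    sequence_len: int = 5

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")

    @property
    def has_cnn(self) -> bool:
        return self.mode in ("insole_only", "fusion")

    @property
    def seq_channels(self) -> int:
        """LSTM input width per timestep: IMU channels plus CoP where used."""
        if self.mode == "fusion":
            return N_IMU_CHANNELS + N_COP_CHANNELS
        if self.mode == "imu_only":
            return N_IMU_CHANNELS
        return N_COP_CHANNELS  # insole_only: the LSTM consumes CoP only

    @property
    def merge_fc(self) -> int:
        return self.merge_fc_fusion if self.mode == "fusion" else self.merge_fc_single

    def spec_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("conv_channels", "conv_kernels", "lstm_fc"):
            data[key] = tuple(data[key])
        return cls(**data)


class GRFEstimator:
    """One leg's AP GRF estimator; built from a ModelSpec and a seed."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        c1, c2 = spec.conv_channels
        k1, k2 = spec.conv_kernels
        if spec.has_cnn:
            side = MAP_SIZE
            side = (side - k1 + 1) // 2      # conv1 + pool
            side = (side - k2 + 1) // 2      # conv2 + pool
            conv1 = Conv2d(1, c1, k1, rng, "conv1")
            conv1.needs_input_grad = False  # branch root: skip dL/dinput
            self.cnn = Sequential(
                conv1, ReLU(), AvgPool2(),
                Conv2d(c1, c2, k2, rng, "conv2"), ReLU(), AvgPool2(),
                Flatten(), Linear(c2 * side * side, spec.cnn_fc, rng, "cnn_fc"), ReLU())
        else:
            self.cnn = None
        layers = []
        n_in = spec.seq_channels
        for i in range(spec.lstm_layers):
            bl = BiLSTM(n_in, spec.lstm_hidden, rng, f"bilstm{i + 1}")
            if i == 0:
                bl.needs_input_grad = False  # branch root: skip dL/dinput
            layers.append(bl)
            n_in = 2 * spec.lstm_hidden
        layers.append(TakeEnds(spec.lstm_hidden))
        for i, width in enumerate(spec.lstm_fc):
            layers.append(Linear(n_in, width, rng, f"lstm_fc{i + 1}"))
            layers.append(ReLU())
            n_in = width
        self.lstm = Sequential(*layers)

        merge_in = spec.lstm_fc[-1] + (spec.cnn_fc if spec.has_cnn else 0)
        self.head = Sequential(
            Linear(merge_in, spec.merge_fc, rng, "merge"), ReLU(),
            Linear(spec.merge_fc, spec.penultimate_fc, rng, "penultimate"), ReLU(),
            Linear(spec.penultimate_fc, 1, rng, "out"))
        self._branch_width = spec.lstm_fc[-1]

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> list[Param]:
        params = []
        if self.cnn is not None:
            params += self.cnn.params()
        params += self.lstm.params() + self.head.params()
        return params

    def count_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def state_dict(self) -> dict:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state dict does not match the model spec")
        for i, p in enumerate(params):
            arr = state[f"p{i}"]
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for parameter {i}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data[...] = arr

    # -- forward / backward -------------------------------------------------

    def _check_batch(self, maps, seqs):
        spec = self.spec
        if seqs.ndim != 3 or seqs.shape[1] != spec.sequence_len \
                or seqs.shape[2] != spec.seq_channels:
            raise ValueError(f"expected sequences (B, {spec.sequence_len}, "
                             f"{spec.seq_channels}), got {seqs.shape}")
        if not np.all(np.isfinite(seqs)):
            raise ValueError("non-finite values in sequence input")
        if spec.has_cnn:
            if maps is None or maps.ndim != 4 or maps.shape[1] != 1 \
                    or maps.shape[2:] != (MAP_SIZE, MAP_SIZE):
                raise ValueError(f"expected maps (B, 1, {MAP_SIZE}, {MAP_SIZE})")
            if not np.all(np.isfinite(maps)):
                raise ValueError("non-finite values in pressure-map input")

    def forward(self, maps, seqs) -> np.ndarray:
        """Estimate AP GRF (%BW), one scalar per sample."""
        seqs = np.ascontiguousarray(seqs, dtype=_nn.F32)
        maps = None if maps is None else np.ascontiguousarray(maps, dtype=_nn.F32)
        self._check_batch(maps, seqs)
        seq_out = self.lstm.forward(seqs)
        if self.cnn is not None:
            cnn_out = self.cnn.forward(maps)
            merged = np.concatenate([cnn_out, seq_out], axis=1)
        else:
            merged = seq_out
        return self.head.forward(merged)[:, 0]

    def backward(self, dout: np.ndarray) -> None:
        g = self.head.backward(dout[:, None].astype(_nn.F32))
        if self.cnn is not None:
            w = self.spec.cnn_fc
            self.cnn.backward(np.ascontiguousarray(g[:, :w]))
            self.lstm.backward(np.ascontiguousarray(g[:, w:]))
        else:
            self.lstm.backward(g)

    def predict(self, maps, seqs, batch_size: int = 512) -> np.ndarray:
        """Inference in batches (no gradient caches kept alive)."""
        out = np.empty(len(seqs), dtype=_nn.F32)
        for lo in range(0, len(seqs), batch_size):
            hi = lo + batch_size
            out[lo:hi] = self.forward(None if maps is None else maps[lo:hi],
                                      seqs[lo:hi])
        return out


def build_model(spec: ModelSpec, seed: int = 0) -> GRFEstimator:
    """Construct an untrained estimator from its spec (seeded init)."""
    return GRFEstimator(spec, seed)


def count_parameters(model: GRFEstimator) -> int:
    return model.count_parameters()


def select_channels(seqs: np.ndarray, mode: str) -> np.ndarray:
    """Slice a full (M, L, 23) IMU+CoP sequence block for a model mode."""
    if mode == "fusion":
        return seqs
    if mode == "imu_only":
        return seqs[:, :, :N_IMU_CHANNELS]
    if mode == "insole_only":
        return seqs[:, :, N_IMU_CHANNELS:N_IMU_CHANNELS + N_COP_CHANNELS]
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(path, model: GRFEstimator, extra: dict | None = None) -> None:
    """Portable .npz checkpoint with a spec-hash guard."""
    meta = {"spec": json.dumps(asdict(model.spec), default=list),
            "spec_hash": model.spec.spec_hash(), "seed": model.seed}
    if extra:
        meta.update({f"x_{k}": v for k, v in extra.items()})
    np.savez(path, __meta__=json.dumps(meta, default=str), **model.state_dict())


def load_checkpoint(path, spec: ModelSpec | None = None) -> GRFEstimator:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        stored = json.loads(meta["spec"])
        for key in ("conv_channels", "conv_kernels", "lstm_fc"):
            stored[key] = tuple(stored[key])
        file_spec = ModelSpec(**stored)
        if spec is not None and spec.spec_hash() != file_spec.spec_hash():
            raise ValueError("checkpoint spec hash does not match the requested spec")
        model = GRFEstimator(file_spec, seed=int(meta["seed"]))
        model.load_state_dict({k: data[k] for k in data.files if k.startswith("p")})
    return model
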