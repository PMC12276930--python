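"""Signal conditioning, gait-event detection, multi-rate alignment and
dataset construction.

The chain, applied per bout and per side:

1. per-sensel insole zeroing over a detected foot-off window;
2. zero-phase 2nd-order Butterworth low-pass (10 Hz) on insole, IMU and
   force-plate signals;
3. spatial Gaussian smoothing (sigma = 0.5 grid units) of the insole frames
   on the native 233-sensel layout, mask-renormalized;
4. heel-strike / toe-off detection independently from force-plate vertical
   GRF and insole total pressure (threshold fraction of per-stride peak,
   debounced);
5. stride-matched clock correction of the insole stream against the force
   plate, known-offset correction of the IMU stream, linear interpolation
   of everything onto a common 100 Hz grid; force targets averaged within
   each 10 ms bin and scaled to %BW;
6. per-trial swing-baseline subtraction (first stride's swing);
7. area-interpolation resize of each pressure frame to a 28 x 28 map;
8. stance masking, stride labelling, min-max normalization (training frames
   only) and fixed-length sequence construction for the estimators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, filtfilt

from .synthgait import (GRID_COLS, GRID_ROWS, IMU_HZ, N_SENSELS, SENSEL_LAYOUT,
                        Bout, RawSession, InsoleStream, G, SIDES,
                        imu_channel_names)

log = logging.getLogger("gaitprop.preprocess")

MAP_SIZE = 28

# IMU normalization groups: one (sensor, signal-type) block shares constants
IMU_GROUPS = {
    "foot_acc": slice(0, 3), "shank_acc": slice(3, 6),
    "foot_gyro": slice(6, 9), "shank_gyro": slice(9, 12), "thigh_gyro": slice(12, 15),
    "foot_ang": slice(15, 17), "shank_ang": slice(17, 19), "thigh_ang": slice(19, 21),
}


@dataclass(frozen=True)
class PreprocConfig:
    butter_order: int = 2
    cutoff_hz: float = 10.0
    gaussian_sigma: float = 0.5        # grid units on the 233-sensel layout
    target_rate_hz: int = 100
    map_size: int = MAP_SIZE
    sequence_len: int = 5
    stance_threshold: float = 0.03     # fraction of per-stride peak vertical load
    min_event_gap: float = 0.4         # s, heel-strike debounce
    insole_zero_window: float = 0.3    # s, length of the foot-off zeroing window

    def __post_init__(self):
        if self.cutoff_hz >= self.target_rate_hz / 2:
            raise ValueError("cutoff must be below the target Nyquist rate")
        if self.sequence_len < 1:
            raise ValueError("sequence_len must be >= 1")


# ---------------------------------------------------------------------------
# filtering

def lowpass_zero_phase(signal: np.ndarray, fs: float,
                       config: PreprocConfig | None = None) -> np.ndarray:
    """Forward-backward (zero-phase) Butterworth low-pass along axis 0.

    Unit DC gain; the effective magnitude response is |H|^2, so a 2nd-order
    filter attenuates a sine at the cutoff frequency to 1/2 amplitude.
    """
    config = config or PreprocConfig()
    if fs <= 2 * config.cutoff_hz:
        raise ValueError(f"sampling rate {fs} Hz too low for {config.cutoff_hz} Hz cutoff")
    b, a = butter(config.butter_order, config.cutoff_hz, fs=fs)
    padlen = 3 * max(len(a), len(b))
    if signal.shape[0] <= padlen:
        raise ValueError(f"signal of length {signal.shape[0]} too short to filter "
                         f"(need > {padlen} samples)")
    return filtfilt(b, a, signal, axis=0)


# ---------------------------------------------------------------------------
# insole zeroing

def find_foot_off_window(total: np.ndarray, fs: float, window_s: float) -> slice:
    """Locate a low-pressure (swing) window of the requested length.

    The candidate is the rolling window with the lowest mean total pressure.
    Because per-sensel offsets keep even unloaded frames well above zero,
    "foot off" is recognized by contrast: a sustained run of frames near the
    signal floor must exist, clearly below the loaded level.  A perfectly
    flat zero signal is accepted as trivially load-free.
    """
    win = max(int(round(window_s * fs)), 1)
    if len(total) < win:
        raise ValueError("stream shorter than the zeroing window")
    kernel = np.ones(win) / win
    rolling = np.convolve(total, kernel, mode="valid")
    floor, hi = float(rolling.min()), float(np.percentile(total, 95))
    if hi - floor < 1e-9:
        return slice(0, win)  # numerically flat stream (e.g. all zero)
    low = total <= floor + 0.3 * (hi - floor)
    run, best = 0, 0
    for flag in low:
        run = run + 1 if flag else 0
        best = max(best, run)
    if best < win:
        raise ValueError("no foot-off interval found")
    start = int(np.argmin(rolling))
    return slice(start, start + win)


def zero_insole(stream: InsoleStream, config: PreprocConfig | None = None) -> InsoleStream:
    """Subtract per-sensel offsets measured during a detected foot-off window."""
    config = config or PreprocConfig()
    fs = 1.0 / float(np.median(np.diff(stream.timestamps)))
    total = stream.pressure.sum(axis=1)
    try:
        window = find_foot_off_window(total, fs, config.insole_zero_window)
    except ValueError as err:
        raise ValueError(f"insole stream ({stream.side}): {err}") from None
    offsets = stream.pressure[window].mean(axis=0)
    return replace(stream, pressure=stream.pressure - offsets[None, :])


# ---------------------------------------------------------------------------
# spatial Gaussian on the sensel layout

_GAUSS_CACHE: dict = {}


def _gaussian_operator(sigma: float) -> np.ndarray:
    """(233, 233) mask-renormalized Gaussian smoothing operator."""
    key = round(float(sigma), 9)
    if key in _GAUSS_CACHE:
        return _GAUSS_CACHE[key]
    if sigma <= 1e-9:
        op = np.eye(N_SENSELS)
    else:
        radius = max(int(np.ceil(3.0 * sigma)), 1)
        coords = SENSEL_LAYOUT.astype(float)
        dr = coords[:, None, 0] - coords[None, :, 0]
        dc = coords[:, None, 1] - coords[None, :, 1]
        k = np.exp(-(dr ** 2 + dc ** 2) / (2.0 * sigma ** 2))
        k[(np.abs(dr) > radius) | (np.abs(dc) > radius)] = 0.0
        op = k / k.sum(axis=1, keepdims=True)
    _GAUSS_CACHE[key] = op
    return op


def spatial_gaussian(frames: np.ndarray, sigma: float = 0.5) -> np.ndarray:
    """Mask-respecting spatial Gaussian filter of insole frames (..., 233)."""
    return frames @ _gaussian_operator(sigma).T


# ---------------------------------------------------------------------------
# gait events

def detect_heel_strikes(v_signal: np.ndarray, fs: float, threshold: float = 0.03,
                        min_gap: float = 0.4, coarse_threshold: float = 0.3):
    """Heel-strike / toe-off indices from a vertical load signal.

    A first pass segments strides at rising crossings of a coarse threshold
    (``coarse_threshold`` x the robust global peak, debounced by ``min_gap``
    seconds), which keeps swing-phase sensor noise from spawning spurious
    events; each event is then refined to the rising crossing of
    ``threshold`` x the per-stride peak, and toe-off is the subsequent
    falling crossing of the same local threshold.  Returns
    (heel_strike_indices, toe_off_indices); empty arrays (with a warning)
    when no events are present.
    """
    v = np.asarray(v_signal, dtype=float)
    peak = float(np.percentile(v, 95))
    if peak <= 0:
        log.warning("no gait events: signal has no positive load")
        return np.array([], dtype=int), np.array([], dtype=int)
    gap = int(round(min_gap * fs))
    thr = coarse_threshold * peak
    above = v >= thr
    rising = np.flatnonzero(~above[:-1] & above[1:]) + 1
    falling = np.flatnonzero(above[:-1] & ~above[1:]) + 1
    hs = []
    for idx in rising:
        if not hs or idx - hs[-1] >= gap:
            hs.append(int(idx))
    hs = np.array(hs, dtype=int)
    if hs.size == 0:
        log.warning("no gait events detected")
        return hs, np.array([], dtype=int)

    # noise floor of the unloaded phase: keeps the refined threshold above
    # the summed sensor noise of e.g. an insole total-pressure signal
    low = v[v <= np.percentile(v, 25)]
    noise_floor = float(np.median(low) + 4.0 * 1.4826
                        * np.median(np.abs(low - np.median(low))))

    # refine each heel strike against the local (per-stride) peak
    refined = []
    bounds = np.concatenate([hs, [len(v)]])
    for i, idx in enumerate(hs):
        local_peak = v[idx:bounds[i + 1]].max()
        local_thr = max(threshold * local_peak, noise_floor)
        j = idx
        while j > 0 and v[j - 1] >= local_thr:
            j -= 1
        while j < len(v) - 1 and v[j] < local_thr:
            j += 1
        refined.append(j)
    hs = np.array(refined, dtype=int)

    toe = []
    for i, idx in enumerate(hs):
        seg_end = bounds[i + 1] if i + 1 < len(bounds) else len(v)
        local_thr = max(threshold * v[idx:seg_end].max(), noise_floor)
        below = np.flatnonzero(v[idx:seg_end] < local_thr)
        toe.append(int(idx + below[0]) if below.size else int(seg_end - 1))
    return hs, np.array(toe, dtype=int)


# ---------------------------------------------------------------------------
# area-interpolation resize

_RESIZE_CACHE: dict = {}


def _overlap_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic (n_out, n_in) box-overlap matrix: output cell i covers
    [i*n_in/n_out, (i+1)*n_in/n_out) of the input axis."""
    key = (n_in, n_out)
    if key in _RESIZE_CACHE:
        return _RESIZE_CACHE[key]
    scale = n_in / n_out
    mat = np.zeros((n_out, n_in))
    for i in range(n_out):
        lo, hi = i * scale, (i + 1) * scale
        for r in range(int(np.floor(lo)), min(int(np.ceil(hi)), n_in)):
            mat[i, r] = max(0.0, min(hi, r + 1) - max(lo, r))
    mat /= scale
    _RESIZE_CACHE[key] = mat
    return mat


def embed_frame(frame_233: np.ndarray) -> np.ndarray:
    """Place sensel values on the native (31, 11) bounding grid (off-mask 0)."""
    out = np.zeros(frame_233.shape[:-1] + (GRID_ROWS, GRID_COLS), dtype=frame_233.dtype)
    out[..., SENSEL_LAYOUT[:, 0], SENSEL_LAYOUT[:, 1]] = frame_233
    return out


def resize_pressure_map(frame_233: np.ndarray, map_size: int = MAP_SIZE) -> np.ndarray:
    """Area-weighted (box) interpolation of one 233-sensel frame to a square map.

    The frame is embedded on its 31 x 11 bounding grid with off-mask cells
    zero; each output pixel averages the input cells it overlaps, weighted
    by overlap area, which preserves constants and the grid mean exactly.
    """
    grid = embed_frame(np.asarray(frame_233, dtype=float))
    rmat = _overlap_matrix(GRID_ROWS, map_size)
    cmat = _overlap_matrix(GRID_COLS, map_size)
    return rmat @ grid @ cmat.T


def _resize_batch(frames: np.ndarray, map_size: int = MAP_SIZE) -> np.ndarray:
    grids = embed_frame(np.ascontiguousarray(frames, dtype=np.float32))
    rmat = _overlap_matrix(GRID_ROWS, map_size).astype(np.float32)
    cmat = _overlap_matrix(GRID_COLS, map_size).astype(np.float32)
    # (N,31,11)@(11,28) -> (N,31,28), then (28,31)@(N,31,28) -> (N,28,28)
    return np.matmul(rmat, grids @ cmat.T)


# ---------------------------------------------------------------------------
# aligned dataset

@dataclass
class AlignedDataset:
    """100 Hz synchronized frames of one leg across bouts."""

    t: np.ndarray             # s within bout
    maps: np.ndarray          # (N, 28, 28) float32
    cop: np.ndarray           # (N, 2)
    imu: np.ndarray           # (N, 21)
    ap_grf: np.ndarray        # %BW target
    v_grf: np.ndarray         # %BW
    stance: np.ndarray        # bool
    stride_id: np.ndarray     # int, -1 outside stance strides
    bout_id: np.ndarray       # int
    side: str
    bout_centers: np.ndarray  # m/s commanded centre speed per bout id
    cws: float
    channel_names: list = field(default_factory=imu_channel_names)
    norm: "NormConstants | None" = None

    @property
    def n_frames(self) -> int:
        return len(self.t)

    def frames_of_bout(self, b: int) -> np.ndarray:
        return np.flatnonzero(self.bout_id == b)


@dataclass
class NormConstants:
    """Per-group min/span constants of min-max normalization."""

    groups: dict  # name -> (min, span)

    def as_arrays(self):
        names = sorted(self.groups)
        return names, np.array([self.groups[n] for n in names], dtype=np.float64)

    @classmethod
    def from_arrays(cls, names, arr):
        return cls({n: (float(a[0]), float(a[1])) for n, a in zip(names, arr)})


def fit_minmax(dataset: AlignedDataset, train_idx: np.ndarray) -> NormConstants:
    """Min-max constants from the training frames only.

    Groups: the whole pressure map, the CoP pair, and one block per IMU
    sensor and signal type (a 3-axis acceleration block shares constants).
    Degenerate groups (max == min) get span 1 so they map to 0.
    """
    groups = {}

    def add(name, values):
        lo, hi = float(values.min()), float(values.max())
        span = hi - lo
        if span <= 0:
            log.warning("degenerate normalization group %r (constant channel)", name)
            span = 1.0
        groups[name] = (lo, span)

    add("pressure", dataset.maps[train_idx])
    add("cop", dataset.cop[train_idx])
    for name, sl in IMU_GROUPS.items():
        add(name, dataset.imu[train_idx, sl])
    return NormConstants(groups)


def apply_minmax(dataset: AlignedDataset, norm: NormConstants) -> AlignedDataset:
    """Normalized copy of the dataset (targets stay in %BW, no clipping)."""
    g = norm.groups
    maps = ((dataset.maps - g["pressure"][0]) / g["pressure"][1]).astype(np.float32)
    cop = (dataset.cop - g["cop"][0]) / g["cop"][1]
    imu = dataset.imu.copy()
    for name, sl in IMU_GROUPS.items():
        lo, span = g[name]
        imu[:, sl] = (imu[:, sl] - lo) / span
    return replace(dataset, maps=maps, cop=cop, imu=imu, norm=norm)


# ---------------------------------------------------------------------------
# alignment

def _bin_average(x: np.ndarray, factor: int) -> np.ndarray:
    n = (len(x) // factor) * factor
    return x[:n].reshape(-1, factor).mean(axis=1)


def align_bout(bout: Bout, side: str, subject, config: PreprocConfig,
               imu_offset: float = 0.0) -> dict:
    """Synchronize one bout's streams onto the 100 Hz force-plate grid.

    The insole clock is recovered stride-by-stride from independently
    detected heel strikes; the IMU clock correction is the known offset
    from the acquisition-time synchronization (``imu_offset``).
    """
    fs_fp = 2000.0
    fs_ins = 50.0
    duration = bout.profile.duration
    to_pctbw = 100.0 / (subject.bodyweight * G)

    fp = bout.kinetics[side].force_plate
    ap = lowpass_zero_phase(fp.ap_grf, fs_fp, config) * to_pctbw
    vg = lowpass_zero_phase(fp.v_grf, fs_fp, config) * to_pctbw

    factor = int(round(fs_fp / config.target_rate_hz))
    ap100 = _bin_average(ap, factor)
    vg100 = _bin_average(vg, factor)
    t_grid = np.arange(len(ap100)) / config.target_rate_hz

    hs_fp_idx, to_fp_idx = detect_heel_strikes(vg, fs_fp, config.stance_threshold,
                                               config.min_event_gap)
    hs_fp = hs_fp_idx / fs_fp
    to_fp = to_fp_idx / fs_fp

    # --- insole: zero, filter, spatial smooth, clock-correct, resample
    ins = zero_insole(bout.insole[side], config)
    pressure = lowpass_zero_phase(ins.pressure, fs_ins, config)
    pressure = spatial_gaussian(pressure, config.gaussian_sigma)
    total = pressure.sum(axis=1)
    hs_ins_idx, _ = detect_heel_strikes(total, fs_ins, config.stance_threshold,
                                        config.min_event_gap)
    # sub-sample mid-rise (50 % of local peak) crossings are steep, hence
    # nearly noise- and quantization-free timing features on both signals
    rise_ins = _mid_rise_times(total, fs_ins, hs_ins_idx)
    rise_fp = _mid_rise_times(vg, fs_fp, hs_fp_idx)
    t_ins_true = _corrected_time(ins.timestamps, rise_ins, rise_fp)

    cop = bout.insole[side].cop
    pressure_g = _interp_columns(t_grid, t_ins_true, pressure)
    cop_g = _interp_columns(t_grid, t_ins_true, cop)

    # --- IMU: filter, known-offset correction, resample
    imu = bout.imu[side]
    mat = np.stack([imu.channels[n] for n in imu_channel_names(side)], axis=1)
    mat = lowpass_zero_phase(mat, float(IMU_HZ), config)
    t_imu_true = imu.timestamps + imu_offset
    imu_g = _interp_columns(t_grid, t_imu_true, mat)

    # --- stance segmentation on the grid (force-plate events)
    stance = np.zeros(len(t_grid), dtype=bool)
    stride_id = np.full(len(t_grid), -1, dtype=int)
    dropped = 0
    for k, (h, to) in enumerate(zip(hs_fp, to_fp)):
        sel = (t_grid >= h) & (t_grid < to)
        if not np.any(sel):
            dropped += 1
            continue
        stance[sel] = True
        stride_id[sel] = k
    if dropped:
        log.info("bout %s/%s: %d empty strides dropped", side, bout.center, dropped)

    # --- swing-baseline subtraction (first stride's swing in this trial)
    pressure_g = _swing_subtract(pressure_g, t_grid, hs_fp, to_fp)

    maps = _resize_batch(pressure_g, config.map_size)
    return {"t": t_grid, "maps": maps, "cop": cop_g, "imu": imu_g,
            "ap": ap100, "vg": vg100, "stance": stance, "stride_id": stride_id,
            "hs": hs_fp, "to": to_fp, "duration": duration}


def _mid_rise_times(v: np.ndarray, fs: float, hs_idx: np.ndarray,
                    frac: float = 0.5) -> np.ndarray:
    """Sub-sample time of the rising ``frac`` x local-peak crossing per stride."""
    out = []
    bounds = np.concatenate([hs_idx, [len(v)]])
    for i, idx in enumerate(hs_idx):
        seg = v[idx:bounds[i + 1]]
        if seg.size < 2:
            continue
        thr = frac * seg.max()
        above = np.flatnonzero(seg >= thr)
        if above.size == 0 or above[0] == 0:
            j = idx + (above[0] if above.size else 0)
            out.append(j / fs)
            continue
        j = idx + above[0]
        t = (j - 1 + (thr - v[j - 1]) / (v[j] - v[j - 1])) / fs
        out.append(t)
    return np.asarray(out)


def _corrected_time(t_rec: np.ndarray, hs_rec: np.ndarray,
                    hs_ref: np.ndarray) -> np.ndarray:
    """True acquisition times from stride-matched event pairs.

    For each reference (force-plate) heel strike, the nearest recorded-clock
    event within 0.25 s is matched; per-pair offsets are outlier-rejected
    around their median, smoothed with a short running mean, and
    interpolated piecewise-linearly over the bout (edges held)."""
    if len(hs_rec) == 0 or len(hs_ref) == 0:
        return t_rec
    pairs_t, pairs_off = [], []
    for h_ref in hs_ref:
        j = int(np.argmin(np.abs(hs_rec - h_ref)))
        if abs(hs_rec[j] - h_ref) <= 0.25:
            pairs_t.append(hs_rec[j])
            pairs_off.append(h_ref - hs_rec[j])
    if not pairs_t:
        log.warning("no matched heel strikes; insole clock left uncorrected")
        return t_rec
    pairs_t = np.asarray(pairs_t)
    pairs_off = np.asarray(pairs_off)
    med = np.median(pairs_off)
    good = np.abs(pairs_off - med) <= 0.03  # reject mismatched event pairs
    if good.any():
        pairs_t, pairs_off = pairs_t[good], pairs_off[good]
    if len(pairs_off) >= 9:  # smooth per-stride jitter of the crossing times
        kernel = np.ones(9) / 9.0
        pad = np.concatenate([np.repeat(pairs_off[0], 4), pairs_off,
                              np.repeat(pairs_off[-1], 4)])
        pairs_off = np.convolve(pad, kernel, mode="valid")
    return t_rec + np.interp(t_rec, pairs_t, pairs_off)


def _interp_columns(t_out: np.ndarray, t_in: np.ndarray, values: np.ndarray) -> np.ndarray:
    out = np.empty((len(t_out), values.shape[1]))
    for j in range(values.shape[1]):
        out[:, j] = np.interp(t_out, t_in, values[:, j])
    return out


def _swing_subtract(pressure: np.ndarray, t: np.ndarray, hs: np.ndarray,
                    to: np.ndarray) -> np.ndarray:
    """Remove the per-sensel mean over the first stride's swing phase."""
    for k in range(len(hs)):
        end = hs[k + 1] if k + 1 < len(hs) else t[-1]
        sel = (t >= to[k]) & (t < end)
        if np.count_nonzero(sel) >= 3:
            if k > 0:
                log.warning("first-stride swing unavailable; using stride %d", k)
            return pressure - pressure[sel].mean(axis=0)[None, :]
    log.warning("no swing interval found; baseline subtraction skipped")
    return pressure


def preprocess_session(session: RawSession, config: PreprocConfig | None = None) -> dict:
    """Run the full chain; returns {side: AlignedDataset} (all bouts stacked)."""
    config = config or PreprocConfig()
    out = {}
    for side in SIDES:
        parts = []
        for b, bout in enumerate(session.bouts):
            al = align_bout(bout, side, session.subject, config,
                            imu_offset=session.offsets.imu)
            al["bout"] = b
            parts.append(al)
        n = sum(len(p["t"]) for p in parts)
        stride_off = 0
        t = np.concatenate([p["t"] for p in parts])
        maps = np.concatenate([p["maps"] for p in parts])
        cop = np.concatenate([p["cop"] for p in parts])
        imu = np.concatenate([p["imu"] for p in parts])
        ap = np.concatenate([p["ap"] for p in parts])
        vg = np.concatenate([p["vg"] for p in parts])
        stance = np.concatenate([p["stance"] for p in parts])
        stride_id = []
        bout_id = []
        for p in parts:
            sid = p["stride_id"].copy()
            sid[sid >= 0] += stride_off
            stride_off += len(p["hs"])
            stride_id.append(sid)
            bout_id.append(np.full(len(p["t"]), p["bout"], dtype=int))
        dataset = AlignedDataset(
            t=t, maps=maps, cop=cop, imu=imu, ap_grf=ap, v_grf=vg,
            stance=stance, stride_id=np.concatenate(stride_id),
            bout_id=np.concatenate(bout_id), side=side,
            bout_centers=np.array([b.profile.v2 for b in session.bouts]),
            cws=session.subject.cws)
        assert dataset.n_frames == n
        out[side] = dataset
    return out


# ---------------------------------------------------------------------------
# sequences

@dataclass
class SequenceSet:
    """Per-stance-frame training samples: CNN map + LSTM sequence + target."""

    maps: np.ndarray        # (M, 1, 28, 28) float32
    seqs: np.ndarray        # (M, L, 23) float32 — 21 IMU channels then CoP (row, col)
    y: np.ndarray           # (M,) %BW
    stride_id: np.ndarray
    bout_id: np.ndarray
    frame_idx: np.ndarray   # index into the parent AlignedDataset

    def __len__(self):
        return len(self.y)

    def subset(self, idx: np.ndarray) -> "SequenceSet":
        return SequenceSet(self.maps[idx], self.seqs[idx], self.y[idx],
                           self.stride_id[idx], self.bout_id[idx],
                           self.frame_idx[idx])


def make_sequences(dataset: AlignedDataset, sequence_len: int = 5,
                   frames: np.ndarray | None = None) -> SequenceSet:
    """One sample per retained stance frame.

    The LSTM input of frame t is frames [t-L+1 .. t] of the IMU + CoP
    channels restricted to the same stance segment; at a segment start the
    window is left-padded by repeating the first stance frame.  The CNN map
    and the target belong to frame t.
    """
    L = sequence_len
    stance_idx = np.flatnonzero(dataset.stance)
    if frames is not None:
        keep = np.zeros(dataset.n_frames, dtype=bool)
        keep[frames] = True
        stance_idx = stance_idx[keep[stance_idx]]
    # a stance frame starts a new segment when the previous frame is not a
    # stance frame of the same stride of the same bout
    stance = dataset.stance
    same_prev = np.zeros(dataset.n_frames, dtype=bool)
    same_prev[1:] = (stance[1:] & stance[:-1]
                     & (dataset.stride_id[1:] == dataset.stride_id[:-1])
                     & (dataset.bout_id[1:] == dataset.bout_id[:-1]))
    seg_start = np.arange(dataset.n_frames)
    for i in np.flatnonzero(same_prev):
        seg_start[i] = seg_start[i - 1]

    chan = np.concatenate([dataset.imu, dataset.cop], axis=1).astype(np.float32)
    idx = np.empty((len(stance_idx), L), dtype=int)
    for j in range(L):
        cand = stance_idx - (L - 1 - j)
        idx[:, j] = np.maximum(cand, seg_start[stance_idx])
    seqs = chan[idx]
    maps = dataset.maps[stance_idx][:, None, :, :]
    return SequenceSet(maps=maps, seqs=seqs,
                       y=dataset.ap_grf[stance_idx].astype(np.float32),
                       stride_id=dataset.stride_id[stance_idx],
                       bout_id=dataset.bout_id[stance_idx],
                       frame_idx=stance_idx)


# ---------------------------------------------------------------------------
# HDF5 persistence of aligned datasets

def save_aligned(datasets: dict, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        for side, ds in datasets.items():
            g = f.create_group(side)
            for name in ("t", "maps", "cop", "imu", "ap_grf", "v_grf",
                         "stance", "stride_id", "bout_id", "bout_centers"):
                g.create_dataset(name, data=getattr(ds, name))
            g.attrs["cws"] = ds.cws
            g.attrs["side"] = side
            if ds.norm is not None:
                names, arr = ds.norm.as_arrays()
                g.create_dataset("norm_values", data=arr)
                g.attrs["norm_names"] = names


def load_aligned(path) -> dict:
    import h5py

    out = {}
    with h5py.File(path, "r") as f:
        for side in f:
            g = f[side]
            norm = None
            if "norm_values" in g:
                norm = NormConstants.from_arrays(list(g.attrs["norm_names"]),
                                                 g["norm_values"][:])
            out[side] = AlignedDataset(
                t=g["t"][:], maps=g["maps"][:], cop=g["cop"][:], imu=g["imu"][:],
                ap_grf=g["ap_grf"][:], v_grf=g["v_grf"][:],
                stance=g["stance"][:].astype(bool), stride_id=g["stride_id"][:],
                bout_id=g["bout_id"][:], side=str(g.attrs["side"]),
                bout_centers=g["bout_centers"][:], cws=float(g.attrs["cws"]),
                norm=norm)
    return out
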