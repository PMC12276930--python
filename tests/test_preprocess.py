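"""Preprocessing: filtering, events, alignment, resize, normalization."""

import numpy as np
import pytest
from dataclasses import replace

from gaitprop.preprocess import (AlignedDataset, PreprocConfig, apply_minmax,
                                 detect_heel_strikes, embed_frame, fit_minmax,
                                 lowpass_zero_phase, make_sequences,
                                 preprocess_session, resize_pressure_map,
                                 save_aligned, load_aligned, spatial_gaussian,
                                 zero_insole, _swing_subtract, IMU_GROUPS)
from gaitprop.synthgait import (GRID_COLS, GRID_ROWS, N_SENSELS, SENSEL_LAYOUT,
                                ClockOffsets, InsoleStream, NoiseLevels,
                                layout_mask, simulate_insole, simulate_kinetics,
                                simulate_session)
from conftest import mini_clinical_session, mini_clinical_subject, mini_profile


# ---------------------------------------------------------------------------
# zero-phase low-pass filter

def test_lowpass_constant_signal_unchanged():
    x = np.full(5000, 3.7)
    assert np.allclose(lowpass_zero_phase(x, 2000.0), x)


def test_lowpass_gain_at_cutoff_is_half():
    """Forward-backward 2nd-order Butterworth: |H|^2 = 1/2 at the cutoff."""
    fs, f = 2000.0, 10.0
    t = np.arange(0, 4.0, 1 / fs)
    y = lowpass_zero_phase(np.sin(2 * np.pi * f * t), fs)
    core = slice(2000, 6000)
    ratio = np.sqrt(np.mean(y[core] ** 2) / 0.5)
    assert ratio == pytest.approx(0.5, rel=0.01)


def test_lowpass_zero_phase_no_lag():
    fs = 200.0
    t = np.arange(0, 10.0, 1 / fs)
    x = np.sin(2 * np.pi * 1.0 * t)
    y = lowpass_zero_phase(x, fs)
    lags = np.arange(-20, 21)
    corr = [np.dot(np.roll(y, k)[30:-30], x[30:-30]) for k in lags]
    assert lags[int(np.argmax(corr))] == 0


def test_lowpass_idempotent_for_band_limited_signal():
    fs = 100.0
    t = np.arange(0, 20.0, 1 / fs)
    x = np.sin(2 * np.pi * 2.0 * t) + 0.3 * np.sin(2 * np.pi * 4.0 * t)
    once = lowpass_zero_phase(x, fs)
    twice = lowpass_zero_phase(once, fs)
    rms = np.sqrt(np.mean((twice - once) ** 2)) / np.sqrt(np.mean(once ** 2))
    assert rms < 0.01


def test_lowpass_rejects_short_or_undersampled():
    with pytest.raises(ValueError):
        lowpass_zero_phase(np.zeros(5), 2000.0)
    with pytest.raises(ValueError):
        lowpass_zero_phase(np.zeros(1000), 15.0)


def test_preproc_config_validation():
    with pytest.raises(ValueError):
        PreprocConfig(cutoff_hz=60.0)
    with pytest.raises(ValueError):
        PreprocConfig(sequence_len=0)


# ---------------------------------------------------------------------------
# insole zeroing

def _square_stream(offset=0.0, n=600, fs=50.0):
    t = np.arange(n) / fs
    total = (np.sin(2 * np.pi * 0.8 * t) > 0.2).astype(float) * 30.0
    weights = np.full(N_SENSELS, 1.0 / N_SENSELS)
    pressure = total[:, None] * weights[None, :] + offset
    return InsoleStream(timestamps=t, pressure=pressure,
                        cop=np.zeros((n, 2)), side="left")


def test_zero_insole_removes_constant_offset_exactly():
    clean = _square_stream(0.0)
    shifted = _square_stream(2.5)
    out = zero_insole(shifted)
    assert np.allclose(out.pressure, clean.pressure, atol=1e-12)


def test_zero_insole_zero_input_stays_zero():
    stream = InsoleStream(np.arange(300) / 50.0, np.zeros((300, N_SENSELS)),
                          np.zeros((300, 2)), "left")
    out = zero_insole(stream)
    assert np.all(out.pressure == 0.0)


def test_zero_insole_errors_when_always_loaded():
    n = 600
    rng = np.random.default_rng(0)
    pressure = np.full((n, N_SENSELS), 5.0) + rng.normal(0, 0.002, (n, N_SENSELS))
    stream = InsoleStream(np.arange(n) / 50.0, pressure, np.zeros((n, 2)), "left")
    with pytest.raises(ValueError, match="left"):
        zero_insole(stream)


def test_zero_insole_recovers_simulated_offsets():
    subject = mini_clinical_subject(noise=NoiseLevels(0.0, 2.0, 0, 0, 0, 0.02))
    kin = simulate_kinetics(mini_profile(0.7, 100), subject, "left", 3)
    ins = simulate_insole(kin, subject, "left", 4)
    out = zero_insole(ins)
    total = out.pressure.sum(axis=1)
    swing = total < 0.05 * np.percentile(total, 95)
    assert np.abs(out.pressure[swing].mean(axis=0)).max() < 0.05


# ---------------------------------------------------------------------------
# spatial Gaussian on the layout

def test_spatial_gaussian_uniform_frame_unchanged():
    frame = np.full(N_SENSELS, 4.2)
    assert np.allclose(spatial_gaussian(frame, 0.5), frame)


def test_spatial_gaussian_interior_impulse_conserved():
    mask = layout_mask()
    # a deep-interior sensel: every neighbour within the kernel radius has
    # its own full kernel window inside the mask (9x9 block for radius 2)
    idx = None
    for i, (r, c) in enumerate(SENSEL_LAYOUT):
        if 4 <= r < GRID_ROWS - 4 and 4 <= c < GRID_COLS - 4 \
                and mask[r - 4:r + 5, c - 4:c + 5].all():
            idx = i
            break
    assert idx is not None
    frame = np.zeros(N_SENSELS)
    frame[idx] = 7.0
    out = spatial_gaussian(frame, 0.5)
    assert out.sum() == pytest.approx(7.0, rel=1e-9)


def test_spatial_gaussian_sigma_zero_is_identity():
    rng = np.random.default_rng(0)
    frame = rng.random(N_SENSELS)
    assert np.allclose(spatial_gaussian(frame, 0.0), frame)


# ---------------------------------------------------------------------------
# gait events

def test_detect_no_events_on_zero_signal():
    hs, to = detect_heel_strikes(np.zeros(5000), 2000.0)
    assert hs.size == 0 and to.size == 0


def test_detect_heel_strikes_within_10ms_of_truth():
    subject = mini_clinical_subject()
    kin = simulate_kinetics(mini_profile(0.7, 100), subject, "left", 5)
    vg = lowpass_zero_phase(kin.force_plate.v_grf, 2000.0)
    hs, to = detect_heel_strikes(vg, 2000.0)
    truth = kin.events.heel_strike_times
    assert len(hs) == len(truth)
    assert np.max(np.abs(hs / 2000.0 - truth)) < 0.010
    truth_to = kin.events.toe_off_times
    assert np.median(np.abs(to / 2000.0 - truth_to)) < 0.015


def test_forceplate_and_insole_detectors_agree():
    """Per-stride timing features from the two independent detectors line up."""
    from gaitprop.preprocess import _mid_rise_times

    subject = mini_clinical_subject()
    kin = simulate_kinetics(mini_profile(0.7, 100), subject, "left", 6)
    ins = simulate_insole(kin, subject, "left", 7)  # no clock offset here
    vg = lowpass_zero_phase(kin.force_plate.v_grf, 2000.0)
    hs_fp, _ = detect_heel_strikes(vg, 2000.0)
    total = spatial_gaussian(lowpass_zero_phase(zero_insole(ins).pressure, 50.0), 0.5).sum(1)
    hs_ins, _ = detect_heel_strikes(total, 50.0)
    assert abs(len(hs_ins) - len(hs_fp)) <= 1
    t_fp = _mid_rise_times(vg, 2000.0, hs_fp)
    t_ins = _mid_rise_times(total, 50.0, hs_ins)
    offsets = [t_fp[np.argmin(np.abs(t_fp - t))] - t for t in t_ins
               if np.abs(t_fp - t).min() < 0.25]
    assert abs(np.median(offsets)) < 0.020


# ---------------------------------------------------------------------------
# area-interpolation resize

def brute_force_resize(grid, n_out):
    """Independent area-overlap oracle, cell-by-cell."""
    n_r, n_c = grid.shape
    out = np.zeros((n_out, n_out))
    sr, sc = n_r / n_out, n_c / n_out
    for i in range(n_out):
        for j in range(n_out):
            r_lo, r_hi = i * sr, (i + 1) * sr
            c_lo, c_hi = j * sc, (j + 1) * sc
            acc = 0.0
            for r in range(int(np.floor(r_lo)), int(np.ceil(r_hi))):
                for c in range(int(np.floor(c_lo)), int(np.ceil(c_hi))):
                    dr = max(0.0, min(r + 1, r_hi) - max(r, r_lo))
                    dc = max(0.0, min(c + 1, c_hi) - max(c, c_lo))
                    acc += grid[r, c] * dr * dc
            out[i, j] = acc / (sr * sc)
    return out


def test_resize_constant_and_zero_frames():
    const = np.full(N_SENSELS, 3.0)
    grid_const = embed_frame(const)
    # area interpolation of the *embedded* grid preserves the constant grid
    assert np.allclose(resize_pressure_map(np.zeros(N_SENSELS)), 0.0)
    assert np.allclose(brute_force_resize(grid_const, 28),
                       resize_pressure_map(const))
    # a fully constant embedded grid maps to the same constant everywhere
    full = np.ones((GRID_ROWS, GRID_COLS)) * 3.0
    from gaitprop.preprocess import _overlap_matrix
    out = _overlap_matrix(GRID_ROWS, 28) @ full @ _overlap_matrix(GRID_COLS, 28).T
    assert np.allclose(out, 3.0)


def test_resize_matches_brute_force_oracle_and_preserves_mean():
    rng = np.random.default_rng(42)
    for _ in range(20):
        frame = rng.random(N_SENSELS) * 10
        ours = resize_pressure_map(frame)
        oracle = brute_force_resize(embed_frame(frame), 28)
        assert np.max(np.abs(ours - oracle)) < 1e-6
        assert ours.mean() == pytest.approx(embed_frame(frame).mean(), rel=1e-6)
        assert ours.min() >= 0.0


# ---------------------------------------------------------------------------
# alignment

def test_alignment_recovers_40ms_insole_clock_offset():
    subject = mini_clinical_subject()
    session = simulate_session(subject, [(mini_profile(0.7, 100), 0.7)], 13,
                               offsets=ClockOffsets(insole=0.040, imu=0.015))
    ds = preprocess_session(session)["left"]
    total = ds.maps.reshape(ds.n_frames, -1).sum(axis=1)
    lags = np.arange(-6, 7)
    corr = np.array([np.corrcoef(np.roll(total, k)[10:-10], ds.v_grf[10:-10])[0, 1]
                     for k in lags])
    k = int(np.argmax(corr))
    assert 0 < k < len(lags) - 1
    # parabolic sub-lag refinement of the correlation peak
    sub = 0.5 * (corr[k - 1] - corr[k + 1]) / (corr[k - 1] - 2 * corr[k] + corr[k + 1])
    peak_lag = lags[k] + sub
    assert abs(peak_lag) < 1.0  # residual misalignment below one 100 Hz frame


def test_aligned_dataset_structure(clin_datasets, clin_session):
    ds = clin_datasets["left"]
    n_bouts = len(clin_session.bouts)
    assert ds.maps.shape[1:] == (28, 28)
    assert ds.imu.shape[1] == 21
    assert ds.n_frames == sum(int(b.profile.duration * 100) for b in clin_session.bouts)
    assert set(np.unique(ds.bout_id)) == set(range(n_bouts))
    # stride ids are contiguous 0..n-1 over stance frames
    sids = np.unique(ds.stride_id[ds.stride_id >= 0])
    assert np.array_equal(sids, np.arange(len(sids)))
    # stance frames only between matched events; targets zero outside stance
    assert np.abs(ds.ap_grf[~ds.stance]).max() < 1.0
    # %BW scaling: vertical load peaks near bodyweight
    assert 80 < np.percentile(ds.v_grf[ds.stance], 95) < 130


def test_aligned_stride_count_matches_simulator(clin_datasets, clin_session):
    ds = clin_datasets["left"]
    truth = sum(len(b.kinetics["left"].events.heel_strike_times)
                for b in clin_session.bouts)
    found = len(np.unique(ds.stride_id[ds.stride_id >= 0]))
    assert abs(found - truth) <= len(clin_session.bouts)  # edge strides only


def test_swing_subtract_removes_constant_residual():
    n = 2000
    t = np.arange(n) / 100.0
    hs = np.array([0.5, 1.8, 3.1])
    to = hs + 0.8
    rng = np.random.default_rng(0)
    base = rng.random((n, N_SENSELS))
    residual = rng.random(N_SENSELS)[None, :] * 2.0
    out = _swing_subtract(base + residual, t, hs, to)
    first_swing = (t >= to[0]) & (t < hs[1])
    expected = base + residual - (base[first_swing] + residual).mean(axis=0)[None, :]
    assert np.allclose(out, expected)


# ---------------------------------------------------------------------------
# normalization

def _tiny_dataset(n=40):
    rng = np.random.default_rng(3)
    ds = AlignedDataset(
        t=np.arange(n) / 100.0, maps=rng.random((n, 28, 28)).astype(np.float32),
        cop=rng.random((n, 2)) * 10, imu=rng.standard_normal((n, 21)) * 5,
        ap_grf=rng.standard_normal(n), v_grf=rng.random(n) * 100,
        stance=np.ones(n, bool), stride_id=np.repeat(np.arange(n // 10), 10),
        bout_id=np.zeros(n, int), side="left", bout_centers=np.array([0.7]),
        cws=0.7)
    ds.imu[:, 20] = 4.0  # constant channel -> degenerate group
    return ds


def test_minmax_maps_training_range_to_unit_interval():
    ds = _tiny_dataset()
    train = np.arange(0, 20)
    norm = fit_minmax(ds, train)
    out = apply_minmax(ds, norm)
    assert out.maps[train].min() == pytest.approx(0.0, abs=1e-6)
    assert out.maps[train].max() == pytest.approx(1.0, abs=1e-6)
    for name, sl in IMU_GROUPS.items():
        block = out.imu[train, sl]
        if name == "thigh_ang":
            continue  # contains the constant channel
        assert block.min() == pytest.approx(0.0, abs=1e-9)
        assert block.max() == pytest.approx(1.0, abs=1e-9)
    # values outside the training range are not clipped
    assert out.imu[20:].max() > 1.0 or out.imu[20:].min() < 0.0
    # degenerate constant channel maps to zero
    lo, span = norm.groups["thigh_ang"]
    assert span >= 1.0 or np.allclose(out.imu[:, 20], 0.0)


def test_minmax_constant_group_maps_to_zero():
    ds = _tiny_dataset()
    ds.imu[:, 19:21] = 4.0  # whole thigh-angle group constant
    norm = fit_minmax(ds, np.arange(20))
    out = apply_minmax(ds, norm)
    assert np.allclose(out.imu[:, 19:21], 0.0)
    assert norm.groups["thigh_ang"][1] == 1.0


def test_norm_constants_roundtrip_bit_exact(tmp_path):
    ds = _tiny_dataset()
    ds.norm = fit_minmax(ds, np.arange(20))
    save_aligned({"left": ds}, tmp_path / "a.h5")
    back = load_aligned(tmp_path / "a.h5")["left"]
    assert back.norm is not None
    for k, (lo, span) in ds.norm.groups.items():
        assert back.norm.groups[k] == (lo, span)  # exact, not approx


# ---------------------------------------------------------------------------
# sequence construction

def test_sequences_one_sample_per_stance_frame(clin_datasets):
    ds = clin_datasets["left"]
    seqs = make_sequences(ds, 5)
    assert len(seqs) == int(ds.stance.sum())
    assert seqs.seqs.shape[1:] == (5, 23)
    assert seqs.maps.shape[1:] == (1, 28, 28)


def test_sequences_padding_and_length_one(clin_datasets):
    ds = clin_datasets["left"]
    seqs5 = make_sequences(ds, 5)
    # frame at a stance-segment start: all 5 rows identical
    stance_idx = np.flatnonzero(ds.stance)
    starts = stance_idx[np.flatnonzero(np.diff(np.concatenate(([-10], stance_idx))) > 1)]
    pos = int(np.flatnonzero(seqs5.frame_idx == starts[1])[0])
    assert np.allclose(seqs5.seqs[pos], seqs5.seqs[pos][0][None, :])
    # mid-stance frame: rows are the 5 preceding frames
    mid = int(np.flatnonzero(seqs5.frame_idx == starts[1] + 20)[0])
    chan = np.concatenate([ds.imu, ds.cop], axis=1)
    assert np.allclose(seqs5.seqs[mid],
                       chan[starts[1] + 16:starts[1] + 21], atol=1e-6)
    seqs1 = make_sequences(ds, 1)
    assert np.allclose(seqs1.seqs[pos][0], seqs5.seqs[pos][-1])
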