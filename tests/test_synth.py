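"""Generator contracts: determinism, mixing algebra, calibrated rates."""

import numpy as np
import pytest
from scipy import stats as sstats

from lamsync import SynthConfig, generate_eeg_day, generate_recording
from lamsync.synth import default_alpha_of_distance, swd_train
from lamsync.spectral import band_power, psd


def test_same_seed_bit_identical():
    cfg = SynthConfig(state_schedule=(("burst_suppression", 30.0),))
    a, gta = generate_recording(cfg, 42)
    b, gtb = generate_recording(cfg, 42)
    np.testing.assert_array_equal(a.signal, b.signal)
    assert gta.burst_intervals == gtb.burst_intervals
    c, _ = generate_recording(cfg, 43)
    assert not np.array_equal(a.signal, c.signal)


def test_noise_only_limit_variance():
    cfg = SynthConfig(state_schedule=(("suppression", 30.0),),
                      suppression_noise_uV=5.0, n_channels=4)
    sess, gt = generate_recording(cfg, 0)
    assert gt.burst_intervals == []
    np.testing.assert_allclose(sess.signal.var(axis=1), 25.0, rtol=0.1)


def test_full_inversion_is_exact_algebra_without_noise():
    cfg = SynthConfig(state_schedule=(("burst_suppression", 30.0),),
                      suppression_noise_uV=0.0, inversion_alpha=-1.0,
                      n_channels=16, subcortical_gain=2.0,
                      spike_rate_in_burst_hz=0.0,
                      spike_rate_out_burst_hz=0.0)
    sess, gt = generate_recording(cfg, 3)
    cortical = sess.channel(5)
    subcortical = sess.channel(14)
    # subcortical = −(gain ratio) × cortical, exactly
    np.testing.assert_allclose(subcortical, -2.0 * cortical, atol=1e-9)
    assert gt.inverted_channels == set(range(13, 17))


def test_realized_burst_count_within_poisson_band():
    """600 s at 7 bursts/min: realized counts stay in the 95% band."""
    counts = []
    for seed in range(12):
        cfg = SynthConfig(n_channels=2, cortex_boundary_channel=2,
                          state_schedule=(("burst_suppression", 600.0),))
        _, gt = generate_recording(cfg, seed)
        counts.append(len(gt.burst_intervals))
    lo, hi = sstats.poisson.ppf([0.025, 0.975], 70)
    assert lo <= np.mean(counts) <= hi


def test_burst_spectral_content_concentrated_in_4_12_hz():
    cfg = SynthConfig(n_channels=2, cortex_boundary_channel=2,
                      state_schedule=(("burst_suppression", 120.0),),
                      background_gain=0.0, suppression_noise_uV=5.0)
    sess, gt = generate_recording(cfg, 1)
    rate = sess.sample_rate
    segs = [sess.channel(1)[int(s * rate):int(e * rate)]
            for s, e in gt.burst_intervals]
    x = np.concatenate(segs)
    r = psd(x, rate)
    frac = band_power(r, 4, 12) / band_power(r, 1, 20)
    assert frac >= 0.70


def test_laminar_gain_jump_recovered_from_burst_rms():
    cfg = SynthConfig(state_schedule=(("burst_suppression", 60.0),),
                      suppression_noise_uV=0.0, subcortical_gain=2.0,
                      inversion_alpha=1.0)
    sess, gt = generate_recording(cfg, 5)
    rate = sess.sample_rate
    mask = np.zeros(sess.n_samples, dtype=bool)
    for s, e in gt.burst_intervals:
        mask[int(s * rate):int(e * rate)] = True
    rms13 = np.sqrt(np.mean(sess.channel(13)[mask] ** 2))
    rms12 = np.sqrt(np.mean(sess.channel(12)[mask] ** 2))
    assert abs(rms13 / rms12 - 2.0) < 0.2


def test_alpha_of_distance_monotone_and_bounded():
    d = np.linspace(0, 4000, 50)
    a = np.array([default_alpha_of_distance(x) for x in d])
    assert np.all(np.diff(a) >= 0)
    assert a[0] == -1.0 and a[-1] == 1.0
    assert default_alpha_of_distance(1200.0) == 0.0


def test_schedule_shorter_than_epoch_rejected():
    cfg = SynthConfig(state_schedule=(("suppression", 0.5),))
    with pytest.raises(ValueError):
        generate_recording(cfg, 0)


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        SynthConfig(burst_rate_per_min=-1.0)
    with pytest.raises(ValueError):
        SynthConfig(inversion_alpha=1.5)
    with pytest.raises(ValueError):
        SynthConfig(state_schedule=(("nap", 10.0),))


# --- EEG day -------------------------------------------------------------

def test_zero_swd_rate_gives_no_events():
    cfg = SynthConfig(eeg_duration_s=600.0, swd_rate_per_hour=0.0)
    _, gt = generate_eeg_day(cfg, 0)
    assert gt.swd_intervals == []


def test_forced_swd_train_spike_count_is_rate_times_duration():
    w, count = swd_train(2.0, 8.0, 100.0, 100.0)
    assert count == 16
    assert len(w) == 200


def test_swd_only_in_nrem_with_elevated_delta():
    cfg = SynthConfig(eeg_duration_s=3600.0, swd_rate_per_hour=6.0)
    sess, gt = generate_eeg_day(cfg, 2)
    assert len(gt.swd_intervals) > 0
    for s, e, count in gt.swd_intervals:
        idx = int(s / cfg.epoch_s)
        assert gt.hypnogram[idx] == "NREM"
        assert count == round(cfg.swd_dur_s * cfg.swd_spike_hz)


def test_realized_swd_count_poisson_band():
    counts = []
    for seed in range(10):
        cfg = SynthConfig(eeg_duration_s=4 * 3600.0, swd_rate_per_hour=3.0)
        _, gt = generate_eeg_day(cfg, seed)
        counts.append(len(gt.swd_intervals))
    lo, hi = sstats.poisson.ppf([0.025, 0.975], 12)
    assert lo <= np.mean(counts) <= hi


def test_swd_enabled_requires_positive_spike_rate():
    cfg = SynthConfig(eeg_duration_s=600.0, swd_rate_per_hour=2.0,
                      swd_spike_hz=0.0)
    with pytest.raises(ValueError):
        generate_eeg_day(cfg, 0)


def test_movement_only_in_active_wake():
    cfg = SynthConfig(eeg_duration_s=1800.0)
    sess, gt = generate_eeg_day(cfg, 4)
    move = sess.movement_per_epoch()
    aw = np.array([lab == "ActiveWake" for lab in gt.hypnogram])
    assert move[aw].min() > 1.0
    assert np.median(move[~aw]) < 0.2
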