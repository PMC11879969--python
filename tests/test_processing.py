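"""Processing chain: OD, MBLL inversion, smoothing, baseline, block averages, QC."""

import dataclasses

import numpy as np
import pytest

from tiltnirs import (
    ConcentrationSeries,
    GroundTruth,
    OpticalGeometry,
    QCConfig,
    RawRecording,
    baseline_correct,
    block_average,
    channel_qc,
    forward_intensity,
    mbll_invert,
    process_recording,
    simulate_concentration,
    smooth,
    to_optical_density,
)
from tiltnirs.processing import OpticalDensitySeries, moving_average
from tiltnirs.study import StudyConfig, recover_amplitudes, simulate_cohort


def _const_raw(value=500.0, n=1000, fs=10.0):
    return RawRecording(
        fs=fs,
        intensity={(ch, wl): np.full(n, value) for ch in ("Fp1",) for wl in (660, 860)},
    )


def test_od_constant_signal_is_zero():
    od = to_optical_density(_const_raw())
    for v in od.od.values():
        np.testing.assert_array_equal(v, 0.0)


def test_od_log10_definition():
    """A sample at I0/10 maps to OD = 1 (decadic convention)."""
    raw = _const_raw(100.0)
    raw.intensity[("Fp1", 660)] = raw.intensity[("Fp1", 660)].copy()
    raw.intensity[("Fp1", 660)][42] = 10.0
    od = to_optical_density(raw, i0=100.0)
    assert od.od[("Fp1", 660)][42] == pytest.approx(1.0)


def test_od_whole_recording_mean_reference(default_design, noise_free_truth):
    """With the default I0 the OD of a synthetic session has ~zero mean."""
    conc, _ = simulate_concentration(default_design, noise_free_truth, rng=0)
    raw = forward_intensity(conc)
    od = to_optical_density(raw)
    for key, v in od.od.items():
        expected = -np.log10(raw.intensity[key] / raw.intensity[key].mean())
        np.testing.assert_allclose(v, expected, atol=1e-12)
        # mean OD is ~0 by construction of I0 (exact zero is broken by Jensen)
        assert abs(v.mean()) < 1e-2
        assert od.i0[key] == pytest.approx(raw.intensity[key].mean())


def test_od_imputes_nonpositive_samples():
    raw = _const_raw(100.0)
    raw.intensity[("Fp1", 860)] = raw.intensity[("Fp1", 860)].copy()
    raw.intensity[("Fp1", 860)][[0, 500]] = 0.0
    od = to_optical_density(raw)
    assert np.isfinite(od.od[("Fp1", 860)]).all()
    assert any("imputed 2" in e for e in od.qc_events)


def test_mbll_zero_od_zero_concentration():
    od = OpticalDensitySeries(
        fs=10.0,
        od={("Fp1", wl): np.zeros(100) for wl in (660, 860)},
        i0={("Fp1", wl): 1.0 for wl in (660, 860)},
    )
    conc = mbll_invert(od)
    np.testing.assert_array_equal(conc.hbo["Fp1"], 0.0)
    np.testing.assert_array_equal(conc.hbr["Fp1"], 0.0)


def test_mbll_unit_hbo_construction():
    """OD built as E_eff @ [1, 0] must invert to dHbO = 1 uM, dHbR = 0."""
    geom = OpticalGeometry()
    od_vec = geom.mbll_matrix() @ np.array([1.0, 0.0])
    od = OpticalDensitySeries(
        fs=10.0,
        od={("Fp1", 660): np.full(10, od_vec[0]), ("Fp1", 860): np.full(10, od_vec[1])},
        i0={("Fp1", 660): 1.0, ("Fp1", 860): 1.0},
    )
    conc = mbll_invert(od, geom)
    np.testing.assert_allclose(conc.hbo["Fp1"], 1.0, atol=1e-12)
    np.testing.assert_allclose(conc.hbr["Fp1"], 0.0, atol=1e-12)


def test_mbll_singular_geometry_rejected():
    ext = {660: {"hbo": 1.0, "hbr": 2.0}, 860: {"hbo": 2.0, "hbr": 4.0}}
    with pytest.raises((ValueError, np.linalg.LinAlgError)):
        OpticalGeometry(extinction=ext).mbll_inverse()


def test_roundtrip_forward_then_invert(default_design, noise_free_truth):
    """Forward intensities invert back to the programmed series to <= 1e-9 relative."""
    conc, _ = simulate_concentration(default_design, noise_free_truth, rng=0)
    raw = forward_intensity(conc, reference_intensity=1000.0)
    rec = mbll_invert(to_optical_density(raw, i0=1000.0))
    for ch in conc.channels:
        scale = np.abs(conc.hbo[ch]).max()
        assert np.abs(rec.hbo[ch] - conc.hbo[ch]).max() <= 1e-9 * scale
        assert np.abs(rec.hbr[ch] - conc.hbr[ch]).max() <= 1e-9 * max(
            np.abs(conc.hbr[ch]).max(), scale
        )


def test_moving_average_constant_and_impulse():
    assert np.allclose(moving_average(np.full(200, 3.3), 50), 3.3)
    x = np.zeros(500)
    x[250] = 1.0
    sm = moving_average(x, 50)
    inner = sm[230:270]
    assert np.max(inner) == pytest.approx(1 / 50)
    assert np.sum(sm > 0) == 50


def test_moving_average_variance_reduction(rng):
    x = rng.standard_normal(200_000)
    sm = moving_average(x, 50)
    ratio = sm[100:-100].var() / x.var()
    assert ratio == pytest.approx(1 / 50, rel=0.2)


def test_moving_average_window_too_long_rejected():
    with pytest.raises(ValueError, match="longer"):
        moving_average(np.zeros(10), 11)


def test_smooth_and_mbll_commute(default_design):
    """Both operations are linear: order does not matter (to 1e-9)."""
    gt = GroundTruth(subject_amplitude_sd=0.0)
    conc, _ = simulate_concentration(default_design, gt, rng=1)
    raw = forward_intensity(conc, reference_intensity=1000.0)
    od = to_optical_density(raw, i0=1000.0)
    a = smooth(mbll_invert(od), 50)
    od_sm = OpticalDensitySeries(
        fs=od.fs,
        od={k: moving_average(v, 50) for k, v in od.od.items()},
        i0=od.i0,
    )
    b = mbll_invert(od_sm)
    for ch in a.channels:
        np.testing.assert_allclose(a.hbo[ch], b.hbo[ch], atol=1e-9)


def _series_from(design, arrays, fs=10.0):
    return ConcentrationSeries(fs=fs, hbo=dict(arrays), hbr={k: v.copy() for k, v in arrays.items()})


def test_baseline_constant_tilt_zeroed(default_design):
    n = int(default_design.protocol_duration_s * 10)
    x = np.repeat([1.0, 2.0, 3.0, 4.0], n // 4)
    series = _series_from(default_design, {"Fp1": x})
    out = baseline_correct(series, default_design)
    np.testing.assert_allclose(out.hbo["Fp1"], 0.0, atol=1e-12)
    assert out.baseline_corrected


def test_baseline_per_tilt_offset_invariance(default_design, noise_free_truth):
    conc, _ = simulate_concentration(default_design, noise_free_truth, rng=2)
    shifted = ConcentrationSeries(
        fs=conc.fs,
        hbo={ch: v.copy() for ch, v in conc.hbo.items()},
        hbr={ch: v.copy() for ch, v in conc.hbr.items()},
    )
    n4 = conc.n_samples // 4
    for i, c in enumerate([0.0, 5.0, -2.0, 9.0]):
        for ch in shifted.channels:
            shifted.hbo[ch][i * n4 : (i + 1) * n4] += c
    a = block_average(baseline_correct(conc, default_design), default_design)
    b = block_average(baseline_correct(shifted, default_design), default_design)
    np.testing.assert_allclose(a["hbo_uM"], b["hbo_uM"], atol=1e-10)


def test_baseline_insufficient_pretask_rejected(default_design):
    design = dataclasses.replace(default_design, task_offset_s=5.0)
    n = int(design.protocol_duration_s * 10)
    series = _series_from(design, {"Fp1": np.zeros(n)})
    with pytest.raises(ValueError, match="baseline"):
        baseline_correct(series, design)


def test_block_average_zero_series(default_design):
    n = int(default_design.protocol_duration_s * 10)
    series = _series_from(default_design, {"Fp1": np.zeros(n), "Fp2": np.zeros(n)})
    table = block_average(series, default_design)
    assert len(table) == 16  # 4 tilts x 4 levels
    assert (table["hbo_uM"] == 0).all()
    assert (table["n_channels_used"] == 2).all()


def test_block_average_channel_exclusion_bookkeeping(default_design):
    n = int(default_design.protocol_duration_s * 10)
    series = _series_from(default_design, {"Fp1": np.ones(n), "Fp2": np.full(n, 3.0)})
    table = block_average(series, default_design, keep_channels=("Fp2",))
    assert (table["n_channels_used"] == 1).all()
    assert (table["hbo_uM"] == 3.0).all()


def test_block_average_past_end_rejected(default_design):
    series = _series_from(default_design, {"Fp1": np.zeros(100)})
    with pytest.raises(ValueError, match="past recording end"):
        block_average(series, default_design)


def test_qc_clean_channels_kept(default_design):
    gt = GroundTruth(subject_amplitude_sd=0.0)
    conc, _ = simulate_concentration(default_design, gt, rng=3)
    raw = forward_intensity(conc)
    report = channel_qc(raw, conc)
    assert all(report.keep.values())
    assert not report.participant_excluded


def test_qc_saturated_channel_excluded(default_design):
    gt = GroundTruth(subject_amplitude_sd=0.0)
    conc, _ = simulate_concentration(default_design, gt, rng=3)
    raw = forward_intensity(conc)
    key = ("Fp1", 660)
    sat = raw.intensity[key].copy()
    sat[: int(0.2 * len(sat))] = sat.max() + 100.0  # A/D clipping over 20% of samples
    raw.intensity[key] = sat
    report = channel_qc(raw, conc)
    assert not report.keep["Fp1"]
    assert any("saturation" in r for r in report.reasons["Fp1"])
    assert report.keep["Fp2"]
    assert not report.participant_excluded


def test_qc_both_channels_bad_excludes_participant(default_design):
    gt = GroundTruth(white_noise_sd_uM=30.0)  # far beyond the residual threshold
    conc, _ = simulate_concentration(default_design, gt, rng=4)
    raw = forward_intensity(conc)
    report = channel_qc(raw, conc, QCConfig(hf_residual_uM=1.0))
    assert report.participant_excluded


def test_end_to_end_linearity_in_amplitudes(default_design, noise_free_truth):
    """Scaling programmed amplitudes by k scales block averages by k (noise-free)."""
    k = 3.7
    scaled = dataclasses.replace(
        noise_free_truth,
        amplitudes_hbo={lv: k * v for lv, v in noise_free_truth.amplitudes_hbo.items()},
        amplitudes_hbr={lv: k * v for lv, v in noise_free_truth.amplitudes_hbr.items()},
    )
    tables = []
    for gt in (noise_free_truth, scaled):
        conc, _ = simulate_concentration(default_design, gt, rng=0)
        raw = forward_intensity(conc)
        table, _, _ = process_recording(raw, default_design)
        tables.append(table)
    a, b = tables
    np.testing.assert_allclose(b["hbo_uM"], k * a["hbo_uM"], rtol=1e-6)
    np.testing.assert_allclose(b["hbr_uM"], k * a["hbr_uM"], rtol=1e-6, atol=1e-12)


def test_drift_offsets_do_not_move_block_averages(noise_free_truth):
    """End-to-end: programmed per-tilt drift has no effect on corrected block means."""
    cfg0 = StudyConfig(n_participants=2, seed=5, ground_truth=noise_free_truth)
    heavy = dataclasses.replace(
        noise_free_truth, drift_offsets={"pre0": 0.0, "m10": 8.0, "m20": -4.0, "post0": 12.0}
    )
    cfg1 = dataclasses.replace(cfg0, ground_truth=heavy)
    b0, *_ = simulate_cohort(cfg0)
    b1, *_ = simulate_cohort(cfg1)
    np.testing.assert_allclose(
        b1[["hbo_uM", "hbr_uM"]].to_numpy(), b0[["hbo_uM", "hbr_uM"]].to_numpy(), atol=1e-10
    )


def test_noise_free_amplitude_recovery_exact(noise_free_truth):
    cfg = StudyConfig(n_participants=2, seed=6, ground_truth=noise_free_truth)
    blocks, _, designs, _, _ = simulate_cohort(cfg)
    rec = recover_amplitudes(blocks, designs, cfg)
    for lv, true in noise_free_truth.amplitudes_hbo.items():
        est = rec.loc[rec["level"] == lv, "amp_hbo_uM"]
        np.testing.assert_allclose(est, true, rtol=1e-6)
    for lv, true in noise_free_truth.amplitudes_hbr.items():
        est = rec.loc[rec["level"] == lv, "amp_hbr_uM"]
        np.testing.assert_allclose(est, true, rtol=1e-6)
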