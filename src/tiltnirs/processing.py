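"""Raw-intensity to block-average processing chain for two-channel CW NIRS.

The chain deliberately mirrors a minimal field pipeline:

1. optical density  ``OD = -log10(I / I0)`` with ``I0`` the mean of the whole
   recording per channel and wavelength;
2. MBLL inversion of the 2x2 extinction system to dHbO/dHbR in umol/L;
3. centred 50-sample moving-average smoothing (5 s at 10 Hz);
4. per-tilt baseline subtraction over the 10 s preceding each tilt's task;
5. 60 s block averages per condition (countdown excluded), then channel
   averaging over QC-surviving channels.

Every stage is linear, so scaling activation amplitudes scales block
averages, and per-tilt constant shifts (the fluid-shift confound) cancel in
step 4 — the computational core of the claim that head-down tilt does not
bias task-evoked measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .optics import DEFAULT_GEOMETRY, OpticalGeometry
from .task import SessionDesign

__all__ = [
    "RawRecording",
    "OpticalDensitySeries",
    "ConcentrationSeries",
    "QCConfig",
    "QCReport",
    "to_optical_density",
    "mbll_invert",
    "smooth",
    "moving_average",
    "baseline_correct",
    "block_average",
    "channel_qc",
    "process_recording",
]

DEFAULT_CHANNELS = ("Fp1", "Fp2")


@dataclass
class RawRecording:
    """Dual-wavelength intensity time series, one array per (channel, wavelength)."""

    fs: float
    intensity: dict[tuple[str, int], np.ndarray]

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.intensity.values()}
        if len(lengths) != 1:
            raise ValueError(f"unequal series lengths: {sorted(lengths)}")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.intensity.values())))

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(ch for ch, _ in self.intensity))

    @property
    def wavelengths(self) -> tuple[int, ...]:
        return tuple(dict.fromkeys(wl for _, wl in self.intensity))


@dataclass
class OpticalDensitySeries:
    fs: float
    od: dict[tuple[str, int], np.ndarray]
    i0: dict[tuple[str, int], float]
    qc_events: list[str] = field(default_factory=list)


@dataclass
class ConcentrationSeries:
    """dHbO/dHbR in umol/L per channel, with provenance flags."""

    fs: float
    hbo: dict[str, np.ndarray]
    hbr: dict[str, np.ndarray]
    filtered: bool = False
    baseline_corrected: bool = False

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.hbo)

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.hbo.values())))


def to_optical_density(
    raw: RawRecording,
    i0: float | dict[tuple[str, int], float] | None = None,
) -> OpticalDensitySeries:
    """Convert intensities to optical density, ``OD = -log10(I / I0)``.

    By default ``I0`` is the arithmetic mean of the whole recording per
    channel and wavelength; pass ``i0`` (scalar or per-(channel, wavelength)
    dict) to reference against a known source intensity instead.  Non-positive
    samples (possible after artifact excursions) are imputed from the nearest
    positive neighbour before the log and logged as QC events.
    """
    od: dict[tuple[str, int], np.ndarray] = {}
    i0s: dict[tuple[str, int], float] = {}
    events: list[str] = []
    for key, series in raw.intensity.items():
        series = np.asarray(series, dtype=float)
        bad = series <= 0
        if bad.all():
            raise ValueError(f"channel {key}: no positive samples")
        if bad.any():
            good_idx = np.flatnonzero(~bad)
            nearest = good_idx[
                np.searchsorted(good_idx, np.flatnonzero(bad)).clip(0, len(good_idx) - 1)
            ]
            # searchsorted gives the right neighbour; take whichever is closer
            left = good_idx[(np.searchsorted(good_idx, np.flatnonzero(bad)) - 1).clip(0)]
            bad_idx = np.flatnonzero(bad)
            use_left = np.abs(bad_idx - left) <= np.abs(bad_idx - nearest)
            fill = np.where(use_left, left, nearest)
            series = series.copy()
            series[bad_idx] = series[fill]
            events.append(
                f"channel {key}: imputed {len(bad_idx)} non-positive sample(s) "
                "by nearest neighbour before log"
            )
        if i0 is None:
            ref = float(series.mean())
        elif isinstance(i0, dict):
            ref = float(i0[key])
        else:
            ref = float(i0)
        if ref <= 0:
            raise ValueError(f"channel {key}: non-positive reference intensity")
        od[key] = -np.log10(series / ref)
        i0s[key] = ref
    return OpticalDensitySeries(fs=raw.fs, od=od, i0=i0s, qc_events=events)


def mbll_invert(
    od_series: OpticalDensitySeries, geometry: OpticalGeometry = DEFAULT_GEOMETRY
) -> ConcentrationSeries:
    """Invert the two-wavelength MBLL system to dHbO/dHbR (umol/L) per channel."""
    inv = geometry.mbll_inverse()
    wl1, wl2 = geometry.wavelengths_nm
    channels = tuple(dict.fromkeys(ch for ch, _ in od_series.od))
    hbo, hbr = {}, {}
    for ch in channels:
        try:
            od_stack = np.vstack([od_series.od[(ch, wl1)], od_series.od[(ch, wl2)]])
        except KeyError as err:
            raise ValueError(f"channel {ch}: missing OD at wavelength {err}") from err
        conc = inv @ od_stack
        hbo[ch], hbr[ch] = conc[0], conc[1]
    return ConcentrationSeries(fs=od_series.fs, hbo=hbo, hbr=hbr)


def moving_average(x: np.ndarray, window_samples: int) -> np.ndarray:
    """Centred moving average with shrinking windows at the edges.

    For even windows the centre sits half a sample late ((w-1)//2 samples
    before, w//2 after), the closest centred placement.  Length-preserving.
    """
    if window_samples < 1:
        raise ValueError("window_samples must be >= 1")
    n = len(x)
    if window_samples > n:
        raise ValueError(f"window ({window_samples}) longer than series ({n})")
    before = (window_samples - 1) // 2
    after = window_samples // 2
    csum = np.concatenate([[0.0], np.cumsum(np.asarray(x, dtype=float))])
    idx = np.arange(n)
    lo = np.maximum(idx - before, 0)
    hi = np.minimum(idx + after + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def smooth(series: ConcentrationSeries, window_samples: int = 50) -> ConcentrationSeries:
    """Moving-average filter both chromophores of every channel (default 50 samples)."""
    return replace(
        series,
        hbo={ch: moving_average(v, window_samples) for ch, v in series.hbo.items()},
        hbr={ch: moving_average(v, window_samples) for ch, v in series.hbr.items()},
        filtered=True,
    )


def _baseline_slice(design: SessionDesign, tilt: str, fs: float, baseline_s: float) -> slice:
    start = design.task_start(tilt) - baseline_s
    if start < design.tilt_start(tilt):
        raise ValueError(
            f"tilt {tilt}: only {design.task_offset_s:.0f} s precede the task, "
            f"cannot take a {baseline_s:.0f} s baseline"
        )
    i0 = int(round(start * fs))
    i1 = int(round(design.task_start(tilt) * fs))
    return slice(i0, i1)


def baseline_correct(
    series: ConcentrationSeries, design: SessionDesign, baseline_s: float = 10.0
) -> ConcentrationSeries:
    """Subtract each tilt's pre-task mean (default 10 s) within that tilt segment.

    The correction is applied separately per channel and chromophore; each
    tilt segment gets its own offset, which is what removes tilt-dependent
    slow shifts from all downstream block averages.
    """
    fs = series.fs
    n = series.n_samples

    def _correct(x: np.ndarray) -> np.ndarray:
        out = x.astype(float).copy()
        for tilt in design.tilt_sequence:
            sl = _baseline_slice(design, tilt, fs, baseline_s)
            if sl.stop > n:
                raise ValueError(f"tilt {tilt}: baseline window extends past recording end")
            seg = slice(
                int(round(design.tilt_start(tilt) * fs)),
                min(int(round((design.tilt_start(tilt) + design.tilt_duration_s) * fs)), n),
            )
            out[seg] -= x[sl].mean()
        return out

    return replace(
        series,
        hbo={ch: _correct(v) for ch, v in series.hbo.items()},
        hbr={ch: _correct(v) for ch, v in series.hbr.items()},
        baseline_corrected=True,
    )


def block_average(
    series: ConcentrationSeries,
    design: SessionDesign,
    participant: int | None = None,
    keep_channels: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Average each block's 60 s trial window, then average across channels.

    Returns a tidy frame with one row per (tilt, level):
    ``participant, tilt, level, hbo_uM, hbr_uM, n_channels_used``.
    Countdowns are excluded from the window.
    """
    channels = keep_channels if keep_channels is not None else series.channels
    if not channels:
        raise ValueError("no channels left to average")
    fs = series.fs
    rows = []
    for tilt, _slot, block, start, end in design.iter_blocks():
        i0, i1 = int(round(start * fs)), int(round(end * fs))
        if i1 > series.n_samples:
            raise ValueError(
                f"block {block.level}@{tilt} window [{start:.0f}, {end:.0f}) s "
                "extends past recording end"
            )
        hbo = float(np.mean([series.hbo[ch][i0:i1].mean() for ch in channels]))
        hbr = float(np.mean([series.hbr[ch][i0:i1].mean() for ch in channels]))
        rows.append(
            {
                "participant": participant,
                "tilt": tilt,
                "level": block.level,
                "hbo_uM": hbo,
                "hbr_uM": hbr,
                "n_channels_used": len(channels),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class QCConfig:
    """Channel-rejection thresholds; a channel is excluded if ANY criterion fires.

    saturation_fraction : reject when more than this fraction of raw samples
        sit at the channel's maximum (clipped A/D converter).
    hf_residual_uM : reject when the standard deviation of the unfiltered
        minus smoothed dHbO exceeds this (broadband/instrument noise).
    jump_uM / max_jumps : reject when more than ``max_jumps`` sample-to-sample
        dHbO steps exceed ``jump_uM`` (motion artifacts).
    """

    saturation_fraction: float = 0.10
    hf_residual_uM: float = 1.0
    jump_uM: float = 5.0
    max_jumps: int = 3
    smooth_window: int = 50


@dataclass
class QCReport:
    keep: dict[str, bool]
    reasons: dict[str, list[str]]
    participant_excluded: bool


def channel_qc(
    raw: RawRecording,
    concentration: ConcentrationSeries,
    config: QCConfig = QCConfig(),
) -> QCReport:
    """Flag excessively noisy channels; never raises, only reports.

    The participant verdict is exclusion when both channels fail, mirroring
    the practice of dropping subjects with no usable channel.
    """
    keep: dict[str, bool] = {}
    reasons: dict[str, list[str]] = {}
    for ch in concentration.channels:
        why: list[str] = []
        for (rch, wl), series in raw.intensity.items():
            if rch != ch:
                continue
            frac = float(np.mean(series == series.max()))
            if frac > config.saturation_fraction:
                why.append(f"saturation at {wl} nm: {frac:.1%} of samples at max")
        hbo = concentration.hbo[ch]
        resid = hbo - moving_average(hbo, min(config.smooth_window, len(hbo)))
        if resid.std() > config.hf_residual_uM:
            why.append(f"high-frequency residual {resid.std():.2f} uM")
        n_jumps = int(np.sum(np.abs(np.diff(hbo)) > config.jump_uM))
        if n_jumps > config.max_jumps:
            why.append(f"{n_jumps} jumps > {config.jump_uM} uM")
        keep[ch] = not why
        reasons[ch] = why
    return QCReport(keep=keep, reasons=reasons, participant_excluded=not any(keep.values()))


def process_recording(
    raw: RawRecording,
    design: SessionDesign,
    geometry: OpticalGeometry = DEFAULT_GEOMETRY,
    participant: int | None = None,
    qc_config: QCConfig = QCConfig(),
    smooth_window: int = 50,
    baseline_s: float = 10.0,
) -> tuple[pd.DataFrame, QCReport, ConcentrationSeries]:
    """Full chain: OD -> MBLL -> smooth -> baseline -> QC -> block averages.

    Returns the block-average table over QC-surviving channels (empty when the
    participant is excluded), the QC report, and the baseline-corrected series.
    """
    od = to_optical_density(raw)
    conc = mbll_invert(od, geometry)
    qc = channel_qc(raw, conc, qc_config)
    conc = smooth(conc, smooth_window)
    conc = baseline_correct(conc, design, baseline_s)
    kept = tuple(ch for ch, ok in qc.keep.items() if ok)
    if not kept:
        return pd.DataFrame(), qc, conc
    table = block_average(conc, design, participant=participant, keep_channels=kept)
    return table, qc, conc
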