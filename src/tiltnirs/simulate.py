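"""Forward model of a head-down-tilt fNIRS session with known ground truth.

The generator produces, for a simulated participant:

* dHbO/dHbR concentration series built from a block-design activation
  (boxcar over each 60 s trial window, convolved with a canonical
  double-gamma hemodynamic response), tilt-dependent slow baseline shifts,
  physiological oscillations (cardiac, respiratory, Mayer waves), white
  sensor noise and optional motion artifacts;
* raw dual-wavelength intensities via the exact MBLL forward model, so the
  processing chain's OD + inversion is its analytic inverse;
* per-trial behavioural responses whose accuracy and latency degrade with
  n-back difficulty.

The HRF kernel is normalised to unit integral, so a sustained block at
programmed amplitude ``a`` plateaus at ``a`` umol/L: amplitudes are
steady-state concentration changes and are the recovery target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .optics import DEFAULT_GEOMETRY, OpticalGeometry
from .processing import DEFAULT_CHANNELS, ConcentrationSeries, RawRecording
from .task import LEVELS, TILTS, SessionDesign, TrialResponse, build_session

__all__ = [
    "HRFParams",
    "OscComponent",
    "Artifact",
    "GroundTruth",
    "BehaviorEffects",
    "hrf_kernel",
    "simulate_concentration",
    "forward_intensity",
    "simulate_behavior",
    "simulate_session",
]


@dataclass(frozen=True)
class HRFParams:
    """Double-gamma HRF shape: peak ~5 s, undershoot ~15 s, ratio 1:6."""

    peak_delay: float = 6.0  # shape of the positive gamma lobe
    undershoot_delay: float = 16.0
    dispersion: float = 1.0  # common scale (s)
    undershoot_ratio: float = 6.0


def hrf_kernel(t: np.ndarray | float, params: HRFParams = HRFParams()) -> np.ndarray:
    """Canonical double-gamma response, peak-normalised to 1; zero for t < 0."""
    t = np.asarray(t, dtype=float)
    p = params

    def _gamma_pdf(x, shape, scale):
        x = np.maximum(x, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(
                x > 0,
                np.exp(
                    (shape - 1) * np.log(np.maximum(x, 1e-300))
                    - x / scale
                    - shape * math.log(scale)
                    - math.lgamma(shape)
                ),
                0.0,
            )
        return out

    h = _gamma_pdf(t, p.peak_delay, p.dispersion) - _gamma_pdf(
        t, p.undershoot_delay, p.dispersion
    ) / p.undershoot_ratio
    # normalise so the positive peak is 1 (evaluated on a fine grid once)
    grid = np.arange(0, 32, 0.01)
    peak = (
        _gamma_pdf(grid, p.peak_delay, p.dispersion)
        - _gamma_pdf(grid, p.undershoot_delay, p.dispersion) / p.undershoot_ratio
    ).max()
    return h / peak


@dataclass(frozen=True)
class OscComponent:
    """One physiological oscillation: sinusoid at ``freq_hz`` with amplitude in umol/L."""

    freq_hz: float
    amp_uM: float
    label: str = ""


@dataclass(frozen=True)
class Artifact:
    """Scheduled motion artifact: a one-sample spike or a sustained baseline jump."""

    time_s: float
    kind: str  # "spike" | "jump"
    magnitude_uM: float
    channel: str | None = None  # None = all channels


@dataclass
class GroundTruth:
    """Programmed generative parameters for one synthetic session.

    Default HbO amplitudes rise and HbR amplitudes fall with n-back load
    (steady-state umol/L); drift offsets model the cephalad-fluid-shift
    baseline change per tilt, reaching each plateau through a causal ~120 s
    smoothstep after the tilt change.
    """

    amplitudes_hbo: dict[str, float] = field(
        default_factory=lambda: {"control": 0.05, "0back": 0.20, "1back": 0.35, "2back": 0.50}
    )
    amplitudes_hbr: dict[str, float] = field(
        default_factory=lambda: {"control": -0.02, "0back": -0.07, "1back": -0.12, "2back": -0.17}
    )
    drift_offsets: dict[str, float] = field(
        default_factory=lambda: {"pre0": 0.0, "m10": 1.5, "m20": 3.0, "post0": 0.5}
    )
    drift_hbr_ratio: float = 0.5  # fluid shift raises total blood volume: HbR follows HbO
    drift_transition_s: float = 120.0
    oscillations: tuple[OscComponent, ...] = (
        OscComponent(1.1, 0.10, "cardiac"),
        OscComponent(0.25, 0.10, "respiratory"),
        OscComponent(0.10, 0.15, "mayer"),
    )
    white_noise_sd_uM: float = 0.20
    channel_correlation: float = 0.3
    subject_amplitude_sd: float = 0.2  # lognormal sigma of a per-subject gain (mean 1)
    artifacts: tuple[Artifact, ...] = ()
    hrf: HRFParams = HRFParams()

    def validate(self, fs: float) -> list[str]:
        """Return warnings (e.g. oscillation above Nyquist); raise on hard errors."""
        warnings = []
        for comp in self.oscillations:
            if comp.freq_hz >= fs / 2:
                warnings.append(
                    f"oscillation {comp.label or comp.freq_hz} at {comp.freq_hz} Hz "
                    f"is at/above Nyquist ({fs / 2} Hz) and will alias"
                )
        for name, amps in (("HbO", self.amplitudes_hbo), ("HbR", self.amplitudes_hbr)):
            missing = [lv for lv in LEVELS if lv not in amps]
            if missing:
                raise ValueError(f"{name} amplitudes missing levels {missing}")
        missing = [t for t in TILTS if t not in self.drift_offsets]
        if missing:
            raise ValueError(f"drift offsets missing tilts {missing}")
        return warnings

    def zero_noise(self) -> "GroundTruth":
        """Copy with all stochastic/nuisance components switched off (drift kept)."""
        return replace(
            self,
            oscillations=(),
            white_noise_sd_uM=0.0,
            subject_amplitude_sd=0.0,
            artifacts=(),
        )


def _unit_integral_kernel(fs: float, params: HRFParams, length_s: float = 40.0) -> np.ndarray:
    t = np.arange(0, length_s, 1.0 / fs)
    k = hrf_kernel(t, params)
    return k / (k.sum() / fs)


def _drift(design: SessionDesign, gt: GroundTruth, n: int, fs: float) -> np.ndarray:
    """Piecewise-constant tilt offsets joined by causal cosine smoothsteps.

    The transition starts exactly at each tilt boundary (the signal cannot
    anticipate the posture change) and completes in ``drift_transition_s``.
    """
    t = np.arange(n) / fs
    offsets = [gt.drift_offsets[tilt] for tilt in design.tilt_sequence]
    out = np.full(n, offsets[0], dtype=float)
    for i in range(1, len(offsets)):
        t0 = i * design.tilt_duration_s
        tau = gt.drift_transition_s
        step = offsets[i] - offsets[i - 1]
        phase = np.clip((t - t0) / tau, 0.0, 1.0)
        out += step * 0.5 * (1.0 - np.cos(np.pi * phase))
    return out


def _activation(
    design: SessionDesign, amplitudes: dict[str, float], fs: float, kernel: np.ndarray, n: int
) -> np.ndarray:
    resp = np.zeros(n)
    for _tilt, _slot, block, start, end in design.iter_blocks():
        amp = amplitudes[block.level]
        if amp == 0.0:
            continue
        boxcar = np.zeros(n)
        boxcar[int(round(start * fs)) : int(round(end * fs))] = amp
        resp += np.convolve(boxcar, kernel)[:n] / fs
    return resp


def simulate_concentration(
    design: SessionDesign,
    ground_truth: GroundTruth | None = None,
    fs: float = 10.0,
    rng: np.random.Generator | int | None = None,
    channels: tuple[str, ...] = DEFAULT_CHANNELS,
) -> tuple[ConcentrationSeries, GroundTruth]:
    """Generate per-channel dHbO/dHbR series for one session.

    Channels share the neural signal and drift; oscillations share phase
    across channels while white noise is correlated at
    ``ground_truth.channel_correlation``.  Returns the series together with
    the (possibly per-subject-scaled) ground truth actually used.
    """
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    gt = ground_truth if ground_truth is not None else GroundTruth()
    gt.validate(fs)
    rng = np.random.default_rng(rng)

    n = int(round(design.protocol_duration_s * fs))
    t = np.arange(n) / fs
    kernel = _unit_integral_kernel(fs, gt.hrf)

    if gt.subject_amplitude_sd > 0:
        sigma = gt.subject_amplitude_sd
        gain = float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))  # E[gain] = 1
        gt = replace(
            gt,
            amplitudes_hbo={k: v * gain for k, v in gt.amplitudes_hbo.items()},
            amplitudes_hbr={k: v * gain for k, v in gt.amplitudes_hbr.items()},
        )

    act_hbo = _activation(design, gt.amplitudes_hbo, fs, kernel, n)
    act_hbr = _activation(design, gt.amplitudes_hbr, fs, kernel, n)
    drift = _drift(design, gt, n, fs)

    osc = np.zeros(n)
    for comp in gt.oscillations:
        phase = rng.uniform(0, 2 * np.pi)
        osc += comp.amp_uM * np.sin(2 * np.pi * comp.freq_hz * t + phase)

    rho = gt.channel_correlation
    common = rng.standard_normal(n)
    hbo, hbr = {}, {}
    for ch in channels:
        indep = rng.standard_normal(n)
        noise = gt.white_noise_sd_uM * (rho * common + math.sqrt(1 - rho**2) * indep)
        x_hbo = act_hbo + drift + osc + noise
        x_hbr = act_hbr + gt.drift_hbr_ratio * drift - 0.4 * osc + 0.5 * gt.white_noise_sd_uM * (
            rho * common + math.sqrt(1 - rho**2) * rng.standard_normal(n)
        )
        for art in gt.artifacts:
            if art.channel is not None and art.channel != ch:
                continue
            idx = int(round(art.time_s * fs))
            if not 0 <= idx < n:
                continue
            if art.kind == "spike":
                x_hbo[idx] += art.magnitude_uM
                x_hbr[idx] += art.magnitude_uM
            elif art.kind == "jump":
                x_hbo[idx:] += art.magnitude_uM
                x_hbr[idx:] += art.magnitude_uM
            else:
                raise ValueError(f"unknown artifact kind {art.kind!r}")
        hbo[ch] = x_hbo
        hbr[ch] = x_hbr
    return ConcentrationSeries(fs=fs, hbo=hbo, hbr=hbr), gt


def forward_intensity(
    series: ConcentrationSeries,
    geometry: OpticalGeometry = DEFAULT_GEOMETRY,
    reference_intensity: float | dict[tuple[str, int], float] = 1000.0,
) -> RawRecording:
    """Exact MBLL forward model: concentrations to raw dual-wavelength intensities.

    ``I(lambda, t) = I_ref(lambda) * 10**(-(E @ c)(lambda, t))`` with ``E`` the
    effective extinction matrix of ``geometry``.  The processing chain's
    OD conversion + inversion recovers ``series`` exactly when ``I0 == I_ref``
    (up to the mean-referencing of I0, which shifts OD by a constant).
    """
    m = geometry.mbll_matrix()
    intensity: dict[tuple[str, int], np.ndarray] = {}
    for ch in series.channels:
        od = m @ np.vstack([series.hbo[ch], series.hbr[ch]])
        for row, wl in enumerate(geometry.wavelengths_nm):
            if isinstance(reference_intensity, dict):
                i_ref = reference_intensity[(ch, wl)]
            else:
                i_ref = float(reference_intensity)
            if i_ref <= 0:
                raise ValueError(f"reference intensity must be positive, got {i_ref}")
            intensity[(ch, wl)] = i_ref * 10.0 ** (-od[row])
    return RawRecording(fs=series.fs, intensity=intensity)


@dataclass(frozen=True)
class BehaviorEffects:
    """Per-level response model: accuracy probability and lognormal RT (s).

    Defaults encode the expected difficulty gradient: accuracy falls and
    latency rises with n; the control condition is a fast simple reaction.
    """

    accuracy: dict[str, float] = field(
        default_factory=lambda: {"control": 0.99, "0back": 0.97, "1back": 0.92, "2back": 0.80}
    )
    rt_mean_s: dict[str, float] = field(
        default_factory=lambda: {"control": 0.45, "0back": 0.85, "1back": 1.10, "2back": 1.25}
    )
    rt_sd_s: dict[str, float] = field(
        default_factory=lambda: {"control": 0.10, "0back": 0.25, "1back": 0.30, "2back": 0.35}
    )
    max_rt_s: float = 2.0

    def validate(self) -> None:
        for lv, p in self.accuracy.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"accuracy probability for {lv} outside [0,1]: {p}")


def _lognormal_rt(rng: np.random.Generator, mean: float, sd: float, max_rt: float) -> float:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    for _ in range(100):  # truncate to (0, max_rt] by resampling
        rt = float(rng.lognormal(mu, math.sqrt(sigma2)))
        if rt <= max_rt:
            return rt
    return max_rt


def simulate_behavior(
    design: SessionDesign,
    effects: BehaviorEffects | None = None,
    rng: np.random.Generator | int | None = None,
) -> dict[tuple[str, int], list[TrialResponse]]:
    """Simulate button presses for every block; keyed by (tilt, slot).

    Scoreable yes/no trials are answered correctly with the level's
    probability (errors press the opposite button); control errors are
    lapses (no press); unscoreable lead-in trials get a random press.
    """
    effects = effects or BehaviorEffects()
    effects.validate()
    rng = np.random.default_rng(rng)
    out: dict[tuple[str, int], list[TrialResponse]] = {}
    for tilt in design.tilt_sequence:
        for slot, block in enumerate(design.blocks_by_tilt[tilt]):
            lv = block.level
            responses = []
            for trial in block.trials:
                rt = _lognormal_rt(
                    rng, effects.rt_mean_s[lv], effects.rt_sd_s[lv], effects.max_rt_s
                )
                if trial.correct_response == "any":
                    if rng.random() < effects.accuracy[lv]:
                        responses.append(TrialResponse(trial.index, "yes", rt))
                    else:
                        responses.append(TrialResponse(trial.index, "none", None))
                elif trial.correct_response is None:
                    responses.append(
                        TrialResponse(trial.index, "yes" if rng.random() < 0.5 else "no", rt)
                    )
                else:
                    if rng.random() < effects.accuracy[lv]:
                        responses.append(TrialResponse(trial.index, trial.correct_response, rt))
                    else:
                        wrong = "no" if trial.correct_response == "yes" else "yes"
                        responses.append(TrialResponse(trial.index, wrong, rt))
            out[(tilt, slot)] = responses
    return out


def simulate_session(
    participant_index: int,
    seed: int,
    ground_truth: GroundTruth | None = None,
    effects: BehaviorEffects | None = None,
    fs: float = 10.0,
    geometry: OpticalGeometry = DEFAULT_GEOMETRY,
):
    """Convenience wrapper: design + raw intensities + responses + ground truth.

    All randomness derives from (seed, participant_index); repeated calls are
    bit-identical.
    """
    design = build_session(participant_index, rng_seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, participant_index, 1]))
    conc, gt_used = simulate_concentration(design, ground_truth, fs=fs, rng=rng)
    raw = forward_intensity(conc, geometry)
    responses = simulate_behavior(design, effects, rng=rng)
    return design, raw, responses, gt_used
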