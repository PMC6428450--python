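"""Synthetic dual-wavelength recordings with known ground truth.

The generator emulates a block-design finger-tapping acquisition:
3.9062 Hz sampling, 10 s-on / 15 s-off × 10 blocks, long (30 mm) and
short (20 mm) channels, and the canonical frequency structure of scalp
hemodynamics — cardiac (~1 Hz), respiration (~0.3 Hz), lagged global
low-frequency oscillations (0.01-0.15 Hz) and slow drift — plus
HbO-increase / HbR-decrease activation in designated ROI channels.

Composition rule: latent hemoglobin dynamics (µM) are summed per channel,
mapped to ΔOD through the forward modified Beer-Lambert law, and
exponentiated to intensity, ``I = I0·exp(−ΔOD) + white noise``.  Bad
channels receive no cardiac component and 10× measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .mbll import concentration_to_od
from .types import (ChannelInfo, ConcentrationSeries, OpticalDensitySeries,
                    ProbeLayout, RawRecording, StimulusDesign, ValidationError)

__all__ = ["SimulationConfig", "ArtifactEvent", "GroundTruth", "canonical_hrf",
           "simulate_recording", "simulate_cohort", "inject_motion",
           "default_layout", "default_design", "neural_response"]


def default_design(n_blocks: int = 10, task_s: float = 10.0, rest_s: float = 15.0,
                   lead_in_s: float = 15.0) -> StimulusDesign:
    """10 s-on / 15 s-off block design with a 15 s lead-in rest."""
    onsets = tuple(lead_in_s + k * (task_s + rest_s) for k in range(n_blocks))
    return StimulusDesign(onsets=onsets, task_duration=task_s, rest_duration=rest_s)


def default_layout(n_long: int = 20, n_short: int = 2,
                   long_distance_mm: float = 30.0,
                   short_distance_mm: float = 20.0,
                   wavelengths=(760.0, 850.0)) -> ProbeLayout:
    """Scaled-down probe: ``n_long`` 30 mm channels, ``n_short`` 20 mm
    short-separation channels, and a 4-channel motor ROI.

    Long channels are split into two hemispheres (first half / second
    half); short channels are appended at the end, one per hemisphere
    when two are requested.
    """
    if n_long < 1:
        raise ValidationError("need at least one long channel")
    if n_short > n_long:
        raise ValidationError("cannot have more short than long channels")
    channels = []
    for i in range(n_long):
        channels.append(ChannelInfo(source_id=i, detector_id=i, distance=long_distance_mm,
                                    is_short=False))
    for j in range(n_short):
        # short optodes re-use a source within each hemisphere
        src = (j * n_long) // max(n_short, 1) if n_short else 0
        channels.append(ChannelInfo(source_id=src, detector_id=n_long + j,
                                    distance=short_distance_mm, is_short=True))
    # 4 motor-ROI channels (or fewer for tiny probes), mirroring a probe
    # whose M1 channels cluster around one detector
    roi_positions = [i for i in (3, 4, 9, 11) if i < n_long]
    if not roi_positions:
        roi_positions = [0]
    return ProbeLayout(channels=tuple(channels), wavelengths=wavelengths,
                       roi_channels=frozenset(roi_positions))


@dataclass(frozen=True)
class ArtifactEvent:
    """A motion artifact: a Gaussian spike or a step baseline shift.

    ``amplitude`` is expressed in multiples of the affected channel's
    (pre-artifact) standard deviation.
    """

    time: float
    kind: str  # "spike" | "baseline_shift"
    amplitude: float
    width: float = 0.5  # seconds, spikes only
    channel: int | None = None  # None = all channels

    def __post_init__(self) -> None:
        if self.kind not in ("spike", "baseline_shift"):
            raise ValidationError(f"unknown artifact kind {self.kind!r}")
        if self.amplitude == 0:
            raise ValidationError("artifact amplitude must be nonzero")


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study's acquisition.

    Amplitudes are in µM of the latent hemoglobin components.  The
    global-LF amplitude pair is calibrated so that the block-level
    Cohen's d of the ROI response (no de-noising pipeline) lands near
    0.8.
    """

    n_channels: int = 20            # long channels
    n_short: int = 2
    fs: float = 3.9062
    design: StimulusDesign = field(default_factory=default_design)
    subject_age: float = 20.0
    activation_hbo_amp: float = 0.5       # µM peak of the ROI response
    activation_hbr_amp: float = -0.5 / 3  # µM, opposite sign, 1 s extra delay
    hbr_delay_s: float = 1.0
    global_lf_band: tuple[float, float] = (0.01, 0.15)
    global_sine_freq: float = 0.1
    global_sine_amp: float = 1.05         # µM (HbO); HbR gets 1/3
    global_noise_amp: float = 0.525       # µM band-limited noise SD (HbO)
    global_lag_range: float = 5.0         # lags drawn uniformly in ± this, s
    cardiac_freq: float = 1.0
    cardiac_amp: float = 0.6              # µM (HbO); HbR gets 1/4
    resp_freq: float = 0.3
    resp_amp: float = 0.2
    drift_amp: float = 0.15               # µM, very-low-frequency (<0.01 Hz)
    noise_sd: float = 0.004               # intensity units (I0 = 1)
    bad_channel_noise_factor: float = 10.0
    short_systemic_gain: float = 1.0      # superficial weighting of short channels
    motion_events: tuple[ArtifactEvent, ...] = ()
    bad_channels: frozenset[int] = field(default_factory=frozenset)
    i0: float = 1.0

    def __post_init__(self) -> None:
        no_activation = self.activation_hbo_amp == 0 and self.activation_hbr_amp == 0
        if not no_activation and not (self.activation_hbr_amp < 0 < self.activation_hbo_amp):
            raise ValidationError(
                "the model assumes activation_hbr_amp < 0 < activation_hbo_amp "
                "(or both zero for a null recording)"
            )
        nyq = self.fs / 2
        for f in (self.global_lf_band[1], self.cardiac_freq, self.resp_freq):
            if f >= nyq:
                raise ValidationError(f"component frequency {f} Hz exceeds Nyquist {nyq} Hz")

    def layout(self) -> ProbeLayout:
        return default_layout(self.n_channels, self.n_short)


@dataclass
class GroundTruth:
    """The simulation's latent state: the recovery-test oracle."""

    true_hbo: np.ndarray            # µM plateau per channel
    true_hbr: np.ndarray
    channel_lags: np.ndarray        # s, global LF delay per channel
    bad_channels: frozenset[int]
    artifact_log: tuple[ArtifactEvent, ...]
    neural_hbo: np.ndarray          # [time] unit response (peak 1)
    neural_hbr: np.ndarray
    global_lf: np.ndarray           # master LF series (unit µM scale applied)
    cardiac: np.ndarray
    resp: np.ndarray
    drift: np.ndarray               # [time, channel]

    def to_dict(self) -> dict:
        return {
            "true_hbo": self.true_hbo.tolist(),
            "true_hbr": self.true_hbr.tolist(),
            "channel_lags": self.channel_lags.tolist(),
            "bad_channels": sorted(self.bad_channels),
            "artifacts": [vars(e) for e in self.artifact_log],
        }


def canonical_hrf(fs: float, duration_s: float = 32.0, peak_s: float = 6.0,
                  undershoot_s: float = 16.0, ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Double-gamma hemodynamic response kernel, normalized to unit peak.

    Gamma densities with unit scale peak at (shape−1), so shapes are
    ``peak_s+1`` and ``undershoot_s+1``.  The kernel peaks at ~``peak_s``
    and decays below 1e-3 of the peak by ``duration_s``.
    """
    if fs <= 0:
        raise ValidationError("fs must be positive")
    if not peak_s < undershoot_s:
        raise ValidationError("peak must precede the undershoot")
    from scipy import stats
    t = np.arange(int(round(duration_s * fs))) / fs
    h = stats.gamma.pdf(t, a=peak_s + 1.0) - ratio * stats.gamma.pdf(t, a=undershoot_s + 1.0)
    return h / np.abs(h).max()


def _bandlimited_noise(n: int, fs: float, band, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD Gaussian noise confined to a frequency band (FFT masking)."""
    white = rng.standard_normal(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec = np.fft.rfft(white)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    spec[~mask] = 0.0
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _fractional_delay(x: np.ndarray, lag_s: float, fs: float) -> np.ndarray:
    """Delay a (periodic, band-limited) series by ``lag_s`` via the FFT
    phase ramp; positive lag shifts the series later in time."""
    n = x.size
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec = np.fft.rfft(x) * np.exp(-2j * np.pi * freqs * lag_s)
    return np.fft.irfft(spec, n=n)


def neural_response(design: StimulusDesign, fs: float, n_samples: int,
                    delay_s: float = 0.0, hrf_kwargs: dict | None = None) -> np.ndarray:
    """Boxcar convolved with the canonical HRF, normalized to unit peak."""
    box = design.boxcar(n_samples, fs)
    h = canonical_hrf(fs, **(hrf_kwargs or {}))
    resp = signal.fftconvolve(box, h)[:n_samples]
    peak = np.abs(resp).max()
    if peak > 0:
        resp = resp / peak
    if delay_s:
        shift = int(round(delay_s * fs))
        resp = np.concatenate([np.zeros(shift), resp[:n_samples - shift]])
    return resp


def simulate_recording(cfg: SimulationConfig, seed: int) -> tuple[RawRecording, GroundTruth]:
    """Generate one subject's raw recording plus its ground truth.

    Deterministic given ``(cfg, seed)``.
    """
    rng = np.random.default_rng(seed)
    layout = cfg.layout()
    nc = layout.n_channels
    design = cfg.design
    end = design.onsets[-1] + design.task_duration + design.rest_duration
    n = int(round(end * cfg.fs))
    t = np.arange(n) / cfg.fs

    # latent components (µM)
    neural_hbo = neural_response(design, cfg.fs, n)
    neural_hbr = neural_response(design, cfg.fs, n, delay_s=cfg.hbr_delay_s)
    master_lf = (cfg.global_sine_amp * np.sin(2 * np.pi * cfg.global_sine_freq * t
                                              + rng.uniform(0, 2 * np.pi))
                 + cfg.global_noise_amp * _bandlimited_noise(n, cfg.fs, cfg.global_lf_band, rng))
    cardiac = cfg.cardiac_amp * np.sin(2 * np.pi * cfg.cardiac_freq * t + rng.uniform(0, 2 * np.pi))
    resp = cfg.resp_amp * np.sin(2 * np.pi * cfg.resp_freq * t + rng.uniform(0, 2 * np.pi))
    lags = rng.uniform(-cfg.global_lag_range, cfg.global_lag_range, size=nc)

    true_hbo = np.zeros(nc)
    true_hbr = np.zeros(nc)
    hbo = np.zeros((n, nc))
    hbr = np.zeros((n, nc))
    drift = np.zeros((n, nc))
    for ci in range(nc):
        is_short = layout.channels[ci].is_short
        systemic_gain = cfg.short_systemic_gain if is_short else 1.0
        lf = _fractional_delay(master_lf, lags[ci], cfg.fs) * systemic_gain
        drift[:, ci] = cfg.drift_amp * signal.sawtooth(
            2 * np.pi * 0.004 * t + rng.uniform(0, 2 * np.pi), width=0.5)
        card = 0.0 if ci in cfg.bad_channels else cardiac * systemic_gain
        hbo[:, ci] = lf + card + resp * systemic_gain + drift[:, ci]
        hbr[:, ci] = (lf / 3 + (card / 4 if np.ndim(card) else 0.0)
                      + resp * systemic_gain / 4 + drift[:, ci] / 3)
        if (ci in layout.roi_channels) and not is_short:
            true_hbo[ci] = cfg.activation_hbo_amp
            true_hbr[ci] = cfg.activation_hbr_amp
            hbo[:, ci] += true_hbo[ci] * neural_hbo
            hbr[:, ci] += true_hbr[ci] * neural_hbr

    conc = ConcentrationSeries(hbo=hbo, hbr=hbr, fs=cfg.fs, layout=layout, stimulus=design)
    od = concentration_to_od(conc, age_years=cfg.subject_age,
                             subject_age_out=cfg.subject_age)
    od_arr = od.od
    if cfg.motion_events:
        od = inject_motion(od, cfg.motion_events, seed=seed)
        od_arr = od.od

    intensity = cfg.i0 * np.exp(-od_arr)
    noise_sd = np.full(nc, cfg.noise_sd)
    for ci in cfg.bad_channels:
        noise_sd[ci] *= cfg.bad_channel_noise_factor
    intensity = intensity + rng.standard_normal(intensity.shape) * noise_sd[None, :, None]
    # keep intensity physical (strictly positive)
    intensity = np.clip(intensity, 1e-6 * cfg.i0, None)

    rec = RawRecording(intensity=intensity, fs=cfg.fs, layout=layout,
                       stimulus=design, subject_age=cfg.subject_age)
    gt = GroundTruth(true_hbo=true_hbo, true_hbr=true_hbr, channel_lags=lags,
                     bad_channels=frozenset(cfg.bad_channels),
                     artifact_log=tuple(cfg.motion_events),
                     neural_hbo=neural_hbo, neural_hbr=neural_hbr,
                     global_lf=master_lf, cardiac=cardiac, resp=resp, drift=drift)
    return rec, gt


def inject_motion(series, events, seed: int = 0):
    """Add spike / baseline-shift artifacts to an OD series (or raw array).

    Spikes add a Gaussian bump of the stated width; baseline shifts add a
    step from the event time onward.  Amplitudes are multiples of each
    affected channel's current standard deviation.
    """
    is_od = isinstance(series, OpticalDensitySeries)
    arr = series.od.copy() if is_od else np.array(series, dtype=float)
    fs = series.fs if is_od else None
    if fs is None:
        raise ValidationError("inject_motion requires an OpticalDensitySeries")
    n = arr.shape[0]
    t = np.arange(n) / fs
    for ev in events:
        if not (0 <= ev.time < n / fs):
            raise ValidationError(f"artifact at {ev.time} s lies outside the recording")
        chans = range(arr.shape[1]) if ev.channel is None else [ev.channel]
        for ci in chans:
            for wi in range(arr.shape[2]):
                sd = arr[:, ci, wi].std()
                if sd == 0:
                    sd = 1.0
                if ev.kind == "spike":
                    sigma = max(ev.width / 2.355, 1e-6)  # width = FWHM
                    arr[:, ci, wi] += ev.amplitude * sd * np.exp(
                        -0.5 * ((t - ev.time) / sigma) ** 2)
                else:
                    arr[t >= ev.time, ci, wi] += ev.amplitude * sd
    if is_od:
        return series.copy_with(arr)
    return arr


def simulate_cohort(cfg: SimulationConfig, n_subjects: int, seed: int):
    """Yield (recording, ground truth) pairs with per-subject child seeds."""
    root = np.random.default_rng(seed)
    seeds = root.integers(0, 2**31 - 1, size=n_subjects)
    for s in seeds:
        yield simulate_recording(cfg, int(s))
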