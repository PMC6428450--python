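"""Automated channel-exclusion criteria.

Two rules:

* Coefficient of variation (CV) of the raw intensity,
  ``CV% = 100·sd/mean`` per wavelength (channel CV = max over the two
  wavelengths); channels with CV above a threshold (default 7.5%) carry
  unphysiological noise and are excluded.
* A windowed cardiac-coupling rule in the PHOEBE style: the recording is
  cut into non-overlapping windows (3 s default); a window passes when
  the scalp coupling index (zero-lag correlation of the two cardiac
  band-passed wavelengths) is >= 0.7 AND the peak normalized cardiac
  cross-power is >= 0.1.  A channel is kept when at least 80% of its
  windows pass.  The rule runs on optical density by default (a raw
  switch is provided).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .mbll import intensity_to_od
from .types import OpticalDensitySeries, RawRecording, ValidationError

__all__ = ["QualityReport", "coefficient_of_variation", "cv_exclusion",
           "sci", "cardiac_power", "phoebe_exclusion"]

CARDIAC_BAND = (0.8, 1.95)


@dataclass
class QualityReport:
    """Per-channel inclusion decisions plus the statistics that drove them."""

    method: str
    excluded: np.ndarray                       # bool [channel]
    cv_percent: np.ndarray | None = None       # [channel]
    fraction_windows_ok: np.ndarray | None = None
    sci_per_window: np.ndarray | None = None   # [channel, window]
    power_per_window: np.ndarray | None = None
    thresholds: dict = field(default_factory=dict)

    @property
    def included_indices(self) -> np.ndarray:
        return np.nonzero(~self.excluded)[0]

    @property
    def excluded_indices(self) -> np.ndarray:
        return np.nonzero(self.excluded)[0]

    def to_dict(self) -> dict:
        d = {"method": self.method, "thresholds": self.thresholds,
             "excluded": self.excluded.astype(bool).tolist()}
        if self.cv_percent is not None:
            d["cv_percent"] = np.round(self.cv_percent, 6).tolist()
        if self.fraction_windows_ok is not None:
            d["fraction_windows_ok"] = np.round(self.fraction_windows_ok, 6).tolist()
        return d


def coefficient_of_variation(raw_channel_intensity) -> float:
    """CV (%) = 100 × sd(data)/mean(data) of one raw intensity series.

    Uses the sample (n−1) standard deviation.  Raw intensity only: on
    optical density the mean is near zero and the ratio degenerates.
    """
    x = np.asarray(raw_channel_intensity, dtype=float)
    if x.size < 2:
        raise ValidationError("CV needs at least 2 samples")
    mean = x.mean()
    if mean <= 0:
        raise ValidationError("degenerate signal: non-positive mean intensity")
    return 100.0 * x.std(ddof=1) / mean


def cv_exclusion(rec: RawRecording, threshold_percent: float = 7.5) -> QualityReport:
    """Exclude channels whose worst-wavelength CV exceeds the threshold."""
    nc = rec.layout.n_channels
    cv = np.empty(nc)
    for ci in range(nc):
        cv[ci] = max(coefficient_of_variation(rec.intensity[:, ci, wi]) for wi in range(2))
    excluded = cv > threshold_percent
    return QualityReport(method="cv", excluded=excluded, cv_percent=cv,
                         thresholds={"cv_percent": threshold_percent})


def _cardiac_bandpass(x: np.ndarray, fs: float, band) -> np.ndarray:
    b, a = signal.butter(3, band, btype="bandpass", fs=fs)
    return signal.filtfilt(b, a, x, axis=0)


def sci(window_w1, window_w2, fs: float, band=CARDIAC_BAND,
        prefiltered: bool = False) -> float:
    """Scalp coupling index: zero-lag Pearson correlation of the
    cardiac-band signals at the two wavelengths of one channel.

    Returns NaN for a zero-variance window (counted as failing upstream).
    """
    x = np.asarray(window_w1, dtype=float)
    y = np.asarray(window_w2, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("windows must have equal length")
    if not prefiltered:
        x = _cardiac_bandpass(x, fs, band)
        y = _cardiac_bandpass(y, fs, band)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def cardiac_power(window_w1, window_w2, fs: float, band=CARDIAC_BAND,
                  prefiltered: bool = False) -> float:
    """Peak normalized cross-spectral power in the cardiac band.

    The windowed cross-correlation of the two (band-passed,
    unit-variance) wavelength signals is Fourier-transformed; the
    spectrum is normalized to unit total power so the returned peak lies
    in [0, 1] and a scale-free threshold (0.1) applies.  Shared cardiac
    pulsation concentrates cross-power at ~1 Hz; uncoupled noise spreads
    it over the whole band.
    """
    x = np.asarray(window_w1, dtype=float)
    y = np.asarray(window_w2, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("windows must have equal length")
    if not prefiltered:
        raw_power = x.var() * y.var()
        x = _cardiac_bandpass(x, fs, band)
        y = _cardiac_bandpass(y, fs, band)
        # a window with essentially no cardiac-band energy carries no
        # cardiac power; without this guard the normalization would
        # amplify the filter's out-of-band leakage
        if raw_power > 0 and x.var() * y.var() < 1e-4 * raw_power:
            return 0.0
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    x = (x - x.mean()) / sx
    y = (y - y.mean()) / sy
    xc = signal.correlate(x, y, mode="full")
    energy = np.sum(xc**2)
    if energy == 0:
        return np.nan
    xc = xc / np.sqrt(energy)  # unit-energy cross-correlation
    spec = np.abs(np.fft.rfft(xc)) ** 2
    total = spec.sum()
    if total == 0:
        return np.nan
    spec = spec / total
    freqs = np.fft.rfftfreq(xc.size, d=1.0 / fs)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(in_band):
        return 0.0
    return float(spec[in_band].max())


def phoebe_exclusion(rec: RawRecording, sci_thresh: float = 0.7,
                     power_thresh: float = 0.1, window_s: float = 3.0,
                     accept_fraction: float = 0.8, band=CARDIAC_BAND,
                     on: str = "od") -> QualityReport:
    """Windowed SCI + cardiac-power exclusion rule.

    A channel is excluded when fewer than ``accept_fraction`` of its
    complete windows satisfy both thresholds.  Runs on optical density
    (``on="od"``, the default) or raw intensity (``on="raw"``).
    """
    if on == "od":
        data = intensity_to_od(rec).od
    elif on == "raw":
        data = rec.intensity
    else:
        raise ValidationError(f"unknown domain {on!r}; use 'od' or 'raw'")
    fs = rec.fs
    win = int(round(window_s * fs))
    if win < 4:
        raise ValidationError("window too short for the cardiac band")
    n_win = data.shape[0] // win
    if n_win < 2:
        raise ValidationError("recording must span at least 2 windows")

    nc = rec.layout.n_channels
    sci_w = np.full((nc, n_win), np.nan)
    pow_w = np.full((nc, n_win), np.nan)
    # band-pass the full series once per channel, then cut windows
    for ci in range(nc):
        x = _cardiac_bandpass(data[:, ci, 0], fs, band)
        y = _cardiac_bandpass(data[:, ci, 1], fs, band)
        for wi in range(n_win):
            sl = slice(wi * win, (wi + 1) * win)
            sci_w[ci, wi] = sci(x[sl], y[sl], fs, band, prefiltered=True)
            pow_w[ci, wi] = cardiac_power(x[sl], y[sl], fs, band, prefiltered=True)
    ok = (sci_w >= sci_thresh) & (pow_w >= power_thresh)
    ok &= np.isfinite(sci_w) & np.isfinite(pow_w)  # undefined windows fail
    fraction = ok.mean(axis=1)
    excluded = fraction < accept_fraction
    return QualityReport(method="phoebe", excluded=excluded,
                         fraction_windows_ok=fraction, sci_per_window=sci_w,
                         power_per_window=pow_w,
                         thresholds={"sci": sci_thresh, "power": power_thresh,
                                     "window_s": window_s,
                                     "accept_fraction": accept_fraction})
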