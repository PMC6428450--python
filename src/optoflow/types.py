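"""Core domain containers for dual-wavelength fNIRS recordings.

All time-series arrays are indexed ``[time, channel]`` or
``[time, channel, wavelength]`` with wavelengths sorted ascending
(760 nm before 850 nm).  Time is in seconds, 0-based from the first
sample; stimulus onsets are seconds, not sample indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ChannelInfo",
    "ProbeLayout",
    "StimulusDesign",
    "RawRecording",
    "OpticalDensitySeries",
    "ConcentrationSeries",
    "ValidationError",
    "validate_recording",
]


class ValidationError(ValueError):
    """A domain-type invariant was violated."""


@dataclass(frozen=True)
class ChannelInfo:
    """One source-detector pair.

    Parameters
    ----------
    source_id, detector_id : int
        Optode indices (0-based).
    distance : float
        Geometric source-detector separation in mm.
    is_short : bool
        True for short-separation channels that sample mostly
        extracerebral tissue.
    """

    source_id: int
    detector_id: int
    distance: float
    is_short: bool = False

    SHORT_BOUND_MM = 20.0

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValidationError(f"channel distance must be > 0, got {self.distance}")
        if self.is_short and self.distance > self.SHORT_BOUND_MM:
            raise ValidationError(
                f"short channel at {self.distance} mm exceeds the "
                f"{self.SHORT_BOUND_MM} mm short-separation bound"
            )


@dataclass(frozen=True)
class ProbeLayout:
    """Ordered channel list, the two wavelengths, and the ROI channel set."""

    channels: tuple[ChannelInfo, ...]
    wavelengths: tuple[float, float]
    roi_channels: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "channels", tuple(self.channels))
        wl = tuple(sorted(float(w) for w in self.wavelengths))
        if len(wl) != 2 or wl[0] == wl[1]:
            raise ValidationError(f"exactly two distinct wavelengths required, got {self.wavelengths}")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "roi_channels", frozenset(int(i) for i in self.roi_channels))
        n = len(self.channels)
        if n == 0:
            raise ValidationError("layout has no channels")
        bad = [i for i in self.roi_channels if not (0 <= i < n)]
        if bad:
            raise ValidationError(f"roi_channels out of range: {bad}")
        if all(c.is_short for c in self.channels):
            raise ValidationError("layout needs at least one long (non-short) channel")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def long_indices(self) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.channels) if not c.is_short], dtype=int)

    @property
    def short_indices(self) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.channels) if c.is_short], dtype=int)

    @property
    def distances_mm(self) -> np.ndarray:
        return np.array([c.distance for c in self.channels], dtype=float)


@dataclass(frozen=True)
class StimulusDesign:
    """Block design: task onsets plus on/off durations.

    The fundamental task frequency is ``1 / (task_duration + rest_duration)``;
    a 10 s-on / 15 s-off design drives the response at 0.04 Hz with the
    first harmonic at 0.08 Hz.
    """

    onsets: tuple[float, ...]
    task_duration: float
    rest_duration: float

    def __post_init__(self) -> None:
        onsets = tuple(float(t) for t in self.onsets)
        object.__setattr__(self, "onsets", onsets)
        if len(onsets) == 0:
            raise ValidationError("at least one stimulus onset required")
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValidationError("onsets must be strictly increasing")
        if self.task_duration <= 0 or self.rest_duration < 0:
            raise ValidationError("durations must be positive")

    @property
    def n_blocks(self) -> int:
        return len(self.onsets)

    @property
    def fundamental_hz(self) -> float:
        return 1.0 / (self.task_duration + self.rest_duration)

    @property
    def first_harmonic_hz(self) -> float:
        return 2.0 * self.fundamental_hz

    def boxcar(self, n_samples: int, fs: float) -> np.ndarray:
        """0/1 task indicator sampled on the recording's time grid."""
        t = np.arange(n_samples) / fs
        box = np.zeros(n_samples)
        for onset in self.onsets:
            box[(t >= onset) & (t < onset + self.task_duration)] = 1.0
        return box


def _as_float_array(x, name: str, ndim: int) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != ndim:
        raise ValidationError(f"{name} must be {ndim}-D [time, channel(, wavelength)], got shape {arr.shape}")
    return arr


@dataclass
class RawRecording:
    """Raw dual-wavelength intensity, geometry, stimuli and subject age.

    ``intensity`` has shape ``[time, channel, wavelength]`` and must be
    strictly positive (it is a light intensity).
    """

    intensity: np.ndarray
    fs: float
    layout: ProbeLayout
    stimulus: StimulusDesign
    subject_age: float

    def __post_init__(self) -> None:
        self.intensity = _as_float_array(self.intensity, "intensity", 3)
        nt, nc, nw = self.intensity.shape
        if nc != self.layout.n_channels:
            raise ValidationError(
                f"intensity has {nc} channels but layout has {self.layout.n_channels}"
            )
        if nw != 2:
            raise ValidationError(f"intensity must carry 2 wavelengths, got {nw}")

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass
class OpticalDensitySeries:
    """Relative optical density ΔOD, shape ``[time, channel, wavelength]``."""

    od: np.ndarray
    fs: float
    layout: ProbeLayout
    stimulus: StimulusDesign | None = None
    subject_age: float | None = None

    def __post_init__(self) -> None:
        self.od = _as_float_array(self.od, "od", 3)
        if not np.all(np.isfinite(self.od)):
            raise ValidationError("optical density contains non-finite values")
        if self.od.shape[1] != self.layout.n_channels:
            raise ValidationError("od channel axis does not match layout")

    @property
    def n_samples(self) -> int:
        return self.od.shape[0]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def copy_with(self, od: np.ndarray) -> "OpticalDensitySeries":
        return OpticalDensitySeries(od=np.array(od, dtype=float), fs=self.fs,
                                    layout=self.layout, stimulus=self.stimulus,
                                    subject_age=self.subject_age)


@dataclass
class ConcentrationSeries:
    """ΔHbO / ΔHbR in µM, each shaped ``[time, channel]``."""

    hbo: np.ndarray
    hbr: np.ndarray
    fs: float
    layout: ProbeLayout
    stimulus: StimulusDesign | None = None

    def __post_init__(self) -> None:
        self.hbo = _as_float_array(self.hbo, "hbo", 2)
        self.hbr = _as_float_array(self.hbr, "hbr", 2)
        if self.hbo.shape != self.hbr.shape:
            raise ValidationError("hbo and hbr must have identical shape")
        if not (np.all(np.isfinite(self.hbo)) and np.all(np.isfinite(self.hbr))):
            raise ValidationError("concentrations contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[0]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def species(self, name: str) -> np.ndarray:
        if name == "hbo":
            return self.hbo
        if name == "hbr":
            return self.hbr
        raise KeyError(name)

    def copy_with(self, hbo: np.ndarray, hbr: np.ndarray) -> "ConcentrationSeries":
        return ConcentrationSeries(hbo=np.array(hbo, dtype=float), hbr=np.array(hbr, dtype=float),
                                   fs=self.fs, layout=self.layout, stimulus=self.stimulus)


def validate_recording(rec: RawRecording) -> list[str]:
    """Check every recording invariant; return issue descriptions.

    Returns an empty list iff the recording is clean.  Never raises: this
    is the reporting counterpart of the constructors' hard checks.
    """
    issues: list[str] = []
    if not rec.fs > 0:
        issues.append(f"non-positive sampling rate fs={rec.fs}")
    if not np.all(np.isfinite(rec.intensity)):
        bad = np.argwhere(~np.isfinite(rec.intensity))
        issues.append(f"non-finite intensity at [time,channel,wavelength]={bad[0].tolist()}")
    nonpos = rec.intensity <= 0
    if np.any(nonpos):
        for ch in np.unique(np.argwhere(nonpos)[:, 1]):
            issues.append(f"non-positive intensity in channel {ch}")
    if rec.fs > 0:
        end = rec.n_samples / rec.fs
        for k, onset in enumerate(rec.stimulus.onsets):
            if onset + rec.stimulus.task_duration > end:
                issues.append(
                    f"StimulusDesign onset {k} at {onset:.2f} s extends past the "
                    f"recording end ({end:.2f} s)"
                )
    if rec.subject_age is not None and rec.subject_age <= 0:
        issues.append(f"non-positive subject age {rec.subject_age}")
    return issues
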