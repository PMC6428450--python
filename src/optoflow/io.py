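"""Readers and writers for SNIRF (HDF5) and a simple CSV interchange dialect.

SNIRF is the canonical container: continuous-wave intensity under
``/nirs/data1``, probe geometry under ``/nirs/probe``, block onsets under
``/nirs/stim1``.  The CSV dialect (one column per channel×wavelength named
``chNN_w<nm>``, JSON side-car with fs/age/onsets/geometry) exists as a
documented plain-text convenience, mainly for tests and small examples.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .types import (ChannelInfo, ProbeLayout, RawRecording, StimulusDesign,
                    ValidationError)

__all__ = ["read_snirf", "write_snirf", "read_csv_recording", "write_csv_recording"]

_STR = h5py.string_dtype(encoding="utf-8")


def write_snirf(rec: RawRecording, path) -> Path:
    """Write a recording as a SNIRF v1.0 continuous-wave file.

    Lossless for intensity, geometry, wavelengths and stimulus onsets.
    Channel separations are encoded through synthetic 2-D optode
    positions (sources on y=0, detectors at y=distance).
    """
    if rec.layout.n_channels == 0:  # unreachable through ProbeLayout, kept for raw arrays
        raise ValidationError("cannot write a recording with 0 channels")
    path = Path(path)
    nt, nc, nw = rec.intensity.shape
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0", dtype=_STR)
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data="sim", dtype=_STR)
        meta.create_dataset("MeasurementDate", data="unknown", dtype=_STR)
        meta.create_dataset("MeasurementTime", data="unknown", dtype=_STR)
        meta.create_dataset("LengthUnit", data="mm", dtype=_STR)
        meta.create_dataset("TimeUnit", data="s", dtype=_STR)
        meta.create_dataset("FrequencyUnit", data="Hz", dtype=_STR)
        meta.create_dataset("SubjectAge", data=float(rec.subject_age))
        meta.create_dataset(
            "RoiChannels", data=json.dumps(sorted(rec.layout.roi_channels)), dtype=_STR
        )
        meta.create_dataset("TaskDuration", data=float(rec.stimulus.task_duration))
        meta.create_dataset("RestDuration", data=float(rec.stimulus.rest_duration))

        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(rec.layout.wavelengths, float))
        n_src = max(c.source_id for c in rec.layout.channels) + 1
        n_det = max(c.detector_id for c in rec.layout.channels) + 1
        src = np.zeros((n_src, 2))
        det = np.zeros((n_det, 2))
        for c in rec.layout.channels:
            src[c.source_id] = (30.0 * c.source_id, 0.0)
            det[c.detector_id] = (30.0 * c.source_id, c.distance)
        probe.create_dataset("sourcePos2D", data=src)
        probe.create_dataset("detectorPos2D", data=det)

        data = nirs.create_group("data1")
        flat = rec.intensity.reshape(nt, nc * nw)  # column order: channel-major, wavelength-minor
        data.create_dataset("dataTimeSeries", data=flat)
        data.create_dataset("time", data=np.arange(nt) / rec.fs)
        for m in range(nc * nw):
            ch, wl = divmod(m, nw)
            g = data.create_group(f"measurementList{m + 1}")
            g.create_dataset("sourceIndex", data=rec.layout.channels[ch].source_id + 1)
            g.create_dataset("detectorIndex", data=rec.layout.channels[ch].detector_id + 1)
            g.create_dataset("wavelengthIndex", data=wl + 1)
            g.create_dataset("dataType", data=1)  # CW amplitude
            g.create_dataset("dataTypeIndex", data=1)

        stim = nirs.create_group("stim1")
        stim.create_dataset("name", data="Tap", dtype=_STR)
        onsets = np.asarray(rec.stimulus.onsets, float)
        stim.create_dataset(
            "data",
            data=np.column_stack([onsets,
                                  np.full_like(onsets, rec.stimulus.task_duration),
                                  np.ones_like(onsets)]),
        )
    return path


def read_snirf(path) -> RawRecording:
    """Read a continuous-wave SNIRF file written by :func:`write_snirf`
    (or any two-wavelength CW SNIRF with the groups used there)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        nirs = f["nirs"]
        probe = nirs["probe"]
        wavelengths = np.asarray(probe["wavelengths"][()], float)
        if wavelengths.size != 2:
            raise ValidationError(
                f"unsupported SNIRF: expected exactly 2 wavelengths, found {wavelengths.size}"
            )
        src = np.asarray(probe["sourcePos2D"][()], float)
        det = np.asarray(probe["detectorPos2D"][()], float)

        data = nirs["data1"]
        ts = np.asarray(data["dataTimeSeries"][()], float)
        time = np.asarray(data["time"][()], float)
        if time.size < 2:
            raise ValidationError("SNIRF time axis too short")
        fs = 1.0 / float(np.median(np.diff(time)))

        ml_keys = sorted((k for k in data.keys() if k.startswith("measurementList")),
                         key=lambda k: int(k[len("measurementList"):]))
        order = np.argsort(wavelengths)
        # group measurements into channels keyed by (source, detector)
        chan_map: dict[tuple[int, int], dict[int, int]] = {}
        for col, k in enumerate(ml_keys):
            g = data[k]
            s = int(g["sourceIndex"][()]) - 1
            d = int(g["detectorIndex"][()]) - 1
            w = int(g["wavelengthIndex"][()]) - 1
            chan_map.setdefault((s, d), {})[w] = col
        pairs = sorted(chan_map, key=lambda sd: min(chan_map[sd].values()))
        nt, nc, nw = ts.shape[0], len(pairs), 2
        intensity = np.empty((nt, nc, nw))
        channels = []
        for ci, (s, d) in enumerate(pairs):
            cols = chan_map[(s, d)]
            if len(cols) != 2:
                raise ValidationError(f"channel (source {s}, detector {d}) lacks both wavelengths")
            for wi, w_orig in enumerate(order):
                intensity[:, ci, wi] = ts[:, cols[int(w_orig)]]
            dist = float(np.linalg.norm(src[s] - det[d]))
            channels.append(ChannelInfo(source_id=s, detector_id=d, distance=dist,
                                        is_short=dist <= ChannelInfo.SHORT_BOUND_MM))
        if np.any(intensity <= 0):
            raise ValidationError("SNIRF intensity contains non-positive values")

        meta = nirs["metaDataTags"]
        age = float(meta["SubjectAge"][()]) if "SubjectAge" in meta else 25.0
        roi = frozenset(json.loads(meta["RoiChannels"][()])) if "RoiChannels" in meta else frozenset()
        stim = nirs["stim1"]
        stim_data = np.atleast_2d(np.asarray(stim["data"][()], float))
        onsets = tuple(stim_data[:, 0])
        task_dur = float(stim_data[0, 1])
        rest_dur = float(meta["RestDuration"][()]) if "RestDuration" in meta else 15.0

    layout = ProbeLayout(channels=tuple(channels),
                         wavelengths=(wavelengths.min(), wavelengths.max()),
                         roi_channels=roi)
    design = StimulusDesign(onsets=onsets, task_duration=task_dur, rest_duration=rest_dur)
    return RawRecording(intensity=intensity, fs=fs, layout=layout,
                        stimulus=design, subject_age=age)


# ---------------------------------------------------------------------------
# CSV dialect


def _column_name(ch: int, wl: float) -> str:
    return f"ch{ch:02d}_w{int(round(wl))}"


def write_csv_recording(rec: RawRecording, intensity_path, meta_path) -> tuple[Path, Path]:
    """Write the CSV dialect: intensity table + JSON side-car."""
    intensity_path, meta_path = Path(intensity_path), Path(meta_path)
    cols = {}
    for ci in range(rec.layout.n_channels):
        for wi, wl in enumerate(rec.layout.wavelengths):
            cols[_column_name(ci, wl)] = rec.intensity[:, ci, wi]
    pd.DataFrame(cols).to_csv(intensity_path, index=False, float_format="%.12g")
    meta = {
        "fs": rec.fs,
        "subject_age": rec.subject_age,
        "onsets": list(rec.stimulus.onsets),
        "task_duration": rec.stimulus.task_duration,
        "rest_duration": rec.stimulus.rest_duration,
        "wavelengths": list(rec.layout.wavelengths),
        "roi_channels": sorted(rec.layout.roi_channels),
        "channels": [
            {"source_id": c.source_id, "detector_id": c.detector_id,
             "distance_mm": c.distance, "is_short": c.is_short}
            for c in rec.layout.channels
        ],
    }
    meta_path.write_text(json.dumps(meta, indent=1))
    return intensity_path, meta_path


def read_csv_recording(intensity_path, meta_path) -> RawRecording:
    """Read the CSV dialect; validates the column set against the side-car."""
    meta = json.loads(Path(meta_path).read_text())
    df = pd.read_csv(intensity_path)
    wavelengths = tuple(sorted(meta["wavelengths"]))
    channels = tuple(
        ChannelInfo(source_id=c["source_id"], detector_id=c["detector_id"],
                    distance=c["distance_mm"], is_short=c["is_short"])
        for c in meta["channels"]
    )
    expected = [_column_name(ci, wl) for ci in range(len(channels)) for wl in wavelengths]
    missing = [c for c in expected if c not in df.columns]
    extra = [c for c in df.columns if c not in expected]
    if missing or extra:
        raise ValidationError(
            f"CSV columns do not match metadata: missing={missing}, unexpected={extra}"
        )
    nt = len(df)
    intensity = np.empty((nt, len(channels), 2))
    for ci in range(len(channels)):
        for wi, wl in enumerate(wavelengths):
            col = _column_name(ci, wl)
            vals = df[col].to_numpy(float)
            bad = np.nonzero(vals <= 0)[0]
            if bad.size:
                raise ValidationError(
                    f"non-positive intensity in column {col!r} at row {bad[0]}"
                )
            intensity[:, ci, wi] = vals
    layout = ProbeLayout(channels=channels, wavelengths=wavelengths,
                         roi_channels=frozenset(meta["roi_channels"]))
    design = StimulusDesign(onsets=tuple(meta["onsets"]),
                            task_duration=meta["task_duration"],
                            rest_duration=meta["rest_duration"])
    return RawRecording(intensity=intensity, fs=meta["fs"], layout=layout,
                        stimulus=design, subject_age=meta["subject_age"])
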