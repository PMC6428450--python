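"""Modified Beer-Lambert law conversions with age-dependent path length.

Intensity -> relative optical density -> hemoglobin concentration changes
(ΔHbO / ΔHbR, µM).  ΔOD uses the natural logarithm,

    ΔOD(λ, t) = −ln( I(λ, t) / Ī(λ) ),    Ī = geometric mean over time,

so the extinction coefficients (tabulated as decadic cm⁻¹ M⁻¹) are
rescaled by ln(10) and to mm⁻¹ µM⁻¹ internally.  The effective photon
path length is distance × DPF(λ, age), with the differential path length
factor taken from the general age/wavelength equation of Scholkmann &
Wolf (validated for frontotemporal locations):

    DPF(λ, A) = α + β A^γ + δ λ³ + ε λ² + ζ λ.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .types import (ConcentrationSeries, OpticalDensitySeries, ProbeLayout,
                    RawRecording, ValidationError)

__all__ = [
    "ExtinctionTable",
    "DPFModel",
    "dpf_age",
    "intensity_to_od",
    "od_to_concentration",
    "concentration_to_od",
]

_LN10 = float(np.log(10.0))


@dataclass(frozen=True)
class ExtinctionTable:
    """Hemoglobin extinction coefficients ε_HbO(λ), ε_HbR(λ).

    Values are stored in natural-log mm⁻¹ µM⁻¹ so that, with distances in
    mm and concentrations in µM, ΔOD = ε·C·d·DPF holds directly.
    """

    table: dict[float, tuple[float, float]]  # λ → (ε_HbO, ε_HbR)

    @classmethod
    def default(cls) -> "ExtinctionTable":
        """Load the packaged Gratzer/Kollias tabulation."""
        raw = json.loads(
            resources.files("optoflow.data").joinpath("extinction_hb.json").read_text()
        )
        scale = _LN10 * 1e-7  # cm⁻¹M⁻¹ (decadic) → mm⁻¹µM⁻¹ (natural log)
        table = {
            float(wl): (v["hbo"] * scale, v["hbr"] * scale)
            for wl, v in raw["coefficients"].items()
        }
        return cls(table=table)

    def matrix(self, wavelengths) -> np.ndarray:
        """2×2 matrix rows=[λ1, λ2], cols=[ε_HbO, ε_HbR]."""
        rows = []
        for wl in wavelengths:
            key = min(self.table, key=lambda k: abs(k - wl))
            if abs(key - wl) > 5.0:
                raise ValidationError(f"no extinction coefficients within 5 nm of {wl} nm")
            rows.append(self.table[key])
        E = np.array(rows, dtype=float)
        if abs(np.linalg.det(E)) < 1e-12:
            raise ValidationError("extinction matrix is singular for this wavelength pair")
        return E


@dataclass(frozen=True)
class DPFModel:
    """Coefficients of the general DPF(λ, age) equation."""

    alpha: float = 223.3
    beta: float = 0.05624
    gamma: float = 0.8493
    delta: float = -5.723e-7
    epsilon: float = 0.001245
    zeta: float = -0.9025

    def __call__(self, wavelength_nm: float, age_years: float) -> float:
        return dpf_age(wavelength_nm, age_years, self)


def dpf_age(wavelength_nm: float, age_years: float, model: DPFModel | None = None) -> float:
    """Differential path length factor at a wavelength for a subject age.

    Longer wavelengths travel a shorter effective path (DPF(760) > DPF(850))
    and DPF grows slowly with age.
    """
    if age_years <= 0:
        raise ValidationError(f"age must be positive, got {age_years}")
    m = model or DPFModel()
    lam = float(wavelength_nm)
    return (m.alpha + m.beta * float(age_years) ** m.gamma
            + m.delta * lam**3 + m.epsilon * lam**2 + m.zeta * lam)


def intensity_to_od(rec: RawRecording) -> OpticalDensitySeries:
    """ΔOD(t) = −ln(I(t)/Ī) per channel and wavelength.

    Ī is the geometric mean over the segment, so the conversion is the
    exact inverse of I = I0·exp(−x): it returns x − mean(x).
    """
    if np.any(rec.intensity <= 0):
        raise ValidationError("intensity must be strictly positive for OD conversion")
    log_i = np.log(rec.intensity)
    od = -(log_i - log_i.mean(axis=0, keepdims=True))
    return OpticalDensitySeries(od=od, fs=rec.fs, layout=rec.layout,
                                stimulus=rec.stimulus, subject_age=rec.subject_age)


def _pathlength_matrix(layout: ProbeLayout, dpf_per_wavelength, ext: ExtinctionTable):
    """Per-wavelength ε matrix and per-channel path lengths d·DPF (mm)."""
    E = ext.matrix(layout.wavelengths)  # [wavelength, species]
    dpf = np.asarray(dpf_per_wavelength, dtype=float)
    if dpf.shape != (2,):
        raise ValidationError("dpf_per_wavelength must give one DPF per wavelength")
    return E, dpf


def od_to_concentration(od: OpticalDensitySeries, layout: ProbeLayout | None = None,
                        dpf_per_wavelength=None, ext: ExtinctionTable | None = None,
                        age_years: float | None = None) -> ConcentrationSeries:
    """Invert the MBLL per channel: solve the 2×2 system

        ΔOD(λ) / (d · DPF(λ)) = ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR

    for (ΔHbO, ΔHbR) in µM.  DPFs default to the age-dependent model
    evaluated at ``age_years`` (or the OD series' stored subject age).
    """
    layout = layout or od.layout
    ext = ext or ExtinctionTable.default()
    if dpf_per_wavelength is None:
        age = age_years if age_years is not None else od.subject_age
        if age is None:
            raise ValidationError("either dpf_per_wavelength or a subject age is required")
        dpf_per_wavelength = [dpf_age(wl, age) for wl in layout.wavelengths]
    E, dpf = _pathlength_matrix(layout, dpf_per_wavelength, ext)
    Einv = np.linalg.inv(E)
    dists = layout.distances_mm  # [channel]
    # normalize OD by per-channel, per-wavelength path length, then invert ε
    scaled = od.od / (dists[None, :, None] * dpf[None, None, :])
    conc = np.einsum("sw,tcw->tcs", Einv, scaled)  # [time, channel, species]
    return ConcentrationSeries(hbo=conc[..., 0], hbr=conc[..., 1], fs=od.fs,
                               layout=layout, stimulus=od.stimulus)


def concentration_to_od(conc: ConcentrationSeries, layout: ProbeLayout | None = None,
                        dpf_per_wavelength=None, ext: ExtinctionTable | None = None,
                        age_years: float | None = None,
                        subject_age_out: float | None = None) -> OpticalDensitySeries:
    """Forward MBLL: exact inverse of :func:`od_to_concentration`.

    Used by the simulator to map latent hemoglobin dynamics to ΔOD.
    """
    layout = layout or conc.layout
    ext = ext or ExtinctionTable.default()
    if dpf_per_wavelength is None:
        if age_years is None:
            raise ValidationError("either dpf_per_wavelength or age_years is required")
        dpf_per_wavelength = [dpf_age(wl, age_years) for wl in layout.wavelengths]
    E, dpf = _pathlength_matrix(layout, dpf_per_wavelength, ext)
    species = np.stack([conc.hbo, conc.hbr], axis=-1)  # [time, channel, species]
    od = np.einsum("ws,tcs->tcw", E, species)
    od *= layout.distances_mm[None, :, None] * dpf[None, None, :]
    return OpticalDensitySeries(od=od, fs=conc.fs, layout=layout, stimulus=conc.stimulus,
                                subject_age=subject_age_out if subject_age_out is not None else age_years)
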