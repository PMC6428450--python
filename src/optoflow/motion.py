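"""Wavelet-based motion artifact correction of optical density series.

Two variants operating per channel and wavelength on the discrete wavelet
transform (Daubechies basis, reflect-padded to a power of two, maximal
dyadic depth, exactly invertible):

* IQR thresholding (MC#1): detail coefficients outside
  [Q1 − α·IQR, Q3 + α·IQR] are zeroed (α = 1.5 by default).  Motion
  spikes concentrate in the tails of the detail-coefficient
  distributions, so this removes spikes while leaving the smooth
  hemodynamic content (approximation coefficients) untouched.
* Kurtosis trimming (MC#2): per decomposition level, the
  largest-magnitude detail coefficients are zeroed iteratively until the
  level's coefficient kurtosis (Pearson definition; Gaussian = 3) drops
  to the threshold (3.3 by default).  This is the more aggressive rule
  and tends to over-correct.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy import stats

from .types import OpticalDensitySeries, ValidationError

__all__ = ["wavelet_motion_correct", "kurtosis_wavelet_motion_correct"]

DEFAULT_WAVELET = "db2"


def _pad_pow2(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Reflect-pad to a power of two with a safety margin on each side.

    With periodization mode the transform is then exactly invertible, and
    the wrap-around discontinuity sits inside the discarded padding.
    """
    n = x.size
    target = 1 << int(np.ceil(np.log2(max(n * 1.25, 8))))
    extra = target - n
    left = extra // 2
    right = extra - left
    left = min(left, n - 1)
    right = min(right, n - 1)
    pieces = [x[left:0:-1] if left else x[:0], x,
              x[-2:-2 - right:-1] if right else x[:0]]
    padded = np.concatenate(pieces)
    if padded.size < target:  # very short series: repeat-pad the remainder
        reps = int(np.ceil(target / padded.size)) + 1
        padded = np.tile(padded, reps)[:target]
    return padded, left


def _decompose(x: np.ndarray, wavelet: str, levels: int | None):
    w = pywt.Wavelet(wavelet)
    if len(x) < 2 * w.dec_len:
        raise ValidationError(
            f"series of length {len(x)} too short for one '{wavelet}' decomposition level"
        )
    padded, offset = _pad_pow2(x)
    max_level = pywt.dwt_max_level(len(padded), w.dec_len)
    level = max_level if levels is None else max(1, min(levels, max_level))
    coeffs = pywt.wavedec(padded, w, mode="periodization", level=level)
    return coeffs, w, offset


def _reconstruct(coeffs, w, offset: int, n: int) -> np.ndarray:
    return pywt.waverec(coeffs, w, mode="periodization")[offset:offset + n]


MIN_LEVEL_SIZE = 64  # quartiles from fewer coefficients are too unstable to threshold


def _whiskers(values: np.ndarray, alpha: float) -> tuple[float, float]:
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return q1 - alpha * iqr, q3 + alpha * iqr


def _channel_iqr(x: np.ndarray, wavelet: str, levels: int | None, alpha: float) -> np.ndarray:
    coeffs, w, offset = _decompose(x, wavelet, levels)
    out = [coeffs[0]]  # approximation untouched
    for detail in coeffs[1:]:
        d = detail.copy()
        # quartiles over nonzero coefficients: structural zeros from a
        # previous correction pass must not tighten the whiskers
        sel = d[d != 0]
        if sel.size >= MIN_LEVEL_SIZE:
            # two-stage whiskers: provisional flagging, then quartiles from
            # the unflagged coefficients, so the artifact does not inflate
            # its own threshold and a second pass finds nothing new
            lo, hi = _whiskers(sel, alpha)
            clean = sel[(sel >= lo) & (sel <= hi)]
            if clean.size >= MIN_LEVEL_SIZE // 2:
                lo, hi = _whiskers(clean, alpha)
            d[(d < lo) | (d > hi)] = 0.0
        out.append(d)
    return _reconstruct(out, w, offset, len(x))


def _channel_kurtosis(x: np.ndarray, wavelet: str, levels: int | None,
                      kurtosis_max: float) -> np.ndarray:
    coeffs, w, offset = _decompose(x, wavelet, levels)
    out = [coeffs[0]]
    for detail in coeffs[1:]:
        d = detail.copy()
        keep = np.ones(d.shape, dtype=bool)
        # trim tails until the surviving coefficients look Gaussian enough
        while keep.sum() > 8:
            k = stats.kurtosis(d[keep], fisher=False, bias=True)
            if not np.isfinite(k) or k <= kurtosis_max:
                break
            idx = np.argmax(np.abs(np.where(keep, d, 0.0)))
            keep[idx] = False
            d[idx] = 0.0
        out.append(d)
    return _reconstruct(out, w, offset, len(x))


def _apply(od: OpticalDensitySeries, fn) -> OpticalDensitySeries:
    arr = od.od
    out = np.empty_like(arr)
    for ci in range(arr.shape[1]):
        for wi in range(arr.shape[2]):
            out[:, ci, wi] = fn(arr[:, ci, wi])
    return od.copy_with(out)


def wavelet_motion_correct(od: OpticalDensitySeries, iqr_alpha: float = 1.5,
                           wavelet: str = DEFAULT_WAVELET,
                           levels: int | None = None) -> OpticalDensitySeries:
    """MC#1: IQR-thresholded wavelet despiking (the gentler correction)."""
    return _apply(od, lambda x: _channel_iqr(x, wavelet, levels, iqr_alpha))


def kurtosis_wavelet_motion_correct(od: OpticalDensitySeries, kurtosis_max: float = 3.3,
                                    wavelet: str = DEFAULT_WAVELET,
                                    levels: int | None = None) -> OpticalDensitySeries:
    """MC#2: kurtosis-trimmed wavelet correction (alters the signal more)."""
    return _apply(od, lambda x: _channel_kurtosis(x, wavelet, levels, kurtosis_max))
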