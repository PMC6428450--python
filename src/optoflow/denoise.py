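"""Low-frequency de-noising: SSD regression, PCA, lag-corrected GloAvg.

Three strategies for removing systemic low-frequency (0.01-0.15 Hz)
hemodynamics that overlap the task band:

* ``ssd_denoise`` — regress the assigned short-separation channel out of
  each long channel, per hemoglobin species, with an LMS adaptive filter
  (operates on concentrations).
* ``pca_denoise`` — remove the first spatial principal component of the
  filtered optical density matrix (long channels only).
* ``lagged_global_average`` — for each channel, lag-align every other
  long channel at its cross-correlation optimum, average the channels
  that correlate above a threshold (r > 0.37, |lag| <= 5 s), and regress
  that per-target global signal out adaptively.  The lag alignment is
  what prevents the spurious anti-correlations plain global-signal
  regression induces.

The adaptive filter is an offline multi-epoch normalized LMS: with the
conventional step size (mu = 1e-4) a single pass over a task-length
recording cannot reach steady state, so the weights are carried across
repeated passes over the data and the residual is emitted on the final
pass.  ``mu = 0`` therefore leaves the target untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .types import ConcentrationSeries, OpticalDensitySeries, ValidationError

__all__ = ["DenoiseResult", "adaptive_filter_regress", "ssd_denoise", "pca_denoise",
           "crosscorr_optimal_lag", "lagged_global_average",
           "correlation_threshold_simulation"]


@dataclass
class DenoiseResult:
    """Cleaned series plus per-channel diagnostics."""

    cleaned: object  # OpticalDensitySeries or ConcentrationSeries
    method: str
    removed_variance_fraction: dict = field(default_factory=dict)
    accepted_channels: dict = field(default_factory=dict)  # GloAvg: target → list
    lags: dict = field(default_factory=dict)               # GloAvg: target → {other: lag_s}
    correlations: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "removed_variance_fraction": {str(k): float(v) for k, v in
                                          self.removed_variance_fraction.items()},
            "accepted_channels": {str(k): list(map(int, v)) for k, v in
                                  self.accepted_channels.items()},
            "flags": {str(k): v for k, v in self.flags.items()},
        }


def adaptive_filter_regress(target, reference, mu: float = 1e-4, M: int = 1,
                            n_epochs: int | None = None) -> np.ndarray:
    """Residual of an LMS adaptive filter tracking ``reference`` in ``target``.

    Both series are standardized internally (the filter is run on
    zero-mean unit-variance copies and the residual is rescaled back), so
    ``mu`` is a scale-free per-sample step.  With ``M = 1`` this is a
    slowly time-varying scalar regression.  ``n_epochs`` passes are run
    over the series (weights carried over, residual from the last pass);
    the default picks enough passes for ``mu·n_epochs·n ≈ 10``, i.e.
    steady state on stationary data.
    """
    d = np.asarray(target, dtype=float)
    x = np.asarray(reference, dtype=float)
    if d.shape != x.shape or d.ndim != 1:
        raise ValidationError("target and reference must be equal-length 1-D series")
    n = d.size
    if M < 1 or n <= M:
        raise ValidationError("filter length M must satisfy 1 <= M < n")
    x_sd = x.std()
    if x_sd == 0:
        raise ValidationError("degenerate reference: zero variance")
    if mu == 0:
        return d.copy()
    d_mean, d_sd = d.mean(), d.std()
    if d_sd == 0:
        d_sd = 1.0
    dn = (d - d_mean) / d_sd
    xn = (x - x.mean()) / x_sd
    if n_epochs is None:
        n_epochs = max(1, int(np.ceil(10.0 / (mu * n))))
    est = np.zeros(n)
    if M == 1:  # scalar fast path (the study's configuration)
        w = 0.0
        dl, xl = dn.tolist(), xn.tolist()
        for epoch in range(n_epochs):
            last = epoch == n_epochs - 1
            for i in range(n):
                xi = xl[i]
                y = w * xi
                w += mu * (dl[i] - y) * xi
                if last:
                    est[i] = y
    else:
        w = np.zeros(M)
        for epoch in range(n_epochs):
            last = epoch == n_epochs - 1
            for i in range(n):
                xi = xn[max(0, i - M + 1): i + 1][::-1]
                if xi.size < M:
                    xi = np.concatenate([xi, np.zeros(M - xi.size)])
                y = float(w @ xi)
                e = dn[i] - y
                w = w + mu * e * xi
                if last:
                    est[i] = y
    return d - est * d_sd


def _variance_fraction_removed(before: np.ndarray, after: np.ndarray) -> float:
    vb = before.var()
    if vb == 0:
        return 0.0
    return float(max(0.0, 1.0 - after.var() / vb))


def ssd_denoise(conc: ConcentrationSeries, assignment: dict[int, int] | None = None,
                mu: float = 1e-4, M: int = 1) -> DenoiseResult:
    """Short-separation regression on concentration changes.

    Each long channel is cleaned against its assigned short channel,
    separately for HbO and HbR (so HbR is altered even when only HbO
    shares superficial signal).  Default assignment: nearest short
    channel by source index (one short per hemisphere in the default
    probe).
    """
    layout = conc.layout
    shorts = layout.short_indices
    if shorts.size == 0:
        raise ValidationError("SSD de-noising requires at least one short channel")
    longs = layout.long_indices
    if assignment is None:
        assignment = {}
        for li in longs:
            src = layout.channels[li].source_id
            assignment[int(li)] = int(min(
                shorts, key=lambda si: abs(layout.channels[si].source_id - src)))
    missing = [li for li in longs if int(li) not in assignment]
    if missing:
        raise ValidationError(f"assignment does not cover long channels {missing}")
    hbo = conc.hbo.copy()
    hbr = conc.hbr.copy()
    removed: dict = {}
    for li in longs:
        si = assignment[int(li)]
        for name, arr in (("hbo", hbo), ("hbr", hbr)):
            before = arr[:, li].copy()
            arr[:, li] = adaptive_filter_regress(before, conc.species(name)[:, si], mu=mu, M=M)
            removed[(int(li), name)] = _variance_fraction_removed(before, arr[:, li])
    return DenoiseResult(cleaned=conc.copy_with(hbo, hbr), method="ssd",
                         removed_variance_fraction=removed,
                         accepted_channels={int(li): [assignment[int(li)]] for li in longs})


def pca_denoise(od: OpticalDensitySeries, n_components: int = 1,
                exclude_short: bool = True) -> DenoiseResult:
    """Remove the leading spatial principal component(s) of the OD matrix.

    The component time courses are estimated by SVD over the long
    channels (both wavelengths stacked) and regressed out of each long
    channel column by least squares; short channels pass through.
    """
    layout = od.layout
    idx = layout.long_indices if exclude_short else np.arange(layout.n_channels)
    if idx.size < 2:
        raise ValidationError("PCA de-noising needs at least 2 channels")
    X = od.od[:, idx, :].reshape(od.n_samples, -1)  # [time, channel*wavelength]
    if X.shape[0] <= X.shape[1]:
        raise ValidationError("series must be longer than the channel count")
    if n_components >= X.shape[1]:
        raise ValidationError("more components requested than channels available")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    comps = U[:, :n_components] * s[:n_components]  # component time courses
    # least-squares removal of the component subspace from every column
    beta, *_ = np.linalg.lstsq(comps, Xc, rcond=None)
    resid = Xc - comps @ beta
    out = od.od.copy()
    out[:, idx, :] = (resid + X.mean(axis=0)).reshape(od.n_samples, idx.size, 2)
    removed = {}
    cols = Xc.shape[1]
    for k in range(cols):
        ci, wi = idx[k // 2], k % 2
        removed[(int(ci), int(wi))] = _variance_fraction_removed(Xc[:, k], resid[:, k])
    return DenoiseResult(cleaned=od.copy_with(out), method="pca",
                         removed_variance_fraction=removed,
                         flags={"component_timecourse": comps[:, 0]})


def crosscorr_optimal_lag(x, y, fs: float, max_lag_s: float = 5.0) -> tuple[float, float]:
    """Lag (s) maximizing the normalized cross-correlation within ±max_lag.

    Positive lag means ``y`` is delayed with respect to ``x``.  Returns
    ``(lag_s, r_at_lag)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("series must be equal-length 1-D")
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("degenerate input: zero variance")
    n = x.size
    max_lag = int(np.floor(max_lag_s * fs))  # never search beyond the stated window
    if n < 2 * max_lag:
        raise ValidationError("series too short for the requested lag window")
    xc = (x - x.mean()) / x.std()
    yc = (y - y.mean()) / y.std()
    full = signal.correlate(yc, xc, mode="full") / n  # index n-1 ⇔ lag 0
    lags = np.arange(-(n - 1), n)
    window = (lags >= -max_lag) & (lags <= max_lag)
    sub = full[window]
    sub_lags = lags[window]
    k = int(np.argmax(sub))
    return sub_lags[k] / fs, float(sub[k])


def _shift_samples(x: np.ndarray, k: int) -> np.ndarray:
    """Shift by k samples (positive = later), zero-padding the edges."""
    out = np.zeros_like(x)
    if k > 0:
        out[k:] = x[:-k]
    elif k < 0:
        out[:k] = x[-k:]
    else:
        out[:] = x
    return out


def lagged_global_average(od: OpticalDensitySeries, r_thresh: float = 0.37,
                          max_lag_s: float = 5.0, exclude_short: bool = True,
                          mu: float = 1e-4, M: int = 1) -> DenoiseResult:
    """Delay-corrected global-average regression on optical density.

    For every long channel x: other long channels are lag-aligned to x at
    their cross-correlation optimum; those with r above threshold and
    |lag| within the window are averaged into a per-target global signal
    that is regressed out of x with the adaptive filter.  Channels with
    no accepted partner are returned unchanged and flagged.  Lags are
    computed per wavelength.
    """
    layout = od.layout
    idx = layout.long_indices if exclude_short else np.arange(layout.n_channels)
    out = od.od.copy()
    removed: dict = {}
    accepted: dict = {}
    lags_d: dict = {}
    corrs_d: dict = {}
    flags: dict = {}
    if idx.size < 2:
        for ci in idx:
            flags[int(ci)] = "no correlated channels"
        return DenoiseResult(cleaned=od.copy_with(out), method="gloavg",
                             flags=flags)
    for wi in range(2):
        data = od.od[:, :, wi]
        for ti in idx:
            x = data[:, ti]
            if x.std() == 0:
                flags[(int(ti), wi)] = "zero variance target"
                continue
            aligned = []
            acc = []
            lag_map = {}
            r_map = {}
            for oi in idx:
                if oi == ti or data[:, oi].std() == 0:
                    continue
                lag_s, r = crosscorr_optimal_lag(x, data[:, oi], od.fs, max_lag_s)
                lag_map[int(oi)] = lag_s
                r_map[int(oi)] = r
                if r > r_thresh and abs(lag_s) <= max_lag_s:
                    # other channel lags x by lag_s → advance it by lag_s to align
                    aligned.append(_shift_samples(data[:, oi], -int(round(lag_s * od.fs))))
                    acc.append(int(oi))
            lags_d[(int(ti), wi)] = lag_map
            corrs_d[(int(ti), wi)] = r_map
            accepted[(int(ti), wi)] = acc
            if not acc:
                flags[(int(ti), wi)] = "no correlated channels"
                continue
            g = np.mean(aligned, axis=0)
            cleaned = adaptive_filter_regress(x, g, mu=mu, M=M)
            removed[(int(ti), wi)] = _variance_fraction_removed(x, cleaned)
            out[:, ti, wi] = cleaned
    return DenoiseResult(cleaned=od.copy_with(out), method="gloavg",
                         removed_variance_fraction=removed, accepted_channels=accepted,
                         lags=lags_d, correlations=corrs_d, flags=flags)


def correlation_threshold_simulation(n_samples: int, fs: float, band=(0.01, 0.15),
                                     n_sims: int = 1000, quantile: float = 0.95,
                                     seed: int = 0, max_lag_s: float = 5.0) -> float:
    """Empirical null for the GloAvg acceptance threshold.

    Simulates pairs of independent band-limited noise of the study's
    length, takes each pair's maximum lag-optimized correlation within
    ±``max_lag_s``, and returns the requested quantile.  A warning flag
    is attached for very small simulation counts.
    """
    if not (0 < band[0] < band[1] < fs / 2):
        raise ValidationError("band must lie within (0, Nyquist)")
    rng = np.random.default_rng(seed)
    from .simulate import _bandlimited_noise
    vals = np.empty(n_sims)
    for k in range(n_sims):
        x = _bandlimited_noise(n_samples, fs, band, rng)
        y = _bandlimited_noise(n_samples, fs, band, rng)
        if max_lag_s == 0:
            vals[k] = float(np.corrcoef(x, y)[0, 1])
        else:
            _, vals[k] = crosscorr_optimal_lag(x, y, fs, max_lag_s)
    result = float(np.quantile(vals, quantile, method="higher" if quantile == 1.0 else "linear"))
    if n_sims < 100:
        import warnings
        warnings.warn(f"correlation threshold from only {n_sims} simulations", stacklevel=2)
    return result
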