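"""Block metrics and prewhitened robust GLM activation detection.

Block metrics: per-block windows pre = [onset−4, onset) s and
dur = [onset+5, onset+15) s; Cohen's d = (mean(dur) − mean(pre))/sd(pre)
and CNR = |mean(dur) − mean(pre)| / sqrt(var(dur) + var(pre)) are
computed on the block-averaged trace.

GLM: intercept + boxcar⊗canonical-HRF main regressor + its first and
second temporal derivatives (orthogonalized against the main column).
The series is prewhitened with an AR(p) model fitted to OLS residuals
(order by AIC) — low-pass filtered hemoglobin series are strongly
autocorrelated and unwhitened t-statistics are inflated — then fitted by
iteratively reweighted least squares with Tukey's bisquare.  Only the
main term's t is used; p-values are BH-adjusted across channels per
species, and a channel counts as active under the combined criterion
only when HbO significantly increases AND HbR significantly decreases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats
from statsmodels.api import RLM
from statsmodels.regression.linear_model import yule_walker
from statsmodels.robust.norms import TukeyBiweight
from statsmodels.stats.multitest import multipletests

from .simulate import canonical_hrf
from .types import ConcentrationSeries, StimulusDesign, ValidationError

__all__ = ["BlockMetrics", "GLMResult", "ActivationDecision", "block_average",
           "cohens_d", "cnr", "roi_max_metric", "build_design_matrix", "prewhiten",
           "robust_glm", "glm_channelwise", "bh_adjust", "activation_decision",
           "paired_t_bh", "method_correlation"]


# ---------------------------------------------------------------------------
# block metrics


@dataclass
class BlockAverages:
    """Block-averaged pre/dur samples for one series."""

    pre_samples: np.ndarray   # block-mean trace over the pre window
    dur_samples: np.ndarray
    pre_block_means: np.ndarray  # one mean per usable block
    dur_block_means: np.ndarray
    n_blocks_used: int
    n_blocks_dropped: int


@dataclass
class BlockMetrics:
    """Cohen's d and CNR per channel and species."""

    cohens_d: dict = field(default_factory=dict)   # (channel, species) → d
    cnr: dict = field(default_factory=dict)
    pre_mean: dict = field(default_factory=dict)
    dur_mean: dict = field(default_factory=dict)


def block_average(series_1d, fs: float, onsets, pre_window=(-4.0, 0.0),
                  dur_window=(5.0, 15.0)) -> BlockAverages:
    """Average task-locked epochs of one channel's series.

    Blocks whose pre or dur window falls outside the recording are
    dropped with a warning; at least one usable block is required.
    """
    x = np.asarray(series_1d, dtype=float)
    n = x.size
    pre_slices, dur_slices = [], []
    pre_len = int(round((pre_window[1] - pre_window[0]) * fs))
    dur_len = int(round((dur_window[1] - dur_window[0]) * fs))
    dropped = 0
    segs = []
    for onset in onsets:
        i_pre = int(round((onset + pre_window[0]) * fs))
        i_dur = int(round((onset + dur_window[0]) * fs))
        if i_pre < 0 or i_dur + dur_len > n:
            dropped += 1
            continue
        segs.append((x[i_pre:i_pre + pre_len], x[i_dur:i_dur + dur_len]))
    if not segs:
        raise ValidationError("no usable blocks: all windows fall outside the recording")
    if dropped:
        warnings.warn(f"dropped {dropped} block(s) with windows outside the recording",
                      stacklevel=2)
    pre_stack = np.stack([s[0] for s in segs])
    dur_stack = np.stack([s[1] for s in segs])
    return BlockAverages(pre_samples=pre_stack.mean(axis=0),
                         dur_samples=dur_stack.mean(axis=0),
                         pre_block_means=pre_stack.mean(axis=1),
                         dur_block_means=dur_stack.mean(axis=1),
                         n_blocks_used=len(segs), n_blocks_dropped=dropped)


def cohens_d(pre_samples, dur_samples) -> float:
    """(mean(dur) − mean(pre)) / sd(pre), with the sample (n−1) SD."""
    pre = np.asarray(pre_samples, dtype=float)
    dur = np.asarray(dur_samples, dtype=float)
    if pre.size < 2:
        raise ValidationError("need at least 2 pre samples")
    sd = pre.std(ddof=1)
    if sd == 0:
        raise ValidationError("undefined Cohen's d: zero pre-window variance")
    return float((dur.mean() - pre.mean()) / sd)


def cnr(pre_samples, dur_samples) -> float:
    """|mean(dur) − mean(pre)| / sqrt(var(dur) + var(pre))."""
    pre = np.asarray(pre_samples, dtype=float)
    dur = np.asarray(dur_samples, dtype=float)
    denom = np.sqrt(pre.var(ddof=1) + dur.var(ddof=1))
    if denom == 0:
        raise ValidationError("undefined CNR: both windows have zero variance")
    return float(abs(dur.mean() - pre.mean()) / denom)


def roi_max_metric(values_per_channel: dict, roi, kind: str = "d_hbo") -> float:
    """Subject-level ROI summary: the extreme value over ROI channels.

    ``kind``: 'd_hbo' → signed maximum, 'd_hbr' → most negative,
    'cnr' → maximum of absolute values.
    """
    roi = list(roi)
    if not roi:
        raise ValidationError("empty ROI")
    vals = np.array([values_per_channel[c] for c in roi], dtype=float)
    if kind == "d_hbo":
        return float(vals.max())
    if kind == "d_hbr":
        return float(vals.min())
    if kind == "cnr":
        return float(np.abs(vals).max())
    raise ValidationError(f"unknown metric kind {kind!r}")


def block_metrics(conc: ConcentrationSeries, pre_window=(-4.0, 0.0),
                  dur_window=(5.0, 15.0)) -> BlockMetrics:
    """Cohen's d and CNR for every channel and species of a recording."""
    if conc.stimulus is None:
        raise ValidationError("concentration series carries no stimulus design")
    out = BlockMetrics()
    for species in ("hbo", "hbr"):
        arr = conc.species(species)
        for ci in range(arr.shape[1]):
            ba = block_average(arr[:, ci], conc.fs, conc.stimulus.onsets,
                               pre_window, dur_window)
            # metrics over per-block window means: block-to-block variability
            # is the noise floor against which the response is judged
            out.cohens_d[(ci, species)] = cohens_d(ba.pre_block_means, ba.dur_block_means)
            out.cnr[(ci, species)] = cnr(ba.pre_block_means, ba.dur_block_means)
            out.pre_mean[(ci, species)] = float(ba.pre_block_means.mean())
            out.dur_mean[(ci, species)] = float(ba.dur_block_means.mean())
    return out


# ---------------------------------------------------------------------------
# design matrix, prewhitening, robust fit


def build_design_matrix(stimulus: StimulusDesign, fs: float, n_samples: int,
                        include_derivatives: bool = True,
                        hrf_kwargs: dict | None = None) -> np.ndarray:
    """Columns: intercept, boxcar⊗HRF, and optionally its first and second
    temporal derivatives orthogonalized against the main column."""
    if n_samples < (stimulus.task_duration + stimulus.rest_duration) * fs:
        raise ValidationError("series shorter than one block")
    box = stimulus.boxcar(n_samples, fs)
    h = canonical_hrf(fs, **(hrf_kwargs or {}))
    main = signal.fftconvolve(box, h)[:n_samples]
    peak = np.abs(main).max()
    if peak > 0:
        main = main / peak
    cols = [np.ones(n_samples), main]
    if include_derivatives:
        d1 = np.gradient(main) * fs
        d2 = np.gradient(d1) / fs  # curvature (dispersion-like) term
        for d in (d1, d2):
            basis = np.column_stack(cols)
            beta, *_ = np.linalg.lstsq(basis, d, rcond=None)
            d = d - basis @ beta  # orthogonalize so the main-term beta is interpretable
            norm = np.linalg.norm(d)
            if norm > 0:
                d = d / norm * np.linalg.norm(main)
            cols.append(d)
    return np.column_stack(cols)


def _ar_whiten(x: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Apply the AR whitening operator a(L) = 1 − φ₁L − … − φ_pL^p."""
    coeffs = np.concatenate([[1.0], -phi])
    return signal.lfilter(coeffs, [1.0], x, axis=0)


def prewhiten(y, X, max_ar_order: int | None = None, fs: float | None = None
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """AR-prewhiten a regression problem.

    An AR(p) model is fitted (Yule-Walker) to the OLS residuals for
    p = 0..max_ar_order and selected by BIC (parsimonious enough that
    white noise keeps order 0-1); the default maximum order is
    ⌈4·fs⌉ (or 16 when fs is unknown).  Both ``y`` and every column of
    ``X`` are filtered with the whitening operator and the first p rows
    are dropped.  Unstable AR fits fall back to AR(1) with a warning.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = y.size
    if max_ar_order is None:
        max_ar_order = int(np.ceil(4 * fs)) if fs else 16
    max_ar_order = min(max_ar_order, (n // 3) - 1)
    if n <= 3 * max(max_ar_order, 1):
        raise ValidationError("series too short for AR estimation")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    best = (np.inf, np.array([]))
    sigma0 = resid.std()
    for p in range(0, max_ar_order + 1):
        if p == 0:
            sigma2 = float(np.mean(resid**2))
            phi = np.array([])
        else:
            try:
                rho, sigma = yule_walker(resid, order=p, method="mle")
            except Exception:
                continue
            innov = _ar_whiten(resid, rho)[p:]
            sigma2 = float(np.mean(innov**2))
            phi = rho
        if sigma2 <= 0:
            continue
        bic = n * np.log(sigma2) + np.log(n) * p
        if bic < best[0]:
            best = (bic, phi)
    phi = best[1]
    if phi.size:
        roots = np.roots(np.concatenate([[1.0], -phi]))
        if np.any(np.abs(roots) > 1.0 + 1e-8):
            warnings.warn("unstable AR fit; falling back to AR(1)", stacklevel=2)
            rho, _ = yule_walker(resid, order=1, method="mle")
            phi = np.clip(rho, -0.98, 0.98)
    p = phi.size
    y_w = _ar_whiten(y, phi)[p:]
    X_w = _ar_whiten(X, phi)[p:]
    # sanity guard: whitening must not blow up
    if sigma0 > 0 and y_w.std() > 50 * sigma0 + 50 * np.abs(y).max():
        warnings.warn("whitened series exploded; reverting to AR(0)", stacklevel=2)
        return y.copy(), X.copy(), np.array([])
    return y_w, X_w, phi


@dataclass
class GLMChannelResult:
    beta_main: float
    t_main: float
    p: float
    ar_order: int
    robust_weight_mean: float


@dataclass
class GLMResult:
    """Per-channel GLM summaries for one species."""

    species: str
    beta: np.ndarray
    t: np.ndarray
    p: np.ndarray
    q: np.ndarray | None = None
    ar_orders: np.ndarray | None = None

    def with_bh(self) -> "GLMResult":
        self.q = bh_adjust(self.p)
        return self


def robust_glm(y, X, main_col: int = 1) -> GLMChannelResult:
    """Tukey-bisquare IRLS fit; t and two-sided p for the main column."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("design matrix is rank deficient")
    model = RLM(y, X, M=TukeyBiweight(4.685))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit()
    beta = fit.params[main_col]
    se = fit.bse[main_col]
    df = max(y.size - X.shape[1], 1)
    t = float(beta / se) if se > 0 else np.inf * np.sign(beta)
    p = float(2 * stats.t.sf(abs(t), df))
    return GLMChannelResult(beta_main=float(beta), t_main=t, p=p, ar_order=0,
                            robust_weight_mean=float(np.mean(fit.weights)))


def glm_channelwise(conc: ConcentrationSeries, include_derivatives: bool = True,
                    prewhitening: bool = True, channels=None,
                    hrf_kwargs: dict | None = None) -> dict[str, GLMResult]:
    """Prewhitened robust GLM for every (long) channel and both species.

    Returns ``{"hbo": GLMResult, "hbr": GLMResult}`` with BH-adjusted q
    across the fitted channels, per species.
    """
    if conc.stimulus is None:
        raise ValidationError("concentration series carries no stimulus design")
    if channels is None:
        channels = conc.layout.long_indices
    channels = np.asarray(list(channels), dtype=int)
    X0 = build_design_matrix(conc.stimulus, conc.fs, conc.n_samples,
                             include_derivatives, hrf_kwargs)
    results = {}
    for species in ("hbo", "hbr"):
        arr = conc.species(species)
        beta = np.full(channels.size, np.nan)
        tval = np.full(channels.size, np.nan)
        pval = np.full(channels.size, np.nan)
        orders = np.zeros(channels.size, dtype=int)
        for k, ci in enumerate(channels):
            y = arr[:, ci]
            if prewhitening:
                y_w, X_w, phi = prewhiten(y, X0, fs=conc.fs)
                orders[k] = phi.size
            else:
                y_w, X_w = y, X0
            r = robust_glm(y_w, X_w)
            beta[k], tval[k], pval[k] = r.beta_main, r.t_main, r.p
        res = GLMResult(species=species, beta=beta, t=tval, p=pval, ar_orders=orders)
        results[species] = res.with_bh()
    return results


# ---------------------------------------------------------------------------
# multiplicity, decisions, comparisons


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ActivationDecision:
    """Per-channel activation under the three criteria."""

    channels: np.ndarray
    oxy_active: np.ndarray
    deoxy_active: np.ndarray
    combined_active: np.ndarray
    alpha: float

    def active_set(self, criterion: str) -> set[int]:
        mask = {"oxy": self.oxy_active, "deoxy": self.deoxy_active,
                "combined": self.combined_active}[criterion]
        return set(self.channels[mask].tolist())


def activation_decision(glm_hbo: GLMResult, glm_hbr: GLMResult,
                        channels=None, alpha: float = 0.05) -> ActivationDecision:
    """Combined criterion: HbO up AND HbR down, each at q < alpha."""
    q_hbo = glm_hbo.q if glm_hbo.q is not None else bh_adjust(glm_hbo.p)
    q_hbr = glm_hbr.q if glm_hbr.q is not None else bh_adjust(glm_hbr.p)
    if q_hbo.shape != q_hbr.shape:
        raise ValidationError("HbO and HbR results cover different channel sets")
    if channels is None:
        channels = np.arange(q_hbo.size)
    channels = np.asarray(channels, dtype=int)
    oxy = (q_hbo < alpha) & (glm_hbo.beta > 0)
    deoxy = (q_hbr < alpha) & (glm_hbr.beta < 0)
    return ActivationDecision(channels=channels, oxy_active=oxy, deoxy_active=deoxy,
                              combined_active=oxy & deoxy, alpha=alpha)


def paired_t_bh(pairs: list[tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
    """Two-sided paired t-tests, BH-corrected across the family.

    ``pairs`` is a list of (values_A, values_B) comparisons; returns the
    corrected p_c per comparison.
    """
    ps = []
    for a, b in pairs:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValidationError("paired vectors must be equal-length 1-D")
        if a.size < 3:
            raise ValidationError("paired t-test needs n >= 3")
        d = a - b
        if np.allclose(d, d[0]):
            # constant difference: t is ±inf (p → 0) or undefined for zero diff
            ps.append(0.0 if d[0] != 0 else 1.0)
        else:
            ps.append(float(stats.ttest_rel(a, b).pvalue))
    return bh_adjust(np.array(ps))


def method_correlation(series_a, series_b) -> float:
    """Pearson correlation between two method outputs' time courses."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("series must have equal length")
    if a.std() == 0 or b.std() == 0:
        raise ValidationError("undefined correlation: zero variance")
    return float(np.corrcoef(a, b)[0, 1])
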