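"""Sliding-window detrended cross-correlation and fluctuation analysis.

The central quantity is the detrended cross-correlation coefficient
DCCC(s): within an analysis window each channel is integrated to a profile,
the profiles are locally detrended in every overlapping sub-window of
length ``s`` by an OLS line, and the residual cross-covariance is averaged
over sub-windows to give the bivariate scaling function F2_dcca(s).
Normalising by the two univariate DFA scaling functions,

    DCCC(s) = F2_dcca(s) / sqrt(F2_dfa_x(s) * F2_dfa_y(s)),

yields a scale-dependent coupling coefficient bounded in [-1, 1]
(Cauchy-Schwarz on the shared sub-window decomposition). Repeating the
computation in sliding analysis windows produces a time-resolved
connectivity tensor, and the per-window OLS slope of log F_dfa(s) on
log s gives a windowed DFA scaling exponent per channel — a local Hurst
exponent whose temporal variance proxies the degree of multifractality.

Conventions, fixed throughout:

* sub-windows at scale ``s`` are the ``K_s = T - s + 1`` maximally
  overlapping windows of exactly ``s`` samples;
* detrending is linear (polynomial order 1);
* the residual covariance in each sub-window uses divisor ``s - 1`` and the
  sub-window average uses divisor ``K_s - 1``;
* each analysis window is mean-centred per channel before integration
  (switchable), so the profile reflects fluctuations rather than the
  window's DC offset;
* constant (zero-variance) channels yield NaN coefficients, never silent
  zeros.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .preprocess import EEGRecording

__all__ = [
    "ScaleSet",
    "WindowPlan",
    "ConnectivityTensor",
    "DFAExponentSeries",
    "integrate_profile",
    "detrended_covariance",
    "dccc",
    "window_fluctuations",
    "sliding_connectivity",
    "dfa_exponent",
    "pair_index",
]

logger = logging.getLogger(__name__)

DEFAULT_SCALES = (8, 16, 32, 64, 128)


@dataclass(frozen=True)
class ScaleSet:
    """Ordered set of detrending scales, in samples (default dyadic 8..128)."""

    scales: tuple[int, ...] = DEFAULT_SCALES

    def __post_init__(self) -> None:
        s = tuple(int(v) for v in self.scales)
        object.__setattr__(self, "scales", s)
        if len(s) < 1:
            raise ValueError("at least one scale required")
        if any(b <= a for a, b in zip(s, s[1:])):
            raise ValueError("scales must be strictly increasing")
        if s[0] < 4:
            raise ValueError("minimum scale is 4 samples")

    @property
    def n_scales(self) -> int:
        return len(self.scales)

    def validate_against(self, win_len: int) -> None:
        if self.scales[-1] > win_len // 4:
            raise ValueError(
                f"largest scale {self.scales[-1]} exceeds window length / 4 "
                f"({win_len // 4})"
            )


@dataclass(frozen=True)
class WindowPlan:
    """Sliding analysis-window layout: length and stride in samples."""

    win_len: int = 1024
    step: int = 128

    def __post_init__(self) -> None:
        if self.win_len < 8 or self.step < 1:
            raise ValueError("win_len >= 8 and step >= 1 required")

    def n_windows(self, n_samples: int) -> int:
        if n_samples < self.win_len:
            raise ValueError(
                f"recording of {n_samples} samples shorter than window "
                f"{self.win_len}"
            )
        return (n_samples - self.win_len) // self.step + 1

    def starts(self, n_samples: int) -> np.ndarray:
        n = self.n_windows(n_samples)
        return np.arange(n) * self.step


def pair_index(labels: list[str]) -> list[tuple[int, int]]:
    """Unordered channel pairs (i < j) in row-major order; the canonical
    flattening used by every tensor in the package."""
    n = len(labels)
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


@dataclass
class ConnectivityTensor:
    """Per-window, per-pair, per-scale DCCC values.

    ``dccc`` has shape (n_windows, n_pairs, n_scales); ``pairs`` maps the
    pair axis onto unordered channel-index pairs; entries may be NaN where a
    channel was constant within a window.
    """

    dccc: np.ndarray
    pairs: list[tuple[int, int]]
    scales: ScaleSet
    labels: list[str]
    window_starts: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_windows(self) -> int:
        return self.dccc.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.dccc.shape[1]

    def pair_labels(self) -> list[tuple[str, str]]:
        return [(self.labels[i], self.labels[j]) for i, j in self.pairs]


@dataclass
class DFAExponentSeries:
    """Windowed DFA scaling exponents, shape (n_windows, n_channels)."""

    exponents: np.ndarray
    labels: list[str]
    window_starts: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def integrate_profile(series: np.ndarray) -> np.ndarray:
    """Cumulative-sum profile of a series (the integration step of DFA/DCCA)."""
    series = np.asarray(series, dtype=float)
    if series.shape[-1] < 2:
        raise ValueError("series must have at least 2 samples")
    if not np.all(np.isfinite(series)):
        raise ValueError("series contains NaN or infinite values")
    return np.cumsum(series, axis=-1)


def _global_detrend(profiles: np.ndarray) -> np.ndarray:
    """Remove each profile's global OLS line.

    Per-sub-window linear detrending is exactly invariant under adding any
    affine function of time to a profile, so this changes no result in
    exact arithmetic — it only shrinks the magnitudes entering the sliding
    cumulative sums, avoiding catastrophic cancellation.
    """
    T = profiles.shape[-1]
    t = np.arange(T, dtype=float)
    tc = t - t.mean()
    denom = tc @ tc
    x = np.atleast_2d(profiles)
    slope = (x @ tc) / denom
    out = x - x.mean(axis=-1, keepdims=True) - slope[:, None] * tc
    return out.reshape(profiles.shape)


def _sliding_window_sums(profiles: np.ndarray, s: int):
    """Sliding sums needed for linear detrending at scale ``s``.

    ``profiles``: (C, T) integrated profiles. Returns, over the
    ``K = T - s + 1`` overlapping sub-windows:

    * ``w1`` (C, K): per-window sums of each profile,
    * ``wt`` (C, K): per-window sums of (local index) * profile,
    * ``s_tt``: the scalar sum of squared centred local indices.
    """
    C, T = profiles.shape
    K = T - s + 1
    zeros = np.zeros((C, 1))
    c1 = np.concatenate([zeros, np.cumsum(profiles, axis=1)], axis=1)
    j = np.arange(T, dtype=float)
    cj = np.concatenate([zeros, np.cumsum(profiles * j, axis=1)], axis=1)
    starts = np.arange(K)
    w1 = c1[:, s:] - c1[:, :-s] if K > 0 else np.empty((C, 0))
    # sum over window of (j - i) * X_j  =  (sum j X_j) - i * (sum X_j)
    wt = (cj[:, s:] - cj[:, :-s]) - starts * w1
    s_tt = s * (s * s - 1) / 12.0
    return w1, wt, s_tt


def window_fluctuations(segment: np.ndarray, scales: ScaleSet,
                        center: bool = True) -> np.ndarray:
    """All pairwise detrended scaling functions for one analysis window.

    Parameters
    ----------
    segment : ndarray (n_channels, win_len)
        Raw (not yet integrated) channel data for one analysis window.
    scales : ScaleSet
    center : bool
        Subtract the per-channel window mean before integration.

    Returns
    -------
    F2 : ndarray (n_channels, n_channels, n_scales)
        ``F2[i, j, k]`` is the averaged detrended residual cross-covariance
        of channels i and j at ``scales.scales[k]``; the diagonal holds the
        univariate DFA scaling functions.
    """
    segment = np.asarray(segment, dtype=float)
    C, T = segment.shape
    if scales.scales[-1] > T:
        raise ValueError("largest scale exceeds window length")
    x = segment - segment.mean(axis=1, keepdims=True) if center else segment
    profiles = _global_detrend(np.cumsum(x, axis=1))

    F2 = np.empty((C, C, scales.n_scales))
    j = np.arange(T, dtype=float)
    # cumulative sums of pairwise profile products, shared across scales
    P = profiles[:, None, :] * profiles[None, :, :]
    cP = np.concatenate([np.zeros((C, C, 1)), np.cumsum(P, axis=2)], axis=2)
    for k, s in enumerate(scales.scales):
        K = T - s + 1
        w1, wt, s_tt = _sliding_window_sums(profiles, s)
        s_tx = wt - (s - 1) / 2.0 * w1
        # per-window centred cross-products  S_xy = sum x y - (sum x)(sum y)/s
        wP = cP[:, :, s:] - cP[:, :, :-s]
        s_xy = wP - w1[:, None, :] * w1[None, :, :] / s
        # residual cross-sum after removing each profile's OLS line
        resid = s_xy - s_tx[:, None, :] * s_tx[None, :, :] / s_tt
        f2 = resid / (s - 1)
        F2[:, :, k] = f2.sum(axis=2) / (K - 1)
    return F2


def detrended_covariance(profile_x: np.ndarray, profile_y: np.ndarray, s: int) -> float:
    """Averaged detrended residual cross-covariance of two profiles at scale ``s``.

    Every one of the ``K_s = T - s + 1`` overlapping sub-windows of length
    ``s`` is linearly detrended by OLS; residual cross-covariances (divisor
    ``s - 1``) are averaged with divisor ``K_s - 1``. With
    ``profile_x is profile_y`` this is the DFA scaling function.
    """
    profile_x = np.asarray(profile_x, dtype=float)
    profile_y = np.asarray(profile_y, dtype=float)
    if profile_x.shape != profile_y.shape or profile_x.ndim != 1:
        raise ValueError("profiles must be 1-D and of equal length")
    T = profile_x.size
    s = int(s)
    if s < 4:
        raise ValueError("scale must be at least 4")
    if s > T:
        raise ValueError(f"scale {s} exceeds series length {T}")
    profiles = _global_detrend(np.vstack([profile_x, profile_y]))
    profile_x, profile_y = profiles
    K = T - s + 1
    w1, wt, s_tt = _sliding_window_sums(profiles, s)
    s_tx = wt - (s - 1) / 2.0 * w1
    prod = profile_x * profile_y
    cp = np.concatenate([[0.0], np.cumsum(prod)])
    s_xy = (cp[s:] - cp[:-s]) - w1[0] * w1[1] / s
    resid = s_xy - s_tx[0] * s_tx[1] / s_tt
    return float(np.sum(resid / (s - 1)) / (K - 1))


def dccc(f2_xy: float, f2_xx: float, f2_yy: float) -> float:
    """Detrended cross-correlation coefficient from the three scaling functions.

    Returns NaN (flagged missing, logged) when either univariate
    fluctuation vanishes — a constant channel has no defined coupling.
    """
    if f2_xx <= 0 or f2_yy <= 0:
        logger.warning("zero-variance channel in DCCC; returning NaN")
        return float("nan")
    return float(f2_xy / math.sqrt(f2_xx * f2_yy))


def dfa_exponent(f2_values: np.ndarray, scales: ScaleSet) -> float:
    """OLS slope of log F(s) on log s across the scale set.

    ``f2_values`` are squared scaling functions F2(s); the exponent is half
    the slope of log F2, identical to the slope of log F. Non-positive F2
    at any scale flags the estimate as missing (NaN).
    """
    f2_values = np.asarray(f2_values, dtype=float)
    if f2_values.size != scales.n_scales:
        raise ValueError("one F2 value per scale required")
    if scales.n_scales < 3:
        raise ValueError("at least 3 scales required for a slope")
    if np.any(f2_values <= 0) or not np.all(np.isfinite(f2_values)):
        return float("nan")
    slope = np.polyfit(np.log(scales.scales), 0.5 * np.log(f2_values), 1)[0]
    return float(slope)


def sliding_connectivity(
    rec: EEGRecording,
    scales: ScaleSet | None = None,
    plan: WindowPlan | None = None,
    center: bool = True,
) -> tuple[ConnectivityTensor, DFAExponentSeries]:
    """Time-resolved DCCC tensor and windowed DFA exponents for a recording.

    For each analysis window (length ``plan.win_len``, stride ``plan.step``)
    every channel is integrated and the full pairwise fluctuation matrix is
    computed at every scale; coefficients and per-channel scaling exponents
    are assembled into (n_windows, n_pairs, n_scales) and
    (n_windows, n_channels) arrays.
    """
    scales = scales or ScaleSet()
    plan = plan or WindowPlan()
    if rec.n_channels < 2:
        raise ValueError("connectivity requires at least 2 channels")
    if plan.win_len <= scales.scales[-1]:
        raise ValueError("window length must exceed the largest scale")
    starts = plan.starts(rec.n_samples)
    pairs = pair_index(rec.labels)
    n_t, n_p, n_s = len(starts), len(pairs), scales.n_scales
    out = np.empty((n_t, n_p, n_s))
    exps = np.empty((n_t, rec.n_channels))
    pi, pj = (np.array(v) for v in zip(*pairs))
    log_s = np.log(scales.scales)
    for w, start in enumerate(starts):
        seg = rec.data[:, start : start + plan.win_len]
        F2 = window_fluctuations(seg, scales, center=center)
        diag = np.einsum("iik->ik", F2)  # (C, n_s) univariate F2
        denom = np.sqrt(diag[pi] * diag[pj])
        num = F2[pi, pj]
        with np.errstate(invalid="ignore", divide="ignore"):
            coef = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), np.nan)
        if np.any(denom <= 0):
            logger.warning("window %d: zero-variance channel, NaN coefficients", w)
        out[w] = coef
        # windowed exponents: vectorized log-log OLS slope per channel
        valid = np.all(diag > 0, axis=1)
        exps[w] = np.nan
        if np.any(valid):
            y = 0.5 * np.log(diag[valid])
            xc = log_s - log_s.mean()
            exps[w, valid] = (y @ xc) / (xc @ xc)
    return (
        ConnectivityTensor(out, pairs, scales, list(rec.labels), starts),
        DFAExponentSeries(exps, list(rec.labels), starts),
    )
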