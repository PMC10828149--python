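"""Synthetic cohort generator: multichannel fractal signals with planted
group differences, plus cognitive scores tied to connectivity summaries.

The generator emulates the statistical structure a dynamic fractal
connectivity study assumes, so every downstream stage (windowed DCCA,
feature selection, group statistics, brain-behavior correlation) can be
exercised and validated without any recorded data:

* each channel is stationary fractional Gaussian noise (fGn) with a
  group-specific Hurst exponent — reduced in the "elderly" group, matching
  the direction of age effects on broadband EEG scaling;
* selected channel pairs share a common source with a group-specific signed
  mixing coefficient rho, planting connectivity differences; the shared
  source may be band-limited so the planted coupling targets a specific
  detrending scale;
* cognitive scores are noisy linear functions of named connectivity
  summaries, giving known monotone brain-behavior relations.

All randomness derives from a single master seed through
``numpy.random.SeedSequence`` spawning, so cohorts are bit-reproducible.

What this does NOT emulate: volume conduction, oscillatory (alpha/beta)
peaks, artifacts, or non-Gaussian EEG amplitude statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocess import EEGRecording

__all__ = [
    "PlantedConnection",
    "ScoreModel",
    "CohortSpec",
    "gen_fgn",
    "gen_coupled_pair",
    "gen_cohort",
    "gen_scores",
]


@dataclass(frozen=True)
class PlantedConnection:
    """A planted coupling between two channels.

    ``rho_young`` / ``rho_elderly`` are signed mixing strengths in [-1, 1];
    ``band_hz`` optionally band-limits the shared source (low, high in Hz)
    so the induced coupling concentrates at the detrending scales whose
    equivalent frequency fs/s falls inside the band.
    """

    ch1: int
    ch2: int
    rho_young: float
    rho_elderly: float
    band_hz: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not (abs(self.rho_young) <= 1 and abs(self.rho_elderly) <= 1):
            raise ValueError("|rho| must be <= 1")
        if self.ch1 == self.ch2:
            raise ValueError("planted connection must join two distinct channels")


@dataclass(frozen=True)
class ScoreModel:
    """One cognitive score: a linear combination of summary columns plus noise."""

    name: str
    weights: dict[str, float]
    noise_sd: float = 1.0


@dataclass
class CohortSpec:
    """Full description of a synthetic two-group cohort.

    Defaults mirror the study design this generator emulates: 24 young and
    19 elderly subjects, 14 channels sampled at 256 Hz for 72 s, with the
    elderly group's per-channel Hurst exponents reduced (0.65 vs 0.75 —
    a realistic broadband EEG scaling contrast of the magnitude reported
    for healthy aging).

    Real cohorts are heterogeneous: group parameters are population means,
    and each subject's coupling strengths and Hurst exponents are drawn
    around them (``rho_subject_sd``, ``h_subject_sd``), so that held-out
    subjects are never mere copies of the training group. Group effects on
    individual connections are themselves heterogeneous: with probability
    ``cross_expression_p`` a subject expresses a given planted connection
    at the other group's mean level, the way age-related connectivity
    alterations affect some individuals and spare others. Coupling is also
    dynamic: the instantaneous mixing strength fluctuates around the
    subject's level with a slow (~seconds) random envelope whose
    coefficient of variation is ``coupling_cv``, so sliding-window
    connectivity estimates vary from window to window the way dynamic
    functional connectivity does in recordings.
    """

    n_young: int = 24
    n_elderly: int = 19
    n_channels: int = 14
    fs: float = 256.0
    duration_s: float = 72.0
    H_young: float | list[float] = 0.75
    H_elderly: float | list[float] = 0.65
    planted: list[PlantedConnection] = field(default_factory=list)
    score_models: list[ScoreModel] = field(default_factory=list)
    rho_subject_sd: float = 0.1
    h_subject_sd: float = 0.02
    coupling_cv: float = 1.0
    coupling_env_cutoff_hz: float = 0.25
    cross_expression_p: float = 0.0
    coupling_gain_sd: float = 0.35
    artifact_events: int = 3
    artifact_dur_s: float = 2.0
    artifact_mix: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_young, self.n_elderly) < 1 or self.n_channels < 2:
            raise ValueError("counts must be >= 1 and n_channels >= 2")
        for h in np.atleast_1d(self.H_young).tolist() + np.atleast_1d(self.H_elderly).tolist():
            if not (0 < h < 1):
                raise ValueError(f"Hurst exponent must lie in (0, 1), got {h}")
        for pc in self.planted:
            if not (0 <= pc.ch1 < self.n_channels and 0 <= pc.ch2 < self.n_channels):
                raise ValueError(
                    f"planted connection ({pc.ch1}, {pc.ch2}) references a "
                    f"missing channel (n_channels={self.n_channels})"
                )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    def hurst(self, group: str, channel: int) -> float:
        h = self.H_young if group == "young" else self.H_elderly
        arr = np.atleast_1d(h)
        return float(arr[channel % arr.size])

    def rho(self, pc: PlantedConnection, group: str) -> float:
        return pc.rho_young if group == "young" else pc.rho_elderly


def _fgn_autocovariance(H: float, n: int) -> np.ndarray:
    k = np.arange(n, dtype=float)
    return 0.5 * (
        np.abs(k + 1) ** (2 * H) - 2 * np.abs(k) ** (2 * H) + np.abs(k - 1) ** (2 * H)
    )


def gen_fgn(H: float, n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Unit-variance fractional Gaussian noise by circulant embedding.

    The exact fGn autocovariance gamma(k) = (|k+1|^2H - 2|k|^2H +
    |k-1|^2H)/2 is embedded in a circulant matrix whose eigenvalues are
    obtained by FFT (Davies-Harte). For fGn with 0 < H < 1 the embedding is
    positive semi-definite; if numerical round-off produces tiny negative
    eigenvalues they are clipped to zero (logged implicitly through the
    clip magnitude being < 1e-8 of the spectrum), which for pathological
    inputs degrades gracefully into an approximate spectral synthesis.
    """
    if not (0 < H < 1):
        raise ValueError(f"Hurst exponent must lie in (0, 1), got {H}")
    if n < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng(seed)
    gamma = _fgn_autocovariance(H, n)
    # first row of the 2(n-1)-circulant: gamma_0..gamma_{n-1}, gamma_{n-2}..gamma_1
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.rfft(row).real
    lam = np.clip(lam, 0.0, None)
    m = row.size
    z = rng.standard_normal(lam.size) + 1j * rng.standard_normal(lam.size)
    z[0] = z[0].real * np.sqrt(2)
    if m % 2 == 0:
        z[-1] = z[-1].real * np.sqrt(2)
    spectrum = np.sqrt(lam / (2 * m)) * z * m ** 0.5
    x = np.fft.irfft(spectrum, n=m)[:n] * np.sqrt(2)
    # exact unit marginal variance
    sd = x.std()
    return x / sd if sd > 0 else x


def gen_coupled_pair(
    H: float, rho: float, n: int, seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """A coupled fGn pair: ``x`` a shared source, ``y = rho*x +
    sqrt(1-rho^2)*independent``, both components fGn(H).

    The sample Pearson correlation of (x, y) converges to ``rho``.
    """
    if abs(rho) > 1:
        raise ValueError("|rho| must be <= 1")
    rng = np.random.default_rng(seed)
    x = gen_fgn(H, n, rng)
    e = gen_fgn(H, n, rng)
    y = rho * x + np.sqrt(1 - rho * rho) * e
    return x, y


def _bandlimit(source: np.ndarray, band_hz: tuple[float, float], fs: float) -> np.ndarray:
    lo, hi = band_hz
    nyq = fs / 2
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band ({lo}, {hi}) must satisfy 0 < lo < hi < fs/2")
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    out = sps.sosfiltfilt(sos, source)
    sd = out.std()
    return out / sd if sd > 0 else out


def _coupling_envelope(
    n: int, fs: float, cv: float, rng: np.random.Generator,
    cutoff_hz: float = 0.25,
) -> np.ndarray:
    """Slow, positive, mean-one modulation of coupling strength.

    Low-pass-filtered Gaussian noise (default correlation time a few
    seconds) scaled to coefficient of variation ``cv``; the envelope makes
    sliding-window connectivity estimates genuinely dynamic.
    """
    if cv <= 0:
        return np.ones(n)
    sos = sps.butter(2, cutoff_hz, btype="lowpass", fs=fs, output="sos")
    z = sps.sosfiltfilt(sos, rng.standard_normal(n))
    sd = z.std()
    if sd > 0:
        z = z / sd
    return np.clip(1.0 + cv * z, 0.0, None)


def gen_cohort(spec: CohortSpec) -> tuple[list[EEGRecording], pd.DataFrame]:
    """Generate all subject recordings plus a ground-truth table.

    Each subject's channels start as independent fGn with the group's Hurst
    exponent; every planted connection then mixes a shared source (drawn
    per subject, optionally band-limited) into both endpoint channels:
    ``ch1 <- shared`` contribution is implicit through re-mixing
    ``ch2 = rho * ch1 + sqrt(1 - rho^2) * ch2``, preserving unit variance
    and the channel's marginal fGn law while inducing correlation rho.

    Returns the recordings and a tidy ground-truth table with one row per
    (subject, planted connection) recording the realised coupling.
    """
    rng_root = np.random.SeedSequence(spec.seed)
    subj_seeds = rng_root.spawn(spec.n_young + spec.n_elderly)
    groups = ["young"] * spec.n_young + ["elderly"] * spec.n_elderly
    labels = [f"ch{c:02d}" for c in range(spec.n_channels)]
    n = spec.n_samples
    recordings: list[EEGRecording] = []
    truth_rows = []
    for idx, (group, ss) in enumerate(zip(groups, subj_seeds)):
        rng = np.random.default_rng(ss)
        sid = f"S{idx:03d}"
        data = np.empty((spec.n_channels, n))
        for c in range(spec.n_channels):
            h = spec.hurst(group, c) + spec.h_subject_sd * rng.standard_normal()
            data[c] = gen_fgn(float(np.clip(h, 0.05, 0.95)), n, rng)
        # one envelope per subject: a global, arousal-like slow modulation
        # of coupling expression shared by every connection
        envelope = _coupling_envelope(
            n, spec.fs, spec.coupling_cv, rng, cutoff_hz=spec.coupling_env_cutoff_hz
        )
        # per-subject global coupling gain: connectivity strength varies
        # between individuals as a whole, not only connection by connection
        gain = max(0.0, 1.0 + spec.coupling_gain_sd * rng.standard_normal())
        for pc in spec.planted:
            expressed_group = group
            if rng.random() < spec.cross_expression_p:
                expressed_group = "elderly" if group == "young" else "young"
            rho = gain * spec.rho(pc, expressed_group) + spec.rho_subject_sd * rng.standard_normal()
            rho = float(np.clip(rho, -0.95, 0.95))
            shared = data[pc.ch1]
            if pc.band_hz is not None:
                shared = _bandlimit(shared, pc.band_hz, spec.fs)
            # time-varying mixing: unit variance preserved at every sample
            r_t = np.clip(rho * envelope, -0.95, 0.95)
            data[pc.ch2] = r_t * shared + np.sqrt(1 - r_t * r_t) * data[pc.ch2]
            truth_rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "ch1": labels[min(pc.ch1, pc.ch2)],
                    "ch2": labels[max(pc.ch1, pc.ch2)],
                    "rho": rho,
                    "band_lo_hz": pc.band_hz[0] if pc.band_hz else np.nan,
                    "band_hi_hz": pc.band_hz[1] if pc.band_hz else np.nan,
                }
            )
        # brief global-mode episodes: all channels transiently share a
        # common broadband source, as uncorrected artifacts or global
        # synchronization do in recordings; affected windows carry little
        # group information
        dur = int(round(spec.artifact_dur_s * spec.fs))
        a = spec.artifact_mix
        if spec.artifact_events > 0 and 0 < dur < n and a > 0:
            global_src = gen_fgn(0.7, n, rng)
            for _ in range(spec.artifact_events):
                start = int(rng.integers(0, n - dur + 1))
                seg = slice(start, start + dur)
                data[:, seg] = (
                    np.sqrt(1 - a * a) * data[:, seg] + a * global_src[seg]
                )
        recordings.append(
            EEGRecording(data, spec.fs, list(labels), subject_id=sid, group=group)
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["subject_id", "group", "ch1", "ch2", "rho", "band_lo_hz", "band_hi_hz"],
    )
    return recordings, truth


def gen_scores(summaries: pd.DataFrame, spec: CohortSpec) -> pd.DataFrame:
    """Cognitive-score table: per subject, each score model's weighted sum of
    summary columns plus Gaussian noise.

    ``summaries`` must be indexed by subject with one column per summary
    statistic. Deterministic given ``spec.seed``.
    """
    # a stream disjoint from the per-subject spawn children of gen_cohort
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    out = pd.DataFrame(index=summaries.index)
    for model in spec.score_models:
        missing = [c for c in model.weights if c not in summaries.columns]
        if missing:
            raise KeyError(f"score '{model.name}' references missing summary columns {missing}")
        vals = np.zeros(len(summaries), dtype=float)
        for col, w in model.weights.items():
            vals = vals + w * summaries[col].to_numpy(dtype=float)
        vals = vals + model.noise_sd * rng.standard_normal(len(summaries))
        out[model.name] = vals
    return out
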