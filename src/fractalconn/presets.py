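"""Preset cohort definitions used by the analysis drivers and validation.

Two cohorts are fixed here, once, as the package's study conditions:

``study_cohort``
    The full design the analysis is sized for — 24 young and 19 elderly
    subjects, 14 channels at 256 Hz, 72-s epochs (137 sliding windows of
    1024 samples at step 128), young/elderly Hurst exponents 0.75/0.65,
    and a handful of planted couplings that are stronger (and mostly
    negative) in the elderly group, echoing the direction of age contrasts
    in fractal connectivity.

``reduced_cohort``
    A desk-scale validation cohort — 6 + 6 subjects, 6 channels, 30
    analysis windows — with three planted discriminative (pair, scale)
    features at a coupling contrast of 0.5 between groups, each targeted
    at a distinct detrending scale through band-limited shared sources
    (scale s maps to fluctuation frequency ~ fs/s). Small enough for
    repeated end-to-end runs, structured enough that the selection stage
    must recover the planted features.
"""

from __future__ import annotations

from .fractal import ScaleSet, WindowPlan
from .synthetic import CohortSpec, PlantedConnection, ScoreModel

__all__ = [
    "study_cohort",
    "study_plan",
    "study_scales",
    "reduced_cohort",
    "reduced_plan",
    "reduced_scales",
    "REDUCED_PLANTED_FEATURES",
]

FS = 256.0

study_scales = ScaleSet((8, 16, 32, 64, 128))
study_plan = WindowPlan(win_len=1024, step=128)

reduced_scales = ScaleSet((8, 32, 128))
reduced_plan = WindowPlan(win_len=1024, step=128)
# 30 analysis windows: 1024 + 29 * 128 samples
REDUCED_N_SAMPLES = reduced_plan.win_len + 29 * reduced_plan.step

# the three planted (pair, scale) features of the reduced cohort: each
# coupling is band-limited so it concentrates at one detrending scale
# (scale s maps to fluctuation frequency ~ fs/s; the 16-64 Hz band loads
# scale 8, the 6-12 Hz band loads scale 32)
_REDUCED_PLANTED = [
    PlantedConnection(0, 1, rho_young=0.1, rho_elderly=0.6, band_hz=(16.0, 64.0)),
    PlantedConnection(2, 3, rho_young=0.6, rho_elderly=0.1, band_hz=(6.0, 12.0)),
    PlantedConnection(4, 5, rho_young=0.1, rho_elderly=0.6, band_hz=(16.0, 64.0)),
]
REDUCED_PLANTED_FEATURES = [
    ("ch00", "ch01", 8),
    ("ch02", "ch03", 32),
    ("ch04", "ch05", 8),
]


def reduced_cohort(seed: int = 0) -> CohortSpec:
    """6+6-subject, 6-channel validation cohort with 3 planted features."""
    return CohortSpec(
        n_young=6,
        n_elderly=6,
        n_channels=6,
        fs=FS,
        duration_s=REDUCED_N_SAMPLES / FS,
        H_young=0.75,
        H_elderly=0.65,
        planted=list(_REDUCED_PLANTED),
        score_models=[
            ScoreModel("response_latency", {"mu_dccc_ch00_ch01_s8": -8.0}, noise_sd=0.5),
            ScoreModel("correct_responses", {"mu_dfa_ch00": 10.0}, noise_sd=0.5),
        ],
        seed=seed,
    )


def study_cohort(seed: int = 0) -> CohortSpec:
    """Full study design: 24 + 19 subjects, 14 channels, 72-s epochs."""
    planted = [
        # anticorrelated long-range couplings, more negative in the elderly
        PlantedConnection(0, 13, rho_young=-0.50, rho_elderly=-0.65),
        PlantedConnection(2, 11, rho_young=-0.45, rho_elderly=-0.58),
        PlantedConnection(8, 9, rho_young=-0.16, rho_elderly=-0.32),
        # positive frontal couplings, stronger in the elderly
        PlantedConnection(0, 2, rho_young=0.48, rho_elderly=0.63),
        PlantedConnection(1, 3, rho_young=0.41, rho_elderly=0.59),
    ]
    return CohortSpec(
        n_young=24,
        n_elderly=19,
        n_channels=14,
        fs=FS,
        duration_s=72.0,
        H_young=0.75,
        H_elderly=0.65,
        planted=planted,
        score_models=[
            ScoreModel("response_latency", {"mu_dccc_ch00_ch02_s64": -6.0}, noise_sd=0.5),
            ScoreModel("correct_responses", {"mu_dfa_ch00": 12.0}, noise_sd=0.5),
        ],
        seed=seed,
    )
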