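"""Synthetic cohorts with the generative structure the models assume.

Two modes are provided. The *tabular* mode emits the long-format alpha
power table directly from the linear predictor — fast, for exercising the
inference machinery. The *waveform* mode synthesizes raw 64-channel
recordings referenced to FCz whose measured log alpha band power equals
the same linear predictor, so the preprocessing and spectral stages are
exercised end to end.

The generative model on the log10(µV²) scale is

    alpha = b0 + b_group·G + (b_sleep + b_sleepxgroup·G)·S + b_eyes·E
          + g_ml·ML + g_ap·AP + g_is·IS + extra interactions
          + u_participant + noise

with G = 1 for the non-abstinent group, E = 1 for eyes open, S the 0–10
sleep-quality rating, and (ML, AP, IS) the electrode's Cartesian
coordinates. Defaults place the group-specific sleep slopes at −0.19
(abstinent) and −0.05 (non-abstinent) with a posterior/right/superior
spatial gradient and an eyes-closed alpha elevation.

Waveform alpha content is a comb of equal-power sinusoids at the 11
alpha-band bin frequencies (8–13 Hz in 0.5 Hz steps, random phase per
2-s block and channel), so that the band mean of log bin power matches
the tabular target exactly under a rectangular taper. A narrowband
single-carrier mode is available via ``alpha_freqs`` but then carries no
round-trip guarantee under the log-then-average band statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import ElectrodeLayout
from .preprocessing import RawRecording
from .spectral import CONDITIONS, TABLE_COLUMNS

__all__ = [
    "ParticipantProfile",
    "GenerativeParams",
    "generate_cohort",
    "generate_alpha_table",
    "generate_recording",
    "inject_artifacts",
    "cohort_covariates",
]

ABSTINENT = "abstinent"
NON_ABSTINENT = "non_abstinent"

#: Minimum abstinence duration defining the abstinent group, days.
ABSTINENCE_CUTOFF_DAYS = 30


@dataclass(frozen=True)
class ParticipantProfile:
    id: str
    group: str
    sleep_quality: int
    days_since_use: int
    random_intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.group not in (ABSTINENT, NON_ABSTINENT):
            raise ValueError(f"unknown group {self.group!r}")
        if not 0 <= self.sleep_quality <= 10:
            raise ValueError("sleep_quality must lie in 0–10")
        if self.days_since_use < 0:
            raise ValueError("days_since_use must be nonnegative")
        if self.group == ABSTINENT and self.days_since_use < ABSTINENCE_CUTOFF_DAYS:
            raise ValueError("abstinent participants have ≥ 30 days since use")
        if self.group == NON_ABSTINENT and self.days_since_use > ABSTINENCE_CUTOFF_DAYS:
            raise ValueError("non-abstinent participants have ≤ 30 days since use")


@dataclass(frozen=True)
class GenerativeParams:
    """Effect sizes, variance components and waveform settings.

    Units: all beta/gamma coefficients and SDs are in log10(µV²);
    artifact_amplitude is in µV. Effect-size defaults follow the
    group-specific sleep slopes −0.19 / −0.05 and a modest eyes-open
    alpha suppression.
    """

    beta0: float = 1.30
    beta_group: float = -0.36
    beta_sleep: float = -0.19
    beta_sleep_x_group: float = 0.14
    beta_eyes: float = -0.40
    gamma_ml: float = 0.10
    gamma_ap: float = -0.30
    gamma_is: float = 0.20
    extra_terms: dict = field(default_factory=dict)  # e.g. {"Sleep:Eyes": 0.02}
    sigma_participant: float = 0.50
    sigma_noise: float = 0.30
    artifact_rate: float = 0.01  # probability per (channel, 2-s block)
    artifact_amplitude: float = 200.0
    sleep_mean: float = 6.0
    sleep_sd: float = 2.0
    sampling_rate: float = 500.0
    duration_s: float = 90.0
    alpha_freqs: tuple[float, ...] | None = None  # None = 8–13 Hz comb
    background_ratio: float = 1.0  # background RMS relative to alpha RMS
    background_exponent: float = 1.0  # 1/f^exponent spectral shape
    taper_fraction: float = 0.10  # taper the downstream estimator applies
    block_random_phase: bool = True  # False: stationary (phases drawn once)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_participant < 0 or self.sigma_noise < 0:
            raise ValueError("standard deviations must be nonnegative")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must lie in [0, 1]")


_FEATURES = ("Sleep", "Group", "Eyes", "ML", "AP", "IS")


def linear_predictor(
    profile: ParticipantProfile,
    ml: np.ndarray,
    ap: np.ndarray,
    is_: np.ndarray,
    eyes_open: int,
    params: GenerativeParams,
) -> np.ndarray:
    """Noise-free expected log alpha power per electrode."""
    g = 1.0 if profile.group == NON_ABSTINENT else 0.0
    s = float(profile.sleep_quality)
    eta = (
        params.beta0
        + params.beta_group * g
        + (params.beta_sleep + params.beta_sleep_x_group * g) * s
        + params.beta_eyes * eyes_open
        + params.gamma_ml * ml
        + params.gamma_ap * ap
        + params.gamma_is * is_
        + profile.random_intercept
    )
    values = {"Sleep": s, "Group": g, "Eyes": float(eyes_open), "ML": ml, "AP": ap, "IS": is_}
    for term, coef in params.extra_terms.items():
        prod = np.ones_like(ml) * coef
        for factor in term.split(":"):
            if factor not in values:
                raise ValueError(f"unknown factor {factor!r} in extra term {term!r}")
            prod = prod * values[factor]
        eta = eta + prod
    return np.asarray(eta, dtype=float)


def _draw_sleep(rng: np.random.Generator, params: GenerativeParams) -> int:
    """Discretized truncated normal on the integers 0–10."""
    raw = rng.normal(params.sleep_mean, params.sleep_sd)
    return int(np.clip(np.rint(raw), 0, 10))


def generate_cohort(
    n_abstinent: int,
    n_non_abstinent: int,
    params: GenerativeParams = GenerativeParams(),
) -> list[ParticipantProfile]:
    """Draw participant profiles; sleep quality iid across both groups."""
    if n_abstinent < 1 or n_non_abstinent < 1:
        raise ValueError("both group sizes must be at least 1")
    rng = np.random.default_rng(params.seed)
    profiles = []
    for i in range(n_abstinent + n_non_abstinent):
        abstinent = i < n_abstinent
        group = ABSTINENT if abstinent else NON_ABSTINENT
        if abstinent:
            days = int(rng.integers(ABSTINENCE_CUTOFF_DAYS, 105))
        else:
            days = int(rng.integers(1, 14))
        u = rng.normal(0.0, params.sigma_participant) if params.sigma_participant > 0 else 0.0
        profiles.append(
            ParticipantProfile(
                id=f"sub-{i + 1:02d}",
                group=group,
                sleep_quality=_draw_sleep(rng, params),
                days_since_use=days,
                random_intercept=float(u),
            )
        )
    return profiles


def read_covariates(path_or_buf) -> pd.DataFrame:
    """Read a participant covariate table from delimited text.

    Expects columns id, group, sleep_quality (or sleep_quality_7d, the
    past-7-days rating) and days_since_use; validates ranges and group
    labels. Returns the normalized frame used by the table builder.
    """
    df = pd.read_csv(path_or_buf, sep=None, engine="python")
    if "sleep_quality_7d" in df.columns and "sleep_quality" not in df.columns:
        df = df.rename(columns={"sleep_quality_7d": "sleep_quality"})
    required = {"id", "group", "sleep_quality", "days_since_use"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"covariate table missing columns {sorted(missing)}")
    bad_groups = set(df["group"]) - {ABSTINENT, NON_ABSTINENT}
    if bad_groups:
        raise ValueError(f"unknown group labels {sorted(bad_groups)}")
    if not df["sleep_quality"].between(0, 10).all():
        raise ValueError("sleep_quality must lie in 0–10")
    if (df["days_since_use"] < 0).any():
        raise ValueError("days_since_use must be nonnegative")
    if df["id"].duplicated().any():
        raise ValueError("duplicate participant ids in covariate table")
    return df[sorted(required, key=["id", "group", "sleep_quality", "days_since_use"].index)]


def cohort_covariates(cohort: list[ParticipantProfile]) -> pd.DataFrame:
    """Covariate table with columns id, group, sleep_quality, days_since_use."""
    return pd.DataFrame(
        {
            "id": [p.id for p in cohort],
            "group": [p.group for p in cohort],
            "sleep_quality": [p.sleep_quality for p in cohort],
            "days_since_use": [p.days_since_use for p in cohort],
        }
    )


def generate_alpha_table(
    cohort: list[ParticipantProfile],
    layout: ElectrodeLayout,
    params: GenerativeParams = GenerativeParams(),
) -> pd.DataFrame:
    """Tabular fast path: one row per participant × electrode × condition."""
    if not cohort:
        raise ValueError("cohort is empty")
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    order = np.argsort(np.asarray(layout.labels))
    rows = []
    for p in cohort:
        for cond in CONDITIONS:
            eyes_open = 1 if cond == "open" else 0
            eta = linear_predictor(p, layout.ml, layout.ap, layout.is_, eyes_open, params)
            noise = (
                rng.normal(0.0, params.sigma_noise, size=len(layout))
                if params.sigma_noise > 0
                else np.zeros(len(layout))
            )
            y = eta + noise
            for i in order:
                rows.append(
                    (
                        p.id,
                        layout.labels[i],
                        layout.ml[i],
                        layout.ap[i],
                        layout.is_[i],
                        cond,
                        y[i],
                        p.group,
                        p.sleep_quality,
                        p.days_since_use,
                    )
                )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def _alpha_comb_freqs(params: GenerativeParams) -> np.ndarray:
    if params.alpha_freqs is not None:
        return np.asarray(params.alpha_freqs, dtype=float)
    return np.arange(8.0, 13.0 + 0.25, 0.5)


def _pink_noise(
    rng: np.random.Generator, n: int, fs: float, exponent: float
) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent amplitude spectrum, unit RMS."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = shape * (rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size))
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _line_gain_weights(
    n: int, fs: float, freqs: np.ndarray, taper_fraction: float
) -> np.ndarray:
    """Per-line power weights that cancel inter-line taper leakage.

    A tapered window is not orthogonal across FFT bins, so each comb line
    leaks a little power into the neighboring band bins and an equal-power
    comb reads slightly hot. G[k, l] is the expected (over phase) measured
    power at band bin k per unit power of a line at frequency l, computed
    with the pipeline's own estimator; scaling line powers by
    v = G⁻¹·1 makes the expected measurement flat at the target.
    """
    from .spectral import PowerSpectrum, periodogram

    t = np.arange(n) / fs
    m = len(freqs)
    G = np.empty((m, m))
    for l, fl in enumerate(freqs):
        carriers = np.stack([np.sin(2 * np.pi * fl * t), np.cos(2 * np.pi * fl * t)])
        spec = periodogram(carriers[:, None, :], fs, taper_fraction)
        band = np.array([
            spec.power[:, np.argmin(np.abs(spec.frequencies - fk))].mean()
            for fk in freqs
        ])
        G[:, l] = band / 0.5  # unit-amplitude carrier has power 1/2
    return np.linalg.solve(G, np.ones(m))


def generate_recording(
    profile: ParticipantProfile,
    condition: str,
    layout: ElectrodeLayout,
    params: GenerativeParams = GenerativeParams(),
) -> RawRecording:
    """Waveform mode: 64 recorded channels referenced to FCz, in µV.

    Scalp potentials are simulated at all 65 montage sites, then the
    online FCz reference is subtracted — average re-referencing in the
    preprocessing stage recovers FCz, exactly as for real recordings.
    Per 2-s block and channel, the alpha comb has per-component power
    10^eta µV² (eta the linear predictor), random phase per block.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    fs = params.sampling_rate
    n_total = int(round(params.duration_s * fs))
    block = int(round(2.0 * fs))
    n_blocks = int(np.ceil(n_total / block))
    eyes_open = 1 if condition == "open" else 0
    eta = linear_predictor(profile, layout.ml, layout.ap, layout.is_, eyes_open, params)
    # Pre-compensate the average-reference bias: measuring channel i after
    # common-average re-referencing yields E[p_i'] = q_i(1-2/n) + mean(q)/n
    # for generated per-component powers q; solve for q so that the
    # measured power hits the target p = 10**eta.
    p_target = 10.0**eta
    n_ch = len(layout)
    q_mean = p_target.mean() / (1.0 - 1.0 / n_ch)
    q = (p_target - q_mean / n_ch) / (1.0 - 2.0 / n_ch)
    q = np.maximum(q, 1e-12)
    freqs = _alpha_comb_freqs(params)
    # cancel inter-line taper leakage (see _line_gain_weights)
    v = _line_gain_weights(block, fs, freqs, params.taper_fraction)
    amp = np.sqrt(2.0 * np.outer(q, np.maximum(v, 0.0)))  # (channel, line), µV

    seed = np.random.SeedSequence(
        [params.seed, 2, _stable_hash(profile.id), eyes_open]
    )
    rng = np.random.default_rng(seed)
    t_block = np.arange(block) / fs
    x = np.empty((n_ch, n_blocks * block))
    fixed_phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_ch, freqs.size))
    for b in range(n_blocks):
        # comb frequencies are multiples of 0.5 Hz, so constant phases
        # repeat seamlessly across 2-s blocks (stationary signal)
        if params.block_random_phase:
            phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_ch, freqs.size))
        else:
            phases = fixed_phases
        carriers = np.sin(
            2.0 * np.pi * freqs[None, :, None] * t_block[None, None, :] + phases[:, :, None]
        )
        x[:, b * block : (b + 1) * block] = (amp[:, :, None] * carriers).sum(axis=1)
    if params.background_ratio > 0:
        alpha_rms = np.sqrt((amp**2).sum(axis=1) / 2.0)
        for c in range(n_ch):
            bg = _pink_noise(rng, n_blocks * block, fs, params.background_exponent)
            x[c] += params.background_ratio * alpha_rms[c] * bg
    x = x[:, :n_total]

    ref = layout.index("FCz")
    recorded = [i for i in range(n_ch) if i != ref]
    data = x[recorded] - x[ref]
    return RawRecording(
        participant=profile.id,
        condition=condition,
        channel_labels=tuple(layout.labels[i] for i in recorded),
        samples=data,
        sampling_rate=fs,
    )


def _stable_hash(s: str) -> int:
    """Deterministic small nonnegative hash of a string (process-stable)."""
    h = 0
    for ch in s:
        h = (h * 131 + ord(ch)) % 2_000_003
    return h


def inject_artifacts(
    recording: RawRecording,
    params: GenerativeParams = GenerativeParams(),
    seed: int | None = None,
) -> tuple[RawRecording, list[tuple[int, int]]]:
    """Add high-amplitude transients at random (channel, 2-s block) sites.

    Each site receives a raised-cosine bump of peak ``artifact_amplitude``
    µV lasting 200 ms at the block centre. Returns the modified recording
    and the ground-truth (channel, block) sites.
    """
    fs = recording.sampling_rate
    block = int(round(2.0 * fs))
    n_blocks = recording.samples.shape[1] // block
    rng = np.random.default_rng(
        np.random.SeedSequence(
            [params.seed if seed is None else seed, 3, _stable_hash(recording.participant)]
        )
    )
    hit = rng.random((recording.samples.shape[0], n_blocks)) < params.artifact_rate
    sites = [(int(c), int(b)) for c, b in zip(*np.nonzero(hit))]
    if not sites:
        return recording, []
    data = recording.samples.copy()
    width = int(round(0.2 * fs))
    bump = params.artifact_amplitude * 0.5 * (1 - np.cos(2 * np.pi * np.arange(width) / width))
    for c, b in sites:
        start = b * block + (block - width) // 2
        data[c, start : start + width] += bump
    return replace(recording, samples=data), sites
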