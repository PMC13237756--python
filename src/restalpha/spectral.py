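"""Spectral estimation of absolute alpha band power.

Power spectra are estimated per channel by averaging one-sided
periodograms of the cleaned 2-s epochs (0.5 Hz resolution). A split
cosine-bell taper ("10% Hanning window": 5% raised cosine at each edge)
is applied per epoch, with the power loss compensated by the squared
window mean (the coherent gain), which keeps the power of in-band
oscillatory lines — the quantity the alpha statistic averages —
invariant to the taper choice. Alpha power is
the mean of log10 bin power over 8–13 Hz inclusive (11 bins), computed
on the epoch-averaged spectrum by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import ElectrodeLayout

__all__ = [
    "PowerSpectrum",
    "SpectralConfig",
    "taper_window",
    "taper",
    "periodogram",
    "alpha_band_power",
    "build_long_table",
    "TABLE_COLUMNS",
]

ALPHA_BAND = (8.0, 13.0)


@dataclass(frozen=True)
class SpectralConfig:
    """Settings of the band-power estimator.

    log_before_band_mean selects the transform order: True (default)
    log-transforms the epoch-averaged spectrum before averaging over the
    band; False averages band bins first, then logs.
    log_each_epoch instead log-transforms per-epoch spectra before the
    epoch average (the alternative reading of "log before average").
    """

    taper_fraction: float = 0.10
    band: tuple[float, float] = ALPHA_BAND
    power_floor: float = 1e-20  # µV², guards log of an empty bin
    log_before_band_mean: bool = True
    log_each_epoch: bool = False


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided power spectrum per channel, averaged over epochs."""

    frequencies: np.ndarray  # Hz
    power: np.ndarray  # (channels, bins), µV² per bin
    n_epochs_averaged: int
    channel_labels: tuple[str, ...] = ()


def taper_window(n: int, taper_fraction: float = 0.10) -> np.ndarray:
    """Split cosine-bell window of length n.

    A raised-cosine ramp covers ``taper_fraction/2`` of the samples at each
    end; fraction 1 gives a full Hann window, 0 a rectangular window.
    """
    if not 0.0 <= taper_fraction <= 1.0:
        raise ValueError(f"taper_fraction must lie in [0, 1], got {taper_fraction}")
    w = np.ones(n)
    m = int(np.floor(taper_fraction * n / 2))
    if m > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(m) / m))
        w[:m] = ramp
        w[-m:] = ramp[::-1]
    if taper_fraction > 0 and m == 0 and n > 0:
        # degenerate short epoch: still honour the zero-endpoint contract
        w[0] = w[-1] = 0.0
    return w


def taper(samples: np.ndarray, taper_fraction: float = 0.10) -> np.ndarray:
    """Apply the split cosine-bell taper along the last axis."""
    samples = np.asarray(samples, dtype=float)
    return samples * taper_window(samples.shape[-1], taper_fraction)


def _periodogram_1d(x: np.ndarray, fs: float, window: np.ndarray) -> np.ndarray:
    """One-sided periodogram normalized so total power = signal variance.

    Power is expressed per frequency bin (not density); with a rectangular
    window the bin values sum to the biased time-domain variance
    (Parseval). Taper power loss is compensated by the squared window
    mean (coherent gain), so an on-bin sinusoid keeps its A²/2 power
    under any taper fraction.
    """
    n = x.shape[-1]
    xw = (x - x.mean(axis=-1, keepdims=True)) * window
    spec = np.fft.rfft(xw, axis=-1)
    p = np.abs(spec) ** 2 / (n * n)
    # fold negative frequencies into the positive side
    if n % 2 == 0:
        p[..., 1:-1] *= 2.0
    else:
        p[..., 1:] *= 2.0
    return p / np.mean(window) ** 2


def periodogram(
    epochs: np.ndarray,
    sampling_rate: float,
    taper_fraction: float = 0.10,
    channel_labels: tuple[str, ...] = (),
    log_each_epoch: bool = False,
    power_floor: float = 1e-20,
) -> PowerSpectrum:
    """Average one-sided periodogram over 2-s epochs.

    Parameters
    ----------
    epochs : (n_epochs, n_channels, n_samples) array in µV.
    log_each_epoch : average log10 spectra across epochs instead of raw
        spectra (returned power is then 10**mean-log, a geometric mean).
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim != 3:
        raise ValueError("epochs must be (n_epochs, n_channels, n_samples)")
    if epochs.shape[0] < 1:
        raise ValueError("no retained epochs to average")
    n = epochs.shape[-1]
    window = taper_window(n, taper_fraction)
    per_epoch = _periodogram_1d(epochs, sampling_rate, window)
    if log_each_epoch:
        power = 10 ** np.log10(np.maximum(per_epoch, power_floor)).mean(axis=0)
    else:
        power = per_epoch.mean(axis=0)
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    return PowerSpectrum(
        frequencies=freqs,
        power=power,
        n_epochs_averaged=epochs.shape[0],
        channel_labels=tuple(channel_labels),
    )


def alpha_band_power(
    spectrum: PowerSpectrum,
    band: tuple[float, float] = ALPHA_BAND,
    power_floor: float | None = None,
    log_before_band_mean: bool = True,
) -> np.ndarray:
    """Log alpha power per channel: mean of log10 bin power over the band.

    Band endpoints are inclusive. With ``log_before_band_mean=False`` the
    band bins are averaged on the µV² scale first and a single log taken.
    """
    lo, hi = band
    f = spectrum.frequencies
    if lo < f[0] or hi > f[-1]:
        raise ValueError(f"band {band} outside spectrum range [{f[0]}, {f[-1]}] Hz")
    mask = (f >= lo) & (f <= hi)
    p = np.atleast_2d(spectrum.power)[:, mask]
    if np.any(p <= 0):
        if power_floor is None:
            raise ValueError(
                "zero power in an alpha-band bin; pass power_floor (e.g. 1e-20 µV²) "
                "to floor empty bins before the log transform"
            )
        p = np.maximum(p, power_floor)
    if log_before_band_mean:
        out = np.log10(p).mean(axis=1)
    else:
        out = np.log10(p.mean(axis=1))
    return out if spectrum.power.ndim == 2 else out[0]


def clean_epochs_spectrum(clean, config: SpectralConfig = SpectralConfig()) -> PowerSpectrum:
    """Periodogram of a :class:`~restalpha.preprocessing.CleanEpochSet`."""
    if clean.epochs.shape[0] < 1:
        raise ValueError("no retained epochs to average")
    return periodogram(
        clean.epochs,
        clean.sampling_rate,
        taper_fraction=config.taper_fraction,
        channel_labels=clean.channel_labels,
        log_each_epoch=config.log_each_epoch,
        power_floor=config.power_floor,
    )


def clean_epochs_band_power(clean, config: SpectralConfig = SpectralConfig()) -> np.ndarray:
    """Log alpha power per channel of a CleanEpochSet."""
    spec = clean_epochs_spectrum(clean, config)
    return alpha_band_power(
        spec,
        band=config.band,
        power_floor=config.power_floor,
        log_before_band_mean=config.log_before_band_mean,
    )


TABLE_COLUMNS = [
    "participant",
    "electrode",
    "ml",
    "ap",
    "is",
    "condition",
    "log_alpha_power",
    "group",
    "sleep_quality",
    "days_since_use",
]

CONDITIONS = ("closed", "open")


def build_long_table(
    band_powers: dict[tuple[str, str], np.ndarray],
    covariates: pd.DataFrame,
    layout: ElectrodeLayout,
) -> pd.DataFrame:
    """Assemble the long-format modelling table.

    Parameters
    ----------
    band_powers : maps (participant id, condition) to a per-electrode log
        alpha power vector ordered as ``layout.labels``. Both conditions
        must be present for every participant.
    covariates : one row per participant with columns id, group,
        sleep_quality, days_since_use.

    Returns a DataFrame with one row per participant x electrode x eye
    condition (130 rows per participant for the 65-electrode montage),
    ordered by (participant, condition, electrode label).
    """
    cov = covariates.set_index("id")
    participants = sorted({pid for pid, _ in band_powers})
    rows = []
    for pid in participants:
        if pid not in cov.index:
            raise ValueError(f"missing covariates for participant {pid!r}")
        for cond in CONDITIONS:
            if (pid, cond) not in band_powers:
                raise ValueError(
                    f"participant {pid!r} is missing the {cond!r} eye condition"
                )
        c = cov.loc[pid]
        for field in ("group", "sleep_quality", "days_since_use"):
            if pd.isna(c[field]):
                raise ValueError(f"covariate {field!r} missing for participant {pid!r}")
        for cond in CONDITIONS:
            power = np.asarray(band_powers[(pid, cond)], dtype=float)
            if power.shape[0] != len(layout):
                raise ValueError(
                    f"band power for {pid!r}/{cond!r} has {power.shape[0]} "
                    f"entries, expected {len(layout)}"
                )
            order = np.argsort(np.asarray(layout.labels))
            for i in order:
                rows.append(
                    (
                        pid,
                        layout.labels[i],
                        layout.ml[i],
                        layout.ap[i],
                        layout.is_[i],
                        cond,
                        power[i],
                        c["group"],
                        c["sleep_quality"],
                        c["days_since_use"],
                    )
                )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def write_table(table: pd.DataFrame, path) -> None:
    """Write an alpha-power table as TSV in the documented column order."""
    table[TABLE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    """Round-trip reader for :func:`write_table` output."""
    df = pd.read_csv(path, sep="\t")
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"alpha-power table missing columns {sorted(missing)}")
    return df[TABLE_COLUMNS]
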