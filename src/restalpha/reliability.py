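"""Split-half internal consistency of alpha power.

Retained epochs are split by temporal order into a first and second
half; alpha power is computed independently per half, and the Pearson
correlation between halves, taken across participants, is reported per
electrode and eye condition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .preprocessing import CleanEpochSet
from .spectral import CONDITIONS, SpectralConfig, clean_epochs_band_power

__all__ = ["split_half_power", "pearson_r", "reliability_report", "ReliabilityReport"]


def split_half_power(
    clean: CleanEpochSet, config: SpectralConfig = SpectralConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Log alpha power per channel for the first and second recording half.

    The retained epochs, in original temporal order, are partitioned into
    the first ⌈m/2⌉ and last ⌊m/2⌋; band power is estimated per half.
    """
    m = clean.epochs.shape[0]
    if m < 2:
        raise ValueError("split-half analysis needs at least 2 retained epochs")
    cut = (m + 1) // 2
    first = replace(clean, epochs=clean.epochs[:cut])
    second = replace(clean, epochs=clean.epochs[cut:])
    return (
        clean_epochs_band_power(first, config),
        clean_epochs_band_power(second, config),
    )


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation across participants."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("correlation needs at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc**2))
    sy = np.sqrt(np.sum(yc**2))
    if sx == 0 or sy == 0:
        raise ValueError("zero variance; correlation undefined")
    return float(np.sum(xc * yc) / (sx * sy))


@dataclass(frozen=True)
class ReliabilityReport:
    """Per electrode × condition split-half r with below-threshold flags."""

    table: pd.DataFrame  # electrode, condition, r, flagged
    threshold: float

    def median_r(self) -> float:
        return float(self.table["r"].median())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def reliability_report(
    halves: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]],
    channel_labels: tuple[str, ...],
    threshold: float = 0.7,
) -> ReliabilityReport:
    """Correlate first- and second-half alpha power across participants.

    Parameters
    ----------
    halves : maps (participant id, condition) to the per-channel
        (first_half, second_half) log alpha power pair.
    threshold : electrodes with r below this are flagged (the
        conventional acceptability bar is r > 0.7).
    """
    participants = sorted({pid for pid, _ in halves})
    if len(participants) < 3:
        raise ValueError("reliability needs at least 3 participants")
    rows = []
    for cond in CONDITIONS:
        firsts = np.array([halves[(p, cond)][0] for p in participants])
        seconds = np.array([halves[(p, cond)][1] for p in participants])
        for i, label in enumerate(channel_labels):
            r = pearson_r(firsts[:, i], seconds[:, i])
            rows.append((label, cond, r, r < threshold))
    return ReliabilityReport(
        table=pd.DataFrame(rows, columns=["electrode", "condition", "r", "flagged"]),
        threshold=threshold,
    )
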