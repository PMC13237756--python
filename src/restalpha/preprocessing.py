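"""Raw EEG to artifact-managed 2-s epoch sets.

The fixed pipeline order is: average re-reference (recovering the online
reference FCz as an explicit channel) → segmentation into contiguous 2-s
windows → threshold artifact detection → channel rule (channels bad in
strictly more than 40% of segments are Hjorth-interpolated everywhere and
their flags cleared) → segment rule (segments with strictly more than 10%
of sensors flagged are dropped).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import REFERENCE_CHANNEL, ElectrodeLayout, NeighborGraph

__all__ = [
    "RawRecording",
    "EpochSet",
    "ArtifactMask",
    "CleanEpochSet",
    "rereference_average",
    "segment",
    "detect_artifacts",
    "apply_channel_rule",
    "apply_segment_rule",
    "hjorth_interpolate",
    "eog_regress",
    "preprocess_recording",
]


@dataclass(frozen=True)
class RawRecording:
    """Multichannel EEG time series in µV (channels × samples)."""

    participant: str
    condition: str  # "open" or "closed"
    channel_labels: tuple[str, ...]
    samples: np.ndarray
    sampling_rate: float = 500.0

    def __post_init__(self) -> None:
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels × time)")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{len(self.channel_labels)} labels but "
                f"{self.samples.shape[0]} sample rows"
            )

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.sampling_rate


@dataclass(frozen=True)
class EpochSet:
    """Ordered equal-length 2-s windows (epochs × channels × samples)."""

    participant: str
    condition: str
    channel_labels: tuple[str, ...]
    epochs: np.ndarray
    sampling_rate: float

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]


@dataclass(frozen=True)
class ArtifactMask:
    """Boolean artifact flag per (channel, epoch)."""

    flags: np.ndarray  # (n_channels, n_epochs)

    @property
    def channel_bad_fraction(self) -> np.ndarray:
        """Fraction of epochs flagged, per channel."""
        return self.flags.mean(axis=1)

    @property
    def epoch_bad_fraction(self) -> np.ndarray:
        """Fraction of sensors flagged, per epoch."""
        return self.flags.mean(axis=0)


@dataclass(frozen=True)
class CleanEpochSet:
    """Retained epochs with provenance of interpolation and rejection."""

    participant: str
    condition: str
    channel_labels: tuple[str, ...]
    epochs: np.ndarray  # (n_retained, n_channels, n_samples)
    sampling_rate: float
    interpolated_channels: tuple[str, ...] = ()
    dropped_epochs: tuple[int, ...] = ()
    retained_indices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if set(self.dropped_epochs) & set(self.retained_indices):
            raise ValueError("an epoch cannot be both dropped and retained")

    @property
    def retained_seconds(self) -> float:
        return self.epochs.shape[0] * self.epochs.shape[2] / self.sampling_rate

    def provenance(self) -> dict:
        return {
            "participant": self.participant,
            "condition": self.condition,
            "interpolated_channels": list(self.interpolated_channels),
            "dropped_epochs": list(self.dropped_epochs),
            "retained_epochs": len(self.retained_indices),
            "retained_seconds": self.retained_seconds,
        }


def rereference_average(recording: RawRecording, layout: ElectrodeLayout) -> RawRecording:
    """Re-reference to the common average, recovering the online reference.

    The cap records 64 channels against FCz; FCz itself is therefore an
    implicit all-zero channel. It is appended explicitly before averaging,
    so the result has 65 channels whose instantaneous mean is zero.
    Applying the operation to a recording that already contains FCz is
    idempotent.
    """
    unknown = set(recording.channel_labels) - set(layout.labels)
    if unknown:
        raise ValueError(f"channels not in the montage: {sorted(unknown)}")
    labels = list(recording.channel_labels)
    data = recording.samples
    if REFERENCE_CHANNEL not in labels:
        labels.append(REFERENCE_CHANNEL)
        data = np.vstack([data, np.zeros((1, data.shape[1]))])
    data = data - data.mean(axis=0, keepdims=True)
    return replace(recording, channel_labels=tuple(labels), samples=data)


def segment(recording: RawRecording, window_s: float = 2.0) -> EpochSet:
    """Cut into contiguous non-overlapping windows; trailing remainder discarded."""
    n_win = int(round(window_s * recording.sampling_rate))
    n_total = recording.samples.shape[1]
    n_epochs = n_total // n_win
    if n_epochs < 1:
        raise ValueError(
            f"recording of {recording.duration:.2f} s is shorter than the "
            f"{window_s} s segmentation window"
        )
    trimmed = recording.samples[:, : n_epochs * n_win]
    epochs = trimmed.reshape(recording.samples.shape[0], n_epochs, n_win)
    epochs = np.transpose(epochs, (1, 0, 2)).copy()
    return EpochSet(
        participant=recording.participant,
        condition=recording.condition,
        channel_labels=recording.channel_labels,
        epochs=epochs,
        sampling_rate=recording.sampling_rate,
    )


def detect_artifacts(
    epochs: EpochSet,
    abs_threshold_uV: float = 100.0,
    step_threshold_uV: float = 50.0,
) -> ArtifactMask:
    """Flag (channel, epoch) cells by amplitude and sample-to-sample step.

    A cell is flagged when any absolute sample exceeds ``abs_threshold_uV``
    or any first difference exceeds ``step_threshold_uV`` within the epoch.
    """
    if abs_threshold_uV <= 0 or step_threshold_uV <= 0:
        raise ValueError("artifact thresholds must be positive")
    x = epochs.epochs
    over_abs = (np.abs(x) > abs_threshold_uV).any(axis=2)
    over_step = (np.abs(np.diff(x, axis=2)) > step_threshold_uV).any(axis=2)
    return ArtifactMask(flags=(over_abs | over_step).T)


def hjorth_interpolate(
    epoch: np.ndarray,
    channel: int,
    graph: NeighborGraph,
    bad_in_epoch: np.ndarray | None = None,
) -> np.ndarray:
    """Replace one channel by the Hjorth-Laplacian neighbor average.

    The replacement is the inverse-angular-distance weighted mean of the
    channel's nearest neighbors, weights normalized to sum to one.
    Neighbors flagged bad in this epoch are excluded.
    """
    nbrs = graph.neighbors[channel]
    dists = graph.distances[channel]
    if bad_in_epoch is not None:
        usable = ~bad_in_epoch[nbrs]
        nbrs, dists = nbrs[usable], dists[usable]
    if nbrs.size == 0:
        raise ValueError(
            f"channel {channel} has no usable neighbors for interpolation"
        )
    w = 1.0 / np.maximum(dists, 1e-12)
    w = w / w.sum()
    return w @ epoch[nbrs]


def apply_channel_rule(
    epochs: EpochSet,
    mask: ArtifactMask,
    graph: NeighborGraph,
    frac: float = 0.40,
) -> tuple[EpochSet, ArtifactMask, tuple[int, ...]]:
    """Interpolate channels bad in strictly more than ``frac`` of segments.

    Interpolated channels are replaced in *every* epoch, using only
    neighbors not flagged in that epoch, and their flags cleared before
    the segment rule runs. In the rare epoch where a target channel has
    no usable neighbor at all, its original samples and flag are kept,
    deferring that epoch to the segment rule. Returns the updated
    epochs, mask, and the interpolated channel indices.
    """
    if mask.flags.shape != (epochs.n_channels, epochs.n_epochs):
        raise ValueError("mask shape does not match epochs")
    bad_frac = mask.channel_bad_fraction
    targets = np.flatnonzero(bad_frac > frac)
    if targets.size == epochs.n_channels:
        raise ValueError("every channel exceeds the artifact fraction; unrecoverable")
    if targets.size == 0:
        return epochs, mask, ()
    data = epochs.epochs.copy()
    flags = mask.flags.copy()
    for e in range(epochs.n_epochs):
        bad_here = mask.flags[:, e]
        for ch in targets:
            try:
                data[e, ch] = hjorth_interpolate(epochs.epochs[e], ch, graph, bad_here)
                flags[ch, e] = False
            except ValueError:
                pass  # no usable neighbor: leave flagged for the segment rule
    return (
        replace(epochs, epochs=data),
        ArtifactMask(flags=flags),
        tuple(int(t) for t in targets),
    )


def apply_segment_rule(
    epochs: EpochSet,
    mask: ArtifactMask,
    frac: float = 0.10,
    interpolated_channels: tuple[int, ...] = (),
) -> CleanEpochSet:
    """Drop epochs whose flagged-sensor fraction strictly exceeds ``frac``."""
    if mask.flags.shape != (epochs.n_channels, epochs.n_epochs):
        raise ValueError("mask shape does not match epochs")
    bad_frac = mask.epoch_bad_fraction
    keep = bad_frac <= frac
    if not keep.any():
        raise ValueError("every segment exceeds the bad-sensor fraction; unrecoverable")
    retained = tuple(int(i) for i in np.flatnonzero(keep))
    dropped = tuple(int(i) for i in np.flatnonzero(~keep))
    return CleanEpochSet(
        participant=epochs.participant,
        condition=epochs.condition,
        channel_labels=epochs.channel_labels,
        epochs=epochs.epochs[keep].copy(),
        sampling_rate=epochs.sampling_rate,
        interpolated_channels=tuple(
            epochs.channel_labels[i] for i in interpolated_channels
        ),
        dropped_epochs=dropped,
        retained_indices=retained,
    )


def eog_regress(recording: RawRecording, eog: np.ndarray) -> RawRecording:
    """Remove each channel's least-squares projection on an EOG trace.

    A lightweight stand-in for component-based ocular correction: each
    channel x is replaced by its residual from the ordinary least-squares
    fit x ~ a + b·g on the EOG trace g (the affine projection, so the
    channel's DC offset is absorbed as well).
    """
    g = np.asarray(eog, dtype=float)
    if g.shape[0] != recording.samples.shape[1]:
        raise ValueError("EOG trace length does not match the recording")
    gc = g - g.mean()
    denom = gc @ gc
    if denom <= 0:
        raise ValueError("EOG channel has zero variance; cannot regress")
    x = recording.samples
    beta = (x @ gc) / denom
    fitted = x.mean(axis=1, keepdims=True) + np.outer(beta, gc)
    return replace(recording, samples=x - fitted)


def preprocess_recording(
    recording: RawRecording,
    layout: ElectrodeLayout,
    graph: NeighborGraph,
    window_s: float = 2.0,
    abs_threshold_uV: float = 100.0,
    step_threshold_uV: float = 50.0,
    channel_frac: float = 0.40,
    segment_frac: float = 0.10,
) -> CleanEpochSet:
    """Full preprocessing chain in the fixed order."""
    reref = rereference_average(recording, layout)
    # order channels as the montage so masks and graphs align
    order = [reref.channel_labels.index(lab) for lab in layout.labels]
    reref = replace(
        reref,
        channel_labels=tuple(layout.labels),
        samples=reref.samples[order],
    )
    epochs = segment(reref, window_s)
    mask = detect_artifacts(epochs, abs_threshold_uV, step_threshold_uV)
    epochs, mask, interp = apply_channel_rule(epochs, mask, graph, channel_frac)
    return apply_segment_rule(epochs, mask, segment_frac, interp)
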