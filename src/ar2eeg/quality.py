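"""Artifact-epoch detection and mutual-information channel screening.

Muscle artifact in scalp EEG is broadband and concentrated above ~16 Hz,
so the 16-70 Hz band-passed recording is reduced to a single composite
envelope (per-channel Hilbert amplitude, z-scored, averaged across
channels, smoothed), and the longest run of samples above a threshold
(default 1 SD) marks the epoch of maximal muscle contamination.

During that epoch, channels that share no information with any other
channel are suspected high-impedance recordings: a normalized mutual
information (NMI) adjacency matrix is computed across channels, each
channel is summarized by its maximum pairwise NMI, and channels below an
inclusion threshold are excluded from the ICA stage.  If no artifact
epoch exists, or screening would exclude everything, all channels are
processed (fallback).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .edf_io import EEGRecording
from .filters import hilbert_envelope, moving_average

__all__ = [
    "ArtifactEpoch",
    "ChannelQualityReport",
    "composite_envelope",
    "longest_suprathreshold_epoch",
    "normalized_mi",
    "mi_adjacency",
    "screen_channels",
]


@dataclass(frozen=True)
class ArtifactEpoch:
    """Half-open sample interval [start, end) of maximal muscle contamination."""

    start_sample: int
    end_sample: int
    peak_sd: float

    def __post_init__(self) -> None:
        if not 0 <= self.start_sample < self.end_sample:
            raise ValueError("epoch interval must satisfy 0 <= start < end")

    @property
    def n_samples(self) -> int:
        return self.end_sample - self.start_sample


@dataclass
class ChannelQualityReport:
    """Per-channel screening outcome.

    ``included[i]`` is True iff ``max_nmi[i] >= threshold``, except in
    fallback mode where every channel is included.
    """

    labels: list[str]
    max_nmi: np.ndarray
    included: np.ndarray  # bool per channel
    threshold: float
    epoch_used: ArtifactEpoch | None
    fallback: bool
    n_bins: int = 16
    notes: list[str] = field(default_factory=list)

    @property
    def included_labels(self) -> list[str]:
        return [l for l, ok in zip(self.labels, self.included) if ok]

    @property
    def excluded_labels(self) -> list[str]:
        return [l for l, ok in zip(self.labels, self.included) if not ok]

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "max_nmi": [float(v) for v in self.max_nmi],
            "included": [bool(v) for v in self.included],
            "threshold": float(self.threshold),
            "epoch": None
            if self.epoch_used is None
            else {
                "start_sample": self.epoch_used.start_sample,
                "end_sample": self.epoch_used.end_sample,
                "peak_sd": float(self.epoch_used.peak_sd),
            },
            "fallback": bool(self.fallback),
            "n_bins": self.n_bins,
            "notes": list(self.notes),
        }


def composite_envelope(
    bandpassed: EEGRecording,
    smooth_window_s: float = 0.5,
    normalization: str = "per_channel",
) -> np.ndarray:
    """Collapse a band-passed recording to one smoothed envelope in SD units.

    Per channel: Hilbert envelope, then (with the default per-channel
    normalization) a z-score over the whole record; the z-scored envelopes
    are averaged across channels, smoothed with a centered moving average
    of ``smooth_window_s`` seconds (window forced odd), and the smoothed
    composite is rescaled to zero mean and unit SD.  The final rescaling
    matters: averaging z-scores across channels shrinks the variance (the
    more channels are artifact-free, the more), so thresholding at "one
    standard deviation" is only meaningful in SD units of the composite
    series itself.  The ``"global"`` alternative averages raw envelopes
    first and z-scores the averaged series.

    Channels whose envelope has zero variance carry no amplitude
    information and are omitted from the average with a warning.  A
    composite with zero variance (all channels constant amplitude) is
    returned as all zeros, so no artifact epoch is found downstream.
    """
    if normalization not in ("per_channel", "global"):
        raise ValueError(f"unknown normalization {normalization!r}")
    envs = []
    for ch, label in zip(bandpassed.data_uv, bandpassed.labels):
        env = hilbert_envelope(ch)
        sd = env.std()
        if sd == 0.0:
            warnings.warn(
                f"channel {label}: zero envelope variance, omitted from composite",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        if normalization == "per_channel":
            envs.append((env - env.mean()) / sd)
        else:
            envs.append(env)
    if not envs:
        raise ValueError("all channels have zero envelope variance")
    comp = np.mean(envs, axis=0)
    win = int(round(smooth_window_s * bandpassed.fs_hz))
    win = max(1, min(win if win % 2 == 1 else win + 1, comp.size - (comp.size + 1) % 2))
    comp = moving_average(comp, win)
    sd = comp.std()
    if sd == 0.0:
        return np.zeros_like(comp)
    return (comp - comp.mean()) / sd


def longest_suprathreshold_epoch(
    envelope: np.ndarray, threshold_sd: float = 1.0
) -> ArtifactEpoch | None:
    """Longest run of consecutive samples strictly above `threshold_sd`.

    Ties are broken toward the earliest run; returns ``None`` when no
    sample exceeds the threshold.
    """
    envelope = np.asarray(envelope, dtype=np.float64)
    above = envelope > threshold_sd
    if not above.any():
        return None
    # run boundaries via the discrete derivative of the indicator
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, above.size]
    lengths = ends - starts
    best = int(np.argmax(lengths))  # argmax returns the first maximum: earliest tie
    s, e = int(starts[best]), int(ends[best])
    return ArtifactEpoch(start_sample=s, end_sample=e, peak_sd=float(envelope[s:e].max()))


def normalized_mi(x: np.ndarray, y: np.ndarray, n_bins: int = 16) -> float:
    """Histogram normalized mutual information, ``I(X;Y)/sqrt(H(X)H(Y))``.

    A joint histogram with `n_bins` equal-width bins per axis spanning
    each series' observed range gives the plug-in MI in nats, normalized
    by the geometric mean of the marginal entropies and clipped to [0, 1].
    Equal-width binning over the observed range makes the value invariant
    to affine rescaling of either input.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D series of equal length")
    if x.size < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} samples, got {x.size}")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("zero entropy: constant input series")
    joint, _, _ = np.histogram2d(x, y, bins=n_bins)
    p = joint / joint.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    hx = -np.sum(px[px > 0] * np.log(px[px > 0]))
    hy = -np.sum(py[py > 0] * np.log(py[py > 0]))
    nz = p > 0
    mi = np.sum(p[nz] * (np.log(p[nz]) - np.log(np.outer(px, py)[nz])))
    if hx <= 0.0 or hy <= 0.0:
        raise ValueError("zero entropy: degenerate marginal")
    return float(np.clip(mi / np.sqrt(hx * hy), 0.0, 1.0))


def mi_adjacency(
    rec: EEGRecording, epoch: ArtifactEpoch, n_bins: int = 16
) -> np.ndarray:
    """Symmetric channel-by-channel NMI matrix over the artifact epoch.

    The diagonal is 0 (self-information is excluded from per-channel
    maxima).  A channel that is constant inside the epoch is electrically
    dead there; its entries are set to 0 so screening excludes it.
    """
    if epoch.end_sample > rec.n_samples:
        raise ValueError("epoch extends past the end of the recording")
    if epoch.n_samples < 4 * n_bins:
        raise ValueError(
            f"epoch of {epoch.n_samples} samples is too short for {n_bins} bins; "
            "use a longer epoch or fewer bins"
        )
    seg = rec.data_uv[:, epoch.start_sample : epoch.end_sample]
    n = rec.n_channels
    adj = np.zeros((n, n))
    live = np.ptp(seg, axis=1) > 0.0
    for i in range(n):
        if not live[i]:
            continue
        for j in range(i + 1, n):
            if not live[j]:
                continue
            adj[i, j] = adj[j, i] = normalized_mi(seg[i], seg[j], n_bins=n_bins)
    return adj


def screen_channels(
    adjacency: np.ndarray,
    inclusion_threshold: float = 0.2,
    labels: list[str] | None = None,
    epoch: ArtifactEpoch | None = None,
    n_bins: int = 16,
) -> ChannelQualityReport:
    """Include each channel iff its maximum pairwise NMI meets the threshold.

    If every channel would be excluded the report switches to fallback:
    all channels included, ``fallback`` flag set.
    """
    adjacency = np.asarray(adjacency, dtype=np.float64)
    if adjacency.ndim != 2 or adjacency.shape[0] != adjacency.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(adjacency, adjacency.T):
        raise ValueError("adjacency must be symmetric")
    n = adjacency.shape[0]
    if labels is None:
        labels = [f"ch{i}" for i in range(n)]
    max_nmi = adjacency.max(axis=1) if n > 1 else np.zeros(n)
    included = max_nmi >= inclusion_threshold
    notes: list[str] = []
    fallback = False
    if not included.any():
        fallback = True
        included = np.ones(n, dtype=bool)
        notes.append("all channels below threshold: fallback to all electrodes")
    return ChannelQualityReport(
        labels=list(labels),
        max_nmi=max_nmi,
        included=included,
        threshold=float(inclusion_threshold),
        epoch_used=epoch,
        fallback=fallback,
        n_bins=n_bins,
        notes=notes,
    )
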