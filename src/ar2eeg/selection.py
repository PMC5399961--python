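"""Myogenic / neurogenic component classification by spatial focality.

Muscle generators sit in scalp and facial muscle directly under one or
two electrodes, so their independent components have scalp topographies
concentrated on few electrodes.  Brain generators are spatially smeared
by volume conduction.  Each component's mixing ("inverse weight") column
is z-scored across electrodes; a component whose topography exceeds a
normalized threshold (default 2 SD) in at least one electrode is labelled
myogenic and removed before back-projection.

Two decision modes are provided.  ``per_component`` tests every component
independently against the threshold.  ``variance_prefix`` assumes the
myogenic components occupy a contiguous prefix of the explained-variance
ordering: the boundary sits after the last component (in variance order)
whose topography is focal, and everything before it is pruned.  The
default is ``per_component``, which never prunes a non-focal component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ica import TrialDecomposition

__all__ = [
    "ComponentLabel",
    "normalize_topography",
    "classify_components",
    "prune_backproject",
]

MYOGENIC = "myogenic"
NEUROGENIC = "neurogenic"


@dataclass(frozen=True)
class ComponentLabel:
    """Classification of one independent component (variance order)."""

    trial_index: int
    component_index: int
    focality: float  # max per-electrode z of the mixing column, SD units
    klass: str  # myogenic | neurogenic
    rule: str  # per_component | variance_prefix

    def to_dict(self) -> dict:
        return {
            "trial_index": self.trial_index,
            "component_index": self.component_index,
            "focality": float(self.focality),
            "klass": self.klass,
            "rule": self.rule,
        }


def normalize_topography(mixing: np.ndarray) -> np.ndarray:
    """Z-score each mixing column across electrodes (population SD).

    ICA component polarity is arbitrary, so each column is first flipped
    to make its largest-magnitude electrode positive; classification is
    then invariant to the sign as well as the scale of the column.  A
    zero-variance column (uniform topography) maps to all zeros.  The
    population-SD convention (divide by n, not n-1) is fixed so focality
    values are reproducible.
    """
    mixing = np.asarray(mixing, dtype=np.float64)
    if mixing.ndim != 2 or mixing.shape[0] < 2:
        raise ValueError("mixing must be channels x components with >= 2 channels")
    peak = mixing[np.argmax(np.abs(mixing), axis=0), np.arange(mixing.shape[1])]
    mixing = mixing * np.where(peak < 0, -1.0, 1.0)[None, :]
    mean = mixing.mean(axis=0, keepdims=True)
    sd = mixing.std(axis=0, keepdims=True)  # ddof=0
    z = np.zeros_like(mixing)
    ok = sd[0] > 0
    z[:, ok] = (mixing[:, ok] - mean[:, ok]) / sd[:, ok]
    return z


def classify_components(
    z: np.ndarray,
    threshold_sd: float = 2.0,
    mode: str = "per_component",
    trial_index: int = 0,
) -> list[ComponentLabel]:
    """Label components myogenic/neurogenic from their topography z-matrix.

    Columns must be ordered by explained variance descending.  In
    ``per_component`` mode, component i is myogenic iff
    ``max_j z[j, i] >= threshold_sd`` (inclusive at the boundary).  In
    ``variance_prefix`` mode, all components up to and including the
    last focal one (highest index in variance order) are myogenic.
    """
    if mode not in ("per_component", "variance_prefix"):
        raise ValueError(f"unknown classification mode {mode!r}")
    z = np.asarray(z, dtype=np.float64)
    maxima = z.max(axis=0) if z.size else np.zeros(z.shape[1])
    focal = maxima >= threshold_sd
    if mode == "per_component":
        myo = focal
    else:
        idx = np.flatnonzero(focal)
        myo = np.zeros(z.shape[1], dtype=bool)
        if idx.size:
            myo[: idx[-1] + 1] = True
    return [
        ComponentLabel(
            trial_index=trial_index,
            component_index=i,
            focality=float(maxima[i]),
            klass=MYOGENIC if myo[i] else NEUROGENIC,
            rule=mode,
        )
        for i in range(z.shape[1])
    ]


def prune_backproject(
    decomp: TrialDecomposition, labels: list[ComponentLabel]
) -> np.ndarray:
    """Back-project only the neurogenic components into channel space.

    Returns ``mixing[:, kept] @ sources[kept] + channel_means``, the same
    shape as the trial data.  Channel means removed before decomposition
    ride along with the neurogenic reconstruction; with every component
    pruned the result is the (near-zero for high-band data) mean rows.
    """
    if len(labels) != decomp.n_components:
        raise ValueError(
            f"{len(labels)} labels for {decomp.n_components} components"
        )
    keep = np.array([lab.klass == NEUROGENIC for lab in labels], dtype=bool)
    n_samples = decomp.sources.shape[1]
    if keep.any():
        cleaned = decomp.mixing[:, keep] @ decomp.sources[keep]
    else:
        cleaned = np.zeros((decomp.mixing.shape[0], n_samples))
    return cleaned + decomp.channel_means[:, None]
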