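"""Trial segmentation and Infomax independent component analysis.

The >16 Hz band is decomposed in consecutive 120-second trials (24,000
samples at 200 Hz), each with natural-gradient Infomax ICA: the data are
mean-centered, whitened by principal components (dimensions below a
variance floor dropped), and an unmixing rotation is learned by
stochastic natural-gradient ascent of the output entropy through a
logistic nonlinearity, with an annealing learning-rate schedule and a
weight-change convergence criterion.  An extended variant that adapts
per-component source signs (sub- vs super-Gaussian) is available but off
by default.  Runs are deterministic given the seed.

Components are ordered by explained variance: the fraction of trial
variance carried by each component's back-projection through the mixing
("inverse weight") matrix, descending.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .edf_io import EEGRecording

__all__ = [
    "TrialDecomposition",
    "segment_trials",
    "infomax_ica",
    "explained_variance",
]

_ANNEAL_DEG = 60.0  # anneal when successive weight updates differ by > 60 deg
_ANNEAL_STEP = 0.98
_BLOWUP = 1e8
_MIN_SAMPLES_FACTOR = 20  # recommended samples >= 20 * channels**2


@dataclass
class TrialDecomposition:
    """Infomax decomposition of one trial of the high-band recording.

    ``unmixing`` (components x channels) maps channel data to source
    activations; ``mixing`` is its pseudoinverse (channels x components),
    the inverse weight matrix whose columns are the component scalp
    topographies.  Components are sorted by ``explained_var`` descending.
    ``channel_means`` holds the per-channel trial means removed before
    decomposition; back-projection restores them.
    """

    trial_index: int
    span: tuple[int, int]
    channels: list[str]
    unmixing: np.ndarray
    mixing: np.ndarray
    sources: np.ndarray
    explained_var: np.ndarray
    channel_means: np.ndarray
    converged: bool
    iterations: int
    n_dropped_dims: int = 0
    seed: int = 0

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]

    def summary(self) -> dict:
        return {
            "trial_index": self.trial_index,
            "span": [int(self.span[0]), int(self.span[1])],
            "n_components": self.n_components,
            "explained_var": [float(v) for v in self.explained_var],
            "converged": bool(self.converged),
            "iterations": int(self.iterations),
            "n_dropped_dims": int(self.n_dropped_dims),
            "seed": int(self.seed),
        }


def segment_trials(
    n_samples: int | EEGRecording, fs_hz: float | None = None, trial_s: float = 120.0
) -> list[tuple[int, int]]:
    """Split a recording into consecutive half-open trial spans.

    Spans are ``round(trial_s * fs)`` samples long.  A final remainder
    shorter than half a trial is merged into the last full trial,
    otherwise it stands as its own (shorter) trial; a recording shorter
    than one trial is a single span.
    """
    if isinstance(n_samples, EEGRecording):
        fs_hz = n_samples.fs_hz
        n = n_samples.n_samples
    else:
        n = int(n_samples)
        if fs_hz is None:
            raise ValueError("fs_hz required when passing a sample count")
    if n <= 0:
        raise ValueError("empty recording")
    trial_len = int(round(trial_s * fs_hz))
    n_full = n // trial_len
    if n_full == 0:
        return [(0, n)]
    spans = [(k * trial_len, (k + 1) * trial_len) for k in range(n_full)]
    rem = n - n_full * trial_len
    if rem > 0:
        if rem < trial_len / 2:
            spans[-1] = (spans[-1][0], n)
        else:
            spans.append((n_full * trial_len, n))
    return spans


def _logistic_infomax(
    xw: np.ndarray, rng: np.random.Generator, tol: float, max_iter: int,
    extended: bool,
) -> tuple[np.ndarray, bool, int]:
    """Learn the k x k unmixing rotation on whitened data (runica schedule)."""
    k, n = xw.shape
    weights = np.eye(k)
    lrate = 0.00065 / np.log(k) if k > 1 else 0.0
    block = max(8, int(np.floor(np.sqrt(n / 3.0))))
    ident = np.eye(k)
    old_weights = weights.copy()
    old_delta = None
    signs = np.ones(k)  # +1 super-Gaussian, -1 sub-Gaussian (extended mode)
    converged = False
    it = 0
    while it < max_iter and lrate > 0:
        perm = rng.permutation(n)
        blowup = False
        if extended:
            # adapt source signs from the kurtosis of current activations
            sub = perm[: min(n, 6000)]
            acts = weights @ xw[:, sub]
            m2 = np.mean(acts**2, axis=1)
            m4 = np.mean(acts**4, axis=1)
            kurt = m4 / np.maximum(m2**2, 1e-30) - 3.0
            signs = np.where(kurt >= 0, 1.0, -1.0)
        for t in range(0, n - block + 1, block):
            u = weights @ xw[:, perm[t : t + block]]
            if extended:
                grad = (
                    block * ident
                    - (signs[:, None] * np.tanh(u)) @ u.T
                    - u @ u.T
                )
            else:
                y = 1.0 / (1.0 + np.exp(-u))
                grad = block * ident + (1.0 - 2.0 * y) @ u.T
            weights = weights + lrate * grad @ weights
            if np.max(np.abs(weights)) > _BLOWUP:
                blowup = True
                break
        it += 1
        if blowup:
            # restart colder, as runica does
            lrate *= 0.5
            weights = np.eye(k)
            old_weights = weights.copy()
            old_delta = None
            if lrate < 1e-10:
                break
            continue
        delta = (weights - old_weights).ravel()
        wchange = float(delta @ delta)
        if old_delta is not None:
            denom = np.sqrt((delta @ delta) * (old_delta @ old_delta))
            if denom > 0:
                cosang = np.clip((delta @ old_delta) / denom, -1.0, 1.0)
                if np.degrees(np.arccos(cosang)) > _ANNEAL_DEG:
                    lrate *= _ANNEAL_STEP
        old_delta = delta
        old_weights = weights.copy()
        if wchange < tol:
            converged = True
            break
    return weights, converged, it


def infomax_ica(
    trial_data: np.ndarray,
    seed: int = 0,
    *,
    tol: float = 1e-6,
    max_iter: int = 512,
    extended: bool = False,
    var_floor: float = 1e-9,
    trial_index: int = 0,
    span: tuple[int, int] | None = None,
    channels: list[str] | None = None,
) -> TrialDecomposition:
    """Decompose one trial (channels x samples) with Infomax ICA.

    The data are centered and whitened by principal components; dimensions
    whose variance falls below ``var_floor`` times the total variance are
    dropped before the rotation (excluded channels and heavy filtering can
    make the data near-singular).  Non-convergence within ``max_iter``
    iterations is reported through the ``converged`` flag with a warning,
    not an error.
    """
    x = np.asarray(trial_data, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("trial_data must be channels x samples")
    n_ch, n = x.shape
    if n < _MIN_SAMPLES_FACTOR * n_ch**2:
        warnings.warn(
            f"only {n} samples for {n_ch} channels "
            f"(recommended >= {_MIN_SAMPLES_FACTOR * n_ch**2}); "
            "decomposition may be unstable",
            RuntimeWarning,
            stacklevel=2,
        )
    means = x.mean(axis=1)
    xc = x - means[:, None]

    cov = (xc @ xc.T) / n
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    total = float(evals.sum())
    if total <= 0.0:
        raise ValueError("trial has zero variance")
    keep = evals > var_floor * total
    if not keep.any():
        raise ValueError("no principal component above the variance floor")
    n_dropped = int((~keep).size - keep.sum())
    ev = evals[keep][::-1]
    ee = evecs[:, keep][:, ::-1]
    white = (ee / np.sqrt(ev)).T  # k x channels
    xw = white @ xc  # unit-covariance data

    k = xw.shape[0]
    rng = np.random.default_rng(seed)
    if k == 1:
        rot, converged, iters = np.eye(1), True, 0
    else:
        rot, converged, iters = _logistic_infomax(xw, rng, tol, max_iter, extended)
        if not converged:
            warnings.warn(
                f"Infomax did not converge in {iters} iterations "
                f"(trial {trial_index}); proceeding with the final weights",
                RuntimeWarning,
                stacklevel=2,
            )

    unmixing = rot @ white  # k x channels
    mixing = np.linalg.pinv(unmixing)  # channels x k
    sources = unmixing @ xc

    frac = _explained_fractions(mixing, sources, xc)
    order = np.argsort(frac)[::-1]
    decomp = TrialDecomposition(
        trial_index=trial_index,
        span=span if span is not None else (0, n),
        channels=list(channels) if channels is not None else [f"ch{i}" for i in range(n_ch)],
        unmixing=unmixing[order],
        mixing=mixing[:, order],
        sources=sources[order],
        explained_var=frac[order],
        channel_means=means,
        converged=converged,
        iterations=iters,
        n_dropped_dims=n_dropped,
        seed=seed,
    )
    return decomp


def _explained_fractions(
    mixing: np.ndarray, sources: np.ndarray, centered: np.ndarray
) -> np.ndarray:
    """Variance fraction of each component's back-projection.

    For component i the back-projection is the rank-1 matrix
    ``outer(mixing[:, i], sources[i])``; its summed channel variance is
    ``||mixing[:, i]||^2 * var(sources[i])``.
    """
    total = centered.var(axis=1).sum()
    if total <= 0:
        return np.zeros(mixing.shape[1])
    col_norm2 = np.sum(mixing**2, axis=0)
    src_var = sources.var(axis=1)
    return col_norm2 * src_var / total


def explained_variance(
    decomp: TrialDecomposition, trial_data: np.ndarray
) -> np.ndarray:
    """Recompute per-component explained-variance fractions on `trial_data`."""
    x = np.asarray(trial_data, dtype=np.float64)
    xc = x - x.mean(axis=1, keepdims=True)
    return _explained_fractions(decomp.mixing, decomp.sources, xc)
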