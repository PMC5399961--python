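"""FIR filtering, complementary band-splitting, envelopes and smoothing.

All filters are even-order linear-phase windowed-sinc (Hamming) designs,
the convention of MATLAB's ``fir1``.  Filtering is applied in a single
forward pass and then advanced by the group delay (order/2 samples) so
the output is time-aligned with the input; edges are padded by signal
reflection.  Time alignment matters because the cleaned high band is
later added back to the low band sample by sample.

The band split at 16 Hz is complementary by construction: the high band
is defined as the input minus the zero-phase low-pass output, so
``low + high == input`` holds exactly for any signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .edf_io import EEGRecording

__all__ = [
    "FIRFilter",
    "design_fir",
    "apply_zero_phase",
    "split_complementary",
    "hilbert_envelope",
    "moving_average",
]


@dataclass(frozen=True)
class FIRFilter:
    """A linear-phase FIR filter: symmetric taps of length ``order + 1``."""

    taps: np.ndarray
    kind: str  # lowpass | highpass | bandpass
    cutoffs_hz: tuple[float, ...]
    order: int
    fs_hz: float


def design_fir(
    kind: str,
    cutoffs_hz: float | tuple[float, ...],
    order: int = 500,
    fs_hz: float = 200.0,
) -> FIRFilter:
    """Design an even-order Hamming-windowed sinc FIR filter.

    Parameters
    ----------
    kind
        ``"lowpass"``, ``"highpass"`` or ``"bandpass"``.
    cutoffs_hz
        One corner frequency for low/highpass, two for bandpass.
    order
        Filter order (tap count minus one); must be even so the design is
        symmetric with integer group delay.
    fs_hz
        Sampling rate the filter is designed for.
    """
    if order % 2 != 0 or order < 2:
        raise ValueError(f"order must be even and >= 2, got {order}")
    cut = (cutoffs_hz,) if np.isscalar(cutoffs_hz) else tuple(cutoffs_hz)
    nyq = fs_hz / 2.0
    if any(not 0.0 < c < nyq for c in cut):
        raise ValueError(f"cutoffs {cut} must lie strictly inside (0, {nyq}) Hz")
    expected = {"lowpass": 1, "highpass": 1, "bandpass": 2}
    if kind not in expected:
        raise ValueError(f"unknown filter kind {kind!r}")
    if len(cut) != expected[kind]:
        raise ValueError(f"{kind} needs {expected[kind]} cutoff(s), got {len(cut)}")
    pass_zero = kind == "lowpass"
    taps = scipy.signal.firwin(
        order + 1, cut, pass_zero=pass_zero, window="hamming", fs=fs_hz
    )
    return FIRFilter(taps=taps, kind=kind, cutoffs_hz=cut, order=order, fs_hz=fs_hz)


def _filter_matrix(data: np.ndarray, filt: FIRFilter) -> np.ndarray:
    """Zero-phase filter each row: reflect-pad, convolve, undo group delay."""
    n = data.shape[-1]
    if n <= filt.order:
        raise ValueError(
            f"signal length {n} must exceed the filter order {filt.order}; "
            "use a shorter filter"
        )
    pad = filt.order
    padded = np.pad(data, [(0, 0)] * (data.ndim - 1) + [(pad, pad)], mode="reflect")
    full = scipy.signal.fftconvolve(padded, filt.taps[None, :], mode="full", axes=-1)
    start = pad + filt.order // 2
    return np.ascontiguousarray(full[..., start : start + n])


def apply_zero_phase(rec: EEGRecording, filt: FIRFilter) -> EEGRecording:
    """Filter every channel with group-delay compensation (output aligned)."""
    if abs(filt.fs_hz - rec.fs_hz) > 1e-9:
        raise ValueError(
            f"filter designed for {filt.fs_hz} Hz but recording is {rec.fs_hz} Hz"
        )
    out = rec.copy_with(data_uv=_filter_matrix(rec.data_uv, filt))
    out.meta.setdefault("processing", []).append(
        f"fir_{filt.kind}_{'-'.join(f'{c:g}' for c in filt.cutoffs_hz)}Hz_order{filt.order}"
    )
    return out


def split_complementary(
    rec: EEGRecording, cutoff_hz: float = 16.0, order: int = 500
) -> tuple[EEGRecording, EEGRecording]:
    """Split a recording into complementary low and high bands at `cutoff_hz`.

    ``low`` is the zero-phase low-pass output; ``high = rec - low``, so
    the two bands add back to the input exactly.  The deviation from two
    independently designed filters is confined to the transition band and
    is recorded in both bands' meta.
    """
    filt = design_fir("lowpass", cutoff_hz, order=order, fs_hz=rec.fs_hz)
    low = apply_zero_phase(rec, filt)
    high = rec.copy_with(data_uv=rec.data_uv - low.data_uv)
    high.meta.setdefault("processing", []).append(
        f"complement_highpass_{cutoff_hz:g}Hz_order{order}"
    )
    return low, high


def hilbert_envelope(x: np.ndarray) -> np.ndarray:
    """Instantaneous amplitude: modulus of the analytic signal."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size < 4:
        raise ValueError("hilbert_envelope expects a 1-D series of length >= 4")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    return np.abs(scipy.signal.hilbert(x))


def moving_average(x: np.ndarray, window_samples: int) -> np.ndarray:
    """Centered moving average; edges use shrinking windows (length kept)."""
    x = np.asarray(x, dtype=np.float64)
    w = int(window_samples)
    if w % 2 != 1:
        raise ValueError(f"window must be odd, got {w}")
    if w > x.size:
        raise ValueError(f"window {w} exceeds series length {x.size}")
    if w == 1:
        return x.copy()
    kernel = np.ones(w)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den
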