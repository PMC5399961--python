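"""Reading and writing scalp EEG as 16-bit EDF / EDF+ files.

EDF stores each signal as 16-bit integers with a per-signal linear map
between the digital range (typically -32768..32767) and a physical range
declared in the header.  The reader returns data in microvolts regardless
of the stored physical dimension (volt multiples are converted, anything
else is rejected, because every downstream amplitude threshold in the
pipeline is calibrated in microvolts).  The writer picks a symmetric
physical range padded at least 1% beyond the observed amplitude extremes,
so a write/read round trip is exact to within one digital quantization
step of that range.

Annotation signals ("EDF Annotations") are dropped on read; on export a
single provenance string is carried in the 80-character recording-id
header field, which clinical viewers display verbatim.
"""

from __future__ import annotations

import datetime as _dt
import math
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["EEGRecording", "read_edf", "write_edf", "select_channels", "EDFError"]

# symmetric digital range: zero microvolts encodes exactly as digital zero
_DIG_MIN = -32767
_DIG_MAX = 32767

#: accepted physical-dimension strings and their scale to microvolts
_UNIT_TO_UV = {
    "uv": 1.0,
    "µv": 1.0,  # micro sign
    "μv": 1.0,  # greek mu
    "mv": 1.0e3,
    "v": 1.0e6,
    "": 1.0,  # unlabeled channels assumed to be microvolts already
}


class EDFError(IOError):
    """Raised for malformed, unreadable or unsupported EDF content."""


@dataclass
class EEGRecording:
    """A multichannel referential scalp EEG held in memory.

    Attributes
    ----------
    labels
        Ordered, unique channel names.  The 10-20 convention plus the
        anterotemporal T1/T2 electrodes is typical but any names are
        accepted.
    fs_hz
        Sampling rate in samples per second, shared by all channels.
    data_uv
        ``(n_channels, n_samples)`` float array in microvolts.
    start_time
        Wall-clock start of the recording, or ``None`` when unknown.
    reference
        Free-text montage description; referential montages are expected.
    meta
        Free-form provenance records (processing steps applied, warnings).
    """

    labels: list[str]
    fs_hz: float
    data_uv: np.ndarray
    start_time: _dt.datetime | None = None
    reference: str = "referential"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data_uv = np.asarray(self.data_uv, dtype=np.float64)
        if self.data_uv.ndim != 2:
            raise ValueError("data_uv must be a 2-D (channels x samples) array")
        if len(self.labels) != self.data_uv.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data_uv.shape[0]} data rows"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if not self.fs_hz > 0:
            raise ValueError("fs_hz must be positive")
        if not np.all(np.isfinite(self.data_uv)):
            raise ValueError("data_uv contains NaN or Inf")

    @property
    def n_channels(self) -> int:
        return self.data_uv.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data_uv.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def copy_with(self, **kwargs) -> "EEGRecording":
        """Return a copy with selected fields replaced (meta is deep-ish copied)."""
        out = dict(
            labels=list(self.labels),
            fs_hz=self.fs_hz,
            data_uv=self.data_uv.copy(),
            start_time=self.start_time,
            reference=self.reference,
            meta=dict(self.meta),
        )
        out.update(kwargs)
        return EEGRecording(**out)


def _pad_ascii(value: str, width: int) -> bytes:
    raw = value.encode("ascii", "replace")[:width]
    return raw.ljust(width, b" ")


def _fmt_float8(value: float) -> str:
    """Format a float into at most 8 ASCII characters, preserving parse-back."""
    for prec in (6, 5, 4, 3, 2, 1):
        s = f"{value:.{prec}g}"
        if len(s) <= 8 and float(s) != 0 or value == 0:
            if len(s) <= 8:
                return s
    raise EDFError(f"cannot encode {value!r} in an 8-character EDF field")


def _round_sig_up(value: float, sig: int = 5) -> float:
    """Round a positive float up to `sig` significant digits."""
    if value <= 0:
        raise ValueError("value must be positive")
    exp = math.floor(math.log10(value))
    quantum = 10.0 ** (exp - sig + 1)
    return math.ceil(value / quantum) * quantum


def write_edf(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording to `path` as a plain 16-bit EDF file.

    The per-channel physical range is symmetric about zero and padded at
    least 1% beyond the largest observed amplitude, so quantization error
    is bounded by (physical range) / 65535.  A channel with zero amplitude
    range is written with a default +/-1 uV range and a warning recorded in
    ``rec.meta['warnings']``.
    """
    path = Path(path)
    n_sig = rec.n_channels
    n = rec.n_samples
    fs = rec.fs_hz

    # Pick the data-record layout: 1-second records when the sample count
    # divides evenly, otherwise a single record spanning the whole file.
    if abs(fs - round(fs)) < 1e-9 and n % int(round(fs)) == 0 and n > 0:
        spr = int(round(fs))
        n_records = n // spr
        record_dur = 1.0
    else:
        spr = n
        n_records = 1
        record_dur = n / fs

    phys_max = np.empty(n_sig)
    for i in range(n_sig):
        amax = float(np.max(np.abs(rec.data_uv[i]))) if n else 0.0
        if amax == 0.0:
            rec.meta.setdefault("warnings", []).append(
                f"channel {rec.labels[i]}: zero amplitude range, wrote default +/-1 uV"
            )
            phys_max[i] = 1.0
        else:
            # pad >=1% then round up to 5 significant digits so the header
            # string parses back to the exact range used for quantization
            phys_max[i] = _round_sig_up(amax * 1.01, 5)

    start = rec.start_time or _dt.datetime(2000, 1, 1)
    recording_id = str(rec.meta.get("provenance", "ar2eeg export"))

    header = bytearray()
    header += _pad_ascii("0", 8)
    header += _pad_ascii(str(rec.meta.get("patient_id", "X X X X")), 80)
    header += _pad_ascii(recording_id, 80)
    header += _pad_ascii(start.strftime("%d.%m.%y"), 8)
    header += _pad_ascii(start.strftime("%H.%M.%S"), 8)
    header += _pad_ascii(str(256 * (1 + n_sig)), 8)
    header += _pad_ascii("", 44)
    header += _pad_ascii(str(n_records), 8)
    header += _pad_ascii(_fmt_float8(record_dur), 8)
    header += _pad_ascii(str(n_sig), 4)

    def sig_field(values, width):
        return b"".join(_pad_ascii(v, width) for v in values)

    header += sig_field(rec.labels, 16)
    header += sig_field(["AgAgCl electrode"] * n_sig, 80)
    header += sig_field(["uV"] * n_sig, 8)
    header += sig_field([_fmt_float8(-pm) for pm in phys_max], 8)
    header += sig_field([_fmt_float8(pm) for pm in phys_max], 8)
    header += sig_field([str(_DIG_MIN)] * n_sig, 8)
    header += sig_field([str(_DIG_MAX)] * n_sig, 8)
    header += sig_field([""] * n_sig, 80)
    header += sig_field([str(spr)] * n_sig, 8)
    header += sig_field([""] * n_sig, 32)

    # physical -> digital, parse the header strings back so both directions
    # use bit-identical range endpoints
    pmaxs = np.array([float(_fmt_float8(pm)) for pm in phys_max])
    scale = (_DIG_MAX - _DIG_MIN) / (2.0 * pmaxs)
    digital = np.rint((rec.data_uv + pmaxs[:, None]) * scale[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_records):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())  # signal-major within each record


def _read_field(buf: bytes, offset: int, width: int) -> str:
    return buf[offset : offset + width].decode("ascii", "replace").strip()


def read_edf(path: str | Path) -> EEGRecording:
    """Read an EDF/EDF+ file into an :class:`EEGRecording` in microvolts.

    Annotation signals are dropped.  All remaining signals must share one
    sampling rate; otherwise the offending channels are named in the error.
    """
    path = Path(path)
    try:
        raw = path.read_bytes()
    except OSError as exc:
        raise EDFError(f"cannot read EDF file {path}: {exc}") from exc
    if len(raw) < 256:
        raise EDFError(f"{path}: truncated EDF header")

    n_records = int(_read_field(raw, 236, 8))
    record_dur = float(_read_field(raw, 244, 8))
    n_sig = int(_read_field(raw, 252, 4))
    if n_sig <= 0:
        raise EDFError(f"{path}: no signals in header")
    if len(raw) < 256 * (1 + n_sig):
        raise EDFError(f"{path}: truncated signal headers")

    # walk the signal-header block field by field, per the EDF layout
    off = 256
    lab = [_read_field(raw, off + i * 16, 16) for i in range(n_sig)]
    off += n_sig * 16 + n_sig * 80
    dims = [_read_field(raw, off + i * 8, 8) for i in range(n_sig)]
    off += n_sig * 8
    pmins = [float(_read_field(raw, off + i * 8, 8)) for i in range(n_sig)]
    off += n_sig * 8
    pmaxs = [float(_read_field(raw, off + i * 8, 8)) for i in range(n_sig)]
    off += n_sig * 8
    dmins = [int(float(_read_field(raw, off + i * 8, 8))) for i in range(n_sig)]
    off += n_sig * 8
    dmaxs = [int(float(_read_field(raw, off + i * 8, 8))) for i in range(n_sig)]
    off += n_sig * 8 + n_sig * 80
    sprs = [int(_read_field(raw, off + i * 8, 8)) for i in range(n_sig)]

    labels, phys_dims = lab, dims

    keep = [i for i, l in enumerate(labels) if l.lower() != "edf annotations"]
    if not keep:
        raise EDFError(f"{path}: only annotation channels present")
    if n_records <= 0 or all(sprs[i] == 0 for i in keep):
        raise EDFError(f"{path}: zero-length record")

    if record_dur <= 0:
        raise EDFError(f"{path}: non-positive record duration")
    rates = {labels[i]: sprs[i] / record_dur for i in keep}
    if len(set(rates.values())) > 1:
        detail = ", ".join(f"{k}={v:g} Hz" for k, v in rates.items())
        raise EDFError(f"{path}: channels with differing sampling rates: {detail}")
    fs = next(iter(rates.values()))

    unit_scale = np.empty(n_sig)
    for i in keep:
        key = phys_dims[i].lower()
        if key not in _UNIT_TO_UV:
            raise EDFError(
                f"{path}: channel {labels[i]} has physical dimension "
                f"{phys_dims[i]!r}, not a volt multiple"
            )
        unit_scale[i] = _UNIT_TO_UV[key]

    data_start = 256 * (1 + n_sig)
    rec_samples = sum(sprs)
    expected = data_start + n_records * rec_samples * 2
    if len(raw) < expected:
        raise EDFError(f"{path}: data section truncated "
                       f"({len(raw)} bytes, expected {expected})")

    flat = np.frombuffer(raw, dtype="<i2", count=n_records * rec_samples,
                         offset=data_start)
    flat = flat.reshape(n_records, rec_samples)
    bounds = np.cumsum([0] + sprs)

    channels = []
    for i in keep:
        dig = flat[:, bounds[i] : bounds[i + 1]].reshape(-1).astype(np.float64)
        gain = (pmaxs[i] - pmins[i]) / (dmaxs[i] - dmins[i])
        channels.append((dig - dmins[i]) * gain + pmins[i])
        channels[-1] *= unit_scale[i]
    data = np.vstack(channels)
    if not np.all(np.isfinite(data)):
        raise EDFError(f"{path}: non-finite samples after scaling")

    try:
        start = _dt.datetime.strptime(
            _read_field(raw, 168, 8) + " " + _read_field(raw, 176, 8),
            "%d.%m.%y %H.%M.%S",
        )
    except ValueError:
        start = None

    return EEGRecording(
        labels=[labels[i] for i in keep],
        fs_hz=fs,
        data_uv=data,
        start_time=start,
        reference="referential",
        meta={"source_file": str(path), "recording_id": _read_field(raw, 88, 80)},
    )


def select_channels(rec: EEGRecording, wanted: list[str]) -> EEGRecording:
    """Return a sub-recording with channels in the requested order."""
    unknown = [w for w in wanted if w not in rec.labels]
    if unknown:
        raise KeyError(f"unknown channel labels: {unknown}")
    idx = [rec.labels.index(w) for w in wanted]
    return rec.copy_with(labels=list(wanted), data_uv=rec.data_uv[idx].copy())
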