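"""Seeded synthetic ictal scalp-EEG scenes with known ground truth.

A scene is an additive mixture of four parts, each returned separately so
cleaning can be scored exactly:

* **neurogenic** — a narrowband (default 20-30 Hz) ictal rhythm that ramps
  up from a configurable onset time, with a spatially smooth topography
  peaking at the onset channel (volume conduction smears brain sources
  across neighbouring electrodes, so the topography decays gently with
  inter-electrode distance on a 2-D 10-20 layout);
* **EMG** — bursts of band-limited (default 20-95 Hz) noise confined to
  one or two electrodes over a muscle group.  Each burst drives a common
  source seen by both active electrodes (weights 1.0 / 0.7) plus smaller
  independent per-electrode noise, so EMG-active channels stay mutually
  informative while remaining spatially focal;
* **background** — a small set of spatially smooth 1/f sources plus
  independent per-channel sensor noise.  Spatially shared background is
  what makes mutual-information channel screening meaningful: real
  electrodes share volume-conducted signal, a dead one does not;
* **bad channels** — electrodes replaced wholesale by independent white
  noise, emulating high-impedance contacts.

Scenes are bitwise deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .edf_io import EEGRecording
from .filters import split_complementary

__all__ = [
    "TEN_TWENTY_LAYOUT",
    "SceneConfig",
    "GroundTruth",
    "simulate_scene",
    "score_cleaning",
]

#: Approximate 2-D positions of 10-20 electrodes (plus T1/T2) on a unit head.
TEN_TWENTY_LAYOUT: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.40, 0.48), "Fz": (0.0, 0.50),
    "F4": (0.40, 0.48), "F8": (0.81, 0.59),
    "T1": (-0.95, 0.31), "T2": (0.95, 0.31),
    "T3": (-1.00, 0.00), "C3": (-0.50, 0.00), "Cz": (0.0, 0.0),
    "C4": (0.50, 0.00), "T4": (1.00, 0.00),
    "T5": (-0.81, -0.59), "P3": (-0.40, -0.48), "Pz": (0.0, -0.50),
    "P4": (0.40, -0.48), "T6": (0.81, -0.59),
    "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
}

_DEFAULT_LABELS = [
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz",
]


@dataclass
class SceneConfig:
    """Parameters of one synthetic scene (defaults define the demo scene)."""

    labels: list[str] = field(default_factory=lambda: list(_DEFAULT_LABELS))
    fs_hz: float = 200.0
    duration_s: float = 300.0
    # ictal rhythm
    onset_s: float = 120.0
    onset_channel: str = "F3"
    rhythm_band_hz: tuple[float, float] = (20.0, 30.0)
    ictal_amplitude_uv: float = 30.0
    spatial_spread: float = 0.9  # Gaussian sigma on the unit-head layout
    ramp_s: float = 20.0
    # EMG bursts; None -> a default alternating left/right temporalis pattern
    emg_bursts: list[tuple[float, float, tuple[str, ...]]] | None = None
    emg_band_hz: tuple[float, float] = (20.0, 95.0)
    emg_amplitude_uv: float = 60.0
    emg_secondary_weight: float = 0.7
    emg_independent_fraction: float = 0.4
    # background
    background_amplitude_uv: float = 10.0
    n_background_sources: int = 8
    sensor_noise_uv: float = 2.0
    # bad channels
    bad_channels: tuple[str, ...] = ()
    bad_channel_amplitude_uv: float = 30.0
    seed: int = 0

    def resolved_bursts(self) -> list[tuple[float, float, tuple[str, ...]]]:
        """Default burst schedule: 5-s bursts every 15 s, alternating sides."""
        if self.emg_bursts is not None:
            return list(self.emg_bursts)
        groups = [("F7", "T3"), ("F8", "T4")]
        groups = [tuple(g for g in grp if g in self.labels) for grp in groups]
        groups = [g for g in groups if g]
        if not groups:
            return []
        bursts = []
        t = 10.0
        k = 0
        while t + 5.0 <= self.duration_s - 5.0:
            bursts.append((t, 5.0, groups[k % len(groups)]))
            t += 15.0
            k += 1
        return bursts


@dataclass
class GroundTruth:
    """Exact additive decomposition of a scene, for scoring cleaning."""

    neurogenic_uv: np.ndarray
    emg_uv: np.ndarray
    background_uv: np.ndarray
    badnoise_uv: np.ndarray
    topographies: dict[str, np.ndarray]
    onset_sample: int
    onset_channel: str
    emg_channels: list[str]
    fs_hz: float


def _coords(labels: list[str]) -> np.ndarray:
    missing = [l for l in labels if l not in TEN_TWENTY_LAYOUT]
    if missing:
        raise ValueError(f"no layout coordinates for channels: {missing}")
    return np.array([TEN_TWENTY_LAYOUT[l] for l in labels])


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                band: tuple[float, float]) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to `band` (brick-wall in FFT)."""
    lo, hi = band
    if not 0 < lo < hi:
        raise ValueError(f"invalid band {band}")
    if hi >= fs / 2:
        raise ValueError(f"band edge {hi} Hz is at/above Nyquist ({fs / 2} Hz)")
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < lo) | (freqs > hi)] = 0.0
    x = np.fft.irfft(spec, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _pink_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-RMS 1/f-amplitude-weighted noise (flat below 1 Hz)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    weight = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    weight[0] = 0.0
    x = np.fft.irfft(spec * weight, n=n)
    return x / np.sqrt(np.mean(x**2))


def _gauss_topo(coords: np.ndarray, center: np.ndarray, sigma: float) -> np.ndarray:
    d2 = np.sum((coords - center[None, :]) ** 2, axis=1)
    return np.exp(-d2 / (2.0 * sigma**2))


def simulate_scene(config: SceneConfig) -> tuple[EEGRecording, GroundTruth]:
    """Generate one scene and its exact ground-truth decomposition."""
    labels = list(config.labels)
    coords = _coords(labels)
    fs = config.fs_hz
    n = int(round(config.duration_s * fs))
    n_ch = len(labels)
    if not 0 <= config.onset_s < config.duration_s:
        raise ValueError("onset must lie within the scene duration")
    if config.rhythm_band_hz[1] >= fs / 2 or config.emg_band_hz[1] >= fs / 2:
        raise ValueError("band edge at or above Nyquist")
    rng = np.random.default_rng(config.seed)
    t = np.arange(n) / fs

    # --- ictal rhythm: ramped narrowband source, smooth topography -------
    onset_sample = int(round(config.onset_s * fs))
    carrier = _band_noise(rng, n, fs, config.rhythm_band_hz)
    env = np.zeros(n)
    ramp_n = max(1, int(round(config.ramp_s * fs)))
    post = n - onset_sample
    ramp = np.minimum(np.arange(post) / ramp_n, 1.0)
    env[onset_sample:] = ramp
    topo_ictal = _gauss_topo(coords, _coords([config.onset_channel])[0],
                             config.spatial_spread)
    neurogenic = topo_ictal[:, None] * (config.ictal_amplitude_uv * env * carrier)

    # --- EMG bursts -------------------------------------------------------
    emg = np.zeros((n_ch, n))
    emg_channels: list[str] = []
    emg_topos = []
    for start_s, dur_s, electrodes in config.resolved_bursts():
        s = int(round(start_s * fs))
        e = min(n, s + int(round(dur_s * fs)))
        if e - s < 4:
            continue
        burst_env = np.zeros(n)
        burst_env[s:e] = np.hanning(e - s)
        weights = np.zeros(n_ch)
        for k, el in enumerate(electrodes[:2]):
            idx = labels.index(el)
            weights[idx] = 1.0 if k == 0 else config.emg_secondary_weight
            if el not in emg_channels:
                emg_channels.append(el)
        common = _band_noise(rng, n, fs, config.emg_band_hz)
        emg += weights[:, None] * (config.emg_amplitude_uv * burst_env * common)
        for el in electrodes[:2]:
            idx = labels.index(el)
            indep = _band_noise(rng, n, fs, config.emg_band_hz)
            emg[idx] += (config.emg_independent_fraction
                         * config.emg_amplitude_uv * burst_env * indep)
        emg_topos.append(weights)

    # --- spatially shared 1/f background + sensor noise ------------------
    background = np.zeros((n_ch, n))
    bg_topos = []
    for _ in range(config.n_background_sources):
        center = coords[rng.integers(n_ch)] + rng.normal(0, 0.15, size=2)
        topo = _gauss_topo(coords, center, 0.6)
        background += topo[:, None] * _pink_noise(rng, n, fs)
        bg_topos.append(topo)
    if config.n_background_sources and config.background_amplitude_uv > 0:
        rms = np.sqrt(np.mean(background**2))
        if rms > 0:
            background *= config.background_amplitude_uv / rms
    if config.sensor_noise_uv > 0:
        background += config.sensor_noise_uv * rng.standard_normal((n_ch, n))

    # --- bad channels: independent white noise replaces everything -------
    badnoise = np.zeros((n_ch, n))
    for el in config.bad_channels:
        idx = labels.index(el)
        neurogenic[idx] = 0.0
        emg[idx] = 0.0
        background[idx] = 0.0
        badnoise[idx] = config.bad_channel_amplitude_uv * rng.standard_normal(n)

    data = neurogenic + emg + background + badnoise
    rec = EEGRecording(
        labels=labels,
        fs_hz=fs,
        data_uv=data,
        reference="referential",
        meta={"provenance": f"ar2eeg synthetic scene seed={config.seed}"},
    )
    truth = GroundTruth(
        neurogenic_uv=neurogenic,
        emg_uv=emg,
        background_uv=background,
        badnoise_uv=badnoise,
        topographies={
            "ictal": topo_ictal,
            "emg": np.array(emg_topos) if emg_topos else np.zeros((0, n_ch)),
            "background": np.array(bg_topos) if bg_topos else np.zeros((0, n_ch)),
        },
        onset_sample=onset_sample,
        onset_channel=config.onset_channel,
        emg_channels=emg_channels,
        fs_hz=fs,
    )
    return rec, truth


def score_cleaning(cleaned: EEGRecording, truth: GroundTruth,
                   suppression_cap_db: float = 60.0) -> dict:
    """Score a cleaned recording against the scene's ground truth.

    Per channel: *neurogenic retention* is the Pearson correlation between
    the cleaned signal and the neurogenic truth over the ictal interval;
    *EMG suppression* is ``10 log10`` of the ratio of >16 Hz artifact
    power before vs after cleaning (artifact = signal minus neurogenic
    truth), capped at `suppression_cap_db`.

    The raw ratio is floored by non-EMG artifact (shared background and
    sensor noise) that a cleaner correctly retains, so the *EMG-excess*
    suppression is also reported: the same ratio computed on the >16 Hz
    power in excess of the background + bad-channel truth, which isolates
    how much of the EMG itself was removed.
    """
    neuro = truth.neurogenic_uv
    if cleaned.data_uv.shape != neuro.shape:
        raise ValueError("cleaned recording and truth shapes differ")
    n_ch = neuro.shape[0]
    onset = truth.onset_sample
    scene = truth.neurogenic_uv + truth.emg_uv + truth.background_uv + truth.badnoise_uv

    retention = np.zeros(n_ch)
    for i in range(n_ch):
        a = cleaned.data_uv[i, onset:]
        b = neuro[i, onset:]
        if a.std() == 0 or b.std() == 0:
            retention[i] = 0.0
        else:
            retention[i] = float(np.corrcoef(a, b)[0, 1])

    def high_power(matrix: np.ndarray) -> np.ndarray:
        wrapper = EEGRecording(labels=cleaned.labels, fs_hz=truth.fs_hz,
                               data_uv=matrix)
        _, high = split_complementary(wrapper, 16.0, 500)
        return high.data_uv.var(axis=1)

    before = high_power(scene - neuro)
    after = high_power(cleaned.data_uv - neuro)

    def ratio_db(num: np.ndarray, den: np.ndarray) -> np.ndarray:
        floor = num * 10.0 ** (-suppression_cap_db / 10.0)
        return 10.0 * np.log10(
            np.maximum(num, 1e-300) / np.maximum(den, np.maximum(floor, 1e-300))
        )

    supp = ratio_db(before, after)

    bg_floor = high_power(truth.background_uv + truth.badnoise_uv)
    excess_before = np.maximum(before - bg_floor, 0.0)
    excess_after = np.maximum(after - bg_floor, 0.0)
    excess_supp = ratio_db(excess_before, excess_after)

    emg_idx = [cleaned.labels.index(l) for l in truth.emg_channels]
    onset_idx = cleaned.labels.index(truth.onset_channel)
    return {
        "retention": retention,
        "suppression_db": supp,
        "emg_excess_suppression_db": excess_supp,
        "retention_onset_channel": float(retention[onset_idx]),
        "suppression_emg_channels_db": supp[emg_idx] if emg_idx else np.array([]),
        "min_suppression_emg_db": float(supp[emg_idx].min()) if emg_idx else float("nan"),
        "min_emg_excess_suppression_db": float(excess_supp[emg_idx].min())
        if emg_idx else float("nan"),
        "mean_retention": float(retention.mean()),
    }
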