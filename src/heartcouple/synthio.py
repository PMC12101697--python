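"""Synthetic multi-site heart-sound / ECG generation and file I/O.

The generator emulates simultaneous four-site phonocardiograms plus one
ECG lead on a shared time axis. Each cardiac cycle contains Gaussian-
windowed S1 and S2 tone bursts with site-specific amplitudes (S1 loudest
at the apex sites T/M, S2 at the base sites A/P) and small site-specific
latencies from acoustic propagation. Abnormal recordings add a
band-limited systolic murmur of which a configurable fraction is a single
component shared by all PCG channels — the shared component raises
inter-channel phase locking, correlation and coherence and lowers
cross-entropy, reproducing the direction of the class differences seen in
real normal vs pathological multi-site recordings. The ECG channel is a
periodic PQRST sum-of-Gaussians template plus a slow drift (0.3 Hz
sinusoid + linear ramp) so that wavelet detrending is exercised.

I/O helpers read and write per-channel WAV files, columnar CSV recordings
and cohort-level feature tables.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.io import wavfile

from .coupling import feature_sort_key
from .records import PCG_SITES, SITE_ORDER, MultiChannelRecording
from .selection import FeatureMatrix

# Site-specific (S1, S2) burst amplitudes: S1 dominates at tricuspid/mitral
# (apex), S2 at aortic/pulmonary (base).
_S1S2_AMP = {"A": (0.7, 1.0), "P": (0.6, 0.9), "T": (1.0, 0.6), "M": (1.1, 0.5)}
# Acoustic propagation latencies per site, seconds.
_LATENCY = {"A": 0.0, "P": 0.002, "T": 0.004, "M": 0.006}


@dataclass
class SimParams:
    """Simulation parameters; defaults give a plausible resting adult.

    ``shared_murmur_fraction`` is the fraction of abnormal murmur energy
    common to all PCG channels (the coupling dial of the abnormal class);
    the remainder is channel-independent band-limited noise.
    """

    fs: float = 4000.0
    duration: float = 5.0
    heart_rate: float = 75.0
    s1_freq: float = 60.0
    s2_freq: float = 90.0
    burst_width: float = 0.05
    murmur_band: tuple[float, float] = (100.0, 400.0)
    murmur_gain: float = 0.5
    shared_murmur_fraction: float = 0.8
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not 0 <= self.shared_murmur_fraction <= 1:
            raise ValueError("shared_murmur_fraction must be in [0, 1]")
        if self.duration * self.heart_rate / 60.0 < 1:
            raise ValueError("duration must cover at least one full cardiac cycle")
        if not 0 < self.murmur_band[0] < self.murmur_band[1] < self.fs / 2:
            raise ValueError(f"murmur band {self.murmur_band} invalid for fs={self.fs}")


def _bursts(t: np.ndarray, centers: np.ndarray, freq: float, width: float) -> np.ndarray:
    sigma = width / 4.0
    out = np.zeros_like(t)
    for tc in centers:
        out += np.exp(-0.5 * ((t - tc) / sigma) ** 2) * np.sin(2 * np.pi * freq * (t - tc))
    return out


def _pqrst(t: np.ndarray, r_times: np.ndarray) -> np.ndarray:
    # (amplitude, offset from R in s, Gaussian width in s)
    waves = [
        (0.15, -0.20, 0.025),  # P
        (-0.10, -0.03, 0.010),  # Q
        (1.00, 0.00, 0.012),  # R
        (-0.15, 0.025, 0.010),  # S
        (0.30, 0.25, 0.035),  # T
    ]
    out = np.zeros_like(t)
    for tr in r_times:
        for amp, off, width in waves:
            out += amp * np.exp(-0.5 * ((t - tr - off) / width) ** 2)
    return out


def _bandlimited_noise(rng: np.random.Generator, n: int, band, fs: float) -> np.ndarray:
    white = rng.standard_normal(n)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)
    return x / x.std()


def generate_recording(params: SimParams, label: str) -> MultiChannelRecording:
    """Generate one five-channel recording (A, P, T, M PCG + E ECG).

    Deterministic for a fixed seed: all random components are drawn in a
    fixed order regardless of label, so a normal and an abnormal recording
    built from identical parameters differ exactly by the gated murmur.
    """
    if label not in ("normal", "abnormal"):
        raise ValueError("label must be 'normal' or 'abnormal'")
    rng = np.random.default_rng(params.seed)
    n = int(round(params.fs * params.duration))
    t = np.arange(n) / params.fs
    period = 60.0 / params.heart_rate
    cycle_starts = np.arange(0.1, params.duration, period)
    s2_offset = 0.35 * period  # end of systole

    # Random components, always drawn (label-independent stream order).
    shared_murmur = _bandlimited_noise(rng, n, params.murmur_band, params.fs)
    indep_murmur = {s: _bandlimited_noise(rng, n, params.murmur_band, params.fs) for s in PCG_SITES}
    white = {s: rng.standard_normal(n) for s in PCG_SITES}
    ecg_white = rng.standard_normal(n)

    # Systolic gate: murmur energy between S1 and S2 of every cycle.
    gate = np.zeros_like(t)
    for tc in cycle_starts:
        gate += np.exp(-0.5 * ((t - tc - 0.5 * s2_offset) / (0.25 * s2_offset)) ** 2)

    frac = params.shared_murmur_fraction
    channels: dict[str, np.ndarray] = {}
    for site in PCG_SITES:
        a1, a2 = _S1S2_AMP[site]
        lat = _LATENCY[site]
        x = a1 * _bursts(t, cycle_starts + lat, params.s1_freq, params.burst_width)
        x = x + a2 * _bursts(t, cycle_starts + s2_offset + lat, params.s2_freq, params.burst_width)
        if label == "abnormal":
            murmur = np.sqrt(frac) * shared_murmur + np.sqrt(1 - frac) * indep_murmur[site]
            x = x + params.murmur_gain * gate * murmur
        channels[site] = x + params.noise_sd * white[site]

    r_times = cycle_starts - 0.04  # R peak slightly precedes S1
    drift = 0.5 * np.sin(2 * np.pi * 0.3 * t) + 0.3 * t / params.duration
    channels["E"] = _pqrst(t, r_times) + drift + 0.2 * params.noise_sd * ecg_white

    meta = {"seed": str(params.seed), "source": "synthetic"}
    return MultiChannelRecording(channels=channels, fs=params.fs, label=label, meta=meta)


def generate_cohort(
    n_normal: int, n_abnormal: int, params: SimParams
) -> list[MultiChannelRecording]:
    """Generate a labeled cohort; recording ``i`` uses seed ``params.seed + i``."""
    if n_normal < 0 or n_abnormal < 0:
        raise ValueError("counts must be >= 0")
    recs: list[MultiChannelRecording] = []
    labels = ["normal"] * n_normal + ["abnormal"] * n_abnormal
    for i, label in enumerate(labels):
        rec = generate_recording(replace(params, seed=params.seed + i), label)
        rec.meta["index"] = str(i)
        recs.append(rec)
    return recs


# ---------------------------------------------------------------------------
# recording I/O
# ---------------------------------------------------------------------------

def write_recording(rec: MultiChannelRecording, directory: str | Path) -> Path:
    """Write one WAV file per channel plus a ``meta.json`` sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for site, x in rec.channels.items():
        wavfile.write(directory / f"{site}.wav", int(rec.fs), x.astype(np.float32))
    meta = {"fs": rec.fs, "label": rec.label, "meta": rec.meta}
    (directory / "meta.json").write_text(json.dumps(meta, indent=1))
    return directory


def _read_wav(path: Path) -> tuple[float, np.ndarray]:
    fs, x = wavfile.read(path)
    x = np.asarray(x)
    if x.dtype == np.int16:
        x = x / 32768.0
    elif x.dtype == np.int32:
        x = x / 2147483648.0
    return float(fs), x.astype(float)


def read_recording(
    source: str | Path | dict[str, str | Path],
    fs: float | None = None,
    label: str = "unknown",
) -> MultiChannelRecording:
    """Read a recording from per-site WAV files or a columnar CSV.

    ``source`` may be a mapping site -> WAV path, a directory containing
    ``<site>.wav`` files (and optionally ``meta.json``), or a CSV file with
    a header row of site labels (one column per channel; ``fs`` required).
    Channels of unequal length are truncated to the shortest with a warning.
    """
    meta: dict = {}
    if isinstance(source, dict):
        paths = {site: Path(p) for site, p in source.items()}
    else:
        source = Path(source)
        if source.is_dir():
            paths = {s: source / f"{s}.wav" for s in SITE_ORDER if (source / f"{s}.wav").exists()}
            if not paths:
                raise FileNotFoundError(f"no <site>.wav files in {source}")
            meta_path = source / "meta.json"
            if meta_path.exists():
                info = json.loads(meta_path.read_text())
                fs = fs if fs is not None else info.get("fs")
                if label == "unknown":
                    label = info.get("label", "unknown")
                meta = info.get("meta", {})
        elif source.suffix.lower() == ".csv":
            if fs is None:
                raise ValueError("fs is required for CSV recordings")
            df = pd.read_csv(source)
            unknown = set(df.columns) - set(SITE_ORDER)
            if unknown:
                raise ValueError(f"unknown site labels in header: {sorted(unknown)}")
            channels = {c: df[c].to_numpy(dtype=float) for c in df.columns}
            return MultiChannelRecording(channels=channels, fs=fs, label=label, meta=meta)
        else:
            raise ValueError(f"cannot interpret recording source {source}")

    unknown = set(paths) - set(SITE_ORDER)
    if unknown:
        raise ValueError(f"unknown site labels: {sorted(unknown)}")
    channels: dict[str, np.ndarray] = {}
    rates = set()
    for site, path in paths.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"missing channel file: {path}")
        file_fs, x = _read_wav(Path(path))
        if x.size == 0:
            raise ValueError(f"zero-length channel {site} in {path}")
        rates.add(file_fs)
        channels[site] = x
    if len(rates) > 1:
        raise ValueError(f"inconsistent sampling rates across channels: {sorted(rates)}")
    file_fs = rates.pop()
    if fs is not None and fs != file_fs:
        raise ValueError(f"declared fs {fs} differs from file fs {file_fs}")
    lengths = {s: x.size for s, x in channels.items()}
    n_min = min(lengths.values())
    if len(set(lengths.values())) > 1:
        warnings.warn(
            f"channels truncated to common length {n_min} (had {lengths})", UserWarning
        )
        channels = {s: x[:n_min] for s, x in channels.items()}
    return MultiChannelRecording(channels=channels, fs=file_fs, label=label, meta=meta)


# ---------------------------------------------------------------------------
# feature-table I/O
# ---------------------------------------------------------------------------

def write_feature_table(
    matrix: FeatureMatrix, destination: str | Path, config_hash: str | None = None
) -> Path:
    """Write a cohort feature table as CSV, feature columns first, label last."""
    destination = Path(destination)
    destination.parent.mkdir(parents=True, exist_ok=True)
    df = matrix.to_dataframe()
    with open(destination, "w") as fh:
        if config_hash is not None:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)
    return destination


def read_feature_table(source: str | Path) -> FeatureMatrix:
    """Read a feature-table CSV, restoring canonical column order by name."""
    df = pd.read_csv(source, comment="#")
    if "label" not in df.columns:
        raise ValueError("feature table must contain a 'label' column")
    feature_cols = [c for c in df.columns if c != "label"]
    try:
        feature_cols = sorted(feature_cols, key=feature_sort_key)
    except ValueError as err:
        raise ValueError(f"malformed feature-table header: {err}") from err
    try:
        values = df[feature_cols].to_numpy(dtype=float)
    except (TypeError, ValueError) as err:
        raise ValueError(f"feature table contains non-numeric cells: {err}") from err
    return FeatureMatrix(
        values=values,
        names=feature_cols,
        labels=df["label"].to_numpy(dtype=str),
    )


def read_table_hash(source: str | Path) -> str | None:
    """Return the config hash embedded in a table's comment header, if any."""
    with open(source) as fh:
        first = fh.readline().strip()
    if first.startswith("# config_hash="):
        return first.split("=", 1)[1]
    return None
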