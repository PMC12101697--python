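"""Denoising and detrending of PCG and ECG channels.

PCG channels are band-pass filtered (default 4.85–1250 Hz, zero phase) to
keep heart-sound energy while rejecting baseline drift and high-frequency
noise. The ECG channel is first detrended by discarding the deepest
approximation coefficients of a discrete wavelet decomposition (Daubechies
family, ten levels by default) and then band-pass filtered to 5–15 Hz,
which sharpens the R peaks. Recordings may be resampled to a common rate
before filtering and z-scored per channel afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
import pywt
from scipy import signal as sps

from .records import PCG_SITES, MultiChannelRecording


@dataclass
class PreprocessConfig:
    """Preprocessing parameters.

    ``target_fs`` of ``None`` keeps the native sampling rate; otherwise the
    recording is resampled (polyphase, anti-aliased) first. The PCG band's
    upper edge is clipped to 95% of the post-resampling Nyquist frequency,
    so the default 1250 Hz edge becomes 950 Hz at the default 2000 Hz rate.
    """

    pcg_band: tuple[float, float] = (4.85, 1250.0)
    pcg_order: int = 4
    ecg_band: tuple[float, float] = (5.0, 15.0)
    wavelet_name: str = "db4"
    dwt_levels: int = 10
    target_fs: float | None = 2000.0
    normalize: bool = True

    def __post_init__(self) -> None:
        for band in (self.pcg_band, self.ecg_band):
            if not 0 < band[0] < band[1]:
                raise ValueError(f"invalid band {band}")
        if self.pcg_order < 1:
            raise ValueError("pcg_order must be >= 1")
        if self.dwt_levels < 1:
            raise ValueError("dwt_levels must be >= 1")
        if self.target_fs is not None and self.target_fs <= 0:
            raise ValueError("target_fs must be positive")


def butterworth_bandpass(
    x: np.ndarray, band: tuple[float, float], order: int, fs: float
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward, symmetric padding).

    Forward-backward application doubles the effective order and cancels
    phase delay, so S1/S2 timing is preserved. Output length equals input
    length.
    """
    x = np.asarray(x, dtype=float)
    low, high = band
    if not 0 < low < high < fs / 2:
        raise ValueError(f"band {band} invalid for fs={fs} (need 0 < low < high < Nyquist)")
    sos = sps.butter(order, (low, high), btype="bandpass", fs=fs, output="sos")
    # sosfiltfilt needs a minimum padding length; reject clearly-too-short input
    if x.size <= 3 * (2 * order + 1):
        raise ValueError(f"signal too short ({x.size} samples) for order-{order} filtering")
    # pad by ~3 periods of the low band edge (clamped): the default padlen is
    # far too short for a 4.85 Hz edge and lets edge transients leak through
    padlen = min(x.size - 1, max(3 * (len(sos) * 6 + 1), int(3 * fs / low)))
    return sps.sosfiltfilt(sos, x, padtype="even", padlen=padlen)


def dwt_detrend(x: np.ndarray, wavelet_name: str = "db4", levels: int = 10) -> np.ndarray:
    """Remove the slow trend by zeroing the deepest DWT approximation.

    The signal is decomposed to ``levels`` levels (symmetric padding), the
    level-``levels`` approximation coefficients are zeroed, and the signal
    is reconstructed. The discarded component is the baseline trend; adding
    it back recovers the input exactly (perfect reconstruction).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2 ** levels:
        raise ValueError(f"need >= 2^{levels} = {2 ** levels} samples, got {x.size}")
    coeffs = pywt.wavedec(x, wavelet_name, mode="symmetric", level=levels)
    coeffs[0] = np.zeros_like(coeffs[0])
    out = pywt.waverec(coeffs, wavelet_name, mode="symmetric")
    return out[: x.size]


def zscore(x: np.ndarray) -> np.ndarray:
    """Standardize to zero mean, unit standard deviation.

    Raises on constant input (zero variance); the caller may substitute
    zeros if that degenerate case is expected.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    sd = x.std()
    if sd == 0:
        raise ValueError("zscore undefined for constant input")
    return (x - x.mean()) / sd


def _resample(x: np.ndarray, fs: float, target_fs: float) -> np.ndarray:
    frac = Fraction(target_fs / fs).limit_denominator(1000)
    return sps.resample_poly(x, frac.numerator, frac.denominator)


def preprocess_recording(
    rec: MultiChannelRecording, cfg: PreprocessConfig | None = None
) -> MultiChannelRecording:
    """Apply the full preprocessing chain to every channel of a recording.

    Order of operations: optional resampling to ``cfg.target_fs``; PCG
    channels band-passed with ``cfg.pcg_band`` (upper edge clipped below
    Nyquist); the ECG channel DWT-detrended then band-passed with
    ``cfg.ecg_band``; optional per-channel z-scoring last. Label and
    metadata are preserved.
    """
    cfg = cfg or PreprocessConfig()
    fs = rec.fs
    channels: dict[str, np.ndarray] = {}
    for site, x in rec.channels.items():
        if cfg.target_fs is not None and cfg.target_fs != fs:
            x = _resample(x, fs, cfg.target_fs)
        new_fs = cfg.target_fs if cfg.target_fs is not None else fs
        if site in PCG_SITES:
            high = min(cfg.pcg_band[1], 0.95 * new_fs / 2)
            x = butterworth_bandpass(x, (cfg.pcg_band[0], high), cfg.pcg_order, new_fs)
        else:  # ECG
            # a 10-level decomposition needs ~2^10 x filter-length samples;
            # clamp so short or resampled records keep a boundary-safe depth
            levels = min(cfg.dwt_levels, pywt.dwt_max_level(x.size, cfg.wavelet_name))
            x = dwt_detrend(x, cfg.wavelet_name, levels)
            x = butterworth_bandpass(x, cfg.ecg_band, cfg.pcg_order, new_fs)
        if cfg.normalize:
            x = zscore(x)
        channels[site] = x
    out_fs = cfg.target_fs if cfg.target_fs is not None else fs
    meta = dict(rec.meta)
    meta["preprocessed"] = "true"
    return MultiChannelRecording(channels=channels, fs=out_fs, label=rec.label, meta=meta)


def make_config(**overrides) -> PreprocessConfig:
    """Convenience constructor applying keyword overrides to the defaults."""
    return replace(PreprocessConfig(), **overrides)
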