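"""Pairwise coupling features between heart-sound / ECG channels.

For every unordered channel pair this module computes 13 scalar coupling
features spanning four families:

* nonlinear synchrony — cross-sample entropy, cross-fuzzy entropy and
  joint distribution entropy of embedded template distances;
* phase synchrony — the phase-locking value (PLV) of the instantaneous
  Hilbert phases;
* spectral dependence — mean and standard deviation of the magnitude-squared
  coherence (MSC), and mean/SD of the real and imaginary parts of the cross
  power spectral density (CPSD) over a frequency band of interest;
* waveform similarity — Pearson correlation, cosine similarity and
  Euclidean distance.

With five channels (A, P, T, M, E) there are C(5,2) = 10 pairs, hence 130
features per recording; with four PCG channels there are 6 pairs and 78
features.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps

from .records import SITE_ORDER, MultiChannelRecording

logger = logging.getLogger(__name__)

#: Canonical per-pair measure names, in the fixed 13-slot order.
MEASURES: tuple[str, ...] = (
    "samen",
    "fuzen",
    "jdisten",
    "plv",
    "msc_mean",
    "msc_std",
    "pearson",
    "cossim",
    "euclid",
    "cpsd_re_mean",
    "cpsd_re_std",
    "cpsd_im_mean",
    "cpsd_im_std",
)

#: Canonical pair order for the full five-channel montage.
PAIR_ORDER_5: tuple[str, ...] = ("AP", "AT", "AM", "AE", "PT", "PM", "PE", "TM", "TE", "ME")


@dataclass
class EmbeddingConfig:
    """Parameters of the template-embedding entropy measures.

    ``m`` is the embedding (template) dimension, ``r`` the match tolerance
    expressed as a multiple of the pooled standard deviation of the pair,
    ``B`` the histogram bin count for joint distribution entropy, and
    ``max_points`` caps the number of samples entering the O(N^2) entropy
    computations (a centered crop is used above the cap).
    """

    m: int = 2
    r: float = 0.2
    B: int = 64
    max_points: int = 2000
    fuzzy_kernel: str = "exponential"  # or "gaussian"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.r <= 0:
            raise ValueError("tolerance r must be > 0")
        if self.B < 2:
            raise ValueError("bin count B must be >= 2")
        if self.max_points < self.m + 2:
            raise ValueError("max_points must be >= m + 2")
        if self.fuzzy_kernel not in ("exponential", "gaussian"):
            raise ValueError("fuzzy_kernel must be 'exponential' or 'gaussian'")


@dataclass
class SpectralConfig:
    """Windowing and band parameters for MSC / CPSD features.

    ``window_length`` of ``None`` means one second of samples (``int(fs)``).
    Summaries (mean/SD) are taken over frequencies inside ``band`` (Hz).
    """

    window_length: int | None = None
    overlap_fraction: float = 0.5
    window_shape: str = "hann"
    band: tuple[float, float] = (4.85, 1000.0)

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.band[0] >= self.band[1]:
            raise ValueError("band must satisfy low < high")

    def resolve_window(self, fs: float) -> tuple[int, int]:
        wl = int(fs) if self.window_length is None else int(self.window_length)
        return wl, int(wl * self.overlap_fraction)


@dataclass
class PairFeatures:
    """The ordered 13-value coupling-feature block for one channel pair."""

    samen: float
    fuzen: float
    jdisten: float
    plv: float
    msc_mean: float
    msc_std: float
    pearson: float
    cossim: float
    euclid: float
    cpsd_re_mean: float
    cpsd_re_std: float
    cpsd_im_mean: float
    cpsd_im_std: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, m) for m in MEASURES], dtype=float)


@dataclass
class FeatureVector:
    """Concatenated PairFeatures blocks for one recording."""

    values: np.ndarray
    names: list[str]
    pair_order: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != len(self.names):
            raise ValueError("values and names length mismatch")
        if self.values.size != 13 * len(self.pair_order):
            raise ValueError("length must be 13 x number of pairs")


def _check_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("inputs must be 1-D")
    if x.size != y.size:
        raise ValueError(f"unequal lengths: {x.size} vs {y.size}")
    return x, y


# ---------------------------------------------------------------------------
# entropy family
# ---------------------------------------------------------------------------

def cross_sample_entropy(x: np.ndarray, y: np.ndarray, m: int = 2, r: float = 0.2) -> float:
    """Cross-sample entropy between two equal-length sequences.

    Templates of length ``m`` are drawn from ``x`` and compared (Chebyshev
    distance, strict ``d < r`` match) against templates drawn from ``y``;
    the statistic is ``-ln(B^{m+1}(r) / B^m(r))`` where ``B^m`` is the mean
    cross-match fraction at template length ``m``. ``r`` is an absolute
    tolerance — callers scale it by the pooled standard deviation.

    Lower values indicate a more regular, more strongly coupled pair.
    Returns NaN (with a warning) when no template pair matches at either
    length, which makes the log ratio undefined.
    """
    x, y = _check_pair(x, y)
    n_samp = x.size
    if n_samp < m + 2:
        raise ValueError(f"need at least m + 2 = {m + 2} samples, got {n_samp}")
    if r <= 0:
        raise ValueError("tolerance r must be > 0")

    base = np.abs(x[:, None] - y[None, :])

    def mean_match(mm: int) -> float:
        n = n_samp - mm + 1
        dist = base[:n, :n]
        for t in range(1, mm):
            dist = np.maximum(dist, base[t:t + n, t:t + n])
        hits = dist < r
        # exclude j == i, keep the template count n in the denominator
        counts = hits.sum(axis=1) - np.diagonal(hits)
        return float(np.mean(counts / n))

    bm = mean_match(m)
    bm1 = mean_match(m + 1)
    if bm == 0.0 or bm1 == 0.0:
        warnings.warn("cross-sample entropy undefined: no template matches", RuntimeWarning)
        return float("nan")
    return float(-math.log(bm1 / bm))


def _centered_templates(x: np.ndarray, mm: int) -> np.ndarray:
    tpl = sliding_window_view(x, mm)
    return tpl - tpl.mean(axis=1, keepdims=True)


def cross_fuzzy_entropy(
    x: np.ndarray, y: np.ndarray, m: int = 2, r: float = 0.2, kernel: str = "exponential"
) -> float:
    """Cross-fuzzy entropy: smooth-kernel variant of cross-sample entropy.

    Each template has its own mean removed; the hard threshold is replaced
    by a similarity kernel of the Chebyshev template distance — by default
    the exponential kernel ``exp(-d / r)``, optionally the squared
    (Gaussian) kernel ``exp(-(d / r)^2)``. Always finite for ``r > 0``.
    """
    x, y = _check_pair(x, y)
    n_samp = x.size
    if n_samp < m + 2:
        raise ValueError(f"need at least m + 2 = {m + 2} samples, got {n_samp}")
    if r <= 0:
        raise ValueError("tolerance r must be > 0")
    if kernel not in ("exponential", "gaussian"):
        raise ValueError("kernel must be 'exponential' or 'gaussian'")

    def phi(mm: int) -> float:
        xc = _centered_templates(x, mm)
        yc = _centered_templates(y, mm)
        dist = np.abs(xc[:, 0][:, None] - yc[:, 0][None, :])
        for t in range(1, mm):
            dist = np.maximum(dist, np.abs(xc[:, t][:, None] - yc[:, t][None, :]))
        if kernel == "exponential":
            sim = np.exp(-dist / r)
        else:
            sim = np.exp(-((dist / r) ** 2))
        total = float(sim.sum() - np.trace(sim))  # j != i
        return total / n_samp

    return float(-math.log(phi(m + 1) / phi(m)))


def joint_distribution_entropy(x: np.ndarray, y: np.ndarray, m: int = 2, B: int = 64) -> float:
    """Shannon entropy (bits) of the pooled cross-template distance histogram.

    All Euclidean distances between length-``m`` templates of ``x`` and of
    ``y`` are pooled; their empirical distribution over ``B`` equal-width
    bins spanning [min d, max d] gives probabilities whose entropy is
    returned. Degenerate inputs where every distance is equal give 0.
    """
    x, y = _check_pair(x, y)
    if x.size < m + 1:
        raise ValueError(f"need at least m + 1 = {m + 1} samples, got {x.size}")
    if B < 2:
        raise ValueError("B must be >= 2")
    xt = sliding_window_view(x, m)
    yt = sliding_window_view(y, m)
    sq = (xt[:, 0][:, None] - yt[:, 0][None, :]) ** 2
    for t in range(1, m):
        sq = sq + (xt[:, t][:, None] - yt[:, t][None, :]) ** 2
    dist = np.sqrt(sq).ravel()
    lo, hi = float(dist.min()), float(dist.max())
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(dist, bins=B, range=(lo, hi))
    p = counts[counts > 0] / dist.size
    return float(-(p * np.log2(p)).sum())


# ---------------------------------------------------------------------------
# phase and spectral family
# ---------------------------------------------------------------------------

def phase_locking_value(x: np.ndarray, y: np.ndarray) -> float:
    """Phase-locking value: |mean unit phasor| of the Hilbert phase difference.

    1 means the instantaneous phase difference is constant over the whole
    record (perfect locking); values near 0 indicate independent phases
    (expectation ~1/sqrt(N) for unrelated noise).
    """
    x, y = _check_pair(x, y)
    if x.size < 4:
        raise ValueError("need at least 4 samples")
    phix = np.angle(sps.hilbert(x))
    phiy = np.angle(sps.hilbert(y))
    return float(np.abs(np.mean(np.exp(1j * (phix - phiy)))))


def _n_segments(n: int, wl: int, noverlap: int) -> int:
    if wl > n:
        return 0
    return (n - wl) // (wl - noverlap) + 1


def msc_features(
    x: np.ndarray, y: np.ndarray, cfg: SpectralConfig, fs: float
) -> tuple[float, float]:
    """Mean and SD of the magnitude-squared coherence over ``cfg.band``.

    Welch-averaged auto/cross spectra; at least two segments are required
    (single-segment coherence is identically 1 and carries no information).
    """
    x, y = _check_pair(x, y)
    wl, noverlap = cfg.resolve_window(fs)
    if _n_segments(x.size, wl, noverlap) < 2:
        raise ValueError("window configuration yields fewer than 2 segments")
    freqs, coh = sps.coherence(
        x, y, fs=fs, window=cfg.window_shape, nperseg=wl, noverlap=noverlap, detrend=False
    )
    mask = (freqs >= cfg.band[0]) & (freqs <= cfg.band[1])
    if not mask.any():
        raise ValueError("no frequency bins inside the summary band")
    sel = coh[mask]
    return float(sel.mean()), float(sel.std())


def cpsd(
    x: np.ndarray, y: np.ndarray, cfg: SpectralConfig, fs: float
) -> tuple[np.ndarray, np.ndarray]:
    """Segment-averaged cross power spectral density S_xy(f) = (1/M) sum X_m Y_m*.

    Returns ``(freqs, S)`` on the one-sided rfft grid. The raw windowed-DFT
    product convention is used (no density normalization, no one-sided
    doubling) so a single rectangular window reduces exactly to X(f) Y*(f).
    """
    x, y = _check_pair(x, y)
    wl, noverlap = cfg.resolve_window(fs)
    if wl > x.size:
        raise ValueError(f"window ({wl}) longer than signal ({x.size})")
    win = sps.get_window(cfg.window_shape, wl)
    step = wl - noverlap
    acc = np.zeros(wl // 2 + 1, dtype=complex)
    m_count = 0
    for start in range(0, x.size - wl + 1, step):
        xf = np.fft.rfft(win * x[start:start + wl])
        yf = np.fft.rfft(win * y[start:start + wl])
        acc += xf * np.conj(yf)
        m_count += 1
    freqs = np.fft.rfftfreq(wl, d=1.0 / fs)
    return freqs, acc / m_count


def cpsd_features(
    x: np.ndarray, y: np.ndarray, cfg: SpectralConfig, fs: float
) -> tuple[float, float, float, float]:
    """Mean/SD of the real and imaginary CPSD parts over ``cfg.band``."""
    freqs, s_xy = cpsd(x, y, cfg, fs)
    mask = (freqs >= cfg.band[0]) & (freqs <= cfg.band[1])
    if not mask.any():
        raise ValueError("no frequency bins inside the summary band")
    sel = s_xy[mask]
    return (
        float(sel.real.mean()),
        float(sel.real.std()),
        float(sel.imag.mean()),
        float(sel.imag.std()),
    )


# ---------------------------------------------------------------------------
# waveform similarity family
# ---------------------------------------------------------------------------

def pearson_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; raises on zero-variance input."""
    x, y = _check_pair(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for constant input")
    return float(np.corrcoef(x, y)[0, 1])


def cosine_similarity(x: np.ndarray, y: np.ndarray) -> float:
    """Inner product over the product of norms (no mean removal)."""
    x, y = _check_pair(x, y)
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(x, y) / (nx * ny))


def euclidean_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Point-to-point Euclidean distance sqrt(sum (x_k - y_k)^2)."""
    x, y = _check_pair(x, y)
    return float(np.linalg.norm(x - y))


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _center_crop(x: np.ndarray, n: int) -> np.ndarray:
    if x.size <= n:
        return x
    start = (x.size - n) // 2
    return x[start:start + n]


def pair_features(
    x: np.ndarray,
    y: np.ndarray,
    emb: EmbeddingConfig,
    spec: SpectralConfig,
    fs: float,
) -> PairFeatures:
    """Compute the 13-feature coupling block for one (preprocessed) pair.

    The O(N^2) entropy measures run on a centered crop of at most
    ``emb.max_points`` samples; all other features use the full signals.
    The entropy tolerance is ``emb.r`` times the pooled standard deviation
    of the cropped pair.
    """
    x, y = _check_pair(x, y)
    xc = _center_crop(x, emb.max_points)
    yc = _center_crop(y, emb.max_points)
    if xc.size < x.size:
        logger.info("entropy features computed on centered crop of %d/%d samples", xc.size, x.size)
    pooled_sd = float(np.concatenate([xc, yc]).std())
    if pooled_sd == 0:
        raise ValueError("pooled standard deviation is zero; cannot scale tolerance")
    r_abs = emb.r * pooled_sd

    msc_mean, msc_std = msc_features(x, y, spec, fs)
    re_m, re_s, im_m, im_s = cpsd_features(x, y, spec, fs)
    return PairFeatures(
        samen=cross_sample_entropy(xc, yc, emb.m, r_abs),
        fuzen=cross_fuzzy_entropy(xc, yc, emb.m, r_abs, emb.fuzzy_kernel),
        jdisten=joint_distribution_entropy(xc, yc, emb.m, emb.B),
        plv=phase_locking_value(x, y),
        msc_mean=msc_mean,
        msc_std=msc_std,
        pearson=pearson_correlation(x, y),
        cossim=cosine_similarity(x, y),
        euclid=euclidean_distance(x, y),
        cpsd_re_mean=re_m,
        cpsd_re_std=re_s,
        cpsd_im_mean=im_m,
        cpsd_im_std=im_s,
    )


def canonical_pairs(sites: tuple[str, ...] | list[str]) -> list[tuple[str, str]]:
    """Unordered channel pairs in canonical site order (AP, AT, ... for 5)."""
    present = [s for s in SITE_ORDER if s in sites]
    return list(itertools.combinations(present, 2))


def feature_names(sites: tuple[str, ...] | list[str]) -> list[str]:
    """Canonical ``<PAIR>_<measure>`` names for the given channel set."""
    return [f"{a}{b}_{m}" for a, b in canonical_pairs(sites) for m in MEASURES]


def feature_sort_key(name: str) -> tuple[int, int]:
    """Sort key placing ``<PAIR>_<measure>`` names in canonical order."""
    pair, _, measure = name.partition("_")
    pairs_all = [f"{a}{b}" for a, b in canonical_pairs(SITE_ORDER)]
    if pair not in pairs_all or measure not in MEASURES:
        raise ValueError(f"not a canonical feature name: {name!r}")
    return pairs_all.index(pair), MEASURES.index(measure)


def extract_features(
    rec: MultiChannelRecording,
    emb: EmbeddingConfig | None = None,
    spec: SpectralConfig | None = None,
) -> FeatureVector:
    """Full per-recording coupling-feature vector over all channel pairs.

    Pairs are enumerated in canonical order (AP, AT, AM, AE, PT, PM, PE,
    TM, TE, ME for five channels; the same scheme with E-pairs dropped for
    four). The vector has length 13 * C(n_channels, 2): 130 for five
    channels, 78 for four.
    """
    emb = emb or EmbeddingConfig()
    spec = spec or SpectralConfig()
    pairs = canonical_pairs(rec.sites)
    values: list[float] = []
    names: list[str] = []
    for a, b in pairs:
        pf = pair_features(rec.channels[a], rec.channels[b], emb, spec, rec.fs)
        values.extend(pf.as_array())
        names.extend(f"{a}{b}_{m}" for m in MEASURES)
    return FeatureVector(np.array(values), names, [f"{a}{b}" for a, b in pairs])
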