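"""Core container for simultaneous multi-site heart-sound recordings.

A recording bundles up to four phonocardiogram (PCG) channels taken at the
classical auscultation sites — aortic (A), pulmonary (P), tricuspid (T) and
mitral (M) — plus an optional single-lead ECG channel (E), all sharing one
time axis and sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical site order used everywhere (channel iteration, pair enumeration).
SITE_ORDER: tuple[str, ...] = ("A", "P", "T", "M", "E")

#: The four phonocardiogram auscultation sites (ECG excluded).
PCG_SITES: tuple[str, ...] = ("A", "P", "T", "M")

#: Allowed class tags.
LABELS: tuple[str, ...] = ("normal", "abnormal", "unknown")


@dataclass
class MultiChannelRecording:
    """Simultaneously recorded PCG (and optional ECG) channels.

    Parameters
    ----------
    channels
        Mapping from site label (subset of ``A, P, T, M, E``) to a 1-D
        sample array. All channels must have equal length >= 2. Stored in
        canonical site order regardless of insertion order.
    fs
        Sampling rate in Hz, > 0.
    label
        Class tag: ``"normal"``, ``"abnormal"`` or ``"unknown"``.
    meta
        Free-form provenance strings (seed, source files, config hash, ...).
    """

    channels: dict[str, np.ndarray]
    fs: float
    label: str = "unknown"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        unknown = set(self.channels) - set(SITE_ORDER)
        if unknown:
            raise ValueError(f"unknown site labels: {sorted(unknown)}")
        if len(self.channels) < 2:
            raise ValueError("at least 2 channels are required")
        ordered: dict[str, np.ndarray] = {}
        lengths = set()
        for site in SITE_ORDER:
            if site in self.channels:
                x = np.asarray(self.channels[site], dtype=float)
                if x.ndim != 1:
                    raise ValueError(f"channel {site} must be 1-D")
                if x.size < 2:
                    raise ValueError(f"channel {site} must have length >= 2")
                ordered[site] = x
                lengths.add(x.size)
        if len(lengths) != 1:
            raise ValueError(f"channels have unequal lengths: {sorted(lengths)}")
        self.channels = ordered

    @property
    def sites(self) -> tuple[str, ...]:
        return tuple(self.channels)

    @property
    def pcg_sites(self) -> tuple[str, ...]:
        return tuple(s for s in self.channels if s in PCG_SITES)

    @property
    def n_samples(self) -> int:
        return next(iter(self.channels.values())).size

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs
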