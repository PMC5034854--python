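"""Core containers shared across the package.

All signals are stored in microvolts (μV) as ``(n_channels, n_samples)``
float arrays, with channel labels naming bipolar derivations.  Event times
are seconds from the start of the record; an event covers the half-open
interval ``[onset_s, onset_s + duration_s)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["EEGRecord", "SeizureAnnotation", "DetectionEvent"]


@dataclass
class EEGRecord:
    """Multichannel EEG signal in μV.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in μV.
    sampling_rate : float
        Samples per second (neonatal ICU monitors record at 250 or 256 Hz).
    channel_labels : list of str
        Bipolar derivation names, e.g. ``"F4-C4"``.
    """

    data: np.ndarray
    sampling_rate: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("EEGRecord.data must be 2-D (channels, samples)")
        if self.channel_labels and len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def time_slice(self, start_s: float, stop_s: float) -> np.ndarray:
        """Return the view of ``data`` covering ``[start_s, stop_s)``."""
        i0 = max(0, int(round(start_s * self.sampling_rate)))
        i1 = min(self.n_samples, int(round(stop_s * self.sampling_rate)))
        if i1 <= i0:
            raise ValueError(f"empty time slice [{start_s}, {stop_s}) s")
        return self.data[:, i0:i1]

    def copy(self) -> "EEGRecord":
        return replace(self, data=self.data.copy(),
                       channel_labels=list(self.channel_labels))


@dataclass(frozen=True)
class SeizureAnnotation:
    """One gold-standard seizure event."""

    onset_s: float
    duration_s: float
    subject_id: str = ""
    period: str = ""  # "pre" or "post" (relative to anticonvulsant dose)

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s

    def overlap_s(self, other: "SeizureAnnotation | DetectionEvent") -> float:
        """Length in seconds of the temporal intersection with ``other``."""
        return max(0.0, min(self.end_s, other.end_s) - max(self.onset_s, other.onset_s))


@dataclass(frozen=True)
class DetectionEvent:
    """Detector output event: where, for how long, and how confident."""

    onset_s: float
    duration_s: float
    channel: str = ""
    peak_probability: float = float("nan")

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s

    def overlap_s(self, other: "SeizureAnnotation | DetectionEvent") -> float:
        return max(0.0, min(self.end_s, other.end_s) - max(self.onset_s, other.onset_s))
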