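"""Neonatal reduced bipolar montage.

Neonatal ICU recordings use a 9-electrode adaptation of the 10–20 system
(F4, F3, T4, C4, Cz, C3, T3, O2, O1) displayed as 8 bipolar derivations.
The derivation chains used here are two parasagittal chains and a central
transverse chain, the usual neonatal "double banana" reduction.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["MontageSpec", "default_montage", "NEONATAL_ELECTRODES", "NEONATAL_BIPOLAR_PAIRS"]

NEONATAL_ELECTRODES = ["F4", "F3", "T4", "C4", "Cz", "C3", "T3", "O2", "O1"]

NEONATAL_BIPOLAR_PAIRS = [
    ("F4", "C4"), ("C4", "O2"),
    ("F3", "C3"), ("C3", "O1"),
    ("T4", "C4"), ("C4", "Cz"),
    ("Cz", "C3"), ("C3", "T3"),
]


@dataclass(frozen=True)
class MontageSpec:
    """Electrode set, bipolar derivations and sampling rate.

    Invariants: exactly 8 bipolar channels, every pair member a named
    electrode, sampling rate 250 or 256 Hz (the two ICU monitor rates).
    """

    electrode_labels: tuple[str, ...] = tuple(NEONATAL_ELECTRODES)
    bipolar_pairs: tuple[tuple[str, str], ...] = tuple(NEONATAL_BIPOLAR_PAIRS)
    sampling_rate: float = 250.0

    def __post_init__(self) -> None:
        if len(self.bipolar_pairs) != 8:
            raise ValueError(
                f"neonatal montage requires exactly 8 bipolar channels, got {len(self.bipolar_pairs)}"
            )
        for a, b in self.bipolar_pairs:
            if a not in self.electrode_labels or b not in self.electrode_labels:
                raise ValueError(f"bipolar pair ({a}, {b}) uses unknown electrode")
        if self.sampling_rate not in (250, 256):
            raise ValueError(f"sampling_rate must be 250 or 256 Hz, got {self.sampling_rate}")

    @property
    def n_channels(self) -> int:
        return len(self.bipolar_pairs)

    @property
    def channel_labels(self) -> list[str]:
        return [f"{a}-{b}" for a, b in self.bipolar_pairs]


def default_montage(sampling_rate: float = 250.0) -> MontageSpec:
    """The standard 8-channel neonatal bipolar montage."""
    return MontageSpec(sampling_rate=sampling_rate)
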