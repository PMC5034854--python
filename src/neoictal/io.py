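"""File formats: EDF records, annotation lists, feature tables.

EDF output is written by a small built-in 16-bit EDF encoder (physical
range ±2000 μV, so the quantisation step is ~0.06 μV); reading goes
through MNE's EDF reader, which also serves as an independent check on
the encoder in the test suite.  Annotation lists — both gold-standard
seizures and detector output — are tab-separated text files with onsets
and durations in seconds from the start of the record, rounded to two
decimals.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import DetectionEvent, EEGRecord, SeizureAnnotation

__all__ = [
    "write_edf", "read_edf",
    "write_annotations", "read_annotations",
    "write_detections", "read_detections",
    "features_to_frame", "write_feature_table", "read_feature_table",
]

PHYS_MIN, PHYS_MAX = -2000.0, 2000.0
DIG_MIN, DIG_MAX = -32768, 32767


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(record: EEGRecord, path) -> None:
    """Write a multichannel μV record as 16-bit EDF (1 s data records).

    Samples beyond the ±2000 μV physical range are clipped; a final
    partial second is zero-padded.
    """
    if record.n_samples == 0 or record.n_channels == 0:
        raise ValueError("cannot write an empty record")
    fs = record.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    ns = record.n_channels
    n_records = int(np.ceil(record.n_samples / fs))
    labels = record.channel_labels or [f"ch{c}" for c in range(ns)]

    header = b"".join([
        _pad("0", 8),
        _pad("X X X X", 80),
        _pad("Startdate X neoictal synthetic EEG", 80),
        _pad("01.01.00", 8),
        _pad("00.00.00", 8),
        _pad(str(256 * (ns + 1)), 8),
        _pad("", 44),
        _pad(str(n_records), 8),
        _pad("1", 8),
        _pad(str(ns), 4),
    ])
    fields = [
        [_pad(lab, 16) for lab in labels],
        [_pad("AgAgCl electrode", 80)] * ns,
        [_pad("uV", 8)] * ns,
        [_pad(str(int(PHYS_MIN)), 8)] * ns,
        [_pad(str(int(PHYS_MAX)), 8)] * ns,
        [_pad(str(DIG_MIN), 8)] * ns,
        [_pad(str(DIG_MAX), 8)] * ns,
        [_pad("HP:0.5Hz LP:70Hz", 80)] * ns,
        [_pad(str(fs), 8)] * ns,
        [_pad("", 32)] * ns,
    ]
    signal_header = b"".join(b"".join(f) for f in fields)

    scale = (DIG_MAX - DIG_MIN) / (PHYS_MAX - PHYS_MIN)
    padded = np.zeros((ns, n_records * fs))
    padded[:, : record.n_samples] = np.clip(record.data, PHYS_MIN, PHYS_MAX)
    digital = np.round((padded - PHYS_MIN) * scale + DIG_MIN).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(signal_header)
        for r in range(n_records):
            block = digital[:, r * fs: (r + 1) * fs]
            fh.write(block.tobytes())  # channel-major within the record


def read_edf(path) -> EEGRecord:
    """Read an EDF file into an :class:`EEGRecord` in μV (via MNE)."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:
        raise ValueError(f"could not parse EDF file {path}: {exc}") from exc
    data = raw.get_data() * 1e6  # V -> μV
    return EEGRecord(data=data, sampling_rate=float(raw.info["sfreq"]),
                     channel_labels=list(raw.ch_names))


# ---------------------------------------------------------------------------
# annotation lists
# ---------------------------------------------------------------------------

_ANN_COLUMNS = ["onset_s", "duration_s", "subject_id", "period"]
_DET_COLUMNS = ["onset_s", "duration_s", "channel", "peak_probability"]


def write_annotations(events: list[SeizureAnnotation], path) -> None:
    """Write gold seizure annotations as a tab-separated event list."""
    with open(path, "w") as fh:
        fh.write("\t".join(_ANN_COLUMNS) + "\n")
        for a in sorted(events, key=lambda e: (e.subject_id, e.period, e.onset_s)):
            fh.write(f"{a.onset_s:.2f}\t{a.duration_s:.2f}\t{a.subject_id}\t{a.period}\n")


def read_annotations(path) -> list[SeizureAnnotation]:
    """Read a gold annotation list; warns on (but keeps) overlapping events."""
    import warnings

    events = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _ANN_COLUMNS:
            raise ValueError(f"{path}: expected header {_ANN_COLUMNS}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}")
            try:
                onset, dur = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}") from exc
            events.append(SeizureAnnotation(onset, dur, parts[2], parts[3]))
    by_key: dict[tuple[str, str], list[SeizureAnnotation]] = {}
    for e in events:
        by_key.setdefault((e.subject_id, e.period), []).append(e)
    for lst in by_key.values():
        lst.sort(key=lambda e: e.onset_s)
        for a, b in zip(lst, lst[1:]):
            if a.end_s > b.onset_s:
                warnings.warn(f"overlapping events at {a.onset_s:.2f}s and "
                              f"{b.onset_s:.2f}s retained", RuntimeWarning,
                              stacklevel=2)
    return events


def write_detections(events: list[DetectionEvent], path) -> None:
    """Write detector events (with peak probability) as a TSV list."""
    with open(path, "w") as fh:
        fh.write("\t".join(_DET_COLUMNS) + "\n")
        for d in sorted(events, key=lambda e: e.onset_s):
            fh.write(f"{d.onset_s:.2f}\t{d.duration_s:.2f}\t{d.channel}\t"
                     f"{d.peak_probability:.3f}\n")


def read_detections(path) -> list[DetectionEvent]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _DET_COLUMNS:
            raise ValueError(f"{path}: expected header {_DET_COLUMNS}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}")
            out.append(DetectionEvent(float(parts[0]), float(parts[1]),
                                      parts[2], float(parts[3])))
    return out


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

#: Output column per measurement, named after the clinical variables.
FEATURE_COLUMNS = {
    "subject_id": "subject_id",
    "period": "period",
    "onset_s": "onset_s",
    "peak_amplitude_uV": "peak_amplitude_uV",
    "rhythmicity_score": "rhythmicity_score",
    "background_score": "background_eeg_score",
    "morphology_onset": "morphology_at_onset",
    "morphology_peak": "morphology_at_peak",
    "duration_s": "duration_s",
    "frequency_variability_hz": "frequency_variability_hz",
    "morphology_changed": "morphology_changed",
    "channels_onset": "channels_involved_onset",
    "channels_peak": "channels_involved_peak",
}


def features_to_frame(features: list) -> pd.DataFrame:
    """One row per seizure, columns named after the clinical variables."""
    rows = []
    for f in features:
        rows.append({col: getattr(f, attr) for attr, col in FEATURE_COLUMNS.items()})
    return pd.DataFrame(rows, columns=list(FEATURE_COLUMNS.values()))


def write_feature_table(features: list, path) -> None:
    features_to_frame(features).to_csv(path, sep="\t", index=False)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
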