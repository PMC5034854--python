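"""Event-based scoring of detector output against gold annotations.

A gold seizure counts as detected when at least one detection event
overlaps it in time by at least one second (each gold seizure is counted
once no matter how many detections cover it); detections overlapping no
gold seizure are false detections.  The per-subject summary is the
detection rate (detected / gold) and the false-detection rate per hour.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import DetectionEvent, SeizureAnnotation

__all__ = ["EvalResult", "match_events", "detection_rate", "evaluate_events"]

MIN_OVERLAP_S = 1.0


@dataclass(frozen=True)
class EvalResult:
    """Detection performance for one subject in one period."""

    subject_id: str
    period: str
    n_gold: int
    n_detected: int
    detection_rate: float
    false_detections: int
    record_hours: float

    @property
    def fd_per_hour(self) -> float:
        return self.false_detections / self.record_hours if self.record_hours > 0 else 0.0


def match_events(gold: list[SeizureAnnotation],
                 detected: list[DetectionEvent],
                 min_overlap_s: float = MIN_OVERLAP_S
                 ) -> tuple[list[bool], list[DetectionEvent]]:
    """Per-gold detected flags plus the list of false detections.

    Every detection is either matched (to one or more gold seizures) or
    false, never both; every gold seizure is either detected or missed.
    """
    flags = []
    matched = [False] * len(detected)
    for g in gold:
        hit = False
        for i, d in enumerate(detected):
            if g.overlap_s(d) >= min_overlap_s:
                hit = True
                matched[i] = True
        flags.append(hit)
    false = [d for d, m in zip(detected, matched) if not m]
    return flags, false


def detection_rate(flags: list[bool]) -> float:
    """Proportion of gold seizures detected."""
    if not flags:
        raise ValueError("detection rate undefined without gold seizures")
    return sum(flags) / len(flags)


def evaluate_events(gold: list[SeizureAnnotation],
                    detected: list[DetectionEvent],
                    record_hours: float,
                    subject_id: str = "", period: str = "") -> EvalResult:
    """Full event-based score for one record."""
    flags, false = match_events(gold, detected)
    return EvalResult(
        subject_id=subject_id, period=period,
        n_gold=len(flags), n_detected=sum(flags),
        detection_rate=detection_rate(flags),
        false_detections=len(false), record_hours=record_hours,
    )
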