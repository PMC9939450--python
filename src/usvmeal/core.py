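"""Shared domain types and vocabularies.

The package analyses rat ultrasonic vocalisations (USVs) recorded with an
ultrasonic microphone (384 kHz sampling) during a two-phase experimental
meal: a 10 min *anticipation* phase (food present but inaccessible) and a
10 min *consumption* phase.  Behaviour is annotated by scan sampling at 1 s
resolution against a fixed ethogram of mutually exclusive categories; USVs
are point events with a subtype label and a median frequency on a 5 kHz
grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

#: Ethogram of mutually exclusive behaviours scored by 1-s scan sampling.
#: "Feeding" can only occur in the consumption phase (food is locked in a
#: tea ball during anticipation).
BEHAVIORS: tuple[str, ...] = (
    "Up explore",
    "Down explore",
    "Sniff food",
    "Move",
    "Grooming",
    "Dig litter",
    "Rearing",
    "Lying down",
    "Immobile",
    "Feeding",
)

#: Behaviours allowed in the anticipation phase (all but Feeding).
ANTICIPATION_BEHAVIORS: tuple[str, ...] = tuple(
    b for b in BEHAVIORS if b != "Feeding"
)

#: The 14 USV subtypes of the amphetamine-call taxonomy used for visual
#: classification of 50 kHz-family calls.
SUBTYPES: tuple[str, ...] = (
    "flat",
    "short",
    "upward ramp",
    "downward ramp",
    "step up",
    "step down",
    "multi-step",
    "trill",
    "trill with jumps",
    "split",
    "inverted U",
    "flat-trill combination",
    "composite",
    "complex",
)

PHASES: tuple[str, ...] = ("anticipation", "consumption")

#: USV inclusion criteria: peak frequency band (kHz), duration (ms) and
#: minimum inter-event gap (ms).
USV_BAND_KHZ: tuple[float, float] = (20.0, 100.0)
USV_DURATION_MS: tuple[float, float] = (10.0, 150.0)
USV_MIN_GAP_MS: float = 20.0


def canonical_behavior(label: str) -> str:
    """Map a case/spacing-insensitive behaviour label to its canonical form.

    Raises ``ValueError`` for labels outside the ethogram.
    """
    key = " ".join(label.strip().lower().split())
    for b in BEHAVIORS:
        if key == b.lower():
            return b
    raise ValueError(f"unknown behavior label: {label!r}")


@dataclass
class UsvEvent:
    """One ultrasonic vocalisation.

    Times are seconds from the start of the phase, on whichever clock the
    event currently lives (audio clock at detection, video clock after
    synchronisation).  ``trajectory_khz`` is the per-frame peak-frequency
    trace in kHz; ``median_freq_khz`` is its median rounded to the nearest
    multiple of 5 kHz.
    """

    session_id: str
    onset_s: float
    offset_s: float
    subtype: Optional[str] = None
    median_freq_khz: Optional[float] = None
    bandwidth_khz: Optional[float] = None
    chew_overlap: bool = False
    trajectory_khz: Optional[np.ndarray] = None
    true_behavior: Optional[str] = None  # ground truth, synthetic data only

    @property
    def duration_ms(self) -> float:
        return (self.offset_s - self.onset_s) * 1000.0

    def shifted(self, delta_s: float) -> "UsvEvent":
        return replace(
            self, onset_s=self.onset_s + delta_s, offset_s=self.offset_s + delta_s
        )


@dataclass
class BehaviorScan:
    """Scan-sampled behaviour sequence for one session phase.

    One label per 1-s bin; bins are half-open ``[k, k+1)`` seconds from
    phase start, so a 10 min phase has exactly 600 labels.
    """

    session_id: str
    phase: str
    labels: Sequence[str]
    bin_s: float = 1.0

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")
        self.labels = [canonical_behavior(l) for l in self.labels]
        if self.phase == "anticipation" and "Feeding" in self.labels:
            raise ValueError("Feeding cannot occur in the anticipation phase")

    @property
    def duration_s(self) -> float:
        return len(self.labels) * self.bin_s

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class SyncOffset:
    """Audio-minus-video clock offset for one session (seconds).

    The video is the behaviour reference frame; subtracting ``offset_s``
    moves audio event times onto the video clock.  Video timing resolution
    is one frame, 40 ms.
    """

    session_id: str
    offset_s: float
    video_resolution_s: float = 0.040


@dataclass
class Session:
    """One rat x phase: events, scan, synchronisation and diet label."""

    session_id: str
    rat_id: str
    phase: str
    events: list[UsvEvent] = field(default_factory=list)
    scan: Optional[BehaviorScan] = None
    sync: Optional[SyncOffset] = None
    diet: Optional[str] = None
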