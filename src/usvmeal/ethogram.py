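"""Scan-sampled behaviour sequences and USV x behaviour co-occurrence.

The video is the behaviour reference frame: audio event times are moved
onto the video clock by subtracting the per-session audio-minus-video
offset.  A call co-occurs with the behaviour of the 1 s scan bin containing
its *onset* (bins are half-open ``[k, k+1)``); a midpoint convention is
available for sensitivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    BEHAVIORS,
    SUBTYPES,
    BehaviorScan,
    Session,
    SyncOffset,
    UsvEvent,
    canonical_behavior,
)

__all__ = [
    "CooccurrenceCount",
    "apply_sync",
    "behavior_at",
    "count_cooccurrences",
    "scan_summary",
    "read_scans",
    "write_scans",
    "read_sync_table",
    "build_sessions",
]


@dataclass
class CooccurrenceCount:
    """Subtype x behaviour contingency matrix for one session."""

    matrix: pd.DataFrame  # index: subtypes, columns: behaviours, int counts
    session_id: str

    @property
    def total(self) -> int:
        return int(self.matrix.to_numpy().sum())


def empty_matrix(
    subtypes: Sequence[str] = SUBTYPES, behaviors: Sequence[str] = BEHAVIORS
) -> pd.DataFrame:
    return pd.DataFrame(
        np.zeros((len(subtypes), len(behaviors)), dtype=int),
        index=list(subtypes),
        columns=list(behaviors),
    )


def apply_sync(
    events: Sequence[UsvEvent],
    sync: SyncOffset,
    phase_duration_s: Optional[float] = None,
) -> list[UsvEvent]:
    """Shift audio-clock events onto the video clock (times minus offset).

    Events whose shifted onset leaves ``[0, phase_duration_s)`` are excluded
    with a warning; order is preserved.
    """
    out: list[UsvEvent] = []
    for e in events:
        shifted = e.shifted(-sync.offset_s)
        if shifted.onset_s < 0 or (
            phase_duration_s is not None and shifted.onset_s >= phase_duration_s
        ):
            warnings.warn(
                f"event at {e.onset_s:.3f}s falls outside the phase after "
                f"synchronisation; excluded"
            )
            continue
        out.append(shifted)
    return out


def behavior_at(
    event: UsvEvent,
    scan: BehaviorScan,
    convention: Literal["onset", "midpoint"] = "onset",
) -> str:
    """Behaviour of the scan bin containing the event onset (or midpoint)."""
    t = (
        event.onset_s
        if convention == "onset"
        else 0.5 * (event.onset_s + event.offset_s)
    )
    k = int(np.floor(t / scan.bin_s))
    if not 0 <= k < len(scan.labels):
        raise ValueError(
            f"event time {t:.3f}s outside the scan span [0, {scan.duration_s:.0f})"
        )
    return scan.labels[k]


def count_cooccurrences(
    session: Session,
    convention: Literal["onset", "midpoint"] = "onset",
    subtypes: Sequence[str] = SUBTYPES,
) -> CooccurrenceCount:
    """Tally events by (subtype, behaviour-at-onset).

    The grand total always equals the session's event count.
    """
    if session.scan is None:
        raise ValueError(f"session {session.session_id} has no behaviour scan")
    mat = empty_matrix(subtypes=subtypes)
    for e in session.events:
        if e.subtype is None:
            raise ValueError("event without a subtype label")
        b = behavior_at(e, session.scan, convention=convention)
        mat.loc[e.subtype, b] += 1
    return CooccurrenceCount(matrix=mat, session_id=session.session_id)


def scan_summary(scan: BehaviorScan) -> pd.DataFrame:
    """Per-behaviour bin counts and fractions (fractions sum to 1)."""
    counts = pd.Series(scan.labels).value_counts()
    counts = counts.reindex(BEHAVIORS, fill_value=0)
    return pd.DataFrame(
        {"count": counts.astype(int), "fraction": counts / len(scan)}
    )


# ---------------------------------------------------------------------------
# file formats


def write_scans(scans: Sequence[BehaviorScan], path: str | Path) -> None:
    """Long-format scan CSV: session_id, phase, bin_index, behavior."""
    rows = []
    for s in scans:
        for k, b in enumerate(s.labels):
            rows.append((s.session_id, s.phase, k, b))
    pd.DataFrame(
        rows, columns=["session_id", "phase", "bin_index", "behavior"]
    ).to_csv(path, index=False)


def read_scans(path: str | Path) -> list[BehaviorScan]:
    """Read and validate scan CSVs (behaviour labels are case-insensitive)."""
    df = pd.read_csv(path)
    required = {"session_id", "phase", "bin_index", "behavior"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"scan file {path} lacks columns: {sorted(missing)}")
    scans = []
    for sid, grp in df.groupby("session_id", sort=True):
        grp = grp.sort_values("bin_index")
        expected = np.arange(len(grp))
        if not np.array_equal(grp["bin_index"].to_numpy(), expected):
            raise ValueError(f"session {sid}: bin_index must be 0..n-1 contiguous")
        phases = grp["phase"].unique()
        if len(phases) != 1:
            raise ValueError(f"session {sid}: mixed phases in one scan")
        scans.append(
            BehaviorScan(
                session_id=str(sid),
                phase=str(phases[0]),
                labels=[canonical_behavior(b) for b in grp["behavior"]],
            )
        )
    return scans


def build_sessions(
    events: pd.DataFrame,
    scans: Sequence[BehaviorScan],
    sync: Optional[dict[str, SyncOffset]] = None,
) -> list[Session]:
    """Assemble Session objects from an event table and scan sequences.

    The event table needs ``session_id, onset_s, offset_s, subtype`` (plus
    optional ``median_freq_khz``, ``rat_id``, ``phase``, ``diet``); when
    rat/phase columns are absent they are parsed from ``session_id`` of the
    form ``<rat>-<phase>``.  Events are moved onto the video clock when a
    sync offset exists for the session.  Scans with no event rows still
    yield (empty) sessions; event session_ids without a scan raise.
    """
    from .synthdata import frame_to_events  # local import avoids a cycle

    scan_by_id = {s.session_id: s for s in scans}
    unknown = set(events["session_id"].astype(str)) - set(scan_by_id)
    if unknown:
        raise ValueError(
            f"event table references sessions with no scan: {sorted(unknown)}"
        )
    sessions = []
    for sid, scan in scan_by_id.items():
        grp = events[events["session_id"].astype(str) == sid]
        evs = frame_to_events(grp) if len(grp) else []
        if "rat_id" in grp.columns and len(grp):
            rat = str(grp["rat_id"].iloc[0])
        else:
            rat = sid.rsplit("-", 1)[0]
        diet = str(grp["diet"].iloc[0]) if "diet" in grp.columns and len(grp) else None
        off = (sync or {}).get(sid)
        if off is not None:
            evs = apply_sync(evs, off, phase_duration_s=scan.duration_s)
        sessions.append(
            Session(
                session_id=sid,
                rat_id=rat,
                phase=scan.phase,
                events=evs,
                scan=scan,
                sync=off,
                diet=diet,
            )
        )
    return sessions


def read_sync_table(path: str | Path) -> dict[str, SyncOffset]:
    """Sync CSV: session_id, offset_s (audio clock minus video clock)."""
    df = pd.read_csv(path)
    required = {"session_id", "offset_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sync file {path} lacks columns: {sorted(missing)}")
    return {
        str(r.session_id): SyncOffset(
            session_id=str(r.session_id), offset_s=float(r.offset_s)
        )
        for r in df.itertuples(index=False)
    }
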