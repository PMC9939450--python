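"""Spectrogram-based USV and chew-click detection and subtype classification.

Calls are detected on a short-time Fourier spectrogram (Hanning window of
1024 samples at a 384 kHz sampling rate, i.e. 375 Hz frequency bins) as
connected regions of bins exceeding an adaptive per-frequency noise floor
inside the 20-100 kHz search band.  Candidates closer than 20 ms are merged,
then the inclusion criteria are applied: duration 10-150 ms and peak
frequency 20-100 kHz.  Each accepted call carries a per-frame
peak-frequency trajectory from which the median frequency (nearest 5 kHz)
and the subtype label are derived.

Pellet-crack chewing clicks appear as near-instantaneous broadband
transients (vertical lines spanning the whole 0-192 kHz range); they are
detected as isolated frames whose above-threshold bins cover most of the
spectrum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .core import (
    USV_BAND_KHZ,
    USV_DURATION_MS,
    USV_MIN_GAP_MS,
    UsvEvent,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SpectrogramParams",
    "ClassifierConfig",
    "Spectrogram",
    "Candidate",
    "ChewClick",
    "compute_spectrogram",
    "detect_events",
    "filter_usv_candidates",
    "estimate_median_frequency",
    "classify_subtype",
    "detect_chew_clicks",
    "flag_chew_overlap",
    "detect_session",
    "events_table",
    "clicks_table",
    "audacity_labels",
]


@dataclass
class SpectrogramParams:
    """STFT and detection settings."""

    sample_rate: int = 384_000
    window: str = "hann"
    window_length: int = 1024
    hop: int = 512
    detection_threshold_db: float = 12.0   # above per-frequency median floor
    band_low_khz: float = USV_BAND_KHZ[0]
    band_high_khz: float = USV_BAND_KHZ[1]
    click_min_coverage: float = 0.8        # fraction of 0-Nyquist bins lit
    # a sub-ms transient can overlap up to ceil((burst + window)/hop) = 3
    # consecutive 50%-overlapped windows
    click_max_frames: int = 3
    # frames with this much broadband coverage (plus one neighbour either
    # side) are blanked before USV segmentation: the spectral skirts of a
    # pellet crack otherwise masquerade as brief calls
    click_exclude_coverage: float = 0.4
    # components narrower than this many frames cannot be calls (a 10 ms
    # minimum-duration call spans ~7 frames); mostly prunes noise specks
    min_component_frames: int = 3

    def __post_init__(self) -> None:
        if self.hop > self.window_length:
            raise ValueError("hop must not exceed the window length")
        nyq = self.sample_rate / 2000.0
        if not (0 <= self.band_low_khz < self.band_high_khz <= nyq):
            raise ValueError("require 0 <= band_low < band_high <= Nyquist (kHz)")

    @property
    def bin_hz(self) -> float:
        return self.sample_rate / self.window_length

    @property
    def frame_step_s(self) -> float:
        return self.hop / self.sample_rate


@dataclass
class ClassifierConfig:
    """Thresholds of the subtype decision cascade (the source taxonomy is
    visual; these operationalise it)."""

    short_max_ms: float = 12.0
    flat_band_khz: float = 5.0
    jump_khz: float = 10.0
    min_oscillations: int = 2      # full FM cycles required for a trill
    osc_prominence_khz: float = 2.0
    max_period_cv: float = 0.4     # quasi-period: cv of inter-extremum spacing
    ramp_min_khz: float = 5.0


@dataclass
class Spectrogram:
    """Power spectrogram in dB with its axes."""

    power_db: np.ndarray          # (n_freqs, n_frames)
    freqs_hz: np.ndarray
    times_s: np.ndarray
    params: SpectrogramParams


@dataclass
class Candidate:
    """A connected above-threshold region reduced to a trajectory."""

    onset_s: float
    offset_s: float
    trajectory_khz: np.ndarray    # per-frame peak frequency

    @property
    def duration_ms(self) -> float:
        return (self.offset_s - self.onset_s) * 1000.0


@dataclass
class ChewClick:
    """One broadband pellet-crack transient."""

    session_id: str
    time_s: float
    duration_ms: float
    band_coverage: float


def compute_spectrogram(waveform: np.ndarray, params: SpectrogramParams) -> Spectrogram:
    """STFT power in dB full scale (a full-scale sine peaks near 0 dB)."""
    x = np.asarray(waveform, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("waveform must be mono (1-D)")
    if len(x) < params.window_length:
        raise ValueError("waveform shorter than one analysis window")
    win = signal.get_window(params.window, params.window_length)
    sft = signal.ShortTimeFFT(
        win, hop=params.hop, fs=params.sample_rate, scale_to="magnitude"
    )
    S = sft.stft(x)
    # one-sided magnitude of a sine of amplitude A is A/2: rescale so dB is
    # relative to full scale
    power = (2.0 * np.abs(S)) ** 2
    power_db = 10.0 * np.log10(np.maximum(power, 1e-20))
    times = sft.t(len(x))
    return Spectrogram(
        power_db=power_db.astype(np.float32),
        freqs_hz=sft.f,
        times_s=times,
        params=params,
    )


def _noise_floor_db(spec: Spectrogram) -> np.ndarray:
    """Adaptive per-frequency noise floor: the median over frames."""
    return np.median(spec.power_db, axis=1)


def _click_frames(spec: Spectrogram) -> tuple[np.ndarray, np.ndarray]:
    """(boolean frame mask, per-frame band coverage) for broadband frames."""
    p = spec.params
    floor = _noise_floor_db(spec)
    above = spec.power_db > (floor[:, None] + p.detection_threshold_db)
    coverage = above.mean(axis=0)
    return coverage >= p.click_min_coverage, coverage


def detect_events(
    spec: Spectrogram, exclude_frames: Optional[np.ndarray] = None
) -> list[Candidate]:
    """Connected-component detection inside the USV search band.

    ``exclude_frames`` (e.g. chew-click frames) are blanked before
    segmentation so broadband transients do not bridge or distort call
    trajectories.
    """
    p = spec.params
    floor = _noise_floor_db(spec)
    fk = spec.freqs_hz / 1000.0
    band = (fk >= p.band_low_khz) & (fk <= p.band_high_khz)
    band_idx = np.where(band)[0]
    sub = spec.power_db[band_idx, :]
    mask = sub > (floor[band_idx, None] + p.detection_threshold_db)
    if exclude_frames is not None:
        mask[:, exclude_frames] = False

    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return []
    out: list[Candidate] = []
    objects = ndimage.find_objects(labels)
    for lab, slc in enumerate(objects, start=1):
        rows, cols = slc
        if cols.stop - cols.start < p.min_component_frames:
            continue
        comp = labels[rows, cols] == lab
        power = np.where(comp, sub[rows, cols], -np.inf)
        traj = []
        for j in range(power.shape[1]):
            col = power[:, j]
            if np.all(np.isinf(col)):
                traj.append(np.nan)
            else:
                traj.append(fk[band_idx[rows]][int(np.argmax(col))])
        traj = (
            pd.Series(traj).interpolate(limit_direction="both").to_numpy()
        )
        # sub-frame endpoints: interpolate the -12 dB crossing of the
        # per-frame peak power, then push each endpoint outward by a
        # quarter window -- a threshold crossing on a tapered call onset
        # sits inward by about that much
        c0, c1 = cols.start, cols.stop - 1
        step = p.frame_step_s
        edge = p.window_length / p.sample_rate / 4.0
        pw = power.max(axis=0)
        thr_db = pw.max() - 12.0
        above = np.where(pw >= thr_db)[0]
        j0, j1 = int(above[0]), int(above[-1])
        onset = float(spec.times_s[c0 + j0])
        if j0 > 0 and np.isfinite(pw[j0 - 1]):
            frac = (thr_db - pw[j0 - 1]) / (pw[j0] - pw[j0 - 1])
            onset = float(spec.times_s[c0 + j0 - 1]) + float(frac) * step
        offset = float(spec.times_s[c0 + j1])
        if j1 < len(pw) - 1 and np.isfinite(pw[j1 + 1]):
            frac = (thr_db - pw[j1 + 1]) / (pw[j1] - pw[j1 + 1])
            offset = float(spec.times_s[c0 + j1 + 1]) - float(frac) * step
        onset -= edge
        offset += edge
        out.append(
            Candidate(
                onset_s=max(0.0, onset), offset_s=offset, trajectory_khz=traj
            )
        )
    out.sort(key=lambda c: c.onset_s)
    return out


def filter_usv_candidates(
    candidates: Sequence[Candidate],
    min_gap_ms: float = USV_MIN_GAP_MS,
    duration_ms: tuple[float, float] = USV_DURATION_MS,
    band_khz: tuple[float, float] = USV_BAND_KHZ,
) -> list[Candidate]:
    """Merge sub-gap candidates, then apply the USV inclusion criteria.

    Candidates separated by less than ``min_gap_ms`` are one call by the
    distinctness rule and are merged (the gap is bridged); the merged set is
    then filtered on duration and on peak frequency staying within the
    search band.  The operation is idempotent.
    """
    cands = sorted(candidates, key=lambda c: c.onset_s)
    merged: list[Candidate] = []
    for c in cands:
        if merged and (c.onset_s - merged[-1].offset_s) * 1000.0 < min_gap_ms:
            prev = merged[-1]
            gap_frames = max(
                0,
                int(round((c.onset_s - prev.offset_s) / 0.001)),
            )
            bridge = np.linspace(
                prev.trajectory_khz[-1], c.trajectory_khz[0], gap_frames + 2
            )[1:-1]
            merged[-1] = Candidate(
                onset_s=prev.onset_s,
                offset_s=max(prev.offset_s, c.offset_s),
                trajectory_khz=np.concatenate(
                    [prev.trajectory_khz, bridge, c.trajectory_khz]
                ),
            )
        else:
            merged.append(c)
    out = []
    for c in merged:
        if not (duration_ms[0] <= c.duration_ms <= duration_ms[1]):
            med = float(np.median(c.trajectory_khz))
            if c.duration_ms > duration_ms[1] and med < 30.0:
                logger.warning(
                    "rejected long low-frequency event (%.0f ms, %.0f kHz) "
                    "at %.2f s; possible 22 kHz long call",
                    c.duration_ms, med, c.onset_s,
                )
            continue
        peak = float(np.median(c.trajectory_khz))
        if not (band_khz[0] <= peak <= band_khz[1]):
            continue
        out.append(c)
    return out


def _round5(x: float) -> float:
    return 5.0 * np.floor(x / 5.0 + 0.5)


def estimate_median_frequency(trajectory_khz: np.ndarray) -> float:
    """Median of the trajectory projected on the frequency axis, to the
    nearest multiple of 5 kHz (ties round half-up)."""
    traj = np.asarray(trajectory_khz, dtype=float)
    if traj.size == 0:
        raise ValueError("empty trajectory")
    return float(_round5(float(np.median(traj))))


def _find_jumps(traj: np.ndarray, jump_khz: float) -> list[tuple[int, float]]:
    """Abrupt frequency jumps as (position, signed size), lag-2 differences
    clustered so one physical jump is reported once."""
    if len(traj) < 3:
        return []
    d2 = traj[2:] - traj[:-2]
    idx = np.where(np.abs(d2) >= jump_khz)[0]
    jumps: list[tuple[int, float]] = []
    i = 0
    while i < len(idx):
        j = i
        while j + 1 < len(idx) and idx[j + 1] - idx[j] <= 2:
            j += 1
        center = int(idx[(i + j) // 2]) + 1
        jumps.append((center, float(d2[idx[(i + j) // 2]])))
        i = j + 1
    return jumps


def _extrema(traj: np.ndarray, prominence: float) -> tuple[np.ndarray, np.ndarray]:
    peaks, _ = signal.find_peaks(traj, prominence=prominence)
    troughs, _ = signal.find_peaks(-traj, prominence=prominence)
    return peaks, troughs


def _oscillation_cycles(seg: np.ndarray, cfg: "ClassifierConfig") -> float:
    """Number of FM cycles, or 0 if the extrema are not quasi-periodic."""
    peaks, troughs = _extrema(seg, cfg.osc_prominence_khz)
    ext = np.sort(np.concatenate([peaks, troughs]))
    if len(ext) >= 3:
        spacing = np.diff(ext)
        if spacing.mean() > 0 and spacing.std() / spacing.mean() > cfg.max_period_cv:
            return 0.0
    return len(ext) / 2.0


def classify_subtype(
    trajectory_khz: np.ndarray,
    duration_ms: float,
    config: Optional[ClassifierConfig] = None,
) -> str:
    """Decision cascade on trajectory statistics.

    Order: short (duration), jump-family (step up/down, multi-step, split,
    trill with jumps), flat (bandwidth), trill (oscillation count),
    inverted U, ramps, composite; anything left is complex.  Always returns
    a label.
    """
    cfg = config or ClassifierConfig()
    traj = np.asarray(trajectory_khz, dtype=float)
    if traj.size == 0:
        raise ValueError("empty trajectory")
    if duration_ms < cfg.short_max_ms:
        return "short"
    smooth = ndimage.median_filter(traj, size=3, mode="nearest")
    jumps = _find_jumps(smooth, cfg.jump_khz)

    if jumps:
        cuts = [0] + [pos for pos, _ in jumps] + [len(smooth)]
        segments = [smooth[a:b] for a, b in zip(cuts[:-1], cuts[1:])]
        segments = [s for s in segments if len(s) >= 2]
        oscillating = any(
            _oscillation_cycles(s, cfg) >= 1.0 for s in segments if len(s) >= 5
        )
        if oscillating:
            return "trill with jumps"
        if len(jumps) == 1:
            return "step up" if jumps[0][1] > 0 else "step down"
        levels = [float(np.median(s)) for s in segments]
        if (
            len(levels) >= 2
            and abs(levels[-1] - levels[0]) < cfg.jump_khz / 2
            and sum(len(s) for s in segments[1:-1]) <= 0.4 * len(smooth)
        ):
            return "split"
        return "multi-step"

    bandwidth = float(smooth.max() - smooth.min())
    if bandwidth <= cfg.flat_band_khz:
        return "flat"

    peaks, troughs = _extrema(smooth, cfg.osc_prominence_khz)
    n_extrema = len(peaks) + len(troughs)
    if _oscillation_cycles(smooth, cfg) >= cfg.min_oscillations:
        # a leading flat portion before the oscillation = flat-trill combo
        first = min(np.concatenate([peaks, troughs]))
        head = smooth[: max(first - 2, 0)]
        if (
            len(head) >= 0.35 * len(smooth)
            and head.size
            and head.max() - head.min() <= cfg.flat_band_khz / 2
        ):
            return "flat-trill combination"
        return "trill"
    if n_extrema == 1 and len(peaks) == 1:
        pos = peaks[0] / len(smooth)
        rise = smooth[peaks[0]] - smooth[0]
        fall = smooth[peaks[0]] - smooth[-1]
        if 0.15 < pos < 0.85 and rise > cfg.flat_band_khz / 2 and fall > cfg.flat_band_khz / 2:
            return "inverted U"

    net = float(smooth[-1] - smooth[0])
    if abs(net) >= max(cfg.ramp_min_khz, bandwidth / 2):
        start_level = smooth[0]
        plateau = np.mean(np.abs(smooth - start_level) <= cfg.flat_band_khz / 2)
        if plateau >= 0.4 and abs(net) >= cfg.ramp_min_khz:
            return "composite"
        return "upward ramp" if net > 0 else "downward ramp"
    return "complex"


def detect_chew_clicks(spec: Spectrogram, session_id: str = "") -> list[ChewClick]:
    """Frames whose above-threshold bins span most of 0-Nyquist.

    Runs of more than ``click_max_frames`` consecutive broadband frames are
    too long for a pellet crack and are ignored.  The reported duration is
    the frame support (the physical transient is shorter than one frame).
    """
    p = spec.params
    is_click, coverage = _click_frames(spec)
    out: list[ChewClick] = []
    idx = np.where(is_click)[0]
    if idx.size == 0:
        return out
    runs = np.split(idx, np.where(np.diff(idx) > 1)[0] + 1)
    for run in runs:
        if len(run) > p.click_max_frames:
            continue
        t = float(np.mean(spec.times_s[run]))
        out.append(
            ChewClick(
                session_id=session_id,
                time_s=t,
                duration_ms=len(run) * p.frame_step_s * 1000.0,
                band_coverage=float(coverage[run].max()),
            )
        )
    return out


def flag_chew_overlap(
    events: Sequence[UsvEvent], clicks: Sequence[ChewClick] | Sequence[float]
) -> list[UsvEvent]:
    """Set ``chew_overlap`` where at least one click falls inside the call."""
    times = np.asarray(
        [c.time_s if isinstance(c, ChewClick) else float(c) for c in clicks]
    )
    out = []
    for e in events:
        hit = bool(np.any((times >= e.onset_s) & (times <= e.offset_s))) if times.size else False
        e.chew_overlap = hit
        out.append(e)
    return out


def detect_session(
    waveform: np.ndarray,
    params: Optional[SpectrogramParams] = None,
    classifier: Optional[ClassifierConfig] = None,
    session_id: str = "",
) -> tuple[list[UsvEvent], list[ChewClick]]:
    """Full per-session pipeline: spectrogram -> clicks -> calls -> labels."""
    params = params or SpectrogramParams()
    spec = compute_spectrogram(waveform, params)
    clicks = detect_chew_clicks(spec, session_id=session_id)
    _, coverage = _click_frames(spec)
    exclude = ndimage.binary_dilation(
        coverage >= params.click_exclude_coverage, iterations=1
    )
    candidates = detect_events(spec, exclude_frames=exclude)
    accepted = filter_usv_candidates(candidates)
    events = []
    for c in accepted:
        events.append(
            UsvEvent(
                session_id=session_id,
                onset_s=c.onset_s,
                offset_s=c.offset_s,
                subtype=classify_subtype(c.trajectory_khz, c.duration_ms, classifier),
                median_freq_khz=estimate_median_frequency(c.trajectory_khz),
                bandwidth_khz=float(
                    np.max(c.trajectory_khz) - np.min(c.trajectory_khz)
                ),
                trajectory_khz=c.trajectory_khz,
            )
        )
    events = flag_chew_overlap(events, clicks)
    return events, clicks


# ---------------------------------------------------------------------------
# tabular output


def events_table(events: Sequence[UsvEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "session_id": [e.session_id for e in events],
            "onset_s": [e.onset_s for e in events],
            "offset_s": [e.offset_s for e in events],
            "duration_ms": [e.duration_ms for e in events],
            "median_freq_khz": [e.median_freq_khz for e in events],
            "bandwidth_khz": [e.bandwidth_khz for e in events],
            "subtype": [e.subtype for e in events],
            "chew_overlap": [e.chew_overlap for e in events],
        }
    )


def clicks_table(clicks: Sequence[ChewClick]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "session_id": [c.session_id for c in clicks],
            "time_s": [c.time_s for c in clicks],
            "duration_ms": [c.duration_ms for c in clicks],
            "band_coverage": [c.band_coverage for c in clicks],
        }
    )


def audacity_labels(events: Sequence[UsvEvent]) -> str:
    """Audacity label track (tab separated: start, end, label) for audit."""
    lines = [
        f"{e.onset_s:.6f}\t{e.offset_s:.6f}\t{e.subtype or 'usv'}" for e in events
    ]
    return "\n".join(lines) + ("\n" if lines else "")
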