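"""Synthetic sessions with known ground truth.

Emulates the structure the analysis assumes: a semi-Markov behaviour
process scan-sampled at 1 s, USV point events whose rate and subtype mixture
depend on the concurrent behaviour, broadband chewing clicks during feeding
bins, and 384 kHz audio in which each call is a tonal component following
its subtype's frequency trajectory.

``association_strength`` interpolates the per-event subtype mixture between
a single global mixture (0, the null: subtype independent of behaviour) and
fully behaviour-specific mixtures (1).  This is exactly the association
structure the Monte Carlo time-shuffling test is designed to detect, so the
generator doubles as the calibration and power harness for that test.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .core import (
    ANTICIPATION_BEHAVIORS,
    BEHAVIORS,
    PHASES,
    SUBTYPES,
    BehaviorScan,
    Session,
    UsvEvent,
)

__all__ = [
    "SyntheticScenario",
    "generate_behavior_scan",
    "generate_usv_events",
    "generate_chew_clicks",
    "generate_session",
    "synthesize_audio",
    "write_wav",
    "read_wav",
    "events_to_frame",
    "frame_to_events",
    "write_events",
    "read_events",
]

# ---------------------------------------------------------------------------
# defaults

#: Mean bout (dwell) duration per behaviour, seconds.  Bouts are
#: exponentially distributed, so scans carry realistic run-lengths instead
#: of i.i.d. per-second draws.
DEFAULT_DWELL_S: dict[str, float] = {
    "Up explore": 8.0,
    "Down explore": 10.0,
    "Sniff food": 5.0,
    "Move": 3.0,
    "Grooming": 10.0,
    "Dig litter": 5.0,
    "Rearing": 3.0,
    "Lying down": 15.0,
    "Immobile": 10.0,
    "Feeding": 25.0,
}

#: Relative preference weights used to build the default embedded
#: transition matrix (row i: probabilities proportional to the weights of
#: the other states).  Feeding is weighted so that it occupies roughly half
#: of the consumption-phase bins, as in a motivated post-fast meal.
_TRANSITION_WEIGHTS: dict[str, float] = {
    "Up explore": 2.0,
    "Down explore": 2.0,
    "Sniff food": 1.0,
    "Move": 1.5,
    "Grooming": 1.0,
    "Dig litter": 0.3,
    "Rearing": 0.5,
    "Lying down": 0.7,
    "Immobile": 1.0,
    "Feeding": 6.0,
}

#: USV emission rate while each behaviour is ongoing, events/min.  The
#: source study reports no per-behaviour rates; these give session totals of
#: roughly 40-60 calls per 10 min phase, the observed order of magnitude.
DEFAULT_USV_RATE: dict[str, float] = {
    "Up explore": 6.0,
    "Down explore": 5.0,
    "Sniff food": 4.0,
    "Move": 3.0,
    "Grooming": 2.0,
    "Dig litter": 1.0,
    "Rearing": 2.0,
    "Lying down": 2.0,
    "Immobile": 2.0,
    "Feeding": 7.0,
}

#: Global subtype mixture (the null mixture): short, flat and multi-step
#: dominate, as in the observed subtype abundance ranking.
DEFAULT_GLOBAL_MIXTURE: dict[str, float] = {
    "flat": 0.20,
    "short": 0.22,
    "upward ramp": 0.07,
    "downward ramp": 0.09,
    "step up": 0.05,
    "step down": 0.04,
    "multi-step": 0.15,
    "trill": 0.07,
    "trill with jumps": 0.002,
    "split": 0.04,
    "inverted U": 0.03,
    "flat-trill combination": 0.008,
    "composite": 0.01,
    "complex": 0.02,
}

#: Multiplicative boosts applied to the global mixture to obtain the
#: behaviour-specific mixtures active at association_strength = 1.  They
#: mirror the qualitative association pattern of interest: flats with
#: feeding, trills when lying down, frequency-modulated calls during upward
#: exploration, multi-steps when immobile.
_BEHAVIOR_MIXTURE_BOOSTS: dict[str, dict[str, float]] = {
    "Feeding": {"flat": 6.0, "short": 1.5, "multi-step": 0.2, "split": 0.2,
                "step up": 0.2},
    "Immobile": {"multi-step": 3.0, "flat": 0.2},
    "Lying down": {"trill": 5.0},
    "Up explore": {"split": 4.0, "upward ramp": 2.5, "inverted U": 2.5,
                   "flat": 0.3},
    "Down explore": {"step up": 3.0},
}

#: Per-subtype frequency-trajectory parameters (kHz / ms).  The taxonomy is
#: visual; numeric shapes are configuration, not constants of nature.
DEFAULT_SUBTYPE_SHAPES: dict[str, dict] = {
    "flat": {"f0_khz": [36.0, 44.0], "dur_ms": [30.0, 100.0]},
    "short": {"f0_khz": [45.0, 65.0], "dur_ms": [10.0, 11.9]},
    "upward ramp": {"f0_khz": [38.0, 50.0], "extent_khz": 20.0,
                    "dur_ms": [30.0, 80.0]},
    "downward ramp": {"f0_khz": [58.0, 75.0], "extent_khz": 20.0,
                      "dur_ms": [30.0, 80.0]},
    "step up": {"f0_khz": [40.0, 55.0], "jump_khz": 15.0,
                "dur_ms": [40.0, 80.0]},
    "step down": {"f0_khz": [55.0, 70.0], "jump_khz": 15.0,
                  "dur_ms": [40.0, 80.0]},
    "multi-step": {"f0_khz": [35.0, 45.0], "jump_khz": 15.0, "n_jumps": 2,
                   "dur_ms": [50.0, 100.0]},
    "trill": {"f0_khz": [50.0, 60.0], "fm_period_ms": 15.0,
              "fm_depth_khz": 5.0, "dur_ms": [45.0, 120.0]},
    "trill with jumps": {"f0_khz": [50.0, 60.0], "fm_period_ms": 15.0,
                         "fm_depth_khz": 5.0, "jump_khz": 15.0,
                         "dur_ms": [45.0, 120.0]},
    "split": {"f0_khz": [45.0, 55.0], "jump_khz": 15.0,
              "excursion_frac": 0.2, "dur_ms": [40.0, 80.0]},
    "inverted U": {"f0_khz": [40.0, 50.0], "height_khz": [10.0, 18.0],
                   "dur_ms": [30.0, 80.0]},
    "flat-trill combination": {"f0_khz": [45.0, 55.0], "fm_period_ms": 15.0,
                               "fm_depth_khz": 5.0, "dur_ms": [60.0, 120.0]},
    "composite": {"f0_khz": [40.0, 50.0], "extent_khz": 15.0,
                  "dur_ms": [60.0, 120.0]},
    "complex": {"f0_khz": [45.0, 60.0], "dur_ms": [40.0, 100.0]},
}


def default_transition_matrix() -> dict[str, dict[str, float]]:
    """Embedded-chain transition matrix built from preference weights."""
    mat: dict[str, dict[str, float]] = {}
    for b in BEHAVIORS:
        others = {o: _TRANSITION_WEIGHTS[o] for o in BEHAVIORS if o != b}
        tot = sum(others.values())
        mat[b] = {o: w / tot for o, w in others.items()}
    return mat


def _behavior_mixtures() -> dict[str, dict[str, float]]:
    out = {}
    for b in BEHAVIORS:
        mix = dict(DEFAULT_GLOBAL_MIXTURE)
        for s, k in _BEHAVIOR_MIXTURE_BOOSTS.get(b, {}).items():
            mix[s] *= k
        tot = sum(mix.values())
        out[b] = {s: v / tot for s, v in mix.items()}
    return out


@dataclass
class SyntheticScenario:
    """Generative parameters for a cohort of synthetic sessions.

    Every probability vector must sum to 1 (checked to 1e-9); the same
    ``seed`` always reproduces byte-identical scans, events and waveforms.
    """

    n_rats: int = 16
    phase_duration_s: float = 600.0
    seed: int = 0
    association_strength: float = 1.0
    behavior_transition: dict[str, dict[str, float]] = field(
        default_factory=default_transition_matrix
    )
    mean_dwell_s: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DWELL_S)
    )
    usv_rate_per_behavior: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_USV_RATE)
    )
    global_subtype_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GLOBAL_MIXTURE)
    )
    subtype_mixture_per_behavior: dict[str, dict[str, float]] = field(
        default_factory=_behavior_mixtures
    )
    subtype_shapes: dict[str, dict] = field(
        default_factory=lambda: {k: dict(v) for k, v in
                                 DEFAULT_SUBTYPE_SHAPES.items()}
    )
    chew_click_rate: float = 3.0      # clicks/s during Feeding bins
    amplitude: float = 0.3            # tone amplitude, linear full scale 1.0
    click_amplitude: float = 0.6
    noise_floor_db: float = -60.0     # Gaussian noise sigma in dBFS
    diets: tuple[str, ...] = ("LP", "HP")

    def __post_init__(self) -> None:
        if not 0.0 <= self.association_strength <= 1.0:
            raise ValueError("association_strength must lie in [0, 1]")
        if self.phase_duration_s % 1.0 != 0.0:
            raise ValueError("phase_duration_s must be a whole number of 1 s bins")
        for b, row in self.behavior_transition.items():
            if b not in BEHAVIORS:
                raise ValueError(f"unknown behavior in transition matrix: {b!r}")
            for t in row:
                if t not in BEHAVIORS:
                    raise ValueError(f"unknown behavior in transition row: {t!r}")
            self._check_simplex(row, f"transition[{b}]")
        self._check_simplex(self.global_subtype_mixture, "global_subtype_mixture")
        for b, mix in self.subtype_mixture_per_behavior.items():
            self._check_simplex(mix, f"subtype_mixture[{b}]")

    @staticmethod
    def _check_simplex(vec: dict[str, float], name: str) -> None:
        tot = sum(vec.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"{name} sums to {tot}, expected 1")
        if any(v < 0 for v in vec.values()):
            raise ValueError(f"{name} has a negative probability")

    # -- per-session reproducibility -------------------------------------
    def session_rng(self, rat_id: str, phase: str) -> np.random.Generator:
        """Independent generator per (scenario seed, rat, phase)."""
        key = zlib.crc32(f"{rat_id}|{phase}".encode())
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed) & 0x7FFFFFFF, key])
        )

    def rat_ids(self) -> list[str]:
        return [f"rat{i + 1:02d}" for i in range(self.n_rats)]

    def diet_of(self, rat_id: str) -> str:
        idx = self.rat_ids().index(rat_id)
        return self.diets[idx % len(self.diets)]

    # -- serialization ---------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["diets"] = list(d["diets"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticScenario":
        d = yaml.safe_load(Path(path).read_text())
        if "diets" in d:
            d["diets"] = tuple(d["diets"])
        return cls(**d)


# ---------------------------------------------------------------------------
# behaviour process


def generate_behavior_scan(
    scenario: SyntheticScenario,
    rat_id: str,
    phase: str,
    rng: Optional[np.random.Generator] = None,
) -> BehaviorScan:
    """Scan-sample the semi-Markov behaviour chain at 1 s resolution.

    Bout durations are exponential with the state's mean dwell; the state
    sequence follows the embedded transition matrix.  In the anticipation
    phase "Feeding" is removed from every transition row (food cannot be
    consumed), and rows are renormalised.
    """
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}")
    rng = rng if rng is not None else scenario.session_rng(rat_id, phase)
    phase_states = BEHAVIORS if phase == "consumption" else ANTICIPATION_BEHAVIORS
    allowed = [
        b for b in phase_states
        if b in scenario.behavior_transition and b in scenario.mean_dwell_s
    ]
    if not allowed:
        raise ValueError("no behaviour reachable in this phase")

    def row_for(state: str) -> tuple[list[str], np.ndarray]:
        row = scenario.behavior_transition[state]
        targets = [t for t in allowed if row.get(t, 0.0) > 0 and t != state]
        probs = np.array([row[t] for t in targets], dtype=float)
        if not targets:  # absorbing state
            return [state], np.array([1.0])
        return targets, probs / probs.sum()

    n_bins = int(round(scenario.phase_duration_s))
    # initial state ~ dwell-weighted occupancy of the allowed states
    w = np.array([scenario.mean_dwell_s[b] for b in allowed], dtype=float)
    state = allowed[rng.choice(len(allowed), p=w / w.sum())]
    labels: list[str] = []
    t = 0.0
    boundary = rng.exponential(scenario.mean_dwell_s[state])
    for k in range(n_bins):
        labels.append(state)
        t = k + 1.0
        while boundary <= t:
            targets, probs = row_for(state)
            state = targets[rng.choice(len(targets), p=probs)]
            boundary += rng.exponential(scenario.mean_dwell_s[state])
    return BehaviorScan(
        session_id=f"{rat_id}-{phase}", phase=phase, labels=labels
    )


# ---------------------------------------------------------------------------
# USV events


def _draw_duration_s(shape: dict, rng: np.random.Generator) -> float:
    lo, hi = shape["dur_ms"]
    return float(rng.uniform(lo, hi)) / 1000.0


def sample_trajectory(
    subtype: str,
    duration_s: float,
    shapes: dict[str, dict],
    rng: np.random.Generator,
    dt_s: float = 0.001,
) -> np.ndarray:
    """Frequency trajectory of one call in kHz, sampled every ``dt_s``."""
    shape = shapes[subtype]
    n = max(2, int(round(duration_s / dt_s)))
    x = np.linspace(0.0, 1.0, n)
    t_ms = x * duration_s * 1000.0
    lo, hi = shape["f0_khz"]
    f0 = rng.uniform(lo, hi)

    if subtype in ("flat", "short"):
        traj = np.full(n, f0)
    elif subtype == "upward ramp":
        traj = f0 + shape["extent_khz"] * x
    elif subtype == "downward ramp":
        traj = f0 - shape["extent_khz"] * x
    elif subtype in ("step up", "step down"):
        sgn = 1.0 if subtype == "step up" else -1.0
        cut = rng.uniform(0.35, 0.65)
        traj = np.where(x < cut, f0, f0 + sgn * shape["jump_khz"])
    elif subtype == "multi-step":
        # steps separated enough to be visually (and digitally) distinct
        for _ in range(50):
            cuts = np.sort(rng.uniform(0.2, 0.8, size=shape["n_jumps"]))
            if len(cuts) < 2 or np.diff(cuts).min() >= 0.15:
                break
        traj = np.full(n, f0)
        for c in cuts:
            traj = traj + np.where(x >= c, shape["jump_khz"], 0.0)
    elif subtype == "trill":
        phase = rng.uniform(0, 2 * np.pi)
        traj = f0 + shape["fm_depth_khz"] * np.sin(
            2 * np.pi * t_ms / shape["fm_period_ms"] + phase
        )
    elif subtype == "trill with jumps":
        phase = rng.uniform(0, 2 * np.pi)
        traj = f0 + shape["fm_depth_khz"] * np.sin(
            2 * np.pi * t_ms / shape["fm_period_ms"] + phase
        )
        traj = traj + np.where(x >= rng.uniform(0.4, 0.6), shape["jump_khz"], 0.0)
    elif subtype == "split":
        half = shape["excursion_frac"] / 2
        mid = rng.uniform(0.35, 0.65)
        exc = (x >= mid - half) & (x < mid + half)
        traj = np.where(exc, f0 + shape["jump_khz"], f0)
    elif subtype == "inverted U":
        h_lo, h_hi = shape["height_khz"]
        traj = f0 + rng.uniform(h_lo, h_hi) * 4 * x * (1 - x)
    elif subtype == "flat-trill combination":
        phase = rng.uniform(0, 2 * np.pi)
        trill = f0 + shape["fm_depth_khz"] * np.sin(
            2 * np.pi * t_ms / shape["fm_period_ms"] + phase
        )
        traj = np.where(x < 0.5, f0, trill)
    elif subtype == "composite":
        traj = np.where(x < 0.5, f0, f0 + shape["extent_khz"] * (x - 0.5) * 2)
    elif subtype == "complex":
        # irregular frequency modulation: piecewise linear through a few
        # random control points (non-periodic, unlike a trill)
        n_ctrl = int(rng.integers(4, 6))
        xs = np.concatenate([[0.0], np.sort(rng.uniform(0.2, 0.8, n_ctrl - 2)), [1.0]])
        xs = np.maximum.accumulate(xs + np.linspace(0, 1e-6, n_ctrl))
        levels = f0 + rng.uniform(-7.0, 7.0, n_ctrl)
        span = levels.max() - levels.min()
        if span < 8.0:
            levels = levels.mean() + (levels - levels.mean()) * (8.0 / max(span, 1e-9))
        traj = np.interp(x, xs, levels)
    else:
        raise ValueError(f"unknown subtype {subtype!r}")
    return np.clip(traj, 21.0, 99.0)


def _round5(x: float) -> float:
    """Round to the nearest multiple of 5 kHz, ties rounding half-up."""
    return 5.0 * np.floor(x / 5.0 + 0.5)


def generate_usv_events(
    scenario: SyntheticScenario,
    scan: BehaviorScan,
    rat_id: str,
    rng: Optional[np.random.Generator] = None,
) -> list[UsvEvent]:
    """Draw USV events from an inhomogeneous Poisson process.

    The rate in each 1 s bin is set by the bin's behaviour; the subtype is
    drawn from ``(1-a) * global + a * behaviour`` mixture with
    ``a = association_strength``.  Consecutive events keep at least a 20 ms
    offset-to-onset gap (resampled within the bin, dropped if impossible).
    """
    rng = rng if rng is not None else scenario.session_rng(rat_id, scan.phase)
    a = scenario.association_strength
    subtypes = list(SUBTYPES)
    g = np.array([scenario.global_subtype_mixture[s] for s in subtypes])
    per_b = {
        b: (1 - a) * g
        + a * np.array([scenario.subtype_mixture_per_behavior[b][s] for s in subtypes])
        for b in BEHAVIORS
    }

    raw: list[tuple[float, str]] = []  # (onset, behavior)
    for k, b in enumerate(scan.labels):
        rate = scenario.usv_rate_per_behavior.get(b, 0.0)
        if rate < 0:
            raise ValueError(f"negative USV rate for {b!r}")
        n = rng.poisson(rate / 60.0 * scan.bin_s)
        for _ in range(n):
            raw.append((k + rng.uniform(0.0, scan.bin_s), b))
    raw.sort(key=lambda p: p[0])

    events: list[UsvEvent] = []
    prev_offset = -np.inf
    for onset, b in raw:
        mix = per_b[b]
        subtype = subtypes[rng.choice(len(subtypes), p=mix)]
        dur = _draw_duration_s(scenario.subtype_shapes[subtype], rng)
        # keep the mandated >= 20 ms gap to the previous call
        tries = 0
        while onset < prev_offset + 0.020 and tries < 10:
            onset = np.floor(onset) + rng.uniform(0.0, scan.bin_s)
            tries += 1
        if onset < prev_offset + 0.020:
            continue
        offset = min(onset + dur, scan.duration_s)
        if (offset - onset) < 0.010:
            continue
        traj = sample_trajectory(subtype, offset - onset, scenario.subtype_shapes, rng)
        events.append(
            UsvEvent(
                session_id=scan.session_id,
                onset_s=float(onset),
                offset_s=float(offset),
                subtype=subtype,
                median_freq_khz=float(_round5(float(np.median(traj)))),
                bandwidth_khz=float(traj.max() - traj.min()),
                trajectory_khz=traj,
                true_behavior=b,
            )
        )
        prev_offset = offset
    events.sort(key=lambda e: e.onset_s)
    return events


def generate_chew_clicks(
    scenario: SyntheticScenario,
    scan: BehaviorScan,
    rng: np.random.Generator,
) -> np.ndarray:
    """Pellet-crack click times (s): Poisson within Feeding bins."""
    times: list[float] = []
    for k, b in enumerate(scan.labels):
        if b != "Feeding":
            continue
        n = rng.poisson(scenario.chew_click_rate * scan.bin_s)
        times.extend(k + rng.uniform(0.0, scan.bin_s, size=n))
    return np.sort(np.asarray(times))


def generate_session(
    scenario: SyntheticScenario, rat_id: str, phase: str
) -> tuple[Session, np.ndarray]:
    """One rat x phase: (Session with scan + ground-truth events, click times)."""
    rng = scenario.session_rng(rat_id, phase)
    scan = generate_behavior_scan(scenario, rat_id, phase, rng=rng)
    events = generate_usv_events(scenario, scan, rat_id, rng=rng)
    clicks = generate_chew_clicks(scenario, scan, rng)
    session = Session(
        session_id=scan.session_id,
        rat_id=rat_id,
        phase=phase,
        events=events,
        scan=scan,
        diet=scenario.diet_of(rat_id) if rat_id in scenario.rat_ids() else None,
    )
    return session, clicks


# ---------------------------------------------------------------------------
# audio


def synthesize_audio(
    events: list[UsvEvent],
    clicks: np.ndarray | list[float],
    scenario: SyntheticScenario,
    duration_s: Optional[float] = None,
    sample_rate: int = 384_000,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Render events + clicks + noise floor to a mono waveform.

    Each call is a phase-continuous tone following its frequency trajectory
    with 2 ms cosine on/off ramps; clicks are 0.5 ms white bursts; the noise
    floor is Gaussian with sigma ``10**(noise_floor_db/20)`` full scale.
    """
    if duration_s is None:
        duration_s = scenario.phase_duration_s
    rng = rng if rng is not None else np.random.default_rng(scenario.seed)
    n_total = int(round(duration_s * sample_rate))
    wave = np.zeros(n_total, dtype=np.float64)

    for ev in events:
        if ev.onset_s >= duration_s:
            warnings.warn(
                f"event at {ev.onset_s:.3f}s outside the {duration_s:.0f}s phase; skipped"
            )
            continue
        offset = ev.offset_s
        if offset > duration_s:
            warnings.warn(
                f"event at {ev.onset_s:.3f}s overlaps the phase end; truncated"
            )
            offset = duration_s
        i0 = int(round(ev.onset_s * sample_rate))
        i1 = int(round(offset * sample_rate))
        n = i1 - i0
        if n <= 0:
            continue
        traj = ev.trajectory_khz
        if traj is None:
            traj = sample_trajectory(
                ev.subtype or "flat", offset - ev.onset_s, scenario.subtype_shapes, rng
            )
        f_hz = np.interp(
            np.linspace(0.0, 1.0, n), np.linspace(0.0, 1.0, len(traj)), traj
        ) * 1000.0
        if np.any(f_hz >= sample_rate / 2):
            raise ValueError("trajectory exceeds the Nyquist frequency")
        phase = 2.0 * np.pi * np.cumsum(f_hz) / sample_rate
        tone = np.sin(phase)
        ramp_n = min(int(0.002 * sample_rate), n // 2)
        env = np.ones(n)
        if ramp_n > 0:
            r = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
            env[:ramp_n] = r
            env[-ramp_n:] = r[::-1]
        wave[i0:i1] += scenario.amplitude * env * tone

    click_n = max(1, int(round(0.0005 * sample_rate)))
    for t in np.asarray(clicks, dtype=float):
        i0 = int(round(t * sample_rate))
        if i0 >= n_total:
            continue
        i1 = min(i0 + click_n, n_total)
        wave[i0:i1] += scenario.click_amplitude * rng.standard_normal(i1 - i0)

    sigma = 10.0 ** (scenario.noise_floor_db / 20.0)
    if sigma > 0:
        wave += sigma * rng.standard_normal(n_total)
    return wave.astype(np.float32)


def write_wav(path: str | Path, waveform: np.ndarray, sample_rate: int = 384_000) -> None:
    """Write 16-bit PCM mono WAV (clipped at full scale)."""
    clipped = np.clip(waveform, -1.0, 1.0)
    wavfile.write(str(path), sample_rate, (clipped * 32767.0).astype(np.int16))


def read_wav(path: str | Path) -> tuple[int, np.ndarray]:
    """Read a WAV file to float64 in [-1, 1]; returns (sample_rate, wave)."""
    sr, data = wavfile.read(str(path))
    if data.ndim > 1:
        data = data[:, 0]
    if data.dtype == np.int16:
        data = data.astype(np.float64) / 32767.0
    elif data.dtype == np.int32:
        data = data.astype(np.float64) / 2147483647.0
    else:
        data = data.astype(np.float64)
    return int(sr), data


# ---------------------------------------------------------------------------
# ground-truth tables


def events_to_frame(events: list[UsvEvent]) -> pd.DataFrame:
    """Ground-truth annotation table (one row per call)."""
    return pd.DataFrame(
        {
            "session_id": [e.session_id for e in events],
            "onset_s": [e.onset_s for e in events],
            "offset_s": [e.offset_s for e in events],
            "subtype": [e.subtype for e in events],
            "true_behavior": [e.true_behavior for e in events],
            "median_freq_khz": [e.median_freq_khz for e in events],
        }
    )


def write_events(events: list[UsvEvent], path) -> None:
    events_to_frame(events).to_csv(path, index=False)


def read_events(path) -> list[UsvEvent]:
    """Read a ground-truth/event CSV back bit-exactly (round-trip floats)."""
    return frame_to_events(pd.read_csv(path, float_precision="round_trip"))


def frame_to_events(df: pd.DataFrame) -> list[UsvEvent]:
    events = []
    for row in df.itertuples(index=False):
        events.append(
            UsvEvent(
                session_id=str(row.session_id),
                onset_s=float(row.onset_s),
                offset_s=float(row.offset_s),
                subtype=None if pd.isna(row.subtype) else str(row.subtype),
                true_behavior=(
                    None
                    if not hasattr(row, "true_behavior") or pd.isna(row.true_behavior)
                    else str(row.true_behavior)
                ),
                median_freq_khz=(
                    None if pd.isna(row.median_freq_khz) else float(row.median_freq_khz)
                ),
            )
        )
    return events
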