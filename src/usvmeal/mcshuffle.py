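"""Monte Carlo time-shuffling test for USV-behaviour association.

For each session (one rat, one phase) every call keeps its subtype but is
reassigned an independent uniform time within the observation period; the
subtype x behaviour co-occurrence matrix is recomputed.  Repeating this
(default 10,000 times) yields a per-cell null distribution of counts; the
observed count is expressed as a z-score against it.  Shuffling is done
separately per rat and the per-rat z-scores are averaged; cells with
``|mean z| >= 2`` are flagged (two-sided normal tail p = 0.0455).

Because shuffled times are i.i.d. uniform, the null count of a subtype with
``n`` events in a behaviour occupying ``m`` of ``M`` bins is exactly
Binomial(n, m/M); :func:`analytic_null` provides this closed form as an
independent oracle for the Monte Carlo machinery.

Rows (subtypes) or columns (behaviours) whose total observed co-occurrence
across all sessions is approximately five or fewer are too rare for the
z approximation and are excluded with a report.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import BEHAVIORS, SUBTYPES, Session
from .ethogram import CooccurrenceCount, count_cooccurrences, empty_matrix

__all__ = [
    "ShuffleConfig",
    "SessionShuffleStats",
    "ShuffleResult",
    "shuffle_once",
    "monte_carlo_z",
    "aggregate_z",
    "rarity_filter",
    "analytic_null",
    "run_shuffle_analysis",
]


@dataclass
class ShuffleConfig:
    n_shuffles: int = 10_000
    z_threshold: float = 2.0
    min_total_events: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")

    def session_rng(self, session_id: str) -> np.random.Generator:
        key = zlib.crc32(session_id.encode())
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed) & 0x7FFFFFFF, key])
        )


@dataclass
class SessionShuffleStats:
    """Per-session observed counts and Monte Carlo null (z is NaN where the
    null sd is zero: such cells carry no evidence)."""

    session_id: str
    observed: pd.DataFrame
    null_mean: pd.DataFrame
    null_sd: pd.DataFrame
    z: pd.DataFrame
    perm_p: pd.DataFrame  # fraction of shuffles at least as far from the null mean


@dataclass
class ShuffleResult:
    per_session: dict[str, SessionShuffleStats]
    mean_z: pd.DataFrame
    n_sessions: pd.DataFrame
    significant: pd.DataFrame          # "positive" / "negative" / "none" / "not-assessable"
    excluded_subtypes: dict[str, int] = field(default_factory=dict)
    excluded_behaviors: dict[str, int] = field(default_factory=dict)
    config: Optional[ShuffleConfig] = None

    def long_table(self) -> pd.DataFrame:
        """Long-format report: one row per (subtype, behaviour) cell."""
        rows = []
        for s in self.mean_z.index:
            for b in self.mean_z.columns:
                obs = sum(
                    int(st.observed.loc[s, b]) for st in self.per_session.values()
                )
                rows.append(
                    {
                        "subtype": s,
                        "behavior": b,
                        "observed_total": obs,
                        "mean_z": self.mean_z.loc[s, b],
                        "n_sessions": int(self.n_sessions.loc[s, b]),
                        "significant": self.significant.loc[s, b],
                    }
                )
        return pd.DataFrame(rows)


def _behavior_indices(session: Session) -> np.ndarray:
    lookup = {b: i for i, b in enumerate(BEHAVIORS)}
    return np.array([lookup[b] for b in session.scan.labels], dtype=np.int64)


def _events_by_subtype(session: Session, subtypes: Sequence[str]) -> dict[str, int]:
    counts = {s: 0 for s in subtypes}
    for e in session.events:
        counts[e.subtype] += 1
    return counts


def shuffle_once(
    session: Session, rng: np.random.Generator
) -> CooccurrenceCount:
    """One shuffle replicate: uniform times, subtypes kept, counts recomputed."""
    if session.scan is None:
        raise ValueError("session has no behaviour scan")
    beh_idx = _behavior_indices(session)
    duration = session.scan.duration_s
    mat = empty_matrix()
    srow = {s: i for i, s in enumerate(SUBTYPES)}
    m = mat.to_numpy()
    for e in session.events:
        t = rng.uniform(0.0, duration)
        k = min(int(t // session.scan.bin_s), len(beh_idx) - 1)
        m[srow[e.subtype], beh_idx[k]] += 1
    return CooccurrenceCount(
        matrix=pd.DataFrame(m, index=list(SUBTYPES), columns=list(BEHAVIORS)),
        session_id=session.session_id,
    )


def monte_carlo_z(
    session: Session,
    config: ShuffleConfig,
    rng: Optional[np.random.Generator] = None,
) -> SessionShuffleStats:
    """Observed counts vs the time-shuffled null for one session.

    z = (observed - null mean) / null sd with the sample sd (ddof 1) over
    shuffle replicates; cells with zero null sd are NaN.
    """
    if session.scan is None:
        raise ValueError("session has no behaviour scan")
    rng = rng if rng is not None else config.session_rng(session.session_id)
    observed = count_cooccurrences(session).matrix
    beh_idx = _behavior_indices(session)
    duration = session.scan.duration_s
    M = len(beh_idx)
    B = len(BEHAVIORS)
    R = config.n_shuffles

    n_by_subtype = _events_by_subtype(session, SUBTYPES)
    null_mean = empty_matrix().astype(float)
    null_sd = empty_matrix().astype(float)
    z = empty_matrix().astype(float) * np.nan
    perm_p = empty_matrix().astype(float) * np.nan

    for s, n in n_by_subtype.items():
        if n == 0:
            null_sd.loc[s] = 0.0
            continue
        times = rng.uniform(0.0, duration, size=(R, n))
        bins = np.minimum((times / session.scan.bin_s).astype(np.int64), M - 1)
        beh = beh_idx[bins]  # (R, n)
        flat = (np.arange(R)[:, None] * B + beh).ravel()
        counts = np.bincount(flat, minlength=R * B).reshape(R, B)
        mu = counts.mean(axis=0)
        sd = counts.std(axis=0, ddof=1)
        null_mean.loc[s] = mu
        null_sd.loc[s] = sd
        obs = observed.loc[s].to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            zr = np.where(sd > 0, (obs - mu) / sd, np.nan)
        z.loc[s] = zr
        dev = np.abs(counts - mu)
        perm_p.loc[s] = (dev >= np.abs(obs - mu)[None, :]).mean(axis=0)

    return SessionShuffleStats(
        session_id=session.session_id,
        observed=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        z=z,
        perm_p=perm_p,
    )


def analytic_null(session: Session) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Closed-form null: Binomial(n, m/M) mean and sd per cell."""
    if session.scan is None:
        raise ValueError("session has no behaviour scan")
    M = len(session.scan.labels)
    occupancy = pd.Series(session.scan.labels).value_counts().reindex(
        BEHAVIORS, fill_value=0
    )
    p = occupancy.to_numpy() / M
    n_by_subtype = _events_by_subtype(session, SUBTYPES)
    mean = empty_matrix().astype(float)
    sd = empty_matrix().astype(float)
    for s, n in n_by_subtype.items():
        mean.loc[s] = n * p
        sd.loc[s] = np.sqrt(n * p * (1.0 - p))
    return mean, sd


def aggregate_z(
    per_session: Sequence[SessionShuffleStats], config: ShuffleConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Average defined per-session z-scores per cell and flag significance.

    Sessions where a cell's z is undefined (the rat never produced the
    subtype, or the null is degenerate) are dropped from that cell's
    average rather than imputed as 0.
    """
    if not per_session:
        raise ValueError("no sessions to aggregate")
    stack = np.stack([st.z.to_numpy() for st in per_session])
    import warnings as _warnings

    with _warnings.catch_warnings():
        # all-NaN cells (subtype never produced) are legitimately NaN
        _warnings.simplefilter("ignore", RuntimeWarning)
        mean_z = np.nanmean(stack, axis=0)
    n_def = np.sum(~np.isnan(stack), axis=0)
    sig = np.full(mean_z.shape, "none", dtype=object)
    sig[np.isnan(mean_z)] = "not-assessable"
    sig[np.nan_to_num(mean_z) >= config.z_threshold] = "positive"
    sig[np.nan_to_num(mean_z) <= -config.z_threshold] = "negative"
    idx, cols = list(SUBTYPES), list(BEHAVIORS)
    return (
        pd.DataFrame(mean_z, index=idx, columns=cols),
        pd.DataFrame(n_def, index=idx, columns=cols),
        pd.DataFrame(sig, index=idx, columns=cols),
    )


def rarity_filter(
    sessions: Sequence[Session], config: ShuffleConfig
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Exclude subtypes/behaviours whose total co-occurrence count over all
    sessions is at or below ``min_total_events`` (z-scores are unstable for
    events that rare).  A threshold of 0 disables the filter."""
    total = empty_matrix()
    for s in sessions:
        total += count_cooccurrences(s).matrix
    row_tot = total.sum(axis=1)
    col_tot = total.sum(axis=0)
    thr = config.min_total_events
    if thr <= 0:
        keep_rows = list(total.index)
        keep_cols = list(total.columns)
    else:
        keep_rows = [s for s in total.index if row_tot[s] > thr]
        keep_cols = [b for b in total.columns if col_tot[b] > thr]
    report_rows = [
        {"axis": "subtype", "label": s, "total": int(row_tot[s]),
         "included": s in keep_rows}
        for s in total.index
    ] + [
        {"axis": "behavior", "label": b, "total": int(col_tot[b]),
         "included": b in keep_cols}
        for b in total.columns
    ]
    return keep_rows, keep_cols, pd.DataFrame(report_rows)


def run_shuffle_analysis(
    sessions: Sequence[Session], config: Optional[ShuffleConfig] = None
) -> ShuffleResult:
    """Full test: per-session Monte Carlo z, cross-rat averaging, rarity
    exclusions and significance flags."""
    config = config or ShuffleConfig()
    per_session = {
        s.session_id: monte_carlo_z(s, config) for s in sessions
    }
    mean_z, n_sessions, significant = aggregate_z(
        list(per_session.values()), config
    )
    keep_rows, keep_cols, report = rarity_filter(sessions, config)
    excluded_subtypes = {
        r["label"]: r["total"]
        for _, r in report.iterrows()
        if r["axis"] == "subtype" and not r["included"]
    }
    excluded_behaviors = {
        r["label"]: r["total"]
        for _, r in report.iterrows()
        if r["axis"] == "behavior" and not r["included"]
    }
    # excluded cells carry no significance flag
    for s in excluded_subtypes:
        significant.loc[s, :] = "excluded"
    for b in excluded_behaviors:
        significant.loc[:, b] = "excluded"
    return ShuffleResult(
        per_session=per_session,
        mean_z=mean_z,
        n_sessions=n_sessions,
        significant=significant,
        excluded_subtypes=excluded_subtypes,
        excluded_behaviors=excluded_behaviors,
        config=config,
    )
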