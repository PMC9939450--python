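"""Phase-comparison and association statistics.

Covers the frequentist half of the analysis:

* **Delta USV** - per rat and subtype, consumption-phase count minus
  anticipation-phase count, compared across subtypes with Kruskal-Wallis
  and Dunn's pairwise post hoc test.
* **Frequency-band summaries** - counts and whole-percent shares of calls
  per frequency band (bounds inclusive on both ends, matching the 5 kHz
  grid of the median-frequency estimates).
* **Chewing chi-square** - association between flat calls and chewing
  clicks, in two layouts: the *paper-faithful* 2x2 built from the four
  printed totals (all USVs, chewing USVs, flats, chewing flats - note the
  flats are counted inside the totals as well), and a *subset-corrected*
  2x2 on disjoint cells.
* **Frequency model** - ordinary least squares of median call frequency
  (kHz) on the co-occurring behaviour plus the individual rat, with
  sequential F tests per factor.  A logistic model could not produce the
  kHz-scale coefficients, t-values and factor F statistics this analysis
  reports, so the linear model is the one implemented.
* **Subtype x diet ANOVA** - two-way ANOVA on per-rat subtype counts used
  to justify pooling the two test-meal diets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .core import SUBTYPES, Session, UsvEvent

logger = logging.getLogger(__name__)

__all__ = [
    "REFERENCE_COEFFICIENTS",
    "REFERENCE_LEVEL",
    "KruskalResult",
    "ChisqResult",
    "FrequencyModel",
    "delta_usv",
    "kruskal_wallis_delta",
    "frequency_band_summary",
    "rounded_percentage",
    "chewing_chisq",
    "fit_frequency_model",
    "predict_frequency",
    "subtype_diet_anova",
    "z_threshold_p",
]

#: Coefficient table of the frequency-vs-behaviour linear model reported for
#: the original 16-rat cohort (kHz scale).  Shipped as a worked example and
#: as the input for :func:`predict_frequency`; the reference behaviour level
#: (absent from the rows) is Down explore.
REFERENCE_LEVEL = "Down explore"
REFERENCE_COEFFICIENTS = pd.DataFrame(
    [
        ("(Intercept)", 72.500, 11.615, 6.242, 8.36e-10),
        ("Feeding", -28.102, 11.643, -2.414, 0.016098),
        ("Grooming", -47.500, 13.743, -3.456, 0.000588),
        ("Immobile", 6.667, 6.706, 0.994, 0.320551),
        ("Lying down", -27.500, 11.995, -2.293, 0.022234),
        ("Move", 10.000, 6.146, 1.627, 0.104259),
        ("Sniff food", -20.000, 10.388, -1.925, 0.054692),
        ("Up explore", -12.500, 12.365, -1.011, 0.312467),
    ],
    columns=["term", "estimate", "std_error", "t_value", "p_value"],
).set_index("term")


# ---------------------------------------------------------------------------
# Delta USV and Kruskal-Wallis / Dunn


def delta_usv(
    sessions: Sequence[Session], min_individuals: int = 2
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-rat, per-subtype consumption minus anticipation counts.

    Subtypes produced by fewer than ``min_individuals`` distinct rats are
    excluded (a single emitter makes the across-rat comparison meaningless);
    the returned report maps excluded subtypes to their total event counts.
    Rats missing one of the two phases are skipped with a warning.
    """
    by_rat: dict[str, dict[str, Session]] = {}
    for s in sessions:
        by_rat.setdefault(s.rat_id, {})[s.phase] = s

    producers: dict[str, set[str]] = {st: set() for st in SUBTYPES}
    totals: dict[str, int] = {st: 0 for st in SUBTYPES}
    for s in sessions:
        for e in s.events:
            producers[e.subtype].add(s.rat_id)
            totals[e.subtype] += 1
    excluded = {
        st: totals[st]
        for st in SUBTYPES
        if totals[st] > 0 and len(producers[st]) < min_individuals
    }
    included = [st for st in SUBTYPES if totals[st] > 0 and st not in excluded]

    rows = []
    for rat, phases in sorted(by_rat.items()):
        if set(phases) != {"anticipation", "consumption"}:
            logger.warning("rat %s lacks one phase; skipped from Delta USV", rat)
            continue
        counts = {
            ph: pd.Series([e.subtype for e in phases[ph].events])
            .value_counts()
            .reindex(SUBTYPES, fill_value=0)
            for ph in ("anticipation", "consumption")
        }
        for st in included:
            rows.append(
                {
                    "rat_id": rat,
                    "subtype": st,
                    "delta": int(counts["consumption"][st] - counts["anticipation"][st]),
                }
            )
    return pd.DataFrame(rows, columns=["rat_id", "subtype", "delta"]), excluded


@dataclass
class KruskalResult:
    H: float
    df: int
    p: float
    dunn: pd.DataFrame  # columns: group1, group2, z, p_unadjusted, p_bonferroni


def _dunn_pairwise(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's z with tie correction; two-sided Bonferroni-adjusted p."""
    labels = list(groups)
    values = np.concatenate([groups[g] for g in labels])
    n_total = len(values)
    ranks = stats.rankdata(values)
    offsets = np.cumsum([0] + [len(groups[g]) for g in labels])
    mean_rank = {
        g: ranks[offsets[i]: offsets[i + 1]].mean() for i, g in enumerate(labels)
    }
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    n_pairs = len(labels) * (len(labels) - 1) // 2
    rows = []
    for g1, g2 in combinations(labels, 2):
        se = np.sqrt(var_base * (1.0 / len(groups[g1]) + 1.0 / len(groups[g2])))
        z = (mean_rank[g1] - mean_rank[g2]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            {
                "group1": g1,
                "group2": g2,
                "z": z,
                "p_unadjusted": p,
                "p_bonferroni": min(1.0, p * n_pairs),
            }
        )
    return pd.DataFrame(rows)


def kruskal_wallis_delta(
    deltas: pd.DataFrame, adjust: Literal["bonferroni", "none"] = "bonferroni"
) -> KruskalResult:
    """Kruskal-Wallis across subtypes on the Delta USV scores (with tie
    correction), plus Dunn's pairwise comparisons."""
    groups = {
        st: grp["delta"].to_numpy(dtype=float)
        for st, grp in deltas.groupby("subtype")
    }
    groups = {g: v for g, v in groups.items() if len(v) >= 2}
    if len(groups) < 2:
        raise ValueError("need at least two subtype groups with >= 2 values")
    df = len(groups) - 1
    all_vals = np.concatenate(list(groups.values()))
    if np.all(all_vals == all_vals[0]):
        dunn = _dunn_pairwise(groups)
        if adjust == "none":
            dunn["p_bonferroni"] = dunn["p_unadjusted"]
        return KruskalResult(H=0.0, df=df, p=1.0, dunn=dunn)
    H, p = stats.kruskal(*groups.values())
    dunn = _dunn_pairwise(groups)
    if adjust == "none":
        dunn["p_bonferroni"] = dunn["p_unadjusted"]
    return KruskalResult(H=float(H), df=df, p=float(p), dunn=dunn)


# ---------------------------------------------------------------------------
# frequency bands


def rounded_percentage(count: int, total: int) -> int:
    """Whole-percent share, ties rounding half-up (e.g. 410/652 -> 63)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return int(np.floor(100.0 * count / total + 0.5))


def frequency_band_summary(
    events: Sequence[UsvEvent],
    bands: Sequence[tuple[str, float, float]] = (
        ("35-45 kHz", 35.0, 45.0),
        (">=50 kHz", 50.0, np.inf),
    ),
) -> pd.DataFrame:
    """Counts and whole-percent shares per frequency band.

    Band bounds are inclusive on both ends; events matching no band fall
    into "other".  With no events an empty frame is returned (percentages
    are undefined).
    """
    freqs = np.array(
        [e.median_freq_khz for e in events if e.median_freq_khz is not None]
    )
    total = len(freqs)
    if total == 0:
        return pd.DataFrame(columns=["band", "count", "percent"])
    rows = []
    assigned = np.zeros(total, dtype=bool)
    for name, lo, hi in bands:
        inb = (freqs >= lo) & (freqs <= hi)
        rows.append(
            {"band": name, "count": int(inb.sum()),
             "percent": rounded_percentage(int(inb.sum()), total)}
        )
        assigned |= inb
    other = int((~assigned).sum())
    rows.append(
        {"band": "other", "count": other,
         "percent": rounded_percentage(other, total)}
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# chewing chi-square


@dataclass
class ChisqResult:
    chi2: float
    df: int
    n: int
    p: float
    mode: str
    table: np.ndarray


def chewing_chisq(
    total_all: int,
    chew_all: int,
    total_flat: int,
    chew_flat: int,
    mode: Literal["paper_faithful", "subset_corrected"] = "paper_faithful",
) -> ChisqResult:
    """Pearson chi-square (no continuity correction) for the flat-vs-chewing
    association.

    ``paper_faithful`` uses the 2x2 of the four headline totals
    ``[[total_all, chew_all], [total_flat, chew_flat]]`` - the layout whose
    cell sum matches the reported N even though flats are counted inside the
    totals.  ``subset_corrected`` rebuilds disjoint cells
    (flat/non-flat x chewing/non-chewing).
    """
    if not (chew_all <= total_all and chew_flat <= total_flat
            and chew_flat <= chew_all and total_flat <= total_all):
        raise ValueError("inconsistent counts")
    if mode == "paper_faithful":
        table = np.array([[total_all, chew_all], [total_flat, chew_flat]], dtype=float)
    elif mode == "subset_corrected":
        table = np.array(
            [
                [chew_flat, total_flat - chew_flat],
                [chew_all - chew_flat,
                 (total_all - total_flat) - (chew_all - chew_flat)],
            ],
            dtype=float,
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return ChisqResult(
        chi2=float(chi2), df=int(df), n=int(table.sum()), p=float(p),
        mode=mode, table=table,
    )


# ---------------------------------------------------------------------------
# frequency ~ behaviour + individual linear model


@dataclass
class FrequencyModel:
    coefficients: pd.DataFrame   # term, estimate, std_error, t_value, p_value
    reference_level: str
    anova: pd.DataFrame          # sequential F per factor
    dropped_behaviors: list[str] = field(default_factory=list)


def fit_frequency_model(
    data: pd.DataFrame,
    reference: str = REFERENCE_LEVEL,
) -> FrequencyModel:
    """OLS of median frequency (kHz) on behaviour + rat factors.

    ``data`` needs columns ``median_freq_khz``, ``behavior``, ``rat_id``.
    Behaviours with fewer than 2 events are dropped (logged); sequential
    (type I) F tests enter behaviour before the individual factor.
    """
    df = data.copy()
    counts = df["behavior"].value_counts()
    dropped = [b for b in counts.index if counts[b] < 2]
    if dropped:
        logger.info("dropping behaviours with <2 events: %s", dropped)
        df = df[~df["behavior"].isin(dropped)]
    if df["behavior"].nunique() < 2:
        raise ValueError("need at least two behaviours with >= 2 events")
    if df["rat_id"].nunique() < 2:
        raise ValueError("individual factor inestimable with a single rat")
    if reference not in set(df["behavior"]):
        reference = sorted(df["behavior"].unique())[0]
    model = smf.ols(
        f"median_freq_khz ~ C(behavior, Treatment(reference={reference!r}))"
        " + C(rat_id)",
        data=df,
    ).fit()
    aov = anova_lm(model, typ=1)
    aov = aov.rename(
        index=lambda s: "behavior" if "behavior" in s else
        ("individual" if "rat_id" in s else s)
    )
    rows = []
    for name, est in model.params.items():
        if "rat_id" in name:
            continue
        if name == "Intercept":
            term = "(Intercept)"
        else:
            term = name.split("[T.")[-1].rstrip("]")
        rows.append(
            {
                "term": term,
                "estimate": est,
                "std_error": model.bse[name],
                "t_value": model.tvalues[name],
                "p_value": model.pvalues[name],
            }
        )
    coef = pd.DataFrame(rows).set_index("term")
    return FrequencyModel(
        coefficients=coef,
        reference_level=reference,
        anova=aov,
        dropped_behaviors=dropped,
    )


def predict_frequency(
    coefficients: pd.DataFrame,
    behavior: str,
    reference_level: str = REFERENCE_LEVEL,
) -> int:
    """Predicted median frequency for a behaviour, nearest integer kHz.

    The prediction is intercept plus the behaviour's estimate (0 for the
    reference level).
    """
    if "(Intercept)" not in coefficients.index:
        raise ValueError("coefficient table lacks an (Intercept) row")
    intercept = float(coefficients.loc["(Intercept)", "estimate"])
    if behavior == reference_level:
        est = 0.0
    elif behavior in coefficients.index:
        est = float(coefficients.loc[behavior, "estimate"])
    else:
        raise ValueError(f"behavior {behavior!r} not in the coefficient table")
    return int(np.floor(intercept + est + 0.5))


# ---------------------------------------------------------------------------
# subtype x diet ANOVA


def subtype_diet_anova(counts: pd.DataFrame) -> pd.DataFrame:
    """Two-way ANOVA of per-rat subtype counts on subtype x diet.

    ``counts`` needs columns ``rat_id``, ``subtype``, ``count``, ``diet``.
    Used to justify pooling diets when the diet main effect and interaction
    are non-significant.  With a single diet level only the subtype factor
    is fitted.
    """
    required = {"rat_id", "subtype", "count", "diet"}
    if missing := required - set(counts.columns):
        raise ValueError(f"missing columns: {sorted(missing)}")
    if counts["diet"].nunique() < 2:
        model = smf.ols("count ~ C(subtype)", data=counts).fit()
        aov = anova_lm(model, typ=2)
        return aov.rename(index=lambda s: "subtype" if "subtype" in s else s)
    model = smf.ols("count ~ C(subtype) * C(diet)", data=counts).fit()
    aov = anova_lm(model, typ=2)

    def _name(s: str) -> str:
        if ":" in s:
            return "subtype:diet"
        if "subtype" in s:
            return "subtype"
        if "diet" in s:
            return "diet"
        return s

    return aov.rename(index=_name)


def z_threshold_p(z: float = 2.0) -> float:
    """Two-sided normal tail probability at the averaged-z threshold."""
    return float(2.0 * stats.norm.sf(abs(z)))
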