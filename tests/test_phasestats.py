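"""Delta USV, rank tests, band summaries, chi-square and the linear model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from usvmeal.core import BehaviorScan, Session, UsvEvent
from usvmeal import phasestats as ps


def _session(rat, phase, subtype_counts, freq=40.0):
    labels = (["Feeding"] if phase == "consumption" else ["Move"]) * 600
    scan = BehaviorScan(f"{rat}-{phase}", phase, labels)
    events, t = [], 0.5
    for st, n in subtype_counts.items():
        for _ in range(n):
            events.append(
                UsvEvent(scan.session_id, t, t + 0.05, subtype=st,
                         median_freq_khz=freq)
            )
            t += 0.5
    return Session(scan.session_id, rat, phase, events, scan)


class TestDeltaUsv:
    def test_consumption_minus_anticipation(self):
        sessions = [
            _session("r1", "anticipation", {"flat": 5, "short": 2}),
            _session("r1", "consumption", {"flat": 9, "short": 2}),
            _session("r2", "anticipation", {"flat": 1, "short": 4}),
            _session("r2", "consumption", {"flat": 2, "short": 1}),
        ]
        deltas, excluded = ps.delta_usv(sessions)
        d = deltas.set_index(["rat_id", "subtype"])["delta"]
        assert d[("r1", "flat")] == 4
        assert d[("r1", "short")] == 0
        assert d[("r2", "short")] == -3
        assert not excluded

    def test_identical_phases_give_zero_deltas(self):
        sessions = [
            _session("r1", "anticipation", {"flat": 3}),
            _session("r1", "consumption", {"flat": 3}),
        ]
        deltas, _ = ps.delta_usv(sessions)
        assert (deltas["delta"] == 0).all()

    def test_phase_swap_negates(self):
        a = [
            _session("r1", "anticipation", {"flat": 5}),
            _session("r1", "consumption", {"flat": 9}),
        ]
        b = [
            _session("r1", "anticipation", {"flat": 9}),
            _session("r1", "consumption", {"flat": 5}),
        ]
        da, _ = ps.delta_usv(a)
        db, _ = ps.delta_usv(b)
        assert (da["delta"].to_numpy() == -db["delta"].to_numpy()).all()

    def test_single_producer_subtype_excluded_with_report(self):
        sessions = [
            _session("r1", "anticipation", {"flat": 3, "trill with jumps": 5}),
            _session("r1", "consumption", {"flat": 4}),
            _session("r2", "anticipation", {"flat": 2}),
            _session("r2", "consumption", {"flat": 2}),
        ]
        deltas, excluded = ps.delta_usv(sessions)
        assert excluded == {"trill with jumps": 5}
        assert "trill with jumps" not in set(deltas["subtype"])

    def test_rat_missing_a_phase_is_skipped(self):
        sessions = [
            _session("r1", "anticipation", {"flat": 3}),
            _session("r1", "consumption", {"flat": 4}),
            _session("r2", "anticipation", {"flat": 9}),
        ]
        deltas, _ = ps.delta_usv(sessions)
        assert set(deltas["rat_id"]) == {"r1"}


def brute_force_kruskal_h(groups):
    """Rank-based H from first principles (with tie correction)."""
    values = np.concatenate(groups)
    ranks = stats.rankdata(values)
    N = len(values)
    start, H = 0, 0.0
    for g in groups:
        r = ranks[start: start + len(g)]
        H += r.sum() ** 2 / len(g)
        start += len(g)
    H = 12.0 / (N * (N + 1)) * H - 3 * (N + 1)
    _, t = np.unique(values, return_counts=True)
    correction = 1 - np.sum(t**3 - t) / (N**3 - N)
    return H / correction if correction > 0 else 0.0


class TestKruskalWallis:
    def _deltas(self, groups):
        rows = []
        for i, g in enumerate(groups):
            for j, v in enumerate(g):
                rows.append({"rat_id": f"r{j}", "subtype": f"s{i}", "delta": v})
        return pd.DataFrame(rows)

    def test_hand_ranked_example(self):
        kw = ps.kruskal_wallis_delta(
            self._deltas([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        )
        assert kw.H == pytest.approx(7.2)
        assert kw.df == 2

    def test_identical_values_give_h_zero_p_one(self):
        kw = ps.kruskal_wallis_delta(self._deltas([[2, 2], [2, 2], [2, 2]]))
        assert kw.H == 0.0 and kw.p == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        sizes = rng.integers(2, 5, size=3)
        groups = [list(rng.integers(-5, 6, size=n)) for n in sizes]
        if all(len(set(g)) == 1 for g in groups) and len({g[0] for g in groups}) == 1:
            pytest.skip("degenerate draw")
        kw = ps.kruskal_wallis_delta(self._deltas(groups))
        assert kw.H == pytest.approx(brute_force_kruskal_h(groups), rel=1e-10)

    def test_dunn_flags_well_separated_pair(self):
        kw = ps.kruskal_wallis_delta(
            self._deltas([[1, 2, 3, 4], [11, 12, 13, 14], [5, 6, 7, 8]])
        )
        row = kw.dunn.set_index(["group1", "group2"]).loc[("s0", "s1")]
        assert row["p_bonferroni"] < 0.05
        assert row["z"] < 0  # s0 ranks below s1

    def test_dunn_z_matches_hand_formula_without_ties(self):
        groups = [[1.0, 4.0, 7.0], [2.0, 5.0, 8.0], [3.0, 6.0, 9.0]]
        kw = ps.kruskal_wallis_delta(self._deltas(groups))
        # mean ranks: 4, 5, 6; var term N(N+1)/12 = 7.5 (no ties)
        se = np.sqrt(7.5 * (1 / 3 + 1 / 3))
        row = kw.dunn.set_index(["group1", "group2"]).loc[("s0", "s1")]
        assert row["z"] == pytest.approx((4 - 5) / se)


class TestBandSummary:
    @pytest.mark.parametrize(
        "count, total, pct",
        [(410, 652, 63), (337, 778, 43), (124, 287, 43), (198, 652, 30)],
    )
    def test_printed_ratios(self, count, total, pct):
        assert ps.rounded_percentage(count, total) == pct

    def test_counts_partition_events(self):
        events = [
            UsvEvent("s", i, i + 0.05, "flat", median_freq_khz=f)
            for i, f in enumerate([40.0, 45.0, 35.0, 55.0, 80.0, 25.0])
        ]
        summ = ps.frequency_band_summary(events).set_index("band")
        assert summ.loc["35-45 kHz", "count"] == 3
        assert summ.loc[">=50 kHz", "count"] == 2
        assert summ.loc["other", "count"] == 1
        assert summ["count"].sum() == 6
        assert abs(summ["percent"].sum() - 100) <= 1

    def test_band_bounds_are_inclusive(self):
        events = [
            UsvEvent("s", 0, 0.05, "flat", median_freq_khz=35.0),
            UsvEvent("s", 1, 1.05, "flat", median_freq_khz=45.0),
        ]
        summ = ps.frequency_band_summary(events).set_index("band")
        assert summ.loc["35-45 kHz", "count"] == 2

    def test_empty_input_gives_empty_frame(self):
        assert ps.frequency_band_summary([]).empty


class TestChewingChisq:
    def test_headline_quadruple(self):
        r = ps.chewing_chisq(652, 198, 287, 124, mode="paper_faithful")
        assert r.chi2 == pytest.approx(6.89, abs=0.005)
        assert r.n == 1261
        assert r.df == 1
        assert r.p == pytest.approx(0.009, abs=0.001)

    def test_independence_gives_zero(self):
        r = ps.chewing_chisq(100, 50, 100, 50, mode="paper_faithful")
        assert r.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_subset_corrected_layout(self):
        # disjoint cells 124/163/74/291: Pearson closed form
        r = ps.chewing_chisq(652, 198, 287, 124, mode="subset_corrected")
        expected = stats.chi2_contingency(
            [[124, 163], [74, 291]], correction=False
        )[0]
        assert r.chi2 == pytest.approx(expected)
        assert r.chi2 == pytest.approx(39.9, abs=0.5)
        assert r.n == 652

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            ps.chewing_chisq(100, 150, 50, 20)


class TestFrequencyModel:
    def _data(self, rng, n_per=30, feeding_shift=-28.5, noise=0.0):
        rows = []
        for rat in ("r1", "r2", "r3"):
            for b, mu in [("Down explore", 72.5), ("Feeding", 72.5 + feeding_shift)]:
                for _ in range(n_per):
                    rows.append(
                        {"median_freq_khz": mu + noise * rng.standard_normal(),
                         "behavior": b, "rat_id": rat}
                    )
        return pd.DataFrame(rows)

    def test_recovers_generative_coefficients(self, rng):
        model = ps.fit_frequency_model(self._data(rng, noise=0.5))
        assert model.reference_level == "Down explore"
        assert model.coefficients.loc["(Intercept)", "estimate"] == pytest.approx(
            72.5, abs=0.5
        )
        assert model.coefficients.loc["Feeding", "estimate"] == pytest.approx(
            -28.5, abs=0.5
        )
        assert model.anova.loc["behavior", "PR(>F)"] < 1e-6

    def test_noiseless_equal_frequencies_give_zero_effects(self, rng):
        model = ps.fit_frequency_model(self._data(rng, feeding_shift=0.0))
        assert model.coefficients.loc["Feeding", "estimate"] == pytest.approx(
            0.0, abs=1e-8
        )

    def test_single_rat_is_an_error(self, rng):
        df = self._data(rng)
        with pytest.raises(ValueError, match="single rat"):
            ps.fit_frequency_model(df[df["rat_id"] == "r1"])

    def test_sparse_behavior_dropped(self, rng):
        df = self._data(rng)
        extra = pd.DataFrame(
            [{"median_freq_khz": 60.0, "behavior": "Rearing", "rat_id": "r1"}]
        )
        model = ps.fit_frequency_model(pd.concat([df, extra], ignore_index=True))
        assert model.dropped_behaviors == ["Rearing"]
        assert "Rearing" not in model.coefficients.index


class TestPredictFrequency:
    @pytest.mark.parametrize(
        "behavior, expected",
        [("Feeding", 44), ("Grooming", 25), ("Lying down", 45),
         ("Immobile", 79), ("Move", 83)],
    )
    def test_reference_table_predictions(self, behavior, expected):
        assert ps.predict_frequency(ps.REFERENCE_COEFFICIENTS, behavior) == expected

    def test_reference_level_is_the_intercept(self):
        assert ps.predict_frequency(ps.REFERENCE_COEFFICIENTS, "Down explore") == 73

    def test_unknown_behavior_rejected(self):
        with pytest.raises(ValueError, match="not in the coefficient table"):
            ps.predict_frequency(ps.REFERENCE_COEFFICIENTS, "Napping")


class TestSubtypeDietAnova:
    def _counts(self, rng, diet_effect=0.0, subtype_effect=True):
        rows = []
        for i in range(16):
            diet = "LP" if i < 8 else "HP"
            for j, st in enumerate([f"s{k}" for k in range(14)]):
                base = (10 + 3 * j) if subtype_effect else 10
                rows.append(
                    {"rat_id": f"r{i}", "subtype": st, "diet": diet,
                     "count": base + diet_effect * (diet == "HP")
                     + rng.normal(0, 2)}
                )
        return pd.DataFrame(rows)

    def test_df_structure(self, rng):
        aov = ps.subtype_diet_anova(self._counts(rng))
        assert aov.loc["subtype", "df"] == 13
        assert aov.loc["diet", "df"] == 1
        assert aov.loc["subtype:diet", "df"] == 13

    def test_subtype_effect_without_diet_effect(self, rng):
        aov = ps.subtype_diet_anova(self._counts(rng))
        assert aov.loc["subtype", "PR(>F)"] < 0.01
        assert aov.loc["diet", "PR(>F)"] > 0.5

    def test_identical_diets_give_tiny_diet_f(self, rng):
        df = self._counts(rng, diet_effect=0.0)
        # force exact balance: duplicate LP counts into HP
        lp = df[df.diet == "LP"].copy()
        hp = lp.copy()
        hp["diet"] = "HP"
        hp["rat_id"] = hp["rat_id"] + "h"
        aov = ps.subtype_diet_anova(pd.concat([lp, hp], ignore_index=True))
        assert aov.loc["diet", "F"] == pytest.approx(0.0, abs=1e-12)

    def test_single_diet_skips_diet_factor(self, rng):
        df = self._counts(rng)
        aov = ps.subtype_diet_anova(df[df.diet == "LP"])
        assert "diet" not in aov.index
        assert aov.loc["subtype", "df"] == 13


def test_z_threshold_two_sided_tail():
    assert ps.z_threshold_p(2.0) == pytest.approx(0.0455, abs=5e-5)
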