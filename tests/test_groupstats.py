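"""Exclusion rules, aggregation, RM-ANOVA, Holm post-hocs, group t-tests."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from beatsync import groupstats
from beatsync.core import InvalidParameterError


def trial_table(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id", "group", "condition", "tempo_bpm",
            "trial_index", "SC", "p", "phase_locked",
        ],
    )


def make_trials(pid, group, n_locked, n_unlocked, sc=2.0, condition="mask"):
    rows = []
    for i in range(n_locked):
        rows.append([pid, group, condition, 110.0, i, sc, 1e-6, True])
    for i in range(n_unlocked):
        rows.append([pid, group, condition, 115.0, i, np.nan, 0.5, False])
    return rows


class TestTrialExclusions:
    def test_above_alpha_excluded(self):
        t = trial_table([["H01", "hearing", "mask", 110.0, 0, 2.0, 0.01, False]])
        kept, excluded = groupstats.apply_trial_exclusions(t, alpha=0.001)
        assert len(kept) == 0 and len(excluded) == 1
        assert excluded["exclusion_reason"].iloc[0] == "not_phase_locked"

    def test_all_locked_kept(self):
        t = trial_table(make_trials("H01", "hearing", 6, 0))
        kept, excluded = groupstats.apply_trial_exclusions(t)
        assert len(kept) == 6 and len(excluded) == 0

    def test_mixed_counts(self):
        t = trial_table(make_trials("H01", "hearing", 7, 5))
        kept, excluded = groupstats.apply_trial_exclusions(t)
        assert len(kept) == 7 and len(excluded) == 5

    def test_empty_input_is_empty_output(self):
        t = trial_table([])
        kept, excluded = groupstats.apply_trial_exclusions(t)
        assert len(kept) == 0 and len(excluded) == 0


class TestParticipantExclusions:
    def test_majority_unlocked_participant_removed(self):
        rows = make_trials("D01", "deaf", 5, 7) + make_trials("D02", "deaf", 12, 0)
        t = trial_table(rows)
        kept, _ = groupstats.apply_trial_exclusions(t)
        kept, pids, reasons = groupstats.apply_participant_exclusions(
            t, kept, outlier_cells=[]
        )
        assert pids == ["D02"]
        assert reasons.iloc[0].tolist() == ["D01", "majority_unlocked"]

    def test_exactly_half_unlocked_is_retained(self):
        t = trial_table(make_trials("D01", "deaf", 6, 6))
        kept, _ = groupstats.apply_trial_exclusions(t)
        _, pids, reasons = groupstats.apply_participant_exclusions(t, kept, outlier_cells=[])
        assert pids == ["D01"] and len(reasons) == 0

    def _cohort_with_outlier(self, outlier_sc):
        rows = []
        scores = [2.0, 2.1, 1.9, 2.2, 1.8, 2.05, outlier_sc]
        for i, sc in enumerate(scores):
            rows += make_trials(f"H{i:02d}", "hearing", 4, 0, sc=sc, condition="auditory")
        return trial_table(rows)

    def test_planted_low_outlier_excluded(self):
        t = self._cohort_with_outlier(0.2)
        kept, _ = groupstats.apply_trial_exclusions(t)
        _, pids, reasons = groupstats.apply_participant_exclusions(
            t, kept, outlier_cells=[("hearing", "auditory")]
        )
        assert "H06" not in pids
        assert reasons["reason"].iloc[0] == "low_outlier_hearing_auditory"
        assert len(reasons) == 1

    def test_participant_at_exact_boundary_retained(self):
        """Strict inequality: a mean exactly at mean - 2*SD stays in."""
        from scipy.optimize import brentq

        others = np.array([2.0, 2.1, 1.9, 2.2, 1.8, 2.05])

        def gap(x):
            s = np.append(others, x)
            return x - (s.mean() - 2 * s.std(ddof=1))

        exact = brentq(gap, -10.0, 1.9, xtol=1e-14)

        def run(value):
            t = self._cohort_with_outlier(value)
            t.loc[t["participant_id"] == "H06", "SC"] = value
            kept, _ = groupstats.apply_trial_exclusions(t)
            _, pids, _ = groupstats.apply_participant_exclusions(
                t, kept, outlier_cells=[("hearing", "auditory")]
            )
            return "H06" in pids

        # strictly below the self-consistent boundary: excluded; at/above: kept
        assert not run(exact - 1e-6)
        assert run(exact + 1e-9)

    def test_small_group_skips_rule_with_warning(self):
        rows = make_trials("H00", "hearing", 4, 0, condition="auditory")
        rows += make_trials("H01", "hearing", 4, 0, condition="auditory")
        t = trial_table(rows)
        kept, _ = groupstats.apply_trial_exclusions(t)
        with pytest.warns(RuntimeWarning, match="outlier rule skipped"):
            _, pids, _ = groupstats.apply_participant_exclusions(
                t, kept, outlier_cells=[("hearing", "auditory")]
            )
        assert pids == ["H00", "H01"]


class TestAggregation:
    def test_two_trials_average(self):
        t = trial_table(
            [
                ["H01", "hearing", "mask", 110.0, 0, 2.0, 1e-6, True],
                ["H01", "hearing", "mask", 110.0, 1, 3.0, 1e-6, True],
            ]
        )
        cells = groupstats.aggregate_cells(t)
        assert len(cells) == 1
        assert cells["SC"].iloc[0] == pytest.approx(2.5)
        assert cells["n_trials"].iloc[0] == 2

    def test_single_survivor_flagged(self):
        t = trial_table([["H01", "hearing", "mask", 110.0, 0, 2.0, 1e-6, True]])
        cells = groupstats.aggregate_cells(t)
        assert cells["n_trials"].iloc[0] == 1

    def test_missing_cell_absent_and_listwise_deleted(self):
        rows = []
        for cond in ("mask", "muff"):
            for tempo in (110.0, 115.0):
                rows.append(["H01", "hearing", cond, tempo, 0, 2.0, 1e-6, True])
        rows.append(["H02", "hearing", "mask", 110.0, 0, 2.0, 1e-6, True])
        cells = groupstats.aggregate_cells(trial_table(rows))
        complete = groupstats.complete_cases(cells, ("mask", "muff"), (110.0, 115.0))
        assert set(complete["participant_id"]) == {"H01"}


def random_cell_table(rng, n_subjects=14, a_levels=3, b_levels=3):
    rows = []
    for s in range(n_subjects):
        for i in range(a_levels):
            for j in range(b_levels):
                rows.append(
                    {
                        "participant_id": f"S{s:02d}",
                        "condition": f"c{i}",
                        "tempo_bpm": float(110 + 5 * j),
                        "SC": rng.normal(2.0 + 0.3 * i, 0.5),
                    }
                )
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_degrees_of_freedom_14_subjects_3_levels(self, rng):
        res = groupstats.rm_anova(random_cell_table(rng))
        cond = res["condition"]
        assert (cond.df_num, cond.df_den) == (2, 26)
        inter = res["condition*tempo_bpm"]
        assert (inter.df_num, inter.df_den) == (4, 52)

    def test_zero_effect_gives_zero_F(self, rng):
        df = random_cell_table(rng)
        # make every participant's scores identical across conditions
        base = df[df["condition"] == "c0"].set_index(["participant_id", "tempo_bpm"])["SC"]
        df["SC"] = df.apply(
            lambda r: base.loc[(r["participant_id"], r["tempo_bpm"])], axis=1
        )
        res = groupstats.rm_anova(df)
        assert res["condition"].F == pytest.approx(0.0, abs=1e-12)
        assert res["condition"].partial_eta_sq == pytest.approx(0.0, abs=1e-12)

    def test_matches_statsmodels_anovarm(self, rng):
        """Cross-check against an established mixed/repeated-measures routine."""
        from statsmodels.stats.anova import AnovaRM

        for _ in range(5):
            df = random_cell_table(rng)
            ours = groupstats.rm_anova(df)
            sm = AnovaRM(
                df, depvar="SC", subject="participant_id",
                within=["condition", "tempo_bpm"],
            ).fit().anova_table
            for effect, key in [
                ("condition", "condition"),
                ("tempo_bpm", "tempo_bpm"),
                ("condition*tempo_bpm", "condition:tempo_bpm"),
            ]:
                e = ours[effect]
                assert e.F == pytest.approx(sm.loc[key, "F Value"], abs=1e-8)
                assert e.df_num == int(sm.loc[key, "Num DF"])
                assert e.df_den == int(sm.loc[key, "Den DF"])
                assert e.p == pytest.approx(sm.loc[key, "Pr > F"], abs=1e-8)

    def test_partial_eta_identity(self, rng):
        """partial eta^2 == F*dfn / (F*dfn + dfd) in a fully-within design."""
        res = groupstats.rm_anova(random_cell_table(rng))
        for e in res.effects:
            expected = e.F * e.df_num / (e.F * e.df_num + e.df_den)
            assert e.partial_eta_sq == pytest.approx(expected, abs=1e-10)

    def test_ss_conservation(self, rng):
        df = random_cell_table(rng)
        res = groupstats.rm_anova(df)
        parts = res.ss_subject + sum(e.ss for e in res.effects) + sum(
            e.ms_error * e.df_den for e in res.effects
        )
        assert parts == pytest.approx(res.ss_total, rel=1e-8)

    def test_null_p_values_are_uniform(self, rng):
        """Exchangeable data with no planted effects: condition p-values are
        uniform (KS test over 500 simulated tables not rejecting at 0.01)."""
        from scipy.stats import kstest

        ps = []
        for _ in range(500):
            df = random_cell_table(rng, n_subjects=8)
            df["SC"] = rng.normal(2.0, 0.5, size=len(df))  # no condition effect
            res = groupstats.rm_anova(df)
            ps.append(res["condition"].p)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_unbalanced_rejected(self, rng):
        df = random_cell_table(rng).iloc[:-1]
        with pytest.raises(InvalidParameterError, match="balanced"):
            groupstats.rm_anova(df)

    def test_single_level_factor_rejected(self, rng):
        df = random_cell_table(rng, a_levels=1)
        with pytest.raises(InvalidParameterError, match="levels"):
            groupstats.rm_anova(df)


class TestHolm:
    def test_hand_stepped_example(self):
        adj = groupstats.holm_posthoc([0.01, 0.02, 0.03])
        assert np.allclose(adj, [0.03, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert groupstats.holm_posthoc([0.2]) == pytest.approx([0.2])

    def test_capped_at_one(self):
        assert np.all(groupstats.holm_posthoc([0.9, 0.95]) <= 1.0)

    def test_domain_error(self):
        with pytest.raises(InvalidParameterError):
            groupstats.holm_posthoc([0.5, 1.2])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=8)
    )
    def test_adjusted_at_least_raw_and_monotone(self, ps):
        adj = groupstats.holm_posthoc(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestTwoSampleT:
    def test_df_for_14_vs_7(self, rng):
        t, df, p = groupstats.two_sample_t(rng.normal(size=14), rng.normal(size=7))
        assert df == 19

    def test_identical_constant_groups(self):
        t, df, p = groupstats.two_sample_t([2.0, 2.0, 2.0], [2.0, 2.0])
        assert t == 0.0 and p == 1.0

    def test_matches_textbook_pooled_formula(self, rng):
        x, y = rng.normal(size=14), rng.normal(1.0, 2.0, size=7)
        t, df, p = groupstats.two_sample_t(x, y)
        sp2 = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) / df
        t0 = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / len(x) + 1 / len(y)))
        assert t == pytest.approx(t0, abs=1e-10)

    def test_tiny_group_rejected(self):
        with pytest.raises(InvalidParameterError):
            groupstats.two_sample_t([1.0], [1.0, 2.0])


class TestAveraging:
    def _cells(self, rows):
        return pd.DataFrame(
            rows, columns=["participant_id", "group", "condition", "tempo_bpm", "SC"]
        )

    def test_mask_muff_average(self):
        cells = self._cells(
            [
                ["D01", "deaf", "mask", 110.0, 2.0],
                ["D01", "deaf", "muff", 110.0, 2.4],
            ]
        )
        combined = groupstats.average_mask_muff(cells)
        assert combined["D01"] == pytest.approx(2.2)

    def test_tempo_averaging_is_arithmetic_mean(self):
        cells = self._cells(
            [["D01", "deaf", "mask", t, v] for t, v in [(110, 1.0), (115, 2.0), (120, 3.0)]]
            + [["D01", "deaf", "muff", 110.0, 2.0]]
        )
        assert groupstats.average_mask_muff(cells)["D01"] == pytest.approx(2.0)

    def test_missing_condition_participant_dropped(self):
        cells = self._cells([["D01", "deaf", "mask", 110.0, 2.0]])
        assert len(groupstats.average_mask_muff(cells)) == 0
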