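"""Discrimination functions, subgroup classification, and group statistics."""

import numpy as np
import pandas as pd
import pytest

from tinassay.inference import (
    PROMINENT_ANTAGONIST,
    PROMINENT_NO_DRUG,
    WEAK_AGONIST,
    classify_subgroups,
    discrimination_function,
    group_compare,
    ihc_group_ttest,
    mixed_anova,
)


def probe_frame(rows):
    return pd.DataFrame(
        rows, columns=["animal_id", "exposed", "stim_kind", "freq_khz", "level_db", "R"]
    )


class TestDiscriminationFunction:
    def test_single_animal_single_probe_per_level(self):
        rows = [("a1", True, "tone", 20.0, lv, r) for lv, r in [(30, 0.5), (50, 0.3), (70, 0.1)]]
        rows.append(("a1", True, "speaker_off", np.nan, np.nan, 0.05))
        per_animal, pooled = discrimination_function(probe_frame(rows), "tone")
        assert list(pooled["mean_R"]) == [0.05, 0.5, 0.3, 0.1]  # OFF point first
        assert pooled["sem_R"].isna().all()  # one animal: SEM undefined/flagged
        assert np.isnan(pooled.iloc[0]["level_db"])

    def test_animals_weighted_equally(self):
        rows = []
        for lv in (30.0, 50.0):
            rows += [("a1", True, "tone", 20.0, lv, 0.2)] * 3  # 3 probes
            rows += [("a2", True, "tone", 20.0, lv, 0.4)] * 7  # 7 probes
        _, pooled = discrimination_function(probe_frame(rows), "tone", include_speaker_off=False)
        assert list(pooled["mean_R"]) == [pytest.approx(0.3)] * 2

    def test_absent_stimulus_errors(self):
        rows = [("a1", True, "tone", 20.0, 50.0, 0.4)]
        with pytest.raises(ValueError, match="bbn"):
            discrimination_function(probe_frame(rows), "bbn")

    def test_simulated_tinnitus_group_lies_below_controls(self):
        """tau=0.8 cohort's 20 kHz function is below the tau=0 cohort at
        every level >= 50 dB (Monte-Carlo under the generative model)."""
        from tinassay.behavior import simulate_cohort
        from tinassay.inference import score_cohort

        cohort = simulate_cohort(6, 6, tau_distribution=0.8, n_sessions=6, seed=17)
        probe_df, _ = score_cohort(cohort)
        exposed = probe_df[probe_df["exposed"]]
        control = probe_df[~probe_df["exposed"]]
        _, f_exp = discrimination_function(exposed, "tone", include_speaker_off=False)
        _, f_ctl = discrimination_function(control, "tone", include_speaker_off=False)
        merged = f_exp.merge(f_ctl, on="level_db", suffixes=("_exp", "_ctl"))
        high = merged[merged["level_db"] >= 50.0]
        assert len(high) == 5
        assert (high["mean_R_exp"] < high["mean_R_ctl"]).all()


class TestClassifySubgroups:
    def make_means(self, n=24, seed=0):
        rng = np.random.default_rng(seed)
        return pd.Series(rng.uniform(0, 1, n), index=[f"E{i:02d}" for i in range(n)])

    def test_sixteen_prominent_eight_weak(self):
        out = classify_subgroups(self.make_means(), seed=1)
        counts = out["group"].value_counts()
        assert counts[PROMINENT_ANTAGONIST] == 8
        assert counts[PROMINENT_NO_DRUG] == 8
        assert counts[WEAK_AGONIST] == 8

    def test_lowest_ratios_are_prominent(self):
        means = self.make_means(seed=3)
        out = classify_subgroups(means, seed=0)
        prominent = set(out[out["group"].str.contains("prominent")]["animal_id"])
        lowest16 = set(means.sort_values().index[:16])
        assert prominent == lowest16

    def test_all_ties_still_sixteen_eight_by_id_order(self):
        means = pd.Series(0.5, index=[f"E{i:02d}" for i in range(24)])
        out = classify_subgroups(means, seed=5)
        assert (out["group"].value_counts() == 8).all()
        weak = out[out["group"] == WEAK_AGONIST]["animal_id"]
        assert set(weak) == {f"E{i:02d}" for i in range(16, 24)}  # tie-break: id order

    def test_input_order_invariance(self):
        means = self.make_means(seed=7)
        a = classify_subgroups(means, seed=2)
        b = classify_subgroups(means.sample(frac=1, random_state=0), seed=2)
        pd.testing.assert_frame_equal(a, b)

    def test_shortfall_is_named(self):
        with pytest.raises(ValueError, match="24"):
            classify_subgroups(self.make_means(n=20), seed=0)

    def test_split_depends_on_seed_only(self):
        means = self.make_means(seed=9)
        a = classify_subgroups(means, seed=4)
        b = classify_subgroups(means, seed=4)
        pd.testing.assert_frame_equal(a, b)


class TestMixedAnova:
    def long(self, cells, reps=1):
        rows = []
        for (subj, grp), values in cells.items():
            for lv, v in enumerate(values):
                rows.append({"animal_id": subj, "group": grp, "level_db": float(lv), "mean_R": v})
        return pd.DataFrame(rows)

    def test_hand_computed_toy(self):
        """2 groups x 2 levels x 2 subjects; sums of squares done by hand:
        SS_group=40.5, SS_subj(group)=10, SS_level=8, SS_inter=0, SS_err=1."""
        data = self.long(
            {
                ("s1", "A"): (3.0, 5.0),
                ("s2", "A"): (4.0, 6.0),
                ("s3", "B"): (7.0, 8.0),
                ("s4", "B"): (9.0, 12.0),
            }
        )
        out = mixed_anova(data).set_index("effect")
        assert out.loc["group", "SS"] == pytest.approx(40.5, abs=1e-10)
        assert out.loc["subjects(group)", "SS"] == pytest.approx(10.0, abs=1e-10)
        assert out.loc["level", "SS"] == pytest.approx(8.0, abs=1e-10)
        assert out.loc["group:level", "SS"] == pytest.approx(0.0, abs=1e-10)
        assert out.loc["residual", "SS"] == pytest.approx(1.0, abs=1e-10)
        assert out.loc["group", "F"] == pytest.approx(8.1, abs=1e-10)
        assert (out.loc["group", "df"], out.loc["group", "df_error"]) == (1, 2)
        assert out.loc["level", "F"] == pytest.approx(16.0, abs=1e-10)
        assert out.loc["group:level", "F"] == 0.0

    def test_identical_groups_give_null_group_effect(self):
        rng = np.random.default_rng(2)
        base = rng.normal(0.5, 0.01, 4)
        cells = {}
        for g in ("A", "B"):
            for s in range(4):
                cells[(f"{g}{s}", g)] = tuple(base)  # groups identical by construction
        out = mixed_anova(self.long(cells)).set_index("effect")
        assert out.loc["group", "F"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc["group", "p"] == pytest.approx(1.0)

    def test_matches_pingouin_on_balanced_designs(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        for g, l, n in [(2, 2, 3), (2, 4, 5), (3, 3, 4)]:
            rows = []
            for gi in range(g):
                for si in range(n):
                    for li in range(l):
                        rows.append(
                            {
                                "animal_id": f"g{gi}s{si}",
                                "group": f"G{gi}",
                                "level_db": float(li),
                                "mean_R": rng.normal(0.1 * gi + 0.05 * li, 0.1),
                            }
                        )
            df = pd.DataFrame(rows)
            mine = mixed_anova(df).set_index("effect")
            theirs = pg.mixed_anova(
                df, dv="mean_R", within="level_db", between="group", subject="animal_id"
            ).set_index("Source")
            assert mine.loc["group", "F"] == pytest.approx(theirs.loc["group", "F"], abs=1e-8)
            assert mine.loc["level", "F"] == pytest.approx(theirs.loc["level_db", "F"], abs=1e-8)
            assert mine.loc["group:level", "F"] == pytest.approx(
                theirs.loc["Interaction", "F"], abs=1e-8
            )

    def test_missing_cells_are_listed(self):
        data = self.long({("s1", "A"): (1.0, 2.0), ("s2", "B"): (1.0, 2.0)})
        data = data.drop(data[(data.animal_id == "s2") & (data.level_db == 1.0)].index)
        with pytest.raises(ValueError, match="s2"):
            mixed_anova(data)

    def test_group_compare_requires_assignments(self):
        lm = pd.DataFrame(
            {"animal_id": ["a", "a", "b", "b"], "level_db": [1.0, 2.0, 1.0, 2.0],
             "mean_R": [0.1, 0.2, 0.3, 0.4]}
        )
        with pytest.raises(ValueError, match="without a group"):
            group_compare(lm, {"a": "x"})


class TestIhcTTest:
    def test_identical_groups(self):
        t, df, p = ihc_group_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and df == 4

    def test_hand_computed_example(self):
        t, df, p = ihc_group_ttest([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert t == pytest.approx(-3.6742346141747673, abs=1e-9)
        assert df == 4
        assert p == pytest.approx(0.021311641128756727, abs=1e-9)

    def test_location_invariance(self):
        a, b = [1.0, 2.5, 3.0, 4.0], [2.0, 2.2, 5.0]
        t1 = ihc_group_ttest(a, b).t
        t2 = ihc_group_ttest([x + 10 for x in a], [x + 10 for x in b]).t
        assert t1 == pytest.approx(t2)

    def test_zero_variance_equal_means_convention(self):
        t, df, p = ihc_group_ttest([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            ihc_group_ttest([1.0], [2.0, 3.0])
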