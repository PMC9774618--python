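"""Tests for exclusions, scale scoring, reliability, and the stats battery."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

import moralcan as mc
from moralcan.analysis import (
    DDI_SPEC,
    FS_SPEC,
    ScaleSpec,
    item_matrix,
    reverse_code,
    tidy_correlations,
)
from moralcan.errors import ValidationError, ZeroVarianceError

pingouin = pytest.importorskip("pingouin")


def demo_frame(latencies, imc_pass=None):
    n = len(latencies)
    return pd.DataFrame(
        {
            "participant_id": [f"P{i}" for i in range(n)],
            "gender": ["male"] * n,
            "age": [30] * n,
            "relationship_status": ["single"] * n,
            "imc_pass": imc_pass if imc_pass is not None else [True] * n,
            "total_latency_s": latencies,
        }
    )


def scales_frame(values: dict, scale_id="fs"):
    rows = [
        {"participant_id": pid, "scale_id": scale_id, "item_id": item,
         "value": v}
        for pid, items in values.items()
        for item, v in items.items()
    ]
    return pd.DataFrame(rows)


class TestExclusions:
    def test_identical_latencies_retain_everyone(self):
        retained, log = mc.apply_exclusions(demo_frame([600.0] * 10))
        assert len(retained) == 10 and len(log) == 0

    def test_imc_failures_dropped_first(self):
        demo = demo_frame([600.0] * 6, imc_pass=[True, False, True, True, True, True])
        retained, log = mc.apply_exclusions(demo)
        assert "P1" not in retained
        assert log.loc[log.participant_id == "P1", "reason"].item() == "imc_failure"

    def test_latency_stats_computed_after_imc_exclusion(self):
        # P0 fails the attention check AND has an enormous latency; with it
        # removed first, the remaining latencies are tight and P5 (late but
        # inside 3 SD of the clean sample including the contaminated stats?)
        # -- the point: the trim must use clean-sample statistics.
        latencies = [1e6, 600, 610, 590, 605, 900]
        demo = demo_frame(latencies, imc_pass=[False] + [True] * 5)
        retained, log = mc.apply_exclusions(demo)
        # clean sample mean ~661, sd ~134 -> 900 is inside 3 SD
        assert set(retained) == {"P1", "P2", "P3", "P4", "P5"}

    def test_boundary_participant_exactly_3sd_is_retained(self):
        """The rule drops strictly-outside values; a participant at exactly
        mean + 3*SD stays (boundary solved numerically for this sample)."""
        rng = np.random.default_rng(11)
        base = list(rng.normal(500.0, 15.0, 29))

        def gap(x):
            full = np.array(base + [x])
            return x - (full.mean() + 3 * full.std(ddof=1))

        x_star = optimize.brentq(gap, max(base), 1e6)
        # land a hair inside the boundary to dodge root-finder residue
        retained, _ = mc.apply_exclusions(demo_frame(base + [x_star - 1e-6]))
        assert len(retained) == 30
        retained, _ = mc.apply_exclusions(demo_frame(base + [x_star * 1.5]))
        assert len(retained) == 29

    def test_row_order_never_changes_the_retained_set(self):
        rng = np.random.default_rng(8)
        latencies = rng.lognormal(6.5, 0.3, 60)
        latencies[7] *= 25
        demo = demo_frame(latencies)
        baseline, _ = mc.apply_exclusions(demo)
        shuffled, _ = mc.apply_exclusions(
            demo.sample(frac=1, random_state=1).reset_index(drop=True)
        )
        assert set(baseline) == set(shuffled)

    def test_missing_latency_raises(self):
        demo = demo_frame([600.0, np.nan, 610.0])
        with pytest.raises(ValidationError, match="latency"):
            mc.apply_exclusions(demo)


class TestScoring:
    def test_sum_of_constant_items(self):
        spec = ScaleSpec("fs", FS_SPEC.item_ids)  # no reverses
        scales = scales_frame({"P0": {i: 3 for i in spec.item_ids}})
        assert mc.score_scale(scales, spec).loc["P0"] == 18

    def test_reverse_item_recoded_before_summing(self):
        spec = ScaleSpec("fs", FS_SPEC.item_ids, reverse_items=("fs_1",))
        items = {"fs_1": 5, **{i: 1 for i in spec.item_ids[1:]}}
        scales = scales_frame({"P0": items})
        assert mc.score_scale(scales, spec).loc["P0"] == 6  # (6-5) + 5*1

    def test_scored_subset_restricts_the_sum(self):
        spec = ScaleSpec("fs", FS_SPEC.item_ids,
                         scored_subset=FS_SPEC.item_ids[:5])
        scales = scales_frame({"P0": {i: 2 for i in FS_SPEC.item_ids}})
        assert mc.score_scale(scales, spec).loc["P0"] == 10

    def test_missing_item_names_participant_and_item(self):
        scales = scales_frame(
            {"P0": {i: 3 for i in FS_SPEC.item_ids},
             "P1": {i: 3 for i in FS_SPEC.item_ids[:-1]}}
        )
        with pytest.raises(ValidationError, match="P1.*fs_6"):
            mc.score_scale(scales, FS_SPEC)

    def test_out_of_range_value_rejected(self):
        scales = scales_frame({"P0": {**{i: 3 for i in FS_SPEC.item_ids},
                                      "fs_2": 7}})
        with pytest.raises(ValidationError, match="out-of-range"):
            mc.score_scale(scales, FS_SPEC)

    def test_reverse_coding_is_an_involution(self):
        values = np.array([1, 2, 3, 4, 5])
        assert (reverse_code(reverse_code(values)) == values).all()

    def test_score_tracks_planted_trait(self, small_cohort):
        scores = mc.score_scale(small_cohort["scales"], DDI_SPEC)
        latents = small_cohort["latents"].set_index("participant_id")
        r = np.corrcoef(scores, latents.loc[scores.index, "dd_latent"])[0, 1]
        assert r > 0.5


class TestCronbachAlpha:
    def test_perfectly_correlated_items(self):
        # parallel items: identical up to a shift, so alpha must be exactly 1
        x = np.arange(10, dtype=float)
        items = pd.DataFrame({"a": x, "b": x + 5})
        assert mc.cronbach_alpha(items) == pytest.approx(1.0)

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(12)
        items = pd.DataFrame(rng.normal(size=(4000, 6)))
        assert abs(mc.cronbach_alpha(items)) < 0.05

    def test_zero_total_variance_is_signalled(self):
        items = pd.DataFrame({"a": [3, 2, 1], "b": [1, 2, 3]})
        with pytest.raises(ZeroVarianceError):
            mc.cronbach_alpha(items)

    def test_matches_independent_implementation(self, small_cohort):
        wide = item_matrix(small_cohort["scales"], FS_SPEC)
        ours = mc.cronbach_alpha(wide)
        theirs = pingouin.cronbach_alpha(data=wide)[0]
        assert ours == pytest.approx(theirs, abs=1e-10)


class TestCorrelations:
    def test_perfect_linear_relation(self):
        df = pd.DataFrame({"x": np.arange(10.0)})
        df["y"] = 2 * df["x"] + 1
        r, p, n = mc.correlation_matrix(df)
        assert r.loc["x", "y"] == pytest.approx(1.0)
        assert p.loc["x", "y"] < 1e-12

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(5000, 2)), columns=["x", "y"])
        r, _, _ = mc.correlation_matrix(df)
        assert abs(r.loc["x", "y"]) < 0.04

    def test_matches_scipy_pearsonr(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.normal(size=(40, 2)), columns=["x", "y"])
        r, p, _ = mc.correlation_matrix(df)
        ref = stats.pearsonr(df["x"], df["y"])
        assert r.loc["x", "y"] == pytest.approx(ref.statistic, abs=1e-12)
        assert p.loc["x", "y"] == pytest.approx(ref.pvalue, abs=1e-12)

    def test_constant_column_warns_and_yields_nan(self):
        df = pd.DataFrame({"x": np.arange(5.0), "c": 1.0})
        with pytest.warns(UserWarning, match="constant"):
            r, p, _ = mc.correlation_matrix(df)
        assert np.isnan(r.loc["x", "c"]) and np.isnan(p.loc["x", "c"])

    def test_matrix_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(15)
        df = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
        r, _, _ = mc.correlation_matrix(df)
        assert np.allclose(r, r.T) and np.allclose(np.diag(r), 1.0)
        tidy = tidy_correlations(*mc.correlation_matrix(df))
        assert len(tidy) == 6


class TestGroupCompare:
    def test_identical_groups(self):
        values = np.r_[np.arange(10.0), np.arange(10.0)]
        labels = ["a"] * 10 + ["b"] * 10
        res = mc.group_compare(values, labels, ("a", "b"))
        assert res.estimate == 0 and res.effect_size == 0

    def test_unit_standardised_difference(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(1.0, 1.0, 4000), rng.normal(0.0, 1.0, 4000)
        res = mc.group_compare(np.r_[a, b], ["a"] * 4000 + ["b"] * 4000,
                               ("a", "b"))
        assert res.effect_size == pytest.approx(1.0, abs=0.06)

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=50)
        labels = ["a"] * 25 + ["b"] * 25
        fwd = mc.group_compare(values, labels, ("a", "b"))
        rev = mc.group_compare(values, labels, ("b", "a"))
        assert fwd.estimate == pytest.approx(-rev.estimate)
        assert fwd.effect_size == pytest.approx(-rev.effect_size)
        assert fwd.p_value == pytest.approx(rev.p_value)

    def test_matches_independent_implementation(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(0.3, 1, 40), rng.normal(0.0, 1.2, 55)
        res = mc.group_compare(np.r_[a, b], ["g1"] * 40 + ["g2"] * 55,
                               ("g1", "g2"))
        ref = pingouin.ttest(a, b, correction=False)
        assert res.estimate == pytest.approx(ref["T"].item(), abs=1e-10)
        assert res.p_value == pytest.approx(ref["p_val"].item(), abs=1e-10)
        assert abs(res.effect_size) == pytest.approx(ref["cohen_d"].item(),
                                                     abs=1e-10)

    def test_empty_group_raises(self):
        with pytest.raises(ValidationError, match="n >= 2"):
            mc.group_compare([1.0, 2.0, 3.0], ["a", "a", "a"], ("a", "b"))


class TestHarman:
    def test_rank_one_data_is_all_first_factor(self):
        x = np.random.default_rng(1).normal(size=200)
        items = pd.DataFrame({f"i{k}": (k + 1) * x for k in range(5)})
        pct, n_gt1 = mc.harman_single_factor(items)
        assert pct == pytest.approx(100.0)
        assert n_gt1 == 1

    def test_independent_items_near_uniform_share(self):
        rng = np.random.default_rng(2)
        items = pd.DataFrame(rng.normal(size=(5000, 10)))
        pct, _ = mc.harman_single_factor(items)
        assert pct == pytest.approx(100 / 10, abs=2.0)

    def test_two_factor_battery_below_threshold(self):
        """Two orthogonal 6-item factors at loading 0.7: the first component
        carries (1 + 5 * 0.49) / 12 ~ 29% of variance, well under 40%."""
        rng = np.random.default_rng(3)
        f1, f2 = rng.normal(size=(2, 3000))
        cols = {}
        for k in range(6):
            cols[f"a{k}"] = 0.7 * f1 + np.sqrt(0.51) * rng.normal(size=3000)
            cols[f"b{k}"] = 0.7 * f2 + np.sqrt(0.51) * rng.normal(size=3000)
        pct, n_gt1 = mc.harman_single_factor(pd.DataFrame(cols))
        assert pct < 40
        assert pct == pytest.approx(100 * (1 + 5 * 0.49) / 12, abs=3.0)
        assert n_gt1 == 2


class TestRunStudy2:
    def test_ac_column_equals_p3_exactly(self, small_cohort):
        res = mc.run_study2(small_cohort["decisions"], small_cohort["scales"],
                            small_cohort["demographics"])
        inc = res.participants[res.participants["included"]]
        assert (inc["ac"] == inc["p3"]).all()

    def test_exclusions_are_logged_with_reasons(self, small_cohort):
        res = mc.run_study2(small_cohort["decisions"], small_cohort["scales"],
                            small_cohort["demographics"])
        demo = small_cohort["demographics"]
        assert (res.exclusions["reason"] == "imc_failure").sum() == (
            (~demo["imc_pass"]).sum()
        )
        n_inc = int(res.participants["included"].sum())
        assert n_inc + len(res.exclusions) == len(demo)

    def test_participant_without_scales_is_logged_not_fatal(self, small_cohort):
        victim = small_cohort["demographics"].loc[
            small_cohort["demographics"]["imc_pass"], "participant_id"
        ].iloc[0]
        scales = small_cohort["scales"]
        res = mc.run_study2(
            small_cohort["decisions"],
            scales[scales["participant_id"] != victim],
            small_cohort["demographics"],
        )
        log = res.exclusions
        assert (
            log.loc[log.participant_id == victim, "reason"].item()
            == "missing_scales"
        )

    def test_planted_sign_pattern_recovered(self):
        """With the full planted trait-parameter structure (si-at +, dd-at +,
        si-op -, dd-op -), the pipeline's significant correlations show the
        planted signs."""
        corr = mc.default_latent_corr()
        order = {k: i for i, k in enumerate(
            ("at", "et", "op", "d", "si", "dd"))}

        def setr(a, b, r):
            corr[order[a], order[b]] = corr[order[b], order[a]] = r

        setr("si", "op", -0.20)
        setr("dd", "op", -0.25)
        cfg = mc.PopulationConfig(n_participants=3000, latent_corr=corr,
                                  latency_outlier_rate=0.0, seed=31)
        data = mc.generate_study2_dataset(cfg)
        res = mc.run_study2(data["decisions"], data["scales"],
                            data["demographics"])
        r, p = res.correlation_r, res.correlation_p
        for a, b, sign in (("si", "at", 1), ("dd", "at", 1),
                           ("si", "op", -1), ("dd", "op", -1)):
            assert np.sign(r.loc[a, b]) == sign
            assert p.loc[a, b] < 0.01

    def test_report_renders(self, small_cohort):
        res = mc.run_study2(small_cohort["decisions"], small_cohort["scales"],
                            small_cohort["demographics"])
        text = res.report()
        assert "Cronbach's alpha" in text
        assert "Group comparisons" in text
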