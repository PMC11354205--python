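"""Exclusions, ACR classification, stratification, and standardization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import qctscreen as q
from qctscreen import epi_report as er


def make_records(ages, sexes, vbmds, flags_missing=None, flags_fracture=None):
    n = len(ages)
    return pd.DataFrame(
        {
            "id": [f"P{i}" for i in range(n)],
            "age": ages,
            "sex": sexes,
            "vbmd": vbmds,
            "flag_missing_L1": flags_missing if flags_missing is not None else [False] * n,
            "flag_fracture_implant": flags_fracture if flags_fracture is not None else [False] * n,
        }
    )


class TestApplyExclusions:
    def test_flowchart_counts(self):
        coh = q.sample_cohort(n=2164, exclusion_counts=(235, 14), seed=0)
        included, tally = q.apply_exclusions(coh.participants)
        assert len(included) == 1915
        assert tally == {"missing_L1": 235, "fracture_implant": 14, "total": 249}

    def test_empty_input(self):
        included, tally = q.apply_exclusions(make_records([], [], []))
        assert len(included) == 0
        assert tally["total"] == 0

    def test_double_flag_counted_once_under_missing_l1(self):
        df = make_records([60], ["male"], [100.0], [True], [True])
        included, tally = q.apply_exclusions(df)
        assert len(included) == 0
        assert tally == {"missing_L1": 1, "fracture_implant": 0, "total": 1}

    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=0, max_size=60))
    def test_conservation_under_random_flags(self, flags):
        n = len(flags)
        df = make_records(
            [55] * n, ["female"] * n, [100.0] * n,
            [a for a, _ in flags], [b for _, b in flags],
        )
        included, tally = q.apply_exclusions(df)
        assert len(included) + tally["total"] == n
        assert tally["missing_L1"] + tally["fracture_implant"] == tally["total"]


class TestClassifyAcr:
    @pytest.mark.parametrize(
        "vbmd,category",
        [
            (79.99, "osteoporosis"),
            (80.0, "osteopenia"),
            (100.0, "osteopenia"),
            (120.0, "osteopenia"),
            (121.0, "normal"),
            (60.0, "osteoporosis"),
        ],
    )
    def test_threshold_rule(self, vbmd, category):
        assert q.classify_acr(vbmd) == category

    def test_enumerated_cohort(self):
        values = [60.0, 80.0, 100.0, 120.0, 121.0]
        got = [q.classify_acr(v) for v in values]
        assert got == ["osteoporosis", "osteopenia", "osteopenia", "osteopenia", "normal"]

    @pytest.mark.parametrize("bad", [0.0, -5.0, np.nan, np.inf])
    def test_invalid_input_rejected(self, bad):
        with pytest.raises(ValueError):
            q.classify_acr(bad)

    @given(st.floats(1.0, 400.0), st.floats(1.0, 400.0))
    def test_monotone_severity(self, a, b):
        lo, hi = min(a, b), max(a, b)
        order = {"osteoporosis": 0, "osteopenia": 1, "normal": 2}
        assert order[q.classify_acr(lo)] <= order[q.classify_acr(hi)]

    def test_series_classification_matches_scalar(self):
        vals = pd.Series([60.0, 80.0, 119.9, 120.0, 200.0])
        assert list(er.classify_acr_series(vals)) == [q.classify_acr(v) for v in vals]

    def test_counts_partition_cohort(self):
        coh = q.sample_cohort(n=800, seed=9).participants
        cats = er.classify_acr_series(coh["true_vbmd"])
        assert cats.value_counts().sum() == 800


class TestStratifyBmd:
    def test_quartiles_match_brute_force(self):
        df = make_records([52] * 5, ["male"] * 5, [1.0, 2.0, 3.0, 4.0, 5.0])
        out = q.stratify_bmd(df)
        row = out[out.age_bin == "50~54"].iloc[0]
        assert row["median_both"] == 3.0
        assert row["q1_both"] == 2.0
        assert row["q3_both"] == 4.0

    def test_single_record_bin(self):
        df = make_records([67], ["female"], [88.5])
        row = q.stratify_bmd(df).set_index("age_bin").loc["65~69"]
        assert row["n_both"] == 1
        assert row["median_both"] == row["q1_both"] == row["q3_both"] == 88.5

    def test_empty_bins_report_nan_not_zero(self):
        df = make_records([25], ["male"], [150.0])
        out = q.stratify_bmd(df).set_index("age_bin")
        assert out.loc["70~74", "n_both"] == 0
        assert np.isnan(out.loc["70~74", "median_both"])

    def test_cohort_median_non_increasing_after_50(self):
        coh = q.sample_cohort(n=6000, seed=23).participants.rename(
            columns={"true_vbmd": "vbmd"}
        )
        out = q.stratify_bmd(coh).set_index("age_bin")
        meds = out.loc["50~54":"85~", "median_both"].to_numpy()
        # generous slack for sampling noise around the monotone truth
        assert np.all(np.diff(meds) <= 5.0)
        assert meds[-1] < meds[0]


class TestCrudePrevalence:
    def test_printed_count_arithmetic(self):
        # >=50 cohort with 424/1232 osteoporotic: crude 34.4%
        n, k = 1232, 424
        vb = [60.0] * k + [150.0] * (n - k)
        df = make_records([60] * n, ["male"] * n, vb)
        df["category"] = er.classify_acr_series(df["vbmd"])
        out = q.crude_prevalence(df)
        assert out["combined"]["n"] == 1232
        assert out["combined"]["counts"]["osteoporosis"] == 424
        assert er.round_half_up(out["combined"]["pct"]["osteoporosis"]) == 34.4

    def test_small_cohort_arithmetic(self):
        df = make_records([55] * 10, ["female"] * 10, [60.0] * 3 + [150.0] * 7)
        df["category"] = er.classify_acr_series(df["vbmd"])
        out = q.crude_prevalence(df)
        assert out["combined"]["pct"]["osteoporosis"] == pytest.approx(30.0)

    def test_under_age_cohort_is_undefined_not_zero(self):
        df = make_records([30, 35], ["male", "female"], [150.0, 140.0])
        df["category"] = er.classify_acr_series(df["vbmd"])
        out = q.crude_prevalence(df, min_age=50)
        assert out["combined"]["n"] == 0
        assert out["combined"]["pct"]["osteoporosis"] is None

    def test_unclassified_records_rejected(self):
        df = make_records([60], ["male"], [100.0])
        with pytest.raises(ValueError):
            q.crude_prevalence(df)


class TestAgeStandardize:
    def test_uniform_prevalence_is_fixed_point(self):
        pbp = {"50~54": 12.5, "55~59": 12.5, "60~64": 12.5}
        std = er.StandardPopulation({"50~54": 0.2, "55~59": 0.5, "60~64": 0.3}, name="w")
        value, name = q.age_standardize(pbp, std)
        assert value == pytest.approx(12.5)
        assert name == "w"

    def test_two_bin_weighted_average(self):
        pbp = {"50~54": 10.0, "55~59": 30.0}
        std = er.StandardPopulation({"50~54": 0.25, "55~59": 0.75}, name="w")
        value, _ = q.age_standardize(pbp, std)
        assert value == pytest.approx(25.0)

    def test_self_weighting_identity_equals_crude(self):
        coh = q.sample_cohort(n=1500, seed=4).participants.rename(
            columns={"true_vbmd": "vbmd"}
        )
        coh["category"] = er.classify_acr_series(coh["vbmd"])
        crude = q.crude_prevalence(coh)["combined"]["pct"]["osteoporosis"]
        binning = er.AgeBinning()
        eligible = coh[coh.age >= 50]
        labels = binning.assign(eligible["age"])
        weights = {
            b: float((labels == b).sum()) / len(eligible)
            for b in binning.labels if (labels == b).sum() > 0
        }
        pbp = er.per_bin_prevalence(coh, "osteoporosis")
        value, _ = q.age_standardize(pbp, er.StandardPopulation(weights, name="self"))
        assert value == pytest.approx(crude, abs=1e-10)

    def test_standardized_bounded_by_bin_extremes(self):
        pbp = {"50~54": 5.0, "55~59": 40.0, "60~64": 20.0}
        std = er.StandardPopulation({"50~54": 0.1, "55~59": 0.6, "60~64": 0.3}, name="w")
        value, _ = q.age_standardize(pbp, std)
        assert 5.0 <= value <= 40.0

    def test_renormalization_warns_when_bins_missing(self):
        pbp = {"50~54": 10.0}
        std = q.synthetic_standard_population()
        with pytest.warns(UserWarning, match="renormalized"):
            value, _ = q.age_standardize(pbp, std)
        assert value == pytest.approx(10.0)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            er.StandardPopulation({"50~54": -0.1, "55~59": 1.1}, name="bad")


class TestPrevalenceReport:
    def test_report_deterministic_for_same_cohort(self, tmp_path):
        coh = q.sample_cohort(n=400, seed=6).participants.rename(
            columns={"true_vbmd": "vbmd"}
        )
        coh["category"] = er.classify_acr_series(coh["vbmd"])
        paths = []
        for i in (1, 2):
            rep = q.prevalence_report(coh)
            p = tmp_path / f"r{i}.csv"
            rep.to_csv(p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_report_names_standard_population(self):
        coh = q.sample_cohort(n=300, seed=8).participants.rename(
            columns={"true_vbmd": "vbmd"}
        )
        coh["category"] = er.classify_acr_series(coh["vbmd"])
        rep = q.prevalence_report(coh)
        assert rep.standard_name == "synthetic-reference-population"
        assert "synthetic-reference-population" in rep.to_text()

    def test_round_half_up_display(self):
        assert er.round_half_up(34.45) == 34.5
        assert er.round_half_up(34.44) == 34.4
        assert er.round_half_up(26.25) == 26.3
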