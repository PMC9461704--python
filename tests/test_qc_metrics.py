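import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from extraqc.qc_metrics import (
    UnitMixError,
    aggregate_lod_status,
    class_composition,
    coefficient_of_variation,
    count_above_lod,
    cv_histogram,
    cv_summary,
    cv_table,
    lod_status_table,
    summarize_above_lod,
    sum_of_concentrations,
    qc_summaries,
)
from extraqc.core_model import load_class_vocabulary

from conftest import make_dataset, replicate_group_dataset


class TestAggregateLodStatus:
    @pytest.mark.parametrize(
        "flags, expected",
        [
            ([True, True, False], "above"),
            ([True, False, False], "below"),
            ([True, True, True], "above"),
            ([True], "below"),
        ],
    )
    def test_at_least_two_replicates_rule(self, flags, expected):
        assert aggregate_lod_status(flags, min_above=2) == expected

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            aggregate_lod_status([])

    def test_exhaustive_truth_table_up_to_four_replicates(self):
        """Aggregation equals the literal 'at least two replicates' count rule."""
        for n in range(1, 5):
            for flags in itertools.product([False, True], repeat=n):
                expected = "above" if sum(flags) >= 2 else "below"
                assert aggregate_lod_status(list(flags)) == expected

    def test_monotone_in_replicate_upgrades(self):
        for n in range(2, 5):
            for flags in itertools.product([False, True], repeat=n):
                before = aggregate_lod_status(list(flags))
                for i in range(n):
                    upgraded = list(flags)
                    upgraded[i] = True
                    after = aggregate_lod_status(upgraded)
                    assert not (before == "above" and after == "below")


class TestCountAboveLod:
    def test_constructed_censoring_pattern(self):
        # 7 of 10 metabolites above LOD in >= 2 of 3 replicates
        conc = {f"m{i:02d}": [10.0, 10.0, 10.0] for i in range(7)}
        conc.update({f"m{i:02d}": [10.0, 0.0, 0.0] for i in range(7, 10)})
        statuses = {m: ["valid" if c > 0 else "below_lod" for c in v] for m, v in conc.items()}
        ds = replicate_group_dataset(conc, lods={m: 1.0 for m in conc}, statuses=statuses)
        counts = count_above_lod(ds)
        assert counts["count"].sum() == 7

    def test_all_below_lod_counts_zero(self):
        conc = {"m1": [0.0, 0.0], "m2": [0.0, 0.0]}
        statuses = {m: ["below_lod"] * 2 for m in conc}
        ds = replicate_group_dataset(conc, statuses=statuses)
        assert count_above_lod(ds).empty

    def test_groups_are_separated_by_tissue(self, small_benchmark):
        counts = count_above_lod(small_benchmark)
        status = lod_status_table(small_benchmark)
        for tissue in ("liver", "HEK"):
            sub = status[(status["tissue"] == tissue) & status["above"]]
            assert counts.loc[counts["tissue"] == tissue, "count"].sum() == len(sub)

    def test_per_class_counts_sum_to_total(self, small_benchmark):
        counts = count_above_lod(small_benchmark)
        status = lod_status_table(small_benchmark)
        totals = counts.groupby(["tissue", "protocol"]) ["count"].sum()
        expected = status[status["above"]].groupby(["tissue", "protocol"]).size()
        assert totals.to_dict() == expected.to_dict()

    def test_summarize_median_and_range(self):
        counts = pd.DataFrame(
            {
                "tissue": ["liver"] * 3,
                "protocol": ["P1", "P2", "P3"],
                "class": ["Amino Acids"] * 3,
                "count": [10, 20, 30],
            }
        )
        out = summarize_above_lod(counts)
        row = out.iloc[0]
        assert (row["median"], row["min"], row["max"]) == (20, 10, 30)

    def test_summarize_single_protocol_collapses(self):
        counts = pd.DataFrame(
            {"tissue": ["HEK"], "protocol": ["P1"], "class": ["Amino Acids"], "count": [5]}
        )
        row = summarize_above_lod(counts).iloc[0]
        assert row["median"] == row["min"] == row["max"] == 5


class TestCoefficientOfVariation:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([2, 2, 2], 0.0),
            ([1, 2, 3], 0.5),
            ([4, 6], np.sqrt(2) / 5),
        ],
    )
    def test_hand_computed_values(self, values, expected):
        assert coefficient_of_variation(values) == pytest.approx(expected, abs=1e-12)

    def test_undefined_cases_return_nan_with_warning(self):
        with pytest.warns(UserWarning):
            assert np.isnan(coefficient_of_variation([1.0]))
        with pytest.warns(UserWarning):
            assert np.isnan(coefficient_of_variation([-1.0, 1.0]))

    @given(
        values=st.lists(st.floats(0.1, 1e4), min_size=2, max_size=8),
        scale=st.floats(0.01, 100),
    )
    def test_scale_invariance(self, values, scale):
        base = coefficient_of_variation(values)
        scaled = coefficient_of_variation([scale * v for v in values])
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-12)


class TestCvSummary:
    def test_constant_replicates_all_below_threshold(self):
        conc = {f"m{i}": [5.0, 5.0, 5.0] for i in range(4)}
        ds = replicate_group_dataset(conc)
        out = cv_summary(ds, above_lod_only=False)
        assert out.iloc[0]["n_cv_below_threshold"] == 4
        assert out.iloc[0]["cv_median"] == 0.0

    def test_cv_half_counts_as_at_or_above_threshold(self):
        ds = replicate_group_dataset({"m1": [1.0, 2.0, 3.0]})
        out = cv_summary(ds, threshold=0.30, above_lod_only=False)
        assert out.iloc[0]["n_cv_below_threshold"] == 0

    def test_median_and_mad_match_brute_force(self, small_benchmark):
        out = cv_summary(small_benchmark, above_lod_only=True, mad_scale=1.0)
        cvs = cv_table(small_benchmark)
        for _, row in out.iterrows():
            sel = cvs[
                (cvs["tissue"] == row["tissue"])
                & (cvs["protocol"] == row["protocol"])
                & cvs["above_lod"]
            ]["cv"].dropna().to_numpy()
            med = np.median(sel)
            assert row["cv_median"] == pytest.approx(med)
            assert row["cv_mad"] == pytest.approx(np.median(np.abs(sel - med)))

    def test_above_lod_restriction_removes_high_cv_mass(self):
        """Censored metabolites are noisier, so restricting the histogram to
        above-LOD metabolites cannot add mass to high-CV bins."""
        rng = np.random.default_rng(0)
        conc = {}
        statuses = {}
        for i in range(20):  # clean metabolites: tight replicates
            conc[f"good{i}"] = list(10 + 0.1 * rng.standard_normal(3))
            statuses[f"good{i}"] = ["valid"] * 3
        for i in range(20):  # censored metabolites: noisy near zero
            vals = np.abs(0.05 * rng.standard_normal(3)).tolist()
            conc[f"bad{i}"] = vals
            statuses[f"bad{i}"] = ["below_lod"] * 3
        ds = replicate_group_dataset(conc, lods={m: 1.0 for m in conc}, statuses=statuses)
        cvs = cv_table(ds)
        hist_all = cv_histogram(cvs)
        hist_above = cv_histogram(cvs[cvs["above_lod"]])
        merged = hist_all.merge(
            hist_above, on=["tissue", "protocol", "bin_low", "bin_high"],
            how="left", suffixes=("_all", "_above"),
        ).fillna(0)
        high = merged[merged["bin_low"] >= 0.5]
        assert (high["count_above"] <= high["count_all"]).all()


class TestSumOfConcentrations:
    def test_simple_sum(self):
        ds = replicate_group_dataset({"m1": [1.0], "m2": [2.0], "m3": [3.0]})
        soc, _ = sum_of_concentrations(ds)
        assert soc["soc"].tolist() == [6.0]

    def test_identical_replicates_give_zero_cv(self):
        ds = replicate_group_dataset({"m1": [2.0, 2.0], "m2": [3.0, 3.0]})
        _, soc_cv = sum_of_concentrations(ds)
        assert soc_cv["soc_cv"].iloc[0] == 0.0

    def test_group_cv_equals_cv_of_replicate_sums(self, small_benchmark):
        soc, soc_cv = sum_of_concentrations(small_benchmark)
        for _, row in soc_cv.iterrows():
            sums = soc[
                (soc["tissue"] == row["tissue"]) & (soc["protocol"] == row["protocol"])
            ]["soc"].to_numpy()
            assert row["soc_cv"] == pytest.approx(coefficient_of_variation(sums))

    def test_valid_only_excludes_censored_values(self):
        ds = replicate_group_dataset(
            {"m1": [1.0, 1.0], "m2": [5.0, 5.0]},
            statuses={"m1": ["valid", "valid"], "m2": ["below_lod", "below_lod"]},
        )
        soc_valid, _ = sum_of_concentrations(ds, include="valid_only")
        soc_all, _ = sum_of_concentrations(ds, include="all_measured")
        assert soc_valid["soc"].tolist() == [1.0, 1.0]
        assert soc_all["soc"].tolist() == [6.0, 6.0]

    def test_mixed_unit_bases_rejected(self, tiny_dataset):
        ds = tiny_dataset
        ds.samples.loc[1, "unit_basis"] = "per_1e6_cells"
        with pytest.raises(UnitMixError):
            sum_of_concentrations(ds)


class TestClassComposition:
    def test_panel_fractions(self):
        vocab = load_class_vocabulary()
        mets = pd.DataFrame(
            {
                "metabolite_id": [f"M{i}" for i in range(630)],
                "class": [c for c, n in vocab.default_counts.items() for _ in range(n)],
                "lod_value": 0.0,
            }
        )
        out = class_composition(mets).set_index("class")
        assert out.loc["Triacylglycerols", "count"] == 242
        assert out.loc["Triacylglycerols", "percent"] == 38.4
        assert out.loc["Glycerophospholipids", "count"] == 90
        assert out.loc["Glycerophospholipids", "percent"] == 14.3

    def test_single_class_is_100_percent(self):
        mets = pd.DataFrame(
            {"metabolite_id": ["a", "b"], "class": ["Amino Acids"] * 2, "lod_value": 0.0}
        )
        assert class_composition(mets)["percent"].tolist() == [100.0]

    def test_rounding_is_half_up(self):
        mets = pd.DataFrame(
            {
                "metabolite_id": [f"m{i}" for i in range(8)],
                "class": ["A"] * 1 + ["B"] * 7,
                "lod_value": 0.0,
            }
        )
        out = class_composition(mets).set_index("class")
        assert out.loc["A", "percent"] == 12.5  # 12.5 exactly -> stays 12.5
        assert out.loc["B", "percent"] == 87.5


class TestBruteForceOracle:
    def test_all_summaries_match_direct_recomputation(self):
        """<= 5 metabolites: every aggregate equals a from-scratch recomputation."""
        rng = np.random.default_rng(4)
        conc = {f"m{i}": list(rng.uniform(0, 10, 3).round(3)) for i in range(5)}
        lods = {m: 2.0 for m in conc}
        statuses = {
            m: ["valid" if c > lods[m] else "below_lod" for c in v] for m, v in conc.items()
        }
        ds = replicate_group_dataset(conc, lods=lods, statuses=statuses)
        summary = qc_summaries(ds)[0]

        n_above = sum(
            1 for m, v in conc.items() if sum(c > lods[m] for c in v) >= 2
        )
        assert summary.n_above_lod_total == n_above
        assert sum(summary.n_above_lod_by_class.values()) == n_above

        cvs = []
        for m, v in conc.items():
            if sum(c > lods[m] for c in v) >= 2:
                arr = np.array(v)
                cvs.append(arr.std(ddof=1) / arr.mean())
        assert summary.cv_median == pytest.approx(np.median(cvs))
        assert summary.n_cv_below_threshold == sum(c < 0.30 for c in cvs)

        sums = [
            sum(v[r] for m, v in conc.items() if statuses[m][r] == "valid")
            for r in range(3)
        ]
        assert summary.soc_per_replicate == {
            r + 1: pytest.approx(s) for r, s in enumerate(sums)
        }
        assert summary.soc_cv == pytest.approx(
            np.std(sums, ddof=1) / np.mean(sums)
        )
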