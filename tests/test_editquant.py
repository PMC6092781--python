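import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from exonskip.editquant import (
    BaseCounts,
    DEFAULT_SEQUENCING_ERROR,
    binomial_excess_log10p,
    call_modified_sites,
    count_bases_sam,
    estimate_error_rate,
    merge_replicates,
    modification_rates,
    read_pileup_tsv,
    wald_two_proportion_test,
    write_pileup_tsv,
)

from conftest import make_genome
from oracles import binom_tail_upper, normal_two_sided_p, wald_z


def counts_from(rows, contig="c", ref="G"):
    """rows: {position: {'A':n, ...}} -> BaseCounts with a uniform ref."""
    table = pd.DataFrame.from_dict(
        {p: {b: r.get(b, 0) for b in "ACGTN"} for p, r in rows.items()}, orient="index"
    )
    table.insert(0, "ref", ref)
    table.index.name = "position"
    return BaseCounts(contig=contig, table=table)


class TestCountBases:
    SAM = (
        "@HD\tVN:1.6\n"
        "@SQ\tSN:c\tLN:50\n"
        "r1\t0\tc\t11\t60\t10M\t*\t0\t0\tGGGGGGGGGG\tIIIIIIIIII\n"
        "r2\t0\tc\t11\t60\t5M\t*\t0\t0\tGGGGA\tIIIII\n"
        "r3\t0\tc\t13\t60\t2S8M\t*\t0\t0\tTTGGGGGGGG\tIIIIIIIIII\n"
        "r4\t4\t*\t0\t0\t*\t*\t0\t0\tAAAA\tIIII\n"
    )

    def test_tallies_soft_clips_and_region(self, tmp_path):
        sam = tmp_path / "a.sam"
        sam.write_text(self.SAM)
        genome = make_genome(c="A" * 10 + "G" * 10 + "A" * 30)
        counts = count_bases_sam(sam, genome, ("c", 10, 20))
        # position 10 (0-based) covered by r1 and r2 only
        assert counts.table.loc[10, "G"] == 2
        # r2's 5th base is A at position 14; r3 starts contributing at 12
        assert counts.table.loc[14, "A"] == 1 and counts.table.loc[14, "G"] == 2
        # soft-clipped bases contribute nothing before r3's alignment start
        assert counts.depth(11) == 2
        assert counts.depth(19) == 2  # r1 + r3; r2 ended

    def test_pileup_tsv_round_trip(self, tmp_path):
        counts = counts_from({5: {"G": 8, "A": 2}, 6: {"G": 10}})
        path = tmp_path / "p.tsv"
        write_pileup_tsv(counts, path)
        again = read_pileup_tsv(path)
        assert again.contig == counts.contig
        pd.testing.assert_frame_equal(
            again.table.astype({b: float for b in "ACGTN"}),
            counts.table.astype({b: float for b in "ACGTN"}),
            check_names=False,
        )


class TestMergeReplicates:
    def test_fraction_averaging(self):
        a = counts_from({0: {"G": 8, "A": 2}})
        b = counts_from({0: {"G": 6, "A": 4}})
        merged = merge_replicates([a, b])
        rates = modification_rates(merged, 0)
        assert rates["G>A"] == pytest.approx(0.3)
        assert rates["ref_fraction"] == pytest.approx(0.7)

    def test_unequal_depths_average_rates_not_counts(self):
        a = counts_from({0: {"G": 90, "A": 10}})  # 10%
        b = counts_from({0: {"G": 700, "A": 300}})  # 30%
        merged = merge_replicates([a, b])
        assert modification_rates(merged, 0)["G>A"] == pytest.approx(0.2)


class TestModificationRates:
    def test_fractions_of_depth(self):
        c = counts_from({0: {"G": 74, "A": 26}})
        assert modification_rates(c, 0)["G>A"] == pytest.approx(0.26)

    def test_pure_reference(self):
        c = counts_from({0: {"G": 100}})
        rates = modification_rates(c, 0)
        assert rates["G>A"] == rates["G>C"] == rates["G>T"] == 0.0

    def test_rates_sum_to_one_minus_ref(self):
        c = counts_from({0: {"A": 50, "C": 25, "T": 25}})
        rates = modification_rates(c, 0)
        assert rates["G>A"] == 0.5 and rates["G>C"] == 0.25 and rates["G>T"] == 0.25
        non_ref = rates["G>A"] + rates["G>C"] + rates["G>T"]
        assert non_ref == pytest.approx(1.0 - rates["ref_fraction"])

    def test_zero_depth_is_error(self):
        c = counts_from({0: {}})
        with pytest.raises(ValueError, match="depth"):
            modification_rates(c, 0)


class TestWald:
    def test_identical_proportions_p_is_one(self):
        assert wald_two_proportion_test(30, 100, 30, 100).p_value == 1.0

    def test_derived_value_against_erfc_oracle(self):
        res = wald_two_proportion_test(50, 100, 10, 100)
        z = wald_z(50, 100, 10, 100)
        assert res.z == pytest.approx(z)
        assert z == pytest.approx(0.4 / math.sqrt(0.0034))
        assert res.p_value == pytest.approx(normal_two_sided_p(z), rel=1e-12)

    def test_symmetry_under_sample_swap(self):
        a = wald_two_proportion_test(17, 60, 41, 90)
        b = wald_two_proportion_test(41, 90, 17, 60)
        assert a.p_value == pytest.approx(b.p_value)

    def test_degenerate_equal_boundaries(self):
        assert wald_two_proportion_test(0, 50, 0, 80).p_value == 1.0
        assert wald_two_proportion_test(50, 50, 80, 80).p_value == 1.0

    def test_degenerate_unequal_uses_pooled_variance(self):
        res = wald_two_proportion_test(0, 50, 50, 50)
        assert 0 < res.p_value < 1e-10

    def test_extreme_z_reports_log10_bound(self):
        res = wald_two_proportion_test(0, 100000, 50000, 100000)
        assert res.p_value == 0.0 and res.log10_p < -323

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(1, 200), st.integers(1, 200), st.integers(0, 200), st.integers(0, 200))
    def test_p_in_unit_interval(self, n1, n2, k1, k2):
        res = wald_two_proportion_test(min(k1, n1), n1, min(k2, n2), n2)
        assert 0.0 <= res.p_value <= 1.0

    def test_p_decreases_with_separation(self):
        ps = [wald_two_proportion_test(50 + d, 1000, 50, 1000).p_value for d in range(0, 60, 10)]
        assert ps == sorted(ps, reverse=True)

    def test_zero_trials_is_error(self):
        with pytest.raises(ValueError):
            wald_two_proportion_test(0, 0, 1, 10)


class TestErrorRate:
    def test_unweighted_mean_of_site_fractions(self):
        c = counts_from({0: {"G": 999, "A": 1}, 1: {"G": 199, "A": 1}})
        assert estimate_error_rate(c) == pytest.approx((0.001 + 0.005) / 2)

    def test_pooled_mode_differs(self):
        c = counts_from({0: {"G": 999, "A": 1}, 1: {"G": 199, "A": 1}})
        assert estimate_error_rate(c, pooled=True) == pytest.approx(2 / 1200)

    def test_all_reference_control_is_zero(self):
        c = counts_from({0: {"G": 1000}, 1: {"G": 500}})
        assert estimate_error_rate(c) == 0.0

    def test_documented_default(self):
        assert DEFAULT_SEQUENCING_ERROR == 0.00383

    def test_no_coverage_is_error(self):
        c = counts_from({0: {}})
        with pytest.raises(ValueError):
            estimate_error_rate(c)


class TestBinomialCalls:
    def test_matches_exact_summation_oracle(self):
        for k, n in [(0, 100), (1, 100), (5, 500), (38, 2000), (100, 2000), (2000, 2000)]:
            ours = 10 ** float(binomial_excess_log10p(k, n, DEFAULT_SEQUENCING_ERROR)[0])
            oracle = binom_tail_upper(k, n, DEFAULT_SEQUENCING_ERROR)
            assert abs(ours - oracle) < 1e-12

    def test_strong_signal_significant(self):
        c = counts_from({0: {"G": 9900, "A": 100}})
        (call,) = call_modified_sites(c, error_rate=DEFAULT_SEQUENCING_ERROR)
        assert call.significant and call.substitution == "G>A"
        assert call.rate == pytest.approx(0.01)

    def test_zero_alternative_reads_p_is_one(self):
        c = counts_from({0: {"G": 5000}})
        (call,) = call_modified_sites(c, error_rate=DEFAULT_SEQUENCING_ERROR)
        assert call.p_value == pytest.approx(1.0) and not call.significant

    def test_observation_at_expectation_not_significant(self):
        n = 10000
        k = round(n * DEFAULT_SEQUENCING_ERROR)
        c = counts_from({0: {"G": n - k, "A": k}})
        (call,) = call_modified_sites(c, error_rate=DEFAULT_SEQUENCING_ERROR)
        assert not call.significant
        assert 0.2 < call.p_value < 0.8  # exact tail at the mean is ~0.5

    def test_only_ct_and_ga_called(self):
        table = pd.DataFrame(
            {
                "ref": ["G", "C", "A", "T"],
                "A": [500, 0, 4500, 0],
                "C": [0, 4500, 0, 0],
                "G": [4500, 0, 0, 0],
                "T": [0, 500, 500, 5000],
            },
            index=pd.Index([0, 1, 2, 3], name="position"),
        )
        table["N"] = 0
        calls = call_modified_sites(BaseCounts("c", table), error_rate=0.00383)
        assert {c.substitution for c in calls} == {"G>A", "C>T"}
        assert {c.position for c in calls} == {0, 1}  # A/T reference sites never called

    def test_underflowing_p_reported_as_log_bound(self):
        c = counts_from({0: {"G": 3715, "A": 1285}})
        (call,) = call_modified_sites(c, error_rate=0.00383)
        assert call.p_value == 0.0
        assert math.isfinite(call.log10_p) and call.log10_p < -1000
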