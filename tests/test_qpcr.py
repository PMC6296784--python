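"""Ct quantitation formulas, replicate handling and dilution selection."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from rloopkit import (
    CtRecord,
    QuantResult,
    chip_percent_enrichment,
    ddct_fold,
    drip_fold_enrichment,
    mock_corrected_drip,
    quantify_chip,
    quantify_ddct,
    quantify_drip,
    read_ct_table,
    relative_normalize,
    select_linear_dilution,
    write_ct_table,
)
from rloopkit.qpcr import BELOW_BACKGROUND, OUT_OF_RANGE

cts = st.floats(10, 35, allow_nan=False)


class TestChipPercentEnrichment:
    def test_equal_input_and_ip_at_neat_dilution_is_100_percent(self):
        assert chip_percent_enrichment(20.0, 20.0, None, 1.0) == pytest.approx(100.0)

    def test_ip_equal_mock_cancels_to_zero(self):
        assert chip_percent_enrichment(18.0, 25.0, 25.0, 8.0) == pytest.approx(0.0)

    def test_frozen_worked_example(self):
        # 100*2^(20-24-log2 10) - 100*2^(20-28-log2 10) = 0.625 - 0.0390625
        assert chip_percent_enrichment(20, 24, 28, 10) == pytest.approx(0.5859375)

    @settings(max_examples=60, derandomize=True)
    @given(cts, cts, st.floats(0.01, 2.0))
    def test_monotone_in_input_and_ip(self, ct_input, ct_ip, delta):
        base = chip_percent_enrichment(ct_input, ct_ip, None, 4.0)
        assert chip_percent_enrichment(ct_input + delta, ct_ip, None, 4.0) > base
        assert chip_percent_enrichment(ct_input, ct_ip + delta, None, 4.0) < base

    def test_nonfinite_ct_rejected(self):
        with pytest.raises(ValueError):
            chip_percent_enrichment(float("nan"), 20.0)
        with pytest.raises(ValueError):
            chip_percent_enrichment(20.0, 20.0, dilution=0.0)


class TestDripFoldEnrichment:
    @pytest.mark.parametrize(
        "ct_input,ct_drip,dilution,expected",
        [(20.0, 20.0, 1.0, 1.0), (20.0, 19.0, 1.0, 2.0), (25.0, 22.0, 1.0, 8.0)],
    )
    def test_cycle_differences_are_powers_of_two(self, ct_input, ct_drip, dilution, expected):
        assert drip_fold_enrichment(ct_input, ct_drip, dilution) == pytest.approx(expected)

    @settings(max_examples=60, derandomize=True)
    @given(cts, cts, st.floats(0.1, 100), st.floats(0.1, 16))
    def test_dilution_ct_compensation_invariance(self, ci, cd, d, c):
        """Multiplying dilution by c while adding log2(c) to the input Ct
        leaves the fold unchanged."""
        a = drip_fold_enrichment(ci, cd, d)
        b = drip_fold_enrichment(ci + math.log2(c), cd, d * c)
        assert a == pytest.approx(b, rel=1e-9)


class TestMockCorrection:
    def _q(self, value, sample="s", locus="L"):
        return QuantResult(sample, locus, value, "fold_over_input")

    def test_zero_mock_leaves_raw_unchanged(self):
        out = mock_corrected_drip(self._q(3.5), self._q(0.0))
        assert out.value == 3.5 and BELOW_BACKGROUND not in out.flags

    def test_equal_mock_flags_below_background(self):
        out = mock_corrected_drip(self._q(2.0), self._q(2.0))
        assert out.value == 0.0 and BELOW_BACKGROUND in out.flags

    def test_subtraction_not_clipped(self, rng):
        for _ in range(20):
            raw, mock = rng.uniform(0, 5, 2)
            out = mock_corrected_drip(self._q(raw), self._q(mock))
            assert out.value == pytest.approx(raw - mock)

    def test_mismatched_locus_is_an_error(self):
        with pytest.raises(ValueError):
            mock_corrected_drip(self._q(1.0, locus="A"), self._q(1.0, locus="B"))


class TestDdctFold:
    def test_all_equal_cts_give_unity(self):
        assert ddct_fold(20, 20, 20, 20) == 1.0

    def test_one_cycle_drop_doubles(self):
        assert ddct_fold(19.0, 20.0, 20.0, 20.0) == pytest.approx(2.0)

    @settings(max_examples=100, derandomize=True)
    @given(cts, cts)
    def test_identity_when_treated_equals_control(self, a, b):
        assert ddct_fold(a, b, a, b) == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=60, derandomize=True)
    @given(cts, cts, cts, cts)
    def test_matches_direct_evaluation(self, tt, rt, tc, rc):
        expected = 2.0 ** (-((tt - rt) - (tc - rc)))
        assert ddct_fold(tt, rt, tc, rc) == pytest.approx(expected, rel=1e-12)


class TestRelativeNormalize:
    def _q(self, sample, locus, value):
        return QuantResult(sample, locus, value, "percent_enrichment")

    def test_reference_maps_to_unity(self):
        res = relative_normalize([self._q("WT", "A", 4.0)], "WT")
        assert res[0].value == 1.0 and res[0].kind == "relative_fold"

    def test_double_of_reference_is_two(self):
        res = relative_normalize(
            [self._q("WT", "A", 2.0), self._q("mut", "A", 4.0)], "WT"
        )
        assert {r.sample: r.value for r in res} == {"WT": 1.0, "mut": 2.0}

    def test_per_locus_division(self, rng):
        results, expected = [], {}
        for locus, ref in (("A", 2.0), ("B", 0.5)):
            results.append(self._q("WT", locus, ref))
            v = float(rng.uniform(0.1, 5))
            results.append(self._q("mut", locus, v))
            expected[("mut", locus)] = v / ref
        out = relative_normalize(results, "WT")
        for r in out:
            if r.sample == "mut":
                assert r.value == pytest.approx(expected[(r.sample, r.locus)])

    def test_missing_reference_names_locus(self):
        with pytest.raises(ValueError, match="'B'"):
            relative_normalize([self._q("WT", "A", 1.0), self._q("mut", "B", 1.0)], "WT")

    def test_nonpositive_reference_is_an_error(self):
        with pytest.raises(ValueError):
            relative_normalize([self._q("WT", "A", 0.0)], "WT")


class TestSelectLinearDilution:
    def _rec(self, ct, dilution=1.0, rep=1):
        return CtRecord("s", "L", "input", dilution, ct, rep)

    def test_single_inside_record_is_chosen(self):
        sel = select_linear_dilution([self._rec(22.0)], (15, 32))
        (rec, flags), = sel.values()
        assert rec.ct == 22.0 and flags == ()

    def test_midmost_of_several_candidates_wins(self):
        recs = [self._rec(12.0, 1), self._rec(22.0, 10), self._rec(35.0, 100)]
        (rec, flags), = select_linear_dilution(recs, (15, 32)).values()
        assert rec.ct == 22.0 and flags == ()

    def test_all_outside_flags_nearest(self):
        recs = [self._rec(10.0, 1), self._rec(36.0, 10)]
        (rec, flags), = select_linear_dilution(recs, (15, 32)).values()
        assert rec.ct == 36.0 and OUT_OF_RANGE in flags

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            select_linear_dilution([])


class TestTablePipelines:
    def _drip_records(self, fold, dilution=10.0, reps=3, base=20.0):
        out = []
        for rep in range(1, reps + 1):
            out.append(CtRecord("s", "L", "input", dilution, base, rep))
            out.append(
                CtRecord("s", "L", "drip", dilution,
                         base - math.log2(dilution) - math.log2(fold), rep)
            )
        return out

    @pytest.mark.parametrize("fold", [1.0, 2.0, 8.0])
    def test_noiseless_drip_table_inverts_exactly(self, fold):
        res = quantify_drip(self._drip_records(fold), subtract_mock=False)
        assert res[0].value == pytest.approx(fold, rel=1e-12)

    def test_drip_mock_subtraction(self):
        records = self._drip_records(4.0)
        for rep in range(1, 4):
            records.append(
                CtRecord("s", "L", "mock", 10.0,
                         20.0 - math.log2(10.0) - math.log2(0.5), rep)
            )
        res = quantify_drip(records)
        assert res[0].value == pytest.approx(3.5, rel=1e-12)

    def test_chip_table_with_mock_recovers_percent(self):
        base, d, percent, mock_pct = 20.0, 10.0, 2.0, 0.5
        records = []
        for rep in (1, 2):
            records.append(CtRecord("s", "L", "input", d, base, rep))
            records.append(CtRecord(
                "s", "L", "ip", d,
                base - math.log2(d) - math.log2((percent + mock_pct) / 100), rep))
            records.append(CtRecord(
                "s", "L", "mock", d,
                base - math.log2(d) - math.log2(mock_pct / 100), rep))
        res = quantify_chip(records)
        assert res[0].value == pytest.approx(percent, rel=1e-12)
        assert res[0].kind == "percent_enrichment"

    def test_ddct_table(self):
        records = []
        for rep in (1, 2):
            records += [
                CtRecord("treated", "L", "ip", 1.0, 18.0, rep),
                CtRecord("control", "L", "ip", 1.0, 20.0, rep),
                CtRecord("treated", "REF", "reference", 1.0, 20.0, rep),
                CtRecord("control", "REF", "reference", 1.0, 20.0, rep),
            ]
        res = quantify_ddct(records, control_sample="control")
        by_sample = {r.sample: r.value for r in res}
        assert by_sample["treated"] == pytest.approx(4.0)
        assert by_sample["control"] == pytest.approx(1.0)

    def test_replicate_sd_propagates_from_replicatewise_evaluation(self):
        records = self._drip_records(4.0)
        # perturb one drip replicate: value-level spread becomes nonzero
        records[3] = CtRecord("s", "L", "drip", 10.0, records[3].ct + 0.5, 2)
        res = quantify_drip(records, subtract_mock=False)
        assert res[0].sd > 0

    def test_mixed_dilutions_in_group_rejected(self):
        records = self._drip_records(2.0)
        records.append(CtRecord("s", "L", "drip", 5.0, 17.0, 4))
        with pytest.raises(ValueError, match="dilution"):
            quantify_drip(records, subtract_mock=False)

    def test_ct_table_roundtrip(self, tmp_path):
        records = self._drip_records(2.0)
        p = tmp_path / "ct.tsv"
        write_ct_table(records, p)
        assert read_ct_table(p) == records
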