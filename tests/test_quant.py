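import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gammafoci import count_de, ddct, percent_input, top_k_mean
from gammafoci.quant import percent_input_table, validate_ct_table


def ct_table(rows):
    return pd.DataFrame(rows, columns=["sample", "group", "target", "replicate", "ct"])


class TestPercentInput:
    def test_one_tenth_input_three_cycle_gap(self):
        assert percent_input(28.0, 25.0, 0.1) == pytest.approx(1.25)

    def test_equal_cts_full_fraction_is_100(self):
        assert percent_input(25.0, 25.0, 1.0) == pytest.approx(100.0)

    def test_value_above_100_flagged_in_table(self):
        # IP richer than the dilution-adjusted input: percent > 100
        table = ct_table(
            [("IP_1", "IP", "locus", 1, 20.0), ("input_1", "input", "locus", 1, 24.0)]
        )
        res = percent_input_table(table, input_fraction=0.1)
        assert res[0].percent_input > 100
        assert res[0].over_100

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            percent_input(25, 25, 0.0)
        with pytest.raises(ValueError):
            percent_input(25, 25, 1.5)

    def test_non_finite_ct_rejected(self):
        with pytest.raises(ValueError):
            percent_input(float("nan"), 25.0, 0.1)

    @settings(deadline=None)
    @given(
        shift=st.floats(-5, 5),
        ct_ip=st.floats(20, 35),
        gap=st.floats(-5, 5),
        frac=st.floats(0.01, 1.0),
    )
    def test_invariant_under_common_ct_shift(self, shift, ct_ip, gap, frac):
        a = percent_input(ct_ip, ct_ip + gap, frac)
        b = percent_input(ct_ip + shift, ct_ip + gap + shift, frac)
        assert a == pytest.approx(b, rel=1e-9)


class TestDdct:
    def _table(self):
        rows = []
        # calibrator: target Ct 25, refs 20/24 -> dCt = 25 - 22 = 3
        # treated: target Ct 23, refs 20/24 -> dCt = 1; ddCt = -2 -> fold 4
        for group, tct in (("ctrl", 25.0), ("trt", 23.0)):
            for r in (1, 2):
                s = f"{group}_{r}"
                rows += [
                    (s, group, "gene", r, tct),
                    (s, group, "ref1", r, 20.0),
                    (s, group, "ref2", r, 24.0),
                ]
        return ct_table(rows)

    def test_calibrator_fold_is_one(self):
        res = {r.group: r for r in ddct(self._table(), "gene", ["ref1", "ref2"], "ctrl")}
        assert res["ctrl"].delta_delta_ct == 0.0
        assert res["ctrl"].fold_change == 1.0

    def test_two_cycle_advantage_is_fold_four(self):
        res = {r.group: r for r in ddct(self._table(), "gene", ["ref1", "ref2"], "ctrl")}
        assert res["trt"].delta_delta_ct == pytest.approx(-2.0)
        assert res["trt"].fold_change == pytest.approx(4.0)

    def test_two_references_combined_by_ct_mean(self):
        # refs at 18 and 22 behave exactly like one reference at 20
        rows = []
        for group, tct in (("ctrl", 25.0), ("trt", 23.0)):
            s = f"{group}_1"
            rows += [
                (s, group, "gene", 1, tct),
                (s, group, "refA", 1, 18.0),
                (s, group, "refB", 1, 22.0),
                (s, group, "refC", 1, 20.0),
            ]
        both = ddct(ct_table(rows), "gene", ["refA", "refB"], "ctrl")
        single = ddct(ct_table(rows), "gene", ["refC"], "ctrl")
        for a, b in zip(both, single):
            assert a.delta_ct == pytest.approx(b.delta_ct)
            assert a.fold_change == pytest.approx(b.fold_change)

    def test_missing_reference_names_sample_and_target(self):
        table = ct_table(
            [("ctrl_1", "ctrl", "gene", 1, 25.0), ("ctrl_1", "ctrl", "ref1", 1, 20.0),
             ("trt_1", "trt", "gene", 1, 22.0)]
        )
        with pytest.raises(ValueError, match="trt_1.*ref1"):
            ddct(table, "gene", ["ref1"], "ctrl")

    def test_fold_is_exact_power_of_ddct(self):
        res = ddct(self._table(), "gene", ["ref1", "ref2"], "ctrl")
        for r in res:
            assert r.fold_change == 2.0 ** (-r.delta_delta_ct)


class TestTopKMean:
    def test_exact_five_values(self):
        assert top_k_mean([1, 2, 3, 4, 5]) == pytest.approx(3.0)

    def test_eight_values_takes_five_largest(self):
        vals = [10, 9, 8, 7, 6, 3, 2, 1]
        assert top_k_mean(vals) == pytest.approx(8.0)

    def test_fewer_than_k_warns_and_averages_all(self):
        with pytest.warns(UserWarning, match="top-5"):
            assert top_k_mean([3.0, 6.0, 9.0]) == pytest.approx(6.0)

    def test_order_invariant(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 3000, 20)
        assert top_k_mean(vals) == top_k_mean(vals[::-1]) == top_k_mean(np.sort(vals))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            top_k_mean([])


class TestCountDe:
    def _table(self, p, lfc):
        return pd.DataFrame({"pvalue": p, "log2fc": lfc})

    def test_all_null_gives_zero_counts(self):
        t = self._table([1.0, 1.0, 1.0], [1.0, -1.0, 0.0])
        counts = count_de(t)
        assert (counts.n_up, counts.n_down) == (0, 0)

    def test_toy_table_hand_counted(self):
        t = self._table(
            [0.01, 0.01, 0.04, 0.5, 0.9, 0.2],
            [2.0, 1.0, -1.5, 2.0, -2.0, 0.0],
        )
        counts = count_de(t)
        assert (counts.n_up, counts.n_down) == (2, 1)

    def test_zero_alpha_counts_nothing(self):
        t = self._table([0.0, 0.001], [1.0, -1.0])
        counts = count_de(t, alpha=0.0)
        assert (counts.n_up, counts.n_down) == (0, 0)

    def test_zero_fold_significant_reported_separately(self):
        t = self._table([0.01], [0.0])
        counts = count_de(t)
        assert (counts.n_up, counts.n_down, counts.n_zero_fold) == (0, 0, 1)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError, match="p-values"):
            count_de(self._table([1.5], [1.0]))

    @settings(deadline=None)
    @given(seed=st.integers(0, 500), a1=st.floats(0, 1), a2=st.floats(0, 1))
    def test_monotone_in_alpha(self, seed, a1, a2):
        rng = np.random.default_rng(seed)
        t = self._table(rng.uniform(0, 1, 50), rng.normal(0, 1, 50))
        lo, hi = sorted([a1, a2])
        c_lo, c_hi = count_de(t, alpha=lo), count_de(t, alpha=hi)
        assert c_lo.n_up <= c_hi.n_up and c_lo.n_down <= c_hi.n_down


class TestValidateCtTable:
    def test_duplicate_wells_rejected(self):
        table = ct_table(
            [("a", "g", "x", 1, 20.0), ("a", "g", "x", 1, 21.0)]
        )
        with pytest.raises(ValueError, match="duplicate"):
            validate_ct_table(table)

    def test_nonpositive_ct_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            validate_ct_table(ct_table([("a", "g", "x", 1, 0.0)]))
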