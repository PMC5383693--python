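import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import wilcoxon as scipy_wilcoxon

from ndrscape import (
    ChromSizes,
    NdrRecord,
    NdrscapeError,
    OccupancyTrack,
    TssRecord,
    call_nucleosomes,
    delta_ndr,
    ndr_lengths,
    summarize_boxplot,
    wilcoxon_one_sample,
)
from _oracles import brute_calls, enumerate_signed_rank


def track_of(values):
    return OccupancyTrack({"chrI": np.asarray(values, dtype=float)})


class TestCallNucleosomes:
    def test_simple_peak(self):
        calls = call_nucleosomes(track_of([0, 1, 3, 2, 0]), maxima_window=4)
        assert calls.positions["chrI"].tolist() == [2]
        assert calls.values["chrI"].tolist() == [3]

    def test_constant_track_no_calls(self):
        calls = call_nucleosomes(track_of(np.ones(300)), maxima_window=100)
        assert len(calls.positions["chrI"]) == 0

    def test_plateau_leftmost(self):
        x = np.zeros(40)
        x[18:21] = 2.0
        calls = call_nucleosomes(track_of(x), maxima_window=10)
        assert calls.positions["chrI"].tolist() == [18]

    def test_edges_not_callable(self):
        x = np.zeros(30)
        x[2] = 5.0  # within window/2 of the start
        calls = call_nucleosomes(track_of(x), maxima_window=10)
        assert len(calls.positions["chrI"]) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        """Exhaustive O(n*w) window scan agrees on mixed-tie random tracks."""
        rng = np.random.default_rng(seed)
        x = np.where(
            rng.random(2000) < 0.3, 0.0, rng.integers(0, 6, 2000).astype(float)
        )
        calls = call_nucleosomes(track_of(x), maxima_window=100)
        np.testing.assert_array_equal(calls.positions["chrI"], brute_calls(x, 100))

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(shift=st.integers(min_value=0, max_value=200))
    def test_shift_equivariance(self, shift):
        rng = np.random.default_rng(42)
        x = rng.random(500)
        base = call_nucleosomes(track_of(x), maxima_window=20).positions["chrI"]
        shifted_track = track_of(np.concatenate([np.zeros(shift), x]))
        shifted = call_nucleosomes(shifted_track, maxima_window=20).positions["chrI"]
        # interior calls translate by the shift (edge effects at the seam aside)
        interior = base[(base >= 10) & (base < 490)]
        got = shifted[np.isin(shifted, interior + shift)]
        np.testing.assert_array_equal(got - shift, interior)

    def test_min_spacing_invariant(self):
        rng = np.random.default_rng(1)
        x = rng.random(3000)
        calls = call_nucleosomes(track_of(x), maxima_window=100).positions["chrI"]
        assert np.all(np.diff(calls) >= 50)


class TestNdrLengths:
    def make_calls(self, positions):
        track = np.zeros(4000)
        track[positions] = 5.0
        return call_nucleosomes(track_of(track), maxima_window=100)

    def test_length_arithmetic(self):
        tss = [TssRecord("g", "chrI", 2000, "+")]
        calls = self.make_calls([2000 - 120, 2000 + 80])
        records, omitted = ndr_lengths(calls, tss)
        assert not omitted
        r = records[0]
        assert (r.up_pos, r.down_pos, r.length) == (1880, 2080, 200)

    def test_call_at_tss_counts_downstream(self):
        tss = [TssRecord("g", "chrI", 2000, "+")]
        records, _ = ndr_lengths(self.make_calls([1900, 2000]), tss)
        assert records[0].down_pos == 2000 and records[0].length == 100

    def test_search_limit_omits(self):
        tss = [TssRecord("g", "chrI", 2000, "+")]
        _, omitted = ndr_lengths(self.make_calls([500, 2100]), tss, search_limit=1000)
        assert "g" in omitted and "upstream" in omitted["g"]

    def test_strand_does_not_affect_length(self):
        calls = self.make_calls([1880, 2080])
        for strand in "+-":
            records, _ = ndr_lengths(calls, [TssRecord("g", "chrI", 2000, strand)])
            assert records[0].length == 200

    def test_matches_nearest_neighbor_scan(self):
        rng = np.random.default_rng(2)
        positions = np.unique(rng.integers(60, 3940, 60))
        calls = self.make_calls(list(positions))
        pos = calls.positions["chrI"]
        tss_list = [TssRecord(f"g{t}", "chrI", int(t), "+") for t in
                    rng.integers(200, 3800, 25)]
        records, omitted = ndr_lengths(calls, tss_list, search_limit=1000)
        by_id = {r.gene_id: r for r in records}
        for gene in tss_list:
            before = [p for p in pos if p < gene.tss]
            after = [p for p in pos if p >= gene.tss]
            expect_up = max(before) if before else None
            expect_down = min(after) if after else None
            usable = (
                expect_up is not None and expect_down is not None
                and gene.tss - expect_up <= 1000 and expect_down - gene.tss <= 1000
            )
            if usable:
                r = by_id[gene.gene_id]
                assert (r.up_pos, r.down_pos) == (expect_up, expect_down)
            else:
                assert gene.gene_id in omitted


class TestDeltaNdr:
    def rec(self, gene, length, tss=1000):
        return NdrRecord(gene, "chrI", tss, tss - length // 2, tss + (length + 1) // 2, length)

    def test_subtraction_direction(self):
        table = delta_ndr([self.rec("g", 160)], [self.rec("g", 200)])
        assert table["delta"].tolist() == [-40]

    def test_inner_join(self):
        table = delta_ndr(
            [self.rec("a", 100), self.rec("b", 150)], [self.rec("b", 120)]
        )
        assert table["gene_id"].tolist() == ["b"]

    def test_identical_inputs_zero(self):
        recs = [self.rec("a", 100), self.rec("b", 150)]
        assert (delta_ndr(recs, recs)["delta"] == 0).all()

    def test_empty_intersection(self):
        with pytest.raises(NdrscapeError):
            delta_ndr([self.rec("a", 100)], [self.rec("b", 100)])


class TestWilcoxon:
    def test_worked_example(self):
        res = wilcoxon_one_sample([-3, -2, -1])
        assert res.statistic == 0
        assert res.pvalue == 0.25
        assert res.n_used == 3 and res.method == "exact"

    def test_symmetric_ties_give_p_one(self):
        res = wilcoxon_one_sample([-1, 1, -2, 2])
        assert res.pvalue == 1.0

    def test_all_zero_error(self):
        with pytest.raises(NdrscapeError, match="nonzero"):
            wilcoxon_one_sample([0, 0, 0])

    @pytest.mark.parametrize("case", range(40))
    def test_matches_enumeration(self, case):
        """Implementation p equals the literal 2^n sign enumeration exactly."""
        rng = np.random.default_rng(case)
        n = int(rng.integers(1, 11))
        deltas = rng.choice([-3, -2, -1, 1, 2, 3], n)
        for alt in ("two-sided", "less", "greater"):
            w, p = enumerate_signed_rank(deltas, alt)
            res = wilcoxon_one_sample(deltas, alt)
            assert res.statistic == w
            assert res.pvalue == p

    def test_matches_closed_form_null_no_ties(self):
        # without ties, P(W <= 0) = 1/2^n and P(W <= 1) = 2/2^n
        for n in (5, 8, 12):
            deltas = -np.arange(1, n + 1, dtype=float)
            res = wilcoxon_one_sample(deltas, alternative="less")
            assert res.pvalue == 1 / 2**n

    def test_permutation_invariance(self):
        deltas = [-5, 3, -2, 7, -1, 4, -6]
        base = wilcoxon_one_sample(deltas).pvalue
        rng = np.random.default_rng(0)
        for _ in range(5):
            perm = rng.permutation(deltas)
            assert wilcoxon_one_sample(perm).pvalue == base

    def test_large_n_matches_scipy_approx(self):
        rng = np.random.default_rng(9)
        deltas = rng.integers(-30, 30, 80)
        deltas = deltas[deltas != 0]
        res = wilcoxon_one_sample(deltas)
        assert res.method == "approx"
        ref = scipy_wilcoxon(deltas, correction=True, method="approx")
        assert res.pvalue == pytest.approx(ref.pvalue, rel=1e-9)

    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            deltas = rng.integers(-4, 5, rng.integers(1, 15))
            if np.all(deltas == 0):
                continue
            p = wilcoxon_one_sample(deltas).pvalue
            assert 0 < p <= 1


class TestBoxplotSummary:
    def test_interpolated_quartiles(self):
        df = summarize_boxplot({"pair": np.arange(1, 10)})
        row = df.iloc[0]
        assert row["median"] == 5 and row["q1"] == 3 and row["q3"] == 7
        assert row["whisker_low"] == 1 and row["whisker_high"] == 9

    def test_single_value(self):
        row = summarize_boxplot({"p": [4.0]}).iloc[0]
        assert (
            row["median"] == row["q1"] == row["q3"]
            == row["whisker_low"] == row["whisker_high"] == 4.0
        )

    def test_symmetric_data_median_equals_mean(self):
        data = np.array([-3, -1, 0, 1, 3], dtype=float)
        row = summarize_boxplot({"p": data}).iloc[0]
        assert row["median"] == data.mean()

    def test_whiskers_clip_outliers(self):
        data = np.array([1, 2, 3, 4, 5, 100], dtype=float)
        row = summarize_boxplot({"p": data}).iloc[0]
        assert row["whisker_high"] == 5
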