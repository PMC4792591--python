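"""Founder/clonal classification, tracing, accumulation, percentages."""

import numpy as np
import pandas as pd
import pytest

from ctcwgs import concordance
from ctcwgs.concordance import (
    accumulation_curve,
    af_recurrence_association,
    germline_check,
    identify_clonal,
    identify_founders,
    percentage,
    summarize,
    trace,
    validation_summary,
)
from ctcwgs.genotyping import LodModelParams
from ctcwgs.io_model import AlleleCountTable, Locus, VariantCallSet


def L(pos, chrom="chr1"):
    return Locus(chrom, pos, "A", "T")


def cs(name, positions):
    return VariantCallSet.from_loci(name, [L(p) for p in positions])


class TestIdentify:
    def test_founder_intersection(self):
        f = identify_founders(cs("P", [1, 2, 3]), cs("M", [2, 3, 4]))
        assert f == {L(2), L(3)}

    def test_control_subtraction(self):
        f = identify_founders(cs("P", [1, 2, 3]), cs("M", [2, 3, 4]), [cs("W", [2])])
        assert f == {L(3)}

    def test_matches_brute_force_on_random_loci(self):
        rng = np.random.default_rng(0)
        pool = [L(int(p)) for p in rng.choice(10**6, size=10_000, replace=False)]
        p_set = set(rng.choice(len(pool), 4000, replace=False))
        m_set = set(rng.choice(len(pool), 4000, replace=False))
        c_set = set(rng.choice(len(pool), 1500, replace=False))
        primary = VariantCallSet.from_loci("P", [pool[i] for i in p_set])
        met = VariantCallSet.from_loci("M", [pool[i] for i in m_set])
        ctrl = VariantCallSet.from_loci("W", [pool[i] for i in c_set])
        got = identify_founders(primary, met, [ctrl])
        brute = {pool[i] for i in p_set if i in m_set and i not in c_set}
        assert got == brute

    def test_clonal_threshold(self):
        sets = [cs("1", [1, 2]), cs("2", [1, 3]), cs("3", [1, 2]), cs("4", [4])]
        assert identify_clonal(sets, k=3) == {L(1)}
        assert L(2) not in identify_clonal(sets, k=3)
        assert identify_clonal(sets, k=1) == {L(1), L(2), L(3), L(4)}

    def test_clonal_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        pool = list(range(10_000))
        sets = [
            cs(str(i), rng.choice(pool, 3000, replace=False)) for i in range(5)
        ]
        got = identify_clonal(sets, k=3)
        brute = {
            L(p) for p in pool
            if sum(L(p) in s for s in sets) >= 3
        }
        assert got == brute

    def test_too_few_ctcs_rejected(self):
        with pytest.raises(ValueError):
            identify_clonal([cs("1", [1])], k=3)


class TestTrace:
    def _counts(self):
        return AlleleCountTable.from_records([
            ("CTC-1", L(1), 28, 2),
            ("CTC-1", L(2), 30, 0),
            ("PRIMARY", L(1), 20, 10),
            ("PRIMARY", L(2), 15, 15),
            ("MET", L(1), 30, 0),
            ("MET", L(2), 25, 5),
        ])

    def test_supported_and_called_flags(self, default_params):
        calls = {"CTC-1": cs("CTC-1", [2])}
        t = trace([L(1), L(2)], self._counts(), calls, default_params, ["CTC-1"])
        row1 = t.df[t.df.pos == 1].iloc[0]
        assert row1["supported_in_CTC-1"] and not row1["called_in_CTC-1"]
        row2 = t.df[t.df.pos == 2].iloc[0]
        assert not row2["supported_in_CTC-1"] and row2["called_in_CTC-1"]
        assert row1.af_primary == pytest.approx(10 / 30)
        assert row1.af_met == 0.0

    def test_missing_rows_are_zero_depth(self, default_params):
        calls = {"CTC-9": cs("CTC-9", [3])}
        t = trace([L(3)], self._counts(), calls, default_params, ["CTC-9"])
        row = t.df.iloc[0]
        assert not row["supported_in_CTC-9"] and row["called_in_CTC-9"]
        assert np.isnan(row.af_primary)


class TestAccumulation:
    def _tracing(self, support_sets, all_loci):
        params = LodModelParams()
        counts = AlleleCountTable.from_records([
            (sid, L(p), 28, 3 if p in sup else 0)
            for sid, sup in support_sets.items()
            for p in all_loci
        ])
        return trace([L(p) for p in all_loci], counts, {}, params,
                     list(support_sets))

    def test_brute_force_hand_example(self):
        t = self._tracing({"c1": {1, 2}, "c2": {2, 3}, "c3": {4}}, [1, 2, 3, 4])
        curve = accumulation_curve(t, ["c1", "c2", "c3"])
        assert curve.mean_count.iloc[0] == pytest.approx(5 / 3)
        assert curve.mean_count.iloc[-1] == 4
        assert curve.min_count.iloc[0] == 1 and curve.max_count.iloc[0] == 2

    def test_identical_sets_flat_curve(self):
        t = self._tracing({"c1": {1, 2}, "c2": {1, 2}, "c3": {1, 2}}, [1, 2, 3])
        curve = accumulation_curve(t, ["c1", "c2", "c3"])
        assert (curve.mean_count == 2).all()

    def test_mean_nondecreasing_and_endpoint_matches_union(self):
        rng = np.random.default_rng(2)
        loci = list(range(1, 201))
        sets = {f"c{i}": set(rng.choice(loci, 60, replace=False)) for i in range(4)}
        t = self._tracing(sets, loci)
        curve = accumulation_curve(t, list(sets))
        means = curve.mean_count.to_numpy()
        assert (np.diff(means) >= -1e-9).all()
        union = len(set().union(*sets.values()))
        assert curve.mean_count.iloc[-1] == union

    def test_too_many_cells_rejected(self, default_params):
        t = self._tracing({f"c{i}": {1} for i in range(13)}, [1])
        with pytest.raises(ValueError, match="subsample"):
            accumulation_curve(t, [f"c{i}" for i in range(13)])


class TestPercentages:
    @pytest.mark.parametrize(
        "num,den,expected",
        [(230, 802, 28.7), (197, 229, 86.0), (116, 229, 50.7),
         (770, 777, 99.1), (23, 25, 92.0)],
    )
    def test_printed_percentages_reproduced(self, num, den, expected):
        assert percentage(num, den) == expected

    def test_zero_denominator_undefined(self):
        assert percentage(5, 0) is None

    def test_half_up_rounding(self):
        assert percentage(1, 800) == 0.1   # 0.125 -> 0.1
        assert percentage(1, 8) == 12.5
        assert percentage(125, 1000) == 12.5
        assert percentage(1005, 10000) == 10.1  # 10.05 rounds half-up


class TestAssociationAndGermline:
    def _tracing_with_af(self, afs, n_support):
        rows = []
        params = LodModelParams()
        loci = [L(i + 1) for i in range(len(afs))]
        counts_rows = []
        for i, (af, ns) in enumerate(zip(afs, n_support)):
            depth = 100
            alt = int(round(af * depth))
            counts_rows.append(("PRIMARY", loci[i], depth - alt, alt))
            counts_rows.append(("MET", loci[i], depth, 0))
            for c in range(4):
                counts_rows.append(
                    (f"CTC-{c+1}", loci[i], 28, 3 if c < ns else 0)
                )
        counts = AlleleCountTable.from_records(counts_rows)
        return trace(loci, counts, {}, params, [f"CTC-{c+1}" for c in range(4)])

    def test_perfectly_ordered_gives_rho_one(self):
        t = self._tracing_with_af([0.1, 0.2, 0.3, 0.4, 0.5], [0, 1, 2, 3, 4])
        rho, n = af_recurrence_association(t, [f"CTC-{c+1}" for c in range(4)])
        assert rho == pytest.approx(1.0) and n == 5

    def test_shuffled_af_gives_small_rho(self):
        rng = np.random.default_rng(3)
        afs = np.linspace(0.05, 0.5, 60)
        support = np.clip((afs * 8).astype(int), 0, 4)
        rhos = []
        for _ in range(100):
            shuffled = rng.permutation(afs)
            t = self._tracing_with_af(shuffled.tolist(), support.tolist())
            rho, _ = af_recurrence_association(t, [f"CTC-{c+1}" for c in range(4)])
            rhos.append(rho)
        assert abs(np.mean(rhos)) < 0.05
        assert np.quantile(np.abs(rhos), 0.95) < 0.35

    def test_all_tied_undefined(self):
        t = self._tracing_with_af([0.3] * 6, [2] * 6)
        rho, n = af_recurrence_association(t, [f"CTC-{c+1}" for c in range(4)])
        assert rho is None and n == 6

    def test_too_few_loci_rejected(self):
        t = self._tracing_with_af([0.1, 0.2], [1, 2])
        with pytest.raises(ValueError):
            af_recurrence_association(t, [f"CTC-{c+1}" for c in range(4)])

    def test_germline_check_counts(self):
        ssnvs = {L(i) for i in range(1, 778)}
        ctrl = VariantCallSet.from_loci("W", [L(i) for i in range(1, 8)])
        assert germline_check(ssnvs, ctrl) == (770, 777, 99.1)
        assert germline_check(ssnvs, VariantCallSet("W", {}))[2] == 100.0
        assert germline_check({L(1)}, VariantCallSet.from_loci("W", [L(1)]))[2] == 0.0

    def test_validation_summary(self):
        df = pd.DataFrame({"confirmed": [True] * 23 + [False] * 2})
        assert validation_summary(df) == (23, 25, 92.0)


def test_simulated_founder_bookkeeping_no_false_negatives(small_config, small_truth, default_params):
    """Every true founder locus with >= support_min_alt alt reads in some
    CTC is traced as supported there (pure bookkeeping, no loss)."""
    from ctcwgs.synthetic_data import simulate_cell_counts, simulate_bulk_counts

    counts = AlleleCountTable.concat(
        [simulate_bulk_counts(small_truth, small_config)]
        + [simulate_cell_counts(small_truth, f"CTC-{i+1}", small_config) for i in range(4)]
    )
    founders = small_truth.loci("founder")
    ctc_ids = [f"CTC-{i+1}" for i in range(4)]
    t = trace(founders, counts, {}, default_params, ctc_ids)
    for sid in ctc_ids:
        lookup = counts.depth_lookup(sid)
        expected = {
            loc for loc in founders
            if lookup.get(loc, (0, 0))[1] >= default_params.support_min_alt
        }
        traced = {
            Locus(r.chrom, int(r.pos), r.ref, r.alt)
            for r in t.df[t.df[f"supported_in_{sid}"]].itertuples(index=False)
        }
        assert traced == expected
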