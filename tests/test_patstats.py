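import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from introland import patstats
from introland.gio import make_windows, polarize
from introland.patstats import (DResult, FdmTrack, TrioSpec, bh_adjust,
                                block_assignment, call_pir, d_min,
                                d_statistic, f_dm_track, f_hom,
                                introgression_index, pattern_counts,
                                top_k_mask)


def rand_freqs(n, seed):
    rng = np.random.default_rng(seed)
    return tuple(rng.random(n) for _ in range(3))


class TestPatternCounts:
    def test_single_site_pure_abba(self):
        c = pattern_counts([0.0], [1.0], [1.0])
        assert c.abba == 1.0 and c.baba == 0.0

    def test_identical_p1_p2_symmetric(self):
        p1 = np.array([0.2, 0.5, 0.9])
        c = pattern_counts(p1, p1, np.array([0.3, 0.7, 0.1]))
        assert c.abba == pytest.approx(c.baba)

    def test_matches_per_site_loop_oracle(self):
        p1, p2, p3 = rand_freqs(1000, 3)
        c = pattern_counts(p1, p2, p3)
        abba = baba = 0.0
        for a, b, d in zip(p1, p2, p3):  # independent straight-line loop
            abba += (1 - a) * b * d
            baba += a * (1 - b) * d
        assert c.abba == pytest.approx(abba, abs=1e-12)
        assert c.baba == pytest.approx(baba, abs=1e-12)
        assert c.block_abba.sum() == pytest.approx(abba, abs=1e-12)

    def test_nan_sites_dropped(self):
        c = pattern_counts([0.0, np.nan], [1.0, 0.5], [1.0, 0.5])
        assert c.n_sites == 1


class TestDStatistic:
    def test_equal_counts_give_zero(self):
        p1, p2, p3 = rand_freqs(400, 5)
        c = pattern_counts(p1, p1, p3)
        r = d_statistic(c)
        assert r.D == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetric_in_p1_p2(self):
        p1, p2, p3 = rand_freqs(500, 6)
        r12 = d_statistic(pattern_counts(p1, p2, p3))
        r21 = d_statistic(pattern_counts(p2, p1, p3))
        assert r12.D == pytest.approx(-r21.D)
        assert abs(r12.Z) == pytest.approx(abs(r21.Z), rel=1e-9)

    def test_jackknife_matches_explicit_leave_one_out(self):
        p1, p2, p3 = rand_freqs(600, 7)
        c = pattern_counts(p1, p2, p3, n_blocks=20)
        r = d_statistic(c)
        # independent leave-one-out recomputation from raw sites
        blocks = block_assignment(600, 20)
        loo = []
        for g in range(20):
            m = blocks != g
            a = np.sum((1 - p1[m]) * p2[m] * p3[m])
            b = np.sum(p1[m] * (1 - p2[m]) * p3[m])
            loo.append((a - b) / (a + b))
        loo = np.array(loo)
        var = 19 / 20 * np.sum((loo - loo.mean()) ** 2)
        assert r.Z == pytest.approx(r.D / np.sqrt(var), rel=1e-9)

    def test_zero_total_flagged_undefined(self):
        c = pattern_counts(np.zeros(50), np.zeros(50), np.zeros(50))
        assert not d_statistic(c).defined

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_d_bounded(self, seed):
        p1, p2, p3 = rand_freqs(120, seed)
        r = d_statistic(pattern_counts(p1, p2, p3))
        assert -1.0 <= r.D <= 1.0


class TestDmin:
    def test_duplicate_taxon_gives_zero_dmin(self):
        rng = np.random.default_rng(0)
        a = rng.random(300)
        freqs = {"A": a, "B": a.copy(), "C": rng.random(300)}
        r = d_min(freqs, ("A", "B", "C"), "O")
        assert abs(r.result.D) == pytest.approx(0.0, abs=1e-12)
        assert {r.arrangement.P1, r.arrangement.P2} == {"A", "B"}
        assert r.arrangement.P3 == "C"

    def test_invariant_under_input_permutation(self):
        rng = np.random.default_rng(11)
        freqs = {k: rng.random(200) for k in "ABC"}
        r1 = d_min(freqs, ("A", "B", "C"), "O")
        r2 = d_min(freqs, ("C", "A", "B"), "O")
        assert r1.arrangement == r2.arrangement
        assert r1.result.D == pytest.approx(r2.result.D)

    def test_chosen_arrangement_matches_exhaustive_search(self):
        rng = np.random.default_rng(11)
        freqs = {k: rng.random(200) for k in "ABC"}
        r = d_min(freqs, ("A", "B", "C"), "O")
        # brute force over the three arrangements
        best = None
        for x, y, z in (("A", "B", "C"), ("A", "C", "B"), ("B", "C", "A")):
            d = d_statistic(pattern_counts(freqs[x], freqs[y], freqs[z]))
            if best is None or abs(d.D) < best[1]:
                best = ((x, y, z), abs(d.D))
        assert abs(r.result.D) == pytest.approx(best[1])


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.037])[0] == pytest.approx(0.037)

    def test_hand_stepup_example(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_ties_stay_equal(self):
        adj = bh_adjust([0.2, 0.2, 0.2])
        assert np.allclose(adj, 0.2)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.random(50)
        ours = bh_adjust(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_adjusted_at_least_raw(self, pvals):
        adj = bh_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)
        assert np.all(adj <= 1.0)


class TestFhom:
    def test_complete_homogenization_gives_one(self):
        rng = np.random.default_rng(2)
        p1, p3 = rng.random(400), rng.random(400)
        assert f_hom(p1, p3.copy(), p3) == pytest.approx(1.0)

    def test_no_asymmetry_gives_zero(self):
        rng = np.random.default_rng(3)
        p1, p3 = rng.random(300), rng.random(300)
        assert f_hom(p1, p1.copy(), p3) == pytest.approx(0.0, abs=1e-12)

    def test_zero_denominator_flagged(self):
        z = np.zeros(10)
        assert np.isnan(f_hom(z, z, z))


class TestFdm:
    def _sim_freqs(self, n=120, seed=9):
        rng = np.random.default_rng(seed)
        return {k: rng.random(n) for k in ("p1", "p2", "p3")}

    def test_no_asymmetry_gives_zero_everywhere(self):
        win = make_windows({"chr1": 100}, 100)
        p1 = np.random.default_rng(1).random(40)
        tr = f_dm_track(p1, p1.copy(), np.full(40, 0.5),
                        np.zeros(40, dtype=int), win, min_snps=1)
        assert tr.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_min_snps_masking(self):
        win = make_windows({"chr1": 100}, 100)
        f = self._sim_freqs(20)
        tr = f_dm_track(f["p1"][:9], f["p2"][:9], f["p3"][:9],
                        np.zeros(9, dtype=int), win, min_snps=10)
        assert np.isnan(tr.values[0])
        tr2 = f_dm_track(f["p1"][:10], f["p2"][:10], f["p3"][:10],
                         np.zeros(10, dtype=int), win, min_snps=10)
        assert not np.isnan(tr2.values[0])

    def test_matches_straight_line_per_site_oracle(self):
        n_win, per = 100, 30
        n = n_win * per
        rng = np.random.default_rng(9)
        p1, p2, p3 = rng.random(n), rng.random(n), rng.random(n)
        wi = np.repeat(np.arange(n_win), per)
        win = make_windows({"chr1": n_win * 100}, 100)
        tr = f_dm_track(p1, p2, p3, wi, win, min_snps=1)
        for w in range(n_win):
            num = den = 0.0
            for i in range(w * per, (w + 1) * per):
                num += (1 - p1[i]) * p2[i] * p3[i] - p1[i] * (1 - p2[i]) * p3[i]
                if p2[i] >= p1[i]:
                    pd_ = max(p2[i], p3[i])
                    den += (1 - p1[i]) * pd_ * pd_ - p1[i] * (1 - pd_) * pd_
                else:
                    pd_ = max(p1[i], p3[i])
                    den -= (1 - pd_) * p2[i] * pd_ - pd_ * (1 - p2[i]) * pd_
            assert tr.values[w] == pytest.approx(num / den, abs=1e-12)

    def test_bounded_on_simulated_data(self, trio_pulse_dataset):
        gm, truth, model, wm = trio_pulse_dataset
        pf = polarize(gm)
        win = truth.table[["window", "chrom", "start", "end"]]
        from introland.gio import assign_windows
        wi = assign_windows(win, pf.chrom, pf.pos)
        tr = f_dm_track(pf.freqs["P1"], pf.freqs["P2"], pf.freqs["P3"],
                        wi, win)
        vals = tr.values[tr.defined]
        assert np.all(vals >= -1.0 - 1e-9) and np.all(vals <= 1.0 + 1e-9)


class TestCallPir:
    def _track(self, values):
        values = np.asarray(values, float)
        win = make_windows({"chr1": len(values) * 100}, 100)
        return FdmTrack(windows=win, values=values,
                        n_snps=np.full(len(values), 50), min_snps=10)

    def test_zero_percent_empty(self):
        assert call_pir(self._track(np.arange(20)), 0.0).sum() == 0

    def test_hundred_percent_all_defined(self):
        v = np.arange(20.0)
        v[3] = np.nan
        assert call_pir(self._track(v), 100.0).sum() == 19

    def test_top_five_of_hundred(self):
        rng = np.random.default_rng(4)
        v = rng.permutation(100).astype(float)
        mask = call_pir(self._track(v), 5.0)
        assert mask.sum() == 5
        assert set(v[mask]) == {95, 96, 97, 98, 99}

    def test_ties_broken_by_genomic_order(self):
        v = np.array([1.0, 5.0, 5.0, 5.0, 0.0])
        mask = call_pir(self._track(v), 40.0)  # ceil(0.4*5) = 2
        assert list(np.nonzero(mask)[0]) == [1, 2]


class TestIntrogressionIndex:
    def test_counting(self):
        win = make_windows({"chr1": 300}, 100)
        ones = np.ones(3, dtype=bool)
        pir = {"t1": np.array([1, 1, 0], bool),
               "t2": np.array([1, 0, 0], bool),
               "t3": np.array([0, 0, 0], bool)}
        defined = {k: ones for k in pir}
        idx = introgression_index(pir, defined, win).index
        assert np.allclose(idx, [2 / 3, 1 / 3, 0.0])

    def test_requires_contributing_trio(self):
        with pytest.raises(ValueError):
            introgression_index({}, {}, make_windows({"chr1": 100}, 100))
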