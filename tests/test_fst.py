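"""Per-SNP FST estimator, window averaging, thresholding and sweep calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import altiscan as al
from altiscan.fst import STATUS_DATA, sweeps_to_frame, window_means


def naive_fst(p1, n1, p2, n2):
    """Scalar transcription of the Hudson estimator, kept independent of the
    vectorized implementation."""
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    if den == 0:
        return np.nan
    return num / den


class TestSnpFst:
    def test_matches_naive_formula_on_random_draws(self):
        rng = np.random.default_rng(42)
        p1 = rng.uniform(0, 1, 1000)
        p2 = rng.uniform(0, 1, 1000)
        n1 = rng.integers(4, 200, 1000)
        n2 = rng.integers(4, 200, 1000)
        got = al.snp_fst(p1, n1, p2, n2, clamp=False)
        want = np.array([naive_fst(*t) for t in zip(p1, n1, p2, n2)])
        # undefined sites agree, defined sites match to near machine precision
        assert np.array_equal(np.isnan(got), np.isnan(want))
        m = ~np.isnan(want)
        assert np.max(np.abs(got[m] - want[m])) < 1e-12

    def test_equal_frequencies_clamp_to_zero(self):
        raw = al.snp_fst([0.5], [20], [0.5], [20], clamp=False)
        assert raw[0] < 0
        assert al.snp_fst([0.5], [20], [0.5], [20])[0] == 0.0

    def test_fixed_difference_is_one(self):
        assert al.snp_fst([1.0], [1000], [0.0], [1000])[0] == pytest.approx(1.0)

    def test_reported_daf_pair(self):
        # derived-allele frequencies 0.79 (52 alleles) vs 0.25 (58 alleles),
        # the most differentiated missense site reported for the target breed
        want = naive_fst(0.79, 52, 0.25, 58)
        got = al.snp_fst([0.79], [52], [0.25], [58])[0]
        assert got == pytest.approx(want, abs=1e-12)
        assert 0.4 < got < 0.5

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(p1=st.floats(0, 1), p2=st.floats(0, 1),
           n1=st.integers(2, 500), n2=st.integers(2, 500))
    def test_range_and_population_symmetry(self, p1, p2, n1, n2):
        a = al.snp_fst([p1], [n1], [p2], [n2])[0]
        b = al.snp_fst([p2], [n2], [p1], [n1])[0]
        if np.isnan(a):
            assert np.isnan(b)
        else:
            assert 0.0 <= a <= 1.0
            assert a == pytest.approx(b, abs=1e-12)

    def test_frequency_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            al.snp_fst([1.2], [10], [0.5], [10])


class TestWindowMeans:
    def test_simple_arithmetic_mean(self):
        wt = window_means(["1"] * 3, [100, 200, 300], [0.1, 0.2, 0.6], w=10_000)
        assert len(wt.df) == 1
        assert wt.df["mean"].iloc[0] == pytest.approx(0.3)
        assert wt.df["n_snps"].iloc[0] == 3

    def test_empty_window_has_no_mean(self):
        wt = window_means(["1"], [25_000], [0.5], w=10_000)
        assert list(wt.df["status"]) == ["empty", "empty", "data"]
        assert wt.df["mean"].isna().tolist() == [True, True, False]

    def test_matches_per_window_loop_oracle(self):
        rng = np.random.default_rng(7)
        pos = np.sort(rng.choice(np.arange(1, 500_001), 1000, replace=False))
        val = rng.uniform(0, 1, 1000)
        wt = window_means(["1"] * 1000, pos, val, w=10_000,
                          chrom_sizes={"1": 500_000})
        for row in wt.df.itertuples(index=False):
            inside = (pos - 1 >= row.start) & (pos - 1 < row.end)
            if row.status == STATUS_DATA:
                assert row.mean == pytest.approx(val[inside].mean())
                assert row.n_snps == inside.sum()
            else:
                assert inside.sum() == 0

    def test_gap_intervals_mark_windows(self):
        wt = window_means(["1"] * 2, [5_000, 25_000], [0.1, 0.2], w=10_000,
                          chrom_sizes={"1": 30_000},
                          gap_intervals={"1": ([12_000], [14_000])})
        assert list(wt.df["status"]) == ["data", "gap", "data"]


class TestTopQuantileThreshold:
    def test_hundred_windows_one_outlier(self):
        wt = window_means(["1"] * 100, np.arange(100) * 10_000 + 5_000,
                          np.arange(1.0, 101.0), w=10_000)
        thr = al.top_quantile_threshold(wt, 0.99)
        assert thr == pytest.approx(99.01)
        assert int((wt.data_means() > thr).sum()) == 1

    def test_constant_track_has_no_outliers(self):
        wt = window_means(["1"] * 100, np.arange(100) * 10_000 + 5_000,
                          np.full(100, 0.3), w=10_000)
        thr = al.top_quantile_threshold(wt, 0.99)
        assert int((wt.data_means() > thr).sum()) == 0

    def test_zero_quantile_marks_everything(self):
        vals = np.arange(1.0, 101.0)
        wt = window_means(["1"] * 100, np.arange(100) * 10_000 + 5_000,
                          vals, w=10_000)
        thr = al.top_quantile_threshold(wt, 0.0)
        assert int((wt.data_means() > thr).sum()) == 99  # all but the minimum

    def test_warns_when_few_windows(self):
        wt = window_means(["1"] * 3, [100, 10_100, 20_100], [0.1, 0.2, 0.3],
                          w=10_000)
        with pytest.warns(UserWarning, match="data windows"):
            al.top_quantile_threshold(wt, 0.99)


def track_from_codes(codes, w=10_000):
    """Build a WindowTrack from symbols: float = data window with that mean,
    'G' = gap, 'E' = empty."""
    rows = []
    for i, c in enumerate(codes):
        if c == "G":
            rows.append(("1", i * w, (i + 1) * w, np.nan, 0, "gap"))
        elif c == "E":
            rows.append(("1", i * w, (i + 1) * w, np.nan, 0, "empty"))
        else:
            rows.append(("1", i * w, (i + 1) * w, float(c), 1, "data"))
    return al.WindowTrack(df=pd.DataFrame(
        rows, columns=["chrom", "start", "end", "mean", "n_snps", "status"]),
        width=w)


def brute_force_sweeps(codes, threshold, min_run, w=10_000):
    """Enumerate qualifying runs directly from the symbol sequence."""
    runs = []
    cur = []
    for i, c in enumerate(codes):
        if c in ("G", "E"):
            continue
        if float(c) > threshold:
            cur.append(i)
        else:
            if len(cur) >= min_run:
                runs.append((cur[0] * w, (cur[-1] + 1) * w, len(cur)))
            cur = []
    if len(cur) >= min_run:
        runs.append((cur[0] * w, (cur[-1] + 1) * w, len(cur)))
    return runs


class TestCallSweeps:
    def test_three_consecutive_outliers_form_one_sweep(self):
        tr = track_from_codes([1, 1, 1])
        sw = al.call_sweeps(tr, 0.5, min_run=3)
        assert len(sw) == 1
        assert (sw[0].start, sw[0].end, sw[0].n_windows) == (0, 30_000, 3)
        assert sw[0].start1 == 1 and sw[0].end1 == 30_000

    def test_below_threshold_window_breaks_run(self):
        tr = track_from_codes([1, 1, 0, 1])
        assert al.call_sweeps(tr, 0.5, min_run=3) == []

    def test_gap_window_bridges_but_does_not_count(self):
        tr = track_from_codes([1, 1, "G", 1])
        sw = al.call_sweeps(tr, 0.5, min_run=3)
        assert len(sw) == 1
        assert (sw[0].start, sw[0].end) == (0, 40_000)  # spans 4 windows
        assert sw[0].n_windows == 3                      # 3 outlier members

    def test_bridging_can_be_disabled(self):
        tr = track_from_codes([1, 1, "G", 1])
        assert al.call_sweeps(tr, 0.5, min_run=3, bridge_gaps=False) == []

    def test_matches_brute_force_enumeration_on_random_tracks(self):
        rng = np.random.default_rng(11)
        n_total = 0
        while n_total < 10_000:
            n = int(rng.integers(20, 120))
            n_total += n
            codes = []
            for _ in range(n):
                r = rng.random()
                if r < 0.1:
                    codes.append("G")
                elif r < 0.2:
                    codes.append("E")
                else:
                    # mostly high values so runs actually occur
                    codes.append(round(float(rng.random() < 0.45), 0))
            tr = track_from_codes(codes)
            got = [(s.start, s.end, s.n_windows)
                   for s in al.call_sweeps(tr, 0.5, min_run=3)]
            assert got == brute_force_sweeps(codes, 0.5, 3)


class TestGenesInSweeps:
    def make_sweep(self, start, end):
        return al.SweepInterval(chrom="1", start=start, end=end, n_windows=3,
                                peak=1.0, mean=1.0)

    def test_contained_and_touching_genes(self):
        genes = pd.DataFrame({
            "chrom": ["1", "1"], "start": [12_000, 30_000],
            "end": [18_000, 35_000], "name": ["inside", "touching_end"]})
        hits = al.genes_in_sweeps([self.make_sweep(10_000, 30_000)], genes)
        assert hits[("1", 10_000, 30_000)] == ["inside"]

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(3)
        genes = pd.DataFrame({
            "chrom": "1",
            "start": (s := np.sort(rng.integers(0, 900_000, 50))),
            "end": s + rng.integers(1_000, 50_000, 50),
            "name": [f"g{i}" for i in range(50)]})
        sweeps = [self.make_sweep(int(a), int(a + ln)) for a, ln in
                  zip(rng.integers(0, 900_000, 5),
                      rng.integers(10_000, 100_000, 5))]
        got = al.genes_in_sweeps(sweeps, genes)
        for sw in sweeps:
            want = [r["name"] for _i, r in genes.iterrows()
                    if r["start"] < sw.end and r["end"] > sw.start]
            assert got[("1", sw.start, sw.end)] == want

    def test_sweep_frame_coordinates(self):
        df = sweeps_to_frame([self.make_sweep(100_170_000, 100_240_000)])
        assert df["start1"].iloc[0] == 100_170_001
        assert df["end1"].iloc[0] == 100_240_000
        assert df["length_bp"].iloc[0] == 70_000
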