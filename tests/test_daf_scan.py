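"""dAF computation, windowed scan, interval delimitation — with brute-force
oracles and monotonicity/masking invariance properties."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beetmbs.daf_scan import (
    detect_intervals,
    per_variant_daf,
    pool_allele_frequency,
    scan_report,
    window_scan,
)
from beetmbs.variants import MISSING, VariantTable


def daf_frame(dafs, chrom="chr1", start=1000, spacing=100):
    dafs = list(dafs)
    pos = start + spacing * np.arange(len(dafs))
    arr = np.array(dafs, dtype=float)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "af_tol": np.where(np.isnan(arr), np.nan, 0.5 + arr / 2),
            "af_sus": np.where(np.isnan(arr), np.nan, 0.5 - arr / 2),
            "daf": arr,
            "depth_tol": 100,
            "depth_sus": 100,
        }
    )


# -- independent brute-force oracles ---------------------------------------

def brute_windows(dafs, window_size):
    """Group unmasked dafs into tumbling windows by explicit slicing."""
    clean = [d for d in dafs if not math.isnan(d)]
    out = []
    for i in range(0, len(clean), window_size):
        chunk = clean[i : i + window_size]
        out.append((len(chunk), sum(chunk) / len(chunk), len(chunk) == window_size))
    return out


def brute_runs(means, threshold, run_min):
    """Enumerate maximal runs of mean > threshold by linear scan."""
    runs, start = [], None
    for i, m in enumerate(list(means) + [-math.inf]):
        if m > threshold and start is None:
            start = i
        elif m <= threshold and start is not None:
            if i - start >= run_min:
                runs.append((start, i - 1))
            start = None
    return runs


class TestPoolAlleleFrequency:
    @pytest.mark.parametrize(
        "ad,tol_is_alt,expected",
        [((0, 20), True, 1.0), ((10, 10), True, 0.5), ((0, 20), False, 0.0)],
    )
    def test_direct(self, ad, tol_is_alt, expected):
        assert pool_allele_frequency(ad, tol_is_alt, min_depth=10) == expected

    def test_masked_below_min_depth(self):
        assert math.isnan(pool_allele_frequency((3, 2), True, min_depth=10))


class TestPerVariantDaf:
    def _table(self, ads_tol, ads_sus, tol_is_alt):
        n = len(ads_tol)
        ad = np.zeros((n, 2, 2), dtype=np.int32)
        ad[:, 0] = ads_sus
        ad[:, 1] = ads_tol
        return VariantTable(
            chrom=np.array(["chr1"] * n, dtype=object),
            pos=np.arange(1, n + 1) * 100,
            ref=np.array(["A"] * n, dtype=object),
            alt=np.array(["G"] * n, dtype=object),
            qual=np.full(n, 100.0),
            samples=["pool_sus", "pool_tol"],
            gt=np.full((n, 2), MISSING, dtype=np.int8),
            ad=ad,
            tol_is_alt=np.array(tol_is_alt),
        )

    def test_ideal_and_signed_values(self):
        table = self._table(
            ads_tol=[(0, 30), (15, 15), (24, 6)],
            ads_sus=[(30, 0), (15, 15), (3, 27)],
            tol_is_alt=[True, True, True],
        )
        out = per_variant_daf(table, ["pool_tol"], ["pool_sus"], min_depth=10)
        assert out["daf"].tolist() == pytest.approx([1.0, 0.0, 0.2 - 0.9])

    def test_orientation_flips_frequency(self):
        table = self._table(ads_tol=[(30, 0)], ads_sus=[(0, 30)], tol_is_alt=[False])
        out = per_variant_daf(table, ["pool_tol"], ["pool_sus"], min_depth=10)
        assert out["daf"].iloc[0] == pytest.approx(1.0)

    def test_multi_library_classes_merge_ad(self):
        """Two shallow tolerant libraries merge to one covered class."""
        n = 1
        ad = np.zeros((n, 3, 2), dtype=np.int32)
        ad[0, 0] = (12, 0)  # pool_sus
        ad[0, 1] = (0, 6)  # tol library 1 — below min_depth alone
        ad[0, 2] = (1, 5)  # tol library 2
        table = VariantTable(
            chrom=np.array(["chr1"], dtype=object),
            pos=np.array([100]),
            ref=np.array(["A"], dtype=object),
            alt=np.array(["G"], dtype=object),
            qual=np.array([99.0]),
            samples=["pool_sus", "tol_a", "tol_b"],
            gt=np.full((1, 3), MISSING, dtype=np.int8),
            ad=ad,
            tol_is_alt=np.array([True]),
        )
        out = per_variant_daf(table, ["tol_a", "tol_b"], ["pool_sus"], min_depth=10)
        assert out["af_tol"].iloc[0] == pytest.approx(11 / 12)
        assert out["depth_tol"].iloc[0] == 12

    def test_requires_orientation(self):
        table = self._table([(1, 1)], [(1, 1)], [True])
        table.tol_is_alt = None
        with pytest.raises(ValueError):
            per_variant_daf(table, ["pool_tol"], ["pool_sus"])


class TestWindowScan:
    def test_single_full_window_of_ones(self):
        w = window_scan(daf_frame([1.0] * 10), window_size=10)
        assert len(w) == 1
        assert w.iloc[0]["mean_daf"] == 1.0 and bool(w.iloc[0]["complete"])

    def test_trailing_partial_window(self):
        w = window_scan(daf_frame([0.2] * 25), window_size=10)
        assert list(w["n_variants"]) == [10, 10, 5]
        assert list(w["complete"]) == [True, True, False]

    def test_mixed_window_mean(self):
        w = window_scan(daf_frame([1.0] * 5 + [0.0] * 5), window_size=10)
        assert w.iloc[0]["mean_daf"] == pytest.approx(0.5)

    def test_windows_never_span_chromosomes(self):
        df = pd.concat(
            [daf_frame([0.3] * 7, chrom="chr1"), daf_frame([0.4] * 7, chrom="chr2")],
            ignore_index=True,
        )
        w = window_scan(df, window_size=10)
        assert list(w["chrom"]) == ["chr1", "chr2"]
        assert list(w["complete"]) == [False, False]

    def test_masked_variants_do_not_occupy_slots(self):
        dafs = [0.9, np.nan, 0.9, np.nan] * 5  # 10 unmasked in 20 records
        w = window_scan(daf_frame(dafs), window_size=10)
        assert len(w) == 1 and w.iloc[0]["n_variants"] == 10
        assert w.iloc[0]["mean_daf"] == pytest.approx(0.9)

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(
            st.one_of(st.floats(-1, 1), st.just(math.nan)), min_size=1, max_size=80
        ),
        st.integers(2, 12),
    )
    def test_matches_brute_force_grouping(self, dafs, window_size):
        w = window_scan(daf_frame(dafs), window_size=window_size)
        expected = brute_windows(dafs, window_size)
        assert len(w) == len(expected)
        for (_, row), (n, mean, complete) in zip(w.iterrows(), expected):
            assert row["n_variants"] == n
            assert row["mean_daf"] == pytest.approx(mean, abs=1e-12)
            assert bool(row["complete"]) == complete
        # |window mean| never exceeds the largest member |daf|
        clean = [abs(d) for d in dafs if not math.isnan(d)]
        if clean:
            assert np.all(np.abs(w["mean_daf"]) <= max(clean) + 1e-12)


def windows_frame(means, chrom="chr1", complete=None):
    n = len(means)
    complete = [True] * n if complete is None else complete
    return pd.DataFrame(
        {
            "chrom": chrom,
            "index": np.arange(n),
            "start_pos": 1000 + 1000 * np.arange(n),
            "end_pos": 1900 + 1000 * np.arange(n),
            "n_variants": 10,
            "mean_daf": means,
            "complete": complete,
        }
    )


class TestDetectIntervals:
    def test_fifty_snp_delimitation(self):
        means = [0.1] * 2 + [0.6] * 5 + [0.1] * 2
        iv = detect_intervals(windows_frame(means), threshold=0.5, run_min=5)
        assert len(iv) == 1
        row = iv.iloc[0]
        assert row["n_snps"] == 50 and row["n_windows"] == 5
        assert (row["first_window"], row["last_window"]) == (2, 6)

    def test_run_below_min_yields_nothing(self):
        iv = detect_intervals(windows_frame([0.9] * 4 + [0.1]), run_min=5)
        assert iv.empty

    def test_two_runs_split_by_one_low_window(self):
        means = [0.8] * 5 + [0.2] + [0.8] * 5
        iv = detect_intervals(windows_frame(means), threshold=0.5, run_min=5)
        assert len(iv) == 2

    def test_incomplete_windows_excluded(self):
        means = [0.9] * 5
        iv = detect_intervals(
            windows_frame(means, complete=[True] * 4 + [False]), run_min=5
        )
        assert iv.empty

    def test_strictly_greater_than_threshold(self):
        iv = detect_intervals(windows_frame([0.5] * 6), threshold=0.5, run_min=5)
        assert iv.empty

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(st.floats(-1, 1), min_size=1, max_size=60),
        st.floats(0.0, 0.9),
        st.integers(1, 6),
    )
    def test_matches_brute_force_run_enumeration(self, means, threshold, run_min):
        iv = detect_intervals(windows_frame(means), threshold, run_min)
        expected = brute_runs(means, threshold, run_min)
        assert [
            (int(r["first_window"]), int(r["last_window"])) for _, r in iv.iterrows()
        ] == expected

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-1, 1), min_size=5, max_size=60))
    def test_monotone_in_threshold_and_run_min(self, means):
        base = detect_intervals(windows_frame(means), threshold=0.3, run_min=3)

        def total_span(iv):
            return int((iv["last_window"] - iv["first_window"] + 1).sum())

        higher = detect_intervals(windows_frame(means), threshold=0.5, run_min=3)
        longer = detect_intervals(windows_frame(means), threshold=0.3, run_min=5)
        assert len(higher) <= len(base) or total_span(higher) <= total_span(base)
        assert total_span(higher) <= total_span(base)
        assert len(longer) <= len(base) and total_span(longer) <= total_span(base)


class TestScanReport:
    def test_summary_mean_over_constructed_windows(self):
        w = windows_frame([0.1, 0.2, 0.3])
        rep = scan_report(w, detect_intervals(w))
        assert rep["global_mean_daf"] == pytest.approx(0.2)
        assert rep["n_intervals"] == 0

    def test_track_has_midpoints(self):
        w = windows_frame([0.1, 0.9])
        rep = scan_report(w, detect_intervals(w))
        assert list(rep["track"]["midpoint"]) == [1450, 2450]
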