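"""Fine/coarse binning, scan-range merging, noise removal, matrix assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fiebin.binning import (
    FINE_SCALE,
    SUPPORTED_WIDTHS,
    FineBin,
    InfusionWindow,
    assign_accurate_mz,
    average_over_window,
    bin_name,
    build_intensity_matrix,
    coarse_bin,
    coarse_key,
    fine_bin_scan,
    fine_key,
    merge_scan_ranges,
    remove_single_scan_events,
    width_decimals,
)
from fiebin.io import ScanEvent, ScanFilter


def scan(mzs, intensities, polarity="positive", scan_range=(50.0, 1500.0)):
    return ScanEvent("s", 1, polarity, scan_range, np.array(mzs), np.array(intensities))


def brute_force_coarse_key(k5: int, width: float) -> int:
    """Independent grid assignment: nearest center by |m/z - center|,
    half-way ties resolved away from zero (to the larger center)."""
    div = 10 ** (5 - width_decimals(width))
    candidates = [k5 // div - 1, k5 // div, k5 // div + 1]
    # distance in fine units; tie -> larger center
    return min(candidates, key=lambda g: (abs(k5 - g * div), -g))


class TestFineBinning:
    def test_rounding_and_sum_aggregation(self):
        bins = fine_bin_scan(scan([133.014158, 133.014162], [600.0, 400.0]))
        assert len(bins) == 1
        assert bins[0].key == 13301416
        assert bins[0].mz == pytest.approx(133.01416)
        assert bins[0].intensity == pytest.approx(1000.0)

    def test_on_grid_peaks_unchanged(self):
        bins = fine_bin_scan(scan([100.00001, 100.00002], [1.0, 2.0]))
        assert [(b.mz, b.intensity) for b in bins] == [
            (100.00001, 1.0),
            (100.00002, 2.0),
        ]

    def test_empty_scan(self):
        assert fine_bin_scan(scan([], [])) == []

    def test_half_case_rounds_away_from_zero(self):
        assert fine_key(133.015005) == 13301501
        assert fine_key(0.000005) == 1


class TestMergeScanRanges:
    low = ScanFilter("positive", (55.0, 280.0))
    high = ScanFilter("positive", (270.0, 1200.0))

    def test_shared_mz_averaged(self):
        merged = merge_scan_ranges(
            {
                self.low: [FineBin(27500000, 100.0)],
                self.high: [FineBin(27500000, 200.0)],
            }
        )
        assert merged == [FineBin(27500000, 150.0)]

    def test_single_occurrence_unchanged(self):
        merged = merge_scan_ranges(
            {self.low: [FineBin(12000000, 42.0)], self.high: []}
        )
        assert merged == [FineBin(12000000, 42.0)]

    def test_disjoint_spectra_concatenate_sorted(self):
        merged = merge_scan_ranges(
            {
                self.high: [FineBin(30000000, 5.0)],
                self.low: [FineBin(10000000, 1.0)],
            }
        )
        assert [b.key for b in merged] == [10000000, 30000000]

    def test_mixed_polarity_rejected(self):
        with pytest.raises(ValueError, match="ionisation modes"):
            merge_scan_ranges(
                {
                    self.low: [FineBin(10000000, 1.0)],
                    ScanFilter("negative", (55.0, 280.0)): [FineBin(10000000, 1.0)],
                }
            )


class TestCoarseBinning:
    def test_example_assignment(self):
        bins = coarse_bin([FineBin(13301416, 1000.0)], 0.01)
        assert len(bins) == 1
        assert bins[0].key == 13301
        assert bins[0].center == pytest.approx(133.01)
        assert bins[0].intensity == pytest.approx(1000.0)

    def test_half_case_goes_up(self):
        (b,) = coarse_bin([FineBin(13301500, 10.0)], 0.01)
        assert b.center == pytest.approx(133.02)

    def test_empty(self):
        assert coarse_bin([], 0.01) == []

    def test_unsupported_width(self):
        with pytest.raises(ValueError, match="unsupported bin width"):
            coarse_bin([FineBin(1, 1.0)], 0.005)

    @given(
        mzs=st.lists(st.floats(50, 1200), min_size=1, max_size=200),
        width=st.sampled_from(sorted(SUPPORTED_WIDTHS)),
    )
    @settings(derandomize=True, max_examples=300)
    def test_grid_matches_brute_force_and_conserves_tic(self, mzs, width):
        intensities = [1.0 + (i % 7) for i in range(len(mzs))]
        s = scan(mzs, intensities)
        fine = fine_bin_scan(s)
        coarse = coarse_bin(fine, width)
        # oracle: membership grouping by nearest center, ties away from zero
        for cb in coarse:
            for member in cb.members:
                assert brute_force_coarse_key(member.key, width) == cb.key
        # nesting: each fine bin in exactly one coarse bin
        assert sorted(m.key for cb in coarse for m in cb.members) == [
            b.key for b in fine
        ]
        # conservation: coarse total == fine total == scan TIC
        tic = float(np.sum(intensities))
        assert sum(cb.intensity for cb in coarse) == pytest.approx(tic, rel=1e-9)
        assert sum(b.intensity for b in fine) == pytest.approx(tic, rel=1e-9)

    @given(mz=st.floats(0.1, 1500), width=st.sampled_from(sorted(SUPPORTED_WIDTHS)))
    @settings(derandomize=True, max_examples=300)
    def test_fine_bin_center_within_half_width(self, mz, width):
        k5 = fine_key(mz)
        center = coarse_key(k5, width) * 10 ** (5 - width_decimals(width))
        # fine m/z sits within half a width of its coarse center (grid units)
        assert abs(k5 - center) <= 10 ** (5 - width_decimals(width)) / 2


def occ_frame(rows):
    return pd.DataFrame(
        rows, columns=["sample", "polarity", "cycle", "fine_key", "intensity", "coarse_key"]
    )


class TestSingleScanRemoval:
    def test_lone_occurrence_removed(self):
        occ = occ_frame([("s1", "positive", 3, 10000000, 5.0, 10000)])
        assert remove_single_scan_events(occ).empty

    def test_same_fine_mz_in_two_scans_kept(self):
        occ = occ_frame(
            [
                ("s1", "positive", 3, 10000000, 5.0, 10000),
                ("s1", "positive", 4, 10000000, 6.0, 10000),
            ]
        )
        assert len(remove_single_scan_events(occ)) == 2

    def test_two_distinct_fine_mz_single_scans_kept(self):
        occ = occ_frame(
            [
                ("s1", "positive", 3, 10000001, 5.0, 10000),
                ("s2", "positive", 5, 10000002, 6.0, 10000),
            ]
        )
        assert len(remove_single_scan_events(occ)) == 2

    def test_same_grid_index_different_polarity_not_pooled(self):
        occ = occ_frame(
            [
                ("s1", "positive", 3, 10000000, 5.0, 10000),
                ("s1", "negative", 3, 10000000, 5.0, 10000),
            ]
        )
        assert remove_single_scan_events(occ).empty

    @given(
        n_scans=st.integers(2, 6),
        data=st.data(),
    )
    @settings(derandomize=True, max_examples=100)
    def test_never_removes_multiply_occupied_bins(self, n_scans, data):
        rows = []
        keys = data.draw(
            st.lists(st.integers(100, 110), min_size=1, max_size=8)
        )
        for i, k in enumerate(keys):
            for cyc in range(1, data.draw(st.integers(1, n_scans)) + 1):
                rows.append(("s1", "positive", cyc, k * 1000 + i, 1.0, k))
        occ = occ_frame(rows)
        filtered = remove_single_scan_events(occ)
        counts = occ.groupby("coarse_key").size()
        for k, n in counts.items():
            if n >= 2:
                assert (filtered["coarse_key"] == k).any()


class TestWindowAveraging:
    def test_present_in_all_window_scans(self):
        occ = occ_frame(
            [("s1", "positive", c, 10000000, 7.0, 10000) for c in range(1, 11)]
        )
        out = average_over_window(occ, InfusionWindow(1, 10))
        assert out["intensity"].tolist() == [pytest.approx(7.0)]

    def test_absent_scans_count_as_zero(self):
        occ = occ_frame(
            [("s1", "positive", c, 10000000, 10.0, 10000) for c in range(1, 6)]
        )
        out = average_over_window(occ, InfusionWindow(1, 10))
        assert out["intensity"].tolist() == [pytest.approx(5.0)]

    def test_empty_occurrences(self):
        out = average_over_window(occ_frame([]), InfusionWindow(1, 5))
        assert out.empty


class TestAccurateMz:
    def test_mode_by_occurrence_count(self):
        occs = [FineBin(13301416, 10.0)] * 8 + [FineBin(13301417, 1000.0)] * 2
        assert assign_accurate_mz(occs) == pytest.approx(133.01416)

    def test_count_tie_broken_by_abundance(self):
        occs = [FineBin(13301416, 20.0)] * 5 + [FineBin(13301418, 10.0)] * 5
        assert assign_accurate_mz(occs) == pytest.approx(133.01416)

    def test_full_tie_broken_by_lower_mz(self):
        occs = [FineBin(13301418, 10.0), FineBin(13301416, 10.0)]
        assert assign_accurate_mz(occs) == pytest.approx(133.01416)

    def test_single_occurrence_identity(self):
        assert assign_accurate_mz([FineBin(21200220, 3.0)]) == pytest.approx(212.00220)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            assign_accurate_mz([])


class TestMatrixAssembly:
    def bin_table(self, names):
        return pd.DataFrame(
            {"polarity": "positive", "center": 100.0}, index=pd.Index(names, name="bin")
        )

    def test_absent_cell_is_zero(self):
        averaged = pd.DataFrame(
            {
                "sample": ["s1", "s1", "s1", "s2", "s2"],
                "polarity": "positive",
                "coarse_key": [10001, 10002, 10003, 10001, 10003],
                "intensity": [1.0, 2.0, 3.0, 4.0, 5.0],
            }
        )
        names = [bin_name("positive", k, 0.01) for k in (10001, 10002, 10003)]
        m = build_intensity_matrix(averaged, self.bin_table(names), ["s1", "s2"], 0.01)
        assert m.intensities.shape == (2, 3)
        assert m.intensities.loc["s2", names[1]] == 0.0
        assert m.intensities.loc["s2", names[0]] == 4.0

    def test_single_cell(self):
        averaged = pd.DataFrame(
            {"sample": ["s1"], "polarity": ["positive"], "coarse_key": [10001],
             "intensity": [2.5]}
        )
        names = [bin_name("positive", 10001, 0.01)]
        m = build_intensity_matrix(averaged, self.bin_table(names), ["s1"], 0.01)
        assert m.intensities.shape == (1, 1)
        assert m.intensities.iloc[0, 0] == 2.5

    def test_duplicate_samples_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_intensity_matrix(
                pd.DataFrame(columns=["sample", "polarity", "coarse_key", "intensity"]),
                self.bin_table([]),
                ["s1", "s1"],
                0.01,
            )


@pytest.mark.parametrize(
    "polarity, key, width, expected",
    [
        ("negative", 13301, 0.01, "n133.01"),
        ("positive", 13301, 0.01, "p133.01"),
        ("negative", 133, 1.0, "n133"),
        ("positive", 1331, 0.1, "p133.1"),
        ("negative", 13301416, 0.0001, "n1330.1416"),
        ("positive", 100, 0.01, "p1.00"),
    ],
)
def test_bin_names_render_at_grid_precision(polarity, key, width, expected):
    assert bin_name(polarity, key, width) == expected
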