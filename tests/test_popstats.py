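"""Population statistics: demographs, maps, regressions, classification."""

import numpy as np
import pandas as pd
import pytest

from icmscope import (
    BChlMeasurement,
    bchl_content,
    build_demograph,
    centroid_map,
    classify_localization,
    foci_count_length_table,
    intensity_content_correlation,
    old_new_intensity_compare,
    pole_distance_stats,
    spacing_pairs,
    spacing_regression,
    tukey_outliers,
)
from icmscope.errors import InsufficientDataError, PairingError
from icmscope.popstats import ClassificationConfig, SpacingPair
from icmscope.quantify import FocusRecord, MedialProfile


def make_profile(cell_id, L, I_fn, step=0.065):
    s = np.arange(0, L, step)
    axis = np.stack([s / step, np.full_like(s, 5.0)], axis=1)
    return MedialProfile(cell_id=cell_id, s=s, I=I_fn(s), sampling_step=step,
                         axis_xy=axis)


class TestDemograph:
    def test_rows_sorted_by_length(self):
        profs = [make_profile(i, L, lambda s: np.ones_like(s))
                 for i, L in enumerate([2.0, 3.0, 2.5])]
        dg = build_demograph(profs)
        assert list(dg.lengths) == sorted(dg.lengths)
        assert dg.row_order == [0, 2, 1]
        assert np.all(np.diff(dg.lengths) >= 0)

    def test_row_support_matches_cell_length(self):
        profs = [make_profile(i, L, lambda s: np.ones_like(s))
                 for i, L in enumerate([2.0, 3.0])]
        dg = build_demograph(profs)
        for row, L in enumerate(dg.lengths):
            n_valid = np.sum(~np.isnan(dg.matrix[row]))
            assert n_valid == pytest.approx(L / dg.bin_step, abs=1.5)

    def test_max1_normalization(self):
        profs = [make_profile(i, 2.5, lambda s: 50 * np.exp(-(s - 1) ** 2))
                 for i in range(3)]
        dg = build_demograph(profs, per_cell_norm="max1")
        for row in dg.matrix:
            assert np.nanmax(row) == pytest.approx(1.0)

    def test_restricted_population_is_pole_enriched(
            self, small_restricted_analysis):
        """Old-pole-aligned demograph: mean intensity in the first 1 µm is at
        least twice that of the middle third."""
        dg = build_demograph(small_restricted_analysis.profiles)
        n = dg.matrix.shape[1]
        first = np.nanmean(dg.matrix[:, : int(1.0 / dg.bin_step)])
        middle = np.nanmean(dg.matrix[:, n // 3 : 2 * n // 3])
        assert first >= 2 * middle

    def test_empty_input(self):
        dg = build_demograph([])
        assert dg.matrix.size == 0


class TestCentroidMap:
    def test_on_axis_midcell_focus_maps_to_center(self,
                                                  small_restricted_analysis):
        cell = small_restricted_analysis.cells[0]
        f = FocusRecord(cell_id=cell.id, centroid_xy=(0, 0),
                        s_pos=cell.length_um / 2, mean_intensity=10.0,
                        prominence=5.0, window=0.6, t_offset_px=0.0)
        pts, _ = centroid_map([cell], [f])
        assert pts.iloc[0].x_norm == pytest.approx(0.5)
        assert pts.iloc[0].y_norm == pytest.approx(0.0)

    def test_restricted_mean_position_matches_model(self, small_restricted_scene,
                                                    small_restricted_analysis):
        res = small_restricted_analysis
        by_cell = {}
        for f in res.foci:
            by_cell.setdefault(f.cell_id, []).append(f)
        assigned = {c.cell_id for c in res.calls if c.old_pole != "unassigned"}
        singles = [fl[0] for cid, fl in by_cell.items()
                   if len(fl) == 1 and cid in assigned]
        pts, outline = centroid_map(res.cells, singles, res.profiles)
        lengths = [c.length_um for c in res.cells]
        expected = 0.6 / np.mean(lengths)
        assert pts["x_norm"].mean() == pytest.approx(expected, abs=0.05)
        assert len(outline) and np.all(outline[:, 1] >= 0)


class TestLengthTable:
    def test_single_extreme_value_is_the_only_outlier(self):
        vals = [1, 2, 3, 4, 100]
        idx = tukey_outliers(vals)
        assert list(idx) == [4]

    def test_equal_values_have_no_outliers(self):
        assert len(tukey_outliers([2.0] * 10)) == 0

    def test_two_focus_cells_are_longer(self, small_restricted_analysis):
        res = small_restricted_analysis
        summary, per_cell = foci_count_length_table(res.cells, res.foci)
        med = summary.set_index("focus_class")["median_um"]
        assert med["2"] > med["1"]
        assert summary["n"].sum() == len(res.cells)


class TestSpacingRegression:
    def test_exact_linear_pairs(self):
        pairs = [SpacingPair(i, L - 1.1, L) for i, L in enumerate([2.5, 3.0, 3.5])]
        reg = spacing_regression(pairs)
        assert reg.slope == pytest.approx(1.0)
        assert reg.intercept == pytest.approx(-1.1)
        assert reg.r == pytest.approx(1.0)

    def test_constant_spacing_flagged(self):
        pairs = [SpacingPair(i, 0.9, L) for i, L in enumerate([2.5, 3.0, 3.5])]
        reg = spacing_regression(pairs)
        assert reg.slope == 0.0
        assert reg.r == 0.0
        assert reg.zero_variance

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            spacing_regression([SpacingPair(1, 1.0, 2.0)])


class TestPoleDistances:
    def test_two_focus_cell_distances(self, small_restricted_analysis):
        cells = small_restricted_analysis.cells[:1]
        L = cells[0].length_um
        foci = [
            FocusRecord(cells[0].id, (0, 0), 0.6, 10, 5, 0.6),
            FocusRecord(cells[0].id, (0, 0), L - 0.5, 10, 5, 0.6),
        ]
        st = pole_distance_stats(foci, cells)
        assert st["old"]["median"] == pytest.approx(0.6)
        assert st["new"]["median"] == pytest.approx(0.5)

    def test_restricted_population_conserves_old_distance(
            self, small_restricted_analysis):
        res = small_restricted_analysis
        st = pole_distance_stats(res.foci, res.cells, res.calls)
        assert st["old"]["median"] == pytest.approx(0.6, rel=0.10)
        assert st["old"]["cv"] <= 0.25


class TestOldNewIntensity:
    def _two_focus_fixture(self, cells, ratio):
        foci = []
        for c in cells:
            if c.length_um < 2.6:
                continue
            foci += [
                FocusRecord(c.id, (0, 0), 0.6, 100.0, 5, 0.6),
                FocusRecord(c.id, (0, 0), c.length_um - 0.5, 100.0 * ratio, 5, 0.6),
            ]
        return foci

    def test_identical_intensities_give_unit_ratio(self,
                                                   small_restricted_analysis):
        cells = small_restricted_analysis.cells
        cmp_ = old_new_intensity_compare(cells, self._two_focus_fixture(cells, 1.0))
        assert cmp_["median_ratio"] == pytest.approx(1.0)

    def test_orientation_swap_inverts_ratio(self, small_restricted_analysis):
        cells = small_restricted_analysis.cells
        foci = self._two_focus_fixture(cells, 0.6)
        fwd = old_new_intensity_compare(cells, foci)
        lengths = {c.id: c.length_um for c in cells}
        swapped = [
            FocusRecord(f.cell_id, f.centroid_xy, lengths[f.cell_id] - f.s_pos,
                        f.mean_intensity, f.prominence, f.window)
            for f in foci
        ]
        rev = old_new_intensity_compare(cells, swapped)
        assert rev["median_ratio"] == pytest.approx(1.0 / fwd["median_ratio"],
                                                    rel=1e-9)

    def test_measured_ratio_matches_model(self, small_restricted_analysis):
        res = small_restricted_analysis
        cmp_ = old_new_intensity_compare(res.cells, res.foci, res.calls)
        assert 0.5 <= cmp_["median_ratio"] <= 0.7


class TestContentCorrelation:
    def test_content_formula(self):
        assert bchl_content(0.5, 1.0) == 0.5
        m = BChlMeasurement("c1", A770=0.4, OD660=0.8)
        assert m.content == pytest.approx(0.5)

    def test_proportional_pairs_give_unit_r(self):
        meas = [BChlMeasurement(f"c{i}", 0.1 * i, 1.0) for i in range(1, 6)]
        intensities = {f"c{i}": 30.0 * i for i in range(1, 6)}
        r, table = intensity_content_correlation(meas, intensities)
        assert r == pytest.approx(1.0)
        assert len(table) == 5

    def test_mismatched_keys_listed(self):
        meas = [BChlMeasurement(f"c{i}", 0.1, 1.0) for i in range(4)]
        with pytest.raises(PairingError, match="c3"):
            intensity_content_correlation(meas, {"c0": 1, "c1": 2, "c2": 3,
                                                 "x9": 4})


class TestClassification:
    def test_boxcar_profile_is_nonfocal(self):
        profs = [make_profile(i, 3.0, lambda s: np.ones_like(s) * 40)
                 for i in range(30)]
        res = classify_localization(profs)
        assert res.label == "nonrestricted"
        assert res.focal_fraction == 0.0

    def test_single_gaussian_occupancy_matches_fwhm(self):
        """sd 0.25 µm in a 3 µm cell: occupancy ≈ 2.355·0.25/3 ≈ 0.20."""
        profs = [make_profile(i, 3.0,
                              lambda s: 100 * np.exp(-((s - 1.5) ** 2) / (2 * 0.25**2)))
                 for i in range(30)]
        res = classify_localization(profs)
        assert res.label == "restricted"
        assert res.occupancy.mean() == pytest.approx(0.20, abs=0.03)

    def test_insufficient_cells_flagged(self):
        profs = [make_profile(i, 3.0, lambda s: np.ones_like(s)) for i in range(5)]
        res = classify_localization(profs)
        assert res.label == "indeterminate"
        assert res.insufficient_data

    def test_synthetic_populations_labelled_correctly(
            self, small_restricted_analysis, small_nonrestricted_analysis):
        cfg = ClassificationConfig(min_cells=20)
        assert classify_localization(small_restricted_analysis.profiles,
                                     cfg).label == "restricted"
        assert classify_localization(small_nonrestricted_analysis.profiles,
                                     cfg).label == "nonrestricted"


def test_statistics_invariant_to_global_gain(small_restricted_analysis):
    """Scaling the fluorescence gain leaves classification, spacing slope and
    the new/old ratio unchanged."""
    res = small_restricted_analysis
    scaled_profiles = []
    for p in res.profiles:
        q = MedialProfile(cell_id=p.cell_id, s=p.s, I=3.0 * p.I,
                          sampling_step=p.sampling_step, axis_xy=p.axis_xy,
                          halfwidth_px=p.halfwidth_px)
        scaled_profiles.append(q)
    base = classify_localization(res.profiles, ClassificationConfig(min_cells=20))
    scaled = classify_localization(scaled_profiles,
                                   ClassificationConfig(min_cells=20))
    assert base.label == scaled.label
    assert base.focal_fraction == pytest.approx(scaled.focal_fraction)

    from icmscope import detect_foci

    foci3 = []
    for p in scaled_profiles:
        foci3.extend(detect_foci(p))
    reg = spacing_regression(spacing_pairs(res.cells, res.foci)) if len(
        spacing_pairs(res.cells, res.foci)) >= 3 else None
    reg3 = spacing_regression(spacing_pairs(res.cells, foci3)) if reg else None
    if reg:
        assert reg3.slope == pytest.approx(reg.slope, rel=1e-6)
    cmp1 = old_new_intensity_compare(res.cells, res.foci, res.calls)
    cmp3 = old_new_intensity_compare(res.cells, foci3, res.calls)
    assert cmp3["median_ratio"] == pytest.approx(cmp1["median_ratio"], rel=0.02)
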