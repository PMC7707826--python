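"""Endocytic actin patch metrics on synthetic track tables."""

import numpy as np
import pytest

from arpsyn import patch_metrics as pm
from arpsyn import synthetic_data as sd


def triangle_track(patch_id="p", first=5, tau=5, decay=5, peak=100.0,
                   bg=0.0, move_px=0.0):
    """Track rising linearly over ``tau`` frames to ``peak`` then decaying;
    optional post-peak displacement."""
    rise = peak * np.arange(1, tau + 2) / (tau + 1)
    fall = peak * (1.0 - np.arange(1, decay + 1) / (decay + 1))
    signal = np.concatenate([rise, fall])
    frames = np.arange(first, first + len(signal))
    n = len(frames)
    x = np.full(n, 20.0)
    y = np.full(n, 20.0)
    if move_px:
        x[tau + 1:] += move_px
    return pm.PatchTrack(patch_id, frames, x, y, signal + bg,
                         np.full(n, bg))


def make_cell(tracks, area=10.0, cell_id="c"):
    return pm.CellRecord(cell_id, tracks, area)


class TestAlignedMeanTrace:
    def test_single_track_peaks_at_zero(self):
        tr = triangle_track(first=5, tau=5, peak=80.0)
        df = pm.aligned_mean_trace([tr], reference_peak=100.0)
        peak_row = df.loc[df["mean"].idxmax()]
        assert peak_row.offset_s == 0.0
        assert peak_row["mean"] == pytest.approx(0.8)

    def test_identical_tracks_have_zero_sd(self):
        tr = triangle_track()
        df = pm.aligned_mean_trace([tr, triangle_track()], reference_peak=50.0)
        assert np.all(df["sd"] == 0.0)
        assert np.all(df["n"] == 2)

    def test_synthetic_wild_type_peak_recovered(self):
        """18 wild-type tracks: the aligned mean peak must sit within 5% of
        the programmed peak intensity."""
        cells, _ = sd.gen_patches("wt", 3, 5)
        tracks = [tr for c in cells for tr in c.tracks
                  if tr.first_frame > 1 and tr.peak_frame() < tr.last_frame]
        preset = sd.PATCH_PRESETS["wt"]
        df = pm.aligned_mean_trace(tracks[:18], reference_peak=preset.peak_mean)
        peak = float(df.loc[df.offset_s == 0.0, "mean"].iloc[0])
        assert peak == pytest.approx(1.0, rel=0.05)


class TestAssemblyTime:
    def test_ramp_then_decay(self):
        tr = triangle_track(first=3, tau=5, bg=10.0)
        assert pm.assembly_time(tr) == 5.0

    def test_monotone_decay_warns_and_returns_zero(self):
        n = 10
        signal = np.linspace(50.0, 5.0, n)
        tr = pm.PatchTrack("p", np.arange(2, 2 + n), np.zeros(n), np.zeros(n),
                           signal, np.zeros(n))
        with pytest.warns(UserWarning, match="peak at first appearance"):
            assert pm.assembly_time(tr) == 0.0

    def test_invariant_to_scaling_and_offset(self):
        tr = triangle_track(first=3, tau=6, bg=0.0)
        scaled = pm.PatchTrack("q", tr.frames, tr.x, tr.y,
                               5.0 * tr.intensity + 30.0,
                               np.full(len(tr.frames), 30.0))
        assert pm.assembly_time(scaled) == pm.assembly_time(tr)

    def test_synthetic_wild_type_mean(self):
        """Mean assembly time over fully observed wild-type tracks recovers
        the programmed 5.1 s."""
        cells, _ = sd.gen_patches("wt", 10, 5)
        asm = pm.assembly_times(cells)
        assert len(asm) >= 100
        assert asm.assembly_s.mean() == pytest.approx(5.1, rel=0.10)


class TestInitiationRate:
    def test_direct_arithmetic(self):
        tracks = [triangle_track(f"p{i}", first=5 + i) for i in range(6)]
        cell = make_cell(tracks, area=10.0)
        assert pm.initiation_rate(cell) == pytest.approx(0.030)

    def test_frame_one_patches_excluded(self):
        tracks = [triangle_track("seen_at_start", first=1),
                  triangle_track("new", first=4)]
        cell = make_cell(tracks, area=5.0)
        assert pm.initiation_rate(cell) == pytest.approx(1 / (5.0 * 20.0))

    def test_appearances_after_window_excluded(self):
        tracks = [triangle_track("late", first=30)]
        assert pm.initiation_rate(make_cell(tracks)) == 0.0

    def test_scales_inversely_with_area(self):
        tracks = [triangle_track(f"p{i}", first=3 + i) for i in range(4)]
        r1 = pm.initiation_rate(make_cell(tracks, area=8.0))
        r2 = pm.initiation_rate(make_cell(tracks, area=16.0))
        assert r1 == pytest.approx(2.0 * r2)

    def test_short_movie_rejected(self):
        cell = pm.CellRecord("c", [], 10.0, movie_duration_s=15.0)
        with pytest.raises(ValueError):
            pm.initiation_rate(cell)

    def test_poisson_rate_recovered_on_large_ensemble(self):
        """>=200 expected initiation events: measured rate within 10% of the
        generating Poisson rate."""
        preset = sd.PATCH_PRESETS["wt"]
        cells, _ = sd.gen_patches(preset, 20, 11)
        mean_rate = np.mean([pm.initiation_rate(c) for c in cells])
        expected_events = (preset.initiation_rate
                           * sum(c.medial_area_um2 for c in cells) * 20.0)
        assert expected_events >= 200
        assert mean_rate == pytest.approx(preset.initiation_rate, rel=0.10)


class TestDensityAndFate:
    def test_density_arithmetic(self):
        tracks = [triangle_track(f"p{i}", first=10) for i in range(12)]
        cell = make_cell(tracks, area=30.0)
        assert pm.patch_density(cell, 12) == pytest.approx(0.4)
        assert pm.patch_density(cell, 59) == 0.0

    def test_internalized_fraction_arithmetic(self):
        moving = [triangle_track(f"m{i}", first=20, move_px=3.0)
                  for i in range(3)]
        static = [triangle_track("s", first=20)]
        cell = make_cell(moving + static)
        assert pm.percent_internalized(cell) == pytest.approx(75.0)

    def test_static_tracks_zero_percent(self):
        tracks = [triangle_track(f"s{i}", first=20) for i in range(4)]
        assert pm.percent_internalized(make_cell(tracks)) == 0.0

    def test_no_patches_at_fate_frame_flagged(self):
        tracks = [triangle_track("early", first=2)]
        with pytest.raises(ValueError, match="undefined"):
            pm.percent_internalized(make_cell(tracks))

    def test_synthetic_internalization_probability_recovered(self):
        cells, _ = sd.gen_patches("wt", 10, 2)
        vals = [pm.percent_internalized(c) for c in cells]
        assert np.mean(vals) == pytest.approx(90.0, abs=8.0)


class TestWholeCellQC:
    def test_identical_cells_zero_variance(self):
        cells = [pm.CellRecord(f"c{i}", [], 10.0, strain="wt",
                               whole_cell_intensity=120.0,
                               extracellular_background=20.0)
                 for i in range(5)]
        out = pm.whole_cell_qc(cells)
        assert out.loc[0, "mean"] == pytest.approx(100.0)
        assert out.loc[0, "sem"] == pytest.approx(0.0)

    def test_background_equal_to_signal_gives_zero(self):
        cells = [pm.CellRecord("c", [], 10.0, strain="wt",
                               whole_cell_intensity=50.0,
                               extracellular_background=50.0)]
        assert pm.whole_cell_qc(cells).loc[0, "mean"] == 0.0


class TestTrackValidation:
    def test_track_invariants(self):
        with pytest.raises(ValueError, match="contiguous"):
            pm.PatchTrack("p", np.array([1, 3]), np.zeros(2), np.zeros(2),
                          np.ones(2), np.zeros(2))
        with pytest.raises(ValueError):
            pm.PatchTrack("p", np.array([1, 2]), np.zeros(2), np.zeros(2),
                          np.array([1.0, -2.0]), np.zeros(2))

    def test_io_roundtrip(self, tmp_path):
        cells, _ = sd.gen_patches("dip1d", 3, 7)
        pm.write_cells(cells, tmp_path / "tracks.tsv", tmp_path / "cells.tsv")
        loaded = pm.read_cells(tmp_path / "tracks.tsv", tmp_path / "cells.tsv")
        assert len(loaded) == len(cells)
        a = cells[0].tracks[0]
        b = loaded[0].tracks[0]
        assert np.array_equal(a.frames, b.frames)
        assert np.allclose(a.intensity, b.intensity, atol=1e-3)
        assert loaded[0].medial_area_um2 == pytest.approx(
            cells[0].medial_area_um2, abs=1e-3)
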