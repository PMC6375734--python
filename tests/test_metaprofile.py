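"""Origin-centred heatmaps, averaged profiles, and time-course tracking."""

import numpy as np
import pytest

import replichip as rc
from replichip.chipnorm import background_normalize, cen_scale
from replichip.coverage import empty_track
from replichip.errors import ValidationError
from replichip.metaprofile import AverageProfile, symmetrized

from conftest import make_origin_set


def _uniform(genome, value):
    track = empty_track(genome, 100, "u")
    for c in genome.names:
        track.data[c][:] = value
    return track


def _normalized_wt(run, attenuated=False):
    chip = run.chip_mut if attenuated else run.chip_wt
    return background_normalize(
        cen_scale(chip, run.cens), cen_scale(run.chip_bg, run.cens), "ratio"
    )


class TestHeatmap:
    def test_constant_track_fills_cells(self, toy_genome):
        oset = make_origin_set(toy_genome, [("chrA", 100_000, 20.0), ("chrB", 50_000, 30.0)])
        hm = rc.build_heatmap(_uniform(toy_genome, 4.0), oset, window=2000)
        assert hm.matrix.shape == (2, 41)
        assert (hm.matrix[~np.isnan(hm.matrix)] == 4.0).all()

    def test_rows_sorted_by_t_rep(self, toy_genome):
        oset = make_origin_set(toy_genome, [("chrA", 100_000, 40.0), ("chrB", 50_000, 15.0)])
        hm = rc.build_heatmap(_uniform(toy_genome, 1.0), oset, window=2000)
        assert [o.t_rep for o in hm.origins] == [15.0, 40.0]

    def test_row_order_invariant_to_input_order(self, toy_genome):
        recs = [("chrA", 100_000, 40.0), ("chrA", 50_000, 15.0), ("chrB", 70_000, 25.0)]
        a = rc.build_heatmap(_uniform(toy_genome, 1.0), make_origin_set(toy_genome, recs), 2000)
        b = rc.build_heatmap(_uniform(toy_genome, 1.0),
                             make_origin_set(toy_genome, recs[::-1]), 2000)
        assert [o.key for o in a.origins] == [o.key for o in b.origins]

    def test_chromosome_edge_cells_masked(self, toy_genome):
        oset = make_origin_set(toy_genome, [("chrA", 500, 20.0)])
        hm = rc.build_heatmap(_uniform(toy_genome, 2.0), oset, window=2000)
        assert np.isnan(hm.matrix[0, 0])  # offset -2000 is before the chromosome
        assert hm.matrix[0, 20] == 2.0

    def test_missing_chromosome_rejected(self, toy_genome):
        partial = rc.GenomeIndex(("chrA",), (500_000,))
        track = _uniform(partial, 1.0)
        oset = make_origin_set(toy_genome, [("chrB", 50_000, 20.0)])
        with pytest.raises(ValidationError, match="chrB"):
            rc.build_heatmap(track, oset, window=2000)

    def test_fork_peaks_flank_origin_rows(self, sim42):
        """>= 80% of fired-origin rows peak within 2 bins of +/- fork_distance."""
        hm = rc.build_heatmap(_normalized_wt(sim42), sim42.origins)
        hits = 0
        for i in range(hm.n_origins):
            row = hm.matrix[i]
            j = int(np.nanargmax(row))
            if abs(abs(hm.offsets[j]) - sim42.cfg.fork_distance) <= 2 * sim42.cfg.bin_width:
                hits += 1
        assert hits / hm.n_origins >= 0.8


class TestAverageProfile:
    def test_single_row_equals_the_row(self, toy_genome):
        oset = make_origin_set(toy_genome, [("chrA", 100_000, 20.0)])
        hm = rc.build_heatmap(_uniform(toy_genome, 3.0), oset, 2000)
        prof = rc.average_profile(hm)
        np.testing.assert_array_equal(prof.mean, hm.matrix[0])
        assert (prof.n_contributing == 1).all()

    def test_mean_of_zero_and_two_rows(self, toy_genome):
        oset = make_origin_set(toy_genome, [("chrA", 100_000, 20.0), ("chrB", 50_000, 30.0)])
        track = _uniform(toy_genome, 0.0)
        track.data["chrB"][:] = 2.0
        prof = rc.average_profile(rc.build_heatmap(track, oset, 2000))
        np.testing.assert_allclose(prof.mean, 1.0)

    def test_column_means_match_heatmap_exactly(self, sim42):
        hm = rc.build_heatmap(_normalized_wt(sim42), sim42.origins)
        prof = rc.average_profile(hm)
        for j in range(hm.matrix.shape[1]):
            col = hm.matrix[:, j]
            col = col[~np.isnan(col)]
            if col.size:
                assert prof.mean[j] == np.mean(col)
                assert prof.n_contributing[j] == col.size
            else:
                assert np.isnan(prof.mean[j]) and prof.n_contributing[j] == 0

    def test_all_masked_column_stays_masked(self, toy_genome):
        oset = make_origin_set(toy_genome, [("chrA", 500, 20.0)])
        prof = rc.average_profile(rc.build_heatmap(_uniform(toy_genome, 1.0), oset, 2000))
        assert np.isnan(prof.mean[0]) and prof.n_contributing[0] == 0

    def test_profile_symmetric_about_origin(self, sim42):
        """Both forks are simulated identically, so the averaged signal is
        mirror-symmetric within sampling error."""
        prof = rc.average_profile(rc.build_heatmap(_normalized_wt(sim42), sim42.origins))
        offsets, folded = symmetrized(prof)
        n_flank = (len(prof.offsets) - 1) // 2
        left = prof.mean[n_flank::-1]
        right = prof.mean[n_flank:]
        ok = ~np.isnan(left) & ~np.isnan(right)
        # compare the two sides where the signal is substantial
        strong = folded > np.nanmedian(folded) * 1.5
        sel = ok & strong
        assert sel.sum() >= 5
        np.testing.assert_allclose(left[sel], right[sel], rtol=0.25)

    def test_attenuation_recovered_from_profile_area(self, sim_seeds):
        """Area of the background-subtracted average profile over the fork
        span (the peaks sit AT +/- fork_distance, so the span extends three
        peak widths beyond it) recovers the 0.1x attenuation within 0.05."""
        for run in sim_seeds:
            reach = run.cfg.fork_distance + 3 * run.cfg.peak_sigma
            area = {}
            for key, chip in (("wt", run.chip_wt), ("mut", run.chip_mut)):
                hm = rc.build_heatmap(cen_scale(chip, run.cens), run.origins)
                prof = rc.average_profile(hm)
                span = np.abs(prof.offsets) <= reach
                baseline = np.nanmean(prof.mean[~span])  # off-fork flanks
                area[key] = np.nansum(prof.mean[span] - baseline)
            assert area["mut"] / area["wt"] == pytest.approx(0.1, abs=0.05)


class TestSignalTracking:
    def _profile(self, offsets, values):
        return AverageProfile(np.asarray(offsets), np.asarray(values, float),
                              np.ones(len(offsets), dtype=int))

    def test_identical_profiles_identical_peaks(self):
        offsets = np.arange(-2000, 2100, 100)
        vals = np.exp(-0.5 * ((np.abs(offsets) - 1000) / 200.0) ** 2)
        p = self._profile(offsets, vals)
        peaks = rc.track_signal_position([p, p])
        assert peaks[0] == peaks[1] == 1000

    def test_single_spike_argmax(self):
        offsets = np.arange(-2000, 2100, 100)
        vals = np.zeros(len(offsets))
        vals[offsets == 700] = 5.0
        peaks = rc.track_signal_position([self._profile(offsets, vals)] * 2)
        assert (peaks == 700).all()

    def test_flat_profile_flagged_undefined(self):
        offsets = np.arange(-2000, 2100, 100)
        flat = self._profile(offsets, np.ones(len(offsets)))
        spike = self._profile(offsets, np.where(offsets == 500, 2.0, 1.0))
        peaks = rc.track_signal_position([flat, spike])
        assert np.isnan(peaks[0]) and peaks[1] == 500

    def test_grid_mismatch_rejected(self):
        a = self._profile(np.arange(-1000, 1100, 100), np.ones(21))
        b = self._profile(np.arange(-2000, 2100, 100), np.ones(41))
        with pytest.raises(ValidationError, match="grids"):
            rc.track_signal_position([a, b])

    def test_peak_moves_with_fork_distance(self, sim42):
        """HU time course: forks at 1 kb then 3 kb move the profile peak."""
        peaks = []
        profiles = []
        for fd in (1000, 3000):
            cfg = sim42.cfg.replace(fork_distance=fd)
            truth = rc.simulate_copy_number(sim42.origins, sim42.genome, cfg)
            wt = cen_scale(rc.sample_reads(truth, cfg, "chip_tagged", sim42.cens),
                           sim42.cens)
            bg = cen_scale(
                rc.sample_reads(truth, cfg, "chip_untagged", sim42.cens, stream=1),
                sim42.cens)
            norm = background_normalize(wt, bg, "ratio")
            profiles.append(rc.average_profile(rc.build_heatmap(norm, sim42.origins)))
        peaks = rc.track_signal_position(profiles)
        assert abs(peaks[0] - 1000) <= 100
        assert abs(peaks[1] - 3000) <= 100
        assert peaks[1] > peaks[0]
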