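"""Generator contracts: determinism, scripted truth, closed-form expectations."""

import numpy as np
import pytest
from scipy import stats

from mitoscreen.errors import GenerationError
from mitoscreen.geometry import annotation_angle
from mitoscreen.synthetic import (
    CellScript,
    MovieSpec,
    SurfaceModel,
    division_schedule,
    gen_anaphase_annotations,
    gen_cycle_exit_counts,
    gen_dual_pulse_counts,
    gen_screen_plates,
    gen_spindle_track,
    gen_timelapse_movie,
)

from conftest import make_movie_spec


class TestMovieGenerator:
    def test_no_division_yields_no_events(self):
        spec = MovieSpec(
            frame_count=5,
            frame_interval_min=3.0,
            cells=[CellScript(phase_schedule=[("interphase", 0, 5)])],
            seed=0,
        )
        stack, truth = gen_timelapse_movie(spec)
        assert stack.shape == (5, 2, 128, 128)
        assert truth.mitotic_durations_min() == {}

    def test_scripted_duration_is_schedule_difference(self):
        # NEBD at frame 10, anaphase onset at frame 20, 3 min/frame -> 30 min
        spec = make_movie_spec(nebd_frame=10, anaphase_frame=20, n_cells=1)
        _, truth = gen_timelapse_movie(spec)
        assert truth.mitotic_durations_min() == {1: 30.0}

    def test_same_seed_bit_identical(self):
        spec = make_movie_spec(seed=5, noise_sd=8.0)
        a, _ = gen_timelapse_movie(spec)
        b, _ = gen_timelapse_movie(make_movie_spec(seed=5, noise_sd=8.0))
        np.testing.assert_array_equal(a, b)

    def test_daughters_start_at_anaphase_onset(self):
        _, truth = gen_timelapse_movie(make_movie_spec(n_cells=1))
        mother = truth.cells[1]
        for did in mother.daughter_ids:
            assert min(truth.cells[did].phases) == mother.anaphase_onset_frame

    def test_event_ordering_invariant(self):
        _, truth = gen_timelapse_movie(make_movie_spec(n_cells=2, seed=9))
        for cell in truth.cells.values():
            if cell.nebd_frame is not None and cell.anaphase_onset_frame is not None:
                assert cell.nebd_frame < cell.anaphase_onset_frame
            if cell.reassembly_frame is not None and cell.parent_id is not None:
                mother = truth.cells[cell.parent_id]
                assert cell.reassembly_frame > mother.anaphase_onset_frame

    def test_overcrowded_image_raises(self):
        spec = make_movie_spec(n_cells=40)
        spec.image_size = (80, 80)
        with pytest.raises(GenerationError):
            gen_timelapse_movie(spec)

    def test_invalid_schedule_rejected(self):
        bad = MovieSpec(
            frame_count=5,
            frame_interval_min=3.0,
            cells=[CellScript(phase_schedule=[("interphase", 0, 3)])],
        )
        with pytest.raises(ValueError):
            bad.validate()


class TestAnnotationGenerator:
    def test_zero_degrees_is_in_plane(self):
        anns, _ = gen_anaphase_annotations(1, angles_deg=np.array([0.0]), seed=0)
        axis = anns[0].centrosome_2 - anns[0].centrosome_1
        assert abs(axis[2]) < 1e-12  # reference plane is z=0

    def test_ninety_degrees_is_along_normal(self):
        anns, _ = gen_anaphase_annotations(1, angles_deg=np.array([90.0]), seed=0)
        axis = anns[0].centrosome_2 - anns[0].centrosome_1
        assert np.hypot(axis[0], axis[1]) < 1e-12

    def test_noise_free_angles_recovered_exactly(self):
        anns, true_angles = gen_anaphase_annotations(20, seed=1)
        est = np.array([annotation_angle(a)[0].alpha_deg for a in anns])
        np.testing.assert_allclose(est, true_angles, atol=1e-9)

    def test_surface_points_never_collinear(self):
        surf = SurfaceModel(point_noise_sd_um=0.2, curvature_amplitude_um=1.0)
        anns, _ = gen_anaphase_annotations(50, surface=surf, n_surface_points=3, seed=2)
        for ann in anns:
            c = ann.surface_points - ann.surface_points.mean(axis=0)
            assert np.linalg.svd(c, compute_uv=False)[1] > 1e-9

    def test_configurable_surface_point_count(self):
        anns, _ = gen_anaphase_annotations(3, n_surface_points=7, seed=0)
        assert all(a.surface_points.shape == (7, 3) for a in anns)
        with pytest.raises(ValueError):
            gen_anaphase_annotations(3, n_surface_points=2)


class TestSpindleTrackGenerator:
    @pytest.mark.parametrize("rate,expected", [(0.0, 0.0), (2.0, 2.0)])
    def test_noise_free_interval_rotation(self, rate, expected):
        track, true_rot = gen_spindle_track(10.0, 1.0, rate, seed=0)
        np.testing.assert_allclose(track.interval_rotations_deg, expected, atol=1e-9)
        np.testing.assert_allclose(true_rot, expected)

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError):
            gen_spindle_track(1.0, 1.0, 2.0)


class TestDualPulseGenerator:
    def test_fractions_match_uniform_phase_expectation(self):
        # E[BrdU+]/n = Ts/Tc, E[EdU+BrdU-]/n = Ti/Tc
        n = 200_000
        c = gen_dual_pulse_counts(24.0, 6.0, 2.5, n, seed=0)
        se_brdu = np.sqrt(0.25 * (1 - 0.25) / n)
        se_leave = np.sqrt((2.5 / 24) * (1 - 2.5 / 24) / n)
        assert abs(c.n_brdu_pos / n - 6 / 24) < 4 * se_brdu
        assert abs(c.n_edu_pos_brdu_neg / n - 2.5 / 24) < 4 * se_leave

    def test_vanishing_interval_leaves_no_single_positives(self):
        c = gen_dual_pulse_counts(24.0, 6.0, 1e-9, 5000, seed=1)
        assert c.n_edu_pos_brdu_neg <= 1

    def test_seed_reproducibility(self):
        a = gen_dual_pulse_counts(24.0, 6.0, 2.5, 1000, seed=7)
        b = gen_dual_pulse_counts(24.0, 6.0, 2.5, 1000, seed=7)
        assert a == b

    def test_parameter_ordering_enforced(self):
        with pytest.raises(ValueError):
            gen_dual_pulse_counts(6.0, 24.0, 2.5, 100)
        with pytest.raises(ValueError):
            gen_dual_pulse_counts(24.0, 6.0, 7.0, 100)


class TestCycleExitGenerator:
    @pytest.mark.parametrize("frac,expected", [(0.0, 0), (1.0, 500)])
    def test_degenerate_fractions(self, frac, expected):
        c = gen_cycle_exit_counts(frac, 500, seed=0)
        assert c.n_brdu_pos_ki67_neg == expected

    def test_estimator_mean_matches_binomial_oracle(self):
        # 500 simulated specimens at exit fraction 0.3, n=1000 labeled cells
        sims = np.array(
            [
                gen_cycle_exit_counts(0.3, 1000, seed=s).n_brdu_pos_ki67_neg / 1000
                for s in range(500)
            ]
        )
        se_of_mean = np.sqrt(0.3 * 0.7 / 1000) / np.sqrt(500)
        assert abs(sims.mean() - 0.3) < 4 * se_of_mean


class TestScreenGenerator:
    def test_no_hits_wells_exchangeable(self):
        ds = gen_screen_plates(n_mimics=24, cells_per_well=50, replicates=1, seed=3)
        wells = [w.durations_min for p in ds.plates for w in p.wells]
        # same lognormal law in every well: KS between two pooled halves
        half = len(wells) // 2
        a = np.concatenate(wells[:half])
        b = np.concatenate(wells[half:])
        assert stats.ks_2samp(a, b).pvalue > 0.01

    def test_layout_covers_each_mimic_once_per_replicate(self):
        ds = gen_screen_plates(n_mimics=135, cells_per_well=5, replicates=2, seed=0)
        for rep in (1, 2):
            mimics = [
                w.mimic_id for p in ds.plates if p.replicate == rep for w in p.wells
            ]
            assert len(mimics) == 135 and len(set(mimics)) == 135

    def test_hit_and_plate_factor_shift_medians(self):
        ds = gen_screen_plates(
            n_mimics=10,
            cells_per_well=400,
            replicates=1,
            hits={"mimic_003": 1.3},
            plate_sampling_factors={"r1p1": 1.2},
            baseline_duration_min=22.0,
            seed=4,
        )
        wells = {w.mimic_id: w.durations_min for w in ds.plates[0].wells}
        assert np.median(wells["mimic_003"]) == pytest.approx(22.0 * 1.3 * 1.2, rel=0.05)
        assert np.median(wells["mimic_001"]) == pytest.approx(22.0 * 1.2, rel=0.05)

    def test_invalid_hit_multiplier(self):
        with pytest.raises(ValueError):
            gen_screen_plates(n_mimics=4, hits={"mimic_001": 0.0})
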