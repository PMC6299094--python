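import hashlib

import numpy as np
import pytest
from scipy import stats

from mucoquant import synthetic
from mucoquant.assays import group_compare, survival_chisq


def digest(arrays):
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()


class TestSimulateTrajectories:
    def test_degenerate_stillness(self):
        ts, _ = synthetic.simulate_trajectories(
            3, 50, 0.1, diffusion_coeff=0.0, seed=0
        )
        for tr in ts:
            assert np.all(tr.x == tr.x[0]) and np.all(tr.y == tr.y[0])

    def test_pure_drift(self):
        ts, _ = synthetic.simulate_trajectories(
            2, 10, dt=1.0, diffusion_coeff=0.0,
            drift_velocity=(1.0, 0.0), seed=0,
        )
        for tr in ts:
            np.testing.assert_allclose(tr.x - tr.x[0], np.arange(10), atol=1e-12)
            assert np.ptp(tr.y) == 0

    def test_brownian_ensemble_msd_matches_closed_form(self):
        # E[dr^2](tau) = 4 D tau dt for 2-D Brownian motion
        from mucoquant.microrheology import ensemble_msd

        D, dt = 0.25, 1 / 60
        ts, _ = synthetic.simulate_trajectories(500, 1800, dt, D, seed=42)
        ens = ensemble_msd(ts, max_lag=100)
        expected = 4 * D * ens.lags_s
        assert np.max(np.abs(ens.msd - expected) / expected) < 0.05

    def test_increment_variance(self):
        # >= 1e5 increments: sample variance within 3 standard errors of 2 D dt
        D, dt, n_beads, n_frames = 0.5, 0.02, 100, 1001
        ts, _ = synthetic.simulate_trajectories(n_beads, n_frames, dt, D, seed=11)
        inc = np.concatenate([np.diff(tr.x) for tr in ts])
        assert inc.size >= 1e5
        target = 2 * D * dt
        se = target * np.sqrt(2 / inc.size)
        assert abs(inc.var() - target) < 3 * se

    def test_bit_identical_seeding(self):
        a, _ = synthetic.simulate_trajectories(
            10, 100, 0.1, 0.3, anomalous_exponent=0.7,
            localization_sigma=0.05, seed=123,
        )
        b, _ = synthetic.simulate_trajectories(
            10, 100, 0.1, 0.3, anomalous_exponent=0.7,
            localization_sigma=0.05, seed=123,
        )
        da = digest([tr.x for tr in a] + [tr.y for tr in a])
        db = digest([tr.x for tr in b] + [tr.y for tr in b])
        assert da == db

    def test_truth_attached(self):
        ts, truth = synthetic.simulate_trajectories(2, 10, 0.1, 0.2, seed=5)
        assert ts.metadata["truth"] is truth
        assert truth.diffusion_coeff == 0.2
        assert truth.seed == 5

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_frames=1),
            dict(dt=0.0),
            dict(dt=-1.0),
            dict(anomalous_exponent=0.0),
            dict(anomalous_exponent=2.5),
        ],
    )
    def test_invalid_arguments(self, kwargs):
        base = dict(n_beads=2, n_frames=10, dt=0.1, diffusion_coeff=0.1, seed=0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            synthetic.simulate_trajectories(**base)

    def test_seed_required(self):
        with pytest.raises(ValueError):
            synthetic.simulate_trajectories(2, 10, 0.1, 0.1)


class TestRenderBeadMovie:
    def _still(self, x, y, n=5):
        from mucoquant.microrheology import Trajectory, TrajectorySet

        return TrajectorySet(
            [Trajectory(0, np.arange(n) * 0.1, np.full(n, x), np.full(n, y))]
        )

    def test_center_maximum(self):
        movie = synthetic.render_bead_movie(
            self._still(25.0, 25.0), (51, 51), psf_sigma=2.0,
            background_noise_sigma=0.0, pixel_size=1.0, seed=0,
        )
        for f in movie.frames:
            assert np.unravel_index(np.argmax(f), f.shape) == (25, 25)

    def test_two_separated_beads_two_maxima(self):
        from mucoquant.microrheology import Trajectory, TrajectorySet

        psf = 2.0
        ts = TrajectorySet(
            [
                Trajectory(0, np.arange(3) * 0.1, np.full(3, 15.0), np.full(3, 25.0)),
                Trajectory(1, np.arange(3) * 0.1, np.full(3, 35.0), np.full(3, 25.0)),
            ]
        )
        movie = synthetic.render_bead_movie(
            ts, (51, 51), psf_sigma=psf, peak_intensity=100.0,
            background_noise_sigma=0.0, pixel_size=1.0, seed=0,
        )
        from scipy import ndimage

        f = movie.frames[0]
        mx = ndimage.maximum_filter(f, size=7)
        n_max = int(((f == mx) & (f > 50.0)).sum())
        assert n_max == 2

    def test_out_of_frame_rejected(self):
        with pytest.raises(ValueError, match="bead 0"):
            synthetic.render_bead_movie(
                self._still(80.0, 25.0), (51, 51), pixel_size=1.0, seed=0
            )

    def test_metadata_carries_source(self):
        ts = self._still(10.0, 10.0)
        movie = synthetic.render_bead_movie(ts, (31, 31), pixel_size=1.0, seed=0)
        assert movie.metadata["source_trajectories"] is ts


class TestMuoctStack:
    def test_beat_period_arithmetic(self):
        stack, truth = synthetic.simulate_muoct_stack(
            30, 7, cbf=8.0, mct_rate=40, frame_rate=100, n_frames=300, seed=0
        )
        assert stack.frame_rate / truth.cbf == pytest.approx(12.5)
        # the PCL band intensity is periodic with that period
        epi = stack.metadata["epithelial_row"]
        band = stack.frames[:, epi - 3, 0]
        np.testing.assert_allclose(band[:50], band[25:75], atol=1e-9)  # 2 periods

    def test_particulate_advance_arithmetic(self):
        # 40 um/s at 1 um/px and 100 fps -> 0.4 px/frame, 50 um in 1.25 s
        rate, ps, fr = 40.0, 1.0, 100.0
        assert rate / ps / fr == pytest.approx(0.4)
        assert 50.0 / rate == pytest.approx(1.25)

    def test_noiseless_depth_recovery(self):
        from mucoquant.muoct import measure_layer_depths

        stack, _ = synthetic.simulate_muoct_stack(
            30, 7, cbf=8, mct_rate=40, n_frames=300, noise_sigma=0.0, seed=1
        )
        d = measure_layer_depths(stack)
        assert d.asl_depth == pytest.approx(30.0, abs=1.0)
        assert d.pcl_depth == pytest.approx(7.0, abs=1.0)

    def test_nyquist_guard(self):
        with pytest.raises(ValueError, match="Nyquist"):
            synthetic.simulate_muoct_stack(30, 7, cbf=60, mct_rate=10,
                                           frame_rate=100, seed=0)

    def test_layer_ordering_guard(self):
        with pytest.raises(ValueError):
            synthetic.simulate_muoct_stack(5, 10, cbf=8, mct_rate=10, seed=0)


class TestSHGFields:
    def test_zero_fraction(self):
        fs, _ = synthetic.simulate_shg_field_set(3, 0.0, seed=0)
        assert all(not m.any() for m in fs.masks)

    def test_full_fraction(self):
        fs, _ = synthetic.simulate_shg_field_set(2, 100.0, seed=0)
        assert all(m.all() for m in fs.masks)

    def test_target_fraction_on_masks(self):
        fs, _ = synthetic.simulate_shg_field_set(
            10, 20.0, between_field_sd=0.0, seed=3
        )
        assert np.all(np.abs(fs.true_fractions - 20.0) < 1.0)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            synthetic.simulate_shg_field_set(2, 120.0, seed=0)

    def test_deterministic(self):
        a, _ = synthetic.simulate_shg_field_set(4, 30.0, noise_sigma=0.1, seed=9)
        b, _ = synthetic.simulate_shg_field_set(4, 30.0, noise_sigma=0.1, seed=9)
        assert digest(a.fields) == digest(b.fields)


class TestPlateAssay:
    def test_noiseless_linear(self):
        plate = synthetic.simulate_plate_assay(
            [5.0, 10.0], 0.02, 0.05, replicate_cv=0.0, seed=0
        )
        w = plate.wells
        np.testing.assert_allclose(
            w.absorbance, 0.05 + 0.02 * w.concentration, rtol=1e-12
        )

    def test_duplicates_identical_without_noise(self):
        plate = synthetic.simulate_plate_assay([7.0], 0.02, 0.05,
                                               replicate_cv=0.0, seed=0)
        u = plate.wells[plate.wells.role == "unknown"]
        assert u.absorbance.nunique() == 1

    def test_cv_recovered(self):
        plate = synthetic.simulate_plate_assay(
            [10.0], 0.02, 0.0, replicate_cv=0.05, n_replicates=1000, seed=4
        )
        a = plate.wells[plate.wells.role == "unknown"].absorbance
        cv = a.std(ddof=1) / a.mean()
        assert abs(cv - 0.05) / 0.05 < 0.20

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            synthetic.simulate_plate_assay([-1.0], 0.02, 0.05, seed=0)


class TestLavage:
    def test_poisson_limit(self):
        lav, _ = synthetic.simulate_lavage_experiment(
            [5000], [50.0], poisson=True, seed=0
        )
        c = lav.counts.total_cells
        assert abs(c.var() / c.mean() - 1.0) < 0.1

    def test_dispersion_guard(self):
        with pytest.raises(ValueError):
            synthetic.simulate_lavage_experiment([5], [10.0], dispersion=0.0, seed=0)

    def test_equal_deaths_zero_chisq(self):
        _, surv = synthetic.simulate_lavage_experiment(
            [10, 10], [50.0, 50.0], deaths_per_group=[3, 3], seed=0
        )
        chi2, _, _ = survival_chisq(list(zip(surv.deaths, surv.totals)))
        assert chi2 == 0.0

    def test_null_type_one_error_calibrated(self):
        # identical groups: Welch-t p-values behave uniformly
        ps = []
        for seed in range(200):
            lav, _ = synthetic.simulate_lavage_experiment(
                [12, 12], [100.0, 100.0], dispersion=5.0, seed=seed
            )
            df = lav.counts
            rep = group_compare(
                {
                    "a": df[df.group == "group0"].total_cells,
                    "b": df[df.group == "group1"].total_cells,
                },
                method="welch_t",
            )
            ps.append(rep["p"])
        ps = np.asarray(ps)
        rate = (ps < 0.05).mean()
        assert abs(rate - 0.05) <= 0.05  # binomial 3-sigma band at n=200
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestSampleFieldsUniform:
    def test_exhaustive(self):
        out = synthetic.sample_fields_uniform((4, 5), 20, seed=0)
        assert sorted(out) == [(r, c) for r in range(4) for c in range(5)]

    def test_stride_arithmetic(self):
        # 15 of 60 positions -> stride 4
        out = synthetic.sample_fields_uniform((6, 10), 15, seed=1)
        flat = sorted(r * 10 + c for r, c in out)
        assert len(set(flat)) == 15
        np.testing.assert_array_equal(np.diff(flat), 4)

    def test_uniform_inclusion(self):
        hits = np.zeros(60)
        for seed in range(1000):
            for r, c in synthetic.sample_fields_uniform((6, 10), 15, seed=seed):
                hits[r * 10 + c] += 1
        freq = hits / 1000
        assert np.all(np.abs(freq - 0.25) < 0.03)

    def test_too_many_fields(self):
        with pytest.raises(ValueError):
            synthetic.sample_fields_uniform((2, 2), 5, seed=0)


def test_image_stack_invariants():
    with pytest.raises(ValueError):
        synthetic.ImageStack(np.zeros((2, 4, 4)), pixel_size=0.0, frame_rate=10)
    with pytest.raises(ValueError):
        synthetic.ImageStack(np.full((2, 4, 4), -1.0), pixel_size=1.0, frame_rate=10)
    with pytest.raises(ValueError):
        synthetic.ImageStack(np.full((2, 4, 4), np.nan), pixel_size=1.0, frame_rate=10)
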