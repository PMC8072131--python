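"""Phantom generator: analytic centrelines, rasterisation truth, determinism."""

import numpy as np
import pytest
from scipy.integrate import quad

import nichequant as nq
from nichequant.exceptions import InvalidSpecError, PlacementError
from nichequant.phantom import (
    expected_timelapse_slope,
    make_centerline,
    polyline_tortuosity,
)


class TestCenterlines:
    def test_straight_tortuosity_is_one(self):
        pts = make_centerline("straight", length_um=100.0)
        assert polyline_tortuosity(pts) == pytest.approx(1.0, abs=1e-12)

    def test_semicircle_tortuosity_is_half_pi(self):
        r = 30.0
        pts = make_centerline("arc", length_um=np.pi * r, amplitude_um=r, step_um=0.05)
        assert polyline_tortuosity(pts) == pytest.approx(np.pi / 2, rel=1e-5)

    def test_sine_tortuosity_matches_quadrature_oracle(self):
        amp, wl = 10.0, 50.0
        pts = make_centerline("sine", length_um=wl, amplitude_um=amp, wavelength_um=wl, step_um=0.02)
        k = 2 * np.pi / wl
        arc, _ = quad(lambda x: np.sqrt(1 + (amp * k * np.cos(k * x)) ** 2), 0, wl, limit=400)
        assert polyline_tortuosity(pts) == pytest.approx(arc / wl, rel=1e-4)

    def test_arc_length_converges_with_step(self):
        coarse = make_centerline("sine", 100.0, 8.0, 40.0, step_um=2.0)
        fine = make_centerline("sine", 100.0, 8.0, 40.0, step_um=0.05)
        from nichequant import polyline_arc_length

        assert polyline_arc_length(fine) > polyline_arc_length(coarse)
        assert polyline_arc_length(fine) == pytest.approx(polyline_arc_length(coarse), rel=0.01)

    def test_tortuosity_invariant_under_rigid_rotation(self):
        pts = make_centerline("sine", 80.0, 6.0, 30.0, step_um=0.5)
        ang = 0.7
        rot = np.array(
            [
                [np.cos(ang), -np.sin(ang), 0],
                [np.sin(ang), np.cos(ang), 0],
                [0, 0, 1],
            ]
        )
        assert polyline_tortuosity(pts @ rot.T + 5.0) == pytest.approx(
            polyline_tortuosity(pts), abs=1e-12
        )

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(kind="straight", length_um=-5.0),
            dict(kind="straight", length_um=10.0, step_um=5.0),
            dict(kind="sine", length_um=50.0, amplitude_um=5.0, wavelength_um=0.0),
            dict(kind="nope", length_um=50.0),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(InvalidSpecError):
            make_centerline(**{"step_um": 0.5, **kwargs})


class TestNichePhantom:
    def test_cylinder_volume_fraction_matches_analytic(self, straight_tube_phantom):
        spec, _, truth = straight_tube_phantom
        # clipped tube length 99 um in a 41*41*100 grid
        expected = np.pi * 3.0**2 * 99.0 / (41 * 41 * 100)
        # the clipped centreline ends within one sampling step of the faces
        assert truth.vessel_volume_fraction == pytest.approx(expected, rel=0.005)
        assert truth.vessel_voxel_fraction == pytest.approx(expected, rel=0.10)

    def test_no_vessels_gives_background_channel(self):
        spec = nq.PhantomSpec(shape=(8, 16, 16), seed=0)
        channels, truth = nq.generate_niche_phantom(spec)
        assert not truth.masks["laminin"].any()
        assert truth.vessel_volume_fraction == 0.0
        assert np.all(channels["laminin"].data == spec.noise.background)

    def test_seeded_generation_is_bit_identical(self):
        spec = nq.PhantomSpec(
            shape=(16, 32, 32),
            vessels=(nq.VesselSpec(kind="sine", radius_um=2.0, amplitude_um=4.0, wavelength_um=20.0),),
            cells=(nq.CellGroupSpec(count=3, depth_um=4.0),),
            chains=(nq.ChainGroupSpec(count=2, semi_axes_um=(6.0, 2.0, 2.0)),),
            noise=nq.NoiseSpec(sigma=15.0),
            seed=42,
        )
        a_ch, a_tr = nq.generate_niche_phantom(spec)
        b_ch, b_tr = nq.generate_niche_phantom(spec)
        for name in a_ch:
            assert np.array_equal(a_ch[name].data, b_ch[name].data)
        assert a_tr.to_json_dict() == b_tr.to_json_dict()

    def test_truth_placements_are_honoured(self):
        spec = nq.PhantomSpec(
            shape=(24, 64, 64),
            vessels=(nq.VesselSpec(kind="straight", radius_um=3.0, start_um=(0.0, 32.0, 8.0)),),
            cells=(nq.CellGroupSpec(count=4, depth_um=3.0, vessel_distance_um=8.0),),
            seed=5,
        )
        _, truth = nq.generate_niche_phantom(spec)
        half_diag = 0.5 * np.sqrt(3.0)
        for c in truth.cells:
            assert abs(c["depth_um"] - 3.0) <= 0.5 + 1e-9
            assert abs(c["vessel_distance_um"] - 8.0) <= half_diag + 1e-9

    def test_impossible_placement_raises(self):
        spec = nq.PhantomSpec(
            shape=(10, 20, 20),
            cells=(nq.CellGroupSpec(count=1, vessel_distance_um=5.0),),  # no vessels
            seed=0,
        )
        with pytest.raises(PlacementError):
            nq.generate_niche_phantom(spec)

    def test_chain_truth_eccentricity_from_semi_axes(self):
        spec = nq.PhantomSpec(
            shape=(30, 40, 40),
            chains=(nq.ChainGroupSpec(count=1, semi_axes_um=(10.0, 4.0, 4.0)),),
            seed=1,
        )
        _, truth = nq.generate_niche_phantom(spec)
        assert truth.chains[0]["eccentricity"] == pytest.approx(1 - 4 / 10)


class TestTimelapseSimulation:
    def test_zero_rates_keep_counts_constant(self):
        counts = nq.simulate_birth_death_counts(50, 0.0, 0.0, 20, seed=0)
        assert np.all(counts == 50)
        assert expected_timelapse_slope(50, 0.0, 0.0, 20) == pytest.approx(0.0)

    def test_deterministic_two_births_per_frame(self):
        movie, truth = nq.simulate_timelapse(
            n_initial=10, births_per_frame=2, n_frames=10, frame_shape=(96, 96), seed=3
        )
        assert truth.frame_counts == list(range(10, 30, 2))
        assert truth.expected_slope == pytest.approx(2.0)
        assert movie.n_frames == 10

    def test_monte_carlo_mean_slope_within_three_se(self):
        n0, p, q, frames = 100, 0.01, 0.005, 200
        slopes = [
            nq.population_slope(
                nq.simulate_birth_death_counts(n0, p, q, frames, seed=seed)
            ).slope_per_frame
            for seed in range(50)
        ]
        slopes = np.asarray(slopes)
        expected = expected_timelapse_slope(n0, p, q, frames)
        se = slopes.std(ddof=1) / np.sqrt(len(slopes))
        assert abs(slopes.mean() - expected) <= 3 * se

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(InvalidSpecError):
            nq.simulate_birth_death_counts(10, 1.2, 0.0, 10)
        with pytest.raises(InvalidSpecError):
            nq.simulate_birth_death_counts(10, 0.1, 0.0, 1)
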