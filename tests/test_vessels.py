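"""Vessel skeleton metrics: tortuosity, diameter, density, distributions."""

import numpy as np
import pytest
from scipy.integrate import quad

import nichequant as nq
from nichequant.exceptions import ContainmentError, EmptyMaskError, InconsistencyError
from nichequant.vessels import VesselBranch


def _tube_mask(spec_kwargs, seed=0):
    spec = nq.PhantomSpec(seed=seed, **spec_kwargs)
    _, truth = nq.generate_niche_phantom(spec)
    return nq.BinaryMask3D(truth.masks["laminin"], spec.spacing_um), truth


class TestSkeletonTopology:
    def test_straight_cylinder_single_branch_two_nodes(self, straight_tube_mask):
        graph = nq.skeletonize_vessels(straight_tube_mask)
        assert graph.n_branches == 1
        assert len(graph.nodes) == 2
        assert all(deg == 1 for _, deg in graph.nodes)
        # the single branch tracks the tube axis
        path = graph.branches[0].path
        assert np.all(path[:, 0] == path[0, 0])
        assert np.all(path[:, 1] == path[0, 1])

    def test_y_junction_three_branches_one_degree3_node(self):
        mask, _ = _tube_mask(
            dict(
                shape=(31, 61, 61),
                vessels=(
                    nq.VesselSpec(kind="straight", radius_um=2.5, length_um=56, start_um=(2, 30, 15)),
                    nq.VesselSpec(
                        kind="straight",
                        radius_um=2.5,
                        length_um=38,
                        start_um=(30, 30, 15),
                        rotation=((0.0, 0.0, 1.0), (0.0, 1.0, 0.0), (-1.0, 0.0, 0.0)),
                    ),
                ),
            )
        )
        graph = nq.skeletonize_vessels(mask)
        assert graph.n_branches == 3
        degrees = sorted(d for _, d in graph.nodes)
        assert degrees == [1, 1, 1, 3]

    def test_isolated_voxel_is_a_zero_branch_node(self):
        m = np.zeros((9, 9, 9), dtype=bool)
        m[4, 4, 4] = True
        graph = nq.skeletonize_vessels(nq.BinaryMask3D(m, (1, 1, 1)))
        assert graph.n_branches == 0
        assert graph.nodes == [((4, 4, 4), 0)]

    def test_skeleton_lies_inside_mask(self, straight_tube_mask):
        graph = nq.skeletonize_vessels(straight_tube_mask)
        vox = graph.voxels
        assert straight_tube_mask.data[tuple(vox.T)].all()

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            nq.skeletonize_vessels(nq.BinaryMask3D(np.zeros((4, 4, 4), bool), (1, 1, 1)))

    def test_one_skeleton_component_per_mask_component(self):
        mask, _ = _tube_mask(
            dict(
                shape=(41, 41, 100),
                vessels=(
                    nq.VesselSpec(kind="straight", radius_um=3.0, start_um=(0, 10, 10)),
                    nq.VesselSpec(kind="straight", radius_um=3.0, start_um=(0, 30, 30)),
                ),
            )
        )
        graph = nq.skeletonize_vessels(mask)
        assert graph.n_branches == 2


class TestTortuosity:
    def test_axis_aligned_straight_path_is_one(self):
        path = np.array([[0, 0, i] for i in range(10)])
        assert nq.branch_tortuosity(path, (1, 1, 1)) == pytest.approx(1.0)

    def test_closed_loop_flagged_undefined(self):
        path = np.array([[0, 0, 0], [0, 0, 1], [0, 1, 1], [0, 1, 0], [0, 0, 0]])
        assert np.isnan(nq.branch_tortuosity(path, (1, 1, 1)))

    def test_straight_tube_median_tortuosity_within_2pc(self, straight_tube_mask):
        graph = nq.skeletonize_vessels(straight_tube_mask)
        assert nq.median_tortuosity(graph) == pytest.approx(1.0, rel=0.02)

    def test_semicircular_tube_recovers_half_pi_within_5pc(self):
        R = 40.0
        mask, truth = _tube_mask(
            dict(
                shape=(17, 101, 61),
                vessels=(
                    nq.VesselSpec(
                        kind="arc", radius_um=2.5, amplitude_um=R, length_um=np.pi * R, start_um=(10, 10, 8)
                    ),
                ),
            )
        )
        graph = nq.skeletonize_vessels(mask)
        assert nq.median_tortuosity(graph) == pytest.approx(np.pi / 2, rel=0.05)

    def test_sine_tube_matches_quadrature_oracle_within_5pc(self):
        amp, wl = 10.0, 50.0
        mask, truth = _tube_mask(
            dict(
                shape=(17, 45, 108),
                vessels=(
                    nq.VesselSpec(
                        kind="sine", radius_um=2.0, amplitude_um=amp, wavelength_um=wl,
                        length_um=2 * wl, start_um=(4, 22, 8),
                    ),
                ),
            )
        )
        k = 2 * np.pi / wl
        arc, _ = quad(lambda x: np.sqrt(1 + (amp * k * np.cos(k * x)) ** 2), 0, 2 * wl, limit=400)
        oracle = arc / (2 * wl)
        assert truth.vessels[0]["tortuosity"] == pytest.approx(oracle, rel=1e-3)
        graph = nq.skeletonize_vessels(mask)
        assert nq.median_tortuosity(graph) == pytest.approx(oracle, rel=0.05)

    def test_tortuosity_invariant_under_phantom_rotation(self):
        base = dict(shape=(41, 41, 100), vessels=(nq.VesselSpec(kind="straight", radius_um=3.0),))
        mask_a, _ = _tube_mask(base)
        rot = ((0.0, 0.0, 1.0), (0.0, 1.0, 0.0), (-1.0, 0.0, 0.0))  # x -> z
        mask_b, _ = _tube_mask(
            dict(shape=(100, 41, 41), vessels=(nq.VesselSpec(kind="straight", radius_um=3.0, rotation=rot),))
        )
        ta = nq.median_tortuosity(nq.skeletonize_vessels(mask_a))
        tb = nq.median_tortuosity(nq.skeletonize_vessels(mask_b))
        assert ta == pytest.approx(tb, rel=0.02)

    def test_total_branch_length_matches_tube_length_within_5pc(self, straight_tube_mask):
        graph = nq.skeletonize_vessels(straight_tube_mask)
        total = sum(b.path_length_um for b in graph.branches)
        assert total == pytest.approx(99.0, rel=0.05)


class TestDiameter:
    def test_radius3_cylinder_diameter_6_within_1um(self, straight_tube_mask):
        _, table = nq.measure_vessels(straight_tube_mask)
        assert abs(table["mean_diameter_um"].iloc[0] - 6.0) <= 1.0

    def test_radius45_cylinder_diameter_9_within_1um(self):
        mask, _ = _tube_mask(
            dict(shape=(40, 40, 100), vessels=(nq.VesselSpec(kind="straight", radius_um=4.5),))
        )
        _, table = nq.measure_vessels(mask)
        assert abs(table["mean_diameter_um"].iloc[0] - 9.0) <= 1.0

    def test_distance_transform_matches_brute_force_on_crop(self):
        # the diameter estimator's EDT agrees with explicit nearest-background search
        from scipy import ndimage

        rng = np.random.default_rng(3)
        m = ndimage.binary_dilation(rng.random((12, 12, 12)) < 0.05, iterations=2)
        if not m.any() or m.all():
            m[5, 5, 5] = True
        edt = ndimage.distance_transform_edt(m, sampling=(1, 1, 1))
        bg = np.argwhere(~m).astype(float)
        for vox in np.argwhere(m)[:50]:
            d = np.sqrt(((bg - vox) ** 2).sum(axis=1).min())
            assert edt[tuple(vox)] == pytest.approx(d, abs=1e-9)

    def test_capillary_cutoff_below_10um(self, straight_tube_mask):
        _, table = nq.measure_vessels(straight_tube_mask, capillary_max_diameter_um=10.0)
        assert table["is_capillary"].all()  # ~6 um vessel
        mask, _ = _tube_mask(
            dict(shape=(41, 41, 80), vessels=(nq.VesselSpec(kind="straight", radius_um=6.0),))
        )
        _, big = nq.measure_vessels(mask)
        assert not big["is_capillary"].any()  # ~12 um vessel

    def test_branch_voxel_outside_mask_raises(self, straight_tube_mask):
        bad = np.array([[0, 0, 0], [0, 0, 1]])
        with pytest.raises(InconsistencyError):
            nq.branch_diameter(bad, straight_tube_mask)


class TestDensity:
    def test_identity_and_empty_cases(self):
        m = np.zeros((6, 6, 6), dtype=bool)
        m[2:4, 2:4, 2:4] = True
        mask = nq.BinaryMask3D(m, (1, 1, 1))
        assert nq.vessel_density(mask, mask) == 1.0
        empty = nq.BinaryMask3D(np.zeros_like(m), (1, 1, 1))
        full = nq.BinaryMask3D(np.ones_like(m), (1, 1, 1))
        assert nq.vessel_density(empty, full) == 0.0

    def test_vessels_outside_niche_raise(self):
        v = nq.BinaryMask3D(np.ones((4, 4, 4), bool), (1, 1, 1))
        niche = nq.BinaryMask3D(np.zeros((4, 4, 4), bool), (1, 1, 1))
        with pytest.raises(ContainmentError):
            nq.vessel_density(v, niche)

    def test_phantom_fraction_recovered_within_10pc(self):
        mask, truth = _tube_mask(
            dict(
                shape=(41, 41, 101),
                vessels=(
                    nq.VesselSpec(kind="straight", radius_um=5.0, start_um=(0, 12, 12)),
                    nq.VesselSpec(kind="straight", radius_um=5.0, start_um=(0, 28, 28)),
                ),
            )
        )
        full = nq.BinaryMask3D(np.ones(mask.shape, bool), mask.spacing)
        measured = nq.vessel_density(mask, full)
        assert measured == pytest.approx(truth.vessel_volume_fraction, rel=0.10)

    def test_density_invariant_under_empty_padding(self, straight_tube_mask):
        niche = nq.BinaryMask3D(np.ones(straight_tube_mask.shape, bool), (1, 1, 1))
        d0 = nq.vessel_density(straight_tube_mask, niche)
        padded = nq.vessel_density(
            nq.BinaryMask3D(np.pad(straight_tube_mask.data, 4), (1, 1, 1)),
            nq.BinaryMask3D(np.pad(niche.data, 4), (1, 1, 1)),
        )
        assert padded == pytest.approx(d0, rel=1e-12)


class TestDiameterDistribution:
    def _branch(self, d):
        return VesselBranch(
            branch_id=0,
            path=np.zeros((2, 3), dtype=int),
            path_length_um=1.0,
            chord_um=1.0,
            tortuosity=1.0,
            local_diameters_um=np.full(4, d),
            mean_diameter_um=d,
        )

    def test_per_branch_sample(self):
        sample = nq.diameter_distribution([self._branch(d) for d in (4, 6, 8)], "per-branch")
        assert sorted(sample) == [4, 6, 8]

    def test_per_voxel_weighting_repeats_local_values(self):
        sample = nq.diameter_distribution([self._branch(4), self._branch(8)], "per-voxel")
        assert len(sample) == 8

    def test_identical_samples_have_zero_ks_distance(self):
        sample = nq.diameter_distribution([self._branch(6)] * 3, "per-branch")
        res = nq.ks_two_sample(sample, sample)
        assert res.statistic == 0.0

    def test_bimodal_radii_give_modes_near_truth(self):
        mask, _ = _tube_mask(
            dict(
                shape=(41, 41, 101),
                vessels=(
                    nq.VesselSpec(kind="straight", radius_um=3.0, start_um=(0, 12, 12)),
                    nq.VesselSpec(kind="straight", radius_um=4.125, start_um=(0, 28, 28)),
                ),
            )
        )
        graph, _ = nq.measure_vessels(mask)
        sample = np.sort(nq.diameter_distribution(graph.branches, "per-branch"))
        assert abs(sample[0] - 6.0) <= 1.0
        assert abs(sample[-1] - 8.25) <= 1.0
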