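"""Pocket and ligand descriptors: closed forms, oracles, invariances."""

import numpy as np
import pandas as pd
import pytest

from oncopocketome.descriptors import (
    boundary_voxels,
    buried_volume,
    compute_pocket_descriptors,
    descriptor_pca,
    exposed_to_solvent,
    globularity,
    hydrophilic_volume,
    hydrophobic_volume,
    integy_moment,
    ligand_descriptors,
    rugosity,
    surface_area,
)
from oncopocketome.grid import GridParams, _ray_offsets, voxel_buriedness
from oncopocketome.pockets import Pocket, detect_pockets


def voxel_ball(radius, spacing):
    n = int(np.ceil(radius / spacing)) + 2
    ax = np.arange(-n, n + 1)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    idx = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    return idx[np.sqrt((idx**2).sum(axis=1)) * spacing <= radius]


def voxel_box(nx, ny, nz):
    gx, gy, gz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


def voxel_ellipsoid(a, b, c, spacing=0.5):
    n = int(np.ceil(max(a, b, c) / spacing)) + 2
    ax = np.arange(-n, n + 1)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    idx = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    x, y, z = (idx * spacing).T
    return idx[(x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0]


class TestGlobularity:
    def test_sphere_is_one_within_discretization(self):
        g = globularity(voxel_ball(6.0, 0.5), 0.5)
        assert g == pytest.approx(1.0, abs=0.05)

    def test_elongated_bar_below_one(self):
        g = globularity(voxel_box(20, 2, 2), 1.0)
        assert g < 1.0

    def test_elongation_at_fixed_volume_decreases_globularity(self):
        # ellipsoids of equal volume, increasingly eccentric
        shapes = [(4.0, 4.0, 4.0), (6.35, 4.0, 2.52), (10.08, 4.0, 1.59)]
        gs = [globularity(voxel_ellipsoid(*s), 0.5) for s in shapes]
        assert gs[0] > gs[1] > gs[2]


class TestRugosity:
    def test_sphere_closed_form_r_over_3(self):
        r = 6.0
        assert rugosity(voxel_ball(r, 0.5), 0.5) == pytest.approx(r / 3, rel=0.05)

    def test_single_voxel_closed_form_h_over_6(self):
        for h in (0.5, 1.0, 2.0):
            assert rugosity(np.array([[0, 0, 0]]), h) == pytest.approx(h / 6)

    def test_doubling_dimensions_doubles_rugosity(self):
        idx = voxel_box(6, 6, 6)
        assert rugosity(idx, 2.0) == pytest.approx(2 * rugosity(idx, 1.0))


class TestFieldVolumes:
    def _pocket_and_field(self, energies):
        """3x3x3 pocket over a synthetic field cube."""
        idx = voxel_box(3, 3, 3)
        pocket = Pocket(indices=idx, origin=np.zeros(3), spacing=1.0,
                        source="complex")

        class FakeField:
            probes = {"DRY": energies, "OH2": energies}

        return pocket, FakeField()

    def test_zero_energies_zero_volume(self):
        pocket, field = self._pocket_and_field(np.zeros((3, 3, 3)))
        assert hydrophobic_volume(pocket, field) == 0.0
        assert hydrophilic_volume(pocket, field) == 0.0

    def test_count_times_voxel_volume(self):
        e = np.zeros((3, 3, 3))
        e.ravel()[:10] = -1.0
        pocket, field = self._pocket_and_field(e)
        assert hydrophobic_volume(pocket, field, threshold=-0.5) == 10.0
        # at 0.8 Å spacing the same count scales by h³
        pocket.spacing = 0.8
        assert hydrophobic_volume(pocket, field, threshold=-0.5) == pytest.approx(
            10 * 0.8**3)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(3)
        e = rng.normal(scale=2.0, size=(3, 3, 3))
        pocket, field = self._pocket_and_field(e)
        v1 = hydrophobic_volume(pocket, field, threshold=-0.5)
        v2 = hydrophobic_volume(pocket, field, threshold=-1.5)
        assert v2 <= v1

    def test_disjoint_wells_separate_voxels(self):
        dry = np.zeros((3, 3, 3))
        oh2 = np.zeros((3, 3, 3))
        dry[0] = -2.0
        oh2[2] = -5.0
        idx = voxel_box(3, 3, 3)
        pocket = Pocket(indices=idx, origin=np.zeros(3), spacing=1.0,
                        source="complex")

        class FakeField:
            probes = {"DRY": dry, "OH2": oh2}

        phobic = hydrophobic_volume(pocket, FakeField())
        philic = hydrophilic_volume(pocket, FakeField())
        assert phobic == 9.0 and philic == 9.0  # non-overlapping layers


class TestSolventExposure:
    def test_enclosed_cavity_zero(self, cavity_bundle):
        pocket = cavity_bundle["pockets"][0]
        assert exposed_to_solvent(pocket, cavity_bundle["structure"]) == 0.0

    def test_open_cavity_positive(self, hemisphere_bundle):
        pockets = detect_pockets(
            hemisphere_bundle["structure"], source="detached_partner_A",
            field=hemisphere_bundle["field"],
            grid_params=hemisphere_bundle["params"])
        assert pockets, "open invagination should be detected"
        assert exposed_to_solvent(
            pockets[0], hemisphere_bundle["structure"]) > 0.0

    def test_min_dist_monotonicity(self, hemisphere_bundle):
        pockets = detect_pockets(
            hemisphere_bundle["structure"], source="detached_partner_A",
            field=hemisphere_bundle["field"],
            grid_params=hemisphere_bundle["params"])
        st_ = hemisphere_bundle["structure"]
        v = [exposed_to_solvent(pockets[0], st_, d) for d in (2.2, 3.0, 4.0)]
        assert v[0] >= v[1] >= v[2]


class TestBuriedVolume:
    def test_enclosed_pocket_fully_buried(self, cavity_bundle):
        pocket = cavity_bundle["pockets"][0]
        headline, low = buried_volume(pocket, cavity_bundle["field"],
                                      cavity_bundle["params"])
        assert headline == pytest.approx(pocket.volume, rel=1e-6)
        assert low == 0.0

    def test_matches_bruteforce_ray_oracle(self, hemisphere_bundle):
        pockets = detect_pockets(
            hemisphere_bundle["structure"], source="detached_partner_A",
            field=hemisphere_bundle["field"],
            grid_params=hemisphere_bundle["params"])
        pocket = pockets[0]
        field = hemisphere_bundle["field"]
        params = hemisphere_bundle["params"]
        sample = pocket.indices[:: max(1, len(pocket.indices) // 15)]
        offsets = _ray_offsets(params)
        dims = field.dims
        expected = []
        for ijk in sample:
            hits = 0
            for ray in offsets:
                for step in ray:
                    p = ijk + step
                    if np.any(p < 0) or np.any(p >= dims):
                        continue
                    if field.inside_protein[tuple(p)]:
                        hits += 1
                        break
            expected.append(hits / len(offsets))
        got = voxel_buriedness(field, sample, params)
        assert np.allclose(got, expected, atol=1e-9)
        headline, _ = buried_volume(pocket, field, params)
        assert 0.0 < headline < pocket.volume


class TestIntegyMoment:
    def test_centrosymmetric_hydrophilics_zero(self):
        coords = np.array([[1.0, 0, 0], [-1.0, 0, 0], [0, 2.0, 0],
                           [0, -2.0, 0]])
        elements = ["O", "O", "N", "N"]
        assert integy_moment(coords, elements) == pytest.approx(0.0, abs=1e-12)

    def test_single_offset_hydrophilic(self):
        # heavy carbon cluster at the origin, one N at (4,0,0): the center
        # of mass stays ~at the origin as the cluster mass grows
        coords = np.concatenate(
            [np.zeros((1000, 3)), [[4.0, 0.0, 0.0]]], axis=0)
        elements = ["C"] * 1000 + ["N"]
        m = integy_moment(coords, elements)
        assert m == pytest.approx(4.0, abs=0.01)

    def test_rotation_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        coords = rng.normal(size=(30, 3))
        elements = ["C", "N", "O"] * 10
        m0 = integy_moment(coords, elements)
        R = Rotation.from_euler("xyz", [10, 70, -30], degrees=True).as_matrix()
        assert integy_moment(coords @ R.T, elements) == pytest.approx(m0)

    def test_no_hydrophilic_flagged_zero(self):
        with pytest.warns(UserWarning):
            m = integy_moment(np.zeros((3, 3)), ["C", "C", "C"])
        assert m == 0.0


class TestPCA:
    def test_single_axis_variance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        df = pd.DataFrame({"a": x, "b": 2 * x, "c": -x})
        _, _, ev = descriptor_pca(df, n_components=2)
        assert ev[0] == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_gaussian_equal_components(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(10_000, 3)), columns=list("abc"))
        _, _, ev = descriptor_pca(df, n_components=3)
        assert np.allclose(ev, 1 / 3, atol=0.02)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        scores, loadings, _ = descriptor_pca(df, n_components=4)
        z = (df - df.mean()) / df.std(ddof=0)
        recon = scores.to_numpy() @ loadings.to_numpy().T
        assert np.allclose(recon, z.to_numpy(), atol=1e-8)

    def test_constant_column_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"a": rng.normal(size=30),
                           "b": rng.normal(size=30),
                           "c": np.ones(30)})
        with pytest.warns(UserWarning, match="constant"):
            scores, loadings, _ = descriptor_pca(df, n_components=2)
        assert "c" not in loadings.index


class TestRigidMotionInvariance:
    def test_descriptors_stable_under_voxel_aligned_shift(self, cavity_bundle):
        from oncopocketome.grid import compute_fields

        st_ = cavity_bundle["structure"]
        params = cavity_bundle["params"]
        shift = (params.spacing * 4, -params.spacing * 2, params.spacing * 6)
        moved = st_.translated(shift)
        field2 = compute_fields(moved, params, probes=("DRY", "OH2"))
        pockets2 = detect_pockets(moved, source="detached_partner_A",
                                  grid_params=params, field=field2)
        d1 = compute_pocket_descriptors(
            cavity_bundle["pockets"][0], cavity_bundle["field"], st_, params)
        d2 = compute_pocket_descriptors(pockets2[0], field2, moved, params)
        for key, v1 in d1.as_dict().items():
            assert d2.as_dict()[key] == pytest.approx(v1, rel=1e-5, abs=1e-6), key


class TestMatchedPocketsPattern:
    def test_shape_alike_fields_differ(self):
        """Two pockets with identical geometry but opposite field makeup:
        near-equal globularity/rugosity, divergent phobic/philic volumes."""
        idx = voxel_ball(4.0, 1.0)
        p1 = Pocket(indices=idx, origin=np.zeros(3), spacing=1.0,
                    source="complex")
        p2 = Pocket(indices=idx.copy(), origin=np.zeros(3), spacing=1.0,
                    source="complex")
        shape = tuple(idx.max(axis=0) + 1)
        phobic = np.full(shape, -2.0)
        philic_none = np.zeros(shape)

        class F1:
            probes = {"DRY": phobic, "OH2": philic_none}

        class F2:
            probes = {"DRY": philic_none, "OH2": np.full(shape, -5.0)}

        assert globularity(p1.indices, 1.0) == globularity(p2.indices, 1.0)
        assert rugosity(p1.indices, 1.0) == rugosity(p2.indices, 1.0)
        assert hydrophobic_volume(p1, F1()) > 0 == hydrophobic_volume(p2, F2())
        assert hydrophilic_volume(p2, F2()) > 0 == hydrophilic_volume(p1, F1())


class TestLigandDescriptors:
    def test_panel_basics(self):
        coords = np.array([[0.0, 0, 0], [1.5, 0, 0], [3.0, 0, 0],
                           [4.5, 0, 0], [6.0, 0, 0]])
        elements = ["C", "C", "N", "C", "O"]
        d = ligand_descriptors(coords, elements)
        assert d["molecular_weight"] == pytest.approx(
            3 * 12.011 + 14.007 + 15.999)
        assert d["n_hba"] == 2 and d["n_hbd"] == 1
        assert d["integy_moment"] > 0
        assert d["radius_of_gyration"] > 0
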