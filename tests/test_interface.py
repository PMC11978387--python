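"""SASA closed forms, rSA classification, stickiness, GD and SC."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from abdock.errors import GeometryError, TableError
from abdock.interface import (
    DEFAULT_PROBE_RADIUS,
    SurfaceAreaRecord,
    atom_sasa,
    atomic_radii,
    classify_residue,
    classify_residues,
    compute_sasa,
    global_density,
    interface_atoms,
    interface_property_panel,
    relative_sa,
    stickiness_scale,
    stickiness_sum,
    surface_area_records,
    surface_complementarity,
    unit_sphere_points,
)
from abdock.structures import AtomRecord, ComplexModel, RigidTransform


def carbon(chain, num, xyz, name="CB"):
    return AtomRecord(chain, num, "", "ALA", name, "C", tuple(map(float, xyz)))


def slab_model(separation=3.8, n=6, spacing=1.9, rot=None, z0=0.0):
    """Two n x n carbon grids; the upper one optionally rotated about x."""
    atoms = []
    center = np.array([n * spacing / 2, n * spacing / 2, separation])
    k = 0
    for chain, z in (("H", z0), ("A", separation)):
        for i in range(n):
            for j in range(n):
                xyz = np.array([i * spacing, j * spacing, z])
                if chain == "A" and rot is not None:
                    xyz = rot @ (xyz - center) + center
                atoms.append(carbon(chain, k + 1, xyz))
                k += 1
    return ComplexModel(atoms, {"H": "heavy", "A": "antigen"}, "slabs")


class TestSasa:
    def test_isolated_atom_matches_sphere_area(self):
        a = [carbon("H", 1, (0, 0, 0))]
        r = atomic_radii()["C"] + DEFAULT_PROBE_RADIUS
        assert atom_sasa(a)[0] == pytest.approx(4 * np.pi * r**2, rel=1e-9)

    def test_far_separated_atoms_are_additive(self):
        atoms = [carbon("H", 1, (0, 0, 0)), carbon("H", 2, (50, 0, 0))]
        single = atom_sasa([atoms[0]])[0]
        assert atom_sasa(atoms).sum() == pytest.approx(2 * single, rel=1e-9)

    def test_two_overlapping_spheres_match_cap_formula(self):
        d = 3.0
        atoms = [carbon("H", 1, (0, 0, 0)), carbon("H", 2, (d, 0, 0))]
        r = atomic_radii()["C"] + DEFAULT_PROBE_RADIUS
        # equal spheres at distance d: each loses a cap of height h = r - d/2
        cap = 2 * np.pi * r * (r - d / 2)
        expected = 4 * np.pi * r**2 - cap
        got = atom_sasa(atoms)
        assert got[0] == pytest.approx(expected, rel=0.01)
        assert got[1] == pytest.approx(expected, rel=0.01)

    def test_agrees_with_independent_shrake_rupley(self, rng):
        biotite_struc = pytest.importorskip("biotite.structure")
        coords = rng.normal(scale=3.0, size=(20, 3))
        atoms = [carbon("H", i + 1, c) for i, c in enumerate(coords)]
        ours = atom_sasa(atoms, sphere_points=960)
        arr = biotite_struc.AtomArray(20)
        arr.coord = np.asarray(coords, dtype=np.float32)
        arr.chain_id[:] = "H"
        arr.res_id[:] = np.arange(1, 21)
        arr.res_name[:] = "ALA"
        arr.atom_name[:] = "CB"
        arr.element[:] = "C"
        theirs = biotite_struc.sasa(
            arr, probe_radius=DEFAULT_PROBE_RADIUS, point_number=960,
            vdw_radii=np.full(20, atomic_radii()["C"]),
        )
        assert ours.sum() == pytest.approx(theirs.sum(), rel=0.02)

    def test_translation_and_rotation_invariance(self, toy_native):
        base = sum(compute_sasa(toy_native).values())
        shifted = toy_native.transformed(
            RigidTransform(rotation=np.eye(3), translation=np.array([11.0, -7.0, 3.0]))
        )
        assert sum(compute_sasa(shifted).values()) == pytest.approx(base, rel=1e-6)
        rot = Rotation.from_euler("xyz", [25, 35, 45], degrees=True).as_matrix()
        rotated = toy_native.transformed(
            RigidTransform(rotation=rot, translation=np.zeros(3))
        )
        assert sum(compute_sasa(rotated).values()) == pytest.approx(base, rel=0.01)

    def test_unknown_element_rejected(self):
        bad = [AtomRecord("H", 1, "", "ALA", "XX", "Xx", (0.0, 0.0, 0.0))]
        with pytest.raises(TableError):
            atom_sasa(bad)

    def test_sphere_points_are_unit_and_deterministic(self):
        pts = unit_sphere_points(960)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
        assert np.array_equal(pts, unit_sphere_points(960))


class TestRelativeSa:
    @pytest.mark.parametrize("factor,expected", [(1.0, 100.0), (0.0, 0.0), (0.5, 50.0)])
    def test_fraction_of_reference(self, factor, expected):
        ref = {"ALA": 129.0}
        rsa = relative_sa({("H", 1, ""): 129.0 * factor}, {("H", 1, ""): "ALA"}, ref)
        assert rsa[("H", 1, "")] == pytest.approx(expected)

    def test_missing_reference_entry_rejected(self):
        with pytest.raises(TableError):
            relative_sa({("H", 1, ""): 5.0}, {("H", 1, ""): "UNK"}, {"ALA": 129.0})


class TestClassification:
    @pytest.mark.parametrize(
        "rsa_c,rsa_u,expected",
        [
            (10.0, 10.0, "interior"),
            (40.0, 40.0, "surface"),
            (40.0, 50.0, "rim"),
            (10.0, 50.0, "core"),
            (10.0, 20.0, "support"),
            (25.0, 25.0, "surface"),  # boundary tie rule
            (25.0, 30.0, "rim"),      # boundary tie rule under binding
        ],
    )
    def test_definitional_truth_table(self, rsa_c, rsa_u, expected):
        assert classify_residue(rsa_c, rsa_u, rsa_u - rsa_c) == expected

    @given(
        st.lists(
            st.tuples(st.floats(0, 120), st.floats(0, 120)), min_size=1, max_size=30
        )
    )
    def test_partition_property(self, pairs):
        records = [
            SurfaceAreaRecord(("H", i, ""), "ALA", min(c, u), max(c, u),
                              min(c, u), max(c, u))
            for i, (c, u) in enumerate(pairs)
        ]
        regions = classify_residues(records)
        changed = {r.residue_id for r in records if r.delta_rsa > 1e-6}
        iface = set(regions.interface_residues())
        assert iface == changed
        assert len(regions.support) + len(regions.rim) + len(regions.core) == len(iface)
        for rid, cls in regions.per_residue.items():
            if rid in changed:
                assert cls in ("support", "rim", "core")
            else:
                assert cls in ("interior", "surface")


class TestStickiness:
    def test_empty_region_sums_to_zero(self):
        assert stickiness_sum([]) == 0.0

    def test_single_residue(self):
        assert stickiness_sum(["PHE"]) == pytest.approx(stickiness_scale()["PHE"])

    def test_hand_summed_region(self):
        names = ["ALA", "TRP", "LYS", "LYS", "SER"]
        expected = 0.0062 + 0.7925 - 1.1806 - 1.1806 - 0.1376
        assert stickiness_sum(names) == pytest.approx(expected, abs=1e-9)

    def test_additive_over_disjoint_regions(self):
        a, b = ["ILE", "VAL"], ["ASP", "GLY", "HIS"]
        assert stickiness_sum(a + b) == pytest.approx(
            stickiness_sum(a) + stickiness_sum(b), abs=1e-12
        )

    def test_missing_residue_type(self):
        with pytest.raises(TableError):
            stickiness_sum(["XYZ"])
        with pytest.warns(UserWarning):
            assert stickiness_sum(["XYZ"], on_missing="skip") == 0.0


class TestInterfaceAtoms:
    def test_non_contacting_chains_have_empty_interface(self):
        atoms = [carbon("H", 1, (0, 0, 0)), carbon("A", 1, (60, 0, 0))]
        model = ComplexModel(atoms, {"H": "heavy", "A": "antigen"}, "far")
        assert interface_atoms(model) == []

    def test_contact_atom_detected(self):
        atoms = [
            carbon("H", 1, (0, 0, 0)),
            carbon("H", 2, (30, 0, 0)),
            carbon("A", 1, (3.6, 0, 0)),
        ]
        model = ComplexModel(atoms, {"H": "heavy", "A": "antigen"}, "dimer")
        idx = interface_atoms(model)
        assert 0 in idx and 2 in idx and 1 not in idx

    def test_matches_brute_force_sa_difference(self, toy_native):
        got = set(interface_atoms(toy_native))
        complexed = atom_sasa(toy_native.atoms)
        expected = set()
        offset = 0
        for role in (("heavy", "light"), ("antigen",)):
            side = toy_native.select_atoms(roles=role)
            side_sasa = atom_sasa(side)
            global_idx = [i for i, a in enumerate(toy_native.atoms) if a in side]
            for local, gi in enumerate(global_idx):
                if side_sasa[local] - complexed[gi] > 1e-6:
                    expected.add(gi)
            offset += len(side)
        assert got == expected

    def test_delta_rsa_never_negative(self, toy_native):
        records = surface_area_records(toy_native)
        assert all(r.delta_rsa >= 0.0 for r in records)


class TestGlobalDensity:
    def test_uniform_disk_matches_ellipse_convention(self, rng):
        n, radius = 4000, 10.0
        r = radius * np.sqrt(rng.uniform(size=n))
        th = rng.uniform(0, 2 * np.pi, n)
        pts = np.column_stack([r * np.cos(th), r * np.sin(th), np.zeros(n)])
        pts[:, 2] = rng.normal(scale=1e-3, size=n)  # break planar degeneracy
        expected = n / (np.pi * radius**2 * 5 / 4)
        assert global_density(pts) == pytest.approx(expected, rel=0.15)

    def test_scaling_law(self, rng):
        pts = rng.normal(size=(40, 3)) * (4, 2, 1)
        gd = global_density(pts)
        assert global_density(pts * 2.0) == pytest.approx(gd / 4.0, abs=1e-9)

    def test_rigid_invariance(self, rng):
        pts = rng.normal(size=(50, 3)) * (3, 2, 1)
        rot = Rotation.from_euler("xyz", [10, 60, 120], degrees=True).as_matrix()
        moved = pts @ rot.T + np.array([5.0, 6.0, 7.0])
        assert global_density(moved) == pytest.approx(global_density(pts), abs=1e-9)

    def test_collinear_rejected(self):
        pts = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(GeometryError):
            global_density(pts)

    def test_volume_convention_needs_thickness(self, rng):
        pts = rng.normal(size=(30, 3))
        assert global_density(pts, convention="ellipsoid-volume") > 0


class TestSurfaceComplementarity:
    def test_parallel_slabs_near_ideal(self):
        sc = surface_complementarity(slab_model())
        assert sc > 0.8

    def test_misaligned_normals_score_lower(self):
        parallel = surface_complementarity(slab_model())
        rot = Rotation.from_euler("x", 90, degrees=True).as_matrix()
        orthogonal = surface_complementarity(slab_model(separation=6.5, rot=rot))
        assert orthogonal < parallel

    def test_nested_shell_beats_tangent_slab(self):
        def ball(chain, n=80, radius=4.0, start=1):
            pts = unit_sphere_points(n) * radius
            return [carbon(chain, start + i, p) for i, p in enumerate(pts)]

        shell_pts = unit_sphere_points(160)
        cap = shell_pts[shell_pts[:, 2] > 0.2] * 7.8
        nested = ComplexModel(
            ball("H") + [carbon("A", i + 1, p) for i, p in enumerate(cap)],
            {"H": "heavy", "A": "antigen"},
            "nested",
        )
        flat = [
            carbon("A", k + 1, (1.9 * i - 5.7, 1.9 * j - 5.7, 7.8))
            for k, (i, j) in enumerate((i, j) for i in range(7) for j in range(7))
        ]
        tangent = ComplexModel(
            ball("H") + flat, {"H": "heavy", "A": "antigen"}, "tangent"
        )
        assert surface_complementarity(nested) > surface_complementarity(tangent)

    def test_rigid_invariance_within_quadrature(self, toy_native):
        base = surface_complementarity(toy_native)
        rot = Rotation.from_euler("xyz", [15, 25, 35], degrees=True).as_matrix()
        moved = toy_native.transformed(
            RigidTransform(rotation=rot, translation=np.array([3.0, 4.0, 5.0]))
        )
        assert surface_complementarity(moved) == pytest.approx(base, abs=0.05)

    def test_bounded(self, toy_native):
        sc = surface_complementarity(toy_native)
        assert -1.0 <= sc <= 1.0

    def test_no_interface_rejected(self):
        atoms = [carbon("H", 1, (0, 0, 0)), carbon("A", 1, (60, 0, 0))]
        model = ComplexModel(atoms, {"H": "heavy", "A": "antigen"}, "far")
        with pytest.raises(GeometryError):
            surface_complementarity(model)


class TestPanel:
    def test_region_sa_sums_to_total(self, toy_native):
        panel = interface_property_panel(toy_native)
        assert panel.sa_total == pytest.approx(
            sum(panel.sa_by_region.values()), abs=1e-9
        )
        assert panel.n_interface_residues > 0
        assert panel.global_density > 0

    def test_stickiness_consistent_with_regions(self, toy_native):
        panel = interface_property_panel(toy_native)
        # toy chains are poly-ALA, so stickiness = 0.0062 * residue count
        assert panel.stickiness_total == pytest.approx(
            0.0062 * panel.n_interface_residues, abs=1e-9
        )
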