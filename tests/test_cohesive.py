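"""Traction-separation laws and interface force assembly."""

import numpy as np
import pytest

from woundsim.cohesive import (
    CellCellCohesiveParams,
    CellSubstrateCohesiveParams,
    PairSet,
    assemble_cell_cell_forces,
    assemble_cell_substrate_forces,
    assemble_interface_forces,
    face_normals,
    pair_kinematics,
    refresh_pairs,
    traction_normal,
    traction_tangential,
)

CC = CellCellCohesiveParams()
CS = CellSubstrateCohesiveParams()


def random_cc_params(rng):
    d0 = rng.uniform(0.0, 0.05)
    dd = d0 + rng.uniform(0.1, 2.0)
    df = dd + rng.uniform(0.1, 2.0)
    ddt = rng.uniform(0.1, 2.0)
    dft = ddt + rng.uniform(0.1, 2.0)
    return CellCellCohesiveParams(
        sigma_cc=rng.uniform(10, 5000), tau_cc=rng.uniform(10, 5000),
        delta0=d0, delta_dn=dd, delta_fn=df, delta_dt=ddt, delta_ft=dft,
        qn=rng.uniform(0.5, 3), pn=rng.uniform(0.5, 3),
        qt=rng.uniform(0.5, 3), pt=rng.uniform(0.5, 3),
    )


class TestNormalLaw:
    @pytest.mark.parametrize(
        "d, expected",
        [
            (1.0, 2000.0),        # peak = σ at the critical separation
            (0.01, 0.0),          # zero crossing at the equilibrium separation
            (0.505, 1648.7212707001282),  # 2·0.5·e^0.5 nN/μm²
            (1.5, 1000.0),        # softening branch 2·((2−1.5)/(2−1))
            (2.0, 0.0),           # cutoff
            (5.0, 0.0),
        ],
    )
    def test_cell_cell_values(self, d, expected):
        assert traction_normal(CC, d) == pytest.approx(expected, abs=1e-9)

    def test_cell_substrate_peak_and_detachment(self):
        assert traction_normal(CS, 0.025) == pytest.approx(5.0)
        assert traction_normal(CS, 0.060) == 0.0
        assert traction_normal(CS, 0.001) == 0.0  # equilibrium at 1 nm

    def test_repulsive_below_equilibrium(self):
        d = np.linspace(-0.5, 0.009, 50)
        assert (traction_normal(CC, d) < 0).all()

    def test_branch_continuity_random_params(self):
        """Branch formulas agree at both breakpoints for 50 random laws."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            p = random_cc_params(rng)
            x = (p.delta_dn - p.delta0) / (p.delta_dn - p.delta0)
            rise_at_dd = p.sigma_cc * x * np.exp((1 - x) * p.qn)
            soft_at_dd = p.sigma_cc * 1.0**p.pn
            assert abs(rise_at_dd - soft_at_dd) < 1e-12 * p.sigma_cc
            assert abs(traction_normal(p, p.delta_dn) - p.sigma_cc) < 1e-12 * p.sigma_cc
            assert abs(traction_normal(p, p.delta_fn)) < 1e-12 * p.sigma_cc

    def test_peak_location_and_value_by_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            p = random_cc_params(rng)
            if p.qn > 1.01 or p.pn > 1.01:
                continue
            d = np.linspace(p.delta0, p.delta_fn, 200001)
            t = traction_normal(p, d)
            i = np.argmax(t)
            assert d[i] == pytest.approx(p.delta_dn, abs=2e-5 * p.delta_fn)
            assert t[i] == pytest.approx(p.sigma_cc, rel=1e-6)


class TestTangentialLaw:
    def test_peak_at_critical_slip(self):
        assert traction_tangential(CC, 1.0) == pytest.approx(2000.0)

    def test_gaussian_rise_value(self):
        # 2·0.5·e^0.375 nN/μm²
        assert traction_tangential(CC, 0.5) == pytest.approx(1454.9914146182014)

    def test_odd_symmetry(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(-3, 3, size=100)
        np.testing.assert_allclose(
            traction_tangential(CC, -d), -traction_tangential(CC, d), atol=1e-12)

    def test_cutoff(self):
        assert traction_tangential(CC, 2.0) == 0.0
        assert traction_tangential(CC, -2.5) == 0.0

    def test_branch_continuity_random_params(self):
        """Branch formulas agree at both breakpoints for 50 random laws."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            p = random_cc_params(rng)
            rise_at_dd = p.tau_cc * np.exp(
                (0.5 - p.delta_dt**2 / (2 * p.delta_dt**2)) * p.qt)
            soft_at_dd = p.tau_cc * 1.0**p.pt
            assert abs(rise_at_dd - soft_at_dd) < 1e-12 * p.tau_cc
            assert abs(traction_tangential(p, p.delta_dt) - p.tau_cc) < 1e-12 * p.tau_cc
            assert abs(traction_tangential(p, p.delta_ft)) < 1e-12 * p.tau_cc


class TestLawBounds:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.01, max_value=10.0, allow_nan=False))
    def test_normal_traction_bounded_by_strength_outside_penetration(self, d):
        t = traction_normal(CC, d)
        assert 0.0 <= t <= CC.sigma_cc * (1 + 1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(min_value=-10.0, max_value=10.0, allow_nan=False))
    def test_tangential_traction_bounded_by_strength(self, d):
        assert abs(traction_tangential(CC, d)) <= CC.tau_cc * (1 + 1e-12)


class TestPairKinematics:
    def test_initial_separation_is_junction_gap(self, quad_mesh):
        u = np.zeros((quad_mesh.n_nodes, 3))
        states = pair_kinematics(quad_mesh, u, quad_mesh.junction_face_pairs[0])
        assert len(states) == 6
        for s in states:
            assert s.d_n == pytest.approx(0.01, rel=1e-6)
            assert np.linalg.norm(s.d_t_vec) < 1e-10
            assert s.area_weight > 0

    def test_rigid_tangential_shift_reads_as_slip(self, quad_mesh):
        mesh = quad_mesh
        pair = mesh.junction_face_pairs[0]
        slave_cell = mesh.face_cell[
            pair[1] if mesh.face_cell[pair[0]] <= mesh.face_cell[pair[1]] else pair[0]]
        # shift the whole slave cell in-plane along the face direction
        quad = mesh.nodes[mesh.lateral_faces[pair[0]]]
        edge = quad[1] - quad[0]
        edge /= np.linalg.norm(edge)
        u = np.zeros((mesh.n_nodes, 3))
        sel = np.unique(mesh.elements[mesh.element_cell_id == slave_cell])
        u[sel] = 0.3 * edge
        states = pair_kinematics(mesh, u, pair)
        for s in states:
            assert np.linalg.norm(s.d_t_vec) == pytest.approx(0.3, rel=1e-6)
            assert s.d_n == pytest.approx(0.01, rel=1e-4)

    def test_separation_matches_point_to_plane_oracle(self, quad_mesh):
        """Under a random affine map (faces stay planar) the normal
        separation equals an independent point-to-plane computation."""
        mesh = quad_mesh
        rng = np.random.default_rng(5)
        A = np.eye(3) + rng.normal(scale=0.02, size=(3, 3))
        b = rng.normal(scale=0.5, size=3)
        u = mesh.nodes @ A.T + b - mesh.nodes
        pair = mesh.junction_face_pairs[1]
        ps = PairSet.from_faces(mesh, [pair[0]], [pair[1]])
        d_n, d_t, n_hat, qp = ps.kinematics(u)
        pos = mesh.nodes + u
        mquad = pos[mesh.lateral_faces[ps.master[0]]]
        n = np.cross(mquad[1] - mquad[0], mquad[3] - mquad[0])
        n /= np.linalg.norm(n)
        n *= np.sign(np.dot(face_normals(mquad[None])[0], n))
        for q in range(6):
            d_plane = np.dot(qp[0, q] - mquad[0], n)
            assert d_n[0, q] == pytest.approx(d_plane, abs=1e-10)

    def test_normals_of_paired_faces_oppose(self, small_mesh):
        u = np.zeros((small_mesh.n_nodes, 3))
        jp = small_mesh.junction_face_pairs
        qa = small_mesh.nodes[small_mesh.lateral_faces[jp[:, 0]]]
        qb = small_mesh.nodes[small_mesh.lateral_faces[jp[:, 1]]]
        dots = (face_normals(qa) * face_normals(qb)).sum(axis=1)
        assert (dots < -np.cos(np.radians(1.0))).all()


class TestAssembly:
    def test_equilibrium_configuration_is_force_free(self, small_mesh):
        u = np.zeros((small_mesh.n_nodes, 3))
        f_cc, f_cs = assemble_interface_forces(small_mesh, u, CC, CS)
        peak_scale = CC.sigma_cc * 100.0  # peak traction × face-area scale
        assert np.abs(f_cc).max() < 1e-9 * peak_scale
        assert np.abs(f_cs).max() < 1e-12

    def test_single_pair_peak_pull_matches_traction_times_area(self, quad_mesh):
        mesh = quad_mesh
        pair = mesh.junction_face_pairs[0]
        ps = PairSet.from_faces(mesh, [pair[0]], [pair[1]])
        mquad = mesh.nodes[mesh.lateral_faces[ps.master[0]]]
        n = face_normals(mquad[None])[0]
        squad_nodes = mesh.lateral_faces[ps.slave[0]]
        u = np.zeros((mesh.n_nodes, 3))
        u[squad_nodes] = (CC.delta_dn - 0.01) * n
        f = assemble_cell_cell_forces(mesh, ps, u, CC)
        area = 30.0 * 10.0  # face edge length × thickness (μm²)
        pull = f[squad_nodes].sum(axis=0)
        # net pull on the slave face: −σ·A along the master normal
        np.testing.assert_allclose(pull, -CC.sigma_cc * area * n, rtol=1e-3)
        # equal and opposite on the master side
        np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-8 * CC.sigma_cc * area)

    def test_newtons_third_law_random_state(self, small_mesh):
        rng = np.random.default_rng(11)
        u = rng.normal(scale=0.05, size=(small_mesh.n_nodes, 3))
        pairs = PairSet.initial(small_mesh)
        f = assemble_cell_cell_forces(small_mesh, pairs, u, CC)
        scale = np.abs(f).max()
        assert np.abs(f.sum(axis=0)).max() < 1e-10 * max(scale, 1.0)

    def test_frame_invariance_of_pair_forces(self, quad_mesh):
        mesh = quad_mesh
        pair = mesh.junction_face_pairs[0]
        ps = PairSet.from_faces(mesh, [pair[0]], [pair[1]])
        rng = np.random.default_rng(2)
        u = rng.normal(scale=0.02, size=(mesh.n_nodes, 3))
        f = assemble_cell_cell_forces(mesh, ps, u, CC)

        th = 0.7
        R = np.array([
            [np.cos(th), -np.sin(th), 0.0],
            [np.sin(th), np.cos(th), 0.0],
            [0.0, 0.0, 1.0],
        ])
        # rotate the whole deformed configuration about the origin
        u_rot = (mesh.nodes + u) @ R.T - mesh.nodes
        f_rot = assemble_cell_cell_forces(mesh, ps, u_rot, CC)
        np.testing.assert_allclose(f_rot, f @ R.T, atol=1e-10 * np.abs(f).max())

    def test_substrate_holds_monolayer_at_standoff(self, small_mesh):
        # push the monolayer down: repulsion; lift it: attraction
        u = np.zeros((small_mesh.n_nodes, 3))
        u[:, 2] = -0.0005
        f_down = assemble_cell_substrate_forces(small_mesh, u, CS)
        assert f_down[:, 2].sum() > 0  # pushed back up
        u[:, 2] = +0.01
        f_up = assemble_cell_substrate_forces(small_mesh, u, CS)
        assert f_up[:, 2].sum() < 0  # pulled back down
        assert np.abs(f_up[:, :2]).max() == 0.0  # flat rigid plane: no shear


class TestRefresh:
    def test_initial_geometry_recovers_constructor_pairs(self, quad_mesh):
        u = np.zeros((quad_mesh.n_nodes, 3))
        initial = PairSet.initial(quad_mesh)
        refreshed = refresh_pairs(quad_mesh, u, cutoff=CC.delta_fn)
        assert refreshed.key_set == initial.key_set

    def test_refresh_keeps_all_ridge_pairs_and_adds_only_near_contacts(self, small_mesh):
        """On irregular tessellations the proximity search recovers every
        ridge pair; extras (from short-edge merging) must genuinely lie
        within the cohesive cutoff."""
        from woundsim.cohesive import _face_qp_distance

        u = np.zeros((small_mesh.n_nodes, 3))
        initial = PairSet.initial(small_mesh)
        refreshed = refresh_pairs(small_mesh, u, cutoff=CC.delta_fn)
        assert refreshed.key_set >= initial.key_set
        for m, s in refreshed.key_set - initial.key_set:
            qa = small_mesh.nodes[small_mesh.lateral_faces[m]][None]
            qb = small_mesh.nodes[small_mesh.lateral_faces[s]][None]
            assert _face_qp_distance(qa, qb)[0] < CC.delta_fn

    def test_separated_faces_lose_their_pair(self, quad_mesh):
        mesh = quad_mesh
        pairs = PairSet.initial(mesh)
        cell = mesh.face_cell[pairs.slave[0]]
        u = np.zeros((mesh.n_nodes, 3))
        sel = np.unique(mesh.elements[mesh.element_cell_id == cell])
        u[sel, 2] = 50.0  # lift one cell far above the sheet
        refreshed = refresh_pairs(mesh, u, cutoff=CC.delta_fn, pairs=pairs)
        assert len(refreshed) < len(pairs)

    def test_pair_list_independent_of_cell_ordering(self, quad_spec):
        import itertools

        from woundsim.geometry import build_voronoi_monolayer, extrude_to_wedges

        seeds = np.array([[15.0, 15.0], [45.0, 15.0], [15.0, 45.0], [45.0, 45.0]])
        reference = None
        for perm in itertools.islice(itertools.permutations(range(4)), 4):
            geom = build_voronoi_monolayer(quad_spec, seeds[list(perm)])
            mesh = extrude_to_wedges(geom, z0=1e-3)
            u = np.zeros((mesh.n_nodes, 3))
            ps = refresh_pairs(mesh, u, cutoff=CC.delta_fn)
            # canonicalise: set of unordered seed-position pairs
            def seedpos(face):
                c = mesh.face_cell[face]
                return tuple(np.round(geom.seeds[c], 6))
            keys = frozenset(
                frozenset((seedpos(m), seedpos(s)))
                for m, s in zip(ps.master, ps.slave)
            )
            if reference is None:
                reference = keys
            else:
                assert keys == reference
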