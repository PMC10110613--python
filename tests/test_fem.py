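"""Wedge-element mechanics and the damped explicit integrator."""

import numpy as np
import pytest

from woundsim.fem import (
    DivergenceError,
    ElasticMaterial,
    InvertedElementError,
    SimulationState,
    explicit_step,
    internal_force,
    lumped_mass,
    precompute,
    shape_functions,
    stable_dt,
    strain_energy,
    wedge_shape,
)

MAT = ElasticMaterial()


class TestShapeFunctions:
    @pytest.mark.parametrize("local", [
        (0.2, 0.3, 0.4), (0.0, 0.0, 0.0), (1 / 3, 1 / 3, 0.5), (0.1, 0.8, 1.0),
    ])
    def test_partition_of_unity(self, local):
        n, _ = shape_functions(np.array(local))
        assert n.sum() == pytest.approx(1.0, abs=1e-14)

    def test_kronecker_delta_at_nodes(self):
        ref = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 0, 1), (0, 1, 1)]
        for a, local in enumerate(ref):
            n, _ = shape_functions(np.array(local, dtype=float))
            expected = np.zeros(6)
            expected[a] = 1.0
            np.testing.assert_allclose(n, expected, atol=1e-14)

    def test_linear_field_reproduced(self, unit_wedge):
        rng = np.random.default_rng(1)
        coef = rng.normal(size=4)
        nodal = coef[0] + unit_wedge.nodes @ coef[1:]
        for _ in range(20):
            loc = rng.uniform(0, 1, 3)
            if loc[0] + loc[1] > 1:
                loc[:2] = 1 - loc[:2]
            n, grad, det = wedge_shape(unit_wedge.nodes[unit_wedge.elements[0]], loc)
            x = n @ unit_wedge.nodes
            assert n @ nodal == pytest.approx(coef[0] + x @ coef[1:], abs=1e-12)
            np.testing.assert_allclose(grad.T @ nodal, coef[1:], atol=1e-12)

    def test_inverted_element_detected(self, unit_wedge):
        bad = unit_wedge.nodes.copy()
        bad[3:, 2] = -1.0  # top below bottom
        with pytest.raises(InvertedElementError):
            wedge_shape(bad[unit_wedge.elements[0]], np.array([0.2, 0.2, 0.5]),
                        element_id=0)


class TestInternalForce:
    def test_reference_state_is_stress_free(self, unit_wedge):
        f = internal_force(unit_wedge, np.zeros((6, 3)), MAT)
        assert np.abs(f).max() == 0.0

    def test_objectivity_under_rigid_motion(self, unit_wedge):
        th = 0.4
        R = np.array([
            [np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        u = unit_wedge.nodes @ R.T + np.array([0.3, -0.2, 0.9]) - unit_wedge.nodes
        f = internal_force(unit_wedge, u, MAT)
        assert np.abs(f).max() < 1e-9 * MAT.E * 1.0

    def test_matches_energy_gradient(self, quad_mesh):
        """F_int equals the central finite difference of the strain energy."""
        pc = precompute(quad_mesh)
        rng = np.random.default_rng(0)
        sel = rng.choice(quad_mesh.n_nodes, size=12, replace=False)
        u = rng.normal(scale=0.02, size=(quad_mesh.n_nodes, 3))
        f = internal_force(quad_mesh, u, MAT, pc)
        eps = 1e-5
        for a in sel:
            for k in range(3):
                up, um = u.copy(), u.copy()
                up[a, k] += eps
                um[a, k] -= eps
                g = (strain_energy(quad_mesh, up, MAT, pc)
                     - strain_energy(quad_mesh, um, MAT, pc)) / (2 * eps)
                assert f[a, k] == pytest.approx(g, rel=1e-6, abs=1e-8)

    def test_inversion_raises_with_element_id(self, unit_wedge):
        u = np.zeros((6, 3))
        u[3:, 2] = -2.0
        with pytest.raises(InvertedElementError):
            internal_force(unit_wedge, u, MAT)


class TestLumpedMass:
    def test_total_mass_is_density_times_volume(self, unit_wedge):
        m = lumped_mass(unit_wedge, MAT)
        assert m.sum() == pytest.approx(MAT.density * 0.5, rel=1e-12)
        assert (m > 0).all()

    def test_mass_additivity_over_layers(self, quad_geom):
        from woundsim.geometry import extrude_to_wedges

        m1 = lumped_mass(extrude_to_wedges(quad_geom, n_layers=1), MAT)
        m2 = lumped_mass(extrude_to_wedges(quad_geom, n_layers=2), MAT)
        assert m2.sum() == pytest.approx(m1.sum(), rel=1e-12)

    def test_mass_independent_of_node_ordering(self, unit_wedge):
        from tests.conftest import MiniMesh

        perm = [1, 2, 0, 4, 5, 3]  # cyclic renumbering of the same wedge
        mesh2 = MiniMesh(unit_wedge.nodes[perm],
                         [[perm.index(i) for i in range(6)]])
        m1 = lumped_mass(unit_wedge, MAT)
        m2 = lumped_mass(mesh2, MAT)
        np.testing.assert_allclose(np.sort(m1), np.sort(m2), rtol=1e-12)


class TestStableDt:
    def test_edge_halving_halves_dt(self, unit_wedge):
        from tests.conftest import MiniMesh

        half = MiniMesh(unit_wedge.nodes * 0.5, unit_wedge.elements)
        assert stable_dt(half, MAT) == pytest.approx(0.5 * stable_dt(unit_wedge, MAT))

    def test_density_scaling(self, unit_wedge):
        heavy = ElasticMaterial(density=4 * MAT.density)
        assert stable_dt(unit_wedge, heavy) == pytest.approx(
            2.0 * stable_dt(unit_wedge, MAT))

    def test_value_matches_hand_computed_wave_speed(self, unit_wedge):
        lam, mu = MAT.lame
        c_d = np.sqrt((lam + 2 * mu) / MAT.density)
        # shortest edge of the unit wedge is 1
        assert stable_dt(unit_wedge, MAT, safety=1.0) == pytest.approx(
            1.0 / c_d, rel=1e-12)


class TestExplicitStep:
    def test_quiescent_state_stays_quiescent(self):
        st = SimulationState.zeros(3, np.ones(3))
        explicit_step(st, np.zeros((3, 3)), np.zeros((3, 3)), dt=0.1)
        assert np.abs(st.u).max() == 0.0
        assert np.abs(st.v).max() == 0.0

    def test_ballistic_closed_form(self):
        m, F, dt = 2.0, 1.5, 0.05
        st = SimulationState.zeros(1, np.array([m]))
        f = np.array([[F, 0.0, 0.0]])
        for _ in range(200):
            explicit_step(st, f, np.zeros((1, 3)), dt)
        assert st.u[0, 0] == pytest.approx(0.5 * (F / m) * st.t**2, abs=1e-10)

    def test_terminal_velocity_under_damping(self):
        m, F, c, dt = 2.0, 1.0, 0.5, 0.05
        st = SimulationState.zeros(1, np.array([m]))
        f = np.array([[F, 0.0, 0.0]])
        for _ in range(4000):
            explicit_step(st, f, np.zeros((1, 3)), dt, damping=c)
        assert st.v[0, 0] == pytest.approx(F / (c * m), rel=1e-9)

    def test_divergence_reported(self):
        st = SimulationState.zeros(1, np.array([1.0]))
        st.u[0, 0] = np.nan
        with pytest.raises(DivergenceError):
            explicit_step(st, np.ones((1, 3)), np.zeros((1, 3)), dt=0.1)

    def test_fixed_mask_pins_dofs(self):
        st = SimulationState.zeros(2, np.ones(2))
        f = np.ones((2, 3))
        mask = np.zeros((2, 3), dtype=bool)
        mask[0] = True
        for _ in range(10):
            explicit_step(st, f, np.zeros((2, 3)), dt=0.1, fixed_mask=mask)
        assert np.abs(st.u[0]).max() == 0.0
        assert np.abs(st.u[1]).min() > 0.0


class TestConservation:
    def test_momentum_conserved_without_external_forces(self, quad_mesh):
        """Internal + cohesive forces alone preserve linear momentum."""
        from woundsim.cohesive import CellCellCohesiveParams, PairSet, \
            assemble_cell_cell_forces

        pc = precompute(quad_mesh)
        mass = lumped_mass(quad_mesh, MAT, pc)
        st = SimulationState.zeros(quad_mesh.n_nodes, mass)
        rng = np.random.default_rng(4)
        st.v = rng.normal(scale=0.5, size=st.v.shape)
        p0 = (mass[:, None] * st.v).sum(axis=0)
        dt = stable_dt(quad_mesh, MAT, 0.3)
        pairs = PairSet.initial(quad_mesh)
        cc = CellCellCohesiveParams()
        for _ in range(1000):
            f_int = internal_force(quad_mesh, st, MAT, pc, check=False)
            f_cc = assemble_cell_cell_forces(quad_mesh, pairs, st.u, cc)
            explicit_step(st, f_cc, f_int, dt)
        p1 = (mass[:, None] * st.v).sum(axis=0)
        assert np.abs(p1 - p0).max() < 1e-10 * np.abs(p0).max()

    def test_energy_drift_small_in_undamped_vibration(self, unit_wedge):
        """The leapfrog shadow energy — strain energy at the full step with
        the product of adjacent half-step velocities — shows no secular
        drift over 10⁴ stable steps."""
        pc = precompute(unit_wedge)
        mass = lumped_mass(unit_wedge, MAT, pc)
        st = SimulationState.zeros(unit_wedge.n_nodes, mass)
        rng = np.random.default_rng(9)
        st.u = rng.normal(scale=0.01, size=st.u.shape)
        dt = stable_dt(unit_wedge, MAT, 0.1)
        energies = []
        v_prev = st.v.copy()
        for _ in range(10000):
            pe = strain_energy(unit_wedge, st.u, MAT, pc)
            f_int = internal_force(unit_wedge, st, MAT, pc, check=False)
            explicit_step(st, np.zeros_like(f_int), f_int, dt)
            ke = 0.5 * (mass[:, None] * v_prev * st.v).sum()
            energies.append(pe + ke)
            v_prev = st.v.copy()
        energies = np.array(energies[1:])
        assert np.abs(energies - energies[0]).max() < 0.01 * energies[0]


class TestPatchTest:
    def test_uniaxial_patch_recovers_modulus_and_poisson(self):
        """A hexagonal cell under uniaxial dead load relaxes to a state whose
        conjugate stress/strain ratio is E and lateral contraction ν."""
        from woundsim.verification import uniaxial_patch_test

        result = uniaxial_patch_test(MAT, strain_target=0.01)
        assert result["modulus_kpa"] == pytest.approx(
            MAT.youngs_modulus, rel=0.005)
        assert result["poisson"] == pytest.approx(MAT.poisson_ratio, rel=0.005)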