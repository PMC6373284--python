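"""Immersed-boundary core: kernel identities, projection, motility, adjust."""

import math

import numpy as np
import pytest

from veinadapt.geometry import (INTIMA, LUMEN, MEDIA, CellAgent, ECMField,
                                MembraneCurve, SimulationGrid,
                                build_basic_geometry, seed_cells)
from veinadapt.mechanics import FieldSet, lame_annulus_energy
from veinadapt.params import MechanicsParams, RemodelingParams
from veinadapt.plasticity import (APOPTOSIS, ECM_PRODUCTION, MITOSIS, Event,
                                  EventBatch)
from veinadapt.remodeling import (IBMState, StokesSolver,
                                  active_velocities, advect_membranes,
                                  assemble_mass_sources, ibm_substep,
                                  inward_outward_adjust, interp_from_grid,
                                  membrane_forces, peskin_delta_weights,
                                  relax_tissue, smc_velocity,
                                  spread_membrane_forces, spread_to_grid,
                                  v_chemotaxis, v_matrix_invasion,
                                  v_random, v_repulsion)

R_SMC = 0.006


@pytest.fixture(scope="module")
def grid():
    return SimulationGrid.enclosing(0.3, 0.0075)


@pytest.fixture(scope="module")
def solver(grid):
    return StokesSolver(grid, RemodelingParams())


class TestDeltaKernel:
    def test_partition_of_unity_at_arbitrary_points(self, grid, rng):
        # sum over the grid of delta_h * h^2 = 1, to machine precision
        pts = rng.uniform(-0.2, 0.2, size=(50, 2))
        _, _, w = peskin_delta_weights(pts, grid.origin[0], grid.origin[1],
                                       grid.h, grid.nx, grid.ny)
        assert np.allclose(w.sum(axis=(1, 2)), 1.0, atol=1e-12)

    def test_spread_conserves_total_force(self, grid, rng):
        pts = rng.uniform(-0.2, 0.2, size=(30, 2))
        F = rng.standard_normal(30)
        fld = spread_to_grid(pts, F, grid.origin[0], grid.origin[1], grid.h,
                             (grid.ny, grid.nx))
        assert fld.sum() * grid.h ** 2 == pytest.approx(F.sum(), abs=1e-12)

    def test_spreading_interpolation_adjoint(self, grid, rng):
        # sum_grid (spread F) . u h^2 == sum_points F . (interp u)
        pts = rng.uniform(-0.25, 0.25, size=(40, 2))
        F = rng.standard_normal(40)
        u = rng.standard_normal((grid.ny, grid.nx))
        fld = spread_to_grid(pts, F, grid.origin[0], grid.origin[1], grid.h,
                             u.shape)
        lhs = float(np.sum(fld * u)) * grid.h ** 2
        rhs = float(np.sum(F * interp_from_grid(u, pts, grid.origin[0],
                                                grid.origin[1], grid.h)))
        assert abs(lhs - rhs) < 1e-12 * max(1.0, abs(lhs))


class TestMembraneForces:
    def test_rest_membrane_exerts_no_force(self, grid):
        m = MembraneCurve.circle(0.2, grid.h, stiffness=0.5)
        assert np.allclose(membrane_forces(m), 0.0)
        f_u, f_v = spread_membrane_forces([m], grid)
        assert not f_u.any() and not f_v.any()

    def test_stretched_circle_pulls_radially_inward(self, grid):
        m = MembraneCurve.circle(0.2, grid.h, stiffness=0.5)
        m.rest_lengths = m.rest_lengths * 0.9      # uniformly stretched by 1/0.9
        F = membrane_forces(m)
        assert np.allclose(F.sum(axis=0), 0.0, atol=1e-12)   # net zero
        radial = np.einsum("ij,ij->i", F, m.points)
        assert np.all(radial < 0)                  # all pointing inward


class TestProjection:
    def test_gradient_fields_are_annihilated(self, grid, solver, rng):
        phi = rng.standard_normal((grid.ny, grid.nx))
        st = IBMState.zeros(grid)
        st.u[:, 1:-1] = (phi[:, 1:] - phi[:, :-1]) / grid.h
        st.v[1:-1, :] = (phi[1:, :] - phi[:-1, :]) / grid.h
        p = RemodelingParams()
        st2 = ibm_substep(st, (np.zeros_like(st.u), np.zeros_like(st.v)),
                          p, solver)
        div = solver.divergence(st2.u, st2.v)
        assert np.abs(div).max() < 1e-7 * max(np.abs(phi).max() / grid.h ** 2, 1.0)

    def test_divergence_free_field_passes_through(self, grid, solver):
        # a solenoidal field with no sources projects onto itself
        st = IBMState.zeros(grid)
        psi = np.fromfunction(
            lambda j, i: np.sin(2 * np.pi * i / grid.nx)
            * np.sin(2 * np.pi * j / grid.ny), (grid.ny + 1, grid.nx + 1))
        st.u = (psi[1:, :] - psi[:-1, :]) / grid.h
        st.v = -(psi[:, 1:] - psi[:, :-1]) / grid.h
        st.u[:, 0] = st.u[:, -1] = 0.0
        st.v[0, :] = st.v[-1, :] = 0.0
        div0 = solver.divergence(st.u, st.v)
        p = RemodelingParams(mu_tissue=1e-9)   # negligible diffusion step
        st2 = ibm_substep(st, (np.zeros_like(st.u), np.zeros_like(st.v)),
                          p, StokesSolver(grid, p))
        div = solver.divergence(st2.u, st2.v)
        assert np.abs(div - div0).max() < 1e-8 * max(np.abs(st.u).max(), 1.0)

    def test_point_source_radial_outflow(self, grid, solver):
        st = IBMState.zeros(grid)
        jc, ic = grid.ny // 2, grid.nx // 2
        st.source_density[jc, ic] = 1.0
        st.source_density -= st.source_density.mean()   # closed-box balance
        p = RemodelingParams()
        st2 = ibm_substep(st, (np.zeros_like(st.u), np.zeros_like(st.v)),
                          p, solver)
        div = solver.divergence(st2.u, st2.v)
        assert np.abs(div - st.source_density).max() < 1e-8
        # outflow through faces around the source cell
        assert st2.u[jc, ic + 1] > 0 and st2.u[jc, ic] < 0
        assert st2.v[jc + 1, ic] > 0 and st2.v[jc, ic] < 0


class TestMassSources:
    def test_empty_batch_zero_field(self, grid):
        s = assemble_mass_sources(EventBatch([]), grid, RemodelingParams(),
                                  R_SMC, 0.003)
        assert not s.any()

    def test_mitosis_and_apoptosis_cancel(self, grid):
        loc = (0.1, 0.05)
        b = EventBatch([Event(MITOSIS, loc), Event(APOPTOSIS, loc)])
        s = assemble_mass_sources(b, grid, RemodelingParams(), R_SMC, 0.003)
        assert np.allclose(s, 0.0)

    def test_source_integral_bookkeeping(self, grid, rng):
        p = RemodelingParams()
        kinds = [MITOSIS, APOPTOSIS, ECM_PRODUCTION]
        events = [Event(k, tuple(rng.uniform(-0.2, 0.2, 2)))
                  for k in rng.choice(kinds, size=20)]
        for e in events:
            if e.kind == ECM_PRODUCTION:
                e.cell_index = (0, 0)
        b = EventBatch(events)
        s = assemble_mass_sources(b, grid, p, R_SMC, 0.003)
        expected = (b.net_smc_area(R_SMC) + b.net_ecm_area(0.003))
        assert s.sum() * grid.h ** 2 * p.delta_t == pytest.approx(expected, rel=1e-12)


class TestAdvection:
    def test_zero_velocity_leaves_membranes(self, grid, solver):
        m = MembraneCurve.circle(0.2, grid.h)
        st = IBMState.zeros(grid)
        out = advect_membranes([m], st, solver, 0.1)
        assert np.allclose(out[0].points, m.points)

    def test_uniform_translation(self, grid, solver):
        m = MembraneCurve.circle(0.1, grid.h)
        st = IBMState.zeros(grid)
        st.u[:, :] = 0.01
        out = advect_membranes([m], st, solver, 0.5)
        interior = np.all(np.abs(m.points) < 0.25, axis=1)
        shift = out[0].points[interior] - m.points[interior]
        assert np.allclose(shift[:, 0], 0.005, atol=1e-9)
        assert np.allclose(shift[:, 1], 0.0, atol=1e-9)


class TestMotilityPotentials:
    def agent(self, x=0.0, y=0.0, layer=INTIMA):
        return CellAgent(0, (x, y), R_SMC, layer, 0.0, 0.0)

    def nb(self, x, y, layer=INTIMA, i=1):
        return CellAgent(i, (x, y), R_SMC, layer, 0.0, 0.0)

    def test_repulsion_linear_profile(self, remod_params):
        a = self.agent()
        cutoff = 2 * remod_params.n_s * R_SMC
        at_cutoff = v_repulsion(a, [self.nb(cutoff, 0.0)], remod_params)
        assert np.allclose(at_cutoff, 0.0)
        near = v_repulsion(a, [self.nb(1e-9, 0.0)], remod_params)
        assert np.linalg.norm(near) == pytest.approx(remod_params.k_S, rel=1e-3)
        half = v_repulsion(a, [self.nb(remod_params.n_s * R_SMC, 0.0)],
                           remod_params)
        assert np.linalg.norm(half) == pytest.approx(remod_params.k_S / 2, rel=1e-9)
        assert half[0] < 0    # pushed away from the neighbor

    def test_repulsion_pair_antiparallel(self, remod_params):
        d = R_SMC  # closer than the cutoff
        a, b = self.agent(0, 0), self.nb(d, 0.0)
        va = v_repulsion(a, [b], remod_params)
        vb = v_repulsion(b, [a], remod_params)
        assert np.allclose(va, -vb)
        assert va[0] < 0 < vb[0]

    def test_invasion_isotropic_neighborhood_cancels(self, grid, remod_params):
        ecm = ECMField(np.ones((grid.ny, grid.nx)), 0.003)
        occupied = np.zeros((grid.ny, grid.nx), dtype=bool)
        v = v_matrix_invasion(self.agent(), ecm, occupied, grid, remod_params)
        assert np.linalg.norm(v) < remod_params.k_E * 1.0   # ~cancels

    def test_invasion_one_sided_attracts(self, grid, remod_params):
        dens = np.zeros((grid.ny, grid.nx))
        dens[:, grid.nx // 2 + 1:] = 1.0     # ECM only to the right of center
        ecm = ECMField(dens, 0.003)
        occupied = np.zeros_like(dens, dtype=bool)
        v = v_matrix_invasion(self.agent(0.0, 0.0), ecm, occupied, grid,
                              remod_params)
        assert v[0] > 0 and abs(v[1]) < 0.2 * v[0]

    def test_invasion_range_is_2_ne_radii(self, grid):
        p = RemodelingParams(n_e=3)
        dens = np.zeros((grid.ny, grid.nx))
        # single ECM cell just beyond the cutoff 6 R_SMC = 0.036
        i = int(round((0.04 - grid.origin[0]) / grid.h))
        j = int(round((0.0 - grid.origin[1]) / grid.h))
        dens[j, i] = 1.0
        ecm = ECMField(dens, 0.003)
        occupied = np.zeros_like(dens, dtype=bool)
        v = v_matrix_invasion(self.agent(0.0, 0.0), ecm, occupied, grid, p)
        assert np.allclose(v, 0.0)

    def test_chemotaxis_follows_gradient_linearly(self, grid):
        X, Y = grid.cell_centers()
        G = 3.0 * X
        gy, gx = np.gradient(G, grid.h)
        p1 = RemodelingParams(k_G=0.001)
        p2 = RemodelingParams(k_G=0.002)
        v1 = v_chemotaxis(self.agent(), (gx, gy), grid, p1)
        v2 = v_chemotaxis(self.agent(), (gx, gy), grid, p2)
        assert v1[0] == pytest.approx(0.003, rel=1e-6)
        assert np.allclose(v2, 2 * v1)
        flat = v_chemotaxis(self.agent(), (np.zeros_like(G), np.zeros_like(G)),
                            grid, p1)
        assert np.allclose(flat, 0.0)

    def test_random_motility_bounded_and_isotropic(self, remod_params, rng):
        draws = np.array([v_random(rng, remod_params, R_SMC)
                          for _ in range(10_000)])
        speeds = np.linalg.norm(draws, axis=1)
        assert np.all(speeds * remod_params.delta_t <= R_SMC + 1e-15)
        mean = draws.mean(axis=0)
        sigma = speeds.std() / math.sqrt(len(draws))
        assert np.all(np.abs(mean) < 3 * sigma + 1e-4 * R_SMC)

    def test_random_stream_reproducible(self, remod_params):
        a = v_random(np.random.default_rng(4), remod_params, R_SMC)
        b = v_random(np.random.default_rng(4), remod_params, R_SMC)
        assert np.allclose(a, b)

    def test_isolated_agent_flat_fields_no_active_motion(self, grid,
                                                         remod_params):
        ecm = ECMField(np.ones((grid.ny, grid.nx)), 0.003)
        G = np.zeros((grid.ny, grid.nx))
        v = smc_velocity(self.agent(), [], ecm, G, np.random.default_rng(0),
                         remod_params, grid,
                         toggles={"repulsion", "chemotaxis"})
        assert np.allclose(v, 0.0)


class TestInwardOutwardAdjust:
    def test_zero_magnitude_or_no_net_gives_zero(self, vessel, mech_params):
        p0 = RemodelingParams(adjust_magnitude=0.0)
        assert inward_outward_adjust(vessel, mech_params, p0, 1e-4) == 0.0
        p1 = RemodelingParams()
        assert inward_outward_adjust(vessel, mech_params, p1, 0.0) == 0.0

    def test_pressurized_wall_prefers_inward_growth(self, vessel, mech_params):
        # oracle: the Lamé energy of the inward-thickened trial is lower
        p = RemodelingParams()
        net = 1e-4
        term = inward_outward_adjust(vessel, mech_params, p, net)
        a_l, a_w = vessel.lumen_area(), vessel.wall_area()
        probe = math.pi * (0.5 * vessel.grid.h) ** 2 + net

        def energy(al):
            a = math.sqrt(al / math.pi)
            b = math.sqrt((al + a_w + net) / math.pi)
            return lame_annulus_energy(a, b, mech_params.p_internal,
                                       mech_params.p_external,
                                       mech_params.E, mech_params.nu)
        assert energy(a_l - probe) < energy(a_l)      # inward lowers energy
        assert term == pytest.approx(-net)

    def test_regression_reopens_lumen_under_inward_mode(self, vessel,
                                                        mech_params):
        # wall loss accommodated on the lumen side appears as a positive term
        p = RemodelingParams()
        term = inward_outward_adjust(vessel, mech_params, p, -1e-4)
        assert term == pytest.approx(1e-4)


class TestRelaxTissue:
    @pytest.fixture()
    def world(self):
        sec = build_basic_geometry(0.24, 0.28, 0.30, h=0.0075,
                                   membrane_stiffness=0.02)
        pop, ecm = seed_cells(sec, 0.25, rng_seed=5)
        shape = sec.region_mask.shape
        fields = FieldSet(np.zeros(shape),
                          np.zeros(len(sec.lumen_wall.points)),
                          np.full(shape, 1.0), np.zeros(shape),
                          sec.lumen_wall.copy())
        return sec, pop, ecm, fields

    def test_quiet_cycle_is_a_fixed_point(self, world, mech_params):
        sec, pop, ecm, fields = world
        p = RemodelingParams(k_S=0, k_E=0, k_G=0, random_motility=0)
        pos0 = pop.pos.copy()
        mem0 = sec.lumen_wall.points.copy()
        relax_tissue(sec, pop, ecm, EventBatch([]), fields, mech_params, p,
                     np.random.default_rng(0))
        assert np.allclose(pop.pos, pos0, atol=1e-12)
        assert np.allclose(sec.lumen_wall.points, mem0, atol=1e-12)

    def test_single_mitosis_grows_wall_by_element_area(self, world,
                                                       mech_params):
        sec, pop, ecm, fields = world
        p = RemodelingParams(k_S=0, k_E=0, k_G=0, random_motility=0)
        A0 = sec.wall_area()
        n0 = len(pop)
        i = int(np.nonzero(pop.layer == INTIMA)[0][0])
        batch = EventBatch([Event(MITOSIS, tuple(pop.pos[i]),
                                  agent_id=int(pop.ids[i]))])
        relax_tissue(sec, pop, ecm, batch, fields, mech_params, p,
                     np.random.default_rng(0))
        assert len(pop) == n0 + 1
        grown = sec.wall_area() - A0
        assert grown == pytest.approx(math.pi * pop.radius ** 2, rel=0.05)

    def test_agents_never_leave_the_wall(self, world, mech_params):
        sec, pop, ecm, fields = world
        p = RemodelingParams(random_motility=3.0)    # vigorous random motion
        rng = np.random.default_rng(1)
        for _ in range(5):
            relax_tissue(sec, pop, ecm, EventBatch([]), fields, mech_params,
                         p, rng)
        labels = sec.layer_of(pop.pos)
        assert np.all((labels == INTIMA) | (labels == MEDIA))
        assert np.array_equal(labels, pop.layer)

    def test_longer_relaxation_lowers_elastic_energy(self, mech_params):
        # a wavy lumen membrane relaxes toward the circle (area-preserving
        # shape relaxation): the longer delta_t runs, the lower the final
        # spring energy — "the more cylindrical the graft"
        from veinadapt.remodeling import membrane_elastic_energy
        energies = []
        for substeps in (2, 8, 32):    # fixed dt_ibm, increasing delta_t
            sec = build_basic_geometry(0.24, 0.28, 0.30, h=0.0075,
                                       membrane_stiffness=0.05)
            th = np.arctan2(sec.lumen_wall.points[:, 1],
                            sec.lumen_wall.points[:, 0])
            r = np.linalg.norm(sec.lumen_wall.points, axis=1) \
                + 0.006 * np.cos(4 * th)
            sec.lumen_wall.points = np.column_stack([r * np.cos(th),
                                                     r * np.sin(th)])
            pop, ecm = seed_cells(sec, 0.0, rng_seed=0)
            shape = sec.region_mask.shape
            fields = FieldSet(np.zeros(shape),
                              np.zeros(len(sec.lumen_wall.points)),
                              np.zeros(shape), np.zeros(shape),
                              sec.lumen_wall.copy())
            p = RemodelingParams(delta_t=substeps * 0.1, substeps=substeps,
                                 k_S=0, k_E=0, k_G=0, random_motility=0,
                                 plastic_rate=0.0)
            relax_tissue(sec, pop, ecm, EventBatch([]), fields, mech_params,
                         p, np.random.default_rng(0))
            energies.append(membrane_elastic_energy(sec.lumen_wall))
        assert energies[0] > energies[1] > energies[2]
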