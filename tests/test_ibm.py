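import numpy as np
import pytest

from furrowsim.geometry import build_cross_section_2d
from furrowsim.ibm import (
    SimulationParams,
    SimulationState,
    compartment_volumes,
    interpolate_velocities,
    peskin_delta_4pt,
    reynolds_number,
    spread_forces,
    step,
)
from furrowsim.mechanics import ForceProtocol, total_forces
from furrowsim.stokes import FluidDomain, VelocityField


class TestKernel:
    def test_partition_of_unity_and_zero_first_moment(self):
        r = np.linspace(0, 0.999, 37)
        shifts = np.arange(-2, 3)[:, None]
        vals = peskin_delta_4pt(r[None, :] - shifts)
        assert np.abs(vals.sum(axis=0) - 1.0).max() < 1e-12
        assert np.abs((shifts * vals).sum(axis=0) - r).max() < 1e-12

    def test_compact_support(self):
        assert peskin_delta_4pt(np.array([2.0, 2.5, -3.0])).max() == 0.0


class TestSpreadInterpolate:
    def test_force_conservation(self, ring80, small_disk_domain, rng):
        F = rng.standard_normal(ring80.nodes.shape)
        f = spread_forces(F, ring80.nodes, small_disk_domain)
        vol = small_disk_domain.cell_measure
        for a in range(2):
            total = f[a].sum() * vol
            assert abs(total - F[:, a].sum()) < 1e-10 * np.abs(F[:, a]).sum()

    def test_uniform_velocity_reproduced(self, ring80, small_disk_domain):
        const = VelocityField(
            components=tuple(
                np.full(small_disk_domain.face_shape(a), c)
                for a, c in enumerate((2.5, -1.5))
            )
        )
        V = interpolate_velocities(const, ring80.nodes, small_disk_domain)
        assert np.abs(V - [2.5, -1.5]).max() < 1e-12

    def test_linear_velocity_field_reproduced(self, small_disk_domain):
        """The 4-point kernel has a vanishing first moment, so linear fields
        interpolate exactly at interior points."""
        dom = small_disk_domain
        comps = []
        for a in range(2):
            o = dom.face_origin(a)
            sh = dom.face_shape(a)
            axes = [o[c] + np.arange(sh[c]) * dom.h for c in range(2)]
            X, Y = np.meshgrid(*axes, indexing="ij")
            comps.append(0.3 * X - 0.7 * Y if a == 0 else 1.1 * X + 0.2 * Y)
        vel = VelocityField(components=tuple(comps))
        pts = np.array([[0.0, 0.0], [10.3, -20.7], [-35.55, 12.1]])
        V = interpolate_velocities(vel, pts, dom)
        expect = np.column_stack(
            [0.3 * pts[:, 0] - 0.7 * pts[:, 1], 1.1 * pts[:, 0] + 0.2 * pts[:, 1]]
        )
        assert np.abs(V - expect).max() < 1e-10

    def test_single_node_on_grid_point_symmetric_weights(self):
        dom = FluidDomain.box((10.0, 10.0), (10, 10))
        # a u-face location: x on a grid line, y at a cell centre
        pt = np.array([[5.0, 4.5]])
        F = np.array([[1.0, 0.0]])
        f = spread_forces(F, pt, dom)
        fx = f[0]
        i, j = 5, 4
        phi = peskin_delta_4pt(np.arange(-1, 3) - 0.0)
        # symmetric support about the node in both axes
        assert fx[i - 1, j] == pytest.approx(fx[i + 1, j])
        assert fx[i, j - 1] == pytest.approx(fx[i, j + 1])
        expect_centre = phi[1] * phi[1] / dom.cell_measure
        assert fx[i, j] == pytest.approx(expect_centre)

    def test_node_outside_grid_rejected(self, small_disk_domain):
        with pytest.raises(ValueError):
            spread_forces(
                np.ones((1, 2)), np.array([[500.0, 0.0]]), small_disk_domain
            )


@pytest.fixture(scope="module")
def toy_setup():
    """Two-cell toy ring on a coarse grid with an active protocol."""
    g = build_cross_section_2d(
        n_cells=2, radius=60.0, cell_height=20.0, gap=8.0,
        nodes_per_membrane=2, n_mesoderm=1,
    )
    dom = FluidDomain.disk(radius=60.0, gap=8.0, eta=1.0, eta_pv=1e-3, n=32)
    proto = ForceProtocol(sigma0=0.02, sigma_max=0.5, ramp_duration=5.0)
    return g, dom, proto


class TestStep:
    def test_equilibrium_fixed_point(self, toy_setup):
        g, dom, _ = toy_setup
        silent = ForceProtocol()
        st = SimulationState(t=0.0, positions=g.nodes.copy())
        out = step(st, g, silent, SimulationParams(dt=0.1, t_max=1.0), dom)
        assert np.abs(out.positions - g.nodes).max() < 1e-12
        assert out.t == pytest.approx(0.1)

    def test_step_matches_independent_composition(self, toy_setup):
        """One step equals a brute-force composition of the five stages:
        kernel spreading by explicit loops, a dense linear solve of the
        assembled Stokes system, interpolation by explicit loops."""
        g, dom, proto = toy_setup
        st = SimulationState(t=2.0, positions=g.nodes * 1.01)
        dt = 0.05
        out = step(st, g, proto, SimulationParams(dt=dt, t_max=1.0), dom)

        F = total_forces(g, proto, st.t, st.positions)
        f = [np.zeros(dom.face_shape(a)) for a in range(2)]
        for a in range(2):
            origin = dom.face_origin(a)
            for (px, py), Fi in zip(st.positions, F):
                gx = (px - origin[0]) / dom.h
                gy = (py - origin[1]) / dom.h
                bx, by = int(np.floor(gx)), int(np.floor(gy))
                for ix in range(bx - 1, bx + 3):
                    for iy in range(by - 1, by + 3):
                        w = (
                            peskin_delta_4pt(np.array([gx - ix]))
                            * peskin_delta_4pt(np.array([gy - iy]))
                        ).item()
                        f[a][ix, iy] += w * Fi[a] / dom.cell_measure

        rhs = np.zeros(dom.n_dof)
        for a in range(2):
            vals = np.where(dom.face_active[a], f[a], 0.0)
            rhs[int(dom._offset[a]):int(dom._offset[a + 1])] = vals.ravel()
        x = np.linalg.solve(dom.matrix.toarray(), rhs)
        u = [
            x[int(dom._offset[a]):int(dom._offset[a + 1])].reshape(dom.face_shape(a))
            for a in range(2)
        ]

        V = np.zeros_like(st.positions)
        for a in range(2):
            origin = dom.face_origin(a)
            for n_i, (px, py) in enumerate(st.positions):
                gx = (px - origin[0]) / dom.h
                gy = (py - origin[1]) / dom.h
                bx, by = int(np.floor(gx)), int(np.floor(gy))
                for ix in range(bx - 1, bx + 3):
                    for iy in range(by - 1, by + 3):
                        w = (
                            peskin_delta_4pt(np.array([gx - ix]))
                            * peskin_delta_4pt(np.array([gy - iy]))
                        ).item()
                        V[n_i, a] += w * u[a][ix, iy]

        expected = st.positions + dt * V
        scale = max(np.abs(expected).max(), 1.0)
        assert np.abs(out.positions - expected).max() < 1e-8 * scale

    def test_first_order_in_dt(self, toy_setup):
        """Halving dt halves the integration error (forward Euler)."""
        g, dom, proto = toy_setup
        horizon = 0.8

        def final(dtl):
            st = SimulationState(t=0.0, positions=g.nodes.copy())
            params = SimulationParams(dt=dtl, t_max=1.0)
            for _ in range(int(round(horizon / dtl))):
                st = step(st, g, proto, params, dom)
            return st.positions

        p1, p2, p4 = final(0.4), final(0.2), final(0.1)
        e1 = np.abs(p1 - p4).max()
        e2 = np.abs(p2 - p4).max()
        assert e2 < e1  # converging
        assert 1.3 < e1 / e2 < 4.0  # roughly first order

    def test_nan_positions_abort(self, toy_setup):
        g, dom, _ = toy_setup
        wild = ForceProtocol(sigma0=0.0, sigma_max=1e9, ramp_mode="instantaneous")
        st = SimulationState(t=1.0, positions=g.nodes.copy())
        with pytest.raises((FloatingPointError, ValueError, RuntimeError)):
            for _ in range(50):
                st = step(st, g, wild, SimulationParams(dt=10.0, t_max=1.0), dom)


class TestCompartmentVolumes:
    def test_translation_invariance(self, ring4):
        st0 = SimulationState(t=0.0, positions=ring4.nodes.copy())
        st1 = SimulationState(t=0.0, positions=ring4.nodes + [3.0, -2.0])
        v0 = compartment_volumes(st0, ring4)
        v1 = compartment_volumes(st1, ring4)
        assert np.allclose(v0["cells"], v1["cells"])
        assert v0["yolk"] == pytest.approx(v1["yolk"])

    def test_open_geometry_reports_merged_and_retained(self, ring80_open):
        st = SimulationState(t=0.0, positions=ring80_open.nodes.copy())
        v = compartment_volumes(st, ring80_open)
        assert "yolk_and_cells" in v and "retained" in v
        assert np.all(v["retained"] > 0)


class TestReynolds:
    def test_direct_evaluation(self):
        assert reynolds_number(1e3, 1e-6, 1e-4, 10.0) == pytest.approx(1e-8)

    def test_halves_with_doubled_viscosity(self):
        assert reynolds_number(1e3, 1e-6, 1e-4, 20.0) == pytest.approx(0.5e-8)

    def test_zero_density(self):
        assert reynolds_number(0.0, 1.0, 1.0, 1.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            reynolds_number(1.0, -1.0, 1.0, 1.0)


class TestThreeDimensionalCoupling:
    def test_spread_interpolate_and_step_3d(self):
        """Smoke test of the full five-step loop on a small spheroid: force
        conservation holds in 3D and a few steps stay finite."""
        from furrowsim.geometry import build_embryo_3d

        g = build_embryo_3d(
            semi_axes=(50.0, 30.0, 30.0), n_bands=4, n_azimuth=8,
            cell_height=10.0, gap=6.0, resolution=1, n_mesoderm_bands=2,
        )
        # margin must exceed the kernel support (2h) at this coarse spacing
        dom = FluidDomain.spheroid(
            semi_axes=(50.0, 30.0, 30.0), gap=6.0, eta=1.0, eta_pv=1e-3,
            n=16, margin=18.0,
        )
        rng = np.random.default_rng(0)
        F = rng.standard_normal(g.nodes.shape)
        f = spread_forces(F, g.nodes, dom)
        for a in range(3):
            total = f[a].sum() * dom.cell_measure
            assert abs(total - F[:, a].sum()) < 1e-10 * np.abs(F[:, a]).sum()

        proto = ForceProtocol(sigma0=0.01, sigma_max=0.2, ramp_duration=5.0)
        st = SimulationState(t=0.0, positions=g.nodes.copy())
        params = SimulationParams(dt=0.05, t_max=1.0)
        for _ in range(3):
            st = step(st, g, proto, params, dom)
        assert np.all(np.isfinite(st.positions))
        vols = compartment_volumes(st, g)["cells"]
        assert np.all(vols > 0)
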