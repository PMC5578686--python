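"""Tests for the rod-and-connector static solver."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from msclgate import fem
from msclgate.forcelaws import (
    Connector,
    ConnectorSet,
    InteractionForceLaw,
    RegularizedLaw,
    build_porelock,
)
from msclgate.helices import default_helix_specs
from msclgate.synth import SyntheticDefaults, gen_geometry

E_TM1 = 22.0
AREA = math.pi * 6.25


def straight_rod_mesh(n_el=4, L=40.0, E=E_TM1):
    """Single vertical rod fixture (not built through geometry)."""
    nodes = np.array([[0.0, 0.0, z] for z in np.linspace(0, L, n_el + 1)])
    seg = L / n_el
    k = E * AREA / seg
    return fem.Mesh(
        nodes=nodes,
        el_i=np.arange(n_el),
        el_j=np.arange(1, n_el + 1),
        el_k=np.full(n_el, k),
        el_L0=np.full(n_el, seg),
        el_E=np.full(n_el, E),
        el_helix=["TM1"] * n_el,
        el_subunit=np.zeros(n_el, dtype=int),
        h_a=np.arange(n_el - 1),
        h_b=np.arange(1, n_el),
        h_c=np.arange(2, n_el + 1),
        h_k=np.full(n_el - 1, E * math.pi * 2.5**4 / 4 / seg),
        h_theta0=np.zeros(n_el - 1),
        tm1_residue_nodes={(0, 19): n_el // 2},
        role_nodes={},
    )


class TestDiscretize:
    def test_series_stiffness_matches_whole_rod(self):
        """Axial stiffnesses of the chained segments combine to E*A/L."""
        geo = gen_geometry("WT", "closed")
        mesh = fem.discretize(geo, default_helix_specs(), 4)
        tm1 = [
            i
            for i in mesh.helix_elements("TM1")
            if mesh.el_subunit[i] == 0
        ]
        k_series = 1.0 / sum(1.0 / mesh.el_k[i] for i in tm1)
        assert k_series == pytest.approx(E_TM1 * AREA / 47.33, rel=1e-9)

    def test_anchor_residues_are_mesh_nodes(self):
        geo = gen_geometry("WT", "closed")
        mesh = fem.discretize(geo, default_helix_specs(), 4)
        for s in range(5):
            for res in (16, 19, 20, 22, 23, 26):
                node = mesh.tm1_residue_nodes[(s, res)]
                expected = geo.tm1_residue_point(s, res)
                assert np.allclose(mesh.nodes[node], expected, atol=1e-9)

    def test_junctions_share_nodes(self):
        geo = gen_geometry("WT", "closed")
        mesh = fem.discretize(geo, default_helix_specs(), 4)
        # N-terminus inner end is the TM1 bottom node
        for s in range(5):
            b = mesh.role_nodes[("tm1_bottom", s)]
            n_els = [
                i
                for i, h in enumerate(mesh.el_helix)
                if h == "N" and mesh.el_subunit[i] == s
            ]
            nodes_of_n = {int(mesh.el_i[i]) for i in n_els} | {
                int(mesh.el_j[i]) for i in n_els
            }
            assert b in nodes_of_n

    def test_too_coarse_mesh_rejected(self):
        geo = gen_geometry("WT", "closed")
        with pytest.raises(ValueError):
            fem.discretize(geo, default_helix_specs(), 1)


class TestSolve:
    def test_zero_displacement_gives_zero_stress(self):
        mesh = straight_rod_mesh()
        path = np.repeat(mesh.nodes[-1][None, :], 3, axis=0)
        bcs = fem.BoundaryConditionSet(fixed=[0], paths={4: path}, increments=2)
        traj = fem.solve(mesh, None, bcs)
        assert traj.converged
        assert np.max(np.abs(traj.element_stresses)) < 1e-10
        assert np.all(traj.iterations[1:] == 0)

    def test_uniaxial_rod_stress_matches_closed_form(self):
        mesh = straight_rod_mesh()
        L, delta = 40.0, 2.0
        path = np.zeros((6, 3))
        path[:, 2] = L + np.linspace(0, delta, 6)
        bcs = fem.BoundaryConditionSet(fixed=[0], paths={4: path}, increments=5)
        traj = fem.solve(mesh, None, bcs)
        assert traj.converged
        sigma = traj.element_stresses[-1]
        assert np.allclose(sigma, E_TM1 * delta / L, rtol=0.01)

    def test_two_particle_connector_equilibrium(self):
        """A free particle bound to a fixed one settles at (2A/B)^(1/6)."""
        law = InteractionForceLaw(A=200.0, B=40.0)
        nodes = np.array([[0.0, 0.0, 0.0], [law.r_eq * 1.4, 0.0, 0.0]])
        mesh = fem.Mesh(
            nodes=nodes,
            el_i=np.array([], dtype=int),
            el_j=np.array([], dtype=int),
            el_k=np.array([]),
            el_L0=np.array([]),
            el_E=np.array([]),
            el_helix=[],
            el_subunit=np.array([], dtype=int),
            h_a=np.array([], dtype=int),
            h_b=np.array([], dtype=int),
            h_c=np.array([], dtype=int),
            h_k=np.array([]),
            h_theta0=np.array([]),
            tm1_residue_nodes={(0, 19): 0, (1, 19): 1},
            role_nodes={},
        )
        cons = ConnectorSet(
            [Connector(subunit=0, belt="L19-L19", residue_a=19, residue_b=19, law=law)]
        )
        path = np.repeat(nodes[0][None, :], 2, axis=0)
        bcs = fem.BoundaryConditionSet(fixed=[], paths={0: path}, increments=1)
        # fixed set must be nonempty: pin node 0 instead of prescribing it
        bcs = fem.BoundaryConditionSet(fixed=[0], paths={}, increments=1)
        traj = fem.solve(mesh, cons, bcs, tol=1e-8)
        sep = np.linalg.norm(traj.coords[-1][1] - traj.coords[-1][0])
        expected = (2.0 * law.A / law.B) ** (1.0 / 6.0)
        assert sep == pytest.approx(expected, rel=1e-6)
        # independent oracle: 1-D brute-force energy minimization
        reg = RegularizedLaw.from_law(law)
        res = minimize_scalar(
            lambda r: reg.energy_force(r)[0], bounds=(0.5 * expected, 1.6 * expected),
            method="bounded", options={"xatol": 1e-10},
        )
        assert sep == pytest.approx(res.x, rel=1e-6)

    def test_small_model_matches_direct_energy_minimization(self):
        """<= 6-node model: solver equilibrium equals a derivative-free
        minimization of the same total energy to 1e-4 Å."""
        mesh = straight_rod_mesh(n_el=3, L=30.0)
        path = np.zeros((3, 3))
        path[:, 2] = 30.0 + np.linspace(0, 1.5, 3)
        path[:, 0] = np.linspace(0, 1.0, 3)  # add a transverse component
        bcs = fem.BoundaryConditionSet(fixed=[0], paths={3: path}, increments=2)
        traj = fem.solve(mesh, None, bcs, tol=1e-9)
        model = fem._Model(mesh=mesh, pairs=[])
        x_full = traj.coords[-1].ravel().copy()
        free = np.ones(mesh.n_nodes * 3, dtype=bool)
        free[:3] = False
        free[9:] = False

        def energy_of(xf):
            x = x_full.copy()
            x[free] = xf
            return model.energy_grad(x)[0]

        from scipy.optimize import minimize

        res = minimize(energy_of, x_full[free], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 20000})
        assert np.max(np.abs(res.x - x_full[free])) < 1e-4

    def test_requires_a_fixed_node(self):
        mesh = straight_rod_mesh()
        path = np.repeat(mesh.nodes[-1][None, :], 2, axis=0)
        with pytest.raises(ValueError, match="fixed"):
            fem.solve(mesh, None, fem.BoundaryConditionSet(fixed=[], paths={4: path}, increments=1))

    def test_disjoint_fixed_and_pulled_sets(self):
        mesh = straight_rod_mesh()
        path = np.repeat(mesh.nodes[0][None, :], 2, axis=0)
        with pytest.raises(ValueError, match="disjoint"):
            fem.BoundaryConditionSet(fixed=[0], paths={0: path}, increments=1)


class TestPoreDiameter:
    def test_five_rods_on_a_circle(self):
        pts = np.array(
            [[4 * np.cos(a), 4 * np.sin(a), 0.0] for a in np.linspace(0, 2 * np.pi, 5, endpoint=False)]
        )
        assert fem.pore_diameter(pts, range(5)) == pytest.approx(8.0)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fem.pore_diameter(np.zeros((3, 3)), [])

    def test_closed_and_open_fixtures(self):
        specs = default_helix_specs()
        for genotype, state, expected in (
            ("WT", "closed", 8.0),
            ("G22N", "closed", 11.0),
            ("WT", "open-target", 28.0),
        ):
            mesh = fem.discretize(gen_geometry(genotype, state), specs, 4)
            d = fem.pore_diameter(mesh.nodes, mesh.window_nodes())
            assert d == pytest.approx(expected, abs=1e-6)


class TestStressMetrics:
    def _make_traj(self, diams, stresses):
        T = len(diams)
        return fem.EquilibriumTrajectory(
            coords=np.zeros((T, 1, 3)),
            pore_diameters=np.asarray(diams, dtype=float),
            mean_tm1_stress=np.asarray(stresses, dtype=float),
            element_stresses=np.zeros((T, 0)),
            connector_gaps=np.zeros((T, 0)),
            connector_forces=np.zeros((T, 0)),
            residuals=np.zeros(T),
            iterations=np.zeros(T, dtype=int),
            converged=True,
            failed_increment=None,
            mesh=None,
        )

    def test_constant_diameter_reports_absent_metrics(self):
        traj = self._make_traj([8.0] * 5, [0.0, 1.0, 2.0, 3.0, 4.0])
        thr, opn, opened = fem.tm1_stress_metrics(traj)
        assert not opened and thr is None and opn is None

    def test_metrics_match_brute_force_scan(self):
        """Threshold/open-state equal an exhaustive scan of the arrays."""
        rng = np.random.default_rng(3)
        diams = np.concatenate([np.linspace(8, 12, 6), np.linspace(14, 28, 6)])
        stresses = rng.uniform(0.5, 8.0, diams.size)
        traj = self._make_traj(diams, stresses)
        thr, opn, opened = fem.tm1_stress_metrics(traj)
        assert opened
        onset_diam = 8.0 + 0.25 * (28.0 - 8.0)
        onset = next(i for i, d in enumerate(diams) if d > onset_diam)
        assert thr == pytest.approx(max(stresses[: onset + 1]))
        assert opn == pytest.approx(stresses[-1])
        assert thr >= 0 and opn >= 0

    def test_short_trajectory_rejected(self):
        traj = self._make_traj([8.0], [0.0])
        with pytest.raises(ValueError):
            fem.tm1_stress_metrics(traj)


class TestChannelEquilibrium:
    def test_closed_channel_is_stress_free(self, defaults):
        """The as-built closed pore-lock is an exact equilibrium."""
        geo = gen_geometry("WT", "closed")
        mesh = fem.discretize(geo, default_helix_specs(), 4)
        cons = build_porelock(geo, defaults.wt_laws())
        model = fem._Model(mesh=mesh, pairs=fem._resolve_connectors(mesh, cons))
        _, g = model.energy_grad(mesh.nodes.ravel())
        assert np.max(np.abs(g)) < 1e-9

    def test_newtons_third_law_for_connectors(self, defaults):
        geo = gen_geometry("WT", "closed")
        mesh = fem.discretize(geo, default_helix_specs(), 4)
        cons = build_porelock(geo, defaults.wt_laws())
        model = fem._Model(mesh=mesh, pairs=fem._resolve_connectors(mesh, cons))
        # in any configuration, internal (connector + elastic) forces are
        # equal and opposite: the gradient summed over all nodes vanishes
        rng = np.random.default_rng(0)
        x = (mesh.nodes + 0.5 * rng.normal(size=mesh.nodes.shape)).ravel()
        _, g = model.energy_grad(x)
        assert np.max(np.abs(g.reshape(-1, 3).sum(axis=0))) < 1e-9
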