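"""Nonlinear static solver for the rod-and-connector channel model.

Helix centerlines are discretized into two-node axial segments with discrete
bending springs at interior nodes (axial stiffness E*A/L per segment, bending
stiffness E*I/l per hinge with A = pi r², I = pi r^4/4), and the pore-lock
contacts enter as two-point connector elements whose force follows a
(possibly generalized) Lennard-Jones law along the line of centers, with the
short-range repulsion capped for robustness.  Gating is displacement
controlled: prescribed nodes move along their path in load increments and
the free nodes are iterated to static equilibrium (quasi-Newton descent on
the total potential energy followed by Newton polishing of the force
residual).  The trajectory records nodal coordinates, element stresses,
connector gaps/forces and the pore diameter at every increment.

Internal units: Å, pN, pN·Å, pN/Å².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .forcelaws import Connector, ConnectorSet, RegularizedLaw
from .geometry import (
    DEFAULT_PORE_WINDOW,
    ChannelGeometry,
    N_SUBUNITS,
    tm1_residue_fraction,
)
from .helices import HelixSpec
from .units import PN_PER_KCAL_MOL_A

#: Residues that must coincide with mesh nodes on TM1: belt anchors, the
#: full constriction window, and the rod ends.
TM1_REQUIRED_RESIDUES = (15, 16, 19, 20, 21, 22, 23, 24, 25, 26, 48)

DEFAULT_LOOP_STIFFNESS = 10.0  # pN/Å, periplasmic TM1-TM2 tether

#: Effective bending rigidity multiplier on the thin-rod pi*r^4/4 (see
#: :func:`discretize`).
DEFAULT_BENDING_SCALE = 10.5

#: Bending multiplier at the N/TM1 and TM2/C joints: stiffer than a free
#: pin (the backbone continues through the joint) but well below the
#: intra-helix rigidity (the N/TM1 joint is the flexible glycine-hinge
#: region).
DEFAULT_JUNCTION_SCALE = 5.0


@dataclass
class Mesh:
    """Discretized channel: nodes, axial elements, bending hinges."""

    nodes: np.ndarray  # (N, 3) reference coordinates
    el_i: np.ndarray
    el_j: np.ndarray
    el_k: np.ndarray  # axial stiffness EA/L0, pN/Å
    el_L0: np.ndarray
    el_E: np.ndarray  # Young's modulus of the parent helix, pN/Å²
    el_helix: list[str]
    el_subunit: np.ndarray
    h_a: np.ndarray
    h_b: np.ndarray
    h_c: np.ndarray
    h_k: np.ndarray  # bending stiffness EI/l, pN·Å
    h_theta0: np.ndarray  # rest angle per hinge (rad); 0 = straight
    tm1_residue_nodes: dict[tuple[int, int], int]
    role_nodes: dict[tuple[str, int], int]
    window: tuple[int, int] = DEFAULT_PORE_WINDOW
    node_subunit: np.ndarray | None = None  # subunit of each node
    node_base: np.ndarray | None = None  # subunit-0 partner index of each node

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def window_nodes(self) -> list[int]:
        lo, hi = self.window
        return [
            idx
            for (s, res), idx in sorted(self.tm1_residue_nodes.items())
            if lo <= res <= hi
        ]

    def helix_elements(self, helix: str) -> np.ndarray:
        return np.array([i for i, h in enumerate(self.el_helix) if h == helix], dtype=int)


def discretize(
    geometry: ChannelGeometry,
    specs: dict[str, HelixSpec],
    elements_per_helix: int = 4,
    loop_stiffness: float = DEFAULT_LOOP_STIFFNESS,
    bending_scale: float = DEFAULT_BENDING_SCALE,
    junction_scale: float = DEFAULT_JUNCTION_SCALE,
) -> Mesh:
    """Build the rod mesh from helix centerlines.

    Every helix polyline becomes a chain of axial segments; TM1 additionally
    receives nodes at all belt-anchor and constriction-window residues so
    connectors attach to mesh nodes exactly.  Coincident helix end points
    (N-terminus/TM1 junction, TM2/C junction) are merged into shared nodes.
    A soft axial tether of stiffness ``loop_stiffness`` links each TM1
    periplasmic end to the corresponding (fixed) TM2 top, standing in for
    the periplasmic loop.

    ``bending_scale`` multiplies the thin-rod second moment pi*r^4/4 in the
    hinge stiffnesses: the 2.5 Å rod radius reproduces the axial compliance
    of an alpha-helix but understates its bending rigidity (persistence
    length ~100 nm implies EI of a few 1e3 pN·Å²), so bending uses an
    effective second moment ``bending_scale * pi*r^4/4``.
    """
    if elements_per_helix < 2:
        raise ValueError("elements_per_helix must be >= 2")
    node_ids: dict[tuple[float, float, float], int] = {}
    coords: list[np.ndarray] = []
    node_subunit: list[int] = []
    node_order: list[int] = []  # creation order within the node's subunit
    _counter = [0]

    def node_at(p: np.ndarray, subunit: int) -> int:
        key = tuple(np.round(p, 9))
        if key not in node_ids:
            node_ids[key] = len(coords)
            coords.append(np.asarray(p, dtype=float))
            node_subunit.append(subunit)
            node_order.append(_counter[0])
            _counter[0] += 1
        return node_ids[key]

    el_i, el_j, el_k, el_L0, el_E, el_helix, el_subunit = [], [], [], [], [], [], []
    h_a, h_b, h_c, h_k, h_theta0 = [], [], [], [], []
    tm1_residue_nodes: dict[tuple[int, int], int] = {}
    role_nodes: dict[tuple[str, int], int] = {}

    def rest_angle(a: int, b: int, c: int) -> float:
        u = coords[b] - coords[a]
        v = coords[c] - coords[b]
        cang = float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
        return float(np.arccos(np.clip(cang, -1.0, 1.0)))

    for s in range(N_SUBUNITS):
        helix_ids: dict[str, list[int]] = {}
        helix_seg: dict[str, list[float]] = {}
        _counter[0] = 0  # restart per-subunit creation order
        for helix in ("TM1", "N", "TM2", "C"):
            spec = specs[helix]
            fracs = set(np.linspace(0.0, 1.0, elements_per_helix + 1))
            if helix == "TM1":
                req = {float(tm1_residue_fraction(r)) for r in TM1_REQUIRED_RESIDUES}
                lo, hi = geometry.tm1_residue_span
                for r in TM1_REQUIRED_RESIDUES:
                    if not lo <= r <= hi:
                        raise ValueError(f"anchor residue {r} outside rod span")
                fracs |= req
            fr = np.array(sorted(fracs))
            pts = [geometry.point_at_arclength(s, helix, f) for f in fr]
            ids = [node_at(p, s) for p in pts]
            if helix == "TM1":
                frac_to_id = dict(zip(fr, ids))
                for r in TM1_REQUIRED_RESIDUES:
                    tm1_residue_nodes[(s, r)] = frac_to_id[float(tm1_residue_fraction(r))]
                role_nodes[("tm1_bottom", s)] = ids[0]
                role_nodes[("tm1_top", s)] = ids[-1]
            elif helix == "N":
                role_nodes[("n_outer", s)] = ids[-1]
            elif helix == "TM2":
                role_nodes[("tm2_top", s)] = ids[0]
            elif helix == "C":
                role_nodes[("c_end", s)] = ids[-1]
            seg_len = [
                float(np.linalg.norm(np.asarray(pts[t + 1]) - np.asarray(pts[t])))
                for t in range(len(pts) - 1)
            ]
            for t in range(len(ids) - 1):
                el_i.append(ids[t])
                el_j.append(ids[t + 1])
                L0 = seg_len[t]
                el_k.append(spec.youngs_modulus * spec.area / L0)
                el_L0.append(L0)
                el_E.append(spec.youngs_modulus)
                el_helix.append(helix)
                el_subunit.append(s)
            for t in range(1, len(ids) - 1):
                h_a.append(ids[t - 1])
                h_b.append(ids[t])
                h_c.append(ids[t + 1])
                lbar = 0.5 * (seg_len[t - 1] + seg_len[t])
                h_k.append(bending_scale * spec.youngs_modulus * spec.second_moment / lbar)
                h_theta0.append(0.0)
            helix_ids[helix] = ids
            helix_seg[helix] = seg_len
        # inter-helix junction hinges with the reference angle as rest angle.
        # The N/TM1 joint is the flexible glycine-hinge region, so it gets
        # only the softer helix's thin-rod stiffness (junction_scale = 1),
        # not the enhanced intra-helix bending rigidity.
        for ha, hb, soft in (("N", "TM1", "N"), ("TM2", "C", "C")):
            a = helix_ids[ha][1]  # node adjacent to the shared joint
            b = helix_ids[ha][0] if ha == "N" else helix_ids[ha][-1]
            c = helix_ids[hb][1]
            lbar = 0.5 * (helix_seg[ha][0] + helix_seg[hb][0])
            h_a.append(a)
            h_b.append(b)
            h_c.append(c)
            h_k.append(junction_scale * specs[soft].youngs_modulus * specs[soft].second_moment / lbar)
            h_theta0.append(rest_angle(a, b, c))

    nodes = np.array(coords)
    # periplasmic loop tethers (soft axial springs, not helix material)
    if loop_stiffness > 0:
        for s in range(N_SUBUNITS):
            a = role_nodes[("tm1_top", s)]
            b = role_nodes[("tm2_top", s)]
            L0 = float(np.linalg.norm(nodes[a] - nodes[b]))
            el_i.append(a)
            el_j.append(b)
            el_k.append(loop_stiffness)
            el_L0.append(max(L0, 1e-9))
            el_E.append(0.0)
            el_helix.append("loop")
            el_subunit.append(s)

    node_subunit_arr = np.array(node_subunit, dtype=int)
    node_order_arr = np.array(node_order, dtype=int)
    base_by_order = {
        node_order_arr[n]: n for n in range(len(coords)) if node_subunit_arr[n] == 0
    }
    node_base = np.array([base_by_order[o] for o in node_order_arr], dtype=int)

    return Mesh(
        nodes=nodes,
        node_subunit=node_subunit_arr,
        node_base=node_base,
        el_i=np.array(el_i, dtype=int),
        el_j=np.array(el_j, dtype=int),
        el_k=np.array(el_k, dtype=float),
        el_L0=np.array(el_L0, dtype=float),
        el_E=np.array(el_E, dtype=float),
        el_helix=el_helix,
        el_subunit=np.array(el_subunit, dtype=int),
        h_a=np.array(h_a, dtype=int),
        h_b=np.array(h_b, dtype=int),
        h_c=np.array(h_c, dtype=int),
        h_k=np.array(h_k, dtype=float),
        h_theta0=np.array(h_theta0, dtype=float),
        tm1_residue_nodes=tm1_residue_nodes,
        role_nodes=role_nodes,
    )


@dataclass
class BoundaryConditionSet:
    """Displacement control: fixed nodes and prescribed node paths.

    ``paths[node]`` is an (increments + 1, 3) array of absolute positions,
    starting at the node's reference position (zero displacement).
    """

    fixed: list[int]
    paths: dict[int, np.ndarray]
    increments: int

    def __post_init__(self) -> None:
        if set(self.fixed) & set(self.paths):
            raise ValueError("pulled and fixed node sets must be disjoint")
        for node, path in self.paths.items():
            path = np.asarray(path, dtype=float)
            if path.shape != (self.increments + 1, 3):
                raise ValueError(
                    f"path for node {node} must have shape ({self.increments + 1}, 3)"
                )
            self.paths[node] = path


@dataclass
class _Model:
    """Assembled energy model over flattened coordinates."""

    mesh: Mesh
    pairs: list[tuple[int, int, RegularizedLaw]]

    def energy_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        m = self.mesh
        X = x.reshape(-1, 3)
        g = np.zeros_like(X)
        d = X[m.el_j] - X[m.el_i]
        L = np.linalg.norm(d, axis=1)
        dL = L - m.el_L0
        e = float(0.5 * np.sum(m.el_k * dL * dL))
        fvec = (m.el_k * dL / L)[:, None] * d
        np.add.at(g, m.el_j, fvec)
        np.add.at(g, m.el_i, -fvec)
        if m.h_a.size:
            u = X[m.h_b] - X[m.h_a]
            v = X[m.h_c] - X[m.h_b]
            nu = np.linalg.norm(u, axis=1)
            nv = np.linalg.norm(v, axis=1)
            uv = np.sum(u * v, axis=1)
            c = uv / (nu * nv)
            eh, w = _hinge_energy_prefactor(c, m.h_theta0)
            e += float(np.sum(m.h_k * eh))
            dc_du = v / (nu * nv)[:, None] - (uv / (nu**3 * nv))[:, None] * u
            dc_dv = u / (nu * nv)[:, None] - (uv / (nu * nv**3))[:, None] * v
            k = (m.h_k * w)[:, None]
            np.add.at(g, m.h_a, -k * dc_du)
            np.add.at(g, m.h_b, k * dc_du - k * dc_dv)
            np.add.at(g, m.h_c, k * dc_dv)
        for a, b, rlaw in self.pairs:
            dvec = X[b] - X[a]
            r = float(np.linalg.norm(dvec))
            ec, fc = rlaw.energy_force(r)
            e += ec
            gv = (-fc / r) * dvec  # dE/dr = -F
            g[b] += gv
            g[a] -= gv
        return e, g.ravel()

    def _hinge_grad(self, X: np.ndarray) -> np.ndarray:
        """Bending-energy gradient contributions per hinge, shape (nh, 3, 3):
        [:, 0] on node a, [:, 1] on node b, [:, 2] on node c."""
        m = self.mesh
        return _hinge_grad_standalone(X[m.h_a], X[m.h_b], X[m.h_c], m.h_k, m.h_theta0)

    def hessian(self, x: np.ndarray) -> np.ndarray:
        """Dense Hessian of the total potential energy (3N x 3N).

        Axial and connector (central-force) contributions are analytic;
        bending blocks are forward finite differences of the analytic hinge
        gradient, which is accurate enough for damped Newton iteration.
        """
        m = self.mesh
        X = x.reshape(-1, 3)
        N = X.shape[0]
        H = np.zeros((3 * N, 3 * N))

        def add_central(i: int, j: int, block: np.ndarray) -> None:
            si, sj = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
            H[si, si] += block
            H[sj, sj] += block
            H[si, sj] -= block
            H[sj, si] -= block

        d = X[m.el_j] - X[m.el_i]
        L = np.linalg.norm(d, axis=1)
        u = d / L[:, None]
        for e in range(len(m.el_i)):
            uu = np.outer(u[e], u[e])
            kt = m.el_k[e]
            kg = m.el_k[e] * (L[e] - m.el_L0[e]) / L[e]
            add_central(int(m.el_i[e]), int(m.el_j[e]), kt * uu + kg * (np.eye(3) - uu))
        for a, b, rlaw in self.pairs:
            dv = X[b] - X[a]
            r = float(np.linalg.norm(dv))
            uv = dv / r
            uu = np.outer(uv, uv)
            _, f, dfdr = rlaw.energy_force_stiffness(r)
            e2 = -dfdr  # E'' = -dF/dr
            e1_over_r = -f / r  # E' = -F
            add_central(a, b, e2 * uu + e1_over_r * (np.eye(3) - uu))
        if m.h_a.size:
            g0 = self._hinge_grad(X)
            eps = 1e-6
            nodes3 = np.stack([m.h_a, m.h_b, m.h_c], axis=1)  # (nh, 3)
            for p in range(3):  # perturbed hinge node (a, b, c)
                for axis in range(3):
                    # FD column: perturb node coordinate per hinge independently
                    # (evaluated hinge-locally; hinges are energetically local)
                    Xa = X[m.h_a].copy()
                    Xb = X[m.h_b].copy()
                    Xc = X[m.h_c].copy()
                    tgt = (Xa, Xb, Xc)[p]
                    tgt[:, axis] += eps
                    g1 = _hinge_grad_standalone(Xa, Xb, Xc, m.h_k, m.h_theta0)
                    dG = (g1 - g0) / eps  # (nh, 3, 3)
                    for q in range(3):
                        rows = 3 * nodes3[:, q]
                        cols = 3 * nodes3[:, p] + axis
                        for comp in range(3):
                            np.add.at(
                                H,
                                (rows + comp, cols),
                                dG[:, q, comp],
                            )
        H = 0.5 * (H + H.T)
        return H

    def element_stresses(self, X: np.ndarray) -> np.ndarray:
        """Signed axial stress E*(L - L0)/L0 per element (0 for tethers)."""
        m = self.mesh
        L = np.linalg.norm(X[m.el_j] - X[m.el_i], axis=1)
        return m.el_E * (L - m.el_L0) / m.el_L0

    def connector_state(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        gaps = np.empty(len(self.pairs))
        forces = np.empty(len(self.pairs))
        for idx, (a, b, rlaw) in enumerate(self.pairs):
            r = float(np.linalg.norm(X[b] - X[a]))
            gaps[idx] = r
            forces[idx] = rlaw.energy_force(r)[1]
        return gaps, forces


def _hinge_energy_prefactor(
    c: np.ndarray, theta0: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(energy, dE/dcos) per hinge for E = 0.5*k*(theta - theta0)^2 (unit k).

    theta = arccos(c) with c the cosine of the bend angle between the two
    segment tangents; the dE/dc factor -(theta - theta0)/sin(theta) has a
    finite straight-hinge limit of -1 for theta0 = 0.
    """
    c = np.clip(c, -1.0, 1.0)
    theta = np.arccos(c)
    dtheta = theta - theta0
    e = 0.5 * dtheta * dtheta
    s = np.sqrt(np.maximum(1.0 - c * c, 1e-24))
    w = np.where(s > 1e-8, -dtheta / s, -1.0 + 0.0 * dtheta)
    # straight-rest hinges approach dE/dc -> -1 as theta -> 0
    w = np.where((s <= 1e-8) & (theta0 == 0.0), -1.0, w)
    return e, w


def _hinge_grad_standalone(
    Xa: np.ndarray,
    Xb: np.ndarray,
    Xc: np.ndarray,
    k: np.ndarray,
    theta0: np.ndarray,
) -> np.ndarray:
    """Gradient of 0.5*k*(theta - theta0)^2 per hinge w.r.t. its three nodes."""
    u = Xb - Xa
    v = Xc - Xb
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    uv = np.sum(u * v, axis=1)
    c = uv / (nu * nv)
    _, w = _hinge_energy_prefactor(c, theta0)
    dc_du = v / (nu * nv)[:, None] - (uv / (nu**3 * nv))[:, None] * u
    dc_dv = u / (nu * nv)[:, None] - (uv / (nu * nv**3))[:, None] * v
    kk = (k * w)[:, None]
    out = np.empty((len(k), 3, 3))
    out[:, 0] = -kk * dc_du
    out[:, 1] = kk * dc_du - kk * dc_dv
    out[:, 2] = kk * dc_dv
    return out


def _resolve_connectors(mesh: Mesh, connectors: ConnectorSet | None) -> list:
    pairs = []
    if connectors is None:
        return pairs
    cache: dict[int, RegularizedLaw] = {}
    for con in connectors.active:
        key = id(con.law)
        if key not in cache:
            cache[key] = RegularizedLaw.from_law(con.law)
        a = mesh.tm1_residue_nodes[(con.subunit, con.residue_a)]
        b = mesh.tm1_residue_nodes[((con.subunit + 1) % N_SUBUNITS, con.residue_b)]
        pairs.append((a, b, cache[key]))
    return pairs


@dataclass
class EquilibriumTrajectory:
    """Per-increment record of the displacement-controlled solution."""

    coords: np.ndarray  # (T+1, N, 3), increment 0 = reference state
    pore_diameters: np.ndarray  # (T+1,)
    mean_tm1_stress: np.ndarray  # (T+1,) mean |axial stress| over TM1, pN/Å²
    element_stresses: np.ndarray  # (T+1, n_elements), signed
    connector_gaps: np.ndarray  # (T+1, n_connectors)
    connector_forces: np.ndarray  # (T+1, n_connectors), pN
    residuals: np.ndarray  # (T+1,) inf-norm of free-node force imbalance
    iterations: np.ndarray  # (T+1,)
    converged: bool
    failed_increment: int | None
    mesh: Mesh = field(repr=False, default=None)

    @property
    def closed_diameter(self) -> float:
        return float(self.pore_diameters[0])

    @property
    def final_diameter(self) -> float:
        return float(self.pore_diameters[-1])

    def helix_max_stress(self, helix: str) -> float:
        """Max |axial stress| over all increments and elements of one helix."""
        idx = self.mesh.helix_elements(helix)
        if idx.size == 0:
            return 0.0
        return float(np.max(np.abs(self.element_stresses[:, idx])))


def pore_diameter(
    coords: np.ndarray,
    window_nodes,
    axis=(0.0, 0.0, 1.0),
) -> float:
    """2x minimum radial distance of the window nodes to the channel axis."""
    window_nodes = list(window_nodes)
    if not window_nodes:
        raise ValueError("empty constriction window")
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    P = np.asarray(coords, dtype=float)[window_nodes]
    radial = P - np.outer(P @ a, a)
    return 2.0 * float(np.min(np.linalg.norm(radial, axis=1)))


def solve(
    mesh: Mesh,
    connectors: ConnectorSet | None,
    bcs: BoundaryConditionSet,
    tol: float | None = None,
    max_iter: int = 100,
    max_bisect: int = 5,
    symmetry: bool = False,
) -> EquilibriumTrajectory:
    """March the prescribed displacements in increments, equilibrating the
    free nodes at each step.

    At every increment the free-node positions minimize the total potential
    energy (rod stretching + bending + connector interaction) by damped
    Newton iteration with an analytic Hessian, warm-started from the
    previous increment.  An increment whose residual cannot be brought
    under ``tol`` is retried with up to ``max_bisect`` step bisections;
    persistent failure truncates the trajectory with the failing increment
    flagged.

    With ``symmetry=True`` (requires a :func:`discretize`-built mesh and
    5-fold symmetric BCs) the solution is constrained to the C5-symmetric
    subspace: subunit-0 nodes are the unknowns and the other subunits are
    their 72°-rotated images.  This selects the concerted iris-like gating
    mode and excludes asymmetric unzipping branches of the pore-lock.
    """
    if not bcs.fixed:
        raise ValueError("at least one fixed node is required")
    if tol is None:
        tm1 = mesh.helix_elements("TM1")
        char = float(np.max(mesh.el_E[tm1])) * np.pi * 2.5**2 if tm1.size else 1e3
        tol = 1e-6 * char
    if tol <= 0:
        raise ValueError("tol must be positive")

    model = _Model(mesh=mesh, pairs=_resolve_connectors(mesh, connectors))
    n = mesh.n_nodes
    controlled = sorted(set(bcs.fixed) | set(bcs.paths))
    free_mask = np.ones(n * 3, dtype=bool)
    for node in controlled:
        free_mask[3 * node : 3 * node + 3] = False

    if symmetry:
        if mesh.node_base is None or mesh.node_subunit is None:
            raise ValueError("symmetry solve requires subunit bookkeeping in the mesh")
        # projection P: x = P q with q the subunit-0 node coordinates
        rots = [
            np.array(
                [
                    [np.cos(2 * np.pi * s / N_SUBUNITS), -np.sin(2 * np.pi * s / N_SUBUNITS), 0],
                    [np.sin(2 * np.pi * s / N_SUBUNITS), np.cos(2 * np.pi * s / N_SUBUNITS), 0],
                    [0, 0, 1],
                ]
            )
            for s in range(N_SUBUNITS)
        ]
        base_nodes = np.nonzero(mesh.node_subunit == 0)[0]
        base_pos = {int(b): k for k, b in enumerate(base_nodes)}
        nq = 3 * len(base_nodes)
        P = np.zeros((3 * n, nq))
        for node in range(n):
            b = base_pos[int(mesh.node_base[node])]
            P[3 * node : 3 * node + 3, 3 * b : 3 * b + 3] = rots[
                int(mesh.node_subunit[node])
            ]
        qfree_mask = np.ones(nq, dtype=bool)
        for node in controlled:
            b = base_pos[int(mesh.node_base[node])]
            qfree_mask[3 * b : 3 * b + 3] = False
        Pf = P[:, qfree_mask]

        def expand(x_full: np.ndarray) -> np.ndarray:
            """Re-symmetrize: rebuild every node from its subunit-0 image."""
            q = x_full.reshape(-1, 3)[base_nodes].ravel()
            return (P @ q).ravel()
    else:
        Pf = None

    x = mesh.nodes.ravel().copy()

    def eg_free(xf: np.ndarray, x_full: np.ndarray):
        x_full = x_full.copy()
        x_full[free_mask] = xf
        e, g = model.energy_grad(x_full)
        return e, g[free_mask]

    def step_y(x_full: np.ndarray, dy: np.ndarray) -> np.ndarray:
        """Apply a free-DOF step in the working space to the full vector."""
        x_new = x_full.copy()
        if symmetry:
            x_new += Pf @ dy
        else:
            x_new[free_mask] = x_full[free_mask] + dy
        return x_new

    def reduce_grad(g: np.ndarray) -> np.ndarray:
        return Pf.T @ g if symmetry else g[free_mask]

    def reduce_hess(H: np.ndarray) -> np.ndarray:
        return Pf.T @ H @ Pf if symmetry else H[np.ix_(free_mask, free_mask)]

    def equilibrate(x_full: np.ndarray) -> tuple[np.ndarray, float, int]:
        """Damped Newton descent of the total energy over the free DOFs."""
        x_full = expand(x_full) if symmetry else x_full.copy()
        lam = 0.0
        nit = 0
        e, g = model.energy_grad(x_full)
        gy = reduce_grad(g)
        for _ in range(max_iter):
            resid = float(np.max(np.abs(g[free_mask]))) if free_mask.any() else 0.0
            if resid <= tol and np.max(np.abs(gy), initial=0.0) <= 5.0 * tol:
                return x_full, resid, nit
            H = reduce_hess(model.hessian(x_full))
            accepted = False
            for _damp in range(40):
                try:
                    c, low = cho_factor(
                        H + lam * np.eye(H.shape[0]), check_finite=False
                    )
                    p = cho_solve((c, low), -gy, check_finite=False)
                except np.linalg.LinAlgError:
                    lam = max(10.0 * lam, 1e-4)
                    continue
                if p @ gy >= 0:  # not a descent direction
                    lam = max(10.0 * lam, 1e-4)
                    continue
                alpha = 1.0
                for _ls in range(40):
                    x_try = step_y(x_full, alpha * p)
                    e_try, g_try = model.energy_grad(x_try)
                    if e_try <= e + 1e-4 * alpha * (p @ gy):
                        x_full, e, g = x_try, e_try, g_try
                        gy = reduce_grad(g)
                        lam *= 0.25
                        accepted = True
                        break
                    alpha *= 0.5
                if accepted:
                    break
                lam = max(10.0 * lam, 1e-4)
            nit += 1
            if not accepted and not symmetry:  # stuck: quasi-Newton restart
                res = minimize(
                    lambda xf: eg_free(xf, x_full),
                    x_full[free_mask],
                    jac=True,
                    method="L-BFGS-B",
                    options={"gtol": 0.1 * tol, "ftol": 1e-16, "maxiter": 1000},
                )
                x_full = x_full.copy()
                x_full[free_mask] = res.x
                e, g = model.energy_grad(x_full)
                gy = reduce_grad(g)
                nit += int(res.nit)
                lam = 1e-4
            elif not accepted:
                break
        resid = float(np.max(np.abs(g[free_mask]))) if free_mask.any() else 0.0
        return x_full, resid, nit

    # per-increment records
    T = bcs.increments
    rec_coords = [mesh.nodes.copy()]
    rec_res = [0.0]
    rec_iter = [0]
    window_nodes = mesh.window_nodes()

    e0, g0 = model.energy_grad(x)
    rec_res[0] = float(np.max(np.abs(g0[free_mask]))) if free_mask.any() else 0.0
    if rec_res[0] > tol:
        x, r0, it0 = equilibrate(x)
        rec_coords[0] = x.reshape(-1, 3).copy()
        rec_res[0] = r0
        rec_iter[0] = it0

    converged = True
    failed_at = None
    for t in range(1, T + 1):
        targets = {node: bcs.paths[node][t] for node in bcs.paths}
        prev = {node: x[3 * node : 3 * node + 3].copy() for node in bcs.paths}
        ok = False
        n_sub, level = 1, 0
        while True:
            x_try = x.copy()
            success = True
            for k in range(1, n_sub + 1):
                for node in bcs.paths:
                    x_try[3 * node : 3 * node + 3] = prev[node] + (
                        targets[node] - prev[node]
                    ) * (k / n_sub)
                x_try, resid, nit = equilibrate(x_try)
                if resid > tol:
                    success = False
                    break
            if success:
                ok = True
                break
            level += 1
            if level > max_bisect:
                break
            n_sub *= 2
        if not ok:
            converged = False
            failed_at = t
            break
        x = x_try
        rec_coords.append(x.reshape(-1, 3).copy())
        rec_res.append(resid)
        rec_iter.append(nit)

    C = np.array(rec_coords)
    Tn = C.shape[0]
    stresses = np.array([model.element_stresses(C[t]) for t in range(Tn)])
    tm1_idx = mesh.helix_elements("TM1")
    if tm1_idx.size:
        w = mesh.el_L0[tm1_idx] / mesh.el_L0[tm1_idx].sum()
        mean_tm1 = np.abs(stresses[:, tm1_idx]) @ w  # arclength-weighted mean
    else:
        mean_tm1 = np.zeros(Tn)
    diam = np.array([pore_diameter(C[t], window_nodes) for t in range(Tn)])
    ngaps = len(model.pairs)
    gaps = np.zeros((Tn, ngaps))
    forces = np.zeros((Tn, ngaps))
    for t in range(Tn):
        gaps[t], forces[t] = model.connector_state(C[t])
    return EquilibriumTrajectory(
        coords=C,
        pore_diameters=diam,
        mean_tm1_stress=mean_tm1,
        element_stresses=stresses,
        connector_gaps=gaps,
        connector_forces=forces,
        residuals=np.array(rec_res),
        iterations=np.array(rec_iter, dtype=int),
        converged=converged,
        failed_increment=failed_at,
        mesh=mesh,
    )


def tm1_stress_metrics(
    traj: EquilibriumTrajectory,
    open_threshold: float = 25.0,
    onset_fraction: float = 0.25,
    open_target: float = 28.0,
) -> tuple[float | None, float | None, bool]:
    """(threshold stress, open-state stress, opened flag) in pN/Å².

    opened: final pore diameter >= ``open_threshold``.  The opening onset is
    the first increment where the diameter exceeds
    closed + onset_fraction * (open_target - closed); the threshold stress is
    the largest mean |axial stress| along TM1 up to and including the onset,
    and the open-state stress is the mean |axial stress| at the final
    increment.  Both are None when the pore never opened.
    """
    if len(traj.pore_diameters) < 2:
        raise ValueError("trajectory needs at least 2 increments")
    closed = traj.closed_diameter
    opened = traj.final_diameter >= open_threshold
    if not opened:
        return None, None, False
    onset_diam = closed + onset_fraction * (open_target - closed)
    above = np.nonzero(traj.pore_diameters > onset_diam)[0]
    onset = int(above[0]) if above.size else len(traj.pore_diameters) - 1
    threshold = float(np.max(traj.mean_tm1_stress[: onset + 1]))
    open_state = float(traj.mean_tm1_stress[-1])
    return threshold, open_state, True
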