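"""Pairwise van der Waals force laws of the MscL pore-lock.

The closed MscL pore is held by five "belts" of inter-subunit van der Waals
contacts between pore-lining TM1 residues (A20-G22, V23-G26, L19-L19,
V23-V23, V16-G22), replicated five-fold around the pentamer: 25 connectors
in total.  Each belt is modelled by a generalized Lennard-Jones force law

    F(r) = 12*A/r**m - 6*B/r**n      (repulsive positive)

which for the standard exponents (m, n) = (13, 7) is the exact negative
gradient of the 12-6 energy  E(r) = A/r**12 - B/r**6.

This module provides the laws themselves, least-squares fitting of (A, B)
and optionally (m, n) to sampled force- or energy-distance curves, the
peak-to-peak well-depth comparison statistic used to quantify the G22N
mutation, uniform strength reduction, and assembly of the 25-connector
pore-lock network.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from scipy.optimize import brentq, least_squares, nnls

from .units import PN_PER_KCAL_MOL_A

#: Canonical belt labels, one per inter-subunit residue-pair contact.
BELTS: tuple[str, ...] = ("A20-G22", "V23-G26", "L19-L19", "V23-V23", "V16-G22")

#: Residue indices (on subunit s, on subunit s+1 mod 5) anchoring each belt.
BELT_RESIDUES: dict[str, tuple[int, int]] = {
    "A20-G22": (20, 22),
    "V23-G26": (23, 26),
    "L19-L19": (19, 19),
    "V23-V23": (23, 23),
    "V16-G22": (16, 22),
}

GENOTYPES = ("WT", "G22N")

N_SUBUNITS = 5


@dataclass(frozen=True)
class InteractionForceLaw:
    """Fitted (A, B, m, n) parameters of one belt's force-distance law.

    A and B are in kcal/mol * Å**(m-1) and kcal/mol * Å**(n-1) respectively
    so that ``12*A/r**m - 6*B/r**n`` is a force in kcal/mol/Å.
    """

    A: float
    B: float
    m: float = 13.0
    n: float = 7.0
    pair: str = ""
    genotype: str = "WT"

    def __post_init__(self) -> None:
        if not (self.A > 0 and self.B > 0):
            raise ValueError(f"A and B must be positive, got A={self.A}, B={self.B}")
        if not (self.m > self.n >= 2):
            raise ValueError(f"exponents must satisfy m > n >= 2, got m={self.m}, n={self.n}")

    @property
    def is_standard(self) -> bool:
        """True for the (13, 7) force law, i.e. the 12-6 energy."""
        return self.m == 13.0 and self.n == 7.0

    @property
    def r_eq(self) -> float:
        """Zero-force (equilibrium) distance in Å: (2A/B)^(1/(m-n))."""
        return (2.0 * self.A / self.B) ** (1.0 / (self.m - self.n))

    @property
    def well_depth(self) -> float:
        """Depth of the energy well in kcal/mol (energy integral of the force)."""
        return -pair_energy_generic(self.A, self.B, self.m, self.n, self.r_eq)

    @classmethod
    def from_well(
        cls, depth: float, r_eq: float, pair: str = "", genotype: str = "WT"
    ) -> "InteractionForceLaw":
        """Build the standard 12-6 law with a given well depth (kcal/mol) and r_eq (Å)."""
        if depth <= 0 or r_eq <= 0:
            raise ValueError("depth and r_eq must be positive")
        A = depth * r_eq**12
        B = 2.0 * depth * r_eq**6
        return cls(A=A, B=B, m=13.0, n=7.0, pair=pair, genotype=genotype)


def pair_energy_generic(A: float, B: float, m: float, n: float, r) -> np.ndarray | float:
    """Energy (kcal/mol) whose negative gradient is 12A/r^m - 6B/r^n.

    For (m, n) = (13, 7) this reduces to the 12-6 form A/r^12 - B/r^6.
    """
    r = np.asarray(r, dtype=float)
    return 12.0 * A / ((m - 1.0) * r ** (m - 1.0)) - 6.0 * B / ((n - 1.0) * r ** (n - 1.0))


def lj_energy(law: InteractionForceLaw, r) -> np.ndarray | float:
    """12-6 energy A/r^12 - B/r^6 in kcal/mol.

    Defined only for the standard exponents (13, 7); generalized-exponent
    laws are force-level objects whose energy uses
    :func:`pair_energy_generic` internally in the solver.
    """
    if not law.is_standard:
        raise ValueError(
            f"energy is defined only for (m, n) = (13, 7); law has ({law.m}, {law.n})"
        )
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distance must be positive")
    out = law.A / r**12 - law.B / r**6
    return float(out) if out.ndim == 0 else out


def lj_force(law: InteractionForceLaw, r) -> np.ndarray | float:
    """Force 12A/r^m - 6B/r^n in pN (positive = repulsive)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distance must be positive")
    f = (12.0 * law.A / r**law.m - 6.0 * law.B / r**law.n) * PN_PER_KCAL_MOL_A
    return float(f) if f.ndim == 0 else f


def peak_attractive_force(law: InteractionForceLaw) -> float:
    """Magnitude (pN) of the strongest attractive (negative) force of the law."""
    # F'(r*) = 0  at  r*^(m-n) = 2*m*A / (n*B)
    r_star = (2.0 * law.A * law.m / (law.B * law.n)) ** (1.0 / (law.m - law.n))
    return float(abs(lj_force(law, r_star)))


@dataclass
class InteractionCurve:
    """Sampled energy/force vs distance data for one residue pair.

    distances in Å (strictly positive, strictly increasing); energies in
    kcal/mol and/or forces in pN — at least one channel must be present.
    """

    pair: str
    genotype: str
    distances: np.ndarray
    energies: np.ndarray | None = None
    forces: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if self.energies is not None:
            self.energies = np.asarray(self.energies, dtype=float)
        if self.forces is not None:
            self.forces = np.asarray(self.forces, dtype=float)
        if self.energies is None and self.forces is None:
            raise ValueError("curve needs at least one of energies/forces")
        if self.distances.size == 0:
            raise ValueError("empty curve")
        if np.any(self.distances <= 0):
            raise ValueError("distances must be strictly positive")
        if np.any(np.diff(self.distances) <= 0):
            raise ValueError("distances must be strictly increasing")
        for arr, name in ((self.energies, "energies"), (self.forces, "forces")):
            if arr is not None and arr.shape != self.distances.shape:
                raise ValueError(f"{name} length does not match distances")

    def force_samples(self) -> np.ndarray:
        """Forces in pN, derived from energies by central differences if absent."""
        if self.forces is not None:
            return self.forces
        return -np.gradient(self.energies, self.distances) * PN_PER_KCAL_MOL_A


@dataclass(frozen=True)
class FitDiagnostics:
    sse: float  # sum of squared force residuals, (kcal/mol/Å)²
    converged: bool
    n_points: int
    free_exponents: bool


def _force_model(A: float, B: float, m: float, n: float, r: np.ndarray) -> np.ndarray:
    return 12.0 * A / r**m - 6.0 * B / r**n


def _linear_ab_fit(r: np.ndarray, f: np.ndarray, m: float, n: float) -> tuple[float, float, float]:
    """Nonnegative least squares for (A, B) at fixed exponents; returns (A, B, sse)."""
    M = np.column_stack([12.0 / r**m, -6.0 / r**n])
    coef, _ = nnls(M, f)
    A, B = coef
    resid = f - M @ coef
    return A, B, float(resid @ resid)


def fit_force_law(
    curve: InteractionCurve, fix_exponents: bool = True
) -> tuple[InteractionForceLaw, FitDiagnostics]:
    """Least-squares fit of a generalized LJ force law to a sampled curve.

    The fit is performed in force space (kcal/mol/Å); energy-only curves are
    differentiated numerically first.  With ``fix_exponents`` the exponents
    are pinned at (13, 7) and the problem is linear in (A, B); otherwise
    (A, B, m, n) are fitted jointly with a multistart over
    m in {11, 13, 15}, n in {5, 7, 9}, and the returned SSE never exceeds
    the fixed-exponent SSE on the same data.
    """
    r = curve.distances
    f = curve.force_samples() / PN_PER_KCAL_MOL_A  # fit in kcal/mol/Å
    n_par = 2 if fix_exponents else 4
    if r.size < max(6, n_par):
        raise ValueError(f"need at least {max(6, n_par)} samples, got {r.size}")
    if not (np.all(np.isfinite(r)) and np.all(np.isfinite(f))):
        raise ValueError("non-finite samples in curve")

    A0, B0, sse_fixed = _linear_ab_fit(r, f, 13.0, 7.0)
    if fix_exponents:
        if A0 <= 0 or B0 <= 0:
            raise ValueError("fixed-exponent fit produced a degenerate (A, B)")
        law = InteractionForceLaw(A0, B0, 13.0, 7.0, curve.pair, curve.genotype)
        return law, FitDiagnostics(sse_fixed, True, r.size, False)

    def residuals(theta: np.ndarray) -> np.ndarray:
        la, lb, m, n = theta
        return _force_model(np.exp(la), np.exp(lb), m, n, r) - f

    best = None
    converged = False
    for m0 in (11.0, 13.0, 15.0):
        for n0 in (5.0, 7.0, 9.0):
            if m0 <= n0:
                continue
            Am, Bm, _ = _linear_ab_fit(r, f, m0, n0)
            if Am <= 0 or Bm <= 0:  # nnls pinned a coefficient; perturb from fixed fit
                Am, Bm = max(A0, 1e-6), max(B0, 1e-6)
            x0 = np.array([np.log(Am), np.log(Bm), m0, n0])
            try:
                res = least_squares(
                    residuals,
                    x0,
                    bounds=([-np.inf, -np.inf, 4.0, 2.0], [np.inf, np.inf, 20.0, 12.0]),
                    xtol=1e-14,
                    ftol=1e-14,
                    gtol=1e-14,
                )
            except Exception:
                continue
            sse = float(2.0 * res.cost)
            la, lb, mf, nf = res.x
            if mf <= nf:
                continue
            cand = (sse, np.exp(la), np.exp(lb), mf, nf, bool(res.success))
            # prefer lower SSE; break near-ties toward (13, 7)
            if best is None or sse < best[0] * (1.0 - 1e-12) or (
                abs(sse - best[0]) <= 1e-12 * max(sse, 1e-300)
                and (mf, nf) == (13.0, 7.0)
            ):
                best = cand
                converged = bool(res.success)

    if best is None or best[0] > sse_fixed:
        # fall back to the fixed-exponent solution: SSE(free) <= SSE(fixed)
        law = InteractionForceLaw(A0, B0, 13.0, 7.0, curve.pair, curve.genotype)
        return law, FitDiagnostics(sse_fixed, best is not None, r.size, True)
    sse, A, B, m, n = best[:5]
    law = InteractionForceLaw(A, B, m, n, curve.pair, curve.genotype)
    return law, FitDiagnostics(sse, converged, r.size, True)


def peak_to_peak_reduction(wt: InteractionCurve, mut: InteractionCurve) -> float:
    """Percent reduction of the sampled well depth from WT to mutant.

    depth = |minimum of the sampled curve| using the energy channel when both
    curves carry energies, otherwise the force channel.  Negative values mean
    the mutant well is deeper.
    """
    if wt.energies is not None and mut.energies is not None:
        d_wt, d_mut = wt.energies.min(), mut.energies.min()
    elif wt.forces is not None and mut.forces is not None:
        d_wt, d_mut = wt.forces.min(), mut.forces.min()
    else:
        raise ValueError("curves must share a channel (both energies or both forces)")
    depth_wt, depth_mut = abs(float(d_wt)), abs(float(d_mut))
    if depth_wt == 0:
        raise ValueError("WT well depth is zero")
    return 100.0 * (depth_wt - depth_mut) / depth_wt


def apply_reduction(law: InteractionForceLaw, rho: float) -> InteractionForceLaw:
    """Scale the interaction strength by (1 - rho).

    A and B scale jointly, so the well depth scales by (1 - rho) while the
    equilibrium distance is unchanged.  rho = 1 is represented by an inactive
    connector downstream; here it returns an A, B scaled by a tiny floor to
    keep the law well-formed.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"reduction fraction must be in [0, 1], got {rho}")
    s = 1.0 - rho
    if s == 0.0:
        s = 1e-300  # strength is handled as inactive by ConnectorSet
    return replace(law, A=law.A * s, B=law.B * s)


@dataclass
class Connector:
    """One inter-subunit contact: belt replicated at subunit pair (s, s+1)."""

    subunit: int
    belt: str
    residue_a: int
    residue_b: int
    law: InteractionForceLaw
    active: bool = True


@dataclass
class ConnectorSet:
    connectors: list[Connector] = field(default_factory=list)

    def __iter__(self):
        return iter(self.connectors)

    def __len__(self) -> int:
        return len(self.connectors)

    @property
    def active(self) -> list[Connector]:
        return [c for c in self.connectors if c.active]

    def belts_present(self) -> set[str]:
        return {c.belt for c in self.connectors}


def build_porelock(
    geometry,
    laws: dict[str, InteractionForceLaw],
    deletions: Iterable[str] = (),
    rho: float = 0.0,
) -> ConnectorSet:
    """Assemble the pore-lock connector network.

    One connector per (belt, subunit pair) excluding deleted belts: the full
    WT set has 25 connectors (5 belts x 5 neighbouring subunit pairs).  A
    uniform strength reduction ``rho`` is applied to all remaining laws.
    ``geometry`` is used to validate that anchor residues lie on the TM1 rod.
    """
    deletions = set(deletions)
    unknown = deletions - set(BELTS)
    if unknown:
        raise ValueError(f"unknown belt label(s) in deletions: {sorted(unknown)}")
    kept = [b for b in BELTS if b not in deletions]
    missing = [b for b in kept if b not in laws]
    if missing:
        raise ValueError(f"no force law provided for belt(s): {missing}")
    if geometry is not None:
        lo, hi = geometry.tm1_residue_span
        for b in kept:
            for res in BELT_RESIDUES[b]:
                if not lo <= res <= hi:
                    raise ValueError(f"anchor residue {res} outside TM1 span {lo}..{hi}")
    connectors = []
    for belt in kept:
        ra, rb = BELT_RESIDUES[belt]
        law = apply_reduction(laws[belt], rho) if rho > 0 else laws[belt]
        for s in range(N_SUBUNITS):
            connectors.append(
                Connector(
                    subunit=s,
                    belt=belt,
                    residue_a=ra,
                    residue_b=rb,
                    law=law,
                    active=rho < 1.0,
                )
            )
    return ConnectorSet(connectors)


# ---------------------------------------------------------------------------
# Regularized connector energetics used by the static solver
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegularizedLaw:
    """A connector-table force law: capped repulsion, finite attraction range.

    Mirrors how the pore-lock enters the structural model as a table of
    force-displacement points: below ``r_cap`` (where the repulsive force
    reaches ``cap_factor`` times the peak attractive force) the force is
    held constant and the energy continues linearly, keeping Newton
    iterations from overflowing the r**-m term; beyond ``r_switch`` the
    interaction is smoothly switched off (smoothstep on the energy) and
    vanishes at ``r_cut``, reflecting the finite distance range over which
    the underlying pairwise interaction data exist.  Energies in pN·Å.
    """

    law: InteractionForceLaw
    r_cap: float
    f_cap: float  # pN, repulsive (positive)
    e_cap: float  # pN·Å at r_cap
    r_switch: float
    r_cut: float

    @classmethod
    def from_law(
        cls,
        law: InteractionForceLaw,
        cap_factor: float = 10.0,
        switch_start: float = 1.35,
        cutoff: float = 1.7,
    ) -> "RegularizedLaw":
        f_peak = peak_attractive_force(law)
        target = cap_factor * f_peak
        r_eq = law.r_eq

        def g(r: float) -> float:
            return lj_force(law, r) - target

        # repulsive branch is monotone decreasing on (0, r_eq)
        lo = r_eq * 1e-3
        while g(lo) < 0:  # pragma: no cover - pathological laws only
            lo *= 0.5
        r_cap = brentq(g, lo, r_eq, xtol=1e-12)
        e_cap = float(
            pair_energy_generic(law.A, law.B, law.m, law.n, r_cap) * PN_PER_KCAL_MOL_A
        )
        return cls(
            law=law,
            r_cap=float(r_cap),
            f_cap=float(target),
            e_cap=e_cap,
            r_switch=float(switch_start * r_eq),
            r_cut=float(cutoff * r_eq),
        )

    def _raw(self, r: float) -> tuple[float, float, float]:
        """(E, F, dF/dr) of the untapered law at r, in pN·Å / pN / pN/Å."""
        law = self.law
        e = float(
            pair_energy_generic(law.A, law.B, law.m, law.n, r) * PN_PER_KCAL_MOL_A
        )
        f = float(lj_force(law, r))
        dfdr = float(
            (-12.0 * law.A * law.m / r ** (law.m + 1.0)
             + 6.0 * law.B * law.n / r ** (law.n + 1.0))
            * PN_PER_KCAL_MOL_A
        )
        return e, f, dfdr

    def energy_force_stiffness(self, r: float) -> tuple[float, float, float]:
        """(energy pN·Å, force pN positive = repulsive, dF/dr pN/Å) at r."""
        if r < self.r_cap:
            return self.e_cap + self.f_cap * (self.r_cap - r), self.f_cap, 0.0
        if r >= self.r_cut:
            return 0.0, 0.0, 0.0
        e, f, dfdr = self._raw(r)
        if r <= self.r_switch:
            return e, f, dfdr
        # smoothstep switch-off of the energy: E~ = E * w(r), F~ = -dE~/dr
        span = self.r_cut - self.r_switch
        t = (r - self.r_switch) / span
        w = 1.0 - 3.0 * t * t + 2.0 * t**3
        dw = (-6.0 * t + 6.0 * t * t) / span
        d2w = (-6.0 + 12.0 * t) / span / span
        et = e * w
        ft = f * w - e * dw
        # dF~/dr = dF/dr * w + F*dw - (-F)*dw - E*d2w = dF/dr*w + 2F*dw... note E' = -F
        dft = dfdr * w + 2.0 * f * dw - e * d2w
        return et, ft, dft

    def energy_force(self, r: float) -> tuple[float, float]:
        """Return (energy pN·Å, force pN, positive = repulsive) at distance r."""
        e, f, _ = self.energy_force_stiffness(r)
        return e, f
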