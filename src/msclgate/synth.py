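"""Synthetic MD-style inputs: interaction curves, helix traces, geometries.

The continuum pipeline consumes three kinds of molecular-dynamics-derived
data: pairwise interaction energy/force vs distance curves for the pore-lock
residue pairs, stress-strain and load-unload traces for the four helices,
and closed/open channel geometries.  This module generates all of them with
seeded reproducibility and known ground-truth parameters, so every estimator
downstream (curve fitting, Young's modulus, elastic-limit detection, the
static solver) can be validated against the generating values.

Default well depths and equilibrium distances are the package's reference
study conditions: equilibrium distances equal the closed-state anchor
distances (the closed channel is exactly stress-free), G22N wells are
shallower by the per-belt peak-to-peak reduction fractions
{V16-G22: 82%, L19-L19: 43%, A20-G22: 0%, V23-V23: 31%, V23-G26: 40%} and
right-shifted by +0.5 Å (except L19-L19).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from . import helices as hx
from .forcelaws import (
    BELT_RESIDUES,
    BELTS,
    GENOTYPES,
    InteractionCurve,
    InteractionForceLaw,
    lj_energy,
    lj_force,
)
from .geometry import ChannelGeometry, ideal_geometry
from .units import PN_PER_KCAL_MOL_A

#: G22N per-belt peak-to-peak well-depth reduction fractions.
G22N_REDUCTION: dict[str, float] = {
    "V16-G22": 0.82,
    "L19-L19": 0.43,
    "A20-G22": 0.00,
    "V23-V23": 0.31,
    "V23-G26": 0.40,
}

#: G22N equilibrium-distance right-shift in Å (L19-L19 is not shifted).
G22N_SHIFT: dict[str, float] = {
    "V16-G22": 0.5,
    "L19-L19": 0.0,
    "A20-G22": 0.5,
    "V23-V23": 0.5,
    "V23-G26": 0.5,
}

#: Default WT well depths in kcal/mol.  V16-G22 is the deepest belt (it is
#: the contact with the largest mutational reduction); the set is calibrated
#: so the pore-lock reproduces the locked/open contrast of the scenario
#: table under the default geometry and displacement protocol.
DEFAULT_WELL_DEPTHS: dict[str, float] = {
    "V16-G22": 7.0,
    "L19-L19": 1.45,
    "A20-G22": 0.5,
    "V23-V23": 1.05,
    "V23-G26": 1.6,
}


@lru_cache(maxsize=1)
def closed_anchor_distances() -> dict[str, float]:
    """Anchor-to-anchor distance of each belt in the closed WT geometry."""
    geo = ideal_geometry("WT", "closed")
    out = {}
    for belt in BELTS:
        ra, rb = BELT_RESIDUES[belt]
        pa = geo.tm1_residue_point(0, ra)
        pb = geo.tm1_residue_point(1, rb)
        out[belt] = float(np.linalg.norm(pa - pb))
    return out


@dataclass
class SyntheticDefaults:
    """Ground-truth parameters behind every synthetic generator."""

    well_depths: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WELL_DEPTHS))
    equilibrium_distances: dict[str, float] = field(
        default_factory=lambda: dict(closed_anchor_distances())
    )
    g22n_reduction: dict[str, float] = field(default_factory=lambda: dict(G22N_REDUCTION))
    g22n_shift: dict[str, float] = field(default_factory=lambda: dict(G22N_SHIFT))
    moduli: dict[str, float] = field(default_factory=lambda: dict(hx.DEFAULT_MODULI))
    yield_strain: dict[str, float] = field(default_factory=lambda: dict(hx.DEFAULT_YIELD_STRAIN))
    yield_force: dict[str, float] = field(default_factory=lambda: dict(hx.DEFAULT_YIELD_FORCE))
    plastic_residual: float = 4.0  # Å of residual elongation past yield
    plastic_slope_fraction: float = 0.1
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for belt, depth in self.well_depths.items():
            if depth <= 0:
                raise ValueError(f"well depth for {belt} must be positive")
        for belt, r in self.equilibrium_distances.items():
            if r <= 0:
                raise ValueError(f"equilibrium distance for {belt} must be positive")

    def law(self, belt: str, genotype: str = "WT") -> InteractionForceLaw:
        """Ground-truth 12-6 law for one belt and genotype."""
        _check_pair_genotype(belt, genotype)
        depth = self.well_depths[belt]
        r_eq = self.equilibrium_distances[belt]
        if genotype == "G22N":
            depth = depth * (1.0 - self.g22n_reduction[belt])
            r_eq = r_eq + self.g22n_shift[belt]
        return InteractionForceLaw.from_well(depth, r_eq, pair=belt, genotype=genotype)

    def wt_laws(self) -> dict[str, InteractionForceLaw]:
        return {belt: self.law(belt, "WT") for belt in BELTS}


def _check_pair_genotype(pair: str, genotype: str) -> None:
    if pair not in BELTS:
        raise ValueError(f"unknown residue pair {pair!r}; expected one of {BELTS}")
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}; expected one of {GENOTYPES}")


def gen_interaction_curve(
    pair: str,
    genotype: str = "WT",
    n_points: int = 50,
    noise_sd: float = 0.0,
    seed: int = 0,
    defaults: SyntheticDefaults | None = None,
) -> InteractionCurve:
    """Sampled (distance, energy, force) curve for one belt and genotype.

    Distances span [0.8, 3] x r_eq and always include r_eq itself, so the
    sampled minimum of a noiseless curve equals the configured well depth
    exactly.  ``noise_sd`` is the Gaussian noise s.d. on energies in
    kcal/mol; forces receive independent noise of noise_sd * 69.48 pN.
    """
    defaults = defaults or SyntheticDefaults()
    _check_pair_genotype(pair, genotype)
    if n_points < 10:
        raise ValueError("n_points must be >= 10")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    law = defaults.law(pair, genotype)
    r_eq = law.r_eq
    r = np.linspace(0.8 * r_eq, 3.0 * r_eq, n_points)
    r[np.argmin(np.abs(r - r_eq))] = r_eq  # pin one sample at the well bottom
    energies = np.asarray(lj_energy(law, r), dtype=float)
    forces = np.asarray(lj_force(law, r), dtype=float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        energies = energies + rng.normal(0.0, noise_sd, r.size)
        forces = forces + rng.normal(0.0, noise_sd * PN_PER_KCAL_MOL_A, r.size)
    return InteractionCurve(
        pair=pair, genotype=genotype, distances=r, energies=energies, forces=forces
    )


def gen_stress_strain(
    helix: str,
    max_strain: float = 0.06,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_points: int = 60,
    defaults: SyntheticDefaults | None = None,
) -> hx.StressStrainCurve:
    """Linear-then-plastic stress-strain curve: sigma = E*eps up to the
    yield strain, then a branch with ``plastic_slope_fraction`` of E."""
    defaults = defaults or SyntheticDefaults()
    if helix not in hx.HELIX_NAMES:
        raise ValueError(f"unknown helix {helix!r}; expected one of {hx.HELIX_NAMES}")
    if not 0.0 < max_strain <= 0.5:
        raise ValueError("max_strain must lie in (0, 0.5]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    E = defaults.moduli[helix]
    eps_y = defaults.yield_strain[helix]
    eps = np.linspace(0.0, max_strain, n_points)
    if eps_y < max_strain:  # pin a sample at the knee
        eps[np.argmin(np.abs(eps - eps_y))] = eps_y
    sig = np.where(
        eps <= eps_y,
        E * eps,
        E * eps_y + defaults.plastic_slope_fraction * E * (eps - eps_y),
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sig = sig + rng.normal(0.0, noise_sd, eps.size)
    return hx.StressStrainCurve(helix=helix, strains=eps, stresses=sig)


def gen_load_unload(
    helix: str,
    peak_strain: float,
    seed: int = 0,
    noise_sd: float = 0.0,
    n_points: int = 40,
    defaults: SyntheticDefaults | None = None,
) -> hx.LoadUnloadTrace:
    """Force-elongation loading/unloading trace for one helix.

    Loading is linear to the yield point (slope = yield force / yield
    elongation at the trace reference length, 50 Å for TM1), then continues
    on the reduced plastic slope.  Unloading retraces to zero residual when
    the peak stayed within the elastic region and otherwise terminates at
    the configured plastic residual elongation (default 4 Å).
    """
    defaults = defaults or SyntheticDefaults()
    if helix not in hx.HELIX_NAMES:
        raise ValueError(f"unknown helix {helix!r}; expected one of {hx.HELIX_NAMES}")
    if peak_strain < 0:
        raise ValueError("peak_strain must be >= 0")
    L0 = hx.TRACE_REFERENCE_LENGTH[helix]
    x_y = defaults.yield_strain[helix] * L0
    k = defaults.yield_force[helix] / x_y
    x_p = peak_strain * L0
    if x_p == 0.0:
        x = np.zeros(2)
        f = np.zeros(2)
        return hx.LoadUnloadTrace(helix=helix, elongations=x, forces=f, peak_index=0)

    def f_load(x: np.ndarray) -> np.ndarray:
        return np.where(
            x <= x_y,
            k * x,
            k * x_y + defaults.plastic_slope_fraction * k * (x - x_y),
        )

    x_up = np.linspace(0.0, x_p, n_points)
    if x_y < x_p:  # pin a sample at the knee so the break is in the data
        x_up[np.argmin(np.abs(x_up - x_y))] = x_y
    f_up = f_load(x_up)
    if x_p <= x_y:
        x_dn = x_up[::-1][1:]
        f_dn = f_up[::-1][1:]
    else:
        residual = defaults.plastic_residual
        x_dn = np.linspace(x_p, residual, n_points)[1:]
        f_dn = f_up[-1] * (x_dn - residual) / (x_p - residual)
    x = np.concatenate([x_up, x_dn])
    f = np.concatenate([f_up, f_dn])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = np.clip(f + rng.normal(0.0, noise_sd, f.size), 0.0, None)
    return hx.LoadUnloadTrace(
        helix=helix, elongations=x, forces=f, peak_index=n_points - 1
    )


def gen_geometry(genotype: str = "WT", state: str = "closed") -> ChannelGeometry:
    """Idealized pentamer geometry (see :func:`msclgate.geometry.ideal_geometry`)."""
    return ideal_geometry(genotype=genotype, state=state)
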