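"""The eleven in-silico gating scenarios and their feasibility analysis.

Each scenario pulls the N-terminal helices (models 1-5) or the N-termini
plus the TM1 cytoplasmic ends (models 6-11) radially outward, under a
uniform pore-lock strength reduction rho and optional belt deletions
(ΔG26 removes the V23-G26 belt, ΔV16 the V16-G22 belt).  Model 11 is the
G22N mutant: per-belt reductions equal to the measured peak-to-peak
well-depth losses instead of a uniform rho.

The prescribed pull amplitude is calibrated once per pulling protocol so
that the *unobstructed* channel (no connectors) ends exactly at the 28 Å
open-target diameter; whether a given scenario actually opens is then
decided by the statics of the pore-lock.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import fem
from .forcelaws import (
    BELTS,
    ConnectorSet,
    InteractionForceLaw,
    apply_reduction,
    build_porelock,
    fit_force_law,
)
from .geometry import ChannelGeometry, N_SUBUNITS
from .helices import HelixSpec, axial_stress, default_helix_specs
from .synth import G22N_REDUCTION, SyntheticDefaults, gen_geometry, gen_interaction_curve
from .units import pn_a2_to_mpa

PULL_N = "N"
PULL_N_TM1 = "N+TM1"

DELTA_G26 = "V23-G26"
DELTA_V16 = "V16-G22"


@dataclass(frozen=True)
class ScenarioSpec:
    """One in-silico gating model."""

    identifier: int | str
    genotype: str = "WT"
    rho: float = 0.0
    deletions: frozenset[str] = frozenset()
    pulling: str = PULL_N
    per_belt_rho: tuple[tuple[str, float], ...] | None = None
    increments: int = 50
    use_g22n_geometry: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if self.pulling not in (PULL_N, PULL_N_TM1):
            raise ValueError(f"unknown pulling set {self.pulling!r}")


#: Table-1/2 scenario definitions (identifier -> configuration).
_SCENARIOS: dict[int, dict] = {
    1: dict(pulling=PULL_N, rho=0.0, deletions=frozenset({DELTA_G26})),
    2: dict(pulling=PULL_N, rho=0.5, deletions=frozenset({DELTA_G26})),
    3: dict(pulling=PULL_N, rho=0.8, deletions=frozenset({DELTA_G26})),
    4: dict(pulling=PULL_N, rho=0.9, deletions=frozenset({DELTA_G26})),
    5: dict(pulling=PULL_N, rho=0.98, deletions=frozenset()),
    6: dict(pulling=PULL_N_TM1, rho=0.0, deletions=frozenset()),
    7: dict(pulling=PULL_N_TM1, rho=0.5, deletions=frozenset()),
    8: dict(pulling=PULL_N_TM1, rho=0.5, deletions=frozenset({DELTA_V16})),
    9: dict(pulling=PULL_N_TM1, rho=0.5, deletions=frozenset({DELTA_G26})),
    10: dict(pulling=PULL_N_TM1, rho=0.75, deletions=frozenset()),
    11: dict(
        pulling=PULL_N_TM1,
        rho=0.0,
        deletions=frozenset(),
        genotype="G22N",
        per_belt_rho=tuple(sorted(G22N_REDUCTION.items())),
    ),
}


def make_scenario(identifier: int, increments: int = 50) -> ScenarioSpec:
    """The configuration of in-silico model 1..11."""
    if identifier not in _SCENARIOS:
        raise ValueError(f"unknown scenario id {identifier!r}; expected 1..11")
    return ScenarioSpec(identifier=identifier, increments=increments, **_SCENARIOS[identifier])


@dataclass
class ScenarioResult:
    """Outputs of one scenario run.  Stresses in MPa; absent metrics are None."""

    identifier: int | str
    final_diameter: float
    closed_diameter: float
    opened: bool
    threshold_stress: float | None
    open_state_stress: float | None
    helix_max_stress: dict[str, float]
    feasibility: dict[str, str] = field(default_factory=dict)
    converged: bool = True
    trajectory: fem.EquilibriumTrajectory | None = field(default=None, repr=False)


def fitted_wt_laws(defaults: SyntheticDefaults) -> dict[str, InteractionForceLaw]:
    """Per-belt WT force laws obtained by fitting the noiseless synthetic
    interaction curves (exact generator/estimator inversion)."""
    laws = {}
    for belt in BELTS:
        curve = gen_interaction_curve(belt, "WT", noise_sd=0.0, defaults=defaults)
        laws[belt], _ = fit_force_law(curve, fix_exponents=True)
    return laws


def scenario_connectors(
    spec: ScenarioSpec, geometry: ChannelGeometry, defaults: SyntheticDefaults
) -> ConnectorSet:
    """Pore-lock for a scenario: fitted WT laws with the scenario's uniform
    reduction, or per-belt reductions for the G22N model."""
    laws = fitted_wt_laws(defaults)
    if spec.per_belt_rho is not None:
        per = dict(spec.per_belt_rho)
        laws = {
            belt: apply_reduction(law, per.get(belt, 0.0)) for belt, law in laws.items()
        }
        return build_porelock(geometry, laws, deletions=spec.deletions, rho=0.0)
    return build_porelock(geometry, laws, deletions=spec.deletions, rho=spec.rho)


def make_pull_bcs(
    mesh: fem.Mesh, pulling: str, amplitude: float, increments: int
) -> fem.BoundaryConditionSet:
    """Displacement-controlled radial pull.

    Pulled nodes (the N-terminal outer ends, plus the TM1 cytoplasmic ends
    for the N+TM1 protocol) translate radially outward by ``amplitude`` Å,
    applied linearly over the increments.  TM2 tops and C-terminal ends are
    fixed.
    """
    fixed = [mesh.role_nodes[("tm2_top", s)] for s in range(N_SUBUNITS)]
    fixed += [mesh.role_nodes[("c_end", s)] for s in range(N_SUBUNITS)]
    pulled: list[int] = [mesh.role_nodes[("n_outer", s)] for s in range(N_SUBUNITS)]
    if pulling == PULL_N_TM1:
        pulled += [mesh.role_nodes[("tm1_bottom", s)] for s in range(N_SUBUNITS)]
    elif pulling != PULL_N:
        raise ValueError(f"unknown pulling set {pulling!r}")
    t = np.linspace(0.0, 1.0, increments + 1)
    paths = {}
    for node in pulled:
        p0 = mesh.nodes[node]
        e_r = np.array([p0[0], p0[1], 0.0])
        e_r = e_r / np.linalg.norm(e_r)
        paths[node] = p0[None, :] + amplitude * t[:, None] * e_r[None, :]
    return fem.BoundaryConditionSet(fixed=sorted(set(fixed)), paths=paths, increments=increments)


_PULL_CACHE: dict[tuple, float] = {}


def calibrate_pull_amplitude(
    mesh: fem.Mesh,
    pulling: str,
    target_diameter: float = 28.0,
    cache_key: tuple | None = None,
) -> float:
    """Pull amplitude that opens the unobstructed channel to the target.

    Solves the connector-free model at full actuation for trial amplitudes
    and root-finds the amplitude whose final constriction diameter equals
    ``target_diameter``.  Without connectors the response is elastic, so a
    single load increment suffices.
    """
    if cache_key is not None and cache_key in _PULL_CACHE:
        return _PULL_CACHE[cache_key]

    def final_diam(amplitude: float) -> float:
        bcs = make_pull_bcs(mesh, pulling, amplitude, increments=1)
        traj = fem.solve(mesh, None, bcs, symmetry=True)
        return traj.final_diameter

    closed = fem.pore_diameter(mesh.nodes, mesh.window_nodes())
    lo = 0.5 * (target_diameter - closed)
    hi = 1.5 * (target_diameter - closed)
    f = lambda a: final_diam(a) - target_diameter
    flo, fhi = f(lo), f(hi)
    while flo > 0:
        lo *= 0.5
        flo = f(lo)
    while fhi < 0:
        hi *= 1.3
        fhi = f(hi)
    amp = float(brentq(f, lo, hi, xtol=1e-3))
    if cache_key is not None:
        _PULL_CACHE[cache_key] = amp
    return amp


def run_scenario(
    spec: ScenarioSpec,
    defaults: SyntheticDefaults | None = None,
    specs: dict[str, HelixSpec] | None = None,
    elements_per_helix: int = 4,
    loop_stiffness: float = fem.DEFAULT_LOOP_STIFFNESS,
    bending_scale: float = fem.DEFAULT_BENDING_SCALE,
    junction_scale: float = fem.DEFAULT_JUNCTION_SCALE,
    tol: float | None = None,
    keep_trajectory: bool = False,
) -> ScenarioResult:
    """Build geometry and pore-lock, apply the scenario's reductions and
    deletions, run the displacement protocol and extract the metrics."""
    defaults = defaults or SyntheticDefaults()
    specs = specs or default_helix_specs(defaults.moduli)
    genotype = spec.genotype if spec.use_g22n_geometry else "WT"
    geometry = gen_geometry(genotype, "closed")
    mesh = fem.discretize(geometry, specs, elements_per_helix, loop_stiffness=loop_stiffness, bending_scale=bending_scale, junction_scale=junction_scale)
    connectors = scenario_connectors(spec, geometry, defaults)
    moduli_key = tuple(sorted((h, s.youngs_modulus) for h, s in specs.items()))
    amp = calibrate_pull_amplitude(
        mesh,
        spec.pulling,
        cache_key=(genotype, spec.pulling, elements_per_helix, loop_stiffness, bending_scale, junction_scale, moduli_key),
    )
    bcs = make_pull_bcs(mesh, spec.pulling, amp, spec.increments)
    try:
        traj = fem.solve(mesh, connectors, bcs, tol=tol, symmetry=True)
    except Exception as exc:  # annotate solver failures with the scenario id
        raise RuntimeError(f"scenario {spec.identifier} failed: {exc}") from exc
    thr, opn, opened = fem.tm1_stress_metrics(traj)
    helix_max = {
        h: pn_a2_to_mpa(traj.helix_max_stress(h)) for h in ("N", "TM1", "TM2", "C")
    }
    result = ScenarioResult(
        identifier=spec.identifier,
        final_diameter=traj.final_diameter,
        closed_diameter=traj.closed_diameter,
        opened=opened,
        threshold_stress=None if thr is None else pn_a2_to_mpa(thr),
        open_state_stress=None if opn is None else pn_a2_to_mpa(opn),
        helix_max_stress=helix_max,
        converged=traj.converged,
        trajectory=traj if keep_trajectory else None,
    )
    result.feasibility = feasibility_check(result, specs)
    return result


def feasibility_check(
    result: ScenarioResult, specs: dict[str, HelixSpec]
) -> dict[str, str]:
    """Compare each helix's peak stress with its elastic capacity.

    Capacity = yield force / (pi r²) expressed in MPa; a helix whose maximum
    stress exceeds it would unfold irreversibly rather than spring back.
    """
    verdicts = {}
    for helix, max_mpa in result.helix_max_stress.items():
        if helix not in specs:
            raise ValueError(f"missing spec for helix {helix}")
        spec = specs[helix]
        capacity = pn_a2_to_mpa(axial_stress(spec.yield_force, spec.radius))
        verdicts[helix] = (
            "exceeds elastic limit" if max_mpa > capacity else "within elastic limit"
        )
    return verdicts


def tabulate(results: list[ScenarioResult]) -> pd.DataFrame:
    """Tables-1/2-style report: one row per scenario.

    Absent stress metrics (pore never opened) are NaN in the DataFrame and
    rendered as '-' by the TSV writer.
    """
    rows = []
    for r in results:
        rows.append(
            {
                "model": r.identifier,
                "pore_size_A": r.final_diameter,
                "threshold_stress_MPa": np.nan
                if r.threshold_stress is None
                else r.threshold_stress,
                "open_state_stress_MPa": np.nan
                if r.open_state_stress is None
                else r.open_state_stress,
                "opened": r.opened,
            }
        )
    cols = ["model", "pore_size_A", "threshold_stress_MPa", "open_state_stress_MPa", "opened"]
    return pd.DataFrame(rows, columns=cols)
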