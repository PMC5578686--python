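"""Elastic characterization of the MscL helices.

Each helix (N-terminal amphipathic helix, pore-lining TM1, TM2, C-terminal
bundle helix) is treated as a homogeneous elastic rod of radius 2.5 Å.
Young's moduli are estimated from stress-strain curves as the initial
(<= 6% strain) slope; the elastic limit and loading reversibility of a helix
are read off load-unload force-elongation traces: a helix that recovers its
initial length on unloading responded elastically, one left with residual
elongation unfolded plastically.

Units: stress in pN/Å² (1 pN/Å² = 100 MPa), force in pN, lengths in Å,
strain dimensionless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

HELIX_NAMES = ("N", "TM1", "TM2", "C")

#: Rod centerline lengths in Å.
HELIX_LENGTHS: dict[str, float] = {"N": 18.65, "TM1": 47.33, "TM2": 42.51, "C": 36.06}

ROD_RADIUS = 2.5  # Å
POISSON_RATIO = 0.48

#: Default Young's moduli in pN/Å² (1 pN/Å² = 100 MPa).  Chosen to satisfy
#: the observed stiffness ordering E(C) > E(TM1) ~ E(TM2) > 4*E(N).
DEFAULT_MODULI: dict[str, float] = {"N": 4.9, "TM1": 22.0, "TM2": 20.0, "C": 30.0}

#: Default yield strains (onset of plastic unfolding).
DEFAULT_YIELD_STRAIN: dict[str, float] = {"N": 0.20, "TM1": 0.30, "TM2": 0.30, "C": 0.30}

#: Default yield forces in pN.  TM1's ~400 pN comes from steered-MD-style
#: load-unload traces; the others are conventions consistent with their
#: moduli and yield strains at the 19.6 Å² rod cross-section.
DEFAULT_YIELD_FORCE: dict[str, float] = {"N": 20.0, "TM1": 400.0, "TM2": 360.0, "C": 500.0}

#: Reference lengths (Å) for strain arithmetic on load-unload traces.  TM1's
#: stretched segment has reference length 50 Å (consistent with all printed
#: (length, strain) pairs, e.g. 60.0 Å <-> 20%), distinct from the 47.33 Å
#: rod length used by the continuum model.
TRACE_REFERENCE_LENGTH: dict[str, float] = {
    "N": HELIX_LENGTHS["N"],
    "TM1": 50.0,
    "TM2": HELIX_LENGTHS["TM2"],
    "C": HELIX_LENGTHS["C"],
}


def rod_area(radius: float = ROD_RADIUS) -> float:
    """Cross-sectional area pi*r² in Å²."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    return math.pi * radius * radius


@dataclass(frozen=True)
class HelixSpec:
    """Material and geometric parameters of one helix rod."""

    name: str
    length: float
    youngs_modulus: float  # pN/Å²
    radius: float = ROD_RADIUS
    poisson: float = POISSON_RATIO
    yield_strain: float = 0.30
    yield_force: float = 400.0  # pN

    def __post_init__(self) -> None:
        if self.length <= 0 or self.radius <= 0 or self.youngs_modulus <= 0:
            raise ValueError("length, radius and modulus must be positive")
        if not 0.0 < self.poisson < 0.5:
            raise ValueError("Poisson ratio must lie in (0, 0.5)")

    @property
    def area(self) -> float:
        return rod_area(self.radius)

    @property
    def second_moment(self) -> float:
        """Area moment of inertia pi*r^4/4 in Å^4."""
        return math.pi * self.radius**4 / 4.0


def default_helix_specs(moduli: dict[str, float] | None = None) -> dict[str, HelixSpec]:
    """The four default helix rods, optionally with overridden moduli."""
    moduli = {**DEFAULT_MODULI, **(moduli or {})}
    return {
        name: HelixSpec(
            name=name,
            length=HELIX_LENGTHS[name],
            youngs_modulus=moduli[name],
            yield_strain=DEFAULT_YIELD_STRAIN[name],
            yield_force=DEFAULT_YIELD_FORCE[name],
        )
        for name in HELIX_NAMES
    }


@dataclass
class StressStrainCurve:
    """Sampled stress (pN/Å²) vs engineering strain for one helix."""

    helix: str
    strains: np.ndarray
    stresses: np.ndarray

    def __post_init__(self) -> None:
        self.strains = np.asarray(self.strains, dtype=float)
        self.stresses = np.asarray(self.stresses, dtype=float)
        if self.strains.shape != self.stresses.shape:
            raise ValueError("strain/stress arrays must have equal length")
        if self.strains.size and self.strains[0] < 0:
            raise ValueError("strains must start at >= 0")


@dataclass
class LoadUnloadTrace:
    """Force-elongation samples of a loading branch followed by unloading."""

    helix: str
    elongations: np.ndarray  # Å
    forces: np.ndarray  # pN, >= 0
    peak_index: int  # index of the peak-elongation sample

    def __post_init__(self) -> None:
        self.elongations = np.asarray(self.elongations, dtype=float)
        self.forces = np.asarray(self.forces, dtype=float)
        if self.elongations.shape != self.forces.shape:
            raise ValueError("elongation/force arrays must have equal length")
        if np.any(self.forces < -1e-9):
            raise ValueError("forces must be nonnegative")
        if not 0 <= self.peak_index < self.elongations.size:
            raise ValueError("peak index out of range")

    @property
    def loading(self) -> tuple[np.ndarray, np.ndarray]:
        i = self.peak_index
        return self.elongations[: i + 1], self.forces[: i + 1]

    @property
    def unloading(self) -> tuple[np.ndarray, np.ndarray]:
        i = self.peak_index
        return self.elongations[i:], self.forces[i:]


def engineering_strain(length: float, reference_length: float) -> float:
    """(L - L0) / L0."""
    if reference_length <= 0:
        raise ValueError("reference length must be positive")
    return (length - reference_length) / reference_length


def axial_stress(force: float, radius: float = ROD_RADIUS) -> float:
    """Uniaxial stress force / (pi r²) in pN/Å²."""
    return force / rod_area(radius)


def youngs_modulus(curve: StressStrainCurve, strain_cap: float = 0.06) -> float:
    """Initial-slope Young's modulus in pN/Å².

    Least-squares line through the origin over samples with strain <= cap:
    E = sum(sigma*eps) / sum(eps²).
    """
    mask = (curve.strains <= strain_cap) & (curve.strains > 0)
    if mask.sum() < 3:
        raise ValueError(
            f"need >= 3 samples with 0 < strain <= {strain_cap}, got {int(mask.sum())}"
        )
    eps = curve.strains[mask]
    sig = curve.stresses[mask]
    return float(eps @ sig / (eps @ eps))


def elastic_limit(
    trace: LoadUnloadTrace | StressStrainCurve,
    reference_length: float | None = None,
    slope_drop: float = 0.5,
) -> tuple[float, float]:
    """Detect the elastic limit as the slope-break point of the loading branch.

    Returns (limit force pN, limit strain) at the largest strain before the
    local slope first drops below ``slope_drop`` times the initial slope.
    Raises ``ValueError('limit not reached')`` for traces without a break.

    For a :class:`LoadUnloadTrace` the loading branch is analysed and
    ``reference_length`` converts elongation to strain (defaults to the
    helix's trace reference length).
    """
    if isinstance(trace, StressStrainCurve):
        x, y = trace.strains, trace.stresses
        to_strain = 1.0
    else:
        if reference_length is None:
            reference_length = TRACE_REFERENCE_LENGTH[trace.helix]
        if reference_length <= 0:
            raise ValueError("reference length must be positive")
        x, y = trace.loading
        to_strain = 1.0 / reference_length
    if x.size < 3:
        raise ValueError("loading branch too short")
    slopes = np.diff(y) / np.diff(x)
    # initial slope from the first decile of the loading branch
    k0 = np.mean(slopes[: max(2, slopes.size // 10)])
    below = np.nonzero(slopes < slope_drop * k0)[0]
    if below.size == 0:
        raise ValueError("limit not reached")
    i = int(below[0])  # last sample before the slope break
    return float(y[i]), float(x[i] * to_strain)


def classify_reversibility(
    trace: LoadUnloadTrace, residual_tol: float = 1.0
) -> tuple[str, float]:
    """Classify an unloading branch as elastic or plastic.

    Returns ("elastic"|"plastic", residual elongation in Å at zero force).
    Elastic iff |residual| <= residual_tol.
    """
    x, f = trace.unloading
    if x.size < 1:
        raise ValueError("trace has no unloading branch")
    if abs(f[-1]) > 1e-6 and x.size < 2:
        raise ValueError("unloading branch does not reach zero force")
    residual = float(x[-1])
    label = "elastic" if abs(residual) <= residual_tol else "plastic"
    return label, residual
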