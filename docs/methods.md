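# Methods

## The model

MscL, the bacterial mechanosensitive channel of large conductance, is a
homopentamer whose pore-lining TM1 helices form a hydrophobic constriction
(the "pore-lock") of inter-subunit van der Waals contacts near residues
V16–G26.  `msclgate` asks a statics question: if the cytoplasmic
N-terminal helices (alone, or together with the TM1 cytoplasmic ends) are
displaced radially outward — as a magnetically actuated nanovalve would do
— does the pore-lock yield and let the pore open to its ~28 Å conducting
diameter, and what stresses do the helices carry on the way?

The channel is a rod-and-connector structure:

- **Rods.**  Each helix (N-terminal, TM1, TM2, C-terminal; lengths 18.65,
  47.33, 42.51, 36.06 Å; radius r = 2.5 Å; Poisson ratio 0.48, recorded
  but not entering the rod stiffness) is a polyline of two-node axial
  segments with stiffness E·A/L (A = πr²) and discrete bending hinges of
  stiffness E·I_eff/l with rest angle θ₀ and energy ½k(θ−θ₀)².
  Default Young's moduli: N 0.49, TM1 2.2, TM2 2.0, C 3.0 GPa — the
  C-terminal helix is stiffest and both transmembrane helices are more
  than four times stiffer than the N-terminus.
- **Connectors.**  The pore-lock is 25 two-point connectors (5 belts ×
  5 neighbouring subunit pairs) between TM1 residues A20–G22, V23–G26,
  L19–L19, V23–V23 and V16–G22, acting along the line of centers with a
  generalized Lennard-Jones force law F(r) = 12A/rᵐ − 6B/rⁿ
  (repulsive positive).  For the standard exponents (m, n) = (13, 7) this
  is the exact negative gradient of E(r) = A/r¹² − B/r⁶.
- **Boundary conditions.**  TM2 periplasmic tops and C-terminal end nodes
  are fixed; each TM1 top is tethered to its TM2 top by a soft axial
  spring (10 pN/Å) standing in for the periplasmic loop.  Pulled nodes
  (N-terminal outer ends; plus TM1 bottom nodes in the N+TM1 protocol)
  move radially outward in displacement increments.

Gating is solved as displacement-controlled nonlinear statics: at every
increment the free nodes minimize the total potential energy (stretching +
bending + connector interaction) by damped Newton iteration with an
analytic Hessian, warm-started from the previous increment, with step
bisection on failure.  The production solver restricts the solution to
the C5-symmetric subspace (subunit 0 is the unknown; the others are its
72°-rotated images), selecting the concerted iris-like gating mode.  The
unrestricted solver is available and exercised in the tests; at the
unlocking bifurcation it follows asymmetric unzipping branches (pairs of
subunits peel sequentially), a physically interesting regime that the
symmetric pore-diameter bookkeeping of this analysis does not describe.

## Pull calibration

The pull amplitude is not a free parameter: for each protocol it is the
amplitude at which the *unobstructed* channel (connectors removed) ends
exactly at the 28 Å open-target constriction, found by root-finding over
connector-free solves.  Whether a scenario actually opens is then decided
entirely by the pore-lock.

## Numerical choices

- Units: Å, pN, pN·Å, pN/Å² internally (1 pN/Å² = 100 MPa;
  1 kcal/mol/Å = 69.48 pN).  Reports print MPa.
- Residual tolerance 1e-6 × E_TM1·A ≈ 4e-4 pN (inf-norm of the free-node
  force imbalance); max 100 Newton iterations per increment, up to 5 step
  bisections.
- Connector tables: the short-range repulsion is capped at 10× the peak
  attractive force (energy continues linearly), and the attraction is
  smoothly switched off between 1.35·r_eq and 1.7·r_eq — connector data
  exist only over a finite distance range, and an infinite tail lets the
  pentamer "ride" a belt at peak attraction by twisting azimuthally
  instead of breaking it.
- Bending rigidity uses an effective second moment 10.5 × πr⁴/4.  The
  thin-rod value (EI ≈ 675 pN·Å²) understates the bending rigidity of an
  α-helix (persistence length ~100 nm ⇒ EI ≈ 4×10³ pN·Å²); the precise
  multiplier was fixed together with the well depths in the calibration
  below.  The N/TM1 joint hinge uses 5 × the N-terminus' thin-rod value:
  the joint region is a flexible hinge, much softer than the helix
  interior, but stiff enough that the open state is unique rather than a
  family of tilted equilibria.
- Mean TM1 stress is the arclength-weighted mean of |element axial
  stress|; a per-element mean would dilute under mesh refinement.
- Pore diameter = 2 × the minimum radial distance to the channel axis
  over TM1 residues 19–26 (all subunits).
- Opening bookkeeping: a run "opened" if the final diameter ≥ 25 Å; the
  onset of significant expansion is the first increment past
  closed + 25% of (28 − closed); the threshold stress is the largest mean
  TM1 stress up to the onset, and the open-state stress is the mean TM1
  stress at the last increment.  Both are reported absent when the pore
  never opened.
- Default discretization: 4 uniform elements per helix plus mandatory TM1
  nodes at every belt-anchor and constriction-window residue; 50
  displacement increments (results are identical at 16, 24 and 50).

## Synthetic data: what it emulates, and what it does not

The generators stand in for molecular-dynamics outputs with known ground
truth:

- **Interaction curves** are 12-6 wells sampled over [0.8, 3]·r_eq with a
  sample pinned at r_eq, optional i.i.d. Gaussian noise, and seeded
  reproducibility.  G22N curves scale the well depth by the per-belt
  peak-to-peak reductions {V16–G22 82%, L19–L19 43%, A20–G22 0%,
  V23–V23 31%, V23–G26 40%} and shift the equilibrium +0.5 Å to the right
  (except L19–L19).
- **Helix traces** are linear-elastic to a yield strain, then a 10%-slope
  plastic branch; load-unload traces retrace to zero residual inside the
  elastic region and terminate at a 4 Å residual beyond it (TM1: 400 pN /
  30% strain elastic limit at the 50 Å trace reference length — distinct
  from the 47.33 Å rod length, and both are kept).
- **Geometries** are ideal 5-fold-symmetric pentamers: straight tilted
  TM1 rods whose residue-19 ring sets the closed constriction (8 Å WT,
  11 Å G22N) with the open target at 28 Å; helix polyline lengths equal
  the declared rod lengths exactly.

Real MD data are not i.i.d.-noisy, pairwise interactions are not exactly
12-6, and real helices are neither straight nor piecewise-linear elastic;
passing tests show that the estimators invert these idealized generators
and that the statics machinery is correct, not that the pipeline would
reproduce any particular all-atom simulation.

## Calibration of the pore-lock (study conditions)

The absolute well depths of the five belts are not published; only the
mutant reduction percentages, the closed/open geometry and the qualitative
scenario table are.  The defaults

    V16–G22 7.0, L19–L19 1.45, A20–G22 0.5, V23–V23 1.05, V23–G26 1.6
    (kcal/mol; equilibrium distances = closed-state anchor distances,
     so the closed channel is exactly stress-free)

were frozen after a parameter study so that one fixed configuration
reproduces the full locked/open contrast: N-only pulling opens the pore
only with ≥80% strength reduction plus the V23–G26 deletion (or a 98%
uniform reduction), N+TM1 pulling opens it with 50% reduction plus either
single-belt deletion or with a 75% uniform reduction, and the G22N
per-belt reductions alone unlock it while a uniform 50% reduction does
not.  Depths of several kcal/mol are plausible for residue-level contacts
(each belt aggregates many atomic pair interactions).  Two structural
features carry the mutant contrast: the V16–G22 belt must dominate the
wild-type lock (it is 82% weakened in G22N, and shields the upper belts
from the bottom-drag demand), and the unreduced A20–G22 belt must be
weak.  The calibration is specific to the default mesh; at finer TM1
discretizations the bottom-drag demand rises and the marginal locked
cases (uniform 50%, N+TM1) unlock.

## Known limitations

- Locked N+TM1 runs end near 14–15 Å rather than ~9 Å: when the TM1
  bottom node itself is displacement-controlled to the full open
  position, window residues a few Å up the rod are dragged outward by
  inextensibility — a geometric floor of the rod representation.
- Helix stresses are one to two decades below solid-continuum values
  reported for equivalent scenarios (mean TM1 threshold stresses here are
  ~4–40 MPa): stress magnitudes depend strongly on anchoring and element
  formulation, which is why the analysis treats stress ordering
  (threshold ≥ open-state; TM1 within its elastic capacity for N+TM1
  pulling; N-terminus overloaded when an 80%-weakened lock is opened
  through it alone) rather than magnitudes as the reportable result.
- No membrane, no solvent, no dynamics, no contact between rods; the
  pore-lock is van der Waals only.
- The locked, partially-engaged states are not mesh-converged at
  desk-scale resolutions (the fully locked and fully open states are);
  the default mesh is part of the frozen study conditions.
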