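"""Readers, writers and run configuration.

All tabular data travel as TSV with explicit unit-bearing column names
(``distance_A``, ``energy_kcal_mol``, ``force_pN``, ``strain``,
``stress_pN_A2``, ``elongation_A``); geometries as JSON (exact) or PDB
(pseudo-atoms, one CA per centerline point, chains A-E, 1e-3 Å precision);
fitted force laws and scenario reports as JSON with sorted keys.  Readers
validate and reject rather than coerce: missing columns, duplicate
distances and non-numeric cells are reported with row-level diagnostics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .forcelaws import InteractionCurve, InteractionForceLaw
from .geometry import ChannelGeometry
from .helices import HELIX_NAMES, LoadUnloadTrace, StressStrainCurve
from .units import PN_PER_KCAL_MOL_A

CHAIN_IDS = "ABCDE"

#: 3-letter pseudo-residue names used for helix segments in PDB output.
HELIX_RESNAMES = {"N": "NTR", "TM1": "TM1", "TM2": "TM2", "C": "CTR"}
RESNAME_TO_HELIX = {v: k for k, v in HELIX_RESNAMES.items()}


# ---------------------------------------------------------------------------
# Interaction curves
# ---------------------------------------------------------------------------


def _read_table(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, comment="#")
    return df, meta


def _numeric_column(df: pd.DataFrame, col: str, path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = np.nonzero(vals.isna().to_numpy() & df[col].notna().to_numpy())[0]
    if bad.size:
        raise ValueError(
            f"{path}: non-numeric value(s) in column {col!r} at data row(s) "
            f"{[int(b) + 1 for b in bad[:5]]}"
        )
    if vals.isna().any():
        rows = [int(r) + 1 for r in np.nonzero(vals.isna().to_numpy())[0][:5]]
        raise ValueError(f"{path}: missing value(s) in column {col!r} at row(s) {rows}")
    return vals.to_numpy(dtype=float)


def read_curve_file(path: str | Path) -> InteractionCurve:
    """Read a distance/energy/force table into an :class:`InteractionCurve`.

    Requires a ``distance_A`` column and at least one of ``energy_kcal_mol``
    / ``force_pN``; rows are sorted by distance; duplicate distances are
    rejected with their row numbers.
    """
    df, meta = _read_table(path)
    if "distance_A" not in df.columns:
        raise ValueError(f"{path}: missing required column 'distance_A'")
    channels = [c for c in ("energy_kcal_mol", "force_pN") if c in df.columns]
    if not channels:
        raise ValueError(
            f"{path}: need at least one of columns 'energy_kcal_mol', 'force_pN'"
        )
    r = _numeric_column(df, "distance_A", path)
    order = np.argsort(r, kind="stable")
    r = r[order]
    dup = np.nonzero(np.diff(r) == 0)[0]
    if dup.size:
        raise ValueError(
            f"{path}: duplicate distance value(s) at sorted row(s) "
            f"{[int(d) + 1 for d in dup[:5]]}"
        )
    kwargs = {}
    if "energy_kcal_mol" in channels:
        kwargs["energies"] = _numeric_column(df, "energy_kcal_mol", path)[order]
    if "force_pN" in channels:
        kwargs["forces"] = _numeric_column(df, "force_pN", path)[order]
    return InteractionCurve(
        pair=meta.get("pair", ""),
        genotype=meta.get("genotype", "WT"),
        distances=r,
        **kwargs,
    )


def write_curve_file(curve: InteractionCurve, path: str | Path) -> None:
    path = Path(path)
    cols = {"distance_A": curve.distances}
    if curve.energies is not None:
        cols["energy_kcal_mol"] = curve.energies
    if curve.forces is not None:
        cols["force_pN"] = curve.forces
    with open(path, "w") as fh:
        fh.write(f"# pair: {curve.pair}\n# genotype: {curve.genotype}\n")
        pd.DataFrame(cols).to_csv(fh, sep="\t", index=False, float_format="%.10g")


def validate_curve_consistency(curve: InteractionCurve, rtol: float = 0.1) -> bool:
    """Check that the force channel matches -dE/dr of the energy channel.

    Central differences of the sampled energies are compared pointwise with
    the force samples, normalized by the local magnitude (floored at 1% of
    the peak force so the flat tail does not dominate); the curve passes
    when the 90th percentile of the deviations is below ``rtol``.  Curves
    with a single channel pass trivially.
    """
    if curve.energies is None or curve.forces is None:
        return True
    fd = -np.gradient(curve.energies, curve.distances) * PN_PER_KCAL_MOL_A
    f = curve.forces
    floor = 1e-2 * (np.max(np.abs(f)) or 1.0)
    dev = np.abs(fd - f) / np.maximum(np.maximum(np.abs(fd), np.abs(f)), floor)
    return bool(np.percentile(dev, 90) < rtol)


# ---------------------------------------------------------------------------
# Helix traces
# ---------------------------------------------------------------------------


def write_stress_strain(curve: StressStrainCurve, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# helix: {curve.helix}\n")
        pd.DataFrame({"strain": curve.strains, "stress_pN_A2": curve.stresses}).to_csv(
            fh, sep="\t", index=False, float_format="%.10g"
        )


def read_stress_strain(path: str | Path) -> StressStrainCurve:
    df, meta = _read_table(path)
    for col in ("strain", "stress_pN_A2"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return StressStrainCurve(
        helix=meta.get("helix", ""),
        strains=_numeric_column(df, "strain", path),
        stresses=_numeric_column(df, "stress_pN_A2", path),
    )


def write_load_unload(trace: LoadUnloadTrace, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# helix: {trace.helix}\n# peak_index: {trace.peak_index}\n")
        pd.DataFrame(
            {"elongation_A": trace.elongations, "force_pN": trace.forces}
        ).to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_load_unload(path: str | Path) -> LoadUnloadTrace:
    df, meta = _read_table(path)
    for col in ("elongation_A", "force_pN"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if "peak_index" not in meta:
        raise ValueError(f"{path}: missing '# peak_index:' header")
    return LoadUnloadTrace(
        helix=meta.get("helix", ""),
        elongations=_numeric_column(df, "elongation_A", path),
        forces=_numeric_column(df, "force_pN", path),
        peak_index=int(meta["peak_index"]),
    )


# ---------------------------------------------------------------------------
# Geometry: JSON (exact) and PDB (visualization / interchange)
# ---------------------------------------------------------------------------


def geometry_to_json(geometry: ChannelGeometry, path: str | Path) -> None:
    obj = {
        "genotype": geometry.genotype,
        "state": geometry.state,
        "axis": geometry.axis.tolist(),
        "polylines": {
            f"{s}:{helix}": pts.tolist()
            for (s, helix), pts in sorted(geometry.polylines.items())
        },
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, indent=1)


def geometry_from_json(path: str | Path) -> ChannelGeometry:
    with open(path) as fh:
        obj = json.load(fh)
    polylines = {}
    for key, pts in obj["polylines"].items():
        s, _, helix = key.partition(":")
        polylines[(int(s), helix)] = np.asarray(pts, dtype=float)
    return ChannelGeometry(
        polylines=polylines,
        genotype=obj.get("genotype", "WT"),
        state=obj.get("state", "closed"),
        axis=np.asarray(obj.get("axis", [0.0, 0.0, 1.0])),
    )


def geometry_to_pdb(geometry: ChannelGeometry, path: str | Path) -> None:
    """Write one CA pseudo-atom per centerline point.

    Chains A-E are subunits 0-4; helix segments are distinguished by the
    pseudo-residue names NTR/TM1/TM2/CTR.  This is a visualization
    convention, not a claim of atomic structure (PDB precision is 1e-3 Å;
    use the JSON form for exact round-trips).
    """
    lines = []
    serial = 1
    resseq: dict[str, int] = {}
    for (s, helix) in sorted(geometry.polylines):
        resname = HELIX_RESNAMES[helix]
        chain = CHAIN_IDS[s]
        for p in geometry.polylines[(s, helix)]:
            resseq[chain] = resseq.get(chain, 0) + 1  # unique id within chain
            lines.append(
                f"ATOM  {serial:5d}  CA  {resname} {chain}{resseq[chain]:4d}    "
                f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}  1.00  0.00           C"
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pdb_geometry(
    path: str | Path,
    chain_map: dict[str, int] | None = None,
    residue_ranges: dict[str, tuple[int, int]] | None = None,
    canonicalize: bool = False,
) -> ChannelGeometry:
    """Build helix centerlines from the Cα records of a 5-chain PDB file.

    By default chains A-E map to subunits 0-4 and helix segments are
    recognized by the NTR/TM1/TM2/CTR pseudo-residue names written by
    :func:`geometry_to_pdb`.  For externally produced files, pass
    ``residue_ranges`` ({helix: (first, last)} author residue numbers) to
    slice the Cα trace instead.  With ``canonicalize`` the structure is
    recentered on its centroid and rotated so its best-fit 5-fold symmetry
    axis lies along +z, making pore measurements rigid-motion invariant.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("channel", str(path))
    model = next(structure.get_models())
    chain_map = chain_map or {c: i for i, c in enumerate(CHAIN_IDS)}
    missing = [c for c in chain_map if c not in [ch.id for ch in model]]
    if missing:
        raise ValueError(f"{path}: missing chain(s) {missing}")
    polylines: dict[tuple[int, str], np.ndarray] = {}
    for chain in model:
        if chain.id not in chain_map:
            continue
        s = chain_map[chain.id]
        if residue_ranges:
            residues = [r for r in chain if "CA" in r]
            for helix, (lo, hi) in residue_ranges.items():
                pts = [
                    r["CA"].coord
                    for r in residues
                    if lo <= r.id[1] <= hi
                ]
                if len(pts) < 2:
                    raise ValueError(
                        f"{path}: chain {chain.id} has <2 CA atoms in {helix} "
                        f"range {lo}-{hi}"
                    )
                polylines[(s, helix)] = np.asarray(pts, dtype=float)
        else:
            for residue in chain:
                if "CA" not in residue:
                    continue
                helix = RESNAME_TO_HELIX.get(residue.get_resname())
                if helix is None:
                    raise ValueError(
                        f"{path}: unknown pseudo-residue {residue.get_resname()!r}; "
                        "pass residue_ranges for external structures"
                    )
                key = (s, helix)
                polylines.setdefault(key, [])
                polylines[key].append(residue["CA"].coord)
            for key in list(polylines):
                if isinstance(polylines[key], list):
                    polylines[key] = np.asarray(polylines[key], dtype=float)
    geo = ChannelGeometry(polylines=polylines)
    if canonicalize:
        geo = canonicalize_geometry(geo)
    return geo


def canonicalize_geometry(geometry: ChannelGeometry) -> ChannelGeometry:
    """Recenter on the centroid and rotate the 5-fold axis onto +z.

    The symmetry axis is the principal axis of the Cα cloud whose moment is
    most separated from the other two (the perpendicular pair is degenerate
    under exact 5-fold symmetry).
    """
    pts = np.vstack(list(geometry.polylines.values()))
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    cov = centered.T @ centered / len(centered)
    w, v = np.linalg.eigh(cov)
    sep = [abs(w[i] - w[(i + 1) % 3]) + abs(w[i] - w[(i + 2) % 3]) for i in range(3)]
    axis = v[:, int(np.argmax(sep))]
    if axis[2] < 0:
        axis = -axis
    # rotation taking axis -> z
    z = np.array([0.0, 0.0, 1.0])
    vcross = np.cross(axis, z)
    c = float(axis @ z)
    if np.linalg.norm(vcross) < 1e-12:
        R = np.eye(3)
    else:
        vx = np.array(
            [
                [0, -vcross[2], vcross[1]],
                [vcross[2], 0, -vcross[0]],
                [-vcross[1], vcross[0], 0],
            ]
        )
        R = np.eye(3) + vx + vx @ vx / (1.0 + c)
    polylines = {
        key: (p - centroid) @ R.T for key, p in geometry.polylines.items()
    }
    return ChannelGeometry(
        polylines=polylines, genotype=geometry.genotype, state=geometry.state
    )


# ---------------------------------------------------------------------------
# Force laws and reports
# ---------------------------------------------------------------------------


def laws_to_json(
    laws: dict[str, InteractionForceLaw],
    path: str | Path,
    sse: dict[str, float] | None = None,
) -> None:
    obj = {
        belt: {
            "pair": law.pair,
            "genotype": law.genotype,
            "A": law.A,
            "B": law.B,
            "m": law.m,
            "n": law.n,
            "sse": None if sse is None else sse.get(belt),
        }
        for belt, law in laws.items()
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, indent=1)


def laws_from_json(path: str | Path) -> dict[str, InteractionForceLaw]:
    with open(path) as fh:
        obj = json.load(fh)
    return {
        belt: InteractionForceLaw(
            A=rec["A"],
            B=rec["B"],
            m=rec.get("m", 13.0),
            n=rec.get("n", 7.0),
            pair=rec.get("pair", belt),
            genotype=rec.get("genotype", "WT"),
        )
        for belt, rec in obj.items()
    }


@dataclasses.dataclass
class RunConfig:
    """Configuration of one pipeline run; unknown keys are rejected."""

    seed: int = 0
    genotype: str = "WT"
    model: int | None = None
    reduction: float = 0.0
    deletions: list[str] = dataclasses.field(default_factory=list)
    pulling: str = "N"
    increments: int = 50
    elements_per_helix: int = 4
    loop_stiffness: float = 10.0
    bending_scale: float = 10.5
    tolerance: float | None = None
    onset_fraction: float = 0.25
    stress_unit: str = "MPa"  # or "pN_A2"
    well_depths: dict[str, float] | None = None
    moduli: dict[str, float] | None = None
    output_dir: str = "out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        """Stable hash of the configuration content."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_report(results, config: RunConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write the scenario report as JSON + TSV.

    Serialization is deterministic (sorted keys, repr floats): two runs with
    identical inputs produce byte-identical files.  Both outputs embed the
    config echo, its hash and the seed.  Returns the written paths.
    """
    from .scenarios import tabulate

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in results:
        rows.append(
            {
                "identifier": r.identifier,
                "final_diameter_A": r.final_diameter,
                "closed_diameter_A": r.closed_diameter,
                "opened": r.opened,
                "threshold_stress_MPa": r.threshold_stress,
                "open_state_stress_MPa": r.open_state_stress,
                "helix_max_stress_MPa": r.helix_max_stress,
                "feasibility": r.feasibility,
                "converged": r.converged,
            }
        )
    payload = {
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "seed": config.seed,
        "results": rows,
    }
    json_path = out_dir / "report.json"
    with open(json_path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1)
    table = tabulate(list(results))
    tsv_path = out_dir / "report.tsv"
    with open(tsv_path, "w") as fh:
        fh.write(f"# config_hash: {config.digest()}\n# seed: {config.seed}\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.6g", na_rep="-")
    return {"json": json_path, "tsv": tsv_path}


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_trajectory(traj, path: str | Path, pdb_path: str | Path | None = None) -> None:
    """Write a per-increment JSON summary of an equilibrium trajectory.

    Optionally also writes a multi-model PDB of the nodal positions (one
    MODEL per increment) for visualization.
    """
    obj = {
        "pore_diameters_A": [float(d) for d in traj.pore_diameters],
        "mean_tm1_stress_pN_A2": [float(s) for s in traj.mean_tm1_stress],
        "residuals_pN": [float(r) for r in traj.residuals],
        "iterations": [int(i) for i in traj.iterations],
        "converged": bool(traj.converged),
        "failed_increment": traj.failed_increment,
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, indent=1)
    if pdb_path is not None:
        lines = []
        for t in range(traj.coords.shape[0]):
            lines.append(f"MODEL {t + 1:8d}")
            for i, p in enumerate(traj.coords[t], start=1):
                lines.append(
                    f"ATOM  {i % 100000:5d}  CA  NOD A{i % 10000:4d}    "
                    f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}  1.00  0.00           C"
                )
            lines.append("ENDMDL")
        lines.append("END")
        Path(pdb_path).write_text("\n".join(lines) + "\n")
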