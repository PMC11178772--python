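"""First-principles structural metrics.

Implements the geometric core of the analysis from scratch:

* optimal rigid superposition (Kabsch, reflection excluded) and RMSD,
* per-frame fitted RMSD series over a multi-model trajectory,
* backbone φ/ψ torsions with Ramachandran-region classification,
* Shrake–Rupley solvent-accessible surface area,
* atom–atom distances and their per-frame series.

Dihedral sign convention: cis = 0°, positive clockwise looking from the
first to the last atom (the standard biomolecular convention). All
coordinates are in Å, angles in degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from matplotlib.path import Path as _MplPath
from scipy.spatial import cKDTree

from .io import Atom, Structure

__all__ = [
    "VDW_RADII",
    "SuperpositionResult",
    "TorsionRecord",
    "SasaResult",
    "kabsch_superpose",
    "rmsd_series",
    "dihedral",
    "backbone_torsions",
    "classify_region",
    "sasa",
    "atom_distance",
    "distance_series",
]

#: van der Waals radii (Å) used for SASA; override via ``sasa(radii=...)``.
VDW_RADII: dict[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}

BACKBONE_NAMES = ("N", "CA", "C")


class DegenerateGeometryError(ValueError):
    """Point set has no unique optimal rotation (rank < 2)."""


@dataclass
class SuperpositionResult:
    """Least-squares rigid superposition: x -> rotation @ x + translation."""

    rmsd: float
    rotation: np.ndarray
    translation: np.ndarray
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> SuperpositionResult:
    """Optimal proper-rotation superposition of ``mobile`` onto ``target``.

    Points are paired by order; reflections are excluded, so the returned
    rotation always has determinant +1. Collinear (rank-deficient) point
    sets have no unique rotation and raise
    :class:`DegenerateGeometryError`.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"coordinate sets must both be (n, 3); got {P.shape} vs {Q.shape}")
    if P.shape[0] < 3:
        raise ValueError("need at least 3 paired atoms")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    for label, X in (("mobile", P0), ("target", Q0)):
        s = np.linalg.svd(X, compute_uv=False)
        if s[1] <= 1e-8 * max(s[0], 1.0):
            raise DegenerateGeometryError(
                f"{label} point set is collinear/degenerate: optimal rotation is not unique"
            )
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = qc - R @ pc
    diff = P0 @ R.T - Q0
    rmsd = float(np.sqrt((diff * diff).sum() / P.shape[0]))
    return SuperpositionResult(rmsd=rmsd, rotation=R, translation=t, n_atoms=P.shape[0])


def _resolve_selection(structure: Structure, selection, model: int) -> list[Atom]:
    if selection is None:
        atoms = [a for a in structure.atoms if a.model == model and a.name in BACKBONE_NAMES]
    elif callable(selection):
        atoms = [a for a in structure.atoms if a.model == model and selection(a)]
    else:
        atoms = structure.select(model=model, **selection)
    return atoms


def rmsd_series(
    traj: Structure,
    reference_model: int = 1,
    selection: dict | None = None,
) -> pd.DataFrame:
    """Per-frame RMSD to a reference frame after least-squares fitting.

    Each frame is fitted to the reference on the same selection it is
    scored on (the molecular-dynamics convention), no mass weighting.
    ``selection`` is a mapping of atom attributes (e.g.
    ``{"chain_id": "A", "name": "CA"}``) or a predicate; the default is
    all backbone N/CA/C atoms. A selected atom missing from any frame is
    an error naming the frame and atom.
    """
    frames = traj.split_models()
    if reference_model not in frames:
        raise KeyError(f"reference model {reference_model} not present")
    ref_atoms = _resolve_selection(frames[reference_model], selection, reference_model)
    if not ref_atoms:
        raise ValueError("selection matches no atoms in the reference model")
    keys = [(a.chain_id, a.res_seq, a.icode, a.name) for a in ref_atoms]
    ref = np.array([a.coords for a in ref_atoms])
    rows = []
    for m, frame in frames.items():
        lookup = {
            (a.chain_id, a.res_seq, a.icode, a.name): a.coords
            for a in _resolve_selection(frame, selection, m)
        }
        try:
            coords = np.array([lookup[k] for k in keys])
        except KeyError as exc:
            raise ValueError(f"frame {m}: selected atom {exc.args[0]} missing") from None
        fit = kabsch_superpose(coords, ref)
        rows.append((m, fit.rmsd))
    return pd.DataFrame(rows, columns=["frame", "rmsd"])


# ---------------------------------------------------------------------------
# Torsions

def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle (degrees, in (-180, 180]) of four points."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m = np.cross(n1, n2)
    y = m @ (b2 / np.linalg.norm(b2))
    x = n1 @ n2
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


#: Coarse Ramachandran region polygons, (phi, psi) vertices in degrees.
#: These are swappable data approximating the usual general-case contours;
#: they are intentionally rectangular and carry no claim of matching any
#: particular published contour set.
RAMA_REGIONS: dict[str, list[list[tuple[float, float]]]] = {
    "favored": [
        [(-180, 90), (-45, 90), (-45, 180), (-180, 180)],        # beta / extended
        [(-160, -70), (-45, -70), (-45, 40), (-160, 40)],        # right-handed alpha
        [(20, -20), (100, -20), (100, 90), (20, 90)],            # left-handed alpha
    ],
    "allowed": [
        [(-180, 70), (-25, 70), (-25, 180), (-180, 180)],
        [(-180, -180), (-45, -180), (-45, -150), (-180, -150)],  # beta, psi wrap
        [(-180, -90), (-25, -90), (-25, 60), (-180, 60)],
        [(0, -40), (120, -40), (120, 110), (0, 110)],
    ],
}


def classify_region(
    phi: float | None,
    psi: float | None,
    regions: dict[str, list[list[tuple[float, float]]]] | None = None,
) -> str:
    """'favored' | 'allowed' | 'outlier' | 'undefined' for a (φ, ψ) pair."""
    if phi is None or psi is None:
        return "undefined"
    regions = RAMA_REGIONS if regions is None else regions
    pt = (phi, psi)
    for name in ("favored", "allowed"):
        for poly in regions.get(name, []):
            if _MplPath(poly, closed=True).contains_point(pt, radius=1e-9):
                return name
    return "outlier"


@dataclass
class TorsionRecord:
    chain_id: str
    res_seq: int
    icode: str
    phi: float | None
    psi: float | None
    region: str


def backbone_torsions(
    structure: Structure,
    chain_id: str,
    model: int = 1,
    regions: dict | None = None,
) -> list[TorsionRecord]:
    """φ/ψ torsions for one chain.

    φ(i) = dihedral(C(i-1), N(i), CA(i), C(i));
    ψ(i) = dihedral(N(i), CA(i), C(i), N(i+1)).
    The first residue has undefined φ, the last undefined ψ; residues
    adjacent to a numbering break or missing a backbone atom get
    undefined torsions with a warning rather than an error.
    """
    atoms = structure.select(chain_id=chain_id, model=model)
    if not atoms:
        raise KeyError(f"chain {chain_id!r} not present in model {model}")
    by_res: dict[tuple[int, str], dict[str, np.ndarray]] = {}
    for a in atoms:
        if a.name in ("N", "CA", "C"):
            by_res.setdefault((a.res_seq, a.icode), {})[a.name] = a.coords
    keys = sorted(by_res)

    def contiguous(k1, k2) -> bool:
        (n1, i1), (n2, i2) = k1, k2
        return (n2 == n1 + 1 and i2 == "") or (n2 == n1 and i2 > i1)

    records: list[TorsionRecord] = []
    for j, key in enumerate(keys):
        res = by_res[key]
        phi = psi = None
        if all(n in res for n in ("N", "CA", "C")):
            if j > 0 and contiguous(keys[j - 1], key) and "C" in by_res[keys[j - 1]]:
                phi = dihedral(by_res[keys[j - 1]]["C"], res["N"], res["CA"], res["C"])
            if j + 1 < len(keys) and contiguous(key, keys[j + 1]) and "N" in by_res[keys[j + 1]]:
                psi = dihedral(res["N"], res["CA"], res["C"], by_res[keys[j + 1]]["N"])
        else:
            warnings.warn(
                f"residue {chain_id}{key[0]}{key[1]}: missing backbone atom, torsions undefined"
            )
        records.append(
            TorsionRecord(
                chain_id=chain_id,
                res_seq=key[0],
                icode=key[1],
                phi=phi,
                psi=psi,
                region=classify_region(phi, psi, regions),
            )
        )
    return records


# ---------------------------------------------------------------------------
# SASA

def _fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform points on the unit sphere (golden-spiral lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


@dataclass
class SasaResult:
    """Shrake–Rupley areas (Å²) per atom and per residue."""

    per_atom: dict[tuple[str, int, str, str], float]
    per_residue: dict[tuple[str, int, str], float]
    probe_radius: float
    n_points: int
    radii: dict[str, float] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return float(sum(self.per_atom.values()))


def sasa(
    structure: Structure,
    probe: float = 1.4,
    n_points: int = 960,
    radii: dict[str, float] | None = None,
    model: int = 1,
) -> SasaResult:
    """Shrake–Rupley solvent-accessible surface area.

    Each atom is given ``n_points`` near-uniform sphere points at radius
    r_vdw + probe; a point is exposed iff it lies outside every
    neighbour's expanded sphere; the atom's area is the exposed fraction
    of 4π(r_vdw + probe)². Unknown elements without a radius override are
    an error.
    """
    rad = dict(VDW_RADII)
    if radii:
        rad.update(radii)
    atoms = [a for a in structure.atoms if a.model == model]
    if not atoms:
        raise ValueError(f"no atoms in model {model}")
    missing = sorted({a.element for a in atoms if a.element not in rad})
    if missing:
        raise KeyError(f"no van der Waals radius for element(s) {missing}; pass radii=...")
    centers = np.array([a.coords for a in atoms])
    expanded = np.array([rad[a.element] + probe for a in atoms])
    unit = _fibonacci_sphere(n_points)
    tree = cKDTree(centers)
    per_atom: dict[tuple[str, int, str, str], float] = {}
    per_res: dict[tuple[str, int, str], float] = {}
    rmax = expanded.max()
    for i, a in enumerate(atoms):
        pts = centers[i] + expanded[i] * unit
        neigh = [j for j in tree.query_ball_point(centers[i], expanded[i] + rmax) if j != i]
        exposed = np.ones(n_points, dtype=bool)
        for j in neigh:
            d = np.linalg.norm(pts - centers[j], axis=1)
            exposed &= d >= expanded[j]
            if not exposed.any():
                break
        area = 4.0 * np.pi * expanded[i] ** 2 * exposed.sum() / n_points
        per_atom[(a.chain_id, a.res_seq, a.icode, a.name)] = float(area)
        rk = (a.chain_id, a.res_seq, a.icode)
        per_res[rk] = per_res.get(rk, 0.0) + float(area)
    return SasaResult(
        per_atom=per_atom,
        per_residue=per_res,
        probe_radius=probe,
        n_points=n_points,
        radii=rad,
    )


# ---------------------------------------------------------------------------
# Distances

def _one_atom(structure: Structure, sel: dict, model: int) -> Atom:
    hits = structure.select(model=model, **sel)
    if len(hits) != 1:
        listing = [
            f"{a.chain_id}/{a.res_name}{a.res_seq}{a.icode}/{a.name}" for a in hits
        ]
        raise ValueError(
            f"selection {sel} resolves to {len(hits)} atoms in model {model}: {listing}"
        )
    return hits[0]


def atom_distance(structure: Structure, sel_a: dict, sel_b: dict, model: int = 1) -> float:
    """Euclidean distance (Å) between two uniquely selected atoms."""
    a = _one_atom(structure, sel_a, model)
    b = _one_atom(structure, sel_b, model)
    return float(np.linalg.norm(a.coords - b.coords))


def distance_series(traj: Structure, sel_a: dict, sel_b: dict) -> pd.DataFrame:
    """``atom_distance`` evaluated in every frame of a trajectory."""
    rows = [
        (m, atom_distance(frame, sel_a, sel_b, model=m))
        for m, frame in traj.split_models().items()
    ]
    return pd.DataFrame(rows, columns=["frame", "distance"])
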