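"""Seeded synthetic-data generators.

Every fixture the pipeline consumes can be generated here with planted
ground truth, so each analysis has a measurable inverse: sequences with
planted cleavage motifs (and a background alphabet that cannot form a
site), ideal-geometry polypeptides whose torsions are the generator
inputs, enzyme–peptide poses with an exactly planted nucleophile–carbonyl
distance, multi-frame trajectories with planted hydrogen-bond geometry
and distance profiles, and clot-assay replicate tables with planted group
effects.

Fixture geometry is deliberately minimal — backbone plus the named key
atoms, not physically relaxed. That is sufficient for the geometric
metrics under test and makes no claim of being simulation-quality
structure. Identical seed and parameters give bit-identical output; each
generator owns its RNG, so fixtures are independently reproducible.

Default study conditions mirror the assay set-up the statistics are used
for: clot groups at mean degradation 12% (buffer control), 55% and 73%
(increasing extract dose) with replicate SD 2.0 at n = 3; competent poses
plant SG–C distances in the 4.2–4.9 Å range with a 7 Å negative control;
stable trajectories plant SG–C quartiles (3.6, 4.4) Å and the negative
control (5.5, 6.4) Å with markedly fewer hydrogen bonds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .clotstats import ClotRecord
from .io import Atom, SeqRecord, Structure
from .specificity import POSITION_TAGS, SpecificityModel, load_specificity, scan_sequence

__all__ = [
    "GenSpec",
    "gen_sequence",
    "gen_polypeptide",
    "gen_pose",
    "gen_trajectory",
    "gen_clot_table",
    "synthetic_actinidin_pair",
    "quartile_profile",
    "relax_profile",
    "gen_preset",
    "PRESETS",
]

_ALL_AA = "ACDEFGHIKLMNPQRSTVWY"

# ideal backbone internal coordinates (Å, degrees)
_B_N_CA, _B_CA_C, _B_C_N = 1.458, 1.525, 1.329
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7


@dataclass(frozen=True)
class GenSpec:
    """A reproducible generator request: a seed plus free-form size and
    plant parameters. Identical specs yield identical output."""

    seed: int
    params: Mapping[str, object] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Sequences

def background_alphabet(model: SpecificityModel) -> str:
    """Residues that can never occupy P1 or P1' under ``model`` — a
    background drawn from these letters cannot form a cleavage site."""
    excluded = model.p1_union() | model.p1prime_union()
    bg = "".join(sorted(set(_ALL_AA) - excluded))
    if not bg:
        raise ValueError("model constrains every residue: no safe background alphabet")
    return bg


def gen_sequence(
    length: int,
    plant_positions: Sequence[int] = (),
    model: SpecificityModel | None = None,
    seed: int = 0,
    numbering_start: int = 1,
    source: str | None = None,
    id: str | None = None,
) -> SeqRecord:
    """A random sequence with cleavage motifs planted at the given
    author-numbered P1 positions and nowhere else.

    The background alphabet excludes every residue allowed at P1 or P1'
    by any source, so background positions cannot match; planted 8-mers
    are drawn from the constrained sets of one source (``source`` label,
    default the model's first fully constrained source, falling back to
    the first). Plant draws are re-sampled until a scan confirms exactly
    the planted site set, so the guarantee is checked, not assumed.
    """
    model = model or load_specificity()
    rng = np.random.default_rng(seed)
    bg = background_alphabet(model)
    positions = sorted(plant_positions)
    idxs = [p - numbering_start for p in positions]
    for i in idxs:
        if i - 3 < 0 or i + 4 >= length:
            raise ValueError(f"planted P1 at {i + numbering_start} does not fit the full P4..P4' window")
    for a, b in zip(idxs, idxs[1:]):
        if b - a < 8:
            raise ValueError(f"planted windows at {a + numbering_start} and {b + numbering_start} overlap")
    if source is None:
        full = [s for s in model.sources if len(s.positions) == len(POSITION_TAGS)]
        src = full[0] if full else model.sources[0]
    else:
        matches = [s for s in model.sources if s.label == source]
        if not matches:
            raise KeyError(f"no source labelled {source!r} in model {model.name!r}")
        src = matches[0]
    numbering = list(range(numbering_start, numbering_start + length))
    for attempt in range(200):
        letters = list(rng.choice(list(bg), size=length))
        for i in idxs:
            for tag, off in POSITION_TAGS.items():
                if tag in src.positions:
                    letters[i + off] = rng.choice(sorted(src.positions[tag]))
        rec = SeqRecord(
            id=id or f"synth_seq_seed{seed}",
            residues="".join(letters),
            numbering=numbering,
        )
        found = [s.p1_pos for s in scan_sequence(rec, model)]
        if found == positions:
            return rec
    raise RuntimeError("could not realise the requested plant without spurious sites")


# ---------------------------------------------------------------------------
# Ideal-geometry polypeptides

def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray, r: float, theta: float, chi: float) -> np.ndarray:
    """Place atom D so that |CD| = r, angle(B,C,D) = theta and
    dihedral(A,B,C,D) = chi (degrees)."""
    th, ch = np.radians(theta), np.radians(chi)
    bc = c - b
    bc_hat = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc_hat)
    n_hat = n / np.linalg.norm(n)
    m = np.cross(n_hat, bc_hat)
    d2 = np.array([-r * np.cos(th), r * np.sin(th) * np.cos(ch), r * np.sin(th) * np.sin(ch)])
    return c + np.column_stack([bc_hat, m, n_hat]) @ d2


def gen_polypeptide(
    n_res: int,
    phi: float,
    psi: float,
    omega: float = 180.0,
    chain_id: str = "A",
) -> Structure:
    """Backbone-only polypeptide with ideal bond geometry whose interior
    residues all measure torsions (phi, psi) exactly."""
    if n_res < 3:
        raise ValueError("need at least 3 residues")
    coords: dict[tuple[int, str], np.ndarray] = {}
    coords[(1, "N")] = np.zeros(3)
    coords[(1, "CA")] = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.radians(180.0 - _A_N_CA_C)
    coords[(1, "C")] = coords[(1, "CA")] + _B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    for i in range(2, n_res + 1):
        coords[(i, "N")] = _place(
            coords[(i - 1, "N")], coords[(i - 1, "CA")], coords[(i - 1, "C")],
            _B_C_N, _A_CA_C_N, psi,
        )
        coords[(i, "CA")] = _place(
            coords[(i - 1, "CA")], coords[(i - 1, "C")], coords[(i, "N")],
            _B_N_CA, _A_C_N_CA, omega,
        )
        coords[(i, "C")] = _place(
            coords[(i - 1, "C")], coords[(i, "N")], coords[(i, "CA")],
            _B_CA_C, _A_N_CA_C, phi,
        )
    atoms = []
    serial = 1
    for i in range(1, n_res + 1):
        for name in ("N", "CA", "C"):
            atoms.append(
                Atom(
                    serial=serial, name=name, res_name="ALA", chain_id=chain_id,
                    res_seq=i, coords=coords[(i, name)],
                    element="N" if name == "N" else "C",
                )
            )
            serial += 1
    return Structure(id=f"ideal_phi{phi}_psi{psi}", atoms=atoms)


# ---------------------------------------------------------------------------
# Poses and trajectories

def _pose_atom_specs(sg_c: float, n_hbonds: int = 0) -> list[tuple]:
    """(name, res_name, chain, res_seq, xyz, element) for a minimal
    enzyme–peptide pose; the scissile carbonyl C sits exactly ``sg_c`` Å
    from Cys25 SG (at the origin)."""
    specs: list[tuple] = [
        # enzyme chain E: catalytic Cys25 with SG at the origin
        ("N", "CYS", "E", 25, (-3.5, 1.0, 0.2), "N"),
        ("CA", "CYS", "E", 25, (-2.3, 0.6, 1.0), "C"),
        ("CB", "CYS", "E", 25, (-1.4, 0.9, -0.2), "C"),
        ("SG", "CYS", "E", 25, (0.0, 0.0, 0.0), "S"),
        # rest of the triad, recorded but not gated
        ("CA", "HIS", "E", 162, (-2.1, -4.2, 0.9), "C"),
        ("NE2", "HIS", "E", 162, (-1.0, -3.3, 0.4), "N"),
        ("CA", "ASN", "E", 182, (-4.0, -2.4, 2.3), "C"),
        ("OD1", "ASN", "E", 182, (-3.0, -1.6, 2.0), "O"),
    ]
    # enzyme anchor residues (CA only), a non-collinear scaffold for RMSD fits
    anchors = [
        (-6.0, 2.0, -1.0), (-7.5, -1.0, 1.5), (-5.0, -3.5, -2.0),
        (-8.0, 1.5, 3.0), (-6.5, 4.0, 2.0), (-9.0, -2.5, -1.5),
    ]
    for k, xyz in enumerate(anchors):
        specs.append(("CA", "GLY", "E", 30 + k, xyz, "C"))
    # peptide chain P: the scissile carbonyl C of residue 1 sits on the +x
    # axis at exactly sg_c from SG; the rest of the peptide is held well
    # away from the enzyme's polar atoms so only planted hydrogen bonds
    # can form, whatever the planted distance
    specs += [
        ("N", "GLY", "P", 1, (sg_c - 0.9, -8.3, 0.7), "N"),
        ("CA", "GLY", "P", 1, (sg_c + 0.3, -7.8, 1.3), "C"),
        ("C", "GLY", "P", 1, (sg_c, 0.0, 0.0), "C"),
        ("N", "GLY", "P", 2, (sg_c + 1.1, -8.6, -0.7), "N"),
        ("CA", "GLY", "P", 2, (sg_c + 2.4, -8.9, -1.1), "C"),
        ("C", "GLY", "P", 2, (sg_c + 3.3, -7.8, -0.6), "C"),
        ("N", "GLY", "P", 3, (sg_c + 3.5, -7.6, 0.7), "N"),
        ("CA", "GLY", "P", 3, (sg_c + 4.7, -6.8, 1.0), "C"),
        ("C", "GLY", "P", 3, (sg_c + 5.9, -7.5, 1.6), "C"),
    ]
    # planted hydrogen bonds: Ser OG (donor, with HG1) on E vs carbonyl O
    # acceptors on P, in a block far from everything else, pairs 8 apart
    for k in range(n_hbonds):
        z = 8.0 * k
        specs.append(("OG", "SER", "E", 50 + k, (0.0, 20.0, z), "O"))
        specs.append(("HG1", "SER", "E", 50 + k, (0.95 * np.cos(np.radians(10.0)),
                                                  20.0 + 0.95 * np.sin(np.radians(10.0)), z), "H"))
        specs.append(("O", "GLY", "P", 61 + k, (2.9, 20.0, z), "O"))
    return specs


def _build(specs: list[tuple], model: int, serial_start: int = 1) -> list[Atom]:
    atoms = []
    for serial, (name, res_name, chain, res_seq, xyz, element) in enumerate(
        specs, start=serial_start
    ):
        atoms.append(
            Atom(
                serial=serial, name=name, res_name=res_name, chain_id=chain,
                res_seq=res_seq, coords=np.asarray(xyz, dtype=float),
                element=element, model=model,
            )
        )
    return atoms


def gen_pose(sg_c: float, n_hbonds: int = 0, seed: int = 0) -> Structure:
    """Minimal enzyme–peptide pose with SG–C planted exactly at ``sg_c`` Å."""
    if sg_c <= 0:
        raise ValueError("sg_c must be positive")
    return Structure(id=f"pose_sgc{sg_c}", atoms=_build(_pose_atom_specs(sg_c, n_hbonds), model=1))


def quartile_profile(n_frames: int, q1: float, q3: float, seed: int = 0) -> np.ndarray:
    """Gaussian draws whose population quartiles are (q1, q3)."""
    if q3 < q1:
        raise ValueError("q3 must be >= q1")
    rng = np.random.default_rng(seed)
    median = 0.5 * (q1 + q3)
    sigma = (q3 - q1) / 1.3489795003921634  # 2 * Phi^-1(0.75)
    return rng.normal(median, sigma, size=n_frames)


def relax_profile(
    n_frames: int, start: float, plateau_q1: float, plateau_q3: float,
    tau_frac: float = 0.08, seed: int = 0,
) -> np.ndarray:
    """Early exponential relaxation from ``start`` onto a noisy plateau
    with the given quartiles — the shape of an equilibrating distance
    series."""
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames)
    median = 0.5 * (plateau_q1 + plateau_q3)
    sigma = (plateau_q3 - plateau_q1) / 1.3489795003921634
    decay = (start - median) * np.exp(-t / max(1.0, tau_frac * n_frames))
    return median + decay + rng.normal(0.0, sigma, size=n_frames)


def gen_trajectory(
    n_frames: int,
    sg_c_profile,
    n_hbonds: int = 0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    peptide_drift: float = 0.0,
) -> Structure:
    """Multi-model trajectory with planted per-frame ground truth.

    ``sg_c_profile`` is a scalar or an array of length ``n_frames``; the
    scissile carbonyl is placed at exactly that distance from SG in each
    frame. ``n_hbonds`` ideal donor–acceptor pairs (D–A 2.9 Å, H–D–A 10°)
    bridge the enzyme and peptide chains in every frame. Gaussian noise
    ``noise_sigma`` perturbs the anchor and peptide backbone atoms (never
    the planted distance or hydrogen-bond atoms), and ``peptide_drift``
    translates the peptide backbone linearly over the run to emulate a
    relaxing ligand.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    profile = np.asarray(sg_c_profile, dtype=float)
    if profile.ndim == 0:
        profile = np.full(n_frames, float(profile))
    if profile.shape != (n_frames,):
        raise ValueError(f"sg_c_profile length {profile.shape} inconsistent with n_frames={n_frames}")
    rng = np.random.default_rng(seed)
    atoms: list[Atom] = []
    serial = 1
    for f in range(n_frames):
        specs = _pose_atom_specs(profile[f], n_hbonds)
        frame_atoms = _build(specs, model=f + 1, serial_start=serial)
        serial += len(frame_atoms)
        shift = peptide_drift * f / max(1, n_frames - 1)
        for a in frame_atoms:
            scissile = a.chain_id == "P" and a.res_seq == 1 and a.name == "C"
            if scissile:
                continue  # the planted distance is never perturbed
            jitter_ok = (
                (a.chain_id == "E" and a.name == "CA")
                or (a.chain_id == "P" and a.res_seq <= 3 and a.name in ("N", "CA", "C"))
            )
            if noise_sigma > 0 and jitter_ok:
                a.coords = a.coords + rng.normal(0.0, noise_sigma, size=3)
            if shift and a.chain_id == "P" and a.res_seq <= 3:
                # per-residue displacement: a non-rigid deformation, so the
                # fitted RMSD of the peptide genuinely grows over the run
                a.coords = a.coords + shift * a.res_seq * np.array([0.0, -1.0, 0.5])
        atoms.extend(frame_atoms)
    return Structure(id=f"traj_seed{seed}", atoms=atoms)


def synthetic_actinidin_pair(seed: int = 2024) -> tuple[SeqRecord, SeqRecord]:
    """SYNTHETIC stand-in for the actinidin sequence-identity comparison.

    Two random 218-residue sequences identical everywhere except position
    101, where the first carries E and the second D — the layout of
    comparing a mature actinidin query against its closest crystallised
    homologue (one substitution in 218 aligned residues, 217/218 =
    99.5%). These are *not* real actinidin sequences, which must be
    supplied by the user as FASTA; they exercise the identical code path
    with a known ground truth.
    """
    rng = np.random.default_rng(seed)
    letters = list(rng.choice(list(_ALL_AA), size=218))
    letters[100] = "E"
    a = SeqRecord(id="synthetic_actinidin_query", residues="".join(letters))
    letters[100] = "D"
    b = SeqRecord(id="synthetic_actinidin_reference", residues="".join(letters))
    return a, b


# ---------------------------------------------------------------------------
# Clot assays

DEFAULT_CLOT_MEANS = {"control": 12.0, "extract_75": 55.0, "extract_100": 73.0}
DEFAULT_CELL_MEANS = {"control": 4.36e7, "extract_75": 3.6e9, "extract_100": 4.3e9}


def gen_clot_table(
    group_means: Mapping[str, float] | None = None,
    sigma: float = 2.0,
    n: int = 3,
    seed: int = 0,
    initial_weight: float = 0.12,
    convention: str = "as_printed",
    cell_means: Mapping[str, float] | None = None,
) -> list[ClotRecord]:
    """Clot-assay replicates with planted group degradation means.

    Per-replicate degradation is N(mean, sigma) and back-solved into a
    final dry weight under the chosen convention, so the analysis formula
    recovers the plant exactly. Defaults mirror a dose-ordered assay:
    control 12%, mid dose 55%, high dose 73%, replicate SD 2, n = 3.
    """
    means = dict(DEFAULT_CLOT_MEANS if group_means is None else group_means)
    cells = dict(DEFAULT_CELL_MEANS if cell_means is None else cell_means)
    rng = np.random.default_rng(seed)
    records = []
    for group, mean in means.items():
        for rep in range(1, n + 1):
            pct = float(rng.normal(mean, sigma))
            pct = max(pct, -50.0)  # keep weights physical
            if convention == "as_printed":
                final = initial_weight / (1.0 + pct / 100.0)
            else:
                final = initial_weight * (1.0 - pct / 100.0)
            cell_mean = cells.get(group)
            released = (
                float(abs(rng.normal(cell_mean, 0.1 * cell_mean))) if cell_mean else None
            )
            records.append(
                ClotRecord(
                    group=group, replicate=rep,
                    initial_weight=initial_weight, final_weight=final,
                    released_cells=released,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Presets

def _preset_fibrin_like(seed: int):
    """Three fibrin-chain-like sequences with the canonical site layout:
    two sites on the Aα-like chain (positions 162 and 171), one on the
    Bβ-like chain (346) and one on the γ-like chain (406). Chains are
    full length with 1-based numbering, so positions survive FASTA
    round-trips."""
    return [
        gen_sequence(200, [162, 171], seed=seed, id="Aa"),
        gen_sequence(360, [346], seed=seed + 1, id="Bb"),
        gen_sequence(420, [406], seed=seed + 2, id="g"),
    ]


PRESETS = {
    "fibrin-like": _preset_fibrin_like,
    "good-pose": lambda seed: gen_pose(4.2, n_hbonds=8, seed=seed),
    "bad-pose": lambda seed: gen_pose(7.0, n_hbonds=2, seed=seed),
    "stable-traj": lambda seed: gen_trajectory(
        200, quartile_profile(200, 3.6, 4.4, seed=seed), n_hbonds=8,
        noise_sigma=0.15, seed=seed,
    ),
    "negative-traj": lambda seed: gen_trajectory(
        200, relax_profile(200, 7.0, 5.5, 6.4, seed=seed), n_hbonds=2,
        noise_sigma=0.15, seed=seed,
    ),
    "relaxing-peptide": lambda seed: gen_trajectory(
        200, quartile_profile(200, 3.6, 4.4, seed=seed), n_hbonds=8,
        noise_sigma=0.15, seed=seed, peptide_drift=6.0,
    ),
    "clot-assay": lambda seed: gen_clot_table(seed=seed),
}


def gen_preset(name: str, seed: int = 0):
    """Named fixture presets: fibrin-like, good-pose, bad-pose,
    stable-traj, negative-traj, relaxing-peptide, clot-assay."""
    try:
        return PRESETS[name](seed)
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
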