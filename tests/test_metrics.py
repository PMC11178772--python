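"""Structural metrics: Kabsch, torsions, SASA, distances."""

import numpy as np
import pytest

from fibryze.io import Atom, Structure
from fibryze.metrics import (
    DegenerateGeometryError,
    atom_distance,
    backbone_torsions,
    classify_region,
    dihedral,
    distance_series,
    kabsch_superpose,
    rmsd_series,
    sasa,
)
from fibryze.synth import gen_polypeptide, gen_pose, gen_trajectory


def quaternion_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Independent minimum-RMSD oracle via the quaternion (Horn) method."""
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    M = P.T @ Q
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam = np.linalg.eigvalsh(K)[-1]
    n = P.shape[0]
    ssd = max(0.0, (P * P).sum() + (Q * Q).sum() - 2.0 * lam)
    return float(np.sqrt(ssd / n))


def _rot(axis, deg):
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(np.radians(deg) * np.asarray(axis, float)).as_matrix()


# --------------------------------------------------------------------- kabsch

def test_identical_sets_have_zero_rmsd(rng):
    P = rng.normal(size=(12, 3))
    assert kabsch_superpose(P, P).rmsd == pytest.approx(0.0, abs=1e-12)


def test_rigid_motion_recovered(rng):
    P = rng.normal(size=(20, 3))
    R = _rot([0, 0, 1], 37.0)
    Q = P @ R.T + np.array([1.0, 2.0, 3.0])
    res = kabsch_superpose(P, Q)
    assert res.rmsd == pytest.approx(0.0, abs=1e-9)
    assert np.allclose(res.rotation, R, atol=1e-9)
    assert np.allclose(res.translation, [1, 2, 3], atol=1e-9)


@pytest.mark.parametrize("seed", range(20))
def test_kabsch_matches_quaternion_oracle(seed):
    rng = np.random.default_rng(seed)
    P, Q = rng.normal(size=(10, 3)), rng.normal(size=(10, 3))
    assert kabsch_superpose(P, Q).rmsd == pytest.approx(quaternion_rmsd(P, Q), abs=1e-9)


def test_rotation_is_proper_and_rmsd_bounded(rng):
    for _ in range(10):
        P, Q = rng.normal(size=(8, 3)), rng.normal(size=(8, 3))
        res = kabsch_superpose(P, Q)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)
        unaligned = np.sqrt(((P - Q) ** 2).sum(axis=1).mean())
        assert res.rmsd <= unaligned + 1e-12


def test_rigid_motion_invariance_of_rmsd(rng):
    P, Q = rng.normal(size=(9, 3)), rng.normal(size=(9, 3))
    base = kabsch_superpose(P, Q).rmsd
    R = _rot([1, 1, 0], 63.0)
    moved = kabsch_superpose(P @ R.T + 5.0, Q @ R.T + 5.0).rmsd
    assert moved == pytest.approx(base, abs=1e-9)


def test_collinear_points_raise():
    P = np.array([[float(i), 0.0, 0.0] for i in range(5)])
    with pytest.raises(DegenerateGeometryError, match="collinear"):
        kabsch_superpose(P, P)


# ---------------------------------------------------------------- rmsd_series

def test_rigid_frames_give_zero_series(rng):
    pose = gen_pose(4.2)
    atoms = []
    for m in range(1, 4):
        R = _rot([0, 0, 1], 20.0 * (m - 1))
        for a in pose.atoms:
            b = Atom(serial=a.serial, name=a.name, res_name=a.res_name,
                     chain_id=a.chain_id, res_seq=a.res_seq,
                     coords=R @ a.coords + m, element=a.element, model=m)
            atoms.append(b)
    traj = Structure(id="rigid", atoms=atoms)
    df = rmsd_series(traj, selection={"name": "CA"})
    assert np.allclose(df["rmsd"], 0.0, atol=1e-9)


def test_missing_atom_names_frame_and_atom():
    traj = gen_trajectory(3, 4.0)
    victim = next(a for a in traj.atoms if a.model == 2 and a.name == "CA" and a.chain_id == "E")
    traj.atoms.remove(victim)
    with pytest.raises(ValueError, match="frame 2"):
        rmsd_series(traj, selection={"chain_id": "E", "name": "CA"})


def test_noise_rmsd_matches_numeric_expectation(rng):
    # frames = reference + iid Gaussian noise sigma on every coordinate;
    # for many atoms the fitted RMSD concentrates near sigma * sqrt(3)
    sigma, n_atoms = 0.1, 300
    base = rng.normal(scale=10.0, size=(n_atoms, 3))
    atoms = []
    for m in range(1, 31):
        noise = rng.normal(scale=sigma, size=(n_atoms, 3)) if m > 1 else 0.0
        coords = base + noise
        for i in range(n_atoms):
            atoms.append(Atom(serial=m * n_atoms + i, name="CA", res_name="GLY",
                              chain_id="A", res_seq=i + 1, coords=coords[i],
                              element="C", model=m))
    df = rmsd_series(Structure(id="n", atoms=atoms), selection={"name": "CA"})
    mean_rmsd = df["rmsd"].iloc[1:].mean()
    assert mean_rmsd == pytest.approx(sigma * np.sqrt(3.0), rel=0.10)


def test_stable_vs_relaxing_fixture_plateaus():
    from fibryze.synth import gen_preset

    plateau = 1.0  # Å, separates a stable chain from a relaxing one here
    stable = gen_preset("stable-traj", seed=4)
    relaxing = gen_preset("relaxing-peptide", seed=4)
    enzyme_sel = {"chain_id": "E", "name": "CA"}
    peptide_sel = {"chain_id": "P", "name": "CA"}
    stable_enzyme = rmsd_series(stable, selection=enzyme_sel)["rmsd"]
    relax_peptide = rmsd_series(relaxing, selection=peptide_sel)["rmsd"]
    assert stable_enzyme.max() < plateau
    assert relax_peptide.iloc[-20:].min() > plateau


# ------------------------------------------------------------------- torsions

def test_hand_computed_dihedral_sign():
    assert dihedral((1, 0, 0), (0, 0, 0), (0, 1, 0), (0, 1, 1)) == pytest.approx(-90.0)


@pytest.mark.parametrize("phi,psi", [(-57.0, -47.0), (-120.0, 120.0)])
def test_generator_inverse_recovery(phi, psi):
    st = gen_polypeptide(10, phi, psi)
    records = backbone_torsions(st, "A")
    for r in records[1:-1]:
        assert r.phi == pytest.approx(phi, abs=1e-6)
        assert r.psi == pytest.approx(psi, abs=1e-6)
    assert records[0].phi is None
    assert records[-1].psi is None


def test_torsions_invariant_under_rigid_motion(rng):
    st = gen_polypeptide(8, -75.0, 140.0)
    R = _rot([1, 2, 3], 51.0)
    for a in st.atoms:
        a.coords = R @ a.coords + np.array([4.0, -2.0, 7.5])
    for r in backbone_torsions(st, "A")[1:-1]:
        assert r.phi == pytest.approx(-75.0, abs=1e-9)
        assert r.psi == pytest.approx(140.0, abs=1e-9)


def test_region_classification():
    assert classify_region(-60.0, -45.0) == "favored"
    assert classify_region(-120.0, 120.0) == "favored"
    assert classify_region(None, -45.0) == "undefined"
    assert classify_region(0.0, -160.0) == "outlier"


def test_missing_backbone_atom_warns_not_fails():
    st = gen_polypeptide(6, -57.0, -47.0)
    st.atoms = [a for a in st.atoms if not (a.res_seq == 3 and a.name == "CA")]
    with pytest.warns(UserWarning, match="missing backbone"):
        records = backbone_torsions(st, "A")
    assert records[2].phi is None and records[2].region == "undefined"


# ----------------------------------------------------------------------- sasa

def _carbon(serial, xyz):
    return Atom(serial=serial, name="C", res_name="UNK", chain_id="A",
                res_seq=serial, coords=np.asarray(xyz, float), element="C",
                hetero=True)


def test_single_atom_closed_form():
    st = Structure(id="c1", atoms=[_carbon(1, (0, 0, 0))])
    r = 1.70 + 1.4
    res = sasa(st)
    assert res.total == pytest.approx(4 * np.pi * r**2, rel=0.005)


def test_distant_atoms_fully_exposed():
    st = Structure(id="c2", atoms=[_carbon(1, (0, 0, 0)), _carbon(2, (20, 0, 0))])
    r = 3.10
    res = sasa(st)
    for area in res.per_atom.values():
        assert area == pytest.approx(4 * np.pi * r**2, rel=0.005)


def test_two_spheres_match_cap_closed_form():
    d, r = 3.0, 3.10
    st = Structure(id="c3", atoms=[_carbon(1, (0, 0, 0)), _carbon(2, (d, 0, 0))])
    h = r - d / 2.0  # hidden cap height per sphere (equal radii)
    expected = 2 * (4 * np.pi * r**2 - 2 * np.pi * r * h)
    assert sasa(st).total == pytest.approx(expected, rel=0.02)


def test_sasa_decreases_as_occluders_added(rng):
    atoms = [_carbon(1, (0, 0, 0))]
    prev = sasa(Structure(id="m", atoms=list(atoms))).per_atom[("A", 1, "", "C")]
    for k in range(2, 6):
        atoms.append(_carbon(k, rng.normal(scale=2.0, size=3)))
        cur = sasa(Structure(id="m", atoms=list(atoms))).per_atom[("A", 1, "", "C")]
        assert cur <= prev + 1e-9
        prev = cur


def test_sasa_converges_with_point_count():
    st = gen_pose(4.2)
    a = sasa(st, n_points=960).total
    b = sasa(st, n_points=4000).total
    assert abs(a - b) / b < 0.01


def test_unknown_element_errors_unless_overridden():
    bad = Atom(serial=1, name="FE", res_name="HEM", chain_id="A", res_seq=1,
               coords=np.zeros(3), element="FE", hetero=True)
    st = Structure(id="fe", atoms=[bad])
    with pytest.raises(KeyError, match="FE"):
        sasa(st)
    res = sasa(st, radii={"FE": 1.6})
    assert res.total == pytest.approx(4 * np.pi * 3.0**2, rel=0.005)


def test_per_residue_sums_atoms():
    st = gen_pose(4.5)
    res = sasa(st)
    for rk, area in res.per_residue.items():
        parts = [v for k, v in res.per_atom.items() if k[:3] == rk]
        assert area == pytest.approx(sum(parts), abs=1e-9)


# ------------------------------------------------------------------ distances

def test_atom_distance_345():
    atoms = [
        Atom(serial=1, name="A1", res_name="UNK", chain_id="A", res_seq=1,
             coords=np.zeros(3), element="C", hetero=True),
        Atom(serial=2, name="A2", res_name="UNK", chain_id="A", res_seq=2,
             coords=np.array([3.0, 4.0, 0.0]), element="C", hetero=True),
    ]
    st = Structure(id="d", atoms=atoms)
    assert atom_distance(st, {"name": "A1"}, {"name": "A2"}) == pytest.approx(5.0)


def test_planted_pose_distance():
    st = gen_pose(4.2)
    d = atom_distance(st, {"res_seq": 25, "name": "SG"}, {"res_seq": 1, "name": "C"})
    assert d == pytest.approx(4.2, abs=1e-6)


def test_ambiguous_selection_lists_matches():
    st = gen_pose(4.2)
    with pytest.raises(ValueError, match="CA"):
        atom_distance(st, {"name": "CA"}, {"name": "SG"})


def test_distance_series_equals_per_frame_recomputation():
    traj = gen_trajectory(20, np.linspace(3.5, 6.5, 20), seed=8, noise_sigma=0.05)
    sel_a = {"res_seq": 25, "name": "SG"}
    sel_b = {"res_seq": 1, "name": "C"}
    df = distance_series(traj, sel_a, sel_b)
    for frame, dist in df.itertuples(index=False):
        assert dist == pytest.approx(atom_distance(traj, sel_a, sel_b, model=frame), abs=1e-12)
    assert np.allclose(df["distance"], np.linspace(3.5, 6.5, 20), atol=1e-6)
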