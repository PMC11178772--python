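"""Pose screening, hydrogen bonds, trajectory summaries, thermodynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fibryze.io import Atom, Structure
from fibryze.posetraj import (
    CatalyticSpec,
    FiveNumber,
    HBondCriteria,
    compact_letters,
    compare_hbond_groups,
    dg_from_kd,
    hbond_count,
    kd_from_dg,
    screen_pose,
    traj_summary,
)
from fibryze.synth import gen_pose, gen_preset, gen_trajectory, quartile_profile


# ------------------------------------------------------------------ screening

@pytest.mark.parametrize(
    "sg_c,threshold,verdict",
    [
        (4.2, 5.0, "accept"),
        (7.0, 5.0, "reject"),
        (4.6, 4.5, "reject"),
        (4.6, 5.0, "accept"),
        (5.0, 5.0, "accept"),  # boundary is inclusive
    ],
)
def test_screen_verdicts(sg_c, threshold, verdict):
    pose = gen_pose(sg_c)
    m = screen_pose(pose, CatalyticSpec(max_sg_c=threshold))
    assert m.sg_c == pytest.approx(sg_c, abs=1e-6)
    assert m.verdict == verdict
    assert m.threshold_used == threshold


def test_screen_records_rest_of_triad():
    m = screen_pose(gen_pose(4.4))
    assert set(m.triad_distances) == {"HIS162/NE2", "ASN182/OD1"}
    assert all(d > 0 for d in m.triad_distances.values())


def test_missing_atom_named_in_error():
    pose = gen_pose(4.2)
    pose.atoms = [a for a in pose.atoms if a.name != "SG"]
    with pytest.raises(KeyError, match="SG"):
        screen_pose(pose)


def test_invalid_catalytic_spec():
    with pytest.raises(ValueError, match="max_sg_c"):
        CatalyticSpec(max_sg_c=0.0)
    with pytest.raises(ValueError, match="distinct"):
        CatalyticSpec(triad=(("CYS", 25, "SG"),) * 3)


# ------------------------------------------------------------- hydrogen bonds

def _hb_frame(da: float, hda_deg: float = 10.0) -> Structure:
    """One donor (with H) on chain D, one acceptor on chain A."""
    h = np.array([0.95 * math.cos(math.radians(hda_deg)),
                  0.95 * math.sin(math.radians(hda_deg)), 0.0])
    atoms = [
        Atom(serial=1, name="OG", res_name="SER", chain_id="D", res_seq=1,
             coords=np.zeros(3), element="O"),
        Atom(serial=2, name="HG1", res_name="SER", chain_id="D", res_seq=1,
             coords=h, element="H"),
        Atom(serial=3, name="O", res_name="GLY", chain_id="A", res_seq=1,
             coords=np.array([da, 0.0, 0.0]), element="O"),
    ]
    return Structure(id="hb", atoms=atoms)


def test_ideal_bond_counts_once():
    assert hbond_count(_hb_frame(2.9), {"chain_id": "D"}, {"chain_id": "A"}) == 1


def test_stretched_bond_does_not_count():
    assert hbond_count(_hb_frame(4.0), {"chain_id": "D"}, {"chain_id": "A"}) == 0


def test_bent_geometry_fails_angle_criterion():
    assert hbond_count(_hb_frame(2.9, hda_deg=60.0), {"chain_id": "D"}, {"chain_id": "A"}) == 0


def test_empty_selection_is_error():
    with pytest.raises(ValueError, match="empty"):
        hbond_count(_hb_frame(2.9), {"chain_id": "Z"}, {"chain_id": "A"})


def _random_polar_frame(seed: int) -> Structure:
    rng = np.random.default_rng(seed)
    atoms = []
    serial = 1
    for chain, n in (("D", 12), ("A", 12)):
        for i in range(n):
            elem = rng.choice(["N", "O"])
            pos = rng.uniform(-6, 6, size=3)
            atoms.append(Atom(serial=serial, name=f"{elem}{i}", res_name="GLY",
                              chain_id=chain, res_seq=i + 1, coords=pos,
                              element=str(elem)))
            serial += 1
    return Structure(id=f"rand{seed}", atoms=atoms)


def oracle_hbonds(frame: Structure, criteria: HBondCriteria) -> int:
    """Exhaustive enumeration over all donor-acceptor pairs (no hydrogens
    present, so the distance criterion applies alone)."""
    donors = [a for a in frame.atoms if a.chain_id == "D" and a.element in "NOS"]
    acceptors = [a for a in frame.atoms if a.chain_id == "A" and a.element in "NOS"]
    return sum(
        1
        for d in donors
        for a in acceptors
        if np.linalg.norm(d.coords - a.coords) <= criteria.max_da
    )


@pytest.mark.parametrize("seed", range(10))
def test_random_frame_matches_exhaustive_oracle(seed):
    frame = _random_polar_frame(seed)
    crit = HBondCriteria()
    got = hbond_count(frame, {"chain_id": "D"}, {"chain_id": "A"}, crit)
    assert got == oracle_hbonds(frame, crit)


def test_count_monotone_in_distance_cutoff():
    frame = _random_polar_frame(3)
    counts = [
        hbond_count(frame, {"chain_id": "D"}, {"chain_id": "A"}, HBondCriteria(max_da=da))
        for da in (5.0, 4.0, 3.5, 3.0, 2.0)
    ]
    assert counts == sorted(counts, reverse=True)


def test_planted_bonds_recovered_exactly():
    pose = gen_pose(4.2, n_hbonds=5)
    assert hbond_count(pose, {"chain_id": "E"}, {"chain_id": "P"}) == 5


# ------------------------------------------------------------------ summaries

def test_five_number_of_small_series():
    f = FiveNumber.of([1, 2, 3, 4, 5])
    assert (f.min, f.q1, f.median, f.q3, f.max) == (1, 2, 3, 4, 5)


def test_five_number_must_be_ordered():
    with pytest.raises(ValueError, match="ordered"):
        FiveNumber(1, 3, 2, 4, 5)


def test_constant_series_mean_and_se():
    traj = gen_trajectory(10, 4.0)
    s = traj_summary(traj, "sg_c", spec=CatalyticSpec())
    assert s.mean == pytest.approx(4.0, abs=1e-9)
    assert s.se == pytest.approx(0.0, abs=1e-9)
    f = s.five_number
    assert f.min == f.max == pytest.approx(4.0, abs=1e-9)


def test_quartile_plant_recovered():
    n = 4000
    traj = gen_trajectory(n, quartile_profile(n, 3.6, 4.4, seed=6), seed=6)
    s = traj_summary(traj, "sg_c", spec=CatalyticSpec())
    assert s.five_number.q1 == pytest.approx(3.6, abs=0.05)
    assert s.five_number.q3 == pytest.approx(4.4, abs=0.05)


def test_summary_needs_two_frames():
    with pytest.raises(ValueError, match="2 frames"):
        traj_summary(gen_pose(4.2), "sg_c", spec=CatalyticSpec())


def test_unknown_metric_and_stray_args_error():
    traj = gen_trajectory(3, 4.0)
    with pytest.raises(ValueError, match="unknown metric"):
        traj_summary(traj, "banana")
    with pytest.raises(TypeError, match="unknown arguments"):
        traj_summary(traj, "sg_c", spec=CatalyticSpec(), bogus=1)


# ------------------------------------------------------------- thermodynamics

def test_zero_dg_gives_unit_kd():
    assert kd_from_dg(0.0) == pytest.approx(1.0)


def test_printed_kd_values_recovered_at_310K():
    assert kd_from_dg(-12.3, 310.0) == pytest.approx(2.1e-9, rel=0.10)
    assert kd_from_dg(-14.1, 310.0) == pytest.approx(1.2e-10, rel=0.10)


@given(st.floats(min_value=-20.0, max_value=0.0))
def test_dg_kd_are_mutual_inverses(x):
    assert dg_from_kd(kd_from_dg(x)) == pytest.approx(x, abs=1e-9)


def test_kd_monotone_and_below_one_for_favorable_binding():
    dgs = np.linspace(-15, 5, 50)
    kds = [kd_from_dg(d) for d in dgs]
    assert all(b > a for a, b in zip(kds, kds[1:]))
    assert all(kd_from_dg(d) < 1.0 for d in dgs if d < 0)


def test_domain_errors():
    with pytest.raises(ValueError, match="positive"):
        dg_from_kd(0.0)
    with pytest.raises(ValueError, match="temperature"):
        kd_from_dg(-10.0, temperature=-1.0)


# ------------------------------------------------------------ group contrasts

def test_identical_groups_share_a_letter(rng):
    vals = rng.normal(10, 1, size=50)
    _, letters = compare_hbond_groups({"a": vals, "b": vals.copy()})
    assert letters["a"] == letters["b"]


def test_separated_groups_get_distinct_letters(rng):
    groups = {
        "good": rng.normal(10, 1, size=100),
        "bad": rng.normal(4, 1, size=100),
    }
    result, letters = compare_hbond_groups(groups, alpha=0.01)
    assert result.p_value < 0.01
    assert set(letters["good"]).isdisjoint(letters["bad"])


def test_three_ordered_groups_letters_follow_ordering(rng):
    groups = {
        "low": rng.normal(4, 1, size=80),
        "mid": rng.normal(8, 1, size=80),
        "high": rng.normal(12, 1, size=80),
    }
    _, letters = compare_hbond_groups(groups, alpha=0.01)
    assert len({letters["low"], letters["mid"], letters["high"]}) == 3


def test_compact_letters_chain_structure():
    # a ~ b, b ~ c, but a !~ c: b must share a letter with both
    nd = {("a", "b"): True, ("b", "c"): True, ("a", "c"): False}
    letters = compact_letters(["a", "b", "c"], nd)
    assert set(letters["a"]) & set(letters["b"])
    assert set(letters["b"]) & set(letters["c"])
    assert not set(letters["a"]) & set(letters["c"])


def test_negative_control_fixture_is_distinguished():
    """A far-docked pose trajectory shows fewer hydrogen bonds and a
    larger SG-C distance distribution than a competent pose."""
    good = gen_preset("stable-traj", seed=21)
    bad = gen_preset("negative-traj", seed=22)
    crit = HBondCriteria()
    hb_good = traj_summary(good, "hbond", donors_sel={"chain_id": "E"},
                           acceptors_sel={"chain_id": "P"}, criteria=crit)
    hb_bad = traj_summary(bad, "hbond", donors_sel={"chain_id": "E"},
                          acceptors_sel={"chain_id": "P"}, criteria=crit)
    result, letters = compare_hbond_groups(
        {"good": hb_good.values, "bad": hb_bad.values}, alpha=0.01
    )
    assert hb_bad.mean < hb_good.mean
    assert set(letters["good"]).isdisjoint(letters["bad"])
    sg_good = traj_summary(good, "sg_c", spec=CatalyticSpec())
    sg_bad = traj_summary(bad, "sg_c", spec=CatalyticSpec())
    assert sg_bad.five_number.q1 > sg_good.five_number.q3
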