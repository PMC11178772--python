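"""Docked-pose screening, trajectory summaries and ΔG ↔ Kd conversion.

A docked enzyme–peptide pose is catalytically competent when the
nucleophile of the cysteine-protease triad (Cys SG by default) sits
within a threshold distance of the scissile carbonyl carbon — 5.0 Å by
default, with 4.5 Å the common stricter choice. Trajectories (multi-model
structures) are summarised per frame: hydrogen-bond counts under
geometric criteria, SG–C distance series, or fitted RMSD, each with mean,
standard error and a five-number summary for box plots.

Binding free energy and the dissociation constant are related by
ΔG = RT ln Kd with R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹; Kd is reported as the
dimensionless exponential, with no standard-state conversion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clotstats import AnovaResult, anova_posthoc
from .io import Atom, Structure
from .metrics import atom_distance, rmsd_series

__all__ = [
    "GAS_CONSTANT_KCAL",
    "CatalyticSpec",
    "PoseMetrics",
    "HBondCriteria",
    "FiveNumber",
    "screen_pose",
    "hbond_count",
    "TrajSummary",
    "traj_summary",
    "kd_from_dg",
    "dg_from_kd",
    "compare_hbond_groups",
    "compact_letters",
]

log = logging.getLogger(__name__)

#: kcal / (mol K)
GAS_CONSTANT_KCAL = 1.9872e-3


@dataclass(frozen=True)
class CatalyticSpec:
    """Catalytic geometry to screen: triad atoms, scissile carbon, cutoff.

    Defaults follow the actinidin triad Cys25(SG)–His162(NE2)–Asn182(OD1).
    ``scissile`` names the P1 residue number and its carbonyl carbon on
    the peptide chain.
    """

    triad: tuple[tuple[str, int, str], ...] = (
        ("CYS", 25, "SG"),
        ("HIS", 162, "NE2"),
        ("ASN", 182, "OD1"),
    )
    scissile: tuple[int, str] = (1, "C")
    max_sg_c: float = 5.0
    enzyme_chain: str | None = None
    peptide_chain: str | None = None

    def __post_init__(self) -> None:
        if self.max_sg_c <= 0:
            raise ValueError("max_sg_c must be positive")
        if len(set(self.triad)) != len(self.triad):
            raise ValueError("triad entries must be distinct")


@dataclass
class PoseMetrics:
    """Screening result for one pose; accept iff sg_c <= threshold_used."""

    sg_c: float
    verdict: str
    threshold_used: float
    triad_distances: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond definition: donor–acceptor distance cutoff
    (Å) and, when hydrogens are present, the H–D–A angle cutoff (deg)."""

    max_da: float = 3.5
    max_angle_hda: float = 30.0

    def __post_init__(self) -> None:
        if self.max_da <= 0 or self.max_angle_hda <= 0:
            raise ValueError("hydrogen-bond criteria must be positive")


@dataclass(frozen=True)
class FiveNumber:
    """min, Q1, median, Q3, max — the whisker-box-plot statistics."""

    min: float
    q1: float
    median: float
    q3: float
    max: float

    def __post_init__(self) -> None:
        vals = (self.min, self.q1, self.median, self.q3, self.max)
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ValueError(f"five-number summary not ordered: {vals}")

    @classmethod
    def of(cls, values) -> "FiveNumber":
        v = np.asarray(values, dtype=float)
        lo, q1, med, q3, hi = np.percentile(v, [0, 25, 50, 75, 100], method="linear")
        return cls(float(lo), float(q1), float(med), float(q3), float(hi))


def _find_atom(
    pose: Structure, res_name: str | None, res_seq: int, name: str,
    chain: str | None, model: int,
) -> Atom:
    sel: dict = {"res_seq": res_seq, "name": name}
    if res_name is not None:
        sel["res_name"] = res_name
    if chain is not None:
        sel["chain_id"] = chain
    hits = pose.select(model=model, **sel)
    if not hits:
        raise KeyError(f"atom {res_name or ''}{res_seq}/{name} not found in pose")
    if len(hits) > 1:
        raise ValueError(
            f"atom {res_name or ''}{res_seq}/{name} ambiguous: "
            f"{[(a.chain_id, a.model) for a in hits]}"
        )
    return hits[0]


def screen_pose(pose: Structure, spec: CatalyticSpec | None = None, model: int = 1) -> PoseMetrics:
    """Screen one docked pose for nucleophilic-attack competence.

    The gate is the distance from the triad's nucleophile key atom (its
    first entry) to the scissile carbonyl carbon; the remaining triad
    atoms are located and their distances to the nucleophile recorded but
    not gated.
    """
    spec = spec or CatalyticSpec()
    nuc_res_name, nuc_res_seq, nuc_name = spec.triad[0]
    nuc = _find_atom(pose, nuc_res_name, nuc_res_seq, nuc_name, spec.enzyme_chain, model)
    sc = _find_atom(pose, None, spec.scissile[0], spec.scissile[1], spec.peptide_chain, model)
    sg_c = float(np.linalg.norm(nuc.coords - sc.coords))
    triad_distances = {}
    for res_name, res_seq, name in spec.triad[1:]:
        atom = _find_atom(pose, res_name, res_seq, name, spec.enzyme_chain, model)
        triad_distances[f"{res_name}{res_seq}/{name}"] = float(
            np.linalg.norm(nuc.coords - atom.coords)
        )
    verdict = "accept" if sg_c <= spec.max_sg_c else "reject"
    return PoseMetrics(
        sg_c=sg_c, verdict=verdict, threshold_used=spec.max_sg_c,
        triad_distances=triad_distances,
    )


def _polar_atoms(frame: Structure, sel: dict, model: int) -> list[Atom]:
    atoms = frame.select(model=model, **sel)
    return [a for a in atoms if a.element in ("N", "O", "S")]


def hbond_count(
    frame: Structure,
    donors_sel: dict,
    acceptors_sel: dict,
    criteria: HBondCriteria | None = None,
    model: int = 1,
) -> int:
    """Count geometric hydrogen bonds between two selections.

    Donors and acceptors are the polar (N/O/S) atoms of each selection; a
    (D, A) pair is a bond when the D–A distance is within ``max_da`` and,
    when D carries a covalent hydrogen (within 1.25 Å, same residue), some
    H–D–A angle is within ``max_angle_hda``. Without hydrogens the angle
    criterion is skipped (logged). Pairs within one selection are not
    counted, and each (D, A) pair counts once.
    """
    criteria = criteria or HBondCriteria()
    donors = _polar_atoms(frame, donors_sel, model)
    acceptors = _polar_atoms(frame, acceptors_sel, model)
    if not donors or not acceptors:
        raise ValueError("empty donor or acceptor selection")
    hydrogens = [a for a in frame.atoms if a.model == model and a.element == "H"]
    if not hydrogens:
        log.info("no hydrogens present: applying the distance criterion only")
    h_by_res: dict[tuple, list] = {}
    for h in hydrogens:
        h_by_res.setdefault(h.residue_key, []).append(h)
    dc = np.array([d.coords for d in donors])
    ac = np.array([a.coords for a in acceptors])
    within = np.linalg.norm(dc[:, None, :] - ac[None, :, :], axis=2) <= criteria.max_da
    count = 0
    for i, d in enumerate(donors):
        attached = [
            h for h in h_by_res.get(d.residue_key, ())
            if np.linalg.norm(h.coords - d.coords) <= 1.25
        ]
        for j in np.nonzero(within[i])[0]:
            a = acceptors[j]
            if a is d or a.residue_key + (a.name,) == d.residue_key + (d.name,):
                continue
            if attached:
                ok = False
                for h in attached:
                    v1 = h.coords - d.coords
                    v2 = a.coords - d.coords
                    cosang = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
                    ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                    if ang <= criteria.max_angle_hda:
                        ok = True
                        break
                if not ok:
                    continue
            count += 1
    return count


@dataclass
class TrajSummary:
    """Per-frame values plus mean ± SE and the five-number summary."""

    metric: str
    table: pd.DataFrame  # columns: frame, value
    mean: float
    se: float
    five_number: FiveNumber

    @property
    def values(self) -> np.ndarray:
        return self.table["value"].to_numpy()


def traj_summary(traj: Structure, metric: str, **args) -> TrajSummary:
    """Summarise a trajectory under one metric.

    ``metric``:
      * ``"hbond"`` — args ``donors_sel``, ``acceptors_sel``, optional
        ``criteria``;
      * ``"sg_c"`` — args ``spec`` (:class:`CatalyticSpec`) or explicit
        ``sel_a``/``sel_b`` atom selections;
      * ``"rmsd"`` — args forwarded to :func:`fibryze.metrics.rmsd_series`.

    Quartiles use linear interpolation (``numpy.percentile``,
    ``method="linear"``).
    """
    frames = traj.split_models()
    if len(frames) < 2:
        raise ValueError("a trajectory needs at least 2 frames")
    if metric == "hbond":
        donors_sel = args.pop("donors_sel")
        acceptors_sel = args.pop("acceptors_sel")
        criteria = args.pop("criteria", None)
        if args:
            raise TypeError(f"unknown arguments for hbond metric: {sorted(args)}")
        rows = [
            (m, float(hbond_count(frame, donors_sel, acceptors_sel, criteria, model=m)))
            for m, frame in frames.items()
        ]
    elif metric == "sg_c":
        if "spec" in args:
            spec: CatalyticSpec = args.pop("spec")
            nuc_res_name, nuc_res_seq, nuc_name = spec.triad[0]
            sel_a = {"res_name": nuc_res_name, "res_seq": nuc_res_seq, "name": nuc_name}
            if spec.enzyme_chain:
                sel_a["chain_id"] = spec.enzyme_chain
            sel_b = {"res_seq": spec.scissile[0], "name": spec.scissile[1]}
            if spec.peptide_chain:
                sel_b["chain_id"] = spec.peptide_chain
        else:
            sel_a = args.pop("sel_a")
            sel_b = args.pop("sel_b")
        if args:
            raise TypeError(f"unknown arguments for sg_c metric: {sorted(args)}")
        rows = [
            (m, atom_distance(frame, sel_a, sel_b, model=m))
            for m, frame in frames.items()
        ]
    elif metric == "rmsd":
        df = rmsd_series(traj, **args)
        rows = list(df.itertuples(index=False, name=None))
    else:
        raise ValueError(f"unknown metric {metric!r}; use hbond, sg_c or rmsd")
    table = pd.DataFrame(rows, columns=["frame", "value"])
    vals = table["value"].to_numpy()
    mean = float(vals.mean())
    se = float(vals.std(ddof=1) / np.sqrt(len(vals)))
    return TrajSummary(
        metric=metric, table=table, mean=mean, se=se, five_number=FiveNumber.of(vals)
    )


# ---------------------------------------------------------------------------
# Thermodynamics

def kd_from_dg(delta_g: float, temperature: float = 310.15) -> float:
    """Dissociation constant from binding free energy: Kd = exp(ΔG/RT).

    ΔG in kcal/mol; Kd is the dimensionless exponential form.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    return math.exp(delta_g / (GAS_CONSTANT_KCAL * temperature))


def dg_from_kd(kd: float, temperature: float = 310.15) -> float:
    """Binding free energy (kcal/mol) from Kd: ΔG = RT ln Kd."""
    if temperature <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    if kd <= 0:
        raise ValueError("kd must be positive")
    return GAS_CONSTANT_KCAL * temperature * math.log(kd)


# ---------------------------------------------------------------------------
# Group comparison

def compact_letters(order: list[str], not_different: dict[tuple[str, str], bool]) -> dict[str, str]:
    """Compact letter display over groups ordered by mean.

    Groups that are not significantly different share at least one
    letter. Maximal runs of mutually non-different groups (in mean order)
    each receive a letter; contained runs are absorbed.
    """
    k = len(order)

    def ns(i: int, j: int) -> bool:
        a, b = order[i], order[j]
        return not_different.get((a, b), not_different.get((b, a), False))

    runs = []
    for i in range(k):
        j = i
        while j + 1 < k and all(ns(x, j + 1) for x in range(i, j + 1)):
            j += 1
        runs.append((i, j))
    maximal = [
        r for r in runs
        if not any(o != r and o[0] <= r[0] and r[1] <= o[1] for o in runs)
    ]
    letters: dict[str, str] = {g: "" for g in order}
    for idx, (i, j) in enumerate(maximal):
        ch = chr(ord("a") + idx)
        for x in range(i, j + 1):
            letters[order[x]] += ch
    return letters


def compare_hbond_groups(
    counts_by_complex: dict[str, "np.typing.ArrayLike"],
    alpha: float = 0.01,
) -> tuple[AnovaResult, dict[str, str]]:
    """ANOVA across per-frame hydrogen-bond counts plus letter display.

    Letters follow the Holm-adjusted pairwise decisions at ``alpha``
    (default 0.01, the convention for trajectory comparisons); groups
    sharing a letter are not significantly different.
    """
    result = anova_posthoc(counts_by_complex, alpha=alpha)
    means = {g: float(np.mean(v)) for g, v in counts_by_complex.items()}
    order = sorted(means, key=lambda g: -means[g])
    nd = {
        (row.group_a, row.group_b): not row.reject_holm
        for row in result.posthoc.itertuples()
    }
    return result, compact_letters(order, nd)
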