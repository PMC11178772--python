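"""Protease substrate specificity: cleavage-site scanning and sequence identity.

A :class:`SpecificityModel` is a set of per-position allowed-residue sets in
Schechter–Berger notation (P4…P1 on the N-terminal side of the scissile
bond, P1'…P4' on the C-terminal side), grouped into evidence sources. The
bundled ``actinidin`` model combines kiwellin-derived and insulin-derived
evidence; under the default ``any_source`` rule a position is a predicted
cleavage site when at least one source is fully satisfied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml
from Bio import Align

from .io import SeqRecord, Structure, extract_sequence, VALID_RESIDUE_LETTERS

__all__ = [
    "POSITION_TAGS",
    "RuleSource",
    "SpecificityModel",
    "CleavageSite",
    "IdentityReport",
    "load_specificity",
    "scan_sequence",
    "pairwise_identity",
    "map_chains",
]

log = logging.getLogger(__name__)

#: Schechter–Berger position tags and their offsets relative to P1.
POSITION_TAGS: dict[str, int] = {
    "P4": -3, "P3": -2, "P2": -1, "P1": 0,
    "P1'": 1, "P2'": 2, "P3'": 3, "P4'": 4,
}

_AA = VALID_RESIDUE_LETTERS - {"X"}


@dataclass(frozen=True)
class RuleSource:
    """One evidence source: allowed residues per constrained position."""

    label: str
    positions: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for tag, residues in self.positions.items():
            if tag not in POSITION_TAGS:
                raise ValueError(f"source {self.label!r}: unknown position tag {tag!r}")
            bad = set(residues) - _AA
            if bad:
                raise ValueError(f"source {self.label!r} {tag}: invalid residues {sorted(bad)}")
            if not residues:
                raise ValueError(f"source {self.label!r} {tag}: empty residue set")
        for required in ("P1", "P1'"):
            if required not in self.positions:
                raise ValueError(f"source {self.label!r}: position {required} must be constrained")


@dataclass(frozen=True)
class SpecificityModel:
    """A named collection of rule sources with a combination rule.

    ``any_source``: a site needs one fully satisfied source.
    ``all_sources``: every source must be satisfied.
    """

    name: str
    sources: tuple[RuleSource, ...]
    combination: str = "any_source"

    def __post_init__(self) -> None:
        if not self.sources:
            raise ValueError("a specificity model needs at least one source")
        if self.combination not in ("any_source", "all_sources"):
            raise ValueError(f"unknown combination rule {self.combination!r}")

    def p1_union(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.sources:
            out |= s.positions["P1"]
        return frozenset(out)

    def p1prime_union(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.sources:
            out |= s.positions["P1'"]
        return frozenset(out)


@dataclass(frozen=True)
class CleavageSite:
    """A predicted scissile bond: cleavage between P1 and P1'.

    ``p1_pos`` is the author-numbered position of P1; ``window`` is the
    P4…P4' context actually tested, '-'-padded where it runs past a
    terminus.
    """

    chain_id: str
    p1_pos: int
    p1_res: str
    p1prime_res: str
    matched_source: str
    window: str


@dataclass
class IdentityReport:
    """Pairwise identity: percent, per-column mismatches, aligned length."""

    percent_identity: float
    mismatches: list[tuple[int, str, str]]
    aligned_length: int


def load_specificity(config: str | Path | dict | None = None) -> SpecificityModel:
    """Load a specificity model from a YAML file or mapping.

    With no argument, returns the bundled actinidin model (kiwellin +
    insulin evidence, ``any_source``).
    """
    if config is None:
        config = resources.files("fibryze.data") / "actinidin.yaml"
    if not isinstance(config, dict):
        with open(str(config)) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict) or "sources" not in config:
        raise ValueError("specificity config must be a mapping with a 'sources' list")
    sources = []
    for src in config["sources"]:
        positions = {
            tag: frozenset(str(r).upper() for r in residues)
            for tag, residues in (src.get("positions") or {}).items()
        }
        sources.append(RuleSource(label=str(src["label"]), positions=positions))
    return SpecificityModel(
        name=str(config.get("name", "unnamed")),
        sources=tuple(sources),
        combination=str(config.get("combination", "any_source")),
    )


def _source_verdict(seq: SeqRecord, i: int, source: RuleSource, breaks: frozenset[int]) -> str:
    """'match' | 'fail' | 'indeterminate' for P1 at 0-based index ``i``."""
    offsets = [POSITION_TAGS[t] for t in source.positions]
    lo, hi = i + min(offsets), i + max(offsets)
    if lo < 0 or hi >= len(seq):
        return "fail"  # constrained tags fall outside the sequence: no wraparound
    if any(lo <= b < hi for b in breaks):
        return "fail"  # never cross a numbering break
    verdict = "match"
    for tag, allowed in source.positions.items():
        res = seq.residues[i + POSITION_TAGS[tag]]
        if res == "X":
            verdict = "indeterminate"
        elif res not in allowed:
            return "fail"
    return verdict


def scan_sequence(
    seq: SeqRecord,
    model: SpecificityModel | None = None,
    return_indeterminate: bool = False,
):
    """Scan a sequence for predicted cleavage sites.

    Every position *i* is tested as P1; a source matches when each of its
    constrained positions lies inside the sequence (windows neither wrap
    nor span author-numbering breaks) and holds an allowed residue.
    Windows containing 'X' at a constrained position are indeterminate,
    never matches. Sites are returned ordered by P1 position.
    """
    if model is None:
        model = load_specificity()
    if len(seq) < 2:
        raise ValueError("sequence must have length >= 2")
    breaks = frozenset(seq.breaks)
    sites: list[CleavageSite] = []
    indeterminate: list[int] = []
    for i in range(len(seq) - 1):
        verdicts = {s.label: _source_verdict(seq, i, s, breaks) for s in model.sources}
        if model.combination == "any_source":
            matched = next((lbl for lbl, v in verdicts.items() if v == "match"), None)
        else:
            matched = (
                model.sources[0].label
                if all(v == "match" for v in verdicts.values())
                else None
            )
        if matched is not None:
            window = "".join(
                seq.residues[i + off] if 0 <= i + off < len(seq) else "-"
                for off in range(-3, 5)
            )
            sites.append(
                CleavageSite(
                    chain_id=seq.id,
                    p1_pos=seq.position(i),
                    p1_res=seq.residues[i],
                    p1prime_res=seq.residues[i + 1],
                    matched_source=matched,
                    window=window,
                )
            )
        elif any(v == "indeterminate" for v in verdicts.values()):
            indeterminate.append(seq.position(i))
    if return_indeterminate:
        return sites, indeterminate
    return sites


def _global_align(a: str, b: str) -> tuple[str, str]:
    """Global alignment, match +1 / mismatch 0 / gap -1; first optimal
    alignment in the aligner's deterministic enumeration order (leftmost
    tie-break)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def pairwise_identity(a: SeqRecord, b: SeqRecord) -> IdentityReport:
    """Percent identity between two sequences.

    Equal-length inputs are compared position-wise; unequal lengths are
    globally aligned first. The denominator is the aligned length
    including gap columns; percent is reported to one decimal. Mismatch
    positions are 1-based alignment columns ('-' marks a gap).
    """
    if not a.residues or not b.residues:
        raise ValueError("cannot compare an empty sequence")
    if len(a) == len(b):
        ga, gb = a.residues, b.residues
    else:
        ga, gb = _global_align(a.residues, b.residues)
    mismatches = [
        (i + 1, ra, rb) for i, (ra, rb) in enumerate(zip(ga, gb)) if ra != rb
    ]
    matches = len(ga) - len(mismatches)
    pct = round(100.0 * matches / len(ga), 1)
    return IdentityReport(percent_identity=pct, mismatches=mismatches, aligned_length=len(ga))


def map_chains(
    structure: Structure,
    references: list[SeqRecord],
    min_identity: float = 30.0,
    model: int = 1,
) -> dict[str, str | None]:
    """Assign each chain of ``structure`` to its closest reference sequence.

    Greedy best-score bijective assignment (ties broken by chain id, then
    reference order); once every reference is used, remaining chains may
    reuse their best reference (crystal structures often carry duplicate
    chains). Chains whose best identity falls below ``min_identity`` are
    left unassigned with a warning.
    """
    if not references:
        raise ValueError("references must be non-empty")
    chains = sorted(structure.chains)
    scores: dict[tuple[str, str], float] = {}
    for c in chains:
        seq = extract_sequence(structure, c, model=model)
        for ref in references:
            scores[(c, ref.id)] = pairwise_identity(seq, ref).percent_identity
    ref_order = {r.id: i for i, r in enumerate(references)}
    ranked = sorted(
        scores.items(), key=lambda kv: (-kv[1], kv[0][0], ref_order[kv[0][1]])
    )
    assignment: dict[str, str | None] = {}
    used_refs: set[str] = set()
    for (c, rid), score in ranked:
        if c in assignment or rid in used_refs or score < min_identity:
            continue
        assignment[c] = rid
        used_refs.add(rid)
        log.info("chain %s -> %s (%.1f%% identity)", c, rid, score)
    for c in chains:
        if c in assignment:
            continue
        best_rid, best = None, -1.0
        for ref in references:
            if scores[(c, ref.id)] > best:
                best_rid, best = ref.id, scores[(c, ref.id)]
        if best >= min_identity:
            assignment[c] = best_rid
            log.info("chain %s -> %s (%.1f%% identity, reference reused)", c, best_rid, best)
        else:
            assignment[c] = None
            log.warning("chain %s unassigned (best identity %.1f%% < %.1f%%)", c, best, min_identity)
    return assignment
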