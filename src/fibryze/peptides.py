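"""Docking-peptide windows around predicted cleavage sites.

Each cleavage site yields one peptide: the two digestion fragments
flanking the scissile bond, truncated to at most ``flank`` residues each
(default 10, i.e. a 20-mer for interior sites with the scissile bond at
its centre). Windows never span a numbering break of the source chain.
Adjacent sites are never merged: one scissile bond, one window.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .io import SeqRecord, write_fasta
from .specificity import CleavageSite

__all__ = ["PeptideWindow", "make_window", "windows_to_fasta", "window_id"]

_GREEK = str.maketrans({"α": "a", "β": "b", "γ": "g"})


@dataclass(frozen=True)
class PeptideWindow:
    """A docking peptide: ``n_flank`` residues ending at P1, then
    ``c_flank`` residues starting at P1'. The scissile bond lies between
    window positions ``n_flank`` and ``n_flank + 1`` (1-based)."""

    site: CleavageSite
    residues: str
    start_pos: int
    end_pos: int
    n_flank: int
    c_flank: int

    def __post_init__(self) -> None:
        if len(self.residues) != self.n_flank + self.c_flank:
            raise ValueError("window length must equal n_flank + c_flank")


def make_window(seq: SeqRecord, site: CleavageSite, flank: int = 10) -> PeptideWindow:
    """Build the docking window for ``site`` on ``seq``.

    The window spans author positions ``p1 - flank + 1 … p1 + flank``,
    truncated at chain termini and at numbering breaks. A site with zero
    residues available on either side (a break right at the scissile
    bond) is an error.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    idx = seq.index_of(site.p1_pos)
    if seq.residues[idx] != site.p1_res:
        raise ValueError(
            f"site/sequence mismatch at {site.p1_pos}: "
            f"{seq.residues[idx]} != {site.p1_res}"
        )
    breaks = seq.breaks
    start = max(0, idx - flank + 1)
    end = min(len(seq) - 1, idx + flank)  # inclusive
    for b in breaks:  # b = last index before a discontinuity
        if start <= b < idx:
            start = max(start, b + 1)
        if idx <= b < end:
            end = min(end, b)
    if end < idx + 1:
        raise ValueError(
            f"site at {site.p1_pos}: numbering break at the scissile bond "
            "leaves zero residues on the C-terminal side"
        )
    n_flank = idx - start + 1
    c_flank = end - idx
    return PeptideWindow(
        site=site,
        residues=seq.residues[start : end + 1],
        start_pos=seq.position(start),
        end_pos=seq.position(end),
        n_flank=n_flank,
        c_flank=c_flank,
    )


def window_id(w: PeptideWindow) -> str:
    """FASTA id encoding chain, P1 position and the flank counts,
    e.g. ``Bb_346_n10c10``."""
    chain = w.site.chain_id.translate(_GREEK).replace(" ", "_")
    return f"{chain}_{w.site.p1_pos}_n{w.n_flank}c{w.c_flank}"


def windows_to_fasta(windows: list[PeptideWindow], path: str | Path) -> None:
    """Write one FASTA record per window; duplicate ids are an error."""
    if not windows:
        raise ValueError("no windows to write")
    records = [SeqRecord(id=window_id(w), residues=w.residues) for w in windows]
    write_fasta(records, path)
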