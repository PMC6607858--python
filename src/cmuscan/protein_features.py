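"""Protein architecture profiling: composition-rich spacers, CHAP catalytic
triads and molecular mass.

The muramidases this package targets share a three-part architecture — an
N-terminal region rich in polar residues, a serine/alanine/threonine-rich
spacer, and a C-terminal CHAP (NlpC/P60) catalytic domain whose triad is a
nucleophilic cysteine, a catalytic histidine and a third polar residue
(H, E, D or N).  The operations here locate each feature:

* a sliding-window composition track and maximal-run caller for the
  low-complexity spacer regions;
* exhaustive C..H..X triad enumeration under configurable spacing limits;
* average-mass molecular weight (the kDa values practitioners compare with
  SDS-PAGE migration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import SeqRecord, SequenceError

#: Average residue (amino acid minus water) masses in Da.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.01524


@dataclass(frozen=True)
class CompositionTrack:
    """Per-position fraction of window residues belonging to a residue set.

    Windows are centred; at the termini the window is truncated to the
    available residues and the denominator is the actual window size.
    """

    protein_id: str
    window: int
    residue_set: frozenset[str]
    values: tuple[float, ...]


@dataclass(frozen=True)
class RichRegion:
    start: int
    end: int  # 0-based half-open
    mean_fraction: float


@dataclass(frozen=True)
class TriadSite:
    cys_pos: int
    his_pos: int
    third_pos: int
    third_residue: str


@dataclass(frozen=True)
class TriadSpacing:
    """Allowed residue gaps (counts of intervening residues) C->H and H->X."""

    min_ch: int = 10
    max_ch: int = 130
    min_hx: int = 3
    max_hx: int = 60


#: Accepted third triad residues: a second histidine, glutamate, aspartate
#: or asparagine.
THIRD_RESIDUES = frozenset("HEDN")


def _check_protein(protein: SeqRecord) -> None:
    if protein.alphabet != "protein":
        raise SequenceError(f"record {protein.id!r} is not a protein record")


def composition_track(protein: SeqRecord, window: int,
                      residue_set: str | frozenset[str]) -> CompositionTrack:
    """Sliding-window fraction of residues in ``residue_set`` at each position."""
    _check_protein(protein)
    if window % 2 == 0 or not (5 <= window <= 51):
        raise ValueError("window must be odd and in [5, 51]")
    seq = protein.sequence
    if window > len(seq):
        raise ValueError("window larger than sequence")
    rset = frozenset(residue_set)
    member = np.fromiter((ch in rset for ch in seq), dtype=float, count=len(seq))
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(member)])
    n = len(seq)
    starts = np.maximum(np.arange(n) - half, 0)
    ends = np.minimum(np.arange(n) + half + 1, n)
    values = (csum[ends] - csum[starts]) / (ends - starts)
    return CompositionTrack(protein_id=protein.id, window=window,
                            residue_set=rset, values=tuple(values.tolist()))


def call_rich_regions(track: CompositionTrack, min_frac: float,
                      min_len: int) -> list[RichRegion]:
    """Maximal runs of positions with track value >= min_frac, length-filtered."""
    regions: list[RichRegion] = []
    n = len(track.values)
    i = 0
    while i < n:
        if track.values[i] >= min_frac:
            j = i
            while j < n and track.values[j] >= min_frac:
                j += 1
            if j - i >= min_len:
                mean = float(np.mean(track.values[i:j]))
                regions.append(RichRegion(start=i, end=j, mean_fraction=mean))
            i = j
        else:
            i += 1
    return regions


def find_triads(protein: SeqRecord, search_start: int = 0,
                search_end: int | None = None,
                spacing: TriadSpacing | None = None) -> list[TriadSite]:
    """All ordered C..H..X occurrences (X in {H, E, D, N}) whose C->H and
    H->X gaps fall inside the spacing limits; sorted by (cys_pos, his_pos,
    third_pos)."""
    _check_protein(protein)
    spacing = spacing or TriadSpacing()
    seq = protein.sequence
    if search_end is None:
        search_end = len(seq)
    if not (0 <= search_start < search_end <= len(seq)):
        raise ValueError(f"invalid search range [{search_start}, {search_end})")
    region = range(search_start, search_end)
    cys = [i for i in region if seq[i] == "C"]
    his = [i for i in region if seq[i] == "H"]
    third = [i for i in region if seq[i] in THIRD_RESIDUES]
    sites: list[TriadSite] = []
    for c in cys:
        for h in his:
            gap_ch = h - c - 1
            if not (spacing.min_ch <= gap_ch <= spacing.max_ch):
                continue
            for x in third:
                gap_hx = x - h - 1
                if not (spacing.min_hx <= gap_hx <= spacing.max_hx):
                    continue
                sites.append(TriadSite(cys_pos=c, his_pos=h, third_pos=x,
                                       third_residue=seq[x]))
    sites.sort(key=lambda s: (s.cys_pos, s.his_pos, s.third_pos))
    return sites


def molecular_mass(protein: SeqRecord | str) -> float:
    """Average molecular mass in Da: sum of residue masses plus one water."""
    seq = protein.sequence if isinstance(protein, SeqRecord) else protein
    if not seq:
        raise SequenceError("empty protein sequence")
    mass = WATER_MASS
    for pos, ch in enumerate(seq):
        try:
            mass += AVERAGE_RESIDUE_MASS[ch]
        except KeyError:
            raise SequenceError(
                f"non-standard residue {ch!r} at position {pos + 1}") from None
    return mass
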