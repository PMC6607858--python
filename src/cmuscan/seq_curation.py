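"""Global-alignment percent identity and greedy redundancy removal.

Identity is computed from a Needleman-Wunsch global alignment; the
denominator is the full alignment length *including gap columns* (stated
explicitly because conventions differ between tools).  Redundancy removal
is a single greedy pass over the records sorted by descending length: a
record is kept iff its identity to every already-kept record is strictly
below the threshold, so a threshold of 100 removes only exact duplicates.
The default threshold of 98% reproduces the curation step applied to the
muramidase homolog datasets before phylogenetic analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import SeqRecord, SequenceError

#: Scoring presets; gap penalties follow common EMBOSS-style defaults.
SCORING_PRESETS = {
    "protein": {"matrix": "BLOSUM62", "open": -10.0, "extend": -0.5},
    "dna": {"match": 5.0, "mismatch": -4.0, "open": -10.0, "extend": -0.5},
}


@dataclass(frozen=True)
class IdentityResult:
    id_a: str
    id_b: str
    identity_pct: float
    aligned_columns: int


@dataclass(frozen=True)
class RedundancyResult:
    retained: tuple[str, ...]
    removed: dict[str, str]  # removed id -> representative retained id
    threshold_pct: float


def _aligner(alphabet: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if alphabet == "protein":
        preset = SCORING_PRESETS["protein"]
        aligner.substitution_matrix = substitution_matrices.load(preset["matrix"])
    else:
        preset = SCORING_PRESETS["dna"]
        aligner.match_score = preset["match"]
        aligner.mismatch_score = preset["mismatch"]
    aligner.open_gap_score = preset["open"]
    aligner.extend_gap_score = preset["extend"]
    return aligner


def global_identity(a: SeqRecord, b: SeqRecord) -> IdentityResult:
    """Percent identity over all columns of an optimal global alignment.

    The scoring preset follows the records' alphabet (BLOSUM62 for protein,
    +5/-4 for DNA, gap open 10 / extend 0.5 in both).  When co-optimal
    alignments exist the aligner's first is used, which is deterministic.
    """
    if a.alphabet != b.alphabet:
        raise SequenceError(
            f"alphabet mismatch: {a.id} is {a.alphabet}, {b.id} is {b.alphabet}")
    aligner = _aligner(a.alphabet)
    aln = aligner.align(a.sequence, b.sequence)[0]
    counts = aln.counts()
    columns = aln.length
    identity = 100.0 * counts.identities / columns
    return IdentityResult(id_a=a.id, id_b=b.id, identity_pct=identity,
                          aligned_columns=columns)


def remove_redundant(records: list[SeqRecord],
                     threshold_pct: float = 98.0) -> RedundancyResult:
    """Greedy redundancy removal at an identity threshold.

    Records are visited in order of descending length (ties: input order).
    A record is retained iff its identity to every already-retained record
    is < ``threshold_pct``; otherwise it is assigned to the first retained
    record meeting the threshold as its representative.
    """
    if not records:
        raise ValueError("at least one record required")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise SequenceError("duplicate ids in input")
    order = sorted(range(len(records)), key=lambda i: (-len(records[i]), i))
    retained: list[SeqRecord] = []
    removed: dict[str, str] = {}
    for i in order:
        rec = records[i]
        representative = None
        for kept in retained:
            if global_identity(rec, kept).identity_pct >= threshold_pct:
                representative = kept.id
                break
        if representative is None:
            retained.append(rec)
        else:
            removed[rec.id] = representative
    return RedundancyResult(retained=tuple(r.id for r in retained),
                            removed=removed, threshold_pct=threshold_pct)
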