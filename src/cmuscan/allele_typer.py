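"""Single-locus VNTR scheme definition and allele calling.

A :class:`LocusScheme` bundles the repeat units of a locus, the conserved
flanking anchors used to locate and orient it, and an allele table mapping
copy-number profiles to allele names.  The bundled ``cmuB`` scheme encodes
the two 18-nt minisatellite units of the *L. casei* BL23 P75-encoding gene
and its four known alleles:

====== ==============================
allele copy-number profile (TR1, TR2)
====== ==============================
cmuB1  (2, 2)   — BL23 baseline
cmuB2  (3, 2)   — extra first-unit copy
cmuB3  (2, 0)   — second unit deleted
cmuB4  (0, 3)   — first unit deleted, extra second-unit copy
====== ==============================

Zero is a legal copy count (deletion alleles); a profile absent from the
table is reported as ``"novel"``.  Typing failures on biological input
(missing anchors, ambiguous orientation) are encoded as warnings on the
call, never raised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .repeat_finder import count_unit_copies
from .seqio import DNA_ALPHABET, SeqRecord, hamming, reverse_complement


class SchemeError(ValueError):
    """Raised for an invalid locus-scheme definition."""


@dataclass(frozen=True)
class RepeatUnit:
    label: str
    sequence: str


@dataclass(frozen=True)
class LocusScheme:
    """Ordered repeat units + flanking anchors + allele table for one locus.

    ``anchors`` is an ordered list: left flank, optional inter-unit spacer
    anchor(s), right flank.  ``allele_table`` maps copy-number profiles (one
    integer per unit, in unit order) to allele names.
    """

    locus_name: str
    anchors: tuple[str, ...]
    units: tuple[RepeatUnit, ...]
    allele_table: dict[tuple[int, ...], str]
    anchor_max_mismatch: int = 2

    def __post_init__(self) -> None:
        if not self.units:
            raise SchemeError("scheme must define at least one repeat unit")
        seqs = [u.sequence for u in self.units]
        if len(set(seqs)) != len(seqs):
            raise SchemeError("unit sequences must be distinct")
        if any(len(s) < 4 for s in seqs):
            raise SchemeError("all unit lengths must be >= 4")
        if len(self.anchors) < 2:
            raise SchemeError("scheme needs at least left and right anchors")
        for a in list(self.anchors) + seqs:
            bad = set(a) - DNA_ALPHABET
            if bad:
                raise SchemeError(f"illegal characters {sorted(bad)} in scheme")
        arity = len(self.units)
        for profile in self.allele_table:
            if len(profile) != arity:
                raise SchemeError(
                    f"profile {profile} has arity {len(profile)}, "
                    f"expected {arity} (one count per unit)"
                )
            if any(c < 0 for c in profile):
                raise SchemeError("profile counts must be >= 0")
        names = list(self.allele_table.values())
        if len(set(names)) != len(names):
            raise SchemeError("allele names must be unique")

    @property
    def left_anchor(self) -> str:
        return self.anchors[0]

    @property
    def right_anchor(self) -> str:
        return self.anchors[-1]


@dataclass(frozen=True)
class AlleleCall:
    """Typing result for one sequence: profile, allele name and diagnostics."""

    seq_id: str
    profile: tuple[int, ...] | None
    allele: str | None
    strand: str | None = None
    anchor_hits: tuple[tuple[int, int], ...] = ()  # (position, mismatches) per anchor
    warnings: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return self.profile is not None

    @property
    def profile_str(self) -> str:
        if self.profile is None:
            return "NA"
        return "-".join(str(c) for c in self.profile)


# The 18-nt minisatellite units of cmuB (L. casei BL23).
CMUB_TR1 = "AGTGCTGCCGCAGAATCC"
CMUB_TR2 = "ACGCCGACTCCTGCACCA"

# Synthetic stand-in anchors: the conserved flanks bordering the cmuB repeat
# region are figure-only data not reproduced here; these deterministic
# sequences play their structural role so the scheme is usable end-to-end.
_SYNTHETIC_LEFT_ANCHOR = "GATCAAGCTGGTCAACGGTTCAGCTGATAC"
_SYNTHETIC_SPACER_ANCHOR = "TTGACCGGAACTGTCAGGTCAAC"
_SYNTHETIC_RIGHT_ANCHOR = "CAGTTCGACCTTGATGGCAACTGGATCGTA"


def bundled_cmub_scheme() -> LocusScheme:
    """The cmuB VNTR scheme: two 18-nt units, four alleles.

    Anchor sequences are synthetic stand-ins (see module note); units and
    the allele table are the published values.
    """
    return LocusScheme(
        locus_name="cmuB",
        anchors=(_SYNTHETIC_LEFT_ANCHOR, _SYNTHETIC_SPACER_ANCHOR,
                 _SYNTHETIC_RIGHT_ANCHOR),
        units=(RepeatUnit("TR1", CMUB_TR1), RepeatUnit("TR2", CMUB_TR2)),
        allele_table={
            (2, 2): "cmuB1",
            (3, 2): "cmuB2",
            (2, 0): "cmuB3",
            (0, 3): "cmuB4",
        },
    )


def load_scheme(path: str | Path) -> LocusScheme:
    """Load a locus scheme from JSON.

    Expected shape::

        {"locus": "cmuB", "anchors": [...], "units": [{"label":, "seq":}, ...],
         "alleles": {"cmuB1": [2, 2], ...}, "anchor_max_mismatch": 2}
    """
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemeError(f"malformed scheme JSON: {exc}") from exc
    try:
        units = tuple(RepeatUnit(u["label"], u["seq"].upper()) for u in data["units"])
        alleles = {tuple(v): k for k, v in data["alleles"].items()}
        if len(alleles) != len(data["alleles"]):
            raise SchemeError("two alleles share one copy-number profile")
        return LocusScheme(
            locus_name=data["locus"],
            anchors=tuple(a.upper() for a in data["anchors"]),
            units=units,
            allele_table=alleles,
            anchor_max_mismatch=int(data.get("anchor_max_mismatch", 2)),
        )
    except KeyError as exc:
        raise SchemeError(f"scheme JSON missing key {exc.args[0]!r}") from exc


def save_scheme(scheme: LocusScheme, path: str | Path) -> None:
    data = {
        "locus": scheme.locus_name,
        "anchors": list(scheme.anchors),
        "units": [{"label": u.label, "seq": u.sequence} for u in scheme.units],
        "alleles": {name: list(profile)
                    for profile, name in scheme.allele_table.items()},
        "anchor_max_mismatch": scheme.anchor_max_mismatch,
    }
    Path(path).write_text(json.dumps(data, indent=2) + "\n")


def _find_anchor(seq: str, anchor: str, max_mm: int, from_pos: int = 0) -> tuple[int, int] | None:
    """Leftmost anchor placement at or after ``from_pos``: exact first, then
    best Hamming <= max_mm."""
    idx = seq.find(anchor, from_pos)
    if idx >= 0:
        return idx, 0
    for p in range(from_pos, len(seq) - len(anchor) + 1):
        mm = hamming(seq[p:p + len(anchor)], anchor)
        if mm <= max_mm:
            return p, mm
    return None


def _place_anchors(seq: str, scheme: LocusScheme) -> list[tuple[int, int]] | None:
    """Place all anchors left to right; None if any anchor is missing."""
    hits: list[tuple[int, int]] = []
    pos = 0
    for anchor in scheme.anchors:
        hit = _find_anchor(seq, anchor, scheme.anchor_max_mismatch, pos)
        if hit is None:
            return None
        hits.append(hit)
        pos = hit[0] + len(anchor)
    return hits


def type_locus(record: SeqRecord, scheme: LocusScheme,
               detect_orientation: bool = True,
               max_mismatch_per_copy: int = 1) -> AlleleCall:
    """Call the allele of one sequence against a locus scheme.

    Anchors are located (exact match first, else best Hamming placement
    within ``anchor_max_mismatch``, leftmost); copies of each unit are then
    counted between the outer anchors with :func:`count_unit_copies` and the
    profile mapped through the allele table.  Zero copies is a legal count.
    By default both strands are tried and the one with successful anchor
    placement is used; if both succeed, the forward strand is used with a
    warning.  Missing anchors yield a failed call with diagnostics.
    """
    if record.alphabet != "dna-iupac":
        raise SchemeError("typing requires a dna record")
    warnings: list[str] = []

    fwd = record.sequence
    placements = {"+": _place_anchors(fwd, scheme)}
    if detect_orientation:
        placements["-"] = _place_anchors(reverse_complement(fwd), scheme)

    usable = [s for s, hits in placements.items() if hits is not None]
    if not usable:
        return AlleleCall(
            seq_id=record.id, profile=None, allele=None,
            warnings=("anchors not found on either strand",),
        )
    if len(usable) > 1:
        warnings.append("anchors place on both strands; using forward")
    strand = usable[0]
    hits = placements[strand]
    assert hits is not None
    seq = fwd if strand == "+" else reverse_complement(fwd)

    left_end = hits[0][0] + len(scheme.anchors[0])
    right_start = hits[-1][0]
    region = seq[left_end:right_start]

    profile = []
    for unit in scheme.units:
        arrays = count_unit_copies(region, unit.sequence, max_mismatch_per_copy)
        copies = sum(a.copies for a in arrays)
        if len(arrays) > 1:
            warnings.append(f"unit {unit.label}: copies split across "
                            f"{len(arrays)} arrays")
        if any(a.partial_trailing for a in arrays):
            warnings.append(f"unit {unit.label}: partial trailing copy ignored")
        profile.append(copies)
    profile_t = tuple(profile)
    allele = scheme.allele_table.get(profile_t, "novel")
    return AlleleCall(
        seq_id=record.id, profile=profile_t, allele=allele, strand=strand,
        anchor_hits=tuple(hits), warnings=tuple(warnings),
    )
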