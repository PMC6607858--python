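"""In-silico PCR with IUPAC-degenerate primers.

Primer sites are located by sliding-window comparison with set-intersection
semantics for ambiguity codes (an R in the primer matches A or G on the
template, and an ambiguous template base matches when the expansion sets
intersect).  A configurable number of substitutions is tolerated, but the
3'-terminal bases of each primer must match exactly (polymerase extension
requires a paired 3' end); indels are not modelled, nor is annealing
thermodynamics — ``annealing_c`` is carried as assay metadata only.

An amplicon is every compatible pairing of a forward-primer site with the
reverse-complement site of the reverse primer downstream of it, within the
configured product-length bounds; both orientations of the template are
considered.  Product length includes both primer footprints.

The two bundled assays are the published diagnostic pairs for the genes
encoding the P40 and P75 muramidases of the *L. casei/paracasei/rhamnosus*
group (expected products ~278 nt and 138 nt respectively).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

from .seqio import (DNA_ALPHABET, SeqRecord, SequenceError, iupac_matches,
                    reverse_complement)


@dataclass(frozen=True)
class PrimerAssay:
    """A degenerate primer pair.  Both primers are given 5'->3' as
    synthesized; the reverse primer binds the opposite strand."""

    name: str
    forward: str
    reverse: str
    annealing_c: float | None = None
    expected_length: int | None = None

    def __post_init__(self) -> None:
        for label, p in (("forward", self.forward), ("reverse", self.reverse)):
            if len(p) < 15:
                raise ValueError(f"{label} primer shorter than 15 nt")
            bad = set(p) - DNA_ALPHABET
            if bad:
                raise SequenceError(
                    f"{label} primer contains illegal characters {sorted(bad)}")


@dataclass(frozen=True)
class PcrParams:
    max_mismatch: int = 2
    three_prime_protect: int = 3
    min_len: int = 40
    max_len: int = 5000


@dataclass(frozen=True)
class PrimerSite:
    """One primer binding site.  ``start``/``end`` are on the given template
    strand (0-based half-open); ``strand`` is the strand the primer anneals
    to ('+': primer reads along the template as given)."""

    start: int
    end: int
    strand: str
    mismatches: int


@dataclass(frozen=True)
class Amplicon:
    template_id: str
    start: int
    end: int
    strand: str
    fwd_mismatches: int
    rev_mismatches: int
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start


# Published diagnostic assays (degenerate bases R = A/G, M = A/C).
BUNDLED_ASSAYS: tuple[PrimerAssay, ...] = (
    PrimerAssay(
        name="P40carh",
        forward="CCTTGGGGTCARTGCACMTGGTACG",
        reverse="CCGGTTGGTGAGCTGAAGCCC",
        annealing_c=55.0,
        expected_length=278,
    ),
    PrimerAssay(
        name="P75carh",
        forward="GACCACCGTATGGAATAGTCC",
        reverse="GGRATCCACTGATTGTCGCC",
        annealing_c=55.0,
        expected_length=138,
    ),
)


def _max_n_run(s: str) -> int:
    run = best = 0
    for ch in s:
        run = run + 1 if ch == "N" else 0
        best = max(best, run)
    return best


def _scan_one_strand(template: str, primer: str, max_mismatch: int,
                     three_prime_protect: int) -> list[tuple[int, int]]:
    """(start, mismatches) for primer read 5'->3' along this strand."""
    L = len(primer)
    protect_from = L - three_prime_protect
    out = []
    for s in range(0, len(template) - L + 1):
        window = template[s:s + L]
        mm = 0
        ok = True
        for i in range(L):
            if not iupac_matches(primer[i], window[i]):
                if i >= protect_from:
                    ok = False
                    break
                mm += 1
                if mm > max_mismatch:
                    ok = False
                    break
        if ok and _max_n_run(window) <= 10:
            out.append((s, mm))
    return out


def find_primer_sites(template: str, primer: str, max_mismatch: int = 2,
                      three_prime_protect: int = 3) -> list[PrimerSite]:
    """All binding sites of one primer on both strands of a template.

    A site qualifies when total substitutions <= ``max_mismatch`` and the
    final ``three_prime_protect`` bases of the primer match exactly.  A run
    of more than 10 Ns inside a putative site voids it.  Coordinates are
    always on the template as given.
    """
    if len(primer) >= len(template):
        raise ValueError("primer must be shorter than template")
    bad = set(template) - DNA_ALPHABET
    if bad:
        raise SequenceError(f"illegal characters {sorted(bad)} in template")
    sites = [PrimerSite(s, s + len(primer), "+", mm)
             for s, mm in _scan_one_strand(template, primer, max_mismatch,
                                           three_prime_protect)]
    # '-' strand: primer anneals to the reverse strand; its footprint on the
    # given strand is the reverse complement of the primer.
    n = len(template)
    for s, mm in _scan_one_strand(reverse_complement(template), primer,
                                  max_mismatch, three_prime_protect):
        start = n - (s + len(primer))
        sites.append(PrimerSite(start, start + len(primer), "-", mm))
    sites.sort(key=lambda x: (x.start, x.strand))
    return sites


def amplify(template: SeqRecord, assay: PrimerAssay,
            params: PcrParams | None = None) -> list[Amplicon]:
    """Predict all PCR products of an assay on one template.

    Products pair a forward-primer site with a downstream reverse-primer
    site on the opposite strand, in either template orientation, within
    [min_len, max_len].  An empty list means no product.
    """
    params = params or PcrParams()
    fwd_sites = find_primer_sites(template.sequence, assay.forward,
                                  params.max_mismatch, params.three_prime_protect)
    rev_sites = find_primer_sites(template.sequence, assay.reverse,
                                  params.max_mismatch, params.three_prime_protect)
    products: list[Amplicon] = []
    # orientation 1: forward primer on '+', reverse primer on '-', fwd upstream
    for f in (s for s in fwd_sites if s.strand == "+"):
        for r in (s for s in rev_sites if s.strand == "-"):
            if r.end <= f.start:
                continue
            length = r.end - f.start
            if f.end <= r.start and params.min_len <= length <= params.max_len:
                products.append(Amplicon(
                    template_id=template.id, start=f.start, end=r.end,
                    strand="+", fwd_mismatches=f.mismatches,
                    rev_mismatches=r.mismatches,
                    sequence=template.sequence[f.start:r.end]))
    # orientation 2: forward primer on '-', reverse primer on '+'
    for f in (s for s in fwd_sites if s.strand == "-"):
        for r in (s for s in rev_sites if s.strand == "+"):
            if f.end <= r.start:
                continue
            length = f.end - r.start
            if r.end <= f.start and params.min_len <= length <= params.max_len:
                products.append(Amplicon(
                    template_id=template.id, start=r.start, end=f.end,
                    strand="-", fwd_mismatches=f.mismatches,
                    rev_mismatches=r.mismatches,
                    sequence=reverse_complement(
                        template.sequence[r.start:f.end])))
    products.sort(key=lambda a: (a.start, a.end, a.strand))
    return products


@dataclass
class DetectionMatrix:
    """Presence/absence of each assay's product across a template panel."""

    template_ids: list[str]
    assay_names: list[str]
    #: (template_id, assay_name) -> list of product lengths
    products: dict[tuple[str, str], list[int]]

    def detected(self, template_id: str, assay_name: str) -> bool:
        return bool(self.products.get((template_id, assay_name)))

    def to_dataframe(self):
        import pandas as pd
        rows = {}
        for tid in self.template_ids:
            rows[tid] = {
                a: (";".join(map(str, self.products[(tid, a)])) or "-")
                for a in self.assay_names
            }
        return pd.DataFrame.from_dict(rows, orient="index")[self.assay_names]


def screen_panel(templates: list[SeqRecord], assays: list[PrimerAssay],
                 params: PcrParams | None = None) -> DetectionMatrix:
    """Run every assay against every template; deterministic given inputs."""
    if not templates or not assays:
        raise ValueError("templates and assays must be non-empty")
    ids = [t.id for t in templates]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate template ids in panel")
    products: dict[tuple[str, str], list[int]] = {}
    for t in templates:
        for a in assays:
            amps = amplify(t, a, params)
            products[(t.id, a.name)] = [amp.length for amp in amps]
    return DetectionMatrix(template_ids=ids,
                           assay_names=[a.name for a in assays],
                           products=products)


def load_assays(path: str | Path) -> list[PrimerAssay]:
    """Load assays from a JSON list of {name, forward, reverse,
    annealing_c, expected_length} objects."""
    with open(path) as fh:
        data = json.load(fh)
    if isinstance(data, dict):
        data = [data]
    return [PrimerAssay(
        name=d["name"], forward=d["forward"].upper(),
        reverse=d["reverse"].upper(),
        annealing_c=d.get("annealing_c"),
        expected_length=d.get("expected_length"),
    ) for d in data]
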