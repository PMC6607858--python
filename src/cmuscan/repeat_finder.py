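"""Tandem-repeat (minisatellite) array detection and targeted copy counting.

Two entry points:

* :func:`find_tandem_arrays` — de novo search for arrays of any unit within a
  length range.  Candidate periods come from self-matches at a fixed lag,
  extended in whole-unit steps under a per-copy substitution budget.
* :func:`count_unit_copies` — targeted search for arrays of a *given* unit
  (used by allele typing, where the repeat units are scheme data).

Arrays contain whole copies only: a trailing partial copy is never counted
but is flagged as a warning on the array.  Indels are not tolerated inside
an array — copy-number variation by whole-unit insertion/deletion is handled
at the allele level, not here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqio import DNA_ALPHABET, SequenceError, hamming


@dataclass(frozen=True)
class RepeatSearchParams:
    """De novo search parameters: unit-length range and per-copy budget."""

    min_unit: int = 10
    max_unit: int = 30
    min_copies: int = 2
    max_mismatch_per_copy: int = 1

    def __post_init__(self) -> None:
        if not (1 <= self.min_unit <= self.max_unit):
            raise ValueError("require 1 <= min_unit <= max_unit")
        if self.min_copies < 2:
            raise ValueError("min_copies must be >= 2")
        if self.max_mismatch_per_copy < 0:
            raise ValueError("max_mismatch_per_copy must be >= 0")


@dataclass(frozen=True)
class RepeatArray:
    """One detected tandem array.

    ``unit`` is the canonical repeat unit (the array copy minimising total
    mismatches for de novo search, the query unit for targeted search).
    ``start``/``end`` are
    0-based half-open on the query; ``end - start == copies * unit_length``.
    ``partial_trailing`` flags an adjacent partial copy that was not counted.
    """

    unit: str
    copies: int
    start: int
    end: int
    mismatches_per_copy: tuple[int, ...]
    strand: str = "+"
    partial_trailing: bool = False

    @property
    def unit_length(self) -> int:
        return len(self.unit)

    def __post_init__(self) -> None:
        if self.end - self.start != self.copies * len(self.unit):
            raise ValueError("array span inconsistent with copies * unit_length")
        if len(self.mismatches_per_copy) != self.copies:
            raise ValueError("one mismatch count per copy required")


def _is_primitive(unit: str) -> bool:
    """A unit is primitive if it is not a whole-number power of a shorter string."""
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


def _check_seq(seq: str) -> None:
    if not seq:
        raise SequenceError("empty sequence")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise SequenceError(f"illegal characters {sorted(bad)} in sequence")


def _extend(seq: str, anchor: int, unit: str, max_mm: int) -> tuple[int, int, list[int], bool]:
    """Maximal run of whole copies of ``unit`` through position ``anchor``.

    Returns (start, end, mismatches_per_copy, partial_trailing).  Extension
    proceeds in whole-unit steps left and right of the anchor copy; a copy
    qualifies if its Hamming distance to ``unit`` is <= max_mm.
    """
    L = len(unit)
    start = anchor
    while start - L >= 0 and hamming(seq[start - L:start], unit) <= max_mm:
        start -= L
    end = anchor + L
    while end + L <= len(seq) and hamming(seq[end:end + L], unit) <= max_mm:
        end += L
    mms = [hamming(seq[p:p + L], unit) for p in range(start, end, L)]
    # partial flanking copy: >= 4 more bases continue the unit beyond the
    # last whole copy (or precede the first one)
    partial = False
    k = 0
    while end + k < len(seq) and k < L - 1 and seq[end + k] == unit[k]:
        k += 1
    if k >= min(4, L - 1):
        partial = True
    k = 0
    while start - 1 - k >= 0 and k < L - 1 and seq[start - 1 - k] == unit[L - 1 - k]:
        k += 1
    if k >= min(4, L - 1):
        partial = True
    return start, end, mms, partial


def _subsets_up_to(items: list[int], k: int) -> list[tuple[int, ...]]:
    """All subsets of ``items`` of size 1..k (order-preserving)."""
    from itertools import combinations
    out: list[tuple[int, ...]] = []
    for size in range(1, min(k, len(items)) + 1):
        out.extend(combinations(items, size))
    return out


def _span_centers(seq: str, start: int, L: int, copies: int,
                  max_mm: int) -> list[tuple[str, list[int]]]:
    """Candidate units ("centres") for the span of ``copies`` lag-L windows.

    A centre is composed per-position of characters occurring in the copies
    and must be within ``max_mm`` substitutions of every copy.  Enumeration
    is complete for budgets 0 and 1 (every valid centre is the first copy or
    a single-position variant of it); for larger budgets it is best-effort.
    Returns (unit, mismatches_per_copy) pairs.
    """
    windows = [seq[start + i * L:start + (i + 1) * L] for i in range(copies)]
    w0 = windows[0]
    cands = {w0}
    frontier = {w0}
    for _ in range(max_mm):
        nxt = set()
        for u in frontier:
            for p in range(L):
                for x in {w[p] for w in windows}:
                    if x != u[p]:
                        nxt.add(u[:p] + x + u[p + 1:])
        cands |= nxt
        frontier = nxt
    out = []
    for u in sorted(cands):
        mms = [hamming(w, u) for w in windows]
        if max(mms) <= max_mm:
            out.append((u, mms))
    return out


def _span_qualifies(seq: str, start: int, L: int, copies: int, max_mm: int) -> bool:
    if start < 0 or start + copies * L > len(seq):
        return False
    return bool(_span_centers(seq, start, L, copies, max_mm))


def find_tandem_arrays(seq: str, params: RepeatSearchParams | None = None) -> list[RepeatArray]:
    """De novo detection of maximal tandem arrays.

    Three stages. *Seeding*: every window ``seq[s:s+L]`` whose lag-L
    neighbour lies within twice the per-copy budget proposes candidate
    units (the window itself and consensus-style variants taking the
    neighbour's characters at disagreement positions), each extended in
    whole-unit steps under the budget.  *Growth*: a seeded span is extended
    by whole units while the enlarged span still admits a unit within the
    budget of every copy, so the reported span cannot be extended in either
    direction.  *Canonicalisation*: the reported unit is the qualifying
    centre with the fewest total mismatches (ties: lexicographically
    smallest); it must be primitive.  Overlapping arrays are resolved
    preferring more copies, then smaller unit length, then fewer total
    mismatches, then leftmost start.  The search is exhaustive for per-copy
    budgets 0 and 1 (the default); larger budgets are best-effort.
    """
    params = params or RepeatSearchParams()
    _check_seq(seq)
    if len(seq) < 2 * params.min_unit:
        raise SequenceError("sequence shorter than two copies of min_unit")

    mm = params.max_mismatch_per_copy
    spans: set[tuple[int, int, int]] = set()  # (start, copies, L)
    for L in range(params.min_unit, min(params.max_unit, len(seq) // 2) + 1):
        for s in range(0, len(seq) - L + 1):
            window = seq[s:s + L]
            units: set[str] = set()
            for ns in (s - L, s + L):
                if ns < 0 or ns + L > len(seq):
                    continue
                neighbour = seq[ns:ns + L]
                diffs = [p for p in range(L) if window[p] != neighbour[p]]
                if len(diffs) > 2 * mm:
                    continue
                units.add(window)
                for subset in _subsets_up_to(diffs, mm):
                    u = list(window)
                    for p in subset:
                        u[p] = neighbour[p]
                    units.add("".join(u))
            for unit in units:
                start, end, _, _ = _extend(seq, s, unit, mm)
                copies = (end - start) // L
                if copies >= 2:
                    spans.add((start, copies, L))

    # growth to maximality: extend by whole units while a centre exists
    grown: set[tuple[int, int, int]] = set()
    for start, copies, L in spans:
        changed = True
        while changed:
            changed = False
            if _span_qualifies(seq, start - L, L, copies + 1, mm):
                start, copies, changed = start - L, copies + 1, True
            if _span_qualifies(seq, start, L, copies + 1, mm):
                copies, changed = copies + 1, True
        grown.add((start, copies, L))

    candidates: list[RepeatArray] = []
    for start, copies, L in grown:
        if copies < params.min_copies:
            continue
        centres = [(u, mms) for u, mms in _span_centers(seq, start, L, copies, mm)
                   if _is_primitive(u)]
        if not centres:
            continue
        unit, mms = min(centres, key=lambda c: (sum(c[1]), c[0]))
        end = start + copies * L
        _, _, _, partial = _extend(seq, start, unit, mm)
        candidates.append(RepeatArray(
            unit=unit, copies=copies, start=start, end=end,
            mismatches_per_copy=tuple(mms), partial_trailing=partial,
        ))

    # overlap resolution: more copies, then smaller unit, then fewer total
    # mismatches (so an exact array beats a phase-shifted noisy variant),
    # then leftmost
    ranked = sorted(
        candidates,
        key=lambda a: (-a.copies, a.unit_length,
                       sum(a.mismatches_per_copy), a.start),
    )
    chosen: list[RepeatArray] = []
    for cand in ranked:
        if all(cand.end <= c.start or cand.start >= c.end for c in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda a: a.start)
    return chosen

def count_unit_copies(seq: str, unit: str, max_mismatch_per_copy: int = 1) -> list[RepeatArray]:
    """Targeted search for maximal arrays of a given unit.

    Unlike de novo search, the unit is fixed (no primitivity re-derivation)
    and single-copy arrays are reported — allele typing needs every whole
    copy, including isolated ones.  Copies are counted in whole units only.
    """
    _check_seq(seq)
    bad = set(unit) - DNA_ALPHABET
    if bad:
        raise SequenceError(f"unit contains illegal characters {sorted(bad)}")
    if len(unit) < 4:
        raise ValueError("unit length must be >= 4")
    L = len(unit)
    if len(seq) < L:
        return []

    hits = [p for p in range(len(seq) - L + 1)
            if hamming(seq[p:p + L], unit) <= max_mismatch_per_copy]
    arrays: list[RepeatArray] = []
    covered_until = -1
    for p in hits:
        if p < covered_until:
            continue
        start, end, mms, partial = _extend(seq, p, unit, max_mismatch_per_copy)
        covered_until = end
        arrays.append(RepeatArray(
            unit=unit, copies=(end - start) // L, start=start, end=end,
            mismatches_per_copy=tuple(mms), partial_trailing=partial,
        ))
    return arrays
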