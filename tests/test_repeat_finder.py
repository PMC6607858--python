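"""De novo tandem-array detection against a brute-force enumeration oracle."""

import numpy as np
import pytest

from cmuscan import RepeatSearchParams, count_unit_copies, find_tandem_arrays
from cmuscan.repeat_finder import RepeatArray, _is_primitive
from cmuscan.seqio import SequenceError, hamming

TR1 = "AGTGCTGCCGCAGAATCC"


def _centres(windows, max_mm):
    """All units built from copy characters lying within max_mm of every
    window; complete enumeration for budgets 0 and 1."""
    assert max_mm <= 1
    L = len(windows[0])
    cands = {windows[0]}
    if max_mm >= 1:
        for p in range(L):
            for w in windows:
                if w[p] != windows[0][p]:
                    cands.add(windows[0][:p] + w[p] + windows[0][p + 1:])
    return [(u, [hamming(w, u) for w in windows]) for u in sorted(cands)
            if max(hamming(w, u) for w in windows) <= max_mm]


def brute_force_arrays(seq, min_unit, max_unit, min_copies, max_mm):
    """Independent oracle: enumerate every (start, unit_length, copies) span;
    a span qualifies when some unit composed of copy characters lies within
    the per-copy budget of every copy, and is maximal when neither one-unit
    extension qualifies.  The reported unit is the primitive qualifying unit
    with fewest total mismatches (ties: lexicographically smallest); spans
    with no primitive unit are dropped.  The documented overlap tie-break
    (more copies, smaller unit, fewer mismatches, leftmost) is then applied."""
    per_span = []
    n = len(seq)

    def windows_of(start, copies, L):
        return [seq[start + i * L:start + (i + 1) * L] for i in range(copies)]

    def qualifies(start, copies, L):
        if start < 0 or start + copies * L > n:
            return False
        return bool(_centres(windows_of(start, copies, L), max_mm))

    for L in range(min_unit, max_unit + 1):
        for start in range(0, n - 2 * L + 1):
            for copies in range(min_copies, (n - start) // L + 1):
                if not qualifies(start, copies, L):
                    continue
                if qualifies(start - L, copies + 1, L) or \
                        qualifies(start, copies + 1, L):
                    continue  # not maximal
                primitive = [(u, mms) for u, mms in
                             _centres(windows_of(start, copies, L), max_mm)
                             if _is_primitive(u)]
                if not primitive:
                    continue
                unit, mms = min(primitive, key=lambda c: (sum(c[1]), c[0]))
                per_span.append(RepeatArray(
                    unit=unit, copies=copies, start=start,
                    end=start + copies * L, mismatches_per_copy=tuple(mms)))
    ranked = sorted(per_span,
                    key=lambda a: (-a.copies, a.unit_length,
                                   sum(a.mismatches_per_copy), a.start))
    chosen = []
    for cand in ranked:
        if all(cand.end <= c.start or cand.start >= c.end for c in chosen):
            chosen.append(cand)
    return sorted(chosen, key=lambda a: a.start)


def random_dna(seed, n):
    return "".join(np.random.default_rng(seed).choice(list("ACGT"), size=n))


class TestFindTandemArrays:
    def test_planted_18nt_minisatellite(self):
        seq = random_dna(1, 120) + TR1 * 2 + random_dna(101, 120)
        arrays = find_tandem_arrays(seq, RepeatSearchParams(10, 30))
        assert len(arrays) == 1
        assert arrays[0].unit_length == 18
        assert arrays[0].copies == 2
        # flank bases can extend the array in a rotated phase, so the
        # canonical unit is some rotation of the planted one
        rotations = {TR1[i:] + TR1[:i] for i in range(18)}
        assert arrays[0].unit in rotations

    def test_forced_primitive_unit_and_maximality(self):
        arrays = find_tandem_arrays(
            "ATATATAT", RepeatSearchParams(2, 4, max_mismatch_per_copy=0))
        assert len(arrays) == 1
        assert arrays[0].unit == "AT"
        assert arrays[0].copies == 4

    def test_random_sequence_without_arrays_is_empty(self):
        # screened: the oracle confirms no qualifying array exists
        params = RepeatSearchParams(10, 30, max_mismatch_per_copy=0)
        for seed in range(7, 30):
            seq = random_dna(seed, 200)
            if not brute_force_arrays(seq, 10, 30, 2, 0):
                assert find_tandem_arrays(seq, params) == []
                return
        pytest.fail("no array-free random sequence found to screen")

    @pytest.mark.parametrize("seed", range(12))
    def test_oracle_equivalence_small_sequences(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(16, 61))
        # biased alphabet so repeats arise by chance
        seq = "".join(rng.choice(list("ACACG"), size=n))
        params = RepeatSearchParams(2, 8, max_mismatch_per_copy=int(seed % 2))
        got = find_tandem_arrays(seq, params)
        expected = brute_force_arrays(seq, 2, 8, 2, seed % 2)
        assert [(a.start, a.end, a.unit) for a in got] == \
            [(a.start, a.end, a.unit) for a in expected]

    @pytest.mark.parametrize("seed", range(100))
    def test_planted_array_recovery(self, seed):
        rng = np.random.default_rng(seed)
        unit = "".join(rng.choice(list("ACGT"), size=18))
        if not _is_primitive(unit):
            unit = TR1
        copies = int(rng.integers(2, 5))
        block = list(unit * copies)
        # at most one substitution per copy (within the detection budget)
        for c in range(copies):
            if rng.random() < 0.5:
                p = int(rng.integers(18))
                block[c * 18 + p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[block[c * 18 + p]]
        seq = random_dna(seed + 1000, 120) + "".join(block) + random_dna(seed + 2000, 120)
        arrays = find_tandem_arrays(seq, RepeatSearchParams(10, 30))
        assert any(a.unit_length == 18 and a.copies == copies for a in arrays)

    def test_span_reconstruction(self):
        # the span is exactly the concatenation of its near-copies, each
        # within the declared mismatch count of the unit
        seq = random_dna(3, 60) + TR1 * 3 + random_dna(103, 60)
        arrays = find_tandem_arrays(seq, RepeatSearchParams(10, 30))
        assert any(a.unit == TR1 and a.copies == 3 for a in arrays)
        for arr in arrays:
            assert arr.end - arr.start == arr.copies * arr.unit_length
            L = arr.unit_length
            copies = [seq[p:p + L] for p in range(arr.start, arr.end, L)]
            assert "".join(copies) == seq[arr.start:arr.end]
            assert tuple(hamming(c, arr.unit) for c in copies) == \
                arr.mismatches_per_copy

    def test_param_validation(self):
        with pytest.raises(ValueError):
            RepeatSearchParams(min_unit=5, max_unit=4)
        with pytest.raises(ValueError):
            RepeatSearchParams(min_copies=1)
        with pytest.raises(SequenceError):
            find_tandem_arrays("", RepeatSearchParams())


class TestCountUnitCopies:
    def test_three_copies_of_given_unit(self):
        seq = random_dna(11, 80) + TR1 * 3 + random_dna(12, 80)
        arrays = count_unit_copies(seq, TR1)
        assert len(arrays) == 1
        assert arrays[0].copies == 3

    def test_absent_unit_yields_empty(self):
        assert count_unit_copies(random_dna(13, 150), TR1) == []

    def test_mismatch_within_budget_counted(self):
        mutated = TR1[:5] + "A" + TR1[6:] if TR1[5] != "A" else TR1[:5] + "C" + TR1[6:]
        seq = "GGGGGG" + TR1 + mutated + "CCCCCC"
        arrays = count_unit_copies(seq, TR1, max_mismatch_per_copy=1)
        assert len(arrays) == 1
        assert arrays[0].copies == 2
        assert arrays[0].mismatches_per_copy == (0, 1)

    def test_whole_copies_only_with_partial_flag(self):
        seq = "GGGGGG" + TR1 * 2 + TR1[:7] + "GGGGGG"
        (arr,) = count_unit_copies(seq, TR1)
        assert arr.copies == 2
        assert arr.partial_trailing

    def test_exhaustive_window_scan_oracle(self):
        # every reported copy position must match the unit within budget,
        # and no extension is possible (maximality)
        seq = random_dna(17, 50) + TR1 * 2 + random_dna(18, 40) + TR1 + random_dna(19, 50)
        arrays = count_unit_copies(seq, TR1)
        assert [a.copies for a in arrays] == [2, 1]
        for a in arrays:
            for p in range(a.start, a.end, 18):
                assert hamming(seq[p:p + 18], TR1) <= 1
            if a.start - 18 >= 0:
                assert hamming(seq[a.start - 18:a.start], TR1) > 1
            if a.end + 18 <= len(seq):
                assert hamming(seq[a.end:a.end + 18], TR1) > 1

    def test_unit_validation(self):
        with pytest.raises(ValueError):
            count_unit_copies("ACGTACGT", "ACG")
        with pytest.raises(SequenceError):
            count_unit_copies("ACGT" * 10, "ACXG")
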