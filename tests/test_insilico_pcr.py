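"""Degenerate-primer site search, amplification and panel screening."""

from collections import Counter
from itertools import product

import numpy as np
import pytest

from cmuscan import (BUNDLED_ASSAYS, GeneratorConfig, PcrParams, PrimerAssay,
                     SeqRecord, amplify, find_primer_sites, make_pcr_template,
                     reverse_complement, screen_panel)
from cmuscan.seqio import IUPAC_EXPANSION

P40 = BUNDLED_ASSAYS[0]
P75 = BUNDLED_ASSAYS[1]


def random_dna(seed, n):
    return "".join(np.random.default_rng(seed).choice(list("ACGT"), size=n))


def expansions(primer):
    """All concrete sequences a degenerate primer stands for."""
    pools = [sorted(IUPAC_EXPANSION[b]) for b in primer]
    return ["".join(p) for p in product(*pools)]


class TestFindPrimerSites:
    def test_exact_expansion_of_degenerate_forward_primer(self):
        concrete = P40.forward.replace("R", "A").replace("M", "C")
        template = random_dna(1, 200) + concrete + random_dna(2, 200)
        sites = [s for s in find_primer_sites(template, P40.forward)
                 if s.strand == "+"]
        assert len(sites) == 1
        assert sites[0].mismatches == 0

    def test_three_prime_mismatch_voids_site(self):
        concrete = P75.forward
        bad = concrete[:-1] + ("A" if concrete[-1] != "A" else "C")
        template = random_dna(3, 100) + bad + random_dna(4, 100)
        sites = find_primer_sites(template, P75.forward, max_mismatch=2,
                                  three_prime_protect=3)
        assert sites == []

    def test_internal_mismatches_within_budget_found(self):
        concrete = P75.forward
        planted = list(concrete)
        planted[4] = "A" if planted[4] != "A" else "C"
        planted[9] = "A" if planted[9] != "A" else "C"
        template = random_dna(11, 500) + "".join(planted) + random_dna(12, 480)
        sites = find_primer_sites(template, P75.forward, max_mismatch=2)
        # exhaustive scan oracle: count qualifying windows on both strands
        expected = 0
        for strand_seq in (template, reverse_complement(template)):
            for s in range(len(strand_seq) - len(concrete) + 1):
                w = strand_seq[s:s + len(concrete)]
                mm = sum(not (set(IUPAC_EXPANSION[p]) & set(IUPAC_EXPANSION[t]))
                         for p, t in zip(P75.forward, w))
                tail_ok = all(set(IUPAC_EXPANSION[p]) & set(IUPAC_EXPANSION[t])
                              for p, t in zip(P75.forward[-3:], w[-3:]))
                if mm <= 2 and tail_ok:
                    expected += 1
        assert len(sites) == expected == 1
        assert sites[0].mismatches == 2

    def test_degenerate_expansion_equivalence(self):
        """Sites of a degenerate primer equal the union of exact-expansion
        sites (on concrete templates, for primers with <= 4 ambiguity
        codes)."""
        primer = P40.forward  # two ambiguity codes -> 4 expansions
        template = (random_dna(21, 150)
                    + primer.replace("R", "G").replace("M", "A")
                    + random_dna(22, 150))
        degenerate = {(s.start, s.strand)
                      for s in find_primer_sites(template, primer, max_mismatch=1)}
        union = set()
        for exp in expansions(primer):
            union |= {(s.start, s.strand)
                      for s in find_primer_sites(template, exp, max_mismatch=1)}
        assert degenerate == union

    def test_mismatch_monotonicity(self):
        template = random_dna(31, 400)
        prev: set = set()
        for mm in (0, 1, 2, 3):
            sites = {(s.start, s.strand)
                     for s in find_primer_sites(template, P75.reverse, mm)}
            assert prev <= sites
            prev = sites

    def test_primer_longer_than_template_rejected(self):
        with pytest.raises(ValueError):
            find_primer_sites("ACGT", P75.forward)


class TestAmplify:
    def test_product_length_is_construction_length(self):
        fwd = P75.forward
        rev_rc = reverse_complement(P75.reverse)
        template = SeqRecord(
            id="t", sequence=random_dna(5, 80) + fwd + random_dna(6, 100)
            + rev_rc + random_dna(7, 80))
        amps = amplify(template, P75)
        assert [a.length for a in amps] == [len(fwd) + 100 + len(P75.reverse)]

    def test_no_reverse_site_no_product(self):
        template = SeqRecord(
            id="t", sequence=random_dna(8, 80) + P75.forward + random_dna(9, 200))
        assert amplify(template, P75) == []

    def test_two_forward_sites_two_products(self):
        fwd = P75.forward
        rev_rc = reverse_complement(P75.reverse)
        template = SeqRecord(
            id="t", sequence=random_dna(10, 60) + fwd + random_dna(11, 50)
            + fwd + random_dna(12, 50) + rev_rc + random_dna(13, 60))
        amps = amplify(template, P75)
        assert len(amps) == 2
        # brute-force pairing oracle: every (fwd site, downstream rev site)
        sites_f = [s for s in find_primer_sites(template.sequence, fwd)
                   if s.strand == "+"]
        sites_r = [s for s in find_primer_sites(template.sequence, P75.reverse)
                   if s.strand == "-"]
        expected = sorted(r.end - f.start for f in sites_f for r in sites_r
                          if f.end <= r.start and 40 <= r.end - f.start <= 5000)
        assert sorted(a.length for a in amps) == expected

    def test_strand_invariance(self):
        for seed in (4, 14, 24):
            tr = make_pcr_template(P40, 278, True, GeneratorConfig(seed=seed))
            rc = SeqRecord(id="rc",
                           sequence=reverse_complement(tr.record.sequence))
            fwd_lengths = Counter(a.length for a in amplify(tr.record, P40))
            rc_lengths = Counter(a.length for a in amplify(rc, P40))
            assert fwd_lengths == rc_lengths

    def test_amplicon_sequence_starts_with_forward_footprint(self):
        tr = make_pcr_template(P75, 138, True, GeneratorConfig(seed=4))
        (amp,) = amplify(tr.record, P75)
        # footprint equals some expansion of the forward primer
        assert any(amp.sequence.startswith(e) for e in expansions(P75.forward))
        assert any(amp.sequence.endswith(reverse_complement(e))
                   for e in expansions(P75.reverse))


class TestScreenPanel:
    def test_positive_and_negative_templates(self):
        pos = make_pcr_template(P75, 138, True, GeneratorConfig(seed=4)).record
        neg = make_pcr_template(P75, 138, False, GeneratorConfig(seed=5)).record
        matrix = screen_panel([pos, neg], [P75])
        assert matrix.detected(pos.id, P75.name)
        assert not matrix.detected(neg.id, P75.name)

    def test_double_positive_row(self):
        p40 = make_pcr_template(P40, 278, True, GeneratorConfig(seed=6)).record
        p75 = make_pcr_template(P75, 138, True, GeneratorConfig(seed=6)).record
        genome = SeqRecord(id="g", sequence=p40.sequence + p75.sequence)
        matrix = screen_panel([genome], list(BUNDLED_ASSAYS))
        assert matrix.detected("g", P40.name)
        assert matrix.detected("g", P75.name)

    def test_panel_truth_table(self):
        templates, truth = [], []
        for i in range(10):
            positive = i < 6
            tr = make_pcr_template(P75, 138, positive,
                                   GeneratorConfig(seed=100 + i))
            templates.append(tr.record)
            truth.append(positive)
        matrix = screen_panel(templates, [P75])
        got = [matrix.detected(t.id, P75.name) for t in templates]
        assert got == truth

    def test_duplicate_ids_rejected(self):
        rec = make_pcr_template(P75, 138, True, GeneratorConfig(seed=4)).record
        with pytest.raises(ValueError, match="duplicate"):
            screen_panel([rec, rec], [P75])


def test_assay_validation():
    with pytest.raises(ValueError, match="shorter"):
        PrimerAssay(name="short", forward="ACGTACGT", reverse=P75.reverse)
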