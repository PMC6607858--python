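"""Seeded generators for every input shape the pipeline consumes.

Each generator returns a :class:`TruthRecord` — the sequence plus the
structured ground truth planted in it — and *self-verifies* that truth by
re-running the targeted detector before returning; a generator that cannot
verify its own output raises instead of emitting a bad fixture.  All
randomness flows through an explicit seed: the same seed and configuration
produce byte-identical sequences on every run and platform.

The noise model is i.i.d. substitutions outside planted elements only.
Indel noise is deliberately not generated: the copy-number variation the
allele scheme models *is* whole-unit insertion/deletion, chosen through the
allele, not through noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .allele_typer import LocusScheme, type_locus
from .insilico_pcr import PcrParams, PrimerAssay, amplify
from .protein_features import composition_track, call_rich_regions, find_triads, TriadSpacing
from .repeat_finder import count_unit_copies
from .seq_curation import global_identity
from .seqio import IUPAC_EXPANSION, SeqRecord, reverse_complement

_BASES = np.array(list("ACGT"))
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


class GeneratorError(RuntimeError):
    """Raised when a generator's self-check fails (bad fixture prevented)."""


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int
    flank_len: int = 120
    snp_rate: float = 0.0
    gc: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.snp_rate <= 0.05):
            raise ValueError("snp_rate must be in [0, 0.05]")
        if self.flank_len < 50:
            raise ValueError("flank_len must be >= 50")


@dataclass(frozen=True)
class TruthRecord:
    record: SeqRecord
    truth: dict[str, Any]


def _rng(cfg: GeneratorConfig) -> np.random.Generator:
    return np.random.default_rng(cfg.seed)


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def _mutate_positions(rng: np.random.Generator, seq: list[str],
                      positions: list[int], rate: float) -> list[int]:
    """Substitute each listed position independently with probability rate."""
    mutated = []
    for p in positions:
        if rng.random() < rate:
            alternatives = [b for b in "ACGT" if b != seq[p]]
            seq[p] = alternatives[rng.integers(len(alternatives))]
            mutated.append(p)
    return mutated


def make_locus(scheme: LocusScheme, allele: str, cfg: GeneratorConfig) -> TruthRecord:
    """A synthetic VNTR locus carrying a named allele of the scheme.

    Layout: random left flank + left anchor + first-unit array + spacer
    anchor(s) + further arrays + right anchor + random right flank, with
    substitution noise at ``snp_rate`` outside arrays and anchors.  The
    truth carries the allele, its profile and array coordinates; the
    generator re-types the locus before returning.
    """
    table = {name: profile for profile, name in scheme.allele_table.items()}
    if allele not in table:
        raise KeyError(f"unknown allele {allele!r} for locus {scheme.locus_name}")
    profile = table[allele]
    rng = _rng(cfg)

    inner_anchors = list(scheme.anchors[1:-1])
    parts: list[str] = []
    protected: list[tuple[int, int]] = []  # spans no noise may touch
    arrays: list[dict[str, Any]] = []

    def _append(s: str, protect: bool) -> None:
        start = sum(len(p) for p in parts)
        parts.append(s)
        if protect:
            protected.append((start, start + len(s)))

    _append(random_dna(rng, cfg.flank_len, cfg.gc), False)
    _append(scheme.left_anchor, True)
    for i, (unit, copies) in enumerate(zip(scheme.units, profile)):
        if copies > 0:
            start = sum(len(p) for p in parts)
            _append(unit.sequence * copies, True)
            arrays.append({"unit_label": unit.label, "unit": unit.sequence,
                           "copies": copies, "start": start,
                           "end": start + copies * len(unit.sequence)})
        if i < len(scheme.units) - 1 and inner_anchors:
            _append(inner_anchors.pop(0), True)
    _append(scheme.right_anchor, True)
    _append(random_dna(rng, cfg.flank_len, cfg.gc), False)

    seq = list("".join(parts))
    if cfg.snp_rate > 0:
        free = [p for p in range(len(seq))
                if not any(a <= p < b for a, b in protected)]
        _mutate_positions(rng, seq, free, cfg.snp_rate)
    record = SeqRecord(id=f"{scheme.locus_name}_{allele}_seed{cfg.seed}",
                       sequence="".join(seq))

    call = type_locus(record, scheme)
    if call.profile != profile or call.allele != allele:
        raise GeneratorError(
            f"self-check failed: planted {allele} {profile}, "
            f"typed {call.allele} {call.profile}")
    return TruthRecord(record=record,
                       truth={"allele": allele, "profile": list(profile),
                              "arrays": arrays})


def make_pcr_template(assay: PrimerAssay, product_len: int, positive: bool,
                      cfg: GeneratorConfig) -> TruthRecord:
    """A synthetic template that does (or provably does not) amplify.

    Positive: one concrete expansion of the forward primer + random insert
    + the reverse complement of one expansion of the reverse primer,
    embedded in random flanks; the product length equals ``product_len``
    exactly.  Negative: both primer sites are degraded by >= 4 substitutions
    each, including the 3'-terminal base, so no product can form.  The
    generator runs :func:`~cmuscan.insilico_pcr.amplify` to verify.
    """
    rng = _rng(cfg)
    min_needed = len(assay.forward) + len(assay.reverse)
    if product_len < min_needed:
        raise ValueError(f"product_len must be >= {min_needed}")

    def expand(primer: str) -> str:
        return "".join(sorted(IUPAC_EXPANSION[b])[rng.integers(len(IUPAC_EXPANSION[b]))]
                       for b in primer)

    fwd_site = expand(assay.forward)
    rev_site_rc = reverse_complement(expand(assay.reverse))
    insert = random_dna(rng, product_len - min_needed, cfg.gc)

    if not positive:
        fwd_site = _degrade_site(rng, fwd_site)
        rev_site_rc = _degrade_site(rng, rev_site_rc, three_prime_left=True)

    seq = (random_dna(rng, cfg.flank_len, cfg.gc) + fwd_site + insert
           + rev_site_rc + random_dna(rng, cfg.flank_len, cfg.gc))
    record = SeqRecord(
        id=f"{assay.name}_{'pos' if positive else 'neg'}_seed{cfg.seed}",
        sequence=seq)

    amps = amplify(record, assay, PcrParams(max_len=max(5000, product_len)))
    if positive:
        if len(amps) != 1 or amps[0].length != product_len:
            raise GeneratorError("self-check failed: expected exactly one "
                                 f"product of {product_len} nt, got "
                                 f"{[a.length for a in amps]}")
    elif amps:
        raise GeneratorError("self-check failed: negative template amplified")
    return TruthRecord(record=record,
                       truth={"assay": assay.name, "positive": positive,
                              "product_len": product_len if positive else None})


def _degrade_site(rng: np.random.Generator, site: str,
                  three_prime_left: bool = False, n_subs: int = 4) -> str:
    """Destroy a primer footprint: n_subs substitutions including the base
    at the primer's 3' terminus (rightmost, or leftmost for a reverse-
    complemented footprint)."""
    seq = list(site)
    terminus = 0 if three_prime_left else len(seq) - 1
    interior = [i for i in range(len(seq)) if i != terminus]
    picks = [terminus] + list(rng.choice(interior, size=n_subs - 1, replace=False))
    for p in picks:
        alternatives = [b for b in "ACGT" if b != seq[p]]
        seq[p] = alternatives[rng.integers(len(alternatives))]
    return "".join(seq)


def make_identity_set(n: int, identities: list[float], cfg: GeneratorConfig,
                      length: int = 400) -> list[TruthRecord]:
    """A base sequence plus derivatives at controlled pairwise identity.

    Derivative *i* carries substitutions targeting ``identities[i]`` percent
    global identity to the base; the generator re-measures with
    :func:`~cmuscan.seq_curation.global_identity` and adjusts until the
    realized identity is within +/-0.5 points of the target.  The truth of
    each derivative carries its realized identity.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if any(not (50.0 <= t <= 100.0) for t in identities):
        raise ValueError("identity targets must be in [50, 100]")
    if len(identities) > n - 1:
        raise ValueError("need n-1 >= len(identities)")
    rng = _rng(cfg)
    base_seq = random_dna(rng, length, cfg.gc)
    base = SeqRecord(id=f"base_seed{cfg.seed}", sequence=base_seq)
    out = [TruthRecord(record=base, truth={"role": "base"})]

    for i, target in enumerate(identities):
        k = int(round(length * (1.0 - target / 100.0)))
        for attempt in range(20):
            seq = list(base_seq)
            positions = rng.choice(length, size=min(k, length), replace=False)
            for p in positions:
                alternatives = [b for b in "ACGT" if b != seq[p]]
                seq[p] = alternatives[rng.integers(len(alternatives))]
            rec = SeqRecord(id=f"derived{i}_seed{cfg.seed}", sequence="".join(seq))
            realized = global_identity(rec, base).identity_pct
            if abs(realized - target) <= 0.5:
                out.append(TruthRecord(record=rec,
                                       truth={"role": "derived",
                                              "target_identity": target,
                                              "realized_identity": realized}))
                break
            # alignment drift: nudge the substitution count and retry
            k += 1 if realized > target else -1
            k = max(0, min(k, length))
        else:
            raise GeneratorError(f"could not reach identity target {target}")
    # remaining records: unrelated random sequences
    for j in range(n - 1 - len(identities)):
        rec = SeqRecord(id=f"unrelated{j}_seed{cfg.seed}",
                        sequence=random_dna(rng, length, cfg.gc))
        out.append(TruthRecord(record=rec, truth={"role": "unrelated"}))
    return out


def make_protein(cfg: GeneratorConfig, length: int = 300,
                 spacer_len: int = 0, spacer_residues: str = "SAT",
                 spacer_start: int | None = None,
                 triad_spacings: tuple[int, int] | None = None) -> TruthRecord:
    """A random protein with an optional planted composition block and/or
    C-H-E triad; truth carries planted coordinates (empty if nothing
    planted).  Self-checks re-run the targeted detectors.
    """
    rng = _rng(cfg)
    truth: dict[str, Any] = {}
    # base sequence free of C and H so planted triads are unambiguous
    background = np.array([a for a in _AA if a not in "CH"])
    seq = list("".join(rng.choice(background, size=length)))

    if spacer_len > 0:
        if spacer_start is None:
            spacer_start = (length - spacer_len) // 2
        if spacer_start + spacer_len > length:
            raise ValueError("planted spacer exceeds protein length")
        residues = list(spacer_residues)
        for p in range(spacer_start, spacer_start + spacer_len):
            seq[p] = residues[rng.integers(len(residues))]
        truth["spacer"] = {"start": spacer_start,
                           "end": spacer_start + spacer_len,
                           "residues": spacer_residues}

    if triad_spacings is not None:
        gap_ch, gap_hx = triad_spacings
        span = 2 + gap_ch + gap_hx + 1
        c_pos = length - span - 5
        if c_pos < 0:
            raise ValueError("triad spacings exceed protein length")
        h_pos = c_pos + gap_ch + 1
        x_pos = h_pos + gap_hx + 1
        seq[c_pos], seq[h_pos], seq[x_pos] = "C", "H", "E"
        truth["triad"] = {"cys_pos": c_pos, "his_pos": h_pos,
                          "third_pos": x_pos, "third_residue": "E"}

    record = SeqRecord(id=f"protein_seed{cfg.seed}", sequence="".join(seq),
                       alphabet="protein")

    if "spacer" in truth:
        track = composition_track(record, window=21,
                                  residue_set=frozenset(spacer_residues))
        regions = call_rich_regions(track, min_frac=0.7, min_len=10)
        planted = truth["spacer"]
        if not any(r.start < planted["end"] and r.end > planted["start"]
                   for r in regions):
            raise GeneratorError("self-check failed: planted spacer not detected")
    if "triad" in truth:
        t = truth["triad"]
        spacing = TriadSpacing(min_ch=t["his_pos"] - t["cys_pos"] - 1,
                               max_ch=t["his_pos"] - t["cys_pos"] - 1,
                               min_hx=t["third_pos"] - t["his_pos"] - 1,
                               max_hx=t["third_pos"] - t["his_pos"] - 1)
        found = find_triads(record, spacing=spacing)
        if (t["cys_pos"], t["his_pos"], t["third_pos"]) not in [
                (s.cys_pos, s.his_pos, s.third_pos) for s in found]:
            raise GeneratorError("self-check failed: planted triad not detected")
    return TruthRecord(record=record, truth=truth)
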