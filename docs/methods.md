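# Methods

This note records the algorithms, parameter defaults and assumptions
behind `cmuscan`, in enough detail to re-implement them.

## Notation

Sequences are 0-based, end-exclusive strings over the DNA or protein
alphabet (TSV/CLI outputs convert to 1-based inclusive coordinates for
display). `d_H(a, b)` is the Hamming distance between equal-length
strings.

## 1. Tandem-array detection (`repeat_finder`)

### Definition

Given parameters (`min_unit`=10, `max_unit`=30, `min_copies`=2,
`max_mismatch_per_copy` *m*=1 by default), a *qualifying span* is
`s[start : start + kL]` for which there exists a *centre* unit `u`
(|u| = L ∈ [min_unit, max_unit], primitive, i.e. not itself a repetition
of a shorter string) with `d_H(copyᵢ, u) ≤ m` for **every** copy *i*,
*k* ≥ `min_copies`. An array is *maximal* when neither
one-unit extension (left or right) admits any centre. Centres are
restricted to characters that occur in the copies at the same column;
this excludes phantom units supported by no evidence in the sequence.

### Algorithm

1. **Seeding.** For each L and offset, compare `s[i : i+L]` with
   `s[i+L : i+2L]`. If they differ at ≤ 2·m positions, generate candidate
   centres: the first copy itself plus variants substituting the second
   copy's character at every subset of ≤ m disagreement positions.
2. **Growth.** Extend each seeded span one unit at a time in both
   directions while the extended span still admits a centre
   (re-checked with `_span_centers`, which enumerates column-wise
   character choices within the per-copy budget — complete for m ≤ 1).
3. **Canonicalisation.** For the final span, pick the primitive centre
   minimising (total mismatches, lexicographic order).
4. **Overlap resolution.** Competing overlapping arrays are ranked by
   (more copies, shorter unit, fewer total mismatches, leftmost start)
   and accepted greedily.

**Exhaustiveness (m ≤ 1).** For m = 0, adjacent copies are equal, so
every array is seeded directly. For m = 1, any two adjacent copies of a
qualifying span differ at ≤ 2 positions (triangle inequality through the
centre), so step 1 fires on every maximal span, and the seeded variant
set contains a valid centre by construction. The test suite verifies
agreement with brute-force enumeration over random sequences
(`tests/test_repeat_finder.py::brute_force_arrays`).

A trailing partial copy (≥ 4 contiguous matching prefix bases after the
last whole copy) sets `partial_trailing` but never changes coordinates
or copy counts.

`count_unit_copies(seq, unit, max_mismatch=1)` is the *targeted*
variant used by the typer: it chains non-overlapping near-copies of a
given unit left to right and accepts runs of ≥ 1 copy (a single copy is
biologically meaningful when counting a known unit between anchors,
unlike in de novo discovery).

## 2. Allele typing (`allele_typer`)

A `LocusScheme` holds ordered anchor sequences, the repeat units, the
profile → allele-name table and `anchor_max_mismatch` (default 2). The
bundled scheme carries the two 18-nt cmuB units
(`AGTGCTGCCGCAGAATCC`, `ACGCCGACTCCTGCACCA`) and the four-allele table
(2,2)→`cmuB1`, (3,2)→`cmuB2`, (2,0)→`cmuB3`, (0,3)→`cmuB4`. Its anchor
sequences are labelled synthetic stand-ins: they delimit the repeat
region in generated and user-supplied data but are not genomic flanks;
schemes for real genomes should be loaded from JSON (`load_scheme`).

Typing: (1) search the forward strand, then the reverse complement, for
all anchors — per anchor, the leftmost **exact** hit wins, falling back
to the leftmost hit with ≤ `anchor_max_mismatch` mismatches; (2) anchors
must appear in order; (3) count each unit's chained copies between the
outer anchors with per-copy budget 1; (4) map the profile through the
table, reporting `novel` for profiles not in it. Failures (missing
anchors, out-of-order anchors) produce a soft `AlleleCall` carrying
warnings rather than an exception, so one bad record cannot abort a
batch. If both strands type, the forward call is returned with a
warning.

## 3. In-silico PCR (`insilico_pcr`)

Primers are matched with IUPAC set-intersection semantics: primer base
*p* matches template base *t* iff expansion(*p*) ∩ expansion(*t*) ≠ ∅.
Defaults (`PcrParams`): ≤ 2 mismatches per site, **zero** mismatches in
the 3 3'-terminal bases (mismatches there block polymerase extension),
product length in [40, 5000] nt. Both strands are scanned; runs of > 10
`N`s void the overlapping windows. An amplicon is a convergent
forward/reverse site pair (either primer may take either role) with
non-overlapping footprints; its length spans the outermost footprint
coordinates, i.e. includes both primers, matching how gel band sizes are
stated. Assays with ≥ 15-nt primers are enforced at construction.

Bundled assays: `P40carh` (fwd `CCTTGGGGTCARTGCACMTGGTACG`, rev
`CCGGTTGGTGAGCTGAAGCCC`, expected 278 nt) and `P75carh` (fwd
`GACCACCGTATGGAATAGTCC`, rev `GGRATCCACTGATTGTCGCC`, expected 138 nt).
`screen_panel` produces a template × assay detection matrix with
observed product lengths.

## 4. Curation (`seq_curation`)

`global_identity` runs Needleman–Wunsch via
`Bio.Align.PairwiseAligner` in global mode. Presets: protein — BLOSUM62,
gap open −10, extend −0.5; DNA — match +5, mismatch −4, same gaps.
Identity = identical columns / **all alignment columns including gaps**
× 100; this denominator penalises length differences, which is the
conservative choice for redundancy detection. Among co-optimal
alignments the aligner's first is used (deterministic).

`remove_redundant` visits records by descending length (ties: input
order) and keeps a record iff its identity to every kept record is
strictly below the threshold (default 98 %); removed records point to
the first kept record meeting the threshold. Keep-longest-first means a
fragment can never displace the full-length sequence it derives from.

## 5. Protein features (`protein_features`)

*Composition track*: at each position, the fraction of residues from a
target set in a centred window (odd width, 5–51); edge windows are
truncated to the sequence, never padded, so edge values stay exact
fractions of real residues. *Rich regions*: maximal runs of track values
≥ `min_frac`, kept when ≥ `min_len`; the run is reported with its mean
fraction.

*CHAP triads*: exhaustive enumeration of ordered Cys…His…X sites
(X ∈ {H, E, D, N}); gaps count intervening residues. Default spacing
(Cys→His 10–130, His→X 3–60) brackets the spacings observed across CHAP
domains broadly; it is a screening default meant to be narrowed per
family, not a trained parameter.

*Molecular mass*: average (not monoisotopic) isotope-abundance residue
masses summed plus one water (18.01524 Da); the 20-entry table is
package-owned and cross-checked in the tests against
`Bio.SeqUtils.molecular_weight`. Ambiguity codes (`X`, `B`, `Z`) are
rejected rather than guessed.

## 6. Synthetic data (`synthetic_data`)

All generators take a `GeneratorConfig` (seed, `flank_len`=120,
`snp_rate`=0 capped at 0.05, `gc`=0.5) and use
`numpy.random.default_rng(seed)` so outputs are byte-identical across
runs and platforms. Each returns a `TruthRecord` (sequence record +
machine-readable truth dict) and **self-verifies**: it re-runs the
package's own detector on the generated sequence and raises
`GeneratorError` on disagreement.

- `make_locus(scheme, allele, cfg)` assembles
  flank–anchor–arrays–anchor–flank per the allele's profile; noise is
  i.i.d. substitution applied **only outside** planted anchors and
  arrays, so truth coordinates stay exact. The snp-rate cap (5 %) keeps
  the generator inside the regime where its self-check can hold.
- `make_pcr_template(assay, product_len, positive, cfg)` embeds concrete
  expansions of the (possibly degenerate) primers at exactly the
  requested product length; negatives degrade one site with 4
  substitutions including a 3'-terminal one, then verify no product.
- `make_identity_set(n, targets, cfg)` derives sequences from a common
  parent by a substitution count implied by the target identity, then
  re-measures with `global_identity` and adjusts until within ±0.5
  percentage points.
- `make_protein(cfg, ...)` plants an S/A/T spacer and/or a C–H–E triad
  at requested spacings in a background drawn without C and H.

## 7. Pipeline and CLI

`run_pipeline(RunConfig)` validates the full configuration before
touching the output directory, then runs curation → repeat discovery →
allele typing, optional PCR screening and protein profiling, writing
TSV/FASTA/JSON artifacts plus a deterministic `summary.json` (no
timestamps or paths inside). CLI exit codes: 0 success, 2 configuration
error, 3 stage failure.

## Limitations

- The repeat search is exhaustive only for per-copy budgets 0 and 1
  (the regime used throughout); larger budgets remain heuristic in the
  seeding step. Insertions/deletions within units are out of scope —
  copies are compared by Hamming distance only.
- In-silico PCR assumes perfect processivity: any site pair within the
  length window amplifies; no thermodynamics, primer-dimer or
  efficiency model.
- Identity is computed from a single optimal alignment; co-optimal
  alignments could differ in identical-column count, though the
  gap-inclusive denominator limits the effect.
- Generators model substitution noise only, and only outside planted
  elements; they are designed for detector validation, not for
  simulating realistic evolutionary divergence.
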