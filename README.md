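# cmuscan

Sequence analysis of bacterial cell-wall muramidase loci: de novo
minisatellite (VNTR) detection, repeat-based allele typing, in-silico PCR
screening, dataset curation, and protein feature profiling — with seeded,
self-verifying synthetic data generators for every analysis.

## Scientific background

Secreted cell-wall hydrolases of *Lacticaseibacillus* such as the P40 and
P75 muramidases are probiotic effector candidates. Two sequence-level
signatures make their genes useful typing and screening targets:

1. **A minisatellite inside the gene encoding the P40-family protein.**
   The locus carries a tandem array built from two distinct 18-nt repeat
   units. Strains differ in how many copies of each unit they carry, and
   the copy-number profile defines a small set of named alleles
   (profile *(c₁, c₂)* → allele name; e.g. (2, 2) → `cmuB1`,
   (3, 2) → `cmuB2`, (2, 0) → `cmuB3`, (0, 3) → `cmuB4`). Typing a strain
   therefore reduces to counting near-exact unit copies between conserved
   anchor sequences.
2. **Diagnostic primer pairs targeting the catalytic (CHAP-domain) coding
   regions** of the two genes, which produce characteristic product
   lengths (278 nt and 138 nt) and let a panel of genomes or isolates be
   screened for gene presence without culture work.

At the protein level the same proteins show low-complexity Ser/Ala/Thr-rich
spacer segments and a CHAP catalytic triad — an ordered Cys…His…X motif
(X ∈ {His, Glu, Asp, Asn}) with characteristic residue spacing.

`cmuscan` implements this analysis stack end to end.

## The model

**Tandem arrays.** An array is a span *s[start:end)* that concatenates
*k* ≥ `min_copies` contiguous near-copies of a primitive unit *u* of length
*L* ∈ [`min_unit`, `max_unit`], each copy within Hamming distance
`max_mismatch_per_copy` of *u*. The reported unit is a *centre string*: a
unit within the per-copy budget of **every** copy, chosen to minimise
(total mismatches, lexicographic order). Arrays are maximal — no
qualifying one-unit extension exists — and overlapping candidates are
resolved by (more copies, shorter unit, fewer total mismatches, leftmost).
For per-copy budgets 0 and 1 the search is exhaustive (it provably agrees
with brute-force enumeration; see `docs/methods.md`).

**Allele typing.** A `LocusScheme` bundles anchor sequences, the repeat
units, and the profile → allele table. Typing locates the anchors on
either strand (exact first, then ≤ 2 mismatches), counts chained unit
copies between them with per-copy budget 1, and looks the profile up in
the table; unknown profiles are reported as `novel` rather than forced
into a named class.

**In-silico PCR.** Primers may contain IUPAC degenerate codes; a primer
base matches a template base when their expansion sets intersect. Sites
allow ≤ 2 mismatches but none in the 3 3'-terminal bases (the
polymerase-extension-critical end), both strands are scanned, and
convergent forward/reverse site pairs within [40, 5000] nt yield
amplicons whose length includes both primer footprints.

**Curation.** Percent identity is computed over *all columns* of an
optimal global (Needleman–Wunsch) alignment — BLOSUM62 for protein,
+5/−4 for DNA, gap open 10 / extend 0.5 — and redundancy removal is
greedy keep-longest-first at a 98 % threshold.

**Protein profiling.** A centred sliding-window composition track (edges
truncated, never padded) drives maximal-run rich-region calling; CHAP
triads are enumerated exhaustively under spacing limits (Cys→His gap
10–130 intervening residues, His→X gap 3–60); molecular mass is the sum
of average residue masses plus one water.

**Synthetic data.** Every generator is seeded (`numpy` `default_rng`),
documents its planted truth in a machine-readable record, applies noise
only *outside* planted elements, and re-runs the corresponding detector
on its own output before returning — a generator bug raises immediately
instead of silently corrupting an experiment.

## Worked example

Simulate one locus per allele, then run the pipeline:

```python
import json
from cmuscan import (GeneratorConfig, RunConfig, bundled_cmub_scheme,
                     make_locus, run_pipeline, write_fasta)

scheme = bundled_cmub_scheme()
loci = [make_locus(scheme, allele, GeneratorConfig(seed=42 + i)).record
        for i, allele in enumerate(["cmuB1", "cmuB2", "cmuB3", "cmuB4"])]
write_fasta(loci, "loci.fa")

summary = run_pipeline(RunConfig(loci_fasta="loci.fa", out_dir="out"))
print(json.dumps(summary["stages"], indent=2))
print(open("out/calls.tsv").read())
```

Output:

```text
{
  "curation": {
    "input": 4,
    "retained": 4,
    "removed": 0
  },
  "repeats": {
    "arrays": 6
  },
  "typing": {
    "typed": 4,
    "failed": 0,
    "allele_classes": [
      "cmuB1",
      "cmuB2",
      "cmuB3",
      "cmuB4"
    ]
  }
}
seq_id	profile	allele	warnings
cmuB_cmuB1_seed42	2-2	cmuB1	-
cmuB_cmuB2_seed43	3-2	cmuB2	-
cmuB_cmuB3_seed44	2-0	cmuB3	-
cmuB_cmuB4_seed45	0-3	cmuB4	-
```

The same steps are available from the shell:

```bash
cmuscan simulate locus --seed 3 --allele cmuB2 --out sim/
cmuscan type-allele --fasta sim/locus.fa --out calls.tsv
cmuscan pcr-screen --fasta genomes.fa --out matrix.tsv
cmuscan run --config pipeline.json
```

`cmuscan --help` lists all subcommands (`dedupe`, `find-repeats`,
`type-allele`, `pcr-screen`, `profile-protein`, `simulate`, `run`).

## Layout

| Path | Contents |
| --- | --- |
| `src/cmuscan/seqio.py` | FASTA I/O, alphabets, IUPAC logic, Hamming |
| `src/cmuscan/repeat_finder.py` | de novo and targeted tandem-array detection |
| `src/cmuscan/allele_typer.py` | locus schemes, anchor placement, allele calls |
| `src/cmuscan/insilico_pcr.py` | degenerate-primer PCR, bundled assays, panel screens |
| `src/cmuscan/seq_curation.py` | global identity, redundancy removal |
| `src/cmuscan/protein_features.py` | composition tracks, rich regions, CHAP triads, mass |
| `src/cmuscan/synthetic_data.py` | seeded self-verifying generators |
| `src/cmuscan/pipeline.py`, `cli.py` | orchestration and `cmuscan` command line |
| `docs/methods.md` | methods note: algorithms, parameters, assumptions |
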