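"""End-to-end workflow: curate -> find repeats -> type alleles -> PCR screen
-> protein profile, with a machine-readable summary.

Every stage writes a diff-able text artifact (TSV or JSON) into the output
directory; the summary JSON aggregates counts and parameters.  Runs are
deterministic given identical inputs and configuration — timestamps appear
only in the log, never in artifacts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import seqio
from .allele_typer import LocusScheme, bundled_cmub_scheme, load_scheme, type_locus
from .insilico_pcr import BUNDLED_ASSAYS, PcrParams, load_assays, screen_panel
from .protein_features import call_rich_regions, composition_track, find_triads, molecular_mass
from .repeat_finder import RepeatSearchParams, find_tandem_arrays
from .seq_curation import remove_redundant

logger = logging.getLogger("cmuscan")


class ConfigError(ValueError):
    """Invalid run configuration (missing files, bad parameters)."""


@dataclass
class RunConfig:
    loci_fasta: Path | None = None
    protein_fasta: Path | None = None
    genomes_fasta: Path | None = None
    scheme_path: Path | None = None      # None -> bundled cmuB scheme
    assay_path: Path | None = None       # None -> bundled assays
    out_dir: Path = Path("cmuscan_out")
    redundancy_threshold: float = 98.0
    repeat_params: RepeatSearchParams = field(default_factory=RepeatSearchParams)
    pcr_params: PcrParams = field(default_factory=PcrParams)
    protein_window: int = 21
    protein_residues: str = "SAT"
    protein_min_frac: float = 0.6
    protein_min_len: int = 15

    def validate(self) -> None:
        for label, p in (("loci_fasta", self.loci_fasta),
                         ("protein_fasta", self.protein_fasta),
                         ("genomes_fasta", self.genomes_fasta),
                         ("scheme_path", self.scheme_path),
                         ("assay_path", self.assay_path)):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{label}: file not found: {p}")
        if self.loci_fasta is None and self.protein_fasta is None \
                and self.genomes_fasta is None:
            raise ConfigError("no inputs: provide at least one FASTA")


def arrays_to_tsv(records, params: RepeatSearchParams, path: Path) -> int:
    rows = []
    for rec in records:
        for arr in find_tandem_arrays(rec.sequence, params):
            start1, end1 = seqio.to_one_based(arr.start, arr.end)
            rows.append({"seq_id": rec.id, "start": start1, "end": end1,
                         "unit": arr.unit, "unit_length": arr.unit_length,
                         "copies": arr.copies,
                         "mismatches": sum(arr.mismatches_per_copy)})
    pd.DataFrame(rows, columns=["seq_id", "start", "end", "unit",
                                "unit_length", "copies", "mismatches"]) \
        .to_csv(path, sep="\t", index=False)
    return len(rows)


def calls_to_tsv(records, scheme: LocusScheme, path: Path):
    calls = [type_locus(rec, scheme) for rec in records]
    pd.DataFrame([{"seq_id": c.seq_id, "profile": c.profile_str,
                   "allele": c.allele or "FAILED",
                   "warnings": ";".join(c.warnings) or "-"} for c in calls]) \
        .to_csv(path, sep="\t", index=False)
    return calls


def run_pipeline(config: RunConfig) -> dict:
    """Execute all applicable stages; returns the summary dict.

    Raises :class:`ConfigError` before any stage runs if the configuration
    is invalid; a stage failure propagates with the stage name in the log.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": {}, "parameters": {
        "redundancy_threshold": config.redundancy_threshold,
        "repeat": vars(config.repeat_params).copy()
        if hasattr(config.repeat_params, "__dict__")
        else {"min_unit": config.repeat_params.min_unit,
              "max_unit": config.repeat_params.max_unit,
              "min_copies": config.repeat_params.min_copies,
              "max_mismatch_per_copy": config.repeat_params.max_mismatch_per_copy},
        "pcr": {"max_mismatch": config.pcr_params.max_mismatch,
                "three_prime_protect": config.pcr_params.three_prime_protect,
                "min_len": config.pcr_params.min_len,
                "max_len": config.pcr_params.max_len},
    }}

    def stage(name):
        logger.info("stage %s starting", name)
        return time.monotonic()

    if config.loci_fasta is not None:
        t0 = stage("curate+repeats+typing")
        loci = seqio.read_fasta(config.loci_fasta, "dna-iupac")

        red = remove_redundant(loci, config.redundancy_threshold)
        kept = [r for r in loci if r.id in set(red.retained)]
        seqio.write_fasta(kept, out / "kept.fa")
        pd.DataFrame([{"removed_id": k, "representative": v}
                      for k, v in sorted(red.removed.items())],
                     columns=["removed_id", "representative"]) \
            .to_csv(out / "dedupe.tsv", sep="\t", index=False)
        summary["stages"]["curation"] = {
            "input": len(loci), "retained": len(kept),
            "removed": len(red.removed)}

        n_arrays = arrays_to_tsv(kept, config.repeat_params, out / "arrays.tsv")
        summary["stages"]["repeats"] = {"arrays": n_arrays}

        scheme = (load_scheme(config.scheme_path) if config.scheme_path
                  else bundled_cmub_scheme())
        calls = calls_to_tsv(kept, scheme, out / "calls.tsv")
        alleles = sorted({c.allele for c in calls if c.ok})
        summary["stages"]["typing"] = {
            "typed": sum(c.ok for c in calls),
            "failed": sum(not c.ok for c in calls),
            "allele_classes": alleles}
        logger.info("loci stages done in %.2fs (%d loci)",
                    time.monotonic() - t0, len(loci))

    if config.genomes_fasta is not None:
        t0 = stage("pcr-screen")
        genomes = seqio.read_fasta(config.genomes_fasta, "dna-iupac")
        assays = (load_assays(config.assay_path) if config.assay_path
                  else list(BUNDLED_ASSAYS))
        matrix = screen_panel(genomes, assays, config.pcr_params)
        matrix.to_dataframe().rename_axis("template").reset_index() \
            .to_csv(out / "matrix.tsv", sep="\t", index=False)
        summary["stages"]["pcr"] = {
            "templates": len(genomes), "assays": len(assays),
            "detected": sum(matrix.detected(t, a)
                            for t in matrix.template_ids
                            for a in matrix.assay_names)}
        logger.info("pcr screen done in %.2fs", time.monotonic() - t0)

    if config.protein_fasta is not None:
        t0 = stage("protein-profile")
        prots = seqio.read_fasta(config.protein_fasta, "protein")
        features = {}
        for p in prots:
            track = composition_track(p, config.protein_window,
                                      frozenset(config.protein_residues))
            regions = call_rich_regions(track, config.protein_min_frac,
                                        config.protein_min_len)
            triads = find_triads(p)
            features[p.id] = {
                "length": len(p),
                "mass_da": round(molecular_mass(p), 2),
                "rich_regions": [{"start": r.start + 1, "end": r.end,
                                  "mean_fraction": round(r.mean_fraction, 3)}
                                 for r in regions],
                "triads": [{"cys": t.cys_pos + 1, "his": t.his_pos + 1,
                            "third": t.third_pos + 1,
                            "third_residue": t.third_residue}
                           for t in triads],
            }
        (out / "features.json").write_text(json.dumps(features, indent=2) + "\n")
        summary["stages"]["proteins"] = {"profiled": len(prots)}
        logger.info("protein profile done in %.2fs", time.monotonic() - t0)

    (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                 sort_keys=True) + "\n")
    return summary
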