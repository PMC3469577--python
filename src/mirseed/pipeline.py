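"""End-to-end orchestration: preprocess -> classify -> map -> discover ->
name -> quantify -> diffexp -> targets, with reports and provenance.

The run consumes a manifest of libraries (id, genotype, condition, day,
FASTQ path) plus reference inputs, applies every stage with the configured
thresholds, and writes one TSV per report plus a JSON provenance record
(config, package version, seed) sufficient to reproduce the run.  Read-count
conservation is asserted between stages: the category table of each library
must partition its retained total exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from ._seq import to_dna, to_rna
from .annotate import DEFAULT_PRECEDENCE, AnnotationDB, classify_reads
from .diffexp import ExpressionRecord, call_differential, round_half_up
from .hairpin import discover_hairpins
from .homology import assign_names, match_mature
from .mapping import KmerIndex, map_read
from .reads import preprocess_fastq
from .targets import scan_transcriptome

__all__ = ["LibrarySpec", "RunConfig", "run_pipeline"]


@dataclass
class LibrarySpec:
    library_id: str
    genotype: str  # HT / LT
    condition: str  # irrigated / drought
    day: int
    fastq: str


@dataclass
class RunConfig:
    genome_fasta: str
    reference_matures_fasta: str
    libraries: list[LibrarySpec]
    annotation_fastas: dict[str, str] = field(default_factory=dict)
    transcripts_fasta: str | None = None
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    min_len: int = 18
    max_len: int = 27
    window: int = 250
    max_star_mismatches: int = 6
    gc_min: float = 30.0
    gc_max: float = 70.0
    max_mismatches: int = 0
    max_hits: int = 15
    homology_max_mm: int = 2
    fc_min: float = 2.0
    alpha: float = 0.05
    e_max: float = 3.0
    min_candidate_count: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must not exceed max_len")
        if self.gc_min > self.gc_max:
            raise ValueError("gc_min must not exceed gc_max")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.fc_min < 1:
            raise ValueError("fc_min must be >= 1")
        ids = [lib.library_id for lib in self.libraries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate library ids in manifest")
        if not self.libraries:
            raise ValueError("manifest lists no libraries")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        libs = [LibrarySpec(**lib) for lib in raw.pop("libraries")]
        return cls(libraries=libs, **raw)


def _read_fasta_dict(path: str | Path) -> dict[str, str]:
    return {rec.id: to_dna(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict[str, object]:
    """Execute the full analysis; returns the in-memory results.

    Writes ``categories_<lib>.tsv``, ``assignments.tsv``, ``precursors.gff3``,
    ``diffexp_<contrast>.tsv``, ``targets.tsv`` and ``provenance.json`` under
    ``out_dir``.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    genome = _read_fasta_dict(config.genome_fasta)
    reference_matures = _read_fasta_dict(config.reference_matures_fasta)

    # --- preprocess + classify ---------------------------------------------
    collapsed: dict[str, list] = {}
    library_n: dict[str, int] = {}
    for lib in config.libraries:
        reads, n = preprocess_fastq(
            lib.fastq, config.adapter, min_len=config.min_len, max_len=config.max_len
        )
        collapsed[lib.library_id], library_n[lib.library_id] = reads, n

    if config.annotation_fastas:
        db = AnnotationDB.from_fasta(config.annotation_fastas)
        precedence = [c for c in DEFAULT_PRECEDENCE if c in {*db.categories(), "antisense exon"}]
        for lib in config.libraries:
            table = classify_reads(collapsed[lib.library_id], db, precedence)
            total_row = table[table.category == "total small RNAs"].iloc[0]
            if int(total_row.total) != library_n[lib.library_id]:
                raise AssertionError(
                    f"category totals do not partition library {lib.library_id}"
                )
            table.to_csv(out_dir / f"categories_{lib.library_id}.tsv", sep="\t", index=False)

    # --- map + discover hairpins ------------------------------------------
    pooled: dict[str, int] = {}
    for reads in collapsed.values():
        for rec in reads:
            pooled[rec.sequence] = pooled.get(rec.sequence, 0) + rec.count
    index = KmerIndex(genome)
    loci = []
    for seq, count in sorted(pooled.items(), key=lambda kv: (-kv[1], kv[0])):
        if count < config.min_candidate_count or len(seq) < index.k:
            continue
        for locus in map_read(
            seq, index, max_mismatches=config.max_mismatches, max_hits=config.max_hits
        ):
            loci.append((seq, locus))
    candidates = discover_hairpins(
        genome,
        loci,
        window=config.window,
        max_star_mismatches=config.max_star_mismatches,
        gc_min=config.gc_min,
        gc_max=config.gc_max,
    )
    passing = {seq: c for seq, c in candidates.items() if c.passed}

    # --- homology naming ---------------------------------------------------
    assignments = []
    for seq in sorted(passing):
        a = match_mature(seq, reference_matures, max_mm=config.homology_max_mm)
        if a.family is not None:
            a.total_count = pooled[seq]
            assignments.append(a)
    assign_names(assignments)
    named = {a.assigned_name: a.candidate for a in assignments if a.assigned_name}
    pd.DataFrame(
        [
            {
                "family": a.family,
                "name": a.assigned_name,
                "mature_sequence": a.rna,
                "matched_references": ",".join(a.matched_references),
                "mismatches": a.mismatches,
                "ambiguous": a.ambiguous,
                "total_count": a.total_count,
            }
            for a in assignments
        ]
    ).to_csv(out_dir / "assignments.tsv", sep="\t", index=False)

    with open(out_dir / "precursors.gff3", "w") as gff:
        gff.write("##gff-version 3\n")
        for seq in sorted(passing):
            c = passing[seq]
            if c.window_locus is None:
                continue
            loc = c.window_locus
            name = next((a.assigned_name for a in assignments if a.candidate == seq), "")
            gff.write(
                f"{loc.reference_id}\tmirseed\tmiRNA_primary_transcript\t"
                f"{loc.start + 1}\t{loc.end}\t.\t{loc.strand}\t.\t"
                f"ID={name or to_rna(seq)};mfe={c.mfe:.1f};gc={c.gc:.1f}\n"
            )

    # --- quantify + differential expression -------------------------------
    seq_counts = {
        lib.library_id: {rec.sequence: rec.count for rec in collapsed[lib.library_id]}
        for lib in config.libraries
    }
    counts = pd.DataFrame(
        {
            lib.library_id: {
                name: seq_counts[lib.library_id].get(seq, 0)
                for name, seq in named.items()
            }
            for lib in config.libraries
        }
    )
    counts.to_csv(out_dir / "counts.tsv", sep="\t")

    by_key = {(lib.genotype, lib.condition, lib.day): lib for lib in config.libraries}
    results = {}
    for (genotype, condition, day), lib in sorted(by_key.items()):
        if condition != "drought":
            continue
        control = by_key.get((genotype, "irrigated", day))
        if control is None:
            continue
        contrast = f"{genotype}D{day}/{genotype}I{day}"
        records = [
            ExpressionRecord(
                name=name,
                count_treated=int(counts.loc[name, lib.library_id]),
                count_control=int(counts.loc[name, control.library_id]),
                n_treated=library_n[lib.library_id],
                n_control=library_n[control.library_id],
            )
            for name in counts.index
        ]
        res = call_differential(
            records, contrast=contrast, fc_min=config.fc_min, alpha=config.alpha
        )
        results[contrast] = res
        pd.DataFrame(
            [
                {
                    "name": r.name,
                    "mature_sequence": to_rna(named[r.name]),
                    "tpm_drought": round_half_up(r.tpm_treated, 2),
                    "tpm_irrigated": round_half_up(r.tpm_control, 2),
                    "fold_change": round_half_up(r.fold_change, 2),
                    "p_value": r.p_value,
                    "significant": "*" if r.significant else "",
                }
                for r in res
            ]
        ).to_csv(
            out_dir / f"diffexp_{contrast.replace('/', '_vs_')}.tsv",
            sep="\t",
            index=False,
        )

    # --- target prediction -------------------------------------------------
    target_hits = []
    if config.transcripts_fasta:
        transcripts = _read_fasta_dict(config.transcripts_fasta)
        target_hits = scan_transcriptome(named, transcripts, e_max=config.e_max)
        pd.DataFrame(
            [
                {
                    "mirna": h.mirna_name,
                    "transcript": h.transcript_id,
                    "expectation": h.expectation,
                    "target_start": h.start,
                    "target_end": h.end,
                    "mirna_fragment": h.mirna_fragment,
                    "target_fragment": h.target_fragment,
                    "inhibition": h.inhibition,
                }
                for h in target_hits
            ]
        ).to_csv(out_dir / "targets.tsv", sep="\t", index=False)

    provenance = {
        "package": "mirseed",
        "version": __version__,
        "seed": config.seed,
        "config": {
            **{
                k: v
                for k, v in asdict(config).items()
                if k not in ("libraries",)
            },
            "libraries": [asdict(lib) for lib in config.libraries],
        },
    }
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)

    return {
        "library_n": library_n,
        "candidates": candidates,
        "assignments": assignments,
        "named": named,
        "counts": counts,
        "diffexp": results,
        "targets": target_hits,
    }
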