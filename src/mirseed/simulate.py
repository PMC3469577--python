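"""Synthetic study generator: toy genome, libraries, and transcriptome.

This module emulates the shape of a drought small-RNA sequencing study so
that every pipeline stage has a fully known truth to be tested against:

* a toy genome carrying planted hairpin precursors at recorded loci, each
  guaranteed (by running the discovery criteria as an oracle during
  generation) to pass the four precursor acceptance criteria;
* planted mature sequences derived from the sorghum-homolog reference set by
  at most two substitutions, so homology naming has a known answer;
* per-category decoy sequences (rRNA, tRNA, snRNA, snoRNA, exon, siRNA) for
  annotation classification;
* simulated libraries with 3' adapters, 16-27 nt inserts, a 21 nt main mode
  and a 24 nt secondary mode, and per-condition planted fold changes under a
  Poisson count model (negative binomial optional);
* a toy transcriptome with target sites planted at recorded spans with known
  mismatch/wobble layouts.

All randomness flows through ``numpy.random.default_rng`` seeded from the
caller; identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._seq import revcomp, to_dna, to_rna
from .curated import REFERENCE_MATURES
from .hairpin import evaluate_precursor, extract_window
from .homology import _best_offset_mismatches
from .mapping import GenomicLocus

__all__ = [
    "PlantedPrecursor",
    "PlantedTarget",
    "SyntheticTruth",
    "make_reference",
    "simulate_counts",
    "simulate_library",
    "make_transcriptome_with_targets",
    "write_truth",
]

CONDITIONS = ("irrigated", "drought")

#: Drought/irrigated expression ratios cycled over planted miRNAs.  Roughly a
#: third are null (ratio 1); the |ratio| >= 3 entries are the strong
#: responders whose direction the end-to-end test must always recover.
DEFAULT_FC_PATTERN = (1.0, 4.0, 0.25, 1.0, 3.0, 1 / 3, 1.0, 2.0, 0.5, 1.0)

#: Baseline abundance range (TPM), log-uniform.  Drought-responsive plant
#: miRNAs are typically moderately to highly expressed, so baselines span
#: hundreds to thousands of TPM.
BASELINE_TPM_RANGE = (400.0, 4000.0)

#: Insert-length weights for unannotated background reads: a main 21 nt mode
#: with a secondary 24 nt mode, as in leaf small-RNA libraries.
BACKGROUND_LENGTHS = (18, 19, 20, 21, 22, 23, 24, 25, 26)
BACKGROUND_WEIGHTS = (0.06, 0.07, 0.09, 0.25, 0.09, 0.09, 0.20, 0.06, 0.09)

BACKGROUND_FRACTION = 0.5  # unannotated reads, as a fraction of depth
DECOY_FRACTION = 0.25  # annotated non-miRNA reads, as a fraction of depth

_DECOY_LENGTHS = {
    "rRNA": 120,
    "tRNA": 76,
    "snRNA": 100,
    "snoRNA": 90,
    "sense exon": 200,
    "siRNA": 24,
}

_STEM_LEN = 94  # random lower stem anchoring the mature/star duplex
_LOOP_LEN = 8
_SPACER_LEN = 120
_WINDOW = 250


@dataclass
class PlantedPrecursor:
    name: str  # planted mature name, e.g. mir001
    reference_name: str  # closest reference mature, e.g. sbi-MIR164b
    mature: str  # DNA
    precursor: str  # DNA
    locus: GenomicLocus  # mature locus on the genome
    precursor_locus: GenomicLocus
    mature_mismatches: int  # substitutions applied vs the reference mature


@dataclass
class PlantedTarget:
    mirna_name: str
    transcript_id: str
    start: int  # 1-based inclusive on the transcript
    end: int
    layout: list[tuple[int, str]]  # (1-based miRNA position, "mismatch"|"wobble")
    expected_expectation: float


@dataclass
class SyntheticTruth:
    seed: int
    precursors: list[PlantedPrecursor]
    mature_set: dict[str, str]  # planted name -> DNA sequence
    baselines_tpm: dict[str, float]
    planted_fc: dict[str, float]  # drought/irrigated expression ratio
    decoys: dict[str, list[str]]
    genome: dict[str, str]
    target_sites: list[PlantedTarget] = field(default_factory=list)

    def reference_matures_dna(self) -> dict[str, str]:
        return {k: to_dna(v) for k, v in REFERENCE_MATURES.items()}


def _random_seq(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def _mutate(rng: np.random.Generator, seq: str, n_sub: int) -> str:
    out = list(seq)
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    for p in positions:
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


def _uniquely_matches(mature: str, reference_name: str, max_mm: int = 2) -> bool:
    """True if ``mature`` is within max_mm of exactly one reference name."""
    close = [
        name
        for name, ref in REFERENCE_MATURES.items()
        if abs(len(to_dna(ref)) - len(mature)) <= 2
        and _best_offset_mismatches(mature, to_dna(ref), 2) <= max_mm
    ]
    return close == [reference_name]


def _plant_mature(
    rng: np.random.Generator, reference_name: str, used: set[str]
) -> tuple[str, int]:
    """A mature 0-2 substitutions from one reference, unambiguous and unused.

    Distinctness matters: planting one sequence at two loci would pool their
    counts and dilute each locus's planted fold change.
    """
    ref = to_dna(REFERENCE_MATURES[reference_name])
    for _ in range(100):
        n_sub = int(rng.integers(0, 3))
        cand = _mutate(rng, ref, n_sub) if n_sub else ref
        if cand not in used and _uniquely_matches(cand, reference_name):
            return cand, n_sub
    raise RuntimeError(f"could not plant a distinct mature for {reference_name}")


def _build_block(
    rng: np.random.Generator, mature: str, window: int = _WINDOW
) -> tuple[str, int, int]:
    """One genome block: spacer + long-stem hairpin precursor + spacer.

    The precursor places the mature/star duplex on top of a ~94 bp random
    lower stem, so the excised window is essentially one designed hairpin
    whose full ladder is the clear energy optimum; the short junk flank and
    the genomic spacers use the low-pairing A/C alphabet.  Returns (block,
    mature offset in block, precursor offset in block).
    """
    left = (window - len(mature)) // 2
    junk = _random_seq(rng, left - _STEM_LEN, "AC")
    stem = _random_seq(rng, _STEM_LEN)
    loop = _random_seq(rng, _LOOP_LEN, "AC")
    pre = junk + stem + mature + loop + revcomp(mature) + revcomp(stem)
    sp5 = _random_seq(rng, _SPACER_LEN, "AC")
    sp3 = _random_seq(rng, _SPACER_LEN, "AC")
    block = sp5 + pre + sp3
    return block, _SPACER_LEN + len(junk) + _STEM_LEN, _SPACER_LEN


def make_reference(
    n_precursors: int,
    n_decoys: int,
    seed: int,
    fc_pattern: tuple[float, ...] = DEFAULT_FC_PATTERN,
    window: int = 250,
) -> SyntheticTruth:
    """Generate the toy genome, annotation decoys, and study truth.

    Each planted precursor is verified against the hairpin discovery criteria
    on its excised window during generation (regenerating flank randomness if
    an unlucky draw fails them), so passing the criteria is a construction
    invariant, not a statistical tendency.
    """
    if n_precursors < 1:
        raise ValueError("n_precursors must be >= 1")
    if n_decoys < 0:
        raise ValueError("n_decoys must be non-negative")
    rng = np.random.default_rng(seed)
    ref_names = list(REFERENCE_MATURES)
    blocks: list[str] = []
    precursors: list[PlantedPrecursor] = []
    mature_set: dict[str, str] = {}
    offset = 0
    for i in range(n_precursors):
        ref_name = ref_names[i % len(ref_names)]
        mature, n_sub = _plant_mature(rng, ref_name, set(mature_set.values()))
        for _attempt in range(30):
            block, m_off, p_off = _build_block(rng, mature, window=window)
            locus = GenomicLocus("chr1", m_off, m_off + len(mature), "+")
            wseq, w_off = extract_window(block, locus, window=window)
            cand = evaluate_precursor(wseq, (w_off, w_off + len(mature)))
            if cand.passed:
                break
        else:
            raise RuntimeError("could not construct a passing precursor")
        name = f"mir{i + 1:03d}"
        pre_len = len(block) - 2 * _SPACER_LEN
        precursors.append(
            PlantedPrecursor(
                name=name,
                reference_name=ref_name,
                mature=mature,
                precursor=block[p_off : p_off + pre_len],
                locus=GenomicLocus(
                    "chr1", offset + m_off, offset + m_off + len(mature), "+"
                ),
                precursor_locus=GenomicLocus(
                    "chr1", offset + p_off, offset + p_off + pre_len, "+"
                ),
                mature_mismatches=n_sub,
            )
        )
        mature_set[name] = mature
        blocks.append(block)
        offset += len(block)
    genome = {"chr1": "".join(blocks)}

    categories = list(_DECOY_LENGTHS)
    decoys: dict[str, list[str]] = {cat: [] for cat in categories}
    for i in range(n_decoys):
        cat = categories[i % len(categories)]
        decoys[cat].append(_random_seq(rng, _DECOY_LENGTHS[cat]))

    log_lo, log_hi = np.log(BASELINE_TPM_RANGE[0]), np.log(BASELINE_TPM_RANGE[1])
    baselines = {
        p.name: float(np.exp(rng.uniform(log_lo, log_hi))) for p in precursors
    }
    planted_fc = {
        p.name: float(fc_pattern[i % len(fc_pattern)])
        for i, p in enumerate(precursors)
    }
    truth = SyntheticTruth(
        seed=seed,
        precursors=precursors,
        mature_set=mature_set,
        baselines_tpm=baselines,
        planted_fc=planted_fc,
        decoys=decoys,
        genome=genome,
    )
    _plan_target_sites(truth, rng)
    return truth


# --- target sites -----------------------------------------------------------

_WOBBLE_TARGET = {"G": "T", "T": "G"}  # miRNA base -> wobble partner
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _site_with_layout(mature: str, layout: list[tuple[int, str]]) -> str:
    """Target fragment (5'->3') complementary to ``mature`` except at the
    planted defects."""
    frag = list(revcomp(mature))
    L = len(mature)
    for pos, kind in layout:
        b = mature[pos - 1]
        j = L - pos  # fragment index pairing with miRNA position ``pos``
        if kind == "wobble":
            frag[j] = _WOBBLE_TARGET[b]
        else:
            partners = {_COMPLEMENT[b]}
            partners.add(_WOBBLE_TARGET.get(b, _COMPLEMENT[b]))
            frag[j] = next(c for c in "ACGT" if c not in partners and c != frag[j])
    return "".join(frag)


def _layout_expectation(layout: list[tuple[int, str]]) -> float:
    e = 0.0
    for pos, kind in layout:
        pen = 0.5 if kind == "wobble" else 1.0
        if 2 <= pos <= 13:
            pen *= 2.0
        e += pen
    return e


def _plan_target_sites(truth: SyntheticTruth, rng: np.random.Generator) -> None:
    """Plant one site per miRNA (up to 8), cycling defect layouts."""
    kinds = ("perfect", "mismatch", "wobble")
    for i, p in enumerate(truth.precursors[:8]):
        kind = kinds[i % len(kinds)]
        L = len(p.mature)
        layout: list[tuple[int, str]] = []
        if kind != "perfect":
            # a defect outside both the seed (2-13) and the central 9-11 span
            candidates = [
                pos
                for pos in range(14, L + 1)
                if kind == "mismatch" or p.mature[pos - 1] in _WOBBLE_TARGET
            ]
            pos = int(rng.choice(candidates))
            layout = [(pos, kind)]
        truth.target_sites.append(
            PlantedTarget(
                mirna_name=p.name,
                transcript_id=f"tx{i + 1:03d}",
                start=0,  # filled in by make_transcriptome_with_targets
                end=0,
                layout=layout,
                expected_expectation=_layout_expectation(layout),
            )
        )


def make_transcriptome_with_targets(
    truth: SyntheticTruth,
    n_transcripts: int,
    seed: int,
    transcript_len: int = 500,
) -> dict[str, str]:
    """Toy transcriptome with each planted site embedded at a recorded span.

    Site i is placed on transcript ``tx{i+1:03d}``; remaining transcripts are
    random background.  Spans are 1-based inclusive and recorded back into
    ``truth.target_sites``.
    """
    if n_transcripts < len(truth.target_sites):
        raise ValueError("n_transcripts must cover all planted target sites")
    rng = np.random.default_rng(seed)
    matures = {p.name: p.mature for p in truth.precursors}
    transcripts: dict[str, str] = {}
    occupied: dict[str, list[tuple[int, int]]] = {}
    for i in range(n_transcripts):
        tid = f"tx{i + 1:03d}"
        transcripts[tid] = _random_seq(rng, transcript_len)
    for site in truth.target_sites:
        frag = _site_with_layout(matures[site.mirna_name], site.layout)
        seq = transcripts[site.transcript_id]
        start0 = int(rng.integers(0, len(seq) - len(frag) + 1))
        span = (start0 + 1, start0 + len(frag))
        for s, e in occupied.get(site.transcript_id, []):
            if not (span[1] < s or span[0] > e):
                raise ValueError("planted target spans collide")
        occupied.setdefault(site.transcript_id, []).append(span)
        transcripts[site.transcript_id] = (
            seq[:start0] + frag + seq[start0 + len(frag) :]
        )
        site.start, site.end = span
    return transcripts


# --- libraries --------------------------------------------------------------


def simulate_counts(
    truth: SyntheticTruth,
    condition: str,
    depth: int,
    rng: np.random.Generator,
    count_model: str = "poisson",
    dispersion: float = 0.1,
) -> dict[str, int]:
    """Draw per-miRNA read counts for one library.

    Expected count = depth * baseline_tpm/1e6 * fc(condition), drawn Poisson
    (the sampling model the count test assumes) or negative binomial with the
    given dispersion (variance = mu + dispersion * mu^2) as a robustness knob.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected {CONDITIONS}")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    counts = {}
    for name, baseline in truth.baselines_tpm.items():
        mu = depth * baseline / 1e6
        if condition == "drought":
            mu *= truth.planted_fc[name]
        if count_model == "poisson":
            counts[name] = int(rng.poisson(mu))
        elif count_model == "nb":
            r = 1.0 / dispersion
            p = r / (r + mu)
            counts[name] = int(rng.negative_binomial(r, p))
        else:
            raise ValueError(f"unknown count model {count_model!r}")
    return counts


def simulate_library(
    truth: SyntheticTruth,
    condition: str,
    depth: int,
    adapter: str,
    seed: int,
    out_path: str | Path,
    read_length: int = 36,
    count_model: str = "poisson",
    dispersion: float = 0.1,
) -> dict[str, int]:
    """Write one simulated FASTQ library; returns true per-miRNA counts.

    Reads are insert + 3' adapter, clipped to ``read_length`` with constant
    Phred+33 quality 'I'.  Composition: planted miRNA reads at their expected
    counts, decoy reads (category sequences' substrings; siRNA decoys whole
    at 24 nt) at 25% of depth, and uniform-random unannotated background
    (18-26 nt, 21/24 nt modes) at 50% of depth.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if len(adapter) < 8:
        raise ValueError("adapter must be at least 8 nt")
    adapter = to_dna(adapter)
    rng = np.random.default_rng(seed)
    mir_counts = simulate_counts(
        truth, condition, depth, rng, count_model=count_model, dispersion=dispersion
    )
    inserts: list[str] = []
    for p in truth.precursors:
        inserts.extend([p.mature] * mir_counts[p.name])

    decoy_pool = [(cat, s) for cat, seqs in truth.decoys.items() for s in seqs]
    n_decoy = rng.poisson(DECOY_FRACTION * depth) if decoy_pool else 0
    if decoy_pool:
        picks = rng.integers(0, len(decoy_pool), size=n_decoy)
        lens = rng.choice(BACKGROUND_LENGTHS, size=n_decoy, p=BACKGROUND_WEIGHTS)
        for idx, ln in zip(picks, lens):
            cat, seq = decoy_pool[int(idx)]
            if cat == "siRNA":
                inserts.append(seq)  # 24 nt, taken whole
            else:
                ln = min(int(ln), len(seq))
                start = int(rng.integers(0, len(seq) - ln + 1))
                inserts.append(seq[start : start + ln])

    n_bg = rng.poisson(BACKGROUND_FRACTION * depth)
    bg_lens = rng.choice(BACKGROUND_LENGTHS, size=n_bg, p=BACKGROUND_WEIGHTS)
    bases = np.array(list("ACGT"))
    for ln in bg_lens:
        inserts.append("".join(bases[rng.integers(0, 4, size=int(ln))]))

    order = rng.permutation(len(inserts))
    qual = "I" * read_length
    with open(out_path, "w") as out:
        for rank, idx in enumerate(order, start=1):
            insert = inserts[int(idx)]
            read = (insert + adapter * (read_length // len(adapter) + 2))[:read_length]
            out.write(f"@read{rank}\n{read}\n+\n{qual[: len(read)]}\n")
    return mir_counts


# --- serialization ----------------------------------------------------------


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as out:
        for name, seq in records.items():
            out.write(f">{name}\n{seq}\n")


def write_truth(truth: SyntheticTruth, out_dir: str | Path) -> dict[str, Path]:
    """Dump genome, annotation sets, reference matures, GFF3 loci, and JSON.

    GFF3 coordinates are 1-based inclusive.  Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["genome"] = out_dir / "genome.fasta"
    write_fasta(truth.genome, paths["genome"])

    paths["reference_matures"] = out_dir / "reference_matures.fasta"
    write_fasta(truth.reference_matures_dna(), paths["reference_matures"])

    for cat, seqs in truth.decoys.items():
        key = f"annotation_{cat.replace(' ', '_')}"
        paths[key] = out_dir / f"{key}.fasta"
        write_fasta({f"{cat.replace(' ', '_')}{i}": s for i, s in enumerate(seqs, 1)}, paths[key])
    paths["annotation_miRNA"] = out_dir / "annotation_miRNA.fasta"
    write_fasta({p.name: p.precursor for p in truth.precursors}, paths["annotation_miRNA"])

    paths["gff"] = out_dir / "truth.gff3"
    with open(paths["gff"], "w") as gff:
        gff.write("##gff-version 3\n")
        for p in truth.precursors:
            pl, ml = p.precursor_locus, p.locus
            gff.write(
                f"chr1\tmirseed_sim\tmiRNA_primary_transcript\t{pl.start + 1}\t"
                f"{pl.end}\t.\t{pl.strand}\t.\tID={p.name}_pre\n"
            )
            gff.write(
                f"chr1\tmirseed_sim\tmiRNA\t{ml.start + 1}\t{ml.end}\t.\t"
                f"{ml.strand}\t.\tID={p.name};Derives_from={p.name}_pre\n"
            )

    paths["json"] = out_dir / "truth.json"
    payload = {
        "seed": truth.seed,
        "mature_set": {k: to_rna(v) for k, v in truth.mature_set.items()},
        "reference_of": {p.name: p.reference_name for p in truth.precursors},
        "baselines_tpm": truth.baselines_tpm,
        "planted_fc": truth.planted_fc,
        "target_sites": [
            {
                "mirna": s.mirna_name,
                "transcript": s.transcript_id,
                "start": s.start,
                "end": s.end,
                "layout": s.layout,
                "expectation": s.expected_expectation,
            }
            for s in truth.target_sites
        ],
    }
    with open(paths["json"], "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return paths
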