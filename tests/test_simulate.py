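"""Synthetic study generator: determinism, planted truth, count model."""

import numpy as np
import pytest

from mirseed.hairpin import evaluate_precursor, extract_window
from mirseed.homology import match_mature
from mirseed.reads import preprocess_fastq
from mirseed.simulate import (
    make_reference,
    make_transcriptome_with_targets,
    simulate_counts,
    simulate_library,
    write_truth,
)

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


class TestMakeReference:
    def test_minimal_case_records_one_locus(self):
        truth = make_reference(1, 0, seed=7)
        assert len(truth.precursors) == 1
        p = truth.precursors[0]
        assert (
            truth.genome["chr1"][p.locus.start : p.locus.end] == p.mature
        )

    def test_deterministic(self):
        a = make_reference(12, 18, seed=1)
        b = make_reference(12, 18, seed=1)
        assert a.genome == b.genome
        assert a.decoys == b.decoys
        assert [p.mature for p in a.precursors] == [p.mature for p in b.precursors]
        assert a.baselines_tpm == b.baselines_tpm

    def test_all_planted_precursors_pass_criteria(self, small_truth):
        for p in small_truth.precursors:
            w, off = extract_window(small_truth.genome["chr1"], p.locus, 250)
            cand = evaluate_precursor(w, (off, off + len(p.mature)))
            assert cand.passed

    def test_matures_unambiguous_and_distinct(self, small_truth):
        matures = [p.mature for p in small_truth.precursors]
        assert len(set(matures)) == len(matures)
        for p in small_truth.precursors:
            a = match_mature(p.mature, small_truth.reference_matures_dna())
            assert a.matched_references == [p.reference_name] or (
                p.reference_name in a.matched_references and not a.ambiguous
            )
            assert a.mismatches <= 2

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            make_reference(0, 5, seed=1)
        with pytest.raises(ValueError):
            make_reference(3, -1, seed=1)


class TestSimulateLibrary:
    def test_zero_depth_rejected(self, small_truth, tmp_path):
        with pytest.raises(ValueError):
            simulate_library(small_truth, "drought", 0, ADAPTER, 1, tmp_path / "x.fastq")

    def test_unknown_condition_rejected(self, small_truth, tmp_path):
        with pytest.raises(ValueError):
            simulate_library(small_truth, "frozen", 100, ADAPTER, 1, tmp_path / "x.fastq")

    def test_short_adapter_rejected(self, small_truth, tmp_path):
        with pytest.raises(ValueError):
            simulate_library(small_truth, "drought", 100, "ACGT", 1, tmp_path / "x.fastq")

    def test_deterministic_fastq(self, small_truth, tmp_path):
        a, b = tmp_path / "a.fastq", tmp_path / "b.fastq"
        simulate_library(small_truth, "drought", 3000, ADAPTER, 5, a)
        simulate_library(small_truth, "drought", 3000, ADAPTER, 5, b)
        assert a.read_bytes() == b.read_bytes()

    def test_preprocessing_recovers_mirna_counts(self, small_truth, tmp_path):
        """Collapsed counts of each planted mature equal the drawn truth."""
        fq = tmp_path / "lib.fastq"
        counts = simulate_library(small_truth, "irrigated", 20_000, ADAPTER, 8, fq)
        collapsed, n = preprocess_fastq(fq, ADAPTER)
        assert n == sum(r.count for r in collapsed)
        by_seq = {r.sequence: r.count for r in collapsed}
        for p in small_truth.precursors:
            assert by_seq.get(p.mature, 0) == counts[p.name]

    def test_insert_length_range(self, small_truth, tmp_path):
        fq = tmp_path / "lib.fastq"
        simulate_library(small_truth, "drought", 5000, ADAPTER, 3, fq)
        collapsed, _ = preprocess_fastq(fq, ADAPTER, min_len=1, max_len=100)
        lengths = sorted({r.length for r in collapsed})
        assert min(lengths) >= 16
        assert max(lengths) <= 27


class TestSimulateCounts:
    def test_poisson_means_track_fold_change(self, small_truth):
        rng = np.random.default_rng(0)
        depth = 10**6
        reps_d = [simulate_counts(small_truth, "drought", depth, rng) for _ in range(30)]
        reps_i = [simulate_counts(small_truth, "irrigated", depth, rng) for _ in range(30)]
        for p in small_truth.precursors:
            mu_i = np.mean([r[p.name] for r in reps_i])
            mu_d = np.mean([r[p.name] for r in reps_d])
            expected = small_truth.baselines_tpm[p.name] * depth / 1e6
            assert mu_i == pytest.approx(expected, rel=0.15)
            assert mu_d == pytest.approx(
                expected * small_truth.planted_fc[p.name], rel=0.15
            )

    def test_nb_model_available(self, small_truth):
        rng = np.random.default_rng(0)
        counts = simulate_counts(
            small_truth, "drought", 10**5, rng, count_model="nb", dispersion=0.2
        )
        assert all(c >= 0 for c in counts.values())


class TestTranscriptome:
    def test_deterministic(self, small_truth):
        a = make_transcriptome_with_targets(small_truth, 10, seed=4)
        b = make_transcriptome_with_targets(small_truth, 10, seed=4)
        assert a == b

    def test_too_few_transcripts_rejected(self, small_truth):
        with pytest.raises(ValueError):
            make_transcriptome_with_targets(small_truth, 1, seed=4)


def test_write_truth_outputs(small_truth, tmp_path):
    paths = write_truth(small_truth, tmp_path)
    assert paths["genome"].exists()
    gff = paths["gff"].read_text()
    assert gff.startswith("##gff-version 3")
    assert gff.count("\tmiRNA\t") == len(small_truth.precursors)
    import json

    payload = json.loads(paths["json"].read_text())
    assert payload["seed"] == small_truth.seed
    assert set(payload["planted_fc"]) == set(small_truth.planted_fc)
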