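"""Repeat counting, GC matching and TRPM profiling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import naive_gc, naive_profile, naive_repeat_count

from telomancer.telocontent import (
    DEFAULT_PATTERNS,
    Read,
    RepeatParams,
    TelomereProfile,
    compute_profile,
    compute_terra,
    count_repeat_occurrences,
    encode_sequences,
    gc_fraction,
    is_telomeric,
    profile_from_matrix,
    read_fastq,
    read_sam,
    reverse_complement,
    sanitize_sequence,
    write_fastq,
    write_profile_tsv,
    _batch_repeat_counts,
)

P = RepeatParams()


def _random_seqs(rng, n, lengths=(30, 49, 60)):
    """Reads mixing background, telomere-like and N-containing content."""
    seqs = []
    for _ in range(n):
        L = int(rng.choice(lengths))
        kind = rng.random()
        if kind < 0.4:
            seq = "".join(rng.choice(list("ACGTN"), size=L, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        elif kind < 0.8:
            reps = [DEFAULT_PATTERNS[i] for i in rng.choice(4, size=L // 6 + 1)]
            seq = "".join(reps)[:L]
            if rng.random() < 0.5:
                seq = reverse_complement(seq)
            # sprinkle point errors
            chars = list(seq)
            for i in range(L):
                if rng.random() < 0.08:
                    chars[i] = "ACGT"[int(rng.integers(4))]
            seq = "".join(chars)
        else:
            half = "".join(rng.choice(list("ACGT"), size=L - L // 2))
            seq = ("TTAGGG" * (L // 12 + 1))[: L // 2] + half
        seqs.append(seq)
    return seqs


class TestRepeatCounting:
    @pytest.mark.parametrize(
        "sequence, expected",
        [
            ("TTAGGG" * 7, 7),
            ("AC" * 25, 0),  # 49+ bp of ACAC..., no pattern
            ("TTAGGGTCAGGGTGAGGGTTGGGG" + "CCCTAA" * 3, 7),
            ("CCCTAA" * 4, 4),  # reverse-complement-only content
            ("A" * 5, 0),  # shorter than one hexamer
        ],
    )
    def test_examples(self, sequence, expected):
        assert count_repeat_occurrences(Read("r", sequence), P) == expected

    def test_revcomp_toggle(self):
        seq = "CCCTAA" * 7
        assert count_repeat_occurrences(seq, P) == 7
        no_rc = RepeatParams(include_reverse_complement=False)
        assert count_repeat_occurrences(seq, no_rc) == 0

    def test_greedy_nonoverlap(self):
        # Offset tandem: greedy consumes 6 bases per match.
        seq = "A" + "TTAGGG" * 3
        assert count_repeat_occurrences(seq, P) == 3

    def test_oracle_equivalence_scalar(self, rng):
        for seq in _random_seqs(rng, 300):
            assert count_repeat_occurrences(seq, P) == naive_repeat_count(
                seq, DEFAULT_PATTERNS
            )

    def test_batch_matches_scalar(self, rng):
        seqs = _random_seqs(rng, 400)
        mat, lengths = encode_sequences(seqs)
        batch = _batch_repeat_counts(mat, P)
        scalar = [count_repeat_occurrences(s, P) for s in seqs]
        assert list(batch) == scalar


class TestClassification:
    def test_threshold_boundary(self):
        assert is_telomeric("TTAGGG" * 7, P) is True
        assert is_telomeric("TTAGGG" * 6 + "A" * 6, P) is False

    def test_scaled_threshold(self):
        params = RepeatParams(scale_threshold_by_length=True)
        seq = "TTAGGG" * 13 + "AC" * 10  # 98 bp, 13 repeats
        assert len(seq) == 98
        assert params.effective_threshold(98) == 14
        assert is_telomeric(seq, params) is False
        assert is_telomeric("TTAGGG" * 14 + "AC" * 7, params) is True

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            RepeatParams(patterns=())
        with pytest.raises(ValueError):
            RepeatParams(patterns=("TTAGG",))
        with pytest.raises(ValueError):
            RepeatParams(gc_low=0.6, gc_high=0.5)
        with pytest.raises(ValueError):
            RepeatParams(repeat_threshold=0)


class TestGC:
    @pytest.mark.parametrize(
        "sequence, expected",
        [("GGCC", 1.0), ("ATAT", 0.0), ("GCATN", 0.5)],
    )
    def test_examples(self, sequence, expected):
        assert gc_fraction(sequence) == expected

    def test_all_n_undefined(self):
        assert gc_fraction("NNNN") is None

    def test_matches_naive(self, rng):
        for seq in _random_seqs(rng, 200):
            assert gc_fraction(seq) == pytest.approx(naive_gc(seq)) or (
                gc_fraction(seq) is None and naive_gc(seq) is None
            )


class TestProfile:
    def test_empty_stream(self):
        prof = compute_profile([], P, "s")
        assert (prof.n_total_reads, prof.n_telomeric_reads, prof.n_gc_matched_reads) == (0, 0, 0)
        assert prof.trpm is None

    def test_trpm_with_matched_background(self):
        telo = ["TTAGGG" * 8] * 10          # 48 bp, GC 0.5, 8 repeats
        background = ["ATGC" * 12] * 99_990  # GC exactly 0.5, no repeats
        prof = compute_profile(telo + background, P, "s")
        assert prof.n_telomeric_reads == 10
        assert prof.n_gc_matched_reads == 100_000  # telomeric reads stay in denominator
        assert prof.trpm == pytest.approx(10 / 100_000 * 1e6)

    def test_trpm_background_outside_window(self):
        telo = ["TTAGGG" * 8] * 10
        background = ["A" * 35 + "G" * 15] * 5_000  # GC 0.3, outside window
        prof = compute_profile(telo + background, P, "s")
        assert prof.n_gc_matched_reads == 10  # only telomeric reads in the window
        assert prof.trpm == pytest.approx(1e6)

    def test_order_invariance_and_duplication(self, rng):
        seqs = _random_seqs(rng, 300)
        prof = compute_profile(seqs, P, "s")
        shuffled = list(seqs)
        rng.shuffle(shuffled)
        prof2 = compute_profile(shuffled, P, "s")
        assert (prof.n_telomeric_reads, prof.n_gc_matched_reads) == (
            prof2.n_telomeric_reads,
            prof2.n_gc_matched_reads,
        )
        doubled = compute_profile(seqs + seqs, P, "s")
        if prof.trpm is not None:
            assert doubled.trpm == pytest.approx(prof.trpm)

    def test_monotonicity(self):
        base = ["TTAGGG" * 8] * 5 + ["ATGC" * 12] * 100
        prof = compute_profile(base, P, "s")
        # telomeric read with GC outside the window: numerator only
        telo_variant = "TCAGGG" * 8  # GC 4/6 = 0.667, outside the window
        assert is_telomeric(telo_variant, P)
        up = compute_profile(base + [telo_variant], P, "s")
        assert up.trpm > prof.trpm
        down = compute_profile(base + ["ATGC" * 12], P, "s")
        assert down.trpm < prof.trpm

    def test_matches_naive_profile(self, rng):
        seqs = _random_seqs(rng, 500)
        prof = compute_profile(seqs, P, "s")
        n, n_tel, n_gc, flags = naive_profile(
            seqs, DEFAULT_PATTERNS, P.repeat_threshold, P.gc_low, P.gc_high
        )
        assert (prof.n_total_reads, prof.n_telomeric_reads, prof.n_gc_matched_reads) == (
            n,
            n_tel,
            n_gc,
        )
        assert [is_telomeric(s, P) for s in seqs] == flags

    def test_terra_same_arithmetic(self, rng):
        seqs = _random_seqs(rng, 100)
        dna = compute_profile(seqs, P, "s")
        rna = compute_terra(seqs, P, "s")
        assert rna.source == "rna"
        assert rna.trpm == dna.trpm

    def test_profile_invariants_enforced(self):
        with pytest.raises(ValueError):
            TelomereProfile("s", 5, 6, 0)


class TestReadValidation:
    def test_alphabet(self):
        with pytest.raises(ValueError):
            Read("r", "ACGU")
        with pytest.raises(ValueError):
            Read("r", "")
        with pytest.raises(ValueError):
            Read("r", "ACGT", mate=3)

    def test_sanitize(self):
        assert sanitize_sequence("acgu-r") == "ACGNNN"


@given(st.integers(1, 20), st.integers(0, 5))
def test_tandem_repeat_count_property(n_repeats, pad):
    """n tandem copies with non-matching padding always count exactly n."""
    seq = "TTAGGG" * n_repeats + "A" * pad
    assert count_repeat_occurrences(seq, P) == n_repeats


class TestIO:
    def test_fastq_roundtrip(self, tmp_path, rng):
        reads = [Read(f"r{i}", s, mate=(i % 2) + 1) for i, s in enumerate(_random_seqs(rng, 50))]
        path = tmp_path / "reads.fastq"
        write_fastq(reads, path)
        back = list(read_fastq(path))
        assert [(r.read_id, r.sequence, r.mate) for r in back] == [
            (r.read_id, r.sequence, r.mate) for r in reads
        ]

    def test_sam_reader_filters_secondary(self, tmp_path):
        sam = tmp_path / "toy.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:unsorted\n"
            "@SQ\tSN:chr1\tLN:1000\n"
            "r1\t4\t*\t0\t0\t*\t*\t0\t0\tTTAGGGTTAGGG\t*\n"          # unmapped: kept
            "r2\t0\t chr1\t1\t60\t12M\t*\t0\t0\tACGTACGTACGT\tIIIIIIIIIIII\n".replace(" chr1", "chr1")
            + "r2\t256\tchr1\t100\t0\t12M\t*\t0\t0\tACGTACGTACGT\t*\n"  # secondary: dropped
            + "r3\t2048\tchr1\t200\t0\t12M\t*\t0\t0\tACGTACGTACGT\t*\n"  # supplementary: dropped
        )
        reads = list(read_sam(sam))
        assert [r.read_id for r in reads] == ["r1", "r2"]

    def test_profile_tsv_na(self, tmp_path):
        prof = TelomereProfile("s1", 10, 0, 0)
        out = tmp_path / "prof.tsv"
        write_profile_tsv([prof], out)
        lines = out.read_text().splitlines()
        assert lines[1].endswith("NA")
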