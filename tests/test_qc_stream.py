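import io

import numpy as np
import pytest

from medusa.model import Thresholds
from medusa.qc_stream import (
    AlignmentRecord,
    FastqRead,
    KmerSeedAligner,
    MalformedFastqError,
    PhredOffsetError,
    count_alignments,
    host_filter,
    quality_filter,
    read_fastq,
    read_sam_alignments,
    stream_align,
)
from medusa import synthdata as sd


def q(phred: int, n: int) -> str:
    return chr(phred + 33) * n


def fq(records):
    return "".join(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n" for r in records)


class TestQualityFilter:
    def test_all_q40_passes_any_threshold(self):
        reads = [FastqRead("r", "ACGT" * 10, q(40, 40))]
        gen, stats = quality_filter(reads, 30, 0.99)
        assert [r.id for r in gen] == ["r"]
        assert stats == {"n_input": 1, "n_pass": 1}

    def test_all_q2_fails_at_min20(self):
        gen, stats = quality_filter([FastqRead("r", "A" * 30, q(2, 30))], 20, 0.8)
        assert list(gen) == []
        assert stats["n_pass"] == 0

    @pytest.mark.parametrize("min_fraction,should_pass", [(0.8, True), (0.81, False)])
    def test_exact_fraction_boundary(self, min_fraction, should_pass):
        # 50 bp, exactly 40 bases at Q30 (>= Q20), 10 at Q10 (< Q20)
        reads = [
            FastqRead(f"r{i}", "A" * 50, q(30, 40) + q(10, 10)) for i in range(10)
        ]
        gen, stats = quality_filter(reads, 20, min_fraction)
        n = len(list(gen))
        assert (n == 10) is should_pass

    def test_quality_below_offset_raises_naming_offset(self):
        reads = [FastqRead("r", "AC", chr(30) + chr(40))]
        gen, _ = quality_filter(reads, 20, 0.8, phred_offset=33)
        with pytest.raises(PhredOffsetError, match="33"):
            list(gen)


def test_read_fastq_malformed_names_record_index(tmp_path):
    p = tmp_path / "bad.fq"
    p.write_text("@r0\nACGT\n+\nIIII\n@r1\nACGT\nIIII\n")  # missing '+' line
    with pytest.raises(MalformedFastqError, match="index 1"):
        list(read_fastq(p))


def test_read_fastq_from_non_seekable_stream():
    """The reader consumes a forward-only stream; no file needed."""
    raw = fq([FastqRead("a", "ACGT", "IIII"), FastqRead("b", "TTTT", "IIII")])

    class Forward(io.StringIO):
        def seek(self, *a):  # pragma: no cover - guard
            raise OSError("not seekable")

    out = list(read_fastq(Forward(raw)))
    assert [r.id for r in out] == ["a", "b"]


class TestHostFilter:
    def host(self, rng):
        return "".join(rng.choice(list("ACGT"), 500))

    def test_no_host_reads_planted(self, rng):
        aligner = KmerSeedAligner({"host": self.host(rng)})
        reads = [FastqRead(f"r{i}", "".join(rng.choice(list("ACGT"), 60)), q(38, 60)) for i in range(20)]
        gen, stats = host_filter(reads, aligner)
        assert len(list(gen)) == 20
        assert stats["n_host"] == 0

    def test_planted_host_reads_removed_exactly(self, rng):
        host = self.host(rng)
        aligner = KmerSeedAligner({"host": host})
        reads = [FastqRead(f"m{i}", "".join(rng.choice(list("ACGT"), 60)), q(38, 60)) for i in range(95)]
        reads += [FastqRead(f"h{i}", host[i * 7 : i * 7 + 60], q(38, 60)) for i in range(5)]
        gen, stats = host_filter(reads, aligner)
        survivors = list(gen)
        assert stats["n_host"] == 5
        assert all(r.id.startswith("m") for r in survivors)

    def test_empty_input(self, rng):
        gen, stats = host_filter([], KmerSeedAligner({"h": self.host(rng)}))
        assert list(gen) == [] and stats["n_host"] == 0


class TestCountAlignments:
    def test_unique_hits_counted_per_reference(self):
        recs = [
            AlignmentRecord("r1", "A", 10),
            AlignmentRecord("r2", "B", 10),
            AlignmentRecord("r3", "A", 10),
            AlignmentRecord("r4", None, 0),
        ]
        c = count_alignments(recs, reference_ids=["A", "B"])
        assert c.to_dict() == {"A": 2, "B": 1}

    def test_tie_break_deterministic_given_seed(self):
        recs = lambda: [
            AlignmentRecord("r1", "A", 5),
            AlignmentRecord("r1", "B", 5),
        ]
        first = count_alignments(recs(), seed=7).to_dict()
        assert count_alignments(recs(), seed=7).to_dict() == first
        assert sum(first.values()) == 1

    def test_many_ties_split_near_evenly(self):
        recs = []
        for i in range(1000):
            recs.append(AlignmentRecord(f"r{i}", "A", 3))
            recs.append(AlignmentRecord(f"r{i}", "B", 3))
        c = count_alignments(recs, seed=11, reference_ids=["A", "B"])
        assert c.sum() == 1000
        # binomial(1000, 0.5): P(outside [450, 550]) < 1e-3
        assert 450 <= c["A"] <= 550

    def test_ungrouped_stream_raises(self):
        recs = [
            AlignmentRecord("r1", "A", 1),
            AlignmentRecord("r2", "A", 1),
            AlignmentRecord("r1", "B", 1),
        ]
        with pytest.raises(ValueError, match="grouped"):
            count_alignments(recs)

    def test_fractional_policy_splits_best_hits(self):
        recs = [
            AlignmentRecord("r1", "A", 5),
            AlignmentRecord("r1", "B", 5),
            AlignmentRecord("r1", "C", 2),
        ]
        c = count_alignments(recs, policy="all-best-fractional", reference_ids=["A", "B", "C"])
        assert c["A"] == pytest.approx(0.5) and c["B"] == pytest.approx(0.5)
        assert c["C"] == 0


def test_sam_adapter_counts_mapped_and_unmapped(tmp_path):
    sam = tmp_path / "x.sam"
    sam.write_text(
        "@HD\tVN:1.6\tSO:queryname\n"
        "@SQ\tSN:refA\tLN:100\n"
        "@SQ\tSN:refB\tLN:100\n"
        "r1\t0\trefA\t1\t60\t10M\t*\t0\t0\tACGTACGTAC\tIIIIIIIIII\tAS:i:20\n"
        "r2\t0\trefA\t5\t60\t10M\t*\t0\t0\tACGTACGTAC\tIIIIIIIIII\tAS:i:18\n"
        "r2\t256\trefB\t5\t60\t10M\t*\t0\t0\tACGTACGTAC\tIIIIIIIIII\tAS:i:12\n"
        "r3\t4\t*\t0\t0\t*\t*\t0\t0\tACGTACGTAC\tIIIIIIIIII\n"
    )
    recs = list(read_sam_alignments(sam))
    assert recs[-1].reference_id is None
    c = count_alignments(recs, reference_ids=["refA", "refB"])
    assert c.to_dict() == {"refA": 2, "refB": 0}  # r2's best hit is refA


class TestStreamAlign:
    @pytest.fixture
    def refs(self):
        refs, _ = sd.make_references(n_species=5, n_genes_per_species=4, gene_len=300, seed=5)
        return refs

    def test_error_free_reads_all_align(self, refs, tmp_path):
        comp = {f"species{i:03d}": 0.2 for i in range(5)}
        path, _ = sd.simulate_run(
            refs, comp, n_reads=2000, sub_error_rate=0.0, host_fraction=0.0,
            frac_bad_reads=0.0, seed=3, out_path=tmp_path / "r1.fastq",
        )
        stats = stream_align([path], refs, refs, Thresholds(), tmp_path / "out", seed=1)
        s = stats[0]
        assert s.n_input == 2000
        assert s.n_pass_qc == 2000
        assert s.n_aligned_genomes == 2000  # exact substrings of the contigs

    def test_empty_fastq_gives_zero_counts(self, refs, tmp_path):
        p = tmp_path / "empty.fastq"
        p.write_text("")
        stats = stream_align([p], refs, refs, Thresholds(), tmp_path / "out", seed=1)
        assert stats[0].n_input == 0
        genes = (tmp_path / "out" / "empty.genes.counts.tsv").read_text()
        assert all(line.endswith("\t0") for line in genes.strip().splitlines()[1:])

    def test_same_seed_byte_identical_outputs(self, refs, tmp_path):
        comp = {f"species{i:03d}": 0.2 for i in range(5)}
        path, _ = sd.simulate_run(
            refs, comp, n_reads=500, seed=9, out_path=tmp_path / "r.fastq",
        )
        stream_align([path], refs, refs, Thresholds(), tmp_path / "a", seed=2)
        stream_align([path], refs, refs, Thresholds(), tmp_path / "b", seed=2)
        for name in ("r.genes.counts.tsv", "r.genomes.counts.tsv", "r.log"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_read_accounting_conserves_input(self, refs, tmp_path):
        comp = {f"species{i:03d}": 0.2 for i in range(5)}
        path, _ = sd.simulate_run(
            refs, comp, n_reads=3000, host_fraction=0.03, frac_bad_reads=0.1,
            seed=4, out_path=tmp_path / "r.fastq",
        )
        stats = stream_align(
            [path], refs, refs, Thresholds(), tmp_path / "out",
            host_reference=refs.subset("host"), seed=1,
        )[0]
        for aligned in (stats.n_aligned_genes, stats.n_aligned_genomes):
            unaligned = stats.n_clean - aligned
            assert stats.n_input == stats.n_fail_qc + stats.n_host + unaligned + aligned

    def test_truncated_input_removes_partial_outputs(self, refs, tmp_path):
        p = tmp_path / "trunc.fastq"
        p.write_text("@r0\nACGT\n+\nIIII\n@r1\nACGT\n")
        with pytest.raises(RuntimeError, match="trunc"):
            stream_align([p], refs, refs, Thresholds(), tmp_path / "out", seed=1)
        assert not list((tmp_path / "out").glob("trunc*"))
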