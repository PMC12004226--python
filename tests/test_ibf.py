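"""Interleaved Bloom filter: sizing, construction, queries, serialization."""
import math

import numpy as np
import pytest

import seqrex as sx
from seqrex import (Bitvector, ExactKmerIndex, IndexConfig,
                    InterleavedBloomFilter, build_index, size_from_fpr,
                    write_fasta)
from seqrex.alphabet import DNA, pack_kmers
from conftest import EXAMPLE1_BINS
from helpers import random_dna


class TestBitvector:
    def test_figure_notation_and_ops(self):
        a, b = Bitvector.from01("011"), Bitvector.from01("010")
        assert str(a & b) == "010" and str(a | b) == "011"
        assert a.count() == 2 and a.indices() == [1, 2]
        assert Bitvector.ones(3).value == 7 and not Bitvector.zeros(3).any()


class TestSizeFromFpr:
    def test_single_element_half_rate(self):
        # 1 - e^(-1/2) = 0.393 <= 0.5 but 1 - e^(-1) = 0.632 > 0.5
        assert size_from_fpr(1, 0.5, 1) == 2

    def test_matches_upward_scan(self):
        n, p, h = 1000, 0.05, 3
        m = 1
        while (1 - math.exp(-h * n / m)) ** h > p:
            m += 1
        assert size_from_fpr(n, p, h) == m

    def test_permissive_rate_needs_one_bit(self):
        # one inserted k-mer, one hash: fpr(1) = 1 - e^-1 = 0.632
        assert size_from_fpr(1, 0.999, 1) == 1

    def test_rejects_degenerate_rate(self):
        with pytest.raises(ValueError):
            size_from_fpr(10, 0.0, 2)
        with pytest.raises(ValueError):
            size_from_fpr(10, 1.0, 2)


def _write_bins(tmp_path, seqs):
    paths = []
    for j, seq in enumerate(seqs):
        p = tmp_path / f"b{j}.fa"
        write_fasta(p, [(f"r{j}", seq)])
        paths.append(str(p))
    return paths


class TestBuildIndex:
    def test_window_count_for_short_record(self, tmp_path):
        idx = build_index(_write_bins(tmp_path, ["ACGT"]),
                          IndexConfig(u=1, k=3))
        assert idx.per_bin_kmer_counts.tolist() == [2]
        assert str(idx.query_kmer("ACG")) == "1" and str(idx.query_kmer("CGT")) == "1"

    def test_worked_example_bin_three_kmers(self, tmp_path):
        idx = build_index(_write_bins(tmp_path, EXAMPLE1_BINS),
                          IndexConfig(u=4, k=3))
        assert idx.per_bin_kmer_counts.tolist() == [4, 7, 7, 4]
        for km in ("ACC", "CCA", "CAG", "AGG", "GGC", "GCT", "CTA"):
            assert idx.query_kmer(km).get(2), km

    def test_ambiguous_windows_skipped(self, tmp_path):
        with pytest.warns(UserWarning):
            idx = build_index(_write_bins(tmp_path, ["ACNGT"]),
                              IndexConfig(u=1, k=3))
        assert idx.per_bin_kmer_counts.tolist() == [0]

    def test_empty_bin_list_rejected(self):
        with pytest.raises(ValueError):
            build_index([], IndexConfig(u=1, k=3))

    def test_missing_file_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            build_index([str(tmp_path / "nope.fa")], IndexConfig(u=1, k=3))


class TestQueries:
    def test_exact_oracle_worked_example(self, example1_index):
        # CCA occurs in ACCCAAGCC, ACCAGGCTA (position 1) and AAGCCA
        assert str(example1_index.query_kmer("CCA")) == "0111"
        assert str(example1_index.query_kmer("GCT")) == "0010"
        assert str(example1_index.query_kmer("TGT")) == "0000"

    def test_no_false_negatives_across_random_corpora(self, rng, tmp_path):
        for trial in range(20):
            d = tmp_path / str(trial)
            d.mkdir()
            seqs = [random_dna(rng, 120) for _ in range(5)]
            idx = build_index(_write_bins(d, seqs),
                              IndexConfig(u=5, k=4, target_fpr=0.2))
            for j, seq in enumerate(seqs):
                for i in range(len(seq) - 3):
                    assert idx.query_kmer(seq[i:i + 4]).get(j)

    def test_bloom_agrees_with_exact_oracle_at_tiny_fpr(self, rng, tmp_path):
        seqs = [random_dna(rng, 400) for _ in range(6)]
        paths = _write_bins(tmp_path, seqs)
        ibf = build_index(paths, IndexConfig(u=6, k=5, target_fpr=1e-6))
        exact = ExactKmerIndex.from_bins(paths, 5)
        agree = total = 0
        for _ in range(2000):
            km = random_dna(rng, 5)
            total += ibf.u
            agree += sum(ibf.query_kmer(km).get(j) == exact.query_kmer(km).get(j)
                         for j in range(ibf.u))
        assert agree / total >= 0.9999

    def test_wrong_length_query_rejected(self, example1_index):
        with pytest.raises(sx.IndexMismatchError):
            example1_index.query_kmer("ACCT")

    def test_illegal_symbol_rejected(self, example1_index):
        with pytest.raises(sx.AlphabetError):
            example1_index.query_kmer("ACN")

    def test_batch_query_matches_scalar_path(self, rng, tmp_path):
        seqs = [random_dna(rng, 200) for _ in range(4)]
        ibf = build_index(_write_bins(tmp_path, seqs), IndexConfig(u=4, k=6))
        kmers = [random_dna(rng, 6) for _ in range(300)]
        packed = np.array([DNA.pack(km) for km in kmers], dtype=np.uint64)
        batch = ibf.query_packed_many(packed)
        for km, row in zip(kmers, batch):
            assert ibf.query_kmer(km) == Bitvector.from_bool(row)


class TestSerialization:
    def test_round_trip_preserves_queries(self, rng, tmp_path):
        seqs = [random_dna(rng, 300) for _ in range(5)]
        ibf = build_index(_write_bins(tmp_path, seqs), IndexConfig(u=5, k=6))
        path = tmp_path / "db.ibf"
        ibf.save(path)
        back = InterleavedBloomFilter.load(path)
        assert back.config == ibf.config
        assert back.bin_names == ibf.bin_names
        assert (back.bits == ibf.bits).all()
        for _ in range(1000):
            km = random_dna(rng, 6)
            assert back.query_kmer(km) == ibf.query_kmer(km)

    def test_truncated_file_rejected(self, tmp_path):
        ibf = build_index(_write_bins(tmp_path, ["ACGTACGTAC"]),
                          IndexConfig(u=1, k=4))
        path = tmp_path / "db.ibf"
        ibf.save(path)
        path.write_bytes(path.read_bytes()[:-10])
        with pytest.raises(sx.IndexFormatError):
            InterleavedBloomFilter.load(path)

    def test_not_an_index_file_rejected(self, tmp_path):
        path = tmp_path / "junk.ibf"
        path.write_bytes(b"definitely not an index")
        with pytest.raises(sx.IndexFormatError):
            InterleavedBloomFilter.load(path)

    def test_reloaded_index_enforces_its_k(self, rng, tmp_path):
        ibf = build_index(_write_bins(tmp_path, [random_dna(rng, 50)]),
                          IndexConfig(u=1, k=6))
        path = tmp_path / "db.ibf"
        ibf.save(path)
        back = InterleavedBloomFilter.load(path)
        with pytest.raises(sx.IndexMismatchError):
            back.query_kmer("ACGTA")


def test_packing_skips_windows_across_ambiguity():
    kmers = pack_kmers("ACNGTA", 3, DNA)
    assert [int(x) for x in kmers] == [DNA.pack("GTA")]
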