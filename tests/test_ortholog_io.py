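"""Gene alignment I/O, the single-copy/full-length filter, concatenation
and codon-position partitioning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codiverge.ortholog_io import (
    CodonAlignment,
    GeneAlignment,
    OrthologTable,
    concatenate,
    filter_single_copy_full_length,
    partition_by_codon_position,
    read_codon_alignment,
    read_gene_alignments,
    write_codon_alignment,
)
from codiverge.synthetic_data import preset_wri_like

from conftest import make_alignment


def _write_fasta(path, sequences):
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")


class TestReadGeneAlignments:
    def test_wellformed_files(self, tmp_path):
        _write_fasta(tmp_path / "g1.fasta", {"A": "ATG" * 100, "B": "ATG" * 100})
        _write_fasta(tmp_path / "g2.fasta", {"A": "GGA" * 150, "B": "GGC" * 150})
        genes = read_gene_alignments([tmp_path / "g1.fasta", tmp_path / "g2.fasta"])
        assert [g.length for g in genes] == [300, 450]
        assert all(g.in_frame for g in genes)

    def test_unequal_lengths_rejected(self, tmp_path):
        _write_fasta(tmp_path / "bad.fasta", {"A": "ATGATG", "B": "ATG"})
        with pytest.raises(ValueError, match="unequal"):
            read_gene_alignments([tmp_path / "bad.fasta"])

    def test_taxon_set_mismatch_rejected(self, tmp_path):
        _write_fasta(tmp_path / "g1.fasta", {"A": "ATG", "B": "ATG"})
        _write_fasta(tmp_path / "g2.fasta", {"A": "ATG", "C": "ATG"})
        with pytest.raises(ValueError, match="taxon set"):
            read_gene_alignments([tmp_path / "g1.fasta", tmp_path / "g2.fasta"])

    def test_out_of_frame_flagged_and_excluded(self, tmp_path):
        _write_fasta(tmp_path / "g1.fasta", {"A": "ATGA", "B": "ATGA"})
        _write_fasta(tmp_path / "g2.fasta", {"A": "ATGGGA", "B": "ATGGGA"})
        with pytest.warns(UserWarning, match="not divisible by 3"):
            genes = read_gene_alignments(
                [tmp_path / "g1.fasta", tmp_path / "g2.fasta"]
            )
        assert [g.in_frame for g in genes] == [False, True]
        aln = concatenate(genes)
        assert [gid for gid, *_ in aln.gene_spans] == ["g2"]

    def test_simulated_geneset_roundtrips(self, tmp_path):
        fx = preset_wri_like(total_bp=3_000, n_genes=5)
        genes, _ = fx.simulate(seed=5)
        aln = concatenate(genes)
        write_codon_alignment(aln, tmp_path / "cat.fasta", tmp_path / "cat.spans.tsv")
        back = read_codon_alignment(tmp_path / "cat.fasta", tmp_path / "cat.spans.tsv")
        assert back.matrix == aln.matrix
        assert back.gene_spans == aln.gene_spans


class TestSingleCopyFullLengthFilter:
    GENOMES = {"wA", "wB", "wC"}

    def test_direct_rule_application(self):
        rows = [
            # geneA: single copy everywhere, same length -> kept
            *[("geneA", g, 1, 900) for g in sorted(self.GENOMES)],
            # geneB: duplicated in one genome -> dropped
            ("geneB", "wA", 1, 600),
            ("geneB", "wB", 2, 600),
            ("geneB", "wC", 1, 600),
            # geneC: lengths differ -> dropped
            ("geneC", "wA", 1, 300),
            ("geneC", "wB", 1, 303),
            ("geneC", "wC", 1, 300),
        ]
        table = OrthologTable.from_records(rows)
        assert filter_single_copy_full_length(table, self.GENOMES) == {"geneA"}

    def test_missing_row_means_absent(self):
        table = OrthologTable.from_records(
            [("geneA", "wA", 1, 900), ("geneA", "wB", 1, 900)]
        )
        assert filter_single_copy_full_length(table, self.GENOMES) == set()

    def test_empty_table(self):
        table = OrthologTable.from_records([])
        table.frame = table.frame.astype(
            {"copy_count": int, "length": int}, errors="ignore"
        )
        assert filter_single_copy_full_length(table, self.GENOMES) == set()

    def test_all_compliant_returned(self):
        rows = [
            (f"gene{i}", g, 1, 300 + 3 * i)
            for i in range(5)
            for g in sorted(self.GENOMES)
        ]
        table = OrthologTable.from_records(rows)
        assert filter_single_copy_full_length(table, self.GENOMES) == {
            f"gene{i}" for i in range(5)
        }

    @given(
        copies=st.lists(
            st.tuples(st.integers(0, 3), st.integers(0, 3), st.integers(0, 3)),
            min_size=1,
            max_size=8,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_adding_a_genome_never_grows_the_set(self, copies):
        rows = []
        for i, (ca, cb, cc) in enumerate(copies):
            for genome, c in zip(("wA", "wB", "wC"), (ca, cb, cc)):
                if c:
                    rows.append((f"gene{i}", genome, c, 300))
        if not rows:
            return
        table = OrthologTable.from_records(rows)
        small = filter_single_copy_full_length(table, {"wA", "wB"})
        large = filter_single_copy_full_length(table, {"wA", "wB", "wC"})
        assert large <= small


class TestConcatenateAndPartition:
    def test_spans_and_length(self):
        g1 = GeneAlignment("g1", {"A": "ATG" * 100, "B": "ATG" * 100})
        g2 = GeneAlignment("g2", {"A": "GGA" * 150, "B": "GGC" * 150})
        aln = concatenate([g1, g2])
        assert aln.length == 750
        assert aln.gene_spans == [("g1", 0, 300), ("g2", 300, 750)]

    def test_empty_keep_gives_empty_alignment(self):
        g1 = GeneAlignment("g1", {"A": "ATG", "B": "ATG"})
        aln = concatenate([g1], keep=set())
        assert aln.length == 0
        assert aln.gene_spans == []

    def test_total_length_is_sum_of_fixture_lengths(self):
        fx = preset_wri_like(total_bp=21_000, n_genes=20)
        genes, _ = fx.simulate(seed=3)
        aln = concatenate(genes)
        assert aln.length == sum(g.length for g in genes) == sum(fx.gene_lengths)

    def test_partition_sizes(self):
        aln = make_alignment({"A": "A" * 750, "B": "A" * 750}, [300, 450])
        parts = partition_by_codon_position(aln)
        assert {p: len(idx) for p, idx in parts.items()} == {1: 250, 2: 250, 3: 250}

    def test_genome_scale_partition_is_exact_thirds(self):
        n = 704_883
        aln = make_alignment({"A": "A" * n})
        parts = partition_by_codon_position(aln)
        assert all(len(idx) == 234_961 for idx in parts.values())

    def test_frame_restarts_at_each_gene(self):
        aln = make_alignment({"A": "A" * 9, "B": "A" * 9}, [3, 6])
        pos = aln.position_index()
        # first site of the second gene is position 1 despite global offset 3
        assert pos[3] == 1
        assert list(pos) == [1, 2, 3, 1, 2, 3, 1, 2, 3]

    @given(lengths=st.lists(st.integers(1, 30).map(lambda k: 3 * k), min_size=1, max_size=6))
    @settings(max_examples=30, deadline=None)
    def test_partition_disjoint_and_complete(self, lengths):
        total = sum(lengths)
        aln = make_alignment({"A": "A" * total}, lengths)
        parts = partition_by_codon_position(aln)
        all_sites = np.concatenate(list(parts.values()))
        assert len(all_sites) == total
        assert len(np.unique(all_sites)) == total
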