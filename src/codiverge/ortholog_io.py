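"""Reading, filtering and concatenating per-gene coding alignments.

The unit of input is one aligned FASTA file per gene, all files sharing the
same taxon set.  Genes pass a single-copy/full-length filter driven by an
ortholog table (one row per gene x genome with a copy count and observed
length), are concatenated in input order, and every site of the concatenated
alignment is indexed by its codon position *within its own gene* -- the
reading frame restarts at 1 at each gene boundary, so concatenation can
never shift frames.

Coordinates are 0-based half-open internally; reports use 1-based inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = set("ACGTN-")

__all__ = [
    "GeneAlignment",
    "OrthologTable",
    "CodonAlignment",
    "read_gene_alignments",
    "filter_single_copy_full_length",
    "concatenate",
    "partition_by_codon_position",
    "write_codon_alignment",
    "read_codon_alignment",
]


@dataclass
class GeneAlignment:
    """A single gene's aligned nucleotide sequences, keyed by taxon."""

    gene_id: str
    sequences: dict[str, str]
    in_frame: bool = True

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(
                f"gene {self.gene_id!r}: sequences have unequal lengths {sorted(lengths)}"
            )
        bad = set("".join(self.sequences.values())) - ALPHABET
        if bad:
            raise ValueError(
                f"gene {self.gene_id!r}: disallowed characters {sorted(bad)}"
            )
        if self.length % 3 != 0:
            self.in_frame = False

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(sorted(self.sequences))


@dataclass
class OrthologTable:
    """Per (gene, genome) copy counts and observed lengths.

    A gene with no row for some genome is treated as absent (copy count 0)
    in that genome.
    """

    frame: pd.DataFrame

    REQUIRED = ("gene_id", "genome_id", "copy_count", "length")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"ortholog table missing columns {missing}")
        if self.frame.duplicated(["gene_id", "genome_id"]).any():
            raise ValueError("ortholog table has duplicate (gene, genome) rows")
        if (self.frame["copy_count"] < 0).any():
            raise ValueError("copy_count must be >= 0")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OrthologTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_records(
        cls, rows: Iterable[tuple[str, str, int, int]]
    ) -> "OrthologTable":
        return cls(pd.DataFrame(rows, columns=list(cls.REQUIRED)))


@dataclass
class CodonAlignment:
    """Concatenated in-frame alignment with gene spans and codon-position index."""

    taxa: tuple[str, ...]
    matrix: dict[str, str]
    gene_spans: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.taxa = tuple(self.taxa)
        total = sum(end - start for _, start, end in self.gene_spans)
        if total != self.length:
            raise ValueError(
                f"gene spans cover {total} sites but alignment has {self.length}"
            )
        for gid, start, end in self.gene_spans:
            if (end - start) % 3 != 0:
                raise ValueError(f"gene {gid!r} span length not divisible by 3")

    @property
    def length(self) -> int:
        return len(self.matrix[self.taxa[0]]) if self.taxa else 0

    def position_index(self) -> np.ndarray:
        """Codon position (1, 2 or 3) of every site, frame restarting per gene."""
        out = np.empty(self.length, dtype=np.int8)
        for _, start, end in self.gene_spans:
            out[start:end] = np.arange(end - start) % 3 + 1
        return out

    def to_codes(self, taxa: Sequence[str] | None = None) -> np.ndarray:
        """Encode sequences as uint8 (A=0, C=1, G=2, T=3, anything else 255)."""
        taxa = tuple(taxa) if taxa is not None else self.taxa
        lookup = np.full(128, 255, dtype=np.uint8)
        for base, code in zip("ACGT", range(4)):
            lookup[ord(base)] = code
        rows = []
        for t in taxa:
            if t not in self.matrix:
                raise KeyError(f"unknown taxon {t!r}")
            rows.append(lookup[np.frombuffer(self.matrix[t].encode(), dtype=np.uint8)])
        return np.vstack(rows) if rows else np.empty((0, 0), dtype=np.uint8)


def read_gene_alignments(paths: Sequence[str | Path]) -> list[GeneAlignment]:
    """Read one aligned FASTA per gene; taxon sets must agree across files.

    Genes whose alignment length is not a multiple of 3 are flagged
    (``in_frame=False``) with a warning and excluded by :func:`concatenate`.
    """
    alignments: list[GeneAlignment] = []
    taxon_set: set[str] | None = None
    for path in paths:
        path = Path(path)
        records = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
        if not records:
            raise ValueError(f"{path}: no sequences found")
        gene = GeneAlignment(gene_id=path.stem, sequences=records)
        if taxon_set is None:
            taxon_set = set(records)
        elif set(records) != taxon_set:
            raise ValueError(
                f"{path}: taxon set {sorted(records)} differs from {sorted(taxon_set)}"
            )
        if not gene.in_frame:
            warnings.warn(
                f"gene {gene.gene_id!r}: length {gene.length} not divisible by 3; "
                "flagged and excluded from concatenation",
                stacklevel=2,
            )
        alignments.append(gene)
    return alignments


def filter_single_copy_full_length(
    table: OrthologTable, genomes: Iterable[str]
) -> set[str]:
    """Genes with exactly one copy in every genome and identical lengths.

    A gene must have copy_count == 1 in each genome of ``genomes`` and the
    same observed length everywhere; missing rows count as absent.
    """
    genomes = set(genomes)
    df = table.frame[table.frame["genome_id"].isin(genomes)]
    kept: set[str] = set()
    for gene_id, sub in df.groupby("gene_id"):
        if set(sub["genome_id"]) != genomes:
            continue
        if (sub["copy_count"] == 1).all() and sub["length"].nunique() == 1:
            kept.add(str(gene_id))
    return kept


def concatenate(
    alignments: Sequence[GeneAlignment], keep: set[str] | None = None
) -> CodonAlignment:
    """Concatenate genes (in input order) into one CodonAlignment.

    ``keep`` restricts to a gene subset (e.g. the single-copy/full-length
    set); out-of-frame genes are always dropped.
    """
    chosen = [
        g
        for g in alignments
        if g.in_frame and (keep is None or g.gene_id in keep)
    ]
    if keep is not None:
        present = {g.gene_id for g in alignments if g.in_frame}
        missing = keep - present
        if missing:
            raise ValueError(f"kept genes not found in-frame: {sorted(missing)}")
    if not chosen:
        return CodonAlignment(taxa=(), matrix={}, gene_spans=[])
    taxa = chosen[0].taxa
    for g in chosen[1:]:
        if g.taxa != taxa:
            raise ValueError(
                f"gene {g.gene_id!r}: taxa {g.taxa} differ from {taxa}"
            )
    parts: dict[str, list[str]] = {t: [] for t in taxa}
    spans: list[tuple[str, int, int]] = []
    offset = 0
    for g in chosen:
        spans.append((g.gene_id, offset, offset + g.length))
        offset += g.length
        for t in taxa:
            parts[t].append(g.sequences[t])
    return CodonAlignment(
        taxa=taxa,
        matrix={t: "".join(parts[t]) for t in taxa},
        gene_spans=spans,
    )


def partition_by_codon_position(aln: CodonAlignment) -> dict[int, np.ndarray]:
    """Site indices of each codon position; disjoint, union covers everything."""
    pos = aln.position_index()
    return {p: np.flatnonzero(pos == p) for p in (1, 2, 3)}


def write_codon_alignment(
    aln: CodonAlignment, fasta_path: str | Path, spans_path: str | Path
) -> None:
    """Write the concatenated FASTA plus a gene-span TSV (1-based inclusive)."""
    records = [
        SeqRecord(Seq(aln.matrix[t]), id=t, description="") for t in aln.taxa
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    pd.DataFrame(
        [(gid, start + 1, end) for gid, start, end in aln.gene_spans],
        columns=["gene_id", "start", "end"],
    ).to_csv(spans_path, sep="\t", index=False)


def read_codon_alignment(
    fasta_path: str | Path, spans_path: str | Path
) -> CodonAlignment:
    records = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta_path), "fasta")}
    spans_df = pd.read_csv(spans_path, sep="\t")
    spans = [
        (str(r.gene_id), int(r.start) - 1, int(r.end))
        for r in spans_df.itertuples()
    ]
    return CodonAlignment(
        taxa=tuple(sorted(records)), matrix=records, gene_spans=spans
    )
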