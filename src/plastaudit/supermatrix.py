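"""Gene selection, supermatrix concatenation and alignment statistics.

A "variable site" is an alignment column holding at least two distinct
unambiguous bases (A/C/G/T) across rows; gaps, N and IUPAC ambiguity
letters are ignored by the variability test.  Missing data counts '-' and
'N' cells only.  Both choices are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
from Bio import SeqIO

__all__ = [
    "AlignmentStats",
    "GeneAlignment",
    "Supermatrix",
    "alignment_statistics",
    "concatenate",
    "select_genes",
    "write_partition_file",
]

log = logging.getLogger(__name__)

GAP = "-"


@dataclass
class GeneAlignment:
    """One gene's multiple alignment: equal-length rows keyed by sample."""

    gene_name: str
    sample_ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.rows):
            raise ValueError("sample_ids and rows length mismatch")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = {s for s in self.sample_ids if self.sample_ids.count(s) > 1}
            raise ValueError(f"duplicate samples in {self.gene_name}: {sorted(dupes)}")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError(f"{self.gene_name}: rows of unequal length {sorted(widths)}")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.sample_ids

    def row_for(self, sample_id: str) -> str:
        return self.rows[self.sample_ids.index(sample_id)]

    @classmethod
    def read_fasta(cls, path: str | Path, gene_name: str | None = None) -> "GeneAlignment":
        path = Path(path)
        records = list(SeqIO.parse(path, "fasta"))
        if not records:
            raise ValueError(f"{path}: empty FASTA")
        name = gene_name or path.name.rsplit(".", 1)[0]
        return cls(
            gene_name=name,
            sample_ids=[r.id for r in records],
            rows=[str(r.seq).upper() for r in records],
        )

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            for sample_id, row in zip(self.sample_ids, self.rows):
                handle.write(f">{sample_id}\n")
                for i in range(0, len(row), 70):
                    handle.write(row[i : i + 70] + "\n")


@dataclass
class Supermatrix:
    """Concatenated gene alignments with a 1-based inclusive partition table."""

    sample_ids: list[str]
    matrix_rows: list[str]
    partitions: list[tuple[str, int, int]]

    @property
    def width(self) -> int:
        return len(self.matrix_rows[0]) if self.matrix_rows else 0

    def write_fasta(self, path: str | Path) -> None:
        GeneAlignment(
            gene_name="supermatrix", sample_ids=self.sample_ids, rows=self.matrix_rows
        ).write_fasta(path)


@dataclass(frozen=True)
class AlignmentStats:
    length_bp: int
    n_variable_sites: int
    pct_variable: float
    pct_missing: float


def select_genes(presence: dict[str, float], threshold: float = 0.90) -> list[str]:
    """Genes present in at least ``threshold`` of samples, sorted by name.
    The boundary is inclusive."""
    for gene, fraction in presence.items():
        if not (0 <= fraction <= 1):
            raise ValueError(f"{gene}: presence fraction {fraction} outside [0,1]")
    return sorted(g for g, fraction in presence.items() if fraction >= threshold)


def concatenate(
    alignments: Sequence[GeneAlignment], sample_universe: Sequence[str]
) -> Supermatrix:
    """Concatenate gene alignments into one supermatrix.

    Rows follow ``sample_universe``; a sample missing from a gene alignment
    gets a gap block across that partition.  Alignment samples outside the
    universe are dropped with a warning.
    """
    if not alignments:
        raise ValueError("concatenate: empty alignment list")
    universe = list(sample_universe)
    if len(set(universe)) != len(universe):
        raise ValueError("sample_universe contains duplicates")

    partitions: list[tuple[str, int, int]] = []
    position = 0
    blocks: list[list[str]] = [[] for _ in universe]
    for alignment in alignments:
        extra = set(alignment.sample_ids) - set(universe)
        if extra:
            log.warning(
                "%s: %d samples outside the universe ignored", alignment.gene_name, len(extra)
            )
        width = alignment.width
        partitions.append((alignment.gene_name, position + 1, position + width))
        position += width
        for i, sample in enumerate(universe):
            if sample in alignment:
                blocks[i].append(alignment.row_for(sample))
            else:
                blocks[i].append(GAP * width)
    return Supermatrix(
        sample_ids=universe,
        matrix_rows=["".join(parts) for parts in blocks],
        partitions=partitions,
    )


def write_partition_file(matrix: Supermatrix, path: str | Path) -> None:
    """RAxML-style partition file: ``DNA, gene = start-end`` (1-based inclusive)."""
    with open(path, "w") as handle:
        for gene, start, end in matrix.partitions:
            handle.write(f"DNA, {gene} = {start}-{end}\n")


def alignment_statistics(
    matrix: Union[Supermatrix, GeneAlignment],
    *,
    missing_chars: str = "-N",
    unambiguous: str = "ACGT",
) -> AlignmentStats:
    """Length, variable-site count/percentage and missing-data percentage."""
    rows = matrix.matrix_rows if isinstance(matrix, Supermatrix) else matrix.rows
    if not rows or not rows[0]:
        raise ValueError("alignment_statistics: zero rows or columns")
    arr = np.frombuffer("".join(r.upper() for r in rows).encode("ascii"), dtype="S1")
    arr = arr.reshape(len(rows), len(rows[0]))
    n_rows, n_cols = arr.shape

    present = np.zeros(n_cols, dtype=np.int64)
    for base in unambiguous:
        present += (arr == base.encode()).any(axis=0)
    n_variable = int((present >= 2).sum())

    missing_mask = np.zeros(arr.shape, dtype=bool)
    for ch in missing_chars:
        missing_mask |= arr == ch.encode()
    n_missing = int(missing_mask.sum())

    return AlignmentStats(
        length_bp=n_cols,
        n_variable_sites=n_variable,
        pct_variable=100.0 * n_variable / n_cols,
        pct_missing=100.0 * n_missing / (n_rows * n_cols),
    )
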