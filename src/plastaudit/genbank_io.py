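"""GenBank flat-file input and per-gene FASTA output.

Parses annotated plastome records, resolves gene/CDS features (including
inverted-repeat duplicates and origin-spanning locations on circular
molecules) into strand-corrected gene observations, and writes per-gene
FASTA files.

Coordinates are 0-based half-open internally; the 1-based inclusive
GenBank convention is converted at the I/O boundary by Biopython.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq, UndefinedSequenceError

__all__ = [
    "DEFAULT_FEATURE_KINDS",
    "GenBankParseError",
    "GeneObservation",
    "PlastomeRecord",
    "extract_gene",
    "normalize_gene_name",
    "parse_plastome",
    "write_gene_fasta",
]

log = logging.getLogger(__name__)

DEFAULT_FEATURE_KINDS = frozenset({"gene", "CDS"})

#: When several annotation kinds describe the same gene, the first kind in
#: this tuple that is present wins.  CDS is preferred because it carries the
#: reading frame needed by the premature-stop test.
_KIND_PRIORITY = ("CDS", "gene")


class GenBankParseError(ValueError):
    """Raised when a GenBank flat file cannot be parsed into a plastome record."""


@dataclass(frozen=True)
class GeneObservation:
    """One annotated copy of one gene in one sample.

    ``segments`` are 0-based half-open intervals on the forward strand, in
    annotation order.  ``sequence`` is strand-corrected: for ``strand == '-'``
    it is the reverse complement of the concatenated forward-strand segments.
    ``copy_index`` (1-based) distinguishes inverted-repeat duplicates.
    """

    gene_name: str
    sample_id: str
    segments: tuple[tuple[int, int], ...]
    strand: str
    sequence: str
    copy_index: int = 1

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        seg_total = sum(e - s for s, e in self.segments)
        if seg_total != len(self.sequence):
            raise ValueError(
                f"{self.sample_id}/{self.gene_name}: segment total {seg_total} "
                f"!= sequence length {len(self.sequence)}"
            )
        if self.copy_index < 1:
            raise ValueError("copy_index must be >= 1")

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


@dataclass
class PlastomeRecord:
    """One sample's annotated plastome: identity, sequence and gene features."""

    sample_id: str
    taxon_name: str
    sequence: str
    is_circular: bool
    features: list[GeneObservation] = field(default_factory=list)

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    def gene_names(self) -> list[str]:
        """Distinct normalized gene names present, in first-seen order."""
        seen: dict[str, None] = {}
        for obs in self.features:
            seen.setdefault(obs.gene_name, None)
        return list(seen)


@lru_cache(maxsize=1)
def _synonym_table() -> dict[str, str]:
    """alias (casefolded) -> canonical gene name, from the shipped data file."""
    table: dict[str, str] = {}
    path = resources.files("plastaudit").joinpath("data/gene_synonyms.tsv")
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        alias, canonical = line.split("\t")
        table[" ".join(alias.casefold().split())] = canonical
        table.setdefault(canonical.casefold(), canonical)
    return table


def normalize_gene_name(raw: str) -> str:
    """Normalize a gene name case-insensitively to its canonical form.

    Unknown names are returned stripped but otherwise untouched, so
    non-focal genes still round-trip.  The synonym table is an editable
    TSV shipped with the package (``data/gene_synonyms.tsv``).
    """
    stripped = raw.strip()
    key = " ".join(stripped.casefold().split())
    return _synonym_table().get(key, stripped)


def _open_maybe_gzip(path: Path) -> IO[str]:
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _feature_gene_name(feature) -> str | None:
    for qualifier in ("gene", "standard_name", "product"):
        values = feature.qualifiers.get(qualifier)
        if values:
            return normalize_gene_name(values[0])
    return None


def parse_plastome(
    path: str | Path,
    feature_kinds: Iterable[str] = DEFAULT_FEATURE_KINDS,
) -> PlastomeRecord:
    """Parse a GenBank flat file (plain or gzipped) into a :class:`PlastomeRecord`.

    Every annotation of a kind in ``feature_kinds`` carrying a gene-name
    qualifier becomes a :class:`GeneObservation`.  When both ``gene`` and
    ``CDS`` annotations exist for the same gene, only the CDS features are
    kept (they carry the reading frame).  join/complement locations are
    resolved by Biopython; origin-spanning features on circular records
    arrive as two segments concatenated in annotation order.

    Raises
    ------
    GenBankParseError
        If the file holds no record or the record has no sequence section.
    """
    path = Path(path)
    kinds = frozenset(feature_kinds)
    with _open_maybe_gzip(path) as handle:
        try:
            record = next(SeqIO.parse(handle, "genbank"), None)
        except ValueError as exc:
            raise GenBankParseError(f"{path}: {exc}") from exc
    if record is None:
        raise GenBankParseError(f"{path}: no GenBank record found")
    try:
        sequence = str(record.seq).upper()
    except UndefinedSequenceError as exc:
        raise GenBankParseError(f"{path}: record has no sequence section") from exc
    if not sequence:
        raise GenBankParseError(f"{path}: record has an empty sequence")

    sample_id = record.id if record.id and record.id != "unknown" else None
    if sample_id is None:
        sample_id = record.name or path.name.removesuffix(".gz").rsplit(".", 1)[0]
    taxon = record.annotations.get("organism", "") or ""
    is_circular = record.annotations.get("topology", "") == "circular"

    # gene name -> kind -> raw features in annotation order
    by_gene: dict[str, dict[str, list]] = {}
    for feature in record.features:
        if feature.type not in kinds:
            continue
        name = _feature_gene_name(feature)
        if name is None:
            continue
        if feature.location is None:
            log.warning("%s: skipping %s %r with unresolvable location",
                        path.name, feature.type, name)
            continue
        by_gene.setdefault(name, {}).setdefault(feature.type, []).append(feature)

    observations: list[GeneObservation] = []
    for name, per_kind in by_gene.items():
        chosen = None
        for kind in _KIND_PRIORITY:
            if kind in per_kind:
                chosen = per_kind[kind]
                break
        if chosen is None:  # a kind outside the priority list
            chosen = next(iter(per_kind.values()))
        copy_index = 0
        for feature in chosen:
            try:
                segments = tuple(
                    (int(part.start), int(part.end)) for part in feature.location.parts
                )
                strand = "-" if feature.location.strand == -1 else "+"
                seq = str(feature.location.extract(Seq(sequence))).upper()
            except Exception:  # malformed location arithmetic
                log.warning("%s: skipping %s %r with unresolvable location",
                            path.name, feature.type, name)
                continue
            copy_index += 1
            observations.append(
                GeneObservation(
                    gene_name=name,
                    sample_id=sample_id,
                    segments=segments,
                    strand=strand,
                    sequence=seq,
                    copy_index=copy_index,
                )
            )

    n = len(sequence)
    for obs in observations:
        for start, end in obs.segments:
            if not (0 <= start < end <= n):
                raise GenBankParseError(
                    f"{path}: {obs.gene_name} segment ({start},{end}) outside [0,{n})"
                )

    return PlastomeRecord(
        sample_id=sample_id,
        taxon_name=taxon,
        sequence=sequence,
        is_circular=is_circular,
        features=observations,
    )


def extract_gene(record: PlastomeRecord, gene_name: str) -> list[GeneObservation]:
    """All observations of ``gene_name`` in ``record``, ordered by copy index.

    An empty list is a valid, meaningful result: absence feeds the "lost"
    state downstream.
    """
    target = normalize_gene_name(gene_name)
    hits = [obs for obs in record.features if obs.gene_name == target]
    return sorted(hits, key=lambda obs: obs.copy_index)


def _wrap(seq: str, width: int = 70) -> Iterator[str]:
    for i in range(0, len(seq), width):
        yield seq[i : i + width]


def write_gene_fasta(
    observations: Sequence[GeneObservation], path: str | Path
) -> None:
    """Write observations to FASTA, header ``sample_id|gene_name|copy_index``,
    sequence wrapped at 70 columns."""
    if not observations:
        raise ValueError("cannot write FASTA from an empty observation list")
    path = Path(path)
    with open(path, "w") as handle:
        for obs in observations:
            handle.write(f">{obs.sample_id}|{obs.gene_name}|{obs.copy_index}\n")
            for line in _wrap(obs.sequence):
                handle.write(line + "\n")
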