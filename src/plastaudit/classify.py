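"""Four-state gene classification and the sample x gene status matrix.

States: functional, truncated (internal stop codon), pseudogenized
(annotated length outside the 80-120% reference window) and lost (absent
or shorter than 20% of the reference).  Boundary semantics are strict:
a ratio of exactly 0.20 is not lost; exactly 0.80 or 1.20 is not
pseudogenized.  Comparisons are done in exact rational arithmetic so the
boundaries behave as stated regardless of float representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio.Data import CodonTable

from plastaudit.genbank_io import GeneObservation, PlastomeRecord, extract_gene
from plastaudit.reference_length import ReferenceLengthSet, Thresholds, _as_fraction

__all__ = [
    "STATES",
    "STATE_LETTERS",
    "GeneStatus",
    "StatusMatrix",
    "build_status_matrix",
    "classify_gene",
    "detect_premature_stop",
]

STATES = ("functional", "truncated", "pseudogenized", "lost")
STATE_LETTERS = {
    "functional": "F",
    "truncated": "T",
    "pseudogenized": "P",
    "lost": "L",
}
_LETTER_STATES = {v: k for k, v in STATE_LETTERS.items()}

#: plastid/bacterial genetic code
DEFAULT_TRANSLATION_TABLE = 11


def _stop_codons(translation_table: int) -> frozenset[str]:
    return frozenset(CodonTable.unambiguous_dna_by_id[translation_table].stop_codons)


def detect_premature_stop(
    cds: str, translation_table: int = DEFAULT_TRANSLATION_TABLE
) -> int | None:
    """1-based codon index of the first internal stop, or ``None``.

    Reads frame 0 from position 0; a trailing 1-2 nt remainder is ignored;
    the final complete codon is exempt (it is the legitimate terminator).
    """
    if len(cds) < 3:
        raise ValueError(f"CDS shorter than one codon ({len(cds)} nt)")
    stops = _stop_codons(translation_table)
    seq = cds.upper().replace("U", "T")
    n_codons = len(seq) // 3
    for i in range(n_codons - 1):
        if seq[3 * i : 3 * i + 3] in stops:
            return i + 1
    return None


@dataclass(frozen=True)
class GeneStatus:
    """Classification of one gene in one sample."""

    sample_id: str
    gene_name: str
    state: str
    observed_length_bp: int = 0
    length_ratio: float = 0.0
    premature_stop_codon_index: int | None = None

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.observed_length_bp < 0:
            raise ValueError("observed_length_bp must be >= 0")

    @property
    def letter(self) -> str:
        return STATE_LETTERS[self.state]


def classify_gene(
    observations: Sequence[GeneObservation],
    reference_length_bp: int,
    thresholds: Thresholds = Thresholds(),
    check_stops: bool = True,
    *,
    sample_id: str = "",
    gene_name: str = "",
    translation_table: int = DEFAULT_TRANSLATION_TABLE,
    truncation_scope: str = "any",
) -> GeneStatus:
    """Classify one gene in one sample from its annotated copies.

    The longest copy represents the sample (a sample with one intact and
    one decayed inverted-repeat copy plausibly retains function).
    Precedence: lost > truncated > pseudogenized > functional.

    ``truncation_scope`` controls where the stop-codon test applies:
    ``"any"`` (default) tests every non-lost copy, so an internal stop
    dominates a length violation; ``"pseudogenized_only"`` restricts
    truncation to copies already outside the length window.
    """
    if reference_length_bp <= 0:
        raise ValueError("reference_length_bp must be positive")
    if truncation_scope not in ("any", "pseudogenized_only"):
        raise ValueError(f"unknown truncation_scope {truncation_scope!r}")

    if observations:
        sample_id = sample_id or observations[0].sample_id
        gene_name = gene_name or observations[0].gene_name

    if not observations:
        return GeneStatus(sample_id=sample_id, gene_name=gene_name, state="lost")

    best = max(observations, key=lambda o: o.length_bp)
    ratio = Fraction(best.length_bp, reference_length_bp)
    stop_index = None
    if check_stops and best.length_bp >= 3:
        stop_index = detect_premature_stop(best.sequence, translation_table)

    lost_bound = _as_fraction(thresholds.lost_fraction)
    lower = _as_fraction(thresholds.pseudo_lower)
    upper = _as_fraction(thresholds.pseudo_upper)
    outside_window = ratio < lower or ratio > upper

    if ratio < lost_bound:
        state = "lost"
    elif stop_index is not None and (truncation_scope == "any" or outside_window):
        state = "truncated"
    elif outside_window:
        state = "pseudogenized"
    else:
        state = "functional"

    return GeneStatus(
        sample_id=sample_id,
        gene_name=gene_name,
        state=state,
        observed_length_bp=best.length_bp,
        length_ratio=float(ratio),
        premature_stop_codon_index=stop_index,
    )


@dataclass
class StatusMatrix:
    """samples x genes grid of :class:`GeneStatus`; exactly one cell per pair."""

    samples: list[str]
    genes: list[str]
    cells: dict[tuple[str, str], GeneStatus] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [
            (s, g) for s in self.samples for g in self.genes if (s, g) not in self.cells
        ]
        if missing:
            raise ValueError(f"status matrix has {len(missing)} empty cells: {missing[:3]}...")

    def state(self, sample: str, gene: str) -> str:
        return self.cells[(sample, gene)].state

    def to_wide_frame(self) -> pd.DataFrame:
        data = {
            gene: [self.cells[(s, gene)].letter for s in self.samples]
            for gene in self.genes
        }
        return pd.DataFrame(data, index=pd.Index(self.samples, name="sample"))

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for sample in self.samples:
            for gene in self.genes:
                cell = self.cells[(sample, gene)]
                rows.append(
                    {
                        "sample": sample,
                        "gene": gene,
                        "state": cell.state,
                        "observed_length_bp": cell.observed_length_bp,
                        "length_ratio": cell.length_ratio,
                        "premature_stop_codon_index": cell.premature_stop_codon_index,
                    }
                )
        return pd.DataFrame(rows)

    def state_counts(self) -> pd.DataFrame:
        """genes x states count table."""
        counts = pd.DataFrame(0, index=self.genes, columns=list(STATES))
        for (_, gene), cell in self.cells.items():
            counts.loc[gene, cell.state] += 1
        counts.index.name = "gene"
        return counts

    def write_tsv(self, path: str | Path) -> None:
        self.to_wide_frame().to_csv(path, sep="\t")

    def write_long_tsv(self, path: str | Path) -> None:
        self.to_long_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "StatusMatrix":
        """Read a wide state-letter TSV.  Only states survive the round
        trip; lengths, ratios and stop indices are not stored in the wide
        format and come back as zero/None."""
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        samples = [str(s) for s in frame.index]
        genes = [str(g) for g in frame.columns]
        cells = {}
        for sample in samples:
            for gene in genes:
                letter = frame.loc[sample, gene]
                cells[(sample, gene)] = GeneStatus(
                    sample_id=sample, gene_name=gene, state=_LETTER_STATES[letter]
                )
        return cls(samples=samples, genes=genes, cells=cells)


def build_status_matrix(
    cohort: Mapping[str, PlastomeRecord],
    genes: Sequence[str],
    refs: ReferenceLengthSet,
    thresholds: Thresholds = Thresholds(),
    check_stops: bool = True,
    *,
    truncation_scope: str = "any",
) -> StatusMatrix:
    """Classify every (sample, gene) pair; absence is state=lost, so the
    matrix has no empty cells."""
    for gene in genes:
        if gene not in refs:
            raise KeyError(f"no reference length for gene {gene!r}")
    samples = list(cohort)
    cells: dict[tuple[str, str], GeneStatus] = {}
    for sample_id, record in cohort.items():
        for gene in genes:
            observations = extract_gene(record, gene)
            cells[(sample_id, gene)] = classify_gene(
                observations,
                refs[gene].reference_length_bp,
                thresholds,
                check_stops,
                sample_id=sample_id,
                gene_name=gene,
                truncation_scope=truncation_scope,
            )
    return StatusMatrix(samples=samples, genes=list(genes), cells=cells)
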