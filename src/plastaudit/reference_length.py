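"""Per-gene reference length inference.

Two-stage rule: a length shared exactly by at least half of the annotated
samples is the reference (consensus path); otherwise a two-pass mean is
used, where the second pass drops samples deviating by >= 30% from the
first-pass mean.  All arithmetic is exact (rational); only the final
two-pass mean is rounded half-up to an integer.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

from plastaudit.genbank_io import GeneObservation, PlastomeRecord

__all__ = [
    "ReferenceLengthEntry",
    "ReferenceLengthSet",
    "Thresholds",
    "consensus_reference_length",
    "determine_reference_lengths",
    "two_pass_mean_reference_length",
]

log = logging.getLogger(__name__)


def _as_fraction(x: Union[float, int, Fraction]) -> Fraction:
    """Decimal-faithful conversion: 0.3 becomes 3/10, not its binary float."""
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    return Fraction(str(x))


@dataclass(frozen=True)
class Thresholds:
    """All tunable proportions of the audit, with their default readings.

    ``pseudo_lower``/``pseudo_upper`` bound the functional length window
    (strictly below/above -> pseudogenized), ``lost_fraction`` the loss
    cutoff (strictly below -> lost), ``consensus_fraction`` the exact-length
    consensus quorum, ``outlier_fraction`` the two-pass-mean exclusion bound
    (deviation >= bound excluded), and ``supermatrix_presence`` the
    gene-selection quorum for supermatrix construction.
    """

    consensus_fraction: float = 0.50
    outlier_fraction: float = 0.30
    pseudo_lower: float = 0.80
    pseudo_upper: float = 1.20
    lost_fraction: float = 0.20
    supermatrix_presence: float = 0.90

    def __post_init__(self) -> None:
        if not (0 < self.lost_fraction < self.pseudo_lower < 1 < self.pseudo_upper):
            raise ValueError(
                "require 0 < lost_fraction < pseudo_lower < 1 < pseudo_upper"
            )
        if not (0 < self.consensus_fraction <= 1):
            raise ValueError("consensus_fraction must be in (0, 1]")
        if not (0 < self.outlier_fraction < 1):
            raise ValueError("outlier_fraction must be in (0, 1)")
        if not (0 < self.supermatrix_presence <= 1):
            raise ValueError("supermatrix_presence must be in (0, 1]")


@dataclass(frozen=True)
class ReferenceLengthEntry:
    reference_length_bp: int
    method: str  # "consensus" | "two_pass_mean"
    n_samples_used: int
    n_excluded: int

    def __post_init__(self) -> None:
        if self.reference_length_bp <= 0:
            raise ValueError("reference_length_bp must be positive")
        if self.method not in ("consensus", "two_pass_mean"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass
class ReferenceLengthSet:
    """gene name -> reference length plus the method that produced it."""

    entries: dict[str, ReferenceLengthEntry] = field(default_factory=dict)

    def __contains__(self, gene: str) -> bool:
        return gene in self.entries

    def __getitem__(self, gene: str) -> ReferenceLengthEntry:
        return self.entries[gene]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> list[str]:
        return list(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene": gene,
                    "reference_length_bp": e.reference_length_bp,
                    "method": e.method,
                    "n_used": e.n_samples_used,
                    "n_excluded": e.n_excluded,
                }
                for gene, e in self.entries.items()
            ]
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ReferenceLengthSet":
        frame = pd.read_csv(path, sep="\t")
        entries = {
            row["gene"]: ReferenceLengthEntry(
                reference_length_bp=int(row["reference_length_bp"]),
                method=str(row["method"]),
                n_samples_used=int(row["n_used"]),
                n_excluded=int(row["n_excluded"]),
            )
            for _, row in frame.iterrows()
        }
        return cls(entries=entries)


def consensus_reference_length(
    lengths: Sequence[int], consensus_fraction: float = 0.50
) -> int | None:
    """Exact-length consensus: the value shared by >= ``consensus_fraction``
    of the inputs, or ``None`` when no value (or more than one, possible only
    at an exact tie) qualifies.
    """
    if not lengths:
        raise ValueError("consensus_reference_length: empty input")
    quorum = _as_fraction(consensus_fraction) * len(lengths)
    qualifying = [value for value, count in Counter(lengths).items() if count >= quorum]
    if len(qualifying) == 1:
        return qualifying[0]
    return None


def two_pass_mean_reference_length(
    lengths: Sequence[int], outlier_fraction: float = 0.30
) -> int:
    """Two-pass mean: drop values deviating >= ``outlier_fraction`` (relative)
    from the first-pass mean, re-average, round half-up.

    Raises if the input is empty or every value is excluded (pathological
    bimodal inputs only; any value equal to the first mean is always kept).
    """
    if not lengths:
        raise ValueError("two_pass_mean_reference_length: empty input")
    bound = _as_fraction(outlier_fraction)
    m1 = Fraction(sum(lengths), len(lengths))
    kept = [ell for ell in lengths if abs(ell - m1) / m1 < bound]
    if not kept:
        raise ValueError(
            f"two_pass_mean_reference_length: all {len(lengths)} values deviate "
            f">= {outlier_fraction} from the first-pass mean {float(m1):.2f}"
        )
    m2 = Fraction(sum(kept), len(kept))
    return int(m2 + Fraction(1, 2))  # floor(x + 1/2): round half-up


Cohort = Mapping[str, Union[PlastomeRecord, Sequence[GeneObservation]]]


def _sample_observations(sample) -> Iterable[GeneObservation]:
    if isinstance(sample, PlastomeRecord):
        return sample.features
    return sample


def cohort_gene_lengths(cohort: Cohort, gene: str) -> list[int]:
    """One length per sample that annotates ``gene``: the longest copy's.

    The longest-copy rule keeps decayed inverted-repeat fragments from
    dragging the mean down and mirrors the classification side.
    """
    lengths: list[int] = []
    for sample in cohort.values():
        copies = [o for o in _sample_observations(sample) if o.gene_name == gene]
        if copies:
            lengths.append(max(o.length_bp for o in copies))
    return lengths


def determine_reference_lengths(
    cohort: Cohort,
    genes: Sequence[str],
    thresholds: Thresholds = Thresholds(),
) -> ReferenceLengthSet:
    """Infer reference lengths for ``genes`` over ``cohort``.

    Per gene: consensus first, two-pass mean as fallback.  Only samples in
    which the gene is annotated contribute.  Genes annotated in zero samples
    are omitted with a logged warning.
    """
    if not cohort:
        raise ValueError("determine_reference_lengths: empty cohort")
    result = ReferenceLengthSet()
    for gene in genes:
        lengths = cohort_gene_lengths(cohort, gene)
        if not lengths:
            log.warning("gene %s annotated in zero samples; no reference entry", gene)
            continue
        consensus = consensus_reference_length(lengths, thresholds.consensus_fraction)
        if consensus is not None:
            entry = ReferenceLengthEntry(
                reference_length_bp=consensus,
                method="consensus",
                n_samples_used=len(lengths),
                n_excluded=0,
            )
        else:
            bound = _as_fraction(thresholds.outlier_fraction)
            m1 = Fraction(sum(lengths), len(lengths))
            kept = [ell for ell in lengths if abs(ell - m1) / m1 < bound]
            value = two_pass_mean_reference_length(lengths, thresholds.outlier_fraction)
            entry = ReferenceLengthEntry(
                reference_length_bp=value,
                method="two_pass_mean",
                n_samples_used=len(kept),
                n_excluded=len(lengths) - len(kept),
            )
        result.entries[gene] = entry
    return result
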