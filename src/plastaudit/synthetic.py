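"""Seeded generators: trees, annotated plastome cohorts with planted gene
states, and alignments with exact variable-site / missing-data counts.

The cohort generator targets the classifier's decision boundaries, not
biological realism: functional genes are stop-free ORFs of the true length,
truncated genes carry one substituted internal stop, pseudogenized genes
are stop-free copies at a fixed length fraction, lost genes are deleted
(or annotated sub-20% fragments).  Every planted fact is echoed in a
truth table so downstream recovery is exactly checkable.
"""

from __future__ import annotations

import dataclasses
import json
import random
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import pandas as pd
import yaml
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from plastaudit.classify import STATES, StatusMatrix
from plastaudit.reference_length import Thresholds, _as_fraction
from plastaudit.treemap import Phylogeny

__all__ = [
    "DolloViolationError",
    "ScenarioEntry",
    "SimulationConfig",
    "TruthRow",
    "TruthTable",
    "simulate_alignment",
    "simulate_cohort",
    "simulate_tree",
]

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
)

#: (tips, gene, state): apply ``state`` to ``gene`` in every listed tip.
#: A clade is expressed by listing its tip set.
ScenarioEntry = tuple[Union[str, tuple[str, ...]], str, str]


class DolloViolationError(ValueError):
    """A scenario re-assigns a lost gene to a non-lost state in a descendant."""


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to generate one cohort deterministically."""

    genes: tuple[tuple[str, int], ...]
    tree_seed: int = 0
    mutation_seed: int = 0
    state_scenario: tuple[ScenarioEntry, ...] = ()
    pseudo_length_factor: float = 0.5
    lost_fragment_factor: float = 0.1
    stop_position_fraction: float = 0.5
    background_substitution_rate: float = 0.0
    lost_mode: str = "delete"  # or "fragment"
    spacer_length: int = 120
    ir_duplicate_genes: tuple[str, ...] = ()
    origin_span_gene: str | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("config needs at least one gene")
        for name, length in self.genes:
            if length < 9 or length % 3:
                raise ValueError(f"{name}: true length must be a multiple of 3, >= 9")
        t = self.thresholds
        pseudo = _as_fraction(self.pseudo_length_factor)
        if not (
            _as_fraction(t.lost_fraction) < pseudo
            and (pseudo < _as_fraction(t.pseudo_lower) or pseudo > _as_fraction(t.pseudo_upper))
        ):
            raise ValueError(
                "pseudo_length_factor must lie outside the functional window and "
                "above the lost cutoff"
            )
        if not _as_fraction(self.lost_fragment_factor) < _as_fraction(t.lost_fraction):
            raise ValueError("lost_fragment_factor must be below the lost cutoff")
        if not (0 < self.stop_position_fraction < 1):
            raise ValueError("stop_position_fraction must be in (0, 1)")
        if self.lost_mode not in ("delete", "fragment"):
            raise ValueError(f"unknown lost_mode {self.lost_mode!r}")
        if not (0 <= self.background_substitution_rate < 1):
            raise ValueError("background_substitution_rate must be in [0, 1)")
        known = {name for name, _ in self.genes}
        for gene in self.ir_duplicate_genes:
            if gene not in known:
                raise ValueError(f"ir_duplicate_genes: unknown gene {gene!r}")
        if self.origin_span_gene is not None and self.origin_span_gene not in known:
            raise ValueError(f"origin_span_gene: unknown gene {self.origin_span_gene!r}")


@dataclass(frozen=True)
class TruthRow:
    sample_id: str
    gene_name: str
    planted_state: str
    planted_length_bp: int
    planted_stop_codon_index: int | None = None


@dataclass
class TruthTable:
    """One row per (sample, gene); the oracle for recovery tests."""

    rows: list[TruthRow] = field(default_factory=list)

    def state_of(self, sample_id: str, gene_name: str) -> str:
        for row in self.rows:
            if row.sample_id == sample_id and row.gene_name == gene_name:
                return row.planted_state
        raise KeyError((sample_id, gene_name))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self.rows])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TruthTable":
        frame = pd.read_csv(path, sep="\t")
        rows = [
            TruthRow(
                sample_id=str(r["sample_id"]),
                gene_name=str(r["gene_name"]),
                planted_state=str(r["planted_state"]),
                planted_length_bp=int(r["planted_length_bp"]),
                planted_stop_codon_index=(
                    None
                    if pd.isna(r["planted_stop_codon_index"])
                    else int(r["planted_stop_codon_index"])
                ),
            )
            for _, r in frame.iterrows()
        ]
        return cls(rows=rows)

    def mismatches(self, matrix: StatusMatrix) -> list[tuple[str, str, str, str]]:
        """(sample, gene, planted, observed) tuples where states disagree."""
        out = []
        for row in self.rows:
            observed = matrix.state(row.sample_id, row.gene_name)
            if observed != row.planted_state:
                out.append((row.sample_id, row.gene_name, row.planted_state, observed))
        return out


def simulate_tree(n_samples: int, seed: int) -> Phylogeny:
    """Random rooted bifurcating tree with exponential branch lengths.

    Identical seed gives a byte-identical Newick string.  Tips are labeled
    ``T001``..``Tnnn``.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    rnd = random.Random(seed)
    subtrees = [f"T{i:03d}" for i in range(1, n_samples + 1)]
    while len(subtrees) > 1:
        i, j = sorted(rnd.sample(range(len(subtrees)), 2))
        right = subtrees.pop(j)
        left = subtrees.pop(i)
        bl_left = rnd.expovariate(1.0)
        bl_right = rnd.expovariate(1.0)
        subtrees.append(f"({left}:{bl_left:.6f},{right}:{bl_right:.6f})")
    return Phylogeny.from_newick_string(subtrees[0] + ";")


def _resolve_states(
    tree: Phylogeny, config: SimulationConfig
) -> dict[str, dict[str, str]]:
    """tip -> gene -> state, default functional, scenario applied in order."""
    tips = tree.tip_names
    genes = [name for name, _ in config.genes]
    states = {tip: {gene: "functional" for gene in genes} for tip in tips}
    for entry in config.state_scenario:
        targets, gene, state = entry
        if isinstance(targets, str):
            targets = (targets,)
        if gene not in genes:
            raise ValueError(f"scenario names unknown gene {gene!r}")
        if state not in STATES:
            raise ValueError(f"scenario names unknown state {state!r}")
        for tip in targets:
            if tip not in states:
                raise ValueError(f"scenario names unknown tip {tip!r}")
            if states[tip][gene] == "lost" and state != "lost":
                raise DolloViolationError(
                    f"{tip}/{gene}: lost earlier in the scenario, cannot revert to "
                    f"{state!r} (losses are irreversible)"
                )
            states[tip][gene] = state
    return states


def _random_spacer(rnd: random.Random, length: int) -> str:
    return "".join(rnd.choice(_BASES) for _ in range(length))


def _stop_free_codons(rnd: random.Random, n_codons: int) -> list[str]:
    return ["ATG"] + [rnd.choice(_NONSTOP_CODONS) for _ in range(n_codons - 1)]


def _functional_orf(rnd: random.Random, length: int) -> str:
    n_codons = length // 3
    codons = _stop_free_codons(rnd, n_codons - 1) + ["TAA"]
    return "".join(codons)


def _truncated_orf(rnd: random.Random, length: int, stop_fraction: float) -> tuple[str, int]:
    n_codons = length // 3
    orf = list(_stop_free_codons(rnd, n_codons - 1) + ["TAA"])
    stop_index = int(stop_fraction * n_codons)  # 1-based codon position
    stop_index = min(max(stop_index, 2), n_codons - 1)
    orf[stop_index - 1] = "TAA"
    return "".join(orf), stop_index


def _decayed_copy(rnd: random.Random, target_length: int) -> str:
    """Stop-free (frame 0) copy of arbitrary length: codon prefix sliced."""
    n_codons = -(-target_length // 3)
    return "".join(_stop_free_codons(rnd, n_codons))[:target_length]


@dataclass
class _FeaturePlan:
    gene_name: str
    segments: list[tuple[int, int]]
    strand: int  # +1 / -1
    oriented_seq: str
    copy_index: int
    protect_frame: bool  # reject substitutions that change stop structure


def _rotate(sequence: str, plans: list[_FeaturePlan], offset: int) -> str:
    n = len(sequence)
    offset %= n
    if offset == 0:
        return sequence
    rotated = sequence[offset:] + sequence[:offset]
    for plan in plans:
        new_segments: list[tuple[int, int]] = []
        for start, end in plan.segments:
            new_start = (start - offset) % n
            new_end = new_start + (end - start)
            if new_end <= n:
                new_segments.append((new_start, new_end))
            else:
                new_segments.append((new_start, n))
                new_segments.append((0, new_end - n))
        plan.segments = new_segments
    return rotated


def _apply_background_substitutions(
    rnd: random.Random, genome: list[str], plans: list[_FeaturePlan], rate: float
) -> None:
    """In-place substitutions; in-gene changes that would create or destroy a
    frame-0 stop codon are rejected so planted states stay recoverable."""
    if rate <= 0:
        return
    starts = []
    spans = []  # (start, end, plan, gene_offset_of_start)
    for plan in plans:
        offset = 0
        for start, end in plan.segments:
            starts.append(start)
            spans.append((start, end, plan, offset))
            offset += end - start
    order = sorted(range(len(starts)), key=lambda k: starts[k])
    starts = [starts[k] for k in order]
    spans = [spans[k] for k in order]

    for pos in range(len(genome)):
        if rnd.random() >= rate:
            continue
        old = genome[pos]
        new = rnd.choice([b for b in _BASES if b != old])
        idx = bisect_right(starts, pos) - 1
        hit = None
        if idx >= 0:
            start, end, plan, seg_offset = spans[idx]
            if start <= pos < end:
                hit = (plan, seg_offset + (pos - start))
        if hit is None:
            genome[pos] = new
            continue
        plan, forward_offset = hit
        if plan.strand == 1:
            gene_offset = forward_offset
            oriented_new = new
        else:
            gene_offset = len(plan.oriented_seq) - 1 - forward_offset
            oriented_new = str(Seq(new).complement())
        codon_i = gene_offset // 3
        codon_start = 3 * codon_i
        codon = plan.oriented_seq[codon_start : codon_start + 3]
        if len(codon) == 3 and plan.protect_frame:
            mutated = (
                codon[: gene_offset - codon_start]
                + oriented_new
                + codon[gene_offset - codon_start + 1 :]
            )
            if (codon in _STOPS) != (mutated in _STOPS):
                continue  # rejected: would change stop-codon structure
        genome[pos] = new
        plan.oriented_seq = (
            plan.oriented_seq[:gene_offset] + oriented_new + plan.oriented_seq[gene_offset + 1 :]
        )


def _plan_to_feature(plan: _FeaturePlan, kind: str) -> SeqFeature:
    locations = [
        FeatureLocation(start, end, strand=plan.strand) for start, end in plan.segments
    ]
    location = locations[0] if len(locations) == 1 else CompoundLocation(locations)
    return SeqFeature(location, type=kind, qualifiers={"gene": [plan.gene_name]})


def simulate_cohort(
    tree: Phylogeny,
    config: SimulationConfig,
    out_dir: str | Path,
) -> tuple[list[Path], TruthTable]:
    """Write one annotated GenBank flat file per tree tip plus the Newick
    tree, the truth table TSV and a YAML echo of the config.

    Returns the GenBank paths (tip order) and the in-memory truth table.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    states = _resolve_states(tree, config)
    rnd = random.Random(config.mutation_seed)
    truth = TruthTable()
    paths: list[Path] = []

    for tip in tree.tip_names:
        parts: list[str] = []
        plans: list[_FeaturePlan] = []
        pos = 0

        def _append(text: str) -> None:
            nonlocal pos
            parts.append(text)
            pos += len(text)

        for gene_index, (gene, true_length) in enumerate(config.genes):
            _append(_random_spacer(rnd, config.spacer_length))
            state = states[tip][gene]
            stop_index: int | None = None
            if state == "functional":
                oriented = _functional_orf(rnd, true_length)
            elif state == "truncated":
                oriented, stop_index = _truncated_orf(
                    rnd, true_length, config.stop_position_fraction
                )
            elif state == "pseudogenized":
                target = round(config.pseudo_length_factor * true_length)
                oriented = _decayed_copy(rnd, target)
            elif config.lost_mode == "fragment":
                target = max(3, round(config.lost_fragment_factor * true_length))
                oriented = _decayed_copy(rnd, target)
            else:  # lost, deleted: no sequence, no annotation
                truth.rows.append(TruthRow(tip, gene, state, 0, None))
                continue

            strand = 1 if (gene_index % 2 == 0 or gene == config.origin_span_gene) else -1
            placed = oriented if strand == 1 else str(Seq(oriented).reverse_complement())
            plans.append(
                _FeaturePlan(
                    gene_name=gene,
                    segments=[(pos, pos + len(placed))],
                    strand=strand,
                    oriented_seq=oriented,
                    copy_index=1,
                    protect_frame=True,
                )
            )
            _append(placed)
            truth.rows.append(TruthRow(tip, gene, state, len(oriented), stop_index))

        # inverted-repeat-style duplicates: a second, identical copy on the
        # opposite strand near the end of the molecule
        for gene in config.ir_duplicate_genes:
            original = next((p for p in plans if p.gene_name == gene), None)
            if original is None:
                continue
            _append(_random_spacer(rnd, config.spacer_length))
            dup_strand = -original.strand
            placed = (
                original.oriented_seq
                if dup_strand == 1
                else str(Seq(original.oriented_seq).reverse_complement())
            )
            plans.append(
                _FeaturePlan(
                    gene_name=gene,
                    segments=[(pos, pos + len(placed))],
                    strand=dup_strand,
                    oriented_seq=original.oriented_seq,
                    copy_index=2,
                    protect_frame=True,
                )
            )
            _append(placed)
        _append(_random_spacer(rnd, config.spacer_length))

        genome = list("".join(parts))
        _apply_background_substitutions(
            rnd, genome, plans, config.background_substitution_rate
        )
        sequence = "".join(genome)

        if config.origin_span_gene is not None:
            span = next(
                (p for p in plans if p.gene_name == config.origin_span_gene), None
            )
            if span is not None:
                start, end = span.segments[0]
                sequence = _rotate(sequence, plans, start + (end - start) // 2)

        record = SeqRecord(
            Seq(sequence),
            id=tip,
            name=tip,
            description=f"synthetic circular plastome {tip}",
            annotations={
                "molecule_type": "DNA",
                "topology": "circular",
                "organism": f"Synthetica {tip.lower()}",
                "date": "01-JAN-2000",
            },
        )
        for plan in plans:
            record.features.append(_plan_to_feature(plan, "gene"))
            record.features.append(_plan_to_feature(plan, "CDS"))

        path = out_dir / f"{tip}.gb"
        with open(path, "w") as handle:
            SeqIO.write(record, handle, "genbank")
        paths.append(path)

    tree.write_newick(out_dir / "tree.nwk")
    truth.write_tsv(out_dir / "truth.tsv")
    echo = json.loads(json.dumps(dataclasses.asdict(config)))
    (out_dir / "config.yaml").write_text(yaml.safe_dump(echo, sort_keys=True))
    return paths, truth


def simulate_alignment(
    n_rows: int,
    n_cols: int,
    n_variable: int,
    pct_missing: float,
    seed: int,
):
    """Alignment with exactly ``n_variable`` variable columns and exactly
    ``floor(pct_missing * cells)`` gap cells; reproducible by seed.

    Two witness rows per variable column are kept gap-free so gaps can
    never erase variability; constant columns hold a single base so gaps
    can never create it.
    """
    from plastaudit.supermatrix import GeneAlignment

    if n_rows < 1 or n_cols < 1:
        raise ValueError("need at least one row and one column")
    if n_variable > n_cols:
        raise ValueError("n_variable cannot exceed n_cols")
    if n_variable > 0 and n_rows < 2:
        raise ValueError("variable columns need at least 2 rows")
    if not (0 <= pct_missing <= 1):
        raise ValueError("pct_missing must be in [0, 1]")
    n_cells = n_rows * n_cols
    n_gaps = int(pct_missing * n_cells)
    if n_gaps > n_cells - 2 * n_variable:
        raise ValueError(
            f"infeasible: {n_gaps} gaps requested but only "
            f"{n_cells - 2 * n_variable} unprotected cells exist"
        )

    rnd = random.Random(seed)
    variable_cols = set(rnd.sample(range(n_cols), n_variable))
    grid = [[""] * n_cols for _ in range(n_rows)]
    for col in range(n_cols):
        if col in variable_cols:
            b0, b1 = rnd.sample(_BASES, 2)
            for row in range(n_rows):
                grid[row][col] = rnd.choice((b0, b1))
            grid[0][col] = b0
            grid[1][col] = b1
        else:
            base = rnd.choice(_BASES)
            for row in range(n_rows):
                grid[row][col] = base

    protected = {(0, col) for col in variable_cols} | {(1, col) for col in variable_cols}
    candidates = [
        (row, col)
        for row in range(n_rows)
        for col in range(n_cols)
        if (row, col) not in protected
    ]
    for row, col in rnd.sample(candidates, n_gaps):
        grid[row][col] = "-"

    return GeneAlignment(
        gene_name="sim",
        sample_ids=[f"r{i + 1}" for i in range(n_rows)],
        rows=["".join(r) for r in grid],
    )
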