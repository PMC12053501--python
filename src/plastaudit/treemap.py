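"""Phylogeny I/O, parsimony loss counting, and the matrix-beside-tree figure.

Loss events are counted with generalized (Hartigan-style) Fitch parsimony:
at each internal node the states carried by the most children are kept and
every child not carrying one of them costs one change.  On bifurcating
trees this reduces to classic Fitch; on polytomies it remains exact.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence, Union

import dendropy
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Patch, Rectangle

from plastaudit.classify import STATES, StatusMatrix

__all__ = [
    "DEFAULT_PALETTE",
    "LossEventSummary",
    "NewickParseError",
    "Phylogeny",
    "fitch_min_transitions",
    "loss_summary",
    "n_genes_lost_at_least",
    "read_tree",
    "render_matrix_tree",
]

log = logging.getLogger(__name__)

DEFAULT_PALETTE = {
    "functional": "#2e7d32",
    "truncated": "#ef6c00",
    "pseudogenized": "#fdd835",
    "lost": "#b0b0b0",
}

#: tip-state binarizations for loss counting
ENCODINGS = {
    "lost_vs_retained": lambda state: "derived" if state == "lost" else "ancestral",
    "functional_vs_nonfunctional": lambda state: (
        "ancestral" if state == "functional" else "derived"
    ),
}


class NewickParseError(ValueError):
    """Raised when a Newick file cannot be parsed."""


@dataclass
class Phylogeny:
    """A rooted tree with named tips; thin wrapper around a dendropy tree."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        self.tree.is_rooted = True
        labels = self.tip_names
        if len(set(labels)) != len(labels):
            raise ValueError("tip names are not unique")

    @classmethod
    def from_newick_string(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:
            raise NewickParseError(f"malformed Newick: {exc}") from exc
        return cls(tree=tree)

    @property
    def tip_names(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    @property
    def n_internal(self) -> int:
        return sum(1 for n in self.tree.preorder_node_iter() if not n.is_leaf())

    def leaf_sets(self) -> list[frozenset[str]]:
        """Tip-label set of every internal node (clades), preorder."""
        sets = []
        for node in self.tree.preorder_node_iter():
            if not node.is_leaf():
                sets.append(
                    frozenset(leaf.taxon.label for leaf in node.leaf_iter())
                )
        return sets

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.as_newick() + "\n")

    def retain_tips(self, labels: Sequence[str]) -> "Phylogeny":
        """Subtree restricted to ``labels`` (unifurcations suppressed)."""
        sub = self.tree.extract_tree_with_taxa_labels(labels=list(labels))
        return Phylogeny(tree=sub)


def read_tree(path: str | Path) -> Phylogeny:
    """Read a rooted Newick tree (support values and branch lengths kept;
    polytomies permitted)."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise NewickParseError(f"{path}: empty file")
    try:
        return Phylogeny.from_newick_string(text)
    except NewickParseError as exc:
        raise NewickParseError(f"{path}: {exc}") from exc


def _as_dendropy(tree: Union[Phylogeny, dendropy.Tree]) -> dendropy.Tree:
    return tree.tree if isinstance(tree, Phylogeny) else tree


def fitch_min_transitions(
    tree: Union[Phylogeny, dendropy.Tree],
    tip_states: Mapping[str, str],
    *,
    root_state: str | None = None,
) -> int:
    """Minimum number of state changes on ``tree`` given ``tip_states``.

    Unordered, unweighted small parsimony over an arbitrary finite alphabet.
    ``root_state`` optionally adds a stem lineage fixed to that state (used
    for loss counting, where the ancestral state is presence): when the
    root's optimal state set lacks it, exactly one extra change is counted.
    This makes a character derived in every tip cost one event, not zero.
    """
    dtree = _as_dendropy(tree)
    changes = 0
    sets: dict[int, dict[str, int]] = {}  # node id -> state -> child votes (leaves: 1)
    root = dtree.seed_node
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon else None
            if label is None or label not in tip_states:
                raise ValueError(f"tip {label!r} has no assigned state")
            sets[id(node)] = {tip_states[label]: 1}
        else:
            children = node.child_nodes()
            votes: Counter[str] = Counter()
            for child in children:
                for state in sets[id(child)]:
                    votes[state] += 1
            best = max(votes.values())
            sets[id(node)] = {s: c for s, c in votes.items() if c == best}
            changes += len(children) - best
    if root_state is not None and root_state not in sets[id(root)]:
        changes += 1
    return changes


@dataclass(frozen=True)
class LossEventSummary:
    """Minimal independent loss count for one gene on one tree."""

    gene_name: str
    n_min_losses: int
    n_tips_lost_state: int
    encoding: str

    def __post_init__(self) -> None:
        if self.n_min_losses > self.n_tips_lost_state:
            raise ValueError("n_min_losses cannot exceed the number of lost tips")


def loss_summary(
    tree: Union[Phylogeny, dendropy.Tree],
    matrix: StatusMatrix,
    encoding: str = "lost_vs_retained",
) -> list[LossEventSummary]:
    """Per-gene minimal loss-transition counts on ``tree``.

    Tips absent from the matrix are pruned with a warning; matrix samples
    absent from the tree are dropped with a warning.  The root is anchored
    at the ancestral (retained) state so that losses covering the whole
    tree still count as one event.
    """
    if encoding not in ENCODINGS:
        raise ValueError(f"unknown encoding {encoding!r}; options: {sorted(ENCODINGS)}")
    binarize = ENCODINGS[encoding]
    phylo = tree if isinstance(tree, Phylogeny) else Phylogeny(tree=tree)
    tips = set(phylo.tip_names)
    samples = set(matrix.samples)
    overlap = tips & samples
    if not overlap:
        raise ValueError("no overlap between tree tips and matrix samples")
    if tips - overlap:
        log.warning("pruning %d tree tips absent from the matrix", len(tips - overlap))
        phylo = phylo.retain_tips(sorted(overlap))
    if samples - overlap:
        log.warning("%d matrix samples absent from the tree are ignored",
                    len(samples - overlap))

    summaries = []
    for gene in matrix.genes:
        tip_states = {s: binarize(matrix.state(s, gene)) for s in overlap}
        n_derived = sum(1 for v in tip_states.values() if v == "derived")
        n_min = fitch_min_transitions(phylo, tip_states, root_state="ancestral")
        summaries.append(
            LossEventSummary(
                gene_name=gene,
                n_min_losses=n_min,
                n_tips_lost_state=n_derived,
                encoding=encoding,
            )
        )
    return summaries


def n_genes_lost_at_least(summaries: Sequence[LossEventSummary], k: int = 2) -> int:
    """How many genes show at least ``k`` independent loss events."""
    return sum(1 for s in summaries if s.n_min_losses >= k)


def _layout(dtree: dendropy.Tree) -> tuple[dict, dict]:
    """x = root distance (unit lengths when missing), y = tip rank."""
    any_missing = any(
        e.length is None for e in dtree.preorder_edge_iter() if e.head_node is not dtree.seed_node
    )
    xs: dict[int, float] = {}
    ys: dict[int, float] = {}
    for node in dtree.preorder_node_iter():
        parent = node.parent_node
        length = 1.0 if (any_missing or node.edge.length is None) else float(node.edge.length)
        xs[id(node)] = 0.0 if parent is None else xs[id(parent)] + length
    rank = 0
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            ys[id(node)] = float(rank)
            rank += 1
        else:
            child_ys = [ys[id(c)] for c in node.child_nodes()]
            ys[id(node)] = sum(child_ys) / len(child_ys)
    return xs, ys


def render_matrix_tree(
    tree: Union[Phylogeny, dendropy.Tree],
    matrix: StatusMatrix,
    out: str | Path,
    palette: Mapping[str, str] | None = None,
    *,
    show_support: bool = True,
) -> tuple[Path, Path]:
    """Render the tree with a colored status grid beside the tips.

    Writes both SVG and PNG next to ``out`` (suffix replaced) and returns
    their paths.  Each grid cell carries an SVG gid ``cell_<sample>_<gene>``
    so figures are structurally checkable.
    """
    if not matrix.samples or not matrix.genes:
        raise ValueError("cannot render an empty status matrix")
    palette = dict(palette or DEFAULT_PALETTE)
    phylo = tree if isinstance(tree, Phylogeny) else Phylogeny(tree=tree)
    missing = set(matrix.samples) ^ set(phylo.tip_names)
    if set(phylo.tip_names) - set(matrix.samples):
        phylo = phylo.retain_tips([t for t in phylo.tip_names if t in set(matrix.samples)])
    if not set(phylo.tip_names):
        raise ValueError("no tree tips overlap the matrix samples")
    if missing:
        log.warning("tree/matrix name mismatch for %d entries", len(missing))

    dtree = phylo.tree
    xs, ys = _layout(dtree)
    n_tips = phylo.n_tips
    n_genes = len(matrix.genes)
    max_x = max(xs.values()) or 1.0

    fig_height = max(2.5, 0.28 * n_tips + 1.2)
    fig_width = max(6.0, 4.0 + 0.3 * n_genes)
    fig, (ax_tree, ax_grid) = plt.subplots(
        1, 2, figsize=(fig_width, fig_height),
        gridspec_kw={"width_ratios": [3, max(1, 0.25 * n_genes)]},
        sharey=True,
    )

    for node in dtree.preorder_node_iter():
        x, y = xs[id(node)], ys[id(node)]
        parent = node.parent_node
        if parent is not None:
            ax_tree.plot([xs[id(parent)], x], [y, y], color="black", lw=1.0)
        if not node.is_leaf():
            child_ys = [ys[id(c)] for c in node.child_nodes()]
            ax_tree.plot([x, x], [min(child_ys), max(child_ys)], color="black", lw=1.0)
            if show_support and node.label:
                ax_tree.annotate(
                    str(node.label), (x, y), textcoords="offset points",
                    xytext=(2, 3), fontsize=6,
                )
        else:
            ax_tree.annotate(
                node.taxon.label, (x, y), textcoords="offset points",
                xytext=(4, -2), fontsize=7,
            )
    ax_tree.set_xlim(-0.02 * max_x, 1.45 * max_x)
    ax_tree.invert_yaxis()
    ax_tree.axis("off")

    tip_y = {leaf.taxon.label: ys[id(leaf)] for leaf in dtree.leaf_node_iter()}
    for sample, y in tip_y.items():
        for j, gene in enumerate(matrix.genes):
            state = matrix.state(sample, gene)
            cell = Rectangle(
                (j, y - 0.4), 0.9, 0.8,
                facecolor=palette[state], edgecolor="white", lw=0.4,
            )
            cell.set_gid(f"cell_{sample}_{gene}")
            ax_grid.add_patch(cell)
    for j, gene in enumerate(matrix.genes):
        ax_grid.annotate(
            gene, (j + 0.45, -0.8), fontsize=7, rotation=90,
            ha="center", va="bottom", annotation_clip=False,
        )
    ax_grid.set_xlim(-0.2, n_genes + 0.2)
    ax_grid.axis("off")

    present_states = [s for s in STATES if any(
        c.state == s for c in matrix.cells.values()
    )]
    handles = [Patch(facecolor=palette[s], label=s) for s in present_states]
    fig.legend(handles=handles, loc="upper left", fontsize=7, frameon=False)

    out = Path(out)
    svg_path = out.with_suffix(".svg")
    png_path = out.with_suffix(".png")
    with plt.rc_context({"svg.fonttype": "none"}):  # keep text searchable
        fig.savefig(svg_path, bbox_inches="tight")
    fig.savefig(png_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return svg_path, png_path
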