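"""Shared test utilities: independent oracles and record builders."""

from __future__ import annotations

import itertools
import random
from pathlib import Path

from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from plastaudit.genbank_io import GeneObservation
from plastaudit.treemap import Phylogeny


def brute_force_min_changes(tree: Phylogeny, tip_states: dict[str, str]) -> int:
    """Exhaustive small-parsimony oracle: minimize edge mismatches over all
    internal-node labelings.  Only feasible for tiny trees."""
    dtree = tree.tree
    internals = [n for n in dtree.preorder_node_iter() if not n.is_leaf()]
    alphabet = sorted(set(tip_states.values()))
    nodes = list(dtree.preorder_node_iter())
    best = None
    for assignment in itertools.product(alphabet, repeat=len(internals)):
        labels = {id(n): s for n, s in zip(internals, assignment)}
        for leaf in dtree.leaf_node_iter():
            labels[id(leaf)] = tip_states[leaf.taxon.label]
        cost = sum(
            1
            for n in nodes
            if n.parent_node is not None and labels[id(n)] != labels[id(n.parent_node)]
        )
        best = cost if best is None else min(best, cost)
    return best


def random_multifurcating_newick(rnd: random.Random, labels: list[str]) -> str:
    """Random rooted tree allowing polytomies (fan-out 2-4)."""

    def build(group: list[str]) -> str:
        if len(group) == 1:
            return group[0]
        k = rnd.randint(2, min(4, len(group)))
        shuffled = group[:]
        rnd.shuffle(shuffled)
        cuts = sorted(rnd.sample(range(1, len(group)), k - 1))
        parts = [
            shuffled[a:b] for a, b in zip([0] + cuts, cuts + [len(group)])
        ]
        return "(" + ",".join(build(p) for p in parts) + ")"

    return build(labels) + ";"


def n_maximal_clades(tree: Phylogeny, tip_set: frozenset[str]) -> int:
    """Number of maximal clades (incl. single tips) fully inside ``tip_set``:
    the minimal number of irreversible-loss events explaining the set."""
    dtree = tree.tree
    leaf_sets = {}
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            leaf_sets[id(node)] = frozenset([node.taxon.label])
        else:
            leaf_sets[id(node)] = frozenset().union(
                *(leaf_sets[id(c)] for c in node.child_nodes())
            )
    count = 0
    for node in dtree.preorder_node_iter():
        inside = leaf_sets[id(node)] <= tip_set
        parent = node.parent_node
        parent_inside = parent is not None and leaf_sets[id(parent)] <= tip_set
        if inside and not parent_inside:
            count += 1
    return count


def disjoint_clades(
    tree: Phylogeny, k: int, min_size: int = 2
) -> list[frozenset[str]]:
    """k pairwise-disjoint proper clades that do not jointly cover the tree
    and whose union is not reducible to fewer clades (no sister merging)."""
    n = tree.n_tips
    candidates = sorted(
        (c for c in tree.leaf_sets() if min_size <= len(c) < n),
        key=len,
    )
    chosen: list[frozenset[str]] = []
    covered: frozenset[str] = frozenset()
    for clade in candidates:
        if clade & covered:
            continue
        union = covered | clade
        if len(union) >= n:  # keep at least one retained tip
            continue
        if n_maximal_clades(tree, union) != len(chosen) + 1:
            continue  # would merge with an already-chosen sister clade
        chosen.append(clade)
        covered = union
        if len(chosen) == k:
            return chosen
    raise AssertionError(f"could not find {k} disjoint clades on this tree")


def stop_free_sequence(length: int) -> str:
    """Frame-0 stop-free nucleotide string of exactly ``length``."""
    return ("ATG" + "AAA" * ((length + 2) // 3))[:length]


def make_observation(
    length: int,
    *,
    gene: str = "ndhX",
    sample: str = "S1",
    sequence: str | None = None,
    copy_index: int = 1,
) -> GeneObservation:
    seq = sequence if sequence is not None else stop_free_sequence(length)
    return GeneObservation(
        gene_name=gene,
        sample_id=sample,
        segments=((0, len(seq)),),
        strand="+",
        sequence=seq,
        copy_index=copy_index,
    )


def write_genbank(
    path: Path,
    sequence: str,
    features: list[tuple[str, int, int, int, str]],
    *,
    name: str = "TESTREC",
    circular: bool = True,
    locations: dict[int, object] | None = None,
) -> Path:
    """Write a small GenBank record.

    ``features``: (gene_name, start0, end0, strand, kind) tuples.
    ``locations`` optionally overrides the location of feature ``i`` with an
    arbitrary Biopython location object (for join/origin-spanning cases).
    """
    record = SeqRecord(
        Seq(sequence),
        id=name,
        name=name,
        description="hand-built test record",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if circular else "linear",
            "organism": "Testus organismus",
            "date": "01-JAN-2000",
        },
    )
    for i, (gene, start, end, strand, kind) in enumerate(features):
        location = (locations or {}).get(i) or FeatureLocation(start, end, strand=strand)
        record.features.append(
            SeqFeature(location, type=kind, qualifiers={"gene": [gene]})
        )
    with open(path, "w") as handle:
        SeqIO.write(record, handle, "genbank")
    return path
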