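import random

import pytest

from _helpers import (
    brute_force_min_changes,
    disjoint_clades,
    random_multifurcating_newick,
)
from plastaudit.classify import GeneStatus, StatusMatrix
from plastaudit.treemap import (
    LossEventSummary,
    NewickParseError,
    Phylogeny,
    fitch_min_transitions,
    loss_summary,
    n_genes_lost_at_least,
    read_tree,
    render_matrix_tree,
)
from plastaudit.synthetic import simulate_tree


class TestReadTree:
    def test_four_tip_tree(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("((A,B),(C,D));\n")
        tree = read_tree(path)
        assert sorted(tree.tip_names) == ["A", "B", "C", "D"]
        assert tree.n_tips == 4
        assert tree.n_internal == 3

    def test_support_values_stored(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("((A,B)95,(C,D)100);\n")
        tree = read_tree(path)
        labels = {
            n.label
            for n in tree.tree.preorder_node_iter()
            if not n.is_leaf() and n.label
        }
        assert labels == {"95", "100"}

    def test_empty_file_raises(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("")
        with pytest.raises(NewickParseError):
            read_tree(path)

    def test_malformed_raises(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("((A,B),(C,D);")
        with pytest.raises(NewickParseError):
            read_tree(path)

    def test_polytomy_permitted(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("(A,B,C,D);\n")
        tree = read_tree(path)
        assert tree.n_tips == 4
        assert tree.n_internal == 1

    def test_duplicate_tips_rejected(self):
        with pytest.raises(ValueError):
            Phylogeny.from_newick_string("((A,A),B);")


class TestFitchMinTransitions:
    def _tree(self, newick):
        return Phylogeny.from_newick_string(newick)

    def test_single_clade_loss(self):
        tree = self._tree("((A,B),(C,D));")
        states = {"A": "lost", "B": "lost", "C": "retained", "D": "retained"}
        assert fitch_min_transitions(tree, states) == 1

    def test_scattered_losses(self):
        tree = self._tree("((A,B),(C,D));")
        states = {"A": "lost", "B": "retained", "C": "lost", "D": "retained"}
        assert fitch_min_transitions(tree, states) == 2
        assert brute_force_min_changes(tree, states) == 2

    def test_no_change(self):
        tree = self._tree("((A,B),(C,D));")
        states = dict.fromkeys("ABCD", "retained")
        assert fitch_min_transitions(tree, states) == 0

    def test_missing_tip_state_raises(self):
        tree = self._tree("((A,B),(C,D));")
        with pytest.raises(ValueError):
            fitch_min_transitions(tree, {"A": "x", "B": "x", "C": "x"})

    def test_root_anchoring_counts_global_loss_once(self):
        tree = self._tree("((A,B),(C,D));")
        all_lost = dict.fromkeys("ABCD", "derived")
        assert fitch_min_transitions(tree, all_lost) == 0
        assert fitch_min_transitions(tree, all_lost, root_state="ancestral") == 1

    def test_root_anchoring_no_cost_when_compatible(self):
        tree = self._tree("((A,B),(C,D));")
        states = {"A": "derived", "B": "derived", "C": "ancestral", "D": "ancestral"}
        assert fitch_min_transitions(tree, states, root_state="ancestral") == 1

    def test_multistate_alphabet(self):
        tree = self._tree("((A,B),(C,D));")
        states = {"A": "x", "B": "y", "C": "z", "D": "z"}
        assert fitch_min_transitions(tree, states) == brute_force_min_changes(tree, states)

    def test_oracle_equivalence_including_polytomies(self):
        rnd = random.Random(99)
        for _ in range(60):
            n = rnd.randint(3, 8)
            labels = [f"L{i}" for i in range(n)]
            tree = Phylogeny.from_newick_string(
                random_multifurcating_newick(rnd, labels)
            )
            states = {t: rnd.choice("ab") for t in labels}
            assert fitch_min_transitions(tree, states) == brute_force_min_changes(
                tree, states
            )

    def test_pruning_ancestral_tips_never_increases(self):
        rnd = random.Random(7)
        for _ in range(25):
            tree = simulate_tree(rnd.randint(4, 9), seed=rnd.randint(0, 999))
            tips = tree.tip_names
            states = {t: rnd.choice(["ancestral", "derived"]) for t in tips}
            full = fitch_min_transitions(tree, states, root_state="ancestral")
            keep = [t for t in tips if states[t] == "derived"] + [
                t for t in tips if states[t] == "ancestral"
            ][:1]
            keep = keep or tips[:2]
            if len(keep) < 2:
                continue
            pruned = tree.retain_tips(keep)
            sub = fitch_min_transitions(
                pruned, {t: states[t] for t in keep}, root_state="ancestral"
            )
            assert sub <= full


def _matrix(states_by_sample, genes):
    samples = list(states_by_sample)
    cells = {}
    for sample, per_gene in states_by_sample.items():
        for gene in genes:
            state = per_gene[gene]
            cells[(sample, gene)] = GeneStatus(
                sample_id=sample,
                gene_name=gene,
                state=state,
                observed_length_bp=0 if state == "lost" else 100,
                length_ratio=0.0 if state == "lost" else 1.0,
            )
    return StatusMatrix(samples=samples, genes=genes, cells=cells)


class TestLossSummary:
    def test_two_disjoint_clades(self):
        tree = Phylogeny.from_newick_string("(((A,B),(C,D)),((E,F),(G,H)));")
        states = {
            s: {"ndhF": "lost" if s in "ABEF" else "functional"} for s in "ABCDEFGH"
        }
        (summary,) = loss_summary(tree, _matrix(states, ["ndhF"]))
        assert summary.n_min_losses == 2
        assert summary.n_tips_lost_state == 4

    def test_retained_everywhere(self):
        tree = Phylogeny.from_newick_string("((A,B),(C,D));")
        states = {s: {"g": "functional"} for s in "ABCD"}
        (summary,) = loss_summary(tree, _matrix(states, ["g"]))
        assert summary.n_min_losses == 0

    def test_single_tip_loss(self):
        tree = Phylogeny.from_newick_string("((A,B),(C,D));")
        states = {s: {"g": "lost" if s == "A" else "functional"} for s in "ABCD"}
        (summary,) = loss_summary(tree, _matrix(states, ["g"]))
        assert summary.n_min_losses == 1

    def test_pseudogenized_counts_as_retained_by_default(self):
        tree = Phylogeny.from_newick_string("((A,B),(C,D));")
        states = {s: {"g": "pseudogenized"} for s in "ABCD"}
        (summary,) = loss_summary(tree, _matrix(states, ["g"]))
        assert summary.n_min_losses == 0

    def test_functional_vs_nonfunctional_encoding(self):
        tree = Phylogeny.from_newick_string("((A,B),(C,D));")
        states = {s: {"g": "pseudogenized"} for s in "ABCD"}
        (summary,) = loss_summary(
            tree, _matrix(states, ["g"]), encoding="functional_vs_nonfunctional"
        )
        assert summary.n_min_losses == 1

    def test_zero_overlap_raises(self):
        tree = Phylogeny.from_newick_string("((A,B),(C,D));")
        states = {s: {"g": "functional"} for s in "WXYZ"}
        with pytest.raises(ValueError):
            loss_summary(tree, _matrix(states, ["g"]))

    def test_extra_tips_pruned(self):
        tree = Phylogeny.from_newick_string("(((A,B),(C,D)),E);")
        states = {s: {"g": "lost" if s in "AB" else "functional"} for s in "ABCD"}
        (summary,) = loss_summary(tree, _matrix(states, ["g"]))
        assert summary.n_min_losses == 1

    def test_unknown_encoding_raises(self):
        tree = Phylogeny.from_newick_string("((A,B),(C,D));")
        states = {s: {"g": "functional"} for s in "ABCD"}
        with pytest.raises(ValueError):
            loss_summary(tree, _matrix(states, ["g"]), encoding="whatever")

    def test_aggregate_counter(self):
        summaries = [
            LossEventSummary("g1", 2, 4, "lost_vs_retained"),
            LossEventSummary("g2", 0, 0, "lost_vs_retained"),
            LossEventSummary("g3", 3, 5, "lost_vs_retained"),
        ]
        assert n_genes_lost_at_least(summaries, 2) == 2

    def test_dollo_planted_clades(self):
        tree = simulate_tree(16, seed=5)
        clades = disjoint_clades(tree, 3)
        lost_tips = set().union(*clades)
        states = {
            t: {"g": "lost" if t in lost_tips else "functional"}
            for t in tree.tip_names
        }
        (summary,) = loss_summary(tree, _matrix(states, ["g"]))
        assert summary.n_min_losses == 3


class TestRenderMatrixTree:
    def _setup(self):
        tree = Phylogeny.from_newick_string("((A:1,B:1)90:1,(C:1,D:1)85:1);")
        genes = [f"g{i}" for i in range(11)]
        base = {g: "functional" for g in genes}
        states = {
            "A": {**base, "g0": "lost"},
            "B": {**base, "g1": "truncated"},
            "C": {**base, "g2": "pseudogenized"},
            "D": dict(base),
        }
        return tree, _matrix(states, genes)

    def test_svg_has_one_cell_per_sample_gene(self, tmp_path):
        tree, matrix = self._setup()
        svg_path, png_path = render_matrix_tree(tree, matrix, tmp_path / "fig.svg")
        assert svg_path.exists() and png_path.exists()
        svg = svg_path.read_text()
        assert svg.count('id="cell_') == 4 * 11

    def test_legend_lists_all_present_states(self, tmp_path):
        tree, matrix = self._setup()
        svg_path, _ = render_matrix_tree(tree, matrix, tmp_path / "fig.svg")
        svg = svg_path.read_text()
        for state in ("functional", "truncated", "pseudogenized", "lost"):
            assert state in svg

    def test_empty_matrix_raises(self, tmp_path):
        tree, _ = self._setup()
        with pytest.raises(ValueError):
            render_matrix_tree(
                tree,
                StatusMatrix(samples=[], genes=[], cells={}),
                tmp_path / "fig.svg",
            )
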