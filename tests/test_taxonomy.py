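"""Monophyly evaluation, support thresholds and species delimitation."""

import itertools

import dendropy
import networkx as nx
import numpy as np
import pytest

from gyrits.distances import DistanceMatrix
from gyrits.models import SubstitutionModel
from gyrits.synthetic_data import simulate_alignment_on_tree
from gyrits.taxonomy import (TreeView, delimit_species, evaluate_groups,
                             is_monophyletic, lineage_report,
                             parse_support_label)


def random_tree(tips, rng):
    """Random topology with unit branch lengths over the given tip labels."""
    taxa = dendropy.TaxonNamespace(tips)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, taxon_namespace=taxa,
        num_extant_tips=len(tips), rng=rng)
    for e in tree.edges():
        e.length = 1.0
    return tree


def brute_force_monophyly(tree, tipset):
    """Enumerate every edge bipartition and compare leafsets directly."""
    all_tips = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    tipset = frozenset(tipset)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if clade == tipset or clade == all_tips - tipset:
            return True
    return False


class TestSupportParsing:
    @pytest.mark.parametrize("label,bp,pp", [
        ("99/1.0", 99.0, 1.0),
        ("75/0.95", 75.0, 0.95),
        ("87", 87.0, None),
        ("0.98", None, 0.98),
        (None, None, None),
        ("", None, None),
    ])
    def test_labels(self, label, bp, pp):
        assert parse_support_label(label) == (bp, pp)

    def test_forced_format(self):
        assert parse_support_label("1", "bp") == (1.0, None)
        assert parse_support_label("1", "pp") == (None, 1.0)


class TestMonophyly:
    def test_simple_quartet(self):
        tv = TreeView.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        assert is_monophyletic(tv, {"a", "b"})[0]
        assert not is_monophyletic(tv, {"a", "c"})[0]

    def test_unknown_tips_error(self):
        tv = TreeView.from_newick("((a:1,b:1):1,c:1);")
        with pytest.raises(ValueError):
            is_monophyletic(tv, {"a", "zzz"})

    def test_agrees_with_bipartition_enumeration(self):
        """Random 8-tip trees, all 2-4-tip subsets, vs exhaustive oracle."""
        import random
        rng = random.Random(404)
        tips = [f"t{i}" for i in range(8)]
        for _ in range(30):
            tree = random_tree(tips, rng)
            tv = TreeView(tree)
            for k in (2, 3, 4):
                for subset in itertools.combinations(tips, k):
                    expected = brute_force_monophyly(tree, subset)
                    assert is_monophyletic(tv, set(subset))[0] == expected

    def test_invariant_under_rerooting(self):
        import random
        rng = random.Random(77)
        tips = [f"t{i}" for i in range(8)]
        tree = random_tree(tips, rng)
        subsets = [set(s) for s in itertools.combinations(tips, 3)]
        reference = [is_monophyletic(TreeView(tree), s)[0] for s in subsets]
        for target in list(tree.leaf_node_iter())[:4]:
            clone = tree.clone(depth=1)
            leaf = clone.find_node_with_taxon_label(target.taxon.label)
            clone.reroot_at_edge(leaf.edge, update_bipartitions=False)
            rerooted = TreeView(clone)
            assert [is_monophyletic(rerooted, s)[0] for s in subsets] == reference


class TestEvaluateGroups:
    def test_true_clades_from_simulated_tree(self, jc):
        """Groups built as clades of the generating tree come back monophyletic."""
        nwk = ("(((a1:0.02,a2:0.02):0.5,(a3:0.02,a4:0.02):0.5):0.5,"
               "((b1:0.02,b2:0.02):0.5,(b3:0.02,b4:0.02):0.5):0.5);")
        _, tree = simulate_alignment_on_tree(nwk, [("P", 200, jc)], seed=8)
        tv = TreeView(tree)
        groups = {f"a{i}": "A" for i in range(1, 5)}
        groups.update({f"b{i}": "B" for i in range(1, 5)})
        results = {r.group: r for r in evaluate_groups(tv, groups)}
        assert results["A"].status == "monophyletic"
        assert results["B"].status == "monophyletic"

    def test_support_thresholds(self):
        tv = TreeView.from_newick("((a:1,b:1)99/1.0:1,((c:1,d:1)60/0.9:1,e:1):1);")
        groups = {"a": "G1", "b": "G1", "c": "G2", "d": "G2", "e": "G3"}
        res = {r.group: r for r in evaluate_groups(tv, groups)}
        assert res["G1"].well_supported and res["G1"].bp == 99
        assert res["G2"].status == "monophyletic" and not res["G2"].well_supported
        assert res["G3"].status == "singleton"

    def test_whole_tree_group_is_uninformative(self):
        tv = TreeView.from_newick("((a:1,b:1):1,c:1);")
        res = evaluate_groups(tv, {"a": "G", "b": "G", "c": "G"})
        assert res[0].status == "monophyletic" and res[0].uninformative

    def test_split_group_reports_offending_tips(self):
        tv = TreeView.from_newick("((a:1,c:1):1,(b:1,d:1):1);")
        res = {r.group: r for r in evaluate_groups(
            tv, {"a": "G", "b": "G", "c": "X", "d": "Y"})}
        assert res["G"].status == "non-monophyletic"
        assert set(res["G"].offending_tips) >= {"c"} or \
            set(res["G"].offending_tips) >= {"d"}

    def test_group_absent_from_tree_errors(self):
        tv = TreeView.from_newick("((a:1,b:1):1,c:1);")
        with pytest.raises(ValueError):
            evaluate_groups(tv, {"a": "G", "nope": "G"})


class TestDelimitation:
    @staticmethod
    def _dm(ids, dists):
        n = len(ids)
        M = np.zeros((n, n))
        for (i, j), d in dists.items():
            M[i, j] = M[j, i] = d
        return DistanceMatrix(ids, M, "p")

    def test_pair_above_threshold_splits(self):
        dm = self._dm(["x", "y"], {(0, 1): 0.014})
        assert len(delimit_species(dm, 0.013)) == 2

    def test_identical_pair_merges(self):
        dm = self._dm(["x", "y"], {(0, 1): 0.0})
        clusters = delimit_species(dm, 0.013)
        assert clusters == {"x": ["x", "y"]}

    def test_matches_graph_component_oracle(self, rng):
        """Single-linkage clusters == connected components of the threshold graph."""
        for rep in range(40):
            n = 20
            ids = [f"s{i:02d}" for i in range(n)]
            M = np.zeros((n, n))
            iu = np.triu_indices(n, 1)
            vals = rng.uniform(0, 0.03, size=len(iu[0]))
            M[iu] = vals
            M = M + M.T
            dm = DistanceMatrix(ids, M, "p")
            clusters = delimit_species(dm, 0.013)
            G = nx.Graph()
            G.add_nodes_from(ids)
            for i, j in zip(*iu):
                if M[i, j] <= 0.013:
                    G.add_edge(ids[i], ids[j])
            oracle = {frozenset(c) for c in nx.connected_components(G)}
            assert {frozenset(m) for m in clusters.values()} == oracle

    def test_invariant_to_id_permutation(self, rng):
        n = 12
        ids = [f"s{i}" for i in range(n)]
        M = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        M[iu] = rng.uniform(0, 0.03, size=len(iu[0]))
        M = M + M.T
        base = {frozenset(m) for m in
                delimit_species(DistanceMatrix(ids, M, "p")).values()}
        perm = rng.permutation(n)
        M2 = M[np.ix_(perm, perm)]
        ids2 = [ids[i] for i in perm]
        shuffled = {frozenset(m) for m in
                    delimit_species(DistanceMatrix(ids2, M2, "p")).values()}
        assert base == shuffled

    def test_monotone_in_threshold(self, rng):
        n = 15
        ids = [f"s{i}" for i in range(n)]
        M = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        M[iu] = rng.uniform(0, 0.05, size=len(iu[0]))
        M = M + M.T
        dm = DistanceMatrix(ids, M, "p")
        counts = [len(delimit_species(dm, th))
                  for th in (0.0, 0.005, 0.013, 0.02, 0.05)]
        assert counts == sorted(counts, reverse=True)

    def test_ml_scale_matrix_guarded(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0, .4], [.4, 0]]), "ml")
        with pytest.raises(ValueError):
            delimit_species(dm)
        assert delimit_species(dm, allow_ml=True)


class TestLineageReport:
    def _fixture(self, jc, n_groups=11, per=2):
        clades = []
        groups = {}
        for g in range(n_groups):
            tips = [f"g{g:02d}_{i}" for i in range(per)]
            for t in tips:
                groups[t] = f"G{g:02d}"
            inner = ",".join(f"{t}:0.01" for t in tips)
            clades.append(f"({inner}):0.3")
        nwk = "(" + ",".join(clades) + ");"
        tv = TreeView.from_newick(nwk)
        ids = list(groups)
        n = len(ids)
        M = np.full((n, n), 0.4)
        for i, j in itertools.combinations(range(n), 2):
            if groups[ids[i]] == groups[ids[j]]:
                M[i, j] = M[j, i] = 0.02
        np.fill_diagonal(M, 0)
        return tv, groups, DistanceMatrix(ids, M, "p")

    def test_eleven_true_lineages_all_monophyletic(self, jc):
        tv, groups, dm = self._fixture(jc)
        table, inter = lineage_report(tv, groups, dm)
        assert len(table) == 11
        assert (table["status"] == "monophyletic").all()
        assert (table["intra_mean_distance"] == 0.02).all()
        assert (inter["inter_mean_distance"] == 0.4).all()

    def test_report_invariant_to_tip_order(self, jc):
        tv, groups, dm = self._fixture(jc, n_groups=4)
        shuffled = dict(reversed(list(groups.items())))
        t1, _ = lineage_report(tv, groups, dm)
        t2, _ = lineage_report(tv, shuffled, dm)
        assert t1.equals(t2)
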