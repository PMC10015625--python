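import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from introland.treekit import (WeightingResult, canonical_topology,
                               count_topologies, enumerate_rooted_topologies,
                               main_topologies, nj_tree, p_distance_matrix,
                               quartet_score, topology_weighting)


def random_additive_tree(labels, seed):
    """Random rooted tree with positive branch lengths; returns
    (newick, path-distance matrix)."""
    rng = np.random.default_rng(seed)
    nodes = [(lab, 0.0) for lab in labels]  # (newick, ignored)
    nwk_nodes = list(labels)
    while len(nwk_nodes) > 1:
        i, j = sorted(rng.choice(len(nwk_nodes), 2, replace=False))
        a, b = nwk_nodes[i], nwk_nodes[j]
        la, lb = rng.uniform(0.5, 3.0, 2).round(2)
        merged = f"({a}:{la},{b}:{lb})"
        nwk_nodes = [x for k, x in enumerate(nwk_nodes) if k not in (i, j)]
        nwk_nodes.append(merged)
    nwk = nwk_nodes[0] + ";"
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.taxon.label: t.taxon for t in tree.leaf_node_iter()}
    D = pd.DataFrame(0.0, index=list(labels), columns=list(labels))
    for x, y in itertools.combinations(labels, 2):
        D.loc[x, y] = D.loc[y, x] = pdm.patristic_distance(taxa[x], taxa[y])
    return nwk, D


class TestNjTree:
    def test_recovers_generating_topology_from_additive_distances(self):
        labs = list("ABCD")
        D = pd.DataFrame([[0, 3, 7, 5], [3, 0, 8, 6], [7, 8, 0, 4],
                          [5, 6, 4, 0]], index=labs, columns=labs, dtype=float)
        t = nj_tree(D)
        # A,B on one side: the A-B path avoids C and D
        assert canonical_topology(t, outgroup="D") == "(((A,B),C),D);"

    def test_zero_distance_pair_becomes_cherry(self):
        labs = list("ABCD")
        D = pd.DataFrame([[0, 0, 5, 5], [0, 0, 5, 5], [5, 5, 0, 2],
                          [5, 5, 2, 0]], index=labs, columns=labs, dtype=float)
        t = nj_tree(D)
        assert canonical_topology(t, outgroup="D") == "(((A,B),C),D);"

    def test_reproduces_additive_matrix(self):
        labs = [f"t{i}" for i in range(8)]
        _, D = random_additive_tree(labs, seed=19)
        t = nj_tree(D)
        pdm = t.phylogenetic_distance_matrix()
        taxa = {x.taxon.label: x.taxon for x in t.leaf_node_iter()}
        for x, y in itertools.combinations(labs, 2):
            assert pdm.patristic_distance(taxa[x], taxa[y]) == \
                pytest.approx(D.loc[x, y], abs=1e-9)

    def test_too_few_tips_rejected(self):
        D = pd.DataFrame(np.zeros((3, 3)), index=list("ABC"),
                         columns=list("ABC"))
        with pytest.raises(ValueError):
            nj_tree(D)

    def test_p_distance_on_dosages(self):
        dos = np.array([[0, 2, -1], [2, 0, 1], [1, 1, 1]], dtype=np.int8)
        D = p_distance_matrix(dos, ["a", "b", "c"])
        # a-b: |0-2|, |2-0|, |1-1| -> mean 4/3, halved
        assert D.loc["a", "b"] == pytest.approx(2 / 3)
        # a-c: site 1 missing; |2-1|, |1-1| -> mean 1/2, halved
        assert D.loc["a", "c"] == pytest.approx(0.25)
        assert D.loc["b", "c"] == D.loc["c", "b"]


class TestCanonicalTopology:
    def test_rotation_invariance(self):
        t1 = dendropy.Tree.get(data="((A,B),(C,(D,O)));", schema="newick")
        t2 = dendropy.Tree.get(data="(((D,O),C),(B,A));", schema="newick")
        assert canonical_topology(t1, outgroup="O") == \
            canonical_topology(t2, outgroup="O")

    def test_nni_neighbors_distinguished(self):
        t1 = dendropy.Tree.get(data="(((A,B),C),O);", schema="newick")
        t2 = dendropy.Tree.get(data="(((A,C),B),O);", schema="newick")
        assert canonical_topology(t1, outgroup="O") != \
            canonical_topology(t2, outgroup="O")

    def test_branch_lengths_ignored(self):
        t1 = dendropy.Tree.get(data="((A:1,B:9):2,(C:1,O:4):1);",
                               schema="newick")
        t2 = dendropy.Tree.get(data="((A,B),(C,O));", schema="newick")
        assert canonical_topology(t1, outgroup="O") == \
            canonical_topology(t2, outgroup="O")

    def test_unrooted_without_outgroup_rejected(self):
        t = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
        t.is_rooted = False
        with pytest.raises(ValueError):
            canonical_topology(t)

    def test_agreement_with_rf_distance_oracle(self):
        # two random 7-tip trees share an ID iff their RF distance is zero
        import dendropy.calculate.treecompare as tc

        labs = [f"x{i}" for i in range(7)]
        ids, trees = [], []
        tns = dendropy.TaxonNamespace()
        for seed in range(30):
            nwk, _ = random_additive_tree(labs + ["O"], seed)
            t = dendropy.Tree.get(data=nwk, schema="newick",
                                  taxon_namespace=tns)
            ids.append(canonical_topology(t, outgroup="O"))
            tr = dendropy.Tree.get(data=nwk, schema="newick",
                                   taxon_namespace=tns)
            tr.encode_bipartitions()
            trees.append(tr)
        for i, j in itertools.combinations(range(30), 2):
            same_id = ids[i] == ids[j]
            rf0 = tc.symmetric_difference(trees[i], trees[j]) == 0
            assert same_id == rf0


class TestCountTopologies:
    @pytest.mark.parametrize("n,expected", [(4, 3), (5, 15), (8, 10395)])
    def test_double_factorial_values(self, n, expected):
        assert count_topologies(n) == expected

    @pytest.mark.parametrize("k", [2, 3, 4, 5, 6])
    def test_matches_exhaustive_enumeration(self, k):
        labs = [f"g{i}" for i in range(k)]
        gen = enumerate_rooted_topologies(labs)
        assert len(set(map(str, gen))) == len(gen)
        assert len(gen) == count_topologies(k + 1,
                                            rooted_with_fixed_outgroup=True)


class TestTopologyWeighting:
    def test_one_tip_per_group_gives_point_mass(self):
        t = dendropy.Tree.get(data="(((a1,b1),c1),o1);", schema="newick")
        gm = {"a1": "A", "b1": "B", "c1": "C", "o1": "O"}
        r = topology_weighting(t, gm, "O")
        assert r.weights == {"(((A,B),C),O);": 1.0}

    def test_weights_sum_to_one(self):
        t = dendropy.Tree.get(
            data="((((a1,b1),(a2,c1)),(b2,c2)),(o1,o2));", schema="newick")
        gm = {"a1": "A", "a2": "A", "b1": "B", "b2": "B",
              "c1": "C", "c2": "C", "o1": "O", "o2": "O"}
        for method in ("exhaustive", "montecarlo"):
            r = topology_weighting(t, gm, "O", method=method, n_samples=200,
                                   seed=1)
            assert sum(r.weights.values()) == pytest.approx(1.0)

    def test_relabeling_within_group_invariant(self):
        nwk = "((((a1,b1),(a2,c1)),(b2,c2)),o1);"
        t1 = dendropy.Tree.get(data=nwk, schema="newick")
        t2 = dendropy.Tree.get(data=nwk.replace("a1", "tmp")
                               .replace("a2", "a1").replace("tmp", "a2"),
                               schema="newick")
        gm = {"a1": "A", "a2": "A", "b1": "B", "b2": "B",
              "c1": "C", "c2": "C", "o1": "O"}
        r1 = topology_weighting(t1, gm, "O", method="exhaustive")
        r2 = topology_weighting(t2, gm, "O", method="exhaustive")
        assert r1.weights == r2.weights

    def test_empty_group_rejected(self):
        t = dendropy.Tree.get(data="(((a1,b1),c1),o1);", schema="newick")
        gm = {"a1": "A", "b1": "B", "c1": "C", "o1": "O", "ghost": "G"}
        with pytest.raises(ValueError, match="no tips"):
            topology_weighting(t, gm, "O")

    def test_more_than_eight_groups_refused(self):
        t = dendropy.Tree.get(
            data="(((((((((t0,t1),t2),t3),t4),t5),t6),t7),t8));",
            schema="newick")
        gm = {f"t{i}": f"G{i}" for i in range(9)}
        with pytest.raises(ValueError, match="8 groups"):
            topology_weighting(t, gm, "G0")


class TestMainTopologies:
    def test_single_window_passthrough(self):
        w = WeightingResult({"T1;": 0.7, "T2;": 0.3}, "exhaustive", 10, {})
        df = main_topologies([w])
        assert dict(zip(df.topology, df.frequency)) == {"T1;": 0.7, "T2;": 0.3}

    def test_threshold_zero_returns_all(self):
        w = WeightingResult({"T1;": 0.999, "T2;": 0.001}, "exhaustive", 10, {})
        df = main_topologies([w], freq_threshold=0.0)
        assert df["main"].all()

    def test_hand_computed_means(self):
        ws = [WeightingResult({"A;": 1.0}, "exhaustive", 1, {})] * 6 + \
             [WeightingResult({"B;": 1.0}, "exhaustive", 1, {})] * 4
        df = main_topologies(ws, freq_threshold=0.5)
        freqs = dict(zip(df.topology, df.frequency))
        assert freqs == {"A;": 0.6, "B;": 0.4}
        assert list(df[df.main].topology) == ["A;"]


class TestQuartetScore:
    def test_identical_trees_score_one(self):
        tns = dendropy.TaxonNamespace()
        sp = dendropy.Tree.get(data="(((A,B),C),(D,O));", schema="newick",
                               taxon_namespace=tns)
        gts = [dendropy.Tree.get(data="(((A,B),C),(D,O));", schema="newick",
                                 taxon_namespace=tns) for _ in range(3)]
        assert quartet_score(sp, gts) == 1.0

    def test_cherry_swap_strictly_below_one(self):
        tns = dendropy.TaxonNamespace()
        sp = dendropy.Tree.get(data="(((A,B),C),(D,O));", schema="newick",
                               taxon_namespace=tns)
        gt = dendropy.Tree.get(data="(((A,C),B),(D,O));", schema="newick",
                               taxon_namespace=tns)
        assert quartet_score(sp, [gt]) < 1.0

    def test_invariant_to_tree_order_and_lengths(self):
        tns = dendropy.TaxonNamespace()
        sp = dendropy.Tree.get(data="(((A,B),C),(D,O));", schema="newick",
                               taxon_namespace=tns)
        g1 = dendropy.Tree.get(data="(((A,C),B),(D,O));", schema="newick",
                               taxon_namespace=tns)
        g2 = dendropy.Tree.get(data="((D:9,O:1),((A:2,B:1):5,C:1):2);",
                               schema="newick", taxon_namespace=tns)
        assert quartet_score(sp, [g1, g2]) == quartet_score(sp, [g2, g1])

    def test_matches_exhaustive_quartet_oracle(self):
        labs = [f"x{i}" for i in range(7)]
        tns = dendropy.TaxonNamespace()
        sp_nwk, _ = random_additive_tree(labs, seed=29)
        sp = dendropy.Tree.get(data=sp_nwk, schema="newick",
                               taxon_namespace=tns)
        gts = []
        for s in range(20):
            nwk, _ = random_additive_tree(labs, seed=100 + s)
            gts.append(dendropy.Tree.get(data=nwk, schema="newick",
                                         taxon_namespace=tns))
        got = quartet_score(sp, gts)

        # oracle: extract each induced 4-taxon subtree and compare its
        # unrooted canonical shape
        def induced_id(tree, quad):
            sub = tree.extract_tree_with_taxa_labels(labels=set(quad))
            sub.is_rooted = False
            sub.update_bipartitions()
            anchor = min(quad)
            for bp in sub.bipartition_encoding:
                leaves = set(bp.leafset_taxa(sub.taxon_namespace))
                labels = {t.label for t in leaves} & set(quad)
                if len(labels) == 2:
                    # normalize to the side containing the anchor taxon
                    if anchor not in labels:
                        labels = set(quad) - labels
                    return frozenset(labels)
            return None

        match = total = 0
        for gt in gts:
            for quad in itertools.combinations(labs, 4):
                qs = induced_id(sp, quad)
                qg = induced_id(gt, quad)
                if qs is None or qg is None:
                    continue
                total += 1
                match += qs == qg
        assert got == pytest.approx(match / total)

    def test_no_shared_quartets_raises(self):
        tns = dendropy.TaxonNamespace()
        sp = dendropy.Tree.get(data="((A,B),(C,O));", schema="newick",
                               taxon_namespace=tns)
        gt = dendropy.Tree.get(data="((E,F),(G,H));", schema="newick",
                               taxon_namespace=tns)
        with pytest.raises(ValueError):
            quartet_score(sp, [gt])
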