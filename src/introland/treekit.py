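"""Per-window trees, canonical topologies, topology weighting and quartet scores.

Trees are dendropy objects; newick is the interchange format throughout.
Per-window trees come from neighbor joining on dosage p-distances (a
surrogate for ML window trees; externally inferred newick trees can be
supplied instead).  Topology weighting follows the Twisst idea: sample one
tip per taxon group, prune the tree to the sampled tips, collapse tips to
group labels, canonicalize the rooted shape and tally.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

__all__ = ["nj_tree", "p_distance_matrix", "canonical_topology",
           "count_topologies", "topology_weighting", "main_topologies",
           "quartet_score", "WeightingResult"]


# ---------------------------------------------------------------------------
# distances and neighbor joining


def p_distance_matrix(dosages: np.ndarray, samples) -> pd.DataFrame:
    """Pairwise p-distance between diploid dosage vectors.

    Distance = mean |d_i - d_j| / 2 over sites where both are genotyped
    (dosage difference normalized to [0, 1]); 0 when no shared sites.
    """
    d = dosages.astype(float)
    d = np.where(d < 0, np.nan, d)
    n = d.shape[1]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff = np.abs(d[:, i] - d[:, j])
            m = ~np.isnan(diff)
            out[i, j] = out[j, i] = (diff[m].mean() / 2.0) if m.any() else 0.0
    return pd.DataFrame(out, index=list(samples), columns=list(samples))


def nj_tree(dist: pd.DataFrame) -> dendropy.Tree:
    """Neighbor joining on a symmetric distance matrix.

    Deterministic: ties in the Q-matrix are broken by the lexicographically
    smallest pair of tip (cluster) labels.  Returns an unrooted dendropy
    tree (trifurcating root node, the usual NJ output shape).
    """
    labels = list(dist.index)
    if len(labels) < 4:
        raise ValueError("neighbor joining needs >= 4 tips")
    D = {a: {b: float(dist.loc[a, b]) for b in labels if b != a} for a in labels}
    taxa = dendropy.TaxonNamespace(labels)
    nodes = {}
    for lab in labels:
        nd = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes[lab] = nd
    active = list(labels)
    counter = itertools.count()
    while len(active) > 2:
        n = len(active)
        r = {a: sum(D[a][b] for b in active if b != a) for a in active}
        best = None
        for a, b in itertools.combinations(sorted(active), 2):
            q = (n - 2) * D[a][b] - r[a] - r[b]
            key = (q, a, b)
            if best is None or key < best:
                best = key
        _, a, b = best
        dab = D[a][b]
        va = 0.5 * dab + (r[a] - r[b]) / (2 * (n - 2))
        vb = dab - va
        new_label = f"__nj{next(counter)}"
        parent = dendropy.Node()
        na, nb = nodes.pop(a), nodes.pop(b)
        na.edge.length = max(va, 0.0)
        nb.edge.length = max(vb, 0.0)
        parent.add_child(na)
        parent.add_child(nb)
        nodes[new_label] = parent
        Dnew = {}
        for c in active:
            if c in (a, b):
                continue
            Dnew[c] = 0.5 * (D[a][c] + D[b][c] - dab)
        D[new_label] = Dnew
        for c, v in Dnew.items():
            D[c][new_label] = v
            del D[c][a], D[c][b]
        active = [x for x in active if x not in (a, b)] + [new_label]
    a, b = sorted(active)
    root = dendropy.Node()
    na, nb = nodes.pop(a), nodes.pop(b)
    na.edge.length = max(D[a][b], 0.0) / 2
    nb.edge.length = max(D[a][b], 0.0) / 2
    root.add_child(na)
    root.add_child(nb)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = False
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree


# ---------------------------------------------------------------------------
# canonical topology identifiers


def _canon(node, rename=None) -> str:
    if node.is_leaf():
        lab = node.taxon.label
        return rename.get(lab, lab) if rename else lab
    parts = sorted(_canon(c, rename) for c in node.child_nodes())
    return "(" + ",".join(parts) + ")"


def root_at_outgroup(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    t = tree.clone(depth=1)
    og = t.find_node_with_taxon_label(outgroup)
    if og is None:
        raise ValueError(f"outgroup {outgroup!r} not in tree")
    # root on the outgroup's edge so the root is binary: (outgroup, rest)
    t.reroot_at_edge(og.edge, update_bipartitions=False,
                     suppress_unifurcations=True)
    t.is_rooted = True
    t.suppress_unifurcations()
    return t


def canonical_topology(tree: dendropy.Tree, outgroup: str | None = None,
                       rename: dict | None = None) -> str:
    """Branch-length-free canonical string of a rooted leaf-labeled topology.

    Children are sorted recursively by their canonical substring, so any
    rotation/ladder order of the same labeled shape yields the same ID.
    ``rename`` optionally maps tip labels (e.g. to group names) before
    canonicalization.  Unrooted input needs an ``outgroup``.
    """
    t = tree
    if outgroup is not None:
        t = root_at_outgroup(tree, outgroup)
    elif not tree.is_rooted:
        raise ValueError("unrooted tree: supply an outgroup")
    return _canon(t.seed_node, rename) + ";"


def count_topologies(n_groups: int, rooted_with_fixed_outgroup: bool = True) -> int:
    """Number of distinct leaf-labeled rooted bifurcating topologies.

    With a fixed outgroup among ``n_groups`` taxa, this is the number of
    rooted bifurcating trees on the n-1 ingroups: (2(n-1)-3)!!.  Without
    the flag, all ``n_groups`` tips are free: (2n-3)!!.
    """
    if n_groups < 2:
        raise ValueError("need >= 2 groups")
    k = n_groups - 1 if rooted_with_fixed_outgroup else n_groups
    if k < 2:
        return 1
    out = 1
    for m in range(2 * k - 3, 0, -2):
        out *= m
    return out


def enumerate_rooted_topologies(labels) -> list:
    """All rooted binary leaf-labeled shapes on ``labels`` (nested 2-tuples).

    Edge-attachment enumeration: each rooted tree on k+1 leaves arises
    uniquely by attaching the new leaf to one of the 2k-1 branches
    (including the root branch), giving the (2k-1)!! recursion.
    """
    labels = sorted(labels)
    trees = [labels[0]]
    for lab in labels[1:]:
        new_trees = []
        for t in trees:
            for nt in _attach_everywhere(t, lab):
                new_trees.append(nt)
        trees = new_trees
    return [_sort_nested(t) for t in trees]


def _attach_everywhere(tree, lab):
    yield (tree, lab)
    if isinstance(tree, tuple):
        a, b = tree
        for na in _attach_everywhere(a, lab):
            yield (na, b)
        for nb in _attach_everywhere(b, lab):
            yield (a, nb)


def _sort_nested(t):
    if not isinstance(t, tuple):
        return t
    a, b = _sort_nested(t[0]), _sort_nested(t[1])
    return (a, b) if _nested_str(a) <= _nested_str(b) else (b, a)


def _nested_str(t):
    if not isinstance(t, tuple):
        return t
    return "(" + ",".join(_nested_str(x) for x in t) + ")"


# ---------------------------------------------------------------------------
# topology weighting (Twisst-style)


@dataclass
class WeightingResult:
    weights: dict           # topology id -> weight (sums to 1)
    method: str             # 'exhaustive' | 'montecarlo'
    n_samples: int
    group_map: dict


def _prune_to_tips(tree: dendropy.Tree, tips) -> dendropy.Tree:
    t = tree.extract_tree_with_taxa_labels(labels=set(tips))
    return t


def topology_weighting(tree: dendropy.Tree, group_map: dict,
                       outgroup_group: str, method: str = "auto",
                       n_samples: int = 1000, seed: int | None = None,
                       exhaustive_limit: int = 10_000) -> WeightingResult:
    """Distribution over group-level topologies induced by one-tip-per-group
    subsampling of a single tree.

    ``group_map`` maps tip label -> group label (every group needs >= 1 tip
    present; at most 8 groups).  Exhaustive mode enumerates every
    combination; Monte-Carlo samples uniformly.  ``method='auto'`` uses
    exhaustive enumeration when the number of combinations is at most
    ``exhaustive_limit``.
    """
    tip_labels = {t.taxon.label for t in tree.leaf_node_iter()}
    groups: dict = {}
    for tip, g in group_map.items():
        if tip in tip_labels:
            groups.setdefault(g, []).append(tip)
    if outgroup_group not in groups:
        raise ValueError(f"outgroup group {outgroup_group!r} has no tips in tree")
    empty = [g for g in set(group_map.values()) if g not in groups]
    if empty:
        raise ValueError(f"groups with no tips in tree: {empty}")
    if len(groups) > 8:
        raise ValueError("more than 8 groups is not supported")
    for g in groups:
        groups[g] = sorted(groups[g])
    names = sorted(groups)
    total = math.prod(len(groups[g]) for g in names)
    if method == "auto":
        method = "exhaustive" if total <= exhaustive_limit else "montecarlo"

    rename = {tip: g for tip, g in group_map.items()}
    tally: dict = {}

    def observe(combo):
        sub = _prune_to_tips(tree, combo)
        tid = canonical_topology(sub, outgroup=
                                 [t for t in combo if rename[t] == outgroup_group][0],
                                 rename=rename)
        tally[tid] = tally.get(tid, 0) + 1

    if method == "exhaustive":
        n_used = total
        for combo in itertools.product(*(groups[g] for g in names)):
            observe(combo)
    elif method == "montecarlo":
        rng = np.random.default_rng(seed)
        n_used = n_samples
        for _ in range(n_samples):
            combo = tuple(groups[g][rng.integers(len(groups[g]))] for g in names)
            observe(combo)
    else:
        raise ValueError(f"unknown method {method!r}")
    weights = {k: v / n_used for k, v in tally.items()}
    return WeightingResult(weights=weights, method=method, n_samples=n_used,
                           group_map=dict(group_map))


def main_topologies(results, freq_threshold: float = 0.015) -> pd.DataFrame:
    """Mean weighting per topology across windows, flagged 'main' above threshold.

    ``results`` is an iterable of per-window WeightingResult (or weight
    dicts).  Windows where a topology is absent contribute weight 0.
    """
    results = list(results)
    if not results:
        raise ValueError("no weighting results")
    dicts = [r.weights if isinstance(r, WeightingResult) else dict(r)
             for r in results]
    all_ids = sorted({k for d in dicts for k in d})
    n = len(dicts)
    rows = []
    for tid in all_ids:
        freq = sum(d.get(tid, 0.0) for d in dicts) / n
        rows.append((tid, freq))
    df = pd.DataFrame(rows, columns=["topology", "frequency"])
    df = df.sort_values("frequency", ascending=False, kind="stable",
                        ignore_index=True)
    df["main"] = df["frequency"] > freq_threshold
    return df


# ---------------------------------------------------------------------------
# quartet score


def _quartet_topology(dmat: dict, a, b, c, d):
    """Resolve {a,b,c,d} by the four-point condition on topological distances.

    Returns the pair grouped with ``a`` (frozenset), or None if unresolved.
    """
    s_ab = dmat[a][b] + dmat[c][d]
    s_ac = dmat[a][c] + dmat[b][d]
    s_ad = dmat[a][d] + dmat[b][c]
    m = min(s_ab, s_ac, s_ad)
    if [s_ab, s_ac, s_ad].count(m) != 1:
        return None
    if m == s_ab:
        return frozenset((a, b))
    if m == s_ac:
        return frozenset((a, c))
    return frozenset((a, d))


def _topo_dist_matrix(tree: dendropy.Tree) -> dict:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.taxon.label: t.taxon for t in tree.leaf_node_iter()}
    out: dict = {}
    for x, tx in taxa.items():
        out[x] = {}
        for y, ty in taxa.items():
            out[x][y] = 0 if x == y else pdm.path_edge_count(tx, ty)
    return out


def quartet_score(species_tree: dendropy.Tree, gene_trees) -> float:
    """Fraction of gene-tree quartets satisfied by the species tree.

    Over all gene trees and all 4-tip subsets resolved in both trees, the
    proportion whose induced unrooted quartet topology matches the species
    tree's.  Branch lengths and gene-tree order are irrelevant.
    Raises ValueError when no comparable quartet exists.
    """
    sp_tips = {t.taxon.label for t in species_tree.leaf_node_iter()}
    sp_d = _topo_dist_matrix(species_tree)
    match = 0
    totaln = 0
    for gt in gene_trees:
        gt_tips = [t.taxon.label for t in gt.leaf_node_iter()]
        shared = sorted(set(gt_tips) & sp_tips)
        if len(shared) < 4:
            continue
        g_d = _topo_dist_matrix(gt)
        for quad in itertools.combinations(shared, 4):
            qs = _quartet_topology(sp_d, *quad)
            qg = _quartet_topology(g_d, *quad)
            if qs is None or qg is None:
                continue
            totaln += 1
            if qs == qg:
                match += 1
    if totaln == 0:
        raise ValueError("no shared resolved quartets")
    return match / totaln
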