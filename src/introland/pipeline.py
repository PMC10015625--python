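"""End-to-end orchestration: simulate/load -> statistics -> landscape -> report.

Also houses the combinatorial enumerators for trios, population pairs and
tree-consistent symmetric quintets.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import gio, landscape, patstats, simcoal, treekit
from .dfoil import QuintetSpec, dfoil_test, pattern_counts5
from .patstats import TrioSpec

logger = logging.getLogger(__name__)

__all__ = ["enumerate_trios", "enumerate_pairs", "enumerate_quintets",
           "RunConfig", "run_pipeline", "trio_table"]


def enumerate_trios(populations, outgroup: str) -> list:
    """One TrioSpec per unordered ingroup triple; the (P1,P2;P3) arrangement
    is resolved downstream by the minimum-|D| rule.  Count = C(n, 3)."""
    pops = list(populations)
    if outgroup in pops:
        raise ValueError("outgroup must not be listed among the ingroups")
    if len(pops) < 3:
        raise ValueError("need >= 3 ingroup populations")
    return [TrioSpec(a, b, c, outgroup)
            for a, b, c in itertools.combinations(sorted(pops), 3)]


def enumerate_pairs(populations) -> list:
    """Unordered population pairs; count = C(n, 2)."""
    pops = sorted(populations)
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    return list(itertools.combinations(pops, 2))


def _node_age(tree: dendropy.Tree, node) -> float:
    """Age of a node = max root-distance of its leaves minus its root-distance
    (time above the present on an ultrametric tree; topological depth
    difference otherwise)."""
    return max(lf.distance_from_root() for lf in node.leaf_iter()) \
        - node.distance_from_root()


def enumerate_quintets(species_tree: dendropy.Tree, populations,
                       outgroup: str) -> list:
    """All symmetric quintets ((P1,P2),(P3,P4),O) consistent with the tree.

    Both pairs must induce a symmetric restricted tree (their MRCAs are
    disjoint clades) and the (P3,P4) divergence must be strictly older
    than the (P1,P2) divergence.  Pairs are label-sorted; the list is
    deduplicated.
    """
    if not species_tree.is_rooted:
        raise ValueError("species tree must be rooted")
    pops = sorted(set(populations) - {outgroup})
    taxa = {t.taxon.label: t.taxon for t in species_tree.leaf_node_iter()}
    missing = [p for p in pops if p not in taxa]
    if missing:
        raise ValueError(f"populations not in species tree: {missing}")
    if any(e.length is None for e in species_tree.preorder_edge_iter()
           if e.head_node is not species_tree.seed_node):
        for e in species_tree.preorder_edge_iter():
            if e.length is None:
                e.length = 1.0
    out = []
    for four in itertools.combinations(pops, 4):
        for pair1, pair2 in _pairings(four):
            m1 = species_tree.mrca(taxa=[taxa[x] for x in pair1])
            m2 = species_tree.mrca(taxa=[taxa[x] for x in pair2])
            leaves1 = {lf.taxon.label for lf in m1.leaf_iter()}
            leaves2 = {lf.taxon.label for lf in m2.leaf_iter()}
            if leaves1 & leaves2:
                continue  # induced tree is not symmetric
            a1, a2 = _node_age(species_tree, m1), _node_age(species_tree, m2)
            if a2 > a1:
                out.append(QuintetSpec(*pair1, *pair2, outgroup))
            elif a1 > a2:
                out.append(QuintetSpec(*pair2, *pair1, outgroup))
    return out


def _pairings(four):
    a, b, c, d = four
    return [((a, b), (c, d)), ((a, c), (b, d)), ((a, d), (b, c))]


# ---------------------------------------------------------------------------
# stages


def trio_table(pf: gio.PolarizedFreqs, trios, n_blocks: int = 20,
               alpha: float = 0.01) -> pd.DataFrame:
    """D_min arrangement, D/Z/p (BH-adjusted) and f_hom for every trio."""
    rows = []
    for trio in trios:
        dm = patstats.d_min(pf.freqs, (trio.P1, trio.P2, trio.P3), trio.O,
                            n_blocks=n_blocks)
        arr = dm.arrangement
        fh = patstats.f_hom(pf.freqs[arr.P1], pf.freqs[arr.P2],
                            pf.freqs[arr.P3],
                            n3_haplotypes=pf.n_haplotypes.get(arr.P3))
        rows.append({
            "P1": arr.P1, "P2": arr.P2, "P3": arr.P3, "O": arr.O,
            "D": dm.result.D, "Z": dm.result.Z, "p": dm.result.p,
            "f_hom": fh,
            "best_p": dm.most_significant[1].p,
        })
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj"] = patstats.bh_adjust(df["p"].fillna(1.0).to_numpy())
        df["significant"] = df["p_adj"] < alpha
    return df


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    Either a simulation block (model + windows + samples) or input paths
    (VCF, population map) must be given.  Thresholds carry the defaults of
    the windowed-scan workflow: BH alpha 0.01, f_dM min 10 SNPs per
    window, top 5% cuts, 20 correlation bins, 5 recombination quintiles.
    """

    outdir: str = "introland_run"
    seed: int = 1
    # simulation block
    simulate: bool = True
    model: object = None
    windows: object = None
    samples_per_pop: dict | None = None
    # input paths (when simulate=False)
    vcf: str | None = None
    pop_map: str | None = None
    outgroup: str | None = None
    window_len: int = 10_000
    gff: str | None = None
    rho_track: str | None = None
    # thresholds
    alpha: float = 0.01
    min_snps: int = 10
    n_blocks: int = 20
    top_q_introgression: float = 0.05
    top_q_fst: float = 0.05
    fst_index_threshold: float = 1.0 / 3.0
    n_bins: int = 10
    quantile_k: int = 5
    # optional stages
    run_topology_weighting: bool = True
    run_dfoil: bool = False
    chronogram: str | None = None
    tip_states: str | None = None

    def config_hash(self) -> str:
        payload = {k: repr(v) for k, v in self.__dict__.items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the stages in dependency order and write all artifacts.

    Returns a report dict (also written as JSON).  Idempotent for a fixed
    seed and config.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "config_hash": cfg.config_hash()}
    stage = "input"
    try:
        if cfg.simulate:
            model = cfg.model if cfg.model is not None else simcoal.ladder_model()
            windows_model = cfg.windows if cfg.windows is not None else \
                simcoal.WindowModel(n_windows=200)
            samples = cfg.samples_per_pop or \
                {p: 2 for p in model.tips}
            gm, truth = simcoal.simulate_dataset(model, windows_model,
                                                 samples, cfg.seed)
            wtab = truth.table[["window", "chrom", "start", "end"]].copy()
            rho = truth.table["rho"].to_numpy()
            gio.write_vcf(gm, out / "simulated.vcf",
                          {windows_model.chrom:
                           windows_model.n_windows * windows_model.window_len})
            gio.write_pop_map(gm.pop_map, out / "pop_map.tsv")
            truth.write_tsv(out / "truth.tsv")
            species_newick = model.newick
        else:
            pop_map = gio.read_pop_map(cfg.pop_map)
            gm = gio.read_vcf_filtered(cfg.vcf, pop_map, cfg.outgroup)
            truth = None
            lengths = {c: int(gm.pos[gm.chrom == c].max())
                       for c in pd.unique(pd.Series(gm.chrom))}
            wtab = gio.make_windows(lengths, cfg.window_len)
            rho = None
            species_newick = None
        if cfg.rho_track is not None:
            rt = pd.read_csv(cfg.rho_track, sep="\t")
            rho = rt["rho"].to_numpy()
        report["n_sites"] = int(gm.n_sites)
        report["populations"] = gm.populations

        stage = "polarize"
        pf = gio.polarize(gm)
        report["n_polarized_sites"] = int(pf.n_sites)
        widx = gio.assign_windows(wtab, pf.chrom, pf.pos)

        stage = "trio_statistics"
        ingroups = gm.ingroups
        trios = enumerate_trios(ingroups, gm.outgroup)
        ttab = trio_table(pf, trios, n_blocks=cfg.n_blocks, alpha=cfg.alpha)
        ttab.to_csv(out / "trios.tsv", sep="\t", index=False)
        report["n_trios"] = len(ttab)
        report["n_significant_trios"] = int(ttab["significant"].sum()) if len(ttab) else 0

        stage = "fdm_pir_index"
        pir_sets, defined_sets = {}, {}
        for row in ttab.itertuples(index=False):
            if not row.significant or not np.isfinite(row.f_hom):
                continue
            tr = patstats.f_dm_track(pf.freqs[row.P1], pf.freqs[row.P2],
                                     pf.freqs[row.P3], widx, wtab,
                                     min_snps=cfg.min_snps)
            x = float(np.clip(100.0 * row.f_hom, 0.0, 100.0))
            key = (row.P1, row.P2, row.P3)
            pir_sets[key] = patstats.call_pir(tr, x)
            defined_sets[key] = tr.defined
        if pir_sets:
            itrack = patstats.introgression_index(pir_sets, defined_sets, wtab)
            introg_index = itrack.index
        else:
            introg_index = np.zeros(len(wtab))
        report["n_contributing_trios"] = len(pir_sets)

        stage = "fst_landscape"
        pairs = enumerate_pairs(ingroups)
        fst_tracks = [landscape.fst_windows(gm, a, b, wtab) for a, b in pairs]
        fst_index = landscape.outlier_index(fst_tracks, top_q=cfg.top_q_fst)
        regions = landscape.classify_regions(
            introg_index, fst_index, wtab, top_q=cfg.top_q_introgression,
            fst_threshold=cfg.fst_index_threshold)
        scan = wtab.copy()
        scan["introgression_index"] = introg_index
        scan["fst_index"] = fst_index
        scan["region"] = regions.labels
        if rho is not None:
            scan["rho"] = rho
            scan["rho_group"] = landscape.quantile_partition(rho, cfg.quantile_k)
        if truth is not None:
            scan["introgressed_truth"] = truth.table["introgressed"].to_numpy()
        if cfg.gff is not None:
            ann = gio.AnnotationIntervals.from_gff3(cfg.gff)
            scan = gio.gene_density(ann, scan)
        scan.to_csv(out / "window_scan.tsv", sep="\t", index=False)
        report["region_counts"] = {
            k: int(v) for k, v in
            pd.Series(regions.labels).value_counts().items()}
        report["introgression_cut"] = regions.introgression_cut
        report["overlap_counts"] = regions.overlap_counts

        stage = "correlations"
        if rho is not None and np.ptp(introg_index) > 0:
            bc = landscape.binned_correlation(introg_index, rho,
                                              n_bins=cfg.n_bins)
            report["introgression_vs_rho"] = {
                "r": bc.r, "p": bc.p, "raw_r": bc.raw_r, "raw_p": bc.raw_p}
        if cfg.gff is not None and np.ptp(introg_index) > 0:
            bc = landscape.binned_correlation(
                introg_index, scan["gene_density"].to_numpy(),
                n_bins=cfg.n_bins)
            report["introgression_vs_gene_density"] = {"r": bc.r, "p": bc.p}

        stage = "topology_weighting"
        if cfg.run_topology_weighting:
            stats = gio.window_site_stats(gm, wtab, min_sites=20, min_pis=4)
            results = []
            group_map = dict(gm.pop_map)
            widx_all = gio.assign_windows(wtab, gm.chrom, gm.pos)
            for w in stats.itertuples(index=False):
                if not w.pass_flag:
                    continue
                m = widx_all == w.window
                if m.sum() < 4:
                    continue
                dist = treekit.p_distance_matrix(gm.dosages[m], gm.samples)
                try:
                    tr = treekit.nj_tree(dist)
                    res = treekit.topology_weighting(
                        tr, group_map, gm.outgroup, method="auto",
                        n_samples=500, seed=cfg.seed + w.window)
                    results.append((w.window, res))
                except ValueError:
                    continue
            if results:
                mt = treekit.main_topologies([r for _, r in results])
                mt.to_csv(out / "topologies.tsv", sep="\t", index=False)
                report["n_weighted_windows"] = len(results)
                report["main_topologies"] = mt[mt["main"]].head(10)[
                    ["topology", "frequency"]].to_dict("records")

        stage = "dfoil"
        if cfg.run_dfoil and species_newick is not None:
            sp_tree = dendropy.Tree.get(data=species_newick, schema="newick")
            # annotate edge lengths from split times for age ordering
            quintets = enumerate_quintets(sp_tree, ingroups, gm.outgroup)
            qrows = []
            for q in quintets:
                c = pattern_counts5(pf.freqs[q.P1], pf.freqs[q.P2],
                                    pf.freqs[q.P3], pf.freqs[q.P4],
                                    n_blocks=cfg.n_blocks)
                r = dfoil_test(c, alpha=cfg.alpha, quintet=q)
                qrows.append({"P1": q.P1, "P2": q.P2, "P3": q.P3, "P4": q.P4,
                              **{k: v for k, v in r.stats.items()},
                              **{f"p_{k}": v for k, v in r.pvalues.items()},
                              "signature": "".join(r.signature),
                              "classification": r.classification})
            pd.DataFrame(qrows).to_csv(out / "quintets.tsv", sep="\t",
                                       index=False)
            report["n_quintets"] = len(qrows)

        stage = "mk"
        if cfg.chronogram and cfg.tip_states:
            from . import traitmk
            chron = dendropy.Tree.get(path=cfg.chronogram, schema="newick")
            chron.is_rooted = True
            states = traitmk.read_tip_states(cfg.tip_states)
            cmp_ = traitmk.fit_and_compare(chron, states, seed=cfg.seed)
            marg = traitmk.marginal_ancestral(chron, states, cmp_.asymmetric
                                              if cmp_.lrt_p < 0.05
                                              else cmp_.symmetric)
            pd.DataFrame(
                [(k, v[0], v[1]) for k, v in marg.items()],
                columns=["clade", "p_state0", "p_state1"],
            ).to_csv(out / "mk_marginals.tsv", sep="\t", index=False)
            report["mk"] = {
                "q01_sym": cmp_.symmetric.q01,
                "q01": cmp_.asymmetric.q01, "q10": cmp_.asymmetric.q10,
                "lrt_p": cmp_.lrt_p,
                "aic": cmp_.aic,
            }
    except Exception as err:
        (out / "FAILED").write_text(f"stage={stage}\n{err!r}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    with open(out / "manifest.json", "w") as fh:
        json.dump({"seed": cfg.seed, "config_hash": cfg.config_hash(),
                   "thresholds": {
                       "alpha": cfg.alpha, "min_snps": cfg.min_snps,
                       "n_blocks": cfg.n_blocks,
                       "top_q_introgression": cfg.top_q_introgression,
                       "top_q_fst": cfg.top_q_fst,
                       "fst_index_threshold": cfg.fst_index_threshold}},
                  fh, indent=2)
    return report
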