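"""Multispecies-coalescent window simulator with dated admixture pulses.

Each genome window carries a single genealogy (no intra-window
recombination; windows are independent), drawn under a species tree with
branch-specific Ne and optional admixture pulses: at a pulse of fraction
``f``, each lineage in the recipient branch is rerouted to the donor branch
with probability ``f`` (backwards in time; the standard instantaneous-pulse
convention).  Mutations follow an infinite-sites model at rate ``mu`` over
``window_len`` bp; genotypes are emitted as biallelic diploid dosages.

The per-window population-scaled recombination rate ``rho`` is an external
covariate only: it never enters the within-window genealogy, but can drive
a recombination-dependent *retention* device in which an introgressed
window survives with probability ``retention(rho)`` and is otherwise
replaced by a fresh species-tree (pulse-free) draw.  Full ground truth
(per-window introgression flags, rho, realized admixture fraction) is
returned alongside the genotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import msprime
import numpy as np
import pandas as pd

from .gio import GenotypeMatrix

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class Pulse:
    """Instantaneous admixture pulse: donor -> recipient (forward in time)."""

    time: float
    donor: str
    recipient: str
    fraction: float


@dataclass
class SpeciesTreeModel:
    """Demography: rooted binary species tree, split times, Ne, mutation rate, pulses.

    Parameters
    ----------
    newick
        Rooted binary tree whose tips are population labels and whose
        internal nodes are named (ancestral branch labels).
    split_times
        internal node label -> time (generations) of the split at that node.
        Times must strictly increase root-ward.
    ne
        branch label (tip or internal node) -> diploid effective size.
        Branches not listed fall back to ``default_ne``.
    mu
        Per-site per-generation mutation rate.
    pulses
        Admixture pulses; each must fall inside the co-existence interval
        of its donor and recipient branches and have fraction in [0, 1].
    """

    newick: str
    split_times: dict
    ne: dict = field(default_factory=dict)
    default_ne: float = 10_000.0
    mu: float = 1e-8
    pulses: list = field(default_factory=list)

    def __post_init__(self):
        self._tree = dendropy.Tree.get(data=self.newick, schema="newick")
        self._children = {}
        self._parent = {}
        labels = set()
        for node in self._tree.preorder_node_iter():
            lab = self._label(node)
            if lab in labels:
                raise ConfigurationError(f"duplicate branch label {lab!r}")
            labels.add(lab)
            if not node.is_leaf():
                kids = node.child_nodes()
                if len(kids) != 2:
                    raise ConfigurationError("species tree must be binary")
                if lab not in self.split_times:
                    raise ConfigurationError(f"no split time for internal node {lab!r}")
                self._children[lab] = [self._label(k) for k in kids]
                for k in kids:
                    self._parent[self._label(k)] = lab
        self._validate_times()
        for p in self.pulses:
            self._validate_pulse(p)

    @staticmethod
    def _label(node) -> str:
        if node.is_leaf():
            return node.taxon.label
        if node.label is None:
            raise ConfigurationError("internal nodes must be labeled")
        return node.label

    @property
    def root_label(self) -> str:
        return self._label(self._tree.seed_node)

    @property
    def tips(self) -> list:
        return [t.label for t in self._tree.taxon_namespace]

    def _validate_times(self):
        for lab, kids in self._children.items():
            t = self.split_times[lab]
            if t <= 0:
                raise ConfigurationError("split times must be positive")
            for k in kids:
                if k in self._children and self.split_times[k] >= t:
                    raise ConfigurationError(
                        f"split times must strictly increase root-ward "
                        f"({k}: {self.split_times[k]} >= {lab}: {t})")

    def branch_interval(self, label: str):
        """[start, end) existence interval of a branch, in generations (pastward)."""
        start = self.split_times.get(label, 0.0) if label in self._children else 0.0
        if label == self.root_label:
            return start, np.inf
        parent = self._parent.get(label)
        if parent is None:
            raise ConfigurationError(f"unknown branch label {label!r}")
        return start, self.split_times[parent]

    def _validate_pulse(self, p: Pulse):
        if not (0.0 <= p.fraction <= 1.0):
            raise ConfigurationError(f"pulse fraction {p.fraction} outside [0, 1]")
        for lab in (p.donor, p.recipient):
            s, e = self.branch_interval(lab)
            if not (s <= p.time < e):
                raise ConfigurationError(
                    f"pulse at t={p.time} outside existence interval "
                    f"[{s}, {e}) of branch {lab!r}")

    def branch_ne(self, label: str) -> float:
        return float(self.ne.get(label, self.default_ne))

    def demography(self, include_pulses: bool = True) -> msprime.Demography:
        dem = msprime.Demography()
        for node in self._tree.postorder_node_iter():
            lab = self._label(node)
            dem.add_population(name=lab, initial_size=self.branch_ne(lab))
        events = []
        for lab, kids in self._children.items():
            events.append(("split", self.split_times[lab], lab, kids))
        if include_pulses:
            for p in self.pulses:
                events.append(("pulse", p.time, p, None))
        # splits before pulses at equal times would deactivate the recipient;
        # order pulses first at ties
        events.sort(key=lambda ev: (ev[1], 0 if ev[0] == "pulse" else 1))
        for kind, t, a, b in events:
            if kind == "split":
                dem.add_population_split(time=t, derived=b, ancestral=a)
            else:
                dem.add_mass_migration(time=t, source=a.recipient, dest=a.donor,
                                       proportion=a.fraction)
        dem.sort_events()
        return dem


@dataclass
class WindowModel:
    """Window grid and covariates for the simulator.

    ``rho`` may be a scalar, a vector of length ``n_windows``, or ``None``
    (a lognormal draw, emulating a genome-wide distribution of
    population-scaled recombination rates).  ``retention`` is an optional
    monotone map rho -> probability in [0, 1] that an introgressed window
    is retained.
    """

    n_windows: int
    window_len: int = 10_000
    rho: object = None
    retention: object = None
    chrom: str = "chr1"

    def rho_vector(self, rng: np.random.Generator) -> np.ndarray:
        if self.rho is None:
            r = rng.lognormal(mean=np.log(5.0), sigma=1.0, size=self.n_windows)
        else:
            r = np.broadcast_to(np.asarray(self.rho, dtype=float),
                                (self.n_windows,)).copy()
        if np.any(r < 0):
            raise ConfigurationError("rho must be >= 0")
        return r


@dataclass
class SimTruth:
    """Ground truth for a simulated dataset."""

    table: pd.DataFrame  # window, chrom, start, end, rho, introgressed, n_migrants
    seed: int

    @property
    def introgressed_fraction(self) -> float:
        return float(self.table["introgressed"].mean())

    def write_tsv(self, path):
        self.table.to_csv(path, sep="\t", index=False)


def _dosages_from_ts(ts, offset: int, window_len: int):
    """Integer positions (1-based, offset applied) and diploid dosages."""
    G = ts.genotype_matrix()  # sites x haplotypes
    dos = G[:, 0::2] + G[:, 1::2]
    pos = np.floor([s.position for s in ts.sites()]).astype(np.int64)
    # infinite-sites positions are continuous; integer collisions are rare --
    # keep the first site at each integer coordinate
    keep = np.concatenate(([True], np.diff(pos) > 0)) if len(pos) else np.array([], bool)
    pos = np.clip(pos[keep], 0, window_len - 1)
    return pos + offset + 1, dos[keep].astype(np.int8)


def _sim_windows(model, samples_per_pop, n_windows, window_len, seed,
                 include_pulses=True):
    """Yield (positions not yet offset) per-window tree sequences with mutations."""
    dem = model.demography(include_pulses=include_pulses)
    sample_sets = [msprime.SampleSet(int(n), population=p, ploidy=2)
                   for p, n in samples_per_pop.items()]
    anc_seed, mut_seed0 = np.random.SeedSequence(seed).generate_state(2) % (2**31 - 1) + 1
    reps = msprime.sim_ancestry(
        samples=sample_sets,
        demography=dem,
        sequence_length=window_len,
        recombination_rate=0,
        record_migrations=include_pulses and bool(model.pulses),
        num_replicates=n_windows,
        random_seed=int(anc_seed),
    )
    mut_seeds = np.random.SeedSequence(int(mut_seed0)).generate_state(n_windows)
    mut_seeds = mut_seeds % (2**31 - 1) + 1
    for i, ts in enumerate(reps):
        mts = msprime.sim_mutations(
            ts, rate=model.mu,
            model=msprime.BinaryMutationModel(),
            discrete_genome=False,
            random_seed=int(mut_seeds[i]),
        )
        yield i, mts


def _window_introgressed(ts, pulses) -> tuple:
    """(flag, n_migrant_lineages): did any lineage take a pulse route?"""
    n = 0
    for mig in ts.migrations():
        for p in pulses:
            if abs(mig.time - p.time) < 1e-9:
                n += 1
                break
    return n > 0, n


def simulate_dataset(model: SpeciesTreeModel, windows: WindowModel,
                     samples_per_pop: dict, seed: int):
    """Simulate genotypes and ground truth over independent windows.

    Returns ``(GenotypeMatrix, SimTruth)``.  Deterministic given ``seed``.
    If ``windows.retention`` is set, each introgressed window is kept with
    probability ``retention(rho)`` and otherwise replaced by a pulse-free
    species-tree draw (and relabeled non-introgressed).
    """
    pops = set(samples_per_pop)
    tips = set(model.tips)
    if not pops <= tips:
        raise ConfigurationError(f"unknown populations: {pops - tips}")
    if len(pops) < 3:
        # single- or two-population draws are legitimate for diversity and
        # calibration checks; site-pattern statistics need >= 3 + outgroup
        logger.info("simulate_dataset: fewer than 3 sampled populations; "
                    "pattern statistics will not be computable downstream")

    ss = np.random.SeedSequence(seed)
    rho_seed, keep_seed, resim_seed = ss.generate_state(3) % (2**31 - 1) + 1
    rng = np.random.default_rng(int(rho_seed))
    rho = windows.rho_vector(rng)

    sample_names = []
    pop_map = {}
    for p, n in samples_per_pop.items():
        for j in range(int(n)):
            name = f"{p}_{j}"
            sample_names.append(name)
            pop_map[name] = p

    per_window = {}
    flags = np.zeros(windows.n_windows, dtype=bool)
    migrants = np.zeros(windows.n_windows, dtype=np.int64)
    for i, mts in _sim_windows(model, samples_per_pop, windows.n_windows,
                               windows.window_len, seed):
        if model.pulses:
            flags[i], migrants[i] = _window_introgressed(mts, model.pulses)
        per_window[i] = mts

    if windows.retention is not None and model.pulses:
        keep_rng = np.random.default_rng(int(keep_seed))
        keep_prob = np.array([float(windows.retention(r)) for r in rho])
        if np.any((keep_prob < 0) | (keep_prob > 1)):
            raise ConfigurationError("retention probabilities must lie in [0, 1]")
        drop = flags & (keep_rng.random(windows.n_windows) >= keep_prob)
        drop_idx = np.nonzero(drop)[0]
        if len(drop_idx):
            for (_, mts), i in zip(
                    _sim_windows(model, samples_per_pop, len(drop_idx),
                                 windows.window_len, int(resim_seed),
                                 include_pulses=False),
                    drop_idx):
                per_window[int(i)] = mts
                flags[int(i)] = False
                migrants[int(i)] = 0

    chroms, poss, rows = [], [], []
    for i in range(windows.n_windows):
        pos, dos = _dosages_from_ts(per_window[i], i * windows.window_len,
                                    windows.window_len)
        chroms.append(np.full(len(pos), windows.chrom, dtype=object))
        poss.append(pos)
        rows.append(dos)
    pos = np.concatenate(poss) if poss else np.array([], np.int64)
    dos = (np.concatenate(rows) if rows
           else np.zeros((0, len(sample_names)), np.int8))
    gm = GenotypeMatrix(
        chrom=np.concatenate(chroms) if chroms else np.array([], object),
        pos=pos,
        ref=np.full(len(pos), "A", dtype=object),
        alt=np.full(len(pos), "T", dtype=object),
        dosages=dos,
        samples=sample_names,
        pop_map=pop_map,
        outgroup=_infer_outgroup(model, samples_per_pop),
    )
    truth = SimTruth(
        table=pd.DataFrame({
            "window": np.arange(windows.n_windows),
            "chrom": windows.chrom,
            "start": np.arange(windows.n_windows) * windows.window_len,
            "end": (np.arange(windows.n_windows) + 1) * windows.window_len,
            "rho": rho,
            "introgressed": flags,
            "n_migrants": migrants,
        }),
        seed=seed,
    )
    return gm, truth


def _infer_outgroup(model: SpeciesTreeModel, samples_per_pop: dict) -> str:
    """The sampled tip whose branch attaches at the root is the outgroup."""
    root_kids = model._children[model.root_label]
    for k in root_kids:
        if k in samples_per_pop:
            return k
    # fall back: deepest-attaching sampled tip
    depth = {p: model.branch_interval(p)[1] for p in samples_per_pop}
    return max(depth, key=depth.get)


def apply_retention(truth: SimTruth, windows: WindowModel, seed: int) -> SimTruth:
    """Label-level retention: keep each introgressed window w.p. retention(rho).

    Returns a new :class:`SimTruth` with dropped windows relabeled
    non-introgressed.  (To also replace the genotypes of dropped windows by
    species-tree draws, pass ``retention`` to :func:`simulate_dataset`,
    which performs the full resimulation.)
    """
    if windows.retention is None:
        raise ConfigurationError("no retention function configured")
    rng = np.random.default_rng(seed)
    tab = truth.table.copy()
    keep_prob = np.array([float(windows.retention(r)) for r in tab["rho"]])
    if np.any((keep_prob < 0) | (keep_prob > 1)):
        raise ConfigurationError("retention probabilities must lie in [0, 1]")
    u = rng.random(len(tab))
    drop = tab["introgressed"].to_numpy() & (u >= keep_prob)
    tab.loc[drop, "introgressed"] = False
    tab.loc[drop, "n_migrants"] = 0
    return SimTruth(table=tab, seed=truth.seed)


# ---------------------------------------------------------------------------
# canned demographies (the package's default study conditions)


def ladder_model(pulses=(), ne: float = 10_000.0, mu: float = 1e-8) -> SpeciesTreeModel:
    """Four ingroups on a ladder tree plus outgroup: ((((P1,P2),P3),P4),O).

    Splits at 10/20/30 kgen with Ne = 10,000 give substantial incomplete
    lineage sorting (internal branches of 0.5 coalescent units); the
    outgroup diverges at 120 kgen.
    """
    return SpeciesTreeModel(
        newick="((((P1,P2)N12,P3)N123,P4)N1234,O)ROOT;",
        split_times={"N12": 10_000, "N123": 20_000, "N1234": 30_000,
                     "ROOT": 120_000},
        default_ne=ne, mu=mu, pulses=list(pulses),
    )


def symmetric_model(pulses=(), ne: float = 10_000.0, mu: float = 1e-8) -> SpeciesTreeModel:
    """Symmetric five-taxon tree (((P1,P2),(P3,P4)),O) for D_FOIL designs.

    The (P3,P4) divergence (30 kgen) predates the (P1,P2) divergence
    (10 kgen), as the five-taxon tests require; the long co-existence of
    the (P1,P2) ancestor with the P3/P4 tip branches (10-30 kgen) gives
    ancestral admixture pulses a detectable footprint.
    """
    return SpeciesTreeModel(
        newick="(((P1,P2)N12,(P3,P4)N34)N1234,O)ROOT;",
        split_times={"N12": 10_000, "N34": 30_000, "N1234": 50_000,
                     "ROOT": 120_000},
        default_ne=ne, mu=mu, pulses=list(pulses),
    )
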