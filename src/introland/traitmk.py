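"""Two-state Mk ancestral-state reconstruction on a dated tree.

Models a binary trait (state 0 = self-compatible, 1 = self-incompatible)
as a continuous-time Markov chain with gain rate q01 (0 -> 1) and loss
rate q10 (1 -> 0) per unit branch time.  Likelihoods use Felsenstein
pruning with the closed-form 2x2 transition matrix; maximum-likelihood
fits compare the symmetric (q01 = q10) and asymmetric models by a 1-df
likelihood-ratio test and AIC; marginal ancestral probabilities combine
root-ward and tip-ward partial likelihoods at every internal node.

The root prior defaults to the stationary distribution of the fitted rate
matrix; a uniform prior is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import optimize, stats as sps

__all__ = ["mk_loglik", "fit_mk", "fit_and_compare", "marginal_ancestral",
           "MkFit", "transition_matrix", "read_tip_states"]


def transition_matrix(q01: float, q10: float, t: float) -> np.ndarray:
    """Closed-form P(t) for the 2-state chain with rates q01, q10."""
    if q01 < 0 or q10 < 0 or t < 0:
        raise ValueError("rates and times must be nonnegative")
    q = q01 + q10
    if q == 0:
        return np.eye(2)
    pi1 = q01 / q
    pi0 = q10 / q
    e = np.exp(-q * t)
    return np.array([
        [pi0 + pi1 * e, pi1 - pi1 * e],
        [pi0 - pi0 * e, pi1 + pi0 * e],
    ])


def stationary(q01: float, q10: float) -> np.ndarray:
    q = q01 + q10
    if q == 0:
        return np.array([0.5, 0.5])
    return np.array([q10 / q, q01 / q])


def _root_prior(q01, q10, root_prior):
    if root_prior == "stationary":
        return stationary(q01, q10)
    if root_prior == "uniform":
        return np.array([0.5, 0.5])
    p = np.asarray(root_prior, float)
    if p.shape != (2,) or not np.isclose(p.sum(), 1.0):
        raise ValueError("root prior must be 'stationary', 'uniform' or a 2-simplex")
    return p


def _check_tree(tree: dendropy.Tree, tip_states: dict):
    tips = [t.taxon.label for t in tree.leaf_node_iter()]
    missing = [t for t in tips if t not in tip_states]
    if missing:
        raise ValueError(f"tips without a state: {missing}")
    bad = {t: tip_states[t] for t in tips if tip_states[t] not in (0, 1)}
    if bad:
        raise ValueError(f"states must be 0/1: {bad}")
    for e in tree.preorder_edge_iter():
        if e.length is not None and e.length < 0:
            raise ValueError("negative branch length")


def _down_pass(tree, tip_states, q01, q10):
    """Post-order conditional likelihoods L[node][s] of the subtree below node."""
    L = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = tip_states[node.taxon.label]
            L[node] = np.array([1.0 - s, float(s)], dtype=float)
        else:
            vec = np.ones(2)
            for child in node.child_nodes():
                P = transition_matrix(q01, q10, child.edge.length or 0.0)
                vec = vec * (P @ L[child])
            L[node] = vec
    return L


def mk_loglik(tree: dendropy.Tree, tip_states: dict, q01: float, q10: float,
              root_prior="stationary") -> float:
    """Log-likelihood of the tip states under the 2-state Mk model."""
    _check_tree(tree, tip_states)
    if q01 < 0 or q10 < 0:
        raise ValueError("rates must be nonnegative")
    L = _down_pass(tree, tip_states, q01, q10)
    pi = _root_prior(q01, q10, root_prior)
    lik = float(pi @ L[tree.seed_node])
    if lik <= 0:
        return -np.inf
    return np.log(lik)


@dataclass
class MkFit:
    q01: float
    q10: float
    logL: float
    model: str                      # 'symmetric' | 'asymmetric'
    root_prior: object = "stationary"
    converged: bool = True
    node_marginals: dict = field(default_factory=dict)

    @property
    def aic(self) -> float:
        k = 1 if self.model == "symmetric" else 2
        return 2 * k - 2 * self.logL


_RATE_BOUNDS = (1e-9, 1e3)


def fit_mk(tree: dendropy.Tree, tip_states: dict, model: str = "asymmetric",
           root_prior="stationary", n_starts: int = 5,
           seed: int | None = 0) -> MkFit:
    """Bounded ML fit of the symmetric (1-d) or asymmetric (2-d) Mk model.

    Rates are optimized on a log scale with multi-start to dodge local
    optima; non-convergence is flagged with the best values found.
    """
    _check_tree(tree, tip_states)
    rng = np.random.default_rng(seed)
    lo, hi = np.log(_RATE_BOUNDS)
    # scale starts to the tree depth so transitions are plausible a priori
    depth = max(nd.distance_from_root() for nd in tree.leaf_node_iter())
    base = np.log(1.0 / max(depth, 1e-9))

    def nll(x):
        if model == "symmetric":
            q01 = q10 = np.exp(x[0])
        else:
            q01, q10 = np.exp(x)
        return -mk_loglik(tree, tip_states, q01, q10, root_prior)

    ndim = 1 if model == "symmetric" else 2
    best = None
    converged = False
    starts = [np.full(ndim, base)]
    for _ in range(n_starts - 1):
        starts.append(base + rng.uniform(-3, 3, size=ndim))
    for x0 in starts:
        res = optimize.minimize(nll, x0, method="L-BFGS-B",
                                bounds=[(lo, hi)] * ndim)
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)
    if model == "symmetric":
        q01 = q10 = float(np.exp(best.x[0]))
    else:
        q01, q10 = (float(v) for v in np.exp(best.x))
    return MkFit(q01=q01, q10=q10, logL=float(-best.fun), model=model,
                 root_prior=root_prior, converged=converged)


@dataclass
class MkComparison:
    symmetric: MkFit
    asymmetric: MkFit
    lrt_stat: float
    lrt_p: float
    degenerate: bool = False

    @property
    def aic(self):
        return {"symmetric": self.symmetric.aic,
                "asymmetric": self.asymmetric.aic}


def fit_and_compare(tree: dendropy.Tree, tip_states: dict,
                    root_prior="stationary", n_starts: int = 5,
                    seed: int | None = 0) -> MkComparison:
    """Fit symmetric and asymmetric models; LRT (1 df) and AIC comparison.

    With all tips in one state the comparison is flagged degenerate (the
    unused rate runs to its bound and the LRT is uninformative).
    """
    sym = fit_mk(tree, tip_states, "symmetric", root_prior,
                 n_starts=n_starts, seed=seed)
    asym = fit_mk(tree, tip_states, "asymmetric", root_prior,
                  n_starts=n_starts, seed=seed)
    # nesting guarantee: asymmetric likelihood can never fall below symmetric
    if asym.logL < sym.logL:
        asym = MkFit(q01=sym.q01, q10=sym.q10, logL=sym.logL,
                     model="asymmetric", root_prior=root_prior,
                     converged=sym.converged)
    stat = max(2 * (asym.logL - sym.logL), 0.0)
    p = float(sps.chi2.sf(stat, df=1))
    states = {tip_states[t.taxon.label] for t in tree.leaf_node_iter()}
    return MkComparison(symmetric=sym, asymmetric=asym, lrt_stat=float(stat),
                        lrt_p=p, degenerate=len(states) < 2)


def marginal_ancestral(tree: dendropy.Tree, tip_states: dict, fit: MkFit,
                       include_tips: bool = False) -> dict:
    """Marginal state probabilities at every internal node (and optionally tips).

    Standard up-down algorithm: the marginal at a node combines the
    down-pass partial likelihood of its subtree with the up-pass partial
    from the rest of the tree through its parent.  Keys are canonical
    clade signatures (sorted, comma-joined tip labels).
    """
    _check_tree(tree, tip_states)
    q01, q10 = fit.q01, fit.q10
    L = _down_pass(tree, tip_states, q01, q10)
    pi = _root_prior(q01, q10, fit.root_prior)
    U = {tree.seed_node: pi.copy()}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            pass
        for child in node.child_nodes():
            # contribution of everything except child's subtree
            sib = np.ones(2)
            for other in node.child_nodes():
                if other is child:
                    continue
                Po = transition_matrix(q01, q10, other.edge.length or 0.0)
                sib = sib * (Po @ L[other])
            above = U[node] * sib
            Pc = transition_matrix(q01, q10, child.edge.length or 0.0)
            U[child] = above @ Pc
    out = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf() and not include_tips:
            continue
        post = U[node] * L[node]
        tot = post.sum()
        clade = ",".join(sorted(t.taxon.label for t in node.leaf_iter()))
        out[clade] = post / tot if tot > 0 else np.array([np.nan, np.nan])
    return out


def read_tip_states(path) -> dict:
    """Tip-state TSV (species, state in {0,1}) -> dict."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", header=None, names=["species", "state"],
                     comment="#")
    return {str(r.species): int(r.state) for r in df.itertuples(index=False)}
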