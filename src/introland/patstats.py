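"""Allele-frequency ABBA-BABA machinery.

Site patterns are counted from per-population derived-allele frequencies
(outgroup-polarized), weighting each site by the probability of drawing
the pattern: ABBA = (1-p1) p2 p3 and BABA = p1 (1-p2) p3.  The D statistic
is (ABBA-BABA)/(ABBA+BABA) with significance from a delete-one block
jackknife; f_hom scales the observed ABBA-BABA excess by the excess under
complete homogenization of P2 by P3; f_dM is the windowed symmetric
(dynamic-donor) admixture statistic used for localizing introgressed
regions (pIRs); the introgression index is the per-window fraction of
significant trios whose pIR set contains the window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TrioSpec", "PatternCounts", "DResult", "pattern_counts", "d_statistic",
    "d_min", "bh_adjust", "f_hom", "f_dm_track", "call_pir",
    "introgression_index",
]


@dataclass(frozen=True)
class TrioSpec:
    P1: str
    P2: str
    P3: str
    O: str

    def __post_init__(self):
        if len({self.P1, self.P2, self.P3, self.O}) != 4:
            raise ValueError("trio labels must be distinct")


@dataclass
class PatternCounts:
    """Frequency-weighted ABBA/BABA sums with per-block partial sums."""

    abba: float
    baba: float
    block_abba: np.ndarray
    block_baba: np.ndarray
    n_sites: int

    @property
    def n_blocks(self) -> int:
        return len(self.block_abba)


@dataclass
class DResult:
    D: float
    Z: float
    p: float
    n_blocks: int
    p_adj: float = np.nan
    defined: bool = True


def _usable(p1, p2, p3):
    m = ~(np.isnan(p1) | np.isnan(p2) | np.isnan(p3))
    return p1[m], p2[m], p3[m]


def block_assignment(n_sites: int, n_blocks: int = 20) -> np.ndarray:
    """Contiguous, equal-site block labels (sizes differ by <= 1)."""
    return (np.arange(n_sites) * n_blocks) // max(n_sites, 1)


def pattern_counts(p1, p2, p3, blocks=None, n_blocks: int = 20) -> PatternCounts:
    """ABBA/BABA sums over polarized sites, partitioned into jackknife blocks."""
    p1, p2, p3 = _usable(np.asarray(p1, float), np.asarray(p2, float),
                         np.asarray(p3, float))
    abba_site = (1 - p1) * p2 * p3
    baba_site = p1 * (1 - p2) * p3
    n = len(p1)
    if blocks is None:
        blocks = block_assignment(n, n_blocks)
    else:
        blocks = np.asarray(blocks)[:n] if len(blocks) != n else np.asarray(blocks)
    nb = int(blocks.max()) + 1 if n else 0
    return PatternCounts(
        abba=float(abba_site.sum()),
        baba=float(baba_site.sum()),
        block_abba=np.bincount(blocks, weights=abba_site, minlength=nb) if n else np.array([]),
        block_baba=np.bincount(blocks, weights=baba_site, minlength=nb) if n else np.array([]),
        n_sites=n,
    )


def d_statistic(counts: PatternCounts) -> DResult:
    """D with Z/p from a delete-one block jackknife."""
    tot = counts.abba + counts.baba
    if tot == 0 or counts.n_blocks < 5:
        return DResult(D=np.nan, Z=np.nan, p=np.nan,
                       n_blocks=counts.n_blocks, defined=False)
    D = (counts.abba - counts.baba) / tot
    g = counts.n_blocks
    loo = np.empty(g)
    for i in range(g):
        a = counts.abba - counts.block_abba[i]
        b = counts.baba - counts.block_baba[i]
        loo[i] = (a - b) / (a + b) if (a + b) != 0 else D
    var = (g - 1) / g * np.sum((loo - loo.mean()) ** 2)
    if var <= 0:
        z = 0.0 if D == 0 else np.inf * np.sign(D)
    else:
        z = D / np.sqrt(var)
    # Student-t tail with g-1 df: the normal tail is anti-conservative for
    # a delete-one jackknife with a modest number of blocks
    p = 2 * sps.t.sf(abs(z), df=g - 1)
    return DResult(D=float(D), Z=float(z), p=float(p), n_blocks=g)


@dataclass
class DminResult:
    """Conservative trio summary: the arrangement minimizing |D|."""

    arrangement: TrioSpec
    result: DResult
    all_results: dict  # (P1,P2,P3) -> DResult
    most_significant: tuple  # ((P1,P2,P3), DResult) with smallest p


def d_min(freqs: dict, taxa, outgroup: str, n_blocks: int = 20) -> DminResult:
    """Evaluate the three (P1,P2;P3) arrangements of an unordered taxon triple.

    Reports the arrangement with minimum |D| (the conservative statistic)
    and, separately, the most significant arrangement (smallest p).
    Arrangements are canonicalized with D >= 0 (P1/P2 ordered so the excess
    pattern is ABBA).
    """
    a, b, c = sorted(taxa)
    results = {}
    for (x, y, z) in ((a, b, c), (a, c, b), (b, c, a)):
        cnt = pattern_counts(freqs[x], freqs[y], freqs[z], n_blocks=n_blocks)
        r = d_statistic(cnt)
        if r.defined and r.D < 0:
            cnt = pattern_counts(freqs[y], freqs[x], freqs[z], n_blocks=n_blocks)
            r = d_statistic(cnt)
            results[(y, x, z)] = r
        else:
            results[(x, y, z)] = r
    defined = {k: v for k, v in results.items() if v.defined}
    if not defined:
        raise ValueError("D undefined for every arrangement")
    min_key = min(defined, key=lambda k: abs(defined[k].D))
    sig_key = min(defined, key=lambda k: defined[k].p)
    return DminResult(
        arrangement=TrioSpec(*min_key, outgroup),
        result=defined[min_key],
        all_results=results,
        most_significant=(sig_key, defined[sig_key]),
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def f_hom(p1, p2, p3, n3_haplotypes: int | None = None) -> float:
    """Admixture fraction: S(P1,P2,P3,O) / S(P1,P3,P3,O).

    The denominator substitutes P3 for P2 (complete homogenization of P2
    by the donor P3).  The squared donor frequency uses the unbiased
    two-draw estimator p(np-1)/(n-1) when the donor haplotype count
    ``n3_haplotypes`` is given — equivalent to the standard practice of
    splitting the donor population in half, and removing the finite-sample
    inflation of the denominator.  Returns NaN if the denominator
    vanishes.
    """
    p1, p2, p3 = _usable(np.asarray(p1, float), np.asarray(p2, float),
                         np.asarray(p3, float))
    num = np.sum((1 - p1) * p2 * p3 - p1 * (1 - p2) * p3)
    if n3_haplotypes is not None and n3_haplotypes >= 2:
        n = n3_haplotypes
        p3sq = p3 * (n * p3 - 1) / (n - 1)
    else:
        p3sq = p3 * p3
    den = np.sum((1 - p1) * p3sq - p1 * (p3 - p3sq))
    if den == 0:
        return np.nan
    return float(num / den)


def f_hom_max_by_pair(trio_table: pd.DataFrame) -> pd.DataFrame:
    """Max f_hom per (P2, P3) pair over all P1 choices (the reported summary)."""
    t = trio_table.dropna(subset=["f_hom"])
    idx = t.groupby(["P2", "P3"])["f_hom"].idxmax()
    return t.loc[idx, ["P2", "P3", "P1", "f_hom"]].reset_index(drop=True)


def _fdm_site_terms(p1, p2, p3):
    """Per-site f_dM numerator and dynamic-donor denominator terms."""
    num = (1 - p1) * p2 * p3 - p1 * (1 - p2) * p3
    den = np.empty_like(num)
    up = p2 >= p1  # P2 side: donor is whichever of (P2, P3) is more derived
    pd_ = np.maximum(p2, p3)
    den[up] = ((1 - p1) * pd_ * pd_ - p1 * (1 - pd_) * pd_)[up]
    pd1 = np.maximum(p1, p3)
    den[~up] = -((1 - pd1) * p2 * pd1 - pd1 * (1 - p2) * pd1)[~up]
    return num, den


@dataclass
class FdmTrack:
    """Per-window f_dM values for one trio (NaN where masked)."""

    windows: pd.DataFrame  # window grid
    values: np.ndarray
    n_snps: np.ndarray
    min_snps: int
    trio: TrioSpec | None = None

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)


def f_dm_track(p1, p2, p3, window_index, windows: pd.DataFrame,
               min_snps: int = 10, trio: TrioSpec | None = None) -> FdmTrack:
    """Windowed f_dM with the symmetric dynamic-donor denominator.

    ``window_index`` assigns each polarized site to a window row (index into
    ``windows``; -1 = outside).  Windows with fewer than ``min_snps``
    usable SNPs are masked.  Values are clipped to [-1, 1] only through the
    estimator's own bounds (no post-hoc clamping).
    """
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    p3 = np.asarray(p3, float)
    wi = np.asarray(window_index)
    ok = (wi >= 0) & ~(np.isnan(p1) | np.isnan(p2) | np.isnan(p3))
    # monomorphic-in-trio sites carry no pattern weight but still count as SNPs
    num, den = _fdm_site_terms(p1[ok], p2[ok], p3[ok])
    n = len(windows)
    wi = wi[ok]
    n_snps = np.bincount(wi, minlength=n)
    num_w = np.bincount(wi, weights=num, minlength=n)
    den_w = np.bincount(wi, weights=den, minlength=n)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(den_w != 0, num_w / den_w, np.nan)
    vals = np.where(n_snps >= min_snps, vals, np.nan)
    return FdmTrack(windows=windows, values=vals, n_snps=n_snps,
                    min_snps=min_snps, trio=trio)


def call_pir(track: FdmTrack, x_percent: float) -> np.ndarray:
    """Flag the top-x% f_dM windows (pIRs) as a boolean mask over windows.

    ``x_percent`` defaults in the pipeline to 100 * f_hom for the trio;
    negative f_hom means x = 0 (no pIRs).  Exactly ceil(x/100 * n_defined)
    windows are flagged, ties at the cutoff broken by genomic order.
    """
    if not (0.0 <= x_percent <= 100.0):
        raise ValueError("x_percent must lie in [0, 100]")
    defined = track.defined
    n_def = int(defined.sum())
    k = int(np.ceil(x_percent / 100.0 * n_def))
    return top_k_mask(track.values, k)


def top_k_mask(values: np.ndarray, k: int) -> np.ndarray:
    """Mask of the k largest defined values; ties broken by position order."""
    mask = np.zeros(len(values), dtype=bool)
    if k <= 0:
        return mask
    defined_idx = np.nonzero(~np.isnan(values))[0]
    if len(defined_idx) == 0:
        return mask
    k = min(k, len(defined_idx))
    # sort by (-value, genomic position): stable, exact count
    order = defined_idx[np.lexsort((defined_idx, -values[defined_idx]))]
    mask[order[:k]] = True
    return mask


@dataclass
class IntrogressionIndexTrack:
    windows: pd.DataFrame
    index: np.ndarray            # fraction of contributing trios flagging the window
    n_trios: np.ndarray          # trios with the window defined
    pir_members: dict            # trio -> boolean mask


def introgression_index(pir_sets: dict, defined_sets: dict,
                        windows: pd.DataFrame) -> IntrogressionIndexTrack:
    """Per-window fraction of significant trios whose pIR set contains the window.

    ``pir_sets``/``defined_sets`` map each contributing (significance-gated)
    trio to its pIR mask and defined-window mask.
    """
    if not pir_sets:
        raise ValueError("no contributing trios")
    n = len(windows)
    flagged = np.zeros(n)
    evaluated = np.zeros(n)
    for trio, mask in pir_sets.items():
        flagged += mask.astype(float)
        evaluated += defined_sets[trio].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        idx = np.where(evaluated > 0, flagged / evaluated, np.nan)
    return IntrogressionIndexTrack(windows=windows, index=idx,
                                   n_trios=evaluated.astype(int),
                                   pir_members=dict(pir_sets))
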