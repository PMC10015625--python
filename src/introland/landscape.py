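"""Windowed differentiation landscape: F_ST, outlier indices, region classes,
recombination-quintile partitions, binned correlations and sweep intersection.

F_ST uses the Weir & Cockerham (1984) estimator with the windowed
ratio-of-sums (weighted) form: window value = sum(a) / sum(a+b+c) over the
per-site variance components, matching the convention of the standard VCF
tooling.  Negative window values are reported unclamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .gio import GenotypeMatrix, MISSING, assign_windows
from .patstats import top_k_mask

__all__ = ["fst_windows", "wc_fst_components", "outlier_index",
           "classify_regions", "quantile_partition", "binned_correlation",
           "sweep_intersect", "FstTrack", "BinnedCorrelation"]


def wc_fst_components(dosages_a: np.ndarray, dosages_b: np.ndarray):
    """Per-site Weir-Cockerham variance components (a, b, c) for two populations.

    Dosages are (n_sites, n_samples) alt-allele counts per diploid with -1
    missing.  Sites with fewer than two genotyped diploids in either
    population get NaN components.  Heterozygote counts come directly from
    dosage == 1.
    """
    r = 2  # number of populations
    comps = []
    for d in (dosages_a, dosages_b):
        d = np.asarray(d, float)
        d = np.where(d == MISSING, np.nan, d)
        n_i = np.sum(~np.isnan(d), axis=1).astype(float)     # diploids sampled
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.nansum(d, axis=1) / (2 * n_i)
        h_i = np.sum(d == 1, axis=1) / np.where(n_i > 0, n_i, np.nan)
        comps.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = comps
    usable = (n1 >= 2) & (n2 >= 2)
    n1 = np.where(usable, n1, np.nan)
    n2 = np.where(usable, n2, np.nan)
    n_bar = (n1 + n2) / r
    n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1))
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - (r - 1) / r * s2
        - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
    c = h_bar / 2
    return a, b, c


@dataclass
class FstTrack:
    windows: pd.DataFrame
    values: np.ndarray
    n_sites: np.ndarray
    pair: tuple
    estimator: str = "weir-cockerham"

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)


def fst_windows(gm: GenotypeMatrix, pop_a: str, pop_b: str,
                windows: pd.DataFrame) -> FstTrack:
    """Windowed Weir-Cockerham F_ST (ratio of sums) for a population pair."""
    ia, ib = gm.sample_indices(pop_a), gm.sample_indices(pop_b)
    a, b, c = wc_fst_components(gm.dosages[:, ia], gm.dosages[:, ib])
    ok = ~np.isnan(a)
    wi = assign_windows(windows, gm.chrom, gm.pos)
    use = ok & (wi >= 0)
    n = len(windows)
    num = np.bincount(wi[use], weights=a[use], minlength=n)
    den = np.bincount(wi[use], weights=(a + b + c)[use], minlength=n)
    n_sites = np.bincount(wi[use], minlength=n)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(den != 0, num / den, np.nan)
    vals = np.where(n_sites > 0, vals, np.nan)
    return FstTrack(windows=windows, values=vals, n_sites=n_sites,
                    pair=(pop_a, pop_b))


def outlier_index(tracks, top_q: float = 0.05) -> np.ndarray:
    """Per-window fraction of tracks for which the window is a top-q outlier.

    Each track contributes its ceil(q * n_defined) largest windows (ties
    broken by genomic order).  Windows undefined in a track count as
    unflagged for that track.
    """
    tracks = list(tracks)
    if not tracks:
        raise ValueError("need >= 1 track")
    arrays = [t.values if hasattr(t, "values") else np.asarray(t, float)
              for t in tracks]
    n = len(arrays[0])
    flagged = np.zeros(n)
    for v in arrays:
        k = int(np.ceil(top_q * np.sum(~np.isnan(v))))
        flagged += top_k_mask(v, k)
    return flagged / len(arrays)


@dataclass
class RegionClassification:
    windows: pd.DataFrame
    labels: np.ndarray                # per-window class label
    introgression_cut: float          # realized top-q threshold actually used
    fst_threshold: float
    overlap_counts: dict              # class-pair overlap summary


def classify_regions(introg_index: np.ndarray, fst_index: np.ndarray,
                     windows: pd.DataFrame, top_q: float = 0.05,
                     fst_threshold: float = 1.0 / 3.0) -> RegionClassification:
    """Label windows as high/low introgression and high-F_ST regions.

    high_introgression: top-q of the introgression index (ties by genomic
    order; the realized cut value is reported, not assumed);
    low_introgression: index exactly 0; high_fst: F_ST index strictly above
    ``fst_threshold``.  A window can be both high-F_ST and an introgression
    class; the primary label then stays with the introgression class and
    the overlap is counted separately.
    """
    introg_index = np.asarray(introg_index, float)
    fst_index = np.asarray(fst_index, float)
    n = len(windows)
    k = int(np.ceil(top_q * np.sum(~np.isnan(introg_index))))
    # a zero index can never mark a high-introgression region: mask zeros
    # out before the top-q cut so an all-zero track yields no highs
    eligible = np.where(introg_index > 0, introg_index, np.nan)
    high_i = top_k_mask(eligible, k)
    low_i = introg_index == 0
    high_f = fst_index > fst_threshold
    cut = float(np.nanmin(introg_index[high_i])) if high_i.any() else np.nan
    labels = np.full(n, "other", dtype=object)
    labels[low_i] = "low_introgression"
    labels[high_i] = "high_introgression"
    only_f = high_f & ~(high_i | low_i)
    labels[only_f] = "high_fst"
    overlap = {
        "high_fst_and_high_introgression": int(np.sum(high_f & high_i)),
        "high_fst_and_low_introgression": int(np.sum(high_f & low_i)),
        "n_high_introgression": int(high_i.sum()),
        "n_low_introgression": int(low_i.sum()),
        "n_high_fst": int(high_f.sum()),
    }
    return RegionClassification(windows=windows, labels=labels,
                                introgression_cut=cut,
                                fst_threshold=fst_threshold,
                                overlap_counts=overlap)


def quantile_partition(covariate: np.ndarray, k: int = 5) -> np.ndarray:
    """Equal-count groups 0..k-1 (low to high), ties broken by position order.

    Group sizes differ by at most one; the larger groups come first.
    Undefined (NaN) entries get -1.
    """
    covariate = np.asarray(covariate, float)
    defined = np.nonzero(~np.isnan(covariate))[0]
    if len(defined) < k:
        raise ValueError("covariate defined on fewer windows than groups")
    order = defined[np.lexsort((defined, covariate[defined]))]
    out = np.full(len(covariate), -1, dtype=np.int64)
    n = len(order)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    start = 0
    for g, s in enumerate(sizes):
        out[order[start:start + s]] = g
        start += s
    return out


@dataclass
class BinnedCorrelation:
    bin_mean_covariate: np.ndarray
    bin_mean_response: np.ndarray
    r: float
    p: float
    slope: float
    intercept: float
    n_bins: int
    raw_r: float
    raw_p: float
    degenerate: bool = False


def binned_correlation(response: np.ndarray, covariate: np.ndarray,
                       n_bins: int = 20) -> BinnedCorrelation:
    """Pearson correlation between equal-count-bin means (as plotted in
    genome-scan figures), plus the raw per-window correlation.

    Windows where either variable is NaN are dropped.  A constant response
    or covariate yields r = 0 with the degenerate flag.
    """
    response = np.asarray(response, float)
    covariate = np.asarray(covariate, float)
    ok = ~(np.isnan(response) | np.isnan(covariate))
    x, y = covariate[ok], response[ok]
    groups = quantile_partition(x, k=n_bins) if len(x) >= n_bins else None
    if groups is None or len(np.unique(groups)) < 3:
        raise ValueError("fewer than 3 non-empty bins")
    bx = np.array([x[groups == g].mean() for g in range(n_bins)])
    by = np.array([y[groups == g].mean() for g in range(n_bins)])
    if np.ptp(by) == 0 or np.ptp(bx) == 0:
        return BinnedCorrelation(bx, by, 0.0, 1.0, 0.0, float(by.mean()),
                                 n_bins, 0.0, 1.0, degenerate=True)
    r, p = sps.pearsonr(bx, by)
    lr = sps.linregress(bx, by)
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        raw_r, raw_p = 0.0, 1.0
    else:
        raw_r, raw_p = sps.pearsonr(x, y)
    return BinnedCorrelation(bx, by, float(r), float(p), float(lr.slope),
                             float(lr.intercept), n_bins,
                             float(raw_r), float(raw_p))


def sweep_intersect(tracks_a, track_b, top_a: float = 0.01,
                    top_b: float = 0.05) -> np.ndarray:
    """High-confidence sweep windows from two independent score tracks.

    Union over reference comparisons of the top-``top_a`` windows of each
    track in ``tracks_a`` (e.g. cross-population haplotype scores against
    each reference), deduplicated, intersected with the top-``top_b``
    windows of ``track_b`` (e.g. a composite sweep score).  Returns a
    boolean mask over windows.
    """
    arrays = [t.values if hasattr(t, "values") else np.asarray(t, float)
              for t in tracks_a]
    vb = track_b.values if hasattr(track_b, "values") else np.asarray(track_b, float)
    union = np.zeros(len(vb), dtype=bool)
    for v in arrays:
        k = int(np.ceil(top_a * np.sum(~np.isnan(v))))
        union |= top_k_mask(v, k)
    kb = int(np.ceil(top_b * np.sum(~np.isnan(vb))))
    return union & top_k_mask(vb, kb)
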