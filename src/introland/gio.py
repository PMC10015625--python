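"""Genotype I/O: filtered VCF reading, polarization, window tables and site stats.

The central container is :class:`GenotypeMatrix`: biallelic derived-allele
dosages (0/1/2, -1 = missing) per site x sample, with a sample->population
map and a designated outgroup population.  All downstream site-pattern
statistics are computed from per-population derived-allele frequencies
produced by :func:`polarize`.

Coordinate conventions: VCF positions are 1-based as read; windows and
annotation intervals are 0-based half-open internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages with population structure.

    Attributes
    ----------
    chrom, pos, ref, alt
        Per-site arrays; ``pos`` is 1-based (VCF convention).
    dosages
        ``(n_sites, n_samples)`` int8 array of alt-allele dosages in
        {0, 1, 2}; -1 marks a missing genotype.
    samples
        Sample names, in column order.
    pop_map
        sample name -> population label.
    outgroup
        Population label used for polarization.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosages: np.ndarray
    samples: list
    pop_map: dict
    outgroup: str

    def __post_init__(self):
        missing_pop = [s for s in self.samples if s not in self.pop_map]
        if missing_pop:
            raise ValueError(f"samples absent from population map: {missing_pop}")
        if self.outgroup not in set(self.pop_map.values()):
            raise ValueError(f"outgroup population {self.outgroup!r} not in pop_map")
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2 or self.dosages.shape[1] != len(self.samples):
            raise ValueError("dosages must be (n_sites, n_samples)")

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[0]

    @property
    def populations(self) -> list:
        """Population labels in stable (first-appearance) order, outgroup last."""
        seen = []
        for s in self.samples:
            p = self.pop_map[s]
            if p not in seen:
                seen.append(p)
        if self.outgroup in seen:
            seen.remove(self.outgroup)
            seen.append(self.outgroup)
        return seen

    @property
    def ingroups(self) -> list:
        return [p for p in self.populations if p != self.outgroup]

    def sample_indices(self, pop: str) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.samples) if self.pop_map[s] == pop],
            dtype=int,
        )

    def subset_sites(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            dosages=self.dosages[mask],
            samples=list(self.samples),
            pop_map=dict(self.pop_map),
            outgroup=self.outgroup,
        )


@dataclass
class VcfFilters:
    """Site filters applied on VCF import.

    Defaults mirror a conservative resequencing workflow: biallelic SNPs
    only, at most 67% missing genotypes, minimum site quality 30, and
    mean-depth bounds (no-ops when the VCF carries no DP field, as for
    simulated data).  Any filter can be disabled by setting it to ``None``.
    """

    biallelic_only: bool = True
    max_missing_fraction: float | None = 0.67
    min_quality: float | None = 30.0
    mean_depth_bounds: tuple | None = (10.0, 500.0)


def read_pop_map(path) -> dict:
    """Two-column TSV (sample, population) -> dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"],
                     dtype=str, comment="#")
    return dict(zip(df["sample"], df["population"]))


def read_vcf_filtered(path, pop_map: dict, outgroup: str,
                      filters: VcfFilters | None = None) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`, dropping sites that fail filters.

    Indels are always dropped.  Per-rule drop counts are logged.
    """
    from cyvcf2 import VCF

    filters = filters if filters is not None else VcfFilters()
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    absent = [s for s in samples if s not in pop_map]
    if absent:
        raise ValueError(f"VCF samples absent from population map: {absent}")

    chroms, poss, refs, alts, rows = [], [], [], [], []
    dropped = {"indel": 0, "multiallelic": 0, "missing": 0, "quality": 0, "depth": 0}
    n_samples = len(samples)
    for var in vcf:
        if var.is_indel:
            dropped["indel"] += 1
            continue
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            if filters.biallelic_only:
                dropped["multiallelic"] += 1
                continue
            else:
                # non-SNP sites are unusable for dosage statistics regardless
                dropped["multiallelic"] += 1
                continue
        if filters.min_quality is not None and var.QUAL is not None:
            if var.QUAL < filters.min_quality:
                dropped["quality"] += 1
                continue
        # gts012: 0/1/2 dosage, 3 = missing
        gts = np.asarray(var.gt_types, dtype=np.int8)
        miss = gts == 3
        if filters.max_missing_fraction is not None:
            if miss.sum() / n_samples > filters.max_missing_fraction:
                dropped["missing"] += 1
                continue
        if filters.mean_depth_bounds is not None:
            try:
                dp = var.format("DP")
            except Exception:
                dp = None
            if dp is not None:
                mean_dp = float(np.nanmean(np.where(dp < 0, np.nan, dp)))
                lo, hi = filters.mean_depth_bounds
                if not (lo <= mean_dp <= hi):
                    dropped["depth"] += 1
                    continue
        gts = np.where(miss, MISSING, gts)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        rows.append(gts)
    logger.info("read_vcf_filtered: retained %d sites, dropped %s", len(rows), dropped)
    dos = np.array(rows, dtype=np.int8) if rows else np.zeros((0, n_samples), np.int8)
    return GenotypeMatrix(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        dosages=dos,
        samples=samples,
        pop_map=dict(pop_map),
        outgroup=outgroup,
    )


def write_vcf(gm: GenotypeMatrix, path, contig_lengths: dict | None = None) -> None:
    """Write a minimal VCF 4.2 with diploid GT fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=introland\n")
        if contig_lengths:
            for c, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={c},length={int(ln)}>\n")
        else:
            for c in pd.unique(pd.Series(gm.chrom)):
                fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for i in range(gm.n_sites):
            gts = "\t".join(gt_strings[int(d)] for d in gm.dosages[i])
            fh.write(f"{gm.chrom[i]}\t{int(gm.pos[i])}\t.\t{gm.ref[i]}\t{gm.alt[i]}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


def write_pop_map(pop_map: dict, path) -> None:
    with open(path, "w") as fh:
        for s, p in pop_map.items():
            fh.write(f"{s}\t{p}\n")


# ---------------------------------------------------------------------------
# polarization


@dataclass
class PolarizedFreqs:
    """Per-site derived-allele frequencies per population.

    ``freqs[pop]`` is an array of derived frequencies over retained
    (polarizable) sites; NaN where the population has no genotyped sample.
    ``site_index`` maps each retained row back into the source matrix.
    """

    chrom: np.ndarray
    pos: np.ndarray
    freqs: dict
    site_index: np.ndarray
    n_dropped_outgroup: int = 0
    n_haplotypes: dict = field(default_factory=dict)  # pop -> 2 x samples

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def pop_freqs(self, *pops):
        return tuple(self.freqs[p] for p in pops)


def polarize(gm: GenotypeMatrix, outgroup_fixed_threshold: float = 1.0) -> PolarizedFreqs:
    """Polarize sites by the outgroup and return per-population derived frequencies.

    The ancestral allele is the allele fixed in the outgroup (at frequency
    >= ``outgroup_fixed_threshold``; default strict fixation).  Sites where
    the outgroup is polymorphic below the threshold, or entirely missing,
    are dropped.  Derived frequency per population = derived dosage sum /
    (2 x non-missing diploids).
    """
    og_idx = gm.sample_indices(gm.outgroup)
    if len(og_idx) == 0:
        raise ValueError("no samples in outgroup population")
    og = gm.dosages[:, og_idx].astype(float)
    og_missing = og == MISSING
    og = np.where(og_missing, np.nan, og)
    n_og = 2 * (~og_missing).sum(axis=1)
    with np.errstate(invalid="ignore"):
        og_alt_freq = np.nansum(og, axis=1) / np.where(n_og == 0, np.nan, n_og)

    tol = 1e-9  # guard the fixation threshold against float representation
    alt_derived = og_alt_freq <= (1.0 - outgroup_fixed_threshold) + tol
    ref_derived = og_alt_freq >= outgroup_fixed_threshold - tol
    keep = (alt_derived | ref_derived) & (n_og > 0)
    n_dropped = int((~keep).sum())

    idx = np.nonzero(keep)[0]
    freqs = {}
    n_haplotypes = {}
    for pop in gm.populations:
        pidx = gm.sample_indices(pop)
        n_haplotypes[pop] = 2 * len(pidx)
        d = gm.dosages[np.ix_(idx, pidx)].astype(float)
        miss = d == MISSING
        d = np.where(miss, np.nan, d)
        n = 2 * (~miss).sum(axis=1)
        with np.errstate(invalid="ignore"):
            alt_freq = np.nansum(d, axis=1) / np.where(n == 0, np.nan, n)
        derived = np.where(ref_derived[idx], 1.0 - alt_freq, alt_freq)
        freqs[pop] = derived
    logger.info("polarize: %d sites retained, %d dropped (outgroup rule)",
                len(idx), n_dropped)
    return PolarizedFreqs(
        chrom=gm.chrom[idx],
        pos=gm.pos[idx],
        freqs=freqs,
        site_index=idx,
        n_dropped_outgroup=n_dropped,
        n_haplotypes=n_haplotypes,
    )


# ---------------------------------------------------------------------------
# windows


def make_windows(contig_lengths: dict, width: int = 10_000) -> pd.DataFrame:
    """Nonoverlapping fixed-width windows (0-based half-open) over contigs."""
    rows = []
    for chrom, length in contig_lengths.items():
        for start in range(0, int(length), width):
            rows.append((chrom, start, min(start + width, int(length))))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df.insert(0, "window", np.arange(len(df)))
    return df


def assign_windows(windows: pd.DataFrame, chrom, pos) -> np.ndarray:
    """Window index for each (chrom, 1-based pos); -1 if outside all windows."""
    out = np.full(len(pos), -1, dtype=np.int64)
    pos0 = np.asarray(pos) - 1  # to 0-based
    chrom = np.asarray(chrom)
    for c, sub in windows.groupby("chrom", sort=False):
        m = chrom == c
        if not m.any():
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        wi = sub["window"].to_numpy()
        j = np.searchsorted(starts, pos0[m], side="right") - 1
        ok = (j >= 0) & (pos0[m] < ends[np.clip(j, 0, len(ends) - 1)])
        res = np.where(ok, wi[np.clip(j, 0, len(wi) - 1)], -1)
        out[np.nonzero(m)[0]] = res
    return out


def window_site_stats(gm: GenotypeMatrix, windows: pd.DataFrame,
                      min_sites: int = 200, min_pis: int = 20) -> pd.DataFrame:
    """Per-window site counts, parsimony-informative site counts and pass flag.

    A parsimony-informative site carries >= 2 alleles each observed on >= 2
    haplotypes (allele copies counted from dosages).  ``pass_flag`` is
    ``n_sites >= min_sites and n_pis >= min_pis``.
    """
    d = gm.dosages.astype(float)
    d = np.where(d == MISSING, np.nan, d)
    n_called = 2 * np.sum(~np.isnan(d), axis=1)
    alt_count = np.nansum(d, axis=1)
    ref_count = n_called - alt_count
    is_pis = (alt_count >= 2) & (ref_count >= 2)

    widx = assign_windows(windows, gm.chrom, gm.pos)
    n = len(windows)
    n_sites = np.bincount(widx[widx >= 0], minlength=n)
    n_pis = np.bincount(widx[(widx >= 0) & is_pis], minlength=n)
    out = windows.copy()
    out["n_sites"] = n_sites
    out["n_pis"] = n_pis
    out["pass_flag"] = (n_sites >= min_sites) & (n_pis >= min_pis)
    return out


# ---------------------------------------------------------------------------
# annotation / gene density


@dataclass
class AnnotationIntervals:
    """Merged gene intervals per chromosome (0-based half-open)."""

    intervals: dict = field(default_factory=dict)
    feature_type: str = "gene"

    @staticmethod
    def merge(pairs) -> np.ndarray:
        arr = sorted((int(s), int(e)) for s, e in pairs if e > s)
        merged = []
        for s, e in arr:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return np.array(merged, dtype=np.int64).reshape(-1, 2)

    @classmethod
    def from_pairs(cls, per_chrom: dict, feature_type: str = "gene"):
        return cls({c: cls.merge(p) for c, p in per_chrom.items()}, feature_type)

    @classmethod
    def from_gff3(cls, path, feature_type: str = "gene"):
        import gffutils

        db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                                keep_order=True)
        per_chrom: dict = {}
        for feat in db.features_of_type(feature_type):
            # GFF3 is 1-based closed; convert to 0-based half-open
            per_chrom.setdefault(feat.seqid, []).append((feat.start - 1, feat.end))
        return cls.from_pairs(per_chrom, feature_type)


def gene_density(ann: AnnotationIntervals, windows: pd.DataFrame) -> pd.DataFrame:
    """Fraction of each window covered by (merged) gene intervals."""
    out = windows.copy()
    dens = np.zeros(len(windows))
    for i, row in enumerate(windows.itertuples(index=False)):
        iv = ann.intervals.get(row.chrom)
        if iv is None or len(iv) == 0:
            continue
        s = np.maximum(iv[:, 0], row.start)
        e = np.minimum(iv[:, 1], row.end)
        cov = np.sum(np.maximum(e - s, 0))
        dens[i] = cov / (row.end - row.start)
    out["gene_density"] = dens
    return out
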