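"""Windowed diversity and differentiation with invariant-site accounting.

pi and dxy are average pairwise differences per site, with denominators
counting every allele comparison at every site with data — variant and
invariant alike — so that sparse variant density never inflates diversity.
FST is Hudson's estimator as a ratio of window totals:
``1 - mean(pi_A, pi_B) / dxy``. Net divergence d_a = dxy - (d_x + d_y)/2
and T = d_a / (2 * lambda) with lambda a per-year mutation rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

__all__ = [
    "WindowStat",
    "DivergenceEstimate",
    "window_stats",
    "window_stats_frame",
    "net_divergence",
    "migration_rate",
    "ld_r2",
    "polarized_sfs",
    "hwe_exact_test",
]


@dataclass(frozen=True)
class WindowStat:
    """Summary statistics for one genomic window (0-based half-open)."""

    chrom: str
    start: int
    end: int
    pi_a: float | None
    pi_b: float | None
    dxy: float | None
    fst: float | None
    n_sites: int          # sites with data in both groups
    n_comparisons: float  # between-group allele comparisons
    n_differences: float  # between-group allele differences


@dataclass(frozen=True)
class DivergenceEstimate:
    """Region-wide net-divergence dating.

    ``t_years`` may be negative when within-group diversity exceeds
    between-group divergence; it is reported, not clipped.
    """

    region: str
    d_x: float
    d_y: float
    d_xy: float
    d_a: float
    lam_per_year: float
    t_years: float
    t_generations: float
    negative: bool


def _pair_counts(gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Within-group per-site (difference, comparison) pair counts.

    For a site with a called alt alleles out of c, the number of differing
    unordered allele pairs is a*(c-a) and the total is c*(c-1)/2.
    """
    called = gt != MISSING
    c = 2 * called.sum(axis=0)
    a = np.where(called, gt, 0).sum(axis=0)
    return (a * (c - a)).astype(float), (c * (c - 1) / 2.0)


def _cross_counts(gt_a: np.ndarray, gt_b: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Between-group per-site (difference, comparison) pair counts."""
    called_a = gt_a != MISSING
    called_b = gt_b != MISSING
    ca = 2 * called_a.sum(axis=0)
    cb = 2 * called_b.sum(axis=0)
    aa = np.where(called_a, gt_a, 0).sum(axis=0)
    ab = np.where(called_b, gt_b, 0).sum(axis=0)
    diffs = aa * (cb - ab) + (ca - aa) * ab
    return diffs.astype(float), (ca * cb).astype(float)


def _ratio(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def window_stats(matrix: GenotypeMatrix,
                 group_a: Sequence[str],
                 group_b: Sequence[str],
                 window_bp: int = 20_000,
                 step_bp: int | None = None,
                 span: tuple[int, int] | None = None) -> list[WindowStat]:
    """Windowed pi (per group), dxy and Hudson FST.

    Windows are fixed-width on the physical axis (default 20 kb,
    non-overlapping unless ``step_bp`` is given). A window with zero
    comparisons reports missing statistics, never zeros; FST is missing
    where dxy is zero.
    """
    step_bp = step_bp or window_bp
    ia = matrix.sample_indices(group_a)
    ib = matrix.sample_indices(group_b)
    out: list[WindowStat] = []
    pos0 = matrix.sites["pos"].to_numpy() - 1
    for chrom in dict.fromkeys(matrix.sites["chrom"]):
        on_chrom = (matrix.sites["chrom"] == chrom).to_numpy()
        p = pos0[on_chrom]
        gt_a = matrix.genotypes[np.ix_(ia, np.flatnonzero(on_chrom))]
        gt_b = matrix.genotypes[np.ix_(ib, np.flatnonzero(on_chrom))]
        lo, hi = span if span is not None else (0, int(p.max()) + 1 if len(p) else 0)
        start = lo
        while start < hi:
            end = min(start + window_bp, hi)
            m = (p >= start) & (p < end)
            out.append(_one_window(chrom, start, end, gt_a[:, m], gt_b[:, m]))
            start += step_bp
    return out


def _one_window(chrom: str, start: int, end: int,
                gt_a: np.ndarray, gt_b: np.ndarray) -> WindowStat:
    da, ca = _pair_counts(gt_a)
    db, cb = _pair_counts(gt_b)
    dab, cab = _cross_counts(gt_a, gt_b)
    pi_a = _ratio(da.sum(), ca.sum())
    pi_b = _ratio(db.sum(), cb.sum())
    dxy = _ratio(dab.sum(), cab.sum())
    fst = None
    if dxy is not None and pi_a is not None and pi_b is not None and dxy > 0:
        fst = 1.0 - 0.5 * (pi_a + pi_b) / dxy
    n_sites = int((cab > 0).sum())
    return WindowStat(chrom, start, end, pi_a, pi_b, dxy, fst,
                      n_sites, float(cab.sum()), float(dab.sum()))


def window_stats_frame(stats: Sequence[WindowStat]) -> pd.DataFrame:
    """Tabulate window statistics with 1-based inclusive coordinates."""
    return pd.DataFrame({
        "chrom": [w.chrom for w in stats],
        "start": [w.start + 1 for w in stats],
        "end": [w.end for w in stats],
        "pi_A": [w.pi_a for w in stats],
        "pi_B": [w.pi_b for w in stats],
        "dxy": [w.dxy for w in stats],
        "fst": [w.fst for w in stats],
        "n_sites": [w.n_sites for w in stats],
    })


def net_divergence(matrix: GenotypeMatrix,
                   group_a: Sequence[str],
                   group_b: Sequence[str],
                   lam_per_year: float,
                   gen_time_years: float = 6.0,
                   region: str = "region",
                   site_mask: np.ndarray | None = None,
                   n_invariant_sites: int = 0) -> DivergenceEstimate:
    """Date the split of two groups from net nucleotide divergence.

    d_x, d_y and dxy are computed from region-total difference and
    comparison counts (not means of per-window ratios), then
    d_a = dxy - (d_x + d_y)/2 and T = d_a / (2 lambda) in years.

    When the matrix holds only variant sites, ``n_invariant_sites`` adds
    the invariant remainder of the region to the comparison denominators
    (invariant sites are assumed fully called).
    """
    if lam_per_year <= 0:
        raise ValueError("mutation rate lambda must be positive")
    ia = matrix.sample_indices(group_a)
    ib = matrix.sample_indices(group_b)
    gt_a, gt_b = matrix.genotypes[ia], matrix.genotypes[ib]
    if site_mask is not None:
        gt_a, gt_b = gt_a[:, site_mask], gt_b[:, site_mask]
    da, ca = _pair_counts(gt_a)
    db, cb = _pair_counts(gt_b)
    dab, cab = _cross_counts(gt_a, gt_b)
    na, nb = 2 * len(ia), 2 * len(ib)
    inv_ca = n_invariant_sites * na * (na - 1) / 2.0
    inv_cb = n_invariant_sites * nb * (nb - 1) / 2.0
    inv_cab = float(n_invariant_sites) * na * nb
    d_x = _ratio(da.sum(), ca.sum() + inv_ca) or 0.0
    d_y = _ratio(db.sum(), cb.sum() + inv_cb) or 0.0
    d_xy = _ratio(dab.sum(), cab.sum() + inv_cab) or 0.0
    d_a = d_xy - 0.5 * (d_x + d_y)
    t_years = d_a / (2.0 * lam_per_year)
    return DivergenceEstimate(
        region=region, d_x=d_x, d_y=d_y, d_xy=d_xy, d_a=d_a,
        lam_per_year=lam_per_year, t_years=t_years,
        t_generations=t_years / gen_time_years, negative=t_years < 0,
    )


def migration_rate(fst: float) -> float:
    """Slatkin's Nm = [(1/FST) - 1] / 4; infinite when FST <= 0."""
    if fst > 1:
        raise ValueError("FST cannot exceed 1")
    if fst <= 0:
        return math.inf
    return ((1.0 / fst) - 1.0) / 4.0


# ---------------------------------------------------------------------------
# Linkage disequilibrium

def ld_r2(matrix: GenotypeMatrix,
          samples: Sequence[str],
          min_maf: float = 0.1,
          max_missing: float = 0.1,
          thin_bp: int = 5_000,
          max_dist_bp: int | None = None) -> pd.DataFrame:
    """Pairwise R^2 between genotype dosages after MAF/missingness filters
    and greedy left-to-right thinning to >= ``thin_bp`` spacing.

    Returns a frame with columns pos_i, pos_j (1-based) and r2; empty when
    fewer than two sites survive.
    """
    idx = matrix.sample_indices(samples)
    gt = matrix.genotypes[idx]
    variant = matrix.is_variant
    called = gt != MISSING
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(called, gt, 0).sum(axis=0) / np.maximum(
            2 * called.sum(axis=0), 1)
    maf = np.minimum(freq, 1 - freq)
    keep = variant & (maf >= min_maf) & ((~called).mean(axis=0) <= max_missing)
    pos = matrix.sites["pos"].to_numpy()[keep]
    gt = gt[:, keep]

    thin_keep: list[int] = []
    last = -np.inf
    for j, p in enumerate(pos):
        if p - last >= thin_bp:
            thin_keep.append(j)
            last = p
    pos = pos[thin_keep]
    gt = gt[:, thin_keep]

    rows = []
    for i in range(len(pos)):
        for j in range(i + 1, len(pos)):
            if max_dist_bp is not None and pos[j] - pos[i] > max_dist_bp:
                break
            both = (gt[:, i] != MISSING) & (gt[:, j] != MISSING)
            x, y = gt[both, i].astype(float), gt[both, j].astype(float)
            if both.sum() < 2 or x.std() == 0 or y.std() == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            rows.append((int(pos[i]), int(pos[j]), float(r * r)))
    return pd.DataFrame(rows, columns=["pos_i", "pos_j", "r2"])


# ---------------------------------------------------------------------------
# Polarized site-frequency spectrum

def polarized_sfs(matrix: GenotypeMatrix,
                  samples: Sequence[str],
                  max_missing: float = 0.2) -> tuple[pd.DataFrame, int]:
    """Derived-allele-count spectra per functional class.

    The derived allele at a biallelic site is the allele differing from the
    outgroup allele AA; sites where AA matches neither allele are excluded
    and counted. Returns (long-format frame with columns fclass /
    derived_count / n_sites, number of unpolarizable sites). Counts are raw
    derived-allele counts among called alleles; monomorphic-in-sample sites
    do not enter the spectrum.
    """
    idx = matrix.sample_indices(samples)
    gt = matrix.genotypes[idx]
    n_chrom = 2 * len(idx)
    counts: dict[tuple[str, int], int] = {}
    excluded = 0
    variant = matrix.is_variant
    for j, site in enumerate(matrix.sites.itertuples(index=False)):
        if not variant[j] or site.aa is None:
            continue
        col = gt[:, j]
        called = col != MISSING
        if (~called).mean() > max_missing:
            continue
        c = 2 * called.sum()
        alt_count = int(col[called].sum())
        if site.aa == site.ref:
            derived = alt_count
        elif site.aa == site.alt:
            derived = c - alt_count
        else:
            excluded += 1
            continue
        if 0 < derived < c:
            fclass = site.fclass or "unclassified"
            counts[(fclass, derived)] = counts.get((fclass, derived), 0) + 1
    rows = [
        {"fclass": fc, "derived_count": k, "n_sites": n}
        for (fc, k), n in sorted(counts.items())
    ]
    frame = pd.DataFrame(rows, columns=["fclass", "derived_count", "n_sites"])
    frame.attrs["n_chromosomes"] = n_chrom
    return frame, excluded


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test

def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value (enumeration over
    heterozygote counts, conditional on allele counts).

    The p-value sums the probabilities of all heterozygote counts with the
    same parity whose conditional probability does not exceed the observed
    one. Monomorphic sites return 1.0.
    """
    n = n_hom_ref + n_het + n_hom_alt
    n_a = 2 * n_hom_alt + n_het  # minor-orientation handled below
    n_minor = min(n_a, 2 * n - n_a)
    if n == 0 or n_minor == 0:
        return 1.0
    # log-probability of each feasible het count, same parity as n_minor
    het_values = list(range(n_minor % 2, n_minor + 1, 2))
    log_probs = []
    lg = math.lgamma
    for h in het_values:
        hom_min = (n_minor - h) // 2
        hom_maj = n - h - hom_min
        if hom_min < 0 or hom_maj < 0:
            log_probs.append(-math.inf)
            continue
        lp = (lg(n + 1) - lg(hom_min + 1) - lg(h + 1) - lg(hom_maj + 1)
              + h * math.log(2)
              + lg(n_minor + 1) + lg(2 * n - n_minor + 1) - lg(2 * n + 1))
        log_probs.append(lp)
    m = max(log_probs)
    probs = np.exp(np.array(log_probs) - m)
    probs /= probs.sum()
    obs = het_values.index(n_het)
    return float(min(1.0, probs[probs <= probs[obs] + 1e-12].sum()))


def hwe_test(matrix: GenotypeMatrix, samples: Sequence[str],
             site_index: int) -> float:
    """HWE exact p-value at one site over the given diploid samples."""
    idx = matrix.sample_indices(samples)
    col = matrix.genotypes[idx, site_index]
    col = col[col != MISSING]
    if len(col) < 5:
        raise ValueError("need >=5 called diploids for the HWE test")
    return hwe_exact_test(int((col == 0).sum()), int((col == 1).sum()),
                          int((col == 2).sum()))
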