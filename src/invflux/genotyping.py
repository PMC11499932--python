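"""Per-individual inversion genotyping (NN / NS / SS).

Two independent routes, mirroring common practice for supergene loci:
a diagnostic-SNP panel polarized on a reference population known to carry
the S arrangement at high frequency, and sliding-window PCA trajectories
in which the two homozygote classes form the extreme clusters and
heterozygotes fall between.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

__all__ = [
    "DiagnosticPanel",
    "Pc1Trajectory",
    "polarize_panel",
    "genotype_by_panel",
    "windowed_pca",
    "call_from_pc1",
]


@dataclass
class DiagnosticPanel:
    """Diagnostic sites with the S-arrangement allele at each.

    ``sites`` columns: chrom, pos (1-based), s_allele ("ref"/"alt");
    ``rule`` records how the panel was polarized.
    """

    sites: pd.DataFrame
    rule: str

    def __len__(self) -> int:
        return len(self.sites)


@dataclass
class Pc1Trajectory:
    """PC1 per individual across SNP windows.

    ``frame`` columns: window (index), midpoint_bp, then one column per
    sample holding that sample's PC1 projection.
    """

    frame: pd.DataFrame
    samples: list[str]
    window_snps: int


def _group_freq(matrix: GenotypeMatrix, idx: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    gt = matrix.genotypes[idx]
    called = gt != MISSING
    tot = 2 * called.sum(axis=0)
    alt = np.where(called, gt, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
    return freq, tot


def polarize_panel(matrix: GenotypeMatrix,
                   reference_pop_samples: Sequence[str],
                   maf_floor: float = 0.2,
                   min_daf: float = 0.8,
                   interval: tuple[str, int, int] | None = None
                   ) -> DiagnosticPanel:
    """Derive a diagnostic panel, assuming the S allele is the one at
    frequency > 0.5 in the reference population.

    Candidate sites are biallelic SNPs (optionally restricted to an
    interval, 0-based half-open) whose combined-cohort MAF reaches
    ``maf_floor`` and whose allele-frequency difference between the
    reference population and the rest of the cohort reaches ``min_daf``
    (the ascertainment that makes the panel diagnostic). Sites with
    reference-population frequency exactly 0.5 are dropped.
    """
    if len(reference_pop_samples) < 2:
        raise ValueError("reference population needs >=2 samples")
    ref_idx = matrix.sample_indices(reference_pop_samples)
    other = [s for s in matrix.samples if s not in set(reference_pop_samples)]
    keep = matrix.is_variant.copy()
    if interval is not None:
        keep &= matrix.region_mask(*interval)
    freq_ref, tot_ref = _group_freq(matrix, ref_idx)
    freq_all, _ = _group_freq(matrix, np.arange(matrix.n_samples))
    keep &= tot_ref >= 4  # >=2 called reference diploids
    with np.errstate(invalid="ignore"):
        keep &= np.minimum(freq_all, 1 - freq_all) >= maf_floor
        keep &= freq_ref != 0.5
        if other:
            freq_other, _ = _group_freq(matrix, matrix.sample_indices(other))
            keep &= np.abs(freq_ref - freq_other) >= min_daf
    sites = matrix.sites.loc[keep, ["chrom", "pos"]].copy()
    sites["s_allele"] = np.where(freq_ref[keep] > 0.5, "alt", "ref")
    rule = (f"S allele = allele at frequency > 0.5 in reference population "
            f"(n={len(reference_pop_samples)}); combined MAF >= {maf_floor}; "
            f"between-group frequency difference >= {min_daf}")
    return DiagnosticPanel(sites.reset_index(drop=True), rule)


def genotype_by_panel(matrix: GenotypeMatrix,
                      panel: DiagnosticPanel,
                      ss_threshold: float = 0.75,
                      nn_threshold: float = 0.25,
                      min_sites: int = 20) -> pd.DataFrame:
    """Label samples NN/NS/SS by mean S-allele dosage over panel sites.

    Dosage is mean(S-allele count)/2 over called panel sites; >= 0.75 is
    SS, <= 0.25 is NN, between is NS; fewer than ``min_sites`` called
    sites yields "unknown".
    """
    key = pd.MultiIndex.from_frame(matrix.sites[["chrom", "pos"]])
    panel_key = pd.MultiIndex.from_frame(panel.sites[["chrom", "pos"]])
    site_pos = key.get_indexer(panel_key)
    found = site_pos >= 0
    site_pos = site_pos[found]
    s_is_alt = (panel.sites["s_allele"].to_numpy() == "alt")[found]

    gt = matrix.genotypes[:, site_pos].astype(float)
    called = gt != MISSING
    s_count = np.where(s_is_alt[None, :], gt, 2 - gt)
    s_count[~called] = np.nan
    n_called = called.sum(axis=1)
    with np.errstate(invalid="ignore"):
        dosage = np.nanmean(s_count, axis=1) / 2.0
    labels = np.where(dosage >= ss_threshold, "SS",
                      np.where(dosage <= nn_threshold, "NN", "NS"))
    labels = np.where(n_called >= min_sites, labels, "unknown")
    return pd.DataFrame({"sample": matrix.samples,
                         "s_dosage": dosage,
                         "n_sites": n_called,
                         "genotype": labels})


def windowed_pca(matrix: GenotypeMatrix,
                 window_snps: int = 200,
                 maf_min: float = 0.01,
                 max_missing: float = 0.2,
                 ss_reference: Sequence[str] | None = None) -> Pc1Trajectory:
    """PC1 of the genotype matrix in consecutive windows of
    ``window_snps`` biallelic SNPs (non-overlapping).

    Per window: genotype codes are mean-imputed at missing calls and
    centered; samples are projected on the leading eigenvector of the
    sample covariance. The sign is fixed so the mean PC1 of the declared
    SS reference samples is positive (falling back to the first sample).
    Zero-variance windows are skipped.
    """
    freq, tot = _group_freq(matrix, np.arange(matrix.n_samples))
    with np.errstate(invalid="ignore"):
        maf = np.minimum(freq, 1 - freq)
    missing_frac = (matrix.genotypes == MISSING).mean(axis=0)
    keep = matrix.is_variant & (maf >= maf_min) & (missing_frac <= max_missing)
    snp_idx = np.flatnonzero(keep)
    if len(snp_idx) < window_snps:
        raise ValueError(
            f"only {len(snp_idx)} SNPs pass filters; need >= {window_snps}")
    pos = matrix.sites["pos"].to_numpy()
    ss_idx = (matrix.sample_indices(ss_reference)
              if ss_reference else None)

    rows = []
    n_windows = len(snp_idx) // window_snps
    for w in range(n_windows):
        cols = snp_idx[w * window_snps:(w + 1) * window_snps]
        g = matrix.genotypes[:, cols].astype(float)
        g[g == MISSING] = np.nan
        col_mean = np.nanmean(g, axis=0)
        g = np.where(np.isnan(g), col_mean[None, :], g) - col_mean[None, :]
        cov = g @ g.T / g.shape[1]
        if not np.any(cov):
            continue
        vals, vecs = np.linalg.eigh(cov)
        pc1 = vecs[:, -1] * np.sqrt(max(vals[-1], 0.0))
        anchor = pc1[ss_idx].mean() if ss_idx is not None else pc1[0]
        if anchor < 0:
            pc1 = -pc1
        mid = 0.5 * (pos[cols[0]] + pos[cols[-1]])
        rows.append([w, mid, *pc1])
    frame = pd.DataFrame(rows, columns=["window", "midpoint_bp",
                                        *matrix.samples])
    return Pc1Trajectory(frame=frame, samples=list(matrix.samples),
                         window_snps=window_snps)


def _kmeans_1d(values: np.ndarray, k: int, max_iter: int = 100
               ) -> tuple[np.ndarray, np.ndarray]:
    """Plain 1-D Lloyd's k-means initialized at min/mid/max quantiles."""
    centers = np.quantile(values, np.linspace(0, 1, k))
    labels = np.zeros(len(values), dtype=int)
    for _ in range(max_iter):
        dist = np.abs(values[:, None] - centers[None, :])
        new_labels = dist.argmin(axis=1)
        if (new_labels == labels).all() and _ > 0:
            break
        labels = new_labels
        for c in range(k):
            if (labels == c).any():
                centers[c] = values[labels == c].mean()
    return labels, centers


def call_from_pc1(traj: Pc1Trajectory,
                  interval: tuple[float, float],
                  anchors: pd.DataFrame | None = None) -> pd.DataFrame:
    """Genotype samples from their median PC1 over in-interval windows.

    Medians are clustered with 1-D k-means (k=3, centers initialized at
    the min/median/max); clusters are labelled from panel-genotyped
    ``anchors`` (frame with sample/genotype columns) when given, else by
    extremity with the positive pole as SS (the PCA sign convention).
    Degenerate input (fewer than 3 distinct medians) falls back to fewer
    clusters.
    """
    lo, hi = interval
    in_win = (traj.frame["midpoint_bp"] >= lo) & (traj.frame["midpoint_bp"] < hi)
    if in_win.sum() < 3:
        raise ValueError("need >=3 windows inside the interval")
    medians = traj.frame.loc[in_win, traj.samples].median(axis=0).to_numpy()
    k = min(3, len(np.unique(medians)))
    labels_idx, centers = _kmeans_1d(medians, k)

    order = np.argsort(centers)  # ascending PC1: NN < NS < SS
    if k == 3:
        name_of = {order[0]: "NN", order[1]: "NS", order[2]: "SS"}
    elif k == 2:
        name_of = {order[0]: "NN", order[1]: "SS"}
    else:
        name_of = {order[0]: "NN"}
    labels = np.array([name_of[i] for i in labels_idx])

    if anchors is not None:
        remap: dict[str, str] = {}
        anchor_gt = dict(zip(anchors["sample"], anchors["genotype"]))
        for cluster in set(labels):
            votes = [anchor_gt[s]
                     for s, c in zip(traj.samples, labels)
                     if c == cluster and anchor_gt.get(s) in ("NN", "NS", "SS")]
            if votes:
                remap[cluster] = max(set(votes), key=votes.count)
        if len(set(remap.values())) == len(remap):  # consistent anchoring
            labels = np.array([remap.get(c, c) for c in labels])
    return pd.DataFrame({"sample": traj.samples,
                         "median_pc1": medians,
                         "genotype": labels})
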