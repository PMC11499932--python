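"""Allele-sharing (gene-flux) scan between inversion homozygote groups.

For each biallelic SNP the minor allele is fixed in the combined NN+SS
cohort, its frequency is computed separately in the two homozygote groups,
and two statistics follow:

    dAF  = |freq_NN - freq_SS|
    dAF' = dAF / max(freq_NN, freq_SS)

dAF' = 1 means the minor allele is private to one arrangement (the
no-gene-flux expectation for a recombination-suppressed inversion); dAF' = 0
means the two arrangements share the allele at identical frequency. SNPs
whose combined minor-allele frequency falls below a floor (default 0.2) are
excluded up front, as near-invariant sites make the ratio noisy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, GenotypeMatrix

__all__ = [
    "DafRecord",
    "EnrichmentResult",
    "daf_prime",
    "scan",
    "classify_extreme",
    "enrichment",
    "low_daf_prime_runs",
]


@dataclass(frozen=True)
class DafRecord:
    chrom: str
    pos: int  # 1-based
    minor_allele: str
    freq_n: float
    freq_s: float
    daf: float
    maf_max: float
    daf_prime: float
    fclass: str | None = None


@dataclass(frozen=True)
class EnrichmentResult:
    """Chi-square enrichment of extreme SNPs across functional categories."""

    table: pd.DataFrame  # category, p_category, observed, expected, pooled
    chi2: float | None
    p_value: float | None
    dof: int | None
    extreme_threshold: float
    n_extreme: int


def daf_prime(freq_n: float, freq_s: float) -> tuple[float, float, float] | None:
    """(dAF, MAFmax, dAF') for one SNP's per-group minor-allele frequencies.

    Returns None when both frequencies are zero (monomorphic in the two
    groups: the ratio is undefined, never a division by zero).
    """
    if not (0 <= freq_n <= 1 and 0 <= freq_s <= 1):
        raise ValueError("frequencies must lie in [0, 1]")
    daf = abs(freq_n - freq_s)
    maf_max = max(freq_n, freq_s)
    if maf_max == 0:
        return None
    return daf, maf_max, daf / maf_max


def scan(matrix: GenotypeMatrix,
         nn_samples: Sequence[str],
         ss_samples: Sequence[str],
         maf_floor: float = 0.2) -> list[DafRecord]:
    """dAF/dAF' at every biallelic SNP passing the combined-MAF floor.

    The minor allele is determined in the combined NN+SS cohort (ties at
    0.5 designate the alt allele minor); missing genotypes are excluded
    from each group's frequency denominator.
    """
    if len(nn_samples) < 2 or len(ss_samples) < 2:
        raise ValueError("each homozygote group needs >=2 samples")
    i_n = matrix.sample_indices(nn_samples)
    i_s = matrix.sample_indices(ss_samples)
    variant = matrix.is_variant
    gt_n = matrix.genotypes[i_n]
    gt_s = matrix.genotypes[i_s]

    def group_counts(gt):
        called = gt != MISSING
        return (np.where(called, gt, 0).sum(axis=0).astype(float),
                2.0 * called.sum(axis=0))

    alt_n, tot_n = group_counts(gt_n)
    alt_s, tot_s = group_counts(gt_s)
    alt_c, tot_c = alt_n + alt_s, tot_n + tot_s
    with np.errstate(invalid="ignore", divide="ignore"):
        freq_alt_c = np.where(tot_c > 0, alt_c / np.maximum(tot_c, 1), np.nan)
    # combined minor allele; tie at 0.5 -> alt is minor
    minor_is_alt = freq_alt_c <= 0.5
    minor_freq_c = np.where(minor_is_alt, freq_alt_c, 1.0 - freq_alt_c)
    keep = variant & (tot_n > 0) & (tot_s > 0) & (minor_freq_c >= maf_floor)

    records: list[DafRecord] = []
    sites = matrix.sites
    for j in np.flatnonzero(keep):
        if minor_is_alt[j]:
            fn = alt_n[j] / tot_n[j]
            fs = alt_s[j] / tot_s[j]
            allele = sites["alt"].iat[j]
        else:
            fn = (tot_n[j] - alt_n[j]) / tot_n[j]
            fs = (tot_s[j] - alt_s[j]) / tot_s[j]
            allele = sites["ref"].iat[j]
        res = daf_prime(fn, fs)
        if res is None:
            continue
        daf, maf_max, dafp = res
        records.append(DafRecord(
            chrom=sites["chrom"].iat[j], pos=int(sites["pos"].iat[j]),
            minor_allele=str(allele), freq_n=fn, freq_s=fs,
            daf=daf, maf_max=maf_max, daf_prime=dafp,
            fclass=sites["fclass"].iat[j],
        ))
    return records


def classify_extreme(records: Sequence[DafRecord],
                     daf_threshold: float = 0.95) -> np.ndarray:
    """Boolean flags for extremely differentiated SNPs (dAF strictly >
    threshold)."""
    return np.array([r.daf > daf_threshold for r in records], dtype=bool)


def enrichment(records: Sequence[DafRecord],
               extreme: np.ndarray,
               daf_threshold: float = 0.95) -> EnrichmentResult:
    """Functional-category enrichment of extreme SNPs.

    p(category) is each category's share among *all* scanned records (no
    dAF filter); the expected extreme count is p(category) x sum(extreme).
    A Pearson chi-square goodness-of-fit test compares observed with
    expected, pooling categories with expected < 1 into "other" (the
    unpooled rows are still reported).
    """
    if len(records) != len(extreme):
        raise ValueError("records and extreme flags must align")
    cats = pd.Series([r.fclass or "unclassified" for r in records])
    n_extreme = int(extreme.sum())
    if n_extreme == 0:
        raise ValueError("no extreme records: enrichment undefined")
    p_cat = cats.value_counts(normalize=True)
    observed = cats[extreme].value_counts().reindex(p_cat.index, fill_value=0)
    expected = p_cat * n_extreme
    table = pd.DataFrame({
        "category": p_cat.index,
        "p_category": p_cat.to_numpy(),
        "observed": observed.to_numpy(),
        "expected": expected.to_numpy(),
    })
    pool = table["expected"] < 1.0
    table["pooled"] = pool.to_numpy()
    kept = table[~pool]
    obs = list(kept["observed"].astype(float))
    exp = list(kept["expected"].astype(float))
    if pool.any():
        obs.append(float(table.loc[pool, "observed"].sum()))
        exp.append(float(table.loc[pool, "expected"].sum()))
    if len(obs) < 2:
        return EnrichmentResult(table, None, None, None, daf_threshold,
                                n_extreme)
    chi2, p = stats.chisquare(obs, exp)
    return EnrichmentResult(table, float(chi2), float(p), len(obs) - 1,
                            daf_threshold, n_extreme)


def low_daf_prime_runs(records: Sequence[DafRecord],
                       cutoff: float = 0.5,
                       min_run: int = 3) -> list[tuple[str, int, int, int]]:
    """Candidate gene-flux regions: runs of >= ``min_run`` consecutive
    records with dAF' below ``cutoff``. Returns (chrom, start0, end0, n)
    intervals (an aggregation convenience; the scan itself is per-SNP).
    """
    runs: list[tuple[str, int, int, int]] = []
    current: list[DafRecord] = []

    def flush():
        if len(current) >= min_run:
            runs.append((current[0].chrom, current[0].pos - 1,
                         current[-1].pos, len(current)))

    for r in records:
        if r.daf_prime < cutoff and (not current or r.chrom == current[0].chrom):
            current.append(r)
        else:
            flush()
            current = [r] if r.daf_prime < cutoff else []
    flush()
    return runs


def records_frame(records: Sequence[DafRecord],
                  extreme: np.ndarray | None = None) -> pd.DataFrame:
    frame = pd.DataFrame([dataclass_asdict(r) for r in records])
    if extreme is not None and len(frame):
        frame["extreme"] = extreme
    return frame


def dataclass_asdict(r: DafRecord) -> dict:
    return {
        "chrom": r.chrom, "pos": r.pos, "minor_allele": r.minor_allele,
        "freq_NN": r.freq_n, "freq_SS": r.freq_s, "dAF": r.daf,
        "MAFmax": r.maf_max, "dAF_prime": r.daf_prime, "category": r.fclass,
    }
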