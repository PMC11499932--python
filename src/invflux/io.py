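"""Readers and writers for the formats the pipeline touches.

Internal coordinates are 0-based half-open; everything user-facing (VCF,
reports, BED names aside) is 1-based inclusive, matching the convention of
the genome browsers and of published breakpoint tables. Genotypes are stored
as alt-allele dosage codes 0/1/2 with -1 for missing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "FilterSpec",
    "SampleTable",
    "GenotypeMatrix",
    "AlignmentBlock",
    "read_allsites_vcf",
    "write_allsites_vcf",
    "read_paf",
    "write_paf",
    "read_sample_table",
    "write_bed",
]


class VcfFormatError(ValueError):
    """Raised for malformed VCF records; carries the 1-based line number."""


class PafFormatError(ValueError):
    """Raised for malformed PAF records; carries the 1-based line number."""


@dataclass(frozen=True)
class FilterSpec:
    """Site- and genotype-level filters for reading an all-sites VCF.

    Order of application: genotype-level masks (GQ/DP) first, then
    site-level missingness, then minor-allele frequency. The MAF filter
    applies only to variant sites when ``keep_invariant`` is set, so that
    all-sites denominators for pi/dxy stay unbiased.
    """

    max_missing_frac: float | None = None
    min_maf: float | None = None
    biallelic_only: bool = True
    region: tuple[str, int, int] | None = None  # chrom, 0-based half-open
    min_gq: int | None = None
    min_depth: int | None = None
    keep_invariant: bool = True


@dataclass
class SampleTable:
    """Sample-to-population map with optional per-locus inversion genotypes."""

    table: pd.DataFrame  # columns: sample, population, genotype_* (optional)

    VALID_GENOTYPES = {"NN", "NS", "SS", "unknown"}

    def __post_init__(self) -> None:
        if self.table["sample"].duplicated().any():
            dups = self.table["sample"][self.table["sample"].duplicated()]
            raise ValueError(f"duplicate sample ids: {sorted(set(dups))}")
        for col in self.table.columns:
            if col.startswith("genotype_"):
                bad = set(self.table[col].dropna()) - self.VALID_GENOTYPES
                if bad:
                    raise ValueError(f"invalid genotype labels in {col}: {bad}")

    @property
    def samples(self) -> list[str]:
        return list(self.table["sample"])

    def population(self, pop: str) -> list[str]:
        return list(self.table.loc[self.table["population"] == pop, "sample"])

    def genotype_group(self, locus: str, genotype: str) -> list[str]:
        col = f"genotype_{locus}"
        return list(self.table.loc[self.table[col] == genotype, "sample"])


@dataclass
class GenotypeMatrix:
    """Diploid genotype dosages plus per-site metadata.

    ``sites`` columns: chrom, pos (1-based), ref, alt (None for invariant
    sites), aa (outgroup/ancestral allele or None), fclass (functional class
    or None). ``genotypes`` has shape (n_samples, n_sites), int8.
    """

    samples: list[str]
    sites: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"genotype shape {self.genotypes.shape} != "
                f"({len(self.samples)}, {len(self.sites)})"
            )
        if not np.isin(self.genotypes, [MISSING, 0, 1, 2]).all():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
        pos = self.sites["pos"].to_numpy()
        for chrom, idx in self.sites.groupby("chrom", sort=False).groups.items():
            p = pos[self.sites.index.get_indexer(idx)]
            if not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {chrom}")
        inv = ~self.is_variant
        if inv.any() and not np.isin(self.genotypes[:, inv], [MISSING, 0]).all():
            raise ValueError("invariant sites must have code 0 or missing")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def is_variant(self) -> np.ndarray:
        return self.sites["alt"].notna().to_numpy()

    def sample_indices(self, names: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[n] for n in names], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown sample {e.args[0]!r}") from None

    def take_sites(self, mask_or_index: np.ndarray) -> "GenotypeMatrix":
        sites = self.sites.loc[mask_or_index] if mask_or_index.dtype == bool \
            else self.sites.iloc[mask_or_index]
        gt = self.genotypes[:, mask_or_index]
        return GenotypeMatrix(list(self.samples), sites.reset_index(drop=True), gt)

    def take_samples(self, names: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_indices(names)
        return GenotypeMatrix(list(names), self.sites.copy(), self.genotypes[idx])

    def region_mask(self, chrom: str, start0: int, end0: int) -> np.ndarray:
        """0-based half-open region mask over sites."""
        pos0 = self.sites["pos"].to_numpy() - 1
        return (
            (self.sites["chrom"] == chrom).to_numpy()
            & (pos0 >= start0)
            & (pos0 < end0)
        )

    def allele_counts(self, sample_idx: np.ndarray | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (alt allele count, called allele count) over samples."""
        gt = self.genotypes if sample_idx is None else self.genotypes[sample_idx]
        called = gt != MISSING
        alt = np.where(called, gt, 0).sum(axis=0)
        return alt.astype(np.int64), (2 * called.sum(axis=0)).astype(np.int64)


@dataclass(frozen=True, order=True)
class AlignmentBlock:
    """One pairwise-alignment record (PAF semantics, 0-based half-open)."""

    query_name: str
    query_start: int
    query_end: int
    strand: str
    target_name: str
    target_start: int
    target_end: int
    matches: int = 0
    block_len: int = 0
    mapq: int = 60

    def __post_init__(self) -> None:
        if not (0 <= self.query_start < self.query_end):
            raise ValueError("query interval must satisfy 0 <= start < end")
        if not (0 <= self.target_start < self.target_end):
            raise ValueError("target interval must satisfy 0 <= start < end")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def target_span(self) -> int:
        return self.target_end - self.target_start


# ---------------------------------------------------------------------------
# VCF

def _site_maf(alt: np.ndarray, called: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(called > 0, alt / np.maximum(called, 1), np.nan)
    return np.minimum(f, 1.0 - f)


def read_allsites_vcf(path: str | Path,
                      filters: FilterSpec | None = None) -> GenotypeMatrix:
    """Read an all-sites VCF (variant + invariant records) into a matrix.

    Indels are dropped. INFO keys ``AA`` (outgroup allele) and ``FCLASS``
    (functional class) populate the site table when present. Filters are
    applied in the order missingness -> MAF.
    """
    from cyvcf2 import VCF

    filters = filters or FilterSpec()
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str | None] = []
    aas: list[str | None] = []
    fclasses: list[str | None] = []
    rows: list[np.ndarray] = []

    for lineno, rec in enumerate(vcf, start=1):
        try:
            ref = rec.REF
            alt_alleles = [a for a in rec.ALT if a != "."]
            if len(ref) != 1 or any(len(a) != 1 for a in alt_alleles):
                continue  # indel
            if filters.biallelic_only and len(alt_alleles) > 1:
                continue
            if filters.region is not None:
                chrom, r0, r1 = filters.region
                if rec.CHROM != chrom or not (r0 <= rec.POS - 1 < r1):
                    continue
            gt = np.asarray(rec.gt_types, dtype=np.int8)  # 0/1/2, 3=missing
            gt = np.where(gt == 3, MISSING, gt)
            if filters.min_gq is not None:
                gq = np.asarray(rec.gt_quals)
                gt = np.where(gq < filters.min_gq, MISSING, gt)
            if filters.min_depth is not None:
                dp = np.asarray(rec.gt_depths)
                gt = np.where(dp < filters.min_depth, MISSING, gt)
            alt = alt_alleles[0] if alt_alleles else None
            if alt is None:
                gt = np.where(gt > 0, MISSING, gt)  # defensive: invariant
            aa = rec.INFO.get("AA")
            fclass = rec.INFO.get("FCLASS")
        except VcfFormatError:
            raise
        except Exception as e:  # pragma: no cover - malformed input path
            raise VcfFormatError(f"malformed VCF record at data line {lineno}: {e}")
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(ref)
        alts.append(alt)
        aas.append(aa)
        fclasses.append(fclass)
        rows.append(gt)

    sites = pd.DataFrame({
        "chrom": chroms, "pos": poss, "ref": refs, "alt": alts,
        "aa": aas, "fclass": fclasses,
    })
    gt = (np.array(rows, dtype=np.int8).T if rows
          else np.zeros((len(samples), 0), dtype=np.int8))
    matrix = GenotypeMatrix(samples, sites, gt)
    return apply_site_filters(matrix, filters)


def apply_site_filters(matrix: GenotypeMatrix,
                       filters: FilterSpec) -> GenotypeMatrix:
    """Apply missingness then MAF site filters; idempotent."""
    keep = np.ones(matrix.n_sites, dtype=bool)
    missing_frac = (matrix.genotypes == MISSING).mean(axis=0)
    if filters.max_missing_frac is not None:
        keep &= missing_frac <= filters.max_missing_frac
    if filters.min_maf is not None:
        alt, called = matrix.allele_counts()
        maf = _site_maf(alt, called)
        fails = ~(maf >= filters.min_maf)
        if filters.keep_invariant:
            fails &= matrix.is_variant
        keep &= ~fails
    if keep.all():
        return matrix
    return matrix.take_sites(keep)


def write_allsites_vcf(path: str | Path, matrix: GenotypeMatrix,
                       contig_lengths: dict[str, int] | None = None) -> None:
    """Write a VCF 4.2 with variant and invariant records.

    Output is deterministic (no timestamps). Invariant sites get ALT "." ;
    the outgroup allele goes to INFO/AA and the functional class to
    INFO/FCLASS.
    """
    lines = [
        "##fileformat=VCFv4.2",
        "##source=invflux",
        '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral (outgroup) allele">',
        '##INFO=<ID=FCLASS,Number=1,Type=String,Description="Functional class">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    if contig_lengths:
        for name, length in contig_lengths.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    else:
        for name in dict.fromkeys(matrix.sites["chrom"]):
            lines.append(f"##contig=<ID={name}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.samples))
    gt_str = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    for j, site in enumerate(matrix.sites.itertuples(index=False)):
        info_parts = []
        if site.aa is not None:
            info_parts.append(f"AA={site.aa}")
        if site.fclass is not None:
            info_parts.append(f"FCLASS={site.fclass}")
        info = ";".join(info_parts) or "."
        alt = site.alt if site.alt is not None else "."
        gts = "\t".join(gt_str[int(g)] for g in matrix.genotypes[:, j])
        lines.append(f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{alt}\t.\t.\t"
                     f"{info}\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PAF

def read_paf(path: str | Path, min_block_len: int = 0) -> list[AlignmentBlock]:
    """Read a PAF file, dropping blocks shorter than ``min_block_len`` on
    the target axis; result sorted by (target name, target start)."""
    blocks: list[AlignmentBlock] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise PafFormatError(
                    f"line {lineno}: expected >=12 columns, got {len(cols)}")
            try:
                block = AlignmentBlock(
                    query_name=cols[0],
                    query_start=int(cols[2]), query_end=int(cols[3]),
                    strand=cols[4],
                    target_name=cols[5],
                    target_start=int(cols[7]), target_end=int(cols[8]),
                    matches=int(cols[9]), block_len=int(cols[10]),
                    mapq=int(cols[11]),
                )
            except ValueError as e:
                raise PafFormatError(f"line {lineno}: {e}")
            if block.target_span >= min_block_len:
                blocks.append(block)
    blocks.sort(key=lambda b: (b.target_name, b.target_start, b.target_end))
    return blocks


def write_paf(path: str | Path, blocks: Iterable[AlignmentBlock],
              query_lengths: dict[str, int] | None = None,
              target_lengths: dict[str, int] | None = None) -> None:
    query_lengths = query_lengths or {}
    target_lengths = target_lengths or {}
    with open(path, "w") as fh:
        for b in blocks:
            qlen = query_lengths.get(b.query_name, b.query_end)
            tlen = target_lengths.get(b.target_name, b.target_end)
            blen = b.block_len or b.target_span
            fh.write("\t".join(map(str, [
                b.query_name, qlen, b.query_start, b.query_end, b.strand,
                b.target_name, tlen, b.target_start, b.target_end,
                b.matches or blen, blen, b.mapq,
            ])) + "\n")


# ---------------------------------------------------------------------------
# Sample table / BED

def read_sample_table(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" not in df.columns or "population" not in df.columns:
        raise ValueError("sample table needs 'sample' and 'population' columns")
    return SampleTable(df)


def write_bed(path: str | Path,
              intervals: Iterable[tuple[str, int, int, str]]) -> None:
    """Write (chrom, start0, end0, name) intervals as BED."""
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")
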