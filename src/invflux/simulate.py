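"""Synthetic cohorts with the statistical structure of a supergene.

The generator emulates a polymorphic chromosomal inversion segregating in
one species: two arrangement haplotype groups (N and S) that descend from a
single ancestral population and stopped exchanging material inside the
inversion interval when the inversion arose, an outgroup lineage for
polarization, and panmictic flanking sequence (arrangement groups only
differ inside the interval, so flank differentiation is ~0). Gene flux
between arrangements is modelled as discrete tract-copy events — the
double-crossover / gene-conversion picture — rather than a continuous
migration rate.

Defaults state a herring-like world: a per-year mutation rate of
3.3e-10 and a six-year generation time (mu = 1.98e-9 per generation), an
arrangement split ~3e5 generations ago (the estimated inversion age in
generations) and a deep outgroup at 2e6 generations (~12 MY at 6 y/gen).
Ne defaults to 1e4 rather than the species' huge historical size so that
desk-scale sequence lengths carry workable variant densities.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import msprime
import numpy as np
import pandas as pd

from .breakpoints import revcomp
from .io import MISSING, AlignmentBlock, GenotypeMatrix, write_paf

__all__ = [
    "CohortParams",
    "FluxTract",
    "CohortTruth",
    "SyntheticCohort",
    "SyntheticAssemblyTruth",
    "simulate_cohort",
    "emit_allsites_vcf",
    "build_assembly_truth",
    "emit_alignments",
    "emit_outgroup_alignments",
    "EmittedAlignments",
]

BASES = np.array(["A", "C", "G", "T"])
FCLASS_NAMES = ("noncoding", "synonymous", "non-synonymous")

LAMBDA_PER_YEAR = 3.3e-10     # per-site per-year substitution rate
GEN_TIME_YEARS = 6.0


@dataclass(frozen=True)
class CohortParams:
    """Stated world of one synthetic inversion cohort."""

    n_N: int = 10                 # NN homozygous diploids
    n_S: int = 10                 # SS homozygous diploids
    n_het: int = 2                # NS heterozygous diploids
    n_outgroup: int = 1           # haploid outgroup samples
    L: int = 1_000_000            # bp
    mu_per_gen: float = LAMBDA_PER_YEAR * GEN_TIME_YEARS
    gen_time_years: float = GEN_TIME_YEARS
    Ne: float = 10_000.0
    T_split_gen: float = 300_000.0
    T_outgroup_gen: float = 2_000_000.0
    inversion_interval: tuple[int, int] = (300_000, 700_000)
    recombination_rate: float = 1e-8
    flux_rate: float = 1.0        # expected tracts per region
    flux_tract_len: float = 25_000.0  # mean tract length, bp
    prop_nonsyn: float = 0.05
    prop_syn: float = 0.05
    missing_rate: float = 0.0
    seed: int = 1
    chrom: str = "chr1"

    def validate(self) -> None:
        start, end = self.inversion_interval
        if not (0 <= start < end <= self.L):
            raise ValueError("inversion_interval must satisfy "
                             "0 <= start < end <= L")
        if not (self.T_outgroup_gen > self.T_split_gen > 0):
            raise ValueError("need T_outgroup_gen > T_split_gen > 0")
        if self.n_N + self.n_S + self.n_het == 0:
            raise ValueError("cohort needs at least one diploid sample")
        if self.n_outgroup < 1:
            raise ValueError("need at least one outgroup haplotype")
        for name in ("mu_per_gen", "recombination_rate", "flux_rate",
                     "flux_tract_len", "missing_rate", "Ne"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0 <= self.prop_nonsyn <= 1 and 0 <= self.prop_syn <= 1
                and self.prop_nonsyn + self.prop_syn <= 1):
            raise ValueError("functional-class proportions must be "
                             "probabilities summing to <= 1")

    @property
    def sample_names(self) -> list[str]:
        return ([f"N{i + 1:02d}" for i in range(self.n_N)]
                + [f"S{i + 1:02d}" for i in range(self.n_S)]
                + [f"H{i + 1:02d}" for i in range(self.n_het)])

    @property
    def truth_genotypes(self) -> dict[str, str]:
        out = {f"N{i + 1:02d}": "NN" for i in range(self.n_N)}
        out.update({f"S{i + 1:02d}": "SS" for i in range(self.n_S)})
        out.update({f"H{i + 1:02d}": "NS" for i in range(self.n_het)})
        return out


@dataclass(frozen=True)
class FluxTract:
    """One realized gene-flux event: the donor haplotype's alleles over
    [start, end) were copied into ``carriers`` recipient haplotypes."""

    start: int
    end: int
    donor_group: str              # "N" or "S"
    donor_hap: int
    carriers: tuple[int, ...]


@dataclass
class CohortTruth:
    genotypes: dict[str, str]     # sample -> NN/NS/SS
    tracts: list[FluxTract]
    t_split_gen: float
    inversion_interval: tuple[int, int]


@dataclass
class SyntheticCohort:
    """A simulated cohort: variant-site genotype matrix plus the implicit
    invariant remainder of the sequence, and full ground truth."""

    params: CohortParams
    matrix: GenotypeMatrix        # variant sites only
    ref_bases: np.ndarray         # dtype U1, length L
    fclass_codes: np.ndarray      # int8 index into FCLASS_NAMES, length L
    truth: CohortTruth

    @property
    def chrom(self) -> str:
        return self.params.chrom

    def allsites_matrix(self) -> GenotypeMatrix:
        """Materialize every position of the region as a site record
        (invariant sites as alt=None, all genotypes 0). Desk scale only:
        the result has ``params.L`` rows."""
        L = self.params.L
        n = self.matrix.n_samples
        var_pos0 = self.matrix.sites["pos"].to_numpy() - 1
        alt = np.full(L, None, dtype=object)
        aa = self.ref_bases.astype(object).copy()
        alt[var_pos0] = self.matrix.sites["alt"].to_numpy()
        aa[var_pos0] = self.matrix.sites["aa"].to_numpy()
        gt = np.zeros((n, L), dtype=np.int8)
        gt[:, var_pos0] = self.matrix.genotypes
        sites = pd.DataFrame({
            "chrom": self.chrom,
            "pos": np.arange(1, L + 1),
            "ref": self.ref_bases.astype(object),
            "alt": alt,
            "aa": aa,
            "fclass": np.array(FCLASS_NAMES, dtype=object)[self.fclass_codes],
        })
        return GenotypeMatrix(list(self.matrix.samples), sites, gt)


# ---------------------------------------------------------------------------

def _split_demography(params: CohortParams) -> msprime.Demography:
    dem = msprime.Demography()
    for name in ("N", "S", "ANC", "OUT", "ROOT"):
        dem.add_population(name=name, initial_size=params.Ne)
    dem.add_population_split(time=params.T_split_gen,
                             derived=["N", "S"], ancestral="ANC")
    dem.add_population_split(time=params.T_outgroup_gen,
                             derived=["ANC", "OUT"], ancestral="ROOT")
    return dem


def _panmictic_demography(params: CohortParams) -> msprime.Demography:
    dem = msprime.Demography()
    for name in ("HER", "OUT", "ROOT"):
        dem.add_population(name=name, initial_size=params.Ne)
    dem.add_population_split(time=params.T_outgroup_gen,
                             derived=["HER", "OUT"], ancestral="ROOT")
    return dem


def _simulate_haplotypes(params: CohortParams, demography, sample_sets,
                         length: int, seed_pair: tuple[int, int]
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Run ancestry + infinite-sites mutations; return (derived-allele
    matrix haps x sites, integer positions 0-based within the segment)."""
    ts = msprime.sim_ancestry(
        samples=sample_sets, demography=demography,
        sequence_length=length,
        recombination_rate=params.recombination_rate,
        random_seed=seed_pair[0])
    ts = msprime.sim_mutations(
        ts, rate=params.mu_per_gen,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False, random_seed=seed_pair[1])
    n_haps = ts.num_samples
    haps = np.zeros((n_haps, ts.num_sites), dtype=np.int8)
    pos = np.zeros(ts.num_sites, dtype=np.int64)
    for j, var in enumerate(ts.variants()):
        haps[:, j] = var.genotypes
        pos[j] = int(var.site.position)
    # infinite-sites positions are floats; flooring can collide -> keep first
    keep = np.concatenate([[True], np.diff(pos) > 0]) if len(pos) else \
        np.zeros(0, dtype=bool)
    return haps[:, keep], pos[keep]


def simulate_cohort(params: CohortParams,
                    tracts: Sequence[tuple[int, int, str, int]] | None = None
                    ) -> SyntheticCohort:
    """Simulate one cohort under the stated world of ``params``.

    Inside the inversion interval the genealogy is a clean two-group split
    (no between-arrangement exchange) onto which gene-flux tracts are
    overlaid as explicit copy events; flanking sequence is panmictic.
    ``tracts`` plants events explicitly as (start, end, donor_group,
    n_carriers) and overrides the Poisson draw. Deterministic per seed.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    seeds = [int(s) for s in rng.integers(1, 2**31 - 1, size=6)]
    start, end = params.inversion_interval
    L = params.L
    inv_len = end - start

    ref_idx = rng.integers(0, 4, size=L)
    ref_bases = BASES[ref_idx].astype("U1")
    fclass_codes = rng.choice(
        3, size=L,
        p=[1 - params.prop_syn - params.prop_nonsyn,
           params.prop_syn, params.prop_nonsyn]).astype(np.int8)

    n_dip = params.n_N + params.n_S + params.n_het
    h_n = 2 * params.n_N + params.n_het
    h_s = 2 * params.n_S + params.n_het

    # inversion interval: two-group split genealogy
    inv_sets = [msprime.SampleSet(h_n, population="N", ploidy=1),
                msprime.SampleSet(h_s, population="S", ploidy=1),
                msprime.SampleSet(params.n_outgroup, population="OUT",
                                  ploidy=1)]
    haps_inv, pos_inv = _simulate_haplotypes(
        params, _split_demography(params), inv_sets, inv_len,
        (seeds[0], seeds[1]))
    pos_inv = pos_inv + start

    flux = _apply_flux(params, rng, haps_inv, pos_inv, h_n, h_s, tracts)

    # flanks: panmictic, concatenated then re-offset around the interval
    flank_len = L - inv_len
    if flank_len > 0:
        fl_sets = [msprime.SampleSet(2 * n_dip, population="HER", ploidy=1),
                   msprime.SampleSet(params.n_outgroup, population="OUT",
                                     ploidy=1)]
        haps_fl, pos_fl = _simulate_haplotypes(
            params, _panmictic_demography(params), fl_sets, flank_len,
            (seeds[2], seeds[3]))
        pos_fl = np.where(pos_fl < start, pos_fl, pos_fl + inv_len)
    else:
        haps_fl = np.zeros((2 * n_dip + params.n_outgroup, 0), dtype=np.int8)
        pos_fl = np.zeros(0, dtype=np.int64)

    # haplotype-to-diploid wiring
    inv_pairs, fl_pairs = [], []
    for i in range(params.n_N):
        inv_pairs.append((2 * i, 2 * i + 1))
    for k in range(params.n_S):
        inv_pairs.append((h_n + 2 * k, h_n + 2 * k + 1))
    for j in range(params.n_het):
        inv_pairs.append((2 * params.n_N + j, h_n + 2 * params.n_S + j))
    for m in range(n_dip):
        fl_pairs.append((2 * m, 2 * m + 1))
    out_inv = h_n + h_s
    out_fl = 2 * n_dip

    g_inv = np.stack([haps_inv[a] + haps_inv[b] for a, b in inv_pairs]) \
        if len(pos_inv) else np.zeros((n_dip, 0), dtype=np.int8)
    g_fl = np.stack([haps_fl[a] + haps_fl[b] for a, b in fl_pairs]) \
        if len(pos_fl) else np.zeros((n_dip, 0), dtype=np.int8)
    aa_inv = haps_inv[out_inv, :] if len(pos_inv) else np.zeros(0, np.int8)
    aa_fl = haps_fl[out_fl, :] if len(pos_fl) else np.zeros(0, np.int8)

    pos0 = np.concatenate([pos_inv, pos_fl])
    order = np.argsort(pos0, kind="stable")
    pos0 = pos0[order]
    geno = np.concatenate([g_inv, g_fl], axis=1)[:, order].astype(np.int8)
    out_derived = np.concatenate([aa_inv, aa_fl])[order]

    ref = ref_bases[pos0].astype(object)
    alt_shift = rng.integers(1, 4, size=len(pos0))
    alt = BASES[(ref_idx[pos0] + alt_shift) % 4].astype(object)
    aa = np.where(out_derived == 1, alt, ref)

    if params.missing_rate > 0:
        miss = rng.random(geno.shape) < params.missing_rate
        geno = np.where(miss, MISSING, geno).astype(np.int8)
        dead = (geno == MISSING).all(axis=0)
        geno[0, dead] = 0  # keep >=1 non-missing genotype per site

    sites = pd.DataFrame({
        "chrom": params.chrom,
        "pos": pos0 + 1,
        "ref": ref,
        "alt": alt,
        "aa": aa,
        "fclass": np.array(FCLASS_NAMES, dtype=object)[fclass_codes[pos0]],
    })
    matrix = GenotypeMatrix(params.sample_names, sites, geno)
    truth = CohortTruth(genotypes=params.truth_genotypes, tracts=flux,
                        t_split_gen=params.T_split_gen,
                        inversion_interval=params.inversion_interval)
    return SyntheticCohort(params=params, matrix=matrix,
                           ref_bases=ref_bases, fclass_codes=fclass_codes,
                           truth=truth)


def _apply_flux(params: CohortParams, rng: np.random.Generator,
                haps: np.ndarray, pos: np.ndarray, h_n: int, h_s: int,
                tracts: Sequence[tuple[int, int, str, int]] | None
                ) -> list[FluxTract]:
    """Overlay gene-flux tract copies on the inversion haplotypes.

    A tract is an old exchange event whose copy has drifted in the
    recipient group: the number of carrier haplotypes is drawn uniformly on
    {1, ..., n_recipient_haps - 1} unless planted explicitly.
    """
    start, end = params.inversion_interval
    groups = {"N": np.arange(h_n), "S": np.arange(h_n, h_n + h_s)}
    events: list[tuple[int, int, str, int]] = []
    if tracts is not None:
        events = [tuple(t) for t in tracts]
    elif params.flux_rate > 0:
        for _ in range(rng.poisson(params.flux_rate)):
            t_start = int(rng.integers(start, end))
            t_len = max(1, int(rng.exponential(params.flux_tract_len)))
            t_end = min(end, t_start + t_len)
            donor = "N" if rng.random() < 0.5 else "S"
            recip = "S" if donor == "N" else "N"
            n_car = int(rng.integers(1, max(2, len(groups[recip]))))
            events.append((t_start, t_end, donor, n_car))

    realized: list[FluxTract] = []
    for t_start, t_end, donor, n_car in events:
        if not (start <= t_start < t_end <= end):
            raise ValueError("flux tract must lie inside the inversion")
        recip = "S" if donor == "N" else "N"
        donor_hap = int(rng.choice(groups[donor]))
        carriers = rng.choice(groups[recip], size=min(n_car,
                              len(groups[recip])), replace=False)
        mask = (pos >= t_start) & (pos < t_end)
        haps[np.ix_(np.sort(carriers), np.flatnonzero(mask))] = \
            haps[donor_hap, mask]
        realized.append(FluxTract(t_start, t_end, donor, donor_hap,
                                  tuple(int(c) for c in np.sort(carriers))))
    return realized


# ---------------------------------------------------------------------------
# All-sites VCF emission

def emit_allsites_vcf(cohort: SyntheticCohort, path: str | Path) -> None:
    """Write the cohort as an all-sites VCF 4.2 (deterministic bytes).

    Every position of the region gets a record; invariant positions carry
    ALT "." and homozygous-reference genotypes. The outgroup allele goes to
    INFO/AA, the functional class to INFO/FCLASS.
    """
    params = cohort.params
    m = cohort.matrix
    var_pos0 = m.sites["pos"].to_numpy() - 1
    var_of_pos = {int(p): j for j, p in enumerate(var_pos0)}
    gt_str = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    inv_gts = "\t".join(["0/0"] * m.n_samples)

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=invflux\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,'
                 'Description="Ancestral (outgroup) allele">\n')
        fh.write('##INFO=<ID=FCLASS,Number=1,Type=String,'
                 'Description="Functional class">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        fh.write(f"##contig=<ID={params.chrom},length={params.L}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(m.samples) + "\n")
        for p in range(params.L):
            fclass = FCLASS_NAMES[cohort.fclass_codes[p]]
            j = var_of_pos.get(p)
            if j is None:
                ref = cohort.ref_bases[p]
                fh.write(f"{params.chrom}\t{p + 1}\t.\t{ref}\t.\t.\t.\t"
                         f"AA={ref};FCLASS={fclass}\tGT\t{inv_gts}\n")
            else:
                site = m.sites.iloc[j]
                gts = "\t".join(gt_str[int(g)] for g in m.genotypes[:, j])
                fh.write(f"{params.chrom}\t{p + 1}\t.\t{site.ref}\t"
                         f"{site.alt}\t.\t.\tAA={site.aa};FCLASS={fclass}"
                         f"\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Assembly truth and analytic alignments

@dataclass
class SyntheticAssemblyTruth:
    """Reference + per-sample contigs with a planted inversion, optionally
    flanked by an inverted duplication pair with a high-identity core."""

    params: CohortParams
    reference: str
    contigs: dict[str, str]
    inverted: dict[str, bool]
    inversion_interval: tuple[int, int]   # 0-based half-open on reference
    dup_len: int = 0
    dup_identity_pct: float = 100.0
    core_len: int = 0
    core_identity_pct: float = 100.0
    seed: int = 0

    @property
    def breakpoints_1based(self) -> tuple[int, int]:
        s, e = self.inversion_interval
        return s + 1, e


def _mutate_to_identity(rng: np.random.Generator, seq: np.ndarray,
                        identity_pct: float) -> None:
    """In-place substitution mutations bringing ``seq`` (char array) to the
    target percent identity against its original state."""
    n_mut = int(round(len(seq) * (1.0 - identity_pct / 100.0)))
    if n_mut == 0:
        return
    idx = rng.choice(len(seq), size=n_mut, replace=False)
    shift = rng.integers(1, 4, size=n_mut)
    base_idx = np.searchsorted(BASES, seq[idx])
    seq[idx] = BASES[(base_idx + shift) % 4]


def build_assembly_truth(params: CohortParams,
                         dup_len_bp: int = 0,
                         dup_identity_pct: float = 95.0,
                         core_len_bp: int = 0,
                         core_identity_pct: float = 97.0
                         ) -> SyntheticAssemblyTruth:
    """Build a reference and per-sample contigs with the inversion planted.

    The alternate (S) arrangement is the reference with the inversion
    interval reverse-complemented. When ``dup_len_bp`` > 0 an inverted
    duplication pair is planted immediately outside both breakpoints: the
    distal copy is the reverse complement of the proximal one, mutated to
    ``dup_identity_pct`` except for a central core of ``core_len_bp`` kept
    at ``core_identity_pct`` (>= 95 by construction of the defaults).
    """
    params.validate()
    start, end = params.inversion_interval
    if dup_len_bp:
        if not (50 < dup_identity_pct <= 100):
            raise ValueError("duplication identity must be in (50, 100]")
        if dup_len_bp >= end - start:
            raise ValueError("duplication longer than the inversion")
        if start - dup_len_bp < 0 or end + dup_len_bp > params.L:
            raise ValueError("no room to plant duplications outside the "
                             "inversion interval")
        if core_len_bp > dup_len_bp:
            raise ValueError("core cannot exceed the duplication length")
    rng = np.random.default_rng(params.seed + 7_919)
    ref = BASES[rng.integers(0, 4, size=params.L)].astype("U1")

    if dup_len_bp:
        prox = ref[start - dup_len_bp:start].copy()
        dist = np.array(list(revcomp("".join(prox))), dtype="U1")
        core_lo = (dup_len_bp - core_len_bp) // 2
        core_hi = core_lo + core_len_bp
        outside = np.concatenate([dist[:core_lo], dist[core_hi:]])
        _mutate_to_identity(rng, outside, dup_identity_pct)
        dist[:core_lo] = outside[:core_lo]
        dist[core_hi:] = outside[core_lo:]
        core = dist[core_lo:core_hi]
        _mutate_to_identity(rng, core, core_identity_pct)
        dist[core_lo:core_hi] = core
        ref[end:end + dup_len_bp] = dist

    ref_str = "".join(ref)
    inverted_str = (ref_str[:start] + revcomp(ref_str[start:end])
                    + ref_str[end:])
    contigs: dict[str, str] = {}
    inverted: dict[str, bool] = {}
    for sample, gt in params.truth_genotypes.items():
        if gt == "NN":
            contigs[sample] = ref_str
            inverted[sample] = False
        elif gt == "SS":
            contigs[sample] = inverted_str
            inverted[sample] = True
        else:
            contigs[f"{sample}_hap1"] = ref_str
            inverted[f"{sample}_hap1"] = False
            contigs[f"{sample}_hap2"] = inverted_str
            inverted[f"{sample}_hap2"] = True
    return SyntheticAssemblyTruth(
        params=params, reference=ref_str, contigs=contigs,
        inverted=inverted, inversion_interval=(start, end),
        dup_len=dup_len_bp, dup_identity_pct=dup_identity_pct,
        core_len=core_len_bp, core_identity_pct=core_identity_pct,
        seed=params.seed)


@dataclass
class EmittedAlignments:
    """Analytic block decomposition of contig-vs-reference alignments plus
    synthetic breakpoint-straddling split reads."""

    contig_blocks: dict[str, list[AlignmentBlock]]
    split_reads: dict[str, list[AlignmentBlock]]
    target_name: str
    target_length: int

    def all_contig_blocks(self) -> list[AlignmentBlock]:
        return [b for blocks in self.contig_blocks.values() for b in blocks]


def emit_alignments(truth: SyntheticAssemblyTruth,
                    out_dir: str | Path | None = None,
                    reads_per_breakpoint: int = 3,
                    read_len: int = 20_000) -> EmittedAlignments:
    """Emit the block decomposition an aligner would produce, analytically.

    An inverted contig yields forward / reverse / forward primary blocks
    with flips at the true breakpoints; a planted duplication pair adds the
    two short reverse-orientation cross-blocks near the breakpoints. For
    each inverted contig, ``reads_per_breakpoint`` split reads straddle
    each breakpoint: two segments of opposite orientation, the inner one
    mapping at the opposite end of the inversion. Optionally writes
    ``contigs.paf`` and ``reads.paf`` under ``out_dir``.
    """
    rng = np.random.default_rng(truth.seed + 104_729)
    start, end = truth.inversion_interval
    L = truth.params.L
    target = truth.params.chrom
    dlen = truth.dup_len
    dup_matches = int(round(dlen * truth.dup_identity_pct / 100.0))

    contig_blocks: dict[str, list[AlignmentBlock]] = {}
    split_reads: dict[str, list[AlignmentBlock]] = {}
    for name, is_inv in truth.inverted.items():
        blocks: list[AlignmentBlock] = []
        if is_inv:
            blocks.append(AlignmentBlock(name, 0, start, "+", target,
                                         0, start, start, start))
            blocks.append(AlignmentBlock(name, start, end, "-", target,
                                         start, end, end - start, end - start))
            blocks.append(AlignmentBlock(name, end, L, "+", target,
                                         end, L, L - end, L - end))
        else:
            blocks.append(AlignmentBlock(name, 0, L, "+", target, 0, L, L, L))
        if dlen:
            blocks.append(AlignmentBlock(name, start - dlen, start, "-",
                                         target, end, end + dlen,
                                         dup_matches, dlen))
            blocks.append(AlignmentBlock(name, end, end + dlen, "-",
                                         target, start - dlen, start,
                                         dup_matches, dlen))
        contig_blocks[name] = blocks

        if is_inv:
            # keep read halves on the sequence: outside parts need room
            # before the proximal / after the distal breakpoint, inside
            # parts must fit in the inverted segment
            max_half = min(read_len // 2, start - dlen, L - end - dlen,
                           (end - start) // 2)
            half = max(200, max_half)
            for i in range(reads_per_breakpoint):
                h_out = int(half + rng.integers(-half // 4, half // 4 + 1))
                h_in = 2 * half - h_out
                rp = f"{name}_read_prox_{i}"
                split_reads[rp] = [
                    AlignmentBlock(rp, 0, h_out, "+", target,
                                   start - h_out, start, h_out, h_out),
                    AlignmentBlock(rp, h_out, read_len, "-", target,
                                   end - h_in, end, h_in, h_in),
                ]
                rd = f"{name}_read_dist_{i}"
                split_reads[rd] = [
                    AlignmentBlock(rd, 0, h_in, "-", target,
                                   start, start + h_in, h_in, h_in),
                    AlignmentBlock(rd, h_in, read_len, "+", target,
                                   end, end + h_out, h_out, h_out),
                ]
    emitted = EmittedAlignments(contig_blocks, split_reads, target, L)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        qlens = {name: len(seq) for name, seq in truth.contigs.items()}
        write_paf(out_dir / "contigs.paf", emitted.all_contig_blocks(),
                  query_lengths=qlens, target_lengths={target: L})
        reads = [b for blocks in split_reads.values() for b in blocks]
        rlens = {b.query_name: read_len for b in reads}
        write_paf(out_dir / "reads.paf", reads, query_lengths=rlens,
                  target_lengths={target: L})
    return emitted


def emit_outgroup_alignments(truth: SyntheticAssemblyTruth
                             ) -> tuple[list[AlignmentBlock],
                                        list[AlignmentBlock]]:
    """Outgroup-vs-arrangement alignments for ancestral-orientation calls.

    The synthetic outgroup retains the reference (N) orientation, so its
    alignment to an N contig is one collinear forward block while the
    alignment to an S contig flips across the inversion.
    """
    start, end = truth.inversion_interval
    L = truth.params.L
    vs_n = [AlignmentBlock("outgroup", 0, L, "+", "N_allele", 0, L, L, L)]
    vs_s = [
        AlignmentBlock("outgroup", 0, start, "+", "S_allele",
                       0, start, start, start),
        AlignmentBlock("outgroup", start, end, "-", "S_allele",
                       start, end, end - start, end - start),
        AlignmentBlock("outgroup", end, L, "+", "S_allele",
                       end, L, L - end, L - end),
    ]
    return vs_n, vs_s
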