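# Methods

This note records the models, parameter defaults, numerical choices and
known limitations behind `invflux`. It states nothing the tests or the
analysis drivers do not themselves compute.

## The synthetic world

`simulate.simulate_cohort` emulates a species segregating for a
chromosomal inversion with two arrangement groups, N and S:

- **Inside the inversion interval** the genealogy is a clean
  two-population split (msprime, populations N and S diverging from one
  ancestral population at `T_split_gen`, an outgroup branching at
  `T_outgroup_gen`, all of size `Ne`). No migration after the split: in
  a heterokaryotype the inverted segment does not recombine between
  arrangements, so the arrangement itself behaves as a non-recombining
  locus while within-arrangement recombination proceeds normally.
- **Flanks** are drawn from a single panmictic population (plus the
  outgroup): arrangement groups only differ inside the interval, so flank
  differentiation is ≈ 0. This idealizes the empirically low flank F_ST;
  it does not reproduce the elevated divergence occasionally seen just
  outside real breakpoints.
- **Gene flux** is overlaid as discrete tract-copy events, matching the
  double-crossover / gene-conversion picture, not a continuous migration
  rate. A tract copies one donor haplotype's alleles over [start, end)
  into k recipient haplotypes. k is drawn uniformly on
  {1, …, 2·n_recipient − 1} (settable when planting): the tract is an old
  event whose copy has drifted in frequency. A single-carrier tract would
  be invisible to the dAF′ scan at realistic sample sizes — a 1/2n
  frequency never clears the combined-MAF floor with dAF′ < 1 — so the
  drifted-carrier model is what makes flux *detectable*, which is the
  phenomenon the generator exists to emulate. Tract lengths (when drawn
  rather than planted) are exponential with mean `flux_tract_len`; the
  tract-length law of real gene flux is unknown and no fidelity is
  claimed.
- **Mutations** are infinite-sites (continuous positions floored to
  integer base pairs; the rare position collision drops the later site).
  This deliberately excludes recurrent and back mutation, so an allele
  shared between arrangements inside the inversion can only come from
  ancestral sharing or flux — the no-flux law below relies on it.

### Defaults and why

| parameter | default | rationale |
|---|---|---|
| λ (per year) | 3.3×10⁻¹⁰ | the substitution rate used for herring dating |
| generation time | 6 y | herring generation time; μ/gen = λ × 6 |
| Ne | 10⁴ | workable variant density at desk-scale L (the species' historical Ne ≈ 4×10⁵ would need chromosome-scale L for the same site counts) |
| T_split_gen | 3×10⁵ | the estimated inversion age in generations (~2 MY at 6 y/gen) |
| T_outgroup_gen | 2×10⁶ | a sprat-like outgroup (~12 MY) |
| L, interval | 1 Mb, 300–700 kb | inversion a minority (40%) of the region, as real inversions are of their chromosomes; a majority-fraction inversion makes orientation-majority calling inherently ambiguous |
| recombination | 10⁻⁸ /bp/gen | vertebrate-typical; not stated for herring |
| functional classes | 5% non-syn, 5% syn, 90% noncoding | i.i.d. labels; downstream only consumes class counts, no codon model |
| flux_rate | 1 tract/region | occasional flux, the phenomenon under study |
| missing_rate | 0 | filters are exercised by injecting it explicitly |

With T_split = 30 coalescent units (2Ne = 2×10⁴), ancestral lineage
sharing between groups is vanishingly rare, so the **no-flux law** holds:
with `flux_rate=0`, every scanned inversion SNP has dAF′ exactly 1.0.
At splits of order 2–4 Ne (the dating-recovery setting) incomplete
lineage sorting *can* produce shared polymorphism; the law is a property
of the default stated world, not of arbitrarily young splits.

### What a green test does not establish

The generator has no selection, no TE dynamics, no reference bias, no
genotyping error model beyond uniform missingness, substitution-only
divergence for the planted duplications (no indels — the duplication
aligner exploits this by staying on one diagonal), and flanks with zero
real structure. Green tests establish the estimators' correctness on
their stated inputs and the recoverability of planted truth, not realism
of herring chromosomes.

## Breakpoint calling

Blocks below `min_block_len` (default 10 kb, the threshold used to keep
non-specific contigs out of real alignments) are dropped; the remainder,
sorted along the reference, are merged into maximal same-strand runs.
Two same-strand blocks do **not** merge across a gap mostly (>50%)
covered by opposite-strand alignment — otherwise the two short reverse
hits of an inverted-duplication pair, sitting on either side of a long
forward block, would merge into a spurious inversion-sized run on
non-inverted samples. The inverted segment is the longest run of the
*minority* strand (by total aligned length, ties preferring "−"): using
the minority rather than literally the reverse strand makes the call
invariant to reverse-complementing the query. Majority-strand alignment
covering a flip point moves the corresponding breakpoint inward
(conservative rule: duplications, indels and repeats at the breakpoints
are placed outside the inversion, so the interval can shrink, never
grow). Runs shorter than `min_inversion_len` (default 100 kb) give a
typed "no inversion" result — heterokaryotype haplotypes and
reference-arrangement samples are normal inputs, not errors. Two
equal-length maximal runs raise an error listing both intervals: such a
case (e.g. a distant alternative distal breakpoint vs a secondary
inversion) needs eyes, not a tie-break.

Monotonicity of the called interval in `min_block_len` is verified on
emitter-generated block sets; it is not a theorem for adversarial inputs
(deleting a forward block that separates two reverse runs can merge
them).

**Consensus and shifts.** Consensus is the per-end modal coordinate, ties
to the smallest; shifts are absolute deviations, zero rendered "-". The
consensus may also be supplied externally (it may rest on more evidence
than the calls at hand — for the bundled published table the Chr6
consensus distal coordinate matches none of its four sample rows); only a
computed consensus is required to coincide with some call.

**Inverted duplications.** Proximal flank vs reverse-complemented distal
flank; exact 21-mer seeds grouped by diagonal, chained within 2 kb,
extended while the 500-bp windowed identity holds, reported at
`min_len`/`min_identity_pct`. Identity = matches / aligned columns × 100
(the diagonal model has no gap columns; on real indel-bearing sequence a
banded aligner would be needed and identities would read lower). The core
is the longest stretch whose every 500-bp window meets
`core_identity_pct`; core length is therefore resolved to the window
size.

**Split reads.** A read supports a call if it has exactly two
opposite-strand segments, exactly one mapping inside the called interval,
and the junction-side edge of the *outside* segment lies within `tol_bp`
(default 500) of a breakpoint. The straddled breakpoint is the one at
that junction; the inside segment maps at the opposite end in reverse
orientation.

**Ancestral orientation.** The arrangement whose outgroup alignment runs
through the interval forward-strand and monotone in both coordinate axes
is ancestral; a flip against both or neither, or coverage below
`min_cover_frac` (default 0.5, with a warning — fragmented outgroup
alignments occur), returns "ambiguous".

## Genotyping

The diagnostic panel assumes the S allele is the one at frequency > 0.5
in a reference population known to be S-enriched; sites at exactly 0.5
are dropped. Candidates are additionally ascertained to be diagnostic:
combined MAF ≥ `maf_floor` (0.2) and between-group frequency difference ≥
`min_daf` (0.8) against the rest of the cohort — without ascertainment
the dosage would be diluted by undifferentiated sites. Per-sample
S-dosage is the mean S-allele count / 2 over ≥ `min_sites` called panel
sites; labels: ≤ 0.25 NN, ≥ 0.75 SS, else NS (symmetric thresholds;
config-exposed; the published heatmap states no calling rule).

Windowed PCA uses non-overlapping 200-SNP windows ("sliding" with an
unstated step is read as step = window), mean-imputes missing genotypes,
and projects on the leading covariance eigenvector, sign-anchored so
declared SS references are positive. Karyotypes from PC1 take per-sample
medians over in-interval windows and cluster them with 1-D k-means
(k = 3, centers initialized at the min/median/max), labelling clusters by
panel-genotyped anchors when available, else by extremity. Degenerate
inputs (fewer distinct medians than clusters) fall back to fewer
clusters.

## Population genetics

π, d_xy: sums of per-site allele-pair differences over sums of allele-pair
comparisons, with invariant sites contributing comparisons (all-sites
denominators); windows are fixed 20-kb, step config-exposed. A window
with zero comparisons reports missing values — never zero — and F_ST is
missing where d_xy = 0. Hudson's ratio-of-averages form is used
(self-contained, no variance components); negative estimates in
near-undifferentiated windows are reported and flagged, not clipped.
Whether windowed F_ST should count invariant sites is moot under this
estimator: they add equal mass to numerator and denominator of each π and
d_xy and cancel in the ratio (a test verifies the window ordering is
unchanged).

Dating uses region-*total* counts (not means of per-window ratios, which
would weight windows by inverse data density), then d_a = d_xy −
(d_x + d_y)/2 and T = d_a/2λ. When only variant sites are materialized,
the invariant remainder enters the denominators as fully-called
comparisons. Gene flux transfers shared variation and so biases T
downward — visible in the worked example and expected for real inversion
ages.

LD: greedy left-to-right thinning to ≥ `thin_bp` (5 kb), then squared
Pearson correlation of dosages over samples called at both sites.
Polarized SFS: derived = the allele differing from the outgroup allele
AA; sites where AA matches neither allele are excluded and counted.
Missing AA excludes a site from polarized analyses only.
Hardy-Weinberg: exact conditional test (closed-form log-factorial
probabilities of each heterozygote count given allele counts; two-sided
by summing probabilities ≤ observed).

## Gene-flux scan

The combined-cohort minor allele is fixed first (tie at 0.5 → alt), then
per-group frequencies, dAF and dAF′ — in that order, so both groups'
frequencies refer to the same allele and the scan is invariant under
swapping group labels. Heterokaryotypes are excluded by construction
(the scan takes NN and SS samples only). Monomorphic-in-both-groups
sites give a typed result, never a division by zero. Extreme =
dAF strictly > 0.95. Enrichment: p(category) from all scanned records,
expected = p(category) × n(extreme), Pearson χ² with categories of
expected < 1 pooled into "other" (reported unpooled as well). The χ² is
calibrated when the extreme fraction is small; with a large extreme
fraction the conditioning on the extreme total deflates the statistic
(finite-population correction) and the test turns conservative. The
run-based export of low-dAF′ regions (≥ k consecutive SNPs below a
cutoff) is an aggregation convenience beyond the per-SNP scan, labelled
as such.

## Known limitations

- The duplication aligner is substitution-only (diagonal); real
  breakpoint repeats with indels need an external banded aligner.
- Flank sequence is panmictic: no isolation-by-distance, no
  breakpoint-adjacent divergence.
- The dAF′ scan needs ≥ 2 diploids per homozygote group and loses power
  rapidly below ~5.
- `allsites_matrix()`/VCF emission materialize every position; intended
  for ≤ a few Mb.
- Strand-majority breakpoint calling is undefined when the inversion
  (plus its duplications) covers ≥ half the aligned span; the caller
  surfaces this as its ambiguity error rather than guessing.
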