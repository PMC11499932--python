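"""Scan the inversion for gene flux with dAF', classify extreme SNPs and
test functional-category enrichment.

The planted 80-kb tract is the only interval where dAF' drops below 0.5;
everywhere else in the inversion the minor allele stays private
(dAF' = 1). Writes results/05_geneflux/{daf,enrichment,flux_runs}.tsv.
"""

import pandas as pd

from common import FLUX_TRACT, homozygote_groups, outdir, showcase_cohort
from invflux import geneflux as gf


def main() -> None:
    out = outdir("05_geneflux")
    cohort = showcase_cohort()
    nn, ss = homozygote_groups(cohort)
    s, e = cohort.truth.inversion_interval

    records = gf.scan(cohort.matrix, nn, ss, maf_floor=0.2)
    extreme = gf.classify_extreme(records, daf_threshold=0.95)
    gf.records_frame(records, extreme).to_csv(out / "daf.tsv", sep="\t",
                                              index=False)
    inside = [r for r in records if s < r.pos <= e]
    shared = [r for r in inside if r.daf_prime < 0.5]
    in_tract = [r for r in shared
                if FLUX_TRACT[0] < r.pos <= FLUX_TRACT[1]]
    print(f"{len(records)} SNPs scanned, {len(inside)} in the inversion; "
          f"{int(extreme.sum())} extreme (dAF > 0.95)")
    print(f"{len(shared)} inversion SNPs show dAF' < 0.5; "
          f"{len(in_tract)} of them fall in the planted tract "
          f"{FLUX_TRACT[0] + 1:,}-{FLUX_TRACT[1]:,}")

    runs = gf.low_daf_prime_runs(records, cutoff=0.5, min_run=3)
    frame = pd.DataFrame(runs, columns=["chrom", "start0", "end0", "n_snps"])
    frame["in_inversion"] = (frame["start0"] >= s) & (frame["end0"] <= e)
    frame.to_csv(out / "flux_runs.tsv", sep="\t", index=False)
    for chrom, lo, hi, n, inside_inv in frame.itertuples(index=False):
        where = "inversion" if inside_inv else "flank (panmictic background)"
        print(f"candidate flux region {chrom}:{lo + 1:,}-{hi:,} "
              f"({n} consecutive low-dAF' SNPs, {where})")

    res = gf.enrichment(records, extreme)
    res.table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    if res.p_value is not None:
        print(f"functional enrichment of extreme SNPs: chi2 = {res.chi2:.2f}"
              f" (dof {res.dof}), p = {res.p_value:.3f}")


if __name__ == "__main__":
    main()
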