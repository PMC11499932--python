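"""Simulate the showcase inversion cohort and summarize what it contains.

Writes the sample table, the ground-truth breakpoints and the planted
gene-flux tract under results/01_simulate/.
"""

import pandas as pd

from common import FLUX_TRACT, PARAMS, homozygote_groups, outdir, \
    showcase_cohort


def main() -> None:
    out = outdir("01_simulate")
    cohort = showcase_cohort()
    m = cohort.matrix
    nn, ss = homozygote_groups(cohort)
    s, e = cohort.truth.inversion_interval

    pd.DataFrame({
        "sample": m.samples,
        "truth_genotype": [cohort.truth.genotypes[x] for x in m.samples],
    }).to_csv(out / "samples.tsv", sep="\t", index=False)
    pd.DataFrame([{
        "chrom": cohort.chrom, "proximal": s + 1, "distal": e,
        "T_split_gen": PARAMS.T_split_gen,
        "flux_tract_start": FLUX_TRACT[0] + 1,
        "flux_tract_end": FLUX_TRACT[1],
        "flux_donor": FLUX_TRACT[2],
    }]).to_csv(out / "truth.tsv", sep="\t", index=False)

    inv_sites = int(m.region_mask(cohort.chrom, s, e).sum())
    print(f"cohort: {m.n_samples} diploids ({len(nn)} NN, {len(ss)} SS), "
          f"{m.n_sites} variant sites over {PARAMS.L/1e6:.1f} Mb")
    print(f"inversion {cohort.chrom}:{s + 1:,}-{e:,} holds {inv_sites} "
          f"variant sites; one planted flux tract "
          f"{FLUX_TRACT[0] + 1:,}-{FLUX_TRACT[1]:,} ({FLUX_TRACT[2]} donor)")


if __name__ == "__main__":
    main()
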