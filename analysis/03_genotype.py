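"""Genotype every individual for the inversion by diagnostic panel and by
sliding-window PCA, and compare both with the simulated truth.

Writes results/03_genotype/genotypes.tsv.
"""


from common import homozygote_groups, outdir, showcase_cohort
from invflux import genotyping as gen


def main() -> None:
    out = outdir("03_genotype")
    cohort = showcase_cohort()
    m = cohort.matrix
    s, e = cohort.truth.inversion_interval
    _, ss = homozygote_groups(cohort)

    panel = gen.polarize_panel(m, ss, interval=(cohort.chrom, s, e))
    by_panel = gen.genotype_by_panel(m, panel)
    traj = gen.windowed_pca(m, window_snps=100, ss_reference=ss)
    by_pca = gen.call_from_pc1(traj, (s, e), anchors=by_panel)

    merged = by_panel.merge(by_pca, on="sample", suffixes=("_panel", "_pca"))
    merged["truth"] = [cohort.truth.genotypes[x] for x in merged["sample"]]
    merged.to_csv(out / "genotypes.tsv", sep="\t", index=False)

    acc_panel = (merged["genotype_panel"] == merged["truth"]).mean()
    acc_pca = (merged["genotype_pca"] == merged["truth"]).mean()
    print(f"diagnostic panel: {len(panel)} sites; "
          f"truth concordance {acc_panel:.0%} (panel), {acc_pca:.0%} (PCA)")
    print(f"PC1 trajectories over {len(traj.frame)} windows of "
          f"{traj.window_snps} SNPs")


if __name__ == "__main__":
    main()
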