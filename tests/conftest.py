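import numpy as np
import pandas as pd
import pytest

from invflux.io import GenotypeMatrix
from invflux.simulate import (CohortParams, build_assembly_truth,
                              emit_alignments, simulate_cohort)


def make_matrix(genotypes, positions=None, chrom="chr1", ref="A", alt="C",
                aa=None, fclass=None, samples=None):
    """Small hand-built genotype matrix for unit tests."""
    gt = np.asarray(genotypes, dtype=np.int8)
    n_samples, n_sites = gt.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1)
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    sites = pd.DataFrame({
        "chrom": chrom,
        "pos": positions,
        "ref": [ref] * n_sites,
        "alt": [alt] * n_sites if not isinstance(alt, list) else alt,
        "aa": [aa] * n_sites if not isinstance(aa, list) else aa,
        "fclass": [fclass] * n_sites if not isinstance(fclass, list)
        else fclass,
    })
    return GenotypeMatrix(samples, sites, gt)


SMALL_WORLD = dict(L=200_000, inversion_interval=(40_000, 160_000),
                   T_split_gen=300_000.0, T_outgroup_gen=2_000_000.0)


@pytest.fixture(scope="session")
def cohort_no_flux():
    """A mid-size no-flux cohort reused across modules (seed-fixed)."""
    params = CohortParams(seed=11, flux_rate=0, **SMALL_WORLD)
    return simulate_cohort(params)


@pytest.fixture(scope="session")
def truth_groups(cohort_no_flux):
    truth = cohort_no_flux.truth.genotypes
    return {label: sorted(s for s, g in truth.items() if g == label)
            for label in ("NN", "NS", "SS")}


@pytest.fixture(scope="session")
def assembly_world():
    """Assembly truth + analytic alignments, clean and with planted 8-kb
    inverted duplications (92% identity, 3-kb core)."""
    params = CohortParams(seed=2, n_N=2, n_S=2, n_het=1, L=400_000,
                          inversion_interval=(150_000, 270_000))
    clean = build_assembly_truth(params)
    dup = build_assembly_truth(params, dup_len_bp=8_000,
                               dup_identity_pct=92.0, core_len_bp=3_000)
    return {
        "params": params,
        "clean": clean,
        "clean_alignments": emit_alignments(clean),
        "dup": dup,
        "dup_alignments": emit_alignments(dup),
    }
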