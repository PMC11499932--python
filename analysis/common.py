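"""Shared stated world for the numbered analysis drivers.

One herring-like synthetic inversion cohort: 1 Mb region, a 600-kb
inversion, 10 NN + 10 SS + 2 NS diploids plus a haploid outgroup,
arrangement split 3e5 generations ago, one planted 80-kb gene-flux tract
(S -> N, 11 carrier haplotypes) so the dAF' scan has a real signal to
find. Every driver re-simulates deterministically from the same seed, so
each script is self-contained and only small summary tables are written
under results/.
"""

from pathlib import Path

from invflux.simulate import CohortParams, simulate_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"

SEED = 1
PARAMS = CohortParams(seed=SEED, flux_rate=0)
FLUX_TRACT = (400_000, 480_000, "S", 11)  # start, end, donor, carriers
DUP_LEN_BP = 8_000
DUP_IDENTITY_PCT = 92.0
CORE_LEN_BP = 3_000


def showcase_cohort():
    return simulate_cohort(PARAMS, tracts=[FLUX_TRACT])


def homozygote_groups(cohort):
    gts = cohort.truth.genotypes
    return ([s for s, g in gts.items() if g == "NN"],
            [s for s, g in gts.items() if g == "SS"])


def outdir(name: str) -> Path:
    path = RESULTS / name
    path.mkdir(parents=True, exist_ok=True)
    return path
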