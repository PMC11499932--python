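"""Bundled reference tables.

``published_breakpoint_table`` carries the published per-sample inversion
breakpoint coordinates for the four Atlantic herring inversions (Chr6,
Chr12, Chr17, Chr23), together with the published consensus coordinates
and the printed per-sample shifts ("-" denotes zero). The Chr6 sample CS2
distal coordinate lies ~559 kb from the consensus — either a different
distal breakpoint or a secondary inversion; the table reports it as
printed. Note the published consensus was established on more evidence
than these rows alone (for Chr6 the consensus distal coordinate matches no
single row), which is why consensus coordinates are carried as data rather
than recomputed.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["published_breakpoint_table"]


def published_breakpoint_table() -> pd.DataFrame:
    """Per-sample breakpoint calls for the four herring inversions.

    Columns: inversion, sample, proximal, distal, consensus_proximal,
    consensus_distal, shift_proximal, shift_distal (shifts as printed,
    "-" for zero). Coordinates are 1-based on the reference assembly.
    """
    ref = resources.files("invflux") / "data" / "herring_breakpoints.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype={
            "proximal": "int64", "distal": "int64",
            "consensus_proximal": "int64", "consensus_distal": "int64",
            "shift_proximal": "string", "shift_distal": "string",
        })
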