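"""Inversion breakpoint calling from alignment orientation flips.

A sample carrying the alternate arrangement aligns to the reference as a
forward block, a reverse-strand block spanning the inverted segment, and a
forward block again; the coordinates where orientation flips are the
breakpoints. Calls are conservative: structural noise (duplications,
indels, repeats) overlapping a flip point is placed *outside* the
inversion, so the called interval can shrink but never grow. Per-sample
calls are summarized into consensus coordinates (per-end mode) with
per-sample shifts.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import AlignmentBlock

__all__ = [
    "BreakpointCall",
    "ConsensusBreakpoints",
    "InvertedDupBlock",
    "AmbiguousInversionError",
    "call_inversion",
    "consensus_and_shifts",
    "find_inverted_duplications",
    "split_read_support",
    "call_ancestral_orientation",
]

DEFAULT_MIN_BLOCK_LEN = 10_000   # discard non-specific short alignments
DEFAULT_MIN_INVERSION_LEN = 100_000


class AmbiguousInversionError(ValueError):
    """Two minority-strand runs of equal maximal span: the caller refuses
    to choose (e.g. a distant distal breakpoint vs a secondary inversion)."""

    def __init__(self, runs: list[tuple[int, int]]):
        self.runs = runs
        super().__init__(
            "ambiguous inversion: equal-length candidate runs "
            + ", ".join(f"[{a}, {b})" for a, b in runs))


@dataclass(frozen=True)
class BreakpointCall:
    """Per-sample inversion interval, 1-based inclusive coordinates."""

    sample: str
    chrom: str
    proximal: int
    distal: int
    n_blocks: int = 0
    n_split_reads: int = 0

    def __post_init__(self) -> None:
        if not self.proximal < self.distal:
            raise ValueError("proximal breakpoint must precede distal")

    @property
    def interval0(self) -> tuple[int, int]:
        """The inverted segment as 0-based half-open."""
        return self.proximal - 1, self.distal


@dataclass
class ConsensusBreakpoints:
    chrom: str
    proximal: int
    distal: int
    shifts: dict[str, tuple[int, int]]  # sample -> (|d prox|, |d dist|)
    supplied: bool = False  # consensus given externally, not computed

    def to_frame(self) -> pd.DataFrame:
        """Per-sample shifts with zeros rendered "-", publication style."""
        rows = [
            {"sample": s,
             "shift_proximal": "-" if p == 0 else str(p),
             "shift_distal": "-" if d == 0 else str(d)}
            for s, (p, d) in self.shifts.items()
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class InvertedDupBlock:
    """An inverted duplication pair flanking a breakpoint, with its
    high-identity core (the presumed ectopic-recombination substrate)."""

    prox_start: int
    prox_end: int
    dist_start: int
    dist_end: int
    length: int
    identity_pct: float
    core_start: int  # coordinates on the proximal flank
    core_end: int
    core_identity_pct: float

    def __post_init__(self) -> None:
        if not (0 <= self.identity_pct <= 100):
            raise ValueError("identity must be a percentage")
        if self.core_end - self.core_start > self.length:
            raise ValueError("core cannot exceed block length")


# ---------------------------------------------------------------------------
# Inversion calling

def _covered_frac(lo: int, hi: int,
                  intervals: Sequence[tuple[int, int]]) -> float:
    if hi <= lo:
        return 0.0
    covered = 0
    last = lo
    for s, e in sorted(intervals):
        s, e = max(s, lo), min(e, hi)
        if e > max(s, last):
            covered += e - max(s, last)
            last = e
    return covered / (hi - lo)


def _strand_runs(blocks: Sequence[AlignmentBlock]
                 ) -> list[tuple[str, int, int, int]]:
    """Maximal same-strand runs on the target axis: (strand, start, end,
    n_blocks). Blocks must be sorted by target start.

    Consecutive same-strand blocks do not merge across a gap that is
    mostly covered by opposite-strand alignment: two short reverse
    duplication hits on either side of a long forward block are two runs,
    not one spurious inversion-sized run.
    """
    by_strand = {"+": [], "-": []}
    for b in blocks:
        by_strand[b.strand].append((b.target_start, b.target_end))
    runs: list[tuple[str, int, int, int]] = []
    for b in blocks:
        if runs and runs[-1][0] == b.strand:
            s, st, en, n = runs[-1]
            opposite = by_strand["-" if b.strand == "+" else "+"]
            if _covered_frac(en, b.target_start, opposite) <= 0.5:
                runs[-1] = (s, st, max(en, b.target_end), n + 1)
                continue
        runs.append((b.strand, b.target_start, b.target_end, 1))
    return runs


def call_inversion(blocks: Sequence[AlignmentBlock],
                   min_block_len: int = DEFAULT_MIN_BLOCK_LEN,
                   min_inversion_len: int = DEFAULT_MIN_INVERSION_LEN,
                   sample: str = "sample") -> BreakpointCall | None:
    """Call an inversion from one sample's alignment to one reference
    chromosome.

    Blocks shorter than ``min_block_len`` on the target axis are dropped;
    the remainder are merged into maximal same-strand runs, and the longest
    run of the *minority* strand (by total aligned length) is the inverted
    segment. Majority-strand alignment overlapping a flip point shifts the
    corresponding breakpoint inward (conservative rule). Returns None when
    no minority run reaches ``min_inversion_len``; raises
    AmbiguousInversionError on equal-length maximal runs.
    """
    kept = sorted((b for b in blocks if b.target_span >= min_block_len),
                  key=lambda b: (b.target_start, b.target_end))
    if not kept:
        return None
    chroms = {b.target_name for b in kept}
    if len(chroms) > 1:
        raise ValueError(f"blocks span multiple targets: {sorted(chroms)}")
    total = {"+": 0, "-": 0}
    for b in kept:
        total[b.strand] += b.target_span
    if total["+"] == 0 or total["-"] == 0:
        return None  # single orientation: no inversion signal
    # the inverted segment aligns on the minority strand; ties prefer "-"
    # (query assumed in reference orientation)
    minority = "-" if total["-"] <= total["+"] else "+"

    runs = _strand_runs(kept)
    inv_runs = [r for r in runs if r[0] == minority]
    spans = [(en - st) for _, st, en, _ in inv_runs]
    best = max(spans)
    if best < min_inversion_len:
        return None
    winners = [r for r, sp in zip(inv_runs, spans) if sp == best]
    if len(winners) > 1:
        raise AmbiguousInversionError([(r[1], r[2]) for r in winners])
    _, prox, dist, n_blocks = winners[0]

    # conservative rule: majority-strand alignment covering a flip point
    # is placed outside the inversion -> breakpoints move inward
    majority_blocks = [b for b in kept if b.strand != minority]
    moved = True
    while moved:
        moved = False
        for b in majority_blocks:
            if b.target_start <= prox < b.target_end and b.target_end <= dist:
                prox = b.target_end
                moved = True
            if b.target_start < dist <= b.target_end and b.target_start >= prox:
                dist = b.target_start
                moved = True
    if prox >= dist:
        return None
    return BreakpointCall(sample=sample, chrom=next(iter(chroms)),
                          proximal=prox + 1, distal=dist, n_blocks=n_blocks)


def consensus_and_shifts(calls: Sequence[BreakpointCall],
                         consensus: tuple[int, int] | None = None
                         ) -> ConsensusBreakpoints:
    """Consensus breakpoints (per-end mode, ties to the smallest
    coordinate) and per-sample absolute shifts.

    ``consensus`` overrides the modal computation when the consensus is
    established externally (e.g. from a larger cohort than the calls at
    hand); in that case it need not coincide with any per-sample call.
    """
    if not calls:
        raise ValueError("need at least one breakpoint call")
    chroms = {c.chrom for c in calls}
    if len(chroms) > 1:
        raise ValueError(f"calls mix chromosomes: {sorted(chroms)}")

    def mode_min(values: Iterable[int]) -> int:
        counts = Counter(values)
        top = max(counts.values())
        return min(v for v, n in counts.items() if n == top)

    if consensus is None:
        cons_prox = mode_min(c.proximal for c in calls)
        cons_dist = mode_min(c.distal for c in calls)
        supplied = False
    else:
        cons_prox, cons_dist = consensus
        supplied = True
    shifts = {
        c.sample: (abs(c.proximal - cons_prox), abs(c.distal - cons_dist))
        for c in calls
    }
    return ConsensusBreakpoints(chrom=next(iter(chroms)), proximal=cons_prox,
                                distal=cons_dist, shifts=shifts,
                                supplied=supplied)


# ---------------------------------------------------------------------------
# Inverted duplications

_COMP = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def find_inverted_duplications(prox_flank: str,
                               dist_flank: str,
                               min_len: int = 1_000,
                               min_identity_pct: float = 85.0,
                               core_identity_pct: float = 95.0,
                               k: int = 21,
                               window: int = 500,
                               max_seed_gap: int = 2_000
                               ) -> list[InvertedDupBlock]:
    """Detect inverted duplication blocks between two breakpoint flanks.

    The proximal flank is compared against the reverse complement of the
    distal flank with a seed-anchored diagonal alignment: exact ``k``-mer
    seeds are grouped by diagonal, chained when closer than
    ``max_seed_gap``, extended while the ``window``-bp identity stays at or
    above ``min_identity_pct``, and reported when the block reaches
    ``min_len`` and its overall identity (matches / aligned columns; the
    diagonal model scores indels as absent) reaches ``min_identity_pct``.
    Each block's core is the longest stretch whose windowed identity stays
    at or above ``core_identity_pct``. Blocks are sorted by length,
    longest first.
    """
    if not prox_flank or not dist_flank:
        raise ValueError("flank sequences must be non-empty")
    if len(prox_flank) > 1_000_000 or len(dist_flank) > 1_000_000:
        raise ValueError("flanks above 1 Mb: extract breakpoint regions first")
    q = prox_flank.upper()
    t = revcomp(dist_flank.upper())

    index: dict[str, list[int]] = {}
    for i in range(len(t) - k + 1):
        index.setdefault(t[i:i + k], []).append(i)
    by_diag: dict[int, list[int]] = {}
    for i in range(len(q) - k + 1):
        for j in index.get(q[i:i + k], ()):
            by_diag.setdefault(i - j, []).append(i)

    blocks: list[InvertedDupBlock] = []
    for diag, qpos in by_diag.items():
        qpos = sorted(set(qpos))
        chains: list[tuple[int, int]] = []
        start = prev = qpos[0]
        for p in qpos[1:]:
            if p - prev > max_seed_gap:
                chains.append((start, prev + k))
                start = p
            prev = p
        chains.append((start, prev + k))
        for lo, hi in chains:
            block = _extend_block(q, t, diag, lo, hi, min_identity_pct, window)
            if block is None:
                continue
            b_lo, b_hi, match = block
            length = b_hi - b_lo
            if length < min_len:
                continue
            identity = 100.0 * match.mean()
            if identity < min_identity_pct:
                continue
            core = _longest_core(match, core_identity_pct, window)
            if core is None:
                core_lo, core_hi, core_id = b_lo, b_lo, 0.0
            else:
                c_lo, c_hi = core
                core_lo, core_hi = b_lo + c_lo, b_lo + c_hi
                core_id = 100.0 * match[c_lo:c_hi].mean()
            # distal-flank coordinates of the matched segment
            t_lo, t_hi = b_lo - diag, b_hi - diag
            d_hi = len(dist_flank) - t_lo
            d_lo = len(dist_flank) - t_hi
            blocks.append(InvertedDupBlock(
                prox_start=b_lo, prox_end=b_hi,
                dist_start=d_lo, dist_end=d_hi,
                length=length, identity_pct=identity,
                core_start=core_lo, core_end=core_hi,
                core_identity_pct=core_id,
            ))
    blocks.sort(key=lambda b: (-b.length, b.prox_start))
    return _dedupe_blocks(blocks)


def _extend_block(q: str, t: str, diag: int, lo: int, hi: int,
                  min_identity_pct: float, window: int
                  ) -> tuple[int, int, np.ndarray] | None:
    """Extend a seed chain along its diagonal while windowed identity
    holds; returns (q_lo, q_hi, per-column match array)."""
    q_min = max(0, diag)
    q_max = min(len(q), len(t) + diag)
    if q_min >= q_max:
        return None
    qa = np.frombuffer(q[q_min:q_max].encode(), dtype=np.uint8)
    ta = np.frombuffer(t[q_min - diag:q_max - diag].encode(), dtype=np.uint8)
    match = qa == ta
    lo_i, hi_i = lo - q_min, hi - q_min
    thr = min_identity_pct / 100.0
    while lo_i > 0:
        step = min(window, lo_i)
        if match[lo_i - step:lo_i].mean() >= thr:
            lo_i -= step
        else:
            break
    while hi_i < len(match):
        step = min(window, len(match) - hi_i)
        if match[hi_i:hi_i + step].mean() >= thr:
            hi_i += step
        else:
            break
    # trim mismatching edges
    while lo_i < hi_i and not match[lo_i]:
        lo_i += 1
    while hi_i > lo_i and not match[hi_i - 1]:
        hi_i -= 1
    if hi_i <= lo_i:
        return None
    return q_min + lo_i, q_min + hi_i, match[lo_i:hi_i]


def _longest_core(match: np.ndarray, core_identity_pct: float,
                  window: int) -> tuple[int, int] | None:
    """Longest contiguous stretch whose every ``window``-bp sliding window
    meets the core identity threshold."""
    n = len(match)
    if n < window:
        ok = np.array([match.mean() >= core_identity_pct / 100.0])
        return (0, n) if ok[0] else None
    csum = np.concatenate([[0], np.cumsum(match)])
    win_id = (csum[window:] - csum[:-window]) / window  # window starting at i
    ok = win_id >= core_identity_pct / 100.0
    best: tuple[int, int] | None = None
    i = 0
    while i < len(ok):
        if ok[i]:
            j = i
            while j < len(ok) and ok[j]:
                j += 1
            span = (i, j - 1 + window)  # windows i..j-1 all pass
            if best is None or span[1] - span[0] > best[1] - best[0]:
                best = span
            i = j
        else:
            i += 1
    return best


def _dedupe_blocks(blocks: list[InvertedDupBlock]) -> list[InvertedDupBlock]:
    """Drop blocks mostly contained in an already-kept longer block."""
    kept: list[InvertedDupBlock] = []
    for b in blocks:
        redundant = False
        for other in kept:
            overlap = (min(b.prox_end, other.prox_end)
                       - max(b.prox_start, other.prox_start))
            if overlap > 0.8 * b.length:
                redundant = True
                break
        if not redundant:
            kept.append(b)
    return kept


# ---------------------------------------------------------------------------
# Split-read support

def split_read_support(read_blocks: Mapping[str, Sequence[AlignmentBlock]],
                       call: BreakpointCall,
                       tol_bp: int = 500) -> dict[str, int]:
    """Count reads whose split alignment supports a breakpoint call.

    A supporting read has exactly two primary segments of opposite strand;
    its junction (the target coordinate where the query switches segments)
    must fall within ``tol_bp`` of a breakpoint, and the inside segment
    must map within the called interval. Returns counts per breakpoint.
    """
    prox0, dist0 = call.interval0
    support = {"proximal": 0, "distal": 0}
    for read, blocks in read_blocks.items():
        if len(blocks) != 2:
            continue
        a, b = sorted(blocks, key=lambda x: x.query_start)
        if a.strand == b.strand:
            continue

        def inside(seg: AlignmentBlock) -> bool:
            return (seg.target_start >= prox0 - tol_bp
                    and seg.target_end <= dist0 + tol_bp)

        if not (inside(a) ^ inside(b)):
            continue
        # the breakpoint the read straddles is at the junction side of its
        # *outside* segment: the query-adjacent edge of that alignment
        outside, outside_is_first = (a, True) if inside(b) else (b, False)
        at_query_end = outside_is_first
        if (outside.strand == "+") == at_query_end:
            junction = outside.target_end
        else:
            junction = outside.target_start
        if abs(junction - prox0) <= tol_bp:
            support["proximal"] += 1
        elif abs(junction - dist0) <= tol_bp:
            support["distal"] += 1
    return support


# ---------------------------------------------------------------------------
# Ancestral orientation

def _collinear(blocks: Sequence[AlignmentBlock],
               interval: tuple[int, int]) -> tuple[bool, float]:
    """(is collinear, coverage fraction) of blocks over a target interval.

    Collinear means every overlapping block is forward-strand and block
    order is monotone in both query and target coordinates.
    """
    lo, hi = interval
    overlapping = sorted(
        (b for b in blocks if b.target_end > lo and b.target_start < hi),
        key=lambda b: b.target_start)
    covered = 0
    last_end = lo
    for b in overlapping:
        s, e = max(b.target_start, lo), min(b.target_end, hi)
        covered += max(0, e - max(s, last_end))
        last_end = max(last_end, e)
    coverage = covered / (hi - lo) if hi > lo else 0.0
    if any(b.strand == "-" for b in overlapping):
        return False, coverage
    q_starts = [b.query_start for b in overlapping]
    return q_starts == sorted(q_starts), coverage


def call_ancestral_orientation(blocks_vs_n: Sequence[AlignmentBlock],
                               blocks_vs_s: Sequence[AlignmentBlock],
                               interval_n: tuple[int, int],
                               interval_s: tuple[int, int] | None = None,
                               min_cover_frac: float = 0.5) -> str:
    """Which arrangement is ancestral, judged by outgroup collinearity.

    The arrangement whose alignment to the outgroup runs through the
    inversion interval without a strand flip is ancestral; a flip against
    both or neither, or insufficient coverage, yields "ambiguous".
    Intervals are 0-based half-open on the respective arrangement sequence.
    """
    interval_s = interval_s or interval_n
    ok_n, cov_n = _collinear(blocks_vs_n, interval_n)
    ok_s, cov_s = _collinear(blocks_vs_s, interval_s)
    if cov_n < min_cover_frac or cov_s < min_cover_frac:
        warnings.warn("outgroup alignment covers too little of the "
                      "inversion interval; call is ambiguous", stacklevel=2)
        return "ambiguous"
    if ok_n and not ok_s:
        return "N_ancestral"
    if ok_s and not ok_n:
        return "S_ancestral"
    return "ambiguous"
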