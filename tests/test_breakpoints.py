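import numpy as np
import pytest

from invflux.breakpoints import (AmbiguousInversionError, BreakpointCall,
                                 call_ancestral_orientation, call_inversion,
                                 consensus_and_shifts,
                                 find_inverted_duplications, revcomp,
                                 split_read_support)
from invflux.datasets import published_breakpoint_table
from invflux.io import AlignmentBlock
from invflux.simulate import emit_outgroup_alignments


def fwd(ts, te, q="contig", t="chr"):
    return AlignmentBlock(q, ts, te, "+", t, ts, te)


def rev(ts, te, q="contig", t="chr"):
    return AlignmentBlock(q, ts, te, "-", t, ts, te)


class TestCallInversion:
    def test_flip_points_become_1based_breakpoints(self):
        blocks = [fwd(0, 10_000), rev(10_000, 20_000), fwd(20_000, 30_000)]
        call = call_inversion(blocks, min_block_len=0, min_inversion_len=1_000)
        assert (call.proximal, call.distal) == (10_001, 20_000)

    def test_all_forward_is_no_inversion_not_an_error(self):
        assert call_inversion([fwd(0, 50_000)], min_block_len=0) is None

    def test_short_reverse_run_below_min_inversion_len(self):
        blocks = [fwd(0, 200_000), rev(200_000, 210_000), fwd(210_000, 400_000)]
        assert call_inversion(blocks, min_block_len=0,
                              min_inversion_len=100_000) is None

    def test_equal_length_runs_raise_listing_both(self):
        blocks = [fwd(0, 100_000), rev(100_000, 150_000), fwd(150_000, 200_000),
                  rev(200_000, 250_000), fwd(250_000, 300_000)]
        with pytest.raises(AmbiguousInversionError) as err:
            call_inversion(blocks, min_block_len=0, min_inversion_len=10_000)
        assert len(err.value.runs) == 2

    def test_recovers_planted_truth_exactly_on_clean_blocks(self, assembly_world):
        truth = assembly_world["clean"]
        em = assembly_world["clean_alignments"]
        for name, is_inv in truth.inverted.items():
            call = call_inversion(em.contig_blocks[name], sample=name)
            if is_inv:
                assert (call.proximal, call.distal) == truth.breakpoints_1based
            else:
                assert call is None

    def test_duplications_contained_and_within_dup_len(self, assembly_world):
        truth = assembly_world["dup"]
        em = assembly_world["dup_alignments"]
        t_prox, t_dist = truth.breakpoints_1based
        for name, is_inv in truth.inverted.items():
            call = call_inversion(em.contig_blocks[name], min_block_len=5_000,
                                  sample=name)
            if not is_inv:
                assert call is None
                continue
            # conservative rule: contained in truth, within dup length
            assert t_prox <= call.proximal
            assert call.distal <= t_dist
            assert call.proximal - t_prox <= truth.dup_len
            assert t_dist - call.distal <= truth.dup_len

    def test_min_block_len_monotonicity_on_emitter_output(self, assembly_world):
        """Raising the block-length floor never widens the interval."""
        for world in ("clean_alignments", "dup_alignments"):
            blocks = assembly_world[world].contig_blocks["S01"]
            widths = []
            for mbl in (0, 2_000, 5_000, 10_000, 20_000):
                call = call_inversion(blocks, min_block_len=mbl, sample="S01")
                if call is not None:
                    widths.append(call.distal - call.proximal)
            assert widths == sorted(widths, reverse=True)

    def test_orientation_symmetry(self, assembly_world):
        """Reverse-complementing the query leaves the interval unchanged."""
        blocks = assembly_world["clean_alignments"].contig_blocks["S01"]
        L = assembly_world["params"].L

        def rc(b):
            return AlignmentBlock(b.query_name, L - b.query_end,
                                  L - b.query_start,
                                  "-" if b.strand == "+" else "+",
                                  b.target_name, b.target_start, b.target_end,
                                  b.matches, b.block_len, b.mapq)

        a = call_inversion(blocks, sample="x")
        b = call_inversion([rc(b) for b in blocks], sample="x")
        assert (a.proximal, a.distal) == (b.proximal, b.distal)


class TestConsensusAndShifts:
    def test_modal_consensus_with_tie_to_smallest(self):
        calls = [BreakpointCall("a", "c", 100, 1_000),
                 BreakpointCall("b", "c", 100, 2_000),
                 BreakpointCall("d", "c", 200, 2_000),
                 BreakpointCall("e", "c", 200, 3_000)]
        cons = consensus_and_shifts(calls)
        assert (cons.proximal, cons.distal) == (100, 2_000)  # ties -> min
        assert cons.shifts["e"] == (100, 1_000)

    def test_single_call_consensus_is_itself(self):
        cons = consensus_and_shifts([BreakpointCall("a", "c", 10, 99)])
        assert (cons.proximal, cons.distal) == (10, 99)
        frame = cons.to_frame()
        assert list(frame.loc[0, ["shift_proximal", "shift_distal"]]) == \
            ["-", "-"]

    def test_mixed_chromosomes_rejected(self):
        with pytest.raises(ValueError, match="chromosomes"):
            consensus_and_shifts([BreakpointCall("a", "c1", 1, 9),
                                  BreakpointCall("b", "c2", 1, 9)])

    def test_published_table_shifts_reproduced_exactly(self):
        """Every published per-sample row reproduces its printed shift
        from the published consensus coordinates (all four inversions)."""
        table = published_breakpoint_table()
        assert len(table) == 22
        for inversion, rows in table.groupby("inversion"):
            calls = [BreakpointCall(r.sample, inversion, r.proximal, r.distal)
                     for r in rows.itertuples()]
            cons = consensus_and_shifts(
                calls, consensus=(int(rows["consensus_proximal"].iloc[0]),
                                  int(rows["consensus_distal"].iloc[0])))
            for r in rows.itertuples():
                want = (0 if r.shift_proximal == "-" else int(r.shift_proximal),
                        0 if r.shift_distal == "-" else int(r.shift_distal))
                assert cons.shifts[r.sample] == want, (inversion, r.sample)


class TestInvertedDuplications:
    def test_perfect_duplication_found_in_full(self):
        rng = np.random.default_rng(5)
        flank = "".join(rng.choice(list("ACGT"), size=20_000))
        dup = flank[-8_000:]
        dist = revcomp(dup) + "".join(rng.choice(list("ACGT"), size=12_000))
        blocks = find_inverted_duplications(flank, dist, min_len=1_000)
        assert blocks, "planted duplication missed"
        top = blocks[0]
        assert top.length == 8_000
        assert top.identity_pct == 100.0
        assert (top.core_start, top.core_end) == (top.prox_start, top.prox_end)

    def test_unrelated_random_sequences_yield_nothing(self):
        rng = np.random.default_rng(6)
        a = "".join(rng.choice(list("ACGT"), size=50_000))
        b = "".join(rng.choice(list("ACGT"), size=50_000))
        assert find_inverted_duplications(a, b, min_len=1_000,
                                          min_identity_pct=85.0) == []

    def test_mutated_block_with_clean_core(self):
        """90%-identity block with a pristine 3-kb centre: the reported
        core has about that length (window-size resolution)."""
        rng = np.random.default_rng(7)
        flank = "".join(rng.choice(list("ACGT"), size=15_000))
        dup = np.array(list(flank[-9_000:]), dtype="U1")
        # mutate outside the central 3 kb to ~90% identity
        outer = np.r_[np.arange(0, 3_000), np.arange(6_000, 9_000)]
        hit = rng.choice(outer, size=900, replace=False)
        for i in hit:
            dup[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[dup[i]]
        dist = revcomp("".join(dup))
        blocks = find_inverted_duplications(flank, dist, min_len=2_000,
                                            min_identity_pct=85.0,
                                            core_identity_pct=95.0)
        assert blocks
        top = blocks[0]
        core_len = top.core_end - top.core_start
        assert abs(core_len - 3_000) <= 500  # within one window
        assert top.core_identity_pct >= 95.0

    def test_synthetic_assembly_duplication_recovered(self, assembly_world):
        truth = assembly_world["dup"]
        s, e = truth.inversion_interval
        prox_flank = truth.reference[s - 10_000:s]
        dist_flank = truth.reference[e:e + 10_000]
        blocks = find_inverted_duplications(prox_flank, dist_flank,
                                            min_len=1_000)
        assert blocks
        assert abs(blocks[0].length - truth.dup_len) < 200
        assert 85.0 <= blocks[0].identity_pct <= 95.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            find_inverted_duplications("", "ACGT")


class TestSplitReadSupport:
    def test_planted_reads_all_counted(self, assembly_world):
        em = assembly_world["dup_alignments"]
        call = call_inversion(em.contig_blocks["S01"], min_block_len=5_000,
                              sample="S01")
        reads = {k: v for k, v in em.split_reads.items()
                 if k.startswith("S01")}
        support = split_read_support(reads, call)
        assert support == {"proximal": 3, "distal": 3}

    def test_contained_forward_read_and_distant_junction_ignored(self):
        call = BreakpointCall("s", "chr", 10_001, 50_000)
        contained = {"r1": [AlignmentBlock("r1", 0, 5_000, "+", "chr",
                                           20_000, 25_000)]}
        assert split_read_support(contained, call) == \
            {"proximal": 0, "distal": 0}
        far = {"r2": [AlignmentBlock("r2", 0, 3_000, "+", "chr", 5_800, 8_800),
                      AlignmentBlock("r2", 3_000, 6_000, "-", "chr",
                                     47_000, 50_000)]}
        # junction at 8,800: 1,200 bp from the proximal breakpoint
        assert split_read_support(far, call, tol_bp=600) == \
            {"proximal": 0, "distal": 0}
        assert split_read_support(far, call, tol_bp=1_200) == \
            {"proximal": 1, "distal": 0}


class TestAncestralOrientation:
    def test_synthetic_truth_reference_orientation_is_ancestral(
            self, assembly_world):
        vs_n, vs_s = emit_outgroup_alignments(assembly_world["clean"])
        interval = assembly_world["clean"].inversion_interval
        assert call_ancestral_orientation(vs_n, vs_s, interval) == \
            "N_ancestral"

    def test_flip_against_both_is_ambiguous(self, assembly_world):
        _, vs_s = emit_outgroup_alignments(assembly_world["clean"])
        interval = assembly_world["clean"].inversion_interval
        assert call_ancestral_orientation(vs_s, vs_s, interval) == "ambiguous"

    def test_low_coverage_warns_and_returns_ambiguous(self):
        thin = [AlignmentBlock("o", 0, 1_000, "+", "t", 0, 1_000)]
        with pytest.warns(UserWarning, match="covers too little"):
            label = call_ancestral_orientation(thin, thin, (0, 100_000))
        assert label == "ambiguous"
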