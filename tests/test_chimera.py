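"""Chimera detection and the midpoint / corrected-boundary split rules."""

import numpy as np
import pytest

from orthotx import chimera, simulate
from orthotx.alignment import AlignmentHit, seed_extend_align
from orthotx.chimera import (ChimeraCall, SubjectEvidence, compute_split,
                             detect_chimera, resolve_assembly,
                             split_transcript, top_two_subjects)
from orthotx.io import gene_of


def _hit(q, s, qs, qe, ss, se, ev=1e-50, bits=500.0):
    alen = qe - qs + 1
    return AlignmentHit(query_id=q, subject_id=s, pct_identity=99.0,
                        align_len=alen, mismatch=0, gapopen=0,
                        q_start=qs, q_end=qe, s_start=ss, s_end=se,
                        evalue=ev, bitscore=bits)


def _ev(sid, qs, qe, smin, smax, ev=1e-50, bits=500.0, minus=False):
    return SubjectEvidence(subject_id=sid, q_start=qs, q_end=qe,
                           s_min=smin, s_max=smax, minus_strand=minus,
                           best_evalue=ev, best_bitscore=bits,
                           total_align_len=qe - qs + 1)


class TestTopTwo:
    def test_single_subject(self):
        top = top_two_subjects([_hit("q", "s1", 1, 300, 1, 300)])
        assert [t.subject_id for t in top] == ["s1"]

    def test_ranking_by_evalue(self):
        top = top_two_subjects([
            _hit("q", "s1", 1, 300, 1, 300, ev=1e-20, bits=100),
            _hit("q", "s2", 400, 700, 1, 301, ev=1e-50, bits=300),
        ])
        assert [t.subject_id for t in top] == ["s2", "s1"]

    def test_three_subjects_best_two_kept(self):
        top = top_two_subjects([
            _hit("q", "s1", 1, 300, 1, 300, ev=1e-50),
            _hit("q", "s2", 1, 300, 1, 300, ev=1e-40),
            _hit("q", "s3", 1, 300, 1, 300, ev=1e-30),
        ])
        assert [t.subject_id for t in top] == ["s1", "s2"]

    def test_multiple_hits_merged_to_spanning_interval(self):
        top = top_two_subjects([
            _hit("q", "s1", 1, 200, 1, 200),
            _hit("q", "s1", 301, 500, 301, 500, ev=1e-40),
        ])
        assert (top[0].q_start, top[0].q_end) == (1, 500)

    def test_empty_hits(self):
        assert top_two_subjects([]) == []


class TestDetect:
    def test_overlapping_different_regions_called(self):
        call = detect_chimera("t", 900, [
            _ev("s1", 1, 480, 1, 480), _ev("s2", 451, 900, 1, 450, ev=1e-40)])
        assert call is not None and call.overlap_len == 30

    def test_nested_intervals_not_called(self):
        call = detect_chimera("t", 900, [
            _ev("s1", 1, 500, 1, 500), _ev("s2", 40, 480, 1, 441, ev=1e-40)])
        assert call is None

    def test_disjoint_intervals_record_gap(self):
        call = detect_chimera("t", 900, [
            _ev("s1", 1, 400, 1, 400), _ev("s2", 501, 900, 1, 400, ev=1e-40)])
        assert call is not None and call.overlap_len == -100

    def test_same_gene_isoforms_never_called(self):
        call = detect_chimera("t", 900, [
            _ev("G1.1", 1, 400, 1, 400),
            _ev("G1.2", 501, 900, 1, 400, ev=1e-40)],
            gene_of=gene_of)
        assert call is None

    def test_short_interval_ignored(self):
        call = detect_chimera("t", 900, [
            _ev("s1", 1, 820, 1, 820), _ev("s2", 841, 900, 1, 60, ev=1e-40)])
        assert call is None


class TestSplit:
    def test_midpoint_small_overlap(self):
        call = detect_chimera("t", 900, [
            _ev("s1", 1, 480, 1, 480), _ev("s2", 451, 900, 1, 450, ev=1e-40)])
        compute_split(call, {"s1": 480, "s2": 450})
        assert call.split_kind == "midpoint"
        assert call.split_positions == (465,)

    def test_midpoint_gap_case(self):
        call = detect_chimera("t", 900, [
            _ev("s1", 1, 400, 1, 400), _ev("s2", 501, 900, 1, 400, ev=1e-40)])
        compute_split(call, {"s1": 400, "s2": 400})
        assert call.split_kind == "midpoint"
        assert call.split_positions == (450,)

    def test_corrected_boundary_uses_subject_tails(self):
        call = detect_chimera("t", 1000, [
            _ev("s1", 1, 400, 1, 380), _ev("s2", 240, 1000, 21, 780,
                                           ev=1e-40)])
        assert call.overlap_len == 161
        compute_split(call, {"s1": 400, "s2": 800})
        assert call.split_kind == "corrected_boundary"
        assert call.split_positions == (420, 220)

    def test_midpoint_split_conserves_sequence(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=900))
        call = ChimeraCall("t", 900, _ev("s1", 1, 480, 1, 480),
                           _ev("s2", 451, 900, 1, 450), overlap_len=30,
                           split_kind="midpoint", split_positions=(465,))
        frags = split_transcript(seq, call)
        assert len(frags[0][1]) == 465 and len(frags[1][1]) == 435
        assert frags[0][1] + frags[1][1] == seq
        assert frags[0][0].endswith("_split1")

    def test_corrected_fragments_cover_transcript(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        call = ChimeraCall("t", 1000, _ev("s1", 1, 400, 1, 380),
                           _ev("s2", 240, 1000, 21, 780), overlap_len=161,
                           split_kind="corrected_boundary",
                           split_positions=(420, 220))
        frags = split_transcript(seq, call)
        assert len(frags[0][1]) == 420 and len(frags[1][1]) == 781
        assert frags[0][1] == seq[:420] and frags[1][1] == seq[219:]

    def test_degenerate_split_left_unsplit(self):
        seq = "ACGT" * 100
        call = ChimeraCall("t", 400, _ev("s1", 1, 200, 1, 200),
                           _ev("s2", 150, 400, 1, 251), overlap_len=51,
                           split_kind="corrected_boundary",
                           split_positions=(400, 1))
        assert split_transcript(seq, call) is None

    def test_midpoint_clamped_inside_transcript(self):
        call = ChimeraCall("t", 300, _ev("s1", 1, 150, 1, 150),
                           _ev("s2", 149, 300, 1, 152), overlap_len=2)
        compute_split(call, {"s1": 150, "s2": 152})
        (m,) = call.split_positions
        assert 1 <= m < 300


class TestResolveAssembly:
    def _run(self, small_reference, species_pair):
        A, _B, truth = species_pair
        ref = small_reference.representative_sequences()
        hits = seed_extend_align(A.sequences, ref, both_strands=False)
        resolved, calls = resolve_assembly(
            A.sequences, hits, {k: len(v) for k, v in ref.items()},
            gene_of=gene_of)
        return A, truth, resolved, calls

    def test_counts_add_up(self, small_reference, species_pair):
        A, _truth, resolved, calls = self._run(small_reference, species_pair)
        assert len(resolved) == len(A.sequences) + len(calls)

    def test_planted_fusions_recovered(self, small_reference, species_pair):
        A, truth, _resolved, calls = self._run(small_reference, species_pair)
        truth_ids = {c.transcript_id for c in truth.chimera_truth["A"]}
        called_ids = {c.transcript_id for c in calls}
        assert len(called_ids & truth_ids) / len(truth_ids) >= 0.9
        assert len(called_ids - truth_ids) == 0

    def test_midpoint_positions_near_planted_junctions(
            self, small_reference, species_pair):
        A, truth, _resolved, calls = self._run(small_reference, species_pair)
        junction = {c.transcript_id: c.junction
                    for c in truth.chimera_truth["A"]}
        checked = 0
        for c in calls:
            if c.split_kind == "midpoint" and c.transcript_id in junction:
                assert abs(c.split_positions[0]
                           - junction[c.transcript_id]) <= 10
                checked += 1
        assert checked >= 1

    def test_idempotent_on_resolved_set(self, small_reference, species_pair):
        _A, _truth, resolved, _calls = self._run(small_reference,
                                                 species_pair)
        ref = small_reference.representative_sequences()
        hits2 = seed_extend_align(resolved, ref, both_strands=False)
        again, calls2 = resolve_assembly(
            resolved, hits2, {k: len(v) for k, v in ref.items()},
            gene_of=gene_of)
        assert calls2 == []
        assert again == resolved

    def test_no_chimeras_passthrough(self, small_reference):
        A, _B, _t = simulate.generate_species_pair(
            small_reference, divergence=0.02, n_chimeras=0, seed=55)
        ref = small_reference.representative_sequences()
        hits = seed_extend_align(A.sequences, ref, both_strands=False)
        resolved, calls = resolve_assembly(
            A.sequences, hits, {k: len(v) for k, v in ref.items()},
            gene_of=gene_of)
        assert calls == [] and resolved == A.sequences
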