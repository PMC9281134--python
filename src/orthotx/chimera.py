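"""Detection and splitting of chimeric transcripts.

De novo assemblies of short reads occasionally fuse two genes' transcripts
into one contig.  Such chimeras betray themselves when the transcript's two
best reference-cDNA hits occupy different regions of the transcript.  The
resolution rule:

* if the two merged hit intervals overlap by fewer than 150 nt (including
  disjoint intervals separated by a gap), the transcript is split at the
  midpoint of the overlap (or gap);
* otherwise the split boundaries are corrected using the unaligned tails of
  the two reference cDNAs: part 1 ends at ``q_end_1 + downstream tail of
  subject 1`` and part 2 starts at ``q_start_2 - upstream tail of subject
  2`` (clamped to the transcript); the two fragments may overlap.

Transcripts whose two best subjects are isoforms of the same reference gene
are never called chimeric (isoform structure, not misassembly), and nested
or near-coincident hit intervals are treated as paralog signal rather than
fusion evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

from .alignment import AlignmentHit, downstream_tail, upstream_tail

__all__ = [
    "SubjectEvidence",
    "ChimeraCall",
    "top_two_subjects",
    "detect_chimera",
    "compute_split",
    "split_transcript",
    "resolve_assembly",
    "DEFAULT_OVERLAP_THRESHOLD",
]

log = logging.getLogger(__name__)

DEFAULT_OVERLAP_THRESHOLD = 150   # nt, the midpoint-vs-corrected cutoff
DEFAULT_MIN_INTERVAL = 100        # nt, minimal merged interval per subject
DEFAULT_OVERLAP_FRACTION = 0.5    # "different regions" criterion


@dataclass(frozen=True)
class SubjectEvidence:
    """One subject's merged evidence on a query transcript."""

    subject_id: str
    q_start: int            # merged (spanning) query interval, 1-based
    q_end: int
    s_min: int              # spanning subject coordinates over all hits
    s_max: int
    minus_strand: bool
    best_evalue: float
    best_bitscore: float
    total_align_len: int

    @property
    def q_len(self) -> int:
        return self.q_end - self.q_start + 1


@dataclass
class ChimeraCall:
    transcript_id: str
    transcript_len: int
    subject_1: SubjectEvidence       # interval starting first on the query
    subject_2: SubjectEvidence
    overlap_len: int                 # negative = gap between the intervals
    split_kind: str | None = None    # "midpoint" | "corrected_boundary"
    split_positions: tuple[int, ...] | None = None


def top_two_subjects(hits: Sequence[AlignmentHit]) -> list[SubjectEvidence]:
    """Best two subjects for one query, with merged query intervals.

    Subjects are ranked by their best hit (e-value ascending, bitscore
    descending, subject id as final tie-break); each subject's hits are
    merged into one spanning query interval.
    """
    if not hits:
        return []
    qids = {h.query_id for h in hits}
    if len(qids) != 1:
        raise ValueError(f"hits must share one query, got {sorted(qids)}")
    by_subject: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_subject.setdefault(h.subject_id, []).append(h)
    merged: list[SubjectEvidence] = []
    for sid, shits in by_subject.items():
        best = min(shits, key=lambda h: (h.evalue, -h.bitscore))
        s_coords = [c for h in shits for c in (h.s_start, h.s_end)]
        merged.append(
            SubjectEvidence(
                subject_id=sid,
                q_start=min(h.q_start for h in shits),
                q_end=max(h.q_end for h in shits),
                s_min=min(s_coords),
                s_max=max(s_coords),
                minus_strand=best.minus_strand,
                best_evalue=best.evalue,
                best_bitscore=best.bitscore,
                total_align_len=sum(h.align_len for h in shits),
            )
        )
    merged.sort(key=lambda s: (s.best_evalue, -s.best_bitscore, s.subject_id))
    return merged[:2]


def detect_chimera(
    transcript_id: str,
    transcript_len: int,
    top_two: Sequence[SubjectEvidence],
    min_interval: int = DEFAULT_MIN_INTERVAL,
    max_overlap_fraction: float = DEFAULT_OVERLAP_FRACTION,
    gene_of: Callable[[str], str] | None = None,
) -> ChimeraCall | None:
    """Call a chimera iff the two best subjects occupy different regions.

    "Different regions" means: both merged intervals are at least
    ``min_interval`` nt long and their overlap is less than
    ``max_overlap_fraction`` of the shorter interval (disjoint intervals
    record a negative overlap).  Subjects that are isoforms of one
    reference gene (per ``gene_of``) never yield a call.
    """
    if len(top_two) < 2:
        return None
    a, b = top_two[0], top_two[1]
    if gene_of is not None and gene_of(a.subject_id) == gene_of(b.subject_id):
        return None
    first, second = (a, b) if (a.q_start, a.q_end) <= (b.q_start, b.q_end) \
        else (b, a)
    if first.q_len < min_interval or second.q_len < min_interval:
        return None
    overlap = first.q_end - second.q_start + 1
    shorter = min(first.q_len, second.q_len)
    if overlap >= max_overlap_fraction * shorter:
        return None
    return ChimeraCall(
        transcript_id=transcript_id,
        transcript_len=transcript_len,
        subject_1=first,
        subject_2=second,
        overlap_len=overlap,
    )


def _subject_downstream_tail(ev: SubjectEvidence, subject_len: int) -> int:
    hit = AlignmentHit(
        query_id="_", subject_id=ev.subject_id, pct_identity=100.0,
        align_len=1, mismatch=0, gapopen=0, q_start=ev.q_start,
        q_end=ev.q_end,
        s_start=ev.s_max if ev.minus_strand else ev.s_min,
        s_end=ev.s_min if ev.minus_strand else ev.s_max,
        evalue=ev.best_evalue, bitscore=ev.best_bitscore,
    )
    return downstream_tail(hit, subject_len)


def _subject_upstream_tail(ev: SubjectEvidence, subject_len: int) -> int:
    hit = AlignmentHit(
        query_id="_", subject_id=ev.subject_id, pct_identity=100.0,
        align_len=1, mismatch=0, gapopen=0, q_start=ev.q_start,
        q_end=ev.q_end,
        s_start=ev.s_max if ev.minus_strand else ev.s_min,
        s_end=ev.s_min if ev.minus_strand else ev.s_max,
        evalue=ev.best_evalue, bitscore=ev.best_bitscore,
    )
    return upstream_tail(hit, subject_len)


def compute_split(
    call: ChimeraCall,
    subject_lengths: Mapping[str, int],
    overlap_threshold: int = DEFAULT_OVERLAP_THRESHOLD,
) -> ChimeraCall:
    """Fill in split kind and position(s) for a detected chimera.

    Overlaps (or gaps) shorter than ``overlap_threshold`` are split at the
    floor midpoint of the overlap/gap region; larger overlaps use the
    corrected boundaries derived from the unaligned reference-cDNA tails.
    """
    L = call.transcript_len
    if call.overlap_len < overlap_threshold:
        # overlap region is [q_start_2, q_end_1]; for gaps the roles swap
        # and the same floor-midpoint expression covers both cases
        mid = (call.subject_2.q_start + call.subject_1.q_end) // 2
        mid = max(1, min(L - 1, mid))
        call.split_kind = "midpoint"
        call.split_positions = (mid,)
        return call
    s1_len = subject_lengths[call.subject_1.subject_id]
    s2_len = subject_lengths[call.subject_2.subject_id]
    end_1 = min(L, call.subject_1.q_end
                + _subject_downstream_tail(call.subject_1, s1_len))
    start_2 = max(1, call.subject_2.q_start
                  - _subject_upstream_tail(call.subject_2, s2_len))
    call.split_kind = "corrected_boundary"
    call.split_positions = (end_1, start_2)
    return call


def split_transcript(
    sequence: str, call: ChimeraCall
) -> list[tuple[str, str]] | None:
    """Split a transcript per its completed call; None if degenerate.

    Midpoint splits partition the sequence exactly; corrected-boundary
    fragments may overlap but always jointly cover it.
    """
    if call.split_kind is None or call.split_positions is None:
        raise ValueError("call has no computed split; run compute_split first")
    L = len(sequence)
    if call.split_kind == "midpoint":
        (m,) = call.split_positions
        frag1 = sequence[:m]
        frag2 = sequence[m:]
    else:
        end_1, start_2 = call.split_positions
        frag1 = sequence[:end_1]
        frag2 = sequence[start_2 - 1:]
    if len(frag1) < 1 or len(frag2) < 1 or len(frag1) >= L or len(frag2) >= L:
        log.warning("degenerate split for %s (%s at %s); left unsplit",
                    call.transcript_id, call.split_kind, call.split_positions)
        return None
    return [
        (f"{call.transcript_id}_split1", frag1),
        (f"{call.transcript_id}_split2", frag2),
    ]


def resolve_assembly(
    transcripts: Mapping[str, str],
    hits: Iterable[AlignmentHit],
    subject_lengths: Mapping[str, int],
    gene_of: Callable[[str], str] | None = None,
    min_interval: int = DEFAULT_MIN_INTERVAL,
    max_overlap_fraction: float = DEFAULT_OVERLAP_FRACTION,
    overlap_threshold: int = DEFAULT_OVERLAP_THRESHOLD,
) -> tuple[dict[str, str], list[ChimeraCall]]:
    """Replace every detected chimera by its two fragments.

    Returns the new transcript set (file order preserved; split fragments
    take their parent's position) and the list of completed calls.
    """
    by_query: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    out: dict[str, str] = {}
    calls: list[ChimeraCall] = []
    for tid, seq in transcripts.items():
        call = None
        qhits = by_query.get(tid)
        if qhits:
            top2 = top_two_subjects(qhits)
            call = detect_chimera(tid, len(seq), top2, min_interval,
                                  max_overlap_fraction, gene_of)
        if call is None:
            out[tid] = seq
            continue
        compute_split(call, subject_lengths, overlap_threshold)
        frags = split_transcript(seq, call)
        if frags is None:
            out[tid] = seq
            continue
        calls.append(call)
        for fid, fseq in frags:
            out[fid] = fseq
    log.info("chimera resolution: %d transcripts in, %d calls, %d out",
             len(transcripts), len(calls), len(out))
    return out, calls


def calls_to_rows(calls: Iterable[ChimeraCall]) -> list[dict]:
    """Flatten calls for the TSV chimera report."""
    rows = []
    for c in calls:
        rows.append(
            {
                "transcript_id": c.transcript_id,
                "transcript_len": c.transcript_len,
                "subject_1": c.subject_1.subject_id,
                "q_start_1": c.subject_1.q_start,
                "q_end_1": c.subject_1.q_end,
                "subject_2": c.subject_2.subject_id,
                "q_start_2": c.subject_2.q_start,
                "q_end_2": c.subject_2.q_end,
                "overlap_len": c.overlap_len,
                "split_kind": c.split_kind,
                "split_positions": ";".join(map(str, c.split_positions)),
            }
        )
    return rows
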