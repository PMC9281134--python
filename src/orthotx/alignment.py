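"""Tabular local-alignment records and a desk-scale seed-and-extend aligner.

The pipeline's comparisons (transcript vs reference cDNA, species A vs
species B) are plain nucleotide local alignments.  On real data users supply
externally computed 12-column tabular hit files (the common "outfmt 6"
dialect); on synthetic data the built-in aligner below produces the same
records, so the whole pipeline runs without an external search tool.

Conventions
-----------
Coordinates are 1-based inclusive.  ``q_start <= q_end`` always; a subject
interval with ``s_start > s_end`` encodes a minus-strand hit.  The aligner is
ungapped (exact k-mer seeding, substitution-aware extension), which matches
the substitution-only synthetic data; it is not a general-purpose search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AlignmentHit",
    "read_hit_table",
    "write_hit_table",
    "seed_extend_align",
    "downstream_tail",
    "upstream_tail",
]

# Karlin-Altschul-style constants for the +1/-2 match/mismatch scoring used
# by the extension; only relative ranking of hits matters downstream.
_LAMBDA = 1.33
_K = 0.621
_MATCH = 1
_MISMATCH = -2


@dataclass(frozen=True)
class AlignmentHit:
    """One ungapped/gapped local alignment record (12-column tabular row)."""

    query_id: str
    subject_id: str
    pct_identity: float
    align_len: int
    mismatch: int
    gapopen: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    @property
    def minus_strand(self) -> bool:
        return self.s_start > self.s_end

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise ValueError(
                f"q_start {self.q_start} > q_end {self.q_end} for {self.query_id}"
            )
        if self.align_len < 1:
            raise ValueError(f"align_len must be >= 1, got {self.align_len}")
        if self.evalue < 0:
            raise ValueError(f"evalue must be >= 0, got {self.evalue}")


class HitValidationError(ValueError):
    """A malformed or out-of-range row in a hit table, with its line number."""


def downstream_tail(hit: AlignmentHit, subject_len: int) -> int:
    """Unaligned subject length past the hit in the direction of increasing
    query coordinate (strand-aware)."""
    if hit.minus_strand:
        return hit.s_end - 1
    return subject_len - hit.s_end


def upstream_tail(hit: AlignmentHit, subject_len: int) -> int:
    """Unaligned subject length before the hit in the direction of
    decreasing query coordinate (strand-aware)."""
    if hit.minus_strand:
        return subject_len - hit.s_start
    return hit.s_start - 1


def read_hit_table(
    path,
    query_lengths: Mapping[str, int] | None = None,
    subject_lengths: Mapping[str, int] | None = None,
) -> list[AlignmentHit]:
    """Read a 12-column tab-separated hit file, validating coordinates.

    ``query_lengths``/``subject_lengths`` are optional id -> length maps;
    when given, any hit whose coordinates fall outside the sequence raises
    :class:`HitValidationError` naming the offending line.
    """
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise HitValidationError(
                    f"{path}:{lineno}: expected 12 columns, got {len(fields)}"
                )
            try:
                hit = AlignmentHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pct_identity=float(fields[2]),
                    align_len=int(fields[3]),
                    mismatch=int(fields[4]),
                    gapopen=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            except ValueError as exc:
                raise HitValidationError(f"{path}:{lineno}: {exc}") from exc
            if query_lengths is not None:
                qlen = query_lengths.get(hit.query_id)
                if qlen is None:
                    raise HitValidationError(
                        f"{path}:{lineno}: unknown query {hit.query_id!r}"
                    )
                if hit.q_start < 1 or hit.q_end > qlen:
                    raise HitValidationError(
                        f"{path}:{lineno}: query interval "
                        f"[{hit.q_start},{hit.q_end}] outside 1..{qlen}"
                    )
            if subject_lengths is not None:
                slen = subject_lengths.get(hit.subject_id)
                if slen is None:
                    raise HitValidationError(
                        f"{path}:{lineno}: unknown subject {hit.subject_id!r}"
                    )
                lo, hi = sorted((hit.s_start, hit.s_end))
                if lo < 1 or hi > slen:
                    raise HitValidationError(
                        f"{path}:{lineno}: subject interval "
                        f"[{hit.s_start},{hit.s_end}] outside 1..{slen}"
                    )
            hits.append(hit)
    return hits


def write_hit_table(hits: Iterable[AlignmentHit], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.pct_identity:.3f}",
                        str(h.align_len),
                        str(h.mismatch),
                        str(h.gapopen),
                        str(h.q_start),
                        str(h.q_end),
                        str(h.s_start),
                        str(h.s_end),
                        f"{h.evalue:.3e}",
                        f"{h.bitscore:.1f}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# built-in aligner
# ---------------------------------------------------------------------------

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lowercase

_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.uint8)


def _encode(seq: str) -> np.ndarray:
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        # non-ACGT symbols (N etc.) get a code that never matches
        arr = np.where(arr == 255, np.uint8(4), arr)
    return arr


def _kmer_codes(arr: np.ndarray, w: int) -> np.ndarray:
    """Integer codes of all w-mers; w-mers containing non-ACGT get code -1."""
    n = arr.shape[0] - w + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    a64 = arr.astype(np.int64)
    for j in range(w):
        codes = codes * 4 + a64[j : j + n]
        bad |= arr[j : j + n] > 3
    codes[bad] = -1
    return codes


def _bitscore(raw: int) -> float:
    return (_LAMBDA * raw - math.log(_K)) / math.log(2.0)


def _extend(
    qa: np.ndarray, sa: np.ndarray, diag: int, seed_q: int, w: int
) -> tuple[int, int, int, int] | None:
    """Best ungapped local alignment on one diagonal containing the seed.

    Returns (q_lo, q_hi, matches, score) with 0-based half-open query
    coordinates, or None if the best score is not positive.
    """
    qlo = max(0, diag)
    qhi = min(qa.shape[0], diag + sa.shape[0])
    if qhi - qlo < w:
        return None
    eq = qa[qlo:qhi] == sa[qlo - diag : qhi - diag]
    steps = np.where(eq, _MATCH, _MISMATCH).astype(np.int64)
    prefix = np.concatenate(([0], np.cumsum(steps)))
    i = seed_q - qlo  # local index of seed start
    # interval [l, r) must contain the seed word [i, i+w)
    left = int(np.argmin(prefix[: i + 1]))
    right_slice = prefix[i + w :]
    right = i + w + int(np.argmax(right_slice))
    score = int(prefix[right] - prefix[left])
    if score <= 0:
        return None
    matches = int(np.count_nonzero(eq[left:right]))
    return qlo + left, qlo + right, matches, score


def seed_extend_align(
    queries: Mapping[str, str],
    subjects: Mapping[str, str],
    word_size: int = 11,
    min_align_len: int = 50,
    max_evalue: float = 1e-6,
    both_strands: bool = True,
) -> list[AlignmentHit]:
    """Ungapped seed-and-extend local alignment of every query vs every subject.

    Exact ``word_size``-mers seed diagonals; each (subject, diagonal) pair is
    extended once to the optimal ungapped local alignment containing the
    seed (+1 match / -2 mismatch).  E-values follow a Karlin-Altschul-style
    model E = m*n*2^(-bitscore) with m, n the summed query/subject lengths.
    """
    if word_size < 8:
        raise ValueError(f"word_size must be >= 8, got {word_size}")
    if not queries or not subjects:
        return []

    subj_ids = sorted(subjects)
    m_total = sum(len(s) for s in queries.values())
    n_total = sum(len(s) for s in subjects.values())

    # index: concatenated per-subject (and per-strand) k-mer codes
    code_chunks: list[np.ndarray] = []
    pos_chunks: list[np.ndarray] = []
    ref_chunks: list[np.ndarray] = []  # index into entries
    entries: list[tuple[str, np.ndarray, bool]] = []  # (id, encoded, is_rc)
    for sid in subj_ids:
        arr = _encode(subjects[sid])
        strands = [(arr, False)]
        if both_strands:
            strands.append((_COMPLEMENT[np.minimum(arr, 3)][::-1].copy(), True))
        for sarr, is_rc in strands:
            codes = _kmer_codes(sarr, word_size)
            if codes.size == 0:
                continue
            keep = codes >= 0
            idx = len(entries)
            entries.append((sid, sarr, is_rc))
            code_chunks.append(codes[keep])
            pos_chunks.append(np.nonzero(keep)[0].astype(np.int64))
            ref_chunks.append(np.full(int(keep.sum()), idx, dtype=np.int64))
    if not entries:
        return []
    all_codes = np.concatenate(code_chunks)
    all_pos = np.concatenate(pos_chunks)
    all_ref = np.concatenate(ref_chunks)
    order = np.argsort(all_codes, kind="stable")
    all_codes = all_codes[order]
    all_pos = all_pos[order]
    all_ref = all_ref[order]

    hits: list[AlignmentHit] = []
    for qid in sorted(queries):
        qa = _encode(queries[qid])
        qcodes = _kmer_codes(qa, word_size)
        if qcodes.size == 0:
            continue
        valid = np.nonzero(qcodes >= 0)[0]
        if valid.size == 0:
            continue
        lo = np.searchsorted(all_codes, qcodes[valid], side="left")
        hi = np.searchsorted(all_codes, qcodes[valid], side="right")
        counts = hi - lo
        nz = counts > 0
        if not nz.any():
            continue
        qpos_rep = np.repeat(valid[nz], counts[nz])
        tot = counts[nz]
        flat = (np.repeat(lo[nz], tot)
                + np.arange(int(tot.sum()))
                - np.repeat(np.cumsum(tot) - tot, tot))
        spos = all_pos[flat]
        sref = all_ref[flat]
        diag = qpos_rep - spos
        # one extension per (subject entry, diagonal); keep smallest seed
        # qpos; diagonals supported by a single seed word are skipped
        # (two-hit heuristic) unless the query is too short to carry two
        key = sref * (2 * len(qa) + 1) + (diag + len(qa))
        sort_idx = np.lexsort((qpos_rep, key))
        key_sorted = key[sort_idx]
        first = np.ones(key_sorted.shape[0], dtype=bool)
        first[1:] = key_sorted[1:] != key_sorted[:-1]
        n_seeds = np.diff(np.append(np.nonzero(first)[0],
                                    key_sorted.shape[0]))
        need = 2 if len(qa) > word_size else 1
        enough = n_seeds >= need
        for j in sort_idx[first][enough]:
            sid, sarr, is_rc = entries[int(sref[j])]
            res = _extend(qa, sarr, int(diag[j]), int(qpos_rep[j]), word_size)
            if res is None:
                continue
            q_lo, q_hi, matches, score = res
            alen = q_hi - q_lo
            if alen < min_align_len:
                continue
            bits = _bitscore(score)
            evalue = m_total * n_total * math.pow(2.0, -bits)
            if evalue > max_evalue:
                continue
            s_lo = q_lo - int(diag[j])  # 0-based on the indexed strand
            s_hi = q_hi - int(diag[j])
            slen = sarr.shape[0]
            if is_rc:
                s_start = slen - s_lo  # 1-based original coords, reversed
                s_end = slen - s_hi + 1
            else:
                s_start = s_lo + 1
                s_end = s_hi
            hits.append(
                AlignmentHit(
                    query_id=qid,
                    subject_id=sid,
                    pct_identity=round(100.0 * matches / alen, 3),
                    align_len=alen,
                    mismatch=alen - matches,
                    gapopen=0,
                    q_start=q_lo + 1,
                    q_end=q_hi,
                    s_start=s_start,
                    s_end=s_end,
                    evalue=evalue,
                    bitscore=round(_bitscore(score), 1),
                )
            )
    hits.sort(key=lambda h: (h.query_id, h.evalue, -h.bitscore, h.subject_id))
    return hits
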