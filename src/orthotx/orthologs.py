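"""Reciprocal-best-hit construction of the 1:1 ortholog-transcriptome.

Transcripts of species A and B are aligned against each other in both
directions.  A pair (a, b) is a reciprocal best hit when b is among a's
co-best subjects (all subjects tying a's best e-value, bitscore and
alignment length) and vice versa.  Pairs must align over more than 250 nt
and the shorter transcript must be at least 50% of the longer one.  A
separate search against the reference cDNA set assigns each transcript a
reference gene, used both to prune redundant isoforms (one transcript per
reference gene per species, keeping the pair with the longest cross-species
alignment) and to name the retained pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

from .alignment import AlignmentHit
from .io import gene_of as default_gene_of

__all__ = [
    "OrthologPair",
    "best_hit_sets",
    "reciprocal_best_pairs",
    "filter_pairs",
    "assign_reference_gene",
    "prune_isoforms",
    "build_ortholog_transcriptome",
    "MIN_PAIR_ALIGN",
    "MIN_LENGTH_RATIO",
]

log = logging.getLogger(__name__)

MIN_PAIR_ALIGN = 250      # nt; pairs need align_len strictly greater
MIN_LENGTH_RATIO = 0.5    # shorter/longer transcript length


@dataclass
class OrthologPair:
    id_A: str
    id_B: str
    align_len_AB: int
    bitscore_AB: float
    len_A: int
    len_B: int
    ref_gene_A: str | None = None
    ref_gene_B: str | None = None
    final_name: str | None = None

    @property
    def length_ratio(self) -> float:
        lo, hi = sorted((self.len_A, self.len_B))
        return lo / hi


def _best_hit(hits: Sequence[AlignmentHit]) -> AlignmentHit:
    return min(hits, key=lambda h: (h.evalue, -h.bitscore, -h.align_len))


def best_hit_sets(
    hits: Iterable[AlignmentHit],
) -> dict[str, dict[str, AlignmentHit]]:
    """query -> {subject: its best hit} for all co-best subjects.

    A subject is co-best when its best hit ties the query's top
    (e-value, bitscore, alignment length) triple exactly.
    """
    per_query: dict[str, dict[str, list[AlignmentHit]]] = {}
    for h in hits:
        per_query.setdefault(h.query_id, {}).setdefault(
            h.subject_id, []).append(h)
    out: dict[str, dict[str, AlignmentHit]] = {}
    for qid, by_subj in per_query.items():
        best_per_subject = {s: _best_hit(hs) for s, hs in by_subj.items()}
        top = min(
            (h.evalue, -h.bitscore, -h.align_len)
            for h in best_per_subject.values()
        )
        out[qid] = {
            s: h for s, h in best_per_subject.items()
            if (h.evalue, -h.bitscore, -h.align_len) == top
        }
    return out


def reciprocal_best_pairs(
    best_A2B: Mapping[str, Mapping[str, AlignmentHit]],
    best_B2A: Mapping[str, Mapping[str, AlignmentHit]],
    lengths_A: Mapping[str, int],
    lengths_B: Mapping[str, int],
) -> list[OrthologPair]:
    """All (a, b) with b co-best for a and a co-best for b.

    Reciprocal ties produce several candidate pairs per transcript; the
    isoform-pruning step enforces 1:1 later.
    """
    pairs: list[OrthologPair] = []
    for a in sorted(best_A2B):
        for b in sorted(best_A2B[a]):
            if a in best_B2A.get(b, {}):
                hit = best_A2B[a][b]
                pairs.append(
                    OrthologPair(
                        id_A=a, id_B=b,
                        align_len_AB=hit.align_len,
                        bitscore_AB=hit.bitscore,
                        len_A=lengths_A[a], len_B=lengths_B[b],
                    )
                )
    return pairs


def filter_pairs(
    pairs: Iterable[OrthologPair],
    min_align: int = MIN_PAIR_ALIGN,
    min_ratio: float = MIN_LENGTH_RATIO,
) -> tuple[list[OrthologPair], list[tuple[OrthologPair, str]]]:
    """Keep pairs with align_len > min_align and length ratio >= min_ratio.

    Returns (kept, excluded-with-reason)."""
    kept: list[OrthologPair] = []
    excluded: list[tuple[OrthologPair, str]] = []
    for p in pairs:
        if p.align_len_AB <= min_align:
            excluded.append((p, f"align_len {p.align_len_AB} <= {min_align}"))
        elif p.length_ratio < min_ratio:
            excluded.append(
                (p, f"length ratio {p.length_ratio:.3f} < {min_ratio}")
            )
        else:
            kept.append(p)
    return kept, excluded


def assign_reference_gene(
    hits_vs_reference: Iterable[AlignmentHit],
    gene_of: Callable[[str], str] = default_gene_of,
) -> dict[str, str]:
    """transcript -> reference gene of its single best reference hit.

    Ties on e-value break by bitscore, then lexicographic subject id.
    Transcripts without hits are simply absent from the map.
    """
    per_query: dict[str, AlignmentHit] = {}
    for h in hits_vs_reference:
        cur = per_query.get(h.query_id)
        if cur is None or (h.evalue, -h.bitscore, h.subject_id) < (
            cur.evalue, -cur.bitscore, cur.subject_id
        ):
            per_query[h.query_id] = h
    return {q: gene_of(h.subject_id) for q, h in per_query.items()}


def prune_isoforms(
    pairs: Sequence[OrthologPair],
    ref_gene_A: Mapping[str, str],
    ref_gene_B: Mapping[str, str],
) -> tuple[list[OrthologPair], list[tuple[OrthologPair, str]]]:
    """Reduce candidate pairs to a strict 1:1 ortholog set.

    Pairs are visited by decreasing cross-species alignment length (ties:
    bitscore, then ids).  A pair is kept when neither transcript is already
    used and its reference gene slot (per species) is free; isoforms
    mapping to different reference genes coexist.  Kept pairs are named by
    their reference gene (species A's assignment wins on disagreement,
    which is logged) or numbered sequentially when neither member has a
    reference hit.
    """
    annotated = []
    for p in pairs:
        p.ref_gene_A = ref_gene_A.get(p.id_A)
        p.ref_gene_B = ref_gene_B.get(p.id_B)
        annotated.append(p)
    annotated.sort(
        key=lambda p: (-p.align_len_AB, -p.bitscore_AB, p.id_A, p.id_B)
    )
    used_A: set[str] = set()
    used_B: set[str] = set()
    used_gene_A: set[str] = set()
    used_gene_B: set[str] = set()
    kept: list[OrthologPair] = []
    excluded: list[tuple[OrthologPair, str]] = []
    for p in annotated:
        if p.id_A in used_A or p.id_B in used_B:
            excluded.append((p, "transcript already paired"))
            continue
        if p.ref_gene_A is not None and p.ref_gene_A in used_gene_A:
            excluded.append(
                (p, f"redundant isoform of {p.ref_gene_A} in species A")
            )
            continue
        if p.ref_gene_B is not None and p.ref_gene_B in used_gene_B:
            excluded.append(
                (p, f"redundant isoform of {p.ref_gene_B} in species B")
            )
            continue
        used_A.add(p.id_A)
        used_B.add(p.id_B)
        if p.ref_gene_A is not None:
            used_gene_A.add(p.ref_gene_A)
        if p.ref_gene_B is not None:
            used_gene_B.add(p.ref_gene_B)
        kept.append(p)
    # naming
    seen_names: set[str] = set()
    counter = 0
    # restore input-ish determinism: name in id order
    for p in sorted(kept, key=lambda p: (p.id_A, p.id_B)):
        if p.ref_gene_A and p.ref_gene_B and p.ref_gene_A != p.ref_gene_B:
            log.warning(
                "naming conflict for (%s, %s): %s vs %s; using species A",
                p.id_A, p.id_B, p.ref_gene_A, p.ref_gene_B,
            )
        name = p.ref_gene_A or p.ref_gene_B
        if name is None:
            counter += 1
            name = f"ORTHO{counter:06d}"
        base = name
        k = 1
        while name in seen_names:
            k += 1
            name = f"{base}_{k}"
        seen_names.add(name)
        p.final_name = name
    kept.sort(key=lambda p: (p.id_A, p.id_B))
    return kept, excluded


def build_ortholog_transcriptome(
    hits_A2B: Iterable[AlignmentHit],
    hits_B2A: Iterable[AlignmentHit],
    hits_A_ref: Iterable[AlignmentHit],
    hits_B_ref: Iterable[AlignmentHit],
    lengths_A: Mapping[str, int],
    lengths_B: Mapping[str, int],
    gene_of: Callable[[str], str] = default_gene_of,
    min_align: int = MIN_PAIR_ALIGN,
    min_ratio: float = MIN_LENGTH_RATIO,
) -> tuple[list[OrthologPair], list[tuple[OrthologPair, str]]]:
    """Full ortholog-transcriptome construction from the four hit tables."""
    ba = best_hit_sets(hits_A2B)
    bb = best_hit_sets(hits_B2A)
    candidates = reciprocal_best_pairs(ba, bb, lengths_A, lengths_B)
    filtered, excluded = filter_pairs(candidates, min_align, min_ratio)
    ga = assign_reference_gene(hits_A_ref, gene_of)
    gb = assign_reference_gene(hits_B_ref, gene_of)
    kept, pruned = prune_isoforms(filtered, ga, gb)
    log.info(
        "orthologs: %d candidates, %d after filters, %d after pruning",
        len(candidates), len(filtered), len(kept),
    )
    return kept, excluded + pruned
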