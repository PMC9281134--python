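"""Mature-miRNA collapsing, small-RNA read counting and ortholog miRNAs.

Mature miRNAs whose sequences are identical or differ by a single
nucleotide are collapsed into one counting group (transitively), so that a
read never maps ambiguously within a family of near-identical matures.  A
read counts for a group when it matches some member full-length — the
shorter of read and member contained in the longer — with at most one
substitution; reads matching several groups are discarded and logged.  A
miRNA group is an ortholog between the two species when it is present
(count >= 1) in both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "MiRNAGroup",
    "collapse_mature_mirnas",
    "match_reads_to_groups",
    "MatchResult",
    "mirna_orthologs",
]

log = logging.getLogger(__name__)

_VALID = set("ACGUT")


def _normalize(seq: str) -> str:
    s = seq.upper().replace("U", "T")
    if set(s) - set("ACGT"):
        raise ValueError(f"sequence contains non-ACGU symbols: {seq!r}")
    return s


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class MiRNAGroup:
    """One counting group of near-identical mature miRNAs."""

    group_id: str                 # member names joined with "/"
    members: tuple[str, ...]      # mature names, sorted
    sequences: tuple[str, ...]    # distinct member sequences (DNA alphabet)


def collapse_mature_mirnas(mature: Mapping[str, str]) -> list[MiRNAGroup]:
    """Connected components linking equal-length sequences at Hamming <= 1.

    Identical sequences merge trivially; the link is applied transitively,
    so a group may span more than one nucleotide end to end.
    """
    names = sorted(mature)
    seqs = {n: _normalize(mature[n]) for n in names}
    parent = {n: n for n in names}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for i, a in enumerate(names):
        for b in names[i + 1:]:
            sa, sb = seqs[a], seqs[b]
            if len(sa) == len(sb) and _hamming(sa, sb) <= 1:
                union(a, b)
    comps: dict[str, list[str]] = {}
    for n in names:
        comps.setdefault(find(n), []).append(n)
    groups = []
    for members in comps.values():
        members = sorted(members)
        uniq = tuple(sorted({seqs[m] for m in members}))
        groups.append(
            MiRNAGroup(group_id="/".join(members), members=tuple(members),
                       sequences=uniq)
        )
    groups.sort(key=lambda g: g.group_id)
    return groups


def _matches_member(read: str, member: str) -> bool:
    """Full-length containment of the shorter in the longer, <=1 mismatch."""
    short, long_ = (read, member) if len(read) <= len(member) else (member,
                                                                    read)
    n, m = len(short), len(long_)
    for off in range(m - n + 1):
        mism = 0
        for i in range(n):
            if short[i] != long_[off + i]:
                mism += 1
                if mism > 1:
                    break
        if mism <= 1:
            return True
    return False


@dataclass
class MatchResult:
    counts: pd.DataFrame          # groups x samples
    presence: pd.DataFrame        # bool, groups x samples
    ambiguous: pd.Series          # discarded multi-group reads per sample
    unmatched: pd.Series          # reads matching no group per sample


def match_reads_to_groups(
    reads_per_sample: Mapping[str, Sequence[str]],
    groups: Sequence[MiRNAGroup],
) -> MatchResult:
    """Count reads per group per sample.

    Group counts + ambiguous + unmatched always sum to the sample's total
    read count.  Identical reads are matched once and counted by
    multiplicity.
    """
    samples = list(reads_per_sample)
    gids = [g.group_id for g in groups]
    counts = pd.DataFrame(0, index=gids, columns=samples, dtype=int)
    ambiguous = pd.Series(0, index=samples, dtype=int)
    unmatched = pd.Series(0, index=samples, dtype=int)
    cache: dict[str, int | None | str] = {}
    for sample, reads in reads_per_sample.items():
        for read in reads:
            r = _normalize(read)
            if r in cache:
                verdict = cache[r]
            else:
                matching = [
                    g.group_id
                    for g in groups
                    if any(_matches_member(r, s) for s in g.sequences)
                ]
                if len(matching) == 1:
                    verdict = matching[0]
                elif len(matching) == 0:
                    verdict = None
                else:
                    verdict = "__ambiguous__"
                    log.debug("read %s matches %d groups; discarded",
                              r, len(matching))
                cache[r] = verdict
            if verdict is None:
                unmatched[sample] += 1
            elif verdict == "__ambiguous__":
                ambiguous[sample] += 1
            else:
                counts.at[verdict, sample] += 1
    return MatchResult(counts=counts, presence=counts >= 1,
                       ambiguous=ambiguous, unmatched=unmatched)


def mirna_orthologs(
    presence_A: Mapping[str, bool] | pd.Series,
    presence_B: Mapping[str, bool] | pd.Series,
) -> list[str]:
    """Groups present in both species (matching the same reference miRNA)."""
    pa = pd.Series(presence_A)
    pb = pd.Series(presence_B)
    universe = pa.index.union(pb.index)
    pa = pa.reindex(universe, fill_value=False)
    pb = pb.reindex(universe, fill_value=False)
    return sorted(universe[(pa & pb)])
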