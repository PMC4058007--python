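"""Collapse proteins that are identical over their entire region of overlap.

Two proteins are redundant when the shorter is an exact contiguous
substring of the longer. Redundant sets are single-linkage connected
components; one representative (the unique longest member, or the first
member encountered among co-longest) is kept per component.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping


@dataclass(frozen=True)
class RedundancyCluster:
    members: tuple[str, ...]  # input order
    representative: str
    rule_used: str  # "longest" | "first"

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            raise ValueError("representative must be a cluster member")


def identical_over_overlap(a: str, b: str) -> bool:
    """True iff the shorter sequence occurs as an exact contiguous
    substring of the longer (equal lengths: sequences must be equal)."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if len(a) <= len(b):
        return a in b
    return b in a


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            # keep the smaller root so component order follows input order
            if rj < ri:
                ri, rj = rj, ri
            self.parent[rj] = ri


def collapse(
    proteins: Mapping[str, str],
) -> tuple[dict[str, str], list[RedundancyCluster]]:
    """Collapse an id->sequence map to representatives.

    Returns the kept id->sequence map (input order preserved) and the
    clusters. Idempotent: collapsing the result changes nothing.
    """
    ids = list(proteins)
    if len(ids) != len(set(ids)):
        raise ValueError("protein ids must be unique")
    seqs = [proteins[i] for i in ids]
    n = len(ids)
    uf = _UnionFind(n)
    # bucket by sequence first so exact duplicates cost O(n)
    by_seq: dict[str, int] = {}
    for i, s in enumerate(seqs):
        if s in by_seq:
            uf.union(by_seq[s], i)
        else:
            by_seq[s] = i
    uniq = sorted(by_seq.items(), key=lambda kv: len(kv[0]))
    for ai in range(len(uniq)):
        sa, ia = uniq[ai]
        for bi in range(ai + 1, len(uniq)):
            sb, ib = uniq[bi]
            if sa in sb:
                uf.union(ia, ib)

    components: dict[int, list[int]] = {}
    for i in range(n):
        components.setdefault(uf.find(i), []).append(i)

    clusters: list[RedundancyCluster] = []
    kept: dict[str, str] = {}
    reps: set[str] = set()
    for root in sorted(components):
        member_idx = components[root]
        max_len = max(len(seqs[i]) for i in member_idx)
        longest = [i for i in member_idx if len(seqs[i]) == max_len]
        rep = longest[0]  # first in input order among co-longest
        rule = "longest" if len(longest) == 1 else "first"
        clusters.append(
            RedundancyCluster(
                members=tuple(ids[i] for i in member_idx),
                representative=ids[rep],
                rule_used=rule,
            )
        )
        reps.add(ids[rep])
    for tid in ids:
        if tid in reps:
            kept[tid] = proteins[tid]
    return kept, clusters
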