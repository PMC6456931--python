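"""Short k-mer hit enumeration and group-seed clustering.

A k-mer hit at (i, j) means seq_a[i:i+k] == seq_b[j:j+k].  Two hits belong
together when their inter-seed distance D = max(|i2-i1|, |j2-j1|) is at
most rho and their diagonal shift |d2 - d1| (d = j - i) is at most delta;
group seeds are the connected components of that relation (single-linkage
transitive closure), so two hits can share a group through intermediates
even if they violate the constraints pairwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

__all__ = [
    "KmerHit",
    "SeedGroup",
    "enumerate_hits",
    "group_hits",
    "group_matched_bases",
    "write_groups_tsv",
]


@dataclass(frozen=True, order=True)
class KmerHit:
    i: int  # start on read 1 (0-based)
    j: int  # start on read 2
    k: int  # hit length

    @property
    def diagonal(self) -> int:
        return self.j - self.i


@dataclass(frozen=True)
class SeedGroup:
    """A transitively closed cluster of k-mer hits.

    span_a / span_b are half-open covered intervals on each read;
    matched_bases counts distinct read-1 positions covered by member hits
    (read 1 is the fixed reference side, so overlapping k-mers are not
    double-counted and indel drift on read 2 cannot inflate the score).
    """

    hits: Tuple[KmerHit, ...]
    span_a: Tuple[int, int]
    span_b: Tuple[int, int]
    matched_bases: int
    diagonal_range: Tuple[int, int]

    @property
    def diagonal(self) -> int:
        """Representative diagonal: median of member-hit diagonals."""
        diags = sorted(h.diagonal for h in self.hits)
        return diags[(len(diags) - 1) // 2]


def enumerate_hits(seq_a: str, seq_b: str, k_group: int) -> List[KmerHit]:
    """All exact k_group-mer matches between two sequences, by hash join.

    k-mers containing non-ACGT symbols never match.  Result is sorted by
    (i, j).
    """
    if k_group < 1:
        raise ValueError("k_group must be >= 1")
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    valid = frozenset("ACGT")
    table: Dict[str, List[int]] = {}
    for j in range(len(seq_b) - k_group + 1):
        kmer = seq_b[j : j + k_group]
        if set(kmer) <= valid:
            table.setdefault(kmer, []).append(j)
    hits: List[KmerHit] = []
    for i in range(len(seq_a) - k_group + 1):
        kmer = seq_a[i : i + k_group]
        for j in table.get(kmer, ()):
            hits.append(KmerHit(i=i, j=j, k=k_group))
    hits.sort()
    return hits


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _make_group(hits: Sequence[KmerHit]) -> SeedGroup:
    hits = tuple(sorted(hits))
    span_a = (min(h.i for h in hits), max(h.i + h.k for h in hits))
    span_b = (min(h.j for h in hits), max(h.j + h.k for h in hits))
    matched = group_matched_bases(hits)
    diags = [h.diagonal for h in hits]
    group = SeedGroup(
        hits=hits,
        span_a=span_a,
        span_b=span_b,
        matched_bases=matched,
        diagonal_range=(min(diags), max(diags)),
    )
    assert matched >= hits[0].k, "a group cannot cover fewer bases than one k-mer"
    return group


def group_hits(hits: Iterable[KmerHit], rho: int, delta: int) -> List[SeedGroup]:
    """Cluster hits into group seeds under the (rho, delta) constraints.

    Hits are deduplicated defensively, sorted by i, and each hit is only
    probed against later hits within the rho-window on i — any pair
    satisfying the distance constraint lies inside that window, so the
    components equal the full transitive closure.  Groups are returned
    ordered by their first hit; the partition is independent of the input
    order of the hits.
    """
    uniq = sorted(set(hits))
    if not uniq:
        return []
    if rho < uniq[0].k:
        raise ValueError("rho must be >= k")
    if delta < 0:
        raise ValueError("delta must be >= 0")
    uf = _UnionFind(len(uniq))
    for a in range(len(uniq)):
        ha = uniq[a]
        for b in range(a + 1, len(uniq)):
            hb = uniq[b]
            di = hb.i - ha.i
            if di > rho:
                break  # sorted by i: nothing further can satisfy D <= rho
            if abs(hb.j - ha.j) > rho:
                continue
            if abs(hb.diagonal - ha.diagonal) > delta:
                continue
            uf.union(a, b)
    components: Dict[int, List[KmerHit]] = {}
    for idx, hit in enumerate(uniq):
        components.setdefault(uf.find(idx), []).append(hit)
    groups = [_make_group(members) for members in components.values()]
    groups.sort(key=lambda g: g.hits[0])
    return groups


def group_matched_bases(hits: Sequence[KmerHit]) -> int:
    """Size of the union of covered read-1 intervals [i, i+k) of the hits."""
    if not hits:
        raise ValueError("group must be non-empty")
    intervals = sorted((h.i, h.i + h.k) for h in hits)
    total = 0
    cur_start, cur_end = intervals[0]
    for start, end in intervals[1:]:
        if start > cur_end:
            total += cur_end - cur_start
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    total += cur_end - cur_start
    return total


def write_groups_tsv(groups: Sequence[SeedGroup], path) -> None:
    """Debug dump of group seeds for one read pair (dot-plot friendly)."""
    with open(path, "w") as fh:
        fh.write(
            "group\thits\ta_start\ta_end\tb_start\tb_end\tmatched_bases\tdiagonal\n"
        )
        for gid, g in enumerate(groups):
            fh.write(
                f"{gid}\t{len(g.hits)}\t{g.span_a[0]}\t{g.span_a[1]}\t"
                f"{g.span_b[0]}\t{g.span_b[1]}\t{g.matched_bases}\t{g.diagonal}\n"
            )
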