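"""Chaining of group seeds and the overlap acceptance rule.

Group seeds for a candidate pair are chained by sparse dynamic programming
under strict precedence (each group must end before the next begins, on
both reads), maximizing the total number of matched bases; no gap penalty
is applied.  Non-collinear chain ends are trimmed away before the chain's
bounding box is extended along its diagonal to the read ends, which yields
the estimated overlap region and its length L_O.

A chain is accepted as an overlap when its matched-base count n reaches
the expectation implied by the seeding calibration,

    n_e = (1/c) * (L_O / rho) * k,

i.e. at least one k-mer's worth of matches per calibrated inter-seed
distance, damped by the sensitivity coefficient c, and when the chained
region covers similarly sized stretches of both reads (indels cannot
stretch one side arbitrarily).
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

from .seeding import SeedGroup

__all__ = [
    "Chain",
    "OverlapCall",
    "chain_groups",
    "trim_collinear",
    "estimate_overlap_region",
    "decide_overlap",
]


@dataclass(frozen=True)
class Chain:
    """An ordered, strictly precedent list of group seeds."""

    groups: Tuple[SeedGroup, ...]
    score: int  # total matched bases n

    @property
    def a_start(self) -> int:
        return self.groups[0].span_a[0]

    @property
    def a_end(self) -> int:
        return self.groups[-1].span_a[1]

    @property
    def b_start(self) -> int:
        return self.groups[0].span_b[0]

    @property
    def b_end(self) -> int:
        return self.groups[-1].span_b[1]

    @property
    def diagonal_profile(self) -> Tuple[int, ...]:
        return tuple(g.diagonal for g in self.groups)


@dataclass(frozen=True)
class OverlapCall:
    """An overlap verdict with approximate coordinates (half-open)."""

    id_a: str
    id_b: str
    strand: str
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    n_matched: int
    l_o: int
    accepted: bool
    reason: str = ""  # 'below-n_e' / 'size-dissimilar' when rejected


def _precedes(g: SeedGroup, h: SeedGroup) -> bool:
    return g.span_a[1] <= h.span_a[0] and g.span_b[1] <= h.span_b[0]


def chain_groups(groups: Sequence[SeedGroup]) -> Chain:
    """Maximum-matched-bases chain under strict precedence.

    O(m^2) sparse DP over groups sorted by (a_start, b_start); ties are
    broken deterministically toward smaller a_start, then smaller b_start.
    """
    if not groups:
        raise ValueError("need at least one group")
    order = sorted(
        range(len(groups)),
        key=lambda t: (groups[t].span_a[0], groups[t].span_b[0], groups[t].span_b[1]),
    )
    gs = [groups[t] for t in order]
    m = len(gs)
    best = [g.matched_bases for g in gs]
    prev: List[Optional[int]] = [None] * m
    for t in range(m):
        for s in range(t):
            if _precedes(gs[s], gs[t]) and best[s] + gs[t].matched_bases > best[t]:
                best[t] = best[s] + gs[t].matched_bases
                prev[t] = s
    # pick chain end: max score, then smaller a_start, then smaller b_start
    end = min(
        range(m),
        key=lambda t: (-best[t], gs[t].span_a[0], gs[t].span_b[0]),
    )
    chain: List[SeedGroup] = []
    cur: Optional[int] = end
    while cur is not None:
        chain.append(gs[cur])
        cur = prev[cur]
    chain.reverse()
    return Chain(groups=tuple(chain), score=best[end])


def trim_collinear(chain: Chain, delta: int, q: float) -> Chain:
    """Keep the maximal-score contiguous sub-chain whose group diagonals
    stay within a band around the sub-chain's median diagonal.

    The band half-width is delta + ceil(q * span): delta bounds local
    drift between neighbouring seeds and q * span bounds the cumulative
    indel drift across the sub-chain's read-1 extent.  Off-diagonal
    terminal groups, which overestimate the overlap region, fall outside
    the band and are trimmed; a chain is never emptied (worst case the
    best single group survives).
    """
    groups = chain.groups
    m = len(groups)
    diags = [g.diagonal for g in groups]
    prefix = [0]
    for g in groups:
        prefix.append(prefix[-1] + g.matched_bases)
    best: Optional[Tuple[int, int, int]] = None  # (score, -start, -end)
    for lo in range(m):
        window: List[int] = []
        for hi in range(lo, m):
            bisect.insort(window, diags[hi])
            med = window[(len(window) - 1) // 2]
            span = groups[hi].span_a[1] - groups[lo].span_a[0]
            half_width = delta + math.ceil(q * span)
            # the band holds iff the extreme diagonals stay inside it
            if max(window[-1] - med, med - window[0]) <= half_width:
                score = prefix[hi + 1] - prefix[lo]
                cand = (score, -lo, -hi)
                if best is None or cand > best:
                    best = cand
    assert best is not None  # single-group windows always qualify
    lo, hi = -best[1], -best[2]
    kept = groups[lo : hi + 1]
    return Chain(groups=tuple(kept), score=sum(g.matched_bases for g in kept))


def estimate_overlap_region(
    chain: Chain, len_a: int, len_b: int
) -> Tuple[int, int, int, int, int]:
    """Extend the chain's bounding box along its diagonal to the read
    ends, clipping at read boundaries.

    Returns (a_start, a_end, b_start, b_end, l_o) with l_o the extended
    span on read 1.  Extending until either read runs out on each side is
    exactly the diagonal extension clipped to the rectangle.
    """
    left = min(chain.a_start, chain.b_start)
    right = min(len_a - chain.a_end, len_b - chain.b_end)
    if right < 0:
        raise ValueError("chain exceeds read bounds")
    a_start = chain.a_start - left
    b_start = chain.b_start - left
    a_end = chain.a_end + right
    b_end = chain.b_end + right
    return a_start, a_end, b_start, b_end, a_end - a_start


def expected_matched_bases(l_o: int, c: float, rho: int, k_group: int) -> float:
    """n_e = (1/c) * (L_O / rho) * k."""
    if c <= 0:
        raise ValueError("c must be > 0")
    return (l_o / rho) * k_group / c


def decide_overlap(
    chain: Chain,
    l_o: int,
    c: float,
    rho: int,
    k_group: int,
    size_similarity_tau: float = 0.3,
    *,
    id_a: str = "a",
    id_b: str = "b",
    strand: str = "+",
    region: Optional[Tuple[int, int, int, int]] = None,
) -> OverlapCall:
    """Apply the acceptance rule to a (trimmed) chain.

    Accepts iff n >= n_e and the chained spans on the two reads differ by
    at most size_similarity_tau of the larger.  ``region`` carries the
    estimated overlap coordinates; it defaults to the chain bounding box.
    """
    if rho < k_group:
        raise ValueError("rho must be >= k_group")
    n_e = expected_matched_bases(l_o, c, rho, k_group)
    span_a = chain.a_end - chain.a_start
    span_b = chain.b_end - chain.b_start
    similar = abs(span_a - span_b) <= size_similarity_tau * max(span_a, span_b)
    reason = ""
    if chain.score < n_e:
        reason = "below-n_e"
    elif not similar:
        reason = "size-dissimilar"
    if region is None:
        region = (chain.a_start, chain.a_end, chain.b_start, chain.b_end)
    return OverlapCall(
        id_a=id_a,
        id_b=id_b,
        strand=strand,
        a_start=region[0],
        a_end=region[1],
        b_start=region[2],
        b_end=region[3],
        n_matched=chain.score,
        l_o=l_o,
        accepted=reason == "",
        reason=reason,
    )


def mirror_call(call: OverlapCall) -> OverlapCall:
    """The same verdict viewed from the other read."""
    return replace(
        call,
        id_a=call.id_b,
        id_b=call.id_a,
        a_start=call.b_start,
        a_end=call.b_end,
        b_start=call.a_start,
        b_end=call.a_end,
    )
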