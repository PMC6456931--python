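"""Generalized suffix array filtration of candidate read pairs.

All reads (and, by default, their reverse complements) are concatenated
with unique terminators into one text; a generalized suffix array plus the
LCP array over it lets us count, for every oriented read pair, the number
of *positional* shared k-mers: position pairs (one per read) whose
suffixes share a common prefix of at least k bases.  Pairs sharing at
least a calibrated number of long k-mers (default: two 15-mers) survive
to the seeding stage; everything else is discarded.

Suffixes in the same maximal run of LCP >= k share the same leading
k-mer, and runs are disjoint, so accumulating cross-read occurrence
products run by run reproduces exactly the brute-force hash join over
k-mer start positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Tuple

import numpy as np

__all__ = [
    "ReadSet",
    "SuffixIndex",
    "CandidatePair",
    "reverse_complement",
    "build_suffix_index",
    "count_shared_kmers",
    "filter_pairs",
    "write_candidates_tsv",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# base encoding used inside the suffix index; terminators and ambiguous
# symbols receive unique codes so they can never extend a common prefix
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ReadSet:
    """Ordered collection of identified reads.

    Read ids must be unique and sequences non-empty; sequences are stored
    uppercased.  Iteration order is insertion order, but all pair-level
    results downstream are canonicalized by id so they do not depend on it.
    """

    def __init__(self, reads: Iterable[Tuple[str, str]] = ()):
        self._seqs: Dict[str, str] = {}
        for read_id, seq in reads:
            self.add(read_id, seq)

    def add(self, read_id: str, seq: str) -> None:
        if read_id in self._seqs:
            raise ValueError(f"duplicate read id: {read_id!r}")
        if not seq:
            raise ValueError(f"empty sequence for read {read_id!r}")
        self._seqs[read_id] = seq.upper()

    def __len__(self) -> int:
        return len(self._seqs)

    def __contains__(self, read_id: str) -> bool:
        return read_id in self._seqs

    def __getitem__(self, read_id: str) -> str:
        return self._seqs[read_id]

    def ids(self) -> List[str]:
        return list(self._seqs)

    def items(self):
        return self._seqs.items()

    def length_of(self, read_id: str) -> int:
        return len(self._seqs[read_id])

    def lengths(self) -> Dict[str, int]:
        return {rid: len(s) for rid, s in self._seqs.items()}


@dataclass
class SuffixIndex:
    """Suffix array + LCP + read-id map over the concatenated oriented reads."""

    read_ids: List[str]
    text_codes: np.ndarray = field(repr=False)  # int codes incl. sentinels
    sa: np.ndarray = field(repr=False)
    lcp: np.ndarray = field(repr=False)  # lcp[i] = LCP(suffix sa[i-1], sa[i]); lcp[0] = 0
    pos_read: np.ndarray = field(repr=False)  # text position -> read index (-1 on terminator)
    pos_forward: np.ndarray = field(repr=False)  # text position -> True if '+' orientation

    @property
    def n(self) -> int:
        return len(self.sa)


def _suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (O(n log^2 n) with numpy sorts).

    ``codes`` must already be distinct-sentinel encoded; any correct
    construction would do — correctness, not asymptotics, is the contract.
    """
    n = len(codes)
    _, rank = np.unique(codes, return_inverse=True)
    rank = rank.astype(np.int64)
    k = 1
    sa = np.argsort(rank, kind="stable")
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        sa = np.lexsort((key2, rank))
        r1, r2 = rank[sa], key2[sa]
        changed = np.empty(n, dtype=np.int64)
        changed[0] = 0
        changed[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[sa] = np.cumsum(changed)
        rank = new_rank
        if rank[sa[-1]] == n - 1:
            return sa
        k *= 2


def _kasai_lcp(codes: np.ndarray, sa: np.ndarray) -> np.ndarray:
    """LCP array via Kasai's algorithm; sentinels are all distinct so
    common prefixes never cross read boundaries."""
    n = len(sa)
    rank = np.empty(n, dtype=np.int64)
    rank[sa] = np.arange(n)
    lcp = np.zeros(n, dtype=np.int64)
    c = codes.tolist()
    sa_l = sa.tolist()
    rank_l = rank.tolist()
    h = 0
    for pos in range(n):
        r = rank_l[pos]
        if r > 0:
            prev = sa_l[r - 1]
            while pos + h < n and prev + h < n and c[pos + h] == c[prev + h]:
                h += 1
            lcp[r] = h
            if h > 0:
                h -= 1
        else:
            h = 0
    return lcp


def build_suffix_index(
    read_set: ReadSet, include_reverse_complement: bool = True
) -> SuffixIndex:
    """Build the generalized suffix array over all oriented reads.

    Each read contributes its forward sequence and, when the flag is set,
    its reverse complement, each followed by a unique terminator.  Bases
    A/C/G/T get shared codes; every terminator and every ambiguous symbol
    gets its own sentinel code (strictly above all bases), so ambiguous
    bases never match anything, including other ambiguous bases.
    """
    if len(read_set) == 0:
        raise ValueError("read set is empty")
    read_ids = read_set.ids()
    pieces: List[Tuple[int, bool, str]] = []
    for idx, rid in enumerate(read_ids):
        seq = read_set[rid]
        pieces.append((idx, True, seq))
        if include_reverse_complement:
            pieces.append((idx, False, reverse_complement(seq)))

    total = sum(len(s) + 1 for _, _, s in pieces)
    codes = np.empty(total, dtype=np.int64)
    pos_read = np.empty(total, dtype=np.int64)
    pos_forward = np.zeros(total, dtype=bool)
    lut = np.full(256, -1, dtype=np.int64)
    for base, code in _BASE_CODE.items():
        lut[ord(base)] = code
    offset = 0
    for idx, forward, seq in pieces:
        m = len(seq)
        codes[offset : offset + m] = lut[np.frombuffer(seq.encode("ascii"), np.uint8)]
        pos_read[offset : offset + m] = idx
        pos_forward[offset : offset + m] = forward
        codes[offset + m] = -1  # terminator placeholder
        pos_read[offset + m] = -1
        offset += m + 1
    # every terminator and every ambiguous base becomes its own sentinel
    sentinels = np.flatnonzero(codes < 0)
    codes[sentinels] = 4 + np.arange(sentinels.size)

    sa = _suffix_array(codes)
    lcp = _kasai_lcp(codes, sa)
    return SuffixIndex(
        read_ids=read_ids,
        text_codes=codes,
        sa=sa,
        lcp=lcp,
        pos_read=pos_read,
        pos_forward=pos_forward,
    )


def count_shared_kmers(
    index: SuffixIndex, k_filter: int, max_run_size: int | None = None
) -> Dict[Tuple[str, str, str], int]:
    """Count positional shared k-mers for every oriented read pair.

    Returns {(id_a, id_b, strand): count} with id_a < id_b (string order).
    Forward-forward occurrence pairs feed the '+' strand; pairs where the
    lower id is forward and the higher id reverse feed the '-' strand.
    The two remaining orientation combinations mirror those counts (every
    match reappears under the reverse complement of its k-mer) and are
    skipped to avoid double counting.  Self pairs, in either orientation,
    are excluded.

    ``max_run_size`` skips suffix-array runs with more occurrences than
    the cap — a guard against pathological repeats that is off by
    default, since dropping runs makes counts diverge from the hash join.
    """
    if k_filter < 1:
        raise ValueError("k_filter must be >= 1")
    lcp = index.lcp
    sa = index.sa
    pos_read = index.pos_read
    pos_forward = index.pos_forward
    read_ids = index.read_ids
    # id rank for canonical ordering by read-id string
    id_order = {rid: r for r, rid in enumerate(sorted(read_ids))}

    mask = lcp >= k_filter
    # run over sa[i0-1 .. i1] wherever mask[i0..i1] is a maximal True stretch
    idx = np.flatnonzero(mask)
    counts: Dict[Tuple[str, str, str], int] = {}
    if idx.size == 0:
        return counts
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    for s, e in zip(starts, ends):
        lo = idx[s] - 1
        hi = idx[e]
        if max_run_size is not None and hi - lo + 1 > max_run_size:
            continue
        tally: Dict[Tuple[int, bool], int] = {}
        for slot in range(lo, hi + 1):
            ridx = pos_read[sa[slot]]
            if ridx < 0:
                continue
            key = (int(ridx), bool(pos_forward[sa[slot]]))
            tally[key] = tally.get(key, 0) + 1
        if len(tally) < 2:
            continue
        keys = list(tally)
        for a in range(len(keys)):
            ra, fa = keys[a]
            for b in range(a + 1, len(keys)):
                rb, fb = keys[b]
                if ra == rb:
                    continue
                ia, ib = read_ids[ra], read_ids[rb]
                if id_order[ia] > id_order[ib]:
                    ia, ib, fa2, fb2 = ib, ia, fb, fa
                else:
                    fa2, fb2 = fa, fb
                if fa2 and fb2:
                    strand = "+"
                elif fa2 and not fb2:
                    strand = "-"
                else:
                    # (-,-) mirrors (+,+); (-,+) mirrors (+,-)
                    continue
                pair = (ia, ib, strand)
                counts[pair] = counts.get(pair, 0) + tally[keys[a]] * tally[keys[b]]
    return counts


@dataclass(frozen=True)
class CandidatePair:
    """A read pair surviving filtration in one relative orientation."""

    id_a: str
    id_b: str
    strand: str  # '+' or '-', orientation of b relative to a
    shared_kmers: int


def filter_pairs(
    pair_counts: Dict[Tuple[str, str, str], int], threshold: int
) -> List[CandidatePair]:
    """Keep oriented pairs with at least ``threshold`` shared k-mers.

    Each orientation is tested independently: a true overlap exists in one
    relative orientation, and summing across orientations would let two
    sub-threshold noise counts pass together.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    kept = [
        CandidatePair(id_a=a, id_b=b, strand=s, shared_kmers=c)
        for (a, b, s), c in pair_counts.items()
        if c >= threshold
    ]
    kept.sort(key=lambda cp: (cp.id_a, cp.id_b, cp.strand))
    return kept


def write_candidates_tsv(candidates: List[CandidatePair], path) -> None:
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tstrand\tshared_kmers\n")
        for cp in candidates:
            fh.write(f"{cp.id_a}\t{cp.id_b}\t{cp.strand}\t{cp.shared_kmers}\n")
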