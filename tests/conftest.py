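"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the code paths they check: shared-k-mer
counts are recomputed by a dictionary hash join over k-mer start
positions, seed grouping by transitive closure over all hit pairs,
chaining by exhaustive subset enumeration, and the calibration
distributions by direct simulation.
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pytest

from groupseed.seeding import KmerHit, SeedGroup
from groupseed.suffix import ReadSet, reverse_complement

BASES = "ACGT"


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_sequence(rng, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def random_read_set(rng, n_reads: int, max_len: int, min_len: int = 5) -> ReadSet:
    return ReadSet(
        (f"r{i:03d}", random_sequence(rng, int(rng.integers(min_len, max_len + 1))))
        for i in range(n_reads)
    )


# ---------------------------------------------------------------- oracles


def hash_join_counts(
    read_set: ReadSet, k: int
) -> Dict[Tuple[str, str, str], int]:
    """Positional shared-k-mer counts by dictionary join, counting
    (a+, b+) and (a+, b-) with a < b by id."""

    def kmer_positions(seq: str) -> Dict[str, List[int]]:
        table: Dict[str, List[int]] = {}
        for i in range(len(seq) - k + 1):
            sub = seq[i : i + k]
            if set(sub) <= set(BASES):
                table.setdefault(sub, []).append(i)
        return table

    ids = sorted(read_set.ids())
    counts: Dict[Tuple[str, str, str], int] = {}
    tables = {rid: kmer_positions(read_set[rid]) for rid in ids}
    rc_tables = {
        rid: kmer_positions(reverse_complement(read_set[rid])) for rid in ids
    }
    for a, b in itertools.combinations(ids, 2):
        for strand, table_b in (("+", tables[b]), ("-", rc_tables[b])):
            total = sum(
                len(pos_a) * len(table_b[kmer])
                for kmer, pos_a in tables[a].items()
                if kmer in table_b
            )
            if total:
                counts[(a, b, strand)] = total
    return counts


def brute_force_hits(seq_a: str, seq_b: str, k: int) -> List[KmerHit]:
    hits = []
    for i in range(len(seq_a) - k + 1):
        for j in range(len(seq_b) - k + 1):
            if seq_a[i : i + k] == seq_b[j : j + k]:
                hits.append(KmerHit(i=i, j=j, k=k))
    return hits


def transitive_closure_groups(
    hits: Sequence[KmerHit], rho: int, delta: int
) -> List[frozenset]:
    """Connected components of the full pairwise constraint graph,
    materialized explicitly and closed with scipy's component labelling."""
    from scipy.sparse.csgraph import connected_components

    uniq = sorted(set(hits))
    ii = np.array([h.i for h in uniq])
    jj = np.array([h.j for h in uniq])
    di = np.abs(ii[:, None] - ii[None, :])
    dj = np.abs(jj[:, None] - jj[None, :])
    shift = np.abs((jj - ii)[:, None] - (jj - ii)[None, :])
    adj = (np.maximum(di, dj) <= rho) & (shift <= delta)
    _, labels = connected_components(adj, directed=False)
    comps: Dict[int, set] = {}
    for h, lab in zip(uniq, labels):
        comps.setdefault(int(lab), set()).add(h)
    return [frozenset(c) for c in comps.values()]


def exhaustive_best_chain(groups: Sequence[SeedGroup]) -> int:
    """Best total matched bases over all strictly precedent subsets."""

    def precedes(g: SeedGroup, h: SeedGroup) -> bool:
        return g.span_a[1] <= h.span_a[0] and g.span_b[1] <= h.span_b[0]

    # any valid chain is strictly increasing in a_start, so checking each
    # subset in a_start order enumerates every chain exactly once
    best = 0
    for r in range(1, len(groups) + 1):
        for subset in itertools.combinations(groups, r):
            ordered = sorted(subset, key=lambda g: (g.span_a[0], g.span_b[0]))
            if all(precedes(ordered[t], ordered[t + 1]) for t in range(r - 1)):
                best = max(best, sum(g.matched_bases for g in ordered))
    return best


def random_groups(rng, n: int, k: int = 9) -> List[SeedGroup]:
    """Random single-hit groups with random geometry."""
    from groupseed.seeding import _make_group

    groups = []
    for _ in range(n):
        i = int(rng.integers(0, 400))
        j = int(rng.integers(0, 400))
        groups.append(_make_group([KmerHit(i=i, j=j, k=k)]))
    return groups


def mc_waiting_samples(p: float, k: int, n_samples: int, rng) -> np.ndarray:
    """Distances between consecutive (disjoint) runs of k heads in a long
    Bernoulli(p) sequence: run-length encode the heads, place a seed
    completion every k heads inside each maximal run, and difference the
    completion positions."""
    samples: List[np.ndarray] = []
    have = 0
    mean_wait = (1 - p**k) / ((1 - p) * p**k) if p < 1 else k
    while have < n_samples:
        m = int((n_samples - have + 10) * mean_wait * 1.3) + 1000
        heads = rng.random(m) < p
        padded = np.concatenate(([False], heads, [False])).astype(np.int8)
        d = np.diff(padded)
        run_starts = np.flatnonzero(d == 1)
        run_ends = np.flatnonzero(d == -1)  # exclusive
        completions = []
        for s, e in zip(run_starts, run_ends):
            completions.append(np.arange(s + k, e + 1, k))
        if not completions:
            continue
        pos = np.concatenate(completions)
        if pos.size < 2:
            continue
        samples.append(np.diff(pos))
        have += samples[-1].size
    return np.concatenate(samples)[:n_samples]


def mc_shift_samples(q: float, l: int, n_samples: int, rng) -> np.ndarray:
    steps = rng.choice([-1, 0, 1], size=(n_samples, l), p=[q, 1 - 2 * q, q])
    return steps.sum(axis=1)
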