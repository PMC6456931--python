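"""The three-stage overlap pipeline: filtration, group seeding, chaining."""

from __future__ import annotations

import logging
from typing import List, Optional, Tuple

from . import chaining, seeding, suffix
from .io import PipelineConfig
from .stats import GroupCriteria
from .suffix import CandidatePair, ReadSet

__all__ = ["run_pipeline", "evaluate_candidate"]

log = logging.getLogger("groupseed")


def evaluate_candidate(
    seq_a: str,
    seq_b: str,
    candidate: CandidatePair,
    criteria: GroupCriteria,
    config: PipelineConfig,
) -> Optional[chaining.OverlapCall]:
    """Run seeding + chaining for one oriented candidate pair.

    ``seq_b`` must already be oriented (reverse-complemented for '-'
    candidates); returned coordinates for '-' calls are converted back to
    the forward strand of read b per PAF convention.
    """
    hits = seeding.enumerate_hits(seq_a, seq_b, criteria.k)
    if not hits:
        return None
    groups = seeding.group_hits(hits, criteria.rho, criteria.delta)
    chain = chaining.chain_groups(groups)
    chain = chaining.trim_collinear(chain, criteria.delta, config.q)
    a_start, a_end, b_start, b_end, l_o = chaining.estimate_overlap_region(
        chain, len(seq_a), len(seq_b)
    )
    if candidate.strand == "-":
        b_start, b_end = len(seq_b) - b_end, len(seq_b) - b_start
    call = chaining.decide_overlap(
        chain,
        l_o,
        c=config.c,
        rho=criteria.rho,
        k_group=criteria.k,
        size_similarity_tau=config.size_similarity_tau,
        id_a=candidate.id_a,
        id_b=candidate.id_b,
        strand=candidate.strand,
        region=(a_start, a_end, b_start, b_end),
    )
    return call


def run_pipeline(
    read_set: ReadSet,
    config: PipelineConfig,
    return_rejected: bool = False,
) -> List[chaining.OverlapCall] | Tuple[list, list]:
    """All-vs-all overlap detection.

    Returns accepted calls, canonically ordered by (id_a, id_b, strand)
    with id_a < id_b, so the output is independent of read input order.
    With ``return_rejected`` the below-threshold / dissimilar candidates
    are returned too, with reason codes.
    """
    if config.min_read_length > 0:
        read_set = ReadSet(
            (rid, seq)
            for rid, seq in read_set.items()
            if len(seq) >= config.min_read_length
        )
    if len(read_set) < 2:
        return ([], []) if return_rejected else []
    criteria = GroupCriteria.calibrate(config.p, config.q, config.group_k, config.alpha)
    log.info(
        "calibrated group criteria: k=%d rho=%d delta=%d",
        criteria.k, criteria.rho, criteria.delta,
    )
    index = suffix.build_suffix_index(read_set, include_reverse_complement=True)
    counts = suffix.count_shared_kmers(index, config.filter_k)
    candidates = suffix.filter_pairs(counts, config.filter_threshold)
    n_pairs = len(read_set) * (len(read_set) - 1) // 2
    log.info(
        "filtration: %d / %d oriented pair counts passed (of %d read pairs)",
        len(candidates), len(counts), n_pairs,
    )
    accepted: List[chaining.OverlapCall] = []
    rejected: List[chaining.OverlapCall] = []
    for cand in candidates:
        seq_a = read_set[cand.id_a]
        seq_b = read_set[cand.id_b]
        if cand.strand == "-":
            seq_b = suffix.reverse_complement(seq_b)
        call = evaluate_candidate(seq_a, seq_b, cand, criteria, config)
        if call is None:
            continue
        if call.accepted:
            accepted.append(call)
        else:
            log.debug(
                "rejected %s/%s/%s: %s", cand.id_a, cand.id_b, cand.strand, call.reason
            )
            rejected.append(call)
    # a pair accepted in both orientations is reported once, keeping the
    # orientation with more matched bases (ties prefer '+')
    best: dict = {}
    for call in accepted:
        key = (call.id_a, call.id_b)
        old = best.get(key)
        if old is None or (call.n_matched, call.strand == "+") > (
            old.n_matched, old.strand == "+"
        ):
            best[key] = call
    result = sorted(best.values(), key=lambda c: (c.id_a, c.id_b, c.strand))
    log.info("chaining: %d pairs accepted, %d rejected", len(result), len(rejected))
    if return_rejected:
        return result, sorted(rejected, key=lambda c: (c.id_a, c.id_b, c.strand))
    return result
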