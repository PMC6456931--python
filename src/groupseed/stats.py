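"""Statistical calibration of grouped short k-mer seeding.

Grouped seeding clusters short exact k-mer matches between two noisy reads
into "group seeds" when the matches are close on both reads and lie on
nearby diagonals.  The two clustering thresholds are calibrated from simple
probabilistic models of the sequencing process:

* the inter-seed distance threshold ``rho`` comes from the waiting-time
  distribution of runs of k successes in Bernoulli(p) trials, where p is
  the per-base match probability between two overlapping reads;
* the diagonal-shift threshold ``delta`` comes from a one-dimensional
  random walk driven by insertions (+1) and deletions (-1), each occurring
  with per-base probability q.

This module also provides the expected k-mer hit counts used to choose the
count threshold of the long-k-mer filtration stage: between two unrelated
reads, positional k-mer hits are essentially uniform noise, while inside a
true overlap an additional signal term proportional to the overlap size
appears.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "ErrorModel",
    "GroupCriteria",
    "WaitingTimeDistribution",
    "DiagonalShiftDistribution",
    "match_probability",
    "expected_random_hits",
    "expected_overlap_hits",
    "waiting_time_distribution",
    "solve_rho",
    "diagonal_shift_distribution",
    "diagonal_shift_probability",
    "solve_delta",
    "recommend_filter_threshold",
]

# Guard band for the waiting-time calibration: the cumulative must clear
# 1 - alpha by more than this slack before a distance is accepted.  At the
# default parameters (p=0.85, k=9, alpha=0.05) the exact CDF grazes the
# level within ~3e-4, and the committed convention resolves that knife edge
# upward (see docs/methods.md).
RHO_GUARD_BAND = 1e-3


@dataclass(frozen=True)
class ErrorModel:
    """Error parameters of a long-read dataset.

    epsilon : per-base read error rate (vs. the true genome), in [0, 1).
    p       : per-base match probability between two overlapping reads
              (treated as an independent dial; defaults to 0.85).
    q       : per-base indel probability in a read-vs-read comparison;
              the "stay" probability 1 - 2q must remain positive.
    alphabet_size : nucleotide alphabet size, default 4.
    alpha   : significance level used for threshold calibration.
    """

    epsilon: float = 0.15
    p: float = 0.85
    q: float = 0.06
    alphabet_size: int = 4
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon < 1.0:
            raise ValueError(f"epsilon must be in [0, 1), got {self.epsilon}")
        if not 0.0 < self.p <= 1.0:
            raise ValueError(f"p must be in (0, 1], got {self.p}")
        if not 0.0 <= self.q < 0.5:
            raise ValueError(f"q must be in [0, 0.5), got {self.q}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.alphabet_size < 2:
            raise ValueError("alphabet_size must be >= 2")


@dataclass(frozen=True)
class GroupCriteria:
    """Calibrated clustering thresholds for group seeding.

    k     : seed k-mer length.
    rho   : maximum inter-seed distance (bases); rho >= k.
    delta : maximum diagonal-shift magnitude (bases).
    """

    k: int
    rho: int
    delta: int

    def __post_init__(self) -> None:
        if self.rho < self.k:
            raise ValueError("rho must be >= k")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")

    @classmethod
    def calibrate(cls, p: float, q: float, k: int, alpha: float) -> "GroupCriteria":
        """Derive (rho, delta) at confidence 1 - alpha, using rho as the
        number of random-walk steps when calibrating delta."""
        rho = solve_rho(p, k, alpha)
        delta = solve_delta(q, rho, alpha)
        return cls(k=k, rho=rho, delta=delta)


@dataclass(frozen=True)
class WaitingTimeDistribution:
    """Distribution of the inter-seed distance D_k between consecutive
    k-mer matches in a Bernoulli(p) match/mismatch sequence.

    ``mass[x]`` is P[D_k = x] for x = 0..support_bound.  The mass is zero
    below k, equals p**k at x = k, and follows the first-passage recursion
    above k.
    """

    p: float
    k: int
    mass: np.ndarray = field(repr=False)

    @property
    def support_bound(self) -> int:
        return len(self.mass) - 1

    def cdf(self) -> np.ndarray:
        return np.cumsum(self.mass)


@dataclass(frozen=True)
class DiagonalShiftDistribution:
    """Distribution of the signed diagonal shift after l steps of the
    insertion/deletion random walk with step law {-1: q, 0: 1-2q, +1: q}.

    ``mass`` has length 2l + 1; index i + l holds P[shift = i].
    """

    q: float
    l: int
    mass: np.ndarray = field(repr=False)

    def prob(self, i: int) -> float:
        if abs(i) > self.l:
            return 0.0
        return float(self.mass[i + self.l])


def match_probability(epsilon: float, k: int, alphabet_size: int = 4) -> float:
    """Probability that a k-mer at an aligned position inside a true
    overlap matches exactly.

    Per aligned base, a match occurs either because both reads are correct,
    (1-eps)^2, or because both were substituted by the same character,
    eps^2 / (|Sigma| - 1); the k-mer match probability is that raised to k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0.0 <= epsilon < 1.0:
        raise ValueError(f"epsilon must be in [0, 1), got {epsilon}")
    if alphabet_size < 2:
        raise ValueError("alphabet_size must be >= 2")
    per_base = (1.0 - epsilon) ** 2 + epsilon**2 / (alphabet_size - 1)
    return per_base**k


def expected_random_hits(
    len_a: int, len_b: int, k: int, alphabet_size: int = 4
) -> float:
    """Expected number of positional k-mer hits between two unrelated
    sequences of the given lengths (hits counted by location, not by
    distinct k-mer, assuming i.i.d. uniform bases)."""
    if len_a < 0 or len_b < 0:
        raise ValueError("lengths must be >= 0")
    if k < 1:
        raise ValueError("k must be >= 1")
    return (1.0 / alphabet_size) ** k * len_a * len_b


def expected_overlap_hits(
    overlap_size: int,
    len_a: int,
    len_b: int,
    epsilon: float,
    k: int,
    alphabet_size: int = 4,
) -> float:
    """Expected positional k-mer hits between two reads sharing a true
    overlap of ``overlap_size`` bases: a signal term P_o * M plus the
    random background term.

    This slightly over-counts, since random hits inside the overlap can
    coincide with signal hits; the bias is negligible at practical k.
    """
    if not 0 <= overlap_size <= min(len_a, len_b):
        raise ValueError("overlap_size must be within both read lengths")
    p_o = match_probability(epsilon, k, alphabet_size)
    return p_o * overlap_size + expected_random_hits(len_a, len_b, k, alphabet_size)


def waiting_time_distribution(
    p: float, k: int, support_bound: int
) -> WaitingTimeDistribution:
    """Tabulate P[D_k = x] for x = 0..support_bound.

    The recursion is the exact first-passage law for the first run of k
    successes in Bernoulli(p) trials:

        P[D_k = x] = 0                                  for x < k
        P[D_k = k] = p**k
        P[D_k = x] = (1-p) p**k (1 - sum_{i<=x-k-1} P[D_k = i])   for x > k

    i.e. trial x-k fails, the following k trials succeed, and no run
    completed by trial x-k-1.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must be in (0, 1], got {p}")
    if k < 1:
        raise ValueError("k must be >= 1")
    if support_bound < k:
        raise ValueError("support_bound must be >= k")
    mass = np.zeros(support_bound + 1)
    mass[k] = p**k
    tail_coeff = (1.0 - p) * p**k
    cum = mass[k]
    # cdf_lag holds sum_{i <= x-k-1} P[i]; it trails the running cumulative
    # by k+1 positions, so we keep a small history window.
    cdf = np.zeros(support_bound + 1)
    cdf[k] = cum
    for x in range(k + 1, support_bound + 1):
        lag = x - k - 1
        excluded = cdf[lag] if lag >= 0 else 0.0
        mass[x] = tail_coeff * (1.0 - excluded)
        cdf[x] = cdf[x - 1] + mass[x]
    return WaitingTimeDistribution(p=p, k=k, mass=mass)


def solve_rho(p: float, k: int, alpha: float, max_support: int = 100_000) -> int:
    """Smallest integer rho whose cumulative waiting-time mass clears
    1 - alpha (by more than the module's guard band).

    Raises if the cumulative cannot reach the level within ``max_support``
    distances, which signals that p is too small for the chosen k.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    level = 1.0 - alpha + RHO_GUARD_BAND
    # grow the support geometrically until the level is cleared
    bound = max(4 * k, 64)
    while bound <= max_support:
        dist = waiting_time_distribution(p, k, bound)
        cdf = dist.cdf()
        # degenerate/near-degenerate case: all mass effectively at x = k
        hit = np.flatnonzero(cdf >= min(level, 1.0 - 1e-12))
        if hit.size:
            return int(hit[0])
        bound *= 4
    raise ValueError(
        f"waiting-time cumulative cannot reach {1 - alpha} within "
        f"{max_support} bases; p={p} is too small for k={k}"
    )


def diagonal_shift_distribution(q: float, l: int) -> DiagonalShiftDistribution:
    """Exact distribution of the diagonal shift after l random-walk steps,
    computed by iterating the single-step convolution with
    {-1: q, 0: 1-2q, +1: q}.  This is the reference implementation; the
    closed form ``diagonal_shift_probability`` is cross-checked against it.
    """
    if not 0.0 <= q < 0.5:
        raise ValueError(f"q must be in [0, 0.5), got {q}")
    if l < 0:
        raise ValueError("l must be >= 0")
    step = np.array([q, 1.0 - 2.0 * q, q])
    mass = np.array([1.0])
    for _ in range(l):
        mass = np.convolve(mass, step)
    return DiagonalShiftDistribution(q=q, l=l, mass=mass)


def diagonal_shift_probability(q: float, l: int, i: int) -> float:
    """Closed-form P[shift = i after l steps]: sum over the number of
    deletions n_d of multinomial path counts

        C(l, |i|+2 n_d) C(|i|+2 n_d, |i|+n_d) q^(2 n_d + |i|) (1-2q)^(l-|i|-2 n_d)

    evaluated in log space to avoid overflow of the binomial coefficients.
    """
    if not 0.0 <= q < 0.5:
        raise ValueError(f"q must be in [0, 0.5), got {q}")
    i = abs(i)
    if i > l:
        return 0.0
    if q == 0.0:
        return 1.0 if i == 0 else 0.0
    stay = 1.0 - 2.0 * q
    terms = []
    for n_d in range((l - i) // 2 + 1):
        moves = i + 2 * n_d  # total indel steps
        log_paths = (
            gammaln(l + 1)
            - gammaln(moves + 1)
            - gammaln(l - moves + 1)
            + gammaln(moves + 1)
            - gammaln(i + n_d + 1)
            - gammaln(n_d + 1)
        )
        log_prob = moves * np.log(q)
        if l - moves > 0:
            if stay == 0.0:
                continue
            log_prob += (l - moves) * np.log(stay)
        terms.append(log_paths + log_prob)
    if not terms:
        return 0.0
    return float(np.exp(logsumexp(terms)))


def solve_delta(q: float, l: int, alpha: float) -> int:
    """Smallest delta with sum_{|i| <= delta} P[i, l] >= 1 - alpha.

    delta = l always suffices, so this cannot fail for valid inputs.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    dist = diagonal_shift_distribution(q, l)
    level = 1.0 - alpha
    cum = dist.prob(0)
    delta = 0
    while cum < level and delta < l:
        delta += 1
        cum += dist.prob(delta) + dist.prob(-delta)
    return delta


def recommend_filter_threshold(
    read_lengths,
    k_filter: int,
    epsilon: float,
    overlap_fraction: float = 0.25,
    alphabet_size: int = 4,
    length_floor: int = 2000,
) -> int:
    """Recommend a shared-k-mer count threshold for the filtration stage.

    The threshold must exceed the random-hit expectation E[X_r] at the
    longest read pair (so unrelated pairs are unlikely to pass) while
    staying below the in-overlap expectation E[X_o] at the shortest
    considered read with overlap M = overlap_fraction * L (so small true
    overlaps still pass).  Reads below ``length_floor`` are ignored when
    picking the pessimistic short length unless all reads are below it.

    Returns max(2, floor(E[X_r]) + 1); warns and returns 2 if no integer
    separates the two expectations.
    """
    lengths = [int(x) for x in read_lengths]
    if not lengths:
        raise ValueError("read_lengths must be non-empty")
    if not 0.0 < overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in (0, 1]")
    longest = max(lengths)
    considered = [x for x in lengths if x >= length_floor] or lengths
    shortest = min(considered)
    e_random = expected_random_hits(longest, longest, k_filter, alphabet_size)
    overlap = int(overlap_fraction * shortest)
    e_overlap = expected_overlap_hits(
        overlap, shortest, shortest, epsilon, k_filter, alphabet_size
    )
    t = max(2, int(np.floor(e_random)) + 1)
    if t > e_overlap:
        warnings.warn(
            f"no count threshold separates random hits (E={e_random:.3g}) from "
            f"in-overlap hits (E={e_overlap:.3g}) at k={k_filter}; "
            "falling back to 2 with low confidence",
            stacklevel=2,
        )
        return 2
    return t
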