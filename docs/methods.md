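# Methods

This note records the models behind `groupseed`, the conventions chosen
where several were defensible, and what the synthetic validation does and
does not show about real data.

## Expected k-mer hit counts (filtration)

Hits are counted *positionally*: a k-mer occurring $a$ times in one read
and $b$ times in the other contributes $a \cdot b$ hits.  Under an
i.i.d. uniform base model, two unrelated reads of lengths $L_1, L_2$
share $E[X_r] = |\Sigma|^{-k} L_1 L_2$ hits in expectation.  Inside a
true overlap of $M$ aligned positions, each position matches with
probability $(1-\varepsilon)^2 + \varepsilon^2/(|\Sigma|-1)$ — both
bases correct, or both independently substituted to the same character —
giving the signal term $P_o M$ on top of the random background.  The
model ignores indels at this stage (substitutions stand in for all error
types) and slightly over-counts because background hits inside the
overlap can coincide with signal hits; both effects are negligible at
$k = 15$.

The count threshold is picked pessimistically on both sides:
$E[X_r]$ is evaluated at the *longest* read pair (worst background) and
$E[X_o]$ at the *shortest* considered read (at least 2000 bases when any
read is that long) with $M$ a quarter of its length (worst small
overlap).  The threshold is the smallest integer exceeding $E[X_r]$,
clamped to at least 2; if that integer exceeds $E[X_o]$ no threshold
separates the regimes, and the function warns and falls back to 2.  For
long-read profiles this yields the default of two 15-mers; for a
short-read metagenome-like profile (mean ~1.7 kb) at $k = 11$ it yields
three 11-mers.

## Waiting-time calibration of the inter-seed distance ρ

Matches between two overlapping reads are modelled as Bernoulli($p$)
trials; a k-mer hit is a run of $k$ successes.  The distance $D_k$
between consecutive disjoint hits follows the exact first-passage law

- $P[D_k = x] = 0$ for $x < k$,
- $P[D_k = k] = p^k$,
- $P[D_k = x] = (1-p)\,p^k\,(1 - \sum_{i \le x-k-1} P[D_k = i])$ for $x > k$

(trial $x-k$ fails, the next $k$ succeed, no earlier completion).  The
tabulated distribution is validated against direct simulation in the
test suite.

**Threshold convention.**  The cumulative of this discrete law grazes
the confidence level at the default parameters: at $p=0.85$, $k=9$,
$\alpha=0.05$ the CDF reaches 0.9503 at distance 53 and 0.9534 at 54 —
within a few $10^{-4}$ of the level.  `solve_rho` therefore requires the
cumulative to clear $1-\alpha$ by a guard band of $10^{-3}$ before
accepting a distance, which resolves such knife-edge crossings upward
(the conservative direction for clustering: a slightly larger ρ never
splits a true group).  This yields ρ = 54 at the defaults.  Away from
the knife edge the guard band is inert — e.g. a certain match
($p = 1$) still gives ρ = k, and the Monte-Carlo 95th percentile is
reproduced for a single-base seed.

$p$ defaults to 0.85 and is deliberately independent of the simulator's
ε: it is the per-base match probability of a read-vs-read comparison,
set directly from the data's error profile rather than derived.

## Random-walk calibration of the diagonal shift δ

Indels between the two reads drift hits across diagonals.  Each compared
base moves the diagonal by +1 (insertion) or −1 (deletion) with
probability $q$ each, else stays.  After $l$ steps the shift follows the
$l$-fold convolution of $\{-1{:}\,q,\ 0{:}\,1{-}2q,\ +1{:}\,q\}$; the
closed-form sum over deletion counts (binomial path counting) is
evaluated in log space and cross-checked against the convolution, which
is the reference implementation.  δ is the smallest bound whose central
mass reaches $1-\alpha$, with $l$ set to the calibrated ρ — the largest
within-group seed separation, hence the worst-case drift window.  At the
defaults this gives δ = 5, stable for $l$ anywhere near 54.

## Filtration index

All oriented reads are concatenated with per-piece unique terminators;
ambiguous bases also become unique sentinels, so they extend no common
prefix.  The suffix array is built by numpy prefix doubling and the LCP
array by Kasai's algorithm.  Shared k-mers are accumulated over maximal
suffix-array runs with adjacent LCP ≥ k: every suffix in such a run
carries the same leading k-mer, and runs are disjoint, so cross-read
occurrence products reproduce a hash join exactly (verified against one
in the tests).  Of the four orientation combinations only (a+, b+) and
(a+, b−) are counted — the other two mirror them under reverse
complementation — and each orientation is thresholded independently,
since a true overlap exists in exactly one relative orientation.

## Group seeding

Group seeds are the connected components (single-linkage transitive
closure) of the hit graph whose edges join hits with
$D \le \rho$ and diagonal shift $\le \delta$.  The implementation sorts
hits by $i$ and probes only the ρ-window — an optimization that cannot
change the components — and is verified against a full pairwise closure.
A group's **matched bases** are the union of covered positions on read
1.  Counting on one fixed side avoids double-counting overlapping
k-mers and keeps the score comparable to $L_O$, which is also measured
on read 1; the read-2 union can differ by the (small) net indel drift.

## Chaining and acceptance

Chaining maximizes total matched bases over chains of groups in strict
precedence (each group ends before the next begins, on both reads),
with no gap penalty; ties break toward smaller read-1 then read-2
start.  The DP is exact and checked against exhaustive enumeration.

The optimal chain can be dragged off-diagonal by spurious terminal
groups, which inflates the estimated overlap.  Trimming keeps the
highest-scoring *contiguous* sub-chain whose representative diagonals
(median of member-hit diagonals) fit in a band of half-width
$\delta + \lceil q \cdot \mathrm{span} \rceil$ around the sub-chain's
median diagonal: δ bounds local drift between neighbouring seeds, and
$q \cdot \mathrm{span}$ the cumulative drift across the sub-chain.  A
single-group window always qualifies, so trimming never empties a chain.

The trimmed chain's bounding box is extended along its diagonal until
either read is exhausted on each side; $L_O$ is the extended span on
read 1.  A pair is reported iff
$n \ge n_e = \frac{1}{c}\frac{L_O}{\rho} k$ — at least one seed's worth
of matched bases per calibrated inter-seed distance, damped by $c$ —
and the chained spans on the two reads differ by at most a fraction
τ of the larger.  Defaults: $c = 2$ (a mid-range sensitivity/precision
trade-off; raising $c$ only adds acceptances) and τ = 0.3, both exposed
as flags.  Coordinates are approximate by design; callers wanting exact
overlap boundaries should align the reported pairs.

## Simulator

The generator emulates the study conditions the package is validated
under: a uniform random genome (default 100 kb), reads at 10X coverage
with truncated-normal placement lengths (mean 8000; sd 1600, i.e. 20% of
the mean, a PBSIM-like spread chosen since no spread is standard; floor
200), uniform strands, and single-pass per-base errors at 1.4%
substitutions, 8.6% insertions, 4.4% deletions (~14.5% total,
indel-dominated as in PacBio data).  Insertions are geometric per
position (emit-without-advance), so read length inflates by
$\approx 1 + p_{ins} - p_{del}$.  Ground truth is exact: every pair of
reads whose genomic intervals intersect by at least 100 bases (a floor
below which "overlap" is not meaningful for seeding; configurable) is a
truth pair, and consecutive overlapping reads along the genome are
marked as irreducible-edge adjacencies.

What it does **not** emulate: genomic repeats and compositional bias
(the random genome makes background hits nearly ideal, so real-data
precision will be lower than synthetic precision), PBSIM quality
profiles and length distributions, circular chromosomes, and chimeric
reads.  Passing the synthetic recovery test therefore demonstrates the
machinery end to end — calibration, filtration, seeding, chaining —
under the stated error model, not performance on any particular
instrument's data.

## Problem sizes and numerics

The test suite validates on desk-scale instances: oracle-equivalence
suites use hundreds of randomized instances (read sets ≤ 20×200 bases,
hit sets ≤ 500, chains ≤ 8 groups); distribution checks use 10⁵
Monte-Carlo samples at 3-standard-error tolerance; the end-to-end
recovery experiment uses a 100 kb genome at 10X (~125 reads, ~1300
truth pairs) with fixed seeds.  Exact equalities are asserted exactly;
the closed-form/convolution agreement at 10⁻¹²; floating comparisons
otherwise at relative 10⁻⁹ or looser as stated in each test.

Known limitations: the suffix-array shared-k-mer pass enumerates all
cross-read occurrence products, so highly repetitive inputs can inflate
run products (an optional run-size cap exists but is off by default);
chaining is O(m²) in the number of groups per pair; and the pipeline is
single-threaded by contract — determinism (byte-identical PAF across
runs and input orderings) is part of the tested interface.
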