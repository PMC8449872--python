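# Methods

## Model and assumptions

The background text of length `n` is generated either by an i.i.d.
(Bernoulli, order 0) process over `{A,C,G,T}` with base frequencies
`P(a)`, or by a stationary first-order Markov chain with transition
matrix `P(b|a)` started from its stationary distribution. The motif is
a fully specified string `S = a₁…a_m` (no ambiguity codes); its window
probability is the chain product `P(S) = P(a₁)·∏ P(aᵢ₊₁|aᵢ)`, which at
order 0 reduces to the product of base frequencies and is computed from
symbol counts so that anagrams receive bit-identical values.

The count distribution formula assumes the motif is **non-clumpable**:
no proper non-empty prefix equals a suffix, so occurrences cannot
overlap. Clumpability is decided by the KMP border array. Clumpable
queries are substituted by a non-clumpable surrogate of identical
window probability — the lexicographically first non-clumpable distinct
anagram (a sorted string with more than one distinct symbol is itself
non-clumpable, so the search is effectively O(1); a 10,000-candidate
cap guards the degenerate cases), else a first/last-character
replacement with a different symbol of exactly equal frequency. Results
obtained through a surrogate are marked `extrapolated`: overlap makes
the true clumpable distribution differ, and no exact formula for that
case is implemented here. When neither strategy applies (homopolymers
under backgrounds where no two frequencies are exactly equal — the
common case for frequencies estimated from a real genome) the motif is
reported `failed` rather than approximated silently.

## The computation

For a non-clumpable motif, `P(j,m,n) = P(S)ʲ Σ ∏ᵧ P(S₀,d_y)`, the sum
running over weak compositions `d₁+…+d_{j+1} = n−mj` of the text
outside the `j` placements, with the avoidance probability obeying
`P(S₀,n) = P(S₀,n−1) − P(S)·P(S₀,n−m)` and base cases 1 below `m`.
The number of compositions is `C(n+j(1−m), n−mj)`.

The production path exploits the geometric convergence of
`R = P(S₀,n+1)/P(S₀,n)`: the recurrence is iterated until consecutive
ratios agree within `ε` (default `1e-7`), defining `n_ε` and `R`; each
segment factor is then `P(S₀,n_ε)·R^(d−n_ε)`, and since the product
depends on the segment lengths only through their sum, the whole
configuration sum collapses to

    P(j,m,n) ≈ P(S)ʲ · R^(n−mj−n_ε(j+1)) · P(S₀,n_ε)^(j+1) · C(n+j(1−m), n−mj).

All production arithmetic is in log space (`scipy.special.gammaln` for
the binomial), so `n` in the millions and `j` in the hundreds cannot
overflow; probabilities are clamped to `[0,1]` after exponentiation and
NaN/negative intermediates abort with an instability error rather than
propagate.

Counts are evaluated for `j = 0, 1, …` up to `min(j_max, ⌊n/m⌋)`
(`j_max` defaults to 500; counts beyond `⌊n/m⌋` are structurally zero)
and evaluation stops once `P(j) < ε` **and** `j` has passed the
distribution's mode (approximated by `⌈E[count]⌉`) — the tolerance
alone would stop at `j = 0` whenever `P(0) < ε`. If the cap bites
before the stopping rule, the distribution is flagged `truncated` and
the unassigned mass is reported as the normalisation residual.

When `(n−m+1)·log(1−P(S)) > log(1−ε)` — i.e. `P(0)` provably exceeds
`1−ε` — the engine short-circuits to the single mass
`P(0) = (1−P(S))^(n−m+1)`, the quantity the inequality bounds. The
expected count is `(n−m+1)·P(S)` with the stationary start convention
(0 when `n < m`), and tail p-values are computed from the stored masses
with the upper tail formed as `1 − Σ_{j<obs} P(j)`, so truncation
residual is automatically included in the enrichment p-value as an
upper bound.

## Normalisation and accuracy profile

The collapsed formula carries a small multiplicative bias per segment:
the avoidance series is `c₁Rᵈ + c₂r₂ᵈ + …`, and extrapolating
`P(S₀,n_ε)·R^(d−n_ε) ≈ c₁Rᵈ` backwards over short segments (where the
true value is exactly 1) errs by a relative `O(P(S))` per segment.
Dividing the distribution by its raw sum whenever that sum exceeds 1
removes the common `c₁^(j+1)`-type bias (measured in the test suite to
improve pointwise agreement with the dynamic-programming referee by
three orders of magnitude at the 20 kb scale) while keeping the stored
residual a meaningful diagnostic; the rescale is deliberately
one-sided so a truncated distribution is never inflated.

The remaining error grows with `P(S)` and shrinks with motif length:
the referee comparisons in `tests/` put it below `1e-6` pointwise for
typical length-6 motifs at `n = 20,000` (below `1e-7` at length 8), at
the `1e-4` scale for window probabilities near `4e-3` (length-4-like
motifs, or extreme-composition motifs under a matching skewed
background) — always two orders of magnitude under the peak mass — and
at the percent level for length-2 motifs (`P(S)` up to 1/16), which sit
far outside the regime the method targets. The exact
configuration-enumeration path (`exact_distribution_enumeration`) is
retained as a reference: it is referee-exact to `1e-12` but exponential
in `j`, guarded at 10⁷ compositions.

The ratio-convergence test uses the gap between consecutive ratios with
a 10⁶-iteration safety cap; the converged `R` is accurate to roughly
the requested `ε` (it solves `r^m − r^{m−1} + P(S) = 0`, verified to
`3e-12` at `ε = 1e-12` in the acceptance suite). The recurrence is
stable for `P(S) < (m−1)^{m−1}/m^m`; beyond it the avoidance values
leave `[0,1]` and the computation aborts with an instability error that
batch processing converts to a per-motif failure record.

## Order-1 mode

Under a first-order background both `P(S)` and the recurrence use the
stationary-start convention (the stationary distribution is the
dominant eigenvector of the transition matrix; a reducible chain raises
an explicit error). The configuration sum treats segments as
independent, which ignores the dependence between a segment's last
symbol and the following window's first symbol; order 0 is the fully
validated mode and order-1 results should be read as approximate. The
oracles support order 1 exactly (the DP carries the previous symbol in
its state), so the magnitude of this boundary effect is measurable.

## Oracles and synthetic data

Two independent referees back the production path. The enumeration
oracle sums the probability of every length-`n` text grouped by
(sliding-window, overlap-counting) occurrence count; per-text
probabilities are double-precision products and per-count sums are
accumulated in extended precision (long double), for an overall error
near `1e-14` — inside the `1e-12` referee tolerance used on the
exhaustive grid. It is guarded at `4ⁿ ≤ 10⁷`. The dynamic-programming
oracle tracks (KMP automaton state, count capped at `j_cap`, previous
symbol at order 1) across text positions and is exact at genome scale.
Both count overlapping occurrences, which coincides with the formula's
count only for non-clumpable motifs; the clumpable case is kept to
demonstrate where the formula does not apply.

The fixture generator emulates the intended workload: i.i.d. genomes at
chosen base frequencies (written as FASTA) and unique random motif sets
of chosen lengths, both byte-identical for a fixed seed. It does not
emulate real-genome features — repeats, composition heterogeneity,
coding structure, long-range correlation — so passing tests demonstrate
correctness of the probability computation under the stated background
models, not goodness-of-fit of those models to any particular organism.

## Defaults and problem sizes

`ε = 1e-7` and `j_max = 500` are the shipped defaults, overridable per
call or via CLI flags. The test and acceptance suites exercise the
exhaustive grid at `n ≤ 10` (the enumeration oracle's comfortable
range), referee comparisons at `n ∈ {1,000; 20,000}` (the scale of the
demonstration figure configuration), and the batch contract at 20,000
length-13 motifs against `n = 5·10⁶` — the workload shape the method
is built for, which completes in seconds because each motif costs only
the `~n_ε + j` iterations of its own series.

## Known limitations

- No exact distribution for clumpable motifs; surrogates extrapolate
  and are always flagged.
- Percent-level approximation error for very short motifs (`m = 2`,
  `P(S)` approaching the stability bound); use the exact reference path
  there.
- Order-1 segment-boundary independence is an approximation (above).
- Multi-record FASTA is concatenated for estimation; junction bigrams
  are not treated specially.
- End-replacement surrogates require *exactly* equal frequencies, so
  homopolymers under estimated (non-tied) backgrounds fail rather than
  approximate.
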