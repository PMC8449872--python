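"""Background sequence models, motif probabilities and clumpability.

The background model describes how the reference text (a genome) is
generated: i.i.d. nucleotides (order 0, Bernoulli) or a stationary
first-order Markov chain (order 1).  Under either model the probability
``P(S)`` that a fixed motif ``S = a_1 ... a_m`` occupies a given window
is a chain product

    order 0:  P(S) = prod_i P(a_i)
    order 1:  P(S) = pi(a_1) * prod_i P(a_{i+1} | a_i)

where ``pi`` is the stationary distribution of the transition matrix.

A motif is *clumpable* when it has a non-trivial border (a proper
non-empty prefix equal to a proper suffix), so that occurrences can
overlap and form clumps.  The count-distribution formula is exact only
for non-clumpable motifs; clumpable queries are extrapolated through a
non-clumpable *surrogate* of equal probability — an anagram when one
exists, otherwise an end-character replacement with an equal-frequency
symbol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

DNA_ALPHABET: tuple[str, ...] = ("A", "C", "G", "T")

#: tolerated deviation of an input frequency vector from summing to one;
#: inputs inside this band are renormalised, outside it rejected.
FREQ_SUM_TOL = 1e-6


class BackgroundError(ValueError):
    """Invalid background-model specification."""


class MotifValidationError(ValueError):
    """Motif contains symbols outside the model alphabet (or is empty)."""


class NonErgodicChainError(ValueError):
    """Order-1 transition matrix has no unique stationary distribution."""


@dataclass(frozen=True)
class BackgroundModel:
    """A validated text-generation model.

    Parameters
    ----------
    order
        0 for i.i.d. symbols, 1 for a first-order Markov chain.
    alphabet
        Ordered symbol set; DNA ``(A, C, G, T)`` by default.
    base_freqs
        Marginal symbol probabilities (order 0: the generation law;
        order 1: used for equal-frequency surrogate replacement).
    transitions
        Conditional probabilities ``(prev, next) -> P(next | prev)``;
        required iff ``order == 1``.
    """

    order: int
    alphabet: tuple[str, ...]
    base_freqs: Mapping[str, float]
    transitions: Mapping[tuple[str, str], float] | None = None

    def freq_array(self) -> np.ndarray:
        return np.array([self.base_freqs[s] for s in self.alphabet], dtype=float)

    def transition_matrix(self) -> np.ndarray:
        if self.order != 1 or self.transitions is None:
            raise BackgroundError("transition matrix only defined for order-1 models")
        k = len(self.alphabet)
        t = np.empty((k, k), dtype=float)
        for i, a in enumerate(self.alphabet):
            for j, b in enumerate(self.alphabet):
                t[i, j] = self.transitions[(a, b)]
        return t

    def symbol_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.alphabet)}


@dataclass(frozen=True)
class MotifQuery:
    """A validated motif with its clumpability status.

    ``surrogate`` holds the non-clumpable stand-in actually analysed when
    the motif itself is clumpable; ``surrogate_method`` records which
    strategy produced it (``anagram`` or ``end_replacement``), ``none``
    for non-clumpable motifs, and ``failed`` when no surrogate exists.
    """

    sequence: str
    m: int
    clumpable: bool
    surrogate: str | None = None
    surrogate_method: str = "none"

    @classmethod
    def from_sequence(cls, sequence: str, model: BackgroundModel) -> "MotifQuery":
        seq = validate_motif(sequence, model)
        if is_clumpable(seq):
            surrogate, method = non_clumpable_surrogate(seq, model)
            return cls(seq, len(seq), True, surrogate, method)
        return cls(seq, len(seq), False, None, "none")

    @property
    def analyzed_sequence(self) -> str:
        """The sequence the distribution engine actually evaluates."""
        if not self.clumpable:
            return self.sequence
        if self.surrogate is None:
            raise MotifValidationError(
                f"no non-clumpable surrogate available for {self.sequence!r}"
            )
        return self.surrogate


def build_background(
    base_freqs: Mapping[str, float],
    order: int = 0,
    transitions: Mapping[tuple[str, str], float] | None = None,
    alphabet: Sequence[str] = DNA_ALPHABET,
) -> BackgroundModel:
    """Validate and normalise a background model specification.

    Frequencies summing to 1 within ``FREQ_SUM_TOL`` are renormalised to
    machine precision; larger deviations are rejected.  For order 1 every
    alphabet symbol needs a full transition row, each row summing to 1
    within the same tolerance.
    """
    alphabet = tuple(alphabet)
    if order not in (0, 1):
        raise BackgroundError(f"order must be 0 or 1, got {order}")
    missing = [s for s in alphabet if s not in base_freqs]
    if missing:
        raise BackgroundError(f"missing base frequencies for {missing}")
    freqs = {s: float(base_freqs[s]) for s in alphabet}
    if any(v < 0 for v in freqs.values()):
        raise BackgroundError("negative base frequency")
    total = math.fsum(freqs.values())
    if abs(total - 1.0) > FREQ_SUM_TOL:
        raise BackgroundError(f"base frequencies sum to {total}, not 1")
    freqs = {s: v / total for s, v in freqs.items()}

    if order == 1:
        if transitions is None:
            raise BackgroundError("order-1 model requires a transition map")
        trans: dict[tuple[str, str], float] = {}
        for a in alphabet:
            row = {b: float(transitions.get((a, b), -1.0)) for b in alphabet}
            if any(v < 0 for v in row.values()):
                raise BackgroundError(f"missing or negative transition row for {a!r}")
            row_sum = math.fsum(row.values())
            if abs(row_sum - 1.0) > FREQ_SUM_TOL:
                raise BackgroundError(f"transition row {a!r} sums to {row_sum}, not 1")
            for b in alphabet:
                trans[(a, b)] = row[b] / row_sum
        return BackgroundModel(1, alphabet, freqs, trans)

    if transitions is not None:
        raise BackgroundError("transitions given but order is 0")
    return BackgroundModel(0, alphabet, freqs, None)


def estimate_from_genome(
    genome: str,
    order: int = 0,
    alphabet: Sequence[str] = DNA_ALPHABET,
) -> tuple[BackgroundModel, int]:
    """Estimate a background model from a genome string.

    The genome is upper-cased; characters outside the alphabet (IUPAC
    ambiguity codes, gaps) are skipped and excluded from the counted
    length.  Returns the model and the counted length ``n``.
    """
    alphabet = tuple(alphabet)
    idx = {s: i for i, s in enumerate(alphabet)}
    codes = [idx[c] for c in genome.upper() if c in idx]
    n = len(codes)
    if n == 0:
        raise BackgroundError("empty usable genome (no alphabet symbols)")
    counts = np.bincount(codes, minlength=len(alphabet)).astype(float)
    freqs = {s: counts[i] / n for i, s in enumerate(alphabet)}
    if order == 0:
        return BackgroundModel(0, alphabet, freqs, None), n

    k = len(alphabet)
    bigram = np.zeros((k, k), dtype=float)
    arr = np.asarray(codes)
    np.add.at(bigram, (arr[:-1], arr[1:]), 1.0)
    trans: dict[tuple[str, str], float] = {}
    for i, a in enumerate(alphabet):
        row_sum = bigram[i].sum()
        for j, b in enumerate(alphabet):
            # unseen context rows fall back to a uniform row to keep the
            # matrix stochastic
            trans[(a, b)] = bigram[i, j] / row_sum if row_sum > 0 else 1.0 / k
    return BackgroundModel(1, alphabet, freqs, trans), n


def validate_motif(sequence: str, model: BackgroundModel) -> str:
    """Upper-case and validate a motif against the model alphabet.

    Ambiguity codes are rejected: the occurrence-probability formula
    requires a fully specified string.
    """
    seq = str(sequence).strip().upper()
    if not seq:
        raise MotifValidationError("empty motif")
    bad = sorted({c for c in seq if c not in model.alphabet})
    if bad:
        raise MotifValidationError(
            f"motif {seq!r} contains non-alphabet symbols {bad}"
        )
    return seq


def motif_probability(model: BackgroundModel, motif: "MotifQuery | str") -> float:
    """Window probability P(S) of the motif under the background model.

    Order 0 is the product of base frequencies over the motif's symbols;
    order 1 starts the chain from the stationary distribution.  A motif
    using a zero-frequency symbol yields exactly 0 (a degenerate input
    that callers must flag, never feed to the recurrence).
    """
    seq = motif.sequence if isinstance(motif, MotifQuery) else validate_motif(motif, model)
    if model.order == 0:
        # product over symbol counts, so anagrams get bit-identical P(S)
        p = 1.0
        for sym in model.alphabet:
            count = seq.count(sym)
            if count:
                p *= model.base_freqs[sym] ** count
        return p
    pi = stationary_distribution(model)
    idx = model.symbol_index()
    t = model.transition_matrix()
    p = pi[idx[seq[0]]]
    for a, b in zip(seq, seq[1:]):
        p *= t[idx[a], idx[b]]
    return float(p)


def stationary_distribution(model: BackgroundModel) -> np.ndarray:
    """Stationary symbol distribution of the model.

    Order 0: the base frequencies.  Order 1: the unique probability
    vector ``pi`` with ``pi @ T = pi``; raises
    :class:`NonErgodicChainError` when the eigenvalue 1 of the transition
    matrix is not simple (reducible chain).
    """
    if model.order == 0:
        return model.freq_array()
    t = model.transition_matrix()
    eigvals, eigvecs = np.linalg.eig(t.T)
    close = np.where(np.abs(eigvals - 1.0) < 1e-9)[0]
    if len(close) != 1:
        raise NonErgodicChainError(
            "transition matrix has no unique stationary distribution"
        )
    v = np.real(eigvecs[:, close[0]])
    pi = v / v.sum()
    if np.any(pi < -1e-12):
        raise NonErgodicChainError("stationary vector has negative entries")
    return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()


def stationary_occurrence_probability(
    model: BackgroundModel, motif: "MotifQuery | str"
) -> float:
    """Probability that the motif starts at an arbitrary stationary text
    position.  Coincides with :func:`motif_probability` under the
    stationary-start convention used throughout."""
    return motif_probability(model, motif)


def prefix_function(sequence: str) -> list[int]:
    """KMP prefix (border) array: ``pi[i]`` is the length of the longest
    proper border of ``sequence[: i + 1]``."""
    m = len(sequence)
    pi = [0] * m
    for i in range(1, m):
        j = pi[i - 1]
        while j > 0 and sequence[i] != sequence[j]:
            j = pi[j - 1]
        if sequence[i] == sequence[j]:
            j += 1
        pi[i] = j
    return pi


def is_clumpable(motif: str) -> bool:
    """True iff the motif has a non-trivial border, so occurrences can
    overlap ("clump")."""
    if not motif:
        raise MotifValidationError("empty motif")
    return prefix_function(motif)[-1] > 0


def _next_permutation(chars: list[str]) -> bool:
    """Advance ``chars`` to the next distinct permutation in lexicographic
    order, in place; returns False when already at the last one."""
    i = len(chars) - 2
    while i >= 0 and chars[i] >= chars[i + 1]:
        i -= 1
    if i < 0:
        return False
    j = len(chars) - 1
    while chars[j] <= chars[i]:
        j -= 1
    chars[i], chars[j] = chars[j], chars[i]
    chars[i + 1 :] = reversed(chars[i + 1 :])
    return True


#: cap on anagram candidates examined before falling back to end
#: replacement; a sorted string with >1 distinct symbol is itself
#: non-clumpable, so the very first candidate normally wins.
_ANAGRAM_SEARCH_CAP = 10_000


def non_clumpable_surrogate(
    motif: str, model: BackgroundModel
) -> tuple[str | None, str]:
    """Equal-probability non-clumpable stand-in for a clumpable motif.

    Searches distinct anagrams in lexicographic order first (an anagram
    has identical P(S) under any order-0 model); failing that, replaces
    the first or last symbol with a different symbol of equal base
    frequency.  Returns ``(surrogate, method)``; ``(None, "failed")``
    when neither strategy yields a non-clumpable string.
    """
    chars = sorted(motif)
    tried = 0
    while True:
        candidate = "".join(chars)
        if not is_clumpable(candidate):
            return candidate, "anagram"
        tried += 1
        if tried >= _ANAGRAM_SEARCH_CAP or not _next_permutation(chars):
            break

    freqs = model.base_freqs
    for pos in (0, len(motif) - 1):
        original = motif[pos]
        for sym in model.alphabet:
            if sym == original or freqs[sym] != freqs[original]:
                continue
            candidate = motif[:pos] + sym + motif[pos + 1 :]
            if not is_clumpable(candidate):
                return candidate, "end_replacement"
    return None, "failed"
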