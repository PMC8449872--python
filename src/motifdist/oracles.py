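"""Independent verification oracles and synthetic-fixture generators.

Two deliberately naive, mutually independent computations of the
occurrence-count distribution serve as referees for the production
formula:

* :func:`enumerate_all_texts_distribution` sums the probability of every
  possible text of length n, grouped by occurrence count — exact by
  construction, feasible only for k^n up to ~10^7;
* :func:`automaton_dp_distribution` runs a dynamic program over the
  motif's KMP matching automaton with the occurrence count as part of
  the state — exact and feasible at genome scale.

Both count *all* sliding-window occurrences, including overlapping ones;
for non-clumpable motifs this coincides with the formula's count, and
the clumpable case is retained to document where the formula does not
apply.

The fixture generators produce random genomes (FASTA) and motif lists
(one per line) from a seeded spec, byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .background import (
    BackgroundModel,
    DNA_ALPHABET,
    prefix_function,
    stationary_distribution,
)


class OracleGuardError(RuntimeError):
    """Requested oracle run exceeds its tractability guard."""


@dataclass(frozen=True)
class FixtureSpec:
    """Seeded description of a synthetic genome + motif-set fixture.

    Defaults mirror the study conditions used throughout: a random
    20,000-base genome and length-13 query motifs.
    """

    genome_length: int = 20_000
    base_freqs: Mapping[str, float] = field(
        default_factory=lambda: {s: 0.25 for s in DNA_ALPHABET}
    )
    motif_lengths: tuple[int, ...] = (13,)
    motif_count: int = 100
    seed: int = 0


def _encode(sequence: str, alphabet: Sequence[str]) -> np.ndarray:
    idx = {s: i for i, s in enumerate(alphabet)}
    return np.array([idx[c] for c in sequence], dtype=np.int64)


def enumerate_all_texts_distribution(
    model: BackgroundModel, motif: str, n: int
) -> dict[int, float]:
    """Ground-truth distribution by enumerating every length-n text.

    Per-text probabilities are double products; the per-count sums are
    accumulated in extended precision (long double), keeping the total
    error below ~1e-14.  Guarded at k^n <= 10^7.
    """
    k = len(model.alphabet)
    if k**n > 10_000_000:
        raise OracleGuardError(f"k^n = {k**n} exceeds the enumeration guard")
    m = len(motif)
    if n < m:
        return {0: 1.0}

    total = k**n
    # texts as a (k^n, n) code matrix, column i = digit i in base k
    cols = np.empty((total, n), dtype=np.int8)
    ar = np.arange(total)
    for i in range(n):
        cols[:, i] = (ar // k ** (n - 1 - i)) % k

    if model.order == 0:
        freqs = model.freq_array()
        weights = freqs[cols].prod(axis=1)
    else:
        start = stationary_distribution(model)
        t = model.transition_matrix()
        weights = start[cols[:, 0]].copy()
        for i in range(1, n):
            weights *= t[cols[:, i - 1], cols[:, i]]

    code = _encode(motif, model.alphabet)
    occ = np.zeros(total, dtype=np.int32)
    for pos in range(n - m + 1):
        window = cols[:, pos : pos + m]
        occ += (window == code).all(axis=1)

    out: dict[int, float] = {}
    for j in range(int(occ.max()) + 1):
        mass = np.sum(weights[occ == j], dtype=np.longdouble)
        if mass > 0:
            out[j] = float(mass)
    return out


def _match_automaton(motif_code: np.ndarray, k: int) -> np.ndarray:
    """KMP matching automaton: ``aut[q, c]`` is the next state from
    state q (length of prefix currently matched, 0..m) on symbol c.
    Entering state m signals one (possibly overlapping) occurrence."""
    m = len(motif_code)
    pi = prefix_function("".join(map(str, motif_code)))
    aut = np.zeros((m + 1, k), dtype=np.int64)
    for q in range(m + 1):
        for c in range(k):
            if q < m and c == motif_code[q]:
                aut[q, c] = q + 1
            elif q > 0:
                aut[q, c] = aut[pi[q - 1], c]
    return aut


def automaton_dp_distribution(
    model: BackgroundModel, motif: str, n: int, j_cap: int
) -> dict[int, float]:
    """Exact count distribution by dynamic programming over
    (automaton state, occurrence count), counts above ``j_cap`` pooled
    into an absorbing overflow bucket that is not reported.

    For order-1 backgrounds the state additionally carries the previous
    symbol.  Guarded at n * m * j_cap <= 10^9 steps.
    """
    m = len(motif)
    k = len(model.alphabet)
    if n * m * max(1, j_cap) > 1_000_000_000:
        raise OracleGuardError("DP step guard exceeded")
    if n < m:
        return {0: 1.0}
    code = _encode(motif, model.alphabet)
    aut = _match_automaton(code, k)
    J = j_cap + 2  # column j_cap + 1 absorbs overflow

    if model.order == 0:
        freqs = model.freq_array()
        V = np.zeros((m + 1, J))
        V[0, 0] = 1.0
        # per-symbol transition targets and emission flags, precomputed
        plans = []
        for c in range(k):
            tgt = aut[:, c]
            emit = tgt == m
            plans.append((tgt, np.nonzero(~emit)[0], np.nonzero(emit)[0], freqs[c]))
        for _ in range(n):
            NV = np.zeros_like(V)
            for tgt, quiet, hits, w in plans:
                src = V * w
                np.add.at(NV, tgt[quiet], src[quiet])
                if hits.size:
                    shifted = np.zeros_like(src[hits])
                    shifted[:, 1:] = src[hits, :-1]
                    shifted[:, -1] += src[hits, -1]
                    np.add.at(NV, tgt[hits], shifted)
            V = NV
        counts = V.sum(axis=0)
    else:
        start = stationary_distribution(model)
        t = model.transition_matrix()
        # state = (automaton state, previous symbol)
        V = np.zeros((m + 1, k, J))
        for c in range(k):  # first text symbol from the stationary law
            q = aut[0, c]
            if q == m:  # m == 1 edge case: immediate occurrence
                V[q, c, 1] += start[c]
            else:
                V[q, c, 0] += start[c]
        for _ in range(n - 1):
            NV = np.zeros_like(V)
            for prev in range(k):
                for c in range(k):
                    w = t[prev, c]
                    tgt = aut[:, c]
                    emit = tgt == m
                    src = V[:, prev, :] * w
                    quiet = np.nonzero(~emit)[0]
                    np.add.at(NV[:, c, :], tgt[quiet], src[quiet])
                    hits = np.nonzero(emit)[0]
                    if hits.size:
                        shifted = np.zeros_like(src[hits])
                        shifted[:, 1:] = src[hits, :-1]
                        shifted[:, -1] += src[hits, -1]
                        np.add.at(NV[:, c, :], tgt[hits], shifted)
            V = NV
        counts = V.sum(axis=(0, 1))

    return {j: float(counts[j]) for j in range(j_cap + 1)}


def random_genome(spec: FixtureSpec, fasta_path: str | Path | None = None) -> str:
    """Seeded i.i.d. genome at the spec's base frequencies; optionally
    written as a single-record FASTA."""
    if spec.genome_length <= 0:
        raise ValueError("genome_length must be positive")
    rng = np.random.default_rng(spec.seed)
    symbols = list(spec.base_freqs)
    probs = np.array([spec.base_freqs[s] for s in symbols], dtype=float)
    probs = probs / probs.sum()
    draw = rng.choice(len(symbols), size=spec.genome_length, p=probs)
    genome = "".join(symbols[i] for i in draw)
    if fasta_path is not None:
        freq_desc = ",".join(f"{s}={spec.base_freqs[s]:g}" for s in symbols)
        with open(fasta_path, "w") as fh:
            fh.write(
                f">synthetic_genome length={spec.genome_length} "
                f"freqs={freq_desc} seed={spec.seed}\n"
            )
            for i in range(0, len(genome), 70):
                fh.write(genome[i : i + 70] + "\n")
    return genome


def random_motif_set(
    spec: FixtureSpec, path: str | Path | None = None
) -> list[str]:
    """Seeded list of unique random motifs, cycling through the spec's
    motif lengths; optionally written one motif per line."""
    rng = np.random.default_rng(spec.seed + 1)
    symbols = list(spec.base_freqs)
    probs = np.array([spec.base_freqs[s] for s in symbols], dtype=float)
    probs = probs / probs.sum()
    motifs: list[str] = []
    seen: set[str] = set()
    i = 0
    while len(motifs) < spec.motif_count:
        length = spec.motif_lengths[i % len(spec.motif_lengths)]
        draw = rng.choice(len(symbols), size=length, p=probs)
        motif = "".join(symbols[c] for c in draw)
        if motif not in seen:
            seen.add(motif)
            motifs.append(motif)
            i += 1
    if path is not None:
        with open(path, "w") as fh:
            fh.write("\n".join(motifs) + "\n")
    return motifs
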