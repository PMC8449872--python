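"""Batch front end: read motifs and a background, run the distribution
engine per motif with per-motif fault isolation, write TSV outputs.

Outputs are two tab-separated files: a one-row-per-motif summary with
the clumpability flag, surrogate, P(S), expected count, convergence
diagnostics and status, and a long-format distribution file with one
(motif, j, probability) row per computed count.  Output is bit-stable
across runs on identical input.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .background import (
    BackgroundModel,
    MotifQuery,
    MotifValidationError,
    build_background,
    estimate_from_genome,
    motif_probability,
    stationary_occurrence_probability,
)
from .distribution import (
    ClumpableMotifError,
    ConvergenceError,
    CountDistribution,
    DegenerateMotifError,
    DistributionConfig,
    NumericalInstabilityError,
    count_distribution,
    expected_count,
    tail_pvalue,
)

logger = logging.getLogger("motifdist")


@dataclass
class ResultRecord:
    """One summary row per input motif.

    ``status`` is ``ok`` for a directly analysed motif, ``extrapolated``
    for a clumpable motif analysed through its surrogate (the value is
    not guaranteed given possible overlap — the flag is mandatory), and
    ``failed`` when no distribution could be produced (``message``
    says why; distribution fields are then absent).
    """

    motif: str
    m: int
    clumped: bool
    surrogate: str
    extrapolated: bool
    P_S: float | None
    expected_count: float | None
    stationary_prob: float | None
    n_epsilon: int | None
    R: float | None
    achieved_tolerance: float | None
    normalization_residual: float | None
    truncated: bool | None
    short_circuited: bool | None
    status: str
    message: str = ""
    observed: int | None = None
    p_ge: float | None = None
    p_le: float | None = None


SUMMARY_COLUMNS = [
    "motif",
    "m",
    "clumped",
    "surrogate",
    "extrapolated",
    "P_S",
    "expected_count",
    "stationary_prob",
    "n_epsilon",
    "R",
    "achieved_tolerance",
    "normalization_residual",
    "truncated",
    "short_circuited",
    "status",
    "message",
]
PVALUE_COLUMNS = ["observed", "p_ge", "p_le"]


def read_motifs(path: str | Path) -> list[str]:
    """Read a one-motif-per-line file: blank lines and ``#`` comments are
    skipped, motifs upper-cased.  Validation happens per motif in
    :func:`run_batch`, so invalid lines become failed records rather
    than aborting the batch."""
    motifs: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            motifs.append(line.upper())
    if not motifs:
        raise ValueError(f"no motifs found in {path}")
    return motifs


def parse_freq_spec(spec: str) -> dict[str, float]:
    """Parse a frequency string like ``A=0.25,C=0.25,G=0.25,T=0.25``."""
    freqs: dict[str, float] = {}
    for item in spec.split(","):
        if "=" not in item:
            raise ValueError(f"bad frequency item {item!r} in {spec!r}")
        sym, value = item.split("=", 1)
        freqs[sym.strip().upper()] = float(value)
    return freqs


def read_fasta_genome(path: str | Path) -> str:
    """Concatenate all records of a FASTA file into one genome string
    (junction-spanning bigrams are not counted in order-1 estimation
    because estimation sees a single concatenated text)."""
    parts = [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
    if not parts:
        raise ValueError(f"no FASTA records in {path}")
    return "".join(parts)


def resolve_background(
    genome_length: int | None = None,
    freqs: Mapping[str, float] | str | None = None,
    fasta: str | Path | None = None,
    order: int = 0,
) -> tuple[BackgroundModel, int]:
    """Build the background from exactly one source: explicit length +
    frequencies, or a FASTA genome (length and frequencies estimated)."""
    explicit = genome_length is not None or freqs is not None
    if explicit and fasta is not None:
        raise ValueError("give either length+frequencies or a FASTA file, not both")
    if fasta is not None:
        genome = read_fasta_genome(fasta)
        model, n = estimate_from_genome(genome, order=order)
        logger.info(
            "background from FASTA %s: n=%d, freqs=%s", fasta, n,
            {s: round(model.base_freqs[s], 4) for s in model.alphabet},
        )
        return model, n
    if genome_length is None or freqs is None:
        raise ValueError("need both a genome length and nucleotide frequencies")
    if isinstance(freqs, str):
        freqs = parse_freq_spec(freqs)
    if order == 1:
        raise ValueError(
            "order-1 background needs a FASTA genome to estimate transitions"
        )
    model = build_background(freqs, order=0)
    logger.info("background from explicit frequencies: n=%d", genome_length)
    return model, int(genome_length)


def _failed(motif: str, message: str, clumped: bool = False,
            surrogate: str = "") -> ResultRecord:
    return ResultRecord(
        motif=motif, m=len(motif), clumped=clumped, surrogate=surrogate,
        extrapolated=False, P_S=None, expected_count=None,
        stationary_prob=None, n_epsilon=None, R=None,
        achieved_tolerance=None, normalization_residual=None,
        truncated=None, short_circuited=None, status="failed",
        message=message,
    )


def analyze_motif(
    motif: str,
    model: BackgroundModel,
    n: int,
    config: DistributionConfig | None = None,
) -> tuple[ResultRecord, CountDistribution | None]:
    """Analyse one motif; clumpable motifs are routed through their
    surrogate and flagged ``extrapolated``.  Any failure is captured in
    the record, never raised."""
    config = config or DistributionConfig()
    try:
        query = MotifQuery.from_sequence(motif, model)
    except MotifValidationError as exc:
        return _failed(motif, str(exc)), None

    surrogate = ""
    if query.clumpable:
        if query.surrogate_method == "failed" or query.surrogate is None:
            return (
                _failed(query.sequence,
                        "clumpable motif with no non-clumpable surrogate",
                        clumped=True),
                None,
            )
        surrogate = query.surrogate

    target = query.analyzed_sequence
    try:
        target_query = MotifQuery.from_sequence(target, model)
        dist = count_distribution(model, target_query, n, config)
        p_s = motif_probability(model, target)
        stat = stationary_occurrence_probability(model, target)
    except (DegenerateMotifError, ConvergenceError,
            NumericalInstabilityError, ClumpableMotifError) as exc:
        return _failed(query.sequence, str(exc), clumped=query.clumpable,
                       surrogate=surrogate), None

    series = dist.series
    record = ResultRecord(
        motif=query.sequence,
        m=query.m,
        clumped=query.clumpable,
        surrogate=surrogate,
        extrapolated=query.clumpable,
        P_S=p_s,
        expected_count=dist.expected_count,
        stationary_prob=stat,
        n_epsilon=series.n_epsilon if series is not None else None,
        R=series.ratio if series is not None else None,
        achieved_tolerance=series.achieved_tolerance if series is not None else None,
        normalization_residual=dist.normalization_residual,
        truncated=dist.truncated,
        short_circuited=dist.mode_short_circuited,
        status="extrapolated" if query.clumpable else "ok",
    )
    return record, dist


def run_batch(
    motifs: Sequence[str],
    model: BackgroundModel,
    n: int,
    config: DistributionConfig | None = None,
    observed_counts: Mapping[str, int] | None = None,
) -> list[tuple[ResultRecord, CountDistribution | None]]:
    """Analyse a batch of motifs independently; one output row per input
    motif, failed ones included.  When observed counts are supplied the
    matching records gain raw (uncorrected) tail p-values."""
    config = config or DistributionConfig()
    results: list[tuple[ResultRecord, CountDistribution | None]] = []
    tally = {"ok": 0, "extrapolated": 0, "failed": 0}
    for motif in motifs:
        record, dist = analyze_motif(motif, model, n, config)
        if (
            observed_counts is not None
            and dist is not None
            and record.motif in observed_counts
        ):
            obs = int(observed_counts[record.motif])
            record.observed = obs
            record.p_ge, record.p_le = tail_pvalue(dist, obs)
        tally[record.status] += 1
        results.append((record, dist))
    logger.info(
        "batch done: %d motifs (%d ok, %d extrapolated, %d failed)",
        len(results), tally["ok"], tally["extrapolated"], tally["failed"],
    )
    return results


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return f"{value:.12g}"
    return str(value)


def write_results(
    results: Iterable[tuple[ResultRecord, CountDistribution | None]],
    out_prefix: str | Path,
    with_pvalues: bool = False,
) -> tuple[Path, Path]:
    """Write ``<prefix>_summary.tsv`` (one record per row, floats at 12
    significant digits) and ``<prefix>_distribution.tsv`` (long format:
    motif, j, probability).  Returns the two paths."""
    results = list(results)
    if not results:
        raise ValueError("no results to write")
    prefix = Path(out_prefix)
    summary_path = prefix.parent / (prefix.name + "_summary.tsv")
    dist_path = prefix.parent / (prefix.name + "_distribution.tsv")
    columns = SUMMARY_COLUMNS + (PVALUE_COLUMNS if with_pvalues else [])

    with open(summary_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(columns)
        for record, _ in results:
            writer.writerow([_fmt(getattr(record, col)) for col in columns])

    with open(dist_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["motif", "j", "probability"])
        for record, dist in results:
            if dist is None:
                continue
            for j in sorted(dist.probs):
                writer.writerow([record.motif, j, _fmt(dist.probs[j])])

    return summary_path, dist_path


def read_observed_counts(path: str | Path) -> dict[str, int]:
    """Read a two-column TSV of motif and observed count; a header row
    (``motif<TAB>count``) is optional."""
    observed: dict[str, int] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"bad observed-counts line {line_no + 1}: {line!r}")
            if line_no == 0 and not parts[1].strip().isdigit():
                continue  # header
            observed[parts[0].strip().upper()] = int(parts[1])
    return observed
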