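"""Batch matching: word lists, FASTA input, TSV reports and k-sweeps.

A :class:`MatchJob` bundles the string pairs, metric, engine and
threshold of one batch run; :func:`run_match_batch` produces one
:class:`ReportRow` per pair, deterministically, and :func:`sweep_k`
re-runs the same pair set over a ladder of thresholds to chart how the
skipped-work ratio falls as ``k`` grows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from Bio import SeqIO

from gedmatch.cost_models import MetricSpec
from gedmatch.engines import ENGINES, run_engine

__all__ = [
    "MatchJob",
    "ReportRow",
    "SweepResult",
    "read_wordlist",
    "read_fasta",
    "run_match_batch",
    "write_report",
    "sweep_k",
    "write_sweep",
]

log = logging.getLogger(__name__)

REPORT_COLUMNS = (
    "input_id",
    "pattern_id",
    "input_len",
    "pattern_len",
    "matched",
    "distance",
    "computed_cells",
    "skipped_cells",
    "skipped_insertion_ops",
    "skipped_operator_evals",
    "skip_ratio",
)


@dataclass
class ReportRow:
    """One line of the batch report; columns as in ``REPORT_COLUMNS``."""

    input_id: str
    pattern_id: str
    input_len: int
    pattern_len: int
    matched: bool
    distance: float
    computed_cells: int
    skipped_cells: int
    skipped_insertion_ops: int
    skipped_operator_evals: int
    skip_ratio: float

    def to_tsv(self) -> str:
        distance = "OVER_K" if math.isinf(self.distance) else f"{self.distance:g}"
        return "\t".join(
            [
                self.input_id,
                self.pattern_id,
                str(self.input_len),
                str(self.pattern_len),
                "1" if self.matched else "0",
                distance,
                str(self.computed_cells),
                str(self.skipped_cells),
                str(self.skipped_insertion_ops),
                str(self.skipped_operator_evals),
                f"{self.skip_ratio:.6f}",
            ]
        )


@dataclass
class MatchJob:
    """Everything one batch run needs.

    ``pairs`` holds ``(input_id, input, pattern_id, pattern)`` tuples.
    ``cross_check_fraction`` > 0 re-runs that share of rows (at least one)
    through the vertical reference engine and raises if any match
    decision disagrees.
    """

    pairs: Sequence[tuple[str, str, str, str]]
    metric: MetricSpec = field(default_factory=lambda: MetricSpec("levenshtein"))
    engine: str = "diag-skip"
    k: float = 2.0
    case_fold: bool = True
    cross_check_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.engine not in ENGINES:
            raise ValueError(f"unknown engine {self.engine!r}; valid: {', '.join(ENGINES)}")
        for input_id, _, pattern_id, _ in self.pairs:
            if not input_id or not pattern_id:
                raise ValueError("every pair needs nonempty input and pattern identifiers")


def read_wordlist(path: Union[str, Path], case_fold: bool = True) -> list[tuple[str, str]]:
    """One token per line; ids are 1-based line numbers; blank lines skipped."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"word list not found: {path}")
    entries: list[tuple[str, str]] = []
    with path.open(encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            word = raw.strip()
            if not word:
                continue
            entries.append((str(lineno), word.lower() if case_fold else word))
    if not entries:
        log.warning("word list %s is empty", path)
    return entries


def read_fasta(path: Union[str, Path], case_fold: bool = True) -> list[tuple[str, str]]:
    """FASTA records as (header token, sequence); wrapped lines concatenated."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    entries: list[tuple[str, str]] = []
    for index, record in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        if not record.id:
            raise ValueError(f"{path}: record {index} has an empty header")
        seq = str(record.seq)
        entries.append((record.id, seq.lower() if case_fold else seq))
    if not entries:
        log.warning("FASTA file %s has no records", path)
    return entries


def _run_pair(
    X: str, Y: str, k: float, metric: MetricSpec, engine: str
) -> ReportRow:
    model = metric.build(Y)
    result = run_engine(X, Y, k, model, engine=engine)
    stats = result.stats
    return ReportRow(
        input_id="",
        pattern_id="",
        input_len=len(X),
        pattern_len=len(Y),
        matched=result.matched,
        distance=result.distance,
        computed_cells=stats.computed_cells,
        skipped_cells=stats.skipped_cells,
        skipped_insertion_ops=stats.skipped_insertion_ops,
        skipped_operator_evals=stats.skipped_operator_evals,
        skip_ratio=stats.combined_skip_ratio,
    )


def run_match_batch(job: MatchJob) -> list[ReportRow]:
    """One report row per pair, in input order, deterministic for a job."""
    rows: list[ReportRow] = []
    for input_id, X, pattern_id, Y in job.pairs:
        if job.case_fold:
            X, Y = X.lower(), Y.lower()
        row = _run_pair(X, Y, job.k, job.metric, job.engine)
        row.input_id, row.pattern_id = input_id, pattern_id
        rows.append(row)
    if job.cross_check_fraction > 0 and rows:
        _cross_check(job, rows)
    log.info(
        "batch: %d pairs, engine=%s, k=%g, match rate %.3f",
        len(rows),
        job.engine,
        job.k,
        sum(r.matched for r in rows) / len(rows) if rows else 0.0,
    )
    return rows


def _cross_check(job: MatchJob, rows: list[ReportRow]) -> None:
    """Re-run a sample of rows through the vertical reference engine."""
    rng = np.random.default_rng(job.seed)
    n_sample = max(1, int(round(job.cross_check_fraction * len(rows))))
    for idx in rng.choice(len(rows), size=min(n_sample, len(rows)), replace=False):
        input_id, X, pattern_id, Y = job.pairs[idx]
        if job.case_fold:
            X, Y = X.lower(), Y.lower()
        reference = _run_pair(X, Y, job.k, job.metric, "vertical")
        if reference.matched != rows[idx].matched:
            raise AssertionError(
                f"engine {job.engine!r} disagrees with vertical reference on "
                f"pair ({input_id}, {pattern_id})"
            )


def write_report(rows: Iterable[ReportRow], path: Union[str, Path], aggregate: bool = False) -> None:
    """TSV report; with ``aggregate`` a mean-skip-ratio comment line is appended."""
    rows = list(rows)
    with Path(path).open("w", encoding="utf-8") as handle:
        handle.write("\t".join(REPORT_COLUMNS) + "\n")
        for row in rows:
            handle.write(row.to_tsv() + "\n")
        if aggregate and rows:
            mean_ratio = sum(r.skip_ratio for r in rows) / len(rows)
            handle.write(f"# mean_skip_ratio\t{mean_ratio:.6f}\n")


@dataclass
class SweepResult:
    """Per-k summary rows plus the monotonicity flag of the skip ratio."""

    rows: list[dict]
    ratios_nonincreasing: bool


def sweep_k(job: MatchJob, k_values: Sequence[float]) -> SweepResult:
    """Re-run the identical pair set at each threshold in ``k_values``.

    Each summary row reports the mean combined skip ratio, the mean of
    the real (not over-threshold) distances, and the match rate.  The
    flag records whether the skip ratio was non-increasing in ``k``.
    """
    if not job.pairs:
        raise ValueError("sweep needs at least one pair")
    if not k_values:
        raise ValueError("sweep needs at least one k value")
    summary: list[dict] = []
    for k in k_values:
        rows = run_match_batch(
            MatchJob(
                pairs=job.pairs,
                metric=job.metric,
                engine=job.engine,
                k=k,
                case_fold=job.case_fold,
                seed=job.seed,
            )
        )
        finite = [r.distance for r in rows if math.isfinite(r.distance)]
        summary.append(
            {
                "k": k,
                "mean_skip_ratio": sum(r.skip_ratio for r in rows) / len(rows),
                "mean_distance": sum(finite) / len(finite) if finite else math.nan,
                "match_rate": sum(r.matched for r in rows) / len(rows),
            }
        )
    ratios = [row["mean_skip_ratio"] for row in summary]
    nonincreasing = all(a >= b - 1e-12 for a, b in zip(ratios, ratios[1:]))
    return SweepResult(rows=summary, ratios_nonincreasing=nonincreasing)


def write_sweep(result: SweepResult, path: Union[str, Path]) -> None:
    with Path(path).open("w", encoding="utf-8") as handle:
        handle.write("k\tmean_skip_ratio\tmean_distance\tmatch_rate\n")
        for row in result.rows:
            mean_distance = "NA" if math.isnan(row["mean_distance"]) else f"{row['mean_distance']:.6f}"
            handle.write(
                f"{row['k']:g}\t{row['mean_skip_ratio']:.6f}\t{mean_distance}\t{row['match_rate']:.6f}\n"
            )
        handle.write(
            f"# skip_ratio_nonincreasing\t{'true' if result.ratios_nonincreasing else 'false'}\n"
        )
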