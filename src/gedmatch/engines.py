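"""Edit-distance engines: full dynamic programming and k-mismatch variants.

The distance between input ``X`` (length *i*) and pattern ``Y`` (length
*j*) is computed over an ``(i+1) x (j+1)`` matrix ``D`` whose cell
``D[a][b]`` holds the weighted edit distance between the length-*a* prefix
of ``X`` and the length-*b* prefix of ``Y``::

    D[a][b] = min( D[a-1][b-1] + substitution(x_a, y_b),
                   D[a-1][b]   + deletion(x_a),
                   D[a][b-1]   + insertion(y_b) )

Five engines fill this matrix with different traversal orders and pruning
strategies:

``vertical``
    Plain DP, column by column — the reference engine.
``diagonal``
    Plain DP over anti-diagonals (cells with constant ``a + b``), upper
    right before lower left; cell values identical to ``vertical``.
``cellwise``
    Thresholded DP in vertical order: an operator is only evaluated when
    its predecessor cell is within the threshold ``k``.
``diag-skip``
    Anti-diagonal traversal with a *pruning register*: one bit per
    pattern column.  Once a column's bit is set, every remaining cell in
    that column (and, by the register's monotone-prefix structure, in all
    columns to its left) is known to exceed ``k``, so the traversal
    `break`s out and skips them wholesale without reading the matrix.
``diag-skip2``
    ``diag-skip`` plus per-operator predecessor checks against ``k``,
    trading extra comparisons for fewer cost-function evaluations.

Thresholded engines guarantee: every cell value ``<= k`` is the exact
distance; skipped or over-threshold cells have true distance ``> k``.
Cells that were never computed hold the ``OVER_K`` sentinel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from gedmatch.cost_models import CostModel

__all__ = [
    "OVER_K",
    "DistanceMatrix",
    "PruningRegister",
    "EngineStats",
    "MatchResult",
    "ENGINES",
    "full_distance_vertical",
    "full_distance_diagonal",
    "kmismatch_cellwise",
    "kmismatch_diagonal_skip",
    "decide_match",
    "compute_skip_stats",
    "run_engine",
]

#: Sentinel stored in matrix cells whose distance was never computed
#: because it provably exceeds the threshold.  Compares greater than any
#: real distance; never fed into cost arithmetic.
OVER_K: float = math.inf

ENGINES = ("vertical", "cellwise", "diagonal", "diag-skip", "diag-skip2")


class DistanceMatrix:
    """The ``(i+1) x (j+1)`` grid of prefix distances.

    Row index = input prefix length, column index = pattern prefix length;
    ``self[0, 0] == 0``.  Cells skipped by a thresholded engine hold
    :data:`OVER_K`.
    """

    def __init__(self, X: str, Y: str) -> None:
        self.X = X
        self.Y = Y
        self.values = np.full((len(X) + 1, len(Y) + 1), OVER_K, dtype=float)
        self.values[0, 0] = 0.0

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def distance(self) -> float:
        """Bottom-right cell: the (possibly over-threshold) final distance."""
        return float(self.values[-1, -1])

    def __getitem__(self, idx: tuple[int, int]) -> float:
        return float(self.values[idx])

    def init_boundaries(self, model: CostModel) -> None:
        """Fill row 0 with cumulative insertions, column 0 with deletions."""
        for a in range(1, self.n_rows):
            self.values[a, 0] = self.values[a - 1, 0] + model.deletion(self.X[a - 1])
        for b in range(1, self.n_cols):
            self.values[0, b] = self.values[0, b - 1] + model.insertion(self.Y[b - 1])

    def to_tsv(self) -> str:
        """Render with prefix-character headers; skipped cells print as INF."""
        header = "\t".join(["", "-"] + list(self.Y))
        lines = [header]
        for a in range(self.n_rows):
            label = "-" if a == 0 else self.X[a - 1]
            cells = [
                "INF" if math.isinf(v) else f"{v:g}" for v in self.values[a]
            ]
            lines.append("\t".join([label] + cells))
        return "\n".join(lines) + "\n"


class PruningRegister:
    """One skip bit per pattern column, with a monotone-prefix invariant.

    ``bits[b] == 1`` asserts that every not-yet-computed cell of column
    ``b`` exceeds the threshold.  Bit 0 (the boundary column) starts set;
    a bit may only be set when its left neighbour already is, so the set
    bits always form a prefix ``0..b``.
    """

    def __init__(self, n_cols: int) -> None:
        if n_cols < 1:
            raise ValueError("register needs at least the boundary column")
        self.bits = [False] * n_cols
        self.bits[0] = True

    def __getitem__(self, b: int) -> bool:
        return self.bits[b]

    def __len__(self) -> int:
        return len(self.bits)

    def set(self, b: int) -> None:
        if b >= 1 and not self.bits[b - 1]:
            raise ValueError(f"setting bit {b} would break the monotone prefix")
        self.bits[b] = True

    @property
    def is_monotone_prefix(self) -> bool:
        seen_zero = False
        for bit in self.bits:
            if bit and seen_zero:
                return False
            seen_zero = seen_zero or not bit
        return True


@dataclass
class EngineStats:
    """Operation counts from one engine run.

    ``skipped_cells`` are interior cells never visited (traversal break or
    early termination); ``skipped_insertion_ops`` counts insertion
    operators dropped because the register marked the left column;
    ``skipped_operator_evals`` counts operators dropped by per-predecessor
    threshold checks (cellwise and ``diag-skip2``).
    """

    n_interior: int = 0
    computed_cells: int = 0
    skipped_cells: int = 0
    skipped_insertion_ops: int = 0
    skipped_operator_evals: int = 0

    @property
    def combined_skip_ratio(self) -> float:
        """Fraction of the 3 operator evaluations per interior cell avoided.

        A fully skipped cell avoids all 3 of its operator evaluations, a
        register-dropped insertion or a predecessor-checked operator
        avoids 1, so the ratio is
        ``(3*skipped_cells + skipped_insertion_ops + skipped_operator_evals)
        / (3 * i * j)`` — 0 when nothing was pruned, 0 for degenerate
        (empty-string) problems.
        """
        if self.n_interior == 0:
            return 0.0
        avoided = (
            3 * self.skipped_cells
            + self.skipped_insertion_ops
            + self.skipped_operator_evals
        )
        return avoided / (3 * self.n_interior)


@dataclass
class MatchResult:
    """Outcome of one k-mismatch run.

    ``matched`` iff ``distance`` is a real value ``<= k``.  For thresholded
    engines an unmatched ``distance`` is either :data:`OVER_K` or an upper
    bound on the true distance; matched distances are exact.
    """

    matched: bool
    distance: float
    k: float
    engine: str
    stats: EngineStats
    matrix: Optional[DistanceMatrix] = None
    register: Optional[PruningRegister] = None


# ---------------------------------------------------------------------------
# full-matrix engines
# ---------------------------------------------------------------------------


def _cell_min(D: np.ndarray, a: int, b: int, X: str, Y: str, model: CostModel) -> float:
    x, y = X[a - 1], Y[b - 1]
    return min(
        D[a - 1, b - 1] + model.substitution(x, y),
        D[a - 1, b] + model.deletion(x),
        D[a, b - 1] + model.insertion(y),
    )


def full_distance_vertical(X: str, Y: str, model: CostModel) -> DistanceMatrix:
    """Complete DP matrix, filled column by column (top to bottom)."""
    matrix = DistanceMatrix(X, Y)
    matrix.init_boundaries(model)
    D = matrix.values
    for b in range(1, len(Y) + 1):
        for a in range(1, len(X) + 1):
            D[a, b] = _cell_min(D, a, b, X, Y, model)
    return matrix


def full_distance_diagonal(X: str, Y: str, model: CostModel) -> DistanceMatrix:
    """Complete DP matrix, filled along anti-diagonals ``a + b = t``.

    Within a traversal the upper-right cell (smallest row index) comes
    first; results are cell-for-cell identical to the vertical engine.
    """
    matrix = DistanceMatrix(X, Y)
    matrix.init_boundaries(model)
    D = matrix.values
    i, j = len(X), len(Y)
    for t in range(2, i + j + 1):
        for a in range(max(1, t - j), min(i, t - 1) + 1):
            D[a, t - a] = _cell_min(D, a, t - a, X, Y, model)
    return matrix


# ---------------------------------------------------------------------------
# k-mismatch engines
# ---------------------------------------------------------------------------


def _check_k(k: float) -> None:
    if k < 0:
        raise ValueError(f"threshold k must be >= 0, got {k}")


def kmismatch_cellwise(
    X: str, Y: str, k: float, model: CostModel, keep_matrix: bool = False
) -> MatchResult:
    """Thresholded DP in vertical order with per-operator predecessor checks.

    Each of the three operator terms is evaluated only when its
    predecessor cell is ``<= k``; a cell with no admissible predecessor
    becomes :data:`OVER_K`.  Every interior cell is still visited.
    """
    _check_k(k)
    matrix = DistanceMatrix(X, Y)
    matrix.init_boundaries(model)
    D = matrix.values
    i, j = len(X), len(Y)
    stats = EngineStats(n_interior=i * j)
    for b in range(1, j + 1):
        y = Y[b - 1]
        for a in range(1, i + 1):
            x = X[a - 1]
            best = OVER_K
            if D[a - 1, b - 1] <= k:
                best = D[a - 1, b - 1] + model.substitution(x, y)
            else:
                stats.skipped_operator_evals += 1
            if D[a - 1, b] <= k:
                best = min(best, D[a - 1, b] + model.deletion(x))
            else:
                stats.skipped_operator_evals += 1
            if D[a, b - 1] <= k:
                best = min(best, D[a, b - 1] + model.insertion(y))
            else:
                stats.skipped_operator_evals += 1
            D[a, b] = best
            stats.computed_cells += 1
    final = matrix.distance
    matched = math.isfinite(final) and final <= k
    return MatchResult(
        matched=matched,
        distance=final,
        k=k,
        engine="cellwise",
        stats=stats,
        matrix=matrix if keep_matrix else None,
    )


def kmismatch_diagonal_skip(
    X: str,
    Y: str,
    k: float,
    model: CostModel,
    variant: Union[str, int] = "I",
    keep_matrix: bool = False,
    early_stop: Optional[bool] = None,
) -> MatchResult:
    """Anti-diagonal thresholded DP with the pruning register.

    Traversal ``t`` visits cells ``(a, b)`` with ``a + b = t`` in
    decreasing-column order.  At each cell:

    1. If the register bit for column ``b`` is set, the rest of the
       traversal (this cell and everything lower-left of it) is skipped.
    2. If ``b == 1`` or the bit for column ``b - 1`` is clear, the full
       three-way minimum is taken (column 0 always holds valid boundary
       values, hence the ``b == 1`` exception); otherwise the insertion
       predecessor lies in a pruned column and only the deletion and
       substitution terms are evaluated.
    3. If the new value exceeds ``k`` while the left column's bit is set,
       column ``b``'s bit is set too — extending the pruned prefix.

    Variant ``"II"`` additionally tests every individual predecessor
    against ``k`` before evaluating its operator; a cell with no
    admissible operator becomes :data:`OVER_K`.

    With ``early_stop`` (default: on unless ``keep_matrix``) the run ends
    as soon as the last column's bit is set — no cell of the final column
    can come in under ``k``, so the pair cannot match.
    """
    _check_k(k)
    variant = {1: "I", 2: "II", "1": "I", "2": "II"}.get(variant, str(variant))
    if variant not in ("I", "II"):
        raise ValueError(f"variant must be I or II, got {variant!r}")
    per_op_checks = variant == "II"
    if early_stop is None:
        early_stop = not keep_matrix

    matrix = DistanceMatrix(X, Y)
    matrix.init_boundaries(model)
    D = matrix.values
    i, j = len(X), len(Y)
    register = PruningRegister(j + 1)
    stats = EngineStats(n_interior=i * j)

    for t in range(2, i + j + 1):
        for a in range(max(1, t - j), min(i, t - 1) + 1):
            b = t - a
            if register[b]:
                break  # rest of this traversal is over k
            x, y = X[a - 1], Y[b - 1]
            best = OVER_K

            sub_pred = D[a - 1, b - 1]
            if per_op_checks and not sub_pred <= k:
                stats.skipped_operator_evals += 1
            elif math.isfinite(sub_pred):
                best = sub_pred + model.substitution(x, y)

            del_pred = D[a - 1, b]
            if per_op_checks and not del_pred <= k:
                stats.skipped_operator_evals += 1
            elif math.isfinite(del_pred):
                best = min(best, del_pred + model.deletion(x))

            if b == 1 or not register[b - 1]:
                ins_pred = D[a, b - 1]
                if per_op_checks and not ins_pred <= k:
                    stats.skipped_operator_evals += 1
                elif math.isfinite(ins_pred):
                    best = min(best, ins_pred + model.insertion(y))
            else:
                stats.skipped_insertion_ops += 1

            D[a, b] = best
            stats.computed_cells += 1
            if best > k and register[b - 1]:
                register.set(b)
        if early_stop and register[j]:
            break

    stats.skipped_cells = i * j - stats.computed_cells
    final = matrix.distance
    matched = math.isfinite(final) and final <= k
    return MatchResult(
        matched=matched,
        distance=final,
        k=k,
        engine="diag-skip" if variant == "I" else "diag-skip2",
        stats=stats,
        matrix=matrix if keep_matrix else None,
        register=register,
    )


# ---------------------------------------------------------------------------
# decisions, statistics, dispatch
# ---------------------------------------------------------------------------


def decide_match(matrix_or_result: Union[DistanceMatrix, MatchResult, float], k: float) -> bool:
    """True iff the final distance is a real value ``<= k``.

    The :data:`OVER_K` sentinel never matches.
    """
    if isinstance(matrix_or_result, MatchResult):
        value = matrix_or_result.distance
    elif isinstance(matrix_or_result, DistanceMatrix):
        value = matrix_or_result.distance
    else:
        value = float(matrix_or_result)
    return math.isfinite(value) and value <= k


def compute_skip_stats(run: Union[MatchResult, EngineStats]) -> EngineStats:
    """Extract the skip-accounting statistics of an engine run.

    Returns the :class:`EngineStats` whose ``combined_skip_ratio`` is the
    fraction of per-cell operator evaluations that were avoided.
    """
    stats = run.stats if isinstance(run, MatchResult) else run
    if stats.computed_cells + stats.skipped_cells != stats.n_interior:
        raise ValueError("inconsistent run record: cells do not sum to i*j")
    return stats


def run_engine(
    X: str,
    Y: str,
    k: float,
    model: CostModel,
    engine: str = "diag-skip",
    keep_matrix: bool = False,
) -> MatchResult:
    """Run the named engine and return a uniform :class:`MatchResult`.

    ``vertical`` and ``diagonal`` compute the full matrix and threshold
    its final cell; the other engines prune.  Valid names: ``vertical``,
    ``cellwise``, ``diagonal``, ``diag-skip``, ``diag-skip2``.
    """
    _check_k(k)
    if engine in ("vertical", "diagonal"):
        fill = full_distance_vertical if engine == "vertical" else full_distance_diagonal
        matrix = fill(X, Y, model)
        stats = EngineStats(n_interior=len(X) * len(Y), computed_cells=len(X) * len(Y))
        return MatchResult(
            matched=decide_match(matrix, k),
            distance=matrix.distance,
            k=k,
            engine=engine,
            stats=stats,
            matrix=matrix if keep_matrix else None,
        )
    if engine == "cellwise":
        return kmismatch_cellwise(X, Y, k, model, keep_matrix=keep_matrix)
    if engine == "diag-skip":
        return kmismatch_diagonal_skip(X, Y, k, model, variant="I", keep_matrix=keep_matrix)
    if engine == "diag-skip2":
        return kmismatch_diagonal_skip(X, Y, k, model, variant="II", keep_matrix=keep_matrix)
    raise ValueError(f"unknown engine {engine!r}; valid: {', '.join(ENGINES)}")
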