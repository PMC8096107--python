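"""Operator cost models for the generalized edit distance.

A cost model is the triple of functions that price the three edit
operators: ``substitution(x, y)``, ``deletion(x)`` and ``insertion(y)``.
The classic Levenshtein metric is the special case where every operator
costs 1 (0 for substituting a character by itself).  The models shipped
here generalize that in the ways a spell checker or sequence matcher
cares about:

``unit_cost_model``
    Levenshtein costs; the baseline metric.
``shape_cost_model``
    Substitution cost inversely proportional to the visual similarity of
    the two glyphs (``C / s(x, y)``), with indel cost an exponential
    function of the pattern length: short patterns pay more for a missing
    character than long ones.
``keyboard_cost_model``
    Substitution cost proportional to the Euclidean distance between the
    two keys on a physical keyboard layout, so adjacent-key typos are
    cheap.
``table_cost_model``
    Arbitrary user-supplied substitution table with constant or per-char
    indel costs.

All shipped models have symmetric substitution, ``substitution(x, x) == 0``
and strictly positive indel costs, so the unit and keyboard metrics are
true distances; the shape metric's indel cost depends on the pattern
length and is therefore asymmetric in its two arguments, by design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Union

__all__ = [
    "CostModel",
    "SimilarityTable",
    "KeyboardLayout",
    "MetricSpec",
    "unit_cost_model",
    "shape_cost_model",
    "keyboard_cost_model",
    "table_cost_model",
    "load_cost_table",
    "save_cost_table",
    "load_keyboard_layout",
    "qwerty_layout",
    "metric_spec_from_config",
]

PairKey = tuple[str, str]


def _pair_key(a: str, b: str) -> PairKey:
    """Canonical unordered key for a character pair."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class CostModel:
    """The triple of operator cost functions defining an edit metric.

    Parameters
    ----------
    name:
        Human-readable label, also used for CLI selection.
    substitution:
        ``(x, y) -> cost >= 0``; must be 0 when ``x == y``.
    deletion, insertion:
        ``(x,) -> cost > 0``.
    params:
        Free-form map of the parameters the model was built with
        (scaling factor, average length, pattern length, ...), kept for
        reporting and reproducibility.
    """

    name: str
    substitution: Callable[[str, str], float]
    deletion: Callable[[str], float]
    insertion: Callable[[str], float]
    params: Mapping[str, object] = field(default_factory=dict)

    def validate(self, alphabet: Iterable[str]) -> None:
        """Check the cost-model axioms on every character pair of *alphabet*.

        Raises ``ValueError`` on the first violated axiom.  Intended for
        user-supplied tables; the shipped constructors already guarantee
        these properties.
        """
        chars = list(alphabet)
        for x in chars:
            if self.substitution(x, x) != 0:
                raise ValueError(f"substitution({x!r}, {x!r}) must be 0")
            dx, ix = self.deletion(x), self.insertion(x)
            if not (dx > 0 and math.isfinite(dx)):
                raise ValueError(f"deletion({x!r}) must be finite and > 0")
            if not (ix > 0 and math.isfinite(ix)):
                raise ValueError(f"insertion({x!r}) must be finite and > 0")
            for y in chars:
                s = self.substitution(x, y)
                if not (s >= 0 and math.isfinite(s)):
                    raise ValueError(f"substitution({x!r}, {y!r}) must be finite and >= 0")
                if s != self.substitution(y, x):
                    raise ValueError(f"substitution not symmetric on ({x!r}, {y!r})")


@dataclass
class SimilarityTable:
    """Pairwise character similarity scores ``s(x, y) > 0``.

    Lookup is order-independent.  Pairs absent from the table fall back to
    ``default_similarity``; when that is ``None`` the *smallest* similarity
    present is used, which translates into the largest substitution cost —
    the conservative choice for unknown pairs.
    """

    entries: dict[PairKey, float] = field(default_factory=dict)
    default_similarity: float | None = None

    def __post_init__(self) -> None:
        normalized: dict[PairKey, float] = {}
        for (a, b), score in self.entries.items():
            if not (score > 0 and math.isfinite(score)):
                raise ValueError(f"similarity for ({a!r}, {b!r}) must be finite and > 0, got {score}")
            key = _pair_key(a, b)
            if key in normalized and normalized[key] != score:
                raise ValueError(f"conflicting similarity entries for pair {key}")
            normalized[key] = score
        self.entries = normalized
        if self.default_similarity is not None and not self.default_similarity > 0:
            raise ValueError("default_similarity must be > 0")

    def lookup(self, a: str, b: str, strict: bool = False) -> float:
        key = _pair_key(a, b)
        if key in self.entries:
            return self.entries[key]
        if strict:
            raise KeyError(f"character pair {key} not in similarity table")
        if self.default_similarity is not None:
            return self.default_similarity
        if self.entries:
            return min(self.entries.values())
        return 1.0

    @classmethod
    def from_tsv(cls, path: Union[str, Path], default_similarity: float | None = None) -> "SimilarityTable":
        return cls(entries=load_cost_table(path), default_similarity=default_similarity)


@dataclass
class KeyboardLayout:
    """Planar key coordinates, in key-pitch units (adjacent keys ~1 apart)."""

    coords: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        seen: dict[tuple[float, float], str] = {}
        for ch, xy in self.coords.items():
            if xy in seen:
                raise ValueError(f"keys {seen[xy]!r} and {ch!r} share coordinate {xy}")
            seen[xy] = ch

    def distance(self, a: str, b: str) -> float:
        ax, ay = self.coords[a]
        bx, by = self.coords[b]
        return math.hypot(ax - bx, ay - by)

    def max_distance(self) -> float:
        keys = list(self.coords)
        return max(
            (self.distance(a, b) for i, a in enumerate(keys) for b in keys[i + 1 :]),
            default=0.0,
        )

    def mean_distance(self) -> float:
        keys = list(self.coords)
        dists = [self.distance(a, b) for i, a in enumerate(keys) for b in keys[i + 1 :]]
        return sum(dists) / len(dists) if dists else 0.0


# ---------------------------------------------------------------------------
# shipped model constructors
# ---------------------------------------------------------------------------


def unit_cost_model() -> CostModel:
    """Levenshtein costs: every operator costs 1, substituting x by x costs 0."""
    return CostModel(
        name="levenshtein",
        substitution=lambda x, y: 0.0 if x == y else 1.0,
        deletion=lambda x: 1.0,
        insertion=lambda y: 1.0,
        params={},
    )


def indel_cost_for_length(average_length: float, pattern_length: int) -> float:
    """Length-weighted indel cost ``exp(average_length / j) / exp(1)``.

    Equals 1 when the pattern has average length, grows for shorter
    patterns (a dropped character hurts a short word more) and decays
    toward ``1/e`` as the pattern length grows without bound.
    """
    if average_length <= 0:
        raise ValueError("average_length must be > 0")
    if pattern_length < 1:
        raise ValueError("pattern_length must be >= 1")
    return math.exp(average_length / pattern_length) / math.e


def shape_cost_model(
    table: SimilarityTable,
    C: float = 1.0,
    average_length: float = 9.4,
    pattern_length: int = 1,
    strict: bool = False,
) -> CostModel:
    """Glyph-shape metric: ``substitution(x, y) = C / s(x, y)`` for ``x != y``.

    The more alike two characters look (large similarity ``s``), the
    cheaper it is to confuse them.  ``C`` is a free scaling factor: only
    cost *ratios* are pinned down by the similarity table.  Deletion and
    insertion share one constant, ``exp(average_length / pattern_length) / e``,
    evaluated once per pattern — mistakes in short patterns are penalized
    more heavily.
    """
    if C <= 0:
        raise ValueError("scaling factor C must be > 0")
    indel = indel_cost_for_length(average_length, pattern_length)

    def substitution(x: str, y: str) -> float:
        if x == y:
            return 0.0
        return C / table.lookup(x, y, strict=strict)

    return CostModel(
        name="shape",
        substitution=substitution,
        deletion=lambda x: indel,
        insertion=lambda y: indel,
        params={
            "C": C,
            "average_length": average_length,
            "pattern_length": pattern_length,
            "indel_cost": indel,
        },
    )


def keyboard_cost_model(
    layout: KeyboardLayout | None = None,
    scale: float = 1.0,
    indel_cost: float | None = None,
    on_missing: str = "max",
) -> CostModel:
    """Keyboard-position metric: substitution cost = key-to-key Euclidean distance.

    Typing 'w' for 'q' is cheap because the keys are adjacent; 'p' for 'q'
    is expensive.  Deletion and insertion share one constant so the metric
    stays symmetric; by default that constant is the layout's mean pairwise
    key distance (times *scale*), a mid-range cost.

    ``on_missing`` controls characters absent from the layout: ``"max"``
    substitutes the largest key distance in the layout, ``"error"`` raises.
    """
    if layout is None:
        layout = qwerty_layout()
    if scale <= 0:
        raise ValueError("scale must be > 0")
    if on_missing not in ("max", "error"):
        raise ValueError("on_missing must be 'max' or 'error'")
    max_cost = scale * layout.max_distance()
    if indel_cost is None:
        indel_cost = scale * layout.mean_distance()
    if indel_cost <= 0:
        raise ValueError("indel_cost must be > 0")

    def substitution(x: str, y: str) -> float:
        if x == y:
            return 0.0
        try:
            return scale * layout.distance(x, y)
        except KeyError:
            if on_missing == "error":
                raise KeyError(f"character not in keyboard layout: {x!r} or {y!r}") from None
            return max_cost

    return CostModel(
        name="keyboard",
        substitution=substitution,
        deletion=lambda x: indel_cost,
        insertion=lambda y: indel_cost,
        params={"scale": scale, "indel_cost": indel_cost, "on_missing": on_missing},
    )


def table_cost_model(
    substitution_table: Mapping[PairKey, float] | None = None,
    deletion_cost: Union[float, Mapping[str, float]] = 1.0,
    insertion_cost: Union[float, Mapping[str, float]] = 1.0,
    default_substitution: float = 1.0,
    name: str = "table",
) -> CostModel:
    """Generic table-driven metric.

    ``substitution_table`` maps unordered character pairs to costs;
    diagonal entries must be zero (absent means zero).  ``deletion_cost``
    and ``insertion_cost`` are either one constant or per-character maps.
    With an empty table and unit defaults this reduces exactly to the
    Levenshtein metric.
    """
    table: dict[PairKey, float] = {}
    for (a, b), cost in (substitution_table or {}).items():
        if cost < 0 or not math.isfinite(cost):
            raise ValueError(f"substitution cost for ({a!r}, {b!r}) must be finite and >= 0")
        if a == b and cost != 0:
            raise ValueError(f"diagonal substitution cost for {a!r} must be 0")
        key = _pair_key(a, b)
        if key in table and table[key] != cost:
            raise ValueError(f"conflicting substitution entries for pair {key}")
        table[key] = cost
    if default_substitution < 0:
        raise ValueError("default_substitution must be >= 0")

    def _per_char(spec: Union[float, Mapping[str, float]], label: str) -> Callable[[str], float]:
        if isinstance(spec, Mapping):
            per_char = dict(spec)
            for ch, cost in per_char.items():
                if not cost > 0:
                    raise ValueError(f"{label} cost for {ch!r} must be > 0")
            fallback = max(per_char.values()) if per_char else 1.0
            return lambda ch: per_char.get(ch, fallback)
        if not spec > 0:
            raise ValueError(f"{label} cost must be > 0")
        const = float(spec)
        return lambda ch: const

    def substitution(x: str, y: str) -> float:
        if x == y:
            return 0.0
        return table.get(_pair_key(x, y), default_substitution)

    return CostModel(
        name=name,
        substitution=substitution,
        deletion=_per_char(deletion_cost, "deletion"),
        insertion=_per_char(insertion_cost, "insertion"),
        params={"default_substitution": default_substitution, "n_table_entries": len(table)},
    )


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------


def load_cost_table(path: Union[str, Path]) -> dict[PairKey, float]:
    """Read a pairwise table from TSV: ``char_a<TAB>char_b<TAB>value``.

    Lines starting with ``#`` and blank lines are skipped.  Values must be
    nonnegative numbers; duplicate pairs with conflicting values are an
    error.  Errors name the offending line number.
    """
    path = Path(path)
    entries: dict[PairKey, float] = {}
    with path.open(encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            a, b, raw_value = parts
            try:
                value = float(raw_value)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric value {raw_value!r}") from None
            if value < 0 or not math.isfinite(value):
                raise ValueError(f"{path}:{lineno}: value must be finite and >= 0, got {value}")
            key = _pair_key(a, b)
            if key in entries and entries[key] != value:
                raise ValueError(f"{path}:{lineno}: conflicting value for pair {key}")
            entries[key] = value
    return entries


def save_cost_table(entries: Mapping[PairKey, float], path: Union[str, Path]) -> None:
    """Write a pairwise table in the TSV dialect ``load_cost_table`` reads."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        for (a, b), value in sorted(entries.items()):
            handle.write(f"{a}\t{b}\t{value:g}\n")


def load_keyboard_layout(path: Union[str, Path]) -> KeyboardLayout:
    """Read a layout from TSV: ``char<TAB>x<TAB>y`` with ``#`` comments."""
    path = Path(path)
    coords: dict[str, tuple[float, float]] = {}
    with path.open(encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            ch, raw_x, raw_y = parts
            try:
                xy = (float(raw_x), float(raw_y))
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinate") from None
            if ch in coords and coords[ch] != xy:
                raise ValueError(f"{path}:{lineno}: conflicting coordinates for {ch!r}")
            coords[ch] = xy
    return KeyboardLayout(coords)


def sample_similarity_table() -> SimilarityTable:
    """Tiny shipped glyph-similarity table: s('a','b') = 2.13, s('o','e') = 4.13.

    'o' and 'e' look more alike than 'a' and 'b', so confusing them is
    cheaper.  Real applications should load a full-alphabet table with
    :func:`load_cost_table`; this sample only pins down the two quantified
    pairs used throughout the documentation and tests.
    """
    return SimilarityTable({("a", "b"): 2.13, ("e", "o"): 4.13})


def sample_substitution_costs() -> dict[PairKey, float]:
    """Tiny shape-based substitution cost table for :func:`table_cost_model`.

    sub('c','e') = 0.42 (similar glyphs), sub('a','h') = 1.20 (dissimilar);
    pairs with the customary constant indel cost 0.76.
    """
    return {("c", "e"): 0.42, ("a", "h"): 1.20}


# Letter rows of a US QWERTY board.  y grows downward; the home and bottom
# rows are staggered right by 0.25 and 0.75 key pitches relative to the top
# row, so horizontally adjacent keys are exactly 1 pitch apart.
_QWERTY_ROWS = (("qwertyuiop", 0.0, 0.0), ("asdfghjkl", 0.25, 1.0), ("zxcvbnm", 0.75, 2.0))


def qwerty_layout() -> KeyboardLayout:
    """The shipped US QWERTY letter layout (26 lowercase keys)."""
    coords = {
        ch: (offset + i, y)
        for row, offset, y in _QWERTY_ROWS
        for i, ch in enumerate(row)
    }
    return KeyboardLayout(coords)


# ---------------------------------------------------------------------------
# metric specification (name + parameters -> per-pattern CostModel)
# ---------------------------------------------------------------------------


@dataclass
class MetricSpec:
    """A named metric with parameters, resolvable to a :class:`CostModel`.

    The shape metric's indel cost depends on the pattern length, so a
    fresh model is built per pattern; the other metrics are built once and
    cached.
    """

    name: str
    similarity: SimilarityTable | None = None
    substitution_table: Mapping[PairKey, float] | None = None
    layout: KeyboardLayout | None = None
    C: float = 1.0
    average_length: float = 9.4
    scale: float = 1.0
    indel_cost: float | None = None
    default_substitution: float = 1.0
    _cached: CostModel | None = field(default=None, repr=False)

    KNOWN = ("levenshtein", "unit", "shape", "keyboard", "table")

    def build(self, pattern: str) -> CostModel:
        if self.name in ("levenshtein", "unit"):
            if self._cached is None:
                self._cached = unit_cost_model()
            return self._cached
        if self.name == "shape":
            table = self.similarity if self.similarity is not None else SimilarityTable()
            return shape_cost_model(
                table,
                C=self.C,
                average_length=self.average_length,
                pattern_length=max(1, len(pattern)),
            )
        if self.name == "keyboard":
            if self._cached is None:
                self._cached = keyboard_cost_model(
                    self.layout, scale=self.scale, indel_cost=self.indel_cost
                )
            return self._cached
        if self.name == "table":
            if self._cached is None:
                indel = self.indel_cost if self.indel_cost is not None else 1.0
                self._cached = table_cost_model(
                    self.substitution_table,
                    deletion_cost=indel,
                    insertion_cost=indel,
                    default_substitution=self.default_substitution,
                )
            return self._cached
        raise ValueError(f"unknown metric {self.name!r}; valid: {', '.join(self.KNOWN)}")


def metric_spec_from_config(config: Mapping[str, object]) -> MetricSpec:
    """Build a :class:`MetricSpec` from a structured (YAML/JSON) mapping.

    Recognized keys: ``metric`` (name), ``cost_table`` (TSV path: similarity
    scores for shape, substitution costs for table), ``layout`` (TSV path),
    ``C``, ``average_length``, ``scale``, ``indel_cost``,
    ``default_substitution``.
    """
    name = str(config.get("metric", "levenshtein"))
    spec = MetricSpec(name=name)
    if "cost_table" in config:
        entries = load_cost_table(str(config["cost_table"]))
        if name == "shape":
            spec.similarity = SimilarityTable(entries)
        else:
            spec.substitution_table = entries
    for key in ("C", "average_length", "scale", "default_substitution"):
        if key in config:
            setattr(spec, key, float(config[key]))  # type: ignore[arg-type]
    if config.get("indel_cost") is not None:
        spec.indel_cost = float(config["indel_cost"])  # type: ignore[arg-type]
    if "layout" in config:
        spec.layout = load_keyboard_layout(str(config["layout"]))
    return spec
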