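"""Synthetic string pairs with controlled lengths and divergence.

The generator emulates the length profile of a natural-language
dictionary: word lengths are drawn from a normal distribution (default
mean 9.4, standard deviation 2.90 — the profile of a large English word
list), rounded and truncated to at least 1, with characters i.i.d.
uniform over the alphabet.  Pair divergence is controlled either by
sampling two independent words or by applying a known number of random
edits to one word.

The module also hosts :func:`oracle_distance`, a memoized recursive
implementation of the weighted edit distance kept deliberately separate
from the matrix engines so it can serve as an independent cross-check in
tests.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Optional

import numpy as np

from gedmatch.cost_models import CostModel

__all__ = [
    "ALPHABETS",
    "GeneratorConfig",
    "random_string",
    "mutate",
    "generate_pairs",
    "oracle_distance",
    "write_pairs_tsv",
]

ALPHABETS = {"az": string.ascii_lowercase, "acgt": "acgt"}

#: largest len(X) * len(Y) the oracle will accept (it is quadratic in
#: memory and meant for test-scale inputs only)
ORACLE_SIZE_GUARD = 10_000


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic pair generator.

    ``n_edits`` (fixed edit count) and ``mutation_rate`` (expected edits
    per character, binomially sampled) are mutually exclusive divergence
    controls; with neither set, the two strings of a pair are sampled
    independently.
    """

    alphabet: str = ALPHABETS["az"]
    mean_length: float = 9.4
    sd_length: float = 2.90
    n_pairs: int = 1000
    seed: int = 0
    n_edits: Optional[int] = None
    mutation_rate: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.alphabet) == 0:
            raise ValueError("alphabet must be nonempty")
        if not self.mean_length > 0:
            raise ValueError("mean_length must be > 0")
        if self.sd_length < 0:
            raise ValueError("sd_length must be >= 0")
        if self.n_edits is not None and self.mutation_rate is not None:
            raise ValueError("set at most one of n_edits and mutation_rate")
        if self.n_edits is not None and self.n_edits < 0:
            raise ValueError("n_edits must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def random_string(config: GeneratorConfig, rng: np.random.Generator) -> str:
    """One word: normal length (rounded, >= 1), characters uniform."""
    length = max(1, int(round(rng.normal(config.mean_length, config.sd_length))))
    idx = rng.integers(0, len(config.alphabet), size=length)
    return "".join(config.alphabet[i] for i in idx)


def mutate(
    X: str,
    n_edits: int,
    rng: np.random.Generator,
    alphabet: str = ALPHABETS["az"],
) -> tuple[str, list[tuple[str, int, str, str]]]:
    """Apply ``n_edits`` random edits to ``X``; return the result and log.

    Each edit is uniformly a substitution, insertion or deletion at a
    uniform position; substitutions always pick a character different
    from the one replaced.  A deletion drawn on an empty string is
    resampled as an insertion.  The log lists ``(op, position, old, new)``
    tuples whose summed operator costs upper-bound the edit distance of
    the resulting pair under any cost model.
    """
    if n_edits < 0:
        raise ValueError("n_edits must be >= 0")
    chars = list(X)
    log: list[tuple[str, int, str, str]] = []
    for _ in range(n_edits):
        op = ("sub", "ins", "del")[rng.integers(0, 3)]
        if op == "del" and not chars:
            op = "ins"
        if op == "sub" and not chars:
            op = "ins"
        if op == "sub":
            pos = int(rng.integers(0, len(chars)))
            old = chars[pos]
            others = [c for c in alphabet if c != old] or [old]
            new = others[rng.integers(0, len(others))]
            chars[pos] = new
            log.append(("sub", pos, old, new))
        elif op == "ins":
            pos = int(rng.integers(0, len(chars) + 1))
            new = alphabet[rng.integers(0, len(alphabet))]
            chars.insert(pos, new)
            log.append(("ins", pos, "", new))
        else:
            pos = int(rng.integers(0, len(chars)))
            log.append(("del", pos, chars[pos], ""))
            del chars[pos]
    return "".join(chars), log


def generate_pairs(config: GeneratorConfig, rng: Optional[np.random.Generator] = None) -> list[tuple[str, str]]:
    """Seeded list of ``n_pairs`` (input, pattern) string pairs."""
    if rng is None:
        rng = config.rng()
    pairs: list[tuple[str, str]] = []
    for _ in range(config.n_pairs):
        X = random_string(config, rng)
        if config.n_edits is not None:
            Y, _ = mutate(X, config.n_edits, rng, config.alphabet)
        elif config.mutation_rate is not None:
            n = int(rng.binomial(len(X), min(1.0, config.mutation_rate)))
            Y, _ = mutate(X, n, rng, config.alphabet)
        else:
            Y = random_string(config, rng)
        pairs.append((X, Y))
    return pairs


def write_pairs_tsv(pairs: list[tuple[str, str]], path) -> None:
    """Two-column TSV: input sequence, pattern."""
    with open(path, "w", encoding="utf-8") as handle:
        for x, y in pairs:
            handle.write(f"{x}\t{y}\n")


def oracle_distance(X: str, Y: str, model: CostModel) -> float:
    """Weighted edit distance by independent memoized recursion.

    Shares nothing with the matrix engines beyond the
    :class:`~gedmatch.cost_models.CostModel` interface; quadratic and
    guarded to ``len(X) * len(Y) <= 10,000``, so test-scale only.
    """
    if len(X) * len(Y) > ORACLE_SIZE_GUARD:
        raise ValueError(
            f"oracle guard exceeded: {len(X)}*{len(Y)} > {ORACLE_SIZE_GUARD}"
        )
    memo: dict[tuple[int, int], float] = {}

    def dist(a: int, b: int) -> float:
        if (a, b) in memo:
            return memo[(a, b)]
        if a == 0 and b == 0:
            value = 0.0
        else:
            candidates = []
            if a > 0 and b > 0:
                candidates.append(dist(a - 1, b - 1) + model.substitution(X[a - 1], Y[b - 1]))
            if a > 0:
                candidates.append(dist(a - 1, b) + model.deletion(X[a - 1]))
            if b > 0:
                candidates.append(dist(a, b - 1) + model.insertion(Y[b - 1]))
            value = min(candidates)
        memo[(a, b)] = value
        return value

    import sys

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, (len(X) + len(Y)) * 4 + 100))
    try:
        return dist(len(X), len(Y))
    finally:
        sys.setrecursionlimit(old_limit)
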