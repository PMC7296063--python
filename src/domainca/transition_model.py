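"""Domain-adjacency transition model.

Every architecture is flanked by two artificial terminator symbols,
``X-start`` and ``X-end``, and a sliding window of size 2 counts every
adjacent ordered pair of symbols across the corpus.  The single pair-count
table backs two conditional views:

* **F2B** (front-to-back): the distribution of the *successor* given a
  predecessor — row-conditional.
* **B2F** (back-to-front): the distribution of the *predecessor* given a
  successor — column-conditional.

Counts are raw observed frequencies: no pseudocounts, no smoothing, and a
pair never seen in training has probability exactly 0.  Terminator
augmentation guarantees every domain has at least one successor pair
(possibly to ``X-end``) and one predecessor pair (possibly from
``X-start``).
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Union

import numpy as np

from .arch_io import Architecture, Corpus

X_START = "X-start"
X_END = "X-end"
TERMINATORS = frozenset({X_START, X_END})


@dataclass(frozen=True)
class AugmentedArchitecture:
    """An architecture with terminators: ``[X-start, d_1, ..., d_k, X-end]``."""

    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "symbols", tuple(self.symbols))
        if len(self.symbols) < 3:
            raise ValueError("augmented architecture shorter than 3 symbols")
        if self.symbols[0] != X_START or self.symbols[-1] != X_END:
            raise ValueError("augmented architecture must be terminator-flanked")
        if any(s in TERMINATORS for s in self.symbols[1:-1]):
            raise ValueError("terminator symbol in architecture interior")

    def __len__(self) -> int:
        return len(self.symbols)


def augment(arch: Architecture) -> AugmentedArchitecture:
    """Flank an architecture with ``X-start`` and ``X-end``."""
    return AugmentedArchitecture(symbols=(X_START, *arch.domains, X_END))


class TransitionModel:
    """Adjacency pair counts over the augmented alphabet.

    Parameters
    ----------
    alphabet:
        The g domain names (terminators excluded).
    pair_counts:
        Mapping (predecessor, successor) -> positive count.  No pair may
        have ``X-end`` as predecessor or ``X-start`` as successor, and the
        pair (``X-start``, ``X-end``) cannot occur because every training
        architecture contains at least one domain.
    """

    def __init__(
        self,
        alphabet: Iterable[str],
        pair_counts: Mapping[tuple[str, str], int],
    ) -> None:
        self.alphabet: frozenset[str] = frozenset(alphabet)
        if self.alphabet & TERMINATORS:
            raise ValueError("terminator symbols may not be in the domain alphabet")
        self.pair_counts: dict[tuple[str, str], int] = dict(pair_counts)
        self._validate()
        # Lazily built sampling tables: symbol -> (symbols, cumulative counts).
        self._succ_rows: dict[str, tuple[list[str], np.ndarray]] = {}
        self._pred_rows: dict[str, tuple[list[str], np.ndarray]] = {}

    def _validate(self) -> None:
        valid = self.alphabet | TERMINATORS
        has_succ: set[str] = set()
        has_pred: set[str] = set()
        for (a, b), count in self.pair_counts.items():
            if count <= 0 or count != int(count):
                raise ValueError(f"pair ({a}, {b}) has non-positive count {count}")
            if a == X_END:
                raise ValueError("X-end cannot be a predecessor")
            if b == X_START:
                raise ValueError("X-start cannot be a successor")
            if a == X_START and b == X_END:
                raise ValueError("pair (X-start, X-end) cannot occur")
            if a not in valid or b not in valid:
                raise ValueError(f"pair ({a}, {b}) uses symbols outside the alphabet")
            has_succ.add(a)
            has_pred.add(b)
        missing = (self.alphabet - has_succ) | (self.alphabet - has_pred)
        if missing:
            raise ValueError(
                f"domains without both successor and predecessor pairs: {sorted(missing)}"
            )

    # ------------------------------------------------------------------
    @property
    def symbols(self) -> frozenset[str]:
        """The g+2 emit-able symbols (domains plus both terminators)."""
        return self.alphabet | TERMINATORS

    @property
    def g(self) -> int:
        return len(self.alphabet)

    @property
    def total_pairs(self) -> int:
        return sum(self.pair_counts.values())

    # ------------------------------------------------------------------
    def successor_weights(self, d: str) -> dict[str, int]:
        """Raw counts of symbols observed immediately after ``d`` (F2B row)."""
        if d == X_END:
            raise ValueError("no successors of the end terminator")
        if d not in self.symbols:
            raise ValueError(f"unknown symbol {d!r}")
        return {b: c for (a, b), c in self.pair_counts.items() if a == d}

    def predecessor_weights(self, d: str) -> dict[str, int]:
        """Raw counts of symbols observed immediately before ``d`` (B2F column)."""
        if d == X_START:
            raise ValueError("no predecessors of the start terminator")
        if d not in self.symbols:
            raise ValueError(f"unknown symbol {d!r}")
        return {a: c for (a, b), c in self.pair_counts.items() if b == d}

    def successor_distribution(self, d: str) -> dict[str, float]:
        """Conditional probability of each successor given ``d``."""
        weights = self.successor_weights(d)
        total = sum(weights.values())
        return {b: c / total for b, c in weights.items()}

    def predecessor_distribution(self, d: str) -> dict[str, float]:
        """Conditional probability of each predecessor given ``d``."""
        weights = self.predecessor_weights(d)
        total = sum(weights.values())
        return {a: c / total for a, c in weights.items()}

    # -- cached cumulative tables for roulette sampling -----------------
    def _successor_row(self, d: str) -> tuple[list[str], np.ndarray]:
        row = self._succ_rows.get(d)
        if row is None:
            weights = self.successor_weights(d)
            symbols = sorted(weights)
            row = (symbols, np.cumsum([float(weights[s]) for s in symbols]))
            self._succ_rows[d] = row
        return row

    def _predecessor_row(self, d: str) -> tuple[list[str], np.ndarray]:
        row = self._pred_rows.get(d)
        if row is None:
            weights = self.predecessor_weights(d)
            symbols = sorted(weights)
            row = (symbols, np.cumsum([float(weights[s]) for s in symbols]))
            self._pred_rows[d] = row
        return row

    # ------------------------------------------------------------------
    def to_csv(self, path: Union[str, Path]) -> None:
        """Serialize the count table (rows = predecessor, columns =
        successor, integer counts) for inspection and reuse."""
        domains = sorted(self.alphabet)
        predecessors = [X_START] + domains
        successors = domains + [X_END]
        with open(path, "w", encoding="utf-8", newline="") as handle:
            writer = csv.writer(handle)
            writer.writerow([""] + successors)
            for a in predecessors:
                writer.writerow(
                    [a] + [self.pair_counts.get((a, b), 0) for b in successors]
                )

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "TransitionModel":
        with open(path, "r", encoding="utf-8", newline="") as handle:
            reader = csv.reader(handle)
            header = next(reader)
            successors = header[1:]
            pair_counts: dict[tuple[str, str], int] = {}
            for row in reader:
                a = row[0]
                for b, cell in zip(successors, row[1:]):
                    count = int(cell)
                    if count:
                        pair_counts[(a, b)] = count
        alphabet = {s for s in successors if s not in TERMINATORS}
        return cls(alphabet=alphabet, pair_counts=pair_counts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TransitionModel):
            return NotImplemented
        return (
            self.alphabet == other.alphabet
            and self.pair_counts == other.pair_counts
        )

    def __repr__(self) -> str:
        return (
            f"TransitionModel(g={self.g}, pairs={len(self.pair_counts)}, "
            f"total={self.total_pairs})"
        )


def build_transition_model(corpus: Corpus) -> TransitionModel:
    """Count adjacent symbol pairs (sliding window of size 2) across the
    terminator-augmented corpus.

    Repeats within one architecture all count: a protein ``[A, A]``
    contributes the pair (A, A).  The total pair count equals
    sum over proteins of (domain count + 1).
    """
    if not len(corpus.architectures):
        raise ValueError("empty corpus")
    pair_counts: Counter[tuple[str, str]] = Counter()
    for arch in corpus.architectures:
        symbols = augment(arch).symbols
        for a, b in zip(symbols, symbols[1:]):
            pair_counts[(a, b)] += 1
    return TransitionModel(alphabet=corpus.alphabet, pair_counts=pair_counts)
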