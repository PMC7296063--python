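"""The (g+3)-state one-dimensional cellular automaton.

The lattice has 2m+1 cells, where m is the largest domain count over the
training proteins; cell states are the g domain classes, the two
terminators ``X-start``/``X-end``, or the empty state (``None`` here).
At t = 0 the center cell holds the ancestral symbol Y and everything else
is empty.  Each synchronous step applies:

* Rule A (inheritance): a non-empty cell keeps its state.
* Rule B (front-to-back): an empty cell whose left neighbor is non-empty
  takes a roulette draw from the successor distribution of that neighbor
  (F2B view) — unless the neighbor is ``X-end``, which has no successors.
* Rule C (back-to-front): an empty cell whose right neighbor is non-empty
  draws from the predecessor distribution of that neighbor (B2F view) —
  unless the neighbor is ``X-start``.
* Rule D: an empty cell with empty neighbors stays empty.

Growth therefore proceeds outward from the center, one cell per side per
step, and freezes on a side once its terminator has evolved.  Evolution
stops early at time k < m when both terminators are present; at t = m any
missing terminator is appended when the architecture is read off.

Randomness: one shared seeded stream; per step the left frontier cell
draws before the right one, and each roulette draw consumes exactly one
uniform variate, with candidates in lexicographic symbol order — this
fixes bit-reproducibility for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .arch_io import Architecture
from .transition_model import TERMINATORS, TransitionModel, X_END, X_START

#: The empty state: "no domain evolved here yet".
EMPTY = None


class SimulationError(RuntimeError):
    """Raised when a simulation cannot produce a valid protein."""


@dataclass
class Lattice:
    """CA cell array at one time step.

    ``cells`` has length 2m+1 with the center fixed at index m; non-empty
    cells always form one contiguous block containing the center.
    """

    cells: list[Optional[str]]
    t: int
    m: int

    def __post_init__(self) -> None:
        if len(self.cells) != 2 * self.m + 1:
            raise ValueError(
                f"lattice of m={self.m} must have {2 * self.m + 1} cells"
            )

    @property
    def center(self) -> int:
        return self.m

    def span(self) -> tuple[int, int]:
        """(leftmost, rightmost) indices of the non-empty block."""
        occupied = [i for i, c in enumerate(self.cells) if c is not EMPTY]
        return occupied[0], occupied[-1]

    def occupied_symbols(self) -> list[str]:
        return [c for c in self.cells if c is not EMPTY]

    def is_terminated(self) -> bool:
        """True when both terminators have evolved."""
        lo, hi = self.span()
        return self.cells[lo] == X_START and self.cells[hi] == X_END


def init_lattice(m: int, ancestor: str, model: Optional[TransitionModel] = None) -> Lattice:
    """All-empty lattice of 2m+1 cells with ``ancestor`` at the center.

    The ancestor may be any domain of the model or either terminator.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if model is not None and ancestor not in model.symbols:
        raise ValueError(f"unknown ancestral domain {ancestor!r}")
    cells: list[Optional[str]] = [EMPTY] * (2 * m + 1)
    cells[m] = ancestor
    return Lattice(cells=cells, t=0, m=m)


def roulette_select(weights: Mapping[str, float], rng: np.random.Generator) -> str:
    """Roulette-wheel selection: return symbol s with probability
    weight(s) / sum(weights), consuming exactly one uniform draw.

    Candidates are scanned in lexicographic symbol order so that a fixed
    seed yields an identical selection sequence across runs.
    """
    symbols = sorted(weights)
    cum = np.cumsum([float(weights[s]) for s in symbols])
    if len(cum) == 0 or cum[-1] <= 0.0:
        raise ValueError("no admissible transition (all-zero weights)")
    u = rng.random() * cum[-1]
    return symbols[int(np.searchsorted(cum, u, side="right"))]


def _draw_from_row(
    row: tuple[Sequence[str], np.ndarray], rng: np.random.Generator
) -> str:
    symbols, cum = row
    u = rng.random() * cum[-1]
    return symbols[int(np.searchsorted(cum, u, side="right"))]


def step(lattice: Lattice, model: TransitionModel, rng: np.random.Generator) -> Lattice:
    """One synchronous update (rules A-D), computed from time-t states only.

    Only the two frontier cells — the empty cells immediately outside the
    occupied block — can change; the left frontier draws first.
    """
    if lattice.t >= lattice.m:
        raise SimulationError(
            f"lattice already at its maximum time step m={lattice.m}"
        )
    cells = list(lattice.cells)
    lo, hi = lattice.span()
    # Rule C: left frontier extends unless bounded by X-start.
    if lo > 0 and lattice.cells[lo] != X_START:
        cells[lo - 1] = _draw_from_row(model._predecessor_row(lattice.cells[lo]), rng)
    # Rule B: right frontier extends unless bounded by X-end.
    if hi < len(cells) - 1 and lattice.cells[hi] != X_END:
        cells[hi + 1] = _draw_from_row(model._successor_row(lattice.cells[hi]), rng)
    return Lattice(cells=cells, t=lattice.t + 1, m=lattice.m)


def simulate_lattice(
    model: TransitionModel, ancestor: str, m: int, rng: np.random.Generator
) -> Lattice:
    """Run the CA from the ancestral seed until both terminators have
    evolved (time k < m) or the maximum time step m is reached."""
    if ancestor not in model.symbols:
        raise ValueError(f"unknown ancestral domain {ancestor!r}")
    lattice = init_lattice(m, ancestor, model)
    while lattice.t < m and not lattice.is_terminated():
        lattice = step(lattice, model, rng)
    return lattice


def read_off(lattice: Lattice, protein_id: str = "evo") -> Architecture:
    """Read the non-empty cells left to right, append any terminator still
    missing at t = m, strip both terminators, and return the architecture."""
    symbols = lattice.occupied_symbols()
    if symbols and symbols[0] != X_START:
        symbols = [X_START] + symbols
    if symbols and symbols[-1] != X_END:
        symbols = symbols + [X_END]
    domains = tuple(s for s in symbols if s not in TERMINATORS)
    if not domains:
        raise SimulationError("empty simulated protein")
    return Architecture(protein_id=protein_id, domains=domains)


def simulate_protein(
    model: TransitionModel,
    ancestor: str,
    m: int,
    rng: np.random.Generator,
    protein_id: str = "evo",
) -> Architecture:
    """Simulate one protein; the result contains the ancestor whenever the
    ancestor is a real domain."""
    return read_off(simulate_lattice(model, ancestor, m, rng), protein_id)


@dataclass(frozen=True)
class SimulatedCorpus:
    """The evolved corpus: ``evo_num`` architectures (terminators stripped)
    produced from one seeded stream."""

    architectures: tuple[Architecture, ...]
    seed: int
    ancestor: str
    evo_num: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "architectures", tuple(self.architectures))
        if len(self.architectures) != self.evo_num:
            raise ValueError("corpus size differs from evo_num")

    @property
    def alphabet(self) -> frozenset[str]:
        return frozenset(d for a in self.architectures for d in a.domains)

    def __len__(self) -> int:
        return len(self.architectures)

    def __iter__(self):
        return iter(self.architectures)


def simulate_corpus(
    model: TransitionModel,
    ancestor: str,
    evo_num: int,
    m: int,
    seed: int,
) -> SimulatedCorpus:
    """``evo_num`` independent protein simulations driven by one seeded
    stream; fully reproducible given (model, ancestor, evo_num, m, seed)."""
    if evo_num < 1:
        raise ValueError(f"evo_num must be >= 1, got {evo_num}")
    rng = np.random.default_rng(seed)
    architectures: list[Architecture] = []
    for i in range(evo_num):
        try:
            architectures.append(
                simulate_protein(model, ancestor, m, rng, protein_id=f"evo_{i + 1}")
            )
        except SimulationError as exc:
            raise SimulationError(f"replicate {i + 1}: {exc}") from exc
    return SimulatedCorpus(
        architectures=tuple(architectures),
        seed=seed,
        ancestor=ancestor,
        evo_num=evo_num,
    )
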