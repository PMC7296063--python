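"""Synthetic architecture corpora from a known first-order Markov chain.

Real training corpora come from HMMER/Pfam annotation of downloaded
protein families; this module replaces them with corpora sampled from a
fully specified ground-truth chain over a small domain alphabet, so every
stage of the pipeline (model building, CA simulation, Hit-Acc scoring) can
be tested against known transition probabilities without any external
data.

The ground truth is a forward-only chain: X-start emits a first domain
from ``start_probs``, each domain then emits a successor (another domain
or X-end) from its ``trans_probs`` row, and walks are truncated at
``max_len`` domains by forcing X-end.  The CA's backward extension is
exercised by simulating from domain ancestors mid-chain.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

from .arch_io import Architecture, Corpus

#: Default cap on sampled architecture length; matches the scale of the
#: most complex architectures seen in real Pfam-annotated corpora
#: (about ten domains).
DEFAULT_MAX_LEN = 10


@dataclass(frozen=True)
class GroundTruthModel:
    """A known chain over ``g`` domains with explicit start/end transitions.

    ``trans_probs`` has one row per domain; its g+1 columns are the g
    domains followed by X-end.  Every row sums to 1, every domain is
    reachable from X-start, and X-end has positive probability from every
    domain, so walks cannot cycle forever even without the length cap.
    """

    domains: tuple[str, ...]
    start_probs: np.ndarray
    trans_probs: np.ndarray
    max_len: int = DEFAULT_MAX_LEN

    def __post_init__(self) -> None:
        g = len(self.domains)
        if g < 1:
            raise ValueError("need at least one domain")
        if self.start_probs.shape != (g,):
            raise ValueError(f"start_probs must have shape ({g},)")
        if self.trans_probs.shape != (g, g + 1):
            raise ValueError(f"trans_probs must have shape ({g}, {g + 1})")
        if self.max_len < 1:
            raise ValueError("max_len must be >= 1")
        if abs(self.start_probs.sum() - 1.0) > 1e-12:
            raise ValueError("start_probs must sum to 1")
        if np.any(np.abs(self.trans_probs.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("every trans_probs row must sum to 1")
        if np.any(self.start_probs < 0) or np.any(self.trans_probs < 0):
            raise ValueError("probabilities must be non-negative")
        # X-end reachable from every domain (no absorbing domain cycles
        # beyond the length cap): reverse reachability from X-end.
        can_end = set(np.nonzero(self.trans_probs[:, g] > 0)[0].tolist())
        changed = True
        while changed:
            changed = False
            for i in range(g):
                if i not in can_end and any(
                    self.trans_probs[i, j] > 0 for j in can_end
                ):
                    can_end.add(i)
                    changed = True
        if len(can_end) != g:
            stuck = [self.domains[i] for i in range(g) if i not in can_end]
            raise ValueError(f"X-end unreachable from domains: {stuck}")
        # Reachability of every domain from X-start.
        reachable = set(np.nonzero(self.start_probs > 0)[0])
        frontier = list(reachable)
        while frontier:
            i = frontier.pop()
            for j in np.nonzero(self.trans_probs[i, :g] > 0)[0]:
                if j not in reachable:
                    reachable.add(int(j))
                    frontier.append(int(j))
        if len(reachable) != g:
            missing = [self.domains[i] for i in range(g) if i not in reachable]
            raise ValueError(f"domains unreachable from X-start: {missing}")

    @property
    def g(self) -> int:
        return len(self.domains)

    def start_distribution(self) -> dict[str, float]:
        return {
            d: float(p) for d, p in zip(self.domains, self.start_probs) if p > 0
        }

    def successor_distribution(self, domain: str) -> dict[str, float]:
        """True successor distribution of ``domain`` over domains + X-end."""
        from .transition_model import X_END

        i = self.domains.index(domain)
        row = self.trans_probs[i]
        out = {d: float(p) for d, p in zip(self.domains, row[: self.g]) if p > 0}
        if row[self.g] > 0:
            out[X_END] = float(row[self.g])
        return out


def make_ground_truth(
    g: int,
    seed: int,
    sparsity: float = 0.3,
    max_len: int = DEFAULT_MAX_LEN,
) -> GroundTruthModel:
    """Random ground-truth chain with about ``(1 - sparsity) * (g + 1)``
    non-zero entries per transition row, deterministic given ``seed``.

    X-end is always a possible successor of every domain; if
    sparsification leaves a domain unreachable from X-start it is given a
    floor start probability so the invariants hold by construction.
    """
    if g < 1:
        raise ValueError(f"g must be >= 1, got {g}")
    if not 0.0 <= sparsity <= 1.0:
        raise ValueError(f"sparsity must be in [0, 1], got {sparsity}")
    rng = np.random.default_rng(seed)
    domains = tuple(f"D{i + 1}" for i in range(g))

    n_nonzero = max(1, round((1.0 - sparsity) * (g + 1)))
    trans = np.zeros((g, g + 1))
    for i in range(g):
        # X-end (column g) is always admissible.  Its probability is drawn
        # in [0.3, 0.5], giving a mean chain length of 2-3 domains — the
        # scale real Pfam-annotated corpora show (a few thousand domain
        # occurrences over ~1,600 proteins averages ~2.6 domains each) —
        # so the max_len safety cap is almost never hit.
        extra = min(n_nonzero - 1, g)
        if extra == 0:
            trans[i, g] = 1.0
            continue
        p_end = rng.uniform(0.3, 0.5)
        cols = rng.choice(g, size=extra, replace=False)
        weights = rng.uniform(0.1, 1.0, size=extra)
        trans[i, cols] = (1.0 - p_end) * weights / weights.sum()
        trans[i, g] = p_end

    n_start = max(1, round((1.0 - sparsity) * g))
    start = np.zeros(g)
    start_cols = rng.choice(g, size=min(n_start, g), replace=False)
    start_weights = rng.uniform(0.1, 1.0, size=len(start_cols))
    start[start_cols] = start_weights

    # Deterministic repair: any domain not reachable through the chain gets
    # a floor start weight.
    reachable = set(np.nonzero(start > 0)[0].tolist())
    frontier = list(reachable)
    while frontier:
        i = frontier.pop()
        for j in np.nonzero(trans[i, :g] > 0)[0]:
            if int(j) not in reachable:
                reachable.add(int(j))
                frontier.append(int(j))
    floor = 0.5 * start[start > 0].min()
    for i in range(g):
        if i not in reachable:
            start[i] = floor
    start = start / start.sum()

    return GroundTruthModel(
        domains=domains, start_probs=start, trans_probs=trans, max_len=max_len
    )


def _walk(gt: GroundTruthModel, rng: np.random.Generator) -> tuple[str, ...]:
    g = gt.g
    start_cum = np.cumsum(gt.start_probs)
    current = int(np.searchsorted(start_cum, rng.random() * start_cum[-1], side="right"))
    path = [current]
    while len(path) < gt.max_len:
        row = gt.trans_probs[current]
        cum = np.cumsum(row)
        nxt = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
        if nxt == g:  # X-end drawn
            break
        path.append(nxt)
        current = nxt
    return tuple(gt.domains[i] for i in path)


def sample_corpus(gt: GroundTruthModel, n_proteins: int, seed: int) -> Corpus:
    """Sample ``n_proteins`` architectures by walking X-start -> ... ->
    X-end, truncating at ``max_len`` by forcing X-end; never empty."""
    if n_proteins < 1:
        raise ValueError(f"n_proteins must be >= 1, got {n_proteins}")
    rng = np.random.default_rng(seed)
    architectures = tuple(
        Architecture(protein_id=f"p{i + 1:06d}", domains=_walk(gt, rng))
        for i in range(n_proteins)
    )
    return Corpus(architectures=architectures)


def write_domtblout(
    corpus: Corpus,
    path: Union[str, Path],
    hit_evalue: float = 1e-50,
    decoy_evalue: float = 1e-5,
    decoy_every: int = 5,
) -> None:
    """Write a synthetic hmmscan ``--domtblout`` file encoding ``corpus``.

    Each domain becomes a 100-residue hit with consistent, non-overlapping
    envelope coordinates and an E-value of ``hit_evalue``; every
    ``decoy_every``-th protein gets one extra trailing "DECOY" hit at
    ``decoy_evalue``, so parsing at a threshold between the two E-values
    recovers exactly the original corpus.  This is a synthetic stand-in
    for real HMMER output, intended for tests and demos.
    """
    lines = [
        "# synthetic hmmscan --domtblout fixture",
        "#                                                               --- full sequence --- -------------- this domain -------------   hmm coord   ali coord   env coord",
        "# target name        accession   tlen query name           accession   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  from    to  from    to  acc description of target",
    ]
    for p_idx, arch in enumerate(corpus.architectures):
        k = len(arch.domains)
        decoy = decoy_every > 0 and (p_idx % decoy_every == decoy_every - 1)
        qlen = 150 * (k + (1 if decoy else 0)) + 50
        for d_idx, domain in enumerate(arch.domains):
            env_from = 1 + 150 * d_idx
            env_to = env_from + 99
            acc = 0.90 + 0.005 * ((p_idx + d_idx) % 10)
            lines.append(
                f"{domain} PF{d_idx + 1:05d}.1 100 {arch.protein_id} - {qlen} "
                f"{hit_evalue:.1e} 250.0 0.1 {d_idx + 1} {k} {hit_evalue:.1e} "
                f"{hit_evalue:.1e} 240.0 0.1 1 100 {env_from} {env_to} "
                f"{env_from} {env_to} {acc:.2f} synthetic fixture hit"
            )
        if decoy:
            env_from = 1 + 150 * k
            env_to = env_from + 99
            lines.append(
                f"DECOY PF99999.1 100 {arch.protein_id} - {qlen} "
                f"{decoy_evalue:.1e} 20.0 0.5 1 1 {decoy_evalue:.1e} "
                f"{decoy_evalue:.1e} 18.0 0.5 1 100 {env_from} {env_to} "
                f"{env_from} {env_to} 0.70 synthetic decoy hit"
            )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
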