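"""Goodness-of-fit statistics between a training corpus and a simulated one.

Three Hit-Acc statistics measure how much of the simulated corpus P^evo is
"real", i.e. already present in the training corpus P':

* **Hit-Acc(DAWP)** — the percentage of simulated proteins whose whole
  ordered domain sequence exactly matches some training architecture.
* **Hit-Acc(TAPD)** / **Hit-Acc(QAPD)** — the percentage of simulated
  triplet / quadruple windows whose n-gram type also occurs in training:
  occurrences of types in the intersection T' ∩ T^evo, weighted by their
  simulated counts, over all simulated n-gram occurrences.

n-gram windows are taken over terminator-augmented sequences, so a
single-domain protein still contributes the triplet
(X-start, D, X-end) and protein termini anchor the windows.

A statistic whose denominator is zero is *undefined* and reported as
``None``, never as 0 or 100.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import NamedTuple, Optional

from .arch_io import Corpus
from .transition_model import TERMINATORS, TransitionModel, augment

#: Separator used when an architecture is rendered as a single item string
#: (frequency reports); domain names never contain it in Pfam.
ARCH_SEPARATOR = ","


class HitAccStat(NamedTuple):
    """One Hit-Acc statistic: ``percent = 100 * hit / total`` (``None``
    when ``total`` is 0)."""

    percent: Optional[float]
    hit: int
    total: int


@dataclass(frozen=True)
class HitAccReport:
    """The three goodness-of-fit statistics with their counts."""

    dawp: HitAccStat
    tapd: HitAccStat
    qapd: HitAccStat

    def to_dict(self) -> dict:
        return {
            name: {"percent": stat.percent, "hit": stat.hit, "total": stat.total}
            for name, stat in (
                ("dawp", self.dawp),
                ("tapd", self.tapd),
                ("qapd", self.qapd),
            )
        }


@dataclass(frozen=True)
class NGramCounts:
    """Counts of contiguous length-n symbol windows (n in {2, 3, 4})."""

    n: int
    counts: dict[tuple[str, ...], int]

    def __post_init__(self) -> None:
        if self.n not in (2, 3, 4):
            raise ValueError(f"n must be 2, 3 or 4, got {self.n}")
        for gram, count in self.counts.items():
            if len(gram) != self.n or count < 1:
                raise ValueError(f"invalid n-gram entry {gram}: {count}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class FrequencyTable:
    """Item counts with derived probabilities (fractions of the total)."""

    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def probabilities(self) -> dict[str, float]:
        total = self.total
        return {item: count / total for item, count in self.counts.items()}


def hit_acc_dawp(train: Corpus, evo) -> HitAccStat:
    """Whole-architecture goodness of fit.

    A simulated protein is a hit when its terminator-stripped ordered
    domain sequence equals some training architecture's sequence;
    duplicates in the simulated corpus each count.
    """
    if not len(evo.architectures):
        raise ValueError("empty simulated corpus")
    train_types = {a.domains for a in train.architectures}
    total = len(evo.architectures)
    hit = sum(1 for a in evo.architectures if a.domains in train_types)
    return HitAccStat(percent=100.0 * hit / total, hit=hit, total=total)


def extract_ngrams(corpus, n: int) -> NGramCounts:
    """Count all contiguous length-n windows over the terminator-augmented
    architectures; architectures with augmented length < n contribute
    nothing."""
    if n not in (3, 4):
        raise ValueError(f"n must be 3 (triplets) or 4 (quadruples), got {n}")
    counts: Counter[tuple[str, ...]] = Counter()
    for arch in corpus.architectures:
        symbols = augment(arch).symbols
        for i in range(len(symbols) - n + 1):
            counts[symbols[i : i + n]] += 1
    return NGramCounts(n=n, counts=dict(counts))


def hit_acc_ngram(train: Corpus, evo, n: int) -> HitAccStat:
    """n-gram goodness of fit: simulated occurrences of n-gram types that
    also occur in training, over all simulated n-gram occurrences."""
    train_types = set(extract_ngrams(train, n).counts)
    evo_counts = extract_ngrams(evo, n).counts
    total = sum(evo_counts.values())
    if total == 0:
        return HitAccStat(percent=None, hit=0, total=0)
    hit = sum(c for gram, c in evo_counts.items() if gram in train_types)
    return HitAccStat(percent=100.0 * hit / total, hit=hit, total=total)


def hit_acc_report(train: Corpus, evo) -> HitAccReport:
    """DAWP, TAPD (n=3) and QAPD (n=4) in one report."""
    return HitAccReport(
        dawp=hit_acc_dawp(train, evo),
        tapd=hit_acc_ngram(train, evo, 3),
        qapd=hit_acc_ngram(train, evo, 4),
    )


def frequency_table(corpus, level: str) -> FrequencyTable:
    """Frequency table of the corpus at ``level`` "domain" (every domain
    occurrence) or "architecture" (whole-sequence types)."""
    if not len(corpus.architectures):
        raise ValueError("empty corpus")
    counts: Counter[str] = Counter()
    if level == "domain":
        for arch in corpus.architectures:
            counts.update(arch.domains)
    elif level == "architecture":
        for arch in corpus.architectures:
            counts[ARCH_SEPARATOR.join(arch.domains)] += 1
    else:
        raise ValueError(f"level must be 'domain' or 'architecture', got {level!r}")
    return FrequencyTable(counts=dict(counts))


def neighbor_degree_distribution(model: TransitionModel) -> dict[str, int]:
    """Number of distinct immediate neighbor *domains* of each domain.

    A symbol is a neighbor of d when it occurs as d's predecessor or
    successor with positive count; terminators are excluded both as keys
    and from the neighbor sets.  In the trained corpora only a few domains
    have many immediate neighbors (the degree distribution is heavy-tailed).
    """
    neighbors: dict[str, set[str]] = {d: set() for d in model.alphabet}
    for a, b in model.pair_counts:
        if a not in TERMINATORS and b not in TERMINATORS:
            neighbors[a].add(b)
            neighbors[b].add(a)
    return {d: len(ns) for d, ns in neighbors.items()}
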