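"""Reading and writing protein domain-architecture data.

A *domain architecture* is the ordered list of conserved domains along a
protein, N- to C-terminal.  Architectures are obtained either from HMMER3
per-domain tabular output (``--domtblout``, one row per domain hit) filtered
at an E-value threshold, or from plain tab-separated architecture files
(one protein per line: ``protein_id<TAB>Dom1,Dom2,...``).

Coordinates are 1-based inclusive envelope coordinates as printed by HMMER.
Domain names are taken verbatim from the model-name column; no case folding.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

#: Default E-value cutoff for accepting a domain hit.
DEFAULT_MAX_EVALUE = 1e-37

#: Two envelopes conflict when their intersection exceeds this fraction of
#: the shorter envelope; smaller overlaps are kept as consecutive domains
#: (Pfam hits frequently abut with slight envelope overlap).
OVERLAP_TOLERANCE = 0.5

# hmmscan --domtblout column indices (whitespace-delimited, 0-based).
_COL_TARGET_NAME = 0   # Pfam model name
_COL_QUERY_NAME = 3    # protein identifier
_COL_I_EVALUE = 12     # per-domain independent E-value
_COL_ENV_FROM = 19
_COL_ENV_TO = 20
_COL_ACC = 21
_MIN_COLUMNS = 22


class ParseError(ValueError):
    """Raised when an input file violates the expected layout."""


@dataclass(frozen=True)
class DomainHit:
    """One domain annotation on one protein.

    ``acc`` is HMMER's average posterior probability of the aligned
    residues, in [0, 1]; it resolves conflicting overlapping hits.
    """

    protein_id: str
    domain_name: str
    env_start: int
    env_end: int
    e_value: float
    acc: float

    def __post_init__(self) -> None:
        if self.env_start > self.env_end:
            raise ValueError(
                f"env_start {self.env_start} > env_end {self.env_end} "
                f"for {self.domain_name} on {self.protein_id}"
            )
        if not 0.0 <= self.acc <= 1.0:
            raise ValueError(f"acc {self.acc} outside [0, 1]")
        if self.e_value < 0:
            raise ValueError(f"negative E-value {self.e_value}")

    @property
    def env_length(self) -> int:
        return self.env_end - self.env_start + 1


@dataclass(frozen=True)
class Architecture:
    """One protein's ordered domain-name sequence (length >= 1)."""

    protein_id: str
    domains: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.domains) < 1:
            raise ValueError(f"architecture for {self.protein_id} is empty")
        object.__setattr__(self, "domains", tuple(self.domains))

    def __len__(self) -> int:
        return len(self.domains)


@dataclass(frozen=True)
class Corpus:
    """A set of architectures; the training data for the transition model."""

    architectures: tuple[Architecture, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "architectures", tuple(self.architectures))

    @property
    def alphabet(self) -> frozenset[str]:
        """Distinct domain names appearing in any architecture."""
        return frozenset(d for a in self.architectures for d in a.domains)

    @property
    def g(self) -> int:
        """Number of distinct domain classes."""
        return len(self.alphabet)

    @property
    def max_domains(self) -> int:
        """Largest domain count over member proteins (the CA's ``m``)."""
        return max(len(a) for a in self.architectures)

    def __len__(self) -> int:
        return len(self.architectures)

    def __iter__(self):
        return iter(self.architectures)


def parse_domtblout(
    path: Union[str, Path], max_evalue: float = DEFAULT_MAX_EVALUE
) -> list[DomainHit]:
    """Parse a HMMER3 ``--domtblout`` file, keeping hits at or below
    ``max_evalue`` (per-domain independent E-value), in file order.

    Raises :class:`ParseError` naming the offending line for malformed
    data lines (too few columns, non-numeric coordinates).
    """
    hits: list[DomainHit] = []
    with open(path, "r", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < _MIN_COLUMNS:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= {_MIN_COLUMNS} "
                    f"whitespace-delimited columns, found {len(fields)}"
                )
            try:
                hit = DomainHit(
                    protein_id=fields[_COL_QUERY_NAME],
                    domain_name=fields[_COL_TARGET_NAME],
                    env_start=int(fields[_COL_ENV_FROM]),
                    env_end=int(fields[_COL_ENV_TO]),
                    e_value=float(fields[_COL_I_EVALUE]),
                    acc=float(fields[_COL_ACC]),
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if hit.e_value <= max_evalue:
                hits.append(hit)
    return hits


def _overlap(a: DomainHit, b: DomainHit) -> int:
    return min(a.env_end, b.env_end) - max(a.env_start, b.env_start) + 1


def _in_conflict(a: DomainHit, b: DomainHit) -> bool:
    shorter = min(a.env_length, b.env_length)
    return _overlap(a, b) > OVERLAP_TOLERANCE * shorter


def hits_to_architecture(hits: Sequence[DomainHit]) -> Architecture:
    """Resolve one protein's hits into an ordered architecture.

    Hits are ordered by ascending envelope start.  Conflicting overlaps
    (intersection > half the shorter envelope) are resolved by keeping the
    hit with the higher acc, ties broken by lower E-value, then file order.
    """
    if not hits:
        raise ValueError("no domains above threshold")
    ids = {h.protein_id for h in hits}
    if len(ids) != 1:
        raise ValueError(f"hits span multiple proteins: {sorted(ids)}")
    # Greedy acceptance in priority order keeps the best hit of each
    # conflicting cluster.
    ranked = sorted(
        range(len(hits)),
        key=lambda i: (-hits[i].acc, hits[i].e_value, i),
    )
    accepted: list[int] = []
    for i in ranked:
        if all(not _in_conflict(hits[i], hits[j]) for j in accepted):
            accepted.append(i)
    accepted.sort(key=lambda i: (hits[i].env_start, hits[i].env_end, i))
    return Architecture(
        protein_id=hits[0].protein_id,
        domains=tuple(hits[i].domain_name for i in accepted),
    )


def group_hits(hits: Iterable[DomainHit]) -> dict[str, list[DomainHit]]:
    """Group hits by protein, preserving first-appearance order."""
    grouped: dict[str, list[DomainHit]] = {}
    for hit in hits:
        grouped.setdefault(hit.protein_id, []).append(hit)
    return grouped


def corpus_from_hits(hits: Iterable[DomainHit]) -> Corpus:
    """Build a corpus from filtered hits (one architecture per protein)."""
    grouped = group_hits(hits)
    if not grouped:
        raise ValueError("empty corpus: no hits passed the E-value filter")
    return Corpus(
        architectures=tuple(
            hits_to_architecture(protein_hits) for protein_hits in grouped.values()
        )
    )


def read_architectures(path: Union[str, Path]) -> Corpus:
    """Read a plain architecture file: ``protein_id<TAB>Dom1,Dom2,...``
    per line; blank lines ignored."""
    architectures: list[Architecture] = []
    with open(path, "r", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if "\t" not in line:
                raise ParseError(
                    f"{path}: line {lineno}: missing tab separator"
                )
            protein_id, _, domain_field = line.partition("\t")
            domains = [d for d in domain_field.split(",") if d]
            if not protein_id or not domains:
                raise ParseError(
                    f"{path}: line {lineno}: empty protein id or domain list"
                )
            architectures.append(
                Architecture(protein_id=protein_id, domains=tuple(domains))
            )
    if not architectures:
        raise ParseError(f"{path}: empty corpus")
    return Corpus(architectures=tuple(architectures))


def write_architectures(corpus, path: Union[str, Path]) -> None:
    """Write architectures as the plain TSV format read back by
    :func:`read_architectures` (accepts any object with ``.architectures``)."""
    with open(path, "w", encoding="utf-8") as handle:
        for arch in corpus.architectures:
            handle.write(f"{arch.protein_id}\t{','.join(arch.domains)}\n")


def write_frequency_csv(
    table, path: Union[str, Path], top_num: int
) -> None:
    """Write a frequency table as CSV: header ``item,frequency,
    probability_percent``, rows sorted by frequency descending (ties
    lexicographic by item), truncated to ``top_num`` rows.

    ``table`` is a mapping item -> count, or any object exposing one as
    ``.counts``.
    """
    if top_num < 1:
        raise ValueError(f"top_num must be >= 1, got {top_num}")
    counts: Mapping[str, int] = getattr(table, "counts", table)
    total = sum(counts.values())
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_num]
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["item", "frequency", "probability_percent"])
        for item, count in rows:
            writer.writerow([item, count, str(round(100.0 * count / total, 2))])
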