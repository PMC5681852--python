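"""Codon table, mutation categories and exhaustive codon-mutation census.

Codons are the unit of mutation throughout the simulator: changing whole
codons never disrupts a reading frame, and classifying each change as
silent (synonymous) or non-silent (non-synonymous) lets the user control
how much of the nucleotide-level divergence shows up in the protein.

Mutations of a codon are grouped into four categories:

* ``C1`` — one base changed, silent (the amino acid is preserved);
* ``C2`` — one base changed, non-silent;
* ``C3`` — two bases changed (silent or not; silent two-base changes are
  rare, about 1% of the two-base space, so they are not split out);
* ``C4`` — three bases changed (likewise pooled).

Start and stop codons are excluded from the mutation space, both as
sources and as targets, so that a mutation can neither destroy a gene's
start/stop nor create a premature stop.  The default start set is the
bacterial-style {ATG, GTG, TTG}; translation always uses the standard
genetic code (alternative starts still translate to their standard amino
acid — the start set only affects exclusion).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping

from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "CodonTable",
    "MutationCategory",
    "CATEGORIES",
    "MutationSpaceCensus",
    "translate",
    "classify_pair",
    "neighbors",
    "enumerate_census",
]

_BASES = "ACGT"
ALL_CODONS: tuple[str, ...] = tuple("".join(p) for p in product(_BASES, repeat=3))

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
#: Bacterial-style start codons. GTG and TTG are common alternative starts
#: in prokaryotes; they are excluded from the mutable codon space alongside
#: ATG but translate to Val/Leu as usual when internal.
BACTERIAL_START_CODONS = frozenset({"ATG", "GTG", "TTG"})


def _standard_codon_to_aa() -> dict[str, str]:
    mapping = dict(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        mapping[stop] = "*"
    return mapping


@dataclass(frozen=True)
class CodonTable:
    """Genetic code plus the start/stop exclusion set.

    Parameters
    ----------
    codon_to_aa
        Map from all 64 DNA triplets to one-letter amino acids, with stops
        rendered as ``'*'``.
    start_codons, stop_codons
        Codons protected from mutation (excluded as both source and target).
    """

    codon_to_aa: Mapping[str, str] = field(default_factory=_standard_codon_to_aa)
    start_codons: frozenset[str] = BACTERIAL_START_CODONS
    stop_codons: frozenset[str] = STOP_CODONS

    def __post_init__(self) -> None:
        if set(self.codon_to_aa) != set(ALL_CODONS):
            raise ValueError("codon_to_aa must cover exactly the 64 DNA codons")

    @property
    def excluded(self) -> frozenset[str]:
        """Codons removed from the mutation space (starts ∪ stops)."""
        return self.start_codons | self.stop_codons

    @property
    def allowed(self) -> tuple[str, ...]:
        """All codons eligible as mutation sources/targets, in lexical order."""
        return tuple(c for c in ALL_CODONS if c not in self.excluded)

    def aa(self, codon: str) -> str:
        _check_codon(codon)
        return self.codon_to_aa[codon]


DEFAULT_TABLE = CodonTable()


@dataclass(frozen=True)
class MutationCategory:
    """One of the four codon-mutation categories C1..C4.

    ``n_bases`` is the number of nucleotides changed by one event of this
    category; ``silent`` constrains the amino-acid outcome (True = must be
    synonymous, False = must not be, None = unconstrained).
    """

    label: str
    n_bases: int
    silent: bool | None

    def matches(self, distance: int, is_silent: bool) -> bool:
        if distance != self.n_bases:
            return False
        return self.silent is None or self.silent == is_silent


C1 = MutationCategory("C1", 1, True)
C2 = MutationCategory("C2", 1, False)
C3 = MutationCategory("C3", 2, None)
C4 = MutationCategory("C4", 3, None)
CATEGORIES: tuple[MutationCategory, ...] = (C1, C2, C3, C4)
_BY_LABEL = {c.label: c for c in CATEGORIES}


def category(label: str) -> MutationCategory:
    """Look up a category by its ``C1``..``C4`` label."""
    try:
        return _BY_LABEL[label]
    except KeyError:
        raise KeyError(f"unknown mutation category {label!r}") from None


@dataclass(frozen=True)
class MutationSpaceCensus:
    """Counts of ordered codon pairs by (Hamming distance, silent flag).

    Pairs are directed ``src -> dst`` with ``src != dst`` and neither codon
    in the excluded set.  Because synonymy is symmetric, each bucket count
    is even.
    """

    counts: Mapping[tuple[int, bool], int]

    def __getitem__(self, key: tuple[int, bool]) -> int:
        return self.counts.get(key, 0)

    def total(self, distance: int) -> int:
        return self[(distance, True)] + self[(distance, False)]

    def to_rows(self) -> list[tuple[str, int, bool, int]]:
        """Rows (category_label, distance, silent, count) for TSV export."""
        return [
            ("C1", 1, True, self[(1, True)]),
            ("C2", 1, False, self[(1, False)]),
            ("C3", 2, True, self[(2, True)]),
            ("C3", 2, False, self[(2, False)]),
            ("C4", 3, True, self[(3, True)]),
            ("C4", 3, False, self[(3, False)]),
        ]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("category_label\tdistance\tsilent\tcount\n")
            for label, dist, silent, count in self.to_rows():
                fh.write(f"{label}\t{dist}\t{str(silent).lower()}\t{count}\n")


class FrameError(ValueError):
    """Sequence length is not a multiple of 3."""


class AlphabetError(ValueError):
    """Sequence contains symbols outside {A, C, G, T}."""


class ExcludedCodonError(ValueError):
    """A start/stop codon was used where the mutation space forbids it."""


def _check_codon(codon: str) -> None:
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise AlphabetError(f"not a DNA codon: {codon!r}")


def check_dna(seq: str) -> None:
    """Raise :class:`AlphabetError` unless ``seq`` is over {A,C,G,T}."""
    if set(seq) - set(_BASES):
        bad = sorted(set(seq) - set(_BASES))
        raise AlphabetError(f"non-ACGT symbols in sequence: {bad}")


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def translate(seq: str, table: CodonTable = DEFAULT_TABLE) -> str:
    """Translate an in-frame DNA sequence, one symbol per codon, stop as '*'."""
    if len(seq) % 3 != 0:
        raise FrameError(f"sequence length {len(seq)} is not a multiple of 3")
    check_dna(seq)
    return "".join(table.codon_to_aa[seq[i : i + 3]] for i in range(0, len(seq), 3))


def classify_pair(
    src: str, dst: str, table: CodonTable = DEFAULT_TABLE
) -> tuple[int, bool]:
    """Classify a directed codon mutation as (hamming distance, silent flag)."""
    _check_codon(src)
    _check_codon(dst)
    if src == dst:
        raise ValueError(f"degenerate pair: {src} -> {dst}")
    if src in table.excluded or dst in table.excluded:
        raise ExcludedCodonError(
            f"pair {src} -> {dst} touches the excluded start/stop set"
        )
    return hamming(src, dst), table.aa(src) == table.aa(dst)


# Neighborhoods are queried once per mutation event; memoize them per table.
# Keyed by table identity, with a strong reference to the table so an id is
# never reused while its cache entry lives.
_NEIGHBOR_CACHE: dict[int, tuple[CodonTable, dict[tuple[str, str], frozenset[str]]]] = {}


def neighbors(
    src: str, cat: MutationCategory, table: CodonTable = DEFAULT_TABLE
) -> frozenset[str]:
    """All target codons reachable from ``src`` by one event of ``cat``.

    May be empty: e.g. TGG (Trp) has no silent one-base neighbor, so
    ``neighbors("TGG", C1)`` is the empty set.
    """
    _check_codon(src)
    if src in table.excluded:
        raise ExcludedCodonError(f"source codon {src} is in the excluded set")
    entry = _NEIGHBOR_CACHE.get(id(table))
    if entry is None or entry[0] is not table:
        entry = (table, {})
        _NEIGHBOR_CACHE[id(table)] = entry
    cache = entry[1]
    key = (src, cat.label)
    if key not in cache:
        out = []
        for dst in table.allowed:
            if dst == src:
                continue
            dist, silent = classify_pair(src, dst, table)
            if cat.matches(dist, silent):
                out.append(dst)
        cache[key] = frozenset(out)
    return cache[key]


def enumerate_census(table: CodonTable = DEFAULT_TABLE) -> MutationSpaceCensus:
    """Exhaustively enumerate the codon-mutation space.

    Loops over all ordered pairs of non-excluded codons and buckets them
    by Hamming distance and synonymy.  Under the default exclusion set
    this yields 124 one-base silent, 356 one-base non-silent, 12
    three-base silent and 1,400 three-base non-silent mutations.
    """
    counts: dict[tuple[int, bool], int] = {}
    allowed = table.allowed
    for src in allowed:
        aa_src = table.aa(src)
        for dst in allowed:
            if src == dst:
                continue
            key = (hamming(src, dst), aa_src == table.aa(dst))
            counts[key] = counts.get(key, 0) + 1
    return MutationSpaceCensus(counts)
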