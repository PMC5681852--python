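"""Insert gene cassettes into recipient genomes at random breakpoints.

Each (optionally mutated) gene is wrapped with a fixed flanking sequence
on both ends — mimicking, e.g., transposon insertion context — and the
resulting cassette is inserted additively into a recipient genome.
Breakpoints are either uniform over the genome's concatenated length or
the midpoints of randomly chosen intergenic regions (when an annotation
is available).  Every insertion is recorded with its 1-based position in
the ORIGINAL (pre-insertion) coordinates, so excising the cassettes in
descending position order restores the original genome byte-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genetic_code import check_dna
from .records import SequenceRecord, reverse_complement

__all__ = [
    "RecipientGenome",
    "IntergenicRegion",
    "InsertionEvent",
    "add_flanks",
    "assign_genes",
    "select_breakpoints",
    "insert_genes",
    "write_insertion_report",
    "read_insertion_report",
    "excise",
    "intergenic_regions_from_features",
]


class CapacityError(ValueError):
    """More insertions requested than distinct breakpoints available."""


@dataclass(frozen=True)
class RecipientGenome:
    """A recipient: one or more replicons/contigs under a single genome id."""

    id: str
    sequences: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        ids = [s.id for s in self.sequences]
        if len(set(ids)) != len(ids):
            raise ValueError(f"genome {self.id}: duplicate sequence ids")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences)

    def sequence(self, seq_id: str) -> SequenceRecord:
        for s in self.sequences:
            if s.id == seq_id:
                return s
        raise KeyError(f"genome {self.id} has no sequence {seq_id!r}")


@dataclass(frozen=True)
class IntergenicRegion:
    """0-based half-open interval between annotated features."""

    seq_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class InsertionEvent:
    """One cassette placed AFTER base ``break_position`` (1-based; 0 = front)."""

    recipient_id: str
    seq_id: str
    break_position: int
    gene_id: str
    cassette_length: int
    flank_length: int


def add_flanks(gene_seq: str, flank: str) -> str:
    """Wrap a gene with the same flank on both ends: flank + gene + flank."""
    if flank:
        check_dna(flank)
    return flank + gene_seq + flank


def assign_genes(
    gene_ids: Sequence[str],
    recipient_ids: Sequence[str],
    rng: np.random.Generator | None = None,
    even: bool = False,
    fixed: Mapping[str, str] | None = None,
) -> dict[str, list[str]]:
    """Assign each gene to one recipient.

    Default is uniform random assignment; ``even=True`` deals genes round-
    robin after a shuffle (equal counts when divisible); ``fixed`` maps
    gene id -> recipient id and bypasses the RNG.
    """
    if not recipient_ids:
        raise ValueError("need at least one recipient genome")
    out: dict[str, list[str]] = {r: [] for r in recipient_ids}
    if fixed is not None:
        for g, r in fixed.items():
            out[r].append(g)
        return out
    rng = np.random.default_rng() if rng is None else rng
    order = list(gene_ids)
    if even:
        order = [order[i] for i in rng.permutation(len(order))]
        for k, g in enumerate(order):
            out[recipient_ids[k % len(recipient_ids)]].append(g)
    else:
        for g in order:
            out[recipient_ids[int(rng.integers(len(recipient_ids)))]].append(g)
    return out


def _concat_to_local(
    genome: RecipientGenome, positions: Iterable[int]
) -> list[tuple[str, int]]:
    """Map 1-based positions on the concatenated genome back to (seq, offset)."""
    bounds = []
    offset = 0
    for s in genome.sequences:
        bounds.append((offset, offset + len(s), s.id))
        offset += len(s)
    out = []
    for p in positions:
        for lo, hi, sid in bounds:
            if lo < p <= hi:
                out.append((sid, p - lo))
                break
        else:
            raise ValueError(f"position {p} outside genome of length {offset}")
    return out


def select_breakpoints(
    genome: RecipientGenome,
    n: int,
    mode: str = "uniform",
    regions: Sequence[IntergenicRegion] | None = None,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, int]]:
    """Choose ``n`` distinct cut points in a recipient genome.

    ``uniform`` draws distinct positions from 1..P over the concatenated
    replicon space, so longer replicons receive proportionally more
    insertions.  ``intergenic`` draws distinct annotated gaps and cuts each
    at its midpoint, guaranteeing no cassette lands inside a feature.
    """
    rng = np.random.default_rng() if rng is None else rng
    if n == 0:
        return []
    if mode == "uniform":
        total = genome.total_length
        if n > total:
            raise CapacityError(
                f"{n} breakpoints requested but genome {genome.id} has only "
                f"{total} positions"
            )
        picks = rng.choice(total, size=n, replace=False) + 1
        return _concat_to_local(genome, picks.tolist())
    if mode == "intergenic":
        if not regions:
            raise CapacityError(
                f"intergenic mode needs annotated regions for genome {genome.id}"
            )
        if n > len(regions):
            raise CapacityError(
                f"{n} breakpoints requested but genome {genome.id} has only "
                f"{len(regions)} intergenic regions"
            )
        idx = rng.choice(len(regions), size=n, replace=False)
        return [(regions[i].seq_id, regions[i].midpoint) for i in idx]
    raise ValueError(f"unknown breakpoint mode {mode!r}")


def insert_genes(
    genome: RecipientGenome,
    placements: Sequence[tuple[str, int, str, str]],
    flank_length: int = 0,
) -> tuple[RecipientGenome, list[InsertionEvent]]:
    """Insert cassettes; returns the modified genome and the event records.

    ``placements`` are (seq_id, break_position, cassette_seq, gene_id) with
    break positions in original 1-based insert-after coordinates.  Within a
    sequence the cassettes are spliced right-to-left so every recorded
    position stays valid in the original frame.
    """
    by_seq: dict[str, list[tuple[int, str, str]]] = {}
    for seq_id, pos, cassette, gene_id in placements:
        by_seq.setdefault(seq_id, []).append((pos, cassette, gene_id))
    events: list[InsertionEvent] = []
    new_seqs: list[SequenceRecord] = []
    for s in genome.sequences:
        todo = by_seq.pop(s.id, [])
        positions = [p for p, _, _ in todo]
        if len(set(positions)) != len(positions):
            raise ValueError(f"duplicate break position on sequence {s.id}")
        for p in positions:
            if not 0 <= p <= len(s):
                raise ValueError(
                    f"break position {p} outside sequence {s.id} (length {len(s)})"
                )
        seq = s.seq
        for pos, cassette, gene_id in sorted(todo, reverse=True):
            seq = seq[:pos] + cassette + seq[pos:]
            events.append(
                InsertionEvent(
                    genome.id, s.id, pos, gene_id, len(cassette), flank_length
                )
            )
        new_seqs.append(SequenceRecord(s.id, seq))
    if by_seq:
        raise KeyError(f"placements reference unknown sequences: {sorted(by_seq)}")
    events.sort(key=lambda e: (e.recipient_id, e.seq_id, e.break_position))
    return RecipientGenome(genome.id, tuple(new_seqs)), events


def excise(modified: RecipientGenome, events: Sequence[InsertionEvent]) -> RecipientGenome:
    """Remove recorded cassettes, restoring the original genome byte-exactly."""
    by_seq: dict[str, list[InsertionEvent]] = {}
    for ev in events:
        if ev.recipient_id == modified.id:
            by_seq.setdefault(ev.seq_id, []).append(ev)
    out = []
    for s in modified.sequences:
        seq = s.seq
        # Ascending order: removing an earlier cassette restores the original
        # frame for everything downstream, so recorded positions stay valid.
        for ev in sorted(by_seq.get(s.id, []), key=lambda e: e.break_position):
            start = ev.break_position
            seq = seq[:start] + seq[start + ev.cassette_length :]
        out.append(SequenceRecord(s.id, seq))
    return RecipientGenome(modified.id, tuple(out))


REPORT_COLUMNS = [
    "recipient_id",
    "seq_id",
    "break_position",
    "gene_id",
    "flank_length",
    "cassette_length",
]


def write_insertion_report(
    events: Iterable[InsertionEvent], path: str | Path
) -> None:
    rows = sorted(
        (
            (e.recipient_id, e.seq_id, e.break_position, e.gene_id,
             e.flank_length, e.cassette_length)
            for e in events
        ),
    )
    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(map(str, row)) + "\n")


def read_insertion_report(path: str | Path) -> list[InsertionEvent]:
    df = pd.read_csv(path, sep="\t")
    return [
        InsertionEvent(
            str(r.recipient_id),
            str(r.seq_id),
            int(r.break_position),
            str(r.gene_id),
            int(r.cassette_length),
            int(r.flank_length),
        )
        for r in df.itertuples(index=False)
    ]


def intergenic_regions_from_features(
    sequence: SequenceRecord,
    features: Sequence[tuple[int, int]],
    min_length: int = 1,
) -> list[IntergenicRegion]:
    """Complement of the union of feature intervals on one sequence.

    ``features`` are 0-based half-open (start, end) intervals; overlaps are
    merged.  Gaps shorter than ``min_length`` are dropped.
    """
    merged: list[list[int]] = []
    for start, end in sorted(features):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    gaps = []
    prev = 0
    for start, end in merged:
        if start - prev >= min_length and start > prev:
            gaps.append(IntergenicRegion(sequence.id, prev, start))
        prev = max(prev, end)
    if len(sequence) - prev >= min_length and len(sequence) > prev:
        gaps.append(IntergenicRegion(sequence.id, prev, len(sequence)))
    return gaps
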