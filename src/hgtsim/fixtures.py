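"""Synthetic donors, recipients, annotations and "perfect assembly" contigs.

Every pipeline stage is testable offline: this module fabricates in-frame
donor CDS sequences, random recipient genomes at a requested GC content,
non-overlapping feature annotations (hence intergenic regions), and
idealized contigs that reconstruct each planted cassette with a chosen
amount of true recipient context on each side — the oracle input for the
recovery evaluator.  Defaults emulate the shape of a ten-donor/ten-
recipient transfer experiment at a reduced scale for fast test runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genetic_code import DEFAULT_TABLE, CodonTable
from .mutation_engine import GeneRecord
from .records import SequenceRecord, write_fasta
from .recovery_eval import AlignmentHit
from .transfer_engine import InsertionEvent, IntergenicRegion, RecipientGenome

__all__ = [
    "FixtureSpec",
    "generate_cds",
    "generate_genome",
    "generate_features",
    "write_gff3",
    "read_gff3_intervals",
    "perfect_contigs",
    "exact_gene_hits",
    "generate_community",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class FixtureSpec:
    """Scale and composition knobs for a synthetic community."""

    n_donor_genes: int = 20
    gene_length_codons: tuple[int, int] = (100, 400)
    n_recipients: int = 3
    recipient_length: tuple[int, int] = (150_000, 250_000)
    gc_content: float = 0.5
    n_features: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gene_length_codons[0] < 3:
            raise ValueError("genes need at least 3 codons")
        if not 0 < self.gc_content < 1:
            raise ValueError("GC content must be in (0, 1)")
        if min(self.n_donor_genes, self.n_recipients, self.n_features) < 0:
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_json(cls, path: str | Path) -> "FixtureSpec":
        with open(path) as fh:
            data = json.load(fh)
        for key in ("gene_length_codons", "recipient_length"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def generate_cds(
    n_codons: int,
    table: CodonTable = DEFAULT_TABLE,
    rng: np.random.Generator | None = None,
    gene_id: str = "gene",
) -> GeneRecord:
    """A valid CDS: start codon + internal non-excluded codons + stop codon.

    Internal codons avoid the whole excluded set, so no internal stops and
    every internal codon is a legal mutation source.
    """
    if n_codons < 3:
        raise ValueError("a CDS needs at least 3 codons (start, body, stop)")
    rng = np.random.default_rng() if rng is None else rng
    start = sorted(table.start_codons)[int(rng.integers(len(table.start_codons)))]
    stop = sorted(table.stop_codons)[int(rng.integers(len(table.stop_codons)))]
    allowed = table.allowed
    internal = [
        allowed[int(i)] for i in rng.integers(len(allowed), size=n_codons - 2)
    ]
    return GeneRecord(gene_id, start + "".join(internal) + stop)


def generate_genome(
    length: int,
    gc: float = 0.5,
    rng: np.random.Generator | None = None,
    seq_id: str = "chr",
) -> SequenceRecord:
    """I.i.d. random genome at the requested GC content."""
    if length <= 0:
        raise ValueError("genome length must be positive")
    rng = np.random.default_rng() if rng is None else rng
    return SequenceRecord(seq_id, _random_bases(rng, length, gc))


def generate_features(
    genome: SequenceRecord,
    n_features: int,
    rng: np.random.Generator | None = None,
    feature_length: tuple[int, int] = (500, 2000),
    min_gap: int = 100,
) -> list[tuple[int, int]]:
    """Non-overlapping 0-based feature intervals leaving intergenic gaps."""
    rng = np.random.default_rng() if rng is None else rng
    if n_features == 0:
        return []
    max_need = n_features * (feature_length[1] + min_gap) + min_gap
    if max_need > len(genome):
        raise ValueError(
            f"cannot pack {n_features} features of up to {feature_length[1]} bp "
            f"into {len(genome)} bp with {min_gap} bp gaps"
        )
    lengths = rng.integers(feature_length[0], feature_length[1] + 1, size=n_features)
    slack = len(genome) - int(lengths.sum()) - (n_features + 1) * min_gap
    cuts = np.sort(rng.integers(0, slack + 1, size=n_features + 1))
    gaps = np.diff(np.concatenate([[0], cuts])) + min_gap
    features = []
    pos = 0
    for gap, flen in zip(gaps, lengths):
        pos += int(gap)
        features.append((pos, pos + int(flen)))
        pos += int(flen)
    return features


def write_gff3(
    path: str | Path,
    seq_id: str,
    features: Sequence[tuple[int, int]],
    feature_type: str = "gene",
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, (start, end) in enumerate(features):
            fh.write(
                f"{seq_id}\thgtsim\t{feature_type}\t{start + 1}\t{end}\t.\t+\t.\t"
                f"ID={feature_type}_{i + 1}\n"
            )


def read_gff3_intervals(
    path: str | Path, feature_types: Sequence[str] = ("gene",)
) -> dict[str, list[tuple[int, int]]]:
    """Feature intervals per sequence id, 0-based half-open."""
    wanted = set(feature_types)
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9 or cols[2] not in wanted:
                continue
            out.setdefault(cols[0], []).append((int(cols[3]) - 1, int(cols[4])))
    for intervals in out.values():
        intervals.sort()
    return out


def perfect_contigs(
    modified: RecipientGenome,
    insertions: Sequence[InsertionEvent],
    context: int,
) -> list[SequenceRecord]:
    """Idealized contigs: each planted cassette plus ``context`` true
    recipient bases on each side, clipped at sequence ends.

    Emulates a flawless assembler so the recovery criterion can be tested
    at known flank lengths.
    """
    if context < 0:
        raise ValueError("context must be non-negative")
    contigs = []
    events = [e for e in insertions if e.recipient_id == modified.id]
    by_seq: dict[str, list[InsertionEvent]] = {}
    for ev in events:
        by_seq.setdefault(ev.seq_id, []).append(ev)
    for seq_id, seq_events in by_seq.items():
        seq = modified.sequence(seq_id).seq
        shift = 0
        for ev in sorted(seq_events, key=lambda e: e.break_position):
            start = ev.break_position + shift  # cassette start, modified frame
            end = start + ev.cassette_length
            lo = max(0, start - context)
            hi = min(len(seq), end + context)
            contigs.append(SequenceRecord(f"contig_{ev.gene_id}", seq[lo:hi]))
            shift += ev.cassette_length
    return contigs


def exact_gene_hits(
    genes: Mapping[str, str], contigs: Sequence[SequenceRecord]
) -> list[AlignmentHit]:
    """Synthetic full-length, 100%-identity hits by exact substring search.

    Stands in for an external nucleotide aligner on error-free contigs,
    producing the same 12-column records a tabular alignment run would.
    """
    from .records import reverse_complement

    hits = []
    for gene_id, gene_seq in genes.items():
        L = len(gene_seq)
        for contig in contigs:
            for strand_seq, minus in ((gene_seq, False), (reverse_complement(gene_seq), True)):
                pos = contig.seq.find(strand_seq)
                while pos != -1:
                    s_start, s_end = (
                        (pos + L, pos + 1) if minus else (pos + 1, pos + L)
                    )
                    hits.append(
                        AlignmentHit(
                            gene_id, contig.id, 100.0, L, 0, 0,
                            1, L, s_start, s_end, 0.0, 2.0 * L,
                        )
                    )
                    pos = contig.seq.find(strand_seq, pos + 1)
    return hits


def generate_community(
    spec: FixtureSpec,
) -> tuple[
    list[GeneRecord],
    list[RecipientGenome],
    dict[str, list[IntergenicRegion]],
    dict[str, list[tuple[int, int]]],
]:
    """Donor genes, recipient genomes, intergenic regions and raw features."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.gene_length_codons
    genes = [
        generate_cds(
            int(rng.integers(lo, hi + 1)), DEFAULT_TABLE, rng, f"donor_gene_{i + 1}"
        )
        for i in range(spec.n_donor_genes)
    ]
    recipients = []
    regions: dict[str, list[IntergenicRegion]] = {}
    features: dict[str, list[tuple[int, int]]] = {}
    from .transfer_engine import intergenic_regions_from_features

    for j in range(spec.n_recipients):
        length = int(rng.integers(spec.recipient_length[0], spec.recipient_length[1] + 1))
        gid = f"recipient_{j + 1}"
        seq = generate_genome(length, spec.gc_content, rng, seq_id=f"{gid}_chr")
        feats = generate_features(seq, spec.n_features, rng)
        recipients.append(RecipientGenome(gid, (seq,)))
        regions[gid] = intergenic_regions_from_features(seq, feats)
        features[gid] = feats
    return genes, recipients, regions, features


def write_fixture_set(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Materialize a fixture set on disk: FASTA, GFF3 and an abundance TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genes, recipients, _, features = generate_community(spec)
    paths: dict[str, Path] = {}
    gene_path = out / "donor_genes.fasta"
    write_fasta([SequenceRecord(g.id, g.seq) for g in genes], gene_path)
    paths["genes"] = gene_path
    abundance = out / "abundance.tsv"
    with open(abundance, "w") as fh:
        fh.write("genome_id\tweight\n")
        for rec in recipients:
            fh.write(f"{rec.id}\t1\n")
    paths["abundance"] = abundance
    recipients_dir = out / "recipients"
    recipients_dir.mkdir(exist_ok=True)
    paths["recipients_dir"] = recipients_dir
    for rec in recipients:
        fasta = recipients_dir / f"{rec.id}.fasta"
        write_fasta(rec.sequences, fasta)
        paths[rec.id] = fasta
        gff = recipients_dir / f"{rec.id}.gff3"
        write_gff3(gff, rec.sequences[0].id, features[rec.id])
        paths[f"{rec.id}_gff"] = gff
    with open(out / "fixture_spec.json", "w") as fh:
        json.dump(asdict(spec), fh, indent=2)
    return paths
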