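"""Error-free paired-end read simulation from a genome community.

Fragments of exactly ``insert_size`` bases (insert size = total fragment
length) are drawn from community members; the forward read is the
fragment's 5' prefix and the reverse read is the reverse complement of
its 3' suffix (FR orientation).  With 100 bp reads and a 250 bp insert
the mates leave a 50 bp inner gap; with 250 bp reads they overlap fully.

The member sequenced for each pair is chosen with probability
proportional to ``abundance weight x member length``, so that equal
weights produce an even sequencing DEPTH across genomes of different
sizes.  Reads are error-free: every read is an exact substring of its
origin sequence or of its reverse complement, and the provenance of each
pair (genome, sequence, fragment start, strand) is retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .records import SequenceRecord, reverse_complement

__all__ = [
    "CommunityProfile",
    "ReadPair",
    "expected_depth",
    "simulate_reads",
    "write_fastq",
    "read_fastq_pairs",
]


@dataclass(frozen=True)
class CommunityProfile:
    """Relative abundance weights and total lengths of community members."""

    members: tuple[tuple[str, float, int], ...]  # (genome id, weight, length)

    def __post_init__(self) -> None:
        if not any(w > 0 for _, w, _ in self.members):
            raise ValueError("community needs at least one member with weight > 0")
        if any(w < 0 for _, w, _ in self.members):
            raise ValueError("abundance weights must be non-negative")

    @property
    def total_length(self) -> int:
        return sum(length for _, _, length in self.members)

    @classmethod
    def uniform(cls, genomes: Mapping[str, Sequence[SequenceRecord]]) -> "CommunityProfile":
        """Equal-weight profile (relative abundances all set to one)."""
        return cls(
            tuple(
                (gid, 1.0, sum(len(s) for s in seqs))
                for gid, seqs in genomes.items()
            )
        )


@dataclass(frozen=True)
class ReadPair:
    pair_id: str
    r1_seq: str
    r2_seq: str
    genome_id: str
    seq_id: str
    fragment_start: int  # 0-based on the forward strand of the origin
    strand: str  # '+' or '-'


def expected_depth(
    profile: CommunityProfile, n_pairs: int, read_length: int
) -> float:
    """Mean fold-coverage of the community: ``n_pairs * 2 * read_length / total``.

    Assumes the uniform-abundance case where sequencing effort is spread
    evenly over the community's total length.
    """
    total = profile.total_length
    if total <= 0:
        raise ValueError("community total length must be positive")
    return n_pairs * 2 * read_length / total


def simulate_reads(
    genomes: Mapping[str, Sequence[SequenceRecord]],
    profile: CommunityProfile,
    n_pairs: int,
    read_length: int = 100,
    insert_size: int = 250,
    rng: np.random.Generator | None = None,
    insert_sd: float = 0.0,
    chunk: int = 100_000,
) -> Iterator[ReadPair]:
    """Stream ``n_pairs`` error-free pairs from the community.

    Member choice is weight x length; the fragment start is uniform over
    valid positions of a length-weighted random sequence of that member;
    the fragment strand is uniform.  ``insert_sd`` adds optional normal
    jitter to the fragment length (default 0: fixed-length fragments).
    Memory use is independent of ``n_pairs``.
    """
    if insert_size < read_length:
        raise ValueError("insert size (fragment length) must be >= read length")
    rng = np.random.default_rng() if rng is None else rng

    members = []
    for gid, weight, _ in profile.members:
        if weight <= 0:
            continue
        seqs = [s for s in genomes[gid] if len(s) >= insert_size]
        if not seqs:
            raise ValueError(
                f"member {gid}: no sequence long enough for a {insert_size} bp fragment"
            )
        lengths = np.array([len(s) for s in seqs], dtype=float)
        members.append((gid, weight * sum(len(s) for s in genomes[gid]), seqs, lengths))
    probs = np.array([m[1] for m in members])
    probs = probs / probs.sum()

    emitted = 0
    while emitted < n_pairs:
        batch = min(chunk, n_pairs - emitted)
        member_idx = rng.choice(len(members), size=batch, p=probs)
        strands = rng.integers(2, size=batch)
        if insert_sd > 0:
            frag_lens = np.maximum(
                read_length,
                np.rint(rng.normal(insert_size, insert_sd, size=batch)).astype(int),
            )
        else:
            frag_lens = np.full(batch, insert_size, dtype=int)
        for k in range(batch):
            gid, _, seqs, lengths = members[member_idx[k]]
            frag_len = int(frag_lens[k])
            valid = lengths >= frag_len
            seq_weights = np.where(valid, lengths - frag_len + 1, 0.0)
            seq = seqs[int(rng.choice(len(seqs), p=seq_weights / seq_weights.sum()))]
            start = int(rng.integers(len(seq) - frag_len + 1))
            fragment = seq.seq[start : start + frag_len]
            strand = "+" if strands[k] == 0 else "-"
            if strand == "-":
                fragment = reverse_complement(fragment)
            r1 = fragment[:read_length]
            r2 = reverse_complement(fragment[-read_length:])
            emitted += 1
            yield ReadPair(
                f"read_{emitted}", r1, r2, gid, seq.id, start, strand
            )


def write_fastq(
    pairs: Iterable[ReadPair],
    r1_path: str | Path,
    r2_path: str | Path,
    provenance_path: str | Path | None = None,
) -> int:
    """Write mates to R1/R2 FASTQ (maximal qualities, ids suffixed /1 and /2).

    Optionally records per-pair provenance as TSV.  Returns the pair count.
    """
    n = 0
    prov = open(provenance_path, "w") if provenance_path else None
    try:
        if prov:
            prov.write("pair_id\tgenome_id\tseq_id\tfragment_start\tstrand\n")
        with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
            for p in pairs:
                f1.write(f"@{p.pair_id}/1\n{p.r1_seq}\n+\n{'I' * len(p.r1_seq)}\n")
                f2.write(f"@{p.pair_id}/2\n{p.r2_seq}\n+\n{'I' * len(p.r2_seq)}\n")
                if prov:
                    prov.write(
                        f"{p.pair_id}\t{p.genome_id}\t{p.seq_id}\t"
                        f"{p.fragment_start}\t{p.strand}\n"
                    )
                n += 1
    finally:
        if prov:
            prov.close()
    return n


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (pair id, r1 sequence, r2 sequence) from a FASTQ pair."""
    from Bio import SeqIO

    for rec1, rec2 in zip(
        SeqIO.parse(str(r1_path), "fastq"), SeqIO.parse(str(r2_path), "fastq")
    ):
        pid = rec1.id.rsplit("/", 1)[0]
        yield pid, str(rec1.seq), str(rec2.seq)
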