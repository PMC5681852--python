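"""Judge whether planted gene transfers were recovered from assembled contigs.

A planted transfer counts as recovered when some contig carries the gene
at >= 99% identity over >= 99% of the gene's length AND at least one of
the contig regions flanking the gene match is longer than 1 kb and
matches the recipient genome.  Strictness: a 1,001 bp flank qualifies, a
1,000 bp flank does not.

Alignment is delegated: the module consumes the standard 12-column
tabular hit format (blastn ``-outfmt 6`` and compatible aligners) for
gene-vs-contig hits, and judges flank/recipient matching either from a
second hit table (flanks vs recipients) or with a built-in exact
substring matcher — sufficient for error-free synthetic contigs and
requiring no external binary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .records import SequenceRecord, reverse_complement
from .transfer_engine import InsertionEvent, RecipientGenome

__all__ = [
    "AlignmentHit",
    "RecoveryRecord",
    "read_hit_table",
    "write_hit_table",
    "filter_hits",
    "match_flank_exact",
    "assess_recovery",
    "summarize",
]

#: Column order of the standard 12-column tabular alignment format.
HIT_COLUMNS = [
    "query_id",
    "subject_id",
    "percent_identity",
    "alignment_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "e_value",
    "bit_score",
]


@dataclass(frozen=True)
class AlignmentHit:
    """One row of a 12-column tabular alignment file.

    Query coordinates satisfy ``q_start <= q_end``; subject coordinates may
    be reversed for minus-strand hits.  All coordinates are 1-based
    inclusive.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float

    @property
    def s_lo(self) -> int:
        return min(self.s_start, self.s_end)

    @property
    def s_hi(self) -> int:
        return max(self.s_start, self.s_end)


@dataclass(frozen=True)
class RecoveryRecord:
    """Verdict for one planted transfer."""

    gene_id: str
    recipient_id: str
    recovered: bool
    contig_id: str | None = None
    left_flank_len: int = 0
    right_flank_len: int = 0
    left_matches: bool = False
    right_matches: bool = False


def read_hit_table(path: str | Path) -> list[AlignmentHit]:
    """Read a headerless 12-column tabular hit file."""
    df = pd.read_csv(path, sep="\t", names=HIT_COLUMNS, header=None, comment="#")
    return [AlignmentHit(**row) for row in df.to_dict("records")]


def write_hit_table(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(getattr(h, c)) for c in HIT_COLUMNS
                )
                + "\n"
            )


def filter_hits(
    hits: Sequence[AlignmentHit],
    gene_lengths: Mapping[str, int],
    min_identity: float = 99.0,
    min_coverage: float = 99.0,
) -> list[AlignmentHit]:
    """Keep hits passing the identity and query-coverage cutoffs.

    Coverage is the aligned fraction of the QUERY (the transferred gene):
    ``100 * (q_end - q_start + 1) / gene_length``.
    """
    kept = []
    for h in hits:
        if h.query_id not in gene_lengths:
            raise KeyError(f"hit query {h.query_id!r} has no recorded gene length")
        coverage = 100.0 * (h.q_end - h.q_start + 1) / gene_lengths[h.query_id]
        if h.percent_identity >= min_identity and coverage >= min_coverage:
            kept.append(h)
    return kept


def match_flank_exact(flank_seq: str, recipient: RecipientGenome) -> bool:
    """True iff the flank (or its reverse complement) occurs in the recipient.

    Exact substring search on either strand — the appropriate matcher for
    error-free synthetic contigs.
    """
    if not flank_seq:
        return False
    rc = reverse_complement(flank_seq)
    return any(flank_seq in s.seq or rc in s.seq for s in recipient.sequences)


def _ranked(hits: Sequence[AlignmentHit]) -> list[AlignmentHit]:
    # highest bit score, then longer alignment, then lexicographic contig id
    return sorted(
        hits, key=lambda h: (-h.bit_score, -h.alignment_length, h.subject_id)
    )


def assess_recovery(
    insertions: Sequence[InsertionEvent],
    gene_hits: Sequence[AlignmentHit],
    contigs: Mapping[str, SequenceRecord],
    recipients: Mapping[str, RecipientGenome],
    min_flank: int = 1000,
    exact_fraction: float = 0.95,
    flank_hits: Sequence[AlignmentHit] | None = None,
    flank_min_identity: float = 99.0,
    flank_min_coverage: float = 95.0,
) -> list[RecoveryRecord]:
    """Evaluate the recovery criterion for every planted transfer.

    For each planted gene, take the best pre-filtered contig hit, measure
    the contig sequence outside the gene match on each side, and test each
    flank against the recipient genome.  A flank matches either when a
    supplied flank-vs-recipient hit table contains a qualifying hit
    (identity >= ``flank_min_identity`` covering >= ``flank_min_coverage``
    percent of the flank) or, by default, when at least ``exact_fraction``
    of the flank is found verbatim in the recipient (the flank itself or a
    trimmed core of that fraction).  Recovery requires a matching flank
    strictly longer than ``min_flank``.
    """
    hits_by_gene: dict[str, list[AlignmentHit]] = {}
    for h in gene_hits:
        hits_by_gene.setdefault(h.query_id, []).append(h)
    flank_index: dict[str, list[AlignmentHit]] = {}
    if flank_hits is not None:
        for h in flank_hits:
            flank_index.setdefault(h.query_id, []).append(h)

    def flank_matches(
        flank_seq: str, recipient: RecipientGenome, flank_query_id: str
    ) -> bool:
        if flank_hits is not None:
            for h in flank_index.get(flank_query_id, []):
                coverage = 100.0 * (h.q_end - h.q_start + 1) / len(flank_seq)
                if (
                    h.subject_id in {s.id for s in recipient.sequences}
                    and h.percent_identity >= flank_min_identity
                    and coverage >= flank_min_coverage
                ):
                    return True
            return False
        if match_flank_exact(flank_seq, recipient):
            return True
        # tolerate ragged contig ends: an exact core covering >= the
        # required fraction of the flank still counts
        core = int(len(flank_seq) * exact_fraction)
        if 0 < core < len(flank_seq):
            trim = len(flank_seq) - core
            return match_flank_exact(
                flank_seq[trim:], recipient
            ) or match_flank_exact(flank_seq[:-trim], recipient)
        return False

    records = []
    for ev in insertions:
        gene_hits_here = hits_by_gene.get(ev.gene_id, [])
        if not gene_hits_here:
            records.append(RecoveryRecord(ev.gene_id, ev.recipient_id, False))
            continue
        recipient = recipients[ev.recipient_id]
        verdict: RecoveryRecord | None = None
        # walk hits best-first; the transfer is recovered if ANY qualifying
        # contig shows a matching long flank, so keep scanning past hits
        # whose flanks fail (e.g. the gene echoed near another cassette)
        for h in _ranked(gene_hits_here):
            try:
                contig = contigs[h.subject_id]
            except KeyError:
                raise KeyError(f"contig {h.subject_id!r} missing from FASTA") from None
            left_len = h.s_lo - 1
            right_len = len(contig.seq) - h.s_hi
            left_ok = left_len > min_flank and flank_matches(
                contig.seq[:left_len], recipient, f"{ev.gene_id}|left"
            )
            right_ok = right_len > min_flank and flank_matches(
                contig.seq[h.s_hi :], recipient, f"{ev.gene_id}|right"
            )
            record = RecoveryRecord(
                ev.gene_id,
                ev.recipient_id,
                left_ok or right_ok,
                h.subject_id,
                left_len,
                right_len,
                left_ok,
                right_ok,
            )
            if verdict is None:
                verdict = record  # best hit's measurements by default
            if record.recovered:
                verdict = record
                break
        records.append(verdict)
    return records


def summarize(records: Sequence[RecoveryRecord]) -> pd.DataFrame:
    """Recovered / total per recipient, with an overall row."""
    df = pd.DataFrame(
        [(r.recipient_id, r.recovered) for r in records],
        columns=["recipient_id", "recovered"],
    )
    if df.empty:
        return pd.DataFrame(columns=["recipient_id", "recovered", "total"])
    per = (
        df.groupby("recipient_id")["recovered"]
        .agg(recovered="sum", total="count")
        .reset_index()
    )
    overall = pd.DataFrame(
        [
            {
                "recipient_id": "ALL",
                "recovered": int(df["recovered"].sum()),
                "total": len(df),
            }
        ]
    )
    per["recovered"] = per["recovered"].astype(int)
    return pd.concat([per, overall], ignore_index=True)


def write_recovery_tables(
    records: Sequence[RecoveryRecord], detail_path: str | Path, summary_path: str | Path
) -> None:
    detail = pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "recipient_id": r.recipient_id,
                "recovered": r.recovered,
                "contig_id": r.contig_id or "",
                "left_flank_len": r.left_flank_len,
                "right_flank_len": r.right_flank_len,
                "left_matches": r.left_matches,
                "right_matches": r.right_matches,
            }
            for r in records
        ]
    )
    detail.to_csv(detail_path, sep="\t", index=False)
    summarize(records).to_csv(summary_path, sep="\t", index=False)
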