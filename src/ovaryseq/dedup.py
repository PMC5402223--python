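"""PCR-duplicate removal for single-end FASTQ reads.

Two reads are PCR duplicates when their first ``prefix_len`` bases (default
10) are identical and their whole-read similarity is strictly greater than
``sim_threshold`` (default 0.90). Similarity is positional identity over the
longer read's length — no indel alignment, which suits fixed-cycle Illumina
reads. Deduplication buckets reads by prefix and keeps the first occurrence
in input order within each bucket.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import DedupParams, InputError, ParseError


@dataclass(frozen=True)
class ReadRecord:
    """A single sequencing read (id, bases, Phred+33 quality string)."""

    read_id: str
    sequence: str
    quality: str

    def __post_init__(self):
        if len(self.sequence) != len(self.quality):
            raise InputError(
                f"read {self.read_id}: sequence and quality lengths differ "
                f"({len(self.sequence)} vs {len(self.quality)})"
            )


@dataclass
class DedupReport:
    """Accounting of a dedup run; n_input = n_kept + n_removed always."""

    n_input: int = 0
    n_kept: int = 0
    n_removed: int = 0
    removed_pairs: list[tuple[str, str]] = field(default_factory=list)


def similarity(read_a: ReadRecord, read_b: ReadRecord) -> float:
    """Fraction of identical aligned positions over the longer read length.

    Positions are compared one-by-one from the first base; no indels are
    considered. Symmetric, in [0, 1].
    """
    a, b = read_a.sequence, read_b.sequence
    if not a or not b:
        raise InputError("similarity: empty sequence")
    matches = sum(x == y for x, y in zip(a, b))
    return matches / max(len(a), len(b))


def is_pcr_duplicate(
    read_a: ReadRecord, read_b: ReadRecord, params: DedupParams | None = None
) -> bool:
    """True iff the reads share their prefix and exceed the similarity bar.

    Both clauses of the operational rule: identical first 10 bases AND
    strictly more than 90% whole-read similarity. A pair at exactly the
    threshold is *not* a duplicate.
    """
    params = params or DedupParams()
    k = params.prefix_len
    if len(read_a.sequence) <= k or len(read_b.sequence) <= k:
        raise InputError(
            f"reads {read_a.read_id}/{read_b.read_id}: shorter than "
            f"prefix_len={k}, not eligible for duplicate comparison"
        )
    if read_a.sequence[:k] != read_b.sequence[:k]:
        return False
    return similarity(read_a, read_b) > params.sim_threshold


def dedup_reads(
    reads: Sequence[ReadRecord], params: DedupParams | None = None
) -> tuple[list[ReadRecord], DedupReport]:
    """Remove PCR duplicates, keeping the first occurrence in input order.

    Reads are bucketed by their prefix; within a bucket each read is tested
    against every already-kept read, and removed on the first duplicate hit.
    Output preserves input order. Idempotent.
    """
    params = params or DedupParams()
    report = DedupReport(n_input=len(reads))
    buckets: dict[str, list[ReadRecord]] = {}
    kept: list[ReadRecord] = []
    for read in reads:
        bucket = buckets.setdefault(read.sequence[: params.prefix_len], [])
        hit = None
        for other in bucket:
            if is_pcr_duplicate(read, other, params):
                hit = other
                break
        if hit is None:
            bucket.append(read)
            kept.append(read)
        else:
            report.removed_pairs.append((hit.read_id, read.read_id))
    report.n_kept = len(kept)
    report.n_removed = report.n_input - report.n_kept
    return kept, report


# ---------------------------------------------------------------- FASTQ I/O


def read_fastq(path: str | Path) -> list[ReadRecord]:
    records = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            qual = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
            records.append(ReadRecord(rec.id, str(rec.seq), qual))
    except ValueError as exc:
        raise ParseError(f"FASTQ record {len(records) + 1}: {exc}") from exc
    return records


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    seq_records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in r.quality]
        seq_records.append(rec)
    SeqIO.write(seq_records, str(path), "fastq")


def dedup_fastq(
    in_path: str | Path,
    out_path: str | Path,
    report_path: str | Path | None = None,
    params: DedupParams | None = None,
) -> DedupReport:
    """File-level wrapper: FASTQ in, deduplicated FASTQ out, TSV report."""
    reads = read_fastq(in_path)
    kept, report = dedup_reads(reads, params)
    write_fastq(kept, out_path)
    if report_path is not None:
        with open(report_path, "w") as fh:
            fh.write(f"# n_input\t{report.n_input}\n")
            fh.write(f"# n_kept\t{report.n_kept}\n")
            fh.write(f"# n_removed\t{report.n_removed}\n")
            fh.write("kept_id\tremoved_id\n")
            for kept_id, removed_id in report.removed_pairs:
                fh.write(f"{kept_id}\t{removed_id}\n")
    return report
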