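"""CLIP read demultiplexing, trimming, and PCR-duplicate collapse.

The library layout modelled here: each raw read starts with a fixed-length
known-sequence index (multiplexing) followed by a fixed-length degenerate
barcode (unique-molecule evidence), then the insert, then a templated
polyA run from the tailing step.  Unique cDNA clones are distinguished
from PCR duplicates by (replicate, chrom, alignment start, strand,
barcode): RT truncation makes read *ends* unreliable, so the 5' alignment
start plus barcode defines the clone.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .genome_model import GeneIndex, GenomicInterval


@dataclass
class ReadLayout:
    """Read-start layout: index then degenerate barcode (default 6+6)."""

    index_length: int = 6
    barcode_length: int = 6
    index_to_replicate: Mapping[str, str] = field(default_factory=dict)
    index_mismatch_tolerance: int = 0
    min_insert_length: int = 18
    min_polya: int = 6
    polya_purity: float = 0.9

    def __post_init__(self) -> None:
        for idx in self.index_to_replicate:
            if len(idx) != self.index_length:
                raise ValueError(
                    f"index {idx!r} does not match declared length "
                    f"{self.index_length}"
                )


@dataclass
class RawClipRead:
    read_id: str
    replicate_id: str
    barcode: str
    insert: str


@dataclass
class DemuxResult:
    reads_by_replicate: dict[str, list[RawClipRead]]
    n_undetermined: int
    n_too_short: int


@dataclass
class ClipTag:
    """A deduplicated CLIP read: the atomic binding evidence."""

    interval: GenomicInterval
    replicate_id: str
    barcode: str
    deletion_offsets: tuple[int, ...] = ()
    collapsed_count: int = 1
    read_id: str = ""

    def __post_init__(self) -> None:
        length = len(self.interval)
        for off in self.deletion_offsets:
            if not 0 <= off < length:
                raise ValueError(
                    f"deletion offset {off} outside tag of length {length}"
                )
        if self.collapsed_count < 1:
            raise ValueError("collapsed_count must be >= 1")

    @property
    def strand(self) -> str:
        return self.interval.strand


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def trim_polya(seq: str, min_polya: int = 6, purity: float = 0.9) -> str:
    """Remove the longest trailing run with >= ``purity`` A content.

    The tailing enzyme produces long but imperfect A tails, so the run may
    contain occasional non-A bases.  Runs shorter than ``min_polya`` are
    left in place.
    """
    n = len(seq)
    best_cut = n
    a_count = 0
    # walk suffixes from the 3' end; suffix seq[j:] has length n - j
    for j in range(n - 1, -1, -1):
        if seq[j] == "A":
            a_count += 1
        length = n - j
        if length >= min_polya and a_count / length >= purity:
            best_cut = j
    return seq[:best_cut]


def demultiplex_and_trim(
    records: Iterable, layout: ReadLayout
) -> DemuxResult:
    """Split FASTQ-like records by index, strip barcode, trim polyA.

    ``records`` may be Biopython SeqRecords or (read_id, sequence) pairs.
    Unknown indices are counted in the ``undetermined`` bucket, never
    silently dropped; inserts shorter than the minimum are discarded with
    a tally.
    """
    out: dict[str, list[RawClipRead]] = {
        rep: [] for rep in layout.index_to_replicate.values()
    }
    n_undet = 0
    n_short = 0
    head = layout.index_length + layout.barcode_length
    for rec in records:
        if hasattr(rec, "seq"):
            read_id, seq = rec.id, str(rec.seq)
        else:
            read_id, seq = rec
        seq = seq.upper()
        if len(seq) < head:
            n_undet += 1
            continue
        index_seq = seq[: layout.index_length]
        replicate = None
        if index_seq in layout.index_to_replicate:
            replicate = layout.index_to_replicate[index_seq]
        elif layout.index_mismatch_tolerance > 0:
            matches = [
                rep
                for idx, rep in layout.index_to_replicate.items()
                if _hamming(index_seq, idx) <= layout.index_mismatch_tolerance
            ]
            if len(matches) == 1:
                replicate = matches[0]
        if replicate is None:
            n_undet += 1
            continue
        barcode = seq[layout.index_length: head]
        insert = trim_polya(seq[head:], layout.min_polya, layout.polya_purity)
        if len(insert) < layout.min_insert_length:
            n_short += 1
            continue
        out[replicate].append(RawClipRead(read_id, replicate, barcode, insert))
    return DemuxResult(out, n_undet, n_short)


def read_fastq(path: str | Path):
    return SeqIO.parse(str(path), "fastq")


def collapse_duplicates(aligned_reads: Sequence[ClipTag]) -> list[ClipTag]:
    """Collapse PCR duplicates into unique tags.

    Duplicate key: (replicate, chrom, start, strand, barcode).  The
    representative is the longest read (ties: lexicographically smallest
    read_id); deletion offsets are merged as the union across duplicates,
    since duplicates derive from one cDNA clone and the union preserves
    crosslink evidence.  Idempotent and input-order invariant.
    """
    groups: dict[tuple, list[ClipTag]] = defaultdict(list)
    for r in aligned_reads:
        if not r.barcode:
            raise ValueError(f"read {r.read_id!r} has no barcode; cannot deduplicate")
        key = (
            r.replicate_id,
            r.interval.chrom,
            r.interval.start,
            r.interval.strand,
            r.barcode,
        )
        groups[key].append(r)
    tags = []
    for key in sorted(groups):
        members = groups[key]
        rep = min(members, key=lambda t: (-len(t.interval), t.read_id))
        length = len(rep.interval)
        offsets = sorted(
            {o for m in members for o in m.deletion_offsets if o < length}
        )
        tags.append(
            ClipTag(
                interval=rep.interval,
                replicate_id=rep.replicate_id,
                barcode=rep.barcode,
                deletion_offsets=tuple(offsets),
                collapsed_count=sum(m.collapsed_count for m in members),
                read_id=rep.read_id,
            )
        )
    return tags


def count_unique_tags(
    tags: Sequence[ClipTag], index: GeneIndex | None = None
) -> pd.DataFrame:
    """Per-replicate unique-tag totals and genic fraction.

    Genic fraction = tags overlapping any same-strand gene span / all
    tags; reported as NA for an empty replicate, and NA throughout if no
    gene index is supplied.
    """
    per_rep: dict[str, dict[str, float]] = {}
    for t in tags:
        d = per_rep.setdefault(t.replicate_id, {"n_tags": 0, "n_genic": 0})
        d["n_tags"] += 1
        if index is not None and index.assign_gene(t.interval) is not None:
            d["n_genic"] += 1
    rows = []
    for rep in sorted(per_rep):
        d = per_rep[rep]
        frac = (
            d["n_genic"] / d["n_tags"]
            if index is not None and d["n_tags"] > 0
            else float("nan")
        )
        rows.append(
            {
                "replicate": rep,
                "n_tags": int(d["n_tags"]),
                "n_genic": int(d["n_genic"]) if index is not None else pd.NA,
                "genic_fraction": frac,
            }
        )
    return pd.DataFrame(rows, columns=["replicate", "n_tags", "n_genic", "genic_fraction"])


def tags_per_gene(tags: Sequence[ClipTag], index: GeneIndex) -> Counter:
    """Unique-tag count per gene (same-strand span overlap)."""
    counts: Counter = Counter()
    for t in tags:
        gid = index.assign_gene(t.interval)
        if gid is not None:
            counts[gid] += 1
    return counts


# ---------------------------------------------------------------------------
# Tag I/O: BED6+ with extra columns replicate, barcode, deletions.

TAG_EXTRA_COLUMNS = ["replicate", "barcode", "deletions"]


def tags_to_frame(tags: Sequence[ClipTag]) -> pd.DataFrame:
    rows = [
        {
            "chrom": t.interval.chrom,
            "start": t.interval.start,
            "end": t.interval.end,
            "name": t.read_id or f"tag{i}",
            "score": t.collapsed_count,
            "strand": t.interval.strand,
            "replicate": t.replicate_id,
            "barcode": t.barcode,
            "deletions": ",".join(map(str, t.deletion_offsets)) or ".",
        }
        for i, t in enumerate(tags)
    ]
    return pd.DataFrame(
        rows, columns=[*"chrom start end name score strand".split(), *TAG_EXTRA_COLUMNS]
    )


def frame_to_tags(df: pd.DataFrame) -> list[ClipTag]:
    tags = []
    for row in df.itertuples(index=False):
        dels = (
            tuple(int(x) for x in str(row.deletions).split(","))
            if str(row.deletions) not in (".", "nan", "")
            else ()
        )
        tags.append(
            ClipTag(
                interval=GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand),
                replicate_id=str(row.replicate),
                barcode=str(row.barcode),
                deletion_offsets=dels,
                collapsed_count=int(row.score),
                read_id=str(row.name),
            )
        )
    return tags


def write_tags(tags: Sequence[ClipTag], path: str | Path) -> None:
    from .genome_model import write_bed

    write_bed(tags_to_frame(tags), path, TAG_EXTRA_COLUMNS)


def read_tags(path: str | Path) -> list[ClipTag]:
    from .genome_model import read_bed

    return frame_to_tags(read_bed(path, TAG_EXTRA_COLUMNS))
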