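"""Shared genomic data types, transcript region derivation, and tabular I/O.

Coordinates are 0-based half-open everywhere internally (BED-native); GTF
input is converted on read (start - 1).  All tag-to-gene assignment is
same-strand only, because CLIP library preparation is strand-specific.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

# Region labels, ordered by assignment priority (highest first).  The
# protein's headline binding classes are 3'UTR and intron; exonic evidence
# must not be diluted by an overlapping intron of another isoform.
THREE_UTR = "3UTR"
FIVE_UTR = "5UTR"
CDS = "CDS"
NONCODING_EXON = "noncoding_exon"
INTRON = "intron"
INTERGENIC = "intergenic"

REGION_PRIORITY: tuple[str, ...] = (
    THREE_UTR,
    FIVE_UTR,
    CDS,
    NONCODING_EXON,
    INTRON,
    INTERGENIC,
)

_PRIORITY_RANK = {label: i for i, label in enumerate(REGION_PRIORITY)}


class AnnotationError(ValueError):
    """Raised for malformed annotation input (carries the line number)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open stranded genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", stranded: bool = True) -> bool:
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end


@dataclass
class TranscriptModel:
    """A transcript: ordered exons plus optional CDS bounds.

    ``exons`` are stored in genomic (ascending) order; use
    :meth:`exons_5to3` for transcript orientation.  CDS bounds are genomic
    (cds_start < cds_end) and must lie within the exon union.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(
                    f"{self.transcript_id}: exons overlap ({s1}-{e1}, {s2}-{e2})"
                )
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"{self.transcript_id}: partial CDS bounds")
        if self.cds_start is not None:
            if not any(
                s <= self.cds_start < e for s, e in self.exons
            ) or not any(s < self.cds_end <= e for s, e in self.exons):
                raise ValueError(
                    f"{self.transcript_id}: CDS bounds outside exon union"
                )

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0][0], self.exons[-1][1], self.strand
        )

    def exons_5to3(self) -> list[tuple[int, int]]:
        """Exons in transcript (5'->3') orientation."""
        return self.exons if self.strand == "+" else self.exons[::-1]

    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, genomic order."""
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_annotation(path: str | Path) -> list[TranscriptModel]:
    """Read a GTF file into TranscriptModels.

    Only ``exon`` and ``CDS`` features are used.  GTF 1-based inclusive
    starts are converted to 0-based half-open.  Output is deterministic:
    sorted by (chrom, start, transcript_id).

    Raises
    ------
    AnnotationError
        naming the offending line number for malformed lines.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields
            if feature not in ("exon", "CDS"):
                continue
            try:
                s, e = int(start) - 1, int(end)
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if not (0 <= s < e):
                raise AnnotationError(
                    f"{path}: line {lineno}: invalid coordinates {start}-{end}"
                )
            if strand not in ("+", "-"):
                raise AnnotationError(
                    f"{path}: line {lineno}: invalid strand {strand!r}"
                )
            ad = _parse_gtf_attributes(attrs)
            tid = ad.get("transcript_id")
            gid = ad.get("gene_id", tid)
            if tid is None:
                raise AnnotationError(
                    f"{path}: line {lineno}: missing transcript_id attribute"
                )
            meta.setdefault(tid, (gid, chrom, strand))
            (exons if feature == "exon" else cds).setdefault(tid, []).append((s, e))
    models = []
    for tid, (gid, chrom, strand) in meta.items():
        tx_exons = exons.get(tid)
        if not tx_exons:
            continue
        cds_bounds = cds.get(tid)
        cs = min(s for s, _ in cds_bounds) if cds_bounds else None
        ce = max(e for _, e in cds_bounds) if cds_bounds else None
        models.append(
            TranscriptModel(gid, tid, chrom, strand, tx_exons, cs, ce)
        )
    models.sort(key=lambda m: (m.chrom, m.exons[0][0], m.transcript_id))
    return models


def derive_regions(model: TranscriptModel) -> dict[str, list[GenomicInterval]]:
    """Split a transcript into 5'UTR/CDS/3'UTR/intron (or noncoding_exon).

    Returned intervals are pairwise disjoint; the exonic labels union to
    the exon union.  Without CDS bounds every exonic base is
    ``noncoding_exon``.
    """
    out: dict[str, list[GenomicInterval]] = {
        FIVE_UTR: [],
        CDS: [],
        THREE_UTR: [],
        NONCODING_EXON: [],
        INTRON: [],
    }
    mk = lambda s, e: GenomicInterval(model.chrom, s, e, model.strand)
    for s, e in model.introns():
        out[INTRON].append(mk(s, e))
    if model.cds_start is None:
        out[NONCODING_EXON] = [mk(s, e) for s, e in model.exons]
        return out
    cs, ce = model.cds_start, model.cds_end
    # genomic-left of CDS is 5'UTR on +, 3'UTR on -
    left_label = FIVE_UTR if model.strand == "+" else THREE_UTR
    right_label = THREE_UTR if model.strand == "+" else FIVE_UTR
    for s, e in model.exons:
        if e <= cs:
            out[left_label].append(mk(s, e))
        elif s >= ce:
            out[right_label].append(mk(s, e))
        else:
            if s < cs:
                out[left_label].append(mk(s, cs))
            out[CDS].append(mk(max(s, cs), min(e, ce)))
            if e > ce:
                out[right_label].append(mk(ce, e))
    return out


class GeneIndex:
    """Overlap index over transcript regions and gene spans.

    A gene, for per-gene statistics, is the union of all transcript spans
    sharing a gene_id (the pre-mRNA span), so intronic tags count toward
    the gene.
    """

    def __init__(self, models: Sequence[TranscriptModel]):
        self.models = list(models)
        # (chrom, strand) -> IntervalTree of region labels / gene ids
        self._regions: dict[tuple[str, str], IntervalTree] = {}
        self._genes: dict[tuple[str, str], IntervalTree] = {}
        gene_bounds: dict[tuple[str, str, str], tuple[int, int]] = {}
        for m in self.models:
            key = (m.chrom, m.strand)
            tree = self._regions.setdefault(key, IntervalTree())
            for label, ivs in derive_regions(m).items():
                for iv in ivs:
                    tree.addi(iv.start, iv.end, label)
            gk = (m.gene_id, m.chrom, m.strand)
            span = m.span
            if gk in gene_bounds:
                s0, e0 = gene_bounds[gk]
                gene_bounds[gk] = (min(s0, span.start), max(e0, span.end))
            else:
                gene_bounds[gk] = (span.start, span.end)
        self.gene_spans: dict[str, GenomicInterval] = {}
        self.gene_lengths: dict[str, int] = {}
        for (gid, chrom, strand), (s, e) in gene_bounds.items():
            self._genes.setdefault((chrom, strand), IntervalTree()).addi(s, e, gid)
            self.gene_spans[gid] = GenomicInterval(chrom, s, e, strand)
            self.gene_lengths[gid] = e - s

    def assign_region(self, interval: GenomicInterval) -> str:
        """Single deterministic region label for an interval.

        Priority over overlapping transcripts:
        3'UTR > 5'UTR > CDS > noncoding_exon > intron > intergenic.
        """
        tree = self._regions.get((interval.chrom, interval.strand))
        if tree is None:
            return INTERGENIC
        hits = tree.overlap(interval.start, interval.end)
        if not hits:
            return INTERGENIC
        return min((h.data for h in hits), key=_PRIORITY_RANK.__getitem__)

    def assign_gene(self, interval: GenomicInterval) -> str | None:
        """Gene id for a same-strand overlapping gene span, or None.

        Ties (interval overlapping several genes) resolve to the largest
        overlap, then lexicographically smallest gene_id.
        """
        tree = self._genes.get((interval.chrom, interval.strand))
        if tree is None:
            return None
        hits = tree.overlap(interval.start, interval.end)
        if not hits:
            return None
        best = max(
            hits,
            key=lambda h: (
                min(h.end, interval.end) - max(h.begin, interval.start),
                h.data,
            ),
        )
        return best.data


# ---------------------------------------------------------------------------
# Tabular I/O: BED6(+) and TSV.  Writers emit deterministic column order,
# newline-terminated UTF-8.

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path: str | Path, extra_columns: Sequence[str] = ()) -> pd.DataFrame:
    """Read BED6 (+ optional named extra columns) into a DataFrame."""
    cols = BED6_COLUMNS + list(extra_columns)
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=cols, comment="#",
            dtype={"chrom": str, "name": str},
        )
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed BED: {exc}") from exc
    if df["start"].isna().any() or df["end"].isna().any():
        bad = int(df.index[df["start"].isna() | df["end"].isna()][0]) + 1
        raise ValueError(f"{path}: line {bad}: missing coordinates")
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_bed(df: pd.DataFrame, path: str | Path,
              extra_columns: Sequence[str] = ()) -> None:
    cols = BED6_COLUMNS + list(extra_columns)
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols,
              lineterminator="\n")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
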