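"""Cassette-exon inclusion statistics, Fisher screening, binding maps.

A cassette (CA) exon sits between two constitutive flanking exons (5'CE,
3'CE).  Junction-spanning reads provide three counts per sample: the two
inclusion junctions (5'CE-CA and CA-3'CE) and the skip junction
(5'CE-3'CE).  The inclusion rate averages the two inclusion junctions to
avoid double-counting inclusion evidence against the single skip
junction:

    I  = (inc_up + inc_down) / 2
    IR = I / (I + skip)

IR is averaged across replicates within each condition and
dI = mean IR(factor-expressing) - mean IR(control); positive dI means
factor-dependent inclusion.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clip_clusters import Cluster
from .clip_reads import ClipTag


@dataclass
class JunctionCounts:
    inc_up: int = 0
    inc_down: int = 0
    skip: int = 0

    @property
    def total(self) -> int:
        return self.inc_up + self.inc_down + self.skip


@dataclass
class CassetteEvent:
    """A 5'CE - CA - 3'CE triple with per-sample junction counts.

    Exon coordinates are genomic half-open intervals in genomic order
    (``up_exon`` leftmost).  In transcript orientation, ``up_exon`` is
    the 5'CE on the plus strand and the 3'CE on the minus strand;
    junction bookkeeping handles the flip.
    """

    event_id: str
    gene_id: str
    chrom: str
    strand: str
    up_exon: tuple[int, int]
    ca_exon: tuple[int, int]
    down_exon: tuple[int, int]
    counts: dict[str, JunctionCounts] = field(default_factory=dict)
    ir: dict[str, float] = field(default_factory=dict)  # per condition mean IR
    delta_i: float = float("nan")
    fisher_p: float = float("nan")
    bound: bool = False

    def __post_init__(self) -> None:
        if not (
            self.up_exon[1] <= self.ca_exon[0]
            and self.ca_exon[1] <= self.down_exon[0]
        ):
            raise ValueError(f"{self.event_id}: exons out of order or overlapping")

    def junctions(self) -> dict[str, tuple[int, int]]:
        """Genomic (donor_end, acceptor_start) per junction role.

        Roles are transcript-oriented: inc_up is 5'CE-CA, inc_down is
        CA-3'CE, skip is 5'CE-3'CE.
        """
        j_left = (self.up_exon[1], self.ca_exon[0])
        j_right = (self.ca_exon[1], self.down_exon[0])
        j_skip = (self.up_exon[1], self.down_exon[0])
        if self.strand == "+":
            return {"inc_up": j_left, "inc_down": j_right, "skip": j_skip}
        return {"inc_up": j_right, "inc_down": j_left, "skip": j_skip}

    @property
    def span(self) -> tuple[int, int]:
        return (self.up_exon[0], self.down_exon[1])


def count_junction_reads(
    junction_evidence: pd.DataFrame,
    events: Sequence[CassetteEvent],
) -> int:
    """Attach per-sample junction counts to events by exact matching.

    ``junction_evidence`` columns: chrom, donor, acceptor, strand,
    sample, count (donor = exon end, acceptor = next exon start, genomic
    half-open coordinates).  Junctions matching no event are ignored;
    their total count is returned as the unmatched tally.
    """
    lookup: dict[tuple, tuple[CassetteEvent, str]] = {}
    for ev in events:
        for role, (d, a) in ev.junctions().items():
            lookup[(ev.chrom, ev.strand, d, a)] = (ev, role)
    unmatched = 0
    for row in junction_evidence.itertuples(index=False):
        key = (row.chrom, row.strand, int(row.donor), int(row.acceptor))
        hit = lookup.get(key)
        if hit is None:
            unmatched += int(row.count)
            continue
        ev, role = hit
        jc = ev.counts.setdefault(str(row.sample), JunctionCounts())
        setattr(jc, role, getattr(jc, role) + int(row.count))
    return unmatched


def inclusion_rate(counts: JunctionCounts) -> float:
    """IR = I / (I + skip) with I = (inc_up + inc_down) / 2; NaN if empty."""
    if counts.total == 0:
        return float("nan")
    i = (counts.inc_up + counts.inc_down) / 2
    return i / (i + counts.skip)


def delta_i(
    event: CassetteEvent,
    condition_design: Mapping[str, str],
    treatment: str,
    control: str,
) -> float:
    """dI = mean IR(treatment) - mean IR(control) over replicates.

    ``condition_design`` maps sample id -> condition.  Per-condition IRs
    are averaged across replicates (NaN replicate IRs dropped); the mean
    IRs are stored on the event.
    """
    per_cond: dict[str, list[float]] = defaultdict(list)
    for sample, counts in event.counts.items():
        cond = condition_design.get(sample)
        if cond is None:
            continue
        ir = inclusion_rate(counts)
        if not math.isnan(ir):
            per_cond[cond].append(ir)
    for cond in (treatment, control):
        if not per_cond.get(cond):
            raise ValueError(
                f"{event.event_id}: no usable samples for condition {cond!r}"
            )
        event.ir[cond] = float(np.mean(per_cond[cond]))
    event.delta_i = event.ir[treatment] - event.ir[control]
    return event.delta_i


def fisher_splice_test(
    event: CassetteEvent,
    condition_design: Mapping[str, str],
    treatment: str,
    control: str,
) -> float:
    """Two-sided Fisher exact test on pooled isoform counts.

    Replicates pool within condition; isoform-1 evidence = inc_up +
    inc_down, isoform-2 = skip.  A zero margin yields p = 1 by
    convention.
    """
    table = np.zeros((2, 2), dtype=int)
    for sample, counts in event.counts.items():
        cond = condition_design.get(sample)
        if cond == treatment:
            row = 0
        elif cond == control:
            row = 1
        else:
            continue
        table[row, 0] += counts.inc_up + counts.inc_down
        table[row, 1] += counts.skip
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        event.fisher_p = 1.0
        return 1.0
    _, p = stats.fisher_exact(table, alternative="two-sided")
    event.fisher_p = float(p)
    return event.fisher_p


def call_regulated_exons(
    events: Sequence[CassetteEvent],
    min_reads: int = 10,
    min_abs_delta_i: float = 0.2,
    alpha: float = 0.05,
) -> tuple[list[CassetteEvent], list[CassetteEvent]]:
    """Split events into (included, excluded) regulated sets.

    An event passes with >= ``min_reads`` total junction reads (summed
    over samples), |dI| >= ``min_abs_delta_i`` and Fisher p <= ``alpha``;
    the dI sign assigns included (dI > 0) vs excluded (dI < 0).
    """
    included, excluded = [], []
    for ev in events:
        total_reads = sum(c.total for c in ev.counts.values())
        if total_reads < min_reads or math.isnan(ev.delta_i):
            continue
        if abs(ev.delta_i) < min_abs_delta_i or not ev.fisher_p <= alpha:
            continue
        (included if ev.delta_i > 0 else excluded).append(ev)
    return included, excluded


def bound_exon(
    event: CassetteEvent,
    clusters: Sequence[Cluster],
    n_replicates: int = 2,
    min_cluster_tags: int = 5,
    min_total_tags: int = 10,
) -> bool:
    """Binding call over the 5'CE-start .. 3'CE-end span of the event.

    True iff the summed tag count of same-strand clusters with
    BC = n_replicates and >= ``min_cluster_tags`` tags overlapping the
    span reaches ``min_total_tags``.
    """
    lo, hi = event.span
    total = 0
    for c in clusters:
        if c.interval.chrom != event.chrom or c.strand != event.strand:
            continue
        if c.bc != n_replicates or c.total_tags < min_cluster_tags:
            continue
        if c.interval.start < hi and lo < c.interval.end:
            total += c.total_tags
    event.bound = total >= min_total_tags
    return event.bound


#: composite-transcript boundary names, transcript orientation
BOUNDARIES = ("5CE_donor", "CA_acceptor", "CA_donor", "3CE_acceptor")


def _boundary_coords(event: CassetteEvent) -> dict[str, tuple[int, str]]:
    """Genomic coordinate and intron side ('left'/'right') per boundary.

    The coordinate is the genomic position of the exon/intron junction
    (exon end for a left-intron boundary means intron extends right).
    """
    if event.strand == "+":
        return {
            "5CE_donor": (event.up_exon[1], "right"),
            "CA_acceptor": (event.ca_exon[0], "left"),
            "CA_donor": (event.ca_exon[1], "right"),
            "3CE_acceptor": (event.down_exon[0], "left"),
        }
    return {
        "5CE_donor": (event.down_exon[0], "left"),
        "CA_acceptor": (event.ca_exon[1], "right"),
        "CA_donor": (event.ca_exon[0], "left"),
        "3CE_acceptor": (event.up_exon[1], "right"),
    }


def complexity_map(
    events: Sequence[CassetteEvent],
    tags: Sequence[ClipTag],
    window: int = 1000,
    exon_margin: int = 50,
) -> dict[str, dict[str, np.ndarray]]:
    """Normalized binding profile around the four composite boundaries.

    For each boundary, offsets run from ``-exon_margin`` (exonic side)
    through ``window - 1`` nt into the intron, in transcript orientation
    with offset 0 the first intronic base.  The value at an offset is the
    fraction of events in the class with >= 1 same-strand tag covering
    that genomic position; intronic reach is truncated at the midpoint of
    short introns.  All values lie in [0, 1].
    """
    if not events:
        return {b: {"offsets": np.arange(-exon_margin, window), "value": np.zeros(exon_margin + window)} for b in BOUNDARIES}
    # per (chrom, strand): sorted starts/ends for coverage queries
    cov: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    grouped: dict[tuple[str, str], list[ClipTag]] = defaultdict(list)
    for t in tags:
        grouped[(t.interval.chrom, t.interval.strand)].append(t)
    for key, ts in grouped.items():
        cov[key] = (
            np.sort([t.interval.start for t in ts]),
            np.sort([t.interval.end for t in ts]),
        )

    offsets = np.arange(-exon_margin, window)
    hits = {b: np.zeros(len(offsets), dtype=float) for b in BOUNDARIES}
    for ev in events:
        key = (ev.chrom, ev.strand)
        introns = {
            "left_of_ca": (ev.up_exon[1], ev.ca_exon[0]),
            "right_of_ca": (ev.ca_exon[1], ev.down_exon[0]),
        }
        for b, (coord, side) in _boundary_coords(ev).items():
            # ``side`` names where the intron sits genomically; walking
            # into the intron is rightward for "right", leftward for
            # "left" (transcript orientation is already encoded in the
            # boundary-to-coordinate mapping above)
            if side == "right":
                positions = coord + offsets
                ilo, ihi = coord, _nearest_intron_end(coord, introns)
            else:
                positions = coord - 1 - offsets
                ilo, ihi = _nearest_intron_start(coord, introns), coord
            # truncate intronic offsets at the intron midpoint
            half = (ihi - ilo) // 2
            valid = (offsets < half) | (offsets < 0)
            if key not in cov:
                continue
            starts, ends = cov[key]
            depth = np.searchsorted(starts, positions, side="right") - np.searchsorted(
                ends, positions, side="right"
            )
            hits[b] += ((depth > 0) & valid).astype(float)
    n = len(events)
    return {
        b: {"offsets": offsets, "value": hits[b] / n} for b in BOUNDARIES
    }


def _nearest_intron_end(coord: int, introns: Mapping[str, tuple[int, int]]) -> int:
    for lo, hi in introns.values():
        if lo == coord:
            return hi
    return coord


def _nearest_intron_start(coord: int, introns: Mapping[str, tuple[int, int]]) -> int:
    for lo, hi in introns.values():
        if hi == coord:
            return lo
    return coord


def events_to_frame(events: Sequence[CassetteEvent]) -> pd.DataFrame:
    rows = []
    for ev in events:
        row = {
            "event_id": ev.event_id,
            "gene_id": ev.gene_id,
            "chrom": ev.chrom,
            "strand": ev.strand,
            "up_exon_start": ev.up_exon[0],
            "up_exon_end": ev.up_exon[1],
            "ca_start": ev.ca_exon[0],
            "ca_end": ev.ca_exon[1],
            "down_exon_start": ev.down_exon[0],
            "down_exon_end": ev.down_exon[1],
            "delta_i": ev.delta_i,
            "fisher_p": ev.fisher_p,
            "bound": ev.bound,
        }
        for cond, ir in sorted(ev.ir.items()):
            row[f"ir_{cond}"] = ir
        rows.append(row)
    return pd.DataFrame(rows)
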