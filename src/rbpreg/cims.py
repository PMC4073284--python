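"""Crosslink-induced mutation site (CIMS) detection from deletion evidence.

Reverse transcription through a crosslinked residue leaves deletions in
CLIP tags; a genomic position where many overlapping tags carry a
deletion pinpoints the contact nucleotide.  Significance is controlled by
a within-tag permutation scheme: each permutation repositions every
deletion uniformly at random within its own tag, conserving per-tag
deletion counts, and the FDR for (deletion count k, coverage m) strata is
the mean permuted exceedance count over the observed count.

Only deletions are modelled; substitutions and truncations are out of
scope here.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clip_reads import ClipTag

#: coverage strata above this bound pool together (small-data stabilizer)
COVERAGE_POOL_BOUND = 100

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


@dataclass
class CimsSite:
    chrom: str
    position: int
    strand: str
    k: int  # tags with a deletion at the position
    m: int  # tags covering the position
    fdr: float = float("nan")
    footprint_seq: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.k <= self.m:
            raise ValueError(f"require 0 < k <= m, got k={self.k}, m={self.m}")


def _coverage_arrays(tags: Sequence[ClipTag]) -> dict[tuple[str, str], tuple[np.ndarray, np.ndarray]]:
    """Sorted start/end arrays per (chrom, strand) for coverage queries."""
    grouped: dict[tuple[str, str], list[ClipTag]] = defaultdict(list)
    for t in tags:
        grouped[(t.interval.chrom, t.interval.strand)].append(t)
    return {
        key: (
            np.sort([t.interval.start for t in ts]),
            np.sort([t.interval.end for t in ts]),
        )
        for key, ts in grouped.items()
    }


def _coverage_at(
    arrays: Mapping[tuple[str, str], tuple[np.ndarray, np.ndarray]],
    chrom: str,
    strand: str,
    positions: np.ndarray,
) -> np.ndarray:
    starts, ends = arrays[(chrom, strand)]
    return np.searchsorted(starts, positions, side="right") - np.searchsorted(
        ends, positions, side="right"
    )


def collect_deletion_sites(tags: Sequence[ClipTag]) -> list[CimsSite]:
    """Tally (k, m) for every genomic position with >= 1 tag deletion.

    A tag with deletions at two positions contributes to both sites' k.
    Deletion offsets outside the tag span are rejected upstream by
    ClipTag validation.
    """
    del_counts: dict[tuple[str, str], Counter] = defaultdict(Counter)
    for t in tags:
        for off in t.deletion_offsets:
            del_counts[(t.interval.chrom, t.interval.strand)][t.interval.start + off] += 1
    arrays = _coverage_arrays(tags)
    sites = []
    for (chrom, strand), counter in sorted(del_counts.items()):
        positions = np.array(sorted(counter))
        cov = _coverage_at(arrays, chrom, strand, positions)
        for pos, m in zip(positions, cov):
            sites.append(CimsSite(chrom, int(pos), strand, counter[int(pos)], int(m)))
    return sites


def _stratum(m: int) -> int:
    return min(m, COVERAGE_POOL_BOUND + 1)


def _exceedance_by_stratum(sites_km: Sequence[tuple[int, int]], kmax: int) -> dict[int, np.ndarray]:
    """For each coverage stratum, counts[j] = #positions with k >= j."""
    out: dict[int, np.ndarray] = {}
    for k, m in sites_km:
        st = _stratum(m)
        arr = out.setdefault(st, np.zeros(kmax + 2, dtype=float))
        arr[1: min(k, kmax) + 1] += 1
    return out


def cims_fdr(
    candidates: Sequence[CimsSite],
    tags: Sequence[ClipTag],
    n_permutations: int = 100,
    seed: int = 0,
    min_k: int = 5,
    max_fdr: float = 0.01,
) -> tuple[list[CimsSite], list[CimsSite]]:
    """Permutation FDR for candidate CIMS; returns (all, reproducible).

    For each of ``n_permutations`` rounds every deletion is moved to a
    uniform random offset within its own tag and the per-position
    deletion tallies recomputed.  FDR(k, m-stratum) = mean permuted count
    of positions in the stratum with deletion count >= k, divided by the
    observed count, clamped to [0, 1] and made non-increasing in k.
    The reproducible set applies k >= ``min_k`` and fdr <= ``max_fdr``.
    """
    if n_permutations < 20:
        raise ValueError("n_permutations must be >= 20")
    if not candidates:
        return [], []
    rng = np.random.default_rng(seed)
    arrays = _coverage_arrays(tags)
    kmax = max(s.k for s in candidates)

    obs = _exceedance_by_stratum([(s.k, s.m) for s in candidates], kmax)
    perm_sum: dict[int, np.ndarray] = {
        st: np.zeros(kmax + 2, dtype=float) for st in obs
    }
    del_tags = [t for t in tags if t.deletion_offsets]
    for _ in range(n_permutations):
        counter: dict[tuple[str, str], Counter] = defaultdict(Counter)
        for t in del_tags:
            length = len(t.interval)
            offs = rng.integers(0, length, size=len(t.deletion_offsets))
            key = (t.interval.chrom, t.interval.strand)
            for off in offs:
                counter[key][t.interval.start + int(off)] += 1
        perm_sites: list[tuple[int, int]] = []
        for (chrom, strand), cnt in counter.items():
            positions = np.array(sorted(cnt))
            cov = _coverage_at(arrays, chrom, strand, positions)
            perm_sites.extend(
                (cnt[int(p)], int(m)) for p, m in zip(positions, cov)
            )
        for st, arr in _exceedance_by_stratum(perm_sites, kmax).items():
            if st in perm_sum:
                perm_sum[st] += arr

    fdr_table: dict[int, np.ndarray] = {}
    for st, obs_arr in obs.items():
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = np.where(obs_arr > 0, (perm_sum[st] / n_permutations) / obs_arr, np.nan)
        raw = np.minimum(raw, 1.0)
        # enforce non-increasing FDR in k: sweep from large k down
        mono = raw.copy()
        for k in range(kmax - 1, 0, -1):
            if np.isnan(mono[k]):
                continue
            nxt = mono[k + 1]
            if not np.isnan(nxt):
                mono[k] = max(mono[k], nxt)
        fdr_table[st] = mono

    annotated = []
    for s in candidates:
        fdr = float(fdr_table[_stratum(s.m)][s.k])
        annotated.append(CimsSite(s.chrom, s.position, s.strand, s.k, s.m, fdr))
    reproducible = [s for s in annotated if s.k >= min_k and s.fdr <= max_fdr]
    return annotated, reproducible


def extract_footprints(
    sites: Sequence[CimsSite],
    sequences: Mapping[str, str],
    halfwidth: int = 10,
) -> list[tuple[CimsSite, str, bool]]:
    """Sequence windows of 2*halfwidth + 1 nt centered on each CIMS.

    Minus-strand windows are reverse-complemented so all footprints read
    in transcript orientation.  Windows running past the sequence end are
    clipped and flagged.
    """
    out = []
    for s in sites:
        seq = sequences[s.chrom]
        lo, hi = s.position - halfwidth, s.position + halfwidth + 1
        clipped = lo < 0 or hi > len(seq)
        window = seq[max(0, lo): min(len(seq), hi)].upper()
        if s.strand == "-":
            window = window.translate(_COMPLEMENT)[::-1]
        out.append((s, window, clipped))
    return out


def _u_fraction(window: str) -> float:
    if not window:
        return float("nan")
    return (window.count("T") + window.count("U")) / len(window)


_U_RUN = re.compile(r"[TU]{4,}")


def base_composition_enrichment(
    windows: Sequence[str],
    background_windows: Sequence[str],
) -> dict:
    """Test footprint windows for uridine enrichment over background.

    Compares per-window U (= T in DNA space) fractions with a one-sided
    Mann-Whitney test (foreground > background) and counts foreground
    windows containing a run of >= 4 U.  Background windows should be
    sampled from matched transcript regions.
    """
    if not windows or not background_windows:
        raise ValueError("both foreground and background windows are required")
    fg = np.array([_u_fraction(w) for w in windows])
    bg = np.array([_u_fraction(w) for w in background_windows])
    if np.all(fg == fg[0]) and np.all(bg == bg[0]) and fg[0] == bg[0]:
        p = 1.0
    else:
        _, p = stats.mannwhitneyu(fg, bg, alternative="greater")
    return {
        "fraction_fg": float(np.mean(fg)),
        "fraction_bg": float(np.mean(bg)),
        "p": float(p),
        "n_fg_with_u_run": int(sum(bool(_U_RUN.search(w.upper())) for w in windows)),
    }


def sites_to_frame(sites: Sequence[CimsSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "position": s.position,
                "strand": s.strand,
                "k": s.k,
                "m": s.m,
                "fdr": s.fdr,
            }
            for s in sites
        ],
        columns=["chrom", "position", "strand", "k", "m", "fdr"],
    )
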