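"""mRNA half-life estimation from transcription-shutoff time courses.

After a transcription block (e.g. actinomycin D) abundance decays as
N(t) = N0 * exp(-lambda * t).  With data normalized to time point 0
(N(0) = 1), ln(abundance) is regressed on time with the intercept fixed
at 0; the half-life is ln(2) / lambda.  Replicates are pooled by fitting
all points jointly, preserving the error structure rather than
averaging first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class DecaySeries:
    """A t0-normalized decay time course for one gene and condition."""

    gene_id: str
    condition_id: str
    timepoints: np.ndarray  # hours, one entry per measurement
    abundance: np.ndarray  # relative to t0 (t0 value == 1)
    replicate: np.ndarray  # replicate id per measurement

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.abundance = np.asarray(self.abundance, dtype=float)
        self.replicate = np.asarray(self.replicate)
        if (self.abundance <= 0).any():
            raise ValueError("abundances must be positive")
        if (self.timepoints < 0).any() or 0.0 not in self.timepoints:
            raise ValueError("timepoints must include 0 and be non-negative")


@dataclass
class HalfLifeFit:
    gene_id: str
    condition_id: str
    half_life: float  # hours; +inf when no decay
    decay_rate: float  # per hour
    r_squared: float
    non_decaying: bool = False


def estimate_half_life(
    series: DecaySeries, free_intercept: bool = False
) -> HalfLifeFit:
    """Least-squares log-linear fit of a decay series.

    With the default fixed-zero intercept (data are t0-normalized)
    slope = sum(t * ln y) / sum(t^2).  A non-negative slope flags a
    non-decaying transcript with infinite half-life.
    """
    t = series.timepoints
    if len(np.unique(t)) < 3:
        raise ValueError("need >= 3 distinct timepoints including 0")
    ln_y = np.log(series.abundance)
    if free_intercept:
        slope, intercept = np.polyfit(t, ln_y, 1)
        fitted = slope * t + intercept
    else:
        slope = float(np.sum(t * ln_y) / np.sum(t**2))
        fitted = slope * t
    ss_res = float(np.sum((ln_y - fitted) ** 2))
    ss_tot = float(np.sum((ln_y - ln_y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    lam = -slope
    if lam <= 0:
        return HalfLifeFit(
            series.gene_id, series.condition_id, math.inf, lam, r2, True
        )
    return HalfLifeFit(
        series.gene_id, series.condition_id, math.log(2) / lam, lam, r2
    )


@dataclass
class HalfLifeComparison:
    fold_change: float  # T_half(b) / T_half(a)
    ci_low: float
    ci_high: float
    ci_level: float
    undefined: bool = False


def _resample_series(series: DecaySeries, rng: np.random.Generator) -> DecaySeries:
    reps = np.unique(series.replicate)
    chosen = rng.choice(reps, size=len(reps), replace=True)
    idx = np.concatenate([np.flatnonzero(series.replicate == r) for r in chosen])
    return DecaySeries(
        series.gene_id,
        series.condition_id,
        series.timepoints[idx],
        series.abundance[idx],
        series.replicate[idx],
    )


def compare_half_lives(
    series_a: DecaySeries,
    series_b: DecaySeries,
    n_boot: int = 1000,
    ci_level: float = 0.95,
    seed: int = 0,
) -> HalfLifeComparison:
    """Half-life fold change T_half(b)/T_half(a) with a bootstrap CI.

    The percentile CI resamples replicates with replacement within each
    series (seeded).  An infinite half-life in the denominator makes the
    ratio undefined.
    """
    fit_a = estimate_half_life(series_a)
    fit_b = estimate_half_life(series_b)
    if math.isinf(fit_a.half_life):
        return HalfLifeComparison(math.nan, math.nan, math.nan, ci_level, True)
    point = fit_b.half_life / fit_a.half_life
    rng = np.random.default_rng(seed)
    ratios = []
    for _ in range(n_boot):
        ra = estimate_half_life(_resample_series(series_a, rng))
        rb = estimate_half_life(_resample_series(series_b, rng))
        if math.isinf(ra.half_life):
            continue
        ratios.append(rb.half_life / ra.half_life)
    if not ratios:
        return HalfLifeComparison(point, math.nan, math.nan, ci_level, False)
    lo, hi = np.quantile(ratios, [(1 - ci_level) / 2, 1 - (1 - ci_level) / 2])
    return HalfLifeComparison(point, float(lo), float(hi), ci_level)


def read_timecourse(path) -> list[DecaySeries]:
    """Read a TSV with columns gene, condition, replicate, time_hr, value."""
    df = pd.read_csv(path, sep="\t")
    return series_from_frame(df)


def series_from_frame(df: pd.DataFrame) -> list[DecaySeries]:
    out = []
    for (gene, cond), grp in df.groupby(["gene", "condition"], sort=True):
        out.append(
            DecaySeries(
                str(gene),
                str(cond),
                grp["time_hr"].to_numpy(dtype=float),
                grp["value"].to_numpy(dtype=float),
                grp["replicate"].to_numpy(),
            )
        )
    return out


def fits_to_frame(fits: Sequence[HalfLifeFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": f.gene_id,
                "condition": f.condition_id,
                "half_life_hr": f.half_life,
                "decay_rate_per_hr": f.decay_rate,
                "r_squared": f.r_squared,
                "non_decaying": f.non_decaying,
            }
            for f in fits
        ]
    )
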