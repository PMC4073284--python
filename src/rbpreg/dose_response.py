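"""Dose-response direct-target screen over inducible-expression clones.

Count matrices (genes x samples) are normalized with the median-of-ratios
size-factor method; per-gene expression is then correlated (Pearson)
with inducer dose separately in each clone.  A gene is called a direct
UP target when (i) the correlation is significant (p below alpha) with
positive r in both wild-type clones, (ii) the expression change is
already detectable at the lowest nonzero dose in both wild-type clones
(|log2FC| >= theta with consistent sign), and (iii) there is no
significant correlation in the mutant clone.  DOWN is symmetric with
negative r.  No multiple-testing correction is applied by default (raw
p-value cutoffs); a Benjamini-Hochberg option exists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class DoseDesign:
    """Sample layout: which clone and dose each sample column carries."""

    sample_to_clone: Mapping[str, str]
    sample_to_dose: Mapping[str, float]
    wt_clones: tuple[str, str] = ("WT6", "WT10")
    mut_clone: str = "MUT3"

    def __post_init__(self) -> None:
        for clone in (*self.wt_clones, self.mut_clone):
            doses = self.doses(clone)
            if len(doses) < 3 or 0.0 not in doses:
                raise ValueError(
                    f"clone {clone}: need >= 3 distinct doses including 0"
                )

    def samples(self, clone: str) -> list[str]:
        return [s for s, c in self.sample_to_clone.items() if c == clone]

    def doses(self, clone: str) -> list[float]:
        return sorted({self.sample_to_dose[s] for s in self.samples(clone)})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kw) -> "DoseDesign":
        """Build from a design table with columns sample, clone, dose."""
        return cls(
            sample_to_clone=dict(zip(df["sample"].astype(str), df["clone"])),
            sample_to_dose=dict(zip(df["sample"].astype(str), df["dose"].astype(float))),
            **kw,
        )


def size_factor_normalize(
    counts: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios library-size normalization.

    factor_j = median over all-positive genes of count_gj / geomean_g,
    then factors are divided by their median (so the reference scale is
    data-driven and a second application yields unit factors).
    """
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in all samples; supply a "
            "pseudo-reference or filter samples"
        )
    sub = counts.loc[positive].astype(float)
    geomean = np.exp(np.log(sub).mean(axis=1))
    factors = sub.div(geomean, axis=0).median(axis=0)
    factors = factors / factors.median()
    return counts / factors, factors


def dose_correlation(
    normalized: pd.DataFrame,
    design: DoseDesign,
    use_log_dose: bool = False,
    use_log_expression: bool = False,
) -> dict[str, pd.DataFrame]:
    """Per-gene Pearson correlation of expression with dose, per clone.

    Returns, per clone, a frame with columns r and p (two-sided, from
    the t transform).  Constant-expression genes get r = NaN, p = 1.
    Options correlate against log1p(dose) instead of the raw dose, and
    log2(expression + 1) instead of raw expression; on the log scales a
    saturating induction response is close to linear, which Pearson
    rewards symmetrically for induced and repressed genes.
    """
    out = {}
    for clone in (*design.wt_clones, design.mut_clone):
        samples = design.samples(clone)
        if len(samples) < 3:
            raise ValueError(f"clone {clone}: need >= 3 samples")
        x = np.array([design.sample_to_dose[s] for s in samples], dtype=float)
        if use_log_dose:
            x = np.log1p(x)
        y = normalized[samples].to_numpy(dtype=float)
        if use_log_expression:
            y = np.log2(y + 1.0)
        xc = x - x.mean()
        yc = y - y.mean(axis=1, keepdims=True)
        sx = np.sqrt((xc ** 2).sum())
        sy = np.sqrt((yc ** 2).sum(axis=1))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (yc @ xc) / (sx * sy)
        n = len(samples)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt((n - 2) / (1 - r ** 2))
        p = 2 * stats.t.sf(np.abs(t), df=n - 2)
        p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
        constant = sy == 0
        r = np.where(constant, np.nan, r)
        p = np.where(constant, 1.0, p)
        out[clone] = pd.DataFrame({"r": r, "p": p}, index=normalized.index)
    return out


def lowest_dose_log2fc(
    normalized: pd.DataFrame, design: DoseDesign, clone: str,
    pseudocount: float = 0.5,
) -> pd.Series:
    """log2 fold change at the lowest nonzero dose vs dose 0."""
    samples = design.samples(clone)
    doses = design.doses(clone)
    lowest = min(d for d in doses if d > 0)
    base = [s for s in samples if design.sample_to_dose[s] == 0.0]
    low = [s for s in samples if design.sample_to_dose[s] == lowest]
    m0 = normalized[base].mean(axis=1)
    m1 = normalized[low].mean(axis=1)
    return np.log2((m1 + pseudocount) / (m0 + pseudocount))


def screen_targets(
    normalized: pd.DataFrame,
    design: DoseDesign,
    correlations: Mapping[str, pd.DataFrame] | None = None,
    alpha_wt: float = 0.01,
    alpha_mut: float = 0.05,
    lowest_dose_fc: float = 0.585,
    bh_correct: bool = False,
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Three-criterion direct-target screen; returns (UP, DOWN, table).

    UP: p < alpha_wt with r > 0 in both wild-type clones, lowest-dose
    |log2FC| >= theta with positive sign in both, and mutant p >
    alpha_mut.  DOWN is the mirror image.  The sets are disjoint by
    construction.
    """
    if correlations is None:
        correlations = dose_correlation(normalized, design)
    wt1, wt2 = design.wt_clones
    for clone in (wt1, wt2, design.mut_clone):
        if clone not in correlations:
            raise ValueError(f"missing correlation results for clone {clone}")
    c1, c2 = correlations[wt1], correlations[wt2]
    cm = correlations[design.mut_clone]
    p1, p2 = c1["p"].to_numpy(), c2["p"].to_numpy()
    if bh_correct:
        p1 = multipletests(p1, method="fdr_bh")[1]
        p2 = multipletests(p2, method="fdr_bh")[1]
    fc1 = lowest_dose_log2fc(normalized, design, wt1)
    fc2 = lowest_dose_log2fc(normalized, design, wt2)
    r1, r2 = c1["r"].to_numpy(), c2["r"].to_numpy()
    mut_ok = cm["p"].to_numpy() > alpha_mut
    sig = (p1 < alpha_wt) & (p2 < alpha_wt)
    fc_up = (fc1.to_numpy() >= lowest_dose_fc) & (fc2.to_numpy() >= lowest_dose_fc)
    fc_down = (fc1.to_numpy() <= -lowest_dose_fc) & (fc2.to_numpy() <= -lowest_dose_fc)
    up = sig & (r1 > 0) & (r2 > 0) & fc_up & mut_ok
    down = sig & (r1 < 0) & (r2 < 0) & fc_down & mut_ok
    table = pd.DataFrame(
        {
            f"r_{wt1}": r1,
            f"p_{wt1}": c1["p"].to_numpy(),
            f"r_{wt2}": r2,
            f"p_{wt2}": c2["p"].to_numpy(),
            f"p_{design.mut_clone}": cm["p"].to_numpy(),
            f"log2fc_lowest_{wt1}": fc1.to_numpy(),
            f"log2fc_lowest_{wt2}": fc2.to_numpy(),
            "classification": np.where(up, "UP", np.where(down, "DOWN", "none")),
        },
        index=normalized.index,
    )
    genes = normalized.index
    return list(genes[up]), list(genes[down]), table


def integrate_binding(
    up_genes: Sequence[str],
    down_genes: Sequence[str],
    per_gene_tag_totals: Mapping[str, int],
    strong_binder_threshold: int = 100,
) -> dict:
    """Bound-fraction summary of the screen sets.

    A gene is a strong binder with > ``strong_binder_threshold`` tags in
    qualifying clusters.  The two-sided Fisher test asks whether strong
    binding prefers the UP or DOWN set.
    """
    def split(genes):
        bound = sum(
            1 for g in genes
            if per_gene_tag_totals.get(g, 0) > strong_binder_threshold
        )
        return bound, len(genes) - bound

    up_b, up_u = split(up_genes)
    dn_b, dn_u = split(down_genes)
    if (up_b + up_u) and (dn_b + dn_u):
        _, p = stats.fisher_exact([[up_b, up_u], [dn_b, dn_u]])
    else:
        p = float("nan")
    return {
        "up_bound": up_b,
        "up_total": len(up_genes),
        "up_bound_fraction": up_b / len(up_genes) if up_genes else float("nan"),
        "down_bound": dn_b,
        "down_total": len(down_genes),
        "down_bound_fraction": dn_b / len(down_genes) if down_genes else float("nan"),
        "fisher_p": float(p),
    }


def signature_score(
    zscores: pd.DataFrame, gene_set: Sequence[str]
) -> pd.Series:
    """Per-sample sum of z-scores over a gene set.

    Genes absent from the matrix are dropped with a warning; an empty
    intersection is an error.
    """
    present = [g for g in gene_set if g in zscores.index]
    missing = sorted(set(gene_set) - set(present))
    if not present:
        raise ValueError("no gene of the set is present in the matrix")
    if missing:
        warnings.warn(
            f"{len(missing)} gene(s) of the set missing from the matrix: "
            + ", ".join(missing[:5])
        )
    return zscores.loc[present].sum(axis=0)
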