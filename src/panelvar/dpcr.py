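"""Digital-PCR Poisson quantification, panel-vs-dPCR concordance, and
cohort VAF-distribution summaries.

A droplet digital PCR run partitions the template into ~20,000 oil
droplets; the mean target copies per droplet follows from the Poisson zero
term, lambda = -ln(1 - k/n) for k positive droplets of n. The VAF implied
by a mutant and a wild-type channel is lambda_mut / (lambda_mut +
lambda_wt). Orthogonal dPCR measurements of low-VAF panel calls are
summarized by the Pearson correlation between the two VAF estimates;
cohort VAF distributions at hotspot groups are summarized as the fraction
of calls strictly below clinically salient thresholds (5, 10, 20%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

__all__ = ["DropletCount", "SaturatedAssayError", "dpcr_lambda", "dpcr_vaf",
           "vaf_concordance", "vaf_distribution_summary"]


class SaturatedAssayError(ValueError):
    """All droplets positive: lambda is unbounded, no estimate is made."""


@dataclass(frozen=True)
class DropletCount:
    """Droplet tallies of one dPCR channel."""

    n_total: int
    n_positive: int
    droplet_volume_nl: float = 0.85  # used only for absolute concentration

    def __post_init__(self) -> None:
        if not (0 <= self.n_positive <= self.n_total):
            raise ValueError("n_positive must be in [0, n_total]")
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        if self.droplet_volume_nl <= 0:
            raise ValueError("droplet_volume_nl must be positive")


def dpcr_lambda(droplets: DropletCount) -> float:
    """Mean target copies per droplet from the Poisson zero term."""
    if droplets.n_positive == droplets.n_total:
        raise SaturatedAssayError(
            "all droplets positive; concentration not quantifiable")
    return -math.log(1.0 - droplets.n_positive / droplets.n_total)


def dpcr_concentration(droplets: DropletCount) -> float:
    """Absolute concentration, copies per nL."""
    return dpcr_lambda(droplets) / droplets.droplet_volume_nl


def dpcr_vaf(mutant: DropletCount | float, wildtype: DropletCount | float) -> float:
    """VAF from mutant and wild-type channel lambdas (or droplet counts)."""
    lam_m = mutant if isinstance(mutant, float) else dpcr_lambda(mutant)
    lam_w = wildtype if isinstance(wildtype, float) else dpcr_lambda(wildtype)
    if lam_m < 0 or lam_w < 0:
        raise ValueError("lambdas must be >= 0")
    if lam_m + lam_w == 0:
        raise ValueError("both channels empty; VAF undefined")
    return lam_m / (lam_m + lam_w)


def vaf_concordance(pairs: pd.DataFrame,
                    depth_bins: int = 3) -> tuple[float, pd.DataFrame]:
    """Pearson correlation between panel and dPCR VAF estimates.

    ``pairs`` needs columns panel_vaf and dpcr_vaf (optionally depth). The
    report stratifies r by depth tertiles when depth is available — higher
    coverage variants tend to show higher concordance.
    """
    required = {"panel_vaf", "dpcr_vaf"}
    missing = required - set(pairs.columns)
    if missing:
        raise ValueError(f"pairs table missing columns: {sorted(missing)}")
    if len(pairs) < 3:
        raise ValueError("need >= 3 pairs")
    x = pairs["panel_vaf"].to_numpy(dtype=float)
    y = pairs["dpcr_vaf"].to_numpy(dtype=float)
    for arr, name in ((x, "panel_vaf"), (y, "dpcr_vaf")):
        if ((arr < 0) | (arr > 1)).any():
            raise ValueError(f"{name} outside [0, 1]")
        if np.ptp(arr) == 0:
            raise ValueError(f"{name} has zero variance")
    r = float(pearsonr(x, y).statistic)
    rows = [{"stratum": "all", "n": len(pairs), "pearson_r": r}]
    if "depth" in pairs.columns and len(pairs) >= 3 * depth_bins:
        strata = pd.qcut(pairs["depth"], depth_bins, duplicates="drop")
        for interval, grp in pairs.groupby(strata, observed=True):
            if len(grp) >= 3 and np.ptp(grp["panel_vaf"]) > 0 \
                    and np.ptp(grp["dpcr_vaf"]) > 0:
                rows.append({
                    "stratum": f"depth {interval}", "n": len(grp),
                    "pearson_r": float(pearsonr(grp["panel_vaf"],
                                                grp["dpcr_vaf"]).statistic)})
    return r, pd.DataFrame(rows)


def vaf_distribution_summary(calls: pd.DataFrame,
                             thresholds: Sequence[float] = (0.05, 0.10, 0.20),
                             group_col: str = "group",
                             vaf_col: str = "vaf") -> pd.DataFrame:
    """Fraction of calls per hotspot group strictly below each VAF threshold.

    Ties at a threshold count as not-below. Empty groups are omitted (the
    returned frame simply has no row for them). Fractions are
    non-decreasing in the threshold by construction.
    """
    if group_col not in calls.columns or vaf_col not in calls.columns:
        raise ValueError(f"calls table needs columns {group_col!r} and {vaf_col!r}")
    rows = []
    for group, grp in calls.groupby(group_col, sort=True):
        if grp.empty:
            continue
        vafs = grp[vaf_col].to_numpy(dtype=float)
        row: dict[str, object] = {"group": group, "n": len(vafs)}
        for t in thresholds:
            below = int((vafs < t).sum())
            row[f"frac_below_{t:g}"] = below / len(vafs)
            row[f"n_below_{t:g}"] = below
        rows.append(row)
    return pd.DataFrame(rows)
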