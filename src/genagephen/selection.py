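"""Selective-constraint contrasts on pairwise Ka/Ks ratios.

Disease versus non-disease (and young versus old) gene groups are compared
with the two-sided Wilcoxon rank-sum test: exact when both arms are small
and tie-free, exact permutation enumeration when small with ties, and the
normal approximation with tie correction otherwise.  The relationship
between pleiotropy and constraint is summarised as the Pearson correlation
between per-system-count bins (1..8, >= 9 by default) and the bin's median
Ka/Ks.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

EXACT_N_MAX = 25
DEFAULT_MAX_BIN = 9


@dataclass
class GroupComparison:
    """Two-group rank-sum contrast."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    statistic: float
    p_value: float
    method: str

    def to_dict(self) -> dict:
        return {
            "groups": [self.label_a, self.label_b],
            "n": [self.n_a, self.n_b],
            "medians": [self.median_a, self.median_b],
            "statistic": self.statistic,
            "p_value": self.p_value,
            "method": self.method,
        }


def compare_kaks_groups(values_a, values_b, label_a: str = "A",
                        label_b: str = "B") -> GroupComparison:
    """Two-sided Wilcoxon rank-sum comparison of two Ka/Ks samples.

    Method selection: exact Mann-Whitney null when both arms have
    n <= 25 and the pooled sample is tie-free; exact enumeration over all
    C(n_a + n_b, n_a) group splits when small with ties; otherwise the
    normal approximation with tie correction and continuity correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = len(a) <= EXACT_N_MAX and len(b) <= EXACT_N_MAX
    if small and not has_ties:
        method = "exact"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    elif small:
        method = "exact-permutation"
        n_splits = comb(len(a) + len(b), len(a))
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided",
            method=stats.PermutationMethod(n_resamples=n_splits,
                                           rng=np.random.default_rng(0)))
    else:
        method = "asymptotic-tie-corrected"
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic")
    return GroupComparison(
        label_a=label_a, label_b=label_b, n_a=len(a), n_b=len(b),
        median_a=float(np.median(a)), median_b=float(np.median(b)),
        statistic=float(res.statistic), p_value=float(min(1.0, res.pvalue)),
        method=method)


def bin_by_system_count(kaks: pd.DataFrame, profiles: pd.DataFrame,
                        partner: str | None = None,
                        purifying_only: bool = True,
                        max_bin: int = DEFAULT_MAX_BIN) -> pd.DataFrame:
    """Median Ka/Ks per affected-system-count bin.

    Genes with m >= ``max_bin`` pool into the top bin.  Returns a frame
    with columns ``bin`` (integer bin value), ``n_genes`` and
    ``median_ka_ks``; empty bins are omitted.
    """
    df = kaks.copy()
    if partner is not None:
        df = df[df["partner"] == partner]
    if purifying_only:
        df = df[df["ka_ks"] < 1.0]
    merged = df.merge(profiles[["gene_id", "m"]], on="gene_id", how="inner")
    merged["bin"] = merged["m"].clip(upper=max_bin)
    out = (merged.groupby("bin")
           .agg(n_genes=("gene_id", "nunique"), median_ka_ks=("ka_ks", "median"))
           .reset_index())
    return out


def kaks_pleiotropy_correlation(bins: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation between system-count bins and median Ka/Ks.

    Raises
    ------
    ValueError
        Fewer than 3 bins, or zero variance in the medians.
    """
    if len(bins) < 3:
        raise ValueError(f"need >= 3 bins, got {len(bins)}")
    x = bins["bin"].to_numpy(dtype=float)
    y = bins["median_ka_ks"].to_numpy(dtype=float)
    if np.std(y) == 0 or np.std(x) == 0:
        raise ValueError("zero variance: correlation undefined")
    rho, p = stats.pearsonr(x, y)
    return float(rho), float(p)


def disease_contrasts(kaks: pd.DataFrame, disease_ids: set[str],
                      purifying_only: bool = True) -> dict:
    """Per-partner disease versus non-disease Ka/Ks comparisons."""
    df = kaks[kaks["ka_ks"] < 1.0] if purifying_only else kaks
    out = {}
    for partner, grp in df.groupby("partner"):
        is_d = grp["gene_id"].isin(disease_ids)
        a, b = grp[is_d]["ka_ks"], grp[~is_d]["ka_ks"]
        if len(a) == 0 or len(b) == 0:
            continue
        out[str(partner)] = compare_kaks_groups(
            a, b, label_a="disease", label_b="non_disease").to_dict()
    return out
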