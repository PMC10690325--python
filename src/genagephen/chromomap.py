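"""Chromosomal distribution of disease genes: per-chromosome counts,
autosomal OLS expectation, excess rates, and sex-ratio statistics.

The model is deliberately simple: the number of disease genes on a
chromosome is regressed (ordinary least squares, with intercept) on the
total number of dated genes, over the 22 autosomes only.  X and Y are then
evaluated against the autosomal fit; a chromosome's *excess rate* is the
percent deviation of its observed count from the fitted expectation,
100 * (n - e) / e.  Sex bias in reproductive disease genes is summarised by
alpha_d = M/F (male over female reproductive disease gene counts) and by
fraction ratios between chromosome classes, reported together with the
cross-product odds ratio, a two-sided Fisher exact test and a Katz
log-scale confidence interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .age_framework import AgeFramework
from .config import AUTOSOMES, SEX_CHROMOSOMES

logger = logging.getLogger(__name__)

CHROM_ORDER = AUTOSOMES + SEX_CHROMOSOMES


@dataclass
class RegressionResult:
    """Autosomal OLS fit of disease counts on totals, evaluated everywhere."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_autosomes: int
    expected: pd.Series = field(repr=False)
    excess_pct: pd.Series = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "slope": self.slope, "intercept": self.intercept,
            "r_squared": self.r_squared, "p_value": self.p_value,
            "n_autosomes": self.n_autosomes,
            "expected": {k: float(v) for k, v in self.expected.items()},
            "excess_pct": {k: (None if pd.isna(v) else float(v))
                           for k, v in self.excess_pct.items()},
        }


@dataclass
class ProportionRatio:
    """Fraction-ratio contrast between two chromosome classes.

    ``ratio`` is (a_hits/a_total) / (b_hits/b_total) — the statistic the
    study headlines; ``odds_ratio`` is the 2x2 cross-product, reported
    separately under its honest name.  The CI is the Katz log-scale
    interval for the fraction ratio; the p-value is a two-sided Fisher
    exact test on the (integer-rounded) 2x2 table.
    """

    ratio: float
    odds_ratio: float
    fisher_p: float
    ci_low: float
    ci_high: float

    def to_dict(self) -> dict:
        return {"fraction_ratio": self.ratio, "odds_ratio": self.odds_ratio,
                "fisher_p": self.fisher_p,
                "ci95": [self.ci_low, self.ci_high]}


def count_by_chromosome(records: pd.DataFrame, profiles: pd.DataFrame,
                        framework: AgeFramework | None = None,
                        ancient_epoch: str = "Euteleostomi") -> pd.DataFrame:
    """Exhaustive per-chromosome tallies of dated and disease genes.

    Returns a frame indexed by chromosome (1..22, X, Y) with columns:
    ``total`` (dated genes), ``disease``, ``reproductive``,
    ``non_reproductive``, ``male_specific``, ``female_specific``,
    ``both``, ``sex_none`` (reproductive-class partition of disease genes)
    and, when a framework is given, the age split ``ancient_disease`` /
    ``young_disease`` (ancient = the configured oldest epoch) plus the same
    split within male/female-specific categories.
    """
    idx = pd.Index(CHROM_ORDER, name="chromosome")
    out = pd.DataFrame(index=idx)
    out["total"] = (records.groupby("chromosome").size()
                    .reindex(idx, fill_value=0))
    prof = profiles[profiles["chromosome"].isin(CHROM_ORDER)]
    g = prof.groupby("chromosome")
    out["disease"] = g.size().reindex(idx, fill_value=0)
    out["reproductive"] = (g["is_reproductive"].sum()
                           .reindex(idx, fill_value=0).astype(int))
    out["non_reproductive"] = out["disease"] - out["reproductive"]
    for cls, col in [("male_specific", "male_specific"),
                     ("female_specific", "female_specific"),
                     ("both", "both"), ("none", "sex_none")]:
        out[col] = (g["reproductive_class"]
                    .agg(lambda s, c=cls: int((s == c).sum()))
                    .reindex(idx, fill_value=0))
    if framework is not None:
        epochs = prof["branch"].map(framework.assign_epoch)
        is_ancient = epochs == ancient_epoch
        out["ancient_disease"] = (prof[is_ancient].groupby("chromosome").size()
                                  .reindex(idx, fill_value=0))
        out["young_disease"] = out["disease"] - out["ancient_disease"]
        for col, cls in [("male_specific", "male_specific"),
                         ("female_specific", "female_specific")]:
            sel = prof["reproductive_class"] == cls
            out[f"ancient_{col}"] = (prof[sel & is_ancient]
                                     .groupby("chromosome").size()
                                     .reindex(idx, fill_value=0))
            out[f"young_{col}"] = out[col] - out[f"ancient_{col}"]
    return out.fillna(0).astype(int)


def excess_rate(observed: float, expected: float) -> float:
    """Percent deviation of an observed count from its expectation:
    100 * (n - e) / e."""
    if expected <= 0:
        raise ValueError(f"expected count must be positive, got {expected}")
    return 100.0 * (observed - expected) / expected


def fit_autosomal_ols(counts: pd.DataFrame, y_col: str = "disease",
                      x_col: str = "total") -> RegressionResult:
    """OLS of ``y_col`` on ``x_col`` over the 22 autosomes, with intercept.

    X and Y are excluded from the fit but evaluated against it: the result
    carries fitted expectations and excess rates for every chromosome.

    Raises
    ------
    ValueError
        Fewer than 3 autosomes with nonzero totals, or degenerate
        x-variance.
    """
    auto = counts.loc[[c for c in AUTOSOMES if c in counts.index]]
    auto = auto[auto[x_col] > 0]
    if len(auto) < 3:
        raise ValueError(f"need >= 3 autosomes with nonzero totals, got {len(auto)}")
    x = auto[x_col].to_numpy(dtype=float)
    y = auto[y_col].to_numpy(dtype=float)
    if np.var(x) == 0:
        raise ValueError("degenerate x-variance on autosomes")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = model.params
    expected = intercept + slope * counts[x_col].astype(float)
    excess = pd.Series(
        [excess_rate(n, e) if e > 0 else np.nan
         for n, e in zip(counts[y_col], expected)],
        index=counts.index, name="excess_pct")
    n_nonpos = int((expected <= 0).sum())
    if n_nonpos:
        logger.warning("%d chromosomes have nonpositive expected counts; "
                       "excess rate undefined there", n_nonpos)
    return RegressionResult(
        slope=float(slope), intercept=float(intercept),
        r_squared=float(model.rsquared), p_value=float(model.f_pvalue),
        n_autosomes=len(auto), expected=expected.rename("expected"),
        excess_pct=excess)


def alpha_d(male_count: float, female_count: float) -> float:
    """Male-to-female reproductive disease gene ratio M/F.

    Raises
    ------
    ValueError
        If the female count is zero (the ratio is undefined).
    """
    if female_count <= 0:
        raise ValueError("alpha_d undefined: female count is zero")
    return male_count / female_count


def proportion_ratio(a_hits: float, a_total: float, b_hits: float,
                     b_total: float, z: float = 1.959963984540054,
                     ) -> ProportionRatio:
    """Fraction ratio (a_hits/a_total) / (b_hits/b_total) with exact-test
    p-value and Katz log-scale CI.

    The Fisher exact test runs on the 2x2 table of rounded integer counts
    (mean per-chromosome counts may be fractional); the ratio itself uses
    the unrounded values.
    """
    if a_total <= 0 or b_total <= 0:
        raise ValueError("totals must be positive")
    if b_hits <= 0:
        raise ValueError("reference hits must be positive for a ratio")
    ratio = (a_hits / a_total) / (b_hits / b_total)
    table = np.round([[a_hits, a_total - a_hits],
                      [b_hits, b_total - b_hits]]).astype(int)
    odds, fisher_p = stats.fisher_exact(table, alternative="two-sided")
    if a_hits > 0:
        se = np.sqrt(max(0.0, 1.0 / a_hits - 1.0 / a_total
                         + 1.0 / b_hits - 1.0 / b_total))
        ci_low = ratio * np.exp(-z * se)
        ci_high = ratio * np.exp(z * se)
    else:
        ci_low, ci_high = 0.0, np.nan
    return ProportionRatio(ratio=float(ratio), odds_ratio=float(odds),
                           fisher_p=float(fisher_p),
                           ci_low=float(ci_low), ci_high=float(ci_high))


def sex_ratio_summary(counts: pd.DataFrame) -> dict:
    """alpha_d and X/Y-versus-autosome fraction ratios from a counts table.

    Autosomal baselines follow the mean-per-autosome convention: hits and
    totals averaged over the 22 autosomes.
    """
    auto = counts.loc[[c for c in AUTOSOMES if c in counts.index]]
    mean_male = float(auto["male_specific"].mean())
    mean_female = float(auto["female_specific"].mean())
    mean_total = float(auto["total"].mean())
    out: dict = {
        "autosome_mean": {"male_specific": mean_male,
                          "female_specific": mean_female,
                          "total": mean_total},
    }
    if mean_female > 0:
        out["alpha_d_autosome_mean"] = alpha_d(mean_male, mean_female)
    for chrom in SEX_CHROMOSOMES:
        if chrom not in counts.index:
            continue
        row = counts.loc[chrom]
        entry: dict = {"male_specific": int(row["male_specific"]),
                       "female_specific": int(row["female_specific"]),
                       "total": int(row["total"])}
        if row["female_specific"] > 0:
            entry["alpha_d"] = alpha_d(row["male_specific"],
                                       row["female_specific"])
        if row["total"] > 0 and mean_male > 0 and mean_total > 0:
            entry["male_fraction_ratio_vs_autosomes"] = proportion_ratio(
                row["male_specific"], row["total"],
                mean_male, mean_total).to_dict()
        out[chrom] = entry
    return out


def age_split_analysis(counts: pd.DataFrame, profiles: pd.DataFrame,
                       framework: AgeFramework,
                       ancient_epoch: str = "Euteleostomi") -> dict:
    """Regression/excess machinery within the ancient/young age split,
    plus the per-epoch alpha_d sequence.

    For each split (ancient = the oldest epoch; young = everything else)
    and each sex-specific category, the autosomal OLS is refitted and the
    X/Y excess rates recomputed.  Per-epoch alpha_d uses profile counts by
    reproductive class.  Splits with no genes are flagged and skipped.
    """
    out: dict = {"splits": {}, "alpha_d_by_epoch": {}}
    for split in ("ancient", "young"):
        section: dict = {}
        for cat in ("male_specific", "female_specific", "disease"):
            col = f"{split}_{cat}" if cat != "disease" else f"{split}_disease"
            if col not in counts.columns or counts[col].sum() == 0:
                logger.warning("age split %s/%s empty; skipped", split, cat)
                continue
            try:
                reg = fit_autosomal_ols(counts, y_col=col)
            except ValueError as exc:
                logger.warning("age split %s/%s regression skipped: %s",
                               split, cat, exc)
                continue
            section[cat] = {
                "slope": reg.slope, "intercept": reg.intercept,
                "r_squared": reg.r_squared, "p_value": reg.p_value,
                "excess_pct_X": (float(reg.excess_pct.get("X", np.nan))
                                 if "X" in reg.excess_pct else None),
                "excess_pct_Y": (float(reg.excess_pct.get("Y", np.nan))
                                 if "Y" in reg.excess_pct else None),
            }
        out["splits"][split] = section

    epochs = profiles["branch"].map(framework.assign_epoch)
    for epoch in framework.epochs:
        sel = profiles[epochs == epoch]
        m = int((sel["reproductive_class"] == "male_specific").sum())
        f = int((sel["reproductive_class"] == "female_specific").sum())
        out["alpha_d_by_epoch"][epoch] = {
            "male": m, "female": f,
            "alpha_d": alpha_d(m, f) if f > 0 else None,
        }
    return out
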