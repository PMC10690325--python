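"""Disease-gene emergence rate per branch and its per-generation and
prevalence derivations.

The per-branch rate is r_i = O_i / (A_i * T_i): the fraction of a branch's
dated genes (A_i) that are disease genes (O_i), per million years of branch
time (T_i).  Under a simplified monogenic model, a genome-wide rate r (per
gene per year) converts to the expected number of causal rare-disease genes
per individual per generation, mu_d = G * g * r, with G the coding-gene
count and g the generation time in years; the derived rare-disease
prevalence is r_RD = 10,000 * mu_d per 10,000 individuals.

Units are carried explicitly: a rate printed as "0.07% per million years"
is the per-year per-gene fraction 0.07e-8, and the conversions between the
two are named functions, never implicit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .age_framework import AgeFramework

#: Defaults for the generation model: Ensembl v110 coding-gene count and the
#: mean human generation interval in years.
DEFAULT_CODING_GENES = 19_831
DEFAULT_GENERATION_YEARS = 26.9
DEFAULT_RATE_PCT_PER_MY = 0.07


@dataclass(frozen=True)
class GenerationModel:
    """Per-generation and prevalence derivation of a genome-wide rate."""

    coding_genes: int
    generation_years: float
    rate_per_gene_per_year: float
    mu_d: float
    prevalence_per_10k: float
    prevalence_rounded: int

    def to_dict(self) -> dict:
        return {
            "G_coding_genes": self.coding_genes,
            "g_generation_years": self.generation_years,
            "r_per_gene_per_year": self.rate_per_gene_per_year,
            "mu_d": self.mu_d,
            "r_RD_per_10000": self.prevalence_per_10k,
            "r_RD_rounded": self.prevalence_rounded,
        }


def emergence_rate(O_i: float, A_i: float, T_i: float) -> float:
    """Per-branch emergence rate r_i = O_i / (A_i * T_i), per My.

    Raises
    ------
    ValueError
        If ``A_i`` is zero/negative or ``T_i`` is not positive.
    """
    if A_i <= 0:
        raise ValueError(f"A_i must be positive, got {A_i}")
    if T_i <= 0:
        raise ValueError(f"T_i must be positive, got {T_i}")
    if O_i < 0 or O_i > A_i:
        raise ValueError(f"O_i must satisfy 0 <= O_i <= A_i, got {O_i}")
    return O_i / (A_i * T_i)


def percent_per_my_to_per_year(rate_pct_per_my: float) -> float:
    """Convert a rate printed as % per My to a per-gene per-year fraction.

    0.07 % per My = 0.0007 per My = 0.07e-8 per year.
    """
    return rate_pct_per_my * 1e-8


def fraction_per_my_to_percent(rate_per_my: float) -> float:
    return rate_per_my * 100.0


def per_generation_rate(coding_genes: float, generation_years: float,
                        rate_per_gene_per_year: float) -> float:
    """mu_d = G * g * r: expected causal rare-disease genes per individual
    per generation, under the simplified monogenic model."""
    if coding_genes <= 0 or generation_years <= 0:
        raise ValueError("coding_genes and generation_years must be positive")
    if rate_per_gene_per_year < 0:
        raise ValueError("rate must be nonnegative")
    return coding_genes * generation_years * rate_per_gene_per_year


def round_half_away(x: float) -> int:
    """Round half away from zero (3.5 -> 4, -3.5 -> -4)."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def prevalence(mu_d: float) -> tuple[float, int]:
    """Rare-disease prevalence per 10,000 individuals: r_RD = 10,000 * mu_d.

    Returns the real value and its nearest-integer presentation (half away
    from zero).
    """
    if mu_d < 0:
        raise ValueError("mu_d must be nonnegative")
    r_rd = 10_000.0 * mu_d
    return r_rd, round_half_away(r_rd)


def generation_model(coding_genes: int = DEFAULT_CODING_GENES,
                     generation_years: float = DEFAULT_GENERATION_YEARS,
                     rate_pct_per_my: float = DEFAULT_RATE_PCT_PER_MY,
                     ) -> GenerationModel:
    """Bundle the mu_d / prevalence derivation for a %-per-My rate."""
    r_year = percent_per_my_to_per_year(rate_pct_per_my)
    mu_d = per_generation_rate(coding_genes, generation_years, r_year)
    r_rd, r_rd_int = prevalence(mu_d)
    return GenerationModel(coding_genes, generation_years, r_year, mu_d,
                           r_rd, r_rd_int)


def branch_stats(records: pd.DataFrame, disease_gene_ids: set[str] | pd.Series,
                 framework: AgeFramework) -> pd.DataFrame:
    """Per-branch O_i, A_i, T_i and emergence rate.

    Parameters
    ----------
    records
        Gene-age records with ``gene_id`` and ``branch`` columns (branches
        already merged).
    disease_gene_ids
        Genes counted as disease genes (must be a subset of the records to
        contribute).

    Returns
    -------
    DataFrame indexed by branch (oldest first) with columns
    ``O, A, T_my, r_per_my, r_pct_per_my``; branches with no dated genes
    are flagged with NaN rates.
    """
    ids = set(disease_gene_ids)
    per_branch = records.groupby("branch")["gene_id"]
    A = per_branch.size()
    O = per_branch.agg(lambda s: int(s.isin(ids).sum()))
    out = pd.DataFrame(index=pd.Index(framework.labels, name="branch"))
    out["O"] = O.reindex(out.index).fillna(0).astype(int)
    out["A"] = A.reindex(out.index).fillna(0).astype(int)
    out["T_my"] = [framework.branch_duration(b) for b in out.index]
    rates = []
    for b, row in out.iterrows():
        if row["A"] == 0:
            rates.append(np.nan)
        else:
            rates.append(emergence_rate(row["O"], row["A"], row["T_my"]))
    out["r_per_my"] = rates
    out["r_pct_per_my"] = out["r_per_my"] * 100.0
    return out
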