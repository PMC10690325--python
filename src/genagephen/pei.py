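"""Phenotype enrichment index (PEI) per organ system within each
evolutionary stage.

Each disease gene contributes weight 1/m to every distinct organ system it
affects, where m is the gene's *global* system count (over all 22 systems,
not restricted to the stage): the more systems a gene affects, the less it
contributes to any one of them.  Within a stage, a system's PEI is the
percentage of the stage's total weighted contribution attributable to that
system, so every stage's PEI values sum to 100.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import SYSTEM_LABELS

logger = logging.getLogger(__name__)


def gene_weight(m: int) -> float:
    """Contribution weight of a gene with pleiotropy m: 1/m."""
    if m < 1:
        raise ValueError(f"pleiotropy m must be >= 1, got {m}")
    return 1.0 / m


def pei_table(profiles: pd.DataFrame, stage_col: str = "stage",
              systems: list[str] | None = None) -> pd.DataFrame:
    """Stage-by-system PEI percentage matrix.

    Parameters
    ----------
    profiles
        One row per disease gene, with a ``systems`` frozenset column, an
        ``m`` column (global distinct-system count) and a stage label
        column.  A gene contributes its weight once per distinct system it
        touches, regardless of how many annotation terms produced the link.
    systems
        Column order of the output (defaults to the 22 OP labels).

    Returns
    -------
    DataFrame indexed by stage with one column per system; each row sums
    to 100 (stages with zero profiles are omitted with a warning).
    """
    systems = list(systems) if systems is not None else list(SYSTEM_LABELS)
    if profiles.empty:
        logger.warning("no profiles: empty PEI table")
        return pd.DataFrame(columns=systems)
    stages = []
    rows = []
    for stage, grp in profiles.groupby(stage_col, sort=True):
        if grp.empty:
            logger.warning("stage %s has no profiles; row omitted", stage)
            continue
        weights = np.zeros(len(systems))
        index = {s: i for i, s in enumerate(systems)}
        for m, gene_systems in zip(grp["m"], grp["systems"]):
            w = gene_weight(int(m))
            for s in gene_systems:
                weights[index[s]] += w
        total = weights.sum()
        if total == 0:
            logger.warning("stage %s has zero total weight; row omitted", stage)
            continue
        stages.append(stage)
        rows.append(100.0 * weights / total)
    table = pd.DataFrame(rows, index=pd.Index(stages, name=stage_col),
                         columns=systems)
    return table


def pei_dispersion(table: pd.DataFrame) -> pd.Series:
    """Per-stage population standard deviation of the PEI values.

    Computed over all system columns of the row (ddof = 0); a uniform row
    has dispersion 0 and a row dominated by one system has a large one.
    """
    return table.std(axis=1, ddof=0).rename("pei_sd")
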