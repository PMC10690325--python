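"""X-chromosome region classification: pseudoautosomal regions, the
conserved/added split, and evolutionary strata.

The eutherian X carries two pseudoautosomal regions (PARs, still
recombining with Y), an X-conserved region shared with the marsupial X,
and an X-added region translocated from autosomes in the eutherian
ancestor.  Finer-grained "evolutionary strata" partition the non-PAR X by
X-Y divergence age, with published coordinate sets from a substitutions
method and a segmentation-and-clustering method.  All coordinate sets are
editable BED-like configuration, not code; intervals are 1-based and
closed, and a gene is assigned by its start coordinate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .config import DEFAULT_X_REGIONS

logger = logging.getLogger(__name__)

MAP_COLUMNS = ["chrom", "start", "end", "label", "method"]


class RegionMapError(ValueError):
    """Invalid X-region map."""


@dataclass
class RegionFraction:
    """Per-region hit fraction: m hits out of b background genes."""

    region: str
    hits: int
    background: int

    @property
    def fraction_pct(self) -> float | None:
        if self.background == 0:
            return None
        return 100.0 * self.hits / self.background


class XRegionMap:
    """Interval map of the X chromosome for one or more methods.

    Methods are independent interval sets (``par``, ``synteny``,
    ``substitutions``, ``segmentation_clustering`` by default); within a
    method intervals must not overlap.  The ``par`` method must contain
    exactly two intervals.
    """

    def __init__(self, table: pd.DataFrame):
        missing = set(MAP_COLUMNS) - set(table.columns)
        if missing:
            raise RegionMapError(f"region map missing columns {sorted(missing)}")
        df = table[MAP_COLUMNS].copy()
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        if (df["start"] <= 0).any() or (df["end"] < df["start"]).any():
            raise RegionMapError("intervals must have 0 < start <= end")
        self.table = df.reset_index(drop=True)
        self._by_method: dict[str, list[tuple[int, int, str]]] = {}
        for method, grp in df.groupby("method"):
            ivals = sorted((int(s), int(e), str(lab))
                           for s, e, lab in zip(grp["start"], grp["end"], grp["label"]))
            for (s1, e1, _), (s2, _, _) in zip(ivals, ivals[1:]):
                if s2 <= e1:
                    raise RegionMapError(
                        f"overlapping intervals in method {method!r}")
            self._by_method[method] = ivals
        if "par" in self._by_method and len(self._by_method["par"]) != 2:
            raise RegionMapError("the 'par' method must define exactly two intervals")

    @classmethod
    def default(cls) -> "XRegionMap":
        return cls(pd.DataFrame(DEFAULT_X_REGIONS, columns=MAP_COLUMNS))

    @classmethod
    def from_tsv(cls, path) -> "XRegionMap":
        return cls(pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str}))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @property
    def methods(self) -> list[str]:
        return sorted(self._by_method)

    def lookup(self, position: int, method: str) -> str | None:
        """Label of the interval containing a 1-based position, or None."""
        if method not in self._by_method:
            raise RegionMapError(f"unknown method {method!r}; "
                                 f"available: {self.methods}")
        for start, end, label in self._by_method[method]:
            if start <= position <= end:
                return label
        return None


def classify_par(record, region_map: XRegionMap) -> str:
    """PAR / nonPAR call for an X-linked gene (by its start coordinate).

    Raises
    ------
    ValueError
        If the gene is not on the X chromosome.
    """
    chrom = str(record["chromosome"] if hasattr(record, "__getitem__")
                else record.chromosome)
    if chrom.replace("chr", "") != "X":
        raise ValueError(f"classify_par expects an X-linked gene, got chr{chrom}")
    pos = int(record["start"] if hasattr(record, "__getitem__") else record.start)
    return "PAR" if region_map.lookup(pos, "par") is not None else "nonPAR"


def assign_region(record, region_map: XRegionMap, method: str) -> str:
    """Region/stratum label of a non-PAR X gene under one method.

    Genes whose start falls in no interval get ``"unassigned"`` (logged).
    """
    pos = int(record["start"] if hasattr(record, "__getitem__") else record.start)
    label = region_map.lookup(pos, method)
    if label is None:
        logger.debug("position %d unassigned under method %s", pos, method)
        return "unassigned"
    return label


def label_x_genes(records: pd.DataFrame, region_map: XRegionMap,
                  method: str) -> pd.DataFrame:
    """Label every X-linked gene with PAR status and a region for a method.

    Returns the X-linked subset of ``records`` with added columns
    ``par_status`` and ``region`` (PAR genes keep region ``"PAR"``; they
    are excluded from strata analyses downstream).
    """
    x = records[records["chromosome"].astype(str).str.replace("chr", "") == "X"].copy()
    x["par_status"] = [classify_par(row, region_map) for _, row in x.iterrows()]
    x["region"] = [
        "PAR" if par == "PAR" else assign_region(row, region_map, method)
        for (_, row), par in zip(x.iterrows(), x["par_status"])
    ]
    return x


def region_fractions(labelled: pd.DataFrame, hits: pd.Series,
                     exclude_par: bool = True) -> list[RegionFraction]:
    """Per-region hit counts m, background counts b, and 100*m/b.

    Parameters
    ----------
    labelled
        Output of :func:`label_x_genes` (must carry ``region``).
    hits
        Boolean series aligned with ``labelled`` (e.g. "is a male-specific
        reproductive disease gene").
    exclude_par
        Drop PAR genes from the tally (the default, matching the study's
        strata analyses).
    """
    df = labelled.copy()
    df["hit"] = hits.reindex(df.index).fillna(False).astype(bool)
    if exclude_par:
        df = df[df["region"] != "PAR"]
    out = []
    for region, grp in df.groupby("region", sort=True):
        frac = RegionFraction(region=str(region), hits=int(grp["hit"].sum()),
                              background=len(grp))
        if frac.background == 0:
            logger.warning("region %s has zero background; fraction undefined",
                           region)
        out.append(frac)
    return out


def fractions_frame(fracs: list[RegionFraction]) -> pd.DataFrame:
    return pd.DataFrame(
        {"region": [f.region for f in fracs],
         "m_hits": [f.hits for f in fracs],
         "b_background": [f.background for f in fracs],
         "fraction_pct": [f.fraction_pct for f in fracs]})
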