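"""Readers, filters and joins for the analysis inputs.

Four tab-separated inputs are normalised here into analysis-ready tables:

* the gene-age table (one row per dated gene, with chromosome placement,
  biotype and ancestral branch label);
* gene-phenotype annotation files in the two standard HPO dialects
  (``genes_to_phenotype`` / ``phenotype_to_genes``);
* the phenotype-term to organ-system mapping (22 OP systems);
* the pairwise ortholog Ka/Ks table.

Filtering mirrors the study design: mitochondrial genes, unplaced genes and
non-protein-coding (RNA) genes are dropped from the age table; annotation
links under neoplasm terms are removed; reproductive classification uses
case-insensitive "reproduct"/"male"/"female" keyword matching on term names
(testing "female" before "male", since the former contains the latter as a
substring).  Every exclusion is tallied in a :class:`FilterReport` so that
``removed + retained == input`` always holds.

The canonical dialect is tab-separated UTF-8 with a header row; lines
starting with ``#`` are comments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .config import PLACED_CHROMOSOMES, SYSTEM_LABELS

logger = logging.getLogger(__name__)

GENE_AGE_COLUMNS = ["gene_id", "symbol", "chromosome", "start", "end", "biotype", "branch"]

#: Column orders of the two supported annotation dialects.
HPO_DIALECTS = {
    "gene_to_phenotype": ["gene_id", "gene_symbol", "hpo_id", "hpo_name"],
    "phenotype_to_gene": ["hpo_id", "hpo_name", "gene_id", "gene_symbol"],
}

REPRODUCTIVE_CLASSES = ["none", "female_specific", "male_specific", "both"]


class IngestError(ValueError):
    """Configuration or record-level input error."""


@dataclass
class FilterReport:
    """Tally of records removed per rule; ``removed + retained == input``."""

    input_count: int = 0
    retained: int = 0
    removed: dict[str, int] = field(default_factory=dict)

    def add_removed(self, rule: str, n: int = 1) -> None:
        self.removed[rule] = self.removed.get(rule, 0) + n

    @property
    def removed_total(self) -> int:
        return sum(self.removed.values())

    def validate(self) -> None:
        if self.removed_total + self.retained != self.input_count:
            raise AssertionError(
                f"filter report does not conserve records: "
                f"{self.removed_total} removed + {self.retained} retained "
                f"!= {self.input_count} input")

    def to_dict(self) -> dict:
        return {"input": self.input_count, "retained": self.retained,
                "removed": dict(self.removed)}


def _read_tsv(path, names: list[str] | None = None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str,
                       header=0, names=names, skip_blank_lines=True)


def read_gene_age_table(path, columns: dict[str, str] | None = None,
                        ) -> tuple[pd.DataFrame, FilterReport]:
    """Read and filter the gene-age table.

    Parameters
    ----------
    path
        TSV with a header; required logical columns are
        ``gene_id, symbol, chromosome, start, end, biotype, branch``.
    columns
        Optional mapping from logical column name to the file's column
        name, for inputs with different headers.

    Returns
    -------
    (records, report)
        ``records`` keeps only protein-coding genes on placed nuclear
        chromosomes (1-22, X, Y).  ``report`` tallies removals per rule:
        ``mitochondrial``, ``unplaced``, ``RNA`` (any non-protein-coding
        biotype).

    Raises
    ------
    IngestError
        If a required column is missing, or a coordinate fails to parse
        (the error names the offending line).
    """
    raw = _read_tsv(path)
    colmap = {c: c for c in GENE_AGE_COLUMNS}
    if columns:
        colmap.update(columns)
    missing = [logical for logical, actual in colmap.items() if actual not in raw.columns]
    if missing:
        raise IngestError(
            f"gene-age table is missing required column(s): "
            f"{', '.join(colmap[m] for m in missing)}")
    df = raw.rename(columns={v: k for k, v in colmap.items()})[GENE_AGE_COLUMNS].copy()

    for coord in ("start", "end"):
        parsed = pd.to_numeric(df[coord], errors="coerce")
        bad = parsed.isna() | (parsed % 1 != 0) | (parsed < 1)
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise IngestError(
                f"malformed {coord} coordinate {df[coord][bad.idxmax()]!r} "
                f"at data line {line}")
        df[coord] = parsed.astype(int)
    if (df["start"] > df["end"]).any():
        i = int((df["start"] > df["end"]).idxmax())
        raise IngestError(f"start > end at data line {i + 2}")

    report = FilterReport(input_count=len(df))
    is_mt = df["chromosome"].str.upper().isin({"MT", "M", "CHRM", "CHRMT"})
    chrom_clean = df["chromosome"].str.replace("^chr", "", regex=True)
    is_unplaced = ~is_mt & ~chrom_clean.isin(PLACED_CHROMOSOMES)
    is_rna = ~is_mt & ~is_unplaced & (df["biotype"] != "protein_coding")
    report.add_removed("mitochondrial", int(is_mt.sum()))
    report.add_removed("unplaced", int(is_unplaced.sum()))
    report.add_removed("RNA", int(is_rna.sum()))
    kept = df[~(is_mt | is_unplaced | is_rna)].copy()
    kept["chromosome"] = chrom_clean[kept.index]
    report.retained = len(kept)
    report.validate()
    return kept.reset_index(drop=True), report


def read_hpo_annotations(path, direction: str = "gene_to_phenotype") -> pd.DataFrame:
    """Read a gene-phenotype annotation file and de-duplicate links.

    Parameters
    ----------
    direction
        ``"gene_to_phenotype"`` or ``"phenotype_to_gene"``; selects the
        column order of the dialect.

    Returns
    -------
    DataFrame with columns ``gene_id, gene_symbol, hpo_id, hpo_name``; each
    (gene, term) pair appears once, term names preserved verbatim.
    """
    if direction not in HPO_DIALECTS:
        raise IngestError(
            f"unknown annotation dialect {direction!r}; "
            f"expected one of {sorted(HPO_DIALECTS)}")
    raw = _read_tsv(path)
    expected = HPO_DIALECTS[direction]
    if len(raw.columns) < len(expected):
        raise IngestError(
            f"{direction} file has {len(raw.columns)} columns, "
            f"expected at least {len(expected)}")
    df = raw.iloc[:, : len(expected)].copy()
    df.columns = expected
    df = df[["gene_id", "gene_symbol", "hpo_id", "hpo_name"]]
    before = len(df)
    df = df.drop_duplicates(subset=["gene_id", "hpo_id"]).reset_index(drop=True)
    dropped = before - len(df)
    if dropped:
        logger.info("collapsed %d duplicate (gene, term) rows", dropped)
    return df


def apply_term_filters(links: pd.DataFrame, neoplasm_terms: set[str],
                       ) -> tuple[pd.DataFrame, FilterReport]:
    """Remove annotation links whose term is in the neoplasm subtree.

    An empty term set is allowed (a warning is logged and all links pass).
    """
    report = FilterReport(input_count=len(links))
    if not neoplasm_terms:
        logger.warning("empty neoplasm term set: no links filtered")
        report.add_removed("neoplasm-term", 0)
        report.retained = len(links)
        report.validate()
        return links.copy(), report
    is_neo = links["hpo_id"].isin(neoplasm_terms)
    report.add_removed("neoplasm-term", int(is_neo.sum()))
    kept = links[~is_neo].reset_index(drop=True)
    report.retained = len(kept)
    report.validate()
    return kept, report


def load_neoplasm_terms(path) -> set[str]:
    """Load a neoplasm term-id set from a plain-text file (one id per line)
    or, for ``.obo`` files, as the descendants of the neoplasm root term
    (requires the optional :mod:`obonet` dependency)."""
    path = str(path)
    if path.endswith(".obo"):
        import networkx as nx
        import obonet

        graph = obonet.read_obo(path)
        root = "HP:0002664"
        if root not in graph:
            raise IngestError(f"neoplasm root {root} absent from {path}")
        # edges point child -> parent, so the subtree is the ancestor set
        return {root} | nx.ancestors(graph, root)
    with open(path) as fh:
        return {line.strip() for line in fh
                if line.strip() and not line.startswith("#")}


def read_system_mapping(path) -> pd.DataFrame:
    """Read the term-to-organ-system mapping table (``hpo_id, system``).

    A term may map to several of the 22 systems (multi-axial annotation);
    each (term, system) pair is one row.
    """
    df = _read_tsv(path)
    if not {"hpo_id", "system"}.issubset(df.columns):
        raise IngestError("system mapping needs columns 'hpo_id' and 'system'")
    bad = set(df["system"].unique()) - set(SYSTEM_LABELS)
    if bad:
        raise IngestError(f"mapping uses unknown system labels: {sorted(bad)}")
    return df[["hpo_id", "system"]].drop_duplicates().reset_index(drop=True)


def map_terms_to_systems(links: pd.DataFrame, mapping: pd.DataFrame,
                         ) -> tuple[pd.DataFrame, FilterReport]:
    """Label links with organ systems.

    A term descending from several of the 22 top-level systems yields one
    labelled link per system (each counts toward the gene's pleiotropy m).
    Links whose term has no mapping are flagged ``unmapped`` and excluded.

    Returns
    -------
    (labelled, report)
        ``labelled`` has the link columns plus ``system``; the report counts
        input *links*, with ``unmapped-system`` removals (a multi-system
        term still counts as one retained link; the extra rows are recorded
        separately in ``report.removed['multi-system-expansion']`` as a
        negative removal would break conservation, so expansions are logged,
        not tallied as removals).
    """
    report = FilterReport(input_count=len(links))
    merged = links.merge(mapping, on="hpo_id", how="left")
    unmapped_links = merged[merged["system"].isna()]["hpo_id"]
    n_unmapped = links["hpo_id"].isin(set(unmapped_links)).sum()
    report.add_removed("unmapped-system", int(n_unmapped))
    labelled = merged.dropna(subset=["system"]).reset_index(drop=True)
    report.retained = report.input_count - report.removed_total
    report.validate()
    n_multi = len(labelled) - report.retained
    if n_multi:
        logger.info("%d extra rows from multi-system terms", n_multi)
    if report.input_count:
        frac = report.removed["unmapped-system"] / report.input_count
        if frac > 0:
            logger.info("unmapped-term link fraction: %.3f", frac)
    return labelled, report


_KEYWORDS = ("reproduct", "male", "female")


def _term_sex_flags(name: str) -> tuple[bool, bool, bool]:
    """(is_reproductive_keyword, is_female, is_male) for one term name.

    "female" is tested before "male" because the former contains the latter
    as a substring; matching is case-insensitive.
    """
    low = name.lower()
    female = "female" in low
    male = (not female) and ("male" in low)
    repro = "reproduct" in low or female or male
    return repro, female, male


def classify_reproductive(links: pd.DataFrame) -> pd.DataFrame:
    """Classify genes by sex-specific reproductive phenotype keywords.

    Scans every term name of every gene.  Genes whose matching terms are
    all male-context become ``male_specific``; all female-context,
    ``female_specific``; both kinds, ``both``; no keyword match, ``none``.
    A gene matching only the generic "reproduct" keyword is reproductive
    but sex-unspecific (class ``none``, ``is_reproductive`` True).

    Returns
    -------
    DataFrame with columns ``gene_id, reproductive_class, is_reproductive``;
    deterministic and invariant to link order.
    """
    flags = links["hpo_name"].map(_term_sex_flags)
    df = pd.DataFrame({
        "gene_id": links["gene_id"],
        "repro": [f[0] for f in flags],
        "female": [f[1] for f in flags],
        "male": [f[2] for f in flags],
    })
    agg = df.groupby("gene_id", sort=True).agg(
        repro=("repro", "any"), female=("female", "any"), male=("male", "any"))

    def _cls(row) -> str:
        if row.female and row.male:
            return "both"
        if row.male:
            return "male_specific"
        if row.female:
            return "female_specific"
        return "none"

    out = pd.DataFrame({
        "gene_id": agg.index,
        "reproductive_class": [_cls(r) for r in agg.itertuples()],
        "is_reproductive": agg["repro"].to_numpy(),
    }).reset_index(drop=True)
    return out


def build_disease_profiles(records: pd.DataFrame, labelled_links: pd.DataFrame,
                           ) -> pd.DataFrame:
    """Join age records with system-labelled links into disease profiles.

    One profile per gene having at least one mapped system *and* an age
    record; genes with links but no age record are excluded (logged).

    Returns
    -------
    DataFrame with columns ``gene_id, systems (frozenset), m,
    reproductive_class, is_reproductive, branch, chromosome, start, end``;
    ``m`` is the gene's number of distinct systems over all 22 (global, not
    stage-restricted).
    """
    sys_sets = (labelled_links.groupby("gene_id", sort=True)["system"]
                .agg(lambda s: frozenset(s)))
    repro = classify_reproductive(labelled_links).set_index("gene_id")
    prof = pd.DataFrame({"systems": sys_sets})
    prof["m"] = prof["systems"].map(len)
    prof = prof.join(repro)
    prof.index.name = "gene_id"
    prof = prof.reset_index()

    rec = records.set_index("gene_id")[["branch", "chromosome", "start", "end"]]
    n_orphan = (~prof["gene_id"].isin(rec.index)).sum()
    if n_orphan:
        logger.info("%d annotated genes lack an age record; excluded", n_orphan)
    prof = prof.merge(rec, left_on="gene_id", right_index=True, how="inner")
    bad = prof[(prof["m"] < 1) | (prof["m"] > len(SYSTEM_LABELS))]
    if len(bad):
        raise IngestError("profile with m outside [1, 22]")
    return prof.reset_index(drop=True)


def read_kaks_table(path) -> tuple[pd.DataFrame, FilterReport]:
    """Read the pairwise ortholog Ka/Ks table (``gene_id, partner, ka_ks``).

    Negative Ka/Ks values are rejected (tallied, with a logged message).
    The returned frame carries a boolean ``purifying`` column (Ka/Ks < 1)
    so callers can take the purifying-selection-only view.
    """
    df = _read_tsv(path)
    required = {"gene_id", "partner", "ka_ks"}
    if not required.issubset(df.columns):
        raise IngestError(f"Ka/Ks table needs columns {sorted(required)}")
    report = FilterReport(input_count=len(df))
    vals = pd.to_numeric(df["ka_ks"], errors="coerce")
    bad = vals.isna() | (vals < 0)
    if bad.any():
        logger.warning("rejected %d Ka/Ks records (negative or unparseable)",
                       int(bad.sum()))
    report.add_removed("invalid-kaks", int(bad.sum()))
    out = df[~bad].copy()
    out["ka_ks"] = vals[~bad].astype(float)
    out["purifying"] = out["ka_ks"] < 1.0
    report.retained = len(out)
    report.validate()
    return out.reset_index(drop=True), report
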