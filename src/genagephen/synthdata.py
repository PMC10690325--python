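"""Synthetic gene-age / phenotype / chromosome / Ka-Ks data generator with
known ground truth.

The generator emulates the statistical structure the analysis assumes,
with every law parameterised and seeded:

* **Disease emergence** — each gene of branch i is a disease gene with
  probability r* x T_i x 1e-2 (r* in % per My, T_i the branch span in My),
  the constant-rate model the per-branch estimator is meant to recover.
* **Pleiotropy** — a disease gene's system count m follows a discretised
  law (randomised rounding of the branch target plus two-sided geometric
  noise, truncated to [1, 22]) whose branch median tracks the logistic
  growth curve with planted rate k*.
* **System assignment** — m distinct organ systems drawn with
  rank-decaying weights; the genitourinary system (OP7) is up-weighted for
  post-Euteleostomi branches, emulating the young-gene reproductive
  enrichment.
* **Sex-specific reproductive labels** — genes with OP7 among their
  systems receive male-specific / female-specific / both / none classes;
  the male-specific probability is multiplied by a planted relative risk
  on X (separately for ancient and young genes) and on Y.
* **Ka/Ks** — Beta values scaled to [0, 1.5] with location shifts: lower
  for disease genes and for higher system counts, higher for younger
  branches, plus small per-partner offsets.

A fixed seed makes every run byte-identical.  Generated files pass all
ingest validations with zero filter surprises unless ``filter_stress`` is
on, which injects mitochondrial / unplaced / RNA genes and neoplasm terms
so the filters have material.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .age_framework import AgeFramework
from .config import CHROMOSOME_SIZES, SYSTEM_LABELS, SYSTEM_NAMES
from .pleiotropy import logistic_predict
from .xstrata import XRegionMap

OP7_INDEX = SYSTEM_LABELS.index("OP7")
TERMS_PER_SYSTEM = 3

#: Default per-branch dated-gene counts (sum 19,665, concentrated on the
#: oldest branch as in real phylostratigraphic tables).
DEFAULT_GENES_PER_BRANCH = {
    "br0": 12_000, "br1": 2_200, "br2": 1_300, "br3": 2_400,
    "br4": 800, "br5": 600, "br6": 365,
}


class SimulationError(ValueError):
    """Infeasible simulation configuration."""


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions."""

    seed: int = 0
    genes_per_branch: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GENES_PER_BRANCH))
    # disease emergence (constant-rate model)
    r_star_pct_per_my: float = 0.07
    # pleiotropy law
    k_star: float = 1.66
    p_max: float = 10.0
    p_0: float = 4.0
    m_noise_p: float = 0.45
    # system assignment
    system_weight_decay: float = 0.7
    op7_young_boost: float = 6.0
    # sex-specific reproductive labels (among OP7 disease genes)
    p_male: float = 0.30
    p_female: float = 0.12
    p_both: float = 0.05
    rho_x_male_ancient: float = 1.6
    rho_x_male_young: float = 3.0
    rho_y_male: float = 3.0
    max_sex_prob: float = 0.90
    ancient_epoch: str = "Euteleostomi"
    # Ka/Ks law
    kaks_coverage: float = 0.65
    kaks_partners: tuple[str, ...] = ("chimpanzee", "bonobo", "macaque")
    kaks_base_mean: float = 0.32
    kaks_disease_shift: float = -0.07
    kaks_m_shift: float = -0.012
    kaks_youth_shift: float = 0.06
    kaks_partner_shift: dict[str, float] = field(
        default_factory=lambda: {"chimpanzee": 0.0, "bonobo": 0.02,
                                 "macaque": -0.08})
    kaks_concentration: float = 8.0
    kaks_scale: float = 1.5
    # filter-stress extras
    filter_stress: bool = False
    n_mt: int = 13
    n_unplaced: int = 80
    n_rna: int = 250
    neoplasm_link_fraction: float = 0.05

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["kaks_partners"] = list(d["kaks_partners"])
        return d


@dataclass
class SimulatedBundle:
    """In-memory simulation output (files are a serialisation of this)."""

    genes: pd.DataFrame        # gene-age table plus hidden truth columns
    links: pd.DataFrame        # gene-phenotype annotation links
    mapping: pd.DataFrame      # term -> system mapping
    kaks: pd.DataFrame
    neoplasm_terms: set[str]
    truth: dict


# ---------------------------------------------------------------------------
# term vocabulary

def _term_id(sys_idx: int, variant: int) -> str:
    return f"HP:0{sys_idx + 1:02d}{variant:04d}"


def _sex_term(kind: str, variant: int) -> tuple[str, str]:
    """(id, name) for OP7 terms carrying the classification keywords."""
    if kind == "male":
        return f"HP:09M{variant:04d}", f"Male infertility, type {variant + 1}"
    if kind == "female":
        return (f"HP:09F{variant:04d}",
                f"Abnormal female internal genitalia, type {variant + 1}")
    return (f"HP:09R{variant:04d}",
            f"Abnormal reproductive system physiology, type {variant + 1}")


NEOPLASM_TERMS = {f"HP:0002{664 + j}": f"Neoplasm of {SYSTEM_NAMES['OP%d' % (j + 1)]}"
                  for j in range(6)}


def term_system_mapping() -> pd.DataFrame:
    """The full term -> system mapping table used by generated bundles."""
    rows = []
    for i, label in enumerate(SYSTEM_LABELS):
        for v in range(TERMS_PER_SYSTEM):
            rows.append((_term_id(i, v), label))
    for kind in ("male", "female", "repro"):
        for v in range(TERMS_PER_SYSTEM):
            tid, _ = _sex_term(kind, v)
            rows.append((tid, "OP7"))
    return pd.DataFrame(rows, columns=["hpo_id", "system"])


# ---------------------------------------------------------------------------
# laws

def _system_log_weights(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """(ancient, young) log-weight vectors over the 22 systems."""
    ranks = np.arange(1, len(SYSTEM_LABELS) + 1, dtype=float)
    w = 1.0 / ranks ** config.system_weight_decay
    w_anc = w / w.sum()
    w_young = w.copy()
    w_young[OP7_INDEX] *= config.op7_young_boost
    w_young = w_young / w_young.sum()
    return np.log(w_anc), np.log(w_young)


def _draw_m(rng: np.random.Generator, target: np.ndarray,
            noise_p: float) -> np.ndarray:
    """Discretised pleiotropy law: randomised rounding of the branch target
    plus symmetric (two-sided geometric) noise, truncated to [1, 22]."""
    base = np.floor(target).astype(int)
    base += (rng.random(len(target)) < (target - np.floor(target))).astype(int)
    noise = (rng.geometric(noise_p, len(target))
             - rng.geometric(noise_p, len(target)))
    return np.clip(base + noise, 1, len(SYSTEM_LABELS))


def _sex_prob_male(config: SimulationConfig, chrom: np.ndarray,
                   young: np.ndarray) -> np.ndarray:
    rho = np.ones(len(chrom))
    is_x = chrom == "X"
    rho[is_x & young] = config.rho_x_male_young
    rho[is_x & ~young] = config.rho_x_male_ancient
    rho[chrom == "Y"] = config.rho_y_male
    return np.minimum(config.max_sex_prob, config.p_male * rho)


def _disease_prob(config: SimulationConfig, framework: AgeFramework) -> dict[str, float]:
    probs = {}
    for b in framework.labels:
        p = config.r_star_pct_per_my * framework.branch_duration(b) * 1e-2
        if p > 1:
            raise SimulationError(
                f"infeasible config: disease probability {p:.3f} > 1 on {b}")
        probs[b] = p
    return probs


# ---------------------------------------------------------------------------
# generation

def simulate_tables(config: SimulationConfig,
                    framework: AgeFramework | None = None) -> SimulatedBundle:
    """Generate the full input bundle in memory.

    Deterministic given ``config.seed``: the same config yields identical
    tables (and, through :func:`simulate_dataset`, byte-identical files).
    """
    framework = framework or AgeFramework()
    unknown = set(config.genes_per_branch) - set(framework.labels)
    if unknown:
        raise SimulationError(f"genes_per_branch names unknown branches: "
                              f"{sorted(unknown)}")
    rng = np.random.default_rng(config.seed)
    p_disease = _disease_prob(config, framework)
    log_w_anc, log_w_young = _system_log_weights(config)

    chroms = np.array(list(CHROMOSOME_SIZES))
    sizes = np.array([CHROMOSOME_SIZES[c] for c in chroms], dtype=float)
    chrom_p = sizes / sizes.sum()

    # -- gene table -------------------------------------------------------
    branch_col, n_total = [], 0
    for b in framework.labels:
        n_b = int(config.genes_per_branch.get(b, 0))
        branch_col.extend([b] * n_b)
        n_total += n_b
    branch = np.array(branch_col)
    gene_id = np.array([f"G{i:06d}" for i in range(n_total)])
    symbol = np.array([f"SYM{i:06d}" for i in range(n_total)])
    chrom = rng.choice(chroms, size=n_total, p=chrom_p)
    size_of = np.array([CHROMOSOME_SIZES[c] for c in chrom], dtype=np.int64)
    length = rng.integers(1_000, 100_000, size=n_total)
    start = 1 + (rng.random(n_total) * (size_of - length - 1)).astype(np.int64)
    end = start + length
    p_vec = np.array([p_disease[b] for b in branch])
    disease = rng.random(n_total) < p_vec

    epoch = np.array([framework.assign_epoch(b) for b in branch])
    young = epoch != config.ancient_epoch

    genes = pd.DataFrame({
        "gene_id": gene_id, "symbol": symbol, "chromosome": chrom,
        "start": start, "end": end, "biotype": "protein_coding",
        "branch": branch, "is_disease": disease,
    })

    # -- pleiotropy + systems for disease genes ---------------------------
    d_idx = np.flatnonzero(disease)
    t_of = {b: framework.t_since_youngest(b) for b in framework.labels}
    target = np.array([
        logistic_predict(t_of[b], config.k_star, config.p_max, config.p_0)
        for b in branch[d_idx]])
    m = _draw_m(rng, target, config.m_noise_p)

    log_w = np.where(young[d_idx][:, None], log_w_young[None, :],
                     log_w_anc[None, :])
    gumbel = rng.gumbel(size=(len(d_idx), len(SYSTEM_LABELS)))
    order = np.argsort(-(log_w + gumbel), axis=1)
    systems = [frozenset(SYSTEM_LABELS[j] for j in order[i, : m[i]])
               for i in range(len(d_idx))]
    has_op7 = np.array(["OP7" in s for s in systems], dtype=bool)

    # -- sex classes ------------------------------------------------------
    p_m = _sex_prob_male(config, chrom[d_idx], young[d_idx])
    u = rng.random(len(d_idx))
    sex_class = np.full(len(d_idx), "none", dtype=object)
    male = has_op7 & (u < p_m)
    female = has_op7 & ~male & (u < p_m + config.p_female)
    both = has_op7 & ~male & ~female & (u < p_m + config.p_female + config.p_both)
    sex_class[male] = "male_specific"
    sex_class[female] = "female_specific"
    sex_class[both] = "both"

    genes["m_true"] = 0
    genes.loc[d_idx, "m_true"] = m
    genes["sex_class_true"] = "none"
    genes.loc[d_idx, "sex_class_true"] = sex_class
    genes["has_op7_true"] = False
    genes.loc[d_idx, "has_op7_true"] = has_op7

    # -- annotation links -------------------------------------------------
    rows = []
    variants = rng.integers(0, TERMS_PER_SYSTEM, size=(len(d_idx), len(SYSTEM_LABELS)))
    for i, gi in enumerate(d_idx):
        g, s = gene_id[gi], symbol[gi]
        for label in sorted(systems[i]):
            v = int(variants[i, SYSTEM_LABELS.index(label)])
            if label == "OP7":
                cls = sex_class[i]
                if cls == "male_specific":
                    tid, name = _sex_term("male", v)
                    rows.append((g, s, tid, name))
                elif cls == "female_specific":
                    tid, name = _sex_term("female", v)
                    rows.append((g, s, tid, name))
                elif cls == "both":
                    for kind in ("female", "male"):
                        tid, name = _sex_term(kind, v)
                        rows.append((g, s, tid, name))
                else:
                    tid, name = _sex_term("repro", v)
                    rows.append((g, s, tid, name))
            else:
                tid = _term_id(SYSTEM_LABELS.index(label), v)
                name = f"Abnormality of {SYSTEM_NAMES[label]}, type {v + 1}"
                rows.append((g, s, tid, name))
    links = pd.DataFrame(rows, columns=["gene_id", "gene_symbol",
                                        "hpo_id", "hpo_name"])

    # -- Ka/Ks ------------------------------------------------------------
    covered = rng.random(n_total) < config.kaks_coverage
    oldest = framework.branches[0].origin_age
    youth = 1.0 - np.array([framework.origin_age(b) for b in branch]) / oldest
    m_full = genes["m_true"].to_numpy()
    kaks_rows = []
    for partner in config.kaks_partners:
        shift = config.kaks_partner_shift.get(partner, 0.0)
        mean = (config.kaks_base_mean
                + config.kaks_disease_shift * disease
                + config.kaks_m_shift * np.maximum(0, m_full - 1) * disease
                + config.kaks_youth_shift * youth + shift)
        f = np.clip(mean / config.kaks_scale, 0.02, 0.98)
        a = f * config.kaks_concentration
        b_par = (1 - f) * config.kaks_concentration
        vals = rng.beta(a, b_par) * config.kaks_scale
        sel = covered
        kaks_rows.append(pd.DataFrame({
            "gene_id": gene_id[sel], "partner": partner,
            "ka_ks": np.round(vals[sel], 6)}))
    kaks = pd.concat(kaks_rows, ignore_index=True)

    # -- filter-stress extras --------------------------------------------
    neoplasm_ids = set(NEOPLASM_TERMS)
    if config.filter_stress:
        extra = []
        for j in range(config.n_mt):
            extra.append((f"GMT{j:04d}", f"MTSYM{j:04d}", "MT", 100 + j * 1000,
                          1000 + j * 1000, "protein_coding", framework.labels[0]))
        for j in range(config.n_unplaced):
            extra.append((f"GUN{j:04d}", f"UNSYM{j:04d}", f"GL{j:06d}.1",
                          1 + j, 5_000 + j, "protein_coding", framework.labels[0]))
        for j in range(config.n_rna):
            extra.append((f"GRN{j:04d}", f"RNSYM{j:04d}",
                          str(1 + j % 22), 1 + j * 100, 5_000 + j * 100,
                          "lncRNA", framework.labels[0]))
        extra_df = pd.DataFrame(extra, columns=["gene_id", "symbol",
                                                "chromosome", "start", "end",
                                                "biotype", "branch"])
        extra_df["is_disease"] = False
        extra_df["m_true"] = 0
        extra_df["sex_class_true"] = "none"
        extra_df["has_op7_true"] = False
        genes = pd.concat([genes, extra_df], ignore_index=True)

        neo_items = sorted(NEOPLASM_TERMS.items())
        hit = rng.random(len(d_idx)) < config.neoplasm_link_fraction
        neo_rows = []
        for i in np.flatnonzero(hit):
            tid, name = neo_items[int(rng.integers(0, len(neo_items)))]
            neo_rows.append((gene_id[d_idx[i]], symbol[d_idx[i]], tid, name))
        if neo_rows:
            links = pd.concat(
                [links, pd.DataFrame(neo_rows, columns=links.columns)],
                ignore_index=True)

    truth = ground_truth_report(config, framework)
    truth["realized"] = {
        "n_genes": int(n_total),
        "n_disease": int(disease.sum()),
        "n_links": int(len(links)),
        "n_male_specific": int((sex_class == "male_specific").sum()),
        "n_female_specific": int((sex_class == "female_specific").sum()),
    }
    return SimulatedBundle(genes=genes, links=links,
                           mapping=term_system_mapping(), kaks=kaks,
                           neoplasm_terms=neoplasm_ids, truth=truth)


def _op7_inclusion_prob(config: SimulationConfig, framework: AgeFramework,
                        young: bool, n_draws: int = 40_000) -> float:
    """Large-sample P(OP7 among a disease gene's systems) for one age
    split, under the configured weights and m-law (internal fixed seed)."""
    rng = np.random.default_rng(12345)
    log_w_anc, log_w_young = _system_log_weights(config)
    log_w = log_w_young if young else log_w_anc
    branches = [b for b in framework.labels
                if (framework.assign_epoch(b) != config.ancient_epoch) == young]
    if not branches:
        return 0.0
    # weight branches by expected disease-gene counts
    weights = np.array([
        config.genes_per_branch.get(b, 0)
        * config.r_star_pct_per_my * framework.branch_duration(b) * 1e-2
        for b in branches])
    if weights.sum() == 0:
        return 0.0
    weights = weights / weights.sum()
    targets = np.array([
        logistic_predict(framework.t_since_youngest(b), config.k_star,
                         config.p_max, config.p_0) for b in branches])
    pick = rng.choice(len(branches), size=n_draws, p=weights)
    m = _draw_m(rng, targets[pick], config.m_noise_p)
    gumbel = rng.gumbel(size=(n_draws, len(SYSTEM_LABELS)))
    ranks = np.argsort(np.argsort(-(log_w[None, :] + gumbel), axis=1), axis=1)
    return float((ranks[:, OP7_INDEX] < m).mean())


def ground_truth_report(config: SimulationConfig,
                        framework: AgeFramework | None = None) -> dict:
    """Expected values of the downstream statistics under a config.

    Closed-form where available (emergence rates, sex-class ratios);
    large-sample (internally seeded) for quantities involving the weighted
    system draw.
    """
    framework = framework or AgeFramework()
    p_disease = _disease_prob(config, framework)
    expected_medians = {
        b: logistic_predict(framework.t_since_youngest(b), config.k_star,
                            config.p_max, config.p_0)
        for b in framework.labels}
    p_m_x_anc = min(config.max_sex_prob, config.p_male * config.rho_x_male_ancient)
    p_m_x_yng = min(config.max_sex_prob, config.p_male * config.rho_x_male_young)
    report = {
        "config": config.to_dict(),
        "expected_r_pct_per_my": {b: config.r_star_pct_per_my
                                  for b in framework.labels},
        "disease_prob_by_branch": p_disease,
        "expected_median_m_by_branch": expected_medians,
        "k_star": config.k_star,
        "expected_alpha_d_autosomes": config.p_male / config.p_female,
        "expected_alpha_d_x_ancient": p_m_x_anc / config.p_female,
        "expected_alpha_d_x_young": p_m_x_yng / config.p_female,
        "planted_male_rr_x_ancient": p_m_x_anc / config.p_male,
        "planted_male_rr_x_young": p_m_x_yng / config.p_male,
    }
    p7y = _op7_inclusion_prob(config, framework, young=True)
    p7a = _op7_inclusion_prob(config, framework, young=False)
    report["op7_inclusion_prob"] = {"young": p7y, "ancient": p7a}
    # disease mass by split, for the mixture relative risk on X
    mass = {True: 0.0, False: 0.0}
    for b in framework.labels:
        yng = framework.assign_epoch(b) != config.ancient_epoch
        mass[yng] += config.genes_per_branch.get(b, 0) * p_disease[b]
    tot = mass[True] + mass[False]
    if tot > 0:
        # P(male-repro | X) / P(male-repro | autosome), mixing age splits
        num = (mass[True] * p7y * p_m_x_yng + mass[False] * p7a * p_m_x_anc)
        den = (mass[True] * p7y + mass[False] * p7a) * config.p_male
        report["expected_male_repro_rr_x_vs_autosome"] = (
            num / den if den > 0 else None)
    return report


# ---------------------------------------------------------------------------
# serialisation

def simulate_dataset(config: SimulationConfig, out_dir,
                     framework: AgeFramework | None = None) -> SimulatedBundle:
    """Generate the bundle and write it as the canonical TSV/JSON files.

    Writes ``gene_ages.tsv``, ``genes_to_phenotype.tsv``,
    ``phenotype_to_genes.tsv``, ``system_map.tsv``, ``kaks.tsv``,
    ``x_regions.tsv``, ``neoplasm_terms.txt``, ``age_framework.yaml`` and
    ``truth.json`` under ``out_dir``.  Same seed, same bytes.
    """
    framework = framework or AgeFramework()
    bundle = simulate_tables(config, framework)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    gene_cols = ["gene_id", "symbol", "chromosome", "start", "end",
                 "biotype", "branch"]
    bundle.genes[gene_cols].to_csv(out / "gene_ages.tsv", sep="\t", index=False)
    bundle.links.to_csv(out / "genes_to_phenotype.tsv", sep="\t", index=False)
    bundle.links[["hpo_id", "hpo_name", "gene_id", "gene_symbol"]].to_csv(
        out / "phenotype_to_genes.tsv", sep="\t", index=False)
    bundle.mapping.to_csv(out / "system_map.tsv", sep="\t", index=False)
    bundle.kaks.to_csv(out / "kaks.tsv", sep="\t", index=False)
    XRegionMap.default().to_tsv(out / "x_regions.tsv")
    with open(out / "neoplasm_terms.txt", "w") as fh:
        for tid in sorted(bundle.neoplasm_terms):
            fh.write(tid + "\n")
    framework.to_yaml(out / "age_framework.yaml")
    with open(out / "truth.json", "w") as fh:
        json.dump(bundle.truth, fh, indent=2, sort_keys=True)
    return bundle
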