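"""End-to-end orchestration: ingest through selection, with a single
``report.json`` carrying every headline statistic.

The pipeline is a pure function of (input files, configuration): rerunning
on the same inputs produces an identical report.  Each stage writes its own
TSV/JSON artefacts; a failing stage aborts with the partial outputs
preserved and listed in ``manifest.json``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import chromomap, emergence, ingest, pei, pleiotropy, selection, xstrata
from .age_framework import DEFAULT_MERGE_FLOOR, AgeFramework, merge_sparse_branches

logger = logging.getLogger(__name__)


@dataclass
class PipelineInputs:
    """Resolved input paths for a full run."""

    gene_ages: Path
    annotations: Path
    system_map: Path
    kaks: Path | None = None
    x_regions: Path | None = None
    framework_yaml: Path | None = None
    neoplasm_terms: Path | None = None
    annotation_direction: str = "gene_to_phenotype"
    merge_floor: int = DEFAULT_MERGE_FLOOR
    generation_model: dict = field(default_factory=dict)

    @classmethod
    def from_bundle_dir(cls, bundle_dir) -> "PipelineInputs":
        """Resolve the file layout written by ``simulate_dataset``."""
        d = Path(bundle_dir)

        def opt(name: str) -> Path | None:
            p = d / name
            return p if p.exists() else None

        return cls(
            gene_ages=d / "gene_ages.tsv",
            annotations=d / "genes_to_phenotype.tsv",
            system_map=d / "system_map.tsv",
            kaks=opt("kaks.tsv"),
            x_regions=opt("x_regions.tsv"),
            framework_yaml=opt("age_framework.yaml"),
            neoplasm_terms=opt("neoplasm_terms.txt"),
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(inputs: PipelineInputs, out_dir) -> dict:
    """Run ingest -> age framework -> emergence -> pleiotropy -> PEI ->
    chromosome map -> X strata -> selection, writing per-stage artefacts
    and ``report.json`` under ``out_dir``.

    Returns the report dict.  On stage failure the exception propagates
    after the manifest of completed artefacts is written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "stages": {}}
    manifest: list[str] = []
    checksums = {}
    for name in ("gene_ages", "annotations", "system_map", "kaks",
                 "x_regions", "framework_yaml", "neoplasm_terms"):
        p = getattr(inputs, name)
        if p is not None:
            checksums[name] = _sha256(Path(p))
    report["input_checksums"] = checksums

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                section = fn()
            except Exception:
                with open(out / "manifest.json", "w") as fh:
                    json.dump({"completed": manifest, "failed_stage": name},
                              fh, indent=2)
                raise
            section["elapsed_s"] = round(time.perf_counter() - t0, 3)
            report["stages"][name] = section
            return section
        return deco

    framework = (AgeFramework.from_yaml(inputs.framework_yaml)
                 if inputs.framework_yaml else AgeFramework())

    # --- ingest ----------------------------------------------------------
    state: dict = {}

    @stage("ingest")
    def _ingest():
        records, age_report = ingest.read_gene_age_table(inputs.gene_ages)
        links = ingest.read_hpo_annotations(inputs.annotations,
                                            inputs.annotation_direction)
        neoplasm = (ingest.load_neoplasm_terms(inputs.neoplasm_terms)
                    if inputs.neoplasm_terms else set())
        links, neo_report = ingest.apply_term_filters(links, neoplasm)
        mapping = ingest.read_system_mapping(inputs.system_map)
        labelled, map_report = ingest.map_terms_to_systems(links, mapping)
        merged, merge_map = merge_sparse_branches(records["branch"], framework,
                                                  inputs.merge_floor)
        records = records.assign(branch=merged)
        profiles = ingest.build_disease_profiles(records, labelled)
        records.to_csv(out / "records.tsv", sep="\t", index=False)
        prof_out = profiles.copy()
        prof_out["systems"] = prof_out["systems"].map(
            lambda s: ",".join(sorted(s)))
        prof_out.to_csv(out / "profiles.tsv", sep="\t", index=False)
        manifest.extend(["records.tsv", "profiles.tsv"])
        state["records"], state["profiles"] = records, profiles
        return {
            "gene_age_filter": age_report.to_dict(),
            "neoplasm_filter": neo_report.to_dict(),
            "system_mapping": map_report.to_dict(),
            "branch_merge_map": merge_map,
            "n_profiles": len(profiles),
        }

    # --- age framework ---------------------------------------------------
    @stage("age_framework")
    def _framework():
        fr = framework.to_frame()
        fr.to_csv(out / "branches.tsv", sep="\t", index=False)
        manifest.append("branches.tsv")
        return {"branches": fr.to_dict(orient="records"),
                "epochs": framework.epochs}

    # --- emergence -------------------------------------------------------
    @stage("emergence")
    def _emergence():
        stats = emergence.branch_stats(
            state["records"], set(state["profiles"]["gene_id"]), framework)
        stats.to_csv(out / "branch_stats.tsv", sep="\t")
        manifest.append("branch_stats.tsv")
        gm = emergence.generation_model(**inputs.generation_model)
        return {"branch_stats": stats.reset_index().to_dict(orient="records"),
                "generation_model": gm.to_dict()}

    # --- pleiotropy ------------------------------------------------------
    @stage("pleiotropy")
    def _pleiotropy():
        series = pleiotropy.op_counts_by_branch(state["profiles"], framework)
        series.to_frame().to_csv(out / "pleiotropy_medians.tsv", sep="\t",
                                 index=False)
        manifest.append("pleiotropy_medians.tsv")
        section: dict = {"medians": series.to_frame().to_dict(orient="records"),
                         "orientation": series.orientation}
        try:
            fit = pleiotropy.fit_series(series)
            section["logistic_fit"] = fit.to_dict()
        except ValueError as exc:
            section["logistic_fit"] = {"error": str(exc)}
        ivals = pleiotropy.epoch_intervals(framework)
        if ivals:
            rates = pleiotropy.delta_op_rate(
                series, [(o, y) for _, o, y in ivals])
            rates.insert(0, "epoch", [e for e, _, _ in ivals])
            section["delta_op_rates"] = rates.to_dict(orient="records")
        state["series"] = series
        return section

    # --- PEI -------------------------------------------------------------
    @stage("pei")
    def _pei():
        profiles = state["profiles"].copy()
        profiles["stage"] = profiles["branch"].map(framework.assign_epoch)
        table = pei.pei_table(profiles)
        table.to_csv(out / "pei.tsv", sep="\t")
        manifest.append("pei.tsv")
        disp = pei.pei_dispersion(table)
        return {"row_sums": {str(k): float(v)
                             for k, v in table.sum(axis=1).items()},
                "dispersion": {str(k): float(v) for k, v in disp.items()}}

    # --- chromosome map --------------------------------------------------
    @stage("chromomap")
    def _chromomap():
        counts = chromomap.count_by_chromosome(
            state["records"], state["profiles"], framework)
        counts.to_csv(out / "chromosome_counts.tsv", sep="\t")
        manifest.append("chromosome_counts.tsv")
        section = {"counts": counts.reset_index().to_dict(orient="records")}
        try:
            reg = chromomap.fit_autosomal_ols(counts)
            section["regression_all_disease"] = reg.to_dict()
        except ValueError as exc:
            section["regression_all_disease"] = {"error": str(exc)}
        section["sex_ratios"] = chromomap.sex_ratio_summary(counts)
        section["age_split"] = chromomap.age_split_analysis(
            counts, state["profiles"], framework)
        state["counts"] = counts
        return section

    # --- X strata --------------------------------------------------------
    @stage("xstrata")
    def _xstrata():
        region_map = (xstrata.XRegionMap.from_tsv(inputs.x_regions)
                      if inputs.x_regions else xstrata.XRegionMap.default())
        profiles = state["profiles"]
        male_ids = set(profiles[profiles["reproductive_class"]
                                == "male_specific"]["gene_id"])
        section = {}
        for method in region_map.methods:
            if method == "par":
                continue
            labelled = xstrata.label_x_genes(state["records"], region_map,
                                             method)
            hits = labelled["gene_id"].isin(male_ids)
            fracs = xstrata.region_fractions(labelled, hits)
            frame = xstrata.fractions_frame(fracs)
            frame.to_csv(out / f"xstrata_{method}.tsv", sep="\t", index=False)
            manifest.append(f"xstrata_{method}.tsv")
            section[method] = frame.to_dict(orient="records")
        return section

    # --- selection -------------------------------------------------------
    @stage("selection")
    def _selection():
        if inputs.kaks is None:
            return {"skipped": "no Ka/Ks table supplied"}
        kaks, kaks_report = ingest.read_kaks_table(inputs.kaks)
        disease_ids = set(state["profiles"]["gene_id"])
        section: dict = {"filter": kaks_report.to_dict(),
                         "disease_vs_nondisease":
                             selection.disease_contrasts(kaks, disease_ids)}
        bins = selection.bin_by_system_count(kaks, state["profiles"],
                                             partner="chimpanzee")
        section["system_count_bins"] = bins.to_dict(orient="records")
        try:
            rho, p = selection.kaks_pleiotropy_correlation(bins)
            section["pleiotropy_correlation"] = {"pearson_rho": rho,
                                                 "p_value": p}
        except ValueError as exc:
            section["pleiotropy_correlation"] = {"error": str(exc)}
        return section

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
    manifest.append("report.json")
    with open(out / "manifest.json", "w") as fh:
        json.dump({"completed": manifest, "failed_stage": None}, fh, indent=2)
    return report


def _jsonable(obj):
    if isinstance(obj, (pd.Series,)):
        return obj.to_dict()
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
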