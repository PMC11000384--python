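"""End-to-end pipeline orchestration.

One YAML config drives the full analysis: simulate (or load) a cohort,
build the P/LP catalogue, summarise carrier burden per subpopulation,
compute gene carrier frequencies, run the population screens, the
extreme-trait screen and the rare-variant burden scan. Every stage writes
TSV outputs into the run directory and is recorded in a machine-readable
manifest (versions, seed, thresholds, output checksums, stage timings).
Given the same config and seed, outputs are byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time

import pandas as pd
import yaml

from . import burden as burden_mod
from . import catalog as catalog_mod
from . import gcf as gcf_mod
from . import screens as screens_mod
from . import traits as traits_mod
from . import rvtest as rvtest_mod
from .datamodel import load_cohort, write_report
from .synthetic import SimulationConfig, simulate_cohort, write_cohort

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Pipeline configuration; every analysis threshold has a default."""

    out_dir: str = "mendelburden_run"
    seed: int = 0
    # either simulate, or give the four input paths
    simulate: dict | None = None
    vcf: str | None = None
    annotations: str | None = None
    subjects: str | None = None
    panels: str | None = None
    # stage thresholds
    plp_categories: list[int] = dataclasses.field(default_factory=lambda: [1, 2])
    af_threshold: float = 0.01
    novel_min_hom: int = 3
    novel_cadd_min: float = 20.0
    novel_gerp_min: float = 3.0
    ref_subpop: str = "ADM"
    dominant_subpop_af_max: float = 0.005
    gcf_threshold: float = 1 / 200
    founder_subpop_af_min: float = 0.01
    founder_global_af_max: float = 0.01
    common_af_min: float = 0.02
    common_reclassify_af: float = 0.05
    depletion_min_expected: float = 3.0
    extreme_rule: str = "all"
    scan_p_threshold: float = 1e-8
    scan_traits: list[str] | None = None
    qc: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = sorted(set(raw) - known)
        if bad:
            raise ValueError(f"unknown run-config keys: {bad}")
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def validate(self) -> None:
        if self.simulate is None:
            missing = [k for k in ("vcf", "annotations", "subjects", "panels")
                       if getattr(self, k) is None]
            if missing:
                raise ValueError(
                    f"config must either set 'simulate' or provide input paths; missing {missing}")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in dependency order; returns the manifest dict.

    A stage failure raises after writing a partial manifest to the run
    directory.
    """
    import mendelburden

    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {
        "package_version": mendelburden.__version__,
        "seed": config.seed,
        "thresholds": dataclasses.asdict(config),
        "stages": {},
        "outputs": {},
    }
    outputs: dict[str, str] = {}

    def out_path(name: str) -> str:
        return os.path.join(config.out_dir, name)

    def finish_stage(name: str, t0: float, written: dict[str, str]) -> None:
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 3)}
        outputs.update(written)

    try:
        # --- inputs ---------------------------------------------------
        t0 = time.time()
        if config.simulate is not None:
            sim_cfg = SimulationConfig.from_dict({"seed": config.seed, **config.simulate})
            cohort, truth = simulate_cohort(sim_cfg)
            paths = write_cohort(cohort, config.out_dir, truth)
            finish_stage("simulate", t0, paths)
        else:
            cohort = load_cohort(config.vcf, config.annotations, config.subjects,
                                 config.panels)
            finish_stage("load", t0, {})

        # --- catalogue ------------------------------------------------
        t0 = time.time()
        classified = catalog_mod.classify_cohort(
            cohort, af_threshold=config.af_threshold, min_hom=config.novel_min_hom,
            cadd_min=config.novel_cadd_min, gerp_min=config.novel_gerp_min)
        write_report(classified, out_path("classified_variants.tsv"))
        counts = catalog_mod.gene_plp_counts(classified, cohort.panels)
        write_report(counts, out_path("gene_plp_counts.tsv"))
        if not classified["is_known_plp"].any():
            logger.warning("catalogue stage selected no known P/LP variants")
        finish_stage("catalog", t0, {"classified": out_path("classified_variants.tsv"),
                                     "gene_plp_counts": out_path("gene_plp_counts.tsv")})

        # --- carrier burden -------------------------------------------
        t0 = time.time()
        burdens = burden_mod.subject_burdens(cohort, classified,
                                             categories=config.plp_categories)
        write_report(burdens, out_path("subject_burden.tsv"))
        ref = config.ref_subpop
        if ref not in set(cohort.subjects["subpopulation"]):
            ref = cohort.subjects["subpopulation"].mode()[0]
            logger.warning("reference subpopulation %s absent; using %s",
                           config.ref_subpop, ref)
        summary = burden_mod.subpop_summary(burdens, cohort.subjects, ref_label=ref)
        write_report(summary, out_path("subpop_summary.tsv"))
        dom = burden_mod.dominant_screen(cohort, classified,
                                         subpop_af_max=config.dominant_subpop_af_max)
        write_report(dom, out_path("dominant_screen.tsv"))
        finish_stage("burden-summary", t0, {"subject_burden": out_path("subject_burden.tsv"),
                                            "subpop_summary": out_path("subpop_summary.tsv"),
                                            "dominant_screen": out_path("dominant_screen.tsv")})

        # --- gene carrier frequency -----------------------------------
        t0 = time.time()
        gcf_table = gcf_mod.gene_gcf(cohort, classified,
                                     categories=tuple(config.plp_categories))
        write_report(gcf_table, out_path("gcf_by_subpop.tsv"))
        finish_stage("gcf", t0, {"gcf": out_path("gcf_by_subpop.tsv")})

        # --- population screens ---------------------------------------
        t0 = time.time()
        founder = screens_mod.find_founder_alleles(
            cohort, classified, subpop_af_min=config.founder_subpop_af_min,
            global_af_max=config.founder_global_af_max)
        write_report(founder, out_path("founder.tsv"))
        common = screens_mod.find_common_plp(cohort, classified,
                                             af_min=config.common_af_min,
                                             reclassify_af=config.common_reclassify_af)
        write_report(common, out_path("common_plp.tsv"))
        depleted = screens_mod.depleted_homozygosity(
            cohort, min_expected=config.depletion_min_expected)
        write_report(depleted, out_path("depleted.tsv"))
        ko = screens_mod.knockout_catalog(cohort, classified)
        write_report(ko["per_subject"], out_path("knockouts.tsv"))
        try:
            corr = screens_mod.af_correlation(cohort, classified)
        except ValueError as exc:
            logger.warning("AF correlation skipped: %s", exc)
            corr = {"r2": None, "n_variants": 0}
        with open(out_path("af_correlation.json"), "w") as fh:
            json.dump(corr, fh, indent=1)
        finish_stage("screens", t0, {"founder": out_path("founder.tsv"),
                                     "common_plp": out_path("common_plp.tsv"),
                                     "depleted": out_path("depleted.tsv"),
                                     "knockouts": out_path("knockouts.tsv"),
                                     "af_correlation": out_path("af_correlation.json")})

        # --- extreme traits -------------------------------------------
        t0 = time.time()
        if not cohort.trait_names:
            raise ValueError("extreme-traits stage requires quantitative traits "
                             "in the subject table")
        candidates = classified[classified["is_novel_candidate"]]
        hits = traits_mod.extreme_homozygote_screen(cohort, candidates,
                                                    rule=config.extreme_rule)
        write_report(hits, out_path("extreme_hits.tsv"))
        finish_stage("extreme-traits", t0, {"extreme_hits": out_path("extreme_hits.tsv")})

        # --- burden scan ----------------------------------------------
        t0 = time.time()
        thresholds = rvtest_mod.QcThresholds(**config.qc)
        full, significant = rvtest_mod.genome_wide_scan(
            cohort, thresholds, traits=config.scan_traits,
            p_threshold=config.scan_p_threshold)
        write_report(full, out_path("scan_results.tsv"))
        write_report(significant, out_path("scan_significant.tsv"))
        finish_stage("burden-scan", t0, {"scan_results": out_path("scan_results.tsv"),
                                         "scan_significant": out_path("scan_significant.tsv")})
    finally:
        manifest["outputs"] = {name: {"path": p, "sha256": _sha256(p)}
                               for name, p in outputs.items() if os.path.exists(p)}
        with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1)

    return manifest
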