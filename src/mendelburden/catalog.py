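"""Known and novel pathogenic-variant cataloguing.

Known disease-causing variants are selected by intersecting the two
clinical databases: the variant must be rare in every external global
population (max AF < 1%), affect the coding region (missense, nonsense,
frameshift or splice-site) or carry an explicit non-coding pathogenic
flag, be disease-causing in HGMD (DM or DM?), and have a ClinVar record
that either is currently Pathogenic/Likely-pathogenic or was previously
so. Selected variants are placed into four categories from the current
ClinVar status:

* category 1 - P/LP with review status >= 2 stars,
* category 2 - P/LP with < 2 stars,
* category 3 - Conflicting interpretations / VUS,
* category 4 - Benign/Likely-benign that was previously annotated P/LP.

Summary statistics conventionally restrict to categories 1-2; categories
3-4 are retained and flagged. Novel candidates are rare, highly deleterious
(CADD > 20, GERP > 3), never classified benign, carried by at least three
cohort homozygotes and not already in the known set.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datamodel import (
    CODING_CONSEQUENCES,
    LOF_CONSEQUENCES,
    Cohort,
    max_global_af,
)

logger = logging.getLogger(__name__)

PLP_CLASSES = {"pathogenic", "likely_pathogenic"}

CLASSIFIED_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "consequence", "plp_category",
    "is_known_plp", "is_novel_candidate", "is_lof", "inheritance", "panels",
    "max_global_af", "n_hom_cohort",
]


def classify_plp_category(clinvar_class: str, clinvar_stars: int,
                          clinvar_prior_plp: bool, hgmd_class: str) -> int | None:
    """Four-category classification of a database-intersection variant.

    Returns ``None`` when the ClinVar x HGMD intersection rule fails
    (both databases must implicate the variant).
    """
    if hgmd_class not in {"DM", "DM_q"}:
        return None
    if clinvar_class in PLP_CLASSES:
        return 1 if clinvar_stars >= 2 else 2
    if clinvar_class in {"conflicting", "vus"}:
        return 3
    if clinvar_class in {"benign", "likely_benign"} and clinvar_prior_plp:
        return 4
    return None


def _categories_vector(ann: pd.DataFrame) -> np.ndarray:
    return np.array([
        classify_plp_category(c, s, p, h) or 0
        for c, s, p, h in zip(ann["clinvar_class"], ann["clinvar_stars"],
                              ann["clinvar_prior_plp"], ann["hgmd_class"])
    ])


def classify_cohort(cohort: Cohort, af_threshold: float = 0.01,
                    min_hom: int = 3, cadd_min: float = 20.0,
                    gerp_min: float = 3.0) -> pd.DataFrame:
    """One classified row per cohort variant, with all catalogue flags."""
    ann = cohort.annotations
    gmax = max_global_af(ann)
    categories = _categories_vector(ann)
    rare = gmax < af_threshold
    coding = ann["consequence"].isin(CODING_CONSEQUENCES).to_numpy()
    region_ok = coding | ann["noncoding_pathogenic"].to_numpy()
    known = (categories > 0) & rare & region_ok

    n_hom = (cohort.gm.gt == 2).sum(axis=0)
    in_panel = ann["gene"].isin(cohort.panels.index).to_numpy()
    if not in_panel.any():
        logger.warning("no annotated gene matches the panel table; "
                       "panel fields will be empty")
    not_benign = ~ann["clinvar_class"].isin({"benign", "likely_benign"}).to_numpy()
    novel = (
        in_panel & rare & ~known & not_benign
        & (ann["cadd"].to_numpy() > cadd_min)
        & (ann["gerp"].to_numpy() > gerp_min)
        & (n_hom >= min_hom)
    )

    lof = ann["consequence"].isin(LOF_CONSEQUENCES).to_numpy() & rare

    panels = cohort.panels.reindex(ann["gene"])
    out = pd.DataFrame({
        "chrom": ann["chrom"].to_numpy(),
        "pos": ann["pos"].to_numpy(),
        "ref": ann["ref"].to_numpy(),
        "alt": ann["alt"].to_numpy(),
        "gene": ann["gene"].to_numpy(),
        "consequence": ann["consequence"].to_numpy(),
        "plp_category": np.where(known, categories, 0),
        "is_known_plp": known,
        "is_novel_candidate": novel,
        "is_lof": lof,
        "inheritance": panels["inheritance"].fillna("other").to_numpy(),
        "panels": panels["panels"].fillna("").to_numpy(),
        "max_global_af": gmax,
        "n_hom_cohort": n_hom,
    })
    logger.info("classified %d variants: %d known P/LP, %d novel candidates, %d rare LoF",
                len(out), int(known.sum()), int(novel.sum()), int(lof.sum()))
    return out


def select_known_plp(cohort: Cohort, af_threshold: float = 0.01) -> pd.DataFrame:
    """Rows of the classified table passing the known-P/LP selection."""
    classified = classify_cohort(cohort, af_threshold=af_threshold)
    return classified[classified["is_known_plp"]].reset_index(drop=True)


def select_novel_candidates(cohort: Cohort, min_hom: int = 3, cadd_min: float = 20.0,
                            gerp_min: float = 3.0, af_threshold: float = 0.01) -> pd.DataFrame:
    """Rows of the classified table passing the novel-candidate selection."""
    classified = classify_cohort(cohort, af_threshold=af_threshold, min_hom=min_hom,
                                 cadd_min=cadd_min, gerp_min=gerp_min)
    return classified[classified["is_novel_candidate"]].reset_index(drop=True)


def lof_flag(consequence: str, max_af: float, af_threshold: float = 0.01) -> bool:
    """Rare loss-of-function rule: nonsense/splice-site/frameshift, AF < 1%."""
    return consequence in LOF_CONSEQUENCES and max_af < af_threshold


def gene_plp_counts(classified: pd.DataFrame, panel_genes: pd.DataFrame,
                    categories: set[int] | None = None) -> pd.DataFrame:
    """Per-gene known-P/LP counts, with the length-adjusted rate.

    ``length_adjusted`` is the count per kilobase of coding sequence
    (NaN and a log entry when the gene has no recorded length). Restricting
    ``categories`` (e.g. {1, 2}) narrows the counted set.
    """
    sel = classified[classified["is_known_plp"]]
    if categories is not None:
        sel = sel[sel["plp_category"].isin(categories)]
    counts = sel.groupby("gene").size()
    out = pd.DataFrame({"gene": panel_genes.index})
    out["n_plp"] = counts.reindex(out["gene"]).fillna(0).astype(int).to_numpy()
    length_kb = panel_genes["coding_length_bp"].reindex(out["gene"]).to_numpy() / 1000.0
    with np.errstate(invalid="ignore", divide="ignore"):
        out["length_adjusted"] = np.where(length_kb > 0, out["n_plp"] / length_kb, np.nan)
    n_missing = int(np.isnan(out["length_adjusted"]).sum())
    if n_missing:
        logger.warning("%d genes lack a coding length; adjusted counts set to NaN", n_missing)
    return out


def genes_below_count_share(classified: pd.DataFrame, max_count: int = 5) -> tuple[int, int]:
    """(genes with < max_count known-P/LP variants, genes with any) among hit genes."""
    counts = classified[classified["is_known_plp"]].groupby("gene").size()
    return int((counts < max_count).sum()), int(len(counts))
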