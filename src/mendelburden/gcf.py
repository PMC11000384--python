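"""Variant carrier frequencies and cumulative gene carrier frequency (GCF).

The carrier frequency of a biallelic variant is the fraction of called
subjects carrying at least one alternate allele,

    CF = (AC - Hom) / (0.5 * AN)

where ``AC`` is the allele count, ``Hom`` the number of homozygous
individuals and ``AN`` the number of called alleles — algebraically
``(n_het + n_hom) / n_called``. A gene's GCF within a subpopulation is the
sum of the carrier frequencies of its pathogenic variants there, a proxy
for couple-level recessive-disease risk used in carrier-screening panel
design (ACMG Tier 3 adopts GCF > 1/200).

GCF tiers follow the strict-">" convention: category 1 (> 1/50),
category 2 (> 1/100 to 1/50), category 3 (> 1/150 to 1/100), category 4
(> 1/200 to 1/150); each upper endpoint belongs to the lower tier.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datamodel import Cohort, genotype_vector_counts

logger = logging.getLogger(__name__)

TIER_BOUNDS = [("cat1", 1 / 50), ("cat2", 1 / 100), ("cat3", 1 / 150), ("cat4", 1 / 200)]
RECESSIVE_MODES = {"recessive", "both"}


def variant_carrier_frequency(ac: int, n_hom: int, an: int) -> float:
    """(AC - Hom) / (0.5 * AN): the fraction of called subjects carrying
    at least one alternate allele."""
    if an <= 0:
        raise ValueError("AN must be positive to compute a carrier frequency")
    return (ac - n_hom) / (0.5 * an)


def gcf_tier(gcf: float) -> str:
    """Tier label for a cumulative carrier frequency (strict lower bounds)."""
    if gcf < 0:
        raise ValueError(f"GCF must be non-negative, got {gcf}")
    for name, bound in TIER_BOUNDS:
        if gcf > bound:
            return name
    return "below"


def gene_gcf(cohort: Cohort, classified: pd.DataFrame,
             unrelated_only: bool = True,
             inheritance_modes: set[str] = RECESSIVE_MODES,
             categories: tuple[int, ...] = (1, 2),
             min_subpop_n: int = 50) -> pd.DataFrame:
    """Cumulative gene carrier frequency per (gene, subpopulation).

    Sums :func:`variant_carrier_frequency` over the gene's known-P/LP
    variants (restricted to ``categories`` and recessive-condition genes by
    default) within each subpopulation, excluding subjects flagged related
    when ``unrelated_only``. Subpopulations smaller than ``min_subpop_n``
    are flagged low-confidence, since sums of carrier frequencies are badly
    overestimated at small n. A GCF above 1 is reported uncapped with a
    warning (the sum-of-frequencies definition permits it).
    """
    sel = (classified["is_known_plp"]
           & classified["plp_category"].isin(categories)
           & classified["inheritance"].isin(inheritance_modes))
    cols = np.flatnonzero(sel.to_numpy())
    genes = classified.loc[sel, "gene"].to_numpy()

    subjects = cohort.subjects
    if unrelated_only and "related" in subjects.columns:
        subjects = subjects[subjects["related"] == 0]
    labels = subjects["subpopulation"].to_numpy()
    row_idx = cohort.gm.subject_indices(list(subjects["subject_id"]))

    rows = []
    for label in sorted(set(labels)):
        sub_rows = row_idx[labels == label]
        n_sub = sub_rows.size
        per_variant = np.zeros(cols.size)
        for k, j in enumerate(cols):
            c = genotype_vector_counts(cohort.gm.gt[sub_rows, j])
            if c["AN"] > 0:
                per_variant[k] = variant_carrier_frequency(c["AC"], c["n_hom"], c["AN"])
        for gene in np.unique(genes):
            mask = genes == gene
            gcf = float(per_variant[mask].sum())
            if gcf > 1:
                logger.warning("GCF above 1 for gene %s in %s (%.3f); reported uncapped",
                               gene, label, gcf)
            rows.append({
                "gene": gene,
                "subpopulation": label,
                "gcf": gcf,
                "n_contributing_variants": int(mask.sum()),
                "tier": gcf_tier(gcf),
                "low_confidence": n_sub < min_subpop_n,
                "n_subjects": n_sub,
            })
    out = pd.DataFrame(rows, columns=["gene", "subpopulation", "gcf",
                                      "n_contributing_variants", "tier",
                                      "low_confidence", "n_subjects"])
    return out


def genes_above_threshold(gcf_table: pd.DataFrame, threshold: float = 1 / 200) -> pd.DataFrame:
    """Genes whose GCF exceeds ``threshold`` in at least one subpopulation,
    with the best subpopulation and tier attached."""
    best = gcf_table.sort_values("gcf", ascending=False).groupby("gene").first()
    hits = best[best["gcf"] > threshold].reset_index()
    return hits.sort_values("gcf", ascending=False).reset_index(drop=True)
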