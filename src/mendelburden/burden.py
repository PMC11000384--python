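"""Per-subject P/LP carrier burden and subpopulation summaries.

A subject is a carrier of a P/LP variant when their genotype is het or
hom-alt. The subpopulation summary reports, per genetic group: carrier
counts and percentage, the mean and range of P/LP variants per subject,
the number of subjects homozygous for recessive-condition P/LP genotypes
and the number heterozygous for dominant-condition P/LP genotypes, plus
fold enrichments of those rates relative to a reference group.

Two conventions matter and are applied throughout:

* the denominator of the homozygote/heterozygote percentages is the
  carrier count of the group, not the group size — this is the reading
  that makes the published summary arithmetic internally consistent;
* fold enrichment is the ratio of those carrier-normalised rates to the
  reference group's rate.

Rounding to one decimal happens only at report time.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import Cohort, alt_allele_frequencies, pct

logger = logging.getLogger(__name__)

RECESSIVE_MODES = {"recessive", "both"}
DOMINANT_MODES = {"dominant", "both"}


def subject_burdens(cohort: Cohort, classified: pd.DataFrame,
                    categories: Iterable[int] = (1, 2)) -> pd.DataFrame:
    """Per-subject carrier counts over the known-P/LP variant set.

    ``n_plp_alleles`` counts distinct P/LP variants carried (one per
    variant whether het or hom); ``n_hom_recessive`` counts homozygous
    P/LP genotypes in recessive-condition genes; ``n_het_dominant``
    counts heterozygous P/LP genotypes in dominant-condition genes. A gene
    with inheritance "both" contributes to both tallies.
    """
    cats = set(categories)
    sel = classified["is_known_plp"] & classified["plp_category"].isin(cats)
    cols = np.flatnonzero(sel.to_numpy())
    g = cohort.gm.gt[:, cols]
    inheritance = classified.loc[sel, "inheritance"].to_numpy()
    rec = np.isin(inheritance, list(RECESSIVE_MODES))
    dom = np.isin(inheritance, list(DOMINANT_MODES))

    carried = (g == 1) | (g == 2)
    out = pd.DataFrame({
        "subject_id": cohort.gm.subjects,
        "n_plp_alleles": carried.sum(axis=1),
        "n_hom_recessive": ((g == 2) & rec).sum(axis=1),
        "n_het_dominant": ((g == 1) & dom).sum(axis=1),
        "carries_arc_allele": (carried & rec).any(axis=1),
    })
    return out.set_index("subject_id", drop=False)


def subpop_summary_from_counts(counts: pd.DataFrame, ref_label: str) -> pd.DataFrame:
    """Summary percentages and fold enrichments from raw per-group counts.

    ``counts`` needs columns: label, n_subjects, n_carriers,
    n_hom_recessive_subjects, n_het_dominant_subjects (one row per group).
    Percentages for hom/het use the carrier count as denominator; folds are
    relative to ``ref_label``. Values are full precision; use
    :func:`mendelburden.datamodel.pct` for the 1-decimal presentation.
    """
    df = counts.set_index("label", drop=False)
    if ref_label not in df.index:
        raise KeyError(f"reference subpopulation {ref_label!r} not present")
    ref = df.loc[ref_label]
    with np.errstate(invalid="ignore", divide="ignore"):
        ref_hom_rate = (ref["n_hom_recessive_subjects"] / ref["n_carriers"]
                        if ref["n_carriers"] else 0.0)
        ref_het_rate = (ref["n_het_dominant_subjects"] / ref["n_carriers"]
                        if ref["n_carriers"] else 0.0)

        out = df.copy()
        out["pct_carriers"] = 100.0 * df["n_carriers"] / df["n_subjects"]
        out["pct_hom_recessive"] = 100.0 * df["n_hom_recessive_subjects"] / df["n_carriers"]
        out["pct_het_dominant"] = 100.0 * df["n_het_dominant_subjects"] / df["n_carriers"]
    if ref_hom_rate > 0:
        out["fold_hom_vs_ref"] = (df["n_hom_recessive_subjects"] / df["n_carriers"]) / ref_hom_rate
    else:
        logger.warning("reference group %s has no recessive homozygotes; "
                       "hom fold enrichment undefined", ref_label)
        out["fold_hom_vs_ref"] = np.nan
    if ref_het_rate > 0:
        out["fold_het_vs_ref"] = (df["n_het_dominant_subjects"] / df["n_carriers"]) / ref_het_rate
    else:
        logger.warning("reference group %s has no dominant heterozygotes; "
                       "het fold enrichment undefined", ref_label)
        out["fold_het_vs_ref"] = np.nan
    return out.reset_index(drop=True)


def subpop_summary(burdens: pd.DataFrame, subjects: pd.DataFrame,
                   ref_label: str = "ADM") -> pd.DataFrame:
    """Per-subpopulation carrier summary computed from subject burdens."""
    merged = burdens.join(subjects["subpopulation"])
    rows = []
    for label, grp in merged.groupby("subpopulation"):
        rows.append({
            "label": label,
            "n_subjects": len(grp),
            "n_carriers": int((grp["n_plp_alleles"] > 0).sum()),
            "mean_plp_per_subject": float(grp["n_plp_alleles"].mean()),
            "min_plp_per_subject": int(grp["n_plp_alleles"].min()),
            "max_plp_per_subject": int(grp["n_plp_alleles"].max()),
            "n_hom_recessive_subjects": int((grp["n_hom_recessive"] > 0).sum()),
            "n_het_dominant_subjects": int((grp["n_het_dominant"] > 0).sum()),
        })
    return subpop_summary_from_counts(pd.DataFrame(rows), ref_label)


def cohort_carrier_shares(burdens: pd.DataFrame) -> dict[str, float]:
    """Headline cohort percentages (both carrier and cohort denominators).

    Reports the overall carrier percentage, the share of carriers with at
    least one recessive-condition allele (over carriers and over the whole
    cohort, since the published phrasing is ambiguous), the percentage of
    subjects homozygous for a recessive P/LP genotype, and the percentage
    heterozygous for a dominant-condition P/LP variant.
    """
    n = len(burdens)
    n_carriers = int((burdens["n_plp_alleles"] > 0).sum())
    n_arc = int(burdens["carries_arc_allele"].sum())
    return {
        "n_subjects": n,
        "n_carriers": n_carriers,
        "pct_carriers": pct(n_carriers, n),
        "n_arc_carriers": n_arc,
        "pct_arc_of_carriers": pct(n_arc, n_carriers) if n_carriers else np.nan,
        "pct_arc_of_cohort": pct(n_arc, n),
        "pct_hom_recessive": pct(int((burdens["n_hom_recessive"] > 0).sum()), n),
        "pct_het_dominant": pct(int((burdens["n_het_dominant"] > 0).sum()), n),
        "mean_plp_per_subject": round(float(burdens["n_plp_alleles"].mean()), 1),
    }


def fold_enrichment(num_count: float, num_denom: float,
                    ref_count: float, ref_denom: float) -> float:
    """Ratio of two rates, e.g. homozygote share vs the reference group's."""
    if ref_count == 0:
        raise ZeroDivisionError("reference rate is zero; fold enrichment undefined")
    return (num_count / num_denom) / (ref_count / ref_denom)


def homozygote_enrichment_test(burdens: pd.DataFrame, subjects: pd.DataFrame,
                               group_a: str, group_b: str | None = None,
                               value: str = "n_hom_recessive") -> dict[str, float]:
    """Two-sided Wilcoxon rank-sum test of per-subject homozygote counts.

    Compares subpopulation ``group_a`` against ``group_b`` (or against all
    other subjects when ``group_b`` is None). Uses the exact null
    distribution when both groups have <= 12 observations and no ties,
    otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    merged = burdens.join(subjects["subpopulation"])
    x = merged.loc[merged["subpopulation"] == group_a, value].to_numpy()
    if group_b is None:
        y = merged.loc[merged["subpopulation"] != group_a, value].to_numpy()
    else:
        y = merged.loc[merged["subpopulation"] == group_b, value].to_numpy()
    return rank_sum_test(x, y)


def rank_sum_test(x: np.ndarray, y: np.ndarray,
                  alternative: str = "two-sided") -> dict[str, float]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    no_ties = len(np.unique(np.concatenate([x, y]))) == x.size + y.size
    method = "exact" if (x.size <= 12 and y.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method,
                             use_continuity=True)
    return {"U": float(res.statistic), "p": float(res.pvalue), "method": method}


def dominant_screen(cohort: Cohort, classified: pd.DataFrame,
                    subpop_af_max: float = 0.005) -> pd.DataFrame:
    """Known-P/LP variants in dominant-condition genes that stay rare
    (< ``subpop_af_max``) in every cohort subpopulation, with het counts."""
    sel = classified["is_known_plp"] & classified["inheritance"].isin(DOMINANT_MODES)
    cols = np.flatnonzero(sel.to_numpy())
    if cols.size == 0:
        return classified.iloc[0:0].assign(n_het=[], max_subpop_af=[])
    subpop_afs = _subpop_af_matrix(cohort, cols)
    max_af = np.nanmax(subpop_afs, axis=0)
    keep = max_af < subpop_af_max
    out = classified.iloc[cols[keep]].copy()
    out["n_het"] = (cohort.gm.gt[:, cols[keep]] == 1).sum(axis=0)
    out["max_subpop_af"] = max_af[keep]
    return out.reset_index(drop=True)


def _subpop_af_matrix(cohort: Cohort, cols: np.ndarray) -> np.ndarray:
    """Within-cohort subpopulation AFs, shape (n_subpops, len(cols))."""
    labels = cohort.subjects["subpopulation"].to_numpy()
    afs = []
    for label in sorted(set(labels)):
        rows = np.flatnonzero(labels == label)
        afs.append(alt_allele_frequencies(cohort.gm.subset_variants(cols), rows))
    return np.vstack(afs)
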