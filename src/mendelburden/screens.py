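"""Population-level variant screens.

Four screens over the classified catalogue:

* **founder alleles** — pathogenic variants common in one cohort
  subpopulation (AF > 1%) while rare in every global database (< 1%),
  the signature of shared descent within an endogamous group;
* **exceedingly common P/LP** — pathogenic variants whose maximum
  within-cohort subpopulation AF reaches 2%, with a reclassification
  flag above 5% (frequencies implausible for a severe pathogenic allele);
* **depleted homozygosity** — globally rare variants with zero observed
  homozygotes where random mating (Hardy-Weinberg, F = 0) predicts at
  least three, suggesting selection against the homozygous state;
* **human knockouts** — per-subject counts of rare loss-of-function
  variants, and LoF variants observed in homozygous form.

Plus the allele-frequency correlation between the cohort and a global
database over variants rare in both.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import Cohort, alt_allele_frequencies

logger = logging.getLogger(__name__)


def _subpop_rows(cohort: Cohort) -> dict[str, np.ndarray]:
    labels = cohort.subjects["subpopulation"].to_numpy()
    return {lab: np.flatnonzero(labels == lab) for lab in sorted(set(labels))}


def find_founder_alleles(cohort: Cohort, classified: pd.DataFrame,
                         subpop_af_min: float = 0.01,
                         global_af_max: float = 0.01) -> pd.DataFrame:
    """One hit per (known-P/LP variant, subpopulation) with within-group
    AF > ``subpop_af_min`` while max global AF < ``global_af_max``.

    ``absent_from_global`` flags hits not seen in any global database.
    """
    sel = np.flatnonzero(classified["is_known_plp"].to_numpy())
    rows = []
    for label, ridx in _subpop_rows(cohort).items():
        afs = alt_allele_frequencies(cohort.gm, ridx)[sel]
        for k, j in enumerate(sel):
            gmax = classified["max_global_af"].iloc[j]
            if afs[k] > subpop_af_min and gmax < global_af_max:
                rec = classified.iloc[j]
                rows.append({
                    "chrom": rec["chrom"], "pos": rec["pos"],
                    "ref": rec["ref"], "alt": rec["alt"], "gene": rec["gene"],
                    "screen": "founder", "subpopulation": label,
                    "cohort_af": float(afs[k]), "max_global_af": float(gmax),
                    "absent_from_global": bool(gmax == 0.0),
                })
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "gene", "screen",
                                       "subpopulation", "cohort_af", "max_global_af",
                                       "absent_from_global"])


def find_common_plp(cohort: Cohort, classified: pd.DataFrame,
                    af_min: float = 0.02,
                    reclassify_af: float = 0.05) -> pd.DataFrame:
    """Known-P/LP variants with maximum within-cohort subpopulation
    AF >= ``af_min``; the ``reclassify_candidate`` flag marks those above
    ``reclassify_af``, frequencies that prompt reconsideration as benign."""
    sel = np.flatnonzero(classified["is_known_plp"].to_numpy())
    if sel.size == 0:
        return pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "gene", "screen",
                                     "max_subpop_af", "best_subpop", "n_hom",
                                     "reclassify_candidate"])
    subpop_af = {lab: alt_allele_frequencies(cohort.gm, ridx)[sel]
                 for lab, ridx in _subpop_rows(cohort).items()}
    af_matrix = np.vstack(list(subpop_af.values()))
    lab_list = list(subpop_af.keys())
    with np.errstate(invalid="ignore"):
        max_af = np.nanmax(af_matrix, axis=0)
        best = np.nanargmax(np.nan_to_num(af_matrix, nan=-1.0), axis=0)
    n_hom = (cohort.gm.gt[:, sel] == 2).sum(axis=0)
    keep = max_af >= af_min
    out = classified.iloc[sel[keep]][["chrom", "pos", "ref", "alt", "gene"]].copy()
    out["screen"] = "common_plp"
    out["max_subpop_af"] = max_af[keep]
    out["best_subpop"] = [lab_list[b] for b in best[keep]]
    out["n_hom"] = n_hom[keep]
    out["reclassify_candidate"] = max_af[keep] > reclassify_af
    return out.reset_index(drop=True)


def af_correlation(cohort: Cohort, classified: pd.DataFrame,
                   global_db: str | None = None, rare_only: bool = True,
                   rare_af: float = 0.01) -> dict:
    """Squared Pearson correlation of cohort AF vs a global-database AF.

    ``global_db`` names an ``af_*`` annotation column; the default pools the
    provided databases by their per-variant maximum. When ``rare_only``,
    restricts to variants rare (< ``rare_af``) in both vectors.
    """
    sel = np.flatnonzero(classified["is_known_plp"].to_numpy())
    cohort_af = alt_allele_frequencies(cohort.gm)[sel]
    if global_db is None:
        global_af = classified["max_global_af"].to_numpy()[sel]
    else:
        if global_db not in cohort.annotations.columns:
            raise KeyError(f"no annotation column {global_db!r}")
        global_af = cohort.annotations[global_db].fillna(0.0).to_numpy()[sel]
    mask = np.isfinite(cohort_af)
    if rare_only:
        mask &= (cohort_af < rare_af) & (global_af < rare_af)
    x, y = cohort_af[mask], global_af[mask]
    if x.size < 3:
        raise ValueError(f"need at least 3 variants for a correlation, have {x.size}")
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("zero variance in an AF vector; correlation undefined")
        return {"r2": None, "n_variants": int(x.size)}
    r, _ = stats.pearsonr(x, y)
    return {"r2": float(r ** 2), "n_variants": int(x.size)}


def depleted_homozygosity(cohort: Cohort, min_expected: float = 3.0,
                          global_af_max: float = 0.01,
                          per_subpop: bool = False) -> pd.DataFrame:
    """Globally rare variants with zero observed homozygotes where random
    mating predicts at least ``min_expected``.

    Expected homozygotes are ``n_called * q**2`` with ``q`` the pooled
    cohort AF from called genotypes — deliberately the F = 0 random-mating
    expectation, so in a consanguineous cohort the screen is conservative.
    ``per_subpop`` recomputes expectation within each subpopulation instead.
    """
    from .datamodel import max_global_af

    gmax = max_global_af(cohort.annotations)
    groups = _subpop_rows(cohort) if per_subpop else {"ALL": np.arange(cohort.gm.n_subjects)}
    rows = []
    for label, ridx in groups.items():
        g = cohort.gm.gt[ridx]
        called = (g != -1).sum(axis=0)
        ac = np.where(g > 0, g, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            q = np.where(called > 0, ac / np.maximum(2 * called, 1), 0.0)
        expected = called * q ** 2
        n_hom = (g == 2).sum(axis=0)
        hit = (gmax < global_af_max) & (expected >= min_expected) & (n_hom == 0)
        for j in np.flatnonzero(hit):
            ann = cohort.annotations.iloc[j]
            rows.append({
                "chrom": ann["chrom"], "pos": ann["pos"],
                "ref": ann["ref"], "alt": ann["alt"], "gene": ann["gene"],
                "screen": "depleted_hom", "subpopulation": label,
                "cohort_af": float(q[j]), "max_global_af": float(gmax[j]),
                "n_hom_observed": 0, "n_hom_expected": float(expected[j]),
            })
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "gene", "screen",
                                       "subpopulation", "cohort_af", "max_global_af",
                                       "n_hom_observed", "n_hom_expected"])


def knockout_catalog(cohort: Cohort, classified: pd.DataFrame) -> dict:
    """Rare-LoF carriage per subject and the homozygous-LoF variant list.

    Returns per-subject counts of rare LoF variants carried (all genes and
    panel genes separately), the list of LoF variants with at least one
    homozygote together with their carrier subject IDs, and per-
    subpopulation mean/variance of homozygous-LoF counts per subject.
    """
    lof_cols = np.flatnonzero(classified["is_lof"].to_numpy())
    in_panel = classified["gene"].isin(cohort.panels.index).to_numpy()[lof_cols]
    g = cohort.gm.gt[:, lof_cols]
    carried = (g == 1) | (g == 2)
    per_subject = pd.DataFrame({
        "subject_id": cohort.gm.subjects,
        "n_lof": carried.sum(axis=1),
        "n_lof_panel": carried[:, in_panel].sum(axis=1),
        "n_hom_lof": (g == 2).sum(axis=1),
    }).set_index("subject_id", drop=False)

    hom_rows = []
    for k, j in enumerate(lof_cols):
        hom_subjects = np.flatnonzero(g[:, k] == 2)
        if hom_subjects.size:
            rec = classified.iloc[j]
            hom_rows.append({
                "chrom": rec["chrom"], "pos": rec["pos"],
                "ref": rec["ref"], "alt": rec["alt"], "gene": rec["gene"],
                "n_hom": int(hom_subjects.size),
                "hom_subjects": ",".join(cohort.gm.subjects[i] for i in hom_subjects),
            })
    hom_lof = pd.DataFrame(hom_rows, columns=["chrom", "pos", "ref", "alt", "gene",
                                              "n_hom", "hom_subjects"])

    merged = per_subject.join(cohort.subjects["subpopulation"])
    by_subpop = merged.groupby("subpopulation")["n_hom_lof"].agg(["mean", "var", "count"])
    return {
        "per_subject": per_subject,
        "mean_lof_per_subject": float(per_subject["n_lof"].mean()),
        "mean_panel_lof_per_subject": float(per_subject["n_lof_panel"].mean()),
        "homozygous_lof": hom_lof,
        "hom_lof_by_subpop": by_subpop,
    }
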