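"""Genome-wide rare-variant burden scan.

Per-call and per-variant QC mirrors stringent short-read practice:

* per call — heterozygote allele balance inside (0.2, 0.8), homozygote
  allele balance above 0.80, genotype quality above 10; failing calls are
  set missing, and calls lacking AD/GQ fail closed;
* per variant — call rate above 90% after call filtering, Hardy-Weinberg
  exact-test P >= 1e-6, alternate-allele frequency below 1% both in the
  cohort and in every global database;
* allele-count — singletons (AC = 1) are removed, and doubletons (AC = 2)
  are retained only when every carrier call has depth >= 10.

Qualifying variants are collapsed per gene into an unweighted per-subject
allele-count burden, which is regressed on each quantitative trait with
ordinary least squares adjusting for age, sex and the first four principal
components (a fixed-effects approximation of a mixed model: the PCs absorb
population structure, and no kinship matrix is assumed). The reported
statistic is the 1-df Wald chi-square for the burden coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .datamodel import Cohort, GenotypeMatrix, max_global_af

logger = logging.getLogger(__name__)

COVARIATE_COLUMNS = ["age", "sex", "pc1", "pc2", "pc3", "pc4"]


@dataclass
class QcThresholds:
    het_ab_low: float = 0.2
    het_ab_high: float = 0.8
    hom_ab_min: float = 0.80
    gq_min: float = 10.0
    call_rate_min: float = 0.90
    hwe_p_min: float = 1e-6
    af_max: float = 0.01
    doubleton_ad_min: int = 10
    # True  -> keep doubletons whose carrier depth passes (drop the rest);
    # False -> the literal opposite reading (drop good-depth doubletons).
    doubleton_keep_high_depth: bool = True

    def __post_init__(self) -> None:
        for bound in (self.het_ab_low, self.het_ab_high, self.hom_ab_min):
            if not 0 <= bound <= 1:
                raise ValueError(f"allele-balance bound outside [0,1]: {bound}")
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not np.isfinite(v):
                raise ValueError(f"threshold {f.name} must be finite")


@dataclass
class BurdenResult:
    gene: str
    trait: str
    n_qualifying_variants: int
    rr: int
    ra: int
    aa: int
    beta: float
    se: float
    chi_sq: float
    p_value: float
    n_used: int
    variants: list[str] = field(default_factory=list)

    @property
    def class_counts(self) -> str:
        return f"{self.rr}|{self.ra}|{self.aa}"


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg test probability.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed
    the observed one. Monomorphic configurations return 1.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("all genotype counts are zero")
    na = n_het + 2 * n_hom_alt  # alt allele count
    if na == 0 or na == 2 * n:
        return 1.0
    hets, probs = _hwe_het_distribution(n, na)
    p_obs = probs[hets == n_het][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-10)].sum()))


def _hwe_het_distribution(n: int, na: int) -> tuple[np.ndarray, np.ndarray]:
    """All possible heterozygote counts given n diploids and na alt alleles,
    with their conditional probabilities (sums to 1)."""
    h = np.arange(na % 2, min(na, 2 * n - na) + 1, 2)
    hom_alt = (na - h) // 2
    hom_ref = n - h - hom_alt
    logp = (h * np.log(2.0)
            + gammaln(n + 1) - gammaln(hom_ref + 1) - gammaln(h + 1) - gammaln(hom_alt + 1)
            + gammaln(na + 1) + gammaln(2 * n - na + 1) - gammaln(2 * n + 1))
    p = np.exp(logp)
    return h, p / p.sum()


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------

def qc_filter(gm: GenotypeMatrix, annotations: pd.DataFrame,
              thresholds: QcThresholds | None = None
              ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the per-call and per-variant QC; returns the qualifying matrix
    (failing calls set missing, failing variants dropped) and a per-variant
    report of every filter decision."""
    thr = thresholds or QcThresholds()
    gt = gm.gt.copy()
    valid = gt >= 0

    ad_total = gm.ad_ref + gm.ad_alt
    has_ad = (gm.ad_ref >= 0) & (gm.ad_alt >= 0) & (ad_total > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ab = np.where(has_ad, gm.ad_alt / np.maximum(ad_total, 1), np.nan)

    fail = np.zeros_like(valid)
    het = valid & (gt == 1)
    hom = valid & (gt == 2)
    fail |= het & (~has_ad | ~((ab > thr.het_ab_low) & (ab < thr.het_ab_high)))
    fail |= hom & (~has_ad | ~(ab > thr.hom_ab_min))
    fail |= valid & ~((gm.gq >= 0) & (gm.gq > thr.gq_min))
    gt[fail] = -1
    n_call_fail = int(fail.sum())
    if n_call_fail:
        logger.info("per-call QC set %d calls missing", n_call_fail)

    n = gm.n_subjects
    called = (gt != -1).sum(axis=0)
    n_het = (gt == 1).sum(axis=0)
    n_hom = (gt == 2).sum(axis=0)
    ac = n_het + 2 * n_hom
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(called > 0, ac / np.maximum(2 * called, 1), 0.0)

    call_rate_ok = called / n > thr.call_rate_min
    hwe_p = np.array([
        hwe_exact_p(int(called[j] - n_het[j] - n_hom[j]), int(n_het[j]), int(n_hom[j]))
        if called[j] > 0 else 1.0
        for j in range(gm.n_variants)
    ])
    hwe_ok = hwe_p >= thr.hwe_p_min
    gmax = max_global_af(annotations)
    af_ok = (af < thr.af_max) & (gmax < thr.af_max)

    not_singleton = ac != 1
    doubleton_ok = np.ones(gm.n_variants, dtype=bool)
    for j in np.flatnonzero(ac == 2):
        carriers = np.flatnonzero(gt[:, j] > 0)
        depths = gm.dp[carriers, j]
        good_depth = bool(np.all(depths >= thr.doubleton_ad_min))
        doubleton_ok[j] = good_depth if thr.doubleton_keep_high_depth else not good_depth

    passing = call_rate_ok & hwe_ok & af_ok & not_singleton & doubleton_ok & (ac > 0)
    report = pd.DataFrame({
        "chrom": [v.chrom for v in gm.variants],
        "pos": [v.pos for v in gm.variants],
        "ref": [v.ref for v in gm.variants],
        "alt": [v.alt for v in gm.variants],
        "ac": ac, "call_rate": called / n, "cohort_af": af,
        "max_global_af": gmax, "hwe_p": hwe_p,
        "pass_call_rate": call_rate_ok, "pass_hwe": hwe_ok, "pass_af": af_ok,
        "pass_not_singleton": not_singleton, "pass_doubleton": doubleton_ok,
        "pass": passing,
    })
    logger.info("variant QC: %d of %d variants qualify", int(passing.sum()), gm.n_variants)
    keep = np.flatnonzero(passing)
    out = gm.subset_variants(keep)
    out.gt = gt[:, keep]
    return out, report


# ---------------------------------------------------------------------------
# collapsing and regression
# ---------------------------------------------------------------------------

def collapse_gene(gmq: GenotypeMatrix, cols: np.ndarray) -> dict:
    """Unweighted allele-count burden over a gene's qualifying variants.

    Missing calls contribute 0. Also returns the genotype-class counts
    RR|RA|AA aggregated over the gene's variants.
    """
    cols = np.asarray(cols, dtype=int)
    if cols.size == 0:
        raise ValueError("gene has no qualifying variants")
    g = gmq.gt[:, cols]
    b = np.where(g > 0, g, 0).sum(axis=1).astype(float)
    return {
        "b": b,
        "rr": int((g == 0).sum()),
        "ra": int((g == 1).sum()),
        "aa": int((g == 2).sum()),
    }


def burden_regression(b: np.ndarray, trait: np.ndarray, covariates: pd.DataFrame,
                      gene: str = "", trait_name: str = "") -> BurdenResult | None:
    """OLS of trait on burden + covariates over complete cases.

    Returns ``None`` (logged) when the burden has no variance among
    complete cases; raises on collinear covariates. ``chi_sq`` is the
    squared Wald statistic for the burden coefficient and ``p_value`` its
    1-df chi-square upper tail.
    """
    import statsmodels.api as sm

    b = np.asarray(b, dtype=float)
    y = np.asarray(trait, dtype=float)
    X = covariates.to_numpy(dtype=float)
    mask = np.isfinite(y) & np.isfinite(b) & np.all(np.isfinite(X), axis=1)
    nb, yb, Xb = b[mask], y[mask], X[mask]
    if mask.sum() < X.shape[1] + 3:
        raise ValueError("too few complete cases for the burden regression")
    if np.var(nb) == 0:
        logger.info("gene %s: zero burden variance; no result", gene)
        return None
    design = np.column_stack([np.ones(mask.sum()), nb, Xb])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = _collinear_columns(Xb, list(covariates.columns))
        raise ValueError(f"collinear covariates in burden regression: {bad}")
    fit = sm.OLS(yb, design).fit()
    beta, se = float(fit.params[1]), float(fit.bse[1])
    chi_sq = (beta / se) ** 2
    return BurdenResult(
        gene=gene, trait=trait_name, n_qualifying_variants=0,
        rr=0, ra=0, aa=0, beta=beta, se=se, chi_sq=chi_sq,
        p_value=float(stats.chi2.sf(chi_sq, df=1)), n_used=int(mask.sum()),
    )


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    bad = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        rank_with = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X]))
        rank_without = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), others]))
        if rank_with == rank_without:
            bad.append(names[j])
    return bad or names


def covariate_frame(subjects: pd.DataFrame) -> pd.DataFrame:
    """Age, sex (male = 1) and PC1-4, as the scan's adjustment set."""
    return pd.DataFrame({
        "age": subjects["age"].to_numpy(dtype=float),
        "sex": (subjects["sex"] == "male").to_numpy(dtype=float),
        "pc1": subjects["pc1"], "pc2": subjects["pc2"],
        "pc3": subjects["pc3"], "pc4": subjects["pc4"],
    }, index=subjects.index)


def genome_wide_scan(cohort: Cohort, thresholds: QcThresholds | None = None,
                     traits: list[str] | None = None,
                     p_threshold: float = 1e-8) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse + regression for every (gene, trait) pair.

    Returns (full sortable results table, rows with p < ``p_threshold``).
    Deterministic given its inputs.
    """
    gmq, report = qc_filter(cohort.gm, cohort.annotations, thresholds)
    ann = cohort.annotations.set_index(
        pd.MultiIndex.from_frame(cohort.annotations[["chrom", "pos", "ref", "alt"]]))
    gene_of = ann["gene"].reindex([tuple(v) for v in gmq.variants]).to_numpy()
    covs = covariate_frame(cohort.subjects)
    traits = traits or cohort.trait_names

    rows = []
    for gene in sorted({g for g in gene_of if g}):
        cols = np.flatnonzero(gene_of == gene)
        coll = collapse_gene(gmq, cols)
        variant_ids = [str(gmq.variants[j]) for j in cols]
        for trait in traits:
            res = burden_regression(coll["b"], cohort.subjects[trait].to_numpy(),
                                    covs, gene=gene, trait_name=trait)
            if res is None:
                continue
            res.n_qualifying_variants = cols.size
            res.rr, res.ra, res.aa = coll["rr"], coll["ra"], coll["aa"]
            res.variants = variant_ids
            rows.append({
                "gene": gene, "trait": trait,
                "n_variants": res.n_qualifying_variants,
                "class_counts": res.class_counts,
                "beta": res.beta, "se": res.se, "chi_sq": res.chi_sq,
                "p_value": res.p_value, "n_used": res.n_used,
                "variant_list": ";".join(variant_ids),
            })
    full = pd.DataFrame(rows, columns=["gene", "trait", "n_variants", "class_counts",
                                       "beta", "se", "chi_sq", "p_value", "n_used",
                                       "variant_list"])
    full = full.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    significant = full[full["p_value"] < p_threshold].reset_index(drop=True)
    logger.info("burden scan: %d gene-trait pairs, %d significant at P < %g",
                len(full), len(significant), p_threshold)
    return full, significant
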