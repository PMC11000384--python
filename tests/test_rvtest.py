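"""QC filters, HWE exact test, gene collapsing and burden regression."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mendelburden.datamodel import GenotypeMatrix, VariantKey, align_annotations
from mendelburden.rvtest import (
    QcThresholds,
    burden_regression,
    collapse_gene,
    covariate_frame,
    genome_wide_scan,
    hwe_exact_p,
    qc_filter,
)

# ---------------------------------------------------------------------------
# HWE exact test against an integer-arithmetic enumeration oracle
# ---------------------------------------------------------------------------

def _hwe_oracle(n_hom_ref, n_het, n_hom_alt):
    """Exact conditional p by full enumeration with rational arithmetic."""
    n = n_hom_ref + n_het + n_hom_alt
    na = n_het + 2 * n_hom_alt
    def prob(h):
        aa = (na - h) // 2
        rr = n - h - aa
        return Fraction(comb(n, h) * comb(n - h, aa) * 2 ** h, 1)
    hs = [h for h in range(na % 2, min(na, 2 * n - na) + 1, 2)]
    weights = {h: prob(h) for h in hs}
    total = sum(weights.values())
    p_obs = Fraction(weights[n_het], total)
    return float(sum(Fraction(w, total) for w in weights.values()
                     if Fraction(w, total) <= p_obs))


@pytest.mark.parametrize("counts", [
    (1, 0, 1), (0, 2, 0), (5, 3, 1), (57, 14, 50), (10, 0, 0), (20, 10, 2),
    (3, 9, 3), (100, 1, 0),
])
def test_hwe_exact_matches_enumeration(counts):
    assert hwe_exact_p(*counts) == pytest.approx(_hwe_oracle(*counts), rel=1e-9)


def test_hwe_minimal_and_monomorphic_cases():
    # (1,0,1): outcome space het in {0,2}; P(0)=1/3 so p = 1/3
    assert hwe_exact_p(1, 0, 1) == pytest.approx(1 / 3)
    assert hwe_exact_p(10, 0, 0) == 1.0
    with pytest.raises(ValueError):
        hwe_exact_p(0, 0, 0)


def test_hwe_distribution_sums_to_one_small():
    from mendelburden.rvtest import _hwe_het_distribution
    for n in (2, 5, 9):
        for na in range(1, 2 * n):
            _, p = _hwe_het_distribution(n, na)
            assert p.sum() == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------

def _qc_cohort(gt, ad_alt=None, dp_val=30, gq_val=60):
    n, m = gt.shape
    dp = np.full((n, m), dp_val, dtype=np.int32)
    if ad_alt is None:
        ad_alt = np.where(gt == 1, dp // 2, np.where(gt == 2, dp, 0))
    ad_ref = dp - ad_alt
    gq = np.full((n, m), gq_val, dtype=np.int32)
    gm = GenotypeMatrix([f"S{i}" for i in range(n)],
                        [VariantKey("1", 100 + j, "A", "T") for j in range(m)],
                        gt.astype(np.int8), ad_ref.astype(np.int32),
                        ad_alt.astype(np.int32), gq, dp)
    ann = pd.DataFrame({
        "chrom": "1", "pos": [100 + j for j in range(m)], "ref": "A", "alt": "T",
        "gene": "G1", "consequence": "missense", "clinvar_class": "absent",
        "clinvar_stars": 0, "clinvar_prior_plp": False, "hgmd_class": "absent",
        "cadd": 0.0, "gerp": 0.0, "noncoding_pathogenic": False, "af_gnomad": 0.0,
    })
    return gm, align_annotations(ann, gm.variants)


def test_het_allele_balance_filter():
    """A het call at AB=0.15 is set missing; a balanced het survives."""
    gt = np.zeros((300, 1), dtype=np.int8)
    gt[:6, 0] = 1
    gm, ann = _qc_cohort(gt)
    gm.ad_alt[0, 0] = int(0.15 * 30)
    gm.ad_ref[0, 0] = 30 - gm.ad_alt[0, 0]
    gmq, report = qc_filter(gm, ann)
    assert report["pass"].iloc[0]
    assert gmq.gt[0, 0] == -1      # the unbalanced call removed
    assert gmq.gt[1, 0] == 1


def test_hom_allele_balance_and_gq_filters():
    gt = np.zeros((2000, 1), dtype=np.int8)
    gt[:2, 0] = 2
    gt[2:5, 0] = 1
    gm, ann = _qc_cohort(gt)
    gm.ad_alt[0, 0] = 20; gm.ad_ref[0, 0] = 10   # hom AB=0.67 < 0.80 -> removed
    gm.gq[2, 0] = 9                              # GQ <= 10 -> removed
    gmq, report = qc_filter(gm, ann)
    assert report["pass"].iloc[0]
    assert gmq.gt[0, 0] == -1
    assert gmq.gt[2, 0] == -1
    assert gmq.gt[1, 0] == 2 and gmq.gt[3, 0] == 1


def test_call_rate_filter():
    """Call rate 0.89 after call filtering removes the variant."""
    gt = np.zeros((200, 2), dtype=np.int8)
    gt[:3, 0] = 1
    gt[:3, 1] = 1
    gt[3:25, 1] = -1   # call rate 0.89
    gm, ann = _qc_cohort(gt)
    _, report = qc_filter(gm, ann)
    assert report["pass"].tolist() == [True, False]
    assert not report["pass_call_rate"].iloc[1]


def test_singleton_and_doubleton_rules():
    gt = np.zeros((400, 3), dtype=np.int8)
    gt[0, 0] = 1              # singleton
    gt[0:2, 1] = 1            # doubleton, good depth
    gt[0:2, 2] = 1            # doubleton, poor depth
    gm, ann = _qc_cohort(gt)
    gm.dp[0, 2] = 8
    gmq, report = qc_filter(gm, ann)
    assert report["pass"].tolist() == [False, True, False]
    # opposite literal reading via the config switch
    thr = QcThresholds(doubleton_keep_high_depth=False)
    _, report2 = qc_filter(gm, ann, thr)
    assert report2["pass"].tolist() == [False, False, True]


def test_af_and_hwe_variant_filters():
    gt = np.zeros((500, 2), dtype=np.int8)
    gt[:100, 0] = 1                      # cohort AF 10% -> too common
    gt[:4, 1] = 2                        # 4 homs, 0 hets: gross HWE violation
    gm, ann = _qc_cohort(gt)
    _, report = qc_filter(gm, ann)
    assert not report["pass_af"].iloc[0]
    assert report["hwe_p"].iloc[1] < 1e-6 and not report["pass_hwe"].iloc[1]


@given(st.floats(min_value=0.9, max_value=0.99), st.floats(min_value=0.001, max_value=0.01))
def test_qc_threshold_monotonicity(demo_cohort, call_rate_min, af_max):
    """Tightening the variant-level thresholds never grows the qualifying
    set, and tightening GQ never increases the number of retained calls."""
    _, cohort, _ = demo_cohort
    base, _ = qc_filter(cohort.gm, cohort.annotations, QcThresholds())
    tight, _ = qc_filter(cohort.gm, cohort.annotations,
                         QcThresholds(call_rate_min=call_rate_min, af_max=af_max))
    assert set(tight.variants) <= set(base.variants)
    loose_calls, _ = qc_filter(cohort.gm, cohort.annotations, QcThresholds(gq_min=10))
    strict_calls, _ = qc_filter(cohort.gm, cohort.annotations, QcThresholds(gq_min=30))
    assert (strict_calls.gt != -1).sum() <= (loose_calls.gt != -1).sum()


# ---------------------------------------------------------------------------
# collapsing and regression
# ---------------------------------------------------------------------------

def test_collapse_counts_and_loop_oracle(rng):
    g = rng.choice([-1, 0, 1, 2], size=(50, 4), p=[0.05, 0.75, 0.15, 0.05])
    gm, _ = _qc_cohort(np.zeros((50, 4), dtype=np.int8))
    gm.gt = g.astype(np.int8)
    out = collapse_gene(gm, np.arange(4))
    for i in range(50):  # loop oracle
        assert out["b"][i] == sum(max(int(g[i, j]), 0) for j in range(4))
    assert out["rr"] == int((g == 0).sum())
    assert out["ra"] == int((g == 1).sum())
    assert out["aa"] == int((g == 2).sum())
    # a subject het at two variants carries burden 2
    gm.gt[0, :2] = 1
    gm.gt[0, 2:] = 0
    assert collapse_gene(gm, np.arange(4))["b"][0] == 2


def test_class_count_string():
    from mendelburden.rvtest import BurdenResult
    r = BurdenResult("G", "t", 1, 16041, 3, 1, 0.0, 1.0, 0.0, 1.0, 16045)
    assert r.class_counts == "16041|3|1"


def _covs(n, rng):
    return pd.DataFrame({
        "age": rng.normal(40, 10, n), "sex": rng.integers(0, 2, n).astype(float),
        "pc1": rng.normal(size=n), "pc2": rng.normal(size=n),
        "pc3": rng.normal(size=n), "pc4": rng.normal(size=n),
    })


def test_regression_recovers_known_effect_and_matches_normal_equations():
    """trait = 0.5*b + covariates + noise: beta within 3 SE of 0.5, and the
    fit equals a closed-form normal-equations solve."""
    rng = np.random.default_rng(13)
    n = 5000
    covs = _covs(n, rng)
    b = rng.binomial(2, 0.02, size=n).astype(float)
    y = 0.5 * b + 0.05 * covs["age"].to_numpy() + rng.normal(size=n)
    res = burden_regression(b, y, covs, gene="G", trait_name="t")
    assert abs(res.beta - 0.5) < 3 * res.se
    # independent oracle: solve X'X beta = X'y
    X = np.column_stack([np.ones(n), b, covs.to_numpy()])
    beta_hat = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta_hat
    sigma2 = resid @ resid / (n - X.shape[1])
    se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
    assert res.beta == pytest.approx(beta_hat[1], rel=1e-10)
    assert res.se == pytest.approx(se, rel=1e-10)
    # p recomputable from chi_sq
    from scipy import stats
    assert res.p_value == pytest.approx(stats.chi2.sf(res.chi_sq, 1), rel=1e-12)


def test_regression_degenerate_inputs():
    rng = np.random.default_rng(1)
    covs = _covs(200, rng)
    y = rng.normal(size=200)
    assert burden_regression(np.zeros(200), y, covs) is None  # constant burden
    covs_bad = covs.copy()
    covs_bad["pc4"] = 2 * covs_bad["pc3"]
    with pytest.raises(ValueError, match="collinear"):
        burden_regression(rng.binomial(1, 0.1, 200).astype(float), y, covs_bad)


def test_scan_flags_strong_spike_and_is_deterministic():
    """A large (2 SD/allele) spiked gene-trait effect crosses P < 1e-8;
    a re-run gives the identical table; null genes yield no hits."""
    from mendelburden.synthetic import (EffectSpike, FounderSpike,
                                        SimulationConfig, SubpopSpec, simulate_cohort)

    cfg = SimulationConfig(
        seed=17,
        subpops=[SubpopSpec("POP", 4000, 0.0)],
        n_genes=10, n_variants=30, af_log10_min=-3.0, af_log10_max=-2.2,
        founder_spikes=[FounderSpike(0, "POP", 0.004)],   # ~32 carriers
        effect_spikes=[EffectSpike(0, "glucose", 2.0, "additive")],
        trait_manifest={"glucose": (5.5, 1.2), "null_t": (0.0, 1.0)},
        n_known_plp=0, n_novel_candidates=0, n_benign_common=0,
    )
    cohort, truth = simulate_cohort(cfg)
    full, sig = genome_wide_scan(cohort, p_threshold=1e-8)
    spiked_gene = cohort.annotations["gene"].iloc[0]
    hit = sig[(sig["gene"] == spiked_gene) & (sig["trait"] == "glucose")]
    assert len(hit) == 1
    # effect is in manifest-SD units; beta reported in raw trait units
    assert hit["beta"].iloc[0] == pytest.approx(2.0 * 1.2, abs=4 * hit["se"].iloc[0])
    # nothing else reaches genome-wide significance
    assert len(sig) == 1
    full2, _ = genome_wide_scan(cohort, p_threshold=1e-8)
    pd.testing.assert_frame_equal(full, full2)


def test_covariate_frame_columns(demo_cohort):
    _, cohort, _ = demo_cohort
    covs = covariate_frame(cohort.subjects)
    assert list(covs.columns) == ["age", "sex", "pc1", "pc2", "pc3", "pc4"]
    assert set(np.unique(covs["sex"])) <= {0.0, 1.0}
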