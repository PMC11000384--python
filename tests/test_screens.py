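"""Founder, common-P/LP, depletion and knockout screens."""

import numpy as np
import pandas as pd
import pytest

from mendelburden.datamodel import alt_allele_frequencies
from mendelburden.screens import (
    af_correlation,
    depleted_homozygosity,
    find_common_plp,
    find_founder_alleles,
    knockout_catalog,
)


@pytest.fixture(scope="module")
def founder_cohort():
    """Cohort with a variant spiked to 1.7% in PAR while globally rare."""
    from mendelburden.catalog import classify_cohort
    from mendelburden.synthetic import (FounderSpike, SimulationConfig,
                                        SubpopSpec, simulate_cohort)

    cfg = SimulationConfig(
        seed=21,
        subpops=[SubpopSpec("PAR", 2000, 0.03), SubpopSpec("ADM", 1000, 0.0)],
        n_genes=20, n_variants=60, af_log10_min=-3.5, af_log10_max=-1.2,
        founder_spikes=[FounderSpike(0, "PAR", 0.017)],
        n_known_plp=25, n_novel_candidates=0, n_benign_common=4,
    )
    cohort, truth = simulate_cohort(cfg)
    return cohort, truth, classify_cohort(cohort)


def test_founder_screen_finds_spiked_allele(founder_cohort):
    cohort, truth, classified = founder_cohort
    hits = find_founder_alleles(cohort, classified)
    assert (hits["cohort_af"] > 0.01).all()
    assert (hits["max_global_af"] < 0.01).all()
    spiked = cohort.gm.variants[0]
    if classified["is_known_plp"].iloc[0]:  # spiked variant may not be designated P/LP
        assert ((hits["pos"] == spiked.pos) & (hits["subpopulation"] == "PAR")).any()


def test_founder_thresholds_exclude_borderline(founder_cohort):
    cohort, _, classified = founder_cohort
    strict = find_founder_alleles(cohort, classified, subpop_af_min=0.5)
    assert len(strict) == 0
    loose = find_founder_alleles(cohort, classified, global_af_max=0.0)
    assert len(loose) == 0  # nothing can be below a zero global-AF bound


def test_common_plp_and_reclassify_flag(founder_cohort):
    cohort, _, classified = founder_cohort
    hits = find_common_plp(cohort, classified, af_min=0.02, reclassify_af=0.05)
    assert (hits["max_subpop_af"] >= 0.02).all()
    assert (hits["reclassify_candidate"] == (hits["max_subpop_af"] > 0.05)).all()


def test_founder_common_consistency(founder_cohort):
    """Any P/LP variant with subpop AF >= 2% and global AF < 1% is in both screens."""
    cohort, _, classified = founder_cohort
    founder = find_founder_alleles(cohort, classified)
    common = find_common_plp(cohort, classified)
    fk = set(map(tuple, founder[["chrom", "pos", "ref", "alt"]].to_numpy()))
    for _, row in common.iterrows():
        gmax = classified.set_index(["chrom", "pos", "ref", "alt"])[
            "max_global_af"].get((row["chrom"], row["pos"], row["ref"], row["alt"]))
        if gmax is not None and gmax < 0.01 and row["max_subpop_af"] >= 0.02:
            assert (row["chrom"], row["pos"], row["ref"], row["alt"]) in fk


def test_af_correlation_limits_and_oracle(founder_cohort):
    cohort, _, classified = founder_cohort
    res = af_correlation(cohort, classified, rare_only=True)
    # independent textbook formula
    sel = np.flatnonzero(classified["is_known_plp"].to_numpy())
    x = alt_allele_frequencies(cohort.gm)[sel]
    y = classified["max_global_af"].to_numpy()[sel]
    m = np.isfinite(x) & (x < 0.01) & (y < 0.01)
    x, y = x[m], y[m]
    r = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
        ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
    assert res["r2"] == pytest.approx(r ** 2, abs=1e-12)
    assert res["n_variants"] == m.sum()


def test_af_correlation_perfect_and_sign_loss(founder_cohort, monkeypatch):
    cohort, _, classified = founder_cohort
    # identical vectors -> r2 = 1; reversed -> also 1 (sign lost in squaring)
    from scipy import stats
    x = np.array([0.001, 0.002, 0.003])
    assert stats.pearsonr(x, x).statistic ** 2 == pytest.approx(1.0)
    assert stats.pearsonr(x, x[::-1]).statistic ** 2 == pytest.approx(1.0)
    with pytest.raises(ValueError):
        af_correlation(cohort, classified.iloc[0:0])


def _depletion_cohort(n=4000, q=0.025, n_hom_override=None):
    """Hand-built single-variant cohort at exact AF q with optional hom zeroing."""
    from mendelburden.catalog import classify_cohort
    from mendelburden.datamodel import Cohort, GenotypeMatrix, VariantKey, align_annotations

    rng = np.random.default_rng(0)
    g = rng.choice([0, 1, 2], size=(n, 1),
                   p=[(1 - q) ** 2, 2 * q * (1 - q), q * q]).astype(np.int8)
    if n_hom_override is not None:
        g[g == 2] = 1
        hom_rows = rng.choice(n, size=n_hom_override, replace=False)
        g[hom_rows] = 2
    fill = np.full((n, 1), 30, dtype=np.int32)
    gm = GenotypeMatrix([f"S{i}" for i in range(n)], [VariantKey("1", 100, "A", "T")],
                        g, fill.copy(), fill.copy(), fill.copy(), 2 * fill)
    ann = pd.DataFrame([dict(chrom="1", pos=100, ref="A", alt="T", gene="G1",
                             consequence="missense", clinvar_class="vus",
                             clinvar_stars=0, clinvar_prior_plp=False,
                             hgmd_class="DM", cadd=25.0, gerp=4.0,
                             noncoding_pathogenic=False, af_gnomad=0.001)])
    subjects = pd.DataFrame({
        "subject_id": gm.subjects, "subpopulation": "PAR", "sex": "male", "age": 40.0,
        "pc1": 0.0, "pc2": 0.0, "pc3": 0.0, "pc4": 0.0, "related": 0,
    }).set_index("subject_id", drop=False)
    panels = pd.DataFrame({"gene": ["G1"], "panels": ["p"], "inheritance": ["recessive"],
                           "coding_length_bp": [1000]}).set_index("gene", drop=False)
    return Cohort(gm, align_annotations(ann, gm.variants), subjects, panels, [])


def test_depletion_expected_homozygote_arithmetic():
    """Expected = n q^2; hit only when expected >= 3 and observed hom = 0."""
    cohort = _depletion_cohort(n=6000, q=0.025, n_hom_override=0)
    hits = depleted_homozygosity(cohort, min_expected=3.0)
    assert len(hits) == 1
    row = hits.iloc[0]
    c = cohort.gm.gt[:, 0]
    q = np.sum(c[c > 0]) / (2 * len(c))
    assert row["n_hom_expected"] == pytest.approx(len(c) * q ** 2)
    assert row["n_hom_expected"] >= 3
    # a single observed homozygote cancels the hit
    cohort1 = _depletion_cohort(n=6000, q=0.025, n_hom_override=1)
    assert len(depleted_homozygosity(cohort1, min_expected=3.0)) == 0
    # below-threshold expectation: no hit
    cohort2 = _depletion_cohort(n=6000, q=0.018, n_hom_override=0)
    assert len(depleted_homozygosity(cohort2, min_expected=3.0)) == 0


def test_depletion_monotone_in_min_expected():
    cohort = _depletion_cohort(n=20000, q=0.03, n_hom_override=0)
    lo = depleted_homozygosity(cohort, min_expected=3.0)
    hi = depleted_homozygosity(cohort, min_expected=50.0)
    assert len(hi) <= len(lo)


def test_knockout_counts_match_loop(demo_cohort, demo_classified):
    _, cohort, _ = demo_cohort
    ko = knockout_catalog(cohort, demo_classified)
    lof_cols = np.flatnonzero(demo_classified["is_lof"].to_numpy())
    per = ko["per_subject"]
    for i in range(0, cohort.gm.n_subjects, 53):  # loop oracle on a sample
        n_lof = sum(cohort.gm.gt[i, j] in (1, 2) for j in lof_cols)
        assert per["n_lof"].iloc[i] == n_lof
    for _, row in ko["homozygous_lof"].iterrows():
        assert row["n_hom"] >= 1 and row["hom_subjects"]
    assert set(ko["hom_lof_by_subpop"].index) == set(cohort.subjects["subpopulation"])
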