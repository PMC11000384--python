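"""Data model, VCF/TSV loading and allele counting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mendelburden.datamodel import (
    GenotypeMatrix,
    VariantKey,
    allele_counts,
    genotype_vector_counts,
    load_annotations,
    load_cohort,
    pct,
    write_report,
)
from mendelburden.synthetic import write_cohort

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n'
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
    "##contig=<ID=1>\n"
)


def _write_inputs(tmp_path, vcf_body, samples, n_traits=1):
    vcf = tmp_path / "c.vcf"
    vcf.write_text(
        VCF_HEADER
        + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples) + "\n" + vcf_body
    )
    subjects = tmp_path / "s.tsv"
    rows = ["subject_id\tsubpopulation\tsex\tage\tpc1\tpc2\tpc3\tpc4\ttrait_a"]
    for i, s in enumerate(samples):
        rows.append(f"{s}\tPAR\tmale\t{30 + i}\t0.1\t0.0\t0.0\t0.0\t{1.0 + i}")
    subjects.write_text("\n".join(rows) + "\n")
    ann = tmp_path / "a.tsv"
    ann.write_text(
        "chrom\tpos\tref\talt\tgene\tconsequence\tclinvar_class\tclinvar_stars\t"
        "clinvar_prior_plp\thgmd_class\tcadd\tgerp\taf_gnomad\n"
        "1\t100\tA\tT\tG1\tmissense\tpathogenic\t2\tFalse\tDM\t25\t4\t0.001\n"
    )
    panels = tmp_path / "p.tsv"
    panels.write_text("gene\tpanels\tinheritance\tcoding_length_bp\nG1\tmetabolic\trecessive\t1500\n")
    return str(vcf), str(ann), str(subjects), str(panels)


def test_load_cohort_roundtrip_shapes(tmp_path):
    """Two samples x three biallelic records load into a 2x3 matrix."""
    body = (
        "1\t100\t.\tA\tT\t.\tPASS\t.\tGT:AD:GQ:DP\t0/1:10,9:60:19\t0/0:20,0:70:20\n"
        "1\t200\t.\tC\tG\t.\tPASS\t.\tGT:AD:GQ:DP\t1/1:0,22:80:22\t0/1:11,12:55:23\n"
        "1\t300\t.\tG\tA\t.\tPASS\t.\tGT:AD:GQ:DP\t./.:.:.:.\t0/0:18,0:66:18\n"
    )
    cohort = load_cohort(*_write_inputs(tmp_path, body, ["SA", "SB"]))
    assert cohort.gm.gt.shape == (2, 3)
    assert cohort.gm.gt[0].tolist() == [1, 2, -1]
    assert cohort.gm.gt[1].tolist() == [0, 1, 0]
    assert cohort.gm.ad_alt[0, 0] == 9 and cohort.gm.dp[1, 1] == 23
    # unannotated variants carry absent database fields
    assert cohort.annotations.loc[1, "clinvar_class"] == "absent"
    assert cohort.annotations.loc[0, "clinvar_class"] == "pathogenic"


def test_multiallelic_decomposition(tmp_path):
    """ALT "T,G" becomes two variants; each gt recoded against one alt."""
    body = (
        "1\t100\t.\tA\tT,G\t.\tPASS\t.\tGT:AD:GQ:DP\t"
        "1/2:2,9,8:60:19\t0/2:10,0,11:70:21\n"
    )
    cohort = load_cohort(*_write_inputs(tmp_path, body, ["SA", "SB"]))
    keys = cohort.gm.variants
    assert keys == [VariantKey("1", 100, "A", "T"), VariantKey("1", 100, "A", "G")]
    # SA is 1/2: one T allele and one G allele
    assert cohort.gm.gt[0].tolist() == [1, 1]
    # SB is 0/2: G het, T absent
    assert cohort.gm.gt[1].tolist() == [0, 1]
    # per-alt allele depths
    assert cohort.gm.ad_alt[0].tolist() == [9, 8]


def test_subject_missing_from_vcf_is_fatal(tmp_path):
    body = "1\t100\t.\tA\tT\t.\tPASS\t.\tGT:AD:GQ:DP\t0/1:10,9:60:19\t0/0:20,0:70:20\n"
    vcf, ann, subjects, panels = _write_inputs(tmp_path, body, ["SA", "SB"])
    extra = open(subjects).read() + "SC\tPAR\tfemale\t40\t0\t0\t0\t0\t2.0\n"
    open(subjects, "w").write(extra)
    with pytest.raises(ValueError, match="SC"):
        load_cohort(vcf, ann, subjects, panels)


def test_duplicate_annotation_rows_are_fatal(tmp_path):
    p = tmp_path / "ann.tsv"
    header = ("chrom\tpos\tref\talt\tgene\tconsequence\tclinvar_class\tclinvar_stars\t"
              "clinvar_prior_plp\thgmd_class\tcadd\tgerp\n")
    row = "1\t100\tA\tT\tG1\tmissense\tpathogenic\t2\tFalse\tDM\t25\t4\n"
    p.write_text(header + row + row)
    with pytest.raises(ValueError, match="duplicate"):
        load_annotations(str(p))


@pytest.mark.parametrize(
    "gts,expected",
    [
        ([0, 1, 2, -1], {"AC": 3, "AN": 6, "n_hom": 1, "n_het": 1, "n_called": 3}),
        ([0, 0, 0, 0], {"AC": 0, "AN": 8, "n_hom": 0, "n_het": 0, "n_called": 4}),
    ],
)
def test_genotype_counting(gts, expected):
    assert genotype_vector_counts(np.asarray(gts, dtype=np.int8)) == expected


def test_allele_counts_match_per_subject_loop(rng):
    """Vectorised counts agree with an independent per-subject tally."""
    n = 200
    g = rng.choice([-1, 0, 1, 2], size=(n, 5), p=[0.02, 0.68, 0.2, 0.1]).astype(np.int8)
    gm = _matrix_from_gt(g)
    for j, v in enumerate(gm.variants):
        ac = an = n_hom = n_het = 0
        for i in range(n):  # brute-force oracle
            if g[i, j] == -1:
                continue
            an += 2
            ac += int(g[i, j])
            n_hom += g[i, j] == 2
            n_het += g[i, j] == 1
        got = allele_counts(gm, v)
        assert (got["AC"], got["AN"], got["n_hom"], got["n_het"]) == (ac, an, n_hom, n_het)


def _matrix_from_gt(g):
    n, m = g.shape
    fill = np.full((n, m), 20, dtype=np.int32)
    return GenotypeMatrix(
        subjects=[f"S{i}" for i in range(n)],
        variants=[VariantKey("1", 100 + j, "A", "T") for j in range(m)],
        gt=g, ad_ref=fill.copy(), ad_alt=fill.copy(), gq=fill.copy(), dp=2 * fill,
    )


@given(st.lists(st.sampled_from([-1, 0, 1, 2]), min_size=2, max_size=60))
def test_count_invariants_and_order_invariance(gts):
    """AC <= AN, n_hom + n_het <= n_called, and shuffling subjects changes nothing."""
    g = np.asarray(gts, dtype=np.int8)
    c = genotype_vector_counts(g)
    assert c["AC"] <= c["AN"]
    assert c["n_hom"] + c["n_het"] <= c["n_called"]
    perm = np.random.default_rng(0).permutation(g.size)
    assert genotype_vector_counts(g[perm]) == c


def test_allele_counts_errors(demo_cohort):
    _, cohort, _ = demo_cohort
    with pytest.raises(ValueError):
        allele_counts(cohort.gm, cohort.gm.variants[0], subject_subset=[])
    with pytest.raises(KeyError):
        allele_counts(cohort.gm, VariantKey("99", 1, "A", "T"))


def test_write_report_roundtrip(tmp_path):
    df = pd.DataFrame({"gene": ["G1"], "value": [0.125]})
    out = tmp_path / "r.tsv"
    write_report(df, str(out))
    back = pd.read_csv(out, sep="\t")
    assert back.equals(df)
    empty = tmp_path / "e.tsv"
    write_report(df.iloc[0:0], str(empty))
    assert open(empty).read().strip() == "gene\tvalue"


def test_load_write_load_idempotent(demo_cohort, tmp_path):
    """Writing a cohort and reloading reproduces genotypes and metadata."""
    _, cohort, _ = demo_cohort
    paths = write_cohort(cohort, str(tmp_path / "a"))
    c1 = load_cohort(paths["vcf"], paths["annotations"], paths["subjects"], paths["panels"])
    paths2 = write_cohort(c1, str(tmp_path / "b"))
    c2 = load_cohort(paths2["vcf"], paths2["annotations"], paths2["subjects"], paths2["panels"])
    assert c1.gm.variants == c2.gm.variants
    assert np.array_equal(c1.gm.gt, c2.gm.gt)
    assert np.array_equal(c1.gm.dp, c2.gm.dp)
    pd.testing.assert_frame_equal(c1.subjects, c2.subjects)


def test_pct_presentation():
    assert pct(794, 1052, 0) == 75
    with pytest.raises(ZeroDivisionError):
        pct(1, 0)
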