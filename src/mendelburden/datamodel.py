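"""Cohort data model and file I/O.

The analysis operates on four linked tables:

* a genotype matrix (subjects x biallelic variants) read from a
  multi-sample VCF with per-call GT/AD/GQ/DP,
* a variant annotation table carrying the database evidence
  (ClinVar class and review stars, HGMD class, consequence, CADD,
  GERP, global allele frequencies),
* a subject table (genetic subpopulation, sex, age, PC1-PC4 and the
  quantitative trait measurements),
* a gene-panel table (panel memberships, OMIM inheritance mode and
  coding length per gene).

Multi-allelic VCF records are decomposed into one biallelic variant per
alternate allele at load time, so ``VariantKey = (chrom, pos, ref, alt)``
identifies every variant uniquely throughout the package.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: genotype codes used everywhere in the package
GT_HOM_REF = 0
GT_HET = 1
GT_HOM_ALT = 2
GT_MISSING = -1

#: controlled vocabularies
CONSEQUENCES = frozenset(
    {"missense", "nonsense", "frameshift", "splice_site", "synonymous", "other_noncoding"}
)
CODING_CONSEQUENCES = frozenset({"missense", "nonsense", "frameshift", "splice_site"})
LOF_CONSEQUENCES = frozenset({"nonsense", "frameshift", "splice_site"})
CLINVAR_CLASSES = frozenset(
    {"pathogenic", "likely_pathogenic", "conflicting", "vus", "benign", "likely_benign", "absent"}
)
HGMD_CLASSES = frozenset({"DM", "DM_q", "other", "absent"})
INHERITANCE_MODES = frozenset({"recessive", "dominant", "both", "other"})

#: mapping from ClinVar review-status strings to the 0-4 star scale.
#: Consumed when an annotation table carries the textual status instead of
#: an integer column.
CLINVAR_REVIEW_STARS: dict[str, int] = {
    "no assertion provided": 0,
    "no assertion criteria provided": 0,
    "no classification provided": 0,
    "criteria provided, single submitter": 1,
    "criteria provided, conflicting interpretations": 1,
    "criteria provided, multiple submitters, no conflicts": 2,
    "reviewed by expert panel": 3,
    "practice guideline": 4,
}

REQUIRED_ANNOTATION_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "consequence",
    "clinvar_class", "clinvar_stars", "clinvar_prior_plp", "hgmd_class",
    "cadd", "gerp",
]
REQUIRED_SUBJECT_COLUMNS = ["subject_id", "subpopulation", "sex", "age", "pc1", "pc2", "pc3", "pc4"]
REQUIRED_PANEL_COLUMNS = ["gene", "panels", "inheritance", "coding_length_bp"]

#: study subpopulation labels (configurable; unknown labels are allowed but flagged)
DEFAULT_SUBPOPULATIONS = ("GAR", "WEP", "ADM", "PAR", "AFR", "SAS")


class VariantKey(NamedTuple):
    """Identity of one biallelic variant (1-based VCF coordinates)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __str__(self) -> str:  # used in reports and error messages
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class GenotypeMatrix:
    """Subjects x variants genotype codes with per-call AD/GQ/DP.

    ``gt`` uses 0/1/2 counts of the alternate allele and -1 for missing
    calls; the depth/quality arrays use -1 where the field was absent.
    """

    subjects: list[str]
    variants: list[VariantKey]
    gt: np.ndarray        # (n_subjects, n_variants) int8
    ad_ref: np.ndarray    # int32, -1 absent
    ad_alt: np.ndarray    # int32, -1 absent
    gq: np.ndarray        # int32, -1 absent
    dp: np.ndarray        # int32, -1 absent

    def __post_init__(self) -> None:
        shape = (len(self.subjects), len(self.variants))
        for name in ("gt", "ad_ref", "ad_alt", "gq", "dp"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        self._subject_idx = {s: i for i, s in enumerate(self.subjects)}
        self._variant_idx = {v: j for j, v in enumerate(self.variants)}
        if len(self._subject_idx) != len(self.subjects):
            raise ValueError("duplicate subject IDs in genotype matrix")
        if len(self._variant_idx) != len(self.variants):
            raise ValueError("duplicate variant keys in genotype matrix")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subject_indices(self, subject_subset: Iterable[str] | None) -> np.ndarray:
        if subject_subset is None:
            return np.arange(self.n_subjects)
        idx = []
        missing = []
        for s in subject_subset:
            i = self._subject_idx.get(s)
            (idx if i is not None else missing).append(i if i is not None else s)
        if missing:
            raise KeyError(f"subjects absent from genotype matrix: {missing[:10]}")
        if not idx:
            raise ValueError("empty subject subset")
        return np.asarray(idx, dtype=int)

    def variant_index(self, variant: VariantKey) -> int:
        try:
            return self._variant_idx[variant]
        except KeyError:
            raise KeyError(f"variant {variant} not in genotype matrix") from None

    def subset_variants(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = np.asarray(keep, dtype=int)
        return GenotypeMatrix(
            subjects=list(self.subjects),
            variants=[self.variants[j] for j in keep],
            gt=self.gt[:, keep].copy(),
            ad_ref=self.ad_ref[:, keep].copy(),
            ad_alt=self.ad_alt[:, keep].copy(),
            gq=self.gq[:, keep].copy(),
            dp=self.dp[:, keep].copy(),
        )

    def subset_subjects(self, subject_ids: Sequence[str]) -> "GenotypeMatrix":
        rows = self.subject_indices(subject_ids)
        return GenotypeMatrix(
            subjects=[self.subjects[i] for i in rows],
            variants=list(self.variants),
            gt=self.gt[rows].copy(),
            ad_ref=self.ad_ref[rows].copy(),
            ad_alt=self.ad_alt[rows].copy(),
            gq=self.gq[rows].copy(),
            dp=self.dp[rows].copy(),
        )


@dataclass
class Cohort:
    """Everything the downstream stages consume."""

    gm: GenotypeMatrix
    annotations: pd.DataFrame   # one row per VariantKey; af_* columns hold global AFs
    subjects: pd.DataFrame      # indexed by subject_id, aligned to gm.subjects order
    panels: pd.DataFrame        # indexed by gene
    trait_names: list[str]

    def af_columns(self) -> list[str]:
        return [c for c in self.annotations.columns if c.startswith("af_")]

    def subpopulations(self) -> list[str]:
        return sorted(self.subjects["subpopulation"].unique())


# ---------------------------------------------------------------------------
# allele counting
# ---------------------------------------------------------------------------

def allele_counts(
    gm: GenotypeMatrix,
    variant: VariantKey,
    subject_subset: Iterable[str] | None = None,
) -> dict[str, int]:
    """Allele and genotype counts for one variant.

    Missing calls are excluded from AN (``AN = 2 * n_called``);
    ``AC = n_het + 2 * n_hom``.
    """
    j = gm.variant_index(variant)
    rows = gm.subject_indices(subject_subset)
    g = gm.gt[rows, j]
    return genotype_vector_counts(g)


def genotype_vector_counts(g: np.ndarray) -> dict[str, int]:
    """Counts for a genotype code vector (0/1/2/-1)."""
    n_hom = int(np.count_nonzero(g == GT_HOM_ALT))
    n_het = int(np.count_nonzero(g == GT_HET))
    n_called = int(np.count_nonzero(g != GT_MISSING))
    return {
        "AC": n_het + 2 * n_hom,
        "AN": 2 * n_called,
        "n_hom": n_hom,
        "n_het": n_het,
        "n_called": n_called,
    }


def alt_allele_frequencies(gm: GenotypeMatrix, rows: np.ndarray | None = None) -> np.ndarray:
    """Vector of alternate-allele frequencies per variant (NaN where AN = 0)."""
    g = gm.gt if rows is None else gm.gt[rows]
    called = g != GT_MISSING
    ac = np.where(g > 0, g, 0).sum(axis=0, dtype=np.int64)
    an = 2 * called.sum(axis=0, dtype=np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(an > 0, ac / np.maximum(an, 1), np.nan)


# ---------------------------------------------------------------------------
# loaders
# ---------------------------------------------------------------------------

def _normalise_sex(value: str) -> str:
    v = str(value).strip().lower()
    if v in {"m", "male", "1"}:
        return "male"
    if v in {"f", "female", "2"}:
        return "female"
    raise ValueError(f"unrecognised sex value: {value!r}")


def load_subjects(path: str) -> tuple[pd.DataFrame, list[str]]:
    """Read the subject table; all columns beyond the fixed ones are traits.

    An optional ``related`` column (0/1) flags subjects to drop from the
    unrelated-only carrier-frequency computations.
    """
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    missing = [c for c in REQUIRED_SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"subject table {path} lacks required columns: {missing}")
    df["sex"] = df["sex"].map(_normalise_sex)
    df["subpopulation"] = df["subpopulation"].astype(str).str.strip().str.upper()
    unknown = sorted(set(df["subpopulation"]) - set(DEFAULT_SUBPOPULATIONS))
    if unknown:
        logger.warning("unknown subpopulation labels retained: %s", unknown)
    if "related" not in df.columns:
        df["related"] = 0
    fixed = REQUIRED_SUBJECT_COLUMNS + ["related"]
    trait_names = [c for c in df.columns if c not in fixed]
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_id entries in subject table")
    return df.set_index("subject_id", drop=False), trait_names


def load_annotations(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in REQUIRED_ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table {path} lacks required columns: {missing}")
    dup = df.duplicated(subset=["chrom", "pos", "ref", "alt"])
    if dup.any():
        bad = df.loc[dup, ["chrom", "pos", "ref", "alt"]].head(5)
        raise ValueError(f"duplicate annotation rows for variant keys:\n{bad}")
    for col in ("clinvar_class", "hgmd_class", "consequence"):
        df[col] = df[col].fillna("absent" if col != "consequence" else "other_noncoding")
    bad_cv = set(df["clinvar_class"]) - CLINVAR_CLASSES
    if bad_cv:
        raise ValueError(f"unknown clinvar_class values: {sorted(bad_cv)}")
    bad_stars = df.loc[~df["clinvar_stars"].isin([0, 1, 2, 3, 4]), "clinvar_stars"]
    if len(bad_stars):
        raise ValueError(f"clinvar_stars outside 0-4: {sorted(set(bad_stars))[:5]}")
    af_cols = [c for c in df.columns if c.startswith("af_")]
    for c in af_cols:
        vals = df[c].astype(float)
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"allele frequencies outside [0,1] in column {c}")
    if "noncoding_pathogenic" not in df.columns:
        df["noncoding_pathogenic"] = False
    df["clinvar_prior_plp"] = df["clinvar_prior_plp"].astype(bool)
    df["noncoding_pathogenic"] = df["noncoding_pathogenic"].astype(bool)
    return df


def load_panels(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"panel table {path} lacks required columns: {missing}")
    if df["gene"].duplicated().any():
        raise ValueError("duplicate gene entries in panel table")
    df["inheritance"] = df["inheritance"].astype(str).str.lower()
    bad = set(df["inheritance"]) - INHERITANCE_MODES
    if bad:
        raise ValueError(f"unknown inheritance modes: {sorted(bad)}")
    if (df["coding_length_bp"] <= 0).any():
        raise ValueError("coding_length_bp must be positive")
    empty = df["panels"].astype(str).str.strip() == ""
    if empty.any():
        raise ValueError("every panel-table gene needs at least one panel")
    return df.set_index("gene", drop=False)


def load_genotypes(vcf_path: str, sample_ids: Sequence[str] | None = None) -> GenotypeMatrix:
    """Read a VCF 4.2 file into a :class:`GenotypeMatrix`.

    Multi-allelic records are decomposed: each alternate allele becomes its
    own biallelic variant, with the per-sample genotype recoded as the count
    of that allele (other alternates count as reference for that row).
    """
    from cyvcf2 import VCF

    vcf = VCF(vcf_path, gts012=False)
    samples = list(vcf.samples)
    if sample_ids is not None:
        missing = [s for s in sample_ids if s not in set(samples)]
        if missing:
            raise ValueError(
                f"subjects in subject table but absent from VCF: {missing[:10]}"
                + ("..." if len(missing) > 10 else "")
            )
        keep_rows = np.asarray([samples.index(s) for s in sample_ids])
        subjects = list(sample_ids)
    else:
        keep_rows = np.arange(len(samples))
        subjects = samples

    variants: list[VariantKey] = []
    gt_cols, adr_cols, ada_cols, gq_cols, dp_cols = [], [], [], [], []
    for rec in vcf:
        gts = np.asarray(rec.genotype.array())[:, :2]  # allele indexes, -1 missing
        try:
            ad = rec.format("AD")
        except KeyError:
            ad = None
        gq = _format_field(rec, "GQ")
        dp = _format_field(rec, "DP")
        for a, alt in enumerate(rec.ALT, start=1):
            key = VariantKey(str(rec.CHROM), int(rec.POS), rec.REF, alt)
            g = (gts == a).sum(axis=1).astype(np.int8)
            g[(gts < 0).any(axis=1)] = GT_MISSING
            variants.append(key)
            gt_cols.append(g[keep_rows])
            if ad is not None and ad.shape[1] > a:
                adr = ad[:, 0].astype(np.int32)
                ada = ad[:, a].astype(np.int32)
                adr[adr < 0] = -1
                ada[ada < 0] = -1
            else:
                adr = np.full(len(samples), -1, dtype=np.int32)
                ada = np.full(len(samples), -1, dtype=np.int32)
            adr_cols.append(adr[keep_rows])
            ada_cols.append(ada[keep_rows])
            gq_cols.append(gq[keep_rows])
            dp_cols.append(dp[keep_rows])

    if not variants:
        raise ValueError(f"no variant records in {vcf_path}")
    return GenotypeMatrix(
        subjects=subjects,
        variants=variants,
        gt=np.column_stack(gt_cols),
        ad_ref=np.column_stack(adr_cols),
        ad_alt=np.column_stack(ada_cols),
        gq=np.column_stack(gq_cols),
        dp=np.column_stack(dp_cols),
    )


def _format_field(rec, name: str) -> np.ndarray:
    try:
        arr = rec.format(name)
    except KeyError:
        arr = None
    if arr is None:
        return np.full(len(rec.genotype.array()), -1, dtype=np.int32)
    arr = np.asarray(arr).reshape(len(arr), -1)[:, 0]
    out = arr.astype(np.int32, copy=True)
    out[~np.isfinite(arr.astype(float))] = -1
    out[out < 0] = -1
    return out


def load_cohort(vcf_path: str, annotation_path: str, subjects_path: str, panels_path: str) -> Cohort:
    """Load and join the four input files into a :class:`Cohort`.

    Only subjects present in the subject table are retained (the VCF sample
    set must be a superset); variants without an annotation row are kept
    with ``absent`` database fields.
    """
    subjects, trait_names = load_subjects(subjects_path)
    annotations = load_annotations(annotation_path)
    panels = load_panels(panels_path)
    gm = load_genotypes(vcf_path, sample_ids=list(subjects["subject_id"]))
    annotations = align_annotations(annotations, gm.variants)
    return Cohort(gm=gm, annotations=annotations, subjects=subjects, panels=panels,
                  trait_names=trait_names)


def align_annotations(annotations: pd.DataFrame, variants: Sequence[VariantKey]) -> pd.DataFrame:
    """Reindex the annotation table to the genotype-matrix variant order.

    Unannotated variants get ``absent`` database classes, NaN scores and no
    global-AF entries.
    """
    keyed = annotations.set_index(
        pd.MultiIndex.from_frame(
            annotations[["chrom", "pos", "ref", "alt"]].assign(
                chrom=annotations["chrom"].astype(str), pos=annotations["pos"].astype(int)
            )
        )
    )
    idx = pd.MultiIndex.from_tuples([tuple(v) for v in variants],
                                    names=["chrom", "pos", "ref", "alt"])
    out = keyed.reindex(idx)
    n_missing = out["gene"].isna().sum()
    if n_missing:
        logger.info("%d variants lack annotation rows; database fields set to 'absent'", n_missing)
    out["gene"] = out["gene"].fillna("")
    out["consequence"] = out["consequence"].fillna("other_noncoding")
    for col in ("clinvar_class", "hgmd_class"):
        out[col] = out[col].fillna("absent")
    out["clinvar_stars"] = out["clinvar_stars"].fillna(0).astype(int)
    for col in ("clinvar_prior_plp", "noncoding_pathogenic"):
        out[col] = out[col].fillna(False).astype(bool)
    out[["chrom", "pos", "ref", "alt"]] = [list(v) for v in variants]
    out["pos"] = out["pos"].astype(int)
    return out.reset_index(drop=True)


def max_global_af(annotations: pd.DataFrame) -> np.ndarray:
    """Maximum allele frequency across the global databases, 0 where absent."""
    af_cols = [c for c in annotations.columns if c.startswith("af_")]
    if not af_cols:
        return np.zeros(len(annotations))
    return annotations[af_cols].fillna(0.0).to_numpy(dtype=float).max(axis=1)


# ---------------------------------------------------------------------------
# report writing
# ---------------------------------------------------------------------------

def write_report(table: pd.DataFrame, path: str, fmt: str = "tsv",
                 float_precision: int = 6) -> None:
    """Write a result table as TSV (default) or JSON with stable columns."""
    if table.shape[1] == 0:
        raise ValueError("refusing to write a table with no columns")
    if table.shape[0] == 0:
        logger.warning("writing header-only report to %s (empty table)", path)
    if fmt == "tsv":
        table.to_csv(path, sep="\t", index=False, float_format=f"%.{float_precision}g")
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump(json.loads(table.to_json(orient="records")), fh, indent=1)
    else:
        raise ValueError(f"unknown report format: {fmt!r}")


def pct(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Report-time percentage with the study's 1-decimal rounding."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round(100.0 * numerator / denominator, decimals)
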