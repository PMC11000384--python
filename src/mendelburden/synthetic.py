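"""Synthetic cohort generator.

The real cohort this package was designed around is access-controlled, so
every downstream stage is exercised on simulated data with the same
statistical structure: several genetic subpopulations of unequal size and
distinct consanguinity levels, panel variants carrying ClinVar/HGMD-style
annotations and subpopulation-divergent allele frequencies (founder
alleles), and quantitative traits with age/sex/PC covariate effects plus
optionally spiked large-effect variants.

Genotypes follow the standard single-parameter inbreeding model: for a
subpopulation with alternate-allele frequency ``q`` and inbreeding
coefficient ``F``,

    P(hom-alt) = q^2 + F q (1 - q)
    P(het)     = 2 q (1 - q) (1 - F)
    P(hom-ref) = (1 - q)^2 + F q (1 - q)

with draws independent across subjects and variants (no linkage
disequilibrium, no explicit pedigrees). All randomness flows from one
seeded :class:`numpy.random.Generator`; a fixed seed gives bit-identical
output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    GT_MISSING,
    Cohort,
    GenotypeMatrix,
    VariantKey,
    align_annotations,
)

logger = logging.getLogger(__name__)

PANEL_NAMES = [
    "severe_recessive_lethal", "ciliary_disorders", "hearing_loss",
    "congenital_anomalies", "metabolic_disorders", "neurodevelopmental",
    "cardiovascular", "ophthalmic", "dermatologic", "renal",
    "hematologic", "immunodeficiency", "skeletal_dysplasia", "mitochondrial",
    "endocrine", "neuromuscular", "acmg_sf", "newborn_screening",
    "embryonic_lethal", "other",
]


@dataclass
class SubpopSpec:
    label: str
    n_subjects: int
    inbreeding_f: float

    def __post_init__(self) -> None:
        if self.inbreeding_f < 0:
            raise ValueError(f"inbreeding F must be >= 0, got {self.inbreeding_f}")
        if not 0 <= self.inbreeding_f < 1:
            raise ValueError(f"inbreeding F must lie in [0, 1), got {self.inbreeding_f}")


@dataclass
class FounderSpike:
    variant_index: int
    subpop: str
    target_af: float


@dataclass
class EffectSpike:
    """A large-effect variant->trait effect, in units of the trait's manifest SD."""

    variant_index: int
    trait: str
    effect_sd: float
    model: str = "recessive"  # or "additive"

    def __post_init__(self) -> None:
        if self.model not in {"recessive", "additive"}:
            raise ValueError(f"unknown effect model {self.model!r}")
        if not np.isfinite(self.effect_sd):
            raise ValueError("effect size must be finite")


def _default_subpops() -> list[SubpopSpec]:
    # Subpopulation sizes follow the study cohort; the per-group inbreeding
    # coefficients are illustrative (the source reports only 29.1% parental
    # consanguinity overall, with the Peninsular group the most inbred).
    return [
        SubpopSpec("GAR", 2311, 0.015),
        SubpopSpec("WEP", 1372, 0.010),
        SubpopSpec("ADM", 1180, 0.005),
        SubpopSpec("PAR", 1052, 0.030),
        SubpopSpec("AFR", 92, 0.015),
        SubpopSpec("SAS", 38, 0.015),
    ]


def _default_traits() -> dict[str, tuple[float, float]]:
    names = ["creatine_kinase", "uric_acid", "glucose", "hba1c", "bmi",
             "alt_gpt", "total_cholesterol", "ldl_cholesterol", "triglycerides",
             "ferritin", "shbg", "homocysteine", "vitamin_d", "myoglobin"]
    names += [f"trait_{i:02d}" for i in range(len(names) + 1, 59)]
    return {name: (0.0, 1.0) for name in names}


@dataclass
class SimulationConfig:
    """Everything the generator needs; defaults emulate the study conditions."""

    seed: int = 0
    subpops: list[SubpopSpec] = field(default_factory=_default_subpops)
    n_genes: int = 200
    n_variants: int = 600
    # per-variant base AF: log10-uniform on [af_log10_min, af_log10_max]
    af_log10_min: float = -4.0
    af_log10_max: float = -1.3
    # per-(variant, subpop) divergence: lognormal multiplier on the base AF
    divergence_sigma: float = 0.5
    founder_spikes: list[FounderSpike] = field(default_factory=list)
    trait_manifest: dict[str, tuple[float, float]] = field(default_factory=_default_traits)
    effect_spikes: list[EffectSpike] = field(default_factory=list)
    # covariate effects on every trait, in manifest-SD units
    beta_age: float = 0.2      # per age-SD (12 years)
    beta_sex: float = 0.3      # male minus female shift
    beta_pc: float = 0.1       # per PC-SD, each of PC1-4
    trait_missing_rate: float = 0.02
    # per-call QC noise
    mean_dp: int = 35
    call_missing_rate: float = 0.005
    gq_mean: float = 65.0
    gq_sd: float = 20.0
    het_ab: float = 0.5
    hom_alt_ab: float = 0.98
    # annotation designations
    n_known_plp: int = 60
    n_novel_candidates: int = 12
    n_benign_common: int = 10

    def __post_init__(self) -> None:
        if sum(s.n_subjects for s in self.subpops) <= 0:
            raise ValueError("total number of subjects must be positive")
        for sp in self.founder_spikes:
            if not 0 < sp.target_af < 1:
                raise ValueError(f"founder spike target AF must lie in (0,1), got {sp.target_af}")

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        raw = dict(raw)
        if "subpops" in raw:
            raw["subpops"] = [SubpopSpec(**s) for s in raw["subpops"]]
        if "founder_spikes" in raw:
            raw["founder_spikes"] = [FounderSpike(**s) for s in raw["founder_spikes"]]
        if "effect_spikes" in raw:
            raw["effect_spikes"] = [EffectSpike(**s) for s in raw["effect_spikes"]]
        if "trait_manifest" in raw:
            raw["trait_manifest"] = {k: tuple(v) for k, v in raw["trait_manifest"].items()}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown simulation config keys: {sorted(bad)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["trait_manifest"] = {k: list(v) for k, v in d["trait_manifest"].items()}
        return d


@dataclass
class SimulationTruth:
    """Ground truth recorded at generation time, for recovery tests."""

    f_by_subpop: dict[str, float]
    true_afs: pd.DataFrame            # subpop x variant-index allele frequencies
    founder_spikes: list[FounderSpike]
    effect_spikes: list[dict]         # includes beta in raw trait units
    known_plp_indices: list[int] = field(default_factory=list)
    novel_candidate_indices: list[int] = field(default_factory=list)
    benign_common_indices: list[int] = field(default_factory=list)

    def to_json(self, path: str) -> None:
        payload = {
            "f_by_subpop": self.f_by_subpop,
            "true_afs": self.true_afs.to_dict(orient="index"),
            "founder_spikes": [dataclasses.asdict(s) for s in self.founder_spikes],
            "effect_spikes": self.effect_spikes,
            "known_plp_indices": self.known_plp_indices,
            "novel_candidate_indices": self.novel_candidate_indices,
            "benign_common_indices": self.benign_common_indices,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=float)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def inbred_genotype_probs(q: np.ndarray, f: float) -> tuple[np.ndarray, np.ndarray]:
    """(P(hom-alt), P(het)) under the inbreeding model."""
    p_hom = q * q + f * q * (1 - q)
    p_het = 2 * q * (1 - q) * (1 - f)
    return p_hom, p_het


def _draw_genotypes(q: np.ndarray, f: float, n: int, rng: np.random.Generator) -> np.ndarray:
    p_hom, p_het = inbred_genotype_probs(q, f)
    u = rng.random((n, q.size))
    return (2 * (u < p_hom) + ((u >= p_hom) & (u < p_hom + p_het))).astype(np.int8)


def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, SimulationTruth]:
    """Draw the genotype matrix (with per-call AD/GQ/DP noise) and its truth."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    m = config.n_variants
    base_q = 10 ** rng.uniform(config.af_log10_min, config.af_log10_max, size=m)

    variants = _variant_keys(m, rng)
    labels = [s.label for s in config.subpops]
    true_afs = np.empty((len(labels), m))
    gt_blocks = []
    subjects: list[str] = []
    offset = 0
    for i, sp in enumerate(config.subpops):
        mult = rng.lognormal(mean=0.0, sigma=config.divergence_sigma, size=m)
        q = base_q * mult
        n_clip = np.count_nonzero((q <= 0) | (q >= 1))
        if n_clip:
            logger.warning("clipping %d subpopulation AFs into (0,1)", n_clip)
        q = np.clip(q, 1e-6, 0.5)
        true_afs[i] = q
        gt_blocks.append(_draw_genotypes(q, sp.inbreeding_f, sp.n_subjects, rng))
        subjects.extend(f"S{offset + k:06d}" for k in range(sp.n_subjects))
        offset += sp.n_subjects
    gt = np.vstack(gt_blocks)

    truth = SimulationTruth(
        f_by_subpop={s.label: s.inbreeding_f for s in config.subpops},
        true_afs=pd.DataFrame(true_afs, index=labels),
        founder_spikes=[],
        effect_spikes=[],
    )
    gm = GenotypeMatrix(
        subjects=subjects, variants=variants, gt=gt,
        **_call_noise(gt, config, rng),
    )
    for spike in config.founder_spikes:
        spike_founder_allele(gm, truth, spike.variant_index, spike.subpop,
                             spike.target_af, config, rng,
                             _subpop_rows(config, spike.subpop))
    return gm, truth


def _variant_keys(m: int, rng: np.random.Generator) -> list[VariantKey]:
    bases = np.array(list("ACGT"))
    chroms = [str(c) for c in rng.integers(1, 23, size=m)]
    pos = np.sort(rng.integers(10_000, 50_000_000, size=m))
    keys = []
    for j in range(m):
        ref, alt = rng.choice(bases, size=2, replace=False)
        keys.append(VariantKey(chroms[j], int(pos[j]) + j, str(ref), str(alt)))
    return keys


def _call_noise(gt: np.ndarray, config: SimulationConfig,
                rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Per-call DP, AD and GQ given the genotype codes, plus missingness."""
    shape = gt.shape
    dp = rng.poisson(config.mean_dp, size=shape).astype(np.int32)
    np.maximum(dp, 1, out=dp)
    ab = np.where(gt == 2, config.hom_alt_ab, np.where(gt == 1, config.het_ab, 0.002))
    ad_alt = rng.binomial(dp, ab).astype(np.int32)
    ad_ref = dp - ad_alt
    gq = np.clip(np.rint(rng.normal(config.gq_mean, config.gq_sd, size=shape)),
                 0, 99).astype(np.int32)
    miss = rng.random(shape) < config.call_missing_rate
    gt[miss] = GT_MISSING
    for arr in (dp, ad_alt, ad_ref, gq):
        arr[miss] = -1
    return {"ad_ref": ad_ref, "ad_alt": ad_alt, "gq": gq, "dp": dp}


def _subpop_rows(config: SimulationConfig, label: str) -> np.ndarray:
    offset = 0
    for sp in config.subpops:
        if sp.label == label:
            return np.arange(offset, offset + sp.n_subjects)
        offset += sp.n_subjects
    raise KeyError(f"unknown subpopulation {label!r}")


def spike_founder_allele(
    gm: GenotypeMatrix,
    truth: SimulationTruth,
    variant_index: int,
    subpop: str,
    target_af: float,
    config: SimulationConfig,
    rng: np.random.Generator,
    rows: np.ndarray | None = None,
) -> None:
    """Redraw one variant's genotypes in one subpopulation at ``target_af``.

    Uses the same inbreeding law with that subpopulation's F; other
    subpopulations are untouched. Truth is updated in place.
    """
    if not 0 < target_af < 1:
        raise ValueError(f"target AF must lie in (0,1), got {target_af}")
    rows = _subpop_rows(config, subpop) if rows is None else rows
    f = truth.f_by_subpop[subpop]
    q = np.asarray([target_af])
    new_gt = _draw_genotypes(q, f, rows.size, rng)[:, 0]
    gm.gt[rows, variant_index] = new_gt
    noise = _call_noise(gm.gt[rows, variant_index:variant_index + 1], config, rng)
    for name, arr in noise.items():
        getattr(gm, name)[rows, variant_index] = arr[:, 0]
    truth.true_afs.loc[subpop, variant_index] = target_af
    truth.founder_spikes.append(FounderSpike(variant_index, subpop, target_af))


# ---------------------------------------------------------------------------
# subjects and traits
# ---------------------------------------------------------------------------

def simulate_subjects(config: SimulationConfig, subject_ids: list[str],
                      rng: np.random.Generator) -> pd.DataFrame:
    """Subpopulation labels, sex, age and the first four PCs.

    PCs place each subpopulation around its own centroid, so they carry
    genuine ancestry signal for the covariate-adjusted models.
    """
    n = len(subject_ids)
    labels = np.concatenate([
        np.repeat(sp.label, sp.n_subjects) for sp in config.subpops
    ])
    sex = np.where(rng.random(n) < 0.563, "male", "female")  # cohort male fraction
    age = np.clip(rng.normal(40.0, 12.0, size=n), 18, 85)
    centroids = rng.normal(0.0, 0.05, size=(len(config.subpops), 4))
    pcs = np.empty((n, 4))
    offset = 0
    for i, sp in enumerate(config.subpops):
        pcs[offset:offset + sp.n_subjects] = (
            centroids[i] + rng.normal(0.0, 0.02, size=(sp.n_subjects, 4))
        )
        offset += sp.n_subjects
    df = pd.DataFrame({
        "subject_id": subject_ids,
        "subpopulation": labels,
        "sex": sex,
        "age": np.round(age, 1),
        "pc1": pcs[:, 0], "pc2": pcs[:, 1], "pc3": pcs[:, 2], "pc4": pcs[:, 3],
        "related": 0,
    })
    return df.set_index("subject_id", drop=False)


def simulate_traits(
    config: SimulationConfig,
    gm: GenotypeMatrix,
    subjects: pd.DataFrame,
    truth: SimulationTruth,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Quantitative traits: covariate effects + spiked variant effects + noise.

    trait = mean + sd * (b_age z_age + b_sex male + sum_k b_pc z_pck
                         + sum_spikes effect * g* + eps),   eps ~ N(0, 1)

    so spike effect sizes are expressed in units of the trait's manifest SD
    (the SD of the residual noise). For recessive spikes ``g* = 1[gt == 2]``;
    for additive spikes ``g*`` is the 0/1/2 allele count (missing calls
    contribute 0). Missing trait values are injected uniformly at random.
    """
    n = gm.n_subjects
    z_age = (subjects["age"].to_numpy() - 40.0) / 12.0
    male = (subjects["sex"] == "male").to_numpy().astype(float)
    pcs = subjects[["pc1", "pc2", "pc3", "pc4"]].to_numpy()
    z_pcs = (pcs - pcs.mean(axis=0)) / pcs.std(axis=0)

    base = (config.beta_age * z_age
            + config.beta_sex * (male - male.mean())
            + z_pcs @ np.full(4, config.beta_pc))

    spikes_by_trait: dict[str, list[EffectSpike]] = {}
    for spike in config.effect_spikes:
        if spike.trait not in config.trait_manifest:
            raise ValueError(f"effect spike names unknown trait {spike.trait!r}")
        spikes_by_trait.setdefault(spike.trait, []).append(spike)

    out = {}
    for name, (mean, sd) in config.trait_manifest.items():
        signal = base.copy()
        for spike in spikes_by_trait.get(name, ()):
            g = gm.gt[:, spike.variant_index]
            gstar = (g == 2).astype(float) if spike.model == "recessive" \
                else np.where(g > 0, g, 0).astype(float)
            signal += spike.effect_sd * gstar
            truth.effect_spikes.append({
                "variant_index": spike.variant_index, "trait": name,
                "effect_sd": spike.effect_sd, "model": spike.model,
                "beta_trait_units": spike.effect_sd * sd,
            })
        values = mean + sd * (signal + rng.normal(size=n))
        values[rng.random(n) < config.trait_missing_rate] = np.nan
        out[name] = values
    return pd.DataFrame(out, index=subjects.index)


# ---------------------------------------------------------------------------
# annotations and panels
# ---------------------------------------------------------------------------

_CONSEQ = ["missense", "nonsense", "frameshift", "splice_site", "synonymous", "other_noncoding"]
_CONSEQ_P = [0.50, 0.06, 0.06, 0.06, 0.17, 0.15]
_CODING = ["missense", "nonsense", "frameshift", "splice_site"]
_CODING_P = [0.70, 0.10, 0.10, 0.10]


def simulate_annotations(
    config: SimulationConfig,
    gm: GenotypeMatrix,
    truth: SimulationTruth,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Variant annotation table plus the gene-panel table.

    Designated "known P/LP" variants receive ClinVar P/LP (mixed review
    stars, with a minority downgraded to the conflicting or benign classes
    carrying a prior-P/LP flag) intersected with HGMD DM/DM?, coding
    consequences and global AF < 1%. Designated "novel candidates" receive
    CADD > 20, GERP > 3, no benign class, and are drawn among variants with
    at least 3 cohort homozygotes. Designated benign-common variants get
    global AF >= 2%.
    """
    m = gm.n_variants
    genes = np.array([f"GENE{i + 1:04d}" for i in range(config.n_genes)])
    gene_of = genes[rng.integers(0, config.n_genes, size=m)]
    consequence = rng.choice(_CONSEQ, p=_CONSEQ_P, size=m).astype(object)
    clinvar = np.full(m, "absent", dtype=object)
    stars = np.zeros(m, dtype=int)
    prior = np.zeros(m, dtype=bool)
    hgmd = np.full(m, "absent", dtype=object)
    cadd = np.round(rng.uniform(0.0, 25.0, size=m), 2)
    gerp = np.round(rng.normal(0.0, 2.0, size=m), 2)
    cohort_hom = (gm.gt == 2).sum(axis=0)

    order = rng.permutation(m)
    n_plp = min(config.n_known_plp, m)
    plp_idx = order[:n_plp]
    pool = [j for j in order[n_plp:] if cohort_hom[j] >= 3]
    novel_idx = np.asarray(pool[: config.n_novel_candidates], dtype=int)
    rest = np.setdiff1d(order[n_plp:], novel_idx)
    benign_idx = rest[: config.n_benign_common]

    # known P/LP: ClinVar class x stars per the four-category scheme
    for j in plp_idx:
        u = rng.random()
        if u < 0.45:        # current P/LP, well reviewed
            clinvar[j] = rng.choice(["pathogenic", "likely_pathogenic"])
            stars[j] = rng.integers(2, 4)
        elif u < 0.80:      # current P/LP, sparse review
            clinvar[j] = rng.choice(["pathogenic", "likely_pathogenic"])
            stars[j] = rng.integers(0, 2)
        elif u < 0.93:      # downgraded to conflicting/VUS
            clinvar[j] = rng.choice(["conflicting", "vus"])
            stars[j] = 1
            prior[j] = True
        else:               # downgraded to benign with a prior P/LP record
            clinvar[j] = rng.choice(["benign", "likely_benign"])
            stars[j] = rng.integers(1, 3)
            prior[j] = True
        hgmd[j] = rng.choice(["DM", "DM_q"], p=[0.8, 0.2])
        consequence[j] = rng.choice(_CODING, p=_CODING_P)
        cadd[j] = np.round(rng.uniform(20.0, 45.0), 2)
        gerp[j] = np.round(rng.uniform(2.0, 6.0), 2)

    for j in novel_idx:
        clinvar[j] = rng.choice(["absent", "vus"], p=[0.7, 0.3])
        hgmd[j] = rng.choice(["absent", "other"], p=[0.8, 0.2])
        cadd[j] = np.round(rng.uniform(20.5, 40.0), 2)
        gerp[j] = np.round(rng.uniform(3.1, 6.0), 2)
        consequence[j] = rng.choice(_CODING, p=_CODING_P)

    for j in benign_idx:
        clinvar[j] = rng.choice(["benign", "likely_benign"])
        stars[j] = rng.integers(1, 3)
        hgmd[j] = "absent"

    # global database AFs: cohort-correlated noise, forced rare for the
    # designated pathogenic/novel sets and common for the benign-common set
    pooled_af = truth.true_afs.mean(axis=0).to_numpy()
    # founder alleles are by construction rare outside the cohort
    founder_idx = np.asarray(sorted({s.variant_index for s in truth.founder_spikes}),
                             dtype=int)
    afs = {}
    for db in ("af_gnomad", "af_onekg", "af_gme"):
        noise = rng.lognormal(0.0, 0.8, size=m)
        af = np.clip(pooled_af * noise, 0.0, 0.5)
        af[rng.random(m) < 0.15] = 0.0  # absent from this database
        af[plp_idx] = np.minimum(af[plp_idx], rng.uniform(0.0, 0.008, size=plp_idx.size))
        if founder_idx.size:
            af[founder_idx] = np.minimum(
                af[founder_idx], rng.uniform(0.0, 0.008, size=founder_idx.size))
        if novel_idx.size:
            af[novel_idx] = np.minimum(af[novel_idx],
                                       rng.uniform(0.0, 0.008, size=novel_idx.size))
        af[benign_idx] = rng.uniform(0.02, 0.20, size=benign_idx.size)
        afs[db] = np.round(af, 6)

    ann = pd.DataFrame({
        "chrom": [v.chrom for v in gm.variants],
        "pos": [v.pos for v in gm.variants],
        "ref": [v.ref for v in gm.variants],
        "alt": [v.alt for v in gm.variants],
        "gene": gene_of,
        "consequence": consequence,
        "clinvar_class": clinvar,
        "clinvar_stars": stars,
        "clinvar_prior_plp": prior,
        "hgmd_class": hgmd,
        "cadd": cadd,
        "gerp": gerp,
        "noncoding_pathogenic": False,
        **afs,
    })

    n_panels = rng.integers(1, 4, size=config.n_genes)
    panel_lists = [",".join(sorted(rng.choice(PANEL_NAMES, size=k, replace=False)))
                   for k in n_panels]
    panels = pd.DataFrame({
        "gene": genes,
        "panels": panel_lists,
        "inheritance": rng.choice(["recessive", "dominant", "both", "other"],
                                  p=[0.55, 0.25, 0.12, 0.08], size=config.n_genes),
        "coding_length_bp": np.maximum(
            rng.lognormal(7.3, 0.6, size=config.n_genes).astype(int), 300),
    }).set_index("gene", drop=False)

    truth.known_plp_indices = sorted(int(j) for j in plp_idx)
    truth.novel_candidate_indices = sorted(int(j) for j in novel_idx)
    truth.benign_common_indices = sorted(int(j) for j in benign_idx)
    return ann, panels


# ---------------------------------------------------------------------------
# orchestration and writers
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, SimulationTruth]:
    """Generate a complete cohort (genotypes, subjects, traits, annotations)."""
    rng = np.random.default_rng(config.seed)
    gm, truth = simulate_genotypes(config, rng)
    subjects = simulate_subjects(config, gm.subjects, rng)
    annotations, panels = simulate_annotations(config, gm, truth, rng)
    traits = simulate_traits(config, gm, subjects, truth, rng)
    subjects = pd.concat([subjects, traits], axis=1)
    cohort = Cohort(
        gm=gm,
        annotations=align_annotations(annotations, gm.variants),
        subjects=subjects,
        panels=panels,
        trait_names=list(config.trait_manifest),
    )
    return cohort, truth


def write_cohort(cohort: Cohort, out_dir: str, truth: SimulationTruth | None = None) -> dict:
    """Write cohort.vcf, annotations.tsv, subjects.tsv, panels.tsv (+ truth.json)."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "cohort.vcf"),
        "annotations": os.path.join(out_dir, "annotations.tsv"),
        "subjects": os.path.join(out_dir, "subjects.tsv"),
        "panels": os.path.join(out_dir, "panels.tsv"),
    }
    write_vcf(cohort.gm, paths["vcf"])
    cohort.annotations.to_csv(paths["annotations"], sep="\t", index=False)
    cohort.subjects.to_csv(paths["subjects"], sep="\t", index=False)
    cohort.panels.to_csv(paths["panels"], sep="\t", index=False)
    if truth is not None:
        paths["truth"] = os.path.join(out_dir, "truth.json")
        truth.to_json(paths["truth"])
    return paths


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write the genotype matrix as an uncompressed VCF 4.2 with GT:AD:GQ:DP."""
    contigs = sorted({v.chrom for v in gm.variants},
                     key=lambda c: (len(c), c))
    order = sorted(range(gm.n_variants),
                   key=lambda j: (contigs.index(gm.variants[j].chrom), gm.variants[j].pos))
    gt_str = np.array([".", "0/0", "0/1", "1/1"])  # index by gt + 1 -> "./." handled below
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.subjects) + "\n")
        for j in order:
            v = gm.variants[j]
            cells = []
            for i in range(gm.n_subjects):
                g = gm.gt[i, j]
                if g == GT_MISSING:
                    cells.append("./.:.:.:.")
                else:
                    cells.append(f"{gt_str[g + 1]}:{gm.ad_ref[i, j]},{gm.ad_alt[i, j]}:"
                                 f"{gm.gq[i, j]}:{gm.dp[i, j]}")
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT:AD:GQ:DP\t"
                     + "\t".join(cells) + "\n")
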