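"""Extreme-trait screening of homozygotes.

Novel-candidate variants are screened by asking whether their cohort
homozygotes sit in the same tail of a quantitative trait's empirical
distribution — above the 95th or below the 5th percentile computed over
all non-missing cohort values. The default decision rule requires every
non-missing homozygote value in the same tail ("all"); a "majority" rule
(more than half) is available. Percentiles use the nearest-rank order
statistic (index ``ceil(p * n)`` of the sorted vector), so a flag near the
boundary does not depend on an interpolation convention.

No multiple-testing correction is applied: this is a hypothesis-generating
screen, and hits are to be triaged against the literature.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .datamodel import Cohort

logger = logging.getLogger(__name__)


def trait_percentiles(values: Iterable[float], probs: Iterable[float] = (0.05, 0.95),
                      min_n: int = 20) -> dict[float, float]:
    """Nearest-rank empirical percentiles over non-missing values."""
    v = np.asarray(list(values), dtype=float)
    v = np.sort(v[np.isfinite(v)])
    if v.size < min_n:
        raise ValueError(f"need at least {min_n} non-missing values, have {v.size}")
    out = {}
    for p in probs:
        k = max(1, math.ceil(p * v.size))
        out[p] = float(v[k - 1])
    return out


def extreme_homozygote_screen(cohort: Cohort, candidates: pd.DataFrame,
                              rule: str = "all", lower: float = 0.05,
                              upper: float = 0.95) -> pd.DataFrame:
    """Flag (variant, trait) pairs whose homozygotes are jointly extreme.

    ``candidates`` is a classified table slice (typically the novel-candidate
    set). For each candidate variant and each trait, the homozygotes'
    non-missing values are compared against the cohort-wide nearest-rank
    thresholds; a hit is emitted per (variant, trait, direction) when the
    rule holds in that tail. Variants without homozygotes are skipped with
    a log entry.
    """
    if rule not in {"all", "majority"}:
        raise ValueError(f"unknown rule {rule!r}")
    thresholds = {}
    for trait in cohort.trait_names:
        try:
            thresholds[trait] = trait_percentiles(cohort.subjects[trait], (lower, upper))
        except ValueError:
            logger.warning("trait %s has too few values; skipped", trait)

    keys = classified_variant_indices(cohort, candidates)
    rows = []
    for (j, rec) in keys:
        hom_rows = np.flatnonzero(cohort.gm.gt[:, j] == 2)
        if hom_rows.size == 0:
            logger.info("candidate %s:%s has no homozygotes; skipped",
                        rec["chrom"], rec["pos"])
            continue
        for trait, thr in thresholds.items():
            vals = cohort.subjects[trait].to_numpy()[hom_rows]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                continue
            lo, hi = thr[lower], thr[upper]
            n_low = int((vals < lo).sum())
            n_high = int((vals > hi).sum())
            for direction, n_ext in (("below_5th", n_low), ("above_95th", n_high)):
                ok = (n_ext == vals.size) if rule == "all" else (n_ext > vals.size / 2)
                if ok and n_ext > 0:
                    rows.append({
                        "chrom": rec["chrom"], "pos": rec["pos"],
                        "ref": rec["ref"], "alt": rec["alt"], "gene": rec["gene"],
                        "trait": trait, "direction": direction,
                        "n_hom": int(hom_rows.size), "n_hom_extreme": n_ext,
                        "hom_values": ",".join(f"{v:.4g}" for v in vals),
                        "threshold_low": lo, "threshold_high": hi,
                    })
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "gene", "trait",
                                       "direction", "n_hom", "n_hom_extreme",
                                       "hom_values", "threshold_low", "threshold_high"])


def classified_variant_indices(cohort: Cohort, table: pd.DataFrame):
    """Pair each classified-table row with its genotype-matrix column index."""
    from .datamodel import VariantKey

    for _, rec in table.iterrows():
        key = VariantKey(str(rec["chrom"]), int(rec["pos"]), rec["ref"], rec["alt"])
        yield cohort.gm.variant_index(key), rec


def plp_carrier_trait_flags(cohort: Cohort, classified: pd.DataFrame,
                            trait_map: Mapping[str, Iterable[str]],
                            lower: float = 0.05, upper: float = 0.95) -> pd.DataFrame:
    """Percentile-flag mapped trait values of known-P/LP carriers.

    ``trait_map`` maps gene symbol -> relevant trait name(s). For recessive-
    condition genes the carriers examined are homozygotes; for dominant-
    condition genes, heterozygotes; genes with "both" report both. Rows with
    missing trait values carry a null value and no flag. This is a screening
    aid, not a clinical interpretation.
    """
    known = classified[classified["is_known_plp"]]
    thresholds = {}
    rows = []
    for j, rec in classified_variant_indices(cohort, known):
        traits = trait_map.get(rec["gene"])
        if not traits:
            continue
        g = cohort.gm.gt[:, j]
        if rec["inheritance"] in {"recessive", "both"}:
            carrier_rows = np.flatnonzero(g == 2)
        elif rec["inheritance"] == "dominant":
            carrier_rows = np.flatnonzero(g == 1)
        else:
            continue
        if rec["inheritance"] == "both":
            carrier_rows = np.flatnonzero((g == 1) | (g == 2))
        for trait in ([traits] if isinstance(traits, str) else traits):
            if trait not in cohort.trait_names:
                logger.warning("mapped trait %s not in cohort; skipped", trait)
                continue
            if trait not in thresholds:
                thresholds[trait] = trait_percentiles(cohort.subjects[trait], (lower, upper))
            thr = thresholds[trait]
            for i in carrier_rows:
                val = cohort.subjects[trait].iloc[i]
                flag = ""
                if np.isfinite(val):
                    if val < thr[lower]:
                        flag = "below_5th"
                    elif val > thr[upper]:
                        flag = "above_95th"
                rows.append({
                    "gene": rec["gene"], "chrom": rec["chrom"], "pos": rec["pos"],
                    "ref": rec["ref"], "alt": rec["alt"],
                    "subject_id": cohort.gm.subjects[i],
                    "zygosity": "hom" if cohort.gm.gt[i, j] == 2 else "het",
                    "trait": trait,
                    "value": float(val) if np.isfinite(val) else None,
                    "flag": flag,
                })
    return pd.DataFrame(rows, columns=["gene", "chrom", "pos", "ref", "alt", "subject_id",
                                       "zygosity", "trait", "value", "flag"])
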