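"""Shared simulation experiments for operating-characteristic tests.

Each helper runs the package end-to-end on generator output under fixed
study-like conditions and returns the measured quantity; the callers
assert against their own expectations.
"""

import numpy as np

from mendelburden.catalog import classify_cohort
from mendelburden.rvtest import genome_wide_scan
from mendelburden.synthetic import (
    EffectSpike,
    FounderSpike,
    SimulationConfig,
    SubpopSpec,
    simulate_cohort,
)
from mendelburden.traits import extreme_homozygote_screen


def burden_spike_pvalue(seed: int, effect_sd: float = 0.5, n: int = 10_000,
                        carrier_af: float = 0.0015) -> float:
    """Scan p-value of a gene carrying one spiked variant (~2*n*af carriers)."""
    cfg = SimulationConfig(
        seed=seed,
        subpops=[SubpopSpec("POP", n, 0.0)],
        n_genes=10, n_variants=30, af_log10_min=-3.6, af_log10_max=-2.8,
        founder_spikes=[FounderSpike(0, "POP", carrier_af)],
        effect_spikes=[EffectSpike(0, "glucose", effect_sd, "additive")],
        trait_manifest={"glucose": (5.5, 1.2)},
        n_known_plp=0, n_novel_candidates=0, n_benign_common=0,
    )
    cohort, _ = simulate_cohort(cfg)
    full, _ = genome_wide_scan(cohort)
    gene = cohort.annotations["gene"].iloc[0]
    row = full[full["gene"] == gene]
    return float(row["p_value"].iloc[0]) if len(row) else 1.0


def null_scan_pvalues(seed: int = 0, n: int = 10_000, n_genes: int = 240,
                      n_variants: int = 700, n_traits: int = 5) -> np.ndarray:
    """P-values of a fully null scan (no spiked effects)."""
    cfg = SimulationConfig(
        seed=seed,
        subpops=[SubpopSpec("POP", n, 0.0)],
        n_genes=n_genes, n_variants=n_variants,
        af_log10_min=-3.0, af_log10_max=-2.1,
        trait_manifest={f"t{i}": (0.0, 1.0) for i in range(n_traits)},
        n_known_plp=0, n_novel_candidates=0, n_benign_common=0,
    )
    cohort, _ = simulate_cohort(cfg)
    full, _ = genome_wide_scan(cohort)
    full = full.sort_values(["gene", "trait"]).reset_index(drop=True)
    return full["p_value"].to_numpy()


def extreme_screen_recovery(n_seeds: int, effect_sd: float = -2.0,
                            n: int = 3000, seed_offset: int = 0) -> tuple[int, int]:
    """(recovered, eligible) spiked recessive variants over seeds.

    Each replicate spikes one variant to an AF giving ~5 expected
    homozygotes and applies the stated effect to one trait; a replicate is
    eligible when at least 3 homozygotes were realised (the candidate
    rule), and recovered when the screen flags (variant, trait, below_5th).
    """
    q = np.sqrt(5.0 / n)
    recovered = eligible = 0
    for s in range(n_seeds):
        cfg = SimulationConfig(
            seed=seed_offset + s,
            subpops=[SubpopSpec("POP", n, 0.0)],
            n_genes=6, n_variants=12, af_log10_min=-3.0, af_log10_max=-2.0,
            founder_spikes=[FounderSpike(0, "POP", q)],
            effect_spikes=[EffectSpike(0, "uric_acid", effect_sd, "recessive")],
            trait_manifest={"uric_acid": (300.0, 60.0), "null_t": (0.0, 1.0)},
            n_known_plp=0, n_novel_candidates=0, n_benign_common=0,
        )
        cohort, _ = simulate_cohort(cfg)
        if int((cohort.gm.gt[:, 0] == 2).sum()) < 3:
            continue
        eligible += 1
        classified = classify_cohort(cohort)
        candidate = classified.iloc[[0]]
        hits = extreme_homozygote_screen(cohort, candidate, rule="all")
        if len(hits[(hits["trait"] == "uric_acid") & (hits["direction"] == "below_5th")]):
            recovered += 1
    return recovered, eligible
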