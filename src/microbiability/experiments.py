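"""Reusable validation experiments on synthetic cohorts.

Each function generates cohorts with known ground truth, runs the relevant
pipeline stage, and reports recovery/calibration summaries. The problem
sizes (n = 400 individuals, 2,000 SNPs, 150 ASVs, 6,000-iteration chains
with 1,000 burn-in, 10 seeds) keep a full battery at desk scale while
leaving the posterior summaries stable to well under the tolerances being
checked.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_qc import aggregate_to_genus
from .kernels import clr_transform, compute_B, compute_G, css_normalize
from .mwas import build_mwas_spec, fit_mwas, mwas_result
from .pcit import build_correlation_set, build_network, pcit
from .synthetic import SimulationConfig, TraitSpec, simulate_cohort
from .varpart import build_model_spec, fit_two_kernel_model, summarize_partition

__all__ = [
    "RECOVERY_CONFIG",
    "variance_recovery",
    "null_variance_calibration",
    "mwas_power_study",
    "mwas_null_calibration",
    "network_edge_recovery",
]

# study-scale-down defaults shared by the recovery experiments
RECOVERY_CONFIG = dict(
    n_individuals=400,
    n_snps=2_000,
    n_asvs=150,
    n_genera=20,
    n_traits=1,
)
CHAIN = dict(iterations=6_000, burn_in=1_000)


def _fit_one(cohort, trait: str, seed: int, **chain_kw):
    G = compute_G(cohort.genotypes)
    B = compute_B(css_normalize(cohort.microbiome))
    spec = build_model_spec(cohort.phenotypes, trait, G, B)
    kw = {**CHAIN, **chain_kw}
    chain = fit_two_kernel_model(spec, seed=seed, **kw)
    return summarize_partition(chain)


def variance_recovery(
    h2: float = 0.30,
    m2: float = 0.25,
    n_seeds: int = 10,
    base_seed: int = 0,
    **chain_kw,
) -> pd.DataFrame:
    """Estimate (h2, m2) on fresh cohorts; one row per seed.

    Returns nominal and estimated fractions plus absolute errors; the mean
    of ``h2_abs_err``/``m2_abs_err`` is the MAE figure of merit.
    """
    rows = []
    for s in range(n_seeds):
        cfg = SimulationConfig(
            **RECOVERY_CONFIG, h2_true=h2, m2_true=m2, seed=base_seed + 1000 + s
        )
        cohort = simulate_cohort(cfg)
        vp = _fit_one(cohort, "T1", seed=base_seed + s, **chain_kw)
        rows.append(
            {
                "seed": s,
                "h2_true": h2,
                "m2_true": m2,
                "h2_hat": vp.h2_mean,
                "m2_hat": vp.m2_mean,
                "h2_abs_err": abs(vp.h2_mean - h2),
                "m2_abs_err": abs(vp.m2_mean - m2),
                "m2_gt_h2": vp.m2_mean > vp.h2_mean,
                "prob_h2_gt_0.1": vp.prob_h2_gt[0.1],
                "prob_m2_gt_0.1": vp.prob_m2_gt[0.1],
            }
        )
    return pd.DataFrame(rows)


def null_variance_calibration(
    n_seeds: int = 5, base_seed: int = 0, **chain_kw
) -> pd.DataFrame:
    """Pure-noise traits (h2 = m2 = 0): fitted fractions should sit near 0."""
    return variance_recovery(
        h2=0.0, m2=0.0, n_seeds=n_seeds, base_seed=base_seed + 50_000, **chain_kw
    )


# ---------------------------------------------------------------------------
# MWAS experiments
# ---------------------------------------------------------------------------

MWAS_CONFIG = dict(
    n_individuals=400,
    n_snps=400,  # genotypes are nuisance here
    n_asvs=120,
    n_genera=13,
)
MWAS_CHAIN = dict(iterations=4_000, burn_in=1_000)


def _run_mwas_cohort(cfg: SimulationConfig, seed: int, bf_threshold: float):
    cohort = simulate_cohort(cfg)
    genus = aggregate_to_genus(cohort.microbiome)
    frames = []
    for i, trait in enumerate(cohort.phenotypes.traits):
        spec = build_mwas_spec(cohort.phenotypes, trait, genus)
        post = fit_mwas(spec, seed=seed + i, **MWAS_CHAIN)
        frames.append(mwas_result(post, threshold=bf_threshold))
    results = pd.concat(frames, ignore_index=True)
    truth_pairs = {
        (t, c["genus"])
        for t, rec in cohort.truth["traits"].items()
        for c in rec["causal_taxa"]
    }
    return results, truth_pairs


def mwas_power_study(
    n_seeds: int = 10,
    n_planted: int = 5,
    effect_size: float = 0.3,
    bf_threshold: float = 2.0,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Plant sparse genus effects and score BF-based recovery per seed.

    Five (trait, genus) effects are planted across 5 traits over 13 genera
    (65 tested pairs, 60 null). Reports true-positive and false-positive
    counts at the BF threshold.
    """
    rows = []
    for s in range(n_seeds):
        cfg = SimulationConfig(
            **MWAS_CONFIG,
            h2_true=0.15,
            m2_true=0.0,
            n_traits=5,
            n_causal_taxa=n_planted,
            taxon_effect_size=effect_size,
            seed=base_seed + 7_000 + s,
        )
        results, truth_pairs = _run_mwas_cohort(
            cfg, seed=base_seed + 70 + 10 * s, bf_threshold=bf_threshold
        )
        hits = {
            (t, g)
            for t, g, ok in zip(
                results["trait"], results["taxon"], results["passes_threshold"]
            )
            if ok
        }
        n_pairs = len(results)
        rows.append(
            {
                "seed": s,
                "n_pairs": n_pairs,
                "n_planted": len(truth_pairs),
                "true_positives": len(hits & truth_pairs),
                "false_positives": len(hits - truth_pairs),
                "n_null_pairs": n_pairs - len(truth_pairs),
            }
        )
    return pd.DataFrame(rows)


def mwas_null_calibration(
    n_seeds: int = 5, bf_threshold: float = 2.0, base_seed: int = 0
) -> pd.DataFrame:
    """No planted effects: fraction of pairs at BF >= threshold per seed."""
    rows = []
    for s in range(n_seeds):
        cfg = SimulationConfig(
            **MWAS_CONFIG,
            h2_true=0.15,
            m2_true=0.0,
            n_traits=3,
            n_causal_taxa=0,
            seed=base_seed + 9_000 + s,
        )
        results, _ = _run_mwas_cohort(
            cfg, seed=base_seed + 90 + 10 * s, bf_threshold=bf_threshold
        )
        rows.append(
            {
                "seed": s,
                "n_pairs": len(results),
                "n_passing": int(results["passes_threshold"].sum()),
                "fp_rate": float(results["passes_threshold"].mean()),
                "max_abs_ratio": float(
                    (results["posterior_mean"].abs() / results["posterior_sd"]).max()
                ),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# network experiments
# ---------------------------------------------------------------------------


def network_edge_recovery(
    n_seeds: int = 10,
    planted_r: float = 0.35,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Plant one genus-trait correlation per trait and score PCIT edges.

    Six traits and 15 genera at n = 400; each trait gets one planted clr-
    genus correlation of |r| = ``planted_r`` (alternating sign). Reports
    planted edges recovered and extra trait-genus edges per seed.
    """
    n_traits = 6
    rows = []
    for s in range(n_seeds):
        genera = [f"genus_{g + 1:03d}" for g in range(15)]
        specs = [
            TraitSpec(
                name=f"T{i + 1}",
                h2=0.15,
                m2=0.0,
                planted_edges=[(genera[i], planted_r * (-1) ** i)],
            )
            for i in range(n_traits)
        ]
        cfg = SimulationConfig(
            n_individuals=400,
            n_snps=400,
            n_asvs=120,
            n_genera=15,
            trait_specs=specs,
            seed=base_seed + 3_000 + s,
        )
        cohort = simulate_cohort(cfg)
        genus = aggregate_to_genus(cohort.microbiome)
        gclr = clr_transform(genus)
        gdf = gclr.to_frame().drop(columns=["unclassified"], errors="ignore")
        traits_df = cohort.phenotypes.data[cohort.phenotypes.traits]
        cs = build_correlation_set(
            traits_df, gdf, covariates=cohort.phenotypes.data[["sex", "batch"]]
        )
        mask = pcit(cs.R)
        net = build_network(mask, cs.R, cs.roles, cs.variable_ids)
        planted = {
            (t, e["genus"])
            for t, rec in cohort.truth["traits"].items()
            for e in rec["planted_edges"]
        }
        found = {
            (t, g) for t, g in zip(net.edges["trait"], net.edges["genus"])
        }
        rows.append(
            {
                "seed": s,
                "n_planted": len(planted),
                "planted_found": len(found & planted),
                "false_edges": len(found - planted),
                "n_edges": len(found),
            }
        )
    return pd.DataFrame(rows)
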