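"""Synthetic cohorts with known ground truth for every pipeline stage.

The generator emulates the statistical structure the analysis assumes:

* biallelic SNP genotypes in Hardy-Weinberg proportions with uniform minor-
  allele frequencies and optional missing calls;
* overdispersed compositional ASV counts: long-tailed (Zipf) genus baseline
  weights, log-normal ASV baselines within genus, per-sample Dirichlet
  composition around the baseline and multinomial counts at a library size
  drawn uniformly per sample;
* phenotypes built from the same generative decomposition the fitter
  assumes, y = X beta + u + m + e, with u ~ N(0, G s2_u) and
  m ~ N(0, B s2_m) drawn by scaled eigenvector mixing of the realized
  kernels (the fitter never sees these draws), plus optional sparse direct
  genus effects on the clr scale and planted genus-trait correlations.

Every quantity needed to score downstream inference (effect vectors,
realized variance fractions, causal pairs, realized planted correlations)
is stored in the cohort's truth record. A single integer seed fully
determines the cohort.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_qc import (
    AbundanceTable,
    GenotypeMatrix,
    PhenotypeTable,
    aggregate_to_genus,
    read_counts,
    read_genotypes,
    read_phenotypes,
    read_taxonomy,
    write_counts,
    write_genotypes,
    write_phenotypes,
    write_taxonomy,
)
from .kernels import clr_transform, compute_B, compute_G, css_normalize

logger = logging.getLogger(__name__)

__all__ = [
    "TraitSpec",
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_genotypes",
    "simulate_microbiome",
    "simulate_phenotypes",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
]


@dataclass
class TraitSpec:
    """Per-trait generative settings; fractions refer to the u/m/e split."""

    name: str
    h2: float = 0.30
    m2: float = 0.25
    causal_genera: list[str] = field(default_factory=list)
    effect_size: float = 0.3  # per causal genus, in trait-SD units
    planted_edges: list[tuple[str, float]] = field(default_factory=list)
    intercept: float = 10.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.h2 < 1.0 and 0.0 <= self.m2 < 1.0):
            raise ValueError("h2 and m2 must lie in [0, 1)")
        if self.h2 + self.m2 >= 1.0:
            raise ValueError("h2 + m2 must be below 1")


@dataclass
class SimulationConfig:
    """Cohort-level generative settings.

    Defaults mirror the study design this pipeline targets: 389 individuals
    on a ~70K SNP array (42,641 SNPs after QC), roughly 2,055 ASVs grouped
    into 68 genera, 16S libraries of 10k-60k reads, and traits with
    heritability/microbiability in the low-to-moderate range. Every
    dimension scales down for fast tests.
    """

    n_individuals: int = 389
    n_snps: int = 42_641
    maf_range: tuple[float, float] = (0.05, 0.5)
    genotype_missing_rate: float = 0.0
    n_asvs: int = 2_055
    n_genera: int = 68
    frac_unclassified: float = 0.03
    library_size_range: tuple[int, int] = (10_000, 60_000)
    overdispersion: float = 100.0  # Dirichlet concentration multiplier
    genus_zipf_exponent: float = 1.0
    asv_lognormal_sigma: float = 1.0
    h2_true: float = 0.30
    m2_true: float = 0.25
    n_traits: int = 3
    n_causal_taxa: int = 0
    taxon_effect_size: float = 0.3
    planted_edges: list[tuple[str, str, float]] = field(default_factory=list)
    sex_effect: float = 0.3
    batch_sd: float = 0.3
    trait_specs: list[TraitSpec] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not (0.0 <= self.h2_true < 1.0 and 0.0 <= self.m2_true < 1.0):
            raise ValueError("h2_true and m2_true must lie in [0, 1)")
        if self.h2_true + self.m2_true >= 1.0:
            raise ValueError("h2_true + m2_true must be below 1")
        if self.library_size_range[0] > self.library_size_range[1]:
            raise ValueError("invalid library_size_range")

    def resolved_trait_specs(self, genera: list[str]) -> list[TraitSpec]:
        if self.trait_specs is not None:
            return self.trait_specs
        specs = [
            TraitSpec(name=f"T{i + 1}", h2=self.h2_true, m2=self.m2_true)
            for i in range(self.n_traits)
        ]
        # distribute config-level causal taxa round-robin over traits
        rng = np.random.default_rng(self.seed + 101)
        if self.n_causal_taxa > 0:
            chosen = rng.choice(
                len(genera), size=min(self.n_causal_taxa, len(genera)),
                replace=False,
            )
            for k, gi in enumerate(chosen):
                spec = specs[k % len(specs)]
                spec.causal_genera.append(genera[gi])
                spec.effect_size = self.taxon_effect_size
        for genus, trait, r in self.planted_edges:
            for spec in specs:
                if spec.name == trait:
                    spec.planted_edges.append((genus, r))
        return specs


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    genotypes: GenotypeMatrix
    microbiome: AbundanceTable
    phenotypes: PhenotypeTable
    truth: dict


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def simulate_genotypes(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """Independent SNPs: MAF ~ U(maf_range), dosage ~ Binomial(2, p)."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    maf = rng.uniform(*cfg.maf_range, size=cfg.n_snps)
    dosages = rng.binomial(2, maf, size=(cfg.n_individuals, cfg.n_snps)).astype(
        float
    )
    if cfg.genotype_missing_rate > 0:
        miss = rng.random(dosages.shape) < cfg.genotype_missing_rate
        dosages[miss] = np.nan
    return GenotypeMatrix(
        individual_ids=[f"ind_{i + 1:04d}" for i in range(cfg.n_individuals)],
        snp_ids=[f"snp_{j + 1:06d}" for j in range(cfg.n_snps)],
        dosages=dosages,
        metadata={"true_maf": maf},
    )


# ---------------------------------------------------------------------------
# microbiome
# ---------------------------------------------------------------------------


def simulate_microbiome(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> AbundanceTable:
    """Dirichlet-multinomial counts around a long-tailed baseline.

    Genus baseline weights follow a Zipf law (rank^-s); each genus's weight
    is spread over its member ASVs with log-normal jitter. Per sample the
    composition is Dirichlet(overdispersion * baseline) and counts are
    multinomial at the sample's library size, so row totals equal the drawn
    library sizes exactly and larger overdispersion means proportions closer
    to the baseline.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    ranks = np.arange(1, cfg.n_genera + 1, dtype=float)
    genus_w = ranks ** (-cfg.genus_zipf_exponent)
    genus_w /= genus_w.sum()
    genera = [f"genus_{g + 1:03d}" for g in range(cfg.n_genera)]

    # membership: ASVs assigned to genera proportionally to genus weight,
    # at least one ASV per genus; a small fraction stays unclassified
    n_uncl = int(round(cfg.frac_unclassified * cfg.n_asvs))
    n_classified = cfg.n_asvs - n_uncl
    if n_classified < cfg.n_genera:
        raise ValueError("need at least one classified ASV per genus")
    assign = list(range(cfg.n_genera))
    extra = rng.choice(
        cfg.n_genera, size=n_classified - cfg.n_genera, replace=True, p=genus_w
    )
    assign.extend(extra.tolist())
    rng.shuffle(assign)
    genus_of = assign + [-1] * n_uncl  # -1 = unclassified

    baseline = np.empty(cfg.n_asvs)
    for g in range(cfg.n_genera):
        members = [j for j, a in enumerate(genus_of) if a == g]
        jitter = rng.lognormal(0.0, cfg.asv_lognormal_sigma, size=len(members))
        baseline[members] = genus_w[g] * jitter / jitter.sum()
    uncl = [j for j, a in enumerate(genus_of) if a == -1]
    if uncl:
        # unclassified ASVs sit in the tail with small baseline mass
        w_uncl = 0.01
        jitter = rng.lognormal(0.0, cfg.asv_lognormal_sigma, size=len(uncl))
        baseline[uncl] = w_uncl * jitter / jitter.sum()
    baseline /= baseline.sum()

    lib = rng.integers(
        cfg.library_size_range[0], cfg.library_size_range[1] + 1,
        size=cfg.n_individuals,
    )
    counts = np.empty((cfg.n_individuals, cfg.n_asvs), dtype=np.int64)
    alpha = cfg.overdispersion * baseline
    for i in range(cfg.n_individuals):
        p = rng.dirichlet(alpha)
        counts[i] = rng.multinomial(lib[i], p)

    asv_ids = [f"asv_{j + 1:05d}" for j in range(cfg.n_asvs)]
    taxonomy = {
        asv_ids[j]: (genera[genus_of[j]] if genus_of[j] >= 0 else "")
        for j in range(cfg.n_asvs)
    }
    return AbundanceTable(
        sample_ids=[f"ind_{i + 1:04d}" for i in range(cfg.n_individuals)],
        feature_ids=asv_ids,
        counts=counts,
        level="asv",
        taxonomy=taxonomy,
        metadata={"library_sizes": lib, "baseline": baseline},
    )


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def _mvn_from_kernel(
    K: np.ndarray, sigma2: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw N(0, K sigma2) by scaled eigenvector mixing."""
    w, U = np.linalg.eigh(K)
    w = np.clip(w, 0.0, None)
    z = rng.standard_normal(w.size)
    return U @ (np.sqrt(w * sigma2) * z)


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    microbiome: AbundanceTable,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[PhenotypeTable, dict]:
    """Phenotypes from y = X beta + u + m + e with known components.

    Total random variance is nominally 1: s2_u = h2, s2_m = m2,
    s2_e = 1 - h2 - m2. The truth record stores, per trait, the realized
    variance fractions of the stored u/m/e draws, the causal genus pairs and
    the realized planted correlations.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    n = genotypes.n_individuals
    ids = list(genotypes.individual_ids)

    G = compute_G(genotypes)
    B = compute_B(css_normalize(microbiome))
    genus_table = aggregate_to_genus(microbiome)
    genus_clr = clr_transform(genus_table)
    genus_cols = {g: k for k, g in enumerate(genus_table.feature_ids)}

    sex = rng.integers(0, 2, size=n)
    batch = rng.integers(0, 6, size=n)
    lab_batch = batch * 2 + rng.integers(0, 2, size=n)

    genera = [g for g in genus_table.feature_ids if g != "unclassified"]
    specs = cfg.resolved_trait_specs(genera)

    data = pd.DataFrame(
        {
            "sex": np.where(sex == 1, "male", "female"),
            "batch": [f"b{b + 1}" for b in batch],
            "lab_batch": [f"lb{lb + 1}" for lb in lab_batch],
        },
        index=ids,
    )
    truth: dict = {"traits": {}, "config_seed": cfg.seed}

    for spec in specs:
        s2u, s2m = spec.h2, spec.m2
        s2e = 1.0 - s2u - s2m
        u = _mvn_from_kernel(G.values, s2u, rng) if s2u > 0 else np.zeros(n)
        m = _mvn_from_kernel(B.values, s2m, rng) if s2m > 0 else np.zeros(n)
        e = rng.normal(0.0, np.sqrt(s2e), size=n)
        y = u + m + e

        causal = []
        for genus in spec.causal_genera:
            gvec = _zscore(genus_clr.values[:, genus_cols[genus]])
            y = y + spec.effect_size * gvec
            causal.append({"genus": genus, "effect_size": spec.effect_size})

        planted = []
        for genus, target_r in spec.planted_edges:
            gvec = _zscore(genus_clr.values[:, genus_cols[genus]])
            sd_y = y.std(ddof=1)
            y = (
                np.sqrt(1.0 - target_r**2) * _zscore(y) + target_r * gvec
            ) * sd_y
            realized = float(np.corrcoef(y, gvec)[0, 1])
            planted.append(
                {"genus": genus, "target_r": target_r, "realized_r": realized}
            )

        # fixed effects on top of the random decomposition
        sex_beta = cfg.sex_effect
        if "PHAGO" in spec.name.upper():
            bb = rng.normal(0.0, cfg.batch_sd, size=12)
            y = y + bb[lab_batch]
        else:
            bb = rng.normal(0.0, cfg.batch_sd, size=6)
            y = y + bb[batch]
        y = y + sex_beta * sex + spec.intercept

        if spec.missing_rate > 0:
            miss = rng.random(n) < spec.missing_rate
            y = np.where(miss, np.nan, y)

        vu, vm, ve = (np.var(v) for v in (u, m, e))
        vtot = vu + vm + ve
        truth["traits"][spec.name] = {
            "h2_nominal": spec.h2,
            "m2_nominal": spec.m2,
            "h2_realized": float(vu / vtot) if vtot > 0 else 0.0,
            "m2_realized": float(vm / vtot) if vtot > 0 else 0.0,
            "u": u.tolist(),
            "m": m.tolist(),
            "e": e.tolist(),
            "causal_taxa": causal,
            "planted_edges": planted,
        }
        data[spec.name] = y

    phen = PhenotypeTable(
        data=data,
        traits=[s.name for s in specs],
        covariate_names=["sex", "batch", "lab_batch"],
    )
    return phen, truth


def simulate_cohort(cfg: SimulationConfig) -> SyntheticCohort:
    """Generate genotypes, microbiome and phenotypes from a single seed."""
    geno = simulate_genotypes(cfg, np.random.default_rng(cfg.seed))
    micro = simulate_microbiome(cfg, np.random.default_rng(cfg.seed + 1))
    phen, truth = simulate_phenotypes(
        geno, micro, cfg, np.random.default_rng(cfg.seed + 2)
    )
    return SyntheticCohort(
        config=cfg, genotypes=geno, microbiome=micro, phenotypes=phen,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# cohort directory round-trip
# ---------------------------------------------------------------------------


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_genotypes(cohort.genotypes, d / "genotypes.tsv")
    write_counts(cohort.microbiome, d / "counts.tsv")
    if cohort.microbiome.taxonomy is not None:
        write_taxonomy(cohort.microbiome.taxonomy, d / "taxonomy.tsv")
    write_phenotypes(cohort.phenotypes, d / "phenotypes.tsv")
    cfg = asdict(cohort.config)
    cfg["trait_specs"] = (
        [asdict(s) for s in cohort.config.trait_specs]
        if cohort.config.trait_specs is not None
        else None
    )
    with open(d / "truth.json", "w") as fh:
        json.dump({"config": cfg, "truth": cohort.truth}, fh, indent=1)


def read_cohort(directory: str | Path) -> SyntheticCohort:
    d = Path(directory)
    with open(d / "truth.json") as fh:
        blob = json.load(fh)
    cfg_d = blob["config"]
    specs = cfg_d.pop("trait_specs", None)
    for key in ("maf_range", "library_size_range"):
        cfg_d[key] = tuple(cfg_d[key])
    cfg_d["planted_edges"] = [tuple(x) for x in cfg_d.get("planted_edges", [])]
    cfg = SimulationConfig(**cfg_d)
    if specs is not None:
        cfg.trait_specs = [
            TraitSpec(**{**s, "planted_edges": [tuple(x) for x in s["planted_edges"]]})
            for s in specs
        ]
    geno = read_genotypes(d / "genotypes.tsv")
    tax = read_taxonomy(d / "taxonomy.tsv") if (d / "taxonomy.tsv").exists() else None
    micro = read_counts(d / "counts.tsv", taxonomy=tax)
    phen = read_phenotypes(d / "phenotypes.tsv")
    return SyntheticCohort(
        config=cfg, genotypes=geno, microbiome=micro, phenotypes=phen,
        truth=blob["truth"],
    )
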