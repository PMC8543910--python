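"""Tabular input/output, quality control and descriptive statistics.

This module holds the three tabular containers the pipeline consumes —
SNP dosage matrices, ASV/genus count tables with a taxonomy map, and
phenotype tables with their covariates — together with the quality-control
filters applied before any modelling:

* SNPs are dropped when the minor-allele frequency is below 5% or the
  missing-call rate exceeds 10%.
* Microbiome samples are dropped below 10,000 reads; ASVs must be present
  in at least 3 samples and carry at least 0.001% of the total counts.

Filters are pure: missing dosages survive QC untouched and are only
mean-imputed inside kernel construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "AbundanceTable",
    "PhenotypeTable",
    "ParseError",
    "QCError",
    "read_genotypes",
    "write_genotypes",
    "read_counts",
    "write_counts",
    "read_taxonomy",
    "write_taxonomy",
    "read_phenotypes",
    "write_phenotypes",
    "snp_qc",
    "filter_microbiome",
    "aggregate_to_genus",
    "describe_traits",
    "default_covariate_map",
]

UNCLASSIFIED = "unclassified"


class ParseError(ValueError):
    """Raised when an input file violates the expected format."""


class QCError(ValueError):
    """Raised when a quality-control step leaves nothing to analyse."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix, coded 0/1/2 with NaN for missing.

    ``allele_freq`` is the frequency of the minor (less common) allele per
    SNP, computed from non-missing calls; it lies in [0, 0.5].
    """

    individual_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray  # float array, NaN = missing
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.individual_ids), len(self.snp_ids)):
            raise ValueError("dosage shape does not match id lists")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ParseError("duplicated individual identifiers")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ParseError("duplicated SNP identifiers")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            i, j = np.argwhere(~valid)[0]
            raise ParseError(
                f"dosage value {self.dosages[i, j]!r} outside {{0,1,2,NA}} at "
                f"individual {self.individual_ids[i]!r}, SNP {self.snp_ids[j]!r}"
            )

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def counted_allele_freq(self) -> np.ndarray:
        """Frequency of the allele counted by the dosage coding (alt allele)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0

    @property
    def allele_freq(self) -> np.ndarray:
        """Minor-allele frequency per SNP, in [0, 0.5]."""
        p = self.counted_allele_freq
        return np.minimum(p, 1.0 - p)

    @property
    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosages, index=self.individual_ids, columns=self.snp_ids
        )


@dataclass
class AbundanceTable:
    """Samples x features non-negative count matrix at ASV or genus level."""

    sample_ids: list[str]
    feature_ids: list[str]
    counts: np.ndarray
    level: str = "asv"  # {"asv", "genus"}
    taxonomy: dict[str, str] | None = None  # feature -> genus, when level=asv
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError("count shape does not match id lists")
        if self.level not in ("asv", "genus"):
            raise ValueError(f"unknown level {self.level!r}")
        if np.any(self.counts < 0):
            raise ParseError("negative counts are not allowed")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.sample_ids, columns=self.feature_ids
        )


@dataclass
class PhenotypeTable:
    """Trait values plus covariate assignment per individual.

    ``data`` holds one row per individual with trait columns (numeric, may
    contain NaN) and covariate columns. ``trait_covariates`` maps each trait
    to the covariate factors entering its fixed-effect design; by default
    phagocytosis traits use the 12-level laboratory batch, everything else
    the 6-level rearing batch, and sex always enters.
    """

    data: pd.DataFrame
    traits: list[str]
    covariate_names: list[str] = field(
        default_factory=lambda: ["sex", "batch", "lab_batch"]
    )
    trait_covariates: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [t for t in self.traits if t not in self.data.columns]
        if missing:
            raise ParseError(f"traits absent from table: {missing}")
        present_cov = [c for c in self.covariate_names if c in self.data.columns]
        self.covariate_names = present_cov
        for c in present_cov:
            if self.data[c].isna().any():
                raise ParseError(f"incomplete covariate assignment in {c!r}")
        if not self.trait_covariates:
            self.trait_covariates = default_covariate_map(
                self.traits, available=present_cov
            )

    @property
    def individual_ids(self) -> list[str]:
        return list(self.data.index.astype(str))

    def covariates_for(self, trait: str) -> pd.DataFrame:
        cols = self.trait_covariates.get(trait, self.covariate_names)
        return self.data[cols]


def default_covariate_map(
    traits: Iterable[str], available: Iterable[str] | None = None
) -> dict[str, list[str]]:
    """Sex + batch for every trait; phagocytosis traits use the lab batch.

    Phagocytosis assays are processed in two laboratory runs per rearing
    batch, hence their own 12-level factor.
    """
    avail = set(available) if available is not None else {"sex", "batch", "lab_batch"}
    out: dict[str, list[str]] = {}
    for t in traits:
        batch_factor = "lab_batch" if "PHAGO" in t.upper() else "batch"
        cols = [c for c in ("sex", batch_factor) if c in avail]
        out[t] = cols
    return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_genotypes(
    path: str | Path, format_hint: str | None = None, transpose: bool = False
) -> GenotypeMatrix:
    """Read a dosage TSV (individuals x SNPs) or a VCF of biallelic SNVs.

    VCF genotypes are converted to alt-allele dosage; multi-allelic records
    are skipped with a warning and counted in ``metadata['skipped_multiallelic']``.
    """
    path = Path(path)
    fmt = format_hint
    if fmt is None:
        fmt = "vcf" if path.suffix in (".vcf", ".bcf") or str(path).endswith(
            ".vcf.gz"
        ) else "tsv"
    if fmt == "vcf":
        return _read_genotypes_vcf(path)
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", "NaN", ""])
    if transpose:
        df = df.T
    try:
        arr = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        arr = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
        bad = np.isnan(arr) & df.notna().to_numpy()
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"malformed dosage {df.iat[i, j]!r} at individual "
            f"{df.index[i]!r}, SNP {df.columns[j]!r}"
        ) from None
    valid = np.isnan(arr) | np.isin(arr, (0.0, 1.0, 2.0))
    if not valid.all():
        i, j = np.argwhere(~valid)[0]
        raise ParseError(
            f"malformed dosage {arr[i, j]!r} at individual "
            f"{df.index[i]!r}, SNP {df.columns[j]!r}"
        )
    return GenotypeMatrix(
        individual_ids=[str(i) for i in df.index],
        snp_ids=[str(c) for c in df.columns],
        dosages=arr,
    )


def _read_genotypes_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids: list[str] = []
    rows: list[np.ndarray] = []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            skipped += 1
            logger.warning("skipping multi-allelic record %s:%s", var.CHROM, var.POS)
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(var.gt_types, dtype=float)
        dos = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        rows.append(dos)
        snp_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
    vcf.close()
    dosages = np.array(rows).T if rows else np.empty((len(samples), 0))
    return GenotypeMatrix(
        individual_ids=samples,
        snp_ids=snp_ids,
        dosages=dosages,
        metadata={"skipped_multiallelic": skipped},
    )


def write_genotypes(g: GenotypeMatrix, path: str | Path) -> None:
    # keep integer appearance for non-missing entries
    d = g.dosages
    txt = np.where(np.isnan(d), "NA", d.astype(np.int64, copy=False).astype(str))
    out = pd.DataFrame(txt, index=g.individual_ids, columns=g.snp_ids)
    out.index.name = "individual"
    out.to_csv(path, sep="\t")


def read_counts(
    path: str | Path,
    taxonomy: Mapping[str, str] | str | Path | None = None,
    level: str = "asv",
    transpose: bool = False,
) -> AbundanceTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if transpose:
        df = df.T
    counts = df.to_numpy()
    if not np.issubdtype(counts.dtype, np.number):
        raise ParseError(f"non-numeric entries in count table {path}")
    tax = None
    if taxonomy is not None:
        tax = (
            dict(taxonomy)
            if isinstance(taxonomy, Mapping)
            else read_taxonomy(taxonomy)
        )
    return AbundanceTable(
        sample_ids=[str(i) for i in df.index],
        feature_ids=[str(c) for c in df.columns],
        counts=counts.astype(np.int64),
        level=level,
        taxonomy=tax,
    )


def write_counts(a: AbundanceTable, path: str | Path) -> None:
    df = a.to_frame()
    df.index.name = "sample"
    df.to_csv(path, sep="\t")


def read_taxonomy(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=0, dtype=str).fillna("")
    if df.shape[1] < 2:
        raise ParseError("taxonomy file needs two columns: feature_id, genus")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_taxonomy(taxonomy: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"feature_id": list(taxonomy), "genus": list(taxonomy.values())}
    ).to_csv(path, sep="\t", index=False)


def read_phenotypes(
    path: str | Path, config: str | Path | Mapping | None = None
) -> PhenotypeTable:
    """Read a phenotype/covariate TSV.

    ``config`` (YAML path or mapping) may declare ``traits``, ``covariates``
    and a ``trait_covariates`` map; without it, columns named sex/batch/
    lab_batch are treated as covariates and every other column as a trait.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    cfg: dict = {}
    if config is not None:
        if isinstance(config, Mapping):
            cfg = dict(config)
        else:
            with open(config) as fh:
                cfg = yaml.safe_load(fh) or {}
    covariates = cfg.get("covariates", ["sex", "batch", "lab_batch"])
    covariates = [c for c in covariates if c in df.columns]
    traits = cfg.get("traits") or [c for c in df.columns if c not in covariates]
    for c in covariates:
        df[c] = df[c].astype(str)
    return PhenotypeTable(
        data=df,
        traits=list(traits),
        covariate_names=covariates,
        trait_covariates=cfg.get("trait_covariates", {}),
    )


def write_phenotypes(p: PhenotypeTable, path: str | Path) -> None:
    out = p.data.copy()
    out.index.name = "individual"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------


def snp_qc(
    g: GenotypeMatrix, maf_min: float = 0.05, miss_max: float = 0.10
) -> GenotypeMatrix:
    """Drop SNPs with minor-allele frequency < ``maf_min`` or missing-call
    rate > ``miss_max``. Missing dosages in surviving SNPs are retained.

    The removal report is stored in ``metadata['qc_report']`` with one count
    per criterion (a SNP failing both is counted under both).
    """
    maf = g.allele_freq
    miss = g.missing_rate
    fail_maf = np.isnan(maf) | (maf < maf_min)
    fail_miss = miss > miss_max
    keep = ~(fail_maf | fail_miss)
    if not keep.any():
        raise QCError("SNP QC removed every SNP")
    report = {
        "input_snps": g.n_snps,
        "removed_maf": int(fail_maf.sum()),
        "removed_missing": int(fail_miss.sum()),
        "removed_total": int((~keep).sum()),
        "retained": int(keep.sum()),
        "maf_min": maf_min,
        "miss_max": miss_max,
    }
    return GenotypeMatrix(
        individual_ids=list(g.individual_ids),
        snp_ids=[s for s, k in zip(g.snp_ids, keep) if k],
        dosages=g.dosages[:, keep],
        metadata={**g.metadata, "qc_report": report},
    )


def filter_microbiome(
    a: AbundanceTable,
    min_reads: int = 10_000,
    min_prevalence: int = 3,
    min_total_frac: float = 1e-5,
    mode: str = "independent",
) -> AbundanceTable:
    """Sample read-depth filter followed by the ASV prevalence/abundance filter.

    Samples with fewer than ``min_reads`` total reads are dropped first; the
    grand total used for the abundance fraction is computed afterwards. In the
    default ``independent`` mode an ASV is kept only when it is present in at
    least ``min_prevalence`` samples AND carries at least ``min_total_frac``
    of the grand total. The ``literal_and`` mode instead discards only ASVs
    failing both criteria simultaneously.
    """
    if a.level != "asv":
        raise ValueError("microbiome filtering operates on ASV-level tables")
    if mode not in ("independent", "literal_and"):
        raise ValueError(f"unknown filter mode {mode!r}")
    depth = a.counts.sum(axis=1)
    keep_s = depth >= min_reads
    if not keep_s.any():
        raise QCError("read-depth filter removed every sample")
    counts = a.counts[keep_s, :]
    grand_total = counts.sum()
    prevalence = (counts > 0).sum(axis=0)
    frac = counts.sum(axis=0) / grand_total
    ok_prev = prevalence >= min_prevalence
    ok_frac = frac >= min_total_frac
    if mode == "independent":
        keep_f = ok_prev & ok_frac
    else:  # literal_and: discard only when both criteria fail
        keep_f = ok_prev | ok_frac
    if not keep_f.any():
        raise QCError("feature filter removed every ASV")
    report = {
        "input_samples": a.n_samples,
        "removed_samples": int((~keep_s).sum()),
        "input_features": a.n_features,
        "removed_low_prevalence": int((~ok_prev).sum()),
        "removed_low_abundance": int((~ok_frac).sum()),
        "removed_features": int((~keep_f).sum()),
        "retained_samples": int(keep_s.sum()),
        "retained_features": int(keep_f.sum()),
        "mode": mode,
        "min_reads": min_reads,
        "min_prevalence": min_prevalence,
        "min_total_frac": min_total_frac,
    }
    tax = None
    if a.taxonomy is not None:
        tax = {
            f: a.taxonomy.get(f, "")
            for f, k in zip(a.feature_ids, keep_f)
            if k
        }
    return AbundanceTable(
        sample_ids=[s for s, k in zip(a.sample_ids, keep_s) if k],
        feature_ids=[f for f, k in zip(a.feature_ids, keep_f) if k],
        counts=counts[:, keep_f],
        level="asv",
        taxonomy=tax,
        metadata={**a.metadata, "filter_report": report},
    )


def aggregate_to_genus(a: AbundanceTable) -> AbundanceTable:
    """Sum ASV counts per genus per sample.

    ASVs lacking a genus assignment are pooled into an ``unclassified``
    feature, which downstream association and network steps exclude by
    default. Per-sample totals restricted to classified ASVs are preserved.
    """
    if a.taxonomy is None:
        raise ValueError("genus aggregation requires a taxonomy map")
    labels = []
    for f in a.feature_ids:
        genus = (a.taxonomy.get(f) or "").strip()
        labels.append(genus if genus else UNCLASSIFIED)
    genera = sorted(set(labels) - {UNCLASSIFIED})
    if UNCLASSIFIED in labels:
        genera = genera + [UNCLASSIFIED]
    idx = {g: k for k, g in enumerate(genera)}
    out = np.zeros((a.n_samples, len(genera)), dtype=a.counts.dtype)
    for j, lab in enumerate(labels):
        out[:, idx[lab]] += a.counts[:, j]
    return AbundanceTable(
        sample_ids=list(a.sample_ids),
        feature_ids=genera,
        counts=out,
        level="genus",
        taxonomy=None,
        metadata=dict(a.metadata),
    )


# ---------------------------------------------------------------------------
# descriptive statistics
# ---------------------------------------------------------------------------


def describe_traits(p: PhenotypeTable) -> pd.DataFrame:
    """Mean, sample SD and coefficient of variation (CV = SD/mean) per trait.

    Missing values are dropped per trait. The CV is flagged undefined (NaN,
    ``cv_defined`` False) when the mean is not positive; a constant trait
    yields CV = 0 with a warning.
    """
    rows = []
    for t in p.traits:
        v = pd.to_numeric(p.data[t], errors="coerce").dropna().to_numpy(float)
        if v.size < 2:
            raise ValueError(f"trait {t!r} has fewer than 2 non-missing values")
        mean = float(v.mean())
        sd = float(v.std(ddof=1))
        if sd == 0.0:
            warnings.warn(f"trait {t!r} is constant; CV set to 0", stacklevel=2)
        if mean > 0:
            cv, defined = sd / mean, True
        else:
            cv, defined = np.nan, False
        rows.append(
            {"trait": t, "n": int(v.size), "mean": mean, "sd": sd, "cv": cv,
             "cv_defined": defined}
        )
    return pd.DataFrame(rows).set_index("trait")
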