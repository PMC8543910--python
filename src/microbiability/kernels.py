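"""Compositional transforms and relationship-matrix construction.

Two kernels drive the variance partition:

* genomic relationship matrix ``G = S S' / (2 Σ_j p_j (1 - p_j))`` where S
  holds dosages centred at twice the minor-allele frequency (VanRaden
  method 1);
* microbial relationship matrix ``B = M M' / n`` where M holds cumulative-
  sum-scaling (CSS) normalized ASV abundances, column-centred and scaled to
  unit sample variance, and n is the number of retained ASV columns.

The centred log-ratio (clr) transform feeds the trait-microbe correlation
network; CSS feeds B. The CSS reference quantile is configurable (default:
median of each sample's positive counts) because the adaptive percentile of
metagenomeSeq is data-dependent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio.stats.composition import clr as _skbio_clr

from .io_qc import AbundanceTable, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "TransformedAbundances",
    "RelationshipMatrix",
    "css_normalize",
    "relative_abundance",
    "clr_transform",
    "compute_G",
    "compute_B",
    "write_kernel",
    "read_kernel",
]


@dataclass
class TransformedAbundances:
    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    transform: str  # {"css", "css_scaled", "relative", "clr"}
    params: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_ids
        )


@dataclass
class RelationshipMatrix:
    """Symmetric positive semi-definite similarity kernel over individuals."""

    individual_ids: list[str]
    values: np.ndarray
    kind: str  # {"genomic", "microbial"}
    denom: float
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.individual_ids)
        if self.values.shape != (n, n):
            raise ValueError("kernel shape does not match individual ids")

    def validate(self, sym_tol: float = 1e-10, eig_tol: float = 1e-8) -> None:
        """Check symmetry and positive semi-definiteness up to tolerance.

        Eigenvalues in (-eig_tol, 0) are treated as numerical zeros; anything
        more negative is a hard error.
        """
        if not np.allclose(self.values, self.values.T, atol=sym_tol):
            raise ValueError(f"{self.kind} kernel is not symmetric")
        scale = max(1.0, float(np.abs(self.values).max()))
        w = np.linalg.eigvalsh(self.values)
        if w.min() < -eig_tol * scale:
            raise ValueError(
                f"{self.kind} kernel has eigenvalue {w.min():.3e} below tolerance"
            )

    def subset(self, idx: np.ndarray) -> "RelationshipMatrix":
        ids = [self.individual_ids[i] for i in idx]
        return RelationshipMatrix(
            individual_ids=ids,
            values=self.values[np.ix_(idx, idx)],
            kind=self.kind,
            denom=self.denom,
            dropped=list(self.dropped),
        )


# ---------------------------------------------------------------------------
# compositional transforms
# ---------------------------------------------------------------------------


def css_normalize(
    a: AbundanceTable, quantile: float = 0.5, scale: float = 1000.0
) -> TransformedAbundances:
    """Cumulative sum scaling: divide each sample's counts by the cumulative
    count up to its ``quantile``-th positive-count quantile, times ``scale``.
    """
    counts = np.asarray(a.counts, dtype=float)
    values = np.empty_like(counts)
    for i in range(counts.shape[0]):
        row = counts[i]
        pos = row[row > 0]
        if pos.size == 0:
            raise ValueError(f"sample {a.sample_ids[i]!r} has all-zero counts")
        q = np.quantile(pos, quantile)
        s = row[row <= q].sum()
        values[i] = row / s * scale
    return TransformedAbundances(
        sample_ids=list(a.sample_ids),
        feature_ids=list(a.feature_ids),
        values=values,
        transform="css",
        params={"quantile": quantile, "scale": scale},
    )


def relative_abundance(a: AbundanceTable) -> TransformedAbundances:
    totals = a.counts.sum(axis=1, keepdims=True).astype(float)
    if np.any(totals == 0):
        raise ValueError("sample with all-zero counts")
    return TransformedAbundances(
        sample_ids=list(a.sample_ids),
        feature_ids=list(a.feature_ids),
        values=a.counts / totals,
        transform="relative",
        params={},
    )


def clr_transform(
    a: AbundanceTable, pseudocount: float = 1.0
) -> TransformedAbundances:
    """Centred log-ratio transform of counts + pseudocount; rows sum to zero."""
    comp = np.asarray(a.counts, dtype=float) + pseudocount
    if np.any(comp <= 0):
        raise ValueError("pseudocount must make every entry positive")
    values = _skbio_clr(comp)
    return TransformedAbundances(
        sample_ids=list(a.sample_ids),
        feature_ids=list(a.feature_ids),
        values=values,
        transform="clr",
        params={"pseudocount": pseudocount},
    )


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------


def compute_G(g: GenotypeMatrix) -> RelationshipMatrix:
    """Genomic relationship matrix from QC'd dosages.

    Missing dosages are mean-imputed per SNP. Dosages are re-polarized so the
    counted allele is the minor one (the kernel is invariant to the flip; the
    convention standardizes the recorded frequencies). Monomorphic SNPs are
    excluded from both the matrix and the denominator with a warning.
    """
    D = np.array(g.dosages, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(D, axis=0)
    nan_mask = np.isnan(D)
    D[nan_mask] = np.take(col_mean, np.where(nan_mask)[1])
    p_alt = col_mean / 2.0
    flip = p_alt > 0.5
    D[:, flip] = 2.0 - D[:, flip]
    p = np.where(flip, 1.0 - p_alt, p_alt)
    mono = (p <= 0.0) | np.isnan(p)
    dropped = [s for s, m in zip(g.snp_ids, mono) if m]
    if dropped:
        warnings.warn(
            f"excluding {len(dropped)} monomorphic SNP(s) from G", stacklevel=2
        )
        D = D[:, ~mono]
        p = p[~mono]
    if p.size == 0:
        raise ValueError("no polymorphic SNPs left for G")
    S = D - 2.0 * p
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    values = (S @ S.T) / denom
    values = (values + values.T) / 2.0
    return RelationshipMatrix(
        individual_ids=list(g.individual_ids),
        values=values,
        kind="genomic",
        denom=denom,
        dropped=dropped,
    )


def compute_B(t: TransformedAbundances) -> RelationshipMatrix:
    """Microbial relationship matrix B = M M' / n from CSS-normalized
    abundances, after column centring and unit-sample-variance scaling.

    Zero-variance columns are dropped with a warning and n (the feature
    count in the denominator) reduced accordingly.
    """
    if t.transform != "css":
        raise ValueError("compute_B expects CSS-normalized abundances")
    V = np.asarray(t.values, dtype=float)
    sd = V.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [f for f, k in zip(t.feature_ids, keep) if not k]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} zero-variance column(s) from B", stacklevel=2
        )
    if keep.sum() < 2:
        raise ValueError("fewer than 2 variable features for B")
    M = (V[:, keep] - V[:, keep].mean(axis=0)) / sd[keep]
    n_feat = int(keep.sum())
    values = (M @ M.T) / n_feat
    values = (values + values.T) / 2.0
    return RelationshipMatrix(
        individual_ids=list(t.sample_ids),
        values=values,
        kind="microbial",
        denom=float(n_feat),
        dropped=dropped,
    )


def write_kernel(k: RelationshipMatrix, path) -> None:
    df = pd.DataFrame(k.values, index=k.individual_ids, columns=k.individual_ids)
    df.index.name = "individual"
    df.to_csv(path, sep="\t")


def read_kernel(path, kind: str = "genomic") -> RelationshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return RelationshipMatrix(
        individual_ids=[str(i) for i in df.index],
        values=df.to_numpy(float),
        kind=kind,
        denom=float("nan"),
    )
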