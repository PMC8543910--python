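"""PCIT correlation filtering and bipartite trait-microbe network building.

PCIT (partial correlation with information theory) decides which pairwise
Pearson correlations are significant without a distributional test: for
every ordered trio (x, y, z) the three first-order partial correlations

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))

are combined into a trio tolerance

    eps = (1/3) (|r_xy.z / r_xy| + |r_xz.y / r_xz| + |r_yz.x / r_yz|),

and the pair (x, y) is eliminated in that trio's context when

    |r_xy| < |eps * r_xz|  and  |r_xy| < |eps * r_yz|.

A pair is significant iff no third variable eliminates it. Ratio terms with
a near-zero direct correlation (|r| below a guard) are skipped and the
average taken over the remaining terms; a trio whose every term is skipped
eliminates nothing.

The network step keeps only significant pairs joining one immune trait and
one genus (trait-trait and genus-genus links are discarded), mirroring how
the bipartite trait-microbe graph is reported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .kernels import TransformedAbundances
from .varpart import build_design

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationSet",
    "TraitMicrobeNetwork",
    "build_correlation_set",
    "pcit",
    "build_network",
    "overlap_with_mwas",
]


@dataclass
class CorrelationSet:
    variable_ids: list[str]
    roles: dict[str, str]  # variable -> {"trait", "genus"}
    R: np.ndarray
    n_samples: int
    min_pair_n: int
    dropped: list[str] = field(default_factory=list)


@dataclass
class TraitMicrobeNetwork:
    graph: nx.Graph
    edges: pd.DataFrame  # trait, genus, r, sign, confirmed_by_mwas
    keystone_trait: str | None
    keystone_genus: str | None

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degrees(self) -> pd.DataFrame:
        rows = [
            {"node": n, "role": d["role"], "degree": deg}
            for (n, d), (_, deg) in zip(
                self.graph.nodes(data=True), self.graph.degree()
            )
        ]
        return pd.DataFrame(rows)


def _residualize(traits: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """OLS residuals of each trait on the covariate dummies, keeping NaNs."""
    X, _ = build_design(covariates)
    out = {}
    for t in traits.columns:
        y = pd.to_numeric(traits[t], errors="coerce").to_numpy(float)
        keep = ~np.isnan(y)
        res = np.full_like(y, np.nan)
        if keep.sum() > X.shape[1]:
            coef, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
            res[keep] = y[keep] - X[keep] @ coef
        out[t] = res
    return pd.DataFrame(out, index=traits.index)


def build_correlation_set(
    traits: pd.DataFrame,
    genus_clr: TransformedAbundances | pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> CorrelationSet:
    """Pairwise Pearson correlations over traits and clr-genus columns.

    When ``covariates`` is given, traits are first residualized on the
    covariate factors (sex + batch) so the correlations are not driven by
    shared fixed effects. Missing trait values are handled pairwise-complete;
    the minimum shared n over pairs is recorded. Zero-variance variables are
    excluded with a warning.
    """
    if isinstance(genus_clr, TransformedAbundances):
        gdf = genus_clr.to_frame()
    else:
        gdf = genus_clr.copy()
    if list(gdf.index.astype(str)) != list(traits.index.astype(str)):
        raise ValueError("trait and genus tables disagree on samples")
    tdf = traits.apply(pd.to_numeric, errors="coerce")
    if covariates is not None:
        tdf = _residualize(tdf, covariates)

    roles = {str(c): "trait" for c in tdf.columns}
    roles.update({str(c): "genus" for c in gdf.columns})
    df = pd.concat(
        [tdf.reset_index(drop=True), gdf.reset_index(drop=True)], axis=1
    )
    df.columns = [str(c) for c in df.columns]

    sd = df.std(ddof=1)
    dropped = [c for c in df.columns if not sd[c] > 0]
    if dropped:
        warnings.warn(f"excluding zero-variance variables: {dropped}", stacklevel=2)
        df = df.drop(columns=dropped)
        for c in dropped:
            roles.pop(c, None)

    R = df.corr(method="pearson").to_numpy(float)
    np.fill_diagonal(R, 1.0)
    R = np.clip(R, -1.0, 1.0)
    notna = df.notna().to_numpy()
    pair_n = notna.T.astype(int) @ notna.astype(int)
    return CorrelationSet(
        variable_ids=list(df.columns),
        roles={c: roles[c] for c in df.columns},
        R=R,
        n_samples=df.shape[0],
        min_pair_n=int(pair_n.min()),
        dropped=dropped,
    )


def pcit(R: np.ndarray, guard: float = 1e-9) -> np.ndarray:
    """Boolean significance mask over pairs (diagonal False).

    Vectorized over the conditioning variable: the full array of first-order
    partial correlations is materialized once (n^3 memory — fine up to a few
    hundred variables).
    """
    R = np.asarray(R, dtype=float)
    n = R.shape[0]
    if R.shape != (n, n):
        raise ValueError("R must be square")
    if n < 3:
        raise ValueError("PCIT needs at least 3 variables")
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("R must be symmetric")
    off = ~np.eye(n, dtype=bool)
    bad = off & (np.abs(R) >= 1.0 - 1e-12)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"degenerate correlation |r|=1 between variables {i} and {j}"
        )

    absR = np.abs(R)
    # P[z, x, y] = partial correlation of (x, y) given z
    P = np.empty((n, n, n))
    for z in range(n):
        rz = R[:, z]
        denom = np.sqrt(np.outer(1.0 - rz**2, 1.0 - rz**2))
        with np.errstate(divide="ignore", invalid="ignore"):
            P[z] = (R - np.outer(rz, rz)) / denom

    significant = off.copy()
    eye = np.eye(n, dtype=bool)
    for z in range(n):
        Sz = np.abs(P[:, :, z])  # Sz[a, b] = |r_{b z . a}|
        rz = absR[:, z]
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.abs(P[z]) / absR          # |r_xy.z| / |r_xy|
            t2 = Sz.T / rz[:, None]           # |r_xz.y| / |r_xz|, denom per x
            t3 = Sz / rz[None, :]             # |r_yz.x| / |r_yz|, denom per y
        t1 = np.where(absR >= guard, t1, np.nan)
        t2 = np.where(rz[:, None] >= guard, t2, np.nan)
        t3 = np.where(rz[None, :] >= guard, t3, np.nan)
        terms = np.stack([t1, t2, t3])
        cnt = np.sum(~np.isnan(terms), axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            eps = np.nanmean(terms, axis=0)
        elim = (
            (absR < eps * rz[:, None])
            & (absR < eps * rz[None, :])
            & (cnt > 0)
        )
        # trios must be three distinct variables
        elim[z, :] = False
        elim[:, z] = False
        elim[eye] = False
        significant &= ~elim
    return significant


def build_network(
    mask: np.ndarray,
    R: np.ndarray,
    roles: dict[str, str] | list[str],
    variable_ids: list[str] | None = None,
    mwas_pairs: set[tuple[str, str]] | None = None,
) -> TraitMicrobeNetwork:
    """Bipartite network from PCIT-significant trait-genus pairs.

    ``roles`` maps variable -> role, or is a list aligned with
    ``variable_ids``. Keystone nodes are the highest-degree trait and genus
    (lexicographic tie-break). An empty network is a valid result.
    """
    if variable_ids is None:
        variable_ids = list(roles)  # dict preserves order
    if not isinstance(roles, dict):
        roles = dict(zip(variable_ids, roles))
    n = len(variable_ids)
    g = nx.Graph()
    for v in variable_ids:
        g.add_node(v, role=roles[v])
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            if not mask[i, j]:
                continue
            a, b = variable_ids[i], variable_ids[j]
            ra, rb = roles[a], roles[b]
            if {ra, rb} != {"trait", "genus"}:
                continue
            trait, genus = (a, b) if ra == "trait" else (b, a)
            r = float(R[i, j])
            confirmed = (
                (trait, genus) in mwas_pairs if mwas_pairs is not None else False
            )
            g.add_edge(trait, genus, r=r, sign=int(np.sign(r)),
                       confirmed_by_mwas=confirmed)
            rows.append(
                {"trait": trait, "genus": genus, "r": r,
                 "sign": int(np.sign(r)), "confirmed_by_mwas": confirmed}
            )
    edges = pd.DataFrame(
        rows, columns=["trait", "genus", "r", "sign", "confirmed_by_mwas"]
    )
    if edges.empty:
        warnings.warn("PCIT network is empty", stacklevel=2)

    def _keystone(role: str) -> str | None:
        deg = sorted(
            (
                (-d, v)
                for v, d in g.degree()
                if roles[v] == role and d > 0
            )
        )
        return deg[0][1] if deg else None

    return TraitMicrobeNetwork(
        graph=g,
        edges=edges,
        keystone_trait=_keystone("trait"),
        keystone_genus=_keystone("genus"),
    )


def overlap_with_mwas(
    network: TraitMicrobeNetwork, mwas_results: pd.DataFrame
) -> dict:
    """Fraction of MWAS associations confirmed by the network.

    ``mwas_results`` is the Bayes-factor table; only rows passing the BF
    threshold count as MWAS associations. Returns counts, the percentage,
    and the per-association confirmation table.
    """
    hits = mwas_results[mwas_results["passes_threshold"]]
    mwas_pairs = {(str(t), str(g)) for t, g in zip(hits["trait"], hits["taxon"])}
    net_pairs = {
        (str(t), str(g))
        for t, g in zip(network.edges["trait"], network.edges["genus"])
    }
    confirmed = sorted(mwas_pairs & net_pairs)
    per_assoc = pd.DataFrame(
        [
            {"trait": t, "genus": g, "confirmed": (t, g) in net_pairs}
            for t, g in sorted(mwas_pairs)
        ],
        columns=["trait", "genus", "confirmed"],
    )
    n_mwas = len(mwas_pairs)
    pct = 100.0 * len(confirmed) / n_mwas if n_mwas else float("nan")
    return {
        "n_mwas": n_mwas,
        "n_network": len(net_pairs),
        "n_confirmed": len(confirmed),
        "pct_confirmed": pct,
        "confirmed_pairs": confirmed,
        "per_association": per_assoc,
    }
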