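"""Two-kernel Bayesian mixed model and h2/m2 posterior summaries.

The model for each trait is

    y = X beta + u + m + e,
    u ~ N(0, G sigma2_u),  m ~ N(0, B sigma2_m),  e ~ N(0, I sigma2_e),

with X the fixed-effect design (intercept, sex, batch or laboratory batch).
Heritability and microbiability are posterior functionals of the variance
components,

    h2 = sigma2_u / (sigma2_u + sigma2_m + sigma2_e),
    m2 = sigma2_m / (sigma2_u + sigma2_m + sigma2_e),

computed per Gibbs draw and then averaged (mean of per-draw ratios; the
ratio of posterior-mean variances is reported alongside).

Implementation: each kernel K is eigendecomposed once, K = U D U', and the
random effect rewritten as independent ridge coefficients on the columns of
U D^{1/2}. Because those columns are mutually orthogonal the coefficient
block has a diagonal full-conditional covariance, giving O(n^2) per-iteration
cost after a one-off O(n^3) decomposition. Variances get scaled-inverse-
chi-square full conditionals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .io_qc import PhenotypeTable
from .kernels import RelationshipMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "MixedModelSpec",
    "PriorSpec",
    "PosteriorChain",
    "VariancePartition",
    "build_model_spec",
    "fit_two_kernel_model",
    "summarize_partition",
    "run_all_traits",
    "geweke_z",
]


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------


@dataclass
class MixedModelSpec:
    trait: str
    y: np.ndarray
    X: np.ndarray
    kernels: list[tuple[RelationshipMatrix, str]]  # e.g. [(G, "u"), (B, "m")]
    x_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        n = self.y.size
        if self.X.shape[0] != n:
            raise ValueError("X and y disagree on record count")
        for k, _ in self.kernels:
            if k.values.shape[0] != n:
                raise ValueError("kernel dimension does not match y")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("fixed-effect design X is rank deficient")


@dataclass
class PriorSpec:
    """Scaled-inverse-chi-square priors for every variance component.

    Scales are derived from the phenotypic variance via an R-squared split:
    the prior mode of component k equals ``r2[k] * var(y)`` (mode of a
    scaled-inv-chi2(nu, S) is nu S / (nu + 2)).
    """

    nu: float = 5.0
    r2: dict[str, float] = field(
        default_factory=lambda: {"u": 0.25, "m": 0.25, "e": 0.5}
    )

    def scales(self, var_y: float, labels: list[str]) -> dict[str, float]:
        out = {}
        for lab in labels + ["e"]:
            r2 = self.r2.get(lab, 0.25)
            out[lab] = r2 * var_y * (self.nu + 2.0) / self.nu
        return out


@dataclass
class PosteriorChain:
    """Retained Gibbs draws of fixed effects and variance components."""

    trait: str
    labels: list[str]
    variance_draws: dict[str, np.ndarray]  # labels + "e" -> draws
    beta_draws: np.ndarray  # draws x n_fixed
    effect_means: dict[str, np.ndarray]  # posterior mean of u, m (per label)
    iterations: int
    burn_in: int
    thin: int
    seed: int
    n_obs: int

    @property
    def n_draws(self) -> int:
        return self.beta_draws.shape[0]


@dataclass
class VariancePartition:
    trait: str
    h2_mean: float
    m2_mean: float
    e2_mean: float
    h2_sd: float
    m2_sd: float
    h2_ci: tuple[float, float]
    m2_ci: tuple[float, float]
    prob_h2_gt: dict[float, float]
    prob_m2_gt: dict[float, float]
    h2_ratio_of_means: float
    m2_ratio_of_means: float
    geweke: dict[str, float]
    n_obs: int
    n_draws: int


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


def build_design(cov: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Intercept + drop-first dummy encoding of the covariate factors."""
    n = cov.shape[0]
    blocks = [np.ones((n, 1))]
    names = ["intercept"]
    for c in cov.columns:
        d = pd.get_dummies(cov[c].astype(str), prefix=c, drop_first=True)
        blocks.append(d.to_numpy(float))
        names.extend(d.columns)
    X = np.hstack(blocks)
    return X, names


def build_model_spec(
    phenotypes: PhenotypeTable,
    trait: str,
    G: RelationshipMatrix,
    B: RelationshipMatrix | None = None,
) -> MixedModelSpec:
    """Align phenotype records with the kernels and assemble the fixed design.

    Individuals with a missing trait value are dropped casewise, with the
    kernel rows/columns subset to match.
    """
    ids = phenotypes.individual_ids
    if list(G.individual_ids) != ids or (
        B is not None and list(B.individual_ids) != ids
    ):
        raise ValueError("kernel individual ids do not match phenotype table")
    y = pd.to_numeric(phenotypes.data[trait], errors="coerce").to_numpy(float)
    keep = ~np.isnan(y)
    idx = np.where(keep)[0]
    cov = phenotypes.covariates_for(trait).iloc[idx]
    X, names = build_design(cov)
    kernels: list[tuple[RelationshipMatrix, str]] = [(G.subset(idx), "u")]
    if B is not None:
        kernels.append((B.subset(idx), "m"))
    return MixedModelSpec(
        trait=trait, y=y[idx], X=X, kernels=kernels, x_names=names
    )


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------


def _kernel_basis(
    k: RelationshipMatrix, eig_tol: float = 1e-8, rank_tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecompose a kernel into an orthogonal ridge basis.

    Returns (Phi, d) with Phi = U D^{1/2} restricted to eigenvalues above
    ``rank_tol`` times the largest; Phi' Phi = diag(d). Small negative
    eigenvalues within ``eig_tol`` are clipped to zero, anything more
    negative raises.
    """
    w, U = np.linalg.eigh(k.values)
    scale = max(1.0, float(w.max()) if w.size else 1.0)
    if w.min() < -eig_tol * scale:
        raise ValueError(
            f"{k.kind} kernel is not PSD (min eigenvalue {w.min():.3e})"
        )
    w = np.clip(w, 0.0, None)
    keep = w > rank_tol * scale
    d = w[keep]
    Phi = U[:, keep] * np.sqrt(d)
    return Phi, d


def fit_two_kernel_model(
    spec: MixedModelSpec,
    prior: PriorSpec | None = None,
    iterations: int = 30_000,
    burn_in: int = 3_000,
    thin: int = 1,
    seed: int = 0,
    fix_variances: dict[str, float] | None = None,
) -> PosteriorChain:
    """Gibbs sampler for the multi-kernel Bayesian ridge model.

    ``fix_variances`` pins named components (labels or ``"e"``) at given
    values instead of sampling them — useful for closed-form cross-checks.
    """
    prior = prior or PriorSpec()
    fix_variances = fix_variances or {}
    rng = np.random.default_rng(seed)
    y = spec.y
    n = y.size
    X = spec.X
    labels = [lab for _, lab in spec.kernels]
    var_y = float(np.var(y, ddof=1))
    S = prior.scales(var_y, labels)
    nu = prior.nu

    bases = {}
    for k, lab in spec.kernels:
        Phi, d = _kernel_basis(k)
        bases[lab] = (Phi, d)

    XtX = X.T @ X
    cF = cho_factor(XtX)
    L = np.linalg.cholesky(XtX)

    # state
    beta = cho_solve(cF, X.T @ y)
    coef = {lab: np.zeros(bases[lab][1].size) for lab in labels}
    sigma2 = {lab: fix_variances.get(lab, S[lab] * nu / (nu + 2.0)) for lab in labels}
    sigma2["e"] = fix_variances.get("e", S["e"] * nu / (nu + 2.0))

    fitted = {lab: np.zeros(n) for lab in labels}  # Phi @ coef per label
    n_ret = (iterations - burn_in) // thin
    if n_ret <= 0:
        raise ValueError("no retained draws: check iterations/burn_in/thin")
    var_draws = {lab: np.empty(n_ret) for lab in labels + ["e"]}
    beta_draws = np.empty((n_ret, X.shape[1]))
    effect_sums = {lab: np.zeros(n) for lab in labels}

    t = 0
    for it in range(iterations):
        # fixed effects
        r = y - sum(fitted.values())
        mean_b = cho_solve(cF, X.T @ r)
        z = rng.standard_normal(X.shape[1])
        beta = mean_b + np.sqrt(sigma2["e"]) * solve_triangular(
            L.T, z, lower=False
        )
        xb = X @ beta

        # random-effect coefficient blocks (orthogonal columns per block)
        for lab in labels:
            Phi, d = bases[lab]
            r = y - xb - sum(fitted[o] for o in labels if o != lab)
            prec = d / sigma2["e"] + 1.0 / sigma2[lab]
            mean_c = (Phi.T @ r) / sigma2["e"] / prec
            coef[lab] = mean_c + rng.standard_normal(d.size) / np.sqrt(prec)
            fitted[lab] = Phi @ coef[lab]

        # variance components
        resid = y - xb - sum(fitted.values())
        if "e" not in fix_variances:
            sigma2["e"] = (nu * S["e"] + resid @ resid) / rng.chisquare(nu + n)
        for lab in labels:
            if lab in fix_variances:
                continue
            c = coef[lab]
            sigma2[lab] = (nu * S[lab] + c @ c) / rng.chisquare(nu + c.size)

        if it >= burn_in and (it - burn_in) % thin == 0 and t < n_ret:
            for lab in labels + ["e"]:
                var_draws[lab][t] = sigma2[lab]
            beta_draws[t] = beta
            for lab in labels:
                effect_sums[lab] += fitted[lab]
            t += 1

    effect_means = {lab: effect_sums[lab] / n_ret for lab in labels}
    return PosteriorChain(
        trait=spec.trait,
        labels=labels,
        variance_draws=var_draws,
        beta_draws=beta_draws,
        effect_means=effect_means,
        iterations=iterations,
        burn_in=burn_in,
        thin=thin,
        seed=seed,
        n_obs=n,
    )


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------


def _batch_means_var(x: np.ndarray, n_batches: int = 20) -> float:
    """Autocorrelation-consistent variance of the segment mean (batch means)."""
    n = x.size
    if n < 4:
        return float(np.var(x, ddof=1) / n) if n > 1 else 0.0
    n_batches = max(2, min(n_batches, n // 2))
    m = n // n_batches
    batches = x[: m * n_batches].reshape(n_batches, m).mean(axis=1)
    return float(batches.var(ddof=1) / n_batches)


def geweke_z(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late chain means.

    Standard errors use batch means, which absorb the chain's
    autocorrelation without a spectral-density fit.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    a = x[: max(2, int(first * n))]
    b = x[int((1.0 - last) * n):]
    se = np.sqrt(_batch_means_var(a) + _batch_means_var(b))
    if se == 0:
        return 0.0
    return float((a.mean() - b.mean()) / se)


def summarize_partition(
    chain: PosteriorChain, thresholds: tuple[float, ...] = (0.1,)
) -> VariancePartition:
    """Posterior means of per-draw h2/m2 ratios plus threshold probabilities.

    Per draw t: h2_t = s2u_t / (s2u_t + s2m_t + s2e_t) and analogously m2_t,
    so h2_t + m2_t + e2_t = 1 exactly. A model fitted without the microbial
    kernel reports m2 = 0.
    """
    su = chain.variance_draws.get("u")
    sm = chain.variance_draws.get("m")
    se = chain.variance_draws["e"]
    if su is None:
        su = np.zeros_like(se)
    if sm is None:
        sm = np.zeros_like(se)
    tot = su + sm + se
    h2 = su / tot
    m2 = sm / tot
    e2 = se / tot
    return VariancePartition(
        trait=chain.trait,
        h2_mean=float(h2.mean()),
        m2_mean=float(m2.mean()),
        e2_mean=float(e2.mean()),
        h2_sd=float(h2.std(ddof=1)) if h2.size > 1 else 0.0,
        m2_sd=float(m2.std(ddof=1)) if m2.size > 1 else 0.0,
        h2_ci=(float(np.quantile(h2, 0.025)), float(np.quantile(h2, 0.975))),
        m2_ci=(float(np.quantile(m2, 0.025)), float(np.quantile(m2, 0.975))),
        prob_h2_gt={th: float((h2 > th).mean()) for th in thresholds},
        prob_m2_gt={th: float((m2 > th).mean()) for th in thresholds},
        h2_ratio_of_means=float(su.mean() / tot.mean()),
        m2_ratio_of_means=float(sm.mean() / tot.mean()),
        geweke={
            lab: geweke_z(chain.variance_draws[lab])
            for lab in chain.variance_draws
        },
        n_obs=chain.n_obs,
        n_draws=int(h2.size),
    )


def run_all_traits(
    phenotypes: PhenotypeTable,
    G: RelationshipMatrix,
    B: RelationshipMatrix,
    prior: PriorSpec | None = None,
    iterations: int = 30_000,
    burn_in: int = 3_000,
    thin: int = 1,
    seed: int = 0,
    thresholds: tuple[float, ...] = (0.1,),
    min_records: int = 50,
) -> pd.DataFrame:
    """Fit the two-kernel model per trait and return a tidy partition table.

    Traits with fewer than ``min_records`` complete records are skipped with
    a warning. Each trait's chain uses a distinct stream derived from
    ``seed``.
    """
    rows = []
    for i, trait in enumerate(phenotypes.traits):
        n_complete = int(
            pd.to_numeric(phenotypes.data[trait], errors="coerce").notna().sum()
        )
        if n_complete < min_records:
            warnings.warn(
                f"skipping trait {trait!r}: only {n_complete} complete records",
                stacklevel=2,
            )
            continue
        spec = build_model_spec(phenotypes, trait, G, B)
        chain = fit_two_kernel_model(
            spec, prior, iterations, burn_in, thin, seed=seed + i
        )
        vp = summarize_partition(chain, thresholds)
        row = {
            "trait": trait,
            "n": vp.n_obs,
            "h2": vp.h2_mean,
            "h2_sd": vp.h2_sd,
            "h2_ci_low": vp.h2_ci[0],
            "h2_ci_high": vp.h2_ci[1],
            "m2": vp.m2_mean,
            "m2_sd": vp.m2_sd,
            "m2_ci_low": vp.m2_ci[0],
            "m2_ci_high": vp.m2_ci[1],
            "e2": vp.e2_mean,
        }
        for th in thresholds:
            row[f"prob_h2_gt_{th}"] = vp.prob_h2_gt[th]
            row[f"prob_m2_gt_{th}"] = vp.prob_m2_gt[th]
        rows.append(row)
    return pd.DataFrame(rows)
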