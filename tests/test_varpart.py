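"""Gibbs sampler correctness, posterior summaries and per-trait driver."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import invgamma

from microbiability import (
    PriorSpec,
    RelationshipMatrix,
    build_model_spec,
    compute_B,
    compute_G,
    css_normalize,
    fit_two_kernel_model,
    run_all_traits,
    summarize_partition,
)
from microbiability.varpart import MixedModelSpec, PosteriorChain, geweke_z


def _identity_kernel(n, kind="genomic"):
    return RelationshipMatrix(
        [f"i{k}" for k in range(n)], np.eye(n), kind=kind, denom=1.0
    )


def _chain_from_draws(su, sm, se):
    su, sm, se = (np.asarray(x, float) for x in (su, sm, se))
    return PosteriorChain(
        trait="t",
        labels=["u", "m"],
        variance_draws={"u": su, "m": sm, "e": se},
        beta_draws=np.zeros((su.size, 1)),
        effect_means={},
        iterations=su.size,
        burn_in=0,
        thin=1,
        seed=0,
        n_obs=10,
    )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def test_constant_chain_exact_ratios():
    vp = summarize_partition(_chain_from_draws([2, 2], [1, 1], [1, 1]))
    assert vp.h2_mean == pytest.approx(0.5)
    assert vp.m2_mean == pytest.approx(0.25)
    assert vp.e2_mean == pytest.approx(0.25)


def test_prob_threshold_boundary():
    vp = summarize_partition(_chain_from_draws([1, 2, 3], [1, 1, 1], [1, 1, 1]))
    assert vp.prob_h2_gt[0.1] == 1.0


def test_mean_of_ratios_not_ratio_of_means(rng):
    # on a skewed chain the two estimators differ; the reported value must
    # equal the brute-force mean of per-draw ratios
    su = rng.lognormal(0.0, 1.2, size=500)
    sm = rng.lognormal(-0.5, 0.8, size=500)
    se = rng.lognormal(0.2, 0.5, size=500)
    vp = summarize_partition(_chain_from_draws(su, sm, se))
    brute = np.mean([a / (a + b + c) for a, b, c in zip(su, sm, se)])
    assert vp.h2_mean == pytest.approx(brute, abs=1e-12)
    assert vp.h2_mean != pytest.approx(vp.h2_ratio_of_means, abs=1e-3)


def test_per_draw_fractions_sum_to_one(rng):
    vp = summarize_partition(
        _chain_from_draws(rng.gamma(2, size=50), rng.gamma(2, size=50),
                          rng.gamma(2, size=50))
    )
    assert vp.h2_mean + vp.m2_mean + vp.e2_mean == pytest.approx(1.0, abs=1e-10)


# ---------------------------------------------------------------------------
# sampler correctness
# ---------------------------------------------------------------------------


def test_determinism_under_seed(rng):
    n = 40
    y = rng.standard_normal(n)
    spec = MixedModelSpec(
        trait="t", y=y, X=np.ones((n, 1)), kernels=[(_identity_kernel(n), "u")]
    )
    c1 = fit_two_kernel_model(spec, iterations=200, burn_in=50, seed=7)
    c2 = fit_two_kernel_model(spec, iterations=200, burn_in=50, seed=7)
    np.testing.assert_array_equal(c1.variance_draws["u"], c2.variance_draws["u"])
    np.testing.assert_array_equal(c1.beta_draws, c2.beta_draws)


def test_posterior_effect_mean_matches_henderson_blup(rng):
    # fixed variances, G = I: the joint posterior mean of (beta, u) solves
    # Henderson's mixed-model equations; the Gibbs average must match it
    n = 60
    u_true = rng.standard_normal(n)
    y = 2.0 + u_true + 0.5 * rng.standard_normal(n)
    X = np.ones((n, 1))
    s2u, s2e = 1.0, 0.25
    spec = MixedModelSpec(
        trait="t", y=y, X=X, kernels=[(_identity_kernel(n), "u")]
    )
    chain = fit_two_kernel_model(
        spec, iterations=30_000, burn_in=2_000, seed=3,
        fix_variances={"u": s2u, "e": s2e},
    )
    lam = s2e / s2u
    top = np.hstack([X.T @ X, X.T])
    bottom = np.hstack([X, np.eye(n) + lam * np.eye(n)])
    lhs = np.vstack([top, bottom])
    rhs = np.concatenate([X.T @ y, y])
    sol = np.linalg.solve(lhs, rhs)
    u_blup = sol[1:]
    np.testing.assert_allclose(chain.effect_means["u"], u_blup, atol=0.06)


def test_variance_posterior_matches_numerical_integration(rng):
    # one-kernel model, intercept projected out: the exact posterior of
    # (s2u, s2e) factorizes over kernel eigenvalues and can be integrated
    # on a grid; the Gibbs h2 posterior mean must agree
    n = 80
    A = rng.standard_normal((n, 30))
    K = A @ A.T / 30
    K = K / np.diag(K).mean()
    kern = RelationshipMatrix([f"i{k}" for k in range(n)], K, "genomic", 1.0)
    w, U = np.linalg.eigh(K)
    y = U @ (np.sqrt(np.clip(w, 0, None) * 0.5) * rng.standard_normal(n))
    y = y + rng.standard_normal(n) * np.sqrt(0.5) + 1.0

    nu = 5.0
    vy = np.var(y, ddof=1)
    Su = 0.25 * vy * (nu + 2) / nu
    Se = 0.5 * vy * (nu + 2) / nu
    # orthonormal basis of the intercept's complement (QR of centred identity):
    # all n-1 contrast eigenvalues are kept, including the kernel's null space
    Q, _ = np.linalg.qr(np.eye(n) - np.ones((n, n)) / n)
    T = Q[:, : n - 1]
    w2, U2 = np.linalg.eigh(T.T @ K @ T)
    wk = np.clip(w2, 0.0, None)
    yt = U2.T @ (T.T @ y)

    def logpost(a, b):
        v = a * wk + b
        ll = -0.5 * np.sum(np.log(v) + yt**2 / v)
        lp = invgamma.logpdf(a, nu / 2, scale=nu * Su / 2)
        lp += invgamma.logpdf(b, nu / 2, scale=nu * Se / 2)
        return ll + lp

    gs = np.linspace(1e-3, 4.0 * vy, 250)
    L = np.array([[logpost(a, b) for b in gs] for a in gs])
    P = np.exp(L - L.max())
    P /= P.sum()
    A2, B2 = np.meshgrid(gs, gs, indexing="ij")
    h2_oracle = float((P * (A2 / (A2 + B2))).sum())

    spec = MixedModelSpec(
        trait="t", y=y, X=np.ones((n, 1)), kernels=[(kern, "u")]
    )
    chain = fit_two_kernel_model(spec, iterations=30_000, burn_in=3_000, seed=11)
    vp = summarize_partition(chain)
    assert vp.h2_mean == pytest.approx(h2_oracle, abs=0.02)


def test_permutation_equivariance_of_summaries(small_cohort, rng):
    # permuting individuals (y and kernels together) leaves the posterior
    # unchanged; summaries agree within Monte-Carlo error
    G = compute_G(small_cohort.genotypes)
    B = compute_B(css_normalize(small_cohort.microbiome))
    spec = build_model_spec(small_cohort.phenotypes, "T1", G, B)
    vp = summarize_partition(
        fit_two_kernel_model(spec, iterations=8_000, burn_in=1_000, seed=1)
    )
    perm = rng.permutation(small_cohort.config.n_individuals)
    phen_p = small_cohort.phenotypes
    data_p = phen_p.data.iloc[perm]
    from microbiability import PhenotypeTable

    phen2 = PhenotypeTable(
        data=data_p, traits=phen_p.traits,
        covariate_names=phen_p.covariate_names,
    )
    Gp = G.subset(perm)
    Bp = B.subset(perm)
    spec2 = build_model_spec(phen2, "T1", Gp, Bp)
    vp2 = summarize_partition(
        fit_two_kernel_model(spec2, iterations=8_000, burn_in=1_000, seed=1)
    )
    assert vp2.h2_mean == pytest.approx(vp.h2_mean, abs=0.03)
    assert vp2.m2_mean == pytest.approx(vp.m2_mean, abs=0.03)


def test_missing_phenotypes_dropped_with_kernel_subsetting(small_cohort):
    G = compute_G(small_cohort.genotypes)
    B = compute_B(css_normalize(small_cohort.microbiome))
    phen = small_cohort.phenotypes
    data = phen.data.copy()
    data.loc[data.index[:10], "T1"] = np.nan
    from microbiability import PhenotypeTable

    phen2 = PhenotypeTable(data=data, traits=phen.traits,
                           covariate_names=phen.covariate_names)
    spec = build_model_spec(phen2, "T1", G, B)
    assert spec.y.size == small_cohort.config.n_individuals - 10
    assert spec.kernels[0][0].values.shape == (spec.y.size, spec.y.size)
    chain = fit_two_kernel_model(spec, iterations=300, burn_in=100, seed=0)
    assert chain.n_obs == spec.y.size


def test_non_psd_kernel_rejected(rng):
    n = 10
    K = -np.eye(n)
    kern = RelationshipMatrix([f"i{k}" for k in range(n)], K, "genomic", 1.0)
    spec = MixedModelSpec(
        trait="t", y=rng.standard_normal(n), X=np.ones((n, 1)),
        kernels=[(kern, "u")],
    )
    with pytest.raises(ValueError, match="PSD"):
        fit_two_kernel_model(spec, iterations=10, burn_in=1, seed=0)


def test_geweke_within_bounds_on_stationary_chain(small_cohort):
    G = compute_G(small_cohort.genotypes)
    B = compute_B(css_normalize(small_cohort.microbiome))
    spec = build_model_spec(small_cohort.phenotypes, "T2", G, B)
    chain = fit_two_kernel_model(spec, iterations=12_000, burn_in=2_000, seed=2)
    vp = summarize_partition(chain)
    for lab, z in vp.geweke.items():
        assert abs(z) < 3.0, f"{lab}: {z}"


# ---------------------------------------------------------------------------
# per-trait driver
# ---------------------------------------------------------------------------


def test_run_all_traits_consistent_rows(small_cohort):
    G = compute_G(small_cohort.genotypes)
    B = compute_B(css_normalize(small_cohort.microbiome))
    out = run_all_traits(
        small_cohort.phenotypes, G, B, iterations=1_500, burn_in=500, seed=0
    )
    assert list(out["trait"]) == small_cohort.phenotypes.traits
    np.testing.assert_allclose(out["h2"] + out["m2"] + out["e2"], 1.0, atol=1e-10)
    assert ((out["h2"] >= 0) & (out["h2"] <= 1)).all()


def test_run_all_traits_skips_sparse_trait(small_cohort):
    G = compute_G(small_cohort.genotypes)
    B = compute_B(css_normalize(small_cohort.microbiome))
    phen = small_cohort.phenotypes
    data = phen.data.copy()
    data["sparse"] = np.nan
    data.loc[data.index[:20], "sparse"] = 1.0
    from microbiability import PhenotypeTable

    phen2 = PhenotypeTable(data=data, traits=phen.traits + ["sparse"],
                           covariate_names=phen.covariate_names)
    with pytest.warns(UserWarning, match="skipping trait 'sparse'"):
        out = run_all_traits(
            phen2, G, B, iterations=400, burn_in=100, seed=0, min_records=50
        )
    assert "sparse" not in set(out["trait"])


def test_prior_scales_follow_r2_split():
    p = PriorSpec(nu=5.0)
    s = p.scales(2.0, ["u", "m"])
    # prior mode nu*S/(nu+2) must equal r2 * var(y)
    assert s["u"] * 5 / 7 == pytest.approx(0.25 * 2.0)
    assert s["e"] * 5 / 7 == pytest.approx(0.5 * 2.0)
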