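"""Null model fitting and Burden/SKAT score statistics."""

import numpy as np
import pytest
from scipy import special, stats

import rarecausal as rc
from rarecausal.assoc import pvalue_mixture_chisq

from conftest import balanced_phenotype, make_genotypes


def test_intercept_only_null_models():
    pheno = balanced_phenotype(40)
    null = rc.fit_null(pheno)
    np.testing.assert_allclose(null.mu_hat, 0.5, atol=1e-8)
    assert abs(null.residuals.sum()) < 1e-8

    y = np.array([1.2, 0.8, 1.5, 0.5])
    cont = rc.PhenotypeTable(
        y=y, trait_type="continuous", sample_ids=[f"s{i}" for i in range(4)]
    )
    null_c = rc.fit_null(cont)
    np.testing.assert_allclose(null_c.mu_hat, y.mean(), atol=1e-12)


def test_logistic_null_matches_irls_oracle():
    """GLM fit agrees with an independently coded IRLS to 1e-8."""
    rng = np.random.default_rng(4)
    n = 300
    x = rng.integers(0, 2, n).astype(float)
    eta = -0.4 + 0.9 * x
    y = (rng.random(n) < special.expit(eta)).astype(float)
    pheno = rc.PhenotypeTable(
        y=y, trait_type="dichotomous", sample_ids=[f"s{i}" for i in range(n)],
        covariates=x,
    )
    null = rc.fit_null(pheno)

    # hand-rolled IRLS
    X = np.column_stack([np.ones(n), x])
    beta = np.zeros(2)
    for _ in range(50):
        mu = special.expit(X @ beta)
        W = mu * (1 - mu)
        step = np.linalg.solve((X.T * W) @ X, X.T @ (y - mu))
        beta = beta + step
        if np.abs(step).max() < 1e-12:
            break
    np.testing.assert_allclose(null.mu_hat, special.expit(X @ beta), atol=1e-8)


def test_perfect_separation_raises():
    x = np.array([0.0, 0, 0, 0, 1, 1, 1, 1])
    pheno = rc.PhenotypeTable(
        y=x.copy(), trait_type="dichotomous",
        sample_ids=[f"s{i}" for i in range(8)], covariates=x,
    )
    with pytest.raises(rc.assoc.AssocError, match="separation"):
        rc.fit_null(pheno)


def _null_from_residuals(residuals):
    """NullModel with prescribed residuals (logit link, mu = y - resid)."""
    resid = np.asarray(residuals, dtype=float)
    mu = np.full(len(resid), 0.5)
    null = rc.NullModel(
        mu_hat=mu, residuals=resid, link="logit",
        X=np.ones((len(resid), 1)), dispersion=1.0,
    )
    return null


def test_score_statistic_direct_arithmetic_oracle():
    """G=[[1,0],[0,1],[1,1]], resid=(0.5,-0.5,0.25): S=(0.75,-0.25),
    Q_burden=0.25, Q_skat=0.625 (independent matrix arithmetic)."""
    G = make_genotypes([[1, 0], [0, 1], [1, 1]])
    null = _null_from_residuals([0.5, -0.5, 0.25])
    S = G.dosages.T @ null.residuals
    np.testing.assert_allclose(S, [0.75, -0.25])
    qb = rc.score_statistic(G, null, rc.ScoreTestConfig(rho=1.0)).Q
    qs = rc.score_statistic(G, null, rc.ScoreTestConfig(rho=0.0)).Q
    assert qb == pytest.approx(0.25)
    assert qs == pytest.approx(0.625)


def test_single_variant_burden_equals_skat():
    rng = np.random.default_rng(1)
    G = make_genotypes(rng.integers(0, 3, (30, 1)))
    null = _null_from_residuals(rng.normal(0, 0.5, 30))
    rb = rc.score_statistic(G, null, rc.ScoreTestConfig(rho=1.0))
    rs = rc.score_statistic(G, null, rc.ScoreTestConfig(rho=0.0))
    S1 = float(G.dosages[:, 0] @ null.residuals)
    assert rb.Q == pytest.approx(S1**2)
    assert rs.Q == pytest.approx(S1**2)
    assert rb.pvalue == pytest.approx(rs.pvalue, rel=1e-10)


def test_zero_residuals_give_q_zero_p_one():
    G = make_genotypes([[1, 0], [0, 1], [2, 1], [0, 0]])
    null = _null_from_residuals([0.0, 0.0, 0.0, 0.0])
    for rho in (0.0, 0.5, 1.0):
        res = rc.score_statistic(G, null, rc.ScoreTestConfig(rho=rho))
        assert res.Q == 0.0
        assert res.pvalue == 1.0


def test_single_eigenvalue_is_exact_chi_square():
    lam = np.array([2.5])
    for Q in (0.1, 1.0, 7.3):
        expected = stats.chi2.sf(Q / 2.5, 1)
        for method in ("moment_match", "davies"):
            assert pvalue_mixture_chisq(Q, lam, method) == pytest.approx(
                expected, rel=1e-6
            )
    assert pvalue_mixture_chisq(0.0, lam) == 1.0


def test_pvalue_invariant_to_variant_order():
    rng = np.random.default_rng(8)
    G = make_genotypes(rng.binomial(2, 0.1, (100, 6)))
    null = _null_from_residuals(rng.normal(0, 0.5, 100))
    perm = rng.permutation(6)
    for rho in (0.0, 1.0):
        p1 = rc.score_statistic(G, null, rc.ScoreTestConfig(rho=rho)).pvalue
        p2 = rc.score_statistic(G.subset(perm), null, rc.ScoreTestConfig(rho=rho)).pvalue
        assert p1 == pytest.approx(p2, rel=1e-9)


def test_all_zero_columns_dropped_with_warning():
    G = make_genotypes([[1, 0], [0, 0], [1, 0]])
    null = _null_from_residuals([0.4, -0.2, 0.1])
    with pytest.warns(UserWarning, match="all-zero"):
        res = rc.score_statistic(G, null)
    assert res.n_variants == 1


@pytest.mark.parametrize(
    "lam",
    [
        np.ones(10),
        np.array([5.0, 1.0, 0.5, 0.2, 0.1]),
        np.geomspace(1.0, 0.01, 20),
    ],
    ids=["flat", "dominant", "geometric"],
)
def test_moment_match_tracks_davies(lam):
    """Kurtosis-matched p-values track the exact inversion: <10% relative
    error for p >= 1e-3 and <20% down to 1e-4 (the far tail is where
    moment matching is known to degrade)."""
    for ptarget in (0.5, 0.05, 1e-3, 1e-4):
        lo, hi = 1e-9, 1e9
        for _ in range(100):
            mid = np.sqrt(lo * hi)
            if pvalue_mixture_chisq(mid, lam, "davies") > ptarget:
                lo = mid
            else:
                hi = mid
        Q = np.sqrt(lo * hi)
        p_davies = pvalue_mixture_chisq(Q, lam, "davies")
        p_liu = pvalue_mixture_chisq(Q, lam, "moment_match")
        tol = 0.10 if p_davies >= 1e-3 else 0.20
        assert abs(p_liu - p_davies) / p_davies < tol


def test_davies_matches_monte_carlo():
    rng = np.random.default_rng(0)
    lam = rng.uniform(0.1, 30, 40)
    sim = (lam * rng.chisquare(1, size=(100_000, 40))).sum(axis=1)
    for q_pct in (50, 95):
        q = np.percentile(sim, q_pct)
        p_mc = (sim >= q).mean()
        p = pvalue_mixture_chisq(q, lam, "davies")
        assert p == pytest.approx(p_mc, abs=3 * np.sqrt(p_mc * (1 - p_mc) / 100_000))


def test_analytic_pvalues_match_permutation_oracle():
    """Mixture-chi-square p-values agree with a 50,000-permutation null on an
    8-variant fixture, within 3 Monte-Carlo standard errors, for Burden and
    SKAT."""
    rng = np.random.default_rng(7)
    n = 2000  # the operating cohort size; the asymptotic null must hold here
    maf = rng.uniform(0.01, 0.05, 8)
    d = rng.binomial(2, maf, size=(n, 8)).astype(float)
    risk = special.expit(-0.2 + 0.25 * d[:, :4].sum(axis=1))
    y = (rng.random(n) < risk).astype(float)
    pheno = rc.PhenotypeTable(
        y=y, trait_type="dichotomous", sample_ids=[f"s{i}" for i in range(n)]
    )
    gm = make_genotypes(d)
    null = rc.fit_null(pheno)

    B = 50_000
    idx = np.argsort(rng.random((B, n)), axis=1)
    S_perm = null.residuals[idx] @ d
    for rho in (1.0, 0.0):
        res = rc.score_statistic(
            gm, null, rc.ScoreTestConfig(rho=rho, pvalue_method="davies")
        )
        Q_perm = S_perm.sum(axis=1) ** 2 if rho == 1.0 else (S_perm**2).sum(axis=1)
        p_perm = float((Q_perm >= res.Q).mean())
        se = np.sqrt(p_perm * (1 - p_perm) / B)
        assert abs(res.pvalue - p_perm) <= 3 * se


def test_type_one_error_is_nominal(small_pool):
    """Under the null (no causal variants) the fraction of p < 0.05 across
    2000 simulated cohorts is 0.05 within binomial error, for both tests."""
    region = rc.draw_region(small_pool, 12_000, seed=31)
    hap = region.haplotypes
    keep = hap.mean(axis=0) > 0  # polymorphic in pool
    hap = hap[:, keep]
    n = 200
    pheno = balanced_phenotype(n)
    null = rc.fit_null(pheno)
    rng = np.random.default_rng(33)
    hits = {"burden": 0, "skat": 0}
    n_rep = 2000
    for _ in range(n_rep):
        pairs = rng.integers(0, hap.shape[0], (n, 2))
        d = hap[pairs[:, 0]].astype(float) + hap[pairs[:, 1]].astype(float)
        poly = d.sum(axis=0) > 0
        gm = make_genotypes(d[:, poly])
        for name, rho in (("burden", 1.0), ("skat", 0.0)):
            p = rc.score_statistic(gm, null, rc.ScoreTestConfig(rho=rho)).pvalue
            hits[name] += p < 0.05
    se = np.sqrt(0.05 * 0.95 / n_rep)
    for name in ("burden", "skat"):
        assert abs(hits[name] / n_rep - 0.05) <= 3.5 * se


def test_beta_maf_weights_upweight_rarer_variants():
    w = rc.beta_maf_weights(np.array([0.001, 0.01, 0.05]))
    assert (np.diff(w) < 0).all()
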