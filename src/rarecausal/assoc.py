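"""Gene-level score tests: Burden, SKAT, and the exchangeable family between.

For trait ``y`` with null-model fitted means ``mu`` the per-variant score is
``S_j = sum_i G_ij (y_i - mu_i)``.  With non-negative weights ``w`` the family
indexed by ``rho`` in [0, 1] is

    Q_rho = rho * (sum_j w_j S_j)^2 + (1 - rho) * sum_j w_j^2 S_j^2

so ``rho = 1`` is the Burden statistic (one squared weighted sum, powerful for
unidirectional effects of similar size) and ``rho = 0`` is SKAT (a weighted sum
of squared scores, robust to mixed effect directions).  Under the null, S is
asymptotically N(0, Phi) with Phi = G' P0 G, where P0 is the GLM projection
V - V X (X' V X)^-1 X' V, so Q_rho follows a mixture of chi-square(1)
distributions whose weights are the eigenvalues of A^(1/2) Phi A^(1/2),
A = rho*ww' + (1-rho)*diag(w^2).  P-values come from moment matching (Liu-type,
default) or numerical characteristic-function inversion (Imhof/Davies).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genotype_io import GenotypeMatrix, PhenotypeTable


class AssocError(RuntimeError):
    pass


@dataclass
class NullModel:
    """GLM of the trait on covariates only (no genetic effect).

    ``mu_hat`` are fitted means, ``residuals = y - mu_hat``, ``X`` the
    covariate matrix including intercept, ``V`` the GLM variance diagonal
    (mu(1-mu) for logit, dispersion for identity).
    """

    mu_hat: np.ndarray
    residuals: np.ndarray
    link: str  # "identity" | "logit"
    X: np.ndarray
    dispersion: float
    V: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.link == "logit":
            self.V = self.mu_hat * (1.0 - self.mu_hat)
        else:
            self.V = np.full(len(self.mu_hat), self.dispersion)


@dataclass
class ScoreTestConfig:
    """Weights, family parameter and p-value method for a score test.

    Default weights are flat (w_j = 1); Beta(1, 25) density weights on the MAF
    are available via :func:`beta_maf_weights` for users who want the usual
    frequency up-weighting of rarer variants.
    """

    weights: np.ndarray | None = None
    rho: float = 1.0
    pvalue_method: str = "moment_match"  # or "davies"

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if self.pvalue_method not in ("moment_match", "davies"):
            raise ValueError(f"unknown pvalue_method {self.pvalue_method!r}")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if (self.weights < 0).any():
                raise ValueError("weights must be non-negative")


@dataclass
class ScoreTestResult:
    Q: float
    eigenvalues: np.ndarray
    pvalue: float
    method: str
    rho: float
    n_variants: int


def beta_maf_weights(maf: np.ndarray, a: float = 1.0, b: float = 25.0) -> np.ndarray:
    """Beta-density weights on MAF (the customary Beta(1,25) up-weighting)."""
    return stats.beta.pdf(np.asarray(maf, dtype=float), a, b)


# ---------------------------------------------------------------------------
# Null model
# ---------------------------------------------------------------------------

def fit_null(pheno: PhenotypeTable) -> NullModel:
    """Fit the covariate-only GLM (intercept always included).

    Dichotomous traits use a logit link, continuous traits the identity link
    with dispersion estimated from the null residuals.
    """
    import statsmodels.api as sm

    n = len(pheno.y)
    X = np.ones((n, 1))
    if pheno.covariates is not None:
        X = np.column_stack([X, pheno.covariates])
    if pheno.trait_type == "dichotomous":
        with warnings.catch_warnings():
            warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
            try:
                res = sm.GLM(pheno.y, X, family=sm.families.Binomial()).fit(maxiter=100)
            except (sm.tools.sm_exceptions.PerfectSeparationError,
                    sm.tools.sm_exceptions.PerfectSeparationWarning) as exc:
                raise AssocError(
                    "perfect separation in the null model; remove the offending covariate"
                ) from exc
        if not res.converged:
            raise AssocError("null model IRLS did not converge")
        mu = np.asarray(res.fittedvalues)
        return NullModel(mu_hat=mu, residuals=pheno.y - mu, link="logit", X=X, dispersion=1.0)
    res = sm.OLS(pheno.y, X).fit()
    mu = np.asarray(res.fittedvalues)
    resid = pheno.y - mu
    dof = max(n - X.shape[1], 1)
    return NullModel(
        mu_hat=mu,
        residuals=resid,
        link="identity",
        X=X,
        dispersion=float(resid @ resid / dof),
    )


# ---------------------------------------------------------------------------
# Score statistic and null spectrum
# ---------------------------------------------------------------------------

def _projected_covariance(Gd: np.ndarray, null: NullModel) -> np.ndarray:
    """Phi = G' P0 G with P0 = V - V X (X' V X)^-1 X' V."""
    V = null.V
    GV = Gd * V[:, None]
    XtVX = null.X.T @ (null.X * V[:, None])
    B = null.X.T @ GV  # (p, m)
    return Gd.T @ GV - B.T @ np.linalg.solve(XtVX, B)


def _mixture_eigenvalues(Phi: np.ndarray, w: np.ndarray, rho: float) -> np.ndarray:
    """Eigenvalues of A^(1/2) Phi A^(1/2), A = rho ww' + (1-rho) diag(w^2)."""
    if rho == 1.0:
        lam = np.array([float(w @ Phi @ w)])
    elif rho == 0.0:
        K = Phi * np.outer(w, w)
        lam = np.linalg.eigvalsh(K)
    else:
        A = rho * np.outer(w, w) + (1.0 - rho) * np.diag(w**2)
        ev, U = np.linalg.eigh(A)
        ev = np.clip(ev, 0.0, None)
        Ah = (U * np.sqrt(ev)) @ U.T
        lam = np.linalg.eigvalsh(Ah @ Phi @ Ah)
    if lam.size and lam.min() < -1e-8 * max(lam.max(), 1e-300):
        raise AssocError("negative eigenvalues in the null quadratic form")
    lam = np.clip(lam, 0.0, None)
    return lam[lam > 1e-12 * max(lam.max(), 1e-300)] if lam.size else lam


def score_statistic(
    G: GenotypeMatrix, null: NullModel, cfg: ScoreTestConfig | None = None
) -> ScoreTestResult:
    """Compute Q_rho and its mixture-of-chi-square p-value."""
    cfg = cfg or ScoreTestConfig()
    G = G.impute_missing()
    w = (
        np.ones(G.n_variants)
        if cfg.weights is None
        else np.asarray(cfg.weights, dtype=float)
    )
    if len(w) != G.n_variants:
        raise AssocError("weights length does not match variant count")
    keep = np.nan_to_num(G.dosages, nan=0.0).sum(axis=0) > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} all-zero genotype columns", stacklevel=2
        )
        G = G.subset(keep)
        w = w[keep]
    Gd = G.dosages
    m = Gd.shape[1]
    S = Gd.T @ null.residuals
    Q = float(cfg.rho * (w @ S) ** 2 + (1.0 - cfg.rho) * np.sum((w * S) ** 2))
    lam = _mixture_eigenvalues(_projected_covariance(Gd, null), w, cfg.rho)
    p = pvalue_mixture_chisq(Q, lam, cfg.pvalue_method)
    return ScoreTestResult(
        Q=Q, eigenvalues=lam, pvalue=p, method=cfg.pvalue_method,
        rho=cfg.rho, n_variants=m,
    )


# ---------------------------------------------------------------------------
# Mixture-of-chi-square tail probabilities
# ---------------------------------------------------------------------------

def _pvalue_liu(Q: float, lam: np.ndarray) -> float:
    """Liu-Tang-Zhang moment matching (mean, variance, skewness/kurtosis)."""
    c1 = lam.sum()
    c2 = np.sum(lam**2)
    c3 = np.sum(lam**3)
    c4 = np.sum(lam**4)
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2.0 * delta
    else:
        delta = 0.0
        df = 1.0 / s2
        a = np.sqrt(df)
    mu_x = df + delta
    sigma_x = np.sqrt(2.0) * a
    t_star = (Q - c1) / np.sqrt(2.0 * c2)
    x = t_star * sigma_x + mu_x
    return float(stats.ncx2.sf(x, df, delta) if delta > 0 else stats.chi2.sf(x, df))


def _pvalue_imhof(Q: float, lam: np.ndarray) -> float:
    """Imhof's exact characteristic-function inversion (Davies-type).

    The oscillatory integral is summed over segments of one oscillation period
    (the phase rate is bounded by (Q + sum lam)/2), stopping once the
    amplitude envelope 1/(u * rho(u)) times the segment length is negligible.
    """
    # far-tail handoff: beyond ~1e-14 the inversion integral is numerically
    # meaningless and the moment-matched tail is returned instead
    p_mm = _pvalue_liu(Q, lam)
    if p_mm < 1e-14:
        return p_mm

    def log_envelope(u: float) -> float:
        return -np.log(u) - 0.25 * np.sum(np.log1p((lam * u) ** 2))

    # one segment per oscillation period (phase rate <= (Q + sum lam)/2);
    # stop where the alternating-tail bound envelope*seg is negligible
    seg = 2.0 * np.pi / (0.5 * (float(lam.sum()) + Q))
    log_tol = np.log(1e-13) - np.log(seg)
    u_stop = seg
    while log_envelope(u_stop) > log_tol and u_stop < 1e9 * seg:
        u_stop *= 2.0
    n_seg = min(int(np.ceil(u_stop / seg)), 200_000)

    # vectorized composite 12-point Gauss-Legendre over all segments
    x, w = np.polynomial.legendre.leggauss(12)
    total = 0.0
    half = 0.5 * seg
    chunk = max(1, 200_000 // max(len(lam), 1))
    for start in range(0, n_seg, chunk):
        stop = min(start + chunk, n_seg)
        mids = (np.arange(start, stop) + 0.5) * seg
        U = (mids[:, None] + half * x[None, :]).ravel()
        lu = U[:, None] * lam[None, :]
        theta = 0.5 * (np.arctan(lu).sum(axis=1) - Q * U)
        log_rho = 0.25 * np.log1p(lu**2).sum(axis=1)
        vals = np.sin(theta) * np.exp(-log_rho) / U
        total += half * float((vals.reshape(stop - start, 12) @ w).sum())
    return float(0.5 + total / np.pi)


def pvalue_mixture_chisq(
    Q: float, eigenvalues: np.ndarray, method: str = "moment_match"
) -> float:
    """P(sum_l lambda_l chi2_1 > Q); clipped to (0, 1]."""
    lam = np.asarray(eigenvalues, dtype=float)
    lam = lam[lam > 0]
    if Q <= 0 or lam.size == 0:
        return 1.0
    if lam.size == 1:
        p = stats.chi2.sf(Q / lam[0], 1)
    elif method == "moment_match":
        p = _pvalue_liu(Q, lam)
    elif method == "davies":
        p = _pvalue_imhof(Q, lam)
    else:
        raise ValueError(f"unknown p-value method {method!r}")
    return float(min(max(p, np.finfo(float).tiny), 1.0))


# ---------------------------------------------------------------------------
# Cached subset testing (used heavily by backward elimination)
# ---------------------------------------------------------------------------

class SubsetScoreCache:
    """Precomputed scores and projected covariance for fast subset tests.

    The null model does not involve genotypes, so S = G'(y - mu) and
    Phi = G' P0 G are computed once; any subset's Burden statistic is then
    (w_A' S_A)^2 with a single null eigenvalue w_A' Phi_AA w_A, and SKAT needs
    only the eigenvalues of the subset block of W^(1/2) Phi W^(1/2).
    """

    def __init__(self, G: GenotypeMatrix, null: NullModel, weights: np.ndarray | None = None):
        G = G.impute_missing()
        self.variant_ids = list(G.variant_ids)
        Gd = np.nan_to_num(G.dosages, nan=0.0)
        self.m = Gd.shape[1]
        self.w = np.ones(self.m) if weights is None else np.asarray(weights, dtype=float)
        self.S = Gd.T @ null.residuals
        self.Phi = _projected_covariance(Gd, null)

    def burden_pvalue(self, idx: np.ndarray) -> float:
        wA = self.w[idx]
        T = float(wA @ self.S[idx])
        lam = float(wA @ self.Phi[np.ix_(idx, idx)] @ wA)
        if lam <= 0:
            return 1.0
        return pvalue_mixture_chisq(T * T, np.array([lam]))

    def skat_pvalue(self, idx: np.ndarray, method: str = "moment_match") -> float:
        wA = self.w[idx]
        Q = float(np.sum((wA * self.S[idx]) ** 2))
        K = self.Phi[np.ix_(idx, idx)] * np.outer(wA, wA)
        lam = np.clip(np.linalg.eigvalsh(K), 0.0, None)
        return pvalue_mixture_chisq(Q, lam, method)

    def pvalue(self, idx: np.ndarray, test: str = "burden", method: str = "moment_match") -> float:
        idx = np.asarray(idx, dtype=int)
        if test == "burden":
            return self.burden_pvalue(idx)
        if test == "skat":
            return self.skat_pvalue(idx, method)
        raise ValueError(f"unknown test {test!r}")
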