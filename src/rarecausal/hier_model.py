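"""Two-stage hierarchical model for per-variant effect estimation.

Stage one is the usual first-stage GLM relating the trait to genotypes and
confounders: logit P(y_i = 1) = alpha_0 + x_i' alpha + g_i' beta.  Stage two
models the per-variant log odds ratios through variant-level annotations:
beta = Z gamma + b, with Z the m x k matrix of variant covariates (intercept,
non-synonymous indicator, damaging flags, conservation scores, ...) and
b ~ N(0, tau^2 I) residual variant effects.  Substituting gives the
generalized linear mixed model

    logit P(y=1) = alpha_0 + X alpha + G Z gamma + G b,   b ~ N(0, tau^2 I).

Estimation is a hybrid of Bayesian and pseudo-likelihood steps: the variance
component tau^2 gets a grid posterior from a Laplace-approximated marginal
likelihood under a half-normal prior on tau, and with tau^2 fixed at its
posterior mean the fixed and random effects are estimated by a ridge-penalized
logistic fit (penalty 1/tau^2 on the b block), which coincides with penalized
quasi-likelihood at convergence for this model shape.  Sparse variants borrow
strength from their annotations (shrinkage toward Z gamma), while variants
with many carriers are dominated by their own carrier counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .genotype_io import AnnotationTable, GenotypeMatrix, PhenotypeTable

logger = logging.getLogger("rarecausal")


class HierModelError(RuntimeError):
    pass


@dataclass
class SecondStageSpec:
    """Variant-level covariate matrix Z (intercept always included)."""

    Z: np.ndarray  # (m, k)
    names: list[str]

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.ndim != 2 or self.Z.shape[1] != len(self.names):
            raise HierModelError("Z shape does not match covariate names")
        if np.isnan(self.Z).any():
            raise HierModelError("Z may not contain missing values (impute as 0)")

    @classmethod
    def from_annotations(
        cls,
        annotations: AnnotationTable,
        variant_ids: list[str],
        columns: list[str] | None = None,
        include_ns_indicator: bool = True,
    ) -> "SecondStageSpec":
        """Build Z = [1 | NS indicator | chosen score columns].

        Missing scores are imputed as 0 (the convention that synonymous /
        unscored variants carry a predictor value of 0).
        """
        m = len(variant_ids)
        blocks = [np.ones((m, 1))]
        names = ["intercept"]
        if include_ns_indicator:
            blocks.append(annotations.stratum(variant_ids).astype(float)[:, None])
            names.append("nonsynonymous")
        if columns:
            blocks.append(annotations.scores(columns, variant_ids))
            names.extend(columns)
        return cls(Z=np.column_stack(blocks), names=names)


@dataclass
class HMConfig:
    """Estimation settings.

    ``tau2_grid`` defaults to 40 geometrically spaced points in [1e-4, 4] on
    the log-OR variance scale; ``prior_scale`` is the scale of the half-normal
    prior on tau.  ``tau2_fixed`` skips stage A and fits at the given value
    (0 collapses the model to a common-effect fit given Z).
    """

    tau2_grid: np.ndarray | None = None
    prior_scale: float = 1.0
    max_iter: int = 200
    tol: float = 1e-8
    tau2_fixed: float | None = None
    seed: int | None = None

    def grid(self) -> np.ndarray:
        if self.tau2_grid is not None:
            return np.asarray(self.tau2_grid, dtype=float)
        return np.geomspace(1e-4, 4.0, 40)


@dataclass
class HierModelFit:
    variant_ids: list[str]
    gamma_hat: np.ndarray
    gamma_se: np.ndarray
    gamma_names: list[str]
    tau2_hat: float
    beta_hat: np.ndarray  # per-variant log OR = (Z gamma)_j + b_j
    se_beta: np.ndarray
    alpha_hat: np.ndarray  # intercept + confounder coefficients
    diagnostics: dict = field(default_factory=dict)

    @property
    def z_scores(self) -> np.ndarray:
        return self.beta_hat / self.se_beta


# ---------------------------------------------------------------------------
# Penalized GLM core
# ---------------------------------------------------------------------------

def _penalized_glm(
    D: np.ndarray,
    y: np.ndarray,
    pen: np.ndarray,
    link: str,
    max_iter: int,
    tol: float,
    theta0: np.ndarray | None = None,
    dispersion: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Newton fit of a ridge-penalized GLM.

    Maximizes loglik(theta) - 0.5 * theta' diag(pen) theta.  Returns the
    estimate, the unpenalized observed information A = D'WD (scaled by the
    dispersion for the identity link), and the unpenalized log-likelihood at
    the optimum (up to constants for the Gaussian case).
    """
    n, p = D.shape
    theta = np.zeros(p) if theta0 is None else theta0.copy()

    if link == "identity":
        A = D.T @ D / dispersion
        H = A + np.diag(pen)
        theta = np.linalg.solve(H, D.T @ y / dispersion)
        resid = y - D @ theta
        ll = -0.5 * float(resid @ resid) / dispersion
        return theta, A, ll

    def penloglik(th: np.ndarray) -> tuple[float, np.ndarray]:
        eta = D @ th
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        return ll - 0.5 * float(pen @ th**2), special.expit(eta)

    pll, mu = penloglik(theta)
    for _ in range(max_iter):
        W = mu * (1.0 - mu)
        grad = D.T @ (y - mu) - pen * theta
        H = (D.T * W) @ D
        H[np.diag_indices_from(H)] += pen + 1e-10
        step = np.linalg.solve(H, grad)
        # step halving on the penalized objective
        t = 1.0
        for _ in range(40):
            cand = theta + t * step
            pll_new, mu_new = penloglik(cand)
            if pll_new >= pll - 1e-12:
                break
            t *= 0.5
        theta, mu = cand, mu_new
        if abs(pll_new - pll) < tol * (abs(pll) + 1.0):
            pll = pll_new
            break
        pll = pll_new
    else:
        raise HierModelError(
            f"penalized fit did not converge in {max_iter} iterations "
            f"(last objective {pll:.6g})"
        )
    W = mu * (1.0 - mu)
    A = (D.T * W) @ D
    eta = D @ theta
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    return theta, A, ll


def _laplace_log_marginal(
    ll: float, b: np.ndarray, A: np.ndarray, n_fixed: int, tau2: float
) -> float:
    """Laplace approximation to log integral of L(y|b) N(b; 0, tau2 I) db.

    Fixed effects are profiled at the joint mode; the curvature of the b block
    is the Schur complement of the fixed-effect block so their estimation is
    accounted for.
    """
    m = len(b)
    A_ff = A[:n_fixed, :n_fixed]
    A_fb = A[:n_fixed, n_fixed:]
    A_bb = A[n_fixed:, n_fixed:]
    S = A_bb - A_fb.T @ np.linalg.solve(A_ff + 1e-10 * np.eye(n_fixed), A_fb)
    M = tau2 * S + np.eye(m)
    sign, logdet = np.linalg.slogdet(M)
    if sign <= 0:
        return -np.inf
    return ll - 0.5 * float(b @ b) / tau2 - 0.5 * logdet


def fit_hierarchical(
    G: GenotypeMatrix,
    pheno: PhenotypeTable,
    Z: SecondStageSpec,
    cfg: HMConfig | None = None,
) -> HierModelFit:
    """Fit the combined GLMM and return per-variant log ORs with SEs.

    Stage A evaluates the Laplace-approximated marginal likelihood of tau^2 on
    the grid, combines it with the half-normal prior on tau, and takes the
    posterior mean.  Stage B refits at that tau^2; the covariance of
    (alpha, gamma, b) comes from the inverse penalized information, and
    se(beta_j) propagates through beta_j = Z_j gamma + b_j.
    """
    cfg = cfg or HMConfig()
    G = G.impute_missing()
    Gd = np.nan_to_num(G.dosages, nan=0.0)
    n, m = Gd.shape
    if m < 2:
        raise HierModelError("need at least 2 variants")
    y = pheno.y
    link = "logit" if pheno.trait_type == "dichotomous" else "identity"
    if link == "identity":
        warnings.warn(
            "continuous-trait hierarchical fit is experimental", stacklevel=2
        )

    X = np.ones((n, 1))
    if pheno.covariates is not None:
        X = np.column_stack([X, pheno.covariates])
    p0 = X.shape[1]

    # drop constant Z columns beyond the intercept; require full column rank
    Zm = Z.Z
    keep = [0] + [
        j for j in range(1, Zm.shape[1]) if np.ptp(Zm[:, j]) > 0
    ]
    if len(keep) < Zm.shape[1]:
        logger.info("dropping %d constant second-stage columns", Zm.shape[1] - len(keep))
    Zm = Zm[:, keep]
    names = [Z.names[j] for j in keep]
    if np.linalg.matrix_rank(Zm) < Zm.shape[1]:
        raise HierModelError("second-stage covariates are collinear")
    k = Zm.shape[1]

    GZ = Gd @ Zm
    dispersion = 1.0
    if link == "identity":
        resid = y - y.mean()
        dispersion = float(resid @ resid / max(n - 1, 1))

    # --- Stage A: grid posterior for tau^2 --------------------------------
    if cfg.tau2_fixed is not None:
        tau2_hat = float(cfg.tau2_fixed)
        grid = None
        posterior = None
    else:
        grid = cfg.grid()
        D = np.column_stack([X, GZ, Gd])
        n_fixed = p0 + k
        logml = np.empty(len(grid))
        theta_ws = None
        for i, t2 in enumerate(grid):
            pen = np.concatenate([np.zeros(n_fixed), np.full(m, 1.0 / t2)])
            theta_ws, A, ll = _penalized_glm(
                D, y, pen, link, cfg.max_iter, cfg.tol, theta_ws, dispersion
            )
            logml[i] = _laplace_log_marginal(ll, theta_ws[n_fixed:], A, n_fixed, t2)
        tau = np.sqrt(grid)
        # half-normal prior on tau, transformed to the tau^2 scale
        log_prior = (
            -0.5 * (tau / cfg.prior_scale) ** 2 - np.log(2.0 * tau * cfg.prior_scale)
        )
        # trapezoid weights for the geometric grid
        dt = np.empty_like(grid)
        dt[1:-1] = (grid[2:] - grid[:-2]) / 2.0
        dt[0] = grid[1] - grid[0]
        dt[-1] = grid[-1] - grid[-2]
        logw = logml + log_prior + np.log(dt)
        logw -= logw.max()
        wpost = np.exp(logw)
        wpost /= wpost.sum()
        tau2_hat = float(wpost @ grid)
        posterior = wpost
        if int(np.argmax(logml)) == len(grid) - 1:
            warnings.warn(
                "tau^2 marginal likelihood peaks at the grid boundary; "
                "consider extending tau2_grid upward",
                stacklevel=2,
            )

    # --- Stage B: PQL fit at tau2_hat -------------------------------------
    if tau2_hat <= 0:
        D = np.column_stack([X, GZ])
        pen = np.zeros(p0 + k)
        theta, A, ll = _penalized_glm(
            D, y, pen, link, cfg.max_iter, cfg.tol, None, dispersion
        )
        b = np.zeros(m)
        Hinv = np.linalg.inv(A + np.diag(pen) + 1e-10 * np.eye(A.shape[0]))
        alpha = theta[:p0]
        gamma = theta[p0 : p0 + k]
        beta = Zm @ gamma
        # var(beta_j) = Z_j' Cov(gamma) Z_j
        Cg = Hinv[p0 : p0 + k, p0 : p0 + k]
        se_beta = np.sqrt(np.einsum("jk,kl,jl->j", Zm, Cg, Zm))
        gamma_se = np.sqrt(np.diag(Cg))
    else:
        D = np.column_stack([X, GZ, Gd])
        n_fixed = p0 + k
        pen = np.concatenate([np.zeros(n_fixed), np.full(m, 1.0 / tau2_hat)])
        theta, A, ll = _penalized_glm(
            D, y, pen, link, cfg.max_iter, cfg.tol, None, dispersion
        )
        H = A + np.diag(pen)
        Hinv = np.linalg.inv(H)
        alpha = theta[:p0]
        gamma = theta[p0:n_fixed]
        b = theta[n_fixed:]
        beta = Zm @ gamma + b
        # beta = M theta with M = [0 | Z | I]; se from M Hinv M'
        M = np.zeros((m, H.shape[0]))
        M[:, p0:n_fixed] = Zm
        M[:, n_fixed:] = np.eye(m)
        se_beta = np.sqrt(np.einsum("ij,jk,ik->i", M, Hinv, M))
        gamma_se = np.sqrt(np.diag(Hinv)[p0:n_fixed])

    if (se_beta <= 0).any():
        raise HierModelError("non-positive standard errors (singular information)")

    return HierModelFit(
        variant_ids=list(G.variant_ids),
        gamma_hat=gamma,
        gamma_se=gamma_se,
        gamma_names=names,
        tau2_hat=tau2_hat,
        beta_hat=beta,
        se_beta=se_beta,
        alpha_hat=alpha,
        diagnostics={
            "tau2_grid": None if grid is None else grid,
            "tau2_posterior": posterior,
            "loglik": ll,
            "link": link,
        },
    )


def rank_variants(
    fit: HierModelFit,
    subset: set[str] | None = None,
    by: str = "beta",
) -> list[str]:
    """Variant ids in descending order of effect (``beta``) or ``z`` score.

    Restricting to a subset (e.g. the backward-elimination selection)
    preserves the relative order of the retained variants; ties are broken by
    variant id for determinism.
    """
    if by == "beta":
        score = fit.beta_hat
    elif by == "z":
        score = fit.z_scores
    else:
        raise ValueError(f"unknown ranking key {by!r}")
    items = [
        (vid, s)
        for vid, s in zip(fit.variant_ids, score)
        if subset is None or vid in subset
    ]
    items.sort(key=lambda t: (-t[1], t[0]))
    return [vid for vid, _ in items]
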