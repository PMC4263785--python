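"""Two-component nonparametric mixture on return counts.

The sample of return counts from the resampling procedure typically shows a
bulk of low-count (null) variants and a right-tail group of high-count
(candidate causal) variants.  An EM algorithm with weighted kernel-density
component estimates separates the two without assuming parametric shapes; the
"interesting" label goes to the component with the larger mean return count.
When the sample shows no usable separation (as is common for the synonymous
stratum), selection falls back to the top-20%-of-return-counts rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .backward_elim import ReturnCountTable

logger = logging.getLogger("rarecausal")


@dataclass
class MixtureFit:
    mixing_proportions: np.ndarray  # (2,), sums to 1
    responsibilities: np.ndarray  # (n, 2), rows sum to 1; column 1 = interesting
    component_labels: np.ndarray  # (n,) str: "interesting" | "non_interesting"
    component_means: np.ndarray  # (2,)
    grid: np.ndarray
    component_densities: np.ndarray  # (2, len(grid))
    bandwidth: float
    iterations: int
    loglik_trace: list[float]
    separated: bool


def _silverman_bandwidth(x: np.ndarray) -> float:
    n = len(x)
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        spread = max(sd, 1e-3)
    return 0.9 * spread * n ** (-0.2)


def _two_means_split(x: np.ndarray) -> float:
    """Threshold of the exact 1-D 2-means partition (min within-cluster SS)."""
    xs = np.sort(x)
    n = len(xs)
    csum = np.cumsum(xs)
    css = np.cumsum(xs**2)
    k = np.arange(1, n)  # lower-cluster sizes
    lo_ss = css[:-1] - csum[:-1] ** 2 / k
    hi_ss = (css[-1] - css[:-1]) - (csum[-1] - csum[:-1]) ** 2 / (n - k)
    cut = int(np.argmin(lo_ss + hi_ss))
    return 0.5 * (xs[cut] + xs[cut + 1])


def fit_np_mixture(
    rc: np.ndarray,
    bandwidth: float | None = None,
    max_iter: int = 500,
    tol: float = 1e-4,
    seed: int | None = None,
) -> MixtureFit:
    """Classification EM for a two-component weighted-KDE mixture.

    Each iteration re-estimates the component kernel densities and mixing
    proportions from the current hard partition (M-step), then reassigns every
    observation to the component with maximal posterior responsibility
    (E-step); it stops when the partition is stable or the mixing proportions
    change by less than ``tol``.  The Gaussian bandwidth is Silverman's rule
    on the pooled sample and stays fixed across iterations.  Initialization is
    the deterministic 1-D 2-means partition, so ``seed`` is accepted only for
    interface symmetry.

    Hard assignments in the M-step are deliberate: a univariate nonparametric
    two-component mixture admits a degenerate fixed point where both component
    densities equal the pooled density (responsibilities -> mixing
    proportions), and the soft EM drifts into it however well it is
    initialized.  The classification variant has no such leakage path and its
    fixed points are stable partitions.
    """
    x = np.asarray(rc, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 observations to fit the mixture")
    if ((x < 0) | (x > 1)).any():
        raise ValueError("return counts must lie in [0, 1]")
    if np.ptp(x) == 0:  # degenerate: all equal -> no separation
        return _degenerate_fit(x)

    h = bandwidth if bandwidth is not None else _silverman_bandwidth(x)
    K = np.exp(-0.5 * ((x[:, None] - x[None, :]) / h) ** 2) / (h * np.sqrt(2 * np.pi))

    split = _two_means_split(x)
    z = np.column_stack([(x <= split).astype(float), (x > split).astype(float)])
    pi = z.mean(axis=0)
    r = z.copy()
    loglik_trace: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        # M-step from the hard partition
        denom = np.maximum(z.sum(axis=0), 1e-12)
        pi = z.mean(axis=0)
        f = K @ z / denom  # component KDEs at the sample points
        # E-step: responsibilities and reassignment
        num = f * pi
        total = np.maximum(num.sum(axis=1, keepdims=True), 1e-300)
        r = num / total
        loglik_trace.append(float(np.log(total).sum()))
        z_new = np.zeros_like(z)
        z_new[np.arange(n), np.argmax(r, axis=1)] = 1.0
        if (z_new == z).all():
            break
        delta = float(np.max(np.abs(z_new.mean(axis=0) - pi)))
        z = z_new
        if delta < tol:
            break

    means = np.array(
        [
            float(np.average(x, weights=np.maximum(z[:, c], 1e-12)))
            for c in range(2)
        ]
    )
    order = np.argsort(means)  # column 1 = larger-mean = interesting
    z = z[:, order]
    r = r[:, order]
    pi = z.mean(axis=0)
    means = means[order]
    labels = np.where(z[:, 1] == 1.0, "interesting", "non_interesting")

    grid = np.linspace(0.0, 1.0, 201)
    Kg = np.exp(-0.5 * ((grid[:, None] - x[None, :]) / h) ** 2) / (
        h * np.sqrt(2 * np.pi)
    )
    dens = (Kg @ z / np.maximum(z.sum(axis=0), 1e-12)).T

    pooled_sd = float(np.std(x, ddof=1))
    # no-separation checks: a vanishing component, component means closer
    # than one pooled SD, or no density valley between the component means
    # (a hard split of a unimodal sample still yields means ~1.6 SD apart,
    # so the mean gap alone cannot detect unimodality)
    pooled_dens = dens[0] * pi[0] + dens[1] * pi[1]
    between = (grid >= means[0]) & (grid <= means[1])
    at_means = np.interp(means, grid, pooled_dens)
    valley = float(pooled_dens[between].min()) if between.any() else float(at_means.min())
    has_valley = valley < 0.9 * at_means.min()
    separated = bool(
        pi.min() >= 0.02
        and abs(means[1] - means[0]) >= pooled_sd > 0
        and has_valley
    )
    return MixtureFit(
        mixing_proportions=pi,
        responsibilities=r,
        component_labels=labels,
        component_means=means,
        grid=grid,
        component_densities=dens,
        bandwidth=h,
        iterations=it,
        loglik_trace=loglik_trace,
        separated=separated,
    )


def _degenerate_fit(x: np.ndarray) -> MixtureFit:
    n = len(x)
    r = np.column_stack([np.ones(n), np.zeros(n)])
    grid = np.linspace(0.0, 1.0, 201)
    return MixtureFit(
        mixing_proportions=np.array([1.0, 0.0]),
        responsibilities=r,
        component_labels=np.array(["non_interesting"] * n),
        component_means=np.array([float(x[0]), float(x[0])]),
        grid=grid,
        component_densities=np.zeros((2, len(grid))),
        bandwidth=0.0,
        iterations=0,
        loglik_trace=[],
        separated=False,
    )


def select_interesting(
    rc_table: ReturnCountTable,
    mode: str = "mixture",
    q: float = 0.20,
    mixture_kwargs: dict | None = None,
) -> set[str]:
    """Variants declared "interesting" from their return counts.

    ``mixture`` mode labels the right-tail EM component; if the fit shows no
    separation (tiny component or overlapping means) it falls back to
    ``quantile`` mode, which returns the ceil(q*m) largest return counts with
    boundary ties all included.
    """
    ids = np.asarray(rc_table.variant_ids)
    rc = rc_table.return_count
    if len(ids) == 0:
        raise ValueError("empty return-count table")
    if mode == "mixture":
        try:
            fit = fit_np_mixture(rc, **(mixture_kwargs or {}))
        except ValueError:
            fit = None
        if fit is not None and fit.separated:
            return set(ids[fit.component_labels == "interesting"])
        logger.info(
            "mixture shows no separation; falling back to top-%d%% return counts",
            int(round(q * 100)),
        )
        mode = "quantile"
    if mode != "quantile":
        raise ValueError(f"unknown selection mode {mode!r}")
    m = len(ids)
    n_top = int(np.ceil(q * m))
    order = np.argsort(rc, kind="mergesort")[::-1]
    threshold = rc[order[n_top - 1]]
    return set(ids[rc >= threshold])
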