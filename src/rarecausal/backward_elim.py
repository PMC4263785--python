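"""Greedy backward elimination on groupwise score tests, with resampling.

The elimination algorithm starts from a set of variants, computes the
groupwise p-value, tries every single-variant deletion, and removes the
variant whose deletion most improves (lowers) the p-value; it stops when no
deletion improves the current p-value and returns the surviving set.  Causal
variants tend to survive because removing them raises the reduced-set p-value.

Because the contribution of one weak variant to a large set is hard to assess,
the procedure is applied to many small random subsets of the region's variants
(2000 resamplings of k variants by default).  For each variant the *return
count* is the fraction of subsets containing it in which it survived to the
final set; causal variants accumulate systematically higher return counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc import NullModel, SubsetScoreCache
from .genotype_io import GenotypeMatrix


@dataclass
class BEConfig:
    """Configuration of one elimination run / resampling procedure.

    ``k`` is the resampled subset size, ``n_resamples`` the number of subsets,
    ``test`` the groupwise statistic used inside the procedure (Burden by
    default; SKAT selectable).  An optional per-variant weight vector (one
    functional score at a time) enters the statistic directly.
    """

    k: int = 10
    n_resamples: int = 2000
    seed: int = 0
    test: str = "burden"  # or "skat"
    pvalue_method: str = "moment_match"
    weights: np.ndarray | None = None

    def echo(self) -> dict:
        return {
            "k": self.k,
            "n_resamples": self.n_resamples,
            "seed": self.seed,
            "test": self.test,
            "pvalue_method": self.pvalue_method,
            "weighted": self.weights is not None,
        }


@dataclass
class EliminationResult:
    final_set: list[str]
    removal_order: list[str]
    p_trace: list[float]

    @property
    def final_index(self) -> np.ndarray:
        return self._final_index

    _final_index: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


@dataclass
class ReturnCountTable:
    """Per-variant sampled/returned tallies and the normalized return count.

    ``return_count = times_returned / times_sampled`` lies in [0, 1]
    (0 for variants never sampled); raw tallies are retained.
    """

    table: pd.DataFrame  # variant_id, times_sampled, times_returned, return_count, stratum
    config: dict

    def __post_init__(self) -> None:
        rc = self.table["return_count"].to_numpy()
        if ((rc < 0) | (rc > 1)).any():
            raise ValueError("return counts must lie in [0, 1]")

    @property
    def variant_ids(self) -> list[str]:
        return list(self.table["variant_id"])

    @property
    def return_count(self) -> np.ndarray:
        return self.table["return_count"].to_numpy()


def _eliminate_indices(
    cache: SubsetScoreCache, subset: np.ndarray, cfg: BEConfig
) -> tuple[np.ndarray, list[int], list[float]]:
    """Core greedy loop on integer indices into ``cache``.

    Ties at the argmin are broken by smallest variant index so runs are
    deterministic.  A set shrinking to one variant terminates as a singleton.
    """
    current = np.sort(np.asarray(subset, dtype=int))
    p_cur = cache.pvalue(current, cfg.test, cfg.pvalue_method)
    trace = [p_cur]
    removed: list[int] = []
    while current.size > 1:
        if cfg.test == "burden":
            p_del = _burden_deletion_pvalues(cache, current)
        else:
            p_del = np.array(
                [
                    cache.pvalue(np.delete(current, i), cfg.test, cfg.pvalue_method)
                    for i in range(current.size)
                ]
            )
        best = int(np.argmin(p_del))  # argmin returns first = smallest index on ties
        if p_del[best] < p_cur:
            removed.append(int(current[best]))
            current = np.delete(current, best)
            p_cur = float(p_del[best])
            trace.append(p_cur)
        else:
            break
    return current, removed, trace


def _burden_deletion_pvalues(cache: SubsetScoreCache, current: np.ndarray) -> np.ndarray:
    """Vectorized Burden p-values for all single-variant deletions.

    For the rank-one Burden form, deleting variant i updates the weighted score
    sum T and the single eigenvalue v = w'Phi w by closed-form downdates.
    """
    from scipy import stats

    wA = cache.w[current]
    SA = cache.S[current]
    PhiA = cache.Phi[np.ix_(current, current)]
    T = wA @ SA
    u = PhiA @ wA
    v = float(wA @ u)
    T_del = T - wA * SA
    v_del = v - 2.0 * wA * u + wA**2 * np.diag(PhiA)
    v_del = np.maximum(v_del, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = stats.chi2.sf(T_del**2 / v_del, 1)
    p[v_del <= 1e-290] = 1.0
    return p


def backward_eliminate(
    G_subset: GenotypeMatrix, null: NullModel, cfg: BEConfig | None = None
) -> EliminationResult:
    """Run the elimination algorithm once on all variants of ``G_subset``."""
    cfg = cfg or BEConfig()
    if G_subset.n_variants < 2:
        raise ValueError("backward elimination needs at least 2 variants")
    cache = SubsetScoreCache(G_subset, null, cfg.weights)
    final_idx, removed, trace = _eliminate_indices(
        cache, np.arange(cache.m), cfg
    )
    res = EliminationResult(
        final_set=[cache.variant_ids[i] for i in final_idx],
        removal_order=[cache.variant_ids[i] for i in removed],
        p_trace=trace,
    )
    res._final_index = final_idx
    return res


def removal_effect_curve(
    G: GenotypeMatrix, null: NullModel, cfg: BEConfig | None = None
) -> list[float]:
    """P-value trajectory of a single elimination run (for diagnostics).

    The trace starts at the full-set p-value and is non-increasing up to the
    stopping step by construction of the removal rule.
    """
    return backward_eliminate(G, null, cfg).p_trace


def resample_return_counts(
    G: GenotypeMatrix,
    null: NullModel,
    cfg: BEConfig | None = None,
    stratum: str = "nonsynonymous-like",
) -> ReturnCountTable:
    """Return counts from repeated elimination on random k-variant subsets.

    Subsets are drawn uniformly without replacement within each resample
    (repeats across resamples are allowed), seeded for exact reproducibility.
    """
    cfg = cfg or BEConfig()
    m = G.n_variants
    if cfg.k < 2:
        raise ValueError("subset size k must be at least 2")
    if m < cfg.k:
        raise ValueError(
            f"region has {m} variants < k={cfg.k}; choose a smaller subset size k"
        )
    cache = SubsetScoreCache(G, null, cfg.weights)
    rng = np.random.default_rng(cfg.seed)
    sampled = np.zeros(m, dtype=int)
    returned = np.zeros(m, dtype=int)
    for _ in range(cfg.n_resamples):
        subset = rng.choice(m, size=cfg.k, replace=False)
        sampled[subset] += 1
        final_idx, _, _ = _eliminate_indices(cache, subset, cfg)
        returned[final_idx] += 1
    with np.errstate(invalid="ignore"):
        rc = np.where(sampled > 0, returned / np.maximum(sampled, 1), 0.0)
    table = pd.DataFrame(
        {
            "variant_id": G.variant_ids,
            "times_sampled": sampled,
            "times_returned": returned,
            "return_count": rc,
            "stratum": stratum,
        }
    )
    return ReturnCountTable(table=table, config=cfg.echo())
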