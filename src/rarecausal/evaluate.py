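"""Ranking and estimation metrics for simulation studies.

Metrics follow the usual benchmarking of variant prioritization methods:
the median 1-based rank of the causal variants in a ranking, the number of
causal variants among the top k (k = 10), absolute bias and nominal-95% Wald
interval coverage of per-variant log OR estimates, and ROC curves comparing a
model-based ranking score against an annotation score alone.  Medians are
lower medians (the smaller of the two central order statistics for even
counts) so that replicate summaries are deterministic integers where the
inputs are integers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def lower_median(values) -> float:
    """Lower median: element at index (n-1)//2 of the sorted values."""
    arr = np.sort(np.asarray(values, dtype=float))
    if arr.size == 0:
        raise ValueError("median of empty sequence")
    return float(arr[(arr.size - 1) // 2])


def median_causal_rank(ranking: list[str], causal: set[str]) -> float | None:
    """Lower median of the 1-based positions of causal ids in the ranking.

    Returns ``None`` when no causal id appears in the ranking (reported as
    missing rather than raising, since replicates with no causal variants in a
    stratum are legitimate).
    """
    positions = [i + 1 for i, vid in enumerate(ranking) if vid in causal]
    if not positions:
        return None
    return lower_median(positions)


def topk_causal_count(ranking: list[str], causal: set[str], k: int = 10) -> int:
    """Number of causal ids among the first k of the ranking."""
    return sum(1 for vid in ranking[:k] if vid in causal)


def bias_coverage(
    beta_hat,
    se_beta,
    truth,
    level: float = 0.95,
) -> tuple[float, float]:
    """Mean absolute error and Wald-interval coverage of effect estimates.

    Accepts single arrays or lists of per-replicate arrays; replicates are
    pooled.  Coverage is the fraction of variants whose interval
    beta_hat +/- z * se covers the true log OR.
    """
    bh = np.concatenate([np.atleast_1d(a) for a in _as_list(beta_hat)])
    se = np.concatenate([np.atleast_1d(a) for a in _as_list(se_beta)])
    tr = np.concatenate([np.atleast_1d(a) for a in _as_list(truth)])
    if not (len(bh) == len(se) == len(tr)):
        raise ValueError("estimates, SEs and truth must align")
    z = stats.norm.ppf(0.5 + level / 2.0)
    abs_bias = float(np.mean(np.abs(bh - tr)))
    covered = np.abs(bh - tr) <= z * se
    return abs_bias, float(np.mean(covered))


def _as_list(x):
    if isinstance(x, (list, tuple)):
        return x
    return [x]


def ranking_roc(
    z_scores: np.ndarray,
    comparison_scores: np.ndarray,
    causal_flags: np.ndarray,
) -> dict:
    """ROC curves/areas for two scores discriminating causal variants.

    The curves are invariant to monotone transforms of either score.  Returns
    a dict with fpr/tpr/auc for the model score and the comparison score.
    """
    from sklearn.metrics import roc_auc_score, roc_curve

    flags = np.asarray(causal_flags, dtype=int)
    out = {}
    for key, score in (("model", z_scores), ("comparison", comparison_scores)):
        fpr, tpr, _ = roc_curve(flags, np.asarray(score, dtype=float))
        out[key] = {
            "fpr": fpr,
            "tpr": tpr,
            "auc": float(roc_auc_score(flags, np.asarray(score, dtype=float))),
        }
    return out


def summarize_replicates(records: list[dict], method: str, seeds: list[int] | None = None) -> pd.DataFrame:
    """Aggregate per-replicate metric dicts into one EvaluationReport row.

    Each record may carry ``median_rank``, ``top10``, ``abs_bias`` and
    ``coverage_95``; medians are summarized by the lower median across
    replicates (the two-level median) and estimation metrics by their mean.
    Monte-Carlo standard errors accompany each summary.
    """
    rows = {"method": method, "n_replicates": len(records)}
    med = [r["median_rank"] for r in records if r.get("median_rank") is not None]
    if med:
        rows["median_rank"] = lower_median(med)
        rows["median_rank_mcse"] = float(np.std(med, ddof=1) / np.sqrt(len(med))) if len(med) > 1 else 0.0
    top = [r["top10"] for r in records if r.get("top10") is not None]
    if top:
        rows["top10_causal_count"] = lower_median(top)
        rows["top10_mcse"] = float(np.std(top, ddof=1) / np.sqrt(len(top))) if len(top) > 1 else 0.0
    for key in ("abs_bias", "coverage_95"):
        vals = [r[key] for r in records if r.get(key) is not None]
        if vals:
            rows[key] = float(np.mean(vals))
            rows[f"{key}_mcse"] = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
    if seeds is not None:
        rows["seeds"] = ",".join(str(s) for s in seeds)
    return pd.DataFrame([rows])
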