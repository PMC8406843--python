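"""Two-group differential abundance testing.

Per feature: two-sided Wilcoxon rank-sum (exact for small tie-free samples,
tie-corrected normal approximation otherwise), Benjamini-Hochberg adjustment
across features, log2 fold change of group means, and an enriched/deficient
call at q < alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .abundance import AbundanceMatrix

__all__ = [
    "DiffResult",
    "wilcoxon_rank_sum",
    "bh_adjust",
    "log2_fold_change",
    "differential_table",
]

# below this group size (and with no ties) the exact null distribution is used
EXACT_N_MAX = 12


@dataclass
class DiffResult:
    feature_id: str
    statistic: float   # rank-sum of the first sample (x)
    p: float
    q: float
    log2fc: float      # AF over CTR
    direction: str     # AF-enriched / AF-deficient / NS


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided rank-sum test; returns (rank-sum of x, p).

    Exact enumeration when ``min(|x|, |y|) <= 12`` and the pooled data has no
    ties; otherwise the tie-corrected normal approximation with continuity
    correction.  Constant pooled data yields p = 1 with a warning.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[: x.size].sum())
    if np.ptp(pooled) == 0:
        warnings.warn("all pooled values identical; p set to 1", stacklevel=2)
        return w, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= EXACT_N_MAX and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return w, float(res.pvalue)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def log2_fold_change(x_af, y_ctr, pseudo: float = 0.0) -> float:
    """log2((mean(AF)+pseudo) / (mean(CTR)+pseudo))."""
    ma = float(np.mean(x_af))
    mc = float(np.mean(y_ctr))
    if ma == 0 and mc == 0:
        warnings.warn("both group means are zero; log2FC set to 0", stacklevel=2)
        return 0.0
    if pseudo <= 0 and (ma == 0 or mc == 0):
        raise ValueError("pseudo must be > 0 when a group mean is zero")
    return float(np.log2((ma + pseudo) / (mc + pseudo)))


def _default_pseudo(values: np.ndarray) -> float:
    nz = values[values > 0]
    return float(nz.min()) / 2.0 if nz.size else 1e-12


def differential_table(
    matrix: AbundanceMatrix,
    alpha: float = 0.05,
    fc_stat: str = "mean",
    pseudo: float | None = None,
) -> pd.DataFrame:
    """Per-feature differential test between the AF and CTR samples.

    ``fc_stat`` selects mean- or median-based fold change.  ``pseudo``
    defaults to half the smallest nonzero abundance in the matrix.
    """
    if matrix.groups is None:
        raise ValueError("matrix carries no group labels")
    af = matrix.group_values("AF").to_numpy(float)
    ctr = matrix.group_values("CTR").to_numpy(float)
    if af.shape[0] == 0 or ctr.shape[0] == 0:
        raise ValueError("both groups (AF, CTR) must be present")
    if pseudo is None:
        pseudo = _default_pseudo(matrix.values.to_numpy(float))
    center = np.mean if fc_stat == "mean" else np.median

    stats_w, pvals, fcs = [], [], []
    for j in range(af.shape[1]):
        w, p = wilcoxon_rank_sum(af[:, j], ctr[:, j])
        stats_w.append(w)
        pvals.append(p)
        ma, mc = float(center(af[:, j])), float(center(ctr[:, j]))
        fcs.append(float(np.log2((ma + pseudo) / (mc + pseudo))))
    qvals = bh_adjust(pvals)
    direction = [
        ("AF-enriched" if fc > 0 else "AF-deficient") if q < alpha else "NS"
        for q, fc in zip(qvals, fcs)
    ]
    return pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "statistic": stats_w,
            "p": pvals,
            "q": qvals,
            "log2fc": fcs,
            "direction": direction,
        }
    )
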