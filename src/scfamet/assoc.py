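"""Spearman correlation networks and logistic association models."""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .diff import bh_adjust

__all__ = ["spearman_network", "logistic_fit"]


def spearman_network(
    table: pd.DataFrame, r_threshold: float = 0.15, alpha: float = 0.05
) -> pd.DataFrame:
    """Pairwise tie-midrank Spearman correlations with BH-FDR edge filtering.

    Returns one row per unordered variable pair with ``kept`` true iff
    ``q < alpha`` and ``|rho| > r_threshold``.  Constant variables are
    excluded with a warning.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 samples")
    constant = [c for c in table.columns if table[c].nunique() <= 1]
    if constant:
        warnings.warn(f"constant variables excluded: {constant}", stacklevel=2)
        table = table.drop(columns=constant)
    cols = list(table.columns)
    rows = []
    for a, b in itertools.combinations(cols, 2):
        rho, p = stats.spearmanr(table[a], table[b])
        rows.append({"node_a": a, "node_b": b, "rho": float(rho), "p": float(p)})
    edges = pd.DataFrame(rows, columns=["node_a", "node_b", "rho", "p"])
    if not edges.empty:
        edges["q"] = bh_adjust(edges["p"].to_numpy())
        edges["kept"] = (edges["q"] < alpha) & (edges["rho"].abs() > r_threshold)
    else:
        edges["q"] = pd.Series(dtype=float)
        edges["kept"] = pd.Series(dtype=bool)
    return edges


_SEPARATION_COEF = 30.0


def _fit_one(y: np.ndarray, X: pd.DataFrame) -> pd.DataFrame:
    design = sm.add_constant(X.astype(float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
        except Exception as exc:  # includes PerfectSeparationError
            raise ValueError(
                f"logistic fit failed ({exc}); consider penalized regression"
            ) from exc
    if np.any(np.abs(res.params.drop("const")) > _SEPARATION_COEF):
        raise ValueError(
            "separation detected (diverging coefficients); consider penalized regression"
        )
    conf = res.conf_int()
    rows = []
    for term in X.columns:
        rows.append(
            {
                "term": term,
                "odds_ratio": float(np.exp(res.params[term])),
                "ci_low": float(np.exp(conf.loc[term, 0])),
                "ci_high": float(np.exp(conf.loc[term, 1])),
                "p": float(res.pvalues[term]),
            }
        )
    return pd.DataFrame(rows)


def logistic_fit(
    outcome, predictors: pd.DataFrame, univariable: bool = True
) -> pd.DataFrame:
    """Logistic regression odds ratios with Wald 95% CIs.

    ``univariable=True`` fits one single-predictor model per column;
    otherwise one joint model over all columns.
    """
    y = np.asarray(outcome, float).ravel()
    if np.unique(y).size != 2:
        raise ValueError("outcome must contain exactly two classes")
    y = (y == y.max()).astype(float)
    predictors = pd.DataFrame(predictors)
    if len(predictors) <= predictors.shape[1]:
        raise ValueError("need more samples than predictors")
    if univariable:
        parts = [_fit_one(y, predictors[[c]]) for c in predictors.columns]
        return pd.concat(parts, ignore_index=True)
    return _fit_one(y, predictors)
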