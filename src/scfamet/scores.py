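"""Sparse linear risk scores: L1-penalized logistic selection, linear score
evaluation, ROC/AUC with DeLong confidence intervals, Nagelkerke R2, and
Harrell-style bootstrap optimism correction.

The three published score models (KO, enzyme, species) ship as packaged JSON
and are loadable with :func:`load_packaged_model`.
"""

from __future__ import annotations

import importlib.resources
import json
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ScoreModel",
    "RocSummary",
    "OptimismReport",
    "load_packaged_model",
    "lasso_select",
    "evaluate_score",
    "roc_auc",
    "bootstrap_optimism",
    "nagelkerke_r2",
]


@dataclass
class ScoreModel:
    """Intercept plus sparse coefficients; score = intercept + sum coef*x."""

    name: str
    intercept: float
    coefficients: dict[str, float]
    selection_meta: dict | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "name": self.name,
                    "intercept": self.intercept,
                    "coefficients": self.coefficients,
                    "selection_meta": self.selection_meta,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "ScoreModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            name=d["name"],
            intercept=float(d["intercept"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            selection_meta=d.get("selection_meta"),
        )


@dataclass
class RocSummary:
    auc: float
    ci_low: float
    ci_high: float
    p: float  # two-sided, vs AUC = 0.5


@dataclass
class OptimismReport:
    apparent_auc: float
    mean_optimism: float
    corrected_auc: float
    apparent_r2: float
    mean_optimism_r2: float
    corrected_r2: float
    B: int
    n_redrawn: int = 0


def load_packaged_model(which: str) -> ScoreModel:
    """Load a published score model: ``"ko"``, ``"enzyme"`` or ``"species"``."""
    which = which.lower()
    if which not in ("ko", "enzyme", "species"):
        raise ValueError("which must be 'ko', 'enzyme' or 'species'")
    ref = importlib.resources.files("scfamet.data") / f"model_{which}.json"
    with importlib.resources.as_file(ref) as p:
        return ScoreModel.from_json(p)


def evaluate_score(model: ScoreModel, sample: Mapping[str, float]) -> float:
    """Linear score for one sample; missing features count as 0 (warned)."""
    missing = [f for f in model.coefficients if f not in sample]
    if missing:
        warnings.warn(
            f"features absent from sample treated as 0: {missing}", stacklevel=2
        )
    total = model.intercept
    for feat, coef in model.coefficients.items():
        total += coef * float(sample.get(feat, 0.0))
    return float(total)


def _cv_deviance(X, y, C, folds, seed):
    """Mean and SE (over folds) of held-out deviance for one penalty."""
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    devs = []
    for tr, te in cv.split(X, y):
        clf = LogisticRegression(
            l1_ratio=1.0, C=C, solver="liblinear", max_iter=2000, random_state=0
        )
        clf.fit(X[tr], y[tr])
        p = np.clip(clf.predict_proba(X[te])[:, 1], 1e-12, 1 - 1e-12)
        devs.append(-2.0 * np.mean(y[te] * np.log(p) + (1 - y[te]) * np.log(1 - p)))
    devs = np.asarray(devs)
    return devs.mean(), devs.std(ddof=1) / np.sqrt(folds)


def lasso_select(
    features: pd.DataFrame,
    labels,
    cv_folds: int = 10,
    seed: int = 0,
    lambda_rule: str = "1se",
    n_lambdas: int = 30,
    standardize: bool = False,
    name: str = "score",
    lambda_fixed: float | None = None,
) -> ScoreModel:
    """L1-penalized logistic selection with cross-validated penalty.

    The penalty path spans lambda_max (first feature enters) down by 4
    decades; ``lambda_rule`` picks the deviance-minimizing penalty ("min") or
    the sparsest penalty within one SE of it ("1se").  ``lambda_fixed``
    bypasses cross-validation and fits at the given penalty.  Features are
    used on their raw scale unless ``standardize`` is set.
    """
    if lambda_rule not in ("min", "1se"):
        raise ValueError("lambda_rule must be 'min' or '1se'")
    X = np.asarray(features, float)
    y = np.asarray(labels, float).ravel()
    if X.shape[1] < 2:
        raise ValueError("need at least 2 candidate features")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("labels must contain exactly two classes")
    y = (y == classes.max()).astype(float)
    if standardize:
        mu, sd = X.mean(0), X.std(0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd

    n = X.shape[0]
    if lambda_fixed is not None:
        lam_sel = float(lambda_fixed)
        folds = cv_folds
    else:
        lam_max = np.abs(X.T @ (y - y.mean())).max() / n
        lam_max = max(lam_max, 1e-10)
        lams = np.geomspace(lam_max, lam_max * 1e-4, n_lambdas)
        Cs = 1.0 / (n * lams)  # sklearn's C is the inverse of the summed penalty

        means, ses = np.empty(n_lambdas), np.empty(n_lambdas)
        folds = min(cv_folds, int(np.bincount(y.astype(int)).min()))
        if folds < 2:
            raise ValueError("too few samples per class for cross-validation")
        for i, C in enumerate(Cs):
            means[i], ses[i] = _cv_deviance(X, y, C, folds, seed)
        i_min = int(np.argmin(means))
        if lambda_rule == "min":
            i_sel = i_min
        else:
            ok = np.where(means <= means[i_min] + ses[i_min])[0]
            i_sel = int(ok.min())  # smallest index = largest lambda = sparsest
        lam_sel = float(lams[i_sel])

    clf = LogisticRegression(
        l1_ratio=1.0, C=1.0 / (n * lam_sel), solver="liblinear", max_iter=5000,
        random_state=0,
    )
    clf.fit(X, y)
    coefs = clf.coef_.ravel()
    if standardize:
        # map back to the raw-abundance scale
        intercept = float(clf.intercept_[0] - np.sum(coefs * mu / sd))
        coefs = coefs / sd
    else:
        intercept = float(clf.intercept_[0])
    nonzero = {
        str(c): float(w)
        for c, w in zip(features.columns, coefs)
        if w != 0.0
    }
    return ScoreModel(
        name=name,
        intercept=intercept,
        coefficients=nonzero,
        selection_meta={
            "lambda": lam_sel,
            "lambda_rule": "fixed" if lambda_fixed is not None else lambda_rule,
            "cv_folds": folds,
            "seed": seed,
        },
    )


def _score_matrix(model: ScoreModel, features: pd.DataFrame) -> np.ndarray:
    s = np.full(len(features), model.intercept, float)
    for feat, coef in model.coefficients.items():
        if feat in features.columns:
            s += coef * features[feat].to_numpy(float)
    return s


def _auc_rank(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC via the Mann-Whitney midrank formula."""
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    n1, n0 = pos.size, neg.size
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _delong_se(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong standard error of the AUC (single-classifier case)."""
    n1, n0 = pos.size, neg.size
    all_ = np.concatenate([pos, neg])
    r_all = stats.rankdata(all_)
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    v10 = (r_all[:n1] - r_pos) / n0          # placement of each positive
    v01 = 1.0 - (r_all[n1:] - r_neg) / n1    # placement of each negative
    s10 = np.var(v10, ddof=1) if n1 > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n0 > 1 else 0.0
    return float(np.sqrt(s10 / n1 + s01 / n0))


def roc_auc(scores, labels) -> RocSummary:
    """AUC with DeLong 95% CI and a normal p-value against AUC = 0.5."""
    scores = np.asarray(scores, float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("labels must contain exactly two classes")
    pos = scores[y == classes.max()]
    neg = scores[y == classes.min()]
    if np.ptp(scores) == 0:
        warnings.warn("constant scores; AUC degenerate at 0.5", stacklevel=2)
        return RocSummary(auc=0.5, ci_low=0.5, ci_high=0.5, p=1.0)
    auc = _auc_rank(pos, neg)
    se = _delong_se(pos, neg)
    if se == 0:
        warnings.warn("degenerate DeLong variance; CI collapsed", stacklevel=2)
        ci_low = ci_high = auc
        p = 0.0 if auc != 0.5 else 1.0
    else:
        z = stats.norm.ppf(0.975)
        ci_low = max(0.0, auc - z * se)
        ci_high = min(1.0, auc + z * se)
        p = float(2 * stats.norm.sf(abs(auc - 0.5) / se))
    return RocSummary(auc=auc, ci_low=ci_low, ci_high=ci_high, p=p)


def nagelkerke_r2(labels, fitted_probs) -> float:
    """Nagelkerke pseudo-R2 from fitted class-1 probabilities."""
    y = np.asarray(labels, float).ravel()
    p = np.asarray(fitted_probs, float).ravel()
    if np.any((p <= 0) | (p >= 1)):
        warnings.warn(
            "fitted probabilities at 0/1 clipped (perfect separation?)", stacklevel=2
        )
        p = np.clip(p, 1e-12, 1 - 1e-12)
    n = y.size
    prev = y.mean()
    prev = min(max(prev, 1e-12), 1 - 1e-12)
    ll1 = np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))
    ll0 = np.sum(y * np.log(prev) + (1 - y) * np.log(1 - prev))
    num = 1.0 - np.exp((2.0 / n) * (ll0 - ll1))
    den = 1.0 - np.exp((2.0 / n) * ll0)
    return float(min(num / den, 1.0))


def _fit_and_probs(features, y, **lasso_kwargs):
    model = lasso_select(features, y, **lasso_kwargs)
    score = _score_matrix(model, features)
    return model, score


def bootstrap_optimism(
    features: pd.DataFrame,
    labels,
    B: int = 500,
    seed: int = 0,
    **lasso_kwargs,
) -> OptimismReport:
    """Bootstrap optimism-corrected AUC and Nagelkerke R2.

    For each resample the full selection + fit is repeated; optimism is the
    performance of the resample model on its own resample minus its
    performance on the original cohort.  Resamples missing a class are
    redrawn (and counted).
    """
    y = np.asarray(labels, float).ravel()
    classes = np.unique(y)
    y = (y == classes.max()).astype(float)
    features = pd.DataFrame(features).reset_index(drop=True)

    model, score = _fit_and_probs(features, y, **lasso_kwargs)
    apparent_auc = roc_auc(score, y).auc if np.ptp(score) > 0 else 0.5
    apparent_r2 = nagelkerke_r2(y, _sigmoid(score))

    rng = np.random.default_rng(seed)
    n = len(y)
    opt_auc, opt_r2 = [], []
    n_redrawn = 0
    for _ in range(B):
        while True:
            idx = rng.integers(0, n, n)
            if np.unique(y[idx]).size == 2:
                break
            n_redrawn += 1
        fb = features.iloc[idx].reset_index(drop=True)
        yb = y[idx]
        mb, sb = _fit_and_probs(fb, yb, **lasso_kwargs)
        auc_bb = roc_auc(sb, yb).auc if np.ptp(sb) > 0 else 0.5
        s_orig = _score_matrix(mb, features)
        auc_bo = roc_auc(s_orig, y).auc if np.ptp(s_orig) > 0 else 0.5
        opt_auc.append(auc_bb - auc_bo)
        opt_r2.append(
            nagelkerke_r2(yb, _sigmoid(sb)) - nagelkerke_r2(y, _sigmoid(s_orig))
        )

    mean_opt = float(np.mean(opt_auc))
    mean_opt_r2 = float(np.mean(opt_r2))
    return OptimismReport(
        apparent_auc=float(apparent_auc),
        mean_optimism=mean_opt,
        corrected_auc=float(apparent_auc - mean_opt),
        apparent_r2=float(apparent_r2),
        mean_optimism_r2=mean_opt_r2,
        corrected_r2=float(apparent_r2 - mean_opt_r2),
        B=B,
        n_redrawn=n_redrawn,
    )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))
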