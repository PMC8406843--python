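"""Three-variable mediation via standardized path analysis.

With single-indicator constructs, PLS path modeling reduces to ordinary
standardized regression: a = slope of M on X, (b, c') = slopes of Y on
(M, X), total = slope of Y on X.  The OLS decomposition identity
``total = c' + a*b`` holds exactly on every fit.  VAF (variance accounted
for) = indirect / total effect, reported with sign and flagged when outside
[0, 1] ("inconsistent mediation").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["MediationModel", "fit_mediation", "bootstrap_mediation"]


@dataclass
class MediationModel:
    a: float          # X -> M
    b: float          # M -> Y | X
    c_direct: float   # X -> Y | M
    total: float
    ide: float        # indirect effect a*b
    vaf: float
    n: int
    inconsistent: bool = False
    boot: dict | None = None

    def to_dict(self) -> dict:
        d = {
            "a": self.a, "b": self.b, "c_direct": self.c_direct,
            "total": self.total, "ide": self.ide, "vaf": self.vaf,
            "n": self.n, "inconsistent": self.inconsistent,
        }
        if self.boot is not None:
            d["boot"] = self.boot
        return d


def _standardize(v: np.ndarray, label: str) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError(f"{label} has zero variance")
    return (v - v.mean()) / sd


def _paths(x: np.ndarray, m: np.ndarray, y: np.ndarray):
    n = x.size
    a = float(x @ m / n)           # slope of standardized M on standardized X
    design = np.column_stack([m, x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    b, c_direct = float(coef[0]), float(coef[1])
    total = float(x @ y / n)
    return a, b, c_direct, total


def fit_mediation(x, m, y) -> MediationModel:
    """Standardized path model for exposure x, mediator m, outcome y."""
    x = np.asarray(x, float).ravel()
    m = np.asarray(m, float).ravel()
    y = np.asarray(y, float).ravel()
    if not (x.size == m.size == y.size):
        raise ValueError("x, m, y must have equal length")
    if x.size < 10:
        raise ValueError("need at least 10 observations")
    xs = _standardize(x, "x")
    ms = _standardize(m, "m")
    ys = _standardize(y, "y")
    a, b, c_direct, total = _paths(xs, ms, ys)
    ide = a * b
    if total == 0:
        warnings.warn("total effect is zero; VAF undefined (nan)", stacklevel=2)
        vaf = float("nan")
    else:
        vaf = ide / total
    inconsistent = not (0.0 <= vaf <= 1.0) if np.isfinite(vaf) else True
    return MediationModel(
        a=a, b=b, c_direct=c_direct, total=total, ide=ide,
        vaf=float(vaf), n=int(x.size), inconsistent=inconsistent,
    )


def _boot_p(draws: np.ndarray) -> float:
    """Two-sided sign-crossing p-value from bootstrap draws (add-one smoothed)."""
    B = draws.size
    lo = (np.sum(draws <= 0) + 1) / (B + 1)
    hi = (np.sum(draws >= 0) + 1) / (B + 1)
    return float(min(1.0, 2.0 * min(lo, hi)))


def bootstrap_mediation(x, m, y, B: int = 500, seed: int = 0) -> MediationModel:
    """Case-resampling bootstrap: percentile CIs and two-sided p per path."""
    if B < 100:
        warnings.warn(f"B={B} < 100 bootstrap resamples is unstable", stacklevel=2)
    model = fit_mediation(x, m, y)
    x = np.asarray(x, float).ravel()
    m = np.asarray(m, float).ravel()
    y = np.asarray(y, float).ravel()
    rng = np.random.default_rng(seed)
    n = x.size
    draws = {k: np.empty(B) for k in ("a", "b", "c_direct", "ide")}
    done = 0
    while done < B:
        idx = rng.integers(0, n, n)
        try:
            fit = fit_mediation(x[idx], m[idx], y[idx])
        except ValueError:  # zero-variance resample; redraw
            continue
        draws["a"][done] = fit.a
        draws["b"][done] = fit.b
        draws["c_direct"][done] = fit.c_direct
        draws["ide"][done] = fit.ide
        done += 1
    boot = {}
    for key, vals in draws.items():
        lo, hi = np.percentile(vals, [2.5, 97.5])
        boot[key] = {"ci_low": float(lo), "ci_high": float(hi), "p": _boot_p(vals)}
    boot["B"] = B
    boot["seed"] = seed
    model.boot = boot
    return model
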