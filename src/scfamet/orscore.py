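"""Group-enrichment odds-ratio statistic for a feature k.

OR(k) = [sum_CTR A_sk / sum_CTR sum_{i!=k} A_si] /
        [sum_AF  A_sk / sum_AF  sum_{i!=k} A_si]

Taken literally, the control group sits in the numerator, so OR > 1 means the
feature carries relatively more mass in controls.  Because published uses of
this statistic disagree on the sign convention, the label mapping is
configurable: ``convention="formula"`` labels OR > 1 as CTR-enriched (the
literal reading), ``convention="af-positive"`` flips log2(OR) so positive
values mean AF-enriched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .abundance import AbundanceMatrix

__all__ = ["OrResult", "or_score", "or_table"]

CONVENTIONS = ("formula", "af-positive")


@dataclass
class OrResult:
    feature_id: str
    or_value: float
    log2_or: float
    label: str  # AF-enriched / CTR-enriched / balanced


def _odds(block: np.ndarray, j: int, pseudo: float) -> float:
    num = block[:, j].sum()
    denom = block.sum() - num
    if num == 0:
        num = pseudo
    if denom == 0:
        denom = pseudo
    return num / denom


def _label(formula_or: float) -> str:
    # formula_or is the literal statistic: > 1 means relatively more in CTR
    if formula_or == 1.0:
        return "balanced"
    return "CTR-enriched" if formula_or > 1.0 else "AF-enriched"


def or_score(
    matrix: AbundanceMatrix,
    k: str,
    pseudo: float = 1e-12,
    convention: str = "formula",
) -> OrResult:
    """OR(k) for one feature; ``pseudo`` replaces zero sums only."""
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}")
    if k not in matrix.values.columns:
        raise ValueError(f"feature {k!r} absent from matrix")
    j = matrix.values.columns.get_loc(k)
    ctr = matrix.group_values("CTR").to_numpy(float)
    af = matrix.group_values("AF").to_numpy(float)
    if ctr.shape[0] == 0 or af.shape[0] == 0:
        raise ValueError("both groups (AF, CTR) must be present")
    formula_or = _odds(ctr, j, pseudo) / _odds(af, j, pseudo)
    label = _label(formula_or)
    or_value = formula_or if convention == "formula" else 1.0 / formula_or
    return OrResult(
        feature_id=k,
        or_value=float(or_value),
        log2_or=float(np.log2(or_value)),
        label=label,
    )


def or_table(
    matrix: AbundanceMatrix, pseudo: float = 1e-12, convention: str = "formula"
) -> pd.DataFrame:
    """OR(k) for every feature of the matrix."""
    rows = [
        or_score(matrix, k, pseudo=pseudo, convention=convention)
        for k in matrix.feature_ids
    ]
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in rows],
            "or_value": [r.or_value for r in rows],
            "log2_or": [r.log2_or for r in rows],
            "label": [r.label for r in rows],
        }
    )
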