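"""Independent brute-force oracles and small random fixtures for the tests.

These deliberately avoid the library code paths they are used to check.
"""

import numpy as np
import pandas as pd

from scfamet.abundance import AbundanceMatrix
from scfamet.taxonomy import Taxonomy


def random_tree(rng, n_nodes=50):
    """Random rooted tree as a Taxonomy; node i's parent is a random j < i."""
    rows = [("n0", "n0", "root", "root")]
    for i in range(1, n_nodes):
        parent = f"n{rng.integers(0, i)}"
        rows.append((f"n{i}", parent, "node", f"name{i}"))
    return Taxonomy(
        pd.DataFrame(rows, columns=["taxon_id", "parent_id", "rank", "name"])
    )


def ancestor_path(taxonomy, node):
    path = [node]
    while taxonomy.parent[node] is not None:
        node = taxonomy.parent[node]
        path.append(node)
    return path


def lca_oracle(taxonomy, taxa):
    """Brute-force LCA: intersect ancestor sets, pick the deepest."""
    common = set(ancestor_path(taxonomy, taxa[0]))
    for t in taxa[1:]:
        common &= set(ancestor_path(taxonomy, t))
    return max(common, key=lambda n: taxonomy.depth[n])


def two_group_matrix(rng, n_ctr=5, n_af=5, n_features=8):
    """Small random compositional matrix with CTR/AF labels."""
    raw = rng.lognormal(0, 1, (n_ctr + n_af, n_features))
    values = raw / raw.sum(axis=1, keepdims=True)
    idx = [f"s{i}" for i in range(n_ctr + n_af)]
    return AbundanceMatrix(
        values=pd.DataFrame(
            values, index=idx, columns=[f"F{j}" for j in range(n_features)]
        ),
        groups=pd.Series(["CTR"] * n_ctr + ["AF"] * n_af, index=idx),
    )


def or_oracle(matrix, k):
    """Direct transcription of the OR(k) formula from group-pooled sums."""
    ctr = matrix.group_values("CTR").to_numpy(float)
    af = matrix.group_values("AF").to_numpy(float)
    j = list(matrix.values.columns).index(k)
    num = ctr[:, j].sum() / (ctr.sum() - ctr[:, j].sum())
    den = af[:, j].sum() / (af.sum() - af[:, j].sum())
    return num / den


def auc_oracle(scores, labels):
    """Brute-force pairwise AUC with 0.5 credit for ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == labels.max()]
    neg = scores[labels == labels.min()]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def rank_sum_exact_p(x, y):
    """Exhaustive two-sided rank-sum p over all labelings (tie-free data)."""
    from itertools import combinations

    pooled = np.concatenate([x, y])
    ranks = pooled.argsort().argsort() + 1  # tie-free by assumption
    n = len(pooled)
    nx = len(x)
    w_obs = ranks[:nx].sum()
    mu = nx * (n + 1) / 2.0
    count = 0
    total = 0
    for combo in combinations(range(n), nx):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            count += 1
    return count / total
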