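"""Synthetic two-group cohorts with planted ground truth.

Everything downstream (catalog intersection, differential testing, OR scores,
LASSO models, LCA, mediation) is testable against the planted structure:

* compositional KO profiles (log-normal, closed to the simplex) with a known
  set of differential KOs at a chosen log2 fold change,
* enzyme abundances induced from species profiles through a species x enzyme
  copy-number ("harboring") matrix,
* clinical covariates whose (exposure, mediator, outcome) triple follows a
  linear path model with known coefficients, and
* gene read tables / alignment hit tables for the normalization and LCA
  stages.

A single integer seed drives one random stream for full reproducibility.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .abundance import AbundanceMatrix, close_rows
from .taxonomy import Taxonomy

__all__ = [
    "CohortConfig",
    "TruthRecord",
    "SyntheticCohort",
    "ENZYMES",
    "generate_cohort",
    "generate_gene_read_table",
    "generate_hit_table",
    "random_taxonomy",
]

ENZYMES = [
    "tesA",
    "tesB",
    "yciA",
    "menI",
    "propionyl CoA transferase",
    "CO dehydrogenase acetyl-CoA synthase complex",
    "butyrate acetoacetate CoA transferase",
]

# multiplicative log-normal sample noise on feature profiles
_PROFILE_SIGMA = 0.5


@dataclass
class CohortConfig:
    n_ctr: int = 50
    n_af: int = 50
    n_ko: int = 200
    n_diff: int = 10
    log2fc_planted: float = 1.0
    species_count: int = 30
    harboring_matrix_density: float = 0.3
    mediation_paths: dict = field(
        default_factory=lambda: {"a": 0.8, "b": 0.7, "c_direct": 0.1}
    )
    noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_ctr", "n_af", "n_ko", "species_count"):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_diff < 0:
            raise ValueError("n_diff must be >= 0")
        if self.n_diff > self.n_ko:
            raise ValueError("n_diff must be <= n_ko")
        if not 0.0 <= self.harboring_matrix_density <= 1.0:
            raise ValueError("harboring_matrix_density must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for key in ("a", "b", "c_direct"):
            if key not in self.mediation_paths:
                raise ValueError(f"mediation_paths missing key {key!r}")
        if not float(self.seed) == int(self.seed):
            raise ValueError("seed must be an integer")


@dataclass
class TruthRecord:
    diff_ko_log2fc: dict              # planted ko_id -> log2 fold change (AF/CTR)
    harboring_matrix: pd.DataFrame    # species x enzyme copy numbers
    true_paths: dict                  # raw generator coefficients a, b, c_direct
    true_paths_standardized: dict     # implied coefficients after standardization
    true_vaf: float                   # a*b / (a*b + c_direct)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "diff_ko_log2fc": self.diff_ko_log2fc,
                    "harboring_matrix": {
                        sp: {e: float(v) for e, v in row.items()}
                        for sp, row in self.harboring_matrix.to_dict("index").items()
                    },
                    "true_paths": self.true_paths,
                    "true_paths_standardized": self.true_paths_standardized,
                    "true_vaf": self.true_vaf,
                },
                fh,
                indent=2,
            )


@dataclass
class SyntheticCohort:
    abundances: AbundanceMatrix          # samples x KO
    species_abundances: AbundanceMatrix  # samples x species
    enzyme_abundances: AbundanceMatrix   # samples x enzyme (induced, unclosed)
    clinical: pd.DataFrame
    truth: TruthRecord

    def to_dir(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.abundances.to_tsv(outdir / "ko_matrix.tsv")
        self.species_abundances.to_tsv(outdir / "species_matrix.tsv")
        self.enzyme_abundances.to_tsv(outdir / "enzyme_matrix.tsv")
        self.clinical.to_csv(outdir / "clinical.tsv", sep="\t", index_label="sample_id")
        self.truth.to_json(outdir / "truth.json")


def _implied_standardized_paths(a: float, b: float, c: float, s: float) -> dict:
    """Population path coefficients after standardizing M and Y.

    With X ~ N(0,1), M = aX + e1, Y = c'X + bM + e2 (residual sd s each),
    sd(M) = sqrt(a^2 + s^2) and sd(Y) = sqrt((c'+ab)^2 + (bs)^2 + s^2); the
    standardized fit converges to (a/sd_M, b sd_M/sd_Y, c'/sd_Y).
    """
    sm = float(np.sqrt(a**2 + s**2))
    sy = float(np.sqrt((c + a * b) ** 2 + (b * s) ** 2 + s**2))
    if sm == 0 or sy == 0:
        return {"a": float("nan"), "b": float("nan"), "c_direct": float("nan")}
    return {"a": a / sm, "b": b * sm / sy, "c_direct": c / sy}


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a fully reproducible synthetic cohort from ``config``."""
    config.validate()
    rng = np.random.default_rng(int(config.seed))
    n = config.n_ctr + config.n_af
    groups = pd.Series(
        ["CTR"] * config.n_ctr + ["AF"] * config.n_af,
        index=[f"S{i:04d}" for i in range(n)],
        name="group",
    )
    samples = groups.index
    af_mask = (groups == "AF").to_numpy()

    # --- KO profiles: shared log-normal base, planted multiplicative shift
    ko_ids = [f"K9{i:04d}" for i in range(config.n_ko)]
    base = rng.lognormal(0.0, 1.0, config.n_ko)
    # planted KOs get the median base so their compositional mass (and hence
    # the closure-induced shift on unplanted KOs) is stable across seeds
    base[: config.n_diff] = 1.0
    raw = base * rng.lognormal(0.0, _PROFILE_SIGMA, (n, config.n_ko))
    planted = ko_ids[: config.n_diff]
    if config.n_diff:
        raw[np.ix_(af_mask, np.arange(config.n_diff))] *= 2.0**config.log2fc_planted
    ko = AbundanceMatrix(
        values=pd.DataFrame(close_rows(raw), index=samples, columns=ko_ids),
        groups=groups,
    )

    # --- species profiles and induced enzyme abundances
    species_ids = [f"sp{i:03d}" for i in range(config.species_count)]
    base_s = rng.lognormal(0.0, 1.0, config.species_count)
    raw_s = base_s * rng.lognormal(0.0, _PROFILE_SIGMA, (n, config.species_count))
    sp_values = close_rows(raw_s)
    species = AbundanceMatrix(
        values=pd.DataFrame(sp_values, index=samples, columns=species_ids),
        groups=groups,
    )
    present = rng.random((config.species_count, len(ENZYMES))) < config.harboring_matrix_density
    copies = (rng.poisson(1.5, present.shape) + 1) * present
    harboring = pd.DataFrame(copies.astype(float), index=species_ids, columns=ENZYMES)
    enzyme = AbundanceMatrix(
        values=pd.DataFrame(
            sp_values @ harboring.to_numpy(), index=samples, columns=ENZYMES
        ),
        groups=groups,
    )

    # --- clinical covariates with a planted mediation triple
    paths = {k: float(v) for k, v in config.mediation_paths.items()}
    a, b, c = paths["a"], paths["b"], paths["c_direct"]
    s = config.noise_sd
    x = rng.standard_normal(n)                      # diversity (exposure)
    m = a * x + s * rng.standard_normal(n)          # hsCRP (mediator)
    y = c * x + b * m + s * rng.standard_normal(n)  # LA diameter (outcome)
    clinical = pd.DataFrame(
        {
            "group": groups,
            "age": np.round(rng.normal(60.0, 8.0, n), 1),
            "BMI": np.round(rng.normal(25.0, 3.0, n), 1),
            "hsCRP": m,
            "LA_diameter": y,
            "diversity": x,
        },
        index=samples,
    )

    denom = a * b + c
    truth = TruthRecord(
        diff_ko_log2fc={k: config.log2fc_planted for k in planted},
        harboring_matrix=harboring,
        true_paths=paths,
        true_paths_standardized=_implied_standardized_paths(a, b, c, s),
        true_vaf=float(a * b / denom) if denom != 0 else float("nan"),
    )
    return SyntheticCohort(
        abundances=ko,
        species_abundances=species,
        enzyme_abundances=enzyme,
        clinical=clinical,
        truth=truth,
    )


def generate_gene_read_table(n_genes: int, seed: int = 0) -> pd.DataFrame:
    """Gene read-count table with lengths; includes sub-threshold genes.

    Counts are drawn from a heavy-tailed negative binomial, so genes with
    0 or 1 reads occur naturally; the first gene is forced below 2 reads to
    guarantee minimum-read-filter coverage.
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be > 0")
    rng = np.random.default_rng(int(seed))
    counts = rng.negative_binomial(1, 0.02, n_genes)
    counts[0] = int(rng.integers(0, 2))  # a guaranteed {0,1}-read gene
    lengths = rng.integers(100, 3000, n_genes)
    return pd.DataFrame(
        {
            "gene_id": [f"g{i:05d}" for i in range(n_genes)],
            "read_count": counts.astype(int),
            "gene_length_bp": lengths.astype(int),
        }
    )


def random_taxonomy(n_species: int, seed: int = 0, n_genera: int | None = None) -> Taxonomy:
    """Small rooted fixture taxonomy: root -> genera -> species."""
    if n_species <= 0:
        raise ValueError("n_species must be > 0")
    rng = np.random.default_rng(int(seed))
    if n_genera is None:
        n_genera = max(2, n_species // 4)
    rows = [{"taxon_id": "t_root", "parent_id": "t_root", "rank": "root", "name": "root"}]
    for g in range(n_genera):
        rows.append(
            {"taxon_id": f"t_g{g:03d}", "parent_id": "t_root", "rank": "genus",
             "name": f"genus_{g}"}
        )
    for i in range(n_species):
        g = int(rng.integers(0, n_genera))
        rows.append(
            {"taxon_id": f"t_s{i:03d}", "parent_id": f"t_g{g:03d}", "rank": "species",
             "name": f"species_{i}"}
        )
    return Taxonomy(pd.DataFrame(rows))


def generate_hit_table(taxonomy: Taxonomy, n_genes: int, seed: int = 0) -> pd.DataFrame:
    """Alignment hit table (gene_id, taxon_id, e_value, bit_score).

    Each gene gets 1-10 hits whose e-values span the 10x retention boundary
    (multipliers up to 100x the best hit); taxa are drawn from the leaves of
    ``taxonomy``.
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be > 0")
    leaves = taxonomy.leaves()
    if not leaves:
        raise ValueError("taxonomy has no leaves")
    rng = np.random.default_rng(int(seed))
    rows = []
    for i in range(n_genes):
        k = int(rng.integers(1, 11))
        top_e = 10.0 ** rng.uniform(-30, -6)
        mult = np.concatenate([[1.0], 10.0 ** rng.uniform(0.0, 2.0, k - 1)])
        taxa = rng.choice(leaves, size=k, replace=True)
        for j in range(k):
            e = top_e * mult[j]
            rows.append(
                {
                    "gene_id": f"g{i:05d}",
                    "taxon_id": taxa[j],
                    "e_value": float(e),
                    "bit_score": float(-10.0 * np.log10(e) + rng.normal(0, 2)),
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "taxon_id", "e_value", "bit_score"])
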