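"""End-to-end orchestration of the analysis stages on a (synthetic) cohort.

Stage order: catalog -> abundance -> taxonomy -> diff -> orscore -> scores ->
mediation -> association, preceded by cohort simulation when no cohort
directory is supplied.  Each stage writes TSV/JSON artifacts into the output
directory; a manifest records the config hash, seed, and a SHA-256 checksum
per artifact so reruns are verifiably reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, catalog, diff, mediation, orscore, scores, taxonomy
from .abundance import AbundanceMatrix, aggregate, normalize_genes
from .simulate import (
    CohortConfig,
    ENZYMES,
    generate_cohort,
    generate_gene_read_table,
    generate_hit_table,
    random_taxonomy,
)

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("scfamet.pipeline")

STAGES = [
    "catalog",
    "abundance",
    "taxonomy",
    "diff",
    "orscore",
    "scores",
    "mediation",
    "association",
]


@dataclass
class PipelineConfig:
    out_dir: str = "scfa_out"
    seed: int = 0
    cohort_dir: str | None = None     # if unset, a cohort is simulated
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides
    compounds: list = field(default_factory=lambda: list(catalog.DEFAULT_COMPOUNDS))
    compound_map: str | None = None   # TSV path; packaged map if unset
    alpha: float = 0.05
    r_threshold: float = 0.15
    or_convention: str = "formula"
    lasso: dict = field(default_factory=lambda: {"cv_folds": 5, "n_lambdas": 15})
    bootstrap_B: int = 200
    n_genes: int = 300
    skip_taxonomy: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest (also written to manifest.json)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": int(config.seed),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "stages": {},
    }

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"][stage] = {
            p.name: _sha256(p) for p in paths if p.exists()
        }
        log.info("stage %s: wrote %s", stage, [p.name for p in paths])

    # ---- cohort (simulated unless a directory is supplied)
    if config.cohort_dir is None:
        cohort_cfg = CohortConfig(**{"seed": config.seed, **config.cohort})
        cohort = generate_cohort(cohort_cfg)
        cohort_dir = out / "cohort"
        cohort.to_dir(cohort_dir)
    else:
        cohort_dir = Path(config.cohort_dir)
        if not cohort_dir.exists():
            raise FileNotFoundError(f"cohort directory not found: {cohort_dir}")
    ko_matrix = AbundanceMatrix.from_tsv(cohort_dir / "ko_matrix.tsv")
    species_matrix = AbundanceMatrix.from_tsv(cohort_dir / "species_matrix.tsv")
    enzyme_matrix = AbundanceMatrix.from_tsv(cohort_dir / "enzyme_matrix.tsv")
    clinical = pd.read_csv(cohort_dir / "clinical.tsv", sep="\t", index_col="sample_id")
    log.info("cohort: %d samples, %d KOs", *ko_matrix.values.shape)

    # ---- stage 1: catalog
    try:
        cmap = catalog.load_compound_map(config.compound_map)
        cat = catalog.build_catalog(cmap, config.compounds)
        cat = catalog.intersect_annotated(cat, set(ko_matrix.feature_ids))
        cat.to_tsv(out / "catalog.tsv")
        dist = catalog.compound_distribution(cat, cat.ko_ids)
        dist.to_csv(out / "distribution.tsv", sep="\t", index=False)
        record("catalog", out / "catalog.tsv", out / "distribution.tsv")
    except Exception as exc:
        raise RuntimeError(f"stage 'catalog' failed: {exc}") from exc

    # ---- stage 2: abundance (gene reads -> normalized -> enzyme aggregation)
    try:
        reads = generate_gene_read_table(config.n_genes, seed=config.seed + 1)
        g = normalize_genes(reads)
        rng = np.random.default_rng(config.seed + 2)
        gene2enzyme = {
            gid: ENZYMES[int(rng.integers(0, len(ENZYMES)))]
            for gid in g.index
            if rng.random() < 0.8
        }
        agg, unmapped = aggregate(g, gene2enzyme)
        g.to_csv(out / "gene_abundance.tsv", sep="\t", header=True)
        agg.to_frame().assign(unmapped_mass=unmapped).to_csv(
            out / "enzyme_aggregate.tsv", sep="\t"
        )
        record("abundance", out / "gene_abundance.tsv", out / "enzyme_aggregate.tsv")
    except Exception as exc:
        raise RuntimeError(f"stage 'abundance' failed: {exc}") from exc

    # ---- stage 3: taxonomy / harboring species (skippable)
    if config.skip_taxonomy:
        log.warning("stage 'taxonomy' skipped by config; downstream stages continue")
    else:
        try:
            taxo = random_taxonomy(species_matrix.values.shape[1], seed=config.seed + 3)
            hits = generate_hit_table(taxo, len(g), seed=config.seed + 4)
            gene2taxon = taxonomy.assign_gene_taxa(hits, taxo)
            harb = taxonomy.harboring_species(gene2enzyme, gene2taxon, g, taxo)
            pd.Series(gene2taxon, name="taxon_id").to_csv(
                out / "gene_taxa.tsv", sep="\t", index_label="gene_id"
            )
            harb.matrix.to_csv(out / "species_enzyme_matrix.tsv", sep="\t")
            harb.species_counts.to_csv(
                out / "enzyme_species_counts.tsv", sep="\t", header=["n_species"]
            )
            harb.excluded_genes.to_csv(out / "excluded_genes.tsv", sep="\t", index=False)
            record(
                "taxonomy",
                out / "gene_taxa.tsv",
                out / "species_enzyme_matrix.tsv",
                out / "enzyme_species_counts.tsv",
                out / "excluded_genes.tsv",
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'taxonomy' failed: {exc}") from exc

    # ---- stage 4: differential abundance
    try:
        dtab = diff.differential_table(ko_matrix, alpha=config.alpha)
        dtab.to_csv(out / "diff_results.tsv", sep="\t", index=False)
        record("diff", out / "diff_results.tsv")
    except Exception as exc:
        raise RuntimeError(f"stage 'diff' failed: {exc}") from exc

    # ---- stage 5: OR scores
    try:
        otab = orscore.or_table(ko_matrix, convention=config.or_convention)
        otab.to_csv(out / "or_scores.tsv", sep="\t", index=False)
        record("orscore", out / "or_scores.tsv")
    except Exception as exc:
        raise RuntimeError(f"stage 'orscore' failed: {exc}") from exc

    # ---- stage 6: score model (LASSO on differential KOs)
    try:
        sig = dtab.loc[dtab["direction"] != "NS", "feature_id"].tolist()
        pool = sig if len(sig) >= 2 else ko_matrix.feature_ids[:20]
        y = (ko_matrix.groups == "AF").astype(int).to_numpy()
        model = scores.lasso_select(
            ko_matrix.values[pool], y, seed=config.seed, name="KO", **config.lasso
        )
        model.to_json(out / "model_ko.json")
        sample_scores = pd.Series(
            [
                scores.evaluate_score(model, row)
                for _, row in ko_matrix.values.iterrows()
            ],
            index=ko_matrix.values.index,
            name="ko_score",
        )
        sample_scores.to_csv(out / "scores.tsv", sep="\t", index_label="sample_id")
        roc = scores.roc_auc(sample_scores.to_numpy(), y)
        with open(out / "roc.json", "w") as fh:
            json.dump(
                {"auc": roc.auc, "ci_low": roc.ci_low, "ci_high": roc.ci_high,
                 "p": roc.p},
                fh, indent=2,
            )
        record("scores", out / "model_ko.json", out / "scores.tsv", out / "roc.json")
    except Exception as exc:
        raise RuntimeError(f"stage 'scores' failed: {exc}") from exc

    # ---- stage 7: mediation (diversity -> hsCRP -> LA diameter)
    try:
        med = mediation.bootstrap_mediation(
            clinical["diversity"], clinical["hsCRP"], clinical["LA_diameter"],
            B=config.bootstrap_B, seed=config.seed,
        )
        with open(out / "mediation.json", "w") as fh:
            json.dump(med.to_dict(), fh, indent=2)
        record("mediation", out / "mediation.json")
    except Exception as exc:
        raise RuntimeError(f"stage 'mediation' failed: {exc}") from exc

    # ---- stage 8: associations (species network + logistic models)
    try:
        net_table = species_matrix.values.copy()
        net_table["ko_score"] = sample_scores
        edges = assoc.spearman_network(
            net_table, r_threshold=config.r_threshold, alpha=config.alpha
        )
        edges.to_csv(out / "edges.tsv", sep="\t", index=False)
        preds = pd.DataFrame(
            {"age": clinical["age"], "BMI": clinical["BMI"], "ko_score": sample_scores}
        )
        try:
            logit = assoc.logistic_fit(y, preds, univariable=False)
        except ValueError as exc:
            log.warning("logistic fit degenerate (%s); univariable fallback", exc)
            logit = assoc.logistic_fit(y, preds[["age", "BMI"]], univariable=True)
        logit.to_csv(out / "logistic_results.tsv", sep="\t", index=False)
        record("association", out / "edges.tsv", out / "logistic_results.tsv")
    except Exception as exc:
        raise RuntimeError(f"stage 'association' failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
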