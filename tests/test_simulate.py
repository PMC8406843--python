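import json

import numpy as np
import pandas as pd
import pytest

from scfamet.simulate import (
    CohortConfig,
    generate_cohort,
    generate_gene_read_table,
    generate_hit_table,
    random_taxonomy,
)


class TestCohortConfig:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_ctr", 0),
            ("n_af", -1),
            ("n_ko", 0),
            ("species_count", 0),
            ("noise_sd", -0.1),
            ("harboring_matrix_density", 1.5),
        ],
    )
    def test_invalid_field_named_in_error(self, field, value):
        cfg = CohortConfig(**{field: value})
        with pytest.raises(ValueError, match=field):
            cfg.validate()

    def test_n_diff_exceeds_n_ko(self):
        with pytest.raises(ValueError, match="n_diff"):
            CohortConfig(n_ko=10, n_diff=11).validate()

    def test_missing_path_key(self):
        with pytest.raises(ValueError, match="c_direct"):
            CohortConfig(mediation_paths={"a": 1, "b": 1}).validate()


class TestGenerateCohort:
    def test_rows_close_to_simplex(self):
        cohort = generate_cohort(CohortConfig(seed=1))
        sums = cohort.abundances.values.sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)
        np.testing.assert_allclose(
            cohort.species_abundances.values.sum(axis=1), 1.0, atol=1e-9
        )

    def test_group_labels(self):
        cohort = generate_cohort(CohortConfig(n_ctr=3, n_af=4, seed=0))
        assert cohort.abundances.groups.value_counts().to_dict() == {"AF": 4, "CTR": 3}

    def test_deterministic_byte_identical(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_cohort(CohortConfig(seed=7)).to_dir(d1)
        generate_cohort(CohortConfig(seed=7)).to_dir(d2)
        for f in d1.iterdir():
            assert f.read_bytes() == (d2 / f.name).read_bytes(), f.name

    def test_different_seed_differs(self):
        a = generate_cohort(CohortConfig(seed=1)).abundances.values
        b = generate_cohort(CohortConfig(seed=2)).abundances.values
        assert not a.equals(b)

    def test_planted_mean_ratio_before_renormalization(self):
        # with many samples, the planted group-mean ratio approaches 2^log2fc;
        # closure shifts it slightly, so test on the compositional ratio of a
        # planted KO against an unplanted reference
        cfg = CohortConfig(n_ctr=2000, n_af=2000, n_ko=50, n_diff=5, seed=3)
        cohort = generate_cohort(cfg)
        vals = cohort.abundances.values
        groups = cohort.abundances.groups
        planted = list(cohort.truth.diff_ko_log2fc)[0]
        reference = cohort.abundances.feature_ids[-1]  # unplanted
        ratio = vals[planted] / vals[reference]
        fc = ratio[groups == "AF"].mean() / ratio[groups == "CTR"].mean()
        assert np.log2(fc) == pytest.approx(1.0, abs=0.1)

    def test_null_case_no_planted_difference(self):
        cfg = CohortConfig(n_diff=0, noise_sd=0.0, seed=5)
        cohort = generate_cohort(cfg)
        assert cohort.truth.diff_ko_log2fc == {}
        from scfamet.diff import differential_table

        table = differential_table(cohort.abundances)
        assert (table["q"] < 0.05).mean() <= 0.05

    def test_enzyme_abundance_is_species_times_copies(self):
        cohort = generate_cohort(CohortConfig(seed=9))
        expected = (
            cohort.species_abundances.values.to_numpy()
            @ cohort.truth.harboring_matrix.to_numpy()
        )
        np.testing.assert_allclose(
            cohort.enzyme_abundances.values.to_numpy(), expected, atol=1e-12
        )

    def test_truth_vaf_invariant(self):
        cohort = generate_cohort(CohortConfig(seed=0))
        p = cohort.truth.true_paths
        expected = p["a"] * p["b"] / (p["a"] * p["b"] + p["c_direct"])
        assert cohort.truth.true_vaf == pytest.approx(expected, abs=1e-12)

    def test_mediation_recovery_large_n(self):
        # averaged over seeds: the per-fit sampling error of VAF at this n is
        # ~0.03 (collinearity between X and M), so a single draw is too noisy
        from scfamet.mediation import fit_mediation

        errs = []
        for seed in (11, 12, 13):
            cfg = CohortConfig(n_ctr=2500, n_af=2500, n_ko=20, noise_sd=0.5, seed=seed)
            cohort = generate_cohort(cfg)
            fit = fit_mediation(
                cohort.clinical["diversity"],
                cohort.clinical["hsCRP"],
                cohort.clinical["LA_diameter"],
            )
            errs.append(fit.vaf - cohort.truth.true_vaf)
        assert abs(np.mean(errs)) < 0.05

    def test_truth_json_written(self, tmp_path):
        generate_cohort(CohortConfig(seed=2)).to_dir(tmp_path)
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert set(truth) >= {
            "diff_ko_log2fc", "harboring_matrix", "true_paths", "true_vaf",
        }


class TestGeneReadTable:
    def test_single_row(self):
        assert len(generate_gene_read_table(1, seed=0)) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_low_count_gene_present(self, seed):
        t = generate_gene_read_table(50, seed=seed)
        assert (t["read_count"] < 2).any()

    def test_deterministic(self):
        t1 = generate_gene_read_table(100, seed=4)
        t2 = generate_gene_read_table(100, seed=4)
        pd.testing.assert_frame_equal(t1, t2)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            generate_gene_read_table(0)


class TestHitTable:
    def test_every_gene_has_hits(self):
        taxo = random_taxonomy(10, seed=0)
        hits = generate_hit_table(taxo, 5, seed=0)
        assert set(hits["gene_id"]) == {f"g{i:05d}" for i in range(5)}
        assert (hits.groupby("gene_id").size() >= 1).all()

    def test_evalues_span_retention_boundary(self):
        taxo = random_taxonomy(10, seed=0)
        hits = generate_hit_table(taxo, 200, seed=1)
        ratios = hits.groupby("gene_id")["e_value"].apply(lambda e: e.max() / e.min())
        assert (ratios > 10).any() and (ratios <= 10).any()

    def test_taxa_are_leaves(self):
        taxo = random_taxonomy(8, seed=2)
        hits = generate_hit_table(taxo, 20, seed=2)
        assert set(hits["taxon_id"]) <= set(taxo.leaves())

    def test_deterministic(self):
        taxo = random_taxonomy(10, seed=0)
        h1 = generate_hit_table(taxo, 30, seed=9)
        h2 = generate_hit_table(taxo, 30, seed=9)
        pd.testing.assert_frame_equal(h1, h2)


def test_random_taxonomy_is_rooted_with_species_leaves():
    taxo = random_taxonomy(20, seed=1)
    assert taxo.root == "t_root"
    leaves = taxo.leaves()
    assert all(taxo.rank[leaf] in ("species", "genus") for leaf in leaves)
    assert sum(1 for t in taxo.parent if taxo.rank[t] == "species") == 20
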