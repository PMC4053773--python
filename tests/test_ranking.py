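import numpy as np
import pandas as pd
import pytest

from conftest import make_matrix
from mirti import ranking as R
from mirti.datamodel import DomainError, ExpressionMatrix, SampleAnnotation
from mirti.simulate import (
    SyntheticConfig,
    make_reference,
    simulate_clinical,
    simulate_expression_cohort,
    simulate_gene_sets,
)
from mirti.correlation import family_expression
from mirti.preprocess import compute_rrf


class TestRankEvidence:
    def test_best_in_every_column_tops(self, rng):
        n = 20
        evidence = pd.DataFrame(
            rng.uniform(0.05, 1.0, size=(n, 2)),
            index=[f"f{i}" for i in range(n)],
            columns=["a", "b"],
        )
        evidence.loc["f1"] = [0.001, 0.002]
        out = R.rank_evidence(evidence, B=199, seed=0)
        assert out.index[0] == "f1"
        assert out.loc["f1", "combined_score"] == 1.0
        # P(permuted mean rank <= 1) = 1/n^2; p stays above the add-one floor
        assert 1 / 200 <= out.loc["f1", "rank_test_p"] <= 0.05

    def test_all_identical_pvalues_tie(self):
        evidence = pd.DataFrame({"a": [0.5] * 4, "b": [0.5] * 4}, index=list("wxyz"))
        out = R.rank_evidence(evidence, B=99, seed=0)
        assert (out["combined_score"] == 2.5).all()

    def test_missing_values_get_worst_rank(self):
        evidence = pd.DataFrame(
            {"a": [0.1, np.nan, 0.2], "b": [0.5, 0.4, 0.3]}, index=["f1", "f2", "f3"]
        )
        out = R.rank_evidence(evidence, B=99, seed=0)
        assert out.loc["f2", "rank_a"] == 3.0

    def test_all_missing_family_excluded(self):
        evidence = pd.DataFrame(
            {"a": [0.1, np.nan, 0.2], "b": [0.3, np.nan, 0.1]}, index=["f1", "f2", "f3"]
        )
        with pytest.warns(UserWarning, match="f2"):
            out = R.rank_evidence(evidence, B=99, seed=0)
        assert "f2" not in out.index

    def test_planted_signal_columns_recovered(self, rng):
        n = 20
        planted = {"f0", "f1", "f2"}
        hits = 0
        for rep in range(20):
            evidence = pd.DataFrame(
                rng.uniform(size=(n, 3)),
                index=[f"f{i}" for i in range(n)],
                columns=["a", "b", "c"],
            )
            for fam in planted:
                evidence.loc[fam] = rng.uniform(0, 0.01, size=3)
            out = R.rank_evidence(evidence, B=99, seed=rep)
            hits += set(out.index[:3]) == planted
        assert hits >= 18

    def test_relabeling_is_consistent(self, rng):
        evidence = pd.DataFrame(
            rng.uniform(size=(6, 2)), index=list("abcdef"), columns=["u", "v"]
        )
        renamed = evidence.rename(index=str.upper)
        out = R.rank_evidence(evidence, B=99, seed=4)
        out_renamed = R.rank_evidence(renamed, B=99, seed=4)
        np.testing.assert_allclose(
            out["combined_score"].to_numpy(),
            out_renamed.rename(index=str.lower)["combined_score"].reindex(out.index),
        )


class TestComparePvalueGroups:
    def test_identical_groups_centered(self):
        t, p = R.compare_pvalue_groups([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(0.5)

    def test_shifted_group_detected(self, rng):
        base = rng.uniform(0.01, 1.0, size=30)
        flagged = base * 10**-2.0  # two -log10 units lower p
        t, p = R.compare_pvalue_groups(flagged, base)
        assert p < 0.01

    def test_small_group_errors(self):
        with pytest.raises(DomainError):
            R.compare_pvalue_groups([0.1], [0.2, 0.3])


@pytest.fixture(scope="module")
def planted_world():
    config = SyntheticConfig(
        seed=77,
        n_genes=120,
        n_families=12,
        samples_per_subtype={"basal-like": 120},
        n_gene_sets=12,
    )
    reference = make_reference(config)
    mirna, mrna, annotation = simulate_expression_cohort(config, reference)
    annotation = simulate_clinical(config, reference.truth, mrna, annotation)
    fam_expr = family_expression(compute_rrf(mirna), reference.families)
    gene_sets, cgc = simulate_gene_sets(config, reference.truth, list(reference.transcripts))
    mp_map = {f: set(g) for f, g in reference.truth.target_map.items()}
    return config, reference, fam_expr, mrna, annotation, gene_sets, cgc, mp_map


class TestAssociateSets:
    def test_planted_targets_give_smallest_p(self, planted_world):
        _, reference, fam_expr, mrna, _, gene_sets, _, mp_map = planted_world
        active = reference.truth.active["basal-like"][0]
        sets = dict(gene_sets)
        sets["OWN_TARGETS"] = sorted(mp_map[active])
        assoc = R.associate_sets(fam_expr, mrna, sets, mp_map, B=199, seed=1)
        fam_assoc = assoc[assoc["family_id"] == active].set_index("set_id")
        assert fam_assoc.loc["OWN_TARGETS", "p_value"] <= fam_assoc["p_value"].min() + 1e-12

    def test_flag_definition_and_bh_monotone(self, planted_world):
        _, _, fam_expr, mrna, _, gene_sets, _, mp_map = planted_world
        assoc = R.associate_sets(fam_expr, mrna, gene_sets, mp_map, B=99, seed=2)
        for _, row in assoc.iterrows():
            members = set(gene_sets[row["set_id"]])
            expected = bool(mp_map.get(row["family_id"], set()) & members)
            assert row["contains_mp_pclip"] == expected
        for _, block in assoc.groupby("family_id"):
            ordered = block.sort_values("p_value")
            assert ordered["bh_q"].is_monotonic_increasing


class TestActivityRanking:
    def test_three_column_evidence_and_recovery(self, planted_world):
        _, reference, fam_expr, mrna, annotation, gene_sets, cgc, mp_map = planted_world
        samples = annotation.samples_in_subtype("basal-like")
        out = R.activity_ranking(
            fam_expr, mrna, mp_map, gene_sets, cgc, B=199, seed=0, sample_ids=samples
        )
        assert {"rank_targets", "rank_pathway", "rank_cgc"} <= set(out.columns)
        assert set(out.index[:3]) == set(reference.truth.active["basal-like"])

    def test_family_without_targets_excluded(self, planted_world):
        _, _, fam_expr, mrna, annotation, gene_sets, cgc, mp_map = planted_world
        crippled = dict(mp_map)
        victim = fam_expr.entity_ids[0]
        crippled[victim] = set()
        with pytest.warns(UserWarning, match=victim):
            out = R.activity_ranking(
                fam_expr, mrna, crippled, gene_sets, cgc, B=99, seed=0,
                sample_ids=annotation.samples_in_subtype("basal-like"),
            )
        assert victim not in out.index


class TestPhenotypeRanking:
    def test_six_columns_when_fully_annotated(self, planted_world):
        _, _, fam_expr, mrna, annotation, _, _, mp_map = planted_world
        out = R.phenotype_ranking(fam_expr, mrna, mp_map, annotation, B=99, seed=0)
        rank_cols = [c for c in out.columns if c.startswith("rank_") and c != "rank_test_p"]
        assert len(rank_cols) == 6

    def test_dropped_column_reduces_width(self, planted_world):
        _, _, fam_expr, mrna, annotation, _, _, mp_map = planted_world
        table = annotation.table.copy()
        table["lymph_node_positive"] = 1  # no variation -> dropped
        out = R.phenotype_ranking(
            fam_expr, mrna, mp_map, SampleAnnotation(table), B=99, seed=0
        )
        rank_cols = [c for c in out.columns if c.startswith("rank_") and c != "rank_test_p"]
        assert len(rank_cols) == 5

    def test_survival_driver_tops_survival_column(self, planted_world):
        _, reference, fam_expr, mrna, annotation, _, _, mp_map = planted_world
        out = R.phenotype_ranking(fam_expr, mrna, mp_map, annotation, B=199, seed=0)
        driver = reference.truth.survival_family
        assert out.loc[driver, "rank_time_overall_survival"] == out[
            "rank_time_overall_survival"
        ].min()


class TestSurvivalSignature:
    def test_planted_hazard_detected(self, planted_world):
        _, reference, fam_expr, mrna, annotation, _, _, mp_map = planted_world
        fam = reference.truth.survival_family
        table = annotation.table
        sig = R.survival_signature(
            fam, fam_expr, sorted(mp_map[fam]), mrna,
            table["time_overall_survival"].to_numpy(),
            table["event_overall_survival"].to_numpy(),
            list(table.index), B=499, seed=0,
        )
        assert sig.gt.p_perm < 0.05
        assert sig.gene_list == sorted(mp_map[fam])

    def test_adjusted_mode_uses_clinical_null(self, planted_world):
        _, reference, fam_expr, mrna, annotation, _, _, mp_map = planted_world
        fam = reference.truth.survival_family
        table = annotation.table
        clinical = table[["grade", "tumor_size_class", "lymph_node_positive"]]
        sig = R.survival_signature(
            fam, fam_expr, sorted(mp_map[fam]), mrna,
            table["time_overall_survival"].to_numpy(),
            table["event_overall_survival"].to_numpy(),
            list(table.index), clinical=clinical, B=199, seed=0,
        )
        assert sig.adjusted
        assert sig.clinical_covariates == ["grade", "tumor_size_class", "lymph_node_positive"]
        assert 0 < sig.gt.p_perm <= 1

    def test_too_few_events_errors(self, planted_world):
        _, reference, fam_expr, mrna, annotation, _, _, mp_map = planted_world
        fam = reference.truth.survival_family
        table = annotation.table
        with pytest.raises(DomainError, match="events"):
            R.survival_signature(
                fam, fam_expr, sorted(mp_map[fam]), mrna,
                table["time_overall_survival"].to_numpy(),
                np.zeros(len(table)),
                list(table.index), B=99, seed=0,
            )

    def test_grade_only_hazard_vanishes_after_adjustment(self, rng):
        # hazard driven purely by an observed clinical covariate: the adjusted
        # test should find no residual signature association
        n = 150
        grade = rng.integers(0, 3, n)
        hazard = 0.1 * np.exp(0.9 * grade)
        times = rng.exponential(1 / hazard)
        censor = rng.uniform(0, 15, n)
        observed = np.minimum(times, censor)
        events = (times <= censor).astype(float)
        samples = [f"s{i}" for i in range(n)]
        mrna = make_matrix(rng.normal(size=(10, n)), "mrna", "a_value", prefix="g",
                           samples=samples)
        fam_expr = make_matrix(rng.normal(size=(1, n)), "mirna", "rrf_family",
                               prefix="f", samples=samples)
        clinical = pd.DataFrame({"grade": grade.astype(float)}, index=samples)
        rejections = 0
        for rep in range(10):
            sig = R.survival_signature(
                "f0", fam_expr, [f"g{i}" for i in range(10)], mrna,
                observed, events, samples, clinical=clinical, B=199, seed=rep,
            )
            rejections += sig.gt.p_perm <= 0.05
        assert rejections <= 2
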