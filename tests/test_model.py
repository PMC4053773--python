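import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from oracles import irls_ridge_logistic
from mirti import model as M
from mirti.datamodel import DomainError


def _prediction_rows(pairs):
    rows = []
    for family_id, gene_id in pairs:
        rows.append(
            {
                "family_id": family_id,
                "gene_id": gene_id,
                "aggregate_pct": 0.3,
                "total_context_score": -0.2,
                "n_cons_7mer_m8": 1,
                "n_cons_7mer_1a": 0,
                "n_cons_8mer": 0,
                "n_noncons_7mer_m8": 0,
                "n_noncons_7mer_1a": 1,
                "n_noncons_8mer": 0,
                "n_conserved_sites": 1,
                "n_nonconserved_sites": 1,
                "conserved_flag": 1,
            }
        )
    return pd.DataFrame(rows)


class TestAssembleAndLabel:
    def test_hand_counted_fixture(self):
        predictions = _prediction_rows(
            [
                ("F1", "g1"), ("F1", "g2"), ("F2", "g1"),          # positives
                ("F1", "g3"), ("F1", "g4"), ("F2", "g2"),          # negatives
                ("F2", "g3"), ("F2", "g4"),                        # negatives
                ("F1", "g7"), ("F2", "g7"),                        # not crosslinked
                ("F3", "g1"),                                      # family not expressed
                ("F1", "g9"),                                      # gene not expressed
            ]
        )
        labeled = M.assemble_and_label(
            predictions,
            parclip_pairs={("F1", "g1"), ("F1", "g2"), ("F2", "g1")},
            crosslinked_genes={"g1", "g2", "g3", "g4"},
            expressed_families={"F1", "F2"},
            expressed_genes={"g1", "g2", "g3", "g4", "g7"},
        )
        assert len(labeled) == 8
        assert labeled["label"].sum() == 3
        assert "g7" not in set(labeled["gene_id"])

    def test_all_one_class_errors(self):
        predictions = _prediction_rows([("F1", "g1"), ("F1", "g2")])
        with pytest.raises(DomainError):
            M.assemble_and_label(
                predictions,
                parclip_pairs=set(),
                crosslinked_genes={"g1", "g2"},
                expressed_families={"F1"},
                expressed_genes={"g1", "g2"},
            )


class TestSplit:
    def _pairs(self, n=100, n_pos=20):
        table = _prediction_rows([("F1", f"g{i}") for i in range(n)])
        table["label"] = [1] * n_pos + [0] * (n - n_pos)
        return table

    def test_stratification_arithmetic(self):
        split = M.split_train_test(self._pairs(), train_fraction=0.5, seed=0)
        train = split[split["split"] == "train"]
        assert len(train) == 50
        assert train["label"].sum() == 10

    def test_deterministic_given_seed(self):
        a = M.split_train_test(self._pairs(), seed=3)
        b = M.split_train_test(self._pairs(), seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_partition(self):
        split = M.split_train_test(self._pairs(), seed=1)
        assert set(split["split"]) == {"train", "test"}
        assert len(split) == 100

    def test_tiny_class_errors(self):
        with pytest.raises(DomainError):
            M.split_train_test(self._pairs(n=5, n_pos=1), seed=0)


def _feature_frame(X, y):
    frame = pd.DataFrame(X, columns=list(M.FEATURE_NAMES)[: X.shape[1]])
    frame["label"] = y
    return frame


class TestElasticNet:
    def test_infinite_lambda_gives_exact_null_model(self, rng):
        X = rng.normal(size=(80, 4))
        y = (rng.random(80) < 0.3).astype(int)
        frame = _feature_frame(X, y)
        fit = M.fit_elastic_net(
            frame, alpha=0.5, lambda_grid=[np.inf], cv_folds=3, seed=0,
            feature_names=tuple(frame.columns[:-1]),
        )
        assert all(c == 0.0 for c in fit.coefficients.values())
        assert fit.intercept == pytest.approx(float(logit(y.mean())))
        post = fit.predict_posterior(frame)
        np.testing.assert_allclose(post, y.mean(), rtol=1e-12)

    def test_ridge_limit_matches_irls_oracle(self, rng):
        n, lam = 120, 0.05
        X = rng.normal(size=(n, 3))
        beta_true = np.array([1.0, -0.5, 0.0])
        y = (rng.random(n) < 1 / (1 + np.exp(-(X @ beta_true)))).astype(int)
        frame = _feature_frame(X, y)
        fit = M.fit_elastic_net(
            frame, alpha=0.0, lambda_grid=[lam], cv_folds=3, seed=0,
            feature_names=tuple(frame.columns[:-1]),
        )
        Xs = (X - X.mean(axis=0)) / X.std(axis=0)
        intercept, beta = irls_ridge_logistic(Xs, y, lam)
        np.testing.assert_allclose(
            list(fit.coefficients.values()), beta, atol=2e-3
        )
        assert fit.intercept == pytest.approx(intercept, abs=2e-3)

    def test_separable_data_high_auc(self, rng):
        X = rng.normal(size=(300, 4))
        y = (X[:, 0] > 0).astype(int)
        frame = _feature_frame(X, y)
        frame["split"] = "train"
        fit = M.fit_elastic_net(
            frame, alpha=0.5, cv_folds=3, seed=0,
            feature_names=tuple(frame.columns[:-2]),
        )
        auc = M.rank_auc(y, fit.predict_posterior(frame))
        assert auc >= 0.99

    def test_zero_variance_feature_dropped(self, rng):
        X = rng.normal(size=(60, 3))
        X[:, 2] = 1.0
        y = (rng.random(60) < 0.5).astype(int)
        frame = _feature_frame(X, y)
        with pytest.warns(UserWarning, match="zero-variance"):
            fit = M.fit_elastic_net(
                frame, alpha=0.5, lambda_grid=[0.1], cv_folds=3, seed=0,
                feature_names=tuple(frame.columns[:-1]),
            )
        assert len(fit.coefficients) == 2

    def test_json_round_trip(self, tmp_path, rng):
        X = rng.normal(size=(60, 3))
        y = (rng.random(60) < 0.5).astype(int)
        frame = _feature_frame(X, y)
        fit = M.fit_elastic_net(frame, alpha=0.5, lambda_grid=[0.1], cv_folds=3, seed=0,
                                feature_names=tuple(frame.columns[:-1]))
        path = tmp_path / "model.json"
        fit.to_json(path)
        back = M.ElasticNetModel.from_json(path)
        np.testing.assert_allclose(back.predict_posterior(frame), fit.predict_posterior(frame))


class TestEvaluation:
    def test_perfect_ordering_auc_one(self):
        assert M.rank_auc(np.array([1, 1, 0, 0]), np.array([0.9, 0.8, 0.2, 0.1])) == 1.0

    def test_ppv_direct_count(self, rng):
        # posteriors {0.9 pos, 0.8 pos, 0.6 neg, 0.2 neg} at cutoff 0.5 -> PPV 2/3
        frame = _feature_frame(rng.normal(size=(4, 2)), [1, 1, 0, 0])
        frame["split"] = "test"

        class FixedModel:
            def predict_posterior(self, pairs):
                return np.array([0.9, 0.8, 0.6, 0.2])[: len(pairs)]

        frame_train = frame.copy()
        frame_train["split"] = "train"
        both = pd.concat([frame_train, frame], ignore_index=True)

        report = M.evaluate_model(FixedModel(), both, cutoff=0.5)
        assert report.fdr_at_cutoff == pytest.approx(1 / 3)

    def test_random_scores_auc_near_half(self, rng):
        y = rng.integers(0, 2, size=2000)
        scores = rng.random(2000)
        assert 0.46 <= M.rank_auc(y, scores) <= 0.54

    def test_midrank_ties_match_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        y = rng.integers(0, 2, size=300)
        scores = rng.integers(0, 5, size=300).astype(float)  # heavy ties
        assert M.rank_auc(y, scores) == pytest.approx(roc_auc_score(y, scores))


class TestSelection:
    def _model_and_candidates(self, posteriors):
        class FixedModel:
            def predict_posterior(self, pairs):
                return np.asarray(posteriors)[: len(pairs)]

        candidates = _prediction_rows([("F1", f"g{i}") for i in range(len(posteriors))])
        return FixedModel(), candidates

    def test_cutoff_above_one_returns_parclip_only(self):
        model, candidates = self._model_and_candidates([0.9, 0.8, 0.7])
        parclip = {("F1", "gX"), ("F1", "g0")}
        out = M.select_mp_pclip(model, candidates, parclip, cutoff=1.01)
        assert set(zip(out["family_id"], out["gene_id"])) == parclip

    def test_set_arithmetic(self):
        posteriors = [0.9] * 10
        model, candidates = self._model_and_candidates(posteriors)
        parclip = {("F1", f"g{i}") for i in range(4)}
        out = M.select_mp_pclip(model, candidates, parclip, cutoff=0.5)
        counts = M.mp_pclip_counts(out)
        assert counts["n_additional"] == 6
        assert counts["n_parclip_supported"] == 4
        assert counts["n_total"] == 10

    def test_tags_partition_union(self):
        model, candidates = self._model_and_candidates([0.9, 0.1, 0.7])
        parclip = {("F1", "g1"), ("F1", "g5")}
        out = M.select_mp_pclip(model, candidates, parclip, cutoff=0.5)
        assert not out.duplicated(["family_id", "gene_id"]).any()
        assert set(out["source"]) <= {"parclip", "model", "both"}

    def test_monotone_in_cutoff(self, rng):
        posteriors = rng.random(30)
        model, candidates = self._model_and_candidates(posteriors)
        parclip = {("F1", "g0")}
        previous = None
        for cutoff in (0.2, 0.5, 0.8):
            out = M.select_mp_pclip(model, candidates, parclip, cutoff=cutoff)
            keys = set(zip(out["family_id"], out["gene_id"]))
            if previous is not None:
                assert keys <= previous
            previous = keys


class TestUnivariate:
    def test_feature_equal_to_label(self, rng):
        frame = _feature_frame(rng.normal(size=(50, 2)), rng.integers(0, 2, 50))
        frame["aggregate_pct"] = frame["label"].astype(float)
        out = M.univariate_feature_assoc(frame, feature_names=("aggregate_pct",))
        assert out.loc[0, "correlation"] == pytest.approx(1.0)

    def test_independent_feature_small_correlation(self, rng):
        frame = _feature_frame(rng.normal(size=(2000, 1)), rng.integers(0, 2, 2000))
        out = M.univariate_feature_assoc(frame, feature_names=("aggregate_pct",))
        assert abs(out.loc[0, "correlation"]) < 0.07

    def test_one_row_per_feature(self, rng):
        frame = pd.DataFrame(
            rng.normal(size=(40, len(M.FEATURE_NAMES))), columns=list(M.FEATURE_NAMES)
        )
        frame["label"] = rng.integers(0, 2, 40)
        out = M.univariate_feature_assoc(frame)
        assert len(out) == 16

    def test_zero_variance_reported_na(self, rng):
        frame = _feature_frame(np.ones((30, 1)), rng.integers(0, 2, 30))
        out = M.univariate_feature_assoc(frame, feature_names=("aggregate_pct",))
        assert np.isnan(out.loc[0, "correlation"])
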