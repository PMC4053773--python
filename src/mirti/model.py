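"""Elastic-net classifier for "PAR-CLIP-like" miRNA-target interactions.

Biochemical binding-site data covers only interactions expressed in the
profiled cell line.  To extend it, candidate (family, gene) prediction pairs
whose gene carries crosslinking evidence are labeled positive when a PAR-CLIP
seed-matched site exists for the pair and negative otherwise, and a binomial
elastic net (LASSO/ridge mixture) is fit on 16 features: four TargetScan-style
scores/counts, six per-site-type counts, four expression moments and two
miRNA-x-mRNA interaction terms.  Pairs without crosslink support are excluded
from training but scored at prediction time; the union of PAR-CLIP pairs and
pairs above a posterior cutoff forms the MP-PCLIP target set.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from statsmodels.stats.multitest import multipletests

from mirti.datamodel import DomainError, ExpressionMatrix, SITE_COUNT_COLUMNS

FEATURE_NAMES = (
    "aggregate_pct",
    "total_context_score",
    "n_conserved_sites",
    "n_nonconserved_sites",
    *SITE_COUNT_COLUMNS,
    "mirna_mean_abundance",
    "mirna_variance",
    "mrna_mean_abundance",
    "mrna_variance",
    "interaction_signed",
    "interaction_unsigned",
)


def assemble_and_label(
    predictions: pd.DataFrame,
    parclip_pairs: set[tuple[str, str]],
    crosslinked_genes: set[str],
    expressed_families: set[str],
    expressed_genes: set[str],
    family_expr: ExpressionMatrix | None = None,
    mrna_expr: ExpressionMatrix | None = None,
    mrna_log2fc: ExpressionMatrix | None = None,
) -> pd.DataFrame:
    """Build the labeled candidate table from a prediction table.

    Candidates are predictions whose family and gene pass the expression
    thresholds and whose gene is crosslinked; the label is positive iff a
    PAR-CLIP seed-matched site exists for the (family, gene) pair.  Expression
    features (means/variances and interaction terms) are attached from the
    patient matrices; the signed interaction term multiplies by the sign of
    the gene's mean log2 fold-change (+1 when no fold-change data exists, as
    for sequencing cohorts).
    """
    table = predictions.copy()
    keep = (
        table["family_id"].isin(expressed_families)
        & table["gene_id"].isin(expressed_genes)
        & table["gene_id"].isin(crosslinked_genes)
    )
    table = table.loc[keep].reset_index(drop=True)

    keys = list(zip(table["family_id"], table["gene_id"]))
    table["label"] = [int(key in parclip_pairs) for key in keys]

    def _moments(expr: ExpressionMatrix | None, ids: pd.Series) -> tuple[np.ndarray, np.ndarray]:
        if expr is None:
            return np.zeros(len(ids)), np.zeros(len(ids))
        mean = expr.data.mean(axis=1)
        var = expr.data.var(axis=1, ddof=1)
        return (
            ids.map(mean).fillna(0.0).to_numpy(),
            ids.map(var).fillna(0.0).to_numpy(),
        )

    mirna_mean, mirna_var = _moments(family_expr, table["family_id"])
    mrna_mean, mrna_var = _moments(mrna_expr, table["gene_id"])
    table["mirna_mean_abundance"] = mirna_mean
    table["mirna_variance"] = mirna_var
    table["mrna_mean_abundance"] = mrna_mean
    table["mrna_variance"] = mrna_var
    if mrna_log2fc is not None:
        sign = np.sign(table["gene_id"].map(mrna_log2fc.data.mean(axis=1)).fillna(0.0))
        sign = sign.replace(0, 1).to_numpy()
    else:
        sign = np.ones(len(table))
    table["interaction_unsigned"] = mirna_mean * mrna_mean
    table["interaction_signed"] = table["interaction_unsigned"] * sign

    n_pos = int(table["label"].sum())
    n_neg = len(table) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DomainError(
            f"model unfittable: {n_pos} positives / {n_neg} negatives after filtering"
        )
    return table


def split_train_test(
    pairs: pd.DataFrame, train_fraction: float = 0.5, seed: int = 0
) -> pd.DataFrame:
    """Stratified random train/test split; adds a ``split`` column."""
    counts = pairs["label"].value_counts()
    if (counts < 2).any() or len(counts) < 2:
        raise DomainError("need >= 2 pairs per class for a stratified split")
    train_idx, test_idx = train_test_split(
        pairs.index,
        train_size=train_fraction,
        stratify=pairs["label"],
        random_state=seed,
        shuffle=True,
    )
    out = pairs.copy()
    out["split"] = "test"
    out.loc[train_idx, "split"] = "train"
    return out


@dataclass
class ElasticNetModel:
    """Fitted binomial elastic net with its standardization transform."""

    coefficients: dict[str, float]
    intercept: float
    alpha: float
    lam: float
    feature_means: dict[str, float]
    feature_sds: dict[str, float]
    cv_seed: int
    lambda_grid: list[float] = field(default_factory=list)
    cv_deviance: list[float] = field(default_factory=list)

    @property
    def feature_names(self) -> list[str]:
        return list(self.coefficients.keys())

    def coefficients_original_scale(self) -> dict[str, float]:
        """Back-transform standardized coefficients to the raw feature scale."""
        return {
            name: self.coefficients[name] / self.feature_sds[name]
            for name in self.coefficients
        }

    def _design(self, pairs: pd.DataFrame) -> np.ndarray:
        cols = []
        for name in self.feature_names:
            x = pairs[name].to_numpy(dtype=float)
            cols.append((x - self.feature_means[name]) / self.feature_sds[name])
        return np.column_stack(cols)

    def predict_posterior(self, pairs: pd.DataFrame) -> np.ndarray:
        beta = np.array([self.coefficients[n] for n in self.feature_names])
        return expit(self._design(pairs) @ beta + self.intercept)

    def to_json(self, path) -> None:
        with open(path, "w") as handle:
            json.dump(
                {
                    "coefficients": self.coefficients,
                    "intercept": self.intercept,
                    "alpha": self.alpha,
                    "lambda": self.lam,
                    "feature_means": self.feature_means,
                    "feature_sds": self.feature_sds,
                    "cv_seed": self.cv_seed,
                    "lambda_grid": self.lambda_grid,
                    "cv_deviance": self.cv_deviance,
                },
                handle,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "ElasticNetModel":
        with open(path) as handle:
            blob = json.load(handle)
        blob["lam"] = blob.pop("lambda")
        return cls(**blob)


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2 * (y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


def _sklearn_fit(X: np.ndarray, y: np.ndarray, alpha: float, lam: float):
    n = len(y)
    clf = LogisticRegression(
        l1_ratio=float(alpha),
        C=1.0 / (n * lam),
        solver="saga",
        max_iter=5000,
        tol=1e-7,
        random_state=0,
    )
    clf.fit(X, y)
    return clf


def default_lambda_grid(X: np.ndarray, y: np.ndarray, alpha: float, n_lambda: int = 15) -> list[float]:
    """glmnet-style grid: log-spaced from the smallest lambda zeroing all
    coefficients down to 1e-3 of it."""
    n = len(y)
    resid = y - y.mean()
    lam_max = np.abs(X.T @ resid).max() / (n * max(alpha, 1e-3))
    lam_max = max(lam_max, 1e-6)
    return list(np.geomspace(lam_max, lam_max * 1e-3, n_lambda))


def fit_elastic_net(
    pairs: pd.DataFrame,
    alpha: float = 0.5,
    lambda_grid: list[float] | None = None,
    cv_folds: int = 10,
    seed: int = 0,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
) -> ElasticNetModel:
    """Fit a binomial elastic net on standardized features.

    ``lambda`` is chosen by ``cv_folds``-fold stratified CV minimizing held-out
    binomial deviance over the grid.  Zero-variance features are dropped with a
    warning.  ``lambda = inf`` yields the analytic null model (all coefficients
    zero, intercept = logit of class prevalence).
    """
    y = pairs["label"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise DomainError("both classes must be present to fit")

    means, sds, kept = {}, {}, []
    for name in feature_names:
        x = pairs[name].to_numpy(dtype=float)
        sd = x.std(ddof=0)
        if sd == 0:
            warnings.warn(f"dropping zero-variance feature {name}")
            continue
        means[name], sds[name] = float(x.mean()), float(sd)
        kept.append(name)
    X = np.column_stack(
        [(pairs[n].to_numpy(dtype=float) - means[n]) / sds[n] for n in kept]
    )

    if lambda_grid is None:
        lambda_grid = default_lambda_grid(X, y, alpha)

    prevalence = y.mean()
    null_intercept = float(logit(prevalence))

    finite = [lam for lam in lambda_grid if np.isfinite(lam)]
    cv_dev = {lam: 0.0 for lam in lambda_grid}
    if finite:
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        folds = list(skf.split(X, y))
        for lam in lambda_grid:
            devs = []
            for train, test in folds:
                if np.isfinite(lam):
                    clf = _sklearn_fit(X[train], y[train], alpha, lam)
                    p = clf.predict_proba(X[test])[:, 1]
                else:
                    p = np.full(len(test), y[train].mean())
                devs.append(_binomial_deviance(y[test], p))
            cv_dev[lam] = float(np.mean(devs))
        best_lam = min(lambda_grid, key=lambda lam: cv_dev[lam])
    else:
        best_lam = lambda_grid[0]

    if np.isfinite(best_lam):
        clf = _sklearn_fit(X, y, alpha, best_lam)
        coefs = dict(zip(kept, clf.coef_[0].astype(float)))
        intercept = float(clf.intercept_[0])
    else:
        coefs = {n: 0.0 for n in kept}
        intercept = null_intercept

    return ElasticNetModel(
        coefficients=coefs,
        intercept=intercept,
        alpha=alpha,
        lam=float(best_lam),
        feature_means=means,
        feature_sds=sds,
        cv_seed=seed,
        lambda_grid=[float(l) for l in lambda_grid],
        cv_deviance=[cv_dev[l] for l in lambda_grid],
    )


def rank_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the rank statistic (midranks for ties)."""
    labels = np.asarray(labels, dtype=float)
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DomainError("AUC needs both classes")
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class EvalReport:
    """AUCs and the PPV-vs-posterior-cutoff curve (FDR = 1 - PPV)."""

    auc_train: float
    auc_test: float
    ppv_curve: pd.DataFrame
    fdr_at_cutoff: float
    cutoff: float


def evaluate_model(
    model: ElasticNetModel,
    pairs: pd.DataFrame,
    cutoff: float = 0.5,
    cutoff_grid: np.ndarray | None = None,
) -> EvalReport:
    """Train/test AUC plus PPV as a function of the posterior cutoff (on test)."""
    if cutoff_grid is None:
        cutoff_grid = np.linspace(0.05, 0.95, 19)
    reports = {}
    for split in ("train", "test"):
        sub = pairs[pairs["split"] == split] if "split" in pairs else pairs
        if sub.empty:
            raise DomainError(f"no pairs in split {split}")
        y = sub["label"].to_numpy()
        if len(np.unique(y)) < 2:
            raise DomainError(f"single-class evaluation set in split {split}")
        reports[split] = (y, model.predict_posterior(sub))

    y_test, p_test = reports["test"]
    rows = []
    for c in cutoff_grid:
        called = p_test >= c
        tp = int((y_test[called] == 1).sum())
        ppv = tp / called.sum() if called.any() else np.nan
        rows.append({"cutoff": c, "n_called": int(called.sum()), "ppv": ppv})
    ppv_curve = pd.DataFrame(rows)

    called = p_test >= cutoff
    tp = int((y_test[called] == 1).sum())
    ppv_at = tp / called.sum() if called.any() else np.nan
    return EvalReport(
        auc_train=rank_auc(*reports["train"]),
        auc_test=rank_auc(*reports["test"]),
        ppv_curve=ppv_curve,
        fdr_at_cutoff=float(1 - ppv_at) if np.isfinite(ppv_at) else np.nan,
        cutoff=cutoff,
    )


def select_mp_pclip(
    model: ElasticNetModel,
    candidates: pd.DataFrame,
    parclip_pairs: set[tuple[str, str]],
    cutoff: float = 0.5,
) -> pd.DataFrame:
    """MP-PCLIP set: union of PAR-CLIP pairs and model calls at ``cutoff``.

    Candidates may include pairs without crosslink support; each selected pair
    is tagged parclip / model / both.  Returns columns family_id, gene_id,
    posterior, source.
    """
    scored = candidates[["family_id", "gene_id"]].copy()
    scored["posterior"] = model.predict_posterior(candidates)
    predicted = scored[scored["posterior"] >= cutoff]

    rows = {}
    for _, row in predicted.iterrows():
        key = (row["family_id"], row["gene_id"])
        rows[key] = {"posterior": row["posterior"], "source": "model"}
    for key in parclip_pairs:
        if key in rows:
            rows[key]["source"] = "both"
        else:
            rows[key] = {"posterior": np.nan, "source": "parclip"}

    out = pd.DataFrame(
        [
            {"family_id": f, "gene_id": g, **vals}
            for (f, g), vals in sorted(rows.items())
        ]
    )
    if out.empty:
        out = pd.DataFrame(columns=["family_id", "gene_id", "posterior", "source"])
    return out


def mp_pclip_counts(selection: pd.DataFrame) -> dict[str, int]:
    source = selection["source"]
    n_parclip = int((source != "model").sum())
    n_model = int((source != "parclip").sum())
    return {
        "n_total": len(selection),
        "n_parclip_supported": int((source == "both").sum()),
        "n_parclip_only": int((source == "parclip").sum()),
        "n_additional": int((source == "model").sum()),
        "n_predicted": n_model,
        "n_parclip": n_parclip,
    }


def univariate_feature_assoc(
    pairs: pd.DataFrame, feature_names: tuple[str, ...] = FEATURE_NAMES
) -> pd.DataFrame:
    """Point-biserial correlation of each feature with the label, BH-corrected."""
    from scipy.stats import pearsonr

    y = pairs["label"].to_numpy(dtype=float)
    rows = []
    for name in feature_names:
        x = pairs[name].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            rows.append({"feature": name, "correlation": np.nan, "p_value": np.nan})
            continue
        r, p = pearsonr(x, y)
        rows.append({"feature": name, "correlation": float(r), "p_value": float(p)})
    table = pd.DataFrame(rows)
    valid = table["p_value"].notna()
    q = np.full(len(table), np.nan)
    if valid.any():
        q[valid.to_numpy()] = multipletests(table.loc[valid, "p_value"], method="fdr_bh")[1]
    table["bh_q"] = q
    return table
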