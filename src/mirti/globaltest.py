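"""Permutation-calibrated Global Test for gene-set association.

The Global Test asks whether a group of covariates (a gene set's expression)
is jointly associated with a response (a miRNA's expression, a clinical
phenotype, or survival).  We use the score-type quadratic statistic

    Q = (1/m) * sum_j (x_j' r)^2

where ``r`` are residuals of the response under the intercept-only null model
and ``x_j`` are the m standardized covariates.  The null model depends on the
response family:

* linear      — centered continuous response;
* logistic    — y - mean(y) for a binary response;
* multinomial — stacked one-vs-rest logistic residuals (Q sums over classes);
* cox         — martingale residuals ``delta_i - H(t_i)`` from the
                Nelson-Aalen cumulative hazard.

Significance is by permutation of sample labels with the add-one rule
p = (1 + #{Q_b >= Q}) / (B + 1); at small n all n! permutations can be
enumerated exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations as iter_permutations

import numpy as np

from mirti.datamodel import DomainError


@dataclass
class GlobalTestResult:
    response_id: str
    covariate_set_id: str
    model_kind: str
    Q: float
    p_perm: float
    n_permutations: int
    n_covariates: int


MODEL_KINDS = ("linear", "logistic", "multinomial", "cox")


def _standardize_columns(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.any():
        raise DomainError("all covariates have zero variance")
    return (X[:, keep] - mean[keep]) / sd[keep]


def nelson_aalen_cumhaz(times: np.ndarray, events: np.ndarray) -> np.ndarray:
    """Nelson-Aalen cumulative hazard evaluated at each sample's own time."""
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    e_sorted = events[order]
    n = len(times)
    cumhaz_sorted = np.empty(n)
    H = 0.0
    i = 0
    while i < n:
        j = i
        while j < n and t_sorted[j] == t_sorted[i]:
            j += 1
        d = e_sorted[i:j].sum()
        at_risk = n - i
        H += d / at_risk
        cumhaz_sorted[i:j] = H
        i = j
    out = np.empty(n)
    out[order] = cumhaz_sorted
    return out


def null_residuals(
    response: np.ndarray, model_kind: str, events: np.ndarray | None = None
) -> np.ndarray:
    """Residual matrix (n x c) under the intercept-only null model."""
    if model_kind == "linear":
        y = np.asarray(response, dtype=float)
        return (y - y.mean())[:, None]
    if model_kind == "logistic":
        y = np.asarray(response, dtype=float)
        classes = np.unique(y)
        if len(classes) != 2:
            raise DomainError(f"logistic response needs two classes, got {len(classes)}")
        y01 = (y == classes.max()).astype(float)
        return (y01 - y01.mean())[:, None]
    if model_kind == "multinomial":
        y = np.asarray(response)
        classes = np.unique(y)
        if len(classes) < 2:
            raise DomainError("multinomial response needs >= 2 classes")
        cols = []
        for c in classes:
            ind = (y == c).astype(float)
            cols.append(ind - ind.mean())
        return np.column_stack(cols)
    if model_kind == "cox":
        times = np.asarray(response, dtype=float)
        if events is None:
            raise DomainError("cox response needs an event indicator")
        events = np.asarray(events, dtype=float)
        if (times < 0).any():
            raise DomainError("survival times must be non-negative")
        if events.sum() == 0:
            raise DomainError("cox response has no events")
        return (events - nelson_aalen_cumhaz(times, events))[:, None]
    raise DomainError(f"unknown model kind {model_kind!r}")


def _quadratic_stat(X_std: np.ndarray, residuals: np.ndarray) -> float:
    m = X_std.shape[1]
    return float(((X_std.T @ residuals) ** 2).sum() / m)


def global_test(
    response,
    X,
    model_kind: str = "linear",
    B: int = 9999,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    events=None,
    exhaustive: bool = False,
    response_id: str = "",
    covariate_set_id: str = "",
    residuals: np.ndarray | None = None,
) -> GlobalTestResult:
    """Permutation Global Test of ``response`` against covariate matrix ``X``.

    ``X`` is n x m (samples x covariates) and is standardized internally.
    ``exhaustive=True`` enumerates all n! sample permutations (n <= 8) and
    reports the exact permutation p; otherwise B Monte-Carlo permutations with
    the add-one rule.  Pre-computed ``residuals`` may be supplied (adjusted
    survival mode passes residuals of a clinical Cox null model).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n < 3:
        raise DomainError("need >= 3 samples")
    if residuals is None:
        residuals = null_residuals(np.asarray(response), model_kind, events=events)
    if residuals.ndim == 1:
        residuals = residuals[:, None]
    if residuals.shape[0] != n:
        raise DomainError("residual / covariate dimension mismatch")
    X_std = _standardize_columns(X)
    m = X_std.shape[1]

    Q = _quadratic_stat(X_std, residuals)
    tol = 1e-12 * max(1.0, abs(Q))

    if exhaustive:
        if n > 8:
            raise DomainError("exhaustive enumeration limited to n <= 8")
        count = 0
        total = 0
        for perm in iter_permutations(range(n)):
            Qb = _quadratic_stat(X_std, residuals[list(perm)])
            count += Qb >= Q - tol
            total += 1
        p = count / total
        n_perm = total
    else:
        rng = np.random.default_rng(seed) if rng is None else rng
        # all residual columns are permuted jointly (rows of the matrix)
        perm_idx = np.argsort(rng.random((B, n)), axis=1)
        XtR = np.tensordot(residuals[perm_idx], X_std, axes=([1], [0]))  # B x c x m
        Qb = (XtR**2).sum(axis=(1, 2)) / m
        p = (1 + int((Qb >= Q - tol).sum())) / (B + 1)
        n_perm = B

    return GlobalTestResult(
        response_id=response_id,
        covariate_set_id=covariate_set_id,
        model_kind=model_kind,
        Q=Q,
        p_perm=float(p),
        n_permutations=n_perm,
        n_covariates=m,
    )


def exhaustive_permutation_count(n: int) -> int:
    return math.factorial(n)
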