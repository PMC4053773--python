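"""Gene-set association, evidence-rank aggregation and prognostic signatures.

miRNA regulatory activity is prioritized by combining three Global-Test
evidence sources per family — association with its own MP-PCLIP targets, the
best association among KEGG-style pathways containing at least one MP-PCLIP
target, and association with a cancer-gene set — into an equal-weight mean
rank with permutation significance.  A second ranking uses phenotype
associations (logistic for node status and lymphovascular invasion,
multinomial for tumor size and grade, Cox for metastasis and survival).
Target prognostic signatures are Cox-mode Global Tests of a family plus its
targets against survival, optionally adjusted for clinical covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from mirti.datamodel import DomainError, ExpressionMatrix, SampleAnnotation
from mirti.globaltest import GlobalTestResult, global_test, null_residuals


def associate_sets(
    family_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    gene_sets: dict[str, list[str]],
    mp_pclip_map: dict[str, set[str]],
    B: int = 999,
    seed: int = 0,
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Global Test of each family's expression against each gene set.

    Response = family expression (linear), covariates = expressed set members.
    BH correction runs across sets within each family.  Each association is
    flagged when the set contains at least one MP-PCLIP target of the family,
    and the Pearson correlation signs of those targets are attached.
    """
    shared = sample_ids if sample_ids is not None else [
        s for s in family_expr.sample_ids if s in set(mrna_expr.sample_ids)
    ]
    expressed = set(mrna_expr.entity_ids)
    rng = np.random.default_rng(seed)

    usable_sets = {}
    for set_id, genes in gene_sets.items():
        members = [g for g in genes if g in expressed]
        if not members:
            warnings.warn(f"gene set {set_id} has no expressed member; skipped")
            continue
        usable_sets[set_id] = members

    rows = []
    for family_id in family_expr.entity_ids:
        y = family_expr.data.loc[family_id, shared].to_numpy(dtype=float)
        targets = mp_pclip_map.get(family_id, set())
        family_rows = []
        for set_id, members in usable_sets.items():
            X = mrna_expr.data.loc[members, shared].to_numpy(dtype=float).T
            gt = global_test(
                y,
                X,
                model_kind="linear",
                B=B,
                rng=rng,
                response_id=family_id,
                covariate_set_id=set_id,
            )
            in_set_targets = sorted(targets & set(members))
            signs = []
            for gene in in_set_targets:
                g = mrna_expr.data.loc[gene, shared].to_numpy(dtype=float)
                if g.std() > 0 and y.std() > 0:
                    signs.append(int(np.sign(np.corrcoef(y, g)[0, 1])))
                else:
                    signs.append(0)
            family_rows.append(
                {
                    "family_id": family_id,
                    "set_id": set_id,
                    "Q": gt.Q,
                    "p_value": gt.p_perm,
                    "contains_mp_pclip": bool(in_set_targets),
                    "mp_pclip_targets": ",".join(in_set_targets),
                    "target_signs": ",".join(str(s) for s in signs),
                }
            )
        if family_rows:
            block = pd.DataFrame(family_rows)
            block["bh_q"] = multipletests(block["p_value"], method="fdr_bh")[1]
            rows.append(block)
    if not rows:
        raise DomainError("no testable (family, gene set) pair")
    return pd.concat(rows, ignore_index=True)


def compare_pvalue_groups(
    p_with_flag: np.ndarray, p_without_flag: np.ndarray
) -> tuple[float, float]:
    """One-sided Welch t-test on -log10 p: flagged associations more significant."""
    a = -np.log10(np.asarray(p_with_flag, dtype=float))
    b = -np.log10(np.asarray(p_without_flag, dtype=float))
    if len(a) < 2 or len(b) < 2:
        raise DomainError("need >= 2 p-values per group")
    t, p = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
    return float(t), float(p)


@dataclass
class EvidenceRank:
    family_id: str
    per_source_ranks: dict[str, float]
    combined_score: float
    rank_test_p: float


def rank_evidence(
    evidence: pd.DataFrame, B: int = 999, seed: int = 0
) -> pd.DataFrame:
    """Equal-weight mean-rank aggregation of per-family evidence p-values.

    Within each column families are ranked ascending by p (ties get average
    ranks, missing values the worst rank).  The combined score is the
    unweighted mean rank; significance comes from B permutations shuffling
    each column's values across families independently, with
    rank_test_p = (1 + #{permuted score <= observed}) / (B + 1).
    Families missing every evidence source are excluded with a warning.
    """
    if evidence.shape[0] < 2:
        raise DomainError("need >= 2 families to rank")
    if evidence.shape[1] < 1:
        raise DomainError("need >= 1 evidence column")
    all_missing = evidence.isna().all(axis=1)
    if all_missing.any():
        warnings.warn(
            f"excluding families with no evidence: {list(evidence.index[all_missing])}"
        )
        evidence = evidence.loc[~all_missing]
    n = len(evidence)
    rng = np.random.default_rng(seed)

    def column_ranks(col: pd.Series) -> np.ndarray:
        ranks = col.rank(method="average", na_option="keep")
        return ranks.fillna(float(n)).to_numpy()

    rank_mat = np.column_stack([column_ranks(evidence[c]) for c in evidence.columns])
    observed = rank_mat.mean(axis=1)

    at_or_below = np.zeros(n, dtype=np.int64)
    for _ in range(B):
        permuted = np.column_stack(
            [rank_mat[rng.permutation(n), j] for j in range(rank_mat.shape[1])]
        )
        at_or_below += permuted.mean(axis=1) <= observed
    p = (1 + at_or_below) / (B + 1)

    out = pd.DataFrame(
        {
            **{f"rank_{c}": rank_mat[:, j] for j, c in enumerate(evidence.columns)},
            "combined_score": observed,
            "rank_test_p": p,
        },
        index=evidence.index,
    )
    return out.sort_values(["combined_score", "rank_test_p"]).rename_axis("family_id")


def activity_ranking(
    family_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    mp_pclip_map: dict[str, set[str]],
    gene_sets: dict[str, list[str]],
    cgc_genes: list[str],
    B: int = 999,
    seed: int = 0,
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Rank families by regulatory activity from three GT evidence sources.

    Columns of the evidence matrix: (1) GT of the family against its MP-PCLIP
    targets; (2) minimum GT p over gene sets containing >= 1 MP-PCLIP target
    of the family; (3) GT against the cancer-gene set.  Families without any
    expressed MP-PCLIP target are excluded.
    """
    shared = sample_ids if sample_ids is not None else [
        s for s in family_expr.sample_ids if s in set(mrna_expr.sample_ids)
    ]
    expressed = set(mrna_expr.entity_ids)
    rng = np.random.default_rng(seed)

    assoc = associate_sets(
        family_expr, mrna_expr, gene_sets, mp_pclip_map, B=B, seed=seed + 1,
        sample_ids=shared,
    )
    cgc_members = [g for g in cgc_genes if g in expressed]

    rows = {}
    for family_id in family_expr.entity_ids:
        targets = sorted(mp_pclip_map.get(family_id, set()) & expressed)
        if not targets:
            warnings.warn(f"family {family_id} has no expressed MP-PCLIP target; excluded")
            continue
        y = family_expr.data.loc[family_id, shared].to_numpy(dtype=float)

        X_t = mrna_expr.data.loc[targets, shared].to_numpy(dtype=float).T
        p_targets = global_test(y, X_t, "linear", B=B, rng=rng).p_perm

        fam_assoc = assoc[(assoc["family_id"] == family_id) & assoc["contains_mp_pclip"]]
        p_pathway = float(fam_assoc["p_value"].min()) if not fam_assoc.empty else np.nan

        if cgc_members:
            X_c = mrna_expr.data.loc[cgc_members, shared].to_numpy(dtype=float).T
            p_cgc = global_test(y, X_c, "linear", B=B, rng=rng).p_perm
        else:
            p_cgc = np.nan
        rows[family_id] = {"targets": p_targets, "pathway": p_pathway, "cgc": p_cgc}

    if len(rows) < 2:
        raise DomainError("fewer than 2 rankable families")
    evidence = pd.DataFrame.from_dict(rows, orient="index")
    return rank_evidence(evidence, B=B, seed=seed + 2)


PHENOTYPE_SPECS = (
    ("lymph_node_positive", "logistic"),
    ("lymphovascular_invasion", "logistic"),
    ("tumor_size_class", "multinomial"),
    ("grade", "multinomial"),
    ("time_to_metastasis", "cox"),
    ("time_overall_survival", "cox"),
)
_EVENT_COLUMN = {
    "time_to_metastasis": "event_metastasis",
    "time_overall_survival": "event_overall_survival",
}


def phenotype_ranking(
    family_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    target_map: dict[str, set[str]],
    annotation: SampleAnnotation,
    B: int = 999,
    seed: int = 0,
    include_mirna: bool = True,
    min_fraction_annotated: float = 0.5,
) -> pd.DataFrame:
    """Rank families by association of their target signature with phenotypes.

    Per family the covariate set is the family's expression (optional) plus
    its targets' expression; the responses are up to six phenotypes with the
    appropriate GT response family.  Phenotypes missing in more than
    ``1 - min_fraction_annotated`` of samples or without variation are dropped.
    """
    shared = [s for s in family_expr.sample_ids if s in set(mrna_expr.sample_ids)]
    shared = [s for s in shared if s in annotation.table.index]
    expressed = set(mrna_expr.entity_ids)
    rng = np.random.default_rng(seed)

    rows: dict[str, dict[str, float]] = {}
    for family_id in family_expr.entity_ids:
        targets = sorted(target_map.get(family_id, set()) & expressed)
        if not targets:
            warnings.warn(f"family {family_id} has no expressed target; excluded")
            continue
        evidence: dict[str, float] = {}
        for column, kind in PHENOTYPE_SPECS:
            if column not in annotation.table.columns:
                continue
            pheno = annotation.table.loc[shared, column]
            usable = pheno.notna()
            if kind == "cox":
                event_col = _EVENT_COLUMN[column]
                if event_col not in annotation.table.columns:
                    continue
                usable &= annotation.table.loc[shared, event_col].notna()
            samples = [s for s, ok in zip(shared, usable) if ok]
            if len(samples) < max(3, int(min_fraction_annotated * len(shared))):
                continue
            blocks = [mrna_expr.data.loc[targets, samples].to_numpy(dtype=float).T]
            if include_mirna:
                blocks.insert(
                    0, family_expr.data.loc[[family_id], samples].to_numpy(dtype=float).T
                )
            X = np.hstack(blocks)
            resp = annotation.table.loc[samples, column]
            try:
                if kind == "cox":
                    events = annotation.table.loc[samples, _EVENT_COLUMN[column]]
                    gt = global_test(
                        resp.to_numpy(dtype=float), X, "cox", B=B, rng=rng,
                        events=events.to_numpy(dtype=float),
                    )
                else:
                    if resp.nunique() < 2:
                        continue  # phenotype without variation
                    gt = global_test(resp.to_numpy(), X, kind, B=B, rng=rng)
            except DomainError:
                continue
            evidence[column] = gt.p_perm
        if evidence:
            rows[family_id] = evidence

    if len(rows) < 2:
        raise DomainError("fewer than 2 rankable families")
    evidence_mat = pd.DataFrame.from_dict(rows, orient="index")
    return rank_evidence(evidence_mat, B=B, seed=seed + 1)


@dataclass
class SurvivalSignature:
    family_id: str
    gene_list: list[str]
    gt: GlobalTestResult
    adjusted: bool = False
    clinical_covariates: list[str] = field(default_factory=list)


def survival_signature(
    family_id: str,
    family_expr: ExpressionMatrix,
    targets: list[str],
    mrna_expr: ExpressionMatrix,
    times: np.ndarray,
    events: np.ndarray,
    sample_ids: list[str],
    clinical: pd.DataFrame | None = None,
    B: int = 999,
    seed: int = 0,
    min_events: int = 10,
    include_mirna: bool = True,
) -> SurvivalSignature:
    """Cox-mode Global Test of a family-plus-targets signature against survival.

    In adjusted mode (``clinical`` given) the null-model residuals are the
    martingale residuals of a Cox fit on the clinical covariates (lifelines),
    so the GT measures association beyond grade/size/node status.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if events.sum() < min_events:
        raise DomainError(f"need >= {min_events} events, got {int(events.sum())}")
    genes = [g for g in targets if g in mrna_expr.data.index]
    if not genes:
        raise DomainError(f"no expressed target for family {family_id}")

    blocks = [mrna_expr.data.loc[genes, sample_ids].to_numpy(dtype=float).T]
    if include_mirna and family_id in family_expr.data.index:
        blocks.insert(0, family_expr.data.loc[[family_id], sample_ids].to_numpy(dtype=float).T)
    X = np.hstack(blocks)

    residuals = None
    clinical_cols: list[str] = []
    if clinical is not None:
        if clinical.isna().any().any():
            raise DomainError("clinical covariates contain missing values")
        from lifelines import CoxPHFitter

        frame = clinical.loc[sample_ids].copy()
        clinical_cols = list(frame.columns)
        frame = pd.get_dummies(frame, drop_first=True).astype(float)
        frame["time"] = times
        frame["event"] = events
        cph = CoxPHFitter(penalizer=0.01)
        cph.fit(frame, duration_col="time", event_col="event")
        martingale = cph.compute_residuals(frame, kind="martingale")
        residuals = martingale["martingale"].reindex(frame.index).to_numpy()[:, None]

    gt = global_test(
        times,
        X,
        model_kind="cox",
        B=B,
        seed=seed,
        events=events,
        residuals=residuals,
        response_id="survival",
        covariate_set_id=family_id,
    )
    return SurvivalSignature(
        family_id=family_id,
        gene_list=genes,
        gt=gt,
        adjusted=clinical is not None,
        clinical_covariates=clinical_cols,
    )


def mp_pclip_map_from_selection(selection: pd.DataFrame) -> dict[str, set[str]]:
    """Convert an MP-PCLIP selection table to a family -> target-gene map."""
    out: dict[str, set[str]] = {}
    for _, row in selection.iterrows():
        out.setdefault(row["family_id"], set()).add(row["gene_id"])
    return out


__all__ = [
    "associate_sets",
    "compare_pvalue_groups",
    "rank_evidence",
    "activity_ranking",
    "phenotype_ranking",
    "survival_signature",
    "SurvivalSignature",
    "EvidenceRank",
    "mp_pclip_map_from_selection",
    "null_residuals",
]
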