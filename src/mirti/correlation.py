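"""Correlation analysis between miRNA families and mRNAs in patient cohorts.

The central statistic compares the distribution of Pearson correlations of
(family, predicted-target) pairs against the remaining (family, gene) pairs:
if abundant miRNAs repress their targets, target correlations shift negative.
The shift is the difference of group medians; significance comes from a
two-sided Wilcoxon rank-sum test.  Abundance thresholds (miRNA RRF, mRNA A or
log-RPKM) are swept to show the shift's dependence on reliably quantified
entities; analyses repeat within molecular subtypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from mirti.datamodel import DomainError, ExpressionMatrix, IntronicHostMap, MirnaFamily, SampleAnnotation


@dataclass
class ShiftResult:
    """Difference of median correlations (targets - background) plus Wilcoxon p."""

    group_label: str
    median_target_r: float
    median_background_r: float
    median_difference: float
    wilcoxon_p: float
    n_target_pairs: int
    n_background_pairs: int


def family_expression(
    mirna_rrf: ExpressionMatrix, families: list[MirnaFamily], aggregation: str = "sum"
) -> ExpressionMatrix:
    """Aggregate member RRFs to family expression (sum preserves the RRF scale;
    ``aggregation='max'`` keeps the top member instead)."""
    if aggregation not in ("sum", "max"):
        raise DomainError(f"unknown aggregation {aggregation!r}")
    rows = {}
    for fam in families:
        members = [m for m in fam.member_ids if m in mirna_rrf.data.index]
        if not members:
            warnings.warn(f"family {fam.family_id} has no expressed member; dropped")
            continue
        block = mirna_rrf.data.loc[members]
        rows[fam.family_id] = block.sum(axis=0) if aggregation == "sum" else block.max(axis=0)
    if not rows:
        raise DomainError("no family has an expressed member")
    data = pd.DataFrame(rows).T
    data.columns = mirna_rrf.data.columns
    return ExpressionMatrix(data, "mirna", "rrf_family")


def _row_standardize(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center rows and scale to unit norm; returns (standardized, keep mask)."""
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    keep = norms > 0
    standardized = np.zeros_like(centered)
    standardized[keep] = centered[keep] / norms[keep, None]
    return standardized, keep


def pair_correlations(
    family_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    target_map: set[tuple[str, str]],
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Pearson r for every (family, gene) pair over shared samples.

    Zero-variance entities are excluded.  Returns columns family_id, gene_id,
    r, n_samples, is_target.
    """
    shared = sample_ids if sample_ids is not None else [
        s for s in family_expr.sample_ids if s in set(mrna_expr.sample_ids)
    ]
    if len(shared) < 3:
        raise DomainError(f"need >= 3 shared samples, got {len(shared)}")

    fam_vals = family_expr.data[shared].to_numpy(dtype=float)
    gene_vals = mrna_expr.data[shared].to_numpy(dtype=float)
    fam_std, fam_keep = _row_standardize(fam_vals)
    gene_std, gene_keep = _row_standardize(gene_vals)

    fam_ids = np.asarray(family_expr.entity_ids)[fam_keep]
    gene_ids = np.asarray(mrna_expr.entity_ids)[gene_keep]
    r = fam_std[fam_keep] @ gene_std[gene_keep].T
    np.clip(r, -1.0, 1.0, out=r)

    fam_col = np.repeat(fam_ids, len(gene_ids))
    gene_col = np.tile(gene_ids, len(fam_ids))
    records = pd.DataFrame(
        {
            "family_id": fam_col,
            "gene_id": gene_col,
            "r": r.ravel(),
            "n_samples": len(shared),
        }
    )
    keys = pd.MultiIndex.from_arrays([records["family_id"], records["gene_id"]])
    records["is_target"] = keys.isin(target_map)
    return records


def _wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p: exact when both groups <= 50 and tie-free, else
    normal approximation with continuity correction."""
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    if max(len(x), len(y)) <= 50 and tie_free:
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def correlation_shift(records: pd.DataFrame, group_label: str = "all") -> ShiftResult:
    """Median difference and Wilcoxon rank-sum test of target vs background r."""
    target_r = records.loc[records["is_target"], "r"].to_numpy()
    background_r = records.loc[~records["is_target"], "r"].to_numpy()
    if len(target_r) == 0 or len(background_r) == 0:
        raise DomainError("both target and background groups must be non-empty")
    med_t = float(np.median(target_r))
    med_b = float(np.median(background_r))
    return ShiftResult(
        group_label=group_label,
        median_target_r=med_t,
        median_background_r=med_b,
        median_difference=med_t - med_b,
        wilcoxon_p=_wilcoxon_rank_sum(target_r, background_r),
        n_target_pairs=len(target_r),
        n_background_pairs=len(background_r),
    )


def threshold_sweep(
    family_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    target_map: set[tuple[str, str]],
    mirna_grid: list[float],
    mrna_grid: list[float],
) -> pd.DataFrame:
    """Correlation shift at every (miRNA threshold, mRNA threshold) grid point.

    Entities are kept when their mean abundance exceeds the threshold.  Rows
    with an empty target or background group are marked invalid.
    """
    if not mirna_grid or not mrna_grid:
        raise DomainError("threshold grids must be non-empty")
    fam_mean = family_expr.data.mean(axis=1)
    mrna_mean = mrna_expr.data.mean(axis=1)
    rows = []
    for mt in mirna_grid:
        fams = list(fam_mean.index[fam_mean > mt])
        for gt in mrna_grid:
            genes = list(mrna_mean.index[mrna_mean > gt])
            row = {
                "mirna_threshold": mt,
                "mrna_threshold": gt,
                "n_mirnas": len(fams),
                "n_mrnas": len(genes),
                "median_difference": np.nan,
                "wilcoxon_p": np.nan,
                "valid": False,
            }
            if fams and genes:
                records = pair_correlations(
                    family_expr.subset_entities(fams), mrna_expr.subset_entities(genes), target_map
                )
                try:
                    shift = correlation_shift(records)
                except DomainError:
                    pass
                else:
                    row.update(
                        median_difference=shift.median_difference,
                        wilcoxon_p=shift.wilcoxon_p,
                        valid=True,
                    )
            rows.append(row)
    return pd.DataFrame(rows)


def subtype_shift(
    family_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    target_map: set[tuple[str, str]],
    annotation: SampleAnnotation,
    min_samples: int = 3,
) -> list[ShiftResult]:
    """Correlation shift computed independently within each subtype's samples."""
    results = []
    shared = [s for s in family_expr.sample_ids if s in set(mrna_expr.sample_ids)]
    subtypes = annotation.table.loc[
        [s for s in shared if s in annotation.table.index], "subtype"
    ]
    for subtype in subtypes.dropna().unique():
        samples = [s for s in shared if subtypes.get(s) == subtype]
        if len(samples) < min_samples:
            warnings.warn(f"subtype {subtype}: only {len(samples)} samples; skipped")
            continue
        records = pair_correlations(family_expr, mrna_expr, target_map, sample_ids=samples)
        results.append(correlation_shift(records, group_label=subtype))
    return results


def intronic_host_analysis(
    mirna_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    host_map: IntronicHostMap,
    n_bins: int = 4,
    n_permutations: int = 999,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Correlation of intronic miRNAs with their host genes, by abundance bin.

    Pairs are binned by miRNA mean abundance (quantile bins); reports per-pair
    r, per-bin mean r, and a one-sided permutation trend test (Jonckheere-style
    statistic: count of concordant pairs across increasing bins) for the claim
    that higher-abundance miRNAs correlate more positively with their hosts.
    """
    rng = np.random.default_rng() if rng is None else rng
    shared = [s for s in mirna_expr.sample_ids if s in set(mrna_expr.sample_ids)]
    pairs = [
        (m, g)
        for m, g in host_map.items()
        if m in mirna_expr.data.index and g in mrna_expr.data.index
    ]
    if not pairs:
        raise DomainError("no intronic miRNA / host gene pair present in both matrices")

    rows = []
    for mirna, gene in pairs:
        x = mirna_expr.data.loc[mirna, shared].to_numpy(dtype=float)
        y = mrna_expr.data.loc[gene, shared].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            continue
        rows.append(
            {
                "mirna_id": mirna,
                "host_gene_id": gene,
                "mean_abundance": float(x.mean()),
                "r": float(np.corrcoef(x, y)[0, 1]),
            }
        )
    per_pair = pd.DataFrame(rows)
    if per_pair.empty:
        raise DomainError("all intronic pairs degenerate")

    n_bins = min(n_bins, per_pair["mean_abundance"].nunique())
    per_pair["bin"] = pd.qcut(
        per_pair["mean_abundance"].rank(method="first"), n_bins, labels=False
    )
    per_bin = (
        per_pair.groupby("bin")["r"].agg(mean_r="mean", n="count").reset_index()
    )

    def jt_statistic(r: np.ndarray, bins: np.ndarray) -> float:
        stat = 0
        for lo in range(n_bins):
            for hi in range(lo + 1, n_bins):
                a, b = r[bins == lo], r[bins == hi]
                stat += (b[None, :] > a[:, None]).sum() + 0.5 * (b[None, :] == a[:, None]).sum()
        return stat

    r_vals = per_pair["r"].to_numpy()
    bins = per_pair["bin"].to_numpy()
    observed = jt_statistic(r_vals, bins)
    exceed = 0
    for _ in range(n_permutations):
        exceed += jt_statistic(r_vals, rng.permutation(bins)) >= observed
    trend_p = (1 + exceed) / (n_permutations + 1)
    return per_pair, per_bin, float(trend_p)


def rank_concordance(ranking_a: pd.Series, ranking_b: pd.Series) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) between two scorings on shared items."""
    shared = ranking_a.index.intersection(ranking_b.index)
    if len(shared) < 3:
        raise DomainError(f"need >= 3 shared items, got {len(shared)}")
    rho, p = stats.spearmanr(ranking_a.loc[shared], ranking_b.loc[shared])
    return float(rho), float(p)
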