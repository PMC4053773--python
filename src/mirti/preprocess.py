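"""Normalization and preprocessing rules applied before any correlation analysis.

These are the dataset-specific conventions of the two profiling platforms:

* two-color microarrays: abundance A = log2(sqrt(R*G)), probes condensed to
  genes when their log2 fold-change profiles agree (pairwise r > 0.8);
* small-RNA sequencing: miRNA abundance as relative read frequency (RRF),
  detection filters on raw counts;
* mRNA sequencing: RPKM, zeros imputed to the per-sample minimum non-zero
  value before log2.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from mirti.datamodel import DomainError, ExpressionMatrix, TwoColorMeasurement


def compute_a_value(m: TwoColorMeasurement) -> float:
    """Two-color abundance: log2 of the geometric mean of the two channels."""
    if not (m.R > 0 and m.G > 0):
        raise DomainError("channel intensities must be positive")
    return math.log2(math.sqrt(m.R * m.G))


def compute_rrf(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Normalize miRNA counts to relative read frequencies (per-sample sums = 1)."""
    if counts.entity_kind != "mirna":
        raise DomainError("RRF normalization applies to miRNA count matrices")
    if counts.scale != "counts":
        raise DomainError(f"expected counts, got scale={counts.scale}")
    totals = counts.data.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise DomainError(f"all-zero sample(s): {list(zero.index)}")
    return ExpressionMatrix(counts.data / totals, "mirna", "rrf")


def detection_filter(
    counts: ExpressionMatrix, min_reads: int = 10, min_sample_frac: float = 0.05
) -> list[str]:
    """Entities with count > ``min_reads`` (strict) in at least
    ``ceil(min_sample_frac * n_samples)`` samples."""
    if counts.scale != "counts":
        raise DomainError(f"detection filter needs counts, got scale={counts.scale}")
    if not (0 < min_sample_frac <= 1):
        raise DomainError("min_sample_frac must lie in (0, 1]")
    required = math.ceil(min_sample_frac * counts.n_samples)
    n_above = (counts.data > min_reads).sum(axis=1)
    return list(counts.data.index[n_above >= required])


def log_transform_rpkm(rpkm: ExpressionMatrix) -> ExpressionMatrix:
    """Per sample, replace zeros by the sample's minimum non-zero RPKM, then log2."""
    if rpkm.scale not in ("rpkm", "counts"):
        raise DomainError(f"expected linear RPKM values, got scale={rpkm.scale}")
    values = rpkm.data.to_numpy(dtype=float).copy()
    if (values < 0).any():
        raise DomainError("RPKM values must be non-negative")
    for j, sample in enumerate(rpkm.sample_ids):
        col = values[:, j]
        nonzero = col[col > 0]
        if nonzero.size == 0:
            raise DomainError(f"all-zero sample: {sample}")
        col[col == 0] = nonzero.min()
    out = pd.DataFrame(np.log2(values), index=rpkm.data.index, columns=rpkm.data.columns)
    return ExpressionMatrix(out, rpkm.entity_kind, "log2rpkm")


def condense_probes(
    probe_matrix: ExpressionMatrix,
    probe_to_gene: dict[str, str],
    r_min: float = 0.8,
) -> ExpressionMatrix:
    """Condense microarray probes to genes.

    Probes of a gene whose pairwise Pearson correlations all exceed ``r_min``
    are averaged.  Groups failing the rule keep only the probe with the highest
    mean abundance.  Zero-variance probes are excluded with a warning.
    """
    if probe_matrix.scale != "log2fc":
        raise DomainError("probe condensation operates on log2 fold-change matrices")
    unmapped = set(probe_matrix.entity_ids) - set(probe_to_gene)
    if unmapped:
        raise DomainError(f"probes without gene mapping: {sorted(unmapped)[:5]}")

    rows: dict[str, np.ndarray] = {}
    by_gene: dict[str, list[str]] = {}
    for probe in probe_matrix.entity_ids:
        by_gene.setdefault(probe_to_gene[probe], []).append(probe)

    for gene, probes in by_gene.items():
        block = probe_matrix.data.loc[probes]
        variances = block.var(axis=1, ddof=1) if block.shape[1] > 1 else block.var(axis=1)
        flat = variances[variances == 0].index.tolist()
        if flat:
            warnings.warn(f"excluding zero-variance probe(s) {flat} for gene {gene}")
            block = block.drop(index=flat)
        if block.shape[0] == 0:
            continue
        if block.shape[0] == 1:
            rows[gene] = block.iloc[0].to_numpy()
            continue
        corr = np.corrcoef(block.to_numpy())
        off_diag = corr[np.triu_indices_from(corr, k=1)]
        if (off_diag > r_min).all():
            rows[gene] = block.mean(axis=0).to_numpy()
        else:
            best = block.mean(axis=1).idxmax()
            rows[gene] = block.loc[best].to_numpy()

    out = pd.DataFrame.from_dict(rows, orient="index", columns=probe_matrix.sample_ids)
    out = out.sort_index()
    return ExpressionMatrix(out, probe_matrix.entity_kind, "log2fc")
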