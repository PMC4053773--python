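"""Synthetic cohort, PAR-CLIP library and prediction-table generator.

Every pipeline input is emitted with the statistical structure the analysis
assumes, plus a ground-truth record for recovery tests:

* a transcriptome with 5'UTR/CDS/3'UTR structure and miRNA seed families;
  8mer seed sites of each family are planted in its target genes' 3'UTRs,
  with a crosslinkable T two bases upstream;
* a patient cohort in which, within each subtype, the targets of that
  subtype's active families are repressed in proportion to the family's
  relative read frequency (log2 reduction beta per unit relative abundance);
* a PAR-CLIP read library with >= 5-read crosslinked clusters over the
  planted sites, crosslinked background clusters without seed sites, and
  sub-threshold decoy clusters, so every filter code path is exercised;
* a prediction table in which true pairs' conservation/context features are
  shifted by a configurable effect (in SD units);
* survival times from an exponential hazard scaled by a planted target
  signature, and logistic / proportional-odds phenotypes.

All outputs are deterministic functions of the configuration (including its
seed); library sizes vary per sample so RRF normalization is non-trivial.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from mirti.datamodel import (
    DomainError,
    ExpressionMatrix,
    MirnaFamily,
    SampleAnnotation,
    TranscriptModel,
)
from mirti.parclip import AlignedRead, reverse_complement, rna_to_dna

_RNA = np.array(list("ACGU"))
_DNA = np.array(list("ACGT"))


@dataclass
class SyntheticConfig:
    """Study-condition parameters for the generator.

    ``beta`` is the planted repression effect in log2 expression units per
    unit relative regulator abundance (family RRF / its subtype mean RRF);
    ``noise_sd`` is the per-sample Gaussian noise of log2 mRNA expression;
    ``feature_shift`` is the separation (in baseline SD units) of true pairs'
    conservation/context features in the prediction table; ``hazard_ratio``
    is per SD of the planted survival signature score.
    """

    n_genes: int = 200
    n_families: int = 20
    samples_per_subtype: dict[str, int] = field(
        default_factory=lambda: {"basal-like": 80, "HER2": 25, "luminal A": 25}
    )
    active_per_subtype: int = 3
    targets_per_family: int = 8
    beta: float = 1.0
    noise_sd: float = 0.25
    mirna_log_sd: float = 1.0
    mirna_sample_sd: float = 0.6
    mean_library_size: float = 5e4
    library_log_sd: float = 0.3
    utr5_len: int = 100
    cds_len: int = 300
    utr3_len: int = 400
    reads_per_cluster: int = 20
    crosslink_prob: float = 0.8
    background_clusters: int = 30
    decoy_clusters: int = 10
    feature_shift: float = 1.0
    decoy_pairs_per_family: int = 65
    n_gene_sets: int = 20
    genes_per_set: int = 15
    cgc_targets_per_family: int = 2
    cgc_extra_genes: int = 10
    baseline_hazard: float = 0.1
    hazard_ratio: float = 2.0
    censor_max: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.crosslink_prob <= 1):
            raise DomainError("crosslink_prob must lie in [0, 1]")
        for name in ("noise_sd", "mirna_log_sd", "mirna_sample_sd", "library_log_sd"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")

    def rng(self, stage: int) -> np.random.Generator:
        """Stage-tagged generator so each stage is independently deterministic."""
        return np.random.default_rng([stage, self.seed])


@dataclass
class GroundTruth:
    """What was planted: targets, active families, site coordinates, signature."""

    target_map: dict[str, list[str]]
    active: dict[str, list[str]]
    site_positions: dict[str, int]  # "family|gene" -> 8mer start (transcript coords)
    crosslink_positions: dict[str, int]  # "family|gene" -> crosslinked T position
    survival_family: str

    @staticmethod
    def key(family_id: str, gene_id: str) -> str:
        return f"{family_id}|{gene_id}"

    def pairs(self) -> set[tuple[str, str]]:
        return {(f, g) for f, genes in self.target_map.items() for g in genes}

    def to_json(self, path) -> None:
        with open(path, "w") as handle:
            json.dump(asdict(self), handle, indent=2)


@dataclass
class Reference:
    transcripts: dict[str, str]
    model: TranscriptModel
    families: list[MirnaFamily]
    truth: GroundTruth


def _random_seq(rng: np.random.Generator, length: int, alphabet=_DNA) -> str:
    return "".join(alphabet[rng.integers(0, 4, size=length)])


def make_reference(config: SyntheticConfig) -> Reference:
    """Transcriptome, families and planted target sites (deterministic)."""
    if config.n_genes < 1 or config.n_families < 1:
        raise DomainError("need at least one gene and one family")
    if config.n_families > 4**7:
        raise DomainError("more families than distinct 7-nt seeds")
    rng = config.rng(1)

    seeds: list[str] = []
    seen = set()
    while len(seeds) < config.n_families:
        seed = _random_seq(rng, 7, _RNA)
        if seed not in seen:
            seen.add(seed)
            seeds.append(seed)
    families = []
    for i, seed in enumerate(seeds):
        fam_id = f"miR-{i + 1}"
        mature = _random_seq(rng, 1, _RNA) + seed + _random_seq(rng, 14, _RNA)
        families.append(
            MirnaFamily(
                family_id=fam_id,
                member_ids=[fam_id],
                seed_2_8=seed,
                mature_sequences={fam_id: mature},
            )
        )

    gene_ids = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    tlen = config.utr5_len + config.cds_len + config.utr3_len
    transcripts = {g: list(_random_seq(rng, tlen)) for g in gene_ids}
    regions = {
        g: {
            "utr5": (0, config.utr5_len),
            "cds": (config.utr5_len, config.utr5_len + config.cds_len),
            "utr3": (config.utr5_len + config.cds_len, tlen),
        }
        for g in gene_ids
    }

    target_map: dict[str, list[str]] = {}
    site_positions: dict[str, int] = {}
    crosslink_positions: dict[str, int] = {}
    occupied: dict[str, list[tuple[int, int]]] = {g: [] for g in gene_ids}
    utr3_start = config.utr5_len + config.cds_len
    for family in families:
        site = reverse_complement(rna_to_dna(family.seed_2_8)) + "A"  # 8mer, 8 nt
        chosen = rng.choice(config.n_genes, size=config.targets_per_family, replace=False)
        targets = []
        for gi in chosen:
            gene = gene_ids[gi]
            placed = False
            for _ in range(100):
                pos = int(rng.integers(utr3_start + 5, tlen - len(site) - 2))
                # wide exclusion zone keeps read clusters of neighbouring sites
                # from merging, so each planted site gets its own CCR
                span = (pos - 45, pos + len(site) + 45)
                if all(span[1] <= s or span[0] >= e for s, e in occupied[gene]):
                    occupied[gene].append(span)
                    placed = True
                    break
            if not placed:
                warnings.warn(f"no room for a site of {family.family_id} in {gene}; skipped")
                continue
            seq = transcripts[gene]
            seq[pos : pos + len(site)] = list(site)
            seq[pos - 2] = "T"  # crosslinkable position upstream of the site
            key = GroundTruth.key(family.family_id, gene)
            site_positions[key] = pos
            crosslink_positions[key] = pos - 2
            targets.append(gene)
        target_map[family.family_id] = targets

    subtypes = list(config.samples_per_subtype)
    active: dict[str, list[str]] = {}
    fam_ids = [f.family_id for f in families]
    for subtype in subtypes:
        k = min(config.active_per_subtype, len(fam_ids))
        idx = rng.choice(len(fam_ids), size=k, replace=False)
        active[subtype] = [fam_ids[i] for i in sorted(idx)]

    truth = GroundTruth(
        target_map=target_map,
        active=active,
        site_positions=site_positions,
        crosslink_positions=crosslink_positions,
        survival_family=active[subtypes[0]][0],
    )
    return Reference(
        transcripts={g: "".join(s) for g, s in transcripts.items()},
        model=TranscriptModel(regions),
        families=families,
        truth=truth,
    )


def simulate_expression_cohort(
    config: SyntheticConfig, reference: Reference
) -> tuple[ExpressionMatrix, ExpressionMatrix, SampleAnnotation]:
    """miRNA counts, mRNA abundance (A-like log2 scale) and subtype annotation.

    miRNA counts are Poisson draws from log-normal per-sample rates scaled to
    a log-normal library size.  Within each subtype, targets of that subtype's
    active families have log2 mRNA expression reduced by
    ``beta * (family RRF / subtype mean family RRF)`` plus Gaussian noise.
    """
    rng = config.rng(2)
    truth = reference.truth
    fam_ids = [f.family_id for f in reference.families]
    gene_ids = list(reference.transcripts)

    sample_ids, subtypes = [], []
    for subtype, n in config.samples_per_subtype.items():
        for i in range(n):
            sample_ids.append(f"S_{subtype.replace(' ', '')}_{i + 1:03d}")
            subtypes.append(subtype)
    n_samples = len(sample_ids)

    base = rng.normal(0.0, config.mirna_log_sd, size=len(fam_ids))
    noise = rng.normal(0.0, config.mirna_sample_sd, size=(len(fam_ids), n_samples))
    weights = np.exp(base[:, None] + noise)
    probs = weights / weights.sum(axis=0, keepdims=True)
    libsize = np.maximum(
        1, rng.lognormal(np.log(config.mean_library_size), config.library_log_sd, n_samples)
    )
    if (libsize <= 0).any():
        raise DomainError("zero library size")
    counts = rng.poisson(probs * libsize[None, :])
    mirna = ExpressionMatrix(
        pd.DataFrame(counts, index=fam_ids, columns=sample_ids), "mirna", "counts"
    )

    col_tot = counts.sum(axis=0)
    if (col_tot == 0).any():
        raise DomainError("sample with zero miRNA reads")
    rrf = counts / col_tot

    base_expr = rng.normal(8.0, 1.0, size=len(gene_ids))
    values = base_expr[:, None] + rng.normal(0.0, config.noise_sd, size=(len(gene_ids), n_samples))
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    fam_index = {f: i for i, f in enumerate(fam_ids)}
    subtype_arr = np.asarray(subtypes)
    for subtype in config.samples_per_subtype:
        cols = np.flatnonzero(subtype_arr == subtype)
        for family_id in truth.active.get(subtype, []):
            fi = fam_index[family_id]
            fam_rrf = rrf[fi, cols]
            mean_rrf = fam_rrf.mean()
            if mean_rrf <= 0:
                continue
            relative = fam_rrf / mean_rrf
            for gene in truth.target_map.get(family_id, []):
                values[gene_index[gene], cols] -= config.beta * relative

    mrna = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids), "mrna", "a_value"
    )
    annotation = SampleAnnotation(
        pd.DataFrame({"subtype": subtypes}, index=pd.Index(sample_ids, name="sample_id"))
    )
    return mirna, mrna, annotation


def simulate_parclip_library(
    config: SyntheticConfig, reference: Reference
) -> list[AlignedRead]:
    """PAR-CLIP reads: crosslinked clusters over planted sites, crosslinked
    background clusters without sites, and sub-threshold decoy clusters."""
    rng = config.rng(3)
    truth = reference.truth
    reads: list[AlignedRead] = []
    counter = 0

    def emit_cluster(transcript_id: str, cpos: int, n_reads: int, xlink_p: float) -> None:
        nonlocal counter
        seq = reference.transcripts[transcript_id]
        for _ in range(n_reads):
            start = int(rng.integers(max(0, cpos - 15), cpos - 4))
            length = int(rng.integers(22, 31))
            end = min(start + length, len(seq))
            converted = rng.random() < xlink_p and start <= cpos < end
            read_seq = list(seq[start:end])
            t2c = ()
            if converted:
                read_seq[cpos - start] = "C"
                t2c = (cpos,)
            counter += 1
            reads.append(
                AlignedRead(
                    read_id=f"R{counter:06d}",
                    transcript_id=transcript_id,
                    start=start,
                    end=end,
                    sequence="".join(read_seq),
                    t2c_positions=t2c,
                    n_mismatches=1 if converted else 0,
                )
            )

    for family_id, genes in truth.target_map.items():
        for gene in genes:
            key = GroundTruth.key(family_id, gene)
            utr3_len_ok = key in truth.crosslink_positions
            if not utr3_len_ok:
                warnings.warn(f"no planted site for {key}; interaction skipped")
                continue
            emit_cluster(
                gene, truth.crosslink_positions[key], config.reads_per_cluster,
                config.crosslink_prob,
            )

    gene_ids = list(reference.transcripts)
    planted_genes = {g for genes in truth.target_map.values() for g in genes}
    background_pool = [g for g in gene_ids if g not in planted_genes] or gene_ids

    def random_t_position(transcript_id: str) -> int | None:
        seq = reference.transcripts[transcript_id]
        t_positions = [i for i, b in enumerate(seq) if b == "T" and 20 <= i < len(seq) - 20]
        if not t_positions:
            return None
        return t_positions[rng.integers(len(t_positions))]

    for _ in range(config.background_clusters):
        gene = background_pool[rng.integers(len(background_pool))]
        cpos = random_t_position(gene)
        if cpos is not None:
            emit_cluster(gene, cpos, config.reads_per_cluster, config.crosslink_prob)
    for _ in range(config.decoy_clusters):
        gene = gene_ids[rng.integers(len(gene_ids))]
        cpos = random_t_position(gene)
        if cpos is not None:
            emit_cluster(gene, cpos, int(rng.integers(2, 5)), config.crosslink_prob)
    return reads


def simulate_prediction_table(
    config: SyntheticConfig, truth: GroundTruth, all_genes: list[str] | None = None
) -> pd.DataFrame:
    """Prediction table: true pairs with shifted features plus decoy pairs.

    True pairs' conservation score, context score and conserved site counts
    are shifted by ``feature_shift`` baseline SDs; decoys draw from the
    baseline distributions.  Includes a ``true_pair`` ground-truth column
    (dropped by the I/O writer).
    """
    if config.feature_shift < 0:
        raise DomainError("feature_shift must be >= 0")
    rng = config.rng(4)
    shift = config.feature_shift

    rows: list[tuple[str, str, bool]] = []
    for family_id, genes in truth.target_map.items():
        for gene in genes:
            rows.append((family_id, gene, True))
    if all_genes is None:
        all_genes = sorted({g for genes in truth.target_map.values() for g in genes})
    for family_id, genes in truth.target_map.items():
        pool = [g for g in all_genes if g not in genes]
        k = min(config.decoy_pairs_per_family, len(pool))
        idx = rng.choice(len(pool), size=k, replace=False)
        for gi in sorted(idx):
            rows.append((family_id, pool[gi], False))

    n = len(rows)
    is_true = np.array([t for *_, t in rows])
    pct = rng.normal(0.35, 0.15, n) + np.where(is_true, shift * 0.15, 0.0)
    pct = np.clip(pct, 0.0, 1.0)
    context = rng.normal(-0.15, 0.10, n) - np.where(is_true, shift * 0.10, 0.0)
    cons_rate = np.where(is_true, 0.4 + shift * np.sqrt(0.4), 0.4)
    cons = rng.poisson(np.tile(cons_rate, (3, 1)))
    noncons = rng.poisson(0.8, size=(3, n))

    table = pd.DataFrame(
        {
            "family_id": [f for f, *_ in rows],
            "gene_id": [g for _, g, _ in rows],
            "aggregate_pct": pct,
            "total_context_score": context,
            "n_cons_7mer_m8": cons[0],
            "n_cons_7mer_1a": cons[1],
            "n_cons_8mer": cons[2],
            "n_noncons_7mer_m8": noncons[0],
            "n_noncons_7mer_1a": noncons[1],
            "n_noncons_8mer": noncons[2],
        }
    )
    table["n_conserved_sites"] = cons.sum(axis=0)
    table["n_nonconserved_sites"] = noncons.sum(axis=0)
    table["conserved_flag"] = (table["n_conserved_sites"] > 0).astype(int)
    table["true_pair"] = is_true
    return table


def simulate_gene_sets(
    config: SyntheticConfig, truth: GroundTruth, gene_ids: list[str]
) -> tuple[dict[str, list[str]], list[str]]:
    """Random KEGG-style gene sets plus a cancer-gene set.

    The cancer-gene set samples a couple of targets per family (cancer genes
    are enriched among miRNA targets) plus random extras, so the cancer-gene
    evidence source is informative for every family.
    """
    rng = config.rng(6)
    sets: dict[str, list[str]] = {}
    for i in range(config.n_gene_sets):
        idx = rng.choice(len(gene_ids), size=min(config.genes_per_set, len(gene_ids)), replace=False)
        sets[f"SET{i + 1:03d}"] = [gene_ids[j] for j in sorted(idx)]

    cgc: set[str] = set()
    for genes in truth.target_map.values():
        if genes:
            k = min(config.cgc_targets_per_family, len(genes))
            idx = rng.choice(len(genes), size=k, replace=False)
            cgc.update(genes[j] for j in idx)
    extra = rng.choice(len(gene_ids), size=min(config.cgc_extra_genes, len(gene_ids)), replace=False)
    cgc.update(gene_ids[j] for j in extra)
    return sets, sorted(cgc)


def simulate_clinical(
    config: SyntheticConfig,
    truth: GroundTruth,
    mrna_expr: ExpressionMatrix,
    annotation: SampleAnnotation,
) -> SampleAnnotation:
    """Survival and phenotype columns driven by the planted signature score.

    The signature score is the standardized mean expression of the survival
    family's target genes; the hazard is ``baseline * HR**score`` (exponential
    event times, uniform censoring), phenotypes use logistic /
    proportional-odds links on the same score.
    """
    if config.hazard_ratio <= 0:
        raise DomainError("hazard ratio must be positive")
    rng = config.rng(5)
    samples = mrna_expr.sample_ids
    genes = [g for g in truth.target_map[truth.survival_family] if g in mrna_expr.data.index]
    if not genes:
        raise DomainError("survival signature has no expressed gene")
    score = mrna_expr.data.loc[genes, samples].mean(axis=0).to_numpy(dtype=float)
    score = (score - score.mean()) / score.std(ddof=0)

    hazard = config.baseline_hazard * np.power(config.hazard_ratio, score)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.uniform(0, config.censor_max, len(samples))
    observed = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    meta_hazard = config.baseline_hazard * np.power(config.hazard_ratio, 0.5 * score)
    meta_time = rng.exponential(1.0 / meta_hazard)
    meta_censor = rng.uniform(0, config.censor_max, len(samples))

    def logistic_draw(strength: float) -> np.ndarray:
        p = 1.0 / (1.0 + np.exp(-strength * score))
        return (rng.random(len(samples)) < p).astype(int)

    def ordinal_draw(strength: float, labels: tuple[str, ...]) -> np.ndarray:
        latent = strength * score + rng.logistic(0, 1, len(samples))
        cuts = np.quantile(latent, [1 / 3, 2 / 3])
        return np.asarray(labels)[np.searchsorted(cuts, latent)]

    table = annotation.table.copy()
    table = table.loc[samples]
    table["lymph_node_positive"] = logistic_draw(0.8)
    table["lymphovascular_invasion"] = logistic_draw(0.5)
    table["tumor_size_class"] = ordinal_draw(0.6, ("<2", "2-5", ">5"))
    table["grade"] = ordinal_draw(0.6, ("good", "moderate", "poor"))
    table["time_to_metastasis"] = np.minimum(meta_time, meta_censor)
    table["event_metastasis"] = (meta_time <= meta_censor).astype(int)
    table["time_overall_survival"] = observed
    table["event_overall_survival"] = event
    return SampleAnnotation(table)
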