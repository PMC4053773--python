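"""End-to-end pipeline orchestration.

Stages run in order: simulate (or load inputs) -> parclip -> correlate ->
model -> associate -> rank -> survival.  Each stage reads the previous
stages' in-memory products, writes its tables under one output directory and
is deterministic given the config and seed.  A requested stage whose inputs
are missing raises before any computation starts.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from mirti import correlation, io, model as model_mod, parclip as pc, ranking
from mirti.datamodel import DomainError
from mirti.preprocess import compute_rrf, detection_filter
from mirti.simulate import (
    Reference,
    SyntheticConfig,
    make_reference,
    simulate_clinical,
    simulate_expression_cohort,
    simulate_gene_sets,
    simulate_parclip_library,
    simulate_prediction_table,
)

logger = logging.getLogger("mirti")

ALL_STAGES = ("simulate", "parclip", "correlate", "model", "associate", "rank", "survival")

DEFAULT_THRESHOLDS = {"mirna_rrf": 1e-4, "mrna_a": 6.5}

_STAGE_REQUIRES = {
    "parclip": ("reads", "transcripts", "families", "transcript_model"),
    "correlate": ("mirna_counts", "mrna_expr", "families", "target_map", "annotation"),
    "model": ("predictions", "parclip_pairs", "crosslinked_genes"),
    "associate": ("gene_sets", "mp_pclip_map"),
    "rank": ("gene_sets", "cgc_genes", "mp_pclip_map"),
    "survival": ("annotation", "mp_pclip_map"),
}


def _check_stage_inputs(stages: list[str], config: dict) -> None:
    """Fail fast when a requested stage cannot obtain its inputs."""
    will_simulate = "simulate" in stages and "synthetic" in config
    available = set(config.get("inputs", {}))
    produced: set[str] = set()
    if will_simulate:
        produced |= {
            "reads", "transcripts", "families", "transcript_model", "mirna_counts",
            "mrna_expr", "annotation", "predictions", "gene_sets", "cgc_genes",
            "target_map",
        }
    for stage in stages:
        if stage == "simulate":
            continue
        for need in _STAGE_REQUIRES.get(stage, ()):  # derived products are checked lazily
            if need in ("parclip_pairs", "crosslinked_genes", "mp_pclip_map"):
                continue
            if need == "target_map" and "predictions" in (available | produced):
                continue
            if need not in available and need not in produced:
                raise DomainError(f"stage {stage!r} requires input {need!r}")
        if stage == "model" and "parclip" not in stages:
            raise DomainError("stage 'model' requires the 'parclip' stage")
        if stage in ("associate", "rank", "survival") and "model" not in stages:
            raise DomainError(f"stage {stage!r} requires the 'model' stage")
        if stage in ("correlate", "model") and not (
            {"mirna_counts", "mrna_expr"} <= (available | produced)
        ):
            raise DomainError(f"stage {stage!r} requires expression inputs")


def run_pipeline(config: dict, out_dir, seed: int | None = None) -> dict:
    """Run the configured stages; returns the in-memory result bundle.

    ``config`` keys: ``synthetic`` (SyntheticConfig overrides) or ``inputs``
    (file paths), ``stages`` (subset, default all), ``thresholds``,
    ``model`` (alpha/cutoff/train_fraction/cv_folds), ``globaltest`` (B),
    ``subtype`` (stratum for model/associate/rank), ``seed``.
    """
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = int(config.get("seed", 0))
    stages = [s for s in config.get("stages", ALL_STAGES) if s in ALL_STAGES]
    _check_stage_inputs(stages, config)
    thresholds = {**DEFAULT_THRESHOLDS, **config.get("thresholds", {})}
    gt_B = int(config.get("globaltest", {}).get("B", 199))
    bundle: dict = {"seed": seed}

    def timer(stage: str):
        logger.info("stage %s starting (t=%.1fs)", stage, time.time() - t0)

    # ---- simulate ----------------------------------------------------------
    if "simulate" in stages:
        timer("simulate")
        syn = dict(config.get("synthetic", {}))
        syn.setdefault("seed", seed)
        scfg = SyntheticConfig(**syn)
        reference = make_reference(scfg)
        mirna_counts, mrna_expr, annotation = simulate_expression_cohort(scfg, reference)
        reads = simulate_parclip_library(scfg, reference)
        predictions = simulate_prediction_table(
            scfg, reference.truth, all_genes=list(reference.transcripts)
        )
        gene_sets, cgc_genes = simulate_gene_sets(
            scfg, reference.truth, list(reference.transcripts)
        )
        annotation = simulate_clinical(scfg, reference.truth, mrna_expr, annotation)

        io.write_fasta(reference.transcripts, out / "transcripts.fa")
        io.write_transcript_model_bed(reference.model, out / "transcript_model.bed")
        io.write_family_table(reference.families, out / "families.tsv")
        io.write_expression_tsv(mirna_counts, out / "mirna_counts.tsv")
        io.write_expression_tsv(mrna_expr, out / "mrna_expression.tsv")
        io.write_sample_annotation(annotation, out / "sample_annotation.tsv")
        io.write_aligned_reads_tsv(reads, out / "parclip_reads.tsv")
        io.write_prediction_table(predictions.drop(columns=["true_pair"]), out / "predictions.tsv")
        io.write_gmt(gene_sets, out / "gene_sets.gmt")
        io.write_gmt({"CGC": cgc_genes}, out / "cgc.gmt")
        reference.truth.to_json(out / "ground_truth.json")

        bundle.update(
            reference=reference,
            truth=reference.truth,
            transcripts=reference.transcripts,
            transcript_model=reference.model,
            families=reference.families,
            mirna_counts=mirna_counts,
            mrna_expr=mrna_expr,
            annotation=annotation,
            reads=reads,
            predictions=predictions,
            gene_sets=gene_sets,
            cgc_genes=cgc_genes,
        )
    elif "inputs" in config:
        paths = config["inputs"]
        loaders = {
            "transcripts": lambda p: io.read_fasta(p),
            "transcript_model": lambda p: io.read_transcript_model_bed(p),
            "families": lambda p: io.read_family_table(p),
            "mirna_counts": lambda p: io.read_expression_tsv(p, "mirna", "counts"),
            "mrna_expr": lambda p: io.read_expression_tsv(p, "mrna", "a_value"),
            "annotation": lambda p: io.read_sample_annotation(p),
            "reads": lambda p: io.read_aligned_reads_tsv(p),
            "predictions": lambda p: io.read_prediction_table(p),
            "gene_sets": lambda p: io.read_gmt(p),
        }
        for key, loader in loaders.items():
            if key in paths:
                bundle[key] = loader(paths[key])
        if "cgc" in paths:
            bundle["cgc_genes"] = io.read_gmt(paths["cgc"]).get("CGC", [])

    # ---- parclip -----------------------------------------------------------
    if "parclip" in stages:
        timer("parclip")
        clusters = pc.cluster_reads(bundle["reads"])
        ccrs = [pc.extract_ccr(c, bundle["transcripts"][c.transcript_id]) for c in clusters]
        sites = pc.call_seed_sites(ccrs, bundle["families"])
        fractions, labels = pc.annotate_regions(clusters, bundle["transcript_model"])
        tid_of_ccr = {c.ccr_id: c.transcript_id for c in ccrs}
        parclip_pairs = {(s.family_id, tid_of_ccr[s.ccr_id]) for s in sites}
        crosslinked_genes = {c.transcript_id for c in clusters}

        if config.get("parclip", {}).get("kmer_enrichment", True):
            rng = np.random.default_rng([10, seed])
            kmer = pc.kmer_enrichment(
                ccrs, k=7, n_shuffles=int(config.get("parclip", {}).get("n_shuffles", 100)),
                rng=rng,
            )
            io.write_table(kmer.table.sort_values("bh_q"), out / "kmer_stats.tsv")
            bundle["kmer"] = kmer

        io.write_table(
            pd.DataFrame(
                [
                    {
                        "cluster_id": c.cluster_id,
                        "transcript_id": c.transcript_id,
                        "start": c.start,
                        "end": c.end,
                        "n_reads": c.n_reads,
                        "crosslinked_fraction": c.crosslinked_fraction,
                        "major_t2c_position": c.major_t2c_position,
                        "region": labels[c.cluster_id],
                    }
                    for c in clusters
                ]
            ),
            out / "clusters.tsv",
        )
        io.write_table(
            pd.DataFrame(
                [
                    {
                        "ccr_id": c.ccr_id,
                        "transcript_id": c.transcript_id,
                        "start": c.start,
                        "end": c.end,
                        "sequence": c.sequence,
                        "truncated": c.truncated_flag,
                    }
                    for c in ccrs
                ]
            ),
            out / "ccrs.tsv",
        )
        io.write_table(
            pd.DataFrame([dataclasses.asdict(s) for s in sites]), out / "seed_sites.tsv"
        )
        io.write_table(
            fractions.rename("fraction").rename_axis("region").reset_index(),
            out / "region_fractions.tsv",
        )
        bundle.update(
            clusters=clusters,
            ccrs=ccrs,
            seed_sites=sites,
            parclip_pairs=parclip_pairs,
            crosslinked_genes=crosslinked_genes,
            region_fractions=fractions,
            conversion_rate=pc.conversion_rate(bundle["reads"]),
        )

    # ---- correlate ---------------------------------------------------------
    if "correlate" in stages:
        timer("correlate")
        counts = bundle["mirna_counts"]
        detected = detection_filter(counts, min_reads=10, min_sample_frac=0.05)
        rrf = compute_rrf(counts.subset_entities(detected) if detected else counts)
        fam_expr = correlation.family_expression(rrf, bundle["families"])
        fam_keep = fam_expr.data.mean(axis=1) > thresholds["mirna_rrf"]
        fam_expr = fam_expr.subset_entities(list(fam_expr.data.index[fam_keep]))
        mrna = bundle["mrna_expr"]
        gene_keep = mrna.data.mean(axis=1) > thresholds["mrna_a"]
        mrna_f = mrna.subset_entities(list(mrna.data.index[gene_keep]))

        preds = bundle["predictions"]
        target_map = set(zip(preds["family_id"], preds["gene_id"]))
        records = correlation.pair_correlations(fam_expr, mrna_f, target_map)
        shift = correlation.correlation_shift(records)
        by_subtype = correlation.subtype_shift(
            fam_expr, mrna_f, target_map, bundle["annotation"]
        )
        shift_table = pd.DataFrame([dataclasses.asdict(s) for s in [shift, *by_subtype]])
        io.write_table(shift_table, out / "correlation_shift.tsv")
        io.write_table(records, out / "pair_correlations.tsv")

        sweep_cfg = config.get("sweep", {})
        if sweep_cfg:
            sweep = correlation.threshold_sweep(
                fam_expr, mrna, target_map,
                sweep_cfg.get("mirna_grid", [0.0, 1e-4, 1e-3]),
                sweep_cfg.get("mrna_grid", [0.0, 6.5, 8.0]),
            )
            io.write_table(sweep, out / "threshold_sweep.tsv")
            bundle["sweep"] = sweep

        bundle.update(
            rrf=rrf,
            family_expr=fam_expr,
            mrna_filtered=mrna_f,
            target_map=target_map,
            pair_records=records,
            shift=shift,
            subtype_shifts=by_subtype,
        )

    # ---- model -------------------------------------------------------------
    if "model" in stages:
        timer("model")
        mcfg = config.get("model", {})
        labeled = model_mod.assemble_and_label(
            bundle["predictions"],
            bundle["parclip_pairs"],
            bundle["crosslinked_genes"],
            expressed_families=set(bundle["family_expr"].entity_ids),
            expressed_genes=set(bundle["mrna_filtered"].entity_ids),
            family_expr=bundle["family_expr"],
            mrna_expr=bundle["mrna_filtered"],
        )
        labeled = model_mod.split_train_test(
            labeled, train_fraction=float(mcfg.get("train_fraction", 0.5)), seed=seed
        )
        fitted = model_mod.fit_elastic_net(
            labeled[labeled["split"] == "train"],
            alpha=float(mcfg.get("alpha", 0.5)),
            cv_folds=int(mcfg.get("cv_folds", 10)),
            seed=seed,
        )
        report = model_mod.evaluate_model(fitted, labeled, cutoff=float(mcfg.get("cutoff", 0.5)))

        # score all expressed candidates, crosslinked or not: the crosslink
        # gate is lifted by passing every expressed gene as "crosslinked"
        features = model_mod.assemble_and_label(
            bundle["predictions"],
            bundle["parclip_pairs"],
            crosslinked_genes=set(bundle["mrna_filtered"].entity_ids),  # no crosslink gate
            expressed_families=set(bundle["family_expr"].entity_ids),
            expressed_genes=set(bundle["mrna_filtered"].entity_ids),
            family_expr=bundle["family_expr"],
            mrna_expr=bundle["mrna_filtered"],
        )
        selection = model_mod.select_mp_pclip(
            fitted, features, bundle["parclip_pairs"], cutoff=float(mcfg.get("cutoff", 0.5))
        )
        counts_dict = model_mod.mp_pclip_counts(selection)
        univariate = model_mod.univariate_feature_assoc(labeled)

        fitted.to_json(out / "model.json")
        io.write_table(labeled, out / "labeled_pairs.tsv")
        io.write_table(report.ppv_curve, out / "ppv_curve.tsv")
        io.write_table(selection, out / "mp_pclip.tsv")
        io.write_table(univariate, out / "univariate_features.tsv")
        io.write_table(
            pd.DataFrame(
                [
                    {
                        "auc_train": report.auc_train,
                        "auc_test": report.auc_test,
                        "fdr_at_cutoff": report.fdr_at_cutoff,
                        **counts_dict,
                    }
                ]
            ),
            out / "model_summary.tsv",
        )
        bundle.update(
            labeled_pairs=labeled,
            elastic_net=fitted,
            eval_report=report,
            mp_pclip=selection,
            mp_pclip_map=ranking.mp_pclip_map_from_selection(selection),
            univariate=univariate,
        )

    # ---- associate ---------------------------------------------------------
    if "associate" in stages:
        timer("associate")
        assoc = ranking.associate_sets(
            bundle["family_expr"],
            bundle["mrna_filtered"],
            bundle["gene_sets"],
            bundle["mp_pclip_map"],
            B=gt_B,
            seed=seed + 100,
        )
        flagged = assoc.loc[assoc["contains_mp_pclip"], "p_value"].to_numpy()
        unflagged = assoc.loc[~assoc["contains_mp_pclip"], "p_value"].to_numpy()
        if len(flagged) >= 2 and len(unflagged) >= 2:
            t_stat, t_p = ranking.compare_pvalue_groups(flagged, unflagged)
        else:
            t_stat, t_p = np.nan, np.nan
        io.write_table(assoc, out / "pathway_associations.tsv")
        io.write_table(
            pd.DataFrame([{"t_statistic": t_stat, "p_value": t_p}]),
            out / "mp_pclip_pvalue_ttest.tsv",
        )
        bundle.update(pathway_associations=assoc, pvalue_ttest=(t_stat, t_p))

    # ---- rank --------------------------------------------------------------
    if "rank" in stages:
        timer("rank")
        subtype = config.get("subtype")
        samples = (
            bundle["annotation"].samples_in_subtype(subtype) if subtype else None
        )
        activity = ranking.activity_ranking(
            bundle["family_expr"],
            bundle["mrna_filtered"],
            bundle["mp_pclip_map"],
            bundle["gene_sets"],
            bundle["cgc_genes"],
            B=gt_B,
            seed=seed + 200,
            sample_ids=samples,
        )
        io.write_table(activity.reset_index(), out / "activity_ranking.tsv")
        bundle["activity_ranking"] = activity
        if "annotation" in bundle and "time_overall_survival" in bundle["annotation"].table:
            phenotype = ranking.phenotype_ranking(
                bundle["family_expr"],
                bundle["mrna_filtered"],
                bundle["mp_pclip_map"],
                bundle["annotation"],
                B=gt_B,
                seed=seed + 300,
            )
            io.write_table(phenotype.reset_index(), out / "phenotype_ranking.tsv")
            bundle["phenotype_ranking"] = phenotype

    # ---- survival ----------------------------------------------------------
    if "survival" in stages:
        timer("survival")
        ann = bundle["annotation"].table
        if "time_overall_survival" not in ann:
            raise DomainError("survival stage requires survival annotation")
        samples = [
            s
            for s in bundle["mrna_filtered"].sample_ids
            if s in ann.index and pd.notna(ann.loc[s, "time_overall_survival"])
        ]
        rows = []
        for family_id, targets in sorted(bundle["mp_pclip_map"].items()):
            try:
                sig = ranking.survival_signature(
                    family_id,
                    bundle["family_expr"],
                    sorted(targets),
                    bundle["mrna_filtered"],
                    ann.loc[samples, "time_overall_survival"].to_numpy(dtype=float),
                    ann.loc[samples, "event_overall_survival"].to_numpy(dtype=float),
                    samples,
                    B=gt_B,
                    seed=seed + 400,
                )
            except DomainError:
                continue
            rows.append(
                {
                    "family_id": family_id,
                    "n_genes": len(sig.gene_list),
                    "genes": ",".join(sig.gene_list),
                    "Q": sig.gt.Q,
                    "p_value": sig.gt.p_perm,
                }
            )
        surv_table = pd.DataFrame(rows)
        if not surv_table.empty:
            from statsmodels.stats.multitest import multipletests

            surv_table["bh_q"] = multipletests(surv_table["p_value"], method="fdr_bh")[1]
        io.write_table(surv_table, out / "survival_signatures.tsv")
        bundle["survival_signatures"] = surv_table

    logger.info("pipeline finished in %.1fs", time.time() - t0)
    return bundle
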