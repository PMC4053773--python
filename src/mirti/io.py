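"""Readers and writers for the pipeline's file formats.

TSV with a header row for matrices, annotations and result tables; GMT for
gene sets; BED (0-based half-open) / GFF3 (1-based inclusive, converted on
ingest) for transcript models; FASTA for sequences; SAM or 7-column TSV for
PAR-CLIP reads; YAML for configs.  Every reader/writer pair round-trips.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from mirti.datamodel import (
    DomainError,
    ExpressionMatrix,
    IntronicHostMap,
    MirnaFamily,
    SampleAnnotation,
    TranscriptModel,
    validate_prediction_table,
)
from mirti.parclip import AlignedRead

# --- expression matrices ----------------------------------------------------


def read_expression_tsv(path, entity_kind: str, scale: str) -> ExpressionMatrix:
    try:
        data = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:  # surface the offending line
        raise DomainError(f"malformed expression table {path}: {exc}") from exc
    return ExpressionMatrix(data, entity_kind, scale)


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    matrix.data.rename_axis("entity_id").to_csv(path, sep="\t", float_format="%.10g")


# --- sample annotation -------------------------------------------------------


def read_sample_annotation(path) -> SampleAnnotation:
    table = pd.read_csv(path, sep="\t", index_col=0)
    return SampleAnnotation(table)


def write_sample_annotation(annotation: SampleAnnotation, path) -> None:
    annotation.table.rename_axis("sample_id").to_csv(path, sep="\t", float_format="%.10g")


# --- miRNA families ----------------------------------------------------------


def read_family_table(path) -> list[MirnaFamily]:
    """TSV columns: family_id, member_ids (comma-joined), seed_2_8,
    mature_sequences (optional, 'member:seq' comma-joined)."""
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    families = []
    for _, row in table.iterrows():
        mature = {}
        if row.get("mature_sequences", ""):
            for item in row["mature_sequences"].split(","):
                member, seq = item.split(":")
                mature[member] = seq
        families.append(
            MirnaFamily(
                family_id=row["family_id"],
                member_ids=row["member_ids"].split(","),
                seed_2_8=row["seed_2_8"],
                mature_sequences=mature,
            )
        )
    return families


def write_family_table(families: list[MirnaFamily], path) -> None:
    rows = [
        {
            "family_id": f.family_id,
            "member_ids": ",".join(f.member_ids),
            "seed_2_8": f.seed_2_8,
            "mature_sequences": ",".join(f"{m}:{s}" for m, s in f.mature_sequences.items()),
        }
        for f in families
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --- gene sets (GMT) ---------------------------------------------------------


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DomainError(f"{path}:{lineno}: GMT line needs name, description, genes")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as handle:
        for name, genes in gene_sets.items():
            handle.write("\t".join([name, description, *genes]) + "\n")


# --- transcript models (BED / GFF3) ------------------------------------------

_GFF3_REGION_FEATURES = {
    "five_prime_UTR": "utr5",
    "CDS": "cds",
    "three_prime_UTR": "utr3",
}


def read_transcript_model_bed(path) -> TranscriptModel:
    """BED: transcript_id, start, end, region in {utr5, cds, utr3}; 0-based half-open."""
    table = pd.read_csv(
        path, sep="\t", header=None, names=["transcript_id", "start", "end", "region"]
    )
    regions: dict[str, dict[str, tuple[int, int]]] = {}
    for _, row in table.iterrows():
        regions.setdefault(row["transcript_id"], {})[row["region"]] = (
            int(row["start"]),
            int(row["end"]),
        )
    return TranscriptModel(regions)


def write_transcript_model_bed(model: TranscriptModel, path) -> None:
    with open(path, "w") as handle:
        for tid in sorted(model.regions):
            for region in ("utr5", "cds", "utr3"):
                if region in model.regions[tid]:
                    s, e = model.regions[tid][region]
                    handle.write(f"{tid}\t{s}\t{e}\t{region}\n")


def read_transcript_model_gff3(path) -> TranscriptModel:
    """GFF3 with seqid = transcript id; 1-based inclusive coordinates converted."""
    regions: dict[str, dict[str, tuple[int, int]]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise DomainError(f"{path}:{lineno}: GFF3 line needs 9 fields")
            seqid, _source, ftype, start, end = fields[:5]
            if ftype not in _GFF3_REGION_FEATURES:
                continue
            region = _GFF3_REGION_FEATURES[ftype]
            regions.setdefault(seqid, {})[region] = (int(start) - 1, int(end))
    return TranscriptModel(regions)


def write_transcript_model_gff3(model: TranscriptModel, path) -> None:
    inverse = {v: k for k, v in _GFF3_REGION_FEATURES.items()}
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for tid in sorted(model.regions):
            for region in ("utr5", "cds", "utr3"):
                if region in model.regions[tid]:
                    s, e = model.regions[tid][region]
                    handle.write(
                        f"{tid}\tmirti\t{inverse[region]}\t{s + 1}\t{e}\t.\t+\t.\tID={tid}.{region}\n"
                    )


# --- sequences ---------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# --- PAR-CLIP reads ----------------------------------------------------------

READS_TSV_COLUMNS = (
    "read_id",
    "transcript_id",
    "start",
    "end",
    "sequence",
    "t2c_positions",
    "n_mismatches",
)


def read_aligned_reads_tsv(path) -> list[AlignedRead]:
    table = pd.read_csv(path, sep="\t", dtype={"t2c_positions": str}).fillna({"t2c_positions": ""})
    missing = set(READS_TSV_COLUMNS) - set(table.columns)
    if missing:
        raise DomainError(f"reads table missing columns: {sorted(missing)}")
    reads = []
    for _, row in table.iterrows():
        t2c = tuple(int(p) for p in str(row["t2c_positions"]).split(";") if p)
        reads.append(
            AlignedRead(
                read_id=row["read_id"],
                transcript_id=row["transcript_id"],
                start=int(row["start"]),
                end=int(row["end"]),
                sequence=row["sequence"],
                t2c_positions=t2c,
                n_mismatches=int(row["n_mismatches"]),
            )
        )
    return reads


def write_aligned_reads_tsv(reads: list[AlignedRead], path) -> None:
    rows = [
        {
            "read_id": r.read_id,
            "transcript_id": r.transcript_id,
            "start": r.start,
            "end": r.end,
            "sequence": r.sequence,
            "t2c_positions": ";".join(str(p) for p in r.t2c_positions),
            "n_mismatches": r.n_mismatches,
        }
        for r in reads
    ]
    pd.DataFrame(rows, columns=list(READS_TSV_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_aligned_reads_sam(path) -> list[AlignedRead]:
    """SAM aligned to transcript references; T-to-C conversions parsed from MD."""
    reads = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            t2c = []
            n_mismatch = 0
            for qpos, rpos, ref_base in aln.get_aligned_pairs(with_seq=True):
                if qpos is None or rpos is None or ref_base is None:
                    continue
                if ref_base.islower():  # pysam lowercases mismatched reference bases
                    n_mismatch += 1
                    if ref_base == "t" and aln.query_sequence[qpos].upper() == "C":
                        t2c.append(rpos)
            reads.append(
                AlignedRead(
                    read_id=aln.query_name,
                    transcript_id=aln.reference_name,
                    start=aln.reference_start,
                    end=aln.reference_end,
                    sequence=aln.query_sequence,
                    t2c_positions=tuple(t2c),
                    n_mismatches=n_mismatch,
                )
            )
    return reads


# --- target maps and prediction tables ---------------------------------------

TARGET_MAP_SOURCES = ("targetscan_conserved", "targetscan_nonconserved", "parclip", "model")


def read_target_map(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = {"family_id", "gene_id", "source"} - set(table.columns)
    if missing:
        raise DomainError(f"target map missing columns: {sorted(missing)}")
    bad = set(table["source"]) - set(TARGET_MAP_SOURCES)
    if bad:
        raise DomainError(f"unknown target map sources: {sorted(bad)}")
    return table


def write_target_map(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_prediction_table(path) -> pd.DataFrame:
    return validate_prediction_table(pd.read_csv(path, sep="\t"))


def write_prediction_table(table: pd.DataFrame, path) -> None:
    validate_prediction_table(table).to_csv(path, sep="\t", index=False)


def read_host_map(path) -> IntronicHostMap:
    table = pd.read_csv(path, sep="\t")
    if table["mirna_id"].duplicated().any():
        raise DomainError("intronic host map lists a miRNA twice")
    return IntronicHostMap(dict(zip(table["mirna_id"], table["host_gene_id"])))


def write_host_map(mapping: IntronicHostMap, path) -> None:
    pd.DataFrame(
        {"mirna_id": list(mapping.keys()), "host_gene_id": list(mapping.values())}
    ).to_csv(path, sep="\t", index=False)


# --- config ------------------------------------------------------------------


def read_config(path) -> dict:
    with open(path) as handle:
        return yaml.safe_load(handle)


def write_config(config: dict, path) -> None:
    with open(path, "w") as handle:
        yaml.safe_dump(config, handle, sort_keys=False)


def write_table(table: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=index, float_format="%.10g")
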