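"""Domain types shared by all pipeline stages.

Conventions
-----------
* All interval coordinates are 0-based half-open in memory.  BED input is taken
  as-is; GFF3 (1-based inclusive) is converted on ingest.
* Expression matrices are entities x samples, with an ``entity_kind`` tag
  (``mirna``/``mrna``) and a ``scale`` tag recording what the numbers mean:
  raw ``counts``, relative read frequencies (``rrf``), two-color array
  abundance (``a_value``), microarray ``log2fc``, or ``log2rpkm``.
* miRNA families group miRNAs sharing seed positions 2-8; the family is named
  by its lowest-numbered member and acts as one regulator throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# "rrf_family" marks per-family sums of member RRFs: same units as RRF but
# columns no longer sum to 1 (families do not partition the miRNA pool).
VALID_SCALES = ("counts", "rrf", "a_value", "log2fc", "rpkm", "log2rpkm", "rrf_family")
VALID_ENTITY_KINDS = ("mirna", "mrna")
SUBTYPES = ("basal-like", "HER2", "luminal A", "luminal B", "normal-like", "unassigned")
TUMOR_SIZE_CLASSES = ("<2", "2-5", ">5")
GRADES = ("good", "moderate", "poor")

RNA_ALPHABET = set("ACGU")
DNA_ALPHABET = set("ACGT")


class DomainError(ValueError):
    """A value violates a domain precondition."""


@dataclass
class ExpressionMatrix:
    """Entities x samples expression values with provenance tags.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by entity id, columns by sample id.
    entity_kind : {"mirna", "mrna"}
    scale : {"counts", "rrf", "a_value", "log2fc", "log2rpkm"}
    """

    data: pd.DataFrame
    entity_kind: str
    scale: str

    def __post_init__(self) -> None:
        if self.entity_kind not in VALID_ENTITY_KINDS:
            raise DomainError(f"unknown entity_kind {self.entity_kind!r}")
        if self.scale not in VALID_SCALES:
            raise DomainError(f"unknown scale {self.scale!r}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise DomainError(f"duplicate entity ids: {dupes}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise DomainError(f"duplicate sample ids: {dupes}")
        values = self.data.to_numpy()
        if self.scale == "counts":
            if values.size and (values < 0).any():
                raise DomainError("counts must be non-negative")
            if values.size and not np.allclose(values, np.round(values)):
                raise DomainError("counts must be integers")
        elif self.scale == "rrf" and values.size:
            if (values < 0).any() or (values > 1).any():
                raise DomainError("RRF values must lie in [0, 1]")
            colsums = values.sum(axis=0)
            if not np.allclose(colsums, 1.0, atol=1e-9):
                bad = self.data.columns[~np.isclose(colsums, 1.0, atol=1e-9)]
                raise DomainError(f"RRF columns must sum to 1: {list(bad)}")

    @property
    def entity_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_entities(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)], self.entity_kind, self.scale)

    def subset_entities(self, entity_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(entity_ids)], self.entity_kind, self.scale)


@dataclass(frozen=True)
class TwoColorMeasurement:
    """One two-color microarray spot: red/green fluorescence (linear scale)."""

    R: float
    G: float

    def __post_init__(self) -> None:
        if not (self.R > 0 and self.G > 0):
            raise DomainError("channel intensities must be positive")


@dataclass
class SampleAnnotation:
    """Per-sample subtype, phenotype and outcome annotation.

    Wraps a DataFrame indexed by sample id.  Recognised columns:
    ``subtype``, ``lymph_node_positive``, ``lymphovascular_invasion``,
    ``tumor_size_class``, ``grade``, ``time_to_metastasis``/``event_metastasis``,
    ``time_overall_survival``/``event_overall_survival``.  Phenotype columns are
    optional and may contain missing values; samples are dropped per-analysis,
    never globally.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise DomainError("duplicate sample ids in annotation")
        if "subtype" in self.table:
            bad = set(self.table["subtype"].dropna()) - set(SUBTYPES)
            if bad:
                raise DomainError(f"unknown subtypes: {sorted(bad)}")
        if "tumor_size_class" in self.table:
            bad = set(self.table["tumor_size_class"].dropna()) - set(TUMOR_SIZE_CLASSES)
            if bad:
                raise DomainError(f"unknown tumor size classes: {sorted(bad)}")
        if "grade" in self.table:
            bad = set(self.table["grade"].dropna()) - set(GRADES)
            if bad:
                raise DomainError(f"unknown grades: {sorted(bad)}")
        for col in ("time_to_metastasis", "time_overall_survival"):
            if col in self.table:
                times = self.table[col].dropna()
                if (times < 0).any():
                    raise DomainError(f"{col} must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def samples_in_subtype(self, subtype: str) -> list[str]:
        mask = self.table["subtype"] == subtype
        return list(self.table.index[mask])


@dataclass
class MirnaFamily:
    """A seed family: miRNAs sharing positions 2-8, named by the lowest member."""

    family_id: str
    member_ids: list[str]
    seed_2_8: str
    mature_sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.seed_2_8) != 7 or set(self.seed_2_8) - RNA_ALPHABET:
            raise DomainError(
                f"seed must be 7 nt over ACGU, got {self.seed_2_8!r} for {self.family_id}"
            )
        for member, seq in self.mature_sequences.items():
            if set(seq) - RNA_ALPHABET:
                raise DomainError(f"mature sequence of {member} not RNA")
            if seq[1:8] != self.seed_2_8:
                raise DomainError(
                    f"positions 2-8 of {member} ({seq[1:8]}) != family seed {self.seed_2_8}"
                )

    @property
    def mature_sequence(self) -> str | None:
        """Mature sequence of the name-giving member, if recorded."""
        if not self.mature_sequences:
            return None
        if self.family_id in self.mature_sequences:
            return self.mature_sequences[self.family_id]
        return next(iter(self.mature_sequences.values()))


# TargetScan-summary-style prediction tables are handled as DataFrames with
# these columns; TargetPrediction is the per-row record type.
SITE_COUNT_COLUMNS = (
    "n_cons_7mer_m8",
    "n_cons_7mer_1a",
    "n_cons_8mer",
    "n_noncons_7mer_m8",
    "n_noncons_7mer_1a",
    "n_noncons_8mer",
)
PREDICTION_COLUMNS = (
    "family_id",
    "gene_id",
    "aggregate_pct",
    "total_context_score",
    *SITE_COUNT_COLUMNS,
    "n_conserved_sites",
    "n_nonconserved_sites",
    "conserved_flag",
)


@dataclass(frozen=True)
class TargetPrediction:
    """One family-gene prediction with conservation/context scores and site counts."""

    family_id: str
    gene_id: str
    aggregate_pct: float
    total_context_score: float
    n_cons_7mer_m8: int = 0
    n_cons_7mer_1a: int = 0
    n_cons_8mer: int = 0
    n_noncons_7mer_m8: int = 0
    n_noncons_7mer_1a: int = 0
    n_noncons_8mer: int = 0
    n_conserved_sites: int = 0
    n_nonconserved_sites: int = 0
    conserved_flag: int = 0

    def __post_init__(self) -> None:
        counts = [getattr(self, c) for c in SITE_COUNT_COLUMNS]
        if any(c < 0 for c in counts):
            raise DomainError("site counts must be non-negative")
        if self.n_conserved_sites != self.n_cons_7mer_m8 + self.n_cons_7mer_1a + self.n_cons_8mer:
            raise DomainError("n_conserved_sites != sum of conserved type counts")
        if self.n_nonconserved_sites != (
            self.n_noncons_7mer_m8 + self.n_noncons_7mer_1a + self.n_noncons_8mer
        ):
            raise DomainError("n_nonconserved_sites != sum of non-conserved type counts")


def validate_prediction_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the invariants of a prediction DataFrame (see ``TargetPrediction``)."""
    missing = set(PREDICTION_COLUMNS) - set(table.columns)
    if missing:
        raise DomainError(f"prediction table missing columns: {sorted(missing)}")
    counts = table[list(SITE_COUNT_COLUMNS)].to_numpy()
    if (counts < 0).any():
        raise DomainError("site counts must be non-negative")
    cons = table[["n_cons_7mer_m8", "n_cons_7mer_1a", "n_cons_8mer"]].sum(axis=1)
    noncons = table[["n_noncons_7mer_m8", "n_noncons_7mer_1a", "n_noncons_8mer"]].sum(axis=1)
    if not (table["n_conserved_sites"] == cons).all():
        raise DomainError("n_conserved_sites != sum of conserved type counts")
    if not (table["n_nonconserved_sites"] == noncons).all():
        raise DomainError("n_nonconserved_sites != sum of non-conserved type counts")
    return table


class IntronicHostMap(dict):
    """miRNA id -> host gene id; one host per miRNA (multi-copy miRNAs absent)."""

    def __init__(self, mapping: dict[str, str]):
        super().__init__(mapping)


@dataclass
class TranscriptModel:
    """5'UTR/CDS/3'UTR intervals per transcript, in transcript coordinates.

    ``regions`` maps transcript id -> {"utr5"|"cds"|"utr3": (start, end)} with
    0-based half-open intervals.  Regions may be absent (e.g. non-coding).
    """

    regions: dict[str, dict[str, tuple[int, int]]]

    def transcript_length(self, transcript_id: str) -> int:
        return max(e for _, e in self.regions[transcript_id].values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.regions
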