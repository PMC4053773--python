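"""AGO2 binding-site identification from PAR-CLIP reads.

4-thiouridine crosslinking leaves diagnostic T-to-C conversions in cDNA reads
of RNA bound to AGO2.  The pipeline is:

1. overlapping reads (>20 nt) are clustered per transcript; clusters with
   fewer than 5 reads or under 20% crosslinked (converted) reads are dropped;
2. a 41-nt crosslink-centered region (CCR) is cut around each cluster's major
   T-to-C conversion position (20 nt of flank each side);
3. k-mer enrichment within CCRs is scored against dinucleotide-preserving
   shuffles (Altschul-Erickson Eulerian-walk construction) — the top 7-mers
   are expected to be reverse complements of abundant miRNA seeds;
4. canonical seed-complementary sites (8mer, 7mer-m8, 7mer-1A, 6mer-1-7) are
   called inside CCRs, and clusters are annotated by transcript region.

All coordinates are transcript-space, 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from mirti.datamodel import DNA_ALPHABET, DomainError, MirnaFamily, TranscriptModel

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_BASE = np.array(list("ACGT"))

SITE_TYPES = ("8mer", "7mer-m8", "7mer-1A", "6mer-1-7")
# most-specific-first precedence used when several site types share a seed core
_SITE_PRECEDENCE = {t: i for i, t in enumerate(SITE_TYPES)}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def rna_to_dna(seq: str) -> str:
    return seq.replace("U", "T")


# ---------------------------------------------------------------------------
# read / cluster / CCR types


@dataclass
class AlignedRead:
    """One aligned PAR-CLIP read in transcript space."""

    read_id: str
    transcript_id: str
    start: int
    end: int
    sequence: str
    t2c_positions: tuple[int, ...] = ()
    n_mismatches: int = 0

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise DomainError(
                f"read {self.read_id}: span {self.end - self.start} != sequence length"
            )
        if self.n_mismatches > 1:
            raise DomainError(f"read {self.read_id}: more than one mismatch")
        for pos in self.t2c_positions:
            if not (self.start <= pos < self.end):
                raise DomainError(f"read {self.read_id}: T-to-C position {pos} outside read")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_crosslinked(self) -> bool:
        return len(self.t2c_positions) > 0


@dataclass
class Cluster:
    """A retained group of overlapping reads on one transcript."""

    cluster_id: str
    transcript_id: str
    start: int
    end: int
    reads: list[AlignedRead]
    crosslinked_fraction: float
    conversion_profile: dict[int, int]
    major_t2c_position: int

    @property
    def n_reads(self) -> int:
        return len(self.reads)


@dataclass
class CCR:
    """Crosslink-centered region: up to 41 nt around the major conversion."""

    ccr_id: str
    cluster_id: str
    transcript_id: str
    sequence: str
    center_position: int
    start: int
    end: int
    truncated_flag: bool

    @property
    def center_offset(self) -> int:
        """Offset of the crosslink site within ``sequence`` (20 if untruncated)."""
        return self.center_position - self.start


@dataclass(frozen=True)
class SeedSite:
    """One canonical seed-complementary site occurrence within a CCR."""

    ccr_id: str
    family_id: str
    site_type: str
    site_start_offset: int


# ---------------------------------------------------------------------------
# clustering and CCR extraction


def conversion_rate(reads: list[AlignedRead]) -> float:
    """Fraction of reads carrying at least one T-to-C conversion."""
    if not reads:
        raise DomainError("conversion_rate of an empty read list")
    return sum(r.is_crosslinked for r in reads) / len(reads)


def cluster_reads(
    reads: list[AlignedRead],
    min_reads: int = 5,
    min_xlink_frac: float = 0.2,
    min_read_len: int = 21,
) -> list[Cluster]:
    """Cluster overlapping reads (length >= ``min_read_len``) per transcript.

    Clustering is transitive single-linkage with >=1 bp overlap.  Clusters with
    fewer than ``min_reads`` reads or a crosslinked-read fraction below
    ``min_xlink_frac`` are dropped.
    """
    eligible = [r for r in reads if r.length >= min_read_len]
    eligible.sort(key=lambda r: (r.transcript_id, r.start, r.end, r.read_id))

    clusters: list[Cluster] = []
    group: list[AlignedRead] = []
    group_end = -1

    def flush(group: list[AlignedRead]) -> None:
        if len(group) < min_reads:
            return
        xfrac = conversion_rate(group)
        if xfrac < min_xlink_frac:
            return
        profile: dict[int, int] = {}
        for r in group:
            for pos in r.t2c_positions:
                profile[pos] = profile.get(pos, 0) + 1
        if profile:
            top = max(profile.values())
            major = min(p for p, c in profile.items() if c == top)  # 5'-most on ties
        else:  # unreachable with min_xlink_frac > 0, defensive
            major = min(r.start for r in group)
        clusters.append(
            Cluster(
                cluster_id=f"CL{len(clusters):05d}",
                transcript_id=group[0].transcript_id,
                start=min(r.start for r in group),
                end=max(r.end for r in group),
                reads=list(group),
                crosslinked_fraction=xfrac,
                conversion_profile=profile,
                major_t2c_position=major,
            )
        )

    for read in eligible:
        if group and (read.transcript_id != group[0].transcript_id or read.start >= group_end):
            flush(group)
            group = []
        group.append(read)
        group_end = max(group_end, read.end) if len(group) > 1 else read.end
    if group:
        flush(group)
    return clusters


def extract_ccr(cluster: Cluster, transcript_seq: str, flank: int = 20) -> CCR:
    """Cut the CCR around the cluster's major T-to-C position.

    The window is ``[center - flank, center + flank + 1)``, clipped (never
    padded) at transcript boundaries; clipping sets ``truncated_flag``.
    """
    center = cluster.major_t2c_position
    if not (0 <= center < len(transcript_seq)):
        raise DomainError(
            f"cluster {cluster.cluster_id}: center {center} outside transcript"
        )
    start = max(0, center - flank)
    end = min(len(transcript_seq), center + flank + 1)
    truncated = (start != center - flank) or (end != center + flank + 1)
    return CCR(
        ccr_id=f"CCR_{cluster.cluster_id}",
        cluster_id=cluster.cluster_id,
        transcript_id=cluster.transcript_id,
        sequence=transcript_seq[start:end],
        center_position=center,
        start=start,
        end=end,
        truncated_flag=truncated,
    )


# ---------------------------------------------------------------------------
# dinucleotide-preserving shuffle (Altschul-Erickson)


def _last_edges_reach(last: dict[str, str], terminal: str) -> bool:
    for v in last:
        cur = v
        for _ in range(4):  # at most 4 distinct vertices
            cur = last.get(cur, terminal if cur == terminal else None)
            if cur == terminal:
                break
            if cur is None:
                return False
        else:
            return False
    return True


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle ``seq`` preserving its exact multiset of overlapping dinucleotides.

    Altschul-Erickson construction: the sequence is an Eulerian walk on the
    di-graph whose edges are its dinucleotides; a random last-exit-edge
    arborescence toward the terminal vertex is drawn, remaining edge orders are
    shuffled, and the walk is replayed.  First and last residue are preserved.
    """
    if len(seq) < 2:
        raise DomainError("sequence must have length >= 2")
    if set(seq) - DNA_ALPHABET:
        raise DomainError(f"non-ACGT character in sequence: {set(seq) - DNA_ALPHABET}")
    source, terminal = seq[0], seq[-1]

    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)

    non_terminal = [v for v in edges if v != terminal]
    if non_terminal:
        while True:
            last = {v: edges[v][rng.integers(len(edges[v]))] for v in non_terminal}
            if _last_edges_reach(last, terminal):
                break
    else:
        last = {}

    order: dict[str, list[str]] = {}
    for v, succ in edges.items():
        succ = list(succ)
        if v in last:
            succ.remove(last[v])
        idx = rng.permutation(len(succ))
        arranged = [succ[i] for i in idx]
        if v in last:
            arranged.append(last[v])
        order[v] = arranged

    out = [source]
    pointers = {v: 0 for v in order}
    cur = source
    for _ in range(len(seq) - 1):
        nxt = order[cur][pointers[cur]]
        pointers[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def dinucleotide_counts(seq: str) -> dict[str, int]:
    """Multiset of overlapping dinucleotides (for invariants and tests)."""
    counts: dict[str, int] = {}
    for a, b in zip(seq, seq[1:]):
        counts[a + b] = counts.get(a + b, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# k-mer enrichment


def _seq_codes(seq: str) -> np.ndarray:
    return np.array([_BASE_CODE[c] for c in seq], dtype=np.int64)


def count_kmers(sequences: list[str], k: int) -> np.ndarray:
    """Occurrence counts of all 4**k k-mers over every window of every sequence."""
    total = np.zeros(4**k, dtype=np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1)
    for seq in sequences:
        if len(seq) < k:
            continue
        codes = _seq_codes(seq)
        windows = np.lib.stride_tricks.sliding_window_view(codes, k)
        total += np.bincount(windows @ powers, minlength=4**k)
    return total


def kmer_index_to_string(index: int, k: int) -> str:
    digits = []
    for _ in range(k):
        digits.append(index % 4)
        index //= 4
    return "".join(_CODE_BASE[d] for d in reversed(digits))


def all_kmers(k: int) -> list[str]:
    return ["".join(_CODE_BASE[d] for d in digits) for digits in np.ndindex(*(4,) * k)]


@dataclass
class KmerEnrichmentResult:
    """Per-k-mer enrichment table plus positional profiles of observed k-mers.

    ``table`` has exactly 4**k rows with columns kmer, observed_count,
    shuffle_mean, shuffle_sd, z_score, p_value, bh_q.  ``positional_profiles``
    maps observed k-mers to {offset relative to the crosslink site: count}.
    """

    table: pd.DataFrame
    positional_profiles: dict[str, dict[int, int]] = field(default_factory=dict)
    k: int = 7
    n_shuffles: int = 0


def kmer_enrichment(
    ccrs: list[CCR],
    k: int = 7,
    n_shuffles: int = 100,
    rng: np.random.Generator | None = None,
) -> KmerEnrichmentResult:
    """Score all 4**k k-mers within CCRs against dinucleotide-preserving shuffles.

    The null distribution of each k-mer's count comes from ``n_shuffles``
    complete shuffled CCR sets.  Empirical p-values use the add-one rule
    (1 + exceedances) / (n_shuffles + 1); BH correction runs across all 4**k
    k-mers; z = (obs - mean) / sd with z = 0 where sd = 0.
    """
    if not ccrs:
        raise DomainError("kmer_enrichment on an empty CCR list")
    if not (4 <= k <= 10):
        raise DomainError("k must lie in [4, 10]")
    if n_shuffles < 100:
        raise DomainError("n_shuffles must be >= 100")
    rng = np.random.default_rng() if rng is None else rng

    sequences = [c.sequence for c in ccrs]
    observed = count_kmers(sequences, k)

    null = np.empty((n_shuffles, 4**k), dtype=np.int64)
    for b in range(n_shuffles):
        shuffled = [dinucleotide_shuffle(s, rng) for s in sequences]
        null[b] = count_kmers(shuffled, k)

    mean = null.mean(axis=0)
    sd = null.std(axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (observed - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    exceed = (null >= observed[None, :]).sum(axis=0)
    p = (1 + exceed) / (n_shuffles + 1)
    _, q, _, _ = multipletests(p, method="fdr_bh")

    table = pd.DataFrame(
        {
            "kmer": all_kmers(k),
            "observed_count": observed,
            "shuffle_mean": mean,
            "shuffle_sd": sd,
            "z_score": z,
            "p_value": p,
            "bh_q": q,
        }
    )

    profiles: dict[str, dict[int, int]] = {}
    for ccr in ccrs:
        seq, center = ccr.sequence, ccr.center_offset
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            prof = profiles.setdefault(kmer, {})
            offset = i - center
            prof[offset] = prof.get(offset, 0) + 1
    return KmerEnrichmentResult(table=table, positional_profiles=profiles, k=k, n_shuffles=n_shuffles)


def complementarity_enrichment(
    ccrs: list[CCR],
    mirna_sequences: dict[str, str],
    k_range: tuple[int, int] = (6, 10),
    n_shuffles: int = 100,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Enrichment of reverse complements of miRNA positions 1-10 subwords in CCRs.

    For each miRNA, k in ``k_range`` and start position 1..(11-k), counts CCRs
    containing the reverse complement of that miRNA subsequence, against the
    same dinucleotide-shuffle null as :func:`kmer_enrichment` (presence per
    CCR, add-one empirical p).
    """
    if not ccrs:
        raise DomainError("complementarity_enrichment on an empty CCR list")
    rng = np.random.default_rng() if rng is None else rng
    sequences = [c.sequence for c in ccrs]

    probes: list[tuple[str, int, int, str]] = []
    for mirna_id, seq in mirna_sequences.items():
        dna = rna_to_dna(seq)
        if len(dna) < 10:
            raise DomainError(f"miRNA {mirna_id} shorter than 10 nt")
        for k in range(k_range[0], k_range[1] + 1):
            for start in range(1, 11 - k + 1):  # 1-based start within positions 1-10
                if start - 1 + k > len(dna):
                    warnings.warn(f"{mirna_id}: k={k} start={start} exceeds sequence")
                    continue
                site = reverse_complement(dna[start - 1 : start - 1 + k])
                probes.append((mirna_id, k, start, site))

    def presence_counts(seqs: list[str]) -> np.ndarray:
        return np.array([sum(site in s for s in seqs) for *_1, site in probes])

    observed = presence_counts(sequences)
    exceed = np.zeros(len(probes), dtype=np.int64)
    for _ in range(n_shuffles):
        shuffled = [dinucleotide_shuffle(s, rng) for s in sequences]
        exceed += presence_counts(shuffled) >= observed
    p = (1 + exceed) / (n_shuffles + 1)

    return pd.DataFrame(
        {
            "mirna_id": [m for m, *_ in probes],
            "k": [k for _, k, *_ in probes],
            "start": [s for _, _, s, _ in probes],
            "site": [site for *_, site in probes],
            "n_ccrs_with_site": observed,
            "p_value": p,
        }
    )


# ---------------------------------------------------------------------------
# seed-site calling


def family_site_strings(family: MirnaFamily) -> dict[str, str]:
    """DNA site strings (5'->3' on the target) for each canonical site type.

    8mer     = revcomp(seed 2-8) + A
    7mer-m8  = revcomp(seed 2-8)
    7mer-1A  = revcomp(seed 2-7) + A
    6mer-1-7 = revcomp(positions 1-7)  (needs the mature sequence for position 1)
    """
    seed_dna = rna_to_dna(family.seed_2_8)
    rc_2_8 = reverse_complement(seed_dna)
    rc_2_7 = reverse_complement(seed_dna[:6])
    sites = {
        "8mer": rc_2_8 + "A",
        "7mer-m8": rc_2_8,
        "7mer-1A": rc_2_7 + "A",
    }
    mature = family.mature_sequence
    if mature is not None and len(mature) >= 7:
        sites["6mer-1-7"] = reverse_complement(rna_to_dna(mature[:7]))
    return sites


def _seed_core_anchor(site_type: str, match_start: int) -> int:
    """Target-space start of the hexamer complementary to seed positions 2-7.

    All four site types contain this core; grouping occurrences by its position
    lets a single biological site be reported once with its most specific type.
    For 8mer/7mer-m8 the core sits one base inside the match (after the m8
    pairing base); for 7mer-1A and 6mer-1-7 it starts at the match itself.
    """
    return match_start + 1 if site_type in ("8mer", "7mer-m8") else match_start


def call_seed_sites(ccrs: list[CCR], families: list[MirnaFamily]) -> list[SeedSite]:
    """Scan CCRs for canonical seed-complementary sites of each family.

    Every occurrence is reported once, with the most specific matching type
    (8mer > 7mer-m8 > 7mer-1A > 6mer-1-7); occurrences are identified by the
    position of the shared seed-2-7 complementary core.
    """
    sites: list[SeedSite] = []
    site_strings = {f.family_id: family_site_strings(f) for f in families}
    for ccr in ccrs:
        seq = ccr.sequence
        for family in families:
            by_anchor: dict[int, tuple[int, str, int]] = {}
            for site_type, pattern in site_strings[family.family_id].items():
                start = seq.find(pattern)
                while start != -1:
                    anchor = _seed_core_anchor(site_type, start)
                    rank = _SITE_PRECEDENCE[site_type]
                    if anchor not in by_anchor or rank < by_anchor[anchor][0]:
                        by_anchor[anchor] = (rank, site_type, start)
                    start = seq.find(pattern, start + 1)
            for anchor in sorted(by_anchor):
                _, site_type, start = by_anchor[anchor]
                sites.append(SeedSite(ccr.ccr_id, family.family_id, site_type, start))
    return sites


# ---------------------------------------------------------------------------
# region annotation and expressed-miRNA selection

_REGION_3PRIME_ORDER = {"utr5": 0, "cds": 1, "utr3": 2}


def annotate_regions(
    clusters: list[Cluster], model: TranscriptModel
) -> tuple[pd.Series, dict[str, str]]:
    """Label each cluster by the transcript region holding the majority of its span.

    Ties go to the 3'-most region.  Clusters on transcripts absent from the
    model are labeled ``unannotated``.  Returns (fractions over annotated
    clusters, cluster_id -> label).
    """
    labels: dict[str, str] = {}
    for cluster in clusters:
        if cluster.transcript_id not in model:
            labels[cluster.cluster_id] = "unannotated"
            continue
        overlaps: dict[str, int] = {}
        for region, (rs, re_) in model.regions[cluster.transcript_id].items():
            overlap = min(cluster.end, re_) - max(cluster.start, rs)
            if overlap > 0:
                overlaps[region] = overlaps.get(region, 0) + overlap
        if not overlaps:
            labels[cluster.cluster_id] = "unannotated"
            continue
        best = max(overlaps.values())
        tied = [r for r, o in overlaps.items() if o == best]
        labels[cluster.cluster_id] = max(tied, key=lambda r: _REGION_3PRIME_ORDER[r])

    annotated = [lab for lab in labels.values() if lab != "unannotated"]
    if annotated:
        fractions = pd.Series(annotated).value_counts(normalize=True)
    else:
        fractions = pd.Series(dtype=float)
    return fractions, labels


def select_top_mirnas(rrf: pd.Series, coverage: float = 0.95) -> list[str]:
    """Smallest descending-RRF prefix of miRNAs reaching cumulative ``coverage``.

    Ties at the cut are all included (stable order by id among equals).
    """
    if not (0 < coverage <= 1):
        raise DomainError("coverage must lie in (0, 1]")
    ordered = rrf.sort_values(ascending=False, kind="mergesort")
    ordered = ordered.iloc[np.lexsort((ordered.index, -ordered.to_numpy()))]
    cum = ordered.cumsum()
    n = int(np.searchsorted(cum.to_numpy(), coverage - 1e-12) + 1)
    n = min(n, len(ordered))
    cutoff = ordered.iloc[n - 1]
    while n < len(ordered) and ordered.iloc[n] == cutoff:
        n += 1
    return list(ordered.index[:n])
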