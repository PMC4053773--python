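import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import bruteforce_seed_sites
from mirti.datamodel import DomainError, MirnaFamily, TranscriptModel
from mirti.parclip import (
    CCR,
    AlignedRead,
    Cluster,
    all_kmers,
    annotate_regions,
    call_seed_sites,
    cluster_reads,
    complementarity_enrichment,
    conversion_rate,
    count_kmers,
    dinucleotide_counts,
    dinucleotide_shuffle,
    extract_ccr,
    family_site_strings,
    kmer_enrichment,
    reverse_complement,
    select_top_mirnas,
)

import pandas as pd


def _read(rid, tid, start, length, t2c=(), n_mismatches=None):
    if n_mismatches is None:
        n_mismatches = 1 if t2c else 0
    return AlignedRead(rid, tid, start, start + length, "A" * length, tuple(t2c), n_mismatches)


def _random_dna(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


class TestClustering:
    def test_cluster_retained_with_thresholds_met(self):
        reads = [_read(f"r{i}", "T1", 100 + i, 22, t2c=(110,) if i < 3 else ()) for i in range(6)]
        clusters = cluster_reads(reads)
        assert len(clusters) == 1
        (c,) = clusters
        assert c.n_reads == 6
        assert c.crosslinked_fraction == pytest.approx(0.5)
        assert c.major_t2c_position == 110

    def test_small_cluster_dropped(self):
        reads = [_read(f"r{i}", "T1", 100 + i, 22, t2c=(110,)) for i in range(4)]
        assert cluster_reads(reads) == []

    def test_low_crosslink_fraction_dropped(self):
        reads = [_read(f"r{i}", "T1", 100 + i, 22, t2c=(110,) if i == 0 else ()) for i in range(6)]
        assert cluster_reads(reads) == []

    def test_gap_separates_clusters(self):
        left = [_read(f"l{i}", "T1", 100 + i, 22, t2c=(110,)) for i in range(5)]
        right = [_read(f"r{i}", "T1", 300 + i, 22, t2c=(310,)) for i in range(5)]
        clusters = cluster_reads(left + right)
        assert len(clusters) == 2
        assert [c.start for c in clusters] == [100, 300]

    def test_short_reads_ignored(self):
        reads = [_read(f"r{i}", "T1", 100, 20, t2c=(110,)) for i in range(10)]
        assert cluster_reads(reads) == []

    def test_conversion_rate(self):
        reads = [_read(f"r{i}", "T1", 0, 22, t2c=(5,) if i < 8 else ()) for i in range(10)]
        assert conversion_rate(reads) == pytest.approx(0.8)
        assert conversion_rate([_read("r", "T", 0, 22)]) == 0.0
        with pytest.raises(DomainError):
            conversion_rate([])


class TestCCRExtraction:
    def _cluster(self, profile, tid="T1"):
        top = max(profile.values())
        major = min(p for p, c in profile.items() if c == top)
        reads = [_read("r", tid, 80, 40, t2c=(major,))] * 5
        return Cluster("CL1", tid, 80, 130, reads, 1.0, profile, major)

    def test_window_arithmetic(self):
        seq = "A" * 200
        ccr = extract_ccr(self._cluster({100: 3, 105: 1}), seq)
        assert (ccr.start, ccr.end) == (80, 121)
        assert len(ccr.sequence) == 41
        assert not ccr.truncated_flag
        assert ccr.center_offset == 20

    def test_tie_takes_five_prime_most(self):
        cluster = self._cluster({105: 2, 100: 2})
        assert cluster.major_t2c_position == 100

    def test_edge_clipping(self):
        cluster = Cluster("CL1", "T1", 0, 30, [_read("r", "T1", 0, 30, t2c=(5,))] * 5,
                          1.0, {5: 5}, 5)
        ccr = extract_ccr(cluster, "A" * 200)
        assert ccr.truncated_flag
        assert len(ccr.sequence) == 26  # [0, 26)
        assert ccr.center_offset == 5

    def test_center_outside_transcript_errors(self):
        reads = [_read("r", "T1", 480, 40, t2c=(500,))] * 5
        cluster = Cluster("CL1", "T1", 480, 520, reads, 1.0, {500: 5}, 500)
        with pytest.raises(DomainError):
            extract_ccr(cluster, "A" * 100)


class TestDinucleotideShuffle:
    def test_unique_eulerian_walk_is_identity(self, rng):
        # the dinucleotide multiset {AC, CA, AC} admits exactly one sequence
        assert dinucleotide_shuffle("ACAC", rng) == "ACAC"

    @given(st.text(alphabet="ACGT", min_size=2, max_size=80))
    @settings(deadline=None, max_examples=150)
    def test_preserves_dinucleotide_multiset(self, seq):
        rng = np.random.default_rng(7)
        out = dinucleotide_shuffle(seq, rng)
        assert dinucleotide_counts(out) == dinucleotide_counts(seq)
        assert out[0] == seq[0] and out[-1] == seq[-1]

    def test_produces_distinct_outputs(self, rng):
        outputs = {dinucleotide_shuffle("AAGCTTGG", rng) for _ in range(1000)}
        assert len(outputs) >= 2
        for out in outputs:
            assert dinucleotide_counts(out) == dinucleotide_counts("AAGCTTGG")

    def test_rejects_non_acgt(self, rng):
        with pytest.raises(DomainError):
            dinucleotide_shuffle("ACGN", rng)


class TestKmerEnrichment:
    def _ccrs(self, sequences):
        return [CCR(f"c{i}", f"cl{i}", "T1", s, 0 + 20, 0, len(s), False)
                for i, s in enumerate(sequences)]

    def test_total_count_invariant(self, rng):
        seqs = [_random_dna(rng, 41) for _ in range(30)]
        counts = count_kmers(seqs, 7)
        assert counts.sum() == sum(len(s) - 6 for s in seqs)

    def test_all_a_ccrs(self, rng):
        result = kmer_enrichment(self._ccrs(["A" * 41] * 5), k=7, n_shuffles=100, rng=rng)
        observed = result.table.set_index("kmer")["observed_count"]
        assert observed["AAAAAAA"] == 5 * 35
        assert observed.drop("AAAAAAA").sum() == 0

    def test_empty_input_errors(self, rng):
        with pytest.raises(DomainError):
            kmer_enrichment([], rng=rng)

    def test_positional_profile_offsets(self, rng):
        seqs = [_random_dna(rng, 41) for _ in range(5)]
        result = kmer_enrichment(self._ccrs(seqs), k=7, n_shuffles=100, rng=rng)
        total = sum(sum(p.values()) for p in result.positional_profiles.values())
        assert total == 5 * 35
        for profile in result.positional_profiles.values():
            assert all(-20 <= off <= 14 for off in profile)


class TestComplementarityEnrichment:
    def test_seed_window_definition(self):
        fam = MirnaFamily("miR-1", ["miR-1"], "AGCUUAU", {"miR-1": "UAGCUUAUCAGACUGAUGUUGA"})
        sites = family_site_strings(fam)
        mirna_dna = "TAGCTTATCAGACTGATGTTGA"
        # the k=7, start=2 window reverse complement equals the 7mer-m8 site
        assert reverse_complement(mirna_dna[1:8]) == sites["7mer-m8"]

    def test_planted_seed_region_outranks(self, rng):
        mirna = "UAGCUUAUCAGACUGAUGUUGA"
        site = reverse_complement("TAGCTTATCA"[1:8])  # 7mer-m8 of positions 2-8
        seqs = []
        for i in range(60):
            s = list(_random_dna(rng, 41))
            if i < 40:
                s[12:19] = list(site)
            seqs.append("".join(s))
        ccrs = [CCR(f"c{i}", "cl", "T1", s, 20, 0, 41, False) for i, s in enumerate(seqs)]
        table = complementarity_enrichment(
            ccrs, {"miR-1": mirna}, k_range=(7, 7), n_shuffles=100, rng=rng
        )
        seed_row = table[(table["k"] == 7) & (table["start"] == 2)].iloc[0]
        assert seed_row["n_ccrs_with_site"] >= 40
        # seed-region window achieves the minimal p (ties at the floor allowed)
        assert seed_row["p_value"] <= table["p_value"].min() + 1e-12

    def test_absent_complement_p_near_one(self, rng):
        ccrs = [CCR(f"c{i}", "cl", "T1", "A" * 41, 20, 0, 41, False) for i in range(10)]
        table = complementarity_enrichment(
            ccrs, {"miR-1": "CCCCCCCCCCCCCCCCCCCCCC"}, k_range=(6, 6), n_shuffles=100, rng=rng
        )
        assert (table["p_value"] > 0.9).all()


class TestSeedSites:
    def test_eight_mer_called(self):
        fam = MirnaFamily("miR-1", ["miR-1"], "AGCUUAU")
        # revcomp(AGCTTAT) = ATAAGCT; 8mer = ATAAGCTA
        ccr = CCR("c1", "cl", "T1", "GGGG" + "ATAAGCTA" + "GGGG", 8, 0, 16, False)
        sites = call_seed_sites([ccr], [fam])
        assert len(sites) == 1
        assert sites[0].site_type == "8mer"
        assert sites[0].site_start_offset == 4

    def test_seven_mer_m8_without_adjacent_a(self):
        fam = MirnaFamily("miR-1", ["miR-1"], "AGCUUAU")
        ccr = CCR("c1", "cl", "T1", "GGGG" + "ATAAGCT" + "G" + "GGG", 8, 0, 15, False)
        sites = call_seed_sites([ccr], [fam])
        assert [s.site_type for s in sites] == ["7mer-m8"]

    def test_no_complement_empty(self):
        fam = MirnaFamily("miR-1", ["miR-1"], "AGCUUAU")
        ccr = CCR("c1", "cl", "T1", "C" * 41, 20, 0, 41, False)
        assert call_seed_sites([ccr], [fam]) == []

    def test_matches_bruteforce_oracle_on_random_ccrs(self, rng):
        families = []
        for i in range(10):
            seed = "".join(np.array(list("ACGU"))[rng.integers(0, 4, 7)])
            mature = "".join(np.array(list("ACGU"))[rng.integers(0, 4, 1)]) + seed + "".join(
                np.array(list("ACGU"))[rng.integers(0, 4, 14)]
            )
            families.append(MirnaFamily(f"f{i}", [f"f{i}"], seed, {f"f{i}": mature}))
        ccrs = [CCR(f"c{i}", "cl", "T1", _random_dna(rng, 41), 20, 0, 41, False)
                for i in range(200)]
        called = {
            (s.ccr_id, s.family_id, s.site_type, s.site_start_offset)
            for s in call_seed_sites(ccrs, families)
        }
        expected = set()
        for ccr in ccrs:
            for fam in families:
                for site_type, offset in bruteforce_seed_sites(ccr.sequence, fam):
                    expected.add((ccr.ccr_id, fam.family_id, site_type, offset))
        assert called == expected


class TestRegionAnnotation:
    model = TranscriptModel({"T1": {"utr5": (0, 100), "cds": (100, 400), "utr3": (400, 800)}})

    def _cluster(self, start, end, tid="T1"):
        return Cluster("CL", tid, start, end, [_read("r", tid, start, 22, t2c=(start,))] * 5,
                       1.0, {start: 5}, start)

    def test_fully_inside_utr3(self):
        fractions, labels = annotate_regions([self._cluster(500, 540)], self.model)
        assert labels["CL"] == "utr3"

    def test_majority_rule(self):
        # 30 nt in CDS, 10 nt in 3'UTR -> CDS
        fractions, labels = annotate_regions([self._cluster(370, 410)], self.model)
        assert labels["CL"] == "cds"

    def test_tie_goes_three_prime(self):
        fractions, labels = annotate_regions([self._cluster(380, 420)], self.model)
        assert labels["CL"] == "utr3"

    def test_unknown_transcript_unannotated(self):
        fractions, labels = annotate_regions([self._cluster(10, 50, tid="TX")], self.model)
        assert labels["CL"] == "unannotated"
        assert fractions.empty

    def test_fractions_sum_to_one(self, rng):
        clusters = [
            Cluster(f"CL{i}", "T1", s, s + 40,
                    [_read(f"r{i}", "T1", s, 22, t2c=(s,))] * 5, 1.0, {s: 5}, s)
            for i, s in enumerate(rng.integers(0, 760, size=10))
        ]
        fractions, labels = annotate_regions(clusters, self.model)
        assert fractions.sum() == pytest.approx(1.0)


class TestTopMirnas:
    def test_cumulative_coverage(self):
        rrf = pd.Series([0.5, 0.3, 0.15, 0.05], index=list("abcd"))
        assert select_top_mirnas(rrf, coverage=0.95) == ["a", "b", "c"]

    def test_full_coverage_returns_all(self):
        rrf = pd.Series([0.5, 0.3, 0.2], index=list("abc"))
        assert set(select_top_mirnas(rrf, coverage=1.0)) == set("abc")

    def test_ties_at_cut_included(self):
        rrf = pd.Series([0.5, 0.2, 0.2, 0.1], index=list("abcd"))
        # coverage 0.7 reached after b, but c ties with b -> both included
        assert select_top_mirnas(rrf, coverage=0.7) == ["a", "b", "c"]

    def test_invalid_coverage(self):
        with pytest.raises(DomainError):
            select_top_mirnas(pd.Series([1.0], index=["a"]), coverage=0.0)


def test_kmer_universe_size():
    assert len(all_kmers(5)) == 4**5
    assert len(set(all_kmers(5))) == 4**5
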