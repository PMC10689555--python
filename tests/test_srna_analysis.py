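"""Small-RNA cleaning, mapping, piRNA calls, hotspots and seed matches."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from paleoscan.formats_io import FastqRead, SequenceRecord
from paleoscan.homology_search import reverse_complement
from paleoscan.srna_analysis import (
    SrnaConfig,
    clean_reads,
    coverage_track,
    hotspots,
    map_srna,
    profile_and_call,
    seed_complementarity,
)
from paleoscan.synthetic_data import (
    InsertionSpec,
    SimulationConfig,
    SrnaLibrarySpec,
    random_dna,
    simulate_genome,
    simulate_srna,
)


def _read(seq, name="r", qual=40):
    return FastqRead(name, seq, [qual] * len(seq))


@pytest.fixture(scope="module")
def locus_sim():
    return simulate_genome(
        SimulationConfig(
            seed=61,
            contig_count=1,
            contig_length=30_000,
            insertions=[InsertionSpec("viral_000", 0.0, 200)],
            decoys_per_category={},
        )
    )


def _locus_record(sim, name="eve1"):
    row = sim.truth.iloc[0]
    seq = sim.contigs[0].sequence[row["start"] : row["start"] + row["length"]]
    return SequenceRecord(name, "", seq)


class TestCleanReads:
    def test_length_window_endpoints_inclusive(self, rng):
        reads = [
            _read(random_dna(rng, n, 0.5), f"r{n}") for n in (17, 18, 32, 33)
        ]
        unique, report = clean_reads(reads)
        kept_lengths = {len(s) for s in unique["sequence"]}
        assert kept_lengths == {18, 32}
        assert report["dropped_length"] == 2

    def test_identical_reads_merge(self, rng):
        seq = random_dna(rng, 27, 0.5)
        unique, report = clean_reads([_read(seq, f"r{i}") for i in range(3)])
        assert len(unique) == 1
        assert int(unique.iloc[0]["count"]) == 3
        assert report["kept"] == 3

    def test_low_quality_rule(self, rng):
        seq = random_dna(rng, 25, 0.5)
        bad = FastqRead("bad", seq, [5] * 6 + [40] * 19)  # 24% below Phred 20
        ok = FastqRead("ok", seq, [5] * 5 + [40] * 20)  # exactly 20%
        unique, report = clean_reads([bad, ok])
        assert report["dropped_low_quality"] == 1
        assert len(unique) == 1

    def test_low_complexity_rule(self):
        unique, report = clean_reads([_read("A" * 25), _read("ACGT" * 6 + "A")])
        assert report["dropped_low_complexity"] == 1
        assert len(unique) == 1

    def test_adapter_trimming(self, rng):
        adapter = "TGGAATTCTCGGGTGCCAAGG"
        core = random_dna(rng, 26, 0.5)
        reads = [
            _read(core + adapter, "full"),
            _read(core + adapter[:10], "suffix"),
            _read(adapter, "adapter_only"),
        ]
        unique, report = clean_reads(reads, adapter=adapter)
        assert report["adapter_trimmed"] == 3
        assert report["dropped_empty"] == 1
        assert set(unique["sequence"]) == {core}

    def test_conservation_and_simulator_truth(self, locus_sim):
        spec = SrnaLibrarySpec(
            total_reads=400,
            pirna_fraction=0.75,
            n_low_quality=17,
            n_low_complexity=9,
            n_out_of_range=12,
        )
        reads, counts = simulate_srna(locus_sim, spec, seed=62)
        unique, report = clean_reads(reads)
        assert report["input"] == len(reads)
        dropped = (
            report["dropped_empty"]
            + report["dropped_low_quality"]
            + report["dropped_low_complexity"]
            + report["dropped_length"]
        )
        assert report["kept"] + dropped == report["input"]
        assert report["dropped_low_quality"] == counts["low_quality"]
        assert report["dropped_low_complexity"] == counts["low_complexity"]
        assert report["dropped_length"] == counts["out_of_range"]
        assert report["kept"] == counts["pirna"] + counts["background"]

    def test_cleaning_is_idempotent(self, locus_sim):
        spec = SrnaLibrarySpec(total_reads=300)
        reads, _ = simulate_srna(locus_sim, spec, seed=63)
        unique1, _ = clean_reads(reads)
        rereads = [
            _read(s, f"u{i}")
            for i, s in enumerate(np.repeat(unique1["sequence"], unique1["count"]))
        ]
        unique2, _ = clean_reads(rereads)
        assert unique1.equals(unique2)


class TestMapSrna:
    def test_minus_strand_mapping(self, locus_sim):
        eve = _locus_record(locus_sim)
        read_seq = reverse_complement(eve.sequence[40:66])
        unique = pd.DataFrame({"sequence": [read_seq], "count": [1]})
        hits = map_srna(unique, [eve])
        assert len(hits) == 1
        assert hits.iloc[0]["strand"] == "-"
        assert hits.iloc[0]["five_prime"] == 65

    def test_one_mismatch_is_unmapped_by_default(self, locus_sim):
        eve = _locus_record(locus_sim)
        seq = list(eve.sequence[10:36])
        seq[12] = "ACGT".replace(seq[12], "")[0]
        unique = pd.DataFrame({"sequence": ["".join(seq)], "count": [1]})
        assert len(map_srna(unique, [eve])) == 0

    def test_planted_single_strand_library(self, locus_sim):
        spec = SrnaLibrarySpec(total_reads=600, pirna_fraction=1.0, p_strand=1.0, p1U=0.9)
        reads, _ = simulate_srna(locus_sim, spec, seed=64)
        unique, _ = clean_reads(reads)
        eve = _locus_record(locus_sim)
        hits = map_srna(unique, [eve])
        assert len(hits) > 0
        assert (hits["strand"] == "+").all()


class TestProfileAndCall:
    def _profile(self, sim, spec, seed):
        reads, _ = simulate_srna(sim, spec, seed=seed)
        unique, _ = clean_reads(reads)
        eve = _locus_record(sim)
        hits = map_srna(unique, [eve])
        profiles = profile_and_call(hits, "lib1", len(unique))
        assert len(profiles) == 1
        return profiles[0]

    def test_planted_pirna_signature_called(self, locus_sim):
        spec = SrnaLibrarySpec(
            total_reads=2000, pirna_fraction=0.9, p1U=0.9, p_strand=1.0
        )
        p = self._profile(locus_sim, spec, 65)
        assert p.pirna_like
        assert p.verdicts["length"] and p.verdicts["first_u"] and p.verdicts["strand"]

    def test_short_symmetric_reads_fail_length_and_strand(self, locus_sim):
        eve = _locus_record(locus_sim)
        rows = []
        for i in range(0, 60, 2):
            rows.append({"sequence": eve.sequence[i : i + 21], "count": 1})
            rows.append(
                {"sequence": reverse_complement(eve.sequence[i + 1 : i + 22]), "count": 1}
            )
        unique = pd.DataFrame(rows).drop_duplicates("sequence")
        hits = map_srna(unique, [eve])
        p = profile_and_call(hits, "lib", len(unique))[0]
        assert not p.pirna_like
        assert not p.verdicts["length"]
        assert not p.verdicts["strand"]

    def test_histogram_conservation(self, locus_sim):
        spec = SrnaLibrarySpec(total_reads=800, pirna_fraction=0.8)
        p = self._profile(locus_sim, spec, 66)
        assert sum(p.length_histogram.values()) == p.unique_mapped
        assert p.plus_count + p.minus_count == p.unique_mapped
        assert sum(p.first_nucleotide.values()) == p.unique_mapped

    def test_strand_antisymmetry(self, locus_sim):
        """Reverse-complementing the nrEVE swaps plus/minus counts."""
        spec = SrnaLibrarySpec(total_reads=500, pirna_fraction=1.0, p_strand=0.7)
        reads, _ = simulate_srna(locus_sim, spec, seed=67)
        unique, _ = clean_reads(reads)
        eve = _locus_record(locus_sim)
        flipped = SequenceRecord(eve.id, "", reverse_complement(eve.sequence))
        p1 = profile_and_call(map_srna(unique, [eve]), "lib", len(unique))[0]
        p2 = profile_and_call(map_srna(unique, [flipped]), "lib", len(unique))[0]
        assert (p1.plus_count, p1.minus_count) == (p2.minus_count, p2.plus_count)


class TestHotspots:
    def test_uniform_starts_no_hotspot(self, locus_sim):
        """Evenly spread 5' ends (unique reads with distinct starts, the
        uniform null) never exceed the mean + 3 SD threshold."""
        eve = _locus_record(locus_sim)
        empty = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            starts = rng.choice(len(eve.sequence) - 30, size=60, replace=False)
            unique = pd.DataFrame(
                {
                    "sequence": [
                        eve.sequence[s : s + int(rng.integers(25, 31))] for s in starts
                    ],
                    "count": 1,
                }
            ).drop_duplicates("sequence")
            hits = map_srna(unique, [eve])
            result = hotspots(hits, eve.id, len(eve.sequence))
            empty += not result.positions
        assert empty >= 19

    def test_spike_is_reported(self, locus_sim):
        eve = _locus_record(locus_sim)
        rows = [
            {"sequence": eve.sequence[50 : 50 + 25 + i], "count": 1} for i in range(8)
        ]  # 8 distinct reads share the 5' position 50
        rows += [{"sequence": eve.sequence[i : i + 26], "count": 1} for i in range(100, 130, 3)]
        unique = pd.DataFrame(rows)
        hits = map_srna(unique, [eve])
        result = hotspots(hits, eve.id, len(eve.sequence))
        assert not result.insufficient_data
        assert 50 in result.positions

    def test_too_few_reads_flagged(self, locus_sim):
        eve = _locus_record(locus_sim)
        unique = pd.DataFrame({"sequence": [eve.sequence[0:26]], "count": [1]})
        hits = map_srna(unique, [eve])
        result = hotspots(hits, eve.id, len(eve.sequence))
        assert result.insufficient_data


@pytest.fixture(scope="module")
def virus():
    rng = np.random.default_rng(71)
    return SequenceRecord("virus", "", random_dna(rng, 10_000, 0.5))


class TestSeedComplementarity:

    def test_perfect_match(self, virus):
        pirna = virus.sequence[400:429]
        (m,) = seed_complementarity([pirna], virus, min_identities=22)
        assert m.identities == 29
        assert m.alignment_length == 29
        assert m.seed_clean
        assert m.target_position == 400

    def test_seed_window_violations(self, virus):
        pirna = list(virus.sequence[600:629])
        for pos in (5, 16):  # 1-based positions 5 and 16 fall in both windows
            pirna[pos - 1] = "ACGT".replace(pirna[pos - 1], "")[0]
        (m,) = seed_complementarity(["".join(pirna)], virus, min_identities=22)
        assert m.identities == 27
        assert sorted(m.mismatch_positions) == [5, 16]
        assert not m.seed_clean

    def test_mismatch_outside_windows_is_clean(self, virus):
        pirna = list(virus.sequence[800:829])
        for pos in (1, 10, 25):
            pirna[pos - 1] = "ACGT".replace(pirna[pos - 1], "")[0]
        (m,) = seed_complementarity(["".join(pirna)], virus, min_identities=22)
        assert m.seed_clean
        assert sorted(m.mismatch_positions) == [1, 10, 25]

    def test_antisense_match(self, virus):
        pirna = reverse_complement(virus.sequence[1200:1228])
        (m,) = seed_complementarity([pirna], virus, min_identities=22)
        assert m.target_strand == "-"
        assert m.identities == 28
        assert m.target_position == 1200

    def test_below_floor_not_reported(self, virus, rng):
        random_pirna = random_dna(rng, 29, 0.5)
        assert seed_complementarity([random_pirna], virus, min_identities=22) == []

    def test_agrees_with_bruteforce_best(self, rng):
        small = SequenceRecord("v", "", random_dna(rng, 500, 0.5))
        for _ in range(20):
            pirna = random_dna(rng, 25, 0.5)
            best = 0
            for template in (small.sequence, reverse_complement(small.sequence)):
                for off in range(len(template) - 25 + 1):
                    best = max(
                        best,
                        sum(a == b for a, b in zip(pirna, template[off : off + 25])),
                    )
            got = seed_complementarity([pirna], small, min_identities=0)
            assert got[0].identities == best

    def test_virus_shorter_than_pirna_is_error(self):
        with pytest.raises(ValueError):
            seed_complementarity(["A" * 29], SequenceRecord("v", "", "ACGT"), 22)


class TestCoverageTrack:
    def test_depth_counts_unique_reads(self, locus_sim):
        eve = _locus_record(locus_sim)
        unique = pd.DataFrame(
            {
                "sequence": [eve.sequence[10:36], reverse_complement(eve.sequence[20:46])],
                "count": [3, 1],
            }
        )
        hits = map_srna(unique, [eve])
        depth = coverage_track(hits, eve.id, len(eve.sequence))
        assert depth[10] == 1 and depth[25] == 2 and depth[45] == 1 and depth[50] == 0
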