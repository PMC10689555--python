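"""Candidate extraction, reciprocal validation, naming, clustering and
reference-genome region assignment."""

import numpy as np
import pandas as pd
import pytest

from paleoscan.eve_discovery import (
    EveCluster,
    assign_function_region,
    assign_function_regions,
    catalogue_from_eves,
    cluster_by_distance,
    discover,
    name_nreve,
)
from paleoscan.formats_io import EveCatalogue, ProteinDbEntry, SequenceRecord, packaged_table1
from paleoscan.synthetic_data import (
    InsertionSpec,
    SimulationConfig,
    diverge_protein,
    random_protein,
    simulate_genome,
    simulate_reference_virus,
)


class TestNaming:
    @pytest.mark.parametrize(
        "species,family,ordinal,expected",
        [
            ("Ceratitis capitata", "Rhabdoviridae", 1, "nrEVE_CcapRhabdo_1"),
            ("Bactrocera cucurbitae", "Narnaviridae", 1, "nrEVE_BcucNarna_1"),
            ("Trupanea jonesi", "Totiviridae", 1, "nrEVE_TjonToti_1"),
            ("Eutreta diana", "unclassified", 2, "nrEVE_EdiaUnc_2"),
        ],
    )
    def test_examples(self, species, family, ordinal, expected):
        assert name_nreve(species, family, ordinal) == expected

    def test_malformed_binomial_is_error(self):
        with pytest.raises(ValueError):
            name_nreve("capitata", "Rhabdoviridae", 1)
        with pytest.raises(ValueError):
            name_nreve("Ceratitis", "Rhabdoviridae", 1)

    def test_ordinal_must_be_positive(self):
        with pytest.raises(ValueError):
            name_nreve("Ceratitis capitata", "Rhabdoviridae", 0)


class TestDiscover:
    def test_planted_fragments_kept_with_truth_labels(self, small_sim):
        eves, verdicts = discover(small_sim.contigs, small_sim.db, "Synthetica exempli")
        truth_viral = small_sim.truth[small_sim.truth["category"] == "viral"]
        assert len(eves) == len(truth_viral)
        by_pos = {}
        for e in eves:
            by_pos[(e.contig, e.top_hit_id)] = e
        for _, row in truth_viral.iterrows():
            match = [
                e
                for e in eves
                if e.contig == row["contig"]
                and e.start - 1 < row["start"] + row["length"]
                and row["start"] < e.start - 1 + e.length
            ]
            assert len(match) == 1
            assert match[0].family == row["family"]
            assert match[0].function == row["function"]
            assert match[0].top_hit_id == row["source_protein"]

    def test_no_decoys_in_catalogue(self, small_sim):
        eves, _ = discover(small_sim.contigs, small_sim.db, "Synthetica exempli")
        decoy_sources = set(
            small_sim.truth.loc[small_sim.truth["category"] != "viral", "source_protein"]
        )
        assert not any(e.top_hit_id in decoy_sources for e in eves)

    def test_verdict_partition(self, small_sim):
        """Every forward candidate lands in exactly one of catalogue /
        discard list."""
        eves, verdicts = discover(small_sim.contigs, small_sim.db, "Synthetica exempli")
        kept = [v for v in verdicts if v.decision == "keep"]
        discarded = [v for v in verdicts if v.decision == "discard"]
        assert len(kept) == len(eves)
        assert len(kept) + len(discarded) == len(verdicts)
        for v in verdicts:
            assert (v.decision == "keep") == (v.best_hit_category == "viral")

    def test_names_are_deterministic(self, small_sim):
        eves1, _ = discover(small_sim.contigs, small_sim.db, "Synthetica exempli")
        eves2, _ = discover(small_sim.contigs, small_sim.db, "Synthetica exempli")
        assert [e.name for e in eves1] == [e.name for e in eves2]
        assert all(e.name.startswith("nrEVE_Sexe") for e in eves1)

    def test_te_decoy_similar_to_viral_entry_is_discarded(self, rng):
        """A planted TE sequence that is ~60% identical to a viral db entry
        is found by the forward screen but discarded at validation, where
        the TE entry itself is the top hit."""
        te_protein = random_protein(rng, 200)
        viral_lookalike = diverge_protein(rng, te_protein, 0.4)
        extra = [
            ProteinDbEntry("viral_fake", viral_lookalike, "viral", "Rhabdoviridae", "Capsid",
                           "negative_ssRNA"),
            ProteinDbEntry("te_real", te_protein, "TE"),
        ]
        sim = simulate_genome(
            SimulationConfig(
                seed=31,
                contig_count=1,
                contig_length=30_000,
                insertions=[InsertionSpec("te_real", divergence=0.0)],
                decoys_per_category={},
                extra_db_entries=extra,
            )
        )
        eves, verdicts = discover(sim.contigs, sim.db, "Synthetica exempli")
        assert eves == []
        assert len(verdicts) == 1
        assert verdicts[0].decision == "discard"
        assert verdicts[0].best_hit_id == "te_real"
        assert verdicts[0].best_hit_category == "TE"

    def test_no_forward_hits_is_not_an_error(self, small_sim):
        background = SequenceRecord("bg", "", "ACGT" * 2000)
        eves, verdicts = discover([background], small_sim.db, "Synthetica exempli")
        assert eves == [] and verdicts == []


class TestClustering:
    def _catalogue(self, rows):
        table = pd.DataFrame(
            rows, columns=["name", "species", "accession", "start", "length"]
        )
        table["region"] = "Capsid"
        table["family"] = "Rhabdoviridae"
        table["transcript_k"] = pd.array([None] * len(table), dtype="Int64")
        table["transcript_n"] = pd.array([None] * len(table), dtype="Int64")
        return EveCatalogue(table)

    def test_catalogue_pair_within_5000(self):
        clusters = cluster_by_distance(packaged_table1(), 5000)
        by_contig = {c.contig: c for c in clusters}
        c = by_contig["LGAM02022319.1"]
        assert c.members == ["nrEVE_BoleTymo_1", "nrEVE_BoleVirga_1"]
        assert c.gaps == [571]

    def test_catalogue_pair_within_1000(self):
        clusters = cluster_by_distance(packaged_table1(), 1000)
        by_contig = {c.contig: c for c in clusters}
        c = by_contig["NW_016157156.1"]
        assert c.members == ["nrEVE_RzepuncRib_1", "nrEVE_RzepVirga_1"]
        assert c.gaps == [301]

    def test_sixty_bp_neighbours(self):
        clusters = cluster_by_distance(packaged_table1(), 200)
        by_contig = {c.contig: c for c in clusters}
        c = by_contig["JXPB01076293.1"]
        assert c.members == ["nrEVE_EdiaRhabdo_9", "nrEVE_EdiaRhabdo_10"]
        assert c.gaps == [60]

    def test_threshold_zero_disjoint(self):
        cat = self._catalogue(
            [
                ("a", "X y", "c1", 100, 50),
                ("b", "X y", "c1", 200, 50),
            ]
        )
        assert cluster_by_distance(cat, 0) == []

    def test_row_order_invariance(self):
        cat = packaged_table1()
        shuffled = EveCatalogue(
            cat.table.sample(frac=1.0, random_state=7).reset_index(drop=True)
        )
        a = cluster_by_distance(cat, 5000)
        b = cluster_by_distance(shuffled, 5000)
        assert [(c.contig, c.members, c.gaps) for c in a] == [
            (c.contig, c.members, c.gaps) for c in b
        ]

    def test_negative_gap_counts_as_zero(self):
        cat = self._catalogue(
            [
                ("a", "X y", "c1", 100, 200),
                ("b", "X y", "c1", 250, 50),
            ]
        )
        clusters = cluster_by_distance(cat, 0)
        assert len(clusters) == 1 and clusters[0].gaps == [0]


@pytest.fixture(scope="module")
def reference():
    return simulate_reference_virus(
        seed=41,
        orf_specs=[("N", "Capsid", 400), ("G", "Glycoprotein", 500), ("L", "RdRp", 1900)],
    )


class TestRegionAssignment:

    def _eve_from(self, rng, genome, lo, hi, name="nrEVE_SexeRhabdo_1"):
        from paleoscan.eve_discovery import NrEve

        seq = genome.sequence[lo:hi]
        return NrEve(
            name=name,
            host_species="Synthetica exempli",
            contig="c1",
            start=1,
            length=len(seq),
            genomic_strand="+",
            family="Rhabdoviridae",
            sense_class="negative_ssRNA",
            function="Hypothetical",
            top_hit_id="x",
            top_identity=1.0,
            top_evalue=1e-30,
            sequence=seq,
        )

    def test_glycoprotein_overlap(self, reference, rng):
        genome, table, _ = reference
        g = next(o for o in table.orfs if o.name == "G")
        eve = self._eve_from(rng, genome, g.start + 99, g.start + 99 + 600)
        result = assign_function_region(eve, genome, table)
        assert result.mapped
        assert result.function == "Glycoprotein"
        assert abs(result.ref_start - (g.start + 100)) <= 3

    def test_intergenic_is_hypothetical(self, reference, rng):
        genome, table, _ = reference
        n = next(o for o in table.orfs if o.name == "N")
        # the spacer between N and G
        eve = self._eve_from(rng, genome, n.end + 10, n.end + 190)
        result = assign_function_region(eve, genome, table)
        assert result.function == "Hypothetical"

    def test_unconfigured_family_is_unmapped(self, reference, rng):
        genome, table, _ = reference
        eve = self._eve_from(rng, genome, 300, 800)
        results = assign_function_regions([eve], references={})
        assert len(results) == 1
        assert not results[0].mapped

    def test_planted_labels_recovered(self):
        """Region labels of >= 10 synthetic nrEVEs derived from reference
        ORFs are reproduced exactly at 20% divergence."""
        genome, table, proteins = simulate_reference_virus(
            seed=43,
            orf_specs=[("N", "Capsid", 400), ("G", "Glycoprotein", 500), ("L", "RdRp", 1500)],
        )
        rng = np.random.default_rng(44)
        from paleoscan.eve_discovery import NrEve
        from paleoscan.synthetic_data import reverse_translate, diverge_protein

        eves, expected = [], []
        orf_list = [o for o in table.orfs]
        for i in range(12):
            orf = orf_list[i % 3]
            protein = proteins[orf.name]
            lo = int(rng.integers(0, len(protein) - 80))
            frag = diverge_protein(rng, protein[lo : lo + 80], 0.2)
            seq = reverse_translate(rng, frag)
            eves.append(
                NrEve(
                    name=f"nrEVE_SexeRhabdo_{i+1}",
                    host_species="Synthetica exempli",
                    contig="c1",
                    start=1,
                    length=len(seq),
                    genomic_strand="+",
                    family="Rhabdoviridae",
                    sense_class="negative_ssRNA",
                    function="Hypothetical",
                    top_hit_id="x",
                    top_identity=0.8,
                    top_evalue=1e-20,
                    sequence=seq,
                )
            )
            expected.append(orf.function)
        results = [assign_function_region(e, genome, table) for e in eves]
        assert [r.function for r in results] == expected


class TestCatalogueFromEves:
    def test_shape_and_roundtrip(self, small_sim):
        eves, _ = discover(small_sim.contigs, small_sim.db, "Synthetica exempli")
        cat = catalogue_from_eves(eves)
        assert len(cat) == len(eves)
        assert set(cat.table["family"]) <= {
            e.family for e in eves
        }
        assert (cat.table["start"] >= 1).all()
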