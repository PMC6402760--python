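import numpy as np
import pytest

from utrlens.catalog_io import Region, read_catalog_fasta
from utrlens.composition import gc_content
from utrlens.conservation import codon_partition_identity, pairwise_identity
from utrlens.kmer_enrichment import count_kmers
from utrlens.mirna_accessibility import find_seed_matches
from utrlens.pas_scan import annotate_pas
from utrlens.synthetic_data import (
    DivergenceSpec,
    PlanError,
    SimulationPlan,
    diverge_family,
    ed_preset,
    expected_pairwise_identity,
    ld_preset,
    simulate_catalog,
    simulate_gene,
    write_outputs,
)
from utrlens.uorf_scan import build_profile

LET7 = "TGAGGTAGTAGGTTGTATAGTT"


def rich_plan(seed=11):
    return SimulationPlan(
        seed=seed,
        n_genes=3,
        utr5_length=320,
        utr3_length=260,
        planted_uorfs=[(25, "optimal", 4), (80, "weak", 3), (150, "adequate", 2)],
        planted_pas=[("AATAAA", 23), ("ATTAAA", 120)],
        planted_kmers=[("CTGGCA", 3)],
        planted_mirna_sites=[("let7", LET7, 200)],
    )


class TestDeterminism:
    def test_same_seed_identical_records(self):
        a = simulate_gene(rich_plan(), 0)
        b = simulate_gene(rich_plan(), 0)
        assert [r.sequence for r in a[:3]] == [r.sequence for r in b[:3]]

    def test_fasta_bytes_identical(self, tmp_path):
        p1 = write_outputs(rich_plan(), tmp_path / "run1")
        p2 = write_outputs(rich_plan(), tmp_path / "run2")
        for key in ("utr5", "utr3", "cds", "truth"):
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_different_seed_differs(self):
        a = simulate_gene(rich_plan(1), 0)
        b = simulate_gene(rich_plan(2), 0)
        assert a[0].sequence != b[0].sequence


class TestPlantedFeatureRecovery:
    def test_uorfs_recovered_with_classes(self):
        utr5, _, _, truth = simulate_gene(rich_plan(), 0)
        profile = build_profile(utr5.sequence)
        found = {
            u.start: (u.cap_distance, u.context_class.value, u.distance_class.value)
            for u in profile.uorfs
        }
        assert len(profile.uorfs) == len(truth["uorfs"]) == 3
        for planted in truth["uorfs"]:
            got = found[planted["start"]]
            assert got == (
                planted["cap_distance"],
                planted["context_class"],
                planted["distance_class"],
            )

    def test_no_spurious_uaugs(self):
        utr5, _, _, truth = simulate_gene(rich_plan(), 1)
        profile = build_profile(utr5.sequence)
        assert profile.n_uaug == len(truth["uorfs"])

    def test_pas_recovered_with_efficiency(self):
        _, utr3, _, truth = simulate_gene(rich_plan(), 0)
        sites = annotate_pas(utr3.sequence)
        assert len(sites) == len(truth["pas"]) == 2
        by_pos = {s.position: s for s in sites}
        canonical = by_pos[truth["pas"][0]["position"]]
        assert canonical.pas_type.value == "C"
        assert canonical.efficiency.value == "VE"

    def test_kmers_present_at_recorded_positions(self):
        utr5, _, _, truth = simulate_gene(rich_plan(), 2)
        for item in truth["kmers"]:
            pos = item["position"] - 1
            assert utr5.sequence[pos : pos + 6] == item["kmer"]
        assert count_kmers([utr5.sequence], 6).get("CTGGCA", 0) >= 3

    def test_mirna_sites_recovered(self):
        _, utr3, _, truth = simulate_gene(rich_plan(), 0)
        matches = find_seed_matches(LET7, utr3.sequence)
        starts = {m.site_start for m in matches}
        for item in truth["mirna_sites"]:
            assert item["site_start"] in starts

    def test_cds_is_open_reading_frame(self):
        _, _, cds, _ = simulate_gene(rich_plan(), 0)
        seq = cds.sequence
        assert seq.startswith("ATG")
        assert seq[-3:] in {"TAA", "TAG", "TGA"}
        internal = {seq[i : i + 3] for i in range(3, len(seq) - 3, 3)}
        assert internal.isdisjoint({"TAA", "TAG", "TGA"})

    def test_bulk_recovery_is_exact(self):
        # >= 200 planted features across a catalog, all recovered exactly
        plan = rich_plan(seed=31)
        plan.n_genes = 34  # 34 * (3 uORFs + 2 PAS + 1 site) = 204 features
        utr5s, utr3s, _, truths = simulate_catalog(plan)
        recovered = planted = 0
        for truth, u5, u3 in zip(truths, utr5s, utr3s):
            profile = build_profile(u5.sequence)
            starts = {u.start for u in profile.uorfs}
            for item in truth["uorfs"]:
                planted += 1
                recovered += item["start"] in starts
            positions = {s.position for s in annotate_pas(u3.sequence)}
            for item in truth["pas"]:
                planted += 1
                recovered += item["position"] in positions
            site_starts = {m.site_start for m in find_seed_matches(LET7, u3.sequence)}
            for item in truth["mirna_sites"]:
                planted += 1
                recovered += item["site_start"] in site_starts
        assert planted >= 200
        assert recovered == planted


class TestBackgroundComposition:
    def test_gc_close_to_target_for_long_sequences(self):
        plan = SimulationPlan(seed=3, utr5_length=800, utr3_length=800, gc_target=0.6)
        utr5, utr3, _, _ = simulate_gene(plan, 0)
        for rec in (utr5, utr3):
            assert gc_content(rec.sequence).gc_percent == pytest.approx(60.0, abs=2.0)


class TestPlanValidation:
    def test_oversized_uorf_rejected(self):
        plan = SimulationPlan(seed=0, utr5_length=30,
                              planted_uorfs=[(25, "optimal", 10)])
        with pytest.raises(PlanError, match="exceeds"):
            simulate_gene(plan, 0)

    def test_overlapping_uorfs_rejected(self):
        plan = SimulationPlan(seed=0, utr5_length=300,
                              planted_uorfs=[(20, "optimal", 4), (25, "weak", 4)])
        with pytest.raises(PlanError, match="overlap"):
            simulate_gene(plan, 0)

    def test_optimal_context_requires_minus3(self):
        plan = SimulationPlan(seed=0, planted_uorfs=[(1, "optimal", 3)])
        with pytest.raises(PlanError, match="-3|−3|cap distance"):
            simulate_gene(plan, 0)

    def test_one_codon_uorf_cannot_have_g_at_plus4(self):
        plan = SimulationPlan(seed=0, planted_uorfs=[(25, "optimal", 1)])
        with pytest.raises(PlanError, match="stop"):
            simulate_gene(plan, 0)

    def test_pas_outside_utr_rejected(self):
        plan = SimulationPlan(seed=0, utr3_length=50, planted_pas=[("AATAAA", 60)])
        with pytest.raises(PlanError, match="fit"):
            simulate_gene(plan, 0)

    def test_excessive_rate_rejected(self):
        with pytest.raises(PlanError, match="saturates"):
            DivergenceSpec(utr=0.9)


class TestDivergence:
    def test_zero_rates_give_identical_orthologs(self):
        utr5, _, cds, _ = simulate_gene(rich_plan(), 0)
        fam, table = diverge_family(
            [utr5, cds], DivergenceSpec(pos1=0, pos2=0, pos3=0, utr=0), seed=7
        )
        for species_records in fam.values():
            assert species_records[0].sequence == utr5.sequence
            assert species_records[1].sequence == cds.sequence
        assert table["n_substitutions"].sum() == 0

    def test_codon_position_ordering(self):
        # third positions 3x faster than first/second: partitioned identity
        # must show id12 > id3 in nearly every replicate
        wins = 0
        for rep in range(100):
            plan = SimulationPlan(seed=500 + rep, utr5_length=60, utr3_length=60,
                                  cds_length=450)
            _, _, cds, _ = simulate_gene(plan, 0)
            spec = DivergenceSpec(pos1=0.1, pos2=0.1, pos3=0.3, utr=0.2,
                                  species=("A", "B"))
            fam, _ = diverge_family([cds], spec, seed=1000 + rep)
            id12, id3 = codon_partition_identity(
                fam["A"][0].sequence, fam["B"][0].sequence
            )
            wins += id12 > id3
        assert wins >= 95

    def test_utr_identity_matches_jukes_cantor_expectation(self):
        # substitution-only divergence keeps sites homologous column by
        # column, so column-wise identity is the exact observable to compare
        # with the closed-form expectation
        from utrlens.conservation import aligned_identity

        rate = 0.45
        identities = []
        for rep in range(40):
            plan = SimulationPlan(seed=200 + rep, utr5_length=600, utr3_length=60)
            utr5, _, _, _ = simulate_gene(plan, 0)
            spec = DivergenceSpec(utr=rate, species=("A", "B"))
            fam, _ = diverge_family([utr5], spec, seed=300 + rep)
            identities.append(
                aligned_identity(fam["A"][0].sequence, fam["B"][0].sequence)
            )
        assert np.mean(identities) == pytest.approx(
            expected_pairwise_identity(rate), abs=5.0
        )

    def test_diverged_cds_stays_open(self):
        _, _, cds, _ = simulate_gene(rich_plan(), 0)
        spec = DivergenceSpec(pos1=0.3, pos2=0.3, pos3=0.3, utr=0.3, species=("A",))
        fam, _ = diverge_family([cds], spec, seed=9)
        seq = fam["A"][0].sequence
        internal = {seq[i : i + 3] for i in range(3, len(seq) - 3, 3)}
        assert internal.isdisjoint({"TAA", "TAG", "TGA"})


class TestPresetsAndIo:
    def test_presets_generate_valid_catalogs(self):
        for preset in (ed_preset(5), ld_preset(5)):
            utr5s, utr3s, cdss, truths = simulate_catalog(preset)
            assert len(utr5s) == len(utr3s) == len(cdss) == len(truths)
            assert len(utr5s) > 0

    def test_ed_preset_has_uorfs_ld_does_not(self):
        utr5s, _, _, _ = simulate_catalog(ed_preset(5))
        assert all(build_profile(r.sequence).n_uorf == 2 for r in utr5s)
        utr5s, _, _, _ = simulate_catalog(ld_preset(5))
        assert all(build_profile(r.sequence).n_uorf == 0 for r in utr5s)

    def test_written_fasta_round_trips(self, tmp_path):
        paths = write_outputs(rich_plan(), tmp_path / "out")
        cat = read_catalog_fasta(paths["utr5"], Region.FIVE_PRIME)
        assert len(cat) == 3

    def test_yaml_round_trip(self, tmp_path):
        plan = rich_plan()
        path = tmp_path / "plan.yaml"
        plan.to_yaml(path)
        loaded = SimulationPlan.from_yaml(path)
        assert loaded == plan
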