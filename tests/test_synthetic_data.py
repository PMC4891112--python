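import dataclasses

import numpy as np
import pytest

from shattercall.events import JunctionSpec, RearrangementEvent
from shattercall.genome import gc_fraction, revcomp
from shattercall.sv_calling import CallerConfig, PairClass, classify_read_pair
from shattercall.synthetic_data import (
    ConflictError,
    IrradiationConfig,
    ReadSimParams,
    build_rescale_map,
    compute_absorbed_dose,
    generate_reference,
    plant_rearrangements,
    rescale_events,
    simulate_probe_track,
    simulate_read_pairs,
)


# ---------------------------------------------------------------------------
# dosimetry
# ---------------------------------------------------------------------------


class TestDose:
    def test_reference_value(self):
        # independent arithmetic: 100 * 11.7e3 eV/um in J, over
        # 1000 kg/m^3 * pi * (1e-6 m)^2 * 1e-6 m
        expected = (100 * 11.7e3 * 1.602176634e-19) / (1000 * np.pi * 1e-12 * 1e-6)
        dose = compute_absorbed_dose(IrradiationConfig(100))
        assert dose == pytest.approx(expected)
        assert dose == pytest.approx(59.7, abs=0.1)

    def test_linearity_exact(self):
        for n in (1, 7, 100):
            d1 = compute_absorbed_dose(IrradiationConfig(n))
            d2 = compute_absorbed_dose(IrradiationConfig(2 * n))
            assert d2 == 2 * d1

    def test_zero_protons(self):
        assert compute_absorbed_dose(IrradiationConfig(0)) == 0.0

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            IrradiationConfig(10, spot_diameter_um=0)
        with pytest.raises(ValueError):
            IrradiationConfig(-1)


# ---------------------------------------------------------------------------
# reference generation
# ---------------------------------------------------------------------------


class TestGenerateReference:
    def test_forced_length(self):
        genome = generate_reference({"chr1": 100_000}, 0.41, seed=1)
        assert genome.lengths == {"chr1": 100_000}

    def test_deterministic(self):
        a = generate_reference({"chr1": 50_000}, 0.41, seed=9)
        b = generate_reference({"chr1": 50_000}, 0.41, seed=9)
        assert a.chromosomes == b.chromosomes

    def test_gc_fraction_within_binomial_bound(self):
        genome = generate_reference({"chr1": 1_000_000}, 0.50, seed=7)
        assert 0.48 <= gc_fraction(genome.chromosomes["chr1"]) <= 0.52

    def test_invalid_length(self):
        with pytest.raises(ValueError):
            generate_reference({"chr1": 0}, 0.4, seed=0)


# ---------------------------------------------------------------------------
# rescaling
# ---------------------------------------------------------------------------


class TestRescale:
    def test_small_gaps_survive_exactly(self):
        rmap = build_rescale_map({"7": [100, 105, 2_000_000, 2_000_377]}, 12_000, 15_000)
        m = rmap.mapping["7"]
        assert m[105] - m[100] == 5
        assert m[2_000_377] - m[2_000_000] == 377
        assert m[2_000_000] - m[105] == 12_000  # capped

    def test_order_preserved(self, demo_events):
        scaled, rmap = rescale_events(demo_events)
        for orig, new in zip(demo_events, scaled):
            assert orig.rtype == new.rtype
            assert orig.chrom1 == new.chrom1 and orig.chrom2 == new.chrom2
        for chrom, table in rmap.mapping.items():
            origs = sorted(table)
            news = [table[p] for p in origs]
            assert news == sorted(news)
            assert len(set(news)) == len(news)

    def test_margins(self):
        rmap = build_rescale_map({"1": [500_000]}, 12_000, 15_000)
        assert rmap.mapping["1"][500_000] == 15_000
        assert rmap.chrom_lengths["1"] == 30_000


# ---------------------------------------------------------------------------
# planting
# ---------------------------------------------------------------------------


def _single_chrom_ref(length=100_000, seed=3):
    return generate_reference({"c1": length}, 0.45, seed=seed)


class TestPlant:
    def test_ld_conserves_sequence(self):
        ref = _single_chrom_ref()
        event = RearrangementEvent("d1", "c1", 40_000, "c1", 50_000, "LD", JunctionSpec.blunt())
        derivative = plant_rearrangements(ref, [event])
        assert len(derivative.contigs["der_d1"]) == 90_000
        assert derivative.truth[0].bases_removed == 10_000

    def test_ct_fusion_matches_manual_concatenation(self):
        ref = generate_reference({"chr5": 60_000, "chr20": 60_000}, 0.41, seed=4)
        event = RearrangementEvent(
            "t1", "chr5", 30_000, "chr20", 20_000, "CT", JunctionSpec.blunt()
        )
        derivative = plant_rearrangements(ref, [event])
        edited = derivative.reference
        expected = edited.fetch("chr5", 1, 30_000) + edited.fetch("chr20", 20_000, 60_000)
        assert derivative.contigs["der_t1"].seq == expected

    def test_ff_contig_is_prefix_plus_inverted_segment(self):
        ref = _single_chrom_ref()
        event = RearrangementEvent("f1", "c1", 30_000, "c1", 45_000, "FF", JunctionSpec.blunt())
        derivative = plant_rearrangements(ref, [event])
        edited = derivative.reference
        expected = edited.fetch("c1", 1, 30_000) + revcomp(edited.fetch("c1", 30_001, 45_000))
        assert derivative.contigs["der_f1"].seq == expected

    def test_rf_contig_retraverses_segment(self):
        ref = _single_chrom_ref()
        event = RearrangementEvent("r1", "c1", 30_000, "c1", 45_000, "RF", JunctionSpec.blunt())
        derivative = plant_rearrangements(ref, [event])
        assert len(derivative.contigs["der_r1"]) == 100_000 + 15_001
        assert derivative.truth[0].bases_added == 15_001

    def test_insertion_adds_bases(self):
        ref = _single_chrom_ref()
        event = RearrangementEvent(
            "i1", "c1", 40_000, "c1", 50_000, "LD", JunctionSpec.insertion("CTGAA")
        )
        derivative = plant_rearrangements(ref, [event])
        assert len(derivative.contigs["der_i1"]) == 90_000 + 5

    def test_length_accounting_for_any_event_list(self, demo_bundle):
        derivative = demo_bundle["derivative"]
        ref = derivative.reference
        for entry in derivative.truth:
            contig = derivative.contigs[entry.contig]
            if entry.rtype == "LD":
                base = ref.length(entry.chrom1)
            elif entry.rtype == "CT":
                base = entry.pos1 + ref.length(entry.chrom2) - entry.pos2 + 1
            else:  # RF and FF both account against the full chromosome
                base = ref.length(entry.chrom1)
            assert len(contig) == base - entry.bases_removed + entry.bases_added

    def test_demo_truth_table_has_14_junctions(self, demo_bundle):
        assert len(demo_bundle["derivative"].truth) == 14

    def test_out_of_bounds_breakpoint(self):
        ref = _single_chrom_ref()
        event = RearrangementEvent("x", "c1", 40_000, "c1", 200_000, "LD", JunctionSpec.blunt())
        with pytest.raises(ValueError):
            plant_rearrangements(ref, [event])

    def test_conflicting_events_raise(self):
        ref = _single_chrom_ref()
        events = [
            RearrangementEvent("a", "c1", 40_000, "c1", 50_000, "LD", JunctionSpec.microhomology("AAAA")),
            RearrangementEvent("b", "c1", 39_998, "c1", 70_000, "LD", JunctionSpec.microhomology("CCCC")),
        ]
        with pytest.raises(ConflictError):
            plant_rearrangements(ref, events)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


class TestSimulateReads:
    def test_mean_implied_insert(self):
        genome = generate_reference({"c1": 100_000}, 0.41, seed=2)
        params = ReadSimParams(seed=5)
        pairs = simulate_read_pairs(genome, params)
        implied = [p.sides[1].end - p.sides[0].pos + 1 for p in pairs]
        assert 295 <= np.mean(implied) <= 305

    def test_planted_ct_produces_discordant_pairs(self):
        ref = generate_reference({"a": 60_000, "b": 60_000}, 0.41, seed=6)
        event = RearrangementEvent("t", "a", 30_000, "b", 30_000, "CT", JunctionSpec.blunt())
        derivative = plant_rearrangements(ref, [event])
        pairs = simulate_read_pairs(derivative, ReadSimParams(seed=7))
        cfg = CallerConfig()
        n_ct = sum(
            1 for p in pairs if classify_read_pair(p, cfg) is PairClass.CT
        )
        assert n_ct >= 3

    def test_error_free_reads_have_zero_mismatches(self):
        genome = generate_reference({"c1": 50_000}, 0.41, seed=2)
        pairs = simulate_read_pairs(genome, ReadSimParams(seed=1))
        assert all(p.end1.nm == 0 and p.end2.nm == 0 for p in pairs)

    def test_error_rate_produces_mismatches(self):
        genome = generate_reference({"c1": 50_000}, 0.41, seed=2)
        pairs = simulate_read_pairs(
            genome, ReadSimParams(substitution_error_rate=0.02, seed=1)
        )
        assert sum(p.end1.nm + p.end2.nm for p in pairs) > 0
        # recorded mismatch counts equal the substitutions applied
        ref_seq = genome.chromosomes["c1"]
        for p in pairs[:200]:
            aligned = ref_seq[p.end1.pos - 1 : p.end1.pos - 1 + len(p.end1.seq)]
            diff = sum(1 for x, y in zip(aligned, p.end1.seq) if x != y)
            assert diff == p.end1.nm

    def test_deterministic(self):
        genome = generate_reference({"c1": 50_000}, 0.41, seed=2)
        a = simulate_read_pairs(genome, ReadSimParams(seed=3))
        b = simulate_read_pairs(genome, ReadSimParams(seed=3))
        assert a == b

    def test_empty_genome_rejected(self):
        from shattercall.genome import ReferenceGenome

        with pytest.raises(ValueError):
            simulate_read_pairs(ReferenceGenome({}), ReadSimParams(seed=0))

    def test_param_validation(self):
        with pytest.raises(ValueError):
            ReadSimParams(read_length=300, insert_mean=200)
        with pytest.raises(ValueError):
            ReadSimParams(coverage=0)
        with pytest.raises(ValueError):
            ReadSimParams(substitution_error_rate=1.0)


# ---------------------------------------------------------------------------
# probe tracks
# ---------------------------------------------------------------------------


class TestProbeTrack:
    def test_flat_noise_free(self):
        track = simulate_probe_track({"c": 50_000}, [], 1_000, 0.0, seed=0)
        assert (track.df["signal"] == 2.0).all()

    def test_deletion_segment_noise_free(self):
        truth = [{"chrom": "c", "start": 10_000, "end": 20_000, "copy": 1.0}]
        track = simulate_probe_track({"c": 50_000}, truth, 1_000, 0.0, seed=0)
        inside = track.subset("c", 10_000, 20_000)
        outside = track.df[(track.df["pos"] < 10_000) | (track.df["pos"] > 20_000)]
        assert (inside["signal"] == 1.0).all()
        assert (outside["signal"] == 2.0).all()

    def test_demo_segments_give_16_shifted_runs(self, cna_run):
        # noise-free rerun on the same rescaled grid
        track = simulate_probe_track(
            cna_run["rmap"].chrom_lengths, cna_run["truth"], 1_000, 0.0, seed=0
        )
        runs = 0
        for chrom in track.chromosomes():
            sig = track.subset(chrom)["signal"].values
            shifted = sig != 2.0
            runs += int(np.sum(shifted[1:] & ~shifted[:-1]) + (1 if shifted[0] else 0))
        assert runs == 16

    def test_each_demo_segment_holds_30_probes(self, cna_run):
        track = cna_run["sample"]
        for seg in cna_run["truth"]:
            assert len(track.subset(seg["chrom"], seg["start"], seg["end"])) >= 30

    def test_baf_states(self):
        truth = [
            {"chrom": "c", "start": 10_000, "end": 20_000, "copy": 1.0},
            {"chrom": "c", "start": 30_000, "end": 40_000, "copy": 3.0},
        ]
        track = simulate_probe_track({"c": 60_000}, truth, 1_000, 0.0, seed=1, het_fraction=1.0)
        loh = track.subset("c", 10_000, 20_000)["baf"]
        assert set(loh.unique()) <= {0.0, 1.0}
        balanced = track.df[(track.df["pos"] < 10_000)]["baf"]
        assert (balanced == 0.5).all()
        gained = track.subset("c", 30_000, 40_000)["baf"]
        assert set(np.round(gained.unique(), 6)) <= {round(1 / 3, 6), round(2 / 3, 6)}

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            simulate_probe_track({"c": 50_000}, [], 1_000, -0.1, seed=0)

    def test_deterministic(self):
        a = simulate_probe_track({"c": 50_000}, [], 1_000, 0.3, seed=4)
        b = simulate_probe_track({"c": 50_000}, [], 1_000, 0.3, seed=4)
        assert a.df.equals(b.df)
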