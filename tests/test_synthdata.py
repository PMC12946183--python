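"""Simulator contracts: community geometry, mechanism laws, nuisance processes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from transductomics import synthdata as sd
from transductomics import (
    CommunitySpec,
    GenomeSpec,
    MechanismParams,
    ProphageSpec,
    add_contamination,
    apply_degradation,
    capacity_from_genome,
    generate_community,
    simulate_particles,
    truth_to_alignments,
)


class TestGenerateCommunity:
    def test_minimal_single_scaffold(self):
        com = generate_community(
            CommunitySpec(genomes=[GenomeSpec("g1", 100_000)], seed=1)
        )
        assert len(com.scaffolds) == 1
        assert int(com.scaffolds.iloc[0]["length"]) == 100_000
        assert len(com.get_sequence("g1")) == 100_000

    def test_prophage_length_recorded(self):
        com = generate_community(
            CommunitySpec(
                genomes=[GenomeSpec("g1", 4_000_000)],
                prophages=[ProphageSpec("g1", 1_000_000, 1_056_900, "pp1")],
                seed=1,
            )
        )
        pp = com.prophages.iloc[0]
        assert int(pp["end"] - pp["start"]) == 56_900

    def test_scaffold_lengths_conserve_genome_lengths(self):
        spec = CommunitySpec(
            genomes=[GenomeSpec("a", 300_000), GenomeSpec("b", 120_000)],
            breakpoints={"a": [100_000, 175_000]},
            seed=3,
        )
        com = generate_community(spec)
        assert com.scaffolds["length"].sum() == 420_000
        assert len(com.scaffolds) == 4

    @pytest.mark.parametrize(
        "prophages, match",
        [
            (
                [
                    ProphageSpec("g1", 100, 5_000, "p1"),
                    ProphageSpec("g1", 4_000, 9_000, "p2"),
                ],
                "overlaps",
            ),
            ([ProphageSpec("g1", 100, 5_000, "p1", pac_offset=9_999)], "pac offset"),
            ([ProphageSpec("g1", 90_000, 150_000, "p1")], "outside genome"),
        ],
    )
    def test_invalid_prophages_rejected_by_name(self, prophages, match):
        spec = CommunitySpec(genomes=[GenomeSpec("g1", 100_000)], prophages=prophages)
        with pytest.raises(sd.CommunityValidationError, match=match):
            generate_community(spec)

    def test_identical_seed_identical_bytes(self, tmp_path):
        outputs = []
        for _ in range(2):
            spec = CommunitySpec(genomes=[GenomeSpec("g1", 20_000)], seed=9)
            com = generate_community(spec)
            truth, reads = simulate_particles(
                com,
                MechanismParams("GTA", genome_id="g1", capacity=4_000),
                40,
                seed=5,
                with_sequences=True,
            )
            sd.write_fasta(reads, tmp_path / "r.fa")
            sd.write_truth(truth, tmp_path / "t.tsv")
            outputs.append(
                ((tmp_path / "r.fa").read_bytes(), (tmp_path / "t.tsv").read_bytes())
            )
        assert outputs[0] == outputs[1]


class TestMechanisms:
    def test_cos_reads_are_exact_unit_genomes(self, phage_community):
        truth, _ = simulate_particles(
            phage_community, MechanismParams("cos", genome_id="crassus"), 100, seed=2
        )
        assert len(truth) == 100
        assert (truth["length"] == 102_000).all()

    def test_headful_length_bounds_and_permuted_starts(self, phage_community):
        H, eps = 43_400, 0.02
        truth, _ = simulate_particles(
            phage_community,
            MechanismParams("headful", genome_id="crassus", capacity=H, imprecision=eps),
            5_000,
            seed=3,
        )
        assert truth["length"].between(42_532, 44_268).all()
        starts = np.sort(truth["start"].to_numpy() % 102_000)
        gaps = np.diff(np.concatenate([starts, [starts[0] + 102_000]]))
        assert gaps.max() < 0.05 * 102_000  # circular permutation covers the genome

    def test_mu_appends_host_dna_and_is_chimeric(self):
        com = generate_community(
            CommunitySpec(
                genomes=[GenomeSpec("mu", 37_000, domain="virus", is_viral=True),
                         GenomeSpec("host", 500_000)],
                seed=4,
            )
        )
        truth, _ = simulate_particles(
            com,
            MechanismParams("mu", genome_id="mu", host_genome_id="host",
                            mu_host_range=(500, 3000)),
            1_000,
            seed=6,
        )
        assert truth["length"].between(37_500, 40_000).all()
        assert truth["chimeric"].all()

    def test_lt_series_geometry_exact_without_jitter(self, lysogen_community):
        # with zero imprecision the k-th fragment starts exactly at pac+(k-1)H
        H, N = 58_400, 5
        truth, _ = simulate_particles(
            lysogen_community,
            MechanismParams("LT", prophage_id="pp1", capacity=H, imprecision=0.0,
                            series_length=N),
            500,
            seed=7,
        )
        pac = 100_000
        expect = pac + (truth["series_k"] - 1) * H
        assert (truth["start"] == expect).all()
        # prophage (56.9 kb) shorter than H: exactly the k=1 fragments are chimeric
        assert (truth["chimeric"] == (truth["series_k"] == 1)).all()

    def test_lt_chimeric_fraction_is_one_over_series_length(self, lysogen_community):
        N = 5
        truth, _ = simulate_particles(
            lysogen_community,
            MechanismParams("LT", prophage_id="pp1", capacity=58_400, series_length=N),
            4_000,
            seed=8,
        )
        frac = truth["chimeric"].mean()
        assert abs(frac - 1 / N) < 0.03

    def test_gta_start_positions_uniform_over_genome(self, lysogen_community):
        # KS vs uniform non-significant at alpha=0.01 in >=95% of replicates
        G = 600_000
        ok = 0
        for rep in range(100):
            truth, _ = simulate_particles(
                lysogen_community,
                MechanismParams("GTA", genome_id="host", capacity=8_650),
                2_000,
                seed=1_000 + rep,
            )
            p = stats.kstest(truth["start"].to_numpy() / G, "uniform").pvalue
            ok += p > 0.01
        assert ok >= 95

    def test_gt_transducing_fraction_and_pseudo_pac_series(self):
        com = generate_community(
            CommunitySpec(
                genomes=[GenomeSpec("phage", 41_700, domain="virus", is_viral=True),
                         GenomeSpec("host", 2_000_000)],
                seed=5,
            )
        )
        truth, _ = simulate_particles(
            com,
            MechanismParams("GT", genome_id="phage", host_genome_id="host",
                            capacity=43_400, transducing_fraction=0.25),
            8_000,
            seed=9,
        )
        host_share = (truth["genome_id"] == "host").mean()
        assert abs(host_share - 0.25) < 0.02
        assert (truth.loc[truth["genome_id"] == "host", "series_k"] >= 1).all()

    def test_zero_particles_yield_empty_outputs(self, phage_community):
        truth, reads = simulate_particles(
            phage_community, MechanismParams("cos", genome_id="crassus"), 0, seed=1,
            with_sequences=True,
        )
        assert len(truth) == 0 and reads == []

    def test_missing_required_parameter_raises(self, phage_community):
        with pytest.raises(sd.CommunityValidationError, match="capacity"):
            simulate_particles(
                phage_community, MechanismParams("headful", genome_id="crassus"), 10, 1
            )

    def test_truth_rows_match_reads_and_lengths(self, lysogen_community):
        truth, reads = simulate_particles(
            lysogen_community,
            MechanismParams("headful", prophage_id="pp1",
                            capacity=capacity_from_genome(56_900)),
            60,
            seed=12,
            with_sequences=True,
        )
        assert len(reads) == len(truth)
        for (rid, seq), (_, row) in zip(reads, truth.iterrows()):
            assert rid == row["read_id"]
            assert len(seq) == row["length"]


class TestDegradation:
    def test_zero_share_is_identity(self, phage_community):
        truth, _ = simulate_particles(
            phage_community, MechanismParams("cos", genome_id="crassus"), 50, seed=2
        )
        out, _ = apply_degradation(truth, degraded_share=0.0, seed=3)
        pd.testing.assert_frame_equal(out, truth)

    def test_fixed_retained_fraction_reproduces_shortened_length(self, lysogen_community):
        truth, _ = simulate_particles(
            lysogen_community,
            MechanismParams("LT", prophage_id="pp1", capacity=58_400, imprecision=0.0),
            200,
            seed=4,
        )
        out, _ = apply_degradation(
            truth, retained_fraction_range=(0.402, 0.402), degraded_share=1.0, seed=5
        )
        assert (out["length"] == 23_477).all()  # round(58,400 * 0.402)

    def test_truncation_preserves_packaging_start(self, lysogen_community):
        truth, _ = simulate_particles(
            lysogen_community,
            MechanismParams("LT", prophage_id="pp1", capacity=58_400),
            300,
            seed=6,
        )
        out, _ = apply_degradation(truth, degraded_share=0.5, seed=7)
        assert (out["start"] == truth["start"]).all()
        degraded = out[out["degraded"]]
        assert len(degraded) > 0
        assert (degraded["length"] <= truth.loc[degraded.index, "length"]).all()


class TestContamination:
    def test_zero_share_is_identity(self, phage_community):
        truth, _ = simulate_particles(
            phage_community, MechanismParams("cos", genome_id="crassus"), 30, seed=2
        )
        out, _ = add_contamination(truth, phage_community, contaminant_share=0.0)
        pd.testing.assert_frame_equal(out, truth)

    def test_contaminant_count_binomial_around_expectation(self, lysogen_community):
        truth, _ = simulate_particles(
            lysogen_community,
            MechanismParams("GTA", genome_id="host", capacity=8_650),
            1_000,
            seed=3,
        )
        out, _ = add_contamination(
            truth, lysogen_community, contaminant_share=0.5, seed=4
        )
        n_contam = int(out["contaminant"].sum())
        # binomial(2000, 0.5): 99% interval approx 1000 +/- 2.576*sqrt(500)
        assert abs(n_contam - 1_000) < 2.576 * np.sqrt(2_000 * 0.25) + 1

    def test_contaminant_lengths_are_broad(self, lysogen_community):
        truth, _ = simulate_particles(
            lysogen_community,
            MechanismParams("GTA", genome_id="host", capacity=8_650),
            2_000,
            seed=5,
        )
        out, _ = add_contamination(
            truth, lysogen_community, contaminant_share=0.5, seed=6
        )
        lens = out.loc[out["contaminant"], "length"].to_numpy(dtype=float)
        # log-normal with log10-sd 0.35 has CV ~0.96; well above the 0.3 floor
        assert lens.std() / lens.mean() > 0.3


class TestTruthToAlignments:
    def test_wrapped_read_splits_into_two_intervals(self, phage_community):
        truth, _ = simulate_particles(
            phage_community,
            MechanismParams("headful", genome_id="crassus", capacity=110_000,
                            imprecision=0.0),
            20,
            seed=8,
        )
        aln = truth_to_alignments(phage_community, truth)
        per_read = aln.groupby("read_id").agg(n=("aln_len", "size"), s=("aln_len", "sum"))
        assert (per_read["n"] >= 2).all()  # capacity > genome forces a wrap
        assert (per_read["s"] == 110_000).all()

    def test_alignment_lengths_conserve_packaged_length(self, lysogen_community):
        truth, _ = simulate_particles(
            lysogen_community,
            MechanismParams("LT", prophage_id="pp1", capacity=58_400),
            100,
            seed=9,
        )
        aln = truth_to_alignments(lysogen_community, truth)
        sums = aln.groupby("read_id")["aln_len"].sum()
        lens = truth.set_index("read_id")["length"]
        assert (sums == lens.loc[sums.index]).all()
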