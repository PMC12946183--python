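"""Alignment loading, filtering, greatest-sum assignment and taxon rollup."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from transductomics import ingest
from transductomics import (
    CommunitySpec,
    GenomeSpec,
    MechanismParams,
    generate_community,
    simulate_particles,
    truth_to_alignments,
)


def _aln(read_id, read_len, scaffold, start, end):
    return {
        "read_id": read_id,
        "read_len": read_len,
        "scaffold_id": scaffold,
        "start": start,
        "end": end,
        "strand": "+",
        "aln_len": end - start,
    }


def _paf_line(read_id, read_len, scaffold, tstart, tend, tlen=1_000_000):
    span = tend - tstart
    return "\t".join(
        map(str, [read_id, read_len, 0, span, "+", scaffold, tlen, tstart, tend, span, span, 60])
    )


class TestLoadAlignments:
    def test_empty_files_yield_empty_tables(self, tmp_path):
        for dialect in ("paf", "tsv"):
            p = tmp_path / f"empty.{dialect}"
            p.write_text("")
            assert len(ingest.load_alignments(p, dialect)) == 0

    def test_paf_target_coordinates_pass_through(self, tmp_path):
        p = tmp_path / "a.paf"
        p.write_text(_paf_line("r1", 5_000, "s1", 10, 1_010) + "\n")
        df = ingest.load_alignments(p, "paf")
        row = df.iloc[0]
        assert (row["start"], row["end"], row["aln_len"]) == (10, 1_010, 1_000)

    def test_dual_encodings_agree(self, tmp_path):
        rows = [_aln("r1", 5_000, "s1", 10, 1_010), _aln("r2", 8_000, "s2", 0, 7_500)]
        tsv = tmp_path / "a.tsv"
        pd.DataFrame(rows).to_csv(tsv, sep="\t", index=False)
        paf = tmp_path / "a.paf"
        paf.write_text(
            "\n".join(
                _paf_line(r["read_id"], r["read_len"], r["scaffold_id"], r["start"], r["end"])
                for r in rows
            )
            + "\n"
        )
        a = ingest.load_alignments(tsv, "tsv")
        b = ingest.load_alignments(paf, "paf")
        pd.testing.assert_frame_equal(a, b)

    def test_malformed_line_reported_with_number(self, tmp_path):
        p = tmp_path / "bad.paf"
        p.write_text(_paf_line("r1", 5_000, "s1", 10, 1_010) + "\nnot\ta\tpaf\n")
        with pytest.raises(ingest.AlignmentParseError, match="line 2"):
            ingest.load_alignments(p, "paf")

    def test_unknown_dialect_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="dialect"):
            ingest.load_alignments(tmp_path / "x", "sam")


class TestFilterAlignments:
    def test_short_reads_and_short_alignments_removed(self):
        df = pd.DataFrame(
            [
                _aln("short_read", 2_999, "s1", 0, 2_500),
                _aln("short_aln", 3_500, "s1", 0, 999),
                _aln("keeper", 3_000, "s1", 0, 1_000),
            ]
        )
        out = ingest.filter_alignments(df)
        assert list(out["read_id"]) == ["keeper"]

    def test_empty_input_empty_output(self):
        df = pd.DataFrame(columns=ingest.ALIGNMENT_COLUMNS)
        assert len(ingest.filter_alignments(df)) == 0

    @settings(deadline=None, max_examples=25)
    @given(
        lens=st.lists(st.tuples(st.integers(1, 10_000), st.integers(1, 5_000)),
                      min_size=0, max_size=30)
    )
    def test_filter_is_idempotent(self, lens):
        df = pd.DataFrame(
            [_aln(f"r{i}", rl, "s1", 0, al) for i, (rl, al) in enumerate(lens)]
        )
        if len(df) == 0:
            df = pd.DataFrame(columns=ingest.ALIGNMENT_COLUMNS)
        once = ingest.filter_alignments(df)
        twice = ingest.filter_alignments(once)
        pd.testing.assert_frame_equal(once, twice)


class TestAssignReads:
    def test_greatest_sum_beats_single_best_alignment(self):
        df = pd.DataFrame(
            [
                _aln("r1", 12_000, "S1", 0, 5_000),
                _aln("r1", 12_000, "S1", 6_000, 10_000),
                _aln("r1", 12_000, "S2", 0, 8_000),
            ]
        )
        out = ingest.assign_reads(df)
        assert out.iloc[0]["scaffold_id"] == "S1"
        assert out.iloc[0]["aln_sum"] == 9_000

    def test_single_alignment_assigned_directly(self):
        out = ingest.assign_reads(pd.DataFrame([_aln("r1", 5_000, "SX", 0, 4_000)]))
        assert list(out["scaffold_id"]) == ["SX"]

    def test_tie_breaks_to_lexicographically_smallest(self):
        df = pd.DataFrame(
            [_aln("r1", 9_000, "SB", 0, 4_000), _aln("r1", 9_000, "SA", 100, 4_100)]
        )
        assert ingest.assign_reads(df).iloc[0]["scaffold_id"] == "SA"

    def test_one_row_per_read(self, rng):
        rows = []
        for i in range(200):
            for s in rng.choice(["A", "B", "C"], size=rng.integers(1, 4), replace=False):
                rows.append(_aln(f"r{i}", 5_000, s, 0, int(rng.integers(1_000, 5_000))))
        out = ingest.assign_reads(pd.DataFrame(rows))
        assert len(out) == 200
        assert out["read_id"].is_unique

    def test_recovers_true_source_on_synthetic_data(self):
        com = generate_community(
            CommunitySpec(
                genomes=[GenomeSpec("phage", 41_700, domain="virus", is_viral=True),
                         GenomeSpec("host", 1_000_000)],
                seed=21,
            )
        )
        truth, _ = simulate_particles(
            com,
            MechanismParams("GT", genome_id="phage", host_genome_id="host",
                            capacity=43_400, transducing_fraction=0.4),
            3_000,
            seed=22,
        )
        aln = truth_to_alignments(com, truth)
        assigned = ingest.assign_reads(ingest.filter_alignments(aln))
        merged = assigned.merge(truth[["read_id", "genome_id", "chimeric"]], on="read_id")
        clean = merged[~merged["chimeric"]]
        assert (clean["scaffold_id"] == clean["genome_id"]).mean() >= 0.99


def _records():
    return pd.DataFrame(
        [
            {"scaffold_id": "v1", "length": 40_000, "bin_id": "", "domain": "virus",
             "taxonomy": "Testvirus", "is_viral": True},
            {"scaffold_id": "m1", "length": 900_000, "bin_id": "bin.1",
             "domain": "bacteria", "taxonomy": "d__Bacteria;g__Gx", "is_viral": False},
            {"scaffold_id": "m2", "length": 700_000, "bin_id": "bin.2",
             "domain": "bacteria", "taxonomy": "d__Bacteria;g__Gy", "is_viral": False},
            {"scaffold_id": "u1", "length": 250_000, "bin_id": "", "domain": "bacteria",
             "taxonomy": "d__Bacteria;g__Gz", "is_viral": False},
            {"scaffold_id": "u2", "length": 250_000, "bin_id": "", "domain": "bacteria",
             "taxonomy": "d__Bacteria;g__Gw", "is_viral": False},
            {"scaffold_id": "a1", "length": 300_000, "bin_id": "abin", "domain": "archaea",
             "taxonomy": "d__Archaea;g__Ga", "is_viral": False},
        ]
    )


def _prophages():
    return pd.DataFrame(
        [
            {"scaffold_id": "m2", "start": 10_000, "end": 50_000, "prophage_id": "ppA"},
            {"scaffold_id": "u2", "start": 5_000, "end": 45_000, "prophage_id": "ppB"},
        ]
    )


class TestCategorizeScaffolds:
    def test_six_category_mapping(self):
        out = ingest.categorize_scaffolds(_records(), _prophages())
        got = dict(zip(out["scaffold_id"], out["category"]))
        assert got == {
            "v1": "Viruses",
            "m1": "MAG bacteria",
            "m2": "MAG bacteria with prophages",
            "u1": "Bacteria unbinned",
            "u2": "Bacteria with prophages",
            "a1": "Archaea",
        }

    def test_categories_partition_scaffolds(self):
        out = ingest.categorize_scaffolds(_records(), _prophages())
        assert out["category"].isin(ingest.CATEGORIES).all()
        assert len(out) == len(_records())

    def test_missing_domain_raises(self):
        rec = _records()
        rec.loc[0, "domain"] = ""
        with pytest.raises(ValueError, match="domain"):
            ingest.categorize_scaffolds(rec, _prophages())


class TestRollupTaxa:
    def _assignments(self, counts):
        rows = []
        for sid, n in counts.items():
            for i in range(n):
                rows.append({"read_id": f"{sid}_{i}", "read_len": 10_000,
                             "scaffold_id": sid, "aln_sum": 8_000})
        return pd.DataFrame(rows)

    def test_rare_entities_dropped_at_thresholds(self):
        rec = ingest.categorize_scaffolds(_records(), _prophages())
        assignments = self._assignments({"m1": 50, "u1": 51, "v1": 201})
        out = ingest.rollup_taxa(assignments, rec)
        taxa = set(out["taxon"])
        assert "bin.1" not in taxa        # MAG with exactly 50 reads: removed
        assert "g__Gz" in taxa            # unbinned scaffold with 51 reads: kept
        assert "Testvirus" in taxa        # viral scaffold just above the 200 bar

    def test_viral_threshold_is_higher(self):
        rec = ingest.categorize_scaffolds(_records(), _prophages())
        out = ingest.rollup_taxa(self._assignments({"v1": 200}), rec)
        assert len(out) == 0

    def test_empty_assignments_empty_rollup(self):
        rec = ingest.categorize_scaffolds(_records(), _prophages())
        empty = pd.DataFrame(columns=["read_id", "read_len", "scaffold_id", "aln_sum"])
        assert len(ingest.rollup_taxa(empty, rec)) == 0

    def test_taxon_label_fallback_order(self):
        rec = ingest.categorize_scaffolds(_records(), _prophages())
        assignments = self._assignments({"m1": 60, "u1": 60})
        out = ingest.rollup_taxa(assignments, rec)
        labels = dict(zip(out["scaffold_id"], out["taxon"]))
        assert labels["m1"] == "bin.1"     # binned: bin id wins
        assert labels["u1"] == "g__Gz"     # unbinned: lowest taxonomy rank
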