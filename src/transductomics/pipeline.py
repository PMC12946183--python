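"""Run orchestration: simulate and analyze runs, and the labelled benchmark.

A *simulate* run realises a configured community, draws particles per
sample under the configured mechanism mixtures, applies degradation and
contamination, and writes truth tables, alignment-interval TSVs, scaffold
metadata and prophage BED (optionally FASTA) plus a checksum manifest.

An *analyze* run consumes alignments + scaffold metadata (+ prophage BED,
+ optional short-read count tables), applies the read filters, resolves
each read to one scaffold, rolls reads up to taxa, detects per-taxon
read-length peaks, classifies packaging events, computes VLP-enrichment
Z-scores where counts allow, and writes peak/event/enrichment tables and
a summary including the share of reads on purely bacterial scaffolds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as _classify
from . import enrichment as _enrichment
from . import ingest as _ingest
from . import peaks as _peaks
from . import synthdata as _synth
from ._rng import substream_seed

__all__ = ["run_simulate", "run_analyze", "run_benchmark", "load_config"]

logger = logging.getLogger(__name__)

BACTERIAL_CATEGORIES = ("MAG bacteria", "Bacteria unbinned")


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _community_from_config(cfg: dict) -> _synth.Community:
    genomes = [
        _synth.GenomeSpec(
            genome_id=g["id"],
            length=int(g["length"]),
            circular=bool(g.get("circular", True)),
            taxon=g.get("taxon", ""),
            bin_id=g.get("bin"),
            domain=g.get("domain", "bacteria"),
            is_viral=bool(g.get("is_viral", False)),
        )
        for g in cfg.get("genomes", [])
    ]
    prophages = [
        _synth.ProphageSpec(
            genome_id=p["genome"],
            start=int(p["start"]),
            end=int(p["end"]),
            prophage_id=p["id"],
            pac_offset=int(p.get("pac_offset", 0)),
        )
        for p in cfg.get("prophages", [])
    ]
    breakpoints = {k: list(v) for k, v in (cfg.get("breakpoints") or {}).items()}
    spec = _synth.CommunitySpec(
        genomes=genomes, prophages=prophages, breakpoints=breakpoints,
        seed=int(cfg.get("seed", 0)),
    )
    return _synth.generate_community(spec)


def _params_from_config(m: dict) -> _synth.MechanismParams:
    kw = dict(
        mechanism=m["mechanism"],
        genome_id=m.get("genome"),
        host_genome_id=m.get("host_genome"),
        prophage_id=m.get("prophage"),
        capacity=m.get("capacity"),
        pac_position=int(m.get("pac_position", 0)),
    )
    for key in (
        "redundancy", "imprecision", "transducing_fraction", "series_length",
        "pseudo_pac_count", "st_flank", "direction",
    ):
        if key in m:
            kw[key] = m[key]
    if "mu_host_range" in m:
        kw["mu_host_range"] = tuple(m["mu_host_range"])
    return _synth.MechanismParams(**kw)


def run_simulate(config: dict, outdir) -> dict:
    """Execute a simulate run; returns the manifest (path -> sha256)."""
    seed = int(config.get("seed", 0))
    community_cfg = dict(config.get("community") or {})
    if not community_cfg.get("genomes"):
        raise _synth.CommunityValidationError("config has no community.genomes")
    community_cfg.setdefault("seed", seed)
    community = _community_from_config(community_cfg)

    # validate every sample before writing anything (atomicity)
    samples = config.get("samples") or []
    plans = []
    for s in samples:
        mixtures = [_params_from_config(m) for m in s.get("particles", [])]
        for p in mixtures:
            p.validate()
        plans.append((s, mixtures))

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with_sequences = bool(config.get("with_sequences", False))
    manifest = {}

    def emit(name, writer):
        path = outdir / name
        writer(path)
        manifest[name] = _sha256(path)

    emit("scaffolds.tsv", lambda p: _synth.write_scaffold_metadata(community, p))
    emit("prophages.bed", lambda p: _synth.write_prophage_bed(community, p))

    for s, mixtures in plans:
        sid = s["sample_id"]
        truths = []
        for j, (m, params) in enumerate(zip(s.get("particles", []), mixtures)):
            sub = substream_seed(seed, f"{sid}:particles:{j}")
            truth, _ = _synth.simulate_particles(
                community, params, int(m.get("n", 0)),
                int(sub.generate_state(1)[0] % (2**31)),
                read_prefix=f"{sid}_{params.mechanism}{j}",
            )
            truths.append(truth)
        truth = pd.concat(truths, ignore_index=True) if truths else _synth._empty_truth()
        deg = s.get("degradation") or {}
        if deg.get("share", 0):
            sub = substream_seed(seed, f"{sid}:degradation")
            truth, _ = _synth.apply_degradation(
                truth,
                retained_fraction_range=tuple(deg.get("retained", (0.1, 0.9))),
                degraded_share=float(deg["share"]),
                seed=int(sub.generate_state(1)[0] % (2**31)),
            )
        con = s.get("contamination") or {}
        if con.get("share", 0):
            sub = substream_seed(seed, f"{sid}:contamination")
            truth, _ = _synth.add_contamination(
                truth, community,
                contaminant_share=float(con["share"]),
                seed=int(sub.generate_state(1)[0] % (2**31)),
            )
        aln = _synth.truth_to_alignments(community, truth)
        emit(f"{sid}_truth.tsv", lambda p, t=truth: _synth.write_truth(t, p))
        emit(f"{sid}_alignments.tsv", lambda p, a=aln: _synth.write_alignments_tsv(a, p))
        if with_sequences:
            reads = _synth.extract_read_sequences(community, truth)
            emit(f"{sid}_reads.fasta", lambda p, r=reads: _synth.write_fasta(r, p))
        logger.info("sample %s: %d particles simulated", sid, len(truth))

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def analyze_sample(
    alignments: pd.DataFrame,
    records: pd.DataFrame,
    prophages: pd.DataFrame,
    *,
    sample_id: str = "sample",
    thresholds: _classify.ClassifyThresholds | None = None,
    min_read_len: int = 3000,
    min_aln_len: int = 1000,
    min_reads_mag: int = 50,
    min_reads_unbinned: int = 50,
    min_reads_viral: int = 200,
    short_read_coverage=None,
    peak_kwargs: dict | None = None,
):
    """Filter, assign, roll up, detect peaks and classify one sample.

    Returns ``(peaks_df, events, summary)`` where ``events`` is a list of
    :class:`~transductomics.classify.PackagingEvent`.
    """
    th = thresholds or _classify.ClassifyThresholds()
    pk = peak_kwargs or {}
    rec = _ingest.categorize_scaffolds(records, prophages)
    filtered = _ingest.filter_alignments(alignments, min_read_len, min_aln_len)
    assigned = _ingest.assign_reads(filtered)
    logger.info(
        "%s: %d alignments -> %d after filters -> %d assigned reads",
        sample_id, len(alignments), len(filtered), len(assigned),
    )
    rolled = _ingest.rollup_taxa(
        assigned, rec, min_reads_mag, min_reads_unbinned, min_reads_viral
    )

    n_assigned = len(assigned)
    bacterial = rolled[rolled["category"].isin(BACTERIAL_CATEGORIES)]
    summary = {
        "sample_id": sample_id,
        "n_alignments": int(len(alignments)),
        "n_filtered_alignments": int(len(filtered)),
        "n_assigned_reads": int(n_assigned),
        "n_retained_reads": int(len(rolled)),
        "bacterial_read_share_pct": (
            100.0 * len(bacterial) / n_assigned if n_assigned else 0.0
        ),
    }

    # per-read alignments restricted to the assigned scaffold
    keyed = filtered.merge(rolled[["read_id", "scaffold_id", "taxon"]],
                           on=["read_id", "scaffold_id"], how="inner")
    scaffold_taxa = rec.copy()
    scaffold_taxa["taxon"] = scaffold_taxa.apply(_ingest.taxon_label, axis=1)

    peak_rows, events = [], []
    for taxon, grp in rolled.groupby("taxon"):
        lengths = grp["read_len"].to_numpy()
        ids = grp["read_id"].to_numpy()
        found = _peaks.detect_peaks(
            lengths, ids, min_peak_reads=th.min_event_reads, **pk
        )
        taxon_scafs = scaffold_taxa[scaffold_taxa["taxon"] == taxon]
        scaffold_lengths = dict(
            zip(taxon_scafs["scaffold_id"], taxon_scafs["length"].astype(int))
        )
        taxon_aln = keyed[keyed["taxon"] == taxon]
        taxon_pp = prophages[prophages["scaffold_id"].isin(scaffold_lengths)] if len(
            prophages
        ) else prophages
        for rank, peak in enumerate(found):
            peak_rows.append(
                {
                    "sample_id": sample_id,
                    "taxon": taxon,
                    "rank": rank,
                    "center": peak.center,
                    "rel_halfwidth": peak.rel_halfwidth,
                    "count": peak.count,
                    "share": peak.share,
                }
            )
            bundle = _classify.build_evidence(
                taxon, sample_id, peak, taxon_aln, scaffold_lengths, taxon_pp,
                short_read_coverage=short_read_coverage, thresholds=th,
            )
            event = _classify.classify_event(bundle, th)
            if event is not None:
                events.append(event)
    peaks_df = pd.DataFrame(
        peak_rows,
        columns=["sample_id", "taxon", "rank", "center", "rel_halfwidth", "count", "share"],
    )
    return peaks_df, events, summary


def run_analyze(config: dict, outdir) -> dict:
    """Execute an analyze run over all configured samples; returns the summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = _ingest.load_scaffold_metadata(config["scaffold_metadata"])
    pp_path = config.get("prophages")
    prophages = (
        _ingest.load_prophage_bed(pp_path)
        if pp_path and Path(pp_path).exists()
        else pd.DataFrame(columns=["scaffold_id", "start", "end", "prophage_id"])
    )
    th = _classify.ClassifyThresholds(**(config.get("thresholds") or {}))
    filters = config.get("filters") or {}

    all_peaks, all_events, summaries = [], [], []
    samples = config.get("samples") or []
    for s in samples:
        aln = _ingest.load_alignments(s["alignments"], s.get("dialect", "tsv"))
        peaks_df, events, summary = analyze_sample(
            aln, records, prophages,
            sample_id=s["sample_id"], thresholds=th,
            min_read_len=int(filters.get("min_read_len", 3000)),
            min_aln_len=int(filters.get("min_aln_len", 1000)),
            min_reads_mag=int(filters.get("min_reads_mag", 50)),
            min_reads_unbinned=int(filters.get("min_reads_unbinned", 50)),
            min_reads_viral=int(filters.get("min_reads_viral", 200)),
        )
        summary["donor"] = s.get("donor", "")
        summary["fraction"] = s.get("fraction", "")
        all_peaks.append(peaks_df)
        all_events.extend(events)
        summaries.append(summary)

    peaks_df = (
        pd.concat(all_peaks, ignore_index=True)
        if all_peaks
        else pd.DataFrame(
            columns=["sample_id", "taxon", "rank", "center", "rel_halfwidth", "count", "share"]
        )
    )
    peaks_df.to_csv(outdir / "peaks.tsv", sep="\t", index=False)
    event_dicts = [e.to_dict() for e in all_events]
    with open(outdir / "events.json", "w") as fh:
        json.dump(event_dicts, fh, indent=2)
    pd.DataFrame(
        [{k: v for k, v in d.items() if k != "rule_trace"} for d in event_dicts]
    ).to_csv(outdir / "events.tsv", sep="\t", index=False)

    # enrichment: donor x fraction VLP counts vs the donor's total sample
    enr_frames = []
    counts_path = config.get("counts")
    if counts_path:
        counts = pd.read_csv(counts_path, sep="\t", dtype={"scaffold_id": str})
        by_donor = {}
        for s in samples:
            by_donor.setdefault(s.get("donor", ""), {})[s.get("fraction", "")] = s["sample_id"]
        for donor, fr in by_donor.items():
            total_sid = fr.get("total")
            if total_sid is None or total_sid not in counts.columns:
                logger.warning("donor %s: no total-DNA counts, enrichment skipped", donor)
                continue
            for fraction in ("B", "T"):
                sid = fr.get(fraction)
                if sid is None or sid not in counts.columns:
                    continue
                df = _enrichment.enrichment_z(
                    counts[sid], counts[total_sid],
                    int(counts[sid].sum()), int(counts[total_sid].sum()),
                    counts["scaffold_id"],
                )
                df.insert(0, "donor", donor)
                df.insert(1, "fraction", fraction)
                enr_frames.append(df)
    if enr_frames:
        pd.concat(enr_frames, ignore_index=True).to_csv(
            outdir / "enrichment.tsv", sep="\t", index=False
        )

    result = {"samples": summaries, "n_events": len(all_events)}
    with open(outdir / "summary.json", "w") as fh:
        json.dump(result, fh, indent=2)
    return result


# ---------------------------------------------------------------------------
# labelled six-mechanism benchmark

BENCHMARK_MECHANISMS = ("cos", "headful", "GT", "ST", "LT", "GTA")
EXPECTED_MODE = {
    "cos": "induction",
    "headful": "induction",
    "GT": "GT",
    "ST": "ST",
    "LT": "LT",
    "GTA": "GTA",
}


def _benchmark_setup(mechanism: str, seed: int):
    """Community + params reproducing one mechanism's study conditions."""
    tax = "d__Bacteria;p__Bacillota;c__Clostridia;f__Testaceae;g__Testus;s__Testus host"
    if mechanism in ("cos", "headful", "ST"):
        genomes = [_synth.GenomeSpec("host", 500_000, taxon=tax)]
        prophages = [_synth.ProphageSpec("host", 200_000, 240_000, "pp1", pac_offset=0)]
        if mechanism == "cos":
            params = _synth.MechanismParams("cos", prophage_id="pp1")
        elif mechanism == "headful":
            params = _synth.MechanismParams(
                "headful", prophage_id="pp1",
                capacity=_synth.capacity_from_genome(40_000, 0.04),
            )
        else:
            params = _synth.MechanismParams(
                "ST", prophage_id="pp1", st_flank=5000, transducing_fraction=1.0,
                series_length=1,
            )
    elif mechanism == "LT":
        genomes = [_synth.GenomeSpec("host", 600_000, taxon=tax)]
        prophages = [_synth.ProphageSpec("host", 100_000, 156_900, "pp1", pac_offset=0)]
        params = _synth.MechanismParams(
            "LT", prophage_id="pp1", capacity=58_400, series_length=5
        )
    elif mechanism == "GT":
        genomes = [
            _synth.GenomeSpec("host", 2_000_000, taxon=tax),
            _synth.GenomeSpec("phage", 41_700, taxon="Testvirus", domain="virus",
                              is_viral=True),
        ]
        prophages = []
        params = _synth.MechanismParams(
            "GT", genome_id="phage", host_genome_id="host",
            capacity=43_400, transducing_fraction=0.3, series_length=5,
            pseudo_pac_count=150,
        )
    elif mechanism == "GTA":
        genomes = [_synth.GenomeSpec("host", 2_000_000, taxon=tax)]
        prophages = []
        params = _synth.MechanismParams("GTA", genome_id="host", capacity=8650)
    else:
        raise ValueError(mechanism)
    spec = _synth.CommunitySpec(genomes=genomes, prophages=prophages, seed=seed)
    return _synth.generate_community(spec), params


def run_benchmark(
    seed: int = 0, n_replicates: int = 20, n_reads: int = 2000
) -> pd.DataFrame:
    """Simulate each mechanism n_replicates times and tabulate the calls.

    Returns a confusion table (rows: true mechanism, columns: called mode,
    plus a 'missed' column for runs where no event was emitted for the
    host taxon).
    """
    modes = list(_classify.MODES) + ["missed"]
    table = pd.DataFrame(0, index=list(BENCHMARK_MECHANISMS), columns=modes)
    for mech in BENCHMARK_MECHANISMS:
        for rep in range(n_replicates):
            sub = substream_seed(seed, f"benchmark:{mech}:{rep}")
            s1, s2 = (int(x % (2**31)) for x in sub.generate_state(2))
            community, params = _benchmark_setup(mech, s1)
            truth, _ = _synth.simulate_particles(community, params, n_reads, s2)
            aln = _synth.truth_to_alignments(community, truth)
            records = community.scaffolds.rename(columns={"length": "length"})[
                ["scaffold_id", "length", "bin_id", "domain", "taxonomy", "is_viral"]
            ]
            pp = community.prophages.rename(
                columns={"scaffold_start": "start_s", "scaffold_end": "end_s"}
            )
            pp = pp[["scaffold_id", "start_s", "end_s", "prophage_id"]].rename(
                columns={"start_s": "start", "end_s": "end"}
            )
            _, events, _ = analyze_sample(aln, records, pp, sample_id=f"{mech}_{rep}")
            host_events = [e for e in events if "Testus" in e.taxon or e.taxon == "host"]
            if not host_events:
                table.loc[mech, "missed"] += 1
                continue
            called = max(host_events, key=lambda e: e.bundle.peak.count).mode
            table.loc[mech, called] += 1
    return table
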