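"""Synthetic communities and capsid-packaged DNA reads with ground truth.

This module simulates the particle populations produced by the DNA packaging
mechanisms that leave diagnostic read-length and mapping signatures in
long-read virome sequencing:

``cos``
    sequence-specific packaging between cohesive-end sites; every particle
    carries exactly one unit genome.
``headful``
    *pac*-initiated packaging of a concatemer; particles are terminally
    redundant, circularly permuted, with a bounded length jitter
    (packaging imprecision, about +/-2%).
``mu``
    Mu-like replicative-transposition packaging; the phage genome plus a
    short stretch (500-3000 bp by default) of flanking host DNA.
``GT``
    generalised transduction; a fraction of particles carry host chromosome
    fragments whose starts follow headful series seeded at pseudo-*pac*
    sites, the rest are ordinary phage virions.
``ST``
    specialised transduction; imprecise prophage excision co-packages host
    DNA immediately flanking the prophage.
``LT``
    lateral transduction; an in-situ headful series that runs from the
    integrated prophage's *pac* site into the chromosome, the first headful
    chimeric whenever the prophage is shorter than the capsid capacity.
``GTA``
    gene-transfer-agent-like packaging; short fragments with uniformly
    random starts over the host genome.

On top of the mechanism simulators sit two nuisance processes: anchored
post-packaging degradation (truncation that preserves the packaging-start
coordinate) and free-DNA contamination with a broad log-normal length
distribution.

Coordinates are 0-based half-open throughout. A fragment that wraps the
origin of its circular packaging unit is stored as a single truth row in
doubled coordinates (``end`` may exceed the unit end); conversion to
alignment intervals splits it into two pieces.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "MECHANISMS",
    "GenomeSpec",
    "ProphageSpec",
    "CommunitySpec",
    "Community",
    "MechanismParams",
    "CommunityValidationError",
    "capacity_from_genome",
    "generate_community",
    "simulate_particles",
    "apply_degradation",
    "add_contamination",
    "truth_to_alignments",
    "extract_read_sequences",
    "write_fasta",
    "write_truth",
    "write_scaffold_metadata",
    "write_prophage_bed",
    "TRUTH_COLUMNS",
]

MECHANISMS = ("cos", "headful", "mu", "GT", "ST", "LT", "GTA")

#: schema of the per-read ground-truth table
TRUTH_COLUMNS = [
    "read_id",
    "mechanism",
    "genome_id",
    "start",
    "end",
    "length",
    "unit_start",
    "unit_end",
    "genome_id2",
    "start2",
    "end2",
    "series_k",
    "chimeric",
    "degraded",
    "contaminant",
]


class CommunityValidationError(ValueError):
    """A community or mechanism specification violates its invariants."""


@dataclass(frozen=True)
class GenomeSpec:
    """One replicon in the simulated community."""

    genome_id: str
    length: int
    circular: bool = True
    taxon: str = ""
    bin_id: Optional[str] = None
    domain: str = "bacteria"  # bacteria | archaea | virus
    is_viral: bool = False


@dataclass(frozen=True)
class ProphageSpec:
    """An integrated prophage interval with its packaging-start offset."""

    genome_id: str
    start: int
    end: int
    prophage_id: str
    pac_offset: int = 0  # bp from prophage start to the pac site

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def pac(self) -> int:
        return self.start + self.pac_offset


@dataclass
class CommunitySpec:
    """Genomes, prophages and scaffolding rules for a synthetic community.

    ``breakpoints`` maps genome_id to sorted internal cut positions; each
    genome is emitted as one scaffold per piece (default: one scaffold).
    """

    genomes: Sequence[GenomeSpec]
    prophages: Sequence[ProphageSpec] = field(default_factory=list)
    breakpoints: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        ids = [g.genome_id for g in self.genomes]
        if len(set(ids)) != len(ids):
            raise CommunityValidationError("duplicate genome ids")
        by_id = {g.genome_id: g for g in self.genomes}
        for g in self.genomes:
            if g.length <= 0:
                raise CommunityValidationError(
                    f"genome {g.genome_id!r}: non-positive length {g.length}"
                )
        seen = {}
        for p in self.prophages:
            if p.genome_id not in by_id:
                raise CommunityValidationError(
                    f"prophage {p.prophage_id!r}: unknown genome {p.genome_id!r}"
                )
            G = by_id[p.genome_id].length
            if not (0 <= p.start < p.end <= G):
                raise CommunityValidationError(
                    f"prophage {p.prophage_id!r}: interval [{p.start}, {p.end}) "
                    f"outside genome of length {G}"
                )
            if not (0 <= p.pac_offset < p.length):
                raise CommunityValidationError(
                    f"prophage {p.prophage_id!r}: pac offset {p.pac_offset} "
                    f"outside prophage of length {p.length}"
                )
            for other in seen.get(p.genome_id, []):
                if p.start < other.end and other.start < p.end:
                    raise CommunityValidationError(
                        f"prophage {p.prophage_id!r} overlaps {other.prophage_id!r}"
                    )
            seen.setdefault(p.genome_id, []).append(p)
        for gid, cuts in self.breakpoints.items():
            if gid not in by_id:
                raise CommunityValidationError(f"breakpoints for unknown genome {gid!r}")
            G = by_id[gid].length
            cuts = sorted(cuts)
            if cuts and (cuts[0] <= 0 or cuts[-1] >= G or len(set(cuts)) != len(cuts)):
                raise CommunityValidationError(
                    f"breakpoints for {gid!r} must be distinct and inside (0, {G})"
                )


@dataclass
class Community:
    """A realised community: scaffold table, prophage table, lazy sequences."""

    spec: CommunitySpec
    scaffolds: pd.DataFrame  # scaffold_id, genome_id, offset, length, bin_id,
    #                          domain, taxonomy, is_viral
    prophages: pd.DataFrame  # prophage_id, genome_id, scaffold_id, start, end,
    #                          pac, scaffold_start, scaffold_end
    _sequences: dict = field(default_factory=dict, repr=False)

    def genome_length(self, genome_id: str) -> int:
        for g in self.spec.genomes:
            if g.genome_id == genome_id:
                return g.length
        raise KeyError(genome_id)

    def genome(self, genome_id: str) -> GenomeSpec:
        for g in self.spec.genomes:
            if g.genome_id == genome_id:
                return g
        raise KeyError(genome_id)

    def prophage(self, prophage_id: str) -> ProphageSpec:
        for p in self.spec.prophages:
            if p.prophage_id == prophage_id:
                return p
        raise KeyError(prophage_id)

    def get_sequence(self, genome_id: str) -> str:
        """Genome sequence, generated deterministically on first access."""
        if genome_id not in self._sequences:
            g = self.genome(genome_id)
            rng = substream(self.spec.seed, f"seq:{genome_id}")
            idx = rng.integers(0, 4, size=g.length)
            self._sequences[genome_id] = (
                np.frombuffer(b"ACGT", dtype="S1")[idx].tobytes().decode("ascii")
            )
        return self._sequences[genome_id]


def generate_community(spec: CommunitySpec) -> Community:
    """Realise a community spec into scaffold and prophage tables.

    Sequences are i.i.d. uniform ACGT and are generated lazily; identical
    seeds yield byte-identical sequences and tables.
    """
    spec.validate()
    scaf_rows = []
    piece_map = {}  # genome_id -> list of (scaffold_id, offset, length)
    for g in spec.genomes:
        cuts = sorted(spec.breakpoints.get(g.genome_id, []))
        edges = [0] + cuts + [g.length]
        pieces = []
        for i in range(len(edges) - 1):
            sid = g.genome_id if len(edges) == 2 else f"{g.genome_id}_s{i:02d}"
            off, ln = edges[i], edges[i + 1] - edges[i]
            pieces.append((sid, off, ln))
            scaf_rows.append(
                {
                    "scaffold_id": sid,
                    "genome_id": g.genome_id,
                    "offset": off,
                    "length": ln,
                    "bin_id": g.bin_id if g.bin_id is not None else "",
                    "domain": g.domain,
                    "taxonomy": g.taxon,
                    "is_viral": g.is_viral,
                }
            )
        piece_map[g.genome_id] = pieces

    pp_rows = []
    for p in spec.prophages:
        home = None
        for sid, off, ln in piece_map[p.genome_id]:
            if off <= p.start and p.end <= off + ln:
                home = (sid, off)
                break
        if home is None:
            raise CommunityValidationError(
                f"prophage {p.prophage_id!r} is split by a scaffold breakpoint"
            )
        sid, off = home
        pp_rows.append(
            {
                "prophage_id": p.prophage_id,
                "genome_id": p.genome_id,
                "scaffold_id": sid,
                "start": p.start,
                "end": p.end,
                "pac": p.pac,
                "scaffold_start": p.start - off,
                "scaffold_end": p.end - off,
            }
        )
    scaffolds = pd.DataFrame(scaf_rows)
    prophages = pd.DataFrame(
        pp_rows,
        columns=[
            "prophage_id",
            "genome_id",
            "scaffold_id",
            "start",
            "end",
            "pac",
            "scaffold_start",
            "scaffold_end",
        ],
    )
    return Community(spec=spec, scaffolds=scaffolds, prophages=prophages)


def capacity_from_genome(genome_length: int, redundancy: float = 0.04) -> int:
    """Headful capsid capacity implied by a genome length and terminal redundancy."""
    return int(round(genome_length * (1.0 + redundancy)))


@dataclass
class MechanismParams:
    """Parameters of one packaging mechanism.

    ``capacity`` is the headful / capsid DNA length H in bp. ``redundancy``
    (terminal redundancy, default 4%) is only used via
    :func:`capacity_from_genome`; ``imprecision`` bounds the per-headful
    length jitter (uniform on +/- imprecision). ``pac_position`` is a
    genomic coordinate on the packaging unit. ``series_length`` caps the
    number of successive headfuls per initiation event.
    """

    mechanism: str
    genome_id: Optional[str] = None
    host_genome_id: Optional[str] = None
    prophage_id: Optional[str] = None
    capacity: Optional[int] = None
    redundancy: float = 0.04
    imprecision: float = 0.02
    pac_position: int = 0
    transducing_fraction: float = 0.3
    series_length: int = 25
    mu_host_range: tuple = (500, 3000)
    pseudo_pac_count: int = 200
    st_flank: int = 5000
    direction: int = 1  # +1: series runs downstream of pac; -1: upstream

    def validate(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise CommunityValidationError(f"unknown mechanism {self.mechanism!r}")
        if not (0.0 <= self.redundancy <= 0.10):
            raise CommunityValidationError("redundancy must be in [0, 0.10]")
        if not (0.0 <= self.imprecision <= 0.05):
            raise CommunityValidationError("imprecision must be in [0, 0.05]")
        if not (0.0 <= self.transducing_fraction <= 1.0):
            raise CommunityValidationError("transducing_fraction must be in [0, 1]")
        if self.mu_host_range[0] > self.mu_host_range[1]:
            raise CommunityValidationError("mu_host_range min > max")
        if self.series_length < 1:
            raise CommunityValidationError("series_length must be >= 1")
        need_capacity = self.mechanism in ("headful", "GT", "LT", "GTA")
        if need_capacity and (self.capacity is None or self.capacity <= 0):
            raise CommunityValidationError(
                f"mechanism {self.mechanism!r} requires a positive capacity"
            )
        if self.mechanism in ("cos", "headful", "GTA", "mu", "GT") and (
            self.genome_id is None and self.prophage_id is None
        ):
            raise CommunityValidationError(
                f"mechanism {self.mechanism!r} requires genome_id (or prophage_id)"
            )
        if self.mechanism in ("mu", "GT") and self.host_genome_id is None:
            raise CommunityValidationError(
                f"mechanism {self.mechanism!r} requires host_genome_id"
            )
        if self.mechanism in ("ST", "LT") and self.prophage_id is None:
            raise CommunityValidationError(
                f"mechanism {self.mechanism!r} requires prophage_id"
            )


def _jitter_lengths(rng: np.random.Generator, H: float, eps: float, n: int) -> np.ndarray:
    if eps <= 0:
        return np.full(n, int(round(H)), dtype=np.int64)
    return np.rint(H * (1.0 + rng.uniform(-eps, eps, size=n))).astype(np.int64)


def _series_offset(rng: np.random.Generator, H: float, eps: float, k: int) -> float:
    """Concatemer offset of the k-th headful: sum of the k-1 preceding lengths."""
    if k <= 1:
        return 0.0
    if eps <= 0:
        return H * (k - 1)
    return float(np.sum(H * (1.0 + rng.uniform(-eps, eps, size=k - 1))))


def _empty_truth() -> pd.DataFrame:
    return pd.DataFrame(columns=TRUTH_COLUMNS).astype(
        {
            "start": np.int64,
            "end": np.int64,
            "length": np.int64,
            "unit_start": np.int64,
            "unit_end": np.int64,
            "start2": np.int64,
            "end2": np.int64,
            "series_k": np.int64,
            "chimeric": bool,
            "degraded": bool,
            "contaminant": bool,
        },
        errors="ignore",
    )


def simulate_particles(
    community: Community,
    params: MechanismParams,
    n_particles: int,
    seed: int,
    *,
    read_prefix: Optional[str] = None,
    with_sequences: bool = False,
):
    """Simulate encapsidated DNA molecules under one packaging mechanism.

    Returns ``(truth, reads)`` where ``truth`` is a DataFrame with one row
    per particle (see :data:`TRUTH_COLUMNS`) and ``reads`` is a list of
    ``(read_id, sequence)`` pairs, or ``None`` unless ``with_sequences``.
    """
    params.validate()
    if n_particles < 0:
        raise CommunityValidationError("n_particles must be >= 0")
    prefix = read_prefix if read_prefix is not None else params.mechanism
    if n_particles == 0:
        truth = _empty_truth()
        return truth, ([] if with_sequences else None)

    rng = np.random.default_rng(seed)
    mech = params.mechanism
    rows = []

    def row(i, gid, start, end, unit_start, unit_end, *, k=0, chim=False,
            gid2="", s2=0, e2=0, extra_len=0):
        rows.append(
            {
                "read_id": f"{prefix}_{i:06d}",
                "mechanism": mech,
                "genome_id": gid,
                "start": int(start),
                "end": int(end),
                "length": int(end - start + extra_len),
                "unit_start": int(unit_start),
                "unit_end": int(unit_end),
                "genome_id2": gid2,
                "start2": int(s2),
                "end2": int(e2),
                "series_k": int(k),
                "chimeric": bool(chim),
                "degraded": False,
                "contaminant": False,
            }
        )

    # resolve the packaging unit: a whole genome or an excised prophage circle
    if params.prophage_id is not None and mech in ("cos", "headful"):
        pp = community.prophage(params.prophage_id)
        gid = pp.genome_id
        u0, u1 = pp.start, pp.end
        pac = pp.pac
    elif mech in ("ST", "LT"):
        pp = community.prophage(params.prophage_id)
        gid = pp.genome_id
        u0, u1 = 0, community.genome_length(gid)
        pac = pp.pac
    else:
        gid = params.genome_id
        u0, u1 = 0, community.genome_length(gid)
        pac = params.pac_position

    U = u1 - u0  # packaging-unit length

    if mech == "cos":
        for i in range(n_particles):
            row(i, gid, u0, u1, u0, u1, k=0)

    elif mech == "headful":
        H, eps = float(params.capacity), params.imprecision
        ks = rng.integers(1, params.series_length + 1, size=n_particles)
        lengths = _jitter_lengths(rng, H, eps, n_particles)
        for i in range(n_particles):
            off = _series_offset(rng, H, eps, int(ks[i]))
            s = u0 + int(round(pac - u0 + off)) % U
            row(i, gid, s, s + lengths[i], u0, u1, k=int(ks[i]))

    elif mech == "mu":
        Gp = community.genome_length(params.genome_id)
        Gh = community.genome_length(params.host_genome_id)
        lo, hi = params.mu_host_range
        host_len = rng.integers(lo, hi + 1, size=n_particles)
        host_start = rng.integers(0, Gh, size=n_particles)
        for i in range(n_particles):
            hs, he = int(host_start[i]), int(host_start[i] + host_len[i])
            row(
                i,
                params.genome_id,
                0,
                Gp,
                0,
                Gp,
                chim=True,
                gid2=params.host_genome_id,
                s2=hs,
                e2=he,
                extra_len=int(host_len[i]),
            )

    elif mech == "GT":
        H, eps = float(params.capacity), params.imprecision
        host = params.host_genome_id
        Gh = community.genome_length(host)
        Gp = community.genome_length(params.genome_id)
        sites = np.sort(rng.integers(0, Gh, size=params.pseudo_pac_count))
        is_transducing = rng.random(n_particles) < params.transducing_fraction
        lengths = _jitter_lengths(rng, H, eps, n_particles)
        ks = rng.integers(1, params.series_length + 1, size=n_particles)
        site_idx = rng.integers(0, len(sites), size=n_particles)
        for i in range(n_particles):
            if is_transducing[i]:
                off = _series_offset(rng, H, eps, int(ks[i]))
                s = int(round(sites[site_idx[i]] + off)) % Gh
                row(i, host, s, s + lengths[i], 0, Gh, k=int(ks[i]))
            else:
                off = _series_offset(rng, H, eps, int(ks[i]))
                s = int(round(pac + off)) % Gp
                row(i, params.genome_id, s, s + lengths[i], 0, Gp, k=int(ks[i]))

    elif mech == "ST":
        eps = params.imprecision
        b = pp.end
        H = params.capacity if params.capacity else (b - pac) + params.st_flank
        is_transducing = rng.random(n_particles) < params.transducing_fraction
        lengths = _jitter_lengths(rng, float(H), eps, n_particles)
        for i in range(n_particles):
            if is_transducing[i]:
                s, e = pac, pac + int(lengths[i])
                row(i, gid, s, e, u0, u1, k=1, chim=e > b)
            else:
                row(i, gid, pp.start, pp.end, u0, u1, k=0)

    elif mech == "LT":
        H, eps = float(params.capacity), params.imprecision
        d = 1 if params.direction >= 0 else -1
        a, b = pp.start, pp.end
        ks = rng.integers(1, params.series_length + 1, size=n_particles)
        lengths = _jitter_lengths(rng, H, eps, n_particles)
        for i in range(n_particles):
            off = _series_offset(rng, H, eps, int(ks[i]))
            if d > 0:
                s = int(round(pac + off)) % U
                e = s + int(lengths[i])
                chim = s < b < e
            else:
                e = int(round(pac - off)) % U
                s = e - int(lengths[i])
                if s < 0:  # wrap leftwards over the origin
                    s += U
                    e += U
                chim = s < a < e
            row(i, gid, s, e, u0, u1, k=int(ks[i]), chim=chim)

    elif mech == "GTA":
        H, eps = float(params.capacity), params.imprecision
        starts = rng.integers(0, U, size=n_particles)
        lengths = _jitter_lengths(rng, H, eps, n_particles)
        for i in range(n_particles):
            s = int(starts[i])
            row(i, gid, s, s + int(lengths[i]), u0, u1, k=0)

    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    reads = extract_read_sequences(community, truth) if with_sequences else None
    return truth, reads


def apply_degradation(
    truth: pd.DataFrame,
    reads=None,
    *,
    retained_fraction_range=(0.1, 0.9),
    degraded_share: float = 0.0,
    seed: int = 0,
):
    """Truncate a share of particles, keeping the packaging-start end.

    The retained fraction of each affected molecule is drawn uniformly from
    ``retained_fraction_range``; the truth ``end`` (and, for chimeric
    molecules, the appended second interval first) is shortened while the
    ``start`` coordinate is preserved, so degraded and intact particles of
    one class share alignment starts.
    """
    lo, hi = retained_fraction_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise CommunityValidationError("retained_fraction_range must satisfy 0<=lo<=hi<=1")
    if not (0.0 <= degraded_share <= 1.0):
        raise CommunityValidationError("degraded_share must be in [0, 1]")
    if degraded_share == 0.0 or len(truth) == 0:
        return truth, reads

    rng = np.random.default_rng(seed)
    truth = truth.copy()
    n = len(truth)
    hit = rng.random(n) < degraded_share
    frac = rng.uniform(lo, hi, size=n)
    new_len = np.rint(truth["length"].to_numpy() * frac).astype(np.int64)
    new_len = np.maximum(new_len, 1)

    for i in np.flatnonzero(hit):
        L = int(new_len[i])
        r = truth.iloc[i]
        prim = int(r["end"] - r["start"])
        if r["genome_id2"] and L > prim:
            truth.iat[i, truth.columns.get_loc("end2")] = int(r["start2"]) + (L - prim)
        else:
            truth.iat[i, truth.columns.get_loc("end")] = int(r["start"]) + L
            truth.iat[i, truth.columns.get_loc("genome_id2")] = ""
            truth.iat[i, truth.columns.get_loc("start2")] = 0
            truth.iat[i, truth.columns.get_loc("end2")] = 0
        truth.iat[i, truth.columns.get_loc("length")] = L
        truth.iat[i, truth.columns.get_loc("degraded")] = True
    if reads is not None:
        id_to_len = dict(zip(truth["read_id"], truth["length"]))
        reads = [(rid, seq[: id_to_len[rid]]) for rid, seq in reads]
    return truth, reads


def add_contamination(
    truth: pd.DataFrame,
    community: Community,
    reads=None,
    *,
    contaminant_share: float = 0.0,
    length_model=(np.log10(8000.0), 0.35),
    seed: int = 0,
):
    """Append free-DNA contaminant reads with a broad log-normal length law.

    ``contaminant_share`` is the expected share of contaminants in the final
    read set; the contaminant count is binomial around that expectation.
    Lengths follow ``10**Normal(mu_log10, sd_log10)``; starts are uniform
    over genomes sampled proportionally to genome length.
    """
    if not (0.0 <= contaminant_share < 1.0):
        raise CommunityValidationError("contaminant_share must be in [0, 1)")
    if contaminant_share == 0.0:
        return truth, reads

    rng = np.random.default_rng(seed)
    n_in = len(truth)
    n_target = int(round(n_in / (1.0 - contaminant_share)))
    n_contam = int(rng.binomial(n_target, contaminant_share)) if n_target else 0
    if n_contam == 0:
        return truth, reads

    genomes = community.spec.genomes
    weights = np.array([g.length for g in genomes], dtype=float)
    weights /= weights.sum()
    gidx = rng.choice(len(genomes), size=n_contam, p=weights)
    mu_l, sd_l = length_model
    lengths = np.maximum(np.rint(10 ** rng.normal(mu_l, sd_l, size=n_contam)), 100)
    lengths = lengths.astype(np.int64)
    rows = []
    for i in range(n_contam):
        g = genomes[gidx[i]]
        L = min(int(lengths[i]), g.length)
        s = int(rng.integers(0, g.length))
        rows.append(
            {
                "read_id": f"contam_{i:06d}",
                "mechanism": "contaminant",
                "genome_id": g.genome_id,
                "start": s,
                "end": s + L,
                "length": L,
                "unit_start": 0,
                "unit_end": g.length,
                "genome_id2": "",
                "start2": 0,
                "end2": 0,
                "series_k": 0,
                "chimeric": False,
                "degraded": False,
                "contaminant": True,
            }
        )
    contam = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    out = pd.concat([truth, contam], ignore_index=True)
    if reads is not None:
        reads = list(reads) + extract_read_sequences(community, contam)
    return out, reads


def _unit_pieces(start: int, end: int, u0: int, u1: int):
    """Split a doubled-coordinate interval on a circular unit into linear pieces."""
    pieces = []
    s, e = start, end
    while e > u1:
        pieces.append((s, u1))
        s, e = u0, u0 + (e - u1)
    pieces.append((s, e))
    return [(a, b) for a, b in pieces if b > a]


def _piece_index(community: Community) -> dict:
    """genome_id -> list of (scaffold_id, offset, length), cached on the community."""
    cache = getattr(community, "_piece_index", None)
    if cache is None:
        cache = {}
        for r in community.scaffolds.itertuples(index=False):
            cache.setdefault(r.genome_id, []).append(
                (r.scaffold_id, int(r.offset), int(r.length))
            )
        community.__dict__["_piece_index"] = cache
    return cache


def _scaffold_pieces(community: Community, genome_id: str, start: int, end: int):
    """Map a linear genome interval onto (scaffold_id, start, end) pieces."""
    out = []
    for sid, off, ln in _piece_index(community)[genome_id]:
        lo, hi = max(start, off), min(end, off + ln)
        if hi > lo:
            out.append((sid, lo - off, hi - off))
    return out


def truth_to_alignments(community: Community, truth: pd.DataFrame) -> pd.DataFrame:
    """Convert truth intervals into alignment rows in the ingest dialect.

    Emits one row per contiguous scaffold piece; wrapped or chimeric
    molecules therefore produce multiple rows for a single read.
    Columns: read_id, read_len, scaffold_id, start, end, strand, aln_len.
    """
    rows = []
    for r in truth.itertuples(index=False):
        intervals = []
        for s, e in _unit_pieces(int(r.start), int(r.end), int(r.unit_start), int(r.unit_end)):
            intervals.extend(
                (sid, a, b) for sid, a, b in _scaffold_pieces(community, r.genome_id, s, e)
            )
        if r.genome_id2:
            g2 = community.genome(r.genome_id2)
            for s, e in _unit_pieces(int(r.start2), int(r.end2), 0, g2.length):
                intervals.extend(
                    (sid, a, b) for sid, a, b in _scaffold_pieces(community, r.genome_id2, s, e)
                )
        for sid, a, b in intervals:
            rows.append(
                {
                    "read_id": r.read_id,
                    "read_len": int(r.length),
                    "scaffold_id": sid,
                    "start": int(a),
                    "end": int(b),
                    "strand": "+",
                    "aln_len": int(b - a),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["read_id", "read_len", "scaffold_id", "start", "end", "strand", "aln_len"],
    )


def extract_read_sequences(community: Community, truth: pd.DataFrame):
    """Materialise read sequences for a truth table (memory permitting)."""
    reads = []
    for r in truth.itertuples(index=False):
        seq = community.get_sequence(r.genome_id)
        parts = [
            seq[s:e]
            for s, e in _unit_pieces(int(r.start), int(r.end), int(r.unit_start), int(r.unit_end))
        ]
        if r.genome_id2:
            seq2 = community.get_sequence(r.genome_id2)
            g2 = community.genome(r.genome_id2)
            parts += [
                seq2[s:e] for s, e in _unit_pieces(int(r.start2), int(r.end2), 0, g2.length)
            ]
        reads.append((r.read_id, "".join(parts)))
    return reads


# ---------------------------------------------------------------------------
# writers (ingest dialect)

def write_fasta(reads, path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in reads)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def write_scaffold_metadata(community: Community, path) -> None:
    cols = ["scaffold_id", "length", "bin_id", "domain", "taxonomy", "is_viral"]
    community.scaffolds[cols].to_csv(path, sep="\t", index=False)


def write_prophage_bed(community: Community, path) -> None:
    """Prophage intervals in scaffold coordinates as BED6 (score column unused)."""
    with open(path, "w") as fh:
        for r in community.prophages.itertuples(index=False):
            fh.write(
                f"{r.scaffold_id}\t{r.scaffold_start}\t{r.scaffold_end}"
                f"\t{r.prophage_id}\t0\t+\n"
            )


def write_alignments_tsv(alignments: pd.DataFrame, path) -> None:
    alignments.to_csv(path, sep="\t", index=False)


__all__.append("write_alignments_tsv")
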