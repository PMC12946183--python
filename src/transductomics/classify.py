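"""Packaging-event classification from peaks, alignments and prophages.

Each detected read-length peak of a taxon is turned into an evidence
bundle — where the peak reads align relative to an annotated prophage
(within / outside / chimeric), whether their alignment starts cluster at
a putative *pac* site, whether starts outside the prophage recur at
multiples of the packaged length from that site (the headful-series
signature of lateral transduction), and how uniformly the reads cover the
taxon's scaffolds — and the bundle is pushed through an ordered decision
table yielding one of:

``induction``  packaged phage genomes from an induced prophage,
``GT``         generalised transduction (uniform coverage, phage-sized
               fragments, no prophage preference),
``ST``         specialised transduction (chimeras confined to the
               prophage boundary, no series),
``LT``         lateral transduction (pac-anchored series into the
               chromosome),
``GTA``        gene-transfer-agent-like packaging (short, very narrow
               fragment peak, uniform coverage),
``ambiguous``  anything that matches no rule.

Every numeric threshold is a tunable field of :class:`ClassifyThresholds`;
the defaults are the package's formalisation of signatures that are
normally judged by eye.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .peaks import LengthPeak

__all__ = [
    "ClassifyThresholds",
    "EvidenceBundle",
    "PackagingEvent",
    "infer_pac_site",
    "classify_read_locus",
    "periodicity_score",
    "coverage_profile",
    "build_evidence",
    "classify_event",
]

MODES = ("induction", "GT", "ST", "LT", "GTA", "ambiguous")


@dataclass
class ClassifyThresholds:
    """Decision-table thresholds (all exposed in the pipeline config)."""

    min_event_reads: int = 50
    length_cut_frac: float = 0.7       # count reads >= this fraction of peak center
    locus_margin: int = 2000           # bp of slack around prophage / pac
    pac_window: int = 500              # half-width of the pac search window
    pac_min_mode_share: float = 0.2
    periodicity_tol: float = 0.02      # x period
    lt_min_chimeric: int = 5
    lt_min_periodicity: float = 0.3
    induction_min_overlap: float = 0.8
    induction_center_lo: float = 0.95  # x prophage length
    induction_center_hi: float = 1.10
    gt_max_cv: float = 0.5
    gt_min_span: int = 200_000         # bp of taxon scaffold space
    gt_max_prophage_share: float = 0.2
    size_split: int = 15_000           # GT vs GTA fragment-size boundary
    gta_max_cv: float = 0.5
    gta_max_rel_halfwidth: float = 0.05
    prophage_match_lo: float = 0.9     # prophage length vs peak center
    prophage_match_hi: float = 1.1
    wave_period_tol: float = 0.05
    coverage_window: int = 10_000      # bp, long-read coverage uniformity


@dataclass
class EvidenceBundle:
    """All quantitative evidence about one taxon x sample x peak."""

    taxon: str
    sample: str
    peak: LengthPeak
    n_counted: int = 0
    n_within: int = 0
    n_outside: int = 0
    n_chimeric: int = 0
    pac_position: Optional[int] = None
    pac_confidence: float = 0.0
    periodicity: float = 0.0
    coverage_cv: float = float("nan")
    scaffold_span: int = 0
    prophage_overlap_share: float = 0.0
    matched_prophage_id: Optional[str] = None
    matched_prophage_length: Optional[int] = None
    wave_period: Optional[float] = None
    wave_decay: bool = False
    boundary_confined: bool = True


@dataclass
class PackagingEvent:
    """One classified packaging event with its full rule trace."""

    taxon: str
    sample: str
    mode: str
    peak_center: float
    bundle: EvidenceBundle = field(repr=False)
    rule_trace: list = field(default_factory=list)

    def to_dict(self) -> dict:
        b = self.bundle
        return {
            "taxon": self.taxon,
            "sample": self.sample,
            "mode": self.mode,
            "peak_center": round(self.peak_center, 1),
            "peak_count": b.peak.count,
            "peak_rel_halfwidth": round(b.peak.rel_halfwidth, 4),
            "n_counted": b.n_counted,
            "n_within": b.n_within,
            "n_outside": b.n_outside,
            "n_chimeric": b.n_chimeric,
            "pac_position": b.pac_position,
            "pac_confidence": round(b.pac_confidence, 3),
            "periodicity": round(b.periodicity, 3),
            "coverage_cv": None if np.isnan(b.coverage_cv) else round(b.coverage_cv, 3),
            "scaffold_span": b.scaffold_span,
            "prophage_overlap_share": round(b.prophage_overlap_share, 3),
            "matched_prophage_id": b.matched_prophage_id,
            "matched_prophage_length": b.matched_prophage_length,
            "wave_period": b.wave_period,
            "rule_trace": list(self.rule_trace),
        }


def infer_pac_site(starts, *, window: int = 500, step: int = 100, min_mode_share: float = 0.2):
    """Locate the modal cluster of alignment starts (the putative pac site).

    Slides a window of total width ``2*window`` in ``step`` bp increments
    over the start positions and returns ``(center, share_of_starts)`` for
    the densest window, or None when fewer than 20 starts are given or the
    densest window holds less than ``min_mode_share`` of them.
    """
    starts = np.sort(np.asarray(starts, dtype=np.int64))
    n = starts.size
    if n < 20:
        return None
    centers = np.arange(starts[0], starts[-1] + step, step)
    lo = np.searchsorted(starts, centers - window, side="left")
    hi = np.searchsorted(starts, centers + window, side="right")
    counts = hi - lo
    best = int(np.argmax(counts))
    share = counts[best] / n
    if share < min_mode_share:
        return None
    return int(centers[best]), float(share)


def classify_read_locus(
    span_start: int,
    span_end: int,
    prophage: tuple,
    pac: int,
    *,
    margin: int = 2000,
) -> str:
    """Place one read span relative to a prophage: within / outside / chimeric.

    ``within``: at least 95% of the span falls inside the prophage interval
    padded by ``margin``. ``chimeric``: the span starts at the pac site
    (within ``margin``) and extends at least ``margin`` beyond the prophage
    boundary in either direction — a single molecule carrying both phage
    and chromosomal DNA. Everything else is ``outside``.
    """
    a, b = prophage
    if not (a < b):
        raise ValueError("invalid prophage interval")
    span_len = span_end - span_start
    if span_len <= 0:
        raise ValueError("invalid read span")
    lo, hi = a - margin, b + margin
    overlap = max(0, min(span_end, hi) - max(span_start, lo))
    if overlap >= 0.95 * span_len:
        return "within"
    right_chimera = abs(span_start - pac) <= margin and span_end >= b + margin
    left_chimera = abs(span_end - pac) <= margin and span_start <= a - margin
    if right_chimera or left_chimera:
        return "chimeric"
    return "outside"


def periodicity_score(
    starts,
    anchor: int,
    period: float,
    *,
    tol: float = 0.02,
    span: Optional[float] = None,
) -> float:
    """Excess share of starts on the lattice anchor + k*period (k >= 1).

    The observed share of starts within ``tol * period`` of a lattice point
    minus the share expected if starts were uniform over the observed span,
    clipped to [0, 1]. Near 1 for a clean headful series, near 0 for
    uniform starts.
    """
    if period <= 0:
        raise ValueError("period must be > 0")
    starts = np.asarray(starts, dtype=float)
    if starts.size < 10:
        return 0.0
    rel = starts - anchor
    k = np.rint(rel / period)
    on_lattice = (k >= 1) & (np.abs(rel - k * period) <= tol * period)
    observed = on_lattice.mean()
    if span is None:
        span = max(starts.max() - min(starts.min(), anchor), period)
    n_lattice = max(int(span // period), 1)
    expected = min(1.0, 2.0 * tol * period * n_lattice / span)
    return float(np.clip(observed - expected, 0.0, 1.0))


def coverage_profile(
    coverage,
    boundary: Optional[int] = None,
    *,
    window: int = 1000,
    smooth_windows: int = 5,
    noise_quantile: float = 2.576,
    min_wave_acf: float = 0.25,
):
    """Windowed-coverage uniformity and periodic-wave detection.

    ``coverage`` is a per-base depth vector. Returns ``(cv, wave)`` where
    ``cv`` is sd/mean of the moving-average-smoothed windowed coverage and
    ``wave`` is ``{"period": bp, "decay": bool}`` when the mean-removed
    profile downstream of ``boundary`` has a dominant positive-lag
    autocorrelation peak above the white-noise band, else None. ``decay``
    is set when successive wave crests are monotonically non-increasing —
    the signature of a headful series whose later fragments are rarer.
    """
    cov = np.asarray(coverage, dtype=float)
    if cov.size < 5 * window:
        raise ValueError("coverage vector must span at least 5 windows")
    if not np.any(cov):
        raise ValueError("all-zero coverage")
    nwin = cov.size // window
    raw = cov[: nwin * window].reshape(nwin, window).mean(axis=1)
    prof = raw
    if smooth_windows > 1:
        kernel = np.ones(smooth_windows)
        norm = np.convolve(np.ones_like(raw), kernel, mode="same")
        prof = np.convolve(raw, kernel, mode="same") / norm
    mean = prof.mean()
    cv = float(prof.std() / mean) if mean > 0 else float("inf")

    wave = None
    start_idx = 0 if boundary is None else min(int(boundary) // window, nwin - 1)
    # autocorrelation on the unsmoothed profile: smoothing would inject
    # short-range correlation and bias the white-noise band
    ds = raw[start_idx:]
    if ds.size >= 8:
        x = ds - ds.mean()
        denom = float(np.dot(x, x))
        if denom > 0:
            nlags = ds.size // 2
            acf = np.array(
                [np.dot(x[: ds.size - lag], x[lag:]) / denom for lag in range(1, nlags + 1)]
            )
            from scipy.signal import find_peaks

            # the band must cover the maximum over ~nlags noise ACF values
            band = max(
                noise_quantile * np.sqrt(np.log(max(nlags, 2))) / np.sqrt(ds.size),
                min_wave_acf,
            )
            idx, _ = find_peaks(acf)
            idx = idx[acf[idx] > band]
            if idx.size:
                lag = int(idx[np.argmax(acf[idx])]) + 1
                first = int(np.argmax(ds[:lag])) if lag <= ds.size else 0
                crests = [
                    ds[first + m * lag] for m in range(ds.size) if first + m * lag < ds.size
                ]
                decay = len(crests) >= 2 and all(
                    crests[m + 1] <= crests[m] * 1.05 for m in range(len(crests) - 1)
                )
                wave = {"period": float(lag * window), "decay": bool(decay)}
    return cv, wave


def _windowed_read_coverage(spans: pd.DataFrame, scaffold_lengths: dict, window: int):
    """Read-count coverage per window over all of a taxon's scaffolds."""
    chunks = []
    for sid, L in scaffold_lengths.items():
        nwin = max(int(L) // window, 1)
        vec = np.zeros(nwin)
        sel = spans[spans["scaffold_id"] == sid]
        for r in sel.itertuples(index=False):
            w0 = min(int(r.start) // window, nwin - 1)
            w1 = min(int(r.end - 1) // window, nwin - 1)
            vec[w0 : w1 + 1] += 1.0
        chunks.append(vec)
    return np.concatenate(chunks) if chunks else np.zeros(0)


def build_evidence(
    taxon: str,
    sample: str,
    peak: LengthPeak,
    alignments: pd.DataFrame,
    scaffold_lengths: dict,
    prophages: Optional[pd.DataFrame] = None,
    *,
    short_read_coverage=None,
    thresholds: Optional[ClassifyThresholds] = None,
) -> EvidenceBundle:
    """Assemble the evidence bundle for one peak of one taxon.

    ``alignments`` holds the taxon's read alignments (ingest dialect,
    already restricted to each read's assigned scaffold);
    ``scaffold_lengths`` maps the taxon's scaffold ids to lengths;
    ``prophages`` carries viral-fragment intervals in scaffold coordinates
    (columns scaffold_id, start, end, prophage_id). ``short_read_coverage``
    optionally maps scaffold_id to a per-base depth vector for wave
    detection.
    """
    th = thresholds or ClassifyThresholds()
    bundle = EvidenceBundle(taxon=taxon, sample=sample, peak=peak)
    members = set(np.asarray(peak.member_ids).tolist())
    aln = alignments[alignments["read_id"].isin(members)]
    if len(aln) == 0:
        return bundle

    spans = (
        aln.groupby(["read_id", "scaffold_id"], as_index=False)
        .agg(start=("start", "min"), end=("end", "max"), read_len=("read_len", "first"))
    )
    length_cut = th.length_cut_frac * peak.center
    counted = spans[spans["read_len"] >= length_cut]
    bundle.n_counted = counted["read_id"].nunique()
    bundle.scaffold_span = int(sum(scaffold_lengths.values()))

    # focal scaffold: where most counted reads sit
    if len(counted):
        focal = counted.groupby("scaffold_id")["read_id"].nunique().idxmax()
    else:
        focal = None

    # pac site from counted alignment starts on the focal scaffold
    pac_pos = None
    if focal is not None:
        focal_starts = counted.loc[counted["scaffold_id"] == focal, "start"].to_numpy()
        hit = infer_pac_site(
            focal_starts,
            window=th.pac_window,
            min_mode_share=th.pac_min_mode_share,
        )
        if hit is not None:
            pac_pos, bundle.pac_confidence = hit
            bundle.pac_position = pac_pos

    # prophage matching: length close to the peak center, or containing pac
    matched = None
    if prophages is not None and len(prophages):
        pp = prophages[prophages["scaffold_id"].isin(scaffold_lengths.keys())]
        best_score = None
        for r in pp.itertuples(index=False):
            plen = int(r.end - r.start)
            by_len = (
                th.prophage_match_lo * peak.center <= plen <= th.prophage_match_hi * peak.center
            )
            by_pac = (
                pac_pos is not None
                and r.scaffold_id == focal
                and (r.start - th.locus_margin) <= pac_pos < (r.end + th.locus_margin)
            )
            if by_len or by_pac:
                score = abs(np.log(plen / peak.center))
                if best_score is None or score < best_score:
                    best_score = score
                    matched = r
        if matched is not None:
            bundle.matched_prophage_id = str(matched.prophage_id)
            bundle.matched_prophage_length = int(matched.end - matched.start)

    # locus trichotomy and boundary confinement
    if matched is not None:
        a, b = int(matched.start), int(matched.end)
        pac_for_locus = pac_pos if (
            pac_pos is not None and (a - th.locus_margin) <= pac_pos < (b + th.locus_margin)
        ) else a
        n_within = n_outside = n_chimeric = 0
        chim_ends, chim_starts = [], []
        outside_starts = []
        for r in counted.itertuples(index=False):
            if r.scaffold_id != matched.scaffold_id:
                n_outside += 1
                continue
            locus = classify_read_locus(
                int(r.start), int(r.end), (a, b), pac_for_locus, margin=th.locus_margin
            )
            if locus == "within":
                n_within += 1
            elif locus == "chimeric":
                n_chimeric += 1
                chim_starts.append(int(r.start))
                chim_ends.append(int(r.end))
            else:
                n_outside += 1
                if int(r.start) >= b or int(r.end) <= a:
                    outside_starts.append(int(r.start))
        bundle.n_within, bundle.n_outside, bundle.n_chimeric = n_within, n_outside, n_chimeric
        if bundle.n_counted:
            bundle.prophage_overlap_share = n_within / bundle.n_counted
        if chim_ends:
            bundle.boundary_confined = max(chim_ends) <= b + peak.center and min(
                chim_starts
            ) >= a - peak.center
        # headful-series periodicity of outside starts from the pac anchor
        if len(outside_starts) >= 10:
            bundle.periodicity = periodicity_score(
                outside_starts, pac_for_locus, peak.center, tol=th.periodicity_tol
            )
    else:
        bundle.n_outside = bundle.n_counted

    # long-read coverage uniformity over the taxon's scaffolds
    covvec = _windowed_read_coverage(counted, scaffold_lengths, th.coverage_window)
    if covvec.size and covvec.mean() > 0:
        bundle.coverage_cv = float(covvec.std() / covvec.mean())

    # short-read coverage wave downstream of the matched prophage
    if short_read_coverage is not None and matched is not None:
        cov = short_read_coverage.get(str(matched.scaffold_id))
        if cov is not None:
            try:
                _, wave = coverage_profile(cov, boundary=int(matched.end))
            except ValueError:
                wave = None
            if wave is not None:
                bundle.wave_period = wave["period"]
                bundle.wave_decay = wave["decay"]
    return bundle


def classify_event(
    bundle: EvidenceBundle, thresholds: Optional[ClassifyThresholds] = None
) -> Optional[PackagingEvent]:
    """Run the ordered decision table on one evidence bundle.

    Returns None when the peak has fewer members than the event minimum.
    The rule trace records every comparison made, in order.
    """
    th = thresholds or ClassifyThresholds()
    b = bundle
    if b.peak.count < th.min_event_reads:
        return None
    trace = []
    center = b.peak.center
    prophage_matched = b.matched_prophage_id is not None
    trace.append(f"prophage_matched={prophage_matched}")

    wave_matched = (
        b.wave_period is not None
        and abs(b.wave_period - center) <= th.wave_period_tol * center
    )

    def make(mode):
        return PackagingEvent(
            taxon=b.taxon, sample=b.sample, mode=mode, peak_center=center,
            bundle=b, rule_trace=trace,
        )

    # LT: pac-anchored series evidence; chimeras count only when they are
    # not confined to the prophage boundary (boundary-confined chimeras are
    # the ST signature and are handled below).
    if prophage_matched:
        trace.append(f"periodicity={b.periodicity:.3f}>={th.lt_min_periodicity}")
        trace.append(f"wave_matched={wave_matched}")
        trace.append(
            f"chimeric={b.n_chimeric}>={th.lt_min_chimeric} and "
            f"not boundary_confined={not b.boundary_confined}"
        )
        if (
            b.periodicity >= th.lt_min_periodicity
            or wave_matched
            or (b.n_chimeric >= th.lt_min_chimeric and not b.boundary_confined)
        ):
            return make("LT")

    # induction: the peak is the prophage itself
    if prophage_matched:
        lo = th.induction_center_lo * b.matched_prophage_length
        hi = th.induction_center_hi * b.matched_prophage_length
        trace.append(
            f"overlap_share={b.prophage_overlap_share:.3f}>={th.induction_min_overlap}"
        )
        trace.append(f"center={center:.0f} in [{lo:.0f}, {hi:.0f}]")
        if b.prophage_overlap_share >= th.induction_min_overlap and lo <= center <= hi:
            return make("induction")

    # ST: boundary-confined chimeras without any series signature
    if prophage_matched:
        trace.append(
            f"ST: chimeric={b.n_chimeric}>0, boundary_confined={b.boundary_confined}, "
            f"periodicity<{th.lt_min_periodicity}, no wave"
        )
        if (
            b.n_chimeric > 0
            and b.boundary_confined
            and b.periodicity < th.lt_min_periodicity
            and not wave_matched
        ):
            return make("ST")

    # GT: uniform coverage of large scaffold space, phage-sized fragments
    cv_ok = not np.isnan(b.coverage_cv) and b.coverage_cv <= th.gt_max_cv
    trace.append(
        f"GT: cv={b.coverage_cv:.3f}<={th.gt_max_cv}, span={b.scaffold_span}>="
        f"{th.gt_min_span}, center>={th.size_split}, "
        f"overlap_share<{th.gt_max_prophage_share}"
    )
    if (
        cv_ok
        and b.scaffold_span >= th.gt_min_span
        and center >= th.size_split
        and b.prophage_overlap_share < th.gt_max_prophage_share
    ):
        return make("GT")

    # GTA: short, very narrow fragment peak with uniform coverage
    trace.append(
        f"GTA: cv={b.coverage_cv:.3f}<={th.gta_max_cv}, center<{th.size_split}, "
        f"rel_halfwidth={b.peak.rel_halfwidth:.4f}<={th.gta_max_rel_halfwidth}"
    )
    if (
        not np.isnan(b.coverage_cv)
        and b.coverage_cv <= th.gta_max_cv
        and center < th.size_split
        and b.peak.rel_halfwidth <= th.gta_max_rel_halfwidth
    ):
        return make("GTA")

    trace.append("fallback: ambiguous")
    return make("ambiguous")
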