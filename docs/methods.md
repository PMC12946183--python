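# Methods

This note documents the models, procedures and numerical choices behind
the package, in the order data flows through it.

## Packaging-mechanism models (synthdata)

The simulator draws individual encapsidated DNA molecules; a molecule is
fully described by its source replicon, its interval on that replicon
(0-based half-open), and flags. Sequences are i.i.d. uniform ACGT and
carry no base-level error model: the analysis operates on alignment
coordinates and molecule lengths, not on base calls, so sequence realism
would add cost without adding test power. For the same reason sequences
are generated lazily; the analysis path runs entirely on interval tables.

Per-mechanism laws (H = capsid capacity in bp, ε = packaging imprecision,
lengths drawn as H·(1+δ) with δ ~ Uniform(−ε, ε)):

- **cos** — every molecule is the exact packaging unit: length equals the
  unit genome, start at the cos site (coordinate 0 of the unit).
- **headful** — initiation at *pac* on a circular concatemer; the k-th
  headful of a series starts at pac plus the summed lengths of the k−1
  preceding headfuls, modulo the unit. k is uniform on 1..series_length
  (default 25, large enough that circularly permuted starts cover the
  genome). Capacity defaults are derived from the genome as
  H = G·(1+ρ) with terminal redundancy ρ = 0.04, inside the canonical
  2–10% range; ε defaults to 0.02 (the canonical ±2%).
- **Mu-like** — the phage genome plus a Uniform(500, 3000) bp stretch of
  host DNA appended; always chimeric.
- **GT** — with probability `transducing_fraction` the molecule is a host
  fragment whose start follows a headful series seeded at one of
  `pseudo_pac_count` pseudo-*pac* sites (default 200, drawn uniformly per
  simulation — the true number and placement of pseudo-sites is unknown,
  and 200 sites on a megabase-scale chromosome gives the near-uniform
  coverage the mechanism is known for); otherwise an ordinary virion
  (headful packaging of the phage genome).
- **ST** — with probability `transducing_fraction`, imprecise excision:
  the molecule runs from the prophage *pac* for one headful sized to
  overshoot the prophage end by `st_flank` (default 5 kb); otherwise the
  exact excised prophage. Only single fragments, never a series.
- **LT** — a headful series anchored at the integrated prophage's *pac*
  and running into the chromosome (direction configurable; default
  downstream). With prophage shorter than H, exactly the k = 1 fragments
  span the boundary, so the chimeric fraction is 1/series_length
  (default 5).
- **GTA** — starts uniform over the host genome, lengths H·(1+δ).

Circular units are handled with doubled coordinates: one truth row per
molecule, `end` may exceed the unit end, and conversion to alignment
intervals splits the molecule into two pieces.

**Degradation** truncates a configurable share of molecules to a retained
fraction drawn from Uniform(0.1, 0.9) by default, always keeping the
packaging-start coordinate — this reproduces the observation that
shortened and full-length molecules of one particle class share alignment
starts. The true retained-length law is unknown (only a mean shortened
size from one system is available); the uniform model is a deliberate
stand-in and is configurable.

**Contamination** adds free-DNA reads with positions uniform over the
community (genomes weighted by length) and lengths
10^Normal(log10 8000, 0.35) — a broad, unimodal law (CV ≈ 0.96) chosen so
that contamination can never masquerade as a discrete packaging peak
under the 5% narrowness cap below. The contaminant count is binomial
around the requested share of the final read set.

All randomness flows from one master seed through named substreams
(CRC32 of the component name as a spawn key), so adding a component never
perturbs the draws of another, and identical configurations produce
byte-identical outputs.

### What the simulator does not model

Realistic nucleotide composition, sequencing error, basecalling
artefacts, chimeric library artefacts, density-gradient physics, and
extracellular-vesicle DNA. Passing tests therefore demonstrate that the
analysis recovers the *geometry* of each mechanism from ideal alignments;
they do not bound the effect of alignment noise or mis-assembly on real
data.

## Ingest

Filters: reads ≥ 3 kb and alignments ≥ 1 kb (both configurable); the
alignment filter is applied before ambiguity resolution. A read aligning
to several scaffolds is assigned to the scaffold with the greatest sum of
its aligned lengths there; ties break to the lexicographically smallest
scaffold id so runs are reproducible. Scaffolds fall into six categories
(Viruses; MAG bacteria with/without prophages; unbinned bacteria
with/without prophages; Archaea). Reads roll up to a taxon label — MAG
bin id, else the lowest non-empty taxonomy rank, else the scaffold id —
and taxa at or below the rare-entity floor (50 reads for bacterial units,
200 for viral scaffolds) are dropped. The floor is applied before event
calling, not only for display: the same noise argument applies.

## Peak detection

Per taxon, read lengths are modelled with a Gaussian KDE in log10 space
at a fixed bandwidth of 0.01 log10 units (≈ ±2.3%, matched to the ±2%
packaging imprecision so a single packaging system forms a single mode).
Local maxima with prominence ≥ 5% of the density maximum are candidate
peaks; candidates whose half-width at half maximum exceeds 5% relative
width are rejected as background (a log-normal background with
log10-sd 0.35 has relative half-width ≈ 1.6 and can never pass). Reads
within ±5% of a surviving center join the nearest center in log space
(ties to the taller peak); peaks keeping fewer than 50 members are
dropped. The reported center is the median member length, which makes
peak centers exactly scale-equivariant. Log-binned histograms
(0.1 log10-unit bins) are provided for length-gradient summaries.

## Enrichment

Scaffold relative abundance is count / total sample reads. The VLP/total
ratio r gets a Z-score across the scaffolds of one donor × fraction;
scaffolds with Z > 2 are flagged as VLP-overrepresented. Zero counts
receive a 0.5-read pseudocount so ratios stay finite; increasing a VLP
count can only raise that scaffold's Z. Z-scores are computed on raw
ratios, following the stated procedure of the upstream analysis, even
though real ratio distributions are right-skewed — `ks_normality`
(one-sample KS against a moment-fitted normal, asymptotic p, Lilliefors
caveat applies) is exposed as the diagnostic for exactly that tension,
and a `log_ratio` switch computes Z on log10 ratios instead. A constant
ratio vector yields all-zero Z-scores rather than an error: a degenerate
sample carries no enrichment signal but should not crash a pipeline run.

## Event classification

For each peak an evidence bundle is assembled from reads ≥ 0.7 × peak
center (the counting cut; generalises the ">40 kb" convention used for a
58.4 kb system): the within / outside / chimeric trichotomy against the
matched prophage (2 kb locus margin; "within" = ≥95% of the span inside
the padded prophage; "chimeric" = starts at *pac* within the margin and
extends at least the margin beyond the boundary, both orientations
supported), an inferred *pac* site (densest 1 kb window of alignment
starts, 100 bp steps, reported when it holds ≥20% of starts), the
periodicity score (share of outside starts within 2% of the lattice
pac + k·peak, minus the uniform expectation), long-read coverage
uniformity (CV of read counts in 10 kb windows over the taxon's
scaffolds), and — when short-read coverage is supplied — a coverage wave
(dominant positive-lag autocorrelation of the windowed profile downstream
of the prophage, with a decay flag when successive crests are
non-increasing; the noise band accounts for the maximum over all lags
tested). A prophage "matches" a peak when its length is within ±10% of
the peak center or it contains the inferred *pac*.

The ordered decision table:

1. **LT** — prophage matched AND (periodicity ≥ 0.3 OR wave period within
   5% of the peak center OR ≥5 chimeras that are *not* confined within one
   peak-length of the boundary);
2. **induction** — ≥80% of counted reads within the prophage AND peak
   center within [0.95, 1.10] × prophage length;
3. **ST** — chimeras present, confined within one peak-length of the
   boundary, and no periodicity or wave;
4. **GT** — coverage CV ≤ 0.5 over ≥200 kb of scaffold space, peak center
   ≥ 15 kb, prophage-overlap share < 0.2;
5. **GTA** — coverage CV ≤ 0.5, center < 15 kb, relative half-width
   ≤ 5%;
6. **ambiguous** otherwise.

These signatures are normally judged by eye; every threshold here is this
package's formalisation, each anchored to printed scales (the 15 kb
GT/GTA split sits between reported GTA fragment sizes of ≤13.4 kb and
phage genome sizes of ≥33 kb; the 0.7 counting cut reproduces the
40 kb/58.4 kb convention), and all are fields of `ClassifyThresholds`.
One deliberate refinement: chimeras alone qualify for LT only when they
extend beyond one peak-length of the prophage boundary. Boundary-confined
chimeras are precisely the ST signature, and an LT caller that accepted
them would make ST undetectable; in practice LT announces itself through
the series (periodicity or wave), which is how the rule fires on
simulated and real-geometry bundles. Events need ≥50 peak members; one
taxon can yield one event per peak. Rule traces record every comparison.

## Benchmark and problem sizes

The labelled benchmark simulates six mechanism configurations (cos and
headful induction of a 40 kb prophage on a 500 kb chromosome; ST with a
5 kb flank; LT with a 56.9 kb prophage and 58.4 kbp capacity on 600 kb;
GT at 30% transducing fraction against a 2 Mb chromosome; GTA at
8.65 kbp on 2 Mb) at 2,000 reads per run, 20 replicates each, and
tabulates calls; per-mechanism recall ≥ 0.9 with default thresholds. The
scaled validation targets in `scripts/acceptance.py` use 2,000–20,000
particles and megabase-scale chromosomes — sizes at which binomial and
KDE errors are comfortably inside the tolerances being checked while a
full run stays in the seconds range.

## Known limitations

- Mechanisms whose geometry collides (e.g. an LT series with series
  length 1, or ST with a flank shorter than the locus margin) are not
  separable by any threshold setting; such bundles fall to induction or
  ambiguous.
- The GT caller needs enough scaffold space (≥200 kb) and coverage depth
  for a stable CV; sparse taxa fall to ambiguous rather than GT.
- Enrichment Z assumes roughly comparable scaffold count distributions
  across donors × fractions; it is a within-sample outlier statistic,
  not a differential-abundance model.
- Wave detection requires short-read coverage input; without it, LT
  calls rest on periodicity and chimeras only.
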