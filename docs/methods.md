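# Methods

This note documents the models and conventions implemented in `cnvdx`, the
choices made where the design was genuinely open, and what the synthetic
data does and does not emulate.

## Dosage model

All quantities derive from the per-probe log2(patient/reference) ratio with
a uniformly diploid baseline: an interval at integer copy number *n* has
expected log2 = log2(*n*/2).  Copy number 0 is floored at log2 = −4 rather
than −∞, because real arrays saturate.  Sex chromosomes are treated
identically to autosomes: clinical arrays hybridize against a sex-matched
reference, so a doubled X in 47,XXY reads log2(4/2) and annotates as x4.
The integer copy-number estimate is round(2·2^mean) (half-up), clipped at
zero; it is non-decreasing in the mean by construction.

The two published thresholds are reconciled as a two-tier rule.  The
candidate tier (|mean log2| ≥ 0.25, ≥ 3 consecutive probes) defines a
*reportable* aberration.  The dosage tier (mean > 0.58 for gains, < −1 for
losses — log2(3/2) and log2(1/2)) defines *full single-copy* dosage.
Segments between the tiers are retained and flagged `sub-integer`
(possible mosaics), never discarded.  The gain tier is strict (">"), the
candidate tier non-strict (ties at exactly 0.25 are accepted).

## Segmentation

Segmentation is a run rule, not a change-point optimisation — no penalty
model, no ADM/CBS re-implementation, no probe-level smoothing:

1. Partition each chromosome's probes into maximal sign-consistent runs;
   a zero or opposite-sign probe terminates a run (no outlier tolerance).
2. Within a run, the candidate segment spans from the first to the last
   probe whose own |log2| meets the candidate threshold; equivalently, run
   ends are trimmed of individually sub-threshold probes.
3. The segment is called if it has ≥ `min_probes` probes and
   |mean log2| ≥ the candidate threshold.

The end trim is the one place this package goes beyond the bare run rule.
Without it, low-level same-sign noise probes flanking a true event would be
absorbed into the run and drag the reported breakpoints outward by several
probe spacings; with it, breakpoints sit on the aberrant probes themselves,
and the recovery tests (below) hold.  The trim changes nothing on clean
data: sub-threshold flanks are exactly the probes a reviewer would exclude.

An independent brute-force enumerator over all O(n²) intervals re-derives
the same selection on arrays of ≤ 50 probes and must agree exactly; this is
a standing property test.

**Aneuploidy.** A chromosome is aneuploid when the fraction of its design
probes covered by same-direction calls reaches `aneuploidy_fraction`
(default 0.9 — a declared convention, chosen so that segmentation gaps of a
few probes cannot mask a whole-chromosome event while 50%-of-arm events
never qualify).  Contributing calls are marked aneuploidy-derived and
removed at the cascade's first stage.  Whole-chromosome events render as
one ISCN line per arm, with the centromeric gap taken from the cytoband
table.

## Filtration cascade

Stage order is fixed: aneuploidy → size → benign population → gene content
→ clinical significance.  Each record is removed at its first failing
stage, which makes the stage counts a partition of the input
(|input| = |kept| + Σ removals) — asserted on every run.  The cascade is
order-invariant in its input and idempotent on its own kept set.

Conventions at each stage:

* **Size**: strictly-less-than 300 kb is excluded; exactly 300 kb passes.
* **Benign population**: a record is benign if a database CNV of compatible
  state (same direction, or `either`) overlaps it reciprocally at ≥ 50% —
  shared length ≥ 50% of *each* interval.  The 50% reciprocal-overlap
  criterion is the community standard for CNV matching and is
  parameterized.
* **Gene content**: ≥ 1 bp overlap with ≥ 1 gene keeps the record;
  "critical" genes are not separately modelled — the filter is purely
  presence/absence, and overlapping symbols are attached to survivors.
* **Clinical significance**: matching uses call-side overlap only
  (≥ 50% of the call), because curated syndrome regions can far exceed an
  individual call.  The best region wins — largest overlap, then
  pathogenic over VUS, then input order — and contributes one label and
  one syndrome per call.

## ISCN nomenclature and sizes

Rendering follows `arr[<build>] <chrom><band_start><band_end>(<start>_<end>)x<n>`,
omitting the end band for single-band calls.  The parser tolerates stray
spaces and hyphens between bands (as typeset tables contain) but treats a
missing `_` coordinate separator or a missing `x<n>` suffix as an error
naming the position.  Parsing inverts rendering for every generator-valid
call (property-tested).

Sizes are reported in Mb **truncated** (not rounded) to one decimal:
floor((end − start + 1)/10⁵)/10.  Truncation is the convention that
reproduces published clinical report sizes from their own printed
coordinates (e.g. a 3,764,485 bp duplication reported as 3.7 Mb, a
38,550,991 bp gain as 38.5 Mb — rounding would print 3.8 and 38.6).
Coordinates are 1-based inclusive throughout, size = end − start + 1; at
0.1 Mb reporting precision the ±1 bp convention never changes output.  The
one on-disk exception is the UCSC cytoBand dialect (0-based half-open),
converted on read.

## qPCR (Livak ΔΔCt)

Amplification efficiency is fixed at 100% (exact doubling), as the Livak
method assumes; no Pfaffl efficiency correction.  Per arm,
ΔCt = mean Ct(target) − mean Ct(endogenous control);
ΔΔCt = ΔCt_patient − ΔCt_calibrator; RQ = 2^−ΔΔCt; copy number =
round(2·RQ).  Direction is called on RQ against 0.75/1.25 — a declared
convention placing the boundaries halfway between the diploid (1.0) and
single-copy-shift (0.5/1.5) expectations.  A two-sample t-test on
per-replicate ΔCt values (patient vs calibrator) is reported alongside each
call but does not gate it.  Concordance with the array is directional:
loss↔decrease, gain↔increase.

## Synthetic data

The generators define the study conditions; they are not tuning knobs.

* **Genome**: miniature (default 4 autosome analogues + X, 30–60 Mb each)
  so full pipelines run in seconds; bands are procedurally generated with
  ISCN-style two-level numbering and tile each chromosome exactly.  A
  packaged fixture (`hg18_cytobands_synthetic.txt`, labelled synthetic)
  reconstructs hg18 band/coordinate pairs consistent with published
  clinical call strings so nomenclature round-trips are testable without a
  genome download.
* **Designs**: the 244K/400K formats target median probe spacings of
  8.9 kb and 5.3 kb respectively; inter-probe steps are uniform in
  [0.5, 1.5]× the target, so the realized median lands on target and probe
  count scales with genome size.
* **Samples**: probe log2 = covering event's expected log2 + Gaussian
  noise.  Default probe noise sd = 0.15 — a typical high-density oligo
  aCGH derivative-log-ratio scale, chosen a priori; no dye bias, GC waves,
  or spatial artifacts are modelled.  At this noise level short spurious
  runs are expected and are removed downstream by the < 300 kb filter, as
  on real arrays.  Recovery properties are stated at sd ≤ 0.05, where
  breakpoint accuracy is probe-limited.
* **Cascade fixture**: co-constructs calls with the database/track/region
  tables so each record fails first at its designated stage.  Removable
  categories reuse loci within per-category slot pools (sample ids cycle);
  each survivor gets its own slot, gene, and clinical region.  The kept
  set encodes a 13/11 pathogenic/VUS split and a 14/10 loss/gain split at
  n = 24 (generalised as round(13/24·n) and round(14/24·n)).  A
  per-record audit that independently re-evaluates all five filters is a
  standing test.
* **qPCR plates**: Ct = base − log2(template) + N(0, sd), triplicate,
  patient target template ∝ CN/2.  Default replicate noise sd = 0.05
  cycles, a typical SYBR triplicate precision chosen a priori; at that
  noise the copy-number estimate recovers the planted CN ≥ 95% of the time
  for CN ∈ {1, 2, 3}.
* **Seeding**: one global seed fans out to per-generator child streams by
  fixed offsets; identical seeds give identical outputs byte for byte.

What passing tests show — and do not show.  The synthetic cohort
demonstrates that the bookkeeping, thresholds, overlap arithmetic, and
nomenclature are implemented exactly; it cannot validate biological
discovery on real arrays, where wave artifacts, mosaicism, and reference
choice dominate error.

## Problem sizes

Default test/analysis scales: ~200 Mb genome, ~49k probes (400K design),
2537-record cohort fixture, 100-replicate breakpoint-recovery runs on a
5 Mb single-chromosome genome (~940 probes), 200 qPCR replicates per copy
number.  These desk scales were chosen so any run completes in seconds
while keeping every statistical property testable.

## Known limitations and open points

* Segment means are computed on unsmoothed probes; no mosaicism
  quantification beyond the sub-integer dosage flag; no inter-sample
  normalization.
* The cascade models "critical gene" as any gene, and benign matching as
  50% reciprocal overlap — both are parameterized conventions, not
  published constants.
* Published cohort tabulations contain internal inconsistencies (a 24-call
  table enumerated as 23 rows with one "Syndromic" label; an aggregate
  elsewhere quoting 42 pathogenic/VUS calls across 19 patients; size-bin
  percentages that cannot arise from 24 equally weighted calls).  The
  fixture encodes the explicitly stated splits (13/11, 14/10); size-bin
  output is offered both count- and bp-weighted; the discrepancies are
  documented, not resolved.
* The ISCN grammar covers microarray strings only — no translocations,
  rings, mosaicism (`mos`), or G-band karyotype strings, which enter the
  cohort comparison as opaque labels with an abnormal flag.
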