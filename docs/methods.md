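# Methods

## Copy-number model and calibration

The copy-number pipeline assumes an HU-arrested population in which every
locus is either unreplicated (1N) or replicated exactly once (2N); forks
do not terminate or re-fire under dNTP depletion, so fractional values in
the profile reflect cell-to-cell heterogeneity and noise, not higher
ploidy. The S/G1 ratio is computed per 100-bp bin (`bin_width`,
configurable); 100 bp resolves 2-kb replication tracts with ~20 bins per
side while keeping Poisson noise per bin manageable at ~100× coverage.

**Ratio orientation.** The ratio is S/G1: replication must *increase* the
statistic for a 1N baseline and a 2.2N ceiling to be meaningful. The
transposed ratio (G1/S) is available behind `literal_orientation=True` for
auditing, and `orientation_looks_inverted()` flags a calibrated profile
whose lower tail is heavier than its upper tail — the signature of swapped
inputs, since dormant regions must sit at the *bottom* of the
distribution. The CLI runs this audit by default (`--no-audit` disables).

**Dormant regions.** Calibration to physical units needs loci of known
copy number. Regions maximally distant from any origin capable of firing
remain 1N throughout an HU arrest. A candidate is a pair of origins
*adjacent in the chromosome's full origin ordering* with both members
late/dormant; requiring adjacency in the full ordering (rather than
adjacency within the late-only subsequence) guarantees no origin of any
class lies inside the gap, which is what licenses the no-replication
assumption — a gap between two late origins that contains fired early
origins would contaminate the baseline. Candidates with gap ≥ the region
width are ranked genome-wide by gap size (ties broken by chromosome order,
then start — determinism) and the top `n_pairs` (default 10) become the
dormant set: a `width`-bp window (default 10 kb) centred on the gap
midpoint, the point farthest from either flanking origin. At the
degenerate gap == width the window abuts the flanking origins; for
maximal-gap pairs the gap is in practice several times the width.

`one_n_value` is the plain mean of unmasked raw ratios pooled over all
dormant bins; after division the dormant-region mean is 1 by construction
(asserted to machine precision in the tests). Calibration is therefore
idempotent and invariant to library-size rescaling of either input.

**Late/dormant classification.** An origin is late/dormant iff
t_rep ≥ `late_threshold`. An explicit class column in the origin file
takes precedence. When no threshold is given it defaults to the 75th
percentile of the input t_rep distribution — a conventional cut that makes
a quarter of origins "late" without a genome-specific timing model.

**Masking.** Bins with G1 below `min_g1_count` (default 1) are masked
rather than stabilised with pseudocounts: a pseudocount fabricates signal
exactly where the data say nothing (unmappable or empty bins). The 2.2N
ceiling is strict (`> 2.2` masks, `== 2.2` survives). Masked bins are NaN
throughout and are omitted from bedGraph exports.

**Fork extent.** `estimate_fork_extent` scans outward from the origin bin
through the contiguous run of bins with calibrated value ≥ `threshold_n`
(default 1.5, the midpoint between 1N and 2N) and reports the distance to
the outer edge of the farthest such bin; the two sides are combined by
max, since forks move symmetrically and the longer side is the better
estimate when the other is truncated by noise or a chromosome end. Bins
masked by the ceiling qualify for the run: they were removed for being too
*high*, so treating them as failures would systematically truncate
extents. A masked origin bin flags the result low-confidence.

## ChIP internal-standard normalization

`cen_scale` divides a track by the mean count per bin within ±`halfwidth`
(default 500 bp) of the centromere midpoints, pooled across all
centromeres — a single scalar, as for a spike-in, not a per-chromosome
factor. The window is anchored on the centromere interval midpoint; the
point-centromeres of budding yeast are ~120 bp, so midpoint-vs-edge
anchoring moves the window by under a bin. A track with zero centromeric
counts has no internal standard and is rejected.

`background_normalize` then compares a tagged strain to the
internal-standard-only strain: per-bin ratio by default ("normalized to"
most commonly denotes division; subtraction floored at zero is exposed as
an option, and the mode used is recorded in the JSON sidecar). Epsilon
for the ratio defaults to half the genome-wide median of the background
track, preventing blow-ups in empty bins while perturbing typical bins by
a bounded, scale-invariant amount. Centromeric windows are masked in the
output and in exported visualization tracks — the internal standard is not
signal. `locus_normalize` (mean over an unreplicated background locus)
gives the same track up to one global constant and serves as the
cross-check normalization.

`attenuation_estimate` quantifies how much fork enrichment a mutant
retains: `(fw(mut) − fw(bg)) / (fw(wt) − fw(bg))` where `fw` is the mean
cen-scaled signal within ±500 bp of the (known or simulated) fork
positions. The background's fork-window *mean* is subtracted, rather than
per-bin floored differences, because flooring at zero biases the
fork-window mean of a near-background track upward (measured: ~0.15 for a
true 0.1 at the default noise level, vs ~0.10 unbiased).

## Metaprofiles

`build_heatmap` extracts a ±`window` (default 5 kb, covering the 2-kb fork
positions with flanks) view around every origin midpoint, one row per
origin, rows sorted by ascending t_rep (ties by chromosome order, then
position) regardless of input file order. The centre column is the
origin's own bin; cells outside the chromosome, and masked track bins,
are NaN and never contribute to averages. Rows are not rescaled —
cross-strain comparability in internal-standard units is the point of the
normalization. `average_profile` computes each column's mean over exactly
its unmasked cells (bit-identical to the heatmap's column means) together
with the contributing count; an all-masked offset stays NaN rather than
becoming zero. `track_signal_position` folds each profile about the
origin and reports the argmax offset of the folded profile per time
point; a flat or all-masked profile has no peak and yields NaN.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
with all rates per 100-bp bin and all counts Poisson:

| parameter | default | meaning |
|---|---|---|
| `depth_lambda` | 100 | expected fragments per 1N bin (≈100× coverage) |
| `fork_distance` | 2000 bp | how far forks travel before stalling |
| `firing_regime` | `sld3A_dbf4A` | all origins fire; `wildtype` fires t_rep ≤ `firing_cutoff` (30 min) |
| `chip_background` | 5 | non-specific ChIP fragments per bin |
| `fork_enrichment` | 30 | peak amplitude of the fork ChIP signal |
| `peak_sigma` | 200 bp | Gaussian width of each fork peak |
| `enrichment_attenuation` | 1 | multiplies fork enrichment (0.1 emulates the recruitment-dead mutant) |
| `cen_amplitude` | 50 | internal-standard amplitude over centromeric bins |
| `cen_halfwidth` | 500 bp | centromeric window half-width |

G1 is flat at `depth_lambda`; S is `depth_lambda ×` true copy number,
where the truth is 2 on bins overlapping the union of `pos ±
fork_distance` intervals of fired origins and 1 elsewhere (overlaps merge;
copy number never exceeds 2). ChIP tracks are background + centromeric
term (+ Gaussian peaks at the two fork positions per fired origin for
tagged samples). Sample kinds and replicate streams draw from independent
generators seeded by `(seed, kind, stream)`, so runs are byte-reproducible
and samples mutually independent. Counts are generated directly per bin
— the analysis consumes binned counts, so fragment-level simulation adds
nothing — but `write_fragments_bed` expands a track into BED fragments
(uniform within bins, midpoints preserved) to exercise the binning reader.

The demo annotation set is a 2-Mb, two-chromosome genome with 60 origins
(one per ~33 kb, the density of yeast ARS elements), t_rep rising
quadratically from ~10 min near the centromere to ~40 min at the
telomeres with 1.2-min scatter — the pericentromeric-early /
subtelomeric-late organisation of the real genome. That spatial clustering
of late origins is what creates runs of adjacent dormant origins; with
these settings every seed tested (0–59) yields ≥ 10 eligible dormant
pairs whose selected gaps (≥ ~20 kb) keep 2-kb forks well clear of the
10-kb dormant windows.

**What the simulator does not model:** mappability and GC bias, fragment
length distributions, sequencing error, copy-number artefacts above 2.2N
(the ceiling mask is exercised by Poisson outliers only), fork-rate
heterogeneity between origins, and partial origin efficiency. Passing
tests therefore demonstrate the correctness and calibration of the
*computations* under the stated noise model, not robustness to every
artefact of real libraries.

## Numerical choices

- Fragments are assigned to the bin containing their midpoint
  (`floor((start+end)/2)`), keeping counts integral and conserved; the
  trailing partial bin of each chromosome is retained.
- bedGraph re-binning is length-weighted (`value × overlap / bin_width`),
  exact for bin-aligned intervals; overlapping intervals are rejected.
- All tracks are float64; masking is NaN; comparisons against the 2.2N
  ceiling are strict.
- Verification problem sizes: the test suite and acceptance script run on
  the 2-Mb / 60-origin demo genome at 100× depth, with five replicate
  seeds for rate-style checks — small enough to run in seconds while
  leaving >1,000 dormant bins and ~2,500 true-2N bins per run, so the
  recovery bands (2N within [1.9, 2.1], extent within one bin for ≥90% of
  origins, attenuation within ±0.05) are statistically meaningful.

## Known limitations

- Dormant-region selection assumes the origin annotation is complete;
  unannotated origins inside a selected gap would silently violate the 1N
  assumption (in real data the 2.2N mask does not protect against this —
  a replicated dormant bin reads ~2N, not >2.2N, but it would inflate 1N
  and *deflate* the rest of the profile, which the orientation audit does
  not catch).
- The centromeric internal standard is taken as invariant across strains;
  the validity check (tagged/untagged scale-factor ratio equals the
  centromeric rate ratio) is exact only on expectations.
- `estimate_fork_extent` reports a point estimate; no uncertainty is
  attached beyond the low-confidence flag.
- Copy-number work beyond the four steps (smoothing, segmentation,
  replication-timing curve fits) is out of scope.
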