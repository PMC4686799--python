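# Methods

## Model

`cfdnafrag` treats apoptotic cfDNA as reads of a nucleosome-protected
genome: endonucleases cleave accessible linker DNA, so a sequenced
fragment is (mostly) one nucleosome's worth of protected DNA plus
variable linker stubs. Three observable consequences organise the
package: (i) the fragment-length distribution is a mixture of a
mononucleosome mode and a dinucleosome mode; (ii) fragment midpoints
(dyads) phase to nucleosome centres, so same-strand read starts show a
distance comb at multiples of the nucleosome repeat; (iii) the coverage
just downstream of a TSS carries the local nucleosome organisation,
which differs between silenced and broadly expressed genes.

## Synthetic generator

The generator is a *distributional* emulator, not a mechanistic
cleavage model: it draws fragments directly from the statistical
structure the analyses are meant to detect, which makes every stage
testable against a known ground truth.

* Nucleosome map: dyads at exact repeat spacing (193 bp = 147 bp core
  + 46 bp linker) from a random phase. The number of dyads is
  `floor((region_length − phase)/repeat)`.
* Lengths: mononucleosome fragments (default fraction 0.85) from
  N(165, 20²); dinucleosome fragments from N(308, 25²); lengths rounded
  and floored at 50 bp. An optional "comb" replaces 15% of the
  mononucleosome draws with discrete modes 152, 143, 133, 122, 112,
  102 bp (geometric weights, ratio 0.7, ±1 bp), emulating the ~10 bp
  periodicity of intra-nucleosomal nicking. The comb is **off** by
  default: with it on, the sub-modes (mean ≈ 137 bp) would drag the
  sub-250 bp mean to ≈161 bp rather than the 165 bp calibration point.
* Positions: a mono fragment's midpoint is a uniformly chosen dyad, a
  di fragment's the midpoint of an adjacent dyad pair (a deliberately
  neutral choice — nothing is assumed about dinucleosome positioning
  beyond underdigestion), plus N(0, 20²) jitter, rounded to the nearest
  integer with ties to even. Fragments are clipped to the region.
* GC bias (off by default): with strength *s* and a per-base GC track,
  fragments are importance-resampled with weight exp(s·(GC − 0.5)),
  mimicking capture/PCR preference for GC-rich template.
* TSS panel: one gene per 5 kb slot on a synthetic contig, random
  strand; the +1 dyad sits 100 bp downstream of the TSS with +2/+3 at
  repeat-length steps, positional jitter inflated ×(1, 1.25, 1.5) with
  array index so stringency decreases along the array.
  Tissue-specific (silenced-gene proxy) arrays use 10 bp jitter;
  housekeeping (expressed-gene proxy) arrays use 45 bp jitter and a
  40% weight reduction of the +1 nucleosome. Panel sizes default to
  134/246. Setting both jitters equal and the depletion to zero makes
  the classes exchangeable — the null configuration used for
  calibration tests.
* Mark intervals: each dyad's 147 bp footprint is covered with the
  requested probability by a mark centred on it; the remaining marks
  are placed uniformly in footprint-free sequence (linkers/flanks,
  shrunk to fit) so uncovered footprints stay mark-free.

All draws flow from a single integer seed through independent
`numpy` `default_rng` streams per product (map / fragments / panel), so
identical configurations are byte-identical.

What the generator does **not** emulate: sequencing errors and base
calls, capture-probe footprints, chromosome-scale heterogeneity,
tissue mixtures, and any genuine dinucleosome positional biology.
Passing tests therefore demonstrate that the *analyses recover the
structure they target at realistic effect sizes and depths*, not that
real cfDNA meets the generator's assumptions.

## Analysis choices

* Fragment = outer span of the proper pair; fragments > 1000 bp are
  removed (a fragment of exactly 1000 bp is kept). Duplicate fragments
  are retained — pile filtering depends on co-located starts.
* Dyad of an even-length fragment: `start + floor(length/2)`.
  Trimming to dyad ± 40 bp requires length ≥ 80 bp.
* Mono/di split: < 250 bp vs 250–350 bp inclusive; longer fragments
  belong to neither fraction and are ignored by phasograms and peak
  calling.
* Phasograms: "co-located" means an identical start coordinate on the
  same strand and chromosome; after pile filtering each retained
  position counts once, so PCR-duplicate mass cannot dominate.
  Read starts derived from a fragment table are its start (plus
  strand) and end − 1 (minus strand). Default pile order 3, maximum
  distance 2500 bp.
* Spacing estimate: Gaussian smoothing (sd 10), peaks ≥ 100 bp apart
  with prominence ≥ 5% of the smoothed range, distances < 100 bp
  excluded (they carry intra-pile cluster mass), spacing = regression
  slope of peak position on index.
* Sub-peak periodicity: lengths from 90 bp up to 5 bp below the
  histogram mode, detrended by subtracting a Gaussian smooth (sd 15);
  maxima ≥ 5 bp apart with prominence above 4·√(mean count) — a
  Poisson noise scale — and at least three maxima are required,
  otherwise the result is flagged undefined.
* Peak calling: Gaussian kernel (sd 30, configurable) on per-base dyad
  counts, zero-padded at the region edges; candidates are local maxima
  ≥ threshold × regional mean density (threshold 1.0); greedy
  acceptance in decreasing density order at ≥ 147 bp separation;
  stringency = smoothed density ÷ regional mean. The kernel form and
  the normaliser are package choices; both are exposed as parameters.
* Mark association: one-sided enrichment with the add-one empirical
  p-value; random sites are whole-footprint-inside placements sampled
  per region proportional to placeable length. No multiplicity
  correction is applied in the headline matrix; a Bonferroni column is
  emitted alongside.
* Ratio grid: per-gene coverage ratios at position pairs (step 10 bp),
  Welch t-test per cell, numerator position in the column and
  denominator in the row; genes with zero denominator coverage are
  dropped cell-wise; the diagonal is fixed at t = 0, p = 1. Contiguous
  significant areas (p < 0.05, 8-connectivity) are ranked by mean p.
  Per-gene ratios (rather than ratios of class-averaged profiles) are
  used because the t-test needs per-gene replicates.

## The resolution score

The score is s(peak)/s(trough): coverage at the first post-TSS peak
over coverage at the subsequent minimum, both read from a lightly
smoothed profile, with peak/trough located on a strongly smoothed one.

* Low-pass filter: zero-phase DFT filter; components with frequency
  above the cutoff (expressed as cycles per base) are zeroed. The
  detection cutoff 0.015 keeps periods ≳ 66 bp — the nucleosome-scale
  structure — and the ratio cutoff 0.07 removes only fine noise.
  The cutoff is compared against ordinary cycles-per-base frequency;
  with a radians-per-sample reading the detection filter would keep
  only ~periods > 400 bp and no first peak could ever be located
  within the 500 bp search window.
* Peak: first centre c (window 50 bp, within the first 500 bases)
  whose value is the maximum of its window with both window edges
  strictly lower. A relative tolerance of 1e-9 on the dominance means
  float-level filter ripple on a constant profile can never produce an
  extremum, so featureless profiles score exactly 1.
* Trough: the minimum of the detection signal between the first peak
  and the next window-peak at least 100 bp away (about half a repeat —
  anything closer is filter ripple, not chromatin structure), required
  to be an interior local minimum within the 500 bp window. A mirrored
  "first window-trough" rule was evaluated and rejected: the brick-wall
  filter leaves ~66 bp Gibbs ripple on the flat-topped coverage domes
  that tightly phased arrays produce, and a first-local-trough rule
  then latches onto ±2% ripple dips, collapsing all scores to ≈1.
* Conventions: no peak or no trough → score 1 (flagged as not found);
  non-positive trough coverage → score undefined (excluded from class
  comparisons, counted). The score is invariant to positive scaling of
  the profile.

Under the default panel the tissue-specific (silenced, phased) class
scores *higher* (≈2.1) than the housekeeping class (≈1.1): sharp
arrays resolve the first peak against its trough. Published work on
this contrast reports class means of 3.5 (tissue-specific) versus 4.4
(housekeeping) — the opposite ordering — while describing
tissue-specific genes as the ones with well-resolved +1/+2/+3 peaks.
The sign convention is therefore ambiguous in the literature; this
package asserts and tests the *separation* of the classes, with the
direction that follows from the constructed effect, and leaves the
sign a reporting convention.

## Problem sizes and calibration checks

Simulation-recovery checks run at the cohort calibration of 200,000
fragments over 1 Mb (≈5,200 nucleosomes), where the 3-pile phasogram
spacing lands within ±3 bp of 193 and the fraction means within
±1/±2 bp of 165/308. Note the 250–350 bp band mean sits near 306 bp,
not 308: truncating N(308, 25²) at 350 bp (+1.7 sd) pulls the band
mean down by ≈1.9 bp. Null calibrations use 200 replicate panels
(12–15 genes per class) for the score comparison and the mark test,
and 10 replicate panels (30 genes per class) for the ratio grid; grid
cells share genes and are strongly correlated, so the significant-cell
fraction is pooled across independent replicates and checked against a
0.02–0.10 band around the nominal 5% rather than a per-grid binomial
band. Jitter-free peak-calling recovery demands ≥95% precision and
recall at ±10 bp.

## Known limitations

* The permutation mark test conditions on the marks and the targeted
  regions; it does not model mark-to-mark correlation.
* Peak calling assumes a single contiguous calling region; coverage
  gaps inside it lower the regional mean density and hence the
  stringency normaliser.
* The dinucleosome "midway" placement is a neutral convention;
  dinucleosome peak-histogram spacings from the generator reflect the
  mononucleosome repeat, not any distinct dinucleosome biology.
* `estimate_spacing` needs at least two resolvable histogram peaks and
  will refuse diffuse histograms rather than guess.
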