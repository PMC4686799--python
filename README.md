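# cfdnafrag

Cell-free DNA (cfDNA) circulating in plasma is released mainly by
apoptosis, which cuts chromatin in the linker DNA between nucleosomes.
Fragment lengths therefore cluster at the mononucleosome (~165 bp) and
dinucleosome (~308 bp) sizes, fragment midpoints phase to nucleosome
dyads with the ~193 bp nucleosome repeat, and the coverage pattern just
downstream of a transcription start site (TSS) differs between genes
that are silenced (sharply phased +1/+2/+3 nucleosomes) and genes that
are broadly expressed (nucleosome depletion and fuzzy positioning).
`cfdnafrag` implements the complete "fragmentomics" analysis stack for
paired-end cfDNA data, together with a synthetic fragment generator so
the whole pipeline can be exercised and validated without sequencing
data. It is aimed at researchers prototyping nucleosome-footprint
analyses of liquid-biopsy data.

## What it computes

* **Fragment ingestion** (`fragmentio`) — couple read pairs into
  fragments (outer span), drop unpaired/secondary reads and fragments
  longer than 1000 bp, split the library into the mononucleosome
  (<250 bp) and dinucleosome (250–350 bp) fractions, trim fragments to
  an 80 bp window around the dyad (midpoint ± 40 bp), and build
  per-base coverage.
* **Phasograms** (`phasogram`) — histograms of distances between
  same-strand read starts, with *N*-pile filtering (keep only start
  positions observed ≥ N times). The dominant spacing is the slope of
  detected histogram peaks regressed on peak index; a nucleosome-phased
  library shows a comb at multiples of the repeat length
  *r* = core + linker = 147 + 46 = 193 bp. The ~10 bp sub-periodicity
  of intra-nucleosomal cleavage is estimated from the length histogram
  below the major mode.
* **Peak calling** (`peakcall`) — Gaussian-kernel smoothing of the
  trimmed-fragment dyad counts; local maxima above a multiple of the
  regional mean density are accepted greedily at ≥147 bp separation, so
  the ±73 bp footprints never overlap. Occupancy is the fraction of a
  target region covered by footprints; per-offset GC profiles quantify
  capture/PCR bias inside called peaks.
* **Mark association** (`marks`) — a one-sided permutation test of
  whether peak footprints intersect epigenetic-mark intervals (BED)
  more often than equally many random 147 bp sites placed uniformly in
  the targeted regions, with the add-one empirical p-value.
* **TSS analysis** (`tss_analysis`) — strand-oriented coverage profiles
  downstream of each TSS; the **first-peak resolution score**

  score = s(peak) / s(trough),

  where peak and trough are found on a strongly low-pass-filtered
  profile (cutoff 0.015 cycles/base) with a 50 bp sliding window within
  the first 500 bases, and s(·) is the profile filtered at 0.07
  cycles/base. A profile with no detectable peak or subsequent minimum
  scores exactly 1. Classes are compared with a Welch t-test, and a
  position-pair coverage-ratio t-statistic grid localises the offsets
  that separate them.
* **Synthetic data** (`synthetic_data`) — nucleosome maps, fragments
  drawn from the length mixture with dyad-phased midpoints, optional
  ~10 bp length comb and GC bias, mark intervals with a controlled
  footprint-overlap fraction, and a TSS gene panel with
  tissue-specific (phased) versus housekeeping (fuzzy, +1-depleted)
  classes.

## Worked example

```python
import cfdnafrag as cf

config = cf.RunConfig(
    seed=11, out_dir="demo_run",
    sim={"region_length": 300_000, "n_fragments": 80_000},
    panel={"n_specific": 30, "n_housekeeping": 40},
)
manifest = cf.run(config)
for key in ("major_mean_length", "minor_mean_length", "phasogram_spacing",
            "n_peaks", "occupancy", "score_mean_tissue_specific",
            "score_mean_housekeeping", "score_p_value"):
    print(key, round(manifest["summary"][key], 3))
```

prints

```
major_mean_length 165.125
minor_mean_length 306.432
phasogram_spacing 192.979
n_peaks 1554
occupancy 0.761
score_mean_tissue_specific 2.087
score_mean_housekeeping 1.094
score_p_value 0.0
```

The mononucleosome fraction averages ~165 bp and the dinucleosome
fraction ~306 bp (the 250–350 bp band truncates the upper tail of the
308 bp mode); the 3-pile phasogram recovers the 193 bp repeat; peak
calling tiles the region with non-overlapping 147 bp footprints; and
the resolution score separates the sharply phased tissue-specific
genes (mean ≈ 2.1) from the fuzzy, +1-depleted housekeeping genes
(mean ≈ 1.1) at a vanishing p-value. The same pipeline runs from the
shell: `cfdna-frag run --config run.json`.

Real alignments enter through `cfdnafrag.pair_and_filter` (any pysam
alignment iterable) or `read_fragments_bed`, and gene tables / mark
intervals are plain TSV/BED.

## Layout

```
src/cfdnafrag/      library (synthetic_data, fragmentio, phasogram,
                    peakcall, marks, tss_analysis, pipeline, cli)
tests/              pytest suite, including end-to-end calibration checks
docs/methods.md     models, parameter choices, numerical details
scripts/acceptance.py   headline-quantity reproduction
```
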