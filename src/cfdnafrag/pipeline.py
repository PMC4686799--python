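"""End-to-end orchestration: simulate → filter → phasogram/peaks → marks → TSS.

One flat :class:`RunConfig` drives every stage; outputs are written as
plain-text formats (BED/TSV/JSON) into an output directory together with
a manifest carrying a SHA-256 checksum per file and a summary report of
the headline quantities (fraction means, spacing estimates, occupancy,
association p-values, class score means).  Runs are byte-reproducible
for a fixed config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fragmentio, marks, peakcall, phasogram, synthetic_data, tss_analysis

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat configuration of a full pipeline run."""

    seed: int
    out_dir: str = "cfdnafrag_run"
    # stage toggles
    do_phasogram: bool = True
    do_peaks: bool = True
    do_marks: bool = True
    do_tss: bool = True
    # generator parameters (forwarded to SimulationConfig / GenePanelSpec)
    sim: dict = field(default_factory=dict)
    panel: dict = field(default_factory=dict)
    # analysis parameters
    pile_order: int = 3
    max_distance: int = 2500
    bandwidth: float = 30.0
    threshold: float = 1.0
    mark_overlap_fraction: float = 0.9
    mark_width: int = 30
    n_permutations: int = 199
    window: int = 700
    step: int = 10
    max_insert: int = 1000

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: RunConfig) -> dict:
    """Execute the configured stages and return the manifest."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    summary: dict = {}

    sim_cfg = synthetic_data.SimulationConfig(seed=config.seed, **config.sim)
    nmap = synthetic_data.generate_nucleosome_map(sim_cfg)
    frags = synthetic_data.generate_fragments(nmap, sim_cfg)
    logger.info("simulated %d fragments over %d bp (%d dyads)",
                len(frags), sim_cfg.region_length, len(nmap))
    files["fragments"] = out / "fragments.bed"
    fragmentio.write_fragments_bed(frags, files["fragments"])

    lengths = fragmentio.length_histogram(frags)
    files["length_histogram"] = out / "length_histogram.tsv"
    lengths.histogram.write_tsv(files["length_histogram"])
    summary["n_fragments"] = len(frags)
    summary["major_mean_length"] = lengths.major_mean
    summary["minor_mean_length"] = lengths.minor_mean

    mono, di = fragmentio.mono_di_split(frags)

    if config.do_phasogram:
        starts = phasogram.read_starts_from_fragments(mono)
        hist = phasogram.compute_phasogram(starts, config.pile_order,
                                           config.max_distance)
        files["phasogram"] = out / "phasogram.tsv"
        hist.write_tsv(files["phasogram"])
        spacing = phasogram.estimate_spacing(hist)
        summary["phasogram_spacing"] = spacing.spacing
        summary["phasogram_fit_r"] = spacing.r
        logger.info("phasogram spacing %.1f bp (r=%.3f)", spacing.spacing, spacing.r)

    peaks = []
    if config.do_peaks:
        trimmed, n_short = fragmentio.trim_fragments(mono)
        peaks = peakcall.call_peaks(trimmed, nmap.region,
                                    bandwidth=config.bandwidth,
                                    threshold=config.threshold)
        files["peaks"] = out / "peaks.bed"
        peakcall.peaks_to_bed(peaks).to_csv(files["peaks"], sep="\t",
                                            header=False, index=False)
        region_df = pd.DataFrame({"chrom": [nmap.chrom],
                                  "start": [nmap.region.start],
                                  "end": [nmap.region.end]})
        summary["n_peaks"] = len(peaks)
        summary["n_untrimmable"] = n_short
        summary["occupancy"] = peakcall.occupancy_fraction(peaks, region_df)
        if len(peaks) >= 2:
            _, sp = phasogram.peak_distance_histogram(
                [p.dyad for p in peaks], config.max_distance)
            summary["peak_histogram_spacing"] = sp.spacing
        di_trimmed, _ = fragmentio.trim_fragments(di)
        if len(di_trimmed):
            di_peaks = peakcall.call_peaks(di_trimmed, nmap.region,
                                           bandwidth=config.bandwidth,
                                           threshold=config.threshold)
            summary["n_di_peaks"] = len(di_peaks)
            if len(di_peaks) >= 2:
                _, sp = phasogram.peak_distance_histogram(
                    [p.dyad for p in di_peaks], config.max_distance)
                summary["di_peak_histogram_spacing"] = sp.spacing
        logger.info("called %d peaks, occupancy %.3f",
                    len(peaks), summary["occupancy"])

    if config.do_marks and peaks:
        mark_df = synthetic_data.generate_mark_intervals(
            nmap, config.mark_overlap_fraction, seed=config.seed + 17,
            mark_width=config.mark_width)
        files["marks"] = out / "marks.bed"
        mark_df.to_csv(files["marks"], sep="\t", header=False, index=False)
        region_df = pd.DataFrame({"chrom": [nmap.chrom],
                                  "start": [nmap.region.start],
                                  "end": [nmap.region.end]})
        inside = [p for p in peaks
                  if p.start >= nmap.region.start and p.end <= nmap.region.end]
        assoc = marks.mark_association_test(
            inside, mark_df, region_df,
            n_permutations=config.n_permutations, seed=config.seed + 29)
        summary["mark_observed_overlap"] = assoc.observed
        summary["mark_null_mean"] = assoc.null_mean
        summary["mark_p_value"] = assoc.p_value

    if config.do_tss:
        panel_spec = synthetic_data.GenePanelSpec(**config.panel)
        genes, panel_frags = synthetic_data.generate_tss_panel(panel_spec, sim_cfg)
        files["genes"] = out / "genes.tsv"
        genes.to_csv(files["genes"], sep="\t", index=False)
        files["panel_fragments"] = out / "panel_fragments.bed"
        fragmentio.write_fragments_bed(panel_frags, files["panel_fragments"])
        profiles = tss_analysis.extract_profiles(panel_frags, genes,
                                                 window=config.window)
        scores = tss_analysis.score_panel(profiles)
        files["scores"] = out / "resolution_scores.tsv"
        scores.to_csv(files["scores"], sep="\t", index=False)
        cmp = tss_analysis.compare_scores(scores)
        summary["score_mean_tissue_specific"] = cmp.mean_specific
        summary["score_mean_housekeeping"] = cmp.mean_housekeeping
        summary["score_p_value"] = cmp.p_value
        grid = tss_analysis.ratio_grid(profiles, step=config.step)
        files["ratio_grid_t"] = out / "ratio_grid_t.tsv"
        files["ratio_grid_mask"] = out / "ratio_grid_mask.tsv"
        np.savetxt(files["ratio_grid_t"], grid.t, delimiter="\t", fmt="%.6g")
        np.savetxt(files["ratio_grid_mask"], grid.mask.astype(int),
                   delimiter="\t", fmt="%d")
        summary["grid_significant_fraction"] = grid.significant_fraction
        summary["grid_n_areas"] = len(grid.areas)
        logger.info("TSS scores: specific %.2f vs housekeeping %.2f (p=%.3g)",
                    cmp.mean_specific, cmp.mean_housekeeping, cmp.p_value)

    manifest = {
        "config": dataclasses.asdict(config),
        "files": {name: {"path": str(path), "sha256": _sha256(path)}
                  for name, path in files.items()},
        "summary": summary,
        "elapsed_s": round(time.time() - t0, 2),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
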