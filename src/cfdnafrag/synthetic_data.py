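"""Synthetic cfDNA fragment generator with nucleosome-guided structure.

Cell-free DNA in plasma is released mainly by apoptosis: endonucleases cut
the linker DNA between nucleosomes, so fragment lengths cluster around the
mononucleosome (~165 bp, core + H1 + some linker) and dinucleosome
(~308 bp) sizes, and fragment midpoints phase to nucleosome dyads with a
repeat length of ~193 bp (147 bp core + 46 bp linker).  This module draws
fragments from exactly that statistical structure — a length mixture plus
dyad-phased midpoints — so that every downstream analysis stage (phasogram,
peak calling, mark association, TSS scoring) can be exercised and validated
against a known ground truth without any sequencing data.

The generator is a distributional emulator, not a mechanistic cleavage
model: it reproduces the reported facts (modes, repeat length, the ~10 bp
sub-periodicity "comb") directly, which is what makes them testable.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from .regions import Region, complement_within

FOOTPRINT_HALF = 73  # nucleosome footprint is dyad ± 73 bp (147 bp inclusive)

FRAGMENT_COLUMNS = ["chrom", "start", "end", "length"]


@dataclass
class SimulationConfig:
    """All knobs of the fragment generator.

    Defaults are the cohort calibration used throughout: a 193 bp
    nucleosome repeat (147 bp core + 46 bp linker), mononucleosome
    fragments at 165 ± 20 bp forming 85% of the library, dinucleosome
    fragments at 308 ± 25 bp, and 20 bp of positional jitter between a
    fragment midpoint and its nucleosome dyad.  The optional "comb" adds
    discrete minor length modes (152, 143, ... 102 bp) below the major
    peak, emulating the ~10 bp periodicity of intra-nucleosomal cleavage;
    it is off by default and carries 15% of the mononucleosome mass when
    enabled, with geometrically decaying weights.
    """

    seed: int
    region_length: int = 1_000_000
    nucleosome_repeat: int = 193
    core_size: int = 147
    linker_size: int = 46
    mono_mode: float = 165.0
    mono_sd: float = 20.0
    di_mode: float = 308.0
    di_sd: float = 25.0
    mono_fraction: float = 0.85
    comb_enabled: bool = False
    comb_modes: tuple[int, ...] = (152, 143, 133, 122, 112, 102)
    comb_ratio: float = 0.7
    comb_mass: float = 0.15
    dyad_jitter_sd: float = 20.0
    n_fragments: int = 200_000
    gc_bias_strength: float = 0.0
    chrom: str = "sim"

    def __post_init__(self) -> None:
        if self.nucleosome_repeat != self.core_size + self.linker_size:
            raise ValueError("nucleosome_repeat must equal core_size + linker_size")
        if not 0.0 <= self.mono_fraction <= 1.0:
            raise ValueError("mono_fraction must lie in [0, 1]")
        for name in ("region_length", "nucleosome_repeat", "core_size", "linker_size",
                     "mono_mode", "di_mode"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mono_sd < 0 or self.di_sd < 0 or self.dyad_jitter_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        modes = tuple(self.comb_modes)
        if any(b >= a for a, b in zip(modes, modes[1:])):
            raise ValueError("comb_modes must be strictly decreasing")
        if any(m >= self.mono_mode for m in modes):
            raise ValueError("comb_modes must all lie below mono_mode")
        if not 0.0 <= self.comb_mass < 1.0:
            raise ValueError("comb_mass must lie in [0, 1)")
        if self.gc_bias_strength < 0:
            raise ValueError("gc_bias_strength must be >= 0")

    @property
    def comb_weights(self) -> np.ndarray:
        """Geometric weights over ``comb_modes`` summing to ``comb_mass``."""
        raw = self.comb_ratio ** np.arange(len(self.comb_modes))
        return self.comb_mass * raw / raw.sum()


@dataclass
class NucleosomeMap:
    """Ground-truth dyad positions within one simulated region."""

    chrom: str
    dyads: np.ndarray
    region: Region

    def __post_init__(self) -> None:
        self.dyads = np.asarray(self.dyads, dtype=np.int64)
        if np.any(np.diff(self.dyads) <= 0):
            raise ValueError("dyads must be strictly increasing")
        if self.dyads.size and (
            self.dyads[0] < self.region.start or self.dyads[-1] >= self.region.end
        ):
            raise ValueError("dyads must lie inside the region")

    def __len__(self) -> int:
        return self.dyads.size


@dataclass
class GenePanelSpec:
    """Composition of the synthetic TSS gene panel.

    Tissue-specific genes model loci silenced in most cfDNA source
    tissues: their downstream nucleosome arrays are sharply phased
    (``phased_jitter_sd``).  Housekeeping genes model ubiquitously
    expressed loci: fuzzy positioning (``fuzzy_jitter_sd``) plus a
    coverage depletion of the +1 nucleosome (``depletion_depth``).
    Panel sizes default to the 134 / 246 split of the gene sets the
    analysis is designed around.
    """

    n_specific: int = 134
    n_housekeeping: int = 246
    exon_window: int = 700
    phased_jitter_sd: float = 10.0
    fuzzy_jitter_sd: float = 45.0
    depletion_depth: float = 0.4

    def __post_init__(self) -> None:
        if self.n_specific < 0 or self.n_housekeeping < 0:
            raise ValueError("gene counts must be non-negative")
        if self.n_specific + self.n_housekeeping == 0:
            raise ValueError("panel must contain at least one gene")
        if self.phased_jitter_sd > self.fuzzy_jitter_sd:
            raise ValueError("phased_jitter_sd must not exceed fuzzy_jitter_sd")
        if not 0.0 <= self.depletion_depth <= 1.0:
            raise ValueError("depletion_depth must lie in [0, 1]")


def generate_nucleosome_map(config: SimulationConfig, *, phase: int | None = None) -> NucleosomeMap:
    """Place dyads at repeat-length spacing from a random phase.

    The number of dyads is ``floor((region_length - phase) / repeat)``;
    with ``phase`` given explicitly the map is fully deterministic, and
    with ``phase=None`` it is drawn uniformly from ``[0, repeat)`` using
    the config seed.
    """
    repeat = config.nucleosome_repeat
    if config.region_length < 2 * repeat:
        raise ValueError(
            f"region_length={config.region_length} too small: "
            f"need at least two repeats ({2 * repeat} bp)"
        )
    if phase is None:
        rng = np.random.default_rng([config.seed, 0])
        phase = int(rng.integers(0, repeat))
    n = (config.region_length - phase) // repeat
    dyads = phase + repeat * np.arange(n, dtype=np.int64)
    return NucleosomeMap(config.chrom, dyads, Region(config.chrom, 0, config.region_length))


def _draw_lengths(rng: np.random.Generator, n_mono: int, n_di: int,
                  config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Draw mono and di fragment lengths (floats, unrounded)."""
    mono = rng.normal(config.mono_mode, config.mono_sd, n_mono)
    if config.comb_enabled and n_mono:
        w = config.comb_weights
        is_comb = rng.random(n_mono) < config.comb_mass
        n_comb = int(is_comb.sum())
        modes = rng.choice(np.asarray(config.comb_modes, dtype=float),
                           size=n_comb, p=w / w.sum())
        mono[is_comb] = modes + rng.integers(-1, 2, n_comb)
    di = rng.normal(config.di_mode, config.di_sd, n_di)
    return mono, di


def generate_fragments(nmap: NucleosomeMap, config: SimulationConfig,
                       gc_track: np.ndarray | None = None) -> pd.DataFrame:
    """Draw cfDNA fragments phased to the nucleosome map.

    Each fragment is mononucleosomal with probability ``mono_fraction``
    (length from the comb-plus-normal mixture, midpoint at a uniformly
    chosen dyad) or dinucleosomal otherwise (length ~ N(di_mode, di_sd),
    midpoint between two adjacent dyads).  Midpoints receive
    N(0, dyad_jitter_sd) jitter and are rounded to the nearest integer
    (ties to even); lengths are rounded and floored at 50 bp; fragments
    are clipped to the region.

    With ``gc_bias_strength > 0`` and a per-base GC track, fragments are
    importance-resampled with weight exp(strength · (GC_mid − 0.5)),
    emulating capture/PCR preference for GC-rich template.

    Returns a BED-like table with columns chrom, start, end, length.
    """
    if len(nmap) == 0:
        raise ValueError("nucleosome map is empty")
    rng = np.random.default_rng([config.seed, 1])
    n = config.n_fragments
    is_mono = rng.random(n) < config.mono_fraction
    n_mono = int(is_mono.sum())
    n_di = n - n_mono

    mono_len, di_len = _draw_lengths(rng, n_mono, n_di, config)
    lengths = np.empty(n)
    lengths[is_mono] = mono_len
    lengths[~is_mono] = di_len

    dyads = nmap.dyads
    mid = np.empty(n)
    mid[is_mono] = dyads[rng.integers(0, dyads.size, n_mono)]
    if n_di:
        if dyads.size < 2:
            raise ValueError("dinucleosome fragments need at least two dyads")
        g = rng.integers(0, dyads.size - 1, n_di)
        mid[~is_mono] = (dyads[g] + dyads[g + 1]) / 2.0
    mid = np.rint(mid + rng.normal(0.0, config.dyad_jitter_sd, n))

    lengths = np.maximum(np.rint(lengths), 50).astype(np.int64)
    start = mid.astype(np.int64) - lengths // 2
    end = start + lengths
    start = np.clip(start, nmap.region.start, nmap.region.end)
    end = np.clip(end, nmap.region.start, nmap.region.end)
    keep = end > start
    frags = pd.DataFrame(
        {
            "chrom": nmap.chrom,
            "start": start[keep],
            "end": end[keep],
        }
    )
    frags["length"] = frags["end"] - frags["start"]

    if config.gc_bias_strength > 0 and gc_track is not None:
        gc_track = np.asarray(gc_track, dtype=float)
        mids = ((frags["start"] + frags["end"]) // 2).to_numpy()
        w = np.exp(config.gc_bias_strength * (gc_track[mids] - 0.5))
        pick = rng.choice(len(frags), size=len(frags), replace=True, p=w / w.sum())
        frags = frags.iloc[np.sort(pick)].reset_index(drop=True)
    return frags


# --- TSS gene panel -------------------------------------------------------

_SLOT = 5000           # one gene per 5 kb slot on the panel contig
_PLUS_TSS_OFFSET = 1500
_MINUS_TSS_OFFSET = 3500
_FIRST_DYAD = 100      # +1 dyad sits 100 bp downstream of the TSS
_N_ARRAY = 3           # +1, +2, +3 nucleosomes
_ARRAY_FUZZ = (1.0, 1.25, 1.5)  # jitter inflation with array index


def generate_tss_panel(spec: GenePanelSpec, config: SimulationConfig
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthesize a TSS gene panel and its cfDNA fragments.

    Each gene occupies its own 5 kb slot on one synthetic contig and
    carries a downstream nucleosome array (+1 at 100 bp past the TSS,
    then repeat-length steps).  Tissue-specific genes get sharply phased
    arrays; housekeeping genes get fuzzy arrays with a depleted +1.
    ``config.n_fragments`` is split evenly across genes.

    Returns ``(gene_table, fragments)``: the gene table has columns
    gene_id, chrom, tss, strand, label.
    """
    rng = np.random.default_rng([config.seed, 2])
    n_genes = spec.n_specific + spec.n_housekeeping
    labels = ["tissue_specific"] * spec.n_specific + ["housekeeping"] * spec.n_housekeeping
    chrom = "panel"
    repeat = config.nucleosome_repeat
    n_per_gene = max(config.n_fragments // n_genes, 1)

    genes = []
    frag_parts = []
    for g, label in enumerate(labels):
        slot0 = g * _SLOT
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            tss = slot0 + _PLUS_TSS_OFFSET
            array = tss + _FIRST_DYAD + repeat * np.arange(_N_ARRAY)
        else:
            tss = slot0 + _MINUS_TSS_OFFSET
            array = tss - _FIRST_DYAD - repeat * np.arange(_N_ARRAY)
        genes.append((f"gene_{g:04d}", chrom, int(tss), strand, label))

        if label == "tissue_specific":
            jitter_sd = spec.phased_jitter_sd
            weights = np.ones(_N_ARRAY)
        else:
            jitter_sd = spec.fuzzy_jitter_sd
            weights = np.ones(_N_ARRAY)
            weights[0] = 1.0 - spec.depletion_depth
        weights = weights / weights.sum()

        is_mono = rng.random(n_per_gene) < config.mono_fraction
        n_mono = int(is_mono.sum())
        n_di = n_per_gene - n_mono
        mono_len, di_len = _draw_lengths(rng, n_mono, n_di, config)
        lengths = np.empty(n_per_gene)
        lengths[is_mono] = mono_len
        lengths[~is_mono] = di_len

        idx_mono = rng.choice(_N_ARRAY, size=n_mono, p=weights)
        mid = np.empty(n_per_gene)
        mid[is_mono] = array[idx_mono]
        if n_di:
            # dinucleosome midpoint between an adjacent dyad pair
            pair_w = (weights[:-1] + weights[1:])
            pair_w = pair_w / pair_w.sum()
            idx_di = rng.choice(_N_ARRAY - 1, size=n_di, p=pair_w)
            mid[~is_mono] = (array[idx_di] + array[idx_di + 1]) / 2.0

        fuzz = np.empty(n_per_gene)
        fuzz[is_mono] = jitter_sd * np.asarray(_ARRAY_FUZZ)[idx_mono]
        if n_di:
            fuzz[~is_mono] = jitter_sd * np.asarray(_ARRAY_FUZZ)[idx_di]
        mid = np.rint(mid + rng.normal(0.0, 1.0, n_per_gene) * fuzz)

        lengths = np.maximum(np.rint(lengths), 50).astype(np.int64)
        start = mid.astype(np.int64) - lengths // 2
        end = start + lengths
        start = np.clip(start, slot0, slot0 + _SLOT)
        end = np.clip(end, slot0, slot0 + _SLOT)
        keep = end > start
        frag_parts.append(pd.DataFrame({"chrom": chrom, "start": start[keep], "end": end[keep]}))

    gene_table = pd.DataFrame(genes, columns=["gene_id", "chrom", "tss", "strand", "label"])
    frags = pd.concat(frag_parts, ignore_index=True)
    frags["length"] = frags["end"] - frags["start"]
    return gene_table, frags


def generate_mark_intervals(nmap: NucleosomeMap, overlap_fraction: float, seed: int,
                            *, mark_width: int = 150, name: str = "mark") -> pd.DataFrame:
    """Emit mark intervals covering a chosen fraction of dyad footprints.

    Each dyad's 147 bp footprint is covered with probability
    ``overlap_fraction`` by a mark centred on the dyad; the remaining
    marks are placed uniformly in sequence not covered by any footprint
    (linkers and flanks), shrunk to fit, so uncovered footprints stay
    mark-free.  Returns a BED4-like table (chrom, start, end, name).
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    dyads = nmap.dyads
    covered = rng.random(dyads.size) < overlap_fraction
    half = mark_width // 2

    starts = list(np.maximum(dyads[covered] - half, nmap.region.start))
    ends = list(np.minimum(dyads[covered] + mark_width - half, nmap.region.end))

    n_rest = int((~covered).sum())
    if n_rest:
        fp_s = dyads - FOOTPRINT_HALF
        fp_e = dyads + FOOTPRINT_HALF + 1
        gap_s, gap_e = complement_within(fp_s, fp_e, nmap.region.start, nmap.region.end)
        gap_len = gap_e - gap_s
        usable = gap_len >= 2
        gap_s, gap_e, gap_len = gap_s[usable], gap_e[usable], gap_len[usable]
        if gap_len.size:
            p = gap_len / gap_len.sum()
            pick = rng.choice(gap_len.size, size=n_rest, p=p)
            width = np.minimum(mark_width, gap_len[pick] - 1)
            off = np.floor(rng.random(n_rest) * (gap_len[pick] - width)).astype(np.int64)
            starts.extend(gap_s[pick] + off)
            ends.extend(gap_s[pick] + off + width)

    marks = pd.DataFrame({"chrom": nmap.chrom,
                          "start": np.asarray(starts, dtype=np.int64),
                          "end": np.asarray(ends, dtype=np.int64)})
    marks = marks.sort_values(["start", "end"], kind="stable").reset_index(drop=True)
    marks["name"] = [f"{name}_{i}" for i in range(len(marks))]
    return marks


def generate_gc_track(config: SimulationConfig, nmap: NucleosomeMap | None = None,
                      *, base_gc: float = 0.40, peak_gc: float = 0.55,
                      width: float = 50.0) -> np.ndarray:
    """Per-base GC fraction with optional enrichment around dyads.

    A smooth helper for exercising the GC-bias knob and gc_profile: the
    track sits at ``base_gc`` and, when a map is supplied, rises to
    ``peak_gc`` in Gaussian bumps (sd ``width``) centred on the dyads.
    """
    gc = np.full(config.region_length, base_gc)
    if nmap is not None:
        x = np.arange(config.region_length, dtype=float)
        for d in nmap.dyads:
            lo = max(0, int(d - 4 * width))
            hi = min(config.region_length, int(d + 4 * width))
            gc[lo:hi] += (peak_gc - base_gc) * np.exp(
                -0.5 * ((x[lo:hi] - d) / width) ** 2
            )
    return np.clip(gc, 0.0, 1.0)
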