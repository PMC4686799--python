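"""TSS profiles, low-pass filtering, resolution score, ratio grid."""

import numpy as np
import pandas as pd
import pytest

from cfdnafrag import (
    GenePanelSpec,
    SimulationConfig,
    TssProfile,
    average_profile,
    compare_scores,
    extract_profiles,
    generate_tss_panel,
    lowpass,
    ratio_grid,
    resolution_score,
    score_panel,
)


def profile(values, label="tissue_specific", gene_id="g"):
    return TssProfile(gene_id, label, np.asarray(values, dtype=float))


class TestAverageProfile:
    def test_single_gene_is_identity(self):
        p = profile(np.arange(700))
        np.testing.assert_array_equal(average_profile([p], "tissue_specific"),
                                      p.coverage)

    def test_mean_of_constant_profiles(self):
        ps = [profile(np.full(700, 2.0)), profile(np.full(700, 4.0))]
        np.testing.assert_allclose(average_profile(ps, "tissue_specific"),
                                   np.full(700, 3.0))

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="label"):
            average_profile([profile(np.ones(700))], "housekeeping")

    def test_phased_panel_maxima_near_array_positions(self):
        spec = GenePanelSpec(n_specific=40, n_housekeeping=2, phased_jitter_sd=10)
        genes, frags = generate_tss_panel(spec, SimulationConfig(seed=44, n_fragments=40_000))
        mean = average_profile(extract_profiles(frags, genes), "tissue_specific")
        # +1 dyad at offset 100, +2 at 293: the class mean must peak nearby
        assert abs(int(np.argmax(mean[:200])) - 100) <= 30
        assert mean[100] > 1.5 * mean[196]  # trough between +1 and +2


class TestLowpass:
    def test_commensurate_passband_component_unchanged(self):
        t = np.arange(1000)
        x = np.cos(2 * np.pi * 5 * t / 1000)  # 0.005 cycles/base < 0.07
        assert np.max(np.abs(lowpass(x, 0.07) - x)) < 1e-9

    def test_stopband_component_reduced_to_mean(self):
        t = np.arange(1000)
        x = 2.0 + np.cos(2 * np.pi * 80 * t / 1000)  # 0.08 cycles/base > 0.07
        assert np.max(np.abs(lowpass(x, 0.07) - 2.0)) < 1e-9

    def test_linearity_recovers_slow_component(self):
        t = np.arange(1000)
        slow = np.cos(2 * np.pi * 5 * t / 1000)
        fast = np.cos(2 * np.pi * 80 * t / 1000)
        assert np.max(np.abs(lowpass(slow + fast, 0.07) - slow)) < 1e-9

    def test_invalid_cutoff(self):
        with pytest.raises(ValueError, match="cutoff"):
            lowpass(np.ones(100), 0.0)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError, match="short"):
            lowpass(np.ones(8), 0.07)


class TestResolutionScore:
    def test_flat_profile_scores_exactly_one(self):
        r = resolution_score(profile(np.full(700, 7.0)))
        assert r.score == 1.0
        assert not r.found

    def test_nucleosome_period_cosine_scores_two(self):
        x = 3 + np.cos(2 * np.pi * np.arange(700) / 193)
        r = resolution_score(profile(x))
        assert r.found
        assert r.score == pytest.approx(2.0, abs=0.1)
        assert abs(r.peak - 193) < 15 and abs(r.trough - 290) < 15

    def test_scale_invariance(self):
        x = 3 + np.cos(2 * np.pi * np.arange(700) / 193)
        a = resolution_score(profile(x))
        b = resolution_score(profile(100.0 * x))
        assert a.score == pytest.approx(b.score, rel=1e-12)

    def test_short_profile_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            resolution_score(profile(np.ones(300)))

    def test_trough_beyond_search_window_scores_one(self):
        # peak near offset 400 but the subsequent minimum falls past 500,
        # outside the restricted search window
        x = 3 + np.cos(2 * np.pi * (np.arange(700) - 400) / 800)
        r = resolution_score(profile(x))
        assert r.score == 1.0 and not r.found


class TestCompareScores:
    def test_identical_multisets_not_separated(self):
        scores = pd.DataFrame({
            "gene_id": list("abcdef"),
            "label": ["tissue_specific"] * 3 + ["housekeeping"] * 3,
            "score": [2.0, 3.0, 4.0, 2.0, 3.0, 4.0],
        })
        cmp = compare_scores(scores)
        assert cmp.mean_specific == cmp.mean_housekeeping
        assert cmp.p_value == pytest.approx(1.0)

    def test_nan_scores_excluded_and_counted(self):
        scores = pd.DataFrame({
            "gene_id": list("abcdefg"),
            "label": ["tissue_specific"] * 4 + ["housekeeping"] * 3,
            "score": [2.0, 3.0, 4.0, np.nan, 1.0, 1.5, 2.0],
        })
        cmp = compare_scores(scores)
        assert cmp.n_excluded == 1

    def test_insufficient_class_rejected(self):
        scores = pd.DataFrame({
            "gene_id": list("abc"),
            "label": ["tissue_specific", "tissue_specific", "housekeeping"],
            "score": [2.0, 3.0, 4.0],
        })
        with pytest.raises(ValueError, match="two usable"):
            compare_scores(scores)

    def test_default_panel_separates_classes(self):
        spec = GenePanelSpec(n_specific=25, n_housekeeping=25)
        genes, frags = generate_tss_panel(spec, SimulationConfig(seed=45, n_fragments=25_000))
        cmp = compare_scores(score_panel(extract_profiles(frags, genes)))
        # phased arrays resolve the first peak; fuzzy depleted arrays do not
        assert cmp.mean_specific > cmp.mean_housekeeping
        assert cmp.p_value < 0.05


class TestRatioGrid:
    @staticmethod
    def small_panel(seed, null=False):
        kwargs = dict(fuzzy_jitter_sd=10, depletion_depth=0.0) if null else {}
        spec = GenePanelSpec(n_specific=20, n_housekeeping=20,
                             phased_jitter_sd=10, **kwargs)
        genes, frags = generate_tss_panel(spec, SimulationConfig(seed=seed,
                                                                 n_fragments=16_000))
        return extract_profiles(frags, genes)

    def test_diagonal_never_significant(self):
        grid = ratio_grid(self.small_panel(50))
        assert np.all(np.diag(grid.t) == 0.0)
        assert np.all(np.diag(grid.p) == 1.0)
        assert not np.any(np.diag(grid.mask))

    def test_grid_geometry(self):
        grid = ratio_grid(self.small_panel(51), step=10)
        assert grid.t.shape == (70, 70)
        np.testing.assert_array_equal(grid.positions, np.arange(0, 700, 10))

    def test_effect_panel_shows_significant_area_at_first_peak(self):
        grid = ratio_grid(self.small_panel(52))
        assert grid.areas, "no significant areas detected"
        top = grid.areas[0]
        # the +1 peak (offset ~100) and its trough (~196) must fall in the
        # top area's position span
        rows = grid.positions[top["rows"]]
        cols = grid.positions[top["cols"]]
        assert rows.min() <= 100 <= rows.max() or cols.min() <= 100 <= cols.max()
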