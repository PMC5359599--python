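"""Generator contracts: layouts, ground truth, rendering, summary path."""

import numpy as np
import pytest
from skimage import measure

from lipidscreen import (
    SimulationConfig,
    generate_plate_layout,
    render_well_image,
    simulate_summary_plate,
    simulate_well_truth,
)
from lipidscreen.models import (
    CHANNEL_LIPID,
    CHANNEL_NUCLEAR,
    ROLE_COMPOUND,
    ROLE_EMPTY,
    ROLE_NEGATIVE,
    ROLE_POSITIVE,
)

from conftest import make_config


class TestLayout:
    def test_role_counts_on_full_plate(self):
        layout = generate_plate_layout(320, 16, seed=7)
        counts = {role: sum(w.role == role for w in layout.wells)
                  for role in (ROLE_COMPOUND, ROLE_NEGATIVE, ROLE_POSITIVE, ROLE_EMPTY)}
        assert counts == {ROLE_COMPOUND: 320, ROLE_NEGATIVE: 16, ROLE_POSITIVE: 16, ROLE_EMPTY: 32}
        assert len(layout.wells) == 384

    def test_deterministic_for_fixed_seed(self):
        a = generate_plate_layout(100, 8, seed=42)
        b = generate_plate_layout(100, 8, seed=42)
        assert a == b
        c = generate_plate_layout(100, 8, seed=43)
        assert a != c

    @pytest.mark.parametrize(
        "n_compounds,controls,match",
        [(400, 0, "below minimum"), (400, 2, "below minimum"), (380, 4, "cannot place")],
    )
    def test_rejects_invalid_designs(self, n_compounds, controls, match):
        with pytest.raises(ValueError, match=match):
            generate_plate_layout(n_compounds, controls, seed=1)

    def test_compound_ids_unique_and_complete(self):
        layout = generate_plate_layout(50, 4, seed=3)
        cids = [w.compound_id for w in layout.wells if w.role == ROLE_COMPOUND]
        assert len(set(cids)) == 50
        assert all(w.compound_id is None for w in layout.wells if w.role != ROLE_COMPOUND)


class TestWellTruth:
    def test_planted_hit_gets_shifted_responder_fraction(self, small_layout):
        cid = next(w.compound_id for w in small_layout.wells if w.role == ROLE_COMPOUND)
        cfg = make_config(hit_effect=0.5, baseline_percent_positive=5.0, planted_hits=(cid,))
        truths = simulate_well_truth(small_layout, cfg)
        hit_well = next(w for w in small_layout.wells if w.compound_id == cid)
        assert truths[hit_well.label].responder_fraction == pytest.approx(0.55)
        neg = small_layout.wells_by_role(ROLE_NEGATIVE)[0]
        assert truths[neg.label].responder_fraction == pytest.approx(0.05)
        pos = small_layout.wells_by_role(ROLE_POSITIVE)[0]
        assert truths[pos.label].responder_fraction == pytest.approx(0.6)

    def test_death_reduces_survivors_deterministically(self, small_layout):
        cid = next(w.compound_id for w in small_layout.wells if w.role == ROLE_COMPOUND)
        cfg = make_config(cells_per_well=300, death_by_compound={cid: 0.8})
        truths = simulate_well_truth(small_layout, cfg)
        well = next(w for w in small_layout.wells if w.compound_id == cid)
        assert truths[well.label].n_surviving == 60

    def test_cell_spacing_respects_exclusion_radius(self, small_layout):
        cfg = make_config()
        truths = simulate_well_truth(small_layout, cfg)
        truth = next(iter(truths.values()))
        xy = np.array([(c.x, c.y) for c in truth.cells])
        d2 = np.sum((xy[None, :, :] - xy[:, None, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        assert np.sqrt(d2.min()) >= 2 * cfg.nucleus_radius_px

    def test_overcrowded_well_raises(self, small_layout):
        cfg = make_config(cells_per_well=5000, image_size=(256, 256))
        with pytest.raises(RuntimeError, match="lower cells_per_well"):
            simulate_well_truth(small_layout, cfg)

    def test_responder_draws_follow_binomial_law(self, small_layout):
        """Monte-Carlo: mean responder fraction over many seeds matches p_true."""
        p, n = 0.05, 300
        fracs = []
        for seed in range(20):
            cfg = make_config(seed=seed, baseline_percent_positive=100 * p, cells_per_well=n)
            truths = simulate_well_truth(small_layout, cfg)
            for w in small_layout.wells:
                if w.role in (ROLE_COMPOUND, ROLE_NEGATIVE):
                    t = truths[w.label]
                    fracs.append(t.n_responders / t.n_surviving)
        se = np.sqrt(p * (1 - p) / n / len(fracs))
        assert abs(np.mean(fracs) - p) < 3 * se

    def test_conservation(self, small_layout):
        cfg = make_config()
        truths = simulate_well_truth(small_layout, cfg)
        for t in truths.values():
            assert t.n_responders <= t.n_surviving <= t.n_cells_seeded


class TestRendering:
    def test_empty_noise_free_well_is_flat_background(self, small_layout):
        from lipidscreen.models import WellTruth

        cfg = make_config()
        truth = WellTruth("A01", 0, 0.0, 0.0, [])
        img = render_well_image(truth, cfg)
        for ch in img.channels.values():
            assert np.all(ch == cfg.background_level)

    def test_bright_region_count_matches_cells(self, small_layout):
        cfg = make_config(cells_per_well=10)
        truths = simulate_well_truth(small_layout, cfg)
        truth = next(iter(truths.values()))
        img = render_well_image(truth, cfg)
        binary = img.channels[CHANNEL_NUCLEAR] > cfg.background_level
        n_regions = measure.label(binary, connectivity=2).max()
        assert n_regions == truth.n_surviving == 10

    def test_rendering_is_deterministic(self, small_layout):
        cfg = make_config(noise_sd=50.0)
        truths = simulate_well_truth(small_layout, cfg)
        truth = next(iter(truths.values()))
        a = render_well_image(truth, cfg)
        b = render_well_image(truth, cfg)
        for key in (CHANNEL_NUCLEAR, CHANNEL_LIPID):
            assert np.array_equal(a.channels[key], b.channels[key])

    def test_pixels_within_16bit_range(self, small_layout):
        cfg = make_config(noise_sd=2000.0, droplet_intensity=60000.0)
        truths = simulate_well_truth(small_layout, cfg)
        img = render_well_image(next(iter(truths.values())), cfg)
        for ch in img.channels.values():
            assert ch.dtype == np.uint16
            assert ch.min() >= 0 and ch.max() <= 65535


class TestSummaryPath:
    def test_degenerate_probabilities(self, small_layout):
        cfg = make_config(positive_control_responder_fraction=1.0,
                          baseline_percent_positive=0.0)
        quants = {q.well_label: q for q in simulate_summary_plate(small_layout, cfg)}
        for w in small_layout.wells_by_role(ROLE_POSITIVE):
            assert quants[w.label].percent_positive == 100.0
        for w in small_layout.wells_by_role(ROLE_NEGATIVE):
            q = quants[w.label]
            assert q.percent_positive == 0.0 and q.total_cells == cfg.cells_per_well

    def test_summary_counts_match_binomial_moments(self, small_layout):
        """Mean and variance of positive counts across >=1000 wells match Binomial(n, p)."""
        p, n = 0.05, 300
        counts = []
        for seed in range(60):
            cfg = make_config(seed=seed, baseline_percent_positive=100 * p, cells_per_well=n)
            counts.extend(
                q.positive_cells
                for q in simulate_summary_plate(small_layout, cfg)
                if q.role == ROLE_COMPOUND
            )
        counts = np.asarray(counts, dtype=float)
        assert counts.size >= 1000
        mean_se = np.sqrt(n * p * (1 - p) / counts.size)
        assert abs(counts.mean() - n * p) < 3 * mean_se
        # variance of a binomial sample variance, normal approximation
        var = n * p * (1 - p)
        var_se = var * np.sqrt(2.0 / (counts.size - 1))
        assert abs(counts.var(ddof=1) - var) < 4 * var_se

    def test_deterministic_per_seed(self, small_layout):
        cfg = make_config(noise_sd=50.0)
        a = simulate_summary_plate(small_layout, cfg)
        b = simulate_summary_plate(small_layout, cfg)
        assert a == b

    def test_dead_well_flagged(self, small_layout):
        cid = next(w.compound_id for w in small_layout.wells if w.role == ROLE_COMPOUND)
        cfg = make_config(death_by_compound={cid: 1.0})
        quants = {q.well_label: q for q in simulate_summary_plate(small_layout, cfg)}
        well = next(w for w in small_layout.wells if w.compound_id == cid)
        q = quants[well.label]
        assert q.total_cells == 0 and q.low_cell_flag and q.percent_positive == 0.0
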