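"""Contact eligibility rules, ψ variants, and the contact-counting engine."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cytograd as cg
from conftest import brute_force_contacts, small_config


class TestEligibility:
    def test_type1_strict_condition(self):
        assert cg.eligible_type1(2, 1, 4.0)
        assert not cg.eligible_type1(3, 1, 4.0)   # boundary is excluded
        assert not cg.eligible_type1(0, 0, 0.0)

    def test_type2_mirrors_type1(self):
        assert cg.eligible_type2(2, 1, 4.0)
        assert not cg.eligible_type2(5, 0, 4.0)

    @settings(max_examples=100, derandomize=True)
    @given(x_p=st.integers(0, 20), x_r=st.integers(0, 20),
           lam=st.floats(0.0, 30.0))
    def test_type1_type2_identical_algebra(self, x_p, x_r, lam):
        assert cg.eligible_type1(x_p, x_r, lam) == cg.eligible_type2(x_p, x_r, lam)

    def test_type3_regions(self):
        assert cg.classify_type3(5, 0, 3.0, 4.0) == "cyt-cyt"      # 4 <= 5 < 7
        assert cg.classify_type3(2, 0, 3.0, 4.0) == "body-contact"
        assert cg.classify_type3(8, 0, 3.0, 4.0) == "none"

    @settings(max_examples=100, derandomize=True)
    @given(x_p=st.integers(0, 12), x_r=st.integers(0, 12),
           lr=st.floats(0.0, 15.0), lp=st.floats(0.0, 15.0))
    def test_type3_partition_is_exhaustive(self, x_p, x_r, lr, lp):
        """Every configuration falls in exactly one of the three regions."""
        label = cg.classify_type3(x_p, x_r, lr, lp)
        sep = x_p + x_r
        if sep < min(lr, lp):
            assert label == "body-contact"
        elif sep < lr + lp:
            assert label == "cyt-cyt"
        else:
            assert label == "none"


class TestPsi:
    def test_constant_extremes(self, rng):
        assert all(cg.psi_constant(1.0, rng) == 1 for _ in range(20))
        assert all(cg.psi_constant(0.0, rng) == 0 for _ in range(20))

    def test_constant_mean(self, rng):
        draws = np.array([cg.psi_constant(0.5, rng) for _ in range(100_000)])
        assert abs(draws.mean() - 0.5) < 3 * 0.5 / math.sqrt(draws.size)

    def test_multiple_site_count(self, rng):
        assert cg.psi_multiple(1.0, 0.0, rng) == 1       # floor clamp
        assert cg.psi_multiple(1.0, 2.5, rng) == 3
        assert cg.psi_multiple(0.0, 10.0, rng) == 0

    def test_position_boundaries(self, rng):
        assert cg.psi_position(1.0, 0, 10.0, rng) == 1
        assert all(cg.psi_position(1.0, 10, 10.0, rng) == 0 for _ in range(10))

    def test_position_linear_attenuation(self, rng):
        draws = np.array([cg.psi_position(1.0, 5, 10.0, rng)
                          for _ in range(100_000)])
        assert abs(draws.mean() - 0.5) < 3 * 0.5 / math.sqrt(draws.size)


def _static_type1_config(n_p=10, n_r=8, lam_um=5.0, mu=1.0, n_replicates=1):
    return cg.validate_config({
        "tissue": {"phi": 1.0, "n_producing_rows": n_p, "n_receiving_rows": n_r},
        "cytonemes": {"length_stats_r": {"mean_um": lam_um, "sd_um": 0.0},
                      "length_stats_p": {"mean_um": lam_um, "sd_um": 0.0},
                      "n_cyt": 1, "static": True},
        "contact": {"contact_type": 1, "mu": mu, "tc_s": 0.0},
        "simulation": {"total_time_s": 5.0, "dt_s": 1.0,
                       "n_replicates": n_replicates, "seed": 5,
                       "half_life_s": math.inf},
    })


class TestCountContacts:
    def test_static_type1_reach_counts(self):
        """Fixed λ_r = 5 cells: N(x_r) = #{x_p : x_p + x_r < 5}."""
        field, _ = cg.run_replicate(_static_type1_config(), 0)
        expected = [max(0, min(10, math.ceil(5 - x_r))) for x_r in range(8)]
        assert field.total_per_row.tolist() == expected
        assert field.total_per_row[0] == 5
        assert field.total_per_row[4] == 1
        assert field.total_per_row[5] == 0

    def test_mu_zero_no_contacts(self):
        field, u = cg.run_replicate(_static_type1_config(mu=0.0), 0)
        assert field.counts.sum() == 0
        assert np.all(u == 0)

    def test_refractory_one_contact_per_episode(self):
        """Static eligibility never lapses → exactly one contact per pair."""
        cfg = _static_type1_config()
        long_cfg = cg.set_by_path(cfg, "simulation.total_time_s", 500.0)
        field, _ = cg.run_replicate(long_cfg, 0)
        assert field.total_per_row.tolist() == cg.run_replicate(cfg, 0)[0].total_per_row.tolist()

    def test_tc_persistence_threshold(self):
        """A triangular cytoneme contacts only rows whose eligibility lasts tc."""
        # λ = 6 cells at v = 0.1 μm/s, phi = 1: eligibility above row sep s
        # lasts 2*(6 - s)/0.1 seconds
        def cfg(tc):
            return cg.validate_config({
                "tissue": {"phi": 1.0, "n_producing_rows": 1,
                           "n_receiving_rows": 6},
                "cytonemes": {"length_stats_r": {"mean_um": 6.0, "sd_um": 0.0},
                              "length_stats_p": {"mean_um": 6.0, "sd_um": 0.0},
                              "n_cyt": 1, "fraction_triangular": 1.0,
                              "creation_gap_s": 1e6},
                "contact": {"contact_type": 1, "mu": 1.0, "tc_s": tc},
                "simulation": {"total_time_s": 120.0, "dt_s": 1.0,
                               "n_replicates": 1, "seed": 2,
                               "half_life_s": math.inf}})
        tight, _ = cg.run_replicate(cfg(50.0), 0)
        # row 4: eligibility window 2*(6-4)/0.1 = 40 s < 50 s -> no contact
        assert tight.total_per_row[4] == 0
        # row 3: 60 s window >= 50 s -> contact
        assert tight.total_per_row[3] == 1
        loose, _ = cg.run_replicate(cfg(0.0), 0)
        assert loose.total_per_row[4] == 1

    def test_psi_multiple_counts_overlap_sites(self):
        """Ψ(μ=1) yields floor(overlap)+1 contacts for a static type-3 pair."""
        cfg = cg.validate_config({
            "tissue": {"phi": 1.0, "n_producing_rows": 1, "n_receiving_rows": 1},
            "cytonemes": {"length_stats_r": {"mean_um": 3.0, "sd_um": 0.0},
                          "length_stats_p": {"mean_um": 4.0, "sd_um": 0.0},
                          "n_cyt": 1, "static": True},
            "contact": {"contact_type": 3, "mu": 1.0, "tc_s": 0.0,
                        "psi_variant": "multiple"},
            "simulation": {"total_time_s": 2.0, "dt_s": 1.0, "n_replicates": 1,
                           "seed": 1, "half_life_s": math.inf}})
        field, _ = cg.run_replicate(cfg, 0)
        # overlap = clamp(3+4-0, 0, 3) = 3 -> 4 sites
        assert field.total_per_row[0] == 4

    def test_position_psi_vanishes_beyond_range(self):
        cfg = cg.validate_config({
            "tissue": {"phi": 1.0, "n_producing_rows": 2, "n_receiving_rows": 6},
            "cytonemes": {"length_stats_r": {"mean_um": 8.0, "sd_um": 0.0},
                          "length_stats_p": {"mean_um": 8.0, "sd_um": 0.0},
                          "n_cyt": 1, "static": True},
            "contact": {"contact_type": 1, "mu": 1.0, "tc_s": 0.0,
                        "psi_variant": "position", "psi_range_max": 3.0},
            "simulation": {"total_time_s": 2.0, "dt_s": 1.0, "n_replicates": 1,
                           "seed": 1, "half_life_s": math.inf}})
        field, _ = cg.run_replicate(cfg, 0)
        assert field.total_per_row[0] > 0
        assert np.all(field.total_per_row[3:] == 0)

    def test_event_channels_recorded(self, rng):
        cfg = cg.validate_config({
            "tissue": {"phi": 1.0, "n_producing_rows": 3, "n_receiving_rows": 5},
            "cytonemes": {"length_stats_r": {"mean_um": 3.0, "sd_um": 0.0},
                          "length_stats_p": {"mean_um": 4.0, "sd_um": 0.0},
                          "n_cyt": 1, "static": True},
            "contact": {"contact_type": 3, "mu": 1.0, "tc_s": 0.0},
            "simulation": {"total_time_s": 2.0, "dt_s": 1.0, "n_replicates": 1,
                           "seed": 1, "half_life_s": math.inf}})
        recv = cg.generate_cycle_schedule(cfg.cytonemes, 2.0, rng,
                                          compartment="receiving", n_rows=5,
                                          phi=1.0)
        prod = cg.generate_cycle_schedule(cfg.cytonemes, 2.0, rng,
                                          compartment="producing", n_rows=3,
                                          phi=1.0)
        field = cg.count_contacts(recv, prod, cfg, rng, keep_events=True)
        channels = {(e.x_p + e.x_r): e.channel for e in field.events}
        for sep, channel in channels.items():
            assert channel == cg.classify_type3(sep, 0, 3.0, 4.0)


class TestOracleEquivalence:
    @pytest.mark.parametrize("contact_type", [1, 2, 3])
    @pytest.mark.parametrize("cwg", [True, False])
    def test_matches_brute_force_enumeration(self, contact_type, cwg):
        """Exact agreement with independent pair enumeration (μ=1, tc=0)."""
        for seed in range(4):
            cfg = cg.validate_config({
                "tissue": {"phi": 2.0, "n_producing_rows": 4,
                           "n_receiving_rows": 4},
                "cytonemes": {
                    "length_stats_r": {"mean_um": 9.0, "sd_um": 3.0},
                    "length_stats_p": {"mean_um": 7.0, "sd_um": 2.0},
                    # unequal velocities keep λ(t) off exact knife-edge ties
                    # between the separation and the length sum at bin centers
                    "v_elong_um_s": 0.13, "v_retract_um_s": 0.07,
                    "n_cyt": 2, "fraction_triangular": 0.5,
                    "t_stationary_mean_s": 40.0,
                    "contact_while_growing_triangular": cwg,
                    "contact_while_growing_trapezoidal": cwg},
                "contact": {"contact_type": contact_type, "mu": 1.0,
                            "tc_s": 0.0},
                "simulation": {"total_time_s": 300.0, "dt_s": 100.0,
                               "n_replicates": 1, "seed": seed,
                               "half_life_s": math.inf}})
            rng = np.random.default_rng(seed)
            recv = cg.generate_cycle_schedule(
                cfg.cytonemes, 300.0, rng, compartment="receiving",
                n_rows=4, phi=2.0)
            prod = cg.generate_cycle_schedule(
                cfg.cytonemes, 300.0, rng, compartment="producing",
                n_rows=4, phi=2.0)
            engine = cg.count_contacts(recv, prod, cfg,
                                       np.random.default_rng(99))
            oracle = brute_force_contacts(recv, prod, cfg)
            np.testing.assert_array_equal(engine.counts, oracle)

    def test_type1_type2_exchangeable(self):
        """Swapping length distributions maps type 1 onto type 2."""
        def total(ct, swap):
            lr = {"mean_um": 9.0, "sd_um": 0.0}
            lp = {"mean_um": 5.0, "sd_um": 0.0}
            cfg = cg.validate_config({
                "tissue": {"phi": 1.0, "n_producing_rows": 6,
                           "n_receiving_rows": 6},
                "cytonemes": {"length_stats_r": lp if swap else lr,
                              "length_stats_p": lr if swap else lp,
                              "n_cyt": 1, "static": True},
                "contact": {"contact_type": ct, "mu": 1.0, "tc_s": 0.0},
                "simulation": {"total_time_s": 2.0, "dt_s": 1.0,
                               "n_replicates": 1, "seed": 1,
                               "half_life_s": math.inf}})
            return cg.run_replicate(cfg, 0)[0].total_per_row
        np.testing.assert_array_equal(total(1, False), total(2, True))
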