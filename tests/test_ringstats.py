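"""Ring-state statistics: compositions, arrangements, tests, and the Ising fit."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from oligoring import ringstats as rs
from oligoring import synthgen as sg


def tiny_table(states_per_ring):
    """Build a table from explicit 6-state rings: [(ring0 states), ...]."""
    rows = []
    for r, ring in enumerate(states_per_ring):
        assert len(ring) == 6
        for pos, state in enumerate(ring):
            rows.append({"particle_id": f"p{r // 2}", "hemichannel": r % 2,
                         "position": pos, "state": state})
    df = pd.DataFrame(rows)
    return rs.ProtomerStateTable(df, tuple(sorted(df["state"].unique())))


class TestStateTable:
    def test_incomplete_ring_rejected(self):
        df = pd.DataFrame({
            "particle_id": ["p0"] * 5, "hemichannel": [0] * 5,
            "position": range(5), "state": ["PLN"] * 5,
        })
        t = rs.ProtomerStateTable(df, ("PLN",))
        with pytest.raises(ValueError, match="positions 0..5"):
            t.validate()

    def test_tsv_round_trip(self, tmp_path):
        t = sg.simulate_state_table(50, seed=3)
        p = tmp_path / "t.tsv"
        t.to_tsv(p)
        t2 = rs.read_table_tsv(p)
        pd.testing.assert_frame_equal(
            t2.df.reset_index(drop=True), t.df.reset_index(drop=True)
        )

    def test_star_round_trip(self, tmp_path):
        t = sg.simulate_state_table(50, seed=4)
        p = tmp_path / "t.star"
        rs.write_table_star(t, p)
        mapping = {i + 1: s for i, s in enumerate(t.states)}
        t2 = rs.read_table_star(p, mapping)
        a = t.df.sort_values(["particle_id", "hemichannel", "position"]).reset_index(drop=True)
        b = t2.df.sort_values(["particle_id", "hemichannel", "position"]).reset_index(drop=True)
        assert (a["state"].to_numpy() == b["state"].to_numpy()).all()


class TestStateFractions:
    def test_all_one_state(self):
        t = tiny_table([["PLN"] * 6])
        assert rs.state_fractions(t) == {"PLN": 1.0}

    def test_direct_count_on_toy_ring(self):
        t = tiny_table([["PLN", "PLN", "GCN", "GCN", "GCN", "FIN"]])
        f = rs.state_fractions(t)
        assert f["PLN"] == pytest.approx(1 / 3)
        assert sum(f.values()) == pytest.approx(1.0, abs=1e-12)

    def test_recovers_generating_fractions(self):
        probs = dict(sg.DEFAULT_STATE_PROBS)
        n_particles = 20_000
        t = sg.simulate_state_table(n_particles, probs, seed=11)
        f = rs.state_fractions(t)
        n = 12 * n_particles
        for s, p in probs.items():
            assert abs(f[s] - p) < 3 * math.sqrt(p * (1 - p) / n)


class TestCompositionHistogram:
    def test_single_particle_all_focal(self):
        t = tiny_table([["PLN"] * 6, ["PLN"] * 6])
        h = rs.composition_histogram(t, "PLN", "channel")
        assert h.counts[12] == 1 and h.total == 1

    def test_hemichannel_totals_double_particle_totals(self):
        t = sg.simulate_state_table(500, seed=5)
        hc = rs.composition_histogram(t, "PLN", "hemichannel")
        ch = rs.composition_histogram(t, "PLN", "channel")
        assert hc.total == 2 * ch.total == 1000
        assert hc.counts.sum() == hc.total

    @pytest.mark.parametrize("state,p", [("PLN", 0.407), ("FIN", 0.22)])
    def test_independent_mode_matches_binomial(self, state, p):
        t = sg.simulate_state_table(10_000, seed=6)
        h = rs.composition_histogram(t, state, "channel")
        binom_mode = int(np.argmax(stats.binom.pmf(np.arange(13), 12, p)))
        assert h.mode == binom_mode
        if state == "PLN":
            assert h.mode == 5  # bell-shaped with a peak at five focal protomers


class TestExpectedComposition:
    def test_degenerate_p(self):
        np.testing.assert_allclose(rs.expected_composition(6, 0.0, 10),
                                   [10, 0, 0, 0, 0, 0, 0])

    def test_pascal_row(self):
        np.testing.assert_allclose(rs.expected_composition(6, 0.5, 64),
                                   [1, 6, 15, 20, 15, 6, 1], atol=1e-9)

    def test_tail_matches_direct_product(self):
        total = 124_079
        expected = rs.expected_composition(12, 0.407, total)
        assert expected[12] == pytest.approx(total * 0.407**12, rel=1e-9)


class TestArrangements:
    def test_k2_classes_brute_force_values(self):
        cls = rs.enumerate_arrangements(2)
        mult = {str(c): c.multiplicity for c in cls}
        # separations 1, 2, 3 around the hexamer
        assert mult == {"000011": 6, "000101": 6, "001001": 3}
        probs = sorted(c.conditional_probability for c in cls)
        assert probs == pytest.approx([0.2, 0.4, 0.4])

    def test_k3_classes_brute_force_values(self):
        cls = rs.enumerate_arrangements(3)
        assert sorted(c.multiplicity for c in cls) == [2, 6, 6, 6]
        assert sum(c.multiplicity for c in cls) == 20

    def test_k6_single_class(self):
        cls = rs.enumerate_arrangements(6)
        assert len(cls) == 1 and cls[0].conditional_probability == 1.0

    @pytest.mark.parametrize("k", range(7))
    def test_multiplicities_sum_to_choose(self, k):
        for sym in ("C6", "D6"):
            cls = rs.enumerate_arrangements(k, sym)
            assert sum(c.multiplicity for c in cls) == math.comb(6, k)
            assert sum(c.conditional_probability for c in cls) == pytest.approx(1.0)

    def test_d6_merges_mirror_classes_at_k3(self):
        assert len(rs.enumerate_arrangements(3, "C6")) == 4
        assert len(rs.enumerate_arrangements(3, "D6")) == 3

    @given(word=st.lists(st.integers(0, 1), min_size=6, max_size=6),
           shift=st.integers(0, 5))
    @settings(max_examples=100, deadline=None)
    def test_canonical_invariant_under_rotation(self, word, shift):
        rotated = word[shift:] + word[:shift]
        assert rs.canonical_arrangement(word) == rs.canonical_arrangement(rotated)
        assert rs.canonical_arrangement(word, "D6") == rs.canonical_arrangement(
            rotated[::-1], "D6"
        )

    def test_observed_adjacent_and_opposite_pairs(self):
        t = tiny_table([
            ["PLN", "PLN", "GCN", "GCN", "GCN", "GCN"],   # separation 1
            ["GCN", "PLN", "GCN", "GCN", "PLN", "GCN"],   # separation 3 (opposite)
        ])
        counts = rs.observed_arrangements(t, "PLN", k=2)
        assert counts[(0, 0, 0, 0, 1, 1)] == 1
        assert counts[(0, 0, 1, 0, 0, 1)] == 1

    def test_independent_data_match_conditional_probabilities(self):
        t = sg.simulate_state_table(20_000, seed=7)
        counts = rs.observed_arrangements(t, "PLN", k=2)
        classes = rs.enumerate_arrangements(2)
        total = sum(counts.values())
        for c in classes:
            p = c.conditional_probability
            obs = counts[c.pattern] / total
            assert abs(obs - p) < 3 * math.sqrt(p * (1 - p) / total)


class TestGoF:
    def test_exact_match_gives_zero_statistic(self):
        res = rs.gof_test([40, 40, 20], [0.4, 0.4, 0.2])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        np.testing.assert_allclose(res.expected, [40, 40, 20])

    def test_small_expected_counts_warn(self):
        with pytest.warns(UserWarning, match="exact"):
            rs.gof_test([3, 1], [0.75, 0.25])

    def test_exact_multinomial_matches_binomial_oracle(self):
        observed = np.array([3, 9])
        probs = np.array([0.5, 0.5])
        res = rs.gof_test(observed, probs, method="exact_multinomial")
        pmf = stats.binom.pmf(np.arange(13), 12, 0.5)
        oracle = pmf[pmf <= pmf[3] + 1e-12].sum()
        assert res.p_value == pytest.approx(oracle, rel=1e-9)

    def test_type_i_error_calibrated(self):
        """Chi-square rejection rate on true-null draws sits near alpha."""
        rng = np.random.default_rng(99)
        probs = np.array([0.4, 0.4, 0.2])
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            obs = rng.multinomial(300, probs)
            if rs.gof_test(obs, probs).p_value < 0.05:
                rejections += 1
        assert 0.03 < rejections / n_rep < 0.07


class TestRingModel:
    def test_marginal_closed_form_at_zero_coupling(self):
        for p in (0.1, 0.4, 0.9):
            h = math.log(p / (1 - p))
            assert rs.ring_marginal_probability(h, 0.0) == pytest.approx(p, abs=1e-12)

    def test_config_probabilities_normalize(self):
        lp = rs.ring_config_log_probs(0.3, 0.7)
        assert np.exp(lp).sum() == pytest.approx(1.0, abs=1e-12)

    def test_independence_fit_recovers_occupancy(self):
        covered = 0
        for seed in (8, 9, 10, 11):
            t = sg.simulate_state_table(5_000, seed=seed)
            fit = rs.fit_ring_model(t, "PLN")
            p_hat = t.rings("PLN").mean()
            # the fitted marginal reproduces the closed-form MLE occupancy
            assert fit.p == pytest.approx(p_hat, abs=5e-3)
            assert abs(fit.J) < 0.1
            covered += fit.J_ci[0] < 0.0 < fit.J_ci[1]
        # a 95% CI may miss the true J = 0 occasionally, but not usually
        assert covered >= 3

    def test_null_field_mle_is_logit_mean(self):
        rings = sg.sample_ring_configs(20_000, 0.4, 0.0, seed=9)
        p_hat = rings.mean()
        h0 = math.log(p_hat / (1 - p_hat))
        assert rs.ring_marginal_probability(h0, 0.0) == pytest.approx(p_hat, abs=1e-8)

    def test_coupled_fit_recovers_j(self):
        rings = sg.sample_ring_configs(50_000, 0.4, 0.5, seed=10)
        fit = rs.fit_ring_model_from_rings(rings)
        assert fit.J_ci[0] < 0.5 < fit.J_ci[1]
        assert fit.lrt_p_value < 1e-6
        assert fit.p == pytest.approx(0.4, abs=0.01)

    def test_positive_coupling_enriches_full_rings(self):
        """At matched marginal, J > 0 raises P(all six focal) above p^6."""
        p = 0.4
        for J in (0.2, 0.5, 1.0):
            h = rs.solve_field_for_marginal(p, J)
            p_full = math.exp(rs.ring_config_log_probs(h, J)[63])
            assert p_full > p**6

    def test_separation_raises(self):
        t = tiny_table([["GCN"] * 6, ["GCN"] * 6])
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="separation"):
                rs.fit_ring_model(t, "PLN")


class TestConfusionCorrection:
    def test_identity_matrix_is_noop(self):
        q = np.array([0.3, 0.2, 0.5])
        np.testing.assert_allclose(rs.invert_confusion(q, np.eye(3)), q)

    def test_symmetric_flip_inverts_exactly(self):
        C = np.array([[0.9, 0.1], [0.1, 0.9]])
        p_true = np.array([0.7, 0.3])
        q = C.T @ p_true
        np.testing.assert_allclose(rs.invert_confusion(q, C), p_true, atol=1e-12)


def test_bonferroni_caps_at_one():
    assert rs.bonferroni([0.01, 0.5, 0.9]) == [0.03, 1.0, 1.0]
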