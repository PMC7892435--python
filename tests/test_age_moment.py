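import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from founderage.age_moment import (
    ConvergenceError,
    NonInformativeMarkerError,
    aggregate_moment,
    bp_to_cm,
    build_markov,
    cm_to_theta,
    markov_age,
    moment_pipeline,
    risch_age,
    risch_from_deltas,
)
from founderage.ld_stats import AncestralHaplotype
from founderage.synthetic_data import default_config, simulate


class TestCmToTheta:
    def test_linear(self):
        assert cm_to_theta(4.92) == pytest.approx(0.0492)

    def test_linear_no_cap(self):
        # deliberately uncapped: 54.8 cM enters as 0.548
        assert cm_to_theta(54.8) == pytest.approx(0.548)

    def test_haldane(self):
        assert cm_to_theta(54.8, "haldane") == pytest.approx(
            0.5 * (1 - math.exp(-1.096))
        )
        assert cm_to_theta(54.8, "haldane") == pytest.approx(0.3329, abs=1e-4)

    def test_kosambi(self):
        assert cm_to_theta(10.0, "kosambi") == pytest.approx(0.5 * math.tanh(0.2))

    def test_zero_distance_error(self):
        with pytest.raises(ValueError):
            cm_to_theta(0.0)

    def test_unknown_function(self):
        with pytest.raises(ValueError):
            cm_to_theta(1.0, "morgan")

    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=50, deadline=None)
    def test_haldane_kosambi_below_half(self, d):
        assert 0 < cm_to_theta(d, "haldane") < 0.5
        assert 0 < cm_to_theta(d, "kosambi") < 0.5


class TestBpToCm:
    def test_definition(self):
        assert bp_to_cm(1_000_000) == pytest.approx(1.17)

    def test_zero(self):
        assert bp_to_cm(0) == 0.0

    def test_inverse_of_marker_distance(self):
        assert bp_to_cm(4_205_128) == pytest.approx(4.92, abs=5e-3)

    def test_negative_error(self):
        with pytest.raises(ValueError):
            bp_to_cm(-1)


class TestRischAge:
    def test_full_ld(self):
        assert risch_age(1.0, 0.01) == 0.0

    def test_closed_form(self):
        assert risch_age(0.25, 0.5) == pytest.approx(2.0)

    def test_printed_marker(self):
        # nearest marker: delta 0.945 at 0.73 cM
        assert risch_age(0.945, 0.0073) == pytest.approx(7.72, abs=0.01)

    def test_noninformative(self):
        with pytest.raises(NonInformativeMarkerError):
            risch_age(0.0, 0.01)
        with pytest.raises(NonInformativeMarkerError):
            risch_age(-0.2, 0.01)

    def test_theta_bounds(self):
        with pytest.raises(ValueError):
            risch_age(0.5, 0.0)
        with pytest.raises(ValueError):
            risch_age(0.5, 1.0)

    @given(
        d1=st.floats(min_value=0.05, max_value=1.0),
        d2=st.floats(min_value=0.05, max_value=1.0),
        theta=st.floats(min_value=1e-4, max_value=0.5),
    )
    @settings(max_examples=100, deadline=None)
    def test_multiplicativity(self, d1, d2, theta):
        total = risch_age(d1 * d2, theta)
        assert total == pytest.approx(risch_age(d1, theta) + risch_age(d2, theta), abs=1e-9)

    @given(
        theta=st.floats(min_value=1e-3, max_value=0.4),
        d_low=st.floats(min_value=0.05, max_value=0.5),
        bump=st.floats(min_value=0.01, max_value=0.4),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_decreasing_in_delta(self, theta, d_low, bump):
        assert risch_age(d_low, theta) > risch_age(min(d_low + bump, 1.0), theta)

    @given(
        delta=st.floats(min_value=0.05, max_value=0.95),
        t_low=st.floats(min_value=1e-3, max_value=0.2),
        bump=st.floats(min_value=0.01, max_value=0.2),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_decreasing_in_theta(self, delta, t_low, bump):
        assert risch_age(delta, t_low) > risch_age(delta, t_low + bump)


class TestAggregateMoment:
    def test_constant(self):
        assert aggregate_moment([10, 10, 10]) == (10.0, 0.0)

    def test_two_values(self):
        mean, sd = aggregate_moment([2, 4])
        assert mean == pytest.approx(3.0)
        assert sd == pytest.approx(math.sqrt(2), abs=1e-9)

    def test_needs_two(self):
        with pytest.raises(ValueError):
            aggregate_moment([5.0])

    def test_table1_summary(self, table1_deltas, paper_map):
        # oracle: direct evaluation of the closed form on the printed pairs
        gs = [
            math.log(table1_deltas[m.name]) / math.log(1 - m.dist_cM / 100)
            for m in paper_map
        ]
        mean, sd = aggregate_moment(gs)
        assert mean == pytest.approx(11.49, abs=0.01)
        assert sd == pytest.approx(5.48, abs=0.01)


class TestBuildMarkov:
    def test_no_event_limit(self):
        model = build_markov([1, 2, 3], 0.0, 0.0, [0.2, 0.3, 0.5])
        assert np.allclose(model.K, np.eye(3))

    def test_full_replacement_limit(self):
        q = [0.2, 0.3, 0.5]
        model = build_markov([1, 2, 3], 1.0, 0.0, q)
        assert np.allclose(model.K, np.tile(q, (3, 1)))

    def test_row_stochastic(self):
        model = build_markov(range(5), 0.01, 5.6e-4, [0.2] * 5)
        assert np.allclose(model.K.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(model.K >= 0)

    def test_mutation_reflects_at_boundaries(self):
        model = build_markov([1, 2, 3], 0.0, 1.0, [1 / 3] * 3)
        # all mutation mass at a boundary steps inward
        assert model.K[0, 1] == pytest.approx(1.0)
        assert model.K[2, 1] == pytest.approx(1.0)
        assert model.K[1, 0] == pytest.approx(0.5)
        assert model.K[1, 2] == pytest.approx(0.5)

    def test_bad_frequencies(self):
        with pytest.raises(ValueError):
            build_markov([1, 2], 0.1, 0.0, [0.5, 0.4])

    def test_theta_mu_budget(self):
        with pytest.raises(ValueError):
            build_markov([1, 2], 0.9, 0.2, [0.5, 0.5])

    def test_stochasticity_preserved_under_iteration(self):
        model = build_markov(range(7), 0.05, 1e-3, [1 / 7] * 7)
        v = np.zeros(7)
        v[3] = 1.0
        for _ in range(50):
            v = v @ model.K
            assert v.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(v >= -1e-15)


class TestMarkovAge:
    def test_no_decay_needed(self):
        model = build_markov([20, 21], 0.05, 0.0, [0.0, 1.0])
        assert markov_age(1.0, model, {20}) == 0

    def test_closed_form(self):
        # mu=0, ancestral control frequency 0: mass decays as (1-theta)^t
        model = build_markov([20, 21], 0.05, 0.0, [0.0, 1.0])
        assert markov_age(0.60, model, {20}) == math.ceil(math.log(0.6) / math.log(0.95))
        assert markov_age(0.60, model, {20}) == 10

    def test_unreachable_target(self):
        # stationary ancestral mass is 0.5; cannot fall to 0.3
        model = build_markov([20, 21], 0.1, 0.0, [0.5, 0.5])
        with pytest.raises(ConvergenceError, match="stationary"):
            markov_age(0.3, model, {20}, max_iter=500)

    def test_split_start_vector(self):
        model = build_markov([24, 25, 26], 0.0, 0.0, [0.0, 0.0, 1.0])
        # no events at all: ancestral mass stays 1, any p_obs=1 target at t=0
        assert markov_age(1.0, model, {24, 25}) == 0

    @pytest.mark.parametrize("theta", [0.01, 0.05, 0.2])
    @pytest.mark.parametrize("p_obs", [0.9, 0.5, 0.2])
    def test_limit_equivalence_with_risch(self, theta, p_obs):
        model = build_markov([20, 21], theta, 0.0, [0.0, 1.0])
        assert markov_age(p_obs, model, {20}) == math.ceil(risch_age(p_obs, theta))

    def test_padding_insensitivity(self, paper_map, paper_founder):
        config = default_config(paper_map, paper_founder, g_true=8, n_carriers=60,
                                n_controls=200, seed=11)
        hapset = simulate(config)
        anc = AncestralHaplotype({k: frozenset({v}) for k, v in paper_founder.items()})
        est2 = moment_pipeline(hapset, anc, method="markov", state_padding=2)
        est4 = moment_pipeline(hapset, anc, method="markov", state_padding=4)
        assert est2.per_marker == est4.per_marker


class TestMomentPipeline:
    def test_table1_risch(self, table1_deltas, paper_map):
        est = risch_from_deltas(table1_deltas, paper_map)
        assert est.g_point == pytest.approx(11.49, abs=0.01)
        assert est.g_sd == pytest.approx(5.48, abs=0.01)
        assert est.years == 287
        assert est.date == 1703
        assert len(est.per_marker) == 8

    def test_haldane_variant_differs(self, table1_deltas, paper_map):
        est = risch_from_deltas(table1_deltas, paper_map, map_function="haldane")
        assert est.g_point > 11.6  # the far marker's theta shrinks, ages grow

    def test_risch_recovery(self, paper_map, paper_founder):
        # large-sample recovery against the generator truth
        mmap = paper_map
        anc = AncestralHaplotype({k: frozenset({v}) for k, v in paper_founder.items()})
        ests = []
        for seed in range(6):
            config = default_config(mmap, paper_founder, g_true=12, n_carriers=500,
                                    n_controls=500, seed=seed)
            # mutation-free variant isolates the LD decay signal
            hapset = simulate(config)
            ests.append(moment_pipeline(hapset, anc, method="risch").g_point)
        assert abs(np.mean(ests) - 12) < 2.0

    def test_single_marker_flagged(self, make_set, one_marker_map):
        anc = AncestralHaplotype({"M1": frozenset({20})})
        hs = make_set(
            one_marker_map,
            carriers=[{"M1": 20}] * 9 + [{"M1": 12}],
            controls=[{"M1": 20}] * 2 + [{"M1": 12}] * 8,
        )
        est = moment_pipeline(hs, anc, method="risch")
        assert est.g_sd is None
        assert len(est.per_marker) == 1

    def test_all_noninformative_error(self, make_set, one_marker_map):
        anc = AncestralHaplotype({"M1": frozenset({20})})
        hs = make_set(
            one_marker_map,
            carriers=[{"M1": 20}] * 3 + [{"M1": 12}] * 7,
            controls=[{"M1": 20}] * 3 + [{"M1": 12}] * 7,
        )
        with pytest.raises(NonInformativeMarkerError):
            moment_pipeline(hs, anc, method="risch")

    def test_markov_on_simulated_data(self, paper_map, paper_founder):
        config = default_config(paper_map, paper_founder, g_true=10, n_carriers=200,
                                n_controls=300, seed=5)
        hapset = simulate(config)
        anc = AncestralHaplotype({k: frozenset({v}) for k, v in paper_founder.items()})
        est = moment_pipeline(hapset, anc, method="markov")
        assert est.method == "markov"
        assert 4 <= est.g_point <= 18
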