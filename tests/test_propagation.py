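"""Value propagation, aging refresh, and the timeline replay."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trialrank import (
    AlgorithmConfig,
    Direction,
    PropagationConfig,
    PropagationEvent,
    SplitRule,
    ValidationError,
    edge_contribution,
    evaluate_network,
    evaluate_with_propagation,
    find_propagation_targets,
    propagate_event,
    refresh_edge,
)


@pytest.fixture
def cml_motif(make_trial):
    """The motif from the CML narrative: the standard beat an old regimen,
    then a newcomer beats the standard (imatinib / IFNA-LoDAC / dasatinib)."""
    old_win = make_trial(
        trial_id="IRIS", year=2003, a="imatinib", b="IFNA/LoDAC",
        p=0.001, effect=0.5, n=1000,
    )
    new_win = make_trial(
        trial_id="DASISION", year=2010, a="dasatinib", b="imatinib",
        p=0.007, effect=0.6, n=500,
    )
    return [old_win, new_win]


class TestFindTargets:
    def test_loss_targets_prior_defeated_regimens(self, cml_motif, config):
        edges = [edge_contribution(t, 2010, config) for t in cml_motif]
        targets = find_propagation_targets("imatinib", 2010, edges, Direction.LOSS)
        assert [t for t, _ in targets] == ["IFNA/LoDAC"]

    def test_gain_targets_prior_victors(self, cml_motif, config):
        edges = [edge_contribution(t, 2010, config) for t in cml_motif]
        targets = find_propagation_targets("IFNA/LoDAC", 2010, edges, Direction.GAIN)
        assert [t for t, _ in targets] == ["imatinib"]

    def test_no_prior_wins_gives_empty_list(self, cml_motif, config):
        edges = [edge_contribution(t, 2010, config) for t in cml_motif]
        assert find_propagation_targets("dasatinib", 2010, edges, Direction.LOSS) == []

    def test_same_year_edge_excluded(self, make_trial, config):
        edge = edge_contribution(make_trial(year=2010), 2010, config)
        assert find_propagation_targets("A", 2010, [edge], Direction.LOSS) == []


class TestRefreshEdge:
    def test_one_half_life_younger_doubles_aging(self, make_trial, config):
        edge = edge_contribution(make_trial(year=2000, p=0.001, effect=0.5, n=1000), 2020, config)
        assert edge.aging == pytest.approx(0.25)
        refreshed = refresh_edge(edge, config.half_life_years)
        assert refreshed.effective_age == 10.0
        assert refreshed.aging == pytest.approx(0.5)
        assert refreshed.magnitude == pytest.approx(2 * edge.magnitude)

    def test_age_floors_at_zero_and_aging_caps_at_one(self, make_trial, config):
        edge = edge_contribution(make_trial(year=2015), 2020, config)
        refreshed = refresh_edge(edge, config.half_life_years)
        assert refreshed.effective_age == 0.0
        assert refreshed.aging == 1.0

    def test_refresh_of_fresh_edge_is_identity(self, make_trial, config):
        edge = edge_contribution(make_trial(year=2020), 2020, config)
        assert refresh_edge(edge, config.half_life_years) is edge


class TestPropagateEvent:
    def _state(self, make_trial, config, n_targets=1):
        trials = [
            make_trial(trial_id=f"W{i}", year=2000, a="S", b=f"O{i}", p=0.001,
                       effect=0.5, n=1000)
            for i in range(n_targets)
        ]
        trials.append(
            make_trial(trial_id="NEW", year=2010, a="N", b="S", p=0.001,
                       effect=0.5, n=1000)
        )
        return evaluate_network(trials, 2010, config)

    def test_half_of_loss_transferred_to_single_target(self, make_trial, config):
        state = self._state(make_trial, config)
        event = PropagationEvent(node="S", delta=-10.0, year=2010, source_trials=("NEW",))
        targets = find_propagation_targets("S", 2010, state.edges, Direction.LOSS)
        prop = PropagationConfig(fraction=0.5, refresh_enabled=False)
        new_state, record = propagate_event(state, event, targets, prop)
        assert new_state.adjustments["S"] == pytest.approx(5.0)  # loss shrinks by 5
        assert new_state.adjustments["O0"] == pytest.approx(-5.0)
        assert dict(record.transfers) == pytest.approx({"O0": -5.0})

    def test_equal_split_among_two_targets(self, make_trial, config):
        state = self._state(make_trial, config, n_targets=2)
        event = PropagationEvent(node="S", delta=-10.0, year=2010, source_trials=("NEW",))
        targets = find_propagation_targets("S", 2010, state.edges, Direction.LOSS)
        prop = PropagationConfig(fraction=0.5, refresh_enabled=False)
        new_state, _ = propagate_event(state, event, targets, prop)
        assert new_state.adjustments["O0"] == pytest.approx(-2.5)
        assert new_state.adjustments["O1"] == pytest.approx(-2.5)
        assert new_state.adjustments["S"] == pytest.approx(5.0)

    def test_proportional_split_follows_edge_magnitudes(self, make_trial, config):
        t1 = make_trial(trial_id="W0", year=2000, a="S", b="O0", p=0.001, effect=0.5, n=1000)
        t2 = make_trial(trial_id="W1", year=2005, a="S", b="O1", p=0.05, effect=1.25, n=100)
        t3 = make_trial(trial_id="NEW", year=2010, a="N", b="S", p=0.001, effect=0.5, n=1000)
        state = evaluate_network([t1, t2, t3], 2010, config)
        targets = find_propagation_targets("S", 2010, state.edges, Direction.LOSS)
        mags = {t: abs(e.magnitude) for t, e in targets}
        event = PropagationEvent(node="S", delta=-10.0, year=2010, source_trials=("NEW",))
        prop = PropagationConfig(fraction=0.5, refresh_enabled=False,
                                 split_rule=SplitRule.PROPORTIONAL)
        new_state, _ = propagate_event(state, event, targets, prop)
        total = mags["O0"] + mags["O1"]
        assert new_state.adjustments["O0"] == pytest.approx(-5.0 * mags["O0"] / total)
        assert new_state.adjustments["O1"] == pytest.approx(-5.0 * mags["O1"] / total)

    def test_no_targets_leaves_state_unchanged(self, make_trial, config):
        state = self._state(make_trial, config)
        event = PropagationEvent(node="N", delta=-3.0, year=2010, source_trials=("NEW",))
        new_state, record = propagate_event(state, event, [], PropagationConfig())
        assert new_state.values == state.values
        assert record.transfers == ()

    def test_zero_delta_event_rejected(self):
        with pytest.raises(ValidationError):
            PropagationEvent(node="S", delta=0.0, year=2010, source_trials=("T",))


class TestReplay:
    def test_fraction_zero_refresh_off_is_bit_identical(self, config):
        from tests_support import random_trials

        trials = random_trials(3, max_trials=25)
        cfg = AlgorithmConfig(
            propagation=PropagationConfig(fraction=0.0, refresh_enabled=False)
        )
        plain = evaluate_network(trials, 2020, cfg)
        replayed = evaluate_with_propagation(trials, 2020, cfg)
        assert replayed.values == plain.values  # exact, not approximate
        assert replayed.edges == plain.edges

    def test_three_node_chain_matches_hand_replay(self, make_trial):
        # standard B beat C in 2001; newcomer A beats B in 2010 (both +-18 fresh)
        t1 = make_trial(trial_id="T1", year=2001, a="B", b="C", p=0.001, effect=0.5, n=1000)
        t2 = make_trial(trial_id="T2", year=2010, a="A", b="B", p=0.001, effect=0.5, n=1000)
        cfg = AlgorithmConfig(
            propagation=PropagationConfig(fraction=0.5, refresh_enabled=False)
        )
        old_mag = 18.0 * 2 ** (-9 / 10)  # aged by 9 years at eval 2010
        state = evaluate_with_propagation([t1, t2], 2010, cfg)
        assert state.value("A") == pytest.approx(18.0)
        assert state.value("B") == pytest.approx(old_mag - 18.0 + 9.0)
        assert state.value("C") == pytest.approx(-old_mag - 9.0)
        pre = evaluate_network([t1, t2], 2010, cfg)
        assert state.value("B") > pre.value("B")

    def test_disconnected_pairs_propagate_independently(self, make_trial):
        cfg = AlgorithmConfig(propagation=PropagationConfig(fraction=0.5))
        pair1 = [
            make_trial(trial_id="P1a", year=2000, a="A", b="B", p=0.001, effect=0.5, n=1000),
            make_trial(trial_id="P1b", year=2010, a="C", b="A", p=0.001, effect=0.5, n=1000),
        ]
        pair2 = [
            make_trial(trial_id="P2a", year=2005, a="X", b="Y", p=0.01, effect=0.7, n=400),
        ]
        combined = evaluate_with_propagation(pair1 + pair2, 2015, cfg)
        alone = evaluate_with_propagation(pair1, 2015, cfg)
        for node in ("A", "B", "C"):
            assert combined.value(node) == pytest.approx(alone.value(node))

    def test_single_generation_only(self, make_trial):
        # chain D->C->B->A of wins; new loss at A must not reach C or D
        trials = [
            make_trial(trial_id="T1", year=1995, a="B", b="C", p=0.001, effect=0.5, n=1000),
            make_trial(trial_id="T0", year=1990, a="C", b="D", p=0.001, effect=0.5, n=1000),
            make_trial(trial_id="T2", year=2000, a="A", b="B", p=0.001, effect=0.5, n=1000),
            make_trial(trial_id="T3", year=2010, a="E", b="A", p=0.001, effect=0.5, n=1000),
        ]
        cfg_off = AlgorithmConfig(
            propagation=PropagationConfig(fraction=0.0, refresh_enabled=False)
        )
        cfg_on = AlgorithmConfig(
            propagation=PropagationConfig(fraction=0.5, refresh_enabled=False)
        )
        base = evaluate_with_propagation(trials[:3], 2010, cfg_off)
        # replay the full timeline but compare only the effect of the final event
        with_final_off = evaluate_with_propagation(trials, 2010, cfg_off)
        with_final_on = evaluate_with_propagation(trials, 2010, cfg_on)
        # T3's loss at A propagates to B (one generation) ...
        assert with_final_on.value("B") != pytest.approx(with_final_off.value("B"))
        # ... but T3 does not change C or D relative to what earlier events did
        delta_c = with_final_on.value("C") - with_final_off.value("C")
        delta_d = with_final_on.value("D") - with_final_off.value("D")
        # C and D changed only via the 1995/2000 events, which are present in
        # both runs with the same fraction... so isolate: rerun without T3.
        without_t3_on = evaluate_with_propagation(trials[:3], 2010, cfg_on)
        assert with_final_on.value("C") - without_t3_on.value("C") == pytest.approx(0.0)
        assert with_final_on.value("D") - without_t3_on.value("D") == pytest.approx(0.0)

    @given(seed=st.integers(0, 5000))
    @settings(max_examples=40, deadline=None)
    def test_conservation_without_refresh(self, seed):
        from tests_support import random_trials

        trials = random_trials(seed)
        cfg = AlgorithmConfig(
            propagation=PropagationConfig(fraction=0.5, refresh_enabled=False)
        )
        state = evaluate_with_propagation(trials, 2020, cfg)
        scale = max(1.0, sum(abs(v) for v in state.values.values()))
        assert abs(sum(state.values.values())) <= 1e-9 * scale

    @given(seed=st.integers(0, 5000))
    @settings(max_examples=20, deadline=None)
    def test_replay_determinism(self, seed):
        from tests_support import random_trials

        trials = random_trials(seed)
        cfg = AlgorithmConfig()
        s1 = evaluate_with_propagation(trials, 2020, cfg)
        s2 = evaluate_with_propagation(trials, 2020, cfg)
        assert s1.values == s2.values
        assert s1.edges == s2.edges

    def test_directional_contract_on_cml_motif(self, cml_motif):
        cfg = AlgorithmConfig(propagation=PropagationConfig(fraction=0.5))
        pre = evaluate_network(cml_motif, 2016, cfg)
        post = evaluate_with_propagation(cml_motif, 2016, cfg)
        assert post.value("imatinib") > pre.value("imatinib")
        assert post.value("IFNA/LoDAC") < pre.value("IFNA/LoDAC")

    def test_trace_records_transfers_and_refreshes(self, cml_motif):
        cfg = AlgorithmConfig(propagation=PropagationConfig(fraction=0.5))
        _, trace = evaluate_with_propagation(cml_motif, 2016, cfg, collect_trace=True)
        (record,) = [r for r in trace if r.event.node == "imatinib"]
        assert record.event.year == 2010
        assert [t for t, _ in record.transfers] == ["IFNA/LoDAC"]
        assert record.refreshed_trials == ("IRIS",)
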