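"""Synchronous dynamics: stepping, enumeration, attractors, mutants, trajectories."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import orbit_oracle
from disnet import fixtures
from disnet.dynamics import (
    BooleanNetwork,
    StateTransitionMap,
    analyze,
    apply_perturbation,
    enumerate_state_space,
    find_attractors,
    parse_rules,
    read_transitions,
    state_to_bits,
    state_to_string,
    step_logic,
    step_threshold,
    string_to_state,
    trajectory,
    write_transitions,
)
from disnet.errors import ConfigurationError, ModeError, ResourceLimitError
from disnet.rules import evaluate

G0 = "0100010100"
THREE_RING = parse_rules("$node[1]=!$node[3]; $node[2]=!$node[1]; $node[3]=!$node[2];")


def threshold_net(n, regulators, self_degrading=frozenset()):
    return BooleanNetwork(n=n, regulators=regulators, self_degrading=frozenset(self_degrading))


class TestStepLogic:
    def test_quiescent_state_is_fixed_point(self, cellcycle_net):
        s = string_to_state(G0)
        assert step_logic(cellcycle_net, s) == s

    def test_negation_ring_flips_uniform_states(self):
        assert step_logic(THREE_RING, 0b000) == 0b111
        assert step_logic(THREE_RING, 0b111) == 0b000

    def test_all_nodes_clamped_dominates_any_input(self):
        net = apply_perturbation(THREE_RING, {1: 1, 2: 0, 3: 1})
        for s in range(8):
            assert step_logic(net, s) == 0b101

    def test_threshold_net_rejected(self):
        tnet = threshold_net(2, {1: [(2, 1)], 2: [(1, 1)]})
        with pytest.raises(ModeError):
            step_logic(tnet, 0)


class TestStepThreshold:
    def test_mutual_activation_two_cycle_and_on_fixed_point(self):
        net = threshold_net(2, {1: [(2, 1)], 2: [(1, 1)]})
        s01, s10, s11 = 0b01, 0b10, 0b11
        assert step_threshold(net, s01) == s10
        assert step_threshold(net, s10) == s01
        assert step_threshold(net, s11) == s11

    def test_mutual_inhibition_collapses_to_off(self):
        net = threshold_net(2, {1: [(2, -1)], 2: [(1, -1)]})
        for s in range(4):
            assert step_threshold(net, s) == 0b00

    def test_isolated_node_holds_unless_self_degrading(self):
        hold = threshold_net(1, {1: []})
        decay = threshold_net(1, {1: []}, self_degrading={1})
        assert step_threshold(hold, 1) == 1 and step_threshold(hold, 0) == 0
        assert step_threshold(decay, 1) == 0

    def test_logic_net_rejected(self):
        with pytest.raises(ModeError):
            step_threshold(THREE_RING, 0)

    def test_threshold_is_sharp_at_one(self):
        # two activators, one inhibitor onto node 1: sum must reach +1
        net = threshold_net(3, {1: [(2, 1), (3, -1)], 2: [], 3: []})
        assert step_threshold(net, 0b010) & 0b100  # +1 >= 1 -> on
        assert not step_threshold(net, 0b011) & 0b100  # +1-1=0 -> off


class TestEnumeration:
    def test_single_node_identity_map(self):
        net = parse_rules("$node[1] = $node[1];")
        stm = enumerate_state_space(net)
        assert stm.successors == [0, 1]

    def test_cellcycle_covers_1024_states(self, cellcycle_net):
        assert enumerate_state_space(cellcycle_net).n_states == 1024

    def test_cap_guards_blowup(self):
        net = fixtures.random_boolean_network(6, 2, "logic", seed=1)
        with pytest.raises(ResourceLimitError, match="cap"):
            enumerate_state_space(net, cap=5)
        assert enumerate_state_space(net, cap=6).n_states == 64

    def test_random_net_matches_truth_table_oracle(self):
        net = fixtures.random_boolean_network(4, 3, "logic", seed=5)
        stm = enumerate_state_space(net)
        for s in range(16):
            bits = state_to_bits(s, 4)
            expected = [evaluate(net.rules[i], bits) for i in range(1, 5)]
            assert state_to_bits(stm.successor(s), 4) == expected

    def test_determinism(self, cellcycle_net):
        a = enumerate_state_space(cellcycle_net)
        b = enumerate_state_space(cellcycle_net)
        assert a.successors == b.successors


class TestAttractors:
    def test_cellcycle_g0_singleton_and_seven_state_cycle(self, cellcycle_net):
        _, att = analyze(cellcycle_net)
        assert len(att.singletons) == 1
        assert att.singletons[0].state_strings(10) == [G0]
        assert len(att.cycles) == 1 and att.cycles[0].period == 7
        assert sum(a.basin_size for a in att.attractors) == 1024

    def test_negation_ring_two_cycles(self):
        _, att = analyze(THREE_RING)
        assert not att.singletons
        assert sorted(a.period for a in att.cycles) == [2, 6]
        two_cycle = next(a for a in att.cycles if a.period == 2)
        assert set(two_cycle.states) == {0b000, 0b111}

    def test_identity_map_all_fixed_points(self):
        stm = StateTransitionMap(2, [0, 1, 2, 3])
        att = find_attractors(stm)
        assert len(att.singletons) == 4
        assert all(a.basin_size == 1 for a in att.attractors)

    def test_canonical_rotation_starts_at_smallest_state(self):
        _, att = analyze(THREE_RING)
        for a in att.cycles:
            assert a.states[0] == min(a.states)

    def test_attractor_closure_and_fixed_point_certificate(self, cellcycle_net):
        stm, att = analyze(cellcycle_net)
        for a in att.attractors:
            cycle = list(a.states)
            for i, s in enumerate(cycle):
                assert stm.successor(s) == cycle[(i + 1) % len(cycle)]
        for a in att.singletons:
            assert step_logic(cellcycle_net, a.states[0]) == a.states[0]

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(1, 8),
           mode=st.sampled_from(["logic", "threshold"]))
    def test_basins_partition_state_space(self, seed, n, mode):
        net = fixtures.random_boolean_network(n, min(3, n), mode, seed=seed)
        _, att = analyze(net)
        assert sum(a.basin_size for a in att.attractors) == 2 ** n

    def test_matches_orbit_following_oracle(self):
        for seed in range(30):
            net = fixtures.random_boolean_network(4, 3, "logic", seed=seed)
            stm, att = analyze(net)
            expected = orbit_oracle(stm.successors)
            got = {a.states: a.basin_size for a in att.attractors}
            assert got == expected


class TestPerturbation:
    def test_rb_knockout_loses_singleton_gains_cycle(self, cellcycle_net):
        mutant = apply_perturbation(cellcycle_net, {2: 0})
        _, att = analyze(mutant)
        assert len(att.singletons) == 0
        assert len(att.cycles) >= 1

    def test_original_network_unmodified(self, cellcycle_net):
        apply_perturbation(cellcycle_net, {2: 0})
        assert cellcycle_net.clamps == {}

    def test_clamp_all_gives_unique_singleton_at_clamp_vector(self):
        clamps = {1: 1, 2: 0, 3: 1}
        net = apply_perturbation(THREE_RING, clamps)
        _, att = analyze(net)
        assert len(att.attractors) == 1
        only = att.attractors[0]
        assert only.kind == "singleton" and only.states[0] == 0b101
        assert only.basin_size == 8

    def test_clamping_fixed_point_value_preserves_fixed_point(self, cellcycle_net):
        s = string_to_state(G0)
        net = apply_perturbation(cellcycle_net, {2: 1})  # Rb is 1 in G0
        assert step_logic(net, s) == s

    def test_conflicting_reclamp_is_error(self, cellcycle_net):
        net = apply_perturbation(cellcycle_net, {2: 0})
        with pytest.raises(ConfigurationError, match="already clamped"):
            apply_perturbation(net, {2: 1})

    def test_edge_count_unaffected_by_clamps(self, cellcycle_net):
        assert apply_perturbation(cellcycle_net, {2: 0}).edge_count == 49


class TestTrajectory:
    def test_start_on_fixed_point_has_length_one(self, cellcycle_net):
        tr = trajectory(cellcycle_net, string_to_state(G0))
        assert tr.state_strings() == [G0]
        assert tr.attractor_entry == 0 and tr.period == 1

    def test_mutual_activation_period_two_from_start(self):
        net = threshold_net(2, {1: [(2, 1)], 2: [(1, 1)]})
        tr = trajectory(net, 0b01)
        assert tr.state_strings() == ["01", "10"]
        assert tr.attractor_entry == 0 and tr.period == 2

    def test_always_terminates_within_state_count(self):
        for seed in (1, 2, 3):
            net = fixtures.random_boolean_network(5, 3, "logic", seed=seed)
            for start in range(32):
                tr = trajectory(net, start, max_steps=32)
                assert tr.converged

    def test_budget_exhaustion_reported_not_raised(self, cellcycle_net):
        tr = trajectory(cellcycle_net, string_to_state("1111111111"), max_steps=1)
        assert not tr.converged and tr.period is None


class TestTransitionsFile:
    def test_single_node_identity_layout(self, tmp_path):
        net = parse_rules("$node[1] = $node[1];")
        stm, att = analyze(net)
        out = tmp_path / "t.txt"
        write_transitions(stm, att, out)
        lines = out.read_text().splitlines()
        assert lines[0] == "0\t0" and lines[1] == "1\t1"
        assert sum(1 for line in lines if "kind=singleton" in line) == 2

    def test_cellcycle_has_1024_transition_lines(self, cellcycle_net, tmp_path):
        stm, att = analyze(cellcycle_net)
        out = tmp_path / "cc.txt"
        write_transitions(stm, att, out)
        data = [line for line in out.read_text().splitlines() if not line.startswith("#")]
        assert len(data) == 1024

    def test_roundtrip_reconstructs_map(self, tmp_path):
        net = fixtures.random_boolean_network(5, 3, "logic", seed=8)
        stm, att = analyze(net)
        out = tmp_path / "r.txt"
        write_transitions(stm, att, out)
        assert read_transitions(out).successors == stm.successors


def test_logic_threshold_consistency_on_positive_chains():
    """A chain of single positive regulators behaves identically under the
    expression semantics and the signed-sum threshold semantics."""
    n = 4
    logic = parse_rules(
        "$node[1]=$node[4]; $node[2]=$node[1]; $node[3]=$node[2]; $node[4]=$node[3];"
    )
    thresh = BooleanNetwork(
        n=n, regulators={1: [(4, 1)], 2: [(1, 1)], 3: [(2, 1)], 4: [(3, 1)]}
    )
    a = enumerate_state_space(logic)
    b = enumerate_state_space(thresh)
    assert a.successors == b.successors


def test_state_string_rendering_node1_leftmost():
    assert state_to_string(0b0100010100, 10) == "0100010100"
    assert state_to_bits(string_to_state("0100010100"), 10)[1] == 1  # node 2 (Rb) on
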