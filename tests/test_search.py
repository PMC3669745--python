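"""Two-phase rewriting semantics and terminal-state enumeration."""

import random

import pytest

from amygsearch import (
    applicable_moves,
    enumerate_terminals,
    enumerate_terminals_naive,
    experiment,
    step,
)
from amygsearch.search import (
    CONDITIONING,
    DONE,
    EXTINGUISHING,
    SearchState,
    compile_experiment,
)


class TestMoves:
    def test_model1_initial_state_offers_nine_increases(self):
        comp = compile_experiment(experiment(1, 1))
        moves = applicable_moves(comp.initial_state, comp)
        assert len(moves) == 9
        assert all(m.direction == +1 for m in moves)

    def test_saturated_weight_offers_no_increase(self):
        comp = compile_experiment(experiment(1, 1))
        mags = tuple(2 for _ in comp.circuit.connections)
        state = SearchState(CONDITIONING, mags)
        assert applicable_moves(state, comp) == []

    def test_done_state_offers_nothing(self):
        comp = compile_experiment(experiment(1, 1))
        state = SearchState(DONE, comp.circuit.initial_magnitudes, (1, 1))
        assert applicable_moves(state, comp) == []

    def test_inapplicable_move_rejected(self):
        comp = compile_experiment(experiment(1, 1))
        moves = applicable_moves(comp.initial_state, comp)
        state = step(comp.initial_state, moves[0], comp)
        bad = [m for m in applicable_moves(comp.initial_state, comp)
               if m not in applicable_moves(state, comp)]
        if bad:
            with pytest.raises(ValueError):
                step(state, bad[0], comp)


class TestPhaseTransitions:
    def test_cs_potentiation_triggers_conditioning_end(self):
        """One LTP step on the CS-to-Fear-pathway weight activates the gate
        and snapshots the interneuron records."""
        comp = compile_experiment(experiment(1, 1))
        move = next(
            m for m in applicable_moves(comp.initial_state, comp)
            if m.label == "wCStoLA2"
        )
        state = step(comp.initial_state, move, comp)
        assert state.phase == EXTINGUISHING
        assert state.records == (1, 1)  # both interneuron weights at initial 1

    def test_depressing_output_weight_completes_extinction(self):
        comp = compile_experiment(experiment(1, 1))
        move = next(
            m for m in applicable_moves(comp.initial_state, comp)
            if m.label == "wCStoLA2"
        )
        ext = step(comp.initial_state, move, comp)
        down = next(m for m in applicable_moves(ext, comp) if m.label == "wBA2toCEm")
        done = step(ext, down, comp)
        assert done.phase == DONE
        assert done.records == (1, 1)

    def test_phase_progression_is_monotone(self, toy):
        order = {CONDITIONING: 0, EXTINGUISHING: 1, DONE: 2}
        comp = compile_experiment(toy)
        frontier = [comp.initial_state]
        seen = set(frontier)
        while frontier:
            nxt = []
            for s in frontier:
                for m in applicable_moves(s, comp):
                    child = step(s, m, comp)
                    assert order[child.phase] >= order[s.phase]
                    if child not in seen:
                        seen.add(child)
                        nxt.append(child)
            frontier = nxt


class TestEnumeration:
    def test_toy_terminal_set_matches_hand_enumeration(self, toy):
        # conditioning: w 0->1 turns the gate on (record 1); extinction:
        # w 1->0 turns it off.  Exactly one terminal configuration.
        ts = enumerate_terminals(toy)
        assert len(ts) == 1
        (state,) = ts
        assert state.magnitudes[0] == 0 and state.records == (1,)

    def test_toy_naive_oracle_agrees(self, toy):
        assert enumerate_terminals_naive(toy).states == enumerate_terminals(toy).states

    def test_naive_depth_limit_zero_gives_empty_set(self, toy):
        assert len(enumerate_terminals_naive(toy, depth_limit=0)) == 0

    @pytest.mark.parametrize("row", [10, 11, 12])
    def test_memoized_equals_naive_on_small_experiments(self, row):
        exp = experiment(1, row)
        memo = enumerate_terminals(exp)
        naive = enumerate_terminals_naive(exp)
        assert memo.states == naive.states

    def test_all_terminals_have_gate_off(self, m1_baseline_terminals):
        comp = compile_experiment(m1_baseline_terminals.experiment)
        for s in m1_baseline_terminals:
            assert s.phase == DONE
            assert not comp.pag_extinction(s.magnitudes)

    def test_magnitudes_stay_bounded(self, m2_baseline_terminals):
        for s in m2_baseline_terminals:
            assert all(0 <= m <= 2 for m in s.magnitudes)

    def test_model1_saturated_dead_end_counted(self, m1_baseline_terminals):
        # the fully saturated configuration never activates the gate
        assert m1_baseline_terminals.n_dead_ends == 1

    def test_extinction_has_no_dead_ends(self, m1_baseline_terminals, m2_baseline_terminals):
        """The all-minimum extinction configuration always deactivates the
        gate, so every extinction path can complete."""
        for ts in (m1_baseline_terminals, m2_baseline_terminals):
            comp = compile_experiment(ts.experiment)
            mags = list(comp.circuit.initial_magnitudes)
            for conn in comp.circuit.connections:
                i = comp.circuit.connection_index[conn.name]
                ext = ts.experiment.schedule.extinction_moves(conn.name)
                if "decrease" in ext:
                    mags[i] = 0
            assert not comp.pag_extinction(tuple(mags))

    def test_order_independence_of_terminal_set(self):
        """Permuting the move-offering order leaves the terminal set intact."""
        exp = experiment(1, 10)
        reference = enumerate_terminals(exp).states
        comp = compile_experiment(exp)
        rng = random.Random(7)
        for _ in range(3):
            moves_c = list(comp.conditioning_moves)
            moves_e = list(comp.extinction_moves)
            rng.shuffle(moves_c)
            rng.shuffle(moves_e)
            comp.conditioning_moves = tuple(moves_c)
            comp.extinction_moves = tuple(moves_e)
            from amygsearch.search import enumerate_terminals as et

            assert et(comp).states == reference

    def test_atlas_tsv_has_one_row_per_configuration(self, toy):
        ts = enumerate_terminals(toy)
        lines = ts.to_tsv().strip().splitlines()
        assert len(lines) == 2 + len(ts)  # provenance + header + rows
        assert "record:wCStoCEm" in lines[1]
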