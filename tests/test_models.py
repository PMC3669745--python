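"""Model library: printed circuits, schedules, registry arithmetic."""

import pytest

from amygsearch import experiment, model1, model2, remove_elements, validate_circuit
from amygsearch.circuit import CircuitError, Context
from amygsearch.models import DECREASE, INCREASE, registry_rows


class TestModel1:
    def test_nine_modifiable_weights(self):
        spec, sched = model1()
        modifiable = [c.name for c in spec.connections if c.modifiable]
        assert len(modifiable) == 9
        assert "wUStoLA2" not in modifiable and "wCEmtoPAG" not in modifiable

    def test_baseline_schedule_directions(self):
        spec, sched = model1()
        for c in spec.connections:
            if c.modifiable:
                assert sched.conditioning_moves(c.name) == {INCREASE}
                assert sched.extinction_moves(c.name) == {DECREASE}
            else:
                assert not sched.conditioning_moves(c.name)
                assert not sched.extinction_moves(c.name)

    def test_records_tracked_for_interneuron_weights(self):
        spec, _ = model1()
        tracked = [c.name for c in spec.connections if c.record_tracked]
        assert sorted(tracked) == ["wLAi1toLA1", "wLAi2toLA2"]

    def test_initial_magnitudes(self):
        spec, _ = model1()
        for c in spec.connections:
            expected = 0 if c.name in ("wCStoLA1", "wCStoLA2") else 1
            assert c.initial_magnitude == expected


class TestModel2:
    def test_il_weights_move_only_in_extinction(self):
        _, sched = model2()
        for n in ("wILtoLAi", "wILtoITCl", "wILtoITCm"):
            assert not sched.conditioning_moves(n)
            assert sched.extinction_moves(n) == {INCREASE}

    def test_fixed_connections(self):
        spec, _ = model2()
        fixed = {c.name for c in spec.connections if not c.modifiable}
        assert fixed == {"wUStoLAi", "wUStoLA1", "wUStoLA2", "wITCltoITCm",
                         "wITCmtoCEm", "wCEmtoPAG"}

    def test_single_record(self):
        spec, _ = model2()
        assert [c.name for c in spec.connections if c.record_tracked] == ["wLAitoLA1"]


class TestConfigurationSpaceSizes:
    """The registry arithmetic behind the printed state-space sizes."""

    @pytest.mark.parametrize(
        "model_id, row_id, size",
        [
            (1, 1, 78_732),   # 3^9 x 2^2
            (2, 1, 39_366),   # 3^9 x 2
            (1, 7, 26_244),   # 3^8 x 2^2
            (1, 10, 324),     # 3^4 x 2^2
            (1, 12, 108),     # 3^3 x 2^2
        ],
    )
    def test_printed_sizes(self, model_id, row_id, size):
        assert experiment(model_id, row_id).configuration_space_size() == size


class TestRegistry:
    def test_thirteen_rows_per_model(self):
        assert set(registry_rows(1)) == set(range(1, 14))
        assert set(registry_rows(2)) == set(range(1, 14))

    def test_unknown_row_rejected(self):
        with pytest.raises(KeyError):
            experiment(1, 14)
        with pytest.raises(KeyError):
            experiment(3, 1)

    def test_row7_freezes_itcm_weight(self):
        exp = experiment(1, 7)
        assert not exp.schedule.conditioning_moves("wITCmtoCEm")
        assert not exp.schedule.extinction_moves("wITCmtoCEm")

    def test_row9_cs_weights_ltp_only_in_extinction(self):
        exp = experiment(1, 9)
        assert not exp.schedule.conditioning_moves("wCStoLA1")
        assert exp.schedule.extinction_moves("wCStoLA1") == {INCREASE}
        assert exp.schedule.conditioning_moves("wCStoLA2") == {INCREASE}
        assert exp.schedule.extinction_moves("wCStoLA2") == {INCREASE}

    def test_model2_tie_groups_rows_8_to_12(self):
        groups = {rid: experiment(2, rid).tie_groups for rid in (8, 9, 10, 11, 12)}
        assert len(groups[8]) == 3
        assert len(groups[10]) == 2 and len(groups[11]) == 2 and len(groups[12]) == 2
        flat12 = {n for g in groups[12] for n in g}
        assert "wILtoLAi" not in flat12  # IL weights free in row 12

    def test_filters_reference_present_connections(self):
        for model_id in (1, 2):
            for rid in registry_rows(model_id):
                exp = experiment(model_id, rid)
                circ = exp.circuit()
                for f in exp.filters:
                    for arg in f[1:]:
                        assert (
                            arg in circ.connection_index or arg in circ.elements
                        ), f"{model_id}/{rid}: {arg}"


class TestRemoveElements:
    def test_ba_removal_silences_itcm_route(self):
        spec, _ = model1()
        edited = remove_elements(spec, ("BA1", "BA2"))
        circ = validate_circuit(edited)
        act = circ.activities({}, Context(CS=1))
        assert act["ITCm"] == 0 and act["CEm"] == 0

    def test_remove_nothing_is_identity(self):
        spec, _ = model1()
        assert remove_elements(spec, ()) == spec

    def test_remove_unknown_rejected(self):
        spec, _ = model1()
        with pytest.raises(CircuitError):
            remove_elements(spec, ("Nucleus",))

    def test_remove_input_rejected(self):
        spec, _ = model1()
        with pytest.raises(CircuitError):
            remove_elements(spec, ("CS",))
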