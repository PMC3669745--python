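"""The two published amygdala circuits and the registry of search conditions.

Model 1 (two parallel Fear / No Fear pathways through LA and BA) and Model 2
(a single pathway through LA with infralimbic input and the intercalated cell
masses) are built here with their printed biases, initial weights and
plasticity schedules.  ``experiment(model_id, row_id)`` returns one of the 26
registered search conditions (13 per model), each combining a schedule
variant, optional structural edits or tie groups, and terminal-state filters,
together with its published configuration count for regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .circuit import (
    Circuit,
    CircuitSpec,
    CircuitError,
    ConnectionSpec,
    Context,
    ElementSpec,
    INPUT,
    INTERNAL,
    OUTPUT_GATE,
    validate_circuit,
)

__all__ = [
    "PlasticitySchedule",
    "Experiment",
    "model1",
    "model2",
    "experiment",
    "remove_elements",
    "registry_rows",
    "MODEL1_ROWS",
    "MODEL2_ROWS",
]

logger = logging.getLogger(__name__)

INCREASE = "increase"
DECREASE = "decrease"


@dataclass(frozen=True)
class PlasticitySchedule:
    """Allowed unit-step directions per connection, per learning phase.

    A direction refers to weight *magnitude*: ``increase`` is LTP (excitatory
    weights more positive, inhibitory more negative), ``decrease`` is LTD.
    Steps have absolute value 1 and may never leave the magnitude range [0, 2].
    Non-modifiable connections have empty move sets.
    """

    conditioning: dict[str, frozenset]
    extinction: dict[str, frozenset]

    def moves(self, phase_moves: dict[str, frozenset], name: str) -> frozenset:
        return phase_moves.get(name, frozenset())

    def conditioning_moves(self, name: str) -> frozenset:
        return self.conditioning.get(name, frozenset())

    def extinction_moves(self, name: str) -> frozenset:
        return self.extinction.get(name, frozenset())

    def with_moves(
        self,
        name: str,
        *,
        conditioning: set | frozenset | None = None,
        extinction: set | frozenset | None = None,
    ) -> "PlasticitySchedule":
        cond = dict(self.conditioning)
        ext = dict(self.extinction)
        if conditioning is not None:
            cond[name] = frozenset(conditioning)
        if extinction is not None:
            ext[name] = frozenset(extinction)
        return PlasticitySchedule(cond, ext)

    def frozen(self, *names: str) -> "PlasticitySchedule":
        """Disallow all moves for the named connections."""
        sched = self
        for n in names:
            sched = sched.with_moves(n, conditioning=frozenset(), extinction=frozenset())
        return sched

    def restricted_to(self, names) -> "PlasticitySchedule":
        keep = set(names)
        return PlasticitySchedule(
            {n: m for n, m in self.conditioning.items() if n in keep},
            {n: m for n, m in self.extinction.items() if n in keep},
        )

    def active_connections(self) -> tuple[str, ...]:
        """Connections with at least one allowed move in either phase."""
        out = []
        for n in dict.fromkeys(list(self.conditioning) + list(self.extinction)):
            if self.conditioning.get(n) or self.extinction.get(n):
                out.append(n)
        return tuple(out)


@dataclass(frozen=True)
class Experiment:
    """One search condition: circuit + schedule + tie groups + filters."""

    model_id: int
    row_id: int
    description: str
    spec: CircuitSpec
    schedule: PlasticitySchedule
    tie_groups: tuple[tuple[str, ...], ...] = ()
    filters: tuple[tuple, ...] = ()  # (name, *args) resolved by queries module
    expected_count: int | None = None
    rectify: bool = False
    # extra connections whose post-conditioning magnitudes are snapshotted on
    # top of the circuit's own record-tracked set (outcome-filter variants)
    extra_records: tuple[str, ...] = ()
    conditioning_context: Context = Context(US=0, CS=1, IL=0)
    extinction_context: Context = Context(US=0, CS=1, IL=1)

    def circuit(self) -> Circuit:
        return validate_circuit(self.spec, rectify=self.rectify)

    def record_connections(self) -> tuple[str, ...]:
        circ = self.circuit()
        present = set(circ.connection_index)
        base = tuple(n for n in circ.record_tracked if n in present)
        return base + tuple(n for n in self.extra_records if n not in base)

    def configuration_space_size(self) -> int:
        """3^(free weight units) x 2^(two-valued weight records).

        A tie group counts as a single three-level unit.  A record parameter
        contributes a factor 2 when its weight can take one conditioning step
        (its post-conditioning value is then either the initial or the
        potentiated magnitude).
        """
        grouped: set[str] = set()
        units = 0
        group_of = {}
        for group in self.tie_groups:
            for n in group:
                group_of[n] = group
        counted_groups: set[tuple[str, ...]] = set()
        for name in self.schedule.active_connections():
            if name in group_of:
                g = group_of[name]
                if g not in counted_groups:
                    counted_groups.add(g)
                    units += 1
            else:
                units += 1
        records = 0
        for name in self.record_connections():
            if INCREASE in self.schedule.conditioning_moves(name):
                records += 1
        return 3**units * 2**records


# ---------------------------------------------------------------------------
# Model 1 (Fear / No Fear pathways; LA -> BA -> {CEm, ITCm} -> CEm -> PAG)
# ---------------------------------------------------------------------------


def _model1_spec() -> CircuitSpec:
    elements = (
        ElementSpec("US", 0, INPUT),
        ElementSpec("CS", 0, INPUT),
        ElementSpec("LA1", 2),
        ElementSpec("LA2", 2),
        ElementSpec("LAi1", 1),
        ElementSpec("LAi2", 1),
        ElementSpec("BA1", 0),
        ElementSpec("BA2", 0),
        ElementSpec("ITCm", 0),
        ElementSpec("CEm", 0),
        ElementSpec("PAG", 0, OUTPUT_GATE),
    )
    connections = (
        ConnectionSpec("CS", "LA1", +1, 0, modifiable=True),
        ConnectionSpec("CS", "LA2", +1, 0, modifiable=True),
        ConnectionSpec("US", "LA2", +1, 1),
        ConnectionSpec("LAi1", "LA1", -1, 1, modifiable=True, record_tracked=True),
        ConnectionSpec("LAi2", "LA2", -1, 1, modifiable=True, record_tracked=True),
        ConnectionSpec("LA1", "BA1", +1, 1, modifiable=True),
        ConnectionSpec("BA1", "ITCm", +1, 1, modifiable=True),
        ConnectionSpec("LA2", "BA2", +1, 1, modifiable=True),
        ConnectionSpec("BA2", "CEm", +1, 1, modifiable=True),
        ConnectionSpec("ITCm", "CEm", -1, 1, modifiable=True),
        ConnectionSpec("CEm", "PAG", +1, 1),
    )
    return CircuitSpec(elements, connections)


def _baseline_schedule(spec: CircuitSpec) -> PlasticitySchedule:
    cond = {}
    ext = {}
    for c in spec.connections:
        if c.modifiable:
            cond[c.name] = frozenset({INCREASE})
            ext[c.name] = frozenset({DECREASE})
        else:
            cond[c.name] = frozenset()
            ext[c.name] = frozenset()
    return PlasticitySchedule(cond, ext)


def model1() -> tuple[CircuitSpec, PlasticitySchedule]:
    """Model 1 spec and its baseline schedule (LTP in conditioning, LTD in
    extinction, for all 9 modifiable weights)."""
    spec = _model1_spec()
    return spec, _baseline_schedule(spec)


# ---------------------------------------------------------------------------
# Model 2 (single pathway with LAi interneuron, ITC masses and IL input)
# ---------------------------------------------------------------------------


def _model2_spec() -> CircuitSpec:
    elements = (
        ElementSpec("US", 0, INPUT),
        ElementSpec("CS", 0, INPUT),
        ElementSpec("IL", 0, INPUT),
        ElementSpec("LAi", 1),
        ElementSpec("LA1", 2),
        ElementSpec("LA2", 1),
        ElementSpec("ITCl", -1),
        ElementSpec("ITCm", 2),
        ElementSpec("CEm", 1),
        ElementSpec("PAG", 0, OUTPUT_GATE),
    )
    connections = (
        ConnectionSpec("CS", "LAi", +1, 0, modifiable=True),
        ConnectionSpec("CS", "LA1", +1, 0, modifiable=True),
        ConnectionSpec("CS", "LA2", +1, 0, modifiable=True),
        ConnectionSpec("US", "LAi", +1, 1),
        ConnectionSpec("US", "LA1", +1, 1),
        ConnectionSpec("US", "LA2", +1, 1),
        ConnectionSpec("IL", "LAi", +1, 0, modifiable=True),
        ConnectionSpec("IL", "ITCl", +1, 0, modifiable=True),
        ConnectionSpec("IL", "ITCm", +1, 0, modifiable=True),
        ConnectionSpec("LAi", "LA1", -1, 1, modifiable=True, record_tracked=True),
        ConnectionSpec("LA1", "ITCl", +1, 1, modifiable=True),
        ConnectionSpec("LA2", "ITCl", +1, 1, modifiable=True),
        ConnectionSpec("ITCl", "ITCm", -1, 1),
        ConnectionSpec("ITCm", "CEm", -1, 1),
        ConnectionSpec("CEm", "PAG", +1, 1),
    )
    return CircuitSpec(elements, connections)


#: the six Model 2 weights with conditioning LTP / extinction LTD
_M2_COND = ("wCStoLAi", "wCStoLA1", "wCStoLA2", "wLAitoLA1", "wLA1toITCl", "wLA2toITCl")
#: the three infralimbic weights, LTP during extinction only
_M2_IL = ("wILtoLAi", "wILtoITCl", "wILtoITCm")


def model2() -> tuple[CircuitSpec, PlasticitySchedule]:
    """Model 2 spec and baseline schedule: the six CS/LA-pathway weights take
    LTP in conditioning and LTD in extinction; the three IL weights take LTP
    during extinction only and never move during conditioning."""
    spec = _model2_spec()
    cond = {c.name: frozenset() for c in spec.connections}
    ext = {c.name: frozenset() for c in spec.connections}
    for n in _M2_COND:
        cond[n] = frozenset({INCREASE})
        ext[n] = frozenset({DECREASE})
    for n in _M2_IL:
        ext[n] = frozenset({INCREASE})
    return spec, PlasticitySchedule(cond, ext)


# ---------------------------------------------------------------------------
# Structural edits
# ---------------------------------------------------------------------------


def remove_elements(spec: CircuitSpec, names) -> CircuitSpec:
    """Remove elements and every incident connection.

    Removing a unit that orphans the path to the output gate is permitted (the
    Model 1 BA-removal variant deliberately does exactly that) but logged.
    """
    names = set(names)
    present = {e.name for e in spec.elements}
    unknown = names - present
    if unknown:
        raise CircuitError(f"cannot remove unknown elements: {sorted(unknown)}")
    for e in spec.elements:
        if e.name in names and e.kind != INTERNAL:
            raise CircuitError(f"cannot remove {e.kind} element {e.name}")
    elements = tuple(e for e in spec.elements if e.name not in names)
    connections = tuple(
        c for c in spec.connections if c.source not in names and c.target not in names
    )
    edited = CircuitSpec(elements, connections)
    targets = {c.target for c in connections}
    for e in elements:
        if e.kind == INTERNAL and e.name not in targets and any(
            c.target == e.name for c in spec.connections
        ):
            logger.warning("element %s lost all of its inputs", e.name)
    return edited


# ---------------------------------------------------------------------------
# Experiment registry (Table rows)
# ---------------------------------------------------------------------------

_LTD = "ltd_of"
_FINALS_EQ = "finals_equal"
_RECORDS_EQ = "records_equal"
_ANY_EXCITED = "any_excited"
_NOT_INHIB = "not_inhibited_by_cs"

MODEL1_ROWS: dict[int, tuple[str, int]] = {
    1: ("no conditions beyond the baseline schedule", 19273),
    2: ("1 and LTD of wLAi1toLA1", 11310),
    3: ("1 and LTD of wLAi2toLA2", 11761),
    4: ("1 and LTD of both wLAi1toLA1 and wLAi2toLA2", 6914),
    5: ("4 and wLAi1toLA1 equal to wLAi2toLA2 after extinction", 3833),
    6: ("5 and wLAi1toLA1 also equal to wLAi2toLA2 after conditioning", 2315),
    7: ("6 but with no plasticity of wITCmtoCEm", 777),
    8: (
        "7 but with no conditioning of wCStoLA1; LTP and LTD allowed for "
        "wCStoLA1 and wCStoLA2, respectively, during extinction",
        773,
    ),
    9: ("8 but with LTP only allowed for both CS weights during extinction", 619),
    10: (
        "9 but with all modification disallowed for wLA1toBA1, wBA1toITCm, "
        "wLA2toBA2 and wBA2toCEm",
        6,
    ),
    11: (
        "10 with the interneuron weights still equal before and after "
        "extinction but their LTD disallowed",
        3,
    ),
    12: ("10 but with all modification disallowed for wCStoLA1", 0),
    13: ("1 but with BA1 and BA2 removed", 0),
}

MODEL2_ROWS: dict[int, tuple[str, int]] = {
    1: ("no conditions beyond the baseline schedule", 8394),
    2: ("1 and LTD of wLAitoLA1", 4659),
    3: ("2 but with LA1 or LA2 excited by CS after extinction", 2335),
    4: ("3 but with neither LA1 nor LA2 inhibited by CS after extinction", 957),
    5: ("4 but with no LTD of wLA1toITCl or wLA2toITCl", 129),
    6: ("5 but with no modification of the IL weights", 0),
    7: ("6 but with LTD of the LA-to-ITCl weights allowed again", 49),
    8: ("4 with CS, LA and IL weight groups each constrained to be equal", 0),
    9: ("8 but with wLAitoLA1 free not to undergo LTD", 0),
    10: ("4 with LA and IL groups tied, CS weights free", 0),
    11: ("4 with CS and IL groups tied, LA weights free", 21),
    12: ("4 with CS and LA groups tied, IL weights free", 42),
    13: ("4 without the LTD requirement but with LTD of wLAitoLA1 disallowed", 303),
}

_M1_EQ_FILTERS = (
    (_FINALS_EQ, "wLAi1toLA1", "wLAi2toLA2"),
    (_RECORDS_EQ, "wLAi1toLA1", "wLAi2toLA2"),
)
_M2_CS_FILTERS = (
    (_ANY_EXCITED, "LA1", "LA2"),
    (_NOT_INHIB, "LA1"),
    (_NOT_INHIB, "LA2"),
)


def _tie(spec: CircuitSpec, groups: dict[str, tuple[str, ...]]) -> CircuitSpec:
    """Return a copy of ``spec`` with tie-group labels attached."""
    member_of = {}
    for label, members in groups.items():
        for m in members:
            member_of[m] = label
    connections = tuple(
        replace(c, tie_group=member_of.get(c.name, c.tie_group)) for c in spec.connections
    )
    return CircuitSpec(spec.elements, connections)


def _model1_experiment(row_id: int, *, q_flags=None) -> Experiment:
    spec, sched = model1()
    text, expected = MODEL1_ROWS[row_id]
    filters: tuple = ()
    if row_id in (2, 4, 5, 6, 7, 8, 9, 10, 12):
        filters += ((_LTD, "wLAi1toLA1"),)
    if row_id in (3, 4, 5, 6, 7, 8, 9, 10, 12):
        filters += ((_LTD, "wLAi2toLA2"),)
    if row_id in (5, 6, 7, 8, 9, 10, 12):
        filters += ((_FINALS_EQ, "wLAi1toLA1", "wLAi2toLA2"),)
    if row_id in (6, 7, 8, 9, 10, 12):
        filters += ((_RECORDS_EQ, "wLAi1toLA1", "wLAi2toLA2"),)
    if row_id == 11:
        filters = _M1_EQ_FILTERS

    if row_id in (7, 8, 9, 10, 11, 12):
        sched = sched.frozen("wITCmtoCEm")
    if row_id in (8, 9, 10, 11, 12):
        # LCM-style CS plasticity: no conditioning of the No Fear CS weight,
        # extinction LTP for it; the Fear CS weight keeps conditioning LTP.
        sched = sched.with_moves(
            "wCStoLA1", conditioning=frozenset(), extinction={INCREASE}
        )
    if row_id == 8:
        sched = sched.with_moves("wCStoLA2", extinction={DECREASE})
    if row_id in (9, 10, 11, 12):
        sched = sched.with_moves("wCStoLA2", extinction={INCREASE})
    if row_id in (10, 11, 12):
        sched = sched.frozen("wLA1toBA1", "wBA1toITCm", "wLA2toBA2", "wBA2toCEm")
    if row_id == 11:
        sched = sched.with_moves("wLAi1toLA1", extinction=frozenset())
        sched = sched.with_moves("wLAi2toLA2", extinction=frozenset())
    if row_id == 12:
        sched = sched.frozen("wCStoLA1")
    if row_id == 13:
        spec = remove_elements(spec, ("BA1", "BA2"))
        sched = sched.restricted_to([c.name for c in spec.connections])
        filters = ()

    return Experiment(
        model_id=1,
        row_id=row_id,
        description=text,
        spec=spec,
        schedule=sched,
        filters=filters,
        expected_count=expected,
        extinction_context=Context(US=0, CS=1, IL=0),
    )


def _model2_experiment(
    row_id: int, *, q5_outcome_filter: bool = False, equality_as_filter: bool = False
) -> Experiment:
    spec, sched = model2()
    text, expected = MODEL2_ROWS[row_id]
    filters: tuple = ()
    tie_groups: tuple[tuple[str, ...], ...] = ()
    extra_records: tuple[str, ...] = ()

    if row_id >= 2 and row_id not in (9, 13):
        filters += ((_LTD, "wLAitoLA1"),)
    if row_id >= 3:
        filters += ((_ANY_EXCITED, "LA1", "LA2"),)
    if row_id >= 4:
        filters += ((_NOT_INHIB, "LA1"), (_NOT_INHIB, "LA2"))

    if row_id in (5, 6):
        if q5_outcome_filter:
            # alternate reading: allow the moves but demand no net LTD in the
            # terminal state (needs extra record parameters)
            extra_records = ("wLA1toITCl", "wLA2toITCl")
            filters += (("no_ltd_of", "wLA1toITCl"), ("no_ltd_of", "wLA2toITCl"))
        else:
            sched = sched.with_moves("wLA1toITCl", extinction=frozenset())
            sched = sched.with_moves("wLA2toITCl", extinction=frozenset())
    if row_id in (6, 7):
        sched = sched.frozen(*_M2_IL)
    if row_id == 13:
        sched = sched.with_moves("wLAitoLA1", extinction=frozenset())

    groups: dict[str, tuple[str, ...]] = {}
    if row_id in (8, 9, 11, 12):
        groups["cs"] = ("wCStoLAi", "wCStoLA1", "wCStoLA2")
    if row_id in (8, 9, 10, 12):
        groups["la"] = ("wLA1toITCl", "wLA2toITCl")
    if row_id in (8, 9, 10, 11):
        groups["il"] = _M2_IL
    if groups:
        if equality_as_filter:
            for members in groups.values():
                filters += ((_FINALS_EQ,) + members,)
        else:
            spec = _tie(spec, groups)
            tie_groups = tuple(groups.values())

    return Experiment(
        model_id=2,
        row_id=row_id,
        description=text,
        spec=spec,
        schedule=sched,
        tie_groups=tie_groups,
        filters=filters,
        expected_count=expected,
        extra_records=extra_records,
    )


def experiment(
    model_id: int,
    row_id: int,
    *,
    rectify: bool = True,
    q5_outcome_filter: bool = False,
    equality_as_filter: bool = False,
) -> Experiment:
    """Return the registered search condition for a table row.

    The keyword flags select documented alternate semantics (diagnostic modes):
    ``rectify`` (default) floors activities at zero -- the calibrated default,
    selected because the published baseline configuration counts discriminate
    the floored from the purely linear semantics; ``q5_outcome_filter`` reads
    the "no LTD of the LA-to-ITCl weights" condition as a terminal-state filter
    instead of a schedule restriction; ``equality_as_filter`` reads the Model 2
    equality constraints as terminal filters instead of tied joint updates.
    """
    if model_id == 1:
        if row_id not in MODEL1_ROWS:
            raise KeyError(f"Model 1 has no row {row_id}")
        exp = _model1_experiment(row_id)
    elif model_id == 2:
        if row_id not in MODEL2_ROWS:
            raise KeyError(f"Model 2 has no row {row_id}")
        exp = _model2_experiment(
            row_id,
            q5_outcome_filter=q5_outcome_filter,
            equality_as_filter=equality_as_filter,
        )
    else:
        raise KeyError(f"unknown model id {model_id}")
    return replace(exp, rectify=rectify)


def registry_rows(model_id: int) -> dict[int, tuple[str, int]]:
    if model_id == 1:
        return dict(MODEL1_ROWS)
    if model_id == 2:
        return dict(MODEL2_ROWS)
    raise KeyError(f"unknown model id {model_id}")
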