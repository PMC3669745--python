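import pytest

from amygsearch import (
    CircuitSpec,
    ConnectionSpec,
    ElementSpec,
    enumerate_terminals,
    experiment,
    model1,
    model2,
    validate_circuit,
)
from amygsearch.circuit import INPUT, OUTPUT_GATE
from amygsearch.models import Experiment, PlasticitySchedule


@pytest.fixture(scope="session")
def m1_circuit():
    spec, _ = model1()
    return validate_circuit(spec)


@pytest.fixture(scope="session")
def m2_circuit():
    spec, _ = model2()
    return validate_circuit(spec)


@pytest.fixture(scope="session")
def m1_baseline_terminals():
    """Baseline Model 1 terminal set (enumerated once per session)."""
    return enumerate_terminals(experiment(1, 1))


@pytest.fixture(scope="session")
def m2_baseline_terminals():
    return enumerate_terminals(experiment(2, 1))


def toy_experiment() -> Experiment:
    """Single excitatory weight from CS straight to CEm: conditioning is one
    LTP step (CEm = 1 under CS), extinction one LTD step back.  The terminal
    set is computable by hand."""
    spec = CircuitSpec(
        elements=(
            ElementSpec("CS", 0, INPUT),
            ElementSpec("CEm", 0),
            ElementSpec("PAG", 0, OUTPUT_GATE),
        ),
        connections=(
            ConnectionSpec("CS", "CEm", +1, 0, modifiable=True, record_tracked=True),
            ConnectionSpec("CEm", "PAG", +1, 1),
        ),
    )
    sched = PlasticitySchedule(
        conditioning={"wCStoCEm": frozenset({"increase"}), "wCEmtoPAG": frozenset()},
        extinction={"wCStoCEm": frozenset({"decrease"}), "wCEmtoPAG": frozenset()},
    )
    return Experiment(
        model_id=1,
        row_id=0,
        description="single-weight toy circuit",
        spec=spec,
        schedule=sched,
    )


@pytest.fixture
def toy():
    return toy_experiment()
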