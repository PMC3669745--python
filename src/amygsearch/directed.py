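"""Real-valued directed search over weight-change vectors (cross-check).

The integer enumeration necessarily restricts weights to three levels.  As a
check that this restriction does not drive the conclusions, a derivative-free
pattern search is run over *real-valued* weight changes: each modifiable
connection gets a conditioning change and an extinction change (in magnitude
space), constrained so the weight stays in [0, 2] at every stage; a stricter
mode additionally forces the changes to respect the integer schedule's allowed
directions.  The objective is the sum
of absolute differences between desired and actual binary fear-gate responses
in the unconditioned, conditioned and extinguished cases.  Searches start from
uniform random feasible points; each probes every parameter by +/-delta,
doubles delta on improvement and halves it otherwise, terminating when delta
falls below 1e-6.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .models import DECREASE, Experiment, INCREASE, experiment as registry_experiment
from .search import compile_experiment

__all__ = [
    "ChangeSet",
    "PatternSearchConfig",
    "RunRecord",
    "BatchSummary",
    "error",
    "sample_start",
    "pattern_search",
    "batch_search",
]

_LTD_MARKER = {1: "wLAi1toLA1", 2: "wLAitoLA1"}
_EPS_LTD = 1e-9


@dataclass(frozen=True)
class _Parameterization:
    """Feasible-box structure for one experiment.

    For each modifiable connection there are up to two free parameters,
    ``delta_cond`` and ``delta_ext``.  Direction constraints mirror the
    integer schedule: conditioning changes are >= 0 where only LTP is allowed
    (and 0 where conditioning is frozen); extinction changes are <= 0 where
    only LTD is allowed, >= 0 where only LTP is allowed, 0 where frozen.
    """

    names: tuple[str, ...]
    initial: tuple[float, ...]
    cond_dirs: tuple[int, ...]  # +1, -1, or 0 = frozen
    ext_dirs: tuple[int, ...]


def _parameterize(exp: Experiment, *, constrain_directions: bool = False) -> _Parameterization:
    comp = compile_experiment(exp)
    names, init, cdirs, edirs = [], [], [], []

    def dir_of(moves) -> int:
        if not moves:
            return 0
        if moves == {INCREASE} or moves == frozenset({INCREASE}):
            return +1
        if moves == {DECREASE} or moves == frozenset({DECREASE}):
            return -1
        return 2  # both directions free

    for conn in comp.circuit.connections:
        c = exp.schedule.conditioning_moves(conn.name)
        e = exp.schedule.extinction_moves(conn.name)
        if not c and not e:
            continue
        names.append(conn.name)
        init.append(float(conn.initial_magnitude))
        if constrain_directions:
            cdirs.append(dir_of(c))
            edirs.append(dir_of(e))
        else:
            cdirs.append(2 if c else 0)
            edirs.append(2 if e else 0)
    return _Parameterization(tuple(names), tuple(init), tuple(cdirs), tuple(edirs))


@dataclass
class ChangeSet:
    """Per-connection real-valued conditioning and extinction changes."""

    names: tuple[str, ...]
    delta_cond: np.ndarray
    delta_ext: np.ndarray

    def as_dict(self) -> dict[str, dict[str, float]]:
        return {
            n: {"delta_cond": float(c), "delta_ext": float(e)}
            for n, c, e in zip(self.names, self.delta_cond, self.delta_ext)
        }


@dataclass
class PatternSearchConfig:
    """Tunables of the pattern search.

    ``initial_step`` is the starting probe size delta (0.5 spans a quarter of
    the [0, 2] magnitude range); ``termination_tol`` is the delta below which
    a search stops (1e-6); ``restarts`` the number of independent seeded
    searches in a batch (1000).
    """

    initial_step: float = 0.5
    termination_tol: float = 1e-6
    restarts: int = 1000
    rng_seed: int = 0
    probe_mode: str = "two_sided"  # or "one_sided"
    binary_response: bool = True
    constrain_directions: bool = False

    def __post_init__(self) -> None:
        if not self.initial_step > self.termination_tol > 0:
            raise ValueError("require initial_step > termination_tol > 0")
        if self.probe_mode not in ("two_sided", "one_sided"):
            raise ValueError(f"unknown probe_mode {self.probe_mode!r}")


def _feasible_cond_interval(par: _Parameterization, i: int) -> tuple[float, float]:
    m0 = par.initial[i]
    lo, hi = -m0, 2.0 - m0
    d = par.cond_dirs[i]
    if d == 0:
        return 0.0, 0.0
    if d == +1:
        lo = max(lo, 0.0)
    elif d == -1:
        hi = min(hi, 0.0)
    return lo, hi


def _feasible_ext_interval(par: _Parameterization, i: int, dc: float) -> tuple[float, float]:
    m1 = par.initial[i] + dc
    lo, hi = -m1, 2.0 - m1
    d = par.ext_dirs[i]
    if d == 0:
        return 0.0, 0.0
    if d == +1:
        lo = max(lo, 0.0)
    elif d == -1:
        hi = min(hi, 0.0)
    return lo, hi


def sample_start(rng: np.random.Generator, experiment: Experiment, **kw) -> ChangeSet:
    """Uniform draw over the constrained space of weight changes: each
    conditioning change uniform on its feasible interval, then each extinction
    change uniform on its conditional interval."""
    par = _parameterize(experiment, **kw)
    n = len(par.names)
    dc = np.zeros(n)
    de = np.zeros(n)
    for i in range(n):
        lo, hi = _feasible_cond_interval(par, i)
        dc[i] = rng.uniform(lo, hi) if hi > lo else lo
        lo, hi = _feasible_ext_interval(par, i, dc[i])
        de[i] = rng.uniform(lo, hi) if hi > lo else lo
    return ChangeSet(par.names, dc, de)


class _Objective:
    """Error of a change set: desired vs. actual gate responses in the
    unconditioned (initial weights, cue on), conditioned (post-LTP weights)
    and extinguished (post-LTP-and-LTD weights) cases."""

    def __init__(self, exp: Experiment, par: _Parameterization, binary_response: bool):
        self.comp = compile_experiment(exp)
        self.par = par
        self.binary = binary_response
        circ = self.comp.circuit
        self.slots = tuple(circ.connection_index[n] for n in par.names)
        self.base = list(float(m) for m in circ.initial_magnitudes)
        cc, ec = exp.conditioning_context, exp.extinction_context
        self.cond_ctx = (cc.US, cc.CS, cc.IL)
        self.ext_ctx = (ec.US, ec.CS, ec.IL)
        self.gate_slot = circ.element_index[circ.output_gate]
        # CEm feeds the gate; for the continuous variant we need its drive
        self._cached_unconditioned = self._response(self.base, self.cond_ctx)

    def _response(self, mags, ctx) -> float:
        act, pag = self.comp.circuit._evaluate(mags, *ctx)
        if self.binary:
            return 1.0 if pag else 0.0
        # continuous variant: gate drive clamped below at zero
        drive = 0.0
        for src, ci, sign in next(
            p[2] for p in self.comp.circuit._plan if p[0] == self.gate_slot
        ):
            drive += sign * mags[ci] * act[src]
        return max(drive, 0.0)

    def __call__(self, dc: np.ndarray, de: np.ndarray) -> float:
        conditioned = list(self.base)
        for i, s in enumerate(self.slots):
            conditioned[s] += dc[i]
        extinguished = list(conditioned)
        for i, s in enumerate(self.slots):
            extinguished[s] += de[i]
        e = abs(self._cached_unconditioned - 0.0)
        e += abs(self._response(conditioned, self.cond_ctx) - 1.0)
        e += abs(self._response(extinguished, self.ext_ctx) - 0.0)
        return e


def error(change_set: ChangeSet, experiment: Experiment, *, binary_response: bool = True) -> float:
    """Objective value of a change set (0 means conditioning then extinction
    both succeed; the unconditioned case is correct by construction)."""
    par = _parameterize(experiment)
    if tuple(change_set.names) != par.names:
        raise ValueError("change set does not match the experiment's parameters")
    _check_bounds(par, change_set.delta_cond, change_set.delta_ext)
    obj = _Objective(experiment, par, binary_response)
    return obj(change_set.delta_cond, change_set.delta_ext)


def _check_bounds(par: _Parameterization, dc, de) -> None:
    tol = 1e-12
    for i in range(len(par.names)):
        lo, hi = _feasible_cond_interval(par, i)
        if not lo - tol <= dc[i] <= hi + tol:
            raise ValueError(f"delta_cond[{par.names[i]}] outside its feasible interval")
        lo, hi = _feasible_ext_interval(par, i, dc[i])
        if not lo - tol <= de[i] <= hi + tol:
            raise ValueError(f"delta_ext[{par.names[i]}] outside its feasible interval")


def _clip_param(par: _Parameterization, dc, de, kind: str, i: int) -> None:
    """Clip one just-perturbed parameter back into its feasible interval."""
    if kind == "cond":
        lo, hi = _feasible_cond_interval(par, i)
        # keep the pair jointly feasible: m0 + dc + de in [0, 2]
        lo = max(lo, -par.initial[i] - de[i])
        hi = min(hi, 2.0 - par.initial[i] - de[i])
        if par.cond_dirs[i] == +1:
            lo = max(lo, 0.0)
        elif par.cond_dirs[i] == -1:
            hi = min(hi, 0.0)
        dc[i] = min(max(dc[i], lo), hi)
    else:
        lo, hi = _feasible_ext_interval(par, i, dc[i])
        de[i] = min(max(de[i], lo), hi)


@dataclass
class RunRecord:
    final_error: float
    change_set: ChangeSet
    iterations: int
    trace: list[tuple[int, float, float]] = field(default_factory=list)


def pattern_search(
    start: ChangeSet,
    config: PatternSearchConfig,
    experiment: Experiment,
    *,
    keep_trace: bool = False,
) -> RunRecord:
    """Coordinate-probe search with step doubling/halving.

    Each round perturbs, in turn, every free parameter by delta (both signs in
    the default two-sided mode), clipping probes to the feasible box.  If the
    best probe strictly improves the error it is accepted (ties among equally
    lowest probes broken by parameter order) and delta doubles; otherwise
    delta halves.  The search ends when delta < the termination tolerance.
    """
    par = _parameterize(experiment, constrain_directions=config.constrain_directions)
    if tuple(start.names) != par.names:
        raise ValueError("start point does not match the experiment's parameters")
    obj = _Objective(experiment, par, config.binary_response)
    dc = np.array(start.delta_cond, dtype=float)
    de = np.array(start.delta_ext, dtype=float)
    current = obj(dc, de)
    delta = config.initial_step
    signs = (+1.0, -1.0) if config.probe_mode == "two_sided" else (+1.0,)
    iterations = 0
    trace: list[tuple[int, float, float]] = []
    free: list[tuple[str, int]] = []
    for i in range(len(par.names)):
        if par.cond_dirs[i] != 0:
            free.append(("cond", i))
        if par.ext_dirs[i] != 0:
            free.append(("ext", i))
    while delta >= config.termination_tol:
        iterations += 1
        best = current
        best_point = None
        for kind, i in free:
            for sign in signs:
                pdc, pde = dc.copy(), de.copy()
                if kind == "cond":
                    pdc[i] += sign * delta
                else:
                    pde[i] += sign * delta
                _clip_param(par, pdc, pde, kind, i)
                if kind == "cond":
                    # a cond probe can strand de outside its interval
                    _clip_param(par, pdc, pde, "ext", i)
                e = obj(pdc, pde)
                if e < best:
                    best = e
                    best_point = (pdc, pde)
        if best_point is not None:
            dc, de = best_point
            current = best
            delta *= 2.0
        else:
            delta /= 2.0
        if keep_trace:
            trace.append((iterations, delta, current))
    return RunRecord(
        final_error=current,
        change_set=ChangeSet(par.names, dc, de),
        iterations=iterations,
        trace=trace,
    )


@dataclass
class BatchSummary:
    """Outcome of a batch of independent seeded searches."""

    model_id: int
    n_runs: int
    n_zero_error: int
    n_zero_error_with_ltd: int
    config: PatternSearchConfig
    final_errors: list[float] = field(default_factory=list)

    @property
    def ltd_percentage(self) -> float | None:
        """LTD runs as a percentage of zero-error runs; None if no run
        achieved zero error (or the batch is empty)."""
        if self.n_zero_error == 0:
            return None
        return 100.0 * self.n_zero_error_with_ltd / self.n_zero_error

    def to_json(self) -> str:
        return json.dumps(
            {
                "model_id": self.model_id,
                "n_runs": self.n_runs,
                "n_zero_error": self.n_zero_error,
                "n_zero_error_with_ltd": self.n_zero_error_with_ltd,
                "ltd_percentage": self.ltd_percentage,
                "config": {
                    "initial_step": self.config.initial_step,
                    "termination_tol": self.config.termination_tol,
                    "restarts": self.config.restarts,
                    "rng_seed": self.config.rng_seed,
                    "probe_mode": self.config.probe_mode,
                    "binary_response": self.config.binary_response,
                    "constrain_directions": self.config.constrain_directions,
                },
            },
            indent=2,
        )


def batch_search(
    config: PatternSearchConfig, experiment: Experiment | int
) -> BatchSummary:
    """Run ``config.restarts`` independent searches from random feasible
    starts; classify zero-error runs by whether the designated GABAergic
    interneuron weight (wLAi1toLA1 in Model 1, wLAitoLA1 in Model 2) ended
    with a strictly negative extinction change (real-valued LTD)."""
    if isinstance(experiment, int):
        exp = registry_experiment(experiment, 1)
    else:
        exp = experiment
    marker = _LTD_MARKER[exp.model_id]
    rng = np.random.default_rng(config.rng_seed)
    n_zero = 0
    n_zero_ltd = 0
    errors: list[float] = []
    for _ in range(config.restarts):
        start = sample_start(rng, exp, constrain_directions=config.constrain_directions)
        rec = pattern_search(start, config, exp)
        errors.append(rec.final_error)
        if rec.final_error == 0:
            n_zero += 1
            idx = rec.change_set.names.index(marker)
            if rec.change_set.delta_ext[idx] < -_EPS_LTD:
                n_zero_ltd += 1
    return BatchSummary(
        model_id=exp.model_id,
        n_runs=config.restarts,
        n_zero_error=n_zero,
        n_zero_error_with_ltd=n_zero_ltd,
        config=config,
        final_errors=errors,
    )
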