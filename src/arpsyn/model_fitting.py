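"""Global estimation of floated rate constants from pyrene trace sets.

All traces of a reaction set are fitted simultaneously.  Each experimental
trace is first converted to filamentous actin via its calibration; the fit
quality is the normalized mean square weighted sum of squares

    objective = [ sum_traces w_tr * sum_t (x_t - y_t)^2 ] / N_points,
    w_tr = 1 / <x^2>_tr,

where x is the measured and y the simulated polymer concentration and the
per-trace weight equalizes traces of different amplitude.  Floated constants
are searched globally in log space with a seeded population-based optimizer
(differential evolution; log-uniform initialization within bounds) and then
polished locally.  Before pathway fitting, the dimer dissociation constant
(text name k_-1) is re-fit against the set's actin-alone control trace,
mirroring how spontaneous-nucleation constants are anchored per reaction set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution, minimize, minimize_scalar

from arpsyn import reaction_model as rm
from arpsyn.trace_analysis import PolymerizationTrace, TraceSet

#: Dip1 concentration cutoff for synergy fits: only reactions with more Dip1
#: than this are fitted, which justifies omitting Wsp1-alone branching.
SYNERGY_DIP1_CUTOFF_UM = 0.5


@dataclass
class FitBudget:
    """Optimizer effort: total population and number of generations."""

    population: int = 50
    generations: int = 200
    polish: bool = True


@dataclass
class FitResult:
    """Estimates, fixed constants and provenance of one global fit."""

    estimates: dict[str, float]
    fixed: dict[str, float]
    objective_value: float
    algorithm: str
    seed: int
    population: int
    generations: int
    n_evaluations: int
    per_trace_residuals: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------

def trace_weight(filament_uM: np.ndarray) -> float:
    """Per-trace weight w = 1 / <x^2> (mean of squared measured values)."""
    msq = float(np.mean(np.square(filament_uM)))
    if msq <= 0:
        raise ValueError("trace has zero mean square; cannot weight")
    return 1.0 / msq


def objective_value(
    sim: dict[str, np.ndarray],
    data: TraceSet,
    per_trace: dict[str, float] | None = None,
) -> float:
    """Normalized mean square weighted sum of squares over fitted traces.

    ``sim`` maps trace_id -> simulated filamentous actin (uM) on that
    trace's own time grid.  Only traces present in ``sim`` contribute.
    """
    total = 0.0
    n_points = 0
    for tr in data:
        if tr.trace_id not in sim:
            continue
        x = tr.filament_uM()
        y = np.asarray(sim[tr.trace_id], dtype=float)
        if y.shape != x.shape:
            raise ValueError(
                f"trace {tr.trace_id}: simulated grid ({y.shape}) does not "
                f"match data grid ({x.shape})"
            )
        contrib = trace_weight(x) * float(np.sum((x - y) ** 2))
        if per_trace is not None:
            per_trace[tr.trace_id] = contrib
        total += contrib
        n_points += len(x)
    if n_points == 0:
        raise ValueError("no overlapping traces between sim and data")
    return total / n_points


# ---------------------------------------------------------------------------
# Simulation of a trace set under a candidate network
# ---------------------------------------------------------------------------

def _initial_for(trace: PolymerizationTrace) -> dict[str, float]:
    c = trace.condition
    initial = {"G": c.actin_uM}
    if c.arp23_nM > 0 or c.dip1_uM > 0:
        initial["C"] = c.arp23_nM / 1000.0
        initial["D"] = c.dip1_uM
    return initial


def simulate_trace_set(
    net: rm.ReactionNetwork,
    traces: list[PolymerizationTrace],
    rtol: float = 1e-6,
    atol: float = 1e-6,
) -> dict[str, np.ndarray]:
    """Simulated filamentous-actin curves for each trace's condition/grid.

    Uses a slightly looser tolerance than the reporting default; fitting
    needs many thousands of solves and the objective is insensitive below
    the data's noise floor.
    """
    out = {}
    for tr in traces:
        res = rm.simulate(net, _initial_for(tr), tr.time, rtol=rtol, atol=atol)
        out[tr.trace_id] = res.filamentous
    return out


def fittable_traces(net: rm.ReactionNetwork, data: TraceSet) -> list[PolymerizationTrace]:
    """Traces that inform the pathway fit.

    The actin-alone control anchors k_-1 separately and is excluded here;
    synergy variants additionally drop reactions at or below 0.5 uM Dip1.
    """
    selected = []
    synergy = net.variant.startswith("synergy")
    for tr in data:
        c = tr.condition
        if c.arp23_nM == 0 and c.dip1_uM == 0:
            continue
        if synergy and c.dip1_uM <= SYNERGY_DIP1_CUTOFF_UM:
            continue
        selected.append(tr)
    return selected


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def with_floated(net: rm.ReactionNetwork, names: list[str] | set[str]) -> rm.ReactionNetwork:
    """Copy of ``net`` with the named constants flagged floated."""
    out = net.with_values({})
    for name in names:
        p = out.params[name]
        out.params[name] = rm.RateConstant(
            p.name, p.value, fixed=False, bounds=rm.default_bounds(name)
        )
    return out


def refit_k_minus1(net: rm.ReactionNetwork, actin_alone: PolymerizationTrace) -> float:
    """Re-fit the dimer dissociation constant on an actin-alone trace.

    One-dimensional log-space search; returns the refit value (1/s).
    """
    x = actin_alone.filament_uM()
    ctl = rm.build_actin_alone({n: p.value for n, p in net.params.items()
                                if n in rm.SPONTANEOUS_DEFAULTS})

    def loss(log_kd2: float) -> float:
        cand = ctl.with_values({"kd2": 10.0 ** log_kd2})
        try:
            res = rm.simulate(cand, _initial_for(actin_alone), actin_alone.time,
                              rtol=1e-6, atol=1e-6)
        except RuntimeError:
            return 1e12
        return float(np.sum((x - res.filamentous) ** 2))

    opt = minimize_scalar(loss, bounds=(3.0, 7.0), method="bounded",
                          options={"xatol": 1e-3})
    return float(10.0 ** opt.x)


def fit(
    net: rm.ReactionNetwork,
    data: TraceSet,
    seed: int,
    budget: FitBudget | None = None,
    refit_dimer_off: bool = False,
) -> FitResult:
    """Globally fit the network's floated constants to a trace set.

    Differential evolution in log10 space (seeded, log-uniform init) followed
    by a Nelder-Mead polish.  ``refit_dimer_off`` first re-anchors k_-1 on
    the set's actin-alone trace and fails if none is present.
    """
    budget = budget or FitBudget()
    floated = net.floated()
    if not floated:
        raise ValueError("no floated constants in the network")

    if refit_dimer_off:
        ctl = data.actin_alone()
        if ctl is None:
            raise ValueError("k_-1 refit requested but the set has no actin-alone trace")
        net = net.with_values({"kd2": refit_k_minus1(net, ctl)})

    traces = fittable_traces(net, data)
    if not traces:
        raise ValueError("no fittable traces for this variant")
    bounds_log = [tuple(np.log10(net.params[n].bounds)) for n in floated]
    n_eval = 0

    def objective_at(log_values: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        cand = net.with_values(
            {n: 10.0 ** v for n, v in zip(floated, log_values)})
        try:
            sim = simulate_trace_set(cand, traces)
        except RuntimeError:
            return 1e9
        return objective_value(sim, data)

    popsize = max(5, int(round(budget.population / len(floated))))
    result = differential_evolution(
        objective_at, bounds_log, seed=seed, maxiter=budget.generations,
        popsize=popsize, init="latinhypercube", polish=False, tol=1e-10,
        mutation=(0.5, 1.0), recombination=0.7,
    )
    best = result.x
    if budget.polish:
        local = minimize(objective_at, best, method="Nelder-Mead",
                         options={"xatol": 1e-4, "fatol": 1e-12, "maxiter": 400})
        if local.fun <= result.fun:
            best = local.x

    final = net.with_values({n: 10.0 ** v for n, v in zip(floated, best)})
    per_trace: dict[str, float] = {}
    obj = objective_value(simulate_trace_set(final, traces), data, per_trace)
    return FitResult(
        estimates={n: float(final.params[n].value) for n in floated},
        fixed={n: float(p.value) for n, p in final.params.items()
               if n not in floated},
        objective_value=float(obj),
        algorithm="differential_evolution+nelder-mead",
        seed=seed,
        population=budget.population,
        generations=budget.generations,
        n_evaluations=n_eval,
        per_trace_residuals=per_trace,
    )


def constants_in_use(net: rm.ReactionNetwork) -> set[str]:
    """Names of rate constants actually referenced by the network's reactions."""
    used = set()
    for rxn in net.reactions:
        used.add(rxn.forward.name)
        if rxn.reverse is not None:
            used.add(rxn.reverse.name)
    return used


def compare_models(
    data: TraceSet,
    n_list: tuple[int, ...] = (0, 1, 2, 3),
    seed: int = 0,
    budget: FitBudget | None = None,
    float_mask: tuple[str, ...] = ("k11", "km10", "km9"),
) -> pd.DataFrame:
    """Fit each monomer-binding variant with matched budgets; rank by objective.

    Constants in ``float_mask`` that a variant does not use (the 0-monomer
    pathway has no monomer-binding step) are dropped from that variant's
    floated set.  Returns a table ordered as given, with the objective value
    and estimates per variant.
    """
    rows = []
    for n in n_list:
        net = rm.build_dip1_model(n)
        usable = [m for m in float_mask if m in constants_in_use(net)]
        if not usable:
            raise ValueError(f"float mask {float_mask} unusable for n={n}")
        net = with_floated(net, usable)
        res = fit(net, data, seed=seed, budget=budget)
        rows.append({
            "n_monomer_steps": n,
            "objective": res.objective_value,
            "floated": ",".join(usable),
            **{f"est_{k}": v for k, v in res.estimates.items()},
        })
    return pd.DataFrame(rows)
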