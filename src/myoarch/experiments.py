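"""Scenarios, the simulation loop, steady-state detection, in-silico tests.

One simulation step follows the model's fixed ordering: net force on the
bound integrins -> bound-integrin kinetics -> nascent-fiber biasing
potential -> instantaneous redistribution of the free pool -> analytics.
The loop tracks the parallel-coupling average psi_mean(t), the global
nascent orientational order, the per-step integrin-conservation residual
and the global force-balance residual, and stores periodic snapshots of
the fields and the nascent director map.

The in-silico hypothesis battery reruns the built-in shapes with the fiber
length-force dependence (L) and the mutual-alignment potential (tau)
switched on or off, the experiment used to rank the two organizing
mechanisms.
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .domains import DomainLattice, ShapeSpec, make_domain, segment_raster
from .fiber_network import (
    fiber_length_field,
    global_orientation,
    orientation_summary,
    parallel_coupling,
)
from .kinetics import (
    IntegrinState,
    ModelParams,
    redistribute_free_integrin,
    step_bound_integrins,
    total_integrin,
)
from .mechanics import biasing_potential, net_force

__all__ = [
    "Scenario",
    "Snapshot",
    "Trajectory",
    "initial_condition",
    "run_simulation",
    "detect_steady_state",
    "director_stabilization_time",
    "axis_formation_time",
    "hypothesis_battery",
    "builtin_scenarios",
    "BATTERY_CONDITIONS",
]

IC_VARIANTS = ("uniform_random_free", "clustered_free", "seeded_bound", "custom")


@dataclass(frozen=True)
class Scenario:
    """A fully specified run: island, parameters, initial condition, length."""

    name: str
    shape: ShapeSpec
    params: ModelParams = ModelParams()
    resolution: Optional[int] = None
    initial: str = "uniform_random_free"
    seeds: tuple[int, ...] = tuple(range(1, 11))
    snapshot_interval: float = 10.0
    record_interval: float = 5.0
    t_total: Optional[float] = None  # None: params default for the shape

    def __post_init__(self) -> None:
        if self.initial not in IC_VARIANTS:
            raise ValueError(f"unknown initial condition {self.initial!r}")

    def run_length(self) -> float:
        if self.t_total is not None:
            return self.t_total
        if self.shape.kind == "circle":
            return self.params.t_total_circle
        return self.params.t_total


@dataclass
class Snapshot:
    time: float
    state: IntegrinState
    director_n: np.ndarray
    density_n: np.ndarray
    oop_n: np.ndarray
    psi: np.ndarray


@dataclass
class Trajectory:
    scenario: Scenario
    seed: int
    times: np.ndarray
    psi_mean: np.ndarray
    global_oop_n: np.ndarray
    snapshots: list[Snapshot] = field(default_factory=list)
    final_state: Optional[IntegrinState] = None
    conservation_max: float = 0.0
    force_balance_max: float = 0.0
    wall_time: float = 0.0
    domain: Optional[DomainLattice] = None


def initial_condition(
    variant: str,
    domain: DomainLattice,
    params: ModelParams,
    seed: int,
    custom: Optional[IntegrinState] = None,
) -> IntegrinState:
    """Initial integrin fields, normalized to total content phi0 * A.

    ``uniform_random_free`` and ``clustered_free`` start with no bound
    integrin (hence no fibers); ``seeded_bound`` starts with a small set of
    premyofibril-bound seeds so fibers exist from the first step.
    Reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    n = domain.n_points
    total = params.phi0 * domain.area
    zeros = np.zeros(n)
    if variant == "uniform_random_free":
        rho_f = rng.uniform(0.5, 1.5, n)
        rho_p, rho_n = zeros, zeros.copy()
    elif variant == "clustered_free":
        rho_f = np.full(n, 0.1)
        centers = domain.points[rng.integers(0, n, 5)]
        for c in centers:
            d2 = ((domain.points - c) ** 2).sum(-1)
            rho_f = rho_f + np.exp(-d2 / (2 * 0.15**2))
        rho_p, rho_n = zeros, zeros.copy()
    elif variant == "seeded_bound":
        rho_f = np.ones(n)
        centers = domain.points[rng.choice(n, size=max(4, n // 30), replace=False)]
        rho_p = np.zeros(n)
        width = 2.0 * domain.spacing  # soft seeds keep the first step stable
        for c in centers:
            d2 = ((domain.points - c) ** 2).sum(-1)
            rho_p = rho_p + np.exp(-d2 / (2 * width**2))
        rho_n = zeros
        bound_share = 0.05
        rho_p *= bound_share * total / (domain.delta_area * rho_p.sum())
        rho_f *= (1 - bound_share) * total / (domain.delta_area * rho_f.sum())
        return IntegrinState(rho_f, rho_p, rho_n)
    elif variant == "custom":
        if custom is None:
            raise ValueError("custom variant requires an explicit state")
        state = custom.copy()
        scale = total / total_integrin(state, domain.delta_area)
        state.rho_f *= scale
        state.rho_p *= scale
        state.rho_n *= scale
        return state
    else:
        raise ValueError(f"unknown initial condition {variant!r}")
    rho_f *= total / (domain.delta_area * rho_f.sum())
    return IntegrinState(rho_f, rho_p, rho_n)


def run_simulation(
    scenario: Scenario,
    seed: int,
    domain: Optional[DomainLattice] = None,
    custom_ic: Optional[IntegrinState] = None,
) -> Trajectory:
    """Run one scenario realization; raises on numerical instability."""
    t0 = _time.perf_counter()
    p = scenario.params
    if domain is None:
        domain = make_domain(scenario.shape, scenario.resolution)
    raster = segment_raster(domain)
    da = domain.delta_area
    state = initial_condition(scenario.initial, domain, p, seed, custom=custom_ic)
    target = p.phi0 * domain.area

    t_end = scenario.run_length()
    n_steps = int(round(t_end / p.dt))
    rec_every = max(1, int(round(scenario.record_interval / p.dt)))
    snap_every = max(1, int(round(scenario.snapshot_interval / p.dt)))

    times, psis, goops = [], [], []
    snapshots: list[Snapshot] = []
    cons_max = 0.0
    fbal_max = 0.0

    def record(step_state: IntegrinState, snap: bool) -> None:
        field = fiber_length_field(
            step_state, domain, k=p.angular_bins, epsilon=p.epsilon, raster=raster
        )
        summ = orientation_summary(field, "n")
        psi, psi_mean = parallel_coupling(summ)
        _, goop = global_orientation(field, "n")
        times.append(step_state.time)
        psis.append(psi_mean)
        goops.append(goop)
        if snap:
            snapshots.append(
                Snapshot(
                    time=step_state.time,
                    state=step_state.copy(),
                    director_n=summ.director.copy(),
                    density_n=summ.density.copy(),
                    oop_n=summ.oop.copy(),
                    psi=psi,
                )
            )

    record(state, snap=True)
    for step in range(1, n_steps + 1):
        force = net_force(state, domain, p)
        fbal = np.abs(da * force.F.sum(axis=0)).max()
        l1 = da * np.abs(force.F).sum()
        if l1 > 0:
            fbal_max = max(fbal_max, fbal / l1)
        state = step_bound_integrins(state, force.magnitude, p)
        chi = biasing_potential(state, domain, p, raster=raster).chi
        state = redistribute_free_integrin(state, chi, p, da)
        cons_max = max(cons_max, abs(total_integrin(state, da) - target) / target)
        if step % rec_every == 0 or step == n_steps:
            record(state, snap=(step % snap_every == 0 or step == n_steps))

    return Trajectory(
        scenario=scenario,
        seed=seed,
        times=np.asarray(times),
        psi_mean=np.asarray(psis),
        global_oop_n=np.asarray(goops),
        snapshots=snapshots,
        final_state=state,
        conservation_max=cons_max,
        force_balance_max=fbal_max,
        wall_time=_time.perf_counter() - t0,
        domain=domain,
    )


def detect_steady_state(
    times: np.ndarray,
    values: np.ndarray,
    rel_tol: float = 1e-3,
    window: Optional[float] = None,
) -> Optional[float]:
    """Earliest time after which the series stops changing.

    Returns the first time from which every forward window of length
    ``window`` (default: 5% of the series span) has relative range below
    ``rel_tol``; ``None`` if the series never settles.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size != values.size or times.size < 2:
        raise ValueError("need matching series with at least 2 points")
    span = times[-1] - times[0]
    if window is None:
        window = 0.05 * span
    if window > span:
        raise ValueError("detection window exceeds the series span")
    w = max(2, int(np.searchsorted(times, times[0] + window, side="right")))
    if w > times.size:
        raise ValueError("series shorter than the detection window")
    scale = max(np.abs(values).max(), np.finfo(float).tiny)
    n = values.size
    stable = np.zeros(n - w + 1, dtype=bool)
    for i in range(n - w + 1):
        win = values[i : i + w]
        stable[i] = (win.max() - win.min()) <= rel_tol * scale
    # require stability to persist for the rest of the series
    ok = np.flip(np.logical_and.accumulate(np.flip(stable)))
    idx = np.nonzero(ok)[0]
    if idx.size == 0:
        return None
    return float(times[idx[0]])


def _angular_diff(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d = np.abs(a - b) % np.pi
    return np.minimum(d, np.pi - d)


def director_stabilization_time(
    traj: Trajectory,
    tol_deg: float = 5.0,
    density_quantile: float = 0.5,
    min_coverage: float = 20.0,
) -> Optional[float]:
    """First snapshot time after which the high-density nascent director map
    stops changing (every later snapshot-to-snapshot change below
    ``tol_deg`` on points above the ``density_quantile`` of nascent
    density).  ``None`` if stability is never observed or fewer than
    ``min_coverage`` au of stable tail exist."""
    snaps = traj.snapshots
    if len(snaps) < 3:
        raise ValueError("trajectory has too few snapshots")
    tol = np.deg2rad(tol_deg)
    changes = []
    for a, b in zip(snaps[:-1], snaps[1:]):
        thresh = np.quantile(b.density_n, density_quantile)
        sel = (b.density_n >= thresh) & ~np.isnan(a.director_n) & ~np.isnan(b.director_n)
        if not sel.any():
            changes.append(np.pi / 2)
            continue
        changes.append(float(_angular_diff(a.director_n[sel], b.director_n[sel]).max()))
    changes = np.asarray(changes)
    ok = np.flip(np.logical_and.accumulate(np.flip(changes < tol)))
    idx = np.nonzero(ok)[0]
    if idx.size == 0:
        return None
    t = snaps[idx[0]].time
    if snaps[-1].time - t < min_coverage:
        return None
    return float(t)


def axis_formation_time(traj: Trajectory, threshold: float = 0.5) -> Optional[float]:
    """First recorded time at which the global nascent orientational order
    exceeds ``threshold`` and stays above it for the rest of the run."""
    above = traj.global_oop_n > threshold
    ok = np.flip(np.logical_and.accumulate(np.flip(above)))
    idx = np.nonzero(ok)[0]
    if idx.size == 0:
        return None
    return float(traj.times[idx[0]])


#: the toggle grid of the in-silico hypothesis experiment
BATTERY_CONDITIONS: tuple[tuple[str, bool, bool], ...] = (
    ("stair", True, True),
    ("stair", True, False),
    ("stair", False, True),
    ("stair", False, False),
    ("square", True, True),
    ("triangle", True, True),
    ("circle", True, True),
    ("circle", True, False),
)


def _condition_name(kind: str, length_dep: bool, align: bool) -> str:
    return f"{kind}_L{'on' if length_dep else 'off'}_tau{'on' if align else 'off'}"


def builtin_scenarios(params: ModelParams = ModelParams()) -> dict[str, Scenario]:
    """The built-in scenario battery: the four fitted/validated shapes plus
    every toggle condition of the hypothesis experiment."""
    out = {}
    for kind, ld, al in BATTERY_CONDITIONS:
        p = replace(params, length_dependent=ld, alignment=al)
        name = _condition_name(kind, ld, al)
        out[name] = Scenario(name=name, shape=ShapeSpec(kind), params=p)
    return out


def hypothesis_battery(
    seeds: tuple[int, ...] = (1,),
    params: ModelParams = ModelParams(),
    resolution: Optional[int] = None,
    conditions: tuple[tuple[str, bool, bool], ...] = BATTERY_CONDITIONS,
) -> dict[str, list[Trajectory]]:
    """Run the toggle grid; returns trajectories per condition name."""
    results: dict[str, list[Trajectory]] = {}
    domains: dict[str, DomainLattice] = {}
    for kind, ld, al in conditions:
        if kind not in domains:
            domains[kind] = make_domain(ShapeSpec(kind), resolution)
        p = replace(params, length_dependent=ld, alignment=al)
        scen = Scenario(
            name=_condition_name(kind, ld, al),
            shape=ShapeSpec(kind),
            params=p,
            resolution=resolution,
            seeds=tuple(seeds),
        )
        results[scen.name] = [
            run_simulation(scen, s, domain=domains[kind]) for s in seeds
        ]
    return results
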