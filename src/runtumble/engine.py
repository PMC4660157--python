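"""Agent-based population engine.

Advances a population of independent cells through the five-stage per-step
loop: (1) evaluate the ligand field at the cell's position, (2) integrate
the intracellular cascade over one timestep with that ligand held fixed,
(3) map the new CheY-P level to a clockwise (tumble) bias against the
cell's own unstimulated reference, (4) draw the run/tumble decision and
move — a run keeps the heading, a tumble reorients then translates — and
(5) apply the domain boundary rule.

Stochasticity is fully seeded: one master seed spawns an initialization
stream plus one independent stream per cell; every cell consumes exactly
three uniforms per step (decision, turn sign, turn magnitude) whether or
not it tumbles, so trajectories are replayable.

The default 50,000 steps of 0.0144 s correspond to about 12 minutes of
swimming.  The per-cell cascades are stepped together by the vectorised
backward-Euler ensemble integrator.
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field as dc_field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import metrics
from .cascade import (CascadeEnsemble, CascadeParams, CascadeState,
                      default_params, scale_protein_totals, steady_state)
from .fields import (MEASP, SERINE, ExponentialFieldSpec, FieldSpec,
                     TwoLigandFieldSpec, background_concentrations,
                     eval_field_at, field_peak)
from .kinematics import KinematicSpec, apply_boundary, turn_angle_from_uniforms
from .motor import RUN, TUMBLE, MotorSpec, cw_bias

__all__ = ["SimulationConfig", "CellState", "SimulationResult", "Population",
           "initialize_population", "step_cell", "run_simulation",
           "run_beta_sweep", "run_two_ligand_grid"]

_TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce one population simulation."""

    n_cells: int = 100
    n_steps: int = 50_000
    dt: float = 0.0144
    field: FieldSpec = dc_field(default_factory=lambda: ExponentialFieldSpec(
        l0=0.1, d=1.0, center=(0.0, 0.0)))
    cascade: CascadeParams = dc_field(default_factory=default_params)
    beta_values: Tuple[float, ...] = (1.0,)
    motor: MotorSpec = dc_field(default_factory=MotorSpec)
    kinematics: KinematicSpec = dc_field(default_factory=KinematicSpec)
    master_seed: int = 0
    record_stride: int = 50
    init_adaptation: str = "local"  # or "background"
    paired_init: bool = True

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")
        if not self.beta_values or any(b <= 0 for b in self.beta_values):
            raise ValueError("beta_values must be non-empty and positive")
        if self.init_adaptation not in ("local", "background"):
            raise ValueError("init_adaptation must be 'local' or 'background'")


@dataclass
class CellState:
    """Single-cell view of the population state."""

    cell_id: int
    position: Tuple[float, float]
    theta: float
    cascade: CascadeState
    yp_star: float
    beta: float
    rng: np.random.Generator


@dataclass
class Population:
    """Vectorised population state (one row per cell)."""

    x: np.ndarray
    y: np.ndarray
    theta: np.ndarray
    z: np.ndarray              # (n, 4): m, Ap, Bp, Yp
    yp_star: np.ndarray
    betas: np.ndarray
    rngs: List[np.random.Generator]
    ensemble: CascadeEnsemble

    @property
    def n(self) -> int:
        return self.x.shape[0]

    def as_cell_states(self) -> List[CellState]:
        return [CellState(cell_id=i, position=(float(self.x[i]),
                                               float(self.y[i])),
                          theta=float(self.theta[i]),
                          cascade=CascadeState.from_array(self.z[i]),
                          yp_star=float(self.yp_star[i]),
                          beta=float(self.betas[i]), rng=self.rngs[i])
                for i in range(self.n)]


def _field_concentrations(spec: FieldSpec, x, y):
    conc = eval_field_at(spec, (x, y))
    La = np.asarray(conc.get(MEASP, 0.0), dtype=float)
    Ls = np.asarray(conc.get(SERINE, 0.0), dtype=float)
    return La, Ls


def initialize_population(config: SimulationConfig) -> Population:
    """Seeded population: uniform positions and headings, cascades at steady
    state, per-cell reference CheY-P at the background concentration.

    Betas are assigned round-robin from ``config.beta_values`` so the
    subpopulations have (near-)equal size.  With ``paired_init`` (default)
    the uniform initial positions and headings are drawn once per
    round-robin block and shared by all subpopulations, a
    common-random-numbers design that removes initial-position variance
    from comparisons between the beta subpopulations without changing any
    marginal distribution.  With ``init_adaptation == "local"`` (default)
    each cell starts pre-adapted to the ligand level at its initial
    position; ``"background"`` starts all cells adapted to the far-field
    background instead.
    """
    n = config.n_cells
    ss = np.random.SeedSequence(config.master_seed)
    children = ss.spawn(n + 1)
    init_rng = np.random.Generator(np.random.PCG64(children[0]))
    rngs = [np.random.Generator(np.random.PCG64(c)) for c in children[1:]]

    (x0, x1), (y0, y1) = config.kinematics.domain
    k = len(config.beta_values)
    if config.paired_init and k > 1:
        # one uniform draw per round-robin block, shared across the block
        n_blocks = (n + k - 1) // k
        bx = init_rng.uniform(x0, x1, size=n_blocks)
        by = init_rng.uniform(y0, y1, size=n_blocks)
        bt = init_rng.uniform(0.0, _TWO_PI, size=n_blocks)
        block = np.arange(n) // k
        x, y, theta = bx[block], by[block], bt[block]
    else:
        x = init_rng.uniform(x0, x1, size=n)
        y = init_rng.uniform(y0, y1, size=n)
        theta = init_rng.uniform(0.0, _TWO_PI, size=n)
    betas = np.array([config.beta_values[i % len(config.beta_values)]
                      for i in range(n)], dtype=float)

    background = background_concentrations(config.field)
    yp_star = np.empty(n)
    z = np.empty((n, 4))
    ss_cache: Dict[float, CascadeState] = {}
    for i in range(n):
        params_i = scale_protein_totals(config.cascade, betas[i])
        b = betas[i]
        if b not in ss_cache:
            try:
                ss_cache[b] = steady_state(params_i, background)
            except Exception as exc:
                raise RuntimeError(
                    f"steady-state initialization failed for beta={b}: {exc}"
                ) from exc
        yp_star[i] = ss_cache[b].Yp
        if config.init_adaptation == "background":
            z[i] = ss_cache[b].as_array()
        else:
            La, Ls = _field_concentrations(config.field, x[i], y[i])
            local = {MEASP: float(La), SERINE: float(Ls)}
            try:
                z[i] = steady_state(params_i, local).as_array()
            except Exception as exc:
                raise RuntimeError(
                    f"steady-state initialization failed for beta={b}: {exc}"
                ) from exc
    ensemble = CascadeEnsemble(config.cascade, betas)
    return Population(x=x, y=y, theta=theta, z=z, yp_star=yp_star,
                      betas=betas, rngs=rngs, ensemble=ensemble)


def step_cell(cell: CellState, config: SimulationConfig) -> CellState:
    """Advance one cell by one timestep through the five-stage loop.

    Consumes three uniforms from the cell's stream (decision, sign, angle)
    regardless of the decision, matching the population loop draw-for-draw.
    """
    ens = CascadeEnsemble(config.cascade, np.array([cell.beta]))
    La, Ls = _field_concentrations(config.field, *cell.position)
    z = ens.step(cell.cascade.as_array()[None, :], La, Ls, config.dt)
    Yp = float(z[0, 3])
    bias = cw_bias(Yp, config.motor, yp_star=cell.yp_star)
    u = cell.rng.random(3)
    theta = cell.theta
    if bias > u[0]:
        theta = float(np.mod(
            theta + turn_angle_from_uniforms(u[1], u[2], config.kinematics),
            _TWO_PI))
    c = config.kinematics.speed
    x = cell.position[0] + c * np.sin(theta) * config.dt
    y = cell.position[1] + c * np.cos(theta) * config.dt
    x, y = apply_boundary((x, y), config.kinematics)
    return CellState(cell_id=cell.cell_id, position=(float(x), float(y)),
                     theta=theta, cascade=CascadeState.from_array(z[0]),
                     yp_star=cell.yp_star, beta=cell.beta, rng=cell.rng)


@dataclass
class SimulationResult:
    """Trajectory table, summary and timing of one simulation."""

    config: SimulationConfig
    trajectories: pd.DataFrame
    summary: metrics.PopulationSummary
    stage_seconds: Dict[str, float]


def _peaks_of(spec: FieldSpec) -> Dict[str, Tuple[float, float]]:
    try:
        pk = field_peak(spec)
    except Exception:
        return {}
    if isinstance(spec, TwoLigandFieldSpec):
        return {name: pos for name, (pos, _val) in pk.items()}
    return {spec.species: pk[0]}


def run_simulation(config: SimulationConfig,
                   attraction_threshold: Optional[float] = None,
                   chunk: int = 2048) -> SimulationResult:
    """Run the full population simulation.

    Records every ``record_stride``-th step (plus the initial and final
    states) into a tidy trajectory table and summarises it against the
    field's peak(s).  Deterministic for a fixed config.
    """
    pop = initialize_population(config)
    n, kin, motor = pop.n, config.kinematics, config.motor
    dt, c = config.dt, config.kinematics.speed
    timers = {"field": 0.0, "cascade": 0.0, "motor": 0.0, "move": 0.0}

    rec_steps = [0] + [s for s in range(1, config.n_steps + 1)
                       if s % config.record_stride == 0]
    if config.n_steps > 0 and config.n_steps % config.record_stride != 0:
        rec_steps.append(config.n_steps)
    n_rec = len(rec_steps)
    rec = {k: np.empty(n_rec * n) for k in
           ("step", "cell", "beta", "x", "y", "theta", "Yp", "m", "bias")}
    rec_state = np.empty(n_rec * n, dtype=object)
    rec_i = 0

    def record(s, bias, tumble):
        nonlocal rec_i
        sl = slice(rec_i * n, (rec_i + 1) * n)
        rec["step"][sl] = s
        rec["cell"][sl] = np.arange(n)
        rec["beta"][sl] = pop.betas
        rec["x"][sl] = pop.x
        rec["y"][sl] = pop.y
        rec["theta"][sl] = pop.theta
        rec["Yp"][sl] = pop.z[:, 3]
        rec["m"][sl] = pop.z[:, 0]
        rec["bias"][sl] = bias
        rec_state[sl] = np.where(tumble, TUMBLE, RUN)
        rec_i += 1

    bias0 = cw_bias(pop.z[:, 3], motor, yp_star=pop.yp_star)
    record(0, bias0, np.zeros(n, dtype=bool))

    s = 0
    while s < config.n_steps:
        todo = min(chunk, config.n_steps - s)
        U = np.empty((n, todo, 3))
        for i, rng in enumerate(pop.rngs):
            U[i] = rng.random((todo, 3))
        for j in range(todo):
            s += 1
            t0 = _time.perf_counter()
            La, Ls = _field_concentrations(config.field, pop.x, pop.y)
            t1 = _time.perf_counter()
            pop.z = pop.ensemble.step(pop.z, La, Ls, dt)
            t2 = _time.perf_counter()
            bias = 1.0 / (1.0 + motor.prefactor *
                          (pop.yp_star / pop.z[:, 3]) ** motor.hill_exponent)
            tumble = bias > U[:, j, 0]
            t3 = _time.perf_counter()
            dtheta = turn_angle_from_uniforms(U[:, j, 1], U[:, j, 2], kin)
            pop.theta = np.where(tumble,
                                 np.mod(pop.theta + dtheta, _TWO_PI),
                                 pop.theta)
            pop.x = pop.x + c * np.sin(pop.theta) * dt
            pop.y = pop.y + c * np.cos(pop.theta) * dt
            pop.x, pop.y = apply_boundary((pop.x, pop.y), kin)
            t4 = _time.perf_counter()
            timers["field"] += t1 - t0
            timers["cascade"] += t2 - t1
            timers["motor"] += t3 - t2
            timers["move"] += t4 - t3
            if rec_i < n_rec and s == rec_steps[rec_i]:
                record(s, bias, tumble)

    traj = pd.DataFrame({
        "step": rec["step"].astype(int),
        "time_s": rec["step"] * dt,
        "cell": rec["cell"].astype(int),
        "beta": rec["beta"],
        "x": rec["x"], "y": rec["y"], "theta": rec["theta"],
        "Yp": rec["Yp"], "m": rec["m"], "bias": rec["bias"],
        "state": rec_state,
    })
    summary = metrics.summarize(traj, _peaks_of(config.field),
                                attraction_threshold=attraction_threshold)
    return SimulationResult(config=config, trajectories=traj,
                            summary=summary, stage_seconds=timers)


def _combo_seeds(master_seed: int, n: int) -> List[int]:
    """Per-combination child seeds derived from the master seed (< 2^31)."""
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint32)
    return [int(v & 0x7FFFFFFF) for v in state]


def run_beta_sweep(config: SimulationConfig,
                   beta_values: Sequence[float] = (0.25, 0.5, 1, 2, 4, 6, 8, 10),
                   d_values: Sequence[float] = (10.0, 1.0, 0.1),
                   ) -> Dict[float, SimulationResult]:
    """One mixed-beta population simulation per gradient steepness ``d``.

    The field spec in ``config`` must be a single-ligand exponential; its
    ``d`` is replaced per run.  Returns {d: SimulationResult}; the
    per-(beta, d) final mean distances live in each result's summary.
    """
    if not isinstance(config.field, ExponentialFieldSpec):
        raise ValueError("beta sweep requires a single exponential field")
    seeds = _combo_seeds(config.master_seed, len(d_values))
    out: Dict[float, SimulationResult] = {}
    for seed, d in zip(seeds, d_values):
        cfg = replace(config, field=replace(config.field, d=d),
                      beta_values=tuple(beta_values), master_seed=seed)
        out[d] = run_simulation(cfg)
    return out


def run_two_ligand_grid(config: SimulationConfig,
                        omega_values: Sequence[float] = (1.0, 5.0, 10.0),
                        upsilon_values: Sequence[float] = (
                            1e-6, 1e-5, 1e-4, 5e-4, 1e-3, 2.5e-3, 5e-3,
                            7.5e-3, 1e-2, 1e-1),
                        attraction_threshold: float = 0.0,
                        keep_results: bool = False):
    """Competition grid: one simulation per (omega, upsilon) pair.

    Each simulation places the MeAsp bump at (-1, 0) scaled by omega and
    the serine bump at (+1, 0) scaled by upsilon, runs the configured
    population, and classifies final positions.  Returns a tidy DataFrame
    with one row per pair (counts, serine fraction, per-peak accumulation
    ratios); with ``keep_results`` also the dict of full results.
    """
    from .fields import two_ligand_field

    pairs = [(w, u) for w in omega_values for u in upsilon_values]
    seeds = _combo_seeds(config.master_seed, max(len(pairs), 1))
    rows = []
    results = {}
    for seed, (w, u) in zip(seeds, pairs):
        cfg = replace(config, field=two_ligand_field(omega=w, upsilon=u),
                      master_seed=seed)
        res = run_simulation(cfg, attraction_threshold=attraction_threshold)
        counts = res.summary.attraction
        rows.append({
            "omega": w, "upsilon": u,
            "n_meAsp": counts.meAsp, "n_serine": counts.serine,
            "n_boundary": counts.boundary,
            "fraction_serine": counts.fraction_serine,
            "ratio_meAsp": res.summary.ratios[MEASP],
            "ratio_serine": res.summary.ratios[SERINE],
        })
        if keep_results:
            results[(w, u)] = res
    table = pd.DataFrame(rows)
    return (table, results) if keep_results else table
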