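"""Intracellular chemotaxis signalling cascade.

Each cell carries a four-variable ODE model of the canonical E. coli
chemotaxis pathway:

* a mixed Tar/Tsr receptor signalling team whose activity Phi follows a
  two-state (MWC) free-energy balance over ligand occupancy and methylation,
* methylation adaptation (CheR methylates inactive receptors, phosphorylated
  CheB demethylates active ones),
* the phospho-relay: active receptors drive CheA autophosphorylation, CheA-P
  transfers phosphate to CheY and CheB, CheZ (plus a spontaneous term)
  dephosphorylates CheY-P.

State variables: mean methylation level ``m`` (dimensionless) and the
phosphorylated concentrations ``Ap``, ``Bp``, ``Yp`` (uM).

The free energy of a signalling team of ``n_cluster`` receptor dimers is

    F = n * [ alpha*(m0 - m)
              + w_tar * ln((1 + [La]/Koff_tar) / (1 + [La]/Kon_tar))
              + w_tsr * ln((1 + [Ls]/Koff_tsr) / (1 + [Ls]/Kon_tsr)) ]   (kT)

and the team activity is Phi = 1 / (1 + exp(F)).  Attractant binding raises F
and so lowers Phi; methylation lowers F and restores activity, closing the
adaptation loop.  Because the methylation balance pins Phi at a
ligand-independent set point (as long as m stays inside its physical range),
adaptation of CheY-P is near-perfect.

The low-affinity binding of MeAsp to Tsr is neglected, valid at the
concentrations the simulator targets.

All protein totals can be scaled together by a single factor ``beta``,
emulating cell-to-cell variation in expression level while the operon
structure keeps the ratios fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, Mapping, Tuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .fields import MEASP, SERINE

__all__ = [
    "CascadeError",
    "ReceptorSpec",
    "CascadeParams",
    "CascadeState",
    "StepResponse",
    "receptor_free_energy",
    "receptor_activity",
    "cascade_derivatives",
    "integrate_cascade",
    "steady_state",
    "scale_protein_totals",
    "adaptation_time",
    "step_response",
    "sensitivity",
    "default_params",
    "CascadeEnsemble",
]


class CascadeError(RuntimeError):
    """Cascade integration or steady-state failure."""


@dataclass(frozen=True)
class ReceptorSpec:
    """Mixed Tar/Tsr receptor signalling team.

    ``methyl_offset``/``methyl_slope`` parameterise the methylation free
    energy f_m(m) = methyl_slope * (methyl_offset - m), in kT per team
    member; ``m_max`` bounds the physical methylation range [0, m_max].
    Dissociation constants are in mM, with Koff < Kon for an attractant
    (binding favours the inactive state).
    """

    n_cluster: float = 54.0
    tar_fraction: float = 1.0 / 3.0
    tsr_fraction: float = 2.0 / 3.0
    K_off_tar: float = 0.02
    K_on_tar: float = 0.3
    K_off_tsr: float = 1.0e-3
    K_on_tsr: float = 1.0
    methyl_offset: float = 1.0
    methyl_slope: float = 1.7
    m_max: float = 4.0

    def __post_init__(self) -> None:
        if not (0 < self.K_off_tar < self.K_on_tar):
            raise CascadeError("require 0 < K_off_tar < K_on_tar")
        if not (0 < self.K_off_tsr < self.K_on_tsr):
            raise CascadeError("require 0 < K_off_tsr < K_on_tsr")
        if self.tar_fraction < 0 or self.tsr_fraction < 0:
            raise CascadeError("receptor fractions must be non-negative")
        if self.tar_fraction + self.tsr_fraction > 1.0 + 1e-12:
            raise CascadeError("receptor fractions must sum to <= 1")
        if self.n_cluster < 1:
            raise CascadeError("n_cluster must be >= 1")
        if self.methyl_slope <= 0 or self.m_max <= 0:
            raise CascadeError("methyl_slope and m_max must be positive")


@dataclass(frozen=True)
class CascadeParams:
    """Cascade constants: totals (uM), rate constants, receptor team, beta.

    The stored totals are the totals in effect; ``beta`` records the scalar
    multiple relative to the base parameter set (see
    :func:`scale_protein_totals`).

    Rates: ``k_A`` (1/s) CheA autophosphorylation scaled by activity;
    ``k_y``, ``k_b`` (1/(uM s)) phosphotransfer to CheY and CheB;
    ``k_z`` (1/(uM s)) CheZ-mediated CheY-P dephosphorylation;
    ``gamma_Y``, ``gamma_B`` (1/s) spontaneous dephosphorylation;
    ``k_R`` (1/(uM s)) CheR methylation, ``k_B`` (1/(uM s)) CheB-P
    demethylation.
    """

    A_T: float = 5.0
    B_T: float = 2.0
    R_T: float = 0.3
    Y_T: float = 9.7
    Z_T: float = 1.1
    k_A: float = 50.0
    k_y: float = 100.0
    k_b: float = 15.0
    k_z: float = 11.1551042
    gamma_Y: float = 0.1
    gamma_B: float = 1.0
    k_R: float = 0.0075
    k_B: float = 0.0075
    receptor: ReceptorSpec = ReceptorSpec()
    beta: float = 1.0

    def __post_init__(self) -> None:
        for name in ("A_T", "B_T", "R_T", "Y_T", "Z_T",
                     "k_A", "k_y", "k_b", "k_z", "k_R", "k_B"):
            if getattr(self, name) <= 0:
                raise CascadeError(f"{name} must be positive")
        if self.gamma_Y < 0 or self.gamma_B < 0:
            raise CascadeError("spontaneous dephosphorylation rates must be >= 0")
        if self.beta <= 0:
            raise CascadeError("beta must be positive")


@dataclass(frozen=True)
class CascadeState:
    """Dynamic cascade state: methylation and phosphorylated concentrations."""

    m: float
    Ap: float
    Bp: float
    Yp: float

    def as_array(self) -> np.ndarray:
        return np.array([self.m, self.Ap, self.Bp, self.Yp], dtype=float)

    @classmethod
    def from_array(cls, z) -> "CascadeState":
        return cls(m=float(z[0]), Ap=float(z[1]), Bp=float(z[2]), Yp=float(z[3]))

    def validate(self, params: CascadeParams) -> None:
        if not (0.0 <= self.Ap <= params.A_T + 1e-9):
            raise CascadeError(f"Ap={self.Ap} outside [0, A_T]")
        if not (0.0 <= self.Bp <= params.B_T + 1e-9):
            raise CascadeError(f"Bp={self.Bp} outside [0, B_T]")
        if not (0.0 <= self.Yp <= params.Y_T + 1e-9):
            raise CascadeError(f"Yp={self.Yp} outside [0, Y_T]")
        if not (0.0 <= self.m <= params.receptor.m_max + 1e-9):
            raise CascadeError(f"m={self.m} outside [0, m_max]")


def _conc_pair(concentrations: Mapping[str, float]) -> Tuple[float, float]:
    La = float(concentrations.get(MEASP, 0.0))
    Ls = float(concentrations.get(SERINE, 0.0))
    if La < 0 or Ls < 0:
        raise CascadeError("ligand concentrations must be non-negative")
    return La, Ls


def receptor_free_energy(receptor: ReceptorSpec, m,
                         concentrations: Mapping[str, float]):
    """Signalling-team free energy F (kT) at methylation m and given ligands."""
    La, Ls = _conc_pair(concentrations)
    r = receptor
    fm = r.methyl_slope * (r.methyl_offset - np.asarray(m, dtype=float))
    tar = r.tar_fraction * np.log((1.0 + La / r.K_off_tar) /
                                  (1.0 + La / r.K_on_tar))
    tsr = r.tsr_fraction * np.log((1.0 + Ls / r.K_off_tsr) /
                                  (1.0 + Ls / r.K_on_tsr))
    return r.n_cluster * (fm + tar + tsr)


def receptor_activity(F):
    """Team activity Phi = 1 / (1 + exp(F)), strictly decreasing in F."""
    F = np.asarray(F, dtype=float)
    out = np.empty_like(F)
    pos = F >= 0
    out[pos] = np.exp(-F[pos]) / (1.0 + np.exp(-F[pos]))
    out[~pos] = 1.0 / (1.0 + np.exp(F[~pos]))
    return out if out.shape else float(out)


def _activity(params: CascadeParams, m, concentrations):
    return receptor_activity(receptor_free_energy(params.receptor, m,
                                                  concentrations))


def cascade_derivatives(state: CascadeState, params: CascadeParams,
                        concentrations: Mapping[str, float]) -> CascadeState:
    """Time derivatives of (m, Ap, Bp, Yp) at frozen ligand concentrations.

    The methylation derivative is forced to zero at the clamp boundaries
    [0, m_max] when it points outside the range.
    """
    p = params
    phi = _activity(p, state.m, concentrations)
    dm = p.k_R * p.R_T * (1.0 - phi) - p.k_B * state.Bp * phi
    if (state.m >= p.receptor.m_max and dm > 0) or (state.m <= 0.0 and dm < 0):
        dm = 0.0
    dAp = (p.k_A * phi * (p.A_T - state.Ap)
           - p.k_y * state.Ap * (p.Y_T - state.Yp)
           - p.k_b * state.Ap * (p.B_T - state.Bp))
    dBp = p.k_b * state.Ap * (p.B_T - state.Bp) - p.gamma_B * state.Bp
    dYp = (p.k_y * state.Ap * (p.Y_T - state.Yp)
           - p.k_z * p.Z_T * state.Yp - p.gamma_Y * state.Yp)
    return CascadeState(m=dm, Ap=dAp, Bp=dBp, Yp=dYp)


def _rhs(params: CascadeParams, concentrations):
    def f(t, z):
        d = cascade_derivatives(CascadeState.from_array(z), params,
                                concentrations)
        return d.as_array()
    return f


def _clip_state(z: np.ndarray, params: CascadeParams) -> np.ndarray:
    z = z.copy()
    z[0] = min(max(z[0], 0.0), params.receptor.m_max)
    z[1] = min(max(z[1], 0.0), params.A_T)
    z[2] = min(max(z[2], 0.0), params.B_T)
    z[3] = min(max(z[3], 0.0), params.Y_T)
    return z


def integrate_cascade(state: CascadeState, params: CascadeParams,
                      concentrations: Mapping[str, float], dt: float,
                      rtol: float = 1e-8, atol: float = 1e-10) -> CascadeState:
    """Advance the cascade by ``dt`` seconds at frozen ligand concentrations.

    Uses a stiff-capable adaptive integrator (LSODA); the ligand is held at
    its value over the whole step (quasi-static within one ABM timestep).
    """
    if dt < 0:
        raise CascadeError("dt must be non-negative")
    if dt == 0:
        return state
    sol = solve_ivp(_rhs(params, concentrations), (0.0, dt), state.as_array(),
                    method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise CascadeError(
            f"cascade integration failed: {sol.message}; state={state}")
    return CascadeState.from_array(_clip_state(sol.y[:, -1], params))


def _phospho_fixed_point(params: CascadeParams, phi: float):
    """Steady (Ap, Bp, Yp) of the phospho-relay at fixed team activity phi."""
    p = params

    def yp_of(Ap):
        return p.k_y * Ap * p.Y_T / (p.k_y * Ap + p.k_z * p.Z_T + p.gamma_Y)

    def bp_of(Ap):
        return p.k_b * Ap * p.B_T / (p.k_b * Ap + p.gamma_B)

    def g(Ap):
        return (p.k_A * phi * (p.A_T - Ap)
                - p.k_y * Ap * (p.Y_T - yp_of(Ap))
                - p.k_b * Ap * (p.B_T - bp_of(Ap)))

    if phi <= 0.0:
        return 0.0, 0.0, 0.0
    Ap = brentq(g, 0.0, p.A_T, xtol=1e-15, rtol=8.9e-16)
    return Ap, bp_of(Ap), yp_of(Ap)


def steady_state(params: CascadeParams,
                 concentrations: Mapping[str, float]) -> CascadeState:
    """Deterministic steady state of the cascade at fixed ligand levels.

    Solved algebraically: the methylation balance
    k_R*[R]_T*(1-Phi) = k_B*Bp(Phi)*Phi pins the adapted activity Phi*
    (a scalar root bracketed on (0, 1)); the phospho-relay fixed point at
    Phi* gives Ap, Bp, Yp; inverting the free energy gives the adapted
    methylation level.  If the required methylation falls outside
    [0, m_max] the level is clamped and the phospho system re-solved at the
    clamped activity (adaptation is then imperfect).
    """
    p = params
    La_Ls = _conc_pair(concentrations)

    def h(phi):
        _, Bp, _ = _phospho_fixed_point(p, phi)
        return p.k_R * p.R_T * (1.0 - phi) - p.k_B * Bp * phi

    lo, hi = 1e-12, 1.0 - 1e-12
    if h(lo) <= 0 or h(hi) >= 0:
        raise CascadeError("methylation balance has no root in (0, 1)")
    phi_star = brentq(h, lo, hi, xtol=1e-15, rtol=8.9e-16)

    # invert F(m) = ln(1/phi - 1) for the adapted methylation level
    r = p.receptor
    F_star = math.log(1.0 / phi_star - 1.0)
    lig = receptor_free_energy(r, r.methyl_offset, dict(zip((MEASP, SERINE),
                                                            La_Ls)))
    # lig = n * (0 + ligand terms) at m = methyl_offset
    ligand_terms = float(lig) / r.n_cluster
    m_star = r.methyl_offset - (F_star / r.n_cluster - ligand_terms) / r.methyl_slope
    if m_star < 0.0 or m_star > r.m_max:
        m_star = min(max(m_star, 0.0), r.m_max)
        phi_star = float(_activity(p, m_star, dict(zip((MEASP, SERINE), La_Ls))))
    Ap, Bp, Yp = _phospho_fixed_point(p, phi_star)
    state = CascadeState(m=float(m_star), Ap=Ap, Bp=Bp, Yp=Yp)

    deriv = cascade_derivatives(state, p, dict(zip((MEASP, SERINE), La_Ls)))
    if max(abs(v) for v in deriv.as_array()) > 1e-9:
        raise CascadeError(
            f"steady-state residual too large: {deriv}; params beta={p.beta}")
    return state


def scale_protein_totals(params: CascadeParams, beta: float) -> CascadeParams:
    """Multiply every protein total {A,B,R,Y,Z}_T by ``beta``; rates untouched."""
    if beta <= 0:
        raise CascadeError("beta must be positive")
    return replace(
        params,
        A_T=params.A_T * beta, B_T=params.B_T * beta, R_T=params.R_T * beta,
        Y_T=params.Y_T * beta, Z_T=params.Z_T * beta,
        beta=params.beta * beta,
    )


@dataclass(frozen=True)
class StepResponse:
    """Summary of the CheY-P response to a step change in ligand.

    ``amplitude`` is the excursion |Yp extremum - Yp pre-step| in uM;
    ``amplitude_fraction`` is the same excursion in the cascade's
    nondimensional units (fraction of total CheY), the scale on which
    responses of cells with different total protein content are compared.
    """

    adaptation_time: float   # s, first return within settle band
    amplitude: float         # uM, |Yp extremum - Yp pre-step|
    amplitude_fraction: float  # amplitude / [Y]_T
    Yp_pre: float
    Yp_extremum: float
    Yp_final: float


def step_response(params: CascadeParams, step: Tuple[float, float],
                  species: str = MEASP, settle_fraction: float = 0.1,
                  t_max: float = 3000.0, n_sample: int = 6000) -> StepResponse:
    """Integrate the response to a ligand step ``(L_before, L_after)``.

    The cell starts at the steady state for ``L_before``; at t = 0 the
    concentration jumps to ``L_after``.  The adaptation time is the first
    time after the CheY-P extremum at which Yp is back within
    ``settle_fraction`` of the gap between the extremum and the final
    (re-adapted) level.
    """
    L0, L1 = step
    pre = steady_state(params, {species: L0})
    if L0 == L1:
        return StepResponse(0.0, 0.0, 0.0, pre.Yp, pre.Yp, pre.Yp)
    conc = {species: L1}
    t_eval = np.linspace(0.0, t_max, n_sample)
    sol = solve_ivp(_rhs(params, conc), (0.0, t_max), pre.as_array(),
                    method="LSODA", rtol=1e-9, atol=1e-12, t_eval=t_eval)
    if not sol.success:
        raise CascadeError(f"step-response integration failed: {sol.message}")
    Yp = sol.y[3]
    Yp_final = float(Yp[-1])
    i_ext = int(np.argmax(np.abs(Yp - pre.Yp)))
    Yp_ext = float(Yp[i_ext])
    amplitude = abs(Yp_ext - pre.Yp)
    if amplitude < 1e-12:
        return StepResponse(0.0, 0.0, 0.0, pre.Yp, pre.Yp, Yp_final)
    gap = settle_fraction * abs(Yp_ext - Yp_final)
    settled = np.abs(Yp[i_ext:] - Yp_final) <= gap
    if not settled.any():
        raise CascadeError("Yp did not re-adapt within t_max")
    t_ad = float(sol.t[i_ext + int(np.argmax(settled))])
    return StepResponse(t_ad, amplitude, amplitude / params.Y_T,
                        pre.Yp, Yp_ext, Yp_final)


def adaptation_time(params: CascadeParams, step: Tuple[float, float],
                    species: str = MEASP, settle_fraction: float = 0.1,
                    t_max: float = 3000.0) -> float:
    """Time for CheY-P to return near its pre-step level after a ligand step."""
    return step_response(params, step, species=species,
                         settle_fraction=settle_fraction, t_max=t_max).adaptation_time


def sensitivity(params: CascadeParams, L: float, species: str = MEASP,
                rel_step: float = 1e-4) -> float:
    """Logarithmic gain S = -d ln(Phi) / d ln([L]) at the adapted state.

    The methylation level is held fixed at its adapted value for ``L`` (the
    instantaneous response of an adapted cell); the derivative is a central
    difference on the log axis.
    """
    if L <= 0:
        raise CascadeError("L must be positive")
    m_star = steady_state(params, {species: L}).m
    lo, hi = L * (1.0 - rel_step), L * (1.0 + rel_step)
    phi_lo = float(_activity(params, m_star, {species: lo}))
    phi_hi = float(_activity(params, m_star, {species: hi}))
    return -(math.log(phi_hi) - math.log(phi_lo)) / (math.log(hi) - math.log(lo))


def default_params() -> CascadeParams:
    """Default cascade parameter set (base totals, beta = 1).

    Totals are at literature scale for E. coli chemotaxis proteins, the
    receptor team is Tsr-dominant (Tar:Tsr = 1:2, the measured abundance
    ratio), adaptation operates on the ~2 minute timescale seen in
    single-cell responses, and the CheZ rate constant is calibrated once so
    the unstimulated steady-state CheY-P at the 0.1 mM MeAsp background
    equals the 4.043 uM reference that anchors the motor curve.  Intended
    to be replaced wholesale by a transcribed published parameter set via
    the config file.
    """
    return CascadeParams()


class CascadeEnsemble:
    """Vectorised fixed-step integrator for a population of cascades.

    Holds per-cell protein totals (each cell's base totals scaled by its own
    beta) and advances all cells simultaneously with a backward-Euler step
    solved by Newton iteration (analytic 4x4 Jacobian, batched linear
    solves).  Backward Euler is L-stable, so the stiff phospho-relay rates
    (~1e3-1e4 1/s) pose no stability constraint at the ABM timestep; the
    slow methylation dynamics that control behaviour are resolved accurately.
    Agreement with the adaptive reference integrator is covered by tests.
    """

    def __init__(self, params: CascadeParams, betas: np.ndarray):
        self.params = params
        self.betas = np.asarray(betas, dtype=float)
        if np.any(self.betas <= 0):
            raise CascadeError("all betas must be positive")
        n = self.betas.shape[0]
        self.n = n
        p = params
        self.A_T = p.A_T * self.betas
        self.B_T = p.B_T * self.betas
        self.R_T = p.R_T * self.betas
        self.Y_T = p.Y_T * self.betas
        self.Z_T = p.Z_T * self.betas

    def activity(self, m, La, Ls):
        r = self.params.receptor
        fm = r.methyl_slope * (r.methyl_offset - m)
        tar = r.tar_fraction * np.log((1.0 + La / r.K_off_tar) /
                                      (1.0 + La / r.K_on_tar))
        tsr = r.tsr_fraction * np.log((1.0 + Ls / r.K_off_tsr) /
                                      (1.0 + Ls / r.K_on_tsr))
        F = r.n_cluster * (fm + tar + tsr)
        return receptor_activity(F)

    def _f_and_jac(self, z, La, Ls):
        """Derivatives f(z) and Jacobian df/dz for z = (m, Ap, Bp, Yp)."""
        p = self.params
        r = p.receptor
        m, Ap, Bp, Yp = z[:, 0], z[:, 1], z[:, 2], z[:, 3]
        phi = self.activity(m, La, Ls)
        dphi_dm = phi * (1.0 - phi) * r.n_cluster * r.methyl_slope

        f = np.empty_like(z)
        f[:, 0] = p.k_R * self.R_T * (1.0 - phi) - p.k_B * Bp * phi
        f[:, 1] = (p.k_A * phi * (self.A_T - Ap)
                   - p.k_y * Ap * (self.Y_T - Yp)
                   - p.k_b * Ap * (self.B_T - Bp))
        f[:, 2] = p.k_b * Ap * (self.B_T - Bp) - p.gamma_B * Bp
        f[:, 3] = (p.k_y * Ap * (self.Y_T - Yp)
                   - p.k_z * self.Z_T * Yp - p.gamma_Y * Yp)

        J = np.zeros((self.n, 4, 4))
        J[:, 0, 0] = (-p.k_R * self.R_T - p.k_B * Bp) * dphi_dm
        J[:, 0, 2] = -p.k_B * phi
        J[:, 1, 0] = p.k_A * (self.A_T - Ap) * dphi_dm
        J[:, 1, 1] = (-p.k_A * phi - p.k_y * (self.Y_T - Yp)
                      - p.k_b * (self.B_T - Bp))
        J[:, 1, 2] = p.k_b * Ap
        J[:, 1, 3] = p.k_y * Ap
        J[:, 2, 1] = p.k_b * (self.B_T - Bp)
        J[:, 2, 2] = -p.k_b * Ap - p.gamma_B
        J[:, 3, 1] = p.k_y * (self.Y_T - Yp)
        J[:, 3, 3] = -p.k_y * Ap - p.k_z * self.Z_T - p.gamma_Y
        return f, J

    def step(self, z: np.ndarray, La, Ls, dt: float,
             newton_tol: float = 1e-11, max_iter: int = 25) -> np.ndarray:
        """One backward-Euler step of length ``dt`` for all cells.

        ``z`` has shape (n, 4) ordered (m, Ap, Bp, Yp); ``La``/``Ls`` are the
        per-cell ligand concentrations frozen over the step.
        """
        La = np.broadcast_to(np.asarray(La, dtype=float), (self.n,))
        Ls = np.broadcast_to(np.asarray(Ls, dtype=float), (self.n,))
        z0 = z
        zk = z.copy()
        eye = np.eye(4)
        for _ in range(max_iter):
            f, J = self._f_and_jac(zk, La, Ls)
            G = zk - z0 - dt * f
            A = eye[None, :, :] - dt * J
            delta = np.linalg.solve(A, G[:, :, None])[:, :, 0]
            zk = zk - delta
            if np.max(np.abs(delta)) < newton_tol:
                break
        else:
            raise CascadeError("ensemble Newton iteration failed to converge")
        # clamp to physical ranges (m bounded, concentrations within totals)
        np.clip(zk[:, 0], 0.0, self.params.receptor.m_max, out=zk[:, 0])
        np.clip(zk[:, 1], 0.0, self.A_T, out=zk[:, 1])
        np.clip(zk[:, 2], 0.0, self.B_T, out=zk[:, 2])
        np.clip(zk[:, 3], 0.0, self.Y_T, out=zk[:, 3])
        return zk
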