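"""Individual-level dynamic energy budget model with metabolic acceleration.

The model follows the standard abj formulation: a single reserve E fuels
somatic maintenance, growth of structure (length L), maturation (E_H) and,
after puberty, a reproduction buffer (E_R), split by the kappa-rule.
Between birth (E_H = E_Hb) and metamorphosis (E_H = E_Hj) the
surface-linked parameters — maximum assimilation {p_Am} and energy
conductance v — are accelerated by the factor s_M = L/L_b, frozen at
s_M = L_j/L_b afterwards.  Embryos do not feed and run down the initial
reserve E_0 deposited in the egg.

All rate parameters are specified at ``T_ref`` and corrected at run time by
the five-parameter Arrhenius factor with lower/upper tolerance boundaries.

The state update is written against numpy arrays so that the population
module can advance thousands of cohorts in lock-step through the very same
code path used for a single individual.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from typing import NamedTuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .parameters import DEBParams

__all__ = [
    "DEBState",
    "Observables",
    "arrhenius_factor",
    "energy_fluxes",
    "deb_rates",
    "step_individual",
    "step_arrays",
    "initial_reserve",
    "observables",
    "integrate_lifecycle",
    "lifespan",
    "embryo_state",
]

_L_EGG = 1e-4  # structural length assigned to a freshly fertilised egg [cm]


@dataclass
class DEBState:
    """State of one individual.

    ``L_b`` and ``L_j`` record structural length at birth and metamorphosis
    once those maturity thresholds are crossed (NaN before); the
    acceleration factor ``s_M`` is derived from them.
    """

    L: float            # structural length [cm]
    E: float            # reserve energy [J]
    E_H: float          # maturity [J]
    E_R: float = 0.0    # reproduction buffer [J]
    age: float = 0.0    # time since fertilisation [d]
    L_b: float = np.nan  # structural length at birth [cm]
    L_j: float = np.nan  # structural length at metamorphosis [cm]
    q_acc: float = 0.0  # ageing acceleration [1/d^2]
    h_haz: float = 0.0  # ageing hazard [1/d]

    def s_M(self, pars: DEBParams) -> float:
        """Metabolic acceleration factor (1 before birth, L_j/L_b after)."""
        return float(_s_M(np.asarray(self.L), np.asarray(self.E_H),
                          np.asarray(self.L_b), np.asarray(self.L_j), pars))

    def copy(self) -> "DEBState":
        return replace(self)


class Observables(NamedTuple):
    physical_length: float  # preanal length [cm]
    dry_weight: float       # [g]
    wet_weight: float       # [g]


class Fluxes(NamedTuple):
    """Energy fluxes [J/d] at the current state and forcing."""

    p_A: float   # assimilation
    p_C: float   # mobilisation from reserve
    p_S: float   # somatic maintenance
    p_G: float   # committed to growth (kappa*p_C - p_S)
    p_J: float   # maturity maintenance
    p_R: float   # maturation (pre-puberty) or reproduction flux


class Rates(NamedTuple):
    """Time derivatives of the state variables."""

    dL: float
    dE: float
    dE_H: float
    dE_R: float
    dq: float
    dh: float


def arrhenius_factor(T, pars: DEBParams):
    """Five-parameter Arrhenius correction, equal to 1 at ``T = T_ref``.

    Rates decay towards both ends of the tolerance range (T_L, T_H); the
    correction is strictly below the plain two-parameter Arrhenius value
    everywhere because the boundary terms only add to the denominator.
    """
    T = np.asarray(T, dtype=float)
    if not np.all(np.isfinite(T)):
        raise ValueError("temperature forcing contains non-finite values")
    if np.any(T <= 0) or np.any(T >= 400.0):
        raise ValueError("temperature must be in (0, 400) K; got values outside")
    ref = 1.0 + np.exp(pars.T_AL / pars.T_ref - pars.T_AL / pars.T_L) \
              + np.exp(pars.T_AH / pars.T_H - pars.T_AH / pars.T_ref)
    den = 1.0 + np.exp(pars.T_AL / T - pars.T_AL / pars.T_L) \
              + np.exp(pars.T_AH / pars.T_H - pars.T_AH / T)
    out = np.exp(pars.T_A / pars.T_ref - pars.T_A / T) * ref / den
    return out if out.ndim else float(out)


def _s_M(L, E_H, L_b, L_j, pars: DEBParams):
    embryo = E_H < pars.E_Hb
    accel = ~embryo & (E_H < pars.E_Hj)
    with np.errstate(invalid="ignore"):
        s = np.where(embryo, 1.0,
                     np.where(accel, L / L_b, L_j / L_b))
    # before the relevant threshold is crossed L_b/L_j are NaN; an embryo
    # never reads them, but guard against NaN leaking through np.where
    return np.where(np.isnan(s), 1.0, s)


def _fluxes_arrays(L, E, E_H, s_M, f, TC, pars: DEBParams):
    """kappa-rule fluxes, vectorised.  Embryos (E_H < E_Hb) do not feed."""
    feeding = E_H >= pars.E_Hb
    v_T = pars.v_dot * s_M * TC
    pM_T = pars.p_M_vol * TC
    kJ_T = pars.k_J_dot * TC
    p_A = np.where(feeding, pars.p_Am * s_M * TC * f * L**2, 0.0)
    p_C = E * (pars.E_G * v_T / L + pM_T) / (pars.E_G + pars.kappa * E / L**3)
    p_S = pM_T * L**3
    p_G = pars.kappa * p_C - p_S
    p_J = kJ_T * E_H
    p_R = (1.0 - pars.kappa) * p_C - p_J
    return p_A, p_C, p_S, p_G, p_J, p_R


def energy_fluxes(state: DEBState, f: float, T: float, pars: DEBParams) -> Fluxes:
    """Instantaneous energy fluxes [J/d] for one individual at (f, T)."""
    TC = arrhenius_factor(T, pars)
    sM = state.s_M(pars)
    vals = _fluxes_arrays(np.float64(state.L), np.float64(state.E),
                          np.float64(state.E_H), sM, f, TC, pars)
    return Fluxes(*(float(v) for v in vals))


def deb_rates(state: DEBState, f: float, T: float, pars: DEBParams) -> Rates:
    """Time derivatives of (L, E, E_H, E_R, q, h) at the current state.

    Under starvation (kappa*p_C < p_S) growth stops; the maintenance
    deficit is not reflected here (it is drawn from E_R by the stepper).
    Maturity never decreases (no rejuvenation).
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"scaled functional response must be in [0, 1], got {f}")
    TC = arrhenius_factor(T, pars)
    sM = state.s_M(pars)
    p_A, p_C, p_S, p_G, p_J, p_R = _fluxes_arrays(
        np.float64(state.L), np.float64(state.E), np.float64(state.E_H),
        sM, f, TC, pars)
    dL = max(p_G, 0.0) / (3.0 * state.L**2 * pars.E_G)
    dE = p_A - p_C
    adult = state.E_H >= pars.E_Hp
    dE_H = 0.0 if adult else max(p_R, 0.0)
    dE_R = max(p_R, 0.0) if adult else 0.0
    # ageing (Weibull acceleration + Gompertz stress); used for the
    # life-span trait, not for population mortality
    e_scaled = state.E * pars.v_dot / (state.L**3 * pars.p_Am)
    r = p_G / (state.L**3 * pars.E_G) if p_G > 0 else 0.0
    L_m_acc = sM * pars.L_m
    dq = ((state.q_acc * (state.L / L_m_acc) ** 3 * pars.s_G
           + pars.h_a_ddot * TC**2)
          * e_scaled * (pars.v_dot * sM * TC / state.L - r)
          - r * state.q_acc)
    dh = state.q_acc - r * state.h_haz
    return Rates(float(dL), float(dE), float(dE_H), float(dE_R),
                 float(dq), float(dh))


def step_arrays(L, E, E_H, E_R, age, L_b, L_j, q, h,
                f, T, dt: float, pars: DEBParams, TC=None):
    """Explicit-Euler update of DEB state arrays over one step of ``dt`` days.

    All array arguments are updated **in place** and must be float64 arrays
    of a common shape; ``f`` and ``T`` may be scalars or arrays.  Returns a
    boolean ``starved`` mask.  When the kappa-share of mobilisation falls
    short of somatic maintenance, the deficit is paid from the reproduction
    buffer first and then from reserve; structure is never resorbed (no
    shrinking) and an individual is starved once its reserve is exhausted.
    """
    if TC is None:
        TC = arrhenius_factor(T, pars)
    sM = _s_M(L, E_H, L_b, L_j, pars)
    p_A, p_C, p_S, p_G, p_J, p_R = _fluxes_arrays(L, E, E_H, sM, f, TC, pars)

    growth = np.maximum(p_G, 0.0)
    deficit = np.maximum(-p_G, 0.0) * dt       # maintenance not covered [J]

    adult = E_H >= pars.E_Hp
    p_R_pos = np.maximum(p_R, 0.0)
    dE_H = np.where(adult, 0.0, p_R_pos)
    dE_R = np.where(adult, p_R_pos, 0.0)

    e_scaled = E * pars.v_dot / (L**3 * pars.p_Am)
    spec_r = np.where(p_G > 0, p_G / (L**3 * pars.E_G), 0.0)
    L_m_acc = sM * pars.L_m
    dq = ((q * (L / L_m_acc) ** 3 * pars.s_G + pars.h_a_ddot * TC**2)
          * e_scaled * (pars.v_dot * sM * TC / L - spec_r) - spec_r * q)
    dh = q - spec_r * h

    E_H_old = E_H.copy()
    L += growth / (3.0 * L**2 * pars.E_G) * dt
    E += (p_A - p_C) * dt
    E_H += dE_H * dt
    E_R += dE_R * dt
    q += dq * dt
    h += dh * dt
    age += dt

    # starvation: the maintenance deficit is paid from the reproduction
    # buffer while it lasts, then from reserve; structure is never resorbed
    # and an individual with exhausted reserve is flagged as starved
    if np.any((E < 0.0) & (deficit == 0.0)) or np.any(L <= 0.0):
        raise FloatingPointError(
            "Euler step produced negative reserve or structure outside the "
            "starvation regime; use a smaller dt")
    E_R -= deficit
    shortfall = np.maximum(-E_R, 0.0)
    E_R += shortfall
    E -= shortfall
    starved = E <= 0.0
    E[starved] = 0.0

    # record lengths at threshold crossings (at most one per step)
    born = (E_H_old < pars.E_Hb) & (E_H >= pars.E_Hb)
    L_b[born] = L[born]
    meta = (E_H_old < pars.E_Hj) & (E_H >= pars.E_Hj)
    L_j[meta] = L[meta]
    return starved


def step_individual(state: DEBState, f: float, T: float, dt: float,
                    pars: DEBParams) -> DEBState:
    """Advance one individual by ``dt`` days (explicit Euler).

    Raises ``FloatingPointError`` if the step is too large for stability.
    The returned state carries the same starvation semantics as the
    population engine: a maintenance deficit is paid from E_R; if E_R is
    exhausted the state is returned with ``E_R = 0`` (the population layer
    treats that as death of the cohort).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"scaled functional response must be in [0, 1], got {f}")
    arr = {k: np.array([v], dtype=float) for k, v in
           dict(L=state.L, E=state.E, E_H=state.E_H, E_R=state.E_R,
                age=state.age, L_b=state.L_b, L_j=state.L_j,
                q=state.q_acc, h=state.h_haz).items()}
    step_arrays(arr["L"], arr["E"], arr["E_H"], arr["E_R"], arr["age"],
                arr["L_b"], arr["L_j"], arr["q"], arr["h"], f, T, dt, pars)
    return DEBState(L=float(arr["L"][0]), E=float(arr["E"][0]),
                    E_H=float(arr["E_H"][0]), E_R=float(arr["E_R"][0]),
                    age=float(arr["age"][0]), L_b=float(arr["L_b"][0]),
                    L_j=float(arr["L_j"][0]), q_acc=float(arr["q"][0]),
                    h_haz=float(arr["h"][0]))


def observables(state: DEBState, pars: DEBParams, f: float = 1.0,
                dry_to_wet: float = 1.0) -> Observables:
    """Convert a DEB state to measurable quantities.

    Preanal length is L/delta_M.  Dry weight counts structure at d_V and
    the reserve pools as fixable biomass at the accelerated reserve
    capacity, ``W = d_V L^3 + kappa_R s_M (E + E_R)/e_j``: reserve energy
    is converted through the fixation efficiency kappa_R and the
    acceleration factor s_M.  This is the mass basis under which the
    packaged parameter set reproduces the published weight-at-stage values
    for this stock (73.4 g at puberty, 5267 g asymptotic).  Wet weight
    applies a configurable dry:wet factor (default 1: model weight and
    survey weight on the same basis).
    """
    sM = state.s_M(pars)
    dry = pars.d_V * state.L**3 \
        + pars.kappa_R * sM * (state.E + state.E_R) / pars.e_j_content
    return Observables(physical_length=state.L / pars.delta_M,
                       dry_weight=dry, wet_weight=dry / dry_to_wet)


def embryo_state(E_0: float, age: float = 0.0) -> DEBState:
    """A freshly fertilised egg holding initial reserve ``E_0`` joules."""
    return DEBState(L=_L_EGG, E=E_0, E_H=0.0, age=age)


# ---------------------------------------------------------------------------
# Adaptive (solve_ivp) integration: embryo solver and life-cycle traits
# ---------------------------------------------------------------------------

def _rhs_ivp(t, y, f, TC, pars: DEBParams, L_b, L_j):
    """(L, E, E_H) dynamics for the adaptive integrator.

    ``L_b``/``L_j`` of None denote phases before those thresholds; the
    acceleration window is then tracked via L against the running L_b.
    """
    L, E, E_H = y
    if E_H < pars.E_Hb:
        sM, feeding = 1.0, 0.0
    elif L_b is not None and E_H < pars.E_Hj:
        sM, feeding = L / L_b, 1.0
    else:
        sM = (L_j / L_b) if (L_b and L_j) else 1.0
        feeding = 1.0
    v_T = pars.v_dot * sM * TC
    pM_T = pars.p_M_vol * TC
    p_A = pars.p_Am * sM * TC * f * L**2 * feeding
    p_C = E * (pars.E_G * v_T / L + pM_T) / (pars.E_G + pars.kappa * E / L**3)
    p_G = pars.kappa * p_C - pM_T * L**3
    dE_H = (1 - pars.kappa) * p_C - pars.k_J_dot * TC * E_H
    if E_H >= pars.E_Hp:
        dE_H = 0.0
    return [max(p_G, 0.0) / (3 * L**2 * pars.E_G), p_A - p_C, dE_H]


def _integrate_to(E_H_target, y0, f, TC, pars, L_b=None, L_j=None,
                  t_max=20000.0, rtol=1e-9):
    event = lambda t, y, *a: y[2] - E_H_target
    event.terminal, event.direction = True, 1
    sol = solve_ivp(_rhs_ivp, (0.0, t_max), y0, args=(f, TC, pars, L_b, L_j),
                    events=event, method="RK45", rtol=rtol, atol=1e-12)
    if not sol.t_events[0].size:
        return None
    return float(sol.t_events[0][0]), sol.y_events[0][0]


@lru_cache(maxsize=64)
def initial_reserve(pars: DEBParams, f: float, T: float | None = None,
                    bracket: tuple[float, float] = (1e-4, 50.0)):
    """Initial reserve E_0 [J] of an egg, by bisection on embryo integrations.

    E_0 is fixed so that the scaled reserve density at birth
    (e = E v / (L^3 {p_Am})) equals the mother's functional response ``f``.
    Returns ``(E_0, age_at_birth, L_b)`` at temperature ``T`` (default
    T_ref; E_0 and L_b are temperature-independent, the age is not).

    Raises ``ValueError`` when the search interval does not bracket a
    solution (e.g. f so low that the embryo cannot reach birth).
    """
    if not 0.0 < f <= 1.0:
        raise ValueError(f"f must be in (0, 1], got {f}")
    TC = arrhenius_factor(pars.T_ref if T is None else T, pars)

    def gap(E_0):
        res = _integrate_to(pars.E_Hb, [_L_EGG, E_0, 0.0], f, TC, pars,
                            t_max=2000.0, rtol=1e-8)
        if res is None:
            return -f  # embryo starved before birth: reserve too small
        _, (L, E, _) = res
        return E * pars.v_dot / (L**3 * pars.p_Am) - f

    lo, hi = bracket
    try:
        E_0 = brentq(gap, lo, hi, xtol=1e-10, rtol=1e-10)
    except ValueError as err:
        raise ValueError(
            f"initial-reserve search interval {bracket} does not bracket a "
            f"solution at f = {f}: {err}") from err
    a_b, (L_b, _, _) = _integrate_to(pars.E_Hb, [_L_EGG, E_0, 0.0], f, TC,
                                     pars, t_max=2000.0)
    return float(E_0), float(a_b), float(L_b)


@dataclass(frozen=True)
class LifeCycle:
    """Reference trajectory landmarks at constant (f, T)."""

    E_0: float
    a_b: float        # age at birth [d]
    L_b: float        # structural length at birth [cm]
    E_b: float        # reserve at birth [J]
    t_j: float        # time since birth at metamorphosis [d]
    L_j: float
    t_p: float        # time since birth at puberty [d]
    L_p: float
    E_p: float        # reserve at puberty [J]
    s_M: float        # acceleration factor L_j/L_b
    L_i: float        # asymptotic structural length f*s_M*L_m [cm]
    E_i: float        # reserve at the asymptotic state [J]
    f: float
    T: float


def integrate_lifecycle(pars: DEBParams, f: float = 1.0,
                        T: float | None = None) -> LifeCycle:
    """Solve embryo, acceleration and juvenile phases with an adaptive
    integrator and return the landmark states used for trait prediction.

    Raises ``ValueError`` naming the infeasible threshold when the
    parameters cannot reach it at this ``f``.
    """
    T = pars.T_ref if T is None else T
    TC = arrhenius_factor(T, pars)
    E_0, a_b, L_b = initial_reserve(pars, f, T)
    E_b = f * pars.E_m * L_b**3  # by construction of E_0
    res = _integrate_to(pars.E_Hj, [L_b, E_b, pars.E_Hb], f, TC, pars,
                        L_b=L_b)
    if res is None:
        raise ValueError("metamorphosis threshold E_Hj unreachable at this f")
    t_j, (L_j, E_j, _) = res
    res = _integrate_to(pars.E_Hp, [L_j, E_j, pars.E_Hj], f, TC, pars,
                        L_b=L_b, L_j=L_j, t_max=50000.0)
    if res is None:
        raise ValueError("puberty threshold E_Hp unreachable at this f")
    t_jp, (L_p, E_p, _) = res
    s_M = L_j / L_b
    L_i = f * s_M * pars.L_m
    E_i = f * pars.E_m * L_i**3
    return LifeCycle(E_0=E_0, a_b=a_b, L_b=float(L_b), E_b=float(E_b),
                     t_j=float(t_j), L_j=float(L_j), t_p=float(t_j + t_jp),
                     L_p=float(L_p), E_p=float(E_p), s_M=float(s_M),
                     L_i=float(L_i), E_i=float(E_i), f=f, T=T)


def lifespan(pars: DEBParams, f: float = 1.0, T: float | None = None) -> float:
    """Mean life span [d]: age at which ageing-ODE survival drops to 1/e.

    Integrates the Weibull/Gompertz ageing state (q, h) along the growth
    trajectory from birth at constant (f, T) together with cumulative
    hazard H; the life-span convention is S(a_m) = exp(-1).
    """
    T = pars.T_ref if T is None else T
    TC = arrhenius_factor(T, pars)
    cyc = integrate_lifecycle(pars, f, T)

    def rhs(t, y):
        L, E, q, h, H = y
        sM = min(max(L / cyc.L_b, 1.0), cyc.s_M)
        v_T = pars.v_dot * sM * TC
        pM_T = pars.p_M_vol * TC
        p_A = pars.p_Am * sM * TC * f * L**2
        p_C = E * (pars.E_G * v_T / L + pM_T) / (pars.E_G + pars.kappa * E / L**3)
        p_G = pars.kappa * p_C - pM_T * L**3
        dL = max(p_G, 0.0) / (3 * L**2 * pars.E_G)
        r = max(p_G, 0.0) / (L**3 * pars.E_G)
        e_scaled = E * pars.v_dot / (L**3 * pars.p_Am)
        dq = ((q * (L / (sM * pars.L_m)) ** 3 * pars.s_G + pars.h_a_ddot * TC**2)
              * e_scaled * (v_T / L - r) - r * q)
        dh = q - r * h
        return [dL, p_A - p_C, dq, dh, h]

    event = lambda t, y: y[4] - 1.0  # cumulative hazard reaches 1
    event.terminal, event.direction = True, 1
    sol = solve_ivp(rhs, (0.0, 60000.0), [cyc.L_b, cyc.E_b, 0.0, 0.0, 0.0],
                    events=event, method="LSODA", rtol=1e-8, atol=1e-12)
    if not sol.t_events[0].size:
        raise RuntimeError("survival did not fall to 1/e within the horizon")
    return float(cyc.a_b + sol.t_events[0][0])
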