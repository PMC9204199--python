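"""Continuous-time lumped-parameter cardiovascular + baroreflex plant.

The circulation is a minimal closed loop: left ventricle (double-Hill
time-varying elastance) -> aortic valve (resistance R3 + inertance L) ->
arterial compliance C3 -> systemic resistance (R1 baseline, sympathetically
modulated) -> venous compliance C2 -> mitral valve (R2) -> ventricle.
Valves are ideal diodes. Total blood volume is conserved exactly by
construction of the mass balance.

The baroreflex arc filters arterial pressure (first order, tau_p), maps it
through a sigmoidal afferent firing curve, and drives sympathetic firing
(decreasing exponential of afferent firing) and vagal firing (increasing
sigmoid). Four delayed first-order effectors respond to the efferent firing:
the sympathetic contributions to heart period, end-systolic elastance and
systemic resistance share one time constant and delay, and the vagal heart
period contribution has its own. The heart period combines additively,
T = T_ev + T_es - T0, and is updated at cycle boundaries.

Stimulation enters as per-cycle firing-rate increments (Hz) added to the
baroreceptive afferent, sympathetic efferent, and vagal efferent channels.

Integration is fixed-step RK4 at dt = 1e-4 s; the per-cycle outputs are
HR = 60/T of the completed cycle and the time-averaged arterial pressure
over that cycle. The stepping kernel is compiled with numba and is batched
over independent trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .params import PlantParameters

__all__ = [
    "CycleOutput", "CardioSim", "double_hill_elastance", "passive_pressure",
    "valve_flow", "efferent_update", "simulate_cycles", "simulate_trials",
    "resting_state", "steady_outputs", "calibrate", "CalibrationError",
]

DT_DEFAULT = 1.0e-4

# ---------------------------------------------------------------------------
# scalar building blocks (also used by the kernel, duplicated there for numba)
# ---------------------------------------------------------------------------


def double_hill_elastance(t_n: float, T: float, p: PlantParameters,
                          E_max: float | None = None) -> float:
    """Time-varying ventricular elastance E(t_n) over one beat of period T.

    E = E_min + a (E_max - E_min) * [x1^n1/(1+x1^n1)] * [1/(1+x2^n2)] with
    x1 = t_n/(alpha1 T), x2 = t_n/(alpha2 T). E(0) = E_min exactly; the
    amplitude ``a`` is normalised so the shape peak reaches E_max.
    """
    if t_n < 0 or T <= 0 or t_n >= T:
        raise ValueError("require 0 <= t_n < T with T > 0")
    if E_max is None:
        E_max = p.E_max
    x1 = (t_n / (p.alpha1 * T)) ** p.n1
    h1 = x1 / (1.0 + x1)
    h2 = 1.0 / (1.0 + (t_n / (p.alpha2 * T)) ** p.n2)
    return p.E_min + p.a * (E_max - p.E_min) * h1 * h2


def passive_pressure(V: float, V_d: float, E: float) -> float:
    """Compartment pressure P = E (V - V_d)."""
    if E < 0:
        raise ValueError("elastance must be non-negative")
    return E * (V - V_d)


def valve_flow(P_in: float, P_out: float, R: float, is_valve: bool = True) -> float:
    """Pressure-driven flow Q = (P_in - P_out)/R; ideal diode when a valve."""
    if R <= 0:
        raise ValueError("resistance must be strictly positive")
    q = (P_in - P_out) / R
    if is_valve and q < 0.0:
        return 0.0
    return q


@dataclass
class EfferentState:
    """First-order effector states of the autonomic arc."""

    T_es: float
    E_max: float
    R_sys: float
    T_ev: float

    def heart_period(self, p: PlantParameters) -> float:
        T = self.T_ev + self.T_es - p.T0
        return max(T, p.T_minimum)


def efferent_update(state: EfferentState, f_es_delayed: float,
                    f_ev_delayed: float, p: PlantParameters,
                    dt: float) -> EfferentState:
    """Advance the four effectors one step under piecewise-constant delayed
    firing (exact exponential update of the first-order relaxations).

    Steady states: theta0 + G * ln(max(f_es - f_es_min, 1)) for the three
    sympathetic effectors and T0 + G_Tev * f_ev for the vagal one.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    ln = math.log(max(f_es_delayed - p.f_es_min, 1.0))
    a_es = 1.0 - math.exp(-dt / p.tau_es)
    a_ev = 1.0 - math.exp(-dt / p.tau_ev)
    return EfferentState(
        T_es=state.T_es + a_es * ((p.T0 + p.G_Ts * ln) - state.T_es),
        E_max=state.E_max + a_es * ((p.E_max + p.G_Emax * ln) - state.E_max),
        R_sys=state.R_sys + a_es * ((p.R1 + p.G_R * ln) - state.R_sys),
        T_ev=state.T_ev + a_ev * ((p.T0 + p.G_Tev * f_ev_delayed) - state.T_ev),
    )


# ---------------------------------------------------------------------------
# parameter packing for the compiled kernel
# ---------------------------------------------------------------------------

_THETA_FIELDS = (
    "R1", "R2", "R3", "C2", "C3", "E_min", "E_max", "T0", "a",
    "alpha1", "alpha2", "n1", "n2", "L", "Vd_lv", "Vd_a", "Vd_v",
    "G_R", "G_Ts", "G_Tev", "G_Emax", "tau_es", "tau_ev", "tau_p",
    "f_es_min", "P_n", "k_a", "f_ab_min", "f_ab_max",
    "f_es_inf", "f_es_0", "k_es", "f_ev_0", "f_ev_inf", "f_ab_0", "k_ev",
    "T_minimum",
)
(_iR1, _iR2, _iR3, _iC2, _iC3, _iEMIN, _iEMAX, _iT0, _iA, _iA1, _iA2,
 _iN1, _iN2, _iL, _iVDLV, _iVDA, _iVDV, _iGR, _iGTS, _iGTEV, _iGEM,
 _iTAUES, _iTAUEV, _iTAUP, _iFESMIN, _iPN, _iKA, _iFABMIN, _iFABMAX,
 _iFESINF, _iFES0, _iKES, _iFEV0, _iFEVINF, _iFAB0, _iKEV,
 _iTMIN) = range(len(_THETA_FIELDS))


def _pack(p: PlantParameters) -> np.ndarray:
    return np.array([getattr(p, f) for f in _THETA_FIELDS], dtype=np.float64)


# continuous state slots 0..8, bookkeeping 9..12
_NY = 9      # V_lv, V_a, V_v, Q_av, P_filt, T_es, Emax_eff, Rsys_eff, T_ev
_NS = 13     # + t_n, T_cur, map_accum, t_elapsed


@njit(cache=False)
def _firing(th, pf, d1, d2, d3):
    z = (pf - th[_iPN]) / th[_iKA]
    if z > 40.0:
        s = 1.0
    elif z < -40.0:
        s = 0.0
    else:
        s = 1.0 / (1.0 + math.exp(-z))
    fab = th[_iFABMIN] + (th[_iFABMAX] - th[_iFABMIN]) * s + d1
    if fab < 0.0:
        fab = 0.0
    fes = th[_iFESINF] + (th[_iFES0] - th[_iFESINF]) * math.exp(-th[_iKES] * fab) + d2
    zv = (fab - th[_iFAB0]) / th[_iKEV]
    if zv > 40.0:
        ev = 1.0
    elif zv < -40.0:
        ev = 0.0
    else:
        e = math.exp(zv)
        ev = e / (1.0 + e)
    fev = th[_iFEV0] + (th[_iFEVINF] - th[_iFEV0]) * ev + d3
    return fes, fev


@njit(cache=False)
def _deriv(th, y, tn, T, fes_d, fev_d, dy):
    # elastance at phase tn of the current beat, using the effector E_max
    x1 = (tn / (th[_iA1] * T)) ** th[_iN1]
    h1 = x1 / (1.0 + x1)
    h2 = 1.0 / (1.0 + (tn / (th[_iA2] * T)) ** th[_iN2])
    E = th[_iEMIN] + th[_iA] * (y[6] - th[_iEMIN]) * h1 * h2
    P_lv = E * (y[0] - th[_iVDLV])
    P_a = (y[1] - th[_iVDA]) / th[_iC3]
    P_v = (y[2] - th[_iVDV]) / th[_iC2]
    # mitral diode
    Q_mv = (P_v - P_lv) / th[_iR2] if P_v > P_lv else 0.0
    # aortic valve: inertance state with diode clamp
    Q_av = y[3]
    if Q_av > 0.0 or P_lv > P_a:
        dQ = (P_lv - P_a - th[_iR3] * Q_av) / th[_iL]
    else:
        dQ = 0.0
    Q_sys = (P_a - P_v) / y[7]
    dy[0] = Q_mv - Q_av
    dy[1] = Q_av - Q_sys
    dy[2] = Q_sys - Q_mv
    dy[3] = dQ
    dy[4] = (P_a - y[4]) / th[_iTAUP]
    ln = fes_d - th[_iFESMIN]
    ln = math.log(ln) if ln > 1.0 else 0.0
    dy[5] = -(y[5] - (th[_iT0] + th[_iGTS] * ln)) / th[_iTAUES]
    dy[6] = -(y[6] - (th[_iEMAX] + th[_iGEM] * ln)) / th[_iTAUES]
    dy[7] = -(y[7] - (th[_iR1] + th[_iGR] * ln)) / th[_iTAUES]
    dy[8] = -(y[8] - (th[_iT0] + th[_iGTEV] * fev_d)) / th[_iTAUEV]
    return P_a


@njit(cache=False)
def _run(th, state, fes_buf, fev_buf, pos, deltas, out, dt, d_es, d_ev):
    """Advance every trial through out.shape[1] cardiac cycles in place."""
    n = state.shape[0]
    n_cycles = out.shape[1]
    BL = fes_buf.shape[1]
    y = np.empty(_NY)
    yt = np.empty(_NY)
    k1 = np.empty(_NY)
    k2 = np.empty(_NY)
    k3 = np.empty(_NY)
    k4 = np.empty(_NY)
    for i in range(n):
        for j in range(_NY):
            y[j] = state[i, j]
        tn = state[i, 9]
        T = state[i, 10]
        map_acc = state[i, 11]
        tel = state[i, 12]
        p = int(pos[i])
        c = 0
        while c < n_cycles:
            d1 = deltas[i, c, 0]
            d2 = deltas[i, c, 1]
            d3 = deltas[i, c, 2]
            fes_d = fes_buf[i, (p - d_es) % BL]
            fev_d = fev_buf[i, (p - d_ev) % BL]
            # RK4 step (tn held at beat phase; elastance sampled per stage)
            pa = _deriv(th, y, tn, T, fes_d, fev_d, k1)
            h = 0.5 * dt
            for j in range(_NY):
                yt[j] = y[j] + h * k1[j]
            t2 = tn + h
            if t2 >= T:
                t2 = T * 0.999999
            _deriv(th, yt, t2, T, fes_d, fev_d, k2)
            for j in range(_NY):
                yt[j] = y[j] + h * k2[j]
            _deriv(th, yt, t2, T, fes_d, fev_d, k3)
            t4 = tn + dt
            if t4 >= T:
                t4 = T * 0.999999
            for j in range(_NY):
                yt[j] = y[j] + dt * k3[j]
            _deriv(th, yt, t4, T, fes_d, fev_d, k4)
            for j in range(_NY):
                y[j] += dt / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
            if y[3] < 0.0:
                y[3] = 0.0
            if not math.isfinite(y[0]):
                out[i, c, 0] = np.nan
                out[i, c, 1] = np.nan
                c = n_cycles
                break
            tn += dt
            map_acc += pa * dt
            tel += dt
            # record efferent firing for the delay lines
            fes_now, fev_now = _firing(th, y[4], d1, d2, d3)
            p = (p + 1) % BL
            fes_buf[i, p] = fes_now
            fev_buf[i, p] = fev_now
            if tn >= T:
                out[i, c, 0] = 60.0 / T
                out[i, c, 1] = map_acc / tel
                tn -= T
                map_acc = 0.0
                tel = 0.0
                Tn = y[8] + y[5] - th[_iT0]
                if Tn < th[_iTMIN]:
                    Tn = th[_iTMIN]
                T = Tn
                c += 1
        for j in range(_NY):
            state[i, j] = y[j]
        state[i, 9] = tn
        state[i, 10] = T
        state[i, 11] = map_acc
        state[i, 12] = tel
        pos[i] = p


# ---------------------------------------------------------------------------
# python-facing simulator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CycleOutput:
    """One completed cardiac cycle: index, heart rate (bpm), MAP (mmHg)."""

    k: int
    hr: float
    map: float


class SimulationError(RuntimeError):
    def __init__(self, cycle: int):
        super().__init__(f"non-finite plant state at cycle {cycle}")
        self.cycle = cycle


class CalibrationError(RuntimeError):
    def __init__(self, residuals):
        super().__init__(f"calibration failed to converge, residuals={residuals}")
        self.residuals = residuals


class CardioSim:
    """Stateful cycle-by-cycle plant simulator (one trajectory).

    ``step(deltas)`` advances one cardiac cycle under constant firing-rate
    increments and returns the completed cycle's (HR, MAP).
    """

    def __init__(self, p: PlantParameters, dt: float = DT_DEFAULT,
                 init_pressure: float = 138.0, state: np.ndarray | None = None):
        self.p = p
        self.dt = dt
        self.theta = _pack(p)
        self.d_es = max(int(round(p.D_es / dt)), 0)
        self.d_ev = max(int(round(p.D_ev / dt)), 0)
        bl = max(self.d_es, self.d_ev) + 2
        self._buf_len = bl
        if state is not None:
            self.state, self.fes_buf, self.fev_buf, self.pos = state
        else:
            self._init_state(init_pressure)
        self.k = 0

    def _init_state(self, pa0: float) -> None:
        p = self.p
        fes, fev = _firing(self.theta, pa0, 0.0, 0.0, 0.0)
        ln = math.log(max(fes - p.f_es_min, 1.0))
        T_es = p.T0 + p.G_Ts * ln
        E_eff = p.E_max + p.G_Emax * ln
        R_eff = p.R1 + p.G_R * ln
        T_ev = p.T0 + p.G_Tev * fev
        T = max(T_ev + T_es - p.T0, p.T_minimum)
        V_a = p.Vd_a + p.C3 * pa0
        V_lv = p.Vd_lv + 50.0
        V_v = p.V_total - V_a - V_lv
        s = np.zeros(_NS)
        s[:9] = [V_lv, V_a, V_v, 0.0, pa0, T_es, E_eff, R_eff, T_ev]
        s[10] = T
        self.state = s.reshape(1, _NS)
        self.fes_buf = np.full((1, self._buf_len), fes)
        self.fev_buf = np.full((1, self._buf_len), fev)
        self.pos = np.zeros(1, dtype=np.int64)

    def copy(self) -> "CardioSim":
        return CardioSim(self.p, self.dt, state=(
            self.state.copy(), self.fes_buf.copy(), self.fev_buf.copy(),
            self.pos.copy()))

    @property
    def total_volume(self) -> float:
        return float(self.state[0, 0] + self.state[0, 1] + self.state[0, 2])

    @property
    def heart_period(self) -> float:
        return float(self.state[0, 10])

    def run(self, deltas_per_cycle: np.ndarray) -> list[CycleOutput]:
        """Advance through one cycle per row of ``deltas_per_cycle`` (n, 3)."""
        d = np.atleast_2d(np.asarray(deltas_per_cycle, dtype=np.float64))
        if d.shape[1] != 3:
            raise ValueError("deltas must have shape (n_cycles, 3)")
        n_cycles = d.shape[0]
        out = np.empty((1, n_cycles, 2))
        _run(self.theta, self.state, self.fes_buf, self.fev_buf, self.pos,
             d.reshape(1, n_cycles, 3), out, self.dt, self.d_es, self.d_ev)
        if not np.all(np.isfinite(out)):
            raise SimulationError(self.k + int(np.argmax(~np.isfinite(out[0, :, 0]))))
        res = [CycleOutput(self.k + j, out[0, j, 0], out[0, j, 1])
               for j in range(n_cycles)]
        self.k += n_cycles
        return res

    def step(self, deltas) -> CycleOutput:
        return self.run(np.asarray(deltas, dtype=float).reshape(1, 3))[0]


def simulate_cycles(p: PlantParameters, deltas_per_cycle: np.ndarray,
                    n_cycles: int | None = None,
                    init: CardioSim | None = None,
                    dt: float = DT_DEFAULT) -> list[CycleOutput]:
    """Simulate ``n_cycles`` cardiac cycles under per-cycle firing increments.

    ``deltas_per_cycle`` is (n_cycles, 3): increments (Hz) added to the
    baroreceptive afferent, sympathetic efferent and vagal efferent firing,
    each held constant within its cycle.
    """
    d = np.atleast_2d(np.asarray(deltas_per_cycle, dtype=float))
    if n_cycles is None:
        n_cycles = d.shape[0]
    if d.shape[0] == 1 and n_cycles > 1:
        d = np.repeat(d, n_cycles, axis=0)
    if n_cycles < 1 or d.shape[0] != n_cycles:
        raise ValueError("need one 3-vector of firing increments per cycle")
    sim = init.copy() if init is not None else CardioSim(p, dt=dt)
    return sim.run(d)


def resting_state(p: PlantParameters, n_settle: int = 200,
                  dt: float = DT_DEFAULT) -> tuple[CardioSim, CycleOutput]:
    """Settle the unstimulated plant and return (settled simulator, last cycle)."""
    sim = CardioSim(p, dt=dt)
    out = sim.run(np.zeros((n_settle, 3)))
    return sim, out[-1]


def steady_outputs(p: PlantParameters, n_settle: int = 200,
                   n_avg: int = 5, dt: float = DT_DEFAULT) -> tuple[float, float]:
    """Unstimulated steady-state (HR, MAP), averaged over the last cycles."""
    sim = CardioSim(p, dt=dt)
    out = sim.run(np.zeros((n_settle, 3)))
    hr = float(np.mean([o.hr for o in out[-n_avg:]]))
    mp = float(np.mean([o.map for o in out[-n_avg:]]))
    return hr, mp


def simulate_trials(p: PlantParameters, deltas: np.ndarray, n_cycles: int,
                    rest: CardioSim | None = None,
                    dt: float = DT_DEFAULT) -> np.ndarray:
    """Batched open-loop trials: each row of ``deltas`` (n_trials, 3) is a
    constant stimulation held for ``n_cycles`` cycles, starting from the
    settled resting state. Returns (n_trials, n_cycles, 2) of (HR, MAP)."""
    deltas = np.asarray(deltas, dtype=np.float64)
    n_trials = deltas.shape[0]
    if rest is None:
        rest, _ = resting_state(p, dt=dt)
    state = np.repeat(rest.state, n_trials, axis=0).copy()
    fes = np.repeat(rest.fes_buf, n_trials, axis=0).copy()
    fev = np.repeat(rest.fev_buf, n_trials, axis=0).copy()
    pos = np.repeat(rest.pos, n_trials).copy()
    dseq = np.repeat(deltas[:, None, :], n_cycles, axis=1)
    out = np.empty((n_trials, n_cycles, 2))
    _run(rest.theta, state, fes, fev, pos, dseq, out, dt,
         rest.d_es, rest.d_ev)
    return out


def calibrate(p: PlantParameters, targets: tuple[float, float] = (409.0, 138.0),
              tol: tuple[float, float] = (1.0, 1.0),
              dt: float = DT_DEFAULT) -> PlantParameters:
    """Adjust (total blood volume, baroreceptor midpoint pressure) so the
    unstimulated steady state matches the target (HR bpm, MAP mmHg).

    Only parameters outside the published set are touched. Raises
    CalibrationError if the residual exceeds ``tol``.
    """
    from scipy.optimize import root

    hr_t, map_t = targets
    if hr_t <= 0 or map_t <= 0:
        raise ValueError("targets must be positive")

    def residual(x):
        q = p.replace(V_total=100.0 * x[0], P_n=100.0 * x[1])
        hr, mp = steady_outputs(q, dt=dt)
        return [hr - hr_t, mp - map_t]

    x0 = np.array([p.V_total / 100.0, p.P_n / 100.0])
    sol = root(residual, x0, method="hybr", options={"xtol": 1e-10})
    res = residual(sol.x)
    if abs(res[0]) > tol[0] or abs(res[1]) > tol[1]:
        raise CalibrationError(res)
    return p.replace(V_total=100.0 * sol.x[0], P_n=100.0 * sol.x[1])
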