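"""Receding-horizon optimization of stimulation parameters.

At every cardiac cycle the controller minimizes a cost over the surrogate's
predicted (HR, MAP) trajectory with respect to the next N_c command
6-vectors (pulse width and frequency at three locations), subject to box
bounds; commands beyond the control horizon are held at the last optimized
move, and only the first optimized action is applied (receding horizon).

Four cost variants are provided:

* ``sparsity``      — quadratic tracking + λ Σ ||u||₁ (drives unused
                      locations to zero, a continuous stand-in for on/off
                      location selection),
* ``min_energy``    — quadratic tracking + λ Σ uᵀRu,
* ``min_overshoot`` — sparsity cost + λ₂ Σ ||u − u(k−1)||₁ (penalizes
                      deviation from the previously applied action),
* ``offset_free``   — tracking toward optimized steady-state targets
                      (u_s, ŷ_s) with an integrating output disturbance d
                      and the terminal constraint r = f_NN(ŷ_s, u_s) + d.

All optimization is performed in normalized space: outputs through the
surrogate's NormStats, inputs scaled by the per-channel training span so a
zero command stays exactly zero (the L1 term must vanish at "off").
Gradients of the rollout cost are supplied to SLSQP as batched forward
differences, which keeps per-cycle solves in the millisecond range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .datagen import NormStats, denormalize, normalize
from .surrogate import SurrogateModel

__all__ = [
    "ControllerConfig", "DisturbanceState", "MPCSolution",
    "cost_sparsity", "cost_min_energy", "cost_min_overshoot",
    "solve_receding_horizon", "solve_offset_free", "disturbance_update",
]

_U_MAX_DEFAULT = np.array([0.5, 50.0, 0.5, 50.0, 0.5, 50.0])

VARIANTS = ("sparsity", "min_energy", "min_overshoot", "offset_free")


@dataclass
class ControllerConfig:
    """Horizons, weights, bounds and solver settings of one MPC variant."""

    variant: str = "sparsity"
    Np: int = 10
    Nc: int = 5
    Q: np.ndarray = field(default_factory=lambda: np.eye(2))
    R: np.ndarray = field(default_factory=lambda: np.eye(6))
    lam: float = 1e-3
    lam1: float = 1e-3
    lam2: float = 5e-5
    u_min: np.ndarray = field(default_factory=lambda: np.zeros(6))
    u_max: np.ndarray = field(default_factory=lambda: _U_MAX_DEFAULT.copy())
    Ld: np.ndarray = field(default_factory=lambda: np.array([0.06, 0.05]))
    tol: float = 1e-5
    max_iter: int = 50
    l1_eps: float = 1e-6   # smoothing of |x| as sqrt(x^2 + eps^2) for SLSQP
    target_weight: float = 100.0  # offset-free: weight (x Np) pulling y_s to r

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown cost variant {self.variant!r}")
        if not 1 <= self.Nc <= self.Np:
            raise ValueError("require 1 <= Nc <= Np")
        self.Q = np.asarray(self.Q, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        self.u_min = np.asarray(self.u_min, dtype=float)
        self.u_max = np.asarray(self.u_max, dtype=float)
        self.Ld = np.asarray(self.Ld, dtype=float)
        if np.any(self.u_min > self.u_max):
            raise ValueError("u_min must be elementwise <= u_max")
        for M in (self.Q, self.R):
            if not np.allclose(M, M.T) or np.any(np.linalg.eigvalsh(M) < -1e-12):
                raise ValueError("Q and R must be symmetric positive semidefinite")
        if min(self.lam, self.lam1, self.lam2) < 0:
            raise ValueError("cost weights must be non-negative")

    @property
    def n_decision(self) -> int:
        """Decision-variable count: 6 per control move, +8 when offset-free."""
        n = 6 * self.Nc
        if self.variant == "offset_free":
            n += 8
        return n


@dataclass
class DisturbanceState:
    """Integrating output-disturbance estimate of the offset-free scheme.

    ``d`` lives in normalized output units and starts at zero; ``y_aug_pred``
    is the previous cycle's one-step augmented prediction (normalized).
    """

    d: np.ndarray = field(default_factory=lambda: np.zeros(2))
    Ld: np.ndarray = field(default_factory=lambda: np.array([0.06, 0.05]))
    y_aug_pred: np.ndarray | None = None
    innovation: np.ndarray = field(default_factory=lambda: np.zeros(2))


@dataclass
class MPCSolution:
    u_seq: np.ndarray            # (Nc, 6) optimized commands, raw units
    y_pred: np.ndarray           # (Np, 2) predicted outputs, raw units
    cost: float
    status: int
    n_iter: int
    success: bool
    u_s: np.ndarray | None = None   # offset-free steady-state input (raw)
    y_s: np.ndarray | None = None   # offset-free steady-state output (raw)

    @property
    def first(self) -> np.ndarray:
        """The action actually applied to the plant."""
        return self.u_seq[0]


# ---------------------------------------------------------------------------
# cost functions (space-agnostic arithmetic on supplied trajectories)
# ---------------------------------------------------------------------------


def _smooth_l1(x, eps):
    return float(np.sum(np.sqrt(x * x + eps * eps)))


def _track(y_hat, r, Q):
    e = np.asarray(r, dtype=float) - np.asarray(y_hat, dtype=float)
    return float(np.einsum("ij,jk,ik->", e, Q, e))


def _check_dims(y_hat, u, r, cfg):
    y_hat = np.atleast_2d(y_hat)
    u = np.atleast_2d(u)
    r = np.atleast_2d(r)
    if y_hat.shape != (cfg.Np, 2) or r.shape != (cfg.Np, 2):
        raise ValueError(f"output/reference trajectories must be ({cfg.Np}, 2)")
    if u.shape != (cfg.Nc, 6):
        raise ValueError(f"input trajectory must be ({cfg.Nc}, 6)")
    return y_hat, u, r


def cost_sparsity(y_hat, u, r, cfg: ControllerConfig) -> float:
    """Σ (r−ŷ)ᵀQ(r−ŷ) + λ Σ ||u||₁."""
    y_hat, u, r = _check_dims(y_hat, u, r, cfg)
    return _track(y_hat, r, cfg.Q) + cfg.lam * _smooth_l1(u, cfg.l1_eps)


def cost_min_energy(y_hat, u, r, cfg: ControllerConfig) -> float:
    """Σ (r−ŷ)ᵀQ(r−ŷ) + λ Σ uᵀRu."""
    y_hat, u, r = _check_dims(y_hat, u, r, cfg)
    quad = float(np.einsum("ij,jk,ik->", u, cfg.R, u))
    return _track(y_hat, r, cfg.Q) + cfg.lam * quad


def cost_min_overshoot(y_hat, u, r, u_prev, cfg: ControllerConfig) -> float:
    """Σ (r−ŷ)ᵀQ(r−ŷ) + λ₁ Σ ||u||₁ + λ₂ Σ ||u − u(k−1)||₁."""
    y_hat, u, r = _check_dims(y_hat, u, r, cfg)
    u_prev = np.asarray(u_prev, dtype=float).reshape(6)
    return (_track(y_hat, r, cfg.Q)
            + cfg.lam1 * _smooth_l1(u, cfg.l1_eps)
            + cfg.lam2 * _smooth_l1(u - u_prev, cfg.l1_eps))


# ---------------------------------------------------------------------------
# surrogate rollouts in normalized space
# ---------------------------------------------------------------------------


def _u_span(norm: NormStats) -> np.ndarray:
    return norm.span[2:8]


def _bcast_state(state, B):
    out = []
    for s in state:
        out.append(tuple(np.repeat(a, B, axis=0) for a in s))
    return out


def _rollout_batch(model: SurrogateModel, state, y0n: np.ndarray,
                   U_s: np.ndarray, Np: int, d=None) -> np.ndarray:
    """Predict (B, Np, 2) normalized outputs for B candidate move sequences.

    ``U_s`` is (B, Nc, 6) in span-scaled units; moves beyond Nc are held.
    ``d`` (2,) is an additive normalized output disturbance (offset-free).
    """
    B, Nc, _ = U_s.shape
    mu_u = model.norm.mu[2:8]
    span = model.norm.span[2:8]
    # span-scaled -> raw -> normalized command
    Un = (U_s * span - mu_u) / span
    st = _bcast_state(state, B)
    y = np.repeat(y0n.reshape(1, 2), B, axis=0)
    out = np.empty((B, Np, 2))
    for i in range(Np):
        u = Un[:, min(i, Nc - 1), :]
        x = np.concatenate([y, u], axis=1)
        y, st, _ = model.step(x, st)
        if d is not None:
            y = y + d
        out[:, i, :] = y
    return out


def _candidate_moves(Nc: int, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Coarse lattice of constant move sequences for global pre-screening.

    Each location takes one of four activation levels (off, 30%, 60%,
    full) applied to both its pulse width and frequency: 64 candidates,
    evaluated in a single batched rollout.
    """
    levels = np.array([0.0, 0.3, 0.6, 1.0])
    cands = []
    for a in levels:
        for b in levels:
            for c in levels:
                u = lo + (hi - lo) * np.array([a, a, b, b, c, c])
                cands.append(u)
    U = np.array(cands)                       # (64, 6), span-scaled
    return np.repeat(U[:, None, :], Nc, axis=1)


def _fd_gradient(f, x, h=1e-7):
    """Forward-difference gradient where f evaluates a whole batch at once."""
    X = np.repeat(x.reshape(1, -1), x.size + 1, axis=0)
    X[1:] += np.eye(x.size) * h
    vals = f(X)
    return (vals[1:] - vals[0]) / h, vals[0]


# ---------------------------------------------------------------------------
# receding-horizon solves
# ---------------------------------------------------------------------------


def _norm_ref(r_traj, Np, norm):
    r = np.atleast_2d(np.asarray(r_traj, dtype=float))
    if r.shape[0] < Np:  # hold the last target beyond the schedule end
        r = np.vstack([r, np.repeat(r[-1:], Np - r.shape[0], axis=0)])
    return normalize(r[:Np], norm.slice(slice(0, 2)))


def solve_receding_horizon(model: SurrogateModel, state, y0, r_traj,
                           cfg: ControllerConfig, u_prev=None,
                           warm_start=None) -> MPCSolution:
    """Solve one cycle of the tracking MPC (sparsity / min-energy /
    min-overshoot variants) and return the optimized move sequence.

    ``state`` is the surrogate's current recurrent state (batch 1); ``y0``
    the measured (HR, MAP); ``r_traj`` the raw reference schedule from the
    current cycle onward. ``warm_start`` is a raw (Nc, 6) initial guess,
    typically the previous solution shifted by one move.
    """
    if cfg.variant == "offset_free":
        raise ValueError("use solve_offset_free for the offset-free variant")
    norm = model.norm
    span = _u_span(norm)
    y0n = normalize(np.asarray(y0, dtype=float).reshape(2),
                    norm.slice(slice(0, 2)))
    rn = _norm_ref(r_traj, cfg.Np, norm)
    lo = cfg.u_min / span
    hi = cfg.u_max / span
    if warm_start is None:
        x0 = np.zeros(6 * cfg.Nc)
    else:
        x0 = (np.asarray(warm_start, dtype=float).reshape(cfg.Nc, 6)
              / span).ravel()
    x0 = np.clip(x0, np.tile(lo, cfg.Nc), np.tile(hi, cfg.Nc))
    u_prev_s = (np.zeros(6) if u_prev is None
                else np.asarray(u_prev, dtype=float).reshape(6) / span)

    def batch_cost(X):
        B = X.shape[0]
        U = X.reshape(B, cfg.Nc, 6)
        Y = _rollout_batch(model, state, y0n, U, cfg.Np)
        e = rn[None, :, :] - Y
        c = np.einsum("bij,jk,bik->b", e, cfg.Q, e)
        if cfg.variant == "sparsity":
            c = c + cfg.lam * np.sqrt(U * U + cfg.l1_eps ** 2).sum(axis=(1, 2))
        elif cfg.variant == "min_energy":
            c = c + cfg.lam * np.einsum("bij,jk,bik->b", U, cfg.R, U)
        else:  # min_overshoot
            dU = U - u_prev_s
            c = (c + cfg.lam1 * np.sqrt(U * U + cfg.l1_eps ** 2).sum(axis=(1, 2))
                 + cfg.lam2 * np.sqrt(dU * dU + cfg.l1_eps ** 2).sum(axis=(1, 2)))
        return c

    def fun(x):
        return float(batch_cost(x.reshape(1, -1))[0])

    def jac(x):
        g, _ = _fd_gradient(batch_cost, x)
        return g

    # global pre-screen over a coarse command lattice plus the warm start;
    # the best candidate seeds the local solve
    cands = np.vstack([
        _candidate_moves(cfg.Nc, lo, hi).reshape(64, -1),
        x0.reshape(1, -1)])
    x0 = cands[int(np.argmin(batch_cost(cands)))]

    res = minimize(fun, x0, jac=jac, method="SLSQP",
                   bounds=list(zip(np.tile(lo, cfg.Nc), np.tile(hi, cfg.Nc))),
                   options={"ftol": cfg.tol, "maxiter": cfg.max_iter})
    xs = np.clip(res.x, np.tile(lo, cfg.Nc), np.tile(hi, cfg.Nc))
    U_s = xs.reshape(cfg.Nc, 6)
    Yn = _rollout_batch(model, state, y0n, U_s[None], cfg.Np)[0]
    return MPCSolution(
        u_seq=np.clip(U_s * span, cfg.u_min, cfg.u_max),
        y_pred=denormalize(Yn, norm.slice(slice(0, 2))),
        cost=float(res.fun), status=int(res.status),
        n_iter=int(res.get("nit", -1)), success=bool(res.success))


def disturbance_update(ds: DisturbanceState, y_measured_n: np.ndarray,
                       y_aug_pred_n: np.ndarray | None = None) -> DisturbanceState:
    """Integrate the disturbance estimate with the latest innovation.

    The innovation is the measured output minus the previous augmented
    prediction (normalized); the estimate follows d <- d + L_d ∘ innovation,
    which converges geometrically on a constant mismatch for 0 < L_d < 2.
    """
    if y_aug_pred_n is None:
        y_aug_pred_n = ds.y_aug_pred
    if y_aug_pred_n is None:  # no prediction yet (scenario start)
        return ds
    eps = np.asarray(y_measured_n, dtype=float) - np.asarray(y_aug_pred_n,
                                                             dtype=float)
    return DisturbanceState(d=ds.d + ds.Ld * eps, Ld=ds.Ld,
                            y_aug_pred=ds.y_aug_pred, innovation=eps)


def solve_offset_free(model: SurrogateModel, state, y0, r_target,
                      ds: DisturbanceState, cfg: ControllerConfig,
                      warm_start=None) -> MPCSolution:
    """Offset-free MPC: optimize moves plus steady-state targets (u_s, ŷ_s)
    subject to the terminal consistency constraint r = f_NN(ŷ_s, u_s) + d.

    The decision vector stacks 6·Nc scaled moves, the scaled steady-state
    input (6) and the normalized steady-state output (2) — 68 variables at
    Nc = 10.
    """
    if cfg.variant != "offset_free":
        raise ValueError("config variant must be 'offset_free'")
    norm = model.norm
    span = _u_span(norm)
    sy = norm.slice(slice(0, 2))
    y0n = normalize(np.asarray(y0, dtype=float).reshape(2), sy)
    rn = normalize(np.asarray(r_target, dtype=float).reshape(2), sy)
    d = ds.d.copy()
    nu = 6 * cfg.Nc
    lo = cfg.u_min / span
    hi = cfg.u_max / span
    bounds = ([*zip(np.tile(lo, cfg.Nc), np.tile(hi, cfg.Nc))]
              + [*zip(lo, hi)] + [(-2.0, 2.0)] * 2)
    if warm_start is None:
        x0 = np.zeros(cfg.n_decision)
        x0[nu + 6:] = rn
    else:
        x0 = np.asarray(warm_start, dtype=float).copy()
    x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])

    mu_u = norm.mu[2:8]

    W = cfg.target_weight * cfg.Np

    def batch_cost(X):
        B = X.shape[0]
        U = X[:, :nu].reshape(B, cfg.Nc, 6)
        u_s = X[:, nu:nu + 6]
        y_s = X[:, nu + 6:]
        Y = _rollout_batch(model, state, y0n, U, cfg.Np, d=d)
        e = y_s[:, None, :] - Y
        c = np.einsum("bij,jk,bik->b", e, cfg.Q, e)
        du = U - u_s[:, None, :]
        c = c + np.einsum("bij,jk,bik->b", du, cfg.R, du)
        # soft steady-state target: pulls y_s onto r, degrading gracefully
        # when the target is not a reachable steady state
        c = c + W * np.sum((y_s - rn) ** 2, axis=1)
        return c

    def fun(x):
        return float(batch_cost(x.reshape(1, -1))[0])

    def jac(x):
        g, _ = _fd_gradient(batch_cost, x)
        return g

    def terminal(x):
        # steady-state consistency: (y_s, u_s) must be a fixed point of the
        # disturbance-augmented model, y_s = f(y_s, u_s) + d; the cost's
        # soft target term drives y_s onto r
        u_s = x[nu:nu + 6]
        y_s = x[nu + 6:]
        un = (u_s * span - mu_u) / span
        xin = np.concatenate([y_s, un]).reshape(1, -1)
        y1, _, _ = model.step(xin, _bcast_state(state, 1))
        return (y1[0] + d) - y_s

    # pre-screen constant-move candidates (steady-state pair seeded at the
    # candidate's last move and the target) to pick the local-solve start
    Ucand = _candidate_moves(cfg.Nc, lo, hi)
    cands = np.hstack([Ucand.reshape(64, -1), Ucand[:, -1, :],
                       np.tile(rn, (64, 1))])
    cands = np.vstack([cands, x0.reshape(1, -1)])
    x0 = cands[int(np.argmin(batch_cost(cands)))]

    res = minimize(fun, x0, jac=jac, method="SLSQP", bounds=bounds,
                   constraints=[{"type": "eq", "fun": terminal}],
                   options={"ftol": cfg.tol, "maxiter": cfg.max_iter})
    xs = np.clip(res.x, [b[0] for b in bounds], [b[1] for b in bounds])
    U_s = xs[:nu].reshape(cfg.Nc, 6)
    Yn = _rollout_batch(model, state, y0n, U_s[None], cfg.Np, d=d)[0]
    return MPCSolution(
        u_seq=np.clip(U_s * span, cfg.u_min, cfg.u_max),
        y_pred=denormalize(Yn, sy),
        cost=float(res.fun), status=int(res.status),
        n_iter=int(res.get("nit", -1)), success=bool(res.success),
        u_s=xs[nu:nu + 6] * span,
        y_s=denormalize(xs[nu + 6:], sy))
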