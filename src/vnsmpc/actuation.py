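"""Stimulation device model: VNS commands to neural firing-rate increments.

A command is six numbers — pulse width (ms) and pulse frequency (Hz) at each
of three cuff locations — plus per-location on/off flags. Fiber recruitment
saturates with pulse width, and the induced firing-rate change scales with
pulse frequency; both follow a Hill saturation with coefficient 2. A 3x3
concentration matrix C maps locations to the three fiber types
(baroreceptive, sympathetic, vagal): in the baseline plant each location
recruits exactly one fiber type (C = identity), while the intra-patient and
overactive-sympathetic variants mix and rescale the concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PW_MAX", "PF_MAX", "VNSCommand", "RecruitmentParams", "FiringDeltas",
    "recruitment_fraction", "rate_gain", "firing_deltas", "build_variant",
]

PW_MAX = 0.5   # ms
PF_MAX = 50.0  # Hz

C_IDENTITY = np.eye(3)
C_INTRA_PATIENT = np.array([[1.1, 0.1, 0.2],
                            [0.1, 0.8, 0.0],
                            [0.2, 0.2, 0.6]])
C_SYMPATHETIC = np.array([[1.3, 0.1, 0.1],
                          [0.1, 1.4, 0.1],
                          [0.1, 0.1, 1.3]])


@dataclass(frozen=True)
class VNSCommand:
    """Per-cycle stimulation command at three locations."""

    pw: tuple[float, float, float]      # pulse widths, ms
    pf: tuple[float, float, float]      # pulse frequencies, Hz
    on: tuple[int, int, int] = (1, 1, 1)

    def __post_init__(self):
        for w in self.pw:
            if not 0.0 <= w <= PW_MAX:
                raise ValueError(f"pulse width {w} outside [0, {PW_MAX}] ms")
        for f in self.pf:
            if not 0.0 <= f <= PF_MAX:
                raise ValueError(f"pulse frequency {f} outside [0, {PF_MAX}] Hz")
        if any(d not in (0, 1) for d in self.on):
            raise ValueError("on/off flags must be 0 or 1")

    @classmethod
    def off(cls) -> "VNSCommand":
        return cls(pw=(0.0, 0.0, 0.0), pf=(0.0, 0.0, 0.0), on=(0, 0, 0))

    @classmethod
    def from_vector(cls, u, on=(1, 1, 1)) -> "VNSCommand":
        """Build from the controller's 6-vector (pw1, pf1, pw2, pf2, pw3, pf3)."""
        u = np.asarray(u, dtype=float)
        if u.shape != (6,):
            raise ValueError("command vector must have shape (6,)")
        return cls(pw=(u[0], u[2], u[4]), pf=(u[1], u[3], u[5]), on=tuple(on))

    def as_vector(self) -> np.ndarray:
        """6-vector (pw1, pf1, pw2, pf2, pw3, pf3) with off locations zeroed."""
        out = np.empty(6)
        for i in range(3):
            out[2 * i] = self.on[i] * self.pw[i]
            out[2 * i + 1] = self.on[i] * self.pf[i]
        return out


@dataclass
class RecruitmentParams:
    """Fiber recruitment constants of the stimulation device model."""

    k_w: float = 0.2     # pulse-width half-saturation (ms)
    k_f: float = 20.0    # pulse-frequency half-saturation (Hz)
    C: np.ndarray = field(default_factory=lambda: C_IDENTITY.copy())
    G: np.ndarray = field(default_factory=lambda: np.array([30.0, 30.0, 30.0]))
    n: int = 3

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if self.k_w <= 0 or self.k_f <= 0:
            raise ValueError("half-saturation constants must be positive")
        if self.C.shape != (self.n, 3):
            raise ValueError(f"C must be {self.n}x3, got {self.C.shape}")
        if np.any(self.C < 0):
            raise ValueError("fiber concentrations must be non-negative")
        if self.G.shape != (3,):
            raise ValueError("G must be a 3-vector of fiber gains")


@dataclass(frozen=True)
class FiringDeltas:
    """Firing-rate increments (Hz) on the baroreceptive afferent, sympathetic
    efferent, and vagal efferent channels."""

    baro: float
    symp: float
    vagal: float

    def as_array(self) -> np.ndarray:
        return np.array([self.baro, self.symp, self.vagal])


def _hill2(x, k):
    z = (np.asarray(x, dtype=float) / k) ** 2
    return z / (1.0 + z)


def recruitment_fraction(pw, k_w: float = 0.2):
    """Fraction of fibers recruited at pulse width ``pw`` (ms).

    Saturating Hill form (coefficient 2): 0 at pw=0, 0.5 at pw=k_w,
    approaching 1 for wide pulses.
    """
    if k_w <= 0:
        raise ValueError("k_w must be positive")
    if np.any(np.asarray(pw) < 0):
        raise ValueError("pulse width must be non-negative")
    return _hill2(pw, k_w)


def rate_gain(pf, k_f: float = 20.0):
    """Relative firing-rate change driven by pulse frequency ``pf`` (Hz)."""
    if k_f <= 0:
        raise ValueError("k_f must be positive")
    if np.any(np.asarray(pf) < 0):
        raise ValueError("pulse frequency must be non-negative")
    return _hill2(pf, k_f)


def firing_deltas(cmd: VNSCommand, rp: RecruitmentParams | None = None) -> FiringDeltas:
    """Aggregate firing-rate increment per fiber type:

        Δf_j = (G_j / n) Σ_i δ_i C_ij F(Pw_i) ΔR(Pf_i)
    """
    if rp is None:
        rp = RecruitmentParams()
    act = np.array([
        cmd.on[i] * recruitment_fraction(cmd.pw[i], rp.k_w) * rate_gain(cmd.pf[i], rp.k_f)
        for i in range(rp.n)
    ])
    df = (rp.G / rp.n) * (act @ rp.C)
    return FiringDeltas(baro=df[0], symp=df[1], vagal=df[2])


def firing_deltas_from_vectors(u: np.ndarray, rp: RecruitmentParams) -> np.ndarray:
    """Vectorised Δf for an array of command 6-vectors, shape (..., 6) -> (..., 3)."""
    u = np.asarray(u, dtype=float)
    pw = u[..., 0::2]
    pf = u[..., 1::2]
    act = _hill2(pw, rp.k_w) * _hill2(pf, rp.k_f)
    return (act @ rp.C) * (rp.G / rp.n)


def build_variant(kind: str):
    """Return (PlantParameters, RecruitmentParams) for a named plant variant.

    ``healthy``: published baseline values, C = identity.
    ``intra_patient``: healthy plant, mixed recruitment concentrations.
    ``sympathetic``: overactive-sympathetic parameter substitutions plus its
    own recruitment matrix and fiber gains (G2=33, G3=27).
    """
    from .params import healthy_parameters, sympathetic_parameters

    if kind == "healthy":
        return healthy_parameters(), RecruitmentParams()
    if kind == "intra_patient":
        return healthy_parameters(), RecruitmentParams(C=C_INTRA_PATIENT.copy())
    if kind == "sympathetic":
        return (sympathetic_parameters(),
                RecruitmentParams(C=C_SYMPATHETIC.copy(),
                                  G=np.array([30.0, 33.0, 27.0])))
    raise ValueError(f"unknown plant variant: {kind!r}")
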