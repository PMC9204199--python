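"""Parameter sets for the lumped-parameter rat cardiovascular/baroreflex plant.

The plant couples three model parts: a closed-loop circulation (time-varying
elastance left ventricle, arterial and venous compliances, diode valves,
outflow inertance), a baroreflex arc (filtered arterial pressure -> afferent
firing -> sympathetic/vagal efferent firing -> first-order delayed effectors
on heart period, contractility and systemic resistance), and a stimulation
device model that injects firing-rate increments into the three neural
channels.

Two named presets are shipped: ``healthy`` (the baseline operating point,
409 bpm / 138 mmHg at rest) and ``sympathetic`` (an overactive-sympathetic
variant with elevated sympathetic gains and reduced vagal gain, resting near
452 bpm / 152 mmHg).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["PlantParameters", "healthy_parameters", "sympathetic_parameters"]


@dataclass
class PlantParameters:
    # -- circulation -------------------------------------------------------
    R1: float = 0.01       # systemic resistance baseline (mmHg·s/ml), efferent-modulated
    R2: float = 0.0001     # mitral valve resistance (mmHg·s/ml)
    R3: float = 0.008      # aortic valve resistance (mmHg·s/ml)
    C2: float = 20.0       # venous compliance (ml/mmHg)
    C3: float = 1.8        # systemic arterial compliance (ml/mmHg)
    E_min: float = 0.02    # end-diastolic elastance (mmHg/ml)
    E_max: float = 1.2     # end-systolic elastance baseline (mmHg/ml), efferent-modulated
    T0: float = 60.0 / 450.0  # intrinsic heart period (s)
    L: float = 1.0e-5      # aortic outflow inertance (mmHg·s²/ml)
    # double-Hill elastance shape (dimensionless)
    a: float = 1.0         # amplitude normalisation (set so the shape peak is 1)
    alpha1: float = 0.3
    alpha2: float = 0.5
    n1: float = 1.9
    n2: float = 21.9
    # unstressed volumes and total blood volume (ml)
    Vd_lv: float = 5.0
    Vd_a: float = 10.0
    Vd_v: float = 50.0
    V_total: float = 800.0  # refined by calibrate()
    # -- efferent effector pathways ---------------------------------------
    G_R: float = 0.06      # systemic resistance gain (mmHg·s/ml per ln-Hz)
    G_Ts: float = -0.01    # sympathetic heart-period gain (s per ln-Hz)
    G_Tev: float = 0.015   # vagal heart-period gain (s/Hz)
    G_Emax: float = 0.3    # contractility gain (mmHg/ml per ln-Hz)
    tau_es: float = 1.0    # sympathetic effector time constant (s)
    tau_ev: float = 0.5    # vagal effector time constant (s)
    D_es: float = 0.3      # sympathetic pathway delay (s)
    D_ev: float = 0.1      # vagal pathway delay (s)
    f_es_min: float = 2.75  # minimum sympathetic firing entering the ln(·) floor (Hz)
    # -- baroreceptor afferent --------------------------------------------
    tau_p: float = 1.0     # arterial pressure filter time constant (s)
    P_n: float = 138.0     # afferent sigmoid midpoint pressure (mmHg); refined by calibrate()
    k_a: float = 100.0     # afferent sigmoid width (mmHg)
    f_ab_min: float = 2.52  # afferent firing floor (Hz)
    f_ab_max: float = 47.78  # afferent firing ceiling (Hz)
    # -- efferent firing maps ---------------------------------------------
    f_es_inf: float = 2.10  # sympathetic firing at high afferent drive (Hz)
    f_es_0: float = 16.11   # sympathetic firing at zero afferent drive (Hz)
    k_es: float = 0.0675    # sympathetic exponential slope (1/Hz)
    f_ev_0: float = 0.2     # vagal firing at low afferent drive (Hz)
    f_ev_inf: float = 2.0   # vagal firing at high afferent drive (Hz)
    f_ab_0: float = 25.0    # vagal sigmoid midpoint (Hz)
    k_ev: float = 7.06      # vagal sigmoid width (Hz)
    # -- numerics ----------------------------------------------------------
    T_minimum: float = 0.05  # heart-period clamp (s); 1200 bpm ceiling

    def __post_init__(self) -> None:
        for name in ("R1", "R2", "R3", "C2", "C3", "E_min", "E_max", "T0",
                     "L", "tau_es", "tau_ev", "tau_p", "V_total"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.E_min >= self.E_max:
            raise ValueError("E_min must be smaller than E_max")
        if self.D_es < 0 or self.D_ev < 0:
            raise ValueError("delays must be non-negative")

    def replace(self, **changes) -> "PlantParameters":
        return dataclasses.replace(self, **changes)

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PlantParameters":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PlantParameters":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _hill_shape_peak(alpha1: float, alpha2: float, n1: float, n2: float,
                     n_grid: int = 20000) -> float:
    """Maximum of the raw double-Hill product over one period (dense scan)."""
    peak = 0.0
    for i in range(1, n_grid):
        x = i / n_grid  # t_n / T
        h1 = (x / alpha1) ** n1
        h1 = h1 / (1.0 + h1)
        h2 = 1.0 / (1.0 + (x / alpha2) ** n2)
        v = h1 * h2
        if v > peak:
            peak = v
    return peak


# Amplitude that makes the elastance reach exactly E_max at the shape peak.
_A_NORM = 1.0 / _hill_shape_peak(0.3, 0.5, 1.9, 21.9)


def healthy_parameters() -> PlantParameters:
    """Baseline parameter preset (resting operating point 409 bpm / 138 mmHg).

    Circulation constants, efferent gains and the intrinsic heart period carry
    the published baseline values; the remaining constants (volumes,
    baroreceptor and efferent-map shapes, delays, time constants) were fixed
    once by anchoring the model's healthy and overactive-sympathetic resting
    points, see docs/methods.md.
    """
    return PlantParameters(
        a=_A_NORM,
        # design-time anchored constants (see docs/methods.md)
        V_total=_DESIGN["V_total"],
        P_n=_DESIGN["P_n"],
        k_a=_DESIGN["k_a"],
        f_es_min=_DESIGN["f_es_min"],
        f_ev_0=_DESIGN["f_ev_0"],
        f_ev_inf=_DESIGN["f_ev_inf"],
        G_Emax=_DESIGN["G_Emax"],
    )


def sympathetic_parameters(base: PlantParameters | None = None) -> PlantParameters:
    """Overactive-sympathetic preset: elevated sympathetic influence, reduced
    vagal tone. Only the published substitutions are applied to the (possibly
    calibrated) healthy parameter set."""
    if base is None:
        base = healthy_parameters()
    return base.replace(
        R1=0.007, R2=0.0002, R3=0.006, C2=25.0, C3=1.4,
        E_min=0.01, E_max=1.1, T0=60.0 / 480.0,
        G_R=0.07, G_Ts=-0.015, G_Tev=0.011,
    )


# Anchored design constants, frozen after the operating-point fit.
_DESIGN = {
    "V_total": 972.4163519900,
    "P_n": 124.1049665466,
    "k_a": 140.0,
    "f_es_min": 2.66,
    "f_ev_0": 0.2,
    "f_ev_inf": 2.2,
    "G_Emax": 0.3,
}
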