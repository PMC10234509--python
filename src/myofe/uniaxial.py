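"""Homogeneous uniaxial-stress driver for elongation protocols.

Emulates the tensile testing of a muscle specimen at a single material
point: the axial stretch history is prescribed, the lateral stretch is
solved at every step so the lateral normal Cauchy stresses vanish
(uniaxial stress), and the fiber lies along the pull axis.  Supports the
two canonical protocols — passive elongation at constant velocity, and
active elongation with an isometric pre-hold to reach full activation
before the pull.

Engineering stress here is axial force per undeformed cross-sectional
area, i.e. the axial first Piola-Kirchhoff component
``sigma_xx * lambda_lat**2``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .constitutive import (
    MaterialPointState,
    advance_fiber_state,
    activation as activation_fn,
    cauchy_stress_batch,
    initial_state,
)
from .errors import ConvergenceError
from .params import MaterialParams

__all__ = [
    "ElongationProtocol",
    "StressStrainCurve",
    "solve_lateral_stretch",
    "run_elongation",
    "curve_metrics",
    "curve_to_frame",
]

_AXIS = np.array([1.0, 0.0, 0.0])


@dataclasses.dataclass(frozen=True)
class ElongationProtocol:
    """Loading protocol of a uniaxial elongation test.

    The default values reproduce the canonical active test: a 50 mm
    specimen held isometric for 0.5 s (to ensure full activation), then
    pulled at 5 mm/s for 2 s (20 % final elongation).
    """

    specimen_length: float = 0.050
    pull_velocity: float = 0.005
    hold_duration: float = 0.5
    pull_duration: float = 2.0
    time_step: float = 1.0e-3
    active: bool = True
    t0: float = 0.0
    t1: float = 1.0e6
    n1: float = 0.0
    n2: float = 1.0

    def __post_init__(self) -> None:
        if not self.pull_duration > 0.0:
            raise ValueError("pull_duration must be positive")
        if not (0.0 < self.time_step <= self.pull_duration / 100.0):
            raise ValueError(
                "time_step must be positive and <= pull_duration/100")

    @classmethod
    def passive(cls, **kw) -> "ElongationProtocol":
        """Passive elongation: no hold, zero activation throughout."""
        kw.setdefault("hold_duration", 0.0)
        return cls(active=False, **kw)

    def axial_stretch(self, t):
        """Prescribed axial stretch history lambda_ax(t)."""
        t = np.asarray(t, dtype=float)
        pull = np.clip(t - self.hold_duration, 0.0, self.pull_duration)
        return 1.0 + self.pull_velocity * pull / self.specimen_length

    def activation_level(self, t, params: MaterialParams):
        if not self.active:
            return np.zeros_like(np.asarray(t, dtype=float)) \
                if np.ndim(t) else 0.0
        sched = params.replace(t0=self.t0, t1=self.t1, n1=self.n1, n2=self.n2)
        return activation_fn(t, sched)


@dataclasses.dataclass
class StressStrainCurve:
    """Time series produced by :func:`run_elongation`."""

    time: np.ndarray
    strain: np.ndarray
    stress: np.ndarray          # engineering stress [Pa]
    cauchy_axial: np.ndarray    # true axial stress [Pa]
    lateral_stretch: np.ndarray
    jacobian: np.ndarray
    activation: np.ndarray
    states: list                # MaterialPointState snapshots


def _uniaxial_stress_components(lambda_ax, lambda_lat, sig_fiber,
                                params: MaterialParams):
    """(sigma_xx, sigma_yy) for F = diag(lambda_ax, lambda_lat, lambda_lat),
    fiber along x."""
    F = np.diag([lambda_ax, lambda_lat, lambda_lat])
    sig = cauchy_stress_batch(F, _AXIS, sig_fiber, params)
    return float(sig[0, 0]), float(sig[1, 1])


def solve_lateral_stretch(axial_stretch: float, state: MaterialPointState,
                          params: MaterialParams,
                          dt: float | None = None,
                          activation_level: float = 0.0,
                          guess: float | None = None):
    """Lateral stretch nulling the lateral Cauchy stress at fixed axial stretch.

    If ``dt`` is given, the fiber state is advanced by one trial increment
    for every candidate lateral stretch (the modified fiber stretch
    depends on J, hence on the lateral stretch); otherwise the frozen
    ``state`` stresses are used.

    Returns ``(lambda_lat, trial_state)`` where ``trial_state`` is the
    advanced state at the solution (or the input state if dt is None).
    """
    if not axial_stretch > 0.0:
        raise ValueError("axial_stretch must be positive")

    def trial(lmb_lat):
        J = axial_stretch * lmb_lat ** 2
        lam_f_bar = J ** (-1.0 / 3.0) * axial_stretch
        if dt is not None:
            st = advance_fiber_state(state, lam_f_bar, dt,
                                     activation_level, params)
        else:
            st = state
        sig_fiber = st.sigma_pe + st.sigma_see
        _, syy = _uniaxial_stress_components(axial_stretch, lmb_lat,
                                             sig_fiber, params)
        return syy, st

    def resid(lmb_lat):
        return trial(lmb_lat)[0]

    x0 = guess if guess is not None else axial_stretch ** (-0.5)
    lo, hi = x0 * 0.95, x0 * 1.05
    flo, fhi = resid(lo), resid(hi)
    for _ in range(40):
        if flo * fhi <= 0.0:
            break
        lo *= 0.97
        hi *= 1.03
        flo, fhi = resid(lo), resid(hi)
    else:
        raise ConvergenceError(
            f"no lateral-stretch bracket; residuals ({flo:.3e}, {fhi:.3e}) "
            f"on [{lo:.4f}, {hi:.4f}]")
    lam_lat = brentq(resid, lo, hi, xtol=1e-14, rtol=8.9e-16)
    syy, st = trial(lam_lat)
    if abs(syy) > 1.0:
        raise ConvergenceError(
            f"lateral stress residual {syy:.3e} Pa exceeds 1 Pa")
    return lam_lat, st


def run_elongation(protocol: ElongationProtocol,
                   params: MaterialParams) -> StressStrainCurve:
    """Run a passive or active elongation protocol at a material point."""
    dt = protocol.time_step
    t_end = protocol.hold_duration + protocol.pull_duration
    n_steps = int(round(t_end / dt))
    times = np.arange(n_steps + 1) * dt

    state = initial_state(1.0)
    lam_lat = 1.0
    rows = {key: [0.0] for key in
            ("strain", "stress", "cauchy", "lat", "J", "act")}
    rows["lat"] = [1.0]
    rows["J"] = [1.0]
    rows["act"][0] = float(protocol.activation_level(0.0, params))
    states = [state.copy()]

    for t in times[1:]:
        lam_ax = float(protocol.axial_stretch(t))
        act = float(protocol.activation_level(t, params))
        lam_lat, state = solve_lateral_stretch(
            lam_ax, state, params, dt=dt, activation_level=act,
            guess=lam_lat)
        sig_fiber = state.sigma_pe + state.sigma_see
        sxx, _ = _uniaxial_stress_components(lam_ax, lam_lat, sig_fiber,
                                             params)
        rows["strain"].append(lam_ax - 1.0)
        rows["stress"].append(sxx * lam_lat ** 2)
        rows["cauchy"].append(sxx)
        rows["lat"].append(lam_lat)
        rows["J"].append(lam_ax * lam_lat ** 2)
        rows["act"].append(act)
        states.append(state.copy())

    return StressStrainCurve(
        time=times,
        strain=np.array(rows["strain"]),
        stress=np.array(rows["stress"]),
        cauchy_axial=np.array(rows["cauchy"]),
        lateral_stretch=np.array(rows["lat"]),
        jacobian=np.array(rows["J"]),
        activation=np.array(rows["act"]),
        states=states,
    )


def curve_metrics(curve: StressStrainCurve,
                  strain_levels=(0.05, 0.10, 0.15, 0.20)) -> dict:
    """Summary metrics: interpolated stress at strain levels, peak stress,
    and secant moduli (stress/strain)."""
    if curve.time.size == 0:
        raise ValueError("empty curve")
    smax = float(np.max(curve.strain))
    out = {"peak_stress": float(np.max(curve.stress)),
           "final_strain": smax}
    for lvl in strain_levels:
        if lvl > smax + 1e-12:
            raise ValueError(
                f"strain level {lvl} outside simulated range [0, {smax:.4f}]")
        val = float(np.interp(lvl, curve.strain, curve.stress))
        out[f"stress_at_{lvl:g}"] = val
        out[f"secant_modulus_at_{lvl:g}"] = val / lvl if lvl > 0 else 0.0
    return out


def curve_to_frame(curve: StressStrainCurve,
                   params: MaterialParams) -> pd.DataFrame:
    """Export the history as a tidy DataFrame (CSV-ready)."""
    k = params.k
    lam_s = np.array([s.lambda_s for s in curve.states])
    lam_m = np.array([s.lambda_m for s in curve.states])
    return pd.DataFrame({
        "time": curve.time,
        "lambda_f": 1.0 + curve.strain,
        "lambda_f_bar": (k * lam_m + lam_s) / (1.0 + k),
        "lambda_s": lam_s,
        "lambda_m": lam_m,
        "lambda_m_dot": [s.lambda_m_dot for s in curve.states],
        "activation": curve.activation,
        "sigma_pe": [s.sigma_pe for s in curve.states],
        "sigma_see": [s.sigma_see for s in curve.states],
        "sigma_ce": [s.sigma_see for s in curve.states],
        "eng_strain": curve.strain,
        "eng_stress": curve.stress,
    })
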