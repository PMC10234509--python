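"""The active-muscle constitutive law.

Strain energy is split additively into

* an isotropic exponential matrix part ``W_I = c (exp(b (I1bar - 3)) - 1)``,
* a volumetric penalty ``W_V = (1/D)(J - 1)^2`` (quasi-incompressibility),
* a fiber part whose stress is the sum of a parallel elastic element (PE)
  and the series CE/SEE pair of the Hill schematic.

The fiber rheology is driven by the modified fiber stretch
``lambda_f_bar`` (volume-eliminated).  The CE and SEE share the fiber
stretch in series: with ``k`` the CE-to-SEE rest-length ratio,

    (1 + k) * lambda_f_bar = k * lambda_m + lambda_s

so the contractile stretch is ``lambda_m = ((1+k) lambda_f_bar -
lambda_s) / k``.  Because the two elements are in series they carry the
same stress; each time increment the SEE stretch increment
``delta_lambda_s`` is found from the scalar governing equation

    f(x) = (w2 + w3 x) exp(alpha x) - w4 x - w5 = 0

whose coefficients follow from equating the incremental SEE stress
update to the CE stress with the hyperbolic force-velocity law.  Two
coefficient sets exist, for the concentric (shortening) and eccentric
(lengthening) phases of the force-velocity relation.

All response functions broadcast over numpy arrays, so a finite-element
solver can advance thousands of material points per call; scalar inputs
return scalars.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import ConvergenceError
from .kinematics import KinematicMeasures
from .params import MaterialParams

__all__ = [
    "MaterialPointState",
    "IncrementCoefficients",
    "matrix_energy",
    "volumetric_energy",
    "volumetric_pressure",
    "f_pe",
    "sigma_pe",
    "sigma_see",
    "force_length",
    "force_velocity",
    "activation",
    "sigma_ce",
    "solve_series_increment",
    "advance_fiber_state",
    "advance_state",
    "cauchy_stress",
    "cauchy_stress_batch",
    "initial_state",
]

_EQ_TOL = 1e-9  # relative residual tolerance of the series solve


@dataclasses.dataclass
class MaterialPointState:
    """Per-point history of the series CE/SEE pair.

    Fields may be scalars or equally-shaped numpy arrays (one entry per
    material point); all operations broadcast.
    """

    time: float = 0.0
    lambda_s: float = 1.0
    lambda_m: float = 1.0
    lambda_m_dot: float = 0.0
    sigma_see: float = 0.0
    sigma_pe: float = 0.0
    activation: float = 0.0

    def copy(self) -> "MaterialPointState":
        return MaterialPointState(
            time=np.copy(self.time) if np.ndim(self.time) else self.time,
            lambda_s=np.copy(self.lambda_s),
            lambda_m=np.copy(self.lambda_m),
            lambda_m_dot=np.copy(self.lambda_m_dot),
            sigma_see=np.copy(self.sigma_see),
            sigma_pe=np.copy(self.sigma_pe),
            activation=np.copy(self.activation),
        )

    def lambda_f_bar(self, params: "MaterialParams"):
        """Modified fiber stretch implied by the series kinematics."""
        k = params.k
        return (k * np.asarray(self.lambda_m) + np.asarray(self.lambda_s)) \
            / (1.0 + k)


@dataclasses.dataclass(frozen=True)
class IncrementCoefficients:
    """Coefficients of the scalar governing equation for one increment."""

    w1: float
    w2: float
    w3: float
    w4: float
    w5: float
    phase: str
    dt: float

    def residual(self, delta_lambda_s, alpha: float):
        x = np.asarray(delta_lambda_s, dtype=float)
        return (self.w2 + self.w3 * x) * np.exp(alpha * x) \
            - self.w4 * x - self.w5


def _as_float(x, scalar: bool):
    return float(x) if scalar else x


# ----------------------------------------------------------------------
# energies

def matrix_energy(I1bar, params: MaterialParams):
    """Isotropic matrix strain-energy density ``c(exp(b(I1bar-3)) - 1)`` [Pa]."""
    I1bar = np.asarray(I1bar, dtype=float)
    scalar = I1bar.ndim == 0
    if np.any(I1bar < 3.0 - 1e-9):
        raise ValueError("I1bar below attainable isochoric range (>= 3)")
    out = params.c * np.expm1(params.b * (I1bar - 3.0))
    return _as_float(out, scalar)


def volumetric_energy(J, params: MaterialParams):
    """Volumetric strain-energy density ``(1/D)(J-1)^2`` [Pa]."""
    J = np.asarray(J, dtype=float)
    scalar = J.ndim == 0
    if np.any(J <= 0.0):
        from .errors import InvalidDeformationError
        raise InvalidDeformationError("non-positive Jacobian")
    out = (J - 1.0) ** 2 / params.D
    return _as_float(out, scalar)


def volumetric_pressure(J, params: MaterialParams):
    """dW_V/dJ = (2/D)(J-1) [Pa] (spherical stress contribution)."""
    J = np.asarray(J, dtype=float)
    scalar = J.ndim == 0
    if np.any(J <= 0.0):
        from .errors import InvalidDeformationError
        raise InvalidDeformationError("non-positive Jacobian")
    out = 2.0 / params.D * (J - 1.0)
    return _as_float(out, scalar)


# ----------------------------------------------------------------------
# element response functions

def f_pe(lambda_f_bar, params: MaterialParams):
    """Normalized PE response: ``A (lambda_f_bar - 1)^2`` in tension, 0 otherwise."""
    lam = np.asarray(lambda_f_bar, dtype=float)
    scalar = lam.ndim == 0
    out = np.where(lam > 1.0, params.A * (lam - 1.0) ** 2, 0.0)
    return _as_float(out, scalar)


def sigma_pe(lambda_f_bar, params: MaterialParams):
    """Parallel-element stress ``sigma0 * f_pe`` [Pa]."""
    out = np.asarray(f_pe(lambda_f_bar, params)) * params.sigma0
    return _as_float(out, np.ndim(lambda_f_bar) == 0)


def sigma_see(lambda_s, params: MaterialParams):
    """Series-elastic-element stress ``beta(exp(alpha(lambda_s-1)) - 1)`` [Pa]."""
    lam = np.asarray(lambda_s, dtype=float)
    scalar = lam.ndim == 0
    out = params.beta * np.expm1(params.alpha * (lam - 1.0))
    return _as_float(out, scalar)


def force_length(lambda_f_bar, params: MaterialParams):
    """Piecewise force-length factor, peak 1 at lambda_f_bar = lambda_opt.

    With ``r = lambda_f_bar / lambda_opt``::

        0               r < 0.4
        9 (r - 0.4)^2   0.4 <= r < 0.6
        1 - 4 (1 - r)^2 0.6 <= r < 1.4
        9 (r - 1.6)^2   1.4 <= r < 1.6
        0               r >= 1.6
    """
    lam = np.asarray(lambda_f_bar, dtype=float)
    scalar = lam.ndim == 0
    r = lam / params.lambda_opt
    out = np.select(
        [r < 0.4, r < 0.6, r < 1.4, r < 1.6],
        [0.0,
         9.0 * (r - 0.4) ** 2,
         1.0 - 4.0 * (1.0 - r) ** 2,
         9.0 * (r - 1.6) ** 2],
        default=0.0,
    )
    return _as_float(out, scalar)


def force_velocity(lambda_m_dot, params: MaterialParams):
    """Hyperbolic force-velocity factor of the CE.

    With ``r = lambda_m_dot / lambda_dot_m_min`` (both negative for
    shortening, so r > 0 concentric, r < 0 eccentric)::

        concentric (lambda_m_dot <= 0):  (1 - r) / (1 + kc r), clamped
            to 0 beyond the maximal shortening rate (r > 1)
        eccentric  (lambda_m_dot > 0):   d - (d-1)(1 + r)/(1 - kc ke r)

    Both branches equal 1 at zero rate; the eccentric branch rises toward
    the asymptote ``d + (d-1)/(kc ke)`` for fast lengthening.
    """
    rate = np.asarray(lambda_m_dot, dtype=float)
    scalar = rate.ndim == 0
    r = rate / params.lambda_dot_m_min
    conc = np.where(r >= 1.0, 0.0, (1.0 - r) / (1.0 + params.kc * r))
    kke = params.kc * params.ke
    ecc = params.d - (params.d - 1.0) * (1.0 + r) / (1.0 - kke * r)
    out = np.where(rate <= 0.0, conc, ecc)
    return _as_float(out, scalar)


def activation(t, params: MaterialParams):
    """Exponential activation schedule between levels n1 and n2.

    Rises from n1 toward n2 after the onset time t0 with rate S, and
    decays back toward n1 after the deactivation time t1.
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    n1, n2, S, t0, t1 = params.n1, params.n2, params.S, params.t0, params.t1

    def h(tj, tk):
        # exponent clamped: h is only consumed for tj >= tk, where it
        # lies in [0, 1); the clamp avoids spurious overflow in the
        # branches np.select evaluates but discards
        return -np.expm1(np.minimum(-S * (tj - tk), 0.0))

    rise = n1 + (n2 - n1) * h(t, t0)
    peak = h(t1, t0)
    decay = n1 + (n2 - n1) * peak * (1.0 - h(t, t1))
    out = np.select([t <= t0, t <= t1], [n1, rise], default=decay)
    return _as_float(out, scalar)


def sigma_ce(lambda_f_bar, lambda_m_dot, activation_level,
             params: MaterialParams):
    """Contractile-element stress ``sigma0 * f_l * f_v * f_t`` [Pa]."""
    out = (params.sigma0
           * np.asarray(force_length(lambda_f_bar, params))
           * np.asarray(force_velocity(lambda_m_dot, params))
           * np.asarray(activation_level, dtype=float))
    scalar = (np.ndim(lambda_f_bar) == 0 and np.ndim(lambda_m_dot) == 0
              and np.ndim(activation_level) == 0)
    return _as_float(out, scalar)


# ----------------------------------------------------------------------
# incremental series-element solve

def _increment_coefficients(lambda_s, lambda_m, sig_s, lambda_f_new,
                            dt, act_new, params: MaterialParams,
                            concentric=None):
    """Vectorized w1..w5 plus the concentric-phase mask.

    P is the rate-independent part of the CE stress,
    ``sigma0 * f_l(lambda_f_bar(t)) * f_t(t+dt)``; M = k*lambda_dot_m_min*dt.
    If ``concentric`` is not given it is decided by the sign of the raw
    equilibrium residual at the zero-rate point x = w1 (the root's phase,
    by monotonicity).
    """
    k, kc, ke, dcoef = params.k, params.kc, params.ke, params.d
    beta = params.beta
    lam_f_old = (k * lambda_m + lambda_s) / (1.0 + k)
    P = params.sigma0 * np.asarray(force_length(lam_f_old, params)) * act_new
    w1 = (1.0 + k) * lambda_f_new - k * lambda_m - lambda_s
    M = k * params.lambda_dot_m_min * dt
    if concentric is None:
        g_w1 = (beta + sig_s) * np.exp(params.alpha * w1) - beta - P
        concentric = g_w1 < 0.0

    bs = beta + sig_s
    # concentric (shortening) coefficient set
    w2c = bs * (1.0 + kc * w1 / M)
    w3c = -bs * kc / M
    w4c = (P - beta * kc) / M
    w5c = beta + P - (P - beta * kc) * w1 / M
    # eccentric (lengthening) coefficient set
    K = kc * ke
    w2e = bs * (1.0 - K * w1 / M)
    w3e = bs * K / M
    w4e = (beta * K + P * (dcoef * K + dcoef - 1.0)) / M
    w5e = beta + P - (beta * K + P * (dcoef * K + dcoef - 1.0)) * w1 / M

    w2 = np.where(concentric, w2c, w2e)
    w3 = np.where(concentric, w3c, w3e)
    w4 = np.where(concentric, w4c, w4e)
    w5 = np.where(concentric, w5c, w5e)
    return w1, w2, w3, w4, w5, concentric


def _governing(x, w2, w3, w4, w5, alpha):
    return (w2 + w3 * x) * np.exp(alpha * x) - w4 * x - w5


def _solve_increment_core(lambda_s, lambda_m, sig_s, lambda_f_new, dt,
                          act_new, params: MaterialParams):
    """Vectorized root of the governing equation for each material point.

    The raw equilibrium residual g(x) = sigma_SEE(x) - sigma_CE(x) is
    strictly increasing in x (SEE stress grows, the CE rate - and with it
    the force-velocity factor - falls), so the root is unique and its
    phase is decided by the sign of g at x = w1 (the zero-rate point):
    g(w1) < 0 means the root lies in the concentric region (lambda_m_dot
    < 0), g(w1) > 0 in the eccentric one.  Each phase's polynomial-
    exponential form is then bisected on a directional bracket anchored
    at w1; if the concentric root exceeds the maximal shortening rate the
    force-velocity factor clamps to zero and the SEE simply unloads
    (closed form).
    """
    lambda_s = np.asarray(lambda_s, dtype=float)
    shape = np.broadcast_shapes(
        lambda_s.shape, np.shape(lambda_m), np.shape(sig_s),
        np.shape(lambda_f_new), np.shape(act_new))
    lambda_s = np.broadcast_to(lambda_s, shape).astype(float)
    lambda_m = np.broadcast_to(np.asarray(lambda_m, float), shape)
    sig_s = np.broadcast_to(np.asarray(sig_s, float), shape)
    lambda_f_new = np.broadcast_to(np.asarray(lambda_f_new, float), shape)
    act_new = np.broadcast_to(np.asarray(act_new, float), shape)

    k, alpha, beta = params.k, params.alpha, params.beta
    lam_f_old = (k * lambda_m + lambda_s) / (1.0 + k)
    P = params.sigma0 * np.asarray(force_length(lam_f_old, params)) * act_new
    w1 = (1.0 + k) * lambda_f_new - k * lambda_m - lambda_s
    bs = beta + sig_s
    g_w1 = bs * np.exp(alpha * w1) - beta - P
    concentric = g_w1 < 0.0

    _, w2, w3, w4, w5, _ = _increment_coefficients(
        lambda_s, lambda_m, sig_s, lambda_f_new, dt, act_new, params,
        concentric=concentric)
    tol = _EQ_TOL * (beta + np.abs(sig_s))

    done = np.abs(g_w1) <= tol
    root = np.where(done, w1, 0.0)

    # directional bracket: concentric roots lie above w1, eccentric below
    width = np.full(shape, 0.5)
    a = np.where(concentric, w1, w1 - width)
    b = np.where(concentric, w1 + width, w1)
    # f has the sign of g within each phase's validity region
    for _ in range(5):
        fa = _governing(a, w2, w3, w4, w5, alpha)
        fb = _governing(b, w2, w3, w4, w5, alpha)
        ok = (fa * fb <= 0.0) | done
        if np.all(ok):
            break
        width = np.where(ok, width, 2.0 * width)
        a = np.where(ok | concentric, a, w1 - width)
        b = np.where(ok | ~concentric, b, w1 + width)
    else:
        bad = np.argwhere(~ok.reshape(-1))[:5].ravel().tolist()
        raise ConvergenceError(
            "no sign change of the governing equation within the expanded "
            f"bracket (w1 +/- 8) for point indices {bad}")

    fa = _governing(a, w2, w3, w4, w5, alpha)
    for _ in range(80):
        m = 0.5 * (a + b)
        fm = _governing(m, w2, w3, w4, w5, alpha)
        left = fa * fm <= 0.0
        b = np.where(left, m, b)
        a = np.where(left, a, m)
        fa = np.where(left, fa, fm)
    root = np.where(done, root, 0.5 * (a + b))

    # beyond maximal shortening rate the CE transmits nothing: SEE unloads
    lam_m_dot = (w1 - root) / (k * dt)
    over = concentric & (lam_m_dot < params.lambda_dot_m_min) & ~done
    if np.any(over):
        unload = np.log(beta / bs) / alpha
        root = np.where(over, unload, root)
        lam_m_dot = (w1 - root) / (k * dt)

    # the defining contract: post-step SEE stress equals CE stress
    see_new = bs * np.exp(alpha * root) - beta
    ce_new = P * np.asarray(force_velocity(lam_m_dot, params))
    res = np.abs(see_new - ce_new)
    if np.any(res > np.maximum(tol, 1e-9 * (beta + params.sigma0))):
        worst = float(np.max(res))
        raise ConvergenceError(
            f"series-equilibrium residual {worst:.3e} Pa exceeds tolerance")
    return root, w1, w2, w3, w4, w5, concentric


def solve_series_increment(state: MaterialPointState, lambda_f_new, dt,
                           activation_level, params: MaterialParams):
    """Solve one increment of the series CE/SEE equilibrium.

    Parameters
    ----------
    state : MaterialPointState
        Converged state at time t.
    lambda_f_new : float
        Modified fiber stretch at t + dt.
    dt : float
        Time increment [s] (> 0).
    activation_level : float
        Activation f_t evaluated at t + dt.

    Returns
    -------
    (delta_lambda_s, IncrementCoefficients)
        The accepted SEE stretch increment and the coefficient record of
        the governing equation (phase 'concentric' or 'eccentric').
    """
    if not dt > 0.0:
        raise ValueError(f"dt must be positive, got {dt}")
    root, w1, w2, w3, w4, w5, conc = _solve_increment_core(
        state.lambda_s, state.lambda_m, state.sigma_see,
        lambda_f_new, dt, activation_level, params)
    scalar = np.ndim(root) == 0 or root.shape == ()
    if scalar or root.size == 1:
        phase = "concentric" if bool(np.ravel(conc)[0]) else "eccentric"
        coeffs = IncrementCoefficients(
            w1=float(np.ravel(w1)[0]), w2=float(np.ravel(w2)[0]),
            w3=float(np.ravel(w3)[0]), w4=float(np.ravel(w4)[0]),
            w5=float(np.ravel(w5)[0]), phase=phase, dt=float(dt))
        return float(np.ravel(root)[0]), coeffs
    phase = np.where(conc, "concentric", "eccentric")
    return root, IncrementCoefficients(w1=w1, w2=w2, w3=w3, w4=w4, w5=w5,
                                       phase=phase, dt=float(dt))


def advance_fiber_state(state: MaterialPointState, lambda_f_bar_new, dt,
                        activation_level,
                        params: MaterialParams) -> MaterialPointState:
    """Advance the fiber rheology one increment (array-friendly).

    Updates lambda_s by the solved increment, lambda_m from the series
    kinematics, lambda_m_dot by backward difference, and the SEE stress
    via its exact incremental exponential update.
    """
    if not dt > 0.0:
        raise ValueError(f"dt must be positive, got {dt}")
    root, *_ = _solve_increment_core(
        state.lambda_s, state.lambda_m, state.sigma_see,
        lambda_f_bar_new, dt, activation_level, params)
    k = params.k
    lambda_s_new = state.lambda_s + root
    lambda_m_new = ((1.0 + k) * np.asarray(lambda_f_bar_new, float)
                    - lambda_s_new) / k
    lambda_m_dot = (lambda_m_new - state.lambda_m) / dt
    sig_s_new = (np.exp(params.alpha * root)
                 * (state.sigma_see + params.beta) - params.beta)
    scalar = np.ndim(lambda_f_bar_new) == 0 and np.ndim(state.lambda_s) == 0
    conv = float if scalar else np.asarray
    return MaterialPointState(
        time=state.time + dt,
        lambda_s=conv(lambda_s_new),
        lambda_m=conv(lambda_m_new),
        lambda_m_dot=conv(lambda_m_dot),
        sigma_see=conv(sig_s_new),
        sigma_pe=conv(np.asarray(sigma_pe(lambda_f_bar_new, params))),
        activation=conv(np.asarray(activation_level, float) + 0.0),
    )


def advance_state(state: MaterialPointState, kin_new: KinematicMeasures,
                  dt, activation_level,
                  params: MaterialParams) -> MaterialPointState:
    """Advance a material point to the new kinematic state at t + dt."""
    return advance_fiber_state(state, kin_new.lambda_f_bar, dt,
                               activation_level, params)


def initial_state(lambda_f_bar=1.0, time=0.0) -> MaterialPointState:
    """Stress-free reference state: lambda_s = 1, lambda_m = lambda_f_bar
    (all fiber stretch initially in the CE), zero SEE stress."""
    lam = np.asarray(lambda_f_bar, dtype=float)
    scalar = lam.ndim == 0
    one = 1.0 if scalar else np.ones_like(lam)
    zero = 0.0 if scalar else np.zeros_like(lam)
    return MaterialPointState(
        time=time, lambda_s=one,
        lambda_m=float(lam) if scalar else lam.copy(),
        lambda_m_dot=zero, sigma_see=zero, sigma_pe=zero, activation=zero)


def isometric_steady_state(lambda_f_bar, params: MaterialParams,
                           duration: float = 2.0, dt: float = 1.0e-3,
                           activation_level: float = 1.0):
    """Hold the modified fiber stretch fixed and march to steady state.

    Vectorized over an array of held stretches.  At steady state the CE
    rate vanishes and the common CE/SEE stress converges to
    ``sigma0 * f_l(lambda_f_bar) * activation``; the transient is the
    SEE loading through the series kinematics.  Returns the final
    :class:`MaterialPointState`.
    """
    lam = np.asarray(lambda_f_bar, dtype=float)
    state = initial_state(lam if lam.ndim else float(lam))
    n_steps = int(round(duration / dt))
    for _ in range(n_steps):
        state = advance_fiber_state(state, lam, dt, activation_level, params)
    return state


# ----------------------------------------------------------------------
# stress assembly

def cauchy_stress_batch(F, a0, sig_fiber, params: MaterialParams,
                        volumetric: bool = True):
    """Cauchy stress for a batch of deformation states.

    Parameters
    ----------
    F : (..., 3, 3) array
    a0 : (..., 3) array of unit reference fiber directions
    sig_fiber : (...) array
        Total fiber stress magnitude sigma_pe + sigma_see [Pa].
    volumetric : bool
        Include the volumetric pressure term (the FE solver replaces it
        with a nodal-averaged variant to avoid locking).

    Notes
    -----
    Standard isochoric/volumetric treatment of quasi-incompressible
    transversely isotropic hyperelasticity: second Piola-Kirchhoff stress
    from 2 dW/dC with deviatoric projection of the isochoric matrix and
    fiber terms, pushed forward, plus the volumetric pressure
    (2/D)(J - 1) on the identity.
    """
    F = np.asarray(F, dtype=float)
    a0 = np.asarray(a0, dtype=float)
    J = np.linalg.det(F)
    if np.any(J <= 0.0):
        from .errors import InvalidDeformationError
        raise InvalidDeformationError("non-positive Jacobian in batch")
    Jm23 = J ** (-2.0 / 3.0)
    B = np.einsum("...ik,...jk->...ij", F, F)
    Bbar = Jm23[..., None, None] * B
    I1bar = np.trace(Bbar, axis1=-2, axis2=-1)
    eye = np.broadcast_to(np.eye(3), F.shape)

    dWI = params.c * params.b * np.exp(params.b * (I1bar - 3.0))
    dev_B = Bbar - (I1bar / 3.0)[..., None, None] * eye
    sig_matrix = (2.0 / J)[..., None, None] * dWI[..., None, None] * dev_B

    a_cur = np.einsum("...ij,...j->...i", F, a0)
    lam_f = np.linalg.norm(a_cur, axis=-1)
    lam_f_bar = J ** (-1.0 / 3.0) * lam_f
    ahat = a_cur / lam_f[..., None]
    m = np.einsum("...i,...j->...ij", ahat, ahat)
    dev_m = m - eye / 3.0
    sig_f = (np.asarray(sig_fiber, float) * lam_f_bar / J)[..., None, None] \
        * dev_m

    out = sig_matrix + sig_f
    if volumetric:
        p = 2.0 / params.D * (J - 1.0)
        out = out + p[..., None, None] * eye
    return out


def cauchy_stress(kin: KinematicMeasures, state: MaterialPointState,
                  params: MaterialParams) -> np.ndarray:
    """Symmetric Cauchy stress tensor [Pa] at one material point.

    Sums the deviatorically projected isochoric matrix term, the fiber
    term of magnitude sigma_pe + sigma_see along the current fiber
    direction, and the volumetric pressure.  Exactly zero at the resting
    reference state; objective under superposed rotations.
    """
    sig_fiber = state.sigma_pe + state.sigma_see
    out = cauchy_stress_batch(kin.F, kin.a0, sig_fiber, params)
    return 0.5 * (out + out.T)  # symmetrize round-off
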