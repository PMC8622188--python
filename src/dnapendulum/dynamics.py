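"""Equations of motion and time integration for the coupled-pendulum chains.

The duplex is modelled as two chains of ``n`` pendulums (the bases), each
attached to an elastic thread (the backbone).  Site ``i`` of strand 1 obeys

    I1_i phi1_i'' = K1_i (phi1_{i-1} - 2 phi1_i + phi1_{i+1})
                    - k12_i R1_i (R1_i + R2_i) sin phi1_i
                    - k12_i R1_i R2_i sin(phi1_i - phi2_i) + F1_i(t)

with single-neighbour backbone coupling at the two chain ends.  Strand 2
carries the published sign structure, whose pair-restoring term enters with
the opposite sign:

    I2_i phi2_i'' = K2_i (phi2_{i-1} - 2 phi2_i + phi2_{i+1})
                    + k12_i R2_i (R1_i + R2_i) sin phi2_i
                    - k12_i R1_i R2_i sin(phi2_i - phi1_i) + F2_i(t)

(a ``symmetrized`` diagnostic variant with the strand-1 sign is available
on :class:`~dnapendulum.parameters.ChainSystem`).  The external influence is

    F_ji(t) = -lambda beta_ji dphi_ji/dt + M(t),

viscous dissipation plus an applied torque.  Together with the initial
conditions this is a Cauchy problem for ``2n`` second-order equations,
integrated here as ``4n`` first-order ones with a fixed-step classical
4th-order Runge-Kutta scheme (deterministic and transparent); a SciPy
adaptive backend is available as an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from .parameters import ChainSystem

__all__ = [
    "ForcingSpec",
    "State",
    "Trajectory",
    "external_torque",
    "rhs",
    "initial_state",
    "integrate",
    "linearized_stiffness",
    "linearized_steady_state",
]

#: Default integration step, s.  The fastest linearized backbone mode has
#: angular frequency ~sqrt(4K/I) ~ 1.4e13 1/s (period ~4.5e-13 s), so 1e-14
#: resolves it roughly 45-fold.
DEFAULT_DT = 1e-14


@dataclass(frozen=True)
class ForcingSpec:
    """External torque specification.

    mode
        ``"constant"``: M(t) = M0;  ``"cosine"``: M(t) = M0 cos(omega t);
        ``"zero"``: no applied torque (dissipation still acts).
    amplitude
        M0 in N·m.  The published working value is 1e-22 N·m, at which a
        constant torque and a slow cosine (omega <= 1e9 1/s) drive nearly
        identical angular dynamics.
    omega
        Angular frequency of the cosine mode, 1/s (ignored otherwise).
    strands
        Which strands receive M(t); dissipation always acts on all
        pendulums.  Default: both.
    sites
        Optional ``(start, stop)`` half-open site range receiving M(t);
        default: every site.
    """

    mode: str = "constant"
    amplitude: float = 1e-22
    omega: float = 0.0
    strands: tuple[int, ...] = (1, 2)
    sites: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "cosine", "zero"):
            raise ValueError(f"unknown forcing mode {self.mode!r}")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if not set(self.strands) <= {1, 2}:
            raise ValueError("strands must be a subset of (1, 2)")

    def target_masks(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        """Per-strand 0/1 masks of the pendulums receiving M(t)."""
        site = np.zeros(n)
        lo, hi = (0, n) if self.sites is None else self.sites
        site[lo:hi] = 1.0
        m1 = site if 1 in self.strands else np.zeros(n)
        m2 = site if 2 in self.strands else np.zeros(n)
        return m1, m2


def external_torque(t: float, forcing: ForcingSpec) -> float:
    """Applied torque M(t) in N·m at time ``t`` (s)."""
    if forcing.mode == "zero":
        return 0.0
    if forcing.mode == "constant":
        return forcing.amplitude
    return forcing.amplitude * np.cos(forcing.omega * t)


@dataclass
class State:
    """Instantaneous state: angles (rad) and angular velocities (rad/s).

    Both arrays have shape ``(2, n)``: row 0 is strand 1, row 1 is strand 2;
    angles are counted counterclockwise and are not wrapped modulo 2 pi.
    """

    t: float
    phi: np.ndarray
    omega: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.atleast_2d(np.asarray(self.phi, dtype=float))
        self.omega = np.atleast_2d(np.asarray(self.omega, dtype=float))
        if self.phi.shape != self.omega.shape or self.phi.shape[0] != 2:
            raise ValueError("phi and omega must both have shape (2, n)")
        if not (np.isfinite(self.phi).all() and np.isfinite(self.omega).all()):
            raise ValueError("state contains non-finite entries")


def _pack(state: State) -> np.ndarray:
    return np.concatenate(
        [state.phi[0], state.phi[1], state.omega[0], state.omega[1]]
    )


def _unpack(y: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    return y[: 2 * n].reshape(2, n).copy(), y[2 * n :].reshape(2, n).copy()


def _make_rhs(
    system: ChainSystem, forcing: ForcingSpec
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Compile the flat-vector right-hand side f(t, y) for y = (phi1, phi2, v1, v2)."""
    n = system.n
    K1, K2 = system.K1, system.K2
    invI1, invI2 = 1.0 / system.I1, 1.0 / system.I2
    # pair-interaction coefficient arrays, precomputed once
    c_self1 = system.k12 * system.R1 * (system.R1 + system.R2)
    c_self2 = system.k12 * system.R2 * (system.R1 + system.R2)
    c_cross = system.k12 * system.R1 * system.R2
    s2 = 1.0 if system.sign_convention == "printed" else -1.0
    lb1 = system.effective_beta1
    lb2 = system.effective_beta2
    m1, m2 = forcing.target_masks(n)
    mode, M0, om = forcing.mode, forcing.amplitude, forcing.omega

    def f(t: float, y: np.ndarray) -> np.ndarray:
        phi1 = y[:n]
        phi2 = y[n : 2 * n]
        v1 = y[2 * n : 3 * n]
        v2 = y[3 * n :]

        dy = np.empty_like(y)
        dy[: 2 * n] = y[2 * n :]  # d(phi)/dt = angular velocity
        a1 = dy[2 * n : 3 * n]
        a2 = dy[3 * n :]

        # backbone torque: K_i (phi_{i-1} - 2 phi_i + phi_{i+1}) inside,
        # single-neighbour form at the chain ends
        a1[1:-1] = K1[1:-1] * (phi1[:-2] - 2.0 * phi1[1:-1] + phi1[2:])
        a1[0] = K1[0] * (phi1[1] - phi1[0])
        a1[-1] = K1[-1] * (phi1[-2] - phi1[-1])
        a2[1:-1] = K2[1:-1] * (phi2[:-2] - 2.0 * phi2[1:-1] + phi2[2:])
        a2[0] = K2[0] * (phi2[1] - phi2[0])
        a2[-1] = K2[-1] * (phi2[-2] - phi2[-1])

        if mode == "zero":
            M = 0.0
        elif mode == "constant":
            M = M0
        else:
            M = M0 * np.cos(om * t)

        cross = np.sin(phi1 - phi2)
        a1 += -c_self1 * np.sin(phi1) - c_cross * cross - lb1 * v1 + M * m1
        a2 += s2 * c_self2 * np.sin(phi2) + c_cross * cross - lb2 * v2 + M * m2
        a1 *= invI1
        a2 *= invI2
        return dy

    return f


def rhs(state: State, t: float, system: ChainSystem, forcing: ForcingSpec) -> State:
    """Time derivative of a state under the equations of motion.

    Returns a :class:`State` whose ``phi`` holds d(phi)/dt and whose
    ``omega`` holds d2(phi)/dt2, evaluated at time ``t``.
    """
    if state.phi.shape[1] != system.n:
        raise ValueError(
            f"state has {state.phi.shape[1]} sites but system has {system.n}"
        )
    f = _make_rhs(system, forcing)
    dy = f(t, _pack(state))
    dphi, domega = _unpack(dy, system.n)
    return State(t=t, phi=dphi, omega=domega)


def initial_state(
    system: ChainSystem,
    phi0: np.ndarray | None = None,
    omega0: np.ndarray | None = None,
) -> State:
    """Initial condition at t = 0.

    By default the duplex starts in mechanical equilibrium: every angle and
    angular velocity zero.  Explicit ``(2, n)`` override arrays are stored
    verbatim.
    """
    n = system.n
    phi = np.zeros((2, n)) if phi0 is None else np.asarray(phi0, dtype=float)
    om = np.zeros((2, n)) if omega0 is None else np.asarray(omega0, dtype=float)
    if phi.shape != (2, n) or om.shape != (2, n):
        raise ValueError(f"override arrays must have shape (2, {n})")
    return State(t=0.0, phi=phi, omega=om)


@dataclass
class Trajectory:
    """Decimated time series of the full ``2n``-pendulum state.

    ``phi`` and ``omega`` have shape ``(n_stored, 2, n)``.  ``meta`` is a
    provenance fingerprint (sequence, viscosity scale, forcing, solver
    settings) carried along so downstream observables and files are
    self-describing.
    """

    times: np.ndarray
    phi: np.ndarray
    omega: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or len(self.times) != self.phi.shape[0]:
            raise ValueError("times and state arrays are inconsistent")
        if len(self.times) and self.times[0] != 0.0 and "t0" not in self.meta:
            raise ValueError("trajectories start at t = 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n(self) -> int:
        return self.phi.shape[2]

    def state(self, idx: int) -> State:
        """Snapshot at stored index ``idx``."""
        return State(t=self.times[idx], phi=self.phi[idx], omega=self.omega[idx])

    def final_state(self) -> State:
        return self.state(len(self.times) - 1)


def integrate(
    system: ChainSystem,
    forcing: ForcingSpec | None = None,
    t_end: float = 2e-9,
    dt: float = DEFAULT_DT,
    initial: State | None = None,
    n_out: int = 1000,
    method: str = "rk4",
    rtol: float = 1e-8,
    atol: float = 1e-12,
    check_stability: bool = True,
) -> Trajectory:
    """Integrate the Cauchy problem over ``[0, t_end]``.

    Parameters
    ----------
    system, forcing
        Assembled coefficients and external-torque specification (defaults
        to the constant 1e-22 N·m working torque on every pendulum).
    t_end, dt
        Horizon and fixed step, s.  The step must resolve the fastest
        linearized mode, ~sqrt(4 max(K/I)); a step beyond ~a tenth of that
        period is rejected.
    initial
        Starting state; defaults to equilibrium.
    n_out
        Number of stored snapshots (decimated from the full step sequence;
        the first and last step are always kept).  Pass 0 to store every step.
    method
        ``"rk4"`` (fixed-step classical Runge-Kutta, default, bit-wise
        deterministic) or ``"scipy"`` (adaptive RK45 via
        :func:`scipy.integrate.solve_ivp`).

    Notes
    -----
    Angles are never wrapped; the model feeds them only through ``sin`` and
    the observables track cumulative deviations.
    """
    forcing = ForcingSpec() if forcing is None else forcing
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    state0 = initial_state(system) if initial is None else initial
    if state0.phi.shape[1] != system.n:
        raise ValueError("initial state does not match the system size")

    # explicit-scheme stability guard against the fastest linearized mode
    omega_max = float(
        np.sqrt(
            4.0
            * max(
                (system.K1 / system.I1).max(),
                (system.K2 / system.I2).max(),
            )
        )
    )
    if check_stability and method == "rk4" and dt * omega_max > 0.6:
        raise ValueError(
            f"step dt={dt:g} s is too large: the fastest linearized mode has "
            f"angular frequency {omega_max:.3g} 1/s; choose dt below "
            f"{0.6 / omega_max:.3g} s"
        )

    f = _make_rhs(system, forcing)
    y0 = _pack(state0)
    meta = {
        "sequence": system.strand1,
        "n": system.n,
        "lambda": system.lam,
        "sign_convention": system.sign_convention,
        "forcing": {
            "mode": forcing.mode,
            "amplitude": forcing.amplitude,
            "omega": forcing.omega,
            "strands": list(forcing.strands),
            "sites": list(forcing.sites) if forcing.sites else None,
        },
        "t_end": t_end,
        "dt": dt,
        "method": method,
        "n_out": n_out,
    }

    if method == "scipy":
        n_store = n_out if n_out > 0 else max(2, int(round(t_end / dt)) + 1)
        t_eval = np.linspace(0.0, t_end, n_store)
        sol = solve_ivp(
            f, (0.0, t_end), y0, method="RK45", t_eval=t_eval, rtol=rtol, atol=atol
        )
        if not sol.success:
            raise RuntimeError(f"adaptive integration failed: {sol.message}")
        ys = sol.y.T
        n = system.n
        phi = ys[:, : 2 * n].reshape(-1, 2, n)
        om = ys[:, 2 * n :].reshape(-1, 2, n)
        return Trajectory(times=sol.t, phi=phi, omega=om, meta=meta)
    if method != "rk4":
        raise ValueError(f"unknown method {method!r}")

    n_steps = max(1, int(round(t_end / dt)))
    dt_eff = t_end / n_steps  # snap the step so the grid ends exactly at t_end
    stride = 1 if n_out <= 0 else max(1, n_steps // n_out)
    store_idx = list(range(0, n_steps + 1, stride))
    if store_idx[-1] != n_steps:
        store_idx.append(n_steps)

    n = system.n
    times = np.empty(len(store_idx))
    phi = np.empty((len(store_idx), 2, n))
    om = np.empty((len(store_idx), 2, n))
    y = y0.copy()
    k = 0
    if store_idx[0] == 0:
        times[0] = 0.0
        phi[0] = y[: 2 * n].reshape(2, n)
        om[0] = y[2 * n :].reshape(2, n)
        k = 1
    h = dt_eff
    for step in range(1, n_steps + 1):
        t = (step - 1) * h
        k1 = f(t, y)
        k2 = f(t + 0.5 * h, y + (0.5 * h) * k1)
        k3 = f(t + 0.5 * h, y + (0.5 * h) * k2)
        k4 = f(t + h, y + h * k3)
        y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if k < len(store_idx) and step == store_idx[k]:
            if not np.isfinite(y).all():
                raise FloatingPointError(
                    f"integration diverged: non-finite state at t = {step * h:.6g} s"
                )
            times[k] = step * h
            phi[k] = y[: 2 * n].reshape(2, n)
            om[k] = y[2 * n :].reshape(2, n)
            k += 1
    return Trajectory(times=times, phi=phi, omega=om, meta=meta)


def linearized_stiffness(system: ChainSystem) -> np.ndarray:
    """Small-angle stiffness operator ``A`` such that I phi'' = A phi + F.

    Ordering: the first ``n`` entries are strand 1, the last ``n`` strand 2.
    Under the published sign structure ``A`` is indefinite (the strand-2
    pair term is anti-restoring), which makes the zero state a saddle; the
    ``symmetrized`` variant yields a negative-definite ``A``.
    """
    n = system.n
    c_self1 = system.k12 * system.R1 * (system.R1 + system.R2)
    c_self2 = system.k12 * system.R2 * (system.R1 + system.R2)
    c_cross = system.k12 * system.R1 * system.R2
    s2 = 1.0 if system.sign_convention == "printed" else -1.0

    A = np.zeros((2 * n, 2 * n))

    def backbone(K: np.ndarray, off: int) -> None:
        for i in range(n):
            if 0 < i < n - 1:
                A[off + i, off + i - 1] += K[i]
                A[off + i, off + i] += -2.0 * K[i]
                A[off + i, off + i + 1] += K[i]
            elif i == 0:
                A[off, off] += -K[0]
                A[off, off + 1] += K[0]
            else:
                A[off + i, off + i - 1] += K[i]
                A[off + i, off + i] += -K[i]

    backbone(system.K1, 0)
    backbone(system.K2, n)
    idx = np.arange(n)
    A[idx, idx] += -c_self1 - c_cross
    A[idx, n + idx] += c_cross
    A[n + idx, n + idx] += s2 * c_self2 - c_cross
    A[n + idx, idx] += c_cross
    return A


def linearized_steady_state(
    system: ChainSystem, forcing: ForcingSpec
) -> np.ndarray:
    """Static small-angle deflection profile under a constant torque.

    Solves ``A phi = -M`` where ``A`` is the linearized stiffness operator
    (``sin x -> x``, all time derivatives zero) and ``M`` the per-pendulum
    applied torque.  Returns a ``(2, n)`` array of angles in rad.

    Raises
    ------
    numpy.linalg.LinAlgError
        If the stiffness operator is singular for the given coefficients.

    Notes
    -----
    This profile is the *equilibrium of the linearized equations*; under
    the published sign structure that equilibrium is dynamically unstable
    (saddle), so long-time integration of the nonlinear system does not in
    general converge to it.  A warning is emitted in that case.
    """
    if forcing.mode != "constant":
        raise ValueError("linearized_steady_state requires constant forcing")
    n = system.n
    A = linearized_stiffness(system)
    m1, m2 = forcing.target_masks(n)
    b = -forcing.amplitude * np.concatenate([m1, m2])
    eig = np.linalg.eigvalsh((A + A.T) / 2.0)
    if eig.max() > 0:
        warnings.warn(
            "linearized stiffness operator is indefinite: the static profile "
            "is a saddle equilibrium and the nonlinear dynamics will not "
            "relax onto it",
            RuntimeWarning,
            stacklevel=2,
        )
    sol = np.linalg.solve(A, b)
    return sol.reshape(2, n)
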