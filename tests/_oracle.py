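"""Independent oracles for cross-checking the production integrator.

Everything here is deliberately written from the model equations directly,
site by site in plain Python scalars, sharing no code with the package's
vectorized right-hand side, so agreement between the two is a genuine
two-route check.
"""

from __future__ import annotations

import math

import numpy as np


def scalar_rhs(y, t, n, I1, I2, R1, R2, K1, K2, k12, lb1, lb2, M):
    """Site-wise scalar evaluation of the equations of motion.

    ``y`` is the flat state (phi1, phi2, v1, v2); ``lb1``/``lb2`` are the
    effective (viscosity-scaled) dissipation coefficients, ``M`` the
    torque value at time ``t`` applied to every pendulum.
    """
    phi1 = y[:n]
    phi2 = y[n:2 * n]
    v1 = y[2 * n:3 * n]
    v2 = y[3 * n:]
    dy = np.empty_like(y)
    dy[:2 * n] = y[2 * n:]
    for i in range(n):
        if i == 0:
            back1 = K1[0] * (phi1[1] - phi1[0])
            back2 = K2[0] * (phi2[1] - phi2[0])
        elif i == n - 1:
            back1 = K1[i] * (phi1[i - 1] - phi1[i])
            back2 = K2[i] * (phi2[i - 1] - phi2[i])
        else:
            back1 = K1[i] * (phi1[i - 1] - 2.0 * phi1[i] + phi1[i + 1])
            back2 = K2[i] * (phi2[i - 1] - 2.0 * phi2[i] + phi2[i + 1])
        f1 = -lb1[i] * v1[i] + M
        f2 = -lb2[i] * v2[i] + M
        a1 = (back1
              - k12[i] * R1[i] * (R1[i] + R2[i]) * math.sin(phi1[i])
              - k12[i] * R1[i] * R2[i] * math.sin(phi1[i] - phi2[i])
              + f1) / I1[i]
        a2 = (back2
              + k12[i] * R2[i] * (R1[i] + R2[i]) * math.sin(phi2[i])
              - k12[i] * R1[i] * R2[i] * math.sin(phi2[i] - phi1[i])
              + f2) / I2[i]
        dy[2 * n + i] = a1
        dy[3 * n + i] = a2
    return dy


def rk4_oracle(system, M0, t_end, dt, y0=None):
    """Tiny-step classical 4th-order integration using the scalar RHS.

    ``M0`` is a constant applied torque (N·m).  Returns the final flat
    state after integrating over [0, t_end].
    """
    n = system.n
    args = (n, system.I1, system.I2, system.R1, system.R2, system.K1,
            system.K2, system.k12, system.effective_beta1,
            system.effective_beta2, M0)
    y = np.zeros(4 * n) if y0 is None else np.array(y0, dtype=float)
    steps = int(round(t_end / dt))
    h = t_end / steps
    t = 0.0
    for _ in range(steps):
        k1 = scalar_rhs(y, t, *args)
        k2 = scalar_rhs(y + 0.5 * h * k1, t + 0.5 * h, *args)
        k3 = scalar_rhs(y + 0.5 * h * k2, t + 0.5 * h, *args)
        k4 = scalar_rhs(y + h * k3, t + h, *args)
        y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        t += h
    return y


def pair_mode_rates(base1="A", base2="T", k12=6.20e-2):
    """Closed-form linearized mode rates of one isolated base pair.

    Small-angle 2x2 system from the boundary equations of the two chains
    with no backbone neighbour: returns (oscillation angular frequencies,
    exponential growth rates), each as a sorted array, from the
    eigenvalues of the acceleration matrix d2(phi)/dt2 = B phi.
    """
    from dnapendulum.parameters import map_base_parameters

    p1 = map_base_parameters(base1)
    p2 = map_base_parameters(base2)
    R1, R2, I1, I2 = p1.lever, p2.lever, p1.inertia, p2.inertia
    B = np.array([
        [-(k12 * R1 * (R1 + R2) + k12 * R1 * R2) / I1, k12 * R1 * R2 / I1],
        [k12 * R1 * R2 / I2, (k12 * R2 * (R1 + R2) - k12 * R1 * R2) / I2],
    ])
    ev = np.linalg.eigvals(B)
    osc = np.sort(np.sqrt(-ev[ev.real < 0].real))
    growth = np.sort(np.sqrt(ev[ev.real > 0].real))
    return osc, growth
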