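"""Fast four-subpopulation neural mass subsystem.

State per population: four second-order synaptic filters, one per
subpopulation (P, P', SOM, PV), stored as (y, z) pairs where z = dy/dt:

    index  0    1    2     3     4      5      6     7
           y_P  z_P  y_P'  z_P'  y_SOM  z_SOM  y_PV  z_PV

Wiring (one population, drive p, slow-IPSP amplitude B, fast-IPSP
amplitude G)::

    y_P    <- (A/tau_a)  * S(V_P)
    y_P'   <- (A/tau_a)  * (p + C_Pp_P * S(C_P_Pp * y_P))
    y_SOM  <- (B/tau_b)  * S(C_SOM_P * y_P)
    y_PV   <- (G/tau_g)  * S(C_P_PV * y_P - C_SOM_PV * y_SOM)
    V_P    =  y_P' - C_P_SOM * y_SOM - C_PV_P * y_PV + ext_input

Each postsynaptic weight appears exactly once on every loop: the P'->P
weight sits inside the y_P' drive (so y_P' enters V_P with weight one), while
the SOM and PV inhibitory weights are applied in the V_P sum. The SOM->P
gain (35) is the argument of the SOM rate sigmoid and the P->SOM gain (25)
weighs y_SOM in V_P. This composition — together with tau_b = 1/30 s — is
the one that reproduces the published equilibrium/bifurcation structure of
the model (Hopf points near B = 2.66, 10.20, 32.14 and folds near
2.79, 3.82, 32.01, 50.38 for the primary-focus parameters).
"""

from __future__ import annotations

import numpy as np

from .params import FastParams

__all__ = [
    "sigmoid_rate",
    "sigmoid_rate_deriv",
    "alpha_impulse",
    "pyramidal_potential",
    "fast_field",
    "fast_jacobian",
    "fast_equilibrium",
    "equilibria_at",
]

_E0 = 5.0      # maximal firing rate
_R = 0.56      # sigmoid steepness
_V0 = 6.0      # half-activation potential [mV]


def sigmoid_rate(v):
    """Wave-to-pulse function S(v) = 5 / (1 + exp(0.56 (6 - v)))."""
    return _E0 / (1.0 + np.exp(np.clip(_R * (_V0 - v), -500.0, 500.0)))


def sigmoid_rate_deriv(v):
    """dS/dv, written in terms of S to avoid overflow."""
    s = sigmoid_rate(v)
    return _R * s * (1.0 - s / _E0)


def alpha_impulse(W: float, tau: float, t):
    """Closed-form impulse response h(t) = (W / tau) t exp(-t / tau).

    This is the analytic response of the second-order filter used by
    :func:`fast_field`; it is used in tests, not in the integration loop.
    """
    t = np.asarray(t, dtype=float)
    out = (W / tau) * t * np.exp(-t / tau)
    return np.where(t >= 0.0, out, 0.0)


def pyramidal_potential(state, fp: FastParams, ext_input: float = 0.0) -> float:
    """Net pyramidal polarization V_P (the model's output proxy for the LFP)."""
    y_Pp, y_SOM, y_PV = state[2], state[4], state[6]
    return y_Pp - fp.C_P_SOM * y_SOM - fp.C_PV_P * y_PV + ext_input


def fast_field(state, fp: FastParams, B: float, G: float, p_input: float,
               ext_input: float = 0.0):
    """Time derivative of the 8-dim fast state of one population."""
    y_P, z_P, y_Pp, z_Pp, y_SOM, z_SOM, y_PV, z_PV = state
    ta, tb, tg, A = fp.tau_a, fp.tau_b, fp.tau_g, fp.A
    V_P = y_Pp - fp.C_P_SOM * y_SOM - fp.C_PV_P * y_PV + ext_input
    return np.array([
        z_P,
        (A / ta) * sigmoid_rate(V_P) - 2.0 / ta * z_P - y_P / ta**2,
        z_Pp,
        (A / ta) * (p_input + fp.C_Pp_P * sigmoid_rate(fp.C_P_Pp * y_P))
        - 2.0 / ta * z_Pp - y_Pp / ta**2,
        z_SOM,
        (B / tb) * sigmoid_rate(fp.C_SOM_P * y_P) - 2.0 / tb * z_SOM
        - y_SOM / tb**2,
        z_PV,
        (G / tg) * sigmoid_rate(fp.C_P_PV * y_P - fp.C_SOM_PV * y_SOM)
        - 2.0 / tg * z_PV - y_PV / tg**2,
    ])


def fast_jacobian(state, fp: FastParams, B: float, G: float,
                  ext_input: float = 0.0):
    """Analytic 8x8 Jacobian of :func:`fast_field` (autonomous part)."""
    y_P, _, y_Pp, _, y_SOM, _, y_PV, _ = state
    ta, tb, tg, A = fp.tau_a, fp.tau_b, fp.tau_g, fp.A
    V_P = y_Pp - fp.C_P_SOM * y_SOM - fp.C_PV_P * y_PV + ext_input
    J = np.zeros((8, 8))
    for iy, tau in ((0, ta), (2, ta), (4, tb), (6, tg)):
        J[iy, iy + 1] = 1.0
        J[iy + 1, iy] = -1.0 / tau**2
        J[iy + 1, iy + 1] = -2.0 / tau
    dS_V = sigmoid_rate_deriv(V_P)
    # z_P row: drive (A/ta) S(V_P); V_P depends on y_P', y_SOM, y_PV
    J[1, 2] += (A / ta) * dS_V
    J[1, 4] += (A / ta) * dS_V * (-fp.C_P_SOM)
    J[1, 6] += (A / ta) * dS_V * (-fp.C_PV_P)
    # z_P' row
    J[3, 0] += (A / ta) * fp.C_Pp_P * sigmoid_rate_deriv(fp.C_P_Pp * y_P) * fp.C_P_Pp
    # z_SOM row
    J[5, 0] += (B / tb) * sigmoid_rate_deriv(fp.C_SOM_P * y_P) * fp.C_SOM_P
    # z_PV row
    arg = fp.C_P_PV * y_P - fp.C_SOM_PV * y_SOM
    dS_arg = sigmoid_rate_deriv(arg)
    J[7, 0] += (G / tg) * dS_arg * fp.C_P_PV
    J[7, 4] += (G / tg) * dS_arg * (-fp.C_SOM_PV)
    return J


def _state_from_vp(VP: float, fp: FastParams, B: float, G: float,
                   p_input: float):
    """Equilibrium 8-dim state implied by a pyramidal potential value."""
    A, ta, tb, tg = fp.A, fp.tau_a, fp.tau_b, fp.tau_g
    y_P = A * ta * sigmoid_rate(VP)
    y_Pp = A * ta * (p_input + fp.C_Pp_P * sigmoid_rate(fp.C_P_Pp * y_P))
    y_SOM = B * tb * sigmoid_rate(fp.C_SOM_P * y_P)
    y_PV = G * tg * sigmoid_rate(fp.C_P_PV * y_P - fp.C_SOM_PV * y_SOM)
    return np.array([y_P, 0.0, y_Pp, 0.0, y_SOM, 0.0, y_PV, 0.0])


def _vp_residual(VP: float, fp: FastParams, B: float, G: float,
                 p_input: float, ext_input: float) -> float:
    st = _state_from_vp(VP, fp, B, G, p_input)
    return pyramidal_potential(st, fp, ext_input) - VP

def equilibria_at(fp: FastParams, B: float, G: float | None = None,
                  p_input: float | None = None, ext_input: float = 0.0,
                  vp_range: tuple[float, float] = (-150.0, 50.0),
                  n_scan: int = 4001) -> list[np.ndarray]:
    """All equilibria of the fast subsystem at a given B.

    The 8-dim fixed-point problem reduces exactly to a scalar fixed point in
    V_P; the scalar equation is scanned densely and each sign change refined
    by Brent's method, then lifted back to the full state.
    """
    from scipy.optimize import brentq
    if G is None:
        G = fp.G
    if p_input is None:
        p_input = fp.p_m
    vps = np.linspace(*vp_range, n_scan)
    res = np.array([_vp_residual(v, fp, B, G, p_input, ext_input) for v in vps])
    out = []
    for i in np.nonzero(np.diff(np.sign(res)) != 0)[0]:
        vp = brentq(_vp_residual, vps[i], vps[i + 1],
                    args=(fp, B, G, p_input, ext_input), xtol=1e-13)
        out.append(_state_from_vp(vp, fp, B, G, p_input))
    return out


def fast_equilibrium(fp: FastParams, B: float, G: float | None = None,
                     p_input: float | None = None,
                     ext_input: float = 0.0) -> np.ndarray:
    """The unique equilibrium at B; raises if the count differs from one."""
    eqs = equilibria_at(fp, B, G, p_input, ext_input)
    if len(eqs) != 1:
        raise ValueError(f"expected a unique equilibrium at B={B}, found {len(eqs)}")
    return eqs[0]
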