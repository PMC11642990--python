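"""Six-variable physiological plasticity system.

Variables (all dimensionless except calcium, in model concentration units):

* ``r``   — available neurotransmitter fraction (short-term depression)
* ``u``   — utilization factor (short-term facilitation)
* ``Ca``  — postsynaptic calcium concentration, driven by synaptic NMDAR
* ``rho`` — synaptic efficacy state; 0 = depressed, 1 = potentiated,
  separatrix at 0.5
* ``Us``  — release probability, consolidating toward the rho-set target
* ``C_AMPA`` — AMPAergic coupling strength, consolidating likewise

The efficacy flow combines a bistable cubic with calcium-gated potentiation
and depression terms Omega_p, Omega_d (sigmoids of calcium with thresholds
theta_p > theta_d). Consolidation is a linear relaxation of (Us, C_AMPA)
between their depressed and potentiated bounds with time constants two
orders of magnitude above tau_rho, which is what makes the long-term state
effectively irreversible on protocol timescales.
"""

from __future__ import annotations

import numpy as np

from .params import PlasticityParams

__all__ = [
    "omega",
    "h_post",
    "stp_field",
    "stp_steady_state",
    "calcium_field",
    "rho_field",
    "consolidation_field",
]


def omega(ca, which: str, pp: PlasticityParams):
    """Calcium-gated rate Omega_p or Omega_d: gamma / (1 + exp(-beta (Ca - theta)))."""
    if which == "potentiation":
        gamma, beta, theta = pp.gamma_p, pp.beta_p, pp.theta_p
    elif which == "depression":
        gamma, beta, theta = pp.gamma_d, pp.beta_d, pp.theta_d
    else:
        raise ValueError(f"which must be 'potentiation' or 'depression', got {which!r}")
    ca = np.asarray(ca, dtype=float)
    out = gamma / (1.0 + np.exp(np.clip(-beta * (ca - theta), -500.0, 500.0)))
    return out.item() if out.ndim == 0 else out


def h_post(v_post, pp: PlasticityParams):
    """Postsynaptic gate H(V) = 1 / (1 + exp(-mu (V - V_th))).

    Population-level stand-in for the NMDAR magnesium block: calcium entry
    requires postsynaptic depolarization.
    """
    v_post = np.asarray(v_post, dtype=float)
    out = 1.0 / (1.0 + np.exp(np.clip(-pp.mu * (v_post - pp.V_th), -500.0, 500.0)))
    return out.item() if out.ndim == 0 else out


def stp_field(r, u, Us, F_pre, pp: PlasticityParams):
    """Short-term plasticity flow (dr/dt, du/dt) under presynaptic rate F_pre."""
    dr = (1.0 - r) / pp.tau_r - u * r * F_pre
    du = (Us - u) / pp.tau_f + Us * (1.0 - u) * F_pre
    return dr, du


def stp_steady_state(F_pre, Us, pp: PlasticityParams):
    """Closed-form steady state of the short-term dynamics at constant rate.

    u* = Us (1 + tau_f F) / (1 + tau_f Us F);  r* = 1 / (1 + tau_r u* F).
    """
    u = Us * (1.0 + pp.tau_f * F_pre) / (1.0 + pp.tau_f * Us * F_pre)
    r = 1.0 / (1.0 + pp.tau_r * u * F_pre)
    return r, u


def calcium_field(Ca, y_NMDA, v_post, pp: PlasticityParams, C_NMDA: float):
    """dCa/dt = C_NMDA y_NMDA h_ca H(v_post) - Ca / tau_ca.

    The glutamate-binding kinetics are carried by the synaptic NMDAergic EPSP
    y_NMDA; the extrasynaptic channel does not drive calcium (its effect is
    routed exclusively through the GABAergic switch K).
    """
    return C_NMDA * y_NMDA * pp.h_ca * h_post(v_post, pp) - Ca / pp.tau_ca


def rho_field(rho, Ca, pp: PlasticityParams):
    """Synaptic efficacy flow (times tau_rho it is the cubic-plus-gates form)."""
    cubic = -rho * (1.0 - rho) * (pp.rho_star - rho)
    gain = (1.0 - rho) * omega(Ca, "potentiation", pp)
    loss = rho * omega(Ca, "depression", pp)
    return (cubic + gain - loss) / pp.tau_rho


def consolidation_field(Us, C_AMPA, rho, pp: PlasticityParams):
    """(dUs/dt, dC_AMPA/dt): linear relaxation toward the rho-set targets."""
    dUs = (pp.Us_d - Us + rho * (pp.Us_p - pp.Us_d)) / pp.tau_U
    dCA = (pp.C_AMPA_d - C_AMPA + rho * (pp.C_AMPA_p - pp.C_AMPA_d)) / pp.tau_CAMPA
    return dUs, dCA
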