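"""Inter-population signalling and the pathological GABAergic switch.

NMM1 reaches NMM2 through three receptor channels, each a second-order
synaptic filter driven by r u A / tau * F_pre (the presynaptic firing rate
modulated by the short-term plasticity state):

* AMPA (fast), weighted in V_P^(2) by the plastic coupling strength C_AMPA;
* synaptic NMDA (slower), gated postsynaptically by H(V_P^(2));
* extrasynaptic NMDA (slowest), active only once the synapse is potentiated
  (release probability above the spillover gate, Us > 0.7).

The extrasynaptic channel drives the integrity variable K through a bistable
cubic: K = 1 is the intact GABAergic system, K = 0 the degraded one, and the
drive term only ever pushes K downward, which makes degradation irreversible.
K modulates NMM2's excitability threshold and fast IPSP amplitude through
two affine maps with slopes -k_B and +k_G.
"""

from __future__ import annotations

import numpy as np

from .params import CouplingParams, PlasticityParams
from .plasticity import h_post

__all__ = [
    "epsp_field",
    "ext_nmda_gate",
    "k_field",
    "pathological_modulation",
    "total_input_nmm2",
]


def epsp_field(y, z, amplitude: float, tau: float, r, u, F_pre):
    """Shared second-order filter for all three receptor channels.

    Drive is (r u amplitude / tau) F_pre; returns (dy/dt, dz/dt).
    """
    dy = z
    dz = (r * u * amplitude / tau) * F_pre - 2.0 / tau * z - y / tau**2
    return dy, dz


def ext_nmda_gate(Us, gate: float = 0.7, smooth: float | None = None):
    """Extrasynaptic NMDAR activation gate.

    Hard indicator 1[Us > gate] by default (the gate the model states as a
    bare inequality); ``smooth`` switches to a logistic of that slope for
    differentiability studies.
    """
    Us = np.asarray(Us, dtype=float)
    if smooth is None:
        out = (Us > gate).astype(float)
    else:
        out = 1.0 / (1.0 + np.exp(np.clip(-smooth * (Us - gate), -500.0, 500.0)))
    return out.item() if out.ndim == 0 else out


def k_field(K, y_NMDA_ext, v_post2, cp: CouplingParams, pp: PlasticityParams):
    """dK/dt = (-K (0.5 - K)(1 - K) - C_NMDA y_NMDA_ext H(V_P2)) / tau_K.

    With zero drive the cubic has stable equilibria at K = 0 and 1 and an
    unstable one at 0.5; positive drive removes the upper pair through a fold
    and leaves K ~ 0 as the global attractor.
    """
    cubic = -K * (0.5 - K) * (1.0 - K)
    drive = cp.C_NMDA * y_NMDA_ext * h_post(v_post2, pp)
    return (cubic - drive) / cp.tau_K


def pathological_modulation(K, cp: CouplingParams, base_b_thr: float,
                            base_G: float):
    """Effective (b_thr, G) of NMM2 under GABAergic degradation.

    b_thr_eff = b_thr - k_B (1 - K);  G_eff = G + k_G (1 - K).
    """
    loss = 1.0 - K
    return base_b_thr - cp.k_B * loss, base_G + cp.k_G * loss


def total_input_nmm2(y_AMPA, y_NMDA, y_NMDA_ext, C_AMPA: float,
                     cp: CouplingParams, pp: PlasticityParams,
                     v_post2_prev: float):
    """External drive added to V_P^(2).

    C_AMPA y_AMPA + C_NMDA (y_NMDA + y_NMDA_ext) H(V_P2_prev); the implicit
    dependence of the NMDA terms on V_P^(2) is resolved with a one-step lag.
    """
    h = h_post(v_post2_prev, pp)
    return C_AMPA * y_AMPA + cp.C_NMDA * (y_NMDA + y_NMDA_ext) * h
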