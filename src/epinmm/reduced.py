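"""Slow-regime reduction of the physiological plasticity system.

On the consolidation timescale the short-term variables and calcium are
slaved to (F_pre, Us): r and u take their closed-form steady states, the
target's depolarization is approximated by its AMPAergic component alone
(assuming the intra-population contributions balance), and calcium becomes

    Ca_s = tau_ca C_NMDA tau_NMDA A_NMDA r_s u_s F_pre h_ca   if V_P2 > V_th
    Ca_s = 0                                                  otherwise.

Treating (Us, C_AMPA) as frozen parameters (their time constants are two
orders of magnitude above tau_rho), the efficacy equation becomes a scalar
flow whose root structure over the (F_pre, Us) plane classifies the
long-term fate of the synapse: bistable (depressed and potentiated both
stable), single depressed, or single potentiated.

Since C_AMPA and Us follow rho through identical first-order laws, their
quasi-steady states are affinely linked; the default map matches the
endpoints: C_AMPA = C_AMPA_d + (Us - Us_d)/(Us_p - Us_d) (C_AMPA_p - C_AMPA_d).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .params import CouplingParams, PlasticityParams
from .plasticity import omega, stp_steady_state

__all__ = [
    "slow_stp",
    "c_ampa_of_us",
    "slow_vpost_and_calcium",
    "rho_equilibria",
    "RegimeMap",
    "build_regime_map",
]


def slow_stp(F_pre, Us, pp: PlasticityParams):
    """(r_s, u_s): closed-form short-term steady state at constant rate."""
    return stp_steady_state(F_pre, Us, pp)


def c_ampa_of_us(Us, pp: PlasticityParams, kappa: float | None = None):
    """Affine link between the two consolidation variables.

    Default: endpoint-matching map; pass ``kappa`` for C_AMPA_d + kappa Us.
    """
    if kappa is not None:
        return pp.C_AMPA_d + kappa * np.asarray(Us, dtype=float)
    frac = (np.asarray(Us, dtype=float) - pp.Us_d) / (pp.Us_p - pp.Us_d)
    return pp.C_AMPA_d + frac * (pp.C_AMPA_p - pp.C_AMPA_d)


def slow_vpost_and_calcium(F_pre, Us, pp: PlasticityParams,
                           cp: CouplingParams,
                           kappa: float | None = None):
    """(V_P2, Ca_s) in the slow regime.

    Calcium is the exact quasi-steady state of its balance equation,
    tau_ca C_NMDA y_NMDA h_ca H(V_P2), with the depolarization gate H kept
    as a smooth factor; the hard if-V_P2-exceeds-threshold approximation is
    its sharp-slope limit and would make the calcium surface jump from zero
    straight to above 1, erasing the distinction between sub-unity
    thresholds. The smooth surface is near zero at low (F_pre, Us), rises
    sharply once the AMPAergic depolarization reaches the gate, and
    plateaus at high drive.
    """
    from .plasticity import h_post
    r, u = slow_stp(F_pre, Us, pp)
    c_ampa = c_ampa_of_us(Us, pp, kappa)
    vp2 = c_ampa * cp.tau_AMPA * cp.A_AMPA * r * u * np.asarray(F_pre, float)
    ca = (pp.tau_ca * cp.C_NMDA * cp.tau_NMDA * cp.A_NMDA
          * r * u * np.asarray(F_pre, float) * pp.h_ca * h_post(vp2, pp))
    if np.ndim(vp2) == 0:
        return float(vp2), float(ca)
    return vp2, ca


def _rho_flow(rho, ca, pp: PlasticityParams):
    return (-rho * (1.0 - rho) * (pp.rho_star - rho)
            + (1.0 - rho) * omega(ca, "potentiation", pp)
            - rho * omega(ca, "depression", pp))


def rho_equilibria(ca: float, pp: PlasticityParams,
                   grid: float = 1e-3, tol: float = 1e-10):
    """All roots of the reduced efficacy flow in [0, 1] with stability flags.

    Dense sign scan at the ``grid`` resolution plus bisection refinement;
    returns a list of (rho*, stable) sorted by rho*. Stability is the sign of
    the flow derivative (finite difference on the refined root).
    """
    from scipy.optimize import brentq
    xs = np.arange(0.0, 1.0 + grid, grid)
    fs = _rho_flow(xs, ca, pp)
    roots = []
    for i in np.nonzero(np.diff(np.sign(fs)) != 0)[0]:
        roots.append(brentq(_rho_flow, xs[i], xs[i + 1], args=(ca, pp),
                            xtol=tol))
    # exact boundary roots (flow vanishes at 0/1 only when the gates do)
    for edge in (0.0, 1.0):
        if abs(_rho_flow(edge, ca, pp)) < 1e-14:
            roots.append(edge)
    roots = sorted(set(np.round(roots, 12)))
    out = []
    h = 1e-6
    for r in roots:
        df = (_rho_flow(min(r + h, 1.0), ca, pp)
              - _rho_flow(max(r - h, 0.0), ca, pp)) / (
                  min(r + h, 1.0) - max(r - h, 0.0))
        out.append((float(r), bool(df < 0)))
    return out


_CLASSES = ("bistable_three", "single_depressed", "single_potentiated")


@dataclass
class RegimeMap:
    """Grid classification of the long-term synaptic fate over (F_pre, Us)."""

    F: np.ndarray               # shape (nF,)
    Us: np.ndarray              # shape (nU,)
    classes: np.ndarray         # shape (nU, nF) of str
    vp2: np.ndarray             # shape (nU, nF)
    ca: np.ndarray              # shape (nU, nF)
    theta_d: float
    theta_p: float
    gamma_p: float

    def count(self, cls: str) -> int:
        return int(np.sum(self.classes == cls))

    def to_csv(self, path) -> None:
        import pandas as pd
        rows = []
        for i, us in enumerate(self.Us):
            for j, f in enumerate(self.F):
                rows.append((f, us, self.classes[i, j], self.vp2[i, j],
                             self.ca[i, j]))
        pd.DataFrame(rows, columns=["F_pre", "Us", "class", "V_P2", "Ca_s"]
                     ).to_csv(path, index=False)


def build_regime_map(theta_d: float, theta_p: float, gamma_p: float,
                     pp: PlasticityParams | None = None,
                     cp: CouplingParams | None = None,
                     n_F: int = 51, n_U: int = 41,
                     F_max: float = 5.0) -> RegimeMap:
    """Classify every (F_pre, Us) cell by the roots of the reduced flow."""
    if pp is None:
        pp = PlasticityParams()
    if cp is None:
        cp = CouplingParams()
    pp = replace(pp, theta_d=theta_d, theta_p=theta_p, gamma_p=gamma_p)
    F = np.linspace(0.0, F_max, n_F)
    Us = np.linspace(1e-3, 1.0, n_U)
    classes = np.empty((n_U, n_F), dtype=object)
    vp2 = np.zeros((n_U, n_F))
    ca = np.zeros((n_U, n_F))
    for i, us in enumerate(Us):
        for j, f in enumerate(F):
            v, c = slow_vpost_and_calcium(f, us, pp, cp)
            vp2[i, j] = v
            ca[i, j] = c
            roots = rho_equilibria(c, pp)
            stable = [r for r, s in roots if s]
            if len(roots) >= 3:
                classes[i, j] = "bistable_three"
            elif len(stable) == 1 and stable[0] > pp.rho_star:
                classes[i, j] = "single_potentiated"
            else:
                classes[i, j] = "single_depressed"
    return RegimeMap(F=F, Us=Us, classes=classes, vp2=vp2, ca=ca,
                     theta_d=theta_d, theta_p=theta_p, gamma_p=gamma_p)
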