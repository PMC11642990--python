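"""Slow (B, n) excitability subsystem: nullclines, folds, excitability class.

The SOM IPSP amplitude B is a slow variable whose N-shaped nullcline
n = f(B) has stable outer branches and an unstable middle branch:

    f(B) = -m1 (B-p1)^2 / (1 + exp(B-p1))
         + 1 / (1 + exp(B-p2))
         + m3 (B-p3)^2 / (1 + exp(p3-B))

so the left parabola is active below p1, the middle sigmoid decreases
through p2, and the right parabola grows above p3. The recovery variable n
relaxes to a decreasing sigmoid of B with inflection at the excitability
threshold b_thr. B values on the right branch correspond to interictal
dynamics of the fast subsystem; the left/middle branches to ictal dynamics.
The right fold (local minimum of f, near but not exactly at p3) is the
critical point of the seizure transition: an equilibrium left of it makes
the subsystem a relaxation oscillator (recurrent spontaneous seizures), an
equilibrium just right of it makes it excitable (perturbations of B trigger
single seizures).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .params import SlowParams

__all__ = [
    "b_nullcline",
    "n_nullcline",
    "slow_field",
    "FoldPair",
    "find_folds",
    "nullcline_intersections",
    "classify_excitability",
]


def b_nullcline(B, sp: SlowParams):
    """f(B): the value of n on the B-nullcline."""
    B = np.asarray(B, dtype=float)
    t1 = -sp.m1 * (B - sp.p1) ** 2 / (1.0 + np.exp(np.clip(B - sp.p1, -500, 500)))
    t2 = 1.0 / (1.0 + np.exp(np.clip(B - sp.p2, -500, 500)))
    t3 = sp.m3 * (B - sp.p3) ** 2 / (1.0 + np.exp(np.clip(sp.p3 - B, -500, 500)))
    out = t1 + t2 + t3
    return out.item() if out.ndim == 0 else out


def n_nullcline(B, b_thr_eff: float, sp: SlowParams):
    """Decreasing sigmoid n_k + n_p / (1 + exp(-n_r (b_thr - B)))."""
    B = np.asarray(B, dtype=float)
    out = sp.n_k + sp.n_p / (1.0 + np.exp(np.clip(-sp.n_r * (b_thr_eff - B), -500, 500)))
    return out.item() if out.ndim == 0 else out


def slow_field(state, b_thr_eff: float, sp: SlowParams):
    """(dB/dt, dn/dt) of the slow subsystem."""
    B, n = state
    dB = sp.delta * (n - b_nullcline(B, sp))
    dn = sp.epsilon * (-n + sp.n_k + sp.n_p
                       / (1.0 + np.exp(np.clip(-sp.n_r * (b_thr_eff - B), -500, 500))))
    return dB, dn


def _fprime(B: float, sp: SlowParams, h: float = 1e-6) -> float:
    return (b_nullcline(B + h, sp) - b_nullcline(B - h, sp)) / (2.0 * h)


@dataclass
class FoldPair:
    """The two extrema of the N-shaped B-nullcline."""
    B_left: float      # local maximum (near p1)
    B_right: float     # local minimum (near p3) — seizure-transition critical point
    n_left: float
    n_right: float


def find_folds(sp: SlowParams) -> FoldPair:
    """Locate both folds of f by bracketed root search on f'.

    Raises ValueError with the observed sign-change count if the nullcline is
    not N-shaped in [p1 - 10, p3 + 10].
    """
    lo, hi = sp.p1 - 10.0, sp.p3 + 10.0
    Bs = np.linspace(lo, hi, 4001)
    h = 1e-6
    fp = (b_nullcline(Bs + h, sp) - b_nullcline(Bs - h, sp)) / (2.0 * h)
    idx = np.nonzero(np.diff(np.sign(fp)) != 0)[0]
    if len(idx) != 2:
        raise ValueError(
            f"B-nullcline is not N-shaped: {len(idx)} extrema in [{lo}, {hi}]")
    roots = [brentq(_fprime, Bs[i], Bs[i + 1], args=(sp,), xtol=1e-8) for i in idx]
    b_l, b_r = sorted(roots)
    return FoldPair(b_l, b_r, b_nullcline(b_l, sp), b_nullcline(b_r, sp))


def nullcline_intersections(b_thr_eff: float, sp: SlowParams,
                            window: tuple[float, float] = (-20.0, 90.0),
                            n_scan: int = 22001) -> list[float]:
    """B coordinates of all equilibria (f(B) = n-nullcline(B))."""
    def g(B):
        return b_nullcline(B, sp) - n_nullcline(B, b_thr_eff, sp)
    Bs = np.linspace(*window, n_scan)
    gv = g(Bs)
    return [brentq(g, Bs[i], Bs[i + 1], xtol=1e-10)
            for i in np.nonzero(np.diff(np.sign(gv)) != 0)[0]]


def classify_excitability(b_thr_eff: float, sp: SlowParams,
                          folds: FoldPair | None = None) -> str:
    """'oscillatory' if the unique equilibrium lies strictly left of the right
    fold (recurrent spontaneous seizures), else 'excitable_rest'.

    Multiple nullcline intersections raise rather than being silently
    resolved. ``folds`` may be passed to avoid recomputation in sweeps.
    """
    if folds is None:
        folds = find_folds(sp)
    inter = nullcline_intersections(b_thr_eff, sp)
    if len(inter) != 1:
        raise ValueError(
            f"expected a unique nullcline intersection, found {len(inter)} at "
            f"B={inter} (b_thr_eff={b_thr_eff})")
    return "oscillatory" if inter[0] < folds.B_right else "excitable_rest"
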