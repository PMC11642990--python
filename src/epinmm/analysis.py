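"""Equilibrium continuation, bifurcation detection and signal analysis.

The fast subsystem's equilibrium branch over the slow-IPSP amplitude B is
S-shaped (it folds back twice), so it is traced by pseudo-arclength
continuation in the 9-dim space (8 fast states, B): secant predictor,
Newton corrector orthogonal to the secant, adaptive step. Eigenvalues of
the analytic 8x8 Jacobian are stored at every accepted point; Hopf points
are refined where the leading complex pair's real part changes sign, folds
where a real eigenvalue crosses zero (equivalently where the branch tangent
reverses in B).

Event detection operates on recorded channels: spikes are local maxima of
V_P above a robust (median + c * MAD) threshold with a refractory window;
seizures are maximal intervals in which B stays below the right fold of the
slow nullcline minus a hysteresis margin (ictal = left/middle-branch
residence).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .fast import fast_field, fast_jacobian, equilibria_at
from .params import FastParams, SlowParams
from .slow import classify_excitability, find_folds

__all__ = [
    "BifurcationBranch", "BifurcationPoint", "EventSet",
    "trace_branch", "detect_bifurcations", "oscillation_envelope",
    "detect_spikes", "detect_seizures", "seizure_delay",
    "normalized_psd", "critical_kb", "spike_frequency",
]


# ---------------------------------------------------------------------------
# continuation

@dataclass
class BifurcationBranch:
    """Ordered equilibrium branch: B values, states, eigenvalues, stability."""

    B: np.ndarray                  # (n,)
    states: np.ndarray             # (n, 8)
    eigvals: np.ndarray            # (n, 8) complex
    stable: np.ndarray             # (n,) bool
    fp: FastParams = field(repr=False, default=None)
    p_input: float = 0.0

    def __len__(self):
        return len(self.B)


@dataclass
class BifurcationPoint:
    kind: str                      # 'hopf' | 'fold'
    B: float
    eigenvalue: complex            # critical eigenvalue at detection
    index: int                     # bracketing segment start in the branch


def _extended_residual(u, fp, G, p_input):
    return fast_field(u[:8], fp, u[8], G, p_input)


def _extended_jacobian(u, fp, G, p_input):
    """8x9 Jacobian of the equilibrium condition wrt (state, B)."""
    J = np.zeros((8, 9))
    J[:, :8] = fast_jacobian(u[:8], fp, u[8], G)
    # only the SOM acceleration row depends on B
    from .fast import sigmoid_rate
    J[5, 8] = sigmoid_rate(fp.C_SOM_P * u[0]) / fp.tau_b
    return J


def _newton_correct(u_pred, tangent, fp, G, p_input, tol=1e-10, maxit=12):
    u = u_pred.copy()
    for _ in range(maxit):
        F = _extended_residual(u, fp, G, p_input)
        res = np.linalg.norm(F)
        if res < tol:
            return u, True
        J = np.vstack([_extended_jacobian(u, fp, G, p_input), tangent])
        rhs = np.concatenate([F, [tangent @ (u - u_pred)]])
        try:
            du = np.linalg.solve(J, rhs)
        except np.linalg.LinAlgError:
            return u, False
        u = u - du
    return u, np.linalg.norm(_extended_residual(u, fp, G, p_input)) < 1e-8


# continuation scales: PSPs are O(1-10) mV while B spans 60, so arclength is
# measured with B downweighted to keep state resolution near the folds
_WB = 1.0


def trace_branch(fp: FastParams, b_range=(0.0, 60.0),
                 p_input: float | None = None, G: float | None = None,
                 ds: float = 0.02, ds_min: float = 1e-4, ds_max: float = 0.1,
                 max_points: int = 40000) -> BifurcationBranch:
    """Pseudo-arclength continuation of fast-subsystem equilibria over B."""
    if p_input is None:
        p_input = fp.p_m
    if G is None:
        G = fp.G
    b0, b1 = b_range
    eqs = equilibria_at(fp, b0, G, p_input)
    if len(eqs) != 1:
        raise ValueError(f"need a unique equilibrium at B={b0} to start "
                         f"(found {len(eqs)})")
    u = np.concatenate([eqs[0], [b0]])
    # initial tangent: toward increasing B
    t = np.zeros(9)
    t[8] = 1.0
    J = np.vstack([_extended_jacobian(u, fp, G, p_input), t])
    rhs = np.zeros(9)
    rhs[8] = 1.0
    t = np.linalg.solve(J, rhs)
    t /= np.linalg.norm(t)
    if t[8] < 0:
        t = -t

    Bs, states = [u[8]], [u[:8].copy()]
    step = ds
    while len(Bs) < max_points:
        if (u[8] > b1 + 1e-9 and t[8] > 0) or (u[8] < b0 - 1e-9 and t[8] < 0):
            break
        u_pred = u + step * t
        u_new, ok = _newton_correct(u_pred, t, fp, G, p_input)
        moved = ok and np.linalg.norm(u_new - u) > 1e-12
        if not moved:
            step *= 0.5
            if step < ds_min:
                raise RuntimeError(
                    f"continuation stalled at B={u[8]:.6f} after {len(Bs)} "
                    "points")
            continue
        t_new = (u_new - u) / np.linalg.norm(u_new - u)
        u, t = u_new, t_new
        Bs.append(u[8])
        states.append(u[:8].copy())
        step = min(step * 1.3, ds_max)

    B = np.array(Bs)
    S = np.array(states)
    eig = np.zeros((len(B), 8), dtype=complex)
    for i in range(len(B)):
        eig[i] = np.linalg.eigvals(fast_jacobian(S[i], fp, B[i], G))
    stable = np.all(eig.real < 0, axis=1)
    return BifurcationBranch(B=B, states=S, eigvals=eig, stable=stable,
                             fp=fp, p_input=p_input)


def _n_unstable(eig) -> int:
    return int(np.sum(eig.real > 0.0))


def _hopf_re(eig) -> float:
    """Real part of the complex pair nearest the imaginary axis (nan if none)."""
    cplx = eig[np.abs(eig.imag) > 1e-6]
    if len(cplx) == 0:
        return np.nan
    return float(cplx.real[np.argmin(np.abs(cplx.real))])


def detect_bifurcations(branch: BifurcationBranch,
                        tol_B: float = 1e-3) -> list[BifurcationPoint]:
    """Locate and refine Hopf and fold points along a traced branch.

    Folds are detected geometrically (the branch tangent reverses in B) and
    refined by a shrinking-step local continuation to the vertex. Hopf
    points are detected as a +-2 change in the number of unstable
    eigenvalues with the critical pair complex, and refined by bisection on
    the real part of the pair nearest the axis; a refined candidate whose
    critical real part is not small is discarded as an eigenvalue-structure
    artefact, never misreported.
    """
    fp, G, p_input = branch.fp, branch.fp.G, branch.p_input
    out = []

    def eig_at(u):
        return np.linalg.eigvals(fast_jacobian(u[:8], fp, u[8], G))

    def point(i):
        return np.concatenate([branch.states[i], [branch.B[i]]])

    # --- folds: tangent reversal in B (ignore zero-length steps)
    dB = np.diff(branch.B)
    nz = np.nonzero(dB != 0.0)[0]
    s = np.sign(dB[nz])
    rev = [int(nz[k]) for k in np.nonzero(s[:-1] * s[1:] < 0)[0]]
    for i in rev:
        # vertex between points i and i+2; walk toward it with shrinking steps
        u = point(i)
        t = point(i + 1) - u
        h = np.linalg.norm(t)
        t /= h
        sgn = np.sign(t[8])
        for _ in range(200):
            if h < 1e-7:
                break
            u_new, ok = _newton_correct(u + h * t, t, fp, G, p_input)
            if not ok:
                h *= 0.5
                continue
            t_new = u_new - u
            nrm = np.linalg.norm(t_new)
            if nrm == 0:
                break
            t_new /= nrm
            if np.sign(t_new[8]) == sgn and t_new @ t > 0:
                u, t = u_new, t_new
            else:
                h *= 0.5
        eig = eig_at(u)
        re = eig[np.abs(eig.imag) <= 1e-6].real
        crit = complex(re[np.argmin(np.abs(re))]) if len(re) else 0j
        out.append(BifurcationPoint(kind="fold", B=float(u[8]),
                                    eigenvalue=crit, index=int(i)))

    fold_segments = {bp.index for bp in out}
    fold_segments |= {i + 1 for i in fold_segments}

    # --- Hopf: unstable count changes by 2 through a complex pair
    nuns = np.array([_n_unstable(e) for e in branch.eigvals])
    for i in np.nonzero(np.abs(np.diff(nuns)) == 2)[0]:
        if i in fold_segments:
            continue
        u0, u1 = point(i), point(i + 1)
        f0 = _hopf_re(branch.eigvals[i])
        f1 = _hopf_re(branch.eigvals[i + 1])
        if not (np.isfinite(f0) and np.isfinite(f1)) or f0 * f1 > 0:
            continue
        for _ in range(80):
            if abs(u1[8] - u0[8]) < tol_B and np.linalg.norm(u1 - u0) < tol_B:
                break
            t = u1 - u0
            t /= np.linalg.norm(t)
            um, ok = _newton_correct(0.5 * (u0 + u1), t, fp, G, p_input)
            if not ok:
                break
            fm = _hopf_re(eig_at(um))
            if np.isfinite(fm) and fm * f0 > 0:
                u0, f0 = um, fm
            else:
                u1, f1 = um, fm
        eig = eig_at(0.5 * (u0 + u1))
        cplx = eig[np.abs(eig.imag) > 1e-6]
        if len(cplx) == 0:
            continue
        crit = cplx[np.argmin(np.abs(cplx.real))]
        if abs(crit.real) > 1e-2 * max(1.0, abs(crit.imag)):
            continue      # not actually a crossing (structure artefact)
        out.append(BifurcationPoint(kind="hopf", B=float(0.5 * (u0[8] + u1[8])),
                                    eigenvalue=complex(crit), index=int(i)))

    out.sort(key=lambda bp: bp.B)
    # dedupe near-coincident repeats of the same kind
    deduped: list[BifurcationPoint] = []
    for bp in out:
        if deduped and deduped[-1].kind == bp.kind and abs(deduped[-1].B - bp.B) < 2 * tol_B:
            continue
        deduped.append(bp)
    return deduped


def oscillation_envelope(B_values, fp: FastParams,
                         p_input: float | None = None,
                         t_sim: float = 4.0, t_discard: float = 2.0,
                         dt: float = 1e-4):
    """(min, max) of y_P per B from direct simulation after transient discard."""
    from .params import default_params
    from .simulator import Protocol, integrate, initial_state
    from dataclasses import replace as _rep
    out = []
    for B in np.atleast_1d(B_values):
        p = default_params()
        p.pop1.fast = _rep(fp)
        p.dt = dt
        p.duration = t_sim
        st = initial_state(p)
        st[:16] = 0.0
        st[16] = B
        proto = Protocol(name="envelope", duration=t_sim,
                         noise_enabled=False, slow1_enabled=False,
                         slow2_enabled=False, coupling_enabled=False,
                         initial_state=st, record_stride=5)
        ts = integrate(p, proto)
        y = ts["y_P1"][ts.time >= t_discard]
        out.append((float(y.min()), float(y.max())))
    return out[0] if np.ndim(B_values) == 0 else out


# ---------------------------------------------------------------------------
# event detection

@dataclass
class EventSet:
    """Detected spikes and seizure intervals for one recording."""

    spike_times: dict               # population id -> array of times [s]
    seizures: dict                  # population id -> list of (start, end)

    def spike_frequency(self, pop: int, window: tuple[float, float]) -> float:
        return spike_frequency(self.spike_times[pop], window)


# documented detector constants
SPIKE_MAD_FACTOR = 6.0
SPIKE_REFRACTORY = 0.2       # [s]
SEIZURE_HYSTERESIS = 1.0     # [mV] below the right fold
SEIZURE_MIN_DURATION = 2.0   # [s]


def detect_spikes(v, dt: float, mad_factor: float = SPIKE_MAD_FACTOR,
                  refractory: float = SPIKE_REFRACTORY) -> np.ndarray:
    """Spike times: local maxima above median + mad_factor * MAD."""
    v = np.asarray(v, dtype=float)
    base = np.median(v)
    mad = np.median(np.abs(v - base))
    if mad == 0.0:
        return np.array([])
    thr = base + mad_factor * mad
    dist = max(1, int(round(refractory / dt)))
    peaks, _ = _signal.find_peaks(v, height=thr, distance=dist)
    return peaks * dt


def detect_seizures(B, dt: float, sp: SlowParams,
                    hysteresis: float = SEIZURE_HYSTERESIS,
                    min_duration: float = SEIZURE_MIN_DURATION):
    """Maximal intervals with B below the right fold minus the hysteresis."""
    B = np.asarray(B, dtype=float)
    thr = find_folds(sp).B_right - hysteresis
    below = B < thr
    edges = np.diff(below.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0] + 1)
    if below[0]:
        starts.insert(0, 0)
    if below[-1]:
        ends.append(len(B))
    out = []
    for s, e in zip(starts, ends):
        if (e - s) * dt >= min_duration:
            out.append((s * dt, e * dt))
    return out


def seizure_delay(seizures1, seizures2, window: float = 80.0,
                  mode: str = "subsequent"):
    """Onset-time differences t1 - t2 for paired seizures.

    ``mode='subsequent'`` pairs each primary-focus seizure with the nearest
    secondary-focus onset that follows it within ``window`` seconds
    (negative values: the primary leads). ``mode='ordinal'`` pairs the k-th
    seizure of each population — the convention used when the degraded
    target also seizes spontaneously, so that delays shrink (toward zero or
    positive) as the target matures into an independent focus. Returns
    (delays, unpaired_primary_onsets).
    """
    on2 = [s for s, _ in seizures2]
    delays, unpaired = [], []
    if mode == "ordinal":
        n = min(len(seizures1), len(on2))
        delays = [seizures1[k][0] - on2[k] for k in range(n)]
        unpaired = [s for s, _ in seizures1[n:]]
        return delays, unpaired
    if mode == "nearest":
        # nearest onset in either direction: once the target seizes
        # spontaneously its onsets decouple from the source's, and the
        # relevant statistic is how closely the two rhythms align
        used = set()
        for s1, _ in seizures1:
            cand = [(abs(s2 - s1), j) for j, s2 in enumerate(on2)
                    if j not in used and abs(s2 - s1) <= window]
            if not cand:
                unpaired.append(s1)
                continue
            _, j = min(cand)
            used.add(j)
            delays.append(s1 - on2[j])
        return delays, unpaired
    if mode != "subsequent":
        raise ValueError(f"unknown mode {mode!r}")
    used = set()
    for s1, _ in seizures1:
        best = None
        for j, s2 in enumerate(on2):
            if j in used or s2 < s1 or s2 - s1 > window:
                continue
            if best is None or s2 < on2[best]:
                best = j
        if best is None:
            unpaired.append(s1)
        else:
            used.add(best)
            delays.append(s1 - on2[best])
    return delays, unpaired


def spike_frequency(times, window: tuple[float, float]) -> float:
    """Spike count divided by window length [spikes / s]."""
    times = np.asarray(times, dtype=float)
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty window")
    return float(np.sum((times >= t0) & (times < t1)) / (t1 - t0))


def normalized_psd(x, fs: float, nperseg: int | None = None):
    """Welch periodogram normalized to unit total power.

    Returns (freqs, psd, peak_frequency, gamma_fraction) with the gamma band
    fixed to 30-90 Hz.
    """
    x = np.asarray(x, dtype=float)
    if nperseg is None:
        nperseg = min(len(x), 2048)
    if len(x) < 2 * nperseg:
        raise ValueError("segment shorter than two Welch windows")
    f, p = _signal.welch(x - x.mean(), fs=fs, nperseg=nperseg)
    total = np.trapezoid(p, f)
    if total > 0:
        p = p / total
    peak = float(f[np.argmax(p)])
    gmask = (f >= 30.0) & (f <= 90.0)
    gamma = float(np.trapezoid(p[gmask], f[gmask]))
    return f, p, peak, gamma


def critical_kb(sp: SlowParams, grid: float = 0.01,
                k_max: float = 20.0) -> float:
    """Smallest k_B (on a ``grid`` resolution) making the fully degraded
    (K = 0) slow subsystem oscillatory.

    The classification is monotone in the threshold shift, so the boundary
    is bracketed by bisection and then snapped up to the grid — equivalent
    to, and much faster than, a linear grid scan.
    """
    folds = find_folds(sp)

    def osc(kb: float) -> bool:
        return classify_excitability(sp.b_thr - kb, sp, folds) == "oscillatory"

    if osc(0.0):
        return 0.0
    if not osc(k_max):
        raise ValueError(f"no oscillatory k_B found below {k_max}")
    lo, hi = 0.0, k_max
    while hi - lo > grid / 8:
        mid = 0.5 * (lo + hi)
        if osc(mid):
            hi = mid
        else:
            lo = mid
    k = np.ceil(hi / grid - 1e-9) * grid
    if not osc(k):            # boundary exactly on a grid point
        k += grid
    return float(round(k, 10))
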