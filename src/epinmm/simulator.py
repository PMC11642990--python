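"""Euler–Maruyama integration of the full two-population network.

The flat network state has 33 entries::

     0- 7  NMM1 fast filters (y_P, z_P, y_P', z_P', y_SOM, z_SOM, y_PV, z_PV)
     8-15  NMM2 fast filters (same order)
    16-17  NMM1 slow subsystem (B, n)
    18-19  NMM2 slow subsystem (B, n)
    20-25  plasticity (r, u, Ca, rho, Us, C_AMPA)
    26-31  coupling EPSPs (y_AMPA, z_AMPA, y_NMDA, z_NMDA, y_ext, z_ext)
    32     GABAergic integrity K

Stochasticity enters three ways, all seeded: the per-step value noise on the
drives p^(i)(t) ~ N(p_m, p_s) (held for one step, no sqrt(dt) scaling — the
drive is specified as a distribution, not a Wiener increment), and Brownian
perturbations on B^(1) and B^(2) scaled by sqrt(dt). Identical
(params, protocol, seed) give bit-identical trajectories.

The NMDA channels' implicit dependence on V_P^(2) through the gate H is
resolved with a one-step lag (error O(dt), far below every synaptic time
constant at the default dt = 1e-4 s).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit

from . import params as _prm
from .params import ModelParams, PlasticityParams, default_params
from .slow import nullcline_intersections

__all__ = [
    "CHANNELS",
    "Protocol",
    "TimeSeries",
    "integrate",
    "initial_state",
    "pulse_pairing_protocol",
    "expansion_protocol",
    "resection_protocol",
    "SIGMA_B_DEFAULT",
    "PULSE1_DEFAULT",
    "PULSE2_DEFAULT",
]

# Documented protocol constants (not published; see docs/methods.md):
# B-perturbation noise amplitude calibrated once so that the excitable
# primary focus (b_thr = 34) seizes at least twice per 500 s in every seed
# (ensemble median 3-4), with the one-mV-higher threshold staying silent.
SIGMA_B_DEFAULT = 0.7
# Rectangular pulses added to p(t) for the spike-pairing protocol, each
# sized to elicit exactly one spike in the quiescent interictal state: a
# strong 10-ms pulse to the primary focus (shapes the glutamate wave) and a
# sharp 5-ms pulse that pins the target population's spike time.
PULSE1_DEFAULT = (2500.0, 0.01)
PULSE2_DEFAULT = (2000.0, 0.005)
PULSE_AMP_DEFAULT = 300.0
PULSE_WIDTH_DEFAULT = 0.005

CHANNELS = [
    "V_P1", "V_P2", "B1", "n1", "B2", "n2",
    "r", "u", "Ca", "rho", "Us", "C_AMPA",
    "K", "y_AMPA", "y_NMDA", "y_NMDA_ext", "y_P1",
]

NSTATE = 33


def _pack_params(p: ModelParams) -> np.ndarray:
    f1, f2 = p.pop1.fast, p.pop2.fast
    s1, s2 = p.pop1.slow, p.pop2.slow
    pl, c = p.plasticity, p.coupling
    def fast(f):
        return [f.A, f.G, f.tau_a, f.tau_b, f.tau_g, f.C_P_Pp, f.C_Pp_P,
                f.C_SOM_P, f.C_PV_P, f.C_P_SOM, f.C_P_PV, f.C_SOM_PV,
                f.p_m, f.p_s]
    def slow(s):
        return [s.p1, s.p2, s.p3, s.m1, s.m3, s.n_k, s.n_p, s.n_r, s.b_thr,
                s.delta, s.epsilon]
    vec = ([p.dt] + fast(f1) + fast(f2) + slow(s1) + slow(s2)
           + [pl.theta_d, pl.theta_p, pl.gamma_d, pl.gamma_p, pl.beta_d,
              pl.beta_p, pl.mu, pl.V_th, pl.h_ca, pl.tau_r, pl.tau_f,
              pl.tau_ca, pl.tau_rho, pl.tau_U, pl.tau_CAMPA, pl.Us_d,
              pl.Us_p, pl.C_AMPA_d, pl.C_AMPA_p, pl.rho_star]
           + [c.A_AMPA, c.A_NMDA, c.A_NMDA_ext, c.tau_AMPA, c.tau_NMDA,
              c.tau_NMDA_ext, c.C_NMDA, c.tau_K, c.k_B, c.k_G, c.Us_gate])
    return np.asarray(vec, dtype=np.float64)


# offsets into the packed parameter vector
_F1, _F2, _S1, _S2, _PL, _CP = 1, 15, 29, 40, 51, 71


@njit(cache=True, fastmath=False)
def _S(v):
    x = 0.56 * (6.0 - v)
    if x > 500.0:
        x = 500.0
    elif x < -500.0:
        x = -500.0
    return 5.0 / (1.0 + math.exp(x))


@njit(cache=True, fastmath=False)
def _H(v, mu, vth):
    x = -mu * (v - vth)
    if x > 500.0:
        x = 500.0
    elif x < -500.0:
        x = -500.0
    return 1.0 / (1.0 + math.exp(x))


@njit(cache=True, fastmath=False)
def _fB(B, p1, p2, p3, m1, m3):
    e1 = B - p1
    if e1 > 500.0:
        e1 = 500.0
    e2 = B - p2
    if e2 > 500.0:
        e2 = 500.0
    e3 = p3 - B
    if e3 > 500.0:
        e3 = 500.0
    t1 = -m1 * (B - p1) ** 2 / (1.0 + math.exp(e1))
    t2 = 1.0 / (1.0 + math.exp(e2))
    t3 = m3 * (B - p3) ** 2 / (1.0 + math.exp(e3))
    return t1 + t2 + t3


@njit(cache=True, fastmath=False)
def _fast_rows(out, st, o, P, fo, A, B, G, p_drive, ext):
    """Derivatives of one population's 8 fast entries (state offset o)."""
    ta = P[fo + 2]
    tb = P[fo + 3]
    tg = P[fo + 4]
    yP = st[o]
    zP = st[o + 1]
    yPp = st[o + 2]
    zPp = st[o + 3]
    ySOM = st[o + 4]
    zSOM = st[o + 5]
    yPV = st[o + 6]
    zPV = st[o + 7]
    VP = yPp - P[fo + 9] * ySOM - P[fo + 8] * yPV + ext
    out[o] = zP
    out[o + 1] = (A / ta) * _S(VP) - 2.0 / ta * zP - yP / (ta * ta)
    out[o + 2] = zPp
    out[o + 3] = ((A / ta) * (p_drive + P[fo + 6] * _S(P[fo + 5] * yP))
                  - 2.0 / ta * zPp - yPp / (ta * ta))
    out[o + 4] = zSOM
    out[o + 5] = ((B / tb) * _S(P[fo + 7] * yP) - 2.0 / tb * zSOM
                  - ySOM / (tb * tb))
    out[o + 6] = zPV
    out[o + 7] = ((G / tg) * _S(P[fo + 10] * yP - P[fo + 11] * ySOM)
                  - 2.0 / tg * zPV - yPV / (tg * tg))
    return VP


@njit(cache=True, fastmath=False)
def _run(state0, P, n_steps, stride, seed,
         pulse1_t, pulse2_t, pulse1_amp, pulse2_amp,
         pulse1_width, pulse2_width,
         sigma_B1, sigma_B2, slow1_on, slow2_on, coupling_on,
         resect_t, noise_on, vp2_prev0):
    np.random.seed(seed)
    dt = P[0]
    sqdt = math.sqrt(dt)
    st = state0.copy()
    d = np.zeros(NSTATE)
    n_rec = n_steps // stride + 1
    rec = np.zeros((n_rec, 17))
    vp2_prev = vp2_prev0

    mu = P[_PL + 6]
    vth = P[_PL + 7]
    hca = P[_PL + 8]
    c_nmda = P[_CP + 6]
    usgate = P[_CP + 10]

    err_step = -1
    irec = 0
    vp1 = 0.0
    vp2 = vp2_prev
    for step in range(n_steps + 1):
        t = step * dt
        # --- drives
        if noise_on == 1.0:
            pd1 = P[_F1 + 12] + P[_F1 + 13] * np.random.normal()
            pd2 = P[_F2 + 12] + P[_F2 + 13] * np.random.normal()
            xiB1 = np.random.normal()
            xiB2 = np.random.normal()
        else:
            pd1 = P[_F1 + 12]
            pd2 = P[_F2 + 12]
            xiB1 = 0.0
            xiB2 = 0.0
        if pulse1_t >= 0.0 and pulse1_t <= t < pulse1_t + pulse1_width:
            pd1 += pulse1_amp
        if pulse2_t >= 0.0 and pulse2_t <= t < pulse2_t + pulse2_width:
            pd2 += pulse2_amp

        A1 = P[_F1] if t < resect_t else 0.0

        # --- effective NMM2 parameters under GABAergic degradation
        K = st[32]
        loss = 1.0 - K
        bthr2_eff = P[_S2 + 8] - P[_CP + 8] * loss
        G2_eff = P[_F2 + 1] + P[_CP + 9] * loss

        B1 = st[16]
        B2 = st[18]

        # --- coupling input to NMM2 (one-step lag through H)
        h2 = _H(vp2_prev, mu, vth)
        if coupling_on == 1.0:
            ext2 = st[25] * st[26] + c_nmda * (st[28] + st[30]) * h2
        else:
            ext2 = 0.0

        # --- fast subsystems (population 1's A possibly zeroed by resection)
        vp1 = _fast_rows(d, st, 0, P, _F1, A1, B1, P[_F1 + 1], pd1, 0.0)
        vp2 = _fast_rows(d, st, 8, P, _F2, P[_F2], B2, G2_eff, pd2, ext2)

        F1 = _S(vp1)

        # --- slow subsystems
        if slow1_on == 1.0:
            d[16] = P[_S1 + 9] * (st[17] - _fB(st[16], P[_S1], P[_S1 + 1],
                                               P[_S1 + 2], P[_S1 + 3], P[_S1 + 4]))
            x = -P[_S1 + 7] * (P[_S1 + 8] - st[16])
            if x > 500.0:
                x = 500.0
            d[17] = P[_S1 + 10] * (-st[17] + P[_S1 + 5]
                                   + P[_S1 + 6] / (1.0 + math.exp(x)))
        else:
            d[16] = 0.0
            d[17] = 0.0
        if slow2_on == 1.0:
            d[18] = P[_S2 + 9] * (st[19] - _fB(st[18], P[_S2], P[_S2 + 1],
                                               P[_S2 + 2], P[_S2 + 3], P[_S2 + 4]))
            x = -P[_S2 + 7] * (bthr2_eff - st[18])
            if x > 500.0:
                x = 500.0
            d[19] = P[_S2 + 10] * (-st[19] + P[_S2 + 5]
                                   + P[_S2 + 6] / (1.0 + math.exp(x)))
        else:
            d[18] = 0.0
            d[19] = 0.0

        # --- plasticity
        r = st[20]
        u = st[21]
        Ca = st[22]
        rho = st[23]
        Us = st[24]
        CA = st[25]
        d[20] = (1.0 - r) / P[_PL + 9] - u * r * F1
        d[21] = (Us - u) / P[_PL + 10] + Us * (1.0 - u) * F1
        d[22] = c_nmda * st[28] * hca * h2 - Ca / P[_PL + 11]
        om_p = P[_PL + 3] / (1.0 + math.exp(max(min(-P[_PL + 5] * (Ca - P[_PL + 1]), 500.0), -500.0)))
        om_d = P[_PL + 2] / (1.0 + math.exp(max(min(-P[_PL + 4] * (Ca - P[_PL]), 500.0), -500.0)))
        d[23] = (-rho * (1.0 - rho) * (P[_PL + 19] - rho)
                 + (1.0 - rho) * om_p - rho * om_d) / P[_PL + 12]
        d[24] = (P[_PL + 15] - Us + rho * (P[_PL + 16] - P[_PL + 15])) / P[_PL + 13]
        d[25] = (P[_PL + 17] - CA + rho * (P[_PL + 18] - P[_PL + 17])) / P[_PL + 14]

        # --- coupling filters
        ru = r * u
        ta_ = P[_CP + 3]
        d[26] = st[27]
        d[27] = (ru * P[_CP] / ta_) * F1 - 2.0 / ta_ * st[27] - st[26] / (ta_ * ta_)
        tn = P[_CP + 4]
        d[28] = st[29]
        d[29] = (ru * P[_CP + 1] / tn) * F1 - 2.0 / tn * st[29] - st[28] / (tn * tn)
        te = P[_CP + 5]
        gate = 1.0 if Us > usgate else 0.0
        d[30] = st[31]
        d[31] = (gate * ru * P[_CP + 2] / te) * F1 - 2.0 / te * st[31] - st[30] / (te * te)
        # --- K
        d[32] = (-K * (0.5 - K) * (1.0 - K)
                 - c_nmda * st[30] * h2) / P[_CP + 7]

        # --- record
        if step % stride == 0:
            rec[irec, 0] = vp1
            rec[irec, 1] = vp2
            rec[irec, 2] = st[16]
            rec[irec, 3] = st[17]
            rec[irec, 4] = st[18]
            rec[irec, 5] = st[19]
            rec[irec, 6] = r
            rec[irec, 7] = u
            rec[irec, 8] = Ca
            rec[irec, 9] = rho
            rec[irec, 10] = Us
            rec[irec, 11] = CA
            rec[irec, 12] = K
            rec[irec, 13] = st[26]
            rec[irec, 14] = st[28]
            rec[irec, 15] = st[30]
            rec[irec, 16] = st[0]
            ok = True
            for j in range(17):
                if not math.isfinite(rec[irec, j]):
                    ok = False
            if not ok:
                err_step = step
                return rec[:irec + 1], st, vp2_prev, err_step
            irec += 1

        if step == n_steps:
            break

        # --- Euler-Maruyama update
        for j in range(NSTATE):
            st[j] = st[j] + dt * d[j]
        if slow1_on == 1.0:
            st[16] += sigma_B1 * sqdt * xiB1
        if slow2_on == 1.0:
            st[18] += sigma_B2 * sqdt * xiB2
        # clip the bistable cubics against step overshoot
        if st[23] < 0.0:
            st[23] = 0.0
        elif st[23] > 1.0:
            st[23] = 1.0
        vp2_prev = vp2

    return rec, st, vp2_prev, err_step


@dataclass
class Protocol:
    """Experiment description: drives, pulses, noise and switches."""

    name: str = "free_run"
    duration: float = 10.0
    seed: int = 0
    record_stride: int = 10           # record every stride-th step (1 ms default)
    pulse1_time: float = -1.0         # rectangular pulse on p^(1); -1 = none
    pulse2_time: float = -1.0
    pulse1_amp: float = PULSE_AMP_DEFAULT
    pulse2_amp: float = PULSE_AMP_DEFAULT
    pulse1_width: float = PULSE_WIDTH_DEFAULT
    pulse2_width: float = PULSE_WIDTH_DEFAULT
    sigma_B1: float = 0.0             # Brownian perturbation on B^(1)
    sigma_B2: float = 0.0
    slow1_enabled: bool = True
    slow2_enabled: bool = True
    coupling_enabled: bool = True
    noise_enabled: bool = True        # stochastic p(t); False = p == p_m
    resect_time: float = math.inf     # A^(1) = 0 from this time on
    initial_state: np.ndarray | None = None
    vp2_prev0: float = 0.0

    def validate(self, check_pulses: bool = True) -> list[str]:
        out = []
        if self.duration <= 0:
            out.append("duration must be > 0")
        for nm in ("pulse1_time", "pulse2_time"):
            v = getattr(self, nm)
            if check_pulses and v >= 0 and not (0 <= v <= self.duration):
                out.append(f"{nm}={v} outside [0, duration]")
        return out


@dataclass
class TimeSeries:
    """Uniformly sampled named channels plus reproducibility metadata."""

    time: np.ndarray
    data: pd.DataFrame
    seed: int
    params_fingerprint: str
    protocol_name: str
    final_state: np.ndarray = field(repr=False, default=None)

    def __getitem__(self, channel: str) -> np.ndarray:
        return self.data[channel].to_numpy()

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "time", self.time)
        out.to_csv(path, index=False)


def fingerprint(p: ModelParams) -> str:
    blob = json.dumps(_prm._to_dict(p), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def initial_state(p: ModelParams, rho0: float = 0.0,
                  K0: float = 1.0, potentiated: bool = False) -> np.ndarray:
    """Default rest state: fast filters at their equilibrium, slow
    subsystems at their nullcline intersection, plasticity depressed (or
    fully consolidated-potentiated), GABAergic system intact."""
    st = np.zeros(NSTATE)
    pl = p.plasticity
    if potentiated:
        rho0 = 1.0
    from .fast import equilibria_at
    from .slow import b_nullcline, find_folds
    for (iB, iF, pop, kb) in ((16, 0, p.pop1, 0.0),
                              (18, 8, p.pop2, p.coupling.k_B)):
        sp = pop.slow
        b_eff = sp.b_thr - kb * (1.0 - K0)
        inter = nullcline_intersections(b_eff, sp)
        B0 = inter[len(inter) // 2]
        # an equilibrium on the middle branch is unstable: start on the right
        # branch instead so the relaxation cycle is entered deterministically
        if B0 < find_folds(sp).B_right:
            B0 = find_folds(sp).B_right + 2.0
        st[iB] = B0
        st[iB + 1] = b_nullcline(B0, sp)
        # fast filters at their (stable) equilibrium for this B: no transient
        eqs = equilibria_at(pop.fast, B0)
        st[iF:iF + 8] = eqs[0]
    st[20] = 1.0            # r
    st[21] = pl.Us_p if potentiated else pl.Us_d   # u
    st[22] = 0.0            # Ca
    st[23] = rho0
    st[24] = pl.Us_p if potentiated else pl.Us_d
    st[25] = pl.C_AMPA_p if potentiated else pl.C_AMPA_d
    st[32] = K0
    return st


def integrate(p: ModelParams, proto: Protocol) -> TimeSeries:
    """Integrate the full network under a protocol. Deterministic per seed."""
    problems = _prm.validate(p) + proto.validate()
    if problems:
        raise ValueError("; ".join(problems))
    P = _pack_params(p)
    st0 = proto.initial_state
    if st0 is None:
        st0 = initial_state(p)
    st0 = np.asarray(st0, dtype=np.float64).copy()
    n_steps = int(round(proto.duration / p.dt))
    rec, final, vp2p, err = _run(
        st0, P, n_steps, proto.record_stride, proto.seed,
        proto.pulse1_time, proto.pulse2_time, proto.pulse1_amp,
        proto.pulse2_amp, proto.pulse1_width, proto.pulse2_width,
        proto.sigma_B1, proto.sigma_B2,
        1.0 if proto.slow1_enabled else 0.0,
        1.0 if proto.slow2_enabled else 0.0,
        1.0 if proto.coupling_enabled else 0.0,
        proto.resect_time, 1.0 if proto.noise_enabled else 0.0,
        proto.vp2_prev0)
    if err >= 0:
        bad = [CHANNELS[j] for j in range(len(CHANNELS))
               if not np.isfinite(rec[-1, j])]
        raise FloatingPointError(
            f"non-finite state at step {err} (t={err * p.dt:.6g} s), "
            f"channels {bad}")
    t = np.arange(rec.shape[0]) * (p.dt * proto.record_stride)
    df = pd.DataFrame(rec, columns=CHANNELS)
    ts = TimeSeries(time=t, data=df, seed=proto.seed,
                    params_fingerprint=fingerprint(p),
                    protocol_name=proto.name, final_state=final)
    ts.vp2_prev = vp2p
    return ts


# ---------------------------------------------------------------------------
# canned protocols


_lag_cache: dict = {}


def _spike_lag(p: ModelParams, pop: int, pulse_amp: float,
               pulse_width: float) -> float:
    """Pulse-to-spike-peak lag of one population (cached per configuration)."""
    key = (fingerprint(p), pop, pulse_amp, pulse_width)
    if key not in _lag_cache:
        proto = Protocol(
            name="lag_probe", duration=2.0, noise_enabled=False,
            pulse1_time=1.0 if pop == 1 else -1.0,
            pulse2_time=1.0 if pop == 2 else -1.0,
            pulse1_amp=pulse_amp, pulse2_amp=pulse_amp,
            pulse1_width=pulse_width, pulse2_width=pulse_width,
            initial_state=initial_state(p), record_stride=1)
        ts = integrate(p, proto)
        v = ts[f"V_P{pop}"]
        _lag_cache[key] = float(ts.time[np.argmax(v)] - 1.0)
    return _lag_cache[key]


def pulse_pairing_protocol(delta_t: float, theta_d: float, theta_p: float,
                           p: ModelParams | None = None,
                           pulse1: tuple[float, float] = PULSE1_DEFAULT,
                           pulse2: tuple[float, float] = PULSE2_DEFAULT,
                           settle: float = 1.0, tail: float = 3.0,
                           full_output: bool = False):
    """Spike-pairing protocol: one elicited spike per population, the target
    population's spike offset by delta_t from synaptic coincidence.

    The primary focus receives a broad pulse (``pulse1`` = (amplitude,
    width)) shaping a single epileptic spike and its glutamate wave; the
    target receives a sharp strong pulse (``pulse2``) that pins its spike
    time. delta_t = 0 is *synaptic coincidence*: the stimulation offset
    between the populations is calibrated once (per parameter set and pulse
    shape) to the delay that maximizes the calcium transient, i.e. the
    glutamate wave and the postsynaptic depolarization fully overlap.
    Positive delta_t delays the target's spike.

    The efficacy variable starts on its separatrix (rho = 0.5) with the
    long-term state depressed ((Us, C_AMPA) at their depressed values);
    returns Delta rho = rho(end) - 0.5.
    """
    if p is None:
        p = default_params()
    p = replace(p)
    p.plasticity = replace(p.plasticity, theta_d=theta_d, theta_p=theta_p)
    offset = _pairing_offset(p, pulse1, pulse2, settle, tail)
    ts = _paired_run(p, settle + offset + delta_t, pulse1, pulse2, settle,
                     tail)
    drho = float(ts["rho"][-1] - 0.5)
    return (drho, ts) if full_output else drho


def _paired_run(p, t2, pulse1, pulse2, settle, tail):
    proto = Protocol(
        name="pulse_pairing", duration=settle + tail, seed=0,
        pulse1_time=settle, pulse2_time=t2,
        pulse1_amp=pulse1[0], pulse1_width=pulse1[1],
        pulse2_amp=pulse2[0], pulse2_width=pulse2[1],
        noise_enabled=False, sigma_B1=0.0, sigma_B2=0.0,
        initial_state=initial_state(p, rho0=0.5),
    )
    return integrate(p, proto)


_offset_cache: dict = {}


def _pairing_offset(p, pulse1, pulse2, settle=1.0, tail=3.0,
                    scan=(-0.02, 0.10, 0.005)) -> float:
    """Stimulation offset realizing synaptic coincidence (max calcium).

    The calcium transient is independent of the plasticity thresholds, so
    the calibration is shared across threshold settings.
    """
    key = (fingerprint(replace(p, plasticity=PlasticityParams())),
           pulse1, pulse2)
    if key not in _offset_cache:
        best, bc = -1.0, 0.0
        for c in np.arange(*scan):
            ts = _paired_run(p, settle + c, pulse1, pulse2, settle, tail)
            ca = float(ts["Ca"].max())
            if ca > best:
                best, bc = ca, float(c)
        _offset_cache[key] = bc
    return _offset_cache[key]


def expansion_protocol(k_B: float, k_G: float,
                       theta: tuple[float, float] = (0.3, 0.4),
                       duration: float = 500.0, seed: int = 0,
                       sigma_B: float = SIGMA_B_DEFAULT,
                       p: ModelParams | None = None,
                       potentiated: bool = True,
                       initial: np.ndarray | None = None) -> tuple[ModelParams, Protocol]:
    """Pathological-expansion run: seizing primary focus degrades the target.

    NMM1 is excitable (b_thr = 34) and seizes under B-noise; the projection
    starts from the consolidated-potentiated state reached by a prior
    physiological run (``potentiated=False`` replays that maturation from
    the depressed state instead); the pathological scalings (k_B, k_G)
    determine NMM2's degradation. Returns (params, protocol) ready for
    :func:`integrate`.
    """
    if p is None:
        p = default_params()
    p = replace(p)
    p.plasticity = replace(p.plasticity, theta_d=theta[0], theta_p=theta[1])
    p.coupling = replace(p.coupling, k_B=k_B, k_G=k_G)
    if initial is None:
        initial = initial_state(p, potentiated=potentiated)
    proto = Protocol(name=f"expansion_kB{k_B}_kG{k_G}", duration=duration,
                     seed=seed, sigma_B1=sigma_B, sigma_B2=sigma_B,
                     initial_state=initial)
    return p, proto


def matured_state(k_B: float, k_G: float, seed: int = 0,
                  duration: float = 500.0, max_extra: float = 300.0,
                  sigma_B: float = SIGMA_B_DEFAULT,
                  theta: tuple[float, float] = (0.3, 0.4)):
    """Run a pathological-expansion and return (params, quiescent end state).

    The run is extended in 20-s chunks (up to ``max_extra``) until both
    populations are interictal (B on the right nullcline branch) and the
    integrity variable has relaxed back near its degraded rest, so that a
    continuation starts from an interictal instant rather than mid-seizure.
    """
    from .slow import find_folds
    p, proto = expansion_protocol(k_B, k_G, theta=theta, duration=duration,
                                  seed=seed, sigma_B=sigma_B)
    ts = integrate(p, proto)
    st = ts.final_state
    fold1 = find_folds(p.pop1.slow).B_right
    fold2 = find_folds(p.pop2.slow).B_right
    extra = 0.0
    chunk_seed = seed + 7919
    while extra < max_extra and not (st[16] > fold1 and st[18] > fold2
                                     and st[32] > -0.05):
        cont = Protocol(name="expansion_extend", duration=20.0,
                        seed=chunk_seed, sigma_B1=sigma_B, sigma_B2=sigma_B,
                        initial_state=st)
        st = integrate(p, cont).final_state
        extra += 20.0
        chunk_seed += 1
    return p, st


def resection_protocol(from_state: np.ndarray, p: ModelParams,
                       duration: float = 300.0, seed: int = 0,
                       sigma_B: float = SIGMA_B_DEFAULT) -> TimeSeries:
    """Continue a run with the primary focus silenced (A^(1) = 0)."""
    proto = Protocol(name="resection", duration=duration, seed=seed,
                     sigma_B1=sigma_B, sigma_B2=sigma_B,
                     resect_time=0.0, initial_state=from_state)
    return integrate(p, proto)
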