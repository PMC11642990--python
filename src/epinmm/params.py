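"""Model parameter bundles, validation and (de)serialization.

The model couples two neural mass populations (NMM1, the epileptic/primary
focus, and NMM2, the initially healthy target). Each population has a fast
four-subpopulation subsystem (pyramidal P, excitatory P', dendrite-projecting
SOM and soma-projecting PV interneurons), a slow excitability subsystem for
the SOM IPSP amplitude B, and NMM2 additionally carries the plastic
glutamatergic input from NMM1 (AMPA / synaptic NMDA / extrasynaptic NMDA)
plus the GABAergic-integrity switch K.

Two published-table conventions are worth flagging because they are easy to
get wrong:

* ``tau_r`` (short-term-plasticity recovery) is listed in the literature both
  as tau_d and tau_r; a read-only ``tau_d`` alias is provided.
* ``tau_b`` is 1/30 s: the slow-IPSP rate constant is 30 s^-1 (tables that
  round to one significant figure print 0.03).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterator

__all__ = [
    "PlasticityParams",
    "FastParams",
    "SlowParams",
    "CouplingParams",
    "ModelParams",
    "default_params",
    "ictal_preset",
    "validate",
    "load_config",
    "save_config",
]


@dataclass
class PlasticityParams:
    """Calcium-controlled plasticity constants (thresholds, rates, bounds)."""

    theta_d: float = 0.1      # LTD calcium threshold
    theta_p: float = 0.4      # LTP calcium threshold
    gamma_d: float = 1.0      # depression amplitude
    gamma_p: float = 5.0      # potentiation amplitude
    beta_d: float = 80.0      # depression sigmoid slope
    beta_p: float = 80.0      # potentiation sigmoid slope
    mu: float = 1.0           # slope of the postsynaptic gate H
    V_th: float = 5.0         # depolarization threshold of H [mV]
    h_ca: float = 10.0        # calcium current scaling
    tau_r: float = 0.200      # STP recovery time constant [s]
    tau_f: float = 0.05       # STP facilitation time constant [s]
    tau_ca: float = 0.05      # calcium decay time constant [s]
    tau_rho: float = 50.0     # synaptic efficacy time constant [s]
    tau_U: float = 100.0      # presynaptic consolidation time constant [s]
    tau_CAMPA: float = 100.0  # postsynaptic consolidation time constant [s]
    Us_d: float = 0.4         # depressed release probability
    Us_p: float = 0.8         # potentiated release probability
    C_AMPA_d: float = 50.0    # depressed AMPAergic coupling strength
    C_AMPA_p: float = 100.0   # potentiated AMPAergic coupling strength
    rho_star: float = 0.5     # efficacy separatrix

    @property
    def tau_d(self) -> float:
        """Alias: the recovery constant is listed as tau_d in some tables."""
        return self.tau_r


@dataclass
class FastParams:
    """One population's fast (four-subpopulation) neural mass constants."""

    A: float = 5.0            # EPSP amplitude [mV]
    G: float = 20.0           # fast (PV) IPSP amplitude [mV]
    B_static: float = 40.0    # SOM IPSP amplitude when the slow subsystem is off [mV]
    tau_a: float = 0.01       # EPSP time constant [s]
    tau_b: float = 1.0 / 30.0  # slow (SOM) IPSP time constant [s]
    tau_g: float = 0.003      # fast (PV) IPSP time constant [s]
    C_P_Pp: float = 135.0     # P -> P'
    C_Pp_P: float = 108.0     # P' -> P
    C_SOM_P: float = 35.0     # SOM -> P
    C_PV_P: float = 200.0     # PV -> P
    C_P_SOM: float = 25.0     # P -> SOM
    C_P_PV: float = 200.0     # P -> PV
    C_SOM_PV: float = 120.0   # SOM -> PV
    p_m: float = 90.0         # mean of the stochastic drive p(t)
    p_s: float = 2.0          # standard deviation of p(t)


@dataclass
class SlowParams:
    """Slow (B, n) excitability subsystem constants."""

    p1: float = 25.0          # local maximum of the B-nullcline [mV]
    p2: float = 30.0          # inflection of the middle branch [mV]
    p3: float = 33.0          # local minimum of the B-nullcline [mV]
    m1: float = 0.0015        # left-branch stiffness
    m3: float = 0.003         # right-branch stiffness
    n_k: float = -0.2         # n-nullcline minimum
    n_p: float = 1.4          # n-nullcline sigmoid amplitude
    n_r: float = 2.0          # n-nullcline slope at the inflection
    b_thr: float = 34.0       # excitability threshold [mV]
    delta: float = 50.0       # B timescale
    epsilon: float = 0.05     # n timescale


@dataclass
class CouplingParams:
    """NMM1 -> NMM2 glutamatergic signalling and the pathological switch."""

    A_AMPA: float = 10.0      # AMPAergic EPSP amplitude [mV]
    A_NMDA: float = 2.0       # synaptic NMDAergic EPSP amplitude [mV]
    A_NMDA_ext: float = 1.0   # extrasynaptic NMDAergic EPSP amplitude [mV]
    tau_AMPA: float = 0.005   # [s]
    tau_NMDA: float = 0.02    # [s]
    tau_NMDA_ext: float = 0.04  # [s]
    C_NMDA: float = 50.0      # NMDAergic coupling (the minimal AMPAergic coupling)
    tau_K: float = 10.0       # K(t) integration time constant [s]
    k_B: float = 0.0          # GABAergic-loss scaling of the excitability threshold
    k_G: float = 0.0          # GABAergic-loss scaling of the PV IPSP amplitude
    Us_gate: float = 0.7      # release-probability threshold for extrasynaptic NMDAR


@dataclass
class PopulationParams:
    fast: FastParams = field(default_factory=FastParams)
    slow: SlowParams = field(default_factory=SlowParams)


@dataclass
class ModelParams:
    """Full parameter bundle: two populations, plasticity, coupling, integration."""

    pop1: PopulationParams = field(default_factory=PopulationParams)
    pop2: PopulationParams = field(default_factory=PopulationParams)
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    coupling: CouplingParams = field(default_factory=CouplingParams)
    dt: float = 1e-4          # integration step [s]
    duration: float = 10.0    # default simulated time [s]
    seed: int = 0


def default_params() -> ModelParams:
    """The published defaults.

    NMM1: A=5, G=20, p_m=90, b_thr=34 (interictal regime).
    NMM2: A=5, G=2, p_m=70, b_thr=44, plus the coupling constants.
    """
    p = ModelParams()
    p.pop2.fast = replace(FastParams(), G=2.0, p_m=70.0)
    p.pop2.slow = replace(SlowParams(), b_thr=44.0)
    return p


def ictal_preset() -> ModelParams:
    """NMM1 in the ictal regime: b_thr^(1) = 32, everything else default."""
    p = default_params()
    p.pop1.slow = replace(p.pop1.slow, b_thr=32.0)
    return p


def _iter_violations(p: ModelParams) -> Iterator[str]:
    pl = p.plasticity
    if not pl.gamma_p > pl.gamma_d:
        yield f"plasticity: gamma_p > gamma_d violated ({pl.gamma_p} <= {pl.gamma_d})"
    if not pl.theta_p > pl.theta_d:
        yield f"plasticity: theta_p > theta_d violated ({pl.theta_p} <= {pl.theta_d})"
    if not pl.tau_r > pl.tau_f:
        yield ("plasticity: depression dominance tau_r > tau_f violated "
               f"({pl.tau_r} <= {pl.tau_f})")
    if not pl.tau_rho < pl.tau_U:
        yield f"plasticity: tau_rho < tau_U violated ({pl.tau_rho} >= {pl.tau_U})"
    if pl.tau_U != pl.tau_CAMPA:
        yield f"plasticity: tau_U == tau_CAMPA violated ({pl.tau_U} != {pl.tau_CAMPA})"
    if not (0.0 <= pl.Us_d < pl.Us_p <= 1.0):
        yield f"plasticity: 0 <= Us_d < Us_p <= 1 violated ({pl.Us_d}, {pl.Us_p})"
    if not pl.C_AMPA_d < pl.C_AMPA_p:
        yield f"plasticity: C_AMPA_d < C_AMPA_p violated ({pl.C_AMPA_d}, {pl.C_AMPA_p})"
    for t in ("tau_r", "tau_f", "tau_ca", "tau_rho", "tau_U", "tau_CAMPA"):
        if getattr(pl, t) <= 0:
            yield f"plasticity: {t} must be > 0"

    for name, pop in (("pop1", p.pop1), ("pop2", p.pop2)):
        f = pop.fast
        for t in ("tau_a", "tau_b", "tau_g"):
            if getattr(f, t) <= 0:
                yield f"{name}.fast: {t} must be > 0"
        if not (f.tau_g < f.tau_a < f.tau_b):
            yield (f"{name}.fast: tau_g < tau_a < tau_b violated "
                   f"({f.tau_g}, {f.tau_a}, {f.tau_b})")
        for c in ("C_P_Pp", "C_Pp_P", "C_SOM_P", "C_PV_P", "C_P_SOM", "C_P_PV",
                  "C_SOM_PV"):
            if getattr(f, c) < 0:
                yield f"{name}.fast: {c} must be >= 0"
        s = pop.slow
        if not (s.p1 < s.p2 < s.p3):
            yield f"{name}.slow: p1 < p2 < p3 violated ({s.p1}, {s.p2}, {s.p3})"
        if not s.epsilon < s.delta:
            yield f"{name}.slow: epsilon < delta violated ({s.epsilon}, {s.delta})"
        if s.m1 <= 0 or s.m3 <= 0:
            yield f"{name}.slow: m1, m3 must be > 0 ({s.m1}, {s.m3})"

    c = p.coupling
    if not (c.tau_AMPA < c.tau_NMDA < c.tau_NMDA_ext):
        yield ("coupling: tau_AMPA < tau_NMDA < tau_NMDA_ext violated "
               f"({c.tau_AMPA}, {c.tau_NMDA}, {c.tau_NMDA_ext})")

    if p.dt <= 0:
        yield f"dt must be > 0 ({p.dt})"
    if p.duration < p.dt:
        yield f"duration >= dt violated ({p.duration} < {p.dt})"


def validate(p: ModelParams) -> list[str]:
    """Return a list of human-readable invariant violations (empty if valid)."""
    return list(_iter_violations(p))


# ---------------------------------------------------------------------------
# serialization

_SECTIONS = {
    "pop1.fast": FastParams, "pop1.slow": SlowParams,
    "pop2.fast": FastParams, "pop2.slow": SlowParams,
    "plasticity": PlasticityParams, "coupling": CouplingParams,
}
_SCALARS = ("dt", "duration", "seed")


def _to_dict(p: ModelParams) -> dict:
    return {
        "pop1": {"fast": asdict(p.pop1.fast), "slow": asdict(p.pop1.slow)},
        "pop2": {"fast": asdict(p.pop2.fast), "slow": asdict(p.pop2.slow)},
        "plasticity": asdict(p.plasticity),
        "coupling": asdict(p.coupling),
        "dt": p.dt, "duration": p.duration, "seed": p.seed,
    }


def save_config(p: ModelParams, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_to_dict(p), indent=2) + "\n")


class ConfigError(ValueError):
    pass


def _apply_section(obj, section: dict, where: str):
    for key, value in section.items():
        if not hasattr(obj, key):
            raise ConfigError(f"unknown key '{where}.{key}'")
        setattr(obj, key, type(getattr(obj, key))(value))


def load_config(path: str | Path) -> ModelParams:
    """Load a (possibly partial) JSON config on top of the published defaults.

    Unknown keys raise :class:`ConfigError` naming the offending key; invariant
    violations raise :class:`ConfigError` listing them.
    """
    try:
        raw = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ConfigError(f"malformed config {path}: {e}") from e
    p = default_params()
    for popname in ("pop1", "pop2"):
        sub = raw.pop(popname, {})
        if not isinstance(sub, dict):
            raise ConfigError(f"section '{popname}' must be a table")
        pop = getattr(p, popname)
        for sec in ("fast", "slow"):
            block = sub.pop(sec, {})
            _apply_section(getattr(pop, sec), block, f"{popname}.{sec}")
        for key in sub:
            raise ConfigError(f"unknown key '{popname}.{key}'")
    _apply_section(p.plasticity, raw.pop("plasticity", {}), "plasticity")
    _apply_section(p.coupling, raw.pop("coupling", {}), "coupling")
    for key, value in list(raw.items()):
        if key not in _SCALARS:
            raise ConfigError(f"unknown key '{key}'")
        setattr(p, key, type(getattr(p, key))(value))
    problems = validate(p)
    if problems:
        raise ConfigError("invalid config: " + "; ".join(problems))
    return p
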