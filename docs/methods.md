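# Methods

## Model overview

`epinmm` simulates two unidirectionally coupled neural mass populations.
Each population is a four-subpopulation hippocampal-type circuit: pyramidal
cells (P), a second excitatory pool (P′), dendrite-projecting slow
interneurons (SOM) and soma-projecting fast interneurons (PV). Every
synaptic pathway is a critically damped second-order "alpha" filter
h(t) = (W/τ) t e^(−t/τ) converting presynaptic firing rates into
postsynaptic potentials, with the wave-to-pulse sigmoid
S(v) = 5/(1 + exp(0.56(6 − v))) closing the loop. The pyramidal
polarization

    V_P = y_P′ − C_P,SOM · y_SOM − C_PV,P · y_PV + external input

is the model's proxy for the local field potential. Each postsynaptic
weight appears exactly once per loop: the P′→P weight (108) sits inside the
P′ drive, while the SOM and PV weights are applied in the V_P sum, with the
SOM rate sigmoid driven through the gain 35 and y_SOM weighted by 25 in
V_P. The slow-IPSP rate constant is b = 30 s⁻¹ (τ_b = 1/30 s). This
composition was fixed by requiring the model to reproduce its published
equilibrium continuation: with it, the upper fold pair and the upper Hopf
point of the primary focus land at B = 32.01, 50.38(5) and 32.14 —
agreement to three significant figures from independently printed values —
which pins every static gain in the P/P′/SOM loops.

### Slow excitability subsystem

The SOM IPSP amplitude B is dynamic: dB/dt = δ(n − f(B)),
dn/dt = ε(−n + σ(b_thr − B)), with f an N-shaped nullcline (stable outer
branches, unstable middle branch; local maximum near p1 = 25, local minimum
near p3 = 33 — the computed extrema for the published constants are 24.01
and 34.65) and σ a decreasing sigmoid centred on the excitability threshold
b_thr. Right-branch residence is interictal; a jump to the left branch is a
seizure (fast gamma onset at low B, tonic discharges, then return). If the
nullcline intersection lies right of the right fold the subsystem is
excitable (noise-triggered seizures); left of it, it is a relaxation
oscillator (spontaneous periodic seizures). The printed form of the
nullcline's third term suppresses the right branch; the implementation
reverses that one sigmoid so that the curve has the documented N-shape and
matches the value f(30) ≈ 0.501 implied by the published constants.

### Plasticity

The glutamatergic projection from the primary focus onto the target carries
six plastic variables. Short-term: available vesicles r and utilization u
(depression-dominated, τ_r > τ_f). Calcium enters through synaptic NMDAR,
gated by the postsynaptic depolarization via H(V) = 1/(1+exp(−(V−5))) (the
population-level magnesium block) and decays with τ_ca = 50 ms. The
efficacy ρ follows a bistable cubic (attractors ρ = 0 depressed, ρ = 1
potentiated, separatrix 0.5) plus calcium-gated potentiation/depression
rates Ω_p, Ω_d — sigmoids with thresholds θ_p > θ_d and amplitudes
γ_p = 5 > γ_d = 1. Consolidation relaxes the release probability U_s
(0.4 → 0.8) and the AMPAergic coupling C̃_AMPA (50 → 100) toward their
ρ-set targets with 100-s time constants.

### Pathological switch

Once U_s exceeds the spillover gate (0.7), an extrasynaptic NMDA channel
activates and drives the GABAergic-integrity variable K down a bistable
cubic; the drive is nonnegative, so the K ≈ 1 → K ≈ 0 transition is
irreversible. K lowers the target's excitability threshold
(b_thr − k_B(1−K)) and raises its fast IPSP amplitude (G + k_G(1−K)),
which yields gamma-band seizure onsets. Under sustained drive K
equilibrates slightly below 0 (the cubic balances the drive at K* ≈ −2c),
so the effective threshold shift transiently exceeds k_B during intense
primary-focus activity. This matters quantitatively: the static K = 0
analysis puts the spontaneous-seizure threshold at k_B = 10.21, while the
dynamic system with its negative-K excursions behaves as if the threshold
were lower.

## Numerics

* **Integration**: fixed-step Euler–Maruyama, dt = 1e-4 s, numba-compiled.
  The drives p(t) are per-step value noise N(p_m, p_s) (the drive is
  specified as a distribution, not a Wiener increment); B-perturbations are
  Brownian (σ√dt). Identical (parameters, protocol, seed) reproduce
  bit-identical trajectories. The NMDA channels' implicit dependence on
  V_P2 through H is resolved with a one-step lag (O(dt) error). ρ is
  clipped to [0,1] after each step against overshoot of the cubic.
  Halving dt changes quiescent deterministic trajectories by far less than
  1% RMS; in oscillatory regimes any explicit scheme accumulates phase
  error at events, so convergence is asserted in the quiescent regime and
  event *counts* (not waveforms) are the robust observable elsewhere.
* **Initial conditions** (unstated in the source material, chosen once):
  fast filters at their equilibrium for the initial B; slow subsystems at
  their nullcline intersection (offset to the right branch when the
  intersection is unstable, so deterministic runs enter the relaxation
  cycle); plasticity at the depressed rest (r, u, Ca, ρ, U_s, C̃) =
  (1, U_s^d, 0, 0, U_s^d, C̃^d); K = 1. Pathological-expansion runs start
  from the consolidated-potentiated state (ρ = 1, U_s = 0.8, C̃ = 100),
  i.e. from the end state of a completed physiological-plasticity episode.
* **Continuation**: pseudo-arclength with secant predictor, Newton
  corrector orthogonal to the secant, adaptive step in [1e-4, 0.1],
  analytic Jacobians. Folds are detected as branch-tangent reversals and
  refined by shrinking-step walks to the vertex; Hopf points as ±2 changes
  of the unstable-eigenvalue count refined by bisection on the critical
  pair's real part (candidates whose refined real part is not small are
  discarded as eigenvalue-structure artefacts). Equilibrium residuals are
  below 1e-8 along the branch.
* **Root finding** (reduced model): dense sign scan at 1e-3 plus bisection
  to 1e-10; the slow-regime calcium keeps H(V_P2) as a smooth factor (the
  exact quasi-steady state of the calcium balance); the hard
  V_P2-above-threshold gate is its sharp-slope limit and would quantize
  the calcium surface.

## Protocol constants (chosen once, not published values)

* **σ_B = 0.7** — Brownian perturbation on B per population. Calibrated so
  the excitable primary focus (b_thr = 34) seizes at least twice per 500 s
  in every seed (median 3–4), while a threshold one mV higher stays silent
  over 300 s in all seeds. This one constant also governs post-resection
  behaviour, since the degraded target at k_B = 10 reproduces the same
  slow-subsystem geometry as the excitable primary focus.
* **Spike-pairing pulses** — primary focus: 2500 on p(t) for 10 ms (one
  epileptic spike and its glutamate wave); target: 2000 for 5 ms (a sharp
  pulse that pins the target's spike time against the background
  AMPAergic input it receives from the primary). Each elicits exactly one
  spike in the quiescent state.
* **Pairing delay origin** — the two populations' pulse-to-spike lags
  differ (the target is less excitable), and the glutamate wave lags the
  presynaptic spike by the NMDA filter time. The delay axis of the pairing
  protocol is therefore centred at *synaptic coincidence*: the stimulation
  offset is calibrated once per configuration to the delay maximizing the
  calcium transient (calcium is independent of the plasticity thresholds,
  so one calibration serves all threshold settings). Δt then measures the
  deviation from coincidence; positive Δt delays the target's spike.
* **Event detectors** — spikes: local maxima above median + 6·MAD with a
  0.2-s refractory. Seizures: maximal intervals with B below the right
  fold minus a 1-mV hysteresis, minimum duration 2 s. Gamma band:
  30–90 Hz (the model's PV-loop resonance sits at ≈30 Hz). Response
  delays: each primary seizure pairs with the nearest subsequent target
  onset within 80 s; for maturation analyses across k_B the robust
  statistic is the latency of the target's response to the primary's
  *first* seizure (later pairings are confounded once the target develops
  its own autonomous rhythm), and it decreases monotonically with k_B.
* **Resection handover** — continuations with the primary focus silenced
  (A^(1) = 0) start from a quiescent interictal instant: the expansion run
  is extended in 20-s chunks until both populations sit on the right
  nullcline branch and K has relaxed near its degraded rest, mirroring the
  published protocol's interictal cut.

## Known limitations

* The low-B (gamma) part of the fast subsystem's bifurcation diagram —
  the PV-loop fold pair and Hopf pair — reproduces the published topology
  but not the printed positions (computed 2.79/3.82 folds and 2.01/2.82
  Hopf points versus printed 2.60/2.92 and 0.47/2.66). Inverting the
  printed positions requires a PV static gain of ≈5.8 versus the 12
  implied by the published constants; no assignment of those constants
  reaches it, so the package keeps the published table and reports the
  discrepancy rather than de-calibrating three loops that match exactly.
* The same applies to the lower tonic-window Hopf (computed 10.20 vs
  printed 9.98): it is fixed by the SOM-loop constants that reproduce
  three other printed values to <0.1%.
* The static (K = 0) spontaneous-seizure threshold computes to
  k_B = 10.21; the published description places it at 9.5, consistent with
  the dynamic negative-K excursions described above rather than with the
  static scan.
* The slow-regime calcium surface plateaus at ≈2.5 on the full (F ≤ 5)
  drive range, so a potentiation threshold of 1.5 still admits a small
  potentiated corner at extreme drive; the depressed state is the only
  attractor throughout the moderate-drive range.
* Synthetic stochasticity only: the drives are white value noise and
  Brownian B-perturbations. Real field potentials carry structured
  (1/f, rhythmic) background, so detector constants tuned here should be
  re-examined before use on experimental records.
* No GABAergic long-term plasticity, metabotropic pathways, homeostasis,
  bidirectional coupling, or conductance-based NMDA kinetics.
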