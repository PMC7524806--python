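# Methods

## The model

`camreg` simulates a single-compartment conductance-based neuron with the
eight-channel complement of crustacean pacemaker cells (A, CaS, CaT, H,
KCa, Kd, Leak, NaV; Prinz-type STG kinetics) and asks when a
calcium-sensing *master regulator* of channel expression compensates for
cell growth, and when it fails.

Membrane potential evolves in conductance-density form,

    C_m dV/dt = -Σ_i ḡ_i m_i^p h_i^q (V - E_i),

with ḡ_i in µS/mm² and C_m = 10 nF/mm², so voltage dynamics are independent
of absolute cell size at fixed densities.  Intracellular calcium follows a
thin-shell balance

    d[Ca]/dt = -φ i_Ca A / (2 F η) - ([Ca] - Ca_∞)/τ_Ca,

where i_Ca is the calcium current density (CaS and CaT only; E_Ca by the
Nernst equation at each step, 3 mM external calcium, RT/2F = 12.2 mV at
10 °C) and η is the effective volume accessible to calcium.  Under the
thin-shell assumption η scales with membrane area A, so the flux prefactor
— and hence every trajectory — is invariant under a pure size change.  The
test suite asserts this exactly (bit-identical traces under joint A, η
doubling).

Integration is exponential Euler at dt = 0.05 ms for V, all gating
variables and calcium.  The scheme is unconditionally stable here; a
10×-finer reference integration changes the reference burst period by
<2% (asserted in the suite).

### Reference model and calcium calibration

The reference conductance densities are (µS/mm²): A 379, CaS 165, CaT 2.35,
H 0.72, KCa 297, Kd 1713, Leak 0.46, NaV 1370.  Geometry defaults to
A = 0.0628 mm² with a ≈1.1 µm calcium shell (η = 6.93·10⁻⁵ mm³), which
reproduces the classic 14.96 µM/nA whole-cell flux factor of this model
lineage; τ_Ca = 200 ms, Ca_∞ = 0.05 µM.

The dimensionless flux gain φ is not constrained by any printed value and
was calibrated once, to φ = 0.5, against two qualitative anchors of the
reference model that the analysis depends on: (i) mean calcium must rise
monotonically with uniform conductance scaling across the scanned range
[0.05, 3], so the calcium level set intersects the size-change diagonal
exactly once; and (ii) the model must burst regularly.  With φ = 0.5 the
reference bursts with period ≈ 750 ms, duty cycle ≈ 0.39 and mean calcium
≈ 97 µM (quick-tier window).  At φ = 1 the calcium-versus-scale curve turns
down beyond ≈1.5× and re-crosses the target, which contradicts anchor (i);
smaller φ (≤0.1) abolishes bursting because KCa loses its calcium drive.

## Regulation model

Each channel's mRNA integrates the calcium error and conductance density
relaxes toward mRNA:

    τ_µi dµ_i/dt = Ca_target - [Ca],      τ_g dg_i/dt = µ_i - g_i,

with µ_i, g_i floored at zero and τ_µi = K / ḡ_i, which makes the model's
own conductance ratios a fixed direction of the controller: increments obey
Δg_j/Δg_i = τ_µi/τ_µj, so all regulated motion lies on the ray through the
current conductance vector (asserted to 1%, and in fact exact up to
floating-point error, in the suite).  τ_g = 5 s — deliberately fast, as in
the tradition this controller comes from, to keep simulations short.

The speed constant K only sets the overall regulation rate; the ratios
carry all of the geometry.  K = 2·10⁶ ms·µS/mm² was calibrated once for
loop stability: the calcium error in this model is O(10–100 µM), and the
resulting integral-loop crossover must sit well below 1/τ_g or the
two-stage controller oscillates and escapes (with K three orders of
magnitude smaller the loop runs away from the reference point itself).
With the default K, recovery from a 4-fold-down uniform perturbation
converges to <1% in ≈150 s of model time.

Closed-loop runs burn in the membrane for 5 s with the controller frozen,
so the integrator engages on the established limit cycle rather than on the
artificial initial condition (V = -60 mV, [Ca] = Ca_∞, gating at steady
state).

### Growth

Growth is linear in area, dA/dt = k, with η/A held constant (thin shell).
Growth perturbs the cell by *diluting* conductance densities
(dg_i/dt gains -g_i·Ȧ/A: channel number is conserved while area grows);
mRNA is not diluted.  The open-loop comparison drives absolute conductances
and area from a constant effector, dG_i/dt = r_i E, dA/dt = r_growth E —
a linear system evaluated in closed form, with the voltage model simulated
only at evaluation points.  Open-loop experiments run until area reaches
16× its initial value (growth over development is many-fold), where the
terminal density approaches the rate-ratio asymptote
g_i → g_i(0)·(r_tuned/r_growth); the reference dynamics are insensitive to
uniform scaling down to ≈0.3×, so shorter horizons would not discriminate a
5× rate mismatch.

## Trace metrics and the four states

Spikes are upward 0 mV crossings.  Bursts are delimited where an
interspike interval exceeds 3× the median ISI; burst period is the mean
inter-burst-start interval, duty cycle is mean burst duration (plus a 5 ms
spike width) over period.  A trace is *canonical* if it bursts regularly
(period CV ≤ 0.2) with period and duty cycle within 10% of the target
dynamics, *other-bursting* outside that band, *tonic-or-one-spike* when
spiking lacks multi-spike burst structure (tonic firing and one-spike
bursting are indistinguishable at the spike-train level and share a label),
and *silent* with no spikes.  Undefined metrics (fewer than three burst
starts) are reported as missing, never zero, and classification falls back
to the spike count.

## Growth-ray fixed points

Because regulation moves only along the ray, compensation reduces to a 1-D
fixed-point problem: where mean calcium (as a function of uniform scale s)
crosses the model's own target.  Scans use 30 log-spaced scales in
[0.05, 3] (scale 1 always included).  Crossings are detected with a
hysteresis band of 5% of the target — 2–3× the measured window-to-window
jitter of the 10-s calcium mean (≤1.8% across random database models) — and
refined by up to 4 bisection simulations in log-scale.  Upward crossings
are stable (negative feedback restores), downward crossings unstable.
Models whose curve only grazes the target from below legitimately have
zero stable crossings; the population statement is the census statistic,
not a per-model invariant.

## Model database (synthetic population)

Databases are generated by seeded rejection sampling: conductance vectors
drawn uniformly from the hypercube [0, 2×reference] per channel and kept
when the simulated dynamics are regular bursting with period and duty cycle
within ±20% of the reference targets.  About 36% of draws burst regularly
and ≈4% pass the similarity filter, so the desk-scale 30-model database
costs ≈750 draws (~1 minute).  Records carry the conductance vector, burst
metrics, the model's own mean calcium (its regulation target) and full
provenance (seed, draw index); save/load round-trips through CSV plus a
JSON manifest with a schema version.

What the generator emulates: a population of same-behaviour, different-
parameter bursters.  What it does not: real channel-expression
correlations, gating-kinetics variability, or any structure beyond the
similarity filter — so passing population statistics show robustness of the
*mechanism* across conductance space, not agreement with biological
expression distributions.

## Plane maps

A plane is a two-set partition of the channels; (x, y) scales each group
jointly relative to the reference, so the diagonal is a pure size change.
Three standard projections ship: calcium-fluxing channels {CaS, CaT} vs the
rest; an arbitrary split; and outward {A, KCa, Kd, Leak} vs inward
{CaS, CaT, H, NaV}.  Default extent is [0.01, 2.5]× the reference per axis.

Level sets are sampled adaptively: 25 seeded random points plus the box
corners, Delaunay triangulation, then repeated subdivision (at the
centroid) of the largest triangle whose nodes straddle the target level,
until the sample budget (140 quick tier) or a minimum-edge stop (2% of the
plane diagonal).  The level set is extracted by linear interpolation on
straddling edges.  Diagonal intersections are counted in uniform-scale
units with crossings closer than 0.2 scale units merged: where the field
gradient along the diagonal is shallow, sampling noise makes the polyline
wiggle across the diagonal around one physical crossing, and 0.2 matches
both the ray-scan resolution and the 20% bands used throughout.

Basin maps run the closed loop (no growth) from each sampled point with
the *reference* controller (its timescales and calcium target; mRNA
initialised to the local conductances) in 100-s checkpoints, stopping when
the terminal classification agrees across two successive checkpoints
(budget 500 s; still-flipping runs are labelled unconverged and excluded).
Refinement subdivides the largest triangle whose nodes disagree in label.
The robustness segmentation pairs an acute map (classification of the
unregulated model at the same points) with the basin map: robust/sensitive
(acute canonical or not) × restorative/pathological (basin canonical or
not).

## Analytic silent states

A regulated neuron can be trapped silent when a depolarised window current
through the calcium channels supplies exactly the influx that holds [Ca] at
the target.  The solver finds, under steady-state gating with [Ca] frozen
at the target: V_Ca — roots of the calcium balance (which depend only on
the calcium-channel conductances; no roots exist below a critical density,
≈9× the reference CaS+CaT at this calibration, so the silent-state analysis
scans the calcium axis up to ~15×); and V_V — roots of the total
steady-state membrane current.  Roots are bracketed on a 0.5 mV grid in
[-80, 0] mV and polished by Brent's method (xtol 10⁻¹² mV; residuals are
asserted to <10⁻⁹ relative).  The silent set is the locus where a V_V
coincides with a V_Ca (closest pairing, matching tolerance 0.05 mV,
bisection in the plane coordinate).  Marginal stability ∂V̇/∂V is reported
at each point, and each point is validated by direct simulation from
(V_V, steady gating, Ca_target): stable if V stays within ±2 mV and
spike-free for 20 s.  Along the curve the simulated stability flips exactly
once (the low-y branch is the trapped state; the upper branch escapes to a
subthreshold orbit), which the suite asserts.

## High-dimensional perturbations

Perturbations of the conductance vector are summarised by the mean and
standard deviation (N-1 denominator) of per-channel relative changes
(g-g₀)/g₀.  The sampler draws relative changes from a normal distribution,
re-standardises them to hit the requested moments exactly, and redraws any
vector that would produce a negative conductance.  Recovery experiments run
the reference controller from the perturbed model to steady state
(conductance drift <0.5% per 50-s chunk, budget 500 s) and report terminal
label and burst metrics.  σ = 0 perturbations are pure scalings —
size-change equivalents — and recover across the whole feasible mean range,
while large-σ perturbations of identical mean fail: recovery tracks the
spread, not the mean.

## Problem sizes and numerical defaults

The shipped `quick` tier (used by the tests and the acceptance script)
simulates 5 s burn-in + 10 s analysis windows, 30-model databases, 30-point
ray scans and 140-point plane budgets; the `full` tier scales these to the
full population sizes (635 models, longer windows, denser planes).  All
randomness flows through explicit integer seeds (NumPy Generator);
simulations are deterministic given (model, dt, initial state).

## Known limitations

- Single compartment, deterministic gating, no temperature dependence; one
  calcium pool serves both KCa gating and the transcription sensor.
- The quick-tier population statistics carry binomial error at n = 30; the
  compensation-quality fraction in particular is dominated by
  single-fixed-point models under the default hypercube bounds and sits
  near the top of its plausible range (see the ray-census analysis output).
- The classifier's burst detector assumes spikes cross 0 mV; strongly
  depolarised-block or plateau dynamics would need a different detector.
- Level-set and basin maps are 2-D sections of an 8-D space; the adaptive
  sampler resolves boundaries only down to its mesh-size stop.
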