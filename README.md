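# camreg

**Calcium-sensing master regulation of ion-channel expression: when does it
compensate for cell growth, and when does it fail?**

Neurons keep their electrical behaviour remarkably stable while growing
many-fold — crustacean pacemaker cells burst the same way in juveniles and
adults.  `camreg` implements, as a tested Python library plus analysis
pipeline, a biophysical account of how a *single* intracellular calcium
sensor that co-regulates the expression of *all* ion channels can achieve
this, and why the very same design is vulnerable to channel-specific
perturbations such as deletions or over-expression.

The package is aimed at computational neuroscientists studying homeostatic
regulation and degenerate ion-channel solutions.

## The model in brief

A single-compartment neuron with the eight STG-type conductances
(A, CaS, CaT, H, KCa, Kd, Leak, NaV) in conductance-density form:

    C_m dV/dt = -Σ_i ḡ_i m_i^p h_i^q (V - E_i)
    d[Ca]/dt  = -φ i_Ca A/(2Fη) - ([Ca]-Ca_∞)/τ_Ca        (thin shell: η ∝ A)

so a pure size change leaves the dynamics untouched *if* densities are
preserved.  A master regulator senses the deviation of average calcium from
a target and transcribes all channels with per-channel timescales
τ_µi ∝ 1/ḡ_i:

    τ_µi dµ_i/dt = Ca_target - [Ca],     τ_g dg_i/dt = µ_i - g_i.

This rule confines all regulated motion to the ray through the model's own
conductance vector (Δg_j/Δg_i = τ_µi/τ_µj) — exactly the direction along
which growth dilutes densities.  Whether regulation compensates a size
change therefore reduces to a one-dimensional fixed-point problem: where
mean calcium, as a function of uniform conductance scale, crosses the
target.  The same confinement makes the controller blind along the calcium
*level set* and traps it in silent states sustained by calcium window
currents — both analysed here (adaptive level-set/basin sampling; an
analytical silent-state solver).

See `docs/methods.md` for the full model, calibration and numerical
choices.

## Layout

    src/camreg/        the library (model, metrics, regulation, ray census,
                       plane sampler, silent-state solver, perturbations,
                       model database)
    analysis/          numbered drivers, one per experiment, writing tables
                       under results/
    scripts/acceptance.py   recomputes the headline population statistics
    tests/             pytest suite (unit, property and acceptance tests)
    configs/           quick (desk-scale) and full (full-scale) tiers

## Worked example

```python
from camreg import (reference_model, simulate, trace_metrics,
                    set_regulation_timescales, run_closed_loop_to_convergence)

ref = reference_model()                       # printed conductance densities
res = simulate(ref, 15_000, burn_in=5_000)    # ms of model time
tm = trace_metrics(res)
print(tm.burst_period, tm.duty_cycle, tm.mean_Ca)
# 749.6 ms   0.394   96.74 uM   -> the regulation target

start = ref.scaled(0.25)                      # 4-fold knock-down of everything
reg = set_regulation_timescales(ref, ca_target=tm.mean_Ca)
reg.mu = start.gbar.copy()
end, converged, t_model, _ = run_closed_loop_to_convergence(start, reg)
print(converged, abs(end.gbar / ref.gbar - 1).max())
# True  0.022  -> regulation restores all eight densities to within ~2%
```

Running the drivers end to end (each prints its finding and writes CSVs):

    python analysis/01_growth_compensation.py
    # closed loop k=1e-07..5e-05: terminal canonical at all four growth
    # rates (density error <2%); open loop preserves the dynamics only at
    # the tuned rate
    python analysis/02_ray_census.py --seed 1
    # census: 86.7% of 30 random bursters have 1-2 stable fixed points
    python analysis/04_silent_states.py
    # 18 analytic silent solutions; stability flips once along the curve

The numbers above are what the scripts print at the shipped quick tier:
the burst period (749.6 ms), duty cycle (0.394) and mean calcium
(96.74 µM) define the regulation set-point; the census fraction says that
for most randomly sampled bursters the calcium-versus-size curve crosses
their own target once or twice with restoring slope, i.e. growth is
compensable; the silent-set output locates the window-current trap where
compensation converges on silence instead.

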