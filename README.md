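# rwwfit

Individualized inference of regional excitation-inhibition (E-I) balance
from resting-state fMRI with biophysical whole-brain network models.

`rwwfit` simulates coupled excitatory-inhibitory neural masses (the
reduced Wong-Wang dynamic mean-field model) on a structural connectome,
converts the synaptic activity to BOLD through a Balloon-Windkessel
model, fits the model's free parameters to a subject's parcellated BOLD
by maximizing a combined static/dynamic functional-connectivity
goodness of fit with an evolution strategy (CMA-ES), and extracts
per-region E-I markers from the optimal simulation. It is aimed at
researchers who want a self-contained, CPU-only, fully deterministic
reference implementation of this pipeline — including the validation
harnesses (feedback inhibition control checks, perturbation sign tests,
ground-truth recovery, noise-seed sensitivity) — on real or synthetic
inputs.

## The model in brief

Per parcel i, input currents to the excitatory (E) and inhibitory (I)
pools:

    I_E,i = W_E + w_EE,i S_E,i + G J Σ_j C_ij S_E,j − w_IE,i S_I,i
    I_I,i = W_I + w_EI,i S_E,i − w_II S_I,i

rates r = H(I) via a sigmoidal transfer, and gating dynamics

    dS_E/dt = −S_E/τ_E + (1 − S_E) γ r_E + σν,
    dS_I/dt = −S_I/τ_I + r_I + σν.

Regional weights are parameterized by biases and coefficients on k
z-scored heterogeneity maps, w_p,i = wb_p (1 + Σ_k c_k,p M_k,i); with
k = 6 the fit has 15 free parameters (G, two biases, twelve
coefficients). w_IE is set by two-stage feedback inhibition control
(FIC) targeting ⟨r_E⟩ ≈ 3 Hz. Fit quality is

    gof = FC_corr − FC_diff − FCD_KS,

and the optimizer minimizes −gof plus soft penalties for out-of-bounds
parameters and for nodes firing outside 2-4 Hz. The regional E-I marker
is the time-averaged excitatory input current ⟨I_E,i⟩ (alternatively
⟨S_E⟩/⟨S_I⟩). See `docs/methods.md` for the full treatment.

## Worked example

Generate a synthetic subject (connectome, heterogeneity maps, and
"empirical" BOLD produced by a ground-truth forward simulation), then
simulate it and extract the E-I map:

```sh
rwwfit synth --out subj --nodes 10 --seed 1 --duration 120
rwwfit simulate --sc subj/sc.tsv --weights subj/weights.tsv \
                --g 1.2 --duration 120 --out sim
rwwfit extract-ei --state sim/state_means.tsv --out ei
```

or, through the library:

```python
>>> import rwwfit as rf
>>> from rwwfit.synth import default_theta
>>> spec = rf.SynthSpec(n_nodes=10, seed=1)
>>> conn, maps = rf.make_connectome(spec), rf.make_maps(spec)
>>> theta = default_theta(maps, seed=1)
>>> cfg = rf.SimConfig(TR=3.0, duration=120.0, burn_in=30.0, noise_seed=42)
>>> weights, fic = rf.run_fic(conn, rf.expand_regional_params(theta, maps),
...                           theta.G, cfg)
>>> fic.converged.all(), fic.trials_used
(True, 1)
>>> sim = rf.simulate(conn, weights, theta.G, cfg)
>>> sim.mean_r_E.round(2)                      # firing rates, Hz
array([3.11, 3.11, 3.11, 3.11, 3.11, 3.11, 3.11, 3.11, 3.11, 3.11])
>>> sim.mean_I_E.round(4)                      # E-I marker, nA
array([0.3775, 0.3775, 0.3775, 0.3775, 0.3775, 0.3775, 0.3775, 0.3775,
       0.3775, 0.3775])
```

All ten nodes fire near the 3 Hz balanced target and the mean excitatory
input currents sit at 0.377 nA — the FIC working point. The regional E-I
map lives in the sub-tolerance spatial structure around that working
point (at full precision `sim.mean_I_E` varies across nodes by a few
1e-5 nA here; heterogeneity, coupling and the noise realization shape
that pattern). Fitting the 15 parameters to a subject's BOLD is
`rwwfit fit --bold ... --sc ... --maps ...` (defaults: CMA-ES with
Λ = 210 particles, ≤ 80 generations, two runs; use `--lambda` /
`--generations` / `--runs` for desk-scale work), and the validation
harnesses are `rwwfit perturb`, `rwwfit recover` and
`rwwfit seed-sweep`.

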