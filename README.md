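# cardiotwin

Imaging-based cardiac digital twins of the left ventricle: which
parameters of a mechanistic heart model can actually be estimated from
a patient's LV cavity volume and regional strain — and what do the
resulting twins say about the underlying disease substrate?

`cardiotwin` is for computational cardiology researchers building
patient-specific ("digital twin", DT) instances of lumped-parameter
heart models from routine non-invasive imaging of patients with LV
mechanical discoordination (left bundle branch block, myocardial
infarction, or both). Such models expose hundreds of parameters; the
data constrain only a subset, and estimating the rest produces twins
that fit equally well but disagree between repeated optimizations. The
package implements a complete parameter-subset-reduction pipeline:

1. **Sensitivity screening** — Morris elementary effects (`mu*` =
   mean |elementary effect|) over volume, strain and strain-rate
   outputs, with leave-one-out convergence checking and bootstrap
   confidence intervals;
2. **Repeated estimation** — dynamic multi-swarm particle swarm
   optimization (60 particles in 20 swarms of 3, randomly regrouped
   every 20 iterations) of the cost

   `chi2 = (chi2_V_ED + chi2_EF + chi2_eps + chi2_epsdot) / (2 + 2 n_seg)`,

   with uncertainties `0.13·V_ED`, `0.14·EF`, 2 % strain and 20 %/s
   strain rate;
3. **Reproducibility gating** — one-way random-effects intraclass
   correlation coefficient over repeated estimations, accepting a
   subset when `ICC_min > 0.75`;
4. **Identifiability ranking** — diaphony
   `d_p = |mean exp(i 2π x_p)|` of the best Sobol samples per cost
   component, removing the least identifiable parameter groups
   (regional groups return as single global-offset parameters);
5. **Credibility indices** — segmental myocardial work from
   stress–strain loop areas, normalized work
   `W_norm,i = W_i / Σ_j W_j`, and the septal-to-lateral workload
   imbalance `ΔW_norm,LW−S = Σ_LW W_norm − Σ_S W_norm`.

A bundled phenomenological multi-segment LV forward model (prescribed
volume template + common-tension patch equilibrium, ~2 ms per cycle
evaluation) and a virtual-patient generator with LBBB-like, MI-like and
combined archetypes make the whole pipeline runnable end-to-end on a
laptop; the forward-model interface is narrow so a full closed-loop
cardiovascular model can be dropped in. See `docs/methods.md` for the
model equations, conventions and limitations.

## Worked example

Estimate cardiac output and the six regional mechanical activation
delays of a noise-free LBBB-like virtual patient, then compute the
workload imbalance of an 18-segment twin:

```python
import numpy as np
from cardiotwin import cohort, registry, forward_model, estimation, work

patient = cohort.generate_patient("LBBB-only", n_seg=6, seed=11,
                                  noise=cohort.NoiseConfig(level=0.0))
reg6 = registry.apply_segmentation(registry.build_homogeneous_registry(), 6)
subset = registry.build_estimation_subset(reg6, ["q0", "dT"])
base = forward_model.reference_parameters(reg6)
cfg = estimation.SwarmConfig(particles=24, n_swarms=8, mc_pool=150,
                             max_iter=300, repeats=3)
results = estimation.repeated_estimation(patient.measurement, subset, base,
                                         cfg, seed=1)
best = min(results, key=lambda r: r.best_chi2)
```

prints (via the surrounding `print` calls):

```
truth q0   : 60.1 mL/s
truth dT   : [  0.   17.1  39.9  68.4  91.2 114.1] ms
best chi2  : 1.72e-05 | termination: energy
est.  q0   : 60.2 mL/s
est.  dT   : [  0.   17.1  39.9  68.4  91.2 114. ] ms
dW_norm(LW-S): 1.135
```

The swarm stops on its energy criterion with a cost of ~2e-5 (a
perfect fit is 0); the recovered cardiac output and all six activation
delays match the ground truth to a fraction of a percent, confirming
these parameters are identifiable from strain + volume data. The
positive `ΔW_norm,LW−S` of the 18-segment LBBB twin quantifies the
septal-to-lateral workload imbalance expected when the lateral wall is
activated late: the septum shortens early against low tension and is
stretched during lateral contraction, wasting work. A homogeneous twin
gives exactly 0.

## Command line

`cardiotwin simulate|cohort|msm|sobol-ident|fit|reduce|work` wrap the
same library stages over CSV/JSON measurement files, e.g.

```bash
cardiotwin cohort --n-seg 6 --counts "LBBB-only:3" --noise-level 0 --out cohort/
cardiotwin fit --measurement cohort/patient_00_LBBB-only.csv \
               --names q0,dT --repeats 5 --seed 1 --out fit.json
cardiotwin reduce --measurements-dir cohort/ --out trace.csv
```

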