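# vsdkit

Analysis toolkit for NMR/EPR studies of gating-modifier toxins binding to
isolated voltage-sensing domains (VSDs) in membrane mimetics — built
around the workflow used to map the binding site of the spider toxin Hm-3
on VSD-II of the Na_V1.4 sodium channel in detergent micelles.

Studies of this kind face a common set of computational tasks, each of
which this package implements as an independent, tested module:

- **`vsdkit.labeling`** — design combinatorial selective 13C,15N labeling
  schemes for cell-free expression. Per sample, each amino-acid type is
  unlabeled (X), 15N (N), 13C' (C) or 13C,15N (D); the presence pattern of
  NH / NH+HNCO / NH+HNCA cross peaks across samples encodes residue
  identity, and `design_scheme` minimizes samples and price while
  maximizing unambiguous backbone assignment.
- **`vsdkit.perturbation`** — chemical-shift-perturbation interface maps
  from apo/bound peak lists: combined CSP
  `sqrt(ddH^2 + (0.2 ddN)^2)`, dilution-corrected intensity ratios,
  interface flags at configurable thresholds (0.015/0.08 ppm, 0.6),
  secondary-shift differences between media, HNCO-intensity mobility
  classes, hetNOE flags, SEC Stokes-radius calibration, and the
  construct↔channel (+551) numbering map.
- **`vsdkit.binding`** — the three-state fast-exchange equilibrium: toxin
  free, bound to micellar sites (one site per N_SITE = 35 detergents,
  `K_M [LM] = [L][M]`), or bound to one of two equivalent VSD sites
  (`K_V [LR] = 2 [L][R]`). Solves species exactly, fits K_V/K_M by
  profiled least squares with seeded bootstrap intervals, and converts
  constants to free energies `dG = RT ln K_d`.
- **`vsdkit.deer`** — four-pulse DEER simulation and inversion: Fresnel
  closed-form dipolar kernel, stretched-exponential background
  `exp(-k t^(D/3))` (D = 2.9), self-consistent modulation-depth/background
  refinement, non-negative Tikhonov inversion (alpha = 1000) on a
  1.5–8 nm grid, and per-peak statistics.
- **`vsdkit.posefilter`** — the six-criterion docking-pose rescoring
  filter (contact area > 250 A^2, >= 3 good contacts, hydrophobic
  complementarity > 0.4, K24/K28/R29 ionic anchor, I27 within 4 A,
  W11/F12/W16 cluster toward the membrane), plus Gromos conformational
  clustering (0.25 nm) and per-residue RMSF.
- **`vsdkit.synthetic`** — seeded generators with planted ground truth for
  every stage: sequences, peak lists, titration tables, DEER traces, and
  toy receptor/ligand poses built to pass or fail each filter criterion by
  construction.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

Fit the receptor-site dissociation constant from a titration table
(columns `VSD0_M, Hm3_0_M, Detergent0_M, reporter, dd_obs_ppm`) and invert
a DEER trace:

```python
import numpy as np
from vsdkit import binding, deer, synthetic

# synthetic receptor-detected titration at the study conditions:
# 23 uM VSD, 22 mM detergent, toxin 0-150 uM, K_M = 90 uM, K_V = 11 uM
system = binding.BindingSystem(K_M=90e-6, K_V=11e-6)
table, truth = synthetic.gen_titration(
    system, vsd0=23e-6, detergent0=22e-3,
    hm3_totals=np.linspace(0, 150e-6, 12),
)
fit = binding.fit_KV(table, binding.BindingSystem(K_M=90e-6))
print(f"K_V = {fit.K * 1e6:.1f} uM")
print(f"dG  = {binding.delta_G(fit.K, T=318.15):.1f} kcal/mol")

# 6-us DEER trace from a folded/unfolded two-state mixture
trace, _ = synthetic.gen_deer(
    [4.2, 6.4], [0.7, 0.5], lam=0.03,
    t_ns=np.arange(0.0, 6001.0, 6.0),
)
dist, form, peaks = deer.analyze_trace(trace, alpha=1000.0, dimension=2.9)
print(f"lambda = {form.lam:.4f}")
for p in peaks:
    print(f"peak: {p['mean_nm']:.2f} +- {p['sd_nm']:.2f} nm "
          f"({p['fraction']:.0%})")
```

prints

```
K_V = 11.0 uM
dG  = -7.2 kcal/mol
lambda = 0.0301
peak: 4.18 +- 0.71 nm (48%)
peak: 6.41 +- 0.54 nm (52%)
```

The fitted K_V recovers the planted constant; -7.2 kcal/mol is the
corresponding binding free energy at 45 C (1 M standard state). The DEER
inversion recovers the modulation depth (3%), both distance-peak means
within one grid step (0.02 nm), and the ~1:1 population of the folded
(4.2 nm) and partially unfolded (6.4 nm) conformations.

A command-line interface mirrors the library
(`vsdkit design-labels | csp-map | fit-binding | deer-sim | deer-fit |
filter-poses | simulate-complex | simulate-titration`), e.g.

```sh
vsdkit fit-binding --table titration.csv --km 9e-5 --nsite 35 --temp-c 45
vsdkit deer-fit --trace trace.dat --alpha 1000 --dim 2.9
```

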