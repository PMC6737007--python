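# Methods

`vsdkit` re-implements, as a tested pipeline, the computational workflow
used to characterize how a spider gating-modifier toxin binds the isolated
second voltage-sensing domain (VSD-II) of the skeletal-muscle sodium
channel Na_V1.4 solubilized in detergent micelles. The five analysis
stages are independent; each is paired with a seeded synthetic generator
that plants a known truth, so the whole pipeline is testable without any
experimental download. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic data do and do not
establish.

## Combinatorial selective labeling (`vsdkit.labeling`)

Each sample assigns one of four labeling types per amino-acid *type*:
unlabeled (X), 15N (N), 13C' (C), or 13C,15N (D). A residue's cross peak
in a 2D 1H,15N-TROSY exists iff it is 15N-labeled and not proline; the 2D
planes of HNCO/HNCA light up iff the *preceding* residue carries 13C'
and/or 13CA. The per-sample symbol is 0 (no NH), 1 (NH only), 2 (NH+HNCO),
3 (NH+HNCA), 4 (NH+both); a residue is assigned when its symbol vector is
visible and unique along the sequence. Coverage is counted over non-proline
residues.

Choices worth noting:

- Only the *sequential* HNCA connectivity enters the code. A real HNCA also
  shows residue *i*'s own CA peak, but intra vs sequential peaks are told
  apart by their CA shift, not by presence, so they add no presence-code
  information.
- Residue 1 carries NH-only information (no predecessor); an N-terminal
  formyl-Met is treated as a normal residue.
- `design_scheme` searches sample counts 1..max; per count it enumerates all
  per-type token vectors exactly while the scheme space is below a
  configurable bound (3x10^5 by default), otherwise a greedy heuristic adds
  one sample at a time, choosing per-type tokens that maximize coverage
  (cheapest token on ties). Ties overall break by total price, then by
  lexicographic order of the token matrix, making the output deterministic.
- Peak overlap/degeneracy in crowded spectra is not modeled: codes assume
  resolvable peaks. Real coverage will be lower than predicted.
- An upper bound used for early stopping: residues whose
  (previous, current) type pair repeats in the sequence are never
  assignable under any scheme, because the code is a function of the type
  pair only.

## Perturbation mapping (`vsdkit.perturbation`)

Combined CSP is the standard weighted-Euclidean form
`sqrt(ddH^2 + (0.2 ddN)^2)` — the source study never prints its
combination formula, so the field's default is adopted with the 15N weight
exposed (`alpha_n`; rationale: the 15N shift dispersion is ~5x 1H).
Intensity ratios are corrected by the dilution factor (C_after/C_before)
before comparison with the 0.6 broadening threshold. Interface flags use
CSP >= threshold OR ratio <= threshold, with 0.015 ppm (ligand-observed)
and 0.08 ppm (receptor-observed) as the conventional levels; inequalities
at thresholds follow the quoted strict forms where stated (hetNOE < 0.6,
HNCO intensity > 2x mean / < 0.5x mean on the raw scale — any log axis is
display only). Unmatched residues are excluded from statistics and counted.
SEC calibration regresses log10(Stokes radius) on elution volume over >= 2
standards (built-in radii: ferritin 6.10 nm, catalase 5.22, aldolase 4.81,
BSA 3.55, ovalbumin 3.05). Construct-to-channel numbering adds 551.

## Binding equilibrium (`vsdkit.binding`)

Three-state fast exchange: ligand free / on a micellar site / on the
receptor, with Langmuir bookkeeping `[site]_0 = [detergent]_0 / N_SITE`
(N_SITE = 35) and equilibria

    K_M [LM] = [L][M],     K_V [LR] = 2 [L][R],

the factor 2 being the statistical factor for two equivalent receptor
sites with single occupancy modeled. Two deliberate simplifications:
detergent consumed by receptor-bearing micelles is not subtracted from the
site pool (detergent is in >= 190-fold excess over ligand in the
experiments this describes), and doubly-occupied receptors are not modeled
(the dissociation-side statistical factor is likewise omitted, matching
the printed form of the equilibrium). The two receptor sites
(extracellular/cytoplasmic) are fitted independently per reporter-residue
group; a shared-K_V fit across reporters is what `fit_KV` does when given
several reporters at once.

Numerics: the ligand mass balance is a strictly increasing scalar function
of the free-ligand concentration on [0, L0]; Brent's method (a safeguarded
bracketing root-finder) solves it to machine precision, and both
equilibrium relations then hold exactly by construction. Fitting profiles
out the per-reporter limiting shift dd_max linearly, leaving a 1-D search
over log10 K; a deterministic log-spaced multi-start guards the scalar
minimization. Uncertainty comes from a seeded residual bootstrap
(percentile 95% interval). A flat response is flagged as non-identifiable
rather than raised. Free energies use dG = RT ln(K_d/c0) with c0 = 1 M,
R = 1.987204e-3 kcal/(mol K), T = 318.15 K by default (45 C, the
measurement temperature); the printed -7.2/-7.5 kcal/mol values are
consistent with this standard state.

## DEER analysis (`vsdkit.deer`)

Kernel: the orientation-averaged dipolar kernel with the nitroxide
constant 52.04 MHz nm^3 (g ~ 2), evaluated by the Fresnel-integral closed
form and cross-checked against quadrature in the tests. Background: a
stretched exponential `exp(-k t^(D/3))` with fractal dimension D = 2.9 by
default (the empirical value for micellar samples; D = 3 is the plain 3D
exponential). Traces: `V = B (1 - lambda (1 - S))` with modulation depth
lambda.

Inversion solves non-negative Tikhonov least squares with a
second-difference roughness operator, `alpha = 1000` by default — the
regularization level the reference analyses of such samples use; the
convention here is `alpha ||L2 P||^2` with the kernel columns carrying the
trapezoidal dr weights. Two or a few grid points at each end of the
distance grid (1.5-8.0 nm, 0.02 nm step, covering the detectable 2-7 nm
range) are pinned to zero.

Background estimation is the delicate step. The plain tail fit
(`background_correct`, window = last half by default) is unbiased only
when all dipolar oscillations have decayed inside the window; a 6.4 nm
component oscillates with a ~5 us period, so a 6 us trace never satisfies
that. `refine_background` therefore refits (lambda, k) jointly with D
fixed: each candidate pair is scored by the data misfit of the re-projected
signal after an edge-pinned inversion, and Nelder-Mead polishes the pair
(subsampled grid first, full grid last). The edge pinning is what makes
this search identifiable — with a free boundary, a wrong lambda leaves a
constant long-time offset that the inversion can absorb as probability
mass piled at the top of the r grid (the kernel tends to 1 as r grows).
Excitation-bandwidth and orientation-selection effects are not modeled.

Peak statistics segment P(r) at the local minima between modes (relative
prominence 0.02) and report per-segment mass fractions. Means and widths
come from a joint Gaussian-mixture fit (one component per segment) rather
than truncated segment moments: cutting two overlapping Gaussians at their
shared minimum biases the truncated means toward each other by several
grid steps even on the *exact* distribution, which the joint fit undoes;
plain moments remain available (`refine=False`) and are the fallback
whenever the fit degenerates (e.g. a uniform P).

## Pose rescoring (`vsdkit.posefilter`)

The six criteria: buried contact area > 250 A^2, >= 3 good contacts,
hydrophobic complementarity > 0.4, an ionic anchor from toxin K24/K28/R29
to a receptor Asp/Glu, toxin I27 within 4 A of the receptor (strict), and
the W11/F12/W16 cluster pointing within 60 deg of the inward membrane
normal. Survivors must pass all six. The thresholds are the published
ones; the geometric cutoffs behind "good contacts" are standard literature
values, not printed in the source study, and all live in `FilterConfig`:
H-bond donor-acceptor <= 3.5 A with antecedent angle >= 120 deg (a missing
antecedent passes the angle check, accepting reduced models), ionic
Lys/Arg nitrogen to carboxylate oxygen <= 4.0 A, stacking ring centroids
<= 5.5 A with inter-plane angle <= 30 deg or 60-120 deg.

Contact area is (SASA_R + SASA_L - SASA_RL)/2 by Shrake-Rupley (probe
1.4 A, 960 points/atom, single-atom vdW radii); whether the published
area is this half-buried quantity or the full buried area cannot be
settled without the undeposited structures — the /2 convention is used
throughout. Complementarity approximates the cited
molecular-hydrophobicity-potential method by sign agreement: at midpoints
of inter-partner atom pairs within 5 A, each partner's MHP is the
exp(-d/2 A)-decayed sum of crude atomic constants (carbons positive,
N/O negative, charged groups strongly negative), and the score is the
mean product of signs in [-1, 1]. This is a deliberate simplification of
full MHP surface maps; its sign behavior, not its absolute scale, is what
the criterion uses. The membrane frame is a planar slab by default
(outward normal, boundary offset) with an optional micelle-sphere mode
(24 A radius). Docking scores are accepted as pass-through annotation and
never recomputed.

Ensembles: Gromos (Daura) clustering with pairwise Kabsch-superposed RMSD
and a 0.25 nm cutoff, most-neighbors center selection with lowest-index
tie-break; RMSF iteratively superposes frames on the running mean and
averages per-atom fluctuations per residue (reported in nm). With CA
selection and 500 frames of isotropic jitter sigma the expected value is
sigma*sqrt(3) minus the ~6/(3N) variance fraction the superposition
absorbs.

## Synthetic data (`vsdkit.synthetic`)

All generators are pure functions of (parameters, seed) and write their
planted truth as JSON. Defaults follow the study conditions: titrations
use 23 uM receptor, 22 mM detergent, ligand 0-150 uM (12 points), K_M =
90 uM, K_V = 11 uM; DEER uses 6 us traces at the experimental 6 ns
increment, lambda = 0.03, D = 2.9 with k = 8e-5 ns^-D/3 (chosen once so
the background decays by ~30% over the trace, a typical depth), and the
two-state folded/unfolded mixture 4.2 +- 0.7 / 6.4 +- 0.5 nm at equal
weight. Peak lists draw per-type amide shifts from a small built-in
random-coil-like table (no database access); "bound" lists shift planted
residues and scale broadened intensities by 0.3.

The toy complex favors testability over realism: an ideal four-helix
bundle (1.5 A rise, 100 deg/turn) with a leucine canopy and a Glu/Asp/Glu
trio on the extracellular face, and a two-layer hairpin stand-in whose
named side chains are placed directly at their targets (no rotamer
sampling). Each filter criterion maps to an independent geometric dial:
bulk-face composition (complementarity), engaged anchor count (good
contacts/anchor), side-chain extension vs retraction (proximity, and
contact area via lifting the body while leaving engaged chains in place),
and ring placement (orientation). In this construction "contact area fails
while the ionic anchor passes" is feasible — the lifted body keeps long
Lys/Arg chains in ionic range while burying well under 250 A^2; the
genuinely infeasible requests are those demanding a contact-dependent
criterion pass with no interface at all, and those raise
`InfeasibleToggleError`. Passing the planted-pose tests therefore shows
the filter implements its stated geometry, not that it would rank real
docking decoys the way the original rescoring did.

What the synthetic data do not emulate: peak overlap and assignment
transfer errors, exchange-regime departures from fast exchange, DEER
orientation selection and noise correlations, and force-field-quality
structures. Conclusions about real data rest on the correctness of the
implemented formulas, which is what the oracle tests (quadrature kernel,
grid-search equilibrium, closed-form quadratic, brute-force scheme
enumeration, analytic two-sphere burial) establish.

## Problem sizes

Tests and the acceptance script run at the study's own scales: 12-point
titrations, 6 us / 1001-point DEER traces on a 326-point distance grid,
toy sequences of up to ~80 residues for labeling design (exact enumeration
is exercised on <= 4 types x 2 samples, where the brute-force oracle is
tractable), and 12-pose filter suites of ~900-atom complexes. The
bootstrap-coverage study uses 50 replicates of 150 resamples.
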