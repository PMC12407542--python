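# Methods

## Model and assumptions

The package treats RAF activation as a closed thermodynamic equilibrium —
no kinetics, no time courses, no transcriptional feedback. The species
network per RAF protomer is:

* open monomer **M**: can dimerize and bind drug;
* autoinhibited monomer **A** = K_A·M: can do neither (the kinase domain is
  clamped by the N-terminus); a drug-bound protomer must release drug
  before re-entering this state, so there is no drug-bound autoinhibited
  species;
* drug-bound monomer **Md** = M·d/K_d;
* dimers **D00, D01, D11** with 0/1/2 drug-bound protomers:
  D00 = M²/K_dim, D01 = 2·M·Md/K_dim, D11 = Md²/K_dim. The factor 2 on D01
  is the statistical count of the two orientations; both dimer sites bind
  drug with the monomer's K_d (no cooperativity across the dimer interface —
  a deliberate simplification, flagged for users, since some earlier PA
  models assume negative cooperativity);
* 14-3-3 complexes: **AS** = A·s/K_Smon (CAS role) and
  **DxyS** = Dxy·s/K_Sdim (DS role). 14-3-3 is dimeric and engages two
  phosphoserines as one unit, so it is counted in dimer units and each
  complex is either unengaged or fully engaged — no singly-bound
  intermediates.

RAS-GTP is implicitly required and not a species; MEK/ERK are not modeled.
"Active RAF" is every drug-free protomer inside a dimer, 14-3-3-clamped or
not (the DS-clamped dimer signals — this is what makes DS raise baseline
signaling).

Model variants enable subsets of the 14-3-3 couplings: CA (none), CAS
(monomer only), DS (dimer only), CAS_DS (both).

## Parameters

All concentrations in µM; all dissociation constants strictly positive.

| parameter | meaning | default |
|---|---|---|
| K_A | [autoinhibited]/[open], dimensionless | 10 |
| K_d | drug–protomer dissociation | 0.1 µM |
| K_dim | RAF dimerization | 0.1 µM |
| K_Smon | 14-3-3 dimer / autoinhibited monomer (CAS) | 0.2 µM |
| K_Sdim | 14-3-3 dimer / RAF dimer (DS) | 0.02 µM |
| R_total | total RAF protomer | 0.04 µM |
| S_total | total 14-3-3 (dimer units) | 1.0 µM |
| D_total | total drug | varies |

The defaults are the reference set used for every descriptive figure and
metric. The meta-parameter α trades the two 14-3-3 roles against each
other: K_Sdim → α·K_Sdim, K_Smon → K_Smon/α, so small α favors DS and large
α favors CAS; α = 1 is the identity.

## Solvers

**Mass-action oracle.** `solve_free_clamped` fixes free drug and free
14-3-3 and solves RAF conservation, a quadratic in M, via the numerically
stable root M = 2R/(c₁+√(c₁²+4c₂R)). `solve_totals` additionally enforces
drug and 14-3-3 conservation by nested bracketed root-finding (Brent's
method — bracketed bisection with secant/inverse-quadratic refinement —
at machine-precision tolerances): free drug on [0, D_total] outside, free
14-3-3 on [0, S_total] inside, the monomer in closed form innermost. Both
brackets are valid because each residual is negative at zero and
non-negative at the total; solutions are accepted only if all three
conservation sums close to 1e-10 relative (they close to ~1e-15 in
practice). Detailed balance is audited by comparing composite association
constants measured from a solved state against the values the parameter
constants require along an alternative assembly order (drug-then-dimerize
vs dimerize-then-drug, and likewise for 14-3-3 engagement); every product
must be 1 to floating-point roundoff.

**Closed forms.** Every variant's baseline and dosed active fraction
collapses to one two-parameter family (see README). The expressions were
re-derived from the species relations and conservation — the test suite
contains a symbolic (sympy) proof that the closed form solves the
conservation polynomial and that the PA inequality's boundary is exactly
the zero-initial-slope locus. The closed forms are evaluated in
cancellation-free arrangements (e.g. F/((√(E²+F)+E)²(1+d_rel))) and agree
with the oracle to ~1e-15 relative.

**14-3-3 convention.** The closed forms are functions of *free* 14-3-3.
Under the excess assumption (unbound 14-3-3 ≫ unbound RAF) free and total
coincide; `effective_s_free` exposes both conventions rather than hiding
the choice, and free-drug dose responses default to clamping free 14-3-3
at S_total. The CAS coupling necessarily enters through K_Smon (S_rel), the
DS coupling through K_Sdim (s_rel); the conserved-totals oracle makes no
excess assumption at all.

## PA observables and numerics

A dose-response curve is active RAF over a strictly increasing dose grid
with dose 0 prepended; the default grid is 121 log-spaced points over
1e-4…1e2 µM. Total-drug mode (the figure convention) solves full
conservation per dose; free-drug mode clamps free drug (and free 14-3-3).

* **PA detection**: the peak must exceed baseline by a relative 1e-9 —
  the curve is tangent to baseline at zero dose, so exact comparison would
  be noise-dominated.
* **Fold change**: grid argmax refined by bounded Brent search in log-dose
  between the argmax's grid neighbours, making the reported maximum
  grid-independent to ~1e-6 relative. If the argmax falls on the top grid
  edge the search window expands upward by decades until the curve turns
  over, so extreme parameter regimes (e.g. deep α limits) are handled.
* **Crossover dose (PA range)**: the unique dose above the peak where
  activity returns to baseline. The lower end of the PA interval is 0⁺
  whenever PA occurs, so this scalar is the whole story. Because the tail
  decays at least as fast as 1/dose, the bracket's upper guess starts at
  peak_dose × fold change and expands by ×10 (a ×1e10 expansion without a
  sign change raises a defect error); the root is then bisected in
  log-dose to ~1e-12.
* **Sweeps**: any two of the parameter fields (or α) on log-spaced axes;
  metrics are baseline %, max %, fold change, crossover dose (NaN where no
  PA). Sweep cells in free-drug mode clamp free 14-3-3 at the cell's
  S_total.

PA-condition margins are oriented so positive always predicts PA:
bound − RAF_rel for the RAF_rel-bounded variants, K_A − bound for the
CAS+DS form (whose bound is on K_A). The printed bound directions — CAS
relaxing, DS tightening with 14-3-3 — hold exactly where the bounds are
positive, i.e. where effective autoinhibition exceeds 1; where a bound is
negative PA is impossible outright and the direction claim is vacuous.
The footnoted limits (excess 14-3-3; free 14-3-3 unperturbed by drug) are
carried on each result as `limit_note`.

The α-limit recovery of the single-role models is verified deep in the
limits (α = 1e±6): at moderate α (e.g. 1e3) the disabled coupling's
dimensionless group is still O(1) at the top of the 14-3-3 axis, so only
the deep limit can agree to 1%.

## Synthetic readout

The generator emulates densitometry-style quantification (pERK/total ERK)
of a model curve: a strictly increasing, saturable Hill link
v_max·aʰ/(aʰ+k_halfʰ) with multiplicative lognormal noise of unit mean and
stated CV (positive, right-skewed ratios; no quantitative noise model of
real blots exists, so the CV is a labeled convention, default 0.1).
Triplicates mirror typical independent-experiment counts; a fixed seed
gives byte-identical output.

What it does *not* emulate: blot-to-blot normalization artifacts, antibody
nonlinearity beyond the Hill shape, correlated within-blot noise, or any
feedback acting on the readout. Passing calibration tests therefore shows
the estimator recovers curve observables through a saturating monotone
link under idealized noise — not that it would survive every real-blot
pathology.

The estimator takes per-dose replicate means; PA range is the last dose
whose mean exceeds the dose-0 mean, log-interpolated to the recrossing
(censored estimates report the top grid dose); fold change is the ratio of
means. Uncertainty is a plain percentile bootstrap (no BCa) over
within-dose replicate resampling. Because the crossover depends only on
order relations among means, it is invariant to any strictly increasing
link — saturation compresses the measured fold change but leaves the
range estimate intact, which is why range is the robust observable for
saturable readouts.

**Known limitation — small-sample coverage.** With triplicates the
percentile bootstrap undercovers: measured coverage of the 95% crossover
interval is ≈ 0.81–0.82 at CV = 0.1 (it rises to ≈ 0.89 at 6 and ≈ 0.93 at
12 replicates). This is the textbook small-n behaviour of the percentile
method, not an implementation defect; misses are two-sided, and
experiment-level resampling is worse. Users wanting calibrated intervals
at n = 3 should increase replicates or use a studentized scheme.

## Problem sizes

Default figure and verification sizes — 121-dose grids, 11×11 sweep
grids, 500 random parameter draws per variant for closed-form/oracle
verification, 20×20 condition-agreement grids, 200 simulated experiments ×
2000 bootstrap draws for calibration — run in seconds on one CPU; they are
the package's reporting defaults and can all be raised via function
arguments or CLI flags.
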