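# Methods

`linamp` models how DNA copy-number amplification of a negative-feedback
("linearizer") synthetic gene circuit raises protein expression — the
mechanism by which engineered CHO cells evolve drug resistance — and
implements the companion computational tools: a triplex-forming
oligonucleotide (TFO) target-site scanner for designing
amplification-specific countermeasures, and the quantification formulas for
the viability, dose-response and qPCR assays used to characterize such
cell populations.

## The circuit model

### Reaction scheme

The circuit couples the humanized tetracycline repressor (hTetR, here
`TetR`) to its own two-operator promoter.  A single transcript encodes both
TetR and the eGFP reporter (separated in the cell by P2A cleavage), so eGFP
also proxies the co-expressed resistance gene.  Doxycycline (Dox) enters
the cell, sequesters TetR and thereby tunes expression.

Species (molecule counts per cell): intracellular Dox; promoter copies with
0, 1 or 2 operators occupied (`D_free`, `D_R1`, `D_R2`); the shared mRNA;
free TetR; the TetR:Dox complex; eGFP.  The mass-action reactions, grouped
into 14 families (17 elementary reactions, since the three binding steps
are reversible):

| family | reaction | rate |
|---|---|---|
| Dox influx | ∅ → Dox | `f · dox_ext` |
| Dox clearance | Dox → ∅ | `g_dox` |
| sequestration | TetR + Dox ⇌ TetR:Dox | `k_seq_on` / `k_seq_off` |
| operator binding 1 | D_free + TetR ⇌ D_R1 | `2r` / `k_off` |
| operator binding 2 | D_R1 + TetR ⇌ D_R2 | `r` / `2·k_off` |
| transcription | D_free → D_free + mRNA | `m` |
| leak (singly bound) | D_R1 → D_R1 + mRNA | `leak_r1 · m` |
| leak (doubly bound) | D_R2 → D_R2 + mRNA | `leak_r2 · m` |
| translation | mRNA → mRNA + TetR (or + eGFP) | `k_tl_tetr`, `k_tl_gfp` |
| decay | mRNA, TetR, eGFP, TetR:Dox → ∅ | `d_m`, `d_tetr`, `d_gfp`, `d_complex` |

Modeling assumptions, chosen where the scheme was genuinely open:

* **1:1 Dox–TetR sequestration.** TetR is treated as one active unit; the
  dimerization detail is unobservable at the level of a simplified scheme.
* **Statistical factors 2r / 2·k_off** on the binding ladder, because the
  two operator sites are identical.
* **Extracellular Dox is an infinite reservoir**: influx is a zeroth-order
  source `f · dox_ext` (medium volume ≫ cell volume), with `dox_ext` in
  ng/mL so doses are stated in assay units.
* **One shared mRNA** with separate translation and decay for the two
  proteins; the resistance gene is not modeled separately — eGFP is its
  proxy, as in the experimental readouts.
* **Copy number scales only the promoter count**: all `n` templates start
  unbound, and no auxiliary polymerase species is tracked separately since
  it would co-scale with the template.
* Promoter conservation `D_free + D_R1 + D_R2 = n` holds exactly in the
  stochastic simulator and structurally (zero column sums of the
  stoichiometry matrix) in the rate equations.

### Why amplification raises expression

Self-repression makes the circuit approximately homeostatic in its
repressor: amplifying the template raises TetR, which drives a *larger
fraction* of promoters into the doubly bound state.  Transcription then
comes increasingly from the `leak_r1`/`leak_r2` terms of the amplified,
repressed templates, so total mRNA — and every protein translated from it —
still rises with copy number.  The `copy_number_sweep` operation exposes
this directly: expression and the doubly-bound fraction rise together.
Ablating the leak (`leak_r1 = leak_r2 = 0`, strong binding) caps the rise,
which is the model's internal control for the mechanism.  Setting the
binding rate `r = 0` reproduces the repressor-dead mutant: maximal, fully
Dox-independent expression equal to the closed form
`n·m·k_tl_gfp/(d_m·d_gfp)`.

### Default calibration

The exact rate values behind the original simulations are not published in
machine-readable form, so the defaults in
`src/linamp/data/default_params.yaml` are the package's own calibration,
chosen once so that (i) the wild-type dose response is monotone and
approximately linear (R² ≈ 0.995) over 0–0.1 ng/mL Dox, the designed
behavior of linearizer circuits; (ii) the 1→15 copy sweep at 0.05 ng/mL
raises eGFP ≈ 3.4-fold while the doubly repressed fraction climbs from
≈ 0.46 to ≈ 0.87; and (iii) molecule counts stay in the tens-to-hundreds so
stochastic simulation is fast and its fluctuations realistic.  Operator
kinetics use a fast-flicker regime (`r = 5 /molecule/h`, `k_off = 50 /h`,
dissociation constant 10 molecules): equilibrium occupancies are identical
to slower kinetics with the same ratio, but promoter-state fluctuations
time-average over the mRNA lifetime, which keeps the stochastic stationary
means close to the deterministic steady state (≈ 0.3–0.8 % at n = 2) — a
property the test suite checks at 3 standard errors.  Linearity of the dose
response comes from near-stoichiometric Dox capture: `k_seq_on·TetR ≫
g_dox` and small `k_seq_off`, so the rate of repressor inactivation tracks
the influx `f·dox_ext` linearly.

### Numerics

* **Deterministic**: `scipy.solve_ivp` (LSODA), default `rtol 1e-8` /
  `atol 1e-10`.  Steady state is declared when
  `max |dx/dt| / (1 + |x|) < 1e-6`; `find_steady_state` integrates in
  doubling time chunks and then polishes with a Powell-hybrid root find on
  the reduced system (with `D_free` eliminated through conservation), so
  the reported fixed point satisfies the rate equations to root-finder
  precision.  The test suite cross-checks it against an independently
  written algebraic solve at 1e-6 relative.
* **Stochastic**: exact direct-method kinetic Monte Carlo on integer
  counts, numba-compiled when numba is importable (the same function runs
  uncompiled otherwise).  An explicit seed is required; there is no hidden
  global randomness in the API.  The kernel uses the NumPy legacy seeding
  interface internally because the compiled path maintains its own RNG
  state.
* **Dox-influx fit** (`fit_dox_influx`): for each candidate `f` the
  arbitrary-units scale has a closed-form least-squares solution, leaving a
  smooth one-dimensional problem in `log f` solved by bounded scalar
  minimization — deterministic, no starting-point sensitivity.  A fit is
  flagged unconverged when the residual is large relative to the observed
  dose-to-dose variation, so dose-independent data (which the wild-type
  model cannot produce) are rejected rather than force-fitted.
* **IC50 fit**: four-parameter log-logistic
  `y = bottom + (top−bottom)/(1+(x/IC50)^hill)`, least squares from a
  deterministic multi-start grid (7 geometric IC50 starts spanning the
  dosed range × Hill slopes {0.5, 1, 2}); lowest SSE wins.  Because the
  grid derives from the dose values, the fit is equivariant under rescaling
  concentrations.  Flat responses return `converged=False` instead of an
  arbitrary IC50.
* Degenerate inputs: `copy_number = 0` is a valid (empty) system;
  promoter fractions for `n = 0` raise; zero total propensity freezes the
  stochastic trajectory.

## TFO target-site scanner

A TFO target is a maximal purine tract: a substring that starts and ends
with a purine (A/G) on its strand, tolerates *isolated* single-pyrimidine
interruptions, and is terminated on both sides by two consecutive
pyrimidines, an `N`, or the sequence boundary.  The scanner is a linear
greedy pass; greediness makes every emitted run maximal (not contained in
any other qualifying substring).  Both strands can be scanned, with
minus-strand hits mapped back to plus-strand coordinates.  The test suite
proves the scanner equal to an exhaustive O(L²) substring enumeration on
thousands of random sequences, including `N`-containing ones.

Design choices: coordinates are 0-based half-open with BED6 output;
`min_length` defaults to 15 (a conservative floor below typical TFO
lengths — the choice is configurable since only "longest stretches" is
specified by the underlying method); `N` terminates runs (conservative);
ranking is by length, then purine fraction, then leftmost start, then
sequence id — a total, deterministic order.

Oligo derivation conventions (the exact motif used for the original
synthesized oligos is not published with the sequences, so all three are
exposed): `antiparallel-GA` (default) — the reverse of the purine-strand
site with `T` placeholders at tolerated gaps; `parallel-CT` — the
pyrimidine motif parallel to the purine strand; `purine-strand` — the raw
site sequence.  Combos mix the top-k candidates at equal ratios (1:1:1 or
1:1:1:1), with the 3'-amino modification recorded as manifest metadata.

## Assay quantification

Pure-function implementations of the standard formulas: alamarBlue
reduction score `S = O2·A570 − O1·A600` (extinction coefficients are
config values from the reagent protocol, not baked-in constants); relative
growth as mean-test over mean-control fold change (per-plate pairing can be
had by calling it per plate; mean-of-replicates is the default
interpretation); fluorescence viability ratio
`R = (test−blank)/(control−blank)`; relative copy number `E^(−ΔΔCt)` with
per-gene efficiency defaulting to 2.0, anchored to real copies per genome
through a reference gene of known copy number (Vinculin, 2 per diploid
genome, configurable); and the mCherry/BFP ratio per BFP-positive cell as
an inverse readout of free active repressor (BFP positivity: explicit
threshold, else the 99th percentile of an untransfected control, else a
fixed floor).

## Synthetic data

The generators emulate the *structure* of the study's measurements with
planted truth: sequences whose only qualifying purine tracts are the
planted ones (rejection-checked against the scanner), lognormal
fluorescence populations moment-matched to a requested arithmetic mean and
CV, 4PL dose-response plates with truncated multiplicative Gaussian noise,
and qPCR tables with `Ct = Ct_base − log_E(ratio) + N(0, sd)` and a
unit-ratio reference gene.  Default study conditions mirror the assay
designs: 8-dose serial dilutions with 4 replicates and 5 % multiplicative
noise for IC50 plates; 3 technical replicates at 0.1 Ct noise and planted
ratios spanning 1–15 for qPCR (the experimentally observed amplification
range).  What the generators deliberately do **not** emulate: cytometry
gating artifacts and spectral spillover, plate edge effects, primer
efficiency drift, polyclonal copy-number mixtures, or growth dynamics — so
passing recovery tests demonstrates estimator correctness under the stated
noise model, not robustness to every real-world artifact.

A master seed is split into independent sub-streams with
`numpy.random.SeedSequence.spawn`; identical (spec, seed) pairs yield
byte-identical outputs, and workflows record config + seeds so any run is
reproducible byte-for-byte from its own report.

## Problem sizes used by the test and acceptance runs

Chosen as the package's own verification scale: 200 stochastic seeds at
n = 2 for the stochastic/deterministic comparison; 50 random parameter sets
for conservation; 1,000 random length-200 sequences for scanner/oracle
equality; 100 plates for IC50 recovery; 1,000 randomized cases per assay
formula.

## Known limitations

* Rate constants are calibrated, not measured; only qualitative/structural
  claims (monotonicity, linearity range, leak dominance, mutant flatness)
  should be read off the defaults.
* The model omits cell growth, division-coupled dilution, and population
  heterogeneity in copy number; expression is per average cell.
* The stochastic stationary mean differs from the ODE fixed point by
  O(covariance) terms for bimolecular steps; the fast-flicker calibration
  makes this small but it is not identically zero.
* The scanner ranks purely by length/purity; it does not model triplex
  thermodynamics or genome-wide off-target binding.
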