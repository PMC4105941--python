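# Methods

## The model family

All variants share one compartmental mass-action skeleton of canonical
TGF-β/Smad signalling in HaCaT keratinocytes. Extracellular TGF-β binds
the type-II receptor and then the type-I receptor to form the
ligand–receptor complex (LRC) at the cell surface; the LRC internalises
into two routes, the early endosome (the signalling pool, which recycles
its receptors while the ligand is destroyed) and the caveolae (which
recycle the intact LRC and are the site of Smad7-directed degradation).
Receptors are produced at constant rates and turn over with first-order
kinetics; the same basal turnover applies to every receptor-containing
species, so the *total* receptor pool relaxes to the production/turnover
balance whatever its distribution — this is what makes the measured flat
T1R level a structural property rather than a tuned coincidence. The
endosomal LRC phosphorylates cytoplasmic Smad2 as a catalytic modifier;
phospho-Smad2 forms homomeric and heteromeric (Smad4) complexes at a
common association rate; monomers shuttle between cytoplasm and nucleus
and complexes import faster than monomers, without a nuclear export
route.

Nuclear species are stored as cytoplasm-volume-relative concentrations
(absolute nuclear concentration × V_nuc/V_cyt). First-order rate
constants are invariant under this substitution and conservation sums
become directly additive — total Smad2 is 571.43 nM and total Smad4
1333.33 nM in these units. The cytoplasm:nucleus volume ratio (default
2.3) therefore never appears in the right-hand side; it is only needed
when converting literature per-volume rates. The extracellular medium is
treated the same way: the ligand state variable is the ligand amount per
cytoplasmic volume, with the medium:cell volume ratio (default 2000,
roughly 2 ml of medium over a near-confluent dish) folded into the
binding rate constant. A 2 ng/ml dose of the 25-kDa TGF-β dimer is 80 pM,
i.e. 160 nM in relative units. This representation makes ligand depletion
by receptor processing an ordinary mass-action consequence: at the lowest
dose of the response grid (0.025 ng/ml = 2 nM relative) the medium is
largely drained within a day, while 2 ng/ml stays effectively saturating.

Negative-regulation mechanisms are toggleable blocks on this skeleton:

* **Dephosphorylation** — first-order dephosphorylation of nuclear
  phospho-Smad2 (the fast mode; in variants with an explicit PPM1A pool
  this lump is replaced by a two-step catalytic cycle:
  reversible phosphatase–substrate binding followed by irreversible
  catalysis).
* **Receptor degradation** — caveolar LRC destroyed at a rate
  proportional to Smad7, which in HaCaT is a high, buffered constant
  (100 nM); only the dynamic-Smad7 variant (S1) makes it a feedback.
* **P-Smad degradation** — first-order Smurf2-route destruction of
  nuclear phospho-Smad2.
* **Endogenous Smad turnover** — zeroth-order synthesis of cytoplasmic
  Smad2 and first-order degradation of phosphorylated and
  unphosphorylated monomers (complexes are exempt); the synthesis rate
  is tied to the basal degradation flux (ksyn = kdeg_S2 × 571.43 nM) so
  the resting total is preserved for any turnover rate.
* **PPM1A stabilisation** (the final model's feedback) — PPM1A is
  synthesised in the cytoplasm, degrades with a ~14-min half-life when
  free, and imports rapidly into the nucleus. Cytoplasmic phospho-Smad2
  scaffolds the association of PTEN with PPM1A; the ternary complex
  releases a PTEN:PPM1A dimer that evades degradation, imports into the
  nucleus slowly (the delayed arm of the feedback) and retains full
  phosphatase activity. Stabilisation therefore raises total PPM1A
  quickly (by intercepting synthesis that would otherwise be degraded)
  but raises *nuclear phosphatase activity* slowly, which is what
  produces the long 1–24 hr decline of phospho-Smad2 after the ~1 hr
  peak. A side effect of the interception is a transient dip in free
  nuclear PPM1A that sharpens the phospho-Smad2 peak.

Model 1 = dephosphorylation; 2 = +receptor degradation;
3 = receptor degradation alone; 4 = P-Smad degradation alone;
5 = dephosphorylation + receptor degradation + P-Smad degradation;
6 = dephosphorylation + P-Smad degradation; 7 = 6 + turnover;
8 = 7 + PPM1A stabilisation. S1 = 5 + dynamic Smad7 feedback;
S2 = 7 with Smad-complex-induced PPM1A expression instead of
stabilisation; S3 = minimal stabilisation variant.

## Parameters

Trafficking and shuttling rates are carried over from the prior-model
lineage (internalisation 0.33/min, endosomal recycling 0.033/min,
caveolar recycling 0.03/min, Smad2 import/export 0.156/0.34 per min,
Smad4 0.08/0.26, complex import 0.9/min). The remaining rates — kinase
strength, dephosphorylation, the negative-regulation rates and the PPM1A
block — are the package's calibrated defaults: they were fixed once so
that the simulated dynamics reproduce the system's published qualitative
anchors (phospho-Smad2 peak near 1 hr; a plateau when dephosphorylation
is the only regulator; elimination within 4 hr after a 30-min pulse plus
receptor-kinase block; flat total T1R and total Smad2; a ~2.4-fold PPM1A
rise by 1 hr; a much larger proteasome-inhibition effect under 8-hr than
30-min exposure; unregulated phospho-Smad2 exceeding ten times the
regulated peak; ≥90 % T1R loss at the top of the receptor-degradation
sweep). `scripts/tune_defaults.py` recomputes every anchor metric from
the frozen defaults. At those defaults roughly a third of the Smad2 pool
is phosphorylated at the peak, and total Smad2 transiently rises ~12 %
during stimulation because complexes are exempt from turnover — within
the noise of the emulated assays.

Fitting operates on log10-transformed rate constants with box bounds
(default 1e-8 to 1e3) using bounded trust-region least squares. The
finite-difference step is set to 1e-3 decades, well above the ODE
integrator noise at the fitting tolerances (rtol 1e-6) — with the default
step the numerical Jacobian is noise-dominated and multistart runs
scatter across spurious local minima. Starts: the current parameter
values, local jitters (±1.5 decades) around them, and global log-uniform
draws. The reported fit is the best of all starts; integration failures
inside the objective return a large finite penalty (1e12) so the
optimiser survives pathological corners.

## Synthetic data

The measured time courses behind the rejection workflow are western-blot
and ELISA quantifications that are not available as numbers, so the
generator simulates a ground-truth model (Model 8 by default) under the
short- and long-exposure protocols, samples the experimental grids
(phospho-Smad2 to 4 hr and to 24 hr, T1R at 10 points to 24 hr, total
Smad2 at 7 points, PPM1A to 8 hr), normalises western-style channels to
their own maximum or to baseline, and draws multiplicative lognormal
replicate noise (unit-mean factors, cv 0.2, n = 3; the ELISA-style
total-Smad2 channel uses cv 0.1). Everything is deterministic given the
seed. What passing tests on these data do **not** show: the generator
has no blot saturation, no loading-control error correlated across
lanes, no inter-day batch effects, and its noise is independent across
time points — real densitometry violates all four, so real-data
performance will be somewhat worse than the recovery numbers here.

## Fitting and the rejection workflow

Each candidate model is fitted to the phospho-Smad2 channels (short and
long exposure simultaneously; models with an explicit PPM1A pool also
fit the PPM1A channel). The receptor and total-Smad channels are
predictions. A channel *flags* a model when its SSE exceeds three times
the best model's SSE on that channel **and** the replicate-mean residual
sequence shows systematic structure — at least three time points beyond
twice the replicate standard error, at least 70 % of them on one side.
(A plain sign-run test was tried first and has essentially no power
here: genuine misfits are often one-sided, which degenerates the run
statistic, and noise-scale residuals dilute the run count.)

Verdicts are staged the way the measurements entered the analysis:
fit quality on phospho-Smad2 first, then the T1R prediction, then
total Smad2. A model flagged by a prediction channel is given the chance
to *accommodate* it — the channel joins its fitting data and the model
is refitted; if the conflict resolves without breaking the phospho fit,
evaluation proceeds with the refitted parameters, otherwise the verdict
is that channel. This reproduces the discriminating logic deterministically:
the receptor-degradation/P-Smad-degradation trade-off is a genuine SSE
ridge (the sweep in `klid_sweep` maps it), so a single unconstrained fit
of Model 5 lands on an arbitrary ridge point; the staged procedure uses
the flat T1R data to push the receptor route to zero and then lets the
flat total-Smad data reject what remains. Model 7 is fitted with its
total-Smad2 constancy constraint as a penalty (deviations beyond 4 %
enter the residual vector with weight 30), which is exactly why it fails
on the phospho channel: balanced turnover can change the height but not
the shape of the phospho-Smad2 curve.

## The MG132 reconciliation

MG132 is modelled as setting the Smurf2-route degradation rate to zero,
touching nothing else; cycloheximide halves every zeroth-order synthesis
rate. The relative P-Smad2 change is (treated − control)/denominator at
1, 2, 4 and 6 hr. The denominator is the control trajectory's **peak**
by default. The pointwise alternative (control at the same time point)
is available but misleading after washout: two trajectories decaying
with rates r and r − kdeg have a pointwise ratio that grows as
exp(kdeg·t) no matter how close both are to zero, which would make the
short-exposure "effect" the larger one — the opposite of what the
blots, which measure absolute band intensities against the dynamic
range of the assay, actually report. With the peak-referenced
definition the 8-hr exposure effect is ~6× the 30-min effect at the
default truth, reproducing the reconciliation of the conflicting
published proteasome-inhibition results: degradation scales with the
integral of nuclear phospho-Smad2, which is large only when the
stimulus, not the observation, is long.

## Numerical choices

LSODA integrates all systems (stiff-capable; the PPM1A block spans rate
scales from 5e-4 to 3/min). Production simulations use rtol 1e-8 /
atol 1e-10; fitting uses rtol 1e-6 / atol 1e-9 for speed. Equilibration
runs 1e4 minutes without ligand at rtol 1e-10 and warns if the residual
relative rate exceeds 1e-8/min. Washout is a hard integration restart:
extracellular and receptor-bound free ligand are zeroed and the
receptor kinase (and fresh binding) disabled, because SB-431542 blocks
the type-I receptor kinase — removing ligand alone would leave
pre-formed complexes signalling. Perturbations are pre-treatments
applied from t = 0 without re-equilibration; they do not alter the
unstimulated steady state of shared species. Simulated concentrations
are clipped at zero only when extracting the equilibrated state (values
at the −1e-12 level from the integrator).

## Problem sizes

The default test and analysis sizes are: 9-point sweep grids (5 points
in the quick correlation check), 10 Monte-Carlo recovery trials,
multistart sizes of 2–6, and 1-min output grids over 24 hr. These keep
a full run of the test suite and the acceptance script comfortable on a
laptop-class machine while leaving the statistical conclusions
unchanged at larger sizes.

## Known limitations

* The rate constants are a calibrated, qualitative-anchor-consistent
  set, not estimates from the original quantifications; absolute
  concentrations and time constants should be read as
  order-of-magnitude.
* Linker- versus tail-phosphorylation of Smad2 is not distinguished;
  the Smurf2 route acts directly on nuclear phospho-Smad2.
* The homomeric Smad complex is pairwise with the heteromeric
  association rate; trimeric stoichiometries are not modelled.
* SBML I/O covers the strict mass-action subset this package emits;
  arbitrary kinetic laws are rejected by design.
* The staged rejection verdict assumes the channels enter in the fixed
  order phospho-Smad2 → T1R → total Smad2 → PPM1A; other orderings can
  attribute a rejection to a different dataset when a model is
  inconsistent with several at once.
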