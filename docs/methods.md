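# Methods

## Model

`vegftrap` simulates the whole-body distribution of vascular endothelial
growth factor (VEGF) in a mouse bearing a human tumor xenograft, and the
pharmacokinetics and pharmacodynamics of the decoy receptor VEGF Trap
(aflibercept). The body is reduced to three well-mixed compartments — normal
tissue (represented by skeletal muscle), blood, and tumor — exchanging soluble
species by transendothelial permeability (`k_p · S · ΔC`) and one-way
lymphatic drainage, with first-order plasma clearance in blood and first-order
proteolytic degradation of free VEGF in the tissue interstitia.

Because the tumor is a human xenograft, host and tumor VEGF are molecularly
distinct and tracked separately: the mouse isoforms VEGF120/VEGF164 are
secreted by myocytes and endothelial cells, the human isoforms VEGF121/VEGF165
by tumor cells. The long isoforms (164/165) carry the heparin-binding exon and
are the only ones that bind glycosaminoglycan (GAG) sites in the extracellular
matrix and basement membranes, and neuropilin co-receptors; this is the sole
structural difference between short and long isoforms. All isoforms bind
VEGFR1 and VEGFR2 on muscle fibers, endothelium (luminal and abluminal faces
of both tissues) and tumor cells, with cross-species pairings assigned the
same rates as same-species ones (no mouse/human kinetic measurements exist to
distinguish them; the rate table is keyed by interaction class, not species
origin). Three soluble VEGF sinks are included: sVEGFR1 (secreted by
endothelium, present in all compartments), alpha-2-macroglobulin (native and
protease-activated forms, confined to blood by its 720 kDa size), and the
VEGF Trap drug, which forms a 1:1 complex with every isoform in every
compartment it reaches.

Tumor volume follows a prescribed exponential `V(t) = V0 · exp(k t)` from an
inoculum of 1e-6 cm^3; drug exposure does not feed back on growth. Treatment
begins when the tumor reaches a trigger volume (default 100 mm^3). All
tumor-compartment concentrations receive a dilution term `-(dV/dt / V) · C`,
so amounts — not concentrations — are conserved under pure growth; secretion
and receptor-insertion sources are specified per unit tissue volume, so
densities per cell stay constant as the tumor grows.

## State variables and bookkeeping

The default xenograft network comprises 258 state variables: 53 in normal
tissue, 126 in blood, 79 in tumor, plus the (analytic) tumor volume. The
published census of this model family constrains the bookkeeping but not
every convention behind it, so the enumeration is rule-driven and every
optional species class is a configuration switch; the manifest prints the
complete per-locale enumeration so the convention is auditable line by line.
The default switches are:

* **Fluid phases.** Four isoforms, sVEGFR1 and its four VEGF complexes, Trap
  and its four complexes in every compartment (14 species); blood adds both
  alpha-2-macroglobulin forms and their eight VEGF complexes (24 total).
* **Matrix.** Three interstitial sub-regions per tissue (ECM, endothelial and
  parenchymal basement membranes), each with free GAG sites and the two
  heparin-binding complexes (9 per tissue).
* **Parenchymal and abluminal endothelial surfaces** (muscle fibers,
  abluminal endothelium of both tissues): VEGFR1, VEGFR2, NRP1, the VEGF
  complexes with each receptor, NRP1 complexes of the long isoforms and their
  VEGFR2-coupled ternaries (15 species each). Internalized complexes are
  degraded immediately (sinks); a constant insertion source balances
  internalization so ligand-free totals hold exactly.
* **Luminal endothelial surfaces** (blood side of both tissues' vessels,
  51 species each): the 15 above, plus unliganded VEGFR1-NRP1 coupling and
  its liganded forms, sVEGFR1 captured on NRP1 (with and without VEGF),
  glycocalyx heparan-sulfate sites and their long-isoform complexes, an
  explicit internalized pool per complex, and intracellular free-receptor
  pools feeding insertion. Plasma clearance of receptor-bound ligand is
  dominated by this surface, which is why its trafficking is resolved.
* **Tumor cell surface** (41 species): NRP2 at the same density as NRP1 (with
  all NRP1-parallel complexes), VEGF-VEGFR1-NRP ternaries, sVEGFR1 capture on
  both neuropilins, surface heparan-sulfate sites, and intracellular receptor
  pools; internalized complexes are not individually tracked.

Internalized complexes degrade their ligand and recycle their receptor
components to the intracellular pools; without recycling, coupled-complex
internalization drains receptor mass far below the configured densities.
Whether sVEGFR1 binds matrix GAG sites is unstated in the source model family
and defaults to off.

## Parameters

Geometric parameters of the tumor compartment are derived, not asserted: from
a 12 um MCF-7-like cell (sphere volume 905 um^3; dodecahedral area 497 um^2
used for the cell-surface density), a 13.94 um capillary lumen with 0.5 um
endothelium and a 23% perimeter correction, a 45% extracellular fluid
fraction and 10% intravascular fraction follow the capillary density
(655 mm^-2), endothelial wall fraction (1.5%), vessel and tumor-cell surface
densities (378 and 2939 cm^2/cm^3), basement-membrane volume fractions
(thin shells on the smooth areas), and the available fluid volume of each
interstitial sub-region (volume x fluid fraction x partition coefficient;
the shipped config carries the published available-fluid values as explicit
overrides where the printed fractions do not reproduce the product exactly).

Key transport and kinetic defaults (all overridable in YAML, units in the key
names): tumor microvascular permeability 4e-7 cm/s for VEGF and 3e-7 cm/s for
Trap and its complex, ten-fold lower for normal endothelium (Trap baseline
3e-8 cm/s); VEGF Trap clearance 1.3e-5 s^-1 free and 2.5e-6 s^-1 complexed
(the two-compartment fitted values); alpha-2-macroglobulin clearance
2.62e-3 min^-1 with synthesis set by mass balance at the measured 1.4 uM
(native) and 14 nM (activated) plasma levels; Trap-VEGF Kd 0.5 pM
(kon 1e7 M^-1 s^-1); secretion isoform splits 8:92 (muscle), 10:90
(endothelium), 50:50 (tumor); sVEGFR1 endothelial secretion 6e-3
molecules/cell/s. Receptor densities and remaining rate constants are
prior-model defaults. The soluble-factor affinities (sVEGFR1-VEGF Kd 50 pM;
weak, high-capacity alpha-2-macroglobulin binding) were set, before any
fitting, so that the drug-free steady state reproduces the reported
physiology: plasma sVEGFR1 ~2 pM (measured range 1-10 pM) and a circulating
VEGF composition of roughly 80% free / 4% sVEGFR1-bound / 16% a2M-bound.

Growth-rate constants are calibrated so the tumor reaches the 100 mm^3
trigger from 1e-6 cm^3 in 14 days (average profile; 10 days for the fast
profile). A consequence worth knowing: with growth continuing exponentially
through the two treatment weeks, tumor burden rises ~100-fold after the
trigger, so tumor-derived (human) VEGF-Trap complex can overtake the
host-derived complex late in treatment — slower post-trigger growth curves
should be configured when simulating beyond ~6 weeks or matching slower
xenograft lines.

## Numerics

Concentrations are stored in pM relative to each compartment's fluid phase
(plasma, or available interstitial fluid; surface and matrix species use the
adjacent fluid as reference volume so every mass-action term is dimensionally
uniform). The right-hand side is compiled to sparse stoichiometry matrices
with an analytic sparse Jacobian; integration uses the implicit BDF method
(relative tolerance 1e-8 by default, absolute 1e-6 pM). Mass action is
evaluated as plain polynomials without clipping, so the rare sub-tolerance
negative excursion self-corrects through the reversed binding flux; dosing
discontinuities are handled by restarting the integrator at each infusion
boundary (a 1-minute intravenous infusion delivering the full dose to
plasma). The drug-free steady state is obtained by long integration (2e7 s)
with an explicit residual check; a cumulative-clearance bookkeeping state
makes drug-mass audits exact to solver tolerance.

## Parameter estimation

The objective is the weighted sum of squared residuals with weights
1/C_experimental, pooled over all time points, doses and observables (free
Trap, mouse-VEGF-Trap, human-VEGF-Trap). Minimization uses bounded
trust-region-reflective least squares in log10 parameter space (the rates
span orders of magnitude; bounds map exactly). Published bounds are applied:
secretion rates 1.5e-6 to 2 molecules/cell/s (the lower bound is the ELISA
detection limit), clearances within one order of magnitude of
ln2/72 h = 1.6e-4 min^-1, Trap Kd 0.25-5 pM, normal-tissue Trap permeability
within one order of 3e-8 cm/s. The multi-start protocol draws starting points
log-uniformly within bounds under a recorded seed; optima are reported as
mean ± SD over converged runs (non-convergent runs are excluded from the
summary but counted). Restart and data-order invariance are tested. No
profile-likelihood or Bayesian uncertainty is computed — mean ± SD over
restarts only.

## Synthetic data

There is no public deposition of the plasma measurements this model family
was fitted to, so pseudo-experiments stand in for them: the simulator is run
at a ground-truth parameter vector over the experimental protocol (tumor
grown to 100 mm^3, then twice-weekly intravenous Trap for two weeks at doses
from {0.5, 1, 2.5, 10, 25} mg/kg), sampled at 2-3 points per week, and
corrupted with mean-unbiased multiplicative log-normal noise whose CV is the
single noise parameter (concentrations are positive and assay CVs scale with
signal). Datasets are bit-identically regenerable from (truth, design, seed).
The generator emulates the sampling structure and noise character of plasma
ELISA time courses; it does not emulate inter-animal variability, assay
detection floors, or departures of the model family itself from reality — so
parameter-recovery results certify the estimation machinery, not the model's
fidelity to any particular experiment.

Recovery experiments at the fitted A673 secretion rates (0.011 / 0.009 /
0.009 molecules/cell/s for muscle / endothelium / tumor) recover the tumor
rate to well within 5% at zero noise, and reproduce the identifiability
asymmetry of plasma-only data: with endothelial secretion dominant, sweeping
muscle secretion from 0 to 0.02 molecules/cell/s changes the objective by
less than 5% — plasma measurements cannot apportion host VEGF production
between muscle and endothelium. The default test and acceptance problem
sizes use one dose level, six or seven sampling times and a few starts; the
machinery is identical at the full design, only slower.

## Sensitivity analysis

The eFAST estimator is implemented from its Fourier definitions: partial
variance `D_i = 2 Σ_p (A²_{pω_i} + B²_{pω_i})` over harmonics p = 1..M,
total variance from the full spectrum, first-order index `S_i = D_i/D_total`,
and total index `S_Ti = 1 − D_ci/D_total` with the complementary band taken
below ω_i/2. Search curves use the arcsine-of-sine transform (uniform or
log-uniform marginals), ω_i = (N_s−1)/(4M) respecting the Nyquist condition,
and complementary frequencies spread as high as the interference bound
(ω_i/2M) allows, preferring non-divisors of ω_i — low complementary
frequencies like {1, 2} make the complementary sub-curve too degenerate to
express interaction variance and bias D_total low. Indices are averaged over
N_r random-phase resamples (defaults M = 4, N_r = 5, N_s sized per the
Nyquist bound). The estimator is validated against the analytic Sobol
indices of an additive linear model (within 0.02 at N_s = 1025) and the
Ishigami closed forms (within 0.03), plus a Monte-Carlo double-loop Sobol
cross-check for interaction detection.

The modular analysis varies one parameter group at a time — tumor receptor
expression, transport, kinetics; membership is an editable mapping — each
parameter log-uniformly within one order of magnitude of baseline (group
ranges are not published, so absolute published bar heights are out of
scope), and analyzes drug-free steady-state mouse/human VEGF and sVEGFR1
levels in the three compartments.

## Known limitations

Single VEGF-A isoform pair per species (no VEGF188/189, VEGFxxxb, PlGF,
VEGF-B/C/D); no platelets; no subcutaneous depot (intravenous administration
assumed, 100% bioavailability); constant tissue composition as the tumor
grows; no feedback of drug on tumor volume or vascular permeability; tumor
lymphatics absent by default. The species census matches the published
structural counts by explicit configuration of the optional species classes
listed above; if the original bookkeeping conventions differed internally,
the per-locale manifest makes the difference localizable rather than hidden.
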