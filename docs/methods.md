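# Methods

## Model scope and structure

`enoskit` models VEGF- and TSP1-regulated eNOS signalling in a single
endothelial cell as a deterministic ODE system.  The network is written as
a rule set over five sub-modules plus the TSP1 interactions and expanded
into explicit species and reactions (`enoskit.network`); the ODE right-hand
side is derived generically from the expanded network, so every mechanism
is governed by exactly one named constant and the perturbation screens can
scale any mechanism in isolation.

Units are nM and minutes.  All fluxes are referenced to the cytosolic
volume; ER and extracellular species pick up the volume ratios
(V_cyt = 1 pL, V_ER = 0.1 pL, V_ext = 10 pL per cell — the three geometric
parameters) in the stoichiometric matrix.  Membrane species are book-kept
as cytosol-referenced concentrations.  PIP₂, extracellular Ca²⁺ and GTP
are clamped boundary pools; IP₃R is a fixed channel density.  The dose
conversion is fixed by 30 ng/mL ≡ 1.1 nM VEGF.

### Receptor module

VEGF binds R2 reversibly (Kd 1 nM); ligated receptor autophosphorylates
(k_phos 6/min) and is dephosphorylated (0.6/min).  Free receptor
internalises slowly (0.02/min), ligated/phosphorylated receptor ten-fold
faster; internalised receptor degrades, and constitutive synthesis
(zeroed by cycloheximide) balances the resting surface pool.  CD47 couples
reversibly to every R2 state; coupling is kinetically neutral by default
(a config switch can penalise phosphorylation of uncoupled receptor).
TSP1 sequesters VEGF in the medium and ligates CD47, including the CD47 of
coupled complexes — binding strips CD47 out of the CD47–R2 state.

### Src/Akt/Hsp90 and the eNOS activity model

pR2 phosphorylates Src; pSrc phosphorylates Akt and activates Hsp90; all
deactivate constitutively.  eNOS exists in eight states — with/without
4-Ca calmodulin (CaM4), with/without active Hsp90, and with/without
Akt-phosphorylation.  The design choices here carry the study's central
mechanism, that Akt and Hsp90 make stimulated eNOS activity independent of
the Ca²⁺ influx:

* active Hsp90 binds both bare and CaM-bound eNOS (same constants);
* pAkt phosphorylates eNOS only within Hsp90-containing complexes;
* the *phosphorylated, Hsp90-bound* complex is mutually stabilised: CaM
  unbinding and Hsp90 unbinding from that one state are both slowed by the
  factor `gamma_Hsp90CaM` (default 150).  Applying the factor to both
  unbinding legs keeps every pure-binding cycle thermodynamically
  consistent (the products of the cycle Kds match); only the ATP-driven
  phosphorylation/dephosphorylation steps break detailed balance, which is
  physically the only place it may be broken.  An earlier variant that
  enhanced CaM affinity on all Hsp90-bound states violated detailed
  balance and produced steady cycling with occupancies far from the
  intended equilibria — worth remembering when adding cooperative binding
  to mass-action networks;
* catalysis is Michaelis–Menten in arginine with
  K_Arg = k_off,Arg/k_on,Arg (rapid equilibrium; arginine is ~30× above
  K_Arg, so explicit Arg-bound states would be numerically invisible), and
  each eNOS form has its own turnover: k_cat,eNOS (0.2/min) for
  non-Hsp90 CaM-bound forms, k_cat,eNOS.Hsp90 (0.5/min) for Hsp90-bound
  forms, ×alpha_phos (12) when phosphorylated, plus a small
  Ca/CaM-independent basal term (f_basal 1e-3).  Keeping the basal and
  Hsp90-bound rates as separate constants is what lets a perturbation of
  the basal catalytic rate act at resting VEGF while sparing the
  stimulated (Hsp90/phospho-carried) response;
* citrulline is recycled to arginine (0.05/min) so that the resting state
  is a true fixed point while Arg+Cit stays conserved.

With these defaults the resting NO production is carried by the
half-saturated plain eNOS·CaM pool (plain Kd 1 nM against a resting CaM4
of 0.77 nM), while the stimulated response is carried by the
CaM-saturated phospho-Hsp90 pool (effective Kd ~7 pM).  That split is what
reproduces the headline directional results: Ca-entry blockade leaves
stimulated NO within 10 %, while CaM-axis perturbations ablate basal NO.

### Calcium module

pR2 phosphorylates PLCγ; active PLCγ converts PIP₂ to IP₃
(Michaelis–Menten against the clamped PIP₂ pool); IP₃ decays first order.
IP₃R release is conductance × IP₃ occupancy × (Ca_ER − Ca_cyt); CRAC entry
is gated by store depletion (inverse Hill in Ca_ER, exponent 4); SERCA is
a Hill-2 pump, PMCA Michaelis–Menten; a passive leak connects ER and
cytosol; a constitutive background influx (first order in clamped
extracellular Ca²⁺) carries ~90 % of resting plasma-membrane entry so that
CRAC blockade perturbs rather than collapses resting Ca²⁺.  Cytosolic
buffering is the instantaneous free fraction f_buf = 0.05 scaling the free
Ca²⁺ derivative.  CaM binds Ca²⁺ in two lumped 2-ion steps (N-lobe then
C-lobe); only CaM4 binds eNOS, and the Ca²⁺ inside bound CaM4 does not
exchange.

The resting sub-system is balanced analytically: at Ca_cyt = 50 nM and
Ca_ER = 100 µM, SERCA (1000 nM/min) exactly cancels the leak, and
background influx (900) plus resting CRAC (100) exactly cancel PMCA
(1000).  The pre-equilibrated model is a fixed point to <1e-8 nM/min, and
resting Ca²⁺ is 50 nM by construction, not by fitting.

### sGC / cGMP / PDE

NO binds the distal heme of sGC; the 1-NO complex activates; NO loss
deactivates; a second NO on the proximal heme desensitises the enzyme
(the desensitised state recovers by releasing NO).  Only active sGC makes
cGMP (Michaelis–Menten on the clamped GTP pool).  cGMP binds PDE's
regulatory site; the complex activates in two steps, and both active
states hydrolyse cGMP (the doubly-activated one twice as fast) — a strong
negative feedback that flattens cGMP against moderate production changes
and, together with sGC saturation/desensitisation at stimulated NO levels,
makes cGMP the most input-robust output of the pathway.

## Numerics

The network compiles once into index arrays; binding a parameter vector is
cheap, so calibration and screens rebuild rate constants thousands of
times without re-deriving structure.  Integration uses LSODA (`odeint`)
with rtol 1e-6, atol 1e-9 nM, an analytic Jacobian (assembled sparsely
from the same arrays; ~5× fewer function evaluations than internal
finite differences), and a hard cap of 20 000 internal steps per output
interval so that pathological parameter draws fail fast into the
calibration penalty instead of stalling.  States are clipped at zero
inside the rate evaluation; the non-negativity tolerance on outputs is
1e-9 nM.  Pre-equilibration integrates 1000 min at zero VEGF/TSP1 with
rtol 1e-8 and caches the resting state per parameter vector.  Stimulus
doses are applied at t = 0 after pre-equilibration; cycloheximide zeroes
receptor synthesis for the stimulus phase only.

## Synthetic data

The generator emulates the *structure* of the published HUVEC
measurements the original study was trained on (digitized Western blots
and calibrated assays; not deposited anywhere): 14 training time courses
(58 points) covering total/membrane/phospho-R2 (± cycloheximide), pSrc at
2.5 ng/mL, pAkt/peNOS at 50 ng/mL, pPLCγ at 80 ng/mL, NO at 10 ng/mL,
IP₃ and Ca²⁺ at 10 ng/mL, cGMP at 30 ng/mL, with 0–60 min time grids
drawn from common experimental practice, plus four independent hold-out
sets.  Arbitrary-unit series are normalized to their within-dataset
maximum; Ca²⁺, IP₃ and cGMP stay in absolute nM.  Noise is multiplicative
lognormal with sigma 0.15 (typical densitometry CV), independent streams
per dataset off one master seed; normalized series are re-normalized
after corruption, exactly as arbitrary-unit data would be.

What passing tests on these data do **not** show: the generator contains
no blot saturation, no inter-lab batch structure, no timing jitter and no
model misspecification — recovery results bound estimator behaviour under
the model's own dynamics, not under real-data artefacts.

## Calibration

Fitting works in log₁₀ parameter space with bounds ±1 decade around
baseline.  The objective applies the same normalization to simulation as
to data (simulated curves of normalized datasets are divided by their own
maximum over the dataset's time points — residuals are invariant to
rescaling the observable), weights each dataset by 1/n points, and
divides residuals by the dataset's maximum so absolute-nM and normalized
series contribute comparably.  The truth generator and the objective share
one prediction path, so the objective at the generating parameters is
exactly zero.  Multi-start: Latin-hypercube starts, an optional one-shot
objective pre-screen that polishes only the most promising starts
(`n_polish`), bounded trust-region least squares (tolerances 1e-8), top-k
ensemble (k = 19 by default, smaller at desk scale).

The shipped 5-parameter recovery study fits k_int,VR2, k_deg,IP3, I_IP3R,
I_SERCA and k_cat,sGC.  The set was chosen with the package's own
identifiability tools plus a practical-identifiability check over several
independent noise realizations; parameters whose influence is erased by
normalization (k_dephos,R2, k_clear,NO) or that enter only through ratios
(k_on/k_off,Arg; k_cat,PLCγ with k_deg,IP3; I_SERCA with K_M,SERCA) are
deliberately excluded, mirroring the workflow rule "fit only influential,
uncorrelated parameters".

## eFAST

Search curves follow the classic recipe: the parameter of interest runs
at the drive frequency ω = (Ns−1)/(2M) with M = 4 harmonics, the others
at low frequencies, with random phases per resample; ranges are
log-uniform over 0.1×–10× baseline.  Two implementation choices matter
for accuracy: complementary frequencies are small odd primes (harmonically
unrelated frequencies only collide at high, low-amplitude harmonics), and
the variance integrals are pooled over the Nr resample curves before the
index ratio is taken, which suppresses the finite-curve cross-spectral
bias of per-curve ratios.  With Ns = 1025 and Nr = 15 the total-order
indices of the Ishigami benchmark are within ±0.005–0.04 of quadrature
truth.  A dummy parameter rides along in every design; parameters are
influential only if their total-order index clears the cutoff (0.2 for
fitting, 0.1 for screen targets) *and* beats the dummy's resample
distribution (one-sided Welch test, p < 0.05).

## Identifiability

Local sensitivities are central finite differences of the stacked,
normalization-matched outputs with respect to log₁₀ parameters (1 %
relative step; a failed integration degrades to one-sided).  Pairs of
columns with |Pearson r| ≥ 0.9 are a-priori unidentifiable; zero-variance
columns (no path to any observable) are reported separately.  When
composing a fit set, the member of each flagged pair with the smaller
total-order sensitivity is fixed (alphabetical tie-break).  On the default
design this correctly discovers, e.g., that k_on,Arg and k_off,Arg enter
only through their ratio (r = −1.000).

## Perturbation screens

TSP1's unknown intracellular actions are modelled phenomenologically:
each candidate parameter (or seed concentration: CaM, eNOS, sGC, GTP,
Src, Hsp90, PIP₂, extracellular Ca²⁺) is scaled by a Hill function of the
TSP1 dose, f_positive(c) = 1 + (F_max−1)·c/(EC50+c) with F_max = 100,
EC50 = 0.022 nM, n = 1 — chosen so the factor is ≈100-fold at the top
experimental dose of 2.2 nM and ~half-maximal two orders of magnitude
below it.  Parameters tagged as promoting eNOS signalling are scaled by
the reciprocal f_negative.  Six log-spaced TSP1 doses span 0.00022–2.2 nM;
the direct high-VEGF screen uses six log-spaced folds from 2 to 100 at
0.389 nM VEGF and zero TSP1.  Scores are fold-changes of the trapezoidal
30-min AUC of Ca²⁺, NO and cGMP against the same parameter set's
unperturbed run (paired design); across a calibration ensemble a
one-sample t-test against 1 supplies the significance gate (p < 0.05),
and the pass thresholds are ≥20 % mean reduction (basal/TSP1 screens) or
≥10 % (direct high-VEGF screen).  For a single parameter set the t-test
is undefined and the threshold decides alone.

## Design decisions and limitations

* The rule set is a re-derivation at ~50 species, not a literal copy of
  any published file; defaults are seeded from physiological ranges and
  re-balanced so the resting state is exact.  Conservation of CaM, sGC,
  PDE, Src, Akt, Hsp90, PLCγ, CD47, eNOS and Arg+Cit is structural (the
  membership vectors annihilate the stoichiometric matrix symbolically).
* CD47–R2 uncoupling is structural only by default; the literature does
  not pin a kinetic consequence, so TSP1's downstream effects live
  entirely in the parameter-scaling screens.
* Extracellular Ca²⁺ and GTP are clamped; NO diffusion to neighbouring
  cells is folded into first-order clearance; there is no MAPK/ERK or DAG
  branch, no BH4/cofactor chemistry, and no spatial resolution.
* cGMP's strong PDE feedback means screen fold-changes for cGMP are
  compressed relative to NO; directional conclusions are robust but
  absolute cGMP fold-changes depend on the PDE constants, which are the
  least constrained part of the default parameterisation.
* SBML L3 export writes explicit MathML kinetic laws for all three rate
  law families; round-trip checks cover structure and parameter values.
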