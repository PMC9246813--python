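# Methods

## Scope and model structure

The package predicts unbound drug concentration–time profiles in brain and
brain-tumor tissue from plasma pharmacokinetics, drug physicochemistry and
(patho)physiology, and inversely estimates blood–tumor-barrier (BTB)
parameters from observed tissue data.

The CNS model has nine compartments: brain microvascular (MV) plasma, brain
ECF, brain ICF, a cell-membrane compartment, lysosomes, and four CSF spaces
(lateral ventricles LV, third+fourth ventricles TFV, cisterna magna CM,
subarachnoid space SAS). Plasma is an empirical one- or two-compartment
model (optional first-order absorption with lag); the MV compartment
exchanges with plasma at the cerebral blood flow, the BBB couples MV and
ECF, ECF bulk flow drains one-way into the LV, CSF flows LV → TFV → CM →
SAS and is resorbed to plasma, and the blood–CSF barrier (split equally
between LV and TFV) is passive. The tumor extension adds five compartments
(tumor MV, ECF, ICF, membrane, lysosomes) with the identical internal
structure, fed from plasma at the tumor blood flow and drained by tumor ECF
bulk flow into the LV; no direct tumor-ECF ↔ brain-ECF exchange is assumed
(no spatial information is available about tumor location). All kinetics
are linear (mass-action); saturable transport is out of scope.

## Transport construction

For a drug with molecular weight MW, octanol–water logP, and a single
dominant ionizable group per its charge class:

- unionized fraction (monoprotic Henderson–Hasselbalch):
  acids `1/(1+10^(pH−pKa))`, bases `1/(1+10^(pKb−pH))`, neutrals exactly 1;
- aqueous diffusivity `D_aq = 9.9e-5 · MW^−0.453` cm²/s;
- neutral-species membrane permeability `log10 P0 = 0.939·logP − 6.21`
  (cm/s).

The diffusivity and permeability correlations are pinned, named constants,
overridable per call; they are this package's declared parameterizations,
not reconstructions of any external model's internals.

Barrier clearances (mL/min; the factor 60 converts cm³/s):

- paracellular: `CL_para = (D_aq/w)·SA·φ/c · 60`, with barrier width
  w = 0.5 µm, base pore areal fraction φ = 1e-4, and c the fitted PPA
  correction factor (a fold-decrease, applied to the BBB and inherited by
  the BTB; the blood–CSF barrier is left uncorrected);
- transcellular: `CL_T = P0·SA·PHF(donor pH)·60`, with the pH factor on the
  donor side only;
- cell membrane exchange: total cell surface area `3·V_ICF/r_cell` for
  spherical cells, water→lipid clearance `P0·SA_cell·60` times the donor
  PHF, lipid→water clearance divided by the membrane partition `10^logP`;
  lysosomes analogously (`r_lyso` fixture) with pH trapping through
  `PHF(pH_lyso)`;
- ECF bulk flow `q_ecf,bulk · V_tissue·(1−f_MV)`; CSF flow is the
  production rate, augmented downstream of the LV by the ECF bulk inflow.

Asymmetry factors representing active transport multiply the transcellular
clearances only (active transporters are membrane proteins; the
paracellular route is AF-free). Given a measured control-brain Kp_uu,ECF,
the AFs are solved in closed form from

    Kp_uu,ECF = (CL_para + AF_in·CL_T,in) / (CL_para + AF_out·CL_T,ef + CL_bulk)

with exactly one AF > 1 (efflux if measured < passive ratio, influx
otherwise). Membrane and lysosome compartments carry no net steady-state
flux and cancel from this ratio.

## Tumor parameter derivation

Five tumor parameters (blood flow, MV and ECF volume fractions,
extracellular and intracellular pH) come from literature per tumor model;
where several values exist the arithmetic mean is used, rounded to 3
significant figures with decimal half-up arithmetic (binary rounding would
turn a mean of 7.325 into 7.32 where the conventional printed value is
7.33). Blood flow and MV fraction reported as tumor/control ratios are
multiplied by the healthy-brain reference values. The BTB surface area is
the BBB area scaled by the tumor/brain MV-volume ratio. Unreported tumor
fields (MV and lysosomal pH, membrane/lysosome volume fractions, ECF bulk
flow per mL, cell radius) inherit healthy-brain values. Tissue density is
pinned at 1 g/mL.

## Fold changes

The BTB differs from the control BBB by two estimated fold changes:

- `f_pore` multiplies the paracellular clearance linearly (slit-pore
  reading: areal pore fraction proportional to pore width at fixed
  junctional length, so the reported effective pore size is
  `f_pore × 0.7 nm`); a quadratic cylindrical-pore alternative is available
  behind `pore_scaling="quadratic"`.
- `f_efflux` scales the active component beyond passive transport,
  `A = (AF−1)·CL_T` on the asymmetric side: the BTB carries `f_efflux·A`,
  added to the efflux side when positive and to the influx side when
  negative. Thus 1 reproduces the control barrier, 0 abolishes active
  transport, and negative values mean reversal to net active influx — the
  only reading under which an estimated negative fold and "completely
  diminished efflux" are simultaneously coherent. An alternative applying
  the fold to AF itself (`efflux_mode="af"`) is provided; `(AF−1)` is the
  default.

## Estimation workflow

Stage 1 (control brain): with AFs frozen from the measured control
Kp_uu,ECF — solved once on the uncorrected barrier (c = 1) — the PPA
correction factor is fit to control-brain ECF data. Freezing the AFs before
correcting PPA keeps the two stages separable and makes the correction
identifiable through the exposure extent (a smaller paracellular clearance
against a fixed active efflux lowers ECF Cmax), which is exactly the
deficiency the correction exists to repair. Stage 2 (tumor): with the
correction frozen, `(f_pore, f_efflux)` are estimated simultaneously from
tumor ECF data.

Both stages minimise the sum of squared residuals on log10 concentrations —
a scale-free proxy for proportional-error maximum likelihood across the
1000-fold concentration ranges involved; a full mixed-effects objective is
deliberately not used (one correction factor and two folds per study do
not support subject-level random effects). Observations at/below the LLOQ are
excluded. Optimisation is trust-region least squares over log-transformed
positive parameters with seeded multi-starts (default: 8 log-spaced starts
for the 1-D stage, a 4×4 grid over log10 f_pore ∈ [−2, 4] and
f_efflux ∈ [−5, 20] for the 2-D stage; per-start evaluation caps of 60/80).

Identifiability: for paracellular-dominant drugs a pore-size increase and
an efflux decrease have nearly identical effects, so the objective has a
ridge along constant in/out ratio. The diagnostic reports the largest
relative spread of near-optimal estimates (objectives within 1% of the
best) across starts; spread above 10% sets `ridge_flag`. The fallback
protocol fixes one fold to 1 and fits the other (1-D, empirically
unimodal). The dispersion threshold and grids are config with pinned
defaults; the dispersion statistic is this package's quantitative
operationalization of "estimates that depend on the starting values".

## Simulation numerics

Every model is a linear ODE system with piecewise-constant inputs. The
default solver propagates the exact solution segment-by-segment with the
matrix exponential (augmented-matrix form for constant infusion inputs);
this is closed-form for linear kinetics, conserves mass to machine
precision, and is fast enough for the estimation loops. An LSODA route
(rtol 1e-8, atol 1e-10) is retained as an independent numerical oracle and
cross-checked to 1e-6 relative agreement in the tests. Impulse doses at
time t are visible to outputs at t (0+ convention); depot doses with lag
enter the absorption compartment at `start + lag`. Dialysate-like interval
observations are predicted as the trapezoidal time-average of the simulated
concentration over the collection interval (5 grid points per bin), the
same quadrature the generator uses.

VPC percentiles use linear interpolation between order statistics;
exposure metrics use trapezoidal integration on the simulation grid. The
relative-accuracy statistic is `RA = (1/M)·Σ_i Σ_j log10(MedP_ij/Obs_ij)`
with M the total observation count; non-positive observations are excluded
and counted.

## Synthetic studies and what they show

The generator emulates microdialysis studies: per subject, exponential IIV
deviations on plasma CL and V_cen, simulation of the full tumor-extended
model, sampling on a 20-min-bin schedule over 0–360 min (interval means by
default; point sampling optional), proportional(/additive) Gaussian
residual error, flooring at zero and censoring below the LLOQ (censored
rows carry the LLOQ). All randomness flows from one mandatory seed. Source
sampling schedules and arm sizes are not public; the defaults are declared
emulations, and probe recovery is taken as 1 (the states are already
unbound ECF concentrations).

Two reference designs fix the study conditions:

- the transcellular probe (neutral, MW 300, logP −0.3, ~46% transcellular
  share on the corrected BBB; BT4C-like tumor; control Kp_uu 0.9; true
  correction 40; true folds (2.5, 0.35); 6 subjects): tumor ECF
  equilibrates on a ~15-min timescale, so extent and kinetics jointly
  identify both folds;
- the paracellular ridge design (methotrexate in an RG-2-like glioma,
  measured control Kp_uu 0.114, correction 14, folds (2.66, 0.392)): the
  tumor tracks plasma quasi-instantaneously and only the in/out ratio is
  identified — the ridge regime.

Passing recovery tests on these designs shows the estimator is correct and
well-calibrated under the assumed noise structure; they do not show
robustness to model misspecification (wrong pathophysiology, nonlinear
transport, probe-recovery drift), which real microdialysis data would add.

## Fixtures and data provenance

Bundled YAML documents carry the drug records, plasma-model parameter sets,
tumor pathophysiology rows (with derivation provenance so every derived
cell can be re-derived from its sources; cells whose sources are not public
are loaded verbatim and never re-derived), measured Kp_uu values and the
reference estimation results. Quantities not available from those tables —
absolute surface areas, CSF volumes and flows, brain volumes, MV pH 7.4,
lysosomal pH 5.0, barrier width, base pore fraction and radius, cell and
lysosome radii, ECF bulk flow per mL — are versioned fixtures chosen from
standard rat/human CNS physiology; property-based tests hold for any
positive parameterization and only printed-number checks rely on the pinned
defaults. The fixture ICF volume closes the volume-fraction budget
(MV + ECF + ICF + membrane + lysosomes = tissue volume), which makes a
tumor with healthy per-volume parameters exactly equivalent to healthy
tissue — a structural invariant the tests exercise.

## Known limitations

- Charge- and size-dependent paracellular selectivity (Renkin sieving),
  pore tortuosity and multiprotic speciation are not modelled; the PPA
  correction factor absorbs them empirically.
- The BCSFB is passive (no transporter data) and the correction factor is
  not applied to it.
- Only a categorical tumor-core/control-brain split is represented; no
  peritumoral or intact-BBB tumor regions, no 3-D spatial gradients.
- Plasma fitting is pooled maximum likelihood with per-subject refits for
  IIV, not a full nonlinear mixed-effects estimator.
- Standard errors/CIs for the fold changes are not computed (multi-start
  dispersion is a diagnostic, not an uncertainty estimate).
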