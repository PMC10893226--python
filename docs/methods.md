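# Model and methods

`ioqsp` is a mechanistic, population-scale simulator of advanced
non-small-cell lung cancer (NSCLC) treated with the triple combination of
atezolizumab (anti-PD-L1), carboplatin, and nab-paclitaxel, or with the
chemotherapy doublet alone. It couples a reduced immune–tumour ODE system to
a virtual-trial layer (Latin hypercube virtual patients, RECIST v1.1
endpoints, PRCC sensitivity analysis, biomarker ROC analysis) so that the
clinical endpoints of a phase-3-like trial can be simulated end to end.

## The tumour balance

The lesion is a well-mixed population of `C` cancer cells with Gompertz
growth toward a geometric carrying capacity and four death channels:

    dC/dt = kC_growth · C · ln(Cmax_eff / C_total)
          − [ kC_death
            + kC_nabp · NabP/(NabP + IC50_nabp) · fc_nabp · f_chemo
            + kC_carb · Carb/(Carb + IC50_carb) · fc_carb · f_chemo
            + kC_T · T/(T + K_C_T·C_total) · T/(T + K_C_Treg·Treg)
                   · help(Th) · (1−H_PD1)(1−H_TGF)(1−H_MDSC) ] · C

with the carrying capacity from spherical geometry,
`Cmax = (4/3)·π·(DIA_T_max/2)³ · DEN_T_cell`, and tumour diameter recovered
by inverting the same relation (RECIST operates on diameters, the ODE on
counts). `H_PD1`, `H_TGF` and `H_MDSC` are saturating inhibition signals in
[0, 1]; `H_PD1` derives from a quasi-equilibrium competitive-binding model
in which atezolizumab sequesters PD-L1 (Kd ≈ 0.4 nM) away from PD-1, and the
resulting synapse complex density passes through a Hill function.

Two model assumptions shape the clinical behaviour and deserve emphasis:

* **Growth-fraction (Norton–Simon) gating of cytotoxic kill.** The chemo
  kill terms are scaled by `f_chemo ∝ prolif/(prolif + K_prolif)` where
  `prolif = kC_growth·ln(Cmax_eff/C)` is the tumour's specific growth
  activity. Cytotoxics preferentially kill proliferating cells; in the
  simulator this (i) reproduces the clinical observation that indolent
  tumours respond poorly to chemotherapy, (ii) prevents the response
  distribution from being a pure growth-rate lottery under the wide
  inter-patient growth spread (ln-SD 1), and (iii) lets baseline immune
  state carry predictive information about outcome.

* **Angiogenic-factor clock.** Nab-paclitaxel exposure induces an angiogenic
  factor `A` (first-order decay, ~70-day timescale) that acts twice: it
  raises the effective capacity, `Cmax_eff = Cmax·(1 + e_ang·A/(A+K_ang))`,
  and it progressively erodes the chemo-accessible cancer fraction through a
  sigmoidal vascular-abnormalisation switch
  `f_deliv = 1 − e_del·Aⁿ/(Aⁿ + K_angⁿ)` (n = 6). The first effect makes
  the induction rate a growth driver in the sensitivity analysis; the second
  is the mechanism by which responders on continuous dosing eventually
  progress, producing a finite median duration of response. Without an
  erosion clock, a patient whose kill rate exceeds growth shrinks
  indefinitely and never meets the RECIST progression criteria.

## The immune network

Around the cancer balance sits a 29-state reconstruction of the
immuno-oncology platform modules across four compartments (central blood,
peripheral tissue, tumour-draining lymph node, tumour):

* dying cancer cells release antigen, weighted ×3 for chemotherapy-induced
  (immunogenic) death relative to baseline turnover;
* antigen matures antigen-presenting cells, which migrate to the lymph node
  and prime naive T cells — CD8 priming is limited by the tumour-specific
  clone number `n_clones`, CD4 priming is not;
* primed cells expand, egress, circulate, and infiltrate the tumour in
  proportion to tumour burden, splitting the CD4 lineage into helpers
  (fraction 1−f_treg) and Tregs;
* effector CD8 cells kill cancer cells (gated by Th help, Treg suppression
  and the three H-signals) and exhaust into a terminal sink at a rate
  increasing with PD-1 engagement and Treg abundance — this is why PD-L1
  blockade durably sustains the effector pool;
* Tregs accumulate slowly in the tumour (t½ ≈ 58 days), gradually eroding
  effector killing: the second relapse clock, specific to the
  immune-dependent arm;
* MDSCs are recruited by tumour burden and by the angiogenic factor
  (VEGF–MDSC axis), TGF-β is secreted by cancer cells and Tregs.

Drug exposure uses a linear two-compartment model for atezolizumab (label
population values: CL 0.2 L/day, V1 3.28 L, V2 3.63 L, Q 0.546 L/day), a
three-compartment model with saturable (Michaelis–Menten) elimination for
nab-paclitaxel, and a piecewise-constant effective tumour concentration for
carboplatin (`f_carb_map · AUC-target` held for one 21-day cycle per dose),
reflecting its stable circulating exposure. Tumour concentrations are
partition coefficients times central concentration. Doses are state jumps
at integration restarts; infusions are treated as boluses because efficacy
endpoints evolve on a daily scale.

## Numerical scheme

The right-hand side is compiled with numba; integration uses LSODA with
rtol 1e−6 and per-species absolute tolerances 1e−6 × a characteristic scale.
Species must stay above −1e−9 × scale (violations raise, they are never
clipped). Each patient is equilibrated by a 200-day drug-free burn-in with
the cancer state clamped at its baseline burden; the post-burn-in state is
the biomarker baseline. Simulating one patient for 400 days takes ~0.1–0.2 s,
so the study-scale cohorts (500–1,000 patients) run in minutes on one CPU.

## Virtual population

26 parameters carry inter-individual variability (the sensitivity-analysis
set: growth and kill rates, chemo potency and nab-p PK, checkpoint binding
and PD-L1 expression, APC/MDSC/Treg/Th rates, inhibition half-max constants,
exhaustion, angiogenic induction, baseline diameter). All biological rates
are log-normal (truncated at ±3 ln-SD); the growth rate uses geometric mean
0.012/day with ln-SD 1.0, the literature-anchored value for this tumour
setting. The Treg priming fraction is a truncated normal on [0.05, 0.6];
the baseline diameter is log-normal (gm 3 cm) truncated to [1, 12] cm.
Latin hypercube sampling stratifies every marginal exactly; a plausibility
screen enforces a RECIST-measurable baseline (≥ 1 cm), positive rates, and
baseline burden below capacity, with rejected rows resampled.

What the generator does *not* emulate: parameter correlations between
patients' axes (none were available to estimate), measurement noise on scan
diameters, inter-lesion heterogeneity, new-lesion formation, and treatment
discontinuation or dose modification. Endpoints therefore reflect a cleaner
world than a real trial: progression can only arise from regrowth of the one
modelled lesion, and response/progression dates are quantised to the 8-week
assessment grid.

## Trial layer

RECIST v1.1 on the single lesion: CR below 1 mm, PR at ≤ −30% from baseline,
PD at ≥ +20% and ≥ +5 mm from the nadir (progression takes precedence over
the baseline comparison), SD otherwise; scans every 8 weeks from day 0 to
day 400; no confirmation scans. ORR CIs are percentile bootstrap (B = 2,000,
seeded); median DOR is the Kaplan–Meier median among responders with
censoring at day 400 and a bootstrap CI. Because response and progression
are only observed at scans, every DOR is a multiple of 56 days and the
step-function KM median can only take values 1.84, 3.68, 5.52 … months;
cohort-level summaries therefore read the median off the linearly
interpolated KM curve (the step convention remains available and is the
default of :func:`median_dor`). PRCC uses average ranks and
residualises each rank-transformed parameter on all others. ROC analysis
sweeps unique score thresholds; ties contribute ½, making the trapezoidal
AUC identical to the Mann–Whitney U statistic over n₁·n₂.

## Calibration

Five hyperparameters — the geometric means of kC_growth, kC_T, IC50_nabp,
n_clones, K50_PD1 — are fitted by Nelder–Mead (common random numbers, same
LHS base across evaluations) to the observed ORR and median DOR of the two
IMpower131 arms, with loss Σ |relative bias| over the four endpoints and a
5% per-endpoint convergence tolerance. Spreads stay fixed so four scalar
targets identify the search. The shipped calibration
(`src/ioqsp/data/calibrated_population.yaml`) combines a documented coarse
grid calibration of those means against the observed endpoints with a
Nelder–Mead polish on 200-patient cohorts; candidate optima are accepted
only if they verify on independent 500-patient draws (the polish's
best-found point did not, so the verified coarse solution is shipped).
With 500 patients the cohort ORR carries a ~2 percentage-point standard
error and the interpolated median DOR a ~0.5–0.8 month one; endpoint
reproduction should be judged against that sampling noise.

## Known limitations

* The full immuno-oncology platform this reconstruction follows comprises
  hundreds of differential equations and parameters; this model keeps
  module-level fidelity with 29 states and 87 parameters. Quantities that
  depend on the fine structure (absolute cell counts per compartment,
  secondary species dynamics) are indicative only.
* Baseline T-cell-density AUCs for discriminating responders come out near
  0.56 (CD8) and 0.50 (CD4) on the calibrated population, below the
  0.71/0.73 reported for the full platform, and CD8 discriminates better
  than CD4 (the full platform reports the reverse ordering). With the
  growth-rate spread pinned at ln-SD 1, the responder margin retains a large
  growth-lottery component that baseline immune state cannot explain; the
  Norton–Simon gating narrows but does not close this gap.
* Exhausted T cells are a terminal sink; checkpoint blockade acts only by
  reducing the inflow into exhaustion, not by reinvigorating exhausted
  cells.
* No overall-survival layer, no toxicity, no metastatic seeding, and no
  resistance evolution.
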