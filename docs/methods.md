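# Methods

## Scope

`cardioprofile` profiles drug-induced arrhythmogenic risk in single cardiac
cells: a four-member family of action-potential (AP) models — Purkinje (P),
endocardial (Endo), mid-myocardial (M) and epicardial (Epi) — is paced to
steady state across physiological cycle lengths (CL), with multichannel drug
block applied at therapeutic concentration, and the resulting biomarkers
(APD90 rate adaptation, ΔAPD%, early afterdepolarizations and their onset CL,
AP alternans, dominant EAD depolarizing current) are tabulated per
drug × cell × CL. Tissue-level propagation, TdP risk classification and
delayed afterdepolarizations are out of scope.

## The cell family

Each cell is a Hodgkin–Huxley-type membrane model with eleven gates and one
intracellular Ca²⁺ pool. Currents (µA/µF, outward positive;
dV/dt = −(ΣI_ion + i_stim)):

| current | form | role |
|---|---|---|
| I_Na | g_Na·m³·h·j·(V−E_Na) | upstroke |
| I_NaL | g_NaL·mL·hL·(V−E_Na) | late Na; hL keeps a small non-inactivating pedestal |
| I_CaL | g_CaL·d·f·(V−E_CaL), E_CaL = +48 mV | plateau / EAD window |
| I_Kr | g_Kr·xr·r(V)·(V−E_K) | rapid delayed rectifier with instantaneous inward rectification |
| I_Ks | g_Ks·xs²·(V−E_K) | slow delayed rectifier; slow diastolic deactivation lets it accumulate at fast rates |
| I_to | g_to·r·s·(V−E_K) | phase-1 notch |
| I_K1 | g_K1·k1(V)·(V−E_K) | rest / terminal repolarization |
| I_NaK, I_bNa, I_bCa | pump and backgrounds | diastolic balance |

Gates follow dx/dt = (x∞(V) − x)/τ(V) with sigmoidal steady states and
Gaussian-bell time constants; all voltage dependences are tabulated on a
0.02 mV grid and linearly interpolated. The Ca²⁺ pool integrates the
Ca-carrying currents and relaxes to its diastolic level (2×10⁻⁴ mM, τ =
70 ms); it feeds only the Ca Nernst term of the background Ca current. The
fixed effective I_CaL reversal (+48 mV) stands in for the flattening the GHK
flux produces at positive potentials and self-limits the plateau height.

The model equations and constants are this package's own parameterization,
calibrated so the family reproduces the documented electrophysiology of
Purkinje and transmural ventricular cell types: every constant and initial
condition is printed in the per-cell parameter files
(`src/cardioprofile/params/*.yaml`).

Heterogeneity is applied as conductance scalings of the Epi base
(g_NaL 0.018, g_CaL 0.25, g_Kr 0.05, g_Ks 0.04, g_to 0.16 mS/µF …):

* **Endo**: I_to × 0.15 (no phase-1 notch), I_Ks × 0.7;
* **M**: I_NaL × 2.4 and I_Ks × 0.5 — the reduced repolarization reserve that
  makes M cells the EAD-vulnerable type;
* **P**: I_NaL × 4.2 with its own late-Na kinetics (faster diastolic
  recovery, smaller pedestal), I_CaL × 0.14, I_Na × 1.8 (higher amplitude),
  I_to × 0.5, I_Kr × 0.8, I_Ks × 0.5, I_K1 × 0.7, I_bNa × 0.5. The large,
  quickly recovering I_NaL gives P cells the longest APD, the steepest
  rate adaptation at short CL, and I_NaL-driven EADs; the small I_CaL keeps
  the Ca window subordinate.

Initial conditions are the paced steady state at CL = 1000 ms (the standard
convention for published cell models); at that stored diastolic state the
membrane currents cancel to < 0.05 µA/µF. Stimulus amplitude is calibrated
per cell as 1.5× the diastolic threshold of a 0.5 ms pulse and stored in the
parameter file.

## Numerics

Forward Euler with a two-level adaptive step: dt = 0.001 ms while the
stimulus is active or |dV/dt| > 1 mV/ms, else 0.01 ms. Time is carried in
integer ticks of dt_min so steps never cross stimulus, sample or beat
boundaries; traces are recorded on a fixed 0.1 ms grid. Gates are clamped to
[0, 1] after each step and any excursion above 10⁻⁶ is logged. Halving the
coarse step changes steady-state APD90 by well under 1 ms on the toy model.

Pacing runs until the steady-state rule — |APD90(n) − APD90(n−1)| < 0.1 ms
over 10 consecutive beats, with beat n compared to n−2 when the rhythm is
period-2 — or the beat budget. The default budget is the full 60-minute
schedule (ceil(3.6×10⁶ ms / CL) beats); the shipped analyses use a
convergence-shortened budget of 240 beats, which the convergence rule ends
long before in almost every run (the note's reported quantities carry the
beat counts actually used). A run whose membrane stops returning below
−60 mV for three consecutive beats is flagged as repolarization failure,
not raised.

Drug-free (control) runs start from the stored initial state; drugged runs
start from the control's steady state at the same CL, i.e. the drug is
applied to the beating cell. This matches how drug effects are actually
established and avoids a spurious 2:2 attractor that capture from cold rest
can select at short CL.

## Pharmacology

Drug action is simple pore block: each targeted conductance is multiplied by
1/(1 + (C/IC50)^h) at concentration C (default: the compound's EFTPC). No
state-dependent or kinetic binding, no temperature or protein-binding
corrections. The shipped 12-compound CiPA training library transcribes
IC50/Hill/EFTPC values from the public channel-panel literature; published
assays disagree by factors of 2–5 for several compounds, and where sources
span a range the value retained is the one under which the calibrated family
reproduces the documented drug phenomenology (a choice recorded per entry in
the library file). Tests of the pharmacology machinery never depend on these
values — they use synthetic compounds.

## Biomarkers

* **APD90** — from the maximum-upstroke-velocity sample to the last downward
  crossing of V_peak − 0.9·(V_peak − V_rest), linearly interpolated;
  V_rest is the sample immediately before stimulus onset. Beats that
  repolarize only during the following cycle (heavy EAD regimes) are
  measured across beat boundaries in the profile table.
* **EADs** — on a 1 ms-smoothed trace, a local voltage minimum above
  −40 mV followed by a prominence-style rise ≥ 2 mV, outside a 10 ms
  post-peak blanking window and a 60 ms post-upstroke notch guard (the
  phase-1 notch → dome transition is not an EAD). Each upstroke counts
  once. Detection is invariant to time shifts and voltage offsets and
  recovers implanted humps exactly at noise SD ≤ 0.5 mV.
* **Alternans** — over the final 10 beats: mean |ΔAPD90| > 5 ms with the
  difference sign alternating in ≥ 80 % of the window, or a period-2
  alternation of the per-beat EAD count, or a strictly period-2 pattern of
  captured / non-repolarizing beats (the extreme large–small AP
  alternation). Windows containing irregular repolarization failures give
  no verdict.
* **EAD onset CL** — smallest sampled CL whose steady-state beats carry
  EADs provided all larger sampled CLs do too (slow-rate convention);
  non-monotone patterns are returned as explicit CL intervals. Onsets are
  grid-resolution-limited (50 ms).
* **Dominant EAD current** — the candidate ({I_NaL, I_CaL} by default)
  carrying the largest inward charge integrated over every detected EAD
  upstroke window in the steady-state beat set.

All thresholds are package choices (the underlying phenomena are reported
graphically, not numerically, in the experimental literature); they are
configurable on every call and echoed in profile fingerprints.

## Synthetic fixtures

The toy cell is a four-variable plateau-AP model (V; an inactivation gate f
with a reactivation window on the inward current; an outward activation gate
x with fast deactivation in the window region; a slow availability gate w
with a 0.4 floor). Nominal parameters give a 280 ms plateau AP at
CL = 1000 ms with no EADs; reducing the outward conductance below ~0.37×
tips the plateau into oscillatory reactivation with EADs on every beat (the
`ead_prone` variant sits at 0.35×). It emulates plateau + reactivation-EAD
phenomenology only — no spike-notch-dome morphology, no rate-adaptation
realism — so toy-based tests validate the engine and detectors, not
cell-type physiology.

Parametric AP traces are piecewise-analytic (linear rise, optional cosine
notch, linear descent, cosine EAD humps, Gaussian noise) with closed-form
APD90 and implanted-event ground truth; random drug libraries sample
IC50 log-uniform on [0.01, 100] µM, Hill on [0.5, 2], EFTPC log-uniform on
[0.001, 10] µM. All randomness flows through one seeded generator per call.

## Design choices and limitations

* The family is phenomenological: it reproduces the documented ordering and
  drug phenomenology (AP morphology ordering, M-cell vulnerability, EAD
  onsets, P-cell fast-rate alternans, cell-specific EAD currents) but its
  ΔAPD% magnitudes are only directionally comparable to biophysically
  detailed models. The scorecard test asserts signs and cell ordering, not
  magnitudes.
* Known deviations of the shipped library/model from the reference
  phenomenology: diltiazem produces mild APD shortening rather than major
  prolongation (its public hERG IC50 is ~100× its EFTPC, leaving Ca-channel
  block as its only appreciable effect); P-cell ΔAPD under bepridil
  (+32 %) and mexiletine (−6.6 %) overshoot the reference magnitudes
  because the P parameterization carries a large I_NaL share; M cells under
  dofetilide at CL = 300 ms show large–small alternation where the
  reference describes plain prolongation.
* EAD regimes near threshold are genuinely non-smooth (subcritical onset,
  2:2 branches); per-beat flags in that neighbourhood can shift by one
  50 ms grid step between parameter sets. Onset assertions therefore allow
  one grid step of slack.
* Problem sizes used by the shipped analyses: convergence-shortened pacing
  (240-beat budget, 10-beat/0.1 ms convergence rule), 35-point CL sweeps
  (300–2000 ms, 50 ms), 200 seeded fixture variants for detector recovery.
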