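# Methods

## Scope and structure

The package simulates TGF-β-mediated interactions at three scales —
intracellular Smad signaling, a cell-centric exchange model of ligand
production and paracrine sharing, and a phenotype-structured tissue
model of a mammary-duct neighbourhood — plus a delay-differential model
of a bone-remodeling niche perturbed by metastatic cells, and a
first-order sensitivity analysis over all of them.  All models are
deterministic mean-field systems; the only randomness in the package is
the mixed-lesion experiment (random per-cycle TGF-β release) and the
Monte-Carlo sensitivity sampling, both driven by explicit seeds.

## Intracellular model

Eight species under mass action: free ligand B, inactive/active receptor
R_in/R_act, cytoplasmic Smad S_c, phospho-Smad pS_c, nuclear pS_n and
S_n, and target mRNA m.  Binding consumes B and R_in; the active complex
hands its ligand to Smad (one complex consumed per phosphorylation);
pS_c translocates at k_t; a constant nuclear phosphatase pool P
dephosphorylates pS_n; transcription integrates pS_n.  The Smad material
S_c+pS_c+pS_n+S_n is exactly conserved, and the only fixed point
compatible with ligand-depletion experiments has B = R_act = 0, with
pS_c, pS_n → 0 and S_c, S_n, m stationary.

The downstream models need only the collapsed first-order decay of
internalized ligand.  Holding S_c at a constant S_c0 (it is large
relative to the receptor pool), the drain on the complex becomes linear
with rate r_sgn = k_phos·S_c0.  The shipped defaults (S_c0 = 100 nmol,
k_phos = 3.018×10⁻⁵ nmol⁻¹ s⁻¹) reproduce the tabulated
r_sgn = 0.003018 s⁻¹ exactly; the individual pathway constants are an
adapted mass-action parameterization of the published kinetics
literature and are fully overridable — every contract in the module
holds for any non-negative parameterization.

## Cellular exchange model

Per phenotype φ = 0..Φ (Φ = 3), an average cell carries extracellular
ligand B_e(φ), receptors R(φ) and internalized complex B_i(φ); one
shared pool B_dr holds the ligand in the diffusive region:

    dB_e/dt = r_syn β_sM(φ) − r_b B_e R − r_pc B_e + r_pc B_dr / ΣN
    dR/dt   = r_syn R_sM(φ) − r_b B_e R
    dB_i/dt = r_b B_e R − r_sgn B_i − r_u B_i δ(φ,0)
    dB_dr/dt = r_pc Σ N(φ) B_e(φ) − r_pc B_dr

Ubiquitination (r_u) applies to healthy cells only.  The return flux
from the diffusive region is split equally over all neighbour cells —
the minimal reading of an unweighted shared outflux; the split lives in
one line of the right-hand side if a weighted variant is wanted.  The
paracrine rate is the Fick's-law discretization D_eff·S/(d·V_dr); the
default 10 s⁻¹ corresponds e.g. to D_eff = 100 µm² s⁻¹ through a 10 µm²
contact surface over a 0.1 µm gap into a 1000 µm³ region.

Because receptor expression exceeds ligand expression for every
phenotype of the default isoform pair (TGFB2/TGFBR3), the receptor pool
grows secularly while B_e, B_i and B_dr relax to quasi-stationary
values; the Smad-bound influx r_sgn·B_i(φ) converges within a few
relaxation times 1/r_sgn ≈ 330 s to r_syn β_sM(φ) (healthy cells:
reduced by the factor r_sgn/(r_sgn+r_u) that ubiquitination diverts).
This is what makes the cross-scale coupling robust to the exact
averaging horizon.

## Tissue model and coupling

Cell counts N(φ) per neighbour volume follow capacity-limited
proliferation and influx-modulated death with two mutation channels (see
README for the equation).  Design points:

- **Response factor.** The serial-amplification cascade is encoded
  phenomenologically as (γ B_in/α)^g with per-phenotype exponents;
  proliferation uses exponent −g_p(φ) so a positive exponent
  *downregulates* proliferation.  The exponent vectors decrease with
  phenotype and end negative: TGF-β's switch from suppressor to
  promoter.  At zero influx the scaled signal is floored at 10⁻¹² to
  keep negative exponents finite (a guard, not biology).
- **Healthy net rate.** The healthy proliferation-rate entry is
  −1×10⁻⁶ s⁻¹: the healthy class carries a slow net decline.  This is
  the reading of the parameter table under which the malignant class
  reaches 10 % of the population at ≈ 23 months, the model's tissue-scale
  calibration point; with a positive entry the take-over lands near 10
  months instead.
- **Crowding** uses the shared total ΣN against phenotype-specific
  capacities C_φ (malignant cells multi-layer, C_Φ = 8 > 6).
- **Malignant jump.** A fraction p_Φ of *every* sub-malignant
  proliferation term is rerouted to the malignant class, with its sign.
  Early on, when only the (declining) healthy class proliferates, the
  malignant class therefore integrates a slightly negative seeding flux
  and sits at an integrator-scale negative value (|N| ≲ 2×10⁻⁶ cells)
  until positive seeding from the pre-neoplastic classes overtakes it.
  The state is integrated and reported unclipped — the signed buffer is
  part of the mean-field dynamics and clipping it between coupling steps
  advances the take-over by months; the undershoot magnitude is recorded
  in trajectory metadata and the non-negativity guarantee is stated up
  to that documented scale.
- **Degradation** r_d applies to all phenotypes (single tabulated rate).
- **Coupling.** One month of tissue time per cellular re-equilibration
  (the scales are 5–8 orders of magnitude apart); cellular horizon
  0.05 day ≈ 13 relaxation times of B_i; influx averaged over the last
  10 % of the horizon; tissue counts passed as continuous averages (both
  models are mean-field).  Halving the tissue step changes 24-month
  outcomes by far less than 1 %.

The 24-month malignant share deserves a caveat: the take-over is a steep
sigmoid (≈ 3 % at 22 months, ≈ 27 % at 24, ≈ 75 % at 26), so the share at
a fixed calendar time is hypersensitive to the crossing time even though
the crossing itself is a robust ≈ 23 months.

## Bone niche model

Nine states (osteocytes, osteoclasts, lining cells, osteoblasts, RANKL,
BMP, CSF, mineral density z, niche TGF-β β) with one state-dependent
lag.  A microfracture removes Ocy_max/30 osteocytes uniformly over one
day; the resulting damage signal (apoptotic debris) is the pulse
integrated with first-order clearance r_dmg and drives RANKL, BMP and
CSF production.  RANKL·CSF recruits osteoclasts; resorption lowers z and
releases TGF-β (r_β·Oc·z); BMP recruits lining cells, which mature into
osteoblasts gated by the BMP level one delay τ(β) ago; osteoblasts
rebuild z, feed back RANKL, and slowly re-bury as osteocytes.  Cancer
cells exchange TGF-β with the niche (c_sec·N_c − c_abs·N_c·β), raising β
and stretching τ toward its 28.38-day ceiling; lining cells then decay
(a_Lng) before maturing, so less bone is rebuilt than resorbed.

Choices on points the published table does not fix:

- **Delay form.** τ(β) = τ̄ + Δ·β/(β+β̄) is the minimal saturating form
  that is positive, finite, monotone and uses exactly the tabulated
  constants (τ̄ = 6.02 d, Δ = 22.36 d, β̄ = 8×10⁻⁸ nmol/V_frac).  At
  working β levels of a control cycle the emergent delay is ≈ 20 days,
  consistent with the stated osteoblast maturation time.  The form is
  pluggable.
- **Maturation flux.** M(t) = m_Lng·BMP(t−τ(β))·Lng(t)/L_ref by
  default: the delayed recruitment signal gates the *currently
  available* pre-osteoblast pool.  Evaluating the lining factor at the
  delayed time as well (`delay_lining=True`) overdraws the pool — the
  drain then exceeds the standing population and forces zero-clipping —
  so it is exposed as an alternative mode, not the default.
- **Damage clearance.** A permanently standing damage signal would hold
  the recruitment sources on forever and the cycle would never
  terminate; first-order clearance (r_dmg = 0.04 d⁻¹) is the minimal
  closure that produces the complete canonical sequence — osteocyte
  drop, RANKL/CSF surge, osteoclast wave, density dip, delayed
  osteoblast wave, recovery — within the ≈ 200-day cycle.
- **Closure constants.** k_CSF (osteoclast depletion of CSF), L_ref
  (maturation normalization), s_f/s_r (bilinear density couplings),
  c_sec/c_abs (cancer exchange) are not tabulated.  They were calibrated
  once — s_f against s_r so the cancer-free cycle is balance-neutral,
  then c_sec so the default load N_c = 2000 ends the cycle 1.00
  percentage point down — and frozen in the defaults.  The loss is
  monotone in N_c (−0.66, −0.85, −1.00 points at 500/1000/2000 cells),
  and scaling the release rate r_β down (up) flips the control balance
  positive (negative).
- **OPG** is not a state; its effect is folded into the RANKL
  degradation rate.

**Integrator.** Method of steps: fixed-step classical RK4 (default
h = 0.01 day) over a dense, linearly interpolated history buffer;
pre-onset history is the constant healthy state.  States are clipped at
zero with a logged count — zero clips occur under defaults.  With the
delayed arguments frozen the integrator agrees with an adaptive ODE
solver to < 10⁻⁶ relative on the smooth part of the field; the
apoptosis-pulse discontinuity at t = 1 day costs locally ~10⁻⁵ at the
default step, which is well below any quantity of interest.  The
mixed-lesion index runs independent cycles with r_β scaled by lognormal
draws (unit mean by default) and reports the sample standard deviation
of the per-cycle balances; it is seed-deterministic.

## Sensitivity analysis

S_i = Var(E[Y|X_i])/Var(Y) by a crude double loop: the total variance
from a joint sample, the conditional means from n_inner draws at each of
n_outer fixed values of X_i.  The estimator carries an O(1/n_inner)
upward bias per index; the standard error is a delete-one jackknife over
the outer loop.  "Spread of 10 %" is read as *standard deviation* 10 %
of the nominal (uniform half-width 0.1·√3·|θ|), which keeps every
support on one side of zero; variance- and half-width-based rules are
selectable.  Vector parameters are sampled per entry; zero nominals are
degenerate.  Outputs are observed at fixed per-model times (cellular
4320 s, tissue 24 months, bone 200 days), all configurable.

## Problem sizes and numerics

Default runs: cellular 0.05 day of model time (stiff LSODA,
rtol 10⁻¹⁰); tissue/coupled runs 24–36 months with monthly coupling
(atol 10⁻¹⁸ — the malignant seed passes through fluxes of 10⁻¹³
cells/s); bone 200 days at h = 0.01 day.  Every headline number in the
README is produced by these settings in seconds on one core.

## What the synthetic pieces do and do not show

The expression fixtures reproduce the frozen TGFB2/TGFBR3 vectors and
perturb them with seed-stable multiplicative noise; they emulate the
*magnitude structure* of expression-derived synthesis levels, not array
noise, probe effects or patient heterogeneity.  Passing tests therefore
demonstrate the internal consistency and calibration of the dynamical
models, not predictive power on clinical expression data.  Further known
limitations: no spatial geometry at any scale (duct or niche), so true
mixed-lesion heterogeneity is only proxied by the variability index;
cancer-cell numbers are constant within a remodeling cycle; mutation is
deterministic mean-field, not an individual-based branching process.
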