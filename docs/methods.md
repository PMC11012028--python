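# Methods

## Question and model structure

The package evaluates, from a societal perspective, whether diagnosing
suspected autism spectrum disorder (ASD) in Thai children aged 1–5 with the
Thai Diagnostic Autism Scale (TDAS) is cost-effective compared with standard
clinical diagnosis (ClinDx). It is a hybrid model:

1. **Diagnostic phase — decision tree.** Each strategy maps the suspected
   cohort to entry shares over {non-ASD, mild, moderate, severe}. In the TDAS
   arm the cohort splits into test-positives (0.8990) and negatives;
   positives split into true and false positives using the reported pair
   (0.8286, 0.1961) renormalised to a branch distribution (the pair sums to
   1.0247 and the tree splits only test-positives; an alternative
   sensitivity/1−specificity reading would need a prevalence the inputs do
   not provide, so it is exposed as the `renormalize_tp_fp` flag instead).
   True positives split by the TDAS severity mix; false positives are
   non-ASD; 0.0071 of the negatives resurface after age five as delayed
   diagnoses, assumed severe. In the ClinDx arm 0.6731 of the cohort is
   diagnosed, of which 0.2000 late (severe) and the rest splits by the ClinDx
   severity mix. Delayed cases enter the cohort model as severe at cycle 0;
   no waiting-time sub-model is attempted.

2. **Follow-up phase — Markov cohort model.** States {non-ASD, mild,
   moderate, severe, dead}, one-year cycles from the cohort's mean diagnosis
   age (3.52 y; life-table lookup by floored attained age) to age 100.
   Annual severity transition probabilities come from the chart-review
   estimates (e.g. moderate→mild 0.2643/yr, moderate→severe 0.0218/yr).
   Background mortality is the life table's q(a), multiplied by the ASD
   mortality relative risk 2.370 in the severity states (clamped at 1).
   Composition is mortality-first — die with min(1, q·RR), then redistribute
   survivors — which keeps rows stochastic for every q. Rewards accrue on
   start-of-cycle occupancy, no half-cycle correction by default (a
   `half_cycle` flag exists); discounting at 3 %/yr for both costs and QALYs,
   cycle 0 undiscounted.

## Accounting convention for undiagnosed children

Children who leave the diagnostic phase without an ASD diagnosis
(test-negatives who never convert, false positives, clinically undiagnosed)
accrue neither costs nor QALYs in either arm ("diagnosed-pathway
accounting", `u_non_asd = 0` and zero non-ASD state costs). This is the only
accounting under which arm-level totals of the reported magnitude can arise
at all: crediting undiagnosed children a utility near 1 for life adds an
almost identical ~28 discounted QALYs × non-ASD share to both arms and
collapses the incremental QALY to ≈0.03. The consequence is that a strategy
that diagnoses *more* children books more QALYs and more costs; the
incremental comparison is then dominated by the diagnosed-share difference
(0.7277 vs 0.6731). `u_non_asd` remains configurable for users who prefer a
whole-cohort accounting.

## Costs

All costs are in USD (inputs already converted at 34.995 THB/USD). Per
severity state, annual cost = outpatient treatment + admission-weighted
inpatient cost + therapy activities (cost × attendance proportion) +
outpatient non-medical (visits/yr × (travel + food + accommodation ×
accommodation proportion + caregiver accompaniment)) + admission non-medical
(per-admission travel/food/accommodation for patient and caregiver, one
accommodation proportion 0.385 applied to both, plus accompaniment) +
caregiver-at-home (hired salary × hired proportion + annual forgone income ×
severity-specific quitting proportion; both salary figures treated as
annual). Severity-specific admission probabilities are not reported
directly; they are recovered by Bayes inversion
P(admit|s) = P(admit)·P(s|admit)/P(s) with P(s) a pooled (equal-weight
TDAS/ClinDx) chart-review mix, configurable. This inversion conserves
expected admissions exactly. Instrument purchase (cost × purchase
proportion) is charged once at model entry by default
(`instruments_one_time`), as an acquisition rather than a recurring cost.

The diagnostic episode itself costs labor/month ÷ (2 diagnoses/week ×
52/12); TDAS adds training (151) and instrument (323) amortisation over 104
diagnoses/provider-year plus per-patient maintenance (0.27) and cloud
storage (1.43) — 21.72 USD/patient vs 7.04 for ClinDx.

## Uncertainty analysis

*Fitting.* Beta by method of moments (ν = m(1−m)/se² − 1); Gamma by
shape = (m/se)², scale = se²/m; Log-normal by natural-scale moment matching
(σ² = ln(1+(se/m)²)); severity mixes as Dirichlet with α = m·n_eff,
n_eff = min over components of m(1−m)/se² (the most conservative choice; the
implied SE is exact for the binding component and wider than reported for
the others, which a single Dirichlet cannot avoid). Cost rows published
without a CI use se = 0.20 × mean. The relative-risk SE (0.0942) is read on
the natural scale; `rr_se_log_scale` switches the interpretation.

*PSA.* 10,000 joint draws (parameters independent across groups; Dirichlet
handles within-mix correlation), each rerunning the entire pipeline for both
strategies. Draws whose transition rows would exceed 1 are redrawn (capped
at 100 per draw; in practice none occur at the default inputs). Summaries:
cost-effectiveness-plane quadrant shares and the CEAC, i.e. the fraction of
draws with positive net monetary benefit WTP·ΔE − ΔC over a WTP grid
(default 0–10,000 USD/QALY in steps of 100). PSA averages are never taken
over raw ICERs.

*OWSA.* Each non-fixed input moves to mean ± 1.96·SE (or ±20 % without an
SE), clamped to its support, all else at base case; Dirichlet components are
varied one at a time with complementary renormalisation of the other two.
Entries are sorted by ICER excursion width into a tornado table.

*Thresholds.* WTP = 160,000 THB/QALY ÷ 34.995 THB/USD = 4572.08 USD/QALY by
default; the alternatively printed 4577 is selectable via
`wtp_usd_override`.

## Life table

No national life table is shipped with the study inputs, so the package
bundles a **synthetic** Thai-like period table
(`data/life_table_thai_synthetic.csv`): Gompertz–Makeham
q(a) = 0.0012 + 1.75275·10⁻⁵·e^(0.102·a) with infant q(0) = 0.008 and
q(100) = 1, calibrated once to Thailand's period life expectancy at birth
(75.3 y). Any real national table can be substituted via the `life_table`
config key (CSV `age,qx`). All reported results are conditional on the
configured table.

## Synthetic study data

`tdas_cea.synthetic` emulates the unpublished primary data: (a) Gompertz
life tables; (b) patient-level chart reviews — multinomial initial
severities and annual multinomial transitions at the true rates, default
n = 295 (the study size), with an annual censoring probability exposed as a
parameter because the real review's follow-up structure is unreported; (c)
cost/utility interviews with Gamma cost items and Beta utilities at the
configured moments. Transition estimation is discrete annual-risk
(events / person-years), matching the model's one-year cycles rather than a
continuous-time survival fit. These generators reproduce the *statistical*
structure the analysis assumes — independent items, homogeneous rates, no
site effects, no informative censoring — so passing recovery tests
demonstrates internal consistency of the pipeline, not validity of the
original data collection.

## Numerical and testing choices

Cohort propagation is exact linear algebra (97 cycles × 5 states); traces
are cross-checked against an independent matrix-power oracle. Row
stochasticity holds to 1e-12, mass conservation to 1e-9, moment round-trips
to 1e-6 relative. ICER pathologies are labelled (dominant / dominated /
equal) rather than reported as signed ratios; the zero-effect, nonzero-cost
boundary maps to dominance. Parameter-recovery tests use 2,000 simulated
patients over 10 years (large enough for binomial CIs a few permille wide,
small enough to run in seconds); the PSA in the acceptance checks uses the
full 10,000 iterations (~30 s).

## Known limitations

- The published headline results were produced in a spreadsheet whose
  internal conventions (life table, per-state cost assembly, the mechanism
  giving arms different per-patient QALYs beyond the severity mix) are not
  recoverable from the printed inputs; this package reproduces the printed
  *inputs and formulas* faithfully, and its base case therefore differs from
  the printed headline numbers (it finds a substantially *lower* ICER,
  ~760 USD/QALY, i.e. the same qualitative conclusion). Every deviation
  source is a logged configuration flag.
- No treatment-effect modelling in the follow-up phase; severity dynamics
  are the observed net of whatever care the source cohort received.
- One admission accommodation proportion is applied to both patient and
  caregiver; the hired-caregiver salary period is assumed annual.
- No value-of-information analysis, no CPI adjustment, no EQ-5D-Y scoring
  (utilities enter as published values).
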