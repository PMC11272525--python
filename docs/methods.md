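# Methods

## Model structure

The engine is a three-state partitioned survival model (PSM). Unlike a
Markov model it never forms transition probabilities: state occupancy at
each cycle's evaluation time is read directly from two survival
functions. With `S_PFS` and `S_OS` the progression-free and overall
survival curves,

    pfs(t)  = min(S_PFS(t), S_OS(t))
    dead(t) = 1 − S_OS(t)
    pd(t)   = S_OS(t) − pfs(t)  ≥ 0,

so the three occupancies sum to one by construction (the `min` guards
against extrapolated curve crossings). The horizon is 173 cycles of 21
days (~9.9 years), long enough that both cohorts are almost entirely
absorbed.

Both curves are Weibull, `S(t) = exp(−λ t^γ)` with time in **months**
(scale λ in month^−γ). Month units make the progression-free restricted
mean of the reference PFS curve ≈ 11.4 months, consistent with the
corresponding life-year outputs; cycle-unit parameterizations are not.

### Hazard-ratio adjustment

The Weibull family with fixed shape is closed under proportional
hazards: multiplying λ by k multiplies the hazard by k uniformly and
gives `S_adj = S^k`. The comparator's curves are therefore derived from
the reference arm's by one hazard ratio per endpoint. Because the pooled
HRs are reported as reference-vs-comparator (HR < 1 meaning the
reference arm does better), the default convention is

    λ_comparator = λ_reference / HR,

which makes the comparator's survival worse when HR < 1. The literal
product `λ × HR` is available (`hr_direction: multiply`) but inverts the
arms' ordering on PFS and is not the default.

### Accrual conventions

* **Evaluation point** — cycle midpoints by default (equivalent to a
  half-cycle correction, and the smallest-bias choice for a
  spreadsheet-style PSM); start-of-cycle is configurable. The choice
  moves totals by less than half a cycle of accrual.
* **Discounting** — continuous-time, `(1 + r)^(−t_years)` at each
  evaluation point, r = 5%/year (one-way range 3–8%).
* **Drug costs** — the full induction bundle for cycles 1–6 and the
  PD-1 maintenance drug from cycle 7 until the 24-month cap (anchored at
  treatment start; 34 cycles of 21 days), always weighted by PFS
  occupancy: all treatment stops at progression, and the model assumes
  best supportive care (zero cost) in PD.
* **Adverse events** — only severe events (≥ grade 3, plus grade-2
  reactive cutaneous capillary endothelial proliferation, RCCEP, a
  camrelizumab-characteristic toxicity requiring management). Management
  costs accrue per cycle as Σ(incidence × cost) over PFS occupancy;
  that convention reproduces the right order of magnitude for both arms'
  AE totals, whereas a one-off cost at entry is two orders too small. A
  `one_off` mode exists for comparison. Disutilities mirror the cost
  convention: the PFS utility is reduced by Σ(incidence × disutility)
  during PFS occupancy (configurable to induction-only).
* **Platinum choice** — the comparator regimen allows cisplatin or
  carboplatin; the default prices cisplatin (first-listed). Swapping is
  a one-line config edit.

## Inputs

All inputs live in one YAML configuration (`data/default_config.yaml`);
no engine module hard-codes a value, and a test verifies that perturbing
any leaf moves the outputs. Key defaults: reference-arm Weibull
(PFS λ = 0.04, γ = 1.28; OS λ = 0.01, γ = 1.53), HR_PFS = 0.75
(0.60–0.94), HR_OS = 0.95 (0.71–1.28), PFS/PD utilities 0.75/0.59,
per-cycle prices in USD converted at 6.73 CNY/USD. Every
{baseline, low, high} triple is a sensitivity parameter; the published
RCCEP disutility row (baseline 0.10, range 0.16–0.24) is kept verbatim
even though the range does not bracket the point value.

## Network meta-analysis

With no head-to-head trial of the two regimens, the hazard ratios come
from an indirect comparison across a path-shaped network (CTC – chemo
comparators – SGP). The pooling is fixed-effect inverse-variance
weighted least squares on the edge-incidence matrix: L = BᵀWB is the
weighted graph Laplacian, effects are `d = L⁺BᵀWy`, and contrast
variances come from the same pseudo-inverse. On a tree this is exactly
the Bucher method (log-HRs add along the path, variances add), which the
tests use as an independent closed-form oracle. Fixed-effect only: with
one trial per edge, heterogeneity is inestimable. The default pipeline
reads the pooled HRs from the configuration (per-trial estimates are not
publicly printed); `pool_network` is exercised on synthetic tables and
available for user-supplied trial data.

## Curve fitting

Two fitters target the same curve:

* `fit_weibull_mle` — reference fitter; maximizes the right-censored
  Weibull log-likelihood `Σ_events ln(λγt^{γ−1}) − Σ_all λt^γ` by
  Nelder-Mead in log-parameter space from the fixed start γ = 1,
  λ = events/Σt (the exponential MLE), tolerance 1e−8, so fits are
  reproducible. `fixed_shape=1` gives the exponential sub-model, whose
  closed-form MLE is a test oracle; lifelines' Weibull fitter is the
  independent cross-check.
* `fit_weibull_to_km_points` — for digitized curve coordinates;
  ordinary least squares on the complementary-log-log scale
  (`ln(−ln S) = ln λ + γ ln t`). Deterministic, and exact on noiseless
  points; survival values of exactly 0 or 1 carry no information on this
  scale and are excluded. Model choice among parametric families is
  summarized by AIC/BIC in the fit report (only the Weibull family is
  implemented; the report structure leaves room for others).

## Sensitivity analysis

**One-way (tornado):** each parameter is set to its low and high bound
in turn with everything else at baseline, the full engine re-runs, and
entries are sorted by |ICER_high − ICER_low|. All 35 configuration
parameters are ranked, not a preselected subset.

**Probabilistic:** 5,000 seeded Monte-Carlo draws. Families by role —
beta for probabilities and (dis)utilities, gamma for costs and
disutility magnitudes, normal for hazard ratios — parameterized by
method of moments from the baseline (mean) and the range read as a 95%
interval (SE = (high − low)/3.92): beta α = m(m(1−m)/s² − 1),
β = (1−m)(…); gamma shape = m²/s², scale = s²/m; zero SE or a boundary
mean degenerates to a point mass (which removes the comparator's RCCEP
incidence, printed as 0, from sampling). HRs are sampled on the **log**
scale by default — their published intervals are asymmetric around the
point estimate, which is the signature of log-scale construction — with
σ from the log-CI width; a natural-scale normal truncated at zero is
configurable. Draws are independent across parameters (no correlation
structure is published). The probabilistic ICER is the ratio of means,
not the mean of per-draw ratios: the latter is unstable whenever the
QALY difference changes sign and is reported only as a diagnostic.
CEACs use the net-monetary-benefit rule, `P(w·ΔQALY − ΔCost > 0)`, on a
WTP grid (0–50,000 by 500) that contains the two GDP thresholds exactly;
the two strategies' curves are complementary by construction.

## Synthetic data

The generators emulate the three inputs the pipeline would consume in
the wild, with known truth: (a) pseudo individual-patient event times —
Weibull by inversion, independent exponential censoring plus an
administrative cutoff (the minimal standard mechanism; the underlying
trials' follow-up patterns are not published and no attempt is made to
guess them); (b) noiseless digitized curve coordinates on a monthly
0–36-month grid, matching typical published axes; (c) per-trial log-HR
tables with normal noise on a connected network. They do not emulate
digitization error, number-at-risk attrition, or informative censoring,
so passing recovery tests demonstrates correctness of the estimators,
not robustness to real digitization artifacts.

## Numerical choices

Restricted means use adaptive quadrature (checked against the
closed form Γ(1 + 1/γ)·λ^(−1/γ)); trace conservation holds to 1e−12 by
construction; deep survival tails underflow to 0.0 in double precision
and are treated as exact zeros; the engine's accruals are verified to
1e−9 against an independently coded plain-Python per-cycle loop under
every convention combination.

## Known limitations

* The published base case cannot be reproduced exactly from its printed
  inputs. The Weibull parameters are given to two decimals (for the OS
  scale, 0.01 vs an unrounded ≈ 0.008 changes life-years by >10%), and
  the published per-arm QALY/LY ratios (≈ 0.37 and 0.31) are lower than
  any stated utility and differ between arms, so the original utility
  accrual convention is not recoverable. Total costs and the headline
  ICER reproduce within ~5% and ~14%; per-arm QALY levels do not. The
  acceptance script reports the recomputed values as computed, without
  calibration toward the published figures.
* The published probabilistic means (incremental cost far above the
  deterministic base case) are not reachable from the stated
  method-of-moments construction, which by design centres every sampled
  parameter on its baseline; the recomputed PSA therefore sits near the
  deterministic results and its acceptability curves are lower.
* Fixed-effect NMA without inconsistency diagnostics; no second-line
  sequencing; grade 1/2 adverse events (except grade-2 RCCEP) excluded;
  no parameter correlations in the PSA; Weibull is the only survival
  family implemented.
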