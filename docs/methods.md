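# Methods

## Model structure

The cohort model is a deterministic annual-cycle state-transition model: a
closed cohort enters at age 40 and is followed to age 80 (41 cycles), with
occupancy tracked as fractions (no microsimulation — the published-style
outputs are cohort-level expectations, and fraction flow computes them
exactly and reproducibly). The base space has 20 states: healthy, 16
organ-specific disease states across three ladders (esophagus 5, cardia 5,
stomach 6), a post-treatment state for endoscopically cured lesions, and
two absorbing death states (UGC death, other-cause death).

Two expansions produce the 45-dimensional propagation vector:

* **Tunnel states.** Advanced cancer carries duration-dependent annual
  death probabilities, so each advanced state is copied into durations
  1–5 and a constant 6+ bucket. The series comes from 5-year survival
  *S₅* under a constant-hazard split, `q = 1 − S₅^{1/5}` for years 1–5,
  with the 6+ value equal to the year-1 value. The split reproduces
  `1 − S₅` exactly over five years (tested at 1e-6).
* **Surveillance copies.** The follow-up arms keep screen-detected
  low-grade lesions under annual endoscopic surveillance. Surveilled mass
  is tracked in parallel copies of the 10 pre-intramucosal states; it
  follows the same natural history (regression to healthy exits
  surveillance; progression past severe grades lands in the ordinary
  cancer states).

**Within-cycle ordering** is fixed and documented, because competing-risk
ordering is otherwise a silent source of irreproducibility: age-specific
other-cause death is applied first, then disease transitions (or the
duration-specific advanced-cancer death probability) act on survivors at
their full annual probabilities. Cycle *t* is attained age 40 + *t*;
mortality lookups never extrapolate — a missing age is an error.

Three mortality inputs are carried: other-cause (all-cause excluding UGC)
by age, UGC background mortality by age, and the advanced-cancer duration
series. Only the first and third drive propagation; applying the
age-indexed UGC series on top of the duration series would double-count
cancer deaths, so it is retained for reporting/export only.

## Screening mechanics

Screening is offered at the scheduled ages (start, start+interval, … ≤ 70;
the model itself runs to 80). Each round:

* a compliance fraction `c_s` (0.60) of every live, non-surveilled state
  attends and incurs the per-endoscopy cost (¥651.36);
* attending lesion mass is detected with sensitivity `Se` (0.96); healthy
  and post-treatment attenders are falsely positive with `1 − Sp`
  (Sp = 0.90) — by default false positives incur no further cost
  (endoscopic biopsy is treated as confirmatory in-session; a per-FP cost
  hook exists);
* management: severe dysplasia/CIS and HGIN are resected (→ post-treatment,
  charged the organ's SD/CIS-grade treatment cost); early cancers are
  resected (→ post-treatment; their treatment cost is charged at state
  entry, see below); lower grades enter surveillance under follow-up arms
  and are left untouched otherwise; advanced cancers are tagged
  screen-detected for costing.

Follow-up rounds run annually (configurable interval): `c_f` (0.75) of
surveilled mass attends, progressed severe grades are detected with `Se`
and resected. Surveilled states are exempt from general screening rounds
so no person-year is charged two endoscopies.

**Cancer treatment costing** charges each case once. Early cancer is
charged at state entry in every arm. Advanced cancer is charged at
diagnosis: the duration-1 tunnel at a cycle start holds exactly the
previous cycle's entries, still undiagnosed; a screening round detects
`c_s·Se` of that mass at the "(screening)" cost and the remainder presents
clinically the same cycle at the "(no screening)" cost. Older tunnels are
already diagnosed and are neither re-screened nor re-charged. Detection of
advanced cancer changes its cost, not its survival (a conservative
choice — any advanced-stage treatment benefit is already embedded in the
duration series).

## Economics

QALYs accrue on start-of-cycle occupancy (after screening), weighted by
state utilities; death contributes zero; post-treatment follows the healthy
utility. No half-cycle correction is applied (flag-free default, chosen for
transparency; the comparisons are differences between arms that share the
accrual convention). Costs and QALYs are discounted at the real annual rate
(base 0.03) from model entry (*t* = 0 at age 40). Internals are in CNY;
reporting divides by 10⁴ to match the published convention.

Frontier construction sorts by cost, removes strong dominance (≥ cost,
≤ QALYs, one strict; cost ties keep the higher-QALY arm, full ties the
lexicographically smallest code), then removes extended dominance
iteratively until neighbour ICURs strictly increase — asserted on every
run. NMB uses λ = ¥70,653/QALY by default with 2× and 3× multiples as
conventional context.

## Parameters and distributions

All scalar inputs live in a flat registry (`compliance.screening`,
`utility.eso_early`, `cost.treat_gastric_sd_cis`, `discount_rate`, …) with
base value, range and PSA distribution, serialized to a versioned YAML
schema (`format: ugc-cea/1`). Period-probability conversion uses
constant-hazard compounding `p₁ = 1 − (1 − p_T)^{1/T}`; rate inputs convert
via `p = 1 − e^{−rate}`.

The published beta/gamma parameter pairs are inconsistent with their
base-case values under a plain reading (e.g. the screening-cost gamma
(2.16, 0.003) has mean 720, not 651.36 — though 2.16/651.36 ≈ 0.0033
reveals the intended rate). The default **recentered** mode therefore keeps
the printed family but centres the sampled mean on the base case: gamma
keeps its printed shape with rate = shape/base; beta is re-derived by
method of moments with mean = base and SD = (range width)/4, truncated by
rejection to the printed range (clamped at utility 1.0). A **raw** mode
uses the printed pairs verbatim. Triangular rows are sampled exactly as
printed (their modes are not always the base value; that inconsistency is
left visible rather than silently corrected). PSA sampling is joint and
independent across parameters; transition probabilities have no published
distributions and are held fixed by default. One root seed spawns
per-iteration child streams, so results are reproducible and order-robust.

Threshold location brackets an argmax-NMB change with a 9-point coarse
scan, bisects the lowest bracket to tolerance, and flags multiplicity when
the scan sees several switches. The tornado metric is the NMB (vs the
no-screening arm, λ = ¥70,653) of the base-case optimal strategy at each
parameter endpoint, ranked by spread.

## Synthetic natural history

The transition table, initial distribution and mortality curves behind the
original cohort are unpublished, so the generator emulates their structure,
not their values:

* onset edges healthy → {mild dysplasia, cardia IM, CAG} (0.004, 0.003,
  0.006/yr), forward ladder probabilities 0.04–0.12/yr, early → advanced
  0.35/yr, regression edges 0.04–0.08/yr confined to pre-intramucosal
  states; per-edge seeded lognormal jitter (SD 0.05) makes seeds distinct
  while intensity multipliers scale whole edge classes;
* initial occupancy ≈ 97.2% healthy with small lesion fractions mirroring
  a 40–44-year-old detection pattern;
* Gompertz-like other-cause mortality, 0.003/yr at 40 rising to 0.055/yr
  at 80 (statistical-yearbook-like shape);
* advanced 5-year survival 0.20/0.20/0.25 (esophagus/cardia/gastric),
  reflecting the ~20–25% advanced-stage survival reported for these
  cancers.

Under the defaults the no-screening cumulative incidence is ≈ 2,300 per
100,000 over the horizon — inside a plausible 2,000–15,000 band for a
40-year window but deliberately not calibrated to any particular
surveillance figure. Consequences: structural and arithmetic results
(conservation, dominance logic, schedule counts, ratio columns, PSA
machinery) transfer to real inputs; absolute cases, deaths, costs and the
identity of the optimal strategy do not — they are properties of the
synthetic tables. What the passing tests show is that the *pipeline* is
correct, not that the synthetic epidemiology matches Shandong's. The
generator omits, among other things: cohort heterogeneity and risk
stratification, secular trends in incidence, age-dependent transition
probabilities (transitions are age-constant by assumption), and
cross-organ correlation of lesions.

## Numerical choices and problem sizes

Occupancy conservation is asserted at 1e-9 every cycle of every run;
operator rows sum to 1 at 1e-12. Matrices are rebuilt per age and shared
across the 41 arms of a batch evaluation. A full 41-arm evaluation takes
≈ 0.3 s, so the default deterministic analyses use the complete grid; the
bundled PSA summaries use 200 iterations (the CLI default remains 1,000),
chosen as ample for curve shapes at the package's test scale. CEAC ties
split equally; probabilities sum to 1 within 1/n by construction.

## Known limitations

* Early cancers never die of UGC directly in the model; they must pass
  through advanced stages. Untreated early-cancer mortality is therefore
  slightly understated.
* Early-cancer treatment cost is charged at state entry in all arms (the
  detection route does not change it), so the no-screening arm implicitly
  assumes early cancers are found and managed clinically.
* Compliance is an independent per-round attendance fraction; persistent
  attender/never-attender subgroups would need cohort stratification.
* The initial prevalent early-cancer mass (0.04% of the cohort) is not
  charged a treatment cost at entry; only incident flows are.
* Utilities and costs are consumed as given; no estimation from survey
  instruments, and no currency conversion.
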