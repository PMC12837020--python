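# Methods

## Model structure and assumptions

The package implements a deterministic, prevalence-based cost-of-illness
model over a one-year horizon from the societal perspective.  All
existing cases in the year are costed (no incidence dynamics, no
discounting); every quantity is an expected value — patient counts stay
fractional and adverse events are costed as probability × bundle cost,
never simulated.  Costs are kept in SAR at full precision throughout;
rounding to 2 decimals happens only at report time.

Severity follows the Scottish grading: R1 (mild non-proliferative
retinopathy), R2 (moderate), R3 (severe), R4 (proliferative), M1/M2
(maculopathy), plus a separate BLIND grade.  Severity classes map
R1 → mild; R2, M1 → moderate; R3 → severe; R4, M2 → sight-threatening.

### Population cascade

Counts flow adult population → diabetics → disease groups, with every
prevalence applied multiplicatively.  The overlap correction factor
CF = combined / (retinopathy + maculopathy) rescales the six R/M grade
counts so patients with both conditions are not double-counted; it is
applied to the grade counts only, not to the blindness count (the
published cascade shows no corrected blind figure).  When the disease
population is entirely empty the degenerate case is defined as CF = 1.
The bundled configuration also stores, as an annotation, a second
published figure for the R4 row whose derivation is undocumented; it is
never used in computation.

### Direct costing conventions

* Frequencies annualize as: every *n* weeks → 52/*n* (a 52-week year, so
  "every 4 weeks" is 13/year, not monthly); every *n* months → 12/*n*;
  once at diagnosis → 1 within the one-year horizon; per-year counts
  verbatim.
* Each protocol line carries a `multiplicity` (default 1), the explicit
  knob for per-eye dosing or multi-day resources; nothing in the
  published inputs fixes eye multiplicity, so the default is
  per-patient.
* An injection-administration fee (SAR 2,000) is charged alongside each
  drug acquisition for both anti-VEGF (every 4 weeks) and triamcinolone
  (every 6 months) in all treated grades.
* Monitoring bundles: R1/R2 have vitrectomy once plus a 3-monthly
  post-operative test bundle; R3/R4 the same bundle plus laser
  photocoagulation (no vitrectomy — the treatment description assigns
  vitrectomy to R1/R2 only and is taken literally); M1/M2 have OCT
  3-monthly and a monthly visit bundle, with laser added for M2.
  Fluorescein angiography is once at diagnosis for every grade.
* Adverse-event bundles are model defaults, config-overridable:
  endophthalmitis uses the intravitreal-strength antibiotics
  (vancomycin 500 mg, ceftazidime 1 g) with sampling, three
  hospitalization days and topical drops; retinal detachment is
  vitrectomy plus three hospitalization days; cataract surgery after
  vitrectomy (R1/R2 only) is phacoemulsification + IOL with the full
  published IOL work-up items and drops.
* Supportive care: visual aids (SAR 3,000/year) for R1, R2, M1, R3;
  psychological support and an annual home-care nurse (SAR 37,000) for
  R4, M2 and BLIND.  Psychological support is costed as 12 psychologist
  visits per year — the convention implied exactly by the published
  psychological-aid component (published total / eligible population =
  SAR 4,140 = 12 × 345).

### Indirect costing

Human capital method: wage/day × lost days × persons.

* Two wage tiers.  Severely impaired, sight-threatened and blind
  patients earn the published reduced salary of SAR 4,000/month
  (÷ 22 working days/month).  Mildly and moderately impaired patients,
  and all caregivers, are valued at a GDP-derived economy-wide wage.
  That wage is not published; the default of SAR 489/day is estimated
  from 2022 national accounts (GDP ≈ SAR 4.155 × 10¹² / 32.175 M
  population / 264 working days) and is an explicit config scalar.
* The 80% employment rate attenuates patient absenteeism in all grades,
  including the 261-day sight-threatening loss (the source is silent;
  applying it uniformly is the consistent choice).  Caregivers are
  costed at full employment since no caregiver rate is stated.
* Absenteeism: 14/21/28 days for mild/moderate/severe, 261 days for
  sight-threatening, none for BLIND (whose burden enters via pension and
  supportive care only).  Caregiver losses: 10 days (moderate: R2, M1)
  and 28 days (severe: R3).
* The annual disability pension per eligible person (R4, M2, BLIND) is
  not published directly; the default SAR 48,000 is the value implied by
  the published pension component divided by the eligible population
  (17,798,627,918 / 370,804.74 = 48,000.00).

### Aggregation and currency

Totals are exact sums; international-dollar figures divide by the PPP
rate (SAR 1.85 per I$, recoverable as the median ratio of the published
SAR/I$ unit-cost pairs); GDP share divides by SAR 10 trillion (2024,
config-overridable).  A zero grand total is flagged `degenerate` and
shares are reported as 0.

## Sensitivity analysis

Every scalar numeric leaf of the parameter tree — prevalences, unit
costs, adverse-event probabilities, protocol frequencies and
multiplicities, days, wages, rates — is perturbed multiplicatively by
±20% (configurable), the grand total recomputed from scratch each time
(no caching of intermediates), and entries ranked by |high − low|.
Booleans, labels and annotations are never perturbed.  Two clamp rules
keep perturbed configurations valid, both flagged in the output rather
than erroring: a fraction pushed above 1 is capped at 1, and a
perturbation that would push the combined prevalence above
retinopathy + maculopathy (correction factor > 1) caps the combined
prevalence at that sum.

The bundled KSA configuration excludes three cohort-defining
denominators from the tornado via `owsa_exclude`: the adult population,
the diabetic prevalence, and the combined (overlap) prevalence.  These
scale essentially the entire model by construction and would mechanically
occupy the top bars at ±20%; excluding them focuses the analysis on the
severity mix, clinical resource use and prices, and with them excluded
the top-ranked driver is the retinopathy prevalence in the diabetic
population, matching the published ranking.  The enumeration default
remains *all* scalar leaves for any config without an exclusion list.

## Synthetic scenarios and the oracle

`generate_scenario` draws schema-valid random parameterizations: grade
prevalences scaled to a random budget below 1; the combined prevalence
drawn inside [max(ret, mac), ret + mac] so the correction factor is
always in (0, 1]; log-normal unit costs around a scale; protocols of
1–6 lines with mixed frequency kinds; adverse-event probabilities in
[0, 0.5]; absenteeism in [0, 300] days.  All randomness flows from one
explicit seed (no global state), and the same seed yields byte-identical
YAML.  Degenerate shapes are available on demand (`n_grades=0` for an
all-zero severity mix, `n_grades=1`, `n_items=0` for empty protocols).

`oracle_total` recomputes the grand total by a deliberately naive
per-grade, per-line enumeration that shares no code with the engines
(its own annualization arithmetic, wage-tier table and supportive-care
constants).  The pipeline must agree with it to 1e-9 relative on 100
seeded scenarios; this, plus linearity/homogeneity and the partition
identity (component totals = grade totals), is what validates the
engines in place of absolute published component totals.

Scenarios emulate the model's *structure*, not Saudi magnitudes, and
real-data features such as correlated prices, non-stationary
prevalence, or heterogeneous adherence are out of scope — passing tests
demonstrate arithmetic correctness of the accounting model, not
epidemiological validity of any particular configuration.

## Known limitations

* The published per-patient direct costs by grade (e.g. SAR 300,046 for
  R1) exceed any sum derivable from the published unit costs and stated
  frequencies by roughly 4×; the missing driver (eye multiplicity,
  visit intensity, or an unlisted cost) is unknown.  The package
  reports its own internally consistent per-patient values and carries
  the published figures only as reference data; consequently absolute
  medication/resource component totals differ from the published
  breakdown while the cascade, supportive-care, pension and identity
  checks reproduce it.
* Transportation and rehabilitation aids, friction-cost productivity
  valuation, presenteeism and unpaid household work are excluded.
* No probabilistic sensitivity analysis; uncertainty handling is the
  one-way deterministic tornado only.
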