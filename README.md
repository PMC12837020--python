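# visioncost

A prevalence-based cost-of-illness (COI) model for diabetes-related
visual impairment and blindness, built for health economists and
policy analysts.  It re-expresses a deterministic spreadsheet-style
burden model as a tested, config-driven Python package: every input —
population denominators, prevalences, treatment protocols, unit costs,
productivity assumptions — lives in one declarative YAML/JSON file, and
the package turns it into a one-year societal burden estimate with a
full sensitivity analysis.

## The model

**Population cascade.**  Adults × diabetic prevalence gives the diabetic
population *D*; severity-grade populations use the Scottish grading of
diabetic retinopathy (R1 mild non-proliferative … R4 proliferative) and
maculopathy (M1, M2), each a prevalence *p<sub>g</sub>* of *D*.  Because
retinopathy and maculopathy co-occur, grade counts are rescaled by an
overlap correction factor

> CF = P(retinopathy ∪ maculopathy) / (P(retinopathy) + P(maculopathy))

so that *n<sub>g</sub>* = *p<sub>g</sub>* · *D* · CF avoids
double-counting patients with both conditions.  Blindness among
diabetics is carried as its own grade, uncorrected.

**Direct costs.**  Annual per-patient cost per grade = treatment-protocol
resources (each line: annualized frequency × multiplicity × unit cost;
"every 4 weeks" = 52/4 = 13/year) + adverse events costed in expectation
(probability × management-bundle cost) + supportive care (visual aids
for mild/moderate/severe; psychological support and a home-care nurse
for sight-threatening disease and blindness).

**Indirect costs.**  Human capital method: wage/day × lost working days ×
affected persons, for patients (attenuated by an employment rate) and
caregivers, plus government disability pensions for sight-threatening
and blind individuals.

**Aggregation.**  Direct + indirect totals in SAR, converted to
international dollars at a purchasing-power-parity (PPP) rate, and
expressed as a share of GDP.

**Sensitivity.**  A one-way deterministic sensitivity analysis perturbs
every scalar input ±20% and ranks parameters by output span (tornado).

The bundled `ksa_2024.yaml` carries the Saudi-Arabia 2024
parameterization transcribed from published national estimates.
Details, conventions and limitations are in
[docs/methods.md](docs/methods.md).

## Worked example

```python
import visioncost as vc

params = vc.default_ksa_parameters()
cascade = vc.build_cascade(params.population)
print(f"CF = {cascade.correction_factor:.6f}")
print(f"R1 patients = {cascade.grade_counts['R1']:,.2f}")

result = vc.run_model(params)
print("\n".join(result.summary_lines()))
```

prints

```
CF = 0.671533
R1 patients = 337,037.96
Total burden: SAR 121,824,361,775.51 (I$ 65,851,006,365.14)
  Direct:   SAR 88,012,570,163.70 (I$ 47,574,362,250.65; 72%)
  Indirect: SAR 33,811,791,611.81 (I$ 18,276,644,114.49; 28%)
  Share of GDP: 1.2%
```

The cascade reproduces the published population figures (337,037.96
mild-NPDR patients from 22.1% × 2,271,011.24 diabetics × CF).  The cost
totals are the engine's own first-principles aggregation of the
published unit costs and protocol frequencies; the published per-patient
grade costs are not derivable from the printed inputs (see
docs/methods.md), so component totals differ from the published
breakdown while all structural identities hold.

The same pipeline is available from the shell:

```sh
coi run   --config src/visioncost/data/ksa_2024.yaml --outdir out/
coi owsa  --config src/visioncost/data/ksa_2024.yaml --outdir out/ --fraction 0.2
coi synth --seed 1 --outdir out/
coi validate --config src/visioncost/data/ksa_2024.yaml
```

`coi run` writes `summary.json` plus cascade and per-grade cost tables;
`coi owsa` writes the ranked tornado table (`tornado.tsv`) — with the
bundled configuration the top-ranked parameter is the prevalence of
retinopathy in the diabetic population.

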