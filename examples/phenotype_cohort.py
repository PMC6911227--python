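"""Case/control phenotyping with exclusion ranges on a simulated cohort.

Simulates 2,000 patients, maps their ICD-10-CM era events to phecodes,
and assembles a type 2 diabetes cohort (target phecode 250.2 and its
descendants). Patients carrying any phecode in the diabetes exclusion
range 249-250.99 — type 1 diabetes, abnormal glucose, ... — without
qualifying as cases are excluded so they cannot contaminate the control
group; the three sets partition the population exactly.
"""

from phemap import (
    CohortSimConfig,
    Vocabulary,
    build_fixture_bundle,
    build_map,
    define_cases_controls,
    map_events,
    simulate_cohort,
)

bundle = build_fixture_bundle()
pmap = build_map(bundle, Vocabulary.ICD10CM)
sim = simulate_cohort(CohortSimConfig(n_patients=2000, seed=42))

events10 = sim.events[sim.events["vocabulary"] == "ICD10CM"]
assignments, unmapped = map_events(events10, pmap)
population = set(sim.subjects["patient_id"])

exclusions = bundle.exclusion_ranges("250.2")  # [249, 250.99]
cohort = define_cases_controls(assignments, "250.2", exclusions, population)

print(f"population : {len(population)}")
print(f"cases      : {len(cohort.cases)}   (>=1 date with phecode 250.2*)")
print(f"excluded   : {len(cohort.excluded)}   (other diabetes-range phecodes)")
print(f"controls   : {len(cohort.controls)}")
assert len(cohort.cases) + len(cohort.excluded) + len(cohort.controls) \
    == len(population)
print("\ncases + excluded + controls = population: partition holds")
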