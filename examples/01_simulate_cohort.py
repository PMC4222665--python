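"""Generate a synthetic multi-registry cohort and inspect its ground truth.

The generator emulates the five linked regional registries (hospital
discharges, outpatient services, drug dispensings, vaccinations, mortality)
plus patient demographics and census denominators, planting each episode's
subtype *mechanism* (a dialysis service 30 days before admission, a prior
hospital stay, a secondary-only pneumonia code...) rather than a label.
"""

from pneumoclass import GeneratorConfig, generate, validate_bundle

config = GeneratorConfig(seed=7, n_patients=2000)
bundle, truth = generate(config)

print(f"patients:            {len(bundle.patients)}")
print(f"hospital admissions: {len(bundle.admissions)}")
print(f"outpatient services: {len(bundle.outpatient)}")
print(f"death records:       {len(bundle.deaths)}")
print(f"validation findings: {validate_bundle(bundle)}")
print()
print("intended subtype mixture (ground truth):")
print(truth["intended_subtype"].value_counts(normalize=True).round(3).to_string())
print()
print("planted qualifying mechanisms among intended-HCAP episodes:")
hcap = truth[truth["intended_subtype"] == "HCAP"]
print(hcap["mechanism"].value_counts().to_string())
# Each intended-HCAP admission carries exactly one planted healthcare
# contact; CAP/PNP episodes carry none, so the classifier can be scored
# against a causally planted truth.
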