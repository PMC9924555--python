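"""Generate a small synthetic IHC cohort and inspect its truth table.

Builds 4 patients x 4 biomarkers x 2 slides at reduced resolution, writes
slides/masks/manifest/truth to ./cohort_demo, and prints the per-patient
biomarker statuses and molecular subtypes the generator encoded.
"""

from ihcsubtype import synth

spec = synth.CohortSpec(
    n_patients=4, slides_per_patient=2, image_shape=(240, 320), master_seed=1
)
manifest, truth = synth.generate_cohort(spec, "cohort_demo")

print(f"wrote {len(manifest)} slides under cohort_demo/")
print(truth.to_string(index=False))
# Each row is one synthetic patient: ER/PR are Allred-positive or -negative,
# ki67 is the proliferation band, her2_score the membrane score, and subtype
# the molecular subtype those four statuses imply.
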