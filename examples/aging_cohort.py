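"""Synthetic aging cohort: does recovered roughness track age?

Generates 12 subjects whose true Ra rises with age (0.35 um/year plus
subject-level noise), renders a small OCT volume per subject, measures Ra
end-to-end, and runs the cohort correlation analysis.
"""

from octskin import (
    CohortRecord,
    PhantomSpec,
    PipelineConfig,
    cohort_analysis,
    make_cohort,
    run_pipeline,
)

base = PhantomSpec(n_slices=20, n_depth=256, n_lateral=256)
cohort = make_cohort(12, age_range=(15.0, 45.0), slope=0.35, noise_sd=1.5,
                     seed=5, baseline_ra=8.0, base_spec=base)

records = []
for i, (volume, truth, age) in enumerate(cohort):
    rough, optics = run_pipeline(volume, PipelineConfig())
    records.append(CohortRecord(
        subject_id=f"subj{i:02d}", age=age, sex="M" if i % 2 else "F",
        Ra=rough.Ra, Rz=rough.Rz,
        epidermal_thickness=optics.epidermal_thickness,
        attenuation_mu=optics.attenuation_mu,
    ))
    print(f"subj{i:02d}: age {age:5.1f} y  true Ra {truth.true_Ra:6.2f}  "
          f"recovered Ra {rough.Ra:6.2f} um")

table = cohort_analysis(records)
print()
print(table.to_string(index=False))
print("\nA Pearson r above 0.6 for Ra vs age (stratum 'all') is flagged as a "
      "strong positive correlation. Thickness and attenuation were generated "
      "age-independent; any correlation they show reflects measurement "
      "artifacts (e.g. rougher surfaces smear the mean depth profile), "
      "not a generated effect.")
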