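"""Diagnostic classification and symptom prevalence across nested samples.

Active migraineurs are graded against three ICHD-2-style criteria
(duration, pain character, accompanying symptoms): ``full`` migraine meets
all three, ``probable`` misses exactly one.  Three nested case samples of
increasing size but decreasing diagnostic stringency share one control set;
per-symptom prevalences are tabulated for each, and pairwise phi
correlations describe how the ten characteristics co-occur.
"""

import migsel as ms

cohort = ms.gen_cohort(ms.SimConfig(n_participants=21111, seed=11))
classes = ms.classify_cohort(cohort)
print(classes.value_counts().to_string(), "\n")

samples = ms.build_nested_samples(classes)
for level, idx in samples.items():
    print(f"{level:20s} cases={idx['cases'].size:5d}  "
          f"controls={idx['controls'].size}")

print("\nSymptom prevalence by nested sample (count, percent):")
table = ms.prevalence_table(cohort.symptoms, samples)
print(table.to_string())

print("\nPhi correlations among full migraineurs (first 4 items):")
phi = ms.symptom_correlation(cohort.symptoms, samples["full_only"]["cases"])
print(phi.iloc[:4, :4].round(3).to_string())
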