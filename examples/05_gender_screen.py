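"""The mean-by-gender screen: find analytes with > 20% gender difference.

Runs the full default-size pipeline (434 persons x 3 visits, bead assay
in two kit lots), then screens mean expression by gender in the cube --
pooled and per lot -- against the generator's planted truth.
"""

from immunomart.pipeline import (build_study_store, gender_fold_table,
                                 screen_gender_bias)
from immunomart.synthetic import (StudySpec, generate_study_data,
                                  ground_truth_screen)

spec = StudySpec(seed=2012)
study = generate_study_data(spec, families=("luminex",))
store = build_study_store(study)

truth = ground_truth_screen(study.manifest, 20.0)
print("planted analytes (>20% true fold):", sorted(truth))

detected = screen_gender_bias(store, threshold_pct=20.0)
print("detected pooled across lots:     ", sorted(detected))
for lot in spec.lots:
    per_lot = screen_gender_bias(store, 20.0, lot=lot)
    print(f"detected within lot {lot}:      ", sorted(per_lot))

table = gender_fold_table(store).set_index("analyte")
print("\nestimated vs true female/male folds for the planted set:")
for analyte in sorted(truth):
    est = table.loc[analyte, "fold_female_over_male"]
    print(f"  {analyte:8s} est {est:.3f}   true"
          f" {study.manifest.true_folds[analyte]:.2f}")
store.close()

# With the default noise (log-sigma 0.3) and cohort size, the screen
# recovers exactly the planted set, and the effect direction is the same
# in both kit lots even though absolute values differ by the lot factor.
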