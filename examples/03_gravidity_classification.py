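"""Full pipeline: can gravid females be told apart from non-gravid ones?

Simulates an imbalanced two-class dataset (mirroring the ~2:1 imbalance of
the motivating study), then evaluates a linear discriminant classifier with
random under-sampling and repeated 10-fold cross-validation.  The printed
table gives per-class precision/recall/F1 as mean +/- 95% CI over repeats.

Runtime: about half a minute.
"""

from entolidar.pipeline import default_two_class_config, run_pipeline

config = default_two_class_config(seed=1, n_repeats=100, n_per_class=(100, 210))
report = run_pipeline(config, "scratch/example_run")

print(report.to_table_frame().to_string(index=False))
mean, hw = report.overall_accuracy
print(f"\noverall accuracy: {mean:.1f} ± {hw:.2f}%  ({report.n_repeats} repeats)")
# Accuracy well above the 50% chance level shows body depolarization and
# wingbeat frequency jointly carry the gravidity signal; the CI reflects
# only the resampling (under-sampling + fold assignment) variability.
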