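"""Calibrate the knowledge decision tree and evaluate it on held-out plots.

Trains the six-rule hierarchy on 60% of the plots (thresholds are the
minimal-error 1-D splits on each rule feature), classifies the 40% verify
split, and prints the calibrated rules plus the confusion-matrix report.
"""

from vegindex import (DISPLAY_NAMES, SceneConfig, accuracy_report,
                      build_knowledge_tree, confusion_matrix, CLASS_ORDER,
                      default_profiles, optimal_feature_set, simulate_scene,
                      split_train_verify)

stack, _, samples = simulate_scene(
    default_profiles(),
    SceneConfig(shape=(90, 90), plots_per_class="table_mirror", seed=1))
samples = split_train_verify(samples, train_fraction=0.6, seed=1)
features = optimal_feature_set(stack)
tree = build_knowledge_tree(features, samples.subset("train"))

print("calibrated rules (applied in order; leftover pixels -> "
      f"{tree.fallback_class}):")
for r in tree.rules:
    op = ">=" if r.direction == "GE" else "<="
    print(f"  {r.feature:9s} {op} {r.threshold:8.4f}  -> {r.assigned_class}")

verify = features.sample_table(samples.subset("verify"))
pred = tree.predict(verify)
cm = confusion_matrix(pred, verify["class"], CLASS_ORDER)
print("\nverification report:")
print(accuracy_report(cm).format_table(DISPLAY_NAMES))
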