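"""Rank feature importance and prune the feature set.

Gini (mean impurity decrease) importance from a forest trained on the full
15-feature set selects which four features to drop; the retained 11 are
then used to retrain a leaner model.
"""

from wearload import (
    FeatureSetSpec,
    evaluate_model,
    featurize_session,
    generate_session,
    rank_importance,
    select_pruned_spec,
    split_dataset,
    train_model,
)
from wearload.features import prune_features

vectors = featurize_session(generate_session(seed=4), FeatureSetSpec.full())
train_set, valid_set = split_dataset(vectors, seed=0)
model = train_model(train_set, "random_forest", 63, seed=0)

ranking = rank_importance(model)
print("normalized Gini importance (descending):")
for name, value in sorted(ranking.items(), key=lambda kv: -kv[1]):
    print(f"  {name:10s} {value:.4f}")

spec11 = select_pruned_spec(ranking, drop_count=4)
print(f"\nretained {len(spec11)} features; dropped "
      f"{sorted(set(ranking) - set(spec11.names))}")

lean = train_model(prune_features(train_set, spec11), "random_forest", 24, seed=0)
report = evaluate_model(lean, prune_features(valid_set, spec11))
print(f"24-tree model on the pruned set: accuracy {report.overall_accuracy:.3f}")
# Dropping the four least informative statistics keeps accuracy while
# shrinking the model the mobile device must evaluate every second.
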