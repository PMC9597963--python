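"""Interpret a trained model: gain importance, per-guide contributions, trees."""

import crisprboost as cb
from crisprboost.interpret import (
    export_tree,
    feature_importance,
    predict_with_contributions,
    tree_to_dot,
)

cfg = cb.GeneratorConfig(n_guides=1500, seed=2)
ds, _ = cb.simulate_dataset(cfg)
targets = [cb.validate_target(s) for s in ds.frame.sequence30]
thermos = cb.compute_thermo_many(targets, engine=cb.HashStubEngine())
X = cb.featurize_frame(targets, thermos)
y = ds.frame.efficiency.to_numpy()
model = cb.train_final(
    X, y, cb.HyperParams(bagging_fraction=1.0), [120] * 10,
    cv=cb.CVConfig(max_trees=300),
)

table = feature_importance(model)
print("top 10 features by normalized gain (fractions sum to 1):")
for _, r in table.head(10).iterrows():
    print(f"  {r['rank']:>2} {r.feature:<10} {r.gain_fraction:.4f}")

bd = predict_with_contributions(model, X.head(1))[0]
print(f"\none guide's prediction = {bd.prediction:.3f}")
print(f"  = base value {bd.base_value:.3f} (training mean) + feature contributions:")
for name, value in bd.top(5):
    print(f"    {name:<10} {value:+.3f}")

root0 = export_tree(model, 0, max_depth=2)
root1 = export_tree(model, 1, max_depth=1)
print(f"\ntree 0 root internal value = {root0.internal_value:.3f} (grand mean)")
print(f"tree 1 root internal value = {root1.internal_value:.3f} "
      "(later trees fit residuals, so 0)")
print(f"tree 0 root split rule     : {root0.rule}")
print(f"DOT export of tree 0 is {len(tree_to_dot(root0))} characters; "
      "render it with graphviz for a figure.")
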