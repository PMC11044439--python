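"""Classify imbalanced sample groups with and without bagging-SMOTE.

400-vs-40 overlapping classes: mode 1 trains 10 base learners on exactly
balanced bootstrap+SMOTE sets, mode 3 trains one learner on the raw data.
The contrast shows up in minority-class recall on an independent test draw.
"""

from cwgcna.classify import predict_ensemble, train_ensemble
from cwgcna.simulate import simulate_imbalanced_classes

m_train, y_train, _ = simulate_imbalanced_classes(seed=5)
m_test, y_test, _ = simulate_imbalanced_classes(seed=1005)
minority = y_test == "c1"

for mode, name in ((1, "bagging-SMOTE"), (3, "no balancing")):
    model = train_ensemble([m_train], y_train, mode=mode, learner="svm", seed=5)
    pred, _ = predict_ensemble(model, [m_test])
    rec = (pred[minority] == "c1").mean()
    acc = (pred == y_test).mean()
    print(f"mode {mode} ({name}): {model.n_base_learners:2d} base learner(s), "
          f"test accuracy {acc:.3f}, minority recall {rec:.3f}")

print("\nThe unbalanced model buys headline accuracy by collapsing onto the")
print("majority class; bagging-SMOTE trades a few accuracy points for a")
print("many-fold gain in minority recall.")
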