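"""Train and evaluate CRT-response classifiers on a synthetic hybrid cohort.

Generates a 57-patient cohort with the published group-conditional
statistics, preprocesses it (missing-value and collinearity removal),
and compares classifiers/selectors under leave-one-out cross-validation —
then contrasts the hybrid feature set with clinical features only.
"""

from crtpredict import (CohortSpec, MLConfig, evaluate,
                        generate_feature_table, kmeans_clusters, pca_lr,
                        preprocess)

table = preprocess(generate_feature_table(CohortSpec(n=57, seed=7)))
print(f"cohort: {table.data.shape[0]} patients, "
      f"{table.data.shape[1]} features after preprocessing")

print("\nLOO ROC AUC by classifier (univariate feature selection, top 8):")
best = None
for clf in ("LR", "LDA", "SVM", "RF"):
    res = evaluate(table, MLConfig(classifier=clf, selector="UST",
                                   cv="loo", seed=0))
    print(f"  {clf:4s}: AUC = {res.auc:.2f}")
    if best is None or res.auc > best[1].auc:
        best = (clf, res)

clf, res = best
print(f"\nbest classifier {clf}: accuracy {res.accuracy:.2f}, "
      f"sensitivity {res.sensitivity:.2f}, specificity {res.specificity:.2f} "
      f"at Youden cutoff {res.cutoff:.2f}")
top = sorted(res.selection_frequency.items(), key=lambda kv: -kv[1])[:8]
print("most frequently selected features across folds:")
for name, freq in top:
    print(f"  {name:20s} selected in {freq:.0%} of folds")

clin = evaluate(table, MLConfig(classifier="LR", selector="UST", cv="loo",
                                seed=0, provenances=("clinical",)))
print(f"\nclinical-features-only LR: AUC = {clin.auc:.2f} vs {res.auc:.2f} "
      "hybrid.  At the published group statistics the clinical block "
      "already carries signal (EF, BMI); the isolated advantage of the "
      "model-driven block is demonstrated in the acceptance suite with "
      "effects planted on model features only.")

pca = pca_lr(table, n_components_range=[2, 4, 6, 8], criterion="EF10")
print("\nPCA + logistic regression (LOO):")
print(pca.to_string(index=False))

labels, summary, _ = kmeans_clusters(table, k=2, seed=0)
print("\nunsupervised 2-means on the first two PCs:")
print(summary.to_string(index=False))
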