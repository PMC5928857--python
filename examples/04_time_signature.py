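"""Derive the dual-level microenvironment signature and classify samples.

Genes enter the signature when differential (Welch t, P < 0.05) between
subtypes at BOTH the mRNA and the protein level with concordant direction;
samples are then called good/bad by nearest-centroid correlation, and the
continuous score is evaluated as an ROC AUC against the planted labels.
A 24-sample cohort is split into train/test halves.
"""

from timeatlas import SimConfig
from timeatlas.signature import (
    ExpressionMatrix,
    classify_samples,
    derive_signature,
    differential_features,
    evaluate_auc,
)
from timeatlas.simulate import generate_expression_cohort, generate_truth_labels

cfg = SimConfig(n_samples=24, cells_per_sample=100, seed=1)  # 2000 genes, 137 planted
truth = generate_truth_labels(cfg)
mrna, protein, planted = generate_expression_cohort(cfg, truth)

train = list(truth[truth == "I"].index[:6]) + list(truth[truth == "II"].index[:6])
test = [s for s in truth.index if s not in train]
mrna_tr = ExpressionMatrix(values=mrna.values[train], level="mRNA")
prot_tr = ExpressionMatrix(values=protein.values[train], level="protein")

diff_m = differential_features(mrna_tr, truth[train])
diff_p = differential_features(prot_tr, truth[train])
print("mRNA hits (p < 0.05) in the 6+6 training half:", int((diff_m["p"] < 0.05).sum()))

sig = derive_signature(diff_m, diff_p, mrna_tr, truth[train])
tp = len(set(sig.genes) & set(planted))
print("signature genes:", len(sig.genes),
      "| recall vs planted: %.2f | precision: %.2f" % (tp / len(planted), tp / len(sig.genes)))

calls = classify_samples(sig, ExpressionMatrix(values=mrna.values[test], level="mRNA"))
accuracy = sum(
    (c.label == "good_TiME") == (truth[c.sample_id] == "I") for c in calls
) / len(calls)
print("held-out classification accuracy (n=%d):" % len(calls), accuracy)

auc = evaluate_auc(
    [c.score for c in calls],
    [int(truth[c.sample_id] == "I") for c in calls],
)
print("ROC AUC of the continuous score:", auc)
# Accuracy/AUC near 1 reflect the strong planted effect (3 SD per gene at
# both molecular levels); with signature_effect=0 they fall to chance.
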