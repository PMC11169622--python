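"""Train the binding classifier with 5-fold cross-validation.

Simulates a corpus with a planted 2-sigma mean shift, assembles features
(embedding + disorder channel), trains one feed-forward model per fold
with three-group under-sampling, and reports each fold's selected
decision cutoff and validation MCC over disordered residues.
"""

import numpy as np

from idrbind.evaluation import binarize, confusion_counts, metric
from idrbind.features import assemble_features
from idrbind.models import ModelConfig, make_folds, predict_scores, train_model
from idrbind.synthetic import SyntheticConfig, generate_embeddings, generate_proteins

config = SyntheticConfig(n_proteins=80, m=32, k_informative=8,
                         effect_size=2.0, seed=1)
records = generate_proteins(config)
embeddings = generate_embeddings(records, config)
features = {r.id: assemble_features(embeddings[r.id], r.disorder_mask)
            for r in records}
labels = {r.id: r.binding_mask.astype(float) for r in records}
disorder = {r.id: r.disorder_mask for r in records}

split = make_folds([r.id for r in records], k=5, seed=0)
model_config = ModelConfig(input_dim=config.m + 1, hidden_units=32,
                           max_epochs=25, seed=0)

print("fold  epochs  cutoff  val MCC (disordered residues)")
for fold in range(5):
    model = train_model(features, labels, disorder, model_config, split,
                        val_fold=fold)
    val_ids = split.fold_ids(fold)
    y = np.concatenate([labels[i] for i in val_ids]) > 0
    d = np.concatenate([disorder[i] for i in val_ids]).astype(bool)
    scores = np.concatenate([predict_scores(model, features[i])
                             for i in val_ids])
    counts = confusion_counts(y, binarize(scores, model.cutoff), d)
    print(f"  {fold}     {len(model.history):3d}    {model.cutoff:.2f}"
          f"    {metric(counts, 'mcc'):.3f}")
# Each fold selects its own cutoff on its validation fold (balanced-
# accuracy grid search); MCC well above 0 shows the planted signal is
# recovered from the embeddings.
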