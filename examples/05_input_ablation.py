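"""Input-feature ablation: which dimensions drive the prediction?

Trains a model on synthetic embeddings where only the first 4 of 16
dimensions carry signal, then zeroes each input column in turn and
measures the MCC drop on validation disordered residues.  The planted
dimensions and the disorder channel (the last input, index m) should
dominate.
"""

import numpy as np

from idrbind.features import assemble_features
from idrbind.models import ModelConfig, ablate_input, make_folds, train_model
from idrbind.synthetic import SyntheticConfig, generate_embeddings, generate_proteins

config = SyntheticConfig(n_proteins=40, m=16, k_informative=4,
                         effect_size=2.5, seed=3)
records = generate_proteins(config)
embeddings = generate_embeddings(records, config)
features = {r.id: assemble_features(embeddings[r.id], r.disorder_mask)
            for r in records}
labels = {r.id: r.binding_mask.astype(float) for r in records}
disorder = {r.id: r.disorder_mask for r in records}

split = make_folds([r.id for r in records], k=5, seed=0)
model = train_model(features, labels, disorder,
                    ModelConfig(input_dim=config.m + 1, hidden_units=24,
                                max_epochs=25, seed=0),
                    split, val_fold=0)

val_ids = split.fold_ids(0)
feats = np.concatenate([features[i] for i in val_ids])
y = np.concatenate([labels[i] for i in val_ids])
d = np.concatenate([disorder[i] for i in val_ids])

importances = [ablate_input(model, feats, y, d, dim)
               for dim in range(config.m + 1)]
order = np.argsort(importances)[::-1]
print("rank  input dim  MCC drop   (dims 0-3 informative, dim 16 = disorder)")
for rank, dim in enumerate(order[:6], 1):
    tag = ("planted" if dim < 4
           else "disorder channel" if dim == config.m else "noise")
    print(f"  {rank}      {dim:3d}     {importances[dim]:+.3f}   {tag}")
# Zeroing an informative column costs MCC; zeroing a pure-noise column
# should cost nothing.
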