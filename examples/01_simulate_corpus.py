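"""Generate a synthetic annotated corpus with planted binding signal.

Builds 60 proteins with disordered regions, binding sub-regions inside
them, and per-residue embeddings in which binding residues carry a mean
shift on a few dimensions.  Prints the realized corpus statistics that
the generator steers toward: about half the proteins positive, binding
covering ~38% of disordered residues, and long binding stretches.
"""

import numpy as np

from idrbind.evaluation import segment_regions
from idrbind.records import protein_class
from idrbind.synthetic import SyntheticConfig, generate_embeddings, generate_proteins

config = SyntheticConfig(n_proteins=60, m=32, k_informative=8,
                         effect_size=2.0, seed=7)
records = generate_proteins(config)
embeddings = generate_embeddings(records, config)

n_pos = sum(protein_class(r) == "positive" for r in records)
n_dis = sum(r.n_disordered for r in records)
n_bind = sum(r.n_binding for r in records)
run_lengths = []
for rec in records:
    _, stats = segment_regions(rec.binding_mask)
    run_lengths.extend(stats.lengths)

print(f"proteins:                 {len(records)} ({n_pos} positive)")
print(f"median length:            {int(np.median([len(r) for r in records]))}")
print(f"disordered residues:      {n_dis}")
print(f"binding / disordered:     {n_bind / n_dis:.3f}  (target 0.38)")
print(f"binding region lengths:   mean {np.mean(run_lengths):.0f}, "
      f"median {np.median(run_lengths):.0f}")
print(f"embedding shape (first):  {embeddings[records[0].id].shape}")
# The binding fraction sits near the curated-corpus value of 38%, and the
# binding annotations form long stretches rather than isolated residues.
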