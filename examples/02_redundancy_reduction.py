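"""Redundancy-reduce a protein set with the HSSP-value criterion.

Creates three mutated copies of one sequence plus three unrelated
sequences, then removes every pair whose percent identity exceeds the
length-dependent homology threshold (HVAL > 0).  The family collapses to
one representative; unrelated sequences survive.
"""

import numpy as np

from idrbind.records import ProteinRecord
from idrbind.redundancy import align_pair, hssp_threshold, hval, reduce_within

rng = np.random.default_rng(0)
letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

base = list(rng.choice(letters, size=260))
records = []
for i, n_subs in enumerate((0, 10, 25)):  # a family: 0/10/25 substitutions
    seq = base.copy()
    for j in rng.choice(260, size=n_subs, replace=False):
        seq[j] = str(rng.choice(letters))
    records.append(ProteinRecord(f"FAM{i}", "".join(seq),
                                 np.zeros(260, int), np.zeros(260, int)))
for i in range(3):  # unrelated random sequences
    seq = "".join(rng.choice(letters, size=260))
    records.append(ProteinRecord(f"UNREL{i}", seq,
                                 np.zeros(260, int), np.zeros(260, int)))

print(f"threshold at alignment length 250: {hssp_threshold(250):.2f}% identity")
stats = align_pair(records[0].sequence, records[1].sequence)
print(f"FAM0 vs FAM1: PIDE {stats.pide:.1f}% over {stats.ali_length} columns, "
      f"HVAL {hval(stats):+.1f}")

result = reduce_within(records)
print(f"retained: {[r.id for r in result.retained]}")
print(f"removed:  {result.removed}")
# A pair is redundant when its identity exceeds the twilight-zone curve;
# greedy hub removal keeps one family member and all unrelated proteins.
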