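"""Reference bookkeeping of the curated corpora this pipeline targets.

The model family was developed on corpora curated from MobiDB entries
with manually curated disorder and binding annotations.  The headline
counts of that curation are recorded here as package constants: they
document the study conditions (class balance, corpus sizes, per-fold
decision cutoffs) that the synthetic generator defaults and the random
baseline frequency are steered to, and they let the bookkeeping be
checked arithmetically without any data download.
"""

from __future__ import annotations

__all__ = [
    "CURATED_CORPUS",
    "TRAIN_SET",
    "TEST_SET",
    "CAID2_BINDING",
    "PER_FOLD_CUTOFFS",
    "INFERENCE_CUTOFF",
    "binding_fraction",
    "nonbinding_fraction",
]

#: Full curated corpus before splitting (proteins with manually curated
#: disorder and binding annotations; extreme-length outliers excluded).
CURATED_CORPUS = {
    "n_proteins": 2816,
    "disordered_residues": 188_940,
    "binding_disordered": 71_818,  # positives: disordered and binding
    "nonbinding_disordered": 117_122,  # negatives: disordered, non-binding
    "max_length": 10_000,
    "excluded_outlier_length": 34_350,  # titin Q8WZ42
}

#: Final training split ("Mobi2k"): 5-fold cross-validation corpus.
TRAIN_SET = {
    "n_proteins": 1780,
    "positives": 697,
    "negatives": 1083,
    "binding_disordered": 64_228,
    "nonbinding_disordered": 101_381,
    # intermediate bookkeeping of the split construction
    "positives_before_rebalance": 679,
    "negatives_before_rebalance": 1083,
    "n_before_rebalance": 1762,
    "moved_from_test": 18,
}

#: Held-out test split ("Mobi195").
TEST_SET = {
    "n_proteins": 195,
    "positives": 80,
    "negatives": 115,
    "binding_disordered": 6657,
    "nonbinding_disordered": 11_644,
    "positives_before_rebalance": 98,
}

#: Community blind benchmark (binding-in-disorder subset).
CAID2_BINDING = {"n_proteins": 78, "binding_residues": 8209}

#: Per-fold decision cutoffs of the published cross-validation models.
PER_FOLD_CUTOFFS = (0.55, 0.40, 0.50, 0.35, 0.30)

#: Cutoff of the released single-fold inference model (strict ">" rule).
INFERENCE_CUTOFF = 0.30


def binding_fraction(counts: dict) -> float:
    """Fraction of disordered residues annotated binding in a corpus."""
    total = counts["binding_disordered"] + counts["nonbinding_disordered"]
    return counts["binding_disordered"] / total


def nonbinding_fraction(counts: dict) -> float:
    return 1.0 - binding_fraction(counts)
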