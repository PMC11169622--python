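"""Synthetic annotated proteins and embeddings with planted ground truth.

Real inputs to this pipeline — curated disorder/binding annotations and
protein-language-model embeddings — cannot be bundled, so every pipeline
stage is exercised on generated data whose signal structure is known in
closed form.  The generator emulates the curated corpus statistics:

* protein lengths log-normal with median 399 residues (the median length
  of a disordered training protein),
* disorder arranged in contiguous regions (positives carry more disorder
  than negatives), binding sub-regions strictly inside disorder with
  log-normal lengths steered to mean ~74 / median ~41 residues,
* the global binding fraction among disordered residues steered to a
  target of 38% by proportional allocation across positive proteins,
* about half the proteins positive (at least one binding region).

Embeddings are class-conditional Gaussians: baseline noise of standard
deviation ``noise_sd``, plus a mean shift of ``effect_size *
noise_sd`` on the first ``k_informative`` of ``m`` dimensions for binding
residues, optionally AR(1)-smoothed along the chain (applied to the noise
so the class-conditional means stay exact).  A mean-shift signal keeps
separability analytic; by default embeddings do not depend on residue
identity, which makes amino-acid-property baselines a deliberate
negative control.  Everything is deterministic per seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np

from .records import ProteinRecord, store_embeddings, write_annotated_fasta

__all__ = [
    "SyntheticConfig",
    "generate_proteins",
    "generate_embeddings",
    "SyntheticEmbedder",
    "write_fixture_dataset",
]

_LETTERS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclasses.dataclass
class SyntheticConfig:
    """Study conditions for the synthetic corpus.

    Length/region parameters mirror the curated corpus statistics (median
    protein length 399; binding stretches mean ~74 / median ~41; binding
    38% of disordered residues); embedding parameters control planted
    signal strength.
    """

    n_proteins: int = 200
    length_median: float = 399.0
    length_sigma: float = 0.6
    min_length: int = 60
    max_length: int = 5000
    positive_fraction: float = 0.5
    disorder_fraction_positive: float = 0.5
    disorder_fraction_negative: float = 0.3
    disorder_region_median: float = 60.0
    disorder_region_sigma: float = 0.8
    min_disorder_region: int = 10
    binding_region_mean: float = 74.0
    binding_region_median: float = 41.0
    binding_fraction: float = 0.38
    m: int = 64
    k_informative: int = 10
    effect_size: float = 2.0
    noise_sd: float = 1.0
    autocorr: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.m < 1 or self.k_informative < 0:
            raise ValueError("counts must be positive")
        if self.k_informative > self.m:
            raise ValueError("k_informative cannot exceed embedding dim m")
        if not (0.0 <= self.autocorr < 1.0):
            raise ValueError("autocorr must be in [0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect size must be >= 0")
        if not (0.0 <= self.binding_fraction <= 1.0):
            raise ValueError("binding_fraction must be in [0, 1]")
        if self.binding_fraction > 0 and (
            self.positive_fraction == 0 or self.disorder_fraction_positive == 0
        ):
            raise ValueError(
                "infeasible config: binding requested but no positive "
                "proteins / no disorder to place it in"
            )
        if self.binding_region_mean < self.binding_region_median:
            raise ValueError("log-normal requires mean >= median")

    @property
    def binding_sigma(self) -> float:
        """Log-normal sigma implied by the (mean, median) pair."""
        return math.sqrt(
            2.0 * math.log(self.binding_region_mean / self.binding_region_median)
        )


def _lognormal_int(rng, median: float, sigma: float, low: int, high: int) -> int:
    value = rng.lognormal(mean=math.log(median), sigma=sigma)
    return int(np.clip(round(value), low, high))


def _place_regions(rng, L: int, target: int, median: float, sigma: float,
                   min_len: int) -> np.ndarray:
    """Non-overlapping regions covering ~``target`` of ``L`` residues."""
    mask = np.zeros(L, dtype=np.uint8)
    if target <= 0:
        return mask
    lengths: list[int] = []
    while sum(lengths) < target:
        lengths.append(_lognormal_int(rng, median, sigma, min_len, L))
    excess = sum(lengths) - target
    lengths[-1] -= excess
    if lengths[-1] < 1:
        lengths.pop()
    total = sum(lengths)
    if total > L:  # short protein: one region spanning the target
        lengths = [min(target, L)]
        total = lengths[0]
    # distribute the slack uniformly among the gaps (stars and bars)
    n_gaps = len(lengths) + 1
    slack = L - total
    cuts = np.sort(rng.integers(0, slack + 1, size=n_gaps - 1))
    gaps = np.diff(np.concatenate(([0], cuts, [slack])))
    pos = 0
    for gap, length in zip(gaps, lengths):
        pos += int(gap)
        mask[pos : pos + length] = 1
        pos += length
    return mask


def _regions_of(mask: np.ndarray) -> list[tuple[int, int]]:
    b = np.flatnonzero(np.diff(np.concatenate(([0], mask, [0]))))
    return [(int(s), int(e)) for s, e in zip(b[::2], b[1::2])]


def generate_proteins(config: SyntheticConfig,
                      seed: int | None = None) -> list[ProteinRecord]:
    """Generate annotated proteins matching the configured corpus statistics.

    Disorder regions never overlap; binding regions sit strictly inside
    disorder; the realized global binding fraction among disordered
    residues tracks ``config.binding_fraction`` by proportional
    allocation.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_pos = int(round(config.n_proteins * config.positive_fraction))
    if config.binding_fraction == 0:
        n_pos = 0
    is_positive = np.zeros(config.n_proteins, dtype=bool)
    is_positive[rng.choice(config.n_proteins, size=n_pos, replace=False)] = True

    lengths = [
        _lognormal_int(rng, config.length_median, config.length_sigma,
                       config.min_length, config.max_length)
        for _ in range(config.n_proteins)
    ]
    disorder_masks = []
    for i, L in enumerate(lengths):
        frac = (config.disorder_fraction_positive if is_positive[i]
                else config.disorder_fraction_negative)
        target = int(round(frac * L))
        disorder_masks.append(
            _place_regions(rng, L, target, config.disorder_region_median,
                           config.disorder_region_sigma,
                           config.min_disorder_region)
        )

    d_total = sum(int(m.sum()) for m in disorder_masks)
    d_pos = sum(int(m.sum()) for i, m in enumerate(disorder_masks)
                if is_positive[i])
    b_total = int(round(config.binding_fraction * d_total))

    records = []
    for i, L in enumerate(lengths):
        dmask = disorder_masks[i]
        bmask = np.zeros(L, dtype=np.uint8)
        if is_positive[i] and d_pos > 0 and b_total > 0:
            quota = max(1, int(round(b_total * int(dmask.sum()) / d_pos)))
            quota = min(quota, int(dmask.sum()))
            need = quota
            regions = _regions_of(dmask)
            rng.shuffle(regions)
            # first pass: one log-normal stretch per disorder region
            for start, end in regions:
                if need <= 0:
                    break
                span = end - start
                run = _lognormal_int(rng, config.binding_region_median,
                                     config.binding_sigma, 1, span)
                run = min(run, need)
                offset = int(rng.integers(0, span - run + 1))
                bmask[start + offset : start + offset + run] = 1
                need = quota - int(bmask.sum())
            # fallback: fill remaining disordered positions to hit the quota
            if need > 0:
                free = np.flatnonzero(dmask.astype(bool) & ~bmask.astype(bool))
                bmask[free[:need]] = 1
        seq = "".join(rng.choice(_LETTERS, size=L))
        records.append(
            ProteinRecord(id=f"SYN{i:04d}", sequence=seq,
                          disorder_mask=dmask, binding_mask=bmask)
        )
    return records


def _ar1(rng, shape, rho: float) -> np.ndarray:
    """Stationary AR(1) noise along axis 0, unit marginal variance."""
    eps = rng.standard_normal(shape)
    if rho == 0.0:
        return eps
    out = np.empty_like(eps)
    out[0] = eps[0]
    scale = math.sqrt(1.0 - rho * rho)
    for t in range(1, shape[0]):
        out[t] = rho * out[t - 1] + scale * eps[t]
    return out


def generate_embeddings(records, config: SyntheticConfig,
                        seed: int | None = None) -> dict[str, np.ndarray]:
    """Per-residue embedding matrices with planted class signal.

    Binding residues receive a mean shift of ``effect_size * noise_sd``
    on the first ``k_informative`` dimensions; the noise is optionally
    AR(1)-correlated along the chain.  Returns ``id -> L x m float32``.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    out: dict[str, np.ndarray] = {}
    shift = config.effect_size * config.noise_sd
    for rec in records:
        noise = _ar1(rng, (len(rec), config.m), config.autocorr)
        emb = noise * config.noise_sd
        if config.k_informative > 0:
            emb[rec.binding_mask.astype(bool), : config.k_informative] += shift
        out[rec.id] = emb.astype(np.float32)
    return out


class SyntheticEmbedder:
    """Pluggable embedder producing deterministic per-sequence noise.

    Satisfies the embedder interface used by the feature assembly: the
    matrix depends only on (sequence, seed), so repeated calls agree.
    With ``identity_linked=True`` each amino acid contributes a fixed
    per-letter mean vector, giving sequence-derived baselines something
    to learn from.
    """

    def __init__(self, m: int = 64, seed: int = 0, noise_sd: float = 1.0,
                 identity_linked: bool = False):
        if m < 1:
            raise ValueError("m must be >= 1")
        self.m = m
        self.seed = seed
        self.noise_sd = noise_sd
        self.identity_linked = identity_linked
        letter_rng = np.random.default_rng(seed + 7919)
        self._letter_means = {
            letter: letter_rng.standard_normal(m)
            for letter in "ACDEFGHIKLMNPQRSTVWYX"
        }

    def embed(self, sequence: str) -> np.ndarray:
        if not sequence:
            raise ValueError("cannot embed an empty sequence")
        import zlib

        key = zlib.crc32(sequence.encode())
        rng = np.random.default_rng((self.seed, key))
        emb = rng.standard_normal((len(sequence), self.m)) * self.noise_sd
        if self.identity_linked:
            emb += np.stack([self._letter_means[c] for c in sequence.upper()])
        return emb.astype(np.float32)


def write_fixture_dataset(directory, records, embeddings,
                          config: SyntheticConfig) -> None:
    """Write a complete fixture: annotated FASTA + HDF5 store + config JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_annotated_fasta(records, directory / "proteins.fasta")
    store = directory / "embeddings.h5"
    if store.exists():
        store.unlink()
    for rec in records:
        store_embeddings(store, rec.id, embeddings[rec.id])
    (directory / "config.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=2, sort_keys=True) + "\n"
    )
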