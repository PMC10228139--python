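"""AIS count fingerprints and Tanimoto similarity.

Because every AIS atomic token already names an atom-centred circular
fragment, dropping the structural tokens of an AIS sequence and counting
what remains yields a count fingerprint directly — no hashing, no fixed
bit length. Count-mode Tanimoto between two such fingerprints is the
min/max (generalized) coefficient

    T(a, b) = sum_k min(a_k, b_k) / sum_k max(a_k, b_k)

over the union of token keys; binary mode is the usual |A∩B| / |A∪B| on
the key sets. Count mode is the default: the fingerprint is defined by
token frequencies, so discarding multiplicity loses information. Binary
mode is kept for comparability with bit-vector fingerprints.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from random import Random

import numpy as np

from .errors import UsageError
from .tokenizers import MoleculeSet, TokenSequence, ais_tokenize

__all__ = [
    "AisFingerprint",
    "SimilarityDistribution",
    "ais_fingerprint",
    "tanimoto",
    "pairwise_similarity_distribution",
]


@dataclass(frozen=True)
class AisFingerprint:
    """Frequency of each atomic AIS token in one molecule."""

    counts: dict[str, int]

    @property
    def n_atoms(self) -> int:
        return sum(self.counts.values())

    @classmethod
    def from_sequence(cls, seq: TokenSequence) -> "AisFingerprint":
        if seq.scheme != "ais":
            raise UsageError("fingerprints are defined on AIS token sequences")
        return cls(dict(Counter(seq.atomic_tokens)))


def ais_fingerprint(smiles: str) -> AisFingerprint:
    """Count fingerprint of a molecule: atomic AIS tokens and their frequency."""
    return AisFingerprint.from_sequence(ais_tokenize(smiles))


def tanimoto(a: AisFingerprint, b: AisFingerprint, mode: str = "count") -> float:
    """Tanimoto similarity of two fingerprints, in [0, 1].

    ``count`` (default): min/max coefficient on frequencies. ``binary``:
    Jaccard on the token key sets.
    """
    if not a.counts and not b.counts:
        raise UsageError("tanimoto of two empty fingerprints is undefined")
    if not a.counts or not b.counts:
        return 0.0
    if mode == "count":
        keys = a.counts.keys() | b.counts.keys()
        num = sum(min(a.counts.get(k, 0), b.counts.get(k, 0)) for k in keys)
        den = sum(max(a.counts.get(k, 0), b.counts.get(k, 0)) for k in keys)
        return num / den
    if mode == "binary":
        sa, sb = set(a.counts), set(b.counts)
        return len(sa & sb) / len(sa | sb)
    raise UsageError(f"unknown tanimoto mode {mode!r} (count or binary)")


@dataclass(frozen=True)
class SimilarityDistribution:
    """Binned pairwise-similarity density over [0, 1]."""

    bin_edges: np.ndarray        # length n_bins + 1
    counts: np.ndarray           # integer counts per bin
    n_pairs: int
    mode: str
    seed: int

    @property
    def density(self) -> np.ndarray:
        widths = np.diff(self.bin_edges)
        return self.counts / (self.counts.sum() * widths)

    @property
    def modal_similarity(self) -> float:
        """Centre of the densest bin — the most probable pair similarity."""
        i = int(np.argmax(self.counts))
        return float((self.bin_edges[i] + self.bin_edges[i + 1]) / 2)

    def to_table(self) -> "list[tuple[float, float, int, float]]":
        """Plot-ready rows (bin_lo, bin_hi, count, density)."""
        dens = self.density
        return [(float(self.bin_edges[i]), float(self.bin_edges[i + 1]),
                 int(self.counts[i]), float(dens[i]))
                for i in range(len(self.counts))]


def pairwise_similarity_distribution(mols: MoleculeSet, n_pairs: int,
                                     seed: int, *, mode: str = "count",
                                     n_bins: int = 100,
                                     ) -> SimilarityDistribution:
    """Distribution of Tanimoto similarities over random molecule pairs.

    Samples ``n_pairs`` unordered pairs uniformly without replacement,
    deterministically under ``seed``, and bins the similarities into
    ``n_bins`` equal-width bins on [0, 1].
    """
    if len(mols) < 2:
        raise UsageError("need at least two molecules for pairwise similarity")
    all_pairs = list(combinations(range(len(mols)), 2))
    if n_pairs > len(all_pairs):
        raise UsageError(
            f"n_pairs={n_pairs} exceeds the {len(all_pairs)} unordered pairs")
    rng = Random(seed)
    chosen = rng.sample(all_pairs, n_pairs)
    fps = [ais_fingerprint(s) for s in mols]
    sims = np.array([tanimoto(fps[i], fps[j], mode) for i, j in chosen])
    if np.all(sims == 1.0):
        warnings.warn("all sampled pairs are identical fingerprints; the "
                      "distribution is a point mass at 1", stacklevel=2)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(sims, bins=edges)
    return SimilarityDistribution(edges, counts, n_pairs, mode, seed)
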