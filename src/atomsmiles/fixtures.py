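"""Bundled molecule sets and synthetic input generators.

Everything the rest of the package needs for testing and demonstration is
generated here with no external downloads: pinned molecule sets spanning
drug-like, chain, ring and isomer regimes; seeded random SMILES
enumeration (random atom-order restarts of the writer); and a builder for
canonicalization training pairs — (non-canonical source, canonical
target) records with xk augmentation, the shape of data used to train
sequence models that learn the canonical form.

Seeding: one integer seed drives the whole run; each molecule gets a
substream derived from the seed and a stable hash of its canonical
SMILES, so reordering a set never changes any molecule's outputs.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from pathlib import Path
from random import Random

from rdkit import Chem

from . import _fixture_data
from .errors import UsageError
from .tokenizers import (
    MoleculeSet,
    ais_tokenize,
    atomwise_tokenize,
    canonical_smiles,
)

__all__ = [
    "FIXTURE_SETS",
    "CanonPairSet",
    "load_fixture_set",
    "enumerate_random_smiles",
    "make_canonicalization_pairs",
    "write_pair_files",
    "filter_by_token_length",
]

logger = logging.getLogger(__name__)

FIXTURE_SETS: dict[str, tuple[str, ...]] = {
    "druglike_small": _fixture_data.DRUGLIKE_SMALL,
    "linear_chains": _fixture_data.LINEAR_CHAINS,
    "ring_probes": _fixture_data.RING_PROBES,
    "octane_isomers": _fixture_data.OCTANE_ISOMERS,
}

#: Default maximum token count for the sequence-length filter.
DEFAULT_MAX_TOKENS = 150


@dataclass(frozen=True)
class CanonPairSet:
    """Aligned (non-canonical source, canonical target) SMILES pairs."""

    pairs: tuple[tuple[str, str], ...]
    augmentation: int
    seed: int


def load_fixture_set(name: str) -> MoleculeSet:
    """Return a pinned bundled molecule set by name."""
    try:
        smiles = FIXTURE_SETS[name]
    except KeyError:
        raise UsageError(
            f"unknown fixture set {name!r}; available: "
            + ", ".join(sorted(FIXTURE_SETS))) from None
    return MoleculeSet(name=name, smiles=smiles, origin="fixture")


def _substream(seed: int, canonical: str) -> Random:
    """Per-molecule RNG independent of set ordering."""
    return Random((seed * 1_000_003 + zlib.crc32(canonical.encode())) % 2**31)


def enumerate_random_smiles(smiles: str, n: int, seed: int) -> list[str]:
    """Draw ``n`` random SMILES writings of one molecule (with replacement).

    Each output is produced by renumbering the atoms with a seeded random
    permutation and writing non-canonically, so all outputs parse to the
    same canonical form as the input.
    """
    if n < 1:
        raise UsageError("n must be >= 1")
    canonical = canonical_smiles(smiles)
    mol = Chem.MolFromSmiles(canonical)
    rng = _substream(seed, canonical)
    n_atoms = mol.GetNumAtoms()
    out = []
    for _ in range(n):
        perm = list(range(n_atoms))
        rng.shuffle(perm)
        out.append(Chem.MolToSmiles(Chem.RenumberAtoms(mol, perm),
                                    canonical=False))
    return out


def make_canonicalization_pairs(mols: MoleculeSet, augmentation: int,
                                seed: int) -> CanonPairSet:
    """Emit ``augmentation`` (source, target) pairs per molecule.

    Sources are random enumerations, distinct where the molecule admits
    enough of them; molecules with fewer distinct writings than requested
    fall back to sampling with replacement (logged). Targets are the
    pinned canonical form.
    """
    if augmentation < 1:
        raise UsageError("augmentation must be >= 1")
    pairs: list[tuple[str, str]] = []
    for s in mols:
        target = canonical_smiles(s)
        # oversample, then keep the first k distinct sources
        candidates = enumerate_random_smiles(s, 20 * augmentation, seed)
        distinct: list[str] = []
        for c in candidates:
            if c not in distinct:
                distinct.append(c)
            if len(distinct) == augmentation:
                break
        if len(distinct) < augmentation:
            logger.info(
                "%s admits only %d distinct enumerations; sampling with "
                "replacement to reach %d", target, len(distinct), augmentation)
            distinct = candidates[:augmentation]
        pairs.extend((src, target) for src in distinct)
    return CanonPairSet(tuple(pairs), augmentation, seed)


def write_pair_files(pair_set: CanonPairSet, out_prefix: str | Path,
                     scheme: str = "ais") -> list[Path]:
    """Write aligned source/target .smi files and their tokenized variants.

    Produces ``<prefix>.src.smi``, ``<prefix>.tgt.smi``, ``<prefix>.src.tok``
    and ``<prefix>.tgt.tok`` (one record per line, line-aligned).
    """
    tokenize = ais_tokenize if scheme == "ais" else atomwise_tokenize
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = [prefix.with_suffix(prefix.suffix + ext)
             for ext in (".src.smi", ".tgt.smi", ".src.tok", ".tgt.tok")]
    src = [p for p, _ in pair_set.pairs]
    tgt = [t for _, t in pair_set.pairs]
    columns = [src, tgt,
               [tokenize(s).token_string() for s in src],
               [tokenize(t).token_string() for t in tgt]]
    for path, lines in zip(paths, columns):
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return paths


def filter_by_token_length(smiles: list[str], scheme: str = "ais",
                           max_tokens: int = DEFAULT_MAX_TOKENS) -> list[str]:
    """Drop records whose token sequence exceeds ``max_tokens`` tokens."""
    tokenize = ais_tokenize if scheme == "ais" else atomwise_tokenize
    return [s for s in smiles if len(tokenize(s)) <= max_tokens]
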