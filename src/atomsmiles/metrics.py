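"""Token-repetition statistics.

The single-token repetition count rep-l of a token sequence s counts the
positions whose token already occurred among the preceding w tokens,

    rep-l = sum over t of [ s_t in s_{t-w} .. s_{t-1} ],

with the window w unbounded by default ("as large as the maximum sequence
length"), in which case rep-l = |s| - (number of distinct tokens). The
normalized repetition rate rep-l / |s| measures how repetitive — hence how
little expressive — a tokenization scheme is for a molecule; repetitive
token streams feed the degeneration loops familiar from neural text
generation. Repetition is counted over the full token sequence including
structural tokens; ``atoms_only=True`` restricts it to atomic tokens for
sensitivity checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .errors import UsageError
from .tokenizers import MoleculeSet, TokenSequence, ais_tokenize, atomwise_tokenize

__all__ = [
    "RepetitionReport",
    "DatasetRepSummary",
    "rep_l",
    "normalized_repetition",
    "dataset_rep_summary",
    "excess_repetition",
    "is_degenerate",
]

#: Table-4 style screening threshold on rep-l(prediction) - rep-l(ground truth).
DEFAULT_EXCESS_THRESHOLD = 2


@dataclass(frozen=True)
class RepetitionReport:
    rep_l: int
    length: int
    window: int | None          # None = unbounded
    smiles: str | None = None

    @property
    def normalized(self) -> float:
        return self.rep_l / self.length


@dataclass(frozen=True)
class DatasetRepSummary:
    per_molecule: tuple[RepetitionReport, ...]
    mean: float
    deviation: float            # sample standard deviation (0 for singletons)
    scheme: str


def _tokenize(smiles: str, scheme: str) -> TokenSequence:
    if scheme == "atomwise":
        return atomwise_tokenize(smiles)
    if scheme == "ais":
        return ais_tokenize(smiles)
    raise UsageError(f"unknown scheme {scheme!r} (expected atomwise or ais)")


def rep_l(tokens: Sequence[str], window: int | None = None) -> RepetitionReport:
    """Count single-token repeats within a preceding window.

    Position t (1-based) contributes 1 when its token occurs among the
    previous min(window, t-1) tokens. ``window=None`` means unbounded,
    where the count equals ``len(tokens) - len(set(tokens))``.
    """
    tokens = list(tokens)
    if not tokens:
        raise UsageError("rep_l requires a non-empty token sequence")
    if window is not None and window < 1:
        raise UsageError("window must be >= 1 or None (unbounded)")
    if window is None:
        count = len(tokens) - len(set(tokens))
    else:
        count = 0
        for t, tok in enumerate(tokens):
            if tok in tokens[max(0, t - window):t]:
                count += 1
    return RepetitionReport(rep_l=count, length=len(tokens), window=window)


def normalized_repetition(smiles: str, scheme: str, *,
                          window: int | None = None,
                          atoms_only: bool = False) -> float:
    """Normalized repetition rate rep-l / |s| of one molecule."""
    seq = _tokenize(smiles, scheme)
    tokens = seq.atomic_tokens if atoms_only else seq.tokens
    return rep_l(tokens, window).normalized


def dataset_rep_summary(mols: MoleculeSet, scheme: str, *,
                        window: int | None = None,
                        atoms_only: bool = False) -> DatasetRepSummary:
    """Per-molecule repetition reports plus mean and sample deviation."""
    if len(mols) == 0:
        raise UsageError("empty molecule set")
    reports = []
    for s in mols:
        seq = _tokenize(s, scheme)
        tokens = seq.atomic_tokens if atoms_only else seq.tokens
        rep = rep_l(tokens, window)
        reports.append(RepetitionReport(rep.rep_l, rep.length, window, smiles=s))
    rates = [r.normalized for r in reports]
    mean = sum(rates) / len(rates)
    if len(rates) > 1:
        dev = math.sqrt(sum((x - mean) ** 2 for x in rates) / (len(rates) - 1))
    else:
        dev = 0.0
    return DatasetRepSummary(tuple(reports), mean, dev, scheme)


def excess_repetition(pred_tokens: Sequence[str],
                      gt_tokens: Sequence[str]) -> int:
    """rep-l(prediction) - rep-l(ground truth), unbounded window."""
    return rep_l(pred_tokens).rep_l - rep_l(gt_tokens).rep_l


def is_degenerate(pred_tokens: Sequence[str], gt_tokens: Sequence[str],
                  threshold: int = DEFAULT_EXCESS_THRESHOLD) -> bool:
    """Screen a prediction whose repetition exceeds its reference by >= threshold."""
    return excess_repetition(pred_tokens, gt_tokens) >= threshold
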