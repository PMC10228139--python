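"""SMILES tokenization: atom-wise and Atom-in-SMILES (AIS) schemes.

Atom-wise tokenization splits a SMILES string into its standard lexical
units — one token per atom (bracket atoms and the two-letter halogens are
single tokens) plus structural tokens for bonds, branches, ring closures
and the fragment dot. It is purely lexical: the tokens concatenate back to
the input string.

AIS tokenization replaces every atomic token with an environment-aware
descriptor built from the parsed molecule::

    [central;ring_flag;neighbors]

where ``central`` carries isotope, element symbol (lower-case iff
aromatic), chirality (``@``/``@@``), explicit hydrogen count and formal
charge in SMILES bracket-atom order; ``ring_flag`` is ``R`` for ring
members (SSSR of the parsed molecule) and ``!R`` otherwise; and
``neighbors`` is the lexicographically sorted concatenation of the
heavy-atom neighbour element symbols. Structural tokens pass through
unchanged, so the AIS sequence aligns position-for-position with the
atom-wise sequence of the same string. The mapping is invertible:
:func:`ais_detokenize` projects an AIS sequence back to a SMILES string
that parses to the same molecule, reproducing canonical inputs
character-for-character.

The chirality suffix is the ``@``/``@@`` symbol the atom receives in the
molecule's canonical SMILES, not the symbol at its position in the input.
The written symbol depends on the local neighbour order of a particular
enumeration, so only the canonical label makes the token multiset
invariant under SMILES enumeration; detokenization recovers the correct
positional symbol with a validate-and-flip pass.

Reference dialect: RDKit's default sanitization, aromaticity perception
and canonical SMILES writer.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger

from .errors import (
    DataError,
    InternalConsistencyError,
    SmilesParseError,
    TokenFormatError,
    UnsupportedFeatureError,
    UsageError,
)

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "AisToken",
    "TokenSequence",
    "MoleculeSet",
    "atomwise_tokenize",
    "ais_tokenize",
    "ais_detokenize",
    "atomic_token_set",
    "canonical_smiles",
    "vocabulary",
    "is_atom_token",
    "is_ais_token",
]

# Organic-subset elements may be written bare; everything else needs brackets.
ORGANIC_SUBSET = {"B", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I"}
AROMATIC_ORGANIC = {"b", "c", "n", "o", "p", "s"}

_ATOM_RE = (
    r"\[[^\]]+\]"      # bracket atom
    r"|Cl|Br"          # two-letter organic-subset halogens
    r"|[BCNOPSFI]"     # one-letter organic subset
    r"|[bcnops]"       # aromatic organic subset
    r"|\*"             # wildcard atom
)
_STRUCT_RE = r"%\d{2}|\d|[-=#$:/\\.()]"
_TOKEN_RE = re.compile(f"({_ATOM_RE})|({_STRUCT_RE})")
_ATOM_TOKEN_RE = re.compile(f"^(?:{_ATOM_RE})$")

# AIS rendered form: exactly three ';'-separated fields in square brackets.
_AIS_TOKEN_RE = re.compile(r"^\[([^;\[\]]*);(R|!R);([A-Za-z*]*)\]$")

_CENTRAL_RE = re.compile(
    r"^(?P<iso>\d+)?"
    r"(?P<sym>Cl|Br|as|se|te|[A-Z][a-z]?|[bcnops*])"
    r"(?P<chi>@{1,2})?"
    r"(?:H(?P<h>\d*))?"
    r"(?P<chg>[+-]\d*)?$"
)


@dataclass(frozen=True)
class AisToken:
    """One environment-aware atomic token."""

    central: str
    ring_flag: str            # "R" | "!R"
    neighbors: str            # sorted heavy-neighbour symbols, e.g. "CCN"

    @property
    def rendered(self) -> str:
        return f"[{self.central};{self.ring_flag};{self.neighbors}]"

    @classmethod
    def parse(cls, token: str) -> "AisToken":
        m = _AIS_TOKEN_RE.match(token)
        if m is None:
            raise TokenFormatError(
                "not an AIS atomic token (expected [central;ring;neighbors])",
                token=token,
            )
        central, ring_flag, neighbors = m.groups()
        if _CENTRAL_RE.match(central) is None:
            raise TokenFormatError("unparseable central-atom descriptor",
                                   token=token)
        if not _is_sorted_symbols(neighbors):
            raise TokenFormatError("neighbor field is not sorted", token=token)
        return cls(central, ring_flag, neighbors)


def _is_sorted_symbols(neighbors: str) -> bool:
    symbols = _split_symbols(neighbors)
    return "".join(symbols) == neighbors and symbols == sorted(symbols)


def _split_symbols(neighbors: str) -> list[str]:
    return re.findall(r"[A-Z*][a-z]?", neighbors)


@dataclass(frozen=True)
class TokenSequence:
    """Ordered tokens of one molecule plus the atomic-position index."""

    tokens: tuple[str, ...]
    scheme: str                      # "atomwise" | "ais"
    source_smiles: str
    atom_positions: tuple[int, ...]  # indices of atomic tokens, reading order

    def __post_init__(self) -> None:
        if self.scheme not in ("atomwise", "ais"):
            raise UsageError(f"unknown scheme {self.scheme!r}")

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)

    @property
    def atomic_tokens(self) -> tuple[str, ...]:
        return tuple(self.tokens[i] for i in self.atom_positions)

    @property
    def structural_tokens(self) -> tuple[str, ...]:
        atomic = set(self.atom_positions)
        return tuple(t for i, t in enumerate(self.tokens) if i not in atomic)

    def token_string(self) -> str:
        """Space-joined token line (tokens never contain spaces)."""
        return " ".join(self.tokens)


@dataclass(frozen=True)
class MoleculeSet:
    """Named collection of SMILES with provenance."""

    name: str
    smiles: tuple[str, ...]
    origin: str = "fixture"          # "fixture" | "file"

    @classmethod
    def from_smiles(cls, name: str, smiles: Iterable[str],
                    origin: str = "fixture") -> "MoleculeSet":
        """Build a validated set; unparseable entries abort with line numbers."""
        entries = tuple(smiles)
        bad = [i + 1 for i, s in enumerate(entries)
               if not s or Chem.MolFromSmiles(s) is None]
        if bad:
            raise DataError(f"{len(bad)} entries of {name!r} are not valid SMILES",
                            lines=bad)
        if not entries:
            raise UsageError(f"molecule set {name!r} is empty")
        return cls(name, entries, origin)

    def __len__(self) -> int:
        return len(self.smiles)

    def __iter__(self):
        return iter(self.smiles)


def is_atom_token(token: str) -> bool:
    """True for tokens that denote an atom in the atom-wise grammar."""
    return _ATOM_TOKEN_RE.match(token) is not None


def is_ais_token(token: str) -> bool:
    """True for tokens in the rendered AIS form ``[central;ring;neighbors]``."""
    return _AIS_TOKEN_RE.match(token) is not None


def _lex(smiles: str) -> list[str]:
    """Longest-match scan over the SMILES token grammar."""
    tokens: list[str] = []
    pos = 0
    while pos < len(smiles):
        m = _TOKEN_RE.match(smiles, pos)
        if m is None:
            raise SmilesParseError(
                f"unexpected character {smiles[pos]!r}", position=pos)
        tokens.append(m.group(0))
        pos = m.end()
    return tokens


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    if not smiles:
        raise UsageError("empty SMILES input")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"not a valid SMILES string: {smiles!r}")
    return mol


def canonical_smiles(smiles: str) -> str:
    """Canonical form in the pinned dialect (RDKit default writer)."""
    return Chem.MolToSmiles(_mol_from_smiles(smiles))


def atomwise_tokenize(smiles: str) -> TokenSequence:
    """Split a SMILES string into standard atom-wise tokens.

    Purely lexical apart from a validity check: the tokens concatenate
    back to the input exactly.
    """
    if not smiles:
        raise UsageError("empty SMILES input")
    tokens = _lex(smiles)
    _mol_from_smiles(smiles)  # reject syntactically plausible garbage
    positions = tuple(i for i, t in enumerate(tokens) if is_atom_token(t))
    return TokenSequence(tuple(tokens), "atomwise", smiles, positions)


def _canonical_chirality_labels(mol: Chem.Mol) -> dict[int, str]:
    """Map atom index -> '@'/'@@' as written in the canonical SMILES."""
    can = Chem.MolToSmiles(mol)
    order_prop = mol.GetProp("_smilesAtomOutputOrder")
    order = [int(x) for x in order_prop.strip("[],").split(",") if x.strip()]
    labels: dict[int, str] = {}
    atom_tokens = [t for t in _lex(can) if is_atom_token(t)]
    for out_pos, tok in enumerate(atom_tokens):
        if tok.startswith("["):
            if "@@" in tok:
                labels[order[out_pos]] = "@@"
            elif "@" in tok:
                labels[order[out_pos]] = "@"
    return labels


_EXPLICIT_H_TOKEN = re.compile(r"^\[\d*H[+-]?\d*\]$")


def _needs_normalization(mol: Chem.Mol, tokens: Sequence[str]) -> bool:
    """Explicit [H] atoms, or kekulized writing of aromatic atoms."""
    if any(a.GetAtomicNum() == 1 for a in mol.GetAtoms()):
        return True
    atom_tokens = [t for t in tokens if is_atom_token(t)]
    if any(_EXPLICIT_H_TOKEN.match(t) for t in atom_tokens):
        return True   # the parser already folded them; rewrite the string
    if len(atom_tokens) != mol.GetNumAtoms():
        return True
    for atom, tok in zip(mol.GetAtoms(), atom_tokens):
        sym = tok[1:-1] if tok.startswith("[") else tok
        written_aromatic = bool(re.match(r"\d*[a-z]", sym))
        if atom.GetIsAromatic() != written_aromatic:
            return True
    return False


def _central_descriptor(atom: Chem.Atom, chirality: str) -> str:
    sym = atom.GetSymbol()
    central = sym.lower() if atom.GetIsAromatic() else sym
    if atom.GetIsotope():
        central = f"{atom.GetIsotope()}{central}"
    central += chirality
    h = atom.GetTotalNumHs()
    if h == 1:
        central += "H"
    elif h > 1:
        central += f"H{h}"
    q = atom.GetFormalCharge()
    if q == 1:
        central += "+"
    elif q == -1:
        central += "-"
    elif q > 1:
        central += f"+{q}"
    elif q < -1:
        central += f"-{-q}"
    return central


def ais_tokenize(smiles: str) -> TokenSequence:
    """Tokenize a SMILES string under the Atom-in-SMILES scheme.

    Every atomic token of the atom-wise sequence is replaced by the
    rendered :class:`AisToken` of the corresponding atom; structural
    tokens keep their positions. Inputs carrying explicit ``[H]`` atoms
    or kekulized aromatic rings are first normalized to the parser's
    SMILES output (hydrogens folded into implicit counts, aromatic atoms
    written lower-case).
    """
    mol = _mol_from_smiles(smiles)
    tokens = _lex(smiles)
    if _needs_normalization(mol, tokens):
        mol = Chem.RemoveHs(mol)
        if any(a.GetAtomicNum() == 1 for a in mol.GetAtoms()):
            raise UnsupportedFeatureError(
                "explicit hydrogens that cannot be folded into implicit "
                f"counts are not supported: {smiles!r}")
        smiles = Chem.MolToSmiles(mol)
        mol = _mol_from_smiles(smiles)    # re-parse: atom order = reading order
        tokens = _lex(smiles)
    positions = tuple(i for i, t in enumerate(tokens) if is_atom_token(t))
    if len(positions) != mol.GetNumAtoms():
        raise InternalConsistencyError(
            f"token/atom count mismatch for {smiles!r}")
    chirality = _canonical_chirality_labels(mol)
    out = list(tokens)
    for reading_idx, tok_idx in enumerate(positions):
        atom = mol.GetAtomWithIdx(reading_idx)
        token = AisToken(
            central=_central_descriptor(atom, chirality.get(reading_idx, "")),
            ring_flag="R" if atom.IsInRing() else "!R",
            neighbors="".join(sorted(
                n.GetSymbol() for n in atom.GetNeighbors()
                if n.GetAtomicNum() > 1)),
        )
        out[tok_idx] = token.rendered
    return TokenSequence(tuple(out), "ais", smiles, positions)


@dataclass
class _ParsedCentral:
    isotope: str
    symbol: str        # as stored: lower-case iff aromatic
    chirality: str
    h_count: int
    charge: str

    @property
    def bare_eligible(self) -> bool:
        return (not self.isotope and not self.chirality and not self.charge
                and (self.symbol in ORGANIC_SUBSET
                     or self.symbol in AROMATIC_ORGANIC
                     or self.symbol == "*"))

    def render(self, chirality: str, bracket: bool) -> str:
        if not bracket:
            return self.symbol
        h = "" if self.h_count == 0 else (
            "H" if self.h_count == 1 else f"H{self.h_count}")
        return f"[{self.isotope}{self.symbol}{chirality}{h}{self.charge}]"


def _parse_ais_atom(token: str) -> _ParsedCentral:
    ais = AisToken.parse(token)
    m = _CENTRAL_RE.match(ais.central)
    assert m is not None  # AisToken.parse already validated
    h = m.group("h")
    return _ParsedCentral(
        isotope=m.group("iso") or "",
        symbol=m.group("sym"),
        chirality=m.group("chi") or "",
        h_count=0 if h is None else (1 if h == "" else int(h)),
        charge=m.group("chg") or "",
    )


def ais_detokenize(seq: TokenSequence | Sequence[str]) -> str:
    """Project an AIS token sequence back to a SMILES string.

    Structural tokens are emitted verbatim. Each atomic token is emitted
    as a bare organic-subset symbol when possible and as a bracket atom
    otherwise; the bare/bracket choice and the positional chirality
    symbol are settled by a validate-and-repair loop — the candidate
    string is re-parsed and atoms whose hydrogen count or canonical
    chirality label disagrees with their token are re-emitted in
    corrected bracket form. For canonical inputs this reproduces the
    input character-for-character.
    """
    if isinstance(seq, TokenSequence):
        if seq.scheme != "ais":
            raise UsageError("ais_detokenize requires an AIS token sequence")
        tokens = list(seq.tokens)
    else:
        tokens = list(seq)
    if not tokens:
        raise UsageError("empty token sequence")

    atoms: list[_ParsedCentral] = []
    layout: list[tuple[str, int | None]] = []   # (literal, atom index or None)
    for tok in tokens:
        if tok.startswith("[") and ";" in tok:
            atoms.append(_parse_ais_atom(tok))
            layout.append(("", len(atoms) - 1))
        elif re.fullmatch(_STRUCT_RE, tok):
            layout.append((tok, None))
        else:
            raise TokenFormatError("not an AIS atomic or structural token",
                                   token=tok)

    forced: set[int] = set()                    # atoms forced into brackets
    coarse: set[int] = set()                    # forced without evidence; relaxable
    flipped: dict[int, str] = {}                # positional chirality overrides

    def build() -> str:
        parts = []
        for literal, idx in layout:
            if idx is None:
                parts.append(literal)
            else:
                a = atoms[idx]
                bracket = idx in forced or not a.bare_eligible
                parts.append(a.render(flipped.get(idx, a.chirality), bracket))
        return "".join(parts)

    def hydrogens_consistent(mol: Chem.Mol) -> bool:
        return (mol.GetNumAtoms() == len(atoms)
                and all(mol.GetAtomWithIdx(i).GetTotalNumHs() == a.h_count
                        for i, a in enumerate(atoms)))

    for _ in range(2 * len(atoms) + 5):
        candidate = build()
        mol = Chem.MolFromSmiles(candidate)
        if mol is None:
            # cannot localize the fault without a parse: bracket the usual
            # culprits (aromatic atoms carrying hydrogens, pyrrole-type)
            # wholesale, then win back bare form atom by atom below
            bare = [i for i, a in enumerate(atoms)
                    if i not in forced and a.bare_eligible]
            repair = [i for i in bare
                      if atoms[i].symbol in AROMATIC_ORGANIC
                      and atoms[i].h_count > 0] or bare
            if not repair:
                raise InternalConsistencyError(
                    f"projection produced unparseable SMILES: {candidate!r}")
            forced.update(repair)
            coarse.update(repair)
            continue
        if mol.GetNumAtoms() != len(atoms):
            raise InternalConsistencyError(
                f"projection changed the atom count: {candidate!r}")
        changed = False
        for i, atom in enumerate(mol.GetAtoms()):
            if atom.GetTotalNumHs() != atoms[i].h_count and i not in forced:
                forced.add(i)
                changed = True
        if changed:
            continue
        if coarse:
            # relax over-bracketed atoms: keep bare form wherever the string
            # still parses with every hydrogen count intact
            for i in sorted(coarse):
                forced.discard(i)
                trial = Chem.MolFromSmiles(build())
                if trial is None or not hydrogens_consistent(trial):
                    forced.add(i)
            coarse.clear()
            continue
        labels = _canonical_chirality_labels(mol)
        for i, a in enumerate(atoms):
            want = a.chirality
            got = labels.get(i, "")
            if want and got and got != want:
                flipped[i] = "@@" if flipped.get(i, want) == "@" else "@"
                changed = True
        if not changed:
            return candidate
    raise InternalConsistencyError("detokenization repair did not converge")


def atomic_token_set(seq: TokenSequence) -> set[str]:
    """Distinct atomic tokens of a sequence (structural tokens excluded)."""
    return set(seq.atomic_tokens)


def vocabulary(mols: Iterable[str], scheme: str) -> Counter:
    """Token frequency over a molecule collection under one scheme."""
    tok = atomwise_tokenize if scheme == "atomwise" else ais_tokenize
    counts: Counter = Counter()
    for s in mols:
        counts.update(tok(s).tokens)
    return counts
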