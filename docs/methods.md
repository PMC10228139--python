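# Methods

## Token model

A SMILES string is first split by a longest-match scan over the standard
token grammar: bracket atoms `[...]`, the two-letter halogens `Cl`/`Br`,
one-letter organic-subset atoms (`B C N O P S F I`), aromatic
lower-case atoms (`b c n o p s`), the wildcard `*`, ring-closure digits
and `%nn`, bond symbols `- = # $ : / \`, branch parentheses and the
fragment dot. This atom-wise tokenization is purely lexical: the tokens
concatenate back to the input exactly, and anything that does not parse
as a molecule under the reference toolkit is rejected with the offending
position.

Atom-in-SMILES (AIS) tokenization replaces each atomic token with a
radius-1 environment descriptor `[central;ring_flag;neighbors]` built
from the parsed molecule:

- **central** — isotope digits, element symbol (lower-case iff the atom
  is aromatic), chirality suffix `@`/`@@`, explicit hydrogen count
  (`H`, `H2`, …; omitted at zero), formal charge (`+`, `-`, `+2`, …).
  The field order mirrors SMILES bracket-atom order, so projecting a
  token back to a bracket atom is a substring operation.
- **ring_flag** — `R` if the atom belongs to an SSSR ring of the parsed
  molecule, `!R` otherwise.
- **neighbors** — heavy-atom neighbour element symbols with
  multiplicity, capitalized regardless of aromaticity, sorted
  lexicographically. Hydrogens live on the central atom, never here.

The environment radius is fixed at 1 in this release. Structural tokens
pass through unchanged, so the AIS sequence of a string is
position-aligned with its atom-wise sequence.

### Chirality convention

The chirality suffix is the `@`/`@@` symbol the atom receives in the
molecule's **canonical** SMILES, not the symbol written at the atom's
position in the input. The positional symbol depends on the neighbour
order of the particular enumeration (the same stereocentre can
legitimately be written `@` in one enumeration and `@@` in another), and
the parser's stored chiral tag is likewise order-relative. Using the
canonical label is the only choice of the three that makes the AIS token
multiset invariant under SMILES enumeration of one molecule, which the
fingerprint application requires. The projection back to SMILES recovers
the correct positional symbol (see below).

### Dialect

Aromaticity perception, SSSR, implicit-hydrogen counting and the
canonical form are those of RDKit's default sanitization and canonical
writer — the pinned reference dialect. Inputs written kekulized
(`C1=CC=CC=C1`) or with explicit `[H]` atoms are normalized to the
parser's SMILES output before AIS tokenization, since hydrogens are
central-atom annotations in this scheme and aromatic atoms must render
lower-case. Hydrogens that cannot be folded into an implicit count
(isotopic `[2H]`, detached `[H+]`) are rejected: the token format has no
hydrogen-isotope channel. Radical centres need no special treatment —
under the toolkit's valence model the explicit hydrogen count in the
token distinguishes a radical (`C[N]C`) from its closed-shell
counterpart (`CNC`), and the projection restores the bracket form.

## Projection back to SMILES

Detokenization emits structural tokens verbatim and each atomic token as
either a bare organic-subset symbol or a bracket atom. The bare/bracket
choice and the positional chirality symbol are settled by a
validate-and-repair loop:

1. Emit every eligible atom bare (organic subset, no
   isotope/chirality/charge).
2. Re-parse. On parse failure, bracket the usual culprits — aromatic
   atoms carrying hydrogens (pyrrole-type `[nH]`) — wholesale, then win
   bare form back atom-by-atom wherever the string still parses with
   every hydrogen count intact.
3. On success, bracket any atom whose re-parsed hydrogen count differs
   from its token, and flip the written `@`/`@@` of any stereocentre
   whose canonical label disagrees with its token.
4. Repeat until stable (bounded by twice the atom count; each atom can
   be forced into bracket form at most once and flipped at most once).

For inputs already in the canonical dialect this reproduces the input
character-for-character; for arbitrary enumerations it reproduces the
molecular graph including stereochemistry.

## Repetition statistics

`rep_l(s, w)` counts positions whose token occurs among the previous
`min(w, t−1)` tokens. The default window is unbounded, where the count
reduces to `|s| − |distinct(s)|`; a finite `--window` is exposed for
experiments. Repetition is counted over the full token sequence,
structural tokens included, because the statistic is defined on the
sequence a model actually emits; `atoms_only=True` restricts to atomic
tokens as a sensitivity check. Dataset summaries report the arithmetic
mean of per-molecule normalized rates and their sample standard
deviation (ddof = 1; 0 for singletons — the deviation estimator was an
open choice and the sample form is the conservative default). The
degeneration screen flags prediction/reference pairs with
`rep_l(pred) − rep_l(ref) ≥ 2` by default.

## Fingerprints

A molecule's fingerprint is the frequency map of its atomic AIS tokens —
structural tokens dropped, no hashing, total mass equal to the
heavy-atom count. Count-mode Tanimoto (min/max over the key union) is
the default because the fingerprint is defined by frequencies; binary
(Jaccard on key sets) is provided for comparability with bit-vector
fingerprints. Pairwise similarity distributions sample unordered pairs
uniformly without replacement under a caller seed and bin into 100
equal-width bins on [0, 1]; the mode is reported as the densest bin's
centre. Whether published density curves of this kind used count or
binary similarity is not always stated; both are available and the
default is documented here.

## Fixtures and generators

Four pinned molecule sets (160 molecules total, stored in the canonical
dialect) cover complementary regimes: `druglike_small` (60 drugs and
drug-like structures, including stereocentres, charges and fused
heteroaromatics), `linear_chains` (42 chains — the high-repetition
regime), `ring_probes` (40 aromatic and saturated ring systems), and
`octane_isomers` (the 18 constitutional isomers of C8H18 —
configurational variation at fixed formula). Sizes were chosen so the
full suite, including 20 random enumerations per molecule, runs in
seconds on one CPU while still exercising every token feature.

Random enumerations are produced by renumbering atoms with a seeded
permutation and writing non-canonically. One integer seed drives a run;
each molecule derives a substream from the seed and a CRC-32 of its
canonical SMILES, so set reordering never changes a molecule's outputs.
The canonicalization pair builder emits, per molecule, *k* enumerated
sources paired with the canonical target — distinct sources where the
molecule admits them, sampling with replacement (logged) where it does
not — and writes line-aligned source/target `.smi` and token files. A
length filter dropping records over 150 tokens mirrors standard
sequence-model preprocessing.

What the fixtures do **not** emulate: database-scale diversity
(organometallics, polymers, very long lipid chains), reaction SMILES,
and corpus-specific token distributions. Passing tests demonstrate the
correctness of the tokenization, metrics and fingerprint machinery, and
the direction of the repetition-rate gap between schemes — not absolute
repetition or similarity values on any external corpus; the modal
pairwise similarity of the bundled drug-like set, in particular, sits
lower than values reported for large homogeneous screening libraries
because the set is small and deliberately heterogeneous.

## Known limitations

- Environment radius is fixed at 1; atoms whose radius-1 environments
  coincide (symmetric substructures) share tokens.
- Bond order and hybridization are not serialized in the token; they are
  recoverable from the structural tokens and aromaticity in context.
- The chirality channel covers tetrahedral `@`/`@@` only; exotic
  stereo-descriptors (`@TH1`, `@AL1`, …) are out of scope, as are
  polymer/macromolecule SMILES extensions and reaction atom-mapping.
- Hydrogen isotopes are rejected rather than silently folded.
- The tokenizer trusts the reference toolkit's aromaticity model;
  strings from toolkits with different perception round-trip at graph
  level but not necessarily string level.
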