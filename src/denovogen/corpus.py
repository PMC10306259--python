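"""Model-ready molecular encodings.

Two codecs live here:

* a SMILES token codec — multi-character-aware tokenization (two-letter
  elements, bracket atoms as single tokens) with GO/EOS/PAD/SEP control codes,
  used by the recurrent and sequence-transformer generators;
* a graph codec — every fragmented molecule becomes a 5 x L integer matrix
  whose rows hold (1) the atom-type code, (2) the 0-based atom index,
  (3) the index of an already-placed neighbor atom (the atom's own index when
  it starts a fragment), (4) the bond-type code, and (5) the 1-based index of
  the fragment being encoded. Columns are laid out as a GO block, a
  fragment block of fixed width, an EOS block, and a linking block that
  carries the bonds joining fragments. The default matrix is 5 x 400.

Bond orders in the graph codec are Kekulé orders: every prefix of a decode is
then a sanitizable substructure, which is what lets masked sampling guarantee
chemically valid outputs. An aromatic bond code is reserved in the vocabulary
but unused by the default encoder.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .molprep import FragmentPair

__all__ = [
    "SmilesVocabulary", "TokenSequence", "build_smiles_vocab",
    "tokenize_smiles", "encode_smiles", "decode_smiles",
    "GraphVocabulary", "GraphMatrix", "build_graph_vocab",
    "default_graph_vocab", "encode_graph", "decode_graph",
    "fragment_columns",
]


# ==========================================================================
# SMILES codec

_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|@@|[BCNOPSFIbcnops*]|%\d{2}|\d|[=#\$/\\\.\-\+\(\):@])"
)

PAD, GO, EOS, SEP = 0, 1, 2, 3
_CONTROL_TOKENS = ["<pad>", "<go>", "<eos>", "<sep>"]


def tokenize_smiles(smiles: str) -> list[str]:
    """Split a SMILES string into chemical tokens; raises if any character
    is left over (i.e. the string contains untokenizable syntax)."""
    tokens = _TOKEN_RE.findall(smiles)
    if "".join(tokens) != smiles:
        raise ValueError(f"cannot tokenize SMILES {smiles!r}")
    return tokens


@dataclass(frozen=True)
class SmilesVocabulary:
    """Bijective token <-> integer-code mapping with reserved control codes."""

    tokens: tuple[str, ...]                       # chemical tokens, sorted
    token_to_code: dict = field(repr=False, default=None)

    def __post_init__(self):
        mapping = {t: i + len(_CONTROL_TOKENS)
                   for i, t in enumerate(self.tokens)}
        object.__setattr__(self, "token_to_code", mapping)

    @property
    def size(self) -> int:
        return len(self.tokens) + len(_CONTROL_TOKENS)

    def code_of(self, token: str) -> int:
        try:
            return self.token_to_code[token]
        except KeyError:
            raise KeyError(f"token {token!r} not in vocabulary") from None

    def token_of(self, code: int) -> str:
        if code < len(_CONTROL_TOKENS):
            return _CONTROL_TOKENS[code]
        return self.tokens[code - len(_CONTROL_TOKENS)]

    def hash(self) -> str:
        return hashlib.sha256("\n".join(self.tokens).encode()).hexdigest()[:16]

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# denovogen SMILES vocabulary v1\n")
            for t in _CONTROL_TOKENS:
                fh.write(t + "\n")
            for t in self.tokens:
                fh.write(t + "\n")

    @classmethod
    def load(cls, path) -> "SmilesVocabulary":
        with open(path, encoding="utf-8") as fh:
            lines = [l.rstrip("\n") for l in fh]
        if lines and lines[0].startswith("# "):
            lines = lines[1:]                     # versioned header comment
        chem = [t for t in lines if t and t not in _CONTROL_TOKENS]
        return cls(tokens=tuple(chem))


@dataclass(frozen=True)
class TokenSequence:
    codes: tuple[int, ...]

    @property
    def length(self) -> int:
        return len(self.codes)


def build_smiles_vocab(corpus: list[str]) -> SmilesVocabulary:
    """Collect every token observed in the corpus, sorted for determinism."""
    if not corpus:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    tokens: set[str] = set()
    for s in corpus:
        tokens.update(tokenize_smiles(s))
    return SmilesVocabulary(tokens=tuple(sorted(tokens)))


def encode_smiles(smiles: str, vocab: SmilesVocabulary,
                  max_len: int) -> TokenSequence:
    """GO + token codes + EOS, right-padded with PAD to ``max_len``."""
    toks = tokenize_smiles(smiles)
    if len(toks) + 2 > max_len:
        raise ValueError(f"SMILES of {len(toks)} tokens exceeds max_len "
                         f"{max_len}")
    codes = [GO] + [vocab.code_of(t) for t in toks] + [EOS]
    codes += [PAD] * (max_len - len(codes))
    return TokenSequence(codes=tuple(codes))


def decode_smiles(seq: TokenSequence | list[int],
                  vocab: SmilesVocabulary) -> str:
    codes = seq.codes if isinstance(seq, TokenSequence) else seq
    out = []
    for c in codes:
        if c == EOS:
            break
        if c in (GO, PAD, SEP):
            continue
        out.append(vocab.token_of(c))
    return "".join(out)


# ==========================================================================
# Graph codec

# bond-type codes; 0 = none/padding
_BOND_CODES = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: 4,   # reserved; default encoder kekulizes
}
_CODE_BONDS = {v: k for k, v in _BOND_CODES.items()}

G_PAD, G_GO, G_EOS = 0, 1, 2
_N_GRAPH_CONTROL = 3


def _atom_descriptor(atom) -> str:
    """Atom-type descriptor: element | formal charge | explicit H count."""
    return f"{atom.GetSymbol()}|{atom.GetFormalCharge()}|{atom.GetNumExplicitHs()}"


@dataclass(frozen=True)
class GraphVocabulary:
    """Atom-type and bond-type codebooks; code 0 is reserved for padding."""

    atom_types: tuple[str, ...]

    @property
    def n_atom_codes(self) -> int:
        return len(self.atom_types) + _N_GRAPH_CONTROL

    def atom_code(self, descriptor: str) -> int:
        try:
            return self.atom_types.index(descriptor) + _N_GRAPH_CONTROL
        except ValueError:
            raise KeyError(f"atom type {descriptor!r} not in graph "
                           "vocabulary") from None

    def descriptor_of(self, code: int) -> str:
        return self.atom_types[code - _N_GRAPH_CONTROL]

    def hash(self) -> str:
        return hashlib.sha256("\n".join(self.atom_types).encode()
                              ).hexdigest()[:16]

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# denovogen graph vocabulary v1\n")
            for t in self.atom_types:
                fh.write(t + "\n")

    @classmethod
    def load(cls, path) -> "GraphVocabulary":
        with open(path, encoding="utf-8") as fh:
            lines = [l.rstrip("\n") for l in fh if l.strip()]
        if lines and lines[0].startswith("# "):
            lines = lines[1:]                     # versioned header comment
        return cls(atom_types=tuple(lines))


def default_graph_vocab() -> GraphVocabulary:
    """Codebook covering the common neutral organic atom environments."""
    types = []
    for sym in ("B", "C", "N", "O", "F", "P", "S", "Cl", "Br", "I"):
        types.append(f"{sym}|0|0")
    types += ["N|1|0", "N|-1|0", "O|-1|0", "N|0|1"]
    return GraphVocabulary(atom_types=tuple(sorted(types)))


def build_graph_vocab(smiles_list: list[str]) -> GraphVocabulary:
    """Collect atom-type descriptors from Kekulé structures of the corpus."""
    if not smiles_list:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    seen: set[str] = set(default_graph_vocab().atom_types)
    for s in smiles_list:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            continue
        kek = Chem.Mol(mol)
        Chem.Kekulize(kek, clearAromaticFlags=True)
        for a in kek.GetAtoms():
            seen.add(_atom_descriptor(a))
    return GraphVocabulary(atom_types=tuple(sorted(seen)))


@dataclass(frozen=True)
class GraphMatrix:
    """5 x L integer encoding of a fragmented molecule."""

    cells: np.ndarray                  # shape (5, L), dtype int
    d: int                             # width of the fragment block
    n_link: int                        # width of the linking block

    @property
    def L(self) -> int:
        return self.cells.shape[1]

    def __post_init__(self):
        if self.cells.shape[0] != 5:
            raise ValueError("graph matrix must have exactly 5 rows")


def _region_columns(mol, kek, regions, ranks):
    """Traverse atom regions in canonical order; emit per-atom and ring-closure
    columns plus the list of inter-region (linking) bonds.

    Returns (columns, link_bonds) where each column is a 5-tuple and each link
    bond is (global_idx_a, global_idx_b, bond_code)."""
    region_of = {}
    for ri, atoms in enumerate(regions):
        for a in atoms:
            region_of[a] = ri
    glob = {}                      # original atom idx -> global encoded idx
    columns = []
    next_idx = 0
    for ri, atoms in enumerate(regions):
        atoms = set(atoms)
        start = min(atoms, key=lambda a: ranks[a])
        frontier = [start]
        visited = set()
        while frontier:
            frontier.sort(key=lambda a: ranks[a])
            cur = frontier.pop(0)
            if cur in visited:
                continue
            visited.add(cur)
            atom = kek.GetAtomWithIdx(cur)
            glob[cur] = next_idx
            # pick tree parent: the visited in-region neighbor of lowest rank
            parents = [n.GetIdx() for n in atom.GetNeighbors()
                       if n.GetIdx() in visited and n.GetIdx() != cur
                       and n.GetIdx() in atoms]
            if parents:
                parent = min(parents, key=lambda a: glob[a])
                bond = kek.GetBondBetweenAtoms(cur, parent)
                columns.append((atom, next_idx, glob[parent],
                                _BOND_CODES[bond.GetBondType()], ri + 1))
            else:
                columns.append((atom, next_idx, next_idx, 0, ri + 1))
            # ring closures: other visited neighbors beyond the tree parent
            for n in atom.GetNeighbors():
                ni = n.GetIdx()
                if (ni in visited and ni in atoms and parents
                        and ni != min(parents, key=lambda a: glob[a])):
                    bond = kek.GetBondBetweenAtoms(cur, ni)
                    columns.append((atom, next_idx, glob[ni],
                                    _BOND_CODES[bond.GetBondType()], ri + 1))
            next_idx += 1
            for n in atom.GetNeighbors():
                ni = n.GetIdx()
                if ni in atoms and ni not in visited:
                    frontier.append(ni)
    link_bonds = []
    for bond in kek.GetBonds():
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if region_of[a] != region_of[b]:
            hi, lo = max(glob[a], glob[b]), min(glob[a], glob[b])
            link_bonds.append((hi, lo, _BOND_CODES[bond.GetBondType()]))
    link_bonds.sort()
    return columns, link_bonds


def _assign_regions(mol, fragments):
    """Partition the molecule's atoms: one region per input fragment (matched
    as a substructure, disjointly), remaining atoms grouped by connectivity."""
    candidates = []
    for i, frag in enumerate(fragments):
        query = Chem.MolFromSmiles(frag)
        matches = [set(m) for m in
                   mol.GetSubstructMatches(query, uniquify=True,
                                           maxMatches=512)]
        if not matches:
            raise ValueError(f"fragment {frag!r} is not a substructure of "
                             "the molecule")
        candidates.append((i, matches))
    # fewest-options-first backtracking over disjoint placements
    candidates.sort(key=lambda t: len(t[1]))
    placed: dict[int, set[int]] = {}

    def place(k: int, assigned: set[int]) -> bool:
        if k == len(candidates):
            return True
        i, matches = candidates[k]
        for m in matches:
            if not (m & assigned):
                placed[i] = m
                if place(k + 1, assigned | m):
                    return True
                del placed[i]
        return False

    if not place(0, set()):
        raise ValueError("fragments cannot be placed disjointly in the "
                         "molecule")
    regions = [sorted(placed[i]) for i in range(len(fragments))]
    assigned = set().union(*placed.values()) if placed else set()
    rest = [a.GetIdx() for a in mol.GetAtoms() if a.GetIdx() not in assigned]
    if rest:
        # group remaining atoms into connected components
        remaining = set(rest)
        while remaining:
            seed = min(remaining)
            comp, frontier = {seed}, [seed]
            while frontier:
                cur = frontier.pop()
                for n in mol.GetAtomWithIdx(cur).GetNeighbors():
                    ni = n.GetIdx()
                    if ni in remaining and ni not in comp:
                        comp.add(ni)
                        frontier.append(ni)
            regions.append(sorted(comp))
            remaining -= comp
    return regions


def encode_graph(pair: FragmentPair, vocab: GraphVocabulary,
                 L: int = 400, n_link: int = 38) -> GraphMatrix:
    """Encode a fragment-molecule pair as a 5 x L graph matrix.

    Block widths follow d = L - n_control - n_link with a GO and an EOS
    column (n_control = 2); the default 400 columns therefore hold a
    360-column fragment block and a 38-column linking block.
    """
    mol = Chem.MolFromSmiles(pair.molecule)
    if mol is None:
        raise ValueError(f"unparsable molecule {pair.molecule!r}")
    kek = Chem.Mol(mol)
    Chem.Kekulize(kek, clearAromaticFlags=True)
    ranks = list(Chem.CanonicalRankAtoms(mol))
    regions = _assign_regions(mol, list(pair.fragments))
    columns, link_bonds = _region_columns(mol, kek, regions, ranks)

    d = L - 2 - n_link
    if len(columns) > d:
        raise ValueError(f"molecule needs {len(columns)} fragment columns; "
                         f"block width is {d}")
    if len(link_bonds) > n_link:
        raise ValueError(f"molecule needs {len(link_bonds)} linking columns; "
                         f"block width is {n_link}")
    cells = np.zeros((5, L), dtype=np.int64)
    cells[0, 0] = G_GO
    for j, (atom, idx, nb, bcode, frag) in enumerate(columns, start=1):
        cells[:, j] = (vocab.atom_code(_atom_descriptor(atom)),
                       idx, nb, bcode, frag)
    cells[0, 1 + d] = G_EOS
    for j, (hi, lo, bcode) in enumerate(link_bonds):
        col = 2 + d + j
        cells[:, col] = (0, hi, lo, bcode, 0)
    return GraphMatrix(cells=cells, d=d, n_link=n_link)


def _atom_from_descriptor(desc: str):
    sym, charge, nh = desc.split("|")
    atom = Chem.Atom(sym)
    atom.SetFormalCharge(int(charge))
    atom.SetNumExplicitHs(int(nh))
    return atom


def decode_graph(matrix: GraphMatrix, vocab: GraphVocabulary) -> str:
    """Rebuild the canonical SMILES from a graph matrix.

    Raises on internally inconsistent matrices (dangling neighbor indices,
    unknown codes, chemically insane bond sets) and on all-padding input.
    """
    cells = matrix.cells
    em = Chem.RWMol()
    n_atoms = 0
    for j in range(cells.shape[1]):
        a, idx, nb, bcode, frag = cells[:, j]
        if j == 0 and a == G_GO:
            continue
        if a == G_EOS:
            continue
        if a == G_PAD and idx == 0 and nb == 0 and bcode == 0:
            continue
        if a >= _N_GRAPH_CONTROL and idx == n_atoms:
            # new atom column
            em.AddAtom(_atom_from_descriptor(vocab.descriptor_of(int(a))))
            if nb != idx:
                if nb >= n_atoms:
                    raise ValueError(f"dangling neighbor index {nb} in col {j}")
                em.AddBond(int(nb), int(idx), _CODE_BONDS[int(bcode)])
            n_atoms += 1
        elif idx < n_atoms and nb < n_atoms:
            # ring-closure or linking column between existing atoms
            if idx == nb:
                raise ValueError(f"self-bond in column {j}")
            if em.GetBondBetweenAtoms(int(idx), int(nb)) is not None:
                raise ValueError(f"duplicate bond in column {j}")
            em.AddBond(int(nb), int(idx), _CODE_BONDS[int(bcode)])
        else:
            raise ValueError(f"inconsistent column {j}: "
                             f"{cells[:, j].tolist()}")
    if n_atoms == 0:
        raise ValueError("all-padding matrix encodes no molecule")
    mol = em.GetMol()
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def fragment_columns(fragments, vocab: GraphVocabulary):
    """Encode input fragments alone (no target molecule) as graph columns.

    Used to condition the graph transformer: each fragment is its own region,
    there are no linking bonds, and atom indices are contiguous across
    fragments. Returns the list of 5-tuples (atom_code, idx, neighbor, bond,
    fragment_index)."""
    mol = Chem.MolFromSmiles(".".join(fragments))
    if mol is None:
        raise ValueError(f"unparsable fragment list {fragments!r}")
    kek = Chem.Mol(mol)
    Chem.Kekulize(kek, clearAromaticFlags=True)
    ranks = list(Chem.CanonicalRankAtoms(mol))
    comps = [list(c) for c in Chem.GetMolFrags(mol)]
    columns, link = _region_columns(mol, kek, comps, ranks)
    assert not link
    return [(vocab.atom_code(_atom_descriptor(atom)), idx, nb, bcode, frag)
            for atom, idx, nb, bcode, frag in columns]
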