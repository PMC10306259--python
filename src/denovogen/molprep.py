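"""Molecule standardization, drug-like filtering and retrosynthetic fragmentation.

The preparation pipeline mirrors common practice for assembling generative-model
training corpora: parse, keep the largest covalent fragment (salt/solvent
stripping), neutralize simple charges, require an organic composition, restrict
to a molecular-weight window (200-1000 Da by default) and deduplicate on
canonical SMILES. Fragmentation uses the BRICS or RECAP retrosynthetic rule
sets; combinations of the resulting leaf fragments paired with the parent
molecule are the training units for the fragment-conditioned generators.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import BRICS, Descriptors, Recap
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

#: Standard medicinal-chemistry element set ("organic subset" plus halogens/B).
DEFAULT_ELEMENTS = frozenset(
    {"H", "B", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I"})


@dataclass(frozen=True)
class MoleculeRecord:
    """One standardized molecule.

    ``canonical`` is empty when the input could not be parsed; ``is_valid``
    is true iff a sane structure was obtained, in which case ``mol_weight``
    is positive.
    """

    raw: str
    canonical: str = ""
    mol_weight: float = 0.0
    is_valid: bool = False
    is_organic: bool = False


@dataclass(frozen=True)
class FragmentPair:
    """A fragment combination plus the molecule it must reconstruct."""

    fragments: tuple[str, ...]
    molecule: str

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)


@dataclass
class PrepConfig:
    """Corpus-preparation parameters.

    Weights are in Dalton; the default 200-1000 window delimits the drug-like
    training range. ``subset_cap`` bounds the number of fragment combinations
    emitted per molecule so the corpus stays linear in molecule count.
    """

    min_weight: float = 200.0
    max_weight: float = 1000.0
    frag_method: str = "BRICS"
    max_fragments: int = 4
    allowed_elements: frozenset = field(default_factory=lambda: DEFAULT_ELEMENTS)
    subset_cap: int = 16
    subset_seed: int = 42

    def __post_init__(self):
        if self.min_weight >= self.max_weight:
            raise ValueError("min_weight must be below max_weight")
        if self.frag_method not in ("BRICS", "RECAP"):
            raise ValueError(f"unknown fragmentation method {self.frag_method!r}")


_UNCHARGER = rdMolStandardize.Uncharger()
_LARGEST = rdMolStandardize.LargestFragmentChooser()


def standardize(raw: str,
                allowed_elements: frozenset = DEFAULT_ELEMENTS) -> MoleculeRecord:
    """Standardize one input SMILES into a :class:`MoleculeRecord`.

    Salts and solvents are stripped by keeping the largest covalent fragment,
    simple charges are neutralized where a proton add/remove suffices, and the
    molecule is flagged organic iff all atoms lie in ``allowed_elements`` and
    at least one carbon is present. Failures are encoded in the flags; this
    function never raises on bad input.
    """
    try:
        mol = Chem.MolFromSmiles(raw)
    except Exception:
        mol = None
    if mol is None:
        return MoleculeRecord(raw=raw)
    try:
        mol = _LARGEST.choose(mol)
        mol = _UNCHARGER.uncharge(mol)
        Chem.SanitizeMol(mol)
        canonical = Chem.MolToSmiles(mol)
        mw = Descriptors.MolWt(mol)
    except Exception:
        return MoleculeRecord(raw=raw)
    symbols = {a.GetSymbol() for a in mol.GetAtoms()}
    organic = symbols <= allowed_elements and "C" in symbols
    return MoleculeRecord(raw=raw, canonical=canonical, mol_weight=mw,
                          is_valid=True, is_organic=organic)


def filter_corpus(records: list[MoleculeRecord],
                  cfg: PrepConfig | None = None) -> list[MoleculeRecord]:
    """Keep valid, organic molecules inside the weight window, deduplicated.

    Order of first occurrence is preserved. An empty result logs a warning
    rather than raising.
    """
    cfg = cfg or PrepConfig()
    seen: set[str] = set()
    kept = []
    for rec in records:
        if not (rec.is_valid and rec.is_organic):
            continue
        if not (cfg.min_weight <= rec.mol_weight <= cfg.max_weight):
            continue
        if rec.canonical in seen:
            continue
        seen.add(rec.canonical)
        kept.append(rec)
    if not kept:
        logger.warning("filter_corpus produced an empty corpus "
                       "(%d records in)", len(records))
    return kept


def strip_attachments(frag_smiles: str) -> str:
    """Remove BRICS/RECAP attachment (dummy) atoms, returning canonical SMILES."""
    mol = Chem.MolFromSmiles(frag_smiles)
    if mol is None:
        raise ValueError(f"unparsable fragment {frag_smiles!r}")
    stripped = Chem.DeleteSubstructs(mol, Chem.MolFromSmarts("[#0]"))
    Chem.SanitizeMol(stripped)
    return Chem.MolToSmiles(stripped)


def fragment(record: MoleculeRecord | str, method: str = "BRICS") -> list[str]:
    """One-pass retrosynthetic fragmentation into leaf fragments.

    Returns the multiset of leaf-fragment SMILES with attachment points
    recorded as dummy atoms (``[n*]``). A molecule with no cleavable bond
    returns a single-element list containing itself. Deterministic for a
    fixed canonical input: fragments are sorted.
    """
    smiles = record.canonical if isinstance(record, MoleculeRecord) else record
    if isinstance(record, MoleculeRecord) and not record.is_valid:
        raise ValueError("cannot fragment an invalid record")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES {smiles!r}")
    if method == "BRICS":
        broken = BRICS.BreakBRICSBonds(mol)
        frags = [Chem.MolToSmiles(f)
                 for f in Chem.GetMolFrags(broken, asMols=True)]
    elif method == "RECAP":
        tree = Recap.RecapDecompose(mol)
        leaves = sorted(tree.GetLeaves().keys())
        frags = leaves if leaves else [Chem.MolToSmiles(mol)]
    else:
        raise ValueError(f"unknown fragmentation method {method!r}")
    return sorted(frags)


def enumerate_pairs(record: MoleculeRecord,
                    cfg: PrepConfig | None = None) -> list[FragmentPair]:
    """Enumerate fragment-combination training pairs for one molecule.

    Every non-empty subset of the leaf fragments of size <= ``max_fragments``
    becomes one pair (attachment points stripped). When the number of subsets
    exceeds ``subset_cap`` a deterministic sample (seeded by ``subset_seed``)
    is drawn instead.
    """
    cfg = cfg or PrepConfig()
    if not record.is_valid:
        raise ValueError("cannot enumerate pairs for an invalid record")
    leaves = fragment(record, cfg.frag_method)
    stripped = []
    for f in leaves:
        s = strip_attachments(f)
        if s:  # attachment-only leaves vanish
            stripped.append(s)
    if not stripped:
        return []
    max_k = min(cfg.max_fragments, len(stripped))
    subsets = [combo
               for k in range(1, max_k + 1)
               for combo in itertools.combinations(stripped, k)]
    if cfg.subset_cap and len(subsets) > cfg.subset_cap:
        rng = np.random.default_rng(cfg.subset_seed)
        idx = rng.choice(len(subsets), size=cfg.subset_cap, replace=False)
        subsets = [subsets[i] for i in sorted(idx)]
    return [FragmentPair(fragments=combo, molecule=record.canonical)
            for combo in subsets]


# --------------------------------------------------------------------------
# Corpus file I/O

def read_smiles_file(path) -> list[str]:
    """Read SMILES from a plain list or a TSV with a (case-insensitive)
    ``SMILES`` header column."""
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if not first:
            return []
        header = [c.strip() for c in first.rstrip("\n").split("\t")]
        lowered = [c.lower() for c in header]
        if "smiles" in lowered:
            col = lowered.index("smiles")
            out = []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) > col and parts[col].strip():
                    out.append(parts[col].strip())
            return out
        out = [first.strip()] if first.strip() else []
        out.extend(line.strip() for line in fh if line.strip())
        return [s.split("\t")[0] for s in out]


def write_smiles_corpus(records: list[MoleculeRecord], path) -> None:
    """Write an RNN training corpus: one canonical SMILES per row."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("SMILES\n")
        for rec in records:
            fh.write(rec.canonical + "\n")


def write_pair_corpus(pairs: list[FragmentPair], path) -> None:
    """Write a transformer corpus: fragments (dot-joined) and target SMILES."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("Frags\tSMILES\n")
        for p in pairs:
            fh.write(".".join(p.fragments) + "\t" + p.molecule + "\n")


def read_pair_corpus(path) -> list[FragmentPair]:
    pairs = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {c.lower(): i for i, c in enumerate(header)}
        fi, si = cols["frags"], cols["smiles"]
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            pairs.append(FragmentPair(fragments=tuple(parts[fi].split(".")),
                                      molecule=parts[si]))
    return pairs
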