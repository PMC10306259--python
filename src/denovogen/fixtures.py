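"""Deterministic toy corpora of drug-like molecules.

Molecules are assembled combinatorially from curated building blocks (aromatic
and saturated rings, amide/ether/sulfonamide-style linkers, small substituents)
so every generated SMILES is valid and organic by construction — no downloads,
no stored data files. The generator is seeded and reproducible; it emulates the
size range and functional-group mix of a drug-like screening set, not the
property distributions of any real database.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors

__all__ = ["FixtureSpec", "make_corpus", "make_env_toy"]

# Ring templates parametrized by the ring-closure digit so several can be
# chained in one SMILES without digit clashes.
_RINGS = [
    "c{d}ccccc{d}",          # benzene
    "c{d}ccncc{d}",          # pyridine
    "c{d}ccc(F)cc{d}",       # fluorophenyl (written with a substituent)
    "C{d}CCNCC{d}",          # piperidine
    "C{d}CCOCC{d}",          # tetrahydropyran
    "c{d}cnccn{d}",          # pyrimidine-like diazine
    "C{d}CCCCC{d}",          # cyclohexane
    "c{d}ccc2ccccc2c{d}",    # naphthalene (uses digit 2 internally)
]
# naphthalene's internal digit 2 clashes if d == 2; handled in _ring().

_LINKERS = [
    "C(=O)N", "NC(=O)", "C(=O)O", "OC(=O)", "CN", "NC",
    "CC", "OCC", "COC", "S(=O)(=O)N", "C(=O)", "C=C", "CCC",
]

_CAPS = ["", "C", "O", "N", "F", "Cl", "C(C)C", "OC", "C(F)(F)F", "C#N"]

_NITROGEN_RICH = {"C(=O)N", "NC(=O)", "CN", "NC", "S(=O)(=O)N"}


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a reproducible toy corpus."""

    n_molecules: int = 300
    seed: int = 1
    weight_range: tuple[float, float] = (200.0, 500.0)
    nitrogen_bias: float = 0.0   # extra probability mass on N-rich linkers


def _ring(template: str, digit: int) -> str:
    if "2" in template and digit == 2:
        digit = 5
    return template.format(d=digit)


def make_corpus(spec: FixtureSpec) -> list[str]:
    """Generate ``n_molecules`` unique canonical SMILES inside the weight range.

    Molecules are ring-linker-ring chains with an optional third ring and a
    terminal substituent; candidates outside the weight window are discarded
    and generation continues until the target count is reached.
    """
    if spec.n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    lo, hi = spec.weight_range
    if lo >= hi:
        raise ValueError("infeasible weight_range")
    rng = np.random.default_rng(spec.seed)
    linker_p = np.ones(len(_LINKERS))
    if spec.nitrogen_bias > 0:
        for i, l in enumerate(_LINKERS):
            if l in _NITROGEN_RICH:
                linker_p[i] += spec.nitrogen_bias * len(_LINKERS)
    linker_p /= linker_p.sum()

    seen: set[str] = set()
    out: list[str] = []
    attempts = 0
    max_attempts = 200 * spec.n_molecules + 1000
    while len(out) < spec.n_molecules:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"weight_range {spec.weight_range} infeasible for the "
                f"building-block library (got {len(out)} molecules)")
        a = _ring(_RINGS[rng.integers(len(_RINGS))], 1)
        l1 = _LINKERS[rng.choice(len(_LINKERS), p=linker_p)]
        b = _ring(_RINGS[rng.integers(len(_RINGS))], 3)
        smi = a + l1 + b
        if rng.random() < 0.5:
            l2 = _LINKERS[rng.choice(len(_LINKERS), p=linker_p)]
            c = _ring(_RINGS[rng.integers(len(_RINGS))], 4)
            smi = smi + l2 + c
        cap = _CAPS[rng.integers(len(_CAPS))]
        smi = smi + cap
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        mw = Descriptors.MolWt(mol)
        if not (lo <= mw <= hi):
            continue
        can = Chem.MolToSmiles(mol)
        if can in seen:
            continue
        seen.add(can)
        out.append(can)
    return out


def make_env_toy():
    """Two-objective toy scoring environment used by the RL smoke tests.

    Objective 1: molecular weight through a smooth-hump desirability centred
    on the 250-400 Da window. Objective 2: a binary contains-nitrogen scorer
    through the identity modifier. Both thresholds 0.5.
    """
    from .environment import (Environment, Objective, SmoothHump, Identity,
                              get_scorer)
    return Environment(
        objectives=[
            Objective(scorer=get_scorer("mol_weight"),
                      modifier=SmoothHump(lower=250.0, upper=400.0, width=50.0),
                      threshold=0.5),
            Objective(scorer=get_scorer("contains_nitrogen"),
                      modifier=Identity(),
                      threshold=0.5),
        ],
        scheme="WS",
    )
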