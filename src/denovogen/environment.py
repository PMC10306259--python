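"""Scoring environments: objectives, desirability modifiers and rewards.

A batch of SMILES is scored in three stages: raw objective scores (any
callable mapping SMILES to numbers), modifier transforms squashing each raw
score into a [0, 1] desirability, and a multiobjective ranking step (see
:mod:`denovogen.moo_rank`) that produces one scalar reward per molecule.
A molecule is *desired* when every modified score meets or exceeds its
objective's threshold. Invalid SMILES receive zero modified scores on all
objectives so batches stay rectangular and reinforcement learning can
penalize invalidity.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import yaml
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, DataStructs, Descriptors

logger = logging.getLogger(__name__)

__all__ = [
    "Scorer", "Modifier", "ClippedScore", "Gaussian", "SmoothHump",
    "Identity", "Objective", "ScoreTable", "Environment",
    "clipped_score", "smooth_hump", "gaussian_modifier", "score_batch",
    "get_scorer", "register_scorer",
]


# ==========================================================================
# Modifiers

class Modifier:
    """Maps raw objective scores onto a [0, 1] desirability scale."""

    kind = "base"

    def __call__(self, x):
        raise NotImplementedError

    def params(self) -> dict:
        return {k: v for k, v in vars(self).items()}


def clipped_score(x, low: float, high: float):
    """Piecewise-linear ramp: 0 at/beyond ``low``, 1 at/beyond ``high``.

    With ``low > high`` the ramp is reversed (a minimization objective)."""
    if low == high:
        raise ValueError("low and high must differ")
    x = np.asarray(x, dtype=float)
    t = (x - low) / (high - low)
    return np.clip(t, 0.0, 1.0)


def gaussian_modifier(x, center: float, sigma: float):
    """exp(-(x - center)^2 / (2 sigma^2)); peak 1 at the center."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.asarray(x, dtype=float)
    return np.exp(-((x - center) ** 2) / (2.0 * sigma ** 2))


def smooth_hump(x, lower: float, upper: float, width: float):
    """Smooth plateau: ~1 on [lower, upper], sigmoid decay of scale ``width``
    outside, rescaled so the supremum (at the interval center) is exactly 1."""
    if width <= 0:
        raise ValueError("width must be positive")
    if lower >= upper:
        raise ValueError("lower must be below upper")
    x = np.asarray(x, dtype=float)
    tau = width / 4.0

    def raw(v):
        a = 1.0 / (1.0 + np.exp(-np.clip((v - (lower - width)) / tau, -60, 60)))
        b = 1.0 / (1.0 + np.exp(-np.clip(((upper + width) - v) / tau, -60, 60)))
        return a * b

    peak = raw(np.array((lower + upper) / 2.0))
    return np.minimum(raw(x) / peak, 1.0)


@dataclass
class ClippedScore(Modifier):
    low: float
    high: float
    kind = "ClippedScore"

    def __call__(self, x):
        return clipped_score(x, self.low, self.high)


@dataclass
class Gaussian(Modifier):
    center: float
    sigma: float
    kind = "Gaussian"

    def __call__(self, x):
        return gaussian_modifier(x, self.center, self.sigma)


@dataclass
class SmoothHump(Modifier):
    lower: float
    upper: float
    width: float
    kind = "SmoothHump"

    def __call__(self, x):
        return smooth_hump(x, self.lower, self.upper, self.width)


@dataclass
class Identity(Modifier):
    """Pass-through for scorers that already emit desirabilities."""

    kind = "Identity"

    def __call__(self, x):
        return np.asarray(x, dtype=float)


_MODIFIERS = {"ClippedScore": ClippedScore, "Gaussian": Gaussian,
              "SmoothHump": SmoothHump, "Identity": Identity}


# ==========================================================================
# Scorers

@dataclass
class Scorer:
    """A named objective function over SMILES lists.

    ``compute`` receives a list of RDKit molecules aligned with the input
    SMILES (None for invalid entries) and returns one float per entry; invalid
    entries come back as NaN."""

    name: str
    fn: callable
    direction: str = "maximize"
    params: dict = field(default_factory=dict)

    def compute(self, smiles: list[str]) -> np.ndarray:
        mols = [Chem.MolFromSmiles(s) if s else None for s in smiles]
        out = np.full(len(smiles), np.nan)
        for i, m in enumerate(mols):
            if m is not None:
                out[i] = self.fn(m)
        return out


_SCORERS: dict[str, callable] = {}


def register_scorer(name: str, fn, direction: str = "maximize"):
    """Plugin hook: register any molecule -> float callable as an objective."""
    _SCORERS[name] = lambda **kw: Scorer(name=name, fn=fn, direction=direction)


def get_scorer(name: str, **params) -> Scorer:
    """Instantiate a built-in or registered scorer by name."""
    if name not in _SCORERS:
        raise KeyError(f"unknown scorer {name!r}; known: {sorted(_SCORERS)}")
    return _SCORERS[name](**params)


def _mw(**kw):
    return Scorer("mol_weight", Descriptors.MolWt, "target-range")


def _logp(**kw):
    return Scorer("logp_estimate", Crippen.MolLogP, "target-range")


def _contains_nitrogen(**kw):
    return Scorer("contains_nitrogen",
                  lambda m: float(any(a.GetSymbol() == "N"
                                      for a in m.GetAtoms())))


def _tanimoto(reference: str = "c1ccccc1", radius: int = 2,
              n_bits: int = 2048, **kw):
    ref = Chem.MolFromSmiles(reference)
    if ref is None:
        raise ValueError(f"unparsable reference {reference!r}")
    gen = AllChem.GetMorganGenerator(radius=radius, fpSize=n_bits)
    ref_fp = gen.GetFingerprint(ref)

    def fn(mol):
        return DataStructs.TanimotoSimilarity(ref_fp, gen.GetFingerprint(mol))

    return Scorer("tanimoto_similarity", fn,
                  params={"reference": reference, "radius": radius,
                          "n_bits": n_bits})


def _sa_proxy(**kw):
    """Fragment-complexity proxy for synthetic accessibility.

    A simple declared stand-in: penalizes macrocycles, dense ring fusion,
    stereocenters and size; 1 = easy, 0 = hard. Not a trained model.
    """
    def fn(mol):
        n = mol.GetNumHeavyAtoms()
        ri = mol.GetRingInfo()
        macro = sum(1 for r in ri.AtomRings() if len(r) > 7)
        fused = sum(1 for r in ri.BondRings()
                    for q in ri.BondRings() if r is not q and set(r) & set(q))
        stereo = len(Chem.FindMolChiralCenters(mol, includeUnassigned=True))
        penalty = 0.02 * max(n - 20, 0) + 0.25 * macro + 0.05 * fused \
            + 0.05 * stereo
        return float(np.clip(1.0 - penalty, 0.0, 1.0))

    return Scorer("sa_score_proxy", fn)


def _ligand_efficiency(affinity: float = 0.0, **kw):
    """Affinity (e.g. a predicted pChEMBL value) per heavy atom."""
    def fn(mol):
        n = mol.GetNumHeavyAtoms()
        return float(affinity) / n if n else 0.0

    return Scorer("ligand_efficiency", fn, params={"affinity": affinity})


def _constant(value: float = 0.5, **kw):
    """Deterministic stub standing in for an external property predictor."""
    return Scorer("constant", lambda m: float(value),
                  params={"value": value})


_SCORERS.update({
    "mol_weight": _mw,
    "logp_estimate": _logp,
    "contains_nitrogen": _contains_nitrogen,
    "tanimoto_similarity": _tanimoto,
    "sa_score_proxy": _sa_proxy,
    "ligand_efficiency": _ligand_efficiency,
    "constant": _constant,
})


# ==========================================================================
# Objectives and score tables

@dataclass
class Objective:
    scorer: Scorer
    modifier: Modifier
    threshold: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")


@dataclass
class ScoreTable:
    """Aligned per-molecule scoring results for one batch."""

    molecules: list[str]
    objective_names: list[str]
    raw: np.ndarray            # (n, k), NaN = missing
    modified: np.ndarray       # (n, k) in [0, 1]
    valid: np.ndarray          # (n,) bool
    desired: np.ndarray        # (n,) bool
    reward: np.ndarray = None  # (n,) filled by the ranking scheme

    def to_frame(self):
        import pandas as pd
        data = {"SMILES": self.molecules, "valid": self.valid}
        for j, name in enumerate(self.objective_names):
            data[f"raw_{name}"] = self.raw[:, j]
            data[f"mod_{name}"] = self.modified[:, j]
        data["desired"] = self.desired
        if self.reward is not None:
            data["reward"] = self.reward
        return pd.DataFrame(data)

    def to_tsv(self, path):
        self.to_frame().to_csv(path, sep="\t", index=False)


def score_batch(smiles: list[str], objectives: list[Objective]) -> ScoreTable:
    """Raw scores, modifier transforms and the all-thresholds desired verdict.

    A scorer that raises marks its whole column missing (logged) and the run
    continues; invalid SMILES get zero modified scores and desired = False.
    """
    if not objectives:
        raise ValueError("need at least one objective")
    n, k = len(smiles), len(objectives)
    valid = np.array([bool(s) and Chem.MolFromSmiles(s) is not None
                      for s in smiles])
    raw = np.full((n, k), np.nan)
    modified = np.zeros((n, k))
    available = np.ones(k, dtype=bool)
    for j, obj in enumerate(objectives):
        try:
            raw[:, j] = obj.scorer.compute(smiles)
        except Exception:
            logger.exception("scorer %s failed; column skipped",
                             obj.scorer.name)
            available[j] = False
            continue
        with np.errstate(invalid="ignore"):
            mod = np.asarray(obj.modifier(raw[:, j]), dtype=float)
        mod = np.where(np.isnan(mod), 0.0, mod)
        modified[:, j] = np.where(valid, mod, 0.0)
    thresholds = np.array([o.threshold for o in objectives])
    desired = valid.copy()
    for j in range(k):
        if available[j]:
            desired &= modified[:, j] >= thresholds[j]
    return ScoreTable(
        molecules=list(smiles),
        objective_names=[o.scorer.name for o in objectives],
        raw=raw, modified=modified, valid=valid, desired=desired)


# ==========================================================================
# Environment = objectives + ranking scheme

@dataclass
class Environment:
    """Objectives plus a reward-ranking scheme (WS, PRCD or PRTD)."""

    objectives: list[Objective]
    scheme: str = "WS"

    def __post_init__(self):
        if self.scheme not in ("WS", "PRCD", "PRTD"):
            raise ValueError(f"unknown ranking scheme {self.scheme!r}")

    def score(self, smiles: list[str]) -> ScoreTable:
        from .moo_rank import compute_rewards
        table = score_batch(smiles, self.objectives)
        table.reward = compute_rewards(table, self.scheme)
        return table

    # -- config round trip -------------------------------------------------

    def to_config(self) -> dict:
        return {
            "scheme": self.scheme,
            "objectives": [
                {"scorer": {"name": o.scorer.name, **o.scorer.params},
                 "modifier": {"kind": o.modifier.kind, **o.modifier.params()},
                 "threshold": o.threshold}
                for o in self.objectives],
        }

    def save(self, path) -> None:
        text = (json.dumps(self.to_config(), indent=2)
                if str(path).endswith(".json")
                else yaml.safe_dump(self.to_config(), sort_keys=False))
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)

    @classmethod
    def from_config(cls, cfg: dict) -> "Environment":
        objectives = []
        for item in cfg["objectives"]:
            sc = dict(item["scorer"])
            scorer = get_scorer(sc.pop("name"), **sc)
            mod = dict(item["modifier"])
            mod_cls = _MODIFIERS[mod.pop("kind")]
            objectives.append(Objective(scorer=scorer,
                                        modifier=mod_cls(**mod),
                                        threshold=item.get("threshold", 0.5)))
        return cls(objectives=objectives, scheme=cfg.get("scheme", "WS"))

    @classmethod
    def load(cls, path) -> "Environment":
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
        cfg = (json.loads(text) if str(path).endswith(".json")
               else yaml.safe_load(text))
        return cls.from_config(cfg)
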