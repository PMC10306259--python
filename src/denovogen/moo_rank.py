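"""Multiobjective reward ranking.

Three schemes turn the n x k matrix of modified (desirability) scores into a
scalar reward per molecule:

* **WS** — dynamic weighted sum: each objective's weight is proportional to
  1 minus its population mean, so the worst-performing objective of the
  current batch receives the largest weight.
* **PRCD** — Pareto fronts (fast non-dominated sort), ranked within each
  front by NSGA-II crowding distance.
* **PRTD** — Pareto fronts ranked within each front by mean Tanimoto
  *distance* to the other front members (2048-bit Morgan fingerprints,
  radius 2), which favors structurally diverse solutions.

For the Pareto schemes the global order (front, then intra-front distance)
is mapped to rewards by linear interpolation, desired compounds into
[0.5, 1.0] and undesired into [0, 0.5), preserving the order strictly.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, DataStructs

__all__ = [
    "weighted_sum_reward", "non_dominated_sort", "crowding_distance",
    "tanimoto_distance_rank", "rank_to_reward", "compute_rewards",
]


def weighted_sum_reward(modified: np.ndarray) -> np.ndarray:
    """Dynamic weighted sum over objectives.

    Weights are w_j ∝ (1 - mean_j), normalized to sum one; a batch that is
    uniformly perfect on every objective falls back to equal weights."""
    modified = np.asarray(modified, dtype=float)
    if modified.ndim != 2 or modified.shape[1] == 0:
        raise ValueError("need an n x k score matrix with k >= 1")
    w = 1.0 - modified.mean(axis=0)
    total = w.sum()
    if total <= 0:
        w = np.full(modified.shape[1], 1.0 / modified.shape[1])
    else:
        w = w / total
    return modified @ w


def non_dominated_sort(modified: np.ndarray) -> list[list[int]]:
    """Fast non-dominated sort (NSGA-II bookkeeping), maximization on all
    columns. Returns fronts as index lists; front 0 is non-dominated.
    Identical rows share a front."""
    s = np.asarray(modified, dtype=float)
    n = s.shape[0]
    if n == 0:
        return []
    # domination counts and dominated-sets in O(n^2 k) vectorized per row
    dominates = [[] for _ in range(n)]
    dom_count = np.zeros(n, dtype=int)
    for i in range(n):
        ge = (s[i] >= s).all(axis=1)
        gt = (s[i] > s).any(axis=1)
        dominated_by_i = ge & gt
        dominated_by_i[i] = False
        dominates[i] = np.nonzero(dominated_by_i)[0].tolist()
        le = (s <= s[i])
        # count of rows dominating i
        dom_count[i] = int(((s >= s[i]).all(axis=1)
                            & (s > s[i]).any(axis=1)).sum())
    fronts = []
    current = np.nonzero(dom_count == 0)[0].tolist()
    remaining = dom_count.copy()
    while current:
        fronts.append(sorted(current))
        nxt = []
        for i in current:
            for j in dominates[i]:
                remaining[j] -= 1
                if remaining[j] == 0:
                    nxt.append(j)
        current = nxt
    return fronts


def crowding_distance(front_scores: np.ndarray) -> np.ndarray:
    """NSGA-II crowding distance within one front.

    Boundary points on any objective get infinite distance; interior points
    accumulate the normalized gap between their neighbors, summed over
    objectives."""
    s = np.asarray(front_scores, dtype=float)
    if s.ndim == 1:
        s = s[:, None]
    m, k = s.shape
    if m <= 2:
        return np.full(m, np.inf)
    dist = np.zeros(m)
    for j in range(k):
        order = np.argsort(s[:, j], kind="stable")
        lo, hi = s[order[0], j], s[order[-1], j]
        dist[order[0]] = dist[order[-1]] = np.inf
        span = hi - lo
        if span == 0:
            continue
        for pos in range(1, m - 1):
            i = order[pos]
            dist[i] += (s[order[pos + 1], j] - s[order[pos - 1], j]) / span
    return dist


_FP_GEN = None


def _fingerprints(smiles: list[str]):
    global _FP_GEN
    if _FP_GEN is None:
        _FP_GEN = AllChem.GetMorganGenerator(radius=2, fpSize=2048)
    fps = []
    for s in smiles:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            raise ValueError(f"invalid SMILES in front: {s!r}")
        fps.append(_FP_GEN.GetFingerprint(mol))
    return fps


def tanimoto_distance_rank(front_molecules: list[str]) -> np.ndarray:
    """Rank positions within a front by mean Tanimoto distance to the rest.

    Returns ranks (0 = best = most distant/diverse). Ties break on canonical
    SMILES order so runs are reproducible."""
    m = len(front_molecules)
    if m == 1:
        return np.array([0])
    fps = _fingerprints(front_molecules)
    mean_dist = np.zeros(m)
    for i in range(m):
        sims = DataStructs.BulkTanimotoSimilarity(
            fps[i], [fps[j] for j in range(m) if j != i])
        mean_dist[i] = 1.0 - float(np.mean(sims))
    canon = [Chem.CanonSmiles(s) for s in front_molecules]
    order = sorted(range(m), key=lambda i: (-mean_dist[i], canon[i]))
    ranks = np.empty(m, dtype=int)
    for pos, i in enumerate(order):
        ranks[i] = pos
    return ranks


def rank_to_reward(fronts: list[list[int]], intra_rank: dict[int, float],
                   desired: np.ndarray) -> np.ndarray:
    """Map a global Pareto order to scalar rewards in [0, 1].

    The global order is front order, then intra-front rank. Desired compounds
    are linearly mapped into [0.5, 1.0] (best first), undesired into
    [0, 0.5); a better global rank always yields a strictly larger reward
    within its desirability class."""
    desired = np.asarray(desired, dtype=bool)
    order = []
    for front in fronts:
        order.extend(sorted(front, key=lambda i: intra_rank.get(i, 0)))
    n = len(order)
    rewards = np.zeros(n)
    des = [i for i in order if desired[i]]
    und = [i for i in order if not desired[i]]
    nd = len(des)
    for pos, i in enumerate(des):
        rewards[i] = 1.0 - 0.5 * (pos / (nd - 1)) if nd > 1 else 1.0
    nu = len(und)
    for pos, i in enumerate(und):
        rewards[i] = 0.5 * (nu - 1 - pos) / nu if nu > 0 else 0.0
    return rewards


def compute_rewards(table, scheme: str) -> np.ndarray:
    """Scalar rewards for a ScoreTable under the named scheme."""
    modified = table.modified
    n = modified.shape[0]
    if n == 0:
        return np.zeros(0)
    if scheme == "WS":
        return weighted_sum_reward(modified)
    fronts = non_dominated_sort(modified)
    intra: dict[int, float] = {}
    for front in fronts:
        fs = modified[front]
        if scheme == "PRCD":
            cd = crowding_distance(fs)
            order = sorted(range(len(front)),
                           key=lambda p: (-cd[p], table.molecules[front[p]]))
            for pos, p in enumerate(order):
                intra[front[p]] = pos
        else:  # PRTD
            mols = [table.molecules[i] for i in front]
            if all(table.valid[i] for i in front):
                ranks = tanimoto_distance_rank(mols)
            else:
                # invalid molecules cannot be fingerprinted; front keeps
                # input order with invalids last
                ranks = np.array(
                    sorted(range(len(front)),
                           key=lambda p: (not table.valid[front[p]], p)))
                ranks = np.argsort(ranks)
            for p, r in enumerate(ranks):
                intra[front[p]] = int(r)
    return rank_to_reward(fronts, intra, table.desired)
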