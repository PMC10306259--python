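"""Reinforcement-learning loop for generator optimization.

Each epoch: sample a batch from a mixture of the trainable *agent* and a
frozen *prior* (the mixing fraction epsilon plays the role of a mutation
rate), score the batch with the environment, convert scores to scalar rewards
under the configured ranking scheme, and update the agent by policy gradient
(REINFORCE): loss = mean over molecules of reward x (-sum of token
log-likelihoods). Invalid molecules carry reward zero.

For extra exploration the agent can draw part of its share from a periodically
refreshed copy of itself (refreshed every ``sync_interval`` epochs, 50 by
default); this is on by default for the RNN generator and off for the
transformers, whose sampling is costlier.

Per-epoch metrics: the fractions of valid, accurate (fragment models only),
unique and desired molecules, and the arithmetic and geometric mean modified
score per objective. The desired ratio selects the best epoch and drives
early stopping.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from rdkit import Chem

from . import nn
from .corpus import PAD
from .environment import Environment, ScoreTable

logger = logging.getLogger(__name__)

__all__ = ["ExplorerConfig", "EpochMetrics", "mixed_sample",
           "policy_gradient_update", "compute_metrics", "rl_train"]


@dataclass
class ExplorerConfig:
    epsilon: float = 0.1          # fraction of samples drawn from the prior
    sync_interval: int = 50       # epochs between auxiliary-network refreshes
    use_periodic_agent: bool = True
    batch_size: int = 64
    epochs: int = 30
    learning_rate: float = 1e-3
    patience: int = 100
    monitor_metric: str = "desired_ratio"
    seed: int = 0
    max_failures: int = 5         # consecutive scoring failures tolerated

    def __post_init__(self):
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")
        if self.sync_interval < 1:
            raise ValueError("sync_interval must be >= 1")


@dataclass
class EpochMetrics:
    epoch: int
    valid_ratio: float
    unique_ratio: float
    desired_ratio: float
    mean_arithmetic: float
    mean_geometric: float
    accurate_ratio: float | None = None
    per_objective_mean: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        row = asdict(self)
        per = row.pop("per_objective_mean")
        for k, v in per.items():
            row[f"mean_{k}"] = v
        return row


def mixed_sample(agent, prior, epsilon: float, n: int, rng,
                 inputs=None, aux=None):
    """Draw n molecules: each from the prior with probability epsilon, else
    from the agent (or, half the time, from the periodically refreshed
    auxiliary copy when one is given). Returns (smiles, codes, provenance)
    with provenance 'prior' / 'agent' / 'aux'."""
    from_prior = rng.random(n) < epsilon
    n_prior = int(from_prior.sum())
    n_agent = n - n_prior

    def draw(gen, m):
        if m == 0:
            return [], []
        if gen.requires_inputs:
            return gen.sample_smiles(m, inputs, rng)
        return gen.sample_smiles(m, rng)

    if aux is not None and n_agent > 1:
        n_aux = n_agent // 2
        n_agent -= n_aux
    else:
        n_aux = 0
    agent_smi, agent_codes = draw(agent, n_agent)
    aux_smi, aux_codes = draw(aux, n_aux) if n_aux else ([], [])
    prior_smi, prior_codes = draw(prior, n_prior)
    smiles = list(agent_smi) + list(aux_smi) + list(prior_smi)
    codes = list(agent_codes) + list(aux_codes) + list(prior_codes)
    provenance = (["agent"] * len(agent_smi) + ["aux"] * len(aux_smi)
                  + ["prior"] * len(prior_smi))
    return smiles, codes, provenance


def _pad_codes(codes_list) -> np.ndarray:
    T = max(len(c) for c in codes_list)
    out = np.full((len(codes_list), T), PAD, dtype=np.int64)
    for i, c in enumerate(codes_list):
        out[i, :len(c)] = c
    return out


def policy_gradient_update(agent, codes_list, rewards: np.ndarray,
                           optimizer) -> float:
    """One REINFORCE step on a batch of sampled sequences.

    loss = mean_i reward_i * (-log p_agent(sequence_i)); sequences of invalid
    molecules should already carry reward 0. Returns the batch loss."""
    rewards = np.asarray(rewards, dtype=float)
    if len(codes_list) != len(rewards):
        raise ValueError("one reward per molecule required")
    if isinstance(codes_list[0], (list, np.ndarray)):
        codes = _pad_codes([np.asarray(c) for c in codes_list])
        logp = agent.sequence_log_prob(codes)          # Tensor (B,)
        loss = (logp * (-rewards / len(rewards))).sum()
    else:
        # graph items: (memory columns, stream) per molecule
        from .tensor import concat
        terms = []
        for (mem, stream), r in zip(codes_list, rewards):
            lp = agent.stream_log_prob(mem, stream)
            terms.append(lp * (-float(r) / len(rewards)))
        loss = concat([t.reshape(1, 1) for t in terms], axis=1).sum()
    if not np.isfinite(loss.item()):
        raise FloatingPointError("non-finite policy-gradient loss")
    optimizer.zero_grad()
    loss.backward()
    optimizer.step()
    return loss.item()


def compute_metrics(epoch: int, smiles: list[str], table: ScoreTable,
                    fragment_inputs=None) -> EpochMetrics:
    """Per-epoch sample quality metrics.

    Arithmetic/geometric means are taken over the modified scores of valid
    molecules, per objective and then averaged across objectives; geometric
    mean of any zeros is zero, so geometric <= arithmetic always holds."""
    n = len(smiles)
    mols = [Chem.MolFromSmiles(s) if s else None for s in smiles]
    valid_mask = np.array([m is not None for m in mols])
    valid_ratio = float(valid_mask.mean()) if n else 0.0
    canon = {Chem.MolToSmiles(m) for m in mols if m is not None}
    unique_ratio = float(len(canon) / n) if n else 0.0
    desired_ratio = float(np.mean(table.desired)) if n else 0.0
    if valid_mask.any():
        vals = table.modified[valid_mask]              # (nv, k)
        per_arith = vals.mean(axis=0)
        per_geo = np.exp(np.mean(np.log(np.clip(vals, 1e-12, None)), axis=0))
        per_geo = np.where((vals == 0).any(axis=0), 0.0, per_geo)
        mean_arith = float(per_arith.mean())
        mean_geo = float(per_geo.mean())
        per_obj = {name: float(v) for name, v
                   in zip(table.objective_names, per_arith)}
    else:
        mean_arith = mean_geo = 0.0
        per_obj = {name: 0.0 for name in table.objective_names}
    accurate = None
    if fragment_inputs is not None:
        hits, total = 0, 0
        for i, m in enumerate(mols):
            if m is None:
                continue
            frags = fragment_inputs[i % len(fragment_inputs)]
            total += 1
            queries = [Chem.MolFromSmiles(f) for f in frags]
            if all(q is not None and m.HasSubstructMatch(q) for q in queries):
                hits += 1
        accurate = hits / total if total else 0.0
    return EpochMetrics(epoch=epoch, valid_ratio=valid_ratio,
                        unique_ratio=unique_ratio, desired_ratio=desired_ratio,
                        mean_arithmetic=mean_arith, mean_geometric=mean_geo,
                        accurate_ratio=accurate, per_objective_mean=per_obj)


def rl_train(agent, prior, environment: Environment, cfg: ExplorerConfig,
             inputs=None, out_dir=None):
    """Policy-gradient training loop.

    Returns (best agent, metrics log, sync_epochs). The auxiliary network,
    when enabled, is refreshed from the agent every ``sync_interval`` epochs.
    The best epoch by ``monitor_metric`` is restored into the agent before
    returning; per-epoch molecule TSVs and the metrics log are written under
    ``out_dir`` when given."""
    if agent.vocab.hash() != prior.vocab.hash():
        raise ValueError("agent and prior must share a vocabulary")
    if cfg.epochs == 0:
        return agent, [], []
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(agent.parameters(), lr=cfg.learning_rate)
    aux = copy.deepcopy(agent) if cfg.use_periodic_agent else None
    best_state, best_metric, bad = agent.state_dict(), None, 0
    log, sync_epochs = [], []
    failures = 0
    for epoch in range(1, cfg.epochs + 1):
        if aux is not None and epoch > 1 and (epoch - 1) % cfg.sync_interval == 0:
            aux.load_state_dict(agent.state_dict())
            sync_epochs.append(epoch - 1)
        smiles, codes, provenance = mixed_sample(
            agent, prior, cfg.epsilon, cfg.batch_size, rng,
            inputs=inputs, aux=aux)
        try:
            table = environment.score(smiles)
        except Exception:
            logger.exception("environment failed at epoch %d; skipping", epoch)
            failures += 1
            if failures > cfg.max_failures:
                raise RuntimeError("too many consecutive environment failures")
            continue
        failures = 0
        rewards = np.where(table.valid, table.reward, 0.0)
        loss = policy_gradient_update(agent, codes, rewards, opt)
        metrics = compute_metrics(epoch, smiles, table,
                                  fragment_inputs=inputs)
        log.append(metrics)
        if out_dir is not None:
            _write_epoch(out_dir, epoch, table, provenance)
        value = getattr(metrics, cfg.monitor_metric)
        if best_metric is None or value > best_metric:
            best_metric, best_state, bad = value, agent.state_dict(), 0
        else:
            bad += 1
            if bad > cfg.patience:
                break
    agent.load_state_dict(best_state)
    if out_dir is not None:
        _write_log(out_dir, log, cfg)
    return agent, log, sync_epochs


def _write_epoch(out_dir, epoch, table: ScoreTable, provenance):
    from pathlib import Path
    p = Path(out_dir)
    p.mkdir(parents=True, exist_ok=True)
    frame = table.to_frame()
    frame["provenance"] = provenance
    frame.to_csv(p / f"molecules_epoch_{epoch:04d}.tsv", sep="\t", index=False)


def _write_log(out_dir, log, cfg):
    from pathlib import Path
    import pandas as pd
    p = Path(out_dir)
    p.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([m.as_row() for m in log]).to_csv(
        p / "rl_log.tsv", sep="\t", index=False)
    with open(p / "rl_run.json", "w", encoding="utf-8") as fh:
        json.dump({"config": asdict(cfg)}, fh, indent=2)
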