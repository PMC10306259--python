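"""The three de novo generator architectures and their training loops.

* :class:`RnnGenerator` — token-level SMILES language model: an embedding
  layer, three recurrent layers (LSTM or GRU), a linear layer and a softmax.
  Generates molecules from scratch; no fragment input.
* :class:`SeqTransformerGenerator` — decoder-only transformer with multi-head
  attention and position-wise feed-forward layers. Conditioned on an input
  fragment combination (tokens before a separator), it grows a full molecule.
* :class:`GraphTransformerGenerator` — transformer encoder over the input
  fragments' graph columns plus a GRU decoder with cross-attention that emits
  graph-matrix columns. Valence-aware masking during sampling means every
  emitted column sequence decodes to a chemically valid molecule.

Training minimizes the average negative log-likelihood of the target tokens;
the loss on a held-out test split is evaluated every epoch for model selection
and early stopping. All randomness flows from explicit seeds, so runs are
reproducible on one machine.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
from rdkit import Chem

from . import nn
from .tensor import Tensor, concat
from .corpus import (GO, EOS, PAD, SEP, GraphVocabulary, SmilesVocabulary,
                     decode_smiles, encode_graph, fragment_columns,
                     tokenize_smiles, _BOND_CODES, _CODE_BONDS,
                     _N_GRAPH_CONTROL)
from .molprep import FragmentPair

logger = logging.getLogger(__name__)

__all__ = [
    "nll_loss", "RnnGeneratorSpec", "SeqTransformerSpec",
    "GraphTransformerSpec", "TrainConfig", "RnnGenerator",
    "SeqTransformerGenerator", "GraphTransformerGenerator",
    "pretrain", "finetune", "sample", "save_checkpoint", "load_checkpoint",
]


# ==========================================================================
# Loss

def nll_loss(predicted: np.ndarray, targets: np.ndarray) -> float:
    """Mean negative log-likelihood of the targets under per-position
    probability distributions.

    ``predicted`` has shape (..., T, V) and rows summing to one; ``targets``
    has shape (..., T). Padding positions (target == PAD) are excluded from
    the mean.
    """
    predicted = np.asarray(predicted, dtype=float)
    targets = np.asarray(targets)
    if predicted.shape[:-1] != targets.shape:
        raise ValueError(f"shape mismatch: distributions {predicted.shape} "
                         f"vs targets {targets.shape}")
    p = np.take_along_axis(predicted, targets[..., None], axis=-1)[..., 0]
    mask = targets != PAD
    return float(-(np.log(np.clip(p, 1e-300, None)) * mask).sum() / mask.sum())


# ==========================================================================
# Specs and training config

@dataclass(frozen=True)
class RnnGeneratorSpec:
    cell: str = "LSTM"                # LSTM or GRU
    n_recurrent_layers: int = 3
    embedding_size: int = 64
    hidden_size: int = 128

    def __post_init__(self):
        if self.cell not in ("LSTM", "GRU"):
            raise ValueError("cell must be LSTM or GRU")
        if self.n_recurrent_layers < 1:
            raise ValueError("need at least one recurrent layer")


@dataclass(frozen=True)
class SeqTransformerSpec:
    n_heads: int = 4
    n_layers: int = 2
    model_dim: int = 64
    ff_dim: int = 128
    max_len: int = 160

    def __post_init__(self):
        if self.model_dim % self.n_heads:
            raise ValueError("model_dim must be divisible by n_heads")


@dataclass(frozen=True)
class GraphTransformerSpec:
    n_heads: int = 4
    n_enc_layers: int = 2
    model_dim: int = 64
    ff_dim: int = 128
    dec_hidden: int = 128
    max_atoms: int = 64

    def __post_init__(self):
        if self.model_dim % self.n_heads:
            raise ValueError("model_dim must be divisible by n_heads")


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 5e-3
    patience: int = 5
    monitor: str = "test_loss"        # or "smiles_validity"
    seed: int = 0
    test_fraction: float = 0.15
    validity_sample: int = 200        # per-epoch samples for validity monitor

    def __post_init__(self):
        if self.patience > self.epochs:
            raise ValueError("patience must not exceed epochs")
        if self.monitor not in ("test_loss", "smiles_validity"):
            raise ValueError(f"unknown monitor {self.monitor!r}")


# ==========================================================================
# SMILES RNN

class RnnGenerator(nn.Module):
    """SMILES language model: embedding, stacked recurrent layers, linear,
    softmax. Ignores fragment inputs."""

    requires_inputs = False

    def __init__(self, spec: RnnGeneratorSpec, vocab: SmilesVocabulary,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.vocab = vocab
        V = vocab.size
        self.embed = nn.Embedding(V, spec.embedding_size, rng)
        Cell = nn.LSTMCell if spec.cell == "LSTM" else nn.GRUCell
        sizes = [spec.embedding_size] + [spec.hidden_size] * spec.n_recurrent_layers
        self.cells = [Cell(sizes[i], sizes[i + 1], rng)
                      for i in range(spec.n_recurrent_layers)]
        self.out = nn.Linear(spec.hidden_size, V, rng)

    # -- core forward ------------------------------------------------------

    def _init_state(self, B):
        H = self.spec.hidden_size
        zeros = lambda: Tensor(np.zeros((B, H)))
        if self.spec.cell == "LSTM":
            return [(zeros(), zeros()) for _ in self.cells]
        return [zeros() for _ in self.cells]

    def _step(self, x: Tensor, state):
        new_state = []
        for i, cell in enumerate(self.cells):
            if self.spec.cell == "LSTM":
                h, c = cell(x, *state[i])
                new_state.append((h, c))
                x = h
            else:
                h = cell(x, state[i])
                new_state.append(h)
                x = h
        return self.out(x), new_state

    def log_probs(self, codes: np.ndarray) -> Tensor:
        """Log-probability of each target token: shape (B, T-1).

        Teacher forcing: position t predicts ``codes[:, t+1]``."""
        codes = np.asarray(codes)
        B, T = codes.shape
        state = self._init_state(B)
        steps = []
        for t in range(T - 1):
            x = self.embed(codes[:, t])
            logits, state = self._step(x, state)
            lp = logits.log_softmax(axis=-1)
            tgt = codes[:, t + 1]
            picked = _take_targets(lp, tgt)
            steps.append(picked)
        return concat([s.reshape(B, 1) for s in steps], axis=1)

    def loss_on_batch(self, codes: np.ndarray) -> Tensor:
        lp = self.log_probs(codes)
        mask = (codes[:, 1:] != PAD).astype(float)
        return (lp * Tensor(-mask)).sum() * (1.0 / mask.sum())

    def sequence_log_prob(self, codes: np.ndarray) -> Tensor:
        """Per-sequence summed log-likelihood (B,), pads masked."""
        lp = self.log_probs(codes)
        mask = (codes[:, 1:] != PAD).astype(float)
        return (lp * Tensor(mask)).sum(axis=1)

    # -- sampling ----------------------------------------------------------

    def sample_codes(self, n: int, max_len: int, rng,
                     temperature: float = 1.0) -> np.ndarray:
        """Multinomial sampling at the given temperature; returns (n, <=max_len)
        integer codes beginning with GO."""
        if n == 0:
            return np.zeros((0, 1), dtype=np.int64)
        state = self._init_state(n)
        cur = np.full(n, GO, dtype=np.int64)
        rows = [cur.copy()]
        done = np.zeros(n, dtype=bool)
        for _ in range(max_len - 1):
            x = self.embed(cur)
            logits, state = self._step(x, state)
            state = _detach_state(state)
            probs = _softmax_np(logits.data / temperature)
            probs[:, PAD] = 0.0
            probs[:, GO] = 0.0
            probs[:, SEP] = 0.0
            probs /= probs.sum(axis=1, keepdims=True)
            cur = _multinomial(probs, rng)
            cur[done] = PAD
            done |= cur == EOS
            rows.append(cur.copy())
            if done.all():
                break
        return np.stack(rows, axis=1)

    def sample_smiles(self, n: int, rng, max_len: int = 128,
                      temperature: float = 1.0):
        codes = self.sample_codes(n, max_len, rng, temperature)
        smiles = [decode_smiles(list(row), self.vocab) for row in codes]
        return smiles, codes

    def meta(self):
        return {"class": "RnnGenerator", "spec": asdict(self.spec),
                "vocab": list(self.vocab.tokens),
                "vocab_hash": self.vocab.hash()}


def _take_targets(lp: Tensor, targets: np.ndarray) -> Tensor:
    """Pick lp[i, targets[i]] with gradient (lp shape (B, V))."""
    B = lp.shape[0]
    out = Tensor(lp.data[np.arange(B), targets], _prev=(lp,))

    def bwd(g):
        if lp.requires_grad:
            if lp.grad is None:
                lp.grad = np.zeros_like(lp.data)
            lp.grad[np.arange(B), targets] += g

    out._backward = bwd
    return out


def _detach_state(state):
    def det(t):
        return Tensor(t.data)
    if isinstance(state[0], tuple):
        return [(det(h), det(c)) for h, c in state]
    return [det(h) for h in state]


def _softmax_np(x):
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _multinomial(probs, rng):
    c = probs.cumsum(axis=1)
    r = rng.random((probs.shape[0], 1))
    return (r < c).argmax(axis=1).astype(np.int64)


# ==========================================================================
# Sequence transformer (decoder-only)

class SeqTransformerGenerator(nn.Module):
    """Decoder-only transformer over ``GO frags <sep> molecule EOS`` token
    streams. Requires fragment inputs; the loss and the sampled region are
    the tokens after the separator."""

    requires_inputs = True

    def __init__(self, spec: SeqTransformerSpec, vocab: SmilesVocabulary,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.vocab = vocab
        V = vocab.size
        self.embed = nn.Embedding(V, spec.model_dim, rng)
        self.pos = nn.Embedding(spec.max_len, spec.model_dim, rng)
        self.blocks = [nn.TransformerBlock(spec.model_dim, spec.n_heads,
                                           spec.ff_dim, rng)
                       for _ in range(spec.n_layers)]
        self.ln_f = nn.LayerNorm(spec.model_dim)
        self.out = nn.Linear(spec.model_dim, V, rng)

    def _logits(self, codes: np.ndarray) -> Tensor:
        B, T = codes.shape
        if T > self.spec.max_len:
            raise ValueError(f"sequence length {T} exceeds max_len "
                             f"{self.spec.max_len}")
        x = self.embed(codes) + self.pos(np.tile(np.arange(T), (B, 1)))
        for blk in self.blocks:
            x = blk(x, causal=True)
        return self.out(self.ln_f(x))

    def log_probs(self, codes: np.ndarray) -> Tensor:
        lp = self._logits(codes[:, :-1]).log_softmax(axis=-1)
        B, Tm1, V = lp.shape
        tgt = codes[:, 1:]
        flat = lp.reshape(B * Tm1, V)
        picked = _take_targets(flat, tgt.reshape(-1))
        return picked.reshape(B, Tm1)

    @staticmethod
    def _loss_mask(codes: np.ndarray) -> np.ndarray:
        """Supervise only tokens after the separator (the molecule part)."""
        after = np.cumsum(codes == SEP, axis=1) > 0
        mask = after[:, :-1] & (codes[:, 1:] != PAD)
        return mask.astype(float)

    def loss_on_batch(self, codes: np.ndarray) -> Tensor:
        lp = self.log_probs(codes)
        mask = self._loss_mask(codes)
        return (lp * Tensor(-mask)).sum() * (1.0 / max(mask.sum(), 1.0))

    def sequence_log_prob(self, codes: np.ndarray) -> Tensor:
        lp = self.log_probs(codes)
        return (lp * Tensor(self._loss_mask(codes))).sum(axis=1)

    # -- sampling ----------------------------------------------------------

    def _prefix(self, fragments) -> list[int]:
        toks = tokenize_smiles(".".join(fragments))
        return [GO] + [self.vocab.code_of(t) for t in toks] + [SEP]

    def sample_smiles(self, n: int, inputs, rng, temperature: float = 1.0):
        """Sample n molecules conditioned on the fragment combination(s).

        ``inputs`` is a list of fragment tuples; one is chosen per sample
        round-robin."""
        if not inputs:
            raise ValueError("sequence transformer requires fragment inputs")
        smiles_out, codes_out = [], []
        for i in range(n):
            frags = inputs[i % len(inputs)]
            prefix = self._prefix(tuple(frags))
            codes = list(prefix)
            for _ in range(self.spec.max_len - len(prefix) - 1):
                logits = self._logits(np.array([codes]))
                probs = _softmax_np(logits.data[0, -1] / temperature)
                probs[[PAD, GO, SEP]] = 0.0
                probs /= probs.sum()
                nxt = int(_multinomial(probs[None, :], rng)[0])
                codes.append(nxt)
                if nxt == EOS:
                    break
            mol_codes = codes[codes.index(SEP) + 1:]
            smiles_out.append(decode_smiles(mol_codes, self.vocab))
            codes_out.append(codes)
        return smiles_out, codes_out

    def meta(self):
        return {"class": "SeqTransformerGenerator", "spec": asdict(self.spec),
                "vocab": list(self.vocab.tokens),
                "vocab_hash": self.vocab.hash()}


# ==========================================================================
# Graph transformer: encoder over fragment columns + GRU decoder

# decoder action space: one action per atom type, then CLOSE, then EOS
def _n_actions(vocab: GraphVocabulary) -> int:
    return len(vocab.atom_types) + 2


#: maximum bonding capacity per atom descriptor (Kekulé orders)
_DEFAULT_VALENCE = {"B": 3, "C": 4, "N": 3, "O": 2, "F": 1, "P": 3, "S": 2,
                    "Cl": 1, "Br": 1, "I": 1}


def _capacity(descriptor: str) -> int:
    sym, charge, nh = descriptor.split("|")
    charge, nh = int(charge), int(nh)
    base = _DEFAULT_VALENCE.get(sym, 4)
    if sym in ("N", "P", "B"):
        base += charge
    elif sym in ("O", "S"):
        base -= abs(charge)
    return max(base - nh, 0)


class GraphTransformerGenerator(nn.Module):
    """Fragment-conditioned graph generator.

    The encoder embeds the input fragments' graph columns and runs them
    through transformer blocks; the GRU decoder, with dot-product attention
    over the encoder memory, emits one graph column per step as an (action,
    attachment pointer(s), bond type) tuple. During sampling every head is
    masked to chemically legal choices (free valence, existing atoms, no
    duplicate bonds, connectivity before EOS), so decoded outputs are always
    valid molecules."""

    requires_inputs = True

    def __init__(self, spec: GraphTransformerSpec, vocab: GraphVocabulary,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.vocab = vocab
        D, H = spec.model_dim, spec.dec_hidden
        nA = _n_actions(vocab)
        self.act_embed = nn.Embedding(nA + 1, D, rng)      # +1: GO slot
        self.bond_embed = nn.Embedding(5, D, rng)
        self.pos_embed = nn.Embedding(spec.max_atoms + 1, D, rng)
        self.frag_embed = nn.Embedding(34, D, rng)
        self.enc_blocks = [nn.TransformerBlock(D, spec.n_heads, spec.ff_dim, rng)
                           for _ in range(spec.n_enc_layers)]
        self.enc_ln = nn.LayerNorm(D)
        self.dec_cell = nn.GRUCell(D, H, rng)
        self.attn_q = nn.Linear(H, D, rng, bias=False)
        self.merge = nn.Linear(H + D, H, rng)
        self.head_action = nn.Linear(H, nA, rng)
        self.head_ptr1 = nn.Linear(H, spec.max_atoms, rng)
        self.head_ptr2 = nn.Linear(H, spec.max_atoms, rng)
        self.head_bond = nn.Linear(H, 3, rng)              # single/double/triple
        self.init_h = nn.Linear(D, H, rng)

    # -- encoding helpers --------------------------------------------------

    def encode_memory(self, columns) -> Tensor:
        """Embed and contextualize the input-fragment columns: (1, M, D)."""
        cols = np.asarray(columns, dtype=np.int64)
        a = cols[:, 0] - _N_GRAPH_CONTROL + 2  # shift atom codes into act space
        x = (self.act_embed(a[None, :])
             + self.bond_embed(cols[None, :, 3])
             + self.pos_embed(cols[None, :, 1])
             + self.pos_embed(cols[None, :, 2])
             + self.frag_embed(np.clip(cols[None, :, 4], 0, 33)))
        for blk in self.enc_blocks:
            x = blk(x)
        return self.enc_ln(x)

    def _step_input(self, prev) -> np.ndarray:
        """Decoder input ids for one previous column."""
        action, p1, p2, bond = prev
        return action, max(p1, 0), max(p2, 0), max(bond, 0)

    def _decode_step(self, prev, h: Tensor, memory: Tensor):
        action, p1, p2, bond = self._step_input(prev)
        x = (self.act_embed(np.array([action]))
             + self.bond_embed(np.array([bond]))
             + self.pos_embed(np.array([p1]))
             + self.pos_embed(np.array([p2])))
        h = self.dec_cell(x, h)
        q = self.attn_q(h)                                 # (1, D)
        att = (q @ memory.reshape(memory.shape[1], memory.shape[2])
               .transpose_last2()) * (1.0 / np.sqrt(self.spec.model_dim))
        w = att.softmax(axis=-1)
        ctx = w @ memory.reshape(memory.shape[1], memory.shape[2])
        hc = self.merge(concat([h, ctx], axis=1)).tanh()
        return h, hc

    def _initial_state(self, memory: Tensor) -> Tensor:
        pooled = Tensor(memory.data.mean(axis=1), _prev=(memory,))

        def bwd(g):
            if memory.requires_grad:
                memory._accum(np.repeat(g[:, None, :], memory.shape[1],
                                        axis=1) / memory.shape[1])
        pooled._backward = bwd
        return self.init_h(pooled).tanh()

    # -- training ----------------------------------------------------------

    GO_ACTION = 0     # reserved act_embed slot for the start step
    CLOSE_EMBED = 1   # reserved act_embed slot for a preceding CLOSE step

    def stream_log_prob(self, memory_cols, stream) -> Tensor:
        """Summed log-likelihood of a target column stream (one molecule)."""
        memory = self.encode_memory(memory_cols)
        h = self._initial_state(memory)
        prev = (self.GO_ACTION, -1, -1, -1)
        terms = []
        for (action, p1, p2, bond) in stream:
            h, hc = self._decode_step(prev, h, memory)
            lp_act = self.head_action(hc).log_softmax(axis=-1)
            terms.append(_take_targets(lp_act, np.array([action])))
            if p1 >= 0:
                lp1 = self.head_ptr1(hc).log_softmax(axis=-1)
                terms.append(_take_targets(lp1, np.array([p1])))
            if p2 >= 0:
                lp2 = self.head_ptr2(hc).log_softmax(axis=-1)
                terms.append(_take_targets(lp2, np.array([p2])))
            if bond >= 0:
                lpb = self.head_bond(hc).log_softmax(axis=-1)
                terms.append(_take_targets(lpb, np.array([bond - 1])))
            prev = (action + 2 if action < len(self.vocab.atom_types)
                    else self.CLOSE_EMBED, p1, p2, bond)
        return concat([t.reshape(1, 1) for t in terms], axis=1).sum()

    def loss_on_items(self, items) -> Tensor:
        """Mean per-supervised-slot NLL over a list of (memory, stream)."""
        total, count = [], 0
        for mem, stream in items:
            total.append(self.stream_log_prob(mem, stream) * -1.0)
            count += sum(1 + (p1 >= 0) + (p2 >= 0) + (b >= 0)
                         for (_, p1, p2, b) in stream)
        return concat([t.reshape(1, 1) for t in total], axis=1).sum() \
            * (1.0 / max(count, 1))

    # -- masked sampling ---------------------------------------------------

    def sample_smiles(self, n: int, inputs, rng, temperature: float = 1.0,
                      max_steps: int = 48):
        """Sample n molecules; each is guaranteed valid by masked decoding.

        The input fragments are placed as the initial partial molecule; the
        decoder then adds atoms, ring/link closures and finally EOS (only
        reachable once the graph is connected)."""
        if not inputs:
            raise ValueError("graph transformer requires fragment inputs")
        out_smiles, out_items = [], []
        for i in range(n):
            frags = tuple(inputs[i % len(inputs)])
            smi, item = self._sample_one(frags, rng, temperature, max_steps)
            out_smiles.append(smi)
            out_items.append(item)
        return out_smiles, out_items

    def _sample_one(self, frags, rng, temperature, max_steps):
        cols = fragment_columns(list(frags), self.vocab)
        memory = self.encode_memory(cols)
        h = self._initial_state(memory)
        prev = (self.GO_ACTION, -1, -1, -1)

        state = _GraphState(self.vocab, self.spec.max_atoms)
        for (a, idx, nb, bcode, frag) in cols:
            if idx == len(state.descs):
                state.add_atom(self.vocab.descriptor_of(a), frag)
                if nb != idx:
                    state.add_bond(int(nb), int(idx), int(bcode))
            else:                       # ring closure inside a fragment
                state.add_bond(int(nb), int(idx), int(bcode))
        stream = []
        n_types = len(self.vocab.atom_types)
        CLOSE, STOP = n_types, n_types + 1
        for _ in range(max_steps):
            h, hc = self._decode_step(prev, h, memory)
            act_mask = state.action_mask()
            lp = self.head_action(hc).data[0] / temperature
            lp[~act_mask] = -np.inf
            action = int(_multinomial(_softmax_np(lp[None, :]), rng)[0])
            if action == STOP:
                break
            if action == CLOSE:
                m1 = state.close_ptr1_mask()
                p1 = self._pick(self.head_ptr1(hc).data[0], m1, temperature, rng)
                m2 = state.close_ptr2_mask(p1)
                p2 = self._pick(self.head_ptr2(hc).data[0], m2, temperature, rng)
                bmask = state.bond_mask(state.free(p1), state.free(p2))
                b = self._pick(self.head_bond(hc).data[0], bmask,
                               temperature, rng) + 1
                state.add_bond(min(p1, p2), max(p1, p2), b)
                stream.append((CLOSE, max(p1, p2), min(p1, p2), b))
                prev = (self.CLOSE_EMBED, p1, p2, b)
            else:
                desc = self.vocab.atom_types[action]
                m1 = state.attach_mask()
                p1 = self._pick(self.head_ptr1(hc).data[0], m1, temperature, rng)
                bmask = state.bond_mask(state.free(p1), _capacity(desc))
                b = self._pick(self.head_bond(hc).data[0], bmask,
                               temperature, rng) + 1
                new_idx = state.add_atom(desc, 0)
                state.add_bond(p1, new_idx, b)
                stream.append((action, p1, -1, b))
                prev = (action + 2, p1, new_idx, b)
        smiles = state.to_smiles()
        return smiles, (cols, stream)

    @staticmethod
    def _pick(logits, mask, temperature, rng):
        l = logits.copy() / temperature
        l[~mask] = -np.inf
        return int(_multinomial(_softmax_np(l[None, :]), rng)[0])

    def meta(self):
        return {"class": "GraphTransformerGenerator", "spec": asdict(self.spec),
                "vocab": list(self.vocab.atom_types),
                "vocab_hash": self.vocab.hash()}


class _GraphState:
    """Partial molecule bookkeeping for masked graph decoding."""

    def __init__(self, vocab: GraphVocabulary, max_atoms: int):
        self.vocab = vocab
        self.max_atoms = max_atoms
        self.descs: list[str] = []
        self.caps: list[int] = []
        self.used: list[int] = []
        self.bonds: dict[tuple[int, int], int] = {}
        self.comp: list[int] = []          # union-find parent

    # union-find ----------------------------------------------------------
    def _find(self, i):
        while self.comp[i] != i:
            self.comp[i] = self.comp[self.comp[i]]
            i = self.comp[i]
        return i

    def n_components(self):
        return len({self._find(i) for i in range(len(self.descs))})

    # construction ---------------------------------------------------------
    def add_atom(self, desc: str, frag: int) -> int:
        self.descs.append(desc)
        self.caps.append(_capacity(desc))
        self.used.append(0)
        self.comp.append(len(self.descs) - 1)
        return len(self.descs) - 1

    def add_bond(self, i: int, j: int, order: int):
        key = (min(i, j), max(i, j))
        if key in self.bonds:
            raise ValueError("duplicate bond")
        self.bonds[key] = order
        self.used[i] += order
        self.used[j] += order
        self.comp[self._find(i)] = self._find(j)

    def free(self, i: int) -> int:
        return self.caps[i] - self.used[i]

    # masks ----------------------------------------------------------------
    def _free_atoms(self):
        return [i for i in range(len(self.descs)) if self.free(i) >= 1]

    def _closable_pairs_exist(self):
        fa = self._free_atoms()
        for ii, i in enumerate(fa):
            for j in fa[ii + 1:]:
                if (i, j) not in self.bonds:
                    return True
        return False

    def action_mask(self) -> np.ndarray:
        n_types = len(self.vocab.atom_types)
        mask = np.zeros(n_types + 2, dtype=bool)
        can_grow = (len(self.descs) < self.max_atoms
                    and bool(self._free_atoms()))
        if can_grow:
            mask[:n_types] = True
        mask[n_types] = self._closable_pairs_exist()          # CLOSE
        mask[n_types + 1] = self.n_components() == 1           # EOS
        if not mask.any():
            # dead end: no legal growth and still disconnected; allow EOS
            # (largest component is returned, still a valid molecule)
            mask[n_types + 1] = True
        return mask

    def attach_mask(self) -> np.ndarray:
        m = np.zeros(self.max_atoms, dtype=bool)
        for i in self._free_atoms():
            m[i] = True
        return m

    def close_ptr1_mask(self) -> np.ndarray:
        m = np.zeros(self.max_atoms, dtype=bool)
        fa = self._free_atoms()
        for i in fa:
            if any(j != i and (min(i, j), max(i, j)) not in self.bonds
                   for j in fa):
                m[i] = True
        return m

    def close_ptr2_mask(self, p1: int) -> np.ndarray:
        m = np.zeros(self.max_atoms, dtype=bool)
        for j in self._free_atoms():
            if j != p1 and (min(p1, j), max(p1, j)) not in self.bonds:
                m[j] = True
        return m

    @staticmethod
    def bond_mask(free_a: int, free_b: int) -> np.ndarray:
        m = np.zeros(3, dtype=bool)
        m[:max(min(free_a, free_b, 3), 0)] = True
        if not m.any():
            m[0] = True   # unreachable by construction; keep sampling safe
        return m

    def to_smiles(self) -> str:
        em = Chem.RWMol()
        for desc in self.descs:
            sym, charge, nh = desc.split("|")
            atom = Chem.Atom(sym)
            atom.SetFormalCharge(int(charge))
            atom.SetNumExplicitHs(int(nh))
            em.AddAtom(atom)
        for (i, j), order in self.bonds.items():
            em.AddBond(i, j, _CODE_BONDS[order])
        mol = em.GetMol()
        frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
        largest = max(frags, key=lambda m: m.GetNumAtoms())
        Chem.SanitizeMol(largest)
        return Chem.MolToSmiles(largest)


# ==========================================================================
# Dataset builders

def encode_smiles_dataset(corpus: list[str], vocab: SmilesVocabulary,
                          max_len: int | None = None) -> np.ndarray:
    lengths = [len(tokenize_smiles(s)) + 2 for s in corpus]
    max_len = max_len or max(lengths)
    from .corpus import encode_smiles
    return np.array([encode_smiles(s, vocab, max_len).codes for s in corpus],
                    dtype=np.int64)


def encode_pair_dataset(pairs: list[FragmentPair], vocab: SmilesVocabulary,
                        max_len: int | None = None) -> np.ndarray:
    rows = []
    for p in pairs:
        ft = tokenize_smiles(".".join(p.fragments))
        mt = tokenize_smiles(p.molecule)
        rows.append([GO] + [vocab.code_of(t) for t in ft] + [SEP]
                    + [vocab.code_of(t) for t in mt] + [EOS])
    max_len = max_len or max(len(r) for r in rows)
    out = np.full((len(rows), max_len), PAD, dtype=np.int64)
    for i, r in enumerate(rows):
        if len(r) > max_len:
            raise ValueError("pair sequence exceeds max_len")
        out[i, :len(r)] = r
    return out


def encode_graph_dataset(pairs: list[FragmentPair],
                         vocab: GraphVocabulary) -> list:
    """Per pair: (memory columns of the input fragments, target column stream
    of the whole molecule)."""
    items = []
    n_types = len(vocab.atom_types)
    CLOSE = n_types
    for p in pairs:
        mem = fragment_columns(list(p.fragments), vocab)
        matrix = encode_graph(p, vocab)
        stream = []
        cells = matrix.cells
        n_seen = 0
        for j in range(cells.shape[1]):
            a, idx, nb, bcode, frag = cells[:, j]
            if a in (0, 1, 2) and bcode == 0 and idx == 0 and nb == 0:
                continue
            if a >= _N_GRAPH_CONTROL and idx == n_seen:
                if nb == idx:     # fragment-start column: no pointer/bond loss
                    stream.append((int(a) - _N_GRAPH_CONTROL, -1, -1, -1))
                else:
                    stream.append((int(a) - _N_GRAPH_CONTROL, int(nb), -1,
                                   int(bcode)))
                n_seen += 1
            else:                 # closure or linking column
                stream.append((CLOSE, int(idx), int(nb), int(bcode)))
        items.append((mem, stream))
    return items


# ==========================================================================
# Training loop

def _split(data, test_fraction, rng):
    n = len(data)
    idx = rng.permutation(n)
    n_test = max(1, int(round(n * test_fraction))) if n > 1 else 0
    test_idx, train_idx = idx[:n_test], idx[n_test:]
    if isinstance(data, np.ndarray):
        return data[train_idx], data[test_idx]
    return [data[i] for i in train_idx], [data[i] for i in test_idx]


def _epoch_metric_better(value, best, monitor):
    if best is None:
        return True
    return value < best if monitor == "test_loss" else value > best


def fit(model, data, cfg: TrainConfig, sample_inputs=None):
    """Train a generator on an encoded dataset with early stopping.

    Returns (model restored to its best epoch, log rows). ``data`` is an
    int array of token codes for sequence models, or a list of
    (memory, stream) items for the graph model.
    """
    if len(data) == 0:
        raise ValueError("empty training corpus")
    rng = np.random.default_rng(cfg.seed)
    train, test = _split(data, cfg.test_fraction, rng)
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    best_state, best_metric, bad = model.state_dict(), None, 0
    log = []

    def batch_loss(batch):
        if isinstance(batch, np.ndarray):
            return model.loss_on_batch(batch)
        return model.loss_on_items(batch)

    def eval_loss(ds):
        if len(ds) == 0:
            return float("nan")
        losses, sizes = [], []
        for batch in _batches(ds, cfg.batch_size):
            losses.append(batch_loss(batch).item())
            sizes.append(len(batch))
        return float(np.average(losses, weights=sizes))

    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(len(train))
        train_shuf = (train[order] if isinstance(train, np.ndarray)
                      else [train[i] for i in order])
        ep_losses = []
        for batch in _batches(train_shuf, cfg.batch_size):
            opt.zero_grad()
            loss = batch_loss(batch)
            if not np.isfinite(loss.item()):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}")
            loss.backward()
            opt.step()
            ep_losses.append(loss.item())
        train_loss = float(np.mean(ep_losses))
        test_loss = eval_loss(test)
        if cfg.monitor == "smiles_validity":
            srng = np.random.default_rng(cfg.seed * 1000 + epoch)
            if sample_inputs is not None:
                smis, _ = model.sample_smiles(cfg.validity_sample,
                                              sample_inputs, srng)
            else:
                smis, _ = model.sample_smiles(cfg.validity_sample, srng)
            monitor_value = float(np.mean(
                [Chem.MolFromSmiles(s) is not None for s in smis]))
        else:
            monitor_value = test_loss if np.isfinite(test_loss) else train_loss
        log.append({"epoch": epoch, "train_loss": train_loss,
                    "test_loss": test_loss, "monitor": monitor_value})
        if _epoch_metric_better(monitor_value, best_metric, cfg.monitor):
            best_metric, best_state, bad = monitor_value, model.state_dict(), 0
        else:
            bad += 1
            if bad > cfg.patience:
                break
    model.load_state_dict(best_state)
    return model, log


def _batches(data, batch_size):
    for i in range(0, len(data), batch_size):
        yield data[i:i + batch_size]


def pretrain(model, data, cfg: TrainConfig, sample_inputs=None):
    """Train from the model's current (fresh) initialization."""
    return fit(model, data, cfg, sample_inputs=sample_inputs)


def finetune(model, data, cfg: TrainConfig, sample_inputs=None):
    """Transfer learning: continue training pretrained weights on a focused
    set. With ``epochs=0`` the model is returned unchanged."""
    if len(data) == 0:
        raise ValueError("empty fine-tuning corpus")
    if cfg.epochs == 0:
        return model, []
    return fit(model, data, cfg, sample_inputs=sample_inputs)


def check_vocab_covers(model, corpus: list[str]):
    """Raise if the corpus uses tokens outside the model's vocabulary."""
    missing = set()
    for s in corpus:
        for t in tokenize_smiles(s):
            if t not in model.vocab.token_to_code:
                missing.add(t)
    if missing:
        raise ValueError(f"corpus tokens missing from model vocabulary: "
                         f"{sorted(missing)}")


def sample(generator, n: int, inputs=None, seed: int = 0,
           temperature: float = 1.0):
    """Sample n SMILES. RNNs ignore ``inputs`` (with a warning); transformer
    generators require them."""
    rng = np.random.default_rng(seed)
    if n == 0:
        return []
    if generator.requires_inputs:
        if not inputs:
            raise ValueError(f"{type(generator).__name__} requires fragment "
                             "inputs")
        smiles, _ = generator.sample_smiles(n, inputs, rng,
                                            temperature=temperature)
    else:
        if inputs:
            logger.warning("RNN generator ignores fragment inputs")
        smiles, _ = generator.sample_smiles(n, rng, temperature=temperature)
    return smiles


# ==========================================================================
# Checkpoints

_CLASSES = {}


def _register_classes():
    _CLASSES.update({
        "RnnGenerator": (RnnGenerator, RnnGeneratorSpec, "smiles"),
        "SeqTransformerGenerator": (SeqTransformerGenerator,
                                    SeqTransformerSpec, "smiles"),
        "GraphTransformerGenerator": (GraphTransformerGenerator,
                                      GraphTransformerSpec, "graph"),
    })


def save_checkpoint(generator, path) -> None:
    """Single-file serialization: weights + spec + vocabulary."""
    meta = generator.meta()
    state = generator.state_dict()
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8),
        **{f"w:{k}": v for k, v in state.items()})


def load_checkpoint(path, expect_vocab=None):
    """Rebuild a generator from a checkpoint file.

    If ``expect_vocab`` is given, refuse to load when its hash differs from
    the stored vocabulary hash."""
    if not _CLASSES:
        _register_classes()
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state = {k[2:]: z[k] for k in z.files if k.startswith("w:")}
    cls, spec_cls, kind = _CLASSES[meta["class"]]
    vocab = (SmilesVocabulary(tokens=tuple(meta["vocab"])) if kind == "smiles"
             else GraphVocabulary(atom_types=tuple(meta["vocab"])))
    if expect_vocab is not None and expect_vocab.hash() != meta["vocab_hash"]:
        raise ValueError("vocabulary hash mismatch: checkpoint was written "
                         "with a different vocabulary")
    gen = cls(spec_cls(**meta["spec"]), vocab)
    gen.load_state_dict(state)
    return gen
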