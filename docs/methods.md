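# Methods

This note records the models, the numerical choices and the limits of what
the test suite demonstrates.

## Molecule preparation

Standardization parses each input with RDKit, keeps the largest covalent
fragment (salt/solvent stripping), neutralizes charges where a simple proton
add/remove suffices (RDKit's `Uncharger`), and canonicalizes. A molecule is
*organic* iff every atom lies in {H, B, C, N, O, P, S, F, Cl, Br, I} and at
least one carbon is present — the standard medicinal-chemistry element set.
Failures are encoded in flags (`is_valid`, `is_organic`), never raised, so a
corpus run survives malformed rows.

Corpus filtering keeps valid, organic molecules with molecular weight in
[`min_weight`, `max_weight`] (defaults 200 and 1000 Da, the usual drug-like
training window) and deduplicates on canonical SMILES, preserving first
occurrence.

Fragmentation applies one pass of the BRICS or RECAP rule sets. BRICS uses
`BreakBRICSBonds` + fragment extraction rather than the set-valued
decomposition so that symmetric molecules keep the correct fragment
*multiset* (biphenyl yields two identical phenyl leaves, not one). Training
pairs enumerate all non-empty leaf subsets up to `max_fragments` (default 4),
capped at `subset_cap` = 16 subsets per molecule sampled under a fixed seed
(42), keeping corpus size linear in molecule count. Stereochemistry is
preserved in SMILES outputs but not in the graph codec.

## Encodings

**SMILES codec.** Regex tokenization treats bracket atoms, two-letter
elements and `%nn` ring closures as single tokens; a reconstruction check
rejects untokenizable input. Codes 0–3 are PAD/GO/EOS/SEP (SEP separates the
fragment prefix from the molecule in sequence-transformer streams — a small
extension of the GO/EOS/PAD control set); chemical tokens follow in sorted
order, so vocabulary construction is deterministic.

**Graph codec.** A molecule becomes a 5 × L integer matrix (default
L = 400). Columns are laid out as 1 GO column, a fragment block of width
d = L − 2 − n_link (default d = 360), 1 EOS column, and a linking block
(n_link = 38 columns) carrying bonds that join fragments. Within the
fragment block, each atom contributes one column — (atom-type code, atom
index, index of one already-placed in-fragment neighbor or itself at a
fragment start, bond code, 1-based fragment index) — and each ring closure
contributes an extra column re-using the current atom's index. Atom-type
descriptors are element | formal charge | explicit-H count; traversal is
breadth-first from the canonically lowest-ranked atom, neighbors in
canonical-rank order, so encoding is deterministic.

Bond orders are Kekulé (single/double/triple); an aromatic bond code is
reserved in the vocabulary but unused by the default encoder. This is the
one place the design deliberately departs from encoding aromatic bonds as
their own type: the graph decoder's validity guarantee rests on every decode
prefix being a sanitizable structure, and partially built aromatic rings are
not. With Kekulé orders, any valence-respecting bond set sanitizes, and
RDKit re-perceives aromaticity on decode, so round trips are canonical-exact.

Fragment regions are re-identified in the parent molecule by disjoint
substructure placement with fewest-options-first backtracking (greedy
placement fails on molecules where a small fragment's only placement lies
inside a larger fragment's match).

## Generators

All three models run on the package's reverse-mode autodiff core
(`denovogen.tensor`, float64 end to end), whose gradients are verified
against finite differences in the test suite. Training uses Adam at a fixed
learning rate, deterministic data splits and shuffles from the run seed, and
restores the best epoch by the monitored metric (held-out mean NLL per
token by default, or sampled-SMILES validity at 200 samples per epoch).
Early stopping triggers after `patience` consecutive non-improving epochs;
patience 0 stops at the first one.

* **RNN**: embedding (48) → three recurrent layers (LSTM or GRU, hidden 96)
  → linear → softmax; samples token-by-token from the softmax at temperature
  1.0. Defaults are desk-scale choices that reach ~30–70 % sampled validity
  after ~60 epochs on the 300-molecule toy corpus, depending on the
  initialization seed.
* **Sequence transformer**: decoder-only, pre-norm blocks with multi-head
  self-attention and position-wise feed-forward layers (default 2 layers,
  4 heads, model dim 64); input stream `GO fragments <sep> molecule EOS`,
  with loss and sampling confined to the post-separator region. Outputs may
  be invalid and are flagged, not dropped.
* **Graph transformer**: a transformer encoder contextualizes the input
  fragments' graph columns; a GRU decoder with dot-product cross-attention
  emits one column per step through four heads — action (atom type, CLOSE,
  or EOS), attachment pointer(s) over existing atom indices, and bond order.
  During sampling every head is masked to chemically legal choices: free
  valence on both partners (capacities from a fixed per-element table,
  charge-adjusted), no duplicate bonds, no self-bonds, and EOS reachable
  only once the partial graph is connected. Should growth dead-end while
  still disconnected (rare), the largest connected component is returned —
  still a valid molecule. Sampling therefore yields valid molecules by
  construction, and because the input fragments form the initial partial
  graph, they are incorporated by construction too. The teacher-forcing
  target stream orders linking columns before EOS; the matrix serialization
  keeps them in the linking block.

Checkpoints are single `.npz` files holding weights, the architecture spec
and the vocabulary (with a hash); loading refuses a mismatched vocabulary
hash.

## Scoring environment

Raw objective scores come from named scorers (molecular weight, a Crippen
logP estimate, Tanimoto similarity to a reference on 2048-bit radius-2
Morgan fingerprints, ligand efficiency = affinity / heavy-atom count, a
binary contains-nitrogen scorer, a deterministic constant stub for external
predictors, and a registration hook for arbitrary callables). The synthetic
accessibility entry is a simple declared fragment-complexity proxy
(penalties for macrocycles, ring fusion, stereocenters and size), not a
trained model.

Modifiers map raw scores into [0, 1]:

* **ClippedScore(low, high)** — piecewise-linear ramp, reversed when
  low > high (monotone in both directions);
* **Gaussian(center, σ)** — exp(−(x−center)²/2σ²);
* **SmoothHump(lower, upper, width)** — a product of two sigmoids with decay
  scale width (τ = width/4) shifted outward by one width, rescaled so the
  plateau center is exactly 1; symmetric about the plateau;
* **Identity** — pass-through for scorers that already emit desirabilities.

Desirability thresholds live in [0, 1] (default 0.5); the comparison is ≥,
so a threshold of 1.0 is attainable. A molecule is desired iff every
available objective passes. Invalid molecules receive modified scores of 0
on all objectives (keeping batches rectangular and letting RL penalize
invalidity); a scorer that raises marks its column missing for the batch and
the run continues.

## Multiobjective rewards

* **WS** — weights w_j ∝ (1 − column mean), renormalized; a uniformly
  perfect batch falls back to equal weights. The statistic driving the
  weights (the population mean per objective) is a design choice.
* **PRCD / PRTD** — fast non-dominated sort (maximization, ties share a
  front; verified against a brute-force all-pairs oracle), then intra-front
  ranking by NSGA-II crowding distance (boundary points infinite; interior
  points sum normalized neighbor gaps) or by mean Tanimoto distance to the
  other front members (the mean-distance variant; larger = more diverse =
  better). Ties break on canonical SMILES for reproducibility.
* Rank → reward: global order (front, then intra-front rank) is linearly
  interpolated, desired molecules into [0.5, 1.0] and undesired into
  [0, 0.5); a single desired molecule earns 1.0, a single undesired one 0.

## Reinforcement learning

Each epoch draws `batch_size` molecules: with probability ε (default 0.1)
from the frozen prior, otherwise from the agent — and when the periodic
auxiliary network is enabled (default for the RNN only), half of the agent
share comes from that copy, which is refreshed from the agent every
`sync_interval` epochs (default 50). The REINFORCE loss is
mean_i reward_i · (−log p_agent(sequence_i)); invalid molecules carry reward
0. The desired ratio selects the best epoch (patience default 100 epochs);
per-epoch molecules and metrics are written as TSV plus a JSON run manifest.

## Toy data

The fixture generator assembles molecules from curated building blocks
(benzene/pyridine/diazine/naphthalene rings, saturated N/O heterocycles,
amide/ester/ether/sulfonamide/alkene linkers, small caps) as
ring–linker–ring(–linker–ring) chains, filtered to a weight window (default
200–500 Da) and deduplicated — validity and organic composition are
guaranteed by construction. It emulates the size range and functional-group
mix of a drug-like screening set, not the property distributions, ring-system
diversity, stereochemistry or charge states of real databases such as
ChEMBL. Passing tests therefore demonstrate mechanism (losses fall, RL
shifts distributions, codecs are exact) at desk scale, not production-scale
generative quality.

## Problem sizes and numerical choices

The suite and the acceptance script run everything at small scale as the
package's own study conditions: 300-molecule corpora, 48/96 RNNs trained 60
epochs, RL for 20 epochs at batch 64 over 5 seeds, 100-molecule round-trip
and validity checks, 200 random instances for the sorting oracle. Sampling
temperature is 1.0 unless overridden. Degenerate inputs are defined
throughout: empty corpora raise, zero-epoch training returns the input
model, n = 0 sampling returns an empty list, single-member Pareto fronts get
infinite crowding distance, and an all-padding graph matrix is an error.

## Known limitations

* Graph encoding drops stereochemistry; the SMILES paths preserve it.
* The sequence transformer's fragment conditioning is not constrained, so
  its fragment-incorporation rate is learned, not guaranteed.
* The graph decoder's valence table is conservative (e.g. sulfur capacity 2
  during de novo growth), so hypervalent motifs such as new sulfonyl groups
  can be decoded from data but are not proposed by the sampler.
* The in-package autodiff core is single-threaded NumPy; it is sized for
  method development and testing, not for training production-scale models.
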