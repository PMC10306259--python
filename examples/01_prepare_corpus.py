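"""Standardize, filter and fragment a small molecule set.

Builds a deterministic toy corpus, pushes it through the preparation
pipeline and fragments acetaminophen with BRICS. The printed fragment count
(3) reflects cleavage of both bonds flanking the amide nitrogen; the retained
corpus honors the default 200-1000 Da drug-like window.
"""

from denovogen.fixtures import FixtureSpec, make_corpus
from denovogen.molprep import (PrepConfig, enumerate_pairs, filter_corpus,
                               fragment, standardize, strip_attachments)

corpus = make_corpus(FixtureSpec(n_molecules=50, seed=1))
records = [standardize(s) for s in corpus + ["not_a_smiles", "[Na+].[Cl-]"]]
kept = filter_corpus(records, PrepConfig())
print(f"{len(records)} records in, {len(kept)} kept "
      "(valid + organic + 200-1000 Da, deduplicated)")

rec = standardize("CC(=O)Nc1ccc(O)cc1")          # acetaminophen
leaves = fragment(rec, "BRICS")
print(f"acetaminophen -> {len(leaves)} BRICS fragments: {leaves}")
print("attachment-stripped:",
      [strip_attachments(f) for f in leaves])

pairs = enumerate_pairs(rec, PrepConfig(min_weight=0, max_fragments=3,
                                        subset_cap=0))
print(f"{len(pairs)} fragment-combination training pairs "
      "(all non-empty subsets of 3 leaves = 2^3 - 1)")
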