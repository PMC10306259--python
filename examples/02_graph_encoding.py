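"""Encode a fragmented molecule as the 5-row graph matrix and decode it back.

The matrix has one column per atom placement (plus ring-closure and
fragment-linking columns) inside a fixed 5 x 400 layout: GO block, fragment
block, EOS block, linking block. Row 5 carries the 1-based fragment index;
decoding reconstructs the exact molecule.
"""

import numpy as np

from denovogen.corpus import build_graph_vocab, decode_graph, encode_graph
from denovogen.molprep import (FragmentPair, fragment, standardize,
                               strip_attachments)

rec = standardize("CC(=O)Nc1ccc(O)cc1")          # acetaminophen
frags = tuple(strip_attachments(f) for f in fragment(rec))
pair = FragmentPair(fragments=frags, molecule=rec.canonical)

vocab = build_graph_vocab([rec.canonical, *frags])
matrix = encode_graph(pair, vocab)
print(f"matrix shape: {matrix.cells.shape}   "
      f"(fragment block {matrix.d} cols, linking block {matrix.n_link})")

block = matrix.cells[:, 1:1 + matrix.d]
used = block[:, block.any(axis=0)]
print(f"{used.shape[1]} used fragment columns; "
      f"fragment indices present: {sorted(set(used[4].tolist()))}")
print("first five columns (atom code, atom idx, neighbor idx, bond, frag):")
print(used[:, :5])

decoded = decode_graph(matrix, vocab)
print(f"decoded: {decoded}   round-trip exact: {decoded == rec.canonical}")
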