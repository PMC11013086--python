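"""Build a neighbor-joining tree with bootstrap supports for a family.

Simulates two diverged subfamilies of four members each, aligns them
with the center-star convenience aligner, computes Poisson-corrected
distances, and prints the NJ tree with bootstrap support percentages on
internal edges (100 column-resampled replicates).
"""

import numpy as np

from kincascade.core_io import SequenceRecord
from kincascade.motifs import AA20
from kincascade.phylogeny import align_family, bootstrap

rng = np.random.default_rng(7)


def mutate(seq: str, n: int) -> str:
    s = list(seq)
    for pos in rng.integers(0, len(s), size=n):
        s[pos] = AA20[rng.integers(20)]
    return "".join(s)


ancestor_a = "".join(AA20[i] for i in rng.integers(0, 20, size=120))
ancestor_b = mutate(ancestor_a, 60)  # deep split between subfamilies

records = [
    SequenceRecord(f"subA_{i}", mutate(ancestor_a, 6)) for i in range(4)
] + [
    SequenceRecord(f"subB_{i}", mutate(ancestor_b, 6)) for i in range(4)
]

alignment = align_family(records)
tree = bootstrap(alignment, B=100, model="poisson", seed=7)
print("NJ tree with bootstrap supports:")
print(tree.to_newick())
supports = [n.support for n in tree.internal_nodes() if n.support is not None]
print(f"\nInternal-edge supports: {supports}")
print("The deep subfamily split should carry ~100% support; shallow edges "
      "within a subfamily may be weakly resolved.")
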