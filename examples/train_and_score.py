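"""Train a knowledge-based potential and rank sequences with it.

Trains the distance-binned pair potential on a few synthetic complexes
(count statistics of protein-DNA atom pairs), then scores every threaded
sequence of a held complex and shows where the native sequence ranks.
"""

from motifthread import curate_complex, train_potential
from motifthread.fixtures import FixtureSpec, make_toy_complex
from motifthread.pipeline import thread_and_score

complexes = []
for seed in range(4):
    spec = FixtureSpec(seed=seed, duplex_length=9, contact_positions=(3, 4, 5))
    complexes.append(curate_complex(make_toy_complex(spec)))

potential = train_potential(complexes)
print(f"trained on {potential.meta['n_complexes']} complexes, "
      f"{potential.meta['n_pairs']} atom pairs, "
      f"{len(potential.energies)} non-zero energy cells")

held = complexes[0]
table = thread_and_score(held, potential).scores
ranked = sorted(table, key=table.get)
rank = ranked.index(held.native_sequence) + 1
print(f"native sequence {held.native_sequence} ranks {rank} of {len(ranked)}")
print(f"best 3: {ranked[:3]}  (lower score = stronger predicted binding)")
# Training counts favor the atom pairings seen in the native complexes, so
# the native sequence scores at or near the top of the enumeration.
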