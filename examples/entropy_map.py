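"""Kingdom-diversity entropy map over a pocket-embedding projection.

Generates 128-d pocket embeddings under two regimes — one shared Gaussian
component for all kingdoms (no kingdom signal) and fully segregated
per-kingdom components — projects each to 2D, and computes the per-bin
Shannon entropy S = -sum p_i ln p_i of the kingdom distribution.  Bins with
fewer than 20 pockets are masked.  S near ln(4) ~ 1.386 means all four
kingdoms mix in a region; S = 0 means a region is kingdom-exclusive.
"""

import numpy as np

from pocketome.embedding import binned_entropy, project
from pocketome.synthetic import SyntheticConfig, generate_embeddings

KINGDOMS = ("Bacteria", "Fungi", "Plantae", "Animalia")

for name, sep in [("shared component (mixed kingdoms)", 0.0),
                  ("segregated components", 60.0)]:
    cfg = SyntheticConfig(
        seed=9, n_species=4, kingdom_mixture={k: (sep, 1.0) for k in KINGDOMS}
    )
    emb = generate_embeddings(cfg, 4000)
    proj = project(emb, method="pca", seed=0)
    grid = binned_entropy(proj, emb.labels["kingdom"].to_numpy(), 10, 10, min_count=20)
    unmasked = grid.entropy[~np.isnan(grid.entropy)]
    print(f"{name}:")
    print(f"  unmasked bins: {len(unmasked)} of {grid.counts.size} "
          f"(mask threshold {grid.min_count} pockets)")
    print(f"  mean entropy {unmasked.mean():.3f} nats "
          f"(max possible ln 4 = {np.log(4):.3f})\n")
print("Mixed kingdoms drive per-bin entropy toward ln(4); segregation toward 0.")
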