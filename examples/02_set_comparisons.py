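"""Compare a footprint against external gene collections with Venn partitions.

Emulates comparing an early consensus footprint with transcriptional
responses to several abiotic stresses: per-set shared counts and
percentages, genes common to all comparators, and genes found in none.
"""

import numpy as np

from txfootprint import NamedGeneSet, multi_overlap, venn_partition

rng = np.random.default_rng(8)
universe = [f"AT1G{i:05d}" for i in range(3000)]
footprint = NamedGeneSet.from_iterable("early_footprint", universe[:101])

# external stress-response sets overlapping the footprint to varying degrees
externals = []
for name, n_shared in [("heat", 83), ("salt", 90), ("high_light", 93), ("oxidative", 93)]:
    members = universe[:n_shared] + list(
        rng.choice(universe[200:], size=400, replace=False)
    )
    externals.append(NamedGeneSet.from_iterable(name, members))

summary = multi_overlap(footprint, externals)
for entry in summary["per_set"]:
    print(f"{entry['name']:>11}: {entry['shared']} shared "
          f"({entry['percent']}% of the footprint; raw {entry['fraction']:.4f})")
print("common to all four stresses:", summary["n_shared_with_all"])
print("in none of them:", summary["n_shared_with_none"])

vp = venn_partition([footprint, *externals[:3]])
only_fp = vp.region_sizes()["1000"]
print(f"Venn region unique to the footprint: {only_fp} genes")
# The percentages say how much of the consensus footprint is re-used by each
# general stress response; genes shared with all four point to a core
# stress-signaling program, genes in none are candidate organelle-specific markers.
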