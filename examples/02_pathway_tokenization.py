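"""Group the gene vocabulary into gene-set super tokens.

Pathway members form one token each; genes without pathway membership are
shuffled by seed and chunked into fixed-size random sets. At atlas scale
(27,985 genes of which 14,426 lack pathway membership, chunk size 110)
this yields 132 random sets alongside the pathway sets.
"""

from celltra import build_grouping, default_spec, generate_pathways, \
    tokens_per_profile
from celltra.io_formats import PathwayCollection

# desk scale: the default synthetic conditions
spec = default_spec(seed=0)
pathways = generate_pathways(spec)
vocab = [f"G{i:04d}" for i in range(spec.n_genes)]
grouping = build_grouping(vocab, pathways, orphan_set_size=110, seed=0)
print(f"desk scale: {grouping.n_pathway_groups} pathway tokens + "
      f"{grouping.n_random_groups} random tokens = "
      f"{tokens_per_profile(grouping)} tokens per cell (plus CLS)")

# atlas-scale arithmetic: 14,426 orphan genes at chunk size 110
atlas_orphans = [f"G{i:05d}" for i in range(14_426)]
atlas = build_grouping(atlas_orphans, PathwayCollection({}),
                       orphan_set_size=110, seed=0)
print(f"atlas scale: {len(atlas_orphans)} pathway-less genes -> "
      f"{atlas.n_random_groups} random gene sets of size 110 "
      f"(last set has {len(atlas.groups[-1])} genes)")
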