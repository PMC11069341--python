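# guildquant

Quantification of microbial guilds from metagenomic data.

A guild is a list of organisms that exploit or produce a key resource,
regardless of their lineage, their environment, or how they implement the
required function. Classical, behavior-based guild definitions do not
transfer to microbes, whose "feeding phenotype" reduces to a handful of
proteins observed only through sequencing. `guildquant` operationalizes the
guild concept for metagenomes: it classifies query sequences placed on an
annotated reference gene tree into functional *implementations* (sequence
spaces that carry out the function in an equivalent way), and quantifies
the contribution of every (taxon, implementation, environment) group of
equivalent sequences *s* through the impact coefficient

```
k_s = A_s · (d_obs,s / d_exp,s) · u_s
```

where `A_s` is the group's summed normalized abundance (TPM), `d_obs,s` its
observed richness (number of distinct unique sequences), `u_s ∈ [0, 1]` the
univocity of its cluster (binary here: functional 1, non-functional 0), and
`d_exp,s = c · A_s^γ` the richness expected from abundance alone under a
per-gene power law fitted by ordinary least squares on the log–log scale.
The richness ratio rewards groups that are more sequence-diverse than their
abundance predicts — diversity that buys functional stability — and the
univocity term annuls sequences that merely resemble the functional ones.

The package is aimed at microbial ecologists post-processing phylogenetic
placements (EPA-ng style jplace files) of functional-gene queries against
curated reference trees.

## What is included

| module | role |
| --- | --- |
| `guildquant.guild_model` | richness power law, impact coefficients, aggregation, fold changes |
| `guildquant.tree_annotation` | univocity propagation from leaf evidence; leaf-trait randomization enrichment of internal nodes (20 000 shuffles, \|z\| ≥ 3, one-tailed permutation P < 0.003); most-general node selection; implementation definition |
| `guildquant.divergence_null` | patristic distances; two-phylomarker (16S vs *rplB* style) bivariate regression null with a ±3σ band; flagging of gene-tree nodes whose divergence taxonomy cannot explain |
| `guildquant.placement_io` | jplace v3 reading/writing, best-hit cluster and consensus-taxonomy assignment, quality filtering, sequence-group construction |
| `guildquant.synthetic_data` | generators for every input with planted ground truth |
| `guildquant.cli` | `guildquant simulate / enrich / quantify / foldchange / divergence` |

## Worked example

Generate a synthetic scenario with planted ground truth and quantify it:

```bash
guildquant simulate --out-dir scn --n-leaves 48 --n-queries 120 --seed 5
guildquant quantify \
    --jplace scn/placements.jplace --abundance scn/abundance.tsv \
    --tree scn/tree.nwk --clusters scn/clusters.tsv \
    --taxonomy scn/taxonomy.tsv --out-dir out \
    --model-c 2.0 --model-gamma 0.5
# kept 120/120 queries (0.00% discarded); mean confidence of kept: 1.000
guildquant foldchange --impact out/impact.tsv --num context=meso --den context=epi
# 1.13945
```

`out/impact.tsv` holds one row per (taxon, implementation, context) group
with its abundance, observed and expected richness, univocity and `k`; the
`foldchange` line above is the ratio of summed mesopelagic to epipelagic
impact. Groups in *incertae* (undefined) tree regions keep an empty `k` —
they are unclassifiable rather than non-functional. The logged discard
percentage and mean confidence describe the placement-quality filter
(confidence = summed like-weight ratio of the winning cluster).

To discover implementations from leaf traits instead of passing
`clusters.tsv` directly:

```bash
guildquant enrich --tree scn/tree.nwk --traits scn/traits.tsv \
    --out-dir enr --n-rand 20000 --seed 1
# 7 significant (node, trait) results; 2 most-general
```

`enr/selected_clusters.tsv` lists the most-general significant nodes —
ready to use as the `--clusters` input of `quantify`.

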