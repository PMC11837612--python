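# genovmap

Dating gene-family origins on a species phylogeny, classifying how novel
families arose, and screening them for retention and copy-number expansion.

## The problem

When a clade (say, an insect order) evolves new biology, part of the genomic
substrate is *taxonomically restricted* gene families: orthogroups present in
the clade but absent from all outgroups. Given an OrthoFinder-style
orthogroup table and a rooted species tree, `genovmap`:

1. **dates each family's origin** by MRCA parsimony — the gain node of an
   orthogroup with presence set $S$ is the most recent node $v$ with
   $L(v) \supseteq S$, where $L(v)$ is the leaf set below $v$. A gain at $v$
   is equivalently a gain on the branch leading to $v$. Under gene loss this
   rule is biased in one direction only: the inferred node can drift toward
   the leaves within the true gain clade, never above it;
2. **classifies each clade-specific family's likely mode of origin** from
   filtered homology evidence (e-value ≤ 1e-5, identity strictly > 25 %, both
   coverages ≥ 60 %) and Pfam-style domain calls (e ≤ 1e-3):
   a passing hit in metazoa outside the clade, or a known domain →
   *duplication + divergence*; otherwise a passing non-metazoan hit →
   *HGT candidate*; otherwise → *de novo candidate*;
3. **screens families for retention and expansion**: retention fraction =
   share of focal species with ≥ 1 copy (default threshold 0.75); expansion
   outliers via Anderson–Darling (the pooled copy counts are right-skewed,
   not normal), a tie-corrected Kruskal–Wallis rank test over orthogroups,
   and one-vs-rest Dunn z tests with Benjamini–Hochberg adjustment, flagging
   families whose mean copy number exceeds the grand mean at adjusted
   p < α;
4. **checks integration-site conservation** by microsynteny: two flanking
   marker genes per side, compared across species through orthogroup
   membership, plus intron counts per family member (longest transcript);
5. **simulates all of the above** — gene birth–loss–duplication on a tree,
   class-conditional hit tables, conserved marker blocks under segment
   rearrangement — with emitted ground truth, so every stage is testable
   without downloading a single genome.

## Worked example

```python
from genovmap import SimConfig, assign_gains, simulate_families, simulate_hits
from genovmap.gain_mapping import mrca, orthogroups_at
from genovmap.origin_classify import classify_origin, filter_hits, summarize_modes
from genovmap.synthetic_data import default_tree

# a 115-leaf tree whose root splits a 99-species focal clade from 16 outgroups
tree, focal = default_tree(seed=42)
focal_node = mrca(tree, focal)

# 300 families born at random internal nodes; 10% per-branch copy loss
cfg = SimConfig(seed=42, tree=tree, n_orthogroups=300,
                loss_prob=0.10, dup_rate=0.05)
table, truth = simulate_families(cfg)

gains = assign_gains(tree, table, min_species=3)
exact = sum(gains.assignments[og] == truth.gain_node[og]
            for og in gains.assignments)
print(f"retained {len(gains.assignments)} families "
      f"(excluded {len(gains.excluded)} in <3 species); "
      f"gain node exact for {exact}/{len(gains.assignments)}")

met, non, taxmap, domains = simulate_hits(truth, cfg)
met, non = filter_hits(met), filter_hits(non)
calls = [classify_origin(og,
                         [g for sp in table.species for g in table.groups[og][sp]],
                         domains, met, non)
         for og in gains.assignments]
print(summarize_modes(calls, gains).sum().to_dict())

ogs = orthogroups_at(gains, focal_node, tree)
print(f"{len(ogs)} families date to the focal-clade stem ({focal_node})")
```

prints

```
retained 175 families (excluded 125 in <3 species); gain node exact for 157/175
{'duplication_divergence': 142, 'hgt': 2, 'de_novo_candidate': 31, 'total': 175}
4 families date to the focal-clade stem (N2)
```

Reading the numbers: 125 of the 300 simulated families survive in fewer than
three species and are excluded before dating, mirroring the standard
minimum-species filter. Of the 175 dated families, 157 map exactly to their
true gain node — the rest drifted *down* into the true gain clade because
loss pruned their presence sets (never up; that is the method's one-sided
bias). With noise-free evidence the origin labels reproduce the planted
proportions exactly, and four families happen to date to the branch leading
to the focal clade.

The same pipeline runs from the shell against files:

```sh
genovmap simulate --preset gains --seed 7 --out-dir sim/
genovmap gains --tree sim/tree.nwk --orthogroups sim/Orthogroups.tsv --out-dir out/
genovmap run --config run.cfg        # full pipeline from a key=value config
```

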