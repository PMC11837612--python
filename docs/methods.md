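# Methods

## Gain dating by MRCA parsimony

An orthogroup's presence set is the set of species with at least one member
gene. Its gain node is the most recent common ancestor of the presence set:
the deepest node whose descendant leaves contain every present species. This
is the parsimony assumption of phylostratigraphy — a single origin, no
convergent gains. Gains are reported on nodes; a gain "at node v" is the same
event as a gain "on the branch leading to v", and the documentation uses the
node convention throughout.

Properties the implementation guarantees (and the tests verify):

* **One-sided loss bias.** Gene loss removes species from the presence set,
  so the inferred node is always inside the subtree rooted at the true gain
  node — the method can date a family too *young*, never too *old*. With no
  loss the assignment is exact.
* **Monotonicity.** Adding species to a presence set never makes the MRCA
  more recent.
* **Partition.** Every retained orthogroup maps to exactly one node, so
  per-node gain counts sum to the retained total, and retained + excluded
  equals the input total.

Orthogroups present in fewer than `min_species = 3` species are excluded
before dating ("present in greater than two species"). The filter is
configurable; when relaxed to 1, single-species families map to leaves and
are species-specific by construction.

### Cross-annotation rescue

Clade-specific candidates can be artifacts of incomplete outgroup
annotation. `rescue_against_alternative_annotation` demotes a candidate if
any member has a hit against an alternative re-annotation of outgroup
genomes passing e-value ≤ 1e-5, identity **strictly above** 25 %, and both
coverages ≥ 60 %. The boundary operators follow the two distinct rules the
thresholds come from (see below); the chosen semantics are logged in output.

## Mode-of-origin classification

Evidence per orthogroup (counted over any member gene — the "any-member"
convention, since per-gene majorities are not better justified and the
per-family question is binary):

| evidence | interpretation |
|---|---|
| passing hit vs metazoa outside the focal clade | duplication + divergence |
| known protein domain (e ≤ 1e-3) | duplication + divergence |
| passing hit vs non-metazoa only | HGT candidate |
| nothing | de novo candidate |

Precedence is duplication > HGT > de novo: homologues in other animals are
positive evidence of vertical descent, so metazoan evidence vetoes an HGT
call even when non-metazoan hits exist. A domain alone (no sequence hit
anywhere) counts as duplication evidence by default; the
`domain_alone_is_duplication` flag turns that off, since domain gain inside
an otherwise novel protein cannot strictly exclude the other modes.

Two deliberately different boundary regimes, each matching the rule it
implements:

* `filter_hits` (partial-homology removal): identity **> 25**,
  coverages **≥ 60**, e-value **≤ 1e-5**.
* `link_orthogroups` (merging homologous orthogroups): identity **≥ 25**,
  coverages **≥ 60** — the linking rule is inclusive at the boundary.

Linking builds the connected component of the seed under the symmetric
"any passing member-vs-member hit" relation, so the result is independent of
which component member seeds the search. Passing hits with query coverage
below 45 % are annotated `partial` in the evidence output (a spurious-
homology caution) but obey the numeric thresholds; structural verification
is out of scope.

A `focal_clade` record inside either outside-clade evidence table raises
immediately — that is leakage of the clade's own sequences into the
"excluding the focal clade" searches, and silently counting it would
mislabel families.

## Copy-number screen

The copy matrix is orthogroup × focal-clade species, with explicit zeros for
absent species. Zeros are observations: the "mean number of gene copies per
orthogroup per species" is a statement about all cells, and the expected
grand mean near 1.16 only arises with zeros counted. A flag restricts the
screen to present cells if a presence-conditional analysis is wanted.

The cascade:

1. **Anderson–Darling** on the pooled cells. Count data are positive and
   right-skewed, so normality is expected to fail; the verdict justifies the
   rank-based tests that follow. The statistic comes from scipy; the p-value
   uses Stephens' case-3 approximation (mean and variance estimated), with
   p = 0 returned beyond the approximation's range, and a constant vector
   treated as an automatic rejection (degenerate, trivially non-normal).
   Fewer than 8 observations is an error. Pooled cells are the default
   target — per-orthogroup means would test a different, less interpretable
   quantity.
2. **Kruskal–Wallis** across orthogroups (groups = orthogroups,
   observations = per-species counts), tie-corrected, df = k − 1. H is
   invariant under strictly monotone transforms of the counts.
3. **Dunn post hoc**, gated by a significant Kruskal–Wallis by default. The
   primary scheme is **one-vs-rest**: each orthogroup's mean joint rank is
   contrasted with the pooled remainder,
   z = (R̄ᵢ − R̄ᵣₑₛₜ) / √(S² (1/nᵢ + 1/nᵣₑₛₜ)) with the standard tie-corrected
   rank variance S². One-vs-rest matches the question asked ("does this
   family deviate from the rest?") and scales linearly; all-pairs is
   available, reporting each family's most extreme pairwise contrast.
   P-values are Benjamini–Hochberg adjusted by default (Bonferroni and Holm
   selectable); flagging is one-sided — adjusted p < α **and** family mean
   above the grand mean — because the screen targets expansion. Two-sided
   flagging is a flag away.

Retention fraction = (#species with ≥ 1 copy) / (#focal species), retained
iff fraction ≥ threshold (inclusive: 75 of 99 species passes 0.75).

## Microsynteny and introns

A target's marker context is its `n_flank = 2` nearest genes each side by
start coordinate, strand-agnostic (strand is recorded but unused — the
conservation question is about gene content, not orientation). Contexts near
chromosome ends are truncated and flagged. Marker homology comes from
orthogroup membership — deterministic, unlike ad-hoc re-searching.

Cross-species comparison counts markers of one context whose homologue lies
within `window = 10` genes of the other context's target. The count is
computed in both directions and the reported shared count is the **minimum**
of the two, which makes the comparison exactly symmetric and bounded by the
smaller flank size; identical neighbourhoods give 4/4, disjoint ones 0. A
neighbourhood is called conserved at `min_shared = 2` of the 4 markers — a
convention (the visual-inspection criterion it replaces has no stated
cutoff), surfaced in the output.

Gene-level intron count is exon count − 1 of the **longest transcript**
(transcript choice is otherwise ambiguous; the convention is flagged in
output). Subfamily summaries report the median.

## The simulator

`simulate_families` implements the generative process the MRCA rule assumes,
plus the two violations worth testing (loss, duplication): one ancestral
copy at the gain node; along each descendant branch every extant copy is
lost with probability q and, surviving, spawns Poisson(λ) duplicates.
Default study shape: 115 leaves = 99-species focal clade + 16 outgroups,
gain nodes uniform over internal nodes, q = 0.05, λ = 0.05. Planted origin
modes default to proportions 0.815 / 0.010 / 0.175
(duplication / HGT / de novo) — the duplication-dominated regime deep
insect nodes show. The null copy-number law is 1 + Poisson(0.1645) per
present cell, putting the grand mean near 1.16 with strong right skew.

`simulate_hits` emits class-conditional evidence: passing metazoan hits
(identity U(30, 80), coverages U(62, 98), e-value 10^U(−50, −6)) and domains
with probability 0.5 for duplication families; passing non-metazoan hits
only for HGT families; nothing for de novo families. The `hit_noise` knob
injects boundary-straddling records (identity U(20, 30), coverage U(55, 65),
e-value 10^U(−6, −4)) that the standard filter must remove.

`simulate_gene_orders` gives every species one ancestral chromosome of gene
slots (41 by default); rearrangement events swap two short segments, with
the event count Poisson(rate × genes) drawn by inverse transform from a
rate-independent uniform stream, so runs at different rates with the same
seed are coupled (higher rate ⇒ the same swaps plus more). This makes the
decay of shared markers with rate monotone in expectation and cheaply
testable.

All generators take a mandatory integer seed; equal seeds give byte-identical
emitted files.

**What the simulator does not emulate:** orthology-inference error (families
are clusters by construction; real orthogroups mix under- and over-
clustering), annotation incompleteness beyond the rescue toggle, sequence
evolution (no alignments, no FASTA), correlated loss across branches, and
inter-chromosomal rearrangement. Passing recovery tests therefore show the
*inference logic* is correct under the stated model, not that real
orthogroup tables satisfy that model.

## Problem sizes and numerical choices

The verification suite uses: 200 random trees × 100 presence sets for MRCA
oracle equivalence; 500 families on the 115-leaf tree for gain recovery
(q ∈ {0, 0.1}); 300 families for label round-trips; 1,000 random records for
boundary agreement; 1,000 null replicates (50 × 99) for Kruskal–Wallis
calibration; 200 replicates for Dunn power (49 baseline + 1 tripled-mean
family); rates {0, 0.05, 0.1, 0.2} × 198 pairs for synteny decay. These
sizes give Monte-Carlo standard errors comfortably below the tolerances
asserted while keeping a full run in seconds.

Other conventions: coordinates are 1-based inclusive and coverage =
(end − start + 1)/length × 100; TSV/UTF-8 only; internal tree nodes without
newick labels get deterministic preorder names N1…Nk so gain maps are
reproducible; subject taxonomy comes from an explicit subject → class map
(never live lookups); headerless 12-column hit tables are rejected because
they carry no length columns to compute coverage from (use the 14-column
qlen/slen extension or a header with qcovs/scovs).

## Known limitations

* MRCA dating cannot see convergent gains or gains-then-total-loss; both are
  folded into younger or absent calls.
* HGT calling from taxon-partitioned presence is a screen, not a proof —
  donor identification needs gene trees, which are out of scope.
* The Dunn one-vs-rest contrast treats families as exchangeable; phylogenetic
  non-independence of species is not modelled (no PGLS-style correction).
* The Anderson–Darling p approximation is for the estimated-parameters case
  only; it is used for a verdict at conventional α, not for precise tail
  probabilities.
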