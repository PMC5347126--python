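# Methods

This note documents the models, parameter choices and numerical decisions
behind `mitolineage`, and what the synthetic-data tests do and do not show
about real data.

## Coordinate frame and reference

All positions are 1-based nucleotide positions (np) on the 16,569-bp
circular human mitochondrial reference frame. The packaged reference
sequence is a **synthetic stand-in** for the rCRS (`synthetic_reference.py`):
a deterministic pseudo-random sequence of the correct length with reference
alleles pinned at every position used by the packaged haplogroup tree, and
with the control-region C-tracts (303–315, 16183–16194) and np 16519 laid
out as on the real molecule. Every algorithm in the package — alignment,
nomenclature, motif algebra, parsimony, rho — depends only on the
coordinate frame and the pinned alleles, so swapping in the real rCRS
changes no logic. The stand-in exists because redistributing the real
sequence was not an option; it must not be mistaken for it.

## Variant calling

Samples are aligned to the reference with an exact unit-cost global
aligner (edlib) whose `k` cap plays the role of an alignment band (default
200); mitogenomes are within a few dozen edits of the reference, so the
optimum is far inside the band, and exceeding it raises an explicit error
suggesting a wider band. Calls at `N` bases are suppressed; calls at masked
positions are suppressed and the mask recorded in the profile
(`excluded_sites`) so downstream stages can distinguish "absent" from
"unobserved". Indels are normalised to their 3'-most equivalent placement,
matching mtDNA nomenclature convention; insertions are reported per
inserted base (`315.1C`, `315.2C`), deletions per deleted position
(`249d`). A leading insertion on the circular molecule is anchored after
np 16569. An optional rotation pre-step (`rotate_to_reference`, off by
default) re-phases circularly permuted inputs.

Masking policy and indel placement are configuration, not hard-wired: the
default mask follows common whole-mitogenome phylogenetic practice.

## Haplogroup tree and motifs

The packaged `australia_2017` table encodes the Aboriginal Australian
clades and their spine to M/N/R. Literature-anchored diagnostics (the M42
definer A9156G; M42a's G12771A and G8251A; M42c's C64T + T195C and the
absence of G8251A, expressed through a back mutation on the M42a1 branch;
P11's C11288T; S one step from N; the nine-mutation M15 motif; C16193T
shared by M15 and M16) are encoded exactly. All other clade motifs are
**synthetic stand-ins**, flagged as such in the file header: the real ones
live in supplementary material not packaged here. Stand-ins give every
named clade a distinct, classifiable motif so topology, classification and
simulation can be exercised end-to-end; they are never to be quoted as real
diagnostics. This was preferred over empty placeholder motifs because an
empty-motif child ties its parent's score exactly and the depth tie-break
would absorb classifications into unsupported leaves.

The cumulative expected motif of a node is the union of branch variants on
the root-to-node path with back mutations (`X!`) cancelling their forward
occurrence — so "defined by the absence of" is representable and M42a1
genuinely lacks 8251A.

## Classification score

The weighted Kulczynski measure (see README) is the scheme used by modern
haplogroup callers. Numerical details: a candidate with zero-weight
expected motif scores term 1 as 1 (vacuously satisfied); an empty
informative profile scores term 2 as 1, so the empty profile maps to the
root with score 1. Ties are broken toward greater depth, then
lexicographically, and reported explicitly in the result (`tied`). Scores
are rounded to 12 decimals before comparison to keep float noise out of
the ordering. Default reliability weights: masked sites 0, np 8251 0.2
(major hotspot), np 9156 0.8 (mildly recurrent), all else 1. Private
mutations at positions unknown to the tree never penalise a candidate —
they are candidate novel sub-lineages, not errors.

## Maximum-parsimony trees

Characters are derived mutations relative to the clade root haplotype:
gains of non-root variants and losses of root-motif variants (losses at a
sample's masked positions are not scored — absence of evidence). Pairwise
compatibility is the rooted two-character test (carrier sets nested or
disjoint). Compatible instances yield the unique perfect phylogeny by
carrier-set inclusion ordering.

Conflicts are resolved by making some character arise more than once. The
resolver works on "blocks" (mutation events with carrier sets) and two
moves per conflicting pair: *split* (duplicate the character across the
intersection/difference) and *merge-up* (gain the character once on the
union and revert it in the overhang — a back mutation). Small instances
(≤ 16 blocks) are searched exactly by branch-and-bound over these moves,
minimising total site-weighted events, with ties resolved deterministically
(victims ordered by weight, position, key); larger instances use a greedy
rule that splits the lowest-weight, highest-conflict character first.
Duplicating cheap (mutable) sites first is the identical-by-state argument
again, now as a tree-building preference.

The builder is not a full Steiner-tree search: under extreme recurrent
mutation density (characters hit about twice per branch across a tiny site
pool) the bounded move set can exceed the true minimum by a small amount.
At mutation densities representative of mitogenome clades (at most a
handful of recurrences among thousands of sites) it matched exhaustive
Fitch-over-all-topologies search on thousands of random instances. Zero
site weights are floored at 10⁻³ inside the resolver so masked characters
cannot be duplicated for free.

## Rho and clocks

ρ is computed in both the path-sum and edge-sum forms and the two are
asserted equal at run time; σ is the edge-weighted (Saillard-type)
estimator. 95% intervals use ±1.96σ (configurable z), floored at zero.
Clocks come in two modes — `years_per_substitution` and
`per_site_per_year` (converted via the genome length, default 16,569) —
and optional rate bounds; when bounds are present the interval is also
propagated across them and the wider envelope reported. The packaged
calibrations are 3,624 years/substitution (whole-genome evolutionary rate)
and 2.67 × 10⁻⁸ /site/year (2.16–3.16 × 10⁻⁸, ancient-DNA-calibrated),
i.e. ≈ 2,260 years/substitution. The purifying-selection correction is a
pluggable transform applied to the year values, identity by default: no
correction curve is bundled, deliberately.

Clade estimates are computed per assigned haplogroup, where a clade's
members are the samples assigned to it or any descendant; an empty clade
yields an empty result, not an error.

## Synthetic cohorts

The simulator emulates the mutational process the rho clock assumes:
branches of a known-depth genealogy (star, or pure-birth/Yule rescaled to
a fixed root age) accumulate Poisson(μ·t) substitutions, with μ the
whole-genome rate of the configured clock (default 1/3,624 per year).
Sites are drawn proportionally to a mutability table (hotspot 8251 weight
5, np 9156 1.25, masked sites 0, otherwise 1 — the inverse view of the
classification reliability weights); transitions are chosen with
probability R/(R+1) with ts/tv ratio R = 20, typical for human mtDNA. A
repeat hit at a site that already left its inherited background toggles it
back, generating back mutations and identical-by-state sharing like the
8251 story. `avoid_homoplasy=True` draws each site at most once genome-wide
and avoids tree-diagnostic positions, giving perfectly recoverable truth
for closure tests.

The default study cohort is 127 genomes with state counts 103 (Queensland),
14 (New South Wales), 6 (Victoria), 2 (Tasmania), 2 (Western Australia),
founders drawn uniformly from the packaged Australian clades (per-clade
founder frequencies of the real cohort are not published in the main
material; uniform is the documented neutral choice), each founder clade a
star of depth 40,000 years by default. Everything is deterministic given
the seed.

What the simulator does *not* emulate: rate heterogeneity beyond the
listed hotspots, indel mutation, heteroplasmy, sequencing error, selection
and population-size dynamics. Passing closure tests therefore demonstrates
algorithmic correctness of the pipeline, not robustness to real-world
artefacts.

## Test and problem sizes

The statistical suites use sizes chosen to make sampling noise small
relative to the tested tolerances while keeping the suite quick: estimator
calibration uses 200 replicate star cohorts of n = 50 at T = 50,000 years
(mean within 2%, interval coverage ≥ 90%); parsimony optimality uses 100
random instances of ≤ 6 tips and a 12-site pool at about one mutation per
branch (already far denser recurrence than real mitogenome data); the rho
identities are checked on 1,000 random trees. Hypothesis-based property
tests run derandomised.

## Known limitations

* The haplogroup tree is a scoped encoding, not a full PhyloTree mirror;
  placeholder motifs are synthetic (flagged in the data file).
* The MP builder is heuristic beyond small instances (bounded exact
  search, then greedy); no reticulate/network output.
* rho-based dating inherits the estimator's known sensitivity to
  non-star topologies and sampling; the per-clock intervals do not model
  calibration uncertainty beyond the supplied rate bounds.
* No Bayesian dating, substitution-model selection, or raw-read
  processing.
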