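# mitolineage

Analysis of human mitochondrial DNA lineages: rCRS-relative variant
calling, haplogroup classification, maximum-parsimony haplotype trees, and
rho-statistic TMRCA estimation under calibrated molecular clocks — with a
synthetic-cohort simulator that provides ground truth for every stage.

The package is aimed at population geneticists working with whole
mitogenomes, in particular the Aboriginal Australian haplogroup landscape
(M42a/M42c, S, N13, O, and the P subclades including the P11 lineage that
unites the former P4b with the Tasmanian P branch). It ships a curated
haplogroup definition tree (`australia_2017`) covering those clades and
their spine to the macrohaplogroup roots M, N and R.

## The model

**Variants.** Every sample is reduced to its differences from the 16,569-bp
revised Cambridge Reference Sequence, written in standard nomenclature
(`A9156G`, `315.1C`, `249d`, with a trailing `!` marking back mutations in
haplogroup definitions). Indels are placed at their 3'-most equivalent
position; the control-region C-tracts (np 303–315, 16183–16194) and np
16519 are masked by default.

**Classification.** A haplogroup *h* with cumulative expected motif *E(h)*
is scored against the observed profile *O* by a weighted Kulczynski
measure,

    K(h) = ½ · ( W(E∩O) / W(E) + W(E∩O) / W(O*) ),

where *O\** is the phylogenetically informative part of *O* (variants at
positions used anywhere in the tree) and *W* sums per-site weights.
Recurrent hotspots are down-weighted (np 8251 → 0.2, np 9156 → 0.8), which
encodes identical-by-state vs identical-by-descent caution; private
mutations never penalise a candidate.

**Parsimony trees.** Within a clade, samples' derived mutations are treated
as binary characters. Pairwise-compatible characters (carrier sets nested
or disjoint) yield the unique perfect phylogeny; conflicts are resolved by
letting the character at the most mutable site arise more than once (or be
gained on a superset and reverted), searched exactly on small instances.

**TMRCA.** The rho statistic is the mean mutation count from the clade root
to its *n* tips, with the edge-weighted standard error

    ρ = (1/n) Σ_tips d(root, tip),   σ = sqrt( Σ_edges (n_e/n)² · ℓ_e ).

Two packaged clocks convert ρ to years: the whole-mitogenome 'evolutionary'
rate (one substitution per 3,624 years) and an ancient-DNA-calibrated rate
(2.67 × 10⁻⁸ substitutions/site/year, 95% HPD 2.16–3.16 × 10⁻⁸). A
purifying-selection correction hook is exposed (identity by default).

**Reference note.** The packaged reference is a clearly labelled *synthetic*
stand-in for the rCRS: identical length, circularity and coordinate frame,
with reference alleles pinned at every position the packaged tree uses. All
algorithms operate on the coordinate frame only.

## Worked example

`examples/02_haplogroup_classification.py` classifies three hand-built
profiles:

```
M42 definer only         -> M42   score 1.000 (runner-up M at 0.895)
full M42c motif          -> M42c  score 1.000 (runner-up M42c1 at 0.926)
M42 + 8251 hotspot       -> M42   score 0.975 (runner-up M42a at 0.900)
```

A profile carrying only the near-stable M42 definer A9156G stays at M42;
adding C64T and T195C moves it to M42c; adding only the 8251 hotspot does
*not* promote it to M42a, because that position's 26 independent
occurrences in PhyloTree make sharing it weak evidence of common descent.

`examples/03_parsimony_and_rho.py` builds the three-sample haplogroup-P
clade in which two samples share C11288T:

```
newick: ((mainland:1,tasmanian:1)h0:1,p4like:2)root;
rho = 2.000, sigma = 0.943, n = 3
soares_whole_mtdna   TMRCA   7.2 KY (95% CI 0.6-13.9)
fu_ancient_dna       TMRCA   4.5 KY (95% CI 0.3-10.8)
```

The mainland and Tasmanian profiles are joined *through* the shared
mutation (edge of length 1 into their common node), every tip sits two
mutations from the root (ρ = 2), and each clock converts that mean into a
clade age with a 95% interval — the faster ancient-DNA-calibrated clock
dating the same ρ younger.

The other examples cover variant calling (`01`) and a full 127-genome
simulated cohort run through the pipeline (`04`). A thin CLI mirrors the
stages: `mitolineage simulate | call | classify | tree | tmrca | all`.

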