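# Methods

This note records the statistical models, conventions and design
choices behind the package, in the spirit of a methods appendix.

## Data model and missing-data semantics

A locus is an aligned set of haplotype rows over `{A,C,G,T,N,?,-}`.
`N` marks unmapped positions and `?` low-quality positions; the two are
preserved distinctly on round-trip because they record different
provenance, but every statistic treats them identically (excluded, like
gaps). All internal coordinates are 0-based half-open; VCF and
annotation files (1-based inclusive) are converted at the boundary.
Heterozygous VCF calls collapse to `N`: the analysis assumes one
haplotype per accession, appropriate for predominantly selfing material;
ambiguity codes would contaminate pairwise difference counts.

## Site classification

Synonymous/non-synonymous site counts follow Nei & Gojobori (1986): for
each reference codon, all nine single-base changes are enumerated
against the standard genetic code and each codon position contributes
the fraction of its three changes that are synonymous. Changes creating
a stop count as non-synonymous; reference stop codons are skipped with a
warning; gap-containing reference codons are skipped (frame ambiguity).
Counts are computed on a single designated reference row — deterministic
and standard for candidate-gene panels — chosen as the first accession
whose CDS is free of gaps and missing data (a frameshift carrier cannot
anchor a reading frame); the row is configurable. Whether site counts
should instead be averaged over all sequences is a genuinely open
convention; single-reference counting was chosen for determinism and is
disclosed here.

An observed polymorphic column is labelled synonymous-eligible if every
non-reference base observed there is a synonymous change against the
reference codon, non-synonymous-eligible if every one is
non-synonymous, and mixed otherwise; mixed columns count only toward
"all" sites. Silent sites are synonymous coding positions plus
noncoding (UTR/intron) positions.

## Diversity statistics

π is the mean over unordered pairs of (differences at class columns) /
(fractional class sites comparable for that pair) — per-pair
normalisation under pairwise deletion. S (and θ̂_w = S/(a₁·L_eff)) uses
complete deletion: a column enters only if every member carries an
unambiguous base, and multi-allelic columns count once (infinite-sites
convention). The default therefore mixes pairwise-deleted π with
complete-deleted S, the combination simple per-locus scripts most often
use; a `policy="complete"` switch makes π complete-deleted too. Inside
Tajima's D both Π (the total mean pairwise difference count) and S are
computed under complete deletion so that the 1989 variance formula,
which assumes a single set of n sequences observed at every site,
remains coherent. D is reported NA when S = 0 or n < 3; note that at
n = 3 the variance constants vanish identically, so D is NA there too.

Flags follow the usual single-gene screening conventions:
`low_diversity` when π or θ̂_w < 0.0005, `extreme_D` when |D| > 2.

Genome-wide values are unweighted means of per-locus statistics
(default), with a `concatenated` switch that pools S, L_eff and Π
instead; which aggregation a given published table used is rarely
stated, so both are available.

## Differentiation

Default estimator: Hudson (1992) F_ST = 1 − π_w/π_b on haplotype
sequences, with π_w the mean of the two within-group π values and π_b
the mean per-site difference over all cross-group pairs; π_b = 0 yields
F_ST = 0. A haploid Weir–Cockerham variance-components estimator
(ratio-of-sums over sites, summed over alleles) is available behind a
switch for cross-checking, since sequence-based studies often cite the
F_ST concept without pinning the estimator. Negative raw values are
clamped to zero for reporting (raw values are retained). Genome-wide
F_ST for a pair is the unweighted mean of per-locus clamped values; a
locus is an outlier when its value strictly exceeds mean + 2·SD across
loci (with SD = 0, strictly greater than the mean). F_ST defaults to
all sites; the seven analysis pairs (three weed–ancestor, one
cultivar–cultivar, three weed–weed) are configurable.

## Trees

K2P distance d = −½ln(1−2P−Q) − ¼ln(1−2Q) over pairwise-deleted sites.
Saturated entries (log argument ≤ 0) are by default replaced by 1.05 ×
the largest defined distance with a warning — bootstrap replicates
occasionally saturate, and silently dropping them would bias support —
or can be made a hard error. Neighbor joining follows Saitou–Nei with
two determinism conventions: Q-matrix ties break at the lowest
(row, column) index, and negative branch-length estimates are set to
zero with the deficit moved to the sibling branch (other NJ
implementations differ here, so bit-level tree comparison across tools
is not expected). Identical sequences are not collapsed into haplotype
classes before tree building: one tip per accession. Bootstrap
resamples columns with replacement; support is the integer percentage
of replicates containing the same bipartition, deterministic under a
fixed seed. Outgroup rooting bisects the edge separating the outgroup
clade; non-monophyletic outgroups root at the edge maximising the
outgroup count (then minimising the ingroup count) on the outgroup
side, with a warning.

## Allele classification and origin inference

Diagnostic polymorphisms live in editable YAML rule files rather than
code, because primary literature typically gives exon-level but not
base-level positions; the packaged coordinates refer to the synthetic
reference. An indel diagnostic reads `del` when its interval is all
gaps, `ref` when all bases, and missing otherwise; any missing
diagnostic downgrades the call's confidence to partial-missing.
Single-diagnostic genes use an ordered pattern → class map with the
wild type as fallback. Multi-SNP haplotype classes (the seed-dormancy
locus' n/k/k′ alleles) use majority-consistent profile matching: a
profile is consistent when every observed diagnostic matches and a
strict majority of its diagnostics were observable; among consistent
profiles the one matching most diagnostics wins (k′ over k), and ties
or recombinant patterns return "unclassified".

Origin inference operationalises "identical or very closely related to
ancestral haplotypes" as nearest-neighbour K2P distance: for each weed
accession, the minimum distance to each non-weed group is ranked;
standing ancestral variation when the weed group's designated ancestor
(aus-like→aus, indica-like→indica, wild-like→wild) uniquely attains the
minimum within a 1e-9 tie tolerance, possible introgression when a
non-ancestral group is strictly nearest, ambiguous on ties. An optional
distance threshold can tighten "closely related"; the default is strict
nearest-neighbour.

CAPS simulation amplifies the primer-to-primer span (reverse primer
matched as its reverse complement; zero or multiple hits are an assay
failure, not an exception), cuts at every recognition-site occurrence
at the enzyme's offset (IUPAC-degenerate sites expanded, e.g. BanI
GGYRCC), and matches sorted fragment lengths against per-class expected
patterns. Fragment lengths always sum to the amplicon length.

## Trait association

Categorical summaries report counts and percent of non-missing;
quantitative summaries mean and sample SD (missing for n = 1).
Genotype→phenotype expectation maps are configuration (Rc→red,
rc/Rc-s→white; Bh4 wild type→black, loss-of-function→straw; sh4-G→
{strong, medium}, sh4-T→{low, non}); map values may be sets because a
two-allele genotype legitimately spans several ordinal shattering
classes. Breaking-tensile-strength class cut-offs (strong < 10 g ≤
medium < 25 g ≤ low < 45 g ≤ non) are package assumptions, configurable,
since published class labels rarely come with printed thresholds.
Kruskal–Wallis uses mid-ranks with the tie-correction factor
1 − Σ(t³−t)/(N³−N) and a χ² upper-tail p (df = k−1); the suite checks
it against an exact permutation null at small n and against an
independent implementation. Post hocs are pairwise two-sided
Mann–Whitney tests with Holm correction, summarised as a compact letter
display.

## Synthetic panels

The generator is a directly implemented Kingman coalescent (exponential
waiting times, uniform pair merges), not a wrapper around an external
simulator, so that it is itself tested code and a truth-table producer.
Time is in units of 2N generations: a pair coalesces at rate 1 and a
branch of length t carries Poisson(θ_total/2 · t) mutations, each
assigned a distinct uniformly chosen column (infinite sites on a finite
grid), giving the classical E[S] = θ_total·a_{n−1} and E[π] = θ per
site used as oracles.

The default panel mirrors a 101-accession South Asian study design:
15/5/5/10 aus-like/indica-like/wild-like/admixed weeds, 15/13/11/5
aus/indica/japonica/admixed cultivars, 18 wild, 4 outgroup accessions;
128 loci of 900 bp with a three-exon 450-bp CDS. Groups are simulated
in divergence clusters on a joint genealogy: each cluster has a base
deme (aus, indica, japonica, wild, outgroup) and derived demes that
merge into it at configured split times (aus-like 0.15, indica-like
0.006, wild-like 0.25, admixed weeds 0.10, admixed cultivars 0.05, in
2N units). Deme sizes are θ_group/θ_scale (θ_scale = 0.009/site), so
within-group diversities land near the configured targets
(0.003–0.009/site, the range typical of rice candidate-gene panels) and
weed–ancestor F_ST is controlled by split time (deep splits between
independent genealogies would otherwise force F_ST toward 0.5).
Clusters are separated by fixed Poisson(divergence·L) mutations; the
outgroup's 0.03/site offset keeps it clearly external for rooting. A
separate two-deme simulator (clean split or island model with scaled
migration M = 4Nm) supports calibration: for the symmetric two-deme
island model the expected coalescence times are T_w = 2 and
T_b = 2 + 1/M, giving Hudson E[F_ST] = 1/(1+2M) — a ratio of expected
diversities, which is why the calibration pools diversities across loci
before forming the ratio (a per-locus mean of ratios is Jensen-biased
downward).

Planted functional alleles assign per-group carrier counts as
round-half-up(frequency × n), sampled without replacement; carriers of
an allele receive all its components (gap runs and/or substitutions) on
columns protected from background mutation, and exact truth tables are
emitted. Default carrier frequencies echo the qualitative pattern of
real panels (loss-of-function Rc/Bh4 alleles common in cultivars, the
sh4 domestication allele near-fixed in cultivars and crop-derived weeds
but absent from wild-like weeds, dormancy-class Sdr4 haplotypes
enriched in weeds). CAPS primer sites and one recognition site per
assayed gene are written into the synthetic reference (mutation-free)
so the in-silico assay runs end to end. Phenotypes equal the
genotype-expected level with probability 1 − ε and flip to a uniformly
chosen other level otherwise; the default ε = 0.06 approximates the
genotype/pericarp discrepancy rate reported for real panels (6 of 95
accessions). The exon sequence of the ancestral haplotype is rewritten
to an open reading frame so translation-based analyses are meaningful.

What the generator does not emulate: recombination within loci,
selection, sequencing error beyond the N/? masks, indel polymorphism
other than the planted diagnostics, and real linkage between loci.
Passing tests therefore demonstrate correctness of the estimators and
the pipeline's bookkeeping under a neutral, recombination-free model —
not robustness to every feature of real resequencing data.

## Problem sizes

The test suite and acceptance script run at desk scale by choice:
neutral calibrations use 500–600 loci of 300 bp at n = 10; the full
synthetic pipeline runs on 64 loci × 101 accessions with 200 bootstrap
replicates; published-style full runs (128 loci, 1000 replicates) use
the same code paths and remain the CLI defaults.

## Known limitations

* Tajima's D under the default mixed missing-data policy uses
  complete-deletion Π internally, which can differ from the reported
  pairwise-deleted π when missingness is heavy.
* The Weir–Cockerham variant is a haploid adaptation and not expected
  to match diploid genotype-based implementations exactly.
* PHYLIP-style NJ programs resolve Q-ties and negative branches
  differently; topologies agree on clean data but branch-level output
  is not bit-comparable.
* The nearest-neighbour origin rule is sensitive to donor-group
  sampling: an ancestral haplotype also segregating in another group
  (common for admixed cultivars) is reported ambiguous, by design.
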