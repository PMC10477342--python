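# Methods

## Scope and model

`wgdkit` implements the inference chain used to detect and date ancient
whole-genome duplications (WGDs) from gene collinearity, together with two
companion clocks: the LTR retrotransposon insertion clock and a
metabolomic pathway differential-abundance (DA) score.  The chain is:

1. homolog pairs by pairwise protein alignment;
2. collinear blocks by monotone chaining of anchors in gene-rank space;
3. Ks (synonymous substitutions per synonymous site) per anchor by NG86,
   one **median Ks per block**;
4. Gaussian-mixture fitting of the block-median Ks distribution with BIC
   model selection — the number of components is the evidence for the
   number of WGD events;
5. synteny-depth ratios against an unduplicated outgroup (a 1:4 modal
   ratio indicates two rounds of doubling);
6. a gene-tree test distinguishing WGDs shared by two species from
   independent events in each lineage;
7. clock conversion T = Ks/(2·r) after an outgroup-anchored relative-rate
   correction.

All of it runs on a built-in forward-time simulator with a complete truth
log, so every estimator in the chain is validated against known answers.

## Simulator

An ancestral genome (default 4 chromosomes × 250 genes, 150 codons per
CDS, random sense codons behind an ATG) evolves along a lineage tree
carrying WGD and speciation events at stated ages (My).  A WGD duplicates
every chromosome; duplicated chromosomes are appended as new chromosomes
and each duplicate gene is deleted independently with probability
1 − retention, ranks closing up (fractionation with clean collinearity —
no rearrangements, by design).  The truth log records each gene's
ancestral gene and, for every pair of genes sharing an ancestor, the
divergence event and the closed-form expectation Ks = 2·r·t.

Sequence divergence is codon-aware.  Along a branch of t years a gene
receives n_s ~ Poisson(r·t·S) synonymous and n_n ~ Poisson(ω·r·t·N)
nonsynonymous substitutions, where S and N are Nei–Gojobori site counts
of the branch-start sequence; each substitution is placed by rejection
sampling of single-nucleotide changes of the required class, and changes
creating stop codons are never accepted.  This keeps ORFs intact and
makes E[synonymous divergence per synonymous site] exactly r·t per
branch, which is the property the downstream estimators are graded
against.  ω defaults to 0.2, a typical purifying-selection dN/dS for
plant paralogs; the synonymous rate defaults to 4.2 × 10⁻⁹ /site/yr so
that WGDs at 57.1 and 41.7 My have truth Ks 0.48 and 0.35 — ages inside
the intervals inferred for the Polygonaceae double-WGD history, Ks inside
the 0.3–0.5 window where the two peaks are expected.

The My → year conversion (10⁶) is applied in one constant
(`simulate.YEARS_PER_MY`).

Known distortions the simulator does **not** emulate: genomic
rearrangement (inversions, translocations), tandem arrays, codon-usage
bias, rate heterogeneity among genes and sites, gene conversion between
paralogs.  Passing tests therefore demonstrate correctness of the
inference chain under clean collinearity and homogeneous rates, not
robustness to those complications in real assemblies.

LTR cohorts: each element's two LTRs start as identical copies and
accumulate Poisson(r·t·L) substitutions independently (uniform sites,
uniform alternative base), so expected pairwise divergence is 2·r·t.

Metabolomes: log2 abundance levels per metabolite with Gaussian replicate
noise (default sd 0.3 log2 units, 3 replicates per group, mirroring a
typical targeted design); 'up'/'down' metabolites receive ±effect
(default 3 log2 units) in the second group; tables are emitted on the
linear scale.

## Homology

Smith–Waterman local alignment with BLOSUM62 and BLAST-convention affine
gaps (a gap of length k costs open + k·extend; defaults 11/1), via
Biopython's `PairwiseAligner`.  Identity is matches over alignment
columns; coverage is the smaller of the two aligned-span fractions.
Pairs pass at identity ≥ 0.4 and coverage ≥ 0.4 (the common gene-family
screen); each gene keeps at most its `top_n = 5` best partners, a pair
surviving only if ranked for *both* genes, which makes the output
symmetric.  A shared 5-mer prefilter keeps all-vs-all desk-scale; tests
assert it loses no pairs relative to exhaustive alignment on small runs.
E-values are deliberately not modelled (no database-size statistics);
the identity/coverage thresholds are the operative filter.

## Collinear blocks

Anchors live in 0-based gene-rank space per chromosome (dot-plot
practice; base-pair coordinates exist only in the GFF3 export).  Within
each chromosome pair the best chain strictly monotone in both genomes
(increasing/increasing = '+', increasing/decreasing = '−') is found by
dynamic programming with score `match_score·n − gap_penalty·Σ(skipped
ranks)` and a per-step rank gap cap; blocks are extracted greedily by
descending chain score, each anchor joining at most one block so that
depth counts are well defined.  Defaults: `min_anchors = 5`,
`max_gap = 25`, `match_score = 1`, `gap_penalty = 0.05` — WGDI/MCScanX-
like conventions, all configurable.  Tandem duplicates (same partner,
adjacent rank) are collapsed before chaining.  The DP is validated
against exhaustive enumeration of all monotone chains on anchor sets of
≤ 10.

Synteny depth of a gene is the number of distinct blocks whose span on
that gene's side covers its rank.  The reduced modal-depth ratio A:B
takes A's multiplicity from the modal coverage of **B's** genes and vice
versa: an unduplicated outgroup each of whose genes is covered by four
regions of a twice-duplicated genome reads 1:4.

## Ks estimation and peak fitting

Codon alignments are protein-guided (global BLOSUM62 alignment of the
translations, gaps back-translated to codon triplets); columns with gaps
are excluded.  NG86 counting: per-position synonymous fractions (changes
to stops count as nonsynonymous so sites per codon sum to 3), site counts
averaged over the two sequences, multi-difference codons averaged over
all substitution orderings excluding pathways through stops (all
orderings if every one is blocked), Jukes–Cantor correction
Ks = −¾·ln(1 − 4/3·pS).  pS or pN ≥ 3/4 marks the pair saturated/invalid.
The implementation is checked against an independent pathway-enumeration
oracle over all sense-codon pairs.

Under the simulator's heterogeneous codon degeneracy the NG86/JC chain
carries the estimator's classical small upward bias at ω = 0 (two-fold
degenerate positions collapse less than JC assumes); at the default
ω = 0.2 and 150-codon genes the cohort mean recovers truth Ks 0.40
within ±0.01 and the median per-pair relative error at 300 codons is
well under 10%.

One Ks value per block — the median over its valid anchors — enters the
mixture fit; blocks with no valid anchor are dropped with a recorded
reason.  Gaussian mixtures are fitted by EM (scikit-learn) for
k = 1..5 on values in (0.02, 2.0] (excluding allelic/tandem noise below
and saturation above), 10 seeded restarts per k, BIC selection with ties
toward smaller k; deterministic given the seed.

Rate correction: the exact formulation of the published
relative-rate method is not reproducible from its description, so the
package uses the transparent outgroup-anchored scaling
c_i = mean(ortholog peak)/ortholog peak_i, corrected paralog peak =
raw·c_i — two lineages that saw the same event through a 2× rate ratio
are brought to a common corrected peak.  Dating: age (My) =
Ks/(2·r·10⁶); the reported interval is peak ± 1 component sd pushed
through the same linear map (component quantiles would be equally
defensible; ±1 sd is the package's choice).

## Shared-vs-independent WGD test

Collinear groups are connected components of the anchor graph restricted
to genes with at least one between-species anchor; groups exceeding
2^(#assumed WGDs) copies in a species are flagged unresolved rather than
interpreted.  Per group, a neighbor-joining tree (scikit-bio) is built on
pairwise K2P distances of the codon alignments — deterministic,
sufficient for a monophyly question on 4–8 leaves, and replaceable by an
external ML tree through the newick interface.  A rooting gene is drawn
uniformly from the focal species (one draw per group by default;
`n_rootings` with majority vote available).  Independent WGDs — events
occurring after the two species diverged — leave each species' surviving
duplicates clustered by species, so in the tree rooted on the chosen
focal gene the *other* species' genes form a monophyletic clade; shared
WGDs pair duplicates across species and destroy that clade.  The verdict
is *independent* when the other species' gene set is monophyletic under
the rooting, *shared* otherwise.  (Testing the focal species' own
remaining genes instead would misclassify clean independent histories:
rooting inside the focal clade, e.g. on x1 of ((x1,x2),(y1,y2)), leaves
{x2,y1,y2}, which is not a clade even though the species separate
perfectly.)  Monophyly is decided on bipartitions: a set S is a clade
under rooting on gene g iff some edge splits the leaves into exactly S
versus the rest.  Groups with missing paralogs leaving fewer than 2
remaining focal or 2 other-species genes, or with saturated
(non-finite) distances, are unresolved and excluded from the
f_shared/f_independent denominator (reported separately).

## LTR clock

Only elements with both LTRs present are admitted.  The two LTRs are
aligned globally (affine gaps) and their Kimura two-parameter distance
K = −½·ln(1−2P−Q) − ¼·ln(1−2Q) computed over unambiguous, gap-free
columns; non-positive log arguments mark saturation.  Insertion age
T = K/(2·r) with r per site per year — at the *Rheum nobile* rate
1.6 × 10⁻⁹, K = 0.0096 dates to 3.0 My.  Burst histograms use half-open
bins [k·w, (k+1)·w) with the modal bin flagged.

## Pathway DA score

Metabolite abundances are compared on the log2 scale with a two-sample
t-test; fold change is the ratio of geometric means.  Status is *up* when
FC ≥ 2 and p < 0.05, *down* when FC ≤ ½ and p < 0.05 — raw p by default,
matching the usual metabolomics screen; a Benjamini–Hochberg flag is
available.  DA score = (n_up − n_down)/n_diff over the pathway's
differential metabolites, so ±1 means all differential members moved one
way; a denominator over all annotated members is available behind a flag
(the ±1 endpoints then require every annotated metabolite to move, which
is stricter than the conventional reading).

## Problem sizes and numerical choices

The bundled study design — the configuration the acceptance checks run —
uses 1,000 ancestral genes on 4 chromosomes, 150-codon CDS, retention
0.7, outgroup split 80 My; the gene-tree direction checks use 220
ancestral genes at retention 1.0 per scenario.  These sizes give
hundreds of blocks/groups while keeping a full chain run in minutes on
one CPU.  Mixture fits need ≥ 20 in-range values; NG86 warns below 30
gap-free codons; NJ requires ≥ 3 taxa and finite distances; negative NJ
branch lengths are clamped to zero; BIC ties break toward fewer
components; depth-ratio modal ties break toward the smaller depth.

## Known limitations

Real genomes violate the simulator's clean-collinearity assumptions
(rearrangements, tandem arrays, nested/solo LTRs, rate heterogeneity);
the homology stage is not an E-value-calibrated search; NG86 is a
counting method, not an ML codon model; the rate correction is a stated
stand-in for the published method; gene trees are distance-based without
support values.  LTR discovery, genome annotation, species-tree dating
and enrichment analyses are out of scope.
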