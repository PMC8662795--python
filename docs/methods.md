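# Methods

This note documents the models, rules and numerical choices behind
`bambusa`, and what the synthetic-data experiments do and do not show.

## Phylostratigraphic gene dating

A phylostratum ladder orders the clades between the root of the Tree of
Life and a focal species into ranks 1..K (rank 1 oldest, rank K the focal
species alone).  Every subject genome used in the homology search belongs
to exactly one stratum.  A gene's age is the **minimum rank** among strata
holding at least one homology hit with e-value ≤ 1e-4 (the conventional
phylostratigraphy cutoff, configurable); a gene with no qualifying hit
outside the focal species is species-specific (rank K).  Hits to the focal
genome itself are ignored during dating — paralogy is handled by
clustering, not by age assignment.

Because polyploid genomes carry many near-identical paralogs, genes are
first clustered and only one representative per cluster is dated.
Clustering is MCL (expansion by matrix squaring, entry-wise inflation at
1.5, column re-normalisation) on the similarity graph whose edge weights
are `-log10(evalue)` of the best hit in either direction, with zero
e-values clamped at 1e-180 so weights stay finite.  Self-loops are set to
the maximum incident weight, the usual damping choice.  Clusters are read
off as connected components of the converged flow's support; for
converged runs this coincides with the attractor systems, and for graphs
whose components are cliques it provably equals connected components (a
tested invariant).  The representative is the longest protein, ties
broken by lexicographically smallest gene id for determinism.  All
cluster members inherit the representative's rank — a deliberate
simplification: non-representative members are never dated
independently.  Copy-number classes follow cluster size (1 singleton,
2 two-gene, ≥3 multigene).

The cluster fixation rate is `r = N/T` (clusters appearing in a stratum
per million years of that stratum's interval).

## Phylotranscriptomic indices

All indices operate on a genes × samples FPKM matrix.

* **TAI** (transcriptome age index), per sample:
  `TAI_s = Σ_i e_is · ps_i / Σ_i e_is` — the expression-weighted mean
  stratum rank.  High TAI = young transcriptome.
* **TDI** (transcriptome divergence index): same weighted mean over
  per-gene Ka/Ks; genes with undefined ω (Ks = 0 or missing) are excluded
  from numerator *and* denominator, never imputed.
* **Relative expression**: each gene's expression is first converted to a
  partial concentration across stages (row divided by row sum), these are
  averaged within a stratum, and each stratum's profile is min–max scaled
  to [0, 1].  Gene-first normalisation was chosen (over stratum-first) so
  the profile is invariant to per-gene scale; a stratum whose average
  profile is constant has no meaningful scaling and is flagged NaN.
* **Expression preference (EP)**: within a sample's 1,000
  highest-expressed genes, a stratum's share of the set's expression
  divided by its share of the gene count; 1 is neutral.  The top-k
  membership uses per-tissue values; k is a flag.
* **tau** tissue specificity: `τ = Σ_j (1 − x_j/x_max) / (N−1)` over N
  tissues, after averaging stage columns of the same tissue (τ is defined
  over tissues; a multi-stage tissue would otherwise dominate N).  0 =
  uniform, 1 = single tissue; all-zero genes are NaN.
* **Expressed fraction**: share of genes with FPKM ≥ 1 (configurable) in
  at least one sample.

**Flat-line test.**  The permutation test asks whether an index profile
deviates from a constant line.  The statistic is the variance of the
profile across samples; the null is built by permuting the per-gene
labels (ages or ω) `n_perm` times (default 1,000, seedable) and
recomputing the profile, and the p-value uses the add-one estimator
`p = (1 + #{perm ≥ obs}) / (1 + n_perm)`, which is never zero and keeps
the test valid at any permutation count.  The per-sample permutation
mean ± SD forms the reported band.  The choice of variance as the
statistic matches the "flat line" null of a constant profile; any
monotone alternative statistic would need its own calibration.

## De novo gene birth

A de novo candidate is an ORF intact in all ingroup species whose
orthologous region carries ORF-disabling lesions in ≥ 1 outgroup species
(regions absent from a species do not veto; with no outgroup region at
all the verdict is *indeterminate*, reported distinctly).

* **Hit filtering**: a nucleotide-level hit is effective when identity
  ≥ 80 and matched bases cover ≥ 20 % of the ORF (boundaries inclusive);
  a genome with ≥ 2 effective hits has no unambiguous ortholog and makes
  the query ineligible.  Reciprocal confirmation requires the ortholog's
  best back-alignment to be the originating ORF, strictly (ties fail).
* **Diagnosis** reads the ortholog in the query's frame via a global
  affine-gap alignment (match 2, mismatch −3, open −5, extend −2;
  Biopython's `PairwiseAligner`).  Lesions: any in-frame stop codon
  before the terminal codon; any internal gap run of length ≢ 0 (mod 3)
  (frameshift); a non-ATG aligned start.  Terminal overhangs are treated
  as missing sequence, not indels.  Fewer than one aligned codon →
  status *absent*.  Coordinates are 0-based internally; reported events
  use the 1-based "at N bp" convention.
* **Origination reconstruction** emits, per lesion, the minimal edit
  moving the ancestral state to the query state: substitutions for
  stop/start codon differences (one event per differing base), the indel
  itself for frameshifts.  Events are applied to the aligned ancestor and
  the diagnosis repeated (up to 10 rounds), so lesion chains resolve;
  the guaranteed round-trip property is that applying all returned
  events leaves a lesion-free frame.  Unrepairable lesions (e.g. region
  absent) are returned as unresolved rather than guessed.
* **Mechanism**: substitution-only, indel-only, or mixed.  No attempt is
  made to order events in evolutionary time beyond position order.

## Ka/Ks (NG86) and the selection test

Sites: per codon and position, the fraction of the three one-step changes
that are synonymous; changes into stop codons count as nonsynonymous, so
every codon carries exactly three sites (this matches Biopython's NG86
and is verified against it in the tests).  Substitutions: codons
differing at k positions are resolved by averaging synonymous /
nonsynonymous step counts over all k! orderings, excluding pathways that
pass through a stop codon (falling back to all pathways when every one is
blocked).  Proportions are Jukes–Cantor corrected
(`d = −3/4 ln(1 − 4p/3)`); saturated proportions (p ≥ 3/4) give NaN.
Codons containing ambiguity codes are skipped whole; a shared terminal
stop codon is ignored; internal stops are an input error.

Significance of ω ≠ 1 is a df = 1 chi-square of the observed
(synonymous, nonsynonymous) substitution counts against the split
expected from the site counts under equal per-site rates.  This replaces
a codeml-style likelihood-ratio test; on clear-cut cases (many
substitutions, ω far from 1) the classification agrees, but borderline
p-values can differ between the two approaches.  When the expected count
in either class is below 1 the comparison has essentially no power and
the result is *ns* with a `low_power` flag.

## SEG calling and enrichment statistics

The tissue-specificity caller is a transparent rule, not a re-implementation
of any published tool's internals: a gene is specific to its top tissue
when τ ≥ 0.85, expression there is ≥ 1 FPKM, and the top tissue exceeds
the runner-up by ≥ 2× (all three are flags).  For fair per-tissue
comparison with a multi-stage tissue, the balanced census re-calls SEGs
with that tissue represented by a single chosen stage column.

The 2×2 chi-square uses the Yates closed form
`Σ (|O−E| − 0.5)²/E`, df = 1, applied unconditionally — this is the
convention that reproduces the published statistic from published
counts.  (R and scipy clamp the correction so it cannot cross the
expectation; the two agree whenever every |O−E| ≥ 0.5, a property the
tests exercise.)  Fisher's exact test is scipy's two-sided
implementation, cross-checked against full hypergeometric enumeration in
the tests.  SBW tagging intersects a tissue's SEGs with genes in ≥ 1
WGD-class pair from a supplied duplicate-class table (duplicate
classification is consumed, never computed); summaries report the
WGD-derived fraction of the tissue's SEGs, the fraction of pairs with
both copies specific, and the fraction of SBW genes with ω ≥ 1.  The
ancestral-state comparison SEG-calls outgroup orthologs of SBW genes
(orthology map supplied, synteny out of scope) and partitions them into
specific / broad / unassessed.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (parameters, seed); a global seed is
expanded into per-component streams via fixed counters, so outputs are
byte-identical on reruns and stable when unrelated parameters change.

* **Hit tables**: a gene born at rank b leaves one strong hit (e-value
  10^−60..10^−10) in every stratum of rank b..K−1 plus a focal self-hit;
  `miss_rate` drops a stratum's hit, `spurious_rate` adds one extra hit
  in a random non-focal stratum.  Under dropout the assigned rank can
  only rise (genes can only look *younger*, never older) — the tested
  monotonicity direction.
* **De novo loci**: random valid ORFs (150–900 nt); ancestral outgroup
  states derived by inverting 1–3 enabling events chosen on disjoint
  codon neighbourhoods in query coordinates and applied right-to-left.
  Indels are placed so the optimal gap position is unique (fragment ends
  must differ from the flanking bases), which is what makes
  coordinate-exact recovery a fair target.  Neutral background
  divergence (default 2 %) is layered onto indel-free ancestors only and
  never creates additional lesions; with a planted indel the ancestor
  carries the lesion edits alone, since mutated flanks could otherwise
  create equal-score gap placements and make "exact position" ill-posed.
* **Expression**: per-gene baseline levels are log-normal across genes
  (median 5 FPKM, log-sd 1.0 — the dispersion of expression levels), and
  each gene varies log-normally across samples with log-sd 0.5 (roughly
  2–3× cross-tissue variation, the regime of broadly expressed genes).
  The within-gene spread is deliberately the smaller of the two: the
  unplanted background is *meant* to be non-specific, and at log-sd 1.0
  about 10 % of background genes would satisfy the SEG rule by chance,
  making planted-truth precision meaningless.  Young-gene bias multiplies
  the youngest strata's genes by the effect size in designated peak
  stages of the multi-stage tissue (effect 1 = null); planted SEGs get a
  50× boost in their tissue and suppression elsewhere.
* **Divergence**: CDS pairs receive synonymous and nonsynonymous
  substitution counts planted at the expectations implied by the
  scheduled (Ks, ω) after Jukes–Cantor inversion — at most one change per
  codon, never creating stops; randomness lies in placement.  Planting
  expectations rather than Poisson draws makes the pair's divergence
  match the scheduled contract; estimator spread then reflects counting
  and correction, not sampling noise of the truth itself.

What passing these suites shows: the inference logic is correct on data
matching its assumptions.  What it does not show: robustness to real
homology-search artefacts (profile-dependent BLAST sensitivity,
alignment ambiguity in repeats), to expression batch effects, or to
orthology errors — none of which the generators model.

## Problem sizes and runtime choices

The test and acceptance experiments use scaled-down sizes chosen as the
package's own defaults for quick, reproducible runs: 600–2,400 genes for
expression experiments, 200 null / 100 power replicates at 200
permutations for flat-line calibration, 100 single-event loci for
recovery, and the full 61 × 61 sense-codon pair grid for the NG86
oracle.  At these sizes the planted effects (4× bias, 50× SEG dominance,
ω schedules between 0.15 and 0.9) are comfortably identifiable, which is
the point: the experiments are correctness checks, not power surveys.

## Known limitations

* Cluster members inherit the representative's age; genes mis-clustered
  by MCL inherit the wrong age silently.
* The flat-line statistic (profile variance) and permutation count are
  this package's definitions; published analyses name the test without
  defining it, so numeric p-values are not comparable across tools.
* The chi-square selection test is a counting approximation to a
  likelihood-ratio test; borderline classifications may differ.
* The SEG rule is a transparent substitute for fuzzy-clustering-based
  callers; absolute SEG counts depend on its three thresholds.
* Reconstruction reports the minimal edits relative to the observed
  outgroup state; it does not infer ancestral states phylogenetically.
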