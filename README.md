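# bambusa

Phylostratigraphic gene dating, young-transcriptome indices, de novo
gene-birth reconstruction and tissue-specificity statistics — the
computational core of the "new genes behind a morphological innovation"
style of analysis, built for lineages such as the woody bamboos where a
burst of lineage-specific genes meets a recent whole-genome duplication.

**Who it is for.** Researchers with protein/CDS FASTA sets, BLAST-style
homology hit tables, and gene × tissue FPKM matrices who want to ask:
how old is each gene, do young genes dominate particular tissues or
developmental stages, which orphans were born de novo from noncoding
DNA and through which enabling mutations, and are tissue-specific genes
enriched for particular duplicate classes?

## The core quantities

* **Gene age (phylostratum)** — genes are assigned the minimum rank
  `ps_i` on a K-rank species ladder (PS1 oldest … PSK species-specific)
  with a qualifying homology hit (e ≤ 10⁻⁴); paralogs are MCL-clustered
  (inflation 1.5) and the cluster inherits its longest member's age.
  Birth statistics include the cluster fixation rate `r = N/T`
  (clusters per My).
* **TAI / TDI** — expression-weighted mean age and divergence per
  sample: `TAI_s = Σ e_is·ps_i / Σ e_is`, `TDI_s = Σ e_is·(Ka_i/Ks_i) /
  Σ e_is`.  A permutation *flat-line test* (statistic: profile variance;
  labels permuted across genes) decides whether a profile deviates from
  a constant line.
* **RE / EP / τ** — per-stratum relative expression across stages
  (min–max scaled mean partial concentration), expression preference of
  the top-1,000 expressed genes (expression share ÷ gene share, 1 =
  neutral), and the τ tissue-specificity score
  `τ = Σ_j (1 − x_j/x_max)/(N−1)`.
* **De novo birth** — orthologous regions are diagnosed in the query
  ORF's frame (premature stops, frameshifting indels, destroyed starts);
  candidates are intact in the ingroup and disabled in ≥ 1 outgroup, and
  the minimal enabling mutations (e.g. a stop-removing T→G substitution
  "at 19 bp") are reconstructed and classified as substitution / indel /
  mixed.
* **Ka/Ks (NG86)** — site and pathway counting with Jukes–Cantor
  correction, plus a χ² test of ω ≠ 1 classifying purifying / positive /
  ns.
* **SEGs and enrichment** — tissue-specific genes via a τ/dominance
  rule, per-stratum census tables, shoot-biased WGD tagging from a
  supplied duplicate-class table, Yates-corrected χ² and Fisher's exact
  tests.

A fully seeded synthetic-data module plants known gene ages, enabling
mutations, expression biases and ω schedules, so every stage is testable
without any genome download.

## Worked example

```python
import bambusa as bb

# 1. plant gene births on a 12-rank ladder and date them back
ladder = bb.simulate_ladder(k_strata=12)
hits, truth = bb.simulate_hit_tables(
    ladder, {1: 200, 4: 120, 10: 40, 11: 25, 12: 80}, seed=7)
ages = bb.assign_strata(hits, ladder, queries=truth.data["birth_rank"].index)
census = bb.stratum_census(ages, young_ranks=(10, 11, 12), max_rank=12)

# 2. expression with young genes 4x over-expressed at two shoot stages
expr, tissue_map, etruth = bb.simulate_expression(
    ages, young_bias_effect=4.0, n_seg_per_tissue=10, seed=7)
res = bb.flat_line_test(expr, ages, n_perm=1000, seed=7)

# 3. SEG calling, 4. de novo reconstruction, 5. Ka/Ks — see below
```

Output of the full script (steps 3–5 analogous, see `docs/methods.md`):

```
genes dated: 465 | orphans (PS10-12): 145 | recovery: 100%
TAI peak: shoot_S5 = 9.36 | planted peaks: ['shoot_S4', 'shoot_S5'] | flat-line p = 0.02797
SEGs called: 70 | precision 1.00 | recall 1.00
outgroup status: disabled | lesion: missing_start
enabling event: T -> A at 1 bp (resolves missing_start) | matches truth: True
Ka = 0.101, Ks = 0.503, omega = 0.20 -> purifying (p = 2.6e-18)
```

Reading it: all 465 planted birth strata are recovered exactly on
noiseless hit tables, with 145 genes in the three youngest ("orphan")
strata.  The TAI profile peaks at one of the two planted peak stages of
the multi-stage shoot-like tissue, and the flat-line test rejects a
constant profile (p ≈ 0.03).  All 70 planted tissue-specific genes are
called with no false positives.  The lesioned outgroup ortholog is
diagnosed noncoding and the planted enabling mutation is rebuilt exactly
(a T→A substitution restoring the start codon at position 1).  The CDS
pair evolved under ω = 0.2 at Ks = 0.5 is estimated at ω = 0.20 and
classified as purifying selection.

A `bambusa` command-line tool wraps the same functions (`cluster`,
`assign-age`, `census`, `tai`, `tdi`, `re`, `ep`, `tau`, `seg`,
`enrich`, `sbw`, `denovo scan|reconstruct`, `kaks`, `simulate …`); run
`bambusa --help`.

## Layout

```
src/bambusa/
  ladder.py      species-ladder model and config I/O
  hits.py        BLAST outfmt-6 dialect reader/writer
  cluster.py     similarity graph + MCL + representatives
  ages.py        stratum assignment, propagation, census, fixation rate
  indices.py     TAI/TDI/RE/EP/tau, flat-line test, expressed fraction
  kaks.py        NG86 Ka/Ks and the selection test
  denovo.py      hit filtering, diagnosis, origination reconstruction
  enrichment.py  SEG calling, censuses, chi-square/Fisher, SBW tagging
  simulate.py    seeded generators with recorded ground truth
  io.py, cli.py  file round-trips and the command-line surface
```

Design notes, assumptions and limitations are in `docs/methods.md`.
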