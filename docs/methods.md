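# Methods

## Scope and data model

The package analyses called genotype scores, not reads. Two marker
classes are handled throughout:

- **SNP (codominant)** — cells in {REF_HOM, ALT_HOM, HET, MISSING},
  mapping the report tokens 0/1/2/– ("0" is the reference homozygote
  for the most common allele, "–" the double-null).
- **PA (dominant presence/absence)** — cells in
  {PRESENT, ABSENT, MISSING}, tokens 1/0/–. The "–" token is glossed in
  DArT reports as putative heterozygosity, but it carries no usable
  count information for a dominant marker, so it is treated as missing
  in every statistic.

The canonical file dialect is a one-row-per-locus CSV
(`locus_id, reproducibility, call_rate, read_depth, tag_sequence,
<individuals…>`); the authentic two-row DArTsoft SNP export is
deliberately not emulated. The missing token is accepted as hyphen,
en-dash or empty cell and always written back as a hyphen, making
read∘write the identity on cell codes.

## Quality control

A locus is retained iff reproducibility > 0.90, mean read depth > 3.5
(SNP) or > 5.0 (PA), and call rate > 0.80 — strict inequalities,
matching the platform's ">" phrasing. Call rate is **recomputed** from
the matrix as the fraction of non-missing cells and the recomputed
value is authoritative; vendor-reported call rates depend on an
unknown sample subset and are not auditable. Rejections record the
first failed criterion in the fixed order reproducibility → depth →
call rate. Retention is order-invariant and monotone: raising any
threshold can only shrink the retained set.

## Linkage criterion

The *x*:(100−*x*) criterion is read as a two-sided rule: carrier
fraction ≥ *x*% in the heterogametic sex AND ≤ (100−*x*)% in the other
sex, with fractions over scored individuals only. The complement rule
on the homogametic side is the only reading consistent with reporting
female-linked candidates under "30:70"/"20:80" labels; its effect is
flagged for sensitivity analysis via the configurable tier list.
Comparisons are non-strict ("at least 70% of males") with a 1e-12
guard against float representation of tiers like 0.7. ALT_HOM counts
as a carrier because recombining sex chromosomes let the heterogametic
sex become homozygous for the linked allele. PERFECT requires tier
1.00 (carrier fraction 1 vs 0), so no locus can be PERFECT under XY
and ZW simultaneously; relabelling the sexes swaps the XY and ZW
candidate sets exactly, and candidate sets are nested across tiers.

`scan_dataset` materialises one result per (locus, criterion) for
reporting; `scan_counts` is the vectorised counting path used for
panels up to 10⁶ loci.

## Association statistics

- **CATT.** The N-scaled variance form
  T = N[NΣwᵢrᵢ − RΣwᵢnᵢ]² / (R(N−R)[NΣwᵢ²nᵢ − (Σwᵢnᵢ)²]), case row =
  males, dosage scores (0,1,2) for SNP and (0,1) for PA, referred to
  χ²(1). This variant equals N·r² (r = score/sex correlation) and
  reaches exactly T = N at perfect binary separation; zero variance is
  reported DEGENERATE with p = 1. T is invariant to affine weight
  changes. The χ²(1) reference is an asymptotic approximation: on
  tables with N ≲ 20 the exact conditional (permutation) distribution
  of T is coarsely discrete and its tail probabilities can differ from
  the χ² p by several hundredths or more — small-sample p-values
  should be read as orderings, not calibrated error rates. The test
  suite quantifies this against multivariate-hypergeometric
  permutation sampling.
- **χ² tests** delegate to scipy (`chisquare`, `chi2_contingency`
  without continuity correction) after dropping zero-expectation
  categories / empty margins.
- **PIC** is implemented as expected heterozygosity 2p(1−p), whose
  range [0, 0.5] matches the index's stated behaviour for biallelic
  DArT loci (the classical Botstein PIC maxes at 0.375 and would not).
  SNP allele frequency is (2·ALT_HOM + HET)/(2·scored); PA uses
  presence frequency.
- **Kruskal–Wallis** uses scipy's tie-corrected H; the **Nemenyi
  post-hoc** is the χ²-approximation variant for independent samples:
  qᵢⱼ = (R̄ᵢ−R̄ⱼ)² / [C·N(N+1)/12·(1/nᵢ+1/nⱼ)] on χ²(k−1), with tie
  correction C = 1 − Σ(t³−t)/(N³−N). No installed package provides
  this variant, so it is written here with a rank-arithmetic oracle in
  the tests.
- p-values are reported raw; Benjamini–Hochberg adjustment is
  available behind `benjamini_hochberg` but off by default.

## Spurious-linkage model

Pᵢ = 0.5ⁿ is the probability that one sex-independent locus shows a
perfectly sex-linked pattern across n sexed individuals (each
individual independently lands on the "correct" side with probability
½). Expected spurious hits over L loci is L·Pᵢ;
`required_sample_size` inverts this for a target budget. For
reproducing published figures quoted at three significant digits,
`round_sig` lets the per-locus probability be rounded before the
multiplication (0.5³⁰ → 9.31×10⁻¹⁰; ×101,642 → 9.463×10⁻⁵, versus
9.466×10⁻⁵ unrounded).

## Hamming distances

Distance between two individuals = (# co-scored loci with different
codes) / (# co-scored loci) — proportional, with pairwise deletion
because no principled missing-data rule exists for these panels. SNP
codes compare as categorical symbols (HET ≠ ALT_HOM ≠ REF_HOM), not
dosages. Pairs with zero co-scored loci are undefined (NaN) and
excluded, with a count, from the within/between-sex summaries (mean ±
sample sd over unordered pairs). The locus subset is an explicit
argument; the intended use is candidate loci, where a genuine
sex-linked panel shows between-sex ≫ within-sex distances. Exports are
deterministic (6-decimal TSV, sex-blocked or lexicographic ordering),
and a locus × individual allelic-state table provides the tabular form
of per-individual index plots.

## Synthetic cohorts

The generator emulates the target study design: ~15 males + 15
females, a large panel of sex-independent markers and a few planted
sex-linked loci.

- **Planted loci.** Heterogametic individuals show the linked state
  (HET for SNP — never ALT_HOM, since the allele rides one sex
  chromosome — PRESENT for PA) with probability `penetrance`
  (default 1.0); the homogametic sex shows it with probability
  `leakage` (default 0.0), the generator's abstraction of X–Y
  recombination. Architectures: XY, ZW, PSD (both roles in one
  cohort), NULL.
- **Background.** Per-locus allele frequency ~ Beta(2, 2) with
  Hardy–Weinberg genotypes independent of sex (intermediate
  frequencies dominating, consistent with PIC distributions skewed
  toward high values on real DArT panels); PA presence probability
  drawn from the same law. Missingness overwrites cells i.i.d. at
  `missing_rate` (default 0.05, comfortably inside the 80% call-rate
  filter).
- **Defaults.** 2,000 SNP + 2,000 PA loci — a desk-scale stand-in for
  the ~50k-per-class panels a real DArTseq run yields; recovery and
  calibration experiments scale the counts per experiment (up to 10⁶
  loci for the null-rate check).
- **Determinism.** One seed; each variable stream (SNP calls, PA
  calls, missingness masks, metadata, tags) uses a substream derived
  with a fixed spawn key, so identical (seed, config) gives
  byte-identical files and adding PA loci never perturbs SNP draws.
- **Parent/offspring pairs.** `simulate_parent_offspring_pair` reuses
  exactly ⌊f·n⌋ parent tag sequences in the offspring dataset (taken
  deterministically from the head of the locus list), emulating
  markers traceable across a cross for tag-based matching.

What the generator does **not** model: linkage disequilibrium and
linkage maps, pedigree/meiosis, read-level error, locus dropout
correlated with genotype, or a biological mechanism for the PA
putative-heterozygote code. Passing recovery tests therefore
demonstrate the scan's correctness under independent loci with known
penetrance — not robustness to LD structure or genotyping artefacts in
real panels.

## Numerical and design notes

- Sex-registry lookups are strict: an individual present in a matrix
  but absent from the registry is a hard error, never silently
  dropped, so the sex ratio a scan sees cannot drift.
- Scan report rows sort by (locus_id, hypothesis, tier); all outputs
  are byte-stable across reruns, and `run_pipeline` output is a pure
  function of (config, seed, inputs).
- Degenerate inputs are flagged, not raised, wherever a statistic has
  a natural degenerate value (zero-variance CATT, single-category χ²,
  all-identical Kruskal–Wallis); structurally invalid inputs
  (negative counts, non-monotone weights, empty matrices) raise.
- Sample standard deviations use ddof = 1; single-observation groups
  report sd 0 within profiles and summaries.

## Known limitations

- The criterion scan is marginal per locus; it does not model joint
  segregation of multiple switch loci beyond planting them
  independently.
- χ²-based p-values (CATT included) are approximations at cohort
  sizes of 15 + 15; exact conditional inference is provided only as a
  test oracle, not as a reporting mode.
- Dominant PA markers conflate heterozygous and homozygous presence;
  the heterozygosity profile therefore reports presence fraction for
  PA, which is not an estimate of heterozygosity sensu stricto.
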