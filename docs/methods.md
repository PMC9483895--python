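# Methods

This note records the models behind each stage, the parameter defaults
and why they were chosen, the numerical conventions, and what the
synthetic-data regime does and does not demonstrate.

## Conservation classification

A reference-genome locus is classified per target species from a pair
of LiftOver-style mapping records:

* `HIGHLY_CONSERVED` — the direct mapping has exactly one hit with
  identity ≥ `min_identity` (default 0.95), and the reciprocal mapping
  of that hit has exactly one hit with identity ≥ `min_identity`
  landing on the same chromosome with |Δstart| + |Δend| ≤ `slop`
  (default 0 bp).
* `ABSENT` — no direct hit exists.
* `DIVERGED` — everything else (multi-hit mappings fail the
  single-orthologous-locus requirement regardless of identity).

`identity` is defined as the fraction of the query sequence recovered
at the mapped locus.  Whether a remapping tool's threshold applies to
minimum match or to aligned-base identity is a user-side decision; both
are representable through this one field.  The absent/diverged
distinction is needed by the human-specific rule and by the synthetic
truth-tracking; the conserved-count analyses only consume
`HIGHLY_CONSERVED`.

The human-specific rule is deliberately permissive in the other
direction: a locus is human-specific when, in both chimpanzee and
bonobo, no mapping reaches `hs_identity_cutoff` (default 0.10, read as
"no mapping achieving ≥ 10% identity", since sub-10% nucleotide
identity is below alignability).  `bona_fide` additionally requires
`intersects_chain` false in both genomes.  Human-specific loci can
still be highly conserved in more distant species — that is the
signature of a loss on the chimpanzee+bonobo branch, not of a recent
human insertion.

## Abundance profiles and resemblance

Profiles are percentages (not raw counts) so species with very
different conserved totals remain comparable; a species with zero
conserved loci has no profile and is excluded with a warning.
Resemblance uses the Pearson product-moment coefficient.  Length-2
profiles are permitted with the degenerate ±1 outcome; zero-variance
profiles raise rather than returning NaN.

## Acquisition-rate dating

The dating model is linear accumulation: loci arise on the lineage to
the reference at a constant rate and the deficit of conserved loci in
a species measures its age.  With anchor counts cᵢ externally dated to
Tₐ (default 29 MYA, the Old World Monkey split) and reference count N,

    rate = (N − mean cᵢ) / (Tₐ − T_ref),     t(c) = (N − c) / rate.

Committed interpretation and known limitations:

* anchoring uses the *mean* anchor count by default (per-species
  anchoring is available by fitting one model per anchor);
* losses on non-reference lineages are ignored, so with retention loss
  the deficit overstates age and estimates are biased upward — the test
  suite asserts this bias direction rather than pretending it away;
* the estimate is scale-consistent (doubling all counts and the rate
  leaves dates unchanged).

## Regulatory domains and association

Basal domain: TSS − 5 kb … TSS + 1 kb on the coding strand (mirrored
for − strand genes), clipped at position 0.  Extension: each side grows
up to `max_extension` (default 1 Mb) from the basal boundary but stops
at the nearest neighbouring basal-domain boundary; chromosome ends clip
when sizes are supplied.  Equivalently — and this is how the test
oracle states it — the extension is the largest flank that avoids every
other gene's basal domain.  The three parameters are the widely used
"basal plus extension" defaults and all are configurable.

A locus links to a gene when it overlaps the extended domain by ≥ 1 bp;
a midpoint-containment mode is available.  Loci overlapping nothing are
recorded as unlinked rather than dropped.  Curated-domain and
gene-filtering refinements of specific association-tool releases are
not modelled.

## Enrichment statistics

`fisher_two_sided` sums, over all tables sharing the observed margins,
the hypergeometric probabilities not exceeding the observed table's
(with the customary 1 + 1e−7 relative slack absorbing floating-point
round-off) — the convention of the mainstream exact-test
implementations.  The implementation enumerates the margin class
directly, which also exposes `fisher_margin_class` for vectorised and
exhaustive-verification use; it is cross-checked in the tests against
an independent implementation and against exact rational enumeration.

Category enrichment supports two table constructions, which differ
only in the Fisher test, never in the percentages or the ratio:

* `method="universe"` (default): the standard partition
  [[k, n−k], [K−k, N−n−K+k]] of the whole universe.  This is a
  calibrated exact test (empirical type-I error ≈ nominal in the null
  simulations) and should be used for new analyses.
* `method="expected_count"`: observed in-category count versus the
  expected-by-chance count for an equally sized linked set,
  [[k, n−k], [e, n−e]] with e = round(n·K/N).  This construction is
  the one behind the published enrichment tables and reproduces their
  printed p-values; it is conservative (the expected column carries no
  sampling variance), so its p-values understate significance.

Differential comparisons are plain Fisher tests of
[[k_A, n_A−k_A], [k_B, n_B−k_B]].  The hypergeometric overlap test is
the upper-tail probability P(X ≥ overlap).  The combined score uses
the natural logarithm, c = ln(p)·z, with z accepted as an input (the
rank-permutation machinery that produces z in enrichment platforms is
out of scope).  Benjamini–Hochberg adjustment is provided as a
utility.  Reported percentages and ratios are rounded half-up to two
decimals, matching table conventions; full precision is kept
internally.

## Synthetic-data regime

The generator emulates the statistical structure the analysis assumes,
not sequences:

* **Locus history.** n = `insertion_rate` × `origin_mya` loci (defaults
  84/MYA over 40 MYA ≈ the 3354-locus catalog scale) with ages uniform
  over the family's residence time.  A locus is present in a species
  when born before its split and not lost on its branch
  (`retention_loss_prob`, default 0.05/branch — there is no published
  loss-rate estimate, so this is a pilot-chosen magnitude that leaves
  the monotone-retention regime intact).  Mapping identity decays
  linearly, clamp(1 − 0.001·T + N(0, 0.005²)), so every present locus
  sits comfortably above the 0.95 threshold at ≤ 29 MYA and calls
  recover planted truth; a 2% reciprocal-failure fraction exercises the
  DIVERGED path.  Coupled chimpanzee+bonobo losses
  (`pan_loss_prob` = 0.03) plant the "human-specific yet
  monkey-conserved" regime.  Subfamily identity is drawn with
  age-shifted intensities (weights at the human catalog's proportions,
  Gaussian activity bumps with a floor) so all subfamilies exist at all
  ages while composition drifts smoothly — this is what produces the
  negative resemblance-vs-divergence association.
* **Species panel.** Human plus chimpanzee and bonobo at 13 MYA,
  gorilla 15.1, orangutan 16.0, gibbon 16.8, and five Old World Monkey
  species at 29 MYA — consensus molecular dates.
* **Gene universe.** 18,777 genes over five 50-Mb chromosomes (small
  enough for brute-force oracles); offspring-survival flags at
  probability 2413/18777, exactly 355 synaptic and 88 fetal-gonad
  marker genes.
* **Perturbation response.** Genes respond with probability 0.53 when
  linked and 0.04 otherwise (the published high-confidence contrast);
  responders are spread over named experiments so the union recovers
  the planted probabilities.

What passing tests on this regime do **not** show: the generator has no
sequence evolution, recombination, indels, insertion-rate bursts (the
observed great-ape expansion is narrative, not modelled), no
chain-level mapping artefacts, and gene positions independent of locus
positions; real-data quantities that depend on genome-scale structure
(per-species correlation values, human-specific totals, linked-gene
totals) are therefore covered qualitatively, not numerically.

## Numerical choices and problem sizes

* Coordinates are 0-based half-open throughout (BED convention).
* Seeded `numpy` generators everywhere; identical configuration ⇒
  identical outputs, and the pipeline's TSV reports are byte-identical
  across reruns.
* Degenerate inputs raise typed errors (zero-variance correlations,
  empty linked sets, zero-accumulation anchors) rather than returning
  NaN.
* The published-table replay compares ratios and percentages exactly at
  two printed decimals and p-values at three significant figures, which
  absorbs two-sided-convention and rounding differences.
* Test problem sizes: the shared synthetic fixture runs ~600 loci ×
  10 species × 800 genes; the dating-recovery and truth-recovery runs
  use the full default regime (~3360 loci); the Fisher enumeration
  sweep covers every margin class with table total ≤ 60 (using
  row/column-swap invariance to halve each margin range); association
  is checked against the all-pairs oracle on 200 random annotations up
  to 100 genes × 1000 loci; null calibration uses 2000 replicates at
  the study's margins.

## Open design points resolved

* The two published target-catalog tables are titled inconsistently
  (the LTR5_Hs catalog carries the LTR7-style title and vice versa);
  the counts' internal consistency (935/486 vs 2957/1570) identifies
  which is which, and the package keys sets by family, not by table.
* "And/or" target sets are unions of gene symbols, not of loci: the
  family-level bookkeeping (377 + 2580 + 558 = 3515) only reconciles
  at gene level.
* Response-set membership is binary; effect direction, when present in
  inputs, is carried as metadata but ignored by the set algebra.
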