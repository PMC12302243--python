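# Methods

This note documents the models, defaults and numerical choices behind
`repdeplete`, and what the synthetic validation does and does not establish.

## Clonotype definitions

T-cell clonotypes (TRB, TRD) are equivalence classes of identical full
nucleotide sequences — gDNA bulk sequencing of a rearranged TCR locus gives
one sequence per clone, so exact identity is the natural clone definition.

B-cell (IGH) clonotypes are inferred clonal lineages. Because somatic
hypermutation diversifies a lineage after V(D)J recombination, identity is
too strict; instead records are partitioned by (V gene, J gene, junction
length) — allele calls are truncated at `*` to the gene level — and
single-linkage clustered on the normalized junction Hamming distance
(mismatches over junction length). Two records share a lineage iff they are
connected by a chain of pairs at distance ≤ the threshold (default **0.15**,
the conventional distance-based clone definition for IgH junctions). Single
linkage reproduces connected-lineage semantics and is exactly checkable
against an all-pairs transitive-closure oracle, which the test suite does.
`N` junction positions count as matches: sequencing ambiguity should merge,
not split, lineages. Gene-level (not allele-level) grouping was chosen
because allele miscalls within a gene are common upstream; the threshold and
grouping are exposed as parameters.

Clone identifiers are assigned deterministically by sorting clones on
(molecule count descending, lexicographically smallest member sequence), so
clone labels are invariant to input record order.

## Somatic hypermutation

SHM is counted over the full V-region alignment (`sequence_alignment` vs
`germline_alignment`), not the junction: a position counts iff both
characters are unambiguous nucleotides and differ; gaps and `N` are
excluded. This matches the usual observed-mutation semantics of germline
annotated rearrangements.

The sample summary "mean SHM per clonotype" is a two-level mean: per-sequence
counts averaged within each clonotype, clone means averaged **unweighted**
across clonotypes. Unweighted averaging keeps a handful of large
germline-near clones from swamping the signal of many small highly mutated
lineages (or vice versa), which is exactly the contrast the bimodal
post-depletion repertoires show. The size-weighted variant is computed as
well (`mean_shm_weighted`) since the choice is genuinely open.

## Repertoire architecture and tracking

* **Clonality** = 1 − H/ln R (one minus Pielou evenness) of clone molecule
  frequencies; a single-clone repertoire is defined as 1.0 (maximally
  clonal). No formula beyond this is assumed anywhere.
* **Top-N proportion**: molecule share of the N most expanded clones; ranks
  tie-break on the lexicographically smallest member sequence for
  determinism. Defaults N = 100 (TRB), 25 per Vδ2 stratum (TRD).
* **Sample overlap**: molecules at follow-up whose nucleotide sequence
  occurs in the baseline reference set, divided by total follow-up
  molecules. The numerator/denominator are molecule-weighted ("proportion of
  the sample" reads as abundance), membership is a set of unique sequences
  ("already detected" reads as detection). The baseline is first reduced to
  a fixed budget (default 10,000 molecules) by seeded subsampling so deep
  baselines do not trivially inflate overlap.
* **Top-N overlap**: |top-N(follow-up) ∩ top-N(baseline)| / min(N,
  follow-up richness), compared by nucleotide sequence so independently
  assigned clone labels still match. The denominator choice (min rather
  than N) keeps the statistic in [0, 1] for shallow follow-ups; it is the
  natural reading of "proportion of top clones already detected".
* **Vδ2 partition**: a TRD record is Vδ2+ iff its V gene is TRDV2.

## Downsampling

Subsampling is molecule-level (UMI-level): each record contributes
`duplicate_count` indistinguishable molecules and exactly *n* are drawn
uniformly without replacement via `numpy`'s multivariate hypergeometric
sampler, then collapsed back to records. Requesting more than available is
an error, never a silent truncation. Two planning rules mirror the study
design: fixed caps (10,000 molecules for control IGH; 100,000 for TRB) and
the matched plan `target_followup = min(followup, cap)`,
`target_baseline = min(baseline, target_followup)` that puts treated
baselines on the same footing as their depleted follow-ups.

All seeds are derived by hashing a root seed with (donor, timepoint, locus,
purpose) keys, so streams are independent of iteration order and adding a
sample never perturbs another sample's draws.

## Reconstitution classification and calibration

A donor is called **reconstituted** iff the follow-up sample contains at
least 1,000 sequenced B cells; the comparison is inclusive (the boundary
value counts as reconstituted — the cutoff phrase "at 1,000" does not fix a
side, so the inclusive reading is documented rather than hidden). The
alternative flow-cytometry cutoff of 10 B cells/µL is exposed as a constant,
not hard-coded as truth. The flow-count calibration is ordinary least
squares with a free intercept (the two anchor points, ~1,000 sequenced at
1 cell/µL and ~5,000 at 10 cells/µL, are not proportional, so no
through-origin constraint), with `predict`/`invert` helpers. The bimodality
report uses Spearman rank correlations because sequenced counts span orders
of magnitude.

## Marker gating

Positivity is raw transcript count > 0, with no normalization — the rule is
normalization-free by construction. Fractions are computed per subset per
sample (per-patient points, not cells pooled across samples); subsets are
retained when ≥ 1% of their cells express the marker; empty subsets are
excluded with a warning rather than dividing by zero. Concordance against
protein labels reports P(protein+ | RNA−) (false-negative rate of the RNA
gate) and P(protein+ | RNA+).

## Inference

Within-cohort baseline/follow-up shifts are tested with two-sided Wilcoxon
signed-rank tests (exact null distribution up to 25 pairs, zero differences
dropped, at least five complete pairs required). The covariate-adjusted
linear and linear-mixed models used in clinical analyses are intentionally
not re-implemented: synthetic cohorts carry no age/sex/history covariates,
and the report tables retain per-donor values so external modelling remains
possible.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, with
ground truth for recovery testing. Per donor and locus:

* Clone abundances follow a Zipf law with exponent **s = 1.1** truncated at
  a fixed richness — heavy-tailed expansion is required for a meaningful
  "top 100" and matches repertoire phenomenology.
* Germline references are a small synthetic allele set (12/10/3 V genes ×2
  alleles and 6/8/4 J genes for IGH/TRB/TRD; 300-nt V region, 48-nt J,
  junction lengths 30–57 in codon steps), generated once from a fixed seed.
  It is a stand-in, not an IMGT database.
* IGH lineages carry a maturity class (naive fraction 0.6); trunk SHM is
  Poisson with mean **0.5** (naive) or **20** (memory/plasma) placed
  uniformly on the V region, plus small per-sequence extra mutations.
  Within-lineage junction variants mutate at most one position, keeping
  member distances far below the 0.15 clustering threshold so clonotype
  truth is well defined; distinct lineages draw independent random junctions
  whose expected distance (~0.75) is far above it.
* CD20dim TRB clone probability is logistic in log clone rank (slope 1.5),
  calibrated by root finding so the marginal CD20dim share is **8%** of
  T cells (the blood CD20dim range is ~5–10%); expansion enrichment is the
  mechanism by which depletion hits the top clones. Vδ2+ TRD clones (55% of
  clones) are depleted with probability **f_vd2 = 0.5**; CD20dim TRB clones
  with **f_T = 1.0**; baseline B lineages with **f_B = 0.99**.
* Treated (OCR) donors draw one of two follow-up B scenarios with equal
  probability: **residual** — only persistent memory lineages (persistence
  0.8, a value no measurement fixes; exposed in config) re-observed at low
  counts (log-normal mean 450) — or **reconstituted** — fresh naive
  lineages with new junctions at higher counts (log-normal mean 8,350;
  the scenario mix reproduces a ~4,400-cell mean follow-up against a
  ~53,700-cell baseline, i.e. a ~92% reduction). Residual counts sit below
  and reconstituted counts above the 1,000-cell threshold by design, with
  enough spread that the classifier boundary is exercised from both sides.
* Control cohorts (11 healthy donors, whose follow-up brackets a
  vaccination; 14 natalizumab-treated donors with deeper B-cell repertoires,
  mean 77,601 molecules) have no depletion; their IGH repertoires resample
  baseline with 15% lineage turnover, their T-cell repertoires with none —
  making the healthy TRB pairs an exact exchangeable null used for the
  type-I-error check.

Identical config + seed produces byte-identical output files.

**Problem sizes.** Default per-sample clone richness is 800 IGH lineages,
1,500 TRB and 400 TRD clones — deliberately smaller than real repertoires
(10⁴–10⁵ clones) so a full 60-donor cohort simulates and analyzes in well
under a minute; molecule depths, cohort sizes, caps and thresholds are kept
at study scale. Statistical recovery tests shrink richness/depth further
(stated in each test) since the properties checked are scale-free.

**What passing tests do not show.** The generator draws junctions uniformly
at random (no VDJ recombination biology, no convergent/public clones), has
no sequencing error, no isotype structure, no allele miscalls, no mutation
hot/cold spots, and its two B-cell scenarios are cleanly separated rather
than a continuum. Recovery results therefore validate the pipeline's
arithmetic and its ability to detect the modelled effects — not the
clinical effect sizes, which only real cohorts can provide.

## Known limitations

* Single-linkage lineage clustering can chain distinct lineages through
  intermediate sequences in very deep, short-junction groups; the threshold
  is conservative but data-independent (no per-sample threshold tuning).
* SHM ignores junction mutations by construction (no germline is available
  for the junction), slightly undercounting total mutation load.
* `sample_overlap` depends on the baseline cap and seed; both are recorded
  in the run log.
* The reconstitution threshold is a step function; donors near 1,000
  sequenced cells are genuinely ambiguous, and a few per cohort fall on the
  wrong side of their generating scenario.
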