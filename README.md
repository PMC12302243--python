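# repdeplete

Longitudinal B-/T-cell receptor (AIRR-seq) repertoire analysis under
anti-CD20 lymphocyte depletion.

Therapeutic anti-CD20 antibodies (e.g. ocrelizumab) remove circulating
CD20+ cells: essentially all B cells, plus the small CD20dim subset of
T cells. `repdeplete` implements the repertoire-sequencing side of studying
that depletion in paired baseline (M00) / six-month follow-up (M06) blood
samples: who disappears, who persists, and whether the B cells seen after
depletion are therapy-resistant survivors or fresh output of the bone
marrow. It is aimed at immunologists and bioinformaticians working with
bulk AIRR rearrangement tables (IGH, TRB, TRD) and single-cell count
matrices.

## What it computes

**Clonotyping.** T-cell clonotypes are groups of identical nucleotide
sequences. B-cell (IGH) clonotypes are clonal lineages: records are
partitioned by (V gene, J gene, junction length) and single-linkage
clustered on normalized junction Hamming distance *d* = mismatches / L,
merging records connected by any chain of pairs with *d* ≤ 0.15.

**Somatic hypermutation (SHM).** Per sequence, the number of positions where
the V-region alignment differs from the inferred germline (gaps and N
excluded); summarized as the unweighted mean over clonotypes of the mean
per-sequence SHM within each clonotype.

**Repertoire architecture.** Clonality is 1 − Pielou evenness,

    clonality = 1 − H / ln R,   H = −Σ pᵢ ln pᵢ,

with pᵢ the molecule frequency of clone *i* and R the clone richness
(0 = perfectly even, 1 = monoclonal). Top-N proportion is the molecule
share of the N most expanded clonotypes (N = 100 for TRB, 25 per Vδ2
stratum for TRD).

**Longitudinal tracking.** Sample overlap is the proportion of follow-up
molecules whose nucleotide sequence was already detected in a seeded
10,000-molecule subsample of the baseline. Top-N overlap compares the top-N
clonotype sets of the two timepoints by sequence. TRD tracking is performed
separately for Vδ2+ (V gene TRDV2) and Vδ2− gamma-delta T cells.

**Downsampling designs.** Molecule-level (UMI-level) subsampling without
replacement, with two plans: a fixed cap (10,000 for control IGH, 100,000
for TRB) and a matched plan where each treated baseline is reduced to its
own follow-up depth (max 10,000).

**Reconstitution classification.** A follow-up B-cell repertoire with at
least 1,000 sequenced B cells (roughly 1 B cell/µL of blood via an OLS
calibration against flow cytometry) is called *reconstituted* (many
near-germline naive sequences, absent at baseline); below that it is
*residual* (few, heavily mutated, baseline-traceable sequences).

**Marker gating.** In single-cell count matrices, a cell is MS4A1 (CD20)
positive iff its raw transcript count is > 0; per-subset positive fractions,
a ≥ 1% retention rule, and RNA-vs-protein concordance rates
(P(protein+ | RNA−), P(protein+ | RNA+)) are reported.

**Synthetic cohorts.** A deterministic generator produces paired-timepoint
AIRR TSVs with Zipf clone-size laws, per-lineage SHM, CD20dim labels
enriched among expanded TRB clones, Vδ2 labels, the two B-cell follow-up
scenarios, and full ground-truth tables — so every analysis step can be
validated against known truth.

## Worked example

Simulate one anti-CD20 treated donor, then analyze the follow-up IGH
repertoire against baseline:

```python
from repdeplete import (
    ScenarioConfig, simulate_donor, assign_bcr_clonotypes, summarize_shm,
    sample_overlap, classify_reconstitution,
)

config = ScenarioConfig()                      # study-design defaults
donor = simulate_donor(config, donor_seed=42,  # one anti-CD20 treated donor
                       donor_id="OCR01", cohort="OCR", loci=("IGH",))
m00, m06 = donor.m00["IGH"], donor.m06["IGH"]

clones = assign_bcr_clonotypes(m06, threshold=0.15)
shm = summarize_shm(m06, clones)
overlap = sample_overlap(m06, m00, baseline_cap=10_000, seed=7)
call = classify_reconstitution(m06.total_molecules)

print(f"simulated scenario       : {donor.scenario}")
print(f"sequenced B cells at M06 : {m06.total_molecules}")
print(f"IGH lineages at M06      : {len(clones)}")
print(f"mean SHM per clonotype   : {shm.mean_shm_per_clonotype:.2f}")
print(f"overlap with baseline    : {overlap.overlap_fraction:.3f}")
print(f"classification           : {call}")
```

Output:

```
simulated scenario       : residual
sequenced B cells at M06 : 478
IGH lineages at M06      : 100
mean SHM per clonotype   : 19.34
overlap with baseline    : 0.962
classification           : residual
```

This donor drew the *residual* scenario: only 478 B cells were sequenced at
follow-up (below the 1,000-cell threshold), they carry ~19 mutations per
clonotype, and 96% of the follow-up molecules were already present at
baseline — surviving differentiated B cells, not bone-marrow output. A
*reconstituted* donor shows the mirror image (thousands of cells, SHM near
zero, overlap near zero).

The same analysis runs from the shell over whole cohorts:

```sh
repdeplete simulate --out cohort/ --seed 42
repdeplete run --manifest cohort/manifest.tsv --seed 42 --out results/
```

which writes `report.json`, `report.tsv` (per-sample and per-donor metrics,
reconstitution calls, paired Wilcoxon signed-rank comparisons per cohort)
and a structured `log.jsonl`.

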