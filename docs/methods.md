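# Methods

This note documents the statistical procedures `driverscape` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the procedures left genuine
freedom.

## Input model and initial filtering

All pipelines consume tab-separated tables in the dialects defined by
`io_filtering`: a MAF-like mutation table (one row per somatic SNA with
`Variant_Classification` and `FILTER` columns), a gene × sample matrix of
GISTIC-style thresholded CNA calls in {−2,−1,0,1,2}, a sample × arm call
table in {−1,0,1} with missing cells, gene × sample expression matrices, a
clinical patient table, sample-quality annotations and tumour-purity
estimates. Missing cells are empty strings on disk and NaN in memory —
never 0, which is a meaningful call everywhere.

Initial filters: only primary-tumour samples (TCGA sample type codes 01, 03,
09); samples flagged `Do_not_use` removed everywhere; samples with cancer
DNA fraction < 0.5 or unknown, or subclonal genome fraction > 0.5 or
unknown, removed *from the arm-call table only* (aneuploidy calls are the
most purity-sensitive data type; thresholds are strict inequalities, so an
exact 0.5 passes both); mutation rows without `FILTER == "PASS"` dropped,
with zero Entrez IDs repaired from Ensembl IDs where a mapping exists
(PASS filtering precedes ID repair; the order is observable only in the
repair log). Clinical records are kept when the ICD-O-3 histology ends in
"/3" (primary malignant neoplasm) and the patient appears in the mutation,
CNA and arm-call data simultaneously. Barcode joins between files of
different granularity use the shared prefix length of the two files; when
several samples of one patient survive filtering, the lexicographically
smallest barcode is kept.

## SNA driver genes (snadrif)

Variant classifications partition into four categories: *inactivating*
(Frame_Shift_Del/Ins, Nonsense, Nonstop, Translation_Start_Site),
*hyperactivating* (De_novo_Start_InFrame, In_Frame_Del/Ins, Missense),
*passenger* (Silent, De_novo_Start_OutOfFrame) and *unclear* (everything
else — UTRs, introns, flanks). Genes whose SNAs are exclusively unclear
(noncoding genes, in practice) are removed. Per gene, with pan-dataset sums
H, I, P:

    NSEI = (H + I + 1) / (P + 1),    HISR = (H + 1) / (I + 1).

The +1 pseudocounts make both indices defined at zero counts (both equal 1
for an unmutated gene). Genes with H + I + P < 10 are not tested — below
ten classifiable SNAs the indices are too grainy to rank (unclear counts do
not help and are excluded from the threshold).

The null distribution is built from the patient × gene matrix of
(H, I, U, P) quadruples, **zero-filled** so that unmutated pairs are real,
drawable cells. Each bootstrap iteration draws one cell per patient
uniformly with replacement from the entire matrix, sums the quadruples and
computes one null (NSEI, HISR) pair. This preserves the marginal count
distribution while destroying gene identity: the expected number of mutated
cells drawn per iteration equals the expected per-gene total, so observed
and null NSEI are on the same scale. A gene's p-value is the share of null
NSEI values *strictly greater* than its own (one-sided: the index is an
enrichment statistic and depletion is not a driver signal); ties at p = 0
are reported as 0 per the literal count ratio, a granularity limitation
acknowledged below. Benjamini–Hochberg step-up at FDR 5% (via
`statsmodels.multipletests(method="fdr_bh")`; an independent hand-written
step-up cross-checks it in the tests) yields the driver list; HISR > 5
labels a driver oncogene-like, HISR ≤ 5 suppressor-like.

A built-in diagnostic recomputes, for every bootstrap iteration, its
p-value against the whole null vector. For an all-distinct null these are
exactly the grid {0, 1/n, …, (n−1)/n}, so the maximal ECDF deviation from
uniform measures the probability mass lost to ties in the discrete null —
the relevant failure mode of a count-ratio statistic.

Parameters: `n_iter` (default 10000; the calibration tests run 2000, which
leaves p-value granularity of 5·10⁻⁴), `min_sna` (10), `q` (0.05), `seed`.
Per-cohort analysis is the same pipeline re-run on one cohort's rows.

## Expression validation of CNA calls (gecnav)

Thresholded CNA segments drag along many dosage-irrelevant genes. Each
gene's expression is encoded relative to its cross-patient median m:

    x < 0.05·m → −2;  0.05·m ≤ x < 0.75·m → −1;  0.75·m ≤ x ≤ 1.25·m → 0;
    1.25·m < x ≤ 1.75·m → 1;  x > 1.75·m → 2.

Boundary membership is chosen so the five bands partition the axis totally
and deterministically; a zero-median gene is degenerate and encodes to 0.
A nonzero CNA call whose sign matches a nonzero expression code is replaced
by that code (so a "+2" call with modestly elevated expression becomes
"+1" — magnitude is taken from the transcriptome); a discordant or neutral
code zeroes the call; genes absent from both expression matrices, and cells
without an expression value, pass through unchanged. Genes found in the
miRNA code matrix are routed there, otherwise to the mRNA matrix. Medians
are computed across all patients (pan-cancer), not per cohort.

The median-relative encoding assumes most samples are unaltered: once an
alteration reaches ~50% frequency the median itself moves and concordant
calls stop validating. This is inherent to the method, and the synthetic
tests plant CNAs below that frequency.

## Aneuploidy drivers (andrif)

Per cohort and arm, the observed statistic is the mean of the non-missing
calls. The null is bootstrap resampling of cohort-sized draws (with
replacement) from the pool of *all* non-missing cells of the whole table —
all arms, all cohorts — repeated `n_iter` times (default 10000). A signed
empirical p is assigned only to means beyond zero and beyond the null
median in the same direction; the tail count is divided by `n_iter/2`
(5000 at the default), which doubles the one-sided tail as a two-sided
correction; values can exceed 1 and are capped at 1 when entering the BH
step-up, run per cohort at FDR 5%. Survivors become DAG/DAL labels.

Whole-chromosome calls derive from arm calls by unanimity: both arms +1 →
+1, both −1 → −1, any arm missing → missing, else 0; the acrocentric
chromosomes 13, 14, 15, 21, 22 take their single arm's call verbatim. The
same average/bootstrap/BH machinery, with an independently derived RNG
stream, yields DCG/DCL labels. Per patient, a −1 call on a DAL/DCL unit or
a +1 call on a DAG/DCG unit is one event, and a chromosome event suppresses
both of that chromosome's arm events to prevent triple-counting.

Known limitation: the pooled null mixes two-arm chromosomes (whose
unanimity-derived calls are much rarer than arm calls) with single-arm
chromosomes (whose calls are exactly arm calls). Single-arm chromosomes are
therefore tested against an overly tight null and account for almost all
false chromosome labels on null data. The overall null labelling rate
stays below the 5% target in the calibration tests, but chromosome-level
calls for 13, 14, 15, 21, 22 deserve extra scepticism.

## Patient-level classification (paldric)

Cohort-level driver lists carry a level (gene or mutation) and scope
(pancancer or cohort). Gene-level lists match MAF rows by Entrez ID,
mutation-level lists by (transcript ID, substitution); rows must carry one
of the nine protein-affecting variant classifications, and cohort-scoped
entries only match patients of that cohort. CNA matching takes listed
genes with any nonzero thresholded call. Per source, SNA- and CNA-derived
(patient, gene) pairs are unioned; pairs found by fewer than
`min_sources` (default 2) sources are discarded.

Each pair is annotated with H, I (0 when the patient never had an SNA
there), the gene's HISR (missing when the gene was never tested) and the
expression-validated CNA status (0 when absent), then classified by the
rule table in the package docstring (`paldric`). The first rule column,
"number of nonsynonymous SNAs", is read as N = H + I, so a suppressor hit
only by truncating SNAs still classifies as an SNA-based suppressor, and
the oncogene rows' I = 0 constraint then implies H ≥ 1. A missing HISR
fails both HISR comparisons: such pairs are low-probability drivers when
any alteration is present and passengers otherwise. Exactly the six
oncogene/suppressor classes count one driver event each.

Patient tallies cover the six gene-level driver classes, passengers and
low-probability pairs (tracked but never counted), plus DCL/DCG/DAL/DAG
from the aneuploidy pipeline, merged by patient ID. Clinical patients
without any event appear with all-zero counts. Stage is normalised to
I–IV through the fallback chain pathologic_stage → clinical_stage →
pathologic_T → clinical_T, stripping sub-stage letters (IIIA → III,
T2b → II); a present but unmappable value (e.g. "Stage X") stops the chain
as missing. Ages bin into decades (<20, 20–29, …, ≥80). Aggregation
produces per-group mean counts per class (groups: gender, age bin, stage,
cohort, or each integer total of 1–100 events); histograms count patients
per integer total 0–100, clamping larger totals into the last bin. Group
comparisons use Welch's unequal-variance t-test with Welch–Satterthwaite
degrees of freedom (one- or two-tailed).

## Benchmarking

Sensitivity = 100·|prediction ∩ controls|/|controls|; specificity =
100·|universe \ controls \ prediction|/|universe \ controls|. The universe
must be supplied explicitly — the package uses the genes observed in the
filtered mutation table, making specificity a closed, reproducible
quantity. Overlap-of-k consensus keeps items predicted by ≥ k sources.

## Synthetic data: what it emulates, and what it does not

The generator produces all seven input tables plus truth tables (planted
driver genes per cohort; planted arm/chromosome events per cohort and per
patient). Defaults: four cohorts of 50 patients (200 total), 500 genes, 39
autosome arms, 20 miRNA genes.

Background mutations are planted directly at the `Variant_Classification`
level — the pipelines consume classifications, not sequences, so no codon
model is simulated. Each background (patient, gene) cell receives a
Poisson number of SNAs with mean `background_sna_rate` = 2.0, split
silent 0.50 / hyperactivating 0.35 / inactivating 0.10 / unclear 0.05 —
roughly the proportions random coding point mutations produce, with the
silent half calibrating neutral NSEI to ≈ 1. The rate itself is a
deliberate compression: the patient axis is shrunk ~50-fold relative to a
real pan-cancer atlas while the *per-gene pan-dataset totals* (~400 SNAs
per gene) — the marginals the NSEI statistic and its bootstrap null
consume — stay at atlas scale. At a per-patient-realistic rate the
500-gene panel would leave every gene under the min-10 filter and the
discrete null would collapse onto a handful of tie values, making
false-discovery and uniformity properties vacuous. The cost is that
per-patient mutation burdens are unrealistically high; any property that
depended on per-patient burden rather than per-gene totals would not
transfer, and no such property is asserted.

Planted oncogenes receive only missense SNAs (Bernoulli per patient),
suppressors only nonsense SNAs, each with a fixed substitution usable for
mutation-level matching; planted genes carry no background SNAs or CNA
noise, so planted counts are exactly interpretable. Planted CNAs are ±2
with per-patient probability; expression follows copy number for an
`expression_concordance` fraction of nonzero calls (factors 2.5 / 1.5 /
0.5 / 0.02 around a per-gene baseline, i.e. beyond the 1.75× and 0.05×
bands), neutral cells drift in U(0.9, 1.1) inside the neutral band. Arm
calls carry symmetric ±1 noise at 0.05 per direction, planted arm events
overwrite the call with the planted direction at the stated frequency,
chromosome events overwrite both arms jointly, and 1% of cells are blanked
to missing afterwards (so a planted per-patient truth row may rarely be
masked). Clinical, purity and quality tables include small planted
fractions of filter-relevant records (non-PASS rows, zeroed Entrez IDs,
low-purity samples, blacklisted aliquots, non-"/3" histologies) so the
filters always have work to do.

Not emulated: mutational signatures and hypermutator phenotypes, subclonal
structure, focal-vs-arm CNA geometry, linkage between neighbouring genes
on a segment, sex chromosomes, and survival endpoints. Passing tests
demonstrate correctness of the statistical machinery under the stated
null/planted conditions, not performance on real tumour data.

## Numerical and reproducibility choices

All randomness flows through `numpy.random.default_rng` seeded from a
single configuration seed; the arm- and chromosome-scope bootstraps use
distinct streams derived via `SeedSequence`. Identical seeds give
byte-identical output files. Bootstrap index draws are chunked to bound
memory at tens of megabytes regardless of `n_iter`. Degenerate inputs have
defined behaviour throughout: empty pools and empty matrices raise,
zero-median genes encode to 0, all-flagged quality tables empty the input
with a warning, empirical p-values of exactly 0 propagate (and always
survive BH — with 10000 iterations this is the procedure's stated
resolution limit). The calibration and recovery tests run 20 replicates at
2000 bootstrap iterations on the default 200 × 500 dataset; these sizes
are the package's test conditions and scale linearly if enlarged.
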