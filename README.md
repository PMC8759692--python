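# driverscape

Tools for predicting, classifying and counting **cancer driver events at the
level of individual patients** from TCGA-PanCanAtlas-style tables: somatic
point mutations (SNAs), GISTIC-thresholded copy-number alterations (CNAs) and
chromosome-arm aneuploidy calls.

Most driver-prediction methods stop at the cohort level ("gene X is a driver
in colorectal cancer"). `driverscape` closes the gap to the patient level: it
discovers driver genes and driver aneuploidies with simple transparent
statistics, validates copy-number calls against expression, translates any
mix of cohort-level driver lists (its own or third-party) into per-patient
events, classifies every (patient, gene) pair into oncogene/suppressor event
types, and aggregates event counts over gender, age, stage and cancer type.
A synthetic-data generator with planted ground truth makes every stage
testable offline.

## Pipelines

| Module | Role |
| --- | --- |
| `io_filtering` | TSV dialects, TCGA barcode handling, primary-sample / quality / purity / PASS / histology filters |
| `snadrif` | SNA driver genes from nonsynonymous/silent enrichment, oncogene vs suppressor classification |
| `gecnav` | expression-concordance validation of thresholded CNA calls |
| `andrif` | driver chromosome-arm and whole-chromosome gains/losses per cohort, per-patient aneuploidy events |
| `paldric` | cohort-level driver lists → per-patient classified events → clinical-group statistics |
| `benchmark` | sensitivity/specificity against positive-control lists, overlap-of-k consensus |
| `synthetic_data` | planted-truth dataset generator |

## The statistics at the core

For each gene, with `H` hyperactivating (missense, in-frame), `I`
inactivating (nonsense, frameshift, nonstop, start-site) and `P` passenger
(silent) SNAs summed over patients:

```
NSEI = (H + I + 1) / (P + 1)        nonsynonymous SNA enrichment index
HISR = (H + 1) / (I + 1)            hyperactivating / inactivating ratio
```

Genes under positive selection have NSEI above the silent background;
HISR > 5 marks oncogene-like genes, HISR ≤ 5 suppressor-like ones.
Significance comes from a bootstrap empirical null (resampling
patient × gene count quadruples from the zero-filled mutation matrix) with
Benjamini–Hochberg selection at FDR 5%. Aneuploidy drivers are found the
same way: observed per-cohort mean arm status versus a bootstrap null of
cohort-sized resamples from the pooled call table, signed empirical
p-values, BH per cohort, labels DAG/DAL (arm gain/loss) and DCG/DCL
(chromosome gain/loss). Each (patient, gene) candidate pair is then
classified by the joint pattern of (H, I, HISR, validated CNA) into
SNA/CNA/mixed oncogene or suppressor events, passengers, or low-probability
drivers; chromosome events override their arm events so a single
missegregation is never counted twice.

## Worked example

```python
from driverscape import TruthConfig, generate, run_snadrif, run_andrif
from driverscape import io_filtering as iof

cohorts = ["COAD", "BRCA", "LUAD", "UCEC"]
config = TruthConfig(
    seed=1,
    planted_oncogenes={c: [("ONCO1", 0.15, 0.0)] for c in cohorts},
    planted_suppressors={c: [("SUPP1", 0.15, 0.0)] for c in cohorts},
    planted_arm_events={"LUAD": [("3p", 1, 0.4)]},
)
ds = generate(config)                      # 200 patients, 500 genes, 39 arms
maf = iof.filter_maf(ds.maf, ds.id_map)    # PASS filter + Entrez repair

sna = run_snadrif(maf, n_iter=2000, seed=1)
print(sna.drivers[["Hugo_Symbol", "H", "I", "P", "NSEI", "HISR", "p_value"]]
      .round(3).to_string(index=False))

an = run_andrif(ds.arms, ds.cohort_of, n_iter=2000, seed=1)
print(sorted(an.arm_labels.items()))
```

prints

```
Hugo_Symbol  H  I  P  NSEI   HISR  p_value
      ONCO1 22  0  0  23.0 23.000      0.0
      SUPP1  0 35  0  36.0  0.028      0.0
[(('LUAD', '3p'), 'DAG')]
```

Both planted genes are recovered out of the 500 tested: the oncogene with 22
pure-missense carriers (NSEI 23, no silent SNAs) and HISR 23 > 5, the
suppressor with 35 truncating SNAs and HISR 0.03 ≤ 5; no background gene is
called. The planted 3p gain at 40% frequency in LUAD is the only arm driver.
Per-patient events then follow from `an.patient_events` and, for gene-level
events, from `paldric.classify` after matching driver lists to patients —
see `driverscape paldric --help`.

A command-line interface mirrors the library:

```
driverscape simulate --config config.yaml --outdir data/
driverscape snadrif --maf data/mutations.tsv --seed 1 --out out/snadrif/
driverscape andrif --arms data/arm_calls.tsv --clinical data/clinical.tsv \
    --seed 1 --out out/andrif/
driverscape gecnav --cna data/cna_thresholded.tsv --expr data/expression.tsv \
    --mirna data/mirna_expression.tsv --out out/cna_validated.tsv
```

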