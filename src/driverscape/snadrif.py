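"""SNA driver gene discovery (SNADRIF).

Driver genes are detected from the enrichment of nonsynonymous over silent
point mutations and classified by the balance of hyperactivating versus
inactivating ones.  For each gene, with H hyperactivating, I inactivating and
P passenger (silent) SNAs summed over patients:

    NSEI = (H + I + 1) / (P + 1)      nonsynonymous SNA enrichment index
    HISR = (H + 1) / (I + 1)          hyperactivating / inactivating ratio

Genes under positive selection accumulate nonsynonymous SNAs in excess of the
silent background, pushing NSEI above 1; HISR > 5 marks oncogene-like genes
(dominated by missense / in-frame changes), HISR <= 5 suppressor-like ones
(dominated by truncations).  Statistical significance comes from a bootstrap
empirical null: a patient × gene matrix of (H, I, U, P) count quadruples,
zero-filled for unmutated pairs, is resampled by drawing one cell per patient
per iteration from the whole matrix; the quadruple sums of each iteration
give one null (NSEI, HISR) pair.  Gene p-values are upper-tail ratios against
the null NSEI vector and enter a Benjamini-Hochberg step-up at FDR 5%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

HYPERACTIVATING = frozenset({
    "De_novo_Start_InFrame", "In_Frame_Del", "In_Frame_Ins", "Missense_Mutation",
})
INACTIVATING = frozenset({
    "Frame_Shift_Del", "Frame_Shift_Ins", "Nonsense_Mutation",
    "Nonstop_Mutation", "Translation_Start_Site",
})
PASSENGER = frozenset({"De_novo_Start_OutOfFrame", "Silent"})

CATEGORIES = ("hyperactivating", "inactivating", "unclear", "passenger")
COUNT_COLUMNS = ["H", "I", "U", "P"]

TALLY_COLUMNS = ["Tumor_Sample_Barcode", "Hugo_Symbol", "Entrez_Gene_Id"] + COUNT_COLUMNS


def classify_variant(variant_classification: str) -> str:
    """Map a Variant_Classification string to an SNA category.

    Categories: frameshifts, nonsense, nonstop and start-site changes are
    potentially inactivating; missense and in-frame changes potentially
    hyperactivating; silent changes passengers; everything else (UTRs,
    flanks, introns, RNA) unclear.
    """
    if variant_classification in INACTIVATING:
        return "inactivating"
    if variant_classification in HYPERACTIVATING:
        return "hyperactivating"
    if variant_classification in PASSENGER:
        return "passenger"
    return "unclear"


def tally(maf: pd.DataFrame) -> pd.DataFrame:
    """Per-(patient, gene) category counts; drops genes with only unclear SNAs.

    Input rows must already be PASS-filtered primary-tumour records.  Output
    has one row per (Tumor_Sample_Barcode, Entrez_Gene_Id) with columns
    H, I, U, P.  Genes whose pan-dataset totals contain nothing but
    unclear-category SNAs (typically noncoding genes) are removed entirely.
    """
    if maf.empty:
        return pd.DataFrame(columns=TALLY_COLUMNS)
    cat = maf["Variant_Classification"].map(classify_variant)
    key = ["Tumor_Sample_Barcode", "Hugo_Symbol", "Entrez_Gene_Id"]
    wide = (pd.crosstab(index=[maf[k] for k in key], columns=cat)
            .reindex(columns=CATEGORIES, fill_value=0)
            .rename(columns=dict(zip(CATEGORIES, COUNT_COLUMNS)))
            .reset_index())
    totals = wide.groupby("Entrez_Gene_Id")[COUNT_COLUMNS].sum()
    informative = totals.index[(totals[["H", "I", "P"]].sum(axis=1) > 0)]
    out = wide[wide["Entrez_Gene_Id"].isin(informative)].reset_index(drop=True)
    return out[TALLY_COLUMNS]


def score_gene(H, I, P):
    """(NSEI, HISR) from category counts; vectorised, pseudocount +1."""
    H = np.asarray(H, dtype=float)
    I = np.asarray(I, dtype=float)
    P = np.asarray(P, dtype=float)
    nsei = (H + I + 1.0) / (P + 1.0)
    hisr = (H + 1.0) / (I + 1.0)
    if nsei.ndim == 0:
        return float(nsei), float(hisr)
    return nsei, hisr


def gene_totals(patient_counts: pd.DataFrame) -> pd.DataFrame:
    """Pan-dataset H/I/U/P sums per gene, with NSEI and HISR columns."""
    totals = (patient_counts.groupby(["Hugo_Symbol", "Entrez_Gene_Id"])
              [COUNT_COLUMNS].sum().reset_index())
    nsei, hisr = score_gene(totals["H"], totals["I"], totals["P"])
    totals["NSEI"] = nsei
    totals["HISR"] = hisr
    return totals


def filter_low_count(genes: pd.DataFrame, min_sna: int = 10) -> pd.DataFrame:
    """Drop genes with fewer than ``min_sna`` classifiable SNAs (H+I+P).

    Unclear-category counts do not contribute to the threshold.
    """
    keep = genes[["H", "I", "P"]].sum(axis=1) >= min_sna
    return genes[keep].reset_index(drop=True)


def bootstrap_null(
    patient_counts: pd.DataFrame,
    n_iter: int = 10000,
    seed: int = 0,
    patients: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Null (NSEI, HISR) vectors from whole-matrix per-patient resampling.

    The conceptual matrix is patients × genes of count quadruples with
    "0.0.0.0" cells for unmutated pairs; those zero cells are drawable.  Each
    iteration draws one cell per patient uniformly with replacement from the
    entire matrix and sums the quadruples.  Returns ``n_iter`` NSEI and HISR
    values; bit-reproducible for a given seed.
    """
    if patient_counts.empty:
        raise ValueError("empty patient-gene count matrix")
    if patients is None:
        patients = sorted(patient_counts["Tumor_Sample_Barcode"].unique())
    n_patients = len(patients)
    n_genes = patient_counts["Entrez_Gene_Id"].nunique()
    n_cells = n_patients * n_genes

    nz = patient_counts[COUNT_COLUMNS].to_numpy(dtype=np.int64)
    nnz = nz.shape[0]
    # sentinel row `nnz` stands for every zero-filled cell
    lookup = np.vstack([nz, np.zeros((1, 4), dtype=np.int64)])

    rng = np.random.default_rng(seed)
    nsei = np.empty(n_iter)
    hisr = np.empty(n_iter)
    # chunked over iterations to bound memory at ~tens of MB
    chunk = max(1, int(2_000_000 / max(n_patients, 1)))
    for start in range(0, n_iter, chunk):
        size = min(chunk, n_iter - start)
        idx = rng.integers(0, n_cells, size=(size, n_patients))
        picked = lookup[np.where(idx < nnz, idx, nnz)]
        sums = picked.sum(axis=1, dtype=np.int64)  # (size, 4): H, I, U, P
        ns, hs = score_gene(sums[:, 0], sums[:, 1], sums[:, 3])
        nsei[start:start + size] = ns
        hisr[start:start + size] = hs
    return nsei, hisr


def gene_pvalue(nsei, null: np.ndarray):
    """Upper-tail empirical p: share of null NSEI values strictly greater."""
    null_sorted = np.sort(np.asarray(null, dtype=float))
    n = null_sorted.size
    nsei = np.asarray(nsei, dtype=float)
    p = (n - np.searchsorted(null_sorted, nsei, side="right")) / n
    if p.ndim == 0:
        return float(p)
    return p


def null_uniformity_check(null: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-iteration null p-values and their max ECDF deviation from uniform.

    Each iteration's p-value is the share of null NSEI values strictly
    greater than its own; for an all-distinct null these are exactly the
    grid {0, 1/n, ..., (n-1)/n} and the deviation is 1/n, so the statistic
    measures the mass lost to ties.
    """
    pvals = gene_pvalue(null, null)
    ks = stats.kstest(pvals, stats.uniform.cdf).statistic
    return pvals, float(ks)


def select_drivers(genes: pd.DataFrame, q: float = 0.05) -> pd.DataFrame:
    """BH step-up over gene p-values; passing genes keep NSEI, HISR, p.

    ``genes`` must carry a ``p_value`` column (see :func:`gene_pvalue`).
    """
    if genes.empty:
        return genes.copy()
    reject = multipletests(genes["p_value"].to_numpy(), alpha=q,
                           method="fdr_bh")[0]
    return genes[reject].reset_index(drop=True)


@dataclass
class SnadrifResult:
    """Outputs of one SNADRIF run."""

    patient_counts: pd.DataFrame   # per-(patient, gene) H/I/U/P
    gene_scores: pd.DataFrame      # tested genes with NSEI/HISR/p_value
    drivers: pd.DataFrame          # BH-passing subset
    null_nsei: np.ndarray
    null_hisr: np.ndarray


def run_snadrif(
    maf: pd.DataFrame,
    n_iter: int = 10000,
    seed: int = 0,
    q: float = 0.05,
    min_sna: int = 10,
) -> SnadrifResult:
    """Full pipeline: tally, score, bootstrap null, p-values, BH selection."""
    counts = tally(maf)
    if counts.empty:
        empty = pd.DataFrame(
            columns=["Hugo_Symbol", "Entrez_Gene_Id", *COUNT_COLUMNS,
                     "NSEI", "HISR", "p_value"])
        return SnadrifResult(counts, empty, empty.copy(),
                             np.empty(0), np.empty(0))
    genes = filter_low_count(gene_totals(counts), min_sna=min_sna)
    null_nsei, null_hisr = bootstrap_null(counts, n_iter=n_iter, seed=seed)
    genes = genes.assign(p_value=gene_pvalue(genes["NSEI"].to_numpy(), null_nsei))
    drivers = select_drivers(genes, q=q)
    return SnadrifResult(counts, genes, drivers, null_nsei, null_hisr)


def encode_quadruple(h: int, i: int, u: int, p: int) -> str:
    """Serialize a count quadruple in the dot-joined "H.I.U.P" form."""
    return f"{h}.{i}.{u}.{p}"


def decode_quadruple(s: str) -> tuple[int, int, int, int]:
    h, i, u, p = (int(x) for x in s.split("."))
    return h, i, u, p


_PATIENT_COUNT_HEADERS = {
    "H": "Number of hyperactivating SNAs",
    "I": "Number of inactivating SNAs",
    "U": "Number of SNAs with unclear role",
    "P": "Number of passenger SNAs",
}


def write_patient_counts(counts: pd.DataFrame, path) -> None:
    """Per-patient classification TSV with the published column names."""
    counts.rename(columns=_PATIENT_COUNT_HEADERS).to_csv(
        path, sep="\t", index=False)


def read_patient_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.rename(columns={v: k for k, v in _PATIENT_COUNT_HEADERS.items()})
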