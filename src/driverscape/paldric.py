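"""Patient-level driver classification and cohort statistics (PALDRIC).

Cohort-level driver gene/mutation lists (from any mix of algorithms) are
translated to per-patient candidate events, each (patient, gene) pair is
classified by the joint pattern of its SNA counts, gene HISR and validated
copy-number status, aneuploidy driver events are merged in, and patient-level
tallies are aggregated over clinical groups.

Classification rules (N = H + I nonsynonymous SNAs, HISR from the SNA driver
pipeline, CNA the expression-validated call):

    SNA-based oncogene          N>=1, I=0, HISR>5,  CNA=0
    CNA-based oncogene          N=0,        HISR>5,  CNA in {1,2}
    Mixed oncogene              N>=1, I=0, HISR>5,  CNA in {1,2}
    SNA-based tumour suppressor N>=1,       HISR<=5, CNA=0
    CNA-based tumour suppressor N=0,        HISR<=5, CNA in {-1,-2}
    Mixed tumour suppressor     N>=1,       HISR<=5, CNA in {-1,-2}
    Passenger                   N=0, CNA=0 (any HISR)
    Low-probability driver      everything else

Each of the six driver classes counts as exactly one driver event.  A pair
with no HISR (the gene never passed the SNA pipeline's count filter) fails
both HISR comparisons: with any alteration present it is a low-probability
driver, with none it is a passenger.
"""

from __future__ import annotations

import logging
import re
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_filtering import GeneSampleMatrix, patient_id

logger = logging.getLogger("driverscape")

MATCHABLE_CLASSIFICATIONS = frozenset({
    "De_novo_Start_InFrame", "Frame_Shift_Del", "Frame_Shift_Ins",
    "In_Frame_Del", "In_Frame_Ins", "Missense_Mutation", "Nonsense_Mutation",
    "Nonstop_Mutation", "Translation_Start_Site",
})

GENE_EVENT_CLASSES = (
    "SNA_oncogene", "CNA_oncogene", "mixed_oncogene",
    "SNA_suppressor", "CNA_suppressor", "mixed_suppressor",
    "passenger", "low_probability",
)
DRIVER_GENE_CLASSES = GENE_EVENT_CLASSES[:6]
ANEUPLOIDY_CLASSES = ("DCL", "DCG", "DAL", "DAG")
ALL_EVENT_CLASSES = GENE_EVENT_CLASSES + ANEUPLOIDY_CLASSES

PAIR_KEY = ["Tumor_Sample_Barcode", "Entrez_Gene_Id"]

_STAGE_RE = re.compile(r"^(?:STAGE\s+)?(IV|III|II|I)[ABC]?$")
_T_RE = re.compile(r"^T([1-4])[A-D]?$")
_T_TO_ROMAN = {"1": "I", "2": "II", "3": "III", "4": "IV"}


# ---------------------------------------------------------------------------
# Cohort-level list -> patient-level pairs
# ---------------------------------------------------------------------------

def _cohort_map(clinical: pd.DataFrame) -> dict[str, str]:
    return dict(zip(clinical["bcr_patient_barcode"].map(patient_id),
                    clinical["acronym"]))


def _cohort_gate(
    entries: pd.DataFrame, barcode_cohorts: pd.Series
) -> pd.Series:
    """True where the list entry's cohort matches or the list is pancancer."""
    pancancer = entries["scope"].eq("pancancer") | entries["cohort"].isna()
    return pancancer | entries["cohort"].eq(barcode_cohorts.to_numpy())


def match_gene_list(
    driver_list: pd.DataFrame, maf: pd.DataFrame, clinical: pd.DataFrame
) -> pd.DataFrame:
    """MAF rows hitting a listed gene, cohort-gated -> unique (barcode, gene).

    Rows must carry one of the nine protein-affecting variant
    classifications; rows from patients absent from the clinical table are
    skipped and logged.
    """
    if not (driver_list["level"] == "gene").all():
        raise ValueError("match_gene_list requires a gene-level driver list")
    cohorts = _cohort_map(clinical)
    sub = maf[maf["Variant_Classification"].isin(MATCHABLE_CLASSIFICATIONS)]
    sub = sub.merge(driver_list[["Entrez_Gene_Id", "scope", "cohort"]],
                    on="Entrez_Gene_Id")
    pat_cohort = sub["Tumor_Sample_Barcode"].map(lambda b: cohorts.get(patient_id(b)))
    n_unknown = int(pat_cohort.isna().sum())
    if n_unknown:
        logger.info("match_gene_list: %d rows from patients absent in the "
                    "clinical table skipped", n_unknown)
    keep = pat_cohort.notna() & _cohort_gate(sub, pat_cohort)
    return sub.loc[keep, PAIR_KEY].drop_duplicates().reset_index(drop=True)


def match_mutation_list(
    driver_list: pd.DataFrame, maf: pd.DataFrame, clinical: pd.DataFrame
) -> pd.DataFrame:
    """As :func:`match_gene_list` but joined on (transcript, substitution)."""
    if not (driver_list["level"] == "mutation").all():
        raise ValueError("match_mutation_list requires a mutation-level list")
    cohorts = _cohort_map(clinical)
    sub = maf[maf["Variant_Classification"].isin(MATCHABLE_CLASSIFICATIONS)]
    sub = sub.merge(
        driver_list[["Transcript_ID", "Substitution", "scope", "cohort"]],
        on=["Transcript_ID", "Substitution"])
    pat_cohort = sub["Tumor_Sample_Barcode"].map(lambda b: cohorts.get(patient_id(b)))
    keep = pat_cohort.notna() & _cohort_gate(sub, pat_cohort)
    return sub.loc[keep, PAIR_KEY].drop_duplicates().reset_index(drop=True)


def match_cna(
    driver_list: pd.DataFrame, cna: GeneSampleMatrix, clinical: pd.DataFrame
) -> pd.DataFrame:
    """Listed genes with a nonzero thresholded CNA call, cohort-gated."""
    cohorts = _cohort_map(clinical)
    listed = driver_list[driver_list["Entrez_Gene_Id"].isin(cna.entrez_ids)]
    if listed.empty:
        return pd.DataFrame(columns=PAIR_KEY)
    sub = cna.values.loc[listed["Entrez_Gene_Id"].unique()]
    long = (sub.stack().rename("cna").reset_index()
            .rename(columns={"level_1": "Tumor_Sample_Barcode"}))
    long = long[long["cna"].isin((-2.0, -1.0, 1.0, 2.0))]
    long = long.merge(listed[["Entrez_Gene_Id", "scope", "cohort"]],
                      on="Entrez_Gene_Id")
    pat_cohort = long["Tumor_Sample_Barcode"].map(lambda b: cohorts.get(patient_id(b)))
    keep = pat_cohort.notna() & _cohort_gate(long, pat_cohort)
    return long.loc[keep, PAIR_KEY].drop_duplicates().reset_index(drop=True)


def combine_source(sna_pairs: pd.DataFrame, cna_pairs: pd.DataFrame) -> pd.DataFrame:
    """Union of one source's SNA- and CNA-derived pairs, deduplicated."""
    both = pd.concat([sna_pairs[PAIR_KEY], cna_pairs[PAIR_KEY]], ignore_index=True)
    return both.drop_duplicates().reset_index(drop=True)


def consensus(
    pair_sets: Sequence[pd.DataFrame], min_sources: int = 2
) -> pd.DataFrame:
    """Pairs present in at least ``min_sources`` per-source sets.

    Output carries a ``source_count`` column.  Each source contributes at
    most one vote per pair.
    """
    if len(pair_sets) < min_sources:
        raise ValueError(
            f"need at least {min_sources} sources, got {len(pair_sets)}")
    votes = pd.concat(
        [s[PAIR_KEY].drop_duplicates() for s in pair_sets], ignore_index=True)
    counted = votes.groupby(PAIR_KEY).size().rename("source_count").reset_index()
    out = counted[counted["source_count"] >= min_sources]
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Annotation and Table-3 classification
# ---------------------------------------------------------------------------

def annotate(
    pairs: pd.DataFrame,
    sna_counts: pd.DataFrame,
    gene_scores: pd.DataFrame,
    validated_cna: GeneSampleMatrix | None,
) -> pd.DataFrame:
    """Attach H, I (0 if absent), HISR (NaN if absent) and CNA (0 if absent)."""
    out = pairs.copy()
    if sna_counts.empty:
        out[["H", "I"]] = 0
    else:
        out = out.merge(
            sna_counts[PAIR_KEY + ["H", "I"]], on=PAIR_KEY, how="left")
        out[["H", "I"]] = out[["H", "I"]].fillna(0).astype(int)
    hisr_map = (gene_scores.set_index("Entrez_Gene_Id")["HISR"]
                if not gene_scores.empty else pd.Series(dtype=float))
    out["HISR"] = out["Entrez_Gene_Id"].map(hisr_map)
    if validated_cna is None:
        out["cna"] = 0
    else:
        idx_g = validated_cna.values.index.get_indexer(out["Entrez_Gene_Id"])
        idx_s = validated_cna.values.columns.get_indexer(out["Tumor_Sample_Barcode"])
        vals = np.zeros(len(out))
        hit = (idx_g >= 0) & (idx_s >= 0)
        raw = validated_cna.values.to_numpy()[idx_g[hit], idx_s[hit]]
        vals[hit] = np.nan_to_num(raw)
        out["cna"] = vals.astype(int)
    return out


def classify(annotated: pd.DataFrame) -> pd.DataFrame:
    """Assign each annotated pair its event class and 0/1 event count.

    Vectorised over rows with columns H, I, HISR (NaN = missing), cna.  The
    rule table is total: exactly one class per combination.
    """
    H = annotated["H"].to_numpy(dtype=float)
    I = annotated["I"].to_numpy(dtype=float)
    hisr = annotated["HISR"].to_numpy(dtype=float)
    cna = annotated["cna"].to_numpy(dtype=float)

    N = H + I
    with np.errstate(invalid="ignore"):
        onc = hisr > 5          # NaN HISR fails both
        sup = hisr <= 5
    amp = (cna == 1) | (cna == 2)
    dele = (cna == -1) | (cna == -2)
    neutral = cna == 0

    conditions = [
        (N >= 1) & (I == 0) & onc & neutral,
        (N == 0) & onc & amp,
        (N >= 1) & (I == 0) & onc & amp,
        (N >= 1) & sup & neutral,
        (N == 0) & sup & dele,
        (N >= 1) & sup & dele,
        (N == 0) & neutral,
    ]
    labels = list(GENE_EVENT_CLASSES[:7])
    event_class = np.select(conditions, labels, default="low_probability")
    out = annotated.copy()
    out["event_class"] = event_class
    out["event_count"] = np.isin(event_class, DRIVER_GENE_CLASSES).astype(int)
    return out


def classify_pair(H: int, I: int, hisr: float | None, cna: int) -> tuple[str, int]:
    """Classify a single (patient, gene) pair; ``hisr=None`` means missing."""
    df = pd.DataFrame({"H": [H], "I": [I],
                       "HISR": [np.nan if hisr is None else hisr],
                       "cna": [cna]})
    row = classify(df).iloc[0]
    return str(row["event_class"]), int(row["event_count"])


# ---------------------------------------------------------------------------
# Patient-level counting, grouping, testing
# ---------------------------------------------------------------------------

def normalize_stage(
    pathologic_stage, clinical_stage, pathologic_T, clinical_T
) -> str | float:
    """Normalise tumour stage to I-IV with the published fallback chain.

    pathologic_stage, else clinical_stage, else pathologic_T, else
    clinical_T; sub-stage letters are stripped (IIIA -> III, T2b -> II);
    unmappable strings give missing.
    """
    for raw in (pathologic_stage, clinical_stage, pathologic_T, clinical_T):
        if raw is None or (isinstance(raw, float) and np.isnan(raw)):
            continue
        s = str(raw).strip().upper()
        if not s:
            continue
        m = _STAGE_RE.match(s)
        if m:
            return m.group(1)
        m = _T_RE.match(s)
        if m:
            return _T_TO_ROMAN[m.group(1)]
        return np.nan  # a value was present but not stage-like
    return np.nan


def count_events(
    classified_pairs: pd.DataFrame,
    aneuploidy_events: pd.DataFrame,
    clinical: pd.DataFrame,
) -> pd.DataFrame:
    """Per-patient tallies over the twelve event classes, zero-filled.

    Every patient in the (already filtered) clinical table appears, with
    all-zero counts if nothing was observed for them.  ``total`` sums the six
    gene-level driver classes and the four aneuploidy classes; passenger and
    low-probability pairs never contribute.
    """
    patients = clinical["bcr_patient_barcode"].map(patient_id)
    counts = pd.DataFrame(0, index=patients, columns=list(ALL_EVENT_CLASSES))

    if not classified_pairs.empty:
        by = (classified_pairs
              .assign(patient=classified_pairs["Tumor_Sample_Barcode"].map(patient_id))
              .groupby(["patient", "event_class"]).size().unstack(fill_value=0))
        by = by.reindex(index=counts.index, columns=GENE_EVENT_CLASSES,
                        fill_value=0).fillna(0).astype(int)
        counts[list(GENE_EVENT_CLASSES)] = by

    if not aneuploidy_events.empty:
        an = (aneuploidy_events
              .assign(patient=aneuploidy_events["Tumor_Sample_Barcode"].map(patient_id))
              .groupby(["patient", "label"]).size().unstack(fill_value=0))
        an = an.reindex(index=counts.index, columns=ANEUPLOIDY_CLASSES,
                        fill_value=0).fillna(0).astype(int)
        counts[list(ANEUPLOIDY_CLASSES)] = an

    counts["total"] = counts[list(DRIVER_GENE_CLASSES)].sum(axis=1) + \
        counts[list(ANEUPLOIDY_CLASSES)].sum(axis=1)

    meta = pd.DataFrame({
        "patient_id": patients.to_numpy(),
        "cohort": clinical["acronym"].to_numpy(),
        "gender": clinical["gender"].str.lower().to_numpy(),
        "age": clinical["age_at_initial_pathologic_diagnosis"].to_numpy(),
        "stage": [
            normalize_stage(ps, cs, pt, ct)
            for ps, cs, pt, ct in zip(
                clinical["pathologic_stage"], clinical["clinical_stage"],
                clinical["pathologic_T"], clinical["clinical_T"])
        ],
    })
    return pd.concat([meta.reset_index(drop=True),
                      counts.reset_index(drop=True)], axis=1)


def age_bin(age) -> str | float:
    """Decade bins: <20, 20-29, ..., 70-79, >=80."""
    if age is None or (isinstance(age, float) and np.isnan(age)):
        return np.nan
    age = int(age)
    if age < 20:
        return "<20"
    if age >= 80:
        return ">=80"
    lo = 10 * (age // 10)
    return f"{lo}-{lo + 9}"


GROUP_KEYS = ("gender", "age_bin", "stage", "cohort", "total_events")


def aggregate(counts: pd.DataFrame, group_by: str) -> pd.DataFrame:
    """Mean event counts per class within clinical groups.

    ``group_by`` is one of gender, age_bin, stage, cohort, total_events.
    Groups with no patients are omitted; total_events groups run over the
    integers 1..100.
    """
    if group_by not in GROUP_KEYS:
        raise ValueError(f"unknown grouping key {group_by!r}")
    df = counts.copy()
    if group_by == "age_bin":
        key = df["age"].map(age_bin)
    elif group_by == "total_events":
        key = df["total"].where((df["total"] >= 1) & (df["total"] <= 100))
    else:
        key = df[group_by]
    cols = list(ALL_EVENT_CLASSES) + ["total"]
    return df.groupby(key, dropna=True)[cols].mean()


def histogram(counts: pd.DataFrame, by_gender: bool = False) -> pd.DataFrame:
    """Patients per integer total driver-event count, bins 0..100.

    Totals above 100 are clamped into the 100 bin (logged).  With
    ``by_gender`` the columns split by gender and keep the marginal sum.
    """
    total = counts["total"].clip(upper=100)
    n_clamped = int((counts["total"] > 100).sum())
    if n_clamped:
        logger.info("histogram: %d patients clamped into the 100 bin", n_clamped)
    bins = pd.Index(range(101), name="total_events")
    if by_gender:
        out = {}
        for g, sub in total.groupby(counts["gender"]):
            out[g] = sub.value_counts().reindex(bins, fill_value=0)
        return pd.DataFrame(out)
    return total.value_counts().reindex(bins, fill_value=0).to_frame("patients")


def welch_t(group_a, group_b, tails: int = 2) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test with Welch-Satterthwaite df.

    ``tails`` 2 gives the usual two-sided p; 1 gives the one-sided p for the
    alternative mean(a) > mean(b).  Groups need >= 2 values each and nonzero
    variance in at least one group.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("both groups have zero variance")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    res = stats.ttest_ind(a, b, equal_var=False)
    t = float(res.statistic)
    df = float(res.df)
    p2 = float(res.pvalue)
    if tails == 2:
        return t, df, p2
    p1 = p2 / 2 if t > 0 else 1 - p2 / 2
    return t, df, p1
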