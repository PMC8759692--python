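"""Patient-level matching, Table-style event classification and aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from driverscape import paldric
from conftest import gene_matrix


def _clinical(patients, cohorts, **extra):
    n = len(patients)
    base = {
        "bcr_patient_barcode": patients,
        "acronym": cohorts,
        "gender": ["MALE"] * n,
        "age_at_initial_pathologic_diagnosis": [60] * n,
        "pathologic_stage": [np.nan] * n,
        "clinical_stage": [np.nan] * n,
        "pathologic_T": [np.nan] * n,
        "clinical_T": [np.nan] * n,
        "icd_o_3_histology": ["8140/3"] * n,
    }
    base.update(extra)
    return pd.DataFrame(base)


def _maf(rows):
    """rows: (barcode, entrez, vc) with fixed transcript/substitution."""
    return pd.DataFrame({
        "Tumor_Sample_Barcode": [r[0] for r in rows],
        "Hugo_Symbol": [f"G{r[1]}" for r in rows],
        "Entrez_Gene_Id": [r[1] for r in rows],
        "Gene": "ENSG0",
        "Transcript_ID": [r[3] if len(r) > 3 else "ENST1" for r in rows],
        "Substitution": [r[4] if len(r) > 4 else "p.A1V" for r in rows],
        "Variant_Classification": [r[2] for r in rows],
        "FILTER": "PASS",
    })


def _gene_list(entries, level="gene", scope="pancancer"):
    """entries: (entrez, cohort-or-None[, transcript, substitution])."""
    return pd.DataFrame({
        "source": "alg",
        "level": level,
        "scope": scope,
        "cohort": [e[1] for e in entries],
        "Hugo_Symbol": [f"G{e[0]}" for e in entries],
        "Entrez_Gene_Id": [e[0] for e in entries],
        "Transcript_ID": [e[2] if len(e) > 2 else np.nan for e in entries],
        "Substitution": [e[3] if len(e) > 3 else np.nan for e in entries],
        "q_value": 0.01,
    })


CLIN = _clinical(["TCGA-AA-0001", "TCGA-BB-0001"], ["COAD", "BRCA"])


# ---------------------------------------------------------------------------
# cohort-level list -> patient pairs
# ---------------------------------------------------------------------------

def test_gene_list_match_requires_protein_affecting_variant():
    maf = _maf([("TCGA-AA-0001-01A", 7, "Missense_Mutation"),
                ("TCGA-AA-0001-01A", 7, "Silent"),
                ("TCGA-AA-0001-01A", 8, "Missense_Mutation")])
    pairs = paldric.match_gene_list(
        _gene_list([(7, "COAD")], scope="cohort"), maf, CLIN)
    assert len(pairs) == 1
    assert pairs.iloc[0]["Entrez_Gene_Id"] == 7


def test_gene_list_cohort_gate_blocks_other_cohorts():
    maf = _maf([("TCGA-BB-0001-01A", 7, "Missense_Mutation")])
    pairs = paldric.match_gene_list(
        _gene_list([(7, "COAD")], scope="cohort"), maf, CLIN)
    assert pairs.empty
    # pancancer lists are not gated
    pairs = paldric.match_gene_list(
        _gene_list([(7, None)], scope="pancancer"), maf, CLIN)
    assert len(pairs) == 1


def test_patient_absent_from_clinical_is_skipped():
    maf = _maf([("TCGA-ZZ-0001-01A", 7, "Missense_Mutation")])
    pairs = paldric.match_gene_list(_gene_list([(7, None)]), maf, CLIN)
    assert pairs.empty


def test_mutation_list_matches_on_transcript_and_substitution():
    maf = _maf([("TCGA-AA-0001-01A", 7, "Missense_Mutation", "ENST1", "p.V600E"),
                ("TCGA-AA-0001-01A", 7, "Missense_Mutation", "ENST1", "p.G12D")])
    lst = _gene_list([(7, None, "ENST1", "p.V600E")], level="mutation")
    pairs = paldric.match_mutation_list(lst, maf, CLIN)
    assert len(pairs) == 1  # the other substitution of the same gene is not a hit


def test_empty_mutation_list_yields_no_pairs():
    maf = _maf([("TCGA-AA-0001-01A", 7, "Missense_Mutation")])
    pairs = paldric.match_mutation_list(
        _gene_list([], level="mutation"), maf, CLIN)
    assert pairs.empty


def test_cna_match_requires_listed_gene_and_nonzero_call():
    cna = gene_matrix([[2, 0], [2, 2]], entrez=[7, 8],
                      samples=["TCGA-AA-0001-01A", "TCGA-BB-0001-01A"])
    pairs = paldric.match_cna(_gene_list([(7, None)]), cna, CLIN)
    assert len(pairs) == 1  # gene 8 unlisted; gene 7 zero in the second patient
    assert pairs.iloc[0]["Tumor_Sample_Barcode"] == "TCGA-AA-0001-01A"


def test_combine_source_deduplicates_pairs():
    a = pd.DataFrame({"Tumor_Sample_Barcode": ["s1", "s2"],
                      "Entrez_Gene_Id": [7, 7]})
    b = pd.DataFrame({"Tumor_Sample_Barcode": ["s1", "s3"],
                      "Entrez_Gene_Id": [7, 9]})
    out = paldric.combine_source(a, b)
    assert len(out) == 3


@pytest.mark.parametrize("min_sources, expected", [(1, 2), (2, 1), (3, 0)])
def test_consensus_thresholds(min_sources, expected):
    shared = pd.DataFrame({"Tumor_Sample_Barcode": ["s1"], "Entrez_Gene_Id": [7]})
    only_a = pd.DataFrame({"Tumor_Sample_Barcode": ["s2"], "Entrez_Gene_Id": [7]})
    sets = [pd.concat([shared, only_a]), shared.copy(), shared.iloc[:0]]
    out = paldric.consensus(sets, min_sources=min_sources)
    assert len(out) == expected
    if expected:
        assert out.iloc[0]["source_count"] == 2


def test_consensus_needs_enough_sources():
    with pytest.raises(ValueError):
        paldric.consensus([pd.DataFrame(columns=paldric.PAIR_KEY)], min_sources=2)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def test_annotation_defaults_for_unmatched_pairs():
    pairs = pd.DataFrame({"Tumor_Sample_Barcode": ["TCGA-AA-0001-01A"],
                          "Entrez_Gene_Id": [7]})
    counts = pd.DataFrame(columns=["Tumor_Sample_Barcode", "Entrez_Gene_Id",
                                   "H", "I"])
    scores = pd.DataFrame(columns=["Entrez_Gene_Id", "HISR"])
    out = paldric.annotate(pairs, counts, scores, None)
    row = out.iloc[0]
    assert row["H"] == 0 and row["I"] == 0      # zeros written on no match
    assert np.isnan(row["HISR"])                # empty cell left
    assert row["cna"] == 0


def test_annotation_copies_matching_records_through():
    pairs = pd.DataFrame({"Tumor_Sample_Barcode": ["TCGA-AA-0001-01A"],
                          "Entrez_Gene_Id": [7]})
    counts = pd.DataFrame({"Tumor_Sample_Barcode": ["TCGA-AA-0001-01A"],
                           "Entrez_Gene_Id": [7], "H": [2], "I": [1]})
    scores = pd.DataFrame({"Entrez_Gene_Id": [7], "HISR": [8.0]})
    validated = gene_matrix([[2]], entrez=[7], samples=["TCGA-AA-0001-01A"])
    row = paldric.annotate(pairs, counts, scores, validated).iloc[0]
    assert (row["H"], row["I"], row["HISR"], row["cna"]) == (2, 1, 8.0, 2)


# ---------------------------------------------------------------------------
# event classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("H, I, hisr, cna, cls, count", [
    (1, 0, 8.0, 0, "SNA_oncogene", 1),
    (0, 0, 8.0, 2, "CNA_oncogene", 1),
    (0, 0, 8.0, 1, "CNA_oncogene", 1),
    (2, 0, 8.0, 1, "mixed_oncogene", 1),
    (1, 0, 3.0, 0, "SNA_suppressor", 1),
    (0, 1, 3.0, 0, "SNA_suppressor", 1),     # truncating-only SNA suppressor
    (0, 0, 3.0, -1, "CNA_suppressor", 1),
    (0, 0, 3.0, -2, "CNA_suppressor", 1),
    (0, 1, 3.0, -2, "mixed_suppressor", 1),
    (0, 0, 2.0, 0, "passenger", 0),
    (0, 0, 8.0, 0, "passenger", 0),          # any HISR with no alteration
    (1, 1, 8.0, 0, "low_probability", 0),    # I>0 blocks the oncogene rows
    (1, 0, 3.0, 2, "low_probability", 0),    # suppressor-like but amplified
    (0, 0, 8.0, -2, "low_probability", 0),   # oncogene-like but deleted
    (1, 0, None, 0, "low_probability", 0),   # missing HISR with an alteration
    (0, 0, None, 0, "passenger", 0),         # missing HISR without one
])
def test_event_classification_rules(H, I, hisr, cna, cls, count):
    assert paldric.classify_pair(H, I, hisr, cna) == (cls, count)


def test_classification_is_total_and_matches_independent_rules():
    """Exhaustive enumeration against an independently written rule oracle."""

    def oracle(H, I, hisr, cna):
        N = H + I
        onc = hisr is not None and hisr > 5
        sup = hisr is not None and hisr <= 5
        if N >= 1 and I == 0 and onc and cna == 0:
            return "SNA_oncogene", 1
        if N == 0 and onc and cna in (1, 2):
            return "CNA_oncogene", 1
        if N >= 1 and I == 0 and onc and cna in (1, 2):
            return "mixed_oncogene", 1
        if N >= 1 and sup and cna == 0:
            return "SNA_suppressor", 1
        if N == 0 and sup and cna in (-1, -2):
            return "CNA_suppressor", 1
        if N >= 1 and sup and cna in (-1, -2):
            return "mixed_suppressor", 1
        if N == 0 and cna == 0:
            return "passenger", 0
        return "low_probability", 0

    for H in range(4):
        for I in range(4):
            for hisr in (None, 1.0, 5.0, 5.01, 10.0):
                for cna in range(-2, 3):
                    got = paldric.classify_pair(H, I, hisr, cna)
                    assert got == oracle(H, I, hisr, cna), (H, I, hisr, cna)


# ---------------------------------------------------------------------------
# patient-level counting and aggregation
# ---------------------------------------------------------------------------

def _classified(rows):
    return pd.DataFrame(rows, columns=["Tumor_Sample_Barcode", "Entrez_Gene_Id",
                                       "event_class", "event_count"])


def test_count_events_totals_and_zero_fill():
    clin = _clinical(["TCGA-AA-0001", "TCGA-BB-0001"], ["COAD", "BRCA"])
    classified = _classified([
        ("TCGA-AA-0001-01A", 7, "SNA_oncogene", 1),
        ("TCGA-AA-0001-01A", 8, "passenger", 0),
    ])
    aneuploidy = pd.DataFrame({
        "Tumor_Sample_Barcode": ["TCGA-AA-0001-01A"] * 2,
        "unit": ["3p", "5q"], "label": ["DAL", "DAL"]})
    out = paldric.count_events(classified, aneuploidy, clin).set_index("patient_id")
    assert out.loc["TCGA-AA-0001", "total"] == 3      # 1 SNA + 2 DAL
    assert out.loc["TCGA-AA-0001", "passenger"] == 1  # tracked but not counted
    assert out.loc["TCGA-BB-0001", "total"] == 0      # zero-filled patient


@pytest.mark.parametrize("ps, cs, pt, ct, expected", [
    ("Stage IIA", None, None, None, "II"),
    (None, "Stage IV", None, None, "IV"),
    (None, None, "T2b", None, "II"),
    (None, None, None, "T4", "IV"),
    ("Stage X", "Stage I", None, None, None),  # unmappable value halts the chain
    (None, None, None, None, None),
])
def test_stage_normalization_fallback_chain(ps, cs, pt, ct, expected):
    got = paldric.normalize_stage(ps, cs, pt, ct)
    if expected is None:
        assert got is np.nan or (isinstance(got, float) and np.isnan(got))
    else:
        assert got == expected


def test_aggregate_means_by_cohort():
    clin = _clinical(["TCGA-AA-0001", "TCGA-AA-0002"], ["COAD", "COAD"])
    classified = _classified([
        ("TCGA-AA-0001-01A", 7, "SNA_oncogene", 1),
        ("TCGA-AA-0001-01A", 8, "SNA_oncogene", 1),
        ("TCGA-AA-0002-01A", 7, "SNA_suppressor", 1),
    ])
    counts = paldric.count_events(
        classified, pd.DataFrame(columns=["Tumor_Sample_Barcode", "unit", "label"]),
        clin)
    agg = paldric.aggregate(counts, "cohort")
    assert agg.loc["COAD", "total"] == pytest.approx(1.5)
    assert agg.loc["COAD", "SNA_oncogene"] == pytest.approx(1.0)


def test_aggregate_by_total_events_constructed_group():
    clin = _clinical(["TCGA-AA-0001", "TCGA-AA-0002"], ["COAD", "COAD"])
    classified = _classified([
        ("TCGA-AA-0001-01A", 7, "SNA_oncogene", 1),
        ("TCGA-AA-0002-01A", 7, "SNA_oncogene", 1),
    ])
    counts = paldric.count_events(
        classified, pd.DataFrame(columns=["Tumor_Sample_Barcode", "unit", "label"]),
        clin)
    agg = paldric.aggregate(counts, "total_events")
    assert agg.loc[1, "SNA_oncogene"] == pytest.approx(1.0)
    assert len(agg) == 1  # empty groups omitted


def test_aggregate_unknown_key_rejected():
    with pytest.raises(ValueError):
        paldric.aggregate(pd.DataFrame(), "zodiac_sign")


def test_age_binning_decades():
    assert paldric.age_bin(15) == "<20"
    assert paldric.age_bin(42) == "40-49"
    assert paldric.age_bin(85) == ">=80"


def test_histogram_binning_and_gender_marginals():
    clin = _clinical(
        ["TCGA-AA-0001", "TCGA-AA-0002", "TCGA-AA-0003"],
        ["COAD"] * 3, gender=["MALE", "FEMALE", "MALE"])
    classified = _classified(
        [("TCGA-AA-0001-01A", 7, "SNA_oncogene", 1),
         ("TCGA-AA-0002-01A", 7, "SNA_oncogene", 1)]
        + [(f"TCGA-AA-0003-01A", g, "SNA_oncogene", 1) for g in range(10, 17)])
    counts = paldric.count_events(
        classified, pd.DataFrame(columns=["Tumor_Sample_Barcode", "unit", "label"]),
        clin)
    hist = paldric.histogram(counts)
    assert hist.loc[1, "patients"] == 2 and hist.loc[7, "patients"] == 1
    assert hist["patients"].sum() == len(clin)
    by_gender = paldric.histogram(counts, by_gender=True)
    assert by_gender.sum().sum() == hist["patients"].sum()


def test_histogram_all_zero_is_a_spike_at_zero():
    clin = _clinical(["TCGA-AA-0001"], ["COAD"])
    counts = paldric.count_events(
        _classified([]), pd.DataFrame(columns=["Tumor_Sample_Barcode", "unit", "label"]),
        clin)
    hist = paldric.histogram(counts)
    assert hist.loc[0, "patients"] == 1 and hist["patients"].sum() == 1


# ---------------------------------------------------------------------------
# Welch's t-test
# ---------------------------------------------------------------------------

def test_welch_identical_groups_gives_p_one():
    t, df, p = paldric.welch_t([1, 2, 3], [1, 2, 3])
    assert t == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_welch_strong_difference_hand_computed():
    # var_a=0, var_b=0.0025: t = -10.025 / sqrt(0.0025/4) = -401
    t, df, p = paldric.welch_t([0, 0, 0, 0], [10, 10, 10, 10.1])
    assert t == pytest.approx(-401, rel=1e-6)
    assert p < 0.01


def test_one_tailed_p_is_half_of_two_tailed_when_t_positive():
    a, b = [5.0, 6.0, 7.0], [1.0, 2.0, 3.5]
    t2, _, p2 = paldric.welch_t(a, b, tails=2)
    t1, _, p1 = paldric.welch_t(a, b, tails=1)
    assert t1 == t2 and t2 > 0
    assert p1 == pytest.approx(p2 / 2)


def test_welch_agrees_with_reference_implementation():
    rng = np.random.default_rng(4)
    a, b = rng.normal(0, 1, 20), rng.normal(0.5, 2, 15)
    t, df, p = paldric.welch_t(a, b)
    ref = stats.ttest_ind(a, b, equal_var=False)
    assert t == pytest.approx(ref.statistic) and p == pytest.approx(ref.pvalue)


@pytest.mark.parametrize("a, b", [([1], [1, 2, 3]), ([2, 2], [3, 3])])
def test_welch_degenerate_groups_rejected(a, b):
    with pytest.raises(ValueError):
        paldric.welch_t(a, b)


# ---------------------------------------------------------------------------
# end-to-end: planted amplification becomes exactly one oncogene event
# ---------------------------------------------------------------------------

def test_planted_amplifications_yield_one_oncogene_event_each(planted_dataset):
    from driverscape import gecnav, snadrif
    from driverscape import io_filtering as iof

    ds = planted_dataset
    maf = iof.filter_maf(ds.maf, ds.id_map)
    sna = snadrif.run_snadrif(maf, n_iter=500, seed=5)
    codes = gecnav.encode_matrix(ds.expression)
    validated = gecnav.validate_cna(ds.cna, codes)
    clin = iof.filter_clinical(
        ds.clinical, maf["Tumor_Sample_Barcode"], ds.cna.sample_barcodes,
        ds.arms.sample_barcodes)

    onco = ds.truth_genes.query("role == 'oncogene'").iloc[0]
    lists = [_gene_list([(int(onco["Entrez_Gene_Id"]), None)]) for _ in range(2)]
    per_source = [
        paldric.combine_source(
            paldric.match_gene_list(lst, maf, clin),
            paldric.match_cna(lst, ds.cna, clin))
        for lst in lists
    ]
    pairs = paldric.consensus(per_source, min_sources=2)
    classified = paldric.classify(paldric.annotate(
        pairs, sna.patient_counts, sna.gene_scores, validated))

    clin_patients = set(clin["bcr_patient_barcode"])
    amped = [
        b for b in ds.cna.sample_barcodes
        if ds.cna.values.at[int(onco["Entrez_Gene_Id"]), b] == 2
        and iof.patient_id(b) in clin_patients
    ]
    assert len(amped) > 10
    sub = classified.set_index("Tumor_Sample_Barcode").loc[amped]
    assert set(sub["event_class"]) <= {"CNA_oncogene", "mixed_oncogene"}
    assert (sub["event_count"] == 1).all()
    assert not sub.index.has_duplicates
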