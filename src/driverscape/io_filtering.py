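"""Readers, writers and initial filters for TCGA-PanCanAtlas-dialect tables.

All tables are tab-separated UTF-8 text with a header row.  Missing cells are
written as empty strings and held internally as NaN — never as 0, since 0 is a
meaningful call in every matrix this package touches.

Sample identity follows the TCGA barcode convention: dash-separated tokens,
the first three identifying the patient (``TCGA-AB-0001``) and the first two
characters of the fourth token giving the sample type code (``01`` = primary
solid tumour, ``03`` = primary blood-derived, ``09`` = primary bone marrow).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("driverscape")

# Sample type codes counted as primary tumours.
PRIMARY_SAMPLE_CODES = frozenset({"01", "03", "09"})

MAF_COLUMNS = [
    "Tumor_Sample_Barcode",
    "Hugo_Symbol",
    "Entrez_Gene_Id",
    "Gene",
    "Transcript_ID",
    "Substitution",
    "Variant_Classification",
    "FILTER",
]

CLINICAL_COLUMNS = [
    "bcr_patient_barcode",
    "acronym",
    "gender",
    "age_at_initial_pathologic_diagnosis",
    "pathologic_stage",
    "clinical_stage",
    "pathologic_T",
    "clinical_T",
    "icd_o_3_histology",
]

PURITY_COLUMNS = ["Sample", "Cancer DNA fraction", "Subclonal genome fraction"]
QUALITY_COLUMNS = ["aliquot_barcode", "Do_not_use"]

DRIVER_LIST_COLUMNS = [
    "source",
    "level",
    "scope",
    "cohort",
    "Hugo_Symbol",
    "Entrez_Gene_Id",
    "Transcript_ID",
    "Substitution",
    "q_value",
]


# ---------------------------------------------------------------------------
# Barcodes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleBarcode:
    """A parsed TCGA sample barcode."""

    full_barcode: str
    patient_id: str
    sample_type_code: str

    @classmethod
    def parse(cls, barcode: str) -> "SampleBarcode":
        tokens = barcode.split("-")
        if len(tokens) < 4 or len(tokens[3]) < 2:
            raise ValueError(f"malformed TCGA barcode: {barcode!r}")
        return cls(
            full_barcode=barcode,
            patient_id="-".join(tokens[:3]),
            sample_type_code=tokens[3][:2],
        )


def patient_id(barcode: str) -> str:
    """Patient identifier: the first three dash-separated barcode tokens."""
    return "-".join(barcode.split("-")[:3])


def sample_type_code(barcode: str) -> str:
    tokens = barcode.split("-")
    if len(tokens) < 4 or len(tokens[3]) < 2:
        raise ValueError(f"malformed TCGA barcode: {barcode!r}")
    return tokens[3][:2]


def filter_primary_samples(barcodes: Sequence[str]) -> list[str]:
    """Keep barcodes of primary tumours (sample type codes 01, 03, 09).

    Order is preserved.  A barcode with fewer than four tokens raises
    ``ValueError`` naming its position.
    """
    kept = []
    for i, bc in enumerate(barcodes):
        try:
            code = sample_type_code(bc)
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from None
        if code in PRIMARY_SAMPLE_CODES:
            kept.append(bc)
    return kept


def primary_mask(barcodes: Iterable[str]) -> np.ndarray:
    """Boolean mask over barcodes selecting primary tumour samples."""
    return np.array([sample_type_code(b) in PRIMARY_SAMPLE_CODES for b in barcodes])


def _shared_prefix_length(a: Iterable[str], b: Iterable[str]) -> int:
    """Join length for two barcode collections of possibly different depth.

    TCGA files record barcodes at different granularity (patient, sample,
    aliquot).  Two files are joined on the shorter of their two typical
    barcode lengths.
    """
    la = min((len(x) for x in a), default=0)
    lb = min((len(x) for x in b), default=0)
    if la == 0 or lb == 0:
        return max(la, lb)
    return min(la, lb)


# ---------------------------------------------------------------------------
# Matrix containers
# ---------------------------------------------------------------------------

@dataclass
class GeneSampleMatrix:
    """A genes × samples matrix with Hugo/Entrez row labels.

    ``values`` is a DataFrame indexed by Entrez Gene ID (int) with sample
    barcodes as columns; ``hugo`` maps Entrez ID -> Hugo symbol.  Missing
    cells are NaN.
    """

    values: pd.DataFrame
    hugo: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate Entrez gene IDs in matrix rows")
        self.hugo = self.hugo.reindex(self.values.index)

    @property
    def entrez_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_barcodes(self) -> list[str]:
        return list(self.values.columns)

    def select_samples(self, barcodes: Sequence[str]) -> "GeneSampleMatrix":
        keep = [c for c in self.values.columns if c in set(barcodes)]
        return GeneSampleMatrix(self.values[keep], self.hugo)


@dataclass
class ArmCallTable:
    """Samples × chromosome-arm calls in {-1, 0, 1}; NaN = missing."""

    calls: pd.DataFrame  # index = sample barcode, columns = arm names

    def __post_init__(self) -> None:
        vals = self.calls.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (-1.0, 0.0, 1.0))
        if not ok.all():
            bad = np.unique(vals[~ok])
            raise ValueError(f"arm calls outside {{-1,0,1,missing}}: {bad}")

    @property
    def sample_barcodes(self) -> list[str]:
        return list(self.calls.index)

    @property
    def arm_names(self) -> list[str]:
        return list(self.calls.columns)

    def select_samples(self, barcodes: Sequence[str]) -> "ArmCallTable":
        keep = [b for b in self.calls.index if b in set(barcodes)]
        return ArmCallTable(self.calls.loc[keep])


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                       na_values=[""], **kwargs)


def read_maf(path) -> pd.DataFrame:
    """Read a mutation table (mc3 dialect).  One row per somatic SNA."""
    df = _read_tsv(path)
    missing = [c for c in MAF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"MAF file {path} lacks columns {missing}")
    df["Entrez_Gene_Id"] = df["Entrez_Gene_Id"].astype(int)
    return df[MAF_COLUMNS]


def write_maf(df: pd.DataFrame, path) -> None:
    df[MAF_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="")


def read_gene_matrix(path, dtype=float) -> GeneSampleMatrix:
    df = pd.read_csv(path, sep="\t")
    df["Entrez_Gene_Id"] = df["Entrez_Gene_Id"].astype(int)
    hugo = df.set_index("Entrez_Gene_Id")["Hugo_Symbol"]
    values = df.drop(columns=["Hugo_Symbol"]).set_index("Entrez_Gene_Id")
    return GeneSampleMatrix(values.astype(dtype), hugo)


def write_gene_matrix(matrix: GeneSampleMatrix, path, float_format=None) -> None:
    out = matrix.values.copy()
    out.insert(0, "Hugo_Symbol", matrix.hugo)
    out.index.name = "Entrez_Gene_Id"
    out.reset_index().to_csv(
        path, sep="\t", index=False, na_rep="", float_format=float_format,
        columns=["Hugo_Symbol", "Entrez_Gene_Id"] + matrix.sample_barcodes,
    )


def read_arm_calls(path) -> ArmCallTable:
    df = pd.read_csv(path, sep="\t").set_index("Sample")
    return ArmCallTable(df.astype(float))


def write_arm_calls(table: ArmCallTable, path) -> None:
    out = table.calls.copy()
    out.index.name = "Sample"
    # calls are integral; render without a trailing .0
    out = out.astype("Int64")
    out.reset_index().to_csv(path, sep="\t", index=False, na_rep="")


def read_clinical(path) -> pd.DataFrame:
    df = _read_tsv(path)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical file {path} lacks columns {missing}")
    df["age_at_initial_pathologic_diagnosis"] = pd.to_numeric(
        df["age_at_initial_pathologic_diagnosis"], errors="coerce")
    return df[CLINICAL_COLUMNS]


def write_clinical(df: pd.DataFrame, path) -> None:
    out = df[CLINICAL_COLUMNS].copy()
    out["age_at_initial_pathologic_diagnosis"] = (
        out["age_at_initial_pathologic_diagnosis"].astype("Int64"))
    out.to_csv(path, sep="\t", index=False, na_rep="")


def read_purity(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df[PURITY_COLUMNS]


def write_purity(df: pd.DataFrame, path) -> None:
    df[PURITY_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="")


def read_quality(path) -> pd.DataFrame:
    df = _read_tsv(path)
    df["Do_not_use"] = df["Do_not_use"].str.lower().eq("true")
    return df[QUALITY_COLUMNS]


def write_quality(df: pd.DataFrame, path) -> None:
    out = df[QUALITY_COLUMNS].copy()
    out["Do_not_use"] = np.where(out["Do_not_use"], "True", "False")
    out.to_csv(path, sep="\t", index=False, na_rep="")


def read_driver_list(path) -> pd.DataFrame:
    df = _read_tsv(path)
    missing = [c for c in DRIVER_LIST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"driver list {path} lacks columns {missing}")
    df["Entrez_Gene_Id"] = df["Entrez_Gene_Id"].astype(int)
    df["q_value"] = pd.to_numeric(df["q_value"], errors="coerce")
    return df[DRIVER_LIST_COLUMNS]


def write_driver_list(df: pd.DataFrame, path) -> None:
    df[DRIVER_LIST_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def apply_quality_blacklist(table, annotations: pd.DataFrame):
    """Drop samples flagged ``Do_not_use`` in the quality-annotation table.

    ``table`` may be a MAF DataFrame, a GeneSampleMatrix or an ArmCallTable.
    Samples without an annotation are kept.  Barcodes are joined on the
    shared prefix length of the two files.
    """
    flagged_full = annotations.loc[annotations["Do_not_use"], "aliquot_barcode"]

    def _kept(barcodes: Sequence[str]) -> list[str]:
        n = _shared_prefix_length(barcodes, annotations["aliquot_barcode"])
        flagged = {b[:n] for b in flagged_full}
        kept = [b for b in barcodes if b[:n] not in flagged]
        if barcodes and not kept:
            logger.warning("quality blacklist removed every sample")
        return kept

    if isinstance(table, GeneSampleMatrix):
        return table.select_samples(_kept(table.sample_barcodes))
    if isinstance(table, ArmCallTable):
        return table.select_samples(_kept(table.sample_barcodes))
    # MAF-like long table
    barcodes = table["Tumor_Sample_Barcode"]
    keep = set(_kept(list(barcodes.unique())))
    return table[barcodes.isin(keep)].reset_index(drop=True)


def apply_purity_filter(arm_table: ArmCallTable, purity: pd.DataFrame) -> ArmCallTable:
    """Drop low-purity / subclonal samples from the arm-call table only.

    Removed: cancer DNA fraction < 0.5 or unknown, or subclonal genome
    fraction > 0.5 or unknown.  Thresholds are strict, so exactly 0.5 passes
    both.  Samples without a purity record are removed (fraction unknown).
    """
    n = _shared_prefix_length(arm_table.sample_barcodes, purity["Sample"])
    cdf = pd.to_numeric(purity[PURITY_COLUMNS[1]], errors="coerce")
    sgf = pd.to_numeric(purity[PURITY_COLUMNS[2]], errors="coerce")
    ok = (cdf >= 0.5) & (sgf <= 0.5)  # NaN fails both, i.e. "unknown" removed
    good = {b[:n] for b in purity.loc[ok, "Sample"]}
    kept = [b for b in arm_table.sample_barcodes if b[:n] in good]
    return arm_table.select_samples(kept)


def filter_maf(maf: pd.DataFrame, id_map: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Keep PASS variants and repair zero Entrez IDs from Ensembl gene IDs.

    ``id_map`` maps Ensembl gene ID -> Entrez ID and may be partial;
    unmappable zero-ID rows are retained with Entrez 0 and counted in a log
    summary.
    """
    out = maf[maf["FILTER"] == "PASS"].copy().reset_index(drop=True)
    zero = out["Entrez_Gene_Id"] == 0
    if id_map and zero.any():
        repaired = out.loc[zero, "Gene"].map(id_map)
        out.loc[zero, "Entrez_Gene_Id"] = repaired.fillna(0).astype(int)
    left = int((out["Entrez_Gene_Id"] == 0).sum())
    if left:
        logger.info("filter_maf: %d PASS rows remain with Entrez ID 0 "
                    "(no Ensembl mapping)", left)
    return out


def filter_clinical(
    clinical: pd.DataFrame,
    mutation_patients: Iterable[str],
    cna_patients: Iterable[str],
    arm_patients: Iterable[str],
) -> pd.DataFrame:
    """Keep primary malignant neoplasms present in all three molecular files.

    A record survives iff its ICD-O-3 histology code ends in "/3" and the
    patient appears in the mutation, CNA and arm-call datasets (patient IDs
    or barcodes accepted; barcodes are truncated to patient IDs).
    """
    def _pids(xs: Iterable[str]) -> set[str]:
        return {patient_id(x) for x in xs}

    present = _pids(mutation_patients) & _pids(cna_patients) & _pids(arm_patients)
    hist = clinical["icd_o_3_histology"].fillna("")
    keep = hist.str.endswith("/3") & clinical["bcr_patient_barcode"].map(
        lambda b: patient_id(b) in present)
    return clinical[keep].reset_index(drop=True)


def dedupe_patient_samples(barcodes: Sequence[str]) -> list[str]:
    """One sample per patient: the lexicographically smallest barcode."""
    best: dict[str, str] = {}
    for b in barcodes:
        p = patient_id(b)
        if p not in best or b < best[p]:
            best[p] = b
    return [best[p] for p in sorted(best)]
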