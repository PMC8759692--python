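"""Synthetic TCGA-dialect cohorts with planted ground truth.

The generator emits the seven input tables the pipelines consume — mutation
table, thresholded CNA matrix, arm-call table, mRNA and miRNA expression
matrices, clinical table, purity and quality annotations — as an internally
consistent dataset with configurable planted drivers, so detection power,
false-discovery calibration and end-to-end event counting are all testable
offline against known truth.

Scale and calibration: the default dataset holds 200 patients in four
cohorts over a 500-gene panel with 39 chromosome arms.  The patient axis is
shrunk relative to a real pan-cancer atlas, but the per-gene pan-dataset SNA
totals — the marginal the enrichment statistic and its bootstrap null
actually consume — are kept at atlas scale (~400 SNAs per gene) by an
elevated per-(patient, gene) background rate.  Background genes are neutral:
half of their SNAs are silent, so their nonsynonymous enrichment is centred
on 1.  Planted oncogenes receive only missense SNAs, planted suppressors
only truncating ones, and planted copy-number drivers are amplified or
deleted with expression moved concordantly for a configurable fraction of
calls.  Arm calls carry symmetric background noise with planted directional
gains/losses at a stated per-patient frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_filtering as iof
from .io_filtering import ArmCallTable, GeneSampleMatrix

DEFAULT_COHORTS = [("COAD", 50), ("BRCA", 50), ("LUAD", 50), ("UCEC", 50)]

# variant classifications drawn within each background category
_HYPER_CLASSES = (["Missense_Mutation", "In_Frame_Del"], [0.9, 0.1])
_INACT_CLASSES = (["Nonsense_Mutation", "Frame_Shift_Del"], [0.6, 0.4])
_UNCLEAR_CLASSES = (["3'UTR", "Intron"], [0.7, 0.3])

_CONCORDANT_FACTOR = {2: 2.5, 1: 1.5, -1: 0.5, -2: 0.02}


def default_arm_names() -> list[str]:
    """The canonical 39 autosome arms (13, 14, 15, 21, 22 are q-only)."""
    arms = []
    for c in range(1, 23):
        if c not in (13, 14, 15, 21, 22):
            arms.append(f"{c}p")
        arms.append(f"{c}q")
    return arms


@dataclass
class TruthConfig:
    """Planted-truth configuration for one synthetic dataset.

    ``planted_oncogenes`` / ``planted_suppressors`` map a cohort acronym to a
    list of (gene name, per-patient SNA probability, per-patient CNA
    probability); ``planted_arm_events`` maps a cohort to (arm, direction,
    frequency) with direction +1/-1, and ``planted_chromosome_events`` plants
    both arms of a chromosome jointly.  ``background_sna_rate`` is the
    expected number of background SNAs per (patient, gene) cell and
    ``silent_fraction`` the silent share of background SNAs.
    """

    cohorts: list[tuple[str, int]] = field(default_factory=lambda: list(DEFAULT_COHORTS))
    n_genes: int = 500
    n_mirna_genes: int = 20
    planted_oncogenes: dict[str, list[tuple[str, float, float]]] = field(default_factory=dict)
    planted_suppressors: dict[str, list[tuple[str, float, float]]] = field(default_factory=dict)
    planted_arm_events: dict[str, list[tuple[str, int, float]]] = field(default_factory=dict)
    planted_chromosome_events: dict[str, list[tuple[str, int, float]]] = field(default_factory=dict)
    background_sna_rate: float = 2.0
    silent_fraction: float = 0.5
    unclear_fraction: float = 0.05
    inactivating_nonsilent_share: float = 0.25
    background_cna_rate: float = 0.01
    arm_noise_rate: float = 0.05
    arm_missing_rate: float = 0.01
    expression_concordance: float = 0.8
    nonpass_fraction: float = 0.02
    zero_entrez_fraction: float = 0.02
    low_purity_fraction: float = 0.05
    blacklist_fraction: float = 0.02
    nonmalignant_fraction: float = 0.02
    arm_names: list[str] = field(default_factory=default_arm_names)
    seed: int = 0

    def validate(self) -> None:
        bad: list[str] = []
        if not self.cohorts or any(n < 1 for _, n in self.cohorts):
            bad.append("cohorts (sizes must be >= 1)")
        probs = {
            "background_sna_rate": (self.background_sna_rate, 0, np.inf),
            "silent_fraction": (self.silent_fraction, 0, 1),
            "unclear_fraction": (self.unclear_fraction, 0, 1),
            "inactivating_nonsilent_share": (self.inactivating_nonsilent_share, 0, 1),
            "background_cna_rate": (self.background_cna_rate, 0, 1),
            "arm_noise_rate": (self.arm_noise_rate, 0, 0.5),
            "arm_missing_rate": (self.arm_missing_rate, 0, 1),
            "expression_concordance": (self.expression_concordance, 0, 1),
            "nonpass_fraction": (self.nonpass_fraction, 0, 1),
            "zero_entrez_fraction": (self.zero_entrez_fraction, 0, 1),
            "low_purity_fraction": (self.low_purity_fraction, 0, 1),
            "blacklist_fraction": (self.blacklist_fraction, 0, 1),
            "nonmalignant_fraction": (self.nonmalignant_fraction, 0, 1),
        }
        bad += [name for name, (v, lo, hi) in probs.items() if not lo <= v <= hi]
        cohort_names = {c for c, _ in self.cohorts}
        for fld in ("planted_oncogenes", "planted_suppressors",
                    "planted_arm_events", "planted_chromosome_events"):
            entries = getattr(self, fld)
            if not set(entries) <= cohort_names:
                bad.append(f"{fld} (unknown cohort)")
            for lst in entries.values():
                for entry in lst:
                    if not 0 <= entry[2] <= 1:
                        bad.append(f"{fld} ({entry[0]}: probability out of [0,1])")
        for cohort, lst in self.planted_arm_events.items():
            for arm, direction, _ in lst:
                if arm not in self.arm_names or direction not in (-1, 1):
                    bad.append(f"planted_arm_events ({cohort}:{arm})")
        if bad:
            raise ValueError("invalid TruthConfig fields: " + "; ".join(bad))


@dataclass
class GeneratedDataset:
    """All generated tables plus the planted-truth records."""

    maf: pd.DataFrame
    cna: GeneSampleMatrix
    arms: ArmCallTable
    expression: GeneSampleMatrix
    mirna: GeneSampleMatrix
    clinical: pd.DataFrame
    purity: pd.DataFrame
    quality: pd.DataFrame
    id_map: dict[str, int]
    cohort_of: dict[str, str]
    truth_genes: pd.DataFrame     # cohort, Hugo_Symbol, Entrez_Gene_Id, role
    truth_units: pd.DataFrame     # cohort, unit, scope, direction
    truth_patient_units: pd.DataFrame  # Tumor_Sample_Barcode, unit, scope, direction

    FILES = {
        "maf": "mutations.tsv",
        "cna": "cna_thresholded.tsv",
        "arms": "arm_calls.tsv",
        "expression": "expression.tsv",
        "mirna": "mirna_expression.tsv",
        "clinical": "clinical.tsv",
        "purity": "purity.tsv",
        "quality": "quality_annotations.tsv",
        "truth_genes": "truth_genes.tsv",
        "truth_units": "truth_units.tsv",
        "truth_patient_units": "truth_patient_units.tsv",
    }

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        f = {k: outdir / v for k, v in self.FILES.items()}
        iof.write_maf(self.maf, f["maf"])
        iof.write_gene_matrix(self.cna, f["cna"])
        iof.write_arm_calls(self.arms, f["arms"])
        iof.write_gene_matrix(self.expression, f["expression"])
        iof.write_gene_matrix(self.mirna, f["mirna"])
        iof.write_clinical(self.clinical, f["clinical"])
        iof.write_purity(self.purity, f["purity"])
        iof.write_quality(self.quality, f["quality"])
        self.truth_genes.to_csv(f["truth_genes"], sep="\t", index=False)
        self.truth_units.to_csv(f["truth_units"], sep="\t", index=False)
        self.truth_patient_units.to_csv(f["truth_patient_units"], sep="\t", index=False)
        return f


def _gene_universe(config: TruthConfig):
    """Gene annotation table: planted genes first, then background fillers."""
    planted: list[tuple[str, str]] = []
    seen = set()
    for source, role in ((config.planted_oncogenes, "oncogene"),
                         (config.planted_suppressors, "suppressor")):
        for lst in source.values():
            for name, _, _ in lst:
                if name not in seen:
                    planted.append((name, role))
                    seen.add(name)
    names = [n for n, _ in planted]
    n_background = config.n_genes - len(names)
    if n_background < 0:
        raise ValueError("n_genes smaller than the number of planted genes")
    names += [f"GENE{i:04d}" for i in range(1, n_background + 1)]
    genes = pd.DataFrame({
        "Hugo_Symbol": names,
        "Entrez_Gene_Id": np.arange(1001, 1001 + len(names)),
        "Gene": [f"ENSG{100000 + i:011d}" for i in range(len(names))],
        "Transcript_ID": [f"ENST{100000 + i:011d}" for i in range(len(names))],
    })
    genes["planted_role"] = [role for _, role in planted] + [""] * n_background
    return genes


def generate(config: TruthConfig) -> GeneratedDataset:
    """Generate one dataset; byte-identical files for identical seeds."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = _gene_universe(config)
    entrez = genes["Entrez_Gene_Id"].to_numpy()
    by_name = genes.set_index("Hugo_Symbol")

    # -- patients ----------------------------------------------------------
    barcodes: list[str] = []
    cohort_of: dict[str, str] = {}
    for ci, (acr, n) in enumerate(config.cohorts):
        for pi in range(n):
            bc = f"TCGA-{chr(65 + ci)}{ci % 10}-{len(barcodes) + 1:04d}-01A"
            barcodes.append(bc)
            cohort_of[bc] = acr
    n_pat = len(barcodes)
    cohort_index = {acr: [b for b in barcodes if cohort_of[b] == acr]
                    for acr, _ in config.cohorts}

    # -- MAF: background then planted --------------------------------------
    bg_genes = genes[genes["planted_role"] == ""]
    bg_counts = rng.poisson(config.background_sna_rate,
                            size=(n_pat, len(bg_genes)))
    pat_idx, gene_idx = np.nonzero(bg_counts)
    reps = bg_counts[pat_idx, gene_idx]
    pat_idx = np.repeat(pat_idx, reps)
    gene_idx = np.repeat(gene_idx, reps)
    n_rows = pat_idx.size
    s, u = config.silent_fraction, config.unclear_fraction
    nonsilent = max(1e-12, 1.0 - s - u)
    p_inact = nonsilent * config.inactivating_nonsilent_share
    p_hyper = nonsilent - p_inact
    cat = rng.choice(4, size=n_rows, p=[p_hyper, p_inact, u, s])
    vc = np.empty(n_rows, dtype=object)
    for code, (classes, probs) in ((0, _HYPER_CLASSES), (1, _INACT_CLASSES),
                                   (2, _UNCLEAR_CLASSES)):
        mask = cat == code
        vc[mask] = rng.choice(classes, size=int(mask.sum()), p=probs)
    vc[cat == 3] = "Silent"

    maf_parts = [pd.DataFrame({
        "Tumor_Sample_Barcode": np.asarray(barcodes, dtype=object)[pat_idx],
        "Hugo_Symbol": bg_genes["Hugo_Symbol"].to_numpy()[gene_idx],
        "Entrez_Gene_Id": bg_genes["Entrez_Gene_Id"].to_numpy()[gene_idx],
        "Gene": bg_genes["Gene"].to_numpy()[gene_idx],
        "Transcript_ID": bg_genes["Transcript_ID"].to_numpy()[gene_idx],
        "Substitution": [f"c.{k}A>G" for k in rng.integers(1, 5000, size=n_rows)],
        "Variant_Classification": vc,
    })]

    truth_gene_rows: list[tuple[str, str, int, str]] = []
    cna_vals = np.zeros((len(genes), n_pat), dtype=int)
    # background CNA noise (half gains, half losses)
    noise = rng.random(cna_vals.shape)
    cna_vals[noise < config.background_cna_rate / 2] = 1
    cna_vals[(noise >= config.background_cna_rate / 2)
             & (noise < config.background_cna_rate)] = -1

    gene_pos = {g: i for i, g in enumerate(genes["Hugo_Symbol"])}
    pat_pos = {b: i for i, b in enumerate(barcodes)}

    for source, role in ((config.planted_oncogenes, "oncogene"),
                         (config.planted_suppressors, "suppressor")):
        for acr, lst in source.items():
            members = cohort_index[acr]
            for name, sna_p, cna_p in lst:
                row = by_name.loc[name]
                truth_gene_rows.append((acr, name, int(row["Entrez_Gene_Id"]), role))
                carriers = [b for b in members if rng.random() < sna_p]
                if carriers:
                    if role == "oncogene":
                        vc_p, sub = "Missense_Mutation", "p.A100V"
                    else:
                        vc_p, sub = "Nonsense_Mutation", "p.R100*"
                    maf_parts.append(pd.DataFrame({
                        "Tumor_Sample_Barcode": carriers,
                        "Hugo_Symbol": name,
                        "Entrez_Gene_Id": int(row["Entrez_Gene_Id"]),
                        "Gene": row["Gene"],
                        "Transcript_ID": row["Transcript_ID"],
                        "Substitution": sub,
                        "Variant_Classification": vc_p,
                    }))
                gi = gene_pos[name]
                # planted genes carry no background CNA noise
                cna_vals[gi, [pat_pos[b] for b in members]] = 0
                amp = 2 if role == "oncogene" else -2
                for b in members:
                    if rng.random() < cna_p:
                        cna_vals[gi, pat_pos[b]] = amp

    maf = pd.concat(maf_parts, ignore_index=True)
    maf["FILTER"] = np.where(rng.random(len(maf)) < config.nonpass_fraction,
                             "wga", "PASS")
    zero_mask = rng.random(len(maf)) < config.zero_entrez_fraction
    maf["true_entrez"] = maf["Entrez_Gene_Id"]
    maf.loc[zero_mask, "Entrez_Gene_Id"] = 0
    id_map = dict(zip(genes["Gene"], genes["Entrez_Gene_Id"].astype(int)))
    maf = maf.drop(columns=["true_entrez"])[iof.MAF_COLUMNS]

    cna = GeneSampleMatrix(
        pd.DataFrame(cna_vals.astype(float), index=genes["Entrez_Gene_Id"],
                     columns=barcodes),
        genes.set_index("Entrez_Gene_Id")["Hugo_Symbol"])

    # -- expression, concordant with CNA for a stated fraction of calls ----
    def _expression_for(sub_cna: np.ndarray, n_genes_sub: int) -> np.ndarray:
        base = 10.0 ** rng.uniform(1, 3, size=n_genes_sub)
        factor = rng.uniform(0.9, 1.1, size=sub_cna.shape)
        nz = sub_cna != 0
        concord = nz & (rng.random(sub_cna.shape) < config.expression_concordance)
        for call, f in _CONCORDANT_FACTOR.items():
            factor[concord & (sub_cna == call)] = f
        return base[:, None] * factor

    expr_vals = _expression_for(cna_vals, len(genes))
    expression = GeneSampleMatrix(
        pd.DataFrame(expr_vals, index=genes["Entrez_Gene_Id"], columns=barcodes),
        genes.set_index("Entrez_Gene_Id")["Hugo_Symbol"])

    mirna_names = [f"hsa-mir-{i:04d}" for i in range(1, config.n_mirna_genes + 1)]
    mirna_entrez = pd.Index(np.arange(900001, 900001 + config.n_mirna_genes),
                            name="Entrez_Gene_Id")
    mirna_cna = np.zeros((config.n_mirna_genes, n_pat), dtype=int)
    mirna_vals = _expression_for(mirna_cna, config.n_mirna_genes)
    mirna = GeneSampleMatrix(
        pd.DataFrame(mirna_vals, index=mirna_entrez, columns=barcodes),
        pd.Series(mirna_names, index=mirna_entrez))

    # -- arm calls ----------------------------------------------------------
    arm_names = list(config.arm_names)
    r = config.arm_noise_rate
    calls = rng.choice([-1.0, 0.0, 1.0], size=(n_pat, len(arm_names)),
                       p=[r, 1 - 2 * r, r])
    truth_unit_rows: list[tuple[str, str, str, int]] = []
    truth_patient_rows: list[tuple[str, str, str, int]] = []
    arm_pos = {a: i for i, a in enumerate(arm_names)}
    for acr, lst in config.planted_arm_events.items():
        for arm, direction, freq in lst:
            truth_unit_rows.append((acr, arm, "arm", direction))
            for b in cohort_index[acr]:
                if rng.random() < freq:
                    calls[pat_pos[b], arm_pos[arm]] = direction
                    truth_patient_rows.append((b, arm, "arm", direction))
    for acr, lst in config.planted_chromosome_events.items():
        for chrom, direction, freq in lst:
            members = [a for a in arm_names
                       if a[:-1] == chrom and a[-1] in "pq"]
            if not members:
                raise ValueError(f"chromosome {chrom!r} has no arms in arm_names")
            truth_unit_rows.append((acr, chrom, "chromosome", direction))
            for b in cohort_index[acr]:
                if rng.random() < freq:
                    for a in members:
                        calls[pat_pos[b], arm_pos[a]] = direction
                    truth_patient_rows.append((b, chrom, "chromosome", direction))
    missing = rng.random(calls.shape) < config.arm_missing_rate
    calls[missing] = np.nan
    arms = ArmCallTable(pd.DataFrame(calls, index=barcodes, columns=arm_names))

    # -- clinical, purity, quality ------------------------------------------
    stages = ["Stage I", "Stage II", "Stage III", "Stage IV"]
    path_stage = rng.choice(stages + [""], size=n_pat,
                            p=[0.2, 0.25, 0.25, 0.2, 0.1])
    clin_stage = rng.choice(stages, size=n_pat)
    histology = np.where(rng.random(n_pat) < config.nonmalignant_fraction,
                         "8140/1", "8140/3")
    clinical = pd.DataFrame({
        "bcr_patient_barcode": [iof.patient_id(b) for b in barcodes],
        "acronym": [cohort_of[b] for b in barcodes],
        "gender": rng.choice(["MALE", "FEMALE"], size=n_pat),
        "age_at_initial_pathologic_diagnosis": rng.integers(25, 86, size=n_pat),
        "pathologic_stage": path_stage,
        "clinical_stage": np.where(path_stage == "", clin_stage, ""),
        "pathologic_T": "",
        "clinical_T": "",
        "icd_o_3_histology": histology,
    })
    for col in ("pathologic_stage", "clinical_stage", "pathologic_T", "clinical_T"):
        clinical[col] = clinical[col].mask(clinical[col] == "", np.nan)

    low = rng.random(n_pat) < config.low_purity_fraction
    purity = pd.DataFrame({
        "Sample": barcodes,
        "Cancer DNA fraction": np.where(low, rng.uniform(0.2, 0.45, n_pat),
                                        rng.uniform(0.55, 0.95, n_pat)).round(4),
        "Subclonal genome fraction": rng.uniform(0.0, 0.45, n_pat).round(4),
    })
    quality = pd.DataFrame({
        "aliquot_barcode": [b + "-01D-1111-01" for b in barcodes],
        "Do_not_use": rng.random(n_pat) < config.blacklist_fraction,
    })

    truth_genes = pd.DataFrame(
        truth_gene_rows,
        columns=["cohort", "Hugo_Symbol", "Entrez_Gene_Id", "role"])
    truth_units = pd.DataFrame(
        truth_unit_rows, columns=["cohort", "unit", "scope", "direction"])
    truth_patient_units = pd.DataFrame(
        truth_patient_rows,
        columns=["Tumor_Sample_Barcode", "unit", "scope", "direction"])

    return GeneratedDataset(
        maf=maf, cna=cna, arms=arms, expression=expression, mirna=mirna,
        clinical=clinical, purity=purity, quality=quality, id_map=id_map,
        cohort_of=cohort_of, truth_genes=truth_genes, truth_units=truth_units,
        truth_patient_units=truth_patient_units)


def truth_compare(predicted: dict[str, set], truth: dict[str, set]) -> pd.DataFrame:
    """Per-class recall and precision of predictions against planted truth.

    Both arguments map a class name to a set of items (genes, (cohort, unit)
    pairs, ...).  Precision is NaN for classes with no predictions.
    """
    rows = []
    for cls in sorted(set(predicted) | set(truth)):
        pred = set(predicted.get(cls, set()))
        true = set(truth.get(cls, set()))
        tp = len(pred & true)
        recall = tp / len(true) if true else np.nan
        precision = tp / len(pred) if pred else np.nan
        rows.append((cls, recall, precision, len(true), len(pred)))
    return pd.DataFrame(
        rows, columns=["class", "recall", "precision", "n_truth", "n_predicted"])
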