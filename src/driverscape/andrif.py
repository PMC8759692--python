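"""Aneuploidy driver discovery (ANDRIF).

Works on a samples × chromosome-arm call table with entries in {-1, 0, +1}
(loss / neutral / gain; missing allowed).  For every cancer-type cohort the
observed mean call of each arm is compared against an empirical null built by
bootstrap: cohort-sized resamples drawn with replacement from the pool of all
non-missing calls of the whole table.  A signed empirical p-value is assigned
only to means that fall on the far side of the null median, and a
Benjamini-Hochberg step-up at FDR 5% within each cohort turns the survivors
into driver labels: DAG/DAL for arm gains/losses, DCG/DCL for whole
chromosomes.  Whole-chromosome calls are derived from the two arm calls
(both +1 -> +1, both -1 -> -1, any missing -> missing, else 0; the acrocentric
chromosomes 13, 14, 15, 21, 22 take their single arm's call verbatim).

The p-value denominator is n_iter/2 (5000 for the canonical 10000
iterations), i.e. the one-sided tail count is doubled; magnitudes are capped
at 1 only when entering the BH step.  Chromosome-level driver events override
arm-level events of the same chromosome in per-patient calling, so one
missegregation is never counted twice.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io_filtering import ArmCallTable, patient_id

ARM_LABELS = ("DAG", "DAL")
CHROMOSOME_LABELS = ("DCG", "DCL")
# chromosomes whose p arm carries no analysable material
SINGLE_ARM_CHROMOSOMES = ("13", "14", "15", "21", "22")

_ARM_RE = re.compile(r"^(\d{1,2}|[XY])([pq])$")


@dataclass
class BootstrapNull:
    """Per-cohort bootstrap distributions of mean alteration status."""

    averages: dict[str, np.ndarray]
    n_iterations: int
    seed: int
    medians: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.medians = {c: float(np.median(v)) for c, v in self.averages.items()}


@dataclass(frozen=True)
class SignedEmpiricalP:
    """Empirical tail ratio with a gain/loss direction.

    ``magnitude`` is tail count / (n_iter/2); it can exceed 1 and is capped
    at 1 only when tested.
    """

    magnitude: float
    direction: str  # "gain" | "loss"


def compute_unit_averages(
    calls: ArmCallTable, cohort_of: Mapping[str, str]
) -> pd.DataFrame:
    """Cohort × unit matrix of mean calls, missing cells excluded.

    Every sample must map to a cohort; unknown samples raise with the
    barcode named.  A (cohort, unit) cell with no non-missing calls is NaN.
    """
    unknown = [b for b in calls.sample_barcodes if b not in cohort_of]
    if unknown:
        raise ValueError(f"samples without a cohort assignment: {unknown[:5]}")
    cohorts = pd.Series({b: cohort_of[b] for b in calls.sample_barcodes})
    return calls.calls.groupby(cohorts).mean()


def bootstrap_null(
    calls: ArmCallTable,
    cohort_sizes: Mapping[str, int],
    n_iter: int = 10000,
    seed: int = 0,
) -> BootstrapNull:
    """Bootstrap cohort-mean nulls from the pool of all non-missing calls."""
    pool = calls.calls.to_numpy(dtype=float).ravel()
    pool = pool[~np.isnan(pool)]
    if pool.size == 0:
        raise ValueError("no non-missing calls to bootstrap from")
    rng = np.random.default_rng(seed)
    averages: dict[str, np.ndarray] = {}
    for cohort in sorted(cohort_sizes):
        n = int(cohort_sizes[cohort])
        draws = rng.integers(0, pool.size, size=(n_iter, n))
        averages[cohort] = pool[draws].mean(axis=1)
    return BootstrapNull(averages=averages, n_iterations=n_iter, seed=seed)


def signed_empirical_p(
    observed: float, null: BootstrapNull, cohort: str
) -> SignedEmpiricalP | None:
    """Tail probability of an observed cohort-arm mean, or None if untestable.

    Testable means lie beyond zero *and* beyond the null median in the same
    direction; everything else is ignored (cell left empty).
    """
    if cohort not in null.averages:
        raise KeyError(f"cohort {cohort!r} absent from bootstrap null")
    if observed is None or np.isnan(observed):
        return None
    vec = null.averages[cohort]
    med = null.medians[cohort]
    half = null.n_iterations / 2
    if observed > 0 and observed > med:
        return SignedEmpiricalP(float((vec > observed).sum()) / half, "gain")
    if observed < 0 and observed < med:
        return SignedEmpiricalP(float((vec < observed).sum()) / half, "loss")
    return None


def bh_select(
    pvals: Mapping[str, SignedEmpiricalP], q: float = 0.05, scope: str = "arm"
) -> dict[str, str]:
    """BH step-up over one cohort's signed p-values -> driver labels.

    Magnitudes are capped at 1 before testing.  Gains map to DAG (arm scope)
    or DCG (chromosome scope), losses to DAL/DCL.
    """
    if scope not in ("arm", "chromosome"):
        raise ValueError(f"unknown scope {scope!r}")
    units = sorted(pvals)
    if not units:
        return {}
    p = np.minimum([pvals[u].magnitude for u in units], 1.0)
    reject = multipletests(p, alpha=q, method="fdr_bh")[0]
    gain, loss = (ARM_LABELS if scope == "arm" else CHROMOSOME_LABELS)
    return {
        u: (gain if pvals[u].direction == "gain" else loss)
        for u, r in zip(units, reject) if r
    }


def label_drivers(
    averages: pd.DataFrame, null: BootstrapNull, q: float = 0.05, scope: str = "arm"
) -> dict[tuple[str, str], str]:
    """Full cohort×unit labelling: signed p-values then per-cohort BH."""
    labels: dict[tuple[str, str], str] = {}
    for cohort in averages.index:
        pvals = {}
        for unit in averages.columns:
            sp = signed_empirical_p(averages.loc[cohort, unit], null, cohort)
            if sp is not None:
                pvals[unit] = sp
        for unit, lab in bh_select(pvals, q=q, scope=scope).items():
            labels[(cohort, unit)] = lab
    return labels


def arm_chromosome(arm_name: str) -> str:
    m = _ARM_RE.match(arm_name)
    if not m:
        raise ValueError(f"unparseable arm name {arm_name!r}")
    return m.group(1)


def build_chromosome_calls(arms: ArmCallTable) -> ArmCallTable:
    """Collapse arm calls to whole-chromosome calls (unanimity rule)."""
    by_chrom: dict[str, list[str]] = {}
    for arm in arms.arm_names:
        by_chrom.setdefault(arm_chromosome(arm), []).append(arm)
    cols = {}
    for chrom, members in by_chrom.items():
        sub = arms.calls[members].to_numpy(dtype=float)
        if len(members) == 1 or chrom in SINGLE_ARM_CHROMOSOMES:
            cols[chrom] = sub[:, 0]
            continue
        any_missing = np.isnan(sub).any(axis=1)
        all_gain = (sub == 1).all(axis=1)
        all_loss = (sub == -1).all(axis=1)
        val = np.where(all_gain, 1.0, np.where(all_loss, -1.0, 0.0))
        cols[chrom] = np.where(any_missing, np.nan, val)
    out = pd.DataFrame(cols, index=arms.calls.index)
    return ArmCallTable(out)


def call_patient_events(
    arm_calls: ArmCallTable,
    chrom_calls: ArmCallTable,
    arm_labels: Mapping[tuple[str, str], str],
    chrom_labels: Mapping[tuple[str, str], str],
    cohort_of: Mapping[str, str],
) -> pd.DataFrame:
    """Per-patient aneuploidy driver events; chromosome overrides its arms.

    Returns a DataFrame with columns Tumor_Sample_Barcode, unit, label.  A
    patient's -1 call on a unit labelled DAL/DCL in their cohort (or +1 on
    DAG/DCG) is one event; when a chromosome event fires, neither of its arm
    events is emitted for that patient.  Patients with zero events simply do
    not appear.
    """
    rows: list[tuple[str, str, str]] = []
    for barcode in chrom_calls.sample_barcodes:
        cohort = cohort_of[barcode]
        fired_chroms: set[str] = set()
        for chrom in chrom_calls.arm_names:
            lab = chrom_labels.get((cohort, chrom))
            if lab is None:
                continue
            call = chrom_calls.calls.at[barcode, chrom]
            if (lab == "DCG" and call == 1) or (lab == "DCL" and call == -1):
                rows.append((barcode, chrom, lab))
                fired_chroms.add(chrom)
        for arm in arm_calls.arm_names:
            if arm_chromosome(arm) in fired_chroms:
                continue  # chromosome event supersedes its arms
            lab = arm_labels.get((cohort, arm))
            if lab is None:
                continue
            call = arm_calls.calls.at[barcode, arm]
            if (lab == "DAG" and call == 1) or (lab == "DAL" and call == -1):
                rows.append((barcode, arm, lab))
    return pd.DataFrame(rows, columns=["Tumor_Sample_Barcode", "unit", "label"])


def summarize_labels(labels: Mapping[tuple[str, str], str]) -> dict[str, pd.Series]:
    """Driver-gain/loss tallies: units per cohort and cohorts per unit."""
    df = pd.DataFrame(
        [(c, u, lab) for (c, u), lab in labels.items()],
        columns=["cohort", "unit", "label"],
    )
    out: dict[str, pd.Series] = {}
    for suffix, labs in (("gain", ("DAG", "DCG")), ("loss", ("DAL", "DCL"))):
        sub = df[df["label"].isin(labs)]
        out[f"units_with_driver_{suffix}_per_cohort"] = (
            sub.groupby("cohort")["unit"].nunique())
        out[f"cohorts_with_driver_{suffix}_per_unit"] = (
            sub.groupby("unit")["cohort"].nunique())
    return out


@dataclass
class AndrifResult:
    """Everything one ANDRIF run produces, for both scopes."""

    arm_averages: pd.DataFrame
    chrom_averages: pd.DataFrame
    arm_null: BootstrapNull
    chrom_null: BootstrapNull
    arm_labels: dict[tuple[str, str], str]
    chrom_labels: dict[tuple[str, str], str]
    patient_events: pd.DataFrame

    @property
    def n_tested_pairs(self) -> int:
        n_cohorts = len(self.arm_averages.index)
        return n_cohorts * (len(self.arm_averages.columns)
                            + len(self.chrom_averages.columns))


def run_andrif(
    arms: ArmCallTable,
    cohort_of: Mapping[str, str],
    n_iter: int = 10000,
    seed: int = 0,
    q: float = 0.05,
) -> AndrifResult:
    """Arm- and chromosome-scope pipeline with distinct derived RNG seeds."""
    arm_seed, chrom_seed = np.random.SeedSequence(seed).generate_state(2)
    cohort_sizes = pd.Series(
        [cohort_of[b] for b in arms.sample_barcodes]).value_counts().to_dict()

    arm_avg = compute_unit_averages(arms, cohort_of)
    arm_null = bootstrap_null(arms, cohort_sizes, n_iter=n_iter, seed=int(arm_seed))
    arm_labels = label_drivers(arm_avg, arm_null, q=q, scope="arm")

    chroms = build_chromosome_calls(arms)
    chrom_avg = compute_unit_averages(chroms, cohort_of)
    chrom_null = bootstrap_null(chroms, cohort_sizes, n_iter=n_iter,
                                seed=int(chrom_seed))
    chrom_labels = label_drivers(chrom_avg, chrom_null, q=q, scope="chromosome")

    events = call_patient_events(arms, chroms, arm_labels, chrom_labels, cohort_of)
    return AndrifResult(arm_avg, chrom_avg, arm_null, chrom_null,
                        arm_labels, chrom_labels, events)


def patient_event_counts(events: pd.DataFrame) -> pd.DataFrame:
    """Wide per-patient counts of DAG/DAL/DCG/DCL events (patients with any)."""
    if events.empty:
        return pd.DataFrame(columns=["DAG", "DAL", "DCG", "DCL"])
    wide = (events.assign(patient=events["Tumor_Sample_Barcode"].map(patient_id))
            .groupby(["patient", "label"]).size().unstack(fill_value=0))
    return wide.reindex(columns=["DAG", "DAL", "DCG", "DCL"], fill_value=0)
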