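"""Cohort selection cascade and patient-level train/validation/test splits.

The cohort is the subset of encounters eligible for modelling: completed
office visits that carry at least one "frequent" full ICD-10 code (a code
observed in at least ``min_patients`` distinct patients), restricted to
patients who retain at least two such encounters. Splits are drawn at the
patient level so no patient's encounters straddle the train/validation/test
boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import EventTables

logger = logging.getLogger(__name__)

__all__ = [
    "Cohort",
    "CohortSplit",
    "select_office_visits",
    "frequent_codes",
    "build_cohort",
    "split_patients",
]

OFFICE_VISIT = "office visit"
COMPLETED = "completed"


@dataclass
class Cohort:
    """Retained encounters/patients plus audit trail of the filtering cascade."""

    encounter_ids: list[str]
    patient_ids: set[str]
    frequent_codes: set[str]
    audit: pd.DataFrame  # columns: stage, n_patients, n_encounters

    @property
    def is_empty(self) -> bool:
        return len(self.encounter_ids) == 0


@dataclass
class CohortSplit:
    train_patients: set[str]
    val_patients: set[str]
    test_patients: set[str]
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0


def select_office_visits(tables: EventTables) -> set[str]:
    """Encounter ids whose type is an office visit and whose status is completed."""
    enc = tables.encounters
    for col in ("encounter_id", "type", "status"):
        if col not in enc.columns:
            raise KeyError(f"encounters table is missing column {col!r}")
    mask = (
        enc["type"].str.strip().str.lower().eq(OFFICE_VISIT)
        & enc["status"].str.strip().str.lower().eq(COMPLETED)
    )
    return set(enc.loc[mask, "encounter_id"])


def frequent_codes(
    diagnoses: pd.DataFrame,
    encounter_ids: set[str],
    min_patients: int = 500,
) -> set[str]:
    """Full ICD-10 codes carried by at least ``min_patients`` distinct patients.

    Counting is per patient (a patient contributes once per code however many
    times the code recurs), within the given encounter universe. The
    threshold is inclusive.
    """
    if min_patients < 1:
        raise ValueError("min_patients must be >= 1")
    dx = diagnoses[diagnoses["encounter_id"].isin(encounter_ids)]
    if dx.empty:
        return set()
    counts = dx.groupby("icd10_code")["patient_id"].nunique()
    return set(counts.index[counts >= min_patients])


def build_cohort(tables: EventTables, min_patients: int = 500) -> Cohort:
    """Apply the selection cascade and record per-stage audit counts.

    Stages, in order: completed office visits; encounters with at least one
    diagnosis; frequent-code computation and restriction; encounters left
    with at least one frequent code; patients with at least two retained
    encounters. One pass suffices — dropping patients removes encounters but
    cannot re-introduce any — which is asserted at the end.
    """
    enc = tables.encounters
    dx = tables.diagnoses
    audit_rows = []

    def _audit(stage: str, enc_ids: set[str]) -> None:
        pats = set(enc.loc[enc["encounter_id"].isin(enc_ids), "patient_id"])
        audit_rows.append((stage, len(pats), len(enc_ids)))

    all_ids = set(enc["encounter_id"])
    _audit("input", all_ids)

    office = select_office_visits(tables)
    _audit("office_visits_completed", office)

    coded = office & set(dx["encounter_id"])
    _audit("with_any_diagnosis", coded)

    freq = frequent_codes(dx, coded, min_patients=min_patients)
    dx_f = dx[dx["encounter_id"].isin(coded) & dx["icd10_code"].isin(freq)]
    with_freq = set(dx_f["encounter_id"])
    _audit("with_frequent_code", with_freq)

    enc_kept = enc[enc["encounter_id"].isin(with_freq)]
    per_pat = enc_kept.groupby("patient_id")["encounter_id"].nunique()
    pats_kept = set(per_pat.index[per_pat >= 2])
    final_ids = set(enc_kept.loc[enc_kept["patient_id"].isin(pats_kept), "encounter_id"])
    _audit("patients_ge2_encounters", final_ids)

    # fixed point: re-applying the >=2 rule changes nothing
    enc_final = enc[enc["encounter_id"].isin(final_ids)]
    again = enc_final.groupby("patient_id")["encounter_id"].nunique()
    assert (again >= 2).all() or final_ids == set()

    audit = pd.DataFrame(audit_rows, columns=["stage", "n_patients", "n_encounters"])
    if not final_ids:
        logger.warning("cohort is empty after filtering")
        return Cohort([], set(), freq, audit)

    order = (
        enc_final[["encounter_id", "patient_id", "date"]]
        .sort_values(["patient_id", "date", "encounter_id"], kind="mergesort")
    )
    return Cohort(order["encounter_id"].tolist(), pats_kept, freq, audit)


def _largest_remainder(n: int, fractions: tuple[float, ...]) -> list[int]:
    quotas = [n * f for f in fractions]
    sizes = [int(q) for q in quotas]
    rem = n - sum(sizes)
    by_frac = sorted(range(len(fractions)), key=lambda i: quotas[i] - sizes[i],
                     reverse=True)
    for i in by_frac[:rem]:
        sizes[i] += 1
    return sizes


def split_patients(
    cohort: Cohort,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> CohortSplit:
    """Seed-deterministic uniformly random patient partition.

    Sizes follow the largest-remainder rounding of the requested fractions,
    so realized counts are within one patient of exact.
    """
    if any(f <= 0 for f in fractions):
        raise ValueError("fractions must be positive")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    patients = sorted(cohort.patient_ids)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(patients))
    sizes = _largest_remainder(len(patients), fractions)
    shuffled = [patients[i] for i in perm]
    a, b = sizes[0], sizes[0] + sizes[1]
    return CohortSplit(
        train_patients=set(shuffled[:a]),
        val_patients=set(shuffled[a:b]),
        test_patients=set(shuffled[b:]),
        fractions=fractions,
        seed=seed,
    )
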