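"""End-to-end orchestration: simulate/load -> cohort -> labels -> features
-> train -> calibrate -> evaluate.

This is the programmatic face of the whole workflow; the CLI and the
examples are thin wrappers over :func:`prepare_data` and
:func:`run_experiment`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import metrics as M
from .cohort import Cohort, CohortSplit, build_cohort, split_patients
from .features import FeatureBuilder, HarmonizedLabs, WindowConfig, harmonize_labs
from .labels import LabelMatrix, build_label_matrix, label_universe
from .model import ModelBundle, TrainConfig, calibrate, fit_multilabel, predict_proba
from .synthetic import EventTables, GroundTruth, SimConfig, generate, harmonization_tables

__all__ = ["PreparedData", "ExperimentResult", "prepare_data", "run_experiment"]


@dataclass
class PreparedData:
    """Aligned feature/label matrices for the three patient splits."""

    cohort: Cohort
    split: CohortSplit
    builder: FeatureBuilder
    label_ids: list[str]
    X: dict[str, sp.csr_matrix]            # split -> features
    Y: dict[str, np.ndarray]               # split -> dense binary labels
    encounter_ids: dict[str, list[str]]    # split -> row order
    encounters: pd.DataFrame               # encounter_id, patient_id, date
    harmonized: HarmonizedLabs | None


def prepare_data(
    tables: EventTables,
    min_patients: int = 500,
    min_lab_patients: int | None = None,
    windows: WindowConfig = WindowConfig(),
    modalities: tuple[str, ...] = ("demo", "diag", "labs"),
    conversion: pd.DataFrame | None = None,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> PreparedData:
    """Run the full data-preparation cascade on raw event tables."""
    cohort = build_cohort(tables, min_patients=min_patients)
    if cohort.is_empty:
        raise ValueError("cohort is empty after filtering")
    split = split_patients(cohort, fractions=fractions, seed=seed)

    labels = label_universe(cohort.frequent_codes)
    enc = tables.encounters[tables.encounters["encounter_id"].isin(set(cohort.encounter_ids))]
    enc = enc.set_index("encounter_id").loc[cohort.encounter_ids].reset_index()

    harmonized = None
    if "labs" in modalities and conversion is not None:
        harmonized = harmonize_labs(
            tables.labs, conversion,
            min_patients=min_lab_patients if min_lab_patients is not None else min_patients,
        )
    use_mods = tuple(m for m in modalities if m != "labs" or harmonized is not None)

    builder = FeatureBuilder(windows=windows, modalities=use_mods)
    builder.fit(tables.patients, tables.diagnoses, harmonized, split.train_patients)

    X, Y, eids = {}, {}, {}
    split_sets = {"train": split.train_patients, "val": split.val_patients,
                  "test": split.test_patients}
    for name, pats in split_sets.items():
        enc_s = enc[enc["patient_id"].isin(pats)]
        lm = build_label_matrix(enc_s["encounter_id"].tolist(), tables.diagnoses,
                                labels, frequent=cohort.frequent_codes)
        enc_kept = enc_s[enc_s["encounter_id"].isin(set(lm.encounter_ids))]
        enc_kept = enc_kept.set_index("encounter_id").loc[lm.encounter_ids].reset_index()
        fm = builder.transform(enc_kept)
        X[name] = fm.matrix
        Y[name] = lm.dense()
        eids[name] = lm.encounter_ids
    return PreparedData(cohort, split, builder, labels, X, Y, eids,
                        enc[["encounter_id", "patient_id", "date"]], harmonized)


@dataclass
class ExperimentResult:
    bundle: ModelBundle
    scores: dict[str, np.ndarray]          # split -> calibrated score matrix
    metrics: dict[str, pd.DataFrame]       # "overall"/"de_novo" per-label tables
    summary: dict[str, float] = field(default_factory=dict)


def run_experiment(
    data: PreparedData,
    config: TrainConfig,
    with_calibration: bool = True,
    eval_split: str = "test",
    ks: tuple[int, ...] = (10,),
) -> ExperimentResult:
    """Train (and optionally calibrate) on the training split, evaluate on
    ``eval_split`` under both the overall and de-novo protocols."""
    bundle = fit_multilabel(data.X["train"], data.Y["train"], data.label_ids,
                            data.builder.schema, config)
    if with_calibration:
        calibrate(bundle, data.X["train"], data.Y["train"])

    scores = {s: predict_proba(bundle, data.X[s]) for s in ("val", eval_split)}
    S, Y = scores[eval_split], data.Y[eval_split]

    overall = M.per_label_metrics(S, Y, data.label_ids, mode="overall")
    mask = M.denovo_mask(data.encounters, data.encounter_ids[eval_split], Y,
                         data.label_ids)
    denovo = M.per_label_metrics(S, Y, data.label_ids, mask=mask, mode="de_novo")

    summary = {
        "median_auroc_overall": M.summarize(overall, "auroc")["median"],
        "median_auroc_denovo": M.summarize(denovo, "auroc")["median"],
        "median_auprc_overall": M.summarize(overall, "auprc")["median"],
        "coverage_error": M.coverage_error(S, Y),
    }
    for k in ks:
        summary[f"recall_at_{k}"] = M.recall_at_k(S, Y, k)
    return ExperimentResult(bundle, scores, {"overall": overall, "de_novo": denovo},
                            summary)


def simulate_and_prepare(
    sim: SimConfig,
    min_patients: int = 20,
    windows: WindowConfig = WindowConfig(),
    modalities: tuple[str, ...] = ("demo", "diag", "labs"),
    split_seed: int | None = None,
) -> tuple[PreparedData, GroundTruth, EventTables]:
    """Convenience wrapper: simulate a cohort and prepare matrices from it.

    ``min_patients`` defaults far below the production threshold of 500
    because synthetic cohorts are a few thousand patients, not half a
    million.
    """
    tables, truth = generate(sim)
    data = prepare_data(
        tables,
        min_patients=min_patients,
        windows=windows,
        modalities=modalities,
        conversion=harmonization_tables(truth) if "labs" in modalities else None,
        seed=sim.seed if split_seed is None else split_seed,
    )
    return data, truth, tables
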