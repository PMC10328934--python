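"""Lab harmonization and time-windowed history features with early fusion.

For each index encounter the feature vector concatenates, in fixed schema
order, (i) demographics — age in fractional years and a one-hot sex block;
(ii) binary presence of each three-character diagnosis prefix within a
look-back window ending strictly before the encounter date; and (iii) per
harmonized lab, a presence indicator plus the most recent in-window value
(numeric labs) or an any-positive indicator (categorical labs). Windows are
closed at the old end and open at the encounter date, so same-day events
never leak into the features.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "WindowConfig",
    "FeatureSchema",
    "FeatureMatrix",
    "HarmonizedLabs",
    "harmonize_labs",
    "aggregate_diagnoses",
    "aggregate_labs",
    "demographics_matrix",
    "fuse",
    "FeatureBuilder",
    "DEFAULT_POSITIVE_LEXICON",
    "DEFAULT_NEGATIVE_LEXICON",
]

ALLOWED_DIAG_WINDOWS = (90, 180, 365, 3650)
ALLOWED_LAB_WINDOWS = (30, 90, 180, 365)

DEFAULT_POSITIVE_LEXICON = frozenset(
    {"positive", "detected", "abnormal", "present", "reactive", "yes", "1"}
)
DEFAULT_NEGATIVE_LEXICON = frozenset(
    {"negative", "not detected", "normal", "absent", "nonreactive", "no", "0"}
)


@dataclass(frozen=True)
class WindowConfig:
    """Look-back windows in days for diagnosis and lab aggregation."""

    diag_window_days: int = 3650
    lab_window_days: int = 365

    def __post_init__(self) -> None:
        if self.diag_window_days not in ALLOWED_DIAG_WINDOWS:
            warnings.warn(
                f"diag_window_days={self.diag_window_days} is outside the standard "
                f"set {ALLOWED_DIAG_WINDOWS}", stacklevel=2)
        if self.lab_window_days not in ALLOWED_LAB_WINDOWS:
            warnings.warn(
                f"lab_window_days={self.lab_window_days} is outside the standard "
                f"set {ALLOWED_LAB_WINDOWS}", stacklevel=2)
        if self.diag_window_days <= 0 or self.lab_window_days <= 0:
            raise ValueError("windows must be positive")


@dataclass
class FeatureSchema:
    """Ordered feature names with modality tags; frozen once fitted."""

    names: list[str]
    modalities: list[str]  # per feature: demo | diag | lab_value | lab_presence
    units: dict[str, str] = field(default_factory=dict)  # lab_value name -> unit

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError("feature names must be unique")
        if len(self.names) != len(self.modalities):
            raise ValueError("names and modalities must align")

    def hash(self) -> str:
        payload = json.dumps([self.names, self.modalities], sort_keys=False)
        return hashlib.sha256(payload.encode()).hexdigest()

    def __len__(self) -> int:
        return len(self.names)


@dataclass
class FeatureMatrix:
    encounter_ids: list[str]
    schema: FeatureSchema
    matrix: sp.csr_matrix

    def dense(self) -> np.ndarray:
        return self.matrix.toarray()


@dataclass
class HarmonizedLabs:
    """Lab events on canonical units/binary values plus a lab registry."""

    events: pd.DataFrame   # patient_id, date, lab_id, value
    registry: pd.DataFrame  # lab_id, kind, canonical_unit
    drop_stats: dict[str, float]


def harmonize_labs(
    labs: pd.DataFrame,
    conversion: pd.DataFrame,
    min_patients: int = 500,
    positive_lexicon: frozenset[str] = DEFAULT_POSITIVE_LEXICON,
    negative_lexicon: frozenset[str] = DEFAULT_NEGATIVE_LEXICON,
) -> HarmonizedLabs:
    """Collapse lab name variants, rescale to canonical units, binarize
    categorical results, and drop infrequent labs.

    ``conversion`` columns: lab_name, unit, lab_id, kind, canonical_unit,
    factor (multiplicative, value_canonical = raw * factor). Events whose
    (name, unit) pair is absent from the table, whose numeric value fails to
    parse, or whose categorical value matches neither lexicon are dropped
    and counted; the dropped fraction is reported in ``drop_stats``.
    """
    if (conversion["factor"] <= 0).any():
        bad = conversion.loc[conversion["factor"] <= 0]
        raise ValueError(f"non-positive conversion factor(s):\n{bad}")

    n_total = len(labs)
    df = labs.merge(conversion, on=["lab_name", "unit"], how="left")
    unmatched = df["lab_id"].isna()

    numeric = df["kind"] == "numeric"
    vals = pd.to_numeric(df["raw_value"], errors="coerce")
    bad_numeric = numeric & vals.isna()

    lowered = df["raw_value"].astype(str).str.strip().str.lower()
    nonnum = df["kind"] == "nonnumeric"
    pos = nonnum & lowered.isin(positive_lexicon)
    neg = nonnum & lowered.isin(negative_lexicon)
    bad_categorical = nonnum & ~(pos | neg)

    drop = unmatched | bad_numeric | bad_categorical
    kept = df[~drop].copy()
    kept["value"] = np.where(
        kept["kind"] == "numeric",
        pd.to_numeric(kept["raw_value"], errors="coerce") * kept["factor"],
        lowered[~drop].isin(positive_lexicon).astype(float),
    )

    per_lab_pat = kept.groupby("lab_id")["patient_id"].nunique()
    frequent = set(per_lab_pat.index[per_lab_pat >= min_patients])
    infrequent_events = int((~kept["lab_id"].isin(frequent)).sum())
    kept = kept[kept["lab_id"].isin(frequent)]

    events = kept[["patient_id", "date", "lab_id", "value"]].reset_index(drop=True)
    registry = (
        conversion[conversion["lab_id"].isin(frequent)][
            ["lab_id", "kind", "canonical_unit"]
        ]
        .drop_duplicates("lab_id")
        .sort_values("lab_id")
        .reset_index(drop=True)
    )
    stats = {
        "n_input_events": n_total,
        "n_unmatched": int(unmatched.sum()),
        "n_unparseable_numeric": int(bad_numeric.sum()),
        "n_unmapped_categorical": int(bad_categorical.sum()),
        "n_infrequent_lab_events": infrequent_events,
        "dropped_fraction": (int(drop.sum()) / n_total) if n_total else 0.0,
    }
    logger.info("lab harmonization drop stats: %s", stats)
    return HarmonizedLabs(events, registry, stats)


def _day_numbers(dates: pd.Series) -> np.ndarray:
    return pd.to_datetime(dates).to_numpy().astype("datetime64[D]").astype(np.int64)


def aggregate_diagnoses(
    diag_events: pd.DataFrame,
    encounters: pd.DataFrame,
    window_days: int,
    vocab: list[str],
) -> sp.csr_matrix:
    """Binary presence of each prefix in ``[date(e) - window, date(e))``.

    ``diag_events`` needs columns (patient_id, date, prefix); ``encounters``
    needs (encounter_id, patient_id, date) and defines the row order. The
    lower bound is closed (an event exactly ``window_days`` before counts),
    the upper bound open (same-day events never count).
    """
    vidx = {v: i for i, v in enumerate(vocab)}
    ev = diag_events[diag_events["prefix"].isin(vidx)]
    enc = encounters[["encounter_id", "patient_id", "date"]].copy()
    enc["row"] = np.arange(len(enc))
    enc["enc_day"] = _day_numbers(enc["date"])
    if ev.empty or enc.empty:
        return sp.csr_matrix((len(enc), len(vocab)))
    ev = ev[["patient_id", "date", "prefix"]].copy()
    ev["ev_day"] = _day_numbers(ev["date"])
    ev = ev.drop_duplicates(["patient_id", "ev_day", "prefix"])
    merged = enc.merge(ev, on="patient_id", how="inner")
    hit = (merged["ev_day"] < merged["enc_day"]) & (
        merged["ev_day"] >= merged["enc_day"] - window_days
    )
    pairs = merged.loc[hit, ["row", "prefix"]].drop_duplicates()
    mat = sp.coo_matrix(
        (np.ones(len(pairs)), (pairs["row"], pairs["prefix"].map(vidx))),
        shape=(len(enc), len(vocab)),
    ).tocsr()
    mat.data[:] = 1.0
    return mat


def aggregate_labs(
    harmonized: HarmonizedLabs,
    encounters: pd.DataFrame,
    window_days: int,
) -> tuple[sp.csr_matrix, list[str], list[str]]:
    """Lab sub-matrix: per numeric lab a presence flag and the most recent
    in-window value; per categorical lab a single any-positive flag.

    Same-date duplicate values resolve to the maximum (deterministic).
    Returns (matrix, feature names, modalities).
    """
    reg = harmonized.registry.sort_values("lab_id")
    names: list[str] = []
    mods: list[str] = []
    col_of: dict[tuple[str, str], int] = {}
    for _, r in reg.iterrows():
        if r["kind"] == "numeric":
            col_of[(r["lab_id"], "presence")] = len(names)
            names.append(f"lab_presence:{r['lab_id']}")
            mods.append("lab_presence")
            col_of[(r["lab_id"], "value")] = len(names)
            names.append(f"lab_value:{r['lab_id']}")
            mods.append("lab_value")
        else:
            col_of[(r["lab_id"], "pos")] = len(names)
            names.append(f"lab_pos:{r['lab_id']}")
            mods.append("lab_presence")

    enc = encounters[["encounter_id", "patient_id", "date"]].copy()
    enc["row"] = np.arange(len(enc))
    enc["enc_day"] = _day_numbers(enc["date"])
    ev = harmonized.events.merge(
        reg[["lab_id", "kind"]], on="lab_id", how="inner"
    ).copy()
    if ev.empty or enc.empty:
        return sp.csr_matrix((len(enc), len(names))), names, mods
    ev["ev_day"] = _day_numbers(ev["date"])

    merged = enc.merge(ev, on="patient_id", how="inner")
    hit = (merged["ev_day"] < merged["enc_day"]) & (
        merged["ev_day"] >= merged["enc_day"] - window_days
    )
    m = merged[hit]

    rows_parts, cols_parts, vals_parts = [], [], []
    num = m[m["kind"] == "numeric"]
    if not num.empty:
        num = num.sort_values(["row", "lab_id", "ev_day", "value"], kind="mergesort")
        last = num.groupby(["row", "lab_id"], sort=False).tail(1)
        r = last["row"].to_numpy()
        pres_col = last["lab_id"].map(lambda l: col_of[(l, "presence")]).to_numpy()
        val_col = last["lab_id"].map(lambda l: col_of[(l, "value")]).to_numpy()
        rows_parts += [r, r]
        cols_parts += [pres_col, val_col]
        vals_parts += [np.ones(len(last)), last["value"].to_numpy(float)]
    nn = m[(m["kind"] == "nonnumeric") & (m["value"] > 0)]
    if not nn.empty:
        pairs = nn[["row", "lab_id"]].drop_duplicates()
        rows_parts.append(pairs["row"].to_numpy())
        cols_parts.append(pairs["lab_id"].map(lambda l: col_of[(l, "pos")]).to_numpy())
        vals_parts.append(np.ones(len(pairs)))

    if rows_parts:
        mat = sp.coo_matrix(
            (np.concatenate(vals_parts),
             (np.concatenate(rows_parts), np.concatenate(cols_parts))),
            shape=(len(enc), len(names)),
        ).tocsr()
    else:
        mat = sp.csr_matrix((len(enc), len(names)))
    return mat, names, mods


def demographics_matrix(
    encounters: pd.DataFrame,
    patients: pd.DataFrame,
) -> tuple[sp.csr_matrix, list[str], list[str]]:
    """Age in fractional years plus one-hot sex, per encounter row."""
    names = ["demo:age", "demo:sex_M", "demo:sex_F", "demo:sex_Unknown"]
    mods = ["demo"] * 4
    enc = encounters.merge(
        patients[["patient_id", "birth_date", "sex"]], on="patient_id", how="left"
    )
    age = (_day_numbers(enc["date"]) - _day_numbers(enc["birth_date"])) / 365.25
    if (age < 0).any():
        bad = enc.loc[np.asarray(age) < 0, "encounter_id"].tolist()[:5]
        raise ValueError(f"negative age for encounters {bad}")
    sex = enc["sex"].where(enc["sex"].isin(["M", "F"]), "Unknown")
    block = np.column_stack(
        [age, (sex == "M").astype(float), (sex == "F").astype(float),
         (sex == "Unknown").astype(float)]
    )
    return sp.csr_matrix(block), names, mods


def fuse(
    blocks: list[tuple[sp.spmatrix, list[str], list[str]]],
    schema: FeatureSchema | None = None,
) -> tuple[sp.csr_matrix, FeatureSchema]:
    """Early fusion: concatenate modality blocks column-wise in order.

    If a ``schema`` is given the concatenated names must match it exactly.
    """
    mats = [b[0] for b in blocks]
    names = [n for b in blocks for n in b[1]]
    mods = [m for b in blocks for m in b[2]]
    fused = sp.hstack(mats, format="csr") if mats else sp.csr_matrix((0, 0))
    out_schema = FeatureSchema(names, mods)
    if schema is not None and (schema.names != names or schema.modalities != mods):
        raise ValueError("fused blocks do not match the fitted schema")
    return fused, schema or out_schema


class FeatureBuilder:
    """Fits a feature schema on the training split, then builds aligned
    feature matrices for any encounter set.

    The diagnosis vocabulary is restricted to prefixes observed among the
    training patients' events (excluded-letter prefixes are retained as
    inputs — symptom history is predictive even though such codes are not
    labels). The schema is fixed at fit time; transform refuses mismatches.
    """

    def __init__(
        self,
        windows: WindowConfig = WindowConfig(),
        modalities: tuple[str, ...] = ("demo", "diag", "labs"),
    ) -> None:
        self.windows = windows
        self.modalities = modalities
        self.schema: FeatureSchema | None = None
        self._diag_vocab: list[str] | None = None

    @staticmethod
    def prefix_events(diagnoses: pd.DataFrame) -> pd.DataFrame:
        """Diagnosis events grouped to three-character prefixes (all letters,
        including excluded ones, since these are inputs not labels)."""
        df = diagnoses[["patient_id", "date", "icd10_code"]].copy()
        df["prefix"] = (
            df["icd10_code"].str.strip().str.upper().str.replace(".", "", regex=False).str[:3]
        )
        return df[["patient_id", "date", "prefix"]]

    def fit(
        self,
        patients: pd.DataFrame,
        diagnoses: pd.DataFrame,
        harmonized: HarmonizedLabs | None,
        train_patient_ids: set[str],
    ) -> "FeatureBuilder":
        ev = self.prefix_events(diagnoses)
        ev = ev[ev["patient_id"].isin(train_patient_ids)]
        self._diag_vocab = sorted(ev["prefix"].unique())
        self._patients = patients
        self._diag_events = self.prefix_events(diagnoses)
        self._harmonized = harmonized

        blocks = []
        if "demo" in self.modalities:
            blocks.append((["demo:age", "demo:sex_M", "demo:sex_F", "demo:sex_Unknown"],
                           ["demo"] * 4))
        if "diag" in self.modalities:
            blocks.append(([f"diag:{p}" for p in self._diag_vocab],
                           ["diag"] * len(self._diag_vocab)))
        if "labs" in self.modalities and harmonized is not None:
            _, lnames, lmods = aggregate_labs(
                harmonized, pd.DataFrame(columns=["encounter_id", "patient_id", "date"]),
                self.windows.lab_window_days)
            blocks.append((lnames, lmods))
        names = [n for b in blocks for n in b[0]]
        mods = [m for b in blocks for m in b[1]]
        units = {}
        if harmonized is not None:
            for _, r in harmonized.registry.iterrows():
                if r["kind"] == "numeric":
                    units[f"lab_value:{r['lab_id']}"] = r["canonical_unit"]
        self.schema = FeatureSchema(names, mods, units)
        return self

    def transform(self, encounters: pd.DataFrame) -> FeatureMatrix:
        if self.schema is None:
            raise RuntimeError("FeatureBuilder must be fitted before transform")
        enc = encounters[["encounter_id", "patient_id", "date"]].reset_index(drop=True)
        blocks: list[tuple[sp.spmatrix, list[str], list[str]]] = []
        if "demo" in self.modalities:
            blocks.append(demographics_matrix(enc, self._patients))
        if "diag" in self.modalities:
            mat = aggregate_diagnoses(
                self._diag_events, enc, self.windows.diag_window_days, self._diag_vocab
            )
            blocks.append((mat, [f"diag:{p}" for p in self._diag_vocab],
                           ["diag"] * len(self._diag_vocab)))
        if "labs" in self.modalities and self._harmonized is not None:
            blocks.append(aggregate_labs(self._harmonized, enc,
                                         self.windows.lab_window_days))
        fused, _ = fuse(blocks, self.schema)
        return FeatureMatrix(enc["encounter_id"].tolist(), self.schema, fused)
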